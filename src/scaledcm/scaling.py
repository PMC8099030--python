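"""Scaling transformations for mechanically similar and scale-free systems.

A system is *scalable* if, whenever ``r(t)`` solves its equation of motion, so
does the rescaled trajectory ``b^beta * b * r(b^alpha t)``.  For Newtonian
gravity this holds exactly at ``alpha = -3/2`` (Kepler's third law); for the
linear DCM it holds for any ``alpha`` provided the coupling matrices co-rescale
as ``A -> b^alpha A`` and ``C -> b^(alpha+1) C``.  For z-scored signals the
amplitude exponent ``beta`` drops out, and the temporal exponent is the
negative of the dynamical critical exponent, ``alpha = -z``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .timeseries import InputSeries, Timeseries

__all__ = [
    "ScaleParams",
    "scale_trajectory",
    "scale_inputs",
    "scale_connectivity",
    "alpha_from_z",
    "z_from_alpha",
    "kepler_alpha",
]


@dataclass(frozen=True)
class ScaleParams:
    """Scale factor ``b``, temporal exponent ``alpha``, amplitude exponent ``beta``.

    ``beta`` is fixed at 0 for z-scored signals (the only case exercised here);
    ``b_per_node`` allows node-wise factors in the elementwise connectivity law.
    """

    b: float
    alpha: float
    beta: float = 0.0
    b_per_node: np.ndarray | None = None

    def __post_init__(self):
        if not self.b > 0:
            raise ValueError("scale factor b must be positive")
        if not np.isfinite([self.b, self.alpha, self.beta]).all():
            raise ValueError("scale parameters must be finite")
        if self.b_per_node is not None:
            bpn = np.atleast_1d(np.asarray(self.b_per_node, dtype=float))
            if np.any(bpn <= 0):
                raise ValueError("per-node factors must be positive")
            object.__setattr__(self, "b_per_node", bpn)


def _resample(values: np.ndarray, dt: float, b: float, alpha: float):
    """Evaluate ``series(b^alpha t)`` on the original grid by cubic interpolation.

    Rescaled times beyond the sampled span are truncated (never extrapolated);
    the returned array may therefore be shorter than the input.
    """
    T = values.shape[1]
    t_new = (np.arange(T) * dt) * b**alpha
    span = (T - 1) * dt
    n_valid = int(np.sum(t_new <= span * (1 + 1e-12)))
    if n_valid < 2:
        raise ValueError("rescaled time exceeds the available span everywhere")
    if n_valid < T:
        warnings.warn(
            f"rescaled series truncated to {n_valid}/{T} samples "
            "(rescaled time exceeds the sampled span)",
            stacklevel=3,
        )
    spline = CubicSpline(np.arange(T) * dt, values, axis=1)
    return spline(t_new[:n_valid])


def scale_trajectory(traj: Timeseries, p: ScaleParams) -> Timeseries:
    """Return ``b^beta * b * r(b^alpha t)`` on the original sampling grid."""
    out = p.b**p.beta * p.b * _resample(traj.values, traj.dt, p.b, p.alpha)
    return Timeseries(out, dt=traj.dt, labels=traj.labels)


def scale_inputs(inputs: InputSeries, p: ScaleParams) -> InputSeries:
    """Time-rescaled perturbations ``v(b^alpha t)`` (no amplitude factor)."""
    return InputSeries(_resample(inputs.values, inputs.dt, p.b, p.alpha), dt=inputs.dt)


def scale_connectivity(A: np.ndarray, C: np.ndarray | None, p: ScaleParams):
    """Co-rescale the coupling matrices so the scaled trajectory solves the DCM.

    Uniform case: ``(b^alpha A, b^(alpha+1) C)``.  With per-node factors
    ``b_i``: ``a_ij -> b_i^(alpha+1)/b_j a_ij`` and
    ``c_ij -> b_i^(alpha+2)/b_j c_ij``; all ``b_i = b`` reproduces the uniform
    case exactly.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    C_arr = None if C is None else np.atleast_2d(np.asarray(C, dtype=float))
    if p.b_per_node is None:
        A_s = p.b**p.alpha * A
        C_s = None if C_arr is None else p.b ** (p.alpha + 1) * C_arr
        return A_s, C_s
    bi = p.b_per_node
    if bi.size != A.shape[0]:
        raise ValueError("per-node factor length must match the number of nodes")
    A_s = (bi[:, None] ** (p.alpha + 1) / bi[None, :]) * A
    C_s = None
    if C_arr is not None:
        if C_arr.shape[1] != bi.size:
            raise ValueError(
                "elementwise C scaling needs one factor per input column"
            )
        C_s = (bi[:, None] ** (p.alpha + 2) / bi[None, :]) * C_arr
    return A_s, C_s


def alpha_from_z(z: float) -> float:
    """Temporal rescaling exponent from the dynamical critical exponent."""
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    return -float(z)


def z_from_alpha(alpha: float) -> float:
    """Dynamical critical exponent from the temporal rescaling exponent."""
    if not np.isfinite(alpha):
        raise ValueError("alpha must be finite")
    return -float(alpha)


def kepler_alpha() -> float:
    """The unique temporal exponent making Newtonian gravity scalable.

    Rescaling a gravitational trajectory leaves a residual factor
    ``b^(2 alpha + 3)`` multiplying the central mass; the exponent vanishes at
    ``alpha = -3/2``, which is Kepler's third law (period^2 proportional to
    semi-major-axis^3).
    """
    return float(np.roots([2.0, 3.0])[0])
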