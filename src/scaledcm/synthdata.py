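"""Seeded generators of scalable and scale-free ground-truth data.

Two kinds of input are needed to exercise the full pipeline:

* *scalable series* — families of multivariate timeseries generated from a
  base coupling matrix ``A`` rescaled as ``A_s = b_s^alpha A`` across scales,
  so the family is scalable by construction with a known temporal exponent;
* *scale-free lattices* — square movies whose block-averaged signals have
  characteristic decay times growing as ``2^(z * level)`` with a known
  dynamical critical exponent ``z``, emulating the statistical structure of
  wide-field calcium imaging (without indicator kinetics or atlas geometry).

Lattices are built coarsest-first: the top-level block signal is an
Ornstein-Uhlenbeck (OU) process with the slowest timescale, and each level
below adds faster, block-centred OU innovations to its parent.  Centring the
four innovations of a block makes 2x2 averaging reproduce the parent signal
exactly (up to amplitude, removed by z-scoring), so the generated hierarchy is
self-consistent under the coarse-graining operator.  OU processes use the
exact AR(1) discretisation ``phi = exp(-dt/tau)`` to keep discretisation bias
out of the ground-truth decay times.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dcm import DCMModel, integrate_model
from .renorm import LatticeMovie
from .timeseries import Timeseries, zscore

__all__ = [
    "SynthSpec",
    "generate_scalable_series",
    "generate_scalefree_lattice",
    "write_fixture_set",
]


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic dataset (seed mandatory: fully reproducible).

    ``parent_weight`` is the variance fraction a region inherits from its
    parent block in the scale-free hierarchy; ``scales`` lists the b_s factors
    of a scalable family.
    """

    kind: str
    seed: int
    T: int = 2000
    dt: float = 0.05
    L: int = 16
    z_true: float | None = None
    alpha_true: float | None = None
    base_timescale: float = 0.15
    noise_sd: float = 0.1
    parent_weight: float = 0.2
    n_regions: int = 2
    scales: tuple = tuple(1.1**k for k in range(10))

    def __post_init__(self):
        if self.kind not in ("scalable_series", "scalefree_lattice"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "scalefree_lattice":
            if self.L < 2 or self.L & (self.L - 1):
                raise ValueError("lattice side L must be a power of 2, >= 2")
            if self.z_true is None:
                raise ValueError("scalefree_lattice requires z_true")
        if self.kind == "scalable_series" and self.alpha_true is None:
            raise ValueError("scalable_series requires alpha_true")
        if not self.base_timescale > self.dt:
            raise ValueError("base_timescale must exceed dt")
        if not 0 < self.parent_weight < 1:
            raise ValueError("parent_weight must lie in (0, 1)")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "seed": self.seed,
            "T": self.T,
            "dt": self.dt,
            "L": self.L,
            "z_true": self.z_true,
            "alpha_true": self.alpha_true,
            "base_timescale": self.base_timescale,
            "noise_sd": self.noise_sd,
            "parent_weight": self.parent_weight,
            "n_regions": self.n_regions,
            "scales": list(self.scales),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SynthSpec":
        d = dict(d)
        d["scales"] = tuple(d.get("scales", ()))
        return cls(**d)


# --------------------------------------------------------------------------- #
# scalable families
# --------------------------------------------------------------------------- #


def _draw_stable_A(rng, n, tau, max_tries=100):
    """Stable coupling matrix: diagonal -1/tau, small random off-diagonals."""
    for _ in range(max_tries):
        A = -np.eye(n) / tau
        off = rng.uniform(-0.3, 0.3, size=(n, n)) / tau
        np.fill_diagonal(off, 0.0)
        A = A + off
        if np.all(np.linalg.eigvals(A).real < -1e-6):
            return A
    raise RuntimeError("failed to draw a stable coupling matrix")


def generate_scalable_series(spec: SynthSpec):
    """Family of (b_s, Timeseries, DCMModel) scalable by construction.

    Each scale integrates ``dx/dt = b_s^alpha A x + w`` from a common random
    initial state, so decay times stretch as ``b_s^-alpha`` across the family.
    """
    if spec.kind != "scalable_series":
        raise ValueError("spec.kind must be 'scalable_series'")
    rng = np.random.default_rng(spec.seed)
    A = _draw_stable_A(rng, spec.n_regions, spec.base_timescale)
    x0 = rng.standard_normal(spec.n_regions)
    out = []
    for i, b in enumerate(spec.scales):
        A_s = b**spec.alpha_true * A
        model = DCMModel(A_s, noise_sd=spec.noise_sd)
        seed_s = int(rng.integers(0, 2**31 - 1)) if spec.noise_sd > 0 else None
        ts = integrate_model(model, x0, None, spec.T, spec.dt, seed=seed_s)
        out.append((float(b), ts, model))
    return out


# --------------------------------------------------------------------------- #
# scale-free lattices
# --------------------------------------------------------------------------- #


def _ou(rng, shape, T, dt, tau):
    """Unit-variance OU paths via the exact AR(1) discretisation."""
    phi = np.exp(-dt / tau)
    innov_sd = np.sqrt(1.0 - phi**2)
    x = np.empty((*shape, T))
    x[..., 0] = rng.standard_normal(shape)
    eps = rng.standard_normal((*shape, T - 1)) * innov_sd
    for t in range(1, T):
        x[..., t] = phi * x[..., t - 1] + eps[..., t - 1]
    return x


def generate_scalefree_lattice(spec: SynthSpec):
    """Levels 0 (finest, ``L x L``) through ``2 x 2`` of a scale-free hierarchy.

    Level-k signals have characteristic timescale ``tau0 * 2^(z k)``; 2x2
    averaging of level k reproduces level k+1 exactly up to amplitude.  The
    hierarchy is seeded internally from a single-region top-level process one
    step coarser than the returned movies.  Region signals carry white
    observation noise of sd ``noise_sd`` and are z-scored.
    """
    if spec.kind != "scalefree_lattice":
        raise ValueError("spec.kind must be 'scalefree_lattice'")
    z, tau0, T, dt = spec.z_true, spec.base_timescale, spec.T, spec.dt
    K = int(np.log2(spec.L))
    tau_top = tau0 * 2.0 ** (z * (K - 1))
    if tau_top >= T * dt:
        raise ValueError(
            f"coarsest analysed timescale {tau_top:g} is not measurable within "
            f"the series duration {T * dt:g}; increase T or reduce z/L"
        )
    rng = np.random.default_rng(spec.seed)
    w = spec.parent_weight
    # build coarsest-first; store the *noise-free* signal per level
    signal = _ou(rng, (1, 1), T, dt, tau_top)
    levels_signal = {K: signal}
    for k in range(K - 1, -1, -1):
        Lk = 2 ** (K - k)
        parent = levels_signal[k + 1]
        tau_k = tau0 * 2.0 ** (z * k)
        d = _ou(rng, (Lk // 2, Lk // 2, 2, 2), T, dt, tau_k)
        d = d - d.mean(axis=(2, 3), keepdims=True)  # centred: blocks average out
        d = d / np.sqrt(0.75)  # restore unit variance after centring
        child = np.sqrt(w) * parent[:, None, :, None, :] * np.ones(
            (1, 2, 1, 2, 1)
        ) + np.sqrt(1 - w) * d.transpose(0, 2, 1, 3, 4)
        levels_signal[k] = child.reshape(Lk, Lk, T)
    movies = []
    for k in range(K):  # finest .. 2x2; the 1x1 top seeds the hierarchy only
        v = levels_signal[k]
        if spec.noise_sd > 0:
            v = v + spec.noise_sd * rng.standard_normal(v.shape)
        v = zscore(v, axis=2)
        movies.append(LatticeMovie(v, dt=dt, level=k, zscored=True))
    return movies


# --------------------------------------------------------------------------- #
# fixture sets
# --------------------------------------------------------------------------- #


def _sha256(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def write_fixture_set(specs, directory) -> dict:
    """Write the datasets of ``specs`` plus a manifest; returns the manifest.

    Checksums are over array contents, so regenerating from the manifest
    reproduces identical data regardless of container-level metadata.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"fixtures": []}
    for i, spec in enumerate(specs):
        entry = {"spec": spec.to_dict(), "files": [], "checksums": []}
        if spec.kind == "scalefree_lattice":
            for movie in generate_scalefree_lattice(spec):
                name = f"fixture{i:03d}_level{movie.level}.h5"
                movie.to_hdf5(directory / name)
                entry["files"].append(name)
                entry["checksums"].append(_sha256(movie.values))
        else:
            for s, (b, ts, _model) in enumerate(generate_scalable_series(spec)):
                name = f"fixture{i:03d}_scale{s}.csv"
                ts.to_csv(directory / name)
                entry["files"].append(name)
                entry["checksums"].append(_sha256(ts.values))
        manifest["fixtures"].append(entry)
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    return manifest
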