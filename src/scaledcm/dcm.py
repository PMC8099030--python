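"""Linear stochastic dynamic causal model: generation, inversion, averaging.

The generative model is the linear state-space system

    dx/dt = A x + C v + w(t)

with intrinsic coupling ``A`` (an ``N x N`` Jacobian-like matrix, units 1/time),
extrinsic coupling ``C`` (``N x m``) from external perturbations ``v``, and
random fluctuations ``w``.  Inversion is variational Laplace on a discretised
likelihood, returning a Gaussian posterior over the free elements of ``A`` (and
``C``) together with the variational free energy ``F`` — a lower bound on log
model evidence that is the currency of all second-level analyses.

Two likelihoods are available:

``onestep``
    One-step prediction through the exact propagator,
    ``x[t+1] = expm(A dt) x[t] + drive``.  Exact and statistically efficient
    for decaying (real-spectrum) stochastic dynamics; the default.
``autocov``
    Matches the empirical lagged autocovariance sequence to the model form
    ``R(k dt) = expm(A k dt) R(0)``.  For narrowband oscillatory data
    (e.g. orbital radii) this captures the quadrature component that a
    one-step map cannot see, and is covariant under time rescaling of the
    data — the property the exponent scan relies on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.ndimage import gaussian_filter1d
from scipy.special import logsumexp

from .laplace import variational_laplace
from .timeseries import InputSeries, Timeseries

__all__ = [
    "DCMModel",
    "PriorSpec",
    "LinearDCM",
    "DCMResults",
    "integrate_model",
    "invert_model",
    "bayesian_model_average",
]


# --------------------------------------------------------------------------- #
# model and prior containers
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class DCMModel:
    """Generative model parameters.

    ``noise_sd`` is the standard deviation of the state fluctuations ``w``;
    ``noise_smoothness`` is the temporal correlation length of ``w`` in time
    units (0 means white).
    """

    A: np.ndarray
    C: np.ndarray | None = None
    noise_sd: float = 0.0
    noise_smoothness: float = 0.0

    def __post_init__(self):
        A = np.atleast_2d(np.asarray(self.A, dtype=float))
        if A.shape[0] != A.shape[1]:
            raise ValueError("A must be square")
        if not np.isfinite(A).all():
            raise ValueError("A contains non-finite entries")
        object.__setattr__(self, "A", A)
        C = self.C
        if C is None:
            C = np.zeros((A.shape[0], 0))
        C = np.atleast_2d(np.asarray(C, dtype=float))
        if C.shape[0] != A.shape[0]:
            raise ValueError("C row count must match A")
        if not np.isfinite(C).all():
            raise ValueError("C contains non-finite entries")
        object.__setattr__(self, "C", C)
        if self.noise_sd < 0 or self.noise_smoothness < 0:
            raise ValueError("noise parameters must be non-negative")

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def m(self) -> int:
        return self.C.shape[1]

    @property
    def is_stable(self) -> bool:
        """All eigenvalues of A in the closed left half-plane."""
        return bool(np.all(np.linalg.eigvals(self.A).real <= 1e-12))


@dataclass(frozen=True)
class PriorSpec:
    """Gaussian shrinkage priors over A and C (variance 0 fixes a parameter)."""

    mean_A: np.ndarray
    var_A: np.ndarray
    mean_C: np.ndarray | None = None
    var_C: np.ndarray | None = None

    def __post_init__(self):
        mA = np.atleast_2d(np.asarray(self.mean_A, dtype=float))
        vA = np.atleast_2d(np.asarray(self.var_A, dtype=float))
        if mA.shape != vA.shape or mA.shape[0] != mA.shape[1]:
            raise ValueError("mean_A and var_A must be equal square matrices")
        if np.any(vA < 0):
            raise ValueError("prior variances must be non-negative")
        object.__setattr__(self, "mean_A", mA)
        object.__setattr__(self, "var_A", vA)
        mC = self.mean_C
        vC = self.var_C
        if mC is None:
            mC = np.zeros((mA.shape[0], 0))
            vC = np.zeros((mA.shape[0], 0))
        mC = np.atleast_2d(np.asarray(mC, dtype=float))
        vC = np.atleast_2d(np.asarray(vC, dtype=float))
        if mC.shape != vC.shape or mC.shape[0] != mA.shape[0]:
            raise ValueError("mean_C/var_C shapes inconsistent with A")
        if np.any(vC < 0):
            raise ValueError("prior variances must be non-negative")
        object.__setattr__(self, "mean_C", mC)
        object.__setattr__(self, "var_C", vC)

    @classmethod
    def default(cls, n: int, m: int = 0, *, c_free: bool = False) -> "PriorSpec":
        """Self-inhibiting default: diagonal means -1, off-diagonal 0, variance 1.

        ``C`` defaults to fixed at zero (``c_free=False``), the convention used
        for spontaneous neural recordings where inputs are regressed out.
        """
        mean_A = -np.eye(n)
        var_A = np.ones((n, n))
        mean_C = np.zeros((n, m))
        var_C = np.ones((n, m)) if c_free else np.zeros((n, m))
        return cls(mean_A, var_A, mean_C, var_C)

    @property
    def n(self) -> int:
        return self.mean_A.shape[0]


# --------------------------------------------------------------------------- #
# forward integration
# --------------------------------------------------------------------------- #


def _drive_matrix(A: np.ndarray, C: np.ndarray, dt: float) -> np.ndarray:
    """``int_0^dt expm(A s) ds @ C`` via an augmented matrix exponential."""
    n, m = C.shape
    if m == 0:
        return np.zeros((n, 0))
    aug = np.zeros((n + m, n + m))
    aug[:n, :n] = A
    aug[:n, n:] = C
    return expm(aug * dt)[:n, n:]


def integrate_model(
    model: DCMModel,
    x0,
    inputs: InputSeries | None,
    T: int,
    dt: float,
    seed: int | None = None,
) -> Timeseries:
    """Integrate ``dx/dt = A x + C v (+ w)`` over ``T`` samples of spacing ``dt``.

    Noiseless propagation uses the exact matrix-exponential solution per sample
    step (piecewise-constant inputs).  When ``model.noise_sd > 0`` and a seed is
    given, generation switches to Euler-Maruyama at ``dt/10`` with the
    fluctuations ``w`` drawn as Gaussian noise, optionally smoothed in time with
    a Gaussian kernel of width ``noise_smoothness`` (unit-power normalised), and
    the fine trajectory is subsampled back to ``dt``.
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    if x0.size != model.n:
        raise ValueError("x0 dimension does not match A")
    if dt <= 0 or T < 2:
        raise ValueError("need dt > 0 and T >= 2")
    if inputs is not None and model.m and inputs.values.shape[0] != model.m:
        raise ValueError("input channel count does not match C")
    V = None
    if model.m and inputs is not None:
        V = inputs.values
        if V.shape[1] < T:
            raise ValueError("input series shorter than requested trajectory")

    if model.noise_sd == 0 or seed is None:
        E = expm(model.A * dt)
        M = _drive_matrix(model.A, model.C, dt)
        out = np.empty((model.n, T))
        out[:, 0] = x0
        for t in range(T - 1):
            out[:, t + 1] = E @ out[:, t]
            if V is not None:
                out[:, t + 1] += M @ V[:, t]
        return Timeseries(out, dt=dt)

    # stochastic generation: Euler-Maruyama on a 10x finer grid
    sub = 10
    h = dt / sub
    n_fine = (T - 1) * sub + 1
    rng = np.random.default_rng(seed)
    xi = rng.standard_normal((model.n, n_fine))
    if model.noise_smoothness > 0:
        sigma = model.noise_smoothness / h
        xi = gaussian_filter1d(xi, sigma, axis=1, mode="wrap")
        impulse = np.zeros(min(n_fine, int(8 * sigma) + 9))
        impulse[impulse.size // 2] = 1.0
        kernel_l2 = np.linalg.norm(gaussian_filter1d(impulse, sigma))
        xi /= kernel_l2  # restore unit marginal sd after smoothing
        noise_step = h * model.noise_sd * xi  # smooth process enters the flow
    else:
        noise_step = np.sqrt(h) * model.noise_sd * xi  # white: diffusion scaling

    x = x0.copy()
    out = np.empty((model.n, T))
    out[:, 0] = x0
    for k in range(1, n_fine):
        drift = model.A @ x
        if V is not None:
            drift = drift + model.C @ V[:, min((k - 1) // sub, T - 1)]
        x = x + h * drift + noise_step[:, k - 1]
        if k % sub == 0:
            out[:, k // sub] = x
    return Timeseries(out, dt=dt)


# --------------------------------------------------------------------------- #
# results container
# --------------------------------------------------------------------------- #


@dataclass
class DCMResults:
    """Laplace posterior from one inversion (or a Bayesian model average).

    ``cov`` is the full covariance over the free parameters, ordered as
    ``param_names``; fixed (zero-prior-variance) parameters keep their prior
    mean and do not appear in ``cov``.
    """

    mean_A: np.ndarray
    mean_C: np.ndarray
    cov: np.ndarray
    free_energy: float
    converged: bool
    n_iter: int
    priors: PriorSpec
    param_names: list = field(default_factory=list)
    free_A: np.ndarray | None = None  # boolean mask over A entries
    free_C: np.ndarray | None = None
    lam: float = np.nan
    free_energy_trace: np.ndarray | None = None
    method: str = ""

    # alias used throughout the second-level machinery
    @property
    def F(self) -> float:
        return self.free_energy

    @property
    def theta(self) -> np.ndarray:
        """Posterior mean over the free parameters (A first, then C)."""
        parts = [self.mean_A[self.free_A]]
        if self.free_C is not None and self.free_C.any():
            parts.append(self.mean_C[self.free_C])
        return np.concatenate(parts) if parts else np.empty(0)

    @property
    def n_free(self) -> int:
        return self.cov.shape[0]

    @property
    def sd_A(self) -> np.ndarray:
        """Posterior standard deviations mapped back onto the A matrix."""
        sd = np.zeros_like(self.mean_A)
        n_a = int(self.free_A.sum())
        sd[self.free_A] = np.sqrt(np.diag(self.cov)[:n_a])
        return sd

    # ---------------------------------------------------------- A-marginals
    def posterior_a(self):
        """(mean vector, covariance block) of the free A elements."""
        n_a = int(self.free_A.sum())
        return self.mean_A[self.free_A], self.cov[:n_a, :n_a]

    def prior_a(self):
        """(prior mean vector, diagonal prior covariance) of the free A elements."""
        return (
            self.priors.mean_A[self.free_A],
            np.diag(self.priors.var_A[self.free_A]),
        )

    def a_element_labels(self):
        idx = np.argwhere(self.free_A)
        return [f"a[{i},{j}]" for i, j in idx]

    # ------------------------------------------------------------- summary
    def summary(self) -> str:
        lines = [
            "Linear DCM results",
            "=" * 54,
            f"method: {self.method or 'n/a'}   converged: {self.converged}"
            f"   iterations: {self.n_iter}",
            f"free energy F: {self.free_energy:.4f} nats"
            f"   log noise precision: {self.lam:.3f}",
            "-" * 54,
            f"{'parameter':<12}{'prior mean':>12}{'post mean':>12}{'post sd':>12}",
        ]
        sds = np.sqrt(np.diag(self.cov)) if self.n_free else np.empty(0)
        k = 0
        for (i, j) in np.argwhere(self.free_A):
            lines.append(
                f"{f'a[{i},{j}]':<12}{self.priors.mean_A[i, j]:>12.4f}"
                f"{self.mean_A[i, j]:>12.4f}{sds[k]:>12.4f}"
            )
            k += 1
        if self.free_C is not None:
            for (i, j) in np.argwhere(self.free_C):
                lines.append(
                    f"{f'c[{i},{j}]':<12}{self.priors.mean_C[i, j]:>12.4f}"
                    f"{self.mean_C[i, j]:>12.4f}{sds[k]:>12.4f}"
                )
                k += 1
        lines.append("=" * 54)
        return "\n".join(lines)

    # ---------------------------------------------------------------- JSON
    def to_json(self, path=None) -> str:
        payload = {
            "cov": self.cov.tolist(),
            "converged": bool(self.converged),
            "free_A": self.free_A.tolist(),
            "free_C": self.free_C.tolist() if self.free_C is not None else None,
            "free_energy": float(self.free_energy),
            "lam": float(self.lam),
            "mean_A": self.mean_A.tolist(),
            "mean_C": self.mean_C.tolist(),
            "method": self.method,
            "n_iter": int(self.n_iter),
            "priors": {
                "mean_A": self.priors.mean_A.tolist(),
                "var_A": self.priors.var_A.tolist(),
                "mean_C": self.priors.mean_C.tolist(),
                "var_C": self.priors.var_C.tolist(),
            },
            "shape_A": list(self.mean_A.shape),
            "shape_C": list(self.mean_C.shape),
        }
        text = json.dumps(payload, sort_keys=True, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "DCMResults":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        priors = PriorSpec(
            np.array(payload["priors"]["mean_A"]),
            np.array(payload["priors"]["var_A"]),
            np.array(payload["priors"]["mean_C"]),
            np.array(payload["priors"]["var_C"]),
        )
        return cls(
            mean_A=np.array(payload["mean_A"]),
            mean_C=np.array(payload["mean_C"]),
            cov=np.array(payload["cov"]).reshape(
                len(payload["cov"]), len(payload["cov"])
            )
            if payload["cov"]
            else np.zeros((0, 0)),
            free_energy=payload["free_energy"],
            converged=payload["converged"],
            n_iter=payload["n_iter"],
            priors=priors,
            free_A=np.array(payload["free_A"], dtype=bool),
            free_C=np.array(payload["free_C"], dtype=bool)
            if payload["free_C"] is not None
            else None,
            lam=payload["lam"],
            method=payload["method"],
        )


# --------------------------------------------------------------------------- #
# the model class
# --------------------------------------------------------------------------- #


class LinearDCM:
    """Linear DCM built from data; ``fit()`` returns :class:`DCMResults`.

    Parameters
    ----------
    data : Timeseries
        Observed region signals (N x T).
    inputs : InputSeries, optional
        External perturbations (m x T); omit for autonomous dynamics.
    priors : PriorSpec, optional
        Defaults to the self-inhibiting prior (diag -1, off-diag 0, var 1,
        C fixed at 0).
    method : {"onestep", "autocov"}
        Likelihood, see the module docstring.
    n_lags : int, optional
        Number of autocovariance lags fitted when ``method="autocov"``
        (default ``min(T // 4, 200)``).
    """

    def __init__(self, data, inputs=None, priors=None, method="onestep", n_lags=None):
        if not isinstance(data, Timeseries):
            data = Timeseries(np.asarray(data, dtype=float), dt=1.0)
        self.data = data
        self.inputs = inputs
        n = data.n_regions
        m = inputs.n_inputs if inputs is not None else 0
        self.priors = priors if priors is not None else PriorSpec.default(n, m)
        if self.priors.n != n:
            raise ValueError("prior dimension does not match data")
        if method not in ("onestep", "autocov"):
            raise ValueError(f"unknown method {method!r}")
        self.method = method
        self.n_lags = n_lags
        if method == "autocov" and np.any(self.priors.var_C > 0):
            raise ValueError("autocov likelihood supports free A parameters only")

    @classmethod
    def from_dataframe(cls, df, dt, **kw) -> "LinearDCM":
        return cls(Timeseries.from_dataframe(df, dt=dt), **kw)

    # ------------------------------------------------------------- fitting
    def fit(
        self,
        max_iter: int = 128,
        tol: float = 1e-6,
        fix_noise_log_precision: float | None = None,
        init_A: np.ndarray | None = None,
    ) -> DCMResults:
        pri = self.priors
        free_A = pri.var_A > 0
        free_C = pri.var_C > 0
        n_a, n_c = int(free_A.sum()), int(free_C.sum())
        d = n_a + n_c
        dt = self.data.dt
        Y = self.data.values
        n, T = Y.shape

        def unpack(theta):
            A = pri.mean_A.copy()
            A[free_A] = theta[:n_a]
            C = pri.mean_C.copy()
            if n_c:
                C[free_C] = theta[n_a:]
            return A, C

        if self.method == "onestep":
            X = Y[:, :-1]
            y = Y[:, 1:].ravel()
            V = self.inputs.values[:, : T - 1] if self.inputs is not None else None
            use_drive = V is not None and (n_c > 0 or np.any(pri.mean_C != 0))

            def g(theta):
                A, C = unpack(theta)
                E = expm(A * dt)
                pred = E @ X
                if use_drive:
                    pred = pred + _drive_matrix(A, C, dt) @ V
                return pred.ravel()

        else:  # autocov
            K = self.n_lags if self.n_lags is not None else min(T // 4, 200)
            K = int(min(max(K, 1), T - 1))
            R = np.empty((K + 1, n, n))
            for k in range(K + 1):
                R[k] = (Y[:, k:] @ Y[:, : T - k].T) / (T - k)
            R0 = R[0]
            y = R[1:].ravel()

            def g(theta):
                A, _ = unpack(theta)
                E = expm(A * dt)
                pred = np.empty((K, n, n))
                P = R0
                for k in range(K):
                    P = E @ P
                    pred[k] = P
                return pred.ravel()

        if d > y.size:
            raise ValueError("fewer data points than free parameters")

        theta0 = np.concatenate([pri.mean_A[free_A], pri.mean_C[free_C]])
        prior_var = np.concatenate([pri.var_A[free_A], pri.var_C[free_C]])
        init = None
        if init_A is not None:
            init = theta0.copy()
            init[:n_a] = np.asarray(init_A, dtype=float)[free_A]

        fit = variational_laplace(
            g,
            y,
            theta0,
            prior_var,
            lam=fix_noise_log_precision,
            fix_lam=fix_noise_log_precision is not None,
            max_iter=max_iter,
            tol=tol,
            init=init,
        )
        A_hat, C_hat = unpack(fit.theta)
        names = [f"a[{i},{j}]" for i, j in np.argwhere(free_A)]
        names += [f"c[{i},{j}]" for i, j in np.argwhere(free_C)]
        return DCMResults(
            mean_A=A_hat,
            mean_C=C_hat,
            cov=fit.cov,
            free_energy=fit.free_energy,
            converged=fit.converged,
            n_iter=fit.n_iter,
            priors=pri,
            param_names=names,
            free_A=free_A,
            free_C=free_C,
            lam=fit.lam,
            free_energy_trace=fit.free_energy_trace,
            method=self.method,
        )

    def simulate(self, model: DCMModel, x0, T=None, seed=None) -> Timeseries:
        """Forward-simulate a model on this dataset's grid."""
        T = T if T is not None else self.data.n_samples
        return integrate_model(model, x0, self.inputs, T, self.data.dt, seed=seed)


def invert_model(
    data: Timeseries,
    inputs: InputSeries | None = None,
    priors: PriorSpec | None = None,
    method: str = "onestep",
    **settings,
) -> DCMResults:
    """Invert the linear DCM on ``data`` (see :class:`LinearDCM`)."""
    n_lags = settings.pop("n_lags", None)
    return LinearDCM(data, inputs, priors, method=method, n_lags=n_lags).fit(**settings)


# --------------------------------------------------------------------------- #
# Bayesian model averaging
# --------------------------------------------------------------------------- #


def bayesian_model_average(posteriors, weights: str = "evidence") -> DCMResults:
    """BMA: weighted combination of the first two posterior moments.

    ``weights="evidence"`` (fixed-effects BMA over candidate models of the
    *same* data) weights by softmax(F): averaging identical posteriors returns
    the same posterior, and a posterior whose free energy exceeds the others'
    by tens of nats dominates entirely.  ``weights="equal"`` averages with
    uniform weights — appropriate when pooling fits of *different* datasets
    (e.g. blocks of a lattice), where evidence differences reflect the data
    segments rather than model preference.
    """
    posteriors = list(posteriors)
    if not posteriors:
        raise ValueError("no posteriors to average")
    ref = posteriors[0]
    for p in posteriors[1:]:
        if p.mean_A.shape != ref.mean_A.shape or p.n_free != ref.n_free:
            raise ValueError("posterior dimensions inconsistent")
    Fs = np.array([p.free_energy for p in posteriors])
    if weights == "evidence":
        w = np.exp(Fs - logsumexp(Fs))
    elif weights == "equal":
        w = np.full(len(posteriors), 1.0 / len(posteriors))
    else:
        raise ValueError(f"unknown weighting {weights!r}")
    thetas = np.stack([p.theta for p in posteriors])
    mean = w @ thetas
    cov = np.zeros_like(ref.cov)
    for wi, p, th in zip(w, posteriors, thetas):
        dthe = th - mean
        cov += wi * (p.cov + np.outer(dthe, dthe))
    n_a = int(ref.free_A.sum())
    mean_A = ref.priors.mean_A.copy()
    mean_A[ref.free_A] = mean[:n_a]
    mean_C = ref.priors.mean_C.copy()
    if ref.free_C is not None and ref.free_C.any():
        mean_C[ref.free_C] = mean[n_a:]
    return DCMResults(
        mean_A=mean_A,
        mean_C=mean_C,
        cov=cov,
        free_energy=float(logsumexp(Fs) - np.log(len(posteriors))),
        converged=all(p.converged for p in posteriors),
        n_iter=max(p.n_iter for p in posteriors),
        priors=ref.priors,
        param_names=list(ref.param_names),
        free_A=ref.free_A,
        free_C=ref.free_C,
        lam=float(w @ np.array([p.lam for p in posteriors])),
        method="bma",
    )
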