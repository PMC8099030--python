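"""Renormalization-group coarse graining of lattice timeseries.

Operations on square ``L x L`` movies of region timecourses: per-region
z-scoring, 2x2 block averaging (one coarse-graining step halves ``L`` and
doubles the effective block factor ``b = 2^level``), region-averaged time
correlation functions, characteristic 1/e decay times, and the dynamical
critical exponent ``z`` obtained from the scaling of decay times across
levels, ``t_level ~ 2^(z * level)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import h5py
import numpy as np
import tifffile

from .timeseries import zscore

__all__ = [
    "LatticeMovie",
    "CorrelationProfile",
    "ExponentEstimate",
    "zscore_regions",
    "coarse_grain_step",
    "time_correlation",
    "decay_time",
    "estimate_z_correlation",
]


@dataclass(frozen=True)
class LatticeMovie:
    """``L x L x T`` array of region timecourses at one coarse-graining level."""

    values: np.ndarray
    dt: float
    level: int = 0
    zscored: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[0] != v.shape[1]:
            raise ValueError(f"expected an (L, L, T) array, got shape {v.shape}")
        if not np.isfinite(v).all():
            raise ValueError("movie contains non-finite values")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.level < 0:
            raise ValueError("level must be non-negative")
        object.__setattr__(self, "values", v)

    @property
    def L(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[2]

    @property
    def block_factor(self) -> int:
        """Effective block side relative to the finest level."""
        return 2**self.level

    def flat(self) -> np.ndarray:
        """(L*L, T) view: one row per region."""
        return self.values.reshape(self.L * self.L, self.n_samples)

    # ------------------------------------------------------------------ I/O
    def to_hdf5(self, path, track_times: bool = False) -> None:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("movie", data=self.values, track_times=track_times)
            d.attrs["dt"] = self.dt
            d.attrs["level"] = self.level
            d.attrs["zscored"] = self.zscored

    @classmethod
    def from_hdf5(cls, path) -> "LatticeMovie":
        with h5py.File(path, "r") as f:
            d = f["movie"]
            return cls(
                d[...],
                dt=float(d.attrs["dt"]),
                level=int(d.attrs.get("level", 0)),
                zscored=bool(d.attrs.get("zscored", False)),
            )

    def to_tiff(self, path) -> None:
        # T frames of L x L, float32
        tifffile.imwrite(
            path,
            self.values.transpose(2, 0, 1).astype(np.float32),
            photometric="minisblack",
        )

    @classmethod
    def from_tiff(cls, path, dt: float, level: int = 0) -> "LatticeMovie":
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        return cls(frames.transpose(1, 2, 0), dt=dt, level=level)


@dataclass(frozen=True)
class CorrelationProfile:
    """Region-averaged time correlation function and its 1/e decay time."""

    lags: np.ndarray
    values: np.ndarray
    n_series: int
    decay: float | None = None  # None when no 1/e crossing in range

    def __post_init__(self):
        if self.values[0] <= 0:
            raise ValueError("zero-lag correlation must be positive")

    @property
    def decay_time(self) -> float:
        return decay_time(self)


@dataclass(frozen=True)
class ExponentEstimate:
    """Dynamical critical exponent and how it was obtained."""

    z: float
    method: str
    per_level_decay_times: np.ndarray
    levels: np.ndarray
    b_base: int = 2

    def __post_init__(self):
        if self.method not in ("correlation", "evidence_scan"):
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def alpha(self) -> float:
        """Equivalent temporal rescaling exponent (alpha = -z)."""
        return -self.z


def zscore_regions(movie: LatticeMovie) -> LatticeMovie:
    """Standardise every region's timecourse (population sd convention)."""
    v = movie.values
    sd = v.std(axis=2)
    if np.any(sd == 0):
        i, j = np.argwhere(sd == 0)[0]
        raise ZeroDivisionError(
            f"region ({i}, {j}) at level {movie.level} has zero variance"
        )
    return replace(movie, values=zscore(v, axis=2), zscored=True)


def coarse_grain_step(movie: LatticeMovie) -> LatticeMovie:
    """Average 2x2 neighbouring regions into blocks; halves L, increments level.

    The output is deliberately *not* re-z-scored: block averaging shrinks
    variance and the caller decides whether to restore the unit-variance
    premise before the next analysis step.
    """
    L = movie.L
    if L < 2 or L % 2:
        raise ValueError(f"cannot coarse-grain an L={L} lattice")
    v = movie.values.reshape(L // 2, 2, L // 2, 2, movie.n_samples).mean(axis=(1, 3))
    return LatticeMovie(v, dt=movie.dt, level=movie.level + 1, zscored=False)


def time_correlation(movie: LatticeMovie, max_lag: int) -> CorrelationProfile:
    """Region-averaged autocorrelation ``C(t)`` with time-origin averaging.

    ``C(k dt) = (1/N) sum_i <x_i(t0 + k dt) x_i(t0)>_t0`` where the ensemble
    average runs over all admissible time origins (stationarity assumed).
    """
    if not movie.zscored:
        movie = zscore_regions(movie)
    X = movie.flat()
    N, T = X.shape
    if not 0 < max_lag < T:
        raise ValueError(f"max_lag must lie in (0, {T})")
    vals = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        vals[k] = np.mean(np.sum(X[:, k:] * X[:, : T - k], axis=1) / (T - k))
    lags = np.arange(max_lag + 1) * movie.dt
    prof = CorrelationProfile(lags=lags, values=vals, n_series=N)
    crossing = _first_crossing(lags, vals)
    return replace(prof, decay=crossing)


def _first_crossing(lags, vals):
    thr = vals[0] / np.e
    below = np.nonzero(vals <= thr)[0]
    if below.size == 0:
        return None
    k = below[0]
    if k == 0:
        return 0.0
    # linear interpolation between the bracketing samples
    t = lags[k - 1] + (lags[k] - lags[k - 1]) * (vals[k - 1] - thr) / (
        vals[k - 1] - vals[k]
    )
    return float(t)


def decay_time(profile: CorrelationProfile) -> float:
    """First time at which ``C(t)`` falls to ``C(0)/e`` (linear interpolation)."""
    t = _first_crossing(profile.lags, profile.values)
    if t is None:
        raise ValueError(
            "correlation does not decay to 1/e within the computed lags; "
            "increase max_lag or the series length"
        )
    return t


def estimate_z_correlation(
    movies, max_lag: int | None = None, re_zscore: bool = True
) -> ExponentEstimate:
    """Dynamical critical exponent from decay times across coarse-graining levels.

    ``z`` is the weighted-least-squares slope of ``log2(decay time)`` against
    level (block factor 2 per step); with two equally weighted levels this
    reduces to ``z = log2(t_b / t_r)``.  Levels are weighted by the square
    root of their region count, since the region-averaged correlation profile
    of a coarser level is estimated from fewer series and its decay time is
    correspondingly noisier.
    """
    movies = list(movies)
    if len(movies) < 2:
        raise ValueError("need at least two coarse-graining levels")
    levels, taus, counts = [], [], []
    for mv in movies:
        if re_zscore or not mv.zscored:
            mv = zscore_regions(mv)
        ml = max_lag if max_lag is not None else mv.n_samples // 2
        prof = time_correlation(mv, ml)
        taus.append(decay_time(prof))
        levels.append(mv.level)
        counts.append(prof.n_series)
    levels = np.asarray(levels, dtype=float)
    taus = np.asarray(taus)
    w = np.sqrt(np.asarray(counts, dtype=float))
    slope = float(np.polyfit(levels, np.log2(taus), 1, w=w)[0])
    return ExponentEstimate(
        z=slope,
        method="correlation",
        per_level_decay_times=taus,
        levels=levels.astype(int),
    )
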