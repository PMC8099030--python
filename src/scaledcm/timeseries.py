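"""Core timeseries containers and their file formats.

Everything downstream (model fitting, scaling transforms, coarse graining)
works on these two containers: a multivariate :class:`Timeseries` sampled on a
uniform grid, and an :class:`InputSeries` of external perturbations aligned to
it.  Signals are dimensionless; ``dt`` carries the time units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

__all__ = ["Timeseries", "InputSeries", "zscore"]


def _as_2d(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2:
        raise ValueError(f"expected a (channels, samples) matrix, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class Timeseries:
    """N signals sampled at a uniform interval ``dt``.

    Parameters
    ----------
    values : (N, T) array
        One row per region/state, one column per sample.
    dt : float
        Sampling interval, > 0.
    zscored : bool
        Whether each row has been standardised to zero mean, unit sd.
    labels : tuple of str, optional
        Row labels (region names); defaults to ``r0, r1, ...``.
    """

    values: np.ndarray
    dt: float
    zscored: bool = False
    labels: tuple = field(default=())

    def __post_init__(self):
        object.__setattr__(self, "values", _as_2d(self.values))
        if self.values.shape[0] < 1 or self.values.shape[1] < 2:
            raise ValueError("need at least 1 region and 2 samples")
        if not np.isfinite(self.values).all():
            raise ValueError("timeseries contains non-finite values")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"r{i}" for i in range(self.values.shape[0]))
            )
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("one label per region required")
        if self.zscored:
            mu = self.values.mean(axis=1)
            sd = self.values.std(axis=1)
            if np.abs(mu).max() > 1e-9 or np.abs(sd - 1.0).max() > 1e-6:
                raise ValueError("zscored flag set but rows are not standardised")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    @property
    def duration(self) -> float:
        return (self.n_samples - 1) * self.dt

    def zscore(self) -> "Timeseries":
        """Row-wise standardisation (population sd)."""
        return replace(self, values=zscore(self.values), zscored=True)

    # ------------------------------------------------------------------ I/O
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.T, columns=list(self.labels), index=self.times)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, dt: float, **kw) -> "Timeseries":
        return cls(df.to_numpy().T, dt=dt, labels=tuple(map(str, df.columns)), **kw)

    def to_csv(self, path) -> None:
        # regions x samples, one header row of region labels
        pd.DataFrame(self.values.T, columns=list(self.labels)).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, dt: float, **kw) -> "Timeseries":
        df = pd.read_csv(path)
        return cls.from_dataframe(df, dt=dt, **kw)

    def to_hdf5(self, path, dataset: str = "signals") -> None:
        with h5py.File(path, "w") as f:
            d = f.create_dataset(dataset, data=self.values)
            d.attrs["dt"] = self.dt
            d.attrs["zscored"] = self.zscored
            d.attrs["labels"] = [str(x) for x in self.labels]

    @classmethod
    def from_hdf5(cls, path, dataset: str = "signals") -> "Timeseries":
        with h5py.File(path, "r") as f:
            d = f[dataset]
            labels = tuple(
                x.decode() if isinstance(x, bytes) else str(x)
                for x in d.attrs.get("labels", ())
            )
            return cls(
                d[...],
                dt=float(d.attrs["dt"]),
                zscored=bool(d.attrs.get("zscored", False)),
                labels=labels,
            )


@dataclass(frozen=True)
class InputSeries:
    """m external perturbation channels, aligned with a :class:`Timeseries`."""

    values: np.ndarray
    dt: float

    def __post_init__(self):
        object.__setattr__(self, "values", _as_2d(self.values))
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not np.isfinite(self.values).all():
            raise ValueError("input series contains non-finite values")

    @property
    def n_inputs(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    @classmethod
    def zeros(cls, m: int, T: int, dt: float) -> "InputSeries":
        return cls(np.zeros((max(m, 1), T)), dt=dt)


def zscore(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Standardise to zero mean and unit (population) standard deviation."""
    values = np.asarray(values, dtype=float)
    mu = values.mean(axis=axis, keepdims=True)
    sd = values.std(axis=axis, keepdims=True)
    if np.any(sd == 0):
        raise ZeroDivisionError("zero-variance signal cannot be z-scored")
    return (values - mu) / sd
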