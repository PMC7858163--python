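"""Conditional velocity: SD scores that adjust for regression to the mean.

Two visits give distance-standard Z-scores Z1 and Z2 at gestational ages
t1 < t2 with correlation r.  Because of regression to the mean, an
extreme Z1 is on average followed by a less extreme Z2 even under normal
growth; the conditional SD score

    cSDS = (Z2 - r * Z1) / sqrt(1 - r**2)

standardizes the second visit given the first and is N(0, 1) when the
pair is standard bivariate normal with correlation r.  cSDS > 0 means
growth faster than expected given the first visit; 0 means perfect
tracking.

The correlation r is supplied by a pluggable model: a parametric
exponential family (optionally with a nugget for measurement error) or a
user-provided correlation table interpolated bilinearly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "ConditionalAssessment",
    "CorrelationModel",
    "ExponentialCorrelation",
    "TableCorrelation",
    "conditional_sds",
    "correlation",
    "assess_trajectory",
]

#: Gestational-age window over which pair correlations are defined (weeks).
CORRELATION_WINDOW = (14.0, 40.0)


def conditional_sds(z1, z2, r12, *, literal_denominator: bool = False):
    """Conditional SD score of the second visit given the first.

    Parameters
    ----------
    z1, z2
        Distance-standard Z-scores at the earlier and later visit.
    r12
        Correlation between the two Z-scores; must satisfy ``|r12| < 1``.
    literal_denominator
        If True, divide by ``1 - r12**2`` instead of its square root
        (a rendering of the formula seen in print; it does not have unit
        variance and is off by default).
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    r = np.asarray(r12, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("|r12| must be < 1 (degenerate conditional distribution)")
    denom = (1.0 - r**2) if literal_denominator else np.sqrt(1.0 - r**2)
    out = (z2 - r * z1) / denom
    return float(out) if out.ndim == 0 else out


class CorrelationModel(Protocol):
    """Evaluable correlation between Z-scores at two gestational ages."""

    def __call__(self, t1, t2) -> np.ndarray | float:  # pragma: no cover - protocol
        ...


@dataclass(frozen=True)
class ExponentialCorrelation:
    """r(t1, t2) = (1 - nugget) * exp(-(|t2 - t1| / range_) ** shape).

    ``range_`` (weeks) sets the decay scale, ``shape`` the decay form
    (1 = exponential, 2 = Gaussian), and ``nugget`` in [0, 1) the
    zero-lag correlation deficit attributable to measurement error.
    """

    range_: float
    shape: float = 1.0
    nugget: float = 0.0

    def __post_init__(self) -> None:
        if self.range_ <= 0:
            raise ValueError("range_ must be positive")
        if self.shape <= 0:
            raise ValueError("shape must be positive")
        if not 0.0 <= self.nugget < 1.0:
            raise ValueError("nugget must be in [0, 1)")

    def at_lag(self, lag):
        lag = np.abs(np.asarray(lag, dtype=float))
        out = (1.0 - self.nugget) * np.exp(-((lag / self.range_) ** self.shape))
        return float(out) if out.ndim == 0 else out

    def __call__(self, t1, t2):
        return self.at_lag(np.asarray(t2, dtype=float) - np.asarray(t1, dtype=float))


class TableCorrelation:
    """Correlation surface from a tabulated (t1, t2, r) grid.

    Values between grid points are interpolated bilinearly; the surface
    is symmetrized so r(t1, t2) = r(t2, t1).
    """

    def __init__(self, times: Sequence[float], matrix: np.ndarray):
        times = np.asarray(sorted(float(t) for t in times))
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (times.size, times.size):
            raise ValueError("correlation matrix shape must match the time grid")
        if np.any((matrix < -1) | (matrix > 1)) or np.any(np.isnan(matrix)):
            raise ValueError("correlations must lie in [-1, 1]")
        matrix = (matrix + matrix.T) / 2.0
        self.times = times
        self.matrix = matrix
        self._interp = RegularGridInterpolator(
            (times, times), matrix, method="linear", bounds_error=True
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TableCorrelation":
        """Build from long-format columns t1, t2, r (diagonal optional)."""
        need = {"t1", "t2", "r"}
        if not need.issubset(df.columns):
            raise ValueError(f"correlation table needs columns {sorted(need)}")
        times = np.unique(np.concatenate([df["t1"].to_numpy(float), df["t2"].to_numpy(float)]))
        idx = {t: i for i, t in enumerate(times)}
        m = np.full((times.size, times.size), np.nan)
        np.fill_diagonal(m, 1.0)
        for t1, t2, r in df[["t1", "t2", "r"]].itertuples(index=False):
            m[idx[float(t1)], idx[float(t2)]] = float(r)
            m[idx[float(t2)], idx[float(t1)]] = float(r)
        if np.isnan(m).any():
            raise ValueError("correlation table does not cover the full (t1, t2) grid")
        return cls(times, m)

    @classmethod
    def from_csv(cls, path) -> "TableCorrelation":
        return cls.from_frame(pd.read_csv(path))

    def __call__(self, t1, t2):
        t1 = np.asarray(t1, dtype=float)
        t2 = np.asarray(t2, dtype=float)
        pts = np.stack(np.broadcast_arrays(t1, t2), axis=-1)
        out = self._interp(pts)
        return float(out) if out.ndim == 0 else out


def correlation(model: CorrelationModel, t1, t2):
    """Correlation r12 for a visit pair, with window and validity checks.

    Requires ``14 <= t1 < t2 <= 40`` (weeks) and returns values in (0, 1].
    """
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    lo, hi = CORRELATION_WINDOW
    if np.any(t1 < lo) or np.any(t2 > hi) or np.any(t1 >= t2):
        raise ValueError(
            f"visit pairs must satisfy {lo} <= t1 < t2 <= {hi} weeks"
        )
    r = np.asarray(model(t1, t2), dtype=float)
    if np.any((r <= 0) | (r > 1)):
        raise ValueError("correlation model returned values outside (0, 1]")
    return float(r) if r.ndim == 0 else r


@dataclass(frozen=True)
class ConditionalAssessment:
    """One consecutive visit pair: Z-scores, correlation, and cSDS."""

    t1: float
    t2: float
    z1: float
    z2: float
    r12: float
    csds: float


def assess_trajectory(
    zs: Sequence[tuple[float, float]] | pd.DataFrame,
    model: CorrelationModel,
    *,
    flag_sd: float = 2.0,
) -> pd.DataFrame:
    """Conditional velocity assessment of a per-fetus Z-score series.

    Parameters
    ----------
    zs
        Ordered (ga, z) pairs, or a DataFrame with columns ``ga`` and
        ``z``; gestational ages must be strictly increasing, >= 2 visits.
    model
        Correlation model used for each consecutive visit pair.
    flag_sd
        Absolute cSDS (and Z) threshold used for the ``flag`` column.

    Returns
    -------
    DataFrame with one row per consecutive pair: t1, t2, z1, z2, r12,
    csds and a ``flag`` in {"slow", "normal", "fast"} by ``flag_sd``.
    """
    if isinstance(zs, pd.DataFrame):
        series = list(zip(zs["ga"].astype(float), zs["z"].astype(float)))
    else:
        series = [(float(t), float(z)) for t, z in zs]
    if len(series) < 2:
        raise ValueError("at least 2 visits are required for a velocity assessment")
    gas = [t for t, _ in series]
    if any(b <= a for a, b in zip(gas, gas[1:])):
        raise ValueError("visit gestational ages must be strictly increasing")
    rows = []
    for (t1, z1), (t2, z2) in zip(series, series[1:]):
        r = correlation(model, t1, t2)
        c = conditional_sds(z1, z2, r)
        flag = "slow" if c < -flag_sd else ("fast" if c > flag_sd else "normal")
        rows.append(
            {"t1": t1, "t2": t2, "z1": z1, "z2": z2, "r12": r, "csds": c, "flag": flag}
        )
    return pd.DataFrame(rows)
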