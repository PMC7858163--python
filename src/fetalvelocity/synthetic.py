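"""Synthetic longitudinal cohorts with known ground truth.

The generator emulates a prescriptive longitudinal ultrasound design:
an initial visit in the 14-18 week window followed by scans every
5 +/- 1 weeks inside the protocol windows 14-18, 19-23, 24-28, 29-33,
34-38 and 39-42 weeks, 4-6 scans per fetus, each biometry measured in
triplicate by masked replicates.

The generating model is separable in Z-space: per fetus and biometry a
latent Z trajectory combines a fetus-level random intercept with a
lag-correlated Gaussian process; sizes are the integrated standard mean
velocity plus Z times a gestational-age-dependent size scale, and iid
replicate error is added per measurement.  The size scale is calibrated
numerically so that adjacent-pair increments at the nominal 5-week
interval have the SD of the published velocity standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .conditional import ExponentialCorrelation
from .standards import BiometryCode, StandardSet, VelocityStandard, published_standards

__all__ = [
    "CohortConfig",
    "sample_schedule",
    "simulate_trajectories",
    "scans_frame",
    "truth_frame",
    "interval_census",
]

#: Protocol visit windows (weeks), in order.
DEFAULT_WINDOWS: tuple[tuple[float, float], ...] = (
    (14.0, 18.0),
    (19.0, 23.0),
    (24.0, 28.0),
    (29.0, 33.0),
    (34.0, 38.0),
    (39.0, 42.0),
)

# Placeholder magnitudes (mm); replicate reproducibility was not printed
# with the standard and these are round numbers of the right order.
DEFAULT_MEASUREMENT_ERROR_SD: Mapping[str, float] = {
    "HC": 2.0,
    "BPD": 1.0,
    "OFD": 1.5,
    "AC": 3.0,
    "FL": 1.0,
}

# Approximate attained sizes at 14 weeks (mm), placeholders anchoring the
# integrated size trajectories; increments never depend on them.
DEFAULT_BASELINE_MM: Mapping[str, float] = {
    "HC": 97.0,
    "BPD": 27.0,
    "OFD": 35.0,
    "AC": 78.0,
    "FL": 13.0,
}


@dataclass(frozen=True)
class CohortConfig:
    """Design and noise parameters of the synthetic cohort.

    ``between_fetus_sd`` is the share (in Z units, < 1) of the unit
    latent variance carried by the fetus-level intercept; the remaining
    variance follows the lag ``correlation`` model.  ``z_scale`` scales
    the whole latent Z process (0 gives noiseless trajectories).
    """

    n_fetuses: int = 100
    seed: int = 0
    windows: tuple[tuple[float, float], ...] = DEFAULT_WINDOWS
    start_center: float = 16.0
    start_jitter: float = 1.0
    gap_mean: float = 5.0
    gap_jitter: float = 1.0
    min_visits: int = 4
    max_visits: int = 6
    missed_visit_prob: float = 0.4
    biometries: tuple[str, ...] = ("HC", "BPD", "OFD", "AC", "FL")
    measurement_error_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MEASUREMENT_ERROR_SD)
    )
    baseline_mm: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINE_MM))
    between_fetus_sd: float = 0.7071067811865476  # half the latent variance
    correlation: ExponentialCorrelation = ExponentialCorrelation(range_=10.0, shape=2.0)
    z_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_fetuses < 1:
            raise ValueError("n_fetuses must be >= 1")
        wins = tuple((float(a), float(b)) for a, b in self.windows)
        object.__setattr__(self, "windows", wins)
        for (a, b), (c, d) in zip(wins, wins[1:]):
            if not (a < b < c < d):
                raise ValueError("visit windows must be ordered and non-overlapping")
        if not 4 <= self.min_visits <= self.max_visits <= min(7, len(wins)):
            raise ValueError(
                f"visits must satisfy 4 <= min <= max <= {min(7, len(wins))} "
                "(one scan per protocol window)"
            )
        if not 0.0 <= self.missed_visit_prob <= 1.0:
            raise ValueError("missed_visit_prob must be in [0, 1]")
        if self.gap_jitter < 0 or self.start_jitter < 0:
            raise ValueError("jitters must be >= 0")
        gmin, gmax = self.gap_mean - self.gap_jitter, self.gap_mean + self.gap_jitter
        if gmin <= 0:
            raise ValueError("gap_mean - gap_jitter must be positive")
        # feasibility: propagate the reachable GA interval window by window
        lo = max(wins[0][0], self.start_center - self.start_jitter)
        hi = min(wins[0][1], self.start_center + self.start_jitter)
        lo, hi = min(lo, wins[0][1]), max(hi, wins[0][0])
        for a, b in wins[1:]:
            lo, hi = max(a, lo + gmin), min(b, hi + gmax)
            if lo > hi:
                raise ValueError(
                    f"window {a}-{b} is unreachable with gaps in "
                    f"[{gmin}, {gmax}] weeks under this schedule"
                )
        if not 0.0 <= self.between_fetus_sd < 1.0:
            raise ValueError("between_fetus_sd must be in [0, 1) (Z units)")
        if self.z_scale < 0:
            raise ValueError("z_scale must be >= 0")
        for b in self.biometries:
            BiometryCode.coerce(b)
            if float(self.measurement_error_sd.get(str(b), -1.0)) < 0:
                raise ValueError(f"measurement_error_sd must be >= 0 for {b}")

    def effective_lag_correlation(self, lag) -> np.ndarray | float:
        """Correlation of the latent Z between two visits ``lag`` weeks apart."""
        tau2 = self.between_fetus_sd**2
        return tau2 + (1.0 - tau2) * self.correlation.at_lag(lag)


def sample_schedule(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Visit gestational ages for one fetus.

    The first visit falls in the first window around ``start_center``;
    each later visit advances by gap_mean +/- gap_jitter (uniform) and is
    clipped into its protocol window, preserving gaps within the jitter
    bounds.  After ``min_visits`` visits, each further window is attended
    with probability 1 - ``missed_visit_prob`` until the first miss
    (drop-out), so adjacent observed gaps stay in the 4-6 week class.
    """
    n = config.min_visits
    while n < config.max_visits and rng.uniform() >= config.missed_visit_prob:
        n += 1
    gmin = config.gap_mean - config.gap_jitter
    gmax = config.gap_mean + config.gap_jitter
    lo0, hi0 = config.windows[0]
    t = float(
        np.clip(config.start_center + rng.uniform(-1.0, 1.0) * config.start_jitter, lo0, hi0)
    )
    out = [t]
    for k in range(1, n):
        lo, hi = config.windows[k]
        gap = config.gap_mean + rng.uniform(-1.0, 1.0) * config.gap_jitter
        lo_b, hi_b = max(lo, t + gmin), min(hi, t + gmax)
        if lo_b > hi_b:  # rare edge: prioritize window membership
            lo_b, hi_b = lo, hi
        t = float(np.clip(t + gap, lo_b, hi_b))
        out.append(t)
    return np.asarray(out)


def _calibrated_size_scale(
    standard: VelocityStandard, config: CohortConfig, error_sd: float
) -> tuple[np.ndarray, np.ndarray]:
    """Size-scale curve sigma_s(ga) matching the velocity SD at the nominal gap.

    An adjacent pair (t, t + g) at the nominal gap g has increment variance

        [s(t)**2 + s(t+g)**2 - 2 rho(g) s(t) s(t+g) + 2 sigma_e**2 / 3] / g**2,

    with rho the effective latent lag correlation.  Setting this equal to
    the standard's velocity SD at the mid-point t + g/2 is a quadratic in
    s(t+g) given s(t), so the curve is built by a forward recursion in
    steps of g:

        s(t+g) = rho s(t) + sqrt(T(t+g/2) - s(t)**2 (1 - rho**2)),

    where T(m) = g**2 SD_vel(m)**2 - 2 sigma_e**2 / 3.  The initial
    segment [lo, lo+g) uses the slope-free solution T / (2 (1 - rho));
    every nominal-gap pair thereafter has the exact target variance.
    """
    g = config.gap_mean
    h = g / 2.0
    rho = float(config.effective_lag_correlation(g))
    lo = config.windows[0][0]
    hi = config.windows[-1][1]
    step = 0.1
    n_gap = int(round(g / step))
    grid = lo + step * np.arange(int(round((hi - lo) / step)) + 1)

    def target(m):
        sd = np.asarray(
            standard.sd_model(np.clip(m, standard.ga_range[0], standard.ga_range[1]))
        )
        return np.maximum((g * sd) ** 2 - 2.0 * error_sd**2 / 3.0, 1e-6)

    s = np.empty_like(grid)
    head = grid < lo + g
    s[head] = np.sqrt(target(grid[head]) / (2.0 * (1.0 - rho)))
    for i in np.nonzero(~head)[0]:
        prev = s[i - n_gap]
        disc = target(grid[i] - h) - prev**2 * (1.0 - rho**2)
        s[i] = rho * prev + np.sqrt(max(float(disc), 1e-6))
    return grid, s


def _mean_size_integral(
    standard: VelocityStandard, lo: float, hi: float, step: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative trapezoidal integral of the mean velocity from ``lo``."""
    grid = np.arange(lo, hi + step, step)
    vel = np.asarray(standard.mean_model(grid))
    cum = np.concatenate([[0.0], np.cumsum((vel[1:] + vel[:-1]) / 2.0 * np.diff(grid))])
    return grid, cum


def simulate_trajectories(
    config: CohortConfig,
    standards: StandardSet | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a cohort; one row per (fetus, visit, biometry).

    Columns: fetus_id, ga_weeks, biometry, value_mm, rep1_mm..rep3_mm,
    true_value_mm, true_z.  The reported value is exactly the replicate
    mean; true values follow the generating model with no replicate
    error.  Identical seed and config give identical output; per-fetus
    random streams are spawned deterministically so generation order
    cannot leak between fetuses.
    """
    standards = standards or published_standards()
    biometries = [BiometryCode.coerce(b) for b in config.biometries]
    for b in biometries:
        if b not in standards:
            raise ValueError(f"no standard supplied for biometry {b.value}")
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    children = root.spawn(config.n_fetuses)

    lo = config.windows[0][0]
    hi = config.windows[-1][1]
    integ = {}
    sscale = {}
    for b in biometries:
        std = standards[b]
        integ[b] = _mean_size_integral(std, lo, hi)
        err = float(config.measurement_error_sd.get(b.value, 0.0))
        sscale[b] = _calibrated_size_scale(std, config, err)

    tau = config.between_fetus_sd
    proc_sd = float(np.sqrt(1.0 - tau**2))
    records: dict[str, list] = {
        "fetus_id": [],
        "ga_weeks": [],
        "biometry": [],
        "value_mm": [],
        "rep1_mm": [],
        "rep2_mm": [],
        "rep3_mm": [],
        "true_value_mm": [],
        "true_z": [],
    }
    nb = len(biometries)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        fid = f"F{i:05d}"
        visits = sample_schedule(config, rng)
        nv = visits.size
        lag = np.abs(visits[:, None] - visits[None, :])
        corr = np.asarray(config.correlation.at_lag(lag))
        np.fill_diagonal(corr, 1.0)
        # tiny jitter guards the Cholesky against numerically singular grids
        L = np.linalg.cholesky(corr + 1e-10 * np.eye(nv))
        G = L @ rng.standard_normal((nv, nb))
        alpha = rng.standard_normal(nb)
        Z = config.z_scale * (tau * alpha[None, :] + proc_sd * G)
        for j, b in enumerate(biometries):
            ggrid, cum = integ[b]
            sgrid, sval = sscale[b]
            base = float(config.baseline_mm.get(b.value, 0.0))
            true_val = (
                base
                + np.interp(visits, ggrid, cum)
                + np.interp(visits, sgrid, sval) * Z[:, j]
            )
            err = float(config.measurement_error_sd.get(b.value, 0.0))
            reps = true_val[:, None] + err * rng.standard_normal((nv, 3))
            value = reps.mean(axis=1)
            records["fetus_id"].extend([fid] * nv)
            records["ga_weeks"].extend(visits.tolist())
            records["biometry"].extend([b.value] * nv)
            records["value_mm"].extend(value.tolist())
            records["rep1_mm"].extend(reps[:, 0].tolist())
            records["rep2_mm"].extend(reps[:, 1].tolist())
            records["rep3_mm"].extend(reps[:, 2].tolist())
            records["true_value_mm"].extend(true_val.tolist())
            records["true_z"].extend(Z[:, j].tolist())
    return pd.DataFrame(records)


def scans_frame(records: pd.DataFrame) -> pd.DataFrame:
    """Project simulated records onto the longitudinal scans CSV schema."""
    cols = ["fetus_id", "ga_weeks", "biometry", "value_mm", "rep1_mm", "rep2_mm", "rep3_mm"]
    return records[cols].copy()


def truth_frame(records: pd.DataFrame) -> pd.DataFrame:
    """Ground-truth sidecar (true size and latent Z per visit)."""
    cols = ["fetus_id", "ga_weeks", "biometry", "true_value_mm", "true_z"]
    return records[cols].copy()


def interval_census(records: pd.DataFrame) -> pd.Series:
    """Completed-week histogram of adjacent visit intervals.

    Counts each fetus's consecutive-visit gaps (one biometry counted
    once), floored to completed weeks.
    """
    one = records.drop_duplicates(["fetus_id", "ga_weeks"]).sort_values(
        ["fetus_id", "ga_weeks"]
    )
    gaps = one.groupby("fetus_id")["ga_weeks"].diff().dropna()
    return np.floor(gaps).astype(int).value_counts().sort_index()
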