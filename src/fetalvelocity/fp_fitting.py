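"""Chart construction: fractional polynomial fits of velocity increments.

The pipeline mirrors how age-specific reference intervals are built from
longitudinal increments: the mean increment is regressed on mid-interval
gestational age over all fractional polynomial power combinations of a
given degree (minimum residual sum of squares wins), the SD is then
estimated by regressing scaled absolute residuals sqrt(pi/2) * |e| on
gestational age (unbiased for a normal SD), and goodness of fit is
reported as per-completed-week empirical vs fitted centiles, residual
q-q data, and coverage outside the named centiles.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fpmodel import FP_POWERS, FPModel, fp_basis
from .increments import VelocityObservation, observations_to_frame
from .standards import (
    NAMED_CENTILE_MULTIPLIERS,
    NAMED_CENTILES,
    BiometryCode,
    VelocityStandard,
)

__all__ = [
    "FPFitResult",
    "GofReport",
    "fit_fp",
    "fit_velocity_standard",
    "empirical_centiles",
    "fp_basis",
]


@dataclass(frozen=True)
class FPFitResult:
    """Best fractional polynomial fit over the candidate power set."""

    model: FPModel
    rss: float
    degree: int
    candidate_count: int
    candidates: pd.DataFrame = field(repr=False)  # powers, rss per candidate

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "rss": self.rss,
            "degree": self.degree,
            "candidate_count": self.candidate_count,
            "candidates": [
                {"powers": list(p), "rss": r}
                for p, r in zip(self.candidates["powers"], self.candidates["rss"])
            ],
        }


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least squares with explicit intercept column; returns (beta, rss)."""
    A = np.column_stack([np.ones(len(y)), X])
    beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    return beta, float(resid @ resid)


def fit_fp(
    x,
    y,
    degree: int = 2,
    *,
    scale: float = 1.0,
    powers: Sequence[float] = FP_POWERS,
) -> FPFitResult:
    """Exhaustive fractional polynomial fit of ``y`` on ``x``.

    Every combination (with repetition) of ``degree`` powers from the
    candidate set is fitted by least squares; the minimum-RSS model wins,
    with ties broken by lexicographic power order (first enumerated kept).

    Parameters
    ----------
    x, y
        Predictor (strictly positive after division by ``scale``) and
        response.
    degree
        Number of FP terms (1 or 2 in practice).
    scale
        Divisor applied to ``x`` before exponentiation, stored on the
        returned model.
    powers
        Candidate power set (default the canonical 8 powers).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if len(x) < degree + 2:
        raise ValueError(
            f"need at least {degree + 2} points to fit an FP{degree} model, got {len(x)}"
        )
    s = x / scale
    if np.any(s <= 0):
        raise ValueError("scaled predictor must be strictly positive")
    combos = list(itertools.combinations_with_replacement(sorted(set(float(p) for p in powers)), degree))
    best: tuple[tuple[float, ...], np.ndarray, float] | None = None
    records = []
    for combo in combos:
        X = fp_basis(s, combo)
        beta, rss = _ols(X, y)
        records.append({"powers": combo, "rss": rss})
        if best is None or rss < best[2] - 1e-12 * max(1.0, best[2]):
            best = (combo, beta, rss)
    assert best is not None
    combo, beta, rss = best
    model = FPModel(powers=combo, coefficients=tuple(beta), scale=scale)
    return FPFitResult(
        model=model,
        rss=rss,
        degree=degree,
        candidate_count=len(combos),
        candidates=pd.DataFrame(records),
    )


def empirical_centiles(
    values, centiles: Sequence[float] = NAMED_CENTILES, min_n: int = 1
) -> dict[float, float]:
    """Order-statistic centiles of one completed-week bin of increments."""
    arr = np.asarray(values, dtype=float)
    if arr.size < min_n or arr.size == 0:
        raise ValueError(f"bin has {arr.size} observations, fewer than min_n={min_n}")
    qs = np.percentile(arr, list(centiles))
    return {float(p): float(q) for p, q in zip(centiles, qs)}


@dataclass
class GofReport:
    """Goodness-of-fit diagnostics for a fitted velocity standard.

    ``week_table`` holds per-completed-week empirical vs fitted centiles;
    ``coverage`` the per-week proportions outside each named centile;
    ``qq`` ordered residual Z-scores against normal quantiles;
    ``z_mean``/``z_sd`` summarize the fitted Z-score distribution.
    """

    week_table: pd.DataFrame
    coverage: pd.DataFrame
    qq: pd.DataFrame
    z_mean: float
    z_sd: float

    def export(self, prefix: str) -> list[str]:
        """Write week-table, coverage and q-q CSVs; returns the paths."""
        paths = []
        for name, frame in [
            ("week_centiles", self.week_table),
            ("coverage", self.coverage),
            ("qq", self.qq),
        ]:
            path = f"{prefix}_{name}.csv"
            frame.to_csv(path, index=False)
            paths.append(path)
        return paths


def _as_frame(obs) -> pd.DataFrame:
    if isinstance(obs, pd.DataFrame):
        return obs
    return observations_to_frame(list(obs))


def fit_velocity_standard(
    obs: Iterable[VelocityObservation] | pd.DataFrame,
    *,
    biometry: BiometryCode | str | None = None,
    mean_degree: int = 2,
    mean_scale: float = 10.0,
    sd_families: Sequence[tuple[tuple[float, ...], float]] = (((1.0,), 1.0), ((3.0,), 10.0)),
    ga_range: tuple[float, float] = (16.0, 38.0),
    decimals: int | None = None,
    min_per_week: int = 20,
) -> tuple[VelocityStandard, GofReport, FPFitResult]:
    """Fit a velocity-increment standard from paired observations.

    Parameters
    ----------
    obs
        Velocity observations for a single biometry (objects or a frame
        with columns mid_ga, increment and optionally biometry).
    biometry
        Code for the fitted standard; inferred from the data if absent.
    mean_degree, mean_scale
        FP degree and predictor scaling for the mean model (defaults:
        FP2 on gestational age / 10, the published convention).
    sd_families
        Candidate (powers, scale) families for the SD curve, selected by
        RSS of the scaled-absolute-residual regression.  Defaults are the
        two published families: linear in GA and cubic in GA/10.
    min_per_week
        Minimum observations for a completed-week bin to enter the
        empirical-centile table (smaller bins are skipped).

    Returns
    -------
    (standard, gof_report, mean_fit)
    """
    frame = _as_frame(obs)
    if biometry is None:
        codes = set(frame.get("biometry", pd.Series(dtype=str)))
        if len(codes) != 1:
            raise ValueError("biometry must be given when observations do not carry one code")
        biometry = codes.pop()
    biometry = BiometryCode.coerce(biometry)
    mid = frame["mid_ga"].to_numpy(dtype=float)
    v = frame["increment"].to_numpy(dtype=float)
    if np.any(mid <= 0):
        raise ValueError("mid-interval gestational ages must be positive")
    if len(v) < 10:
        raise ValueError(
            f"underdetermined fit: {len(v)} velocity observations "
            "(mean and SD curves need at least 10)"
        )

    mean_fit = fit_fp(mid, v, degree=mean_degree, scale=mean_scale)
    resid = v - np.asarray(mean_fit.model(mid))

    # SD: regress sqrt(pi/2)*|e| on GA within each candidate family; the
    # scaling makes the fit unbiased for a normal residual SD.
    target = np.sqrt(np.pi / 2.0) * np.abs(resid)
    best_sd: tuple[FPModel, float] | None = None
    for powers, scale in sd_families:
        X = fp_basis(mid / scale, powers)
        beta, rss = _ols(X, target)
        if best_sd is None or rss < best_sd[1]:
            best_sd = (FPModel(powers=tuple(powers), coefficients=tuple(beta), scale=scale), rss)
    assert best_sd is not None
    sd_model = best_sd[0]

    standard = VelocityStandard(
        biometry=biometry,
        mean_model=mean_fit.model,
        sd_model=sd_model,
        ga_range=ga_range,
        decimals=decimals if decimals is not None else (2 if biometry is BiometryCode.HC else 1),
    )
    report = _gof_report(standard, mid, v, min_per_week=min_per_week)
    return standard, report, mean_fit


def _gof_report(
    standard: VelocityStandard, mid: np.ndarray, v: np.ndarray, *, min_per_week: int
) -> GofReport:
    sd_vals = np.asarray(standard.sd_model(mid))
    if np.any(sd_vals <= 0):
        raise ValueError("fitted SD model is not positive over the data range")
    z = (v - np.asarray(standard.mean_model(mid))) / sd_vals
    weeks = np.floor(mid).astype(int)  # completed weeks: 38 = 38+0 .. 38+6
    week_rows, cov_rows = [], []
    for wk in np.unique(weeks):
        sel = v[weeks == wk]
        zsel = z[weeks == wk]
        if sel.size < min_per_week:
            continue
        emp = empirical_centiles(sel)
        mu_w, sd_w = float(standard.mean_model(wk + 0.5)), float(standard.sd_model(wk + 0.5))
        row = {"week": int(wk), "n": int(sel.size)}
        cov = {"week": int(wk), "n": int(sel.size)}
        for p, mult in NAMED_CENTILE_MULTIPLIERS.items():
            row[f"emp_c{p:g}"] = emp[p]
            row[f"fit_c{p:g}"] = mu_w + mult * sd_w
            if p < 50:
                cov[f"below_c{p:g}"] = float(np.mean(zsel < mult))
            elif p > 50:
                cov[f"above_c{p:g}"] = float(np.mean(zsel > mult))
        week_rows.append(row)
        cov_rows.append(cov)
    zs = np.sort(z)
    theo = stats.norm.ppf((np.arange(1, zs.size + 1) - 0.5) / zs.size)
    qq = pd.DataFrame({"normal_quantile": theo, "residual_z": zs})
    return GofReport(
        week_table=pd.DataFrame(week_rows),
        coverage=pd.DataFrame(cov_rows),
        qq=qq,
        z_mean=float(np.mean(z)),
        z_sd=float(np.std(z, ddof=1)),
    )


def export_fit_report(path, standard: VelocityStandard, mean_fit: FPFitResult) -> None:
    """Write the fitted standard as a loadable standard-definition JSON.

    The file follows the standard-definition schema (so it can be passed
    anywhere a standard is accepted) with the mean-fit search record
    (powers, rss per candidate) attached under ``mean_fit``.
    """
    payload = {
        "name": "Refitted velocity increment standard",
        "ga_unit": "weeks",
        "value_unit": "mm/wk",
        "biometries": {standard.biometry.value: standard.to_dict()},
        "mean_fit": mean_fit.to_dict(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
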