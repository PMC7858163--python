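"""Velocity increments from longitudinal scan records.

An increment is (Y2 - Y1) / (t2 - t1) in mm/wk for a pair of scans of the
same fetus and biometry, carried at the mid-interval gestational age
(t1 + t2) / 2.  Scan protocols with visits every ~5 weeks yield adjacent
intervals of 4-6 weeks and one-skip intervals of 8-12 weeks; pairing
policy and interval bounds are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .standards import BiometryCode

__all__ = [
    "Measurement",
    "VelocityObservation",
    "PAIRING_POLICIES",
    "triplicate_average",
    "velocity_increment",
    "build_pairs",
    "pairs_from_frame",
    "observations_to_frame",
]

PAIRING_POLICIES = ("adjacent", "adjacent_plus_one_skip", "all_pairs")

#: Default interval bounds (weeks): the protocol's adjacent 4/5/6-week
#: intervals plus their 8-12-week combinations; nothing shorter or longer.
DEFAULT_INTERVAL_BOUNDS = (4.0, 12.0)


def triplicate_average(values: Sequence[float]) -> float:
    """Arithmetic mean of the three masked replicate measurements (mm)."""
    vals = [float(v) for v in values]
    if len(vals) != 3:
        raise ValueError(f"expected exactly 3 replicate values, got {len(vals)}")
    if any(v <= 0 for v in vals):
        raise ValueError("replicate measurements must be positive (mm)")
    return sum(vals) / 3.0


@dataclass(frozen=True)
class Measurement:
    """One biometry value (mm) at one gestational age for one fetus.

    If ``replicates`` is given, ``value`` may be omitted and defaults to
    their mean; if both are given they must agree.
    """

    fetus_id: str
    biometry: BiometryCode
    ga: float
    value: float | None = None
    replicates: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "biometry", BiometryCode.coerce(self.biometry))
        object.__setattr__(self, "ga", float(self.ga))
        if not 0.0 < self.ga < 45.0:
            raise ValueError(f"gestational age {self.ga} outside (0, 45) weeks")
        if self.replicates is not None:
            reps = tuple(float(v) for v in self.replicates)
            object.__setattr__(self, "replicates", reps)
            mean = triplicate_average(reps)
            if self.value is None:
                object.__setattr__(self, "value", mean)
            elif abs(float(self.value) - mean) > 1e-6:
                raise ValueError(
                    f"value {self.value} is not the mean of replicates {reps}"
                )
        if self.value is None:
            raise ValueError("either value or replicates must be provided")
        object.__setattr__(self, "value", float(self.value))
        if self.value <= 0:
            raise ValueError(f"measurement value must be positive, got {self.value}")


@dataclass(frozen=True)
class VelocityObservation:
    """A velocity increment (mm/wk) carried at the mid-interval GA."""

    fetus_id: str
    biometry: BiometryCode
    mid_ga: float
    increment: float
    interval: float
    from_ga: float
    to_ga: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "biometry", BiometryCode.coerce(self.biometry))
        if not self.interval > 0:
            raise ValueError("interval must be positive")
        if abs(self.to_ga - self.from_ga - self.interval) > 1e-9:
            raise ValueError("interval must equal to_ga - from_ga")
        if abs((self.from_ga + self.to_ga) / 2.0 - self.mid_ga) > 1e-9:
            raise ValueError("mid_ga must be the interval midpoint")


def velocity_increment(m1: Measurement, m2: Measurement) -> VelocityObservation:
    """Velocity increment (Y2 - Y1) / (t2 - t1) for a pair of scans."""
    if m1.fetus_id != m2.fetus_id:
        raise ValueError("measurements are from different fetuses")
    if m1.biometry != m2.biometry:
        raise ValueError("measurements are of different biometries")
    dt = m2.ga - m1.ga
    if dt == 0:
        raise ValueError(
            f"zero interval at GA {m1.ga} for fetus {m1.fetus_id}: duplicated visit"
        )
    if dt < 0:
        raise ValueError("m2 must be the later scan (t2 > t1)")
    return VelocityObservation(
        fetus_id=m1.fetus_id,
        biometry=m1.biometry,
        mid_ga=(m1.ga + m2.ga) / 2.0,
        increment=(m2.value - m1.value) / dt,
        interval=dt,
        from_ga=m1.ga,
        to_ga=m2.ga,
    )


def _pair_indices(n: int, policy: str) -> list[tuple[int, int]]:
    if policy == "adjacent":
        return [(i, i + 1) for i in range(n - 1)]
    if policy == "adjacent_plus_one_skip":
        out = []
        for i in range(n - 1):
            out.append((i, i + 1))
            if i + 2 < n:
                out.append((i, i + 2))
        return out
    if policy == "all_pairs":
        return [(i, j) for i in range(n - 1) for j in range(i + 1, n)]
    raise ValueError(f"unknown pairing policy {policy!r}; expected one of {PAIRING_POLICIES}")


def build_pairs(
    scans: Iterable[Measurement],
    policy: str = "adjacent_plus_one_skip",
    interval_bounds: tuple[float, float] = DEFAULT_INTERVAL_BOUNDS,
) -> list[VelocityObservation]:
    """Pair longitudinal scans into velocity observations.

    Scans are grouped by (fetus, biometry); within each group they must be
    sorted by gestational age.  Duplicate visits at identical GA keep the
    first scan with a warning (a zero denominator is a protocol violation,
    not data).  Pairs whose interval falls outside ``interval_bounds``
    (inclusive, weeks) are dropped.  Output ordering is deterministic:
    by fetus, biometry, from_ga, to_ga.
    """
    lo, hi = interval_bounds
    if not 0 < lo <= hi:
        raise ValueError(f"invalid interval bounds {interval_bounds}")
    groups: dict[tuple[str, BiometryCode], list[Measurement]] = {}
    for m in scans:
        groups.setdefault((m.fetus_id, m.biometry), []).append(m)
    out: list[VelocityObservation] = []
    for key in sorted(groups, key=lambda k: (str(k[0]), k[1].value)):
        series = groups[key]
        gas = [m.ga for m in series]
        if gas != sorted(gas):
            raise ValueError(f"scans for fetus {key[0]} / {key[1].value} are not sorted by GA")
        deduped: list[Measurement] = []
        for m in series:
            if deduped and m.ga == deduped[-1].ga:
                warnings.warn(
                    f"duplicate visit at GA {m.ga} for fetus {m.fetus_id} "
                    f"({m.biometry.value}): keeping the first scan",
                    stacklevel=2,
                )
                continue
            deduped.append(m)
        for i, j in _pair_indices(len(deduped), policy):
            obs = velocity_increment(deduped[i], deduped[j])
            if lo <= obs.interval <= hi:
                out.append(obs)
    return out


def pairs_from_frame(
    df: pd.DataFrame,
    policy: str = "adjacent_plus_one_skip",
    interval_bounds: tuple[float, float] = DEFAULT_INTERVAL_BOUNDS,
) -> pd.DataFrame:
    """Vectorised pairing for a longitudinal scans DataFrame.

    ``df`` must have columns fetus_id, ga_weeks, biometry, value_mm (the
    longitudinal CSV schema).  Returns one row per velocity observation
    with columns fetus_id, biometry, from_ga, to_ga, mid_ga, interval,
    increment.  Semantics match :func:`build_pairs`.
    """
    lo, hi = interval_bounds
    if not 0 < lo <= hi:
        raise ValueError(f"invalid interval bounds {interval_bounds}")
    if policy not in PAIRING_POLICIES:
        raise ValueError(f"unknown pairing policy {policy!r}; expected one of {PAIRING_POLICIES}")
    work = df[["fetus_id", "biometry", "ga_weeks", "value_mm"]].copy()
    work["biometry"] = [BiometryCode.coerce(b).value for b in work["biometry"]]
    work = work.sort_values(["fetus_id", "biometry", "ga_weeks"], kind="mergesort")
    dup = work.duplicated(["fetus_id", "biometry", "ga_weeks"])
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} duplicate visits (identical GA) dropped, keeping first scans",
            stacklevel=2,
        )
        work = work[~dup]
    shifts = {"adjacent": (1,), "adjacent_plus_one_skip": (1, 2), "all_pairs": None}[policy]
    if shifts is None:
        max_n = int(work.groupby(["fetus_id", "biometry"]).size().max()) if len(work) else 0
        shifts = tuple(range(1, max_n))
    grp = work.groupby(["fetus_id", "biometry"], sort=False)
    frames = []
    for k in shifts:
        nxt = grp[["ga_weeks", "value_mm"]].shift(-k)
        mask = nxt["ga_weeks"].notna()
        pair = work[mask].copy()
        pair["to_ga"] = nxt.loc[mask, "ga_weeks"].to_numpy()
        pair["to_value"] = nxt.loc[mask, "value_mm"].to_numpy()
        frames.append(pair)
    if not frames:
        return pd.DataFrame(
            columns=["fetus_id", "biometry", "from_ga", "to_ga", "mid_ga", "interval", "increment"]
        )
    pairs = pd.concat(frames, ignore_index=True)
    pairs = pairs.rename(columns={"ga_weeks": "from_ga", "value_mm": "from_value"})
    pairs["interval"] = pairs["to_ga"] - pairs["from_ga"]
    pairs = pairs[(pairs["interval"] >= lo) & (pairs["interval"] <= hi)]
    pairs["mid_ga"] = (pairs["from_ga"] + pairs["to_ga"]) / 2.0
    pairs["increment"] = (pairs["to_value"] - pairs["from_value"]) / pairs["interval"]
    pairs = pairs.sort_values(["fetus_id", "biometry", "from_ga", "to_ga"], kind="mergesort")
    cols = ["fetus_id", "biometry", "from_ga", "to_ga", "mid_ga", "interval", "increment"]
    return pairs[cols].reset_index(drop=True)


def observations_to_frame(observations: Iterable[VelocityObservation]) -> pd.DataFrame:
    """Tabulate velocity observations (one row per pair)."""
    rows = [
        {
            "fetus_id": o.fetus_id,
            "biometry": o.biometry.value,
            "from_ga": o.from_ga,
            "to_ga": o.to_ga,
            "mid_ga": o.mid_ga,
            "interval": o.interval,
            "increment": o.increment,
        }
        for o in observations
    ]
    return pd.DataFrame(
        rows, columns=["fetus_id", "biometry", "from_ga", "to_ga", "mid_ga", "interval", "increment"]
    )
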