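"""Evaluation of fetal growth velocity-increment standards.

The published standard gives, for each of the five routine biometry
measures (HC, BPD, OFD, AC, FL), a fractional polynomial model for the
mean and for the SD of the velocity increment (mm/wk) as a function of
gestational age, valid over 16-38 completed weeks.  Centiles follow the
normal model mean + z * SD with the fixed multipliers z = -1.88, -1.645,
-1.28, 0, 1.28, 1.645, 1.88 for the 3rd/5th/10th/50th/90th/95th/97th
centiles.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .fpmodel import FPModel, chart_round

__all__ = [
    "BiometryCode",
    "VelocityStandard",
    "StandardSet",
    "GARangeWarning",
    "NAMED_CENTILE_MULTIPLIERS",
    "centile_multiplier",
    "load_standard_set",
    "published_standards",
    "mean_velocity",
    "sd_velocity",
    "centile_velocity",
    "zscore_velocity",
    "centile_table",
    "peak_velocity",
    "percent_of_term_size",
    "export_chart_csv",
]


class BiometryCode(str, enum.Enum):
    """The five standard fetal ultrasound biometry measures (mm)."""

    HC = "HC"  # head circumference
    BPD = "BPD"  # biparietal diameter
    OFD = "OFD"  # occipitofrontal diameter
    AC = "AC"  # abdominal circumference
    FL = "FL"  # femur length

    @classmethod
    def coerce(cls, value: "BiometryCode | str") -> "BiometryCode":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).upper())
        except ValueError:
            raise ValueError(
                f"unknown biometry code {value!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


class GARangeWarning(UserWarning):
    """Gestational age outside the validated range of a standard."""


#: Printed normal multipliers for the seven named chart centiles.
NAMED_CENTILE_MULTIPLIERS: Mapping[float, float] = {
    3.0: -1.88,
    5.0: -1.645,
    10.0: -1.28,
    50.0: 0.0,
    90.0: 1.28,
    95.0: 1.645,
    97.0: 1.88,
}

NAMED_CENTILES: tuple[float, ...] = tuple(NAMED_CENTILE_MULTIPLIERS)

#: Hard evaluation domain for gestational age (weeks); no pregnancy
#: reaches 45 weeks, so outside it evaluation is an error, not a warning.
GA_HARD_BOUNDS = (0.0, 45.0)


def centile_multiplier(p: float) -> float:
    """Normal multiplier for the ``p``-th centile.

    The seven named chart centiles use the printed multipliers exactly
    (so tables reproduce bit-for-bit); any other p in (0, 100) maps to
    the standard-normal quantile.
    """
    p = float(p)
    if not 0.0 < p < 100.0:
        raise ValueError(f"centile must be in (0, 100), got {p}")
    if p in NAMED_CENTILE_MULTIPLIERS:
        return NAMED_CENTILE_MULTIPLIERS[p]
    return float(stats.norm.ppf(p / 100.0))


@dataclass(frozen=True)
class VelocityStandard:
    """Mean/SD model pair for one biometry's velocity increment."""

    biometry: BiometryCode
    mean_model: FPModel
    sd_model: FPModel
    ga_range: tuple[float, float] = (16.0, 38.0)
    decimals: int = 1  # printed chart precision

    def __post_init__(self) -> None:
        object.__setattr__(self, "biometry", BiometryCode.coerce(self.biometry))
        lo, hi = self.ga_range
        if not (GA_HARD_BOUNDS[0] < lo < hi <= GA_HARD_BOUNDS[1]):
            raise ValueError(f"invalid ga_range {self.ga_range}")
        grid = np.linspace(lo, hi, 221)
        mu, sd = self.mean_model(grid), self.sd_model(grid)
        if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(sd))):
            raise ValueError("mean/SD model not finite over ga_range")
        if np.any(sd <= 0):
            raise ValueError("SD model must be strictly positive over ga_range")

    # -- evaluation ---------------------------------------------------

    def _check_ga(self, ga, out_of_range: str):
        arr = np.atleast_1d(np.asarray(ga, dtype=float))
        if np.any(~np.isfinite(arr)) or np.any(arr <= GA_HARD_BOUNDS[0]) or np.any(
            arr >= GA_HARD_BOUNDS[1]
        ):
            raise ValueError(
                f"gestational age outside the hard domain "
                f"({GA_HARD_BOUNDS[0]}, {GA_HARD_BOUNDS[1]}) weeks"
            )
        lo, hi = self.ga_range
        if np.any(arr < lo) or np.any(arr > hi):
            msg = (
                f"gestational age outside the validated {lo}-{hi} week range of "
                f"the {self.biometry.value} velocity standard"
            )
            if out_of_range == "error":
                raise ValueError(msg)
            if out_of_range == "warn":
                warnings.warn(msg, GARangeWarning, stacklevel=3)
            elif out_of_range != "ignore":
                raise ValueError(f"out_of_range must be warn|error|ignore, got {out_of_range!r}")

    def mean(self, ga, *, out_of_range: str = "warn"):
        """Expected velocity increment (mm/wk) at gestational age ``ga``."""
        self._check_ga(ga, out_of_range)
        return self.mean_model(ga)

    def sd(self, ga, *, out_of_range: str = "warn"):
        """SD of the velocity increment (mm/wk) at ``ga``."""
        self._check_ga(ga, out_of_range)
        return self.sd_model(ga)

    def centile(self, ga, p: float, *, out_of_range: str = "warn"):
        """The ``p``-th velocity-increment centile (mm/wk) at ``ga``."""
        z = centile_multiplier(p)
        self._check_ga(ga, out_of_range)
        return self.mean_model(ga) + z * self.sd_model(ga)

    def zscore(self, ga, value, *, out_of_range: str = "warn"):
        """Z-score of an observed velocity increment at ``ga``."""
        self._check_ga(ga, out_of_range)
        return (np.asarray(value, dtype=float) - self.mean_model(ga)) / self.sd_model(ga)

    def peak(self) -> tuple[float, float]:
        """Gestational age and value of the maximum mean velocity.

        Returns the continuous argmax of the mean model over ``ga_range``.
        For the repeated-power-2 models the interior stationary point has
        the closed form ln s* = -(2 b + c) / (2 c) in s = GA / scale; the
        argmax is that point when it falls inside the range, else the
        better range boundary.
        """
        lo, hi = self.ga_range
        candidates = [lo, hi]
        m = self.mean_model
        if m.powers == (2.0, 2.0):
            _, b, c = m.coefficients
            if c != 0.0:
                s_star = float(np.exp(-(2 * b + c) / (2 * c)))
                ga_star = s_star * m.scale
                if lo < ga_star < hi:
                    candidates.append(ga_star)
        else:
            # interior critical points: sign changes of the derivative on
            # a fine grid, refined by bisection
            grid = np.linspace(lo, hi, 4001)
            d = np.asarray(m.derivative(grid))
            sign = np.sign(d)
            (idx,) = np.nonzero(sign[:-1] * sign[1:] < 0)
            for i in idx:
                root = optimize.brentq(lambda g: float(m.derivative(g)), grid[i], grid[i + 1])
                candidates.append(float(root))
        values = [float(m(g)) for g in candidates]
        k = int(np.argmax(values))
        return float(candidates[k]), values[k]

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "mean": self.mean_model.to_dict(),
            "sd": self.sd_model.to_dict(),
            "ga_range": list(self.ga_range),
            "decimals": self.decimals,
        }

    @classmethod
    def from_dict(cls, biometry, d: dict, default_range=(16.0, 38.0)) -> "VelocityStandard":
        return cls(
            biometry=BiometryCode.coerce(biometry),
            mean_model=FPModel.from_dict(d["mean"]),
            sd_model=FPModel.from_dict(d["sd"]),
            ga_range=tuple(d.get("ga_range", default_range)),
            decimals=int(d.get("decimals", 1)),
        )


class StandardSet(dict):
    """Mapping BiometryCode -> VelocityStandard with JSON round-trip."""

    def __getitem__(self, key) -> VelocityStandard:
        return super().__getitem__(BiometryCode.coerce(key))

    def to_json(self, path) -> None:
        payload = {
            "name": "Fetal growth velocity increment standard",
            "ga_unit": "weeks",
            "value_unit": "mm/wk",
            "biometries": {b.value: s.to_dict() for b, s in self.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_mapping(cls, payload: Mapping) -> "StandardSet":
        default_range = tuple(payload.get("ga_range", (16.0, 38.0)))
        out = cls()
        for name, block in payload["biometries"].items():
            code = BiometryCode.coerce(name)
            out[code] = VelocityStandard.from_dict(code, block, default_range)
        return out

    @classmethod
    def from_json(cls, path) -> "StandardSet":
        with open(path) as fh:
            return cls.from_mapping(json.load(fh))


_PUBLISHED: StandardSet | None = None


def published_standards() -> StandardSet:
    """The published velocity-increment standard set (all five biometries)."""
    global _PUBLISHED
    if _PUBLISHED is None:
        with resources.files(__package__).joinpath("data/velocity_standards.json").open() as fh:
            _PUBLISHED = StandardSet.from_mapping(json.load(fh))
    return _PUBLISHED


def load_standard_set(path=None) -> StandardSet:
    """Load a standard-definition JSON file, or the shipped standard."""
    return published_standards() if path is None else StandardSet.from_json(path)


def _std(biometry, standard: StandardSet | VelocityStandard | None) -> VelocityStandard:
    if isinstance(standard, VelocityStandard):
        return standard
    return (standard or published_standards())[BiometryCode.coerce(biometry)]


def mean_velocity(biometry, ga, *, standard=None, out_of_range="warn"):
    """Expected velocity increment (mm/wk) for ``biometry`` at ``ga`` weeks."""
    return _std(biometry, standard).mean(ga, out_of_range=out_of_range)


def sd_velocity(biometry, ga, *, standard=None, out_of_range="warn"):
    """SD of the velocity increment (mm/wk) for ``biometry`` at ``ga`` weeks."""
    return _std(biometry, standard).sd(ga, out_of_range=out_of_range)


def centile_velocity(biometry, ga, p, *, standard=None, out_of_range="warn"):
    """``p``-th centile of the velocity increment (mm/wk)."""
    return _std(biometry, standard).centile(ga, p, out_of_range=out_of_range)


def zscore_velocity(biometry, ga, value, *, standard=None, out_of_range="warn"):
    """Z-score of an observed velocity increment (mm/wk)."""
    return _std(biometry, standard).zscore(ga, value, out_of_range=out_of_range)


def percent_of_term_size(biometry, ga, term_size_mm, *, standard=None, out_of_range="warn"):
    """Mean velocity as a percentage of the attained size at term (%/wk).

    ``term_size_mm`` is the attained size at 40 weeks from a distance
    (size-for-GA) standard, supplied by the caller.
    """
    if np.any(np.asarray(term_size_mm, dtype=float) <= 0):
        raise ValueError("term size must be positive (mm)")
    return 100.0 * np.asarray(mean_velocity(biometry, ga, standard=standard, out_of_range=out_of_range)) / term_size_mm


def peak_velocity(biometry, *, standard=None) -> tuple[float, float]:
    """(gestational age, mm/wk) of the maximum mean velocity increment."""
    return _std(biometry, standard).peak()


def centile_table(
    biometry,
    ga_list: Iterable[float] | None = None,
    centiles: Sequence[float] = NAMED_CENTILES,
    decimals: int | str | None = "published",
    *,
    standard=None,
    out_of_range="warn",
) -> pd.DataFrame:
    """Chart table of velocity-increment centiles by gestational age.

    Parameters
    ----------
    ga_list
        Gestational ages (weeks); defaults to integer weeks 16-38.
    centiles
        Centiles to tabulate (default: the seven named chart centiles).
    decimals
        ``"published"`` rounds each cell with the chart convention at the
        biometry's printed precision (2 dp for HC, 1 dp otherwise);
        an int forces that precision; ``None`` leaves cells unrounded.

    Returns
    -------
    DataFrame indexed by ``ga`` with one ``c<p>`` column per centile.
    """
    std = _std(biometry, standard)
    if ga_list is None:
        ga_list = np.arange(std.ga_range[0], std.ga_range[1] + 1)
    ga = np.atleast_1d(np.asarray(list(ga_list), dtype=float))
    std._check_ga(ga, out_of_range)
    mu, sd = std.mean_model(ga), std.sd_model(ga)
    if decimals == "published":
        decimals = std.decimals
    cols = {}
    for p in centiles:
        vals = mu + centile_multiplier(p) * sd
        if decimals is not None:
            vals = np.array([chart_round(v, int(decimals)) for v in vals])
        label = f"c{p:g}"
        cols[label] = vals
    out = pd.DataFrame(cols, index=pd.Index(ga, name="ga"))
    return out


def export_chart_csv(biometry, path, **kwargs) -> pd.DataFrame:
    """Write a published-format chart CSV (columns ga, c3, ..., c97)."""
    table = centile_table(biometry, **kwargs)
    table.reset_index().to_csv(path, index=False)
    return table
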