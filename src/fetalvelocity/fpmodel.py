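"""Fractional polynomial models in the Royston–Altman convention.

A fractional polynomial (FP) in a positive predictor x with powers
(p1, ..., pm) drawn from the canonical set {-2, -1, -0.5, 0, 0.5, 1, 2, 3}
is b0 + b1*H1(x) + ... + bm*Hm(x), where a power of 0 denotes ln(x) and a
repeated power p contributes both x**p and x**p * ln(x).  All logarithms
are natural.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

#: Canonical candidate power set for FP model search.
FP_POWERS: tuple[float, ...] = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


def fp_basis(x: np.ndarray | Sequence[float] | float, powers: Sequence[float]) -> np.ndarray:
    """Design matrix (without intercept) of the FP basis at ``x``.

    Powers are sorted ascending before applying the repeated-power rule:
    the first occurrence of p maps to x**p (ln x for p == 0) and each
    repeat multiplies the previous column by ln x.

    Parameters
    ----------
    x
        Positive predictor values.
    powers
        FP powers; values outside :data:`FP_POWERS` are accepted (the
        canonical set is a search convention, not an evaluation limit).

    Returns
    -------
    ndarray of shape (n, len(powers)).
    """
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.size and np.nanmin(arr) <= 0:
        raise ValueError("fractional polynomial predictor must be strictly positive")
    logx = np.log(arr)
    cols: list[np.ndarray] = []
    prev_power: float | None = None
    for p in sorted(float(p) for p in powers):
        if prev_power is not None and p == prev_power:
            cols.append(cols[-1] * logx)
        elif p == 0.0:
            cols.append(logx.copy())
        else:
            cols.append(arr**p)
        prev_power = p
    return np.column_stack(cols) if cols else np.empty((arr.shape[0], 0))


@dataclass(frozen=True)
class FPModel:
    """A fitted or published fractional polynomial curve.

    Attributes
    ----------
    powers
        FP powers (ascending); 0 encodes ln, repeats add log terms.
    coefficients
        Intercept followed by one coefficient per basis column.
    scale
        Divisor applied to the predictor before exponentiation.  The
        published velocity-increment mean models use gestational age / 10;
        some SD models use the bare gestational age (scale 1).
    """

    powers: tuple[float, ...]
    coefficients: tuple[float, ...]
    scale: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "powers", tuple(sorted(float(p) for p in self.powers)))
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))
        if self.scale <= 0:
            raise ValueError("predictor scale must be positive")
        if len(self.coefficients) != len(self.powers) + 1:
            raise ValueError(
                f"expected {len(self.powers) + 1} coefficients (intercept + basis terms), "
                f"got {len(self.coefficients)}"
            )

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        scalar = np.isscalar(x) or (isinstance(x, np.ndarray) and x.ndim == 0)
        s = np.atleast_1d(np.asarray(x, dtype=float)) / self.scale
        X = fp_basis(s, self.powers)
        beta = np.asarray(self.coefficients)
        y = beta[0] + X @ beta[1:]
        return float(y[0]) if scalar else y

    def derivative(self, x: np.ndarray | float, h: float = 1e-5) -> np.ndarray | float:
        """Central-difference derivative with respect to the unscaled predictor."""
        return (self(np.asarray(x, dtype=float) + h) - self(np.asarray(x, dtype=float) - h)) / (2 * h)

    def to_dict(self) -> dict:
        return {
            "powers": list(self.powers),
            "coefficients": list(self.coefficients),
            "scale": self.scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FPModel":
        return cls(tuple(d["powers"]), tuple(d["coefficients"]), float(d.get("scale", 1.0)))


def round_half_up(x: float, decimals: int) -> float:
    """Round with halves away from zero (spreadsheet convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def chart_round(x: float, decimals: int) -> float:
    """Round a centile value the way the published charts do.

    The printed charts were derived from a 2-decimal intermediate: values
    are rounded half-up to 2 decimals first and then to the display
    precision.  For 2-decimal charts the first stage is idempotent; for
    1-decimal charts the two-stage rule differs from direct rounding for
    values in the [.x45, .x50) band and matches every printed cell.
    """
    return round_half_up(round_half_up(x, max(decimals, 2)), decimals)
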