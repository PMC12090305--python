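"""Indicator normalization: linear P1/P99 rescaling onto the [0, 1] scale.

Raw indicators (distances in m, basal area in m²/ha, ...) are mapped to
dimensionless predisposition scores by a clamped linear ramp between a
lower and an upper threshold. Thresholds are either fixed by configuration
or taken as the 1st and 99th percentiles of the pooled observed values of a
run, which keeps the mapping robust to outliers. A *positive* direction
maps lower→0 and upper→1 (predisposition grows with the raw value), a
*negative* direction maps lower→1 and upper→0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin


class DegenerateNormalizationError(ValueError):
    """Raised when thresholds collapse (lower == upper) or a value pool has
    no spread, so no linear rescaling is defined. Callers must then supply
    fixed thresholds explicitly."""


@dataclass(frozen=True)
class NormalizationSpec:
    """Direction and thresholds mapping a raw indicator to [0, 1].

    Parameters
    ----------
    direction : {"positive", "negative"}
        positive: lower→0, upper→1; negative: lower→1, upper→0.
    lower, upper : float
        Raw-value thresholds, lower < upper. Values beyond them clamp.
    source : str
        Provenance tag, e.g. ``"fixed"`` or ``"percentile(1,99)"``.
    """

    direction: str
    lower: float
    upper: float
    source: str = "fixed"

    def __post_init__(self) -> None:
        if self.direction not in ("positive", "negative"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ValueError("thresholds must be finite")
        if self.lower >= self.upper:
            raise DegenerateNormalizationError(
                f"lower threshold {self.lower} must be < upper {self.upper}"
            )


def normalize_linear(value, spec: NormalizationSpec):
    """Clamped linear rescaling of ``value`` under ``spec``.

    Accepts scalars or arrays; NaN raw values propagate as NaN scalars are
    rejected. Returns score(s) in [0, 1].
    """
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0 and not np.isfinite(arr):
        raise ValueError("non-finite raw value")
    score = (arr - spec.lower) / (spec.upper - spec.lower)
    score = np.clip(score, 0.0, 1.0)
    if spec.direction == "negative":
        score = 1.0 - score
    return float(score) if np.ndim(value) == 0 else score


def percentile_thresholds(values, p_lo: float = 1.0, p_hi: float = 99.0,
                          name: str = "indicator") -> tuple[float, float]:
    """Lower/upper thresholds as the ``p_lo``-th and ``p_hi``-th percentiles
    of the pooled values (linear interpolation between order statistics,
    i.e. the type-7 convention).

    Raises
    ------
    DegenerateNormalizationError
        If fewer than two distinct finite values are supplied — a pool with
        no spread cannot define a rescaling.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2 or np.unique(arr).size < 2:
        raise DegenerateNormalizationError(
            f"{name}: need >= 2 distinct finite values to derive percentile "
            "thresholds; supply fixed thresholds instead"
        )
    lower, upper = np.percentile(arr, [p_lo, p_hi], method="linear")
    if lower >= upper:
        raise DegenerateNormalizationError(
            f"{name}: P{p_lo}/P{p_hi} thresholds coincide ({lower}); "
            "supply fixed thresholds instead"
        )
    return float(lower), float(upper)


class PercentileNormalizer(TransformerMixin, BaseEstimator):
    """Column-wise P1/P99 linear normalizer for raw indicator tables.

    fit() pools each column's observed values and stores the percentile
    thresholds; transform() applies the clamped linear ramp per column in
    the configured direction. Columns not listed in ``directions`` pass
    through untouched.

    Parameters
    ----------
    directions : mapping of column -> {"positive", "negative"}
        Columns to normalize and their direction.
    p_lo, p_hi : float, default 1 and 99
        Percentile ranks defining the thresholds.
    fixed : mapping of column -> (lower, upper), optional
        Overrides: these columns use fixed thresholds instead of
        run-derived percentiles.

    Attributes
    ----------
    specs_ : dict of column -> NormalizationSpec
        Resolved thresholds after fit.
    """

    def __init__(self, directions: Mapping[str, str] | None = None,
                 p_lo: float = 1.0, p_hi: float = 99.0,
                 fixed: Mapping[str, tuple[float, float]] | None = None):
        self.directions = directions
        self.p_lo = p_lo
        self.p_hi = p_hi
        self.fixed = fixed

    def fit(self, X: pd.DataFrame, y=None) -> "PercentileNormalizer":
        if not isinstance(X, pd.DataFrame):
            raise TypeError("PercentileNormalizer expects a DataFrame")
        directions = dict(self.directions or {})
        fixed = dict(self.fixed or {})
        missing = set(directions) - set(X.columns)
        if missing:
            raise ValueError(f"columns absent from input: {sorted(missing)}")
        self.specs_ = {}
        for col, direction in directions.items():
            if col in fixed:
                lo, hi = fixed[col]
                self.specs_[col] = NormalizationSpec(direction, lo, hi, "fixed")
            else:
                lo, hi = percentile_thresholds(
                    X[col].to_numpy(), self.p_lo, self.p_hi, name=col)
                self.specs_[col] = NormalizationSpec(
                    direction, lo, hi, f"percentile({self.p_lo:g},{self.p_hi:g})")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "specs_"):
            raise ValueError("PercentileNormalizer is not fitted")
        out = X.copy()
        for col, spec in self.specs_.items():
            out[col] = normalize_linear(X[col].to_numpy(), spec)
        return out

    def thresholds_frame(self) -> pd.DataFrame:
        """Resolved thresholds as a tidy table (indicator, direction,
        lower, upper, source) — the run's normalization record."""
        rows = [
            {"indicator": c, "direction": s.direction,
             "lower": s.lower, "upper": s.upper, "source": s.source}
            for c, s in self.specs_.items()
        ]
        return pd.DataFrame(rows)
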