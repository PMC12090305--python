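"""End-to-end assessment: raw indicators → component scores → pFire.

`FirePredispositionScorer` is the fit/transform core. fit() learns the
P1/P99 normalization thresholds from the pooled raw indicator values of a
run (all stands x timesteps x managements x climates — predisposition is a
relative measure over the observed data); transform() maps the raw table
to the 14 component scores and appends pFire under the configured
weighting. `assemble_raw_table` joins the site stage (terrain, WUI —
static per stand) onto the stand/scenario stage, and `run_all` wires a
synthetic landscape + trajectories through the whole chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import components as comp
from .climate import score_climate
from .normalization import (NormalizationSpec, normalize_linear,
                            percentile_thresholds)
from .stand import FireExposureParams, stand_indicator_table
from .terrain import assess_terrain, score_aspect, score_slope
from .weighting import aggregate_pfire, preset_scenarios
from .wui import distances_table

KEY_COLUMNS = ("stand_id", "timestep", "management", "climate")


class FirePredispositionScorer(TransformerMixin, BaseEstimator):
    """Transformer from raw indicator tables to scored tables with pFire.

    Parameters
    ----------
    weights : str or dict, default "expert_weights"
        A preset scenario name (eq_weights, eq_weights_group,
        expert_weights, expert_weights_table6/8, random_weights) or a
        component -> weight mapping (any non-negative scale; renormalized
        per side at aggregation).
    p_lo, p_hi : float
        Percentile ranks for the run-derived thresholds.
    fixed_thresholds : dict, optional
        component name -> (lower, upper) overriding the run-derived
        thresholds (required for degenerate pools, e.g. tiny study areas).
    conifer_basis : unused here; kept at the stand stage.

    Attributes
    ----------
    specs_ : dict of component -> NormalizationSpec for the
        percentile-normalized components.
    curvature_p1_ : float or None
        Threshold under which mean concave curvature scores 1.
    weights_ : dict, the resolved per-component weight vector.
    """

    RAW = comp.RAW_COLUMNS

    def __init__(self, weights="expert_weights", p_lo: float = 1.0,
                 p_hi: float = 99.0, fixed_thresholds: dict | None = None):
        self.weights = weights
        self.p_lo = p_lo
        self.p_hi = p_hi
        self.fixed_thresholds = fixed_thresholds

    def _resolve_weights(self) -> dict:
        if isinstance(self.weights, str):
            presets = preset_scenarios()
            if self.weights not in presets:
                raise ValueError(
                    f"unknown weighting scenario {self.weights!r}; "
                    f"presets: {sorted(presets)}")
            return presets[self.weights]
        return dict(self.weights)

    def fit(self, X: pd.DataFrame, y=None) -> "FirePredispositionScorer":
        missing = [c for c in self.RAW.values() if c not in X.columns]
        if missing:
            raise ValueError(f"raw indicator columns missing: {missing}")
        fixed = dict(self.fixed_thresholds or {})
        self.specs_ = {}
        for name, direction in comp.PERCENTILE_NORMALIZED.items():
            raw_col = self.RAW[name]
            if name in fixed:
                lo, hi = fixed[name]
                src = "fixed"
            else:
                lo, hi = percentile_thresholds(
                    X[raw_col].to_numpy(), self.p_lo, self.p_hi, name=name)
                src = f"percentile({self.p_lo:g},{self.p_hi:g})"
            self.specs_[name] = NormalizationSpec(direction, lo, hi, src)
        # curvature: 1 at the P1 of the observed concave means, 0 at >= 0
        if "pf.ter_curv" in fixed:
            self.curvature_p1_ = float(fixed["pf.ter_curv"][0])
        else:
            curv = X[self.RAW["pf.ter_curv"]].to_numpy(dtype=float)
            neg = curv[np.isfinite(curv) & (curv < 0)]
            self.curvature_p1_ = (float(np.percentile(neg, self.p_lo))
                                  if neg.size else None)
        self.weights_ = self._resolve_weights()
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "specs_"):
            raise ValueError("scorer is not fitted")
        out = X[[c for c in KEY_COLUMNS if c in X.columns]].copy()
        if "empty_stand" in X.columns:
            out["empty_stand"] = X["empty_stand"]
        out["pf.ter_slp"] = [score_slope(v)
                             for v in X[self.RAW["pf.ter_slp"]]]
        out["pf.ter_asp"] = [score_aspect(v)
                             for v in X[self.RAW["pf.ter_asp"]]]
        curv = X[self.RAW["pf.ter_curv"]].to_numpy(dtype=float)
        if self.curvature_p1_ is not None:
            spec = NormalizationSpec("negative", self.curvature_p1_, 0.0)
            out["pf.ter_curv"] = normalize_linear(np.minimum(curv, 0.0),
                                                  spec)
        else:
            out["pf.ter_curv"] = np.zeros(len(X))
        out["pf.clim"] = score_climate(X[self.RAW["pf.clim"]].to_numpy())
        for name, spec in self.specs_.items():
            out[name] = normalize_linear(
                X[self.RAW[name]].to_numpy(dtype=float), spec)
        # components already on the 0-1 predisposition scale
        for name in ("pf.scs_conif", "pf.scs_lack_resist",
                     "pf.scs_lack_resil"):
            out[name] = np.clip(X[self.RAW[name]].to_numpy(dtype=float),
                                0.0, 1.0)
        out["pFire"] = aggregate_pfire(
            out[list(comp.ALL_COMPONENTS)], self.weights_).to_numpy()
        return out

    def thresholds_frame(self) -> pd.DataFrame:
        """Resolved normalization thresholds of the run, tidy."""
        rows = [{"indicator": n, "direction": s.direction, "lower": s.lower,
                 "upper": s.upper, "source": s.source}
                for n, s in self.specs_.items()]
        if self.curvature_p1_ is not None:
            rows.append({"indicator": "pf.ter_curv", "direction": "negative",
                         "lower": self.curvature_p1_, "upper": 0.0,
                         "source": f"percentile({self.p_lo:g}) of concave means"})
        return pd.DataFrame(rows)


@dataclass
class AssessmentResult:
    """Scored table + run metadata."""

    scores: pd.DataFrame
    raw: pd.DataFrame
    thresholds: pd.DataFrame
    site_table: pd.DataFrame = None
    flags: dict = field(default_factory=dict)


def assemble_raw_table(site_table: pd.DataFrame,
                       stand_table: pd.DataFrame) -> pd.DataFrame:
    """Join static per-stand site indicators onto the per-scenario stand
    indicator table (inner join on stand_id)."""
    merged = stand_table.merge(site_table.reset_index(), on="stand_id",
                               how="left", validate="many_to_one")
    # aspect is legitimately NaN on flat cells (scores 0 downstream)
    site_cols = [c for c in site_table.columns if c != "aspect_deg"]
    if merged[site_cols].isna().any().any():
        bad = merged.loc[merged[site_cols].isna().any(axis=1),
                         "stand_id"].unique()
        raise ValueError(f"stands without site indicators: {list(bad)[:5]}")
    return merged


def compute_site_table(landscape, window_coarse: int = 7,
                       window_fine: int = 9) -> pd.DataFrame:
    """Terrain + WUI raw indicators per stand (static over scenarios)."""
    terrain = assess_terrain(landscape.dem_coarse, landscape.dem_fine,
                             landscape.stands, window_coarse, window_fine)
    dist = distances_table(landscape.stands, landscape.layers)
    return terrain.table[["slope_deg", "aspect_deg",
                          "mean_neg_curv"]].join(dist)


def run_all(landscape, states, weights="expert_weights",
            params: FireExposureParams | None = None,
            fixed_thresholds: dict | None = None,
            window_coarse: int = 7, window_fine: int = 9
            ) -> AssessmentResult:
    """Full chain on a landscape + stand states under one weighting."""
    site = compute_site_table(landscape, window_coarse, window_fine)
    stand_table = stand_indicator_table(states, params=params)
    raw = assemble_raw_table(site, stand_table)
    scorer = FirePredispositionScorer(
        weights=weights, fixed_thresholds=fixed_thresholds)
    scores = scorer.fit(raw).transform(raw)
    flags = {"empty_stands": int(raw["empty_stand"].sum())}
    return AssessmentResult(scores, raw, scorer.thresholds_frame(),
                            site_table=site, flags=flags)
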