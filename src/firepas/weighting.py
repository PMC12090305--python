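"""Hierarchical expert weighting and the pFire aggregation.

Weights are elicited at two levels: sub-group weights (λp over the
site-related sub-groups terrain/climate/WUI, λq over the stand-related
sub-groups), each summing to 1, and within-group component weights
(ω, summing to 1 inside each sub-group). Final component weights multiply
through the hierarchy, λ = λ_group · ω, so they again sum to 1 per side;
for reporting they are rescaled by the side's maximum (λ̂ = λ/max λ).

pFire is the compensatory additive aggregation

    pFire = 0.5 · Σ_s λ_s · ST_s  +  0.5 · Σ_i λ_i · SI_i

over the six stand-related (ST) and eight site-related (SI) component
scores. Any non-negative weight vector is accepted (e.g. raw scenario
ratios); weights are renormalized to sum to 1 per side before aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .components import (ALL_COMPONENTS, SITE_COMPONENTS, SITE_GROUPS,
                         STAND_COMPONENTS, STAND_GROUPS)

_SUM_TOL = 1e-9


class WeightSchemeError(ValueError):
    pass


@dataclass
class WeightScheme:
    """Hierarchical weighting: sub-group weights + within-group weights.

    ``site_groups``/``stand_groups`` map group name -> λ_group;
    ``within`` maps component -> ω within its group.
    """

    site_groups: dict[str, float]
    stand_groups: dict[str, float]
    within: dict[str, float]
    name: str = "custom"

    def validate(self) -> None:
        for label, groups, registry in (
                ("site", self.site_groups, SITE_GROUPS),
                ("stand", self.stand_groups, STAND_GROUPS)):
            if set(groups) != set(registry):
                raise WeightSchemeError(
                    f"{label} sub-groups must be exactly {sorted(registry)}")
            if abs(sum(groups.values()) - 1.0) > _SUM_TOL:
                raise WeightSchemeError(
                    f"{label} sub-group weights must sum to 1")
            for gname, members in registry.items():
                s = sum(self.within.get(m, 0.0) for m in members)
                if abs(s - 1.0) > _SUM_TOL:
                    raise WeightSchemeError(
                        f"within-group weights of {gname!r} sum to {s}, not 1")

    def compose(self) -> dict[str, float]:
        """Final per-component weights λ = λ_group · ω (sum 1 per side)."""
        self.validate()
        final = {}
        for registry, groups in ((SITE_GROUPS, self.site_groups),
                                 (STAND_GROUPS, self.stand_groups)):
            for gname, members in registry.items():
                for comp in members:
                    final[comp] = groups[gname] * self.within[comp]
        return final


def compose_final_weights(scheme: WeightScheme) -> dict[str, float]:
    return scheme.compose()


def rescale_weights(final: dict[str, float], ndigits: int | None = 2
                    ) -> dict[str, float]:
    """λ̂ = λ / max(λ), separately per side; rounded for reporting
    (``ndigits=None`` keeps full precision)."""
    out = {}
    for side in (SITE_COMPONENTS, STAND_COMPONENTS):
        present = [c for c in side if c in final]
        if not present:
            continue
        mx = max(final[c] for c in present)
        if mx <= 0:
            raise WeightSchemeError("maximum weight must be > 0")
        for c in present:
            v = final[c] / mx
            out[c] = round(v, ndigits) if ndigits is not None else v
    return out


def _renormalize(weights: dict[str, float], side) -> dict[str, float]:
    missing = [c for c in side if c not in weights]
    if missing:
        raise WeightSchemeError(f"missing weights for {missing}")
    vec = {c: float(weights[c]) for c in side}
    if any(v < 0 for v in vec.values()):
        raise WeightSchemeError("weights must be >= 0")
    s = sum(vec.values())
    if s <= 0:
        raise WeightSchemeError("at least one weight per side must be > 0")
    return {c: v / s for c, v in vec.items()}


def normalized_weights(weights: dict[str, float]) -> dict[str, float]:
    """Per-side sum-to-1 renormalization of any non-negative weight
    vector over the 14 components."""
    out = _renormalize(weights, SITE_COMPONENTS)
    out.update(_renormalize(weights, STAND_COMPONENTS))
    return out


def aggregate_pfire(scores, weights: dict[str, float],
                    allow_missing: bool = False):
    """pFire from the 14 component scores and a per-component weight
    vector (any non-negative scale; renormalized per side).

    ``scores`` is a mapping component -> score, or a DataFrame with one
    column per component (returns a Series then). With
    ``allow_missing=True`` absent components are dropped and the remaining
    weights renormalized — exploratory use only.
    """
    if isinstance(scores, pd.DataFrame):
        cols = set(scores.columns)
    else:
        cols = set(scores)
    missing = [c for c in ALL_COMPONENTS if c not in cols]
    if missing and not allow_missing:
        raise WeightSchemeError(f"missing component scores: {missing}")
    site = [c for c in SITE_COMPONENTS if c in cols]
    stand = [c for c in STAND_COMPONENTS if c in cols]
    w = {c: float(weights[c]) for c in site + stand}
    ws = sum(w[c] for c in site)
    wt = sum(w[c] for c in stand)
    if ws <= 0 or wt <= 0:
        raise WeightSchemeError("each side needs positive total weight")

    def side_sum(cs, total):
        if isinstance(scores, pd.DataFrame):
            acc = sum(scores[c] * (w[c] / total) for c in cs)
        else:
            acc = sum(scores[c] * (w[c] / total) for c in cs)
        return acc

    result = 0.5 * side_sum(site, ws) + 0.5 * side_sum(stand, wt)
    if isinstance(scores, pd.DataFrame):
        return result.rename("pFire")
    return float(result)


# ------------------------------------------------------------- presets

def _expert_hierarchical() -> WeightScheme:
    return WeightScheme(
        site_groups={"terrain": 0.40, "climate": 0.30, "wui": 0.30},
        stand_groups={"scs_fuel": 0.50, "scs_resist": 0.50},
        within={
            "pf.ter_slp": 0.40, "pf.ter_asp": 0.40, "pf.ter_curv": 0.20,
            "pf.clim": 1.0,
            "pf.wui_build": 0.25, "pf.wui_road": 0.25,
            "pf.wui_road_drv": 0.25, "pf.wui_waterbody": 0.25,
            "pf.scs_fuel": 0.40, "pf.scs_conif": 0.20,
            "pf.scs_vert": 0.20, "pf.scs_horiz": 0.20,
            "pf.scs_lack_resist": 0.50, "pf.scs_lack_resil": 0.50,
        },
        name="expert_weights_table6",
    )


def _equal_group_weights() -> dict[str, float]:
    """Equal weighting at the sub-group level.

    Site side: the three sub-groups (terrain, climate, WUI) share weight
    equally and components split equally within each. Stand side: the
    composition-and-structure components form one sub-group (the
    fuel/resistance split exists only for expert elicitation), so all six
    are equal. Ratios mirror the published scenario column
    (0.33 / 1 / 0.25 site, 0.17 stand, at 2 dp).
    """
    w = {}
    for members in SITE_GROUPS.values():
        for c in members:
            w[c] = 1.0 / len(members)
    for c in STAND_COMPONENTS:
        w[c] = 1.0 / len(STAND_COMPONENTS)
    return w


def preset_scenarios() -> dict[str, dict[str, float]]:
    """Named per-component weight-ratio scenarios.

    ``expert_weights`` (= ``expert_weights_table6``) carries the
    hierarchically composed expert weights. ``expert_weights_table8`` is
    the variant printed with the published scenario table, whose site
    ratios swap aspect and curvature relative to the hierarchical
    composition; both are shipped unreconciled. ``random_weights`` is the
    published single random draw.
    """
    expert = _expert_hierarchical().compose()
    table8_expert = dict(rescale_weights(expert, ndigits=2))
    table8_expert.update({"pf.ter_curv": 0.53, "pf.ter_slp": 0.53,
                          "pf.ter_asp": 0.27})
    return {
        "eq_weights": {c: 1.0 for c in ALL_COMPONENTS},
        "eq_weights_group": _equal_group_weights(),
        "expert_weights": expert,
        "expert_weights_table6": expert,
        "expert_weights_table8": table8_expert,
        "random_weights": {
            "pf.ter_curv": 0.19, "pf.ter_slp": 0.83, "pf.ter_asp": 0.32,
            "pf.clim": 0.36, "pf.wui_build": 0.89, "pf.wui_road": 0.21,
            "pf.wui_road_drv": 0.19, "pf.wui_waterbody": 0.39,
            "pf.scs_fuel": 0.16, "pf.scs_conif": 0.39, "pf.scs_vert": 0.62,
            "pf.scs_horiz": 0.71, "pf.scs_lack_resist": 0.98,
            "pf.scs_lack_resil": 0.66,
        },
    }


def expert_scheme() -> WeightScheme:
    """The hierarchical expert weighting (sub-group + within-group form)."""
    return _expert_hierarchical()


def weights_report(scheme: WeightScheme) -> pd.DataFrame:
    """Tidy report of the hierarchy: component, group, λ_group, ω, final λ
    and normalized λ̂ (2 dp), mirroring the published weight tables."""
    final = scheme.compose()
    rescaled = rescale_weights(final, ndigits=2)
    rows = []
    for registry, groups in ((SITE_GROUPS, scheme.site_groups),
                             (STAND_GROUPS, scheme.stand_groups)):
        for gname, members in registry.items():
            for c in members:
                rows.append({
                    "component": c, "group": gname,
                    "group_weight": groups[gname],
                    "within_weight": scheme.within[c],
                    "final_weight": final[c],
                    "normalized_weight": rescaled[c],
                })
    return pd.DataFrame(rows)
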