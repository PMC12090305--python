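"""Stand-related predisposition components from cohort tree lists.

A stand is described by cohorts (species, dbh in cm, height in m, stems/ha)
as emitted by forest gap models. Six components are derived:

* fuel load — basal area per ha (m²/ha), P1/P99-normalized;
* conifer share — basal-area share of coniferous species, used directly;
* vertical fuel connectivity — coefficient of variation of tree height
  CV_h = sd_h / mean_h (stems-weighted, population sd), P1/P99-normalized;
* horizontal fuel connectivity — Reineke stand density index
  SDI = N · (dg/25)^1.605 with dg the quadratic mean diameter (cm),
  P1/P99-normalized;
* lack of resistance — basal-area-weighted mean probability of post-fire
  tree mortality, combining crown scorch and cambium kill:

      P_m = C_k^(t_c/t_f − 0.5),  with P_m = 1 when t_c < 0.5·t_f,
      t_c = 3.36 · bt²            (bt bark thickness, mm),
      C_k = (h_k − h_t + cl)(h_t − h_k + cl)/cl²  clamped to [0, 1],
      h_k = 3.94·FLI^1.17 / [(T_c − T_a)·(0.11·FLI + MFWS³)^0.5],
      h_cb = h_t (1 − e^{−(l0 + l1·(h_t/dbh) + l2·dbh)}),  cl = h_t − h_cb;

* lack of long-term resilience — basal-area-weighted mean of a
  semi-quantitative species sensitivity score (0 extremely resilient …
  1 extremely sensitive), from palaeoecological fire-sensitivity records.

Scorch height h_k is evaluated once from fixed exposure parameters so that
stands are compared under identical fire conditions. Bark thickness uses a
pluggable per-species allometry; the shipped default is affine in dbh with
synthetic but plausible coefficients (thick-barked pines/larch, thin-barked
beech/spruce).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

BARK_FLOOR_MM = 0.1

#: crown-base allometry coefficients (l0, l1, l2) per parametrized species
CROWN_COEFFS = {
    "Picea abies": (-0.0443, -0.8823, -0.0004),
    "Abies alba": (0.1409, -0.8480, -0.0042),
    "Pinus sylvestris": (0.376, -0.9963, -0.0218),
    "Fagus sylvatica": (-0.5478, -0.1094, -0.0023),
    "Quercus petraea": (-0.9967, -0.2043, 0.0032),
}

#: long-term fire-sensitivity classification (higher = more sensitive,
#: i.e. greater lack of resilience)
RESILIENCE_SCORES = {
    "Alnus viridis": 0.00, "Castanea sativa": 0.00, "Pinus mugo": 0.00,
    "Alnus spp.": 0.20, "Corylus avellana": 0.20, "Pinus sylvestris": 0.20,
    "Quercus spp.": 0.20, "Quercus petraea": 0.20, "Salix spp.": 0.20,
    "Betula spp.": 0.40, "Larix decidua": 0.40,
    "Fagus sylvatica": 0.60, "Picea abies": 0.60, "Pinus cembra": 0.60,
    "Acer spp.": 0.80, "Fraxinus spp.": 0.80, "Ostrya carpinifolia": 0.80,
    "Tilia spp.": 0.80, "Ulmus spp.": 0.80,
    "Abies alba": 1.00,
}


@dataclass(frozen=True)
class TreeRecord:
    """One simulated cohort: species, dbh (cm), height (m), stems/ha."""

    species: str
    dbh: float
    height: float
    stems: float

    def __post_init__(self) -> None:
        if self.dbh <= 0 or self.height <= 0:
            raise ValueError("dbh and height must be > 0")
        if self.stems < 0:
            raise ValueError("stems must be >= 0")

    @property
    def basal_area(self) -> float:
        """Cohort basal area, m²/ha: stems · π · (dbh/200)²."""
        return self.stems * np.pi * (self.dbh / 200.0) ** 2


@dataclass(frozen=True)
class SpeciesTraits:
    """Per-species traits feeding the stand components."""

    species: str
    is_conifer: bool
    allometry_group: str          # key into CROWN_COEFFS
    bark_coeffs: tuple[float, float]  # (b0 mm, b1 mm/cm): bt = b0 + b1·dbh
    resilience_score: float

    def __post_init__(self) -> None:
        if self.allometry_group not in CROWN_COEFFS:
            raise ValueError(
                f"{self.species}: unknown allometry group "
                f"{self.allometry_group!r}")
        if self.resilience_score not in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
            raise ValueError(
                f"{self.species}: resilience score must be one of the six "
                "classification levels")


def _traits(species, conifer, group, bark):
    return SpeciesTraits(species, conifer, group, bark,
                         RESILIENCE_SCORES[species])


#: shipped default registry; bark coefficients are synthetic-but-plausible
#: affine allometries (mm vs cm dbh), not a published parametrization
DEFAULT_SPECIES_TRAITS = {
    t.species: t for t in [
        _traits("Picea abies", True, "Picea abies", (2.0, 0.30)),
        _traits("Abies alba", True, "Abies alba", (3.0, 0.35)),
        _traits("Pinus sylvestris", True, "Pinus sylvestris", (2.0, 0.55)),
        _traits("Pinus cembra", True, "Pinus sylvestris", (2.0, 0.40)),
        _traits("Pinus mugo", True, "Pinus sylvestris", (2.0, 0.40)),
        _traits("Larix decidua", True, "Picea abies", (4.0, 0.60)),
        _traits("Fagus sylvatica", False, "Fagus sylvatica", (2.5, 0.10)),
        _traits("Quercus petraea", False, "Quercus petraea", (4.0, 0.40)),
        _traits("Betula spp.", False, "Fagus sylvatica", (2.0, 0.15)),
        _traits("Acer spp.", False, "Fagus sylvatica", (2.0, 0.20)),
        _traits("Fraxinus spp.", False, "Fagus sylvatica", (2.0, 0.20)),
        _traits("Castanea sativa", False, "Quercus petraea", (3.0, 0.35)),
        _traits("Alnus viridis", False, "Fagus sylvatica", (1.5, 0.15)),
    ]
}


@dataclass(frozen=True)
class FireExposureParams:
    """Fixed fire-exposure conditions shared by all stands.

    t_f: fire exposure duration, s; FLI: fireline intensity, kW/m (upper
    bound of medium-intensity surface fires); MFWS: mid-flame wind speed,
    m/s; T_c: lethal tissue temperature, °C; T_a: ambient temperature, °C.
    """

    t_f: float = 300.0
    fli: float = 630.0
    mfws: float = 1.8
    t_lethal: float = 60.0
    t_ambient: float = 15.0

    def __post_init__(self) -> None:
        if min(self.t_f, self.fli, self.mfws) < 0:
            raise ValueError("exposure parameters must be non-negative")
        if self.t_lethal <= self.t_ambient:
            raise ValueError("lethal temperature must exceed ambient")


@dataclass
class StandState:
    """A stand's tree list under one (timestep, management, climate) key."""

    stand_id: str
    trees: list[TreeRecord]
    fcdi: float = 0.0
    timestep: int | str = 0
    management: str = "NO"
    climate: str = "historical"

    @property
    def is_empty(self) -> bool:
        return not any(t.stems > 0 for t in self.trees)


# ---------------------------------------------------------------- structure

def basal_area_per_ha(trees: list[TreeRecord]) -> float:
    """Total living basal area, m²/ha; 0 for an empty stand."""
    return float(sum(t.basal_area for t in trees))


def conifer_share(trees: list[TreeRecord],
                  traits: dict[str, SpeciesTraits],
                  basis: str = "basal_area") -> float:
    """Conifer fraction in [0, 1], by basal area (default) or stem count.
    Empty stands score 0 (no fuel)."""
    if basis not in ("basal_area", "stems"):
        raise ValueError("basis must be 'basal_area' or 'stems'")
    weigh = ((lambda t: t.basal_area) if basis == "basal_area"
             else (lambda t: t.stems))
    total = sum(weigh(t) for t in trees)
    if total <= 0:
        return 0.0
    con = sum(weigh(t) for t in trees
              if _lookup(traits, t.species).is_conifer)
    return float(con / total)


def cv_height(trees: list[TreeRecord], ddof: int = 0) -> float:
    """Coefficient of variation of tree height, stems-weighted.

    CV_h = sd_h / mean_h with the population sd by default (``ddof=0``);
    a single cohort (or empty stand) has no variation and returns 0.
    """
    live = [t for t in trees if t.stems > 0]
    if len(live) <= 1:
        return 0.0
    h = np.array([t.height for t in live])
    w = np.array([t.stems for t in live])
    mean = np.average(h, weights=w)
    var = np.average((h - mean) ** 2, weights=w)
    if ddof:
        n = w.sum()
        var *= n / (n - ddof)
    return float(np.sqrt(var) / mean)


def sdi(trees: list[TreeRecord]) -> float:
    """Reineke stand density index N·(dg/25)^1.605; 0 for an empty stand."""
    n = sum(t.stems for t in trees)
    if n <= 0:
        return 0.0
    dg = np.sqrt(sum(t.stems * t.dbh ** 2 for t in trees) / n)
    return float(n * (dg / 25.0) ** 1.605)


# ------------------------------------------------------- mortality chain

def bark_thickness(traits: SpeciesTraits, dbh: float, height: float,
                   allometry: Callable | None = None) -> float:
    """Bark thickness bt in mm.

    Default: affine allometry bt = b0 + b1·dbh from the species traits;
    ``allometry(traits, dbh, height)`` overrides it. Floored at 0.1 mm.
    """
    if dbh <= 0 or height <= 0:
        raise ValueError("dbh and height must be > 0")
    if allometry is not None:
        bt = float(allometry(traits, dbh, height))
    else:
        b0, b1 = traits.bark_coeffs
        bt = b0 + b1 * dbh
    return max(bt, BARK_FLOOR_MM)


def time_to_cambium_kill(bt: float) -> float:
    """Seconds of heat exposure lethal to the cambium: t_c = 3.36·bt²."""
    if bt <= 0:
        raise ValueError("bark thickness must be > 0")
    return 3.36 * bt ** 2


def crown_base_height(traits: SpeciesTraits, dbh: float,
                      height: float) -> float:
    """Crown base height h_cb (m) from the species crown allometry

        h_cb = h_t · (1 − e^{l0 + l1·(h_t/dbh) + l2·dbh})

    (the exponent is negative over the coefficients' validity range, so
    h_cb ∈ (0, h_t)); clamped to [0, height) against pathological
    coefficient/input combinations. The model is advisory outside
    height/dbh ratios of 0.15–1.25 m/cm."""
    l0, l1, l2 = CROWN_COEFFS[traits.allometry_group]
    raw = height * (1.0 - np.exp(l0 + l1 * (height / dbh) + l2 * dbh))
    eps = 1e-9 * height
    return float(np.clip(raw, 0.0, height - eps))


def crown_length(traits: SpeciesTraits, dbh: float, height: float) -> float:
    return height - crown_base_height(traits, dbh, height)


def scorch_height(params: FireExposureParams) -> float:
    """Crown scorch height h_k in m from fireline intensity, wind speed
    and the ambient-to-lethal temperature span."""
    num = 3.94 * params.fli ** 1.17
    den = ((params.t_lethal - params.t_ambient)
           * np.sqrt(0.11 * params.fli + params.mfws ** 3))
    return float(num / den)


def crown_scorch_fraction(height: float, h_k: float,
                          crown_len: float) -> float:
    """Scorched crown volume fraction C_k in [0, 1]."""
    if crown_len <= 0:
        raise ValueError("crown length must be > 0")
    if h_k >= height:
        return 1.0
    if h_k <= height - crown_len:
        return 0.0
    ck = ((h_k - height + crown_len) * (height - h_k + crown_len)
          / crown_len ** 2)
    return float(np.clip(ck, 0.0, 1.0))


def tree_mortality(c_k: float, t_c: float,
                   params: FireExposureParams) -> float:
    """Probability of post-fire tree mortality P_m.

    Thin-barked trees whose cambium is killed within half the exposure
    time die outright (P_m = 1); otherwise P_m = C_k^(t_c/t_f − 0.5).
    """
    if not 0.0 <= c_k <= 1.0:
        raise ValueError("C_k must lie in [0, 1]")
    if t_c <= 0:
        raise ValueError("t_c must be > 0")
    if t_c < 0.5 * params.t_f:
        return 1.0
    if c_k == 0.0:
        return 0.0
    return float(np.clip(c_k ** (t_c / params.t_f - 0.5), 0.0, 1.0))


def cohort_mortality(tree: TreeRecord, traits: SpeciesTraits,
                     params: FireExposureParams, h_k: float | None = None,
                     allometry: Callable | None = None) -> float:
    """P_m for one cohort, running the full chain bt → t_c, crown → C_k."""
    if h_k is None:
        h_k = scorch_height(params)
    bt = bark_thickness(traits, tree.dbh, tree.height, allometry)
    t_c = time_to_cambium_kill(bt)
    cl = crown_length(traits, tree.dbh, tree.height)
    c_k = crown_scorch_fraction(tree.height, h_k, cl)
    return tree_mortality(c_k, t_c, params)


def _lookup(traits: dict[str, SpeciesTraits], species: str) -> SpeciesTraits:
    try:
        return traits[species]
    except KeyError:
        raise KeyError(f"no traits configured for species {species!r}") from None


def _ba_weighted_mean(trees, values) -> float:
    ba = np.array([t.basal_area for t in trees])
    total = ba.sum()
    if total <= 0:
        raise ValueError("stand has zero basal area")
    if len(set(values)) == 1:  # monocultures stay exact
        return float(values[0])
    return float(np.dot(ba, values) / total)


def stand_lack_of_resistance(trees: list[TreeRecord],
                             traits: dict[str, SpeciesTraits],
                             params: FireExposureParams,
                             h_k: float | None = None,
                             allometry: Callable | None = None) -> float:
    """pf.scs_lack_resist: basal-area-weighted mean cohort mortality."""
    live = [t for t in trees if t.stems > 0]
    if not live:
        raise ValueError("empty stand: resistance undefined")
    if h_k is None:
        h_k = scorch_height(params)
    pm = [cohort_mortality(t, _lookup(traits, t.species), params, h_k,
                           allometry) for t in live]
    return _ba_weighted_mean(live, pm)


def stand_lack_of_resilience(trees: list[TreeRecord],
                             traits: dict[str, SpeciesTraits]) -> float:
    """pf.scs_lack_resil: basal-area-weighted mean species sensitivity."""
    live = [t for t in trees if t.stems > 0]
    if not live:
        raise ValueError("empty stand: resilience undefined")
    scores = [_lookup(traits, t.species).resilience_score for t in live]
    return _ba_weighted_mean(live, scores)


# ------------------------------------------------------------- assembly

def stand_raw_indicators(state: StandState,
                         traits: dict[str, SpeciesTraits],
                         params: FireExposureParams | None = None,
                         h_k: float | None = None,
                         conifer_basis: str = "basal_area",
                         allometry: Callable | None = None) -> dict:
    """Raw values of all six stand components for one stand state.

    Empty (e.g. freshly clear-cut) stands score 0 on every component and
    carry ``empty_stand=True`` — no fuel, no crown, nothing to burn.
    """
    params = params or FireExposureParams()
    if state.is_empty:
        return {"basal_area": 0.0, "conifer_share": 0.0, "cv_height": 0.0,
                "sdi": 0.0, "p_mortality": 0.0, "resilience_raw": 0.0,
                "empty_stand": True}
    live = [t for t in state.trees if t.stems > 0]
    return {
        "basal_area": basal_area_per_ha(live),
        "conifer_share": conifer_share(live, traits, conifer_basis),
        "cv_height": cv_height(live),
        "sdi": sdi(live),
        "p_mortality": stand_lack_of_resistance(live, traits, params, h_k,
                                                allometry),
        "resilience_raw": stand_lack_of_resilience(live, traits),
        "empty_stand": False,
    }


def stand_indicator_table(states: list[StandState],
                          traits: dict[str, SpeciesTraits] | None = None,
                          params: FireExposureParams | None = None,
                          conifer_basis: str = "basal_area",
                          allometry: Callable | None = None) -> pd.DataFrame:
    """Raw stand indicators for a collection of stand states, keyed by
    (stand_id, timestep, management, climate). Scorch height is computed
    once and shared."""
    traits = traits or DEFAULT_SPECIES_TRAITS
    params = params or FireExposureParams()
    h_k = scorch_height(params)
    rows = []
    for st in states:
        row = {"stand_id": st.stand_id, "timestep": st.timestep,
               "management": st.management, "climate": st.climate,
               "fcdi": st.fcdi}
        row.update(stand_raw_indicators(st, traits, params, h_k,
                                        conifer_basis, allometry))
        rows.append(row)
    return pd.DataFrame(rows)
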