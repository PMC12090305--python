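"""Component name registry for the fire predisposition assessment system.

The overall score pFire is a 0.5/0.5 weighted sum of eight *site-related*
components (terrain, climate, wildland-urban interface) and six
*stand-related* components (stand composition and structure). Every module
refers to components by the names below.
"""

from __future__ import annotations

# Site-related components, grouped
TERRAIN = ("pf.ter_slp", "pf.ter_asp", "pf.ter_curv")
CLIMATE = ("pf.clim",)
WUI = ("pf.wui_build", "pf.wui_road", "pf.wui_road_drv", "pf.wui_waterbody")

# Stand-related components, grouped (composition & structure split into the
# fuel group and the resistance/resilience group for weighting)
SCS_FUEL = ("pf.scs_fuel", "pf.scs_conif", "pf.scs_vert", "pf.scs_horiz")
SCS_RESIST = ("pf.scs_lack_resist", "pf.scs_lack_resil")

SITE_COMPONENTS = TERRAIN + CLIMATE + WUI
STAND_COMPONENTS = SCS_FUEL + SCS_RESIST
ALL_COMPONENTS = SITE_COMPONENTS + STAND_COMPONENTS

SITE_GROUPS = {"terrain": TERRAIN, "climate": CLIMATE, "wui": WUI}
STAND_GROUPS = {"scs_fuel": SCS_FUEL, "scs_resist": SCS_RESIST}

#: raw-value column feeding each component score
RAW_COLUMNS = {
    "pf.ter_slp": "slope_deg",
    "pf.ter_asp": "aspect_deg",
    "pf.ter_curv": "mean_neg_curv",
    "pf.clim": "fcdi",
    "pf.wui_build": "dist_build",
    "pf.wui_road": "dist_road",
    "pf.wui_road_drv": "dist_road_drv",
    "pf.wui_waterbody": "dist_waterbody",
    "pf.scs_fuel": "basal_area",
    "pf.scs_conif": "conifer_share",
    "pf.scs_vert": "cv_height",
    "pf.scs_horiz": "sdi",
    "pf.scs_lack_resist": "p_mortality",
    "pf.scs_lack_resil": "resilience_raw",
}

#: components whose raw value is rescaled between the 1st and 99th
#: percentile of the pooled observed values, with normalization direction
PERCENTILE_NORMALIZED = {
    "pf.wui_build": "negative",
    "pf.wui_road": "negative",
    "pf.wui_road_drv": "positive",
    "pf.wui_waterbody": "positive",
    "pf.scs_fuel": "positive",
    "pf.scs_vert": "positive",
    "pf.scs_horiz": "positive",
}
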