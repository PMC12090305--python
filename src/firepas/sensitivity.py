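"""Weighting-scenario sensitivity analysis for pFire.

Validation machinery: pFire is recomputed under alternative weighting
scenarios (equal, group-equal, expert, random draws); agreement between
scenario rankings is summarized by Spearman rank correlations, score
distributions are compared in 0.05-wide bins, and predefined scenarios are
located within an ensemble of random-weight scenarios whose component
weights are drawn uniformly from {0, 0.1, ..., 1.0} per side (all-zero
sides rejected and redrawn).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .components import ALL_COMPONENTS, SITE_COMPONENTS, STAND_COMPONENTS
from .weighting import aggregate_pfire


@dataclass
class WeightScenario:
    """A named per-component weight-ratio vector (pre-normalization)."""

    name: str
    weights: dict[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.weights.values()):
            raise ValueError("weights must be >= 0")
        for side in (SITE_COMPONENTS, STAND_COMPONENTS):
            if not any(self.weights.get(c, 0) > 0 for c in side):
                raise ValueError(
                    f"{self.name}: at least one positive weight per side")


class ConstantScoresError(ValueError):
    """A scenario produced a constant pFire vector; its rank correlation
    is undefined and must not be silently reported as 0."""


def spearman_matrix(score_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank correlations between scenario columns.

    ``score_table`` holds one pFire vector per column over an identical
    set of states. Ties get average ranks; a constant column raises.
    """
    if score_table.shape[1] < 2 or score_table.shape[0] < 3:
        raise ValueError("need >= 2 scenarios over >= 3 states")
    for col in score_table.columns:
        if score_table[col].nunique() < 2:
            raise ConstantScoresError(
                f"scenario {col!r} has constant scores; Spearman undefined")
    cols = list(score_table.columns)
    n = len(cols)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            rho = stats.spearmanr(score_table[cols[i]],
                                  score_table[cols[j]]).statistic
            mat[i, j] = mat[j, i] = rho
    return pd.DataFrame(mat, index=cols, columns=cols)


def random_weight_scenarios(n: int, seed: int, step: float = 0.1
                            ) -> list[WeightScenario]:
    """``n`` reproducible random scenarios; each component weight drawn
    uniformly from {0, step, ..., 1}. Draws whose site or stand side is
    all-zero are rejected and redrawn. Scenario i uses a child stream of
    the master seed so the ensemble is extensible."""
    if n < 1:
        raise ValueError("n must be >= 1")
    levels = int(round(1.0 / step))
    master = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(master.spawn(n)):
        rng = np.random.default_rng(child)
        while True:
            draw = rng.integers(0, levels + 1, size=len(ALL_COMPONENTS))
            weights = {c: float(v) * step
                       for c, v in zip(ALL_COMPONENTS, draw)}
            ok = all(any(weights[c] > 0 for c in side)
                     for side in (SITE_COMPONENTS, STAND_COMPONENTS))
            if ok:
                break
        out.append(WeightScenario(f"random_{seed}_{i:04d}", weights))
    return out


def bin_scores(values, bin_width: float = 0.05) -> pd.DataFrame:
    """Histogram of pFire scores in left-closed bins of ``bin_width``
    ([0, 0.05), ..., [0.95, 1.0] with the last bin closed)."""
    arr = np.asarray(values, dtype=float)
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ValueError("scores must lie in [0, 1]")
    nbins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, nbins + 1)
    counts, _ = np.histogram(arr, bins=edges)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "count": counts})


def scenario_sweep(score_table: pd.DataFrame,
                   scenarios: list[WeightScenario]) -> pd.DataFrame:
    """pFire per state per scenario, long-form.

    ``score_table`` holds the 14 component-score columns plus any key
    columns (stand_id, timestep, management, climate), which are carried
    through; output adds ``scenario`` and ``pFire``.
    """
    keys = [c for c in score_table.columns if c not in ALL_COMPONENTS]
    frames = []
    for sc in scenarios:
        pf = aggregate_pfire(score_table[list(ALL_COMPONENTS)], sc.weights)
        frame = score_table[keys].copy()
        frame["scenario"] = sc.name
        frame["pFire"] = pf.to_numpy()
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def ensemble_summary(score_table: pd.DataFrame,
                     predefined: list[WeightScenario],
                     n_random: int, seed: int) -> pd.DataFrame:
    """Mean pFire of each predefined scenario located within the random
    ensemble: rank (1 = highest mean) and quantile of each predefined
    mean among the ``n_random`` random-scenario means."""
    randoms = random_weight_scenarios(n_random, seed)
    comp = score_table[list(ALL_COMPONENTS)]
    random_means = np.array([
        aggregate_pfire(comp, sc.weights).mean() for sc in randoms])
    rows = []
    for sc in predefined:
        m = float(aggregate_pfire(comp, sc.weights).mean())
        rows.append({
            "scenario": sc.name, "mean_pfire": m,
            "ensemble_rank": int(1 + np.sum(random_means > m)),
            "ensemble_quantile": float(np.mean(random_means <= m)),
            "ensemble_min": float(random_means.min()),
            "ensemble_max": float(random_means.max()),
        })
    return pd.DataFrame(rows)
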