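"""Analytic estimators supporting the cross-feeding control arguments.

Three small, self-contained calculations:

* an upper bound on the metabolite concentration that passive cell lysis
  could release into a culture supernatant, given intracellular
  concentration, dead-cell fraction, cell count and cell volume — used to
  argue that observed extracellular amino acids cannot be a lysis artifact;
* an exact rank-sum test that a set of secreted amino acids sits low in a
  biosynthetic-cost ranking;
* a through-origin proportionality fit of total amino acid secretion
  against nitrogen load.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LysisParams",
    "lysis_release",
    "release_ratio",
    "cost_rank_test",
    "nitrogen_response_fit",
]


@dataclass(frozen=True)
class LysisParams:
    """Inputs of the lysis-release bound.

    c_intracellular     intracellular metabolite concentration (mM)
    dead_fraction       fraction of dead/lysed cells (e.g. 0.0004 for 0.04%)
    cells_per_ml_per_od viable cells per mL of culture per unit OD600
    od                  culture optical density (OD600)
    cell_volume_fl      single-cell volume (fL)
    medium_volume_ml    culture volume considered (mL)
    """

    c_intracellular: float
    dead_fraction: float
    cells_per_ml_per_od: float = 32e6
    od: float = 1.0
    cell_volume_fl: float = 45.54
    medium_volume_ml: float = 1.0

    def validate(self) -> None:
        vals = {
            "c_intracellular": self.c_intracellular,
            "dead_fraction": self.dead_fraction,
            "cells_per_ml_per_od": self.cells_per_ml_per_od,
            "od": self.od,
            "cell_volume_fl": self.cell_volume_fl,
            "medium_volume_ml": self.medium_volume_ml,
        }
        for name, v in vals.items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.dead_fraction > 1:
            raise ValueError(f"dead_fraction must be <= 1, got {self.dead_fraction}")
        if self.medium_volume_ml == 0:
            raise ValueError("medium volume must be positive")


def lysis_release(params: LysisParams) -> float:
    """Concentration (mM) released into the medium by lysis of dead cells.

    The lysed cells' total intracellular volume is diluted into the medium:
    C = c_intra · (dead_fraction · cells/mL/OD · OD · V_medium · V_cell) / V_medium,
    with cell volume converted fL → L. Linear in every factor.
    """
    params.validate()
    n_lysed = (
        params.dead_fraction
        * params.cells_per_ml_per_od
        * params.od
        * params.medium_volume_ml
    )
    lysed_volume_l = n_lysed * params.cell_volume_fl * 1e-15
    medium_volume_l = params.medium_volume_ml * 1e-3
    return params.c_intracellular * lysed_volume_l / medium_volume_l


def release_ratio(observed_mm: float, estimated_mm: float) -> float:
    """Observed / lysis-estimated concentration; inf when the estimate is 0."""
    if estimated_mm < 0 or observed_mm < 0:
        raise ValueError("concentrations must be non-negative")
    if estimated_mm == 0:
        return math.inf
    return observed_mm / estimated_mm


def cost_rank_test(
    costs: pd.Series, secreted: set[str] | list[str], metric: str | None = None
) -> tuple[dict[str, float], float, float]:
    """Exact one-sided rank-sum test that secreted amino acids are cheap.

    ``costs`` maps amino acid → biosynthetic cost under one metric (pass a
    DataFrame column; ``metric`` selects a column if a DataFrame is given).
    Returns (ranks of secreted amino acids, rank-sum statistic, exact
    one-sided p). The p-value is the fraction of all C(n, |S|) equally
    likely assignments of the secreted labels whose rank-sum is ≤ the
    observed one — exact under ties via midranks.
    """
    if isinstance(costs, pd.DataFrame):
        if metric is None:
            raise ValueError("metric column required for a DataFrame cost table")
        costs = costs[metric]
    secreted = sorted(set(secreted))
    if not secreted:
        raise ValueError("secreted set is empty")
    missing = [a for a in secreted if a not in costs.index]
    if missing:
        raise KeyError(f"secreted amino acids missing from cost table: {missing}")
    ranks = pd.Series(
        stats.rankdata(costs.to_numpy(dtype=float)), index=costs.index
    )
    sec_ranks = ranks[secreted]
    observed = float(sec_ranks.sum())
    n, k = len(costs), len(secreted)
    all_ranks = ranks.to_numpy()
    count = 0
    total = math.comb(n, k)
    for combo in itertools.combinations(range(n), k):
        if all_ranks[list(combo)].sum() <= observed + 1e-9:
            count += 1
    p = count / total
    return dict(sec_ranks), observed, p


def nitrogen_response_fit(
    nitrogen_levels, total_secretion
) -> tuple[float, float]:
    """Least-squares proportionality fit y = k·x through the origin.

    Returns (slope k, R² of the through-origin fit, i.e. 1 − SS_res/Σy²).
    A poor R² is reported as-is: it is the evidence against proportionality.
    """
    x = np.asarray(nitrogen_levels, dtype=float)
    y = np.asarray(total_secretion, dtype=float)
    if x.shape != y.shape:
        raise ValueError("nitrogen levels and secretion totals differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 nitrogen levels")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("all nitrogen levels are zero")
    slope = float(np.sum(x * y) / sxx)
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum(y * y))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return slope, r2
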