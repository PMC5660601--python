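"""Correlation of expression and secretion phenotypes with LAB growth.

The experimental design is small-n by nature: a handful of yeast strains
(regulatory knockouts plus wild type) each condition a medium, and the
growth of a lactic acid bacterium in that medium is the phenotype. Three
layers of inference are provided:

1. per-gene Spearman and Pearson correlations between expression across
   strains and LAB growth;
2. exact permutation p-values for small-n Spearman correlations by full
   enumeration of rank permutations (n ≤ 8);
3. reporter-style gene-set enrichment: per-gene correlation ranks are
   converted to normal scores, combined into one z per gene, set scores are
   mean member z, and significance comes from a permutation null of random
   same-size gene draws, followed by Benjamini–Hochberg correction.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneCorr",
    "EnrichmentResult",
    "gene_growth_correlations",
    "exact_spearman_p",
    "exact_spearman_p_fraction",
    "rank_combine_z",
    "reporter_enrichment",
    "bh_adjust",
    "secretion_growth_association",
]

logger = logging.getLogger(__name__)

MAX_EXACT_N = 8
DEFAULT_N_PERM = 10_000
DEFAULT_MIN_SET_SIZE = 5


@dataclass(frozen=True)
class GeneCorr:
    gene: str
    rho_spearman: float
    rho_pearson: float
    zero_variance: bool = False


@dataclass(frozen=True)
class EnrichmentResult:
    name: str
    size: int
    score_z: float
    p: float
    q: float
    direction: str


# ---------------------------------------------------------------------------
# per-gene correlations


def gene_growth_correlations(expr: pd.DataFrame, growth: pd.Series) -> pd.DataFrame:
    """Spearman and Pearson correlation of each gene's expression with growth.

    ``expr`` is genes × strains; ``growth`` maps strain → LAB final OD.
    Zero-variance genes are flagged (rho set to 0) rather than dropped.
    """
    strains = list(expr.columns)
    if set(strains) != set(growth.index):
        raise ValueError("strain sets of expression matrix and growth table differ")
    if len(strains) < 3:
        raise ValueError("need at least 3 strains for correlation")
    g = growth.reindex(strains).to_numpy(dtype=float)
    X = expr.to_numpy(dtype=float)

    def corr_rows(M, v):
        Mc = M - M.mean(axis=1, keepdims=True)
        vc = v - v.mean()
        denom = np.sqrt((Mc**2).sum(axis=1) * (vc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Mc @ vc) / denom
        return r

    pearson = corr_rows(X, g)
    ranks = stats.rankdata(X, axis=1)
    g_ranks = stats.rankdata(g)
    spearman = corr_rows(ranks, g_ranks)
    zero_var = X.std(axis=1) == 0
    return pd.DataFrame(
        {
            "rho_spearman": np.where(zero_var, 0.0, spearman),
            "rho_pearson": np.where(zero_var, 0.0, pearson),
            "zero_variance": zero_var,
        },
        index=expr.index,
    )


# ---------------------------------------------------------------------------
# exact small-n Spearman inference


def _spearman_rho_from_perm(perm: tuple[int, ...], n: int) -> float:
    d2 = sum((perm[i] - i) ** 2 for i in range(n))
    return 1.0 - 6.0 * d2 / (n * (n * n - 1))


def exact_spearman_p_fraction(
    rho_obs: float, n: int, alternative: str = "one-sided-greater"
) -> Fraction:
    """Exact permutation p-value for a Spearman rho at sample size n.

    Enumerates all n! rank permutations; the p-value is the fraction with
    rho ≥ rho_obs (one-sided-greater) or |rho| ≥ |rho_obs| (two-sided),
    returned as an exact rational. Valid for untied ranks with 3 ≤ n ≤ 8.
    """
    if not 3 <= n <= MAX_EXACT_N:
        raise ValueError(
            f"exact enumeration supports 3 <= n <= {MAX_EXACT_N}; "
            f"use an approximate method for n = {n}"
        )
    if alternative not in ("one-sided-greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    tol = 1e-12
    count = 0
    total = math.factorial(n)
    for perm in itertools.permutations(range(n)):
        rho = _spearman_rho_from_perm(perm, n)
        if alternative == "one-sided-greater":
            hit = rho >= rho_obs - tol
        else:
            hit = abs(rho) >= abs(rho_obs) - tol
        if hit:
            count += 1
    return Fraction(count, total)


def exact_spearman_p(
    rho_obs: float, n: int, alternative: str = "one-sided-greater"
) -> float:
    return float(exact_spearman_p_fraction(rho_obs, n, alternative))


def secretion_growth_association(
    totals: pd.Series, growth: pd.Series, alternative: str = "one-sided-greater"
) -> tuple[float, float]:
    """Spearman rho between per-strain totals and LAB growth, with exact p.

    Tied values are midranked; with ties the enumerated null (over untied
    permutations) is approximate, which is logged.
    """
    strains = [s for s in totals.index if s in growth.index]
    if len(strains) != len(totals) or len(strains) != len(growth):
        raise ValueError("strain sets of totals and growth differ")
    x = totals.reindex(strains).to_numpy(dtype=float)
    y = growth.reindex(strains).to_numpy(dtype=float)
    n = len(x)
    if len(set(x)) < n or len(set(y)) < n:
        logger.warning("ties present: midranks used; exact p is approximate")
    rho = round(float(stats.spearmanr(x, y).statistic), 12)  # snap float noise
    p = exact_spearman_p(rho, n, alternative=alternative)
    return rho, p


# ---------------------------------------------------------------------------
# rank combination and reporter enrichment


def rank_combine_z(
    corrs: pd.DataFrame, scaling: str = "empirical"
) -> pd.DataFrame:
    """Combine the two correlation rankings into one z and p per gene.

    Each coefficient column is midranked across genes (largest rho → largest
    rank) and mapped to a normal score Φ⁻¹(rank / (n+1)). The two scores are
    averaged; the average is rescaled to unit variance either with the
    empirically estimated correlation between the two score vectors
    (``scaling="empirical"``, default) or assuming independence
    (``scaling="sqrt2"``). p is the standard normal upper tail of z.
    """
    if len(corrs) < 2:
        raise ValueError("need at least 2 genes to rank")
    if scaling not in ("empirical", "sqrt2"):
        raise ValueError(f"unknown scaling {scaling!r}")
    n = len(corrs)

    def normal_scores(values):
        r = stats.rankdata(values)
        return stats.norm.ppf(r / (n + 1))

    z_s = normal_scores(corrs["rho_spearman"].to_numpy(dtype=float))
    z_p = normal_scores(corrs["rho_pearson"].to_numpy(dtype=float))
    mean_z = (z_s + z_p) / 2.0
    if np.allclose(mean_z, 0.0):
        z = np.zeros(n)
    else:
        if scaling == "empirical":
            rho_sp = float(np.corrcoef(z_s, z_p)[0, 1]) if n > 2 else 1.0
            if not np.isfinite(rho_sp):
                rho_sp = 1.0
            scale = math.sqrt((1.0 + rho_sp) / 2.0)
        else:
            scale = math.sqrt(0.5)
        scale = max(scale, 1e-12)
        z = mean_z / scale
    return pd.DataFrame(
        {"z": z, "p": stats.norm.sf(z)}, index=corrs.index
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values (monotone in p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def reporter_enrichment(
    gene_z: pd.Series,
    gene_sets: dict[str, list[str]],
    n_perm: int = DEFAULT_N_PERM,
    min_size: int = DEFAULT_MIN_SET_SIZE,
    seed: int = 0,
) -> pd.DataFrame:
    """Reporter-style gene-set enrichment against a permutation null.

    A set's score is the mean z of its member genes present in ``gene_z``.
    The null for size k is the distribution of mean z over ``n_perm`` random
    draws of k genes without replacement; p is the upper-tail fraction with
    a (r+1)/(n_perm+1) continuity correction, and q is BH-adjusted across
    all tested sets. Sets smaller than ``min_size`` (after intersection with
    the measured genes) are excluded with a log notice.
    """
    rng = np.random.default_rng(seed)
    z = gene_z.to_numpy(dtype=float)
    index = {g: i for i, g in enumerate(gene_z.index)}
    n_genes = len(z)

    tested: list[dict] = []
    skipped: list[str] = []
    member_idx: dict[str, np.ndarray] = {}
    for name, genes in gene_sets.items():
        idx = np.array([index[g] for g in genes if g in index], dtype=int)
        if idx.size == 0:
            skipped.append(name)
            logger.warning("gene set %r has no genes in the matrix; skipped", name)
            continue
        if idx.size < min_size:
            skipped.append(name)
            logger.info("gene set %r below min size %d; excluded", name, min_size)
            continue
        member_idx[name] = idx

    null_by_size: dict[int, np.ndarray] = {}
    for k in sorted({v.size for v in member_idx.values()}):
        draws = np.empty(n_perm)
        for i in range(n_perm):
            draws[i] = z[rng.choice(n_genes, size=k, replace=False)].mean()
        null_by_size[k] = np.sort(draws)

    for name, idx in member_idx.items():
        score = float(z[idx].mean())
        null = null_by_size[idx.size]
        # upper tail with mid-p handling of exact ties (tolerance absorbs
        # float summation-order noise)
        tol = 1e-9 * max(1.0, abs(score))
        n_ge = null.size - np.searchsorted(null, score - tol, side="left")
        n_gt = null.size - np.searchsorted(null, score + tol, side="right")
        r = n_gt + 0.5 * (n_ge - n_gt)
        p = (r + 1) / (n_perm + 1)
        tested.append(
            {
                "name": name,
                "size": int(idx.size),
                "score_z": score,
                "p": p,
                "direction": "up" if score >= 0 else "down",
            }
        )
    df = pd.DataFrame(tested, columns=["name", "size", "score_z", "p", "direction"])
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
    else:
        df["q"] = np.array([], dtype=float)
    df.attrs["skipped_sets"] = skipped
    return df.set_index("name")[["size", "score_z", "p", "q", "direction"]]
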