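"""Genotype–phenotype statistics for per-individual cohort tables.

A cohort table has one row per individual: a three-level duplication
genotype (WT/WT, WT/dup, dup/dup) and a positive continuous phenotype
(hepatic expression in arbitrary units, or a pharmacokinetic AUC in
min×ng/ml). The primary comparison contrasts the homozygote groups with a
two-sided Mann–Whitney U test; effect sizes are summarised as percent
reduction of the group median, and the share of phenotype variability
attributable to the genotype as the R² of an allele-dosage regression on
log phenotype with a permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

GENOTYPE_DOSAGE = {"WT/WT": 0, "WT/dup": 1, "dup/dup": 2}


def validate_cohort(table: pd.DataFrame, phenotype_col: str) -> None:
    if not set(table["genotype"]) <= set(GENOTYPE_DOSAGE):
        raise ValueError("genotype must be one of WT/WT, WT/dup, dup/dup")
    if (table[phenotype_col] <= 0).any():
        raise ValueError("phenotype values must be positive")


def mann_whitney(group_a, group_b, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns (U of group_a, p).

    ``mode='exact'`` enumerates the null distribution (valid without ties);
    ``'normal_approx'`` uses the normal approximation with tie and
    continuity corrections; ``'auto'`` picks exact when min(nA, nB) <= 8 and
    the pooled values contain no ties.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        return a.size * b.size / 2, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        mode = "exact" if (min(a.size, b.size) <= 8 and not has_ties) \
            else "normal_approx"
    if mode == "exact":
        if has_ties:
            raise ValueError("exact mode requires tie-free data")
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="exact")
    elif mode == "normal_approx":
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(res.statistic), float(res.pvalue)


def mann_whitney_enumerate(group_a, group_b) -> tuple[float, float]:
    """Brute-force exact test by full enumeration of rank assignments.

    Independent oracle used for validation; O(C(nA+nB, nA)).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size < pooled.size:
        raise ValueError("enumeration oracle requires tie-free data")
    n, na = pooled.size, a.size
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    mean_u = na * (b.size) / 2
    count = 0
    for idx in combinations(range(n), na):
        u = ranks[list(idx)].sum() - na * (na + 1) / 2
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return float(u_obs), count / comb(n, na)


@dataclass(frozen=True)
class MedianReduction:
    percent: float            # 100 * (1 - median(dup) / median(wt))
    percent_rounded: int
    median_dup: float
    median_wt: float


def median_reduction(dup_values, wt_values) -> MedianReduction:
    """Percent reduction of the duplication-group median vs wild type."""
    m_dup = float(np.median(np.asarray(dup_values, dtype=float)))
    m_wt = float(np.median(np.asarray(wt_values, dtype=float)))
    if m_wt == 0:
        raise ValueError("wild-type median is zero")
    pct = 100.0 * (1.0 - m_dup / m_wt)
    return MedianReduction(percent=pct, percent_rounded=round(pct),
                           median_dup=m_dup, median_wt=m_wt)


@dataclass(frozen=True)
class VarianceExplained:
    r_squared: float
    slope_log: float          # per-allele effect on log phenotype
    p_permutation: float
    n_permutations: int


def variance_explained(table: pd.DataFrame, phenotype_col: str,
                       n_permutations: int = 1000,
                       seed: int = 0) -> VarianceExplained:
    """R² of regressing log phenotype on duplication-allele dosage (0/1/2),
    with a permutation p-value for the R²."""
    validate_cohort(table, phenotype_col)
    y = np.log(table[phenotype_col].to_numpy(dtype=float))
    x = table["genotype"].map(GENOTYPE_DOSAGE).to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need at least two genotype groups")

    def r2(xv: np.ndarray) -> float:
        c = np.corrcoef(xv, y)[0, 1]
        return float(c * c)

    slope = float(np.polyfit(x, y, 1)[0])
    obs = r2(x)
    rng = np.random.default_rng(seed)
    hits = 0
    xp = x.copy()
    for _ in range(n_permutations):
        rng.shuffle(xp)
        if r2(xp) >= obs - 1e-15:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return VarianceExplained(r_squared=obs, slope_log=slope, p_permutation=p,
                             n_permutations=n_permutations)


def effect_for_target_r2(dosages, sigma_log: float,
                         target_r2: float) -> float:
    """Per-allele log effect giving a population R² of ``target_r2`` for the
    given dosage distribution and residual log-SD."""
    x = np.asarray(dosages, dtype=float)
    var_x = x.var()
    if var_x == 0:
        raise ValueError("dosage distribution is degenerate")
    if not 0 <= target_r2 < 1:
        raise ValueError("target_r2 must be in [0, 1)")
    return -sigma_log * np.sqrt(target_r2 / ((1 - target_r2) * var_x))


def simulate_cohort(n_per_genotype: dict[str, int], median_wt: float,
                    median_reduction_hom: float, sigma_log: float,
                    seed: int = 0,
                    phenotype_col: str = "phenotype") -> pd.DataFrame:
    """Log-normal phenotypes with a log-additive per-allele median shift.

    The homozygous duplication median is reduced by
    ``median_reduction_hom`` (fraction of the wild-type median);
    heterozygotes sit at the geometric midpoint.
    """
    if not 0 <= median_reduction_hom < 1:
        raise ValueError("median_reduction_hom must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    beta = 0.5 * np.log(1 - median_reduction_hom)   # per-allele log effect
    for gt, n in n_per_genotype.items():
        dose = GENOTYPE_DOSAGE[gt]
        mu = np.log(median_wt) + beta * dose
        vals = np.exp(rng.normal(mu, sigma_log, size=n))
        for j, v in enumerate(vals):
            rows.append((f"{gt}-{j:03d}", gt, float(v)))
    return pd.DataFrame(rows, columns=["id", "genotype", phenotype_col])


def hwe_genotype_counts(n: int, maf: float) -> dict[str, int]:
    """Hardy–Weinberg genotype counts for the duplication allele."""
    p = maf
    n_hom = round(n * p * p)
    n_het = round(n * 2 * p * (1 - p))
    return {"WT/WT": n - n_hom - n_het, "WT/dup": n_het, "dup/dup": n_hom}
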