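"""Estimands of the splicing study: splice fractions, allele fractions,
allelic expression imbalance, and closed-form inversion of the
mis-splicing/decay model.

Model (heterozygote, equal allelic transcription, complete linkage): each
duplication-haplotype transcript is alternatively spliced with probability
``m``; each alternative transcript is degraded before sequencing with
probability ``d``. Among surviving transcripts the A-allele read fraction is

    f_A = (1 - m d) / (2 - m d),

the alternative-read fraction is ``m (1 - d) / (2 - m d)``, and the ratio of
correctly spliced A to G reads is ``r = 1 - m``. Observing f_A and the
alternative fraction therefore identifies (m, d) in closed form:

    m d = (1 - 2 f_A) / (1 - f_A),
    m   = m d + alt_frac * (2 - m d),
    d   = m d / m.

Binomial proportions carry Wilson (score) 95% intervals — the observed liver
alternative fractions sit near 0.3%, where Wald intervals degenerate.
Unclassified reads are excluded from every denominator and reported
separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from . import refmodel as rm
from .classify import UNCLASSIFIED, CountTable

Z95 = 1.959964


def wilson_ci(count: int | np.ndarray, nobs: int | np.ndarray,
              ) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    return lo, hi


@dataclass(frozen=True)
class SpliceQuant:
    f_correct: float
    ci95: tuple[float, float]
    n_classified: int
    unclassified_frac: float


def splice_fraction(counts: CountTable) -> SpliceQuant:
    """Fraction of classified reads that are correctly spliced, with 95% CI."""
    n_cor = counts.n(splice=rm.CORRECT)
    n_alt = counts.n(splice=rm.ALTERNATIVE)
    n = n_cor + n_alt
    if n == 0:
        raise ValueError("no reads with a splice classification")
    lo, hi = wilson_ci(n_cor, n)
    return SpliceQuant(f_correct=n_cor / n, ci95=(float(lo), float(hi)),
                       n_classified=n,
                       unclassified_frac=1 - n / counts.total
                       if counts.total else 0.0)


@dataclass(frozen=True)
class AlleleQuant:
    f_A: float
    ci95: tuple[float, float]
    n_A: int
    n_G: int
    stratum: str


def allele_fraction(counts: CountTable, stratum: str = "all") -> AlleleQuant:
    """A-allele fraction among allele-classified reads.

    ``stratum='all'`` uses every read with a called allele; ``'correct_only'``
    restricts to reads also called correctly spliced.
    """
    if stratum == "all":
        n_a, n_g = counts.n(allele="A"), counts.n(allele="G")
    elif stratum == "correct_only":
        n_a = counts.n(splice=rm.CORRECT, allele="A")
        n_g = counts.n(splice=rm.CORRECT, allele="G")
    else:
        raise ValueError(f"unknown stratum {stratum!r}")
    n = n_a + n_g
    if n == 0:
        raise ValueError("no reads with an allele classification")
    lo, hi = wilson_ci(n_a, n)
    return AlleleQuant(f_A=n_a / n, ci95=(float(lo), float(hi)),
                       n_A=n_a, n_G=n_g, stratum=stratum)


# ---------------------------------------------------------------------------
# Allelic expression imbalance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AEIResult:
    f_A_DNA: float
    f_A_RNA: float
    diff: float
    t_stat: float
    p_value: float
    n_samples: int
    zero_variance: bool = False


def aei_test(pairs: list[tuple[float, float]]) -> AEIResult:
    """Paired two-sided t-test of per-sample DNA vs RNA A-allele fractions."""
    if len(pairs) < 2:
        raise ValueError("need at least two (DNA, RNA) pairs")
    dna = np.array([p[0] for p in pairs], dtype=float)
    rna = np.array([p[1] for p in pairs], dtype=float)
    diffs = dna - rna
    if np.allclose(diffs.std(ddof=1), 0.0):
        # degenerate: identical differences in every sample
        p = 1.0 if math.isclose(float(diffs.mean()), 0.0, abs_tol=1e-15) \
            else 0.0
        return AEIResult(float(dna.mean()), float(rna.mean()),
                         float(diffs.mean()), t_stat=math.inf if p == 0.0
                         else 0.0, p_value=p, n_samples=len(pairs),
                         zero_variance=True)
    t, p = stats.ttest_rel(dna, rna)
    return AEIResult(float(dna.mean()), float(rna.mean()),
                     float(diffs.mean()), t_stat=float(t), p_value=float(p),
                     n_samples=len(pairs))


# ---------------------------------------------------------------------------
# Forward model and closed-form inversion
# ---------------------------------------------------------------------------

def forward_allele_fraction(m, d):
    """Heterozygote surviving A-read fraction (1 - md) / (2 - md), rho = 1."""
    md = np.asarray(m, dtype=float) * np.asarray(d, dtype=float)
    return (1 - md) / (2 - md)


def forward_alt_fraction(m, d, genotype: str = "WT/dup"):
    """Surviving alternative-read fraction for a duplication carrier."""
    m = np.asarray(m, dtype=float)
    d = np.asarray(d, dtype=float)
    if genotype == "WT/dup":
        return m * (1 - d) / (2 - m * d)
    if genotype == "dup/dup":
        return m * (1 - d) / (1 - m * d)
    raise ValueError("alternative reads require a duplication allele")


def solve_decay_for_alt_frac(m: float, alt_frac: float,
                             genotype: str = "dup/dup") -> float:
    """Decay probability d such that the surviving alternative fraction
    equals ``alt_frac`` at mis-splicing probability ``m``."""
    if not 0 < m <= 1:
        raise ValueError("m must be in (0, 1]")
    if genotype == "dup/dup":
        d = (m - alt_frac) / (m * (1 - alt_frac))
    elif genotype == "WT/dup":
        d = (m - 2 * alt_frac) / (m * (1 - alt_frac))
    else:
        raise ValueError("alternative reads require a duplication allele")
    if not 0 <= d <= 1:
        raise ValueError("no valid decay probability for these inputs")
    return d


@dataclass(frozen=True)
class NMDEstimate:
    md: float
    m: float
    d: float
    r: float              # expected correct-A / correct-G ratio, 1 - m
    flags: tuple[str, ...] = ()

    @property
    def clamped(self) -> bool:
        return any("clamp" in f or "imbalance" in f for f in self.flags)


def _clamp01(x: float, name: str, flags: list[str]) -> float:
    if x < 0.0:
        flags.append(f"{name} clamped from {x:.6g} to 0")
        return 0.0
    if x > 1.0:
        flags.append(f"{name} clamped from {x:.6g} to 1")
        return 1.0
    return x


def nmd_invert(f_A_RNA: float, alt_frac: float) -> NMDEstimate:
    """Invert the heterozygote forward model for (m, d).

    Assumes equal allelic transcription (rho = 1) and complete linkage;
    values falling outside [0, 1] are clamped with explicit flags.
    """
    if not 0.0 < f_A_RNA < 1.0:
        raise ValueError("f_A_RNA must be in (0, 1)")
    if not 0.0 <= alt_frac < 1.0:
        raise ValueError("alt_frac must be in [0, 1)")
    flags: list[str] = []
    if f_A_RNA >= 0.5:
        md = 0.0
        flags.append("no detectable imbalance")
    else:
        md = (1 - 2 * f_A_RNA) / (1 - f_A_RNA)
    md = _clamp01(md, "md", flags)
    m = md + alt_frac * (2 - md)
    m = _clamp01(m, "m", flags)
    d = md / m if m > 0 else 0.0
    d = _clamp01(d, "d", flags)
    return NMDEstimate(md=md, m=m, d=d, r=1 - m, flags=tuple(flags))


def nmd_from_ratio(r: float, md: float | None = None) -> NMDEstimate:
    """Estimate mis-splicing from the correct-read A/G ratio: m = 1 - r.

    With the md product supplied (from the allele-fraction estimator) the
    decay probability follows as d = md / m.
    """
    if r < 0:
        raise ValueError("ratio must be non-negative")
    flags: list[str] = []
    m = _clamp01(1 - r, "m", flags)
    if md is None:
        return NMDEstimate(md=math.nan, m=m, d=math.nan, r=r,
                           flags=tuple(flags))
    if m == 0 and md > 0:
        flags.append("md > 0 with m = 0: inconsistent inputs, d undefined")
        d = math.nan
    else:
        d = _clamp01(md / m, "d", flags) if m > 0 else 0.0
    return NMDEstimate(md=md, m=m, d=d, r=r, flags=tuple(flags))


# ---------------------------------------------------------------------------
# Pyrosequencing-style linear calibration
# ---------------------------------------------------------------------------

def pyro_calibrate(known_fracs: list[float],
                   observed_signals: list[float]) -> tuple[float, float]:
    """Least-squares line mapping true fractions to observed signals.

    Returns (slope, intercept) of signal = slope * frac + intercept, fit on a
    calibration series of constructs with known isoform fractions.
    """
    x = np.asarray(known_fracs, dtype=float)
    y = np.asarray(observed_signals, dtype=float)
    if x.size != y.size or x.size < 2 or np.unique(x).size < 2:
        raise ValueError("need at least two distinct known fractions")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def pyro_apply(calibration: tuple[float, float], signal: float) -> float:
    """Invert the calibration line; corrected fractions are clamped to [0,1]."""
    slope, intercept = calibration
    if slope == 0:
        raise ValueError("degenerate calibration: zero slope")
    return float(min(1.0, max(0.0, (signal - intercept) / slope)))
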