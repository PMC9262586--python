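"""Reversion-rate statistics, group comparisons and digital-PCR algebra.

Frequencies and rates are reported as medians with 95% confidence intervals
from exact binomial order statistics (or min–max ranges below six
replicates).  Group comparisons use the two-sided Mann–Whitney U test for
rates and Fisher's exact test for fractions.  Digital-PCR quantification
converts positive-droplet fractions to concentrations through Poisson
occupancy, lambda = -ln(1 - positives/total).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RateEstimate",
    "reversion_frequency",
    "median_rate",
    "compare_groups",
    "compare_fractions",
    "predict_fraction_shift",
    "du_mutation_fraction",
    "ddpcr_frequency",
    "outcome_fractions",
]


@dataclass(frozen=True)
class RateEstimate:
    n_cultures: int
    median: float
    ci_low: float
    ci_high: float
    method: str  # "binomial_order_statistic" or "range"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.median <= self.ci_high):
            raise ValueError("CI must bracket the median")


def reversion_frequency(
    selective_count: float,
    selective_volume_factor: float,
    viable_count: float,
    viable_volume_factor: float,
) -> float:
    """Per-cell reversion frequency from plate counts.

    ``frequency = (selective_count x its volume factor) /
    (viable_count x its volume factor)``; the volume factors scale each plate
    count up to the whole culture.
    """
    if selective_count < 0 or viable_count < 0:
        raise ValueError("counts must be >= 0")
    viable_total = viable_count * viable_volume_factor
    if viable_total <= 0:
        raise ValueError("viable cell estimate must be positive")
    return (selective_count * selective_volume_factor) / viable_total


def median_ci_ranks(n: int, confidence: float = 0.95) -> tuple[int, int]:
    """Largest symmetric order-statistic ranks (1-based) with coverage >= confidence."""
    best = (1, n)
    for j in range(1, n // 2 + 1):
        coverage = 1.0 - 2.0 * sps.binom.cdf(j - 1, n, 0.5)
        if coverage >= confidence:
            best = (j, n + 1 - j)
        else:
            break
    return best


def median_rate(frequencies, confidence: float = 0.95) -> RateEstimate:
    """Median of per-culture frequencies with a 95% CI.

    For n >= 6 the interval is the exact binomial order-statistic CI of the
    median (the smallest symmetric rank pair reaching the requested
    coverage); below 6 replicates the reported interval is the min–max
    range.
    """
    x = np.sort(np.asarray(list(frequencies), dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("need at least one culture")
    med = float(np.median(x))
    if n < 6:
        return RateEstimate(n, med, float(x[0]), float(x[-1]), "range")
    lo_rank, hi_rank = median_ci_ranks(n, confidence)
    return RateEstimate(n, med, float(x[lo_rank - 1]), float(x[hi_rank - 1]),
                        "binomial_order_statistic")


def compare_groups(freqs_a, freqs_b) -> dict:
    """Two-sided Mann–Whitney U comparison of two rate/frequency groups.

    Exact enumeration when both groups have at most 8 observations and no
    ties across groups; tie-corrected normal approximation otherwise.
    All-tied inputs return p = 1, flagged.
    """
    a = np.asarray(list(freqs_a), dtype=float)
    b = np.asarray(list(freqs_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return {"p_value": 1.0, "statistic": a.size * b.size / 2.0,
                "method": "degenerate", "flags": ("all_tied",)}
    has_ties = np.unique(pooled).size < pooled.size
    if max(a.size, b.size) <= 8 and not has_ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        method = "asymptotic"
    return {"p_value": float(min(res.pvalue, 1.0)), "statistic": float(res.statistic),
            "method": method, "flags": ()}


def compare_fractions(table) -> dict:
    """Two-sided Fisher's exact test on a 2x2 count table."""
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(np.int64)
        if t.shape != (2, 2) or (t < 0).any():
            raise ValueError("table must be 2x2 with nonnegative integer counts")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return {"p_value": float(p), "odds_ratio": float(odds), "method": "fisher_exact"}


def predict_fraction_shift(
    frac_a: float, overall_rate_ratio: float, class_rate_ratio: float
) -> float:
    """Predict a deletion class's fraction after an orientation change.

    If the complementary class rises ``class_rate_ratio``-fold while the
    overall reversion rate rises ``overall_rate_ratio``-fold, the focal
    class's frequency falls ``class_rate_ratio``-fold and its *fraction* of
    outcomes becomes ``frac_a / (class_rate_ratio * overall_rate_ratio)``.
    E.g. a class at 33% of outcomes with ratios 5.1 and 3.3 drops to ~2%.
    """
    if frac_a <= 0 or overall_rate_ratio <= 0 or class_rate_ratio <= 0:
        raise ValueError("inputs must be positive")
    return frac_a / (class_rate_ratio * overall_rate_ratio)


def du_mutation_fraction(ung1_to_wt_rate_ratio: float) -> float:
    """Percentage of dU lesions that become mutations with Ung1 active.

    Assumes every dU mutates when uracil glycosylase is absent, so the
    wild-type mutation fraction is ``100 / ratio`` percent: a 4.2x
    ung1Δ/UNG1 rate ratio implies ~24% of dUs led to mutations.
    """
    if ung1_to_wt_rate_ratio < 1:
        raise ValueError("ratio must be >= 1 (ung1Δ rate cannot be below wild type)")
    return 100.0 / ung1_to_wt_rate_ratio


def ddpcr_frequency(
    pos_target: int,
    total_target: int,
    pos_ref: int,
    total_ref: int,
    dilution_ratio: float = 1.0,
) -> float:
    """Event frequency per genome from two-channel droplet counts.

    Per channel, the concentration is ``lambda = -ln(1 - positives/total)``
    (Poisson occupancy); the frequency is the target/reference concentration
    ratio times the dilution ratio between the two reactions.  Saturated
    channels (every droplet positive) are undefined.
    """
    for pos, total in ((pos_target, total_target), (pos_ref, total_ref)):
        if total <= 0 or not (0 <= pos <= total):
            raise ValueError("need 0 <= positives <= total with total > 0")
    if pos_target == total_target or pos_ref == total_ref:
        raise ValueError("saturated channel: concentration undefined")
    if pos_ref == 0:
        raise ValueError("reference channel has no positive droplets")
    lam_t = -math.log(1.0 - pos_target / total_target)
    lam_r = -math.log(1.0 - pos_ref / total_ref)
    return (lam_t / lam_r) * dilution_ratio


def outcome_fractions(
    phenotypes: pd.DataFrame,
    classes: tuple[str, ...] = ("BIR", "gene_conversion", "chromosome_loss", "half_crossover"),
    reference_strain: str | None = None,
    strain_col: str = "strain",
    class_col: str = "outcome_class",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-strain DSB-repair outcome fractions with Fisher comparisons.

    ``phenotypes`` holds one colony per row with a strain label and an
    outcome class.  Returns ``(fractions, comparisons)``: per-strain class
    fractions (summing to 1), and for each non-reference strain and class a
    two-sided Fisher p-value of class-vs-rest against the reference strain.
    Unknown class codes raise ``ValueError``.
    """
    unknown = set(phenotypes[class_col]) - set(classes)
    if unknown:
        raise ValueError(f"unknown phenotype codes: {sorted(unknown)}")
    counts = (
        phenotypes.groupby([strain_col, class_col]).size()
        .unstack(fill_value=0).reindex(columns=list(classes), fill_value=0)
    )
    fractions = counts.div(counts.sum(axis=1), axis=0)
    comparisons = []
    if reference_strain is not None:
        ref = counts.loc[reference_strain]
        ref_total = int(ref.sum())
        for strain in counts.index:
            if strain == reference_strain:
                continue
            row = counts.loc[strain]
            total = int(row.sum())
            for cls in classes:
                table = [[int(row[cls]), total - int(row[cls])],
                         [int(ref[cls]), ref_total - int(ref[cls])]]
                comparisons.append(dict(
                    strain=strain, outcome_class=cls,
                    p_value=compare_fractions(table)["p_value"],
                ))
    return fractions, pd.DataFrame(comparisons)
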