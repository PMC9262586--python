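"""Variant filtering and strand-resolved classification.

Per-outcome variant sets (from any caller, as tables or VCF) are filtered by
allele fraction, purged of recurrent pre-existing variants, and classified:

* ``strand_class``: ``CtoN`` for Watson-strand C references (A3A lesions in
  the nascent-strand ssDNA, the lagging-strand template), ``GtoN`` for
  Watson-strand G references (lesions in the D-loop bottom template strand),
  ``other`` for everything else.  Indels are ingested but classed ``other``.
* ``arm`` / ``on_track``: position relative to the centromere and the BIR
  track interval.
* ``tcw``: whether the variant sits in an A3A-preferred TCA/TCT (TCW) motif,
  evaluated on the Watson strand for C references and on the Crick strand
  (reverse complement) for G references.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeModel

__all__ = [
    "filter_variants",
    "classify_strand_and_track",
    "annotate_motif",
    "summarize_outcomes",
    "run_variant_pipeline",
    "OutcomeSummary",
]

TCW = ("TCA", "TCT")
TCW_CRICK = ("TGA", "AGA")  # Watson triplets whose Crick strand reads TCA/TCT


def _as_cohort(tables: list[pd.DataFrame] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(tables, pd.DataFrame):
        return tables.copy()
    return pd.concat(tables, ignore_index=True)


def filter_variants(
    tables: list[pd.DataFrame] | pd.DataFrame,
    af_min: float = 0.35,
    hom_threshold: float = 0.85,
    min_recurrence: int = 2,
    keep_af_at_threshold: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Apply allele-fraction and recurrence filters; annotate zygosity.

    * Variants with allele fraction below ``af_min`` are removed (a fraction
      exactly at the threshold is kept by default; set
      ``keep_af_at_threshold=False`` to remove it too).
    * Allele fraction >= ``hom_threshold`` is called homozygous, otherwise
      heterozygous.
    * Any variant whose ``(chrom, pos, alt)`` occurs in at least
      ``min_recurrence`` distinct samples of the cohort is treated as
      pre-existing and removed from every sample.
    * Records with allele fractions outside [0, 1] are rejected and reported.

    Returns ``(filtered cohort table, report)`` where the report carries the
    rejected-record table and per-filter removal counts.  Input ordering is
    preserved.
    """
    df = _as_cohort(tables)
    report: dict = {}
    bad = df[(df["af"] < 0) | (df["af"] > 1) | df["af"].isna()]
    report["rejected_invalid_af"] = bad
    df = df.drop(bad.index)

    if keep_af_at_threshold:
        low = df["af"] < af_min
    else:
        low = df["af"] <= af_min
    report["n_removed_low_af"] = int(low.sum())
    df = df[~low]

    key = df["chrom"].astype(str) + ":" + df["pos"].astype(str) + ":" + df["alt"].astype(str)
    nsamples = df.groupby(key)["sample_id"].transform("nunique")
    recurrent = nsamples >= min_recurrence
    report["n_removed_recurrent"] = int(recurrent.sum())
    df = df[~recurrent].copy()

    df["zygosity"] = np.where(df["af"] >= hom_threshold, "homozygous", "heterozygous")
    return df, report


def classify_strand_and_track(
    df: pd.DataFrame, genome: GenomeModel
) -> pd.DataFrame:
    """Annotate strand class, chromosome arm, track membership, mutation type.

    Positions are 1-based in the table and validated against chromosome
    lengths.  Substitutions only enter the C->N / G->N classes; indels and
    multi-base records are classed ``other``.
    """
    df = df.copy()
    for chrom, pos in zip(df["chrom"], df["pos"]):
        genome.validate_position(chrom, int(pos) - 1)
    ref = df["ref"].astype(str)
    alt = df["alt"].astype(str)
    is_snv = (ref.str.len() == 1) & (alt.str.len() == 1)
    df["strand_class"] = np.select(
        [is_snv & (ref == "C"), is_snv & (ref == "G")],
        ["CtoN", "GtoN"],
        default="other",
    )
    df["mutation_type"] = np.where(is_snv, ref + ">" + alt, "indel")
    df["arm"] = [genome.arm_of(c, int(p) - 1) for c, p in zip(df["chrom"], df["pos"])]
    df["on_track"] = [genome.on_track(c, int(p) - 1) for c, p in zip(df["chrom"], df["pos"])]
    return df


def annotate_motif(
    df: pd.DataFrame, reference: dict[str, str]
) -> pd.DataFrame:
    """Set the ``tcw`` flag from the reference trinucleotide context.

    For C->N variants the Watson triplet centred on the variant must be TCA
    or TCT; for G->N the reverse-complement (Crick) triplet is tested, i.e.
    the Watson triplet must be TGA or AGA.  Variants at contig edges with
    insufficient context get ``tcw = <NA>`` and ``tcw_defined = False``.
    """
    df = df.copy()
    tcw: list = []
    defined: list[bool] = []
    for chrom, pos, sclass in zip(df["chrom"], df["pos"], df["strand_class"]):
        seq = reference[chrom]
        i = int(pos) - 1  # to 0-based
        if i - 1 < 0 or i + 1 >= len(seq):
            tcw.append(pd.NA)
            defined.append(False)
            continue
        triplet = seq[i - 1:i + 2]
        if sclass == "CtoN":
            tcw.append(triplet in TCW)
        elif sclass == "GtoN":
            tcw.append(triplet in TCW_CRICK)
        else:
            tcw.append(False)
        defined.append(True)
    df["tcw"] = pd.array(tcw, dtype="boolean")
    df["tcw_defined"] = defined
    return df


@dataclass
class OutcomeSummary:
    """Per-group counts, per-outcome means and mutation-type spectra."""

    group: str
    n_samples: int
    per_sample: pd.DataFrame       # counts per sample x (strand_class, mutation_type, on_track)
    totals: pd.Series              # summed over samples
    means: pd.Series               # totals / n_samples
    spectrum: pd.Series            # mutation-type fractions among substitutions
    flags: tuple[str, ...] = ()

    def track_count(self, strand_class: str, mutation_type: str | None = None) -> int:
        sel = self.per_sample.reset_index()
        sel = sel[(sel["strand_class"] == strand_class) & sel["on_track"]]
        if mutation_type is not None:
            sel = sel[sel["mutation_type"] == mutation_type]
        return int(sel["count"].sum())

    def track_mean(self, strand_class: str, mutation_type: str | None = None) -> float:
        return self.track_count(strand_class, mutation_type) / self.n_samples


def summarize_outcomes(
    df: pd.DataFrame,
    groups: dict[str, str] | None = None,
    samples: dict[str, list[str]] | None = None,
) -> dict[str, OutcomeSummary]:
    """Summarize classified variants per group.

    ``groups`` maps sample_id -> group label (default: one group, "all");
    ``samples`` may list every sample per group so outcomes with zero
    surviving variants still enter the denominators.
    """
    if groups is None:
        groups = {s: "all" for s in df["sample_id"].unique()}
    membership: dict[str, list[str]] = {}
    for sample, grp in groups.items():
        membership.setdefault(grp, []).append(sample)
    if samples:
        for grp, extra in samples.items():
            known = set(membership.get(grp, []))
            membership[grp] = sorted(known | set(extra))

    out: dict[str, OutcomeSummary] = {}
    for grp, members in membership.items():
        sub = df[df["sample_id"].isin(members)]
        flags: tuple[str, ...] = ()
        n = len(members)
        if n == 0:
            flags = ("empty_group",)
        counts = (
            sub.groupby(["sample_id", "strand_class", "mutation_type", "on_track"])
            .size()
            .rename("count")
        )
        totals = counts.groupby(["strand_class", "mutation_type", "on_track"]).sum()
        means = totals / n if n else totals * float("nan")
        snv = sub[sub["strand_class"].isin(["CtoN", "GtoN"])]
        spectrum = (
            snv["mutation_type"].value_counts(normalize=True).sort_index()
            if len(snv) else pd.Series(dtype=float)
        )
        out[grp] = OutcomeSummary(
            group=grp, n_samples=n, per_sample=counts.to_frame(),
            totals=totals, means=means, spectrum=spectrum, flags=flags,
        )
    return out


def run_variant_pipeline(
    tables: list[pd.DataFrame] | pd.DataFrame,
    genome: GenomeModel,
    reference: dict[str, str] | None = None,
    groups: dict[str, str] | None = None,
    samples: dict[str, list[str]] | None = None,
    **filter_kwargs,
) -> tuple[pd.DataFrame, dict[str, OutcomeSummary], dict]:
    """Filter, classify, (optionally) motif-annotate and summarize."""
    filtered, report = filter_variants(tables, **filter_kwargs)
    classified = classify_strand_and_track(filtered, genome)
    if reference is not None:
        classified = annotate_motif(classified, reference)
    summaries = summarize_outcomes(classified, groups=groups, samples=samples)
    return classified, summaries, report
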