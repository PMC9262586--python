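"""Synthetic inputs with known ground truth.

Everything the downstream stages consume can be generated here: amplicon
read pools over the reporter construct with engineered junctions and
contaminants, per-outcome variant tables with strand-structured APOBEC3A
(A3A) lesions along the BIR track, and culture-level colony/droplet count
tables.

The lesion model places C->N mutations at TCW-motif cytosines of the Watson
strand (A3A damage to the nascent-strand ssDNA, the lagging-strand template)
and G->N mutations at positions whose Crick strand carries a TCW motif (A3A
damage to the D-loop bottom template strand, D-BTS).  With uracil glycosylase
absent (ung1Δ), every deaminated cytosine templates an adenine, so C lesions
yield C->T only and D-BTS lesions yield G->A only; with Ung1 active, abasic
sites add the transversion classes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeModel, synthesize_reference
from .junctions import AmpliconRead
from .reporter import ReporterConstruct, revcomp

__all__ = [
    "LesionSimConfig",
    "VariantSimResult",
    "generate_junction_reads",
    "simulate_variant_tables",
    "simulate_assay_counts",
    "simulate_droplets",
]

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

VARIANT_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "af"]


# ---------------------------------------------------------------------------
# Amplicon read pools
# ---------------------------------------------------------------------------

def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return "".join(arr)


def generate_junction_reads(
    construct: ReporterConstruct,
    fixture_mix: dict[str, int] | None = None,
    no_deletion_count: int = 0,
    contaminant_counts: dict[str, int] | None = None,
    error_rate: float = 0.0,
    seed: int = 0,
    revcomp_fraction: float = 0.5,
    quality_char: str = "I",
) -> list[AmpliconRead]:
    """Generate an amplicon read pool with ground-truth labels.

    Junction reads are the amplicon with the fixture's deletion applied;
    both primers are present at the ends before errors.  Substitution errors
    are applied i.i.d. at ``error_rate`` (primers included, as on a real
    sequencer).  Low-complexity contaminants are homopolymer/dinucleotide
    repeats; short contaminants are primer-bearing fragments under 220 bp.
    A ``revcomp_fraction`` of reads is emitted reverse-complemented, as in a
    real unstranded amplicon library.  Deterministic per seed.
    """
    if not (0.0 <= error_rate < 1.0):
        raise ValueError("error_rate must be in [0, 1)")
    fixture_mix = fixture_mix or {}
    contaminant_counts = contaminant_counts or {}
    for key in contaminant_counts:
        if key not in ("low_complexity", "short"):
            raise ValueError(f"unknown contaminant class {key!r}")
    for name, count in fixture_mix.items():
        construct.fixture(name)  # raises KeyError for unknown fixtures
        if count < 0:
            raise ValueError("counts must be >= 0")

    rng = np.random.default_rng(seed)
    reads: list[AmpliconRead] = []

    def emit(template: str, truth: str) -> None:
        seq = _mutate(template, rng, error_rate)
        if rng.random() < revcomp_fraction:
            seq = revcomp(seq)
        reads.append(AmpliconRead(
            read_id=f"read_{len(reads):06d}",
            sequence=seq,
            quality=quality_char * len(seq),
            truth=truth,
        ))

    for name in sorted(fixture_mix):
        fx = construct.fixture(name)
        template = construct.apply_deletion(fx.left_bp, fx.right_bp)
        for _ in range(fixture_mix[name]):
            emit(template, name)
    for _ in range(no_deletion_count):
        emit(construct.sequence, "no_deletion")
    for _ in range(contaminant_counts.get("low_complexity", 0)):
        unit = ["A", "T", "AT", "AC", "G"][rng.integers(5)]
        length = int(rng.integers(230, len(construct.sequence) + 1))
        emit((unit * length)[:length], "low_complexity")
    for _ in range(contaminant_counts.get("short", 0)):
        length = int(rng.integers(60, 220))
        tail = "".join(rng.choice(_BASES, size=max(length - len(construct.fwd_primer), 0)))
        emit((construct.fwd_primer + tail)[:length], "short")

    order = rng.permutation(len(reads))
    return [reads[i] for i in order]


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LesionSimConfig:
    """Study conditions for per-outcome variant simulation.

    Defaults mirror a wild-type (Ung1-proficient) cohort: 62 BIR outcomes
    with a mean of ~5.6 nascent-strand (C->N) and ~0.66 D-BTS (G->N)
    A3A lesions per outcome on the repair track.
    """

    n_outcomes: int = 62
    nascent_rate: float = 5.6
    dbts_rate: float = 0.66
    ung1_active: bool = True
    motif_strict: bool = True
    shared_variant_rate: float = 1.0
    artifact_rate: float = 2.0
    hom_fraction: float = 0.10
    # allele-fraction generative model
    het_beta: tuple[float, float] = (20.0, 20.0)
    hom_beta: tuple[float, float] = (60.0, 3.0)
    artifact_af_range: tuple[float, float] = (0.05, 0.30)
    # mutation-type mixture with Ung1 active (C->T, C->G, C->A and mirror)
    spectrum_ung1: tuple[float, float, float] = (0.45, 0.45, 0.10)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_outcomes < 1:
            raise ValueError("n_outcomes must be >= 1")
        for rate in (self.nascent_rate, self.dbts_rate,
                     self.shared_variant_rate, self.artifact_rate):
            if rate < 0:
                raise ValueError("rates must be >= 0")


@dataclass
class VariantSimResult:
    tables: list[pd.DataFrame]
    truth: pd.DataFrame  # sample_id, chrom, pos, ref, alt, af, origin

    @property
    def n_true_nascent(self) -> int:
        return int((self.truth["origin"] == "nascent").sum())

    @property
    def n_true_dbts(self) -> int:
        return int((self.truth["origin"] == "dbts").sum())


def _motif_positions(seq: str, motifs: tuple[str, ...], margin: int = 2) -> np.ndarray:
    """0-based positions of the middle base of any of the 3-bp motifs."""
    hits: list[int] = []
    for motif in motifs:
        pattern = "(?=" + "".join(f"[{m}]" for m in motif) + ")"
        hits.extend(m.start() + 1 for m in re.finditer(pattern, seq))
    pos = np.array(sorted(set(hits)), dtype=np.int64)
    return pos[(pos >= margin) & (pos < len(seq) - margin)]


def simulate_variant_tables(
    genome: GenomeModel,
    cfg: LesionSimConfig,
    reference: dict[str, str] | None = None,
) -> VariantSimResult:
    """Simulate per-outcome variant record sets with full ground truth.

    Per outcome, nascent (C->N) and D-BTS (G->N) lesion counts on the track
    are Poisson with the configured rates; positions are drawn without
    replacement from the track's TCW-compatible sites (when ``motif_strict``)
    or from all C/G sites.  Shared pre-existing variants are injected
    identically into every outcome; artifact variants get allele fractions
    below 0.35 so the allele-fraction filter can remove them.
    """
    tchrom, tstart, tend = genome.track_interval
    if reference is None:
        reference = synthesize_reference(genome, cfg.seed)
    track_seq = reference[tchrom][tstart:tend]

    rng = np.random.default_rng(cfg.seed)
    if cfg.motif_strict:
        c_sites = _motif_positions(track_seq, ("TCA", "TCT")) + tstart
        g_sites = _motif_positions(track_seq, ("TGA", "AGA")) + tstart
    else:
        arr = np.frombuffer(track_seq.encode(), dtype="S1")
        c_sites = np.flatnonzero(arr == b"C") + tstart
        g_sites = np.flatnonzero(arr == b"G") + tstart
        margin = (c_sites >= tstart + 2) & (c_sites < tend - 2)
        c_sites = c_sites[margin]
        g_sites = g_sites[(g_sites >= tstart + 2) & (g_sites < tend - 2)]

    chrom_names = [name for name, _ in genome.chromosomes]
    chrom_lengths = np.array([length for _, length in genome.chromosomes], dtype=float)
    chrom_probs = chrom_lengths / chrom_lengths.sum()

    def draw_af(origin: str) -> float:
        if origin == "artifact":
            lo, hi = cfg.artifact_af_range
            return float(rng.uniform(lo, hi))
        if rng.random() < cfg.hom_fraction:
            a, b = cfg.hom_beta
        else:
            a, b = cfg.het_beta
        return float(np.clip(rng.beta(a, b), 0.0, 1.0))

    def draw_alt(ref_base: str) -> str:
        if not cfg.ung1_active:
            # persistent dU: adenine across from uracil, so C->T (Watson C)
            # and G->A (Watson G, Crick-strand C->T)
            return "T" if ref_base == "C" else "A"
        p = np.array(cfg.spectrum_ung1) / sum(cfg.spectrum_ung1)
        if ref_base == "C":
            return str(rng.choice(["T", "G", "A"], p=p))
        return str(rng.choice(["A", "C", "T"], p=p))

    def random_site() -> tuple[str, int, str, str]:
        ci = int(rng.choice(len(chrom_names), p=chrom_probs))
        chrom = chrom_names[ci]
        pos0 = int(rng.integers(2, genome.length_of(chrom) - 2))
        ref_base = reference[chrom][pos0]
        alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
        return chrom, pos0 + 1, ref_base, alt  # 1-based table coordinate

    shared: list[dict] = []
    for _ in range(rng.poisson(cfg.shared_variant_rate)):
        chrom, pos, ref_base, alt = random_site()
        shared.append(dict(chrom=chrom, pos=pos, ref=ref_base, alt=alt,
                           af=draw_af("shared"), origin="shared"))

    tables: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    for k in range(cfg.n_outcomes):
        sample = f"outcome_{k:03d}"
        rows: list[dict] = []
        for sites, rate, ref_base, origin in (
            (c_sites, cfg.nascent_rate, "C", "nascent"),
            (g_sites, cfg.dbts_rate, "G", "dbts"),
        ):
            n = int(rng.poisson(rate))
            n = min(n, len(sites))
            picked = rng.choice(sites, size=n, replace=False) if n else []
            for pos in picked:  # picked sites are 0-based; tables are 1-based
                rows.append(dict(chrom=tchrom, pos=int(pos) + 1, ref=ref_base,
                                 alt=draw_alt(ref_base), af=draw_af(origin),
                                 origin=origin))
        for rec in shared:
            rows.append(dict(rec))
        for _ in range(rng.poisson(cfg.artifact_rate)):
            chrom, pos, ref_base, alt = random_site()
            rows.append(dict(chrom=chrom, pos=pos, ref=ref_base, alt=alt,
                             af=draw_af("artifact"), origin="artifact"))
        for row in rows:
            row["sample_id"] = sample
        truth_rows.extend(rows)
        table = pd.DataFrame(rows, columns=VARIANT_COLUMNS + ["origin"])
        tables.append(table[VARIANT_COLUMNS].copy())

    truth = pd.DataFrame(truth_rows, columns=VARIANT_COLUMNS + ["origin"])
    return VariantSimResult(tables=tables, truth=truth)


# ---------------------------------------------------------------------------
# Assay counts
# ---------------------------------------------------------------------------

def simulate_assay_counts(
    true_frequency: float,
    n_cultures: int,
    cells_plated: int,
    seed: int = 0,
    viable_dilution: float = 1e-4,
) -> pd.DataFrame:
    """Colony-count table for a reversion-frequency assay.

    Per culture, the selective-plate count is Binomial(cells_plated,
    true_frequency); the viable count is a Binomial subsample at
    ``viable_dilution``.  Volume factors convert plate counts back to
    per-culture totals.
    """
    if not (0.0 <= true_frequency <= 1.0):
        raise ValueError("true_frequency must be in [0, 1]")
    if n_cultures < 1 or cells_plated < 1:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    sel = rng.binomial(cells_plated, true_frequency, size=n_cultures)
    via = rng.binomial(cells_plated, viable_dilution, size=n_cultures)
    return pd.DataFrame({
        "culture": [f"culture_{i:02d}" for i in range(n_cultures)],
        "selective_count": sel,
        "selective_factor": 1.0,
        "viable_count": via,
        "viable_factor": 1.0 / viable_dilution,
        "true_frequency": true_frequency,
    })


def simulate_droplets(
    target_conc: float,
    ref_conc: float,
    n_droplets: int = 20_000,
    droplet_volume: float = 0.85e-3,
    seed: int = 0,
) -> pd.DataFrame:
    """Droplet-count table for a two-channel digital PCR experiment.

    Positive-droplet counts are Binomial with occupancy probability
    ``1 - exp(-concentration * droplet_volume)`` (Poisson loading).
    Concentrations are copies per unit volume; the default droplet volume is
    0.85 nL expressed in µL.
    """
    if min(target_conc, ref_conc) < 0 or n_droplets < 1 or droplet_volume <= 0:
        raise ValueError("concentrations must be >= 0 and counts positive")
    rng = np.random.default_rng(seed)
    rows = []
    for channel, conc in (("target", target_conc), ("reference", ref_conc)):
        p = 1.0 - np.exp(-conc * droplet_volume)
        rows.append(dict(channel=channel, positives=int(rng.binomial(n_droplets, p)),
                         total=n_droplets, true_concentration=conc))
    return pd.DataFrame(rows)
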