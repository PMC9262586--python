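"""Readers/writers for the standard formats the pipeline touches.

FASTA/FASTQ go through Biopython, VCF through pysam, tables through pandas.
Construct feature coordinates travel as a YAML sidecar next to the FASTA.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import GenomeModel
from .junctions import AmpliconRead
from .reporter import JunctionFixture, ReporterConstruct, ReporterGeometry

__all__ = [
    "write_fasta", "read_fasta_reads", "write_fastq", "read_fastq_reads",
    "write_construct", "read_construct",
    "write_variant_vcf", "read_variant_vcf",
    "write_track_bed",
]


def write_fasta(sequences: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta_reads(path: str | os.PathLike) -> list[AmpliconRead]:
    return [AmpliconRead(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fastq(reads: list[AmpliconRead], path: str | os.PathLike) -> None:
    records = []
    for read in reads:
        rec = SeqRecord(Seq(read.sequence), id=read.read_id,
                        description=read.truth or "")
        qual = read.quality or "I" * len(read.sequence)
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq_reads(path: str | os.PathLike) -> list[AmpliconRead]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append(AmpliconRead(rec.id, str(rec.seq).upper(), quality=qual))
    return out


def write_construct(construct: ReporterConstruct, fasta_path: str | os.PathLike) -> None:
    """Write the construct FASTA plus a YAML sidecar of features/fixtures."""
    write_fasta({"reporter": construct.sequence}, fasta_path)
    meta = {
        "geometry": {
            "ir_len": construct.geometry.ir_len,
            "spacer_len": construct.geometry.spacer_len,
            "dr_len": construct.geometry.dr_len,
            "orientation": construct.geometry.orientation,
        },
        "flank_len": construct.flank_len,
        "fwd_primer": construct.fwd_primer,
        "rev_primer": construct.rev_primer,
        "features": {k: list(v) for k, v in construct.feature_coords.items()},
        "fixtures": [
            {"name": f.name, "left_bp": f.left_bp, "right_bp": f.right_bp,
             "expected_mh": f.expected_mh}
            for f in construct.fixtures
        ],
    }
    Path(str(fasta_path) + ".yaml").write_text(yaml.safe_dump(meta))


def read_construct(fasta_path: str | os.PathLike) -> ReporterConstruct:
    rec = next(SeqIO.parse(str(fasta_path), "fasta"))
    meta = yaml.safe_load(Path(str(fasta_path) + ".yaml").read_text())
    return ReporterConstruct(
        sequence=str(rec.seq).upper(),
        feature_coords={k: tuple(v) for k, v in meta["features"].items()},
        fixtures=tuple(JunctionFixture(**fx) for fx in meta["fixtures"]),
        geometry=ReporterGeometry(**meta["geometry"]),
        flank_len=meta["flank_len"],
        fwd_primer=meta["fwd_primer"],
        rev_primer=meta["rev_primer"],
    )


def write_variant_vcf(
    table: pd.DataFrame, genome: GenomeModel, path: str | os.PathLike
) -> None:
    """Write one sample's variant table as VCF v4.2 with an AF FORMAT field.

    Table positions are 1-based (column ``pos``); ``sample_id`` must be
    single-valued.
    """
    samples = table["sample_id"].unique()
    if len(samples) != 1:
        raise ValueError("write one sample per VCF")
    header = pysam.VariantHeader()
    for name, length in genome.chromosomes:
        header.contigs.add(name, length=length)
    header.add_meta("FORMAT", items=[("ID", "AF"), ("Number", "A"),
                                     ("Type", "Float"),
                                     ("Description", "Allele fraction")])
    header.add_sample(str(samples[0]))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        sorted_table = table.sort_values(["chrom", "pos"])
        for _, row in sorted_table.iterrows():
            rec = vcf.new_record(
                contig=row["chrom"], start=int(row["pos"]) - 1,
                alleles=(row["ref"], row["alt"]),
            )
            rec.samples[str(samples[0])]["AF"] = float(row["af"])
            vcf.write(rec)


def read_variant_vcf(
    path: str | os.PathLike, sample_id: str | None = None, af_key: str = "AF"
) -> pd.DataFrame:
    """Read a VCF into the pipeline's variant table.

    Multi-allelic records are split into biallelic rows.  The allele
    fraction is taken from the FORMAT field ``af_key`` when present, falling
    back to INFO.
    """
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        vcf_samples = list(vcf.header.samples)
        sid = sample_id or (vcf_samples[0] if vcf_samples else Path(path).stem)
        for rec in vcf:
            alts = rec.alts or ()
            for i, alt in enumerate(alts):
                af = None
                if vcf_samples and af_key in rec.samples[vcf_samples[0]]:
                    value = rec.samples[vcf_samples[0]][af_key]
                    af = value[i] if isinstance(value, tuple) else value
                elif af_key in rec.info:
                    value = rec.info[af_key]
                    af = value[i] if isinstance(value, tuple) else value
                rows.append(dict(sample_id=sid, chrom=rec.chrom, pos=rec.pos,
                                 ref=rec.ref, alt=alt,
                                 af=float(af) if af is not None else float("nan")))
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "ref", "alt", "af"])


def write_track_bed(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """BED of on-track variants (0-based half-open single-base intervals)."""
    sub = df[df["on_track"]]
    with open(path, "w") as fh:
        for _, row in sub.iterrows():
            name = f"{row['sample_id']}:{row['ref']}>{row['alt']}"
            fh.write(f"{row['chrom']}\t{int(row['pos']) - 1}\t{int(row['pos'])}\t{name}\n")
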