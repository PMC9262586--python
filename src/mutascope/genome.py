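"""Genome coordinate model for break-induced replication (BIR) track analyses.

A :class:`GenomeModel` describes a set of nominal chromosomes, their centromere
positions, and a single half-open "track" interval: the chromosome arm along
which BIR repair synthesis proceeds.  The track defines which mutations count
as BIR-associated and what fraction of the genome the random-redistribution
null may hit by chance.

Coordinates are 0-based, half-open throughout the package; VCF emission
converts to 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenomeModel", "default_genome", "synthesize_reference"]

# Nominal chromosome sizes (bp) loosely following the budding-yeast karyotype,
# adjusted so the total is exactly 12.0 Mb and the default 120-kb track is
# exactly 1% of the genome.
DEFAULT_CHROMOSOMES: tuple[tuple[str, int], ...] = (
    ("chrI", 230_000),
    ("chrII", 810_000),
    ("chrIII", 320_000),
    ("chrIV", 1_464_000),
    ("chrV", 580_000),
    ("chrVI", 270_000),
    ("chrVII", 1_090_000),
    ("chrVIII", 560_000),
    ("chrIX", 440_000),
    ("chrX", 745_000),
    ("chrXI", 666_000),
    ("chrXII", 1_078_000),
    ("chrXIII", 924_000),
    ("chrXIV", 784_000),
    ("chrXV", 1_091_000),
    ("chrXVI", 948_000),
)


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome lengths, centromeres and the BIR track interval.

    Parameters
    ----------
    chromosomes
        Sequence of ``(name, length)`` pairs.
    centromeres
        Mapping of chromosome name to centromere coordinate.  Positions left
        of the centromere are the "left" arm, positions at or right of it the
        "right" arm.
    track_interval
        ``(chrom, start, end)`` half-open interval of the BIR repair track.
    """

    chromosomes: tuple[tuple[str, int], ...]
    centromeres: dict[str, int]
    track_interval: tuple[str, int, int]
    _lengths: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        if len(lengths) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        object.__setattr__(self, "_lengths", lengths)
        chrom, start, end = self.track_interval
        if chrom not in lengths:
            raise ValueError(f"track chromosome {chrom!r} not in genome")
        if not (0 <= start < end <= lengths[chrom]):
            raise ValueError("track interval must satisfy 0 <= start < end <= chrom length")
        if not (0.0 < self.track_fraction < 1.0):
            raise ValueError("track fraction must be in (0, 1)")
        for name, cen in self.centromeres.items():
            if name not in lengths:
                raise ValueError(f"centromere for unknown chromosome {name!r}")
            if not (0 < cen < lengths[name]):
                raise ValueError(f"centromere of {name} must lie strictly inside the chromosome")

    # -- basic geometry -------------------------------------------------

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    @property
    def track_length(self) -> int:
        _, start, end = self.track_interval
        return end - start

    @property
    def track_fraction(self) -> float:
        return self.track_length / self.total_length

    def length_of(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def offset_of(self, chrom: str) -> int:
        """Start of ``chrom`` in the concatenated genome coordinate."""
        off = 0
        for name, length in self.chromosomes:
            if name == chrom:
                return off
            off += length
        raise KeyError(f"unknown chromosome {chrom!r}")

    @property
    def track_concat_interval(self) -> tuple[int, int]:
        chrom, start, end = self.track_interval
        off = self.offset_of(chrom)
        return off + start, off + end

    # -- queries --------------------------------------------------------

    def validate_position(self, chrom: str, pos: int) -> None:
        if not (0 <= pos < self.length_of(chrom)):
            raise ValueError(f"position {pos} outside {chrom} (length {self.length_of(chrom)})")

    def arm_of(self, chrom: str, pos: int) -> str:
        """Return ``"left"`` or ``"right"`` relative to the centromere."""
        self.validate_position(chrom, pos)
        cen = self.centromeres.get(chrom)
        if cen is None:
            raise KeyError(f"no centromere recorded for {chrom}")
        return "left" if pos < cen else "right"

    def on_track(self, chrom: str, pos: int) -> bool:
        tchrom, start, end = self.track_interval
        return chrom == tchrom and start <= pos < end


def default_genome() -> GenomeModel:
    """The default 12.0-Mb, 16-chromosome model.

    The BIR track is the terminal 120 kb of the chrIII right arm, i.e. exactly
    1% of the genome, emulating a repair track that covers roughly one percent
    of a yeast-sized genome.
    """
    centromeres = {name: (115_000 if name == "chrIII" else length // 2)
                   for name, length in DEFAULT_CHROMOSOMES}
    return GenomeModel(
        chromosomes=DEFAULT_CHROMOSOMES,
        centromeres=centromeres,
        track_interval=("chrIII", 200_000, 320_000),
    )


def synthesize_reference(
    genome: GenomeModel,
    seed: int,
    chroms: list[str] | None = None,
    gc: float = 0.40,
) -> dict[str, str]:
    """Generate a random reference sequence for ``genome``.

    Each chromosome gets an independent stream keyed by ``(seed, index)`` so
    the same chromosome sequence is produced regardless of which subset is
    requested.
    """
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.frombuffer(b"ACGT", dtype="S1")
    out: dict[str, str] = {}
    for idx, (name, length) in enumerate(genome.chromosomes):
        if chroms is not None and name not in chroms:
            continue
        rng = np.random.default_rng([int(seed), idx])
        seq = rng.choice(bases, size=length, p=probs)
        out[name] = seq.tobytes().decode()
    return out
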