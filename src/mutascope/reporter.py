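"""Synthetic quasi-palindrome reporter construct with engineered deletion fixtures.

The reporter emulates a *lys2*-style inverted-repeat (IR) insertion: two IR
arms separated by a short spacer, flanked on both sides by identical direct
repeats (DRs), embedded in an amplicon bounded by the two final-PCR primers.
Because the insertion duplicates one DR copy, its net inserted length is
``2*ir_len + spacer_len + dr_len`` (156 bp for the default 69/9/9 geometry)
and the precise excision of the insertion leaves a DR-length microhomology at
the junction.

Four canonical junction fixtures are engineered into the sequence:

========  ========  =============  ========
fixture   deletion  microhomology  in frame
========  ========  =============  ========
precise   156 bp    9 bp           yes
typeI     126 bp    6 bp           yes
typeII    171 bp    6 bp           yes
J1        125 bp    5 bp           no
========  ========  =============  ========

Type I retains part of the left IR arm (left breakpoint inside the IR, right
microhomology outside the insertion); Type II has the opposite polarity and
additionally removes flanking reporter sequence; J1 is the frequent
out-of-frame class.  Flank and arm bases are adjusted so each fixture carries
*exactly* its expected microhomology: the shared run cannot be extended in
either direction.  A brute-force verification pass asserts this after
assembly, for both insert orientations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import left_align, microhomology_length

__all__ = [
    "ReporterGeometry",
    "JunctionFixture",
    "ReporterConstruct",
    "build_reporter",
    "revcomp",
    "FWD_PRIMER",
    "REV_PRIMER",
]

# Final-amplicon primer pair of the deep-sequencing protocol.
FWD_PRIMER = "GTTCGTACCCCTCTCGAGAATA"
REV_PRIMER = "CCATCCACTTCTCATCTGAAAGACC"

_COMP = str.maketrans("ACGTN", "TGCAN")
_BASES = "ACGT"


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _complement(base: str) -> str:
    return base.translate(_COMP)


@dataclass(frozen=True)
class ReporterGeometry:
    """Arm/spacer/repeat lengths and insert orientation.

    ``orientation`` flips the insertion relative to the amplicon primers:
    Ori1 and Ori2 exchange which strand of the quasi-palindrome serves as the
    template for leading- vs lagging-strand BIR synthesis.
    """

    ir_len: int = 69
    spacer_len: int = 9
    dr_len: int = 9
    orientation: str = "Ori1"

    def __post_init__(self) -> None:
        if min(self.ir_len, self.spacer_len, self.dr_len) <= 0:
            raise ValueError("geometry lengths must be positive")
        if self.orientation not in ("Ori1", "Ori2"):
            raise ValueError("orientation must be 'Ori1' or 'Ori2'")

    @property
    def inserted_length(self) -> int:
        """Net inserted length: the insertion duplicates one DR copy."""
        return 2 * self.ir_len + self.spacer_len + self.dr_len

    @property
    def region_length(self) -> int:
        """DR + IR + spacer + IR + DR footprint."""
        return self.inserted_length + self.dr_len


@dataclass(frozen=True)
class JunctionFixture:
    name: str
    left_bp: int
    right_bp: int
    expected_mh: int

    @property
    def expected_len(self) -> int:
        return self.right_bp - self.left_bp

    @property
    def in_frame(self) -> bool:
        return self.expected_len % 3 == 0


@dataclass(frozen=True)
class ReporterConstruct:
    """Amplicon sequence, feature map and canonical junction fixtures."""

    sequence: str
    feature_coords: dict[str, tuple[int, int]]
    fixtures: tuple[JunctionFixture, ...]
    geometry: ReporterGeometry
    flank_len: int
    fwd_primer: str
    rev_primer: str

    def fixture(self, name: str) -> JunctionFixture:
        for fx in self.fixtures:
            if fx.name == name:
                return fx
        raise KeyError(f"no fixture named {name!r}; have {[f.name for f in self.fixtures]}")

    def feature_seq(self, name: str) -> str:
        start, end = self.feature_coords[name]
        return self.sequence[start:end]

    @property
    def insertion_interval(self) -> tuple[int, int]:
        return self.feature_coords["left_DR"][0], self.feature_coords["right_DR"][1]

    def apply_deletion(self, left: int, right: int) -> str:
        if not (0 <= left < right <= len(self.sequence)):
            raise ValueError("breakpoints outside construct")
        return self.sequence[:left] + self.sequence[right:]


def _pick(rng: np.random.Generator, exclude: set[str]) -> str:
    for base in rng.permutation(list(_BASES)):
        if base not in exclude:
            return str(base)
    raise RuntimeError("no base available")  # pragma: no cover


def _verify(seq: str, fixtures: tuple[JunctionFixture, ...]) -> None:
    for fx in fixtures:
        aligned = left_align(seq, fx.left_bp, fx.right_bp)
        if aligned != (fx.left_bp, fx.right_bp):
            raise ValueError(
                f"fixture {fx.name}: breakpoints {fx.left_bp, fx.right_bp} are not "
                f"left-aligned (canonical {aligned}); geometry cannot host the fixtures"
            )
        mh = microhomology_length(seq, fx.left_bp, fx.right_bp)
        if mh != fx.expected_mh:
            raise ValueError(
                f"fixture {fx.name}: engineered microhomology is {mh} bp, "
                f"expected {fx.expected_mh} bp; geometry cannot host the fixtures"
            )


def build_reporter(
    geometry: ReporterGeometry | None = None,
    flank_len: int = 120,
    seed: int = 0,
    fwd_primer: str = FWD_PRIMER,
    rev_primer: str = REV_PRIMER,
) -> ReporterConstruct:
    """Build the reporter amplicon with engineered junction fixtures.

    The construct is ``fwd_primer + left flank + DR-IR-spacer-IR-DR + right
    flank + revcomp(rev_primer)`` with random flank/arm sequence drawn from
    ``seed`` and then locally repaired so every canonical fixture carries
    exactly its expected microhomology.  Deterministic for a given seed; the
    Ori2 construct differs from Ori1 only by reverse complement of the
    insertion region.

    Raises ``ValueError`` for geometries that cannot host the fixtures
    (arms shorter than a fixture's microhomology, or too short for the
    engineered junction offsets: requires ``ir_len >= 65``, ``dr_len >= 7``,
    ``flank_len >= 80``).
    """
    geo = geometry or ReporterGeometry()
    ir, sp, dr = geo.ir_len, geo.spacer_len, geo.dr_len
    mh_by_fixture = {"precise": dr, "typeI": 6, "typeII": 6, "J1": 5}
    if ir < max(mh_by_fixture.values()):
        raise ValueError(
            f"ir_len={ir} is shorter than a fixture microhomology "
            f"({max(mh_by_fixture.values())} bp): microhomology cannot be embedded"
        )
    if ir < 65 or dr < 7 or flank_len < 80:
        raise ValueError(
            "geometry cannot host the canonical fixtures: "
            "requires ir_len >= 65, dr_len >= 7, flank_len >= 80"
        )
    if flank_len < len(fwd_primer) + 53 or flank_len < len(rev_primer) + 52:
        raise ValueError("flank_len too short for primers plus fixture overhangs")

    rng = np.random.default_rng(seed)
    rand = lambda n: [str(b) for b in rng.choice(list(_BASES), size=n)]  # noqa: E731

    DR = rand(dr)
    SP = rand(sp)
    L = rand(ir)
    F = flank_len
    flank_l = list(fwd_primer) + rand(F - len(fwd_primer))
    flank_r = rand(F - len(rev_primer)) + list(revcomp(rev_primer))

    a1 = ir - 45  # left-IR offset of the Type I left breakpoint

    # Engineer microhomologies into the left IR (right IR follows by revcomp).
    L[a1:a1 + 6] = DR[dr - 6:dr]                       # typeI: IR vs right DR
    for i in range(5):                                  # J1: IR vs IR (via revcomp)
        L[3 + i] = _complement(L[ir - 51 - i])
    # Break unwanted extensions.
    L[a1 - 1] = _pick(rng, {DR[dr - 7]})
    L[2] = _pick(rng, {_complement(L[ir - 50])})
    L[8] = _pick(rng, {_complement(L[ir - 56])})

    R = [_complement(b) for b in reversed(L)]

    # typeII (Ori1): microhomology in the left flank vs the right IR.
    flank_l[F - 51:F - 45] = R[33:39]
    flank_l[F - 52] = _pick(rng, {R[32]})
    flank_l[F - 45] = _pick(rng, {R[39]})
    flank_l[F - 1] = _pick(rng, {_complement(L[0]), _complement(L[a1 + 6])})
    flank_r[0] = _pick(rng, {L[0], L[a1 + 6]})
    # typeII (Ori2): mirrored microhomology in the right flank.
    flank_r[45:51] = L[ir - 39:ir - 33]
    flank_r[44] = _pick(rng, {L[ir - 40]})
    flank_r[51] = _pick(rng, {L[ir - 33]})

    insertion = DR + L + SP + R + DR
    region = geo.region_length
    ins_len = geo.inserted_length

    fixtures_ori1 = (
        JunctionFixture("precise", F, F + ins_len, dr),
        JunctionFixture("typeI", F + dr + a1, F + region - 6, 6),
        JunctionFixture("typeII", F - 51, F + dr + ir + sp + 33, 6),
        JunctionFixture("J1", F + dr + 3, F + dr + ir + sp + 50, 5),
    )

    if geo.orientation == "Ori1":
        seq = "".join(flank_l + insertion + flank_r)
        fixtures = fixtures_ori1
    else:
        seq = "".join(flank_l) + revcomp("".join(insertion)) + "".join(flank_r)
        # Mirror each Ori1 fixture: the leftmost Ori2 placement is the image
        # of the rightmost Ori1 placement under the insertion flip.
        fixtures = tuple(
            JunctionFixture(
                fx.name,
                2 * F + region - (fx.right_bp + fx.expected_mh),
                2 * F + region - (fx.left_bp + fx.expected_mh),
                fx.expected_mh,
            )
            for fx in fixtures_ori1
        )

    feature_coords = {
        "left_flank": (0, F),
        "left_DR": (F, F + dr),
        "left_IR": (F + dr, F + dr + ir),
        "spacer": (F + dr + ir, F + dr + ir + sp),
        "right_IR": (F + dr + ir + sp, F + dr + 2 * ir + sp),
        "right_DR": (F + region - dr, F + region),
        "right_flank": (F + region, 2 * F + region),
    }

    _verify(seq, fixtures)
    construct = ReporterConstruct(
        sequence=seq,
        feature_coords=feature_coords,
        fixtures=fixtures,
        geometry=geo,
        flank_len=flank_len,
        fwd_primer=fwd_primer,
        rev_primer=rev_primer,
    )
    # Structural sanity: IR arms are reverse complements, DR copies identical.
    if geo.orientation == "Ori1":
        assert construct.feature_seq("right_IR") == revcomp(construct.feature_seq("left_IR"))
        assert construct.feature_seq("left_DR") == construct.feature_seq("right_DR")
    return construct
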