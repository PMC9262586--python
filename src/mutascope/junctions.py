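"""Amplicon junction caller: read filtering, deletion detection, classification.

Reproduces a deep-sequencing deletion analysis as a composable filter
cascade:

1. low-complexity (DUST-style) filtering,
2. exact primer anchoring and reorientation to the forward strand,
3. minimum-length and no-deletion removal,
4. grouping of identical sequences, junction detection on the common groups,
5. assignment of remaining reads to detected junctions within a two-error
   (substitution) tolerance,
6. classification of calls against the construct's canonical fixtures.

Deletion detection assumes a single contiguous deletion and substitution-only
errors, so the deletion length is fixed by the read/construct length
difference; the junction is placed to minimize mismatches, left-aligned
within its microhomology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .alignment import left_align, microhomology_length
from .reporter import JunctionFixture, ReporterConstruct, revcomp

__all__ = [
    "AmpliconRead",
    "DeletionCall",
    "JunctionPipelineResult",
    "dust_score",
    "filter_low_complexity",
    "anchor_primers",
    "length_and_identity_filter",
    "detect_deletion",
    "classify_junction",
    "group_and_assign",
    "run_junction_pipeline",
]


@dataclass(frozen=True)
class AmpliconRead:
    read_id: str
    sequence: str
    quality: str | None = None
    truth: str | None = None  # ground-truth label for synthetic reads

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGTN"):
            raise ValueError(f"read {self.read_id}: sequence has non-ACGTN characters")


@dataclass(frozen=True)
class DeletionCall:
    """A single-deletion junction, left-aligned within its microhomology."""

    call_id: str
    left_bp: int
    right_bp: int
    mh_len: int
    class_label: str = "other"
    support: int = 1
    mismatches: int = 0

    @property
    def del_len(self) -> int:
        return self.right_bp - self.left_bp

    @property
    def in_frame(self) -> bool:
        return self.del_len % 3 == 0


# ---------------------------------------------------------------------------
# DUST-style low-complexity score
# ---------------------------------------------------------------------------

def dust_score(sequence: str, window: int = 64, step: int = 32) -> float:
    """Low-complexity score in [0, 1].

    Over windows of ``window`` bp, the raw score is the triplet-redundancy sum
    ``sum c*(c-1)/2`` over trinucleotide counts ``c`` divided by
    ``window_length - 2``, normalized so a homopolymer scores 1.0 and a window
    whose trinucleotides are all distinct scores 0.0.  The read score is the
    maximum over windows.  Sequences shorter than 3 bp are undefined and
    raise ``ValueError`` (callers pass such reads through, flagged).
    """
    n = len(sequence)
    if n < 3:
        raise ValueError("dust score undefined for sequences shorter than 3 bp")
    starts = list(range(0, max(n - window, 0) + 1, step))
    if starts[-1] != max(n - window, 0):
        starts.append(max(n - window, 0))
    best = 0.0
    for s in starts:
        win = sequence[s:s + window]
        w = len(win)
        ntrip = w - 2
        counts: dict[str, int] = {}
        for i in range(ntrip):
            t = win[i:i + 3]
            counts[t] = counts.get(t, 0) + 1
        raw = sum(c * (c - 1) // 2 for c in counts.values()) / ntrip
        max_raw = (ntrip - 1) / 2  # homopolymer: one triplet repeated ntrip times
        score = raw / max_raw if max_raw > 0 else 0.0
        best = max(best, score)
    return best


def filter_low_complexity(
    reads: list[AmpliconRead],
    threshold: float = 0.07,
    mode: str = "conventional",
) -> tuple[list[AmpliconRead], list[AmpliconRead]]:
    """Split reads into (kept, removed) by DUST score.

    ``mode="conventional"`` removes low-complexity reads (score above the
    threshold).  ``mode="as-printed"`` removes reads scoring *below* the
    threshold instead, matching a published protocol description verbatim;
    see the methods note for why this direction is not the default.  Reads
    too short to score are kept.
    """
    if mode not in ("conventional", "as-printed"):
        raise ValueError("mode must be 'conventional' or 'as-printed'")
    kept: list[AmpliconRead] = []
    removed: list[AmpliconRead] = []
    for read in reads:
        try:
            score = dust_score(read.sequence)
        except ValueError:
            kept.append(read)  # undefined: passed through, flagged by length
            continue
        drop = score < threshold if mode == "as-printed" else score > threshold
        (removed if drop else kept).append(read)
    return kept, removed


# ---------------------------------------------------------------------------
# Primer anchoring
# ---------------------------------------------------------------------------

def anchor_primers(
    read: AmpliconRead, fwd: str, rev: str
) -> tuple[AmpliconRead | None, str]:
    """Anchor a read on an exact primer match and orient it forward.

    Returns ``(trimmed_read, reason)``; the read is ``None`` when rejected
    with ``reason`` one of ``"no_primer"`` or ``"ambiguous"``.  A read
    containing the forward primer is trimmed to start at the primer's 5'
    end; a read containing the reverse primer (a reverse-orientation read)
    is trimmed at the reverse primer's 5' end and reverse-complemented.
    One-mismatch primer copies do not match: the primer sequence must be
    unchanged.
    """
    if not fwd or not rev:
        raise ValueError("primers must be nonempty")
    i_fwd = read.sequence.find(fwd)
    i_rev = read.sequence.find(rev)
    if i_fwd >= 0 and i_rev >= 0:
        return None, "ambiguous"
    if i_fwd >= 0:
        return replace(read, sequence=read.sequence[i_fwd:],
                       quality=read.quality[i_fwd:] if read.quality else None), "ok"
    if i_rev >= 0:
        trimmed = read.sequence[i_rev:]
        qual = read.quality[i_rev:] if read.quality else None
        return replace(read, sequence=revcomp(trimmed),
                       quality=qual[::-1] if qual else None), "ok"
    return None, "no_primer"


# ---------------------------------------------------------------------------
# Length / no-deletion filter
# ---------------------------------------------------------------------------

def length_and_identity_filter(
    reads: list[AmpliconRead],
    reference: str,
    min_len: int = 220,
    mismatch_slack: int = 2,
) -> tuple[list[AmpliconRead], dict[str, list[AmpliconRead]]]:
    """Drop short reads and reads supporting no-deletion events.

    A read is "no-deletion" when it has the reference length and at most
    ``mismatch_slack`` substitutions against the no-deletion amplicon.
    """
    kept: list[AmpliconRead] = []
    removed: dict[str, list[AmpliconRead]] = {"short": [], "no_deletion": []}
    for read in reads:
        if len(read.sequence) < min_len:
            removed["short"].append(read)
            continue
        if len(read.sequence) == len(reference):
            mm = sum(a != b for a, b in zip(read.sequence, reference))
            if mm <= mismatch_slack:
                removed["no_deletion"].append(read)
                continue
        kept.append(read)
    return kept, removed


# ---------------------------------------------------------------------------
# Deletion detection
# ---------------------------------------------------------------------------

def detect_deletion(
    read: AmpliconRead | str,
    construct: ReporterConstruct | str,
    mismatch_slack: int = 2,
) -> DeletionCall | None:
    """Find the single contiguous deletion that best explains ``read``.

    The read must be primer-anchored and forward-oriented so that it aligns
    to both construct ends; with substitution-only errors the deletion length
    is then ``len(construct) - len(read)``.  The junction position is chosen
    to minimize mismatches (maximal flank matches on both sides), preferring
    the leftmost minimizer, then left-aligned on the construct within the
    junction microhomology.  Returns ``None`` when no placement fits within
    ``mismatch_slack`` (e.g. reads implying two separate deletions) or when
    the read is not shorter than the construct.
    """
    seq = read.sequence if isinstance(read, AmpliconRead) else read
    ref = construct.sequence if isinstance(construct, ReporterConstruct) else construct
    read_id = read.read_id if isinstance(read, AmpliconRead) else "read"
    dlen = len(ref) - len(seq)
    if dlen <= 0:
        return None
    n = len(seq)
    # prefix_mm[i]: mismatches of seq[:i] vs ref[:i]
    prefix_mm = [0] * (n + 1)
    for i in range(n):
        prefix_mm[i + 1] = prefix_mm[i] + (seq[i] != ref[i])
    # suffix_mm[i]: mismatches of seq[i:] vs ref[i+dlen:]
    suffix_mm = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        suffix_mm[i] = suffix_mm[i + 1] + (seq[i] != ref[i + dlen])
    best_l, best_mm = 0, None
    for l in range(n + 1):
        mm = prefix_mm[l] + suffix_mm[l]
        if best_mm is None or mm < best_mm:
            best_l, best_mm = l, mm
    if best_mm is None or best_mm > mismatch_slack:
        return None
    left, right = left_align(ref, best_l, best_l + dlen)
    mh = microhomology_length(ref, left, right)
    return DeletionCall(
        call_id=read_id, left_bp=left, right_bp=right, mh_len=mh,
        mismatches=best_mm,
    )


def classify_junction(
    call: DeletionCall, fixtures: tuple[JunctionFixture, ...] | list[JunctionFixture]
) -> str:
    """Label a call by exact (left-aligned) breakpoint match to a fixture."""
    for fx in fixtures:
        if (call.left_bp, call.right_bp) == (fx.left_bp, fx.right_bp):
            return fx.name
    return "other"


# ---------------------------------------------------------------------------
# Grouping and assignment
# ---------------------------------------------------------------------------

@dataclass
class ReadGroup:
    sequence: str
    reads: list[AmpliconRead]
    call: DeletionCall | None = None

    @property
    def support(self) -> int:
        return len(self.reads)


def group_and_assign(
    reads: list[AmpliconRead],
    construct: ReporterConstruct,
    tolerance: int = 2,
    min_support: int = 5,
    coverage: float = 0.90,
    mismatch_slack: int = 2,
) -> tuple[list[ReadGroup], list[AmpliconRead]]:
    """Group identical sequences, call junctions on the common groups, and
    assign the remaining reads to those junction references.

    The most common groups — the largest groups covering at least
    ``coverage`` of the grouped reads, each with support >= ``min_support``
    — define junction references.  Every other read is assigned to a
    reference iff its Hamming distance to the reference sequence is at most
    ``tolerance`` (equal lengths only; no indels).  Distance ties break
    toward the higher-support junction, then lexicographically by sequence.
    Returns ``(junction groups, unassigned reads)``.
    """
    by_seq: dict[str, list[AmpliconRead]] = {}
    for read in reads:
        by_seq.setdefault(read.sequence, []).append(read)
    groups = sorted(
        (ReadGroup(seq, members) for seq, members in by_seq.items()),
        key=lambda g: (-g.support, g.sequence),
    )
    total = sum(g.support for g in groups)
    references: list[ReadGroup] = []
    covered = 0
    for g in groups:
        if g.support < min_support and references:
            break
        call = detect_deletion(
            AmpliconRead(f"group_{len(references)}", g.sequence),
            construct, mismatch_slack=mismatch_slack,
        )
        if call is not None:
            g.call = replace(call, support=g.support)
            references.append(g)
        covered += g.support
        if total and covered / total >= coverage and len(references) > 0:
            break
    ref_set = {id(g) for g in references}
    unassigned: list[AmpliconRead] = []
    for g in groups:
        if id(g) in ref_set:
            continue
        candidates: list[tuple[int, int, str, ReadGroup]] = []
        for ref in references:
            if len(ref.sequence) != len(g.sequence):
                continue
            d = sum(a != b for a, b in zip(g.sequence, ref.sequence))
            if d <= tolerance:
                # tie-break: distance, then higher support, then sequence order
                candidates.append((d, -ref.support, ref.sequence, ref))
        if candidates:
            candidates.sort(key=lambda t: t[:3])
            candidates[0][3].reads.extend(g.reads)
        else:
            unassigned.extend(g.reads)
    for ref in references:
        ref.call = replace(ref.call, support=ref.support)
    return references, unassigned


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class JunctionPipelineResult:
    groups: list[ReadGroup]
    unassigned: list[AmpliconRead]
    rejected: dict[str, list[AmpliconRead]]
    n_input: int

    @property
    def counts(self) -> dict[str, int]:
        out = {f"rejected_{k}": len(v) for k, v in self.rejected.items()}
        out["called"] = sum(g.support for g in self.groups)
        out["unassigned"] = len(self.unassigned)
        out["input"] = self.n_input
        return out

    def conserved(self) -> bool:
        c = self.counts
        return c["input"] == (sum(len(v) for v in self.rejected.values())
                              + c["called"] + c["unassigned"])


def run_junction_pipeline(
    reads: list[AmpliconRead],
    construct: ReporterConstruct,
    fwd_primer: str | None = None,
    rev_primer: str | None = None,
    dust_threshold: float = 0.07,
    dust_mode: str = "conventional",
    min_len: int = 220,
    tolerance: int = 2,
    mismatch_slack: int = 2,
    min_support: int = 5,
) -> JunctionPipelineResult:
    """Filter reads, detect junctions, assign, and classify against fixtures."""
    fwd = fwd_primer or construct.fwd_primer
    rev = rev_primer or construct.rev_primer
    n_input = len(reads)
    kept, dusted = filter_low_complexity(reads, dust_threshold, dust_mode)
    anchored: list[AmpliconRead] = []
    rejected_primer: list[AmpliconRead] = []
    for read in kept:
        trimmed, reason = anchor_primers(read, fwd, rev)
        if trimmed is None:
            rejected_primer.append(read)
        else:
            anchored.append(trimmed)
    survivors, removed = length_and_identity_filter(
        anchored, construct.sequence, min_len=min_len, mismatch_slack=mismatch_slack
    )
    groups, unassigned = group_and_assign(
        survivors, construct, tolerance=tolerance,
        min_support=min_support, mismatch_slack=mismatch_slack,
    )
    for g in groups:
        g.call = replace(g.call, class_label=classify_junction(g.call, construct.fixtures))
    return JunctionPipelineResult(
        groups=groups,
        unassigned=unassigned,
        rejected={
            "dust": dusted,
            "primer": rejected_primer,
            "length": removed["short"],
            "no_deletion": removed["no_deletion"],
        },
        n_input=n_input,
    )
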