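"""Indel detection, reading-frame tracing and allele-functionality calls.

A 2-bp insertion in the exon's 5' region shifts the reading frame and, on
its own, exposes premature stop codons; a downstream frame-restoring
deletion compensates it.  The extant alleles are labelled A (wild-type,
no frameshifting indels), a (disrupted: an unpaired frameshifting indel)
and alpha (restored: every frameshifting indel absorbed in a compensatory
pair).  Genotype functionality follows the three-allele scheme: A/A and
alpha/alpha are fully functional, a/a is sterile, and every heterozygote
is possibly functional but subfertile.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from Bio import Align

from .grammar import STOP, ExonSequence, InputError, translate_frame

__all__ = [
    "IndelEvent",
    "CompensatoryPair",
    "AlleleState",
    "AlleleLabel",
    "Fertility",
    "pairwise_align",
    "detect_indels",
    "frame_trace",
    "find_compensatory_pairs",
    "classify_allele_state",
    "classify_genotype_fertility",
    "ALIGN_SCORES",
]

# global alignment scores; fixed so indel coordinates are reproducible
ALIGN_SCORES = {"match": 1.0, "mismatch": -1.0, "open": -4.0, "extend": -1.0}


class IndelKind(str, enum.Enum):
    INS = "INS"
    DEL = "DEL"


@dataclass(frozen=True)
class IndelEvent:
    ref_pos: int          # 0-based on the reference
    kind: IndelKind
    length: int
    bases: str            # inserted bases (INS) or deleted reference span (DEL)

    def __post_init__(self) -> None:
        if self.length < 1 or len(self.bases) != self.length:
            raise InputError("indel length must be >= 1 and match its bases")

    @property
    def shift(self) -> int:
        return self.length % 3

    @property
    def signed_shift(self) -> int:
        return self.length if self.kind is IndelKind.INS else -self.length


@dataclass(frozen=True)
class CompensatoryPair:
    first: IndelEvent
    second: IndelEvent

    def __post_init__(self) -> None:
        if self.first.ref_pos >= self.second.ref_pos:
            raise InputError("pair members must be ordered by reference position")
        if self.net_shift % 3 != 0:
            raise InputError("a compensatory pair must restore the frame")
        if self.first.shift == 0 or self.second.shift == 0:
            raise InputError("in-frame events cannot be pair members")

    @property
    def net_shift(self) -> int:
        return self.first.signed_shift + self.second.signed_shift

    @property
    def disrupted_span(self) -> tuple[int, int]:
        return (self.first.ref_pos, self.second.ref_pos)


class AlleleLabel(str, enum.Enum):
    WILDTYPE_A = "WILDTYPE_A"
    DISRUPTED_a = "DISRUPTED_a"
    RESTORED_ALPHA = "RESTORED_ALPHA"


class Fertility(str, enum.Enum):
    FUNCTIONAL = "FUNCTIONAL"
    SUBFERTILE_HET = "SUBFERTILE_HET"
    STERILE = "STERILE"


@dataclass
class AlleleState:
    label: AlleleLabel
    indels: list[IndelEvent] = field(default_factory=list)
    pairs: list[CompensatoryPair] = field(default_factory=list)
    residual: list[IndelEvent] = field(default_factory=list)
    premature_stops: list[int] = field(default_factory=list)  # codon positions
    frame_trace: list[int] = field(default_factory=list)      # per-codon offsets


# ---------------------------------------------------------------------------
# alignment and indel calling

def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = ALIGN_SCORES["match"]
    a.mismatch_score = ALIGN_SCORES["mismatch"]
    a.open_gap_score = ALIGN_SCORES["open"]
    a.extend_gap_score = ALIGN_SCORES["extend"]
    return a


def pairwise_align(query: str, ref: str) -> Align.Alignment:
    """Global alignment of query against reference (affine gaps).

    Deterministic: the aligner's first optimal alignment is taken, which
    under these scores prefers mismatches over gaps and places gaps
    left-most among ties.
    """
    if not query or not ref:
        raise InputError("cannot align empty sequences")
    return _aligner().align(query, ref)[0]


def detect_indels(alignment: Align.Alignment) -> list[IndelEvent]:
    """Call maximal gap runs from a query-vs-reference alignment.

    Positions are on reference coordinates; an insertion is reported at
    the reference position before which the bases are inserted.
    """
    query = str(alignment.sequences[0])
    ref = str(alignment.sequences[1])
    q_aln, r_aln = alignment[0], alignment[1]
    events: list[IndelEvent] = []
    ref_pos = 0
    i = 0
    n = len(q_aln)
    while i < n:
        if r_aln[i] == "-":  # insertion in query
            j = i
            while j < n and r_aln[j] == "-":
                j += 1
            events.append(IndelEvent(ref_pos, IndelKind.INS, j - i, q_aln[i:j]))
            i = j
        elif q_aln[i] == "-":  # deletion from reference
            j = i
            while j < n and q_aln[j] == "-":
                j += 1
            events.append(IndelEvent(ref_pos, IndelKind.DEL, j - i, r_aln[i:j]))
            ref_pos += j - i
            i = j
        else:
            ref_pos += 1
            i += 1
    assert ref_pos == len(ref)
    _ = query
    return events


def apply_indels(ref: str, indels: list[IndelEvent]) -> str:
    """Replay indel events on the reference; inverse of detect_indels."""
    out = []
    pos = 0
    for ev in sorted(indels, key=lambda e: e.ref_pos):
        out.append(ref[pos : ev.ref_pos])
        if ev.kind is IndelKind.INS:
            out.append(ev.bases)
            pos = ev.ref_pos
        else:
            if ref[ev.ref_pos : ev.ref_pos + ev.length] != ev.bases:
                raise InputError("deletion bases do not match the reference")
            pos = ev.ref_pos + ev.length
    out.append(ref[pos:])
    return "".join(out)


# ---------------------------------------------------------------------------
# frame tracing

def frame_trace(
    query: str, indels: list[IndelEvent], ref_len: Optional[int] = None
) -> tuple[list[int], list[int]]:
    """Per-codon frame offsets of the query plus premature stop positions.

    The cumulative shift after each indel is (+length for INS, -length for
    DEL) mod 3; the query is translated in its own frame 0 and stop codons
    falling in shifted regions (or anywhere before the terminus) are
    recorded as 0-based codon positions.
    """
    ordered = sorted(indels, key=lambda e: e.ref_pos)
    for a, b in zip(ordered, ordered[1:]):
        end_a = a.ref_pos + (a.length if a.kind is IndelKind.DEL else 0)
        if b.ref_pos < end_a:
            raise InputError("overlapping indels")
    # frame offset at each query nucleotide position
    # map: walk the query; the offset changes at the query coordinate of each indel
    offsets_at: list[tuple[int, int]] = [(0, 0)]
    shift = 0
    q_coord_delta = 0  # query coord - ref coord
    for ev in ordered:
        if ev.kind is IndelKind.INS:
            q_start = ev.ref_pos + q_coord_delta
            q_coord_delta += ev.length
            shift = (shift + ev.length) % 3
            offsets_at.append((q_start + ev.length, shift))
        else:
            q_start = ev.ref_pos + q_coord_delta
            q_coord_delta -= ev.length
            shift = (shift - ev.length) % 3
            offsets_at.append((q_start, shift))
    n_codons = len(query) // 3
    per_codon = []
    for c in range(n_codons):
        pos = 3 * c
        off = 0
        for start, s in offsets_at:
            if pos >= start:
                off = s
        per_codon.append(off)
    peptide = translate_frame(query, 0)
    stops = [i for i, aa in enumerate(peptide) if aa == STOP]
    # the annotated terminus is not premature
    if stops and stops[-1] == len(peptide) - 1:
        stops = stops[:-1]
    return per_codon, stops


# ---------------------------------------------------------------------------
# compensatory pairing and allele classification

def find_compensatory_pairs(
    indels: list[IndelEvent],
) -> tuple[list[CompensatoryPair], list[IndelEvent]]:
    """Greedy left-to-right pairing of frame-restoring indels.

    Each frameshifting event is paired with the nearest downstream
    frameshifting event that returns the cumulative shift to zero; events
    with shift 0 are never pair members.  Multi-event restorations are not
    guessed: whatever cannot be paired two-by-two is returned as residual.
    """
    ordered = sorted(indels, key=lambda e: e.ref_pos)
    shifting = [e for e in ordered if e.shift != 0]
    pairs: list[CompensatoryPair] = []
    residual: list[IndelEvent] = []
    i = 0
    while i < len(shifting):
        first = shifting[i]
        mate = None
        for j in range(i + 1, len(shifting)):
            cand = shifting[j]
            if (first.signed_shift + cand.signed_shift) % 3 == 0:
                mate = j
                break
            # an intervening event that does not close the pair leaves the
            # frame open; greedy pairing only looks at the next closers
        if mate == i + 1:
            pairs.append(CompensatoryPair(first, shifting[mate]))
            i = mate + 1
        else:
            # nearest closer is not adjacent: the intervening events keep
            # the span out of frame, so nothing is absorbed here
            residual.append(first)
            i += 1
    return pairs, residual


def classify_allele_state(
    exon: ExonSequence | str, reference: ExonSequence | str
) -> AlleleState:
    """Classify an allele as wild-type A, disrupted a or restored alpha."""
    query_nt = exon.nt if isinstance(exon, ExonSequence) else exon
    ref_nt = reference.nt if isinstance(reference, ExonSequence) else reference
    aln = pairwise_align(query_nt, ref_nt)
    indels = detect_indels(aln)
    pairs, residual = find_compensatory_pairs(indels)
    per_codon, stops = frame_trace(query_nt, indels, ref_len=len(ref_nt))
    if any(e.shift != 0 for e in residual):
        label = AlleleLabel.DISRUPTED_a
    elif pairs:
        label = AlleleLabel.RESTORED_ALPHA
    else:
        label = AlleleLabel.WILDTYPE_A
    state = AlleleState(
        label=label,
        indels=indels,
        pairs=pairs,
        residual=residual,
        premature_stops=stops,
        frame_trace=per_codon,
    )
    if label is AlleleLabel.RESTORED_ALPHA:
        _check_downstream_restoration(query_nt, ref_nt, pairs, indels)
    return state


def _check_downstream_restoration(
    query: str, ref: str, pairs: list[CompensatoryPair], indels: list[IndelEvent]
) -> None:
    """Verify translation matches the reference downstream of the last pair
    when no other differences are present (best effort; substitutions
    elsewhere simply skip the check)."""
    last = pairs[-1].second
    ref_resume = last.ref_pos + (last.length if last.kind is IndelKind.DEL else 0)
    # next codon boundary on the reference
    start = 3 * ((ref_resume + 2) // 3)
    delta = sum(e.signed_shift for e in indels if e.ref_pos <= last.ref_pos)
    q_start = start + delta
    if q_start < 0 or q_start % 3 != 0:
        return
    ref_tail = translate_frame(ref[start:], 0) if len(ref) - start >= 3 else ""
    q_tail = translate_frame(query[q_start:], 0) if len(query) - q_start >= 3 else ""
    if ref_tail and q_tail and ref_tail != q_tail:
        # substitutions may legitimately differ; only a frame-wide mismatch
        # (pervasive disagreement) indicates a failed restoration
        same = sum(a == b for a, b in zip(ref_tail, q_tail))
        if same < 0.5 * min(len(ref_tail), len(q_tail)):
            raise InputError("restored allele does not match reference downstream")


def classify_genotype_fertility(state1: AlleleLabel | AlleleState,
                                state2: AlleleLabel | AlleleState) -> Fertility:
    """Fertility of a genotype under the three-allele A/a/alpha scheme."""
    l1 = state1.label if isinstance(state1, AlleleState) else state1
    l2 = state2.label if isinstance(state2, AlleleState) else state2
    if l1 != l2:
        return Fertility.SUBFERTILE_HET
    if l1 is AlleleLabel.DISRUPTED_a:
        return Fertility.STERILE
    return Fertility.FUNCTIONAL
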