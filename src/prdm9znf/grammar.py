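"""C2H2 zinc-finger grammar for the PRDM9 zinc-finger-domain exon.

The exon splits into a conserved 5' region and a 3' array of tandem 84-bp
C2H2 repeats.  Each canonical repeat encodes 28 residues matching the
ligand template C-x2-C-x12-H-x3-H; the three residues at helix positions
-1, 3 and 6 contact DNA (the "binding triplet"), with helix position 2
added for the quadruplet.

Coordinates are 0-based half-open internally; reports are 1-based
inclusive.  Within a canonical 28-mer starting at the first cysteine
(C1 = residue 1, C2 = residue 4, H1 = residue 17, H2 = residue 21) the
alpha-helix is placed so that H1 sits at helix position +7, hence helix
-1/2/3/6 = residues 10/12/13/16 (1-based).  The map is a documented
convention, configurable via the module constants.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "ExonSequence",
    "ZincFinger",
    "ExonAnnotation",
    "FingerClass",
    "FingerWindow",
    "InputError",
    "NotExtractableError",
    "SegmentationError",
    "translate_frame",
    "scan_fingers",
    "classify_finger",
    "segment_exon",
    "extract_triplet",
    "extract_quadruplet",
    "helix_position",
    "FINGER_RES",
    "FINGER_NT",
    "LIGAND_OFFSETS",
    "TRIPLET_OFFSETS",
    "QUADRUPLET_OFFSETS",
]

DNA_ALPHABET = frozenset("ACGTN")
STOP = "*"

FINGER_RES = 28          # residues per canonical finger
FINGER_NT = 3 * FINGER_RES  # 84 bp
TRUNC5_RES = 25          # 5'-truncated finger: lacks the first cysteine codon

# 0-based offsets within the 28-mer
LIGAND_OFFSETS = ((0, "C"), (3, "C"), (16, "H"), (20, "H"))
LIGAND_NAMES = ("C1", "C2", "H1", "H2")
TRIPLET_OFFSETS = (9, 12, 15)        # helix -1, 3, 6
QUADRUPLET_OFFSETS = (9, 11, 12, 15)  # helix -1, 2, 3, 6
HELIX_OFFSET = 10  # helix position = 1-based residue - HELIX_OFFSET


class InputError(ValueError):
    """Invalid input to a grammar operation."""


class NotExtractableError(ValueError):
    """Binding residues cannot be read from this finger."""


class SegmentationError(ValueError):
    """No C2H2 repeat run could be located in the exon."""


class FingerClass(str, enum.Enum):
    C2H2 = "C2H2"
    DEGENERATE_LIGAND = "DEGENERATE_LIGAND"
    FORMER_FRAMESHIFTED = "FORMER_FRAMESHIFTED"
    TRUNC_5PRIME = "TRUNC_5PRIME"
    TRUNC_3PRIME = "TRUNC_3PRIME"


@dataclass(frozen=True)
class ExonSequence:
    """A zinc-finger-domain exon nucleotide sequence with sample metadata."""

    seq_id: str
    nt: str
    individual_id: str = ""
    species_label: str = ""
    region_label: str = ""
    site_label: str = ""

    def __post_init__(self) -> None:
        if not self.nt:
            raise InputError(f"{self.seq_id}: empty sequence")
        bad = set(self.nt) - DNA_ALPHABET
        if bad:
            raise InputError(f"{self.seq_id}: non-IUPAC characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.nt)


@dataclass(frozen=True)
class ZincFinger:
    """One classified repeat unit of the array (or the 5' region)."""

    index_in_array: int
    nt_span: tuple[int, int]  # 0-based half-open on the exon
    peptide: str
    finger_class: FingerClass
    # four (name, expected, observed, intact) entries for C1, C2, H1, H2
    ligand_states: tuple[tuple[str, str, str, bool], ...]

    def __post_init__(self) -> None:
        if self.nt_span[1] - self.nt_span[0] != 3 * len(self.peptide):
            raise InputError("nt_span length must equal 3 x peptide length")

    @property
    def triplet(self) -> str:
        return extract_triplet(self)

    @property
    def quadruplet(self) -> str:
        return extract_quadruplet(self)

    @property
    def intact(self) -> bool:
        return all(s[3] for s in self.ligand_states)


@dataclass
class ExonAnnotation:
    """Segmentation of an exon into 5' region and C2H2 array."""

    exon: ExonSequence
    five_prime_span: tuple[int, int]
    fingers: list[ZincFinger]
    c2h2_array_start: int  # 0-based exon nt offset

    @property
    def array_fingers(self) -> list[ZincFinger]:
        return [f for f in self.fingers if f.nt_span[0] >= self.c2h2_array_start]

    @property
    def five_prime_fingers(self) -> list[ZincFinger]:
        return [f for f in self.fingers if f.nt_span[0] < self.c2h2_array_start]


# ---------------------------------------------------------------------------
# translation

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = STOP


def translate_frame(nt: str, offset: int = 0) -> str:
    """Translate ``nt`` in reading frame ``offset`` (0, 1 or 2).

    Stop codons are rendered as '*' and translation continues past them —
    stop positions are data, not termination.  Codons containing N give
    'X'; a trailing partial codon is dropped.
    """
    if offset not in (0, 1, 2):
        raise InputError(f"offset must be 0, 1 or 2, got {offset}")
    bad = set(nt) - DNA_ALPHABET
    if bad:
        raise InputError(f"non-IUPAC characters {sorted(bad)}")
    if len(nt) < 3:
        raise InputError("sequence shorter than one codon")
    sub = nt[offset:]
    out = []
    for i in range(0, len(sub) - len(sub) % 3, 3):
        codon = sub[i : i + 3]
        out.append("X" if "N" in codon else _CODON_TABLE[codon])
    return "".join(out)


# ---------------------------------------------------------------------------
# finger scanning and classification

@dataclass(frozen=True)
class FingerWindow:
    """A candidate 28-residue finger window from a greedy scan."""

    start: int  # 0-based residue offset in the scanned peptide
    peptide: str
    ligand_flags: tuple[bool, bool, bool, bool]

    @property
    def n_intact(self) -> int:
        return sum(self.ligand_flags)


def _ligand_flags(window: str) -> tuple[bool, ...]:
    return tuple(window[off] == exp for off, exp in LIGAND_OFFSETS)


def scan_fingers(peptide: str, max_substituted: int = 1) -> list[FingerWindow]:
    """Greedy left-to-right scan for 28-residue C-x2-C-x12-H-x3-H windows.

    Windows anchor at the first cysteine; near-misses with exactly one
    ligand substituted are also reported (so degenerate fingers are seen).
    After a match the scan resumes at the window end.
    """
    if len(peptide) < TRUNC5_RES:
        raise InputError("peptide shorter than a truncated finger (25 residues)")
    out: list[FingerWindow] = []
    i = 0
    n = len(peptide)
    while i + FINGER_RES <= n:
        window = peptide[i : i + FINGER_RES]
        if STOP in window:
            i += 1
            continue
        flags = _ligand_flags(window)
        if sum(flags) >= 4 - max_substituted:
            out.append(FingerWindow(i, window, flags))  # type: ignore[arg-type]
            i += FINGER_RES
        else:
            i += 1
    return out


def _ligand_states(
    peptide: str, offsets: Sequence[tuple[int, str]] = LIGAND_OFFSETS
) -> tuple[tuple[str, str, str, bool], ...]:
    states = []
    for name, (off, expected) in zip(LIGAND_NAMES, offsets):
        if 0 <= off < len(peptide):
            obs = peptide[off]
            states.append((name, expected, obs, obs == expected))
        else:
            states.append((name, expected, "-", False))
    return tuple(states)


def _trunc5_states(peptide: str) -> tuple[tuple[str, str, str, bool], ...]:
    # 25-mer starts at the second cysteine codon: C1 absent by construction
    offs = [("C1", -3, "C"), ("C2", 0, "C"), ("H1", 13, "H"), ("H2", 17, "H")]
    states = []
    for name, off, expected in offs:
        if 0 <= off < len(peptide):
            obs = peptide[off]
            states.append((name, expected, obs, obs == expected))
        else:
            states.append((name, expected, "-", False))
    return tuple(states)


def classify_finger(
    window: FingerWindow | str,
    index_in_array: int = 0,
    nt_start: int = 0,
    frame_shifted: bool = False,
    terminal_fragment: bool = False,
) -> ZincFinger:
    """Classify a scanned window (or terminal fragment) into a ZincFinger.

    ``frame_shifted`` is supplied by the indel analysis for windows whose
    codons fall in a shifted frame; ``terminal_fragment`` marks an
    array-terminal fragment shortened by a stop codon.
    """
    peptide = window.peptide if isinstance(window, FingerWindow) else window
    n = len(peptide)
    if n == FINGER_RES:
        states = _ligand_states(peptide)
        if frame_shifted:
            cls = FingerClass.FORMER_FRAMESHIFTED
        elif all(s[3] for s in states):
            cls = FingerClass.C2H2
        else:
            cls = FingerClass.DEGENERATE_LIGAND
    elif n == TRUNC5_RES and not terminal_fragment:
        states = _trunc5_states(peptide)
        # C2, H1, H2 must be present for the truncated class
        if not (states[1][3] and states[2][3] and states[3][3]):
            cls = FingerClass.DEGENERATE_LIGAND if not frame_shifted else FingerClass.FORMER_FRAMESHIFTED
        else:
            cls = FingerClass.TRUNC_5PRIME
    elif terminal_fragment and 17 <= n < FINGER_RES:
        # shortened by a stop: accept when C1, C2 and at least H1 remain
        states = _ligand_states(peptide)
        if states[0][3] and states[1][3] and states[2][3]:
            cls = FingerClass.TRUNC_3PRIME
        else:
            raise InputError(f"terminal fragment of length {n} lacks C,C,H ligands")
    else:
        raise InputError(f"window of impossible length {n}")
    return ZincFinger(
        index_in_array=index_in_array,
        nt_span=(nt_start, nt_start + 3 * n),
        peptide=peptide,
        finger_class=cls,
        ligand_states=states,
    )


# ---------------------------------------------------------------------------
# exon segmentation

def _contiguous_blocks(windows: list[FingerWindow]) -> list[list[FingerWindow]]:
    blocks: list[list[FingerWindow]] = []
    for w in windows:
        if blocks and w.start == blocks[-1][-1].start + FINGER_RES:
            blocks[-1].append(w)
        else:
            blocks.append([w])
    return blocks


def segment_exon(
    exon: ExonSequence, reference: Optional[ExonAnnotation] = None
) -> ExonAnnotation:
    """Segment an exon into its 5' region and 3' C2H2 array.

    Translates in the annotated frame (frame 0 of the supplied sequence;
    frame excursions are owned by the indel analysis), scans for finger
    windows, and sets the array start at the first canonical finger of the
    uninterrupted 84-bp repeat run.  Fingers upstream of it — including
    ligand-degenerate ones — belong to the 5' region.
    """
    if len(exon.nt) < FINGER_NT:
        raise SegmentationError(
            f"{exon.seq_id}: exon of {len(exon.nt)} bp is shorter than one finger"
        )
    peptide = translate_frame(exon.nt, 0)
    windows = scan_fingers(peptide)
    blocks = _contiguous_blocks(windows)
    best = None
    best_count = 0
    for block in blocks:
        n_c2h2 = sum(1 for w in block if w.n_intact == 4)
        if n_c2h2 > best_count:
            best, best_count = block, n_c2h2
    if best is None or best_count == 0:
        raise SegmentationError(
            f"{exon.seq_id}: no C2H2 repeat run found "
            f"({len(windows)} candidate windows, none fully intact)"
        )
    first_c2h2 = next(w for w in best if w.n_intact == 4)
    array_start_nt = 3 * first_c2h2.start

    fingers: list[ZincFinger] = []
    arr_idx = 0
    for w in windows:
        in_array = 3 * w.start >= array_start_nt
        fingers.append(
            classify_finger(w, index_in_array=arr_idx if in_array else -1,
                            nt_start=3 * w.start)
        )
        if in_array:
            arr_idx += 1

    # array-terminal fragment shortened by a stop codon
    last = fingers[-1] if fingers else None
    if last is not None and last.nt_span[0] >= array_start_nt:
        tail_start = last.nt_span[1] // 3
        tail = peptide[tail_start:]
        stop_at = tail.find(STOP)
        frag = tail[:stop_at] if stop_at >= 0 else tail
        if 17 <= len(frag) < FINGER_RES:
            try:
                fingers.append(
                    classify_finger(frag, index_in_array=arr_idx,
                                    nt_start=3 * tail_start,
                                    terminal_fragment=True)
                )
            except InputError:
                pass
    return ExonAnnotation(
        exon=exon,
        five_prime_span=(0, array_start_nt),
        fingers=fingers,
        c2h2_array_start=array_start_nt,
    )


# ---------------------------------------------------------------------------
# binding residues

def helix_position(residue_1based: int) -> int:
    """Map a 1-based residue index within the 28-mer to a helix position.

    The helix starts at residue 11 (so H1 at residue 17 is +7); residues
    before the start count backwards from -1 — there is no position 0,
    per the usual C2H2 numbering.  Residues 10/13/16 are -1/3/6.
    """
    h = residue_1based - HELIX_OFFSET
    return h if h > 0 else h - 1


def _binding_residues(f: ZincFinger, offsets: Sequence[int]) -> str:
    if f.finger_class in (FingerClass.C2H2, FingerClass.DEGENERATE_LIGAND):
        local = offsets
    elif f.finger_class == FingerClass.TRUNC_5PRIME:
        local = [o - 3 for o in offsets]
    elif f.finger_class == FingerClass.TRUNC_3PRIME:
        local = offsets
    else:
        raise NotExtractableError(f"class {f.finger_class.value} has no binding triplet")
    if any(o < 0 or o >= len(f.peptide) for o in local):
        raise NotExtractableError(
            f"finger of length {len(f.peptide)} lacks a binding-residue offset"
        )
    return "".join(f.peptide[o] for o in local)


def extract_triplet(f: ZincFinger) -> str:
    """Residues at helix -1, 3, 6 (peptide residues 10/13/16, 1-based)."""
    return _binding_residues(f, TRIPLET_OFFSETS)


def extract_quadruplet(f: ZincFinger) -> str:
    """Residues at helix -1, 2, 3, 6 (peptide residues 10/12/13/16)."""
    return _binding_residues(f, QUADRUPLET_OFFSETS)
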