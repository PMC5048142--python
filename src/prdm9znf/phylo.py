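"""Masked zinc-finger phylogenies: K80 distances, neighbor joining, bootstrap.

Finger nucleotide alignments are preprocessed the way repeat-family
phylogenies require: identical fingers are collapsed within each genus,
and the four DNA-binding codons (helix -1, 2, 3, 6) are masked so that
the positively selected binding positions do not drive the topology.
Distances follow Kimura's two-parameter model,

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q)),

with P and Q the transition and transversion proportions over pairwise
complete (non-gap, non-N) sites.  Trees are inferred by canonical
neighbor joining with nonparametric bootstrap supports; internal nodes
below a support threshold are collapsed into polytomies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .grammar import FINGER_RES, QUADRUPLET_OFFSETS, InputError

__all__ = [
    "FingerAlignment",
    "PairwiseSubstCounts",
    "TreeNode",
    "SaturationError",
    "collapse_identical",
    "mask_binding_positions",
    "count_substitutions",
    "k80_distance",
    "distance_matrix",
    "nj_tree",
    "tree_distance",
    "bootstrap_support",
    "collapse_low_support",
    "bipartitions",
    "to_newick",
]

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
GAPLIKE = frozenset("-N")


class SaturationError(ValueError):
    """Substitution proportions beyond the reach of the K80 correction."""


@dataclass(frozen=True)
class PairwiseSubstCounts:
    P: float  # transition proportion
    Q: float  # transversion proportion
    n_sites: int

    def __post_init__(self) -> None:
        if not (0 <= self.P < 1 and 0 <= self.Q < 1 and self.P + self.Q <= 1):
            raise InputError("P, Q must be proportions with P + Q <= 1")


@dataclass
class FingerAlignment:
    """Masked finger rows: (label, group, nucleotide string) triples."""

    rows: list[tuple[str, str, str]]
    masked_positions: tuple[int, ...] = ()

    @property
    def labels(self) -> list[str]:
        return [r[0] for r in self.rows]

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][2]) if self.rows else 0


@dataclass
class TreeNode:
    label: str = ""
    length: float = 0.0
    support: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_labels(self) -> frozenset:
        return frozenset(l.label for l in self.leaves())

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


# ---------------------------------------------------------------------------
# alignment preprocessing

def collapse_identical(
    rows: Iterable[tuple[str, str, str]]
) -> tuple[list[tuple[str, str, str]], dict[str, list[str]]]:
    """Collapse byte-identical sequences within each group (genus).

    Identical sequences in different groups are retained separately.
    Returns deduplicated rows (first-seen representative) and a map from
    representative label to all member labels.
    """
    rows = list(rows)
    if not rows:
        raise InputError("no rows to collapse")
    seen: dict[tuple[str, str], str] = {}
    out: list[tuple[str, str, str]] = []
    members: dict[str, list[str]] = {}
    for label, group, seq in rows:
        key = (group, seq)
        if key in seen:
            members[seen[key]].append(label)
        else:
            seen[key] = label
            members[label] = [label]
            out.append((label, group, seq))
    return out, members


def mask_binding_positions(
    rows: Iterable[tuple[str, str, str]],
    masked_codons: Sequence[int] = QUADRUPLET_OFFSETS,
) -> FingerAlignment:
    """Remove the DNA-binding codons from finger rows.

    Rows are codon-aligned to the canonical 28-codon frame first:
    75-nt 5'-truncated fingers (starting at the second cysteine) are
    right-aligned by padding three gap codons on the left; shorter
    3'-truncated fingers are padded with gap codons on the right.  The
    codons at helix -1, 2, 3, 6 (0-based codon indices 9, 11, 12, 15)
    are then excised, leaving 72 columns for a canonical 84-nt finger.
    """
    out = []
    for label, group, seq in rows:
        if len(seq) % 3 != 0:
            raise InputError(f"{label}: length {len(seq)} not a multiple of 3")
        n_codons = len(seq) // 3
        if n_codons > FINGER_RES:
            raise InputError(f"{label}: {n_codons} codons exceeds a finger")
        if n_codons == FINGER_RES - 3:  # 5'-truncated: lacks first cysteine codon
            aligned = "---" * 3 + seq
        else:
            aligned = seq + "---" * (FINGER_RES - n_codons)
        codons = [aligned[3 * i : 3 * i + 3] for i in range(FINGER_RES)]
        masked = "".join(c for i, c in enumerate(codons) if i not in masked_codons)
        out.append((label, group, masked))
    return FingerAlignment(rows=out, masked_positions=tuple(masked_codons))


# ---------------------------------------------------------------------------
# distances

def count_substitutions(a: str, b: str) -> PairwiseSubstCounts:
    """Transition/transversion proportions over pairwise complete sites."""
    if len(a) != len(b):
        raise InputError("sequences of unequal length")
    ts = tv = n = 0
    for x, y in zip(a, b):
        if x in GAPLIKE or y in GAPLIKE:
            continue
        n += 1
        if x == y:
            continue
        same_class = (x in PURINES) == (y in PURINES)
        if same_class:
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise InputError("no comparable sites")
    return PairwiseSubstCounts(P=ts / n, Q=tv / n, n_sites=n)


def k80_distance(c: PairwiseSubstCounts) -> float:
    """Kimura (1980) two-parameter distance from P, Q proportions."""
    w1 = 1.0 - 2.0 * c.P - c.Q
    w2 = 1.0 - 2.0 * c.Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"saturated: P={c.P:.4f}, Q={c.Q:.4f}")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def distance_matrix(
    aln: FingerAlignment, saturation_ceiling: Optional[float] = None
) -> np.ndarray:
    """Pairwise K80 distance matrix (pairwise deletion of gap/N sites)."""
    seqs = [r[2] for r in aln.rows]
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = k80_distance(count_substitutions(seqs[i], seqs[j]))
            except SaturationError:
                if saturation_ceiling is None:
                    raise
                d = saturation_ceiling
            D[i, j] = D[j, i] = d
    return D


# ---------------------------------------------------------------------------
# neighbor joining

def nj_tree(D: np.ndarray, labels: Sequence[str]) -> TreeNode:
    """Canonical neighbor joining (Saitou & Nei Q-criterion).

    Tie-break on Q by lowest (row, col) index pair; negative branch
    lengths are clamped to zero.  The returned tree is the unrooted
    topology represented with a trifurcating root (bifurcating for 3
    taxa' final join).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T) or n != len(labels):
        raise InputError("distance matrix must be square and symmetric")
    if n < 3:
        raise InputError("need at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(label=l) for l in labels]
    active = list(range(n))
    D = D.copy()
    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        vi = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = D[i, j] - vi
        ni, nj_ = nodes[i], nodes[j]
        ni.length = max(vi, 0.0)
        nj_.length = max(vj, 0.0)
        parent = TreeNode(children=[ni, nj_])
        # reuse slot i for the new node; retire j
        new_row = np.zeros(D.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        D[i, :] = new_row
        D[:, i] = new_row
        nodes[i] = parent
        active.remove(j)
    # final join of the remaining three nodes
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, l in zip((a, b, c), (la, lb, lc)):
        nodes[idx].length = max(l, 0.0)
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]])


def tree_distance(tree: TreeNode, a: str, b: str) -> float:
    """Path length between two leaves (for additivity checks)."""

    def path(node: TreeNode, target: str) -> Optional[list[TreeNode]]:
        if node.is_leaf:
            return [node] if node.label == target else None
        for c in node.children:
            p = path(c, target)
            if p is not None:
                return [node] + p
        return None

    pa, pb = path(tree, a), path(tree, b)
    if pa is None or pb is None:
        raise InputError("leaf not in tree")
    k = 0
    while k < min(len(pa), len(pb)) and pa[k] is pb[k]:
        k += 1
    return sum(n.length for n in pa[k:]) + sum(n.length for n in pb[k:])


# ---------------------------------------------------------------------------
# bootstrap and support

def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions, each encoded as the leaf-set side not
    containing the lexicographically smallest leaf label."""
    all_leaves = tree.leaf_labels()
    anchor = min(all_leaves)
    out = set()
    for node in tree.walk():
        if node is tree or node.is_leaf:
            continue
        side = node.leaf_labels()
        if anchor in side:
            side = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(side)
    return out


def bootstrap_support(
    aln: FingerAlignment,
    n_reps: int = 100,
    seed: int = 0,
    saturation_ceiling: Optional[float] = 5.0,
) -> TreeNode:
    """NJ tree with nonparametric bootstrap supports on internal edges.

    Alignment columns are resampled with replacement per replicate; the
    support of each internal edge of the tree built from the original
    alignment is the fraction of replicate trees containing the same
    leaf-set bipartition.
    """
    if len(aln.rows) < 3:
        raise InputError("bootstrap needs at least 3 rows")
    if n_reps < 1:
        raise InputError("n_reps must be >= 1")
    labels = aln.labels
    tree = nj_tree(distance_matrix(aln, saturation_ceiling), labels)
    all_leaves = tree.leaf_labels()
    anchor = min(all_leaves)
    counts: dict[frozenset, int] = {bp: 0 for bp in bipartitions(tree)}
    rng = np.random.default_rng(seed)
    L = aln.n_cols
    seqs = [r[2] for r in aln.rows]
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep_rows = [
            (lab, grp, "".join(seq[c] for c in cols))
            for (lab, grp, _), seq in zip(aln.rows, seqs)
        ]
        rep_aln = FingerAlignment(rows=rep_rows, masked_positions=aln.masked_positions)
        try:
            rep_tree = nj_tree(distance_matrix(rep_aln, saturation_ceiling), labels)
        except InputError:
            continue
        rep_bps = bipartitions(rep_tree)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    for node in tree.walk():
        if node is tree or node.is_leaf:
            continue
        side = node.leaf_labels()
        if anchor in side:
            side = all_leaves - side
        if side in counts:
            node.support = counts[side] / n_reps
    return tree


def collapse_low_support(tree: TreeNode, threshold: float = 0.5) -> TreeNode:
    """Contract internal edges with support below the threshold into
    polytomies.  Leaves are never removed; idempotent."""

    def rebuild(node: TreeNode) -> TreeNode:
        if node.is_leaf:
            return TreeNode(label=node.label, length=node.length,
                            support=node.support)
        new_children: list[TreeNode] = []
        for child in node.children:
            nc = rebuild(child)
            if (not nc.is_leaf and nc.support is not None
                    and nc.support < threshold):
                for gc in nc.children:
                    # absorb the contracted edge's length into the children
                    gc.length += nc.length
                    new_children.append(gc)
            else:
                new_children.append(nc)
        return TreeNode(label=node.label, length=node.length,
                        support=node.support, children=new_children)

    return rebuild(tree)


# ---------------------------------------------------------------------------
# serialization

def to_newick(tree: TreeNode, decimals: int = 6) -> str:
    """Newick string with supports as internal node labels."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return f"{node.label}:{node.length:.{decimals}f}"
        inner = ",".join(fmt(c) for c in node.children)
        sup = "" if node.support is None else f"{node.support:g}"
        if node is tree:
            return f"({inner}){sup}"
        return f"({inner}){sup}:{node.length:.{decimals}f}"

    return fmt(tree) + ";"
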