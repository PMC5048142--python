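"""K80 distances, neighbor joining, bootstrap supports, node collapsing."""

import math

import numpy as np
import pytest

from prdm9znf.grammar import InputError
from prdm9znf.phylo import (
    FingerAlignment,
    PairwiseSubstCounts,
    SaturationError,
    bipartitions,
    bootstrap_support,
    collapse_identical,
    collapse_low_support,
    count_substitutions,
    distance_matrix,
    k80_distance,
    mask_binding_positions,
    nj_tree,
    to_newick,
    tree_distance,
    TreeNode,
)
from prdm9znf.simulate import SimConfig, make_reference_exon, random_additive_tree


def _tree_matrix(tree, labels):
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = tree_distance(tree, labels[i], labels[j])
    return D


class TestCollapseIdentical:
    def test_within_group_collapses(self):
        rows = [("a", "g1", "ACGT"), ("b", "g1", "ACGT")]
        dedup, members = collapse_identical(rows)
        assert len(dedup) == 1
        assert members["a"] == ["a", "b"]

    def test_cross_group_retained(self):
        rows = [("a", "g1", "ACGT"), ("b", "g2", "ACGT")]
        dedup, _ = collapse_identical(rows)
        assert len(dedup) == 2

    def test_distinct_unchanged(self):
        rows = [("a", "g1", "ACGT"), ("b", "g1", "ACGA")]
        dedup, members = collapse_identical(rows)
        assert dedup == rows
        assert all(len(v) == 1 for v in members.values())


class TestMasking:
    def test_canonical_finger_masks_to_72(self, reference):
        exon, truth, _ = reference
        unit = truth.array_units[0]
        aln = mask_binding_positions([("f1", "g", unit)])
        assert len(aln.rows[0][2]) == 72

    def test_truncated_finger_right_aligned(self, reference):
        exon, truth, _ = reference
        unit = truth.array_units[0]
        aln = mask_binding_positions([("f1", "g", unit[9:])])  # 75-nt 5'-trunc
        masked = aln.rows[0][2]
        assert masked.startswith("---" * 3)
        assert len(masked.replace("-", "")) == 63  # 75 - 4 masked codons

    def test_binding_codon_changes_invisible(self, reference):
        exon, truth, _ = reference
        unit = truth.array_units[0]
        variant = list(unit)
        for codon_idx in (9, 11, 12, 15):
            variant[3 * codon_idx : 3 * codon_idx + 3] = "GCA"
        rows = [("a", "g", unit), ("b", "g", "".join(variant))]
        aln = mask_binding_positions(rows)
        assert aln.rows[0][2] == aln.rows[1][2]

    def test_bad_length_rejected(self):
        with pytest.raises(InputError):
            mask_binding_positions([("a", "g", "ACGTA")])


class TestK80:
    def test_zero_distance(self):
        assert k80_distance(PairwiseSubstCounts(0.0, 0.0, 84)) == 0.0

    def test_closed_form_value(self):
        # independent evaluation of -1/2 ln((1-2P-Q) sqrt(1-2Q))
        P, Q = 4 / 84, 2 / 84
        expected = -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
        assert k80_distance(PairwiseSubstCounts(P, Q, 84)) == pytest.approx(expected)
        assert expected == pytest.approx(0.0756, abs=1e-4)

    def test_monotone_in_transitions(self):
        q = 0.05
        ds = [k80_distance(PairwiseSubstCounts(p, q, 100)) for p in (0.01, 0.1, 0.2)]
        assert ds == sorted(ds) and ds[0] < ds[-1]

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k80_distance(PairwiseSubstCounts(0.5, 0.1, 100))

    def test_counts_ignore_gap_columns(self):
        c = count_substitutions("AC-GT", "GCNGA")
        assert c.n_sites == 4  # gap/N column dropped
        assert c.P == pytest.approx(1 / 4)  # A<->G transition
        assert c.Q == pytest.approx(1 / 4)  # T<->A transversion


class TestNeighborJoining:
    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_additive_topology(self, seed):
        tree, labels = random_additive_tree(6, seed=seed)
        D = _tree_matrix(tree, labels)
        inferred = nj_tree(D, labels)
        assert bipartitions(inferred) == bipartitions(tree)

    def test_path_lengths_reproduce_additive_input(self):
        tree, labels = random_additive_tree(7, seed=99)
        D = _tree_matrix(tree, labels)
        inferred = nj_tree(D, labels)
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                got = tree_distance(inferred, labels[i], labels[j])
                assert got == pytest.approx(D[i, j], abs=1e-9)

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        t = nj_tree(D, ["a", "b", "c"])
        lengths = {c.label: c.length for c in t.children}
        assert lengths == {"a": pytest.approx(1.0), "b": pytest.approx(2.0),
                           "c": pytest.approx(3.0)}

    def test_ultrametric_matches_upgma_topology(self):
        # (a,b) at height 1, (c,d) at height 1, joined at height 3
        D = np.array(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 2], [6, 6, 2, 0]], float
        )
        t = nj_tree(D, ["a", "b", "c", "d"])
        assert bipartitions(t) in (
            {frozenset({"c", "d"})},
            {frozenset({"a", "b"})},
        )

    def test_asymmetric_rejected(self):
        D = np.array([[0, 1, 2], [1, 0, 3], [2, 4, 0]], float)
        with pytest.raises(InputError):
            nj_tree(D, list("abc"))

    def test_agrees_with_skbio_on_random_matrix(self):
        """Independent cross-check against scikit-bio's NJ implementation."""
        skbio = pytest.importorskip("skbio")
        tree, labels = random_additive_tree(8, seed=5)
        D = _tree_matrix(tree, labels)
        ours = bipartitions(nj_tree(D, labels))
        dm = skbio.DistanceMatrix(D, ids=labels)
        sk_tree = skbio.tree.nj(dm)
        anchor = min(labels)
        theirs = set()
        for node in sk_tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            if anchor in side:
                side = frozenset(labels) - side
            if 1 < len(side) < len(labels) - 1:
                theirs.add(side)
        assert ours == theirs


@pytest.fixture(scope="module")
def two_clade_alignment():
    rng = np.random.default_rng(17)
    base = "".join(rng.choice(list("ACGT"), size=72))

    def mutate(s, k):
        s = list(s)
        for p in rng.choice(len(s), size=k, replace=False):
            s[p] = rng.choice([b for b in "ACGT" if b != s[p]])
        return "".join(s)

    clade_a, clade_b = mutate(base, 18), mutate(base, 18)
    rows = [(f"A{i}", "g", mutate(clade_a, 2)) for i in range(4)]
    rows += [(f"B{i}", "g", mutate(clade_b, 2)) for i in range(4)]
    return FingerAlignment(rows=rows)


class TestBootstrap:

    def test_separating_bipartition_strongly_supported(self, two_clade_alignment):
        tree = bootstrap_support(two_clade_alignment, n_reps=100, seed=1)
        split = frozenset(f"B{i}" for i in range(4))
        supports = {}
        all_leaves = tree.leaf_labels()
        anchor = min(all_leaves)
        for node in tree.walk():
            if node is tree or node.is_leaf:
                continue
            side = node.leaf_labels()
            if anchor in side:
                side = all_leaves - side
            supports[side] = node.support
        assert supports[split] >= 0.95

    def test_supports_are_probabilities(self, two_clade_alignment):
        tree = bootstrap_support(two_clade_alignment, n_reps=50, seed=2)
        for node in tree.walk():
            if node is not tree and not node.is_leaf and node.support is not None:
                assert 0.0 <= node.support <= 1.0

    def test_seeded_runs_identical(self, two_clade_alignment):
        t1 = bootstrap_support(two_clade_alignment, n_reps=20, seed=7)
        t2 = bootstrap_support(two_clade_alignment, n_reps=20, seed=7)
        assert to_newick(t1) == to_newick(t2)

    def test_too_few_rows_rejected(self):
        with pytest.raises(InputError):
            bootstrap_support(FingerAlignment(rows=[("a", "g", "ACGT")]), 10, 0)


class TestCollapseLowSupport:
    def _tree(self, support):
        a, b, c, d = (TreeNode(label=l, length=1.0) for l in "abcd")
        inner = TreeNode(children=[a, b], length=0.5, support=support)
        return TreeNode(children=[inner, c, d])

    def test_high_support_unchanged(self):
        t = self._tree(0.9)
        assert to_newick(collapse_low_support(t, 0.5)) == to_newick(t)

    def test_low_support_yields_star(self):
        collapsed = collapse_low_support(self._tree(0.4), 0.5)
        assert len(collapsed.children) == 4
        assert bipartitions(collapsed) == set()

    def test_idempotent(self):
        once = collapse_low_support(self._tree(0.4), 0.5)
        twice = collapse_low_support(once, 0.5)
        assert to_newick(once) == to_newick(twice)

    def test_leaf_set_preserved(self):
        t = self._tree(0.1)
        assert collapse_low_support(t, 0.5).leaf_labels() == t.leaf_labels()

    def test_path_lengths_preserved(self):
        t = self._tree(0.3)
        c = collapse_low_support(t, 0.5)
        assert tree_distance(c, "a", "c") == pytest.approx(
            tree_distance(t, "a", "c")
        )


class TestMaskingInvariance:
    def test_tree_invariant_to_binding_codon_substitutions(self, reference):
        """Substitutions placed only at binding codons never change the tree."""
        exon, truth, _ = reference
        units = truth.array_units[:5]
        rows = [(f"f{i}", "g", u) for i, u in enumerate(units)]
        variant_rows = []
        rng = np.random.default_rng(3)
        for label, g, u in rows:
            v = list(u)
            codon_idx = rng.choice((9, 11, 12, 15))
            v[3 * codon_idx : 3 * codon_idx + 3] = rng.choice(
                ["GCA", "TTA", "CGA"]
            )
            variant_rows.append((label, g, "".join(v)))
        t1 = nj_tree(distance_matrix(mask_binding_positions(rows)),
                     [r[0] for r in rows])
        t2 = nj_tree(distance_matrix(mask_binding_positions(variant_rows)),
                     [r[0] for r in variant_rows])
        assert to_newick(t1) == to_newick(t2)
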