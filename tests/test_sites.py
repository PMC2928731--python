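import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import haploscope as h
from haploscope.sites import (
    classify_recurrent_aa_changes,
    count_synonymous_diffs,
    distinct_haplotypes,
    fitch_site_steps,
    label_association_test,
    mutation_rate,
)
from conftest import make_alignment


def exhaustive_min_steps(tree, column):
    """Oracle: minimise changes over all internal state assignments."""
    post = list(tree.postorder())
    internals = [n for n in post if not n.is_leaf]
    mask = {"A": {0}, "C": {1}, "G": {2}, "T": {3}, "N": {0, 1, 2, 3},
            "-": {0, 1, 2, 3}}
    leaf_states = {}
    for leaf, ch in column.items():
        leaf_states[leaf] = mask[ch]
    best = None
    for assign in itertools.product(range(4), repeat=len(internals)):
        amap = {id(n): s for n, s in zip(internals, assign)}
        cost = 0
        ok = True
        for n in post:
            if n.parent is None:
                continue
            ps = amap[id(n.parent)]
            if n.is_leaf:
                if ps not in leaf_states[n.label]:
                    cost += 1
            else:
                cost += amap[id(n)] != ps
        best = cost if best is None else min(best, cost)
    return best


class TestFitchSteps:
    def test_constant_column_zero_steps(self, four_taxon_tree):
        aln = make_alignment({k: "AAA" for k in "abcd"})
        assert fitch_site_steps(aln, four_taxon_tree).min_steps.tolist() == [0, 0, 0]

    def test_known_four_taxon_columns(self, four_taxon_tree):
        # columns: all-different (3 steps), split-concordant (1 step)
        aln = make_alignment({"a": "AA", "b": "CA", "c": "GC", "d": "TC"})
        assert fitch_site_steps(aln, four_taxon_tree).min_steps.tolist() == [3, 1]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        tree = h.simulate_tree(n, seed=seed)
        labels = tree.leaf_labels()
        cols = ["".join(rng.choice(list("ACGTN-"), size=n)) for _ in range(25)]
        aln = make_alignment(
            {lab: "".join(c[i] for c in cols) for i, lab in enumerate(labels)}
        )
        got = fitch_site_steps(aln, tree).min_steps
        for j, col in enumerate(cols):
            want = exhaustive_min_steps(
                tree, dict(zip(labels, col))
            )
            assert got[j] == want, f"column {j} ({col})"

    def test_leaf_order_invariance(self, small_alignment):
        aln, tree = small_alignment
        rev = h.Alignment(list(reversed(aln.records)))
        assert (
            fitch_site_steps(aln, tree).min_steps.sum()
            == fitch_site_steps(rev, tree).min_steps.sum()
        )

    def test_label_mismatch_rejected(self, four_taxon_tree):
        aln = make_alignment({"a": "A", "b": "A", "c": "A", "x": "A"})
        with pytest.raises(ValueError, match="mismatch"):
            fitch_site_steps(aln, four_taxon_tree)


class TestAminoAcidFlags:
    def test_synonymous_third_position_not_flagged(self, four_taxon_tree):
        # GGA/GGC both glycine
        aln = make_alignment(
            {"a": "GGA", "b": "GGA", "c": "GGC", "d": "GGC"}
        )
        profile = fitch_site_steps(aln, four_taxon_tree)
        flagged = classify_recurrent_aa_changes(profile, aln, frame=0)
        assert flagged == []
        assert not profile.aa_change_flag.any()

    def test_first_position_replacement_flagged(self, four_taxon_tree):
        # CCA (Pro) vs ACA (Thr)
        aln = make_alignment(
            {"a": "CCA", "b": "CCA", "c": "ACA", "d": "ACA"}
        )
        profile = fitch_site_steps(aln, four_taxon_tree)
        flagged = classify_recurrent_aa_changes(profile, aln, frame=0)
        assert len(flagged) == 1
        assert flagged[0].site == 0
        assert set(flagged[0].amino_acids) == {"P", "T"}

    def test_recurrent_requires_two_steps(self):
        # A/C alternates across the two cherries: two independent origins
        tree = h.parse_newick("((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1);")
        aln = make_alignment(
            {"a": "CCA", "b": "ACA", "c": "CCA", "d": "ACA"}
        )
        profile = fitch_site_steps(aln, tree)
        assert profile.min_steps[0] == 2
        flagged = classify_recurrent_aa_changes(profile, aln, frame=0)
        assert flagged[0].recurrent

    def test_constant_column_never_flagged(self, four_taxon_tree):
        aln = make_alignment({k: "ATGATG" for k in "abcd"})
        profile = fitch_site_steps(aln, four_taxon_tree)
        assert classify_recurrent_aa_changes(profile, aln, frame=0) == []


class TestSynonymousCounts:
    def test_identical_records(self):
        a = h.SequenceRecord(id="a", bases="ATGGGATAA")
        assert count_synonymous_diffs(a, a).astuple() == (0, 0, 0)

    @pytest.mark.parametrize(
        "ca,cb,expected",
        [
            ("GGA", "GGG", (1, 0, 0)),  # Gly -> Gly
            ("ATG", "ATA", (0, 1, 0)),  # Met -> Ile
            ("GGA", "GCG", (0, 0, 2)),  # two hits in one codon
            ("GNA", "GNG", (0, 0, 1)),  # context missing
        ],
    )
    def test_single_codon_classification(self, ca, cb, expected):
        a = h.SequenceRecord(id="a", bases="ATG" + ca)
        b = h.SequenceRecord(id="b", bases="ATG" + cb)
        assert count_synonymous_diffs(a, b).astuple() == expected

    def test_counts_partition_differing_sites(self):
        rng = np.random.default_rng(11)
        x = "".join(rng.choice(list("ACGT"), 300))
        y = list(x)
        for j in rng.choice(300, 40, replace=False):
            y[j] = {"A": "G", "G": "A", "C": "T", "T": "C"}[y[j]]
        a = h.SequenceRecord(id="a", bases=x)
        b = h.SequenceRecord(id="b", bases="".join(y))
        counts = count_synonymous_diffs(a, b)
        n_diff = sum(p != q for p, q in zip(a.bases, b.bases))
        assert counts.syn + counts.nonsyn + counts.ambiguous == n_diff

    def test_trailing_partial_codon_excluded(self):
        a = h.SequenceRecord(id="a", bases="GGAC")
        b = h.SequenceRecord(id="b", bases="GGAT")
        assert count_synonymous_diffs(a, b).astuple() == (0, 0, 0)


class TestMutationRate:
    @pytest.mark.parametrize(
        "s,expected", [(3, 5.5e-4), (10, 1.8e-3), (0, 0.0)]
    )
    def test_reference_bounds(self, s, expected):
        """s synonymous differences over 500 bp and 11 years."""
        rate = mutation_rate(s, 500, 11).rate
        assert rate == pytest.approx(expected, rel=0.05)

    @given(
        st.integers(min_value=0, max_value=50),
        st.integers(min_value=100, max_value=2000),
        st.floats(min_value=0.5, max_value=50),
    )
    @settings(max_examples=30, deadline=None)
    def test_scaling_laws(self, s, length, years):
        base = mutation_rate(s, length, years).rate
        assert mutation_rate(2 * s, length, years).rate == pytest.approx(2 * base)
        assert mutation_rate(s, 2 * length, years).rate == pytest.approx(base / 2)
        assert mutation_rate(s, length, 2 * years).rate == pytest.approx(base / 2)

    def test_nonpositive_years_rejected(self):
        with pytest.raises(ValueError):
            mutation_rate(3, 500, 0)


class TestDistinctHaplotypes:
    def test_exact_grouping(self):
        aln = make_alignment({"s1": "AAA", "s2": "AAA", "s3": "AAC"})
        groups = distinct_haplotypes(aln, "strict")
        assert groups.n_distinct == 2

    def test_missing_tolerant_merges_compatible(self):
        aln = make_alignment({"s1": "AAN", "s2": "AAA"})
        assert distinct_haplotypes(aln, "strict").n_distinct == 2
        assert distinct_haplotypes(aln, "missing-tolerant").n_distinct == 1

    def test_identical_timepoints_group_together(self):
        aln = make_alignment({"line1_t0": "ACGTAC", "line1_t3m": "ACGTAC"})
        groups = distinct_haplotypes(aln, "strict")
        assert groups.n_distinct == 1
        assert sorted(groups.groups[0]) == ["line1_t0", "line1_t3m"]


class TestLabelAssociation:
    def test_concordant_labels_small_p(self):
        tree = h.parse_newick(
            "(((a1:1,a2:1):1,(a3:1,a4:1):1):2,((b1:1,b2:1):1,(b3:1,b4:1):1):2);"
        )
        labels = {f"a{i}": "A" for i in range(1, 5)}
        labels.update({f"b{i}": "B" for i in range(1, 5)})
        p = label_association_test(tree, labels, n_perm=999, seed=1)
        assert p <= 0.05

    def test_null_p_values_calibrated(self):
        """Labels drawn from the permutation null give valid p-values.

        The Fitch-step statistic is very discrete on 12 leaves, so the
        null p-value distribution is lumpy; validity means it is
        super-uniform: P(p <= a) <= a (plus Monte-Carlo slack) at every
        level, with the one-offset estimator keeping p >= 1/(n_perm+1).
        """
        tree = h.simulate_tree(12, seed=3)
        leaves = tree.leaf_labels()
        rng = np.random.default_rng(4)
        pvals = np.array(
            [
                label_association_test(
                    tree,
                    dict(zip(leaves, rng.permutation(["A"] * 6 + ["B"] * 6))),
                    n_perm=99,
                    seed=5,
                )
                for _ in range(200)
            ]
        )
        for level in (0.05, 0.25, 0.5):
            slack = 3.0 * np.sqrt(level * (1 - level) / len(pvals))
            assert (pvals <= level).mean() <= level + slack
        assert pvals.min() >= 1 / 100
        assert len(np.unique(np.round(pvals, 2))) > 3

    def test_degenerate_single_category(self):
        tree = h.simulate_tree(5, seed=1)
        labels = {l: "A" for l in tree.leaf_labels()}
        labels[tree.leaf_labels()[0]] = "B"
        with pytest.raises(ValueError, match=">= 2"):
            label_association_test(tree, labels)
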