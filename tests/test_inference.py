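import math

import numpy as np
import pytest

import haploscope as h
from haploscope.inference import (
    DistanceMatrix,
    chi2_quantile,
    jc_distance_matrix,
    lrt,
    lrt_decision,
    nj_tree,
    nni_search,
    select_model,
)


def _random_additive_tree(n, seed):
    tree = h.simulate_tree(n, seed=seed, mean_branch=0.2)
    for e in tree.edges():
        e.length = max(e.length, 0.05)
    labels = tree.leaf_labels()
    import itertools

    paths = {}
    for a, b in itertools.combinations(tree.leaves(), 2):
        anc = set()
        n_ = a
        while n_ is not None:
            anc.add(id(n_))
            n_ = n_.parent
        d = 0.0
        x = b
        while id(x) not in anc:
            d += x.length
            x = x.parent
        y = a
        while y is not x:
            d += y.length
            y = y.parent
        paths[frozenset((a.label, b.label))] = d
    D = np.zeros((n, n))
    for i, la in enumerate(labels):
        for j, lb in enumerate(labels):
            if i != j:
                D[i, j] = paths[frozenset((la, lb))]
    return tree, DistanceMatrix(
        labels=labels, d=D, flagged=np.zeros((n, n), dtype=bool)
    )


class TestJCDistances:
    def test_identical_pair_zero(self):
        aln = h.Alignment(
            [
                h.SequenceRecord(id="a", bases="ACGTACGTAC"),
                h.SequenceRecord(id="b", bases="ACGTACGTAC"),
            ]
        )
        assert jc_distance_matrix(aln).d[0, 1] == 0.0

    def test_closed_form_at_p_10_percent(self):
        bases_a = "A" * 100
        bases_b = "C" * 10 + "A" * 90
        aln = h.Alignment(
            [
                h.SequenceRecord(id="a", bases=bases_a),
                h.SequenceRecord(id="b", bases=bases_b),
            ]
        )
        d = jc_distance_matrix(aln).d[0, 1]
        assert d == pytest.approx(-0.75 * math.log(1 - 4 * 0.1 / 3), abs=1e-12)
        assert round(d, 5) == 0.10733

    def test_saturated_pair_flagged_and_capped(self):
        aln = h.Alignment(
            [
                h.SequenceRecord(id="a", bases="A" * 10),
                h.SequenceRecord(id="b", bases="C" * 8 + "A" * 2),
            ]
        )
        dm = jc_distance_matrix(aln)
        assert dm.flagged[0, 1]
        assert dm.d[0, 1] == h.inference.SATURATION_CAP

    def test_comparisons_ignore_ns(self):
        aln = h.Alignment(
            [
                h.SequenceRecord(id="a", bases="NNGTACGTAC"),
                h.SequenceRecord(id="b", bases="CCGTACGTNN"),
            ]
        )
        assert jc_distance_matrix(aln).d[0, 1] == 0.0

    def test_all_n_record_rejected(self):
        aln = h.Alignment(
            [
                h.SequenceRecord(id="a", bases="NNNN"),
                h.SequenceRecord(id="b", bases="ACGT"),
            ]
        )
        with pytest.raises(ValueError, match="'a'"):
            jc_distance_matrix(aln)


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        dm = DistanceMatrix(
            labels=["a", "b"],
            d=np.array([[0.0, 0.3], [0.3, 0.0]]),
            flagged=np.zeros((2, 2), dtype=bool),
        )
        t = nj_tree(dm)
        assert sum(e.length for e in t.edges()) == pytest.approx(0.3)

    def test_four_taxon_additive_metric_recovered(self):
        d = {
            ("a", "b"): 0.3,
            ("a", "c"): 0.45,
            ("a", "d"): 0.55,
            ("b", "c"): 0.55,
            ("b", "d"): 0.65,
            ("c", "d"): 0.4,
        }
        labels = ["a", "b", "c", "d"]
        D = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = labels.index(x), labels.index(y)
            D[i, j] = D[j, i] = v
        t = nj_tree(
            DistanceMatrix(labels=labels, d=D, flagged=np.zeros((4, 4), bool))
        )
        assert t.splits() == {frozenset({"c", "d"})}
        # exact branch lengths follow from additivity
        lens = {n.label: n.length for n in t.leaves()}
        assert lens["a"] == pytest.approx(0.1)
        assert lens["b"] == pytest.approx(0.2)

    @pytest.mark.parametrize("n", [5, 6, 8])
    def test_additive_metric_reproduces_tree(self, n):
        """NJ is consistent on additive distances."""
        true, dm = _random_additive_tree(n, seed=n)
        assert h.robinson_foulds(nj_tree(dm), true) == 0

    def test_label_permutation_invariance(self):
        true, dm = _random_additive_tree(6, seed=17)
        t1 = nj_tree(dm)
        order = [3, 1, 5, 0, 4, 2]
        dm2 = DistanceMatrix(
            labels=[dm.labels[i] for i in order],
            d=dm.d[np.ix_(order, order)],
            flagged=dm.flagged[np.ix_(order, order)],
        )
        assert h.robinson_foulds(t1, nj_tree(dm2)) == 0

    def test_agrees_with_skbio(self):
        pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(23)
        true, dm = _random_additive_tree(7, seed=23)
        noisy = dm.d + rng.uniform(0, 0.01, dm.d.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        ours = nj_tree(
            DistanceMatrix(labels=dm.labels, d=noisy, flagged=dm.flagged)
        )
        ref = skbio_nj(SkbioDM(noisy, ids=dm.labels))
        ref_tree = h.parse_newick(str(ref).strip())
        assert h.robinson_foulds(ours, ref_tree) == 0


class TestNNISearch:
    def test_search_does_not_worsen_start(self, small_alignment):
        aln, _ = small_alignment
        start = h.optimize_parameters(
            aln, nj_tree(jc_distance_matrix(aln)), "JC"
        )
        res = nni_search(aln, "JC")
        assert res.lnL >= start.lnL - 1e-6

    def test_seed_repeatable(self, small_alignment):
        aln, _ = small_alignment
        r1 = nni_search(aln, "JC", seed=1)
        r2 = nni_search(aln, "JC", seed=1)
        assert r1.lnL == r2.lnL
        assert r1.tree.newick() == r2.tree.newick()

    def test_topology_recovery_simulation(self):
        """NNI search recovers the generating 6-taxon topology."""
        hits = 0
        for seed in range(10):
            true = h.simulate_tree(6, seed=seed, mean_branch=0.1)
            for e in true.edges():
                if not e.is_leaf:
                    e.length = max(e.length, 0.1)
            aln = h.evolve_sequences(
                true, h.SubstModelParams(), 2000, seed=seed + 100
            )
            res = nni_search(aln, "JC", seed)
            hits += h.robinson_foulds(res.tree, true) == 0
        assert hits >= 9


class TestChi2AndLRT:
    def test_reference_quantiles(self):
        assert chi2_quantile(0.001, 1) == pytest.approx(10.83, abs=0.005)
        assert chi2_quantile(0.05, 1) == pytest.approx(3.84, abs=0.005)
        assert chi2_quantile(1.0, 1) == 0.0

    def test_quantile_inverts_tail(self):
        from scipy.stats import chi2 as chi2_dist

        for p in (0.3, 0.05, 0.001):
            for df in (1, 3):
                assert chi2_dist.sf(
                    chi2_quantile(p, df), df
                ) == pytest.approx(p, abs=1e-8)

    def test_rate_heterogeneity_stat_rejects(self):
        """A 2ΔlnL of 27.25 on one degree of freedom clears the 0.1%
        critical value of 10.83."""
        res = lrt_decision(27.2504, df=1, level=0.001)
        assert res.critical_value == pytest.approx(10.83, abs=0.005)
        assert res.reject
        assert res.p_value < 0.001

    def test_equal_likelihoods_not_rejected(self):
        res = lrt_decision(0.0, df=1, level=0.05)
        assert res.p_value == pytest.approx(1.0)
        assert not res.reject

    def test_non_nested_specs_rejected(self, small_alignment):
        aln, tree = small_alignment
        a = h.optimize_parameters(aln, tree, "JC+G")
        b = h.optimize_parameters(aln, tree, "HKY+I")
        with pytest.raises(ValueError, match="not nested"):
            lrt(a, b)

    def test_type_one_error_without_heterogeneity(self):
        """Testing +Γ on homogeneous data stays conservative (boundary)."""
        rejections = 0
        n_reps = 200
        for seed in range(n_reps):
            true = h.simulate_tree(6, seed=seed, mean_branch=0.05)
            aln = h.evolve_sequences(
                true, h.SubstModelParams(), 300, seed=seed + 3000
            )
            null = h.optimize_parameters(aln, true, "JC")
            alt = h.optimize_parameters(
                aln,
                null.tree,
                h.parse_model_spec("JC+G", K=4),
                init_params=null.params,
            )
            rejections += lrt(null, alt, 0.05).reject
        assert rejections / n_reps <= 0.08


class TestModelSelection:
    def test_single_candidate_returned(self, small_alignment):
        aln, _ = small_alignment
        ranks = select_model(aln, ["JC"])
        assert len(ranks) == 1 and ranks[0].spec.name == "JC"

    def test_gamma_data_prefers_gamma_models(self):
        hits = 0
        for seed in range(6):
            t = h.simulate_tree(10, seed=seed, mean_branch=0.05)
            m = h.SubstModelParams(
                exchangeabilities=[1, 4, 1, 1, 4, 1],
                pi=[0.3, 0.2, 0.22, 0.28],
                alpha=0.1,
                K=4,
            )
            aln = h.evolve_sequences(t, m, 1500, seed=seed + 50)
            ranks = select_model(
                aln, ["GTR", "GTR+I", "GTR+G", "GTR+G+I"], K=4
            )
            hits += ranks[0].spec.gamma
        assert hits >= 5

    def test_homogeneous_jc_data_keeps_jc_close(self):
        hits = 0
        for seed in range(6):
            t = h.simulate_tree(8, seed=seed + 40, mean_branch=0.05)
            aln = h.evolve_sequences(t, h.SubstModelParams(), 1500, seed=seed)
            ranks = select_model(aln, ["JC", "JC+G", "HKY", "GTR"], K=4)
            best = ranks[0].aic
            jc_aic = next(r.aic for r in ranks if r.spec.name == "JC")
            hits += jc_aic - best <= 2.0
        assert hits >= 5
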