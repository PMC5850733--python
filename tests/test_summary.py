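"""Summary species-tree estimators: quartet scoring, triples, SVD
flattenings, majority vote."""

from itertools import combinations
from math import exp, log

import numpy as np
import pytest

from gibbonmsc.genedist import sample_topology_counts
from gibbonmsc.gibbon import GENE_TREE_1, GENE_TREE_7, candidate_trees
from gibbonmsc.likelihood import SitePatternCounts
from gibbonmsc.simulate import GeneTree, LocusModel, simulate_gene_tree, SampleConfig
from gibbonmsc.summary import (FlatteningMatrix, QuartetTally, astral_score,
                               astral_search, flattening_matrix, majority_vote,
                               mpest_pseudolik, mpest_search, pooled_patterns,
                               quartet_length, run_all_summary,
                               subsample_one_per_species, svd_quartets_search,
                               svd_split_score)
from gibbonmsc.trees import (CoalUnitTree, SpeciesTreeModel, Topology,
                             topology_id)


class TestMajorityVote:
    def test_most_frequent_wins(self):
        a, b = Topology((("x", "y"), "z")), Topology((("x", "z"), "y"))
        assert majority_vote([a, a, b]) == a

    def test_all_identical(self):
        a = Topology((("x", "y"), "z"))
        assert majority_vote([a, a]) == a

    def test_deterministic_tie_break(self):
        a, b = Topology((("x", "y"), "z")), Topology((("x", "z"), "y"))
        assert majority_vote([a, b]) == majority_vote([b, a])

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            majority_vote([])

    def test_gibbon_regime_elects_the_anomalous_tree(self, gibbon_true_gene_trees):
        from gibbonmsc.trees import _prune
        rooted = [Topology(_prune(t.root, "O")) for t in gibbon_true_gene_trees]
        assert topology_id(majority_vote(rooted)) == 7


class TestAstral:
    def test_star_support_maps_to_zero_length(self):
        assert quartet_length(1 / 3) == 0.0
        assert quartet_length(0.2) == 0.0
        assert quartet_length(1.0) == float("inf")
        # inversion consistency: q = 1 - (2/3)exp(-t)
        for t in (0.1, 1.0, 2.33):
            q = 1 - (2 / 3) * exp(-t)
            assert quartet_length(q) == pytest.approx(t)

    def test_score_counts_matching_quartets(self):
        trees = [Topology(((("A", "B"), "C"), "D"))] * 3 + \
                [Topology(((("A", "C"), "B"), "D"))] * 2
        cand = Topology(((("A", "B"), "C"), "D"))
        assert astral_score(trees, cand) == 3
        cand2 = Topology(((("A", "C"), "B"), "D"))
        assert astral_score(trees, cand2) == 2

    def test_search_recovers_tree1_with_branch_lengths(self, gibbon_true_gene_trees,
                                                       cands6):
        key, top, scores, branches = astral_search(gibbon_true_gene_trees, cands6)
        assert key == 1
        by_clade = {b.clade: b for b in branches}
        h = by_clade[frozenset({"Hm", "Hp"})]
        # true H branch is 2.330 coalescent units; MC error at 4,000 trees
        assert h.length == pytest.approx(2.330, abs=0.15)
        assert h.q_hat > 0.9

    def test_consistency_accuracy_grows_with_trees(self, noncoding_cu, cands6):
        rng = np.random.default_rng(12)
        accs = []
        for n in (30, 120, 480):
            correct = 0
            reps = 12
            for _ in range(reps):
                counts = sample_topology_counts(noncoding_cu, n, rng, outgroup="O")
                trees = [t for t, c in counts.items() for _ in range(c)]
                key, *_ = astral_search(trees, cands6)
                correct += key == 1
            accs.append(correct / reps)
        assert accs[-1] >= accs[0]
        assert accs[-1] >= 0.75


class TestMPEST:
    def test_closed_form_branch_length(self):
        """Triple frequencies (1/2, 1/4, 1/4) maximise the trinomial at
        exp(-t) = 3/4, i.e. t = ln(4/3) = 0.2877."""
        cand = Topology((("A", "B"), "C"))
        trees = ([Topology((("A", "B"), "C"))] * 2 +
                 [Topology((("A", "C"), "B"))] * 1 +
                 [Topology((("B", "C"), "A"))] * 1)
        _, _, results = mpest_search(trees, {0: cand})
        t_hat = results[0][1][frozenset({"A", "B"})]
        assert t_hat == pytest.approx(-log(0.75), abs=1e-4)
        # grid-search oracle
        grid = np.linspace(0, 2, 4001)
        lls = [mpest_pseudolik(trees, cand, {frozenset({"A", "B"}): t}) for t in grid]
        assert grid[int(np.argmax(lls))] == pytest.approx(-log(0.75), abs=1e-3)

    def test_all_matching_caps_length(self):
        cand = Topology((("A", "B"), "C"))
        trees = [cand] * 20
        _, best, results = mpest_search(trees, {0: cand, 1: Topology((("A", "C"), "B"))})
        assert best == cand
        assert results[0][1][frozenset({"A", "B"})] > 5

    def test_star_frequencies_tie(self):
        trees = [Topology((("A", "B"), "C")), Topology((("A", "C"), "B")),
                 Topology((("B", "C"), "A"))]
        cands = {0: trees[0], 1: trees[1], 2: trees[2]}
        _, _, results = mpest_search(trees, cands)
        lls = [results[k][0] for k in cands]
        assert max(lls) - min(lls) < 1e-6

    def test_recovers_tree1_from_true_gibbon_trees(self, gibbon_true_gene_trees, cands5):
        from gibbonmsc.trees import _prune
        rooted = [Topology(_prune(t.root, "O")) for t in gibbon_true_gene_trees]
        key, top, _ = mpest_search(rooted, cands5)
        assert key == 1

    def test_unrooted_input_rejected(self):
        with pytest.raises(TypeError):
            mpest_search([object()], {0: Topology((("A", "B"), "C"))})


def _exact_pattern_probs(gt: GeneTree) -> np.ndarray:
    """Exact JC site-pattern probabilities (256-vector) for a 4-tip
    clock gene tree — test-local oracle via direct matrix products."""
    names = sorted(gt.topology.tips)

    def pmat(t):
        e = exp(-4.0 * t / 3.0)
        return np.full((4, 4), 0.25 - 0.25 * e) + np.eye(4) * e

    lengths = gt.branch_lengths()

    def rec(node):
        """Partial likelihood array over (state at node, tip states...)"""
        if isinstance(node, str):
            out = np.zeros((4, 4))  # state at node x observed tip state
            np.fill_diagonal(out, 1.0)
            return [node], out.reshape(4, 4)
        (na, pa), (nb, pb) = (rec(c) for c in node)
        ma = pmat(lengths[frozenset(na)])
        mb = pmat(lengths[frozenset(nb)])
        ta = np.tensordot(ma, pa, axes=(1, 0))  # parent state x tips_a...
        tb = np.tensordot(mb, pb, axes=(1, 0))
        sa, sb = ta.shape[1:], tb.shape[1:]
        res = (ta.reshape(4, -1, 1) * tb.reshape(4, 1, -1)).reshape((4,) + sa + sb)
        return na + nb, res

    order, arr = rec(gt.topology.root)
    probs = np.tensordot(np.full(4, 0.25), arr, axes=(0, 0))
    # reorder axes to sorted tip names
    perm = [order.index(n) for n in names]
    probs = np.transpose(probs, perm)
    return probs.reshape(-1)


class TestSVD:
    def _species_model(self):
        top = Topology((("A", "B"), ("C", "D")))
        return SpeciesTreeModel(
            top, {frozenset("AB"): 0.002, frozenset("CD"): 0.003,
                  frozenset("ABCD"): 0.004},
            {p: 0.004 for p in [frozenset("AB"), frozenset("CD"), frozenset("ABCD")]})

    def test_expected_flattening_rank_at_most_10(self, rng):
        """The exact MSC+JC expected pattern distribution flattened by
        the true split has rank <= 10; a wrong split scores strictly
        larger.  (Individual gene trees or finite mixtures do not have
        this property — only the full coalescent expectation does.)"""
        from gibbonmsc.genedist import expected_pattern_probabilities
        m = self._species_model()
        names, probs = expected_pattern_probabilities(m)
        assert probs.sum() == pytest.approx(1.0, abs=1e-10)
        # agreement with the per-tree oracle, Monte-Carlo averaged
        cfg = SampleConfig({s: 1 for s in "ABCD"})
        mc = np.zeros(256)
        n = 400
        for _ in range(n):
            mc += _exact_pattern_probs(simulate_gene_tree(m, cfg, rng))
        mc /= n
        assert np.abs(mc - probs.reshape(-1)).max() < 0.01
        f_true = probs.reshape(16, 16)  # rows (A,B), cols (C,D)
        sv = np.linalg.svd(f_true, compute_uv=False)
        assert sv[10:].max() < 1e-10
        score_true = svd_split_score(f_true)
        f_wrong = probs.transpose(0, 2, 1, 3).reshape(16, 16)  # AC|BD
        score_wrong = svd_split_score(f_wrong)
        assert score_true < 1e-10
        assert score_wrong > 100 * max(score_true, 1e-14)

    def test_label_symmetry_of_best_split(self, rng):
        """Permuting the two sequences within a side leaves the score
        invariant."""
        m = self._species_model()
        from gibbonmsc.simulate import simulate_dataset
        loci = simulate_dataset(m, SampleConfig({s: 1 for s in "ABCD"}), None,
                                20, rng, sites=300)
        spc = pooled_patterns(loci, ["A", "B", "C", "D"])
        f1 = flattening_matrix(spc, ["A", "B"], ["C", "D"]).score()
        f2 = flattening_matrix(spc, ["B", "A"], ["D", "C"]).score()
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_search_finds_true_split_on_easy_data(self, rng):
        m = self._species_model()
        from gibbonmsc.simulate import simulate_dataset
        loci = simulate_dataset(m, SampleConfig({s: 1 for s in "ABCD"}), None,
                                60, rng, sites=500)
        cands = {0: Topology((("A", "B"), ("C", "D"))),
                 1: Topology((("A", "C"), ("B", "D"))),
                 2: Topology((("A", "D"), ("B", "C")))}
        key, top, totals = svd_quartets_search(loci, cands)
        assert key == 0

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            svd_quartets_search([], {0: Topology((("A", "B"), "C"))})

    def test_bad_matrix_shape_rejected(self):
        with pytest.raises(ValueError):
            svd_split_score(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            svd_split_score(np.zeros((16, 16)))


class TestDriver:
    def test_easy_regime_all_methods_agree(self, rng):
        """Long internal branches (t = 5): every estimator returns the
        true species tree."""
        theta = 0.002
        dt = 5 * theta / 2
        top = Topology(((("B", "S"), "N"), ("Hm", "Hp")))
        lengths = {frozenset({"B", "S"}): 5.0, frozenset({"B", "S", "N"}): 5.0,
                   frozenset({"Hm", "Hp"}): 5.0}
        cu = CoalUnitTree(top, lengths, stem=9.0)
        counts = sample_topology_counts(cu, 400, rng, outgroup="O")
        trees = [t for t, c in counts.items() for _ in range(c)]
        cands = candidate_trees(outgroup=True)
        key, best, *_ = astral_search(trees, cands)
        assert key == 1
        from gibbonmsc.trees import _prune
        rooted = [Topology(_prune(t.root, "O")) for t in trees]
        assert topology_id(majority_vote(rooted)) == 1
        k2, *_ = mpest_search(rooted, candidate_trees(outgroup=False))
        assert k2 == 1

    def test_run_all_summary_reports_each_method(self, gibbon_true_gene_trees, cands6):
        from gibbonmsc.summary import astral_search
        from gibbonmsc.trees import _prune
        trees = gibbon_true_gene_trees[:800]
        rooted = [Topology(_prune(t.root, "O")) for t in trees]
        res = run_all_summary(cands6, gene_trees=trees, rooted_gene_trees=rooted,
                              methods=("majority", "astral"))
        assert set(res) == {"majority", "astral"}
        # the driver must agree with calling the estimator directly
        key, top, *_ = astral_search(trees, cands6)
        assert res["astral"] == (key, top)

    def test_empty_input_rejected(self, cands6):
        with pytest.raises(ValueError):
            run_all_summary(cands6, methods=("astral",))

    def test_subsample_one_per_species(self, rng):
        aln = {"A_1": "AC", "A_2": "GT", "B": "CC"}
        out = subsample_one_per_species(aln, ["A", "B"], rng)
        assert set(out) == {"A", "B"}
        assert out["A"] in ("AC", "GT") and out["B"] == "CC"
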