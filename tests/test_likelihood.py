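"""Pruning likelihood vs exhaustive state-sum oracle, JC distances, ML
tree search, and concatenation."""

from itertools import product
from math import exp, log

import numpy as np
import pytest

from gibbonmsc.likelihood import (SitePatternCounts, concat_ml, concatenate,
                                  discrete_gamma_rates, jc_distance,
                                  jc_distance_matrix, log_likelihood,
                                  ml_gene_tree, rooted_clades_from_splits,
                                  upgma_topology)
from gibbonmsc.simulate import (GeneTree, LocusModel, NUCLEOTIDES,
                                simulate_alignment)
from gibbonmsc.trees import Topology


class TestJCDistance:
    def test_identical_is_zero(self):
        assert jc_distance("ACGT", "ACGT") == 0.0

    def test_closed_form(self):
        # build sequences with mismatch proportion exactly 0.0357 (= 50/1400)
        n, k = 1400, 50
        s1 = "A" * n
        s2 = "C" * k + "A" * (n - k)
        p = k / n
        assert jc_distance(s1, s2) == pytest.approx(-0.75 * log(1 - 4 * p / 3))
        assert jc_distance(s1, s2) == pytest.approx(0.03659, abs=5e-5)

    def test_saturation_raises(self):
        with pytest.raises(ValueError, match="saturated"):
            jc_distance("AAAA", "CCCC")

    def test_gap_sites_skipped_pairwise(self):
        assert jc_distance("AC-T", "ACNT") == 0.0

    def test_unbiased_on_simulated_data(self, rng):
        d = 0.01
        gt = GeneTree(Topology(("x", "y")), {frozenset("xy"): d / 2})
        ests = []
        for _ in range(40):
            aln = simulate_alignment(gt, LocusModel.jc(), 2000, rng)
            ests.append(jc_distance(aln["x"], aln["y"]))
        se = np.std(ests) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - d) < 4 * se


def _brute_force_loglik(top, lengths, aln, lm, ncat):
    """Exhaustive sum over internal-state assignments (oracle)."""
    rates = discrete_gamma_rates(lm.alpha, ncat)
    lam, u, uinv = lm.eigensystem()

    def pmat(t):
        return u @ np.diag(np.exp(lam * t)) @ uinv

    pi = np.asarray(lm.pi)
    code = {c: i for i, c in enumerate(NUCLEOTIDES)}
    names = sorted(aln)
    L = len(aln[names[0]])
    internals = sorted(top.internal_clades(), key=sorted)
    total = 0.0
    for site in range(L):
        obs = {n: code[aln[n][site]] for n in names}
        site_p = 0.0
        for r in rates:
            mats = {c: pmat(lengths[c] * r) for c in lengths}
            for assign in product(range(4), repeat=len(internals)):
                states = dict(zip(internals, assign))

                def state_of(clade):
                    (n,) = clade if len(clade) == 1 else (None,)
                    return obs[n] if n is not None else states[clade]

                term = pi[states[top.tips]]
                for c in internals:
                    for child in _children(top, c):
                        term *= mats[child][states[c], state_of(child)]
                site_p += term / len(rates)
        total += log(site_p)
    return total


def _children(top, clade):
    def rec(node):
        if isinstance(node, str):
            return frozenset([node]), None
        cl, _ = rec(node[0])
        cr, _ = rec(node[1])
        me = cl | cr
        if me == clade:
            found.append([cl, cr])
        return me, None

    found: list = []
    rec(top.root)
    return found[0]


class TestPruningAgainstOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_small_trees_and_models(self, seed):
        rng = np.random.default_rng(seed)
        tops = [Topology((("A", "B"), "C")), Topology(((("A", "B"), "C"), "D")),
                Topology((("A", "B"), ("C", "D")))]
        top = tops[seed % 3]
        lengths = {c: float(rng.uniform(0.01, 0.5))
                   for c in top.clades() if c != top.tips}
        pi = rng.dirichlet([10, 10, 10, 10])
        lm = LocusModel(pi=tuple(pi), exch=tuple(rng.dirichlet([5] * 6)),
                        alpha=float(rng.uniform(0.3, 5.0)))
        aln = {n: "".join(rng.choice(list("TCAG"), size=3)) for n in sorted(top.tips)}
        mine = log_likelihood(top, lengths, aln, lm, ncat=4)
        oracle = _brute_force_loglik(top, lengths, aln, lm, 4)
        assert mine == pytest.approx(oracle, abs=1e-9)

    def test_all_identical_zero_lengths_jc(self):
        top = Topology((("A", "B"), "C"))
        lengths = {c: 0.0 for c in top.clades() if c != top.tips}
        aln = {"A": "TTTT", "B": "TTTT", "C": "TTTT"}
        assert log_likelihood(top, lengths, aln) == pytest.approx(4 * log(0.25))

    def test_impossible_pattern_is_minus_inf(self):
        top = Topology((("A", "B"), "C"))
        lengths = {c: 0.0 for c in top.clades() if c != top.tips}
        aln = {"A": "T", "B": "C", "C": "T"}
        assert log_likelihood(top, lengths, aln) == -np.inf

    def test_rerooting_invariance(self, rng):
        """Reversible model: likelihood must not depend on root placement
        (pulley principle)."""
        lm = LocusModel(pi=(0.3, 0.2, 0.3, 0.2),
                        exch=(1.2, 0.8, 1.0, 0.9, 1.1, 2.0), alpha=1.0)
        aln = {"A": "TCGA", "B": "TCAA", "C": "TAGA", "D": "CAGA"}
        # same unrooted tree rooted two ways; edge lengths preserved
        t1 = Topology((("A", "B"), ("C", "D")))
        l1 = {frozenset("A"): 0.1, frozenset("B"): 0.2, frozenset("AB"): 0.15,
              frozenset("C"): 0.3, frozenset("D"): 0.25, frozenset("CD"): 0.05}
        t2 = Topology(((("C", "D"), "B"), "A"))
        l2 = {frozenset("C"): 0.3, frozenset("D"): 0.25, frozenset("CD"): 0.2,
              frozenset("B"): 0.2, frozenset("BCD"): 0.05, frozenset("A"): 0.05}
        # t1 splits root across AB-CD edge (0.15 + 0.05); t2 across the A edge
        assert log_likelihood(t1, l1, aln, lm) == pytest.approx(
            log_likelihood(t2, l2, aln, lm), abs=1e-9)

    def test_pattern_compression_and_order_invariance(self, rng):
        lm = LocusModel.jc()
        top = Topology((("A", "B"), "C"))
        lengths = {c: 0.1 for c in top.clades() if c != top.tips}
        base = {"A": "TCGATC", "B": "TCAATC", "C": "TAGATC"}
        perm = np.random.default_rng(0).permutation(6)
        shuffled = {k: "".join(v[i] for i in perm) for k, v in base.items()}
        assert log_likelihood(top, lengths, base, lm) == pytest.approx(
            log_likelihood(top, lengths, shuffled, lm))
        spc = SitePatternCounts.from_alignment(base)
        assert log_likelihood(top, lengths, spc, lm) == pytest.approx(
            log_likelihood(top, lengths, base, lm))


class TestDiscreteGamma:
    def test_category_means_average_to_one(self):
        for alpha in (0.2, 1.0, 5.0):
            r = discrete_gamma_rates(alpha, 4)
            assert r.mean() == pytest.approx(1.0, abs=1e-8)
            assert (np.diff(r) > 0).all()

    def test_infinite_alpha_single_rate(self):
        assert discrete_gamma_rates(float("inf")).tolist() == [1.0]


class TestMLGeneTree:
    def test_recovers_topology_on_informative_data(self, rng):
        truth = Topology(((("A", "B"), "C"), ("D", "E")))
        gt = GeneTree(truth, {frozenset("AB"): 0.02, frozenset("ABC"): 0.05,
                              frozenset("DE"): 0.03, frozenset("ABCDE"): 0.09})
        aln = simulate_alignment(gt, LocusModel.jc(), 5000, rng)
        mt = ml_gene_tree(aln)
        assert mt.splits == frozenset({frozenset("AB"), frozenset("DE")})

    def test_three_sequences_single_topology(self, rng):
        gt = GeneTree(Topology((("A", "B"), "C")),
                      {frozenset("AB"): 0.02, frozenset("ABC"): 0.06})
        aln = simulate_alignment(gt, LocusModel.jc(), 1000, rng)
        mt = ml_gene_tree(aln)
        assert mt.splits == frozenset()  # 3-tip unrooted tree has no internal edge
        assert mt.loglik < 0

    def test_short_branches_collapse_to_polytomy(self, rng):
        truth = Topology(((("A", "B"), "C"), ("D", "E")))
        gt = GeneTree(truth, {frozenset("AB"): 0.03, frozenset("ABC"): 0.0500001,
                              frozenset("DE"): 0.05, frozenset("ABCDE"): 0.09})
        # ABC branch has length ~1e-7 < collapse threshold of 1e-6
        aln = simulate_alignment(gt, LocusModel.jc(), 3000, rng)
        mt = ml_gene_tree(aln)
        assert frozenset("AB") in mt.splits
        # the near-zero branch must not be confidently resolved
        assert len(mt.splits) <= 2

    def test_nni_equals_exhaustive_on_small_case(self, rng):
        gt = GeneTree(Topology(((("A", "B"), "C"), ("D", "E"))),
                      {frozenset("AB"): 0.02, frozenset("ABC"): 0.04,
                       frozenset("DE"): 0.03, frozenset("ABCDE"): 0.08})
        aln = simulate_alignment(gt, LocusModel.jc(), 2000, rng)
        ex = ml_gene_tree(aln, search="exhaustive")
        nn = ml_gene_tree(aln, search="nni")
        assert nn.splits == ex.splits
        assert nn.loglik == pytest.approx(ex.loglik, abs=0.05)

    def test_rooted_clades_from_splits(self):
        tips = frozenset("ABCDO")
        splits = frozenset({frozenset("AB"), frozenset("ABC")})
        clades = rooted_clades_from_splits(tips, splits, "O")
        assert frozenset("AB") in clades and frozenset("ABC") in clades
        assert frozenset("ABCD") in clades  # the ingroup root
        with pytest.raises(ValueError):
            rooted_clades_from_splits(tips, splits, "Z")


class TestConcatenation:
    def test_concatenate_checks_names(self):
        with pytest.raises(ValueError):
            concatenate([{"A": "AC"}, {"B": "AC"}])
        sup = concatenate([{"A": "AC", "B": "GT"}, {"A": "TT", "B": "CC"}])
        assert sup == {"A": "ACTT", "B": "GTCC"}

    def test_easy_regime_true_tree_wins(self, rng):
        truth = Topology(((("A", "B"), "C"), "D"))
        gt = GeneTree(truth, {frozenset("AB"): 0.02, frozenset("ABC"): 0.05,
                              frozenset("ABCD"): 0.1})
        loci = [simulate_alignment(gt, LocusModel.jc(), 1500, rng) for _ in range(2)]
        # candidates with distinct unrooted shapes (AB|CD vs AC|BD vs AD|BC)
        cands = [truth, Topology((("A", "C"), ("B", "D"))),
                 Topology((("A", "D"), ("B", "C")))]
        ranked = concat_ml(loci, cands)
        assert ranked[0][0] == truth
        assert ranked[0][1] > ranked[1][1]

    def test_single_locus_matches_ml_gene_tree_winner(self, rng):
        gt = GeneTree(Topology(((("A", "B"), "C"), "D")),
                      {frozenset("AB"): 0.03, frozenset("ABC"): 0.06,
                       frozenset("ABCD"): 0.12})
        aln = simulate_alignment(gt, LocusModel.jc(), 3000, rng)
        mt = ml_gene_tree(aln, search="exhaustive")
        from gibbonmsc.trees import enumerate_rooted_topologies
        cands = [Topology((t.root, "D")) for t in enumerate_rooted_topologies(["A", "B", "C"])]
        cands += [Topology((("A", "B"), ("C", "D"))), Topology((("A", "C"), ("B", "D"))),
                  Topology((("A", "D"), ("B", "C")))]
        # dedupe unrooted-equivalent candidates by their split sets
        ranked = concat_ml([aln], cands)
        win_splits = frozenset(s for s in ranked[0][0].unrooted_splits())
        win_small = frozenset(min(s, key=sorted) for s in win_splits)
        assert win_small == mt.splits or mt.splits == frozenset()


class TestUPGMA:
    def test_clock_data_recovers_shape(self, rng):
        truth = Topology(((("A", "B"), "C"), "D"))
        gt = GeneTree(truth, {frozenset("AB"): 0.01, frozenset("ABC"): 0.03,
                              frozenset("ABCD"): 0.08})
        aln = simulate_alignment(gt, LocusModel.jc(), 8000, rng)
        assert upgma_topology(aln) == truth

    def test_distance_matrix_symmetry(self):
        names, d = jc_distance_matrix({"A": "ACGT", "B": "ACGA", "C": "ACTT"})
        assert (d == d.T).all() and np.diag(d).sum() == 0
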