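"""MSC gene-tree/sequence simulator: waiting times, locus-model
regimes, sequence evolution, and the isolation-with-migration variant."""

from math import exp, sqrt

import numpy as np
import pytest

from gibbonmsc.genedist import _death_chain_probs
from gibbonmsc.simulate import (CODING_REGIME, GeneTree, IMTripletParams,
                                LocusModel, NONCODING_REGIME, SampleConfig,
                                draw_locus_model, simulate_alignment,
                                simulate_dataset, simulate_gene_tree,
                                simulate_im_gene_tree, write_fasta,
                                write_phylip)
from gibbonmsc.trees import SpeciesTreeModel, Topology


def _pair_model(theta=0.002):
    top = Topology(("x", "y"))
    return SpeciesTreeModel(top, {frozenset("xy"): 0.0001},
                            {frozenset("x"): theta, frozenset("xy"): theta})


class TestCoalescentWaitingTimes:
    def test_pair_mean_is_theta_over_2(self, rng):
        theta = 0.002
        top = Topology(("x", "y"))
        m = SpeciesTreeModel(top, {frozenset("xy"): 10.0}, {frozenset("xy"): theta})
        # both tips in the root population from time ~0: sample ages
        cfg = SampleConfig({"x": 1, "y": 1})
        n = 30_000
        ages = np.empty(n)
        for i in range(n):
            gt = simulate_gene_tree(m, cfg, rng)
            ages[i] = gt.ages[frozenset("xy")] - 10.0
        se = (theta / 2) / sqrt(n)
        assert abs(ages.mean() - theta / 2) < 3.5 * se

    def test_sister_pair_coalescence_probability(self, rng):
        """Two sister species, one tip each, internal branch t coalescent
        units: P(coalesce within the branch) = 1 - e^(-t)."""
        t = 2.330
        theta = 0.002
        dtau = t * theta / 2
        top = Topology((("a", "b"), "c"))
        m = SpeciesTreeModel(
            top, {frozenset("ab"): 0.001, frozenset("abc"): 0.001 + dtau},
            {frozenset("ab"): theta, frozenset("abc"): 0.01})
        cfg = SampleConfig({"a": 1, "b": 1, "c": 1})
        n = 20_000
        hits = 0
        for _ in range(n):
            gt = simulate_gene_tree(m, cfg, rng)
            ab = frozenset("ab")
            if ab in gt.ages and gt.ages[ab] < 0.001 + dtau:
                hits += 1
        p = 1 - exp(-t)
        assert abs(hits / n - p) < 4 * sqrt(p * (1 - p) / n)
        assert p == pytest.approx(0.9027, abs=5e-4)

    def test_lineage_count_matches_death_chain(self, rng):
        """Number of surviving lineages after time t in one population
        follows the Kingman death chain (chi-square GOF)."""
        theta = 0.002
        t_cu = 0.8
        top = Topology((("a", "b"), ("c", "d")))
        tau_root = theta / 2 * t_cu  # branch spans t_cu coalescent units
        m = SpeciesTreeModel(
            top, {frozenset("ab"): 0.0, frozenset("cd"): 0.0,
                  frozenset("abcd"): tau_root},
            {p: theta for p in [frozenset("ab"), frozenset("cd"), frozenset("abcd")]})
        # trick: all four lineages thrown together at time 0 is awkward in a
        # species tree; instead count survivors of a 4-lineage tip population
        top1 = Topology(("a", "z"))
        m1 = SpeciesTreeModel(top1, {frozenset("az"): tau_root},
                              {frozenset("a"): theta, frozenset("az"): theta * 1000})
        cfg = SampleConfig({"a": 4, "z": 1})
        n = 8_000
        counts = np.zeros(4)
        for _ in range(n):
            gt = simulate_gene_tree(m1, cfg, rng)
            survivors = 4 - sum(1 for c, pop in gt.populations.items()
                                if pop == frozenset("a"))
            counts[survivors - 1] += 1
        expected = np.array(_death_chain_probs(4, t_cu)) * n
        keep = expected > 5
        chi2 = (((counts - expected) ** 2) / expected)[keep].sum()
        from scipy.stats import chi2 as chi2_dist
        assert chi2_dist.sf(chi2, keep.sum() - 1) > 1e-4

    def test_gene_tree_invariants_hold(self, gibbon_model, rng):
        cfg = SampleConfig({sp: 2 for sp in ["B", "S", "N", "Hm", "Hp"]} | {"O": 1})
        for _ in range(20):
            gt = simulate_gene_tree(gibbon_model, cfg, rng)
            gt.validate(gibbon_model)


class TestLocusModelRegimes:
    def test_dirichlet_means(self, rng):
        draws = [draw_locus_model(NONCODING_REGIME, rng) for _ in range(3000)]
        mean_pi = np.mean([m.pi for m in draws], axis=0)
        expect = np.array([44.8, 30.5, 44.8, 30.6]) / 150.7
        assert np.allclose(mean_pi, expect, atol=0.01)

    def test_mean_gamma_shape(self, rng):
        for reg, mean in [(NONCODING_REGIME, 5.0), (CODING_REGIME, 2.0)]:
            alphas = [draw_locus_model(reg, rng).alpha for _ in range(3000)]
            se = np.std(alphas) / sqrt(len(alphas))
            assert abs(np.mean(alphas) - mean) < 4 * se
            assert reg.mean_alpha() == pytest.approx(mean)

    def test_transition_transversion_ratio(self, rng):
        """D(10,5,5,5,5,10) puts twice the weight on the two transition
        exchangeabilities: the expected ratio is exactly 2."""
        conc = NONCODING_REGIME.exch_concentration
        exact = ((conc[0] + conc[5]) / 2) / (sum(conc[1:5]) / 4)
        assert exact == 2.0
        draws = [draw_locus_model(NONCODING_REGIME, rng) for _ in range(3000)]
        ts = np.mean([(m.exch[0] + m.exch[5]) / 2 for m in draws])
        tv = np.mean([sum(m.exch[1:5]) / 4 for m in draws])
        assert ts / tv == pytest.approx(2.0, abs=0.08)

    def test_rate_matrix_normalised(self, rng):
        lm = draw_locus_model(CODING_REGIME, rng)
        q = lm.rate_matrix()
        pi = np.asarray(lm.pi)
        assert pi @ q == pytest.approx(np.zeros(4), abs=1e-12)  # stationarity
        assert -(pi * np.diag(q)).sum() == pytest.approx(1.0)

    def test_jc_special_case(self):
        lm = LocusModel.jc()
        assert lm.is_jc
        q = lm.rate_matrix()
        assert np.allclose(q[~np.eye(4, dtype=bool)], 1 / 3)


class TestSequenceEvolution:
    def test_jc_p_distance(self, rng):
        d = 0.05
        gt = GeneTree(Topology(("x", "y")), {frozenset("xy"): d / 2})
        aln = simulate_alignment(gt, LocusModel.jc(), 100_000, rng)
        p = np.mean([a != b for a, b in zip(aln["x"], aln["y"])])
        expect = 0.75 * (1 - exp(-4 * d / 3))
        assert abs(p - expect) < 4 * sqrt(expect * (1 - expect) / 100_000)

    def test_zero_length_tree_identical_sequences(self, rng):
        gt = GeneTree(Topology((("x", "y"), "z")),
                      {frozenset("xy"): 0.0, frozenset("xyz"): 0.0})
        aln = simulate_alignment(gt, LocusModel.jc(), 500, rng)
        assert aln["x"] == aln["y"] == aln["z"]

    def test_gtr_stationary_composition(self, rng):
        lm = draw_locus_model(NONCODING_REGIME, rng)
        gt = GeneTree(Topology(("x", "y")), {frozenset("xy"): 0.05})
        aln = simulate_alignment(gt, lm, 50_000, rng)
        from gibbonmsc.simulate import NUCLEOTIDES
        obs = np.array([aln["x"].count(c) for c in NUCLEOTIDES]) / 50_000
        assert np.allclose(obs, lm.pi, atol=0.01)

    def test_dataset_shapes_and_truth_retained(self, gibbon_model, rng):
        cfg = SampleConfig({sp: 1 for sp in ["B", "S", "N", "Hm", "Hp", "O"]})
        loci = simulate_dataset(gibbon_model, cfg, NONCODING_REGIME, 5, rng, sites=100)
        assert len(loci) == 5
        for l in loci:
            assert set(l.alignment) == {"B", "S", "N", "Hm", "Hp", "O"}
            assert all(len(s) == 100 for s in l.alignment.values())
            l.gene_tree.validate(gibbon_model)
        assert simulate_dataset(gibbon_model, cfg, None, 0, rng) == []


class TestWriters:
    def test_phylip_and_fasta(self):
        aln = {"A": "ACGT", "B": "ACGA"}
        ph = write_phylip(aln)
        assert ph.splitlines()[0].split() == ["2", "4"]
        fa = write_fasta(aln)
        from io import StringIO
        from Bio import SeqIO
        recs = {r.id: str(r.seq) for r in SeqIO.parse(StringIO(fa), "fasta")}
        assert recs == aln


class TestIsolationWithMigration:
    def test_reduces_to_msc_without_migration(self, rng):
        """At M = 0 the ABC-configuration topology frequencies match the
        3-taxon MSC formula."""
        p = IMTripletParams(0.02, 0.01, 0.005, 0.004, 0.002, 0.002)
        t_cu = 2 * (p.tau_abc - p.tau_ab) / p.theta_ab
        expect_mismatch = exp(-t_cu) / 3
        n = 8_000
        mism = 0
        for _ in range(n):
            gt = simulate_im_gene_tree(p, "ABC", rng)
            if not gt.topology.has_clade({"a", "b"}):
                mism += 1
        p_hat = mism / n / 2  # two mismatch topologies
        se = sqrt(expect_mismatch * (1 - expect_mismatch) / n)
        assert abs(p_hat - expect_mismatch) < 4 * se

    def test_no_coalescence_before_divergence_without_migration(self, rng):
        p = IMTripletParams(0.02, 0.01, 0.005, 0.004, 0.002, 0.002)
        for _ in range(300):
            gt = simulate_im_gene_tree(p, "ABC", rng)
            gt.validate()
            ab = frozenset("ab")
            if ab in gt.ages:
                assert gt.ages[ab] >= p.tau_ab

    def test_strong_migration_approaches_panmixia(self, rng):
        """With huge symmetric migration and theta_A = theta_B the two
        demes behave as one: pair coalescence rate halves (mean time
        ~theta instead of theta/2)."""
        theta = 0.001
        p = IMTripletParams(0.5, 0.4, 0.005, 0.004, theta, theta,
                            m_ab=50.0, m_ba=50.0)
        n = 4_000
        times = []
        for _ in range(n):
            gt = simulate_im_gene_tree(p, "ABC", rng)
            ab = frozenset("ab")
            if ab in gt.ages and gt.ages[ab] < p.tau_ab:
                times.append(gt.ages[ab])
        mean = np.mean(times)
        se = np.std(times) / sqrt(len(times))
        assert abs(mean - theta) < 4 * se + 0.05 * theta

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            IMTripletParams(0.01, 0.02, 0.005, 0.004, 0.002, 0.002)
        with pytest.raises(ValueError):
            IMTripletParams(0.02, 0.01, 0.005, 0.004, 0.002, 0.002, m_ab=-1)
        p = IMTripletParams(0.02, 0.01, 0.005, 0.004, 0.002, 0.002)
        with pytest.raises(ValueError):
            simulate_im_gene_tree(p, "XYZ", np.random.default_rng(0))
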