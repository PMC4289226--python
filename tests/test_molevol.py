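"""Molecular evolution: orthologs, codon alignment, dN/dS, null-distribution
outliers, NJ trees, site models and LRTs."""

import numpy as np
import pytest
import dendropy

from venomforge import molevol, seqsim
from venomforge.molevol import (
    codon_align,
    fit_site_model,
    lrt_pvalue,
    ng86_counts,
    ng86_rates,
    nj_tree,
    pairwise_loglik,
    pairwise_rates,
    rate_outlier_analysis,
    rbh_orthologs,
    wilcoxon_rank_sum,
)
from venomforge.codons import SENSE_CODONS

from oracles import ng86_counts_oracle, wilcoxon_two_sided_oracle


def _random_cds(rng, n_codons):
    body = "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, n_codons - 2))
    return "ATG" + body + "TAA"


class TestRbhOrthologs:
    def test_identical_proteomes_pair_every_protein(self, rng):
        prots = {
            f"p{i}": "".join(
                "ACDEFGHIKLMNPQRSTVWY"[j] for j in rng.integers(0, 20, 120)
            )
            for i in range(6)
        }
        pairs = rbh_orthologs(prots, dict(prots))
        assert pairs == sorted((k, k) for k in prots)

    def test_truth_orthologs_recovered_without_false_pairs(self, small_truth, small_config):
        sp_a, sp_b = small_config.species
        prot_a = {
            t.id: t.mature_protein() for t in small_truth.transcripts[sp_a]
        }
        prot_b = {
            t.id: t.mature_protein() for t in small_truth.transcripts[sp_b]
        }
        pairs = rbh_orthologs(prot_a, prot_b)
        true_pairs = set(small_truth.ortholog_map)
        found = set(pairs)
        by_a = small_truth.by_id(sp_a)
        # no pair across different gene families
        for a, b in found:
            ta, tb = by_a[a], small_truth.by_id(sp_b)[b]
            assert ta.class_label == tb.class_label
        recovered = len(true_pairs & found) / len(true_pairs)
        assert recovered >= 0.95

    def test_empty_input_gives_empty_output(self):
        assert rbh_orthologs({}, {"a": "MKT"}) == []

    def test_excluded_entries_never_pair(self, rng):
        prots = {
            "keep": "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ" * 3,
            "mito": "MLTVAARLLPLLPLLLLLLPPRGAQG" * 3,
        }
        pairs = rbh_orthologs(prots, dict(prots), exclude={"mito"})
        assert pairs == [("keep", "keep")]


class TestCodonAlign:
    def test_identical_cds_align_without_gaps(self, rng):
        cds = _random_cds(rng, 80)
        pair = codon_align(cds, cds)
        assert pair.gapped_positions == 0
        assert pair.cds_a == pair.cds_b

    def test_gap_threshold_boundary(self, rng):
        cds = _random_cds(rng, 120)
        # remove 9 internal codons -> 27 gapped positions -> excluded
        del9 = cds[:60] + cds[87:]
        assert codon_align(cds, del9) is None
        # remove 8 internal codons -> 24 gapped positions -> retained
        del8 = cds[:60] + cds[84:]
        pair = codon_align(cds, del8)
        assert pair is not None
        assert pair.gapped_positions == 24
        # gapped codon columns removed before analysis
        assert len(pair.cds_a) == len(pair.cds_b) == len(del8) - 3

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError):
            codon_align("ATGAA", "ATGAAATAA")


class TestNG86:
    def test_counts_match_bruteforce_oracle_on_random_pairs(self, rng):
        for _ in range(25):
            a = _random_cds(rng, 40)
            b, _, _ = seqsim.evolve_codon_sequences(a, 1.0, 2.0, 0.4, int(rng.integers(1e6)))
            assert ng86_counts(a, b) == pytest.approx(ng86_counts_oracle(a, b))

    def test_identical_sequences_have_zero_rates(self, rng):
        cds = _random_cds(rng, 60)
        r = ng86_rates(cds, cds)
        assert r.dn == 0.0 and r.ds == 0.0 and r.omega is None

    def test_two_codon_synonymous_difference(self):
        # TTT|TTA vs TTT|TTG: the third-position A<->G change is synonymous
        # by every pathway, so Nd = 0 and dN = 0; with S = 1 site the
        # synonymous proportion is 1 and the JC correction is undefined
        S, N, Sd, Nd = ng86_counts("TTTTTA", "TTTTTG")
        assert (S, N, Sd, Nd) == pytest.approx(
            ng86_counts_oracle("TTTTTA", "TTTTTG")
        )
        assert Nd == 0.0 and Sd == 1.0
        assert S == pytest.approx(1.0)
        r = ng86_rates("TTTTTA", "TTTTTG")
        assert r.dn == 0.0
        assert r.ds is None and "0.75" in r.reason

    def test_saturated_sequences_reported_undefined(self):
        r = ng86_rates("ATGAAA", "ATGTTT")  # wildly diverged tiny pair
        assert r.omega is None

    def test_ml_omega_recovery_from_simulation(self, rng):
        anc = _random_cds(rng, 5000)
        d1, d2, _ = seqsim.evolve_codon_sequences(anc, 0.25, 2.0, 0.3, 97)
        pair = codon_align(d1, d2)
        uniform_pi = np.full(61, 1 / 61)
        r = pairwise_rates(pair, method="ML", pi=uniform_pi)
        assert r.omega == pytest.approx(0.25, abs=0.05)


class TestWilcoxon:
    def test_textbook_exact_value(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_samples_give_p_one(self):
        assert wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_too_small_samples_undefined(self):
        assert wilcoxon_rank_sum([1.0], [2.0, 3.0]) is None

    @pytest.mark.parametrize("n,m", [(2, 2), (3, 5), (4, 4), (5, 8), (8, 8)])
    def test_matches_full_enumeration(self, n, m, rng):
        x = rng.normal(0, 1, n)
        y = rng.normal(0.8, 1, m)
        assert wilcoxon_rank_sum(x, y) == pytest.approx(
            wilcoxon_two_sided_oracle(list(x), list(y))
        )


class TestRateOutliers:
    def _rates(self, dns, dss):
        return [
            molevol.PairwiseRates(
                dn=dn, ds=ds, omega=(dn / ds if ds else None), method="counting"
            )
            for dn, ds in zip(dns, dss)
        ]

    def test_null_drawn_toxins_exceed_at_five_percent(self, rng):
        null_dn = rng.gamma(2.0, 0.01, 2000)
        null_ds = rng.gamma(2.0, 0.05, 2000)
        nontoxins = self._rates(null_dn[:1000], null_ds[:1000])
        toxins = self._rates(null_dn[1000:], null_ds[1000:])
        summary = rate_outlier_analysis(toxins, nontoxins)
        for stat in ("dN", "dS", "omega"):
            n = summary.n_toxin[stat]
            k = summary.toxin_exceed_counts[stat]
            sd = np.sqrt(n * 0.05 * 0.95)
            assert abs(k - 0.05 * n) < 3 * sd

    def test_shifted_toxins_detected(self, rng):
        nontoxins = self._rates(
            rng.gamma(2.0, 0.01, 200), rng.gamma(2.0, 0.05, 200)
        )
        toxins = self._rates(
            rng.gamma(2.0, 0.05, 11), rng.gamma(2.0, 0.05, 11)
        )
        summary = rate_outlier_analysis(toxins, nontoxins)
        assert summary.wilcoxon_p["dN"] < 0.01
        assert summary.toxin_exceed_counts["dN"] >= 8

    def test_empty_nontoxins_rejected(self):
        with pytest.raises(ValueError):
            rate_outlier_analysis([], [])


class TestNJTree:
    def test_fewer_than_three_sequences_rejected(self):
        with pytest.raises(ValueError):
            nj_tree({"a": "ACGT", "b": "ACGT"})

    def test_identical_sequences_give_zero_branch_lengths(self, rng):
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 300))
        newick = nj_tree({"a": seq, "b": seq, "c": seq})
        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert all((e.length or 0.0) == 0.0 for e in tree.edges())

    def test_topology_recovered_from_simulation(self, rng):
        tree_s = "((a:0.05,b:0.05):0.15,(c:0.05,d:0.05):0.15);"
        tree = dendropy.Tree.get(data=tree_s, schema="newick")
        aln = seqsim.simulate_codon_alignment(tree, 400, 1.0, 2.0, 13)
        newick = nj_tree(aln)
        out = dendropy.Tree.get(data=newick, schema="newick")
        splits = {
            frozenset(l.taxon.label for l in n.leaf_iter())
            for n in out.preorder_node_iter()
            if not n.is_leaf()
        }
        assert frozenset({"a", "b"}) in splits or frozenset({"c", "d"}) in splits


TREE4 = "((a:0.15,b:0.15):0.08,(c:0.15,d:0.15):0.08);"


@pytest.fixture(scope="module")
def aln4():
    tree = dendropy.Tree.get(data=TREE4, schema="newick")
    return seqsim.simulate_codon_alignment(tree, 200, 0.4, 2.0, 21)


class TestSiteModels:
    tree4 = TREE4

    def test_m2a_with_empty_selection_class_reduces_to_m1a(self, aln4):
        m1a = fit_site_model(aln4, self.tree4, "M1a")
        m2a_null = fit_site_model(
            aln4, self.tree4, "M2a", fixed={"f1": 1.0}
        )  # p2 = 0
        assert m2a_null.lnl == pytest.approx(m1a.lnl, abs=1e-3)

    def test_nested_models_never_fit_worse(self, aln4):
        m0 = fit_site_model(aln4, self.tree4, "M0")
        m1a = fit_site_model(aln4, self.tree4, "M1a")
        m2a = fit_site_model(aln4, self.tree4, "M2a")
        m7 = fit_site_model(aln4, self.tree4, "M7")
        m8 = fit_site_model(aln4, self.tree4, "M8")
        assert m2a.lnl >= m1a.lnl - 1e-4
        assert m8.lnl >= m7.lnl - 1e-4
        assert m2a.lnl >= m0.lnl - 1e-4
        for fit in (m1a, m2a, m7, m8):
            assert sum(fit.p) == pytest.approx(1.0, abs=1e-9)

    def test_two_sequence_m0_equals_pairwise_likelihood(self, rng):
        anc = _random_cds(rng, 150)
        a, b, _ = seqsim.evolve_codon_sequences(anc, 0.5, 2.0, 0.3, 31)
        pair = codon_align(a, b)
        aln = {"x": pair.cds_a, "y": pair.cds_b}
        tree = "(x:0.15,y:0.15);"
        fit = fit_site_model(aln, tree, "M0")
        direct = pairwise_loglik(
            pair.cds_a,
            pair.cds_b,
            t=0.3 * fit.tree_scale,
            kappa=fit.kappa,
            omega=fit.w[0],
            pi=fit.codon_freqs,
        )
        assert fit.lnl == pytest.approx(direct, abs=1e-6)


class TestLRT:
    def test_equal_likelihoods_give_p_one(self):
        assert lrt_pvalue(100.0, 100.0).p == 1.0

    def test_negative_statistic_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            res = lrt_pvalue(100.0, 101.0)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_df2_tail_is_exponential(self):
        res = lrt_pvalue(50.0, 40.0, df=2)
        assert res.p == pytest.approx(np.exp(-10.0))
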