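import numpy as np
import pytest

from delscan import codons
from delscan.formats_io import CodonAlignment, Phylogeny
from delscan.lrt import (
    CodonModelParams,
    GeneLRT,
    SiteTestResult,
    allele_novelty,
    bonferroni_threshold,
    build_rate_matrix,
    call_deleterious,
    f3x4_frequencies,
    fit_gene_model,
    site_log_likelihood,
)
from delscan.lrt import test_site as run_site_test
from delscan.simulate import (
    SimulationSpec,
    random_tree,
    simulate_alignment,
    uniform_pi,
)

from .oracles import enumerate_loglik


def random_params(rng, rho=None):
    pi = rng.dirichlet(np.ones(codons.N_STATES))
    return CodonModelParams(
        kappa=float(rng.uniform(0.5, 5.0)),
        omega_g=1.0,
        rho=float(rng.uniform(0.2, 2.0)) if rho is None else rho,
        pi=pi,
    )


class TestRateMatrix:
    def test_omega_zero_kills_nonsynonymous(self, uniform_params):
        q = build_rate_matrix(uniform_params, 0.0)
        assert np.all(q[codons.IS_NONSYN] == 0.0)

    def test_rows_sum_to_zero(self, uniform_params):
        q = build_rate_matrix(uniform_params, 0.7)
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)

    def test_uniform_neutral_rates_equal_over_neighbors(self):
        params = CodonModelParams(1.0, 1.0, 1.0, uniform_pi())
        q = build_rate_matrix(params, 1.0)
        off = q[codons.NEIGHBOR]
        assert np.allclose(off, off[0])
        assert np.all(q[~codons.NEIGHBOR & ~np.eye(61, dtype=bool)] == 0.0)

    def test_neutral_mean_rate_is_one(self, rng):
        params = random_params(rng)
        q = build_rate_matrix(params, 1.0)
        assert -float(params.pi @ np.diag(q)) == pytest.approx(1.0)

    def test_detailed_balance(self, rng):
        for _ in range(5):
            params = random_params(rng)
            q = build_rate_matrix(params, float(rng.uniform(0.05, 3.0)))
            flux = params.pi[:, None] * q
            assert np.allclose(flux, flux.T, atol=1e-14)


class TestSiteLikelihood:
    def test_single_taxon_is_log_pi(self, small_tree, uniform_params):
        taxa = small_tree.tip_labels
        seqs = ["ATG" for _ in taxa]
        aln = CodonAlignment(taxa, seqs, taxa[0])
        exclude = frozenset(taxa[1:])
        lnl = site_log_likelihood(aln, small_tree, uniform_params, 1.0, 0, exclude)
        state = codons.CODON_STATE["ATG"]
        assert lnl == pytest.approx(np.log(uniform_params.pi[state]))

    def test_zero_length_identical_is_log_pi(self, uniform_params):
        tree = Phylogeny.from_newick("(A:0.0,B:0.0);")
        aln = CodonAlignment(["A", "B"], ["ATG", "ATG"], "A")
        lnl = site_log_likelihood(aln, tree, uniform_params, 1.0, 0)
        assert lnl == pytest.approx(np.log(uniform_params.pi[codons.CODON_STATE["ATG"]]))

    def test_zero_length_differing_hits_floor(self, uniform_params):
        tree = Phylogeny.from_newick("(A:0.0,B:0.0);")
        aln = CodonAlignment(["A", "B"], ["ATG", "GTG"], "A")
        lnl = site_log_likelihood(aln, tree, uniform_params, 1.0, 0)
        assert lnl < -700

    def test_all_missing_rejected(self, uniform_params):
        tree = Phylogeny.from_newick("(A:0.1,B:0.1);")
        aln = CodonAlignment(["A", "B"], ["ATG", "ATG"], "A")
        with pytest.raises(ValueError, match="missing"):
            site_log_likelihood(
                aln, tree, uniform_params, 1.0, 0, exclude={"A", "B"}
            )

    def test_matches_enumeration_oracle(self, rng):
        """Pruning equals explicit internal-state enumeration (small trees)."""
        for _ in range(5):
            n_taxa = int(rng.integers(2, 5))
            tree = random_tree(
                n_taxa, float(rng.uniform(0.3, 2.0)), seed=int(rng.integers(2**31))
            )
            params = random_params(rng)
            omega = float(rng.uniform(0.05, 3.0))
            spec = SimulationSpec(
                tree=tree,
                kappa=params.kappa,
                site_omega=[omega, omega],
                seed=int(rng.integers(2**31)),
                pi=params.pi,
            )
            aln = simulate_alignment(spec)
            for col in range(2):
                fast = site_log_likelihood(aln, tree, params, omega, col)
                slow = enumerate_loglik(aln, tree, params, omega, col)
                assert fast == pytest.approx(slow, abs=1e-9)


class TestGeneFit:
    def test_two_taxon_alignment_rejected(self):
        tree = Phylogeny.from_newick("(A:0.1,B:0.1);")
        aln = CodonAlignment(["A", "B"], ["ATGGGTCATTGTACTGCA"] * 2, "A")
        with pytest.raises(ValueError, match="taxa"):
            fit_gene_model(aln, tree)

    def test_identical_sequences_give_rho_at_floor(self, small_tree):
        seq = "ATGGGTCATTGTACTGCAGGATTACCA" + "GCT" * 3
        aln = CodonAlignment(
            small_tree.tip_labels, [seq] * 5, small_tree.tip_labels[0]
        )
        params = fit_gene_model(aln, small_tree)
        assert params.rho < 1e-4

    def test_parameter_recovery_single_replicate(self, big_tree):
        spec = SimulationSpec(
            tree=big_tree, kappa=2.0, site_omega=np.full(400, 0.5), seed=81
        )
        aln = simulate_alignment(spec)
        params = fit_gene_model(aln, big_tree)
        assert params.converged
        assert 1.6 <= params.kappa <= 2.4
        assert 0.4 <= params.omega_g <= 0.6

    def test_f3x4_sums_to_one(self, big_tree):
        spec = SimulationSpec(
            tree=big_tree, kappa=2.0, site_omega=np.ones(50), seed=3
        )
        aln = simulate_alignment(spec)
        pi = f3x4_frequencies(aln, frozenset({aln.query_taxon}))
        assert pi.sum() == pytest.approx(1.0)
        assert np.all(pi > 0)


class TestSiteTest:
    def test_zero_branch_tree_gives_null(self, uniform_params):
        tree = Phylogeny.from_newick(
            "(" + ",".join(f"t{i}:0.0" for i in range(12)) + ");"
        )
        aln = CodonAlignment(
            [f"t{i}" for i in range(12)], ["ATGGGT"] * 12, "t0"
        )
        res = run_site_test(aln, tree, uniform_params, 0)
        assert res.statistic == pytest.approx(0.0, abs=1e-8)
        assert res.p_value == pytest.approx(1.0)

    def test_conserved_codon_is_constrained(self, uniform_params):
        tree = random_tree(20, 5.0, seed=5)
        taxa = tree.tip_labels
        aln = CodonAlignment(taxa, ["ATGGGT"] * len(taxa), taxa[0])
        res = run_site_test(aln, tree, uniform_params, 0)
        assert res.omega_site <= 2e-4  # at the lower bound
        assert res.statistic > 0

    def test_nine_species_untested(self, uniform_params):
        tree = random_tree(10, 2.0, seed=6)
        taxa = tree.tip_labels
        seqs = ["ATGGGT"] * 10
        aln = CodonAlignment(taxa, seqs, taxa[0])
        # 9 informative non-query species -> below the 10-species minimum
        assert aln.n_informative(0) == 9
        res = run_site_test(aln, tree, uniform_params, 0)
        assert res.verdict == "untested"

    def test_nesting_lnl1_ge_lnl0(self, big_tree, uniform_params):
        spec = SimulationSpec(
            tree=big_tree, kappa=2.0, site_omega=np.ones(30), seed=12
        )
        aln = simulate_alignment(spec)
        runner = GeneLRT(aln, big_tree, params=uniform_params)
        for res in runner.test_all():
            assert res.lnl1 >= res.lnl0 - 1e-9
            assert res.statistic >= 0
            assert 0 <= res.p_value <= 1

    def test_batched_equals_per_site(self, big_tree, uniform_params):
        spec = SimulationSpec(
            tree=big_tree, kappa=2.0, site_omega=np.ones(10), seed=13
        )
        aln = simulate_alignment(spec)
        runner = GeneLRT(aln, big_tree, params=uniform_params)
        batched = runner.test_all()
        for res in batched:
            single = runner.test(res.codon_index)
            assert res.statistic == pytest.approx(single.statistic, abs=1e-6)
            assert res.p_value == pytest.approx(single.p_value, abs=1e-8)

    def test_masking_ignores_query_data(self, big_tree, uniform_params):
        """A divergent query sequence must not change masked results."""
        spec = SimulationSpec(
            tree=big_tree, kappa=2.0, site_omega=np.ones(5), seed=14
        )
        aln = simulate_alignment(spec)
        qi = aln.query_index
        mutated_seqs = list(aln.aligned_seqs)
        mutated_seqs[qi] = "AAT" * aln.n_codons
        aln2 = CodonAlignment(aln.taxa, mutated_seqs, aln.query_taxon)
        r1 = run_site_test(aln, big_tree, uniform_params, 0)
        r2 = run_site_test(aln2, big_tree, uniform_params, 0)
        assert r1.lnl0 == pytest.approx(r2.lnl0, abs=1e-9)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-6)
        # unmasked likelihoods do differ: masking is load-bearing
        l1 = site_log_likelihood(aln, big_tree, uniform_params, 1.0, 0)
        l2 = site_log_likelihood(aln2, big_tree, uniform_params, 1.0, 0)
        assert abs(l1 - l2) > 1e-6


class TestCallRules:
    def test_novelty_examples(self, small_tree):
        taxa = ["q", "a", "b", "c"]
        aln = CodonAlignment(taxa, ["ATG", "ATG", "ATG", "GTG"], "q")
        # non-query first-column states {A, A, G}
        assert allele_novelty(aln, 0, "A", "C") is True
        aln2 = CodonAlignment(taxa, ["ATG", "ATG", "CTG", "CTG"], "q")
        assert allele_novelty(aln2, 0, "A", "C") is False

    def test_novelty_vacuous_when_no_outgroup_data(self):
        aln = CodonAlignment(["q", "a"], ["ATG", "---"], "q")
        assert allele_novelty(aln, 0, "A", "C") is True

    def test_novelty_column_bounds(self):
        aln = CodonAlignment(["q", "a"], ["ATG", "ATG"], "q")
        with pytest.raises(IndexError):
            allele_novelty(aln, 3, "A", "C")

    def test_bonferroni_printed_thresholds(self):
        assert bonferroni_threshold(0.05, 59277) == pytest.approx(8.4e-7, rel=0.01)
        assert bonferroni_threshold(0.05, 64087) == pytest.approx(7.8e-7, rel=0.01)
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_bonferroni_rejects_bad_input(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)

    @pytest.mark.parametrize(
        "p,novel,omega,expected",
        [
            (1e-8, True, 0.01, "deleterious"),
            (1e-8, False, 0.01, "tolerated"),
            (0.01, True, 0.01, "tolerated"),
            (1e-8, True, 1.5, "tolerated"),
        ],
    )
    def test_call_rule(self, p, novel, omega, expected):
        res = SiteTestResult(
            codon_index=0,
            n_species_informative=15,
            p_value=p,
            novel=novel,
            omega_site=omega,
            verdict="tolerated",
        )
        assert call_deleterious(res, 8.4e-7) == expected

    def test_untested_passthrough(self):
        res = SiteTestResult(codon_index=0, n_species_informative=5)
        assert call_deleterious(res, 1e-6) == "untested"
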