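import numpy as np
import pytest
from scipy.stats import chi2_contingency

from sorensen_equiv import (
    JointEnrichmentProbs,
    SimulationScenario,
    UndefinedSorensenError,
    build_table,
    expand_grid,
    generate_table,
    generate_table_twostage,
    profile_from_lists,
    run_grid,
    run_scenario,
    synth_gene_lists,
)


class TestGenerators:
    def test_degenerate_law(self):
        p = JointEnrichmentProbs(0.0, 0.0, 0.0, 1.0)
        t = generate_table(50, p, np.random.default_rng(0))
        assert (t.n11, t.n10, t.n01, t.n00) == (0, 0, 0, 50)

    def test_mean_cell_count(self, rng):
        p = JointEnrichmentProbs(0.0125, 0.005, 0.005)
        n11 = [generate_table(1000, p, rng).n11 for _ in range(10_000)]
        se = np.sqrt(1000 * 0.0125 * (1 - 0.0125) / 10_000)
        assert abs(np.mean(n11) - 12.5) < 3 * se

    def test_deterministic_under_seed(self):
        p = JointEnrichmentProbs(0.2, 0.1, 0.1)
        t1 = generate_table(100, p, np.random.default_rng(5))
        t2 = generate_table(100, p, np.random.default_rng(5))
        assert t1 == t2
        t3 = generate_table_twostage(100, p, np.random.default_rng(5))
        t4 = generate_table_twostage(100, p, np.random.default_rng(5))
        assert t3 == t4

    def test_twostage_saturated_enrichment(self):
        p = JointEnrichmentProbs(0.5, 0.25, 0.25, 0.0)
        t = generate_table_twostage(40, p, np.random.default_rng(1))
        assert t.n00 == 0

    def test_generators_distributionally_identical(self, rng):
        """Two-sample chi-square over the drawn tables (as categories,
        pooling rare ones) does not separate the two schemes."""
        n, p = 50, JointEnrichmentProbs(0.2, 0.1, 0.1)
        draws_a, draws_b = {}, {}
        for _ in range(10_000):
            ta = generate_table(n, p, rng)
            tb = generate_table_twostage(n, p, rng)
            key_a = (ta.n11, ta.n01, ta.n10)
            key_b = (tb.n11, tb.n01, tb.n10)
            draws_a[key_a] = draws_a.get(key_a, 0) + 1
            draws_b[key_b] = draws_b.get(key_b, 0) + 1
        keys = sorted(set(draws_a) | set(draws_b))
        a = np.array([draws_a.get(k, 0) for k in keys])
        b = np.array([draws_b.get(k, 0) for k in keys])
        # pool categories until every expected count is >= 5
        order = np.argsort(-(a + b))
        a, b = a[order], b[order]
        pooled_a, pooled_b = [], []
        acc_a = acc_b = 0
        for x, y in zip(a, b):
            acc_a += x
            acc_b += y
            if acc_a + acc_b >= 20:
                pooled_a.append(acc_a)
                pooled_b.append(acc_b)
                acc_a = acc_b = 0
        if acc_a + acc_b:
            pooled_a[-1] += acc_a
            pooled_b[-1] += acc_b
        _, p_value, _, _ = chi2_contingency([pooled_a, pooled_b])
        assert p_value > 0.01


class TestRunScenario:
    def test_power_regime(self):
        from sorensen_equiv import p11_for_target

        p11 = p11_for_target(0.1, 0.05, 0.05)
        sc = SimulationScenario(
            n=5000, p=JointEnrichmentProbs(p11, 0.05, 0.05), d0=0.4444,
            n_sim=2000, seed=101,
        )
        res = run_scenario(sc)
        assert res.rejection_rate > 0.95

    def test_alpha_zero_never_rejects(self):
        sc = SimulationScenario(
            n=1000, p=JointEnrichmentProbs(0.125, 0.05, 0.05), d0=0.5,
            alpha=0.0, n_sim=500, seed=7,
        )
        assert run_scenario(sc).rejection_rate == 0.0

    def test_effective_replicates_below_request_when_sparse(self):
        sc = SimulationScenario(
            n=200, p=JointEnrichmentProbs(0.005, 0.002, 0.002), d0=0.5,
            n_sim=2000, seed=3,
        )
        res = run_scenario(sc)
        assert res.n_sim_effective < 2000

    def test_coverage_near_nominal_high_enrichment(self):
        sc = SimulationScenario(
            n=10_000, p=JointEnrichmentProbs(0.5, 0.2, 0.2), d0=2.0 / 7.0,
            n_sim=20_000, seed=11,
        )
        res = run_scenario(sc)
        se = np.sqrt(0.95 * 0.05 / res.n_sim_effective)
        assert abs(res.coverage - 0.95) < 3 * se

    def test_bootstrap_scenario_runs(self):
        sc = SimulationScenario(
            n=1000, p=JointEnrichmentProbs(0.125, 0.05, 0.05), d0=2.0 / 7.0,
            n_sim=100, method="bootstrap", B=200, seed=13,
        )
        res = run_scenario(sc)
        assert 0.0 <= res.rejection_rate <= 1.0
        assert res.n_sim_effective == 100


class TestRunGrid:
    def test_reference_d0_levels_expand(self):
        scenarios = expand_grid(
            d0_values=[0.2857, 0.3103, 0.4444, 0.4737],
            n_values=[1000],
            discordant_pairs=[(0.05, 0.05)],
            n_sim=10,
        )
        assert sorted({sc.d0 for sc in scenarios}) == [0.2857, 0.3103, 0.4444, 0.4737]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            run_grid([])

    def test_deterministic_under_master_seed(self):
        scenarios = expand_grid(
            d0_values=[0.4444], n_values=[500],
            discordant_pairs=[(0.05, 0.05), (0.1, 0.1)], n_sim=2000,
        )
        f1 = run_grid(scenarios, master_seed=99)
        f2 = run_grid(scenarios, master_seed=99)
        assert f1.equals(f2)

    def test_failed_scenario_recorded_not_fatal(self):
        good = SimulationScenario(
            n=100, p=JointEnrichmentProbs(0.2, 0.1, 0.1), d0=0.5, n_sim=50
        )
        bad = SimulationScenario(
            n=100, p=JointEnrichmentProbs(0.0, 0.0, 0.0, 1.0), d0=0.5, n_sim=50
        )
        frame = run_grid([good, bad], master_seed=1)
        assert frame.loc[0, "error"] == ""
        assert frame.loc[1, "error"] != ""
        assert np.isnan(frame.loc[1, "rejection_rate"])


class TestSynthGeneLists:
    def test_planted_pattern_recovered(self):
        lists, coll, universe, truth = synth_gene_lists(
            n_genes=2000, n_terms=20, planted=(5, 2, 2), effect_strength=0.75,
            seed=31,
        )
        profile = profile_from_lists(lists, universe, coll)
        table = build_table(profile, "list_1", "list_2")
        assert (table.n11, table.n10, table.n01) == (5, 2, 2)

    def test_recovery_rate_across_seeds(self):
        hits = 0
        for seed in range(40):
            lists, coll, universe, truth = synth_gene_lists(
                n_genes=2000, n_terms=15, planted=(5, 2, 2),
                effect_strength=0.75, seed=seed,
            )
            profile = profile_from_lists(lists, universe, coll)
            t = build_table(profile, "list_1", "list_2")
            hits += (t.n11, t.n10, t.n01) == (5, 2, 2)
        assert hits >= 38  # >= 95% of seeds

    def test_no_planting_gives_all_zero_profile(self):
        lists, coll, universe, _ = synth_gene_lists(
            n_genes=1000, n_terms=8, planted=(0, 0, 0), seed=5
        )
        profile = profile_from_lists(lists, universe, coll)
        table = build_table(profile, "list_1", "list_2")
        from sorensen_equiv import equivalence_test_normal

        with pytest.raises(UndefinedSorensenError):
            equivalence_test_normal(table, d0=0.5, alpha=0.05)

    def test_deterministic_under_seed(self):
        a = synth_gene_lists(500, 6, (2, 1, 1), seed=77)
        b = synth_gene_lists(500, 6, (2, 1, 1), seed=77)
        assert a[0] == b[0] and a[1].sets == b[1].sets

    def test_infeasible_planting_rejected(self):
        with pytest.raises(ValueError):
            synth_gene_lists(100, 10, (6, 6, 6))
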