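import numpy as np
import pytest

from owlserr import (
    MCSettings,
    build_comparison_scheme,
    default_parameter_table,
    exact_mann_whitney,
    mc_comparison,
    run_all_comparisons,
    significance_band,
)


class TestExactMannWhitney:
    def test_complete_separation(self):
        assert exact_mann_whitney([1, 2, 3, 4, 5], [6, 7, 8, 9, 10]) == pytest.approx(2 / 252)

    def test_identical_samples_give_p_one(self):
        assert exact_mann_whitney([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]) == 1.0

    def test_single_crossover_matches_oracle(self, mw_oracle):
        a, b = [1, 2, 3, 4, 10], [5, 6, 7, 8, 9]
        assert exact_mann_whitney(a, b) == mw_oracle(a, b)

    def test_agrees_with_enumeration_oracle_on_random_samples(self, mw_oracle):
        """Exact equality with an independent brute-force enumeration on 500
        random 5-vs-5 samples, including ties from rounded values."""
        rng = np.random.default_rng(42)
        for i in range(500):
            if i % 2:
                a = np.round(rng.normal(0, 2, 5), 0)  # coarse rounding forces ties
                b = np.round(rng.normal(1, 2, 5), 0)
            else:
                a = rng.normal(0, 1, 5)
                b = rng.normal(0.8, 1, 5)
            assert exact_mann_whitney(a, b) == mw_oracle(a, b)

    def test_unequal_and_larger_sample_sizes_stay_exact(self, mw_oracle):
        rng = np.random.default_rng(3)
        for n_a, n_b in [(3, 5), (4, 4), (6, 7), (2, 9)]:
            a, b = rng.normal(0, 1, n_a), rng.normal(0.5, 1, n_b)
            assert exact_mann_whitney(a, b) == mw_oracle(a, b)

    def test_invariant_under_monotone_transformation(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            a, b = rng.normal(0, 1, 5), rng.normal(1, 1, 5)
            p = exact_mann_whitney(a, b)
            assert exact_mann_whitney(np.exp(a), np.exp(b)) == p
            assert exact_mann_whitney(a**3, b**3) == p

    def test_non_finite_values_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            exact_mann_whitney([1, 2, 3, 4, np.nan], [5, 6, 7, 8, 9])

    def test_oversized_samples_rejected(self):
        with pytest.raises(ValueError, match="exact test supports"):
            exact_mann_whitney(list(range(11)), [1, 2, 3])


class TestSignificanceBand:
    @pytest.mark.parametrize(
        "fraction,band",
        [
            (0.995, "***"),
            (0.97, "**"),
            (0.80, "*"),
            (0.50, "ns"),
            # band edges fall in the lower band ("more than" read strictly)
            (0.99, "**"),
            (0.95, "*"),
            (0.67, "ns"),
            (0.0, "ns"),
            (1.0, "***"),
        ],
    )
    def test_banding(self, fraction, band):
        assert significance_band(fraction) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            significance_band(1.2)


class TestMCComparison:
    def test_equal_constant_groups_never_significant(self):
        g = np.full((5, 5), 3.0)
        r = mc_comparison(g, g, MCSettings(n_runs=500, seed=1))
        assert r.fraction_significant == 0.0
        assert r.band == "ns"

    def test_fully_separated_groups_always_significant(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 1, size=(5, 5))
        b = rng.uniform(10, 11, size=(5, 5))
        r = mc_comparison(a, b, MCSettings(n_runs=500, seed=1))
        assert r.fraction_significant == 1.0
        assert r.band == "***"

    def test_fraction_monotone_in_mean_shift(self):
        """Larger group separation never lowers the fraction of significant
        runs (same base noise and resampling seed per shift)."""
        rng = np.random.default_rng(5)
        base_a = rng.normal(0, 1, size=(5, 5))
        base_b = rng.normal(0, 1, size=(5, 5))
        fractions = [
            mc_comparison(base_a, base_b + shift, MCSettings(n_runs=2000, seed=9)
                          ).fraction_significant
            for shift in (0.0, 1.0, 2.0, 4.0)
        ]
        assert fractions == sorted(fractions)
        assert fractions[-1] > 0.99

    def test_determinism_under_fixed_seed(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, (5, 5)), rng.normal(1, 1, (5, 5))
        r1 = mc_comparison(a, b, MCSettings(n_runs=1000, seed=33))
        r2 = mc_comparison(a, b, MCSettings(n_runs=1000, seed=33))
        assert r1.fraction_significant == r2.fraction_significant

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="group_a"):
            mc_comparison(np.empty((0, 5)), np.ones((5, 5)))


class TestComparisonScheme:
    def test_mode_cardinalities_match_study_design(self, default_config):
        table = default_config.species_table
        expected = {
            "diff_activity_all": 24,          # 4 nocturnal x 3 diurnal x 2 positions
            "diff_activity_diff_size": 16,    # 8 unequal-size cross pairs x 2
            "same_activity_nocturnal": 12,    # C(4,2) pairs x 2
            "same_activity_diurnal": 6,       # C(3,2) pairs x 2
            "within_species_positions": 7,    # one 0.2-vs-0.4 pair per species
        }
        for mode, n in expected.items():
            scheme = build_comparison_scheme(table, mode, positions=(0.2, 0.4))
            assert len(scheme) == n, mode
            assert len(set(scheme.pairs)) == n  # no duplicates

    def test_diff_size_pairs_enumerated_by_brute_force(self, default_config):
        table = default_config.species_table
        want = {
            frozenset((a.name, b.name))
            for i, a in enumerate(table)
            for b in table[i + 1:]
            if a.activity != b.activity and a.size_class != b.size_class
        }
        scheme = build_comparison_scheme(table, "diff_activity_diff_size", positions=(0.2,))
        got = {frozenset((p[0].species, p[1].species)) for p in scheme.pairs}
        assert got == want and len(scheme) == len(want)

    def test_unknown_mode_rejected(self, default_config):
        with pytest.raises(ValueError, match="unknown mode"):
            build_comparison_scheme(default_config.species_table, "by_habitat")


class TestRunAllComparisons:
    def test_one_result_per_pair(self, dataset_seed1, default_config):
        scheme = build_comparison_scheme(default_config.species_table, "diff_activity_all")
        results = run_all_comparisons(
            dataset_seed1, scheme, "inclination_deg", MCSettings(n_runs=200, seed=1)
        )
        assert len(results) == 24
        keys = {(r.group_a, r.group_b) for r in results}
        assert len(keys) == 24

    def test_results_stable_under_scheme_extension(self, dataset_seed1, default_config):
        """Per-pair RNG substreams: adding comparisons does not perturb
        existing results."""
        table = default_config.species_table
        small = build_comparison_scheme(table, "same_activity_diurnal")
        large = build_comparison_scheme(table, "diff_activity_all")
        settings = MCSettings(n_runs=300, seed=2)
        got_small = {
            (r.group_a, r.group_b): r.fraction_significant
            for r in run_all_comparisons(dataset_seed1, small, "length_mm", settings)
        }
        combined = type(small)(
            mode=small.mode, positions=small.positions, pairs=large.pairs + small.pairs
        )
        got_combined = {
            (r.group_a, r.group_b): r.fraction_significant
            for r in run_all_comparisons(dataset_seed1, combined, "length_mm", settings)
        }
        for key, fraction in got_small.items():
            assert got_combined[key] == fraction

    def test_missing_cell_reported_with_offender(self, dataset_seed1, default_config):
        scheme = build_comparison_scheme(default_config.species_table, "diff_activity_all")
        trimmed = dataset_seed1[~(
            (dataset_seed1["species"] == "B_bubo") & (dataset_seed1["position"] == 0.2)
        )]
        with pytest.raises(ValueError, match=r"B_bubo, 0.2"):
            run_all_comparisons(trimmed, scheme, "inclination_deg", MCSettings(n_runs=10))

    def test_within_species_null_positions_all_ns(self, default_config):
        """With no positional effect in the generator, the within-species
        0.2-vs-0.4 comparisons come out non-significant."""
        mt = default_config.mean_table.copy()
        at02 = mt[mt["position"] == 0.2].set_index("species")
        for param in ("inclination_deg", "tip_displacement_deg", "length_mm"):
            mt.loc[mt["position"] == 0.4, param] = (
                mt.loc[mt["position"] == 0.4, "species"].map(at02[param]).to_numpy()
            )
        cfg = default_config.with_overrides(mean_table=mt)
        from owlserr import generate_dataset

        df = generate_dataset(cfg, seed=6)
        scheme = build_comparison_scheme(cfg.species_table, "within_species_positions")
        results = run_all_comparisons(df, scheme, "inclination_deg",
                                      MCSettings(n_runs=1000, seed=6))
        assert all(r.band == "ns" for r in results)
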