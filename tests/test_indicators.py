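"""Indicator and comparison statistics against hand and brute-force
oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ecocompare import indicators as ind, roster as ros


class TestTrophicLevels:
    def _diet(self, rows):
        groups = sorted({g for r in rows for g in (r[0], r[1])})
        d = pd.DataFrame(0.0, index=groups, columns=groups)
        for pred, prey, p in rows:
            d.loc[pred, prey] = p
        return d

    def test_herbivore_is_level_two(self):
        d = self._diet([("grazer", "algae", 1.0)])
        tl = ind.trophic_levels(d, producers={"algae"})
        assert tl["algae"] == 1.0
        assert tl["grazer"] == pytest.approx(2.0)

    def test_chain_reaches_level_three(self):
        d = self._diet([("a", "algae", 1.0), ("b", "a", 1.0)])
        tl = ind.trophic_levels(d, producers={"algae"})
        assert tl["b"] == pytest.approx(3.0)

    def test_bacteria_feeder_sits_just_above_the_floor(self):
        d = self._diet([("eater", "bugs", 1.0)])
        tl = ind.trophic_levels(d, producers=set(), bacteria={"bugs"})
        assert tl["bugs"] == 0.01
        assert tl["eater"] == pytest.approx(1.01)

    def test_duplicate_prey_split_leaves_predator_unchanged(self):
        a = self._diet([("pred", "x", 1.0), ("x", "algae", 1.0),
                        ("y", "algae", 1.0)])
        b = self._diet([("pred", "x", 0.4), ("pred", "y", 0.6),
                        ("x", "algae", 1.0), ("y", "algae", 1.0)])
        ta = ind.trophic_levels(a, producers={"algae"})
        tb = ind.trophic_levels(b, producers={"algae"})
        assert ta["pred"] == pytest.approx(tb["pred"])

    def test_mixed_diet_weighted_mean(self):
        d = self._diet([("omni", "algae", 0.5), ("omni", "grazer", 0.5),
                        ("grazer", "algae", 1.0)])
        tl = ind.trophic_levels(d, producers={"algae"})
        assert tl["omni"] == pytest.approx(1.0 + 0.5 * 1.0 + 0.5 * 2.0)


class TestPreyCategories:
    def test_aggregation_preserves_row_sums(self):
        diet = pd.DataFrame(
            {"a": [0.3], "b": [0.5], "c": [0.2]}, index=["pred"]
        )
        cats = ind.summarise_prey_categories(
            diet, {"a": "Teleost", "b": "Teleost", "c": "Mollusc"}
        )
        assert cats.loc["pred", "Teleost"] == pytest.approx(0.8)
        assert cats.loc["pred"].sum() == pytest.approx(1.0)

    def test_prey_order_irrelevant(self):
        m = {"a": "Teleost", "b": "Mollusc"}
        d1 = pd.DataFrame({"a": [0.4], "b": [0.6]}, index=["p"])
        d2 = pd.DataFrame({"b": [0.6], "a": [0.4]}, index=["p"])
        pd.testing.assert_frame_equal(ind.summarise_prey_categories(d1, m),
                                      ind.summarise_prey_categories(d2, m))

    def test_unmapped_prey_fatal(self):
        diet = pd.DataFrame({"mystery": [1.0]}, index=["pred"])
        with pytest.raises(KeyError, match="mystery"):
            ind.summarise_prey_categories(diet, {})

    def test_packaged_map_covers_roster(self, roster):
        cats = ros.load_prey_categories()
        assert set(roster["group_id"]) <= set(cats["group_id"])


class TestKemptonsQ:
    def test_geometric_toy_gives_unity(self):
        b = pd.Series([1000.0, 100.0, 10.0, 1.0], index=list("abcd"))
        tl = pd.Series(3.5, index=list("abcd"))
        assert ind.kemptons_q(b, tl) == pytest.approx(1.0)

    def test_scale_invariance(self):
        b = pd.Series([1000.0, 100.0, 10.0, 1.0], index=list("abcd"))
        tl = pd.Series(3.5, index=list("abcd"))
        assert ind.kemptons_q(10 * b, tl) == pytest.approx(ind.kemptons_q(b, tl))

    def test_steeper_decline_lowers_q(self):
        """Brute force over geometric biomass series: a larger decay ratio
        (steeper ranked-biomass slope) always lowers Q."""
        tl = pd.Series(3.5, index=range(8))
        qs = []
        for ratio in (2.0, 4.0, 8.0, 16.0):
            b = pd.Series(ratio ** -np.arange(8), index=range(8))
            qs.append(ind.kemptons_q(b, tl))
        assert all(q2 < q1 for q1, q2 in zip(qs, qs[1:]))

    def test_too_few_upper_level_groups_fatal(self):
        b = pd.Series([10.0, 5.0, 2.0, 1.0], index=list("abcd"))
        tl = pd.Series([3.5, 3.5, 2.0, 2.0], index=list("abcd"))
        with pytest.raises(ValueError, match=">= 4"):
            ind.kemptons_q(b, tl)

    def test_flat_biomass_flagged_undefined(self):
        b = pd.Series(1.0, index=range(6))
        tl = pd.Series(3.5, index=range(6))
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(ind.kemptons_q(b, tl))


class TestPerturbationSuite:
    @staticmethod
    def _toy_runner(extra_m, horizon):
        """Two competing prey and one predator with closed-form end state:
        added mortality on a group shrinks it and releases its competitor."""
        base = pd.Series({"a": 100.0, "b": 50.0, "c": 10.0})
        out = base.copy()
        for g, m in extra_m.items():
            out[g] = base[g] * np.exp(-m * horizon)
            for other in base.index:
                if other != g:
                    out[other] = base[other] * (1 + 0.1 * m * horizon)
        return out

    def test_zero_levels_give_zero_impacts(self):
        imp = ind.run_perturbation_suite(self._toy_runner, ["a", "b", "c"],
                                         levels=(0.0,), horizon=10)
        assert np.allclose(imp.mean.to_numpy(), 0.0)

    def test_direction_of_impacts(self):
        imp = ind.run_perturbation_suite(self._toy_runner, ["a", "b", "c"],
                                         levels=(0.1, 0.005), horizon=50)
        assert imp.mean.loc["a", "a"] < 0          # hurt itself
        assert imp.mean.loc["a", "b"] > 0          # released the others
        assert imp.mean.loc["a", "c"] > 0

    def test_failed_run_names_the_group(self):
        def bad_runner(extra_m, horizon):
            if "b" in extra_m:
                raise RuntimeError("model exploded")
            return pd.Series({"a": 1.0, "b": 1.0})

        with pytest.raises(RuntimeError, match="'b'"):
            ind.run_perturbation_suite(bad_runner, ["a", "b"], levels=(0.1,),
                                       horizon=5)


class TestKeystoneness:
    def test_worked_example_is_zero(self):
        """Impact row (0.3, 0.4) with biomass rank 2:
        KS = log10(0.5 * 2) = 0."""
        imp = pd.DataFrame([[0.0, 0.3, 0.4],
                            [0.1, 0.0, 0.1],
                            [0.1, 0.1, 0.0]],
                           index=list("abc"), columns=list("abc"))
        b = pd.Series({"a": 5.0, "b": 10.0, "c": 1.0})  # a has drank 2
        table = ind.keystoneness(imp, b)
        assert table.loc["a", "ks"] == pytest.approx(0.0, abs=1e-12)

    def test_tenfold_impacts_shift_ks_by_one(self):
        imp = pd.DataFrame([[0.0, 0.03, 0.04], [0.1, 0.0, 0.1],
                            [0.1, 0.1, 0.0]],
                           index=list("abc"), columns=list("abc"))
        b = pd.Series({"a": 5.0, "b": 10.0, "c": 1.0})
        lo = ind.keystoneness(imp, b).loc["a", "ks"]
        imp.loc["a"] *= 10.0
        hi = ind.keystoneness(imp, b).loc["a", "ks"]
        assert hi - lo == pytest.approx(1.0, abs=1e-12)

    def test_three_species_brute_force(self):
        imp = pd.DataFrame([[0.0, 0.2, -0.1],
                            [0.5, 0.0, 0.3],
                            [0.05, -0.02, 0.0]],
                           index=list("abc"), columns=list("abc"))
        b = pd.Series({"a": 100.0, "b": 1.0, "c": 10.0})
        table = ind.keystoneness(imp, b)
        expect = {}
        dranks = {"a": 1, "b": 3, "c": 2}
        for g in "abc":
            row = imp.loc[g].drop(g)
            expect[g] = np.log10(np.sqrt((row**2).sum()) * dranks[g])
        for g in "abc":
            assert table.loc[g, "ks"] == pytest.approx(expect[g])
        ranked = sorted(expect, key=lambda g: -expect[g])
        for pos, g in enumerate(ranked, start=1):
            assert table.loc[g, "ks_rank"] == pos

    def test_rank_invariant_to_biomass_rescaling(self):
        imp = pd.DataFrame(np.random.default_rng(1).uniform(0, 0.3, (4, 4)),
                           index=list("abcd"), columns=list("abcd"))
        b = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("abcd"))
        r1 = ind.keystoneness(imp, b)["ks_rank"]
        r2 = ind.keystoneness(imp, 7.5 * b)["ks_rank"]
        pd.testing.assert_series_equal(r1, r2)

    def test_zero_impact_row_ranked_last(self):
        imp = pd.DataFrame([[0.0, 0.0], [0.3, 0.0]], index=list("ab"),
                           columns=list("ab"))
        b = pd.Series({"a": 1.0, "b": 2.0})
        table = ind.keystoneness(imp, b)
        assert np.isneginf(table.loc["a", "ks"])
        assert table.loc["a", "ks_rank"] == 2


class TestRankThirds:
    def test_identical_rankings_all_same(self):
        r = pd.Series(range(1, 31), index=[f"g{i}" for i in range(30)])
        out = ind.classify_rank_thirds(r, r)
        assert out == {"same_third": 30, "opposite_thirds": 0, "other": 0}

    def test_reversed_ranking_of_30(self):
        """Brute force: reversing 30 ranks puts the top and bottom thirds
        opposite (20 groups) and keeps the middle third in place (10)."""
        idx = [f"g{i}" for i in range(30)]
        a = pd.Series(range(1, 31), index=idx)
        b = pd.Series(range(30, 0, -1), index=idx)
        out = ind.classify_rank_thirds(a, b)
        assert out == {"same_third": 10, "opposite_thirds": 20, "other": 0}

    def test_n_not_divisible_by_three(self):
        """n=10 splits 4/3/3; enumeration of the reversed ranking."""
        idx = [f"g{i}" for i in range(10)]
        a = pd.Series(range(1, 11), index=idx)
        b = pd.Series(range(10, 0, -1), index=idx)
        out = ind.classify_rank_thirds(a, b)
        # thirds of a: ranks 1-4 / 5-7 / 8-10; reversed rank r -> 11 - r
        expect = {"same_third": 0, "opposite_thirds": 0, "other": 0}
        def third(r):
            return 0 if r <= 4 else (1 if r <= 7 else 2)
        for r in range(1, 11):
            ta, tb = third(r), third(11 - r)
            key = ("same_third" if ta == tb
                   else "opposite_thirds" if abs(ta - tb) == 2 else "other")
            expect[key] += 1
        assert out == expect

    def test_mismatched_sets_fatal(self):
        a = pd.Series([1, 2], index=["x", "y"])
        b = pd.Series([1, 2], index=["x", "z"])
        with pytest.raises(ValueError):
            ind.classify_rank_thirds(a, b)


class TestDietSpearman:
    def test_identical_diets(self):
        d = pd.Series({"x": 0.5, "y": 0.3, "z": 0.2})
        assert ind.diet_spearman(d, d) == pytest.approx(1.0)

    def test_disjoint_diets_get_minus_one(self):
        a = pd.Series({"x": 0.6, "y": 0.4, "z": 0.0})
        b = pd.Series({"x": 0.0, "y": 0.0, "z": 1.0})
        assert ind.diet_spearman(a, b) == -1.0

    def test_perfect_rank_reversal(self):
        a = pd.Series({"x": 0.7, "y": 0.2, "z": 0.1})
        b = pd.Series({"x": 0.1, "y": 0.2, "z": 0.7})
        assert ind.diet_spearman(a, b) == pytest.approx(-1.0)

    def test_drop_prey_changes_the_universe(self):
        a = pd.Series({"plankton": 0.9, "x": 0.1, "y": 0.0})
        b = pd.Series({"plankton": 0.9, "x": 0.0, "y": 0.1})
        with_p = ind.diet_spearman(a, b)
        without = ind.diet_spearman(a, b, drop_prey={"plankton"})
        assert without == -1.0
        assert with_p > without

    def test_empty_universe_fatal(self):
        a = pd.Series({"p": 1.0})
        with pytest.raises(ValueError):
            ind.diet_spearman(a, a, drop_prey={"p"})

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_symmetry_and_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        prey = [f"p{i}" for i in range(6)]
        a = pd.Series(rng.dirichlet(np.ones(6)), index=prey)
        b = pd.Series(rng.dirichlet(np.ones(6)), index=prey)
        r1 = ind.diet_spearman(a, b)
        r2 = ind.diet_spearman(b, a)
        perm = rng.permutation(prey)
        r3 = ind.diet_spearman(a.loc[perm], b.loc[perm])
        assert r1 == pytest.approx(r2)
        assert r1 == pytest.approx(r3)


class TestSkillPearson:
    years = np.arange(2000, 2012)

    def test_scaled_index_has_unit_correlation(self):
        model = pd.Series(np.linspace(50, 150, 12), index=self.years)
        r, rescaled = ind.skill_pearson(model, 2.0 * model)
        assert r == pytest.approx(1.0)
        assert rescaled.mean() == pytest.approx(model.mean())

    def test_anticorrelated_index(self):
        model = pd.Series(np.linspace(50, 150, 12), index=self.years)
        index = model.mean() * 2 - model
        r, _ = ind.skill_pearson(model, index)
        assert r == pytest.approx(-1.0)

    def test_too_few_overlapping_years_fatal(self):
        model = pd.Series([1.0, 2.0], index=[2000, 2001])
        with pytest.raises(ValueError, match="overlapping"):
            ind.skill_pearson(model, model)

    def test_constant_series_flagged(self):
        model = pd.Series(1.0, index=self.years)
        index = pd.Series(np.linspace(1, 2, 12), index=self.years)
        with pytest.warns(UserWarning, match="zero variance"):
            r, _ = ind.skill_pearson(model, index)
        assert np.isnan(r)

    def test_toy_series_reproduce_reference_correlations(self):
        """Round trip through the packaged skill table: toy (model,
        survey) pairs constructed for each printed correlation give back
        exactly that correlation."""
        table = ros.load_skill_table()
        for i, row in table.iterrows():
            model, survey = ind.make_skill_toy_series(row["survey_r"], n=11,
                                                      seed=100 + i)
            r, _ = ind.skill_pearson(model, survey)
            assert r == pytest.approx(row["survey_r"], abs=1e-9)


class TestBetweenRunCV:
    years = np.arange(2000, 2010)

    def _frame(self, value):
        return pd.DataFrame({"g": value}, index=self.years)

    def test_identical_runs_zero_cv(self):
        ens = [self._frame(5.0), self._frame(5.0), self._frame(5.0)]
        assert ind.between_run_cv(ens, (2000, 2009))["g"] == 0.0

    def test_two_run_hand_oracle(self):
        """Runs at 1 and 3 every year: CV = sd/mean = sqrt(2)/2."""
        ens = [self._frame(1.0), self._frame(3.0)]
        cv = ind.between_run_cv(ens, (2000, 2009))["g"]
        assert cv == pytest.approx(np.sqrt(2.0) / 2.0)

    def test_window_outside_span_fatal(self):
        ens = [self._frame(1.0), self._frame(3.0)]
        with pytest.raises(ValueError, match="window"):
            ind.between_run_cv(ens, (1990, 2009))

    def test_p90_reduction_on_constant_cvs(self):
        ens = [self._frame(1.0), self._frame(3.0)]
        p90 = ind.between_run_cv(ens, (2000, 2009), reduce="p90")["g"]
        assert p90 == pytest.approx(np.sqrt(2.0) / 2.0)


class TestForcingDesigns:
    def test_single_year_library_warns(self):
        with pytest.warns(UserWarning, match="single-year"):
            designs = ind.bootstrap_forcing_design([2008], n_runs=3, n_years=5,
                                                   seed=1)
        assert all(seq == designs[0] for seq in designs)

    def test_year_frequencies_uniform(self):
        """Monte-Carlo check: across 50 runs of 115 draws from 6 years,
        each year's frequency is within 3 binomial SE of 1/6."""
        years = list(range(2008, 2014))
        designs = ind.bootstrap_forcing_design(years, n_runs=50, n_years=115,
                                               burn_in_len=0, seed=7)
        draws = np.concatenate(designs)
        n = len(draws)
        se = np.sqrt((1 / 6) * (5 / 6) / n)
        for y in years:
            assert abs((draws == y).mean() - 1 / 6) < 3 * se

    def test_burn_in_prefix(self):
        designs = ind.bootstrap_forcing_design([1, 2], n_runs=2, n_years=10,
                                               burn_in_year=1, burn_in_len=35,
                                               seed=3)
        for seq in designs:
            assert seq[:35] == [1] * 35
            assert len(seq) == 45

    def test_seeded_reproducibility(self):
        a = ind.bootstrap_forcing_design([1, 2, 3], 5, 20, seed=9)
        b = ind.bootstrap_forcing_design([1, 2, 3], 5, 20, seed=9)
        assert a == b

    def test_repeat_year_design(self):
        designs = ind.repeat_year_design([2008, 2009, 2010], n_years=10,
                                         burn_in_len=5)
        assert len(designs) == 3
        for seq, y in zip(designs, (2008, 2009, 2010)):
            assert seq == [y] * 15


class TestRepresentativeYear:
    def _library(self, offsets):
        rows = []
        months = np.arange(1, 13)
        cycle = np.sin(2 * np.pi * months / 12)
        for y, off in offsets.items():
            for m, c in zip(months, cycle):
                rows.append({"year": y, "month": m,
                             "temp_anom": c + off, "prod_mult": 1.0 + 0.1 * c + off})
        return pd.DataFrame(rows)

    def test_mean_member_selected(self):
        lib = self._library({2008: 0.2, 2009: -0.2, 2010: 0.0})
        year, table = ind.representative_year(lib)
        assert year == 2010
        assert table.loc[2010, "combined_ss"] == pytest.approx(0.0)

    def test_smaller_offset_wins(self):
        lib = self._library({2008: 0.05, 2009: 0.5, 2010: -0.5})
        year, _ = ind.representative_year(lib)
        assert year == 2008

    def test_two_identical_deviations_tie_to_earliest(self):
        # with two years the deviations from their mean are symmetric,
        # so the scores tie and the earliest year is returned
        lib = self._library({2008: 0.1, 2009: 0.5})
        with pytest.warns(UserWarning, match="tie"):
            year, _ = ind.representative_year(lib)
        assert year == 2008

    def test_three_year_brute_force(self):
        lib = self._library({2008: 0.3, 2009: -0.1, 2010: 0.15})
        year, table = ind.representative_year(lib)
        # exhaustive check against direct sum-of-squares per year
        wide = lib.pivot(index="month", columns="year", values="temp_anom")
        mean_cycle = wide.mean(axis=1)
        ss_vals = {y: ((wide[y] - mean_cycle) ** 2).sum() for y in wide.columns}
        assert year == min(ss_vals, key=ss_vals.get)


class TestResponseCorrelations:
    years = np.arange(1990, 2010)

    def test_self_comparison_unity(self):
        b = pd.DataFrame({"g1": np.linspace(1, 2, 20),
                          "g2": np.sin(np.arange(20))}, index=self.years)
        out = ind.response_correlation_matrix({"m1": b, "m2": b.copy()})
        assert out.loc["g1", "m1_vs_m2"] == pytest.approx(1.0)
        assert out.loc["g2", "m1_vs_m2"] == pytest.approx(1.0)

    def test_negated_trajectory(self):
        b = pd.DataFrame({"g": np.linspace(1, 2, 20)}, index=self.years)
        neg = pd.DataFrame({"g": 2 * b["g"].mean() - b["g"]}, index=self.years)
        out = ind.response_correlation_matrix({"m1": b, "m2": neg})
        assert out.loc["g", "m1_vs_m2"] == pytest.approx(-1.0)

    def test_missing_group_marked_na(self):
        a = pd.DataFrame({"g": np.linspace(1, 2, 20),
                          "only_a": np.linspace(3, 1, 20)}, index=self.years)
        b = pd.DataFrame({"g": np.linspace(2, 1, 20)}, index=self.years)
        out = ind.response_correlation_matrix({"m1": a, "m2": b})
        assert np.isnan(out.loc["only_a", "m1_vs_m2"])

    def test_three_model_toy_matches_pairwise(self):
        rng = np.random.default_rng(5)
        frames = {
            name: pd.DataFrame({"g": rng.normal(size=20)}, index=self.years)
            for name in ("a", "b", "c")
        }
        out = ind.response_correlation_matrix(frames)
        from scipy.stats import pearsonr
        for pair in ("a_vs_b", "a_vs_c", "b_vs_c"):
            m1, m2 = pair.split("_vs_")
            expect = pearsonr(frames[m1]["g"], frames[m2]["g"])[0]
            assert out.loc["g", pair] == pytest.approx(expect)


class TestDiversityComparison:
    years = np.arange(2000, 2010)

    def test_identical_series_unit_ratio(self):
        q = pd.Series(np.linspace(5, 6, 10), index=self.years)
        scaled, ratios = ind.diversity_comparison({"ref": q, "alt": q.copy()},
                                                  reference="ref")
        assert np.allclose(ratios["alt"], 1.0)

    def test_constant_factor_removed_by_scaling(self):
        q = pd.Series(np.linspace(5, 6, 10), index=self.years)
        scaled, ratios = ind.diversity_comparison({"ref": q, "alt": 2.0 * q},
                                                  reference="ref")
        assert np.allclose(ratios["alt"], 1.0)
        assert scaled["alt"].mean() == pytest.approx(scaled["ref"].mean())

    def test_scaled_means_equal(self):
        rng = np.random.default_rng(3)
        q1 = pd.Series(5 + rng.random(10), index=self.years)
        q2 = pd.Series(9 + rng.random(10), index=self.years)
        scaled, _ = ind.diversity_comparison({"ref": q1, "alt": q2},
                                             reference="ref")
        assert scaled["alt"].mean() == pytest.approx(scaled["ref"].mean(),
                                                     abs=1e-12)


class TestSizeDiagnostics:
    def test_uniform_weight_sample(self):
        out = ind.lmax_estimate(0.01, 3.0, weights=np.full(50, 1000.0))
        assert out == pytest.approx((1000.0 / 0.01) ** (1 / 3))

    def test_hand_evaluation(self):
        """a=0.01, b=3, w=1000 g: L = 100000^(1/3) ~ 46.42 cm."""
        out = ind.lmax_estimate(0.01, 3.0, weights=np.full(10, 1000.0),
                                mode="max")
        assert out == pytest.approx(46.42, abs=0.01)

    def test_larger_condition_factor_shortens_fish(self):
        lo = ind.lmax_estimate(0.01, 3.0, weights=np.full(10, 1000.0))
        hi = ind.lmax_estimate(0.02, 3.0, weights=np.full(10, 1000.0))
        assert hi < lo

    def test_empty_sample_fatal(self):
        with pytest.raises(ValueError):
            ind.lmax_estimate(0.01, 3.0, weights=np.array([]))


class TestMortalityDecay:
    def test_exact_exponential_recovery(self):
        ages = np.arange(0, 12)
        props = pd.Series(np.exp(-0.3 * ages), index=ages)
        props /= props.sum()
        m_hat, diff = ind.mortality_decay_check(props, m_lit=0.3)
        assert m_hat == pytest.approx(0.3, abs=1e-6)
        assert diff == pytest.approx(0.0, abs=1e-6)

    def test_uniform_proportions_zero_mortality(self):
        props = pd.Series(1.0 / 8, index=np.arange(8))
        m_hat, _ = ind.mortality_decay_check(props, m_lit=0.2)
        assert m_hat == pytest.approx(0.0, abs=1e-12)

    def test_noisy_decay_within_two_se(self):
        """Simulation recovery: proportions with lognormal noise give an
        estimate within 2 SE of the generating mortality."""
        rng = np.random.default_rng(11)
        ages = np.arange(0, 15)
        m_true, sd = 0.4, 0.1
        log_p = -m_true * ages + rng.normal(0, sd, len(ages))
        props = pd.Series(np.exp(log_p), index=ages)
        props /= props.sum()
        m_hat, _ = ind.mortality_decay_check(props, m_lit=m_true)
        x = ages - ages.mean()
        se = sd / np.sqrt((x**2).sum())
        assert abs(m_hat - m_true) < 2 * se

    def test_zero_tail_warns(self):
        props = pd.Series([0.7, 0.3, 0.0, 0.0], index=np.arange(4))
        with pytest.warns(UserWarning, match="positive support"):
            m_hat, _ = ind.mortality_decay_check(props, m_lit=0.5)
        assert m_hat > 0
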