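import numpy as np
import pytest

from metabostrat import (
    SplitConfig,
    cross_validate,
    fpr_cancer,
    fpr_obesity,
    prevalence_corrected_fpr,
    roc_curve_F,
    roc_region_GF,
    tpr_cancer,
    tpr_obesity,
)
from metabostrat.errors import (
    CohortValidationError,
    EstimationError,
    UndefinedMetricError,
)

from conftest import make_cohort
from oracles import brute_force_f, brute_force_gf, fpr_oracle, impute_f_oracle, impute_gf_oracle, tpr_oracle


class TestRates:
    def test_tpr_counting(self):
        ref = ["c", "c", "c", "c", "h"]
        imp = ["c", "c", "c", "h", "h"]
        assert tpr_cancer(ref, imp) == 0.75
        assert tpr_cancer(["c", "c"], ["c", "c"]) == 1.0
        assert tpr_cancer(["c", "c"], ["h", "h"]) == 0.0

    def test_tpr_undefined_without_cancer(self):
        with pytest.raises(UndefinedMetricError):
            tpr_cancer(["h", "o"], ["h", "o"])

    def test_fpr_reduces_to_healthy_only_at_zero_prevalence(self):
        ref = ["h"] * 10 + ["o"] * 5
        imp = ["c"] + ["h"] * 9 + ["c"] * 5
        assert fpr_cancer(ref, imp, p_o=0.0) == pytest.approx(0.1)

    def test_fpr_hand_computed_weighted_example(self):
        """|VnH| = 10 with 0 false positives, |VnO| = 5 all imputed cancer,
        p_O = 0.2 => x = 0.4 and FPR = (0 + 0.4*5) / (10 + 0.4*5) = 1/6."""
        ref = ["h"] * 10 + ["o"] * 5
        imp = ["h"] * 10 + ["c"] * 5
        assert fpr_cancer(ref, imp, p_o=0.2) == pytest.approx(1 / 6)

    def test_fpr_zero_when_nothing_imputed_cancer(self):
        ref = ["h"] * 4 + ["o"] * 2
        imp = ["h"] * 4 + ["o"] * 2
        assert fpr_cancer(ref, imp, p_o=0.3) == 0.0

    def test_fpr_needs_obesity_samples_when_weighted(self):
        with pytest.raises(UndefinedMetricError):
            fpr_cancer(["h", "c"], ["h", "c"], p_o=0.2)

    def test_fpr_needs_healthy_samples(self):
        with pytest.raises(UndefinedMetricError):
            fpr_cancer(["c", "o"], ["c", "o"], p_o=0.0)

    def test_obesity_rates_swap_roles(self):
        ref = ["o", "o", "h", "h", "c", "c"]
        imp = ["o", "h", "h", "h", "o", "c"]
        assert tpr_obesity(ref, imp) == 0.5
        # x = 0.5 * 2 / 2 = 0.5; FPR_O = (0 + 0.5*1) / (2 + 0.5*2) ...
        assert fpr_obesity(ref, imp, p_c=0.5) == pytest.approx(0.5 / 3)

    def test_generalised_confounder_weighting(self):
        """The generalised form gives every confounder class d the weight
        x_d = p_d |H| / |D_d|; here one confounder, checked by hand."""
        ref = ["h"] * 6 + ["o"] * 3 + ["c"] * 2
        imp = ["c", "h", "h", "h", "h", "h", "c", "c", "h", "c", "c"]
        # target c: FP from h: 1/6; o: 2 of 3 imputed c, x_o = 0.2*6/3 = 0.4
        expected = (1 + 0.4 * 2) / (6 + 0.4 * 3)
        assert prevalence_corrected_fpr(
            ref, imp, "c", {"o": 0.2}
        ) == pytest.approx(expected)

    def test_monotonicity_extra_healthy_false_positive(self):
        ref = ["h"] * 5 + ["c"] * 3 + ["o"] * 2
        imp = ["h"] * 5 + ["c"] * 3 + ["h"] * 2
        base = fpr_cancer(ref, imp, p_o=0.2)
        worse = fpr_cancer(ref + ["h"], imp + ["c"], p_o=0.2)
        assert worse > base


class TestRocF:
    def test_perfectly_separated_cohort_contains_corner(self):
        cohort = make_cohort(
            [("c1", "BC", 0.02, 1e8), ("c2", "LC", 0.03, 1e8),
             ("h1", "H", 0.07, 1e8), ("h2", "H", 0.09, 1e8)]
        )
        roc = roc_curve_F(cohort)
        points = set(zip(roc.fpr.round(12), roc.tpr.round(12)))
        assert (0.0, 1.0) in points
        assert (0.0, 0.0) in points and (1.0, 1.0) in points

    def test_sorted_by_fpr_with_endpoints(self, default_cohort):
        roc = roc_curve_F(default_cohort)
        assert (roc.fpr.diff().dropna() >= 0).all()
        assert roc.iloc[0].tolist()[1:] == [0.0, 0.0]
        assert roc.iloc[-1].tolist()[1:] == [1.0, 1.0]

    def test_single_threshold_degenerate_grid(self):
        cohort = make_cohort([("h1", "H", 0.05, 1e8), ("c1", "BC", 0.05, 1e8)])
        assert len(roc_curve_F(cohort)) == 3

    def test_null_cohort_curve_near_diagonal(self):
        """With labels carrying no formate signal the curve hugs the diagonal
        (trapezoidal area within 0.5 +/- 0.1)."""
        rng = np.random.default_rng(21)
        n = 300
        formate = rng.uniform(0.02, 0.10, size=n)
        subtypes = rng.permutation(["H"] * 150 + ["BC"] * 150)
        cohort = make_cohort(
            [(f"s{i}", subtypes[i], float(formate[i]), 1e8) for i in range(n)]
        )
        roc = roc_curve_F(cohort)
        auc = np.trapezoid(roc.tpr, roc.fpr)
        assert abs(auc - 0.5) < 0.1


class TestRocRegionGF:
    def test_grid_size_and_corner_on_separable_cohort(self, toy_cohort):
        region = roc_region_GF(toy_cohort, p_o=0.2)
        n_g = len(np.unique(toy_cohort.glucose)) + 2
        n_f = len(np.unique(toy_cohort.formate)) + 2
        assert len(region) == n_g * n_f
        assert ((region.fpr == 0) & (region.tpr == 1)).any()

    def test_degenerates_to_f_curve_at_max_glucose_sentinel(self, toy_cohort):
        """Restricting the region to the top glucose sentinel reproduces the
        F-classifier curve point set computed on the same samples."""
        region = roc_region_GF(toy_cohort, p_o=0.0)
        top = region[region.g_t == region.g_t.max()]
        curve = roc_curve_F(toy_cohort, include_obesity=True, p_o=0.0)
        region_points = {
            (round(f, 12), round(fp, 12), round(tp, 12))
            for f, fp, tp in zip(top.f_t, top.fpr, top.tpr)
        }
        curve_points = {
            (round(f, 12), round(fp, 12), round(tp, 12))
            for f, fp, tp in zip(curve.f_t, curve.fpr, curve.tpr)
        }
        assert region_points == curve_points

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(31)
        from conftest import random_small_cohort

        cohort = random_small_cohort(rng, n_max=9)
        region = roc_region_GF(cohort, p_o=0.2)
        ref = list(cohort.merged)
        for row in region.itertuples():
            imp = impute_gf_oracle(cohort.glucose, cohort.formate, row.g_t, row.f_t)
            assert row.tpr == pytest.approx(tpr_oracle(ref, imp), abs=1e-12)
            assert row.fpr == pytest.approx(fpr_oracle(ref, imp, p_o=0.2), abs=1e-12)


class TestCrossValidate:
    def test_perfect_separation_yields_perfect_medians(self):
        rows = []
        for i in range(8):
            rows.append((f"h{i}", "H", 0.07 + 0.002 * i, 9e7 + i * 1e5))
        for i in range(8):
            rows.append((f"c{i}", "BC", 0.02 + 0.002 * i, 9e7 + i * 1e5))
        cohort = make_cohort(rows)
        result = cross_validate(
            cohort, "F", SplitConfig(n_realisations=1000, seed=5, p_o=0.0)
        )
        assert result.tpr.median == 1.0
        assert result.fpr.median == 0.0

    def test_identical_values_collapse_percentiles(self):
        rows = [(f"h{i}", "H", 0.08, 9e7) for i in range(6)]
        rows += [(f"c{i}", "BC", 0.02, 9e7) for i in range(6)]
        cohort = make_cohort(rows)
        result = cross_validate(
            cohort, "F", SplitConfig(n_realisations=300, seed=2, p_o=0.0)
        )
        assert result.tpr.lo == result.tpr.median == result.tpr.hi == 1.0

    def test_seeded_reproducibility_and_skip_accounting(self, default_cohort):
        cfg = SplitConfig(n_realisations=50, seed=17, p_o=0.2)
        a = cross_validate(default_cohort, "GF", cfg)
        b = cross_validate(default_cohort, "GF", cfg)
        assert a.tpr == b.tpr and a.fpr == b.fpr
        total = cfg.n_realisations
        assert a.tpr.n_valid <= total and a.fpr.n_valid <= total

    def test_zero_valid_realisations_is_an_error(self):
        # two healthy samples only: training can never contain both classes
        cohort = make_cohort([("h1", "H", 0.08, 9e7), ("h2", "H", 0.09, 9e7)])
        with pytest.raises(EstimationError, match="degenerate"):
            cross_validate(cohort, "F", SplitConfig(n_realisations=20, seed=1))

    def test_unknown_classifier_kind_rejected(self, toy_cohort):
        with pytest.raises(CohortValidationError):
            cross_validate(toy_cohort, "X", SplitConfig(n_realisations=5, seed=1))

    def test_per_realisation_metrics_match_straight_line_oracle(self):
        """On a small cohort, every realisation's TPR/FPR must equal a naive
        reimplementation (explicit set intersections, brute-force threshold
        search) fed the same Bernoulli splits."""
        rng = np.random.default_rng(63)
        from conftest import random_small_cohort

        cohort = random_small_cohort(rng, n_max=12, n_min=12)
        cfg = SplitConfig(n_realisations=60, seed=29, p_o=0.2)
        result = cross_validate(cohort, "GF", cfg)

        glucose, formate, merged = (
            list(cohort.glucose),
            list(cohort.formate),
            list(cohort.merged),
        )
        children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_realisations)
        for k, child in enumerate(children):
            split_rng = np.random.default_rng(child)
            in_train = split_rng.random(len(cohort)) < cfg.train_probability
            train_idx = [i for i in range(len(cohort)) if in_train[i]]
            val_idx = [i for i in range(len(cohort)) if not in_train[i]]
            train_classes = {merged[i] for i in train_idx}
            if not {"h", "c", "o"} <= train_classes:
                assert np.isnan(result.tpr_values[k])
                assert np.isnan(result.fpr_values[k])
                continue
            g_0, f_0, _ = brute_force_gf(
                [glucose[i] for i in train_idx],
                [formate[i] for i in train_idx],
                [merged[i] for i in train_idx],
            )
            imp = impute_gf_oracle(
                [glucose[i] for i in val_idx], [formate[i] for i in val_idx], g_0, f_0
            )
            ref = [merged[i] for i in val_idx]
            if "c" in ref:
                assert result.tpr_values[k] == pytest.approx(
                    tpr_oracle(ref, imp), abs=1e-12
                )
            else:
                assert np.isnan(result.tpr_values[k])
            if "h" in ref and "o" in ref:
                assert result.fpr_values[k] == pytest.approx(
                    fpr_oracle(ref, imp, p_o=cfg.p_o), abs=1e-12
                )
            else:
                assert np.isnan(result.fpr_values[k])
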