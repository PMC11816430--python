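import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lpfsbench as lb
from lpfsbench.core import ValidationError
from lpfsbench.validation import GroupSummary, _linear_coefficients

# published severity-group summaries (n, M, SD) for two traits
NA_GROUPS = [
    GroupSummary("healthy", 442, 2.70, 0.65),
    GroupSummary("mild", 44, 3.45, 0.50),
    GroupSummary("moderate", 32, 3.64, 0.58),
    GroupSummary("severe", 12, 3.78, 0.52),
]
DN_GROUPS = [
    GroupSummary("healthy", 442, 2.12, 0.62),
    GroupSummary("mild", 44, 2.74, 0.68),
    GroupSummary("moderate", 32, 3.20, 0.66),
    GroupSummary("severe", 12, 3.29, 0.77),
]


class TestAnova:
    def test_published_negative_affectivity_effect(self):
        res = lb.anova_oneway(NA_GROUPS)
        assert round(res.effect_size, 2) == 0.21
        assert res.df == (3, 526)

    def test_equal_means_give_null_f(self):
        groups = [GroupSummary(str(i), 50, 3.0, 0.5) for i in range(3)]
        res = lb.anova_oneway(groups)
        assert res.statistic == 0.0 and res.effect_size == 0.0

    def test_summary_mode_equals_raw_mode(self, rng):
        raws = [rng.normal(loc, 1.0, size=n) for loc, n in [(0, 40), (0.4, 55), (1.0, 30)]]
        summaries = [
            GroupSummary(str(i), len(r), float(r.mean()), float(r.std(ddof=1)))
            for i, r in enumerate(raws)
        ]
        f_raw = lb.anova_oneway(raws).statistic
        f_sum = lb.anova_oneway(summaries).statistic
        assert abs(f_raw - f_sum) < 1e-10
        # independent oracle
        f_scipy, p_scipy = stats.f_oneway(*raws)
        assert f_raw == pytest.approx(f_scipy, abs=1e-10)
        assert lb.anova_oneway(raws).p_value == pytest.approx(p_scipy, abs=1e-12)

    def test_tiny_group_rejected_in_summary_mode(self):
        with pytest.raises(ValidationError, match="n >= 2"):
            lb.anova_oneway([GroupSummary("a", 1, 0.0, 0.0), GroupSummary("b", 5, 1.0, 1.0)])


class TestTukey:
    def test_identical_groups_not_rejected(self):
        groups = [GroupSummary("a", 60, 2.0, 0.7), GroupSummary("b", 60, 2.0, 0.7)]
        pairs = lb.tukey_posthoc(groups)
        assert len(pairs) == 1
        assert pairs[0].p_adjusted > 0.99

    def test_pair_order_symmetric(self, rng):
        raws = [rng.normal(m, 1, 80) for m in (0.0, 0.5, 1.0)]
        forward = lb.tukey_posthoc(raws)
        backward = lb.tukey_posthoc(raws[::-1])
        p_fwd = sorted(p.p_adjusted for p in forward)
        p_bwd = sorted(p.p_adjusted for p in backward)
        assert np.allclose(p_fwd, p_bwd, atol=1e-12)

    def test_power_for_one_shifted_group(self, rng):
        """A group shifted by one SD at n = 100/group is detected essentially
        always in all three of its pairwise comparisons."""
        hits = 0
        reps = 100
        for _ in range(reps):
            raws = [rng.normal(0, 1, 100) for _ in range(3)] + [rng.normal(1.0, 1, 100)]
            pairs = lb.tukey_posthoc(raws)
            shifted = [p for p in pairs if "group4" in (p.group_a, p.group_b)]
            hits += all(p.p_adjusted < 0.05 for p in shifted)
        assert hits / reps > 0.95


class TestLinearContrast:
    def test_published_disinhibition_trend(self):
        res = lb.linear_contrast(DN_GROUPS)
        assert 6.5 < res.statistic < 7.4
        assert res.df == (526,)

    def test_orthogonality_for_balanced_even_spacing(self):
        groups = [GroupSummary(str(i), 50, 1.0 + 0.5 * i, 0.6) for i in range(4)]
        res = lb.linear_contrast(groups)
        assert res.statistic > 0
        # quadratic coefficients are orthogonal to a linear pattern of means
        quad = np.array([1.0, -1.0, -1.0, 1.0])
        means = np.array([g.mean for g in groups])
        assert abs(quad @ means) < 1e-12

    def test_reversal_flips_sign(self):
        forward = lb.linear_contrast(DN_GROUPS)
        backward = lb.linear_contrast(DN_GROUPS[::-1])
        assert forward.statistic == pytest.approx(-backward.statistic, abs=1e-12)

    def test_classical_integer_coefficients(self):
        assert np.allclose(_linear_coefficients(4), [-3, -1, 1, 3])
        assert np.allclose(_linear_coefficients(3), [-1, 0, 1])


class TestManova:
    def test_univariate_reduces_to_anova(self, rng):
        raws = [rng.normal(m, 1, 60)[:, None] for m in (0.0, 0.3, 0.8)]
        res = lb.manova_wilks(raws)
        eta_sq = lb.anova_oneway([r.ravel() for r in raws]).effect_size
        assert res.effect_size == pytest.approx(1.0 - eta_sq, abs=1e-10)

    def test_duplicated_variable_is_singular(self, rng):
        base = [rng.normal(0, 1, (50, 1)) for _ in range(3)]
        doubled = [np.hstack([g, g]) for g in base]
        with pytest.raises(ValidationError, match="singular"):
            lb.manova_wilks(doubled)

    def test_null_calibration(self, rng):
        """Under identical multivariate distributions the type-I error at
        alpha = .05 is nominal and lambda stays near one."""
        rejections = 0
        lams = []
        reps = 1000
        for _ in range(reps):
            groups = [rng.normal(0, 1, (125, 3)) for _ in range(4)]
            res = lb.manova_wilks(groups)
            lams.append(res.effect_size)
            rejections += res.p_value < 0.05
        assert 0.03 <= rejections / reps <= 0.07
        assert np.mean(lams) > 0.9

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.multivariate.manova import MANOVA

        groups = [rng.normal(m, 1, (60, 2)) for m in (0.0, 0.4, 0.9)]
        res = lb.manova_wilks(groups)
        y = np.vstack(groups)
        g = np.repeat([0, 1, 2], 60)
        df = pd.DataFrame({"y1": y[:, 0], "y2": y[:, 1], "g": g.astype(str)})
        sm_res = MANOVA.from_formula("y1 + y2 ~ g", data=df).mv_test()
        table = sm_res.results["g"]["stat"]
        assert res.effect_size == pytest.approx(table.loc["Wilks' lambda", "Value"], abs=1e-8)
        assert res.statistic == pytest.approx(table.loc["Wilks' lambda", "F Value"], rel=1e-6)


class TestChiSquare:
    @pytest.mark.parametrize(
        "yes,expected_chi2",
        [
            ((289, 29, 19, 8), 0.50),   # romantic relationship
            ((32, 7, 4, 1), 4.74),      # psychiatric diagnosis
            ((48, 10, 8, 3), 11.06),    # psychotherapy seeking
        ],
    )
    def test_published_2x4_tables(self, yes, expected_chi2):
        totals = np.array([442, 44, 32, 12])
        yes = np.array(yes, dtype=float)
        table = lb.ContingencyTable(
            counts=np.vstack([yes, totals - yes]),
            row_labels=("yes", "no"),
            col_labels=("healthy", "mild", "moderate", "severe"),
        )
        assert round(lb.chi_square(table).statistic, 2) == expected_chi2

    def test_independent_margins_give_zero(self):
        table = lb.ContingencyTable(
            counts=np.outer([30, 70], [20, 50, 30]) / 100.0,
            row_labels=("a", "b"), col_labels=("x", "y", "z"),
        )
        assert lb.chi_square(table).statistic == pytest.approx(0.0, abs=1e-10)

    def test_hand_computed_2x2(self):
        table = lb.ContingencyTable(
            counts=np.array([[10.0, 20.0], [20.0, 10.0]]),
            row_labels=("a", "b"), col_labels=("x", "y"),
        )
        assert lb.chi_square(table).statistic == pytest.approx(100.0 / 15.0, abs=1e-6)

    def test_transposition_invariance(self, rng):
        counts = rng.integers(5, 50, size=(2, 4)).astype(float)
        a = lb.chi_square(lb.ContingencyTable(counts, ("r1", "r2"), ("a", "b", "c", "d")))
        b = lb.chi_square(lb.ContingencyTable(counts.T, ("a", "b", "c", "d"), ("r1", "r2")))
        assert a.statistic == pytest.approx(b.statistic, abs=1e-10)
        assert a.effect_size == pytest.approx(b.effect_size, abs=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError, match="margin"):
            lb.chi_square(
                lb.ContingencyTable(np.array([[0.0, 0.0], [5.0, 5.0]]), ("a", "b"), ("x", "y"))
            )


class TestCohensD:
    def test_published_sample_comparison(self):
        d, t_res = lb.cohens_d_summary(23.36, 7.08, 530, 24.08, 7.68, 1030)
        assert round(d, 2) == 0.10
        # the published t is recoverable only within the precision the
        # 2-decimal summary statistics support
        assert abs(t_res.statistic) == pytest.approx(1.74, abs=0.1)

    def test_equal_means(self):
        d, _ = lb.cohens_d_summary(2.0, 0.5, 30, 2.0, 0.7, 40)
        assert d == 0.0

    def test_symmetric_in_samples(self):
        d1, _ = lb.cohens_d_summary(2.0, 0.5, 30, 2.6, 0.7, 40)
        d2, _ = lb.cohens_d_summary(2.6, 0.7, 40, 2.0, 0.5, 30)
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_degenerate_pooled_sd(self):
        with pytest.raises(ValidationError, match="zero pooled SD"):
            lb.cohens_d_summary(1.0, 0.0, 10, 2.0, 0.0, 10)


class TestGroupTable:
    def test_matches_direct_tabulation(self, ref_benchmarks):
        spec = lb.SimulationSpec(n=2000, seed=21)
        responses, covs, theta = lb.simulate_cohort(spec)
        scores = lb.total_scores(responses)
        bundle = lb.build_group_table(scores, covs, ref_benchmarks, pool_extreme=True)
        # independent pandas groupby oracle
        classes = [
            c.value for c in lb.classify_scores(scores, ref_benchmarks, pool_extreme=True)
        ]
        df = covs.data.assign(cls=classes)
        for cls, size in bundle.group_sizes.items():
            assert size == (df["cls"] == cls.value).sum()
        oracle = df.groupby("cls")["NA"].agg(["count", "mean", "std"])
        for cls, summ in bundle.continuous_summaries["NA"].items():
            row = oracle.loc[cls.value]
            assert summ.n == row["count"]
            assert summ.mean == pytest.approx(row["mean"], abs=1e-12)
            assert summ.sd == pytest.approx(row["std"], abs=1e-12)
        assert sum(bundle.group_sizes.values()) == 2000

    def test_single_group_cohort_skips_comparisons(self, ref_benchmarks):
        covs = lb.CovariateFrame(
            data=pd.DataFrame({"NA": np.full(30, 2.0), "diag": np.zeros(30, dtype=int)})
        )
        scores = np.full(30, 20)
        bundle = lb.build_group_table(scores, covs, ref_benchmarks)
        assert bundle.group_sizes[lb.SeverityClass.HEALTHY] == 30
        assert not bundle.continuous_tests
        assert bundle.warnings

    def test_monotone_validity_of_trait_means(self, ref_benchmarks):
        """Covariates generated with positive latent slopes have non-decreasing
        group means across severity classes."""
        spec = lb.SimulationSpec(n=5000, seed=17)
        responses, covs, _ = lb.simulate_cohort(spec)
        bundle = lb.build_group_table(
            lb.total_scores(responses), covs, ref_benchmarks, pool_extreme=True
        )
        for var in ("NA", "DT", "DL", "DN"):
            means = [
                bundle.continuous_summaries[var][cls].mean
                for cls in bundle.group_order
                if cls in bundle.continuous_summaries[var]
            ]
            assert (np.diff(means) > -0.05).all() and means[-1] > means[0]
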