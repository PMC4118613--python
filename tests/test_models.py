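"""Likelihood fits, effect decomposition and test statistics.

The independent oracle for the fits is an ordinary one-way group-means
regression: class means via least squares on a one-hot design, and the LR
statistic via the exact F-to-LR monotone transformation
LR = n·ln(1 + F·(k−1)/(n−k)).
"""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from fsqtl import models
from fsqtl.errors import (
    DegenerateFitError,
    IncompleteClassesError,
    NotSegregatingError,
    SparseClassError,
)
from fsqtl.types import Effects, Marker, SegType

M_LM = Marker("m_lm", SegType.LMXLL, 1, 0.0)
M_HK = Marker("m_hk", SegType.HKXHK, 1, 0.0)
M_AB = Marker("m_ab", SegType.ABXCD, 1, 0.0)
MARKERS = {
    SegType.ABXCD: M_AB,
    SegType.HKXHK: M_HK,
    SegType.LMXLL: M_LM,
    SegType.NNXNP: Marker("m_nn", SegType.NNXNP, 1, 0.0),
}


class TestFitMarker:
    def test_two_class_means_rss_sigma2(self):
        fit = models.fit_marker(
            M_LM, ["ll", "ll", "lm", "lm"], [0, 2, 4, 6], min_class_n=1
        )
        assert fit.class_means == {"ll": 1.0, "lm": 5.0}
        assert fit.rss == pytest.approx(4.0)
        assert fit.sigma2 == pytest.approx(1.0)
        assert fit.loglik == pytest.approx(
            -0.5 * 4 * (math.log(2 * math.pi * 1.0) + 1)
        )

    def test_monomorphic_marker_not_segregating(self):
        with pytest.raises(NotSegregatingError):
            models.fit_marker(M_HK, ["hh"] * 6, np.arange(6.0), min_class_n=1)

    def test_sparse_class_flags_marker_unusable(self):
        calls = ["hh"] * 6 + ["hk"] * 6 + ["kk"] * 2
        with pytest.raises(SparseClassError, match="kk"):
            models.fit_marker(M_HK, calls, np.arange(14.0), min_class_n=5)

    def test_missing_calls_and_phenotypes_dropped(self):
        fit = models.fit_marker(
            M_LM,
            ["ll", None, "lm", "lm", "ll"],
            [1.0, 9.0, 4.0, 6.0, np.nan],
            min_class_n=1,
        )
        assert fit.n == 3
        assert fit.class_counts == {"ll": 1, "lm": 2}

    def test_zero_residual_variance_degenerate(self):
        with pytest.raises(DegenerateFitError):
            models.fit_marker(
                M_LM, ["ll", "ll", "lm", "lm"], [1, 1, 2, 2], min_class_n=1
            )


class TestFitNull:
    def test_grand_mean_and_rss(self):
        fit = models.fit_null([0, 2, 4, 6])
        assert fit.class_means == {"all": 3.0}
        assert fit.rss == pytest.approx(20.0)

    def test_constant_phenotype_degenerate(self):
        with pytest.raises(DegenerateFitError):
            models.fit_null([5.0, 5.0])

    def test_null_rss_bounds_full_rss(self, rng):
        for seg, marker in MARKERS.items():
            calls = rng.choice(seg.classes, size=60).tolist()
            y = rng.normal(size=60)
            full = models.fit_marker(marker, calls, y, min_class_n=1)
            null = models.fit_null(y)
            assert null.rss >= full.rss - 1e-12


class TestOracleEquivalence:
    """fit_marker + likelihood_ratio vs a one-way regression oracle."""

    @pytest.mark.parametrize("seg", list(SegType))
    def test_matches_group_means_regression(self, seg, rng):
        marker = MARKERS[seg]
        for _ in range(200):
            n = int(rng.integers(30, 80))
            calls = rng.choice(seg.classes, size=n).tolist()
            while len(set(calls)) < seg.n_classes:
                calls = rng.choice(seg.classes, size=n).tolist()
            y = rng.normal(loc=rng.normal(scale=2), scale=1.5, size=n)
            fit = models.fit_marker(marker, calls, y, min_class_n=1)
            # least-squares oracle on a one-hot design
            X = np.array([[c == k for k in seg.classes] for c in calls], float)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            for j, k in enumerate(seg.classes):
                assert fit.class_means[k] == pytest.approx(beta[j], abs=1e-10)
            # LR oracle through the one-way ANOVA F statistic
            groups = [y[np.array(calls) == k] for k in seg.classes]
            F = stats.f_oneway(*groups).statistic
            k_, n_ = seg.n_classes, n
            lr_oracle = n_ * math.log(1 + F * (k_ - 1) / (n_ - k_))
            null = models.fit_null(y, index=fit.individual_index)
            lr, df, _ = models.likelihood_ratio(null, fit)
            assert lr == pytest.approx(lr_oracle, abs=1e-8)
            assert df == k_ - 1


def fit_from_means(marker, means, min_class_n=1):
    """A non-degenerate fit whose class means are exactly ``means``.

    Two observations per class at mean ± 1 keep the class means exact
    while leaving a nonzero residual variance.
    """
    calls, y = [], []
    for klass, m in means.items():
        calls += [klass, klass]
        y += [m - 1.0, m + 1.0]
    return models.fit_marker(marker, calls, y, min_class_n=min_class_n)


class TestDecomposeEffects:
    def test_equal_means_give_zero_effects(self):
        fit = models.fit_marker(
            M_AB,
            ["ac", "ad", "bc", "bd"] * 3,
            [7.0, 7.0, 7.0, 7.0, 7.1, 7.1, 7.1, 7.1, 6.9, 6.9, 6.9, 6.9],
            min_class_n=1,
        )
        e = models.decompose_effects(fit)
        assert (e.mu, e.a1, e.a2, e.d) == pytest.approx((7.0, 0.0, 0.0, 0.0))

    def test_four_class_solution_matches_linear_solver(self):
        means = {"ac": 4.0, "ad": 2.0, "bc": 1.0, "bd": 0.0}
        fit = fit_from_means(M_AB, means)
        # oracle: solve the 4x4 genotypic-value system directly
        A = np.array(
            [
                [1, 1, 1, 1],
                [1, 1, -1, -1],
                [1, -1, 1, -1],
                [1, -1, -1, -1],
            ],
            dtype=float,
        )
        mu, a1, a2, d = np.linalg.solve(A, np.array([4.0, 2.0, 1.0, 0.0]))
        e = models.decompose_effects(fit)
        assert (e.mu, e.a1, e.a2, e.d) == pytest.approx((mu, a1, a2, d))
        assert (e.mu, e.a1, e.a2, e.d) == pytest.approx((2.0, 1.0, 0.5, 0.5))

    def test_three_class_closed_form(self):
        fit = fit_from_means(M_HK, {"hh": 2.0, "hk": 5.0, "kk": 0.0})
        e = models.decompose_effects(fit)
        assert (e.mu, e.a1, e.d) == pytest.approx((1.0, 1.0, 4.0))
        assert e.a2 is None

    def test_testcross_midpoint(self):
        fit = fit_from_means(M_LM, {"ll": 2.0, "lm": 6.0})
        e = models.decompose_effects(fit)
        assert (e.mu, e.a1) == pytest.approx((4.0, 2.0))
        assert e.a2 is None and e.d is None

    def test_incomplete_class_set_rejected(self):
        fit = fit_from_means(M_AB, {"ac": 1.0, "ad": 2.0, "bc": 4.0})
        with pytest.raises(IncompleteClassesError):
            models.decompose_effects(fit)

    @pytest.mark.parametrize("orthogonal", [False, True])
    @pytest.mark.parametrize("seg", list(SegType))
    def test_roundtrip_through_forward_equations(self, seg, orthogonal, rng):
        """decompose_effects inverts the genotypic-value equations exactly."""
        for _ in range(50):
            vals = rng.normal(scale=3, size=4)
            e_in = Effects(
                seg_type=seg,
                mu=vals[0],
                a1=vals[1],
                a2=vals[2] if seg is SegType.ABXCD else None,
                d=(
                    vals[3]
                    if seg in (SegType.ABXCD, SegType.HKXHK)
                    else None
                ),
            )
            means = models.effects_to_class_means(
                e_in, orthogonal_dominance=orthogonal
            )
            fit = fit_from_means(MARKERS[seg], means)
            e_out = models.decompose_effects(
                fit, orthogonal_dominance=orthogonal
            )
            assert e_out.mu == pytest.approx(e_in.mu, abs=1e-12)
            assert e_out.a1 == pytest.approx(e_in.a1, abs=1e-12)
            if e_in.a2 is not None:
                assert e_out.a2 == pytest.approx(e_in.a2, abs=1e-12)
            if e_in.d is not None:
                assert e_out.d == pytest.approx(e_in.d, abs=1e-12)

    def test_verbatim_and_orthogonal_parameterizations_differ(self):
        """The default system's d is twice the orthogonal dominance contrast."""
        means = {"ac": 4.0, "ad": 2.0, "bc": 1.0, "bd": 3.0}
        fit = fit_from_means(M_AB, means)
        verbatim = models.decompose_effects(fit)
        ortho = models.decompose_effects(fit, orthogonal_dominance=True)
        assert verbatim.d == pytest.approx(2 * ortho.d)


class TestLikelihoodRatio:
    def test_identical_fits_give_zero(self):
        y = [0.0, 2.0, 4.0, 6.0]
        null = models.fit_null(y)
        lr, df, p = models.likelihood_ratio(null, null)
        assert lr == 0.0 and p == 1.0

    def test_chi_square_tail_example(self):
        """n=8, RSS halved, 2 classes: LR = 8·ln2, p from chi-square(1)."""
        calls = ["ll"] * 4 + ["lm"] * 4
        y = np.array([-1.0, 1.0, -1.0, 1.0, 1.0, 3.0, 1.0, 3.0])
        # RSS_full = 8, RSS_null = 16 by construction
        full = models.fit_marker(M_LM, calls, y, min_class_n=1)
        null = models.fit_null(y, index=full.individual_index)
        assert null.rss == pytest.approx(16.0)
        assert full.rss == pytest.approx(8.0)
        lr, df, p = models.likelihood_ratio(null, full)
        assert lr == pytest.approx(5.545177444479562, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(0.018531677751199058, abs=1e-12)

    def test_df_equals_classes_minus_one(self, rng):
        for seg, expected_df in [
            (SegType.ABXCD, 3),
            (SegType.HKXHK, 2),
            (SegType.LMXLL, 1),
        ]:
            calls = list(seg.classes) * 10
            y = rng.normal(size=len(calls))
            full = models.fit_marker(MARKERS[seg], calls, y, min_class_n=1)
            null = models.fit_null(y, index=full.individual_index)
            assert models.likelihood_ratio(null, full)[1] == expected_df

    def test_mismatched_individual_sets_rejected(self):
        y = [0.0, 2.0, 4.0, 6.0]
        full = models.fit_marker(
            M_LM, ["ll", "ll", "lm", "lm"], y, min_class_n=1
        )
        null = models.fit_null(y[:3])
        with pytest.raises(ValueError, match="subset"):
            models.likelihood_ratio(null, full)

    @given(
        c=st.floats(0.1, 50.0),
        b=st.floats(-100.0, 100.0),
        flip=st.booleans(),
    )
    def test_lr_invariant_under_affine_phenotype_transform(self, c, b, flip):
        rng = np.random.default_rng(7)
        calls = (["hh"] * 8 + ["hk"] * 16 + ["kk"] * 8)
        y = rng.normal(size=32) + np.array(
            [{"hh": 1.0, "hk": 0.4, "kk": -1.0}[k] for k in calls]
        )
        scale = -c if flip else c
        full1 = models.fit_marker(M_HK, calls, y, min_class_n=1)
        null1 = models.fit_null(y, index=full1.individual_index)
        y2 = scale * y + b
        full2 = models.fit_marker(M_HK, calls, y2, min_class_n=1)
        null2 = models.fit_null(y2, index=full2.individual_index)
        lr1 = models.likelihood_ratio(null1, full1)[0]
        lr2 = models.likelihood_ratio(null2, full2)[0]
        assert lr2 == pytest.approx(lr1, rel=1e-9)


class TestVarianceExplained:
    def test_edge_values(self):
        y = [0.0, 2.0, 4.0, 6.0]
        null = models.fit_null(y)
        assert models.variance_explained(null, null) == 0.0

    def test_identity_with_lr(self, rng):
        """R² = 1 − exp(−LR/n) exactly, for every cross type."""
        for seg, marker in MARKERS.items():
            for _ in range(25):
                calls = rng.choice(seg.classes, size=50).tolist()
                y = rng.normal(size=50) + [len(c) * 0.3 for c in calls]
                try:
                    full = models.fit_marker(marker, calls, y, min_class_n=1)
                except NotSegregatingError:
                    continue
                null = models.fit_null(y, index=full.individual_index)
                lr, _, _ = models.likelihood_ratio(null, full)
                r2 = models.variance_explained(null, full)
                assert r2 == pytest.approx(
                    1.0 - math.exp(-lr / full.n), abs=1e-12
                )


class TestDominanceRatio:
    def test_overdominant_biallelic_example(self):
        e = Effects(SegType.HKXHK, mu=0.0, a1=0.02, d=0.30)
        assert models.dominance_ratio(e) == pytest.approx(15.0)

    def test_no_dominance(self):
        e = Effects(SegType.HKXHK, mu=0.0, a1=1.0, d=0.0)
        assert models.dominance_ratio(e) == 0.0

    def test_four_class_uses_mean_absolute_additive(self):
        e = Effects(SegType.ABXCD, mu=0.0, a1=1.0, a2=3.0, d=4.0)
        assert models.dominance_ratio(e) == pytest.approx(2.0)

    def test_testcross_has_no_ratio(self):
        assert models.dominance_ratio(Effects(SegType.LMXLL, 0.0, 1.0)) is None

    def test_zero_additive_warns_infinite(self):
        e = Effects(SegType.HKXHK, mu=0.0, a1=0.0, d=0.5)
        with pytest.warns(UserWarning):
            assert models.dominance_ratio(e) == math.inf
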