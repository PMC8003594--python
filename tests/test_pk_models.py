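"""Time-activity model evaluation, family assignment, and robust fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tracedose import (
    FitOptions,
    ModelFamily,
    OrganClass,
    PKModel,
    TimeActivitySeries,
    assign_model_family,
    fit_timeactivity,
    physical_decay_constant,
    predict,
)
from tracedose.errors import InsufficientDataError, ValidationError

from conftest import ANIMALS, T_GRID, make_series

amplitudes = st.floats(0.01, 50.0)
rates = st.floats(0.003, 5.0)


def valid_models():
    return st.one_of(
        st.tuples(amplitudes, rates, rates).map(
            lambda p: PKModel(ModelFamily.UPTAKE_WASHOUT, p)
        ),
        st.tuples(amplitudes, rates).map(
            lambda p: PKModel(ModelFamily.UPTAKE_PHYSDECAY, (*p, math.log(2) / 192.6))
        ),
        st.tuples(amplitudes, rates, amplitudes, rates).map(
            lambda p: PKModel(ModelFamily.BIEXP, p)
        ),
    )


class TestPredict:
    @pytest.mark.parametrize(
        "model, t, expected",
        [
            (PKModel("uptake_washout", (10, 1, 0.1)), 0.0, 0.0),
            (PKModel("biexp", (3, 0.5, 2, 0.01)), 0.0, 5.0),
            # independent high-precision arithmetic: 10 (1-e^-6) e^-0.6
            (
                PKModel("uptake_washout", (10, 1, 0.1)),
                6.0,
                10.0 * (1.0 - math.exp(-6.0)) * math.exp(-0.6),
            ),
        ],
    )
    def test_closed_form_values(self, model, t, expected):
        assert predict(model, t) == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            predict(PKModel("biexp", (1, 1, 1, 1)), -0.1)

    @pytest.mark.parametrize(
        "family, params",
        [
            ("biexp", (1.0, -0.5, 1.0, 0.1)),
            ("biexp", (-1.0, 0.5, 1.0, 0.1)),
            ("uptake_washout", (1.0, 1.0, 0.0)),
            ("uptake_washout", (1.0, 1.0)),
        ],
    )
    def test_invalid_parameters_rejected(self, family, params):
        with pytest.raises(ValidationError):
            PKModel(family, params)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(model=valid_models(), t=st.floats(0.0, 500.0))
    def test_nonnegative_and_continuous(self, model, t):
        y = predict(model, t)
        assert y >= 0.0
        # continuity: small step moves the value by O(step)
        y2 = predict(model, t + 1e-7)
        assert abs(y2 - y) < 1e-4 * max(1.0, sum(model.params))

    def test_large_uptake_rate_limit_is_pure_decay(self):
        """b -> inf turns uptake-physdecay into a * exp(-lambda t)."""
        lam = physical_decay_constant(192.6)
        m = PKModel("uptake_physdecay", (7.0, 1e6, lam))
        t = np.array([0.5, 1.0, 6.0, 72.0])
        expected = 7.0 * np.exp(-lam * t)
        np.testing.assert_allclose(predict(m, t), expected, rtol=1e-6)


class TestDecayConstantAndFamilies:
    def test_half_life_one_hour(self):
        assert physical_decay_constant(1.0) == pytest.approx(math.log(2.0))

    def test_iodine131_default(self):
        assert physical_decay_constant(192.6) == pytest.approx(
            math.log(2.0) / 192.6, rel=1e-15
        )

    def test_rate_vanishes_monotonically_with_half_life(self):
        hl = np.array([1.0, 10.0, 1e3, 1e6, 1e9])
        lam = np.array([physical_decay_constant(h) for h in hl])
        assert np.all(np.diff(lam) < 0) and lam[-1] < 1e-9

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_half_life_rejected(self, bad):
        with pytest.raises(ValidationError):
            physical_decay_constant(bad)

    @pytest.mark.parametrize(
        "organ_class, family",
        [
            (OrganClass.TUMOR, ModelFamily.UPTAKE_WASHOUT),
            (OrganClass.EYE, ModelFamily.UPTAKE_PHYSDECAY),
            (OrganClass.OTHER, ModelFamily.BIEXP),
        ],
    )
    def test_family_assignment(self, organ_class, family):
        assert assign_model_family(organ_class) is family

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            assign_model_family("gland")


NOISE_FREE_CASES = [
    PKModel("biexp", (5.0, 0.8, 1.0, 0.02)),
    PKModel("uptake_washout", (30.4, 0.74, 0.0087)),
    PKModel("uptake_physdecay", (9.0, 0.35, math.log(2) / 192.6)),
]


class TestFitting:
    @pytest.mark.parametrize("truth", NOISE_FREE_CASES, ids=lambda m: m.family.value)
    def test_noise_free_recovery_is_exact(self, truth):
        series = make_series(truth)
        res = fit_timeactivity(series, truth.family)
        assert res.converged
        np.testing.assert_allclose(res.model.params, truth.params, rtol=1e-6)
        np.testing.assert_allclose(res.robust_weights, 1.0)

    @pytest.mark.parametrize("truth", NOISE_FREE_CASES, ids=lambda m: m.family.value)
    def test_refit_of_own_predictions_is_idempotent(self, truth):
        noisy = make_series(truth, cv=0.10, seed=4)
        first = fit_timeactivity(noisy, truth.family)
        clean = TimeActivitySeries(
            "organ", noisy.times, predict(first.model, noisy.times), noisy.animals
        )
        second = fit_timeactivity(clean, truth.family)
        np.testing.assert_allclose(second.model.params, first.model.params, rtol=1e-6)

    def test_fit_invariant_to_point_ordering(self, biexp_truth):
        series = make_series(biexp_truth, cv=0.10, seed=7)
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(series))
        shuffled = TimeActivitySeries(
            "organ",
            series.times[perm],
            series.values[perm],
            tuple(series.animals[i] for i in perm),
        )
        a = fit_timeactivity(series, "biexp")
        b = fit_timeactivity(shuffled, "biexp")
        np.testing.assert_allclose(a.model.params, b.model.params, rtol=1e-10)

    def test_robust_fit_resists_gross_outlier(self, biexp_truth):
        series = make_series(biexp_truth, cv=0.05, seed=3)
        values = series.values.copy()
        values[7] *= 10.0  # one animal counted 10x too high
        corrupted = TimeActivitySeries("organ", series.times, values, series.animals)
        truth = np.array(biexp_truth.params)
        robust = fit_timeactivity(corrupted, "biexp")
        plain = fit_timeactivity(corrupted, "biexp", FitOptions(robust=False))
        err_robust = np.linalg.norm((np.array(robust.model.params) - truth) / truth)
        err_plain = np.linalg.norm((np.array(plain.model.params) - truth) / truth)
        assert err_robust < err_plain
        assert robust.robust_weights.min() < 0.5  # the outlier was down-weighted

    def test_too_few_timepoints_raises(self, biexp_truth):
        t = np.array([1.0, 6.0, 24.0])
        series = TimeActivitySeries(
            "organ", t, predict(biexp_truth, t), ("a", "b", "c")
        )
        with pytest.raises(InsufficientDataError):
            fit_timeactivity(series, "biexp")

    def test_degenerate_biexp_collapses_to_monoexponential(self):
        # mono-exponential data: the two rates coincide and are unidentifiable
        mono = PKModel("biexp", (4.0, 0.1, 0.0, 0.1))
        series = make_series(mono)
        res = fit_timeactivity(series, "biexp")
        if res.degenerate:
            a, b, c, d = res.model.params
            assert c == 0.0 and b == d
        # either way the fitted curve must match the data
        np.testing.assert_allclose(
            predict(res.model, series.times), series.values, rtol=1e-5, atol=1e-8
        )
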