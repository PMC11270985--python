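import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import optimize

import multistress as ms
from multistress.sam import GeneralStressEstimate

DOSES = [0.0, 0.01, 0.1, 1.0, 10.0, 100.0, 215.0, 465.0, 1000.0]


class TestCapacityTransforms:
    def test_boundary_conditions(self, capacity):
        assert ms.stress_to_survival(0.0, capacity) == 1.0
        assert ms.stress_to_survival(1.0, capacity) == 0.0
        assert ms.stress_to_survival(1.5, capacity) == 0.0

    def test_symmetric_midpoint(self, capacity):
        assert ms.stress_to_survival(0.5, capacity) == pytest.approx(0.5)
        assert ms.survival_to_stress(0.5, capacity) == pytest.approx(0.5)

    def test_negative_stress_rejected(self, capacity):
        with pytest.raises(ms.DomainError):
            ms.stress_to_survival(-0.1, capacity)

    def test_inverse_round_trip_on_grid(self, capacity):
        grid = np.linspace(0.0, 1.0, 1000)
        for p in grid:
            back = ms.stress_to_survival(
                ms.survival_to_stress(float(p), capacity), capacity)
            assert back == pytest.approx(p, abs=1e-9)

    def test_strictly_decreasing_inside_unit_interval(self, capacity):
        s = np.linspace(0.01, 0.99, 200)
        surv = capacity.survival(s)
        assert np.all(np.diff(surv) < 0)

    def test_asymmetric_shapes_allowed(self):
        skewed = ms.StressCapacityDistribution(2.0, 5.0)
        assert ms.stress_to_survival(0.5, skewed) != pytest.approx(0.5, abs=0.01)


def test_total_general_stress_sum_and_permutation():
    assert ms.total_general_stress([0.3, 0.2]) == pytest.approx(0.5)
    assert ms.total_general_stress([]) == 0.0
    rng = np.random.default_rng(0)
    vals = rng.uniform(0, 0.5, 10)
    assert ms.total_general_stress(vals) == pytest.approx(
        ms.total_general_stress(vals[::-1]))
    levels = [ms.StressLevel(0.1, "toxicant"), ms.StressLevel(0.2, "temperature")]
    assert ms.total_general_stress(levels) == pytest.approx(0.3)


def test_stress_level_rejects_negative():
    with pytest.raises(ms.ValidationError):
        ms.StressLevel(-0.1)


class TestQuantification:
    def test_identical_combined_gives_zero(self, symmetric_curve, capacity):
        alone = {float(t): float(symmetric_curve.survival_at(t)) for t in DOSES}
        est = ms.quantify_stressor_stress(symmetric_curve, alone, capacity)
        assert isinstance(est, GeneralStressEstimate)
        assert est.value == pytest.approx(0.0, abs=1e-12)

    def test_exact_recovery_from_forward_model(self, symmetric_curve, capacity):
        s_true = 0.2
        forward = ms.sam_predict_curve(symmetric_curve, s_true, capacity)
        combined = {float(t): float(forward(t)) for t in DOSES}
        est = ms.quantify_stressor_stress(symmetric_curve, combined, capacity)
        assert est.value == pytest.approx(s_true, abs=1e-10)
        assert set(est.per_dose.columns) >= {"dose", "stress_extra", "censored"}

    def test_recovery_from_binomial_counts(self, symmetric_curve, capacity):
        rng = np.random.default_rng(11)
        forward = ms.sam_predict_curve(symmetric_curve, 0.2, capacity)
        n = 20000
        import pandas as pd
        table = pd.DataFrame({
            "clothianidin_conc": DOSES,
            "n_exposed": n,
            "n_immobile": [rng.binomial(n, 1.0 - float(forward(t)))
                           for t in DOSES],
        })
        est = ms.quantify_stressor_stress(symmetric_curve, table, capacity)
        assert est.value == pytest.approx(0.2, abs=0.02)

    def test_negative_shift_floored_at_zero(self, symmetric_curve, capacity):
        better = {float(t): min(1.0, float(symmetric_curve.survival_at(t)) + 0.05)
                  for t in DOSES}
        est = ms.quantify_stressor_stress(symmetric_curve, better, capacity)
        assert est.value == 0.0

    def test_saturated_window_raises(self, capacity):
        curve = ms.LL5Curve(2.0, 0.0, 1.0, 100.0, 1.0)
        dead = {float(t): 0.0 for t in DOSES}
        with pytest.raises(ms.DomainError):
            ms.quantify_stressor_stress(curve, dead, capacity)


class TestSamPrediction:
    def test_zero_stress_is_identity(self, symmetric_curve, capacity):
        curve = ms.sam_predict_curve(symmetric_curve, 0.0, capacity)
        grid = np.geomspace(0.1, 1000, 50)
        assert np.allclose(curve(grid), symmetric_curve.survival_at(grid),
                           atol=1e-12)
        assert ms.sam_predict_ec50(symmetric_curve, 0.0, capacity) == \
            pytest.approx(symmetric_curve.ec(50.0).dose, rel=1e-9)

    def test_control_survival_drop_symmetric(self, symmetric_curve, capacity):
        curve = ms.sam_predict_curve(symmetric_curve, 0.5, capacity)
        assert float(curve(0.0)) == pytest.approx(0.5)

    def test_predicted_curve_below_unstressed(self, symmetric_curve, capacity):
        curve = ms.sam_predict_curve(symmetric_curve, 0.25, capacity)
        grid = np.geomspace(0.01, 1e4, 200)
        assert np.all(curve(grid) <= symmetric_curve.survival_at(grid) + 1e-12)

    def test_ec50_matches_root_oracle(self, symmetric_curve, capacity):
        s = 0.17
        pred = ms.sam_predict_ec50(symmetric_curve, s, capacity)
        forward = ms.sam_predict_curve(symmetric_curve, s, capacity)
        n0 = float(forward(0.0))
        n_inf = float(capacity.survival(capacity.stress(0.0) + s))
        target = 0.5 * (n0 + n_inf)
        oracle = np.exp(optimize.brentq(
            lambda lt: float(forward(np.exp(lt))) - target, -20, 30,
            xtol=1e-12))
        assert pred == pytest.approx(oracle, rel=1e-9)

    def test_nonincreasing_in_stress(self, symmetric_curve, capacity):
        preds = [ms.sam_predict_ec50(symmetric_curve, s, capacity)
                 for s in (0.0, 0.1, 0.2, 0.3, 0.4)]
        assert all(a >= b - 1e-9 for a, b in zip(preds, preds[1:]))

    def test_relative_to_unstressed_control_mode(self, symmetric_curve, capacity):
        pred = ms.sam_predict_ec50(symmetric_curve, 0.2, capacity,
                                   relative_to="unstressed_control")
        assert pred < ms.sam_predict_ec50(symmetric_curve, 0.2, capacity)
        with pytest.raises(ms.DomainError):
            ms.sam_predict_ec50(symmetric_curve, 0.6, capacity,
                                relative_to="unstressed_control")


@given(
    b=st.floats(1.0, 4.0), e=st.floats(5.0, 500.0),
    f=st.floats(0.5, 2.0), c=st.floats(0.0, 0.1),
    s_env=st.floats(0.02, 0.35),
    alpha=st.floats(1.5, 5.0), beta=st.floats(1.5, 5.0),
)
def test_self_consistency_mdr_is_one(b, e, f, c, s_env, alpha, beta):
    """Quantifying an added stressor's General-Stress from a condition's own
    forward-generated data and predicting with it reproduces the observed
    EC50 exactly (MDR = 1)."""
    curve = ms.LL5Curve(b, c, 1.0, e, f)
    dist = ms.StressCapacityDistribution(alpha, beta)
    forward = ms.sam_predict_curve(curve, s_env, dist)
    combined = {float(t): float(forward(t)) for t in DOSES}
    est = ms.quantify_stressor_stress(curve, combined, dist)
    predicted = ms.sam_predict_ec50(curve, est.value, dist)
    n0 = float(forward(0.0))
    n_inf = float(dist.survival(dist.stress(0.0) + s_env))
    target = 0.5 * (n0 + n_inf)
    observed = np.exp(optimize.brentq(
        lambda lt: float(forward(np.exp(lt))) - target,
        np.log(e) - 40, np.log(e) + 40, xtol=1e-13))
    assert predicted / observed == pytest.approx(1.0, abs=1e-6)
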