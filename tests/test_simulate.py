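import numpy as np
import pandas as pd
import pytest
from scipy import stats

import multistress as ms
from multistress.doseresponse import LogLogistic5, ll5_effect


def test_identical_seed_identical_table(default_config, default_table):
    again, _ = ms.generate_experiment(ms.SyntheticConfig(seed=0))
    pd.testing.assert_frame_equal(default_table, again)


def test_different_seed_differs():
    t1, _ = ms.generate_experiment(ms.SyntheticConfig(seed=1))
    t2, _ = ms.generate_experiment(ms.SyntheticConfig(seed=2))
    assert not t1["n_immobile"].equals(t2["n_immobile"])


def test_full_factorial_shape(default_table):
    # 9 doses x 3 prochloraz x 3 temperatures x (4 + 8 streams) x 3 replicates
    assert len(default_table) == 9 * 3 * 3 * (4 + 8) * 3
    assert set(default_table["population"]) == {"reference", "agricultural"}
    per_treat = default_table.groupby(
        ["population", "temperature", "prochloraz_conc", "clothianidin_conc"]
    )["n_exposed"].sum()
    # 12 animals per stream population and treatment
    assert (per_treat.loc["reference"] == 12 * 4).all()
    assert (per_treat.loc["agricultural"] == 12 * 8).all()
    per_stream = default_table.groupby(
        ["population", "stream", "temperature", "prochloraz_conc",
         "clothianidin_conc"])["n_exposed"].sum()
    assert (per_stream == 12).all()


def test_zero_stress_reduces_to_bare_curve(default_config):
    cfg = ms.SyntheticConfig(
        stress_prochloraz={0.0: 0.0, 1.0: 0.0, 10.0: 0.0},
        stress_temperature={16.0: 0.0, 19.0: 0.0, 22.0: 0.0},
        stress_adaptation=0.0)
    pop = cfg.populations["reference"]
    doses = np.array(cfg.doses)
    expected = ms.expected_survival(cfg, "reference", 19.0, 10.0, doses)
    bare = 1.0 - ll5_effect(doses, pop.slope_b, pop.lower_c, pop.upper_d,
                            pop.ec50, pop.asymmetry_f)
    assert np.allclose(expected, bare, atol=1e-12)


def test_expected_immobility_monotone_in_dose_and_stress(default_config):
    cfg = default_config
    doses = np.array(cfg.doses)
    surv = ms.expected_survival(cfg, "reference", 16.0, 0.0, doses)
    assert np.all(np.diff(1.0 - surv) >= 0)  # nondecreasing in dose
    for dose in (10.0, 100.0):
        by_proch = [float(ms.expected_survival(cfg, "reference", 16.0, p, dose))
                    for p in (0.0, 1.0, 10.0)]
        by_temp = [float(ms.expected_survival(cfg, "reference", t, 0.0, dose))
                   for t in (16.0, 19.0, 22.0)]
        assert by_proch == sorted(by_proch, reverse=True)
        assert by_temp == sorted(by_temp, reverse=True)


def test_large_n_recovers_configured_ec50s():
    cfg = ms.SyntheticConfig(
        seed=21, n_per_treatment=3000, n_replicates=3,
        n_streams={"reference": 1, "agricultural": 1},
        stress_prochloraz={0.0: 0.0, 1.0: 0.0, 10.0: 0.0},
        stress_temperature={16.0: 0.0, 19.0: 0.0, 22.0: 0.0},
        stress_adaptation=0.0)
    table, _ = ms.generate_experiment(cfg)
    for pop, true_ec50 in (("reference", 67.0), ("agricultural", 148.0)):
        sub = table[(table.population == pop) & (table.temperature == 16.0)
                    & (table.prochloraz_conc == 0.0)]
        est = LogLogistic5.from_table(sub).fit().ec(50.0, ci="profile")
        assert est.ci_low <= true_ec50 <= est.ci_high


def test_temperature_stress_lowers_fitted_ec50_in_expectation():
    """Monte-Carlo sign test: at the default warming stress the fitted EC50
    at 19 °C falls below the 16 °C one in clearly more than half of runs."""
    wins = 0
    n_seeds = 50
    for seed in range(n_seeds):
        cfg = ms.SyntheticConfig(seed=seed)
        table, _ = ms.generate_experiment(cfg)
        ec = {}
        for temp in (16.0, 19.0):
            sub = table[(table.population == "reference")
                        & (table.temperature == temp)
                        & (table.prochloraz_conc == 0.0)]
            ec[temp] = LogLogistic5.from_table(sub).fit().ec(50, ci="none").dose
        wins += ec[19.0] < ec[16.0]
    assert stats.binomtest(wins, n_seeds, 0.5,
                           alternative="greater").pvalue < 0.01


def test_invalid_config_names_field():
    with pytest.raises(ms.ValidationError, match="n_per_treatment"):
        ms.SyntheticConfig(n_per_treatment=0)
    with pytest.raises(ms.ValidationError, match="stress_adaptation"):
        ms.SyntheticConfig(stress_adaptation=-0.1)
    with pytest.raises(ms.ValidationError, match="temperature"):
        ms.SyntheticConfig(temperatures=(16.0, 25.0))


def test_cell_substreams_stable_under_grid_extension():
    """Adding a prochloraz level must not perturb other cells' draws."""
    base_cfg = ms.SyntheticConfig(seed=9)
    ext_cfg = ms.SyntheticConfig(
        seed=9, prochloraz_levels=(0.0, 1.0, 10.0, 30.0),
        stress_prochloraz={0.0: 0.0, 1.0: 0.04, 10.0: 0.10, 30.0: 0.15})
    base, _ = ms.generate_experiment(base_cfg)
    ext, _ = ms.generate_experiment(ext_cfg)
    keys = ["population", "stream", "temperature", "prochloraz_conc",
            "clothianidin_conc", "replicate"]
    merged = base.merge(ext, on=keys, suffixes=("_base", "_ext"))
    assert len(merged) == len(base)
    assert (merged["n_immobile_base"] == merged["n_immobile_ext"]).all()


def test_ground_truth_sidecar_contents(default_config):
    _, truth = ms.generate_experiment(default_config)
    assert truth["populations"]["reference"]["ec50"] == 67.0
    assert truth["populations"]["agricultural"]["ec50"] == 148.0
    assert len(truth["expected_survival"]) == 9 * 3 * 3 * 2
    assert "synthetic" in truth["note"]


class TestSiteTable:
    def test_noise_free_regression_is_exact(self):
        frame = ms.generate_site_table(12, noise_sd=0.0, seed=1)
        reg = ms.linear_regression(frame["log_tu_max"],
                                   frame["community_index"])
        assert reg.r2_adj == pytest.approx(1.0, abs=1e-9)
        assert reg.slope == pytest.approx(-0.12, abs=1e-12)

    def test_slope_recovered_at_n_100(self):
        frame = ms.generate_site_table(100, noise_sd=0.05, seed=2)
        reg = ms.linear_regression(frame["log_tu_max"],
                                   frame["community_index"])
        x = frame["log_tu_max"].to_numpy()
        resid = (frame["community_index"]
                 - (reg.intercept + reg.slope * x)).to_numpy()
        se = np.sqrt(resid @ resid / (100 - 2)
                     / ((x - x.mean()) @ (x - x.mean())))
        assert abs(reg.slope - (-0.12)) < 1.984 * se

    def test_site_count_echo_and_minimum(self):
        assert len(ms.generate_site_table(12, seed=0)) == 12
        with pytest.raises(ms.ValidationError):
            ms.generate_site_table(2)
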