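import numpy as np
import pandas as pd
import pytest

from fruitflux import (
    CampaignScenario,
    SeasonalConductanceModel,
    WeatherScenario,
    bootstrap_ci,
    build_conductance_dataset,
    fit_seasonal_model,
    fit_with_bootstrap,
    generate_weather,
    infer_conductance,
    interpolate_conductance,
    predict_E,
)
from fruitflux.conductance import observations_from_conductance
from fruitflux.errors import (
    DomainError,
    ExtrapolationWarning,
    FitError,
    PairingError,
    PercentileFallbackWarning,
    UndefinedConductanceError,
)

CAMPAIGN_DAYS = (23, 35, 49, 65, 94, 140)
ALPHA, BETA = 13400.0, -1.90


def power_law_obs(n_per_day=100, sigma=0.0, seed=0):
    """Conductance samples drawn exactly (or lognormally) from the power law."""
    rng = np.random.default_rng(seed)
    tau = np.repeat(CAMPAIGN_DAYS, n_per_day).astype(float)
    G = ALPHA * tau**BETA
    if sigma > 0.0:
        G = G * np.exp(rng.normal(0.0, sigma, size=tau.size))
    return observations_from_conductance(tau, G)


class TestInferConductance:
    def test_zero_flux(self):
        assert infer_conductance(0.0, 0.01) == 0.0

    def test_division(self):
        assert infer_conductance(0.4, 0.01155) == pytest.approx(
            34.63203463203464, rel=1e-12
        )

    def test_round_trip_with_prediction(self):
        model = SeasonalConductanceModel(
            alpha=ALPHA, beta=BETA, adj_r2=1.0, n_obs=6, tau_range=(23.0, 140.0)
        )
        from fruitflux import delta_pw

        d = delta_pw(22.0, 40.0)
        E = predict_E(model, 50.0, 22.0, 40.0)
        G = interpolate_conductance(model, 50.0)
        assert infer_conductance(E, d) == pytest.approx(G, rel=1e-12)

    def test_nonpositive_driving_force(self):
        with pytest.raises(UndefinedConductanceError):
            infer_conductance(0.4, 0.0)
        with pytest.raises(UndefinedConductanceError):
            infer_conductance(0.4, -0.01)


class TestBuildConductanceDataset:
    def test_empty_input(self, quiet_weather):
        obs = build_conductance_dataset(
            pd.DataFrame(
                columns=["fruit_id", "timestamp", "weight_g", "length_cm", "width_cm"]
            ),
            quiet_weather,
            "2022-05-23",
        )
        assert obs.empty

    def test_saturated_interval_excluded(self):
        ts = pd.date_range("2022-06-15", periods=3, freq="h")
        weather = pd.DataFrame(
            {"timestamp": ts, "T_C": 20.0, "RH_pct": 100.0, "W_ms": 1.0,
             "R_kJ_m2": 0.0}
        )
        weighings = pd.DataFrame(
            {
                "fruit_id": "f1",
                "timestamp": ts[:2],
                "weight_g": [80.0, 79.99],
                "length_cm": 6.0,
                "width_cm": 5.0,
            }
        )
        obs = build_conductance_dataset(weighings, weather, "2022-05-23")
        assert len(obs) == 1
        assert not obs["included"].iloc[0]
        assert obs["reason"].iloc[0] == "zero driving force"
        assert np.isnan(obs["G"].iloc[0])

    def test_negative_loss_flagged(self):
        ts = pd.date_range("2022-06-15", periods=3, freq="h")
        weather = pd.DataFrame(
            {"timestamp": ts, "T_C": 20.0, "RH_pct": 50.0, "W_ms": 1.0,
             "R_kJ_m2": 0.0}
        )
        weighings = pd.DataFrame(
            {
                "fruit_id": "f1",
                "timestamp": ts[:3],
                "weight_g": [80.0, 80.01, 80.0],
                "length_cm": 6.0,
                "width_cm": 5.0,
            }
        )
        obs = build_conductance_dataset(weighings, weather, "2022-05-23")
        assert obs["reason"].tolist() == ["nonpositive flux", ""]
        assert obs["included"].tolist() == [False, True]

    def test_orphaned_interval_raises(self):
        ts = pd.date_range("2022-06-15", periods=3, freq="h")
        weather = pd.DataFrame(
            {"timestamp": ts, "T_C": 20.0, "RH_pct": 50.0, "W_ms": 1.0,
             "R_kJ_m2": 0.0}
        )
        weighings = pd.DataFrame(
            {
                "fruit_id": "f1",
                "timestamp": pd.date_range("2023-06-15", periods=2, freq="h"),
                "weight_g": [80.0, 79.9],
                "length_cm": 6.0,
                "width_cm": 5.0,
            }
        )
        with pytest.raises(PairingError):
            build_conductance_dataset(weighings, weather, "2022-05-23")

    def test_noiseless_recovery_matches_truth(self, noiseless_campaign, noiseless_obs):
        _, _, truth = noiseless_campaign
        obs = noiseless_obs
        assert obs["included"].all()
        merged = obs.merge(truth, on=["fruit_id", "timestamp"], suffixes=("", "_t"))
        assert len(merged) == len(obs)
        np.testing.assert_allclose(merged["G"], merged["G_true"], rtol=1e-9)
        np.testing.assert_allclose(merged["delta_pw"], merged["delta_pw_t"], rtol=1e-12)


class TestFitSeasonalModel:
    def test_noiseless_power_law_recovery(self):
        model = fit_seasonal_model(power_law_obs())
        assert model.alpha == pytest.approx(ALPHA, rel=1e-6)
        assert model.beta == pytest.approx(BETA, rel=1e-6)
        assert model.adj_r2 == pytest.approx(1.0, abs=1e-9)
        assert model.tau_range == (23.0, 140.0)
        assert model.n_obs == 600

    def test_flat_conductance(self):
        obs = observations_from_conductance([23.0, 49.0, 94.0, 140.0], [5.0] * 4)
        model = fit_seasonal_model(obs)
        assert model.beta == pytest.approx(0.0, abs=1e-12)
        assert model.alpha == pytest.approx(5.0, rel=1e-12)

    def test_insufficient_data(self):
        with pytest.raises(FitError):
            fit_seasonal_model(observations_from_conductance([23.0, 35.0], [3.0, 2.0]))
        with pytest.raises(FitError):
            fit_seasonal_model(
                observations_from_conductance([23.0] * 5, [3.0, 2.0, 4.0, 3.0, 2.0])
            )

    def test_excluded_rows_do_not_crash_fit(self):
        obs = power_law_obs(n_per_day=10)
        bad = obs.iloc[:5].copy()
        bad["E_mmol_cm2_h"] = -0.01
        bad["included"] = False
        bad["reason"] = "nonpositive flux"
        both = pd.concat([obs, bad], ignore_index=True)
        m_all = fit_seasonal_model(obs)
        m_mixed = fit_seasonal_model(both)
        assert m_mixed.n_obs == m_all.n_obs
        assert m_mixed.alpha == pytest.approx(m_all.alpha, rel=1e-12)

    def test_log_base_invariance_against_independent_polyfit(self):
        # independent oracle: numpy polyfit on base-10 logs
        obs = power_law_obs(n_per_day=20, sigma=0.3, seed=4)
        inc = obs[obs["included"]]
        b10, a10 = np.polyfit(
            np.log10(inc["tau_days"]), np.log10(inc["G"]), 1
        )
        model = fit_seasonal_model(obs)
        assert model.beta == pytest.approx(b10, rel=1e-9)
        assert model.alpha == pytest.approx(10**a10, rel=1e-9)


class TestBootstrap:
    def test_noiseless_intervals_collapse(self):
        obs = power_law_obs(n_per_day=20)
        alpha_ci, beta_ci = bootstrap_ci(obs, n_boot=50, seed=3)
        assert alpha_ci[0] == pytest.approx(ALPHA, rel=1e-6)
        assert alpha_ci[1] == pytest.approx(ALPHA, rel=1e-6)
        assert beta_ci[0] == pytest.approx(BETA, rel=1e-6)
        assert beta_ci[1] == pytest.approx(BETA, rel=1e-6)

    def test_seed_determinism(self):
        obs = power_law_obs(n_per_day=20, sigma=0.2, seed=5)
        a1, b1 = bootstrap_ci(obs, n_boot=60, seed=42)
        a2, b2 = bootstrap_ci(obs, n_boot=60, seed=42)
        assert a1 == a2 and b1 == b2
        a3, _ = bootstrap_ci(obs, n_boot=60, seed=43)
        assert a3 != a1

    def test_intervals_bracket_point_estimate(self):
        obs = power_law_obs(n_per_day=30, sigma=0.2, seed=6)
        model = fit_with_bootstrap(obs, n_boot=100, seed=1)
        assert model.alpha_ci[0] <= model.alpha <= model.alpha_ci[1]
        assert model.beta_ci[0] <= model.beta <= model.beta_ci[1]

    def test_rescaling_equivariance(self):
        obs = power_law_obs(n_per_day=20, sigma=0.2, seed=8)
        scaled = obs.copy()
        scaled["G"] = scaled["G"] * 10.0
        scaled["E_mmol_cm2_h"] = scaled["E_mmol_cm2_h"] * 10.0
        a1, b1 = bootstrap_ci(obs, n_boot=80, seed=9)
        a2, b2 = bootstrap_ci(scaled, n_boot=80, seed=9)
        assert a2[0] == pytest.approx(10 * a1[0], rel=1e-9)
        assert a2[1] == pytest.approx(10 * a1[1], rel=1e-9)
        assert b2[0] == pytest.approx(b1[0], rel=1e-9)
        assert b2[1] == pytest.approx(b1[1], rel=1e-9)

    def test_width_shrinks_with_sample_size(self):
        # bootstrap scaling: quadrupling n should roughly halve CI width
        w = {}
        for n in (150, 600):
            obs = power_law_obs(n_per_day=n // 6, sigma=0.2, seed=11)
            _, beta_ci = bootstrap_ci(obs, n_boot=200, seed=12)
            w[n] = beta_ci[1] - beta_ci[0]
        ratio = w[150] / w[600]
        assert 1.3 < ratio < 3.2

    def test_percentile_fallback_when_one_sided(self):
        from fruitflux.conductance import _bca_interval

        boot = np.full(100, 2.0)  # every resample above the point estimate
        jack = np.zeros(20)
        with pytest.warns(PercentileFallbackWarning):
            lo, hi = _bca_interval(1.0, boot, jack)
        assert lo == hi == 2.0

    def test_parameter_validation(self):
        obs = power_law_obs(n_per_day=5)
        with pytest.raises(DomainError):
            bootstrap_ci(obs, n_boot=1)
        with pytest.raises(DomainError):
            bootstrap_ci(obs, frac=0.0)


class TestInterpolateConductance:
    @pytest.fixture()
    def model(self):
        return SeasonalConductanceModel(
            alpha=ALPHA, beta=BETA, adj_r2=0.87, n_obs=658, tau_range=(23.0, 140.0)
        )

    def test_day_23(self, model):
        # frozen: 13400*23**-1.9
        assert interpolate_conductance(model, 23.0) == pytest.approx(
            34.65946940750558, rel=1e-9
        )

    def test_day_140(self, model):
        # frozen: 13400*140**-1.9
        assert interpolate_conductance(model, 140.0) == pytest.approx(
            1.1206281574820034, rel=1e-9
        )

    def test_tau_one_returns_alpha(self, model):
        with pytest.warns(ExtrapolationWarning):
            assert interpolate_conductance(model, 1.0) == pytest.approx(
                ALPHA, rel=1e-12
            )

    def test_strictly_decreasing_grid(self, model):
        tau = np.linspace(23.0, 140.0, 500)
        g = interpolate_conductance(model, tau)
        assert np.all(np.diff(g) < 0)

    def test_domain_error(self, model):
        with pytest.raises(DomainError):
            interpolate_conductance(model, 0.0)

    def test_extrapolation_warns_not_errors(self, model):
        with pytest.warns(ExtrapolationWarning):
            val = interpolate_conductance(model, 150.0)
        assert val > 0


def test_noisy_campaign_beta_bias_small():
    """Mean fitted exponent over seeded replicates stays near generator truth."""
    betas = []
    weather = generate_weather(WeatherScenario(seed=0))
    for seed in range(10):
        cs = CampaignScenario(seed=seed)
        from fruitflux import generate_campaign

        weighings, _ = generate_campaign(cs, weather)
        obs = build_conductance_dataset(weighings, weather, cs.full_bloom)
        betas.append(fit_seasonal_model(obs).beta)
    assert abs(np.mean(betas) - BETA) < 0.05
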