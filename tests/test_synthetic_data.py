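import numpy as np
import pandas as pd
import pytest

from conespot import synthetic_data as sd
from conespot import threshold_pipeline as tp


class TestGenerateMosaic:
    def test_degenerate_all_l(self):
        spec = sd.MosaicSpec(n_rows=10, n_cols=10, global_prop_L=1.0,
                             s_fraction=0.0, unclassified_fraction=0.0, seed=1)
        m = sd.generate_mosaic(spec)
        assert set(m.types) == {"L"}

    def test_deterministic_under_seed(self):
        a = sd.generate_mosaic(sd.MosaicSpec(seed=7))
        b = sd.generate_mosaic(sd.MosaicSpec(seed=7))
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.types, b.types)
        c = sd.generate_mosaic(sd.MosaicSpec(seed=8))
        assert not np.array_equal(a.positions, c.positions)

    def test_realized_composition_within_binomial_bound(self):
        """10,000 L/M cones at pL = 1.47/2.47: realized fraction within the
        3-sigma binomial envelope (+-0.015)."""
        spec = sd.MosaicSpec(n_rows=100, n_cols=100, s_fraction=0.0,
                             unclassified_fraction=0.0,
                             global_prop_L=sd.PROP_L_SUBJECT_A, seed=12)
        m = sd.generate_mosaic(spec)
        assert m.global_prop_L() == pytest.approx(1.47 / 2.47, abs=0.015)

    @pytest.mark.parametrize("kwargs", [
        {"center_spacing": 0.0},
        {"global_prop_L": 1.2},
        {"s_fraction": 0.6, "unclassified_fraction": 0.5},
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sd.MosaicSpec(**kwargs)


class TestThresholdTruth:
    def test_noise_free_endpoint(self, observer, fundamentals):
        quiet = sd.ObserverSpec(site_noise_sd=0.0, wavelength_noise_sd=0.0)
        rng = np.random.default_rng(0)
        t = sd.simulate_threshold_truth(quiet, 1.0, 680.0, fundamentals, rng)
        exc = fundamentals.excitations()
        base = sd._baseline_intensity(quiet, exc)
        assert t == pytest.approx(base / exc["L680"])

    def test_ratio_monotone_in_prop_l(self, fundamentals):
        """threshold(680)/threshold(543) falls as pL rises, because the L
        pigment favors 680 nm more than the M pigment does."""
        quiet = sd.ObserverSpec(site_noise_sd=0.0, wavelength_noise_sd=0.0)
        rng = np.random.default_rng(0)
        pls = np.linspace(0.0, 1.0, 11)
        ratios = [
            sd.simulate_threshold_truth(quiet, p, 680.0, fundamentals, rng)
            / sd.simulate_threshold_truth(quiet, p, 543.0, fundamentals, rng)
            for p in pls
        ]
        assert np.all(np.diff(ratios) < 0)

    def test_log_noise_sd_consistency(self, fundamentals):
        """The SD of log10 threshold over many draws matches the requested
        site noise within 10%."""
        noisy = sd.ObserverSpec(site_noise_sd=0.12, wavelength_noise_sd=0.0)
        rng = np.random.default_rng(3)
        draws = np.array([
            sd.simulate_threshold_truth(noisy, 0.6, 680.0, fundamentals, rng)
            for _ in range(1000)
        ])
        assert np.std(np.log10(draws)) == pytest.approx(0.12, rel=0.10)

    def test_invalid_prop_l_rejected(self, observer, fundamentals):
        with pytest.raises(ValueError):
            sd.simulate_threshold_truth(observer, 1.5, 680.0, fundamentals,
                                        np.random.default_rng(0))


@pytest.fixture(scope="module")
def small_session(mosaic, observer):
    sess = sd.SessionSpec(n_locations=3, seed=5)
    return sd.simulate_session(mosaic, observer, sess)


class TestSimulateSession:
    def test_trial_count_per_condition(self, mosaic, observer):
        """100 trials per (site, wavelength): four 25-trial staircases."""
        sess = sd.SessionSpec(n_locations=2, staircases_per_condition=4,
                              staircase_starts=(0.25, 0.75, 0.25, 0.75),
                              seed=9)
        trials, _ = sd.simulate_session(mosaic, observer, sess)
        counts = trials.groupby(["site_id", "wavelength_nm"]).size()
        assert (counts == 100).all()

    def test_zero_jitter_passes_inclusion(self, mosaic, observer):
        sess = sd.SessionSpec(n_locations=2, delivery_jitter_sd=0.0, seed=4)
        trials, _ = sd.simulate_session(mosaic, observer, sess)
        assert (trials["max_abs_dx_arcmin"] == 0).all()
        _, rate = tp.inclusion_filter(trials)
        assert rate == 1.0

    def test_deterministic_under_seed(self, mosaic, observer, small_session):
        trials, sites = small_session
        trials2, sites2 = sd.simulate_session(
            mosaic, observer, sd.SessionSpec(n_locations=3, seed=5))
        pd.testing.assert_frame_equal(trials, trials2)
        pd.testing.assert_frame_equal(sites, sites2)

    def test_schema_consumable_without_coercion(self, small_session):
        trials, sites = small_session
        for col in ("trial_id", "site_id", "wavelength_nm",
                    "intensity_quanta_s_deg2", "max_abs_dx_arcmin",
                    "max_abs_dy_arcmin", "seen", "response"):
            assert col in trials.columns
        assert trials["intensity_quanta_s_deg2"].gt(0).all()
        assert ((trials["response"] == "not_seen") == ~trials["seen"]).all()
        est = tp.fit_thresholds(trials)
        assert len(est) == 6  # 3 sites x 2 wavelengths

    def test_steep_slope_gives_step_responses(self, mosaic):
        """A near-vertical psychometric makes detection a step at threshold."""
        obs = sd.ObserverSpec(psychometric_slope=20.0, lapse_rate=0.0,
                              site_noise_sd=0.0, wavelength_noise_sd=0.0)
        sess = sd.SessionSpec(n_locations=2, seed=6)
        trials, sites = sd.simulate_session(mosaic, obs, sess)
        truth = sites.set_index("site_id")
        for wl in (543.0, 680.0):
            sub = trials[trials["wavelength_nm"] == wl]
            alpha = truth[f"true_threshold_{int(wl)}"].loc[sub["site_id"]]
            rel = sub["intensity_quanta_s_deg2"].to_numpy() / alpha.to_numpy()
            clear = (rel < 0.7) | (rel > 1.4)
            expected = rel[clear] > 1.0
            assert np.mean(sub["seen"].to_numpy()[clear] == expected) > 0.97


class TestSimulateColorResponse:
    def test_zero_betas_give_half_probability(self):
        obs = sd.ObserverSpec(chromatic_betas=(0.0, 0.0, 0.0, 0.0))
        rng = np.random.default_rng(0)
        hits = sum(
            sd.simulate_color_response(2.0, 0.5, 1.0, obs, 680.0, rng,
                                       non_expected_rate=0.0) == "red"
            for _ in range(20000)
        )
        # 3-sigma binomial envelope around p = 0.5
        assert abs(hits / 20000 - 0.5) < 3 * 0.5 / np.sqrt(20000)

    def test_intensity_doubling_multiplies_odds(self):
        """With b1 = ln(2.94), doubling intensity multiplies the odds of the
        expected chromatic response by 2.94."""
        obs = sd.ObserverSpec(chromatic_betas=(-1.0, np.log(2.94), 0.0, 0.0))
        rng = np.random.default_rng(1)
        n = 200_000

        def rate(intensity):
            r = sum(
                sd.simulate_color_response(intensity, 0.5, 1.0, obs, 680.0,
                                           rng, non_expected_rate=0.0) == "red"
                for _ in range(n)
            ) / n
            return r

        p1, p2 = rate(1.0), rate(2.0)
        odds_factor = (p2 / (1 - p2)) / (p1 / (1 - p1))
        assert odds_factor == pytest.approx(2.94, rel=0.05)

    def test_empirical_rate_matches_logistic(self):
        from scipy.special import expit

        obs = sd.ObserverSpec()
        b0, b1, b2, b3 = obs.chromatic_betas
        eta = b0 + b1 * np.log2(3.0) + b2 * 0.8 + b3 * 1.5
        p = expit(eta)
        rng = np.random.default_rng(2)
        n = 100_000
        hits = sum(
            sd.simulate_color_response(3.0, 0.8, 1.5, obs, 680.0, rng,
                                       non_expected_rate=0.0) == "red"
            for _ in range(n)
        )
        assert abs(hits / n - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_non_expected_rate(self):
        obs = sd.ObserverSpec(chromatic_betas=(-20.0, 0.0, 0.0, 0.0))
        rng = np.random.default_rng(3)
        n = 50_000
        greens = sum(
            sd.simulate_color_response(1.0, 0.5, 1.0, obs, 680.0, rng,
                                       non_expected_rate=0.01) == "green"
            for _ in range(n)
        )
        assert greens / n == pytest.approx(0.01, abs=0.002)

    def test_invalid_intensity_rejected(self, observer):
        with pytest.raises(ValueError):
            sd.simulate_color_response(0.0, 0.5, 1.0, observer, 680.0,
                                       np.random.default_rng(0))


def test_recentered_intercepts_sum_to_zero():
    rng = np.random.default_rng(0)
    draws = sd.draw_random_intercepts(rng, (0.4, 1.0), 2, center=True)
    assert np.allclose(draws.sum(axis=1), 0.0)


def test_observer_validation():
    with pytest.raises(ValueError):
        sd.ObserverSpec(lapse_rate=0.7)
    with pytest.raises(ValueError):
        sd.ObserverSpec(psychometric_slope=-1.0)
    with pytest.raises(ValueError):
        sd.SessionSpec(trials_per_staircase=0)
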