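"""Protonation statistics, tempered reweighting and titration fits."""

import math

import numpy as np
import pytest

from phafed.analysis import (
    TitrationPoint,
    basin_visits,
    classify_frames,
    fit_coupled,
    fit_hh,
    free_energy_profile,
    his_deprot_fraction,
    ionization_energy_series,
    pka_from_trajectories,
    prediction_metrics,
    reweight_fraction,
    _coupled_protons,
)
from phafed.constants import KB
from phafed.engine import Trajectory


class TestClassification:
    def test_direct_count(self):
        assert classify_frames([0.1, 0.5, 0.9, 0.95, 0.05]) == (2, 2, 1)

    def test_all_mixed(self):
        assert classify_frames([0.5] * 7) == (0, 0, 7)

    def test_threshold_insensitivity_away_from_boundaries(self, rng):
        lam = np.concatenate([rng.uniform(0, 0.15, 100),
                              rng.uniform(0.85, 1.0, 100),
                              rng.uniform(0.3, 0.7, 50)])
        assert classify_frames(lam, 0.2, 0.8) == classify_frames(lam, 0.19, 0.81)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            classify_frames([])

    def test_visit_counting_ignores_mixed_excursions(self):
        lam = [0.1, 0.5, 0.1, 0.9, 0.5, 0.9, 0.1]
        assert basin_visits(lam) == (2, 1)


class TestReweighting:
    def test_identity_at_equal_temperatures(self):
        f, flag = reweight_fraction(300, 700, 750.0, 750.0)
        assert f == pytest.approx(0.7)
        assert not flag

    def test_power_law_mapping(self):
        # ratio 4 at T_lambda/T = 2.5 -> 4^2.5 = 32 -> 32/33
        f, _ = reweight_fraction(200, 800, 750.0, 300.0)
        assert f == pytest.approx(32.0 / 33.0, abs=1e-9)

    def test_symmetric_counts_stay_half(self):
        for t_lam in (300.0, 750.0, 1500.0):
            f, _ = reweight_fraction(500, 500, t_lam, 300.0)
            assert f == pytest.approx(0.5)

    def test_one_sided_counts_flagged(self):
        assert reweight_fraction(100, 0, 750.0, 300.0) == (0.0, True)
        assert reweight_fraction(0, 100, 750.0, 300.0) == (1.0, True)

    def test_no_classified_frames_rejected(self):
        with pytest.raises(ValueError):
            reweight_fraction(0, 0, 750.0, 300.0)

    def test_monotone_in_ratio(self):
        fs = [reweight_fraction(1000 - n, n, 1500.0, 300.0)[0]
              for n in (100, 300, 500, 700, 900)]
        assert np.all(np.diff(fs) > 0)

    def test_his_pooled_neutral_states(self):
        assert his_deprot_fraction(200, 100, 100, 750.0, 750.0)[0] == \
            pytest.approx(0.5)
        assert his_deprot_fraction(100, 0, 0, 750.0, 300.0) == (0.0, True)
        assert his_deprot_fraction(100, 300, 100, 300.0, 300.0)[0] == \
            pytest.approx(0.8)


class TestFreeEnergyProfile:
    def test_uniform_samples_flat(self, rng):
        lam = rng.uniform(0, 1, 200_000)
        centers, F = free_energy_profile(lam, 750.0, n_bins=20,
                                         lam_range=(0.0, 1.0))
        assert np.nanmax(F) < 0.25  # sampling noise bound, kJ/mol

    def test_recovers_quadratic_potential(self, rng):
        a, t_lam = 30.0, 750.0
        sigma = math.sqrt(KB * t_lam / (2 * a))
        lam = rng.normal(0.0, sigma, 500_000)
        centers, F = free_energy_profile(lam, t_lam, n_bins=30,
                                         lam_range=(-3 * sigma, 3 * sigma))
        ok = np.isfinite(F) & (np.abs(centers) < 2 * sigma)
        expected = a * centers[ok] ** 2
        assert np.allclose(F[ok], expected - expected.min(),
                           atol=0.05 * expected.max())

    def test_linear_in_temperature(self, rng):
        lam = rng.uniform(0, 1, 10_000) ** 2
        _, f1 = free_energy_profile(lam, 300.0, n_bins=15, lam_range=(0, 1))
        _, f2 = free_energy_profile(lam, 600.0, n_bins=15, lam_range=(0, 1))
        ok = np.isfinite(f1)
        assert np.allclose(f2[ok], 2 * f1[ok], atol=1e-9)

    def test_empty_bins_are_nan_not_zero(self):
        lam = np.array([0.05] * 100 + [0.95] * 100)
        _, F = free_energy_profile(lam, 300.0, n_bins=10, lam_range=(0, 1))
        assert np.isnan(F[4])

    def test_consistency_with_count_reweighting(self, rng):
        """Basin fractions via the profile route equal the count route."""
        lam = np.concatenate([rng.uniform(-0.1, 0.18, 6000),
                              rng.uniform(0.82, 1.1, 3000),
                              rng.uniform(0.3, 0.7, 800)])
        t_lam, t = 750.0, 300.0
        n_p, n_d, _ = classify_frames(lam)
        f_counts, _ = reweight_fraction(n_p, n_d, t_lam, t)
        # profile route: re-exponentiate F at T_lambda, pool mass per basin
        centers, F = free_energy_profile(lam, t_lam, n_bins=35,
                                         lam_range=(-0.2, 1.2))
        mass = np.where(np.isfinite(F), np.exp(-F / (KB * t_lam)), 0.0)
        m_p = mass[centers < 0.2].sum()
        m_d = mass[centers > 0.8].sum()
        log_r = (t_lam / t) * math.log(m_d / m_p)
        f_profile = 1.0 / (1.0 + math.exp(-log_r))
        assert f_profile == pytest.approx(f_counts, abs=1e-6)


class TestIonizationEnergy:
    def test_equal_cumulative_counts_zero(self):
        lam = np.array([0.1, 0.9] * 50)
        _, dg = ionization_energy_series(lam, 300.0, stride=10)
        assert dg[-1] == pytest.approx(0.0)

    def test_ratio_ten_gives_ln10_kbt(self):
        lam = np.array([0.9] * 100 + [0.1] * 10)
        idx, dg = ionization_energy_series(lam, 300.0, stride=110)
        assert dg[-1] == pytest.approx(-5.74338, abs=5e-4)

    def test_one_sided_prefix_is_undefined(self):
        lam = np.array([0.1] * 50 + [0.9] * 50)
        idx, dg = ionization_energy_series(lam, 300.0, stride=10)
        assert np.isnan(dg[idx <= 50]).all()
        assert np.isfinite(dg[idx > 60]).all()


def _hh_points(pka, n, ph_values, noise=0.0, rng=None):
    f = 1.0 / (1.0 + 10.0 ** (n * (pka - np.asarray(ph_values))))
    if noise:
        f = np.clip(f + rng.normal(0, noise, f.size), 0.0, 1.0)
    return [TitrationPoint(pH=p, fraction=v) for p, v in zip(ph_values, f)]


class TestHendersonHasselbalch:
    def test_exact_recovery_noiseless(self):
        fit = fit_hh(_hh_points(4.25, 1.0, np.arange(2.0, 8.0)))
        assert fit.pKa == pytest.approx(4.25, abs=1e-6)
        assert fit.hill_n == pytest.approx(1.0, abs=1e-6)

    def test_exact_recovery_fractional_hill(self):
        fit = fit_hh(_hh_points(6.0, 0.8, np.arange(3.0, 10.0)))
        assert fit.hill_n == pytest.approx(0.8, abs=1e-6)

    def test_degenerate_data_flagged_no_fit(self):
        pts = [TitrationPoint(pH=p, fraction=0.0) for p in (2.0, 3.0, 4.0)]
        fit = fit_hh(pts)
        assert not fit.converged
        assert "degenerate_no_fit" in fit.flags

    def test_monte_carlo_noise_study(self):
        """Median |error| < 0.05 at sigma = 0.02 fraction noise, 3 replicates."""
        rng = np.random.default_rng(99)
        errors = []
        for _ in range(100):
            reps = [_hh_points(4.25, 1.0, np.arange(2.0, 8.0), 0.02, rng)
                    for _ in range(3)]
            fits = [fit_hh(r).pKa for r in reps]
            errors.append(abs(np.mean(fits) - 4.25))
        assert np.median(errors) < 0.05
        assert np.mean(errors) < 0.05  # estimator bias well below tolerance


class TestCoupledTitration:
    # stepwise constants of two independent sites at pKa 3 and 5:
    # 1/K1 = 10^3 + 10^5, K1·K2 = 10^-8 (exact binomial-to-stepwise map)
    PKA1_EXACT = 8.0 - math.log10(10 ** 3 + 10 ** 5)  # 2.99568...
    PKA2_EXACT = math.log10(10 ** 3 + 10 ** 5)  # 5.00432...

    def test_uncoupled_sites_recover_stepwise_transform(self):
        ph = np.arange(1.0, 8.5, 0.5)
        pts1 = _hh_points(3.0, 1.0, ph)
        pts2 = _hh_points(5.0, 1.0, ph)
        fit = fit_coupled(pts1, pts2)
        assert fit.pKa == pytest.approx(self.PKA1_EXACT, abs=1e-6)
        assert fit.pKa2 == pytest.approx(self.PKA2_EXACT, abs=1e-6)
        # the stepwise pair approaches the independent-site values
        assert fit.pKa == pytest.approx(3.0, abs=5e-3)
        assert fit.pKa2 == pytest.approx(5.0, abs=5e-3)

    def test_identical_sites_midpoint_symmetry(self):
        assert _coupled_protons(4.0, 4.0, 4.0) == pytest.approx(1.0)

    def test_saturation_limits(self):
        assert _coupled_protons(-6.0, 3.0, 5.0) == pytest.approx(2.0, abs=1e-3)
        assert _coupled_protons(12.0, 3.0, 5.0) == pytest.approx(0.0, abs=1e-3)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            fit_coupled(_hh_points(3.0, 1.0, [2.0, 3.0, 4.0]),
                        _hh_points(5.0, 1.0, [2.0, 3.0, 5.0]))


class TestPredictionMetrics:
    def test_perfect_prediction(self):
        m = prediction_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m["MUE"], m["RMSE"], m["pearson_r"]) == (0.0, 0.0, 1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            prediction_metrics([1.0, 2.0], [1.0])

    def test_zero_variance_r_flagged(self):
        m = prediction_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert not m["r_defined"]
        assert math.isnan(m["pearson_r"])


def _synthetic_trajectory(pka, ph, t_lambda, seed, n_frames=20_000,
                          replicate=0):
    """Frames drawn from the tempered two-state distribution at T_lambda."""
    rng = np.random.default_rng(seed)
    log_r_hot = math.log(10.0) * (ph - pka) * (300.0 / t_lambda)
    f_hot = 1.0 / (1.0 + math.exp(-log_r_hot))
    deprot = rng.random(n_frames) < f_hot
    lam = np.where(deprot, rng.uniform(0.85, 1.0, n_frames),
                   rng.uniform(0.0, 0.15, n_frames))
    n = n_frames
    return Trajectory(
        times=0.02 * np.arange(1, n + 1), lam=lam[:, None],
        lambda_names=["lam_site"], env=np.zeros((n, 0)),
        gate=np.zeros((n, 0)), s=np.zeros((n, 0)), temps=np.zeros((n, 5)),
        energies=np.zeros((n, 10)),
        metadata={"pH": ph, "seed": seed, "replicate": replicate,
                  "mode": "ph_afed", "dt": 0.002, "sample_stride": 10,
                  "T_lambda": [t_lambda]},
    )


class TestPipeline:
    def test_recovers_pka_from_tempered_samples(self):
        """Closed-form tempered sampling at pKa 4.25 -> recovery within 0.05."""
        trajs = []
        for ip, ph in enumerate(np.arange(2.0, 8.0)):
            for rep in range(3):
                trajs.append(_synthetic_trajectory(
                    4.25, float(ph), 750.0, seed=100 * ip + rep,
                    replicate=rep))
        pka, std, table = pka_from_trajectories(trajs, "site", T=300.0)
        assert pka == pytest.approx(4.25, abs=0.05)
        assert std < 0.05

    def test_identical_replicates_zero_std(self):
        trajs = []
        for ip, ph in enumerate(np.arange(2.0, 8.0)):
            for rep in range(3):
                trajs.append(_synthetic_trajectory(
                    4.25, float(ph), 750.0, seed=ip, replicate=rep))
        _, std, _ = pka_from_trajectories(trajs, "site", T=300.0)
        assert std == 0.0

    def test_too_few_ph_values_rejected(self):
        trajs = [_synthetic_trajectory(4.25, 4.0, 750.0, 0),
                 _synthetic_trajectory(4.25, 5.0, 750.0, 1)]
        with pytest.raises(ValueError):
            pka_from_trajectories(trajs, "site", T=300.0)

    def test_unknown_site_rejected(self):
        trajs = [_synthetic_trajectory(4.25, 4.0, 750.0, 0)]
        with pytest.raises(KeyError):
            trajs[0].site_columns("nope")
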