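"""Synthetic-cohort generator: closed-form coupling, determinism, forward model."""

from __future__ import annotations

import numpy as np
import pytest

from oracles import bessel_ratio_series
from plvnet.bands import BETA2, get_band
from plvnet.connectivity import instantaneous_phase, plv
from plvnet.spectral import band_power, welch_psd
from plvnet.synthcohort import (SimulationSpec, control_spec, expected_plv_from_kappa,
                                make_toy_lead_field, pd_like_spec, project_to_sensors,
                                simulate_coupled_sources, simulate_group_study)


class TestExpectedPLV:
    @pytest.mark.parametrize("kappa", [0.5, 1.0, 2.0, 5.0, 10.0])
    def test_matches_independent_series_expansion(self, kappa):
        assert expected_plv_from_kappa(kappa) == pytest.approx(
            bessel_ratio_series(kappa), abs=1e-10)

    def test_limits(self):
        assert expected_plv_from_kappa(0.0) == 0.0
        assert expected_plv_from_kappa(1e6) == pytest.approx(1.0, abs=1e-5)

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            expected_plv_from_kappa(-1.0)


class TestSimulateCoupledSources:
    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SimulationSpec(duration=-5)
        with pytest.raises(ValueError):
            SimulationSpec(coupling_kappa={((0, 1), "alpha"): -2.0})
        with pytest.raises(ValueError):
            simulate_coupled_sources(SimulationSpec(duration=5))

    def test_seed_determinism(self):
        spec = SimulationSpec(n_regions=4, fs=250, duration=10.5, seed=9)
        a, _ = simulate_coupled_sources(spec)
        b, _ = simulate_coupled_sources(spec)
        assert np.array_equal(a.data, b.data)
        c, _ = simulate_coupled_sources(
            SimulationSpec(n_regions=4, fs=250, duration=10.5, seed=10))
        assert not np.array_equal(a.data, c.data)

    @pytest.mark.parametrize("kappa,tol", [(0.0, 0.05), (2.0, 0.05), (1e6, 0.05)])
    def test_measured_plv_tracks_closed_form(self, kappa, tol):
        """Measured PLV at 60 s approaches I1(k)/I0(k) for planted pairs."""
        pairs = [(0, 1), (2, 3), (4, 5)]
        spec = SimulationSpec(
            n_regions=6, fs=250, duration=60,
            coupling_kappa={(p, "beta2"): kappa for p in pairs}, seed=21)
        src, truth = simulate_coupled_sources(spec)
        phases = instantaneous_phase(src.data, BETA2, src.fs)
        measured = np.mean([plv(phases[i], phases[j]) for i, j in pairs])
        expected = expected_plv_from_kappa(kappa)
        assert truth.expected_plv[((0, 1), "beta2")] == pytest.approx(expected)
        assert measured == pytest.approx(expected, abs=tol)

    def test_plv_monotone_in_kappa(self):
        """Mean measured PLV increases with planted concentration."""
        means = []
        for kappa in (0.0, 1.0, 2.0, 5.0):
            spec = SimulationSpec(
                n_regions=4, fs=250, duration=30,
                coupling_kappa={((0, 1), "beta2"): kappa, ((2, 3), "beta2"): kappa},
                seed=3)
            src, _ = simulate_coupled_sources(spec)
            ph = instantaneous_phase(src.data, BETA2, src.fs)
            means.append(np.mean([plv(ph[0], ph[1]), plv(ph[2], ph[3])]))
        assert means == sorted(means)


class TestToyLeadField:
    def test_determinism_and_no_zero_columns(self):
        a = make_toy_lead_field(16, 20, seed=4)
        b = make_toy_lead_field(16, 20, seed=4)
        assert np.array_equal(a.gain, b.gain)
        assert not np.any(np.all(a.gain == 0, axis=0))
        assert np.isfinite(np.linalg.cond(make_toy_lead_field(20, 20, seed=1).gain))

    def test_rank_is_sensor_count(self, toy_lead_field):
        """A 32 x 68 toy gain has full row rank (independent SVD check)."""
        s = np.linalg.svd(toy_lead_field.gain, compute_uv=False)
        assert np.sum(s > s[0] * 1e-10) == 32

    def test_minimum_sizes_enforced(self):
        with pytest.raises(ValueError):
            make_toy_lead_field(3, 10)


class TestProjectToSensors:
    def test_identity_gain_passthrough(self):
        src, _ = simulate_coupled_sources(
            SimulationSpec(n_regions=4, fs=250, duration=10, noise_sd=0.1, seed=2))
        lf = make_toy_lead_field(4, 4, seed=0)
        lf.gain = np.eye(4)
        rec = project_to_sensors(src, lf, sensor_noise_sd=0.0)
        assert np.allclose(rec.data, src.data)

    def test_sensor_covariance_matches_forward_model(self, toy_lead_field):
        """Noiseless sensor covariance equals G Cov(src) G' (matrix oracle)."""
        rng = np.random.default_rng(0)
        data = rng.normal(size=(68, 4000))
        from conftest import make_source_activity
        src = make_source_activity(data, fs=250.0)
        rec = project_to_sensors(src, toy_lead_field, sensor_noise_sd=0.0)
        gain = toy_lead_field.gain
        expected = gain @ np.cov(data) @ gain.T
        assert np.allclose(np.cov(rec.data), expected, rtol=1e-10)

    def test_linearity_in_gain(self, toy_lead_field):
        from conftest import make_source_activity
        import copy
        src = make_source_activity(np.random.default_rng(1).normal(size=(68, 500)),
                                   fs=250.0)
        rec1 = project_to_sensors(src, toy_lead_field)
        doubled = copy.deepcopy(toy_lead_field)
        doubled.gain = 2 * doubled.gain
        rec2 = project_to_sensors(src, doubled)
        assert np.allclose(rec2.data, 2 * rec1.data)

    def test_dimension_mismatch_rejected(self, toy_lead_field):
        from conftest import make_source_activity
        src = make_source_activity(np.zeros((5, 500)), fs=250.0)
        with pytest.raises(ValueError, match="mismatch"):
            project_to_sensors(src, toy_lead_field)


class TestGroupStudy:
    def test_group_sizes_and_pairing_validation(self):
        planted = (0, 1, 2)
        with pytest.raises(ValueError):
            simulate_group_study(
                control_spec(n_regions=4, fs=250, duration=10),
                pd_like_spec("OFF", n_regions=4, fs=250, duration=10,
                             planted_regions=planted),
                pd_like_spec("ON", n_regions=4, fs=250, duration=10,
                             planted_regions=planted),
                n_per_group=1)
        with pytest.raises(ValueError, match="share their seed"):
            simulate_group_study(
                control_spec(n_regions=4, fs=250, duration=10),
                pd_like_spec("OFF", n_regions=4, fs=250, duration=10, seed=1,
                             planted_regions=planted),
                pd_like_spec("ON", n_regions=4, fs=250, duration=10, seed=2,
                             planted_regions=planted),
                n_per_group=3)

    def test_identical_specs_give_null_effects(self):
        hc = control_spec(n_regions=4, fs=250, duration=10, seed=0)
        study = simulate_group_study(hc, hc, hc, n_per_group=2, sources_only=True)
        assert all(r == pytest.approx(1.0)
                   for r in study.ground_truth.expected_band_power_ratio.values())
        assert not study.ground_truth.planted_edges

    def test_paired_conditions_share_unplanted_bands(self):
        """OFF/ON differ only in the planted beta2 coupling: the theta
        content of the within-subject difference is essentially zero."""
        regions = tuple(range(5, 10))
        off = pd_like_spec("OFF", n_regions=12, fs=250, duration=12, seed=8,
                           planted_regions=regions)
        on = pd_like_spec("ON", n_regions=12, fs=250, duration=12, seed=8,
                          planted_regions=regions)
        study = simulate_group_study(control_spec(n_regions=12, fs=250, duration=12,
                                                  seed=8),
                                     off, on, n_per_group=2, sources_only=True)
        diff = study.sources["PD_OFF"][0].data - study.sources["PD_ON"][0].data
        psd = welch_psd(diff, 250.0)
        theta_p = band_power(psd, get_band("theta")).mean()
        beta2_p = band_power(psd, get_band("beta2")).mean()
        assert beta2_p > 100 * max(theta_p, 1e-12)

    def test_planted_theta_power_ratio_realized(self):
        """Amplitude ratio 1.5 yields a band-power ratio near 1.5^2 = 2.25."""
        n = 12
        hc = control_spec(n_regions=8, fs=250, duration=60, seed=40)
        off = pd_like_spec("OFF", n_regions=8, fs=250, duration=60, seed=41,
                           planted_regions=(0, 1))
        on = pd_like_spec("ON", n_regions=8, fs=250, duration=60, seed=41,
                          planted_regions=(0, 1))
        study = simulate_group_study(hc, off, on, n_per_group=n, sources_only=True)
        theta = get_band("theta")

        def mean_theta(cond):
            return np.mean([band_power(welch_psd(s.data, s.fs), theta).mean()
                            for s in study.sources[cond]])

        ratio = mean_theta("PD_OFF") / mean_theta("HC")
        assert study.ground_truth.expected_band_power_ratio["theta"] == pytest.approx(2.25)
        assert ratio == pytest.approx(2.25, rel=0.10)
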