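"""Ground-truth generators: analytic oracles, determinism, and invariants."""

import dataclasses
import math

import numpy as np
import pytest

from immunopet.core import O15_FRAME_SCHEDULE, ZR89, FrameSchedule
from immunopet.dosimetry import OrganBiokinetics, residence_time
from immunopet.plasma import fit_intact_fraction
from immunopet.simulate import (
    InputFunctionParams,
    IntactFractionParams,
    OrganParams,
    PlasmaParams,
    SimulationConfig,
    analytic_input_auc,
    generate_input_function,
    generate_organ_biokinetics,
    generate_plasma_series,
    generate_tissue_tac,
    input_function,
)


class TestInputFunction:
    def test_zero_amplitude_gives_zero_curve(self):
        cfg = SimulationConfig(
            input_function_params=InputFunctionParams(peak_amplitude_kBq_per_mL=0.0)
        )
        tac = generate_input_function(cfg)
        assert np.all(tac.concentration_kBq_per_mL == 0)

    def test_peak_lands_in_expected_frame(self, sim_config):
        p = sim_config.input_function_params
        tac = generate_input_function(sim_config)
        peak_t = p.t0_s + p.peak_time_s
        mids = tac.schedule.mid_times_s
        # argmax within the frame closest to the analytic peak time
        assert abs(mids[np.argmax(tac.concentration_kBq_per_mL)] - peak_t) <= 4.0
        assert peak_t < 60.0  # bolus peaks within the first minute

    def test_auc_matches_closed_form(self, sim_config):
        p = sim_config.input_function_params
        c_a = input_function(p)
        t = np.linspace(0.0, 300.0, 600_001)  # minutes, far past any washout
        numeric = np.trapezoid(c_a(t), t)
        assert numeric == pytest.approx(analytic_input_auc(p), rel=5e-3)

    def test_zero_before_bolus_arrival(self, sim_config):
        c_a = input_function(sim_config.input_function_params)
        t0_min = sim_config.input_function_params.t0_s / 60.0
        assert np.all(c_a(np.linspace(0, t0_min, 50)) == 0)


class TestTissueTac:
    def test_k1_zero_gives_zero_curve(self, input_tac):
        cfg = SimulationConfig(tissue_params={"r": (0.0, 1.0)})
        tac = generate_tissue_tac(cfg, "r", input_tac)
        assert np.all(tac.concentration_kBq_per_mL == 0)

    def test_constant_input_approaches_k1_over_k2(self):
        # long frames so late midpoints reach the plateau K1/k2 = 0.5
        sched = FrameSchedule.from_blocks([(40, 30.0)])
        from immunopet.core import O15, TimeActivityCurve

        const = TimeActivityCurve("arterial_input", sched, np.ones(40), True, O15)
        cfg = SimulationConfig(tissue_params={"r": (2.0, 4.0)})
        tac = generate_tissue_tac(cfg, "r", const, noisy=False)
        t_mid = sched.mid_times_min
        # closed form applies after the interpolant's left edge (first mid-time)
        expected = 0.5 * (1 - np.exp(-4.0 * (t_mid - t_mid[0])))
        assert tac.concentration_kBq_per_mL[-5:] == pytest.approx(expected[-5:], rel=2e-3)

    def test_missing_region_rejected(self, sim_config, input_tac):
        with pytest.raises(KeyError):
            generate_tissue_tac(sim_config, "no-such-region", input_tac)

    def test_noisy_output_bitwise_reproducible(self, sim_config, input_tac):
        region = next(iter(sim_config.tissue_params))
        a = generate_tissue_tac(sim_config, region, input_tac, noisy=True)
        b = generate_tissue_tac(sim_config, region, input_tac, noisy=True)
        assert np.array_equal(a.concentration_kBq_per_mL, b.concentration_kBq_per_mL)

    def test_noise_streams_differ_between_regions(self, input_tac):
        cfg = SimulationConfig(seed=7, tissue_params={"a": (2.0, 2.0), "b": (2.0, 2.0)})
        ta = generate_tissue_tac(cfg, "a", input_tac, noisy=True)
        tb = generate_tissue_tac(cfg, "b", input_tac, noisy=True)
        assert not np.array_equal(ta.concentration_kBq_per_mL, tb.concentration_kBq_per_mL)

    def test_noise_free_matches_independent_convolution(self, sim_config, input_tac):
        """1TCM generator vs direct numerical evaluation of the convolution integral."""
        region = next(iter(sim_config.tissue_params))
        K1, k2 = sim_config.tissue_params[region]
        tac = generate_tissue_tac(sim_config, region, input_tac, noisy=False)
        mids = input_tac.schedule.mid_times_min
        conc = input_tac.concentration_kBq_per_mL
        for i, t in enumerate(mids):
            s = np.linspace(0.0, t, 4001)
            u = np.interp(s, mids, conc, left=0.0, right=conc[-1])
            integrand = u * np.exp(-k2 * (t - s))
            expected = K1 * np.trapezoid(integrand, s)
            assert tac.concentration_kBq_per_mL[i] == pytest.approx(expected, rel=1e-3, abs=1e-9)


class TestOrganBiokinetics:
    def test_pure_physical_decay_limit(self):
        # instant uptake, no biological clearance: f = u * 2^(-t/T_half)
        cfg = SimulationConfig(
            organ_params={"liver": OrganParams(0.4, uptake_rate_per_h=math.inf)}
        )
        df = generate_organ_biokinetics(cfg)
        t = df["time_h"].to_numpy()
        expected = 0.4 * np.exp2(-t / ZR89.half_life_h)
        assert df["fraction_id"].to_numpy() == pytest.approx(expected, rel=1e-9)

    def test_zero_uptake_gives_zero_curves(self):
        cfg = SimulationConfig(organ_params={"liver": OrganParams(0.0)})
        df = generate_organ_biokinetics(cfg)
        assert (df["fraction_id"] == 0).all()

    def test_unit_uptake_integral_is_half_life_over_ln2(self):
        # analytic integral of 2^(-t/79.2 h) over [0, inf) is 114.26 h
        cfg = SimulationConfig(organ_params={"body": OrganParams(1.0, uptake_rate_per_h=math.inf)})
        times = np.linspace(0.0, 400.0, 8001)
        df = generate_organ_biokinetics(cfg, times_h=times)
        bio = OrganBiokinetics("body", times, df["fraction_id"].to_numpy())
        tau = residence_time(bio, ZR89)
        assert tau == pytest.approx(ZR89.half_life_h / math.log(2), rel=1e-4)

    def test_liver_has_largest_uptake_by_default(self, sim_config):
        u = {k: p.uptake_fraction for k, p in sim_config.organ_params.items()}
        assert max(u, key=u.get) == "liver"
        assert u["liver"] > u["spleen"] > u["kidneys"]

    def test_fraction_sums_bounded_by_one(self, sim_config):
        df = generate_organ_biokinetics(sim_config)
        assert (df.groupby("time_h")["fraction_id"].sum() <= 1 + 1e-12).all()

    def test_overcommitted_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            SimulationConfig(organ_params={"a": OrganParams(0.7), "b": OrganParams(0.6)})


class TestPlasmaSeries:
    def test_initial_concentration_is_dose_over_volume(self):
        cfg = SimulationConfig(
            plasma_params=PlasmaParams(v_central_mL=100.0, fractions=(1.0,), rates_per_h=(0.1,))
        )
        df = generate_plasma_series(cfg, times_h=np.array([0.0, 1.0, 2.0]))
        # 7.2 MBq / 100 mL = 0.072 MBq/mL = 72 kBq/mL
        assert df["plasma_kBq_per_mL"].iloc[0] == pytest.approx(72.0, rel=1e-12)

    def test_intact_fraction_starts_at_configured_value(self, sim_config):
        df = generate_plasma_series(sim_config, times_h=np.array([0.0, 24.0]))
        assert df["intact_pct"].iloc[0] == sim_config.intact_params.initial_pct

    def test_intact_rate_recovered_from_noise_free_series(self):
        cfg = SimulationConfig(intact_params=IntactFractionParams(initial_pct=97.0, rate_per_d=0.42))
        df = generate_plasma_series(cfg)
        f0, rate = fit_intact_fraction(df["time_h"].to_numpy(), df["intact_pct"].to_numpy())
        assert rate == pytest.approx(0.42, rel=1e-2)
        assert f0 == pytest.approx(97.0, rel=1e-2)

    def test_blood_tracks_plasma_at_configured_ratio(self, sim_config):
        df = generate_plasma_series(sim_config)
        ratio = df["blood_kBq_per_mL"] / df["plasma_kBq_per_mL"]
        assert ratio.to_numpy() == pytest.approx(
            np.full(len(df), sim_config.plasma_params.blood_to_plasma_ratio), rel=1e-12
        )

    def test_noisy_series_deterministic_per_seed(self, sim_config):
        a = generate_plasma_series(sim_config, noisy=True)
        b = generate_plasma_series(sim_config, noisy=True)
        assert a.equals(b)
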