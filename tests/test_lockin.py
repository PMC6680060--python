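"""Sine+DC estimator: exact RC inversion, trace pipeline, delta protocol."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sinedc as sd
from sinedc.lockin import _sine_amplitude


def rc_components(f, rs, rm, cm):
    """Analytic normalized components (A, B, Gt) of the three-element circuit."""
    y = 1.0 / (rs + 1.0 / (1.0 / rm + 1j * 2 * np.pi * f * cm))
    return y.real, y.imag, 1.0 / (rs + rm)


class TestFitPhase:
    def test_recovers_alpha(self):
        w = sd.make_sine(sd.SineSpec(f_sine=500.0, amplitude=15.0,
                                     v_hold=-80.0, phase=0.7), 10e-3, 1e-6)
        assert sd.fit_phase(w, 500.0) == pytest.approx(0.7, abs=1e-9)

    def test_wraps_into_principal_interval(self):
        w = sd.make_sine(sd.SineSpec(f_sine=500.0, amplitude=15.0,
                                     v_hold=-80.0, phase=3 * np.pi / 2), 10e-3, 1e-6)
        assert sd.fit_phase(w, 500.0) == pytest.approx(-np.pi / 2, abs=1e-9)

    def test_constant_waveform_rejected(self):
        t = np.arange(0, 10e-3, 1e-6)
        w = sd.Waveform(t=t, v=np.full_like(t, -80e-3), dt=1e-6)
        with pytest.raises(ValueError):
            sd.fit_phase(w, 500.0)


class TestFitComponents:
    def test_exact_basis_recovery(self):
        f, alpha, dt = 250.0, 0.4, 1e-5
        t = np.arange(0, 4 / f, dt)
        w = 2 * np.pi * f
        i = 3e-12 * np.sin(w * t + alpha) + 4e-12 * np.cos(w * t + alpha) + 10e-12
        fit = sd.fit_components(i, t, f, alpha, v_amplitude=15e-3)
        assert fit.A1 == pytest.approx(3e-12, rel=1e-10)
        assert fit.A2 == pytest.approx(4e-12, rel=1e-10)
        assert fit.I_DC == pytest.approx(10e-12, rel=1e-10)
        assert fit.A == pytest.approx(3e-12 / 15e-3, rel=1e-10)

    def test_pure_dc(self):
        t = np.arange(0, 0.01, 1e-5)
        fit = sd.fit_components(np.full_like(t, 5e-12), t, 200.0, 0.0, 15e-3)
        assert abs(fit.A1) < 1e-22 and abs(fit.A2) < 1e-22
        assert fit.I_DC == pytest.approx(5e-12)

    def test_non_integer_window_rejected(self):
        t = np.arange(0, 0.0107, 1e-5)
        with pytest.raises(ValueError):
            sd.fit_components(np.zeros_like(t), t, 200.0, 0.0, 15e-3)


class TestSineDc:
    @pytest.mark.parametrize("f", [100.0, 1000.0, 10000.0])
    @pytest.mark.parametrize("circuit", [(10e6, 1e9, 10e-12), (5e6, 0.5e9, 6e-12)])
    def test_exact_rc_inverse(self, f, circuit):
        rs, rm, cm = circuit
        a, b, gt = rc_components(f, *circuit)
        est = sd.sine_dc(a, b, gt, f)
        assert est.valid
        assert est.c_m == pytest.approx(cm * 1e12, rel=1e-9)
        assert est.r_m == pytest.approx(rm / 1e9, rel=1e-9)
        assert est.r_s == pytest.approx(rs / 1e6, rel=1e-9)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        rs=st.floats(1e6, 250e6),
        rm=st.floats(0.1e9, 20e9),
        cm=st.floats(1e-12, 50e-12),
        f=st.floats(50.0, 20000.0),
    )
    def test_roundtrip_property(self, rs, rm, cm, f):
        # algebraic inverse: reconstruct Y from the estimate, recompute A, B
        a, b, gt = rc_components(f, rs, rm, cm)
        est = sd.sine_dc(a, b, gt, f)
        a2, b2, gt2 = rc_components(f, est.r_s * 1e6, est.r_m * 1e9, est.c_m * 1e-12)
        assert a2 == pytest.approx(a, rel=1e-8)
        assert b2 == pytest.approx(b, rel=1e-8)
        assert gt2 == pytest.approx(gt, rel=1e-8)

    def test_degenerate_flagged_invalid(self):
        est = sd.sine_dc(1e-9, 0.0, 0.5e-9, 1000.0)
        assert not est.valid and np.isnan(est.c_m)


class TestEstimateTrace:
    def test_rc_constant_series(self, rc_sys):
        f, dt = 2000.0, 1e-6
        w = sd.make_sine(sd.SineSpec(f_sine=f), 12 / f, dt)
        tr = sd.simulate(rc_sys, w, dt)
        df = sd.estimate_trace(w, tr, f, v_hold=-80.0, settle_cycles=6)
        assert df["c_m_pF"].std() / df["c_m_pF"].mean() < 1e-6
        assert df["c_m_pF"].mean() == pytest.approx(10.0, rel=1e-3)
        assert df["r_s_MOhm"].mean() == pytest.approx(10.0, rel=1e-3)
        assert df["r_m_GOhm"].mean() == pytest.approx(1.0, rel=1e-3)

    def test_noise_averaging_statistics(self):
        """10-cycle block averaging shrinks per-cycle noise ~1/√10."""
        f, dt, n_cyc = 2000.0, 1e-5, 300
        w = sd.make_sine(sd.SineSpec(f_sine=f, amplitude=15.0, v_hold=-80.0),
                         n_cyc / f, dt)
        a, b, gt = rc_components(f, 10e6, 1e9, 10e-12)
        amp = 15e-3
        wv = 2 * np.pi * f
        i = amp * (a * np.sin(wv * w.t) + b * np.cos(wv * w.t)) + gt * (-80e-3 + 60e-3)
        tr = sd.TraceSet(t=w.t, v_cmd=w.v, i_electrode=i, dt=dt)
        noisy = sd.add_current_noise(tr, sd.NoiseSpec(current_sd=5.0, seed=11))
        per_cycle = sd.estimate_trace(w, noisy, f, v_hold=-80.0)
        cfg = sd.LockinConfig(baseline_lowpass=1e9)  # isolate the block average
        block = sd.average_baseline(per_cycle, cfg)
        ratio = per_cycle["c_m_pF"].std() / block["c_m_pF"].std()
        assert 2.2 < ratio < 4.5  # √10 ≈ 3.16 within sampling scatter


class TestDeltaMeasurement:
    def _series(self, cm, n=50, f=2000.0):
        t = np.arange(n) / f
        return pd.DataFrame({
            "t": t, "c_m_pF": np.full(n, cm), "r_m_GOhm": np.ones(n),
            "r_s_MOhm": np.full(n, 10.0), "g_t_S": np.full(n, 1e-9),
        })

    def test_identical_pre_post_zero(self):
        d = sd.delta_measurement(self._series(10.0), self._series(10.0))
        assert d["d_cm_fF"] == 0.0 and d["d_rm_MOhm"] == 0.0

    def test_capacitance_step_resolved(self):
        d = sd.delta_measurement(self._series(10.0), self._series(10.055))
        assert d["d_cm_fF"] == pytest.approx(55.0)

    def test_empty_windows_rejected(self):
        with pytest.raises(ValueError):
            sd.delta_measurement(self._series(10.0).iloc[:0], self._series(10.0))


class TestAccuracy:
    def test_values(self):
        assert sd.accuracy(4.34, 4.34) == 1.0
        assert sd.accuracy(2.17, 4.34) == 0.5
        with pytest.raises(ValueError):
            sd.accuracy(1.0, 0.0)


class TestLobularDelta:
    """Somatic detection of a 0.5 µm² lobular surface increase."""

    @pytest.fixture(scope="class")
    def delta_100hz(self, aii, preset13, disc_fine, lobular_ids):
        el = sd.Electrode(rs=50.0, site=(0, aii.soma_id, 0.5))
        base = sd.assemble(sd.discretize(aii, disc_fine, preset13), preset13, el)
        pert = sd.increase_surface(aii, lobular_ids[8], (0.0, 1.0), 0.5)
        post = sd.assemble(sd.discretize(pert, disc_fine, preset13), preset13, el)
        return base, post

    def test_delta_cm_near_theory_at_100hz(self, delta_100hz, preset13):
        # ΔCm(theory) = 0.5 µm² × 0.9016 µF/cm² = 4.51 fF; accuracy high at 100 Hz
        base, post = delta_100hz
        e0 = sd.estimate_from_system(base, 100.0, -80.0, -60.0)
        e1 = sd.estimate_from_system(post, 100.0, -80.0, -60.0)
        d_cm = (e1.c_m - e0.c_m) * 1e3
        theory = 0.5 * preset13.cm_spec * 10.0
        assert theory == pytest.approx(4.51, abs=0.005)
        assert sd.accuracy(d_cm, theory) == pytest.approx(1.0, abs=0.15)

    def test_rs_crosstalk_sign_at_low_f(self, delta_100hz):
        # capacitance increase appears as a small apparent Rs *decrease*
        base, post = delta_100hz
        e0 = sd.estimate_from_system(base, 100.0, -80.0, -60.0)
        e1 = sd.estimate_from_system(post, 100.0, -80.0, -60.0)
        assert e1.r_s < e0.r_s

    def test_time_domain_delta_matches_oracle(self, delta_100hz):
        """Pre/post windows from simulated 100 Hz traces reproduce the
        frequency-domain delta."""
        base, post = delta_100hz
        f, dt, settle = 100.0, 1e-6, 2
        w = sd.make_sine(sd.SineSpec(f_sine=f, amplitude=15.0, v_hold=-80.0),
                         (settle + 4) / f, dt)
        dfs = []
        for sys in (base, post):
            tr = sd.simulate(sys, w, dt)
            dfs.append(sd.estimate_trace(w, tr, f, v_hold=-80.0,
                                         settle_cycles=settle))
        d_td = dfs[1]["c_m_pF"].mean() - dfs[0]["c_m_pF"].mean()
        e0 = sd.estimate_from_system(base, f, -80.0, -60.0)
        e1 = sd.estimate_from_system(post, f, -80.0, -60.0)
        d_fd = e1.c_m - e0.c_m
        assert d_td == pytest.approx(d_fd, rel=2e-3)


class TestFrequencyDependence:
    def test_rs_insensitivity(self, aii, preset13, disc_fine):
        # noiseless estimates for Rs 1/50/250 MΩ differ by < 1%
        cell = sd.discretize(aii, disc_fine, preset13)
        cms = {}
        for rs in (1.0, 50.0, 250.0):
            sys = sd.assemble(cell, preset13,
                              sd.Electrode(rs=rs, site=(0, aii.soma_id, 0.5)))
            cms[rs] = [sd.estimate_from_system(sys, f, -80.0, -60.0).c_m
                       for f in (100.0, 1000.0, 10000.0)]
        ref = np.array(cms[50.0])
        for rs in (1.0, 250.0):
            assert np.max(np.abs(np.array(cms[rs]) - ref) / ref) < 0.01

    def test_low_frequency_limit_and_monotone_decay(self, aii, aii_sys, preset13):
        cm_theory = sd.surface_area(aii) * preset13.cm_spec * 1e-2
        cms = [sd.estimate_from_system(aii_sys, f, -80.0, -60.0).c_m
               for f in (100.0, 200.0, 400.0, 1000.0, 2000.0, 4000.0, 10000.0)]
        assert cms[0] >= 0.95 * cm_theory
        assert all(a > b for a, b in zip(cms, cms[1:]))
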