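"""Reduced neuron models: dynamics, knockouts, and the OLM stutter phenotype."""

from dataclasses import replace

import numpy as np
import pytest

from ca1pac import neurons as nr


@pytest.fixture(scope="module")
def olm():
    return nr.NEURON_REGISTRY["OLM"]


@pytest.fixture(scope="module")
def pvbc():
    return nr.NEURON_REGISTRY["PVBC"]


@pytest.fixture(scope="module")
def pyr():
    return nr.NEURON_REGISTRY["PYR"]


class TestNeuronStep:
    def test_resting_fixed_point(self, pyr):
        st = nr.NeuronState(v=pyr.e_leak)
        for _ in range(100):
            st, spiked = nr.neuron_step(st, pyr, [], 0.05)
            assert not spiked
        assert st.v == pytest.approx(pyr.e_leak, abs=1e-9)

    def test_dt_bounds_enforced(self, pyr):
        with pytest.raises(ValueError, match="dt"):
            nr.neuron_step(nr.NeuronState(v=-65.0), pyr, [], 0.2)

    def test_nonfinite_state_halts_with_diagnostic(self, pyr):
        with pytest.raises(FloatingPointError, match="non-finite"):
            nr.neuron_step(nr.NeuronState(v=float("nan")), pyr, [], 0.05)

    def test_constant_suprathreshold_drive_without_cagk_is_tonic(self, olm):
        p = nr.apply_knockout(olm, "CAGK_analog")
        spk = nr.run_single_neuron(p, exc_rate=0.0, g_const=4.0, e_const=0.0,
                                   duration=5000.0, seed=0)
        isi = np.diff(spk)
        assert spk.size > 20
        assert isi.std() / isi.mean() < 0.1

    def test_voltage_bounded_under_physiological_drive(self, olm):
        # E_K <= V <= 0 throughout a strongly driven run
        import math

        st = nr.NeuronState(v=olm.e_leak)
        rng = np.random.default_rng(1)
        g = 0.0
        for i in range(40_000):
            g = g * math.exp(-0.05 / 3.0) + rng.poisson(0.2) * 1.0
            st, _ = nr.neuron_step(st, olm, [(g, 0.0)], 0.05)
            assert olm.e_k <= st.v <= 0.0


class TestKnockouts:
    def test_apply_twice_idempotent(self, olm):
        once = nr.apply_knockout(olm, "KDR_analog")
        twice = nr.apply_knockout(once, "KDR_analog")
        assert once == twice

    def test_unknown_channel_rejected_listing_valid(self, olm):
        with pytest.raises(ValueError, match="KDR_analog"):
            nr.apply_knockout(olm, "NaV_analog")

    def test_kdr_knockout_raises_firing_at_fixed_drive(self, olm):
        ko = nr.apply_knockout(olm, "KDR_analog")
        r_ctrl = nr.run_single_neuron(olm, exc_rate=170, exc_amp=1.5, exc_tau=50.0,
                                      duration=6000, seed=2).size
        r_ko = nr.run_single_neuron(ko, exc_rate=170, exc_amp=1.5, exc_tau=50.0,
                                    duration=6000, seed=2).size
        assert r_ko > r_ctrl

    def test_kdr_knockout_lowers_sustained_firing_rheobase(self, olm):
        # minimum drive for sustained (>= 10 Hz) firing is lower without
        # the fast AHP conductance
        ko = nr.apply_knockout(olm, "KDR_analog")

        def min_drive(p):
            for rate in [60, 80, 100, 120, 140, 160]:
                spk = nr.run_single_neuron(p, exc_rate=rate, exc_amp=1.5,
                                           exc_tau=50.0, duration=6000, seed=3)
                if spk.size / 6.0 >= 10.0:
                    return rate
            return 180

        assert min_drive(ko) < min_drive(olm)


class TestLIFReduction:
    def test_subthreshold_sinusoidal_conductance_matches_membrane_filter(self, pyr):
        # with adaptation removed the model is a conductance-based LIF;
        # a small sinusoidal conductance on top of a constant one drives a
        # voltage sinusoid with gain and phase of the RC membrane filter
        p = replace(pyr, w_fast_jump=0.0, g_kca_max=0.0, ca_jump=0.0)
        g0, g1, f = 2.0, 0.02, 8.0
        dt = 0.05
        w = 2 * np.pi * f / 1000.0  # rad per ms
        st = nr.NeuronState(v=p.e_leak)
        vs, ts = [], []
        for i in range(200_000):
            t = i * dt
            g = g0 + g1 * np.sin(w * t)
            st, spiked = nr.neuron_step(st, p, [(g, 0.0)], dt)
            assert not spiked
            if t > 2000.0:
                vs.append(st.v); ts.append(t)
        vs, ts = np.asarray(vs), np.asarray(ts)
        g_tot = p.g_leak + g0
        v_bar = (p.g_leak * p.e_leak) / g_tot
        tau = p.c_m / g_tot  # ms
        gain = g1 * (0.0 - v_bar) / g_tot / np.sqrt(1 + (w * tau) ** 2)
        phase = -np.arctan(w * tau)
        expected = v_bar + gain * np.sin(w * ts + phase)
        assert np.mean(vs) == pytest.approx(v_bar, abs=0.02)
        resid = vs - expected
        assert np.std(resid) < 0.05 * gain


class TestCalibrateReport:
    def test_rate_monotone_in_drive(self, pyr):
        df = nr.calibrate_report(pyr, [200, 600, 1200, 2400], duration=3000.0, seed=4)
        assert (np.diff(df["rate_hz"].to_numpy()) >= 0).all()

    def test_olm_burstiness_higher_near_rheobase(self, olm):
        df = nr.calibrate_report(olm, [100, 450], duration=8000.0, seed=5,
                                 exc_amp=1.5, exc_tau=50.0)
        near, far = df["burstiness"].to_numpy()
        assert near > far

    def test_pvbc_never_bursts(self, pvbc):
        # drives spanning the fast-spiking operating range (~30-160 Hz)
        df = nr.calibrate_report(pvbc, [2000, 3000, 5000], duration=8000.0, seed=6)
        assert (df["rate_hz"] > 10.0).all()
        assert (df["burstiness"].fillna(0.0) < 0.1).all()

    def test_empty_sweep_rejected(self, pyr):
        with pytest.raises(ValueError, match="nonempty"):
            nr.calibrate_report(pyr, [])


class TestOLMPhenotypeGate:
    """Near-rheobase: gamma-interval bursts at theta recurrence.
    Far above rheobase: tonic spiking at slow-gamma intervals."""

    def test_near_rheobase_bimodal_isi(self, olm):
        isis = []
        for seed in (6, 7, 8):
            spk = nr.run_single_neuron(olm, exc_rate=100, exc_amp=1.5, exc_tau=50.0,
                                       duration=10_000, seed=seed)
            isis.append(np.diff(spk))
        isi = np.concatenate(isis)
        frac_gamma = np.mean((isi > 15) & (isi < 67))   # 15-67 ms ~ 15-50 Hz
        frac_theta = np.mean((isi > 120) & (isi < 400))  # theta-interval gaps
        assert frac_gamma >= 0.2
        assert frac_theta >= 0.15

    def test_far_above_rheobase_tonic_gamma(self, olm):
        spk = nr.run_single_neuron(olm, exc_rate=300, exc_amp=1.5, exc_tau=50.0,
                                   duration=10_000, seed=9)
        isi = np.diff(spk)
        assert 20.0 <= np.median(isi) <= 50.0
        assert np.mean(isi > 120) < 0.05

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="v_reset"):
            nr.ReducedNeuronParams(c_m=100, g_leak=10, e_leak=-65, v_thresh=-60,
                                   v_reset=-50)
        with pytest.raises(ValueError, match="knockout"):
            nr.ReducedNeuronParams(c_m=100, g_leak=10, e_leak=-65, v_thresh=-50,
                                   v_reset=-60, knockouts=frozenset({"bogus"}))
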