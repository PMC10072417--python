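"""Tsodyks-Markram synapse dynamics against analytic and fine-step oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ca1pac import stp


@pytest.fixture(scope="module")
def facilitating():
    return stp.registry_params("PYR->OLM")  # U=0.07 F=470 D=38


@pytest.fixture(scope="module")
def depressing():
    return stp.registry_params("PYR->PVBC")  # U=0.32 F=0 D=110


class TestApplySpike:
    def test_first_release_is_U(self, facilitating, depressing):
        for p in (facilitating, depressing):
            _, rel = stp.tm_apply_spike(stp.TMState(), p, 10.0)
            assert rel == pytest.approx(p.U)

    def test_two_spike_depressing_hand_value(self, depressing):
        # second release after 20 ms: U * (1 - U*exp(-20/110)), frozen
        rel = stp.tm_release_train(depressing, [0.0, 20.0])
        expected = 0.32 * (1.0 - 0.32 * np.exp(-20.0 / 110.0))
        assert rel[1] == pytest.approx(expected, rel=1e-12)
        assert rel[1] == pytest.approx(0.2346237011891015, rel=1e-12)

    def test_full_recovery_limit(self, facilitating, depressing):
        for p in (facilitating, depressing):
            rel = stp.tm_release_train(p, [0.0, 1e7])
            assert rel[1] == pytest.approx(p.U, rel=1e-9)

    def test_time_backwards_rejected(self, depressing):
        state, _ = stp.tm_apply_spike(stp.TMState(), depressing, 10.0)
        with pytest.raises(ValueError, match="backwards"):
            stp.tm_apply_spike(state, depressing, 5.0)


class TestPeriodicSteadyState:
    def test_closed_form_depressing(self, depressing):
        # R* = (1-e)/(1-(1-U)e) with e = exp(-isi/D); release* = U R*
        e = np.exp(-20.0 / 110.0)
        r_star = (1 - e) / (1 - 0.68 * e)
        expected = 0.32 * r_star
        got = stp.tm_periodic_steady_state(depressing, 20.0)
        assert got == pytest.approx(expected, rel=1e-12)
        # value frozen from iterating the recursion 1000 steps
        assert got == pytest.approx(0.12284796208766384, rel=1e-10)

    def test_long_isi_limit(self, depressing):
        assert stp.tm_periodic_steady_state(depressing, 50 * 110.0) == pytest.approx(
            depressing.U, rel=1e-9
        )

    @pytest.mark.parametrize("name", ["PYR->OLM", "PYR->PVBC", "OLM->PYR", "PVBC->PYR"])
    def test_iterated_recursion_converges_to_fixed_point(self, name):
        p = stp.registry_params(name)
        rel = stp.tm_release_train(p, np.arange(500) * 20.0)
        assert rel[-1] == pytest.approx(
            stp.tm_periodic_steady_state(p, 20.0), abs=1e-9
        )

    def test_nonpositive_isi_rejected(self, depressing):
        with pytest.raises(ValueError):
            stp.tm_periodic_steady_state(depressing, 0.0)


class TestFineStepOracle:
    def test_event_driven_matches_fine_step_on_random_trains(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(20):
            U = rng.uniform(0.05, 0.95)
            F = 0.0 if rng.random() < 0.3 else rng.uniform(10, 600)
            D = rng.uniform(10, 2000)
            p = stp.TMParams(U=U, F=F, D=D)
            times = np.round(np.cumsum(rng.exponential(20.0, size=20)), 3)
            a = stp.tm_release_train(p, times)
            b = stp.tm_fine_step_oracle(p, times)
            worst = max(worst, float(np.max(np.abs(a - b) / a)))
        assert worst < 1e-6


class TestTrainPhenotypes:
    def test_facilitating_release_grows_over_50hz_train(self, facilitating):
        rel = stp.tm_release_train(facilitating, np.arange(5) * 20.0)
        assert rel[2] > rel[0]
        assert np.all(np.diff(rel) > 0)

    def test_depressing_release_strictly_decreases(self, depressing):
        rel = stp.tm_release_train(depressing, np.arange(5) * 20.0)
        assert np.all(np.diff(rel) < 0)


class TestConductanceTrace:
    def test_single_event_is_exponential_decay(self):
        p = stp.TMParams(tau_decay_fast=5.0)
        grid = np.arange(0.0, 40.0, 0.5)
        g = stp.conductance_trace([(10.0, 2.0)], p, grid)
        mask = grid >= 10.0
        assert np.allclose(g[mask], 2.0 * np.exp(-(grid[mask] - 10.0) / 5.0))
        assert np.all(g[~mask] == 0.0)

    def test_coincident_events_superpose_linearly(self):
        p = stp.TMParams(tau_decay_fast=5.0, tau_decay_slow=50.0, slow_ratio=0.3)
        grid = np.arange(0.0, 100.0, 0.5)
        one = stp.conductance_trace([(10.0, 1.5)], p, grid)
        two = stp.conductance_trace([(10.0, 1.5), (10.0, 1.5)], p, grid)
        assert np.allclose(two, 2.0 * one)

    def test_depressing_train_peaks_strictly_decrease(self, depressing):
        from dataclasses import replace

        times = np.arange(6) * 20.0
        rel = stp.tm_release_train(depressing, times)
        amps = rel / depressing.U
        grid = np.arange(0.0, 140.0, 0.01)
        # fast kernel only: the slow NMDA-like tail accumulates by design
        fast_only = replace(depressing, tau_decay_slow=0.0, slow_ratio=0.0)
        g = stp.conductance_trace(list(zip(times, amps)), fast_only, grid)
        peaks = [g[np.searchsorted(grid, t)] for t in times]
        assert np.all(np.diff(peaks) < 0)

    def test_empty_events_zero_trace(self, depressing):
        g = stp.conductance_trace([], depressing, np.arange(10.0))
        assert np.all(g == 0)

    def test_nonmonotone_grid_rejected(self, depressing):
        with pytest.raises(ValueError, match="increasing"):
            stp.conductance_trace([], depressing, np.array([0.0, 2.0, 1.0]))


class TestInvariants:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        u_param=st.floats(0.01, 1.0),
        f=st.one_of(st.just(0.0), st.floats(1.0, 1000.0)),
        d=st.one_of(st.just(0.0), st.floats(1.0, 3000.0)),
        isis=st.lists(st.floats(0.01, 500.0), min_size=1, max_size=30),
    )
    def test_u_and_R_stay_in_unit_interval(self, u_param, f, d, isis):
        p = stp.TMParams(U=u_param, F=f, D=d)
        state = stp.TMState()
        t = 0.0
        for isi in isis:
            t += isi
            state, rel = stp.tm_apply_spike(state, p, t)
            assert 0.0 <= state.u <= 1.0
            assert 0.0 <= state.R <= 1.0
            assert 0.0 <= rel <= 1.0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="U"):
            stp.TMParams(U=0.0)
        with pytest.raises(ValueError, match="F"):
            stp.TMParams(F=-1.0)
        with pytest.raises(ValueError, match="g_range"):
            stp.TMParams(g_range=(2.0, 1.0))

    def test_registry_unknown_name(self):
        with pytest.raises(KeyError, match="unknown synapse type"):
            stp.registry_params("PYR->XYZ")
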