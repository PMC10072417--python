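"""Reduced single-compartment neuron models for PYR, PVBC and OLM cells.

Each cell is an adaptive conductance-based leaky integrate-and-fire unit
with two spike-triggered adaptation conductances reversing at E_K:

* ``w_fast`` — a fast after-hyperpolarization conductance incremented by
  ``w_fast_jump`` per spike, decaying with ``tau_fast`` (the delayed-
  rectifier-potassium analog, knockout name ``KDR_analog``); it sets the
  intra-burst (gamma) inter-spike interval and raises the effective
  threshold for sustained firing.
* ``g_KCa`` — a calcium-gated potassium conductance
  ``g_kca_max * Ca / (Ca + k_half)`` where the dimensionless calcium
  variable jumps by ``ca_jump`` per spike and decays with ``tau_ca`` (the
  Ca-gated-potassium analog, knockout name ``CAGK_analog``); its slow
  accumulation terminates bursts and its recovery sets the inter-burst
  (theta) interval.

With OLM parameters near rheobase this produces the stutter-bursting
phenotype — clusters of gamma-interval spikes recurring at theta
intervals — on which theta-nested gamma in the feedback circuit relies.
Knock-outs zero the corresponding conductance contribution and are applied
through :func:`apply_knockout`.

Integration is exponential-Euler at dt <= 0.1 ms; the membrane equation is

    C dV/dt = -g_L (V - E_L) - sum_syn g_syn (V - E_syn)
              - (w_fast + g_KCa) (V - E_K)

with reset to ``v_reset`` and an absolute refractory period after spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ReducedNeuronParams",
    "NeuronState",
    "KNOCKOUT_CHANNELS",
    "NEURON_REGISTRY",
    "neuron_step",
    "apply_knockout",
    "PopulationState",
    "population_init",
    "population_step",
    "run_single_neuron",
    "calibrate_report",
    "isi_statistics",
]

KNOCKOUT_CHANNELS = ("KDR_analog", "CAGK_analog")


@dataclass(frozen=True)
class ReducedNeuronParams:
    """Adaptive LIF parameters (pF, nS, mV, ms)."""

    c_m: float
    g_leak: float
    e_leak: float
    v_thresh: float
    v_reset: float
    refrac: float = 2.0
    w_fast_jump: float = 0.0
    tau_fast: float = 30.0
    e_k: float = -90.0
    ca_jump: float = 0.0
    tau_ca: float = 200.0
    g_kca_max: float = 0.0
    k_half: float = 0.5
    knockouts: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.tau_fast <= 0 or self.tau_ca <= 0:
            raise ValueError("tau_fast and tau_ca must be positive")
        if min(self.c_m, self.g_leak, self.w_fast_jump, self.g_kca_max) < 0:
            raise ValueError("capacitance and conductances must be >= 0")
        if self.v_reset >= self.v_thresh:
            raise ValueError(
                f"v_reset {self.v_reset} must be below v_thresh {self.v_thresh}"
            )
        bad = set(self.knockouts) - set(KNOCKOUT_CHANNELS)
        if bad:
            raise ValueError(
                f"unknown knockout channel(s) {sorted(bad)}; "
                f"valid: {list(KNOCKOUT_CHANNELS)}"
            )

    @property
    def kdr_active(self) -> bool:
        return "KDR_analog" not in self.knockouts

    @property
    def cagk_active(self) -> bool:
        return "CAGK_analog" not in self.knockouts


@dataclass
class NeuronState:
    v: float
    w_fast: float = 0.0
    ca: float = 0.0
    t_last_spike: float = -np.inf
    t: float = 0.0


def apply_knockout(params: ReducedNeuronParams, channel: str) -> ReducedNeuronParams:
    """Return params with ``channel``'s conductance contribution zeroed.

    Idempotent; unknown channel names are rejected with the valid list.
    """
    if channel not in KNOCKOUT_CHANNELS:
        raise ValueError(
            f"unknown knockout channel {channel!r}; valid: {list(KNOCKOUT_CHANNELS)}"
        )
    return replace(params, knockouts=params.knockouts | {channel})


def neuron_step(
    state: NeuronState,
    params: ReducedNeuronParams,
    syn_conductances: list[tuple[float, float]],
    dt: float,
) -> tuple[NeuronState, bool]:
    """One exponential-Euler step; returns (new state, spiked).

    ``syn_conductances`` is a list of (g in nS, reversal in mV) pairs held
    constant over the step.  Requires 0 < dt <= 0.1 ms.
    """
    if not (0.0 < dt <= 0.1):
        raise ValueError(f"dt must be in (0, 0.1] ms, got {dt}")
    if not (np.isfinite(state.v) and np.isfinite(state.w_fast) and np.isfinite(state.ca)):
        raise FloatingPointError(f"non-finite neuron state: {state}")
    w = state.w_fast * np.exp(-dt / params.tau_fast)
    ca = state.ca * np.exp(-dt / params.tau_ca)
    g_adapt = 0.0
    if params.kdr_active:
        g_adapt += w
    if params.cagk_active:
        g_adapt += params.g_kca_max * ca / (ca + params.k_half)
    g_tot = params.g_leak + g_adapt + sum(g for g, _ in syn_conductances)
    drive = (
        params.g_leak * params.e_leak
        + g_adapt * params.e_k
        + sum(g * e for g, e in syn_conductances)
    )
    t_new = state.t + dt
    if t_new - state.t_last_spike < params.refrac:
        v = params.v_reset
    else:
        v_inf = drive / g_tot
        v = v_inf + (state.v - v_inf) * np.exp(-g_tot * dt / params.c_m)
    spiked = v >= params.v_thresh
    t_last = state.t_last_spike
    if spiked:
        v = params.v_reset
        w += params.w_fast_jump
        ca += params.ca_jump
        t_last = t_new
    return NeuronState(v=v, w_fast=w, ca=ca, t_last_spike=t_last, t=t_new), bool(spiked)


# ---------------------------------------------------------------------------
# vectorized population stepping (used by the network simulator)
# ---------------------------------------------------------------------------

@dataclass
class PopulationState:
    v: np.ndarray
    w_fast: np.ndarray
    ca: np.ndarray
    refrac_left: np.ndarray  # ms until refractoriness ends


def population_init(
    params: ReducedNeuronParams, n: int, rng: np.random.Generator | None = None
) -> PopulationState:
    """Fresh state; membrane potentials jittered below threshold if rng given."""
    v = np.full(n, params.e_leak)
    if rng is not None:
        v = v + rng.uniform(-3.0, 3.0, size=n)
    return PopulationState(
        v=v,
        w_fast=np.zeros(n),
        ca=np.zeros(n),
        refrac_left=np.zeros(n),
    )


def population_step(
    st: PopulationState,
    params: ReducedNeuronParams,
    g_syn: list[tuple[np.ndarray, float]],
    dt: float,
    decay_fast: float,
    decay_ca: float,
) -> np.ndarray:
    """Vectorized step for one population; returns boolean spike mask.

    ``decay_fast``/``decay_ca`` are the precomputed per-step exponential
    decay factors for the adaptation variables.
    """
    st.w_fast *= decay_fast
    st.ca *= decay_ca
    g_adapt = 0.0
    if params.kdr_active:
        g_adapt = g_adapt + st.w_fast
    if params.cagk_active:
        g_adapt = g_adapt + params.g_kca_max * st.ca / (st.ca + params.k_half)
    g_tot = params.g_leak + g_adapt
    drive = params.g_leak * params.e_leak + g_adapt * params.e_k
    for g, e in g_syn:
        g_tot = g_tot + g
        drive = drive + g * e
    v_inf = drive / g_tot
    v_new = v_inf + (st.v - v_inf) * np.exp(-g_tot * (dt / params.c_m))
    in_refrac = st.refrac_left > 0
    v_new[in_refrac] = params.v_reset
    st.refrac_left[in_refrac] -= dt
    if not np.all(np.isfinite(v_new)):
        bad = int(np.nonzero(~np.isfinite(v_new))[0][0])
        raise FloatingPointError(f"non-finite membrane potential in cell {bad}")
    spiked = v_new >= params.v_thresh
    if spiked.any():
        v_new[spiked] = params.v_reset
        st.w_fast[spiked] += params.w_fast_jump
        st.ca[spiked] += params.ca_jump
        st.refrac_left[spiked] = params.refrac
    st.v = v_new
    return spiked


# ---------------------------------------------------------------------------
# single-cell experiments and calibration
# ---------------------------------------------------------------------------

def run_single_neuron(
    params: ReducedNeuronParams,
    exc_rate: float,
    exc_amp: float = 0.6,
    exc_tau: float = 3.0,
    duration: float = 5000.0,
    dt: float = 0.05,
    seed: int = 0,
    g_const: float = 0.0,
    e_const: float = 0.0,
) -> np.ndarray:
    """Drive one cell with Poisson excitatory conductance events; spike times.

    Events arrive at ``exc_rate`` Hz with amplitude ``exc_amp`` nS and decay
    ``exc_tau`` ms (reversal 0 mV); ``g_const`` adds a constant conductance
    with reversal ``e_const``.  Returns spike times in ms.
    """
    import math

    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / dt))
    # pre-binned Poisson event amplitudes per step
    lam = exc_rate * dt * 1e-3
    events = (rng.poisson(lam, size=n_steps) * exc_amp).tolist()
    decay_fast = math.exp(-dt / params.tau_fast)
    decay_ca = math.exp(-dt / params.tau_ca)
    decay_syn = math.exp(-dt / exc_tau)
    kdr, cagk = params.kdr_active, params.cagk_active
    g_leak, e_leak, e_k, c_m = params.g_leak, params.e_leak, params.e_k, params.c_m
    g_kca_max, k_half = params.g_kca_max, params.k_half
    v_thresh, v_reset, refrac = params.v_thresh, params.v_reset, params.refrac
    v, w, ca, g_e = e_leak, 0.0, 0.0, 0.0
    refrac_left = 0.0
    spikes: list[float] = []
    # scalar fast path: identical update rule to population_step
    for i in range(n_steps):
        g_e = g_e * decay_syn + events[i]
        w *= decay_fast
        ca *= decay_ca
        g_adapt = (w if kdr else 0.0) + (
            g_kca_max * ca / (ca + k_half) if cagk else 0.0
        )
        g_tot = g_leak + g_adapt + g_e + g_const
        drive = g_leak * e_leak + g_adapt * e_k + g_const * e_const
        if refrac_left > 0:
            v = v_reset
            refrac_left -= dt
        else:
            v_inf = drive / g_tot
            v = v_inf + (v - v_inf) * math.exp(-g_tot * dt / c_m)
        if v >= v_thresh:
            spikes.append((i + 1) * dt)
            v = v_reset
            w += params.w_fast_jump
            ca += params.ca_jump
            refrac_left = refrac
    return np.asarray(spikes)


def isi_statistics(spike_times: np.ndarray) -> dict[str, float]:
    """Rate-free ISI summary: CV and the burstiness index.

    Burstiness = fraction of inter-spike intervals shorter than 60 ms whose
    previous or next interval exceeds 120 ms (gamma-interval spikes flanked
    by theta-interval silence).
    """
    isi = np.diff(np.asarray(spike_times, float))
    if isi.size < 2:
        return {"isi_cv": np.nan, "burstiness": np.nan}
    cv = float(isi.std() / isi.mean())
    short = isi < 60.0
    neighbor_long = np.zeros(isi.size, dtype=bool)
    neighbor_long[1:] |= isi[:-1] > 120.0
    neighbor_long[:-1] |= isi[1:] > 120.0
    burst = float(np.mean(short & neighbor_long))
    return {"isi_cv": cv, "burstiness": burst}


def calibrate_report(
    params: ReducedNeuronParams,
    drive_rates: list[float],
    duration: float = 5000.0,
    seed: int = 0,
    **drive_kwargs,
) -> pd.DataFrame:
    """f-I-style table over Poisson drive levels.

    One row per drive rate (Hz of excitatory input events): mean firing
    rate, ISI CV and burstiness index.
    """
    if len(drive_rates) == 0:
        raise ValueError("drive sweep must be nonempty")
    rows = []
    for k, r in enumerate(drive_rates):
        spk = run_single_neuron(
            params, exc_rate=r, duration=duration, seed=seed + k, **drive_kwargs
        )
        stats = isi_statistics(spk)
        rows.append(
            {
                "drive_rate_hz": r,
                "rate_hz": spk.size / (duration * 1e-3),
                "isi_cv": stats["isi_cv"],
                "burstiness": stats["burstiness"],
            }
        )
    return pd.DataFrame(rows)


# Default parameter sets.  OLM values are calibrated so that near-rheobase
# Poisson drive yields stutter bursts (intra-burst ISIs at slow-gamma
# intervals, inter-burst gaps at theta intervals) and strong drive yields
# tonic gamma-interval spiking; PVBC is fast-spiking non-bursting; PYR is a
# regular cell with mild spike-frequency adaptation.
NEURON_REGISTRY: dict[str, ReducedNeuronParams] = {
    "PYR": ReducedNeuronParams(
        c_m=150.0, g_leak=10.0, e_leak=-67.0, v_thresh=-50.0, v_reset=-60.0,
        refrac=2.0, w_fast_jump=3.0, tau_fast=80.0, ca_jump=0.0, tau_ca=300.0,
        g_kca_max=0.0,
    ),
    "PVBC": ReducedNeuronParams(
        c_m=100.0, g_leak=10.0, e_leak=-65.0, v_thresh=-48.0, v_reset=-62.0,
        refrac=2.0, w_fast_jump=1.0, tau_fast=8.0, ca_jump=0.0, tau_ca=100.0,
        g_kca_max=0.0,
    ),
    "OLM": ReducedNeuronParams(
        c_m=80.0, g_leak=5.0, e_leak=-60.0, v_thresh=-45.0, v_reset=-55.0,
        refrac=2.0, w_fast_jump=15.0, tau_fast=25.0, ca_jump=0.15, tau_ca=200.0,
        g_kca_max=30.0, k_half=1.0,
    ),
}
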