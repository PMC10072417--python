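"""Event-driven Tsodyks-Markram (TM) short-term plasticity synapses.

The TM model tracks two per-connection state variables: utilization ``u``
(facilitation; relaxes to 0 with time constant ``F``) and the available
resource fraction ``R`` (depression; recovers to 1 with time constant ``D``).
On each presynaptic spike, after relaxing both variables over the elapsed
interval,

    u <- u + U * (1 - u)        (u = U exactly when F = 0)
    release = u * R
    R <- R * (1 - u)

so the very first event of a rested synapse releases exactly ``U``.
Conductance event amplitudes are normalized as ``g_peak * release / U`` so
that a rested synapse produces a peak conductance of ``g_peak``.

Postsynaptic conductance kernels are peak-normalized single-exponential
decays (instantaneous rise): a fast AMPA/GABA-like component plus an
optional slow NMDA-like component scaled by ``slow_ratio``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TMParams",
    "TMState",
    "tm_apply_spike",
    "tm_release_train",
    "tm_periodic_steady_state",
    "tm_fine_step_oracle",
    "conductance_trace",
    "SYNAPSE_REGISTRY",
]


@dataclass(frozen=True)
class TMParams:
    """Parameters of one synapse type (TM dynamics + conductance kernel).

    Times in ms, conductances in nS, potentials in mV.  ``F = 0`` means no
    facilitation (u pinned at U); ``D = 0`` means no depression (R pinned
    at 1); ``tau_decay_slow = 0`` disables the slow kernel component.
    """

    U: float = 1.0
    F: float = 0.0
    D: float = 0.0
    tau_rise: float = 0.0
    tau_decay_fast: float = 3.0
    tau_decay_slow: float = 0.0
    slow_ratio: float = 0.0
    g_range: tuple[float, float] = (1.0, 1.0)
    e_rev: float = 0.0
    delay_range: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.U <= 1.0):
            raise ValueError(f"U must be in (0, 1], got {self.U}")
        for name in ("F", "D", "tau_rise", "tau_decay_fast", "tau_decay_slow"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.g_range[0] > self.g_range[1]:
            raise ValueError(f"g_range must satisfy g_min <= g_max, got {self.g_range}")
        if self.delay_range[0] > self.delay_range[1]:
            raise ValueError(
                f"delay_range must satisfy d_min <= d_max, got {self.delay_range}"
            )


@dataclass
class TMState:
    """Running state of one connection: utilization, resources, last event time."""

    u: float = 0.0
    R: float = 1.0
    t_last: float | None = None


def tm_apply_spike(
    state: TMState, params: TMParams, t: float
) -> tuple[TMState, float]:
    """Advance the TM recursion by one presynaptic spike at time ``t`` (ms).

    Returns the new state and the release fraction ``u*R`` in [0, 1].
    Time must not run backwards.
    """
    if state.t_last is not None and t < state.t_last:
        raise ValueError(
            f"presynaptic time going backwards: t={t} < t_last={state.t_last}"
        )
    if state.t_last is None:
        u, R = 0.0, 1.0
    else:
        dt = t - state.t_last
        u = state.u * np.exp(-dt / params.F) if params.F > 0 else 0.0
        R = 1.0 - (1.0 - state.R) * np.exp(-dt / params.D) if params.D > 0 else 1.0
    u = params.U if params.F == 0 else u + params.U * (1.0 - u)
    release = u * R
    R = R * (1.0 - u)
    return TMState(u=u, R=R, t_last=t), float(release)


def tm_release_train(params: TMParams, times: np.ndarray) -> np.ndarray:
    """Release fractions for a whole presynaptic spike train (sorted times, ms)."""
    times = np.asarray(times, dtype=float)
    state = TMState()
    out = np.empty(times.shape, dtype=float)
    for i, t in enumerate(times):
        state, out[i] = tm_apply_spike(state, params, float(t))
    return out


def tm_periodic_steady_state(params: TMParams, isi: float) -> float:
    """Steady-state release fraction under an infinite periodic train.

    For ``F = 0`` the closed form is
    ``R* = (1 - e^(-isi/D)) / (1 - (1-U) e^(-isi/D))``, release* = ``U R*``.
    For ``F > 0`` the 2-d fixed point of the per-spike map is solved by
    iteration to an increment below 1e-12 (the map is a contraction).
    """
    if isi <= 0:
        raise ValueError(f"isi must be positive, got {isi}")
    U = params.U
    eD = np.exp(-isi / params.D) if params.D > 0 else 0.0
    if params.F == 0:
        R_star = (1.0 - eD) / (1.0 - (1.0 - U) * eD)
        return float(U * R_star)
    eF = np.exp(-isi / params.F)
    # post-increment u*, pre-release R* of the per-spike map
    u, R = U, 1.0
    for _ in range(100_000):
        u_next = u * eF + U * (1.0 - u * eF)
        R_next = 1.0 - (1.0 - R * (1.0 - u)) * eD
        if abs(u_next - u) + abs(R_next - R) < 1e-12:
            u, R = u_next, R_next
            break
        u, R = u_next, R_next
    return float(u * R)


def tm_fine_step_oracle(
    params: TMParams, times: np.ndarray, dt: float = 0.001
) -> np.ndarray:
    """Brute-force fine-step Runge-Kutta integration of the TM ODEs.

    Independent reference for :func:`tm_release_train`: between spikes
    ``du/dt = -u/F`` and ``dR/dt = (1-R)/D`` are advanced with classical
    RK4 steps of ``dt`` ms; the per-spike jumps are applied exactly as in
    the event-driven recursion.

    For a linear decay ODE an RK4 step multiplies the deviation from
    equilibrium by the fixed factor ``1 - k + k^2/2 - k^3/6 + k^4/24``
    (k = dt/tau), so ``n`` steps compound to that factor to the power
    ``n``; the power is evaluated directly instead of looping, returning
    bit-for-bit the step-loop values.
    """
    def rk4_factor(tau: float) -> float:
        k = dt / tau
        return 1.0 - k + k**2 / 2.0 - k**3 / 6.0 + k**4 / 24.0

    times = np.asarray(times, dtype=float)
    u, R = 0.0, 1.0
    t = times[0] if times.size else 0.0
    out = np.empty(times.shape, dtype=float)
    fu = rk4_factor(params.F) if params.F > 0 else 0.0
    fR = rk4_factor(params.D) if params.D > 0 else 0.0
    for i, ts in enumerate(times):
        n = int(round((ts - t) / dt))
        if params.F > 0:
            u *= fu**n
        R = 1.0 - (1.0 - R) * fR**n if params.D > 0 else 1.0
        t = ts
        u = params.U if params.F == 0 else u + params.U * (1.0 - u)
        out[i] = u * R
        R *= 1.0 - u
    return out


def conductance_trace(
    events: list[tuple[float, float]],
    params: TMParams,
    grid: np.ndarray,
    delay: float = 0.0,
) -> np.ndarray:
    """Superpose conductance kernels for delivered events on a time grid (ms).

    ``events`` are ``(time_ms, amplitude_nS)`` pairs; each contributes
    ``amplitude * [exp(-(t-t0)/tau_fast) + slow_ratio * exp(-(t-t0)/tau_slow)]``
    for ``t >= t0 = time + delay``.  Linearity: traces of event lists add.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    g = np.zeros_like(grid)
    for t0, amp in events:
        tt = grid - (t0 + delay)
        mask = tt >= 0
        g[mask] += amp * np.exp(-tt[mask] / params.tau_decay_fast)
        if params.tau_decay_slow > 0 and params.slow_ratio > 0:
            g[mask] += amp * params.slow_ratio * np.exp(-tt[mask] / params.tau_decay_slow)
    return g


# Named synapse-type registry.  TM constants follow the hippocampal CA1
# paired-recording literature for each projection; PYR->PYR and PVBC->PVBC
# short-term dynamics are not separately constrained here and default to
# static synapses (F = D = 0, U = 1).
SYNAPSE_REGISTRY: dict[str, TMParams] = {
    "PYR->OLM": TMParams(
        U=0.07, F=470.0, D=38.0, tau_decay_fast=1.7, tau_decay_slow=148.5,
        slow_ratio=0.28, g_range=(0.2, 0.4), e_rev=0.0,
    ),
    "PYR->PVBC": TMParams(
        U=0.32, F=0.0, D=110.0, tau_decay_fast=4.12, tau_decay_slow=298.75,
        slow_ratio=0.28, g_range=(0.3, 0.7), e_rev=0.0,
    ),
    "OLM->PYR": TMParams(
        U=0.3, F=6.0, D=1770.0, tau_decay_fast=18.0, g_range=(1.0, 1.4),
        e_rev=-80.0,
    ),
    "PVBC->PYR": TMParams(
        U=0.16, F=8.6, D=965.0, tau_decay_fast=5.94, g_range=(1.0, 1.2),
        e_rev=-80.0,
    ),
    "PYR->PYR": TMParams(
        U=1.0, F=0.0, D=0.0, tau_decay_fast=3.0, tau_decay_slow=148.5,
        slow_ratio=1.22, g_range=(0.5, 0.7), e_rev=0.0,
    ),
    "PVBC->PVBC": TMParams(
        U=1.0, F=0.0, D=0.0, tau_decay_fast=5.94, g_range=(4.2, 4.8),
        e_rev=-80.0,
    ),
    "SC->PYR": TMParams(
        U=1.0, F=0.0, D=0.0, tau_decay_fast=3.0, tau_decay_slow=148.5,
        slow_ratio=1.22, g_range=(0.55, 0.65), e_rev=0.0,
    ),
}


def registry_params(name: str, **overrides) -> TMParams:
    """Fetch a registry entry, optionally overriding fields."""
    if name not in SYNAPSE_REGISTRY:
        raise KeyError(
            f"unknown synapse type {name!r}; known: {sorted(SYNAPSE_REGISTRY)}"
        )
    p = SYNAPSE_REGISTRY[name]
    return replace(p, **overrides) if overrides else p
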