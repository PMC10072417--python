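"""Reduced CA1 microcircuit builder and simulator.

Circuit variants connect pyramidal cells (PYR), parvalbumin basket cells
(PVBC) and oriens-lacunosum/moleculare cells (OLM) with binomially
distributed synapse counts per ordered cell pair, Tsodyks-Markram
short-term plasticity per connection, and conductance kernels per synapse.
Model cells stand for groups of biological cells; group size enters
through the binomial trial count ``N = group_size(pre) * syn_per_conn``.

Variants:

* ``FM``    — full model: 480 PYR, 20x4 PVBC, 20 OLM; all six recurrent
  projections; OLM->PYR GABA decay 18 ms with depressing STP.
* ``FMx``   — FM without the OLM->PYR feedback.
* ``FMfix`` — FM with OLM->PYR STP frozen (F = D = 0: fixed-strength).
* ``SM``    — simplified feedback circuit: 120x4 PYR and 10x2 OLM only,
  PYR->OLM (facilitating) and OLM->PYR (static, GABA decay 11.8 ms).
* ``SMx``   — SM without OLM->PYR.
* ``SM25`` / ``SM7`` — SM with OLM->PYR strength x3 and GABA decay
  25 / 7 ms.

Excitatory drive arrives on PYR cells as independent Schaffer-collateral
(SC) Poisson processes: ``scil / 20`` processes per cell at 34 Hz, each
contacting the cell through 6 static synapses.

All simulations are deterministic given ``NetworkConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import analysis as ana
from .neurons import (
    NEURON_REGISTRY,
    PopulationState,
    ReducedNeuronParams,
    apply_knockout,
    population_init,
    population_step,
)
from .stp import SYNAPSE_REGISTRY, TMParams

__all__ = [
    "PopulationSpec",
    "ConnectionSpec",
    "NetworkConfig",
    "VARIANTS",
    "DEFAULT_SYN_SCALE",
    "Network",
    "build_network",
    "scil_to_inputs",
    "simulate",
    "run_sweep",
    "population_sizes",
]

SC_RATE_HZ = 34.0
SC_SYNAPSES = 6
SC_PROCESS_DIVISOR = 20

CONNECTION_STATS: dict[str, tuple[float, int]] = {
    # projection -> (connection probability, synapses per connection)
    "PYR->OLM": (0.35, 5),
    "PYR->PVBC": (0.35, 6),
    "OLM->PYR": (0.4, 13),
    "PVBC->PYR": (0.25, 11),
    "PYR->PYR": (0.35, 3),
    "PVBC->PVBC": (0.35, 5),
}

# Per-projection conductance scale factors calibrated so the reduced
# point neurons sit in the operating regime of the detailed circuit
# (PYR ~13-26 Hz, OLM stutter-bursting at the calibrated SC level); see
# docs/methods.md for the calibration procedure.
DEFAULT_SYN_SCALE: dict[str, float] = {
    "SC->PYR": 0.03,
    "PYR->OLM": 0.008,
    "PYR->PVBC": 0.02,
    "OLM->PYR": 1.0,
    "PVBC->PYR": 1.0,
    "PYR->PYR": 0.002,
    "PVBC->PVBC": 1.0,
}

# SC input level at which the calibrated SM circuit sits in its
# theta-nested-gamma operating regime (chosen from a SCIL sweep of the SM
# variant as the level with robust theta and slow-gamma expression).
CALIBRATED_SCIL = 220


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    n_groups: int
    group_size: int = 1

    def __post_init__(self) -> None:
        if self.n_groups < 0 or self.group_size < 1:
            raise ValueError("need n_groups >= 0 and group_size >= 1")


@dataclass(frozen=True)
class ConnectionSpec:
    pre: str
    post: str
    p_conn: float
    syn_per_conn: int
    tm: TMParams

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_conn <= 1.0):
            raise ValueError(f"p_conn must be in [0, 1], got {self.p_conn}")
        if self.syn_per_conn < 0:
            raise ValueError("syn_per_conn must be >= 0")

    @property
    def name(self) -> str:
        return f"{self.pre}->{self.post}"


@dataclass(frozen=True)
class NetworkConfig:
    variant: str = "SM"
    scil: int = 180
    duration: float = 6300.0
    discard: float = 2000.0
    dt: float = 0.05
    seed: int = 0
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; known: {sorted(VARIANTS)}"
            )
        if self.scil < 0 or self.scil % SC_PROCESS_DIVISOR != 0:
            raise ValueError(
                f"scil must be a nonnegative multiple of {SC_PROCESS_DIVISOR}, "
                f"got {self.scil}"
            )
        if self.discard >= self.duration:
            raise ValueError("discard must be smaller than duration")
        if not (0.0 < self.dt <= 0.1):
            raise ValueError(f"dt must be in (0, 0.1] ms, got {self.dt}")
        known = {"knockouts", "syn_scale", "drop_projections", "tm_patches", "neuron_params"}
        bad = set(self.overrides) - known
        if bad:
            raise ValueError(f"unknown override keys {sorted(bad)}; known: {sorted(known)}")


def _variant_table() -> dict[str, dict]:
    fm_pops = [
        PopulationSpec("PYR", 480, 1),
        PopulationSpec("PVBC", 20, 4),
        PopulationSpec("OLM", 20, 1),
    ]
    sm_pops = [PopulationSpec("PYR", 120, 4), PopulationSpec("OLM", 10, 2)]
    fm_proj = list(CONNECTION_STATS)
    sm_proj = ["PYR->OLM", "OLM->PYR"]
    sm_patch = {"OLM->PYR": {"F": 0.0, "D": 0.0, "tau_decay_fast": 11.8}}
    return {
        "FM": dict(populations=fm_pops, projections=fm_proj, tm_patches={}, g_mult={}),
        "FMx": dict(
            populations=fm_pops,
            projections=[p for p in fm_proj if p != "OLM->PYR"],
            tm_patches={}, g_mult={},
        ),
        "FMfix": dict(
            populations=fm_pops, projections=fm_proj,
            tm_patches={"OLM->PYR": {"F": 0.0, "D": 0.0}}, g_mult={},
        ),
        "SM": dict(populations=sm_pops, projections=sm_proj, tm_patches=sm_patch, g_mult={}),
        "SMx": dict(
            populations=sm_pops, projections=["PYR->OLM"], tm_patches={}, g_mult={},
        ),
        "SM25": dict(
            populations=sm_pops, projections=sm_proj,
            tm_patches={"OLM->PYR": {"F": 0.0, "D": 0.0, "tau_decay_fast": 25.0}},
            g_mult={"OLM->PYR": 3.0},
        ),
        "SM7": dict(
            populations=sm_pops, projections=sm_proj,
            tm_patches={"OLM->PYR": {"F": 0.0, "D": 0.0, "tau_decay_fast": 7.0}},
            g_mult={"OLM->PYR": 3.0},
        ),
    }


VARIANTS = _variant_table()


def population_sizes(variant: str) -> dict[str, int]:
    """Model-cell count per population for a variant."""
    return {p.name: p.n_groups for p in VARIANTS[variant]["populations"]}


@dataclass
class _Projection:
    """Built state of one projection (all arrays index model cells)."""

    name: str
    pre: str
    post: str
    tm: TMParams
    conn_ptr: np.ndarray      # (n_pre+1,) slice bounds into conn arrays
    conn_post: np.ndarray
    conn_gpeak: np.ndarray
    syn_ptr: np.ndarray       # (n_pre+1,) slice bounds into synapse arrays
    syn_local: np.ndarray     # conn index local to the pre cell's slice
    syn_post: np.ndarray
    syn_delay_steps: np.ndarray
    # runtime state
    u: np.ndarray = field(default=None)
    R: np.ndarray = field(default=None)
    t_last: np.ndarray = field(default=None)

    @property
    def n_synapses(self) -> int:
        return int(self.syn_post.size)


@dataclass
class Network:
    config: NetworkConfig
    populations: dict[str, PopulationSpec]
    neuron_params: dict[str, ReducedNeuronParams]
    projections: list[_Projection]
    syn_scale: dict[str, float]


def _resolve_tm(name: str, variant_info: dict, overrides: dict) -> TMParams:
    patch = dict(variant_info["tm_patches"].get(name, {}))
    patch.update(overrides.get("tm_patches", {}).get(name, {}))
    g_mult = variant_info["g_mult"].get(name, 1.0)
    p = SYNAPSE_REGISTRY[name]
    if patch:
        p = replace(p, **patch)
    if g_mult != 1.0:
        p = replace(p, g_range=(p.g_range[0] * g_mult, p.g_range[1] * g_mult))
    return p


def build_network(config: NetworkConfig) -> Network:
    """Instantiate cells and synapses for a configuration.

    For each ordered (pre, post) model-cell pair of a projection the number
    of synaptic contacts is drawn Binomial(N, p) with
    ``N = group_size(pre) * syn_per_conn`` and ``p = p_conn``; the peak
    conductance is drawn once per connection (uniform on the projection's
    g-range) and shared by its contacts, while each contact gets its own
    uniform delay.  Self-connections are excluded.
    """
    info = VARIANTS[config.variant]
    rng = np.random.default_rng(config.seed)
    pops = {p.name: p for p in info["populations"]}
    nparams = {}
    for name in pops:
        p = NEURON_REGISTRY[name]
        for patch_name, patch in config.overrides.get("neuron_params", {}).items():
            if patch_name == name:
                p = replace(p, **patch)
        for ko in config.overrides.get("knockouts", {}).get(name, []):
            p = apply_knockout(p, ko)
        nparams[name] = p
    syn_scale = dict(DEFAULT_SYN_SCALE)
    syn_scale.update(config.overrides.get("syn_scale", {}))

    dropped = set(config.overrides.get("drop_projections", []))
    projections = []
    for name in info["projections"]:
        if name in dropped:
            continue
        pre, post = name.split("->")
        p_conn, syn_per_conn = CONNECTION_STATS[name]
        tm = _resolve_tm(name, info, config.overrides)
        n_pre, n_post = pops[pre].n_groups, pops[post].n_groups
        N = pops[pre].group_size * syn_per_conn
        conn_ptr = [0]
        conn_post, conn_gpeak = [], []
        syn_ptr = [0]
        syn_local, syn_post, syn_delay = [], [], []
        scale = syn_scale.get(name, 1.0)
        for i in range(n_pre):
            counts = rng.binomial(N, p_conn, size=n_post)
            if pre == post:
                counts[i] = 0
            tgt = np.nonzero(counts)[0]
            g = rng.uniform(tm.g_range[0], tm.g_range[1], size=tgt.size) * scale
            conn_post.append(tgt)
            conn_gpeak.append(g)
            conn_ptr.append(conn_ptr[-1] + tgt.size)
            reps = counts[tgt]
            syn_local.append(np.repeat(np.arange(tgt.size), reps))
            syn_post.append(np.repeat(tgt, reps))
            n_syn = int(reps.sum())
            d = rng.uniform(tm.delay_range[0], tm.delay_range[1], size=n_syn)
            syn_delay.append(np.maximum(1, np.round(d / config.dt)).astype(np.int64))
            syn_ptr.append(syn_ptr[-1] + n_syn)
        n_conn = conn_ptr[-1]
        proj = _Projection(
            name=name, pre=pre, post=post, tm=tm,
            conn_ptr=np.asarray(conn_ptr),
            conn_post=np.concatenate(conn_post) if n_conn else np.empty(0, int),
            conn_gpeak=np.concatenate(conn_gpeak) if n_conn else np.empty(0),
            syn_ptr=np.asarray(syn_ptr),
            syn_local=np.concatenate(syn_local) if n_conn else np.empty(0, int),
            syn_post=np.concatenate(syn_post) if n_conn else np.empty(0, int),
            syn_delay_steps=np.concatenate(syn_delay) if n_conn else np.empty(0, int),
        )
        proj.u = np.zeros(n_conn)
        proj.R = np.ones(n_conn)
        proj.t_last = np.full(n_conn, -np.inf)
        projections.append(proj)
    return Network(
        config=config, populations=pops, neuron_params=nparams,
        projections=projections, syn_scale=syn_scale,
    )


def scil_to_inputs(
    scil: int,
    n_pyr: int,
    duration: float,
    dt: float,
    rng: np.random.Generator,
    scale: float = 1.0,
    tm: TMParams | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pre-generate Schaffer-collateral drive events for all PYR cells.

    ``scil / 20`` independent 34 Hz Poisson processes per cell, each making
    6 static synapses with per-synapse conductance uniform on the SC
    g-range (times ``scale``) and delay uniform on [0.5, 2] ms.  Returns
    ``(delivery_step, pyr_index, amplitude)`` sorted by step.
    """
    if scil < 0 or scil % SC_PROCESS_DIVISOR != 0:
        raise ValueError(
            f"scil must be a nonnegative multiple of {SC_PROCESS_DIVISOR}, got {scil}"
        )
    tm = SYNAPSE_REGISTRY["SC->PYR"] if tm is None else tm
    n_proc = scil // SC_PROCESS_DIVISOR
    n_steps = int(round(duration / dt))
    steps, posts, amps = [], [], []
    for cell in range(n_pyr):
        for _ in range(n_proc):
            n_ev = rng.poisson(SC_RATE_HZ * duration * 1e-3)
            t_ev = np.sort(rng.uniform(0.0, duration, size=n_ev))
            g = rng.uniform(tm.g_range[0], tm.g_range[1], size=SC_SYNAPSES) * scale
            d = np.maximum(
                1, np.round(rng.uniform(*tm.delay_range, size=SC_SYNAPSES) / dt)
            ).astype(np.int64)
            ev_steps = np.round(t_ev / dt).astype(np.int64)
            all_steps = (ev_steps[:, None] + d[None, :]).ravel()
            all_amps = np.broadcast_to(g, (n_ev, SC_SYNAPSES)).ravel()
            ok = all_steps < n_steps
            steps.append(all_steps[ok])
            amps.append(all_amps[ok])
            posts.append(np.full(int(ok.sum()), cell, dtype=np.int64))
    if steps:
        steps = np.concatenate(steps)
        posts = np.concatenate(posts)
        amps = np.concatenate(amps)
    else:
        steps = np.empty(0, np.int64); posts = np.empty(0, np.int64); amps = np.empty(0)
    order = np.argsort(steps, kind="stable")
    return steps[order], posts[order], amps[order]


def simulate(
    network: Network,
    record_traces: list[tuple[str, int]] | None = None,
    trace_stride: int = 20,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Run the fixed-step simulation; returns the spike table.

    Spikes are delivered to postsynaptic conductances after their per-
    synapse delay and pass through the per-connection TM state.  The whole
    duration is simulated and returned (the equilibration window is
    discarded at analysis time).  If ``record_traces`` names (population,
    cell) pairs, a second frame with membrane potentials subsampled every
    ``trace_stride`` steps is returned as well.
    """
    cfg = network.config
    dt = cfg.dt
    n_steps = int(round(cfg.duration / dt))
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))

    pop_names = list(network.populations)
    n_cells = {p: network.populations[p].n_groups for p in pop_names}
    states: dict[str, PopulationState] = {}
    decays: dict[str, tuple[float, float]] = {}
    for p in pop_names:
        par = network.neuron_params[p]
        states[p] = population_init(par, n_cells[p], rng)
        decays[p] = (np.exp(-dt / par.tau_fast), np.exp(-dt / par.tau_ca))

    # SC drive (PYR only)
    sc_tm = SYNAPSE_REGISTRY["SC->PYR"]
    has_pyr = "PYR" in n_cells
    if has_pyr and cfg.scil > 0:
        ev_steps, ev_posts, ev_amps = scil_to_inputs(
            cfg.scil, n_cells["PYR"], cfg.duration, dt, rng,
            scale=network.syn_scale.get("SC->PYR", 1.0),
        )
        ev_ptr = np.searchsorted(ev_steps, np.arange(n_steps + 1))
    else:
        ev_posts = np.empty(0, np.int64); ev_amps = np.empty(0)
        ev_ptr = np.zeros(n_steps + 1, np.int64)
    g_sc_fast = np.zeros(n_cells.get("PYR", 0))
    g_sc_slow = np.zeros(n_cells.get("PYR", 0))
    sc_dec_fast = np.exp(-dt / sc_tm.tau_decay_fast)
    sc_dec_slow = np.exp(-dt / sc_tm.tau_decay_slow) if sc_tm.tau_decay_slow else 0.0

    # per-projection conductances and delivery ring buffers
    L = 1
    for proj in network.projections:
        if proj.n_synapses:
            L = max(L, int(proj.syn_delay_steps.max()) + 1)
    proj_state = []
    for proj in network.projections:
        tm = proj.tm
        proj_state.append(
            dict(
                buf=np.zeros((L, n_cells[proj.post])),
                g_fast=np.zeros(n_cells[proj.post]),
                g_slow=np.zeros(n_cells[proj.post]) if tm.tau_decay_slow else None,
                dec_fast=np.exp(-dt / tm.tau_decay_fast),
                dec_slow=np.exp(-dt / tm.tau_decay_slow) if tm.tau_decay_slow else 0.0,
            )
        )
    out_proj: dict[str, list[int]] = {p: [] for p in pop_names}
    for k, proj in enumerate(network.projections):
        out_proj[proj.pre].append(k)

    spike_pop, spike_cell, spike_time = [], [], []
    traces = {key: [] for key in (record_traces or [])}

    for s in range(n_steps):
        t_now = (s + 1) * dt
        row = s % L
        # conductance updates
        if has_pyr:
            g_sc_fast *= sc_dec_fast
            g_sc_slow *= sc_dec_slow
            lo, hi = ev_ptr[s], ev_ptr[s + 1]
            if hi > lo:
                np.add.at(g_sc_fast, ev_posts[lo:hi], ev_amps[lo:hi])
                np.add.at(g_sc_slow, ev_posts[lo:hi], ev_amps[lo:hi] * sc_tm.slow_ratio)
        for proj, ps in zip(network.projections, proj_state):
            inc = ps["buf"][row]
            ps["g_fast"] *= ps["dec_fast"]
            ps["g_fast"] += inc
            if ps["g_slow"] is not None:
                ps["g_slow"] *= ps["dec_slow"]
                ps["g_slow"] += inc * proj.tm.slow_ratio
            inc[:] = 0.0
        # neuron updates
        for p in pop_names:
            g_syn = []
            if p == "PYR" and has_pyr:
                g_syn.append((g_sc_fast, sc_tm.e_rev))
                g_syn.append((g_sc_slow, sc_tm.e_rev))
            for proj, ps in zip(network.projections, proj_state):
                if proj.post != p:
                    continue
                g_syn.append((ps["g_fast"], proj.tm.e_rev))
                if ps["g_slow"] is not None:
                    g_syn.append((ps["g_slow"], proj.tm.e_rev))
            par = network.neuron_params[p]
            try:
                spiked = population_step(states[p], par, g_syn, dt, *decays[p])
            except FloatingPointError as e:
                raise FloatingPointError(
                    f"numerical blow-up in population {p} at t={t_now:.2f} ms: {e}"
                ) from None
            if spiked.any():
                cells = np.nonzero(spiked)[0]
                spike_pop.extend([p] * cells.size)
                spike_cell.extend(cells.tolist())
                spike_time.extend([t_now] * cells.size)
                # propagate through outgoing projections
                for k in out_proj[p]:
                    proj, ps = network.projections[k], proj_state[k]
                    tm = proj.tm
                    for i in cells:
                        cs = slice(proj.conn_ptr[i], proj.conn_ptr[i + 1])
                        if cs.start == cs.stop:
                            continue
                        dt_arr = t_now - proj.t_last[cs]
                        u = proj.u[cs]
                        R = proj.R[cs]
                        if tm.F > 0:
                            u = u * np.exp(-dt_arr / tm.F)
                            np.nan_to_num(u, copy=False)  # -inf t_last -> exp(-inf)=0
                            u = u + tm.U * (1.0 - u)
                        else:
                            u = np.full_like(u, tm.U)
                        if tm.D > 0:
                            decay = np.exp(-dt_arr / tm.D)
                            decay[~np.isfinite(decay)] = 0.0
                            R = 1.0 - (1.0 - R) * decay
                        else:
                            R = np.ones_like(R)
                        release = u * R
                        proj.u[cs] = u
                        proj.R[cs] = R * (1.0 - u)
                        proj.t_last[cs] = t_now
                        amp_conn = proj.conn_gpeak[cs] * (release / tm.U)
                        ss = slice(proj.syn_ptr[i], proj.syn_ptr[i + 1])
                        rows = (s + proj.syn_delay_steps[ss]) % L
                        np.add.at(
                            ps["buf"], (rows, proj.syn_post[ss]),
                            amp_conn[proj.syn_local[ss]],
                        )
        if record_traces:
            if s % trace_stride == 0:
                for (p, i) in record_traces:
                    traces[(p, i)].append(states[p].v[i])

    spikes = pd.DataFrame(
        {
            "population": pd.array(spike_pop, dtype=object),
            "cell_id": np.asarray(spike_cell, dtype=int),
            "time_ms": np.asarray(spike_time, dtype=float),
        }
    )
    spikes = spikes.sort_values(["time_ms", "population", "cell_id"], kind="stable").reset_index(drop=True)
    if record_traces:
        tr = pd.DataFrame(
            {f"{p}_{i}": np.asarray(v) for (p, i), v in traces.items()}
        )
        tr.insert(0, "time_ms", np.arange(len(tr)) * trace_stride * dt + dt)
        return spikes, tr
    return spikes


# ---------------------------------------------------------------------------
# SCIL sweeps
# ---------------------------------------------------------------------------

def simulation_metrics(
    spikes: pd.DataFrame, config: NetworkConfig, como: bool = True
) -> dict[str, float]:
    """Standard per-run metrics from a spike table.

    Rates per population; OLM-or-PYR reference population theta/gamma peak
    frequency and strength; comodulogram band mean/peak PAC of the
    reference population rate.
    """
    sizes = population_sizes(config.variant)
    out: dict[str, float] = {}
    ref = "OLM" if "OLM" in sizes else "PYR"
    for p, n in sizes.items():
        r = ana.bin_rates(
            spikes, p, discard=config.discard, duration=config.duration, n_cells=n
        ) if (spikes["population"] == p).any() else ana.RateSeries(
            values=np.zeros(int((config.duration - config.discard) / 4.0)),
            t0=config.discard,
        )
        out[f"rate_{p}"] = float(r.values.mean())
        win = min(2048.0, r.values.size * r.bin_width / 2)
        psd = ana.welch_psd(r, window_ms=win)
        for band, label in ((ana.THETA_BAND, "theta"), (ana.GAMMA_BAND, "gamma")):
            try:
                bm = ana.peak_in_band(psd, band)
                out[f"{label}_peak_freq_{p}"] = bm.peak_freq
                out[f"{label}_strength_{p}"] = bm.strength
            except ValueError:
                out[f"{label}_peak_freq_{p}"] = np.nan
                out[f"{label}_strength_{p}"] = np.nan
        if p == ref and como:
            try:
                c = ana.comodulogram(
                    r,
                    phase_freqs=np.arange(1.0, 8.01, 0.5),
                    amp_freqs=np.arange(15.0, 50.01, 1.0),
                )
                out["pac_band_mean"] = ana.pac_band_mean(c)
                out["pac_band_peak"] = ana.pac_band_peak(c)
            except ValueError:
                out["pac_band_mean"] = 0.0 if r.values.std() == 0 else np.nan
                out["pac_band_peak"] = 0.0 if r.values.std() == 0 else np.nan
    return out


def run_sweep(
    variant: str,
    scil_list: list[int],
    n_replicates: int = 2,
    base_seed: int = 0,
    duration: float = 6300.0,
    overrides: dict | None = None,
    smooth: int = 3,
) -> pd.DataFrame:
    """Simulate and analyze a SCIL sweep with replicate averaging.

    For each SC input level, ``n_replicates`` independently configured
    simulations are run (replicate ``r`` of SCIL index ``k`` uses seed
    ``base_seed + 1000 * k + r`` so adding replicates never reseeds earlier
    ones); per-run metrics are averaged, SEM across replicates attached,
    and each metric curve smoothed with a 3-point moving average across
    neighbouring SCIL values.  Returns a tidy frame (variant, scil,
    metric, mean, sem).
    """
    if len(scil_list) == 0:
        raise ValueError("scil list must be nonempty")
    if sorted(scil_list) != list(scil_list):
        raise ValueError("scil list must be sorted ascending")
    if n_replicates < 2:
        import warnings

        warnings.warn("n_replicates < 2: SEM reported as 0", stacklevel=2)
    per_metric: dict[str, list[list[float]]] = {}
    for k, scil in enumerate(scil_list):
        vals: dict[str, list[float]] = {}
        for r in range(n_replicates):
            cfg = NetworkConfig(
                variant=variant, scil=scil, duration=duration,
                seed=base_seed + 1000 * k + r, overrides=overrides or {},
            )
            met = simulation_metrics(simulate(build_network(cfg)), cfg)
            for m, v in met.items():
                vals.setdefault(m, []).append(v)
        for m, v in vals.items():
            per_metric.setdefault(m, []).append(v)
    rows = []
    for m, series in per_metric.items():
        means = np.array([np.nanmean(v) for v in series])
        sems = np.array(
            [
                (np.nanstd(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
                for v in series
            ]
        )
        means_s = ana.moving_average(means, smooth)
        for scil, mu, se in zip(scil_list, means_s, sems):
            rows.append(
                {"variant": variant, "scil": scil, "metric": m, "mean": mu, "sem": se}
            )
    return pd.DataFrame(rows)
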