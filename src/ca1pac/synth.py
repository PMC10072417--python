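"""Synthetic signals and spike trains with known theta-nested-gamma structure.

Three generators provide ground-truth fixtures for the analysis chain:

* :func:`gen_pac_signal` — a slow sinusoid plus a fast sinusoid whose
  amplitude is a linear function of the slow one (controllable coupling
  depth), plus white noise.  Because the coupling is linear in
  ``sin``/``cos`` of the slow phase, the GLM comodulogram estimator has an
  analytically predictable response to it.
* :func:`gen_burst_spikes` — stutter-bursting spike trains: clusters of
  gamma-interval spikes recurring each theta cycle, separated by silence.
* :func:`gen_covarying_powers` — standardized band-power series pairs with
  a target correlation (bivariate-normal construction).

All generators take a frozen spec carrying its own seed and are fully
deterministic given that spec.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PACSignalSpec",
    "BurstSpikesSpec",
    "CovaryingPowerSpec",
    "gen_pac_signal",
    "gen_burst_spikes",
    "gen_covarying_powers",
]


@dataclass(frozen=True)
class PACSignalSpec:
    """Amplitude-modulated two-tone test signal.

    ``depth`` in [0, 1] sets how strongly the slow (``f_phase``) cycle
    modulates the fast (``f_amp``) amplitude: 0 = no coupling, 1 = the fast
    component vanishes at the slow trough.
    """

    f_phase: float = 4.5
    f_amp: float = 25.0
    depth: float = 0.8
    noise_sd: float = 0.0
    fs: float = 500.0
    duration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.depth <= 1.0):
            raise ValueError(f"depth must be in [0, 1], got {self.depth}")
        if not (0.0 < self.f_phase < self.f_amp):
            raise ValueError(
                f"need 0 < f_phase < f_amp, got {self.f_phase}, {self.f_amp}"
            )
        if self.f_amp >= self.fs / 2:
            raise ValueError(
                f"f_amp={self.f_amp} must be below Nyquist {self.fs / 2}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9 or n <= 0:
            raise ValueError(
                f"duration*fs must be a positive integer sample count, got {n}"
            )


def gen_pac_signal(spec: PACSignalSpec) -> np.ndarray:
    """Sample ``x(t) = sin(2π f_p t) + m(t) sin(2π f_a t) + ε(t)``.

    The fast-component envelope is
    ``m(t) = 1 - depth + depth * (1 + sin(2π f_p t)) / 2``: it equals 1 at
    the slow-sinusoid peak and ``1 - depth`` at its trough.  ``ε`` is iid
    Normal(0, noise_sd²) from a generator seeded with ``spec.seed``.
    """
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    slow = np.sin(2 * np.pi * spec.f_phase * t)
    env = 1.0 - spec.depth + spec.depth * (1.0 + slow) / 2.0
    x = slow + env * np.sin(2 * np.pi * spec.f_amp * t)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        x = x + rng.normal(0.0, spec.noise_sd, size=n)
    return x


@dataclass(frozen=True)
class BurstSpikesSpec:
    """Theta-recurring gamma bursts across a homogeneous cell population.

    Each theta cycle opens a burst window covering a fraction
    ``1 - inter_burst_silence`` of the cycle; inside it a cell may spike at
    gamma-period slots (shared envelope, per-cell independent occupancy),
    with mean ``spikes_per_burst`` spikes per cycle and Gaussian timing
    jitter ``jitter_sd`` (ms) per spike.
    """

    n_cells: int = 10
    theta_f: float = 5.0
    gamma_f: float = 25.0
    spikes_per_burst: float = 2.5
    inter_burst_silence: float = 0.5
    jitter_sd: float = 1.0
    duration: float = 60_000.0
    seed: int = 0
    population: str = "SYN"

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError(f"n_cells must be >= 0, got {self.n_cells}")
        if self.theta_f <= 0 or self.gamma_f <= 0:
            raise ValueError("theta_f and gamma_f must be positive")
        if self.gamma_f <= self.theta_f:
            raise ValueError(
                f"need gamma_f > theta_f, got {self.gamma_f} <= {self.theta_f}"
            )
        if self.spikes_per_burst < 0:
            raise ValueError("spikes_per_burst must be >= 0")
        if not (0.0 <= self.inter_burst_silence < 1.0):
            raise ValueError("inter_burst_silence must be in [0, 1)")
        if self.jitter_sd < 0 or self.duration < 0:
            raise ValueError("jitter_sd and duration must be >= 0")


def gen_burst_spikes(spec: BurstSpikesSpec) -> pd.DataFrame:
    """Generate a spike table (columns population, cell_id, time_ms).

    Gamma-period slots inside each theta cycle's burst window are occupied
    independently per cell with probability ``spikes_per_burst / n_slots``
    (clipped at 1), so with ``jitter_sd = 0`` intra-burst inter-spike
    intervals are multiples of ``1000 / gamma_f`` ms and the expected
    per-cell rate is ``theta_f * min(spikes_per_burst, n_slots)`` Hz.
    """
    rng = np.random.default_rng(spec.seed)
    theta_period = 1000.0 / spec.theta_f
    gamma_period = 1000.0 / spec.gamma_f
    burst_len = (1.0 - spec.inter_burst_silence) * theta_period
    n_slots = max(1, int(np.floor(burst_len / gamma_period)) + 1)
    p_slot = min(1.0, spec.spikes_per_burst / n_slots)
    n_cycles = int(np.ceil(spec.duration / theta_period))

    pops, cells, times = [], [], []
    for cell in range(spec.n_cells):
        # (n_cycles, n_slots) occupancy; slot k sits at cycle_start + k*gamma_period
        occ = rng.random((n_cycles, n_slots)) < p_slot
        cyc, slot = np.nonzero(occ)
        t = cyc * theta_period + slot * gamma_period
        if spec.jitter_sd > 0:
            t = t + rng.normal(0.0, spec.jitter_sd, size=t.size)
        t = t[(t >= 0) & (t < spec.duration)]
        t.sort()
        times.append(t)
        cells.append(np.full(t.size, cell, dtype=int))
    times = np.concatenate(times) if times else np.empty(0)
    cells = np.concatenate(cells) if cells else np.empty(0, dtype=int)
    return pd.DataFrame(
        {
            "population": np.full(times.size, spec.population, dtype=object),
            "cell_id": cells,
            "time_ms": times,
        }
    )


@dataclass(frozen=True)
class CovaryingPowerSpec:
    """Pair of standardized series with target population correlation rho."""

    n_windows: int = 600
    rho: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.rho) > 1.0:
            raise ValueError(f"|rho| must be <= 1, got {self.rho}")
        if self.n_windows < 3:
            raise ValueError(f"n_windows must be >= 3, got {self.n_windows}")


def gen_covarying_powers(spec: CovaryingPowerSpec) -> tuple[np.ndarray, np.ndarray]:
    """Two zero-mean unit-variance series with correlation ``rho``.

    Construction: x ~ N(0,1); y = rho*x + sqrt(1-rho²)*z with independent
    z ~ N(0,1); both then standardized to exact sample mean 0, sd 1.
    """
    rng = np.random.default_rng(spec.seed)
    x = rng.standard_normal(spec.n_windows)
    z = rng.standard_normal(spec.n_windows)
    y = spec.rho * x + np.sqrt(max(0.0, 1.0 - spec.rho**2)) * z
    x = (x - x.mean()) / x.std()
    y = (y - y.mean()) / y.std()
    return x, y
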