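"""YAML configuration loading and validation.

A config file declares a simulation (variant, SC input level, seeds,
duration) plus optional analysis settings and parameter overrides.  Every
omitted key falls back to the calibrated defaults; unknown keys are
rejected so typos cannot silently change an experiment.

Schema (all keys optional)::

    variant: FM | FMx | FMfix | SM | SMx | SM25 | SM7   (default FM)
    scil: 180            # SC input level, nonnegative multiple of 20
    duration: 6300.0     # ms
    discard: 2000.0      # ms discarded at analysis time
    dt: 0.05             # ms
    seed: 0
    n_replicates: 2
    overrides:
      knockouts: {OLM: [KDR_analog, CAGK_analog]}
      syn_scale: {SC->PYR: 0.03}
      tm_patches: {OLM->PYR: {tau_decay_fast: 11.8}}
      neuron_params: {OLM: {w_fast_jump: 15.0}}
      drop_projections: [OLM->PYR]
    analysis:
      phase_band: [1.0, 8.0]
      amp_band: [15.0, 50.0]
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .network import NetworkConfig

__all__ = ["ExperimentConfig", "load_config"]

_TOP_KEYS = {
    "variant", "scil", "duration", "discard", "dt", "seed", "n_replicates",
    "overrides", "analysis",
}
_ANALYSIS_KEYS = {"phase_band", "amp_band"}


@dataclass(frozen=True)
class ExperimentConfig:
    network: NetworkConfig
    n_replicates: int = 2
    phase_band: tuple[float, float] = (1.0, 8.0)
    amp_band: tuple[float, float] = (15.0, 50.0)


def load_config(path: str | Path) -> ExperimentConfig:
    """Parse and validate a YAML config; empty file means full defaults."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)}; known: {sorted(_TOP_KEYS)}"
        )
    ana = raw.get("analysis") or {}
    bad = set(ana) - _ANALYSIS_KEYS
    if bad:
        raise ValueError(
            f"unknown analysis key(s) {sorted(bad)}; known: {sorted(_ANALYSIS_KEYS)}"
        )
    n_rep = int(raw.get("n_replicates", 2))
    if n_rep < 1:
        raise ValueError(f"n_replicates must be >= 1, got {n_rep}")
    net = NetworkConfig(
        variant=raw.get("variant", "FM"),
        scil=int(raw.get("scil", 180)),
        duration=float(raw.get("duration", 6300.0)),
        discard=float(raw.get("discard", 2000.0)),
        dt=float(raw.get("dt", 0.05)),
        seed=int(raw.get("seed", 0)),
        overrides=raw.get("overrides") or {},
    )
    return ExperimentConfig(
        network=net,
        n_replicates=n_rep,
        phase_band=tuple(ana.get("phase_band", (1.0, 8.0))),
        amp_band=tuple(ana.get("amp_band", (15.0, 50.0))),
    )
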