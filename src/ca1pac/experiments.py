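"""Canonical circuit experiments: variant runs, knockouts, rheobase sweeps.

These functions bundle a simulation with the standard oscillation readouts
so that mechanism comparisons (feedback removal, GABA-decay manipulation,
channel knockouts) are computed identically wherever they are invoked.
"""

from __future__ import annotations

import numpy as np

from . import analysis as ana
from .network import (
    CALIBRATED_SCIL,
    NetworkConfig,
    build_network,
    population_sizes,
    simulate,
)

__all__ = [
    "oscillation_summary",
    "min_scil_sustained_olm",
    "SUSTAINED_OLM_RATE_HZ",
]

# "Sustained firing" threshold for the OLM rheobase sweep: continuous
# spiking at slow-gamma intervals, i.e. a population mean at or above the
# 15-50 Hz band floor (with margin for the stutter duty cycle).
SUSTAINED_OLM_RATE_HZ = 18.0


def oscillation_summary(
    variant: str,
    seed: int,
    scil: int = CALIBRATED_SCIL,
    duration: float = 6300.0,
    overrides: dict | None = None,
    n_surrogates: int = 0,
) -> dict:
    """Simulate one variant and report the standard oscillation metrics.

    Per population: mean rate, theta/gamma peak frequency, peak strength,
    and peak-to-band-median ratio (the detectability statistic).  For the
    reference population (OLM when present): comodulogram band-mean/peak
    PAC, plus - when ``n_surrogates`` > 0 - the time-shift surrogate null
    of the band-mean PAC and its 95th percentile.
    """
    cfg = NetworkConfig(
        variant=variant, scil=scil, duration=duration, seed=seed,
        overrides=overrides or {},
    )
    spikes = simulate(build_network(cfg))
    sizes = population_sizes(variant)
    ref = "OLM" if "OLM" in sizes else "PYR"
    out: dict = {"variant": variant, "seed": seed, "scil": scil}
    for p, n in sizes.items():
        r = ana.bin_rates(
            spikes, p, discard=cfg.discard, duration=duration, n_cells=n
        )
        out[f"rate_{p}"] = float(r.values.mean())
        psd = ana.welch_psd(r)
        for band, label in ((ana.THETA_BAND, "theta"), (ana.GAMMA_BAND, "gamma")):
            bm = ana.peak_in_band(psd, band)
            in_band = psd.power[(psd.freqs >= band[0]) & (psd.freqs <= band[1])]
            med = float(np.median(in_band))
            out[f"{label}_peak_freq_{p}"] = bm.peak_freq
            out[f"{label}_strength_{p}"] = bm.strength
            out[f"{label}_peak_ratio_{p}"] = bm.strength / med if med > 0 else np.inf
        if p == ref:
            c = ana.comodulogram(
                r,
                phase_freqs=np.arange(1.0, 8.01, 0.5),
                amp_freqs=np.arange(15.0, 50.01, 1.0),
            )
            out["pac_band_mean"] = ana.pac_band_mean(c)
            out["pac_band_peak"] = ana.pac_band_peak(c)
            if n_surrogates > 0:
                obs, surr = ana.surrogate_band_pac(
                    r, n_surrogates=n_surrogates, seed=seed + 7919
                )
                out["pac_surrogate_q95"] = float(np.quantile(surr, 0.95))
                out["pac_observed_coarse"] = obs
    out["reference_population"] = ref
    return out


def min_scil_sustained_olm(
    knockout: bool,
    seed: int,
    threshold_hz: float = SUSTAINED_OLM_RATE_HZ,
    scil_grid: tuple[int, ...] = (160, 180, 200, 220, 240, 260, 280, 300),
    duration: float = 3000.0,
    discard: float = 1000.0,
) -> int:
    """Minimum SC input level sustaining OLM firing above ``threshold_hz``.

    Measured in the feedforward circuit (SMx: PYR->OLM only) so that the
    intrinsic-excitability effect of the KDR-analog knockout is read out
    directly rather than compensated by feedback inhibition.  Returns the
    first grid value reaching the threshold (or one step past the grid).
    """
    overrides = {"knockouts": {"OLM": ["KDR_analog"]}} if knockout else {}
    n_olm = population_sizes("SMx")["OLM"]
    for scil in scil_grid:
        cfg = NetworkConfig(
            variant="SMx", scil=scil, duration=duration, discard=discard,
            seed=seed, overrides=overrides,
        )
        spikes = simulate(build_network(cfg))
        sel = (spikes["population"] == "OLM") & (spikes["time_ms"] >= discard)
        rate = sel.sum() / n_olm / ((duration - discard) * 1e-3)
        if rate >= threshold_hz:
            return scil
    return scil_grid[-1] + 20
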