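"""Oscillation analysis for population spike trains.

The chain mirrors standard practice for detecting theta-nested slow gamma
in hippocampal population activity:

1. spike tables -> population firing-rate series (4 ms bins, with an
   initial equilibration window discarded);
2. Welch power spectra (Hann taper, 2048 ms windows, 2-point smoothing)
   and band peak extraction (theta 1-8 Hz, slow gamma 15-50 Hz);
3. phase-amplitude comodulograms using the GLM (Penny-style) estimator:
   PAC(f_theta, f_gamma) is the R-squared of regressing the f_gamma
   amplitude envelope on cos/sin of the f_theta phase;
4. theta-cycle averaging of rate series between successive troughs of the
   band-passed reference rhythm;
5. spectrogram band-power series and their linear covariation.

All series are uniform-grid; times in ms at the binning interface,
frequencies in Hz throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

__all__ = [
    "RateSeries",
    "PSD",
    "Spectrogram",
    "Comodulogram",
    "BandMetrics",
    "ThetaCycleAverage",
    "CovariationResult",
    "bin_rates",
    "moving_average",
    "welch_psd",
    "peak_in_band",
    "phase_amplitude",
    "pac_glm",
    "comodulogram",
    "pac_band_mean",
    "pac_band_peak",
    "surrogate_band_pac",
    "retain_segments",
    "theta_cycle_average",
    "spectrogram",
    "band_power_timeseries",
    "power_covariation",
    "THETA_BAND",
    "GAMMA_BAND",
]

# Scalar-statistic bands: theta phase 1-8 Hz, slow-gamma amplitude 15-50 Hz.
THETA_BAND = (1.0, 8.0)
GAMMA_BAND = (15.0, 50.0)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class RateSeries:
    """Population firing rate per bin, in Hz (count / bin / cell)."""

    values: np.ndarray
    bin_width: float = 4.0  # ms
    t0: float = 2000.0  # ms, start of the first bin

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1000.0 / self.bin_width

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0 + self.bin_width * (np.arange(self.values.size) + 0.5)


@dataclass
class PSD:
    freqs: np.ndarray
    power: np.ndarray
    window_ms: float = 2048.0
    window: str = "hann"


@dataclass
class Spectrogram:
    times: np.ndarray  # s
    freqs: np.ndarray  # Hz
    power: np.ndarray  # (freqs, times)


@dataclass
class Comodulogram:
    phase_freqs: np.ndarray
    amp_freqs: np.ndarray
    pac: np.ndarray  # (phase, amp), R-squared values in [0, 1]


@dataclass
class BandMetrics:
    peak_freq: float
    strength: float

    @property
    def log_strength(self) -> float:
        return float(np.log10(self.strength)) if self.strength > 0 else -np.inf


@dataclass
class ThetaCycleAverage:
    templates: dict[str, np.ndarray]
    n_segments_used: int
    f_theta: float


@dataclass
class CovariationResult:
    r_squared: float
    slope: float
    n_windows: int


# ---------------------------------------------------------------------------
# rates and spectra
# ---------------------------------------------------------------------------

def bin_rates(
    spikes: pd.DataFrame,
    population: str,
    bin_width: float = 4.0,
    discard: float = 2000.0,
    duration: float | None = None,
    n_cells: int | None = None,
) -> RateSeries:
    """Bin one population's spikes into a firing-rate series.

    Rate per bin is ``count / (bin_width_s * n_cells)`` in Hz.  ``n_cells``
    defaults to the number of distinct cell ids observed for that
    population (pass the true cell count when silent cells exist);
    ``duration`` defaults to the latest spike time in the table, rounded up
    to a whole bin.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    known = spikes["population"].unique()
    if population not in known and len(known) > 0:
        raise KeyError(
            f"unknown population {population!r}; table has {sorted(known)}"
        )
    sub = spikes[spikes["population"] == population]
    if n_cells is None:
        n_cells = max(1, sub["cell_id"].nunique())
    if duration is None:
        t_max = float(spikes["time_ms"].max()) if len(spikes) else discard
        duration = discard + bin_width * np.ceil(max(0.0, t_max - discard) / bin_width)
    n_bins = int(np.ceil((duration - discard) / bin_width))
    if n_bins <= 0:
        raise ValueError(f"no analysis window: duration {duration} <= discard {discard}")
    t = sub["time_ms"].to_numpy()
    t = t[(t >= discard) & (t < discard + n_bins * bin_width)]
    counts = np.bincount(((t - discard) / bin_width).astype(int), minlength=n_bins)
    rate = counts / (bin_width * 1e-3 * n_cells)
    return RateSeries(values=rate.astype(float), bin_width=bin_width, t0=discard)


def moving_average(x: np.ndarray, n: int) -> np.ndarray:
    """Centered n-point moving average, same length (shrinking at edges)."""
    if n <= 1:
        return np.asarray(x, dtype=float)
    x = np.asarray(x, dtype=float)
    c = np.cumsum(np.concatenate(([0.0], x)))
    half_lo, half_hi = (n - 1) // 2, n // 2
    idx = np.arange(x.size)
    lo = np.maximum(0, idx - half_lo)
    hi = np.minimum(x.size, idx + half_hi + 1)
    return (c[hi] - c[lo]) / (hi - lo)


def welch_psd(
    rate: RateSeries, window_ms: float = 2048.0, smooth_points: int = 2
) -> PSD:
    """Welch averaged-periodogram PSD of a rate series.

    Hann taper, ``window_ms``-long segments with 50% overlap, followed by an
    ``smooth_points``-point moving average of the power values.
    """
    nperseg = int(round(window_ms / rate.bin_width))
    if rate.values.size < nperseg:
        raise ValueError(
            f"series of {rate.values.size} samples shorter than "
            f"window of {nperseg} samples"
        )
    freqs, power = sps.welch(
        rate.values, fs=rate.fs, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2,
    )
    power = moving_average(power, smooth_points)
    return PSD(freqs=freqs, power=power, window_ms=window_ms)


def peak_in_band(psd: PSD, band: tuple[float, float]) -> BandMetrics:
    """Location and height of the PSD maximum inside a closed band."""
    lo, hi = band
    if lo > hi:
        raise ValueError(f"empty band {band}")
    if lo < psd.freqs[0] or hi > psd.freqs[-1]:
        raise ValueError(
            f"band {band} outside frequency range "
            f"[{psd.freqs[0]}, {psd.freqs[-1]}]"
        )
    mask = (psd.freqs >= lo) & (psd.freqs <= hi)
    if not mask.any():
        raise ValueError(f"no frequency samples inside band {band}")
    i = np.argmax(psd.power[mask])
    return BandMetrics(
        peak_freq=float(psd.freqs[mask][i]), strength=float(psd.power[mask][i])
    )


# ---------------------------------------------------------------------------
# phase-amplitude coupling
# ---------------------------------------------------------------------------

def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float, order: int) -> np.ndarray:
    """Zero-phase Butterworth bandpass (forward-backward, SOS form)."""
    nyq = fs / 2.0
    lo = max(lo, 0.05)
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz overlaps Nyquist {nyq} Hz")
    sos = sps.butter(order, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    return sps.sosfiltfilt(sos, x)


def phase_amplitude(
    x: np.ndarray,
    fs: float,
    f_phase: float,
    f_amp: float,
    phase_hw: float = 1.0,
    amp_hw: float | None = None,
    order: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous phase at ``f_phase`` and amplitude envelope at ``f_amp``.

    The phase band is ``f_phase ± phase_hw``; the amplitude band half-width
    is fixed (default 8 Hz) so the coupling sidebands at
    ``f_amp ± f_phase`` pass the filter for any phase frequency up to 8 Hz
    while keeping the passband identical across the phase axis (a
    phase-frequency-dependent width would bias the comodulogram argmax
    toward wider bands).  Phase/amplitude come from the analytic signal
    (Hilbert transform) of each band-passed series.
    """
    if amp_hw is None:
        amp_hw = 8.0
    xp = _bandpass(np.asarray(x, float), fs, f_phase - phase_hw, f_phase + phase_hw, order)
    xa = _bandpass(np.asarray(x, float), fs, f_amp - amp_hw, f_amp + amp_hw, order)
    phi = np.angle(sps.hilbert(xp))
    amp = np.abs(sps.hilbert(xa))
    return phi, amp


def pac_glm(phi: np.ndarray, amp: np.ndarray) -> float:
    """R-squared of the regression ``A ~ b0 + b1 cos(phi) + b2 sin(phi)``.

    This is the GLM phase-amplitude coupling statistic: the fraction of
    amplitude-envelope variance explained by the first circular harmonic of
    the phase.  Scale-free in ``amp`` and bounded in [0, 1].
    """
    a = amp - amp.mean()
    sst = float(a @ a)
    if sst <= 0:
        return 0.0
    X = np.column_stack([np.cos(phi), np.sin(phi)])
    X = X - X.mean(axis=0)
    coef, *_ = np.linalg.lstsq(X, a, rcond=None)
    ssr = float(a @ a - (a - X @ coef) @ (a - X @ coef))
    return float(min(1.0, max(0.0, ssr / sst)))


def comodulogram(
    rate: RateSeries | np.ndarray,
    phase_freqs: np.ndarray | None = None,
    amp_freqs: np.ndarray | None = None,
    fs: float | None = None,
    phase_hw: float = 1.0,
    amp_hw: float = 8.0,
) -> Comodulogram:
    """PAC matrix over a (phase frequency, amplitude frequency) grid.

    Defaults: phase 1-12 Hz in 0.5 Hz steps, amplitude 12-50 Hz in 1 Hz
    steps, phase/amplitude band half-widths 1 / 8 Hz.  Accepts a
    :class:`RateSeries` or a plain array plus ``fs``.
    """
    if isinstance(rate, RateSeries):
        x, fs = rate.values, rate.fs
    else:
        if fs is None:
            raise ValueError("fs is required for array input")
        x = np.asarray(rate, float)
    phase_freqs = (
        np.arange(1.0, 12.01, 0.5) if phase_freqs is None else np.asarray(phase_freqs, float)
    )
    amp_freqs = (
        np.arange(12.0, 50.01, 1.0) if amp_freqs is None else np.asarray(amp_freqs, float)
    )
    if x.size < 3 * fs / phase_freqs.min():
        raise ValueError(
            "series too short: need at least ~3 cycles of the slowest "
            f"phase frequency {phase_freqs.min()} Hz"
        )
    # amplitude envelopes are phase-frequency independent: extract once
    amps = [
        np.abs(sps.hilbert(_bandpass(x, fs, fa - amp_hw, fa + amp_hw, 3)))
        for fa in amp_freqs
    ]
    pac = np.zeros((phase_freqs.size, amp_freqs.size))
    for i, fp in enumerate(phase_freqs):
        xp = _bandpass(x, fs, fp - phase_hw, fp + phase_hw, 3)
        phi = np.angle(sps.hilbert(xp))
        cs = np.column_stack([np.cos(phi), np.sin(phi)])
        cs = cs - cs.mean(axis=0)
        for j, a in enumerate(amps):
            pac[i, j] = pac_glm_precomputed(cs, a)
    return Comodulogram(phase_freqs=phase_freqs, amp_freqs=amp_freqs, pac=pac)


def _band_mask(grid: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    return (grid >= band[0]) & (grid <= band[1])


def pac_band_mean(
    como: Comodulogram,
    phase_band: tuple[float, float] = THETA_BAND,
    amp_band: tuple[float, float] = GAMMA_BAND,
) -> float:
    """Mean PAC over grid points inside phase_band x amp_band."""
    pm, am = _band_mask(como.phase_freqs, phase_band), _band_mask(como.amp_freqs, amp_band)
    if not pm.any() or not am.any():
        raise ValueError(
            f"bands {phase_band} x {amp_band} select no grid points"
        )
    return float(como.pac[np.ix_(pm, am)].mean())


def pac_band_peak(
    como: Comodulogram,
    phase_band: tuple[float, float] = THETA_BAND,
    amp_band: tuple[float, float] = GAMMA_BAND,
) -> float:
    """Maximum PAC over grid points inside phase_band x amp_band."""
    pm, am = _band_mask(como.phase_freqs, phase_band), _band_mask(como.amp_freqs, amp_band)
    if not pm.any() or not am.any():
        raise ValueError(
            f"bands {phase_band} x {amp_band} select no grid points"
        )
    return float(como.pac[np.ix_(pm, am)].max())


def surrogate_band_pac(
    rate: RateSeries | np.ndarray,
    n_surrogates: int = 100,
    phase_band: tuple[float, float] = THETA_BAND,
    amp_band: tuple[float, float] = GAMMA_BAND,
    phase_step: float = 1.0,
    amp_step: float = 5.0,
    fs: float | None = None,
    seed: int = 0,
    method: str = "timeshift",
    stat: str = "mean",
    amp_hw: float = 8.0,
) -> tuple[float, np.ndarray]:
    """Observed band PAC and its surrogate null distribution.

    ``timeshift`` surrogates circularly shift each amplitude envelope
    relative to its phase series by a random offset of at least one slow
    cycle, and ``scramble`` randomizes the envelope's Fourier phases; both
    preserve the envelope's amplitude spectrum, which suits stochastic
    signals whose phase diffuses but degenerates for strictly periodic
    fixtures (the GLM R-squared of two pure tones is invariant to their
    relative phase).  ``blockshuffle`` permutes the envelope in blocks of
    a few slow cycles relative to the phase series, decohering any
    rhythmic envelope component (its coherent power drops by the block
    count) while leaving incoherent noise components distributionally
    unchanged - the appropriate permutation null for periodic fixtures.
    The GLM regression is re-fit per surrogate on the cached envelopes,
    so the cost is dominated by the one-off filtering.

    Returns ``(observed, surrogate_values)`` for the band statistic
    (``mean`` or ``peak``) over a coarse grid with the given steps.
    """
    if isinstance(rate, RateSeries):
        x, fs = rate.values, rate.fs
    else:
        if fs is None:
            raise ValueError("fs is required for array input")
        x = np.asarray(rate, float)
    rng = np.random.default_rng(seed)
    pfs = np.arange(phase_band[0], phase_band[1] + 1e-9, phase_step)
    afs = np.arange(amp_band[0], amp_band[1] + 1e-9, amp_step)
    n = x.size
    designs = []
    for fp in pfs:
        xp = _bandpass(x, fs, fp - 1.0, fp + 1.0, 3)
        phi = np.angle(sps.hilbert(xp))
        cs = np.column_stack([np.cos(phi), np.sin(phi)])
        designs.append(cs - cs.mean(axis=0))
    amp_envs = [
        np.abs(sps.hilbert(_bandpass(x, fs, fa - amp_hw, fa + amp_hw, 3)))
        for fa in afs
    ]

    vals = np.empty((pfs.size, afs.size))
    for i in range(pfs.size):
        for j, a in enumerate(amp_envs):
            vals[i, j] = pac_glm_precomputed(designs[i], a)
    observed = float(vals.mean() if stat == "mean" else vals.max())

    min_shift = max(1, int(fs / phase_band[0]))
    surr = np.empty(n_surrogates)
    if method == "timeshift":
        # A circular shift of the amplitude envelope leaves its mean and
        # sum of squares unchanged, so the GLM R-squared at every shift
        # follows from the circular cross-correlations of the envelope
        # with the cos/sin regressors - two FFTs per grid cell give all
        # n shifts at once.
        r2_all = np.empty((pfs.size, afs.size, n))
        for i, cs in enumerate(designs):
            c0, s0 = cs[:, 0], cs[:, 1]
            G = np.array([[c0 @ c0, c0 @ s0], [c0 @ s0, s0 @ s0]])
            Gi = np.linalg.inv(G)
            Fc, Fs = np.fft.rfft(c0), np.fft.rfft(s0)
            for j, a in enumerate(amp_envs):
                a0 = a - a.mean()
                sst = float(a0 @ a0)
                if sst <= 0:
                    r2_all[i, j] = 0.0
                    continue
                Fa = np.conj(np.fft.rfft(a0))
                b1 = np.fft.irfft(Fc * Fa, n=n)
                b2 = np.fft.irfft(Fs * Fa, n=n)
                ssr = (
                    Gi[0, 0] * b1 * b1 + 2 * Gi[0, 1] * b1 * b2 + Gi[1, 1] * b2 * b2
                )
                r2_all[i, j] = np.clip(ssr / sst, 0.0, 1.0)
        offs = rng.integers(min_shift, n - min_shift, size=(n_surrogates, pfs.size, afs.size))
        ii, jj = np.meshgrid(np.arange(pfs.size), np.arange(afs.size), indexing="ij")
        for k in range(n_surrogates):
            v = r2_all[ii, jj, offs[k]]
            surr[k] = v.mean() if stat == "mean" else v.max()
    elif method == "blockshuffle":
        block_s = max(1.0, 2.0 / phase_band[0])
        n_blocks = max(4, int(round(n / (block_s * fs))))
        # precompute Gram inverses and centered envelopes
        grams, c0s, s0s = [], [], []
        for cs in designs:
            c0, s0 = cs[:, 0], cs[:, 1]
            G = np.array([[c0 @ c0, c0 @ s0], [c0 @ s0, s0 @ s0]])
            grams.append(np.linalg.inv(G))
            c0s.append(c0)
            s0s.append(s0)
        a0s = [a - a.mean() for a in amp_envs]
        ssts = [float(a0 @ a0) for a0 in a0s]
        for k in range(n_surrogates):
            # random cut points each surrogate: block lengths incommensurate
            # with any fixed modulation period, so displaced blocks land at
            # uniformly random relative phase
            cuts = np.sort(rng.choice(np.arange(1, n), size=n_blocks - 1, replace=False))
            bounds = np.concatenate(([0], cuts, [n]))
            order = rng.permutation(n_blocks)
            idx = np.concatenate([np.arange(bounds[b], bounds[b + 1]) for b in order])
            vals_k = np.empty((pfs.size, afs.size))
            for j, a0 in enumerate(a0s):
                ap = a0[idx]
                ap = ap - ap.mean()
                for i in range(pfs.size):
                    b1, b2 = c0s[i] @ ap, s0s[i] @ ap
                    Gi = grams[i]
                    ssr = Gi[0, 0] * b1 * b1 + 2 * Gi[0, 1] * b1 * b2 + Gi[1, 1] * b2 * b2
                    vals_k[i, j] = min(1.0, max(0.0, ssr / ssts[j])) if ssts[j] > 0 else 0.0
            surr[k] = vals_k.mean() if stat == "mean" else vals_k.max()
    elif method == "scramble":
        for k in range(n_surrogates):
            vals_k = np.empty((pfs.size, afs.size))
            scr = [_phase_scramble(a, rng) for a in amp_envs]
            for i in range(pfs.size):
                for j, a in enumerate(scr):
                    vals_k[i, j] = pac_glm_precomputed(designs[i], a)
            surr[k] = vals_k.mean() if stat == "mean" else vals_k.max()
    else:
        raise ValueError(f"unknown surrogate method {method!r}")
    return observed, surr


def pac_glm_precomputed(design: np.ndarray, amp: np.ndarray) -> float:
    """GLM PAC R-squared from a centered cos/sin design matrix."""
    a = amp - amp.mean()
    sst = float(a @ a)
    if sst <= 0:
        return 0.0
    coef, *_ = np.linalg.lstsq(design, a, rcond=None)
    resid = a - design @ coef
    return float(min(1.0, max(0.0, (sst - float(resid @ resid)) / sst)))


def _phase_scramble(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Randomize Fourier phases, preserving the amplitude spectrum."""
    X = np.fft.rfft(x)
    phases = rng.uniform(0, 2 * np.pi, size=X.size)
    phases[0] = 0.0
    return np.fft.irfft(np.abs(X) * np.exp(1j * phases), n=x.size)


# ---------------------------------------------------------------------------
# theta-cycle averaging
# ---------------------------------------------------------------------------

def retain_segments(lengths_s: np.ndarray, f_theta: float) -> np.ndarray:
    """Boolean mask of trough-to-trough segment lengths inside the closed
    tolerance interval ``[0.9 / f_theta, 1.1 / f_theta]`` seconds."""
    lengths_s = np.asarray(lengths_s, float)
    return (lengths_s >= 0.9 / f_theta) & (lengths_s <= 1.1 / f_theta)


def _block_resample(x: np.ndarray, m: int) -> np.ndarray:
    """Moving-average decimation of ``x`` to ``m`` points (block means)."""
    n = x.size
    if n == m:
        return x.astype(float)
    edges = np.linspace(0, n, m + 1)
    out = np.empty(m)
    for j in range(m):
        lo, hi = int(np.floor(edges[j])), max(int(np.floor(edges[j])) + 1, int(np.ceil(edges[j + 1])))
        out[j] = x[lo:min(hi, n)].mean()
    return out


def theta_cycle_average(
    rates: dict[str, RateSeries],
    reference: RateSeries,
    f_theta: float | None = None,
) -> ThetaCycleAverage:
    """Average rate series over theta cycles of a reference rhythm.

    Steps: (1) the reference theta peak frequency f_theta is read off its
    Welch PSD in 1-8 Hz unless given; (2) the reference is band-passed in
    ``f_theta ± 1`` Hz with a zero-phase 5th-order Butterworth filter;
    (3) local minima of the filtered trace lying below its mean mark
    troughs; (4) every population's rate series is cut at those troughs;
    (5) segments with length outside the closed interval
    ``[0.9/f_theta, 1.1/f_theta]`` s are discarded; (6) retained segments
    are moving-average-decimated to the shortest retained length and
    (7) averaged per population.
    """
    if f_theta is None:
        psd = welch_psd(reference, window_ms=min(2048.0, reference.values.size * reference.bin_width / 2))
        f_theta = peak_in_band(psd, THETA_BAND).peak_freq
    filt = _bandpass(reference.values, reference.fs, f_theta - 1.0, f_theta + 1.0, 5)
    if filt.std() < 1e-12 * max(1.0, float(np.std(reference.values))):
        raise ValueError(
            "no valid theta cycles: reference has no detectable oscillation "
            f"around {f_theta} Hz"
        )
    # troughs: strict local minima below the filtered-trace mean
    interior = np.arange(1, filt.size - 1)
    is_trough = (filt[interior] < filt[interior - 1]) & (filt[interior] <= filt[interior + 1])
    troughs = interior[is_trough & (filt[interior] < filt.mean())]
    if troughs.size < 2:
        raise ValueError("no valid theta cycles: fewer than two troughs detected")
    lengths_s = np.diff(troughs) * reference.bin_width * 1e-3
    keep = retain_segments(lengths_s, f_theta)
    if not keep.any():
        raise ValueError(
            "no valid theta cycles: all segments outside the "
            f"[{0.9 / f_theta:.3f}, {1.1 / f_theta:.3f}] s tolerance"
        )
    seg_bounds = [
        (troughs[i], troughs[i + 1]) for i in np.nonzero(keep)[0]
    ]
    min_len = min(b - a for a, b in seg_bounds)
    templates = {}
    for name, rs in rates.items():
        segs = [
            _block_resample(rs.values[a:b], min_len) for a, b in seg_bounds
        ]
        templates[name] = np.mean(segs, axis=0)
    return ThetaCycleAverage(
        templates=templates, n_segments_used=len(seg_bounds), f_theta=float(f_theta)
    )


# ---------------------------------------------------------------------------
# spectrogram band power and covariation
# ---------------------------------------------------------------------------

def spectrogram(rate: RateSeries, window_ms: float = 256.0) -> Spectrogram:
    """Short-time spectrum (Hann taper, 50% overlap)."""
    nperseg = int(round(window_ms / rate.bin_width))
    if rate.values.size <= nperseg:
        raise ValueError("series not longer than the spectrogram window")
    freqs, times, power = sps.spectrogram(
        rate.values, fs=rate.fs, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2,
    )
    return Spectrogram(times=times, freqs=freqs, power=power)


def band_power_timeseries(
    spec: Spectrogram, center: float, bandwidth: float
) -> np.ndarray:
    """Standardized band-power series: spectrogram rows averaged over
    ``center ± bandwidth/2`` then z-scored (exact mean 0, sd 1)."""
    lo, hi = center - bandwidth / 2.0, center + bandwidth / 2.0
    mask = (spec.freqs >= lo) & (spec.freqs <= hi)
    if not mask.any():
        raise ValueError(
            f"band [{lo}, {hi}] Hz selects no spectrogram frequencies"
        )
    p = spec.power[mask].mean(axis=0)
    sd = p.std()
    if sd == 0:
        raise ValueError("zero-variance band power: cannot standardize")
    return (p - p.mean()) / sd


def power_covariation(
    theta_power: np.ndarray, gamma_power: np.ndarray
) -> CovariationResult:
    """OLS regression of gamma band power on theta band power."""
    theta_power = np.asarray(theta_power, float)
    gamma_power = np.asarray(gamma_power, float)
    if theta_power.size != gamma_power.size:
        raise ValueError("series lengths differ")
    if theta_power.size < 3:
        raise ValueError("need at least 3 windows")
    if theta_power.std() == 0 or gamma_power.std() == 0:
        raise ValueError("zero-variance input")
    res = spstats.linregress(theta_power, gamma_power)
    return CovariationResult(
        r_squared=float(res.rvalue**2),
        slope=float(res.slope),
        n_windows=int(theta_power.size),
    )


# ---------------------------------------------------------------------------
# one-call summary
# ---------------------------------------------------------------------------

def full_metrics(
    spikes: pd.DataFrame,
    n_cells: dict[str, int] | None = None,
    discard: float = 2000.0,
    duration: float | None = None,
    phase_band: tuple[float, float] = THETA_BAND,
    amp_band: tuple[float, float] = GAMMA_BAND,
) -> dict:
    """Standard metric summary of a spike table.

    Per population: mean rate, theta/gamma PSD peak frequency and strength.
    For the reference population (OLM if present, else the first): band
    mean/peak PAC of the comodulogram, and the theta/gamma spectrogram
    band-power covariation (R-squared and slope).
    """
    pops = sorted(spikes["population"].unique())
    if not pops:
        raise ValueError("empty spike table")
    ref = "OLM" if "OLM" in pops else pops[0]
    out: dict = {"populations": {}}
    for p in pops:
        n = (n_cells or {}).get(p)
        r = bin_rates(spikes, p, discard=discard, duration=duration, n_cells=n)
        # Welch window 2048 ms, clamped to half the series for short runs
        win = min(2048.0, r.values.size * r.bin_width / 2)
        psd = welch_psd(r, window_ms=win)
        th = peak_in_band(psd, phase_band)
        ga = peak_in_band(psd, amp_band)
        out["populations"][p] = {
            "rate": float(r.values.mean()),
            "theta_peak_freq": th.peak_freq,
            "theta_strength": th.strength,
            "gamma_peak_freq": ga.peak_freq,
            "gamma_strength": ga.strength,
        }
        if p == ref:
            try:
                c = comodulogram(
                    r,
                    phase_freqs=np.arange(phase_band[0], phase_band[1] + 1e-9, 0.5),
                    amp_freqs=np.arange(amp_band[0], amp_band[1] + 1e-9, 1.0),
                )
                out["pac_band_mean"] = pac_band_mean(c, phase_band, amp_band)
                out["pac_band_peak"] = pac_band_peak(c, phase_band, amp_band)
            except ValueError:
                out["pac_band_mean"] = float("nan")
                out["pac_band_peak"] = float("nan")
            try:
                spec = spectrogram(r)
                tp = band_power_timeseries(spec, th.peak_freq, 1.0)
                gp = band_power_timeseries(spec, ga.peak_freq, 8.0)
                cv = power_covariation(tp, gp)
                out["covariation"] = {"r2": cv.r_squared, "slope": cv.slope}
            except ValueError:
                out["covariation"] = {"r2": float("nan"), "slope": float("nan")}
    out["reference_population"] = ref
    return out
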