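# Methods

This note records the models, conventions and calibration behind
`ca1pac`, at the level a maintainer needs to change them safely.

## Synapses

Each connection (ordered pre/post model-cell pair with at least one
synaptic contact) carries one Tsodyks–Markram state (u, R). The update
convention is decay-then-increment with release before depletion and
initial state u=0, R=1, so a rested synapse releases exactly U on its
first event. F=0 pins u at U (no facilitation); D=0 pins R at 1 (no
depression). Conductance event amplitudes are `g_peak * release / U`, so
the first event of a rested synapse has amplitude `g_peak`; this
normalization is a convention choice (the alternative, amplitude
∝ u·R without the 1/U factor, rescales g uniformly and is absorbed by
the calibration scales below).

Kernels are peak-normalized instantaneous-rise exponentials: a fast
component (AMPA- or GABA-like) plus an optional slow component scaled by
`slow_ratio` (the NMDA-like part; the published "NMDA ratio" is read as a
slow:fast peak-conductance ratio). The NMDA Mg²⁺ voltage block is not
modeled — the slow component is a passive conductance. This is the single
largest deviation from the biophysical synapse and the reason excitatory
projections need the scale factors described under *Calibration*.

Two oracles guard the event-driven recursion: a closed-form periodic
fixed point (exact for F=0, fixed-point iteration to 1e-12 otherwise) and
a fine-step reference integrator of the inter-spike ODEs
(`tm_fine_step_oracle`). The reference uses classical RK4 at dt=0.001 ms:
a first-order Euler reference at that step has intrinsic error
~Δt·dt/(2D²) ≈ 7e-6 per 20 ms interval for D=38 ms, larger than the
1e-6 agreement we require of the recursion itself, whereas RK4's O(dt⁴)
error is ~1e-10. Since n RK4 steps of a linear decay compound to a fixed
per-step factor to the n-th power, the reference is evaluated in closed
form, bit-identical to the step loop.

## Neurons

All three cell types are the same adaptive conductance-based LIF:

    C dV/dt = −g_L(V−E_L) − Σ g_syn(V−E_syn) − (w + g_KCa)(V−E_K)

with spike at V ≥ V_T, reset to V_r, absolute refractory 2 ms, and two
spike-triggered adaptation conductances: `w += w_fast_jump` decaying with
τ_fast (fast AHP; knockout name `KDR_analog`) and a calcium variable
`Ca += ca_jump` decaying with τ_ca gating
`g_KCa = g_kca_max · Ca/(Ca + K_half)` (knockout name `CAGK_analog`).
Integration is exponential-Euler at dt = 0.05 ms; E_K = −90 mV,
E_syn = 0 mV (excitatory) / −80 mV (inhibitory). Channel knockouts zero
the corresponding conductance contribution, mirroring the
set-the-peak-conductance-to-zero manipulation of detailed models; the
reduced model cannot distinguish the individual Ca-channel subtypes, so a
Ca-channel knockout collapses onto the CAGK knockout.

OLM parameters (C=80 pF, g_L=5 nS, E_L=−60, V_T=−45, V_r=−55,
w_jump=15 nS, τ_fast=25 ms, ca_jump=0.15, τ_ca=200 ms, g_KCa,max=30 nS,
K_half=1) were chosen so that, under Poisson conductance drive with a
slow component (50 ms events, as its circuit input has through the slow
NMDA-like kernel):

* near rheobase (~100 events/s of 1.5 nS) the ISI distribution is
  bimodal — ~24% of intervals at gamma (15–67 ms) and ~28% at theta
  (120–400 ms): stutter bursts;
* at 2–3× that drive the cell fires tonically at slow-gamma intervals
  (median ISI 26–39 ms), the frequency increasing with drive.

The mechanism only needs these qualitative phenotypes; absolute
frequencies of the detailed multicompartment models are calibration
targets, not guarantees. PYR is a mildly adapting regular cell; PVBC is
fast-spiking with no slow adaptation (no burst mechanism by
construction).

## Network

Model cells represent groups of biological cells; group size enters only
through the binomial synapse-count draw `B(group_size(pre) ×
syn_per_conn, p_conn)` per ordered pair (self-connections excluded).
Peak conductance is drawn once per connection (uniform on the
projection's range) and shared by its contacts; each contact draws its
own delay uniform on [0.5, 2] ms, quantized to the integration step.
Schaffer-collateral drive is `scil/20` independent Poisson processes per
PYR at 34 Hz, each contacting the cell through 6 static synapses
(g ∈ [0.55, 0.65] nS before scaling). Simulations run 6.3 s; the first
2 s are discarded at analysis time. A simulation is fully determined by
its `NetworkConfig` (variant, SCIL, duration, dt, seed, overrides).

### Calibration

Because the point neurons integrate the un-blocked slow kernel over its
full 148.5 ms decay, the raw excitatory conductances are far too strong
(the slow component alone would contribute hundreds of nS). Each
projection therefore carries a scale factor, fixed once by calibration
against the published operating rates (PYR ≈ 13–26 Hz, OLM ≈ 5–15 Hz,
interneurons driven but not saturated):

| projection | scale | | projection | scale |
|---|---|---|---|---|
| SC→PYR | 0.03 | | OLM→PYR | 1.0 |
| PYR→OLM | 0.008 | | PVBC→PYR | 1.0 |
| PYR→PVBC | 0.02 | | PVBC→PVBC | 1.0 |
| PYR→PYR | 0.002 | | | |

Inhibitory projections are unscaled. PYR→PYR is the most sensitive knob:
recurrent excitation through the slow kernel is explosively supralinear,
and 0.002 keeps the full model at its intended rates.

The operating SC level was then located with a SCIL sweep of the SM
variant (160–280, six seeds): at SCIL 220 every seed shows OLM theta and
slow-gamma PSD peaks at 14–1600× their band medians and
surrogate-significant band-mean PAC (0.05–0.19 against a time-shift
surrogate 95th percentile of 0.02–0.05). `CALIBRATED_SCIL = 220` is the
default for the mechanism experiments. Mechanism contrasts are reported
as means over two independently configured replicate simulations,
matching the two-replicates-per-condition averaging convention of the
sweep machinery (`run_sweep` additionally applies a 3-point moving
average across neighbouring SCIL and reports SEM over replicates).

At this operating point the SM expresses theta at ~7.5–7.8 Hz and slow
gamma at ~24 Hz. The theta frequency sits in the upper half of the 1–8 Hz
analysis band (detailed-model circuits put it nearer 4.5 Hz); it is set
by the OLM calcium recovery time and the loop gain, and all mechanism
contrasts are frequency-band-based, so this offset does not affect them.

## Analysis conventions

* **Rates**: 4 ms bins, Hz per cell (`count/(bin·n_cells)`); the 30-point
  display smoothing is never applied before spectral estimation.
* **Spectra**: Welch, Hann taper, 2048 ms windows, 50% overlap, 2-point
  moving-average smoothing of power (window clamped to half the series
  for short diagnostic runs). Band peaks are closed-interval maxima;
  strength is reported raw, with a log transform available.
* **Comodulogram**: per phase frequency, band-pass f_θ ± 1 Hz
  (3rd-order Butterworth, forward–backward), phase from the analytic
  signal; per amplitude frequency, band-pass f_γ ± 8 Hz, envelope from
  the analytic signal; PAC = R² of A ~ 1 + cos φ + sin φ. The amplitude
  half-width is *fixed* at 8 Hz rather than growing with f_θ: it must
  exceed the coupling sideband offset (f_γ ± f_θ) for all phase
  frequencies of interest (≤ 8 Hz), and a width that grows with f_θ
  monotonically inflates R² along the phase axis, biasing the argmax
  upward by ~1 Hz. Scalar statistics (band mean and band peak) use
  phase 1–8 × amplitude 15–50 Hz; the wider 1–12 × 12–50 grid is the
  plotting default, and both band conventions are selectable.
* **Surrogates**: three nulls with different validity domains.
  *Time shift* (circular shift of the envelope by ≥ one slow cycle) and
  *Fourier scramble* preserve the envelope's amplitude spectrum, which is
  correct for stochastic signals whose phase diffuses (circuit rates) but
  degenerate for strictly periodic fixtures — the GLM R² of two pure
  tones is invariant to their relative phase, so those surrogates
  reproduce the observed value by construction. *Block permutation*
  (random-boundary blocks of ~2 slow cycles, permuted relative to the
  phase series) decoheres rhythmic envelope components (coherent power
  drops by the block count) while leaving incoherent noise components
  distributionally unchanged; it calibrates at the nominal 5% false-
  positive rate on uncoupled fixtures and is the default for synthetic-
  signal testing. Time-shift surrogate sweeps use an FFT cross-
  correlation identity to evaluate all shifts at once.
* **Theta-cycle averaging**: reference theta frequency from the 1–8 Hz
  PSD peak; zero-phase 5th-order Butterworth band-pass f_Θ ± 1 Hz;
  troughs are strict local minima below the filtered-trace mean;
  segments outside the closed interval [0.9/f_Θ, 1.1/f_Θ] are discarded;
  retained segments are block-mean decimated to the shortest retained
  length and averaged. A reference with no detectable oscillation raises
  an explicit "no valid theta cycles" error.
* **Covariation**: spectrogram (Hann, 256 ms, 50% overlap); band powers
  averaged over 1 Hz (theta) and 8 Hz (gamma) bands centered on the
  respective PSD peaks, z-scored exactly, OLS of gamma on theta. The
  1 s-window/4 Hz/16 Hz alternative convention can be reproduced by
  passing those widths.

## Synthetic generators

`gen_pac_signal` produces
`sin(2π f_p t) + [1 − d + d(1 + sin(2π f_p t))/2]·sin(2π f_a t) + ε`,
coupling linear in the slow sinusoid so the GLM estimator's response is
analytically predictable; depth d=0 is the exact null. Its phase
component is deterministic — unlike real rhythms it never diffuses, which
is precisely why the block-permutation surrogate exists (above).
`gen_burst_spikes` occupies gamma-period slots inside a theta duty-cycle
window independently per cell with probability `spikes_per_burst /
n_slots`, plus Gaussian timing jitter: with zero jitter, intra-burst ISIs
sit exactly on the gamma grid and the expected per-cell rate is
`theta_f · spikes_per_burst`. `gen_covarying_powers` is the standard
bivariate-normal construction with exact sample standardization.
Passing tests on these fixtures demonstrates the estimators recover
constructed structure; it does not certify behavior on signals with
frequency drift, nonstationarity or 1/f backgrounds, which the fixtures
deliberately lack.

## Problem sizes

The test suite and the acceptance script run circuit simulations at the
published protocol size (6.3 s, 2 s discarded, dt = 0.05 ms) for the SM
family, with two replicate seeds per condition; the KDR rheobase sweep
uses 3 s runs over a SCIL grid with a 20-step resolution (the drive
quantum); synapse-oracle checks use 100 random 25-event Poisson trains;
synthetic-signal checks use 20–60 s signals at 250–500 Hz with 10–50
seeds and 20–200 surrogates per test.

## Known limitations

* No dendrites, no Mg block, no per-channel biophysics: knockout results
  are directional analogies, not quantitative channel predictions, and
  the KDR knockout's excitability effect is read out in the feedforward
  circuit because closed-loop feedback compensates rate changes near
  threshold.
* One TM state per connection (contacts of a connection share release);
  stochastic release and receptor saturation are not modeled.
* The theta frequency of the reduced SM sits high in the theta band
  (~7.5 Hz at the calibrated operating point).
* Population rates are per model cell; group size is a wiring
  multiplier only.
* The full model (FM) is calibrated to plausible operating rates but the
  mechanism experiments target the SM family, as the contrasts there are
  the interpretable ones.
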