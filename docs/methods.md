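# Methods

This note documents the models, algorithms, defaults and design
choices behind entrainkit, and what the synthetic-data tests do and do
not establish about real recordings.

## Data model

The raw input is an RFID homecage visit log: one event per visit onset
(`animal_id`, timestamp, antenna). A visit is the interval during which
an animal is continuously detected by one antenna; entrainkit counts
visit *onsets* per epoch (onset counting is additive across epochs,
whereas duration-weighting of multi-epoch visits would not be; a
duration-weighted variant is deliberately not implemented). Epochs are
5-min, half-open `[start, start + ε)`, labeled by their start time.

Absolute time is hours from the experiment origin, with `t = 0` at a
lights-on. Zeitgeber time (ZT) is hours since the most recent lights-on
of the governing schedule segment, modulo the cycle length; ZT 0 =
lights-on, dark = ZT 12–24 under 12:12 LD. In constant darkness (DD)
the ZT axis extrapolates the phase of the last LD segment. After a
phase shift, ZT follows the new schedule from its first lights-on; the
shift itself is realized by truncating one dark phase.

## Cosinor

Single-component least squares at fixed trial period τ via the linear
form `y = M + β_c·cos(ωt) + β_s·sin(ωt)`, `ω = 2π/τ`. Amplitude
`A = √(β_c²+β_s²)`; acrophase = ZT of the fitted peak (`atan2(β_s,β_c)/ω`
mod 24), chosen over the classical negative-radians convention because
every downstream contrast is phrased in ZT hours. Preconditions: ≥ 4
points, span ≥ one period (waived for sparse expression-style courses),
≥ 3 distinct phases. A constant input returns `A = 0` with the
acrophase flagged undefined (NaN), never an arbitrary number. Fits on
noiseless cosines are exact to machine precision (tested), and the fit
agrees with an independent dense-grid-search oracle to 1e-6.

Multi-day LD windows are fitted pooled at τ = 24 h (the entrainment
question is "where does activity sit relative to the zeitgeber"); DD
windows are fitted at the periodogram peak, since no zeitgeber defines
a 24-h phase there. A per-cycle mode (`cosinor_per_cycle`) exists for
cycle-resolved acrophases around phase shifts.

## χ²-periodogram

Trial periods 20–25 h at 5-min resolution (61 grid points; trial
periods are whole numbers of epochs). For each trial period P the
series is folded into P phase columns with means `M̄_h` and counts
`K_h`, and

    Q_P = N · Σ_h K_h (M̄_h − M̄)² / Σ_i (x_i − M̄)².

This is the one-way-ANOVA (between/total sum-of-squares) form of the
folded-variance statistic, computed over **all** N points. Two
properties motivated this default over truncating each trial period to
whole cycles:

1. *Exactness.* Within-column variance is non-negative, so `Q_P ≤ N`
   with equality exactly when every column is constant — on noiseless
   periodic input the grid argmax is the true period.
2. *Smoothness.* The noise expectation of the numerator is
   `Σ_h K_h σ²/K_h = P σ²`, smooth in P. Whole-cycle truncation makes
   the folded cycle count K = ⌊N/P⌋ drop discontinuously along the
   grid; on a 6-day record the drop (6 → 5) lands exactly at P = 24 h
   and inflates Q_P on the long-period side by ≈ P·σ²·(1/5 − 1/6),
   which under any realistic noise displaces the argmax 1–3 grid steps
   above 24 h. The truncating variant (equal column counts,
   `Q_P = N_used·Σ_h(M̄_h−M̄)²/Σ_i(x_i−M̄)²`) remains available via
   `whole_cycles=True`.

The peak is the unconditional grid argmax ("highest peak"); exact ties
break toward the period closest to 24 h, then the smaller period.
χ²(P−1) 0.99 quantiles are reported per trial period for reference but
never gate peak selection.

## DFA

Profile = cumulative sum of the mean-subtracted counts; windows of n
epochs in a forward pass plus a backward pass (so the tail is used);
per-window polynomial detrending of order 1 (DFA-1); F(n) = pooled RMS
residual; exponent = least-squares slope of log F vs log n. Defaults:
~15 log-spaced integer scales from 6 epochs (30 min) to N/4, single
global fit, no crossover segmentation. The vectorized implementation
matches a naive per-window reference to 1e-10, and the exponent is
exactly affine-invariant.

Calibration (tested, 10 seeds, n = 2¹⁴): white noise → 0.50 ± 0.03,
fractional Gaussian noise H = 0.8 → 0.80 ± 0.05, integrated white
noise → 1.50 ± 0.05.

**Fit range for the study metric.** The fit range is genuinely
underdetermined for rhythmic records: at scales approaching the
circadian period the rhythm dominates F(n), at sub-circadian scales a
smooth rhythm is locally linear and removed by the detrending while
*sharp* masking transitions still inflate F(n). The study pipeline
(`run_all_metrics`) therefore fits the exponent over 30 min–6 h, where
the exponent reflects intrinsic fluctuation structure plus exactly the
rigid-gating signature the entrainment comparison needs; the full
ladder up to N/4 is still computed and returned for sensitivity
analyses. The DD-window exponent is sensitive to the maximum scale
(documented by test: extending the fit toward N/4 raises it), which is
why the range is recorded in every result.

## Active-phase algorithm

5-min binned counts → sliding Gaussian smoothing, total span 4 h
(±2 h), σ = span/4 = 1 h, i.e. truncation at 2σ, weights renormalized
at record edges. "4-h width" is read as the total kernel span; a
different σ can be passed explicitly. Smoothing restarts at LD/DD
regime boundaries so free-running epochs never borrow entrained
neighbors. The threshold is the mean of the *smoothed* series over the
analysis window (equals the raw mean up to edge effects), applied per
window; epochs above it are active; runs separated by gaps ≤ 1 h
(inclusive at exactly 1 h) merge into bouts; each bout belongs to the
LD cycle whose window (dark onset − 6 h, dark onset + 18 h) contains
its midpoint — the 6-h lead keeps anticipatory onsets attached to the
coming night — and the longest bout per cycle is primary, others are
flagged secondary. Offsets running past lights-on are reported
unwrapped (> 24) so duration = offset − onset stays linear; wrapped
values are also emitted for plotting.

On a noiseless 12-h dark-aligned box the mean threshold crosses at the
box edges, so the detected duration is 12 h up to one epoch (tested at
±0.5 h). When a cosine modulation rides inside the box (the rigid
phenotype preset), the window mean sits above the smoothed edge value
and both crossings pull inward by ~0.2–0.4 h; detected durations of
≈11.6–11.9 h against the nominal 12-h dark phase are therefore a
property of the mean-threshold algorithm, not a defect.

## Synthetic actigraphy generator

Rate model per animal (visits/h on the epoch grid):

    λ(t) = mean_rate · [modulation(t) · gate(t) + burst(t)] · noise(t)

with events drawn by thinning a homogeneous Poisson bound at max λ —
exact for the piecewise-constant rate, bit-reproducible under a fixed
seed.

*Oscillator.* Internal circadian time ζ(t) advances at
24/entrained_period per hour under LD with an exponential pull toward
schedule ZT (time constant `reentrainment_rate_cycles`), and at
24/intrinsic_period in DD (default intrinsic period 23.7 h, the
typical mouse free-running value). The phase error e(t) = ZT − ζ is
zero in steady entrainment, ~6 h right after a 6-h advance, and ~4 h
after two weeks of DD (the free-run drift).

*Modulation.* `1 + A·coh(t)·cos(2π(ζ − φ)/24)` where φ is the preset
acrophase and coh(t) is a rhythm-coherence state: 1 under steady
entrainment, decaying with a 7-day time constant in DD (floor 0.2 — a
detectable free-running rhythm persists), and rebuilt during
re-entrainment six times slower than the phase re-locks (phase first,
amplitude later). Coherence is what differentiates forced
resynchronization after DD (weak, mask-dominated rhythm → acrophase
delayed toward the dark-phase midpoint, raised scaling exponent) from
an abrupt phase advance without DD (full-amplitude clock-driven
modulation at the old phase → activity onset lags the new dark onset
and lights-on truncates the bout).

*Photic gate.* Raised-cosine edges: ramp-up centred
`anticipation_hours` before dark onset and ramp-down centred
`offset_lag_hours` after lights-on (half-widths equal those
parameters; zero width = hard box, the rigid-masking phenotype).
Outside the gate, activity is scaled by a floor that interpolates
between the preset's entrained masking (`gate_floor`) and strong
masking (0.05) as the oscillator misaligns — light suppresses activity
directly whenever clock and schedule disagree. Anticipation and offset
lag scale with the same alignment maturity (e-folding 1 h of phase
error): anticipatory behavior is a property of the entrained state.
The gate is disabled in DD.

*Dark-onset burst.* A brief surge (Gaussian, σ = 6 min, peak 2.5× the
base rate) at dark onset — the lights-off surge of nocturnal rodents.
Being narrower than the smallest DFA scale (30 min) it contributes
like white noise to the scaling exponent, while its periodic precision
sharpens the χ²-periodogram peak decisively.

*Noise.* `exp(σ·X − σ²/2)` with X exact fractional Gaussian noise
(Davies–Harte circulant embedding) at the preset Hurst exponent;
mean-one multiplicative noise keeps rates non-negative. σ = 0.45 was
calibrated once, jointly with `mean_rate` = 240 visits/h, so that the
DFA exponent of the binned counts tracks the generative Hurst exponent
(Poisson sampling adds white noise that biases the slope toward 0.5
when σ²·counts-per-epoch ≲ 1) while the periodogram peak stays on
24.0 h for entrained simulations.

*Presets* (qualitative contrasts; numbers are calibration choices):

| parameter | control | dex | mehg |
|---|---|---|---|
| rhythm_amplitude | 0.6 | 0.8 | 0.3 |
| acrophase (ZT h) | 17 | 18 | 17 |
| anticipation (h) | 1.5 | 0 | 1.5 |
| offset_lag (h) | 1.0 | 0.1 | 1.0 |
| gate_floor | 0.7 | 0.02 | 0.7 |
| re-entrainment (cycles) | 4.0 | 0.3 | 4.0 |
| hurst | 0.8 | 0.8 | 0.8 |

`dex_aged` additionally drifts the entrained period to 23.6 h. The
re-entrainment constants encode only the ordinal contrast (rigid
phenotype faster than control); no quantitative time constant is
available to anchor them. The control's weak entrained masking
(floor 0.7) reflects that a healthy animal's nocturnality is
clock-driven rather than light-clamped; it is what keeps the control's
LD and DD scaling exponents close while the rigid phenotype's hard
gating raises its LD exponent — with strong masking the control would
show the same LD/DD gap as the rigid phenotype.

*Expression courses.* Fibroblast-style clock-gene time courses:
`mesor + A·exp(−d·t)·cos(2π(t − φ)/24) + ε`, truncated positive,
sampled 6–36 h post-synchronization. Presets: control A = 0.5,
d = 0.02/h; attenuated group A = 0.18, d = 0.05/h.

## Experimental protocols

- `baseline`: ≥ 3 LD acclimation cycles (excluded from analysis)
  followed by 3 analyzed LD cycles.
- `dd_reentrain`: baseline, then 14 days DD analyzed over the last
  72 h, then LD resumed in phase and analyzed over the first 3 cycles
  (forced synchronization).
- `phase_advance`: 6-h advance by dark-phase truncation; per-cycle
  windows indexed from the first new lights-on.

`run_all_metrics` emits one row per animal × window (cosinor,
periodogram, DFA, active-phase summary for LD windows) and never
aborts a batch: a failing submodule leaves NaNs and an error log
entry. Group-level inference (ANOVA, post hocs) is intentionally out
of scope — the output tables are tidy input for any statistics
package.

## What the synthetic tests do and do not show

The generator reproduces the statistical structure the analyses
assume — Poisson event sampling, long-range-correlated rate noise,
entrained/free-running cosine modulation, photic masking — and the
round-trip suite shows the pipeline recovers period (±5 min, grid
limited), acrophase (±0.5 h), Hurst exponent (±0.05, fitted over
30 min–4 h in DD where the rhythm contributes least) and amplitude
rank order at realistic record lengths (6 days). It does not emulate
ultradian bout structure, antenna collisions or positional masking,
inter-animal interaction, slow aging trends within a recording, or
weather-/husbandry-induced nonstationarity; passing tests therefore
validate the estimators and their wiring, not the biological
faithfulness of any preset. Tolerances on stochastic checks were set
from the estimators' sampling variability at the stated problem
sizes, not tuned per seed.

## Numerical notes and degenerate inputs

- Constant series: cosinor returns A = 0 with undefined acrophase; DFA
  and the periodogram raise a degenerate-input error; classification
  warns and returns an all-inactive mask.
- Periodogram requires ≥ 2 cycles of the longest trial period; DFA
  requires max scale ≤ N/4 and ≥ 2 (default ≥ 8) scales in the fit.
- Argmax ties (periodogram) and equal-length bouts (active phase,
  longest-per-cycle rule) break deterministically.
- All randomness flows through numpy Generators seeded from explicit
  integers; identical config + seed ⇒ byte-identical event streams and
  metric tables (tested).
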