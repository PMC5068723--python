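# entrainkit

Circadian-entrainment analysis of rodent homecage actigraphy: cosinor
rhythmometry, χ²-periodogram period estimation, detrended fluctuation
analysis (DFA), and active-phase (onset/offset/duration) detection for
RFID visit event streams — plus a synthetic actigraphy generator with
phenotype presets so every stage of the pipeline can be validated
against known ground truth without animal data.

## Who this is for

Chronobiologists and behavioral neuroscientists who record spontaneous
home-cage activity (RFID antennas, running wheels, infrared beams) and
want to quantify how well an animal's activity rhythm is entrained to
the light–dark (LD) cycle: how strongly it oscillates, when it peaks,
whether its period follows the zeitgeber, how "fractal" its
fluctuations are, and how quickly it re-entrains after a phase shift or
a spell of constant darkness (DD).

## The methods

All time is zeitgeber time (ZT): ZT 0 = lights-on, so under a 12:12 LD
cycle the dark (active) phase of a nocturnal animal spans ZT 12–24.
Visit events are binned into 5-minute epochs.

**Cosinor rhythmometry.** Least-squares fit of a single cosine at a
fixed trial period τ,

    y(t) = M + A·cos(2π(t − φ)/τ),

estimated via the linear parametrization `M + β_c·cos(2πt/τ) +
β_s·sin(2πt/τ)`; mesor `M`, amplitude `A = √(β_c² + β_s²)` and
acrophase `φ` (time of the fitted peak, reported in ZT hours rather
than the classical negative-radians convention).

**χ²-periodogram.** For each trial period P on a 20–25 h grid at 5-min
resolution, the series is folded into P phase columns and

    Q_P = N · Σ_h K_h (M̄_h − M̄)² / Σ_i (x_i − M̄)²

compares the between-column variance of the fold with the total
variance (K_h = column counts). The rhythm's period is the highest peak
of Q_P over the grid.

**DFA.** The mean-subtracted series is integrated, cut into windows of
n epochs (forward and backward passes), linearly detrended per window,
and the pooled RMS residual F(n) is regressed on n in log–log space.
The slope α is 0.5 for uncorrelated noise, ≈0.8 for healthy rodent and
human activity, 1.5 for integrated white noise, and rises when a strong
diurnal rhythm dominates the record.

**Active-phase detection.** Counts are smoothed with a sliding Gaussian
window (4 h total span, σ = 1 h), epochs above the individual's window
mean are "active", runs of active epochs separated by gaps of at most
1 h merge into one bout, and each bout is assigned to an LD cycle.
Onset and offset are the ZT of the bout's edges (offsets past lights-on
are reported unwrapped, e.g. 24.7), duration = offset − onset.

**Synthetic actigraphy.** Visit events are drawn as an inhomogeneous
Poisson process (thinning) whose rate is the product of a circadian
cosine modulation (driven by an internal oscillator that entrains to
LD, free-runs at ~23.7 h in DD, and relaxes exponentially after a
schedule disruption), a photic gate (activity permitted from shortly
before dark onset until shortly after lights-on; masking strengthens
when the oscillator is misaligned), a sharp dark-onset activity surge,
and exponentiated fractional Gaussian noise with tunable Hurst
exponent. Presets: `control` (anticipates dark onset, runs past
lights-on, slow re-entrainer), `dex` (rigidly light-masked, no
anticipation, near-instant re-entrainment), `mehg` (control timing,
low amplitude), `dex_aged` (entrained period drifting short of 24 h).
See `docs/methods.md` for the model and every default.

## Worked example

Simulate three phenotypes for six 12:12 LD days and run the analyses:

```bash
cat > cfg.yaml <<EOF
schedule:
  protocol: standard_ld
  days: 6
animals:
  m1: control
  m2: dex
  m3: mehg
seed: 42
EOF
entrainkit simulate --config cfg.yaml --out sim/
entrainkit periodogram --input sim/binned.csv
entrainkit cosinor     --input sim/binned.csv --period 24
entrainkit dfa         --input sim/binned.csv
```

which prints

```
animal_id  peak_period_hours
       m1          24.000000
       m2          24.000000
       m3          24.083333

animal_id  trial_period_hours     mesor  amplitude  acrophase_zt  percent_rhythm
       m1                24.0 22.151620  17.616221     17.152220        0.446288
       m2                24.0 16.770255  21.455800     17.902591        0.586497
       m3                24.0 15.737847   8.368005     17.055004        0.304563

animal_id  scaling_exponent   fit_r2
       m1          1.078490 0.987797
       m2          1.171957 0.992232
       m3          1.014183 0.987726
```

Reading the numbers: all three animals entrain a ≈24 h period (the
periodogram grid step is 5 min). The anticipating phenotypes (`m1`
control, `m3` mehg) peak *before* the middle of the dark phase
(acrophase ZT 17.1–17.2) whereas the rigidly gated `m2` peaks at
ZT 17.9 ≈ 18, the dark-phase midpoint; `m2` also shows the largest
cosinor amplitude (its activity is compressed into the dark phase) and
the highest scaling exponent (stronger diurnal background rhythm),
while the low-amplitude `m3` oscillates at less than half the control
amplitude — the phenotype contrasts the pipeline is designed to
resolve. The same analyses accept recorded event CSVs
(`animal_id,timestamp,antenna_id`) via `entrainkit run`.

The library mirrors the CLI one-to-one
(`simulate_activity`, `bin_events`, `cosinor_fit`,
`chi_square_periodogram`, `dfa`, `gaussian_smooth` /
`classify_active_epochs` / `detect_active_phases`,
`segment_experiment` / `run_all_metrics` / `phase_shift_response`).

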