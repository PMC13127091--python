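# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `stimwell`, and what the test suite does and does not
demonstrate about real instruments.

## Equivalent circuit

A well is modelled as R_e in series with the parallel pair (interface
element, R_f):

- **Interface element.** Either an ideal double-layer capacitor C_dl or a
  constant phase element Z_CPE = 1/(Q(jω)ⁿ), 0 < n ≤ 1.  The CPE captures
  the distributed relaxation of rough/nanostructured electrodes; n = 1
  recovers the ideal capacitor exactly.  The engineering sign convention is
  used throughout (capacitive Z″ < 0, ω = 2πf).
- **R_f** is treated as a constant circuit element.  Physically the faradaic
  branch is potential-dependent; the constant-R_f idealisation is the same
  one used when simulating such devices with SPICE-class tools, and it is
  what EIS fitting returns.
- **Composition.** All N wells of a device are assumed identical.  Parallel
  wiring (voltage-controlled devices) divides the well impedance by N;
  series wiring (current-controlled) multiplies it by N.  The lumped
  single-cell equivalents {N·C, R_f/N, R_e/N} and {C/N, N·R_f, N·R_e}
  reproduce the device impedance identically at every frequency; for CPE
  wells with n < 1 the lumped cell uses the converted effective C_dl and is
  therefore an approximation.
- **CPE → C_dl conversion.** Default is the Brug formula
  C_dl = Q^(1/n)·(1/R_e + 1/R_f)^((n−1)/n), appropriate for
  surface-distributed time constants with a series electrolyte resistance —
  which is the geometry of a plate electrode in culture medium.  The
  Hsu–Mansfeld variant C_dl = Q^(1/n)·R_f^((1−n)/n) (characteristic
  frequency of the R_f‖CPE arc) is selectable by flag; it attributes the
  dispersion to the faradaic arc instead and typically gives larger values
  when R_f ≫ R_e.

## EIS fitting

`fit_spectrum` performs complex nonlinear least squares (via lmfit's
Levenberg–Marquardt) with **modulus weighting**: residuals are divided by
|Z| per point, so decades-apart impedance magnitudes contribute comparably.
Starting values are derived deterministically from the data — R_e from
Re(Z) at the highest frequency, R_e + R_f from Re(Z) at the lowest, Q from
|Z″| at mid-band with n started at 0.9 — so no user guess is needed and the
fit is reproducible.  `ideal_randles` pins n = 1.  A spectrum with no
imaginary content falls back to a resistance-only fit with a warning;
non-convergence returns best-effort parameters flagged `converged=False`.
Fits require ≥ 2 decades of frequency coverage; the default simulation grid
is 50 log-spaced points over 10 mHz–100 kHz, the standard potentiostat
sweep for these devices.

## Transient simulation

Both stimulation modes reduce, on each constant waveform segment, to a
linear first-order ODE in the double-layer voltage V_c:

- VC (parallel wiring): V_source = I_total(Z_out + R_m) + V_well with
  I_total = N·I_e, V_well = I_e·R_e + V_c and C·dV_c/dt = I_e − V_c/R_f.
  The loop resistance seen per well is R_s = N(Z_out + R_m) + R_e.
- CC (series wiring): I_e is commanded; C·dV_c/dt = I_e − V_c/R_f,
  V_source = N·V_well (+ I_e·R_m when a monitor is in the loop).

The integrator advances V_c **analytically** per segment (exponential
stepping), so pulse trains incur only floating-point error — verified
against closed forms and an adaptive Runge–Kutta reference at ≤ 1e−8.  Two
numerical details matter:

- `expm1` is used everywhere `1 − e^(−x)` appears, and the segment integral
  of the relaxation term switches to a Taylor series when Δt/τ < 1e−4;
  otherwise the R_f → ∞ limits (τ → ∞, asymptote → ∞) cancel
  catastrophically.
- The cumulative charge ∫I_e dt is accumulated from the same analytic
  per-segment integrals rather than by quadrature of the samples, so charge
  accounting is exact even though the delivered current is discontinuous at
  segment edges.  (Trace-level integration of *measured* data, in
  `monitor.integrate_charge`, necessarily uses the trapezoidal rule on the
  sampled grid; when discontinuity times are supplied it corrects the
  crossing intervals by left-limit extrapolation, keeping the quadrature
  second-order there too.)

Samples at a segment boundary carry the post-jump value (right-continuous
convention).  The initial double layer is fully discharged (V_c(0) = 0)
unless a state is supplied.  CPE interfaces have no finite-dimensional
time-domain state, so transient runs use the effective C_dl from the
CPE conversion.  Compliance violations (source current in VC, source
voltage in CC) warn and flag the result rather than aborting, so a user can
see where a protocol fails.

Charge accounting splits each period at the segmentize boundaries: the
injection interval is the leading run of segments above the offset
baseline, recovery is the rest of the period, and Q_acc = Q_inj − Q_rec by
construction.  A dc waveform has no pulse structure and reports cumulative
charge only.

## CV safe-window estimation

The window-expansion procedure records consecutive triangular sweeps over
progressively wider potential windows (default start [−0.55, +0.85] V, the
conservative side of generic Pt water-splitting values; sweep rate 0.1 V/s;
1 mV steps).  For each window the absolute current difference ΔI between
consecutive cycles is read at both extremes, each extreme taken from the
sample nearest the limit on the sweep moving toward that limit.  The
estimated limit per side is the last window extreme *before* ΔI first
exceeds `rel_threshold` × baseline, with baseline the median ΔI of the
smallest window and `rel_threshold` defaulting to 3 — a scale-free
change-detection rule standing in for the qualitative "pronounced increase"
criterion.  Each side is estimated independently; a side that never
triggers returns the widest tested extreme flagged "onset not reached".
The rule is deliberately conservative: it reports the last extreme proven
quiet, which sits up to one increment inside the true onset.

Two study-design choices matter for the recovery statistics:

- **Expansion increment 0.15 V.**  The procedure is usually described with
  ±0.5 V increments, but reported windows for different electrode materials
  differ by sub-0.5 V amounts, so a finer schedule is evidently in use;
  the increment is exposed as a parameter and the recovery studies use
  0.15 V.
- **16 cycles per window in the studies** (the generator's minimum default
  is 2, enough to form one ΔI).  The decision statistic is a ratio of
  medians of |differences of noisy readings|; with a single cycle pair per
  window the baseline is one half-normal draw and the false-trigger
  probability P(X > 3Y) for iid draws is ≈ 0.2 per window, at any noise
  scale.  With ~15 consecutive-pair differences per window the medians
  concentrate and the 3× rule becomes reliable (≥ 94 % recovery within one
  increment across seed sets at the study noise level).

## Synthetic data

Generators are pure functions of (truth, grid, seed) — reproducibility is
bitwise, with no global random state.

- **EIS**: exact model spectrum plus proportional complex Gaussian noise,
  |Z|·σ·(ε₁ + jε₂); the recovery studies use σ = 2 %, 50 points over
  10 mHz–100 kHz.
- **CV**: current = capacitive rectangle C_dl·(±rate) + ohmic leak V/R_f +
  Tafel-type exponentials i₀[e^((V−V_ox)/b) − e^(−(V−V_red)/b)] for the
  anodic/cathodic onsets.  The faradaic term grows by `cycle_growth`
  (default 25 %) per consecutive cycle, a phenomenological stand-in for the
  cycle-over-cycle activation that the ΔI readout detects on real
  electrodes.  Study noise is additive Gaussian, σ = 50 nA — a realistic
  instrument floor for µA-scale currents.
- **Scope**: channels constructed so V_CH2 − V_CH1 = I_total·R_m and CH2
  carries V_well (parallel) or the total drop (series), plus per-channel
  additive noise.

What these generators do **not** emulate: reference-electrode drift, ohmic
drop distortion, instrument quantisation, electrode nonlinearity within a
pulse, cross-well heterogeneity, or temperature effects.  Passing recovery
tests therefore demonstrate the estimators are correct and robust to
realistic noise levels, not that every real-device artefact is handled.

## Life-cycle QC

`lifecycle_qc` compares groups of fitted (C_dl, R_f) values across use
counts against the mandatory "New" group: per-group means and dispersions,
relative drift vs New, and a one-way fixed-effects ANOVA per parameter.
The flag is `inspect` when any drift exceeds the threshold (default 25 %, an
engineering guard because significance alone is sample-size dependent) or
when an ANOVA rejects at the family-wise α = 0.05 shared across the two
monitored parameters (Bonferroni, 0.025 each).  The family-wise correction
is deliberate: screening two parameters each at 0.05 would flag an
unchanged device ~10 % of the time, defeating the purpose of a
"no change on a healthy device" check.  Raw per-parameter p-values are
always reported.

## Monitoring-trace reduction

The reduction implements the monitor relations literally: V_R = V_CH2 −
V_CH1, I_total = V_R/R_m; parallel wiring gives I_e = I_total/N and
V_well = V_CH2, series wiring gives I_e = I_total and V_well = V_CH2/N (the
monitor drop is *not* subtracted from V_CH2 in series mode — documented
assumption matching the probe placement).  Because the text-level formulas
underdetermine the probe topology, a `polarity` flag (±1) flips the current
sign for the opposite probe ordering.  Channels on different time bases are
linearly interpolated onto CH2's grid; otherwise native grids are used.

## Problem sizes

The shipped studies are sized to run in seconds on one CPU: 100 spectra ×
50 points for EIS recovery, 50 scans × 8 windows × 16 cycles for CV
recovery, 200 replicate studies × 3 groups × 6 devices for the QC null
rate, 30 ms at 1 µs steps for the round-trip traces.  All are comfortably
past the point where the statistics stabilise; larger sizes change the
reported rates by less than their seed-to-seed scatter.

## Known limitations

- Constant R_f and effective-C_dl transients: no Butler–Volmer kinetics, no
  CPE memory effects in the time domain.
- Identical-wells composition; per-well heterogeneity is out of scope.
- The CV forward model is phenomenological; it supports testing the window
  *estimator*, not mechanistic electrochemistry.
- Safety checking evaluates per-well V_well against a fixed window; it does
  not model pH or gas evolution directly.
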