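# Methods

## Signal model

A whole-cell voltage-clamp current trace is modelled as

I(t) = I_hold + ΔI_tonic · w(t) + Σ_k a_k · K(t − t_k) + ε(t)

with inward currents negative throughout.

* **Holding current** `I_hold` (pA): the stationary baseline before drug
  application.
* **Tonic shift** `ΔI_tonic` (pA, signed): the drug-induced sustained
  change, negative for an agonist inducing an inward tonic current,
  positive for an antagonist blocking one. The wash-in profile
  `w(t) = 1 − exp(−(t − t_drug)/τ_wash)` for `t ≥ t_drug` (0 before)
  models gradual bath exchange; `τ_wash` defaults to 30 s.
* **sIPSCs**: arrival times `t_k` follow a homogeneous Poisson process
  with rate `event_rate_hz` (default 2 Hz), rescaled by
  `post_drug_event_scale` after the drug (0 for an antagonist, which
  abolishes phasic events; 1 for an agonist). Peak magnitudes `a_k` are
  lognormal (mean 30 pA, CV 0.5) — strictly positive and right-skewed,
  as real sIPSC amplitude distributions are — applied as negative
  (inward) deflections. The kernel `K` is a difference of exponentials
  `exp(−t/τ_d) − exp(−t/τ_r)`, peak-normalized to 1, with `τ_r` = 1 ms
  and `τ_d` = 10 ms, order-of-magnitude GABA_A synaptic kinetics.
* **Noise** `ε`: Gaussian white noise (SD `noise_sd_pa`, default 3 pA,
  quoted before filtering) passed through a second-order Butterworth
  low-pass at `filter_cutoff_hz` (default 4 kHz), standing in for the
  acquisition chain's hardware Bessel filter. The filter applies to the
  noise only, so the noiseless degenerate case is exact. A cutoff at or
  above Nyquist disables the filter.

Sampling is 10 kHz by default. The step-response simulator uses a
single-RC membrane: during a current pulse the voltage relaxes
exponentially toward `V_rest + I·R` with `1 pA × 1 MΩ = 10⁻³ mV`.

### Cohorts

`simulate_cohort` redraws selected parameters per cell around a template.
Two dispersion families are offered: `normal` (clipped at sign
constraints for magnitude-like fields) and `lognormal`, moment-matched on
the magnitude with the template's sign restored. The lognormal family is
the right choice for strictly-signed quantities such as tonic-shift
magnitudes: a normal draw near zero would fold through zero and inflate
the cohort's mean magnitude, whereas the lognormal preserves the group
mean exactly. Per-cell seeds derive from the cohort seed, so a cohort is
reproducible as a whole.

## Quantification procedure

1. **Event screening.** The trace is detrended with a 0.5-s moving
   average (removing the baseline and the slow wash-in ramp); the
   residual noise SD is estimated robustly as 1.4826 × MAD so events do
   not inflate it. Samples deviating *inward* beyond `threshold_sd` SDs
   (default 3) for at least `min_width_ms` (default 2 ms) form an event
   interval. These thresholds operationalize "visible synaptic event"
   and are configurable; there is no universal definition.
2. **Epoch selection.** Each phase (pre: `[0, t_drug)`; post:
   `[t_drug + post_delay_s, end)`) is scanned exhaustively at every
   sample for 5-s windows. Event-free windows are preferred,
   earliest-first without overlap; if fewer than three exist — the
   normal situation at realistic sIPSC rates — the selection falls back
   to the lowest-event-density windows (ties to the earlier start),
   flags them `clean=False` and warns. A greedy pick is accepted only if
   the remaining epochs can still be placed in the free gaps, so the
   selection never deadlocks on a feasible phase. `post_delay_s`
   defaults to 120 s = 4 wash-in time constants, at which the tonic
   shift is ≥ 98% complete; waiting for the plateau keeps the
   steady-state shift estimate's systematic bias under 2%, comfortably
   inside the quantification tolerance.
3. **All-point histogram.** Uniform 0.5-pA bins aligned to the pA grid,
   spanning the epoch's range; counts conserve the sample count. 0.5 pA
   resolves few-pA shifts while leaving ~500 expected counts in central
   bins of a 50,000-sample epoch. A zero-variance epoch degenerates to
   one bin and is flagged.
4. **Constrained Gaussian fit.** Unweighted least squares (Poisson
   weighting behind a flag) of `A·exp(−(I−μ)²/2σ²)` on the window from
   two bins beyond the mode toward the event-tail side through the far
   edge of the opposite side. With inward events the tail side is
   negative: the fit sees the peak, two tail bins and the whole positive
   flank, which events never touch. Initial values: mode-bin center
   (μ), FWHM/2.355 (σ), mode count (A). A failed optimization returns
   `converged=False` rather than garbage, and the phase-level routine
   raises with the epoch index. Both the tail side and the two-bin
   offset are configurable, because with a low-Cl⁻ internal solution (or
   excitatory events) the contaminating tail would sit on the positive
   side instead.
5. **Tonic current.** Per-phase holding current is the arithmetic mean
   of the three epoch μs; the tonic current is the magnitude of the
   pre/post difference with the signed value retained; current density
   is magnitude / capacitance (pF), left absent — never zero — when the
   capacitance is unknown.

## Statistics

For two groups of sizes n₁, n₂ with no ties, the null distribution of
the Mann–Whitney U statistic is enumerated exactly by the counting
recursion N(u; n₁, n₂) = N(u − n₂; n₁ − 1, n₂) + N(u; n₁, n₂ − 1)
(coefficients of the Gaussian binomial), in int64 — exact for the
n₁ + n₂ ≤ 30 samples the exact path accepts. The two-sided p is
`min(1, 2·min(P(U ≤ u), P(U ≥ u)))`, the doubled smaller tail including
the observed point mass — the convention of the classical exact tables.
With ties (or larger samples) the test falls back to a seeded
permutation test on mid-ranks (default 10⁵ resamples) and labels the
result accordingly. Group summaries are mean ± SEM (SD/√n, NaN for
n = 1). Input resistance is ΔV/ΔI from 100-ms averaging windows:
baseline immediately before pulse onset, steady state over the last
100 ms of the pulse. The 2^(−ΔΔCt) helper performs standard relative
qPCR quantification against a reference gene and calibrator sample.

## What the simulator does and does not emulate

It emulates: stationary baselines with filtered Gaussian noise, Poisson
sIPSC trains with realistic skewed amplitudes and bi-exponential
kinetics, gradual drug wash-in, event abolition by an antagonist, and
between-cell parameter dispersion. It does **not** emulate: baseline
drift unrelated to the drug (series-resistance changes, seal
degradation), bursty or rate-modulated event trains, event kinetic
variability within a cell, voltage-gated conductances, or
series-resistance/capacitance-transient artifacts. Passing recovery
tests therefore demonstrates correctness of the estimator under the
stated signal model, not robustness to every pathology of real
recordings — in particular, a slow monotonic drift would bias the
pre/post difference in real data and must be screened by the
experimenter.

Default problem sizes (175-s traces at 10 kHz; 50 seeds per shift level
in the recovery sweep; 200 paired draws for the robustness check; 10⁴
datasets for the null calibration) were chosen to make Monte-Carlo
standard errors small relative to the tolerances being checked while
keeping a full validation run on a single CPU in the minutes range.

## Numerical and design notes

* Bin edges are anchored to integer multiples of the bin width so
  histograms of the same data are identical regardless of segment
  offset; the top edge is extended one bin when the maximum lands on it,
  keeping count conservation exact.
* The event detector treats only inward deviations as events; outward
  deviations are noise by assumption of the signal model.
* Determinism: every stochastic component takes an explicit seed;
  `simulate_trace` is bit-reproducible for identical configs, the
  pipeline writes files atomically and its run report contains no
  timestamps, so repeated runs are byte-identical.
* The trace text dialect stores no time column (time is implied by the
  sampling rate), keeps units explicit, and the reader refuses unit
  mismatches rather than rescaling silently.
* Reported holding currents keep the inward-negative sign; tonic
  currents and densities are reported as magnitudes with the signed
  shift retained, since published group values are conventionally
  magnitudes.

## Known limitations

* The exact U enumeration assumes no ties; measured currents are
  effectively continuous, so the permutation fallback is rarely needed.
* The constrained fit assumes the event-free flank is Gaussian; strong
  1/f noise or line pickup would violate this.
* One step response per call for input resistance; sweep averaging is
  the caller's responsibility.
* ABF/proprietary acquisition formats are out of scope; convert to the
  text dialect first.
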