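# Methods

## Setting

The pipeline quantifies kilohertz-frequency electrical stimulation (KES)
conduction block of motor axons from isometric force.  A proximal
intrafascicular electrode (aLIFE) evokes muscle twitches with 5 Hz
supra-threshold biphasic pulses; a distal electrode (bLIFE) in the tibial
fascicle delivers a continuous KES sine during a gated *block* phase.  Each
trial follows a three-phase cycle — roughly 2 s *pre-block*, 4 s *block*,
2 s *post-block* — preceded by a 1 s stimulus-free blank used for the
baseline estimate.  At 5 Hz this yields 10 pre-block, 20 block and 10
post-block twitches; the first 10 block twitches are discarded so the KES
onset transient does not contaminate the block-phase average, leaving a
symmetric 10-twitch average per phase.  (Phase durations, pulse rate and the
discard count are all configuration fields.)

All analysis operates on physical time, not sample counts, so the sampling
rate may be anything above twice the 100 Hz low-pass cutoff; acquisition
hardware typically runs at 30 kS/s, while tests and the synthetic replica
run at 1–5 kS/s.

## Preprocessing

1. **Baseline**: the mean over the 1 s blank is subtracted.
2. **Band-pass 0.1–100 Hz, zero-phase**: the low-pass is a 4th-order
   Butterworth applied forward–backward.  A conventional 2nd-order high-pass
   section at 0.1 Hz is numerically unstable when the normalized cutoff
   approaches 1e-6 (30 kS/s), so the high-pass is realised equivalently by
   estimating the slow trend on a ≤2 kHz decimated grid with a zero-phase
   0.1 Hz Butterworth low-pass, interpolating it back, and subtracting.
   Pass-band gain at 5 Hz is within 1%; a 1 kHz carrier residue is
   attenuated by ≥99%.
3. **Segmentation**: triggers are assigned to phases by the half-open rule
   `[kes_onset, kes_offset)`.
4. **Triggered averaging** over the full 200 ms inter-stimulus window
   starting at the trigger (no pre-trigger samples); a fixed shorter window
   was rejected because it truncates slow relaxation.
5. **Twitch metrics**: each averaged twitch is referenced to its own
   window-start baseline (first sample) before metrics are taken.  Long
   twitch trains carry a large mean-force component; any high-pass shifts
   the per-phase baseline by an amount that is still settling near phase
   transitions, and the window-start reference removes that offset exactly
   because it is constant over 200 ms.  The peak and trapezoidal AUC are
   then taken on the positive-clipped (rectified) trace.  Rectified-positive
   versus signed AUC is a configuration flag; rectified is the default so
   metrics are non-negative and insensitive to filter undershoot.

Recordings are oriented before analysis: with the plantarflexion-positive
axis convention, trials observing the peroneal fascicle (dorsiflexion,
negative force) are sign-flipped, making every metric fascicle-agnostic.

## Block quantification

- `BLK = 1 − X_block/X_pre` on a common basis (peak force by default, AUC
  as the alternative).  Negative BLK is retained — sub-threshold KES can
  facilitate recruitment.
- `B_TH` detection scans a strictly increasing amplitude sweep for the
  first block-phase peak below 5% of its own pre-block peak (the 5%
  fraction is configurable).  "Not blocked within the tested range" is a
  sentinel value, not an error, because real spillover sweeps routinely
  never cross.  Averaged-with-discard twitch peaks are used for the
  detection, consistent with the rest of the pipeline.  `B_avg` (the
  per-frequency mean of detected thresholds) defaults to global scope
  across the manifest, switchable per animal.
- Charge chain: `T_KES = 1/(2 f_KES)`; `Q_per_phase = 2 B_TH T_KES/π`
  (charge in one half-cycle of a sine); `S_LIFE = π ø L` for a cylindrical
  active site; `σ_per_phase = Q/S` reported in µC·cm⁻².  Substituting
  `T_KES` collapses the chain to `σ = B_TH/(π² f ø L)`, which serves as the
  independent closed-form oracle in the tests.
- Strength-duration curves are fitted with the Weiss hyperbolic model
  `I(PW) = I_rh (1 + t_ch/PW)`; being linear in `1/PW`, the least-squares
  solution is exact.  Block-duration or SD curves are normalized to their
  value at the 17 µs half-period anchor, linearly interpolated in
  half-period when not sampled exactly (16.7 µs at 30 kHz is the nearest
  physical grid point).
- Selectivity of the target fascicle is its block amount minus the mean of
  the others; for the TF/PF pair, `S_TF = BLK_TF − BLK_PF` (antisymmetric).

## Recruitment fits

`BLK(I) = 1/(1+e^{−β(I−σ)})` is fitted by bounded trust-region least
squares inside `0.5 < σ < 3 mA`, `3 < β < 30 mA⁻¹` so parameters cannot
escape to an extreme; fits landing at a bound are flagged.  Five restarts
on a σ×β lattice (plus a data-driven start at the empirical 50% crossing)
guard against local minima on noisy low-n curves.  Fits are unweighted and
negative-BLK points are retained, both switchable.  R² is
`1 − SS_res/SS_tot` on the fitted points.  Per-frequency summaries report
arithmetic mean parameters and the mean-parameter sigmoid on a common grid.

## Onset response

With the activation train silenced, the KES onset transient is reduced to
its rectified peak, the AUC over the 10%-bounded interval, and
`TD = t_0.1f − t_0.1i`, the first up-crossing to the last down-crossing of
10% of the peak, linearly interpolated between samples (multimodal
responses therefore use the outermost crossings).  TD is invariant to
uniform force scaling.  When the response has not decayed below 10% by the
end of the search window, TD is right-censored at the window length and
flagged.  The AUC over the bounded interval (rather than the whole window)
is the default, switchable.  Metrics are normalized to the within-dataset
maximum before group comparisons (mean ± sd by amplitude ratio, frequency
and observed fascicle).

## Fatigue

`decrease = |X_pre − X_post|/X_pre`, `f_X = 1 − decrease`, computed from
the 10-twitch averaged metrics.  Scenarios: the control protocols *no-KES*
(activation throughout, KES off) and *ideal-block* (all stimulation off
during the block phase), plus *weak-block* (0 < BLK < 0.25) and
*strong-block* (BLK > 0.75) groups assigned from the measured block amount
of sweep trials.  Group boundaries are open intervals exactly as defined,
so BLK = 0.25 or 0.75 stays ungrouped.

## Statistics

Per-dataset linear and quadratic OLS of threshold on frequency
(statsmodels), with the quadratic-term coefficient test for curvature;
Spearman rank correlation with an exact permutation p-value for n ≤ 9
(asymptotic beyond); one-way repeated-measures ANOVA (subjects = dataset id
by default, switchable) with Bonferroni-multiplied pairwise paired t
post-hocs (family = all C(k,2) pairs); pooled-variance unpaired t by
default with Welch behind a flag.  Greenhouse–Geisser ε is computed and
reported but not applied by default.

## Synthetic generator

The generator emulates the statistical and temporal structure the analysis
assumes, with recoverable ground truth; it is not a biophysical axon model.

- **Twitch kernel** `g(t) = (t/T_c) e^{1−t/T_c}` (classic two-parameter
  twitch; peak 1 at `T_c`, closed-form integral), truncated at one
  inter-stimulus interval: at 5 Hz with `T_c ≤ 40 ms` the discarded tail is
  ~2% of peak, and truncation makes window-aligned identities exact.
- **Block law**: block-phase twitch gain is `1 − BLK_true(I)` with
  `BLK_true` the logistic sigmoid at the ground-truth `(σ*, β*)`.  Default
  TF truth anchors σ* to 0.74 / 1.2 / 1.8 / 2.5 / 3.2 / 3.98 mA at
  5/10/15/20/25/30 kHz with β* decreasing from 14 to 6 mA⁻¹; the peroneal
  spillover truth uses a much higher σ and a shallow slope (β = 1.5 mA⁻¹)
  so PF block stays partial over the swept range.  Spillover sweeps share
  the TF amplitude axis (ratios of the TF threshold), mirroring the B_avg
  sweep rule.
- **Onset transient**: gamma-shaped pulse `A x e^{1−x}` whose 10% crossings
  are `−W₀(−0.1/e)` and `−W₋₁(−0.1/e)` in units of its time constant
  (Lambert W), so the true TD is closed-form; a triangular kernel with
  trivially closed-form crossings is also available.  Peak and duration
  scale with `10 kHz/f_KES`, reproducing the attenuation of the onset at
  higher blocking frequencies; the non-target fascicle sees the transient
  scaled by `spillover_fraction`.
- **Fatigue/recovery**: the force state declines per twitch by
  `fatigue_rate × transmitted activation` and recovers exponentially toward
  1 at `recovery_rate` per second while the pool rests.  Defaults
  (`fatigue_rate = 0.006`/twitch, `recovery_rate = 0.02`/s) produce a
  pre-to-post peak-force decrease near 15% without KES, ~5% under an ideal
  block, and the no-KES > weak > strong ≥ ideal ordering.
- **Facilitation**: optional gain ≥ 1 applied when `I < 0.75 σ*` (the
  sub-threshold force-amplification regime); the magnitude of the in vivo
  effect is not quantified in the literature this emulates, so the gain is
  a free parameter, off by default.
- **Noise and drift**: additive white Gaussian noise (default sd 0.01 N on
  1 N twitches) and a slow sinusoidal baseline wander (0.02 N, 60 s).
- **Determinism**: one RNG stream per recording, derived from
  `(seed, row index)` via `SeedSequence`, so datasets are reproducible
  row-wise and bit-identical under a fixed seed.

What the generator does **not** emulate — stimulus artifacts, motor-unit
discreteness and size-principle recruitment, carry-over block after long
KES, EMG, co-contraction mechanics — bounds what green tests show about
real data: they validate the estimators against the assumed signal
structure, not the biology.

## Problem sizes and numerical choices

The test suite and acceptance script run scaled-down study replicas (one or
two datasets per protocol family, 5–21 amplitudes per sweep, 1–5 kS/s);
these sizes are the package's own defaults for desk-scale validation and
can be raised freely.  Recruitment-recovery checks use 500 noisy sweeps per
σ* at the 21-point grid; fatigue-ordering checks use 50 replicates of
10+10 control trials plus six sweep trials whose true block amounts sit
well inside the weak/strong groups.  Degenerate inputs are first-class:
empty sweeps, all-identical BLK, constant SD points, all-zero onset windows
and zero-variance samples each raise a named error or return a documented
sentinel rather than propagating NaNs.

## Known limitations

- The threshold search assumes a monotone sweep; non-monotone block (seen
  with some waveforms or above 30 kHz elsewhere) would need a different
  detection rule.
- The HDF5-style bulk container mentioned as an option for very large
  sweeps is not implemented; the CSV + JSON sidecar format covers the
  pipeline's needs and stays human-inspectable.
- The adapter for the publicly deposited in vivo archive is a stub: the
  archive's internal layout is undocumented, so recordings must be
  converted to this package's format first.
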