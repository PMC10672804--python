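# Methods

`sospin` implements an analysis chain for the coordination of sleep
spindles and slow oscillations (SOs) in developmental sleep EEG, together
with a ground-truth simulator that makes every stage testable without
real recordings. This note documents the models, the defaults and why
they were chosen, the numerical conventions, and the limits of what the
synthetic tests can show.

## The synthetic polysomnography model

A recording is a sum of three components per channel:

1. **Aperiodic background.** Gaussian noise spectrally shaped so its
   one-sided PSD is `A·f^−a` (µV²/Hz) for 0.5–35 Hz and zero outside,
   emulating a 0.3–35 Hz band-passed acquisition chain. Defaults
   `A = 100`, `a = 1.5` give a broadband RMS of ≈16 µV and an in-band
   (11.5–14.5 Hz) RMS of ≈2.5 µV — the order of magnitude of NREM scalp
   EEG. `band_rms(A, a, lo, hi)` gives the closed-form in-band RMS, so
   burst amplitudes can be expressed as signal-to-noise ratios: we define
   SNR as *burst RMS amplitude over in-band background RMS* (for a
   sinusoidal burst of peak amplitude `c`, burst RMS is `c/√2`; for an SO
   of peak-to-peak `P`, the equivalent-sine RMS is `P/(2√2)` against the
   0.2–4 Hz band).

2. **Slow oscillations.** A negative half-sine followed by a positive
   half-sine spanning one period of `so_freq_hz` (default 0.75 Hz, legal
   range 0.5–1 Hz). Events are global — identical times on all channels —
   with a topographic amplitude gradient (defaults 250 µV peak-to-peak
   frontal, 150 µV centro-parietal/occipital; frontal dominance is the
   mature pattern). Density defaults to 3/min of eligible sleep, the
   typical overnight NREM-pooled rate; counts are deterministic,
   `round(density · duration)`, so cardinality tests are exact.

3. **Spindles.** Hann-windowed sinusoids, default 1.5 s, 25 µV peak,
   centred on `spindle_freq_hz` with a per-event spread of
   `spindle_freq_jitter_hz` (default 0.5 Hz, clipped to 9–16 Hz). The
   event-level spread matters: it is what gives a subject *both* a
   dominant development-specific rhythm and a minority of events in the
   canonical 12.5–16 Hz band, which is precisely the structure the
   maturity scores quantify — without it, the adult-like and
   development-specific detectors return identical event sets and the
   maturity construct is degenerate. The 1.5-s default duration reflects
   reported durations of developmental centro-parietal spindles and the
   detector's geometry: with the mean + 1.5 SD envelope threshold, only
   the central ≈45 % of a Hann burst exceeds threshold at moderate SNR,
   so events much shorter than ~1.2 s fall under the 0.5-s minimum-run
   rule even when clearly present.

**Coupling.** Phase 0 is the SO up peak and ±π the down peak, linear in
time across the cycle. A `coupled_fraction` of spindles is centred at
`up_peak + θ·T/(2π)` with `θ ~ von Mises(coupling_phase_rad,
coupling_kappa)`; the rest are placed uniformly in artifact-free NREM
outside every SO ± 1.2 s (set `so_exclusion_margin_s=None` to place them
independently of SO timing — the correct chance model for type-I-error
simulations, since the default exclusion rule produces *negative*
coupling, an empty PETH in the extreme).

**What the generator does not emulate:** sleep-cycle architecture and
REM, K-complexes, non-stationary background, spatially continuous
topographies (channels differ only by group amplitude), EMG/EOG/ECG, and
real artifact morphology (the mask is plumbing: contiguous 1-s blocks).
Passing tests therefore demonstrate algorithmic correctness and
statistical calibration under the stated model, not clinical performance
on real polysomnography.

## Detection

**Individual band.** NREM (N2+N3) spectra are means of Hann-tapered
periodograms of non-overlapping, fully artifact-free 5-s segments aligned
to the 30-s hypnogram grid (0.2 Hz resolution), averaged over the
channels of a topographic group. The aperiodic background `A·f^−a` is
fitted by iteratively reweighted least squares (Tukey bisquare, c =
4.685, ≤50 iterations, 1e-8 coefficient tolerance) on log-power vs
log-frequency over 2–30 Hz — a range that stays clear of the acquisition
band edges — and subtracted. The spindle peak is the highest local
maximum (first-derivative sign change, ties to the lower frequency) of
the corrected spectrum strictly inside 9–16 Hz; the individual band is
peak ± 1.5 Hz, flagged when its lower edge falls below 9 Hz. When no
local maximum exists, detection falls back to a configurable reference
peak (pipeline default 12 Hz), flagged in the output.

**Spindles.** On the channel-group average: zero-phase (two-pass)
order-6 Butterworth band-pass with 10-s reflection padding; 0.2-s moving
RMS; 0.2-s moving-average smoothing. Threshold = mean(envelope) +
1.5·SD(filtered signal), both over artifact-free N2+N3 only. Maximal
supra-threshold runs of 0.5–3 s are events; events separated by ≤0.25 s
merge unless the merged span reaches 3 s; events touching artifact or
non-NREM seconds are discarded. Event frequency is the zero-crossing
count / 2 / duration; amplitude is the peak-to-peak of the filtered
signal within the event. "Adult-like" events use the fixed 12.5–16 Hz
band, "development-specific" events the individual band, both on
centro-parietal channels.

**Slow oscillations.** On the 0.2–4 Hz filtered average: candidates are
negative-then-positive half-wave pairs whose span (first negative-going
zero-crossing to the closing crossing) corresponds to 0.5–1 Hz.
Candidates overlapping artifacts are dropped *before* thresholding, then
only candidates with peak-to-peak ≥ 1.25× the candidate mean *and*
negative amplitude ≥ 1.25× the candidate mean survive. The criterion is
self-normalizing: global signal rescaling leaves the surviving set
unchanged. The 1.25 factor is exposed (`amp_criterion_factor`) because
pooling conventions differ between labs.

## Coupling statistics

**Time–frequency.** Trials are SO down peak ± 3 s (fully artifact-free
NREM) and an equal number of 6-s SO-free segments at least 6 s from every
down peak. Morlet decomposition (12 cycles, 5–20 Hz in 1-Hz steps) runs
at the native rate; power is interpolated onto the ±1.2 s / 0.002 s
output grid and contrasted per subject with a pooled-variance two-sample
t-map (Welch optional).

**Cluster-based permutation test.** One-sample (sign-flip) test of
subject maps against zero: pixels above the two-tailed critical t at the
cluster-forming α (default 0.05) form 4-neighbour (or 1-D) clusters;
cluster mass is the sum of t; the null is the per-sign maximum cluster
mass over random whole-subject sign flips; reported p values are doubled
(one-sided test per sign, Bonferroni over signs), so they lie in (0, 2]
and are significant below 0.05. Sums of squares are flip-invariant, so
the permutation recomputes t from flipped means only.

**PETH / KL.** Spindle centres within ±1.2 s of each down peak are pooled
into 24 half-open 100-ms bins (a centre at exactly +1.2 s is excluded; a
centre inside two overlapping windows counts once per window) and
normalized to percent of in-window events. The surrogate is the observed
percentage vector shuffled across bins (default 1000 shuffles) and
averaged — implemented literally, although its expectation is the uniform
vector, because the shuffle count then also sets the surrogate's residual
variance. The modulation index is `D_KL(p‖q) = Σ p·ln(p/q)` on
proportions (nats); zero observed bins contribute zero, and a zero
surrogate bin under observed support is an error, not a silent zero. A
paired observed-vs-surrogate cluster test across subjects and a
half-sampling control (`downsample_control`) complete the battery.

**Validity regime.** The sign-flip null assumes per-bin differences are
symmetric about zero under chance. That holds when per-bin expected
counts are roughly ≥10 (night-scale data: hundreds of in-window spindles
per subject); with only a handful of in-window events the observed PETH
is a sparse multinomial, differences are strongly skewed, and the test is
anti-conservative — our calibration runs measured false-positive rates
near 1 at ~5 events/subject, 0.10 at ~100, and the nominal 0.05 at ~300.
The type-I acceptance simulation therefore uses full-night event counts;
applying the PETH cluster test to subjects with few in-window events is
explicitly unsupported.

## Maturity scores and linking

Raw fast-spindle maturity = adult-like − development-specific feature
differences (density, amplitude; frequency difference sign-inverted so
small gaps mean high maturity); SO maturity = frontal − centro-parietal
SO amplitude. All raw scores are Z-transformed with the sample SD across
*all* recordings in the analysis set, and the three spindle indicators
are compressed by PCA (covariance of the already-standardized columns;
scores are projections on the unit-norm first eigenvector, oriented to a
positive frequency-maturity loading). Rows with missing scores — e.g.
zero adult-like events — are excluded from the decomposition and stay
missing downstream.

**PLSC.** Both blocks are column-standardized; the 3×p cross-correlation
matrix is decomposed by SVD. Dimension significance: permutation of X
rows against Y, `p = (1 + #{S_perm ≥ S_obs}) / (n_perm + 1)` per
dimension on its own singular value, no Procrustes rotation. Stability:
subject bootstrap with per-dimension sign alignment to the original
vectors; pixel reliability as bootstrap ratios (original salience /
bootstrap SE; |BSR| > 1.96 conventionally stable); the X-side pattern is
also reported as correlations between the latent Y score and the raw X
columns with percentile 95 % CIs. Degenerate resamples (a constant
column) are rejected and redrawn.

**Gamma GLMM.** `kl ~ spindle_maturity_component + so_maturity + (1 |
subject)`, gamma family, log link, estimated by `lme4::glmer` (bobyqa)
through `Rscript`; this module owns validation (strictly positive
response, complete columns) and result extraction, and surfaces
convergence messages instead of hiding them. With one observation per
subject the random intercept is near-singular — lme4 reports it, the
fixed-effect estimates remain consistent, and the recovery tests check
exactly that.

## Problem sizes and reproducibility

Synthetic checks use 10-minute recordings for detector work (5-seed
averages), 12-subject cohorts for group inference, 100-repetition
Monte-Carlo runs for type-I calibration (6-h event-level nights), 200
repetitions for PLSC null calibration, and 10 × n=100 simulations for
GLMM recovery — sizes chosen so each check is statistically informative
while a full run of the suite and the acceptance script stays
desk-scale. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); pipeline runs log every parameter, seed and
effective permutation count to `provenance.json`, and rerunning with the
same configuration is bit-identical. The reduced `ci_profile`
(500 permutations/bootstraps instead of 5000) is flagged in the log.

## Known limitations

- EDF export is 16-bit with a per-channel symmetric physical range
  rounded to 0.1 µV; quantization error is ≤ range/65536.
- The artifact stand-in mask does not model any published artifact
  detector; analyses only require *a* mask.
- Detection operates on channel-group averages (average-then-detect);
  per-channel detection with event-level pooling is not implemented.
- The PETH surrogate equals the uniform distribution in expectation;
  shuffling is retained for fidelity to the described procedure, not
  because it adds information.
- Cluster p-value doubling makes the reported values Bonferroni-style
  bounds; they can exceed 1 and are compared against 0.05 as stated.
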