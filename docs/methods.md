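# Methods

## Signal model and synthetic data

The trace generator produces what the processing pipeline assumes the
microscope produced:

    F(t) = B(t) · (1 + Σ_trials m · k(t − t_onset)) + ε(t)

* **Bleaching envelope** B(t) = baseline_F · (a₁·e^(−t/τ₁) + a₂·e^(−t/τ₂) + c).
  Defaults: baseline_F = 1000 a.u., a₁ = 0.4, τ₁ = 20 s, a₂ = 0.3,
  τ₂ = 200 s, c = 0.3, i.e. a fast and a slow bleaching component decaying
  toward a plateau, all positive.  Per-ROI parameters are jittered
  log-normally (CV 0.1 by default) so every ROI has its own ground-truth
  baseline.
* **Transient kernel** k(t) = (e^(−t/τ_decay) − e^(−t/τ_rise)) normalized to
  unit peak, zero for t < 0; defaults τ_rise = 50 ms, τ_decay = 400 ms —
  fast-indicator (GCaMP6f-scale) dynamics.  The exact kernel shape is not a
  claim about the indicator; the pipeline is only required to be robust to
  it, and tests exercise that via parameter recovery rather than kernel
  identity.
* **Amplitude** m = amp × effect_map[genotype][compartment].  The base peak
  ΔF/F is 0.5; the default effect map gives the experimental genotype 0.5×
  responses in the cell body and lobula arbors (Lo1/Lo4), 1× in M1/M8/M10,
  and 3× in M5, with both control genotypes flat at 1×.  These defaults set
  a qualitative pattern for the pipeline to resolve; no measured effect size
  is hard-coded as truth.
* **Onset timing.**  The physical stimulus onset lags the nominal command
  by (delay − frame/2) + U[0, frame) with frame = 8.33 ms and delay =
  6.25 ms, so the lag varies within one stimulus frame and its mean equals
  the measured delay.  Analysis compensates the mean only, leaving the
  ±4.2 ms residual jitter the real experiment also has.
* **Noise** is i.i.d. Gaussian on F with SD noise_sd (default 100 a.u.; with
  the default amplitude and baseline this is a per-frame peak-signal SNR of
  5).  A Poisson mode (variance matched to noise_sd at the mean intensity)
  is available behind a flag.  The generator does not emulate optics (PSF,
  scanning artifacts), motion beyond integer translation, or biophysical
  channel dynamics — passing tests therefore demonstrate correctness of the
  *analysis* under the stated signal model, not robustness to every failure
  mode of real microscopy.

The movie generator renders each ROI trace as a uniform-intensity disk on a
flat background rather than a Gaussian profile: the contract is that the
ROI-mask mean minus the background mean reproduces the generating trace
within quantization, which only a flat profile satisfies exactly.

Random numbers come from named substreams of one root seed (SeedSequence
spawn keys derived from stream names), so per-ROI identity parameters are
stable across stimulus protocols and adding records to one part of a
simulation never perturbs another.

## Trace processing

* **Bleach fit.**  Least squares of a₁·e^(−t/τ₁) + a₂·e^(−t/τ₂) + c over
  the masked frames.  The offset c is included by default (real baselines
  plateau, and the pure two-exponential model is nested at c = 0; a
  no-offset mode exists).  The fit is log-parameterized — amplitudes, time
  constants and offset are all positive, which encodes that the baseline is
  decaying fluorescence and guarantees F₀ > 0 — and solved by
  Levenberg–Marquardt with an analytic Jacobian; τ's start at 10% and 100%
  of the trace duration, amplitudes from the first/last masked values.  Up
  to 5 seeded restarts run only if the deterministic start fails; the
  lowest SSE wins.  Components are reported with τ₁ ≤ τ₂.  A constant trace
  collapses to the offset.  For the flash-off-gray protocol the fitting mask
  is the final 25% of every gray interleave (375 ms of 1500 ms), including
  the leading gray; for the search protocol all frames are used.
* **Stimulus-locked average.**  Windows are centred on the grid point
  (symmetric [t − w/2, t + w/2)), which preserves peak timing; the grid is
  −pre + k·shift with shift = 8.33 ms, so the output rate is ~120 Hz and a
  25 ms window shares each sample across 3 consecutive bins.  Bins with no
  samples are dropped (they occur when a single trial is averaged at a
  window below the frame period); per-bin SEM uses the ddof = 1 SD.  The
  implementation computes each bin directly from the pooled sorted samples
  and is tested for equality against an independent brute-force mean.
* **Responder rule.**  The detection criterion is deliberately explicit
  because response detection thresholds are a free choice: a ROI responds
  if max |mean ΔF/F| in the response window exceeds k·SD of the mean trace
  in the pre-stimulus baseline window, k = 3 by default, evaluated on the
  search-protocol average.  Dark-flash responses are computed but excluded
  from group statistics by default.
* **Peaks and normalization.**  Peak = extreme of the averaged trace in the
  expected direction within the response window (default 0–0.5 s after
  onset).  Peaks are divided by the no-Flp control group mean, making the
  control mean exactly 1 by construction.  Group SEMs are across ROIs;
  per-fly aggregation is a caller-side groupby.
* **Registration** is translation-only: each frame is shifted by the integer
  displacement maximizing its circular FFT cross-correlation with the mean
  of the first 10 frames, clamped to a configurable maximum with a logged
  warning.  This stands in for general-purpose alignment tools and is not
  meant for rotation or non-rigid motion.

## Colocalization

One-to-one matching under a strict (<) distance threshold.  The matching is
distance-optimal: maximum cardinality over the sub-threshold pairs, and
minimal total distance among maximum matchings, solved as a linear
assignment with forbidden pairs priced out.  A greedy nearest-pair rule was
considered and rejected — it can strand matchable spots (a 4+7-spot
counterexample loses one pair), whereas the optimal matching provably equals
the exhaustive maximum-matching oracle the tests compare against.  A
one-to-many "any spot within radius" mode exists for sensitivity analysis.
Percentages are summarized across specimens (each individually scored visual
system is one observation); a single specimen reports SEM = 0 with an
explicit flag.  Manual post-hoc corrections of individual matches are out of
scope.

## Genetics statistics

* Survival expectation enumerates the four equiprobable zygote classes of a
  heterozygote × heterozygote cross, removes lethal classes (the balancer
  homozygote is lethal by default), and reports the scored class's share
  among survivors — 1/3 for the standard complementation cross.
* The one-proportion z-test uses the null proportion in the standard error
  and a two-sided normal p without continuity correction; an exact binomial
  is the cross-check in tests.
* Fisher's exact test is two-tailed by the probability-mass convention
  (scipy), verified against hypergeometric enumeration for small tables.
* ΔΔCt: technical replicates are averaged per biological replicate,
  ΔCt = Ct_target − Ct_reference, the point estimate is
  100·2^(mean ΔCt_ND − mean ΔCt_D) (ideal doubling, base 2; measured primer
  efficiencies are metadata, not corrections), and the t-test runs on the
  per-replicate ΔCt values.  Per-replicate display values are
  100·2^(mean ΔCt_ND − ΔCt_rep); because the point estimate averages in log
  space, the linear-scale mean of the noisy ND replicates is only
  approximately 100%.
* Post-hoc t-tests are pooled-variance Student's tests by default (Welch
  behind a flag), Bonferroni-adjusted p = min(1, m·p).  Asterisks are
  displayed only when the experimental group differs from both controls at
  adjusted p < 0.05, and the displayed tier is that of the larger adjusted
  p.  Identical-sample degenerate cases (zero variance, equal means) report
  p = 1 rather than NaN.

## Problem sizes and determinism

The test suite and analysis drivers run the full pipeline at reduced but
structurally complete sizes — typically 4–50 ROIs per condition, 6–15 light
flashes per ROI, 40–70 spots per cloud, 2000-replicate Monte-Carlo for
calibration, 10 seeds for power — sizes chosen so the statistical checks
(median peak-recovery error ≤ 10% at SNR 5, null display rate ≤ 5%,
≥ 90% detection of the 3× M5 effect) are well-resolved while a complete run
stays in the minutes range on one core.  Every random draw descends from a
single root seed, and an end-to-end run with a fixed seed is byte-identical
across executions.

## Known limitations

The bleach fit's two time constants are weakly identified when their ratio
is small or the record is much shorter than τ₂; the fit then returns a
degenerate-but-equivalent baseline (near-equal τ's), which leaves ΔF/F
essentially unchanged but makes individual parameter values untrustworthy —
parameter-recovery claims hold for noiseless, well-separated components.
The responder criterion and response window are interpretations, exposed as
configuration.  The colocalization matching is globally optimal for the
stated objective, but whether commercial tools enforce one-to-one matching
is unknown; the any-within-radius mode brackets that uncertainty.
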