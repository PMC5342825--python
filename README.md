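# flpstop-pipeline

Analysis pipeline for conditional gene-disruption experiments in the
*Drosophila* visual system: two-photon calcium-imaging trace processing,
cassette-inversion counting by 3D spot colocalization, and the genetics and
expression statistics that accompany such a study.

## Who this is for

Experiments with an invertible FlpStop-style cassette ask three quantitative
questions: does the disrupting orientation abolish gene function
(complementation survival counts, paralysis counts, qRT-PCR transcript
levels)? how efficiently does the driver invert the cassette (fraction of
driver-labeled cells that also express the tdTomato inversion reporter)? and
what does removing the gene do to neuronal physiology (GCaMP6f responses per
cellular compartment)?  This package implements the full computational path
for all three, plus a seeded synthetic-data generator that emulates the raw
data's statistical structure and carries ground truth, so every stage is
testable by parameter recovery.

## The core computations

**Calcium imaging.**  For each ROI, fluorescence is background-subtracted
and the photobleaching baseline is fitted as
F₀(t) = a₁·e^(−t/τ₁) + a₂·e^(−t/τ₂) + c (least squares; for the
flash-off-gray protocol only frames in the last 25% of each gray interleave
are fitted, placing ΔF/F = 0 at the between-flash baseline).  Then
ΔF/F = (F(t) − F₀(t))/F₀(t).  Stimulus onsets are corrected by the measured
projector delay (6.25 ms) and every frame time is reassigned relative to
each transition; a simple moving average with a 25 ms window and an 8.33 ms
shift resamples the pooled samples from the 38.9 Hz acquisition rate to
~120 Hz with 3-point boxcar smoothing.  The peak response to a light flash
is the ΔF/F value farthest from zero in the direction of the initial
calcium increase; peaks are normalized to the no-Flp control group mean,
and genotypes are compared per compartment by one-way ANOVA with
Bonferroni-corrected post-hoc t-tests (asterisks shown only when the
experimental group differs from both controls; the less significant tier is
displayed).

**Colocalization.**  Cell centres from two channels (µm coordinates) are
matched one-to-one under a distance threshold (3.5 µm; 2.5 µm for tightly
packed T4 cells) by a distance-optimal maximum matching; inversion
efficiency is the percentage of channel-A spots matched, summarized as
mean ± SEM across specimens.

**Genetics statistics.**  Mendelian survival expectation by zygote-class
enumeration (the balancer complementation cross gives the 33% null),
one-proportion z-test z = (p̂ − p₀)/√(p₀(1−p₀)/n), two-tailed Fisher's
exact test, and ΔΔCt transcript quantification
%transcript = 100 · 2^((Ct_ND,target − Ct_ND,ref) − (Ct_D,target − Ct_D,ref))
with a Student's t-test on the per-replicate ΔCt values.

## Worked example

```sh
python analysis/01_simulate_dataset.py --seed 1
python analysis/02_process_traces.py
python analysis/03_inversion_efficiency.py
python analysis/04_genetics_stats.py
```

The second step prints, for the default effect map (experimental responses
halved in the cell body and lobula arbors, unchanged in M1/M8/M10, tripled
in M5):

```
per-compartment summary (experimental normalized peak, display tier):
        Lo1:  0.62×  ***
        Lo4:  0.60×  ***
         M1:  0.90×  ns
        M10:  0.99×  ns
         M5:  2.70×  ***
         M8:  1.06×  ns
  cell_body:  0.58×  ***

compartments significantly different from both controls: ['Lo1', 'Lo4', 'M5', 'cell_body']
```

i.e. the pipeline recovers the programmed compartment-specific effects —
reduced responses where the multiplier is 0.5, an increase where it is 3,
and no false calls in the unchanged compartments.  The colocalization step
reports `inversion efficiency: 90.0% ± 0.0%` for the planted 90%
double-labeled fraction, and the genetics step prints the observed survival
fraction with its z-test against the 33% expectation and a transcript level
near the true 50%.

The same stages are scriptable through one CLI:

```sh
flpstop-pipeline simulate traces --seed 1 --out sim/
flpstop-pipeline process --traces sim/traces.csv --stimlog sim/stimulus_log.json --out proc/
flpstop-pipeline stats ztest --k 147 --n 400
```

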