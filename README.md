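# rcpquant

Quantification of rolling-circle amplification products (RCPs) in two-color
fluorescence images: spot detection, per-signal signal-to-noise ratio,
a nearest-neighbor test for RCP disintegration, and colocalization analysis —
plus a synthetic scene generator so every method can be exercised and
validated against known ground truth without any microscope data.

## Scientific background

RCPs are micrometre-sized DNA balls produced by rolling circle amplification
and read out as diffraction-limited fluorescent spots. Hybridizing a
*compaction oligonucleotide* during amplification cross-links the concatemer
into a tighter ball. Compaction has two measurable consequences in images:

1. **Brighter, higher-SNR spots.** The same number of fluorophores is
   concentrated in a smaller volume, so peak intensity and signal-to-noise
   ratio rise.
2. **Fewer disintegrated products.** A non-compacted RCP can unravel into
   several nearby fragments that all carry the same detection color. Split
   products inflate the frequency at which a signal's nearest neighbor has
   the same color, relative to what random placement would give.

`rcpquant` implements the image statistics needed to measure both effects,
and a generator that renders compact and dispersed scenes from the *same*
underlying ground truth (same parent positions and total fluorophore
content) so the effects can be isolated.

## Core statistics

**Background correction.** Each z-stack is reduced to
`corrected = max_z(I) − min_z(I)`, removing static background while keeping
in-focus signal. The detection threshold is `2 × mode` of the corrected
image's intensities within its [2nd, 98th] percentile range.

**Spot filtering.** Connected components (8-connectivity) above threshold
are kept as single RCPs when `area ≤ 40 px` and
`circularity = 4π·area / perimeter² ≥ 0.5`; larger or irregular components
are treated as clusters and excluded from per-spot statistics.

**SNR.** For a signal at center *c*,

```
r  = max{ I(p) : |p − c| ≤ 3 }  /  SD{ I(p) : 3 < |p − c| ≤ 7 }
SNR_dB = 20 · log10(r)
```

Signals whose measurement disk leaves the image, sits within two disk radii
of another candidate, or touches another detected object are excluded so
every annulus estimates pure background.

**Integrity (disintegration) test.** With `n₁` signals of color 1 and `n₂`
of color 2, the observed fraction of signals whose Euclidean nearest
neighbor has the same color is compared to a Monte Carlo null: 10 replicates
of `n₁ + n₂` points placed uniformly at random on the camera field with the
same per-color counts. Under random placement the expected frequency has the
closed form

```
f_null = [ n₁(n₁−1) + n₂(n₂−1) ] / [ n(n−1) ],   n = n₁ + n₂
```

The observed frequency is tested against the null replicates with a
prediction-interval t statistic,
`t = (f_obs − mean_null) / (sd_null · √(1 + 1/n_rep))`, df = `n_rep − 1`,
which asks whether the observation could be an 11th draw from the null.

**Colocalization.** Slide images are compared by pixel
intersection-over-union of the two binarized channels. Solution-phase
objects (flow-type readout) are classified per channel at a PMT threshold
of 35 counts with a size gate of 2–30 px; objects positive in both channels
count toward the dual-color fraction, and dual fractions across compaction-
oligo concentrations are compared with one-way ANOVA followed by Fisher's
LSD post-hoc tests.

## Worked example

`examples/full_pipeline.py` simulates a dispersed two-color scene
(200 RCPs, 512×512×16) and runs every stage:

```
$ python examples/full_pipeline.py
true RCPs: 200  detected ch1/ch2: 296/234  after cluster filter: 122/122
local maxima ch1/ch2: 150/161  SNR-eligible: 70/62
ch1 SNR: 26.37 dB (SD 3.02)
same-color NN frequency: 83.6% vs null 49.6%, p = 1.5e-07
channel overlap: 0.00%
```

Disintegrated RCPs split into several same-color sub-foci, so more
components are detected than true RCPs, and the same-color nearest-neighbor
frequency (83.6%) far exceeds the random-placement null (49.6%). The two
colors are placed independently, so pixel overlap is at chance (here 0%).

The compaction contrast itself (`examples/snr_comparison.py`, same ground
truth rendered both ways):

```
compact    n= 88  peak  206.1 (SD  43.2)  SNR 29.43 dB (SD 1.76)
dispersed  n= 69  peak  165.0 (SD  48.7)  SNR 26.57 dB (SD 3.41)
t-test: p = 2.27e-10
```

Other examples: `simulate_scene.py` (generator and ground-truth table),
`integrity_null.py` (Monte Carlo vs closed-form null at real experiment
sizes), `colocalization.py` (slide overlap, solution-phase classification,
dose-response ANOVA + LSD).

A `rcpquant` command-line interface exposes the same stages
(`rcpquant all --config run.yaml --out results/`); see `rcpquant --help`.

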