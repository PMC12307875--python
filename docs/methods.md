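# Methods

`mamquant` quantifies the imaging and plate-based readouts used to study
ER stress–driven changes in ER–mitochondria communication: organelle
contact (MAM) overlap, mitochondrial morphology, autophagy/mitophagy flux
with tandem fluorophores, organellar calcium dynamics, fractional ATP
bioenergetics, flow-cytometry summaries, and a downstream differential-
expression screen. Every analysis has a paired synthetic generator with
exact ground truth, so the whole pipeline is testable without microscope
or sequencer output.

## Overlap index (ER–mitochondria contact)

All channels of a comparison are processed with one parameter set:
percentile contrast stretch into [0, 1], optional unsharp masking (fixed
radius 2 px, amount 1, recorded in provenance), and one global threshold.
By default the threshold is Otsu's, computed once on the pooled control
batch and applied to every image; a fixed value can be supplied instead.
Connected components smaller than 10 pixels are removed (strictly below:
a 10-pixel punctum survives); components are 8-connected, the common
default for diffraction-limited fluorescence puncta, and the choice is
recorded in the mask provenance.

The contact readout per sample is the number of pixel coordinates
foreground in both binarized channels, optionally after dilating both
masks by a small disk (default radius 0 for measurement; the synthetic
ground truth uses radius 1 to express that diffraction-limited signals
touching within a pixel count as contact). The **overlap index** is each
sample's overlap pixel count divided by the mean count of the control
group, so the control group averages to 1 by construction; group
mean ± SEM are reported, with the SEM of a singleton group reported as
absent rather than 0. A three-way variant counts coordinates foreground
in ER, mitochondria and a protein channel simultaneously.

Pearson's correlation is computed separately, on raw (contrast-adjusted
but unbinarized) intensities over the whole image or a cell ROI. It is
deliberately not derived from the binary masks: the overlap index and the
correlation coefficient are two different statistics and both are exposed.
Zero-variance channels yield an absent value with a reason, not a number.

## Mitochondrial morphometry

Lengths are measured per connected component as the longest end-to-end
geodesic path through the skeleton. Two discretization corrections matter:

- **Chain-code bias.** Summing unit/√2 steps along an 8-connected path
  overestimates oblique straight segments by up to ~8%. The path is
  therefore resampled every 5 pixels and measured as a Euclidean polyline.
- **End caps.** The skeleton over- or under-reaches the organelle tips
  depending on orientation. The path is extended by the inscribed radius
  (Euclidean distance transform) at each end and shortened by the object
  width (twice the median inscribed radius along the skeleton). For a
  capsule-shaped object this recovers the centerline between the end-cap
  centers.

On noiseless synthetic capsules of 1–8 µm this estimator is unbiased with
a maximum per-object error around 6–7%. Skeletons with no endpoints
(loops) fall back to a double-sweep diameter approximation. Objects below
the 10-pixel small-puncta cutoff are excluded.

Each length maps to one of three categories: fragmented (< 2.5 µm),
intermediate (2.5–5 µm) or filamentous (> 5 µm). The boundary values 2.5
and 5.0 µm are assigned to intermediate — the middle bin is read as the
closed interval — and the rule is total: every non-negative length gets
exactly one category. Group summaries pool objects and report category
counts, fractions, and length median/quartiles (violin-ready).

## Tandem-fluorophore flux readouts

Puncta are segmented on the red channel (threshold + small-object filter)
and carry mean intensities of both channels. A punctum is **green-positive
(dual)** when its mean green intensity exceeds the background median plus
k·MAD (k = 3 by default), with background taken outside the red-channel
foreground; otherwise it is **red-only** (EGFP quenched, i.e. an acidic
compartment). With a flat noiseless background the MAD is zero and the
rule degenerates to "any green strictly above background"; a small
relative tolerance keeps floating-point accumulation from flipping puncta
that sit exactly at background.

Readouts: red-puncta percentage = 100 · #red-only / #total per cell
(absent for zero puncta); red-intensity percentage =
100 · Σred / (Σred + Σgreen) over an ROI, invariant to common rescaling
of both channels; and co-positive puncta counts, where a marker punctum
(LC3 or CD63) counts as containing mitochondria when its footprint
overlaps the mitochondrial mask by at least max(1 px, a configurable
fraction of its area). The any-overlap default is an explicit software
approximation of what was a manual "engulfment" call at the bench.

## Calcium ΔF/F0

The indicator is divided by its co-expressed reference channel at every
timepoint first — R(t) = I(t)/ref(t) — and ΔF/F0 is computed on the
ratio: dff0(t) = (R(t) − R(0)) / R(0). The order matters: shared
multiplicative artifacts (photobleaching, focus drift) cancel in R before
the fold change is formed, and dff0(0) = 0 exactly. Zero reference values
or a non-positive initial ratio raise errors naming the timepoint. Group
curves are pointwise mean ± SEM across traces on a shared timebase; both
across-cell and across-experiment aggregation are possible by choosing
what a "trace" is. For efflux kinetics, ln(1 + dff0) is linear in time
with slope −k, which `fit_rate_constant` exploits.

## ATP bioenergetics

With condition means Ā over replicates: glucose dependence =
(Ā_ctrl − Ā_DG)/Ā_ctrl, FAO/AAO capacity its complement, mitochondrial
dependence = (Ā_ctrl − Ā_OA)/Ā_ctrl, glycolytic capacity its complement.
The pair sums equal 1 exactly by construction and the profile is
invariant to rescaling all luminescence. Fractions are ratios of
condition means by default (a per-replicate mode exists); values outside
[0, 1], which noise can produce, are flagged, not truncated.

The combined DG+OA arm has no agreed role in the four fractions; it is
loaded and reported, and an optional `baseline="dgoa"` mode subtracts its
mean from every condition first (treating the double-inhibited signal as
a floor). In the generator the DGOA mean follows independent action,
B·(1−g)·(1−m) clipped at zero — a modeling choice, since no combination
formula is implied by the single-inhibitor definitions.

## Flow cytometry

Per-sample MFI is the arithmetic mean over events (not geometric; the
choice is recorded), the potential-to-mass readout is MFI_TMRM/MFI_MTG,
and fold changes divide by the control-group mean so the control group
averages to 1.

## Expression screen and qPCR

The volcano filter calls up/down at |log2FC| ≥ 2 and p ≤ 0.01, both
boundaries inclusive; the p boundary is inclusive by its definition and
the fold-change boundary is set inclusive for symmetry. The filter uses
whichever p-value column it is given (raw by default; an adjusted column
can be designated) and the three calls partition the table. Mitochondrial
membership is a case-insensitive match against a user-supplied plain-text
gene list (a MitoCarta-style inventory; not bundled — tests use synthetic
lists). Upstream count modeling is out of scope.

qPCR fold change is 2^(−ΔΔCt) with ΔCt = mean Ct(target) − mean Ct(ref)
per condition and ΔΔCt = ΔCt(treated) − ΔCt(control); it is invariant to
per-condition constant offsets and requires all four cells of the 2×2
design.

## Group comparison

`compare_groups` reports means ± SEM, fold change vs the reference group,
and an unpaired two-tailed Welch t-test. Welch is used because it is the
safer default when variances are unequal and is labeled in the output;
the zero-variance-in-both-groups case is reported explicitly as
degenerate rather than producing a silent NaN.

## Synthetic data: what it does and does not emulate

Generators are pure functions of (parameters, seed) using one explicit
`numpy` Generator per call — no global state — and rendered noiseless
foregrounds equal the stored ground-truth masks exactly.

- **Cell images** (256×256 default, 0.05 µm/px): ER tubules are dilated
  persistent random walks (width 3 px); mitochondria are straight
  capsules (width 5 px, length 15–35 px); a configurable number of
  capsules is centered on ER foreground so expected contact area scales
  linearly with that count — this linearity is what makes the 2× group
  ratio recoverable. Contact ground truth is dilate(ER,1) ∧ dilate(mito,1).
  Protein puncta (radius 2 px) are seeded 70% inside contacts by default.
- **Capsule fields** (512×512, 0.1 µm/px): 30 non-overlapping straight
  capsules with lengths uniform on 1–8 µm, spanning all three morphology
  bins; true length is the Euclidean centerline length of the rounded
  endpoints. Placement failure after 500 attempts raises an error naming
  how many were placed.
- **Reporter images**: exactly round(n·f) red-only puncta (half away from
  zero), background 0.05, dual green 0.9 — chosen so noiseless recovery
  is exact and testable.
- **Traces**: exponential efflux/influx (default k = 0.01 /s, A = 100,
  120 points at 5 s), constant reference (50), optional shared bleaching.
- **Plates**: mean-preserving multiplicative lognormal replicate noise,
  σ² = ln(1 + cv²), defaults cv = 5%, n = 3, B = 1000 RLu.
- **Gene tables**: 1000 null / 25 up / 15 down by default; null log2FC is
  clipped inside ±1.5 and spiked |log2FC| ≥ 2 with p ≤ 10⁻³, so threshold
  recovery is structurally exact; null p-values are uniform.
- **Flow events**: per-channel lognormal, closed-form MFI exp(µ + σ²/2).

Not emulated: point-spread functions, camera noise models, 3D stacks,
curved or branching mitochondria, punctum size variation, spectral
bleed-through, autofluorescence, or biologically realistic DE p-value
distributions. Passing recovery tests therefore demonstrates that the
estimators are correct on their stated geometry and noise, not that they
are robust to every optical artifact of real micrographs.

## Numerical choices and edge cases

- Degenerate contrast stretch (constant image) maps to all zeros.
- Fold changes over a zero control mean are errors, not infinities.
- SEM of singleton groups, Pearson of zero-variance channels, and
  percentages of zero-puncta cells are reported absent with reasons.
- The noisy-plate recovery test checks RMS error and bias per fraction
  (≤ 0.05) over a 200-plate ensemble; with cv 5% and n = 3 the single-
  plate estimator sd is ≈ 0.02, so individual plates occasionally exceed
  0.05 — an irreducible property of the prescribed noise, which is why
  the ensemble summary is the tested quantity.
- Pipeline runs are byte-identical for identical config + seed; the JSON
  run log records version, seed and the full parameter set.

## Problem sizes

Default test and demonstration sizes — 10 images/group at 256², 30
capsules at 512², 200 plates, 50k flow events, 1040-gene tables — were
chosen so each stage's statistical target (15% ratio recovery, 10% length
error, 0.05 fraction RMS) is met with margin while a full run completes
in seconds on one CPU.
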