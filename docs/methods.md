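# Methods

This note documents the models, conventions and design choices behind
`compartquant`: what each stage computes, what the synthetic data emulate,
and where the open decisions were settled.

## Segmentation model

The four ROI classes are built from two structural channels. Nuclei come from
the nuclear channel by Otsu thresholding (all thresholds are configurable;
Otsu is the default throughout), a small-object filter, and a
distance-transform watershed that splits touching nuclei (minimum peak
separation 4 µm; area gate 20–400 µm², both in physical units). Somata are
nucleus-seeded watershed regions of the MAP2 mask on the distance-to-nucleus
elevation, with two guards: a morphological opening (radius 1 µm) first
removes structures thinner than ~2 µm so thin neurites are not annexed, and a
hard cap of 15 µm from the seed nucleus bounds soma extent. The cap value is a
design choice: it only matters when the opening leaves wide proximal shafts
attached, and 15 µm comfortably exceeds a developing soma radius. One soma per
nucleus, same label, nucleus ⊆ soma always.

Neurites are the thresholded MAP2 signal combined with a multi-scale Sato
ridge (tubeness) response (σ = 1, 2 px) gated at half the intensity cut, minus
the soma mask, despeckled (components ≤ 2 µm², 8-connected), and skeletonized.
Total length sums skeleton adjacencies — pixel size for orthogonal steps,
√2 × pixel size for diagonal steps — and endpoint tips are skeleton pixels of
degree 1. On constructed polyline fixtures this recovers length within ~2%
(the skeleton's corner pixels contribute a small positive bias; the 5%
tolerance used in tests covers it). Neurite morphology is quantified per well,
not per cell. Whole cells are connected components of the MAP2 mask; for
counting, the per-well MAP2+ cell count is the number of nuclei lying inside
MAP2+ components, because components merge wherever neurites of different
cells touch and component counting would then undercount arbitrarily.

## Puncta detection and colocalization

The intensity reference comes from negative-control wells (background model
plus structural channels, no puncta signal): threshold = mean background
intensity + *k*·SD with *k* = 0 by default. Detection binarizes the channel at
threshold + `detect_k`·SD (default 5 background SDs): at that level the
probability of a background pixel crossing is ~3·10⁻⁷, so background texture
cannot seed spots, while any spot bright enough to be analyzable (≥ 5× the
threshold) is far above it. Touching spots are split by a watershed seeded at
local maxima of a lightly smoothed (σ = 0.5 px) image. Footprints are the
above-level pixels of each region; retained puncta need mean intensity above
the negative-control threshold and an equivalent-circular diameter
2·√(area/π)·pixel within 0.4–4 µm (inclusive; the bound is a diameter, not an
area). Compartment assignment is by centroid membership, soma before neurite
before whole cell. Sub-resolution spot pairs (centers ≲ 0.5 µm apart) are
genuinely unresolvable and merge; at the default densities this costs a few
percent of counts at the highest planted density and cancels almost entirely
in the ΔΔPC ratio.

Colocalization is deliberately asymmetric (channel A overlaid onto channel B):
fraction = |footprint_A ∩ ∪footprints_B| / |footprint_A|, colocalized iff
≥ 0.5 — a tie at exactly one half counts — and an A punctum overlapping two B
puncta still counts once, because the readout is colocalized puncta, not pairs.

## Normalization chain

ΔPC divides the compartment's puncta count by its denominator (somata count,
MAP2+ cell count, neurite length in µm); ΔΔPC divides by the same-plate
wild-type ΔPC, where several wild-type wells contribute their mean. ΔMI, ΔID/
ΔΔID and log₁₀(2^−ΔΔCt) follow the same ratio-to-same-batch-reference pattern;
the three housekeeping Cts are combined by their arithmetic mean (equivalently
the geometric mean of housekeeping expression). Zero or missing denominators
flag the value as missing (NaN) — never a division result, never imputed —
and missing values are excluded listwise at the statistics stage. Puromycin
intensities are ratioed without background subtraction. Technical-replicate
wells are averaged to one value per (clone, biological replicate) before any
test is run; the pipeline enforces this structurally.

## Calcium features

F₀ is the mean prestimulus fluorescence; the baseline window defaults to all
frames up to 1 s before onset (the prestimulus period is otherwise
unspecified; the 1 s guard keeps early rise out of the baseline). Onset is the
frame receiving the maximal first difference of the cross-ROI mean ΔF/F₀
trace, ties resolved to the earliest frame; a constant trace has no onset and
the caller must supply one. Features use a 0–20 s poststimulus window: peak =
max ΔF/F₀; AUC = trapezoidal integral of (ΔF/F₀ − baseline mean); latency =
onset to peak; rise time = 10%→90% of peak on the rising limb with linear
interpolation between frames. A trace that never leaves baseline reports
peak 0, AUC 0 and latency 0 with a quality flag, avoiding undefined arithmetic
downstream; its rise time is missing. Responder means peak strictly greater
than baseline mean + 3·baseline SD, computed on raw (unsmoothed) ΔF/F₀.
Group comparisons use the two-sided Wilcoxon rank-sum test — exact when both
groups have ≤ 25 untied observations, the tie-corrected normal approximation
otherwise — with ROIs treated as independent observations.

## Proteomics

All analyses run on log₂ LFQ values with explicit missingness; non-detections
are never zero-imputed. The detection filter keeps proteins identified in
≥ 70% of retained samples (outlier samples may be excluded first) and is
idempotent. Compartment-exclusive sets are computed on the unfiltered table —
a protein detected only where it was detectable is the signal here, and the
filter would erase exactly the most exclusive proteins. The neurite-vs-soma
comparison uses ordinary pooled-variance two-sample *t* tests per protein on
pairwise-complete values with BH adjustment; a moderated (empirical-Bayes)
variant would shrink per-protein variances but changes nothing on the
synthetic tables used for validation, where planted |log₂FC| = 3 effects at
n = 6 vs 6 and SD 0.3 are detected with power ≈ 1. log₂FC is
mean(neurite) − mean(soma); the pass rule is adj. *p* < 0.05 and
|log₂FC| > 1.5. The abundance ratio divides the log₂ values themselves
(soma/neurite, per matched clone × replicate) — a ratio of logs, as the
analysis it reproduces prints it — and a difference-of-logs column is emitted
alongside because the ratio's scale depends on the arbitrary LFQ offset.

## Gene modules

Each member gene is z-scored across samples (n − 1 denominator); the module
score of a sample is the mean member z-score. Standardization is per gene
across samples — the per-sample alternative would remove exactly the genotype
contrasts the score exists to expose. Scores therefore sum to zero across
samples exactly (used as a numerical check at 10⁻¹⁰). Genes missing from the
matrix are dropped (warning below 50% coverage; error only when no member is
present); zero-variance genes are excluded with a warning.

## Statistics

The normality gate runs Shapiro–Wilk per group at α = 0.05; any failing,
undersized (n < 3) or degenerate group routes the comparison to the
nonparametric branch. η² = SS_between/SS_total for ANOVA;
η²_H = (H − k + 1)/(n − k) for Kruskal–Wallis (the H-based analogue).
Multiway ANOVA reports main effects only, with Type-I sequential sums of
squares on (near-)balanced designs. Dunn's z uses mean ranks with the
tie-corrected variance and Holm step-down adjustment. Fisher's overlap builds
the 2×2 table from set sizes, overlap and a user-supplied background size
(the background is a required input — there is no defensible default).
Bootstrap mean differences resample within groups with replacement and report
a percentile interval, deterministic under the seed.

## Synthetic data

The generators define the study conditions the tests run under. Plates:
384×384 px at 0.25 µm/px (a 96 µm field, matching a high-magnification
confocal field of view), 6 cells per well, 3 neurites per cell of mean length
60 µm with 30% branch probability, 3 technical wells per genotype plus one
negative-control well per plate. Puncta are isotropic Gaussian spots truncated
at their nominal diameter (drawn uniformly from 0.5–1.0 µm, the
diffraction-limited regime of synaptic puncta) so that on a noise-free
background the above-threshold footprint is exactly the rasterized disk of
that diameter — the recorded ground-truth diameter is that footprint's
equivalent-circular diameter, keeping generator and detector self-consistent.
Baseline densities are 4 puncta per 100 µm neurite and 4 per soma, sparse as
expected for day-7 immature neurons; genotype effects multiply per-compartment
densities (default homozygous-mutant condition: 3.3× neurite, 0.8× soma,
matching the direction and magnitude of the presynaptic-marker findings). The
background is Gaussian (mean 100, SD 10, arbitrary units) — acquisition noise
statistics are free parameters chosen to give realistic ~8:1 spot-to-noise
contrast. Negative-control wells carry the full background and structural
channels but no puncta-channel signal, which is the operational meaning of a
secondary-antibody-only control.

Calcium traces are baseline F₀ = 100 plus one difference-of-exponentials
transient (rise τ 0.5 s, decay τ 4 s — the kernel shape is a modeling choice;
its closed-form peak time validates the extractor) with per-ROI amplitudes
from a normal truncated at zero and white acquisition noise. The day-7 preset
plants group mean peak ΔF/F₀ of 1.222 (wild type) versus 1.383 (homozygous
mutant) at 40 ROIs per group. LFQ tables draw protein baselines from
N(25, 2²) in log₂ with within-protein SD 0.3 and left-censored missingness,
logistic in abundance (midpoint two between-protein SDs below the mean) —
the mechanism that makes the 70% filter meaningful; planted exclusives are
forced all-missing in the opposite compartment, and non-planted proteins keep
at least one detection per compartment so the planted sets are recoverable
exactly. Expression matrices are unit-variance noise with per-module mean
shifts; note that a +1 SD planted shift in half the samples appears as
1/√1.25 ≈ 0.89 on the z-score scale, because the shift itself inflates each
gene's cross-sample SD.

What the simulations do not emulate: optics (PSF, 3D stacks, spectral
bleed-through), photobleaching, uneven illumination, cell-density gradients,
real LFQ normalization artifacts, or correlated biological variability between
wells. Passing tests therefore demonstrate the correctness of the
quantification logic under controlled conditions, not robustness to every
artifact of real acquisitions.

## Problem sizes

Validation runs are sized for a single CPU: fold-change recovery uses 20
simulated plates per multiplier (ΔΔPC standard error ≈ 2–4%, comfortably
inside the 10% recovery criterion), detection metrics use a 4-well plate with
≥ 5× threshold spots, type-I error calibration uses 2,000 null simulations per
test, and the responder brute-force check uses 1,000 traces.

## Known limitations

Spot merging at high densities biases counts a few percent low (see above);
the moderated differential test is not implemented; soma segmentation assumes
roughly convex somata (the opening guard removes thin arms); skeleton length
carries a small positive corner bias; the pipeline treats wells as
exchangeable within a plate and does not model plate-order or edge effects.
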