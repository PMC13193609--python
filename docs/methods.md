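# Methods

`condensate-kit` implements the quantitative procedures used to characterize
polyphosphate (polyP)-dependent Hfq condensates ("H-bodies") in
nitrogen-starved *E. coli*, together with synthetic-data generators that make
every stage verifiable by parameter recovery.  This note documents the models,
their assumptions, the tunable parameters, and the numerical choices made
where the design was genuinely open.

## Single-molecule diffusion states (`trajectory_dynamics`)

**Per-track mobility.**  For tracks of at least 7 frames, the mean squared
displacement over lags k = 1..5 is fit by linear least squares to

    MSD(kτ) = 4·D·kτ + 4·σ²

where D (µm²/s) is the apparent diffusion coefficient, τ the frame interval
(default 20 ms, i.e. 50 Hz acquisition) and σ (µm) the localization error.  A
negative fitted slope is clamped to D = 0 and flagged rather than reported as
a negative mobility.

**Stable-focus detection.**  All localizations are summed into a composite
image (one count per pixel), normalized to [0, 1], and blob-detected with a
Laplacian-of-Gaussian detector (min_sigma = 3, max_sigma = 5, threshold =
0.1).  Normalization matters: the LoG threshold is scale-dependent and only
meaningful on a fixed intensity range.  Each blob is segmented into the
pixels within σ·√2 of its center (the standard 2-D blob-radius convention);
pixels claimed by two blobs go to the nearer center so regions stay disjoint.
A putative focus is kept only if at least 10 trajectories of at least 10
frames each have at least 70% of their localizations inside it — this rejects
transient density fluctuations and keeps only stably occupied regions.

**Overlap classification.**  A trajectory is "In" if every localization falls
inside a kept focus, "In/out" if between 25% and 99% do, and "Out" below 25%.

**Squared-displacement CDF mixture.**  Consecutive-frame squared
displacements r² from tracks of ≥ 4 frames are pooled and their empirical CDF
fit by bounded nonlinear least squares to

    P(r², τ) = 1 − Σᵢ αᵢ · exp(−r² / ((8/3)·Dᵢ·τ)),   Σαᵢ = 1

with two or three states.  The fit is unweighted, evaluated at every observed
r², with the weights constrained to the simplex via bounds plus a penalty on
Σα > 1, three seeded starts against local minima, and states reported in
increasing-D order (ties broken by larger weight).  The (8/3) exponent scale
is used exactly as printed in the source procedure; the standard 4·D·τ scale
of an ideal 2-D Brownian displacement law is available behind
`standard_factor=True`.  No localization-error term is added to the exponent.
Fits with two states within 5% in D are flagged degenerate — on
single-state input the optimizer may legitimately split the weight across two
near-identical components, which is why tests assert recovered *weight near
the true D* rather than individual α values in that limit.

**State fractions.**  With the full-pool three-state fit and a second
three-state fit on the In + In/out displacement subset,

    F_condensate = ((N_In + N_InOut) / N_total) · (α₁ + α₂)_subset
    F_free       = α₃ of the full fit      (the D₃ > 1 µm²/s free state)
    F_nucleoid   = 1 − F_free − F_condensate

with all counts being displacement counts, so the fractions are shares of the
analysed displacements.  The subset fit is unconstrained; consistency of its
D₃ with free diffusion is asserted post hoc (a warning is emitted when the
full-fit D₃ ≤ 1 µm²/s).

## In vivo focus quantitation (`focus_quant`)

Cell masks (an upstream segmentation product) are dilated by 4 px and
replaced by their convex hulls; contested pixels go to the cell with the
nearest original centroid.  The focus threshold is global per image:
median + 3.5·MAD over all pooled within-cell pixels, with the *raw* MAD (no
1.4826 normal-consistency factor).  Focal centers are local maxima on
8-connectivity (a plateau pixel qualifies if no neighbour is strictly
greater) strictly above the threshold; regions grow over supra-threshold
pixels by 4-connectivity, and are kept only with ≥ 3 px and ≥ 1 center.
Because the threshold is an affine function of the intensities, the whole
caller is equivariant under adding a constant to the image.

Focus/background ratios divide the mean intensity over a cell's focus pixels
by the mean over its remaining expanded-mask pixels (optionally log2); the
measured channel may differ from the channel in which foci were called,
which is how co-recruited proteins (e.g. degradosome components) are ratioed
over regions called in the Hfq channel.  Colocalization is the Spearman rank
correlation over within-cell pixels, summarized as the mean across cells per
imaging field; cells with a constant channel are excluded with a warning.
The same caller applied to mammalian cell masks is the P-body counting
primitive; count normalization to a control condition is a plain ratio.

FRAP traces, normalized to the mean of three pre-bleach frames with the
bleach frame at t = 0, are fit to the one-phase association
y(t) = base + (plateau − base)(1 − e^(−kt)); t½ = ln2/k, with 95% CIs from
the fit covariance and non-recovering traces pinned at the rate lower bound
and flagged.

## In vitro droplet pipeline (`droplet_quant`)

Segmentation: CLAHE (clip limit 0.01) → Gaussian blur (σ = 2 px) → Canny
(σ = 1) → morphological closing (disk radius 3) → hole filling; enclosed
regions ≥ 150 px become candidates.  The Canny hysteresis thresholds are
fixed at 0.1/0.3 on the CLAHE-normalized scale rather than derived from
intensity quantiles: quantile-automatic thresholds adapt to whatever contrast
is present and therefore hallucinate edges in featureless noise fields,
whereas droplet edges survive the blur at a fixed absolute contrast.  All
segmentation parameters are exposed in `SegmentationParams`.

Candidates must pass five shape filters: circularity (4πA/P²) ≥ 0.4,
major/minor axis ratio < 1.4, eccentricity < 0.8, solidity > 0.9, and extent
in (0.55, 0.95).  The perimeter is the weighted boundary-pixel perimeter of
`skimage.measure.regionprops`, which slightly depresses circularity for small
regions; filters are oracle-tested on rasterized primitives.

Phase calls: per-field droplet counts and total areas are log-scaled as
log10(x+1) (so zero-count fields are representable), pooled across *all*
fields of *all* conditions, and Otsu-thresholded once per metric.  A
condition is phase-separated if the median count or median area across its
fields exceeds the respective threshold.  When a pooled metric is degenerate
(all identical) its threshold is undefined and calls on it are negative with
a warning.  Note that inside an empty inter-mode gap every Otsu split is
equally optimal; equivalence with an exhaustive search is therefore asserted
on the achieved between-class variance and the induced partition, not on the
threshold coordinate.

## Rifampicin-chase decay (`rna_decay`)

Counts are normalized per sample to relative abundances (count / sample
total) and genomic features are then divided by the median relative abundance
of the spike-ins exceeding 5×10⁻⁴ relative abundance, giving per-cell-scale
abundances.  The procedure is invariant to per-sample count rescaling and
idempotent when spike-ins are carried through.

Per gene, y = a·exp(−t/b) is fit to all replicate-level observations by
bounded least squares ('dogbox', both parameters ≥ 0, initialized at
a = 0.001, b = 20); replicates enter as separate points to preserve degrees
of freedom for the b t-statistic (p from b/SE(b), df = n − 2).  Because the
stated initialization is far from data on an arbitrary abundance scale, a
steep decay can trap the optimizer on the b = 0 boundary; the fit then
restarts once from the observed t = 0 level, and the restart is accepted only
if it lowers the residual.  Genes with all-zero counts are skipped.

Genes are kept when Benjamini–Hochberg q < 0.1 and R² > 0.5 in both
genotypes.  The 5–65 min window is a reporting/classification window: fits
outside it are retained but flagged, not discarded.  Stability categories
compare the two genotypes' decay constants τ: stable-vs-unstable when τ > 65
min in one genotype and < 55 min in the other; directional (WT > mutant or
mutant > WT) when both are < 65 min and one exceeds the other by ≥ 10 min;
otherwise unclassified.  Genotype distributions are compared by the unpaired
two-sided Wilcoxon rank-sum test with the median shift reported as
(median_mut − median_WT)/median_WT.

## Untemplated poly(A) tails (`polya_tails`)

With the sequencing adapter adjacent to the read start, a 3′ A-tail appears
as a leading 'T' run on the stored read.  The default tail count is the
maximal uninterrupted leading-T run (a total-T mode exists but also counts
templated Ts).  Reads are assigned to the gene whose 3′-end window — 50 bp
upstream to 250 bp downstream of the 3′ end in transcription direction
(301 bases, strand-aware) — contains the read's tail-proximal mapped
coordinate; multi-window hits resolve to the nearest 3′ end.  This gene-level
window deliberately accepts operon-level ambiguity rather than depending on
a complete transcript annotation.

Per gene, tail lengths across the 2×2 design (genotype × starvation, four
replicates each) are fit by maximum-likelihood zero-inflated negative
binomial regression: one mean coefficient per condition (log link, no
intercept), a single shared zero-inflation logit and a single NB2
overdispersion α (var = µ + αµ²), capped at 500 optimizer iterations.  The
inflation/zero-count ridge is handled by multi-start over inflation
{0.05, 0.3, 0.6} with the best finite log-likelihood winning; all-zero genes
are reported as inflation 1 with unidentifiable means and flagged.  Condition
contrasts are Δ(mean tail) = exp(β_b) − exp(β_a) with a delta-method Wald
p-value from the coefficient covariance; transcriptome summaries are the
cumulative distributions of per-gene estimated means per condition.

## Enrichment statistics (`enrichment_stats`)

Effect sizes are split into equally populated rank-based quintiles with ties
broken by stable input order.  Term × bin enrichment uses the 2×2 odds ratio
with the small-sample estimator (+0.5 per cell), a matching Woolf CI, and a
Yates continuity-corrected chi-square p (the epitools `oddsratio.small` +
`chisq.test(correct=TRUE)` convention).  Gene-set overlaps are tested by
permutation: the query set is redrawn uniformly from the universe (1,000
draws by convention; tests scale to 200), overlaps with every reference set
and multi-way reference intersection are recomputed, and
p = (1 + #{null ≥ obs})/(n_perm + 1) — the add-one estimator never returns 0.
The one-sample proportion test is z = (k/n − p₀)/√(p₀(1−p₀)/n) with a normal
two-sided p and an exact-binomial option.

Two calibration caveats, verified empirically: (i) the Monte-Carlo p is
uniform only up to rank ties, so uniformity checks need a null configuration
with a wide overlap distribution; (ii) the normal proportion-test p tracks
the exact binomial closely in the bulk (z ≈ 1.5) but its *relative* error in
far tails diverges — the extreme-significance claims it supports are bounds,
not precise tail probabilities.

## Synthetic data (`synthetic_data`)

What the generators emulate, and what they do not:

- **Trajectories**: Brownian walks from the three-state mixture (defaults:
  fractions 0.25/0.30/0.45 condensate/nucleoid/free, D = 0.05/0.3/2.0 µm²/s,
  τ = 20 ms, localization noise σ = 0.03 µm/coordinate, geometric track
  lengths with median 10 frames).  Condensate confinement is a reflecting
  disk boundary — the simplest mechanism producing focus-overlapping slow
  tracks; the within-focus D is a free parameter defaulting to D₁.  No
  photophysics (blinking, bleaching) or EMCCD noise.
- **Cell images**: Gaussian spots on constant background with i.i.d. Gaussian
  noise, two channels with tunable correlation.  Real backgrounds are
  structured; passing tests show detector correctness, not robustness to
  autofluorescence gradients.
- **Droplet fields**: uniform-intensity disks/ellipses/squares on noise.
- **Decay counts**: per-gene a·exp(−t/b) expectations scaled by per-sample
  library factors, Poisson-sampled (the simplest noise under which the
  fitting stage must work; overdispersion is not simulated by default), plus
  24 log-spaced spike-in species (500–50,000 expected counts) scaled only by
  the library factor.  The spike ladder sits entirely above the 5×10⁻⁴
  qualifying cutoff at the default depth: without a stable rRNA-like bulk
  (deliberately not modelled) a spike straddling the cutoff would drift in
  and out of the qualifying set as the library total decays, shifting the
  qualifying median across timepoints and biasing fitted b upward by ~15%.
- **Poly(A) reads**: reads placed uniformly inside each gene's 3′ window with
  leading-T runs drawn from the gene/condition ZINB; the inner sequence
  avoids T so the run length is unambiguous by construction.  Adapter
  trimming and UMI structure are not modelled.

All generators are deterministic given their seed; every consumer of
randomness takes an explicit seed.

## Problem sizes in the standard checks

The recovery checks run at desk scale chosen for statistical adequacy:
5,000 pooled displacements for the direct three-state fit; 3,000 tracks
(~38,000 displacements) for the end-to-end state-fraction pipeline; 20 imaging
fields for focus precision/recall; 100 genes per decay constant in
{10, 20, 40, 60} min at ≥ 500 expected t = 0 counts; 10,000 reads per gene
(2,500 per condition) for ZINB recovery; 200 repetitions × 200 permutations
for the calibration check.  At these sizes the observed recovery errors sit
well inside the stated tolerances (α within ±0.05, D within ±20%, state
fractions within ±0.07, decay b median relative error ≤ 10%, ZINB means
within ±10% and inflation within ±0.05).

## Known limitations

- The (8/3) CDF exponent scale is implemented as printed without a derivation;
  comparisons against simulations using the standard 4Dτ law will show a
  proportional offset in fitted D (the weights α are unaffected).
- Focus-region segmentation from LoG blobs uses a disk of radius σ·√2; real
  condensates are not perfectly disk-shaped, and the classification of tracks
  skirting a focus edge inherits this convention.
- The ZINB fit shares one inflation and one dispersion across conditions by
  design; genuine condition-specific dropout is absorbed into the means.
- The decay simulator omits the stable rRNA bulk of real libraries, so the
  spike-in qualifying rule is only exercised in its stable regime (see above).
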