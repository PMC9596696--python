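# Methods

This note records the models, numerical choices and known limitations of
`seedgwas`, in the spirit of a statistical-software methods appendix. It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Silhouette geometry

A seed image is thresholded (Otsu by default; a fixed threshold is kept
for synthetic fixtures), reduced to its largest 8-connected component with
interior holes filled, and traced with the Moore-neighbour algorithm using
Jacob's stopping criterion. The boundary polygon runs through
*pixel centers*; pixel (row, col) maps to (x = col·s, y = row·s) for scale
s in mm/px, and orientation is normalised to a positive shoelace area.

**Staircase bias and smoothing.** The raw 8-connected trace is a staircase
whose length overestimates a smooth contour by roughly 5% (the classic
chain-code bias: a straight edge at angle θ is walked with axis and
diagonal steps totalling length cos θ + (√2−1) sin θ per unit). Because the
derived traits divide by the perimeter (Circ, Convexity, Shape), the
measurement path applies a circular 5-point moving average to the vertex
chain before measuring (`smooth_boundary`, the default in
`measure_image`). On a 5 mm disk rendered at 0.02 mm/px this brings the
perimeter error from ~5.4% to ~0.03% while moving the area by under 0.01
percentage points; the raw trace remains available and is what
`trace_boundary` returns.

**Primitive measures.** Area and Perim come from the (smoothed) polygon
itself; CHull/CArea from its convex hull; Feret from a rotating-calipers
walk over antipodal hull-vertex pairs (ties in distance broken toward the
direction with the smallest angle to the x-axis); Breadth as the hull's
projection extent perpendicular to the Feret direction; MinR/MaxR as the
minimum segment distance / maximum vertex distance from the area-weighted
centroid — MinR is deliberately the *inscribed circle centered at the
center of mass*, not the larger maximal inscribed circle; MBCRadius is the
radius of the minimal enclosing circle of the hull vertices.

**A conditioning caveat.** For silhouettes with blunt tips (superellipse
order n noticeably above 2) the maximal-diameter pair is nearly degenerate:
competing vertex pairs differ by ~0.1% of the diameter, so pixelisation can
tilt the estimated Feret axis by a few degrees and move
Breadth-perpendicular-to-Feret by ~2%. Feret itself is stable; the
rotation-invariance guarantee (<1% across rotations) holds for shapes with
a well-separated diameter, such as ellipses and typical elongated grains.

## Trait formulas

The 34 traits follow the standard silhouette-descriptor formulas listed in
the README. Two circularity conventions exist in the trait-table
literature: the dimensionless 4πA/P² (≤ 1 by the isoperimetric inequality)
and an area-proportional 4πA whose *population mean* is 4π times the mean
area. Both are implemented (`circ_variant="table5" | "scaled"`); the
dimensionless form is the default, and `mean_consistency` exposes the
linear-in-area identities (4π·Ā, Ā/π) used to cross-check published
population means. PerEquivD is implemented exactly as the published tables
use it (Area/π — an area-scaled quantity despite its name, confirmed by
the printed means). Thousand-kernel weight is a weighed, per-accession
quantity joined onto the image-derived table, never computed from images.

## Phenotype statistics

The combined ANOVA assumes a *balanced* genotype × environment × replicate
layout with replicates nested in environments (incomplete-block designs
are out of scope; an alpha-lattice trial is treated as complete blocks, a
documented simplification). Environments are fixed and genotypes random,
which fixes the denominators: F_Gen = MS_Gen/MS_G×E,
F_G×E = MS_G×E/MS_Err, F_Env = MS_Env/MS_Rep(Env),
F_Rep(Env) = MS_Rep(Env)/MS_Err. Components follow the EMS equations
(σ²_e = MS_Err, σ²_ge = (MS_G×E − MS_Err)/r, σ²_g = (MS_Gen − MS_G×E)/(er);
negatives clamped to zero and flagged), and entry-mean heritability is
H² = σ²_g/(σ²_g + σ²_ge/e + σ²_e/(er)). Because published tables sometimes
print H² per environment, a within-environment variant
σ²_g/(σ²_g + σ²_e/r) from the one-environment Gen × Rep ANOVA is also
provided. Correlations are pairwise-complete Pearson r with t-based
two-sided p-values (n−2 df); CV uses the sample standard deviation;
quartiles use linear interpolation.

## Population genetics

LD is the composite estimator for unphased genotypes: squared Pearson
correlation of dosage vectors, with significance from χ² = n·r² (1 df) —
a documented stand-in for the exact procedures inside standard GWAS GUIs,
calibrated by the test suite at the nominal level. Distances are genetic
(cM); physical positions are not modelled. The decay curve is a tricube
local-*linear* regression evaluated on a distance grid; the bandwidth at
each grid point is the distance to the ⌈frac·n⌉-th nearest observation,
so globally linear data are reproduced exactly, and the decay distance is
the first grid crossing below a configurable r² threshold (default 0.1).
Kinship is VanRaden's ZZ′/(2Σp(1−p)) with mean-imputed missing calls;
PCA is the eigendecomposition of K with percent variance eigenvalue/trace.
k-means on the leading PC scores (fixed seed, 10 restarts) is a labelled
*proxy* for Bayesian admixture grouping, not a replacement. Neighbor
joining uses the Saitou–Nei algorithm with negative branch lengths clamped
to zero; the default tree distance is 1 − K_ij/max(K), a pragmatic choice
since kinship is the quantity the rest of the pipeline already computes.

## Mixed-model scan

The null model is fitted by REML after one spectral decomposition of K:
with K = U S U′ and δ = σ²_e/σ²_g, the rotated residual weights are
S_i + δ and the profiled restricted likelihood is searched over
log δ ∈ [−10, 10] — a 61-point grid bracket followed by bounded Brent
refinement to 1e-6 (the grid guards against local optima in the profile).
Per-marker tests are generalised least squares in the rotated space with a
1-df Wald F. `p3d=True` (default) reuses the null δ for every marker and
is fully vectorised: covariates are projected out once by QR and all
marker effects, standard errors and F statistics follow from column-wise
inner products. `p3d=False` re-optimises δ per marker (exact, slow,
intended for small marker sets). "LOD" language in multi-locus tools is a
likelihood-ratio quantity; this package reports −log10 p, which is the
comparable single-marker scale. Default structure covariates are the first
3 PC score vectors, matching a 3-subpopulation panel.

The marker×environment interaction scan stacks per-environment phenotypes,
rotates each block by U with a *shared* δ (geometric mean of the
per-environment REML estimates) and F-tests the interaction columns
(sum-to-zero environment coding, e−1 df). It is a fixed-effect analogue of
multi-environment QTN models — useful for detecting sign-flips or strong
effect heterogeneity — and makes no attempt at the variance-component
decomposition of dedicated multi-locus QEI software.

## Synthetic data: what it emulates and what it does not

The generators define the study conditions under which every guarantee is
tested.

* **Silhouettes** are superellipses |x/a|ⁿ + |y/b|ⁿ ≤ 1 (default a=3.4,
  b=1.6 mm — an elongated wheat-grain outline), rendered bright-on-dark at
  0.02 mm/px (≈800 dpi class resolution) with optional Gaussian intensity
  noise. Closed-form area and, for n ≥ 1, Feret = 2·max(a,b) and
  Breadth = 2·min(a,b) give analytic ground truth. Real seed images add
  texture, shading, crease shadows and touching seeds — none of which are
  emulated, so passing tests certify the geometry pipeline, not robustness
  to photographic artefacts.
* **Genotypes**: 21 wheat chromosomes (A/B/D subgenomes), default 300
  accessions in K=3 subpopulations (the structure reported for Iranian
  wheat panels), Balding–Nichols subpopulation frequencies at F_ST
  defaults of 0.2, and LD from a Gaussian-copula AR(1) along each
  chromosome with latent correlation exp(−d/L), L = 3 cM — chosen so that
  most significant pairs fall within 10 cM, the pattern reported for such
  panels. This produces a monotone expected r² decay but not the blocky
  haplotype mosaics, allele-frequency spectra or imputation artefacts of
  real GBS data.
* **Phenotypes**: y_ijk = μ_j + Σ_q a_q x_iq + g_i + (gE)_ij + rep_k(j) +
  ε_ijk with e=2 environments and r=2 replicates (a two-repeat,
  two-regime trial). Defaults: focal-trait (seed volume) means 38.92 /
  28.38 mm³ for the favourable and stressed environment, target entry-mean
  H² = 0.8 (σ²_g derived from σ²_ge=2, σ²_rep=0.5, σ²_e=3 to hit the
  target exactly in expectation), and TKW coupled to volume within each
  environment at correlation 0.8 (means 42.1 / 28.2 g) — mirroring the
  strong volume–weight correlations such trials report. Incomplete-block
  (alpha-lattice) structure is not simulated.

All generators are bit-reproducible from one integer seed per call.

## Problem sizes and tolerances

The test suite and acceptance script run at desk scale, chosen to make the
statistical assertions sharp: 20 random convex polygons for the
calipers-vs-brute-force check (1e-9 agreement); 0.02 mm/px rasters for the
closed-form geometry checks (≤1.5%); ~10⁵ null marker tests for type-I
calibration at α=0.01 (±0.005); 50 scans of n=300 × m≈2000 panels for
planted-QTN power (≥80% top-hit rate with the QTN at 10% of variance and a
30% polygenic background); 100 replicates for H² recovery (median absolute
error ≤0.08 at target 0.8). REML convergence tolerance is 1e-6 on log δ;
eigenvalues of K are clipped at zero; monomorphic markers are excluded
from kinship, LD and scans with flags rather than silently.

## Known limitations

* One seed per image; no touching-seed separation, colour calibration or
  lens-distortion handling.
* Balanced designs only in the ANOVA; no mixed-model adjusted means.
* The χ²=n·r² LD significance and the k-means admixture proxy are
  simplifications and labelled as such.
* The QEI test is fixed-effect; multi-locus shrinkage methods are out of
  scope.
* Breadth is ill-conditioned for blunt-tipped silhouettes (see above).
* The irrigation module reproduces scheduling arithmetic; it is not an
  evapotranspiration model (no Penman–Monteith, no weather ingestion).
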