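# Methods

This note documents the models, numerical choices and limitations behind
`surfwave`.  It is written for users who want to know what the package
computes and what the passing test suite does and does not demonstrate.

## Surface measures on corresponded meshes

All geometry is carried by closed, consistently oriented, genus-0 triangle
meshes with vertices in millimetres.  Topology is validated on load: every
directed edge must appear exactly once (closedness + orientation), the
Euler characteristic must be 2, and zero-area faces are rejected rather
than repaired.

Correspondence between a subject surface and the template is assumed given
by shared mesh topology: subject vertex k corresponds to template vertex k.
In a clinical setting this correspondence is established by nonlinear
registration of each subject to the template; here the synthetic generator
produces it by construction.  Rigid alignment (rotation + translation, no
scaling) is the closed-form orthogonal-Procrustes/Kabsch fit over
corresponded vertices.

The **signed distance field** at template vertex k is the displacement of
the corresponded subject vertex projected on the template's outward unit
normal (area-weighted average of incident face normals, globally oriented
away from the centroid — adequate for the star-shaped surfaces targeted
here).  Positive values are protrusions, negative indentations.  A
`nearest_point` variant measures the unsigned distance to the nearest point
of the subject surface (exact point-to-triangle distance with KD-tree
candidate pruning; pruning can widen its search but never changes the
result) and takes its sign from the same normal test; the two modes agree
to within ~10% of the amplitude on smooth, low-amplitude deformations and
the choice between them is a user decision, as surface-based studies report
both conventions.  **Thickness** is the same nearest-distance kernel
applied from an outer to an inner surface, non-negative by construction.

## Conformal spherical parameterization

The template is mapped to the unit sphere in two stages.

1. *Planar flattening.*  The cotangent-weight FEM stiffness matrix
   discretizes the Laplace–Beltrami operator.  The derivative-of-Dirac
   (dipole) source at the puncture vertex is discretized through the
   hat-function gradients on one face incident to the puncture — three
   equal-and-opposite complex loads on the puncture and two adjacent 1-ring
   vertices.  One sparse symmetric solve (the constant mode pinned at the
   vertex farthest from the puncture) yields complex planar coordinates;
   inverse stereographic projection takes them to the sphere, the far field
   landing at the north pole.  This map is bijective in practice but
   carries O(h) angle distortion from the linear FEM discretization.
2. *Harmonic refinement.*  Starting from that initialization, the embedding
   is relaxed to the discrete harmonic map — which for genus-0 sphere
   targets is the conformal map — by Jacobi-scaled tangential descent of
   the cotangent harmonic energy, keeping vertices on the sphere.  The
   conformal group's degeneracy (Möbius transformations can drain the
   energy by concentrating all vertices near a point) is controlled by
   periodic Möbius re-centering.

Normalization makes the result reproducible: sphere inversions are applied
until the area-weighted centroid of the mapped vertices is at the origin
(tolerance 1e-8, at most 100 inversions, damped), and the sphere is rotated
so the puncture sits exactly at the north pole.  On an icosphere input the
parameterization reproduces the identity up to ~1e-3 rad mean corner-angle
change with zero flipped triangles; on a 10% radial bump it beats central
projection on both mean and 95th-percentile angle distortion.  Angle
distortion is reported per triangle as the maximum absolute corner-angle
change between the original and spherical embeddings.

Fields are transferred to the wavelet icosphere by locating each icosphere
vertex in the spherical triangulation (central-projection barycentric
coordinates; KD-tree candidates with exhaustive fallback, so acceleration
cannot change the result) and interpolating barycentrically (weights sum to
1); a nearest-vertex mode exists for comparison.  Vertices not covered by
any triangle — the signature of flipped triangles — raise an error listing
the offending vertices.

## Lifting-scheme spherical wavelets

The icosphere hierarchy stores, per level, the mesh, the two parent-edge
endpoints of every vertex introduced by subdivision, prediction stencils
and barycentric vertex areas.  Analysis proceeds from the finest level J
down to 0; at each step the "odd" vertices are predicted from the coarse
vertices, residuals become the wavelet coefficients γ, and the update step
adds `I_{j+1,m} / (2 I_{j,i})` times each residual to its two parents,
where the `I` are the integrals of the interpolating scaling functions
(vertex areas at the finest level, propagated through the two-scale
relation).  This choice gives every wavelet a vanishing integral, so the
area-weighted mean of the field is preserved exactly at every level, and
both steps invert exactly (reconstruction error ~1e-16 relative).

Stencils: the linear scheme averages the two parents; the butterfly scheme
uses the standard 8-point weights (parents 1/2, wings 1/8, outer vertices
−1/16) with Zorin's modified-butterfly ring weights around the twelve
valence-5 vertices (ring weight `s_q = (1/4 + cos(2πq/K) + cos(4πq/K)/2)/K`,
center 3/4).  A caveat documented here deliberately: on a
midpoint-projected icosphere the vertex positions deviate from a regular
parametrization at O(h²), so the butterfly's cubic precision (verified on a
planar lattice in the tests) degrades to roughly second order on the
sphere.  Empirically its detail coefficients on a radially-linear field are
~3.3× smaller than the linear scheme's (L2, J=4); the regression test
freezes the bound at 0.4.

Coefficient order is fixed by icosphere vertex index; the flat
serialization is `[λ₀, γ₀, γ₁, …]`.  Default finest level J = 4 (2,562
vertices); the default analysis level is 2 (162 coefficients per region).

## Features, selection, nuisance control

Feature vectors concatenate level-j scaling coefficients across regions in
fixed region order, with per-feature provenance (region, level, vertex).
Selection is a per-coefficient two-sample test between the two diagnosed
groups — Welch's t by default (Student and Mann–Whitney available) — keeping
p < α with α = 1e-7 by default; at such thresholds no further
multiple-testing correction is applied.  Zero-variance coefficients follow
a documented convention: p = 1 if both groups are constant and equal, p = 0
if constant and different.

Age and sex effects are removed by OLS on [1, age, sex(M=0,F=1)], age linear
only.  The regression is fit on the training cohort and its coefficients
are applied to held-out subjects, so cross-validation folds never estimate
nuisance effects from test data.  Covariates that make the design
rank-deficient (e.g. sex in a single-sex cohort) are dropped with a logged
warning.

## Clustering, labeling, classification

Agglomerative clustering is greedy: at each step the pair of clusters
minimizing the criterion is merged.  Ward's criterion is implemented
directly as the ESS increase, `|A||B|/(|A|+|B|) · ||mean(A)−mean(B)||²`
(so two singletons merge at height ‖x−y‖²/2 — note this is the raw ESS
increase, not the square-root convention some libraries report); average
linkage is the mean pairwise Euclidean distance.  The standardized
Euclidean metric divides each feature by its cohort standard deviation
first (used when regions on different scales are concatenated);
zero-variance features are dropped from that metric with a warning.  Exact
criterion ties are broken by the lexicographically smallest cluster-id
pair, deterministically.  Merge sequences and heights are verified against
a brute-force greedy oracle on all cohorts with n ≤ 8.

The diagnostic cut removes the root merge (a k-group cut is provided for
the four-cell synthetic analysis).  Groups get the majority diagnosis of
their members, ties broken toward the lexicographically first label with a
logged warning; group means and, for the standardized metric, the
training-set scales are frozen into the model.  A held-out subject gets the
label of the nearer group mean (training scales applied); exact distance
ties go to the first-listed group with a tie flag.

## Cross-validation and adjusted rates

`loo` retrains the entire procedure — residualization, selection,
clustering, labeling — on the n−1 remaining subjects for every fold.
`split_half` draws stratified halves (⌈n/2⌉/⌊n/2⌋ per class), trains on one
half, classifies the other, and additionally runs LOO inside each of the 2
× n_splits half-cohorts.  The adjusted rate per class is
`LOO + (mean split-half − mean LOO-on-split)`, clipped into [0, 1] with a
flag (the raw formula can leave the interval).  Sensitivity and specificity
are 1 minus the adjusted rates of the patient and comparison classes;
PPV = TP/(TP+FP) with TP = sensitivity·n_patient, FP =
(1−specificity)·n_comparison.  Printed-table reproduction uses decimal
half-up rounding, matching how such tables are conventionally rounded.
For three classes, an iterative two-way strategy first separates the
declared merged pair from the third class, then separates the pair with an
independently selected feature set; both stages run inside the per-subject
LOO loop.  A mean-based selection test can only drive stage 1 when both
merged classes deviate from the third in the same direction — the regime
the strategy is intended for.

## Synthetic study designs

`make_template` builds a star-shaped, origin-centered template: an
icosphere scaled to radius 80 mm plus a smooth random radial field (real
spherical harmonics of degrees 2–4, rms = `bumpiness`, default 3 mm).  At
level 4 the mean edge length is ~6 mm, comfortably below the 15-mm
deformation footprint.

`add_deformation` displaces vertices within geodesic radius width/2
(default width 15 mm) of a site radially by amplitude × a C¹ cosine taper;
protrusions outward, indentations inward.  The deformation geometry is
measured from a fixed reference center (the origin) and the nominal radius
is estimated from the far hemisphere only, so applying the opposite
polarity restores the input exactly — a useful algebraic property for
testing.  The deformation **depth** is not fixed by the width; the default
amplitude is 7.5 mm (half the width, the depth of a pressed-in hemisphere)
and is exposed for sweeps.  Sites A and B are fixed unit directions ~87° of
arc apart.  `rigid_place` applies a uniform random rotation about the
centroid plus a ±20 mm/axis translation (`seed=None` reserved for the
identity).

`individual_variation` adds a smooth correlated radial field (spherical
harmonics up to degree ≈ 180°/scale, unit rms scaled to the requested
amplitude).  Two amplitudes play different roles.  As a *raw anatomy*
stand-in, 2 mm rms at 30° scale is realistic and is what the generator
example tests.  The *cohort default*, however, is 0.25 mm rms: cohort
fields emulate measurements taken **after** each subject has been spatially
normalized to the template, where nonlinear registration has absorbed gross
anatomical differences and what survives is a smooth, sub-millimetre
residual.  This distinction matters quantitatively: the level-2 coefficient
response to a 15-mm, 7.5-mm-deep bump is only ~1.5–3 mm (the bump is
narrower than the level-2 vertex spacing, and the interpolating transform
samples it where a coarse vertex happens to fall), so with 2 mm of
surviving noise no coefficient can reach p < 1e-7 at n = 10 per group,
whereas with post-normalization residuals the published regime reproduces:
level-2 coefficients recover the polarity groups with 0–1 misassignments
per 20, and level-0 coefficients — where the deformation response (~0.1 mm)
is buried under the smooth residual variability — cluster by individual
anatomy instead and perform poorly.

Cohorts are generated from a `numpy SeedSequence` tree spawned from the
cohort seed (template, covariates, per-subject variation and placement all
on named substreams), making datasets bit-reproducible from (spec, seed).
Demographics are placeholders (ages uniform 20–50, balanced sexes) unless
an age effect is injected explicitly for residualization tests.

## Pipeline defaults and problem sizes

`PipelineConfig` defaults: finest level J=4, analysis level 2, linear
lifted scheme, Euclidean metric, Ward linkage, α=1e-7, 10 splits.  The
conformal parameterization and the resampling operator belong to the
template and are computed once per cohort; the default puncture maximizes
the minimal arc distance to the deformation sites so the pole's distortion
stays away from the regions of interest.

The shipped experiments use the published design sizes: 40 surfaces (10 per
site × polarity cell) for the single-template experiment, evaluated over 20
seeds in the tests; 20 distinct individuals (10 per polarity at one site)
for the multi-individual experiment; 100 repetitions for the null
(label-shuffled) checks with LOO evaluated on a 40-repetition subset.
These sizes keep the full suite at a few minutes on one CPU while leaving
the acceptance margins wide.

## What passing tests show — and what they do not

The synthetic cohorts validate the machinery end to end (correspondence →
measures → conformal transfer → wavelets → selection → clustering →
validation) under known ground truth, including the published qualitative
contrast between analysis resolutions.  They do not emulate folded cortical
anatomy, segmentation or registration error structure, scanner effects, or
disease-specific morphology; real-data performance claims cannot be made
from them.  The clinical comparisons reported alongside the original method
are represented here only through their printed rate arithmetic (adjusted
rates, sensitivity/specificity, PPV), since no imaging data are available.

Other known limitations: the conformal map's accuracy is bounded by the
discrete harmonic approximation (refinement tolerance 1e-10, max 1500
iterations); the butterfly scheme's vanishing-moment advantage is reduced
on geodesic grids (see above); hierarchical clustering is greedy and can
hit local optima on ambiguous cohorts; and `add_deformation` assumes a
star-shaped surface about its reference center.
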