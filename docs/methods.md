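# Methods

`epimorph` implements a single-cell morphometric and mechanical analysis of
planar epithelial sheets: per-cell apical morphometrics, Bayesian force
inference, joint spatial PCA (jsPCA) across samples, Gaussian-mixture
clustering with cross-condition transfer, and the accompanying spatial
statistics.  A synthetic-epithelium generator emulating the dorsal
pericardial wall (DPW) of the early mouse embryo provides ground-truth
mechanics and region labels, so every stage of the pipeline is testable
without imaging data.  This note records the models, the parameters that
matter, the numerical choices, and what the synthetic validation does and
does not establish.

## Coordinate and angle conventions

x is the embryonic left–right (LR) axis, y the anterior–posterior (AP) axis
with y increasing posteriorly (arterial pole at low y, venous pole at high
y); positions are in µm.  Cell orientation θ and principal stress direction
ϑ₁ are axial (mod-180°) angles stored in (−90°, 90°] with 0° along the LR
axis and 90° along the AP axis.  Nucleus→Golgi polarity is directional, in
(−180°, 180°].

For the multivariate analysis the two angle columns are re-referenced to the
AP axis, wrap(θ − 90°), before standardization (configuration
`angle_reference="ap"`; `"lr"` keeps the stored convention).  The reason is
the axial wrap: an AP-oriented cell population straddles ±90° in the
LR-referenced convention, which makes plain numeric averages and 1-D mixture
components meaningless for exactly the cell population of greatest interest.
With AP-referenced angles the three DPW populations sit near −45°, +45° and
0°, all far from the wrap, and a posterior cluster has a near-zero raw-scale
signature mean.  Cluster signatures additionally report axial circular means
and SDs for angle columns, since plain moments depend on the reference
choice.

## Synthetic epithelium (forward model)

**Geometry.**  Cells are a Lloyd-relaxed Voronoi tessellation of a
rectangle (default 300 × 300 µm) with a semicircular notch (radius 60 µm) on
the anterior edge standing in for the inferior outflow tract; the notch is
cosmetic and configurable.  Each of `n_cells` seed points yields one clipped
cell; sliver edges left by clipping are merged at generation time.  Defaults:
`n_cells = 1600` (one cell ≈ 52 µm², matching mid-gestation DPW apical
areas); validation runs use 300–800 cells per sample to keep simulations
small — a problem-size choice, with the domain unchanged.

**Region pattern.**  Three regions partition the sheet: bilateral anterior
domains targeting ±45° orientation and a posterior band (posterior 40% of
the height) targeting 90° (the AP axis), with the posterior region extending
anteriorly along the midline as a tongue (half-width 25 µm) between the two
anterior populations — the layout of AP-oriented cells reaching the midline
between bilateral anterior populations that converge on the outflow tract.
Labels are assigned by cell centroid, boundary-inclusive in listing order.

**Tissue-scale stretch.**  Regional cell elongation is imposed the way the
embryo does it — by tissue-scale deformation held at the sheet margin —
rather than by per-cell prescriptions.  Two fold-free stages warp the mesh:

1. an RK4-integrated smooth velocity field (a diffeomorphism by
   construction) blending a uniform area-preserving scaling diag(a, 1/a) in
   the anterior domains, an area-preserving AP stretch (factor 2.0) in the
   posterior band, and an x-compression (2.0) with mild AP elongation (1.6)
   in the midline tongue;
2. a closed-form vertical shear y += k·S(x − xc) applied outside the tongue.
   x never changes and the shift is y-independent, so this map cannot fold.
   Solving Shear(k)∘diag(a, 1/a) for a principal direction of exactly ±45°
   with axis ratio s² gives k = (s⁴−1)/(s⁴+1) and a = (1−k²)^(−1/4); the
   default anterior stretch is s = 1.8.  Posterior cells, already
   AP-stretched, end a few degrees off 90° laterally — a fan around the
   venous pole.

Transition widths (tongue shoulder ≈ 8 µm, anterior/posterior border 10 µm)
are of order one cell diameter; cells inside them are genuinely intermediate
in orientation, which bounds how sharply any downstream classifier can match
the geometric ground truth.

**Mechanics.**  Edge tensions are log-normal with mean 1 and CV
`base_cv = 0.2` (junctional tension variability of order 20% is typical for
early epithelia), multiplied by an alignment factor 1 + g·cos²(β − α) for an
edge at axial angle β in a region with target α (g = 1.0 posterior,
0.6 anterior).  Edges aligned with the regional axis are the tense ones;
with the margin held, they carry the excess stress, so the inferred
principal stress direction follows the target and the posterior band is the
most anisotropic.  Cell pressures are drawn as small zero-mean perturbations
(SD 0.02, clipped at ±0.05).  Gauges: mean tension 1, mean pressure 0.

**Relaxation.**  The sheet is driven to static force balance under the
standard tension + area-elasticity vertex model,
E = Σ_j T_j ℓ_j + (K/2) Σ_i (A_i − A₀_i)², with K = 1/⟨A⟩ and preferred
areas A₀ chosen so the drawn pressures emerge at the start
(P_i = −K(A_i − A₀_i)); A₀ is floored at 40% of the median area so crushed
cells push back rather than degenerate.  A constant-pressure forward model
is not usable here: its energy is unbounded below (area grows quadratically
with vertex excursions, tension cost only linearly), whereas the
area-elastic energy is coercive and the realized pressures are recovered
exactly from the converged areas.  Boundary vertices are anchored to their
warped positions by stiff springs (5 force units/µm) standing in for the
surrounding tissue and carry no balance requirement; interior vertices are
minimized with L-BFGS, alternating with the topology moves of epithelial
mechanics — T1-type collapse of junctions driven below 2% of the median edge
length (rosette formation) and T2 extrusion of vanishing triangles — and
finished with a damped force-descent polish whose accepted steps have
non-increasing residual.  Cells that converge into twisted outlines (rare,
at the sheared lateral margin) have their anchors released and are relaxed
again; the few random tessellations that still fail are discarded and
regenerated from a deterministic seed offset.  The returned ground truth
carries the realized tensions and pressures, re-gauged (joint scaling and a
constant pressure shift leave every interior balance untouched); the default
residual tolerance is 1e−4 in units of the mean tension, per vertex.

**Negative control.**  `randomize=True` permutes the region labels (with
their orientation targets) across cells and omits the coherent tissue-scale
stretch: label proportions are kept, all spatial structure is destroyed.

## Morphometrics

Area and perimeter use the shoelace formula and edge-length sums; the
orientation and eccentricity come from the closed-form second-order area
moments of the polygon (per-edge triangle decomposition): θ is the principal
axis of the moment tensor and e = √(1 − (b/a)²) from the moment-equivalent
ellipse semi-axes.  This is mesh-native and resolution-independent; the
eccentricity of a w×ℓ rectangle is √(1 − (w/ℓ)²) and regular polygons give
0.  Neighbor counts use the shared-mesh-edge relation.  Moment-isotropic
cells have undefined orientation and report 0°.

## Force inference

The straight-edge balance operator A has two rows (x, y) per interior
vertex: Σ_j T_j û_j + Σ_i P_i ∂A_i/∂p = 0 (the pressure term is the
lever-arm form P·n̂·ℓ/2 per incident cell edge).  Unknowns x = (T, P) are
estimated by minimizing ‖Ax‖² + μ‖x − x₀‖²_B with prior centers T₀ = 1,
P₀ = 0.  The pressure block needs an explicit prior because a constant
pressure shift lies in the null space of the interior-vertex operator.  μ is
selected on a log grid (10⁻⁶…10^1.0) by maximizing the marginal likelihood;
with σ̂² profiled out this is the minimization of
N·log S(μ) + log det(AᵀA + μB) − M·log μ, computed via sparse LU; ties break
toward the larger μ (stronger prior).  Gauges are applied post hoc (tensions
rescaled to mean 1, pressures shifted to mean 0).

Edges whose two endpoints are both on the sheet boundary appear in no
balance equation and are unidentifiable in principle; recovery statistics
are therefore reported over the mechanically constrained edges (at least one
free endpoint).  On plain equilibrated sheets (300 cells, tension CV 0.2)
tension recovery is Pearson r ≈ 0.91–0.94 and pressure recovery r ≈
0.92–0.97 across seeds.  Under the strongly stretched DPW pattern the
balance system is closer to degenerate (junction angles approach collinear)
and tension recovery degrades, while the derived stress *directions* remain
accurate — the quantity the downstream analysis uses.

Per-cell stress is the Batchelor average
σ_i = −P_i I + (1/2A_i) Σ_{j∈i} T_j (ℓ_j⊗ℓ_j)/|ℓ_j| with λ₁ ≥ λ₂, principal
direction ϑ₁ and anisotropy ratio r = λ₂/λ₁ (near 1 isotropic, near 0
anisotropic; classification threshold r < 0.3).  r is reported only for
λ₁ > 0 (NaN otherwise, flagged, imputed at the sample median in the analysis
matrix); isotropic tensors report ϑ₁ = 0 with a degeneracy flag.

## Spatial statistics and jsPCA

The neighbor matrix W is the shared-edge relation; L is its row-normalized
form.  Moran's index of a centered vector is MI = zᵀLz/zᵀz.  Feature
matrices are standardized per sample (population SD).  The per-sample
product matrix M_k = X_kᵀ(L_k + L_kᵀ)X_k / (2n_k) is the covariance weighted
by spatial autocorrelation; for L = I it reduces to the covariance, the
classical-PCA limit.

Because M_k depends on each sample's own adjacency, the samples are combined
by approximate joint diagonalization: Jacobi 2×2 rotations over a fixed
lexicographic pair order, each rotation the closed-form optimum for its pair
(principal eigenvector of the accumulated [α, β] outer products with
α = M_ii − M_jj, β = 2M_ij), swept until the joint off-diagonal criterion
improves by < 1e−12.  Components are ranked by the mean of diag(VᵀM_kV)
across samples (the aggregation for K > 1 is unspecified in the underlying
method; mean is the default, median and min are available) and each
component is sign-fixed so its orientation loading is ≥ 0.  For K = 1 the
procedure reduces to the eigendecomposition of M₁.

## Clustering

A 1-D Gaussian mixture (free per-component variances, variance floor 1e−6,
EM with 20 seeded restarts) is fit on the pooled jsPC1 scores of the
training cohort; k is selected by minimizing AIC = 2(3k−1) − 2 log L (ties
to the smaller k).  Components are labeled 1..k by ascending mean.  Cells
from other conditions are standardized with their own per-sample parameters,
projected on the training jsPC1, and assigned by maximum posterior under the
frozen model (equidistant ties to the lower-mean component).  The
AP-symmetrized variant replaces orientation by its axial distance to the AP
axis and stress direction by |ϑ₁| (both in [0, 90]) and runs the full
jsPCA → GMM(k = 2) pipeline, merging mirror-image left/right populations.

## Group statistics

The AP coordinate is normalized per sample as y_norm = −2(y − y_mid)/(Y_max
− Y_min) with y_mid the midrange, giving exactly [−1, 1] with +1 at the
arterial pole; the midrange (not the mean) is the centering that achieves
the unit range.  Cluster positions are compared with one-sided Mann–Whitney
U tests: full enumeration of group assignments (tie-aware midranks,
inclusive tail P(U ≥ u)) for n_A + n_B ≤ 16, otherwise the normal
approximation with tie correction.  Deviations from AP symmetry use the
one-sample Wilcoxon signed-rank test against 0 (zeros dropped; exact
enumeration of the 2ⁿ sign assignments for n ≤ 20, otherwise the normal
approximation), applied to subsets such as vertical cells (within 10° of the
AP axis), horizontal cells (within 10° of the LR axis) and anisotropic cells
(r < 0.3).  Raw p-values are reported, with no multiplicity correction.

## What the synthetic validation shows — and what it does not

Passing tests establish that each stage implements its stated computation
(against closed forms, independent brute-force oracles, enumerations and
permutation nulls) and that the full pipeline recovers a planted regional
organization end to end.  The generator emulates regional orientation
patterns, stress anisotropy, mechanical equilibrium and multi-sample
variability; it does not emulate segmentation errors, curved junctions,
3-D surface projection artifacts, cell divisions, or intercellular
correlation structures beyond the mechanics, so quantitative performance on
real segmentations (in particular force-inference accuracy under curvature)
is not implied.

A structural limit worth stating: the three regional populations sit 45°
apart in orientation while a mechanically self-consistent equilibrium — with
genuine transition zones at region interfaces, T1/T2 topology noise and
equilibrium shape fluctuations — leaves within-region orientation scatter of
roughly ±20–25°, comparable to the ±20–29° spread of the corresponding real
cluster signatures.  The Bayes error of a 1-D three-component mixture at
that separation-to-scatter ratio is of order 10%, which caps the achievable
agreement between feature-space clusters and geometric region labels at an
adjusted Rand index around 0.7 (the acceptance run reports ≈ 0.73 at six
samples of 800 cells, and the index saturates rather than improves with
larger cohorts); pushing the synthetic tissue to be substantially more
ordered than the real one would make the test easier but the testbed less
faithful.  The cluster maps, posterior enrichment statistics and loadings
are robust well before the ARI ceiling is reached.

## Determinism

Every stochastic operation takes an explicit seed; sample seeds, mechanics
seeds and GMM restarts are all derived from the pipeline seed.  Rerunning a
persisted configuration reproduces every artifact bit-identically (the
output manifest records SHA-256 hashes; figure metadata is stripped of
timestamps).
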