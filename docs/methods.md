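# Methods

`atriashape` analyses the shape of the left-atrial (LA) body — pulmonary
veins and appendage excluded — as a smooth closed surface, and asks which
scalar descriptors of that surface separate patients whose atrial
fibrillation recurs after catheter ablation from those whose does not.
This note records the models, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## Surface representation

Each anatomy is a closed C1 surface assembled from bicubic Hermite
patches. A node carries 12 degrees of freedom (DOF): position (3) and
three derivative carriers (first parametric derivatives along the two
chart directions plus the mixed partial, 3 components each). The
standard template is a UV-sphere of radius 20 mm with 12 longitudinal
segments and 11 latitude rings: 134 nodes, 144 faces (120 quads, 24 pole
triangles stored as collapsed quads so one patch code path serves every
face), 276 edges, Euler characteristic 2. A subject is the flat vector
of all DOFs, 134 x 12 = 1608 numbers; node 0 is always the most inferior
point, which fixes anatomical correspondence across subjects.

Axes are anatomical: +x right-to-left (LR), +y posterior-to-anterior
(AP), +z foot-to-head (FH). Every marker definition depends on this
convention.

Node derivatives are stored per unit of the template's global
(theta, phi) parametrisation. Each face corner holds a fixed 3x3 matrix
mapping the stored derivative stack to the patch-local derivatives:
regular corners use the diagonal arc-span scaling (dtheta, dphi,
dtheta*dphi); pole corners blend the pole node's two tangent carriers by
the corner's longitude (the analytic form of d/dphi at a sphere pole).
Because these maps are fixed at construction and shared data determine
shared edges, C1 continuity survives arbitrary deformation of the DOFs.
Positions on a shared edge agree between neighbouring patches to below
1e-9 mm.

Geometric integrals (area, enclosed volume, volume centroid) use tensor
Gauss–Legendre quadrature per patch (order 4 by default; order 8 changes
the sphere template's volume by < 1e-4 %) with the divergence theorem
for volume. On the sphere template the volume and area errors against
the analytic values are ~0.02 %.

## Template personalisation

A segmentation arrives as a point cloud in patient axes. Alignment is
translation to the centroid plus isotropic RMS-radius scaling — no
rotation, because rotating would destroy the inferior-node
correspondence the axes convention provides. Warping then alternates:

1. **Correspondence**: every cloud point is projected to its closest
   point on the current surface (seeded from an 8x8 per-patch sample
   grid, refined by damped Gauss–Newton in the patch chart, previous
   correspondences kept as extra seeds).
2. **Solve**: all node DOFs are updated by one sparse linear
   least-squares solve of data misfit + lambda * Sobolev penalty, where
   the penalty is the squared graph bi-Laplacian of the DOF displacement
   from an affine-transformed template reference, plus a small (1e-3 *
   lambda) absolute anchor toward that reference.
3. **Reference update**: the affine reference is re-fitted to the new
   DOFs under the same penalty norm.

All three steps are non-increasing in the joint objective, so the
iteration is monotone (asserted from the logged trace). The affine
reference keeps global scaling/shear unpenalised — without it, high
stiffness shrinks the fitted volume. The absolute anchor exists because
the bi-Laplacian has a constant nullspace per DOF group: mixed-derivative
DOFs are nearly invisible to the data term and would otherwise drift
unboundedly along that nullspace.

**Stiffness default (0.1).** Calibrated once on synthetic truth so that
(i) a noise-free cloud refits to < 0.1 mm mean error, (ii) at 1 mm cloud
noise the enclosed volume is recovered to ~1–2 % and node positions to
<1 mm. A single lambda cannot simultaneously leave a ~1 mm residual on
noisy clouds and satisfy (i); the recovery targets won. Raising lambda
trades residual for smoothing, and both regimes remain reachable through
the `stiffness` argument.

Fit error is always reported as the mean unsigned distance from cloud
points to the *smooth* surface (Gauss–Newton projection), not to the
discrete samples; nearest-sample distances alone carry a ~0.1 mm floor.

## Shape atlas and discriminant modes

PCA runs on centred shape vectors via SVD; modes are unit vectors,
subject scores carry the variance (at most n-1 non-degenerate modes).
The retained mode count is the smallest k whose cohort-mean
node-position reconstruction error (mean over nodes of the position
discrepancy, averaged per subject then over subjects; derivative DOFs
excluded) is below a threshold, default 1 mm — roughly half a typical MR
voxel. Note that only the full-DOF residual norm is guaranteed monotone
in k; the position-only error is monotone in practice on structured
cohorts but not as a theorem.

Fisher LDA in the retained PCA-score subspace supplies discriminant
modes: w ∝ Sw^-1 (mu1 - mu0) with a relative ridge of 1e-8 * tr(Sw)/d
when the pooled within-class covariance is near-singular, oriented so
the positive class scores higher. The *inclusive* mode (iLDA) uses all
retained modes. The *optimized* mode (oLDA) exhaustively searches mode
subsets, scoring each by leave-one-out (LOO) AUC; ties prefer fewer
modes, then lexicographic order. With 8 retained modes the default
subset sizes 2..8 give 247 candidates; sizes 1..8 give 255 — both are
reachable through `min_subset`, and the package deliberately exposes the
discrepancy rather than resolving it. Extreme shapes for visualisation
are mean ± n_sd score-SDs along a discriminant direction mapped back to
shape space.

## Markers

- **Volume / surface area**: quadrature integrals above.
- **AP radius (mesh)**: half the minimal caliper width of the equatorial
  contour (plane through the volume centroid) — the shortest equatorial
  radius, invariant to in-plane rotation.
- **AP radius (segmentation)**: half the y-extent of cloud points within
  a ±2 mm slab at the cloud's centre-of-mass height; the raw-image
  counterpart, deliberately noisier.
- **LR/FH radii and ratios**: axis-aligned half-extents of dense surface
  samples.
- **Sphericity**: least-squares sphere fit (algebraic initialisation +
  Levenberg–Marquardt on the geometric residual), then
  (1 - mean|r_i - R| / R) * 100. Scale-invariant; 100 for a sphere. The
  normalisation by the mean absolute residual is one concrete reading of
  a "normalised sum of residuals" and is fixed in config.
- **Vertical asymmetry (VA)**: with z0 the volume-centroid height and H
  the smaller pole distance, mirrored slice pairs at z0 ± (j-1/2)H/n
  (n = 50 by default) contribute the difference of AP extents of the
  cross-section contour, superior minus inferior; VA is the sum in mm.
  Positive VA: superior hemisphere AP-larger. The hemispheres are split
  at the volume centroid (robust to noise, unlike the bounding-box
  midpoint). VA = 0 for any z-mirror-symmetric shape and flips sign
  under z-reflection for every slice count; those properties, not the
  slice count, are the definition's invariants. Cross-sections are
  computed on a dense triangulation of the Hermite surface (10 segments
  per patch edge) by vectorised edge–plane crossing, checked in tests
  against sectioning and against a closed-form slice oracle.

Markers are assembled into a per-subject table; the echo AP radius and
recurrence labels are merged from a clinical CSV on `subject_id`.
Missing values stay missing (flagged, never imputed).

## Recurrence classification

AUC uses the Mann–Whitney rank statistic with half credit for ties.
LOO cross-validation trains the Fisher combination on n-1 subjects and
scores the held-out one; the pooled out-of-fold scores give the LOO AUC
(the only well-defined pooling for LOO), with the resubstitution AUC
reported as the optimistic reference. The marker-combination search
enumerates every subset of the configured markers (63 for 6 markers),
z-scores per subset, uses complete cases per subset (so each subset sees
the maximum usable cohort), and ranks by LOO AUC.

Group-score distributions are summarised by per-group maximum-likelihood
normal fits plus their Bhattacharyya overlap coefficient.

Localised shape differences use two-sample Hotelling T² per node on 3D
node positions after rigid-only generalised Procrustes alignment (3
iterations, Kabsch rotations, no scaling), with exact F p-values and — by
default — no multiple-testing correction (a Bonferroni switch exists).
Under the null the per-node type-I rate is ~0.01 at alpha = 0.01.

## Synthetic cohorts

The generator emulates what is known about LA-body shape statistics: an
AP-flattened ellipsoid (median semi-axes 30, 20, 30 mm — volume ~75 mL,
typical for AF patients) with a smooth superior-posterior prominence
(median 4 mm, emulating the bulge near the left pulmonary-vein ostia)
and a superior-vs-inferior AP scaling factor gamma (median 0.90) that
plants vertical asymmetry. Cohort variation is a shared log-normal size
factor (CV 0.15) dominating per-axis factors (CV 0.08), so the first PCA
mode is size and correlates with volume at |rho| > 0.9. Node noise
(0.5 mm) emulates residual personalisation error; clouds are surface
samples with 1 mm noise, matching reported segmentation-fit residuals.
The deformation is applied analytically to the template (derivatives by
central finite differences of the composed map; pole tangent carriers
rebuilt exactly), so ground truth is a valid Hermite mesh.

Labels come from a logistic model on the z-scored TRUE (noise-free)
sphericity and VA (beta = +0.8 and -0.8; intercept solved so prevalence
matches 0.31 at 12 months, 0.40 at 24 months). The two horizons share
one uniform draw per subject, so recurrence is monotone in time: a
12-month recurrence stays recurrent at 24 months. The expected AUC of the
true linear predictor — the Bayes ceiling for that cohort — is computed
in closed form by averaging pairwise concordance over the label
distribution, rather than by Monte-Carlo draws; this removes simulation
error from the reference. Any shortfall of a downstream classifier
against this ceiling is attributable to pipeline noise, which is the
lever the recovery experiments use.

What passing these experiments shows: the pipeline recovers planted
geometry, planted discriminant structure, and planted marker relevance
at realistic noise. What it does not show: anything about real atria —
the generator has no pulmonary veins or appendage stumps, no wall
thickness, no non-ellipsoidal remodelling, and its marker-label link is
exactly the model the classifier assumes.

### Scales used by the bundled experiments

The recovery experiments run at the cohort scale the generator defaults
to (n = 144) except where selection consistency needs more subjects:
the LOO-vs-Bayes comparison uses one n = 500 cohort, and the
marker-subset win-rate uses 10 seeded replicates at n = 144. Distractor
markers in the win-rate experiment must be label-independent by
construction; geometric size markers are only approximately so (volume
and FH radius jointly encode axis ratios, which drive sphericity), so
the experiment uses volume plus an explicit noise marker as
distractors.

**On subset-selection consistency.** Ranking marker subsets by LOO AUC
and taking the argmax identifies a *sufficient* subset reliably, but not
the *minimal* one: a superset containing an extra noise marker beats the
true pair whenever the paired AUC-difference noise exceeds the small
overfitting penalty, and that probability does not vanish with n
(LOO-CV model selection is asymptotically liberal, like AIC). In an
idealised simulation with noise-free markers and the default label
model, the exact planted pair wins ~70–78 % of replicates (one or two
independent distractors; flat from n = 144 to n = 500), while the
winning subset *contains* the pair essentially always. The experiments
therefore report both rates; containment is the property a user should
rely on, and the exact-win rate is reported for transparency.

## Known limitations

- The template topology fixes correspondence by orientation alone; no
  anatomical landmark matching beyond the inferior node.
- Closest-point projection clamps to the patch chart; a foot point lying
  exactly on a patch boundary may be attributed to either neighbour
  (distances are unaffected).
- The sphericity normalisation and the VA slice recipe are fixed
  concrete choices among several defensible readings; both are config
  knobs, and cross-cohort comparability of absolute VA values depends on
  the slice count.
- Echo AP radius is an imported number; the package performs no echo
  image analysis.
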