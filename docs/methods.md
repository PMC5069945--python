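# Methods

`bivshape` implements a population-based statistical shape analysis of
bi-ventricular cardiac geometry: a PCA point-distribution model over
populations of corresponded surface meshes, a currents kernel metric as a
global one-parameter shape measure, a summed loading score as a regional
measure, leave-one-out kNN classification of patients vs controls from either
scalar, and univariate correlation of shape-mode loadings with clinical
diagnostic indices. Because clinical CMR cohorts cannot be redistributed, the
package ships a synthetic cohort generator with *planted* shape-mode structure
so that every stage can be validated against known ground truth.

## The shape model

Each subject is three closed triangulated surfaces — LV endocardium, LV
epicardium, RV endocardium — sharing one template topology (the RV epicardium
is excluded; the RV free wall is too thin to delineate reliably on short-axis
cine images). Point correspondence across a population is by vertex index.
This template-correspondence assumption is the central desk-scale
simplification of the package: a full deformable-registration atlas (the way
correspondence is usually obtained from real segmentations) is out of scope,
and all statistical machinery downstream is agnostic to how correspondence was
produced.

Subjects are stacked as rows `x_i` of concatenated vertex coordinates
(LV endo ‖ LV epi ‖ RV endo, mm). With mean `x̄` and centred data `C`,
the model is the eigendecomposition of the sample covariance
`S = CᵀC/(n−1)`, computed in the dual (the n×n Gram matrix `CCᵀ`), exact
and memory-light since 3V ≫ n. At most n−1 modes carry variance.
Loadings are reported in SD units (`ℓ_ik = φ_kᵀ(x_i − x̄)/√λ_k`), so the
training population has per-mode mean 0 and sample SD 1, and "shape at
±1 SD" is `x̄ ± √λ_k φ_k`. PCA mode signs are arbitrary; the convention
fixes each mode's largest-magnitude coordinate positive. The number of
modes retained downstream is the smallest m whose cumulative variance
fraction reaches a threshold, default 0.8.

Alignment before modelling is generalized Procrustes with rotation and
translation only, iterated against the evolving mean (initialised from the
first subject, convergence 1e-8 mm, cap 100 iterations). **No scaling is ever
applied**: ventricular size is a disease signal, not a nuisance parameter.

## The currents metric

An oriented surface is represented by its triangle barycenters `c_i` and
area-weighted normals `n_i`; two surfaces are compared through the Gaussian
kernel inner product

    ⟨a, b⟩ = Σ_ij exp(−‖c_i − d_j‖²/σ_w²) (n_i · m_j),

with distance `d(a,b) = √(⟨a,a⟩ − 2⟨a,b⟩ + ⟨b,b⟩)`. This is
correspondence-free and orientation-sensitive. The kernel width σ_w (default
10 mm) sets the scale below which shape differences are smoothed away; 10 mm
is of the order of wall thickness and of the regional features of interest
(outflow-tract elongation, inlet/outlet bulging) at clinical voxel sizes.
The double sum is evaluated directly; at cohort sizes (hundreds to a few
thousand faces) this is exact and fast, so no grid or FFT approximation is
used.

Numerical notes: the three per-surface distances are combined as a
root-sum-square (how the three surfaces enter the "bi-ventricle" distance is
a design choice isolated in `biventricle_distance`); degenerate triangles
(area < 1e-12 mm²) are dropped with a warning rather than erroring, since
lofting can produce apex slivers; the squared distance is clamped at zero for
round-off down to −1e-9. Because the self inner products are large (mm⁴
scale), "zero" distances are zero only to ~1e-7 relative — tests and users
should compare distances relatively, not to absolute 1e-9. The discretisation
error of the double sum scales like (edge/σ_w)²: at the default template
resolution a 1→4 subdivision still moves distances by ~8 %, while meshes with
edges ≲ 3 mm are stable below 1 %. Distances are therefore only comparable
across meshes of identical resolution, which the template guarantees.

In the leave-one-out protocol each control is compared to the vertex-wise mean
of the other N−1 controls, and each patient to the full control mean, so no
subject contributes to its own reference.

## The summed loading score

The regional scalar score of a subject with loadings `ℓ` against a control
group with per-mode mean μ and SD s is

    score = Σ_{k=1..5} f_k · |ℓ_k − μ_k| / s_k,

where `f_k` is mode k's variance fraction: per-mode z-normalisation against
controls, absolute value (mode signs are arbitrary), variance-fraction
weighting, summation. The exact normalisation of such a score is a genuinely
open design choice; this one is isolated behind `summed_loading_score` so
alternatives are swappable. A consequence of the absolute value is that
controls' negative tails also score high: with a +3 SD group shift on mode 1
alone, the seed-averaged ROC AUC of the score is 0.949, not 1. Controls are
scored leave-one-out (each against the other controls' statistics).

## Classification and associations

The kNN classifier (k = 3) operates on one scalar feature, leave-one-out, with
neighbour ties broken toward the lower subject index. Sensitivity and
specificity are per-group accuracies (patients / controls respectively). ROC
curves sweep all distinct thresholds ("score > t ⇒ patient"); AUC is the
trapezoid area; the operating cut-off maximises accuracy with sensitivity as
first tie-break (a missed patient costs more than a false alarm) and the lower
threshold as second.

Associations between loadings and clinical indices use Spearman's ρ (mid-ranks),
Kendall's τ_b (tie-corrected), and Pearson's r, each two-sided; binary and
ordinal indices enter numerically, which the rank tests make defensible. For
n ≤ 8 the rank-test p-values are exact by full enumeration of the n!
permutations; above that, the standard t and normal approximations (via SciPy)
are used. CCA of the five-mode block against a single index reduces to the
multiple correlation R of the regression of the index on the loadings, with
the overall-regression F test as the p-value (the single-response reduction of
Rao's F approximation to Wilks' Λ). The screen applies a p < 0.05 gate and
deliberately **no multiple-testing correction** — it is an exploratory screen
in which a missed effect is costlier than a false flag — and the output
metadata records the p-values as uncorrected.

## The synthetic cohort generator

The template is a stylised bi-ventricle: LV endo- and epicardium as nested
truncated half-ellipsoids (semi-axes 25/25/75 and 33/33/82 mm) closed with a
flat basal cap at z = 0 and apex toward −z; the RV endocardium as a laterally
offset half-ellipsoid (32/36/66 mm, centred 50 mm toward +x) with a concave
septal indentation facing the LV (crescent cross-section) and a smooth
anterior bulge marking the outflow tract. All three surfaces are watertight
and share the ring-shell vertex layout (apex pole, rings, basal centre).

Five deformation fields are constructed geometrically — global dilation
(radial scaling about the bi-ventricle centroid), RVOT elongation (axial
displacement under a Gaussian bump at the outflow rim), septal tilt (linear
base-to-apex shear of the RV septal wall), base–apex lengthening (z scaling),
and RV inlet/outlet bulging (two outward Gaussian bumps) — then Gram–Schmidt
orthonormalised in that order, so the planted covariance is exactly diagonal
in the resulting basis. Subject i is

    x_i = template + Σ_k z_ik √(v_k T) φ_k + ε_i,

with `z_ik` iid standard normal (optionally mean-shifted per mode to model a
group effect), `v_k` the planted variance fractions — default 44/15/10/7/5 %
with a 19 % residual — and `ε_i` isotropic per-vertex jitter carrying the
residual variance spread thinly over all ~2600 coordinates, so no single noise
direction competes with a planted mode (each sample noise direction carries
≈ 0.7 % of T at n = 27). The total variance scale T defaults to 20 000 mm²,
chosen so that ±1 SD of the dominant mode displaces vertices by a few mm, the
magnitude of visible remodelling at clinical image resolution. All sampling
is a pure function of (spec, seed) through one `numpy` generator.

Clinical indices are drawn from the planted loadings: binary flags as
Bernoulli(logistic(β·z)), criteria counts as monotone rounded functions of a
linked loading plus Gaussian noise, and the diagnostic category derived from
the count rule. The link strengths and the group mean offsets are free
parameters of the simulation — nothing in the underlying study quantifies
them — and the defaults are chosen once to give clear but imperfect group
separation and detectable but not trivial associations.

### What the generator does and does not emulate

It emulates: a low-rank shape population with a known dominant-mode spectrum,
residual anatomical noise, group mean differences, and stochastically linked
clinical indices. It does **not** emulate segmentation error structure,
slice-direction anisotropy, registration/correspondence error, non-linear or
localised disease remodelling, or realistic index base rates. Passing tests
therefore demonstrate that the *analysis machinery* is correct and calibrated,
not that the pipeline would achieve any particular accuracy on real CMR data.

### Finite-sample behaviour worth knowing

At the default study scale (n = 27, 3V ≈ 2600) PCA eigenvalue estimates are
biased and noisy in well-understood ways, and the tests are calibrated to the
attainable regime rather than to the asymptotic ideal:

* The leading sample variance fractions are inflated (ordering/selection bias
  plus noise absorption): the seed-averaged first fraction recovers 44 %
  within ±3 points but sits near 46 %, and the cumulative fraction of the
  first four modes hovers at ≈ 0.80, so the per-seed 80 %-mode count
  fluctuates between 4 and 6 with 5 the modal and seed-averaged value.
* Principal angles between the planted and fitted 5-mode subspaces follow
  spiked-covariance asymptotics at p/n ≈ 100: from ≈ 7° for the 44 % mode up
  to ≈ 21° for the 5 % mode (seed-averaged mean ≈ 16°). At zero residual
  noise recovery is exact to < 1e-6 rad.

## Pipeline structure

`bivshape run-all` executes: simulate → generalized Procrustes (pooled) → PCA
(one model per group, for each population's own mode spectrum, plus one pooled
model that expresses both groups on common axes for scoring and correlation)
→ currents LOO distances to the control mean → summed scores → kNN-LOO and ROC
for each scalar → association screen of patient loadings against the simulated
clinical table. Every stage is a pure function of (config, seed); reruns are
bitwise reproducible, and each run writes a manifest (config, versions,
artifact list). ED and ES would be modelled separately on real cine data; the
synthetic generator produces a single phase, treated as ES by default.

## Known limitations

Template correspondence replaces registration entirely; the misalignment
correction and temporal resampling are reasonable stand-ins (least-squares
line through LV-epi centroids; linear non-periodic interpolation at 30 frames)
for acquisition-specific algorithms whose details vary; the kernel width has
no data-driven calibration here; and all classification/association numbers
produced on synthetic cohorts depend on the free effect-size parameters above
and generalise to no real population.
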