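# Methods

## Pipeline overview

The analysis chain mirrors a standard diffusion-tensor connectomics
protocol for a two-group (chronic stroke vs. healthy control, 13 + 13)
comparison: deterministic fiber tracking on a principal-direction volume →
endpoint assignment to an 80-ROI parcellation → per-subject FA /
fiber-count / mean-length / connection-weight matrices → rank-based
Gaussian re-normalization of the connection weights → nodal metrics (rFA,
CS) → homotopic hemisphere alignment → subnetwork MANOVA battery →
clinical-score correlations → network-based statistic on the edge
matrices.  Every stage is importable on its own; the numbered scripts
under `analysis/` are thin narrative drivers.

## Tracking (FACT)

Streamlines advance by a fixed step (default 0.5 voxels) along the
principal direction of the **current** voxel — nearest-voxel lookup, no
interpolation, the defining property of FACT.  Tracking runs
bidirectionally from one seed per voxel whose FA reaches the stopping
threshold, and terminates on (i) leaving the volume, (ii) entering a voxel
with FA below threshold, or (iii) a turn between consecutive steps
exceeding the angle threshold.  Defaults: FA threshold 0.15, angle 45°,
step 0.5 — the angle is the protocol's stated value; the FA threshold and
step are the conventional FACT settings, exposed in `TrackingConfig`.
Coordinates are voxel-indexed, 0-based, points at voxel centers.

Smoothing fits a least-squares cubic B-spline whose interior knots are
spaced about four output samples apart in chord-length parameter, then
resamples uniformly in arc length; endpoints are pinned.  Because the fit
is a projection onto a fixed spline space, re-smoothing a smoothed track
is a near-no-op (length change well under 0.5% for tracks obeying the
45° rule); arbitrary white-noise polylines are outside that domain and
keep contracting on repeated passes.

## Connectome construction

Two ROIs are connected if at least one retained fiber has one endpoint in
each.  Edge values: FA = unweighted mean over connecting fibers of the
per-fiber mean FA (fiber weighting by length is a defensible alternative;
the unweighted mean is used and documented); CW per the formula in the
README.  Zero-length fibers are rejected (they would divide by zero) and
counted.  Matrices are dense, exactly symmetric by construction, zero
diagonal, and share one sparsity support per subject.

The re-normalization ranks the **nonzero** upper-triangle CWs (average
ranks on ties) and maps rank *r* of *n* to `0.5 + 0.1·Φ⁻¹((r−0.5)/n)`.
The (r−0.5)/n offset keeps quantiles finite and pairs symmetric around the
median, so the transformed sample mean is exactly 0.5 and the SD
approaches 0.1 from below (≈0.0005 short at n = 780 — a finite-n quantile
effect).  Structural zeros stay zero: including absent edges would let CS
be dominated by support size rather than connection strength.

## Parcellation and subnetworks

The shipped table (`data/parcellation_dk80.tsv`) has 68 cortical + 12
subcortical ROIs (34 + 6 per hemisphere, Desikan-Killiany-style names)
with surface sizes at plausible atlas scale and a homotopic L↔R
involution.  The grouping into 12 functional blocks — default-mode,
attention, visual-recognition, auditory, sensory-motor and subcortical per
hemisphere — is a documented reconstruction (e.g. precentral/postcentral/
paracentral/superior-frontal → sensory-motor; hippocampus and the other
deep nuclei → subcortical); any table with the same columns can be
substituted.  Hemisphere alignment permutes rows/columns by the homotopic
involution for right-lesion subjects so the ipsilesional hemisphere is
always left; flipping twice restores the input exactly.

## Synthetic data

The generator emulates the study conditions rather than raw diffusion
signal: two groups of 13 subjects (configurable), 80-ROI sparse symmetric
connectomes.  Raw CW edges are i.i.d. log-normal(0, 1) — positive and
right-skewed, as raw weights are; FA edges are Beta(5, 3) rescaled to
[0.2, 0.7]; counts Poisson(20)+1; lengths uniform 20–100.  A shared base
support keeps 30% of edges (default), with 2% per-subject jitter; the
base support is hemispherically **mirror-symmetric**, without which
flipping right-lesion subjects (but no controls) would create systematic
group differences in edge presence and void the null.  Matrices are
emitted in the ipsilesional-left analysis convention: right-lesion
subjects are marked as already flipped, so planted effects sit at their
stated indices for every subject.

Planted effects: `edge_shift` is added to the raw CW of the target edges
in the stroke group (targets and their mirrors are forced into every
support; only the targets are shifted).  Clinical scores follow
`score = intercept + slope·CS(target ROI) + N(0, noise_sd)`, rounded and
clipped to the score range; `noise_sd_for_spearman` converts a desired
population Spearman into a noise SD via ρ_s = (6/π)·arcsin(r/2).  Because
a ROI's CS location depends on its degree in the dataset's sparse
support, links should be calibrated against a pilot cohort drawn with the
same seed.  Healthy records carry missing clinical fields.

What passing tests do **not** show about real data: no diffusion signal,
noise, or crossing-fiber geometry is simulated; edge values are
independent given the support, whereas real connectomes are spatially
correlated; the planted-effect sizes are chosen, not estimated from
patients.  The synthetic results validate the machinery and its error
control, not any clinical claim.

## Statistics

* **Box's M** with the standard χ² scaling; homogeneity flagged at the
  conventional p < 0.001 criterion.
* **MANOVA**: two-group Wilks' Λ = det(E)/det(E+H) with Rao's F — exact
  for two groups (identical to Hotelling's T²) and reducing to the
  one-way ANOVA for one variable (identity verified to 1e-10).
* **Follow-up ANOVAs** at 0.05/k within a k-ROI subnetwork; since they
  serve to locate a significant multivariate effect, no ROI is flagged in
  a block whose MANOVA is not itself significant.  Under the global null
  the per-block MANOVA rejection rate is calibrated at α (measured
  0.050–0.056 over 480 block-tests), so across 24 block-metric analyses a
  false-positive trickle of ~1 flagged ROI per couple of runs is expected
  and correct.
* **Spearman + FDR**: t-approximation p-values (exact permutation
  available for n ≤ 10); Benjamini-Hochberg within each metric-by-score
  family across the candidate ROIs (a pooled family is available).
* **Partial correlation** controlling ipsilesional PLIC mean FA:
  first-order formula with a t test on n−3 df; rank-transformed by
  default to match the Spearman zero-order analysis, Pearson mode
  switchable.
* **2×2 tests** report Pearson X², Yates-corrected X² and one/two-sided
  Fisher exact side by side — at n = 26 the variants differ (X² p ≈
  0.011 vs one-sided Fisher ≈ 0.015 on the gender table) and published
  values rarely state which was used.

## Network-based statistic

One-tailed pooled-variance t at every edge (both directions run as
separate analyses), threshold default 1.8, components = connected
subgraphs of the supra-threshold edges, size = edge count (extent).  The
null of the maximal component size is built from random relabelings of
subjects (group sizes preserved); `p = (1 + #{null ≥ size}) /
(1 + n_permutations)`, so p-values lie in [1/(m+1), 1].  For combined
n ≤ 10, or when the permutation request reaches the number of distinct
relabelings, the null is enumerated exactly.  Edges absent in any subject
are masked by default (t-tests on structurally absent connections are
meaningless); the presence fraction is configurable.  The permutation
engine computes all relabelings' t statistics with two matrix products
and extracts components with a union-find over kept edges only (~4% of
edges under the null), which keeps a 500-dataset × 1000-permutation
calibration under a minute.

A property of extent-based NBS worth knowing: at the lenient threshold
1.8 (~4% of null edges survive) the null maximal component grows quickly
with graph size — P(max ≥ 3 edges) is ≈0.06 on 8-node graphs, ≈0.16 at
10, ≈0.38 at 14 (measured over 1000 null simulations).  A focal 3-edge
effect is therefore resolvable only when it is a substantial fraction of
the network; the planted-component power demonstrations use 6-node
graphs for this reason, while error-rate calibration uses 20-node graphs
where the same growth is exactly what the permutation null accounts for.

## Numerical choices and degenerate inputs

Ties in ranking get average ranks; an all-equal CW matrix re-samples to
all 0.5 with a warning.  Zero-variance edges are masked in the NBS and
flagged degenerate (p = 0) in ANOVAs.  Singular covariance/SSCP matrices
raise with advice to reduce the block size.  Streamline smoothing of
fewer than 4 points is a logged no-op.  All simulations derive from
`numpy.random.default_rng` seeds; identical seeds give bit-identical
outputs, and every pipeline output carries a YAML provenance sidecar
(version, seed, config hash).

## Problem sizes used in the shipped demonstrations

Cohort statistics use the embedded 13-patient table.  Phantom validation
uses a 40×20×11 grid with two radius-1.5 bundles (~600 streamlines).
Statistical calibration uses 13 + 13 subjects throughout: 20-node graphs
for edge-level calibration and FWER (500 datasets × 1000 permutations),
6-node graphs for planted-component power, 80 ROIs for the full battery
and pipeline runs.  These sizes make the whole suite reproducible on a
single CPU in minutes while keeping every sample-size-dependent constant
(n = 13 per group) at the study's value.

## Known limitations

Single-tensor deterministic tracking cannot represent crossing fibers;
probabilistic and multi-tensor models are out of scope.  Surface sizes
and the PLIC FA covariate are inputs, not computed.  The
ROI→subnetwork table is a reconstruction, not the original assignment.
Real-data effect sizes (Wilks' Λ, ρ, NBS component counts from patient
scans) are not reproducible without the scans and are represented only by
planted-effect recovery on synthetic data.
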