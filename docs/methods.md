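# Methods

This note records the statistical models, conventions and numerical choices
behind `loopgate`, in the order an analysis runs.

## Superposition

All fluctuation statistics are computed after rigid-body motion has been
removed. `kabsch_superpose` solves the least-squares rotation by SVD of the
3×3 cross-covariance (Kabsch), with the usual determinant correction so the
rotation is always proper (det +1); the transformation is fitted on a chosen
atom selection and applied to all atoms of the frame. `iterative_mean_fit`
alternates fitting all frames to the current mean structure and recomputing
the mean, until the mean moves by less than `tol` (default 1e-5 Å RMSD,
at most 50 iterations; non-convergence warns and returns the best iterate).
Fitting onto the converged mean — rather than an arbitrary frame — is the
standard essential-dynamics preprocessing step; it is the default (`prefit`)
for RMSF, covariance and DCCM. The fit needs at least 3 non-collinear atoms;
nearly degenerate references (e.g. the mean of a pure-noise ensemble, which
collapses toward a point) converge slowly but correctly.

Synthetic ensembles are generated in a common frame by construction, so
analyses on them may pass `prefit=False`; results differ only at O(6/3N) —
the share of variance in the six rigid-body degrees of freedom that fitting
removes.

## Positional covariance and essential dynamics

The covariance is the literal trajectory average with divisor = frame count
(population convention, not n−1), over the Cartesian coordinates of the
selected atoms (by convention all Cα). No mass weighting is applied
anywhere. Eigenpairs come from a symmetric eigendecomposition
(`numpy.linalg.eigh`) after symmetrizing against roundoff; eigenvalues are
clipped at 0 and sorted descending; each eigenvector is flipped so its
largest-magnitude component is positive, making projections reproducible
across BLAS builds. Projections subtract the model's mean structure and dot
with the eigenvectors; by construction the projection series of the building
ensemble has zero mean and per-mode variance equal to the eigenvalue.
Extreme-projection frames (used to pull representative open/closed
snapshots) break ties toward the earliest frame.

## Free-energy landscape

The (PC1, PC2) plane is binned on a 50×50 grid (configurable) spanning the
observed ranges with 1% padding, and inverted:

    ΔG(bin) = −k_B · T · [ln P(bin) − ln P_ref],   k_B = 0.0019872041 kcal/(mol·K)

with T defaulting to 300 K. **Reference convention:** `P_ref` is the
probability of the *most populated* bin, so the global minimum is exactly 0
and all ΔG ≥ 0. Formulations of this estimator sometimes write the reference
as "P_min"; taken literally (the least populated bin) that would make every
ΔG ≤ 0 and put the zero point at the worst-sampled bin, contradicting the
universal rendering of landscapes with basins as minima. This package uses
the maximum-probability reference throughout. Empty bins are masked, counts
always sum to the frame count, and a warning is raised when there are fewer
samples than bins.

### Basin detection

"How many conformational ensembles does the landscape show?" is answered by
flooding the grid in order of increasing ΔG (8-connected). When two growing
catchments meet, the shallower one counts as a distinct basin only if the
saddle between them lies at least `min_barrier` (default 0.5 kcal/mol, a bit
below k_B·T at 300 K) above its own minimum; otherwise it is treated as a
counting-noise wrinkle and merged. Catchments separated by unsampled (masked)
regions never meet and always stay distinct. Detection runs on a ΔG grid
recomputed from Gaussian-smoothed counts (σ = 1 bin, a common smoothing scale
for histogram landscapes; set `smoothing_sigma=0` to disable), while the
*reported* depth of each basin is read off the raw grid (minimum over the
detected bin's 3×3 neighbourhood), so closed-form depth checks are unaffected
by smoothing. Surviving minima deeper than `depth_cutoff` (default
2.0 kcal/mol above the global minimum) are discarded, and minima within
`min_separation_bins` (default 3, Chebyshev) are merged keeping the deeper.
A plain local-minimum rule without the persistence step was tried first and
rejected: Poisson noise on a 50×50 histogram of 1e5 samples produces several
spurious shallow minima per landscape, making planted basin counts
unrecoverable.

Validated behaviour: planted Gaussian-mixture basin counts {1, 2, 3, 4, 7}
with center separation ≥ 5× the basin width are recovered exactly across
seeds at n = 5·10⁴ and 10⁵ samples, and the depth difference between two
basins with weights w₁/w₂ matches −k_B·T·ln(w₁/w₂) within 0.1 kcal/mol at
n = 10⁵.

## Dynamic cross-correlation

`S_ij` contracts the full 3-D displacement vectors (isotropic dot product),
not per-component correlations, and the displacement reference is the
trajectory-mean position — the standard DCCM reading, not a time-lagged
correlation. The diagonal is set to exactly 1 for atoms with non-zero
fluctuation; atoms whose coordinates never change across frames are masked
(a bit-identity check guards against summation roundoff leaving
variance ~1e-32). Values are clipped to [−1, 1] and symmetrized against
roundoff. `block_correlation_score` averages the cross block of two residue
ranges; negative values mean anti-correlated loop motion.

## Hydrogen bonds

The default criterion is a heavy-atom donor–acceptor distance ≤ 3.5 Å with
an *inclusive* boundary (the boundary convention must be fixed for exact
occupancy identities; inclusive was chosen and is documented here). A
donor–H···acceptor angle cutoff (default 120°, measured at the hydrogen) is
applied only when explicit hydrogens are present and `heavy_atom_only` is
disabled — Cα/heavy-atom ensembles carry no hydrogens, and distance-based
reasoning on heavy atoms is the common practice for such data. Pairs within
one residue are excluded. Occupancy is the mean over all analyzed frames of
the per-frame criterion indicator (an exact identity, tested against brute
force); a `skip_frames` option drops an equilibration window but the default
analyzes every frame, since any equilibration split is a per-study choice.
Water bridges are per-frame: a water oxygen (residue HOH/WAT/SOL) within the
distance criterion of at least one atom on each side, reported once per
qualifying water with the closest partner on each side. Trajectory-wide
water-bridge statistics are out of scope.

## Synthetic ensembles

The generators are pure functions of (spec, seed) — identical inputs give
bit-identical output — and emulate statistics, not dynamics: no force field,
integrator or solvent.

- **Gaussian mode ensembles**: frames = mean + Σ_k a_k·z_k·mode_k + σ·noise
  with orthonormal modes and strictly decreasing amplitudes, so the
  population covariance is exactly Σ a_k²·mode_k·mode_kᵀ + σ²·I. The helical
  mean-structure helper provides a spatially extended (well-conditioned)
  default geometry.
- **Two-loop gating ensembles**: a Cα chain whose two pocket loops face each
  other across the pocket center (mean gap `initial_gap`, default 11 Å — the
  middle, semi-closed band). The gating coordinate is two-state (rest ≈ 0,
  displaced ≈ 1 with probability `state_probability` = 0.35 and Gaussian
  spread 0.15), making the gap distribution bimodal as loop-gated pockets
  are; loop atoms move by `amplitude` (default 2.5 Å) × coordinate along the
  planted pattern. `approaching` moves both loops toward the pocket center,
  `opening` apart, `anti-parallel` in the same global direction (one toward,
  one away) — so approaching/opening give negative loop–loop DCCM blocks and
  anti-parallel positive ones. The pocket center is defined as the midpoint
  of the two loop centroids in the mean structure, which makes the three
  motion labels unambiguous. Non-loop residues carry isotropic noise only
  (default σ = 0.3 Å).
- **Basin mixtures**: (PC1, PC2) samples from isotropic 2-D Gaussian
  mixtures; the analytic basin offset is −k_B·T·ln(w_i/w_max).
- **H-bond series**: a stationary two-state Markov chain whose bound
  fraction is the target occupancy, with mean bound dwell time
  `mean_dwell_frames` (default 10 frames — chosen by a power analysis so
  that the integrated autocorrelation leaves the standard error of a
  50,000-frame occupancy estimate near 0.006, well inside the ±0.02 band the
  recovery checks use, while keeping the series autocorrelated like real
  occupancy traces; longer dwells are one field away). Bound/unbound
  distances are drawn about their means (defaults 3.0 / 5.5 Å, σ = 0.15 Å)
  and clipped to the correct side of the criterion cutoff, so the realized
  state fraction and the measured occupancy coincide; the clipping moves the
  bound-state mean by < 1e-3 Å at the default σ.

What the generators do **not** emulate: anharmonicity beyond two-state
gating, solvent structure, real H-bond geometry (donor chemistry, angle
distributions), sequential frame correlation in the coordinate ensembles
(frames are i.i.d. except the H-bond series), or coupling between the
gating mode and side-chain packing. Passing tests therefore demonstrate that
the analysis stack recovers planted statistical structure at known sample
sizes — not that any particular biological conclusion from real
trajectories is correct.

## Pocket-state classifier

A two-threshold rule on the loop-gap distance: gap ≤ 6.5 Å → closed,
gap ≥ 12.0 Å → open, else semi-closed (both thresholds configurable). The
defaults cleanly separate the canonical exemplar distances (5.0 | 8.4 |
15.5, 20.9 Å); any thresholds strictly inside (5.0, 8.4) and (8.4, 15.5)
produce the same labels for those exemplars. Published analyses often assign
states from single extreme-projection snapshots; the per-frame rule here is
a deliberate generalization (it yields state fractions and a modal state),
not a reimplementation of that snapshot procedure.

## Problem sizes

Default validation sizes were chosen so each closed-form check sits at ≥ 3
standard errors from its tolerance: 50,000 frames for single-mode eigenvalue
and RMSF recovery (Monte-Carlo error ~0.6%, tolerances 2–3%), 100,000
samples for landscape depths (±0.1 kcal/mol), 20,000 frames for DCCM block
scores, and 100 random instances of ≤ 5 atoms × ≤ 50 frames for exact oracle
equivalence at 1e-12.

## Known limitations

- PDB output writes minimal ATOM/HETATM/MODEL records, no headers, and
  assumes ≤ 3-character residue names for column alignment.
- The selection grammar is conjunctive only (clauses joined by `and`); there
  is no `or`, `not`, or distance-based selection.
- No binary trajectory formats (DCD/XTC/TRR); multi-model PDB and XYZ only.
- Water-bridge detection is distance-based and per-frame; it does not check
  hydrogen geometry at the water.
- The FEL is strictly 2-D over (PC1, PC2); no higher-dimensional landscapes
  or kinetic (Markov-state) modeling.
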