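# Methods

## Scope and model

The package quantifies how a perturbation (constant pulling force, bound
ligand, or both) reshapes the internal dynamics of a multi-domain protein,
using only Cα coordinates from replicated trajectories. Four analysis
families are implemented: dynamic cross-correlation with pair
classification; a correlation-weighted residue interaction network scored
by betweenness centrality; structural observables (extension, RMSD, RMSF,
per-residue displacement) with convergence diagnostics; and coordinate
PCA. A synthetic-ensemble generator provides ground-truth inputs for all
of them.

All lengths are nm internally and ns for time; PDB I/O converts to/from Å;
inter-residue distances for the network criterion are reported in Å
because the contact cutoff (7 Å) is a structural-biology convention.

## Synthetic ensembles

One replica is `reference + noise_sd · L z_t (+ t · drift_vector on the
drift group)`, with `L Lᵀ` the designed residue–residue correlation matrix
(unit diagonal; `intra_block_corr` within each named domain block;
`inter_block_corr` across blocks; zero elsewhere), the same correlation
applied independently along x, y, z, and `z_t` i.i.d. standard normal.
Defaults mirror the study conditions the generator stands in for: 1000
frames spanning 100 ns (0.1 ns/frame), three replicas per condition,
0.1 nm displacement noise. A master seed spawns one child seed per replica
(`numpy.random.SeedSequence`), so replicas are independent yet individually
reproducible and adding a replica never perturbs earlier ones.

What the generator emulates: domain-level correlated motion (force-like
global coupling raises `inter_block_corr` / block span; ligand-like
softening lowers local coupling), force-driven extension (cumulative drift
of a pulling group along z), and replica-to-replica variability. What it
does not: temporal autocorrelation (frames are independent — every
estimator here is a frame average, so this only makes sampling theory
exact, but block/window diagnostics on synthetic data see i.i.d.
statistics, not slow relaxation), anisotropic per-residue fluctuation,
side-chain detail, and solvent or force-field physics. Tests passing on
synthetic data therefore validate the estimators, not the biology of any
particular system.

Reference layouts are deterministic: an extended chain with the canonical
0.38 nm Cα virtual-bond spacing, or a two-lobe cubic-lattice dumbbell
whose lobes are separated well beyond the contact cutoff. On the linear
chain only sequence neighbours (3.8 Å) fall inside the 7 Å cutoff, so the
residue network is a path graph — convenient for closed-form betweenness
checks.

Because the per-axis correlation equals the designed matrix, the nDCC
estimator's expectation is the designed matrix exactly when no rigid-body
fit is applied. Parameter-recovery tests therefore run with superposition
disabled; at 1000 frames the empirical matrix deviates from the design by
< 0.08 (max-abs), consistent with Fisher-z sampling error.

## Superposition

Least-squares rigid fitting uses the Kabsch algorithm (SVD of the
cross-covariance with determinant correction) with uniform Cα weights —
mass weighting is deliberately not applied, since all analyses are
Cα-only and residue-mass differences are not resolvable there. Fits
require ≥ 3 non-collinear atoms; collinearity is detected from the second
singular value of the centered cloud (< 1e-10). Fluctuation-type analyses
(RMSF, covariance, nDCC) use a two-pass fit: frames are fit to frame 0,
the mean is taken, and the original frames are refit to that mean.

## Observables

* **RMSD** per frame versus a reference conformation, after Kabsch
  superposition by default; a no-fit mode measures the lab-frame
  deviation, which under pulling includes the rigid displacement. Which
  convention a published number used is not always stated, so both are
  exposed and the default (fit) is recorded in every report header.
* **RMSF** per residue about the trajectory mean after the two-pass fit;
  the scalar "average RMSF" is the mean of the profile over residues.
* **Extension** e(t) = [centroid(pull) − centroid(ref)] · axis, zeroed at
  frame 0, computed without superposition: the observable lives in the
  pulling frame, where the reference group mimics membrane confinement.
  Centroids are uniform-weight.
* **Per-residue displacement** between first and final conformations, with
  optional superposition of the final onto the first.

## Convergence diagnostics

* **Block analysis:** consecutive equal blocks (default up to 25 ns), the
  trailing partial block discarded; SEM = sd(block means, ddof = 1)/√n.
  With fixed block length the SEM of i.i.d. data scales as n_blocks^(−1/2).
* **Bootstrap:** percentile method for the mean — 1000 resamples with
  replacement, CI from the 2.5th/97.5th percentiles. BCa correction is
  deliberately not used; the percentile convention is the one the interval
  definition states. A pooled mode resamples within each replica and
  combines all resampled means into a single distribution before taking
  percentiles. Long-run coverage at n = 200 Gaussian values is ≈ 94%, the
  familiar mild undercoverage of the percentile method.
* **RMSF window differences:** RMSF computed independently in consecutive
  10 ns windows (each fit to its own mean), |Δ| between non-overlapping
  successive pairs (w1 vs w2, w3 vs w4); shrinking differences over time
  indicate converged fluctuations. Trailing frames not filling a window
  are discarded.

## Correlation network

nDCC is computed from 3-vector displacements about the time-averaged
position (numerator: frame-averaged dot product). Superposition before
nDCC defaults on, removing rigid-body motion; the flag matters under
pulling, where collective drift contributes strongly to raw correlations —
and rigid-fit removal also redistributes designed correlations, which is
why recovery tests run unfitted. A residue with zero displacement variance
gets zero off-diagonal correlation by convention, with a warning. Replica
combination follows two conventions, both exposed: nDCC matrices are
averaged element-wise across replicas; betweenness is computed per replica
and then averaged.

Pair classification uses the ±0.25 band with boundary values assigned to
the coupled bins, so the partition is total and deterministic
(open-interval definitions leave exact boundary values unassigned).

Graph construction: edge iff |C_ij| > 0.30 and d_ij < 7 Å, where d_ij is
the frame-averaged Cα–Cα distance (stable and seedless; a single-frame
option exists). Weights w_ij = −log|C_ij| ≥ 0. Betweenness uses weighted
(Dijkstra) shortest paths with exact tie splitting (Brandes accumulation,
via NetworkX) and the pair-count normalization 2/((n−1)(n−2)); the
normalization convention is stated in report headers because different
graph libraries default differently. Weighted rather than hop-count paths
are primary: the weight definition exists precisely to grade path strength.
Isolated residues stay in the graph with zero centrality; disconnected
pairs contribute nothing.

Domain aggregation reports per-domain mean centrality, the
condition/control ratio, percent difference, and the count of hub residues
with C_B ≥ 2 × the control mean over **all** residues (global-mean
convention; a per-residue-control variant is available behind a flag).
Note an arithmetic consequence of the global-mean convention: doubling
every residue's centrality flags exactly those residues at or above the
control mean, not all residues — only the per-residue variant flags all.

## PCA

Covariance is the sample covariance (ddof = 1) of the flattened superposed
coordinates. Modes are eigenpairs in descending order; each eigenvector's
sign is fixed to have non-negative projection onto the net first-to-last
frame displacement (falling back to first-nonzero-component-positive), so
porcupine arrow directions are reproducible run to run. Porcupine arrows
are mode components × √eigenvalue × user scale, so length encodes motion
amplitude; a raw-eigenvector mode is available via scale alone. PCA runs
per replica by default. Domain centre-of-geometry displacement is
last-minus-first frame per domain after fitting the trajectory to its
mean; a no-fit mode measures it in the pulling frame, which is the
appropriate frame when the displacement of interest *is* the drift.

## Pipeline

A single JSON config drives the multi-condition comparison. A condition
labeled `control` anchors all normalizations. Every CSV carries a header
with the thresholds (c_min, d_max, band edge, hub factor), superposition
flags, seed, package version, and a hash of the analysis parameters, so a
rerun with the same config and seed is byte-identical. Exit codes: 0
success, 2 configuration error, 3 data error.

## Problem sizes and numerical choices

The test and calibration workloads use deliberately small ensembles —
tens of residues, hundreds of frames, three replicas — chosen so the
statistical bounds being asserted (Fisher-z error at 1000 frames, binomial
error of coverage at 500 datasets, chi-distribution moments at 1000
frames) are tight enough to be meaningful while the whole suite stays
interactive. Tolerances: symmetry/diagonal of correlation matrices 1e-10;
eigenvector orthonormality 1e-8; rigid-recovery RMSD 1e-10 nm; exact
(1e-12) agreement between betweenness and brute-force path enumeration.

## Known limitations

No temporal autocorrelation in synthetic data (see above); no
periodic-boundary handling beyond the whole-molecule assumption; no
mass-weighting anywhere; community detection, suboptimal paths and
mutual-information correlations are out of scope. Headline observables of
any real pulling study (multi-nm extensions and RMSDs, condition-specific
pair fractions and hub counts) depend on the deposited trajectories of
that study; this package reproduces the *machinery*, validated on designed
ensembles.
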