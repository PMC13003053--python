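# allodyn

Trajectory analysis of how mechanical force and ligand binding reshape the
internal dynamics of the platelet integrin αIIbβ3 — and, more generally, of
any multi-domain protein whose activation is probed by equilibrium and
steered molecular-dynamics simulation. The package is aimed at
computational structural biologists who have Cα trajectories (equilibrium
or constant-force pulling, several replicas per condition) and want the
standard battery of observables that distinguishes a mechanically activated
ensemble from a biochemically perturbed one:

* **Dynamic cross-correlation.** For residues *i*, *j* with displacements
  Δ**r**ᵢ(t) = **r**ᵢ(t) − ⟨**r**ᵢ⟩,

  C_ij = ⟨Δ**r**ᵢ · Δ**r**ⱼ⟩ / √(⟨Δ**r**ᵢ²⟩⟨Δ**r**ⱼ²⟩) ∈ [−1, 1],

  averaged over replicas, with pairs classified as correlated
  (C ≥ 0.25), non-correlated (−0.25 < C < 0.25) or anti-correlated
  (C ≤ −0.25).
* **Residue interaction network.** Nodes are Cα atoms; an edge (i, j)
  requires |C_ij| > 0.30 **and** mean Cα–Cα distance d_ij < 7 Å (the range
  of noncovalent contacts), weighted w_ij = −log|C_ij|. Weighted
  betweenness centrality C_B(v) = Σ_{s≠v≠t} σ_st(v)/σ_st ranks residues as
  communication hubs; domain-level means, percent changes versus a control
  condition, and counts of high-BC residues (C_B ≥ 2 × control mean)
  summarize allosteric reorganization.
* **Extension, RMSD, RMSF** along the pulling axis and about the mean
  structure, with Kabsch superposition; per-residue displacement between
  input and final conformations.
* **Convergence diagnostics:** block averaging (SEM of consecutive time
  blocks), percentile bootstrap confidence intervals of the mean (1000
  resamples, 2.5th/97.5th percentiles, per-replica and pooled), and
  |ΔRMSF| between successive time windows.
* **PCA:** eigenmodes of the 3n × 3n Cα covariance, porcupine vector
  fields (mode × √eigenvalue), and per-domain centre-of-geometry
  displacement.

Because full-scale MD output is enormous, the package ships a first-class
synthetic-trajectory generator: multi-replica Cα ensembles with *designed*
block correlation structure (domain coupling), optional cumulative drift
along a pulling axis (force-like extension), and Gaussian noise. The
designed correlation matrix is the analytic expectation of the nDCC
estimator, so every stage of the pipeline is testable against known ground
truth.

## Worked example

```python
from allodyn import (SyntheticSpec, generate_ensemble, ndcc_matrix,
                     average_matrices, classify_pairs, mean_distance_matrix,
                     build_graph, betweenness, rmsd_series, bootstrap_ci)

spec = SyntheticSpec(
    n_residues=60, n_frames=500,
    domain_blocks=(("head", 0, 30), ("leg", 30, 60)),
    intra_block_corr=0.6, inter_block_corr=0.2,
    noise_sd=0.1, seed=11,
)
reference, designed, replicas = generate_ensemble(spec)

mats = [ndcc_matrix(t, superpose=False) for t in replicas]
frac = classify_pairs(average_matrices(mats))
print(f"correlated {frac.correlated:.1%}  non-correlated {frac.non_correlated:.1%}"
      f"  anti-correlated {frac.anti_correlated:.1%}")

g = build_graph(mats[0], mean_distance_matrix(replicas[0]))
bc = betweenness(g)
print(f"edges {g.number_of_edges()}  max BC {bc.values.max():.3f}"
      f" at residue {bc.labels[int(bc.values.argmax())]}")

rmsd = rmsd_series(replicas[0], replicas[0].coords[0])
ci = bootstrap_ci(rmsd.values, seed=0)
print(f"mean RMSD {ci.point:.3f} nm, 95% CI [{ci.lower:.3f}, {ci.upper:.3f}]")
```

prints

```
correlated 49.2%  non-correlated 50.8%  anti-correlated 0.0%
edges 58  max BC 0.123 at residue A:15
mean RMSD 0.158 nm, 95% CI [0.157, 0.160]
```

Half the residue pairs are within-domain pairs designed at C = 0.6 and land
in the correlated band; the weak cross-domain coupling (0.2) stays
non-correlated, so the correlated fraction is the within-domain pair
fraction, ≈ 49%. The residue graph of the extended chain links spatially
adjacent, strongly coupled neighbours, so the highest-betweenness residue
sits mid-domain; and the bootstrap CI of the mean RMSD is tight because the
frames are independent draws around a static reference.

The same analyses run from the shell — `allodyn generate`, `inspect`,
`metrics`, `ndcc`, `network`, `pca`, and `allodyn run --config run.json`
for the full multi-condition comparison (control-normalized centrality
tables, pair-fraction tables, per-condition CSV reports with every
threshold and seed recorded in the header).

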