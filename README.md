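# voxflex

Quantify and **localize conformational flexibility and surface plasticity**
of protein ensembles — and compare two ensembles (for example a naïve and an
affinity-matured antibody fragment) for rigidification.

Antibody binding sites, and the CDR-H3 loop in particular, often rigidify
during affinity maturation: the mature antibody samples fewer loop
conformations and presents a less variable molecular surface. `voxflex`
measures this from conformational ensembles (multi-model PDB files, e.g.
MD trajectory snapshots) along two complementary axes:

1. **Flexibility metrics** — pairwise Cα 2D-RMSD matrices, average-linkage
   (UPGMA) cluster counts at a distance cutoff (default 1.2 Å), per-atom RMSF
   and crystallographic B-factors (B = 8π²/3 · RMSF²), and ψ-torsion
   (sin, cos) features.
2. **Voxel-occupancy plasticity maps** — the package's core method. After
   aligning all frames to a common scaffold frame, each voxel of a grid over
   the protein is marked occupied (1) when its center lies inside any heavy
   atom's van der Waals sphere. The per-voxel mean over frames is the average
   protein surface; the per-voxel standard deviation, which for binary
   occupancy equals √(p(1−p)), highlights regions that are sometimes
   protein-occupied and sometimes solvent-exposed. Both grids are smoothed
   with a 3-D Gaussian (σ = 1.5 Å). The **global plasticity** scalar is the
   volume integral of the smoothed SD grid over supra-threshold voxels (Å³);
   **localization** attributes each such voxel to the residue of its nearest
   heavy atom, and a difference grid (naïve − matured) maps where plasticity
   was lost.

A minimal kinetics stack (tICA → k-means microstates → Markov-state model
with stationary distribution π, implied timescales tᵢ = −τ/ln λᵢ, crisp
PCCA-style macrostates and a Chapman–Kolmogorov test) reconstructs the
thermodynamics and kinetics of loop-state transitions from the same
ψ-torsion features.

A seeded synthetic-ensemble generator with closed-form ground truth
(fluctuation magnitudes, two-state loop kinetics, occupancy statistics)
backs the test suite and provides ready-made flexible-vs-rigid fixtures.

## Worked example

Generate a flexible ("naive", σ_loop = 1.0 Å with two-state hopping) and a
rigid ("matured", σ_loop = 0.2 Å) synthetic ensemble pair of 200 frames,
then run the full comparison:

```sh
voxflex synth --preset naive-matured --seed 1 -o fixtures
voxflex compare fixtures/naive.pdb fixtures/matured.pdb -o out
```

which prints:

```json
{"cluster_count": {"naive": 147, "matured": 1},
 "global_plasticity_A3": {"naive": 1077.65, "matured": 482.76},
 "loop_rmsf_mean_A": {"naive": 2.289, "matured": 0.453}}
```

Reading the numbers: the flexible loop scatters its 200 frames over 147 RMSD
clusters at the 1.2 Å cutoff while the rigid loop collapses into one; the
flexible ensemble's smoothed occupancy-SD integral (1078 Å³) is more than
twice the rigid one's (483 Å³ — the residual coming from scaffold thermal
noise and surface boundary voxels); and the loop Cα RMSF drops from 2.29 Å
(≈ √(3σ² + d²/4) for σ = 1 Å and a 3 Å two-state displacement) to 0.45 Å.
`out/` additionally contains the per-frame cluster labels, RMSF/B-factor and
per-residue plasticity CSV tables, smoothed mean/SD grids and the
naïve−matured difference grid as OpenDX files, a B-factor-encoded PDB for
visualizing localized plasticity, and the full `report.json`.

The same analyses are available as library functions
(`voxflex.occupancy_stats`, `voxflex.gauss_filter`,
`voxflex.global_plasticity`, `voxflex.average_linkage_cluster`,
`voxflex.tica`, `voxflex.estimate_msm`, …) operating on `Ensemble` objects
from `voxflex.read_pdb_ensemble` or the `voxflex.synthetic` generator.

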