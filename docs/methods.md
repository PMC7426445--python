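# Methods

## Scope and data model

`voxflex` analyses conformational ensembles: a fixed topology (atoms,
residues, chains, Bondi-style van der Waals radii) plus F frames of Cartesian
coordinates in Å, read from multi-model PDB files or produced by the built-in
synthetic generator. Internal atom and residue indices are 0-based; author
residue numbers are preserved for selections and output but never used as
array indices. Waters (HOH/WAT) are excluded on reading by default.
Hydrogens are kept in the topology but excluded from occupancy grids by
default (`selection="heavy"`); a flag includes them, since ensembles from
different sources differ in whether hydrogens are present at all.

## Superposition

All analyses assume a common coordinate frame. Frames are superposed by the
standard least-squares rigid fit (SVD of the weighted covariance, reflection
excluded by sign-correcting the smallest singular vector), with uniform
weights — the convention that matches Cα-RMSD-based flexibility analyses.
The default fitting mask is the *scaffold* (the complement of the analyzed
loop): fitting on the loop itself would absorb part of the loop motion into
the superposition and understate its flexibility. `align_ensemble` supports
a frame reference or an iterated mean reference (fit → recompute mean until
the mean moves < 1e-6 Å RMS or 20 iterations; the iteration is seeded with a
frame-0 fit so the overall placement is fixed). For two-ensemble comparisons
`pair_align` brings both ensembles onto the mean scaffold structure of the
first, ending with a one-shot fit of both to that same reference so that an
identical pair maps to bitwise-comparable coordinates. Making the
common-frame step explicit is a deliberate design choice: difference grids
are meaningless unless both maps live in one frame.

## Flexibility metrics

- **2D-RMSD**: pairwise frame-to-frame RMSD over a selection (default: loop
  Cα), pairwise-refit by default. The fitted pairwise RMSD is computed from
  the singular values of each pair's 3×3 correlation matrix, which equals
  the Kabsch minimum.
- **RMSF/B-factor**: rmsf_i = √⟨|x_i(f) − ⟨x_i⟩|²⟩ on the pre-aligned
  ensemble; B = (8π²/3)·RMSF², the isotropic Debye–Waller relation — the
  standard crystallographic convention.
- **ψ torsions**: the signed N–CA–C–N′ dihedral per residue (atan2 form,
  IUPAC sign convention, validated against an independent trajectory-analysis
  library), mapped to (−π, π]. Features are per-residue (sin ψ, cos ψ)
  pairs, interleaved in residue order. Chain-terminal residues without a
  following N are dropped with a logged notice. `metadynamics_cv` exposes
  the corresponding linear-combination collective variable (all-ones
  coefficients by default — the plain sum — since no canonical weights
  exist); it is a descriptor only, no biasing is performed.

## Clustering

`average_linkage_cluster` is unweighted average linkage (UPGMA: the
arithmetic mean over all cross-pairs of the *raw* distance matrix, maintained
efficiently by the Lance–Williams update) with epsilon-style termination:
agglomeration stops *before* the first merge whose linkage distance would
exceed the cutoff, which guarantees every pair of final clusters has average
inter-cluster distance strictly above the cutoff. Merge ties break to the
lexicographically lowest cluster-index pair; final labels are ordered by
decreasing cluster size (ties by lowest member frame); representatives are
the member with minimal average distance to the rest of the cluster (ties to
the lowest frame index). The default distance is pairwise-fitted loop-Cα
RMSD; pre-aligned (unfitted) distances are available via
`rmsd_matrix(..., fit=False)`. The cluster count at a 1.2 Å cutoff is the
headline flexibility metric; `cluster_count_sweep` checks its robustness
across cutoffs.

## Occupancy plasticity

**Occupancy definition.** Per frame, a voxel is occupied (1) iff its center
lies within `vdw_radius + probe` of any selected atom (probe default 0 Å).
Binary occupancy is the simplest definition under which "sometimes occupied,
sometimes solvent-exposed" maps exactly onto high per-voxel SD, and it gives
a free correctness oracle: the population SD of a 0/1 variable is
√(p(1−p)), so the SD grid is checked voxelwise against per-frame grids.

**Grid geometry.** Isotropic spacing (default 1.0 Å); the grid covers the
bounding box of all heavy atoms of all frames of all input ensembles,
inflated by `padding` (default 4.0 Å) plus the largest vdW radius on every
side. Voxel centers are at `origin + (i+½)·spacing`. The margin guarantees
the protein never touches the grid edge, which in turn makes the Gaussian
smoothing mass-preserving in practice.

**Smoothing.** Separable 3-D Gaussian, σ in Å (default 1.5 Å = 1.5 voxels at
default spacing), kernel truncated at 4σ, unit-sum, reflect padding. Raw SD
grids are speckled — even rigid surfaces produce scattered partially
occupied boundary voxels — and smoothing pools these into coherent regions.
Both mean and SD grids are smoothed, but scoring and localization consume
only the smoothed SD: the SD is the plasticity signal.

**Scoring and localization.** Global plasticity = Σ value·spacing³ over
voxels above a threshold (default 0.05, dimensionless on the SD scale
[0, 0.5]), giving an SD-weighted volume in Å³. Localization assigns each
supra-threshold voxel to the residue of its nearest heavy atom in the
*ensemble-mean* structure when within `max_dist` (default 4.0 Å), else to an
"unassigned" bucket; the attribution uses a single stable address space (the
mean structure) rather than per-frame nearest atoms. Per-residue scores plus
the unassigned remainder reproduce the global integral exactly (a tested
conservation property). Difference grids are elementwise A − B on identical
grid geometry; positive values mean more plasticity in A.

Defaults (spacing 1.0 Å, σ 1.5 Å, probe 0 Å, threshold 0.05, padding 4.0 Å)
are package choices, exposed in the config and recorded in output metadata.
The global score is therefore comparable only between runs with identical
grid protocol — which `pair_align` + a shared `GridSpec` enforce for pairs.

## Kinetics stack

- **tICA** at lag τ (frames): mean-free features, instantaneous covariance
  C00 symmetrized over both lag windows, time-lagged covariance symmetrized
  as (C + Cᵀ)/2, generalized eigenproblem C0τ v = λ C00 v with ε·I
  (ε = 1e-10) regularization on C00; eigenvalues sorted descending. The
  symmetrized estimator makes the spectrum real and time-reversal invariant.
- **Microstates**: seeded k-means++ (scikit-learn, `n_init=1`,
  tol 1e-6, ≤ 500 iterations) on the leading tICs; deterministic given the
  seed.
- **MSM**: sliding-window transition counts at lag τ, restricted to the
  largest strongly connected component (active set; retained count fraction
  reported). Reversible estimation symmetrizes counts, (C + Cᵀ)/2, then
  row-normalizes — detailed balance holds by construction, and π is the
  normalized row-sum vector. This is an approximation to the full reversible
  maximum-likelihood estimator, adequate for well-sampled chains; the full
  MLE is a possible extension. Implied timescales tᵢ = −τ/ln λᵢ; λ ≤ 0
  yields NaN (undefined marker).
- **Macrostates**: crisp spectral lumping — k-means on each microstate's
  coordinates in the first n right eigenvectors of T (computed through the
  π-symmetrized similarity transform) — rather than the fuzzy-membership
  PCCA+ optimization. This reproduces block structure exactly for nearly
  decomposable chains, the regime the tests exercise, and is flagged as a
  simplification. Macrostate populations are Σπ over members; a π-weighted
  coarse transition matrix is provided.
- **Validation**: implied-timescale flatness across lags and the
  Chapman–Kolmogorov test (T(τ)^k vs a fresh estimate at kτ on the common
  active set, max-abs deviation reported).

Lags are in frames throughout the library; the CLI converts from time given
a frame-interval option.

## Synthetic generator

The generator emulates the flexible-naïve vs rigid-matured contrast with
closed-form ground truth. A scaffold chain S (default 30 residues) traces a
non-planar path of exact 3.8 Å Cα steps — non-planarity matters: a collinear
scaffold would leave one rotational degree of freedom undetermined in a
scaffold-only fit — and a loop chain H (default 8 residues, numbered 95–102
in the CDR-H3 spirit) runs parallel to it. Backbone N/CA/C/O atoms are
placed planar-trans, so the base ψ is exactly 180°. Frames are i.i.d.
isotropic Gaussian displacements (σ_scaffold = 0.2 Å, σ_loop configurable);
in two-state mode the loop additionally toggles between its base position
and a rigid 3.0 Å offset via a symmetric Markov chain with switch
probability q = 0.1 per frame, giving π = (½, ½), λ₂ = 1 − 2q, and
half-occupancy (maximal-SD) voxels in the state-specific volume. The hidden
state trajectory is stored in the ensemble metadata as kinetics ground
truth. Expectations used in tests: per-atom RMSF = σ√3 for i.i.d. isotropic
noise, √(3σ² + d²/4) with the symmetric two-state offset d.

The default naïve/matured pair (σ_loop 1.0 Å two-state vs 0.2 Å
single-state, 200 frames each, shared scaffold statistics) was chosen once
as a realistic desk-scale analogue of the contrast between a multi-state
flexible loop and a rigidified one. What the generator does *not* emulate:
temporally correlated thermal motion (frames are i.i.d. apart from the
two-state chain), side chains, solvent, anharmonic backbone geometry
changes, or physically realistic force-field dynamics. Passing tests
therefore demonstrate the correctness of the *measurement* chain — that the
metrics order known-flexible above known-rigid and recover known parameters
— not that any particular real antibody behaves this way.

## Numerical choices and degenerate inputs

- Kabsch requires ≥ 3 atoms; rank-deficient (collinear) point sets still
  return a valid proper-rotation minimizer via SVD.
- Single-frame ensembles: RMSF warns and returns zeros; clustering returns
  one cluster; SD grids are identically zero and the global plasticity of a
  static ensemble is exactly 0 (binary occupancy makes this exact, not just
  approximate).
- PDB B-factor output clips to [0, 999.99] with a logged warning and uses
  the fixed-column `%6.2f` format; coordinates round-trip to the PDB's
  1e-3 Å precision; OpenDX grids round-trip metadata exactly and values to
  1e-5 relative (8-significant-digit output).
- Unknown elements get the default 1.70 Å radius with a logged warning.
- Clustering and k-means tie-breaks are deterministic (documented above), so
  repeated runs with one seed are bit-reproducible.

## Problem sizes

Test and acceptance runs use 60–400-frame synthetic ensembles (200 frames
for the default pair), 10⁵-step chains for kinetic parameter recovery and
5 × 10⁴-step AR(1) series for tICA recovery — sizes at which the closed-form
expectations hold to the stated tolerances (2 % on π, 5 % on t₂ and on the
tICA eigenvalue) while a full suite completes in about a minute.

## Known limitations

- Occupancy is full-volume, not a surface shell; a shell extraction (e.g.
  morphological gradient of the mean grid) is future work.
- The reversible MSM estimator and the crisp macrostate assignment are
  simplifications (see above); Bayesian error bars are out of scope.
- No mmCIF, no binary trajectory writing; XTC/DCD reading is possible via
  external conversion to multi-model PDB.
- Global plasticity depends on the grid protocol (spacing, σ, threshold);
  only like-for-like comparisons are meaningful.
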