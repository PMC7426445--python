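"""Synthetic conformational ensembles with known ground truth.

Toy poly-alanine-like systems: a rigid scaffold chain ("S") standing in for
the antibody framework and a separate loop segment (chain "H", author residue
numbers starting at 95, echoing CDR-H3 numbering) whose fluctuation magnitude
and state kinetics are dialled in exactly.  Every quantity the analysis
modules measure — RMSF, cluster counts, occupancy statistics, two-state
stationary populations and relaxation times — has a closed-form expectation
under this generator, so each stage of the pipeline can be validated without
external data.

Frames are i.i.d. isotropic Gaussian displacements of the base geometry
(per-axis σ as configured), except the optional two-state loop mode, where the
whole loop additionally toggles between its base position and a rigidly
displaced alternative via a symmetric two-state Markov chain: switch
probability q per frame gives π = (½, ½) and λ₂ = 1 − 2q, and voxels covered
in only one of the two states are occupied in about half the frames —
maximal-SD territory.

The default naïve/matured pair contrasts a flexible two-state loop
(σ_loop = 1.0 Å) with a rigid single-state one (σ_loop = 0.2 Å) over an
identically fluctuating scaffold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import Atom, Ensemble, Topology

CA_SPACING = 3.8  # consecutive Cα distance, Å

# backbone atom offsets from the residue's Cα, chosen planar-trans so the
# psi dihedral of the base geometry is exactly 180 degrees
_BACKBONE_OFFSETS = {
    "N": np.array([-1.2, 0.8, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.2, 0.8, 0.0]),
    "O": np.array([1.2, 2.0, 0.0]),
}
_BACKBONE_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O"}
_LOOP_FIRST_RESSEQ = 95
_LOOP_OFFSET = np.array([0.0, 8.0, 0.0])  # loop chain placed parallel to scaffold


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic two-chain ensemble.

    σ values are per-axis Gaussian displacement scales in Å;
    ``state_displacement`` is the rigid offset of the loop's second state and
    ``p_switch`` the per-frame switching probability of the symmetric
    two-state chain.
    """

    n_residues_scaffold: int = 30
    n_residues_loop: int = 8
    sigma_scaffold: float = 0.2
    sigma_loop: float = 1.0
    two_state: bool = False
    state_displacement: float = 3.0
    p_switch: float = 0.1
    n_frames: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_scaffold < 0 or self.sigma_loop < 0:
            raise ValueError("sigmas must be non-negative")
        if not 0.0 <= self.p_switch <= 1.0:
            raise ValueError("p_switch must lie in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")


# scaffold Cα steps cycle through four tilted directions (each of length 1) so
# the scaffold trace is non-planar and pins all six rigid degrees of freedom
# in a scaffold-only superposition; the loop chain stays straight.
_SCAFFOLD_STEPS = np.array(
    [[1.0, 0.35, 0.0], [1.0, 0.0, 0.35], [1.0, -0.35, 0.0], [1.0, 0.0, -0.35]]
)
_SCAFFOLD_STEPS /= np.linalg.norm(_SCAFFOLD_STEPS, axis=1, keepdims=True)


def make_toy_topology(spec: SyntheticSpec) -> tuple[Topology, np.ndarray]:
    """Deterministic two-chain backbone topology and base coordinates.

    Scaffold residues trace a non-planar 3.8 Å-per-step path on chain S; loop
    residues run straight along x on chain H, offset in y, numbered from 95.
    """
    atoms: list[Atom] = []
    residues: list[tuple[str, str, str]] = []
    coords: list[np.ndarray] = []
    serial = 1

    def add_chain(chain_id: str, n_res: int, first_seq: int, origin: np.ndarray,
                  nonplanar: bool = False):
        nonlocal serial
        ca = origin.astype(float).copy()
        for r in range(n_res):
            res_index = len(residues)
            residues.append((chain_id, str(first_seq + r), "ALA"))
            if r > 0:
                step = (
                    _SCAFFOLD_STEPS[(r - 1) % len(_SCAFFOLD_STEPS)]
                    if nonplanar
                    else np.array([1.0, 0.0, 0.0])
                )
                ca = ca + CA_SPACING * step
            for name in ("N", "CA", "C", "O"):
                atoms.append(
                    Atom(
                        serial=serial,
                        name=name,
                        element=_BACKBONE_ELEMENTS[name],
                        vdw_radius={"C": 1.70, "N": 1.55, "O": 1.52}[_BACKBONE_ELEMENTS[name]],
                        residue_index=res_index,
                        residue_name="ALA",
                        residue_seq=str(first_seq + r),
                        chain_id=chain_id,
                    )
                )
                coords.append(ca + _BACKBONE_OFFSETS[name])
                serial += 1

    add_chain("S", spec.n_residues_scaffold, 1, np.zeros(3), nonplanar=True)
    add_chain("H", spec.n_residues_loop, _LOOP_FIRST_RESSEQ, _LOOP_OFFSET)
    return Topology(atoms=tuple(atoms), residues=tuple(residues)), np.array(coords)


def generate_ensemble(spec: SyntheticSpec) -> Ensemble:
    """Sample an ensemble from the spec's fluctuation and kinetics model.

    Ensemble metadata records the spec, the seed, and — in two-state mode —
    the hidden per-frame state trajectory (the kinetics ground truth).
    """
    topology, base = make_toy_topology(spec)
    rng = np.random.default_rng(spec.seed)
    n_atoms = base.shape[0]
    loop_mask = np.array([a.chain_id == "H" for a in topology.atoms])

    sigma = np.where(loop_mask, spec.sigma_loop, spec.sigma_scaffold)
    noise = rng.normal(size=(spec.n_frames, n_atoms, 3)) * sigma[None, :, None]
    coords = base[None, :, :] + noise

    states = np.zeros(spec.n_frames, dtype=int)
    if spec.two_state:
        flips = rng.random(spec.n_frames - 1) < spec.p_switch
        states[1:] = np.cumsum(flips) % 2
        offset = np.array([0.0, 0.0, spec.state_displacement])
        coords[np.ix_(states == 1, np.flatnonzero(loop_mask))] += offset

    metadata = {
        "generator": "voxflex.synthetic",
        "seed": spec.seed,
        "spec": spec,
        "rng": "numpy.random.default_rng(PCG64)",
    }
    if spec.two_state:
        metadata["state_trajectory"] = states
    return Ensemble(topology=topology, coords=coords, metadata=metadata)


def naive_matured_pair(
    seed: int = 0, n_frames: int = 200
) -> tuple[Ensemble, Ensemble]:
    """A flexible "naïve" and a rigid "matured" ensemble on one topology.

    Ground truth by construction: the naïve ensemble has the larger loop RMSF,
    more RMSD clusters at any cutoff, larger global plasticity and broader
    occupancy-SD support; scaffold statistics are identical (same σ, different
    random streams).
    """
    naive_spec = SyntheticSpec(
        sigma_loop=1.0, two_state=True, n_frames=n_frames, seed=seed,
    )
    matured_spec = SyntheticSpec(
        sigma_loop=0.2, two_state=False, n_frames=n_frames, seed=seed + 1_000_003,
    )
    return generate_ensemble(naive_spec), generate_ensemble(matured_spec)
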