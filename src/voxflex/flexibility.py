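"""Per-atom and per-residue flexibility metrics: 2D-RMSD, RMSF, B-factors, ψ torsions.

The 2D-RMSD matrix (pairwise frame-to-frame Cα RMSD over a loop selection) and
per-atom RMSF are the classical flexibility readouts that accompany the voxel
plasticity maps.  B-factors follow the isotropic Debye–Waller convention
B = (8π²/3)·RMSF².  ψ backbone torsions, expressed as per-residue (sin ψ,
cos ψ) pairs, are the featurization used for the kinetics stack and for
torsion-space collective variables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import Ensemble, Selection, resolve_selection
from .superpose import kabsch

logger = logging.getLogger("voxflex")

BFACTOR_CONSTANT = 8.0 * np.pi**2 / 3.0


@dataclass(frozen=True)
class RmsdMatrix:
    """Symmetric F×F matrix of pairwise frame RMSDs over a selection."""

    values: np.ndarray
    selection: Selection
    fitted: bool

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RMSD matrix must be square")
        if not np.allclose(v, v.T, atol=1e-8) or np.any(np.diag(v) > 1e-8) or np.any(v < 0):
            raise ValueError("RMSD matrix must be symmetric, non-negative, zero-diagonal")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class FlexibilityProfile:
    """Per-selected-atom RMSF (Å) and derived B-factor (Å²)."""

    selection: Selection
    rmsf: np.ndarray
    bfactor: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.rmsf < 0):
            raise ValueError("RMSF must be non-negative")


@dataclass(frozen=True)
class TorsionFeatures:
    """ψ torsions (F×R, radians in (−π, π]) and their (sin, cos) feature matrix.

    ``features`` is F×2R with columns interleaved per residue:
    (sin ψ₁, cos ψ₁, sin ψ₂, cos ψ₂, …), in the order of ``residues``.
    """

    psi: np.ndarray
    features: np.ndarray
    residues: tuple[tuple[str, str], ...]  # (chain_id, residue_seq)

    @property
    def n_residues(self) -> int:
        return len(self.residues)


def rmsd_matrix(ensemble: Ensemble, selection: Selection | str, fit: bool = True) -> RmsdMatrix:
    """Pairwise frame-to-frame RMSD over a selection (the 2D-RMSD plot).

    ``fit=True`` refits each frame pair by a rigid superposition on the
    selection atoms; ``fit=False`` uses the coordinates as given (the ensemble
    should already be aligned).
    """
    if isinstance(selection, str):
        selection = resolve_selection(ensemble.topology, selection)
    idx = selection.indices
    X = ensemble.coords[:, idx, :]
    F = X.shape[0]
    values = np.zeros((F, F))
    if fit:
        centred = X - X.mean(axis=1, keepdims=True)
        sq = np.einsum("fij,fij->f", centred, centred)
        n = X.shape[1]
        for i in range(F):
            for j in range(i + 1, F):
                # minimized RMSD from the SVD of the 3x3 correlation matrix
                H = centred[i].T @ centred[j]
                S = np.linalg.svd(H, compute_uv=False)
                d = np.sign(np.linalg.det(centred[i].T @ centred[j]))
                if d < 0:
                    S = S.copy()
                    S[-1] = -S[-1]
                msd = (sq[i] + sq[j] - 2.0 * S.sum()) / n
                values[i, j] = values[j, i] = np.sqrt(max(msd, 0.0))
    else:
        for i in range(F):
            diff = X[i + 1:] - X[i]
            if diff.size:
                r = np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1))
                values[i, i + 1:] = r
                values[i + 1:, i] = r
    return RmsdMatrix(values=values, selection=selection, fitted=fit)


def rmsf(ensemble: Ensemble, selection: Selection | str) -> FlexibilityProfile:
    """Root-mean-square fluctuation per selected atom, on a pre-aligned ensemble.

    rmsf[i] = sqrt(mean over frames of |x_i(f) − ⟨x_i⟩|²); the B-factor column
    applies B = (8π²/3)·RMSF².  A single-frame ensemble gives all zeros.
    """
    if isinstance(selection, str):
        selection = resolve_selection(ensemble.topology, selection)
    idx = selection.indices
    X = ensemble.coords[:, idx, :]
    if X.shape[0] == 1:
        logger.warning("RMSF of a single-frame ensemble is identically zero")
    mean = X.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum((X - mean) ** 2, axis=2), axis=0))
    return FlexibilityProfile(
        selection=selection,
        rmsf=fluct,
        bfactor=BFACTOR_CONSTANT * fluct**2,
    )


def _dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Signed dihedral of four points (broadcast over leading axes), IUPAC sign."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(b2 / np.linalg.norm(b2, axis=-1, keepdims=True), n1)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    return np.arctan2(y, x)


def psi_features(ensemble: Ensemble, residue_selection: str) -> TorsionFeatures:
    """ψ torsions (N–CA–C–N′ dihedral) for each selected residue, all frames.

    Residues missing any of the four atoms — in particular chain-terminal
    residues without a following N — are dropped with a logged notice.
    """
    topo = ensemble.topology
    sel = resolve_selection(topo, residue_selection)
    selected_residues = sorted(
        {topo.atoms[i].residue_index for i in sel.resolved_indices}
    )

    # backbone atom lookup: residue_index -> {atom name: atom position}
    backbone: dict[int, dict[str, int]] = {}
    for i, atom in enumerate(topo.atoms):
        if atom.name in ("N", "CA", "C"):
            backbone.setdefault(atom.residue_index, {})[atom.name] = i

    quads: list[tuple[int, int, int, int]] = []
    kept: list[tuple[str, str]] = []
    for r in selected_residues:
        this = backbone.get(r, {})
        chain = topo.residues[r][0]
        nxt = backbone.get(r + 1, {})
        next_same_chain = r + 1 < len(topo.residues) and topo.residues[r + 1][0] == chain
        if {"N", "CA", "C"} <= this.keys() and next_same_chain and "N" in nxt:
            quads.append((this["N"], this["CA"], this["C"], nxt["N"]))
            kept.append((chain, topo.residues[r][1]))
        else:
            logger.info(
                "residue %s%s dropped from psi featurization (incomplete N-CA-C-N' quadruple)",
                chain, topo.residues[r][1],
            )
    if not quads:
        raise ValueError("no residue in the selection has a complete N-CA-C-N' quadruple")

    q = np.array(quads)  # (R, 4)
    C = ensemble.coords
    psi = _dihedral(C[:, q[:, 0]], C[:, q[:, 1]], C[:, q[:, 2]], C[:, q[:, 3]])  # (F, R)
    # map −π to +π so the range is (−π, π]
    psi = np.where(np.isclose(psi, -np.pi), np.pi, psi)

    F, R = psi.shape
    features = np.empty((F, 2 * R))
    features[:, 0::2] = np.sin(psi)
    features[:, 1::2] = np.cos(psi)
    return TorsionFeatures(psi=psi, features=features, residues=tuple(kept))


def metadynamics_cv(features: TorsionFeatures, coefficients: np.ndarray | None = None) -> np.ndarray:
    """Linear combination of the (sin ψ, cos ψ) features: one scalar per frame.

    This is the torsion-space collective variable used to bias enhanced
    sampling; here it serves purely as a 1-D descriptor (no biasing is
    performed).  Coefficients default to all ones (a plain sum).
    """
    if coefficients is None:
        coefficients = np.ones(features.features.shape[1])
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.shape != (features.features.shape[1],):
        raise ValueError(
            f"expected {features.features.shape[1]} coefficients "
            f"(2 per residue), got {coefficients.shape}"
        )
    return features.features @ coefficients
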