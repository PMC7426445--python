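"""Rigid-body superposition (Kabsch) and ensemble alignment.

All grid and RMSD analyses assume every frame — and, for two-ensemble
comparisons, both ensembles — lives in one common coordinate frame.  The fit
is an ordinary weighted least-squares rigid superposition with the reflection
branch excluded, computed by singular value decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import Ensemble, Selection, resolve_selection


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation, applied as ``x @ R.T + t``."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthogonal")
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def kabsch(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    Returns the minimizing :class:`RigidTransform` and the minimized RMSD in Å.
    Reflections are excluded by sign-correcting the smallest singular vector.
    Collinear or otherwise degenerate point sets still return a valid
    minimizer (SVD handles rank deficiency).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (N, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 atoms for a rigid fit, got {n}")
    if not (np.all(np.isfinite(mobile)) and np.all(np.isfinite(reference))):
        raise ValueError("coordinates must be finite")

    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()

    mu_m = w @ mobile
    mu_r = w @ reference
    X = mobile - mu_m
    Y = reference - mu_r

    H = (X * w[:, None]).T @ Y
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_r - R @ mu_m

    transformed = X @ R.T
    rmsd = float(np.sqrt(np.sum(w[:, None] * (transformed - Y) ** 2)))
    return RigidTransform(rotation=R, translation=t), rmsd


def _fit_frames_to(coords: np.ndarray, fit_idx: np.ndarray, ref_fit: np.ndarray) -> np.ndarray:
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        tf, _ = kabsch(coords[f, fit_idx], ref_fit)
        out[f] = tf.apply(coords[f])
    return out


def align_ensemble(
    ensemble: Ensemble,
    fit_selection: Selection | str,
    reference: int | str = 0,
    *,
    tol: float = 1e-6,
    max_iter: int = 20,
) -> Ensemble:
    """Superpose every frame onto a reference on the fit-selection atoms.

    ``reference`` is a frame index or ``"mean"``; mean mode iterates
    fit → recompute mean until the mean structure moves less than ``tol`` Å
    (RMS over fit atoms) or ``max_iter`` iterations.
    """
    if isinstance(fit_selection, str):
        fit_selection = resolve_selection(ensemble.topology, fit_selection)
    idx = fit_selection.indices
    coords = ensemble.coords.copy()

    if reference == "mean":
        # seed with frame 0 to fix the overall placement
        coords = _fit_frames_to(coords, idx, coords[0, idx])
        mean_fit = coords[:, idx].mean(axis=0)
        for _ in range(max_iter):
            coords = _fit_frames_to(coords, idx, mean_fit)
            new_mean = coords[:, idx].mean(axis=0)
            shift = float(np.sqrt(np.mean(np.sum((new_mean - mean_fit) ** 2, axis=1))))
            mean_fit = new_mean
            if shift < tol:
                break
    else:
        ref = int(reference)
        coords = _fit_frames_to(coords, idx, coords[ref, idx])

    return Ensemble(
        topology=ensemble.topology,
        coords=coords,
        frame_ids=ensemble.frame_ids,
        metadata=dict(ensemble.metadata),
    )


def pair_align(
    ensemble_a: Ensemble,
    ensemble_b: Ensemble,
    shared_selection: str,
) -> tuple[Ensemble, Ensemble]:
    """Bring two ensembles into one frame via a shared (scaffold) selection.

    Ensemble A is aligned to the mean of its own shared atoms; ensemble B's
    frames are then fitted onto that same mean structure, so difference grids
    and paired plasticity maps are directly comparable.
    """
    sel_a = resolve_selection(ensemble_a.topology, shared_selection)
    sel_b = resolve_selection(ensemble_b.topology, shared_selection)
    if len(sel_a.resolved_indices) != len(sel_b.resolved_indices):
        raise ValueError(
            "shared selection resolves to unequal atom counts: "
            f"{len(sel_a.resolved_indices)} in ensemble A, "
            f"{len(sel_b.resolved_indices)} in ensemble B"
        )
    aligned_a = align_ensemble(ensemble_a, sel_a, reference="mean")
    ref_fit = aligned_a.coords[:, sel_a.indices].mean(axis=0)
    # final one-shot fit of both ensembles to the same reference, so an
    # identical pair maps to identical coordinates
    coords_a = _fit_frames_to(aligned_a.coords, sel_a.indices, ref_fit)
    aligned_a = Ensemble(
        topology=aligned_a.topology, coords=coords_a,
        frame_ids=aligned_a.frame_ids, metadata=aligned_a.metadata,
    )
    coords_b = _fit_frames_to(ensemble_b.coords.copy(), sel_b.indices, ref_fit)
    aligned_b = Ensemble(
        topology=ensemble_b.topology,
        coords=coords_b,
        frame_ids=ensemble_b.frame_ids,
        metadata=dict(ensemble_b.metadata),
    )
    return aligned_a, aligned_b


def mean_structure(ensemble: Ensemble) -> np.ndarray:
    """Per-atom mean coordinates over frames (assumes a pre-aligned ensemble)."""
    return ensemble.coords.mean(axis=0)
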