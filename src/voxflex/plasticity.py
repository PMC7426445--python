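"""Voxel-occupancy plasticity maps: grid statistics, smoothing, scoring, localization.

The central idea: lay an axis-aligned voxel lattice over an aligned ensemble
and, for every frame, mark each voxel as occupied (1) when its center lies
inside the van der Waals sphere of any selected atom, else 0.  The per-voxel
mean over frames is the average protein surface; the per-voxel standard
deviation highlights regions that are sometimes occupied by the protein and
sometimes solvent-exposed — the hallmark of conformational plasticity.  For
binary occupancy the population SD obeys sd = sqrt(p·(1−p)) exactly, peaking
at 0.5 where a voxel is occupied in half the frames.

Raw SD grids are speckled (even rigid regions have a few partially occupied
boundary voxels), so both grids are smoothed with a 3-D Gaussian before
interpretation.  The global plasticity scalar integrates the smoothed SD over
supra-threshold voxels (units Å³); localization attributes each such voxel to
the residue of its nearest heavy atom in the ensemble-mean structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .io_formats import Ensemble, Selection, Topology

GRID_KINDS = ("mean", "sd", "mean_smoothed", "sd_smoothed", "difference")


@dataclass(frozen=True)
class GridSpec:
    """Geometry of an axis-aligned voxel lattice.

    ``origin`` is the low corner of voxel (0,0,0); voxel centers sit at
    ``origin + (i+½, j+½, k+½)·spacing``.  Spacing is isotropic, in Å.
    """

    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if len(self.dims) != 3 or any(d < 1 for d in self.dims):
            raise ValueError("dims must be three positive integers")

    def centers_1d(self, axis: int) -> np.ndarray:
        return self.origin[axis] + (np.arange(self.dims[axis]) + 0.5) * self.spacing

    @property
    def voxel_volume(self) -> float:
        return self.spacing**3

    def same_geometry(self, other: "GridSpec", atol: float = 1e-9) -> bool:
        return (
            self.dims == other.dims
            and abs(self.spacing - other.spacing) <= atol
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass(frozen=True)
class OccupancyGrid:
    """A scalar per voxel on a :class:`GridSpec`; ``kind`` records the statistic."""

    spec: GridSpec
    values: np.ndarray
    kind: str
    n_frames: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != tuple(self.spec.dims):
            raise ValueError(f"values shape {v.shape} does not match dims {self.spec.dims}")
        if self.kind not in GRID_KINDS:
            raise ValueError(f"unknown grid kind {self.kind!r}")


@dataclass(frozen=True)
class PlasticityProfile:
    """Global plasticity integral and its per-residue partition (all in Å³)."""

    per_residue: Mapping[tuple[str, str], float]
    unassigned: float
    global_score: float
    sigma_used: float
    threshold_used: float


# ---------------------------------------------------------------------------
# Grid construction and occupancy statistics
# ---------------------------------------------------------------------------

def _selected_atom_indices(topology: Topology, selection) -> np.ndarray:
    if selection == "heavy":
        return topology.heavy_indices()
    if isinstance(selection, Selection):
        return selection.indices
    raise TypeError("selection must be 'heavy' or a Selection")


def make_grid_spec(
    ensembles: Ensemble | list[Ensemble],
    spacing: float = 1.0,
    padding: float = 4.0,
    *,
    heavy_only: bool = True,
) -> GridSpec:
    """Grid covering the bounding box of all frames of one or two aligned
    ensembles, inflated by ``padding`` plus the largest vdW radius on every side."""
    if isinstance(ensembles, Ensemble):
        ensembles = [ensembles]
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    mins, maxs, max_r = [], [], 0.0
    for ens in ensembles:
        idx = ens.topology.heavy_indices() if heavy_only else np.arange(ens.n_atoms)
        if idx.size == 0:
            raise ValueError("ensemble has no atoms in the grid selection")
        pts = ens.coords[:, idx, :].reshape(-1, 3)
        mins.append(pts.min(axis=0))
        maxs.append(pts.max(axis=0))
        max_r = max(max_r, float(ens.topology.vdw_radii()[idx].max()))
    lo = np.min(mins, axis=0) - (padding + max_r)
    hi = np.max(maxs, axis=0) + (padding + max_r)
    dims = tuple(int(np.ceil((hi[a] - lo[a]) / spacing)) for a in range(3))
    dims = tuple(max(d, 1) for d in dims)
    return GridSpec(origin=lo, spacing=spacing, dims=dims)


def frame_occupancy(
    ensemble: Ensemble,
    frame: int,
    spec: GridSpec,
    selection="heavy",
    probe: float = 0.0,
) -> np.ndarray:
    """Binary occupancy of one frame: voxel center within vdW radius + probe
    of any selected atom.  Raises if a selected atom falls outside the grid."""
    idx = _selected_atom_indices(ensemble.topology, selection)
    radii = ensemble.topology.vdw_radii()[idx] + probe
    coords = ensemble.coords[frame, idx, :]
    occ = np.zeros(spec.dims, dtype=bool)
    cx, cy, cz = (spec.centers_1d(a) for a in range(3))
    h = spec.spacing
    for a, (pos, r) in enumerate(zip(coords, radii)):
        ilo = np.floor((pos - r - spec.origin) / h).astype(int)
        ihi = np.ceil((pos + r - spec.origin) / h).astype(int)
        if np.any(pos < spec.origin) or np.any(
            pos > spec.origin + np.array(spec.dims) * h
        ):
            atom = ensemble.topology.atoms[idx[a]]
            raise ValueError(
                f"frame {frame}: atom serial {atom.serial} ({atom.name}) "
                "lies outside the grid"
            )
        ilo = np.clip(ilo, 0, np.array(spec.dims) - 1)
        ihi = np.clip(ihi, 0, np.array(spec.dims) - 1)
        dx2 = (cx[ilo[0]:ihi[0] + 1] - pos[0]) ** 2
        dy2 = (cy[ilo[1]:ihi[1] + 1] - pos[1]) ** 2
        dz2 = (cz[ilo[2]:ihi[2] + 1] - pos[2]) ** 2
        inside = (
            dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
        ) <= r * r
        occ[ilo[0]:ihi[0] + 1, ilo[1]:ihi[1] + 1, ilo[2]:ihi[2] + 1] |= inside
    return occ


def occupancy_stats(
    ensemble: Ensemble,
    spec: GridSpec,
    selection="heavy",
    probe: float = 0.0,
) -> tuple[OccupancyGrid, OccupancyGrid]:
    """Per-voxel mean and population SD of binary occupancy over all frames.

    For 0/1 occupancy the population SD equals sqrt(p(1−p)) where p is the
    occupied fraction; it is maximal (0.5) for voxels occupied in exactly half
    of the frames — the sometimes-protein, sometimes-solvent regions.
    """
    F = ensemble.n_frames
    acc = np.zeros(spec.dims, dtype=np.int64)
    for f in range(F):
        acc += frame_occupancy(ensemble, f, spec, selection, probe)
    p = acc / F
    # binary occupancy: E[occ²] = E[occ] = p, so population variance = p − p²
    sd = np.sqrt(p * (1.0 - p))
    return (
        OccupancyGrid(spec=spec, values=p, kind="mean", n_frames=F),
        OccupancyGrid(spec=spec, values=sd, kind="sd", n_frames=F),
    )


# ---------------------------------------------------------------------------
# Smoothing and scoring
# ---------------------------------------------------------------------------

def gauss_filter(grid: OccupancyGrid, sigma: float = 1.5) -> OccupancyGrid:
    """Separable 3-D Gaussian smoothing of a grid; ``sigma`` in Å.

    Kernel truncated at 4σ, unit sum, reflect padding at the boundaries (so
    total grid mass is preserved for interior-supported grids).  σ = 0 returns
    the grid unchanged apart from the kind suffix.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if grid.kind in ("mean", "sd"):
        new_kind = grid.kind + "_smoothed"
    else:
        new_kind = grid.kind
    if sigma == 0:
        return OccupancyGrid(spec=grid.spec, values=grid.values.copy(),
                             kind=new_kind, n_frames=grid.n_frames)
    sigma_vox = sigma / grid.spec.spacing
    smoothed = ndimage.gaussian_filter(grid.values, sigma=sigma_vox,
                                       mode="reflect", truncate=4.0)
    return OccupancyGrid(spec=grid.spec, values=smoothed,
                         kind=new_kind, n_frames=grid.n_frames)


def global_plasticity(sd_grid: OccupancyGrid, threshold: float = 0.05) -> float:
    """Volume-weighted integral of the SD grid over supra-threshold voxels (Å³)."""
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("threshold must lie in [0, 0.5]")
    if sd_grid.kind not in ("sd", "sd_smoothed"):
        raise ValueError(f"expected an SD grid, got kind {sd_grid.kind!r}")
    v = sd_grid.values
    return float(v[v > threshold].sum() * sd_grid.spec.voxel_volume)


def localize_plasticity(
    sd_grid: OccupancyGrid,
    topology: Topology,
    reference_coords: np.ndarray,
    max_dist: float = 4.0,
    threshold: float = 0.05,
    sigma_used: float = float("nan"),
) -> PlasticityProfile:
    """Attribute supra-threshold SD voxels to residues of a reference structure.

    Each voxel above ``threshold`` is assigned to the residue of the nearest
    heavy atom in ``reference_coords`` (normally the ensemble mean) if within
    ``max_dist`` Å, otherwise counted as unassigned.  Per-residue score and
    the unassigned remainder sum to the global plasticity integral.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("threshold must lie in [0, 0.5]")
    if sd_grid.kind not in ("sd", "sd_smoothed"):
        raise ValueError(f"expected an SD grid, got kind {sd_grid.kind!r}")
    spec = sd_grid.spec
    mask = sd_grid.values > threshold
    vol = spec.voxel_volume
    heavy = topology.heavy_indices()
    per_residue: dict[tuple[str, str], float] = {
        (c, s): 0.0 for c, s, _ in topology.residues
    }
    unassigned = 0.0
    if mask.any():
        ii, jj, kk = np.nonzero(mask)
        centers = spec.origin + (np.stack([ii, jj, kk], axis=1) + 0.5) * spec.spacing
        tree = cKDTree(np.asarray(reference_coords)[heavy])
        dist, nearest = tree.query(centers)
        vals = sd_grid.values[mask] * vol
        for d, a, v in zip(dist, nearest, vals):
            if d <= max_dist:
                atom = topology.atoms[heavy[a]]
                per_residue[(atom.chain_id, atom.residue_seq)] += v
            else:
                unassigned += v
    global_score = float(sum(per_residue.values()) + unassigned)
    return PlasticityProfile(
        per_residue=per_residue,
        unassigned=float(unassigned),
        global_score=global_score,
        sigma_used=sigma_used,
        threshold_used=threshold,
    )


def plasticity_difference(grid_a: OccupancyGrid, grid_b: OccupancyGrid) -> OccupancyGrid:
    """Elementwise A − B on identical grid geometry; positive = more plasticity in A."""
    if not grid_a.spec.same_geometry(grid_b.spec):
        raise ValueError(
            "grid specs differ: "
            f"A(origin={grid_a.spec.origin.tolist()}, spacing={grid_a.spec.spacing}, "
            f"dims={grid_a.spec.dims}) vs "
            f"B(origin={grid_b.spec.origin.tolist()}, spacing={grid_b.spec.spacing}, "
            f"dims={grid_b.spec.dims})"
        )
    if grid_a.kind != grid_b.kind:
        raise ValueError(f"grid kinds differ: {grid_a.kind!r} vs {grid_b.kind!r}")
    return OccupancyGrid(
        spec=grid_a.spec,
        values=grid_a.values - grid_b.values,
        kind="difference",
        n_frames=max(grid_a.n_frames, grid_b.n_frames),
    )
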