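"""Structures, ensembles, volumetric grids and atom selections: types and I/O.

The package's exchange formats are deliberately plain text: multi-model PDB for
conformational ensembles, OpenDX ``gridpositions counts`` for voxel grids, and
CSV for matrices and per-residue tables.  Internal atom and residue indices are
0-based; author residue numbers from the PDB are preserved for display and
selection but never used as array indices.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

logger = logging.getLogger("voxflex")

# Bondi-style van der Waals radii in Å; unknown elements fall back to carbon.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
}
DEFAULT_VDW_RADIUS = 1.70

#: Residue names treated as solvent and excluded from ensembles by default.
WATER_RESNAMES = frozenset({"HOH", "WAT"})


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    """A single atom of the topology.

    ``residue_index`` is the 0-based position in the owning
    :class:`Topology`'s residue list; ``residue_seq`` is the author-assigned
    residue number from the PDB (a string so insertion codes survive).
    """

    serial: int
    name: str
    element: str
    vdw_radius: float
    residue_index: int
    residue_name: str
    residue_seq: str
    chain_id: str

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError(f"atom {self.serial} {self.name}: empty element")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial} {self.name}: vdw_radius must be > 0")


@dataclass(frozen=True)
class Topology:
    """Ordered atoms plus the residue table they index into."""

    atoms: tuple[Atom, ...]
    residues: tuple[tuple[str, str, str], ...]  # (chain_id, residue_seq, residue_name)

    def __post_init__(self) -> None:
        for atom in self.atoms:
            if not 0 <= atom.residue_index < len(self.residues):
                raise ValueError(
                    f"atom {atom.serial} addresses residue {atom.residue_index} "
                    f"outside residue table of size {len(self.residues)}"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.is_heavy], dtype=int)

    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)


@dataclass
class Ensemble:
    """A conformational ensemble: one topology, F frames of Cartesian Å coordinates."""

    topology: Topology
    coords: np.ndarray  # (F, N, 3) float
    frame_ids: tuple[str, ...] = ()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (F, N, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 1 or self.coords.shape[1] < 1:
            raise ValueError("ensemble needs at least one frame and one atom")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coords have {self.coords.shape[1]} atoms, "
                f"topology has {self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if not self.frame_ids:
            self.frame_ids = tuple(str(i + 1) for i in range(self.n_frames))

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass(frozen=True)
class Selection:
    """A resolved atom selection: the expression and the matching atom indices."""

    expression: str
    resolved_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.resolved_indices) == 0:
            raise ValueError("selection matched no atoms")
        idx = np.asarray(self.resolved_indices)
        if np.any(np.diff(idx) <= 0):
            raise ValueError("resolved indices must be strictly increasing")

    @property
    def indices(self) -> np.ndarray:
        return np.array(self.resolved_indices, dtype=int)


# ---------------------------------------------------------------------------
# Selection language:  chain <id> [resid <a>-<b>] [name <n1,n2,...>]
# ---------------------------------------------------------------------------

_SELECTION_RE = re.compile(
    r"^\s*chain\s+(?P<chain>\S+)"
    r"(?:\s+resid\s+(?P<lo>-?\d+)\s*-\s*(?P<hi>-?\d+))?"
    r"(?:\s+name\s+(?P<names>\S+))?\s*$"
)


def resolve_selection(topology: Topology, expression: str) -> Selection:
    """Resolve a ``chain H resid 95-102 name CA`` style expression to atom indices.

    Clauses are AND-combined; ``resid`` compares against the numeric part of the
    author residue number.  Raises ``ValueError`` if no atom matches.
    """
    m = _SELECTION_RE.match(expression)
    if m is None:
        raise ValueError(
            f"cannot parse selection {expression!r}; expected "
            "'chain <id> [resid <a>-<b>] [name <n1,n2,...>]'"
        )
    chain = m.group("chain")
    lo = int(m.group("lo")) if m.group("lo") is not None else None
    hi = int(m.group("hi")) if m.group("hi") is not None else None
    names = set(m.group("names").split(",")) if m.group("names") else None

    picked = []
    for i, atom in enumerate(topology.atoms):
        if atom.chain_id != chain:
            continue
        if lo is not None:
            seq_num = int(re.match(r"-?\d+", atom.residue_seq).group())
            if not lo <= seq_num <= hi:
                continue
        if names is not None and atom.name not in names:
            continue
        picked.append(i)
    if not picked:
        raise ValueError(f"selection matched no atoms: {expression!r}")
    return Selection(expression=expression, resolved_indices=tuple(picked))


# ---------------------------------------------------------------------------
# Multi-model PDB
# ---------------------------------------------------------------------------

def _infer_element(atom_name: str) -> str:
    """Element from the atom-name columns when columns 77-78 are blank.

    PDB convention: a name starting in column 13 whose first character is a
    letter names the element with that letter (one-letter organic set), except
    names like ``1HB``; names starting in column 13 with a two-letter element
    (CA calcium vs CA alpha-carbon) cannot be distinguished here, so we take
    the protein reading: first alphabetic character.
    """
    stripped = atom_name.strip()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return ""


def _parse_atom_line(line: str, lineno: int):
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16]
        resname = line[17:20].strip()
        chain = line[21]
        resseq = line[22:26].strip() + line[26].strip()  # insertion code appended
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_str = line[54:60].strip() if len(line) > 54 else ""
        occupancy = float(occ_str) if occ_str else 1.0
        element = line[76:78].strip().upper() if len(line) >= 78 else ""
    except ValueError as exc:
        raise ValueError(f"line {lineno}: unreadable coordinates: {exc}") from None
    if not element:
        element = _infer_element(name)
    return serial, name, altloc, resname, chain, resseq, (x, y, z), occupancy, element


def read_pdb_ensemble(
    path: str | Path,
    *,
    exclude_waters: bool = True,
) -> Ensemble:
    """Read a multi-model PDB file into an :class:`Ensemble`.

    Each MODEL record opens a frame; a file without MODEL records is a single
    frame.  All frames must present the same atoms (matched against the first
    model by serial and name).  Altloc conflicts keep the highest-occupancy
    location, ties resolved in favour of blank/'A'.  Waters (HOH/WAT) are
    skipped unless ``exclude_waters=False``.
    """
    path = Path(path)
    models: list[list] = []
    current: list | None = None
    saw_model_record = False

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6]
            if record == "MODEL ":
                saw_model_record = True
                current = []
                models.append(current)
            elif record == "ENDMDL":
                current = None
            elif record in ("ATOM  ", "HETATM"):
                parsed = _parse_atom_line(line, lineno)
                if exclude_waters and parsed[3] in WATER_RESNAMES:
                    continue
                if current is None:
                    if saw_model_record:
                        continue  # atoms after ENDMDL outside any model
                    current = []
                    models.append(current)
                current.append(parsed)

    if not models or not models[0]:
        raise ValueError(f"{path}: no atoms found")

    models = [m for m in models if m]

    # Altloc resolution on the first model defines the canonical atom list.
    def resolve_altlocs(entries):
        best: dict[tuple, tuple] = {}
        order: list[tuple] = []
        for e in entries:
            serial, name, altloc, resname, chain, resseq, xyz, occ, elem = e
            key = (chain, resseq, name)
            if key not in best:
                best[key] = e
                order.append(key)
            else:
                prev = best[key]
                prev_occ, prev_alt = prev[7], prev[2]
                if occ > prev_occ or (occ == prev_occ and altloc in (" ", "A") and prev_alt not in (" ", "A")):
                    best[key] = e
        return [best[k] for k in order]

    first = resolve_altlocs(models[0])
    n_atoms = len(first)

    residues: list[tuple[str, str, str]] = []
    res_index: dict[tuple[str, str], int] = {}
    atoms: list[Atom] = []
    warned_elements: set[str] = set()
    for serial, name, _alt, resname, chain, resseq, _xyz, _occ, elem in first:
        rkey = (chain, resseq)
        if rkey not in res_index:
            res_index[rkey] = len(residues)
            residues.append((chain, resseq, resname))
        if elem not in VDW_RADII and elem not in warned_elements:
            logger.warning("unknown element %r: using default vdW radius %.2f Å", elem, DEFAULT_VDW_RADIUS)
            warned_elements.add(elem)
        atoms.append(
            Atom(
                serial=serial,
                name=name,
                element=elem,
                vdw_radius=VDW_RADII.get(elem, DEFAULT_VDW_RADIUS),
                residue_index=res_index[rkey],
                residue_name=resname,
                residue_seq=resseq,
                chain_id=chain,
            )
        )
    topology = Topology(atoms=tuple(atoms), residues=tuple(residues))

    key_to_pos = {(a.serial, a.name): i for i, a in enumerate(atoms)}
    coords = np.empty((len(models), n_atoms, 3), dtype=float)
    for f, entries in enumerate(models):
        entries = resolve_altlocs(entries)
        if len(entries) != n_atoms:
            raise ValueError(
                f"model {f + 1}: expected {n_atoms} atoms, found {len(entries)}"
            )
        for serial, name, _alt, _resname, _chain, _resseq, xyz, _occ, _elem in entries:
            pos = key_to_pos.get((serial, name))
            if pos is None:
                raise ValueError(
                    f"model {f + 1}: atom serial {serial} name {name!r} "
                    "not present in model 1"
                )
            coords[f, pos] = xyz

    return Ensemble(topology=topology, coords=coords)


def _format_atom_line(atom: Atom, xyz: np.ndarray, bfactor: float = 0.0) -> str:
    name = atom.name
    # PDB column 13 alignment: 1-3 character names start in column 14.
    name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
    seq_m = re.match(r"(-?\d+)(.*)", atom.residue_seq)
    resseq, icode = (seq_m.group(1), seq_m.group(2) or " ") if seq_m else (atom.residue_seq, " ")
    b = min(max(bfactor, 0.0), 999.99)
    return (
        f"ATOM  {atom.serial:>5d} {name_field}"
        f" {atom.residue_name:<3s} {atom.chain_id}{int(resseq):>4d}{icode[:1]}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{b:6.2f}"
        f"          {atom.element:>2s}"
    )


def write_pdb_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Write all frames of an ensemble as a multi-model PDB file."""
    path = Path(path)
    with open(path, "w") as fh:
        for f in range(ensemble.n_frames):
            fh.write(f"MODEL     {f + 1:>4d}\n")
            for a, atom in enumerate(ensemble.topology.atoms):
                fh.write(_format_atom_line(atom, ensemble.coords[f, a]) + "\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_bfactor_pdb(
    ensemble: Ensemble,
    frame: int,
    per_residue_values: Mapping[tuple[str, str], float],
    path: str | Path,
) -> None:
    """Write one frame with per-residue scores in the B-factor column.

    ``per_residue_values`` maps ``(chain_id, residue_seq)`` to a score; atoms of
    unscored residues get 0.00.  Scores outside [0, 999.99] are clipped with a
    logged warning (the column holds 6 characters, 2 decimals).
    """
    path = Path(path)
    topo = ensemble.topology
    with open(path, "w") as fh:
        for a, atom in enumerate(topo.atoms):
            score = float(per_residue_values.get((atom.chain_id, atom.residue_seq), 0.0))
            if not np.isfinite(score):
                raise ValueError(f"non-finite score for residue {atom.chain_id}{atom.residue_seq}")
            if score < 0.0 or score > 999.99:
                logger.warning(
                    "score %.6g for residue %s%s clipped to B-factor range [0, 999.99]",
                    score, atom.chain_id, atom.residue_seq,
                )
            fh.write(_format_atom_line(atom, ensemble.coords[frame, a], bfactor=score) + "\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# OpenDX volumetric grids ("gridpositions counts" dialect, z fastest-varying)
# ---------------------------------------------------------------------------

def write_dx_grid(grid, path: str | Path) -> None:
    """Write an occupancy grid as an OpenDX scalar field.

    Standard DX data ordering: the z index varies fastest.  Grid metadata
    (origin, spacing, dims) round-trips exactly; values to ≤1e-5 relative.
    """
    path = Path(path)
    spec = grid.spec
    nx, ny, nz = spec.dims
    with open(path, "w") as fh:
        fh.write(f"# voxflex occupancy grid, kind={grid.kind}, n_frames={grid.n_frames}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {spec.origin[0]:.6f} {spec.origin[1]:.6f} {spec.origin[2]:.6f}\n")
        fh.write(f"delta {spec.spacing:.6f} 0.000000 0.000000\n")
        fh.write(f"delta 0.000000 {spec.spacing:.6f} 0.000000\n")
        fh.write(f"delta 0.000000 0.000000 {spec.spacing:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n")
        flat = np.asarray(grid.values, dtype=float).reshape(-1)  # C order: z fastest
        for start in range(0, flat.size, 3):
            chunk = flat[start:start + 3]
            fh.write(" ".join(f"{v:.8e}" for v in chunk) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "regular positions regular connections" class field\n')


def read_dx_grid(path: str | Path):
    """Read an OpenDX scalar grid written by :func:`write_dx_grid` (or APBS-style)."""
    from .plasticity import GridSpec, OccupancyGrid  # deferred: avoid cycle

    path = Path(path)
    dims = None
    origin = None
    deltas: list[list[float]] = []
    values: list[float] = []
    n_items = None
    kind = "mean"
    n_frames = 0
    in_data = False

    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                m = re.search(r"kind=(\w+)", stripped)
                if m:
                    kind = m.group(1)
                m = re.search(r"n_frames=(\d+)", stripped)
                if m:
                    n_frames = int(m.group(1))
                continue
            if stripped.startswith("object") and "gridpositions" in stripped:
                tokens = stripped.split()
                try:
                    dims = tuple(int(t) for t in tokens[-3:])
                except ValueError:
                    raise ValueError(f"malformed DX header: bad counts in {stripped!r}")
            elif stripped.startswith("origin"):
                origin = np.array([float(t) for t in stripped.split()[1:4]])
            elif stripped.startswith("delta"):
                deltas.append([float(t) for t in stripped.split()[1:4]])
            elif "data follows" in stripped:
                m = re.search(r"items\s+(\d+)", stripped)
                if m:
                    n_items = int(m.group(1))
                in_data = True
            elif stripped.startswith(("attribute", "component", "object")):
                in_data = False
            elif in_data:
                for tok in stripped.split():
                    try:
                        values.append(float(tok))
                    except ValueError:
                        raise ValueError(f"malformed DX data token {tok!r}")

    if dims is None or origin is None or len(deltas) != 3:
        raise ValueError(f"{path}: malformed DX header (missing counts/origin/delta)")
    expected = dims[0] * dims[1] * dims[2]
    if n_items is not None and n_items != expected:
        raise ValueError(f"{path}: header declares {n_items} items, counts imply {expected}")
    if len(values) != expected:
        raise ValueError(f"{path}: expected {expected} values, found {len(values)}")
    spacing = deltas[0][0]
    spec = GridSpec(origin=np.asarray(origin), spacing=spacing, dims=tuple(dims))
    data = np.array(values, dtype=float).reshape(dims)
    return OccupancyGrid(spec=spec, values=data, kind=kind, n_frames=n_frames)


# ---------------------------------------------------------------------------
# CSV helpers
# ---------------------------------------------------------------------------

def residue_key_str(key: tuple[str, str]) -> str:
    return f"{key[0]}:{key[1]}"
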