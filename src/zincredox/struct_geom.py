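"""Structural geometry of zinc sites.

Covers a minimal multi-model PDB coordinate reader/writer, zinc-pocket
detection with coordination-class assignment, Zn-ligand distance series
and bound/released status, windowed Kabsch superposition RMSD, and a
deterministic Shrake-Rupley solvent-accessible surface area with
cysteine-cluster relative exposure.

Conventions: distances in Angstrom; zinc is considered released from a
ligand once the Zn-ligand distance strictly exceeds 4 Å; the sphere-point
layout for SASA is a seed-free Fibonacci lattice so results are
bit-reproducible at a fixed point count.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

import numpy as np
from scipy.spatial import cKDTree

from .zinc_annotation import CoordinationClass, classify_coordination

__all__ = [
    "Structure",
    "ZincPocket",
    "ExposureResult",
    "PDBParseError",
    "DEFAULT_VDW_RADII",
    "CYS_RESIDUE_ALIASES",
    "parse_structure",
    "structure_to_pdb",
    "atom_distance",
    "find_zinc_pockets",
    "zn_s_distance_series",
    "pocket_window_selection",
    "kabsch_superpose",
    "rmsd_series",
    "shrake_rupley_sasa",
    "cluster_exposure",
]

RELEASE_DISTANCE = 4.0  # Å; strictly beyond this a ligand no longer binds zinc

#: van der Waals radii (Å) used for SASA; override via the radii argument
DEFAULT_VDW_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "ZN": 1.39, "P": 1.80,
}

#: residue names accepted as cysteine variants (incl. oxidized forms)
CYS_RESIDUE_ALIASES: frozenset[str] = frozenset({"CYS", "CYM", "CSO", "CSX", "CSD", "OCS"})

_LIGAND_ATOMS: dict[str, tuple[str, ...]] = {
    "CYS": ("SG",), "HIS": ("ND1", "NE2"), "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"),
}
_RESIDUE_LETTER = {"CYS": "C", "HIS": "H", "ASP": "D", "GLU": "E"}


class PDBParseError(ValueError):
    """Malformed PDB coordinate record (message carries the line number)."""


@dataclass
class Structure:
    """Atom table shared by one or more coordinate frames (PDB models)."""

    elements: list[str]
    atom_names: list[str]
    residue_names: list[str]
    residue_numbers: list[int]
    chain_ids: list[str]
    frames: list[np.ndarray]  # each (n_atoms, 3) float64

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coords(self, frame: int = 0) -> np.ndarray:
        return self.frames[frame]

    def canonical_residue(self, index: int) -> str:
        """Residue name with oxidized-cysteine variants mapped back to CYS."""
        name = self.residue_names[index]
        return "CYS" if name in CYS_RESIDUE_ALIASES else name

    def subset(self, indices: Sequence[int]) -> "Structure":
        idx = list(indices)
        return Structure(
            [self.elements[i] for i in idx],
            [self.atom_names[i] for i in idx],
            [self.residue_names[i] for i in idx],
            [self.residue_numbers[i] for i in idx],
            [self.chain_ids[i] for i in idx],
            [f[idx] for f in self.frames],
        )


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    return "".join(c for c in stripped if c.isalpha())[:1].upper() if stripped else ""


def parse_structure(pdb_stream: TextIO | str) -> Structure:
    """Parse ATOM/HETATM/MODEL/ENDMDL records into a Structure.

    Multi-model files yield one shared atom table (from the first model)
    plus one coordinate frame per model.  A coordinate field that does not
    parse raises :class:`PDBParseError` naming the offending line.
    """
    if isinstance(pdb_stream, str):
        pdb_stream = io.StringIO(pdb_stream)

    frames: list[list[list[float]]] = []
    current: list[list[float]] | None = None
    table: dict[str, list] = {k: [] for k in ("el", "an", "rn", "ri", "ch")}
    first_model_done = False

    for lineno, raw in enumerate(pdb_stream, start=1):
        rec = raw[:6].strip()
        if rec == "MODEL":
            if current:
                frames.append(current)
                first_model_done = True
            current = []
        elif rec == "ENDMDL":
            if current is not None:
                frames.append(current)
                first_model_done = True
                current = None
        elif rec in ("ATOM", "HETATM"):
            if current is None:
                current = []
            try:
                xyz = [float(raw[30:38]), float(raw[38:46]), float(raw[46:54])]
                res_num = int(raw[22:26])
            except ValueError as exc:
                raise PDBParseError(f"line {lineno}: bad coordinate record: {raw.rstrip()!r}") from exc
            if not all(math.isfinite(v) for v in xyz):
                raise PDBParseError(f"line {lineno}: non-finite coordinate")
            current.append(xyz)
            if not first_model_done and len(frames) == 0:
                element = raw[76:78].strip().upper() or _guess_element(raw[12:16])
                table["el"].append(element)
                table["an"].append(raw[12:16].strip())
                table["rn"].append(raw[17:20].strip())
                table["ri"].append(res_num)
                table["ch"].append(raw[21].strip() or "A")
    if current:
        frames.append(current)
    if not frames:
        raise PDBParseError("no coordinate records found")
    n = len(table["el"])
    arrays = []
    for i, f in enumerate(frames):
        if len(f) != n:
            raise PDBParseError(f"model {i + 1} has {len(f)} atoms, expected {n}")
        arrays.append(np.asarray(f, dtype=float))
    return Structure(table["el"], table["an"], table["rn"], table["ri"], table["ch"], arrays)


def structure_to_pdb(structure: Structure) -> str:
    """Serialize to PDB text (MODEL/ENDMDL blocks when multi-frame); byte-stable."""
    lines: list[str] = []
    multi = structure.n_frames > 1
    for f, coords in enumerate(structure.frames, start=1):
        if multi:
            lines.append(f"MODEL     {f:4d}")
        for i in range(structure.n_atoms):
            el = structure.elements[i]
            record = "HETATM" if structure.residue_names[i] in ("ZN", "HOH") else "ATOM  "
            name = structure.atom_names[i]
            name_field = f" {name:<3s}" if len(name) < 4 else name
            x, y, z = coords[i]
            lines.append(
                f"{record}{i + 1:5d} {name_field:<4s} {structure.residue_names[i]:<3s} "
                f"{structure.chain_ids[i]:1s}{structure.residue_numbers[i]:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {el:>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def atom_distance(structure: Structure, frame: int, i: int, j: int) -> float:
    """Euclidean distance (Å) between atoms i and j in one frame."""
    coords = structure.coords(frame)
    if not (0 <= i < structure.n_atoms and 0 <= j < structure.n_atoms):
        raise IndexError(f"atom index out of range: {i}, {j}")
    return float(np.linalg.norm(coords[i] - coords[j]))


# ---------------------------------------------------------------------------
# zinc pockets

@dataclass
class ZincPocket:
    zinc_index: int
    ligand_indices: list[int]              # one ligand atom per coordinating residue
    ligand_residues: list[tuple[str, int]]  # (chain, residue number)
    distances: list[float]
    coordination_class: CoordinationClass

    @property
    def status(self) -> str:
        return "Bound" if all(d <= RELEASE_DISTANCE for d in self.distances) else "Released"


def find_zinc_pockets(structure: Structure, frame: int = 0, cutoff: float = 3.0) -> list[ZincPocket]:
    """Detect zinc sites: ligand atoms (Cys Sγ, His Nδ1/Nε2, Asp/Glu carboxylate O)
    within ``cutoff`` Å of each Zn, one (nearest) ligand atom per residue.

    Detection uses a tight 3 Å cutoff typical of inner-sphere Zn-ligand
    bonds; the 4 Å threshold only decides Bound vs Released afterwards.
    """
    coords = structure.coords(frame)
    zinc_indices = [i for i in range(structure.n_atoms) if structure.elements[i] == "ZN"]
    pockets: list[ZincPocket] = []
    for zi in zinc_indices:
        best: dict[tuple[str, int, str], tuple[float, int]] = {}
        for ai in range(structure.n_atoms):
            res = structure.canonical_residue(ai)
            if res not in _LIGAND_ATOMS or structure.atom_names[ai] not in _LIGAND_ATOMS[res]:
                continue
            d = float(np.linalg.norm(coords[ai] - coords[zi]))
            if d > cutoff:
                continue
            key = (structure.chain_ids[ai], structure.residue_numbers[ai], res)
            if key not in best or d < best[key][0]:
                best[key] = (d, ai)
        if not best:
            continue
        items = sorted(best.items(), key=lambda kv: kv[1][0])
        residues = [(chain, num) for (chain, num, _res), _ in items]
        letters = [_RESIDUE_LETTER[res] for (_c, _n, res), _ in items]
        pockets.append(ZincPocket(
            zinc_index=zi,
            ligand_indices=[ai for _, (_, ai) in items],
            ligand_residues=residues,
            distances=[d for _, (d, _) in items],
            coordination_class=classify_coordination(letters),
        ))
    return pockets


def zn_s_distance_series(structure: Structure, pocket: ZincPocket) -> dict:
    """Per-frame Zn-ligand distances, per-ligand means, per-frame Bound/Released."""
    distances = np.empty((structure.n_frames, len(pocket.ligand_indices)))
    for f in range(structure.n_frames):
        coords = structure.coords(f)
        distances[f] = np.linalg.norm(coords[pocket.ligand_indices] - coords[pocket.zinc_index], axis=1)
    status = ["Bound" if row.max() <= RELEASE_DISTANCE else "Released" for row in distances]
    return {
        "distances": distances,
        "per_ligand_mean": distances.mean(axis=0),
        "status": status,
    }


def pocket_window_selection(
    structure: Structure,
    cys_residues: Iterable[tuple[str, int]],
    half_window: int = 6,
) -> list[int]:
    """Cα atoms of residues within ±``half_window`` of each cysteine.

    Overlapping windows are merged; windows truncate at chain termini
    (author residue numbering).  A cysteine residue without a Cα atom
    raises ``ValueError``.
    """
    ca_by_residue: dict[tuple[str, int], int] = {}
    for i in range(structure.n_atoms):
        if structure.atom_names[i] == "CA":
            ca_by_residue.setdefault((structure.chain_ids[i], structure.residue_numbers[i]), i)
    selected: set[int] = set()
    for chain, num in cys_residues:
        if (chain, num) not in ca_by_residue:
            raise ValueError(f"cysteine {chain}{num} lacks a CA atom")
        for offset in range(-half_window, half_window + 1):
            idx = ca_by_residue.get((chain, num + offset))
            if idx is not None:
                selected.add(idx)
    return sorted(selected)


# ---------------------------------------------------------------------------
# superposition

def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> dict:
    """Least-squares optimal rigid superposition of B onto A (Kabsch, SVD form).

    Reflections are excluded by the determinant correction, as appropriate
    for chiral molecules.  Returns the proper rotation matrix, the
    translation, and the minimal RMSD.  Requires n >= 3 non-collinear
    paired points.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("paired (n, 3) coordinate sets required")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    if np.linalg.matrix_rank(A0, tol=1e-9) < 2 or np.linalg.matrix_rank(B0, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) coordinate set")
    H = B0.T @ A0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    rmsd = float(np.sqrt(np.sum((A0 - B0 @ R.T) ** 2) / n))
    translation = ca - R @ cb
    return {"rotation": R, "translation": translation, "rmsd": rmsd}


def rmsd_series(
    structure: Structure,
    reference_frame: int,
    selection: Sequence[int],
) -> np.ndarray:
    """Kabsch RMSD of every frame against a reference frame over an atom selection."""
    sel = list(selection)
    ref = structure.coords(reference_frame)[sel]
    return np.array([
        kabsch_superpose(ref, structure.coords(f)[sel])["rmsd"]
        for f in range(structure.n_frames)
    ])


# ---------------------------------------------------------------------------
# solvent accessibility

def _fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point layout (golden-angle spiral)."""
    i = np.arange(n_points, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n_points
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(
    structure: Structure,
    frame: int = 0,
    probe: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²), Shrake-Rupley style.

    Each atom's extended sphere (vdW radius + probe) is sampled with a
    Fibonacci lattice of ``n_points``; a point is accessible when it lies
    outside every neighbour's extended sphere.  An isolated atom therefore
    returns exactly 4π(r+w)².  Unknown elements without a configured
    radius raise ``ValueError``.
    """
    radii = {**DEFAULT_VDW_RADII, **(radii or {})}
    coords = structure.coords(frame)
    try:
        r_ext = np.array([radii[el] for el in structure.elements]) + probe
    except KeyError as exc:
        raise ValueError(f"no van der Waals radius configured for element {exc.args[0]!r}") from exc

    unit = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * r_ext.max()
    sasa = np.zeros(structure.n_atoms)
    for i in range(structure.n_atoms):
        neighbours = [j for j in tree.query_ball_point(coords[i], r_ext[i] + r_ext.max())
                      if j != i and np.linalg.norm(coords[j] - coords[i]) < r_ext[i] + r_ext[j]]
        area = 4.0 * math.pi * r_ext[i] ** 2
        if not neighbours:
            sasa[i] = area
            continue
        points = coords[i] + r_ext[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d = np.linalg.norm(points - coords[j], axis=1)
            accessible &= d >= r_ext[j]
        sasa[i] = area * accessible.sum() / n_points
    return sasa


@dataclass(frozen=True)
class ExposureResult:
    total_sasa: float
    cluster_shielded_sasa: float
    cluster_isolated_sasa: float

    @property
    def relative_exposure(self) -> float:
        return self.cluster_shielded_sasa / self.cluster_isolated_sasa


def cluster_exposure(
    structure: Structure,
    frame: int = 0,
    cluster_residues: Iterable[tuple[str, int]] = (),
    probe: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
) -> ExposureResult:
    """Relative solvent exposure of a residue cluster: shielded / isolated SASA.

    Shielded SASA sums the cluster atoms' accessibility inside the full
    structure; isolated SASA recomputes it with every non-cluster atom
    removed.  The ratio is <= 1 up to sampling tolerance.
    """
    cluster = set(cluster_residues)
    if not cluster:
        raise ValueError("empty cluster")
    indices = [i for i in range(structure.n_atoms)
               if (structure.chain_ids[i], structure.residue_numbers[i]) in cluster]
    if not indices:
        raise ValueError("cluster residues not present in structure")
    full = shrake_rupley_sasa(structure, frame, probe, n_points, radii)
    isolated_structure = structure.subset(indices)
    isolated = shrake_rupley_sasa(isolated_structure, frame, probe, n_points, radii)
    return ExposureResult(
        total_sasa=float(full.sum()),
        cluster_shielded_sasa=float(full[indices].sum()),
        cluster_isolated_sasa=float(isolated.sum()),
    )
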