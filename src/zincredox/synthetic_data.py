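"""Seeded generators for every input class, with planted ground truth.

Each generator is a pure function of its parameters and seed: rerunning
with the same arguments reproduces the output byte for byte.  Class
counts are allocated deterministically (largest-remainder rounding), not
sampled, so fraction-recovery checks are exact.  Random sequence fill
excludes cysteine except where explicitly injected, so motif counts are
fully controlled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .depletion_abundance import RegulationClass
from .redox_integration import AGING_GRID, KineticClass
from .struct_geom import Structure, structure_to_pdb

__all__ = [
    "SyntheticTruth",
    "OXIDATION_TEMPLATES",
    "ABUNDANCE_TEMPLATES",
    "allocate_counts",
    "generate_proteome",
    "generate_oxidation_dataset",
    "generate_abundance_dataset",
    "generate_toy_structure",
]

# 19 canonical residues minus cysteine; fill alphabet for random sequence
_BACKGROUND_AA = "ADEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside every generated dataset."""

    zbp_flags: dict[str, bool] = field(default_factory=dict)
    motif_positions: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    profile_classes: dict[tuple[str, int], KineticClass] = field(default_factory=dict)
    profile_templates: dict[tuple[str, int], tuple[float, ...]] = field(default_factory=dict)
    regulation_classes: dict[str, RegulationClass] = field(default_factory=dict)
    pocket: dict = field(default_factory=dict)


def allocate_counts(n: int, fractions: Mapping[str, float]) -> dict[str, int]:
    """Deterministic largest-remainder allocation of n items to classes."""
    raw = {k: n * f for k, f in fractions.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    remainder = n - sum(counts.values())
    order = sorted(raw, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in order[:remainder]:
        counts[k] += 1
    return counts


# ---------------------------------------------------------------------------
# proteomes

def _random_sequence(rng: np.random.Generator, length: int) -> list[str]:
    return list(rng.choice(list(_BACKGROUND_AA), size=length))


def _inject_motif(seq: list[str], start0: int, gap: int) -> None:
    seq[start0] = "C"
    seq[start0 + gap] = "C"


def _cys_positions(seq: Sequence[str]) -> list[int]:
    return [i for i, aa in enumerate(seq) if aa == "C"]


def generate_proteome(
    n_proteins: int,
    zbp_fraction: float = 0.12,
    motif_rates: Mapping[str, float] | None = None,
    cys_rate: float = 0.0,
    length_range: tuple[int, int] = (80, 400),
    seed: int = 0,
    species_id: str = "synthetic",
) -> tuple[str, str, SyntheticTruth]:
    """Generate a proteome table + FASTA with planted zinc-binding proteins and motifs.

    ``motif_rates`` gives the fraction of proteins carrying one planted
    motif of each pattern (default CxxC 0.20, CxxxC 0.05); every
    zinc-binding protein carries a CxxC motif, so the CxxC rate must be at
    least ``zbp_fraction``.  ZBP proteins receive consistent annotations:
    a GO molecular-function term containing "zinc" and binding-site rows
    at the injected motif cysteines.  ``cys_rate`` plants additional lone
    cysteines per residue, spaced so that no accidental CxxC/CxxxC
    windows arise.  Returns (proteome TSV text, FASTA text, truth).
    """
    motif_rates = dict(motif_rates or {"CxxC": 0.20, "CxxxC": 0.05})
    min_len, max_len = length_range
    if min_len < 12:
        raise ValueError("minimum length must fit a motif with flanks (>= 12)")
    if motif_rates.get("CxxC", 0.0) < zbp_fraction:
        raise ValueError("CxxC motif rate must be >= zbp_fraction (ZBPs carry a CxxC)")

    rng = np.random.default_rng(seed)
    n_zbp = allocate_counts(n_proteins, {"zbp": zbp_fraction, "rest": 1 - zbp_fraction})["zbp"]
    rate_cxxc = motif_rates.get("CxxC", 0.0)
    rate_cxxxc = motif_rates.get("CxxxC", 0.0)
    n_cxxc = allocate_counts(n_proteins, {"m": rate_cxxc, "rest": 1 - rate_cxxc})["m"]
    n_cxxxc = allocate_counts(n_proteins, {"m": rate_cxxxc, "rest": 1 - rate_cxxxc})["m"]

    order = rng.permutation(n_proteins)
    zbp_set = set(order[:n_zbp].tolist())
    cxxc_set = set(order[:n_cxxc].tolist())            # superset of the ZBP set
    cxxxc_set = set(order[n_cxxc:n_cxxc + n_cxxxc].tolist())

    truth = SyntheticTruth()
    tsv_rows = [
        "accession\tentry_name\tgene_name\tsequence\treviewed\tfragment\tec_number\t"
        "go_mf\tcofactor\tbinding_site\tzinc_finger\tkeywords\tpdb_ids"
    ]
    fasta_lines: list[str] = []
    for i in range(n_proteins):
        acc = f"SYN{i:05d}"
        length = int(rng.integers(min_len, max_len + 1))
        seq = _random_sequence(rng, length)
        motifs: list[tuple[str, int]] = []
        if i in cxxc_set:
            start0 = int(rng.integers(1, length - 4))
            _inject_motif(seq, start0, 3)
            motifs.append(("CxxC", start0 + 1))
        if i in cxxxc_set:
            start0 = _find_free_slot(rng, seq, length, gap=4)
            if start0 is not None:
                _inject_motif(seq, start0, 4)
                motifs.append(("CxxxC", start0 + 1))
        if cys_rate > 0:
            _plant_lone_cysteines(rng, seq, cys_rate)

        is_zbp = i in zbp_set
        go = "zinc ion binding" if is_zbp else "catalytic activity"
        binding = ""
        if is_zbp and motifs:
            positions = [motifs[0][1], motifs[0][1] + 3]
            binding = ";".join(f"{p}:Zn(2+)" for p in positions)
        sequence = "".join(seq)
        tsv_rows.append(
            f"{acc}\t{acc}_SYN\tGEN{i:05d}\t{sequence}\tyes\tno\t\t{go}\t\t{binding}\t\t\t"
        )
        fasta_lines.append(f">sp|{acc}|{acc}_SYN")
        fasta_lines.extend(sequence[j:j + 60] for j in range(0, len(sequence), 60))
        truth.zbp_flags[acc] = is_zbp
        truth.motif_positions[acc] = motifs
    return "\n".join(tsv_rows) + "\n", "\n".join(fasta_lines) + "\n", truth


def _find_free_slot(rng: np.random.Generator, seq: list[str], length: int, gap: int) -> int | None:
    """A start index where planting C..C (span gap) creates no second, accidental motif."""
    existing = _cys_positions(seq)
    for _ in range(200):
        start0 = int(rng.integers(1, length - gap - 1))
        new = {start0, start0 + gap}
        ok = all(abs(p - q) >= 5 for p in new for q in existing)
        if ok:
            return start0
    return None


def _plant_lone_cysteines(rng: np.random.Generator, seq: list[str], cys_rate: float) -> None:
    """Insert isolated cysteines (>= 5 residues from any other C) at about cys_rate per residue."""
    n_extra = int(round(cys_rate * len(seq)))
    for _ in range(n_extra):
        existing = _cys_positions(seq)
        for _attempt in range(50):
            pos = int(rng.integers(0, len(seq)))
            if all(abs(pos - q) >= 5 for q in existing):
                seq[pos] = "C"
                break


# ---------------------------------------------------------------------------
# oxidation kinetics

#: noise-free % oxidation over (LOG, day0, day3, day6, day9) per kinetic class.
#: The middle/late templates follow the low-basal / rise-by-day-6 / high-day-9
#: trend of zinc-binding CxxC proteins; the separate "ribosomal" template
#: reproduces the early-rising, highly oxidized ribosomal trajectory
#: (day0 ~30%, day3 ~36%, day6 ~49%, day9 ~79%).
OXIDATION_TEMPLATES: dict[KineticClass, tuple[float, ...]] = {
    KineticClass.EARLY: (10.0, 30.0, 35.0, 40.0, 55.0),
    KineticClass.MIDDLE: (10.0, 12.0, 13.0, 35.0, 45.0),
    KineticClass.LATE: (10.0, 11.0, 12.0, 13.0, 50.0),
    KineticClass.HIGH: (85.0, 88.0, 90.0, 87.0, 92.0),
    KineticClass.MIXED: (30.0, 35.0, 28.0, 33.0, 30.0),
}

RIBOSOMAL_TEMPLATE: tuple[float, ...] = (12.0, 30.0, 36.0, 49.0, 79.0)

DEFAULT_CLASS_MIX: dict[KineticClass, float] = {
    KineticClass.EARLY: 0.25,
    KineticClass.MIDDLE: 0.20,
    KineticClass.LATE: 0.25,
    KineticClass.HIGH: 0.10,
    KineticClass.MIXED: 0.20,
}


def generate_oxidation_dataset(
    n_sites: int,
    class_mix: Mapping[KineticClass, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[str, SyntheticTruth]:
    """Generate a site-level oxidation TSV over the aging grid with planted classes.

    Per-site values are the class template plus Gaussian noise (sd in
    percentage points), clipped to [0, 100].  Returns (TSV text, truth).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    class_mix = dict(class_mix or DEFAULT_CLASS_MIX)
    if abs(sum(class_mix.values()) - 1.0) > 1e-9:
        raise ValueError("class_mix must sum to 1")
    counts = allocate_counts(n_sites, {k.value: v for k, v in class_mix.items()})
    rng = np.random.default_rng(seed)

    truth = SyntheticTruth()
    rows = ["accession\tcys_position\tcondition\tpercent_oxidized"]
    site_index = 0
    for cls in sorted(class_mix, key=lambda c: c.value):
        template = OXIDATION_TEMPLATES[cls]
        for _ in range(counts[cls.value]):
            acc = f"OXS{site_index:05d}"
            pos = int(rng.integers(5, 400))
            noise = rng.normal(0.0, noise_sd, size=len(AGING_GRID)) if noise_sd else np.zeros(len(AGING_GRID))
            values = np.clip(np.asarray(template) + noise, 0.0, 100.0)
            for cond, value in zip(AGING_GRID, values):
                rows.append(f"{acc}\t{pos}\t{cond}\t{value:.4f}")
            truth.profile_classes[(acc, pos)] = cls
            truth.profile_templates[(acc, pos)] = template
            site_index += 1
    return "\n".join(rows) + "\n", truth


# ---------------------------------------------------------------------------
# depletion abundance

#: log2 fold-change trajectories vs t0 over hours (0, 2, 4, 8, 16).
#: "TransientUp" mimics the ribosomal response to zinc depletion: an
#: immediate rise within 4 h followed by a steep decline.
ABUNDANCE_TEMPLATES: dict[str, tuple[float, ...]] = {
    "Up": (0.0, 0.3, 0.6, 0.9, 1.2),
    "Down": (0.0, -0.2, -0.5, -0.8, -1.1),
    "Unchanged": (0.0, 0.1, -0.1, 0.05, 0.0),
    "TransientUp": (0.0, 0.5, 0.8, -0.2, -0.9),
}

_FINAL_CLASS = {
    "Up": RegulationClass.UP,
    "Down": RegulationClass.DOWN,
    "Unchanged": RegulationClass.UNCHANGED,
    "TransientUp": RegulationClass.DOWN,
}

DEFAULT_ABUNDANCE_MIX = {"Up": 0.45, "Down": 0.25, "Unchanged": 0.20, "TransientUp": 0.10}


def generate_abundance_dataset(
    n_proteins: int,
    class_mix: Mapping[str, float] | None = None,
    timepoints: Sequence[float] = (0.0, 2.0, 4.0, 8.0, 16.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[str, SyntheticTruth]:
    """Generate a long-format abundance TSV (accession, time_h, value) with planted classes.

    t0 must be among the timepoints and its value is exactly 0.  Truth
    records the regulation class at the final timepoint.
    """
    if 0.0 not in timepoints:
        raise ValueError("timepoints must include t0 = 0")
    class_mix = dict(class_mix or DEFAULT_ABUNDANCE_MIX)
    counts = allocate_counts(n_proteins, class_mix)
    rng = np.random.default_rng(seed)
    grid = np.asarray(sorted(timepoints), dtype=float)
    template_grid = np.asarray([0.0, 2.0, 4.0, 8.0, 16.0])

    truth = SyntheticTruth()
    rows = ["accession\ttime_h\tvalue"]
    index = 0
    for name in sorted(class_mix):
        template = np.interp(grid, template_grid, ABUNDANCE_TEMPLATES[name])
        for _ in range(counts[name]):
            acc = f"ABN{index:05d}"
            noise = rng.normal(0.0, noise_sd, size=grid.size) if noise_sd else np.zeros(grid.size)
            values = template + noise
            values[grid == 0.0] = 0.0
            for t, v in zip(grid, values):
                rows.append(f"{acc}\t{t:g}\t{v:.4f}")
            truth.regulation_classes[acc] = _FINAL_CLASS[name]
            index += 1
    return "\n".join(rows) + "\n", truth


# ---------------------------------------------------------------------------
# toy structures

_TETRAHEDRAL = np.array([
    [1.0, 1.0, 1.0],
    [1.0, -1.0, -1.0],
    [-1.0, 1.0, -1.0],
    [-1.0, -1.0, 1.0],
]) / math.sqrt(3.0)

_POCKET_RESIDUES = {
    "C4": ("CYS", "CYS", "CYS", "CYS"),
    "C3H1": ("CYS", "CYS", "CYS", "HIS"),
    "C2H2": ("CYS", "CYS", "HIS", "HIS"),
}


def generate_toy_structure(
    n_shell_atoms: int = 60,
    zn_s_distance: float = 2.33,
    pocket_class: str = "C4",
    seed: int = 0,
    drift_schedule: Sequence[float] | None = None,
) -> tuple[str, SyntheticTruth]:
    """Toy globule with one planted zinc site in tetrahedral geometry.

    The zinc sits at the origin with four ligand atoms (Cys Sγ and/or His
    Nδ1 by ``pocket_class``) at exactly ``zn_s_distance`` Å along
    tetrahedral directions; the default distance lies inside the 2.3-2.6 Å
    band typical of bound Zn-S pairs.  Each ligand residue also gets a Cα
    atom further out, and ``n_shell_atoms`` carbon atoms form a random
    globular shell (radius 7-11 Å).  ``drift_schedule`` — target distances
    for the first ligand — produces one frame per entry, modelling zinc
    release.  Returns (PDB text, truth).
    """
    if pocket_class not in _POCKET_RESIDUES:
        raise ValueError(f"pocket_class must be one of {sorted(_POCKET_RESIDUES)}")
    rng = np.random.default_rng(seed)

    elements, names, resnames, resnums, chains = [], [], [], [], []
    coords: list[np.ndarray] = []

    def add(element, name, resname, resnum, xyz):
        elements.append(element)
        names.append(name)
        resnames.append(resname)
        resnums.append(resnum)
        chains.append("A")
        coords.append(np.asarray(xyz, dtype=float))

    add("ZN", "ZN", "ZN", 200, [0.0, 0.0, 0.0])
    ligand_indices = []
    for k, resname in enumerate(_POCKET_RESIDUES[pocket_class]):
        direction = _TETRAHEDRAL[k]
        atom = "SG" if resname == "CYS" else "ND1"
        element = "S" if resname == "CYS" else "N"
        resnum = 10 + 10 * k  # well-separated residue numbers
        ligand_indices.append(len(elements))
        add(element, atom, resname, resnum, direction * zn_s_distance)
        add("C", "CA", resname, resnum, direction * (zn_s_distance + 2.4))

    for s in range(n_shell_atoms):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        radius = float(rng.uniform(7.0, 11.0))
        add("C", "CA", "ALA", 100 + s, v * radius)

    base = np.vstack(coords)
    frames = [base]
    if drift_schedule is not None:
        frames = []
        direction = _TETRAHEDRAL[0]
        for target in drift_schedule:
            frame = base.copy()
            frame[ligand_indices[0]] = direction * float(target)
            frames.append(frame)
    # coordinates round-trip through fixed-precision PDB text, so quantize
    # first and derive the planted truth from the quantized geometry
    frames = [np.round(f, 3) for f in frames]

    structure = Structure(elements, names, resnames, resnums, chains, frames)
    zn = frames[0][0]
    ligand_distances = [float(np.linalg.norm(frames[0][i] - zn)) for i in ligand_indices]
    first_released = None
    if drift_schedule is not None:
        for f, frame in enumerate(frames):
            if max(np.linalg.norm(frame[i] - frame[0]) for i in ligand_indices) > 4.0:
                first_released = f
                break
    truth = SyntheticTruth()
    truth.pocket = {
        "class": pocket_class,
        "zn_s_distance": zn_s_distance,
        "ligand_distances": ligand_distances,
        "drift_schedule": list(drift_schedule) if drift_schedule is not None else None,
        "first_released_frame": first_released,
    }
    return structure_to_pdb(structure), truth
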