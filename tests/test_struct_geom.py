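import io
import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from zincredox.struct_geom import (
    DEFAULT_VDW_RADII,
    PDBParseError,
    Structure,
    atom_distance,
    cluster_exposure,
    find_zinc_pockets,
    kabsch_superpose,
    parse_structure,
    pocket_window_selection,
    rmsd_series,
    shrake_rupley_sasa,
    structure_to_pdb,
    zn_s_distance_series,
)
from zincredox.synthetic_data import generate_toy_structure

MINIMAL_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       1.000   2.000   2.000  1.00  0.00           C
HETATM    3 ZN   ZN  A   3       2.330   0.000   0.000  1.00  0.00          ZN
"""


def brute_force_rmsd(A, B):
    """Numeric minimizer over rotations (centroids aligned), independent of Kabsch."""
    A0 = A - A.mean(axis=0)
    B0 = B - B.mean(axis=0)

    def cost(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(np.mean(np.sum((A0 - B0 @ R.T) ** 2, axis=1)))

    best = math.inf
    rng = np.random.default_rng(123)
    for start in rng.uniform(-math.pi, math.pi, size=(24, 3)):
        res = minimize(cost, start, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        best = min(best, res.fun)
    return best


class TestParsing:
    def test_minimal_three_atom_file(self):
        s = parse_structure(MINIMAL_PDB)
        assert s.n_atoms == 3 and s.n_frames == 1
        assert s.elements == ["C", "C", "ZN"]
        assert s.residue_numbers == [1, 2, 3]

    def test_two_model_file_shares_one_atom_table(self):
        text = "MODEL        1\n" + MINIMAL_PDB + "ENDMDL\nMODEL        2\n" + MINIMAL_PDB + "ENDMDL\nEND\n"
        s = parse_structure(text)
        assert s.n_atoms == 3 and s.n_frames == 2

    def test_malformed_coordinate_raises_with_line_number(self):
        bad = MINIMAL_PDB.replace("2.330", "x.xxx")
        with pytest.raises(PDBParseError, match="line 3"):
            parse_structure(bad)

    def test_round_trip_through_writer(self):
        s = parse_structure(MINIMAL_PDB)
        s2 = parse_structure(structure_to_pdb(s))
        assert s2.elements == s.elements and s2.atom_names == s.atom_names
        np.testing.assert_allclose(s2.coords(0), s.coords(0), atol=1e-3)


class TestDistances:
    def test_axis_aligned(self):
        s = parse_structure(MINIMAL_PDB)
        assert atom_distance(s, 0, 0, 2) == pytest.approx(2.33)

    def test_three_four_five(self):
        s = Structure(["C", "C"], ["CA", "CA"], ["ALA", "ALA"], [1, 2], ["A", "A"],
                      [np.array([[0.0, 0.0, 0.0], [1.0, 2.0, 2.0]])])
        assert atom_distance(s, 0, 0, 1) == pytest.approx(3.0)
        assert atom_distance(s, 0, 0, 0) == 0.0

    def test_out_of_range_index(self):
        s = parse_structure(MINIMAL_PDB)
        with pytest.raises(IndexError):
            atom_distance(s, 0, 0, 99)


class TestPockets:
    def test_planted_c4_pocket_recovered_exactly(self):
        pdb, truth = generate_toy_structure(seed=7)
        pockets = find_zinc_pockets(parse_structure(pdb))
        assert len(pockets) == 1
        p = pockets[0]
        assert p.coordination_class.value == "C4" and p.status == "Bound"
        assert p.distances == pytest.approx([2.33] * 4, abs=2e-3)

    def test_c3h1_pocket(self):
        pdb, _ = generate_toy_structure(pocket_class="C3H1", seed=7)
        pockets = find_zinc_pockets(parse_structure(pdb))
        assert pockets[0].coordination_class.value == "C3H1"

    def test_c2h2_pocket(self):
        pdb, _ = generate_toy_structure(pocket_class="C2H2", seed=7)
        pockets = find_zinc_pockets(parse_structure(pdb))
        assert pockets[0].coordination_class.value == "C2H2"

    def test_no_zinc_means_no_pockets(self):
        s = parse_structure(MINIMAL_PDB.replace("ZN", "CA").replace("HETATM", "ATOM  "))
        assert find_zinc_pockets(s) == []

    def test_released_when_ligand_beyond_four_angstrom(self):
        pdb, _ = generate_toy_structure(seed=7, drift_schedule=[2.33, 4.5])
        s = parse_structure(pdb)
        pocket = find_zinc_pockets(s, frame=0)[0]
        series = zn_s_distance_series(s, pocket)
        assert series["status"] == ["Bound", "Released"]

    def test_boundary_four_angstrom_is_bound(self):
        pdb, _ = generate_toy_structure(seed=7, drift_schedule=[2.33, 4.0])
        s = parse_structure(pdb)
        pocket = find_zinc_pockets(s, frame=0)[0]
        assert zn_s_distance_series(s, pocket)["status"] == ["Bound", "Bound"]

    def test_drift_series_first_released_matches_schedule(self):
        schedule = np.linspace(2.3, 6.0, 10)
        pdb, truth = generate_toy_structure(seed=7, drift_schedule=schedule)
        s = parse_structure(pdb)
        pocket = find_zinc_pockets(s, frame=0)[0]
        status = zn_s_distance_series(s, pocket)["status"]
        assert status.index("Released") == truth.pocket["first_released_frame"]


class TestWindowSelection:
    def _chain(self, n_residues, cys_at=()):
        coords = np.array([[float(i), 0.0, 0.0] for i in range(n_residues)])
        resnames = ["CYS" if i + 1 in cys_at else "ALA" for i in range(n_residues)]
        return Structure(["C"] * n_residues, ["CA"] * n_residues, resnames,
                         list(range(1, n_residues + 1)), ["A"] * n_residues, [coords])

    def test_truncation_at_terminus(self):
        s = self._chain(20, cys_at=(3,))
        selected = pocket_window_selection(s, [("A", 3)])
        assert [s.residue_numbers[i] for i in selected] == list(range(1, 10))

    def test_overlapping_windows_deduplicated(self):
        s = self._chain(25, cys_at=(10, 13))
        selected = pocket_window_selection(s, [("A", 10), ("A", 13)])
        assert [s.residue_numbers[i] for i in selected] == list(range(4, 20))

    def test_four_separated_cysteines_bound(self):
        s = self._chain(120, cys_at=(10, 40, 70, 100))
        selected = pocket_window_selection(s, [("A", c) for c in (10, 40, 70, 100)])
        assert len(selected) == 4 * 13

    def test_missing_ca_is_an_error(self):
        s = self._chain(20)
        with pytest.raises(ValueError, match="CA"):
            pocket_window_selection(s, [("A", 99)])


class TestKabsch:
    def test_identical_sets_have_zero_rmsd(self):
        A = np.random.default_rng(0).normal(size=(6, 3))
        assert kabsch_superpose(A, A)["rmsd"] == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_invariance(self):
        A = np.random.default_rng(1).normal(size=(7, 3))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        B = A @ R.T + np.array([1.0, -2.0, 3.0])
        assert kabsch_superpose(A, B)["rmsd"] == pytest.approx(0.0, abs=1e-9)

    def test_unit_square_with_displaced_corner_matches_brute_force(self):
        A = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        B = A.copy()
        B[2, 2] = 1.0
        rmsd = kabsch_superpose(A, B)["rmsd"]
        assert rmsd == pytest.approx(brute_force_rmsd(A, B), abs=1e-3)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        A, B = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        assert kabsch_superpose(A, B)["rmsd"] == pytest.approx(
            kabsch_superpose(B, A)["rmsd"], abs=1e-12)

    def test_agrees_with_scipy_alignment(self):
        rng = np.random.default_rng(3)
        A, B = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
        _, scipy_rssd = Rotation.align_vectors(A - A.mean(0), B - B.mean(0))
        assert kabsch_superpose(A, B)["rmsd"] == pytest.approx(
            scipy_rssd / math.sqrt(8), abs=1e-9)

    def test_reflection_excluded(self):
        # mirror image of a chiral set cannot reach zero with a proper rotation
        A = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        B = A.copy()
        B[:, 2] *= -1
        result = kabsch_superpose(A, B)
        assert np.linalg.det(result["rotation"]) == pytest.approx(1.0)
        assert result["rmsd"] > 0.1

    def test_too_few_or_collinear_points_error(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)


class TestRmsdSeries:
    def test_identical_frames_are_zero(self):
        coords = np.random.default_rng(4).normal(size=(10, 3))
        s = Structure(["C"] * 10, ["CA"] * 10, ["ALA"] * 10, list(range(1, 11)),
                      ["A"] * 10, [coords, coords.copy(), coords.copy()])
        np.testing.assert_allclose(rmsd_series(s, 0, range(10)), 0.0, atol=1e-12)

    def test_pure_translation_is_zero(self):
        coords = np.random.default_rng(5).normal(size=(10, 3))
        s = Structure(["C"] * 10, ["CA"] * 10, ["ALA"] * 10, list(range(1, 11)),
                      ["A"] * 10, [coords, coords + np.array([5.0, -3.0, 2.0])])
        np.testing.assert_allclose(rmsd_series(s, 0, range(10)), 0.0, atol=1e-9)

    def test_planted_deformation_matches_per_frame_oracle(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(8, 3)) * 4
        frames = [base + k * 0.3 * rng.normal(size=(8, 3)) for k in range(4)]
        s = Structure(["C"] * 8, ["CA"] * 8, ["ALA"] * 8, list(range(1, 9)),
                      ["A"] * 8, frames)
        series = rmsd_series(s, 0, range(8))
        for f in range(4):
            assert series[f] == pytest.approx(brute_force_rmsd(base, frames[f]), abs=1e-3)


class TestSasa:
    def _single_atom(self, element="C"):
        return Structure([element], ["CA"], ["ALA"], [1], ["A"],
                         [np.zeros((1, 3))])

    def test_isolated_atom_is_analytic_sphere(self):
        for element, r in DEFAULT_VDW_RADII.items():
            sasa = shrake_rupley_sasa(self._single_atom(element), n_points=960)
            analytic = 4 * math.pi * (r + 1.4) ** 2
            assert abs(sasa[0] - analytic) / analytic < 0.02

    def test_distant_atoms_are_additive(self):
        s = Structure(["C", "C"], ["CA", "CA"], ["ALA", "ALA"], [1, 2], ["A", "A"],
                      [np.array([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]])])
        sasa = shrake_rupley_sasa(s)
        analytic = 4 * math.pi * (1.7 + 1.4) ** 2
        assert sasa.sum() == pytest.approx(2 * analytic, rel=1e-9)

    def test_enclosed_atom_has_near_zero_area(self):
        # dense shell of carbons at 3 Å around a central carbon
        shell = []
        for theta in np.linspace(0.3, math.pi - 0.3, 10):
            for phi in np.linspace(0, 2 * math.pi, 14, endpoint=False):
                shell.append([3 * math.sin(theta) * math.cos(phi),
                              3 * math.sin(theta) * math.sin(phi),
                              3 * math.cos(theta)])
        shell += [[0, 0, 3.0], [0, 0, -3.0]]
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        n = len(coords)
        s = Structure(["C"] * n, ["CA"] * n, ["ALA"] * n, list(range(1, n + 1)),
                      ["A"] * n, [coords])
        sasa = shrake_rupley_sasa(s)
        assert sasa[0] < 1.0

    def test_unknown_element_without_radius_errors(self):
        with pytest.raises(ValueError, match="radius"):
            shrake_rupley_sasa(self._single_atom("XX"))

    def test_cross_check_against_mdtraj_on_toy_structure(self):
        mdtraj = pytest.importorskip("mdtraj")
        pdb, _ = generate_toy_structure(seed=11)
        import tempfile, os
        with tempfile.NamedTemporaryFile("w", suffix=".pdb", delete=False) as fh:
            fh.write(pdb)
            path = fh.name
        try:
            traj = mdtraj.load(path)
            reference = mdtraj.shrake_rupley(traj, probe_radius=0.14, n_sphere_points=960)
            reference_total = reference.sum() * 100.0  # nm^2 -> A^2
        finally:
            os.unlink(path)
        ours = shrake_rupley_sasa(parse_structure(pdb)).sum()
        assert ours == pytest.approx(reference_total, rel=0.03)


class TestClusterExposure:
    def test_whole_structure_cluster_has_unit_exposure(self):
        pdb, _ = generate_toy_structure(seed=12, n_shell_atoms=10)
        s = parse_structure(pdb)
        residues = {(s.chain_ids[i], s.residue_numbers[i]) for i in range(s.n_atoms)}
        result = cluster_exposure(s, cluster_residues=residues, n_points=240)
        assert result.relative_exposure == pytest.approx(1.0, abs=1e-9)

    def test_shielded_never_exceeds_isolated(self):
        pdb, _ = generate_toy_structure(seed=13)
        s = parse_structure(pdb)
        cys = sorted({(s.chain_ids[i], s.residue_numbers[i]) for i in range(s.n_atoms)
                      if s.residue_names[i] == "CYS"})
        result = cluster_exposure(s, cluster_residues=cys, n_points=480)
        assert result.cluster_shielded_sasa <= result.cluster_isolated_sasa * (1 + 1e-6)
        assert 0.0 < result.relative_exposure <= 1.0

    def test_removing_shell_increases_exposure(self):
        pdb_dense, _ = generate_toy_structure(seed=14, n_shell_atoms=200)
        pdb_sparse, _ = generate_toy_structure(seed=14, n_shell_atoms=5)
        def ratio(pdb):
            s = parse_structure(pdb)
            cys = sorted({(s.chain_ids[i], s.residue_numbers[i]) for i in range(s.n_atoms)
                          if s.residue_names[i] == "CYS"})
            return cluster_exposure(s, cluster_residues=cys, n_points=240).relative_exposure
        assert ratio(pdb_sparse) > ratio(pdb_dense)

    def test_empty_cluster_is_an_error(self):
        pdb, _ = generate_toy_structure(seed=15)
        with pytest.raises(ValueError):
            cluster_exposure(parse_structure(pdb), cluster_residues=[])
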