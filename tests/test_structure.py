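"""Geometric primitives: parsing, distances, H-bonds, clashes, superposition."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mtrfkit import structure as st
from mtrfkit import synthetic as syn


def atom(chain, res_id, res_name, atom_name, element, coord, **kw):
    return {
        "chain": chain, "res_id": res_id, "res_name": res_name,
        "atom_name": atom_name, "element": element, "coord": np.array(coord, float),
        **kw,
    }


def random_rigid_transform(seed):
    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=rng).as_matrix()
    trans = rng.uniform(-50, 50, 3)
    return rot, trans


# ---------------------------------------------------------------------------
# independent naive oracles

def oracle_hbonds(model, geom=None):
    """All-pairs donor/acceptor scan written independently of detect_hbonds."""
    geom = geom or st.HBondGeometry()
    a = model.atoms
    n = len(model)
    bonds = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            role_i = st.donor_acceptor_role(a.res_name[i], a.atom_name[i])
            role_j = st.donor_acceptor_role(a.res_name[j], a.atom_name[j])
            if "D" not in role_i or "A" not in role_j:
                continue
            if model.residue_key(i) == model.residue_key(j):
                continue
            d = float(np.linalg.norm(a.coord[i] - a.coord[j]))
            if geom.min_distance <= d <= geom.max_distance:
                bonds.add((model.atom_id(i), model.atom_id(j)))
    return bonds


def oracle_clashes(model, threshold=st.SEVERE_CLASH_OVERLAP):
    a = model.atoms
    n = len(model)
    clashes = set()
    for i in range(n):
        for j in range(i + 1, n):
            ei, ej = a.element[i].strip().upper(), a.element[j].strip().upper()
            if ei == "H" or ej == "H":
                continue
            ki, kj = model.residue_key(i), model.residue_key(j)
            if ki == kj or (ki[0] == kj[0] and abs(ki[1] - kj[1]) <= 1):
                continue
            d = float(np.linalg.norm(a.coord[i] - a.coord[j]))
            if st.VDW_RADII[ei] + st.VDW_RADII[ej] - d > threshold:
                clashes.add(tuple(sorted((model.atom_id(i), model.atom_id(j)))))
    return clashes


def random_polar_model(seed, n_residues=60):
    """Random compact arrangement of small polar residues (no hydrogens)."""
    rng = np.random.default_rng(seed)
    records = []
    names = [("SER", "OG", "O"), ("LYS", "NZ", "N"), ("ASP", "OD1", "O"),
             ("ALA", "CB", "C"), ("GLN", "NE2", "N"), ("GLN", "OE1", "O")]
    for i in range(n_residues):
        res_name, atom_name, element = names[rng.integers(len(names))]
        records.append(atom(
            "AB"[int(rng.integers(2))], 1 + i, res_name, atom_name, element,
            rng.uniform(0, 18, 3),
        ))
    return st.StructureModel.from_records(records)


# ---------------------------------------------------------------------------

class TestParsing:
    def test_two_atom_file_round_trip(self, tmp_path):
        model = st.StructureModel.from_records([
            atom("A", 1, "GLY", "CA", "C", (0, 0, 0)),
            atom("A", 2, "GLY", "CA", "C", (3.8, 0, 0)),
        ])
        path = tmp_path / "two.pdb"
        st.write_structure(model, path)
        back = st.read_structure(path)
        assert len(back) == 2
        assert np.abs(back.coords - model.coords).max() < 1e-3

    def test_altloc_highest_occupancy_wins(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40 10.00           C\n"
            "ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.60 10.00           C\n"
            "END\n"
        )
        model = st.read_structure(path)
        assert len(model) == 1
        assert model.coords[0][0] == pytest.approx(1.0)

    def test_altloc_tie_prefers_a(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.50 10.00           C\n"
            "ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.50 10.00           C\n"
            "END\n"
        )
        model = st.read_structure(path)
        assert len(model) == 1
        assert model.coords[0][0] == pytest.approx(0.0)

    def test_malformed_coordinate_reports_line(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00           C\n"
            "ATOM      2  CA  ALA A   2       xxxxx   0.000   0.000  1.00 10.00           C\n"
        )
        with pytest.raises(st.StructureFormatError, match=":2"):
            st.read_structure(path)

    def test_generated_structure_reparses_losslessly(self, tmp_path):
        recipe = syn.StructureRecipe(
            planted_hbonds=(
                (syn.AtomSpec("P", 1, "ALA", "N", "N"),
                 syn.AtomSpec("P", 3, "ALA", "O", "O"), 2.9, None),
            ),
            decoding_state="stacked",
        )
        model, _ = syn.gen_structure(recipe)
        path = tmp_path / "gen.pdb"
        st.write_structure(model, path)
        back = st.read_structure(path)
        assert len(back) == len(model)
        assert np.abs(back.coords - model.coords).max() < 1e-3

    def test_selection_patterns(self, complexes):
        model, _ = complexes[("mtrf1", "stacked")]
        assert len(model.select("R:286-301:CA")) == 16
        assert len(model.select("R:115A")) == 7  # insert arginine atoms
        assert len(model.select("A:1493:N*")) == 5  # adenine ring nitrogens
        with pytest.raises(st.SelectionError):
            model.select("Z:999")


class TestMinDistance:
    def test_coincident_points(self):
        model = st.StructureModel.from_records([
            atom("A", 1, "GLY", "CA", "C", (1, 2, 3)),
            atom("B", 1, "GLY", "CA", "C", (1, 2, 3)),
        ])
        assert st.min_distance(model, "A:*", "B:*") == 0.0

    def test_three_four_five_triangle(self):
        model = st.StructureModel.from_records([
            atom("A", 1, "GLY", "CA", "C", (0, 0, 0)),
            atom("B", 1, "GLY", "CA", "C", (3, 4, 0)),
        ])
        assert st.min_distance(model, "A:*", "B:*") == pytest.approx(5.0)

    def test_symmetric_in_arguments(self, complexes):
        model, _ = complexes[("rf1", "recognized")]
        d1 = st.min_distance(model, "R:295:O", "A:1493")
        d2 = st.min_distance(model, "A:1493", "R:295:O")
        assert d1 == d2

    def test_empty_selection_raises(self, complexes):
        model, _ = complexes[("rf1", "stacked")]
        with pytest.raises(st.SelectionError):
            st.min_distance(model, "Z:1", "A:1493")


class TestHBonds:
    def test_polar_atoms_far_apart_not_bonded(self):
        model = st.StructureModel.from_records([
            atom("A", 1, "LYS", "NZ", "N", (0, 0, 0)),
            atom("A", 5, "ASP", "OD1", "O", (10, 0, 0)),
        ])
        assert st.detect_hbonds(model, "A:1", "A:5") == []

    def test_planted_ideal_pair_detected_exactly_once(self):
        recipe = syn.StructureRecipe(planted_hbonds=(
            (syn.AtomSpec("A", 1, "LYS", "NZ", "N"),
             syn.AtomSpec("A", 5, "ASP", "OD1", "O"), 2.9, 180.0),
        ))
        model, _ = syn.gen_structure(recipe)
        bonds = st.detect_hbonds(model, model, model)
        assert len(bonds) == 1
        assert bonds[0].donor == "A:1:NZ"
        assert bonds[0].acceptor == "A:5:OD1"
        assert bonds[0].distance == pytest.approx(2.9, abs=1e-6)
        assert bonds[0].angle == pytest.approx(180.0, abs=0.5)

    def test_angle_cutoff_applies_only_with_hydrogens(self):
        # same heavy-atom geometry, bent hydrogen: rejected with H present
        bent = syn.StructureRecipe(planted_hbonds=(
            (syn.AtomSpec("A", 1, "SER", "OG", "O"),
             syn.AtomSpec("A", 5, "ASP", "OD1", "O"), 3.0, 100.0),
        ))
        with pytest.raises(syn.RecipeError):
            bent.validate()
        model = st.StructureModel.from_records([
            atom("A", 1, "SER", "OG", "O", (0, 0, 0)),
            atom("A", 1, "SER", "HG", "H", (-0.7, 0.7, 0)),  # points away
            atom("A", 5, "ASP", "OD1", "O", (3.0, 0, 0)),
        ])
        assert st.detect_hbonds(model, "A:1", "A:5") == []
        no_h = st.StructureModel.from_records([
            atom("A", 1, "SER", "OG", "O", (0, 0, 0)),
            atom("A", 5, "ASP", "OD1", "O", (3.0, 0, 0)),
        ])
        assert len(st.detect_hbonds(no_h, "A:1", "A:5")) == 1

    def test_matches_all_pairs_oracle_on_random_models(self):
        for seed in range(10):
            model = random_polar_model(seed)
            found = {(b.donor, b.acceptor)
                     for b in st.detect_hbonds(model, model, model)}
            assert found == oracle_hbonds(model)

    def test_rigid_motion_invariance(self):
        model = random_polar_model(42)
        bonds = st.detect_hbonds(model, model, model)
        rot, trans = random_rigid_transform(7)
        moved = st.StructureModel(model.atoms.copy())
        moved.atoms.coord = model.coords @ rot.T + trans
        moved_bonds = st.detect_hbonds(moved, moved, moved)
        assert [(b.donor, b.acceptor) for b in bonds] == [
            (b.donor, b.acceptor) for b in moved_bonds
        ]
        for b1, b2 in zip(bonds, moved_bonds):
            assert abs(b1.distance - b2.distance) < 1e-6


class TestClashes:
    def test_two_carbons_overlap_arithmetic(self):
        model = st.StructureModel.from_records([
            atom("A", 1, "ALA", "CB", "C", (0, 0, 0)),
            atom("A", 4, "ALA", "CB", "C", (2.0, 0, 0)),
        ])
        clashes = st.detect_clashes(model, "A:1", "A:4")
        assert len(clashes) == 1
        assert clashes[0].overlap == pytest.approx(1.40)

    def test_distant_selections_no_clash(self):
        model = st.StructureModel.from_records([
            atom("A", 1, "ALA", "CB", "C", (0, 0, 0)),
            atom("A", 4, "ALA", "CB", "C", (9.0, 0, 0)),
        ])
        assert st.detect_clashes(model, "A:1", "A:4") == []

    def test_bonded_neighbors_excluded(self):
        model = st.StructureModel.from_records([
            atom("A", 1, "ALA", "C", "C", (0, 0, 0)),
            atom("A", 2, "ALA", "N", "N", (1.33, 0, 0)),
        ])
        assert st.detect_clashes(model, "A:1", "A:2") == []

    def test_unknown_element_named_in_error(self):
        model = st.StructureModel.from_records([
            atom("A", 1, "HEM", "FE", "FE", (0, 0, 0)),
            atom("A", 4, "ALA", "CB", "C", (1.0, 0, 0)),
        ])
        with pytest.raises(KeyError, match="FE"):
            st.detect_clashes(model, "A:1", "A:4")

    def test_matches_all_pairs_oracle_on_random_models(self):
        for seed in range(10):
            model = random_polar_model(seed, n_residues=80)
            found = {tuple(sorted((c.atom_a, c.atom_b)))
                     for c in st.detect_clashes(model, model, model)}
            assert found == oracle_clashes(model)

    def test_rigid_motion_invariance(self):
        model = random_polar_model(11, n_residues=80)
        before = st.detect_clashes(model, model, model)
        rot, trans = random_rigid_transform(3)
        moved = st.StructureModel(model.atoms.copy())
        moved.atoms.coord = model.coords @ rot.T + trans
        after = st.detect_clashes(moved, moved, moved)
        assert [(c.atom_a, c.atom_b) for c in before] == [
            (c.atom_a, c.atom_b) for c in after
        ]
        for c1, c2 in zip(before, after):
            assert abs(c1.overlap - c2.overlap) < 1e-6


class TestSuperpose:
    def test_self_fit_identity(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-10, 10, (20, 3))
        t = st.superpose(x, x)
        assert t.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(t.translation, 0, atol=1e-9)

    def test_apply_and_recover_perturbation(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(-10, 10, (50, 3))
        rot, trans = random_rigid_transform(5)
        moved = x @ rot.T + trans
        t = st.superpose(moved, x)
        assert t.rmsd <= 1e-6
        assert np.abs(t.apply(moved) - x).max() <= 1e-6

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(-5, 5, (10, 3))
        y = rng.uniform(-5, 5, (10, 3))
        t = st.superpose(x, y)
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(t.rotation @ t.rotation.T, np.eye(3), atol=1e-9)

    def test_noisy_copy_rmsd_matches_quaternion_oracle(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(-10, 10, (50, 3))
        rot, trans = random_rigid_transform(8)
        noisy = (x + rng.normal(0, 0.2, x.shape)) @ rot.T + trans
        t = st.superpose(noisy, x)
        assert 0.15 <= t.rmsd <= 0.45
        # independent quaternion-based fitter
        xc = x - x.mean(axis=0)
        nc = noisy - noisy.mean(axis=0)
        oracle_rot, oracle_rssd = Rotation.align_vectors(xc, nc)
        oracle_rmsd = oracle_rssd / np.sqrt(len(x))
        assert t.rmsd == pytest.approx(oracle_rmsd, abs=1e-9)
        assert np.allclose(t.rotation, oracle_rot.as_matrix(), atol=1e-6)

    def test_rmsd_symmetric_under_swap(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(-10, 10, (30, 3))
        y = x + rng.normal(0, 0.5, x.shape)
        assert st.superpose(x, y).rmsd == pytest.approx(st.superpose(y, x).rmsd, abs=1e-9)

    def test_degenerate_input_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(ValueError):
            st.superpose(line, line + 1)
        with pytest.raises(ValueError):
            st.superpose(np.zeros((2, 3)), np.zeros((2, 3)))
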