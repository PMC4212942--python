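"""Structure parsing, cleanup, reflection and Horn superposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from biogps.fixtures import PocketRecipe, make_mirror, make_toy_pocket
from biogps.structure_io import (
    Atom,
    RigidTransform,
    Structure,
    StructureError,
    backbone_rmsd,
    backbone_rmsd_matrix,
    extract_anchors,
    horn_fit,
    read_pdb,
    reflect_structure,
    strip_non_protein,
    superpose_on_anchors,
    write_pdb,
)
from conftest import random_rigid


def _pdb_line(serial, name, resname, resnum, x, y, z, element, altloc=" ", record="ATOM"):
    return (
        f"{record:<6}{serial:5d} {name:<4}{altloc}{resname:<3} A{resnum:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2}"
    )


class TestReadPdb:
    def test_two_atom_parse(self):
        text = "\n".join(
            [
                _pdb_line(1, "N", "GLY", 1, 0.0, 0.0, 0.0, "N"),
                _pdb_line(2, "CA", "GLY", 1, 1.5, 0.0, 0.0, "C"),
            ]
        )
        s = read_pdb(text)
        assert len(s) == 2
        assert s.atoms[0].position == (0.0, 0.0, 0.0)
        assert s.atoms[1].position == (1.5, 0.0, 0.0)
        assert s.atoms[1].name == "CA"
        assert s.atoms[1].element == "C"

    def test_altloc_first_only(self):
        with_alt = "\n".join(
            [
                _pdb_line(1, "N", "GLY", 1, 0.0, 0.0, 0.0, "N"),
                _pdb_line(2, "CA", "GLY", 1, 1.5, 0.0, 0.0, "C", altloc="A"),
                _pdb_line(3, "CA", "GLY", 1, 1.7, 0.0, 0.0, "C", altloc="B"),
            ]
        )
        without = "\n".join(
            [
                _pdb_line(1, "N", "GLY", 1, 0.0, 0.0, 0.0, "N"),
                _pdb_line(2, "CA", "GLY", 1, 1.5, 0.0, 0.0, "C"),
            ]
        )
        sa, sb = read_pdb(with_alt), read_pdb(without)
        assert len(sa) == len(sb) == 2
        assert sa.atoms[1].position[0] == pytest.approx(1.5)

    def test_no_coordinate_records_errors(self):
        with pytest.raises(StructureError, match="ATOM"):
            read_pdb("HEADER    JUNK\nEND\n")

    def test_roundtrip_through_writer(self):
        s = make_toy_pocket(PocketRecipe(seed=3))
        s2 = read_pdb(write_pdb(s))
        assert len(s2) == len(s)
        np.testing.assert_allclose(s2.coords(), s.coords(), atol=1e-3)
        assert [a.name for a in s2.atoms] == [a.name for a in s.atoms]


class TestStripNonProtein:
    def _mixed(self):
        atoms = [
            Atom(i + 1, "CA", "C", "ALA", i + 1, "A", (float(i), 0.0, 0.0))
            for i in range(10)
        ]
        atoms += [
            Atom(11, "O", "O", "HOH", 100, "A", (20.0, 0.0, 0.0)),
            Atom(12, "O", "O", "HOH", 101, "A", (21.0, 0.0, 0.0)),
            Atom(13, "O", "O", "HOH", 102, "A", (22.0, 0.0, 0.0)),
            Atom(14, "C1", "C", "NAG", 200, "A", (23.0, 0.0, 0.0)),
        ]
        return Structure("mixed", atoms)

    def test_waters_and_sugars_removed(self):
        s = strip_non_protein(self._mixed())
        assert len(s) == 10
        assert all(a.residue_name == "ALA" for a in s.atoms)

    def test_all_protein_identity(self):
        s = Structure(
            "p", [Atom(1, "CA", "C", "GLY", 1, "A", (0, 0, 0)), Atom(2, "CA", "C", "ALA", 2, "A", (3, 0, 0))]
        )
        assert strip_non_protein(s).atoms == s.atoms

    def test_no_protein_errors(self):
        s = Structure("w", [Atom(1, "O", "O", "HOH", 1, "A", (0, 0, 0))])
        with pytest.raises(StructureError, match="no protein"):
            strip_non_protein(s)


class TestReflect:
    def test_sign_flip_on_x_only(self):
        s = Structure("r", [Atom(1, "CA", "C", "GLY", 1, "A", (1.0, 2.0, 3.0))])
        assert reflect_structure(s).atoms[0].position == (-1.0, 2.0, 3.0)

    def test_involution_bit_exact(self):
        s = make_toy_pocket(PocketRecipe(seed=5))
        assert reflect_structure(reflect_structure(s)).atoms == s.atoms

    def test_tetrahedron_volume_sign_flips(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(0, 3, (4, 3))
        s = Structure(
            "t",
            [Atom(i + 1, "CA", "C", "GLY", i + 1, "A", tuple(p)) for i, p in enumerate(pts)],
        )
        vol = lambda x: np.linalg.det(x[1:] - x[0])
        assert vol(reflect_structure(s).coords()) == pytest.approx(-vol(s.coords()))


class TestAnchors:
    def test_default_atoms_resolved(self):
        s = make_toy_pocket(PocketRecipe(seed=1))
        anc = extract_anchors(s, "HIS 224", ["THR 40", "GLN 106"], "SER 105 OG")
        assert anc.base_atom.name == "NE2" and anc.base_atom.residue_name == "HIS"
        assert {a.residue_name for a in anc.oxyanion_atoms} == {"THR", "GLN"}
        assert all(a.name == "N" for a in anc.oxyanion_atoms)
        assert anc.serine_og.name == "OG"

    def test_missing_residue_names_selector(self):
        s = make_toy_pocket(PocketRecipe(seed=1))
        with pytest.raises(StructureError, match="999"):
            extract_anchors(s, "HIS 999", ["THR 40", "GLN 106"])

    def test_tyrosine_oxyanion_override(self):
        atoms = [
            Atom(1, "NE2", "N", "HIS", 10, "A", (0.0, 0.0, 0.0)),
            Atom(2, "N", "N", "GLY", 20, "A", (4.0, 0.0, 0.0)),
            Atom(3, "OH", "O", "TYR", 150, "A", (0.0, 4.0, 0.0)),
            Atom(4, "N", "N", "TYR", 150, "A", (0.0, 5.0, 1.0)),
        ]
        anc = extract_anchors(Structure("tyr", atoms), "HIS 10", ["GLY 20", "TYR 150 OH"])
        assert anc.oxyanion_atoms[1].name == "OH"


class TestHornFit:
    def test_identity_on_equal_sets(self):
        pts = np.random.default_rng(1).normal(0, 5, (6, 3))
        tr, rmsd = horn_fit(pts, pts)
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(tr.translation, 0, atol=1e-9)
        assert rmsd == pytest.approx(0, abs=1e-9)

    def test_recovers_known_rotation(self):
        rng = np.random.default_rng(2)
        R0 = Rotation.random(random_state=7).as_matrix()
        t0 = rng.uniform(-5, 5, 3)
        pts = rng.normal(0, 4, (8, 3))
        tr, rmsd = horn_fit(pts, pts @ R0.T + t0)
        np.testing.assert_allclose(tr.rotation, R0, atol=1e-6)
        np.testing.assert_allclose(tr.translation, t0, atol=1e-6)
        assert rmsd < 1e-9

    def test_mirror_set_has_positive_rmsd_matching_grid_oracle(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(0, 2, (5, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        _, rmsd = horn_fit(pts, mirrored)
        assert rmsd > 1e-6
        grid_best = _grid_search_rmsd(pts, mirrored, step_deg=10)
        r_max = np.linalg.norm(pts - pts.mean(0), axis=1).max()
        tol = 2 * np.sin(np.radians(10)) * r_max
        assert rmsd <= grid_best + 1e-9
        assert grid_best <= rmsd + tol

    def test_agrees_with_kabsch_cross_check(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 3, (7, 3)), rng.normal(0, 3, (7, 3))
        _, rmsd = horn_fit(a, b)
        rot, ssd = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
        ref = np.sqrt(np.mean(np.sum((rot.apply(a - a.mean(0)) - (b - b.mean(0))) ** 2, axis=1)))
        assert rmsd == pytest.approx(ref, abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 10_000))
    def test_rmsd_invariant_under_common_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 3, (6, 3)), rng.normal(0, 3, (6, 3))
        _, r1 = horn_fit(a, b)
        g = random_rigid(seed + 1)
        _, r2 = horn_fit(g.apply(a), g.apply(b))
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_degenerate_inputs_error(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        tri = np.random.default_rng(0).normal(0, 1, (4, 3))
        with pytest.raises(ValueError, match="collinear"):
            horn_fit(line, tri)
        with pytest.raises(ValueError, match="mismatch"):
            horn_fit(tri, tri[:3])
        with pytest.raises(ValueError, match="at least 3"):
            horn_fit(tri[:2], tri[:2])


def _grid_search_rmsd(moving, fixed, step_deg=10):
    """Brute-force best proper-rotation RMSD over an Euler-angle grid."""
    a = moving - moving.mean(0)
    b = fixed - fixed.mean(0)
    angles = np.arange(0, 360, step_deg)
    betas = np.arange(0, 181, step_deg)
    best = np.inf
    for al in angles:
        for be in betas:
            for ga in angles:
                R = Rotation.from_euler("zyz", [al, be, ga], degrees=True).as_matrix()
                r = np.sqrt(np.mean(np.sum((a @ R.T - b) ** 2, axis=1)))
                best = min(best, r)
    return best


def _anchors(s):
    return extract_anchors(s, "HIS 224", ["THR 40", "GLN 106"], "SER 105 OG")


class TestSuperposeOnAnchors:
    def test_identical_structures_reach_zero(self):
        s1 = make_toy_pocket(PocketRecipe(seed=1), "a")
        s2 = make_toy_pocket(PocketRecipe(seed=1), "b")
        g = random_rigid(4)
        s2 = s2.with_coords(g.apply(s2.coords()))
        aligned, trace = superpose_on_anchors([(s1, _anchors(s1)), (s2, _anchors(s2))])
        assert trace[-1] == pytest.approx(0, abs=1e-9)
        np.testing.assert_allclose(aligned[0].coords(), aligned[1].coords(), atol=1e-6)

    def test_trace_monotone_nonincreasing(self):
        structs = [make_toy_pocket(PocketRecipe(seed=k), f"s{k}") for k in (1, 2, 3, 4)]
        _, trace = superpose_on_anchors([(s, _anchors(s)) for s in structs], iterations=15)
        assert np.all(np.diff(trace) <= 1e-9)

    def test_mirror_pair_rejoined_by_auto_reflect(self):
        s1 = make_toy_pocket(PocketRecipe(seed=1), "a")
        m = make_mirror(make_toy_pocket(PocketRecipe(seed=1), "b"))
        _, trace = superpose_on_anchors(
            [(s1, _anchors(s1)), (m, _anchors(m))], auto_reflect=True
        )
        assert trace[-1] == pytest.approx(0, abs=1e-9)

    def test_single_iteration_equals_pairwise_fit(self):
        s1 = make_toy_pocket(PocketRecipe(seed=1), "a")
        s2 = make_toy_pocket(PocketRecipe(seed=2), "b")
        aligned, _ = superpose_on_anchors([(s1, _anchors(s1)), (s2, _anchors(s2))], iterations=1)
        tr, _ = horn_fit(_anchors(s2).points(), _anchors(s1).points())
        np.testing.assert_allclose(aligned[1].coords(), tr.apply(s2.coords()), atol=1e-9)


def _chain(seed, n_res=6):
    """A synthetic backbone chain (N, CA, C, O per residue)."""
    rng = np.random.default_rng(seed)
    atoms = []
    serial = 1
    for i in range(n_res):
        base = np.array([3.8 * i, 0.0, 0.0])
        for j, name in enumerate(("N", "CA", "C", "O")):
            pos = base + rng.normal(0, 0.5, 3) + np.array([j * 0.8, 0, 0])
            atoms.append(Atom(serial, name, name[0], "GLY", i + 1, "A", tuple(pos)))
            serial += 1
    return Structure(f"chain{seed}", atoms)


class TestBackboneRmsd:
    def test_duplicate_gives_zero_matrix(self):
        s = _chain(1)
        m = backbone_rmsd_matrix([s, s])
        np.testing.assert_allclose(m, 0, atol=1e-9)
        assert m.shape == (2, 2)

    def test_rigidly_moved_copy_is_zero(self):
        s = _chain(2)
        g = random_rigid(9)
        assert backbone_rmsd(s, s.with_coords(g.apply(s.coords()))) == pytest.approx(0, abs=1e-6)

    def test_displaced_atom_matches_superposition_oracle(self):
        s = _chain(3)
        xyz = s.coords()
        xyz2 = xyz.copy()
        xyz2[5] += np.array([0.9, 0.0, 0.0])
        s2 = s.with_coords(xyz2)
        d, n = 0.9, len(xyz)
        r = backbone_rmsd(s, s2)
        # optimal superposition can only reduce the naive closed form d/sqrt(n)
        assert r <= d / np.sqrt(n) + 1e-9
        rot, _ = Rotation.align_vectors(xyz2 - xyz2.mean(0), xyz - xyz.mean(0))
        ref = np.sqrt(np.mean(np.sum((rot.apply(xyz - xyz.mean(0)) - (xyz2 - xyz2.mean(0))) ** 2, axis=1)))
        assert r == pytest.approx(ref, abs=1e-9)

    def test_structure_without_backbone_errors(self):
        bad = Structure("b", [Atom(1, "ZN", "ZN", "HOH", 1, "A", (0, 0, 0))])
        with pytest.raises(StructureError, match="backbone"):
            backbone_rmsd(_chain(1), bad)

    def test_matrix_symmetric_nonnegative(self):
        structs = [_chain(k) for k in range(3)]
        m = backbone_rmsd_matrix(structs)
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        assert np.all(np.diag(m) == 0) and np.all(m >= 0)
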