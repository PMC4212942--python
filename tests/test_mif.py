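"""Probe fields, pseudo-field condensation, point selection and overlap volumes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from biogps.fixtures import CLASS_FRACTIONS, PocketRecipe, make_toy_pocket
from biogps.mif import (
    ALL_PROBES,
    InteractionField,
    ProbeParameters,
    ProbeType,
    PseudoField,
    RepresentativePoint,
    compute_field,
    field_overlap,
    field_volume,
    select_points,
    to_pseudo_field,
)
from biogps.pocket import GridSpec, Pocket, detect_pocket
from biogps.structure_io import Atom, Structure
from conftest import random_rigid

PARAMS = ProbeParameters()


def _pocket_with_nodes(node_positions, spacing=1.0):
    """A Pocket whose masked nodes are exactly the given lattice positions."""
    pos = np.atleast_2d(np.asarray(node_positions, dtype=float))
    lo = pos.min(0) - 2 * spacing
    shape = tuple(int(np.ceil((pos.max(0)[i] - lo[i]) / spacing)) + 3 for i in range(3))
    grid = GridSpec(tuple(lo), spacing, shape)
    mask = np.zeros(shape, dtype=bool)
    for p in pos:
        idx = tuple(int(round((p[i] - lo[i]) / spacing)) for i in range(3))
        mask[idx] = True
    return Pocket(grid, mask, pos.mean(0))


def _nh_group(origin=(0.0, 0.0, 0.0), direction=(1.0, 0.0, 0.0)):
    o, u = np.asarray(origin), np.asarray(direction, dtype=float)
    u /= np.linalg.norm(u)
    return Structure(
        "nh",
        [
            Atom(1, "N", "N", "GLY", 1, "A", tuple(o)),
            Atom(2, "H", "H", "GLY", 1, "A", tuple(o + u * 1.0)),
        ],
    )


class TestComputeField:
    def test_o_probe_favorable_along_donor_direction(self):
        s = _nh_group()
        node = np.array([2.9, 0.0, 0.0])  # on the N-H axis at the H-bond optimum
        pocket = _pocket_with_nodes([node])
        fld = compute_field(s, pocket, ProbeType.O, PARAMS)
        assert fld.energy[0] < 0

    def test_angular_term_suppresses_off_axis(self):
        s = _nh_group()
        on = compute_field(s, _pocket_with_nodes([[2.9, 0, 0]]), ProbeType.O, PARAMS).energy[0]
        off = compute_field(s, _pocket_with_nodes([[0, 2.9, 0]]), ProbeType.O, PARAMS).energy[0]
        assert on < off  # perpendicular approach loses the cos² factor

    @pytest.mark.parametrize("probe", ALL_PROBES)
    def test_clash_clamps_high_for_every_probe(self, probe):
        s = _nh_group()
        pocket = _pocket_with_nodes([[0.5, 0.0, 0.0]])
        fld = compute_field(s, pocket, probe, PARAMS)
        assert fld.energy[0] == pytest.approx(PARAMS.e_clamp_hi)

    def test_dry_single_carbon_closed_form(self):
        s = Structure("c", [Atom(1, "CB", "C", "ALA", 1, "A", (0.0, 0.0, 0.0))])
        r = 4.0
        pocket = _pocket_with_nodes([[r, 0.0, 0.0]])
        fld = compute_field(s, pocket, ProbeType.DRY, PARAMS)
        x = PARAMS.lj_r_min / r
        expected = PARAMS.lj_epsilon * (x**12 - 2 * x**6) - PARAMS.w_phobic * np.exp(
            -((r - PARAMS.dry_r0) ** 2) / 2.0
        )
        assert fld.energy[0] == pytest.approx(expected, abs=1e-9)

    def test_rigid_motion_invariance_on_regridded_nodes(self):
        s = make_toy_pocket(PocketRecipe(seed=9))
        g = random_rigid(23)
        s2 = s.with_coords(g.apply(s.coords()))
        p2 = detect_pocket(s2)  # grid rebuilt from the moved bounding box
        f2 = compute_field(s2, p2, ProbeType.O, PARAMS)
        # evaluate the original-frame field at the same spatial points
        back = g.inverse().apply(p2.node_positions())

        class _CloudPocket:
            grid = p2.grid
            n_nodes = len(back)

            @staticmethod
            def node_positions():
                return back

        f_ref = compute_field(s, _CloudPocket(), ProbeType.O, PARAMS)
        assert np.median(np.abs(f2.energy - f_ref.energy)) < 0.1
        assert np.max(np.abs(f2.energy - f_ref.energy)) < 1e-6

    def test_donor_vs_hydrophobic_probe_contrast(self):
        donor = make_toy_pocket(PocketRecipe(seed=31, fractions=CLASS_FRACTIONS["donor"]))
        dry = make_toy_pocket(PocketRecipe(seed=32, fractions=CLASS_FRACTIONS["dry"]))
        means = {}
        for tag, s in (("donor", donor), ("dry", dry)):
            p = detect_pocket(s)
            means[tag] = {
                probe: compute_field(s, p, probe, PARAMS).energy.mean()
                for probe in (ProbeType.O, ProbeType.DRY)
            }
        assert means["donor"][ProbeType.O] < means["dry"][ProbeType.O]
        assert means["dry"][ProbeType.DRY] < means["donor"][ProbeType.DRY]


class TestToPseudoField:
    def _carbonyl(self, x=0.0):
        return [
            Atom(int(x) * 2 + 1, "C", "C", "ALA", int(x) + 1, "A", (x, 0.0, 1.23)),
            Atom(int(x) * 2 + 2, "O", "O", "ALA", int(x) + 1, "A", (x, 0.0, 0.0)),
        ]

    def test_single_carbonyl_centers_on_oxygen(self):
        s = Structure("co", self._carbonyl())
        pocket = _pocket_with_nodes([[0.0, 0.0, -2.9]])
        fld = compute_field(s, pocket, ProbeType.N1, PARAMS)
        pf = to_pseudo_field(fld, s, PARAMS)
        assert pf.n_centers == 1
        assert s.atoms[pf.atom_indices[0]].name == "O"
        assert pf.weights[0] > 0

    def test_zero_field_gives_zero_weights(self):
        s = Structure("co", self._carbonyl())
        pocket = _pocket_with_nodes([[0.0, 0.0, -2.9]])
        fld = InteractionField(ProbeType.N1, pocket, np.zeros(pocket.n_nodes))
        pf = to_pseudo_field(fld, s, PARAMS)
        assert np.all(pf.weights == 0)

    def test_symmetric_carbonyls_get_equal_weights(self):
        s = Structure("co2", self._carbonyl(0.0) + self._carbonyl(20.0))
        nodes = [[0.0, 0.0, -2.9], [20.0, 0.0, -2.9]]
        pocket = _pocket_with_nodes(nodes)
        fld = compute_field(s, pocket, ProbeType.N1, PARAMS)
        pf = to_pseudo_field(fld, s, PARAMS)
        assert pf.n_centers == 2
        assert pf.weights[0] == pytest.approx(pf.weights[1], abs=1e-6)

    def test_no_eligible_atoms_gives_empty_field(self):
        s = Structure("c", [Atom(1, "CB", "C", "ALA", 1, "A", (0.0, 0.0, 0.0))])
        pocket = _pocket_with_nodes([[3.0, 0.0, 0.0]])
        fld = compute_field(s, pocket, ProbeType.O, PARAMS)  # no donors present
        assert to_pseudo_field(fld, s, PARAMS).n_centers == 0


class TestSelectPoints:
    def _field_with_minima(self, minima, base=0.0):
        span = np.arange(0, 13.0)
        nodes = [(x, y, 0.0) for x in span for y in span]
        pocket = _pocket_with_nodes(nodes)
        pos = pocket.node_positions()
        energy = np.full(len(pos), base)
        for (mx, my), e in minima.items():
            i = int(np.argmin(np.linalg.norm(pos - np.array([mx, my, 0.0]), axis=1)))
            energy[i] = e
        return InteractionField(ProbeType.H, pocket, energy)

    def test_three_separated_minima_found_ranked(self):
        fld = self._field_with_minima({(1, 1): -5.0, (6, 6): -4.0, (11, 1): -3.0})
        pts = select_points(fld, k_max=5, min_sep=1.5, params=PARAMS)
        assert [p.energy for p in pts] == [-5.0, -4.0, -3.0]
        assert pts[0].position[:2] == (1.0, 1.0)

    def test_uniform_zero_field_gives_nothing(self):
        fld = self._field_with_minima({})
        assert select_points(fld, k_max=5, min_sep=1.5, params=PARAMS) == []

    def test_close_minima_keep_only_deeper(self):
        fld = self._field_with_minima({(5, 5): -5.0, (6, 5): -4.0})
        pts = select_points(fld, k_max=5, min_sep=3.0, params=PARAMS)
        assert len(pts) == 1 and pts[0].energy == -5.0

    def test_min_sep_below_spacing_rejected(self):
        fld = self._field_with_minima({(1, 1): -5.0})
        with pytest.raises(ValueError, match="min_sep"):
            select_points(fld, k_max=5, min_sep=0.5, params=PARAMS)


def _gauss_field(centers, weights, sigma=1.0, probe=ProbeType.H):
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    w = np.asarray(weights, dtype=float)
    return PseudoField(probe, np.arange(len(w)), centers, w, np.full(len(w), sigma))


class TestFieldOverlap:
    def test_self_overlap_is_full_volume(self):
        f = _gauss_field([[0, 0, 0], [3, 0, 0]], [1.0, 2.0])
        va, vb, vov = field_overlap(f, f)
        assert va == pytest.approx(vb)
        assert vov == pytest.approx(va, rel=1e-6)

    def test_distant_fields_barely_overlap(self):
        a = _gauss_field([[0, 0, 0]], [1.0])
        b = _gauss_field([[15.0, 0, 0]], [1.0])  # 15 σ apart
        va, _, vov = field_overlap(a, b)
        assert vov < 1e-6 * va

    def test_offset_gaussians_match_closed_form(self):
        sigma, d = 1.0, 1.3
        a = _gauss_field([[0, 0, 0]], [1.0], sigma)
        b = _gauss_field([[d, 0, 0]], [1.0], sigma)
        va, vb, vov = field_overlap(a, b)
        # normalized cross-correlation of two unit Gaussians at offset d
        expected = np.exp(-(d**2) / (4 * sigma**2)) * (2 * np.pi * sigma**2) ** 1.5
        assert vov == pytest.approx(expected, rel=1e-9)
        assert va == pytest.approx((2 * np.pi * sigma**2) ** 1.5, rel=1e-12)

    def test_probe_mismatch_rejected(self):
        a = _gauss_field([[0, 0, 0]], [1.0], probe=ProbeType.O)
        b = _gauss_field([[0, 0, 0]], [1.0], probe=ProbeType.N1)
        with pytest.raises(ValueError, match="probe"):
            field_overlap(a, b)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 10_000))
    def test_swap_symmetry_and_cauchy_schwarz(self, seed):
        rng = np.random.default_rng(seed)
        a = _gauss_field(rng.normal(0, 3, (4, 3)), rng.uniform(0.1, 2, 4))
        b = _gauss_field(rng.normal(0, 3, (5, 3)), rng.uniform(0.1, 2, 5))
        t = random_rigid(seed + 1)
        va, vb, vov = field_overlap(a, b, t)
        vb2, va2, vov2 = field_overlap(b, a, t.inverse())
        assert vov == pytest.approx(vov2, rel=1e-6, abs=1e-9)
        assert vov <= min(va, vb) * (1 + 1e-6)

    def test_volume_formula(self):
        f = _gauss_field([[0, 0, 0]], [2.0], sigma=0.8)
        assert field_volume(f) == pytest.approx(2.0 * (2 * np.pi * 0.64) ** 1.5)
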