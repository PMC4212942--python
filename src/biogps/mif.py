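"""Probe interaction fields on pocket nodes and their condensation.

Four chemical probes sense complementary site properties on the pocket
lattice: **H** (neutral shape probe, steric term only), **O** (a
carbonyl-like acceptor probe sensing the site's H-bond *donors*), **N1**
(an amide-NH-like donor probe sensing the site's *acceptors*) and **DRY**
(hydrophobic). Probe charge is carried implicitly by the sign and size of
the H-bond well. The energy model is deliberately simple and fully
parameterized here:

    E_LJ(r)  = ε[(r_min/r)^12 − 2(r_min/r)^6]          (all probes, steric)
    E_HB(r,θ) = E_hb · cos²θ · exp(−(r − r_hb)²/2w²)   (O vs donors, N1 vs
                 acceptors; zero beyond the cutoff; θ from the donor-H or
                 lone-pair proxy direction)
    E_DRY(r) = −w_phobic · exp(−(r − 4.0)²/2)          (over carbons bonded
                 only to C/H)

The field is then condensed: favorable node energies are attributed to the
nearest chemically eligible atom, giving an atom-centred, density-like
pseudo-field of Gaussian kernels whose overlap volumes drive all scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from enum import Enum

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from . import chem
from .pocket import Pocket
from .structure_io import Structure

_BOND_CUTOFF = 1.8  # Å, heavy-atom covalent bond detection
_H_BOND_CUTOFF = 1.3  # Å, X–H bond detection


class ProbeType(str, Enum):
    H = "H"  # shape
    O = "O"  # senses site H-bond donors
    N1 = "N1"  # senses site H-bond acceptors
    DRY = "DRY"  # hydrophobic

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


ALL_PROBES = (ProbeType.H, ProbeType.O, ProbeType.N1, ProbeType.DRY)


@dataclass
class ProbeParameters:
    """Open, overridable parameters of the simplified probe energy model.

    Units: kcal/mol for energies, Å for lengths. ``sigma`` is the kernel
    width of the condensed pseudo-field, per probe.
    """

    lj_epsilon: float = 0.10
    lj_r_min: float = 3.40
    e_hb: float = -4.0
    r_hb: float = 2.9
    hb_width: float = 0.4
    hb_cutoff: float = 4.0
    w_phobic: float = 1.0
    dry_r0: float = 4.0
    e_clamp_lo: float = -15.0
    e_clamp_hi: float = 5.0
    e_shape_cut: float = -0.5
    sigma: dict = dc_field(
        default_factory=lambda: {
            ProbeType.H: 1.0,
            ProbeType.O: 0.8,
            ProbeType.N1: 0.8,
            ProbeType.DRY: 1.2,
        }
    )

    def __post_init__(self):
        if self.lj_epsilon <= 0 or self.lj_r_min <= 0:
            raise ValueError("LJ parameters must be positive")
        for v in (self.e_hb, self.r_hb, self.hb_width, self.w_phobic):
            if not np.isfinite(v):
                raise ValueError("probe parameters must be finite")

    @classmethod
    def from_dict(cls, d: dict) -> "ProbeParameters":
        d = dict(d)
        sigma = d.pop("sigma", None)
        p = cls(**d)
        if sigma:
            p.sigma.update({ProbeType(k): float(v) for k, v in sigma.items()})
        return p


@dataclass
class InteractionField:
    """Per-probe energies (kcal/mol; negative = favorable) on the pocket nodes.

    ``energy`` is the full field (steric + probe chemistry). ``chemistry``
    holds the probe-specific component alone (H-bond well or hydrophobic
    kernel; zero for the H probe) — it is what the condensation step
    attributes to atoms, so that the polar and hydrophobic pseudo-densities
    encode chemistry while shape lives in the H probe.
    """

    probe: ProbeType
    pocket: Pocket
    energy: np.ndarray  # (n_nodes,), aligned with pocket.node_positions()
    chemistry: np.ndarray | None = None  # (n_nodes,), probe-specific part

    def __post_init__(self):
        self.energy = np.asarray(self.energy, dtype=float)
        if self.energy.shape != (self.pocket.n_nodes,):
            raise ValueError("energy array does not match pocket node count")
        if not np.all(np.isfinite(self.energy)):
            raise ValueError("non-finite field energy")
        if self.chemistry is not None:
            self.chemistry = np.asarray(self.chemistry, dtype=float)
            if self.chemistry.shape != self.energy.shape:
                raise ValueError("chemistry array does not match energy array")


@dataclass
class PseudoField:
    """Atom-centred Gaussian condensation of an interaction field.

    ``weights[i]`` is the absolute sum of favorable field energy attributed
    to atom ``atom_indices[i]``; kernels have per-probe width ``sigmas[i]``.
    """

    probe: ProbeType
    atom_indices: np.ndarray  # (k,) indices into the source structure
    positions: np.ndarray  # (k, 3)
    weights: np.ndarray  # (k,), ≥ 0
    sigmas: np.ndarray  # (k,), Å

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        self.sigmas = np.asarray(self.sigmas, dtype=float).reshape(-1)
        if np.any(self.weights < 0):
            raise ValueError("pseudo-field weights must be non-negative")

    @property
    def n_centers(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class RepresentativePoint:
    """A selected field minimum standing for a region of favorable energy."""

    position: tuple[float, float, float]
    probe: ProbeType
    energy: float


# ---------------------------------------------------------------------------
# Atom typing helpers
# ---------------------------------------------------------------------------

def _heavy_indices(s: Structure) -> np.ndarray:
    return np.array([i for i, a in enumerate(s.atoms) if a.element.upper() != "H"], dtype=int)


def _bond_table(s: Structure) -> dict[int, list[int]]:
    """Distance-based bonded-neighbor lists (covalent cutoffs)."""
    xyz = s.coords()
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(r=_BOND_CUTOFF)
    bonds: dict[int, list[int]] = {i: [] for i in range(len(s.atoms))}
    for i, j in pairs:
        ei = s.atoms[i].element.upper()
        ej = s.atoms[j].element.upper()
        d = np.linalg.norm(xyz[i] - xyz[j])
        if ("H" in (ei, ej)) and d > _H_BOND_CUTOFF:
            continue
        bonds[i].append(j)
        bonds[j].append(i)
    return bonds


def donor_indices(s: Structure) -> list[int]:
    return [
        i
        for i, a in enumerate(s.atoms)
        if a.element.upper() != "H" and chem.is_donor(a.residue_name, a.name)
    ]


def acceptor_indices(s: Structure) -> list[int]:
    return [
        i
        for i, a in enumerate(s.atoms)
        if a.element.upper() != "H" and chem.is_acceptor(a.residue_name, a.name)
    ]


def nonpolar_carbon_indices(s: Structure, bonds: dict[int, list[int]] | None = None) -> list[int]:
    bonds = bonds if bonds is not None else _bond_table(s)
    out = []
    for i, a in enumerate(s.atoms):
        neigh = [s.atoms[j].element for j in bonds[i]]
        if chem.is_nonpolar_carbon(a.element, neigh):
            out.append(i)
    return out


def _polar_directions(
    s: Structure, indices: list[int], bonds: dict[int, list[int]]
) -> np.ndarray:
    """Unit direction of each polar atom's H (donor) or lone-pair proxy.

    Donors with an explicit hydrogen use the X→H vector; otherwise (and for
    acceptors) the direction points away from the mean of the bonded heavy
    neighbors. Atoms with no bonded neighbors get a zero direction, which
    disables the angular term (cos²θ treated as 1 there: an unconstrained
    free group).
    """
    xyz = s.coords()
    dirs = np.zeros((len(indices), 3))
    for k, i in enumerate(indices):
        h_nels = [j for j in bonds[i] if s.atoms[j].element.upper() == "H"]
        heavy = [j for j in bonds[i] if s.atoms[j].element.upper() != "H"]
        if h_nels:
            v = xyz[h_nels[0]] - xyz[i]
        elif heavy:
            v = xyz[i] - np.mean(xyz[heavy], axis=0)
        else:
            continue
        n = np.linalg.norm(v)
        if n > 1e-9:
            dirs[k] = v / n
    return dirs


# ---------------------------------------------------------------------------
# Field computation
# ---------------------------------------------------------------------------

def _lj_energy(dist: np.ndarray, params: ProbeParameters) -> np.ndarray:
    r = np.maximum(dist, 0.3)
    x = params.lj_r_min / r
    return params.lj_epsilon * (x**12 - 2.0 * x**6)


def _hbond_energy(
    nodes: np.ndarray, centers: np.ndarray, dirs: np.ndarray, params: ProbeParameters
) -> np.ndarray:
    """Summed directional H-bond well between nodes and polar site atoms."""
    if len(centers) == 0:
        return np.zeros(len(nodes))
    diff = nodes[:, None, :] - centers[None, :, :]  # (n, k, 3)
    dist = np.linalg.norm(diff, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = diff / np.maximum(dist[..., None], 1e-9)
    cos_t = np.einsum("nkd,kd->nk", unit, dirs)
    free = np.linalg.norm(dirs, axis=1) < 1e-9  # unconstrained groups
    cos_t[:, free] = 1.0
    ang = np.clip(cos_t, 0.0, 1.0) ** 2
    radial = np.exp(-((dist - params.r_hb) ** 2) / (2.0 * params.hb_width**2))
    radial[dist > params.hb_cutoff] = 0.0
    return (params.e_hb * ang * radial).sum(axis=1)


def compute_field(
    s: Structure,
    pocket: Pocket,
    probe: ProbeType,
    params: ProbeParameters | None = None,
) -> InteractionField:
    """Evaluate one probe's interaction energy at every pocket node.

    All probes carry the steric Lennard-Jones term (so clashes clamp to
    ``e_clamp_hi`` for every probe); O and N1 add the directional H-bond
    well against the site's donors and acceptors respectively; DRY adds the
    hydrophobic kernel over aliphatic carbons.
    """
    probe = ProbeType(probe)
    params = params or ProbeParameters()
    nodes = pocket.node_positions()
    xyz = s.coords()
    heavy = _heavy_indices(s)
    dist_heavy = cdist(nodes, xyz[heavy])
    steric = _lj_energy(dist_heavy, params).sum(axis=1)
    chem = np.zeros(len(nodes))

    if probe in (ProbeType.O, ProbeType.N1):
        bonds = _bond_table(s)
        idx = donor_indices(s) if probe == ProbeType.O else acceptor_indices(s)
        dirs = _polar_directions(s, idx, bonds)
        chem = _hbond_energy(nodes, xyz[idx], dirs, params)
    elif probe == ProbeType.DRY:
        bonds = _bond_table(s)
        idx = nonpolar_carbon_indices(s, bonds)
        if idx:
            d = cdist(nodes, xyz[idx])
            chem = -params.w_phobic * np.exp(
                -((d - params.dry_r0) ** 2) / 2.0
            ).sum(axis=1)

    energy = np.clip(steric + chem, params.e_clamp_lo, params.e_clamp_hi)
    chem = np.clip(chem, params.e_clamp_lo, params.e_clamp_hi)
    return InteractionField(probe, pocket, energy, chem)


# ---------------------------------------------------------------------------
# Condensation to pseudo-fields
# ---------------------------------------------------------------------------

_LINING_DISTANCE = 5.0  # Å: heavy atoms this close to the mask line the pocket


def eligible_atoms(s: Structure, pocket: Pocket, probe: ProbeType) -> list[int]:
    """Atoms that may carry a pseudo-field center for the given probe."""
    probe = ProbeType(probe)
    if probe == ProbeType.O:
        return donor_indices(s)
    if probe == ProbeType.N1:
        return acceptor_indices(s)
    if probe == ProbeType.DRY:
        return nonpolar_carbon_indices(s)
    # H probe: heavy atoms lining the pocket
    xyz = s.coords()
    tree = cKDTree(pocket.node_positions())
    d, _ = tree.query(xyz)
    return [
        i
        for i in _heavy_indices(s)
        if d[i] <= _LINING_DISTANCE
    ]


def to_pseudo_field(
    field: InteractionField,
    s: Structure,
    params: ProbeParameters | None = None,
) -> PseudoField:
    """Condense a node field into atom-centred Gaussian kernels.

    Each node with favorable (negative) energy contributes |E| to the
    nearest eligible atom for the field's probe; the per-atom totals become
    kernel weights with the probe's width. For the chemical probes (O, N1,
    DRY) the attributed energy is the probe-specific component — the
    steric baseline belongs to the H (shape) probe, and attributing it
    here would bury the chemistry under class-blind shape signal. No
    eligible atoms → an empty pseudo-field.
    """
    params = params or ProbeParameters()
    sigma = params.sigma[field.probe]
    idx = eligible_atoms(s, field.pocket, field.probe)
    if not idx:
        return PseudoField(
            field.probe,
            np.empty(0, dtype=int),
            np.empty((0, 3)),
            np.empty(0),
            np.empty(0),
        )
    xyz = s.coords()[idx]
    nodes = field.pocket.node_positions()
    values = field.energy
    if field.probe != ProbeType.H and field.chemistry is not None:
        values = field.chemistry
    fav = values < 0
    weights = np.zeros(len(idx))
    if fav.any():
        tree = cKDTree(xyz)
        _, nearest = tree.query(nodes[fav])
        np.add.at(weights, nearest, -values[fav])
    # unit-integral kernels: a center's volume contribution equals its
    # attributed |energy|, so probes pool by energy, not by kernel width —
    # the weighting that puts polar and hydrophobic signals on one scale
    weights = weights / (2.0 * np.pi * sigma**2) ** 1.5
    return PseudoField(
        field.probe,
        np.asarray(idx, dtype=int),
        xyz,
        weights,
        np.full(len(idx), sigma),
    )


# ---------------------------------------------------------------------------
# Representative points
# ---------------------------------------------------------------------------

def select_points(
    field: InteractionField,
    k_max: int = 30,
    min_sep: float = 1.5,
    energy_cutoff: float | None = None,
    params: ProbeParameters | None = None,
) -> list[RepresentativePoint]:
    """Greedy energy/space-coverage selection of representative points.

    Repeatedly takes the most favorable remaining node and discards nodes
    within ``min_sep``; stops at ``k_max`` points or once the best remaining
    energy exceeds the cutoff. Ties break on lexicographic node index, so
    the selection is fully deterministic.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    params = params or ProbeParameters()
    if min_sep < field.pocket.grid.spacing:
        raise ValueError("min_sep must be at least the grid spacing")
    cutoff = params.e_shape_cut if energy_cutoff is None else energy_cutoff

    nodes = field.pocket.node_positions()
    order = np.lexsort(
        (np.arange(len(nodes)), field.energy)
    )  # energy ascending, then node index
    alive = np.ones(len(nodes), dtype=bool)
    chosen: list[RepresentativePoint] = []
    for i in order:
        if len(chosen) >= k_max:
            break
        if not alive[i] or field.energy[i] > cutoff:
            continue
        p = nodes[i]
        chosen.append(
            RepresentativePoint(tuple(float(v) for v in p), field.probe, float(field.energy[i]))
        )
        alive &= np.linalg.norm(nodes - p, axis=1) >= min_sep
    return chosen


# ---------------------------------------------------------------------------
# Gaussian volumes & overlap
# ---------------------------------------------------------------------------

def field_volume(f: PseudoField) -> float:
    """Analytic integral of the kernel sum: Σ w_i (2πσ_i²)^{3/2}."""
    return float(np.sum(f.weights * (2.0 * np.pi * f.sigmas**2) ** 1.5))


def _cross_integral(
    pos_a: np.ndarray,
    w_a: np.ndarray,
    s_a: np.ndarray,
    pos_b: np.ndarray,
    w_b: np.ndarray,
    s_b: np.ndarray,
) -> float:
    """⟨f_a, f_b⟩ = Σ_ij w_i w_j (2π σ_i²σ_j²/(σ_i²+σ_j²))^{3/2} e^{−d²/2(σ_i²+σ_j²)}."""
    if len(w_a) == 0 or len(w_b) == 0:
        return 0.0
    s2 = s_a[:, None] ** 2 + s_b[None, :] ** 2
    pref = (2.0 * np.pi * (s_a[:, None] ** 2 * s_b[None, :] ** 2) / s2) ** 1.5
    d2 = cdist(pos_a, pos_b, metric="sqeuclidean")
    return float(np.sum(w_a[:, None] * w_b[None, :] * pref * np.exp(-d2 / (2.0 * s2))))


def field_overlap(a: PseudoField, b: PseudoField, transform=None) -> tuple[float, float, float]:
    """Overlap volume of two pseudo-fields under a rigid transform of ``b``.

    Returns ``(V_a, V_b, V_overlap)``. The overlap is the normalized Gaussian
    cross-correlation scaled to volume units,
    ``V_ov = ⟨f_a, f_b∘T⁻¹⟩ / √(⟨f_a,f_a⟩⟨f_b,f_b⟩) · min(V_a, V_b)``,
    so that a field against itself under the identity overlaps completely and
    the Cauchy–Schwarz bound keeps V_ov ≤ min(V_a, V_b).
    """
    if a.probe != b.probe:
        raise ValueError(f"probe mismatch: {a.probe} vs {b.probe}")
    pos_b = b.positions if transform is None else transform.apply(b.positions)
    va, vb = field_volume(a), field_volume(b)
    if a.n_centers == 0 or b.n_centers == 0:
        return va, vb, 0.0
    oaa = _cross_integral(a.positions, a.weights, a.sigmas, a.positions, a.weights, a.sigmas)
    obb = _cross_integral(pos_b, b.weights, b.sigmas, pos_b, b.weights, b.sigmas)
    oab = _cross_integral(a.positions, a.weights, a.sigmas, pos_b, b.weights, b.sigmas)
    denom = np.sqrt(oaa * obb)
    if denom <= 0.0:
        return va, vb, 0.0
    vov = min(1.0, oab / denom) * min(va, vb)
    return va, vb, float(max(0.0, vov))
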