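"""Deterministic synthetic pockets: the offline test bed for every stage.

A toy pocket is a spherical cup of small rigid chemical groups pointing at
a focal point: backbone-like N–H donors, carbonyl C=O acceptors and
methyl-like carbons, in controllable fractions, behind an inert backing
shell that makes the cavity buried. Every structure carries a catalytic
serine Oγ at the cup bottom and a triad-like anchor set (His Nε2 plus two
amide nitrogens) outside the cup, so superposition, auto-reflection and the
serine-anchored pocket fallback are all exercisable. Generation is fully
seeded: identical (seed, recipe) gives bit-identical PDB text. Stepwise
"mutant" morphs convert lining groups toward a target chemistry with the
unchanged groups frozen, giving a controllable ground truth for projection.

These pockets emulate lining chemistry and cup geometry only — not real
hydrolase folds, flexibility or solvent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure_io import Atom, Structure, reflect_structure

DONOR, ACCEPTOR, HYDROPHOBIC = "donor", "acceptor", "hydrophobic"

#: backing shells wrap this many degrees past the lining cone
_SHELL_CONE_EXTRA = 2.0
_SHELL_OFFSETS = ((8, 2.5), (10, 3.9))  # (atoms per lining group, radial offset (A))
#: inward lip rings at the mouth: (radial pull-in (A), z offset above the rim (A))
_LIP_RINGS = ((0.9, 0.0), (0.45, 1.2))
_LIP_SPACING = 2.0  # A between lip atoms along the ring
_GROUP_TYPES = (DONOR, ACCEPTOR, HYDROPHOBIC)

#: canonical recipe classes used throughout the tests
CLASS_FRACTIONS = {
    "donor": (0.70, 0.15, 0.15),
    "acceptor": (0.15, 0.70, 0.15),
    "dry": (0.15, 0.15, 0.70),
}


@dataclass(frozen=True)
class PocketRecipe:
    """Parameters of one synthetic pocket."""

    seed: int
    n_lining: int = 16
    fractions: tuple = (0.70, 0.15, 0.15)  # (donor, acceptor, hydrophobic)
    cup_radius: float = 6.0  # Å
    jitter: float = 0.30  # Å, positional noise σ
    cone_deg: float = 35.0  # half-angle of the cup opening around +z

    def __post_init__(self):
        f = np.asarray(self.fractions, dtype=float)
        if len(f) != 3 or np.any(f < 0) or np.any(f > 1):
            raise ValueError("fractions must be three values in [0, 1]")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if self.n_lining < 8:
            raise ValueError("n_lining must be at least 8")
        if self.cup_radius <= 2 or self.jitter < 0:
            raise ValueError("bad cup geometry")

    @property
    def focal_point(self) -> tuple:
        return (0.0, 0.0, 0.0)

    @property
    def rim_z(self) -> float:
        """z of the cavity mouth: the lip-constriction plane."""
        return self.cup_radius * math.cos(math.radians(self.cone_deg))


def _fibonacci_directions(n: int, z_max: float, z_min: float = -1.0) -> np.ndarray:
    """n unit vectors quasi-uniform over the spherical band z_min <= z <= z_max."""
    golden = (1 + 5**0.5) / 2
    dirs = []
    k = 0
    while len(dirs) < n:
        # sample the full sphere densely enough, keep the band
        total = max(8, int(np.ceil(n / max((z_max + 1) / 2, 1e-6))) + k)
        dirs = []
        for i in range(total):
            z = 1 - 2 * (i + 0.5) / total
            if z > z_max or z < z_min:
                continue
            r = math.sqrt(max(0.0, 1 - z * z))
            phi = 2 * math.pi * ((i / golden) % 1.0)
            dirs.append((r * math.cos(phi), r * math.sin(phi), z))
            if len(dirs) == n:
                break
        k += 8
        if k > 10000:  # pragma: no cover - defensive
            raise RuntimeError("direction sampling failed")
    return np.array(dirs)


def _type_counts(n: int, fractions) -> list[str]:
    counts = [int(round(f * n)) for f in fractions]
    while sum(counts) > n:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < n:
        counts[int(np.argmin(counts))] += 1
    types = []
    for t, c in zip(_GROUP_TYPES, counts):
        types.extend([t] * c)
    return types


def _group_atoms(gtype: str, center: np.ndarray, u: np.ndarray, resnum: int):
    """Atoms of one lining group at ``center`` with outward normal ``u``.

    Functional atoms point inward (toward the focus): the donor's H, the
    carbonyl O's lone pairs (C sits behind the O) and the methyl carbon all
    face the cavity.
    """
    c = center
    if gtype == DONOR:  # backbone-like amide N-H (glycine fragment)
        return [
            ("N", "N", "GLY", resnum, tuple(c)),
            ("H", "H", "GLY", resnum, tuple(c - u * 1.0)),
        ]
    if gtype == ACCEPTOR:  # carbonyl C=O (alanine fragment)
        return [
            ("C", "C", "ALA", resnum, tuple(c + u * 1.23)),
            ("O", "O", "ALA", resnum, tuple(c)),
        ]
    # methyl-like side-chain carbon
    return [("CB", "C", "ALA", resnum, tuple(c))]


def make_toy_pocket(recipe: PocketRecipe, structure_id: str | None = None) -> Structure:
    """Build a synthetic cup pocket from a recipe (deterministic per seed)."""
    rng = np.random.default_rng(recipe.seed)
    z_max = math.cos(math.radians(recipe.cone_deg))

    # the bottom pole (25° cone) is reserved for the catalytic serine
    dirs = _fibonacci_directions(recipe.n_lining, z_max, z_min=-math.cos(math.radians(25.0)))
    types = _type_counts(recipe.n_lining, recipe.fractions)
    perm = rng.permutation(recipe.n_lining)
    types = [types[i] for i in perm]
    # jitter truncated at 2σ: lining groups never clash into the backing shell
    noise = np.clip(
        rng.normal(0.0, recipe.jitter, size=dirs.shape),
        -2 * recipe.jitter,
        2 * recipe.jitter,
    )
    centers = dirs * recipe.cup_radius + noise

    records = []  # (name, element, resname, resnum, pos)
    for g in range(recipe.n_lining):
        u = dirs[g] / np.linalg.norm(dirs[g])
        records.extend(_group_atoms(types[g], centers[g], u, resnum=g + 1))

    # inert double backing shell (proline N: neither donor, acceptor nor DRY
    # carbon); two offset layers seal ray leaks between lining groups
    z_shell = math.cos(math.radians(recipe.cone_deg - _SHELL_CONE_EXTRA))
    shell = 300
    for mult, off in _SHELL_OFFSETS:
        count = mult * recipe.n_lining
        for u in _fibonacci_directions(count, z_shell):
            records.append(("N", "N", "PRO", shell, tuple(u * (recipe.cup_radius + off))))
            shell += 1
    # inward lip rings constrict the mouth: the buriedness boundary becomes a
    # sharp plane instead of a soft throat, keeping the mask rotation-stable
    rim_z = recipe.cup_radius * math.cos(math.radians(recipe.cone_deg))
    rim_r = recipe.cup_radius * math.sin(math.radians(recipe.cone_deg))
    for pull, dz in _LIP_RINGS:
        rr = rim_r - pull
        n_ring = max(8, int(round(2 * math.pi * rr / _LIP_SPACING)))
        for k in range(n_ring):
            ph = 2 * math.pi * k / n_ring
            records.append(
                ("N", "N", "PRO", shell, (rr * math.cos(ph), rr * math.sin(ph), rim_z + dz))
            )
            shell += 1

    # catalytic serine at the cup bottom
    og = np.array([0.0, 0.0, -recipe.cup_radius])
    records.append(("OG", "O", "SER", 105, tuple(og)))
    records.append(("CB", "C", "SER", 105, tuple(og + np.array([0.0, 0.0, -1.43]))))

    # triad-like anchors outside the cup (fixed chirality across recipes)
    zb = -recipe.cup_radius - 3.0
    records.append(("NE2", "N", "HIS", 224, (2.3, 1.8, zb)))
    records.append(("N", "N", "THR", 40, (-2.3, 1.8, zb)))
    records.append(("N", "N", "GLN", 106, (0.0, -2.6, zb + 1.0)))

    atoms = [
        Atom(
            serial=i + 1,
            name=name,
            element=elem,
            residue_name=resn,
            residue_number=resi,
            chain="A",
            position=tuple(round(float(x), 3) for x in pos),
        )
        for i, (name, elem, resn, resi, pos) in enumerate(records)
    ]
    sid = structure_id or f"pocket_s{recipe.seed}"
    meta = {
        "recipe": recipe,
        "seed": recipe.seed,
        "group_types": list(types),
        "group_centers": centers.copy(),
        "group_dirs": dirs.copy(),
    }
    return Structure(sid, atoms, meta)


def make_class_set(per_class: int = 8, seed: int = 7, classes=None) -> list[Structure]:
    """The standard three-class fixture set (donor/acceptor/dry × seeds)."""
    classes = classes or list(CLASS_FRACTIONS)
    out = []
    for cname in classes:
        fr = CLASS_FRACTIONS[cname]
        for k in range(per_class):
            rec = PocketRecipe(seed=seed * 1000 + len(out), fractions=fr)
            s = make_toy_pocket(rec, structure_id=f"{cname}_{k}")
            s.meta["class"] = cname
            out.append(s)
    return out


def make_mirror(s: Structure) -> Structure:
    """Enantiomeric copy (x → −x), tagged in the id."""
    m = reflect_structure(s)
    m.id = s.id + "_mirror"
    m.meta["mirror"] = True
    return m


def morph_pocket(s: Structure, target_fractions, steps: int, seed: int) -> list[Structure]:
    """Stepwise conversion of a toy pocket's lining toward a target chemistry.

    Returns ``steps + 1`` structures; step 0 is the input, the last step has
    lining composition ≈ the target (within 1/n_lining). Group positions are
    frozen; only a seeded, progressively larger subset of group types
    changes. Same (input, target, steps, seed) → identical series.
    """
    if "group_types" not in s.meta:
        raise ValueError("morph_pocket requires a structure from make_toy_pocket")
    if steps < 0:
        raise ValueError("steps must be >= 0")
    recipe: PocketRecipe = s.meta["recipe"]
    types0 = list(s.meta["group_types"])
    centers = s.meta["group_centers"]
    dirs = s.meta["group_dirs"]
    n = recipe.n_lining

    target_types = _type_counts(n, target_fractions)
    rng = np.random.default_rng(seed)

    # assign final types so composition matches the target while keeping as
    # many groups unchanged as possible; surplus reassignments in rng order
    need = {t: target_types.count(t) for t in _GROUP_TYPES}
    final = [None] * n
    for i in range(n):
        if need.get(types0[i], 0) > 0:
            final[i] = types0[i]
            need[types0[i]] -= 1
    unassigned = [i for i in range(n) if final[i] is None]
    rng.shuffle(unassigned)
    pool = [t for t in _GROUP_TYPES for _ in range(need[t])]
    for i, t in zip(unassigned, pool):
        final[i] = t

    changed = [i for i in range(n) if final[i] != types0[i]]
    changed = list(rng.permutation(changed))

    series = []
    for k in range(steps + 1):
        n_conv = int(round(len(changed) * (k / steps))) if steps > 0 else 0
        conv = set(changed[:n_conv])
        types_k = [final[i] if i in conv else types0[i] for i in range(n)]
        records = []
        for g in range(n):
            u = dirs[g] / np.linalg.norm(dirs[g])
            records.extend(_group_atoms(types_k[g], centers[g], u, resnum=g + 1))
        # non-lining atoms (shell, serine, anchors) are identical to the input
        fixed = [a for a in s.atoms if a.residue_number >= 300 or a.residue_number in (105, 224, 40, 106)]
        atoms = [
            Atom(
                serial=i + 1,
                name=name,
                element=elem,
                residue_name=resn,
                residue_number=resi,
                chain="A",
                position=tuple(round(float(x), 3) for x in pos),
            )
            for i, (name, elem, resn, resi, pos) in enumerate(records)
        ]
        offset = len(atoms)
        for j, a in enumerate(fixed):
            atoms.append(
                Atom(
                    serial=offset + j + 1,
                    name=a.name,
                    element=a.element,
                    residue_name=a.residue_name,
                    residue_number=a.residue_number,
                    chain=a.chain,
                    position=a.position,
                )
            )
        sk = Structure(f"{s.id}_m{k}", atoms, dict(s.meta))
        sk.meta["group_types"] = types_k
        sk.meta["morph_step"] = k
        series.append(sk)
    return series


def write_fixture_set(out_dir, per_class: int = 8, seed: int = 7) -> list[tuple]:
    """Write the class set as PDB files plus a manifest TSV; returns (id, class, seed)."""
    import os

    from .structure_io import write_pdb

    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for s in make_class_set(per_class=per_class, seed=seed):
        write_pdb(s, os.path.join(out_dir, f"{s.id}.pdb"))
        rows.append((s.id, s.meta["class"], s.meta["seed"]))
    with open(os.path.join(out_dir, "manifest.tsv"), "w") as fh:
        fh.write("id\tclass\tseed\n")
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
    return rows
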