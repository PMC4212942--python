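"""Protein structure I/O, cleanup, reflection and catalytic-machinery superposition.

Structures are read from PDB files (model 1, first altloc only) into a light
atom-list container. Superposition never uses sequence or fold information:
it acts on three (optionally four) catalytic anchor atoms — the general-base
nitrogen, the two oxyanion-hole backbone amide nitrogens and, when present,
the catalytic serine Oγ — refined by an iterative quaternion (Horn) fit.
Active sites with mirror-image catalytic machinery are handled by an explicit
reflection of the first coordinate axis, applied automatically when the
signed volume of the anchor tetrahedron disagrees with the reference.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .chem import BACKBONE_ATOMS, STANDARD_AMINO_ACIDS


class StructureError(ValueError):
    """Raised for unparseable, empty or chemically unusable structures."""


@dataclass(frozen=True)
class Atom:
    """One atom record: identity plus Cartesian position in Å."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str
    position: tuple[float, float, float]

    def __post_init__(self):
        if not self.element:
            raise StructureError(f"atom {self.serial} {self.name}: empty element")
        if not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.serial} {self.name}: non-finite position")


@dataclass
class Structure:
    """An ordered collection of atoms with a label.

    ``meta`` carries generator bookkeeping (e.g. the recipe of a synthetic
    pocket) and is never written to PDB beyond REMARK lines.
    """

    id: str
    atoms: list[Atom]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise StructureError(f"{self.id}: duplicate atom serials")

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """(n, 3) float array of positions, Å."""
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    def with_coords(self, xyz: np.ndarray, new_id: str | None = None) -> "Structure":
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            replace(a, position=(float(p[0]), float(p[1]), float(p[2])))
            for a, p in zip(self.atoms, xyz)
        ]
        return Structure(new_id or self.id, atoms, dict(self.meta))

    def find_atom(self, residue_name: str, residue_number: int, atom_name: str) -> int:
        """Index of the first matching atom; StructureError if absent."""
        for i, a in enumerate(self.atoms):
            if (
                a.residue_name == residue_name
                and a.residue_number == residue_number
                and a.name == atom_name
            ):
                return i
        raise StructureError(
            f"{self.id}: no atom '{residue_name} {residue_number} {atom_name}'"
        )


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def read_pdb(source, structure_id: str | None = None) -> Structure:
    """Parse a PDB file or PDB-format string into a Structure.

    Model 1 only; of alternate locations only the first (blank or 'A') is
    kept; HETATM records are retained here and removed by
    :func:`strip_non_protein`.
    """
    import os

    if isinstance(source, (str, os.PathLike)) and "\n" not in str(source):
        path = str(source)
        with open(path) as fh:
            text = fh.read()
        default_id = os.path.splitext(os.path.basename(path))[0]
    else:
        text = str(source)
        default_id = "structure"

    lines = text.splitlines()
    if not any(l.startswith(("ATOM", "HETATM")) for l in lines):
        first_bad = next((l for l in lines if l.strip()), "<empty input>")
        raise StructureError(
            f"no ATOM/HETATM records found; first line was: {first_bad!r}"
        )

    pdb = PDBFile.read(io.StringIO(text))
    arr = pdb.get_structure(model=1, altloc="first", extra_fields=["atom_id"])

    atoms = []
    for i in range(arr.array_length()):
        element = str(arr.element[i]) or _guess_element(str(arr.atom_name[i]))
        atoms.append(
            Atom(
                serial=int(arr.atom_id[i]),
                name=str(arr.atom_name[i]),
                element=element,
                residue_name=str(arr.res_name[i]),
                residue_number=int(arr.res_id[i]),
                chain=str(arr.chain_id[i]) or "A",
                position=tuple(float(x) for x in arr.coord[i]),
            )
        )
    return Structure(structure_id or default_id, atoms)


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


def write_pdb(s: Structure, path=None) -> str:
    """Write a Structure as PDB text; also to ``path`` when given."""
    n = len(s.atoms)
    arr = struc.AtomArray(n)
    arr.coord = s.coords().astype(np.float32)
    arr.chain_id = np.array([a.chain for a in s.atoms])
    arr.res_id = np.array([a.residue_number for a in s.atoms])
    arr.res_name = np.array([a.residue_name for a in s.atoms])
    arr.atom_name = np.array([a.name for a in s.atoms])
    arr.element = np.array([a.element for a in s.atoms])
    arr.hetero = np.array(
        [a.residue_name not in STANDARD_AMINO_ACIDS for a in s.atoms]
    )
    arr.set_annotation("atom_id", np.array([a.serial for a in s.atoms]))
    pdb = PDBFile()
    pdb.set_structure(arr)
    remark = [f"REMARK 250 ID {s.id}"]
    for k, v in s.meta.items():
        if isinstance(v, (str, int, float)):
            remark.append(f"REMARK 250 {str(k).upper()} {v}")
    text = "\n".join(remark + pdb.lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def strip_non_protein(s: Structure) -> Structure:
    """Keep only atoms of the 20 standard amino acids (waters, ligands, sugars go)."""
    atoms = [a for a in s.atoms if a.residue_name in STANDARD_AMINO_ACIDS]
    if not atoms:
        raise StructureError(f"{s.id}: no protein content")
    return Structure(s.id, atoms, dict(s.meta))


def reflect_structure(s: Structure) -> Structure:
    """Mirror the structure through the x = 0 plane (x → −x; y, z untouched)."""
    atoms = [
        replace(a, position=(-a.position[0], a.position[1], a.position[2]))
        for a in s.atoms
    ]
    return Structure(s.id, atoms, dict(s.meta))


# ---------------------------------------------------------------------------
# Catalytic anchors
# ---------------------------------------------------------------------------

#: default side-chain base nitrogen per residue type
_BASE_ATOM_DEFAULT = {"HIS": "NE2", "LYS": "NZ", "ARG": "NH1"}


def _parse_selector(spec) -> tuple[str, int, str | None]:
    """'HIS 224 NE2' or 'HIS 224' → (resname, resnum, atom-or-None)."""
    if isinstance(spec, (tuple, list)):
        parts = [str(p) for p in spec]
    else:
        parts = str(spec).split()
    if len(parts) not in (2, 3):
        raise StructureError(f"bad residue selector {spec!r}")
    name, num = parts[0].upper(), int(parts[1])
    atom = parts[2].upper() if len(parts) == 3 else None
    return name, num, atom


@dataclass
class CatalyticAnchors:
    """Atom references used for superposition: general base, oxyanion hole, serine Oγ.

    Indices into the owning structure's atom list are kept so anchors can be
    re-resolved after a coordinate transform.
    """

    base_atom: Atom
    oxyanion_atoms: tuple[Atom, Atom]
    serine_og: Atom | None
    indices: tuple[int, ...]  # (base, oxy1, oxy2[, ser])

    def __post_init__(self):
        pts = self.points()[:3]
        keys = {tuple(p) for p in pts}
        if len(keys) != 3:
            raise StructureError("anchor atoms are not distinct")
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        if d.max() >= 20.0:
            raise StructureError(
                f"anchor atoms too far apart ({d.max():.1f} Å >= 20 Å)"
            )

    def points(self) -> np.ndarray:
        atoms = [self.base_atom, *self.oxyanion_atoms]
        if self.serine_og is not None:
            atoms.append(self.serine_og)
        return np.array([a.position for a in atoms], dtype=float)

    def remap(self, s: Structure) -> "CatalyticAnchors":
        """Re-resolve the same atom indices against (a transformed copy of) s."""
        idx = self.indices
        ser = s.atoms[idx[3]] if len(idx) == 4 else None
        return CatalyticAnchors(
            s.atoms[idx[0]], (s.atoms[idx[1]], s.atoms[idx[2]]), ser, idx
        )

    def signed_volume(self) -> float | None:
        """Signed volume of the (base, oxy1, oxy2, Oγ) tetrahedron; None without Oγ."""
        if self.serine_og is None:
            return None
        p = self.points()
        return float(np.linalg.det(p[1:4] - p[0]) / 6.0)


def extract_anchors(
    s: Structure,
    base_spec,
    oxyanion_specs,
    serine_spec=None,
) -> CatalyticAnchors:
    """Resolve catalytic anchor selectors on a structure.

    ``base_spec`` names the general-base residue ('HIS 224' → its Nε2 by
    default, or 'HIS 224 ND1' to override). Each of the two
    ``oxyanion_specs`` resolves to the backbone amide N unless an explicit
    atom name overrides it (e.g. 'TYR 150 OH' for a Tyr-based oxyanion hole).
    """
    bname, bnum, batom = _parse_selector(base_spec)
    if batom is None:
        batom = _BASE_ATOM_DEFAULT.get(bname)
        if batom is None:
            raise StructureError(
                f"no default base atom for residue {bname}; give one explicitly"
            )
    try:
        bidx = s.find_atom(bname, bnum, batom)
    except StructureError as e:
        raise StructureError(f"base selector {base_spec!r}: {e}") from e

    if len(oxyanion_specs) != 2:
        raise StructureError("exactly two oxyanion-hole selectors required")
    oidx = []
    for spec in oxyanion_specs:
        oname, onum, oatom = _parse_selector(spec)
        try:
            oidx.append(s.find_atom(oname, onum, oatom or "N"))
        except StructureError as e:
            raise StructureError(f"oxyanion selector {spec!r}: {e}") from e

    sidx = None
    if serine_spec is not None:
        sname, snum, satom = _parse_selector(serine_spec)
        try:
            sidx = s.find_atom(sname, snum, satom or "OG")
        except StructureError as e:
            raise StructureError(f"serine selector {serine_spec!r}: {e}") from e

    indices = (bidx, oidx[0], oidx[1]) + ((sidx,) if sidx is not None else ())
    ser = s.atoms[sidx] if sidx is not None else None
    return CatalyticAnchors(
        s.atoms[bidx], (s.atoms[oidx[0]], s.atoms[oidx[1]]), ser, indices
    )


# ---------------------------------------------------------------------------
# Rigid transforms & Horn superposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x ↦ R·x + t (matrices act on column vectors)."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3×3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthogonal within 1e-9")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation is not proper (det ≠ +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def horn_fit(moving, fixed) -> tuple[RigidTransform, float]:
    """Least-squares proper rigid superposition (quaternion method).

    Returns the transform taking ``moving`` onto ``fixed`` and the residual
    RMSD. The rotation is the closed-form optimum: the eigenvector of the
    4×4 quaternion matrix built from the cross-covariance of the centred
    point sets, belonging to its largest eigenvalue. Reflections are never
    produced; a mirror-image point set therefore keeps a strictly positive
    residual.
    """
    mv = np.asarray(moving, dtype=float).reshape(-1, 3)
    fx = np.asarray(fixed, dtype=float).reshape(-1, 3)
    if mv.shape != fx.shape:
        raise ValueError(f"point count mismatch: {mv.shape[0]} vs {fx.shape[0]}")
    n = mv.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")

    cm, cf = mv.mean(axis=0), fx.mean(axis=0)
    a, b = mv - cm, fx - cf
    for pts, label in ((a, "moving"), (b, "fixed")):
        if np.linalg.matrix_rank(pts, tol=1e-8) < 2:
            raise ValueError(f"degenerate geometry: {label} points are collinear")

    S = a.T @ b  # cross-covariance
    sxx, sxy, sxz = S[0]
    syx, syy, syz = S[1]
    szx, szy, szz = S[2]
    N = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    w, v = np.linalg.eigh(N)
    q = v[:, -1]  # unit quaternion (w, x, y, z) of the max eigenvalue
    qw, qx, qy, qz = q
    R = np.array(
        [
            [
                qw * qw + qx * qx - qy * qy - qz * qz,
                2 * (qx * qy - qw * qz),
                2 * (qx * qz + qw * qy),
            ],
            [
                2 * (qx * qy + qw * qz),
                qw * qw - qx * qx + qy * qy - qz * qz,
                2 * (qy * qz - qw * qx),
            ],
            [
                2 * (qx * qz - qw * qy),
                2 * (qy * qz + qw * qx),
                qw * qw - qx * qx - qy * qy + qz * qz,
            ],
        ]
    )
    # re-orthonormalize to meet the 1e-9 properness contract
    U, _, Vt = np.linalg.svd(R)
    R = U @ Vt
    if np.linalg.det(R) < 0:  # numerically safeguarded; Horn R is proper
        U[:, -1] *= -1
        R = U @ Vt
    t = cf - R @ cm
    tr = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((tr.apply(mv) - fx) ** 2, axis=1))))
    return tr, rmsd


def superpose_on_anchors(
    structures: list[tuple[Structure, CatalyticAnchors]],
    iterations: int = 15,
    auto_reflect: bool = False,
):
    """Iteratively superpose structures on their catalytic anchor atoms.

    Round 1 fits every structure onto the first (the reference); each later
    round refits every structure onto the arithmetic mean of the current
    anchor positions. With ``auto_reflect`` a structure whose anchor
    tetrahedron has the opposite signed volume to the reference (serine Oγ
    required on both) is mirrored before fitting.

    Returns ``(aligned_structures, trace)`` where ``trace[r]`` is the overall
    anchor RMSD about the mean after round r (non-increasing).
    """
    if len(structures) < 2:
        raise ValueError("need at least two structures")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")

    pairs = [(s, anc.remap(s)) for s, anc in structures]

    if auto_reflect:
        ref_vol = pairs[0][1].signed_volume()
        out = [pairs[0]]
        for s, anc in pairs[1:]:
            vol = anc.signed_volume()
            if ref_vol is not None and vol is not None and ref_vol * vol < 0:
                s2 = reflect_structure(s)
                out.append((s2, anc.remap(s2)))
            else:
                out.append((s, anc))
        pairs = out

    npts = min(len(anc.indices) for _, anc in pairs)  # 3, or 4 when all have Oγ

    def anchor_pts(anc):
        return anc.points()[:npts]

    current = list(pairs)
    trace = []
    for rnd in range(iterations):
        if rnd == 0:
            target = anchor_pts(current[0][1])
            fitted = [current[0]]
            to_fit = current[1:]
        else:
            target = np.mean([anchor_pts(anc) for _, anc in current], axis=0)
            fitted = []
            to_fit = current
        for s, anc in to_fit:
            tr, _ = horn_fit(anchor_pts(anc), target)
            s2 = s.with_coords(tr.apply(s.coords()))
            fitted.append((s2, anc.remap(s2)))
        current = fitted
        all_pts = np.array([anchor_pts(anc) for _, anc in current])
        mean = all_pts.mean(axis=0)
        trace.append(float(np.sqrt(np.mean(np.sum((all_pts - mean) ** 2, axis=-1)))))
    return [s for s, _ in current], np.array(trace)


# ---------------------------------------------------------------------------
# Backbone RMSD baseline
# ---------------------------------------------------------------------------

def _backbone_by_residue(s: Structure) -> list[dict[str, np.ndarray]]:
    residues: dict[tuple, dict[str, np.ndarray]] = {}
    order: list[tuple] = []
    for a in s.atoms:
        if a.name in BACKBONE_ATOMS and a.residue_name in STANDARD_AMINO_ACIDS:
            key = (a.chain, a.residue_number)
            if key not in residues:
                residues[key] = {}
                order.append(key)
            residues[key].setdefault(a.name, np.array(a.position, dtype=float))
    return [residues[k] for k in order]


def backbone_rmsd(a: Structure, b: Structure) -> float:
    """Backbone RMSD after optimal superposition, pairing residues by rank."""
    ra, rb = _backbone_by_residue(a), _backbone_by_residue(b)
    if not ra or not rb:
        lacking = a.id if not ra else b.id
        raise StructureError(f"{lacking}: no backbone atoms")
    n = min(len(ra), len(rb))
    pa, pb = [], []
    for i in range(n):
        for name in BACKBONE_ATOMS:
            if name in ra[i] and name in rb[i]:
                pa.append(ra[i][name])
                pb.append(rb[i][name])
    if len(pa) < 3:
        raise StructureError("fewer than 3 shared backbone atoms")
    _, rmsd = horn_fit(np.array(pa), np.array(pb))
    return rmsd


def backbone_rmsd_matrix(structures: list[Structure]) -> np.ndarray:
    """Symmetric all-against-all backbone RMSD matrix (Å), zero diagonal."""
    n = len(structures)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = backbone_rmsd(structures[i], structures[j])
    return m
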