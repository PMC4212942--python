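"""Active-site detection on a 3-D lattice.

A pocket is an *enclosed but accessible* region: lattice nodes that lie
outside the protein's van der Waals volume (with a 1.4 Å solvent probe) yet
see protein in most scan directions. The detector is a buriedness scan in
the LIGSITE tradition: 26 lattice rays per node, a node is buried when at
least ``b_min`` of them hit protein within ``scan_range``. The pocket is
the largest 26-connected buried component. A deterministic fallback,
anchored on the catalytic serine Oγ, is provided for workflows where cavity
detection must not influence the result (e.g. projecting point mutants).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .chem import vdw_radius
from .structure_io import Structure


class PocketError(ValueError):
    """Raised when no usable pocket can be found."""


@dataclass(frozen=True)
class GridSpec:
    """A regular Cartesian lattice: origin (Å), spacing (Å), node counts."""

    origin: tuple[float, float, float]
    spacing: float
    shape: tuple[int, int, int]

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if any(s < 2 for s in self.shape):
            raise ValueError("grid shape must be at least 2 per axis")

    @classmethod
    def around(cls, s: Structure, spacing: float = 1.0, margin: float = 4.0) -> "GridSpec":
        """Lattice covering the structure's bounding box plus a margin."""
        xyz = s.coords()
        lo = xyz.min(axis=0) - margin
        hi = xyz.max(axis=0) + margin
        shape = tuple(int(np.ceil((hi[i] - lo[i]) / spacing)) + 1 for i in range(3))
        return cls(tuple(float(v) for v in lo), float(spacing), shape)

    def node_coords(self) -> np.ndarray:
        """(nx*ny*nz, 3) array of node positions in C order."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return np.asarray(self.origin) + idx * self.spacing

    def position(self, index: tuple[int, int, int]) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(index) * self.spacing


@dataclass
class Pocket:
    """A detected site: lattice, boolean node mask and mask centroid."""

    grid: GridSpec
    mask: np.ndarray  # bool, shape == grid.shape
    centroid: np.ndarray  # (3,), Å

    def __post_init__(self):
        if self.mask.shape != tuple(self.grid.shape):
            raise ValueError("mask shape does not match grid")
        if not self.mask.any():
            raise PocketError("empty pocket mask")

    @property
    def n_nodes(self) -> int:
        return int(self.mask.sum())

    def node_positions(self) -> np.ndarray:
        idx = np.argwhere(self.mask)
        return np.asarray(self.grid.origin) + idx * self.grid.spacing

    def contains(self, point, tol: float = 0.0) -> bool:
        """Whether ``point`` lies within ``tol`` + spacing/2 of a masked node."""
        d = np.linalg.norm(self.node_positions() - np.asarray(point), axis=1)
        return bool(d.min() <= self.grid.spacing / 2 * np.sqrt(3) + tol)


# 26 scan directions: all nonzero offsets in {-1,0,1}^3
_DIRECTIONS = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ],
    dtype=int,
)


def _occupancy(s: Structure, grid: GridSpec, pad: float) -> np.ndarray:
    """Boolean grid: node within (vdW radius + pad) of any heavy atom.

    Hydrogens are ignored, the usual convention in cavity detection: polar
    H's must not exclude the very region where an H-bonding probe sits.
    """
    nodes = grid.node_coords()
    tree = cKDTree(nodes)
    occ = np.zeros(len(nodes), dtype=bool)
    for a in s.atoms:
        if a.element.upper() == "H":
            continue
        r = vdw_radius(a.element) + pad
        occ[tree.query_ball_point(a.position, r)] = True
    return occ.reshape(grid.shape)


def _shift(arr: np.ndarray, offset: np.ndarray) -> np.ndarray:
    """Shift a boolean grid by an integer offset, zero-filling at the borders."""
    out = np.zeros_like(arr)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, o in enumerate(offset):
        if o > 0:
            src[ax], dst[ax] = slice(o, None), slice(None, -o)
        elif o < 0:
            src[ax], dst[ax] = slice(None, o), slice(-o, None)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def buriedness(protein: np.ndarray, spacing: float, scan_range: float) -> np.ndarray:
    """Per-node count (0–26) of lattice directions that hit protein within range."""
    counts = np.zeros(protein.shape, dtype=np.int8)
    for d in _DIRECTIONS:
        step_len = np.linalg.norm(d) * spacing
        n_steps = int(np.floor(scan_range / step_len))
        hit = np.zeros_like(protein)
        for k in range(1, n_steps + 1):
            hit |= _shift(protein, d * k)
        counts += hit
    return counts


def detect_pocket(
    s: Structure,
    spacing: float = 1.0,
    margin: float = 4.0,
    probe_radius: float = 1.4,
    scan_range: float = 8.0,
    b_min: int = 16,
    max_pocket_radius: float = 25.0,
    grid: GridSpec | None = None,
) -> Pocket:
    """Detect the largest buried cavity of a structure.

    Nodes must be solvent-accessible (outside every atom's van der Waals
    sphere inflated by ``probe_radius``) and buried (≥ ``b_min`` of 26 scan
    directions hit protein within ``scan_range`` Å). Ties between equally
    large components go to the one whose centroid is nearest the structure
    centroid.
    """
    if len(s.atoms) < 30:
        raise PocketError(
            f"{s.id}: only {len(s.atoms)} atoms; use pocket_from_serine for tiny inputs"
        )
    if grid is None:
        grid = GridSpec.around(s, spacing=spacing, margin=margin)
    protein = _occupancy(s, grid, pad=0.0)
    accessible = ~_occupancy(s, grid, pad=probe_radius)
    counts = buriedness(protein, grid.spacing, scan_range)
    candidate = accessible & (counts >= b_min)
    if not candidate.any():
        raise PocketError(f"{s.id}: no pocket found")

    labels, n_comp = ndimage.label(candidate, structure=np.ones((3, 3, 3), dtype=int))
    sizes = ndimage.sum_labels(candidate, labels, index=np.arange(1, n_comp + 1))
    best = int(sizes.max())
    tied = [i + 1 for i, sz in enumerate(sizes) if int(sz) == best]
    if len(tied) > 1:
        struct_centroid = s.coords().mean(axis=0)
        origin = np.asarray(grid.origin)

        def comp_dist(lab):
            idx = np.argwhere(labels == lab)
            c = origin + idx.mean(axis=0) * grid.spacing
            return np.linalg.norm(c - struct_centroid)

        tied.sort(key=comp_dist)
    mask = labels == tied[0]

    centroid = _mask_centroid(grid, mask)
    far = _node_distances(grid, mask, centroid) > max_pocket_radius
    if far.any():
        mask = mask.copy()
        mask[tuple(np.argwhere(mask)[far].T)] = False
        centroid = _mask_centroid(grid, mask)
    return Pocket(grid, mask, centroid)


def pocket_from_serine(
    s: Structure,
    serine_og,
    radius: float = 10.0,
    spacing: float = 1.0,
    margin: float = 4.0,
    probe_radius: float = 1.4,
    grid: GridSpec | None = None,
) -> Pocket:
    """Deterministic pocket: accessible nodes within ``radius`` of the serine Oγ.

    ``serine_og`` is an Atom, a selector string ('SER 105 OG') or a 3-vector.
    """
    if hasattr(serine_og, "position"):
        center = np.asarray(serine_og.position, dtype=float)
    elif isinstance(serine_og, str):
        from .structure_io import _parse_selector

        name, num, atom = _parse_selector(serine_og)
        idx = s.find_atom(name, num, atom or "OG")
        center = np.asarray(s.atoms[idx].position, dtype=float)
    else:
        center = np.asarray(serine_og, dtype=float).reshape(3)

    if grid is None:
        grid = GridSpec.around(s, spacing=spacing, margin=margin)
    accessible = ~_occupancy(s, grid, pad=probe_radius)
    nodes = grid.node_coords()
    near = (np.linalg.norm(nodes - center, axis=1) <= radius).reshape(grid.shape)
    mask = accessible & near
    if not mask.any():
        raise PocketError(f"{s.id}: no pocket found within {radius} Å of serine Oγ")
    return Pocket(grid, mask, _mask_centroid(grid, mask))


def _mask_centroid(grid: GridSpec, mask: np.ndarray) -> np.ndarray:
    idx = np.argwhere(mask)
    return np.asarray(grid.origin) + idx.mean(axis=0) * grid.spacing


def _node_distances(grid: GridSpec, mask: np.ndarray, point: np.ndarray) -> np.ndarray:
    idx = np.argwhere(mask)
    pos = np.asarray(grid.origin) + idx * grid.spacing
    return np.linalg.norm(pos - point, axis=1)


# ---------------------------------------------------------------------------
# Export helpers
# ---------------------------------------------------------------------------

def write_dx(grid: GridSpec, values: np.ndarray, path) -> None:
    """Write a scalar lattice as an OpenDX grid (visualisation interchange)."""
    nx, ny, nz = grid.shape
    vals = np.asarray(values, dtype=float).reshape(grid.shape)
    with open(path, "w") as fh:
        fh.write(
            f"object 1 class gridpositions counts {nx} {ny} {nz}\n"
            f"origin {grid.origin[0]:.3f} {grid.origin[1]:.3f} {grid.origin[2]:.3f}\n"
            f"delta {grid.spacing:.3f} 0 0\n"
            f"delta 0 {grid.spacing:.3f} 0\n"
            f"delta 0 0 {grid.spacing:.3f}\n"
            f"object 2 class gridconnections counts {nx} {ny} {nz}\n"
            f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n"
        )
        flat = vals.ravel(order="C")
        for i in range(0, len(flat), 3):
            fh.write(" ".join(f"{v:.5e}" for v in flat[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')


def pocket_to_pseudo_pdb(p: Pocket, path=None) -> str:
    """Masked nodes as HETATM pseudo-atoms, for quick visual inspection."""
    lines = []
    for i, pos in enumerate(p.node_positions(), start=1):
        lines.append(
            f"HETATM{i % 100000:5d}  DU  PKT A{(i % 9999) + 1:4d}    "
            f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}  1.00  0.00          DU"
        )
    text = "\n".join(lines) + "\nEND\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
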