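"""Four-point fingerprints: the alignment-free Common Reference Framework.

Every combination of four representative points is a *quadruplet*, encoded
by its sorted probe-label multiset, its six binned inter-point distances in
a canonical order, and a chirality sign. Because the code depends only on
labels, distances and handedness, it is invariant under rigid motion of the
site — two sites can be compared by joining their code sets with no prior
superposition. Reflection flips the chirality field (and nothing else), so
mirror-image sites are distinguishable.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field as dc_field

import numpy as np

from .mif import ProbeType, RepresentativePoint

_PROBE_RANK = {ProbeType.H: 0, ProbeType.O: 1, ProbeType.N1: 2, ProbeType.DRY: 3}
_RANK_PROBE = {v: k for k, v in _PROBE_RANK.items()}

#: defaults of the discretization
BIN_WIDTH = 1.0  # Å
MAX_DIST = 16.0  # Å; larger distances share the top bin
PLANARITY_VOLUME = 0.5  # Å³; |signed volume| below this → chirality 0
_N_BINS = 16
_EPS = 1e-9  # guards bin edges against float noise from rigid motions


@dataclass(frozen=True)
class Quadruplet:
    """Four representative points in canonical order with derived geometry."""

    points: tuple  # 4 RepresentativePoint, canonical order
    probe_labels: tuple  # 4 ProbeType, non-decreasing rank
    distances: tuple  # 6 floats: d01 d02 d03 d12 d13 d23 of the canonical order
    chirality: int  # -1, 0, +1

    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.points], dtype=float)

    @property
    def energy_sum(self) -> float:
        return float(sum(abs(p.energy) for p in self.points))


def _sort_key(rank: int, incident: tuple, energy: float) -> tuple:
    return (rank, tuple(round(d, 6) for d in incident), round(energy, 9))


def _signed_volume(pos) -> float:
    (x0, y0, z0), (x1, y1, z1), (x2, y2, z2), (x3, y3, z3) = (
        tuple(map(float, p)) for p in pos
    )
    ax, ay, az = x1 - x0, y1 - y0, z1 - z0
    bx, by, bz = x2 - x0, y2 - y0, z2 - z0
    cx, cy, cz = x3 - x0, y3 - y0, z3 - z0
    det = ax * (by * cz - bz * cy) - ay * (bx * cz - bz * cx) + az * (bx * cy - by * cx)
    return det / 6.0


def canonical_quadruplet(points) -> Quadruplet:
    """Canonicalize four points into a permutation-invariant Quadruplet.

    Points are ordered by (probe rank, sorted incident distances, energy);
    chirality is the sign of the signed volume in that order, zeroed for
    near-planar sets. When the sort keys tie, chirality is the maximum over
    all key-consistent orderings, which keeps the result independent of the
    input permutation (at the cost of chirality for symmetric sets).
    """
    pts = list(points)
    if len(pts) != 4:
        raise ValueError("a quadruplet needs exactly 4 points")
    pos = np.array([p.position for p in pts], dtype=float)
    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    keys = [
        _sort_key(
            _PROBE_RANK[ProbeType(pts[i].probe)],
            tuple(sorted(d[i, j] for j in range(4) if j != i)),
            pts[i].energy,
        )
        for i in range(4)
    ]
    order = sorted(range(4), key=lambda i: keys[i])
    opos = pos[order]
    sv = _signed_volume(opos)
    chir = 0 if abs(sv) < PLANARITY_VOLUME else (1 if sv > 0 else -1)

    if chir != 0 and len(set(keys)) < 4:
        # ties: take the max chirality over key-consistent orderings
        signs = []
        for perm in itertools.permutations(range(4)):
            if [keys[i] for i in perm] == [keys[i] for i in order]:
                v = _signed_volume(pos[list(perm)])
                signs.append(0 if abs(v) < PLANARITY_VOLUME else (1 if v > 0 else -1))
        chir = max(signs)

    dists = tuple(
        float(d[order[i], order[j]]) for i, j in ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
    )
    return Quadruplet(
        points=tuple(pts[i] for i in order),
        probe_labels=tuple(ProbeType(pts[i].probe) for i in order),
        distances=dists,
        chirality=chir,
    )


def enumerate_quadruplets(points) -> list[Quadruplet]:
    """All C(n,4) canonical quadruplets of a point list (n < 4 → empty)."""
    pts = list(points)
    return [canonical_quadruplet(c) for c in itertools.combinations(pts, 4)]


def _bin_index(dist: float, bin_width: float, n_bins: int) -> int:
    return min(int(dist / bin_width + _EPS), n_bins - 1)


def encode_quadruplet(
    q: Quadruplet, bin_width: float = BIN_WIDTH, max_dist: float = MAX_DIST
) -> int:
    """Pack a quadruplet into an integer code.

    Layout (most→least significant): 4 probe ranks (2 bits each), 6 distance
    bins (6 bits each), chirality+1 (2 bits). Identical canonical quadruplets
    yield identical codes; rigid motion preserves the code, reflection flips
    only the chirality field.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = max(1, int(np.ceil(max_dist / bin_width)))
    code = 0
    for lab in q.probe_labels:
        code = (code << 2) | _PROBE_RANK[ProbeType(lab)]
    for dist in q.distances:
        code = (code << 6) | _bin_index(dist, bin_width, n_bins)
    code = (code << 2) | (q.chirality + 1)
    return code


@dataclass
class BioFingerprint:
    """A site's Common Reference Framework: quadruplet codes over pooled points.

    ``point_order[r]`` gives quadruplet r's four point indices in canonical
    order; ``codes[r]`` its integer code; ``energies[r]`` the summed |energy|
    used to rank matches. ``codebook`` maps code → row indices.
    """

    structure_id: str
    points: list  # pooled RepresentativePoint list
    bin_width: float
    max_dist: float
    point_order: np.ndarray  # (m, 4) int32
    codes: np.ndarray  # (m,) int64
    energies: np.ndarray  # (m,) float64
    _codebook: dict | None = dc_field(default=None, repr=False)

    @property
    def n_quadruplets(self) -> int:
        return len(self.codes)

    @property
    def codebook(self) -> dict[int, np.ndarray]:
        if self._codebook is None:
            order = np.argsort(self.codes, kind="stable")
            cb: dict[int, np.ndarray] = {}
            sorted_codes = self.codes[order]
            bounds = np.flatnonzero(np.diff(sorted_codes)) + 1
            for chunk in np.split(order, bounds):
                if len(chunk):
                    cb[int(self.codes[chunk[0]])] = chunk
            self._codebook = cb
        return self._codebook

    def quadruplet(self, row: int) -> Quadruplet:
        return canonical_quadruplet([self.points[i] for i in self.point_order[row]])

    def positions(self, row: int) -> np.ndarray:
        return np.array(
            [self.points[i].position for i in self.point_order[row]], dtype=float
        )

    def to_json(self, path=None) -> str:
        doc = {
            "structure_id": self.structure_id,
            "bin_width": self.bin_width,
            "max_dist": self.max_dist,
            "n_quadruplets": int(self.n_quadruplets),
            "points": [
                {
                    "position": list(p.position),
                    "probe": str(ProbeType(p.probe).value),
                    "energy": p.energy,
                }
                for p in self.points
            ],
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "BioFingerprint":
        import os

        if isinstance(source, (str, os.PathLike)) and "\n" not in str(source):
            with open(source) as fh:
                doc = json.load(fh)
        else:
            doc = json.loads(source)
        points = [
            RepresentativePoint(
                tuple(p["position"]), ProbeType(p["probe"]), float(p["energy"])
            )
            for p in doc["points"]
        ]
        fp = build_fingerprint(
            points,
            bin_width=doc["bin_width"],
            max_dist=doc["max_dist"],
            max_pooled=len(points),
            structure_id=doc["structure_id"],
        )
        if fp.n_quadruplets != doc["n_quadruplets"]:
            raise ValueError("fingerprint JSON is inconsistent with its points")
        return fp


def pool_points(points_by_probe, max_pooled: int = 30) -> list:
    """Pool representative points across probes, strongest first, balanced.

    Round-robin over probes in rank order, each probe's points sorted by
    |energy| descending, until ``max_pooled`` points are collected. Keeps
    the quadruplet count desk-scale while every probe stays represented.
    """
    if isinstance(points_by_probe, dict):
        streams = [
            sorted(points_by_probe.get(p, []), key=lambda rp: (-abs(rp.energy), rp.position))
            for p in sorted(_PROBE_RANK, key=_PROBE_RANK.get)
        ]
    else:
        streams = [sorted(points_by_probe, key=lambda rp: (-abs(rp.energy), rp.position))]
    pooled: list = []
    i = 0
    while len(pooled) < max_pooled and any(streams):
        stream = streams[i % len(streams)]
        if stream:
            pooled.append(stream.pop(0))
        if not stream:
            streams.pop(i % len(streams))
            # keep round-robin position consistent after removal
            i -= 1
        i += 1
    return pooled


def build_fingerprint(
    points_by_probe,
    bin_width: float = BIN_WIDTH,
    max_dist: float = MAX_DIST,
    max_pooled: int = 30,
    structure_id: str = "site",
) -> BioFingerprint:
    """Enumerate and encode all quadruplets of the pooled point set.

    Accepts either a probe → points mapping or a flat point list. Fewer than
    four pooled points yield an empty fingerprint.
    """
    pts = pool_points(points_by_probe, max_pooled=max_pooled)
    n = len(pts)
    if n < 4:
        return BioFingerprint(
            structure_id,
            pts,
            bin_width,
            max_dist,
            np.empty((0, 4), dtype=np.int32),
            np.empty(0, dtype=np.int64),
            np.empty(0),
        )
    # precomputed scalar tables for the tight enumeration loop; the loop
    # reproduces canonical_quadruplet/encode_quadruplet exactly (same keys,
    # same rounding), with a fallback to the general routine on key ties
    pos = [tuple(map(float, p.position)) for p in pts]
    dmat = np.linalg.norm(
        np.array(pos)[:, None, :] - np.array(pos)[None, :, :], axis=-1
    )
    drnd = np.round(dmat, 6).tolist()
    dmat = dmat.tolist()
    n_bins = max(1, int(np.ceil(max_dist / bin_width)))
    bins = [
        [min(int(dmat[i][j] / bin_width + _EPS), n_bins - 1) for j in range(n)]
        for i in range(n)
    ]
    ranks = [_PROBE_RANK[ProbeType(p.probe)] for p in pts]
    erat = [round(p.energy, 9) for p in pts]
    eabs = [abs(p.energy) for p in pts]

    order_rows, codes, energies = [], [], []
    for combo in itertools.combinations(range(n), 4):
        keys = [
            (
                ranks[i],
                tuple(sorted(drnd[i][j] for j in combo if j != i)),
                erat[i],
            )
            for i in combo
        ]
        local = sorted(range(4), key=lambda k: keys[k])
        o = [combo[k] for k in local]
        sv = _signed_volume((pos[o[0]], pos[o[1]], pos[o[2]], pos[o[3]]))
        chir = 0 if abs(sv) < PLANARITY_VOLUME else (1 if sv > 0 else -1)
        if chir != 0 and len(set(keys)) < 4:
            q = canonical_quadruplet([pts[i] for i in combo])
            chir = q.chirality
        code = 0
        for i in o:
            code = (code << 2) | ranks[i]
        for i, j in ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)):
            code = (code << 6) | bins[o[i]][o[j]]
        code = (code << 2) | (chir + 1)
        order_rows.append(o)
        codes.append(code)
        energies.append(eabs[o[0]] + eabs[o[1]] + eabs[o[2]] + eabs[o[3]])
    return BioFingerprint(
        structure_id,
        pts,
        bin_width,
        max_dist,
        np.array(order_rows, dtype=np.int32),
        np.array(codes, dtype=np.int64),
        np.array(energies, dtype=float),
    )
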