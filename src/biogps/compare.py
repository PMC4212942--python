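"""All-against-all active-site comparison via quadruplet matching.

Two sites are compared without any prior superposition: their fingerprints
are joined on identical quadruplet codes, each matched pair of quadruplets
proposes a rigid pose (quaternion fit of the four canonical points), and
candidate poses are scored by the Tanimoto ratio of pseudo-field overlap
volumes. The pose maximizing the global (all-probe, volume-pooled) score is
kept and per-probe scores are reported at that single pose. Batch runs emit
five square similarity matrices: one per probe plus the global score.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.spatial.distance import cdist

from .fingerprint import BioFingerprint, build_fingerprint
from .mif import (
    ALL_PROBES,
    ProbeParameters,
    ProbeType,
    PseudoField,
    compute_field,
    field_overlap,
    select_points,
    to_pseudo_field,
)
from .pocket import Pocket, detect_pocket, pocket_from_serine
from .structure_io import RigidTransform, Structure, horn_fit


@dataclass
class SiteDescription:
    """Everything needed to compare one site: fingerprint + pseudo-fields."""

    id: str
    fingerprint: BioFingerprint
    pseudo_fields: dict  # ProbeType -> PseudoField

    def pooled(self) -> "PooledCloud":
        """Union of all probes' kernels (for the global, volume-pooled score)."""
        return pool_fields(self.pseudo_fields)


_PROBE_INDEX = {p: i for i, p in enumerate(ALL_PROBES)}


@dataclass
class PooledCloud:
    """All probes' kernels side by side, each keeping its probe identity.

    The global score overlaps this union probe-with-probe (an O kernel never
    overlaps an N1 kernel): the probes are different chemical 'colors' of
    density, and crossing them would make a donor-lined and an
    acceptor-lined site look alike.
    """

    positions: np.ndarray  # (k, 3)
    weights: np.ndarray  # (k,)
    sigmas: np.ndarray  # (k,)
    labels: np.ndarray  # (k,) int probe index

    @property
    def n_centers(self) -> int:
        return len(self.weights)

    @property
    def volume(self) -> float:
        return float(np.sum(self.weights * (2.0 * np.pi * self.sigmas**2) ** 1.5))


def pool_fields(fields_by_probe: dict) -> PooledCloud:
    """Concatenate per-probe kernel clouds, labelled by probe."""
    fields = [
        (probe, f)
        for probe, f in fields_by_probe.items()
        if f is not None and f.n_centers
    ]
    if not fields:
        z = np.empty(0)
        return PooledCloud(np.empty((0, 3)), z, z, np.empty(0, dtype=int))
    return PooledCloud(
        np.concatenate([f.positions for _, f in fields]),
        np.concatenate([f.weights for _, f in fields]),
        np.concatenate([f.sigmas for _, f in fields]),
        np.concatenate(
            [np.full(f.n_centers, _PROBE_INDEX[ProbeType(p)]) for p, f in fields]
        ),
    )


def _pooled_pref(a: PooledCloud, b: PooledCloud) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Gaussian prefactors with cross-probe pairs masked to zero."""
    s2 = a.sigmas[:, None] ** 2 + b.sigmas[None, :] ** 2
    pref = (
        a.weights[:, None]
        * b.weights[None, :]
        * (2.0 * np.pi * (a.sigmas[:, None] ** 2 * b.sigmas[None, :] ** 2) / s2) ** 1.5
    )
    pref = pref * (a.labels[:, None] == b.labels[None, :])
    return pref, s2


def _pooled_inner(a: PooledCloud, pos_a: np.ndarray, b: PooledCloud, pos_b: np.ndarray) -> float:
    pref, s2 = _pooled_pref(a, b)
    d2 = cdist(pos_a, pos_b, metric="sqeuclidean")
    return float(np.sum(pref * np.exp(-d2 / (2.0 * s2))))


def _prune(f: PseudoField, min_weight: float = 1e-6) -> PseudoField:
    keep = f.weights > min_weight
    return PseudoField(
        f.probe, f.atom_indices[keep], f.positions[keep], f.weights[keep], f.sigmas[keep]
    )


def describe_site(
    s: Structure,
    pocket: Pocket | None = None,
    params: ProbeParameters | None = None,
    serine=None,
    k_max: int = 30,
    min_sep: float = 1.5,
    max_pooled: int = 30,
    bin_width: float = 1.0,
    max_dist: float = 16.0,
) -> SiteDescription:
    """Run the per-site half of the method: pocket → fields → points → fingerprint."""
    params = params or ProbeParameters()
    if pocket is None:
        pocket = (
            pocket_from_serine(s, serine) if serine is not None else detect_pocket(s)
        )
    points_by_probe = {}
    pseudo = {}
    for probe in ALL_PROBES:
        fld = compute_field(s, pocket, probe, params)
        points_by_probe[probe] = select_points(fld, k_max=k_max, min_sep=min_sep, params=params)
        pseudo[probe] = _prune(to_pseudo_field(fld, s, params))
    fp = build_fingerprint(
        points_by_probe,
        bin_width=bin_width,
        max_dist=max_dist,
        max_pooled=max_pooled,
        structure_id=s.id,
    )
    return SiteDescription(s.id, fp, pseudo)


def transform_site(site: SiteDescription, t: RigidTransform, new_id: str | None = None) -> SiteDescription:
    """Rigidly move a full site description (points, fingerprint, kernels).

    The fingerprint is rebuilt from the moved points; its code multiset is
    invariant under the motion, which is what pose recovery exploits.
    """
    from .mif import RepresentativePoint

    moved_pts = [
        RepresentativePoint(
            tuple(float(v) for v in t.apply(np.asarray(p.position))),
            p.probe,
            p.energy,
        )
        for p in site.fingerprint.points
    ]
    fp = build_fingerprint(
        moved_pts,
        bin_width=site.fingerprint.bin_width,
        max_dist=site.fingerprint.max_dist,
        max_pooled=len(moved_pts),
        structure_id=new_id or site.id,
    )
    fields = {
        probe: PseudoField(
            f.probe, f.atom_indices, t.apply(f.positions), f.weights, f.sigmas
        )
        for probe, f in site.pseudo_fields.items()
    }
    return SiteDescription(new_id or site.id, fp, fields)


# ---------------------------------------------------------------------------
# Quadruplet matching and poses
# ---------------------------------------------------------------------------

_PER_CODE_CAP = 20  # rows considered per code and side before global ranking


@dataclass(frozen=True)
class QuadrupletMatch:
    code: int
    row_a: int
    row_b: int
    energy: float  # combined |energy| of the eight points


def match_quadruplets(
    fa: BioFingerprint, fb: BioFingerprint, top_m: int = 200
) -> list[QuadrupletMatch]:
    """Exact-key join of two fingerprints' code sets.

    Within a shared code, rows pair combinatorially (capped per side by
    energy rank); the joined list is sorted by combined |energy| descending
    with symmetric tie-breaks and truncated to ``top_m``.
    """
    shared = set(fa.codebook) & set(fb.codebook)
    matches: list[QuadrupletMatch] = []
    for code in shared:
        ra = fa.codebook[code]
        rb = fb.codebook[code]
        ra = ra[np.argsort(-fa.energies[ra], kind="stable")][:_PER_CODE_CAP]
        rb = rb[np.argsort(-fb.energies[rb], kind="stable")][:_PER_CODE_CAP]
        for i in ra:
            for j in rb:
                matches.append(
                    QuadrupletMatch(
                        code,
                        int(i),
                        int(j),
                        float(fa.energies[i] + fb.energies[j]),
                    )
                )
    matches.sort(
        key=lambda m: (
            -m.energy,
            m.code,
            tuple(sorted((round(fa.energies[m.row_a], 9), round(fb.energies[m.row_b], 9)))),
        )
    )
    return matches[:top_m]


def pose_from_match(
    fa: BioFingerprint, fb: BioFingerprint, match: QuadrupletMatch
) -> RigidTransform | None:
    """Rigid pose overlaying b's quadruplet onto a's; None when degenerate."""
    pa = fa.positions(match.row_a)
    pb = fb.positions(match.row_b)
    try:
        tr, _ = horn_fit(pb, pa)
    except ValueError:
        return None  # collinear quadruplet: skip signal
    return tr


def _dedupe_poses(
    poses: list[RigidTransform], rot_tol_deg: float = 2.0, trans_tol: float = 0.25
) -> list[RigidTransform]:
    kept: list[RigidTransform] = []
    cos_tol = np.cos(np.radians(rot_tol_deg))
    for t in poses:
        dup = False
        for k in kept:
            rel = k.rotation.T @ t.rotation
            c = (np.trace(rel) - 1.0) / 2.0
            if c >= cos_tol and np.linalg.norm(t.translation - k.translation) < trans_tol:
                dup = True
                break
        if not dup:
            kept.append(t)
    return kept


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

@dataclass
class ProbeScores:
    """Per-probe and global Tanimoto similarity at one superposition."""

    scores: dict  # ProbeType -> float in [0,1], or None when probe absent both sides
    global_score: float
    best_transform: RigidTransform | None
    no_pose: bool = False

    def __getitem__(self, probe) -> float | None:
        return self.scores[ProbeType(probe)]


def _tanimoto(va: float, vb: float, vov: float) -> float:
    denom = va + vb - vov
    if denom <= 0:
        return 0.0
    return float(min(1.0, vov / denom))


def _global_overlap(pa: PooledCloud, pb: PooledCloud, pos_b: np.ndarray) -> float:
    """Tanimoto of the pooled clouds (probe-with-probe) with b transformed."""
    va, vb = pa.volume, pb.volume
    if pa.n_centers == 0 or pb.n_centers == 0:
        return 1.0 if pa.n_centers == pb.n_centers else 0.0
    oaa = _pooled_inner(pa, pa.positions, pa, pa.positions)
    obb = _pooled_inner(pb, pos_b, pb, pos_b)
    oab = _pooled_inner(pa, pa.positions, pb, pos_b)
    denom = np.sqrt(oaa * obb)
    if denom <= 0:
        return 0.0
    vov = min(1.0, oab / denom) * min(va, vb)
    return _tanimoto(va, vb, vov)


def score_pose(
    a_fields: dict, b_fields: dict, t: RigidTransform
) -> ProbeScores:
    """Tanimoto scores of two pseudo-field sets at a given superposition."""
    scores = {}
    for probe in ALL_PROBES:
        pa = a_fields.get(probe)
        pb = b_fields.get(probe)
        if pa is None or pb is None or (pa.n_centers == 0 and pb.n_centers == 0):
            scores[probe] = None
            continue
        va, vb, vov = field_overlap(pa, pb, t)
        scores[probe] = _tanimoto(va, vb, vov)
    pa_pool = pool_fields(a_fields)
    pb_pool = pool_fields(b_fields)
    g = _global_overlap(pa_pool, pb_pool, t.apply(pb_pool.positions))
    return ProbeScores(scores, g, t)


def compare_pair(
    a: SiteDescription,
    b: SiteDescription,
    top_m: int = 200,
    rot_tol_deg: float = 2.0,
    trans_tol: float = 0.25,
) -> ProbeScores:
    """Best-pose comparison of two sites.

    Pose candidates come from the top-``top_m`` quadruplet matches, deduped
    by rotation/translation proximity; the global score selects the pose
    (first-encountered wins ties) and all probe scores are reported there.
    Zero usable poses give all-zero scores flagged ``no_pose``.
    """
    matches = match_quadruplets(a.fingerprint, b.fingerprint, top_m=top_m)
    poses = [
        p
        for m in matches
        if (p := pose_from_match(a.fingerprint, b.fingerprint, m)) is not None
    ]
    poses = _dedupe_poses(poses, rot_tol_deg, trans_tol)
    if not poses:
        return ProbeScores(
            {p: 0.0 for p in ALL_PROBES}, 0.0, None, no_pose=True
        )

    pa_pool = a.pooled()
    pb_pool = b.pooled()
    best_t, best_g = None, -1.0
    if pa_pool.n_centers and pb_pool.n_centers:
        # evaluate the pooled Tanimoto for all poses in one vectorized sweep
        oaa = _pooled_inner(pa_pool, pa_pool.positions, pa_pool, pa_pool.positions)
        obb = _pooled_inner(pb_pool, pb_pool.positions, pb_pool, pb_pool.positions)
        va, vb = pa_pool.volume, pb_pool.volume
        pref, s2 = _pooled_pref(pa_pool, pb_pool)
        denom = np.sqrt(oaa * obb)
        for t in poses:
            d2 = cdist(pa_pool.positions, t.apply(pb_pool.positions), metric="sqeuclidean")
            oab = float(np.sum(pref * np.exp(-d2 / (2.0 * s2))))
            vov = min(1.0, oab / denom) * min(va, vb) if denom > 0 else 0.0
            g = _tanimoto(va, vb, vov)
            if g > best_g + 1e-12:
                best_g, best_t = g, t
    else:
        best_t = poses[0]
    return score_pose(a.pseudo_fields, b.pseudo_fields, best_t)


# ---------------------------------------------------------------------------
# Batch comparison
# ---------------------------------------------------------------------------

_MATRIX_KEYS = ("H", "O", "N1", "DRY", "global")


@dataclass
class SimilarityMatrices:
    """Five symmetric all-against-all score matrices (H, O, N1, DRY, global).

    Entries are in [0,1]; an entry is NaN when that probe is absent on both
    sides of the pair. Failed pairwise comparisons are flagged, not fatal.
    """

    ids: list
    matrices: dict  # key in _MATRIX_KEYS -> (n, n) ndarray
    flags: list = dc_field(default_factory=list)  # (i, j, reason)

    def __getitem__(self, key) -> np.ndarray:
        return self.matrices[str(key)]

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_tsv(self, key, path=None) -> str:
        m = self.matrices[str(key)]
        lines = ["\t".join(["id"] + list(self.ids))]
        for i, sid in enumerate(self.ids):
            lines.append("\t".join([sid] + [f"{v:.6f}" for v in m[i]]))
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_tsv(cls, paths: dict) -> "SimilarityMatrices":
        ids = None
        matrices = {}
        for key, path in paths.items():
            with open(path) as fh:
                header = fh.readline().rstrip("\n").split("\t")[1:]
                rows = [
                    [float(v) for v in line.rstrip("\n").split("\t")[1:]]
                    for line in fh
                    if line.strip()
                ]
            if ids is None:
                ids = header
            elif ids != header:
                raise ValueError("matrix files disagree on structure ids")
            matrices[str(key)] = np.array(rows)
        return cls(ids, matrices)


def all_against_all(
    sites: list, top_m: int = 200, self_tol: float = 1e-6
) -> SimilarityMatrices:
    """Compare every site with itself and with every other site.

    The upper triangle (and diagonal) is computed and mirrored; the computed
    self-similarities are asserted ≈ 1. Pairwise failures become flagged
    zero entries rather than aborting the batch.
    """
    if len(sites) < 2:
        raise ValueError("need at least two sites")
    n = len(sites)
    mats = {k: np.full((n, n), np.nan) for k in _MATRIX_KEYS}
    flags = []
    for i in range(n):
        for j in range(i, n):
            try:
                ps = compare_pair(sites[i], sites[j], top_m=top_m)
            except Exception as exc:  # noqa: BLE001 - batch robustness by contract
                flags.append((i, j, repr(exc)))
                ps = ProbeScores({p: 0.0 for p in ALL_PROBES}, 0.0, None, no_pose=True)
            if ps.no_pose and i != j:
                flags.append((i, j, "no usable pose"))
            for probe in ALL_PROBES:
                v = ps.scores[probe]
                mats[probe.value][i, j] = mats[probe.value][j, i] = (
                    np.nan if v is None else v
                )
            mats["global"][i, j] = mats["global"][j, i] = ps.global_score
        if abs(mats["global"][i, i] - 1.0) > self_tol:
            flags.append((i, i, f"self-similarity {mats['global'][i, i]:.6f} != 1"))
    return SimilarityMatrices([s.id for s in sites], mats, flags)
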