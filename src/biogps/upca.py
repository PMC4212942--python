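"""Unsupervised pattern analysis of similarity profiles.

Each structure is described by its row of a similarity matrix — its
Tanimoto profile against every reference structure. PCA of those profiles
(mean-centred, unscaled) yields a low-dimensional map in which clusters of
like sites emerge without any supervision; the first component maximizes
the profile variance, later components the remaining variance. A fitted
model stores the column means and loadings, so *new* structures (e.g.
designed mutants) can be projected into the existing map by computing only
their similarity row against the original references — the model is never
refitted. A classical-MDS embedding of a backbone-RMSD matrix is provided
as the purely geometric baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np


@dataclass
class Embedding:
    """Low-dimensional coordinates of a set of structures."""

    ids: list
    coords: np.ndarray  # (n, k)
    variance_shares: np.ndarray  # (k,)
    labels: list | None = None  # optional class labels, plotting only
    warning: str | None = None

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if len(self.ids) != self.coords.shape[0]:
            raise ValueError("coordinate count must equal id count")

    def to_tsv(self, path=None) -> str:
        k = self.coords.shape[1]
        header = ["id"] + [f"PC{i + 1}" for i in range(k)]
        if self.labels is not None:
            header.append("label")
        lines = ["\t".join(header)]
        for i, sid in enumerate(self.ids):
            row = [sid] + [f"{v:.6f}" for v in self.coords[i]]
            if self.labels is not None:
                row.append(str(self.labels[i]))
            lines.append("\t".join(row))
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass
class UPCAModel:
    """A fitted PCA over similarity profiles, able to project new sites.

    Self-similarity entries (the matrix diagonal, identically 1) carry no
    comparative information and would give training rows a spike a new
    object's profile can never have, biasing every projection toward the
    map centre. When ``self_impute`` is set, the fit replaced each diagonal
    with its column's off-diagonal mean, and projection applies the same
    replacement to any row entry that identifies the object as a reference.
    """

    reference_ids: list
    which: str  # feature matrix used: H | O | N1 | DRY | global
    means: np.ndarray  # (n,)
    loadings: np.ndarray  # (n, k), orthonormal columns
    explained_variance_ratio: np.ndarray  # (k,), non-increasing, each in [0,1]
    training_scores: np.ndarray = dc_field(default=None, repr=False)  # (n, k)
    self_impute: np.ndarray | None = None  # (n,), per-column imputed self values

    def __post_init__(self):
        evr = np.asarray(self.explained_variance_ratio, dtype=float)
        if np.any(evr < -1e-12) or np.any(evr > 1 + 1e-9):
            raise ValueError("explained variance ratios must lie in [0, 1]")
        if np.any(np.diff(evr) > 1e-9):
            raise ValueError("explained variance ratios must be non-increasing")
        if evr.sum() > 1 + 1e-9:
            raise ValueError("explained variance ratios sum above 1")
        g = self.loadings.T @ self.loadings
        if not np.allclose(g, np.eye(self.loadings.shape[1]), atol=1e-9):
            raise ValueError("loadings columns are not orthonormal within 1e-9")

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, rows: np.ndarray) -> np.ndarray:
        """Project similarity rows (n-vectors against the references).

        With ``self_impute`` set, entries ≥ 1 − 1e-3 are replaced by the
        stored imputed value of their column: a similarity of ~1 says "this
        object *is* that reference", which the fit-time features also
        excluded. Projecting a training structure therefore reproduces its
        fit-time scores exactly.
        """
        rows = np.atleast_2d(np.asarray(rows, dtype=float)).copy()
        if rows.shape[1] != len(self.reference_ids):
            raise ValueError(
                f"similarity rows must have length {len(self.reference_ids)}"
            )
        if self.self_impute is not None:
            for r in rows:
                hit = r >= 1.0 - 1e-3
                r[hit] = self.self_impute[hit]
        return (rows - self.means) @ self.loadings

    def to_json(self, path=None) -> str:
        doc = {
            "reference_ids": list(self.reference_ids),
            "which": self.which,
            "means": self.means.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "training_scores": self.training_scores.tolist()
            if self.training_scores is not None
            else None,
            "self_impute": self.self_impute.tolist()
            if self.self_impute is not None
            else None,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "UPCAModel":
        import os

        if isinstance(source, (str, os.PathLike)) and "\n" not in str(source):
            with open(source) as fh:
                doc = json.load(fh)
        else:
            doc = json.loads(source)
        return cls(
            doc["reference_ids"],
            doc["which"],
            np.array(doc["means"]),
            np.array(doc["loadings"]),
            np.array(doc["explained_variance_ratio"]),
            np.array(doc["training_scores"]) if doc["training_scores"] is not None else None,
            np.array(doc["self_impute"]) if doc.get("self_impute") is not None else None,
        )


def _fix_signs(loadings: np.ndarray, scores: np.ndarray):
    """Deterministic sign convention: each column's largest-|.| loading positive."""
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return loadings, scores


def impute_self_similarity(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Replace the diagonal with each column's off-diagonal mean.

    Returns the imputed matrix and the imputed values (one per column).
    """
    X = np.array(X, dtype=float)
    n = X.shape[0]
    off = X.copy()
    np.fill_diagonal(off, np.nan)
    vals = np.nanmean(off, axis=0)
    X2 = X.copy()
    X2[np.diag_indices(n)] = vals
    return X2, vals


def fit_upca(similarity, which: str = "global", n_components: int = 2,
             impute_self: bool = True):
    """Fit PCA on the rows of a similarity matrix.

    ``similarity`` is a SimilarityMatrices (the ``which`` matrix is taken)
    or a plain symmetric array. Returns ``(UPCAModel, Embedding)``. Each
    object's feature vector is its similarity row to all n references;
    columns are mean-centred, not variance-scaled. With ``impute_self``
    (the default) the self-similarity diagonal is replaced by each column's
    off-diagonal mean before fitting, so training profiles and projected
    profiles live in the same feature space (see UPCAModel).
    """
    if hasattr(similarity, "matrices"):
        ids = list(similarity.ids)
        X = np.array(similarity.matrices[str(which)], dtype=float)
    else:
        X = np.array(similarity, dtype=float)
        ids = [f"obj{i}" for i in range(X.shape[0])]
    n = X.shape[0]
    if X.shape != (n, n):
        raise ValueError("similarity matrix must be square")
    if n < 3:
        raise ValueError("need at least 3 objects")
    if not np.allclose(X, X.T, atol=1e-6, equal_nan=True):
        raise ValueError("similarity matrix is not symmetric")
    if np.isnan(X).any():
        raise ValueError(f"matrix '{which}' has undefined entries; fit on a defined probe")
    if n_components > n:
        raise ValueError("n_components cannot exceed the number of objects")

    self_vals = None
    if impute_self:
        X, self_vals = impute_self_similarity(X)
    means = X.mean(axis=0)
    Xc = X - means
    # SVD of the centred data == eigendecomposition of its covariance
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(S**2))
    evr_all = S**2 / total if total > 0 else np.zeros_like(S)
    loadings = Vt[:n_components].T.copy()
    scores = Xc @ loadings
    loadings, scores = _fix_signs(loadings, scores)
    model = UPCAModel(
        ids, str(which), means, loadings, evr_all[:n_components], scores, self_vals
    )
    emb = Embedding(ids, scores, evr_all[:n_components])
    return model, emb


def project(model: UPCAModel, new_site, reference_sites, **compare_kwargs) -> Embedding:
    """Place a new structure into a fitted map without refitting.

    The new site's Tanimoto similarity against each original reference is
    computed with the compare machinery, centred with the model's stored
    means and multiplied by the loadings. ``reference_sites`` must cover
    every reference id of the model.
    """
    from .compare import compare_pair
    from .mif import ProbeType

    by_id = {s.id: s for s in reference_sites}
    missing = [rid for rid in model.reference_ids if rid not in by_id]
    if missing:
        raise ValueError(f"missing reference site descriptions: {missing}")
    row = np.empty(len(model.reference_ids))
    for i, rid in enumerate(model.reference_ids):
        ps = compare_pair(new_site, by_id[rid], **compare_kwargs)
        if model.which == "global":
            row[i] = ps.global_score
        else:
            v = ps.scores[ProbeType(model.which)]
            row[i] = np.nan if v is None else v
    if np.isnan(row).any():
        raise ValueError("projection similarity row has undefined entries")
    coords = model.transform(row)
    return Embedding([new_site.id], coords, model.explained_variance_ratio)


def project_row(model: UPCAModel, similarity_row) -> np.ndarray:
    """Project a precomputed similarity row; returns (k,) coordinates."""
    return model.transform(similarity_row)[0]


# ---------------------------------------------------------------------------
# Classical MDS baseline on backbone RMSD
# ---------------------------------------------------------------------------

def baseline_rmsd_mds(distances: np.ndarray, n_components: int = 2) -> Embedding:
    """Torgerson classical MDS of a distance matrix (the geometric baseline).

    Double-centres the squared distances, takes the top eigenpairs of the
    Gram matrix and scales eigenvectors by √λ. A warning is attached when
    more than 30% of the spectrum's mass is negative (non-Euclidean input).
    """
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise ValueError("distance matrix diagonal must be zero")

    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]

    neg_mass = float(np.sum(np.abs(w[w < 0])))
    tot_mass = float(np.sum(np.abs(w)))
    warning = None
    if tot_mass > 0 and neg_mass / tot_mass > 0.30:
        warning = f"negative eigenvalue mass {neg_mass / tot_mass:.0%} of spectrum"

    lam = np.clip(w[:n_components], 0.0, None)
    coords = v[:, :n_components] * np.sqrt(lam)
    shares = lam / tot_mass if tot_mass > 0 else np.zeros(n_components)
    coords, _ = _fix_signs(coords.copy(), np.zeros_like(coords)) if coords.size else (coords, None)
    return Embedding([f"obj{i}" for i in range(n)], coords, shares, warning=warning)


# ---------------------------------------------------------------------------
# Plotting
# ---------------------------------------------------------------------------

def plot_embedding(emb: Embedding, path, title: str = "UPCA map") -> None:
    """Scatter of the first two components, colored by label when present."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    xy = emb.coords[:, :2]
    if emb.labels is not None:
        for lab in sorted(set(map(str, emb.labels))):
            sel = [i for i, l in enumerate(emb.labels) if str(l) == lab]
            ax.scatter(xy[sel, 0], xy[sel, 1], label=lab, s=30)
        ax.legend()
    else:
        ax.scatter(xy[:, 0], xy[:, 1], s=30)
    vs = emb.variance_shares
    ax.set_xlabel(f"PC1 ({vs[0] * 100:.0f}%)" if len(vs) > 0 else "PC1")
    ax.set_ylabel(f"PC2 ({vs[1] * 100:.0f}%)" if len(vs) > 1 else "PC2")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
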