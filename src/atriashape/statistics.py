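"""Cohort shape statistics: PCA atlas, discriminant (LDA) shape modes.

Shape vectors (one 12*V-dimensional vector per subject) are decomposed by
principal component analysis on centred data; modes are unit vectors and
the per-mode standard deviations of the subject scores are stored
separately.  The number of retained modes is chosen so that the cohort
mean node-position reconstruction error drops below a threshold
(default 1 mm, about half a typical MR voxel).

Discriminant analysis runs in the retained PCA-score subspace.  The
*inclusive* mode (iLDA) is the Fisher direction over all retained modes;
the *optimized* mode (oLDA) results from an exhaustive subset search over
the retained modes, each candidate scored by leave-one-out
cross-validated AUC.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .hermite import DOF_PER_NODE, HermiteMesh, mesh_to_vector, vector_to_mesh

__all__ = [
    "PCAModel",
    "DiscriminantMode",
    "build_pca",
    "reconstruct",
    "node_reconstruction_error",
    "select_num_modes",
    "fisher_lda",
    "build_ilda",
    "build_olda",
    "synthesize_extreme_shapes",
    "group_mean_shape",
    "mode_marker_correlation",
]


@dataclass
class PCAModel:
    """PCA shape atlas.

    Attributes
    ----------
    mean_shape : (d,) cohort mean shape vector
    modes : (n_modes, d) orthonormal directions, ranked by variance
    mode_sd : (n_modes,) standard deviation of subject scores per mode
    explained_fraction : (n_modes,) fraction of total variance per mode
    scores : (n_subjects, n_modes) per-subject mode scores
    """

    mean_shape: np.ndarray
    modes: np.ndarray
    mode_sd: np.ndarray
    explained_fraction: np.ndarray
    scores: np.ndarray

    @property
    def n_modes(self) -> int:
        return int(self.modes.shape[0])

    @property
    def n_subjects(self) -> int:
        return int(self.scores.shape[0])


@dataclass
class DiscriminantMode:
    """A discriminant direction in PCA-score space and its shape-space image.

    ``subject_scores`` are the projections of the (subspace-restricted)
    PCA scores onto ``direction_pca``; ``direction_shape`` is the same
    direction mapped through the PCA modes back to shape space.
    """

    subspace_ids: list
    direction_pca: np.ndarray
    direction_shape: np.ndarray
    subject_scores: np.ndarray
    kind: str = "inclusive"
    search_log: list = field(default_factory=list)


def _as_matrix(vectors) -> np.ndarray:
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2:
        X = np.vstack([np.asarray(v, dtype=float).ravel() for v in vectors])
    return X


def build_pca(vectors) -> PCAModel:
    """Principal component analysis of cohort shape vectors.

    SVD of the centred data matrix; at most ``n_subjects - 1``
    non-degenerate modes.  Modes are unit vectors; subject scores carry
    the variance.
    """
    X = _as_matrix(vectors)
    n, d = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 subjects")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # drop numerically-zero directions (rank <= n-1 after centring)
    keep = s > max(s[0], 1e-300) * 1e-10 if s[0] > 0 else s > 0
    k = int(np.sum(keep))
    s = s[:k]
    Vt = Vt[:k]
    scores = Xc @ Vt.T
    var = s**2 / n
    total = float(np.sum(Xc**2) / n)
    return PCAModel(
        mean_shape=mean,
        modes=Vt,
        mode_sd=scores.std(axis=0, ddof=0),
        explained_fraction=var / total if total > 0 else var * 0,
        scores=scores,
    )


def reconstruct(pca: PCAModel, subject: int, k: int) -> np.ndarray:
    """Subject's shape vector rebuilt from the first ``k`` PCA modes.

    ``k = 0`` (degenerate) returns the mean shape; ``k = n_modes`` is
    exact up to numerical precision.
    """
    if not 0 <= k <= pca.n_modes:
        raise ValueError(f"k must be in [0, {pca.n_modes}]")
    if k == 0:
        return pca.mean_shape.copy()
    return pca.mean_shape + pca.scores[subject, :k] @ pca.modes[:k]


def node_reconstruction_error(original: HermiteMesh, recon: HermiteMesh) -> float:
    """Mean Euclidean distance between node positions (derivatives excluded), mm."""
    if original.topology.faces.shape != recon.topology.faces.shape or not np.array_equal(
        original.topology.faces, recon.topology.faces
    ):
        raise ValueError("meshes must share the same topology")
    d = np.linalg.norm(original.positions - recon.positions, axis=1)
    return float(d.mean())


def _vector_node_error(v1: np.ndarray, v2: np.ndarray) -> float:
    """node_reconstruction_error on raw shape vectors."""
    p1 = v1.reshape(-1, DOF_PER_NODE)[:, :3]
    p2 = v2.reshape(-1, DOF_PER_NODE)[:, :3]
    return float(np.linalg.norm(p1 - p2, axis=1).mean())


def select_num_modes(pca: PCAModel, vectors=None, threshold: float = 1.0) -> int:
    """Smallest mode count whose cohort-mean node reconstruction error is
    below ``threshold`` (mm).

    The error for subject i at k modes is the mean over nodes of the
    position discrepancy between the original and the k-mode
    reconstruction, averaged per subject and then over the cohort.
    Falls back to all modes (with a warning) if the threshold is never
    reached.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    X = _as_matrix(vectors) if vectors is not None else pca.mean_shape + pca.scores @ pca.modes
    for k in range(1, pca.n_modes + 1):
        errs = [
            _vector_node_error(X[i], reconstruct(pca, i, k))
            for i in range(pca.n_subjects)
        ]
        if float(np.mean(errs)) < threshold:
            return k
    warnings.warn(
        f"reconstruction error never dropped below {threshold} mm; using all modes"
    )
    return pca.n_modes


def fisher_lda(scores: np.ndarray, labels: np.ndarray, ridge: float | None = None):
    """Fisher linear discriminant direction and scalar scores.

    ``w`` is proportional to ``S_w^-1 (mu_1 - mu_0)`` with the pooled
    within-class covariance ``S_w`` (plus a small ridge when
    near-singular), normalised to unit length and oriented so the
    positive class has the larger mean score.

    Returns
    -------
    (w, scalar_scores) -- ``scalar_scores = scores @ w``.
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    if X.shape[0] == 1 and np.asarray(labels).size > 1:
        X = X.T
    y = np.asarray(labels).astype(int).ravel()
    if X.shape[0] != y.size:
        raise ValueError("scores and labels disagree on subject count")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    X0, X1 = X[y == classes[0]], X[y == classes[1]]
    d = X.shape[1]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    dmu = mu1 - mu0
    if np.allclose(dmu, 0):
        warnings.warn("identical class means: discriminant direction is degenerate")
    Sw = np.zeros((d, d))
    for Xi, mui in ((X0, mu0), (X1, mu1)):
        C = Xi - mui
        Sw += C.T @ C
    n_eff = max(len(y) - 2, 1)
    Sw /= n_eff
    if ridge is None:
        ridge = 1e-8 * np.trace(Sw) / d if np.trace(Sw) > 0 else 1e-8
    w = np.linalg.solve(Sw + ridge * np.eye(d), dmu)
    nrm = np.linalg.norm(w)
    if nrm == 0:
        w = dmu if np.linalg.norm(dmu) > 0 else np.ones(d)
        nrm = np.linalg.norm(w)
    w = w / nrm
    s = X @ w
    if s[y == classes[1]].mean() < s[y == classes[0]].mean():
        w, s = -w, -s
    return w, s


def _shape_direction(pca: PCAModel, subspace_ids, w: np.ndarray) -> np.ndarray:
    return w @ pca.modes[list(subspace_ids)]


def build_ilda(pca: PCAModel, labels, k_selected: int) -> DiscriminantMode:
    """Inclusive LDA: Fisher direction over PCA modes 1..k_selected."""
    ids = list(range(k_selected))
    w, s = fisher_lda(pca.scores[:, :k_selected], labels)
    return DiscriminantMode(
        subspace_ids=ids,
        direction_pca=w,
        direction_shape=_shape_direction(pca, ids, w),
        subject_scores=s,
        kind="inclusive",
    )


def build_olda(
    pca: PCAModel,
    labels,
    k_selected: int,
    min_subset: int = 2,
) -> DiscriminantMode:
    """Optimized LDA: exhaustive subset search under leave-one-out AUC.

    Every subset of sizes ``min_subset..k_selected`` of the first
    ``k_selected`` modes is scored by the LOO-CV AUC of its Fisher
    combination (247 subsets for 8 modes at the default ``min_subset=2``;
    255 with ``min_subset=1``).  Ties prefer fewer modes, then
    lexicographic order.  The full search log (subset, resubstitution
    AUC, LOO AUC) is attached to the returned mode.
    """
    from .classify import loo_cv

    if k_selected < min_subset:
        raise ValueError("k_selected must be at least min_subset")
    y = np.asarray(labels).astype(int).ravel()
    log = []
    best = None
    for size in range(min_subset, k_selected + 1):
        for subset in itertools.combinations(range(k_selected), size):
            feats = pca.scores[:, list(subset)]
            cv = loo_cv(feats, y)
            log.append(
                {"subset": subset, "loo_auc": cv.loo_auc,
                 "resubstitution_auc": cv.resubstitution_auc}
            )
            key = (cv.loo_auc, -len(subset), tuple(-i for i in subset))
            if best is None or key > best[0]:
                best = (key, subset)
    subset = list(best[1])
    w, s = fisher_lda(pca.scores[:, subset], y)
    return DiscriminantMode(
        subspace_ids=subset,
        direction_pca=w,
        direction_shape=_shape_direction(pca, subset, w),
        subject_scores=s,
        kind="optimized",
        search_log=log,
    )


def synthesize_extreme_shapes(pca: PCAModel, dmode: DiscriminantMode, n_sd: float = 2.0):
    """Mean shape +/- ``n_sd`` score-SDs along a discriminant mode.

    Visualises the morphology at the extremes of the discriminant axis
    (e.g. typical recurrent vs non-recurrent anatomy).
    """
    sd = float(np.std(dmode.subject_scores, ddof=0))
    if sd == 0:
        raise ValueError("discriminant scores have zero variance")
    delta = n_sd * sd * dmode.direction_shape
    return pca.mean_shape + delta, pca.mean_shape - delta


def group_mean_shape(vectors, labels, group) -> np.ndarray:
    """Arithmetic mean shape vector of one label group."""
    X = _as_matrix(vectors)
    y = np.asarray(labels).ravel()
    mask = y == group
    if not mask.any():
        raise ValueError(f"no subjects with label {group!r}")
    return X[mask].mean(axis=0)


def mode_marker_correlation(pca: PCAModel, marker_values) -> np.ndarray:
    """Pearson correlation of each mode's scores with a scalar marker.

    The sign of each correlation is arbitrary (PCA mode orientation is a
    convention); interpret magnitudes.
    """
    m = np.asarray(marker_values, dtype=float).ravel()
    if m.size != pca.n_subjects:
        raise ValueError("need one marker value per subject")
    if np.std(m) == 0:
        raise ValueError("marker has zero variance")
    mc = m - m.mean()
    out = np.empty(pca.n_modes)
    for j in range(pca.n_modes):
        sc = pca.scores[:, j] - pca.scores[:, j].mean()
        denom = np.linalg.norm(sc) * np.linalg.norm(mc)
        out[j] = float(sc @ mc / denom) if denom > 0 else 0.0
    return out


def meshes_to_vectors(meshes) -> np.ndarray:
    """Stack HermiteMesh objects into a subjects x DOF matrix."""
    return np.vstack([mesh_to_vector(m) for m in meshes])


def vector_to_mesh_like(vector: np.ndarray, like: HermiteMesh) -> HermiteMesh:
    """Rebuild a mesh from a shape vector using another mesh's topology."""
    return vector_to_mesh(vector, like.topology, n_nodes=like.n_nodes)
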