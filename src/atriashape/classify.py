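"""Recurrence classification: ROC/AUC, leave-one-out CV, marker-subset
search, Gaussian score fits, and per-node Hotelling T-squared tests.

AUC uses the rank (Mann-Whitney) formulation with half credit for ties.
Leave-one-out cross-validation pools the out-of-fold scores of every
subject into a single AUC, the only well-defined pooling for LOO; the
resubstitution AUC of the full fit is reported alongside as the
optimistic reference.  Node-wise group comparisons run two-sample
Hotelling T-squared tests on 3D node positions after rigid (no scaling)
generalised Procrustes alignment, with no multiplicity correction by
default.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .statistics import fisher_lda

__all__ = [
    "ROCResult",
    "CVResult",
    "NodeTestResult",
    "roc_auc",
    "loo_cv",
    "marker_combination_search",
    "gaussian_group_fit",
    "hotelling_per_node",
    "rigid_align_meshes",
]


@dataclass
class ROCResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_pos: int
    n_neg: int


@dataclass
class CVResult:
    oof_scores: np.ndarray
    loo_auc: float
    resubstitution_auc: float
    skipped_folds: list = field(default_factory=list)


@dataclass
class NodeTestResult:
    t2: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    alpha: float


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int).ravel()
    if np.unique(y).size != 2:
        raise ValueError("labels must contain exactly two classes")
    return y


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve and AUC by the Mann-Whitney rank statistic (ties get 1/2).

    The AUC is the probability that a positive subject scores above a
    negative one; the returned (FPR, TPR) polyline is the standard
    threshold sweep.
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = _check_binary(labels)
    pos = y == y.max()
    n_pos = int(pos.sum())
    n_neg = int(len(y) - n_pos)
    ranks = stats.rankdata(s)
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-s, kind="stable")
    y_sorted = pos[order].astype(float)
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # collapse tied thresholds
    s_sorted = s[order]
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    return ROCResult(float(auc), fpr, tpr, thresholds, n_pos, n_neg)


def _default_classifier(X_train, y_train, X_test):
    """Fisher LDA scorer used by LOO-CV unless another is supplied."""
    w, _ = fisher_lda(X_train, y_train)
    return np.atleast_2d(X_test) @ w


def loo_cv(features, labels, classifier=_default_classifier) -> CVResult:
    """Leave-one-out cross-validation of a scoring classifier.

    Each subject is scored by a model trained on the remaining n - 1;
    folds whose training set collapses to a single class are skipped with
    a warning.  Deterministic: no internal randomness.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] == 1 and np.asarray(labels).size > 1:
        X = X.T
    y = _check_binary(labels)
    n = len(y)
    if n < 3:
        raise ValueError("LOO-CV needs at least 3 subjects")
    oof = np.full(n, np.nan)
    skipped = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if np.unique(y[mask]).size < 2:
            skipped.append(i)
            warnings.warn(f"fold {i}: single-class training set, skipped")
            continue
        oof[i] = classifier(X[mask], y[mask], X[i:i + 1])[0]
    valid = ~np.isnan(oof)
    loo = roc_auc(oof[valid], y[valid]).auc if np.unique(y[valid]).size == 2 else np.nan
    full_scores = classifier(X, y, X)
    resub = roc_auc(full_scores, y).auc
    return CVResult(oof, float(loo), float(resub), skipped)


def marker_combination_search(
    markers: pd.DataFrame,
    labels,
    marker_columns=None,
    min_size: int = 1,
    max_size: int | None = None,
) -> list[dict]:
    """Exhaustive LDA-combination search over marker subsets.

    Every subset of the configured marker columns (63 subsets for 6
    markers at sizes 1..6) is scored by LOO-CV AUC of its Fisher LDA
    combination.  Subjects missing any value required by a subset are
    excluded for that subset only, so each subset uses the maximum
    available cohort; subsets with too few usable subjects are skipped
    and logged.  Markers are z-scored per subset before the LDA.

    Returns the search log sorted by decreasing LOO AUC; each entry
    carries ``subset``, ``n_used``, ``loo_auc``, ``resubstitution_auc``.
    """
    y_all = np.asarray(labels, dtype=float).ravel()
    cols = list(marker_columns) if marker_columns is not None else [
        c for c in markers.columns if markers[c].dtype.kind in "fi"
    ]
    if not cols:
        raise ValueError("no marker columns to search over")
    max_size = max_size or len(cols)
    results = []
    for size in range(min_size, max_size + 1):
        for subset in itertools.combinations(cols, size):
            sub = markers.loc[:, list(subset)].to_numpy(dtype=float)
            usable = ~np.isnan(sub).any(axis=1) & ~np.isnan(y_all)
            ysub = y_all[usable].astype(int)
            if usable.sum() < 3 or np.unique(ysub).size < 2:
                results.append({"subset": subset, "n_used": int(usable.sum()),
                                "loo_auc": np.nan, "resubstitution_auc": np.nan,
                                "skipped": True})
                continue
            Xsub = sub[usable]
            mu, sd = Xsub.mean(axis=0), Xsub.std(axis=0)
            sd[sd == 0] = 1.0
            cv = loo_cv((Xsub - mu) / sd, ysub)
            results.append({"subset": subset, "n_used": int(usable.sum()),
                            "loo_auc": cv.loo_auc,
                            "resubstitution_auc": cv.resubstitution_auc,
                            "skipped": False})
    results.sort(key=lambda r: (-(r["loo_auc"] if np.isfinite(r["loo_auc"]) else -np.inf),
                                len(r["subset"]), r["subset"]))
    return results


def gaussian_group_fit(scores, labels) -> dict:
    """Per-group maximum-likelihood normal fits plus their Bhattacharyya
    overlap coefficient (1 = identical groups, -> 0 for full separation)."""
    s = np.asarray(scores, dtype=float).ravel()
    y = _check_binary(labels)
    out = {}
    params = []
    for g in np.unique(y):
        grp = s[y == g]
        if len(grp) < 2:
            raise ValueError("need >= 2 subjects per group")
        mu, sd = float(grp.mean()), float(grp.std(ddof=0))
        if sd == 0:
            raise ValueError("zero within-group variance")
        out[int(g)] = {"mean": mu, "sd": sd, "n": len(grp)}
        params.append((mu, sd))
    (m0, s0), (m1, s1) = params
    db = 0.25 * (m0 - m1) ** 2 / (s0**2 + s1**2) + 0.5 * np.log(
        (s0**2 + s1**2) / (2 * s0 * s1)
    )
    out["overlap"] = float(np.exp(-db))
    return out


# ---------------------------------------------------------------------------
# Node-wise Hotelling tests


def _kabsch(P: np.ndarray, Q: np.ndarray):
    """Rigid (rotation + translation, det +1) transform of P onto Q."""
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return R, cq - R @ cp


def rigid_align_meshes(position_sets: np.ndarray, n_gpa_iter: int = 3) -> np.ndarray:
    """Generalised Procrustes alignment, rigid only (no scaling).

    ``position_sets`` is (n_subjects, V, 3); every subject is aligned to
    the running mean shape, iterated ``n_gpa_iter`` times.
    """
    P = np.asarray(position_sets, dtype=float).copy()
    for _ in range(n_gpa_iter):
        ref = P.mean(axis=0)
        for i in range(len(P)):
            R, t = _kabsch(P[i], ref)
            P[i] = P[i] @ R.T + t
    return P


def hotelling_per_node(
    meshes_a,
    meshes_b,
    alpha: float = 0.01,
    bonferroni: bool = False,
    align: bool = True,
) -> NodeTestResult:
    """Two-sample Hotelling T-squared test at every mesh node.

    All meshes are first rigidly aligned together (GPA); each node's 3D
    positions are then compared between groups with the pooled-covariance
    T-squared statistic and its exact F reference.  By default no
    multiple-testing correction is applied (set ``bonferroni`` to divide
    alpha by the node count).

    ``meshes_a`` / ``meshes_b`` may be HermiteMesh sequences or
    (n, V, 3) position arrays.
    """
    def positions(group):
        arrs = [m.positions if hasattr(m, "positions") else np.asarray(m, dtype=float)
                for m in group]
        return np.stack(arrs)

    A = positions(meshes_a)
    B = positions(meshes_b)
    n1, n2 = len(A), len(B)
    if n1 < 4 or n2 < 4:
        raise ValueError("need >= 4 subjects per group")
    if A.shape[1:] != B.shape[1:]:
        raise ValueError("groups must share mesh topology")
    allp = np.concatenate([A, B])
    if align:
        allp = rigid_align_meshes(allp)
    A, B = allp[:n1], allp[n1:]

    V = A.shape[1]
    p = 3
    t2 = np.zeros(V)
    for v in range(V):
        xa, xb = A[:, v, :], B[:, v, :]
        da = xa - xa.mean(axis=0)
        db = xb - xb.mean(axis=0)
        S = (da.T @ da + db.T @ db) / (n1 + n2 - 2)
        diff = xa.mean(axis=0) - xb.mean(axis=0)
        S = S + np.eye(p) * 1e-12 * max(np.trace(S), 1e-30)
        t2[v] = (n1 * n2) / (n1 + n2) * diff @ np.linalg.solve(S, diff)
    dof2 = n1 + n2 - p - 1
    f_stat = t2 * dof2 / ((n1 + n2 - 2) * p)
    pvals = stats.f.sf(f_stat, p, dof2)
    thresh = alpha / V if bonferroni else alpha
    return NodeTestResult(t2, pvals, pvals < thresh, alpha)
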