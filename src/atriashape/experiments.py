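"""Self-contained validation experiments.

Each function re-runs one slice of the pipeline from scratch against an
analytic value, an independent oracle, or planted synthetic truth, and
returns plain numbers.  They back both the acceptance test suite and
``scripts/acceptance.py``; problem sizes are chosen so the full set runs
in minutes on one CPU (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np

from .classify import hotelling_per_node, loo_cv, marker_combination_search, roc_auc
from .fitting import SegmentationCloud, fit_template
from .hermite import make_sphere_template, sample_surface, surface_integrals
from .markers import compute_marker_table, sphericity, vertical_asymmetry
from .statistics import build_pca, fisher_lda, mode_marker_correlation
from .synthetic import CohortConfig, _deform_template, _subject_map, generate_cohort

__all__ = [
    "sphere_geometry",
    "c1_edge_gap",
    "fit_recovery",
    "pca_counting",
    "fisher_oracle_excess",
    "auc_hand_example",
    "va_slice_oracle_error",
    "mode1_volume_correlation",
    "marker_search_win_rate",
    "loo_vs_bayes",
    "hotelling_null_rate",
]


def sphere_geometry() -> dict:
    """Template counts plus volume/area/sphericity/VA against analytic values."""
    mesh = make_sphere_template(20.0)
    ints = surface_integrals(mesh)
    v_true = 4 / 3 * np.pi * 20**3
    a_true = 4 * np.pi * 20**2
    pts, *_ = sample_surface(mesh, 8)
    ell = mesh.copy()
    S = np.diag([1.6, 0.95, 1.3])  # mirror-symmetric non-sphere
    for attr in ("positions", "deriv_u", "deriv_v", "deriv_uv"):
        setattr(ell, attr, getattr(ell, attr) @ S.T)
    return {
        "node_count": mesh.n_nodes,
        "face_count": mesh.n_faces,
        "shape_vector_length": mesh.n_nodes * 12,
        "volume_error_pct": 100 * abs(ints["volume"] - v_true) / v_true,
        "area_error_pct": 100 * abs(ints["area"] - a_true) / a_true,
        "sphere_sphericity_pct": sphericity(pts),
        "mirror_symmetric_va_mm": vertical_asymmetry(ell),
    }


def c1_edge_gap() -> float:
    """Max position gap (mm) across all shared patch edges of the template."""
    from .hermite import _eval_many

    mesh = make_sphere_template(20.0)
    faces = mesh.topology.faces
    corner_uv = np.array([(0, 0), (1, 0), (0, 1), (1, 1)], dtype=float)
    edge_faces: dict = {}
    for f in range(len(faces)):
        for k1, k2 in ((0, 1), (1, 3), (3, 2), (2, 0)):
            a, b = faces[f, k1], faces[f, k2]
            if a != b:
                edge_faces.setdefault(frozenset((a, b)), []).append((f, k1, k2))
    t = np.linspace(0, 1, 10)
    worst = 0.0
    for users in edge_faces.values():
        traces = []
        for f, k1, k2 in users:
            uv = corner_uv[k1][None] * (1 - t)[:, None] + corner_uv[k2][None] * t[:, None]
            if faces[f, k1] > faces[f, k2]:
                uv = uv[::-1]
            traces.append(_eval_many(mesh, np.full(len(t), f), uv[:, 0], uv[:, 1]))
        worst = max(worst, float(np.abs(traces[0] - traces[1]).max()))
    return worst


def fit_recovery(seed: int) -> dict:
    """Template-fit accuracy on synthetic truth: clean and 1 mm noise."""
    rng = np.random.default_rng(seed)
    template = make_sphere_template(20.0)
    latent = dict(radius_lr=30.0, radius_ap=20.0, radius_fh=30.0,
                  prominence=4.0, prominence_width=0.55, gamma=0.9)
    truth = _deform_template(template, _subject_map(latent))
    pts, *_ = sample_surface(truth, 7)
    base = pts[rng.integers(0, len(pts), 4000)]

    _, clean_rep = fit_template(SegmentationCloud(base), template, max_iter=30)
    noisy_cloud = SegmentationCloud(base + rng.normal(0, 1.0, base.shape))
    fitted, noisy_rep = fit_template(noisy_cloud, template, max_iter=30)
    v_true = surface_integrals(truth)["volume"]
    v_fit = surface_integrals(fitted)["volume"]
    node_err = float(np.linalg.norm(fitted.positions - truth.positions, axis=1).mean())
    return {
        "self_fit_mean_error_mm": clean_rep.mean_error,
        "noisy_fit_mean_error_mm": noisy_rep.mean_error,
        "noisy_fit_node_error_mm": node_err,
        "volume_recovery_error_pct": 100 * abs(v_fit - v_true) / v_true,
    }


def pca_counting(seed: int) -> dict:
    """Mode counts: 144 generic subjects and the oLDA/marker subset counts."""
    from itertools import combinations

    rng = np.random.default_rng(seed)
    pca = build_pca(rng.normal(size=(144, 1608)))
    n_olda = sum(
        1 for size in range(2, 9) for _ in combinations(range(8), size)
    )
    n_markers = 2**6 - 1
    return {
        "pca_modes_144_subjects": pca.n_modes,
        "olda_subsets_8_modes": n_olda,
        "marker_subsets_6_markers": n_markers,
    }


def fisher_oracle_excess(seed: int) -> float:
    """Best Fisher-ratio excess of 10k random directions over the LDA solution
    (non-positive means the closed form wins, as it must)."""
    rng = np.random.default_rng(seed)
    n, d = 50, 3
    X = rng.normal(size=(n, d))
    y = (np.arange(n) % 2).astype(int)
    X[y == 1, 1] += 1.5
    w, _ = fisher_lda(X, y)

    def ratio(v):
        s = X @ v
        s0, s1 = s[y == 0], s[y == 1]
        w0 = s0.var(ddof=1) * (len(s0) - 1) + s1.var(ddof=1) * (len(s1) - 1)
        return (s1.mean() - s0.mean()) ** 2 / w0

    dirs = rng.normal(size=(10_000, d))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return float(max(ratio(v) for v in dirs) - ratio(w))


def auc_hand_example() -> float:
    """AUC of scores (1,3,2,4) vs labels (0,0,1,1): 3 of 4 pairs concordant."""
    return roc_auc([1, 3, 2, 4], [0, 0, 1, 1]).auc


def va_slice_oracle_error() -> float:
    """Relative error (%) of mesh VA against the closed-form slice oracle
    for an analytic egg (ellipsoid with superior AP scaling)."""
    from scipy.integrate import quad

    a_lr, a_ap, a_fh, gamma = 28.0, 20.0, 30.0, 1.2
    template = make_sphere_template(20.0)
    latent = dict(radius_lr=a_lr, radius_ap=a_ap, radius_fh=a_fh,
                  prominence=0.0, prominence_width=0.55, gamma=gamma)
    egg = _deform_template(template, _subject_map(latent))

    def g(z):
        return 1 + (gamma - 1) / (1 + np.exp(-4 * z / a_fh))

    def ap_extent(z):
        return 2 * a_ap * np.sqrt(max(0.0, 1 - (z / a_fh) ** 2)) * g(z)

    def area(z):
        return (1 - (z / a_fh) ** 2) * g(z)

    z0 = quad(lambda z: z * area(z), -a_fh, a_fh)[0] / quad(area, -a_fh, a_fh)[0]
    H = min(a_fh - z0, z0 + a_fh)
    n = 50
    oracle = sum(
        ap_extent(z0 + (j - 0.5) * H / n) - ap_extent(z0 - (j - 0.5) * H / n)
        for j in range(1, n + 1)
    )
    value = vertical_asymmetry(egg, n_slice_pairs=n, n_per_edge=14)
    return 100 * abs(value - oracle) / abs(oracle)


def mode1_volume_correlation(seed: int, n_subjects: int = 60) -> float:
    """|Pearson rho| between PCA mode-1 scores and volume on a synthetic cohort."""
    from .statistics import meshes_to_vectors

    cohort = generate_cohort(
        CohortConfig(n_subjects=n_subjects, seed=seed), with_clouds=False
    )
    pca = build_pca(meshes_to_vectors(cohort.meshes))
    vols = [surface_integrals(m)["volume"] for m in cohort.meshes]
    return float(abs(mode_marker_correlation(pca, vols)[0]))


def marker_search_win_rate(seed: int, n_replicates: int = 10,
                           n_subjects: int = 144) -> dict:
    """Planted-marker recovery of the exhaustive LDA subset search.

    Labels depend on sphericity and vertical asymmetry only; distractors
    are volume (label-independent by construction) and one explicit
    noise marker.  Reports how often the LOO-AUC winner is exactly the
    planted pair, and how often it at least contains it.
    """
    truth = {"sphericity_pct", "vertical_asymmetry_mm"}
    exact = contains = 0
    for rep in range(n_replicates):
        cfg = CohortConfig(n_subjects=n_subjects, seed=seed + rep)
        cohort = generate_cohort(cfg, with_clouds=False)
        table = compute_marker_table(cohort.meshes)
        rng = np.random.default_rng(seed + 5000 + rep)
        table["noise_marker"] = rng.normal(size=len(table))
        y = cohort.labels["recurrence_12m"].to_numpy()
        results = marker_combination_search(
            table, y,
            marker_columns=["volume_mm3", "noise_marker",
                            "sphericity_pct", "vertical_asymmetry_mm"],
        )
        best = set(results[0]["subset"])
        exact += best == truth
        contains += truth <= best
    return {
        "exact_win_rate": exact / n_replicates,
        "containment_rate": contains / n_replicates,
        "n_replicates": n_replicates,
        "n_subjects": n_subjects,
    }


def loo_vs_bayes(seed: int, n_subjects: int = 500) -> dict:
    """LOO AUC of the measured sphericity+VA LDA vs the cohort Bayes AUC."""
    cohort = generate_cohort(
        CohortConfig(n_subjects=n_subjects, seed=seed), with_clouds=False
    )
    table = compute_marker_table(cohort.meshes)
    X = table[["sphericity_pct", "vertical_asymmetry_mm"]].to_numpy()
    X = (X - X.mean(0)) / X.std(0)
    y = cohort.labels["recurrence_12m"].to_numpy()
    loo = loo_cv(X, y).loo_auc
    return {
        "loo_auc": loo,
        "bayes_auc": cohort.bayes_auc_12m,
        "gap": abs(loo - cohort.bayes_auc_12m),
        "n_subjects": n_subjects,
    }


def hotelling_null_rate(seed: int, n_replicates: int = 200,
                        n_nodes: int = 40, group_size: int = 10) -> float:
    """Per-node type-I rate of the Hotelling test under the null at alpha=0.01."""
    rng = np.random.default_rng(seed)
    hits = total = 0
    for _ in range(n_replicates):
        base = rng.normal(size=(n_nodes, 3)) * 20
        A = base + rng.normal(0, 1.0, (group_size, n_nodes, 3))
        B = base + rng.normal(0, 1.0, (group_size, n_nodes, 3))
        res = hotelling_per_node(A, B, alpha=0.01, align=False)
        hits += int(res.significant.sum())
        total += n_nodes
    return hits / total
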