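"""Covariate-constrained manifold learning (CCML).

An ISOMAP-style embedding for high-dimension, low-sample-size network data
in which the first coordinate of the low-dimensional space is clamped to
``alpha * covariate`` (here the hub-disruption slope kappa) while the
remaining coordinates are free.  The embedding minimizes the raw stress

    sum_{i<j} (d_geo(i, j) - ||y_i - y_j||)^2

over the free coordinates and the scalar ``alpha``, where ``d_geo`` are
geodesic (k-nearest-neighbour shortest-path) distances between the
per-record feature vectors.  Group separation in the embedded space is
assessed with a label-permutation test on the Euclidean distance between
group centroids, plus two leave-one-out stability diagnostics.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.sparse.csgraph import connected_components, shortest_path
from sklearn.base import BaseEstimator
from sklearn.neighbors import kneighbors_graph

from .permutation import PermutationResult, _finalize

__all__ = [
    "geodesic_distances",
    "CCML",
    "centroid_distance_test",
    "loo_centroid_stability",
    "check_feature_matrix",
]


def geodesic_distances(features: np.ndarray, k: int = 6) -> tuple[np.ndarray, int]:
    """Shortest-path distances over the Euclidean k-nearest-neighbour graph.

    If the kNN graph is disconnected, k is escalated (with a warning) until
    it connects; at ``k = n_records - 1`` the graph is complete and geodesic
    distances equal Euclidean ones.  Returns (distance matrix, k used).
    """
    x = np.asarray(features, dtype=float)
    n = x.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    k = min(k, n - 1)
    while True:
        g = kneighbors_graph(x, n_neighbors=k, mode="distance")
        g = g.maximum(g.T)  # symmetrize
        n_comp, _ = connected_components(g, directed=False)
        if n_comp == 1:
            break
        if k >= n - 1:
            raise RuntimeError("complete neighbour graph is disconnected (duplicate points?)")
        warnings.warn(
            f"kNN graph disconnected at k={k}; escalating to k={k + 1}", stacklevel=2
        )
        k += 1
    d = shortest_path(g, method="D", directed=False)
    return d, k


def _stress_and_grad(
    params: np.ndarray, covariate: np.ndarray, d_geo: np.ndarray, n: int, dim: int
) -> tuple[float, np.ndarray]:
    alpha = params[0]
    free = params[1:].reshape(n, dim - 1)
    y = np.column_stack([alpha * covariate, free])
    diff = y[:, None, :] - y[None, :, :]
    r = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(r, 1.0)  # avoid 0/0; diagonal residual is 0 anyway
    resid = r - d_geo
    np.fill_diagonal(resid, 0.0)
    stress = 0.5 * float((resid**2).sum())  # each pair counted twice -> x0.5
    w = resid / r
    np.fill_diagonal(w, 0.0)
    # dstress/dy_i = 2 * sum_j w_ij (y_i - y_j)  (the pair i<j appears twice)
    grad_y = 2.0 * (w.sum(axis=1)[:, None] * y - w @ y)
    g_alpha = float(grad_y[:, 0] @ covariate)
    grad = np.concatenate([[g_alpha], grad_y[:, 1:].ravel()])
    return stress, grad


def stress_of(coords: np.ndarray, d_geo: np.ndarray) -> float:
    """Raw stress of a configuration against a target distance matrix."""
    diff = coords[:, None, :] - coords[None, :, :]
    r = np.sqrt((diff**2).sum(axis=-1))
    iu = np.triu_indices(len(coords), k=1)
    return float(((r - d_geo)[iu] ** 2).sum())


def _classical_mds(d: np.ndarray, dim: int) -> np.ndarray:
    n = len(d)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:dim]
    w = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(w)


def check_feature_matrix(features: np.ndarray, allow_degenerate: bool = False) -> np.ndarray:
    """Refuse feature matrices with constant-zero columns unless overridden.

    Nodal clustering coefficients often contain structural zeros; columns
    that are zero for every record carry no geometry and distort geodesic
    scaling, so they are rejected by default.
    """
    x = np.asarray(features, dtype=float)
    degenerate = np.all(x == 0, axis=0)
    if degenerate.any() and not allow_degenerate:
        raise ValueError(
            f"{int(degenerate.sum())} feature column(s) are constant zero "
            "(e.g. nodal clustering with structural zeros); pass "
            "allow_degenerate=True to override"
        )
    return x


class CCML(BaseEstimator):
    """Covariate-constrained ISOMAP-style embedding.

    Parameters
    ----------
    n_components : int
        Embedding dimension (>= 2); coordinate 0 is the constrained one.
    n_neighbors : int
        k for the geodesic kNN graph (escalated automatically if the graph
        is disconnected).
    random_state : int
        Seed recorded for provenance (the optimizer itself is deterministic
        given the initialization).
    allow_degenerate_features : bool
        Permit constant-zero feature columns (see ``check_feature_matrix``).

    Attributes
    ----------
    embedding_ : (n_records, n_components) coordinates; column 0 equals
        ``alpha_ * covariate`` exactly.
    alpha_ : fitted covariate scale (NaN when the covariate is degenerate
        and the fit falls back to an unconstrained embedding).
    stress_ : final raw stress value.
    stress_normalized_ : stress divided by ``sum d_geo**2`` over pairs.
    dist_geo_ : geodesic distance matrix used.
    n_neighbors_ : k actually used after any escalation.
    """

    def __init__(
        self,
        n_components: int = 2,
        n_neighbors: int = 6,
        random_state: int = 0,
        allow_degenerate_features: bool = False,
        maxiter: int = 500,
    ):
        self.n_components = n_components
        self.n_neighbors = n_neighbors
        self.random_state = random_state
        self.allow_degenerate_features = allow_degenerate_features
        self.maxiter = maxiter

    def fit(self, X, covariate):
        x = check_feature_matrix(X, self.allow_degenerate_features)
        kappa = np.asarray(covariate, dtype=float)
        n = x.shape[0]
        if n < 4:
            raise ValueError("need at least 4 records")
        if self.n_components < 2:
            raise ValueError("n_components must be >= 2")
        if not np.all(np.isfinite(kappa)):
            raise ValueError("covariate must be finite")

        d_geo, k_used = geodesic_distances(x, self.n_neighbors)
        dim = self.n_components
        init = _classical_mds(d_geo, dim)

        if np.ptp(kappa) == 0:
            warnings.warn(
                "covariate is constant; alpha unidentifiable - falling back to "
                "an unconstrained ISOMAP embedding", stacklevel=2
            )
            self.embedding_ = init
            self.alpha_ = float("nan")
            self.stress_ = stress_of(init, d_geo)
        else:
            # alpha init: least-squares projection of coordinate 0 on kappa
            alpha0 = float(kappa @ init[:, 0] / (kappa @ kappa))
            if alpha0 == 0.0:
                alpha0 = 1.0
            params0 = np.concatenate([[alpha0], init[:, 1:].ravel()])
            self._trace = []
            res = minimize(
                _stress_and_grad,
                params0,
                args=(kappa, d_geo, n, dim),
                jac=True,
                method="L-BFGS-B",
                callback=lambda p: self._trace.append(
                    _stress_and_grad(p, kappa, d_geo, n, dim)[0]
                ),
                options={"maxiter": self.maxiter},
            )
            alpha = float(res.x[0])
            free = res.x[1:].reshape(n, dim - 1)
            self.embedding_ = np.column_stack([alpha * kappa, free])
            self.alpha_ = alpha
            self.stress_ = stress_of(self.embedding_, d_geo)

        iu = np.triu_indices(n, k=1)
        denom = float((d_geo[iu] ** 2).sum())
        self.stress_normalized_ = self.stress_ / denom if denom > 0 else 0.0
        self.dist_geo_ = d_geo
        self.n_neighbors_ = k_used
        self.covariate_ = kappa
        return self

    def fit_transform(self, X, covariate):
        return self.fit(X, covariate).embedding_


def centroid_distance_test(
    embedding: np.ndarray,
    labels,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Label-permutation test of the distance between two group centroids.

    The p-value is the upper-tail probability that a random relabelling
    yields a centroid distance at least as large as the observed one
    (add-one convention).
    """
    y = np.asarray(embedding, dtype=float)
    lab = np.asarray(labels)
    groups = np.unique(lab)
    if len(groups) != 2:
        raise ValueError("centroid test requires exactly 2 label groups")
    if min((lab == g).sum() for g in groups) < 2:
        raise ValueError("each group needs at least 2 records")

    def dist(mask: np.ndarray) -> float:
        return float(np.linalg.norm(y[mask].mean(axis=0) - y[~mask].mean(axis=0)))

    mask = lab == groups[0]
    observed = dist(mask)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = dist(rng.permutation(mask))
    res = _finalize("centroid_distance", null, observed, seed, center=False)
    # distance statistic: one-sided upper-tail p is the meaningful one
    res.p_two_tailed = float((1 + int(np.sum(null >= observed))) / (1 + n_perm))
    return res


def loo_centroid_stability(
    features: np.ndarray,
    covariate,
    labels,
    mode: str = "fixed_embedding",
    ccml_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Leave-one-out centroid-distance diagnostics.

    'fixed_embedding' refits nothing: each record is dropped from a single
    full-sample embedding and the centroid distance recomputed.  'refit'
    re-estimates the CCML embedding without the held-out record each time
    (slower, probes structural stability of the manifold itself).
    """
    x = np.asarray(features, dtype=float)
    kappa = np.asarray(covariate, dtype=float)
    lab = np.asarray(labels)
    groups = np.unique(lab)
    if len(groups) != 2:
        raise ValueError("need exactly 2 label groups")
    if min((lab == g).sum() for g in groups) < 5:
        raise ValueError("need at least 5 records per group")
    kw = ccml_kwargs or {}

    def dist(y: np.ndarray, labs: np.ndarray) -> float:
        m = labs == groups[0]
        return float(np.linalg.norm(y[m].mean(axis=0) - y[~m].mean(axis=0)))

    n = len(x)
    rows = []
    if mode == "fixed_embedding":
        emb = CCML(**kw).fit(x, kappa).embedding_
        for i in range(n):
            keep = np.arange(n) != i
            rows.append((i, dist(emb[keep], lab[keep])))
    elif mode == "refit":
        for i in range(n):
            keep = np.arange(n) != i
            emb = CCML(**kw).fit(x[keep], kappa[keep]).embedding_
            rows.append((i, dist(emb, lab[keep])))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(rows, columns=["left_out", "centroid_distance"]).set_index("left_out")
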