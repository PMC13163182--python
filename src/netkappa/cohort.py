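"""Synthetic multi-subject, multi-condition cohort with implanted hub disruption.

Emulates a longitudinal resting-state design: 28 subjects scanned under
three conditions (rested wakefulness RW as reference, total sleep
deprivation TSD, chronic sleep restriction CSR), 89 regions, 8-minute scans
at TR = 1.25 s (384 volumes).  Cross-regional covariance has a
core-periphery hub structure, and each non-reference condition applies a
degree-sequence disruption with a controllable target slope kappa, so the
hub-disruption analysis downstream can be validated by parameter recovery.

Two output routes exist: full regional time series (AR(1)-filtered
multivariate Gaussian with the target covariance) or, directly, per-scan
graphs/degree sequences, which is the fast path used for permutation
calibration studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .graphs import build_graph

__all__ = [
    "ParameterizationError",
    "CohortSpec",
    "RegionalTimeSeriesSet",
    "generate_cohort",
    "generate_graph_cohort",
    "implant_disruption",
]


class ParameterizationError(ValueError):
    """Raised when a cohort specification cannot yield a valid covariance."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort; defaults mirror the study design."""

    n_subjects: int = 28
    conditions: tuple[str, ...] = ("RW", "TSD", "CSR")
    n_regions: int = 89
    n_volumes: int = 384  # 8 min at TR = 1.25 s
    tr_seconds: float = 1.25
    hub_fraction: float = 0.15
    # within-hub / hub-periphery / periphery-periphery correlation levels
    base_connectivity: tuple[float, float, float] = (0.83, 0.34, 0.14)
    kappa_targets: dict = field(default_factory=lambda: {"RW": 0.0, "TSD": -0.5, "CSR": -0.3})
    temporal_ar: float = 0.3
    noise_sd: float = 0.0
    subject_jitter_sd: float = 0.02
    edge_budget: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_regions < 5:
            raise ValueError("n_regions must be >= 5")
        if not 0 <= self.temporal_ar < 1:
            raise ValueError("temporal_ar must be in [0, 1)")
        if any(not 0 <= c < 1 for c in self.base_connectivity):
            raise ValueError("connectivity levels must be in [0, 1)")
        n = self.n_regions
        if not n - 1 <= self.edge_budget <= n * (n - 1) // 2:
            raise ValueError(
                f"edge_budget {self.edge_budget} infeasible for {n} regions"
            )
        ref = self.conditions[0]
        targets = dict(self.kappa_targets)
        targets.setdefault(ref, 0.0)
        if targets[ref] != 0.0:
            raise ValueError(f"reference condition {ref!r} must have kappa_target = 0")
        for c in self.conditions:
            targets.setdefault(c, 0.0)
        object.__setattr__(self, "kappa_targets", targets)
        # base block-correlation matrix must be positive definite
        if np.linalg.eigvalsh(self._base_correlation()).min() <= 1e-10:
            raise ParameterizationError(
                f"connectivity levels {self.base_connectivity} do not yield a "
                "positive-definite correlation matrix"
            )

    @property
    def n_hubs(self) -> int:
        return max(1, int(round(self.hub_fraction * self.n_regions)))

    @property
    def region_ids(self) -> list[str]:
        return [f"R{i:03d}" for i in range(self.n_regions)]

    def _base_correlation(self) -> np.ndarray:
        a, b, c = self.base_connectivity
        n, h = self.n_regions, self.n_hubs
        r = np.full((n, n), c)
        r[:h, :h] = a
        r[:h, h:] = b
        r[h:, :h] = b
        np.fill_diagonal(r, 1.0)
        return r


@dataclass
class RegionalTimeSeriesSet:
    """Regional mean time series for one subject in one condition."""

    subject_id: str
    condition: str
    values: np.ndarray  # regions x volumes
    region_ids: list[str]
    tr_seconds: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.isnan(v).any():
            raise ValueError("time series contain missing values")
        if v.shape[0] != len(self.region_ids):
            raise ValueError("row count must equal the number of regions")
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("region_ids must be unique")
        self.values = v


def _nearest_correlation(r: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and renormalize the diagonal to 1."""
    w, v = np.linalg.eigh((r + r.T) / 2.0)
    w = np.clip(w, 1e-6, None)
    r = (v * w) @ v.T
    d = np.sqrt(np.diag(r))
    r = r / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return r


def _subject_correlation(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Subject-specific core-periphery correlation matrix.

    Built from per-node connection strengths ``u_i`` (rank-one structure
    ``r_ij ~ u_i u_j``): hubs draw narrowly around sqrt(within-hub level),
    periphery broadly around sqrt(periphery level), which gives each subject
    a heterogeneous, reproducible degree profile - the regime in which a
    hub-disruption slope is informative.  The hub-periphery block is
    rescaled to the requested cross level, and symmetric jitter adds further
    subject idiosyncrasy.
    """
    a, b, c = spec.base_connectivity
    n, h = spec.n_regions, spec.n_hubs
    uh, up = np.sqrt(a), np.sqrt(c)
    u = np.concatenate(
        [
            rng.uniform(uh * 0.94, min(uh * 1.06, 0.995), size=h),
            rng.uniform(up * 0.45, up * 1.55, size=n - h),
        ]
    )
    r = np.outer(u, u)
    if uh * up > 0:
        cross = b / (uh * up)
        r[:h, h:] *= cross
        r[h:, :h] *= cross
    if spec.subject_jitter_sd > 0:
        j = rng.normal(0.0, spec.subject_jitter_sd, size=(n, n))
        r = r + (j + j.T) / 2.0
    r = np.clip(r, -0.95, 0.95)
    np.fill_diagonal(r, 1.0)
    return _nearest_correlation(r)


def _balance_to_sum(d: np.ndarray, target_sum: int, n: int, frac: np.ndarray) -> np.ndarray:
    """Round real degrees to integers in [1, n-1] summing to target_sum."""
    d = np.clip(np.floor(d).astype(int), 1, n - 1)
    deficit = target_sum - int(d.sum())
    order = np.argsort(-frac, kind="stable")  # largest remainder first
    i = 0
    step = 1 if deficit > 0 else -1
    guard = 0
    while deficit != 0:
        k = order[i % n]
        nd = d[k] + step
        if 1 <= nd <= n - 1:
            d[k] = nd
            deficit -= step
        i += 1
        guard += 1
        if guard > 50 * n * abs(step):
            raise ParameterizationError("cannot balance degree sequence to edge budget")
    return d


def _make_graphical(d: np.ndarray, n: int) -> np.ndarray:
    """Redistribute degree (sum-preserving) until the sequence is graphical."""
    d = d.copy()
    for _ in range(10 * n):
        if nx.is_graphical(list(map(int, d))):
            return d
        hi, lo = int(np.argmax(d)), int(np.argmin(d))
        if d[hi] - d[lo] < 2:
            break
        d[hi] -= 1
        d[lo] += 1
    raise ParameterizationError("degree sequence is not graphical and cannot be repaired")


def _ensure_connected(g: nx.Graph, rng: np.random.Generator) -> nx.Graph:
    """Degree-preserving repair of a disconnected realization.

    Swaps one edge from the largest component with one from another
    component ((u,v),(x,y) -> (u,x),(v,y)); across components the new edges
    cannot already exist, so each swap merges two components.
    """
    while not nx.is_connected(g):
        comps = sorted(nx.connected_components(g), key=len, reverse=True)
        edges_a = sorted(g.subgraph(comps[0]).edges)
        edges_b = sorted(g.subgraph(comps[1]).edges)
        u, v = edges_a[int(rng.integers(len(edges_a)))]
        x, y = edges_b[int(rng.integers(len(edges_b)))]
        g.remove_edges_from([(u, v), (x, y)])
        g.add_edges_from([(u, x), (v, y)])
    return g


def implant_disruption(
    reference_degrees,
    kappa_target: float,
    total_edges: int,
    seed: int | np.random.Generator = 0,
    n_rewire: int | None = None,
) -> tuple[np.ndarray, nx.Graph]:
    """Build a degree sequence (and a realized graph) disrupted by ``kappa_target``.

    Inverts the HDI regression: target degrees are
    ``d'_i = round(d_i + kappa*d_i + c)`` with the offset ``c`` chosen so the
    total edge count is preserved (``sum d' = 2*total_edges``), values
    clipped to [1, N-1] and rebalanced.  The sequence is realized by a
    Havel-Hakimi construction followed by seeded double-edge-swap rewiring,
    so regressing (d' - d) on d recovers the slope up to rounding.
    """
    d = np.asarray(reference_degrees, dtype=float)
    labels = list(getattr(reference_degrees, "index", range(len(d))))
    n = len(d)
    if not -1.5 <= kappa_target <= 0.5:
        raise ValueError("kappa_target must lie in [-1.5, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    raw = (1.0 + kappa_target) * d
    c = (2 * total_edges - raw.sum()) / n
    raw = raw + c
    dp = _balance_to_sum(raw, 2 * total_edges, n, raw - np.floor(raw))
    dp = _make_graphical(dp, n)

    # havel_hakimi_graph assigns node i exactly degree dp[i]
    g = nx.Graph(nx.havel_hakimi_graph(list(map(int, dp))))
    if n_rewire is None:
        n_rewire = 2 * total_edges
    if g.number_of_edges() > 1 and n_rewire > 0:
        try:
            nx.double_edge_swap(g, nswap=n_rewire, max_tries=20 * n_rewire, seed=int(rng.integers(2**31)))
        except nx.NetworkXAlgorithmError:
            pass  # fewer swaps than requested; realized degrees are unaffected
    g = _ensure_connected(g, rng)
    g = nx.relabel_nodes(g, dict(enumerate(labels)))
    out = np.array([g.degree[labels[i]] for i in range(n)], dtype=int)
    if isinstance(reference_degrees, pd.Series):
        return pd.Series(out, index=reference_degrees.index), g
    return out, g


def _reference_degrees(spec: CohortSpec, r: np.ndarray) -> pd.Series:
    bg = build_graph(_as_cm(r, spec.region_ids), spec.edge_budget)
    return pd.Series(
        [bg.graph.degree[rid] for rid in spec.region_ids],
        index=pd.Index(spec.region_ids, name="node_id"),
        dtype=float,
    )


class _PlainMatrix:
    def __init__(self, values, region_ids):
        self.values = values
        self.region_ids = region_ids


def _as_cm(values: np.ndarray, region_ids: list[str]) -> _PlainMatrix:
    return _PlainMatrix(values, region_ids)


def _graph_based_correlation(
    adjacency: np.ndarray,
    strengths: np.ndarray,
    r_on: float = 0.45,
    off_lo: float = 0.03,
    off_hi: float = 0.20,
) -> np.ndarray:
    """Correlation matrix whose fixed-budget graph equals a given adjacency.

    On-edge correlations get a flat boost ``r_on`` on top of a smooth
    off-edge gradient ``off_lo + (off_hi-off_lo)*s_i*s_j`` driven by
    normalized node strengths, so the noiseless top-|E| graph reproduces the
    adjacency exactly while near-threshold behaviour under estimation noise
    stays smooth and node strengths carry the subject's signature.  The
    result is projected to the nearest valid correlation matrix.
    """
    s = strengths - strengths.min()
    s = s / max(np.ptp(strengths), 1e-9)
    r = off_lo + (off_hi - off_lo) * np.outer(s, s) + r_on * adjacency
    np.fill_diagonal(r, 1.0)
    return _nearest_correlation(r)


def _simulate_series(
    r: np.ndarray, spec: CohortSpec, rng: np.random.Generator
) -> np.ndarray:
    """AR(1)-filtered multivariate Gaussian with stationary covariance r."""
    n, t = spec.n_regions, spec.n_volumes
    chol = np.linalg.cholesky(r + 1e-9 * np.eye(n))
    eps = rng.standard_normal((t, n)) @ chol.T
    phi = spec.temporal_ar
    x = np.empty((t, n))
    x[0] = eps[0]
    scale = np.sqrt(1.0 - phi**2)
    for k in range(1, t):
        x[k] = phi * x[k - 1] + scale * eps[k]
    out = x.T
    if spec.noise_sd > 0:
        out = out + spec.noise_sd * rng.standard_normal(out.shape)
    return out


def _subject_streams(spec: CohortSpec) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(spec.seed).spawn(spec.n_subjects)


def generate_cohort(spec: CohortSpec) -> list[RegionalTimeSeriesSet]:
    """Generate ``n_subjects * len(conditions)`` regional time-series sets.

    Each subject gets a jittered core-periphery correlation matrix; each
    non-reference condition disrupts the subject's reference degree sequence
    toward its ``kappa_target`` and propagates the change to the generating
    covariance.  All randomness flows from ``spec.seed`` through per-subject
    derived streams, so the output is bitwise reproducible.
    """
    import networkx as nx_mod

    out: list[RegionalTimeSeriesSet] = []
    for s, ss in enumerate(_subject_streams(spec)):
        streams = ss.spawn(2 * len(spec.conditions) + 1)
        rng_struct = np.random.default_rng(streams[0])
        r_raw = _subject_correlation(spec, rng_struct)
        d_ref = _reference_degrees(spec, r_raw)
        a_ref = nx_mod.to_numpy_array(
            build_graph(_as_cm(r_raw, spec.region_ids), spec.edge_budget).graph,
            nodelist=spec.region_ids,
        )
        u = np.sqrt(np.abs(r_raw).sum(axis=1))
        r_ref = _graph_based_correlation(a_ref, u)
        subject_id = f"sub-{s + 1:02d}"
        for c_idx, cond in enumerate(spec.conditions):
            kappa = spec.kappa_targets[cond]
            if kappa == 0.0:
                r_cond = r_ref
            else:
                d_target, g_cond = implant_disruption(
                    d_ref, kappa, spec.edge_budget,
                    seed=np.random.default_rng(streams[2 * c_idx + 1]),
                )
                a_cond = nx_mod.to_numpy_array(g_cond, nodelist=spec.region_ids)
                lam = np.sqrt((np.asarray(d_target, float) + 1.0) / (d_ref.values + 1.0))
                r_cond = _graph_based_correlation(a_cond, u * lam)
            rng_cond = np.random.default_rng(streams[2 * c_idx + 2])
            values = _simulate_series(r_cond, spec, rng_cond)
            out.append(
                RegionalTimeSeriesSet(
                    subject_id=subject_id,
                    condition=cond,
                    values=values,
                    region_ids=spec.region_ids,
                    tr_seconds=spec.tr_seconds,
                )
            )
    return out


def generate_graph_cohort(
    spec: CohortSpec,
    condition_noise_sd: float = 1.5,
    realize: bool = True,
) -> dict[tuple[str, str], pd.Series | nx.Graph]:
    """Generate per-scan degree sequences (or realized graphs) directly.

    Fast path bypassing time-series simulation: each subject's reference
    degree profile comes from the graph of their generating correlation; per
    condition the profile is disrupted toward ``kappa_target`` and jittered
    by a sum-preserving degree noise (``condition_noise_sd`` edges per node,
    emulating finite-scan estimation noise; applied to every condition
    including the reference, so conditions with equal targets remain
    exchangeable).  With ``realize=True`` values are realized graphs whose
    degrees equal the jittered targets; otherwise degree Series.
    """
    out: dict[tuple[str, str], pd.Series | nx.Graph] = {}
    n, e = spec.n_regions, spec.edge_budget
    for s, ss in enumerate(_subject_streams(spec)):
        streams = ss.spawn(len(spec.conditions) + 1)
        rng_struct = np.random.default_rng(streams[0])
        r_ref = _subject_correlation(spec, rng_struct)
        d_ref = _reference_degrees(spec, r_ref)
        subject_id = f"sub-{s + 1:02d}"
        for c_idx, cond in enumerate(spec.conditions):
            rng = np.random.default_rng(streams[c_idx + 1])
            kappa = spec.kappa_targets[cond]
            raw = (1.0 + kappa) * d_ref.values
            raw = raw + (2 * e - raw.sum()) / n
            if condition_noise_sd > 0:
                noise = rng.normal(0.0, condition_noise_sd, size=n)
                raw = raw + noise - noise.mean()  # sum-preserving jitter
            dp = _balance_to_sum(raw, 2 * e, n, raw - np.floor(raw))
            dp = _make_graphical(dp, n)
            degrees = pd.Series(dp.astype(float), index=d_ref.index)
            if realize:
                g = nx.relabel_nodes(
                    nx.Graph(nx.havel_hakimi_graph(list(map(int, dp)))),
                    dict(enumerate(spec.region_ids)),
                )
                try:
                    nx.double_edge_swap(g, nswap=2 * e, max_tries=40 * e, seed=int(rng.integers(2**31)))
                except nx.NetworkXAlgorithmError:
                    pass
                out[(subject_id, cond)] = _ensure_connected(g, rng)
            else:
                out[(subject_id, cond)] = degrees
    return out
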