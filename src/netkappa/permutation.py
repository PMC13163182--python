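"""Permutation validation of the within-subject hub-disruption analysis.

Three cohort-level tests probe what the within-subject HDI actually
measures:

1. node-label shuffling in the deprived condition (is the extra sensitivity
   of the within-subject index due to preserved anatomical correspondence?);
2. breaking the subject pairing (does comparing graphs from different brains
   inflate apparent disruption?);
3. within-subject condition-label swaps (could the observed kappa arise from
   arbitrary condition assignment?).

Generic paired (sign-flip) and unpaired (full-shuffle) mean-difference
permutation tests for global and nodal metrics are also provided.  All
p-values use the add-one convention and are therefore never zero; two-tailed
p-values are centered on the null mean by default, since some of these nulls
are not centered at zero by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hdi import kappa_slopes

__all__ = [
    "PermutationResult",
    "test_node_shuffle",
    "test_pair_break",
    "test_condition_shuffle",
    "paired_permutation_compare",
    "unpaired_permutation_compare",
]


@dataclass
class PermutationResult:
    """Observed statistic against a permutation null distribution."""

    test: str
    n_permutations: int
    null_distribution: np.ndarray
    observed: float
    p_two_tailed: float
    cohens_d: float
    seed: int

    def summary(self) -> dict:
        return {
            "test": self.test,
            "n_permutations": self.n_permutations,
            "observed": self.observed,
            "null_mean": float(np.mean(self.null_distribution)),
            "null_sd": float(np.std(self.null_distribution, ddof=1)),
            "p_two_tailed": self.p_two_tailed,
            "cohens_d": self.cohens_d,
            "seed": self.seed,
        }


def _finalize(
    test: str,
    null: np.ndarray,
    observed: float,
    seed: int,
    center: bool = True,
) -> PermutationResult:
    null = np.asarray(null, dtype=float)
    n_perm = len(null)
    mu = float(null.mean()) if center else 0.0
    exceed = int(np.sum(np.abs(null - mu) >= np.abs(observed - mu)))
    p = (1 + exceed) / (1 + n_perm)
    sd = float(null.std(ddof=1))
    d = (observed - float(null.mean())) / sd if sd > 0 else 0.0
    return PermutationResult(
        test=test,
        n_permutations=n_perm,
        null_distribution=null,
        observed=float(observed),
        p_two_tailed=float(p),
        cohens_d=float(d),
        seed=seed,
    )


def _check_n_perm(n_perm: int) -> None:
    if n_perm < 100:
        warnings.warn(f"n_perm = {n_perm} < 100: p-values will be unstable", stacklevel=3)


def _degree_matrix(graphs: dict, condition: str) -> tuple[list[str], np.ndarray, list]:
    """Stack per-subject degree vectors of one condition into (S, N)."""
    subjects = sorted({s for s, c in graphs if c == condition})
    rows, node_ids = [], None
    for s in subjects:
        g = graphs[(s, condition)]
        if isinstance(g, pd.Series):
            vals = g
        else:
            import networkx as nx

            graph = g if isinstance(g, nx.Graph) else g.graph
            nodes = getattr(g, "node_ids", sorted(graph.nodes))
            vals = pd.Series([graph.degree[n] for n in nodes], index=nodes, dtype=float)
        if node_ids is None:
            node_ids = list(vals.index)
        rows.append(vals.reindex(node_ids).values)
    return subjects, np.asarray(rows, dtype=float), node_ids


def test_node_shuffle(
    graphs: dict,
    reference: str,
    deprived: str,
    n_perm: int = 10_000,
    seed: int = 0,
    fit_intercept: bool = True,
) -> PermutationResult:
    """First validation test: node-label shuffling in the deprived scans.

    For each permutation the deprived-condition node labels are shuffled per
    subject (reference labels and subject pairing kept), and both the
    within-subject and the group-reference HDI are computed.  The statistic
    is ``mean(kappa_within - kappa_group)``; negative values mean stronger
    apparent disruption when each subject's own baseline is the reference.
    """
    _check_n_perm(n_perm)
    rng = np.random.default_rng(seed)
    subjects, ref, _ = _degree_matrix(graphs, reference)
    subjects_d, dep, _ = _degree_matrix(graphs, deprived)
    if subjects != subjects_d:
        raise ValueError("subject sets differ between conditions")
    s, n = ref.shape
    group_ref = np.broadcast_to(ref.mean(axis=0), (s, n))

    def statistic(dep_mat: np.ndarray) -> float:
        kw = kappa_slopes(ref, dep_mat, fit_intercept)
        kg = kappa_slopes(group_ref, dep_mat, fit_intercept)
        return float(np.mean(kw - kg))

    observed = statistic(dep)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = np.array([rng.permutation(n) for _ in range(s)])
        null[b] = statistic(np.take_along_axis(dep, perm, axis=1))
    return _finalize("node_shuffle", null, observed, seed)


def test_pair_break(
    graphs: dict,
    reference: str,
    deprived: str,
    n_perm: int = 10_000,
    seed: int = 0,
    fit_intercept: bool = True,
) -> PermutationResult:
    """Second validation test: break the subject pairing.

    Each deprived scan is paired with a uniformly chosen subject's reference
    scan (self-pairings allowed with probability 1/n); the statistic is the
    mean within-subject kappa under the broken pairing, compared with the
    observed correctly-paired mean.
    """
    _check_n_perm(n_perm)
    rng = np.random.default_rng(seed)
    subjects, ref, _ = _degree_matrix(graphs, reference)
    subjects_d, dep, _ = _degree_matrix(graphs, deprived)
    if subjects != subjects_d:
        raise ValueError("subject sets differ between conditions")
    s = len(subjects)
    if s < 3:
        raise ValueError("need at least 3 subjects to break pairing meaningfully")
    observed = float(np.mean(kappa_slopes(ref, dep, fit_intercept)))
    null = np.empty(n_perm)
    for b in range(n_perm):
        order = rng.permutation(s)
        null[b] = float(np.mean(kappa_slopes(ref[order], dep, fit_intercept)))
    return _finalize("pair_break", null, observed, seed)


def test_condition_shuffle(
    nodal_values: dict,
    condition: str,
    reference: str,
    n_perm: int = 10_000,
    seed: int = 0,
    fit_intercept: bool = True,
) -> PermutationResult:
    """Third validation test: within-subject condition-label swaps.

    ``nodal_values`` maps (subject_id, condition) to a per-node metric
    Series.  Swapping the two labels of a subject exchanges the roles of the
    regressor and the change, so the null is built from the 2^S possible
    per-subject orientation choices (sampled).  The statistic is the mean
    within-subject kappa.
    """
    _check_n_perm(n_perm)
    rng = np.random.default_rng(seed)
    subjects, ref, _ = _degree_matrix(nodal_values, reference)
    subjects_c, dep, _ = _degree_matrix(nodal_values, condition)
    if subjects != subjects_c:
        raise ValueError("incomplete within-subject condition data")
    s = len(subjects)
    k_fwd = kappa_slopes(ref, dep, fit_intercept)  # condition vs reference
    k_rev = kappa_slopes(dep, ref, fit_intercept)  # labels swapped
    observed = float(np.mean(k_fwd))
    flips = rng.integers(0, 2, size=(n_perm, s)).astype(bool)
    null = np.where(flips, k_rev, k_fwd).mean(axis=1)
    return _finalize("condition_shuffle", null, observed, seed)


def paired_permutation_compare(
    values_a,
    values_b,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Sign-flip permutation test of the mean paired difference b - a."""
    _check_n_perm(n_perm)
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    diff = b - a
    observed = float(diff.mean())
    if np.all(diff == 0):
        null = np.zeros(n_perm)
        res = _finalize("paired_compare", null, observed, seed)
        res.p_two_tailed = 1.0
        return res
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, len(diff))) * 2 - 1
    null = (signs * diff).mean(axis=1)
    return _finalize("paired_compare", null, observed, seed)


def unpaired_permutation_compare(
    values_a,
    values_b,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Full-shuffle permutation test of the mean difference b - a."""
    _check_n_perm(n_perm)
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    pooled = np.concatenate([a, b])
    na = len(a)
    observed = float(b.mean() - a.mean())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(pooled)
        null[k] = perm[na:].mean() - perm[:na].mean()
    return _finalize("unpaired_compare", null, observed, seed)
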