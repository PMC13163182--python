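"""Multiple-comparison control and tidy result aggregation.

FDR control uses the Benjamini-Hochberg linear step-up procedure, applied
within-family: q = 0.05 for global-metric families and q = 0.1 for nodal
families by default, matching the asymmetric error budget conventional for
few global versus many nodal tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_fdr", "cohens_d_null", "aggregate_results", "Q_GLOBAL", "Q_NODAL"]

Q_GLOBAL = 0.05
Q_NODAL = 0.1


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection flags).

    Rejections are all hypotheses ranked at or below the largest k with
    ``p_(k) <= k * q / m``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def cohens_d_null(observed: float, null_distribution) -> float:
    """Effect size of an observed statistic against a permutation null:
    ``(observed - mean(null)) / sd(null)``."""
    null = np.asarray(null_distribution, dtype=float)
    sd = null.std(ddof=1)
    if sd == 0:
        raise ValueError("null distribution has zero spread; d undefined")
    return float((observed - null.mean()) / sd)


def aggregate_results(
    families: dict[str, pd.DataFrame],
    q_by_family: dict[str, float] | None = None,
    manifest: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Apply within-family BH-FDR and stack results into one tidy table.

    ``families`` maps a family name (e.g. 'global', 'nodal_degree', 'hdi',
    'ccml') to a DataFrame with at least columns ``unit``, ``comparison``,
    ``statistic``, ``p_raw``.  Returns the stacked table (family, unit,
    comparison, statistic, p_raw, p_adjusted, significant_at_q) plus a run
    report recording the q used per family and any provenance passed in
    ``manifest`` (seeds, thresholds, atlas, edge budgets).
    """
    q_by_family = q_by_family or {}
    out = []
    report: dict = {"families": {}, **(manifest or {})}
    for family, table in families.items():
        if table.empty:
            report["families"][family] = {"q": None, "n_tests": 0, "n_significant": 0}
            continue
        t = table.copy()
        required = {"unit", "comparison", "statistic", "p_raw"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"family {family!r} missing columns {sorted(missing)}")
        if t.duplicated(["unit", "comparison"]).any():
            raise ValueError(f"family {family!r} has duplicate (unit, comparison) keys")
        q = q_by_family.get(family, Q_NODAL if family.startswith("nodal") else Q_GLOBAL)
        p_adj, reject = bh_fdr(t["p_raw"].values, q)
        t["p_adjusted"] = p_adj
        t["significant_at_q"] = reject
        t.insert(0, "family", family)
        out.append(t)
        report["families"][family] = {
            "q": q,
            "n_tests": len(t),
            "n_significant": int(reject.sum()),
        }
    table = (
        pd.concat(out, ignore_index=True)
        if out
        else pd.DataFrame(
            columns=[
                "family", "unit", "comparison", "statistic",
                "p_raw", "p_adjusted", "significant_at_q",
            ]
        )
    )
    return table, report
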