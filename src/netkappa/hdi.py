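"""Within-subject Hub Disruption Index (HDI, kappa).

For a nodal metric m over N regions, two conditions of the same subject are
compared by regressing the per-node change on the reference value:

    m_i(cond) - m_i(ref) = kappa * m_i(ref) + epsilon_i

The slope kappa is the HDI.  kappa ~ 0 means preserved topology; kappa < 0
means regions that were hubs in the reference lost centrality while
peripheral regions gained it.  The within-subject variant uses each
subject's own baseline scan as the reference; the group-level variant (used
by the first permutation test) regresses against the group-mean reference
profile instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["KappaFit", "kappa_within", "kappa_group", "hdi_table", "kappa_slopes"]

log = logging.getLogger(__name__)

DEFAULT_COMPARISONS = (("TSD", "RW"), ("CSR", "RW"), ("CSR", "TSD"))


@dataclass
class KappaFit:
    """One fitted HDI regression."""

    kappa: float
    intercept: float
    residuals: np.ndarray
    r_squared: float
    n_nodes: int
    subject_id: str | None = None
    comparison: tuple[str, str] | None = None
    metric: str | None = None
    mode: str = "within_subject"

    def scatter_data(self, m_ref: pd.Series, m_cond: pd.Series) -> pd.DataFrame:
        """Per-node (reference value, change) pairs for HDI scatter plots."""
        ref, cond = _align(m_ref, m_cond)
        return pd.DataFrame(
            {"m_ref": ref.values, "delta": cond.values - ref.values},
            index=ref.index,
        )


def _align(m_ref, m_cond) -> tuple[pd.Series, pd.Series]:
    ref = pd.Series(m_ref, dtype=float)
    cond = pd.Series(m_cond, dtype=float)
    if not ref.index.equals(cond.index):
        if set(ref.index) != set(cond.index):
            raise ValueError("node identities of reference and condition do not match")
        cond = cond.reindex(ref.index)
    if len(ref) < 3:
        raise ValueError("need at least 3 nodes for an HDI regression")
    return ref, cond


def _fit(ref: np.ndarray, delta: np.ndarray, fit_intercept: bool) -> tuple[float, float, np.ndarray, float]:
    if fit_intercept:
        x = np.column_stack([ref, np.ones_like(ref)])
    else:
        x = ref[:, None]
    if np.ptp(ref) == 0:
        raise ValueError("reference metric has zero variance; HDI slope undefined")
    coef, *_ = np.linalg.lstsq(x, delta, rcond=None)
    kappa = float(coef[0])
    intercept = float(coef[1]) if fit_intercept else 0.0
    fitted = x @ coef
    resid = delta - fitted
    ss_tot = float(np.sum((delta - delta.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return kappa, intercept, resid, r2


def kappa_within(
    m_ref,
    m_cond,
    fit_intercept: bool = True,
    subject_id: str | None = None,
    comparison: tuple[str, str] | None = None,
    metric: str | None = None,
) -> KappaFit:
    """OLS slope of (m_cond - m_ref) on m_ref, aligned by node id.

    Inputs are pandas Series indexed by node_id (plain arrays are accepted
    and matched positionally via a default RangeIndex).  With
    ``fit_intercept=False`` the regression is forced through the origin,
    matching the index's defining equation literally.
    """
    ref, cond = _align(m_ref, m_cond)
    kappa, intercept, resid, r2 = _fit(
        ref.values, cond.values - ref.values, fit_intercept
    )
    return KappaFit(
        kappa=kappa,
        intercept=intercept,
        residuals=resid,
        r_squared=r2,
        n_nodes=len(ref),
        subject_id=subject_id,
        comparison=comparison,
        metric=metric,
        mode="within_subject",
    )


def kappa_group(
    m_cond,
    group_ref_mean,
    fit_intercept: bool = True,
    subject_id: str | None = None,
    comparison: tuple[str, str] | None = None,
    metric: str | None = None,
) -> KappaFit:
    """Group-level HDI: the regressor is the group-mean reference profile."""
    fit = kappa_within(
        group_ref_mean,
        m_cond,
        fit_intercept=fit_intercept,
        subject_id=subject_id,
        comparison=comparison,
        metric=metric,
    )
    fit.mode = "group_level"
    return fit


def kappa_slopes(ref: np.ndarray, cond: np.ndarray, fit_intercept: bool = True) -> np.ndarray:
    """Vectorized HDI slopes, one per row of (S, N) arrays.

    Used by the permutation tests, where thousands of slope fits are needed.
    With an intercept the slope is cov(delta, ref) / var(ref) per row.
    """
    ref = np.asarray(ref, dtype=float)
    cond = np.asarray(cond, dtype=float)
    delta = cond - ref
    if fit_intercept:
        rc = ref - ref.mean(axis=-1, keepdims=True)
        dc = delta - delta.mean(axis=-1, keepdims=True)
        return (rc * dc).sum(axis=-1) / (rc * rc).sum(axis=-1)
    return (ref * delta).sum(axis=-1) / (ref * ref).sum(axis=-1)


def hdi_table(
    nodal_metrics: pd.DataFrame,
    comparisons: tuple[tuple[str, str], ...] = DEFAULT_COMPARISONS,
    metrics: tuple[str, ...] | None = None,
    fit_intercept: bool = True,
) -> pd.DataFrame:
    """Complete kappa table across subjects, comparisons and metrics.

    ``nodal_metrics`` is the tidy table produced by
    :func:`netkappa.metrics.nodal_metric_table` (columns subject_id,
    condition, node_id, metric, value).  Subjects missing a condition of a
    comparison are excluded from that comparison with a logged warning.
    Returns a DataFrame with one row per (subject, comparison, metric).
    """
    if metrics is None:
        metrics = tuple(sorted(nodal_metrics["metric"].unique()))
    rows = []
    for metric in metrics:
        sub = nodal_metrics[nodal_metrics["metric"] == metric]
        pivot = sub.pivot_table(
            index=["subject_id", "node_id"], columns="condition", values="value"
        )
        for cond, ref in comparisons:
            if cond not in pivot.columns or ref not in pivot.columns:
                log.warning("comparison (%s vs %s): condition missing entirely", cond, ref)
                continue
            for subject_id, block in pivot.groupby(level="subject_id"):
                block = block.droplevel("subject_id")
                if block[[cond, ref]].isna().any().any():
                    log.warning(
                        "subject %s excluded from (%s vs %s): incomplete data",
                        subject_id, cond, ref,
                    )
                    continue
                fit = kappa_within(
                    block[ref], block[cond],
                    fit_intercept=fit_intercept,
                    subject_id=str(subject_id),
                    comparison=(cond, ref),
                    metric=metric,
                )
                rows.append(
                    {
                        "subject_id": str(subject_id),
                        "comparison": f"{cond}_vs_{ref}",
                        "metric": metric,
                        "kappa": fit.kappa,
                        "intercept": fit.intercept,
                        "r_squared": fit.r_squared,
                    }
                )
    table = pd.DataFrame(rows)
    if not table.empty:
        dup = table.duplicated(["subject_id", "comparison", "metric"])
        if dup.any():
            raise ValueError("duplicate (subject, comparison, metric) fits")
    return table
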