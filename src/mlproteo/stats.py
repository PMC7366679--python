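"""Shared statistical primitives for the differential layers.

All three quantitative layers (interaction, cross-link, phospho/total
proteome) use the same core: a pooled-variance two-sided t-test per analyte,
Benjamini-Hochberg adjustment within each mutant-vs-reference contrast, and
regulation calls against fold-change / adjusted-p thresholds. Fisher's exact
test (two-sided, minimum-likelihood definition) backs the enrichment
analyses.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import ValidationError

logger = logging.getLogger("mlproteo.stats")

__all__ = [
    "student_t_two_sided",
    "bh_adjust",
    "fisher_two_sided",
    "differential_long",
]


def student_t_two_sided(group_a: Sequence[float], group_b: Sequence[float],
                        ) -> tuple[float, float]:
    """Two-tailed unpaired Student's t-test with pooled (equal) variance.

    Degenerate convention: if the pooled variance is exactly zero the test
    is decided by the means alone — equal means give ``(0.0, 1.0)``,
    unequal means give ``(+/-inf, 0.0)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("non-finite values in t-test input")
    na, nb = a.size, b.size
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    diff = a.mean() - b.mean()
    if pooled == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        return float(np.sign(diff)) * float("inf"), 0.0
    t = diff / np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    p = 2.0 * sps.t.sf(abs(t), df=na + nb - 2)
    return float(t), float(min(p, 1.0))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj p_(i) = min_{j >= i} ( p_(j) * n / j ), capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def fisher_two_sided(table: Sequence[Sequence[int]], rel_tol: float = 1e-7) -> float:
    """Two-sided Fisher's exact p for a 2x2 table of counts.

    The p-value sums hypergeometric probabilities of every table with the
    observed margins whose probability does not exceed the observed table's
    (within relative tolerance ``rel_tol`` for floating-point ties). A table
    with any zero margin is degenerate and returns 1.0.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValidationError("table must be 2x2 non-negative integers")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 1.0
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, c1, r1)
    p_obs = sps.hypergeom.pmf(a, n, c1, r1)
    p = float(pmf[pmf <= p_obs * (1.0 + rel_tol)].sum())
    return min(p, 1.0)


def differential_long(records: pd.DataFrame, reference: str,
                      fc_thresh: float = 1.0, adj_p_thresh: float = 0.05,
                      ) -> pd.DataFrame:
    """Per-analyte differential testing of each condition against a reference.

    ``records`` is a long quant table (``analyte_id``, ``condition``,
    ``replicate``, ``intensity``) with strictly positive intensities; the
    test operates on log2 intensities. For each non-reference condition,
    analytes with at least two finite observations on both sides are tested
    (pooled-variance two-sided t), p-values are BH-adjusted within that
    contrast, and a regulation call of ``up``/``down``/``none`` is made at
    ``|log2FC| > fc_thresh`` and ``adj p <= adj_p_thresh``. Analytes
    quantified on only one side of a contrast are excluded and logged.
    """
    if reference not in set(records["condition"]):
        raise ValidationError(f"reference condition {reference!r} not in table")
    obs = records.dropna(subset=["intensity"]).copy()
    if (obs["intensity"] <= 0).any():
        raise ValidationError("intensities must be > 0 for log2 testing")
    obs["log2_intensity"] = np.log2(obs["intensity"].astype(float))
    ref_groups = {
        aid: g["log2_intensity"].to_numpy()
        for aid, g in obs[obs["condition"] == reference].groupby("analyte_id")
    }
    rows = []
    for cond in sorted(set(obs["condition"]) - {reference}):
        sub = obs[obs["condition"] == cond]
        contrast = []
        n_skipped = 0
        for aid, g in sub.groupby("analyte_id"):
            mut = g["log2_intensity"].to_numpy()
            ref = ref_groups.get(aid)
            if ref is None or len(ref) < 2 or len(mut) < 2:
                n_skipped += 1
                continue
            log2fc = float(mut.mean() - ref.mean())
            _, p = student_t_two_sided(mut, ref)
            contrast.append((aid, log2fc, p))
        if n_skipped:
            logger.info("contrast %s vs %s: %d analyte(s) excluded "
                        "(insufficient observations)", cond, reference, n_skipped)
        if not contrast:
            continue
        ids, fcs, ps = zip(*contrast)
        adj = bh_adjust(ps)
        for aid, fc, p, ap in zip(ids, fcs, ps, adj):
            if abs(fc) > fc_thresh and ap <= adj_p_thresh:
                call = "up" if fc > 0 else "down"
            else:
                call = "none"
            rows.append((aid, cond, fc, p, float(ap), call))
    return pd.DataFrame(
        rows,
        columns=["analyte_id", "condition", "log2fc", "pvalue", "adj_pvalue",
                 "regulated"],
    )
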