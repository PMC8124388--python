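"""Per-sample activity inference: ssGSEA, signed-regulon (aREA-style) TF
activity, and ssGSEA-based immune-infiltration scores.

ssGSEA scores a gene set in one sample as the integrated difference between
the rank-weighted in-set ECDF and the unweighted out-of-set ECDF, walking
the genes in descending expression order; weights are |rank|^alpha
(default alpha 0.25, the convention of the method family).  Scores depend
on ranks only, so any strictly monotone transform of a sample's expression
leaves them unchanged.

Regulon activity maps each gene's within-sample rank to a standard-normal
quantile and averages the signed quantiles of the regulon's targets scaled
by sqrt(m); under random ranks the score is asymptotically N(0,1), so it is
reported directly as a normalized enrichment score (NES).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger("luadstrat")


@dataclass
class ActivityMatrix:
    scores: pd.DataFrame  # signatures x samples
    method: str  # ssgsea | area | immune
    skipped: list[str]  # signatures with no matched genes / below size floor


def _ssgsea_sample(values: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """ES for one sample: integrated ECDF difference down the ranked list.

    ``values`` are the sample's expression values over all genes present;
    ``in_set`` is a boolean mask of set membership.
    """
    n = values.size
    m = int(in_set.sum())
    order = np.argsort(-values, kind="stable")
    ranks = stats.rankdata(values)  # ascending, average ties; top gene -> n
    w = np.abs(ranks) ** alpha
    in_ordered = in_set[order]
    w_ordered = np.where(in_ordered, w[order], 0.0)
    denom_in = w_ordered.sum()
    p_in = np.cumsum(w_ordered) / denom_in if denom_in > 0 else np.zeros(n)
    n_out = n - m
    if n_out > 0:
        p_out = np.cumsum(~in_ordered) / n_out
    else:
        p_out = np.zeros(n)  # empty complement contributes 0
    return float(np.sum(p_in - p_out))


def ssgsea(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> ActivityMatrix:
    """Single-sample GSEA enrichment scores, signatures x samples.

    Sets with no genes in the matrix are skipped (recorded); missing
    expression values are dropped per sample before ranking.  With
    ``normalize`` the whole score matrix is rescaled by its range
    (max ES - min ES).
    """
    genes = pd.Index(expr.gene_ids)
    masks: dict[str, np.ndarray] = {}
    skipped: list[str] = []
    for name, members in sets:
        mask = genes.isin(list(members))
        if mask.sum() == 0:
            skipped.append(name)
            logger.warning("gene set %r has no genes in the matrix; skipped", name)
        else:
            masks[name] = mask
    vals = expr.values
    out = np.empty((len(masks), vals.shape[1]))
    for j in range(vals.shape[1]):
        col = vals[:, j]
        present = ~np.isnan(col)
        col_p = col[present]
        for i, (name, mask) in enumerate(masks.items()):
            mask_p = mask[present]
            if mask_p.sum() == 0:
                out[i, j] = 0.0
            else:
                out[i, j] = _ssgsea_sample(col_p, mask_p, alpha)
    if normalize and out.size:
        rng_ = out.max() - out.min()
        if rng_ > 0:
            out = out / rng_
    scores = pd.DataFrame(out, index=list(masks), columns=expr.sample_ids)
    return ActivityMatrix(scores=scores, method="ssgsea", skipped=skipped)


def area_activity(
    expr: ExpressionMatrix,
    regulons: GeneSetCollection,
    regulon_min: int = 5,
) -> ActivityMatrix:
    """Signed-regulon TF activity as an analytic-null NES per sample.

    For sample s with ascending average ranks r_g over the n present genes,
    t_g = Phi^{-1}(r_g / (n + 1)); regulon R of size m scores
    NES = sum_{g in R} sign_g * t_g / sqrt(m).
    """
    vals = expr.values
    genes = pd.Index(expr.gene_ids)
    n_genes, n_samples = vals.shape

    # per-sample normal quantiles of expression ranks (NaN-aware)
    t = np.full_like(vals, np.nan, dtype=float)
    for j in range(n_samples):
        col = vals[:, j]
        present = ~np.isnan(col)
        r = stats.rankdata(col[present])
        t[present, j] = stats.norm.ppf(r / (present.sum() + 1))

    rows: dict[str, np.ndarray] = {}
    skipped: list[str] = []
    for name, members in regulons:
        idx = [genes.get_loc(g) for g in members if g in genes]
        signs = np.array([members[g] for g in members if g in genes], dtype=float)
        if len(idx) < regulon_min:
            skipped.append(name)
            logger.warning("regulon %r below size floor (%d genes); skipped", name, len(idx))
            continue
        tg = t[idx, :]  # m x samples, NaN where gene missing in a sample
        ok = ~np.isnan(tg)
        contrib = np.where(ok, signs[:, None] * tg, 0.0)
        m_eff = ok.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rows[name] = contrib.sum(axis=0) / np.sqrt(np.maximum(m_eff, 1.0))
    scores = pd.DataFrame(rows, index=expr.sample_ids).T
    scores.columns = expr.sample_ids
    return ActivityMatrix(scores=scores, method="area", skipped=skipped)


def immune_score(
    expr: ExpressionMatrix,
    immune_sets: GeneSetCollection,
    alpha: float = 0.25,
) -> pd.Series:
    """Immune-infiltration score: ssGSEA over immune signatures, summed per sample."""
    act = ssgsea(expr, immune_sets, alpha=alpha, normalize=True)
    return act.scores.sum(axis=0).rename("immune_score")
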