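"""Stage 1: call dependency-essential genes and intersect with tumor DEGs.

A gene is dependency-essential when its CERES score falls strictly below a
threshold (default -1) in at least a fraction (default 75%) of the screened
cell lines.  Tumor-vs-paired-normal differential expression uses a paired
moderated t test with empirical-Bayes variance shrinkage: gene-wise
variances are shrunk toward a common prior whose scale and degrees of
freedom are estimated by method-of-moments on the log sample variances
(the scaled inverse-chi-square working model).  The essential panel is the
intersection of the dependency hits with the genes upregulated (q below and
log2FC above the thresholds) in every DEG cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_formats import DependencyMatrix, ExpressionMatrix

logger = logging.getLogger("luadstrat")


@dataclass
class DEGResult:
    """Per-gene paired differential expression statistics."""

    table: pd.DataFrame  # index gene; columns log2fc, t, p, q, n_pairs
    prior_df: float
    prior_var: float

    def passing(self, q_max: float = 0.01, log2fc_min: float = 1.0) -> list[str]:
        t = self.table
        return list(t.index[(t["q"] < q_max) & (t["log2fc"] > log2fc_min)])


@dataclass
class EssentialPanel:
    genes: list[str]
    provenance: pd.DataFrame  # index gene; columns dependency_essential, upregulated_all
    median_pairwise_r: float | None = None


def call_essential(
    dep: DependencyMatrix, score_threshold: float = -1.0, line_fraction: float = 0.75
) -> list[str]:
    """Genes with CERES < threshold in >= line_fraction of non-missing lines.

    Output sorted by ascending median score (most essential first).  Genes
    with no non-missing scores are excluded with a warning.
    """
    if not 0.0 < line_fraction <= 1.0:
        raise ValueError("line_fraction must lie in (0, 1]")
    vals = dep.data.to_numpy(dtype=float)
    present = ~np.isnan(vals)
    n_present = present.sum(axis=1)
    empty = n_present == 0
    if empty.any():
        logger.warning(
            "excluding %d genes with all-missing dependency scores", int(empty.sum())
        )
    below = np.where(present, vals < score_threshold, False).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_present > 0, below / np.maximum(n_present, 1), 0.0)
    hit = (frac >= line_fraction) & ~empty
    import warnings

    with warnings.catch_warnings():
        # all-missing genes produce an expected all-NaN median; already handled
        warnings.simplefilter("ignore", RuntimeWarning)
        medians = np.nanmedian(np.where(present, vals, np.nan), axis=1)
    genes = np.asarray(dep.gene_ids)[hit]
    order = np.argsort(medians[hit], kind="stable")
    return list(genes[order])


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in [0,1])."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _fit_inverse_chisq_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (prior_df d0, prior_var s0^2) on log variances.

    Under the scaled inverse-chi-square working model,
    E[log s^2] = log s0^2 + digamma(d/2) - log(d/2) - (digamma(d0/2) - log(d0/2))
    and Var[log s^2] = trigamma(d/2) + trigamma(d0/2); the second moment is
    inverted for d0 (Newton on trigamma), the first gives s0^2.
    """
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    n = z.size
    if n < 2:
        return np.inf, float(np.exp(np.mean(e))) if n else 1.0
    evar = np.var(z, ddof=1) - special.polygamma(1, df / 2)
    if evar <= 0:
        # variances more concentrated than chi-square sampling alone: infinite
        # prior df, all genes share one variance (geometric mean, so identical
        # sample variances shrink to themselves exactly)
        return np.inf, float(np.exp(np.mean(z)))
    # solve trigamma(d0/2) = evar for d0/2 by Newton (limma-style inversion)
    x = 0.5 + 1.0 / evar
    for _ in range(50):
        tri = special.polygamma(1, x)
        diff = (tri * (1 - tri / evar)) / special.polygamma(2, x)
        x += diff
        if abs(diff) < 1e-10 * x:
            break
    d0 = 2 * x
    s0_sq = float(np.exp(np.mean(e) + special.digamma(x) - np.log(x)))
    return float(d0), s0_sq


def paired_moderated_ttest(
    tumor: ExpressionMatrix,
    normal: ExpressionMatrix,
    pairs: list[tuple[str, str]],
) -> DEGResult:
    """Paired moderated t test on tumor - normal differences per gene.

    ``pairs`` is a bijection between tumor and normal sample ids.  The mean
    paired difference is the log2 fold change; gene variances are shrunk
    toward the method-of-moments prior and the moderated t is referred to a
    t distribution with augmented degrees of freedom.
    """
    t_ids = [a for a, _ in pairs]
    n_ids = [b for _, b in pairs]
    if len(set(t_ids)) != len(t_ids) or len(set(n_ids)) != len(n_ids):
        raise ValueError("pairing must be a bijection (duplicate sample in pairs)")
    missing_t = [s for s in t_ids if s not in tumor.data.columns]
    missing_n = [s for s in n_ids if s not in normal.data.columns]
    if missing_t or missing_n:
        raise ValueError(f"pairing references absent samples: {missing_t + missing_n}")

    genes = [g for g in tumor.gene_ids if g in set(normal.gene_ids)]
    diffs = tumor.data.loc[genes, t_ids].to_numpy() - normal.data.loc[genes, n_ids].to_numpy()
    n_used = (~np.isnan(diffs)).sum(axis=1)
    if (n_used < 2).any():
        bad = [g for g, m in zip(genes, n_used < 2) if m]
        raise ValueError(f"genes with <2 complete pairs: {bad[:10]}")

    mean_d = np.nanmean(diffs, axis=1)
    s2 = np.nanvar(diffs, axis=1, ddof=1)
    df = n_used - 1

    if np.allclose(s2, 0.0):
        logger.warning("all paired differences constant; falling back to ordinary t")
        d0, s0_sq = 0.0, 0.0
        s2_post = s2
        df_total = df.astype(float)
    else:
        d0, s0_sq = _fit_inverse_chisq_prior(s2, float(df[0]))
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df_total = np.full_like(s2, np.inf)
        else:
            s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
            df_total = df + d0

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = mean_d / np.sqrt(s2_post / n_used)
    tstat = np.where(np.isnan(tstat) & (mean_d == 0), 0.0, tstat)
    finite_df = np.where(np.isinf(df_total), 1e12, df_total)
    p = 2 * stats.t.sf(np.abs(tstat), finite_df)
    q = bh_adjust(p)

    table = pd.DataFrame(
        {"log2fc": mean_d, "t": tstat, "p": p, "q": q, "n_pairs": n_used},
        index=pd.Index(genes, name="gene"),
    )
    return DEGResult(table=table, prior_df=float(d0), prior_var=float(s0_sq))


def build_panel(
    essential: list[str],
    deg_results: list[DEGResult],
    q_max: float = 0.01,
    log2fc_min: float = 1.0,
) -> EssentialPanel:
    """Panel = dependency-essential genes upregulated in EVERY DEG cohort."""
    if not deg_results:
        raise ValueError("at least one DEG cohort is required")
    up_sets = [set(r.passing(q_max, log2fc_min)) for r in deg_results]
    up_all = set.intersection(*up_sets)
    panel = [g for g in essential if g in up_all]
    tested = set.union(*(set(r.table.index) for r in deg_results))
    prov = pd.DataFrame(
        {
            "dependency_essential": True,
            "upregulated_all_cohorts": [g in up_all for g in essential],
            "deg_tested": [g in tested for g in essential],
        },
        index=pd.Index(essential, name="gene"),
    )
    if not panel:
        logger.warning("essential panel is empty after intersection")
    return EssentialPanel(genes=panel, provenance=prov)


def median_pairwise_correlation(expr: ExpressionMatrix, genes: list[str]) -> float:
    """Median of all pairwise Pearson correlations among panel genes.

    Pairwise-complete on missing values; panel genes absent from the matrix
    are excluded with a warning.
    """
    present = [g for g in genes if g in expr.data.index]
    absent = [g for g in genes if g not in expr.data.index]
    if absent:
        logger.warning("panel genes absent from expression matrix: %s", absent)
    if len(present) < 2:
        raise ValueError("need >=2 panel genes present in the expression matrix")
    corr = expr.data.loc[present].T.corr(method="pearson")  # pairwise complete
    iu = np.triu_indices(len(present), k=1)
    return float(np.nanmedian(corr.to_numpy()[iu]))
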