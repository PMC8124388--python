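"""Cross-cluster association statistics.

Kruskal-Wallis with post-hoc Dunn tests screen per-sample activities for
cluster differences; Fisher exact tests measure enrichment of binary
categories (mutations, focal copy-number flags, pathology) in clusters;
logistic and ordinary-least-squares models relate clusters to stage and to
activities adjusted for stage; tumor mutation burden is the non-silent
mutation count per 38 Mb of exome; drug response compares AUC across
predicted cell-line clusters after a tested-fraction filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io_formats import DrugResponseTable, MutationTable

logger = logging.getLogger("luadstrat")


@dataclass
class GroupTestResult:
    feature: str
    h_statistic: float  # tie-corrected Kruskal-Wallis H
    p_value: float
    dunn: pd.DataFrame  # index (group_i, group_j); columns z, p, p_holm
    group_medians: dict
    group_n: dict


@dataclass
class EnrichmentResult:
    category: str
    cluster: object
    table: np.ndarray  # 2x2 [[a, b], [c, d]] = [in/out cluster] x [in/out category]
    odds_ratio: float  # sample OR (ad)/(bc); inf/0 when a zero cell
    p_value: float
    zero_cell: bool
    log_odds: float | None = None
    log_odds_p: float | None = None


@dataclass
class TmbResult:
    table: pd.DataFrame  # index sample; columns n_non_silent, tmb
    exome_mb: float


def kruskal_dunn(
    values: pd.Series, groups: pd.Series, feature: str = "", holm: bool = False
) -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis H plus all pairwise Dunn z tests.

    Dunn's z for groups i, j is the mean-rank difference over
    sqrt[(N(N+1)/12 - tie correction)(1/n_i + 1/n_j)]; two-sided normal p,
    optionally Holm-adjusted.
    """
    df = pd.DataFrame({"v": values, "g": groups}).dropna()
    levels = sorted(df["g"].unique())
    if len(levels) < 2:
        raise ValueError("need >=2 groups with observations")
    present = set(df["g"])
    missing = [g for g in sorted(set(groups.dropna())) if g not in present]
    if missing:
        raise ValueError(f"groups empty after missing-value removal: {missing}")
    arrays = [df.loc[df["g"] == g, "v"].to_numpy() for g in levels]
    if np.ptp(np.concatenate(arrays)) == 0:
        h, p = 0.0, 1.0  # scipy refuses all-identical data; H is 0 by definition
    else:
        h, p = stats.kruskal(*arrays)

    n = len(df)
    ranks = stats.rankdata(df["v"])
    df = df.assign(r=ranks)
    mean_ranks = df.groupby("g")["r"].mean()
    sizes = df.groupby("g")["r"].size()
    _, tie_counts = np.unique(df["v"], return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (n - 1)) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term

    rows = []
    for i, gi in enumerate(levels):
        for gj in levels[i + 1 :]:
            se = np.sqrt(var_base * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
            z = (mean_ranks[gi] - mean_ranks[gj]) / se if se > 0 else 0.0
            rows.append((gi, gj, z, 2 * stats.norm.sf(abs(z))))
    dunn = pd.DataFrame(rows, columns=["group_i", "group_j", "z", "p"]).set_index(
        ["group_i", "group_j"]
    )
    if holm:
        order = np.argsort(dunn["p"].to_numpy())
        m = len(dunn)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * dunn["p"].iloc[idx])
            adj[idx] = min(1.0, running)
        dunn["p_holm"] = adj
    medians = df.groupby("g")["v"].median().to_dict()
    return GroupTestResult(
        feature=feature,
        h_statistic=float(h),
        p_value=float(p),
        dunn=dunn,
        group_medians=medians,
        group_n=sizes.to_dict(),
    )


def screen_activities(
    acts, clusters: pd.Series, p_max: float = 1e-3, holm: bool = False
) -> list[GroupTestResult]:
    """Kruskal-Wallis screen of every signature; keep KW p < p_max, rank by p."""
    scores = acts.scores if hasattr(acts, "scores") else acts
    common = [s for s in scores.columns if s in clusters.index]
    results = []
    for sig in scores.index:
        res = kruskal_dunn(
            scores.loc[sig, common], clusters.loc[common], feature=sig, holm=holm
        )
        if res.p_value < p_max:
            results.append(res)
    return sorted(results, key=lambda r: r.p_value)


def fisher_enrichment(
    in_cluster: pd.Series, in_category: pd.Series, category: str = "", cluster=None
) -> EnrichmentResult:
    """Two-sided Fisher exact test of a binary category against a cluster.

    Reports the sample odds ratio (ad)/(bc); a zero cell gives inf or 0
    with a flag, the p-value is still exact.
    """
    a_idx = in_cluster.index.intersection(in_category.index)
    x = in_cluster.loc[a_idx].astype(bool)
    y = in_category.loc[a_idx].astype(bool)
    a = int((x & y).sum())
    b = int((x & ~y).sum())
    c = int((~x & y).sum())
    d = int((~x & ~y).sum())
    table = np.array([[a, b], [c, d]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    zero = min(a, b, c, d) == 0
    if b * c == 0:
        orr = np.inf if a * d > 0 else (0.0 if a * d == 0 and (b or c) else np.nan)
    else:
        orr = (a * d) / (b * c)
    return EnrichmentResult(
        category=category, cluster=cluster, table=table,
        odds_ratio=float(orr), p_value=float(p), zero_cell=zero,
    )


def mutation_enrichment(
    muts: MutationTable,
    clusters: pd.Series,
    genes: list[str] | None = None,
    p_max: float = 1e-3,
) -> pd.DataFrame:
    """Fisher enrichment of non-silent mutations per (gene, cluster)."""
    ns = muts.records[muts.records["variant_class"] == "non_silent"]
    mutated = ns.groupby("gene")["sample"].apply(set)
    genes = list(mutated.index) if genes is None else genes
    rows = []
    for gene in genes:
        carriers = mutated.get(gene, set())
        in_cat = pd.Series([s in carriers for s in clusters.index], index=clusters.index)
        for c in sorted(clusters.unique()):
            res = fisher_enrichment(clusters == c, in_cat, category=gene, cluster=c)
            rows.append((gene, c, res.odds_ratio, res.p_value, res.p_value < p_max))
    return pd.DataFrame(
        rows, columns=["gene", "cluster", "odds_ratio", "p", "significant"]
    )


def binarize_stage(stage: pd.Series) -> pd.Series:
    """High = {III, IV} vs low = {I, II}; all-low cohorts fall back to II vs I."""
    s = stage.astype(str).str.strip().str.upper()
    known = {"I", "IA", "IB", "II", "IIA", "IIB", "III", "IIIA", "IIIB", "IV", "IVA", "IVB"}
    bad = sorted(set(s) - known)
    if bad:
        raise ValueError(f"unrecognised stage labels: {bad}")
    base = s.str.extract(r"^(IV|III|II|I)")[0]
    high = base.isin(["III", "IV"])
    if not high.any():
        logger.info("no stage III/IV in cohort; binarizing II vs I instead")
        high = base == "II"
    return high.astype(int).rename("stage_high")


def logistic_stage_model(
    clusters: pd.Series, stage_binary: pd.Series, reference=3
) -> pd.DataFrame:
    """Logistic fit of binary stage on cluster indicators vs a reference cluster."""
    common = clusters.index.intersection(stage_binary.index)
    cl = clusters.loc[common]
    y = stage_binary.loc[common].astype(float)
    levels = sorted(cl.unique())
    if reference not in levels:
        raise ValueError(f"reference cluster {reference} absent from labels")
    others = [c for c in levels if c != reference]
    X = pd.DataFrame(
        {f"cluster_{c}_vs_{reference}": (cl == c).astype(float) for c in others},
        index=common,
    )
    X = sm.add_constant(X)
    # complete separation check: any contrast cell empty
    for c in levels:
        vals = y[cl == c]
        if vals.nunique() < 2 and len(vals) > 1:
            logger.warning("cluster %s has one stage level only (possible separation)", c)
    try:
        fit = sm.Logit(y, X).fit(disp=0)
    except Exception as exc:  # perfect separation raises in statsmodels
        raise RuntimeError(f"logistic fit failed (separation?): {exc}") from exc
    out = pd.DataFrame(
        {"log_odds": fit.params, "se": fit.bse, "p": fit.pvalues}
    ).drop(index="const")
    return out


def adjusted_linear_model(
    activity: pd.Series, clusters: pd.Series, stage: pd.Series, reference=3
) -> pd.DataFrame:
    """OLS of activity on cluster contrasts with binary stage as covariate."""
    common = activity.index.intersection(clusters.index).intersection(stage.index)
    y = activity.loc[common].astype(float)
    cl = clusters.loc[common]
    levels = sorted(cl.unique())
    others = [c for c in levels if c != reference]
    X = pd.DataFrame(
        {f"cluster_{c}_vs_{reference}": (cl == c).astype(float) for c in others},
        index=common,
    )
    X["stage_high"] = stage.loc[common].astype(float)
    X = sm.add_constant(X)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.to_numpy(), 0)
        collinear = corr.stack().idxmax()
        raise ValueError(f"design matrix rank deficient; near-collinear columns {collinear}")
    if y.var(ddof=0) == 0:
        out = pd.DataFrame(
            {"coef": 0.0, "se": 0.0, "p": 1.0}, index=X.columns
        ).drop(index="const")
        return out
    fit = sm.OLS(y, X).fit()
    return pd.DataFrame(
        {"coef": fit.params, "se": fit.bse, "p": fit.pvalues}
    ).drop(index="const")


def compute_tmb(
    muts: MutationTable, samples: list[str], exome_mb: float = 38.0
) -> TmbResult:
    """Tumor mutation burden: non-silent mutation count / exome_mb per sample."""
    if exome_mb <= 0:
        raise ValueError("exome_mb must be > 0")
    ns = muts.records[muts.records["variant_class"] == "non_silent"]
    counts = ns.groupby("sample").size()
    n = pd.Series(0, index=pd.Index(samples, name="sample"), dtype=int)
    common = counts.index.intersection(n.index)
    n.loc[common] = counts.loc[common].astype(int)
    table = pd.DataFrame({"n_non_silent": n, "tmb": n / exome_mb})
    return TmbResult(table=table, exome_mb=exome_mb)


def drug_response_compare(
    drugs: DrugResponseTable,
    labels: pd.Series,
    min_tested_fraction: float = 0.75,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Kruskal-Wallis comparison of drug AUC across predicted clusters.

    Compounds tested on more than ``min_tested_fraction`` of the labeled
    cell lines are analysed; the significant set is KW p < alpha.
    """
    lines = [l for l in drugs.data.columns if l in labels.index]
    sub = drugs.data[lines]
    tested_frac = sub.notna().mean(axis=1)
    kept = tested_frac[tested_frac > min_tested_fraction].index
    if len(kept) == 0:
        logger.warning("no compound passes the tested-fraction filter")
        return pd.DataFrame(
            columns=["compound", "h", "p", "significant", "tested_fraction",
                     "lowest_median_cluster"]
        )
    rows = []
    lab = labels.loc[lines]
    for comp in kept:
        res = kruskal_dunn(sub.loc[comp], lab, feature=comp)
        low_cluster = min(res.group_medians, key=res.group_medians.get)
        rows.append(
            (comp, res.h_statistic, res.p_value, res.p_value < alpha,
             float(tested_frac[comp]), low_cluster)
        )
    out = pd.DataFrame(
        rows, columns=["compound", "h", "p", "significant", "tested_fraction",
                       "lowest_median_cluster"],
    )
    return out.sort_values("p").reset_index(drop=True)
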