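"""Synthetic LUAD-like cohorts with the statistical structure the pipeline assumes.

The generator plants (a) a correlated essential-gene block driven by one
latent per-sample factor plus a three-cluster mean gradient, (b) paired
tumor/normal expression with the essential genes upregulated in tumors,
(c) cluster-dependent exponential survival, TP53 mutation frequency, tumor
mutation burden and stage, (d) a CERES-scale dependency matrix in which the
planted genes score as essential, and (e) a drug-response table with
compounds sensitised in cluster 1.  Everything is keyed to one seed and is
byte-identical across runs (numpy PCG64 generator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    ClinicalTable,
    DependencyMatrix,
    DrugResponseTable,
    ExpressionMatrix,
    MutationTable,
)

#: cluster-1 expression shift is highest: expression rises cluster 3 -> 2 -> 1
DEFAULT_CLUSTER_SHIFTS = (1.5, 0.0, -1.5)
DEFAULT_CLUSTER_PROPORTIONS = (0.25, 0.40, 0.35)


@dataclass
class SimulationConfig:
    """Knobs of the cohort generator; the defaults ARE the study conditions.

    Essential-gene expression is
    ``x_gs = baseline_g + shift_{cluster(s)} + eta_{g,cluster(s)} + loading * f_s + noise``
    where ``f_s`` is a per-sample latent factor (the shared proliferation
    program driving the gene-gene correlation block) and ``eta_{g,c}`` is a
    fixed per-gene, per-cluster effect (sd ``cluster_shift_gene_sd``) that
    gives each cluster its own expression profile direction — without it the
    block is rank one and correlation-based sample distances cannot see the
    clusters.  With the defaults (loading 1.09, gene-cluster sd 1.0, noise sd
    1.0) the planted block's expected median pairwise Pearson r is ~0.62.
    """

    n_samples: int = 500
    n_background_genes: int = 1000
    n_essential_genes: int = 36
    cluster_proportions: tuple[float, ...] = DEFAULT_CLUSTER_PROPORTIONS
    cluster_mean_shift: tuple[float, ...] = DEFAULT_CLUSTER_SHIFTS
    factor_loading: float = 1.09
    cluster_shift_gene_sd: float = 1.0
    noise_sd: float = 1.0
    hazard_ratio_c1_vs_c3: float = 1.6
    baseline_hazard: float = 0.012  # events per month in cluster 3
    censoring_rate: float = 0.5  # sets the uniform follow-up window
    follow_up_months: float = 120.0
    tp53_mut_prob: tuple[float, ...] = (0.70, 0.45, 0.20)
    tmb_mean: tuple[float, ...] = (9.0, 6.0, 3.0)  # mutations per Mb
    exome_mb: float = 38.0
    silent_fraction: float = 0.3  # extra silent records per non-silent count
    stage_logodds_c1_vs_c3: float = 1.0
    stage_base_prob: float = 0.25  # P(high stage) in cluster 3
    n_pairs: int = 50
    deg_log2fc: float = 1.5
    n_cell_lines: int = 31
    ceres_essential_mean: float = -1.5
    ceres_sd: float = 0.2
    baseline_expression_mean: float = 5.0
    baseline_expression_sd: float = 1.0
    seed: int = 0
    #: seed for gene-level truth (baselines, loadings, cluster profiles);
    #: kept separate from `seed` so cohorts drawn with different seeds share
    #: the same underlying biology and a classifier can transfer between them
    biology_seed: int = 7

    def validate(self) -> None:
        k = len(self.cluster_proportions)
        if abs(sum(self.cluster_proportions) - 1.0) > 1e-9:
            raise ValueError("cluster_proportions must sum to 1")
        if len(self.cluster_mean_shift) != k or len(self.tp53_mut_prob) != k or len(self.tmb_mean) != k:
            raise ValueError("per-cluster parameter vectors must share one length")
        if self.noise_sd <= 0 or self.ceres_sd <= 0 or self.baseline_expression_sd <= 0:
            raise ValueError("all standard deviations must be > 0")
        if self.cluster_shift_gene_sd < 0:
            raise ValueError("cluster_shift_gene_sd must be >= 0")
        for p in (*self.tp53_mut_prob, self.stage_base_prob, self.censoring_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.n_pairs > self.n_samples:
            raise ValueError("n_pairs cannot exceed n_samples")
        if self.n_samples < 2 or self.n_essential_genes < 2:
            raise ValueError("need >=2 samples and >=2 essential genes")


@dataclass
class SyntheticCohort:
    """All tables of one simulated study, keyed by consistent identifiers."""

    tumor: ExpressionMatrix
    normal: ExpressionMatrix  # paired normals, n_pairs samples
    pairs: list[tuple[str, str]]  # (tumor sample, normal sample)
    true_labels: pd.Series  # cluster in {1..k}, index = tumor sample ids
    clinical: ClinicalTable
    mutations: MutationTable
    dependency: DependencyMatrix
    drugs: DrugResponseTable
    essential_genes: list[str]
    cell_line_expression: ExpressionMatrix = None
    cell_line_labels: pd.Series = None
    config: SimulationConfig = field(default_factory=SimulationConfig)


def _expression_block(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    labels: np.ndarray,
    gene_baselines: np.ndarray,
    loadings: np.ndarray,
    gene_cluster_effects: np.ndarray,
    n_background: int,
    sample_ids: list[str],
    gene_ids: list[str],
) -> pd.DataFrame:
    """Essential genes: baseline + cluster shift (+ per-gene cluster effect)
    + loading * factor + noise; background genes pure noise around baseline."""
    n = len(labels)
    shifts = np.asarray(cfg.cluster_mean_shift)[labels - 1]  # (n,)
    factor = rng.normal(0.0, 1.0, size=n)
    n_ess = len(loadings)
    ess = (
        gene_baselines[:n_ess, None]
        + shifts[None, :]
        + gene_cluster_effects[:, labels - 1]
        + loadings[:, None] * factor[None, :]
        + rng.normal(0.0, cfg.noise_sd, size=(n_ess, n))
    )
    bg = gene_baselines[n_ess:, None] + rng.normal(0.0, cfg.noise_sd, size=(n_background, n))
    return pd.DataFrame(np.vstack([ess, bg]), index=gene_ids, columns=sample_ids)


def simulate_cohort(config: SimulationConfig | None = None) -> SyntheticCohort:
    """Draw one full synthetic cohort under ``config`` (deterministic per seed)."""
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    k = len(cfg.cluster_proportions)
    n = cfg.n_samples
    sample_ids = [f"T{i:04d}" for i in range(n)]
    ess_genes = [f"ESS{i:03d}" for i in range(cfg.n_essential_genes)]
    bg_genes = [f"BG{i:04d}" for i in range(cfg.n_background_genes)]
    gene_ids = ess_genes + bg_genes

    labels = rng.choice(np.arange(1, k + 1), size=n, p=cfg.cluster_proportions)
    rng_bio = np.random.default_rng(cfg.biology_seed)
    gene_baselines = rng_bio.normal(
        cfg.baseline_expression_mean, cfg.baseline_expression_sd, size=len(gene_ids)
    )
    loadings = np.full(cfg.n_essential_genes, cfg.factor_loading)
    gene_cluster_effects = rng_bio.normal(
        0.0, cfg.cluster_shift_gene_sd, size=(cfg.n_essential_genes, k)
    )

    tumor_df = _expression_block(
        rng, cfg, labels, gene_baselines, loadings, gene_cluster_effects,
        cfg.n_background_genes, sample_ids, gene_ids
    )
    tumor = ExpressionMatrix(tumor_df)

    # paired normals: essential genes sit deg_log2fc below their tumor value,
    # background genes are unshifted; fresh noise on every normal sample
    pair_tumors = sample_ids[: cfg.n_pairs]
    normal_ids = [f"N{i:04d}" for i in range(cfg.n_pairs)]
    shift = np.zeros((len(gene_ids), 1))
    shift[: cfg.n_essential_genes, 0] = cfg.deg_log2fc
    normal_vals = (
        tumor_df[pair_tumors].to_numpy()
        - shift
        + rng.normal(0.0, cfg.noise_sd, size=(len(gene_ids), cfg.n_pairs))
    )
    normal = ExpressionMatrix(pd.DataFrame(normal_vals, index=gene_ids, columns=normal_ids))
    pairs = list(zip(pair_tumors, normal_ids))

    clinical = _simulate_clinical(rng, cfg, labels, sample_ids)
    mutations = _simulate_mutations(rng, cfg, labels, sample_ids, bg_genes)

    # dependency screen: planted genes essential across the cell-line panel
    line_ids = [f"CL{i:02d}" for i in range(cfg.n_cell_lines)]
    dep_vals = rng.normal(0.0, cfg.ceres_sd, size=(len(gene_ids), cfg.n_cell_lines))
    dep_vals[: cfg.n_essential_genes] += cfg.ceres_essential_mean
    dependency = DependencyMatrix(pd.DataFrame(dep_vals, index=gene_ids, columns=line_ids))

    # cell-line expression (same structure, no pairing) for classifier transfer
    line_labels = rng.choice(np.arange(1, k + 1), size=cfg.n_cell_lines, p=cfg.cluster_proportions)
    line_df = _expression_block(
        rng, cfg, line_labels, gene_baselines, loadings, gene_cluster_effects,
        cfg.n_background_genes, line_ids, gene_ids
    )
    cell_line_expression = ExpressionMatrix(line_df)
    cell_line_labels = pd.Series(line_labels, index=line_ids, name="cluster")

    drugs = simulate_drug_response(
        cell_line_labels, n_compounds=20, n_sensitive=2, effect=0.3,
        seed=int(rng.integers(2**31)),
    )

    return SyntheticCohort(
        tumor=tumor,
        normal=normal,
        pairs=pairs,
        true_labels=pd.Series(labels, index=sample_ids, name="cluster"),
        clinical=clinical,
        mutations=mutations,
        dependency=dependency,
        drugs=drugs,
        essential_genes=ess_genes,
        cell_line_expression=cell_line_expression,
        cell_line_labels=cell_line_labels,
        config=cfg,
    )


def _cluster_hazard_multipliers(cfg: SimulationConfig) -> np.ndarray:
    """Geometric ladder from 1 (last cluster) to hazard_ratio_c1_vs_c3 (cluster 1)."""
    k = len(cfg.cluster_proportions)
    hr = cfg.hazard_ratio_c1_vs_c3
    exponents = np.linspace(1.0, 0.0, k)  # cluster 1 -> hr, cluster k -> 1
    return hr**exponents


def _simulate_clinical(
    rng: np.random.Generator, cfg: SimulationConfig, labels: np.ndarray, sample_ids: list[str]
) -> ClinicalTable:
    hazards = cfg.baseline_hazard * _cluster_hazard_multipliers(cfg)[labels - 1]
    event_times = rng.exponential(1.0 / hazards)
    censor_times = rng.uniform(0.0, cfg.follow_up_months, size=len(labels))
    os_time = np.minimum(event_times, censor_times)
    os_event = (event_times <= censor_times).astype(int)

    k = len(cfg.cluster_proportions)
    base_logit = np.log(cfg.stage_base_prob / (1 - cfg.stage_base_prob))
    logodds = base_logit + cfg.stage_logodds_c1_vs_c3 * np.linspace(1.0, 0.0, k)[labels - 1]
    p_high = 1.0 / (1.0 + np.exp(-logodds))
    high = rng.random(len(labels)) < p_high
    stage = np.where(high, rng.choice(["III", "IV"], size=len(labels)),
                     rng.choice(["I", "II"], size=len(labels)))

    pathology_pools = {  # cluster -> dominant pathology, mirrors the enrichment design
        1: ["micropapillary/solid", "acinar/papillary", "invasive mucinous"],
        2: ["acinar/papillary", "micropapillary/solid", "lepidic"],
        3: ["lepidic", "acinar/papillary", "invasive mucinous"],
    }
    pathology = [
        rng.choice(pathology_pools.get(int(c), ["acinar/papillary"]), p=[0.6, 0.3, 0.1])
        for c in labels
    ]

    df = pd.DataFrame(
        {
            "os_time": os_time,
            "os_event": os_event,
            "stage": stage,
            "pathology": pathology,
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    return ClinicalTable(df)


def _simulate_mutations(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    labels: np.ndarray,
    sample_ids: list[str],
    passenger_genes: list[str],
) -> MutationTable:
    rows: list[tuple[str, str, str]] = []
    tp53 = np.asarray(cfg.tp53_mut_prob)
    tmb = np.asarray(cfg.tmb_mean)
    for sid, lab in zip(sample_ids, labels):
        if rng.random() < tp53[lab - 1]:
            rows.append((sid, "TP53", "non_silent"))
        n_passenger = rng.poisson(tmb[lab - 1] * cfg.exome_mb)
        genes = rng.choice(passenger_genes, size=n_passenger)
        rows.extend((sid, g, "non_silent") for g in genes)
        n_silent = rng.poisson(cfg.silent_fraction * tmb[lab - 1] * cfg.exome_mb)
        genes = rng.choice(passenger_genes, size=n_silent)
        rows.extend((sid, g, "silent") for g in genes)
    df = pd.DataFrame(rows, columns=["sample", "gene", "variant_class"])
    return MutationTable(df)


def simulate_drug_response(
    labels: pd.Series,
    n_compounds: int = 20,
    n_sensitive: int = 2,
    effect: float = 0.3,
    missing_fraction: float = 0.1,
    seed: int = 0,
) -> DrugResponseTable:
    """Drug AUC table with ``n_sensitive`` compounds sensitised (lower AUC) in cluster 1.

    A ``missing_fraction`` of entries is blanked so the tested-fraction filter
    downstream has something to exclude.
    """
    if len(labels) == 0:
        raise ValueError("labels must be non-empty")
    if n_sensitive > n_compounds:
        raise ValueError("n_sensitive cannot exceed n_compounds")
    rng = np.random.default_rng(seed)
    lines = list(labels.index)
    auc = rng.normal(0.7, 0.08, size=(n_compounds, len(lines)))
    is_c1 = (labels.to_numpy() == 1)
    auc[:n_sensitive, is_c1] -= effect
    auc = np.clip(auc, 0.0, 1.0)
    mask = rng.random(auc.shape) < missing_fraction
    auc[mask] = np.nan
    compounds = [f"DRUG{i:03d}" for i in range(n_compounds)]
    return DrugResponseTable(pd.DataFrame(auc, index=compounds, columns=lines))
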