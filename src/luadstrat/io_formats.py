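"""Readers and writers for the tables the stratification pipeline consumes.

Expression comes in as a genes x samples matrix of log2 units (TSV or GCT
1.2), gene sets as GMT (optionally with ",+1"/",-1" sign suffixes for
regulons), mutations as a three-column MAF-lite TSV, and clinical / drug
tables as plain TSV.  Every reader validates hard: duplicate identifiers,
non-numeric cells and malformed sign tokens are errors, never silently
repaired.  Identifiers are matched case-sensitively and exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("luadstrat")

#: default collapse of MAF variant classes to the binary vocabulary
DEFAULT_MAF_COLLAPSE: dict[str, str] = {
    "Silent": "silent",
    "Intron": "silent",
    "3'UTR": "silent",
    "5'UTR": "silent",
    "IGR": "silent",
    "RNA": "silent",
}

VARIANT_CLASSES = ("non_silent", "silent")


def _check_unique(ids, what: str) -> None:
    s = pd.Index(ids)
    if s.has_duplicates:
        dupes = sorted(s[s.duplicated()].unique().tolist())
        raise ValueError(f"duplicate {what} identifiers: {dupes}")


@dataclass
class ExpressionMatrix:
    """log2 expression, genes x samples; missing values allowed (NaN)."""

    data: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        if self.data.shape[0] < 2 or self.data.shape[1] < 2:
            raise ValueError(
                f"expression matrix needs >=2 genes and >=2 samples, got {self.data.shape}"
            )
        vals = self.data.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError("expression matrix contains non-finite (inf) values")
        self.data = pd.DataFrame(vals, index=self.data.index, columns=self.data.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from expression matrix: {missing}")
        return ExpressionMatrix(self.data.loc[list(genes)])


@dataclass
class DependencyMatrix:
    """CERES dependency scores, genes x cell lines; negative = essential."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "cell line")
        if self.data.shape[1] < 1:
            raise ValueError("dependency matrix needs at least one cell line")
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class GeneSetCollection:
    """Named gene sets; members carry a sign (+1/-1), +1 unless regulon mode."""

    sets: dict[str, dict[str, int]]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            bad = {g: s for g, s in members.items() if s not in (1, -1)}
            if bad:
                raise ValueError(f"gene set {name!r} has signs outside +/-1: {bad}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def members(self, name: str) -> list[str]:
        return list(self.sets[name])


@dataclass
class MutationTable:
    """Binary mutation calls: (sample, gene, non_silent|silent) records."""

    records: pd.DataFrame  # columns sample, gene, variant_class

    def __post_init__(self) -> None:
        required = {"sample", "gene", "variant_class"}
        if not required.issubset(self.records.columns):
            raise ValueError(f"mutation table needs columns {sorted(required)}")
        if self.records[list(required)].isna().any().any():
            raise ValueError("mutation table has missing fields")
        bad = set(self.records["variant_class"]) - set(VARIANT_CLASSES)
        if bad:
            raise ValueError(f"unknown variant classes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)

    def concat(self, other: "MutationTable") -> "MutationTable":
        return MutationTable(
            pd.concat([self.records, other.records], ignore_index=True)
        )


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates: survival, stage, optional labels."""

    data: pd.DataFrame  # index = sample ids

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        for col in ("os_time", "os_event"):
            if col not in self.data.columns:
                raise ValueError(f"clinical table missing column {col!r}")
        if (self.data["os_time"].astype(float) < 0).any():
            raise ValueError("os_time must be >= 0")
        ev = set(self.data["os_event"].astype(int))
        if not ev.issubset({0, 1}):
            raise ValueError(f"os_event must be binary, saw {sorted(ev)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class DrugResponseTable:
    """Drug-response AUC in [0,1], compounds x cell lines; missing allowed."""

    data: pd.DataFrame  # index = compound ids, columns = cell line ids

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "compound")
        _check_unique(self.data.columns, "cell line")
        vals = self.data.to_numpy(dtype=float)
        present = ~np.isnan(vals)
        if ((vals[present] < 0) | (vals[present] > 1)).any():
            raise ValueError("AUC values must lie in [0, 1]")


# ---------------------------------------------------------------------------
# expression I/O


def _validate_numeric(df: pd.DataFrame, path: str) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    # "NA"/empty were already NaN in the raw frame; anything newly NaN was text
    bad = out.isna() & df.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell at gene {df.index[r]!r}, sample {df.columns[c]!r}: "
            f"{df.iat[r, c]!r}"
        )
    return out


def read_expression(path: str, format: str = "tsv") -> ExpressionMatrix:
    """Read a genes x samples log2 expression matrix from TSV or GCT 1.2."""
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    elif format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise ValueError(f"{path}: expected GCT version line '#1.2', got {version!r}")
            try:
                n_genes, n_samples = (int(x) for x in fh.readline().split())
            except ValueError as exc:
                raise ValueError(f"{path}: malformed GCT dimensions line") from exc
            df = pd.read_csv(fh, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
        df = df.drop(columns=df.columns[0])  # Description column
        if df.shape != (n_genes, n_samples):
            raise ValueError(
                f"{path}: GCT dims line says {(n_genes, n_samples)}, table is {df.shape}"
            )
    else:
        raise ValueError(f"unknown expression format {format!r}")
    df.index = df.index.astype(str)
    return ExpressionMatrix(_validate_numeric(df, path))


def write_expression(matrix: ExpressionMatrix, path: str, format: str = "tsv") -> None:
    if format == "tsv":
        matrix.data.to_csv(path, sep="\t", na_rep="NA", index_label="gene")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\n")
            out = matrix.data.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", na_rep="NA", index_label="Name")
    else:
        raise ValueError(f"unknown expression format {format!r}")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gene_sets(path: str, signed: bool = False) -> GeneSetCollection:
    """Read a GMT file; with ``signed`` each member carries a ,+1/,-1 suffix."""
    sets: dict[str, dict[str, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: gene set with no members")
            name, _desc, *members = fields
            parsed: dict[str, int] = {}
            for token in members:
                if not token:
                    continue
                if signed and "," in token:
                    gene, _, signtok = token.rpartition(",")
                    if signtok not in ("+1", "-1", "1"):
                        raise ValueError(
                            f"{path}:{lineno}: malformed sign token {token!r}"
                        )
                    sign = -1 if signtok == "-1" else 1
                else:
                    gene, sign = token, 1
                if gene in parsed:
                    raise ValueError(f"{path}:{lineno}: duplicate member {gene!r} in {name!r}")
                parsed[gene] = sign
            if not parsed:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = parsed
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path: str, signed: bool = False) -> None:
    with open(path, "w") as fh:
        for name, members in collection:
            if signed:
                toks = [f"{g},{'+1' if s > 0 else '-1'}" for g, s in members.items()]
            else:
                toks = list(members)
            fh.write("\t".join([name, "na", *toks]) + "\n")


# ---------------------------------------------------------------------------
# mutations (MAF-lite)


def read_mutations(path: str, collapse: dict[str, str] | None = None) -> MutationTable:
    """Read a MAF-lite TSV (sample, gene, variant_classification).

    MAF variant classes are collapsed to {non_silent, silent}: classes in
    ``collapse`` map explicitly, every other class is non_silent.
    """
    collapse = DEFAULT_MAF_COLLAPSE if collapse is None else collapse
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "gene", "variant_classification"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: MAF-lite needs columns {sorted(required)}")
    classes = df["variant_classification"]
    collapsed = classes.map(lambda c: collapse.get(c, "non_silent"))
    # already-collapsed inputs pass through
    collapsed = classes.where(classes.isin(VARIANT_CLASSES), collapsed)
    out = pd.DataFrame(
        {"sample": df["sample"], "gene": df["gene"], "variant_class": collapsed}
    )
    table = MutationTable(out)
    if len(table) != len(df):
        raise AssertionError("reader dropped mutation records")  # pragma: no cover
    return table


def write_mutations(table: MutationTable, path: str) -> None:
    out = table.records.rename(columns={"variant_class": "variant_classification"})
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# clinical / drug tables


def read_clinical(path: str) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    df.index = df.index.astype(str)
    df["os_time"] = pd.to_numeric(df["os_time"])
    df["os_event"] = pd.to_numeric(df["os_event"]).astype(int)
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path: str) -> None:
    table.data.to_csv(path, sep="\t", na_rep="NA", index_label="sample")


def read_drug_response(path: str) -> DrugResponseTable:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    df.index = df.index.astype(str)
    return DrugResponseTable(_validate_numeric(df, path))


def write_drug_response(table: DrugResponseTable, path: str) -> None:
    table.data.to_csv(path, sep="\t", na_rep="NA", index_label="compound")


def read_dependency(path: str) -> DependencyMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    df.index = df.index.astype(str)
    return DependencyMatrix(_validate_numeric(df, path))


def write_dependency(matrix: DependencyMatrix, path: str) -> None:
    matrix.data.to_csv(path, sep="\t", na_rep="NA", index_label="gene")
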