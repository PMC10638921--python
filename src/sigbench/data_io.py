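"""Readers, writers and grouping helpers for the formats the toolkit touches.

Expression matrices are delimited text (TSV or CSV, auto-detected) with a
gene-identifier first column and a header row of sample identifiers.
Gene-set libraries use the GMT exchange format: one term per line,
``name<TAB>description<TAB>gene1<TAB>gene2...``. Gene symbols are
upper-cased on ingest so signatures match library terms regardless of the
source's capitalisation convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ValueKind = Literal["counts", "signed_log"]

CONDITION_VALUES = ("treatment", "control", "other")


def normalize_gene(gene: str) -> str:
    """Case-normalize a gene symbol (upper-case, stripped). Idempotent."""
    return gene.strip().upper()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GeneExpressionMatrix:
    """A gene x sample real-valued matrix with a declared value kind.

    ``value_kind`` is ``"counts"`` for nonnegative RNA-seq count data and
    ``"signed_log"`` for already log-scale profiles that may be negative
    (e.g. normalized L1000 level-3 expression values).
    """

    values: pd.DataFrame  # genes (index) x samples (columns)
    value_kind: ValueKind

    def __post_init__(self) -> None:
        if self.value_kind not in ("counts", "signed_log"):
            raise ValueError(f"unknown value_kind: {self.value_kind!r}")
        idx = self.values.index
        if idx.duplicated().any():
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene_ids: {dupes[:5]}")
        cols = self.values.columns
        if cols.duplicated().any():
            dupes = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample_ids: {dupes[:5]}")
        if self.value_kind == "counts" and (self.values.to_numpy() < 0).any():
            raise ValueError("counts matrix contains negative values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class GeneSetLibrary:
    """Ordered named gene sets with optional per-term metadata.

    ``terms`` maps term name -> (description, gene set); insertion order is
    preserved for deterministic iteration. ``term_meta`` optionally maps a
    term name to ``(factor symbol, species, context)`` as parsed from
    ChEA-style term names like ``NR3C1 12345 ChIP-Seq LUNG Human``.
    """

    terms: dict[str, tuple[str, list[str]]] = field(default_factory=dict)
    term_meta: dict[str, tuple[str, str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, genes) in self.terms.items():
            if not genes:
                raise ValueError(f"term {name!r} has an empty gene set")

    @property
    def term_names(self) -> list[str]:
        return list(self.terms)

    def genes(self, term: str) -> list[str]:
        return self.terms[term][1]

    def gene_set(self, term: str) -> set[str]:
        return set(self.terms[term][1])

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for _, genes in self.terms.values():
            out.update(genes)
        return out

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class DrugTargetRecord:
    drug_id: str
    target_gene: str
    relation: str  # inhibitor | activator | other


@dataclass
class DrugTargetCatalog:
    """Known drug-target relationships (Pharos-style flat records)."""

    records: list[DrugTargetRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            key = (rec.drug_id, rec.target_gene, rec.relation)
            if key in seen:
                raise ValueError(f"duplicate drug-target record: {key}")
            seen.add(key)

    def targets_of(self, drug_id: str, relation: str | None = None) -> set[str]:
        return {
            r.target_gene
            for r in self.records
            if r.drug_id == drug_id and (relation is None or r.relation == relation)
        }

    @property
    def drug_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.drug_id, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def _parse_chea_meta(term_name: str) -> tuple[str, str, str] | None:
    # ChEA-style names: "<TF> <accession> <assay> <context...> <Species>"
    parts = term_name.split()
    if len(parts) < 3:
        return None
    factor = normalize_gene(parts[0])
    species = parts[-1].lower()
    context = " ".join(parts[2:-1]) if len(parts) > 3 else ""
    return factor, species, context


def read_gmt(path: str | Path) -> GeneSetLibrary:
    """Read a GMT gene-set library.

    Each line must have at least three tab-separated fields: term name,
    description, and one or more genes. Empty gene tokens are dropped and
    duplicate genes within a term are deduplicated (first occurrence wins).
    Duplicate term names are a hard error.
    """
    path = Path(path)
    terms: dict[str, tuple[str, list[str]]] = {}
    term_meta: dict[str, tuple[str, str, str]] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name, desc = fields[0], fields[1]
            if name in terms:
                raise ValueError(f"{path}:{lineno}: duplicate term name {name!r}")
            genes: list[str] = []
            seen: set[str] = set()
            for tok in fields[2:]:
                g = normalize_gene(tok)
                if g and g not in seen:
                    genes.append(g)
                    seen.add(g)
            if not genes:
                raise ValueError(f"{path}:{lineno}: term {name!r} has no genes")
            terms[name] = (desc, genes)
            meta = _parse_chea_meta(name)
            if meta is not None:
                term_meta[name] = meta
    return GeneSetLibrary(terms=terms, term_meta=term_meta)


def write_gmt(library: GeneSetLibrary, path: str | Path) -> Path:
    """Write a library to GMT, terms in order, genes in insertion order."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for name, (desc, genes) in library.terms.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")
    return path


# ---------------------------------------------------------------------------
# Expression matrices and metadata
# ---------------------------------------------------------------------------


def _sniff_sep(path: Path) -> str:
    with path.open(encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_expression_matrix(path: str | Path, value_kind: ValueKind) -> GeneExpressionMatrix:
    """Read a delimited gene x sample matrix (gene id first column).

    Non-numeric cells and negative counts raise with the offending
    location. Duplicate gene rows are collapsed by keeping the row with the
    largest total absolute value.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.map(normalize_gene)
    try:
        df = df.astype(float)
    except ValueError:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                gene = df.index[bad.to_numpy().argmax()]
                raise ValueError(
                    f"{path}: non-numeric cell at gene {gene!r}, sample {col!r}"
                ) from None
        raise
    if value_kind == "counts" and (df.to_numpy() < 0).any():
        arr = df.to_numpy()
        gi, si = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"{path}: negative count at gene {df.index[gi]!r}, sample {df.columns[si]!r}"
        )
    if df.index.duplicated().any():
        # keep, per duplicated gene id, the row with the largest total |value|
        strength = df.abs().sum(axis=1)
        df = df.assign(__strength=strength.to_numpy())
        df = (
            df.sort_values("__strength", ascending=False, kind="stable")
            .groupby(level=0, sort=False)
            .head(1)
            .drop(columns="__strength")
        )
        df = df.loc[~df.index.duplicated()]
    return GeneExpressionMatrix(values=df, value_kind=value_kind)


def write_expression_matrix(matrix: GeneExpressionMatrix, path: str | Path) -> Path:
    path = Path(path)
    matrix.values.to_csv(path, sep="\t", index_label="gene")
    return path


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata table.

    Requires ``sample_id`` and ``condition`` columns; ``batch_id`` and
    ``perturbagen`` are optional. Condition strings outside
    {treatment, control} map to "other". Duplicate sample ids are an error.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("sample_id", "condition"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicated sample_id(s): {dupes[:5]}")
    df["condition"] = (
        df["condition"].str.strip().str.lower().where(
            df["condition"].str.strip().str.lower().isin(CONDITION_VALUES), "other"
        )
    )
    if "batch_id" not in df.columns:
        df["batch_id"] = ""
    if "perturbagen" not in df.columns:
        df["perturbagen"] = ""
    df["batch_id"] = df["batch_id"].fillna("")
    df["perturbagen"] = df["perturbagen"].fillna("")
    return df.set_index("sample_id", drop=False)


def read_drug_target_catalog(path: str | Path) -> DrugTargetCatalog:
    """Read a drug-target catalog TSV with columns drug_id, target_gene, relation."""
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("drug_id", "target_gene", "relation"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    records = [
        DrugTargetRecord(
            drug_id=row.drug_id,
            target_gene=normalize_gene(row.target_gene),
            relation=row.relation.strip().lower()
            if row.relation.strip().lower() in ("inhibitor", "activator")
            else "other",
        )
        for row in df.itertuples()
    ]
    return DrugTargetCatalog(records=records)


def write_drug_target_catalog(catalog: DrugTargetCatalog, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [(r.drug_id, r.target_gene, r.relation) for r in catalog.records],
        columns=["drug_id", "target_gene", "relation"],
    ).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Batch resolution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BatchComparison:
    batch_id: str
    treatment: tuple[str, ...]
    control: tuple[str, ...]


def split_batches(
    matrix: GeneExpressionMatrix,
    metadata: pd.DataFrame,
    perturbagen: str,
) -> list[BatchComparison]:
    """Resolve per-batch treatment/control sample groups.

    Within each batch (a unique cell line x timepoint label), treatment
    samples are those whose ``perturbagen`` matches; control samples are
    all other samples in the same batch — the L1000 level-3 convention
    where the background pool of a plate serves as the control. Batches
    lacking either group are dropped with a warning; if no batch yields
    both groups, this is a hard error.
    """
    missing = [s for s in matrix.sample_ids if s not in metadata.index]
    if missing:
        raise ValueError(f"samples absent from metadata: {missing[:5]}")
    meta = metadata.loc[matrix.sample_ids]
    if (meta["perturbagen"] == perturbagen).sum() == 0:
        raise ValueError(f"perturbagen {perturbagen!r} not found in any sample")
    comparisons: list[BatchComparison] = []
    for batch_id, sub in meta.groupby("batch_id", sort=True):
        is_treat = sub["perturbagen"] == perturbagen
        treatment = tuple(sub.index[is_treat])
        control = tuple(sub.index[~is_treat])
        if not treatment or not control:
            logger.warning(
                "batch %r dropped: %d treatment, %d control samples",
                batch_id, len(treatment), len(control),
            )
            warnings.warn(
                f"batch {batch_id!r} dropped ({len(treatment)} treatment, "
                f"{len(control)} control)",
                stacklevel=2,
            )
            continue
        comparisons.append(BatchComparison(str(batch_id), treatment, control))
    if not comparisons:
        raise ValueError("no batch has both treatment and control samples")
    return comparisons


def treatment_control_groups(metadata: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Explicit condition-label grouping for RNA-seq style designs."""
    treatment = list(metadata.index[metadata["condition"] == "treatment"])
    control = list(metadata.index[metadata["condition"] == "control"])
    if not treatment or not control:
        raise ValueError(
            f"need both groups: {len(treatment)} treatment, {len(control)} control"
        )
    return treatment, control
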