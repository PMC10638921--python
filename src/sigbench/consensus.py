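"""Consensus perturbation signatures and drug-target recovery.

A consensus signature collapses the per-batch (cell line x timepoint)
signatures of one perturbagen into a single context-agnostic vector, by
elementwise mean, median, or a correlation-weighted average in which each
input is weighted by its mean Pearson correlation with the other inputs
(floored at a small epsilon, normalised to sum 1).

Drug consensus signatures are then correlated against CRISPR-KO consensus
signatures: for each drug, KO genes ranked by Pearson correlation
descending should place the drug's known inhibited targets near the top,
which is scored with the bridge-curve machinery and per-target ranks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from sigbench.benchmark import BridgeCurve, average_curves, bridge_curve
from sigbench.data_io import DrugTargetCatalog, GeneSetLibrary, normalize_gene
from sigbench.enrichment import TermSelector

logger = logging.getLogger(__name__)

WEIGHT_FLOOR = 0.01


@dataclass
class ConsensusSignature:
    """Per-perturbagen aggregated coefficient vector over a shared universe."""

    perturbagen_id: str
    coefficient: pd.Series  # indexed by gene id
    method: str  # mean | median | weighted
    n_inputs: int
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if (w < 0).any() or not np.isclose(w.sum(), 1.0):
                raise ValueError("weights must be nonnegative and sum to 1")
            self.weights = w


def _stack(vectors: Sequence[pd.Series]) -> tuple[np.ndarray, pd.Index]:
    if not vectors:
        raise ValueError("need at least one input signature")
    index = vectors[0].index
    for v in vectors[1:]:
        if not v.index.equals(index):
            raise ValueError("input signatures have mismatched gene universes")
    return np.column_stack([v.to_numpy(dtype=float) for v in vectors]), index


def consensus_mean(
    vectors: Sequence[pd.Series], perturbagen_id: str = ""
) -> ConsensusSignature:
    """Elementwise mean of per-batch signature vectors."""
    mat, index = _stack(vectors)
    return ConsensusSignature(
        perturbagen_id=perturbagen_id,
        coefficient=pd.Series(mat.mean(axis=1), index=index),
        method="mean",
        n_inputs=mat.shape[1],
    )


def consensus_median(
    vectors: Sequence[pd.Series], perturbagen_id: str = ""
) -> ConsensusSignature:
    """Elementwise median of per-batch signature vectors."""
    mat, index = _stack(vectors)
    return ConsensusSignature(
        perturbagen_id=perturbagen_id,
        coefficient=pd.Series(np.median(mat, axis=1), index=index),
        method="median",
        n_inputs=mat.shape[1],
    )


def consensus_weighted(
    vectors: Sequence[pd.Series],
    perturbagen_id: str = "",
    weight_floor: float = WEIGHT_FLOOR,
) -> ConsensusSignature:
    """Correlation-weighted average of per-batch signature vectors.

    Each input's raw weight is its mean Pearson correlation with the other
    inputs, floored at ``weight_floor`` (so discordant or zero-variance
    inputs contribute minimally rather than negatively), then normalised
    to sum 1. A single input is returned unchanged with weight 1.
    """
    mat, index = _stack(vectors)
    m = mat.shape[1]
    if m == 1:
        weights = np.array([1.0])
    else:
        sd = mat.std(axis=0)
        degenerate = sd == 0
        if degenerate.any():
            logger.warning(
                "%d zero-variance input(s) receive floor weight", int(degenerate.sum())
            )
        safe = mat.copy()
        safe[:, degenerate] = np.nan
        with np.errstate(invalid="ignore"):
            rho = np.corrcoef(safe, rowvar=False)
        rho = np.nan_to_num(rho, nan=0.0)
        np.fill_diagonal(rho, 1.0)
        raw = (rho.sum(axis=1) - 1.0) / (m - 1)
        raw[degenerate] = weight_floor
        raw = np.maximum(raw, weight_floor)
        weights = raw / raw.sum()
    return ConsensusSignature(
        perturbagen_id=perturbagen_id,
        coefficient=pd.Series(mat @ weights, index=index),
        method="weighted",
        n_inputs=m,
        weights=weights,
    )


CONSENSUS_METHODS = {
    "mean": consensus_mean,
    "median": consensus_median,
    "weighted": consensus_weighted,
}


@dataclass
class SimilarityMatrix:
    """Drug x KO-gene Pearson correlation table."""

    values: pd.DataFrame  # drugs (rows) x KO genes (columns)

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValueError("similarity matrix contains non-finite entries")
        if np.any(arr < -1 - 1e-9) or np.any(arr > 1 + 1e-9):
            raise ValueError("correlations outside [-1, 1]")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def ko_gene_ids(self) -> list[str]:
        return list(self.values.columns)


def similarity_matrix(
    drug_consensus: Sequence[ConsensusSignature],
    ko_consensus: Sequence[ConsensusSignature],
) -> SimilarityMatrix:
    """Pearson correlation of every drug consensus with every KO consensus.

    Zero-variance vectors would make the correlation undefined; their
    entries are set to 0 with a warning.
    """
    if not drug_consensus or not ko_consensus:
        raise ValueError("need at least one drug and one KO consensus signature")
    index = drug_consensus[0].coefficient.index
    for sig in list(drug_consensus) + list(ko_consensus):
        if not sig.coefficient.index.equals(index):
            raise ValueError("consensus signatures have mismatched gene universes")
    d = np.column_stack([s.coefficient.to_numpy() for s in drug_consensus])
    k = np.column_stack([s.coefficient.to_numpy() for s in ko_consensus])
    d_c = d - d.mean(axis=0)
    k_c = k - k.mean(axis=0)
    d_sd = np.sqrt((d_c**2).sum(axis=0))
    k_sd = np.sqrt((k_c**2).sum(axis=0))
    if (d_sd == 0).any() or (k_sd == 0).any():
        logger.warning("zero-variance consensus vector(s): correlations set to 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (d_c.T @ k_c) / np.outer(d_sd, k_sd)
    corr = np.nan_to_num(corr, nan=0.0, posinf=0.0, neginf=0.0)
    corr = np.clip(corr, -1.0, 1.0)
    return SimilarityMatrix(
        values=pd.DataFrame(
            corr,
            index=[s.perturbagen_id for s in drug_consensus],
            columns=[s.perturbagen_id for s in ko_consensus],
        )
    )


@dataclass
class TargetRecovery:
    """Per-drug known-target ranks and the averaged recovery curve."""

    target_ranks: pd.DataFrame  # drug_id, target_gene, rank, pcc, n_kos
    curve: BridgeCurve
    n_drugs: int


def rank_targets(
    matrix: SimilarityMatrix,
    catalog: DrugTargetCatalog,
    relation: str = "inhibitor",
) -> TargetRecovery:
    """Score known-target recovery from the drug x KO similarity matrix.

    Drugs are restricted to those with at least one catalogued target of
    the requested relation present among the KO columns (the inhibitor
    filter: an inhibitory drug's signature should resemble its target's
    knockout signature). Per drug, KO genes are ranked by correlation
    descending (ties by gene id) and the ranks of known targets recorded;
    the recovery curve is the per-drug bridge curve averaged over drugs.
    """
    ko_set = set(matrix.ko_gene_ids)
    rows: list[dict] = []
    curves: list[BridgeCurve] = []
    for drug in matrix.drug_ids:
        targets = {normalize_gene(t) for t in catalog.targets_of(drug, relation)} & ko_set
        if not targets:
            continue
        sims = matrix.values.loc[drug]
        order = sims.to_frame("pcc").assign(gene=sims.index)
        order = order.sort_values(["pcc", "gene"], ascending=[False, True], kind="stable")
        ranked_genes = order["gene"].tolist()
        rank_of = {g: i + 1 for i, g in enumerate(ranked_genes)}
        for t in sorted(targets):
            rows.append(
                {
                    "drug_id": drug,
                    "target_gene": t,
                    "rank": rank_of[t],
                    "pcc": float(sims[t]),
                    "n_kos": len(ranked_genes),
                }
            )
        curves.append(bridge_curve(ranked_genes, targets))
    if not rows:
        raise ValueError(
            f"no qualifying drugs: no drug has a {relation!r} target among the KO genes"
        )
    return TargetRecovery(
        target_ranks=pd.DataFrame(rows),
        curve=average_curves(curves),
        n_drugs=len(curves),
    )


def mean_reciprocal_rank(recovery: TargetRecovery) -> float:
    """MRR of each drug's best-ranked known target."""
    best = recovery.target_ranks.groupby("drug_id")["rank"].min()
    return float((1.0 / best).mean())


def predict_drugs(
    matrix: SimilarityMatrix, target_gene: str, k: int = 100
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k most similar and most opposite drugs for a KO target gene.

    Similar drugs are the k highest signed correlations descending;
    opposite drugs the k lowest ascending. Ties break by drug id for
    determinism. Returns two tables with columns (drug_id, pcc).
    """
    target_gene = normalize_gene(target_gene)
    if target_gene not in matrix.values.columns:
        raise KeyError(f"unknown target gene {target_gene!r}")
    if not 1 <= k <= len(matrix.drug_ids):
        raise ValueError(f"k must be in [1, {len(matrix.drug_ids)}]")
    col = matrix.values[target_gene]
    df = col.to_frame("pcc").assign(drug_id=col.index)
    similar = (
        df.sort_values(["pcc", "drug_id"], ascending=[False, True], kind="stable")
        .head(k)[["drug_id", "pcc"]]
        .reset_index(drop=True)
    )
    opposite = (
        df.sort_values(["pcc", "drug_id"], ascending=[True, True], kind="stable")
        .head(k)[["drug_id", "pcc"]]
        .reset_index(drop=True)
    )
    return similar, opposite


def overlap_with_targets(
    consensus: ConsensusSignature,
    n_top: int,
    library: GeneSetLibrary,
    selectors: Mapping[str, TermSelector],
) -> pd.DataFrame:
    """Overlap of a consensus signature's top genes with TF target sets.

    The top ``n_top`` up- and down-regulated genes of the consensus are
    intersected with, for each named selector, the union of its matching
    terms' gene sets. The returned table has one row per (selector,
    direction) plus, when several selectors are given, rows for the
    multi-way intersection of all selector target sets.
    """
    coef = consensus.coefficient.sort_values(ascending=False, kind="stable")
    up = [g for g in coef.index[:n_top] if coef[g] > 0]
    coef_asc = consensus.coefficient.sort_values(ascending=True, kind="stable")
    down = [g for g in coef_asc.index[:n_top] if coef_asc[g] < 0]
    target_sets: dict[str, set[str]] = {}
    for name, sel in selectors.items():
        genes: set[str] = set()
        matched = 0
        for term in library.term_names:
            if sel(term, library.term_meta.get(term)):
                genes |= library.gene_set(term)
                matched += 1
        if matched == 0:
            raise ValueError(f"selector {name!r} matches no library terms")
        target_sets[name] = genes
    rows = []
    for name, genes in target_sets.items():
        for direction, query in (("up", set(up)), ("down", set(down))):
            inter = sorted(genes & query)
            rows.append(
                {
                    "selector": name,
                    "direction": direction,
                    "overlap": len(inter),
                    "target_set_size": len(genes),
                    "query_size": len(query),
                    "genes": ";".join(inter),
                }
            )
    if len(target_sets) > 1:
        multi = set.intersection(*target_sets.values())
        for direction, query in (("up", set(up)), ("down", set(down))):
            inter = sorted(multi & query)
            rows.append(
                {
                    "selector": "&".join(target_sets),
                    "direction": direction,
                    "overlap": len(inter),
                    "target_set_size": len(multi),
                    "query_size": len(query),
                    "genes": ";".join(inter),
                }
            )
    return pd.DataFrame(rows)
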