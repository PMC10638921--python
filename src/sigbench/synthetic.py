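"""Synthetic fixtures with the statistical structure the benchmark assumes.

Three generators emulate the three data families the toolkit consumes,
without any downloads:

* :func:`make_count_experiment` — bulk RNA-seq style negative-binomial
  counts for a small two-group design (four treated vs four untreated by
  default), with the genes of planted library terms shifted by a known
  log2 effect in the treatment group, plus a gene-set library containing
  the planted terms among size-matched decoy terms.
* :func:`make_l1000_experiment` — signed log-scale Gaussian profiles with
  per-batch (cell line x timepoint) additive effects, a few perturbation
  samples per batch and a larger background pool that serves as the
  control group.
* :func:`make_perturbation_collection` — drug and CRISPR-KO consensus
  signature collections over a landmark-gene-sized universe, with planted
  inhibitor drug-target pairs whose expected Pearson correlation is set by
  construction, and a matching drug-target catalog.

All generators are pure functions of the spec (seed included): repeated
calls return identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from sigbench.consensus import ConsensusSignature
from sigbench.data_io import (
    DrugTargetCatalog,
    DrugTargetRecord,
    GeneExpressionMatrix,
    GeneSetLibrary,
    _parse_chea_meta,
)


@dataclass(frozen=True)
class PlantedTerm:
    """A library term whose genes carry a real group effect."""

    size: int = 50
    effect: float = 2.0  # log2 scale (additive on signed profiles)
    direction: str = "up"  # up | down

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if self.size < 1:
            raise ValueError("term size must be >= 1")


def _default_planted() -> dict[str, PlantedTerm]:
    return {"TF001 001 ChIP-Seq SIM Human": PlantedTerm()}


@dataclass
class SimulationSpec:
    """Parameters of the synthetic experiments.

    Count-experiment fields mirror a small bulk RNA-seq comparison:
    ``n_treatment``/``n_control`` of 4 each, negative-binomial counts with
    dispersion ``nb_dispersion`` and log-normal baseline means
    (``exp(N(baseline_log_mean, baseline_log_sd))``). ``planted_terms``
    maps term names to the effect their genes carry; the generated library
    adds ``n_decoy_terms`` size-matched terms from non-planted genes.

    L1000-experiment fields: ``n_batches`` batches, each with
    ``n_treatment`` perturbation samples and ``n_background`` background
    samples, additive per-gene batch effects of s.d. ``batch_effect_sd``
    and within-batch noise of s.d. ``noise_sd``.

    Perturbation-collection fields: ``n_drugs`` x ``n_kos`` consensus
    collections over ``signature_length`` genes with ``n_planted_pairs``
    inhibitor pairs built to an expected Pearson correlation of
    ``target_pcc``.
    """

    seed: int
    n_genes: int = 10000
    n_treatment: int = 4
    n_control: int = 4
    planted_terms: dict[str, PlantedTerm] = field(default_factory=_default_planted)
    n_decoy_terms: int = 49
    nb_dispersion: float = 0.1
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.0
    n_batches: int = 2
    n_background: int = 17
    batch_effect_sd: float = 1.0
    noise_sd: float = 1.0
    perturbagen_label: str = "dex"
    n_drugs: int = 50
    n_kos: int = 30
    n_planted_pairs: int = 20
    target_pcc: float = 0.7
    signature_length: int = 978

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.batch_effect_sd < 0:
            raise ValueError("batch_effect_sd must be >= 0")
        if not -1.0 <= self.target_pcc <= 1.0:
            raise ValueError("target_pcc must be in [-1, 1]")
        needed = sum(t.size for t in self.planted_terms.values())
        if needed > self.n_genes:
            raise ValueError("planted term genes exceed n_genes")
        if self.n_planted_pairs > self.n_drugs:
            raise ValueError("more planted pairs than drugs")


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def _build_library(
    rng: np.random.Generator,
    genes: Sequence[str],
    planted_genes: dict[str, list[str]],
    n_decoys: int,
) -> GeneSetLibrary:
    terms: dict[str, tuple[str, list[str]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    all_planted: set[str] = set()
    for gs in planted_genes.values():
        all_planted.update(gs)
    for name, gs in planted_genes.items():
        terms[name] = ("planted", list(gs))
        m = _parse_chea_meta(name)
        if m is not None:
            meta[name] = m
    pool = [g for g in genes if g not in all_planted]
    sizes = [len(gs) for gs in planted_genes.values()] or [50]
    for i in range(n_decoys):
        size = min(sizes[i % len(sizes)], len(pool))
        draw = rng.choice(len(pool), size=size, replace=False)
        name = f"DECOY{i + 1:03d} {i + 1:03d} ChIP-Seq SIM Human"
        terms[name] = ("decoy", [pool[j] for j in sorted(draw)])
        m = _parse_chea_meta(name)
        if m is not None:
            meta[name] = m
    return GeneSetLibrary(terms=terms, term_meta=meta)


def make_count_experiment(
    spec: SimulationSpec,
) -> tuple[GeneExpressionMatrix, pd.DataFrame, GeneSetLibrary]:
    """Simulate a two-group RNA-seq count matrix with planted DE terms.

    Counts are NB(mu, dispersion) with per-gene baselines drawn log-normal
    across genes; genes of each planted term have their treatment-group
    mean multiplied by ``2**effect`` (divided for "down" terms).
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec.n_genes)
    baseline = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd, spec.n_genes)

    # assign disjoint gene blocks to the planted terms
    perm = rng.permutation(spec.n_genes)
    planted_genes: dict[str, list[str]] = {}
    fold = np.ones(spec.n_genes)
    pos = 0
    for name, term in spec.planted_terms.items():
        idx = perm[pos : pos + term.size]
        pos += term.size
        planted_genes[name] = sorted(genes[i] for i in idx)
        fold[idx] = 2.0**term.effect if term.direction == "up" else 2.0**-term.effect

    n_inv = 1.0 / spec.nb_dispersion  # NB shape so that var = mu + disp*mu^2

    def _draw(mu: np.ndarray, n_samples: int) -> np.ndarray:
        p = n_inv / (n_inv + mu)
        return rng.negative_binomial(
            n_inv, p[:, None], size=(spec.n_genes, n_samples)
        ).astype(float)

    xt = _draw(baseline * fold, spec.n_treatment)
    xc = _draw(baseline, spec.n_control)
    sample_ids = [f"T{i + 1}" for i in range(spec.n_treatment)] + [
        f"C{i + 1}" for i in range(spec.n_control)
    ]
    values = pd.DataFrame(np.hstack([xt, xc]), index=genes, columns=sample_ids)
    matrix = GeneExpressionMatrix(values=values, value_kind="counts")
    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "condition": ["treatment"] * spec.n_treatment
            + ["control"] * spec.n_control,
            "batch_id": "all",
            "perturbagen": [spec.perturbagen_label] * spec.n_treatment
            + [""] * spec.n_control,
        }
    ).set_index("sample_id", drop=False)
    library = _build_library(rng, genes, planted_genes, spec.n_decoy_terms)
    return matrix, metadata, library


def make_l1000_experiment(
    spec: SimulationSpec,
) -> tuple[GeneExpressionMatrix, pd.DataFrame, GeneSetLibrary]:
    """Simulate signed log-scale profiles with batch structure.

    Each batch gets its own additive per-gene offset (s.d.
    ``batch_effect_sd``); every sample adds N(0, noise_sd) noise.
    Perturbation samples shift the planted genes additively by the term
    effect (sign per direction); the remaining samples form the background
    control pool of their batch.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec.n_genes)

    perm = rng.permutation(spec.n_genes)
    planted_genes: dict[str, list[str]] = {}
    shift = np.zeros(spec.n_genes)
    pos = 0
    for name, term in spec.planted_terms.items():
        idx = perm[pos : pos + term.size]
        pos += term.size
        planted_genes[name] = sorted(genes[i] for i in idx)
        shift[idx] = term.effect if term.direction == "up" else -term.effect

    cols: list[np.ndarray] = []
    sample_ids: list[str] = []
    conditions: list[str] = []
    batch_ids: list[str] = []
    perturbagens: list[str] = []
    for b in range(spec.n_batches):
        batch_effect = rng.normal(0.0, spec.batch_effect_sd, spec.n_genes)
        n_total = spec.n_treatment + spec.n_background
        for j in range(n_total):
            is_treat = j < spec.n_treatment
            x = batch_effect + rng.normal(0.0, spec.noise_sd, spec.n_genes)
            if is_treat:
                x = x + shift
            cols.append(x)
            sample_ids.append(f"B{b + 1:02d}S{j + 1:02d}")
            conditions.append("treatment" if is_treat else "other")
            batch_ids.append(f"B{b + 1:02d}")
            perturbagens.append(spec.perturbagen_label if is_treat else "")
    values = pd.DataFrame(
        np.column_stack(cols), index=genes, columns=sample_ids
    )
    matrix = GeneExpressionMatrix(values=values, value_kind="signed_log")
    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "condition": conditions,
            "batch_id": batch_ids,
            "perturbagen": perturbagens,
        }
    ).set_index("sample_id", drop=False)
    library = _build_library(rng, genes, planted_genes, spec.n_decoy_terms)
    return matrix, metadata, library


def make_perturbation_collection(
    spec: SimulationSpec,
) -> tuple[list[ConsensusSignature], list[ConsensusSignature], DrugTargetCatalog]:
    """Simulate drug and CRISPR-KO consensus collections with planted pairs.

    KO signatures are i.i.d. standard Gaussian vectors. Each planted
    (drug, target) pair sets drug = rho * KO_target + sqrt(1 - rho^2) * eps
    so the expected Pearson correlation equals ``target_pcc``; unplanted
    drugs are pure noise. The catalog labels planted pairs as inhibitors
    and adds decoy activator relations on random unplanted combinations.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec.signature_length)
    ko_ids = [f"KO{i + 1:04d}" for i in range(spec.n_kos)]
    drug_ids = [f"DRUG{i + 1:04d}" for i in range(spec.n_drugs)]
    ko_mat = rng.standard_normal((spec.signature_length, spec.n_kos))
    rho = spec.target_pcc
    planted_target: dict[str, str] = {}
    drug_vecs: list[np.ndarray] = []
    for i, drug in enumerate(drug_ids):
        eps = rng.standard_normal(spec.signature_length)
        if i < spec.n_planted_pairs:
            ko_idx = i % spec.n_kos
            planted_target[drug] = ko_ids[ko_idx]
            vec = rho * ko_mat[:, ko_idx] + np.sqrt(max(0.0, 1 - rho**2)) * eps
        else:
            vec = eps
        drug_vecs.append(vec)

    def _consensus(pid: str, vec: np.ndarray) -> ConsensusSignature:
        return ConsensusSignature(
            perturbagen_id=pid,
            coefficient=pd.Series(vec, index=genes),
            method="mean",
            n_inputs=1,
        )

    drugs = [_consensus(d, v) for d, v in zip(drug_ids, drug_vecs)]
    kos = [_consensus(k, ko_mat[:, i]) for i, k in enumerate(ko_ids)]
    records = [
        DrugTargetRecord(drug_id=d, target_gene=t, relation="inhibitor")
        for d, t in planted_target.items()
    ]
    # decoy activator relations on unplanted combinations
    n_decoys = spec.n_planted_pairs
    for _ in range(n_decoys):
        d = drug_ids[int(rng.integers(spec.n_planted_pairs, spec.n_drugs))] if (
            spec.n_planted_pairs < spec.n_drugs
        ) else drug_ids[int(rng.integers(0, spec.n_drugs))]
        t = ko_ids[int(rng.integers(0, spec.n_kos))]
        rec = DrugTargetRecord(drug_id=d, target_gene=t, relation="activator")
        if (rec.drug_id, rec.target_gene, rec.relation) not in {
            (r.drug_id, r.target_gene, r.relation) for r in records
        }:
            records.append(rec)
    return drugs, kos, DrugTargetCatalog(records=records)
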