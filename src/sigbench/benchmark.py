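"""Benchmark orchestration: enrichment-rank summaries and bridge curves.

A *bridge curve* measures how early the members of a target gene set occur
in a ranked gene list: at normalized rank x = k/N the curve is the
deviation of the target set's rank ECDF from the uniform CDF,

    y(k) = hits(k)/S - k/N,

where hits(k) counts target genes among the top k and S is the target set
size. The curve starts above (or below) zero and returns to exactly zero
at k = N; a ranking that puts all S target genes first peaks at 1 - S/N,
the maximum attainable. The *leading edge* summarises the earliest part of
the curve (x <= x_max) where strong methods show the sharpest deviation.

``run_benchmark`` wires the stages together: signatures per method and
batch, top-N directional gene sets, local Fisher enrichment, target-term
ranks, and batch-then-term averaged bridge curves, with a size-matched
random-query baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from sigbench.data_io import (
    BatchComparison,
    GeneExpressionMatrix,
    GeneSetLibrary,
    split_batches,
    treatment_control_groups,
)
from sigbench.enrichment import (
    TermSelector,
    fisher_enrich,
    random_baseline,
    term_ranks,
    top_genes,
)
from sigbench.signatures import MethodParams, Signature, compute_signature

DIRECTIONS = ("up", "down", "combined")

_GRID_POINTS = 1000


@dataclass
class BridgeCurve:
    """Running-sum deviation of a target set's rank ECDF from uniform."""

    x: np.ndarray  # normalized ranks k/N
    y: np.ndarray  # deviation at each k
    n_genes_N: int
    target_size_S: int

    @property
    def peak(self) -> float:
        return float(self.y.max())

    def leading_edge_area(self, x_max: float = 0.01) -> float:
        """Mean deviation over the initial segment x <= x_max."""
        mask = self.x <= x_max
        if not mask.any():
            mask = np.zeros_like(self.x, dtype=bool)
            mask[0] = True
        return float(self.y[mask].mean())

    def resampled(self, grid: np.ndarray) -> np.ndarray:
        """Step-interpolate y onto a normalized-rank grid (previous value)."""
        idx = np.searchsorted(self.x, grid, side="left")
        idx = np.clip(idx, 0, len(self.x) - 1)
        return self.y[idx]


def bridge_curve(
    ranked_genes: Sequence[str],
    target: Iterable[str],
    universe: Iterable[str] | None = None,
) -> BridgeCurve:
    """Compute the running-sum bridge curve of a target set in a ranking.

    ``ranked_genes`` must be a permutation of the universe (most to least
    significant). The target set is intersected with the universe and must
    not be empty afterwards.
    """
    ranked = list(ranked_genes)
    n = len(ranked)
    uni = set(ranked) if universe is None else set(universe)
    if len(ranked) != len(uni) or set(ranked) != uni:
        raise ValueError("ranked gene list must be a permutation of the universe")
    target_set = set(target) & uni
    if not target_set:
        raise ValueError("target set is disjoint from the universe")
    s = len(target_set)
    hits = np.cumsum(np.fromiter((g in target_set for g in ranked), dtype=float, count=n))
    k = np.arange(1, n + 1)
    y = hits / s - k / n
    return BridgeCurve(x=k / n, y=y, n_genes_N=n, target_size_S=s)


def average_curves(
    curves: Sequence[BridgeCurve],
    groups: Sequence[object] | None = None,
    grid_points: int = _GRID_POINTS,
) -> BridgeCurve:
    """Pointwise mean of bridge curves, optionally in two stages.

    With ``groups`` given (one label per curve, e.g. the perturbagen
    batch), curves are first averaged within each group and the group
    means are then averaged — the batches-then-terms order, which differs
    from a flat mean when group sizes are unbalanced. Curves with
    different N are aligned by step interpolation onto a fixed
    normalized-rank grid.
    """
    if not curves:
        raise ValueError("no curves to average")
    same_n = len({c.n_genes_N for c in curves}) == 1
    if same_n:
        grid = curves[0].x
        mat = np.vstack([c.y for c in curves])
    else:
        grid = np.arange(1, grid_points + 1) / grid_points
        mat = np.vstack([c.resampled(grid) for c in curves])
    if groups is not None:
        if len(groups) != len(curves):
            raise ValueError("groups must have one label per curve")
        keys = pd.unique(np.asarray(groups, dtype=object))
        garr = np.asarray(groups, dtype=object)
        mat = np.vstack([mat[garr == key].mean(axis=0) for key in keys])
    y = mat.mean(axis=0)
    n = curves[0].n_genes_N if same_n else grid_points
    s = int(round(float(np.mean([c.target_size_S for c in curves]))))
    return BridgeCurve(x=grid, y=y, n_genes_N=n, target_size_S=max(s, 1))


def rank_genes(signature: Signature) -> list[str]:
    """Total gene ordering under the signature's declared ranking key."""
    return signature.ordered_genes()


@dataclass
class BenchmarkConfig:
    """Knobs of a benchmark run.

    ``n_top`` is the hard cut-off for directional gene sets (top 100 up,
    top 100 down, combined 200 by default). ``x_max`` and ``x_max_alt``
    are the leading-edge windows reported side by side (top 1% and 2% of
    ranks). ``perturbagen`` switches batch mode on: comparisons come from
    ``split_batches`` instead of explicit condition labels.
    """

    methods: list[str] = field(default_factory=lambda: ["logfc", "welch_t", "chdir"])
    n_top: int = 100
    x_max: float = 0.01
    x_max_alt: float = 0.02
    x_max_alt: float = 0.02
    species: tuple[str, ...] | None = ("human", "mouse")
    blacklist: tuple[str, ...] = ()
    seed: int = 0
    n_random_draws: int = 10
    perturbagen: str | None = None
    batches_then_terms: bool = True
    params: MethodParams = field(default_factory=MethodParams)

    def __post_init__(self) -> None:
        if not 0 < self.x_max <= 1:
            raise ValueError("x_max must be in (0, 1]")
        if self.n_top < 1:
            raise ValueError("n_top must be >= 1")


@dataclass
class BenchmarkReport:
    rank_table: pd.DataFrame  # method, direction, term, batch, rank
    curve_table: pd.DataFrame  # method, x, y (batch-then-term averaged)
    curves: dict[str, BridgeCurve]  # per method
    config: BenchmarkConfig


def _resolve_comparisons(
    matrix: GeneExpressionMatrix,
    metadata: pd.DataFrame,
    config: BenchmarkConfig,
) -> list[BatchComparison]:
    if config.perturbagen is not None:
        return split_batches(matrix, metadata, config.perturbagen)
    treatment, control = treatment_control_groups(metadata)
    treatment = [s for s in treatment if s in matrix.sample_ids]
    control = [s for s in control if s in matrix.sample_ids]
    return [BatchComparison("all", tuple(treatment), tuple(control))]


def run_benchmark(
    matrix: GeneExpressionMatrix,
    metadata: pd.DataFrame,
    library: GeneSetLibrary,
    target_selector: TermSelector,
    config: BenchmarkConfig | None = None,
) -> BenchmarkReport:
    """Evaluate signature methods by target-term recovery.

    For every method x batch comparison: compute the signature, extract
    top-N up/down/combined gene sets, Fisher-enrich each against the
    library, record the ranks of selector-matched target terms, and build
    a bridge curve of each target term's gene set over the full ranked
    gene list. Rank rows for a size-matched random baseline are appended,
    and curves are averaged batches-first, then across terms.
    """
    config = config or BenchmarkConfig()
    if not config.methods:
        raise ValueError("config.methods must name at least one method")
    comparisons = _resolve_comparisons(matrix, metadata, config)
    universe = sorted(set(matrix.gene_ids) & library.all_genes()) or sorted(
        matrix.gene_ids
    )
    target_terms = [
        t for t in library.term_names
        if t not in set(config.blacklist)
        and target_selector(t, library.term_meta.get(t))
    ]
    if not target_terms:
        raise ValueError("target selector matches no library terms")

    rank_rows: list[dict] = []
    curve_acc: dict[str, tuple[list[BridgeCurve], list[str]]] = {
        m: ([], []) for m in config.methods
    }
    for comp in comparisons:
        for method in config.methods:
            try:
                sig = compute_signature(
                    method, matrix, comp.treatment, comp.control, config.params
                )
            except ValueError as exc:
                raise ValueError(f"batch {comp.batch_id!r}, method {method!r}: {exc}")
            gene_sets = top_genes(sig, config.n_top)
            for direction in DIRECTIONS:
                query = gene_sets.by_direction(direction)
                if not query:
                    continue
                results = fisher_enrich(query, library, universe)
                for term, rank in term_ranks(
                    results,
                    target_selector,
                    library=library,
                    species=config.species,
                    blacklist=config.blacklist,
                ):
                    rank_rows.append(
                        {
                            "method": method,
                            "direction": direction,
                            "term": term,
                            "batch": comp.batch_id,
                            "rank": rank,
                        }
                    )
            ranked = rank_genes(sig)
            for term in target_terms:
                term_genes = library.gene_set(term) & set(ranked)
                if not term_genes:
                    continue
                curves, terms = curve_acc[method]
                curves.append(bridge_curve(ranked, term_genes))
                terms.append(term)

    # size-matched random baseline over the enrichment universe
    rng_seed = config.seed
    for direction, size in (
        ("up", config.n_top),
        ("down", config.n_top),
        ("combined", 2 * config.n_top),
    ):
        size = min(size, len(universe))
        ranks = random_baseline(
            universe,
            size,
            library,
            target_selector,
            n_draws=config.n_random_draws,
            seed=rng_seed,
            species=config.species,
            blacklist=config.blacklist,
        )
        rng_seed += 1
        for r in ranks:
            rank_rows.append(
                {
                    "method": "random",
                    "direction": direction,
                    "term": "*",
                    "batch": "*",
                    "rank": r,
                }
            )

    curves_out: dict[str, BridgeCurve] = {}
    curve_frames = []
    for method, (curves, terms) in curve_acc.items():
        if not curves:
            continue
        # batches-then-terms: average the per-term curves over batches first
        if config.batches_then_terms:
            per_term = []
            for term in dict.fromkeys(terms):
                sub = [c for c, t in zip(curves, terms) if t == term]
                per_term.append(average_curves(sub))
            avg = average_curves(per_term)
        else:
            avg = average_curves(curves)
        curves_out[method] = avg
        curve_frames.append(
            pd.DataFrame({"method": method, "x": avg.x, "y": avg.y})
        )
    rank_table = pd.DataFrame(
        rank_rows, columns=["method", "direction", "term", "batch", "rank"]
    )
    curve_table = (
        pd.concat(curve_frames, ignore_index=True)
        if curve_frames
        else pd.DataFrame(columns=["method", "x", "y"])
    )
    return BenchmarkReport(
        rank_table=rank_table, curve_table=curve_table, curves=curves_out, config=config
    )


def summarize(report: BenchmarkReport) -> pd.DataFrame:
    """Summary table: rank statistics per (method, direction) plus leading edge.

    Rows are sorted by mean rank ascending (best method first); the
    leading-edge columns give the mean bridge deviation over the top 1%
    and 2% of ranks for each method. Output is deterministic.
    """
    if report.rank_table.empty:
        raise ValueError("empty report")
    grouped = report.rank_table.groupby(["method", "direction"], sort=True)["rank"]
    summary = grouped.agg(
        mean_rank="mean",
        median_rank="median",
        q1_rank=lambda s: s.quantile(0.25),
        q3_rank=lambda s: s.quantile(0.75),
        n_obs="count",
    ).reset_index()
    le1 = {
        m: c.leading_edge_area(report.config.x_max) for m, c in report.curves.items()
    }
    le2 = {
        m: c.leading_edge_area(report.config.x_max_alt)
        for m, c in report.curves.items()
    }
    summary["leading_edge"] = summary["method"].map(le1)
    summary["leading_edge_alt"] = summary["method"].map(le2)
    summary = summary.sort_values(
        ["mean_rank", "method", "direction"], kind="stable"
    ).reset_index(drop=True)
    return summary


def write_report(report: BenchmarkReport, out_dir) -> dict[str, str]:
    """Write rank_table.tsv, curves.tsv and summary.tsv with stable formatting."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    rank_path = out / "rank_table.tsv"
    report.rank_table.to_csv(rank_path, sep="\t", index=False)
    paths["rank_table"] = str(rank_path)
    curve_path = out / "curves.tsv"
    report.curve_table.to_csv(curve_path, sep="\t", index=False, float_format="%.10g")
    paths["curves"] = str(curve_path)
    summary_path = out / "summary.tsv"
    summarize(report).to_csv(summary_path, sep="\t", index=False, float_format="%.10g")
    paths["summary"] = str(summary_path)
    return paths
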