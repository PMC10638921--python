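"""Local gene-set enrichment by Fisher's exact (hypergeometric) test.

Replaces remote enrichment-service calls with an in-process equivalent:
given a query gene set and a library, each term is scored by the one-sided
hypergeometric tail probability of its overlap with the query inside a
finite gene universe, then terms are ranked by p ascending (odds-ratio and
term-name tie-breaks keep the order total).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from sigbench.data_io import GeneSetLibrary, normalize_gene
from sigbench.signatures import Signature


@dataclass
class DirectionalGeneSets:
    """Top up-/down-regulated gene sets extracted from a signature."""

    up: list[str]
    down: list[str]
    n_requested: int

    @property
    def combined(self) -> list[str]:
        seen = dict.fromkeys(self.up)
        for g in self.down:
            seen.setdefault(g, None)
        return list(seen)

    def by_direction(self, direction: str) -> list[str]:
        if direction == "up":
            return self.up
        if direction == "down":
            return self.down
        if direction == "combined":
            return self.combined
        raise ValueError(f"unknown direction {direction!r}")


@dataclass
class EnrichmentResult:
    term_name: str
    overlap_k: int
    term_size_K: int
    query_size_n: int
    universe_N: int
    p_value: float
    odds_ratio: float
    rank: int


def top_genes(signature: Signature, n: int) -> DirectionalGeneSets:
    """Extract the top-n up and top-n down genes of a signature.

    Genes are taken in ranking order (p ascending or |coefficient|
    descending per the signature's declared key); the up set holds the
    best-ranked genes with positive coefficient, the down set the
    best-ranked with negative coefficient. Zero-coefficient genes belong to
    neither direction. Either set may be shorter than n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ordered = signature.ordered_genes()
    coef = signature.coefficient
    up: list[str] = []
    down: list[str] = []
    for g in ordered:
        c = coef[g]
        if c > 0 and len(up) < n:
            up.append(g)
        elif c < 0 and len(down) < n:
            down.append(g)
        if len(up) >= n and len(down) >= n:
            break
    if not up or not down:
        warnings.warn(
            f"degenerate signature: {len(up)} up / {len(down)} down genes",
            stacklevel=2,
        )
    return DirectionalGeneSets(up=up, down=down, n_requested=n)


def _odds_ratio(k: int, K: int, n: int, N: int) -> float:
    # 2x2 table: [k, K-k; n-k, N-K-n+k], Haldane 0.5 correction on zero cells
    a, b, c, d = k, K - k, n - k, N - K - n + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def fisher_enrich(
    query: Iterable[str],
    library: GeneSetLibrary,
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Rank library terms by one-sided Fisher-exact enrichment in a query.

    For each term, with N the universe size, K the term genes in the
    universe, n the query size and k the query/term overlap, the p-value is
    the upper hypergeometric tail P(X >= k). Results are sorted by p
    ascending, ties by odds ratio descending then term name.
    """
    universe_set = {normalize_gene(g) for g in universe}
    if not universe_set:
        raise ValueError("empty universe")
    query_set = {normalize_gene(g) for g in query} & universe_set
    N = len(universe_set)
    n = len(query_set)
    rows: list[EnrichmentResult] = []
    for term in library.term_names:
        term_genes = library.gene_set(term) & universe_set
        K = len(term_genes)
        k = len(query_set & term_genes)
        # P(X >= k) for X ~ Hypergeom(N, K, n); k = 0 gives the full tail (p = 1)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K > 0 else 1.0
        p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
        rows.append(
            EnrichmentResult(
                term_name=term,
                overlap_k=k,
                term_size_K=K,
                query_size_n=n,
                universe_N=N,
                p_value=p,
                odds_ratio=_odds_ratio(k, K, n, N),
                rank=0,
            )
        )
    rows.sort(key=lambda r: (r.p_value, -r.odds_ratio, r.term_name))
    for i, r in enumerate(rows, start=1):
        r.rank = i
    return rows


TermSelector = Callable[[str, tuple[str, str, str] | None], bool]


def selector_for_factor(
    factor: str,
    species: Sequence[str] | None = ("human", "mouse"),
) -> TermSelector:
    """Build a selector matching terms annotated with a given TF symbol.

    Falls back to a prefix match on the term name when no metadata is
    attached. An optional species whitelist mirrors the convention of
    keeping only human and mouse ChIP-seq terms.
    """
    factor = normalize_gene(factor)
    species_set = {s.lower() for s in species} if species is not None else None

    def _sel(term_name: str, meta: tuple[str, str, str] | None) -> bool:
        if meta is not None:
            f, sp, _ = meta
            if f != factor:
                return False
            return species_set is None or sp in species_set
        return normalize_gene(term_name.split()[0]) == factor

    return _sel


def term_ranks(
    results: Sequence[EnrichmentResult],
    selector: TermSelector,
    library: GeneSetLibrary | None = None,
    species: Sequence[str] | None = None,
    blacklist: Iterable[str] = (),
) -> list[tuple[str, int]]:
    """1-based enrichment ranks of the terms matched by a selector.

    A species filter and an explicit term blacklist are applied *before*
    ranks are recomputed, so the returned ranks refer to the filtered term
    list only (ranks are a permutation of 1..#surviving terms).
    """
    blacklist_set = set(blacklist)
    meta = library.term_meta if library is not None else {}
    species_set = {s.lower() for s in species} if species is not None else None

    surviving = []
    for r in sorted(results, key=lambda r: r.rank):
        if r.term_name in blacklist_set:
            continue
        if species_set is not None:
            m = meta.get(r.term_name)
            if m is not None and m[1] not in species_set:
                continue
        surviving.append(r)
    out: list[tuple[str, int]] = []
    for new_rank, r in enumerate(surviving, start=1):
        if selector(r.term_name, meta.get(r.term_name)):
            out.append((r.term_name, new_rank))
    if not out:
        warnings.warn("selector matched no terms", stacklevel=2)
    return out


def random_baseline(
    universe: Sequence[str],
    set_size: int,
    library: GeneSetLibrary,
    selector: TermSelector,
    n_draws: int = 100,
    seed: int = 0,
    species: Sequence[str] | None = None,
    blacklist: Iterable[str] = (),
) -> list[int]:
    """Null rank distribution from uniformly drawn query gene sets.

    Draws ``n_draws`` query sets of ``set_size`` genes without replacement
    from the universe, runs the same enrichment + rank extraction as a real
    query, and pools the selector-matched ranks. Fully reproducible given
    the seed.
    """
    universe = list(dict.fromkeys(normalize_gene(g) for g in universe))
    if set_size > len(universe):
        raise ValueError("set_size exceeds universe size")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    ranks: list[int] = []
    for _ in range(n_draws):
        draw = rng.choice(len(universe), size=set_size, replace=False)
        query = [universe[i] for i in draw]
        results = fisher_enrich(query, library, universe)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pairs = term_ranks(
                results, selector, library=library, species=species, blacklist=blacklist
            )
        ranks.extend(rank for _, rank in pairs)
    return ranks
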