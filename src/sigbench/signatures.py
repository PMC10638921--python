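"""Per-gene differential-expression signature methods for two-group comparisons.

Implemented methods:

* ``logfc`` — difference of group means on log2 scale (counts are
  log-transformed with a pseudocount; signed profiles are used directly).
* ``welch_t`` — per-gene two-sample t statistic, unequal variances by
  default, with a two-sided p-value.
* ``ranksum`` — Wilcoxon rank-sum z statistic with midranks for ties;
  exact two-sided p for small tie-free groups, normal approximation with
  tie correction otherwise.
* ``chdir`` — the characteristic direction: the shrinkage-regularised
  linear-discriminant direction between the two groups, unit-normalised,
  solved in the sample-spanned subspace so it is cheap at genes >> samples.
* ``modz`` — moderated z: replicate signatures averaged with weights from
  pairwise Spearman correlations.

External methods (e.g. wrappers around DESeq2 or limma-voom) can be
registered at run time through :func:`register_external_method`.

A signature carries a ``ranking_key`` declaring how its genes are ordered
for downstream enrichment: significance-based methods rank by p-value
ascending, coefficient-only methods by absolute coefficient descending.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from sigbench.data_io import GeneExpressionMatrix

RANKING_KEYS = ("p_value_asc", "abs_coefficient_desc")


@dataclass
class MethodParams:
    """Tunable parameters shared across signature methods.

    pseudocount
        Added before the log2 transform of count data (default 1).
    chdir_gamma
        Shrinkage weight for the characteristic direction's pooled
        covariance: ``gamma * S_pooled + (1 - gamma) * (tr(S)/p) * I``.
    equal_var
        Use the pooled-variance t-test instead of Welch's.
    modz_min_weight
        Floor on raw replicate weights before normalisation.
    min_count, min_total_count
        Low-expression filter thresholds (edgeR-style convention).
    cpm_normalize
        Scale counts to counts-per-million before the log-fold-change
        transform (off by default; the methods are otherwise
        library-size-agnostic).
    """

    pseudocount: float = 1.0
    chdir_gamma: float = 0.5
    equal_var: bool = False
    modz_min_weight: float = 0.01
    min_count: float = 10.0
    min_total_count: float = 15.0
    cpm_normalize: bool = False

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if not 0.0 <= self.chdir_gamma <= 1.0:
            raise ValueError("chdir_gamma must be in [0, 1]")
        if self.modz_min_weight < 0:
            raise ValueError("modz_min_weight must be >= 0")


@dataclass
class Signature:
    """Per-gene differential-expression effect for one comparison.

    ``coefficient`` is the signed effect (log2FC, t, z, CD component or
    aggregated z); positive means higher in treatment. ``p_value`` is
    present for significance-based methods. ``ranking_key`` declares the
    order used when extracting top genes.
    """

    coefficient: pd.Series  # indexed by gene id
    method: str
    ranking_key: str
    p_value: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.ranking_key not in RANKING_KEYS:
            raise ValueError(f"unknown ranking_key: {self.ranking_key!r}")
        if self.coefficient.index.duplicated().any():
            raise ValueError("duplicate gene ids in signature")
        if self.ranking_key == "p_value_asc":
            if self.p_value is None:
                raise ValueError("p_value_asc ranking requires p-values")
            if not self.coefficient.index.equals(self.p_value.index):
                raise ValueError("coefficient and p_value gene ids differ")
            pv = self.p_value.to_numpy()
            if np.any(~np.isfinite(pv)) or np.any(pv <= 0) or np.any(pv > 1):
                raise ValueError("p-values must be finite and in (0, 1]")
        if not np.all(np.isfinite(self.coefficient.to_numpy())):
            raise ValueError("coefficients must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.coefficient.index)

    def ordered_genes(self) -> list[str]:
        """Genes from most to least significant under the ranking key.

        Ties break by |coefficient| descending then gene id ascending, so
        the order is total and deterministic.
        """
        df = pd.DataFrame(
            {
                "gene": self.coefficient.index,
                "abscoef": self.coefficient.abs().to_numpy(),
            }
        )
        if self.ranking_key == "p_value_asc":
            df["p"] = self.p_value.to_numpy()
            df = df.sort_values(
                ["p", "abscoef", "gene"], ascending=[True, False, True], kind="stable"
            )
        else:
            df = df.sort_values(
                ["abscoef", "gene"], ascending=[False, True], kind="stable"
            )
        return df["gene"].tolist()


# ---------------------------------------------------------------------------
# Low-expression filter
# ---------------------------------------------------------------------------


def filter_low_expression(
    matrix: GeneExpressionMatrix,
    group_sizes: tuple[int, int],
    params: MethodParams | None = None,
) -> GeneExpressionMatrix:
    """Drop weakly expressed genes from a counts matrix.

    A gene is kept iff its count is >= ``min_count`` in at least k samples,
    where k is the smaller group size, AND its total count across all
    samples is >= ``min_total_count``. This restates the edgeR
    ``filterByExpr`` convention with explicit thresholds; gene order is
    preserved.
    """
    params = params or MethodParams()
    if matrix.value_kind != "counts":
        raise ValueError("low-expression filtering applies to counts matrices")
    k = min(group_sizes)
    if k < 1:
        raise ValueError("both group sizes must be >= 1")
    arr = matrix.values.to_numpy()
    keep = ((arr >= params.min_count).sum(axis=1) >= k) & (
        arr.sum(axis=1) >= params.min_total_count
    )
    if not keep.any():
        raise ValueError("all genes removed by the low-expression filter")
    return GeneExpressionMatrix(values=matrix.values.loc[keep], value_kind="counts")


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _group_arrays(
    matrix: GeneExpressionMatrix,
    treatment: Sequence[str],
    control: Sequence[str],
    min_per_group: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    if len(treatment) < min_per_group or len(control) < min_per_group:
        raise ValueError(
            f"need >= {min_per_group} samples per group, got "
            f"{len(treatment)} treatment / {len(control)} control"
        )
    xt = matrix.values[list(treatment)].to_numpy(dtype=float)
    xc = matrix.values[list(control)].to_numpy(dtype=float)
    return xt, xc


def _log_counts(arr: np.ndarray, params: MethodParams) -> np.ndarray:
    if params.cpm_normalize:
        libsize = arr.sum(axis=0, keepdims=True)
        libsize = np.where(libsize == 0, 1.0, libsize)
        arr = arr / libsize * 1e6
    return np.log2(arr + params.pseudocount)


# ---------------------------------------------------------------------------
# Methods
# ---------------------------------------------------------------------------


def signature_logfc(
    matrix: GeneExpressionMatrix,
    treatment: Sequence[str],
    control: Sequence[str],
    params: MethodParams | None = None,
) -> Signature:
    """Log2 fold change: difference of group means on log2 scale."""
    params = params or MethodParams()
    xt, xc = _group_arrays(matrix, treatment, control)
    if matrix.value_kind == "counts":
        xt = _log_counts(xt, params)
        xc = _log_counts(xc, params)
    coef = xt.mean(axis=1) - xc.mean(axis=1)
    return Signature(
        coefficient=pd.Series(coef, index=matrix.values.index),
        method="logfc",
        ranking_key="abs_coefficient_desc",
    )


def signature_welch_t(
    matrix: GeneExpressionMatrix,
    treatment: Sequence[str],
    control: Sequence[str],
    params: MethodParams | None = None,
) -> Signature:
    """Two-sample t-test per gene (Welch's unequal-variance by default).

    Genes with zero variance in both groups get coefficient 0 and p 1 so
    the downstream ranking stays total.
    """
    params = params or MethodParams()
    xt, xc = _group_arrays(matrix, treatment, control, min_per_group=2)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # zero-variance genes trip scipy's precision-loss warning; they are
        # handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(xt, xc, axis=1, equal_var=params.equal_var)
    zero_var = (xt.var(axis=1) == 0) & (xc.var(axis=1) == 0)
    t = np.where(zero_var | ~np.isfinite(t), 0.0, t)
    p = np.where(zero_var | ~np.isfinite(p), 1.0, p)
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    idx = matrix.values.index
    return Signature(
        coefficient=pd.Series(t, index=idx),
        p_value=pd.Series(p, index=idx),
        method="welch_t",
        ranking_key="p_value_asc",
    )


_EXACT_RANKSUM_MAX_N = 10


def _ranksum_gene(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)  # midranks for ties
    w = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    # tie-corrected variance of the rank sum
    n = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return 0.0, 1.0
    z = (w - mu) / np.sqrt(var)
    has_ties = len(counts) < n
    if not has_ties and max(n1, n2) <= _EXACT_RANKSUM_MAX_N:
        p = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
    else:
        p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def signature_ranksum(
    matrix: GeneExpressionMatrix,
    treatment: Sequence[str],
    control: Sequence[str],
    params: MethodParams | None = None,
) -> Signature:
    """Wilcoxon rank-sum test per gene.

    The coefficient is the z statistic of the treatment rank sum (positive
    = higher in treatment). For tie-free comparisons with both groups of
    size <= 10 the two-sided p-value is exact (full permutation null);
    larger or tied comparisons use the tie-corrected normal approximation.
    """
    xt, xc = _group_arrays(matrix, treatment, control, min_per_group=2)
    out = np.array([_ranksum_gene(xt[i], xc[i]) for i in range(xt.shape[0])])
    z, p = out[:, 0], out[:, 1]
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    idx = matrix.values.index
    return Signature(
        coefficient=pd.Series(z, index=idx),
        p_value=pd.Series(p, index=idx),
        method="ranksum",
        ranking_key="p_value_asc",
    )


def _chdir_direction(
    xt: np.ndarray, xc: np.ndarray, gamma: float
) -> np.ndarray:
    """Solve (gamma*S_pooled + lambda*I) b = delta in the sample subspace.

    ``S_pooled`` is the pooled within-group covariance, ``lambda`` the
    trace-scaled identity shrinkage target ``(1-gamma)*tr(S)/p``. The
    Woodbury identity turns the p x p solve into an n x n solve, where n
    is the total sample count.
    """
    p = xt.shape[0]
    n1, n2 = xt.shape[1], xc.shape[1]
    n = n1 + n2
    mu_t = xt.mean(axis=1)
    mu_c = xc.mean(axis=1)
    delta = mu_t - mu_c
    z = np.hstack([xt - mu_t[:, None], xc - mu_c[:, None]])  # p x n, centered
    dof = max(n - 2, 1)
    trace = float((z**2).sum()) / dof
    if trace == 0.0 and not np.any(delta):
        raise ValueError("degenerate comparison: identical group means and zero covariance")
    lam = (1.0 - gamma) * trace / p
    c = gamma / dof
    if lam <= 0.0 or c == 0.0:
        if lam > 0.0:
            b = delta / lam
        else:
            # no usable curvature: fall back to the mean-difference direction
            b = delta.copy()
    else:
        # Woodbury: (c*Z*Z' + lam*I)^-1 d = (d - Z (lam/c I + Z'Z)^-1 Z'd) / lam
        m = z.T @ z + (lam / c) * np.eye(n)
        b = (delta - z @ np.linalg.solve(m, z.T @ delta)) / lam
    norm = np.linalg.norm(b)
    if norm == 0.0:
        raise ValueError("degenerate comparison: zero characteristic direction")
    return b / norm


def signature_characteristic_direction(
    matrix: GeneExpressionMatrix,
    treatment: Sequence[str],
    control: Sequence[str],
    params: MethodParams | None = None,
) -> Signature:
    """Characteristic direction: shrinkage-LDA direction between groups.

    The coefficient vector is proportional to ``S_gamma^-1 (mu_t - mu_c)``
    with ``S_gamma = gamma*S_pooled + (1-gamma)*(tr(S_pooled)/p)*I`` and is
    normalised to unit Euclidean norm. Positive components indicate genes
    higher in treatment.
    """
    params = params or MethodParams()
    xt, xc = _group_arrays(matrix, treatment, control, min_per_group=2)
    b = _chdir_direction(xt, xc, params.chdir_gamma)
    return Signature(
        coefficient=pd.Series(b, index=matrix.values.index),
        method="chdir",
        ranking_key="abs_coefficient_desc",
    )


def signature_modz(
    replicates: Sequence[Signature],
    params: MethodParams | None = None,
) -> Signature:
    """Moderated-z aggregation of replicate signatures.

    Each replicate's raw weight is its average Spearman correlation with
    the other replicates, floored at ``modz_min_weight``; weights are
    normalised to sum 1 and the output is the weighted sum of replicate
    coefficient vectors over their common gene universe.
    """
    params = params or MethodParams()
    if not replicates:
        raise ValueError("need at least one replicate signature")
    index = replicates[0].coefficient.index
    for sig in replicates[1:]:
        if not sig.coefficient.index.equals(index):
            raise ValueError("replicate signatures have mismatched gene universes")
    m = len(replicates)
    mat = np.column_stack([s.coefficient.to_numpy() for s in replicates])
    if m == 1:
        weights = np.array([1.0])
    else:
        rho = stats.spearmanr(mat).statistic
        if m == 2:  # scipy returns a scalar for two columns
            rho = np.array([[1.0, rho], [rho, 1.0]])
        rho = np.nan_to_num(rho, nan=0.0)
        np.fill_diagonal(rho, 1.0)
        raw = (rho.sum(axis=1) - 1.0) / (m - 1)  # exclude self-correlation 1
        raw = np.maximum(raw, params.modz_min_weight)
        weights = raw / raw.sum()
    coef = mat @ weights
    return Signature(
        coefficient=pd.Series(coef, index=index),
        method="modz",
        ranking_key="abs_coefficient_desc",
    )


# ---------------------------------------------------------------------------
# Method registry
# ---------------------------------------------------------------------------

SignatureFn = Callable[
    [GeneExpressionMatrix, Sequence[str], Sequence[str], MethodParams], Signature
]

_BUILTIN_METHODS: dict[str, SignatureFn] = {
    "logfc": lambda m, t, c, p: signature_logfc(m, t, c, p),
    "welch_t": lambda m, t, c, p: signature_welch_t(m, t, c, p),
    "ranksum": lambda m, t, c, p: signature_ranksum(m, t, c, p),
    "chdir": lambda m, t, c, p: signature_characteristic_direction(m, t, c, p),
}

_EXTERNAL_METHODS: dict[str, tuple[SignatureFn, bool]] = {}


def register_external_method(
    name: str, fn: SignatureFn, counts_only: bool = False
) -> str:
    """Register an external signature adapter under ``external:<name>``.

    ``counts_only`` adapters are refused on signed-log input (a count model
    such as DESeq2 cannot consume signed expression values). The adapter's
    output is validated against the Signature contract at call time.
    """
    handle = f"external:{name}"
    _EXTERNAL_METHODS[handle] = (fn, counts_only)
    return handle


def available_methods() -> list[str]:
    return list(_BUILTIN_METHODS) + list(_EXTERNAL_METHODS)


def compute_signature(
    method: str,
    matrix: GeneExpressionMatrix,
    treatment: Sequence[str],
    control: Sequence[str],
    params: MethodParams | None = None,
) -> Signature:
    """Dispatch a signature computation by method name."""
    params = params or MethodParams()
    if method in _BUILTIN_METHODS:
        return _BUILTIN_METHODS[method](matrix, treatment, control, params)
    if method in _EXTERNAL_METHODS:
        fn, counts_only = _EXTERNAL_METHODS[method]
        if counts_only and matrix.value_kind == "signed_log":
            raise ValueError(
                f"method {method!r} requires count data and cannot consume "
                "signed log-scale values"
            )
        sig = fn(matrix, treatment, control, params)
        if not isinstance(sig, Signature):
            raise ValueError(f"external method {method!r} returned a non-Signature")
        if set(sig.gene_ids) != set(matrix.gene_ids):
            raise ValueError(
                f"external method {method!r} returned a signature over a "
                "different gene universe"
            )
        return sig
    raise KeyError(
        f"unknown method {method!r}; available: {', '.join(available_methods())}"
    )
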