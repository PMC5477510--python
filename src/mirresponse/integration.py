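"""Responder-stratified miRNA-mRNA correlation and the random-gene null.

Given normalized miRNA and gene expression matrices over matched samples,
the analysis asks what fraction of a pathway gene panel is significantly
correlated (Pearson, two-sided, unadjusted p < alpha) with at least one of
the query miRNAs, separately within responders and nonresponders. Because
the criterion is ">= 1 of M miRNAs at per-pair alpha", its baseline under
independence is 1 - (1 - alpha)^M (about 18.5% for M = 4 at alpha = 0.05),
so raw fractions are only interpretable against an empirical null: the
panel is replaced by random draws of ``set_size`` genes from the measured
universe (panel excluded) and the same criterion applied, yielding a
permutation distribution of fractions and an empirical enrichment p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .errors import InvalidConfigError
from .targets import normalize_gene_id

__all__ = [
    "CorrelationReport",
    "PermutationNullReport",
    "EnrichmentComparison",
    "correlate_panel",
    "permutation_null",
    "compare_enrichment",
]

MIN_SAMPLES = 4


def _pearson_matrix(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs Pearson r and two-sided p between rows of X and rows of Y.

    Returns (r, p, x_flat, y_flat) where the flat masks flag zero-variance
    rows; pairs involving a flat series get r = nan and p = 1 (recorded as
    non-significant, never dropped silently).
    """
    n = X.shape[1]
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    xs = np.sqrt((Xc**2).sum(axis=1))
    ys = np.sqrt((Yc**2).sum(axis=1))
    x_flat = xs == 0
    y_flat = ys == 0
    xs_safe = np.where(x_flat, 1.0, xs)
    ys_safe = np.where(y_flat, 1.0, ys)
    r = (Xc / xs_safe[:, None]) @ (Yc / ys_safe[:, None]).T
    r = np.clip(r, -1.0, 1.0)
    r[x_flat, :] = np.nan
    r[:, y_flat] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * t_dist.sf(np.abs(tstat), df=n - 2)
    p = np.where(np.isnan(r), 1.0, p)
    p = np.where(np.isinf(tstat), 0.0, p)
    return r, p, x_flat, y_flat


@dataclass
class CorrelationReport:
    """Pair-level correlations and per-stratum correlated-gene fractions.

    pairs
        DataFrame with columns ``stratum``, ``gene``, ``mirna``, ``r``,
        ``p_value``, ``zero_variance``.
    fractions
        stratum -> fraction of panel genes significant with >= 1 query
        miRNA at per-pair alpha.
    correlated_genes
        stratum -> frozenset of panel genes meeting the criterion.
    """

    pairs: pd.DataFrame
    fractions: dict[str, float]
    correlated_genes: dict[str, frozenset[str]]
    alpha: float
    panel: tuple[str, ...]
    query_mirnas: tuple[str, ...]


def _gene_significance(
    mirna_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    samples: Sequence[str],
    alpha: float,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Pair table and per-gene 'correlated with >= 1 miRNA' flags."""
    cols = list(samples)
    if len(cols) < MIN_SAMPLES:
        raise InvalidConfigError(
            f"need >= {MIN_SAMPLES} samples per stratum, got {len(cols)}"
        )
    X = gene_expr[cols].to_numpy(dtype=float)
    Y = mirna_expr[cols].to_numpy(dtype=float)
    r, p, g_flat, m_flat = _pearson_matrix(X, Y)
    sig_any = (p < alpha).any(axis=1)
    table = pd.DataFrame(
        {
            "gene": np.repeat(gene_expr.index.to_numpy(), len(mirna_expr.index)),
            "mirna": np.tile(mirna_expr.index.to_numpy(), len(gene_expr.index)),
            "r": r.ravel(),
            "p_value": p.ravel(),
            "zero_variance": (
                np.repeat(g_flat, len(mirna_expr.index))
                | np.tile(m_flat, len(gene_expr.index))
            ),
        }
    )
    return table, sig_any


def correlate_panel(
    mirna_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    panel: Iterable[str],
    strata: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
) -> CorrelationReport:
    """Pearson correlation of each panel gene with each query miRNA, per stratum.

    ``mirna_expr`` (query miRNAs x samples) and ``gene_expr`` (genes x
    samples) must share the sample columns named by ``strata`` (a mapping
    like ``{"responder": [...sample ids...], "nonresponder": [...]}``; at
    least 4 samples per stratum). A gene counts as *correlated* in a
    stratum when any of its query-miRNA p-values is below ``alpha``
    (unadjusted, per standard practice for this screen; the permutation
    null carries the multiplicity burden). Zero-variance series yield
    undefined r, flagged and counted as non-significant.
    """
    if not (0 < alpha < 1):
        raise InvalidConfigError("alpha must lie in (0, 1)")
    panel_keys = [normalize_gene_id(g) for g in panel]
    if not panel_keys:
        raise InvalidConfigError("empty gene panel")
    index_map = {normalize_gene_id(g): g for g in gene_expr.index}
    missing = [g for g in panel_keys if g not in index_map]
    if missing:
        raise InvalidConfigError(f"panel genes absent from expression matrix: {missing}")
    rows = [index_map[g] for g in panel_keys]
    sub_genes = gene_expr.loc[rows]

    tables = []
    fractions: dict[str, float] = {}
    correlated: dict[str, frozenset[str]] = {}
    for stratum, samples in strata.items():
        table, sig_any = _gene_significance(mirna_expr, sub_genes, samples, alpha)
        table.insert(0, "stratum", stratum)
        tables.append(table)
        fractions[stratum] = float(sig_any.mean())
        correlated[stratum] = frozenset(
            str(g) for g, s in zip(sub_genes.index, sig_any) if s
        )
    return CorrelationReport(
        pairs=pd.concat(tables, ignore_index=True),
        fractions=fractions,
        correlated_genes=correlated,
        alpha=alpha,
        panel=tuple(str(g) for g in sub_genes.index),
        query_mirnas=tuple(str(m) for m in mirna_expr.index),
    )


@dataclass
class PermutationNullReport:
    """Null distribution of the correlated-gene fraction over random panels."""

    set_size: int
    n_permutations: int
    fractions: np.ndarray
    seed: int
    alpha: float
    level: str = "gene"

    @property
    def mean_fraction(self) -> float:
        return float(np.mean(self.fractions))


def permutation_null(
    mirna_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    samples: Sequence[str],
    panel: Iterable[str] = (),
    set_size: int = 50,
    n_permutations: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    level: str = "gene",
) -> PermutationNullReport:
    """Correlated-gene fraction for random gene sets of size ``set_size``.

    Each permutation draws ``set_size`` genes uniformly without replacement
    from the measured universe minus the panel (keeping the null disjoint
    from the alternative), applies the same correlated-gene criterion as
    :func:`correlate_panel` on the given sample columns, and records the
    fraction. ``level="pair"`` counts significant (gene, miRNA) pairs
    instead of genes with >= 1 significant miRNA. Deterministic under
    ``seed``.
    """
    if level not in ("gene", "pair"):
        raise InvalidConfigError("level must be 'gene' or 'pair'")
    if set_size < 1 or n_permutations < 1:
        raise InvalidConfigError("set_size and n_permutations must be >= 1")
    panel_keys = {normalize_gene_id(g) for g in panel}
    universe = [g for g in gene_expr.index if normalize_gene_id(g) not in panel_keys]
    if len(universe) < set_size:
        raise InvalidConfigError(
            f"universe ({len(universe)} genes after excluding the panel) "
            f"smaller than set_size={set_size}"
        )

    # the criterion is separable per gene: compute each universe gene's
    # significance once, then permutations only index into the flags
    sub = gene_expr.loc[universe]
    cols = list(samples)
    if len(cols) < MIN_SAMPLES:
        raise InvalidConfigError(
            f"need >= {MIN_SAMPLES} samples, got {len(cols)}"
        )
    X = sub[cols].to_numpy(dtype=float)
    Y = mirna_expr[cols].to_numpy(dtype=float)
    _, p, _, _ = _pearson_matrix(X, Y)
    if level == "gene":
        gene_stat = (p < alpha).any(axis=1).astype(float)
    else:
        gene_stat = (p < alpha).mean(axis=1)

    rng = np.random.default_rng(seed)
    fractions = np.empty(n_permutations)
    for b in range(n_permutations):
        idx = rng.choice(len(universe), size=set_size, replace=False)
        fractions[b] = gene_stat[idx].mean()
    return PermutationNullReport(
        set_size=set_size,
        n_permutations=n_permutations,
        fractions=fractions,
        seed=seed,
        alpha=alpha,
        level=level,
    )


@dataclass
class EnrichmentComparison:
    """Observed correlated-gene fraction against its permutation null."""

    observed_fraction: float
    null_mean_fraction: float
    empirical_p: float
    stratum: str


def compare_enrichment(
    observed: CorrelationReport,
    null: PermutationNullReport,
    stratum: str = "responder",
) -> EnrichmentComparison:
    """Empirical enrichment p-value of the panel fraction over the null.

    p = (#{null fractions >= observed} + 1) / (n_permutations + 1), so the
    smallest attainable value is 1 / (B + 1) and an observed fraction below
    every null draw yields p = 1.
    """
    if stratum not in observed.fractions:
        raise InvalidConfigError(f"no stratum {stratum!r} in the correlation report")
    obs = observed.fractions[stratum]
    b = int((null.fractions >= obs).sum())
    return EnrichmentComparison(
        observed_fraction=obs,
        null_mean_fraction=null.mean_fraction,
        empirical_p=(b + 1) / (null.n_permutations + 1),
        stratum=stratum,
    )
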