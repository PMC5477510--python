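"""Paired two-class differential expression for count data.

The test is a nonparametric, resampling-based paired comparison in the
spirit of SAM adapted to sequencing counts: library depths are equalized by
Poisson downsampling to the minimum depth, a Wilcoxon signed-rank score is
computed per miRNA over the within-subject (T8 - T0) differences, the score
is averaged over resamples, and two-sided significance comes from the
sign-flip permutation null (each subject's difference flipped independently,
which is the exact null for exchangeable paired data). P values are
Benjamini-Hochberg adjusted across miRNAs.

Because the sign flips act on subjects — not on miRNAs — the permutation
statistic factorizes: with ``t[i, j]`` the mean signed rank of pair j for
miRNA i, a flipped statistic is just ``sum_j eps_j * t[i, j]``. The null is
therefore computed by one matrix product, and for 2^n_pairs <= 4096 the
full enumeration replaces sampling, making small-n p-values exact.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import InsufficientPairsError, InvalidConfigError
from .smallrna import CountMatrix, Normalized, normalize

__all__ = ["DEConfig", "paired_rank_test", "fold_change", "bh_adjust"]

#: full sign-flip enumeration replaces sampling when 2**n_pairs is at most this
ENUMERATION_LIMIT = 4096

MIN_PAIRS = 4


@dataclass(frozen=True)
class DEConfig:
    """Parameters of the paired differential-expression test.

    n_resamples
        Poisson downsampling repetitions averaged into the statistic.
    n_permutations
        Sign-flip draws for the null when full enumeration is infeasible.
    fdr_threshold
        BH-adjusted significance level used by callers (default 5%).
    pseudocount
        Stabilizer added to both means in the fold-change ratio.
    """

    n_resamples: int = 20
    n_permutations: int = 1000
    fdr_threshold: float = 0.05
    pseudocount: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_resamples < 1 or self.n_permutations < 1:
            raise InvalidConfigError("resample/permutation counts must be >= 1")
        if not (0 < self.fdr_threshold < 1):
            raise InvalidConfigError("fdr_threshold must lie in (0, 1)")
        if not (self.pseudocount > 0 and math.isfinite(self.pseudocount)):
            raise InvalidConfigError("pseudocount must be positive and finite")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    q(i) = min over j >= i (in sorted order) of p(j) * m / j, capped at 1;
    returned in the input order. Order-preserving and invariant under input
    permutation (up to reordering).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise InvalidConfigError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InvalidConfigError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _signed_ranks(D: np.ndarray) -> np.ndarray:
    """Row-wise Wilcoxon signed ranks: zeros dropped, ties mid-ranked.

    D is (n_features, n_pairs); returns the same shape with each nonzero
    entry replaced by sign(d) * rank(|d|) among that row's nonzero entries,
    and zeros contributing 0.
    """
    A = np.abs(D).astype(float)
    A[A == 0] = np.nan
    ranks = rankdata(A, axis=1, nan_policy="omit")
    ranks = np.nan_to_num(ranks, nan=0.0)
    return np.sign(D) * ranks


def _sign_matrix(n_pairs: int, cfg: DEConfig, rng: np.random.Generator):
    """(B, n_pairs) matrix of +/-1 flips; full enumeration when feasible."""
    if 2**n_pairs <= ENUMERATION_LIMIT:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n_pairs)))
        return signs, True
    signs = rng.integers(0, 2, size=(cfg.n_permutations, n_pairs)) * 2.0 - 1.0
    return signs, False


def paired_rank_test(m: CountMatrix, cfg: DEConfig = DEConfig()) -> pd.DataFrame:
    """Paired two-class test of T8 vs T0 within one stratum.

    Requires every subject in ``m`` to have exactly one T0 and one T8
    column, and at least 4 pairs. Returns a DataFrame with columns
    ``mirna``, ``fold_change``, ``statistic``, ``p_value``, ``adjusted_p``,
    sorted by adjusted p then by \\|log2 FC\\| (descending), then by ID.

    The statistic is the mean (over ``n_resamples`` Poisson downsamplings to
    the minimum library depth) of the signed-rank sum of the per-subject
    T8 - T0 differences; negative values mean downregulation after
    treatment. P values are two-sided sign-flip permutation probabilities —
    exact via full enumeration when 2^pairs <= 4096, otherwise sampled with
    add-one smoothing p = (b + 1) / (B + 1).
    """
    subjects, t0_cols, t8_cols = m.pairs()
    n_pairs = len(subjects)
    if n_pairs < MIN_PAIRS:
        raise InsufficientPairsError(
            f"need at least {MIN_PAIRS} subject pairs, got {n_pairs}"
        )

    C = m.counts.to_numpy(dtype=float)
    depths = C.sum(axis=0)
    scale = depths.min() / depths  # Poisson thinning factors, <= 1
    col_idx = {c: i for i, c in enumerate(m.counts.columns)}
    i0 = [col_idx[c] for c in t0_cols]
    i8 = [col_idx[c] for c in t8_cols]

    rng = np.random.default_rng(cfg.seed)
    at_min = scale == 1.0  # already at the minimum depth: no thinning needed
    T = np.zeros((C.shape[0], n_pairs))
    for _ in range(cfg.n_resamples):
        down = np.where(at_min[None, :], C, rng.poisson(C * scale[None, :]))
        D = down[:, i8] - down[:, i0]
        T += _signed_ranks(D)
    T /= cfg.n_resamples

    stat = T.sum(axis=1)
    signs, enumerated = _sign_matrix(n_pairs, cfg, rng)
    null = np.abs(T @ signs.T)  # (n_mirnas, B)
    # ties must count: compare with a small slack against float jitter
    exceed = (null >= np.abs(stat)[:, None] - 1e-9).sum(axis=1)
    if enumerated:
        p = exceed / signs.shape[0]
    else:
        p = (exceed + 1) / (signs.shape[0] + 1)

    norm = normalize(m)
    fc = fold_change(norm, pseudocount=cfg.pseudocount)

    out = pd.DataFrame(
        {
            "mirna": m.counts.index,
            "fold_change": fc.loc[m.counts.index].to_numpy(),
            "statistic": stat,
            "p_value": p,
            "adjusted_p": bh_adjust(p),
        }
    )
    out["_abs_lfc"] = np.abs(np.log2(out["fold_change"]))
    out = (
        out.sort_values(
            ["adjusted_p", "_abs_lfc", "mirna"], ascending=[True, False, True]
        )
        .drop(columns="_abs_lfc")
        .reset_index(drop=True)
    )
    return out


def fold_change(
    norm: Normalized,
    sample_meta: pd.DataFrame | None = None,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-miRNA fold change T8/T0 on de-logged normalized values.

    Back-transforms the log2(x + 1) normalized matrix to size-factor-scaled
    counts (2^v - 1), averages within each timepoint, and returns
    ``(mean_T8 + pseudocount) / (mean_T0 + pseudocount)``. FC < 1 means
    downregulation after treatment; the pseudocount keeps the ratio finite
    and positive for all-zero miRNAs and vanishes in the pseudocount -> 0
    limit.
    """
    if pseudocount <= 0:
        raise InvalidConfigError("pseudocount must be positive")
    meta = sample_meta if sample_meta is not None else norm.sample_meta
    if meta is None:
        raise InvalidConfigError("fold_change requires sample metadata")
    t0_cols = meta.index[meta["timepoint"] == "T0"]
    t8_cols = meta.index[meta["timepoint"] == "T8"]
    if len(t0_cols) == 0 or len(t8_cols) == 0:
        raise InvalidConfigError("need samples at both T0 and T8")
    delogged = 2.0 ** norm.values - 1.0
    mean_t0 = delogged[t0_cols].mean(axis=1)
    mean_t8 = delogged[t8_cols].mean(axis=1)
    fc = (mean_t8 + pseudocount) / (mean_t0 + pseudocount)
    fc.name = "fold_change"
    return fc
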