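"""Consensus miRNA-target prediction and gene-set enrichment.

Individual target-prediction sources (sequence-based databases such as
TargetScan, miRanda, miRDB, ...) have high false-positive rates; the
standard remedy is source voting. Here a gene counts as a target of a
miRNA only when at least ``k`` of the ``n`` sources predict the pair
(default 5 of 7), and the combined panel keeps only genes targeted by at
least ``m`` of the ``M`` query miRNAs (default 3), reflecting the
hypothesis that co-regulated miRNAs share pathways.

Pathway enrichment of the resulting gene set is a one-sided hypergeometric
(Fisher) test per pathway against a gene universe, BH-adjusted across
pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .diffexp import bh_adjust
from .errors import InvalidConfigError

__all__ = [
    "PredictionTable",
    "ConsensusTargetSet",
    "consensus_targets",
    "enrich",
    "normalize_gene_id",
]


def normalize_gene_id(gene: str) -> str:
    """Canonical gene key: upper-cased symbol (source tables mix cases)."""
    return gene.strip().upper()


def _normalize_mirna(mirna: str) -> str:
    from .cohort import normalize_mirna_id

    return normalize_mirna_id(mirna)


@dataclass
class PredictionTable:
    """All (miRNA, gene) pairs predicted by one source."""

    source_name: str
    pairs: frozenset[tuple[str, str]]

    @classmethod
    def from_pairs(
        cls, source_name: str, pairs: Iterable[tuple[str, str]]
    ) -> "PredictionTable":
        """Build with ID normalization (case-insensitive miRNAs, upper-case genes)."""
        return cls(
            source_name=source_name,
            pairs=frozenset(
                (_normalize_mirna(m), normalize_gene_id(g)) for m, g in pairs
            ),
        )

    def genes(self) -> frozenset[str]:
        return frozenset(g for _, g in self.pairs)


@dataclass
class ConsensusTargetSet:
    """Per-miRNA and combined target sets after the two voting stages.

    per_mirna[mu] holds genes predicted for mu by >= k sources; ``combined``
    holds genes in per_mirna of >= m of the M query miRNAs. ``source_support``
    (pair -> number of sources) and ``mirna_support`` (gene -> number of
    supporting miRNAs) are retained for audit.
    """

    per_mirna: dict[str, frozenset[str]]
    combined: frozenset[str]
    k: int
    m: int
    source_support: dict[tuple[str, str], int] = field(default_factory=dict)
    mirna_support: dict[str, int] = field(default_factory=dict)

    @property
    def query_mirnas(self) -> list[str]:
        return list(self.per_mirna)

    def union(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.per_mirna.values():
            out |= genes
        return frozenset(out)


def consensus_targets(
    tables: Sequence[PredictionTable],
    mirnas: Sequence[str],
    k: int = 5,
    m: int = 3,
) -> ConsensusTargetSet:
    """Two-stage consensus filter over prediction sources.

    Stage 1 (source vote): gene g is a target of query miRNA mu iff at
    least ``k`` of the ``len(tables)`` sources contain (mu, g).
    Stage 2 (miRNA vote): g enters the combined panel iff it passed stage 1
    for at least ``m`` of the query miRNAs.

    Increasing k or m can only shrink the output; the result is invariant
    to the order of tables and of miRNAs.
    """
    if not tables:
        raise InvalidConfigError("no prediction tables given")
    if not (1 <= k <= len(tables)):
        raise InvalidConfigError(f"k={k} must lie in [1, {len(tables)}] sources")
    if not mirnas:
        raise InvalidConfigError("no query miRNAs given")
    if not (1 <= m <= len(mirnas)):
        raise InvalidConfigError(f"m={m} must lie in [1, {len(mirnas)}] query miRNAs")

    queries = [_normalize_mirna(mu) for mu in mirnas]
    if len(set(queries)) != len(queries):
        raise InvalidConfigError("duplicate query miRNAs")

    qset = set(queries)
    support: dict[tuple[str, str], int] = {}
    for table in tables:
        for pair in table.pairs:
            if pair[0] in qset:
                support[pair] = support.get(pair, 0) + 1

    per_mirna = {
        mu: frozenset(g for (mm, g), c in support.items() if mm == mu and c >= k)
        for mu in queries
    }
    mirna_support: dict[str, int] = {}
    for genes in per_mirna.values():
        for g in genes:
            mirna_support[g] = mirna_support.get(g, 0) + 1
    combined = frozenset(g for g, c in mirna_support.items() if c >= m)

    return ConsensusTargetSet(
        per_mirna=per_mirna,
        combined=combined,
        k=k,
        m=m,
        source_support=support,
        mirna_support=mirna_support,
    )


def enrich(
    gene_set: Iterable[str],
    pathways: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of ``gene_set`` in each pathway.

    With universe size N, pathway size K (after intersecting with the
    universe), query size n and overlap q, the p-value is
    P[X >= q] for X ~ Hypergeom(N, K, n). Returns a DataFrame with columns
    ``pathway``, ``overlap``, ``pathway_size``, ``query_size``,
    ``universe_size``, ``p_value``, ``adjusted_p`` sorted by p then name.
    """
    universe_set = frozenset(normalize_gene_id(g) for g in universe)
    if not universe_set:
        raise InvalidConfigError("empty gene universe")
    query = frozenset(normalize_gene_id(g) for g in gene_set)
    if not query <= universe_set:
        raise InvalidConfigError(
            f"{len(query - universe_set)} query gene(s) outside the universe"
        )
    if not pathways:
        raise InvalidConfigError("no pathways given")

    N, n = len(universe_set), len(query)
    rows = []
    for name, members in pathways.items():
        pw = frozenset(normalize_gene_id(g) for g in members) & universe_set
        K = len(pw)
        q = len(pw & query)
        p = float(hypergeom.sf(q - 1, N, K, n))
        rows.append((name, q, K, n, N, min(p, 1.0)))
    out = pd.DataFrame(
        rows,
        columns=[
            "pathway",
            "overlap",
            "pathway_size",
            "query_size",
            "universe_size",
            "p_value",
        ],
    )
    out["adjusted_p"] = bh_adjust(out["p_value"].to_numpy())
    return out.sort_values(["p_value", "pathway"]).reset_index(drop=True)
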