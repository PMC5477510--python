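"""Small RNA-seq read QC, mature-miRNA counting, detection filter, normalization.

The QC stage mirrors a standard small-RNA pipeline for ~22 nt inserts
sequenced with a 3' adapter: a read is usable only if the adapter is found
(leftmost perfect match of its first ``adapter_seed_length`` bases), the
insert 5' of the adapter is 15-40 nt, and the insert's mean Phred quality
exceeds 30. Counting assigns each insert to a mature miRNA by exact sequence
identity, or as an exact prefix of the mature sequence when at least 16
bases match (3' end trimming variability); inserts compatible with more
than one reference are discarded as ambiguous.

Detection filtering keeps a miRNA only if it reaches 10 counts in at least
80% of libraries. Normalization uses median-of-ratios size factors followed
by a log2(x + 1) transform; all downstream statistics are rank- or
correlation-based, which this variance-stabilizing transform serves.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FastqParseError, InvalidConfigError, PairingError

__all__ = [
    "ReadFilterConfig",
    "FilterResult",
    "CountMatrix",
    "filter_reads",
    "count_mirnas",
    "detection_filter",
    "normalize",
    "Normalized",
]

#: rejection reasons, in the order the filters are applied
REJECTION_REASONS = ("no_adapter", "length", "quality")

#: minimum matching bases for a prefix hit against a mature reference
MIN_PREFIX_MATCH = 16


@dataclass(frozen=True)
class ReadFilterConfig:
    """Read-level QC parameters.

    adapter
        3' adapter nucleotide sequence; only its first ``adapter_seed_length``
        bases are used for detection (perfect match required).
    min_length, max_length
        Inclusive insert-length window in nucleotides (default 15-40).
    min_mean_phred
        Inserts must have mean Phred quality strictly above this (default 30),
        computed on the trimmed insert, not the raw read.
    phred_offset
        ASCII offset of the quality encoding; fixed to Sanger +33 by default.
    """

    adapter: str
    adapter_seed_length: int = 10
    min_length: int = 15
    max_length: int = 40
    min_mean_phred: float = 30.0
    phred_offset: int = 33

    def __post_init__(self) -> None:
        if not self.adapter or not all(
            c in "ACGTUN" for c in self.adapter.upper()
        ):
            raise InvalidConfigError("adapter must be a nonempty nucleotide string")
        if not (0 < self.min_length <= self.max_length):
            raise InvalidConfigError("need 0 < min_length <= max_length")
        if not (0 < self.adapter_seed_length <= len(self.adapter)):
            raise InvalidConfigError("adapter_seed_length must fit within adapter")
        if not math.isfinite(self.min_mean_phred):
            raise InvalidConfigError("min_mean_phred must be finite")

    @property
    def seed(self) -> str:
        return self.adapter[: self.adapter_seed_length].upper()


@dataclass
class FilterResult:
    """Kept inserts plus a per-reason rejection tally.

    Invariant: ``kept + sum(tally.values()) == total_reads``.
    """

    inserts: list[str]
    tally: dict[str, int]
    total_reads: int

    @property
    def kept(self) -> int:
        return len(self.inserts)


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _iter_fastq(source) -> Iterator:
    """Yield SeqRecords, re-raising parse failures with the record index."""
    if isinstance(source, (str, Path)):
        handle = _open_maybe_gzip(source)
    else:
        handle = source
    parser = SeqIO.parse(handle, "fastq")
    index = 0
    while True:
        try:
            record = next(parser)
        except StopIteration:
            break
        except ValueError as exc:
            raise FastqParseError(
                f"malformed FASTQ record at index {index}: {exc}", record_index=index
            ) from exc
        yield record
        index += 1


def filter_reads(fastq, cfg: ReadFilterConfig) -> FilterResult:
    """Apply adapter / length / quality filters to a FASTQ stream.

    ``fastq`` may be a path (plain or .gz), an open text handle, or an
    iterable of Bio.SeqRecord objects. A read is kept iff

    1. the adapter seed (first ``adapter_seed_length`` adapter bases) occurs
       in the read — the leftmost occurrence defines the insert boundary;
    2. the insert (bases 5' of that occurrence) is within the length window;
    3. the insert's mean Phred quality is strictly above ``min_mean_phred``.

    The first failing filter, in that order, claims the rejection. Non-ACGT
    bases pass through the filters (they simply never match a reference
    later). Returns the kept inserts and the per-reason tally.
    """
    if isinstance(fastq, (str, Path)) or hasattr(fastq, "read"):
        records = _iter_fastq(fastq)
    else:
        records = iter(fastq)

    seed = cfg.seed
    inserts: list[str] = []
    tally = {reason: 0 for reason in REJECTION_REASONS}
    total = 0
    for record in records:
        total += 1
        seq = str(record.seq).upper()
        pos = seq.find(seed)
        if pos < 0:
            tally["no_adapter"] += 1
            continue
        if not (cfg.min_length <= pos <= cfg.max_length):
            tally["length"] += 1
            continue
        quals = record.letter_annotations["phred_quality"][:pos]
        if sum(quals) / pos <= cfg.min_mean_phred:
            tally["quality"] += 1
            continue
        inserts.append(seq[:pos])
    return FilterResult(inserts=inserts, tally=tally, total_reads=total)


@dataclass
class CountMatrix:
    """Integer miRNA x sample count matrix with per-sample metadata.

    counts
        DataFrame, rows indexed by miRNA ID, columns by sample ID
        (convention: ``"<subject>_<T0|T8>"``).
    sample_meta
        Optional DataFrame indexed by sample ID with columns ``subject``,
        ``timepoint`` and, when known, ``arm`` and ``response``. Required
        by paired operations.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise InvalidConfigError("counts must be non-negative")
        if self.sample_meta is not None:
            if set(self.sample_meta.index) != set(self.counts.columns):
                raise PairingError("sample_meta index must match count columns")
            self.sample_meta = self.sample_meta.loc[self.counts.columns]

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def restrict(self, arm=None, response=None) -> "CountMatrix":
        """Subset columns to one arm and/or response stratum."""
        if self.sample_meta is None:
            raise PairingError("restrict() requires sample metadata")
        meta = self.sample_meta
        mask = pd.Series(True, index=meta.index)
        if arm is not None:
            mask &= meta["arm"] == getattr(arm, "value", arm)
        if response is not None:
            mask &= meta["response"] == getattr(response, "value", response)
        cols = meta.index[mask]
        return CountMatrix(self.counts[cols].copy(), meta.loc[cols].copy())

    def pairs(self) -> tuple[list[str], list[str], list[str]]:
        """Return (subjects, T0 columns, T8 columns) in matched order.

        Raises PairingError unless every subject has exactly one T0 and one
        T8 column.
        """
        if self.sample_meta is None:
            raise PairingError("pairing requires sample metadata")
        meta = self.sample_meta
        t0_cols, t8_cols, subjects = [], [], []
        for subject, group in meta.groupby("subject", sort=True):
            tps = sorted(group["timepoint"])
            if tps != ["T0", "T8"]:
                raise PairingError(
                    f"subject {subject!r} has timepoints {tps}, need exactly [T0, T8]"
                )
            subjects.append(str(subject))
            t0_cols.append(group.index[group["timepoint"] == "T0"][0])
            t8_cols.append(group.index[group["timepoint"] == "T8"][0])
        return subjects, t0_cols, t8_cols


def count_mirnas(
    inserts_by_sample: Mapping[str, Sequence[str]],
    reference: Mapping[str, str],
    sample_meta: pd.DataFrame | None = None,
) -> tuple[CountMatrix, dict[str, dict[str, int]]]:
    """Count QC-passed inserts against a mature miRNA reference.

    An insert increments a miRNA iff it equals the mature sequence exactly,
    or is an exact prefix of it with at least ``MIN_PREFIX_MATCH`` (16)
    matching bases. Inserts compatible with two or more references are
    discarded as ambiguous; unmatched and ambiguous inserts are tallied
    per sample.

    Parameters
    ----------
    inserts_by_sample : mapping sample ID -> insert sequences.
    reference : mapping miRNA ID -> mature sequence (IDs must be unique,
        which a dict enforces; sequences may repeat and then produce
        ambiguity).

    Returns
    -------
    (CountMatrix, tallies) where tallies[sample] has keys ``assigned``,
    ``ambiguous``, ``unmatched``.
    """
    if not reference:
        raise InvalidConfigError("empty miRNA reference")
    ref_upper = {mid: seq.upper().replace("U", "T") for mid, seq in reference.items()}

    # index references by their first MIN_PREFIX_MATCH bases; short mature
    # sequences can only be hit by a full-length exact match
    prefix_index: dict[str, list[str]] = {}
    exact_index: dict[str, list[str]] = {}
    for mid, seq in ref_upper.items():
        exact_index.setdefault(seq, []).append(mid)
        if len(seq) >= MIN_PREFIX_MATCH:
            prefix_index.setdefault(seq[:MIN_PREFIX_MATCH], []).append(mid)

    mirna_ids = list(ref_upper)
    row_of = {mid: i for i, mid in enumerate(mirna_ids)}
    samples = list(inserts_by_sample)
    counts = np.zeros((len(mirna_ids), len(samples)), dtype=np.int64)
    tallies: dict[str, dict[str, int]] = {}

    for j, sample in enumerate(samples):
        tally = {"assigned": 0, "ambiguous": 0, "unmatched": 0}
        for raw in inserts_by_sample[sample]:
            insert = raw.upper().replace("U", "T")
            if len(insert) < MIN_PREFIX_MATCH:
                hits = exact_index.get(insert, [])
            else:
                hits = [
                    mid
                    for mid in prefix_index.get(insert[:MIN_PREFIX_MATCH], [])
                    if ref_upper[mid].startswith(insert)
                ]
            if len(hits) == 1:
                counts[row_of[hits[0]], j] += 1
                tally["assigned"] += 1
            elif hits:
                tally["ambiguous"] += 1
            else:
                tally["unmatched"] += 1
        tallies[sample] = tally

    df = pd.DataFrame(counts, index=mirna_ids, columns=samples)
    return CountMatrix(df, sample_meta), tallies


def detection_filter(
    m: CountMatrix, min_count: int = 10, min_fraction: float = 0.8
) -> CountMatrix:
    """Keep miRNAs detected (>= min_count reads) in >= min_fraction of samples.

    The sample threshold is ``ceil(min_fraction * n_samples)``, i.e. a miRNA
    detected in exactly 80% of libraries is retained. Idempotent.
    """
    if not (0 < min_fraction <= 1):
        raise InvalidConfigError("min_fraction must be in (0, 1]")
    n = m.counts.shape[1]
    detected = (m.counts.to_numpy() >= min_count).sum(axis=1)
    # float-robust ceil: k passes iff k/n >= min_fraction
    keep = detected >= min_fraction * n - 1e-9
    counts = m.counts.loc[keep].copy()
    return CountMatrix(counts, None if m.sample_meta is None else m.sample_meta.copy())


@dataclass
class Normalized:
    """Log2-scale normalized expression with the size factors that produced it."""

    values: pd.DataFrame  # log2(count / size_factor + 1)
    size_factors: pd.Series
    sample_meta: pd.DataFrame | None = None


def normalize(m: CountMatrix) -> Normalized:
    """Median-of-ratios size factors + log2(x + 1) transform.

    Size factor of sample s = median over miRNAs of count[i, s] divided by
    the geometric mean of miRNA i across samples, computed over miRNAs with
    no zero counts (zeros would zero the geometric mean). Normalized value =
    ``log2(count / size_factor + 1)``; rank order within each sample is
    preserved.

    Raises on an all-zero sample (its size factor is undefined) and when no
    miRNA is zero-free in all samples.
    """
    C = m.counts.to_numpy(dtype=float)
    all_zero = C.sum(axis=0) == 0
    if all_zero.any():
        bad = [c for c, z in zip(m.counts.columns, all_zero) if z]
        raise InvalidConfigError(f"sample(s) with all-zero counts: {bad}")
    positive_rows = (C > 0).all(axis=1)
    if not positive_rows.any():
        raise InvalidConfigError(
            "no miRNA has nonzero counts in every sample; size factors undefined"
        )
    ref = C[positive_rows]
    log_geo_mean = np.log(ref).mean(axis=1)
    sf = np.exp(np.median(np.log(ref) - log_geo_mean[:, None], axis=0))
    values = np.log2(C / sf[None, :] + 1.0)
    return Normalized(
        values=pd.DataFrame(values, index=m.counts.index, columns=m.counts.columns),
        size_factors=pd.Series(sf, index=m.counts.columns, name="size_factor"),
        sample_meta=None if m.sample_meta is None else m.sample_meta.copy(),
    )
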