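"""Readers and writers for the pipeline's plain-text formats.

Counts and expression matrices are TSV with feature IDs in the first
column and ``"<subject>_<T0|T8>"`` sample columns; sample metadata is TSV
with columns subject/arm/madrs_t0/madrs_t8 (+ derived response);
significant sets mirror the published table layout (mirna, fold_change,
adjusted_p); prediction sources are TSV with columns source/mirna/gene;
pathway collections use the tab-delimited GMT convention (name,
description, member genes).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .cohort import Arm, Response, SignificantSet, SubjectRecord
from .errors import InvalidConfigError
from .smallrna import CountMatrix
from .targets import PredictionTable

__all__ = [
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_counts",
    "read_counts",
    "write_metadata",
    "read_metadata",
    "cohort_to_frame",
    "read_significant_set",
    "write_significant_set",
    "read_gmt",
    "write_gmt",
    "read_prediction_tables",
    "write_prediction_table",
    "read_mature_fasta",
    "write_json_report",
]


def write_matrix_tsv(df: pd.DataFrame, path, index_label: str = "feature") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts(m: CountMatrix, counts_path, meta_path=None) -> None:
    write_matrix_tsv(m.counts, counts_path, index_label="mirna")
    if meta_path is not None:
        if m.sample_meta is None:
            raise InvalidConfigError("count matrix carries no sample metadata")
        m.sample_meta.to_csv(meta_path, sep="\t", index_label="sample")


def read_counts(counts_path, meta_path=None) -> CountMatrix:
    counts = read_matrix_tsv(counts_path)
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return CountMatrix(counts, meta)


def cohort_to_frame(cohort: Sequence[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject": [s.subject_id for s in cohort],
            "arm": [s.arm.value for s in cohort],
            "madrs_t0": [s.madrs_t0 for s in cohort],
            "madrs_t8": [s.madrs_t8 for s in cohort],
            "response": [s.response.value for s in cohort],
        }
    ).set_index("subject")


def write_metadata(cohort: Sequence[SubjectRecord], path) -> None:
    cohort_to_frame(cohort).to_csv(path, sep="\t", index_label="subject")


def read_metadata(path) -> list[SubjectRecord]:
    """Read subject metadata, re-deriving the response label from MADRS."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [
        SubjectRecord.from_scores(
            str(subject), row["arm"], row["madrs_t0"], row["madrs_t8"]
        )
        for subject, row in df.iterrows()
    ]


def sample_meta_from_cohort(cohort: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Per-sample metadata frame for the paired column convention."""
    rows = []
    for s in cohort:
        for tp in ("T0", "T8"):
            rows.append(
                {
                    "sample": f"{s.subject_id}_{tp}",
                    "subject": s.subject_id,
                    "timepoint": tp,
                    "arm": s.arm.value,
                    "response": s.response.value,
                }
            )
    return pd.DataFrame(rows).set_index("sample")


def read_significant_set(path, arm: Arm | str, stratum: Response | str) -> SignificantSet:
    table = pd.read_csv(path, sep="\t")
    return SignificantSet(arm=Arm(arm), stratum=Response(stratum), table=table)


def write_significant_set(s: SignificantSet, path) -> None:
    s.table.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: one pathway per line (name, description, genes...)."""
    pathways: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InvalidConfigError(
                    f"GMT line needs name, description and >= 1 gene: {parts[0]!r}"
                )
            pathways[parts[0]] = [g for g in parts[2:] if g]
    return pathways


def write_gmt(pathways: Mapping[str, Iterable[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in pathways.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_prediction_tables(paths_or_dir) -> list[PredictionTable]:
    """Read per-source prediction TSVs (columns: source, mirna, gene).

    Accepts a directory (all ``*.tsv`` inside), a single file containing
    one or more sources, or an iterable of files; tables are grouped by
    the ``source`` column.
    """
    p = Path(paths_or_dir) if isinstance(paths_or_dir, (str, Path)) else None
    if p is not None and p.is_dir():
        files = sorted(p.glob("*.tsv"))
    elif p is not None:
        files = [p]
    else:
        files = [Path(x) for x in paths_or_dir]
    if not files:
        raise InvalidConfigError("no prediction tables found")
    frames = [pd.read_csv(f, sep="\t") for f in files]
    df = pd.concat(frames, ignore_index=True)
    missing = {"source", "mirna", "gene"} - set(df.columns)
    if missing:
        raise InvalidConfigError(f"prediction table missing columns {missing}")
    return [
        PredictionTable.from_pairs(str(name), zip(group["mirna"], group["gene"]))
        for name, group in df.groupby("source", sort=True)
    ]


def write_prediction_table(table: PredictionTable, path) -> None:
    df = pd.DataFrame(sorted(table.pairs), columns=["mirna", "gene"])
    df.insert(0, "source", table.source_name)
    df.to_csv(path, sep="\t", index=False)


def read_mature_fasta(path) -> dict[str, str]:
    """Mature miRNA reference FASTA -> {id: sequence} (IDs must be unique)."""
    reference: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in reference:
            raise InvalidConfigError(f"duplicate reference ID {record.id!r}")
        reference[record.id] = str(record.seq)
    if not reference:
        raise InvalidConfigError("empty miRNA reference FASTA")
    return reference


def write_json_report(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (frozenset, set)):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
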