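"""Synthetic cohorts with the statistical structure of the clinical study.

The generator emulates a randomized placebo-controlled antidepressant trial
with paired (baseline T0, week-8 T8) blood draws per subject and two arms
(drug / placebo). Each subject carries MADRS scores at both timepoints from
which the responder label is derivable; a configurable subset of *marker*
miRNAs is downregulated at T8 in responders only (both arms), matching the
responder-specific signal the analysis is designed to detect; planted
target genes are anticorrelated with their marker miRNA in responders only;
and per-source target-prediction tables contain each true (miRNA, gene)
pair with a given sensitivity and each false pair with a given
false-positive rate.

Counts follow a negative binomial with per-sample log-normal size factors
(the standard RNA-seq noise model). Every stage draws from its own RNG
stream seeded from (seed, stage-name), so stages are decoupled and
identical (config, seed) gives bit-identical output.

Defaults mirror the study design: 129 subjects per arm (258 paired
patients), 281 detected miRNAs with 5 markers at log2 FC -1, ~15,000 gene
probes with a 36-gene target panel shared by the markers, and 7 prediction
sources.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, fields
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import Arm, Response, SubjectRecord, normalize_mirna_id
from .errors import ConsistencyError, InvalidConfigError
from .smallrna import CountMatrix, Normalized, normalize
from .targets import PredictionTable

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "generate_cohort",
    "generate_counts",
    "generate_expression",
    "generate_prediction_sources",
    "generate_pathways",
    "simulate_study",
    "mirna_ids",
    "gene_ids",
    "marker_mirnas",
    "true_target_map",
    "write_synthetic_fastq",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with trial-like defaults.

    n_subjects_per_arm
        Subjects randomized to each of drug and placebo (129 + 129 = 258).
    responder_fraction
        Per-subject probability of responding (>50% MADRS decrease).
    n_mirnas / n_marker_mirnas / marker_log2fc
        Detected miRNAs; how many are true response markers; their log2
        fold change at T8 in responders (negative = downregulation).
    n_genes / n_target_genes_per_marker / target_correlation
        Measured gene probes; size of the shared target panel (every marker
        targets every panel gene, emulating co-regulation); planted Pearson
        correlation between a panel gene and its anchor marker miRNA in
        responders (in (-1, 0]).
    library_size_mean / dispersion
        Expected counted reads per library; negative-binomial dispersion
        (variance = mu + dispersion * mu^2; 0 gives deterministic rounded
        means).
    n_sources / source_sensitivity / source_false_positive_rate
        Prediction sources and their per-pair inclusion probabilities.
    """

    n_subjects_per_arm: int = 129
    responder_fraction: float = 0.5
    n_mirnas: int = 281
    n_marker_mirnas: int = 5
    marker_log2fc: float = -1.0
    n_genes: int = 15000
    n_target_genes_per_marker: int = 36
    target_correlation: float = -0.8
    library_size_mean: int = 1_000_000
    dispersion: float = 0.1
    n_sources: int = 7
    source_sensitivity: float = 0.9
    source_false_positive_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise InvalidConfigError(f"{f.name} must be finite, got {v!r}")
        if self.n_subjects_per_arm < 1:
            raise InvalidConfigError("n_subjects_per_arm must be positive")
        for name in (
            "responder_fraction",
            "source_sensitivity",
            "source_false_positive_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidConfigError(f"{name} must lie in [0, 1]")
        if self.n_mirnas < 1 or self.n_genes < 1:
            raise InvalidConfigError("n_mirnas and n_genes must be positive")
        if not (0 <= self.n_marker_mirnas <= self.n_mirnas):
            raise InvalidConfigError("need 0 <= n_marker_mirnas <= n_mirnas")
        if self.n_target_genes_per_marker < 1:
            raise InvalidConfigError("n_target_genes_per_marker must be positive")
        if self.n_target_genes_per_marker > self.n_genes:
            raise InvalidConfigError("target panel cannot exceed n_genes")
        if not (-1.0 < self.target_correlation <= 0.0):
            raise InvalidConfigError("target_correlation must lie in (-1, 0]")
        if self.library_size_mean < 1:
            raise InvalidConfigError("library_size_mean must be positive")
        if self.dispersion < 0:
            raise InvalidConfigError("dispersion must be >= 0")
        if self.n_sources < 1:
            raise InvalidConfigError("n_sources must be positive")
        if self.seed < 0 or self.seed >= 2**31:
            raise InvalidConfigError("seed must lie in [0, 2^31)")


def _rng(cfg: SimulationConfig, stage: str) -> np.random.Generator:
    """One decoupled RNG stream per (seed, stage-name)."""
    return np.random.default_rng([cfg.seed, zlib.crc32(stage.encode())])


def mirna_ids(cfg: SimulationConfig) -> list[str]:
    """Synthetic mature-miRNA IDs; the first ``n_marker_mirnas`` are markers."""
    return [f"miR-syn-{i + 1:04d}" for i in range(cfg.n_mirnas)]


def marker_mirnas(cfg: SimulationConfig) -> list[str]:
    return mirna_ids(cfg)[: cfg.n_marker_mirnas]


def gene_ids(cfg: SimulationConfig) -> list[str]:
    return [f"GENE{i + 1:05d}" for i in range(cfg.n_genes)]


def generate_cohort(cfg: SimulationConfig) -> list[SubjectRecord]:
    """Simulate subjects with MADRS scores encoding planted response labels.

    Baseline MADRS is uniform on [22, 40] (trial entry requires >= 22); the
    planted label is Bernoulli(responder_fraction) per subject, so the
    realized responder count is Binomial. The percent decrease d is drawn
    from a scaled Beta(2, 2) strictly above 0.5 for responders and at or
    below 0.5 for nonresponders, and T8 = T0 * (1 - d); re-deriving the
    label from the scores therefore reproduces the planted label exactly.
    """
    rng = _rng(cfg, "cohort")
    subjects: list[SubjectRecord] = []
    for arm, prefix in ((Arm.DRUG, "D"), (Arm.PLACEBO, "P")):
        for i in range(cfg.n_subjects_per_arm):
            t0 = rng.uniform(22.0, 40.0)
            responder = rng.random() < cfg.responder_fraction
            x = rng.beta(2.0, 2.0)
            if responder:
                d = 0.5 + 0.45 * max(x, 1e-6)  # d in (0.5, 0.95]
            else:
                d = 0.5 - 0.65 * x  # d in (-0.15, 0.5]
            t8 = t0 * (1.0 - d)
            record = SubjectRecord.from_scores(f"{prefix}{i + 1:04d}", arm, t0, t8)
            expected = Response.RESPONDER if responder else Response.NONRESPONDER
            assert record.response == expected  # planted label round-trips
            subjects.append(record)
    return subjects


def _sample_columns(cohort: Sequence[SubjectRecord]) -> pd.DataFrame:
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


def generate_counts(
    cohort: Sequence[SubjectRecord], cfg: SimulationConfig
) -> CountMatrix:
    """Negative-binomial paired count matrix with responder-specific markers.

    Per-miRNA baseline abundances are log-normal (sigma 1.5) scaled to an
    expected ``library_size_mean`` per library; per-sample size factors are
    log-normal (sigma 0.25). Marker miRNAs are multiplied by
    ``2**marker_log2fc`` only in T8 columns of responders — nonresponders
    and all T0 columns are unshifted.
    """
    if not cohort:
        raise InvalidConfigError("cohort is empty")
    rng = _rng(cfg, "counts")
    meta = _sample_columns(cohort)
    ids = mirna_ids(cfg)

    weights = rng.lognormal(mean=0.0, sigma=1.5, size=cfg.n_mirnas)
    base = weights / weights.sum() * cfg.library_size_mean
    sf = rng.lognormal(mean=0.0, sigma=0.25, size=len(meta))

    is_marker = np.zeros(cfg.n_mirnas, dtype=bool)
    is_marker[: cfg.n_marker_mirnas] = True
    shifted_col = (
        (meta["timepoint"] == "T8") & (meta["response"] == Response.RESPONDER.value)
    ).to_numpy()
    mu = base[:, None] * sf[None, :]
    mu = mu * np.where(
        is_marker[:, None] & shifted_col[None, :], 2.0**cfg.marker_log2fc, 1.0
    )

    if cfg.dispersion == 0:
        counts = np.rint(mu).astype(np.int64)
    else:
        n_param = 1.0 / cfg.dispersion
        p_param = 1.0 / (1.0 + cfg.dispersion * mu)
        counts = rng.negative_binomial(n_param, p_param).astype(np.int64)

    df = pd.DataFrame(counts, index=ids, columns=meta.index)
    return CountMatrix(df, meta)


def true_target_map(cfg: SimulationConfig) -> dict[str, frozenset[str]]:
    """Planted miRNA -> target-gene map: one shared panel for all markers.

    The panel (``n_target_genes_per_marker`` genes drawn without replacement
    from the gene universe) is targeted by every marker, emulating a set of
    co-regulated pathway genes under joint miRNA control.
    """
    rng = _rng(cfg, "targets")
    genes = np.array(gene_ids(cfg))
    panel = rng.choice(genes, size=cfg.n_target_genes_per_marker, replace=False)
    panel_set = frozenset(str(g) for g in sorted(panel))
    return {mu: panel_set for mu in marker_mirnas(cfg)}


def target_anchors(cfg: SimulationConfig) -> dict[str, str]:
    """Assign each panel gene an anchor marker (round-robin) for planting."""
    markers = marker_mirnas(cfg)
    panel = sorted(next(iter(true_target_map(cfg).values()), frozenset()))
    return {g: markers[i % len(markers)] for i, g in enumerate(panel)} if markers else {}


def generate_expression(
    cohort: Sequence[SubjectRecord],
    true_targets: Mapping[str, frozenset[str]],
    cfg: SimulationConfig,
    mirna_expr: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Gene expression matrix with responder-only planted anticorrelation.

    Each planted target gene's residual, in responder samples only, is
    ``rho * z + sqrt(1 - rho^2) * eps`` where z is its anchor marker's
    standardized normalized expression across responder samples and
    rho = ``target_correlation``; nonresponder samples and all non-target
    genes are independent noise. Values live on a microarray-like log2
    scale (baseline ~ N(8, 2), unit residual SD).
    """
    if not cohort:
        raise InvalidConfigError("cohort is empty")
    if mirna_expr is None:
        mirna_expr = normalize(generate_counts(cohort, cfg)).values
    unknown = [mu for mu in true_targets if mu not in set(mirna_expr.index)]
    if unknown:
        raise ConsistencyError(f"targets reference unknown miRNAs: {unknown}")

    rng = _rng(cfg, "expression")
    meta = _sample_columns(cohort)
    if list(meta.index) != list(mirna_expr.columns):
        raise ConsistencyError("miRNA expression columns do not match the cohort")
    genes = gene_ids(cfg)
    n_samples = len(meta)

    baseline = rng.normal(8.0, 2.0, size=cfg.n_genes)
    resid = rng.normal(0.0, 1.0, size=(cfg.n_genes, n_samples))

    responder_cols = (meta["response"] == Response.RESPONDER.value).to_numpy()
    rho = cfg.target_correlation
    if responder_cols.any() and rho != 0.0:
        markers = list(true_targets)
        panel = sorted(set().union(*true_targets.values())) if markers else []
        gene_row = {g: i for i, g in enumerate(genes)}
        missing = [g for g in panel if g not in gene_row]
        if missing:
            raise ConsistencyError(f"targets reference unknown genes: {missing}")
        anchors = {g: markers[i % len(markers)] for i, g in enumerate(panel)}
        M = mirna_expr.loc[:, responder_cols].to_numpy(dtype=float)
        for g in panel:
            x = M[list(mirna_expr.index).index(anchors[g])]
            sd = x.std()
            if sd == 0:
                continue  # flat marker: nothing to correlate against
            z = (x - x.mean()) / sd
            eps = resid[gene_row[g], responder_cols]
            resid[gene_row[g], responder_cols] = (
                rho * z + math.sqrt(1.0 - rho**2) * eps
            )
    values = baseline[:, None] + resid
    return pd.DataFrame(values, index=genes, columns=meta.index)


def generate_prediction_sources(
    cfg: SimulationConfig, true_targets: Mapping[str, frozenset[str]]
) -> list[PredictionTable]:
    """Per-source prediction tables with given sensitivity and FP rate.

    Each source independently contains each true (marker, gene) pair with
    probability ``source_sensitivity`` and each false pair — query miRNA x
    any non-target gene — with probability ``source_false_positive_rate``.
    """
    rng = _rng(cfg, "sources")
    genes = gene_ids(cfg)
    queries = list(true_targets)
    tables = []
    for s in range(cfg.n_sources):
        pairs: list[tuple[str, str]] = []
        for mu in queries:
            targets = true_targets[mu]
            is_true = np.array([g in targets for g in genes])
            u = rng.random(len(genes))
            take = np.where(
                is_true, u < cfg.source_sensitivity, u < cfg.source_false_positive_rate
            )
            pairs.extend((mu, g) for g, t in zip(genes, take) if t)
        tables.append(PredictionTable.from_pairs(f"source{s + 1:02d}", pairs))
    return tables


def generate_pathways(
    cfg: SimulationConfig,
    true_targets: Mapping[str, frozenset[str]],
    n_random_pathways: int = 10,
    random_pathway_size: int = 50,
) -> dict[str, list[str]]:
    """Pathway gene sets: the planted panel plus random decoy pathways."""
    rng = _rng(cfg, "pathways")
    panel = sorted(set().union(*true_targets.values())) if true_targets else []
    others = [g for g in gene_ids(cfg) if g not in set(panel)]
    pathways: dict[str, list[str]] = {"MAPK_WNT_SIGNALING": list(panel)}
    size = min(random_pathway_size, len(others))
    for i in range(n_random_pathways):
        draw = rng.choice(len(others), size=size, replace=False)
        pathways[f"RANDOM_PATHWAY_{i + 1:02d}"] = sorted(others[j] for j in draw)
    return pathways


@dataclass
class SimulatedStudy:
    """Everything one run of the synthetic study produces."""

    cfg: SimulationConfig
    cohort: list[SubjectRecord]
    counts: CountMatrix
    mirna_norm: Normalized
    gene_expr: pd.DataFrame
    true_targets: dict[str, frozenset[str]]
    sources: list[PredictionTable]
    pathways: dict[str, list[str]]

    @property
    def marker_ids(self) -> list[str]:
        return marker_mirnas(self.cfg)

    @property
    def marker_keys(self) -> frozenset[str]:
        return frozenset(normalize_mirna_id(m) for m in self.marker_ids)

    @property
    def panel(self) -> list[str]:
        return sorted(set().union(*self.true_targets.values())) if self.true_targets else []

    def stratum_samples(self, response: Response | str, arm: Arm | str | None = None):
        """Sample columns of one response stratum (optionally one arm)."""
        meta = self.counts.sample_meta
        mask = meta["response"] == getattr(response, "value", response)
        if arm is not None:
            mask &= meta["arm"] == getattr(arm, "value", arm)
        return list(meta.index[mask])


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Run every generator stage once and bundle the outputs."""
    cohort = generate_cohort(cfg)
    counts = generate_counts(cohort, cfg)
    mirna_norm = normalize(counts)
    true_targets = true_target_map(cfg)
    gene_expr = generate_expression(
        cohort, true_targets, cfg, mirna_expr=mirna_norm.values
    )
    sources = generate_prediction_sources(cfg, true_targets)
    pathways = generate_pathways(cfg, true_targets)
    return SimulatedStudy(
        cfg=cfg,
        cohort=cohort,
        counts=counts,
        mirna_norm=mirna_norm,
        gene_expr=gene_expr,
        true_targets=true_targets,
        sources=sources,
        pathways=pathways,
    )


def write_synthetic_fastq(
    path,
    inserts: Sequence[str],
    adapter: str,
    quality_char: str = "I",
    read_length: int = 50,
) -> None:
    """Write a minimal FASTQ of insert+adapter reads for QC testing.

    Each read is the insert followed by the adapter, padded with 'A' to
    ``read_length`` and uniform quality (default 'I' = Q40). This is a
    fixture writer, not a read simulator: no sequencing-error model.
    """
    with open(path, "w") as fh:
        for i, insert in enumerate(inserts):
            seq = (insert + adapter)[:read_length]
            seq = seq + "A" * (read_length - len(seq))
            fh.write(f"@read{i}\n{seq}\n+\n{quality_char * len(seq)}\n")
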