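"""End-to-end orchestration: simulate -> DE -> candidates -> targets -> integrate.

This is the programmatic equivalent of the ``mirresponse run-all`` command:
it runs the paired differential-expression test in all four
(arm x response) cells, derives candidate marker miRNAs by cross-arm set
algebra, applies the consensus target filter to the prediction sources,
and closes with the responder-stratified correlation analysis against the
random-gene permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import (
    Arm,
    CandidateReport,
    Response,
    SignificantSet,
    derive_candidates,
)
from .diffexp import DEConfig, paired_rank_test
from .integration import (
    CorrelationReport,
    EnrichmentComparison,
    PermutationNullReport,
    compare_enrichment,
    correlate_panel,
    permutation_null,
)
from .smallrna import CountMatrix
from .synthetic_data import SimulatedStudy, SimulationConfig, simulate_study
from .targets import ConsensusTargetSet, consensus_targets

__all__ = ["StudyResult", "run_study", "differential_expression_by_cell"]


@dataclass
class StudyResult:
    """Bundle of every stage's output for one synthetic study run."""

    study: SimulatedStudy
    de_tables: dict[str, pd.DataFrame]  # "<arm>_<response>" -> DE table
    significant_sets: dict[str, SignificantSet]
    candidates: CandidateReport
    consensus: ConsensusTargetSet | None
    correlation: CorrelationReport | None
    null: PermutationNullReport | None
    enrichment: EnrichmentComparison | None


def differential_expression_by_cell(
    counts: CountMatrix, de_cfg: DEConfig
) -> tuple[dict[str, pd.DataFrame], dict[str, SignificantSet]]:
    """Run the paired test in each (arm, response) cell of a count matrix.

    Returns the full DE tables and the significant sets (adjusted p below
    the configured FDR threshold) keyed ``"<arm>_<response>"``.
    """
    de_tables: dict[str, pd.DataFrame] = {}
    sig_sets: dict[str, SignificantSet] = {}
    for arm in (Arm.DRUG, Arm.PLACEBO):
        for response in (Response.RESPONDER, Response.NONRESPONDER):
            cell = counts.restrict(arm=arm, response=response)
            table = paired_rank_test(cell, de_cfg)
            key = f"{arm.value}_{response.value}"
            de_tables[key] = table
            sig = table[table["adjusted_p"] < de_cfg.fdr_threshold]
            sig_sets[key] = SignificantSet(
                arm=arm,
                stratum=response,
                table=sig[["mirna", "fold_change", "adjusted_p"]].reset_index(
                    drop=True
                ),
            )
    return de_tables, sig_sets


def run_study(
    cfg: SimulationConfig,
    de_cfg: DEConfig | None = None,
    k: int = 5,
    m: int = 3,
    alpha: float = 0.05,
    set_size: int = 50,
    n_null_permutations: int = 100,
) -> StudyResult:
    """Full discovery pipeline on one synthetic study.

    The consensus filter queries the derived candidate miRNAs; the
    correlation stage uses the consensus combined gene panel, responder vs
    nonresponder strata pooled across arms, and a random-gene permutation
    null of ``set_size`` genes x ``n_null_permutations`` draws. Integration
    stages are skipped (None) when no candidates or no panel genes survive.
    """
    if de_cfg is None:
        # the smallest attainable adjusted p is m_mirnas / (k_hits * (B + 1));
        # B must be large enough for a handful of true positives to clear the
        # FDR threshold among a few hundred miRNAs
        de_cfg = DEConfig(seed=cfg.seed, n_permutations=10000)
    study = simulate_study(cfg)
    de_tables, sig_sets = differential_expression_by_cell(study.counts, de_cfg)
    candidates = derive_candidates(sig_sets.values())

    consensus = correlation = null = enrichment = None
    candidate_ids = candidates.candidate_names
    if candidate_ids and study.sources:
        m_eff = min(m, len(candidate_ids))
        consensus = consensus_targets(study.sources, candidate_ids, k=k, m=m_eff)
        panel = sorted(consensus.combined)
        if panel:
            mirna_rows = [
                mid
                for mid in study.mirna_norm.values.index
                if mid in set(candidate_ids)
            ]
            mirna_expr = study.mirna_norm.values.loc[mirna_rows]
            strata = {
                "responder": study.stratum_samples(Response.RESPONDER),
                "nonresponder": study.stratum_samples(Response.NONRESPONDER),
            }
            correlation = correlate_panel(
                mirna_expr, study.gene_expr, panel, strata, alpha=alpha
            )
            null = permutation_null(
                mirna_expr,
                study.gene_expr,
                samples=strata["responder"],
                panel=panel,
                set_size=min(set_size, len(study.gene_expr) - len(panel)),
                n_permutations=n_null_permutations,
                alpha=alpha,
                seed=cfg.seed,
            )
            enrichment = compare_enrichment(correlation, null, stratum="responder")

    return StudyResult(
        study=study,
        de_tables=de_tables,
        significant_sets=sig_sets,
        candidates=candidates,
        consensus=consensus,
        correlation=correlation,
        null=null,
        enrichment=enrichment,
    )
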