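"""The synthetic study generator: determinism, planted structure, recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, pearsonr

from mirresponse.cohort import Response, classify_response
from mirresponse.errors import ConsistencyError, InvalidConfigError
from mirresponse.smallrna import normalize
from mirresponse.synthetic_data import (
    SimulationConfig,
    generate_cohort,
    generate_counts,
    generate_expression,
    generate_prediction_sources,
    marker_mirnas,
    simulate_study,
    target_anchors,
    true_target_map,
)
from mirresponse.targets import consensus_targets


class TestConfigValidation:
    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(marker_log2fc=float("nan"))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"responder_fraction": 1.2},
            {"n_marker_mirnas": 300, "n_mirnas": 100},
            {"target_correlation": 0.5},
            {"target_correlation": -1.0},
            {"dispersion": -0.1},
            {"n_subjects_per_arm": 0},
        ],
    )
    def test_out_of_range_rejected(self, kwargs):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(**kwargs)


class TestGenerateCohort:
    def test_degenerate_fractions(self):
        all_resp = generate_cohort(
            SimulationConfig(n_subjects_per_arm=10, responder_fraction=1.0, seed=1)
        )
        assert len(all_resp) == 20
        assert all(s.response is Response.RESPONDER for s in all_resp)
        none = generate_cohort(
            SimulationConfig(n_subjects_per_arm=10, responder_fraction=0.0, seed=1)
        )
        assert all(s.response is Response.NONRESPONDER for s in none)

    def test_planted_labels_roundtrip_through_madrs(self):
        """Re-deriving the label from the simulated scores via the clinical
        response rule reproduces the stored label for every subject."""
        cohort = generate_cohort(
            SimulationConfig(n_subjects_per_arm=129, responder_fraction=0.5, seed=7)
        )
        assert len(cohort) == 258
        for s in cohort:
            assert classify_response(s.madrs_t0, s.madrs_t8) is s.response

    def test_entry_criterion_baseline_at_least_22(self):
        cohort = generate_cohort(SimulationConfig(n_subjects_per_arm=50, seed=2))
        assert all(s.madrs_t0 >= 22 for s in cohort)

    def test_both_arms_present(self):
        cohort = generate_cohort(SimulationConfig(n_subjects_per_arm=5, seed=0))
        assert {s.arm.value for s in cohort} == {"drug", "placebo"}


class TestGenerateCounts:
    def test_marker_t8_t0_ratio_near_half_at_minus_one_log2fc(self):
        """With log2 FC -1 planted in responders, the empirical mean T8/T0
        ratio of marker miRNAs across 40 responder pairs is near 0.5."""
        cfg = SimulationConfig(
            n_subjects_per_arm=40,
            responder_fraction=1.0,
            n_mirnas=100,
            n_marker_mirnas=5,
            marker_log2fc=-1.0,
            seed=13,
        )
        cm = generate_counts(generate_cohort(cfg), cfg).restrict(arm="drug")
        meta = cm.sample_meta
        t0 = cm.counts[meta.index[meta["timepoint"] == "T0"]].mean(axis=1)
        t8 = cm.counts[meta.index[meta["timepoint"] == "T8"]].mean(axis=1)
        ratios = (t8 / t0)[marker_mirnas(cfg)]
        assert ((ratios > 0.4) & (ratios < 0.6)).all()

    def test_nonresponders_unshifted(self):
        cfg = SimulationConfig(
            n_subjects_per_arm=60,
            responder_fraction=0.0,
            n_mirnas=80,
            marker_log2fc=-1.0,
            seed=5,
        )
        cm = generate_counts(generate_cohort(cfg), cfg)
        meta = cm.sample_meta
        t0 = cm.counts[meta.index[meta["timepoint"] == "T0"]].mean(axis=1)
        t8 = cm.counts[meta.index[meta["timepoint"] == "T8"]].mean(axis=1)
        ratios = (t8 / t0)[marker_mirnas(cfg)]
        assert ((ratios > 0.8) & (ratios < 1.25)).all()

    def test_zero_dispersion_counts_equal_rounded_means(self):
        """In the dispersion -> 0 limit counts are deterministic, so the
        count matrix has (up to rounding) rank one within unshifted columns:
        cross-ratios of high-abundance rows agree across samples."""
        cfg = SimulationConfig(
            n_subjects_per_arm=6,
            n_mirnas=40,
            n_marker_mirnas=0,
            dispersion=0.0,
            library_size_mean=500_000,
            seed=3,
        )
        cm = generate_counts(generate_cohort(cfg), cfg)
        top = cm.counts.loc[cm.counts.mean(axis=1).nlargest(10).index].to_numpy(float)
        col_ratio = top / top[:, :1]
        expected = col_ratio.mean(axis=0, keepdims=True)
        assert np.allclose(col_ratio, expected, rtol=1e-3)

    def test_empty_cohort_rejected(self):
        with pytest.raises(InvalidConfigError):
            generate_counts([], SimulationConfig())


class TestGenerateExpression:
    def _study_parts(self, **overrides):
        params = dict(
            n_subjects_per_arm=40,
            responder_fraction=0.5,
            n_mirnas=50,
            n_marker_mirnas=4,
            n_genes=400,
            n_target_genes_per_marker=40,
            seed=21,
        )
        params.update(overrides)
        cfg = SimulationConfig(**params)
        cohort = generate_cohort(cfg)
        targets = true_target_map(cfg)
        mirna_expr = normalize(generate_counts(cohort, cfg)).values
        expr = generate_expression(cohort, targets, cfg, mirna_expr=mirna_expr)
        return cfg, cohort, targets, mirna_expr, expr

    def _responder_cols(self, cohort):
        return [
            f"{s.subject_id}_{tp}"
            for s in cohort
            if s.response is Response.RESPONDER
            for tp in ("T0", "T8")
        ]

    def test_planted_pairs_reach_target_correlation(self):
        cfg, cohort, targets, mirna_expr, expr = self._study_parts(
            target_correlation=-0.8, responder_fraction=1.0, n_subjects_per_arm=40
        )
        cols = self._responder_cols(cohort)
        anchors = target_anchors(cfg)
        hits = 0
        for gene, mu in anchors.items():
            r, _ = pearsonr(expr.loc[gene, cols], mirna_expr.loc[mu, cols])
            hits += 0.6 <= abs(r) <= 0.95
        assert hits >= 0.9 * len(anchors)

    def test_zero_correlation_is_null(self):
        cfg, cohort, targets, mirna_expr, expr = self._study_parts(
            target_correlation=0.0, responder_fraction=1.0
        )
        cols = self._responder_cols(cohort)
        anchors = target_anchors(cfg)
        sig = sum(
            pearsonr(expr.loc[g, cols], mirna_expr.loc[mu, cols])[1] < 0.05
            for g, mu in anchors.items()
        )
        assert sig <= 0.20 * len(anchors)  # ~5% expected, generous bound

    def test_no_responders_no_planted_correlation(self):
        cfg, cohort, targets, mirna_expr, expr = self._study_parts(
            target_correlation=-0.8, responder_fraction=0.0
        )
        cols = [f"{s.subject_id}_{tp}" for s in cohort for tp in ("T0", "T8")]
        anchors = target_anchors(cfg)
        rs = [
            abs(pearsonr(expr.loc[g, cols], mirna_expr.loc[mu, cols])[0])
            for g, mu in anchors.items()
        ]
        assert max(rs) < 0.5

    def test_unknown_target_mirna_rejected(self):
        cfg = SimulationConfig(n_subjects_per_arm=5, n_mirnas=10, seed=1)
        cohort = generate_cohort(cfg)
        mirna_expr = normalize(generate_counts(cohort, cfg)).values
        with pytest.raises(ConsistencyError):
            generate_expression(
                cohort, {"miR-ghost": frozenset({"GENE00001"})}, cfg, mirna_expr
            )


class TestPredictionSources:
    def test_perfect_sources_recover_exact_truth(self):
        cfg = SimulationConfig(
            n_genes=200,
            n_target_genes_per_marker=15,
            source_sensitivity=1.0,
            source_false_positive_rate=0.0,
            seed=4,
        )
        truth = true_target_map(cfg)
        tables = generate_prediction_sources(cfg, truth)
        result = consensus_targets(tables, list(truth), k=5, m=1)
        for mu, genes in truth.items():
            assert result.per_mirna[mu.lower()] == {g.upper() for g in genes}

    def test_zero_sensitivity_gives_empty_consensus(self):
        cfg = SimulationConfig(
            n_genes=100,
            source_sensitivity=0.0,
            source_false_positive_rate=0.0,
            seed=4,
        )
        truth = true_target_map(cfg)
        tables = generate_prediction_sources(cfg, truth)
        result = consensus_targets(tables, list(truth), k=5, m=1)
        assert result.union() == frozenset()

    def test_recovery_matches_binomial_tail(self):
        """Each true pair survives k=5-of-7 voting with probability
        P[Binom(7, 0.9) >= 5]; realized recovery stays within 5% of it."""
        cfg = SimulationConfig(
            n_genes=500,
            n_marker_mirnas=5,
            n_target_genes_per_marker=200,
            source_sensitivity=0.9,
            source_false_positive_rate=0.05,
            seed=8,
        )
        truth = true_target_map(cfg)
        tables = generate_prediction_sources(cfg, truth)
        result = consensus_targets(tables, list(truth), k=5, m=1)
        recovered = sum(
            g.upper() in result.per_mirna[mu.lower()]
            for mu, genes in truth.items()
            for g in genes
        )
        n_true = sum(len(g) for g in truth.values())
        tail = binom.sf(4, 7, 0.9)
        assert recovered / n_true >= tail - 0.05


class TestDeterminism:
    def test_identical_seed_bitwise_identical_outputs(self):
        cfg = SimulationConfig(
            n_subjects_per_arm=12, n_mirnas=30, n_genes=80,
            n_target_genes_per_marker=8, seed=99,
        )
        a, b = simulate_study(cfg), simulate_study(cfg)
        assert a.counts.counts.to_csv() == b.counts.counts.to_csv()
        assert a.gene_expr.to_csv() == b.gene_expr.to_csv()
        assert [t.pairs for t in a.sources] == [t.pairs for t in b.sources]
        assert a.pathways == b.pathways
        assert [s.madrs_t8 for s in a.cohort] == [s.madrs_t8 for s in b.cohort]

    def test_different_seeds_differ(self):
        base = dict(n_subjects_per_arm=12, n_mirnas=30, n_genes=80, n_target_genes_per_marker=8)
        a = simulate_study(SimulationConfig(seed=1, **base))
        b = simulate_study(SimulationConfig(seed=2, **base))
        assert a.counts.counts.to_csv() != b.counts.counts.to_csv()
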