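"""Clinical cohort model: response classification and cross-arm set algebra.

The trial design this package analyses is a randomized placebo-controlled
antidepressant study with paired blood draws at baseline (T0) and after eight
weeks of treatment (T8). Depression severity is scored on the
Montgomery-Asberg Depression Rating Scale (MADRS); a subject is a *responder*
when their MADRS score drops by strictly more than 50% from baseline.

Candidate response-marker miRNAs are derived by set algebra over the
per-arm, per-stratum lists of significantly changed miRNAs:

* shared candidates  = significant in drug responders AND placebo responders,
  minus any miRNA also significant in the *nonresponders* of both arms
  (such a miRNA tracks treatment exposure or time, not clinical outcome);
* drug-specific set  = significant in drug responders only.

The published significant-miRNA tables for the duloxetine trial (GEO
accession GSE97154) ship with the package and can be loaded with
:func:`load_duloxetine_trial_sets`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

from .errors import (
    IncompleteInputError,
    InvalidConfigError,
    UndefinedPercentChangeError,
)

__all__ = [
    "Arm",
    "Response",
    "SubjectRecord",
    "SignificantSet",
    "CandidateReport",
    "classify_response",
    "derive_candidates",
    "normalize_mirna_id",
    "load_duloxetine_trial_sets",
    "STUDY_COHORTS",
    "cohort_sample_count",
    "total_samples",
]


class Arm(str, Enum):
    """Treatment arm of the randomized trial."""

    DRUG = "drug"
    PLACEBO = "placebo"


class Response(str, Enum):
    """Treatment-outcome stratum derived from the MADRS change."""

    RESPONDER = "responder"
    NONRESPONDER = "nonresponder"


#: Sizes of the human cohorts analysed by the original study: subjects and
#: the number of timepoints sampled per subject. Paired blood cohorts
#: contribute 2 samples per subject; post-mortem brain tissue one.
STUDY_COHORTS: Mapping[str, Mapping[str, int]] = {
    "discovery": {"subjects": 258, "timepoints": 2},
    "replication_1": {"subjects": 61, "timepoints": 2},
    "replication_2": {"subjects": 158, "timepoints": 2},
    "postmortem_brain": {"subjects": 52, "timepoints": 1},
}


def cohort_sample_count(name: str) -> int:
    """Number of biological samples contributed by one study cohort."""
    c = STUDY_COHORTS[name]
    return c["subjects"] * c["timepoints"]


def total_samples() -> int:
    """Total human samples across all study cohorts."""
    return sum(cohort_sample_count(name) for name in STUDY_COHORTS)


def classify_response(madrs_t0: float, madrs_t8: float) -> Response:
    """Classify a subject as responder/nonresponder from MADRS scores.

    A responder shows a strictly greater than 50% decrease from baseline:
    ``(madrs_t0 - madrs_t8) / madrs_t0 > 0.5``. A decrease of exactly 50%
    is a nonresponder. The rule is scale-invariant: multiplying both scores
    by any positive constant leaves the label unchanged.

    Parameters
    ----------
    madrs_t0 : baseline MADRS score (points); must be > 0.
    madrs_t8 : post-treatment MADRS score (points); must be >= 0.

    Raises
    ------
    UndefinedPercentChangeError
        If ``madrs_t0`` is zero (percent change undefined).
    InvalidConfigError
        If either score is negative or non-finite.
    """
    if not (math.isfinite(madrs_t0) and math.isfinite(madrs_t8)):
        raise InvalidConfigError("MADRS scores must be finite")
    if madrs_t0 < 0 or madrs_t8 < 0:
        raise InvalidConfigError("MADRS scores must be non-negative")
    if madrs_t0 == 0:
        raise UndefinedPercentChangeError(
            "baseline MADRS is zero; percent change undefined"
        )
    decrease = (madrs_t0 - madrs_t8) / madrs_t0
    return Response.RESPONDER if decrease > 0.5 else Response.NONRESPONDER


@dataclass(frozen=True)
class SubjectRecord:
    """One trial participant with paired MADRS scores and derived label."""

    subject_id: str
    arm: Arm
    madrs_t0: float
    madrs_t8: float
    response: Response

    @classmethod
    def from_scores(
        cls, subject_id: str, arm: Arm | str, madrs_t0: float, madrs_t8: float
    ) -> "SubjectRecord":
        """Build a record, deriving the response label from the scores."""
        return cls(
            subject_id=subject_id,
            arm=Arm(arm),
            madrs_t0=float(madrs_t0),
            madrs_t8=float(madrs_t8),
            response=classify_response(madrs_t0, madrs_t8),
        )


def normalize_mirna_id(mirna_id: str) -> str:
    """Canonical miRNA key: lower-case, species prefix ("hsa-") stripped.

    Published tables mix spellings like ``miR-636`` and ``hsa-miR-636``;
    matching is case-insensitive after removing the species prefix.
    """
    s = mirna_id.strip()
    if s.lower().startswith(("hsa-", "mmu-")):
        s = s[4:]
    return s.lower()


@dataclass
class SignificantSet:
    """Significantly changed miRNAs for one (arm, stratum) cell.

    ``table`` has columns ``mirna``, ``fold_change`` (T8/T0 ratio, > 0 or
    NaN when unpublished) and ``adjusted_p`` (BH-corrected, in [0, 1] or
    NaN). Membership alone drives the set algebra; effect sizes are kept
    for reporting and direction-concordance checks.
    """

    arm: Arm
    stratum: Response
    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"mirna", "fold_change", "adjusted_p"}
        missing = required - set(self.table.columns)
        if missing:
            raise InvalidConfigError(f"significant-set table missing columns {missing}")
        fc = self.table["fold_change"]
        if ((fc <= 0) & fc.notna()).any():
            raise InvalidConfigError("fold changes must be > 0")
        ap = self.table["adjusted_p"]
        if (((ap < 0) | (ap > 1)) & ap.notna()).any():
            raise InvalidConfigError("adjusted P values must lie in [0, 1]")
        if self.table["mirna"].map(normalize_mirna_id).duplicated().any():
            raise InvalidConfigError("duplicate miRNA IDs in significant set")

    @property
    def mirnas(self) -> frozenset[str]:
        """Normalized miRNA keys in this set."""
        return frozenset(normalize_mirna_id(m) for m in self.table["mirna"])

    @property
    def display_names(self) -> dict[str, str]:
        """Map normalized key -> spelling used in the source table."""
        return {normalize_mirna_id(m): m for m in self.table["mirna"]}

    def fold_changes(self) -> dict[str, float]:
        return {
            normalize_mirna_id(m): fc
            for m, fc in zip(self.table["mirna"], self.table["fold_change"])
        }


@dataclass
class CandidateReport:
    """Result of the cross-arm candidate derivation.

    All sets hold normalized miRNA keys; ``display`` maps them back to the
    spelling of the input tables (drug-responder table preferred).
    """

    shared: frozenset[str]
    drug_specific: frozenset[str]
    excluded: frozenset[str]
    candidates: frozenset[str]
    cardinalities: dict[str, int]
    display: dict[str, str] = field(default_factory=dict)

    def display_names(self, keys: Iterable[str]) -> list[str]:
        return sorted(self.display.get(k, k) for k in keys)

    @property
    def candidate_names(self) -> list[str]:
        return self.display_names(self.candidates)


def derive_candidates(sets: Iterable[SignificantSet]) -> CandidateReport:
    """Cross-arm set algebra deriving candidate response-marker miRNAs.

    Requires a responder set for both arms; nonresponder sets are optional.
    Returns the responder intersection, the drug-specific difference, the
    miRNAs excluded for being significant in the nonresponders of *both*
    arms, and the final candidate set (intersection minus exclusions).

    A miRNA significant in only one arm's nonresponders is flagged with a
    warning but kept. Shared responder miRNAs whose fold changes disagree
    in direction between arms are likewise warned about, never dropped.
    """
    by_cell: dict[tuple[Arm, Response], SignificantSet] = {}
    for s in sets:
        key = (s.arm, s.stratum)
        if key in by_cell:
            raise IncompleteInputError(f"duplicate significant set for {key}")
        by_cell[key] = s

    for arm in (Arm.DRUG, Arm.PLACEBO):
        if (arm, Response.RESPONDER) not in by_cell:
            raise IncompleteInputError(f"missing responder set for arm '{arm.value}'")

    drug_resp = by_cell[(Arm.DRUG, Response.RESPONDER)]
    plac_resp = by_cell[(Arm.PLACEBO, Response.RESPONDER)]
    drug_nonresp = by_cell.get((Arm.DRUG, Response.NONRESPONDER))
    plac_nonresp = by_cell.get((Arm.PLACEBO, Response.NONRESPONDER))

    shared = drug_resp.mirnas & plac_resp.mirnas
    drug_specific = drug_resp.mirnas - plac_resp.mirnas

    dn = drug_nonresp.mirnas if drug_nonresp is not None else frozenset()
    pn = plac_nonresp.mirnas if plac_nonresp is not None else frozenset()
    excluded = frozenset(shared & dn & pn)
    one_arm_only = (shared & (dn ^ pn)) - excluded
    if one_arm_only:
        warnings.warn(
            "miRNA(s) significant in nonresponders of one arm only, kept as "
            f"candidates: {sorted(one_arm_only)}",
            stacklevel=2,
        )

    # direction concordance between arms on the shared set (sign of log FC)
    fc_drug = drug_resp.fold_changes()
    fc_plac = plac_resp.fold_changes()
    discordant = sorted(
        m
        for m in shared
        if not (math.isnan(fc_drug[m]) or math.isnan(fc_plac[m]))
        and (fc_drug[m] > 1.0) != (fc_plac[m] > 1.0)
    )
    if discordant:
        warnings.warn(
            f"shared miRNA(s) change in opposite directions between arms: {discordant}",
            stacklevel=2,
        )

    candidates = frozenset(shared - excluded)
    display = dict(plac_resp.display_names)
    display.update(drug_resp.display_names)  # drug spelling wins
    return CandidateReport(
        shared=frozenset(shared),
        drug_specific=frozenset(drug_specific),
        excluded=excluded,
        candidates=candidates,
        cardinalities={
            "drug_responder": len(drug_resp.mirnas),
            "placebo_responder": len(plac_resp.mirnas),
            "shared": len(shared),
            "drug_specific": len(drug_specific),
            "excluded": len(excluded),
            "candidates": len(candidates),
        },
        display=display,
    )


def _load_packaged_set(filename: str, arm: Arm, stratum: Response) -> SignificantSet:
    with resources.files("mirresponse.data").joinpath(filename).open() as fh:
        table = pd.read_csv(fh, sep="\t")
    return SignificantSet(arm=arm, stratum=stratum, table=table)


def load_duloxetine_trial_sets() -> dict[str, SignificantSet]:
    """Load the published significant-miRNA sets of the duloxetine trial.

    Returns the four (arm, stratum) cells keyed ``"drug_responder"``,
    ``"placebo_responder"``, ``"drug_nonresponder"``, ``"placebo_nonresponder"``.
    The responder tables carry published fold changes and adjusted P values;
    the nonresponder files record membership only (miR-503-5p, the one miRNA
    significant in nonresponders of both arms — its effect sizes were not
    published), with NaN effect columns.
    """
    return {
        "drug_responder": _load_packaged_set(
            "duloxetine_responders_significant.tsv", Arm.DRUG, Response.RESPONDER
        ),
        "placebo_responder": _load_packaged_set(
            "placebo_responders_significant.tsv", Arm.PLACEBO, Response.RESPONDER
        ),
        "drug_nonresponder": _load_packaged_set(
            "duloxetine_nonresponders_significant.tsv", Arm.DRUG, Response.NONRESPONDER
        ),
        "placebo_nonresponder": _load_packaged_set(
            "placebo_nonresponders_significant.tsv", Arm.PLACEBO, Response.NONRESPONDER
        ),
    }
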