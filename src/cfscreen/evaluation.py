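"""Screening test properties and Table-1-style strategy comparisons.

Conventions:

* A "referral" is a ``CF_REFERRAL`` outcome; ``CARRIER_REPORT`` is a
  secondary finding tallied on its own row and never counted as a false
  positive.
* Disease-positive defaults to any CF class (classical + non-classical);
  a classical-only definition is switchable, in which case referred
  non-classical newborns count as false positives by construction.
* Meconium-ileus cases are diagnosed clinically before screening reports
  and are excluded from sensitivity denominators by default (they stay in
  specificity bookkeeping as true positives/negatives like anyone else —
  they are diseased, so they never enter the specificity denominator).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .core import Phenotype
from .protocol import (
    Outcome,
    PilotStrategyConfig,
    PilotVariant,
    ProtocolConfig,
    Step,
    screen_cohort,
)

__all__ = [
    "DiseaseDefinition",
    "CohortSummary",
    "summarize",
    "compare_strategies",
    "summaries_to_frame",
    "STRATEGY_LABELS",
]


class DiseaseDefinition(str, enum.Enum):
    ANY_CF = "ANY_CF"
    CLASSICAL_ONLY = "CLASSICAL_ONLY"

    @property
    def phenotypes(self) -> frozenset[str]:
        if self is DiseaseDefinition.CLASSICAL_ONLY:
            return frozenset({Phenotype.CLASSICAL_CF.value})
        return frozenset(
            {Phenotype.CLASSICAL_CF.value, Phenotype.NON_CLASSICAL_CF.value}
        )


@dataclass(frozen=True)
class CohortSummary:
    """Cross-tabulated screening outcome counts plus test properties.

    ``sensitivity``/``ppv`` are NaN with the matching ``*_defined`` flag
    False when their denominator is empty.
    """

    strategy: str
    n_screened: int
    abnormal_results: int  # CF referrals (carrier reports excluded)
    classical_cf_detected: int
    non_classical_cf_detected: int
    carriers_reported: int
    false_positive_referrals: int
    sensitivity: float
    specificity: float
    ppv: float
    dna_tests_used: int
    ega_tests_used: int
    sensitivity_defined: bool = True
    ppv_defined: bool = True

    def as_dict(self) -> dict:
        return asdict(self)


def _ratio(num: int, den: int) -> tuple[float, bool]:
    if den == 0:
        return math.nan, False
    return num / den, True


def summarize(
    cohort: pd.DataFrame,
    results: pd.DataFrame,
    disease_definition: DiseaseDefinition = DiseaseDefinition.ANY_CF,
    exclude_meconium_ileus: bool = True,
    strategy: str = "",
) -> CohortSummary:
    """Summarise one strategy's results against the cohort's truth.

    ``cohort`` and ``results`` must cover exactly the same newborn ids.
    """
    if len(cohort) != len(results) or not np.array_equal(
        np.sort(cohort["id"].to_numpy()), np.sort(results["newborn_id"].to_numpy())
    ):
        raise ValueError("results do not align 1:1 with cohort ids")

    merged = cohort.merge(
        results, left_on="id", right_on="newborn_id", validate="one_to_one"
    )
    outcome = merged["outcome"].to_numpy()
    pheno = merged["phenotype"].to_numpy()
    referred = outcome == Outcome.CF_REFERRAL.value
    diseased = np.isin(pheno, list(disease_definition.phenotypes))
    meconium = merged["meconium_ileus"].to_numpy().astype(bool)

    sens_denominator = diseased & ~meconium if exclude_meconium_ileus else diseased
    detected_for_sens = int((referred & sens_denominator).sum())
    sensitivity, sens_defined = _ratio(detected_for_sens, int(sens_denominator.sum()))

    non_diseased = ~diseased
    false_pos = int((referred & non_diseased).sum())
    true_neg = int((~referred & non_diseased).sum())
    specificity, _ = _ratio(true_neg, true_neg + false_pos)

    true_pos_referrals = int((referred & diseased).sum())
    ppv, ppv_defined = _ratio(true_pos_referrals, int(referred.sum()))

    steps_s = merged["steps"].astype(str)
    dna_used = int(steps_s.str.contains(Step.PANEL.value, regex=False).sum())
    ega_used = int(steps_s.str.contains(Step.EGA.value, regex=False).sum())

    return CohortSummary(
        strategy=strategy,
        n_screened=len(merged),
        abnormal_results=int(referred.sum()),
        classical_cf_detected=int(
            (referred & (pheno == Phenotype.CLASSICAL_CF.value)).sum()
        ),
        non_classical_cf_detected=int(
            (referred & (pheno == Phenotype.NON_CLASSICAL_CF.value)).sum()
        ),
        carriers_reported=int((outcome == Outcome.CARRIER_REPORT.value).sum()),
        false_positive_referrals=false_pos,
        sensitivity=sensitivity,
        specificity=specificity,
        ppv=ppv,
        dna_tests_used=dna_used,
        ega_tests_used=ega_used,
        sensitivity_defined=sens_defined,
        ppv_defined=ppv_defined,
    )


STRATEGY_LABELS = ("pilot_irt_pap", "pilot_irt_dna_ega", "combined", "national")


def default_strategy_set(
    national: ProtocolConfig | None = None,
) -> dict[str, ProtocolConfig | PilotStrategyConfig]:
    return {
        "pilot_irt_pap": PilotStrategyConfig(variant=PilotVariant.IRT_PAP),
        "pilot_irt_dna_ega": PilotStrategyConfig(variant=PilotVariant.IRT_DNA_EGA),
        "combined": PilotStrategyConfig(variant=PilotVariant.COMBINED),
        "national": national or ProtocolConfig(),
    }


def compare_strategies(
    cohort: pd.DataFrame,
    strategies: dict[str, ProtocolConfig | PilotStrategyConfig] | None = None,
    disease_definition: DiseaseDefinition = DiseaseDefinition.ANY_CF,
    exclude_meconium_ileus: bool = True,
) -> dict[str, CohortSummary]:
    """Screen one cohort under every strategy and summarise each.

    The default strategy set is the two pilot strategies, their combined
    scenario (the DNA tiers applied only to IRT/PAP-positive samples,
    mirroring how the combined column of the pilot comparison was
    calculated), and the national four-step protocol.
    """
    if strategies is None:
        strategies = default_strategy_set()
    out: dict[str, CohortSummary] = {}
    for label, cfg in strategies.items():
        results = screen_cohort(cohort, cfg)
        out[label] = summarize(
            cohort,
            results,
            disease_definition=disease_definition,
            exclude_meconium_ileus=exclude_meconium_ileus,
            strategy=label,
        )
    return out


def summaries_to_frame(summaries: dict[str, CohortSummary]) -> pd.DataFrame:
    """Tabulate summaries with strategies as columns (Table-1 layout)."""
    frame = pd.DataFrame({k: v.as_dict() for k, v in summaries.items()})
    return frame.drop(index=["strategy"])
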