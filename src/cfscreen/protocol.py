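"""Screening strategy engines.

The national four-step protocol:

1. IRT on the heel-prick spot; below the cutoff (default 60 µg/l) stop.
2. PAP, with an IRT-dependent cutoff: 3.0 µg/l for IRT in [60, 100),
   1.6 µg/l for IRT >= 100.
3. Mutation panel on the same spot: two panel mutations refer immediately,
   one proceeds to sequencing, none is negative unless the failsafe fires
   (IRT >= 100 and PAP >= 1.6 sends panel-negative samples to sequencing,
   because a very strong biomarker signal with no common mutation suggests
   a rare, often migrant-ancestry, mutation).
4. Extended gene analysis (CFTR sequencing): two disease alleles refer,
   one is a reportable carrier finding (parents can opt out), none closes
   the case.

Two pilot-era strategies and their intersection are also provided: pure
IRT/PAP (a biochemical rule with no DNA), IRT followed directly by
panel+sequencing, and the combined scenario that applies the DNA tiers only
to IRT/PAP-positive samples.

Boundary conventions: positivity thresholds are inclusive (>=), negativity
strict (<); IRT exactly 100 takes the high-IRT PAP cutoff.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .core import AlleleState
from .population import Newborn

__all__ = [
    "Outcome",
    "Step",
    "PilotVariant",
    "ProtocolConfig",
    "PilotStrategyConfig",
    "ScreeningResult",
    "screen_national",
    "screen_pilot",
    "screen_cohort",
    "recalibrate_pap",
    "results_to_frame",
    "RESULT_COLUMNS",
]


class Outcome(str, enum.Enum):
    NEGATIVE = "NEGATIVE"
    CF_REFERRAL = "CF_REFERRAL"
    CARRIER_REPORT = "CARRIER_REPORT"
    NEGATIVE_AFTER_EGA = "NEGATIVE_AFTER_EGA"


class Step(str, enum.Enum):
    IRT = "IRT"
    PAP = "PAP"
    PANEL = "PANEL"
    EGA = "EGA"


class PilotVariant(str, enum.Enum):
    IRT_PAP = "IRT_PAP"
    IRT_DNA_EGA = "IRT_DNA_EGA"
    COMBINED = "COMBINED"


PAP_RECALIBRATION_FACTOR = Fraction(5, 3)


def recalibrate_pap(raw):
    """Correct a pre-2011 PAP value for the kit calibration error (x 5/3).

    The original kit calibrators assumed a 3 mm blood-spot punch holds 5 µl
    of blood; it holds 3 µl, so historical concentrations must be multiplied
    by 5/3.  Exact for Fraction input; ``raw * 5 / 3`` for floats (3.0 maps
    to exactly 5.0).
    """
    if raw < 0:
        raise ValueError(f"PAP concentration must be non-negative, got {raw}")
    if isinstance(raw, Fraction):
        return raw * PAP_RECALIBRATION_FACTOR
    return raw * 5.0 / 3.0


@dataclass(frozen=True)
class ProtocolConfig:
    """Cutoffs and rules of the national four-step protocol (µg/l)."""

    irt_cutoff: float = 60.0
    irt_high: float = 100.0
    pap_cutoff_mid: float = 3.0
    pap_cutoff_high: float = 1.6
    failsafe_enabled: bool = True
    carrier_reporting: bool = True
    ega_sensitivity: float = 1.0  # per-allele detection probability in step 4

    def __post_init__(self) -> None:
        if not 0 < self.irt_cutoff < self.irt_high:
            raise ValueError(
                f"need 0 < irt_cutoff < irt_high, got {self.irt_cutoff}, {self.irt_high}"
            )
        if self.pap_cutoff_high > self.pap_cutoff_mid:
            raise ValueError(
                "pap_cutoff_high must not exceed pap_cutoff_mid "
                f"(got {self.pap_cutoff_high} > {self.pap_cutoff_mid})"
            )
        if min(self.pap_cutoff_mid, self.pap_cutoff_high) < 0:
            raise ValueError("PAP cutoffs must be non-negative")
        if not 0.0 <= self.ega_sensitivity <= 1.0:
            raise ValueError("ega_sensitivity must lie in [0, 1]")


@dataclass(frozen=True)
class PilotStrategyConfig:
    """Pilot-era strategy thresholds (Table-1 style).

    PAP thresholds are stated on the pre-correction kit scale; when
    ``cohort_pap_is_corrected`` (the default, matching cohorts simulated on
    the modern scale) they are mapped through :func:`recalibrate_pap`
    before comparison.
    """

    variant: PilotVariant = PilotVariant.IRT_PAP
    irt_entry: float = 50.0
    irt_high: float = 100.0
    pap_entry: float = 1.8
    pap_high: float = 1.0
    cohort_pap_is_corrected: bool = True
    carrier_reporting: bool = True
    ega_sensitivity: float = 1.0

    def __post_init__(self) -> None:
        for name in ("irt_entry", "irt_high", "pap_entry", "pap_high"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def effective_pap_entry(self) -> float:
        return (
            recalibrate_pap(self.pap_entry)
            if self.cohort_pap_is_corrected
            else self.pap_entry
        )

    @property
    def effective_pap_high(self) -> float:
        return (
            recalibrate_pap(self.pap_high)
            if self.cohort_pap_is_corrected
            else self.pap_high
        )


@dataclass(frozen=True)
class ScreeningResult:
    """Per-newborn trace of one strategy run."""

    newborn_id: int
    steps: tuple[Step, ...]
    outcome: Outcome
    panel_mutations_found: int = 0
    ega_mutations_found: int = 0
    via_failsafe: bool = False


def _count_alleles(
    allele1: AlleleState, allele2: AlleleState
) -> tuple[int, int]:
    """(panel-detectable, total disease) allele counts."""
    panel = allele1.is_panel_detectable + allele2.is_panel_detectable
    disease = allele1.is_disease + allele2.is_disease
    return panel, disease


def _ega_detected(
    n_disease: int, sensitivity: float, rng: np.random.Generator | None
) -> int:
    if sensitivity >= 1.0:
        return n_disease
    if rng is None:
        raise ValueError("ega_sensitivity < 1 requires an rng")
    return int(rng.binomial(n_disease, sensitivity)) if n_disease else 0


def _terminal_after_ega(found: int, carrier_reporting: bool) -> Outcome:
    if found >= 2:
        return Outcome.CF_REFERRAL
    if found == 1:
        return Outcome.CARRIER_REPORT if carrier_reporting else Outcome.NEGATIVE_AFTER_EGA
    return Outcome.NEGATIVE_AFTER_EGA


def _screen_national_values(
    newborn_id: int,
    irt: float,
    pap: float,
    allele1: AlleleState,
    allele2: AlleleState,
    cfg: ProtocolConfig,
    rng: np.random.Generator | None = None,
) -> ScreeningResult:
    steps = [Step.IRT]
    if irt < cfg.irt_cutoff:
        return ScreeningResult(newborn_id, tuple(steps), Outcome.NEGATIVE)

    steps.append(Step.PAP)
    high_irt = irt >= cfg.irt_high
    pap_cut = cfg.pap_cutoff_high if high_irt else cfg.pap_cutoff_mid
    if pap < pap_cut:
        return ScreeningResult(newborn_id, tuple(steps), Outcome.NEGATIVE)

    steps.append(Step.PANEL)
    n_panel, n_disease = _count_alleles(allele1, allele2)
    if n_panel == 2:
        return ScreeningResult(
            newborn_id, tuple(steps), Outcome.CF_REFERRAL, panel_mutations_found=2
        )
    via_failsafe = False
    if n_panel == 0:
        failsafe_fires = (
            cfg.failsafe_enabled and high_irt and pap >= cfg.pap_cutoff_high
        )
        if not failsafe_fires:
            return ScreeningResult(
                newborn_id, tuple(steps), Outcome.NEGATIVE, panel_mutations_found=0
            )
        via_failsafe = True

    steps.append(Step.EGA)
    found = _ega_detected(n_disease, cfg.ega_sensitivity, rng)
    return ScreeningResult(
        newborn_id,
        tuple(steps),
        _terminal_after_ega(found, cfg.carrier_reporting),
        panel_mutations_found=n_panel,
        ega_mutations_found=found,
        via_failsafe=via_failsafe,
    )


def screen_national(
    newborn: Newborn,
    cfg: ProtocolConfig = ProtocolConfig(),
    rng: np.random.Generator | None = None,
) -> ScreeningResult:
    """Run the national four-step decision tree on one newborn."""
    return _screen_national_values(
        newborn.id, newborn.irt, newborn.pap, newborn.allele1, newborn.allele2, cfg, rng
    )


def _pilot_biochemical_positive(
    irt: float, pap: float, cfg: PilotStrategyConfig
) -> bool:
    return (irt >= cfg.irt_entry and pap >= cfg.effective_pap_entry) or (
        irt >= cfg.irt_high and pap >= cfg.effective_pap_high
    )


def _pilot_dna_tiers(
    newborn_id: int,
    steps: list[Step],
    allele1: AlleleState,
    allele2: AlleleState,
    cfg: PilotStrategyConfig,
    rng: np.random.Generator | None,
) -> ScreeningResult:
    """Panel + sequencing tiers shared by the DNA and combined variants."""
    steps.append(Step.PANEL)
    n_panel, n_disease = _count_alleles(allele1, allele2)
    if n_panel == 2:
        return ScreeningResult(
            newborn_id, tuple(steps), Outcome.CF_REFERRAL, panel_mutations_found=2
        )
    if n_panel == 0:  # pilot strategies have no failsafe
        return ScreeningResult(
            newborn_id, tuple(steps), Outcome.NEGATIVE, panel_mutations_found=0
        )
    steps.append(Step.EGA)
    found = _ega_detected(n_disease, cfg.ega_sensitivity, rng)
    return ScreeningResult(
        newborn_id,
        tuple(steps),
        _terminal_after_ega(found, cfg.carrier_reporting),
        panel_mutations_found=n_panel,
        ega_mutations_found=found,
    )


def _screen_pilot_values(
    newborn_id: int,
    irt: float,
    pap: float,
    allele1: AlleleState,
    allele2: AlleleState,
    cfg: PilotStrategyConfig,
    rng: np.random.Generator | None = None,
) -> ScreeningResult:
    if cfg.variant is PilotVariant.IRT_PAP:
        steps = [Step.IRT]
        if irt < cfg.irt_entry:
            return ScreeningResult(newborn_id, tuple(steps), Outcome.NEGATIVE)
        steps.append(Step.PAP)
        outcome = (
            Outcome.CF_REFERRAL
            if _pilot_biochemical_positive(irt, pap, cfg)
            else Outcome.NEGATIVE
        )
        return ScreeningResult(newborn_id, tuple(steps), outcome)

    if cfg.variant is PilotVariant.IRT_DNA_EGA:
        steps = [Step.IRT]
        if irt < cfg.irt_entry:
            return ScreeningResult(newborn_id, tuple(steps), Outcome.NEGATIVE)
        return _pilot_dna_tiers(newborn_id, steps, allele1, allele2, cfg, rng)

    if cfg.variant is PilotVariant.COMBINED:
        steps = [Step.IRT]
        if irt < cfg.irt_entry:
            return ScreeningResult(newborn_id, tuple(steps), Outcome.NEGATIVE)
        steps.append(Step.PAP)
        if not _pilot_biochemical_positive(irt, pap, cfg):
            return ScreeningResult(newborn_id, tuple(steps), Outcome.NEGATIVE)
        return _pilot_dna_tiers(newborn_id, steps, allele1, allele2, cfg, rng)

    raise ValueError(f"unknown pilot variant: {cfg.variant!r}")


def screen_pilot(
    newborn: Newborn,
    cfg: PilotStrategyConfig,
    rng: np.random.Generator | None = None,
) -> ScreeningResult:
    """Run one pilot-era strategy on one newborn."""
    return _screen_pilot_values(
        newborn.id, newborn.irt, newborn.pap, newborn.allele1, newborn.allele2, cfg, rng
    )


RESULT_COLUMNS = [
    "newborn_id",
    "steps",
    "outcome",
    "panel_found",
    "ega_found",
    "via_failsafe",
]


def screen_cohort(
    cohort: pd.DataFrame,
    strategy: ProtocolConfig | PilotStrategyConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Screen every newborn in a cohort table under one strategy.

    Returns one row per newborn, in cohort order; each row depends only on
    that newborn, so results are invariant to processing order.
    """
    national = isinstance(strategy, ProtocolConfig)
    records = []
    for row in cohort.itertuples(index=False):
        a1 = AlleleState(row.allele1)
        a2 = AlleleState(row.allele2)
        if national:
            res = _screen_national_values(
                int(row.id), row.irt_ugl, row.pap_ugl, a1, a2, strategy, rng
            )
        else:
            res = _screen_pilot_values(
                int(row.id), row.irt_ugl, row.pap_ugl, a1, a2, strategy, rng
            )
        records.append(
            (
                res.newborn_id,
                "|".join(s.value for s in res.steps),
                res.outcome.value,
                res.panel_mutations_found,
                res.ega_mutations_found,
                int(res.via_failsafe),
            )
        )
    return pd.DataFrame.from_records(records, columns=RESULT_COLUMNS)


def results_to_frame(results: list[ScreeningResult]) -> pd.DataFrame:
    """Convert ScreeningResult records to the tabular result layout."""
    return pd.DataFrame.from_records(
        [
            (
                r.newborn_id,
                "|".join(s.value for s in r.steps),
                r.outcome.value,
                r.panel_mutations_found,
                r.ega_mutations_found,
                int(r.via_failsafe),
            )
            for r in results
        ],
        columns=RESULT_COLUMNS,
    )
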