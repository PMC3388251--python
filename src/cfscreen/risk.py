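"""Autosomal-recessive carrier-risk calculus for genetic counselling.

When newborn screening reveals a healthy carrier child, the recurrence risk
for the parents' next pregnancies rises well above the population birth
prevalence.  With population carrier frequency c the allele frequency is
q = c/2, the birth prevalence q^2, and — in the Punnett-square formulation
used in Dutch counselling practice — the risk of a CF-affected child once a
carrier child is known is q/4 (for c = 1:30: 1/240 versus 1/3600, a
15-fold increase).

A conditional-probability treatment of the same situation (one parent is a
proven carrier; the partner transmits a mutant allele with probability q)
gives q/2 instead; both are exposed, under different names, and never
silently substituted for one another.

All operations preserve :class:`fractions.Fraction` inputs exactly, so the
headline values come out as exact rationals.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from fractions import Fraction
from numbers import Real

__all__ = [
    "ParentTest",
    "RiskInputs",
    "RiskResult",
    "allele_frequency",
    "birth_prevalence",
    "risk_given_carrier_child",
    "risk_given_carrier_child_conditional",
    "residual_carrier_probability",
    "full_risk_report",
]


def _check_prob(name: str, value) -> None:
    if not isinstance(value, Real):
        raise TypeError(f"{name} must be a real number, got {type(value).__name__}")
    if not 0 <= value <= 1:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


class ParentTest(str, enum.Enum):
    NONE = "NONE"
    PANEL_NEGATIVE = "PANEL_NEGATIVE"
    SEQUENCING_NEGATIVE = "SEQUENCING_NEGATIVE"


@dataclass(frozen=True)
class RiskInputs:
    """Inputs to the counselling report.

    ``panel_sensitivity`` is the probability that the parental test detects
    a mutant allele in a true carrier (for sequencing effectively 1.0; for
    a mutation panel the panel's coverage in the parent's ancestry group).
    """

    carrier_frequency: Fraction | float
    parent_test: ParentTest = ParentTest.NONE
    panel_sensitivity: Fraction | float = 1

    def __post_init__(self) -> None:
        _check_prob("carrier_frequency", self.carrier_frequency)
        _check_prob("panel_sensitivity", self.panel_sensitivity)


@dataclass(frozen=True)
class RiskResult:
    """Derived probabilities; exact rationals when inputs are rational."""

    allele_frequency: Fraction | float
    birth_prevalence: Fraction | float
    risk_given_carrier_child: Fraction | float
    residual_parent_carrier_prob: Fraction | float
    residual_risk_next_pregnancy: Fraction | float


def allele_frequency(carrier_frequency):
    """Allele frequency q = c/2 from a population carrier frequency c.

    (A carrier holds one mutant of two alleles, so half the carrier
    frequency, neglecting the rare affected homozygotes.)
    """
    _check_prob("carrier_frequency", carrier_frequency)
    return carrier_frequency / 2


def birth_prevalence(q):
    """Hardy–Weinberg birth prevalence q^2 of the recessive disease."""
    _check_prob("allele_frequency", q)
    return q * q


def risk_given_carrier_child(q):
    """Next-pregnancy CF risk after a carrier child: q/4 (Punnett-square form).

    This is the formulation used in the counselling literature (1/240 for
    q = 1/60).  See :func:`risk_given_carrier_child_conditional` for the
    conditional-probability alternative q/2.
    """
    _check_prob("allele_frequency", q)
    return q / 4


def risk_given_carrier_child_conditional(q):
    """Conditional treatment of the same risk: q/2.

    One parent is a proven carrier and transmits the mutant allele with
    probability 1/2; the partner transmits a mutant allele with probability
    approximately q.  This differs from :func:`risk_given_carrier_child` by
    a factor of 2 and is exposed for users who prefer the fully
    conditioned derivation.
    """
    _check_prob("allele_frequency", q)
    return q / 2


def residual_carrier_probability(prior, sensitivity):
    """Posterior carrier probability after a negative test.

    Bayes update over the four (carrier?, detected?) outcomes::

        P(carrier | negative) = p(1-s) / (p(1-s) + 1 - p)

    Monotone decreasing in the test sensitivity s; equals the prior at
    s = 0 and 0 at s = 1.  The degenerate prior = 1, s = 1 case returns 0
    by the limit convention (a certain carrier certainly tests positive).
    """
    _check_prob("prior", prior)
    _check_prob("sensitivity", sensitivity)
    numerator = prior * (1 - sensitivity)
    denominator = numerator + (1 - prior)
    if denominator == 0:
        return prior * 0  # limit convention, type-preserving zero
    return numerator / denominator


def full_risk_report(inputs: RiskInputs) -> RiskResult:
    """Compose the counselling quantities from the component operations.

    With no parental test the partner's carrier probability is the
    population carrier frequency and the next-pregnancy risk is the
    headline q/4.  A negative parental test shrinks the partner carrier
    probability by the Bayes update, and the next-pregnancy risk is
    recomputed through the same q/4 rule on the residual allele frequency.
    """
    c = inputs.carrier_frequency
    q = allele_frequency(c)
    if inputs.parent_test is ParentTest.NONE:
        residual = c
    else:
        residual = residual_carrier_probability(c, inputs.panel_sensitivity)
    return RiskResult(
        allele_frequency=q,
        birth_prevalence=birth_prevalence(q),
        risk_given_carrier_child=risk_given_carrier_child(q),
        residual_parent_carrier_prob=residual,
        residual_risk_next_pregnancy=risk_given_carrier_child(
            allele_frequency(residual)
        ),
    )
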