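"""Shared domain vocabulary for the screening simulator.

CF is autosomal recessive: two CFTR disease alleles give disease (classical
or a milder non-classical form), one gives healthy carrier status.  The
mutation panel used in tier 3 of the screening protocol recognises only a
fixed set of common mutations, so each disease allele is either
panel-detectable or not; extended gene analysis (sequencing) sees all of
them.
"""

from __future__ import annotations

import enum


class AlleleState(str, enum.Enum):
    """State of one CFTR allele.

    ``PANEL_MUTATION`` and ``NON_PANEL_MUTATION`` are both disease alleles;
    only the former is visible to the tier-3 mutation panel.
    """

    WILDTYPE = "WILDTYPE"
    PANEL_MUTATION = "PANEL_MUTATION"
    NON_PANEL_MUTATION = "NON_PANEL_MUTATION"

    @property
    def is_disease(self) -> bool:
        return self is not AlleleState.WILDTYPE

    @property
    def is_panel_detectable(self) -> bool:
        return self is AlleleState.PANEL_MUTATION


class Phenotype(str, enum.Enum):
    UNAFFECTED = "UNAFFECTED"
    CARRIER = "CARRIER"
    CLASSICAL_CF = "CLASSICAL_CF"
    NON_CLASSICAL_CF = "NON_CLASSICAL_CF"

    @property
    def is_cf(self) -> bool:
        return self in (Phenotype.CLASSICAL_CF, Phenotype.NON_CLASSICAL_CF)


#: Fixed phenotype order used wherever phenotypes index an array.
PHENOTYPE_ORDER: tuple[Phenotype, ...] = (
    Phenotype.UNAFFECTED,
    Phenotype.CARRIER,
    Phenotype.CLASSICAL_CF,
    Phenotype.NON_CLASSICAL_CF,
)


class Marker(str, enum.Enum):
    """Dried-blood-spot biomarkers, both in µg/l."""

    IRT = "IRT"
    PAP = "PAP"
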