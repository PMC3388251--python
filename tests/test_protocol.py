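"""Protocol engine: decision-tree semantics against an independent oracle."""

import itertools
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cfscreen import (
    AlleleState,
    Newborn,
    Outcome,
    Phenotype,
    PilotStrategyConfig,
    PilotVariant,
    ProtocolConfig,
    Step,
    recalibrate_pap,
    screen_cohort,
    screen_national,
    screen_pilot,
)

W = AlleleState.WILDTYPE
P = AlleleState.PANEL_MUTATION
N = AlleleState.NON_PANEL_MUTATION


def make_newborn(irt, pap, a1=W, a2=W, newborn_id=0):
    n_disease = a1.is_disease + a2.is_disease
    phenotype = {
        0: Phenotype.UNAFFECTED,
        1: Phenotype.CARRIER,
        2: Phenotype.CLASSICAL_CF,
    }[n_disease]
    return Newborn(
        id=newborn_id,
        stratum="test",
        allele1=a1,
        allele2=a2,
        phenotype=phenotype,
        meconium_ileus=False,
        irt=irt,
        pap=pap,
    )


def four_step_oracle(irt, pap, a1, a2):
    """Hand-written truth table of the national tree, fixed cutoffs.

    Written independently of the engine, with the published constants
    inlined: negative below IRT 60; negative below PAP 3.0 (IRT 60-100) or
    1.6 (IRT >= 100); two panel mutations refer; one goes to sequencing;
    none goes to sequencing only via the failsafe (IRT >= 100, PAP >= 1.6);
    sequencing refers on two disease alleles, reports a carrier on one.
    """
    if irt < 60.0:
        return Outcome.NEGATIVE
    if irt < 100.0:
        if pap < 3.0:
            return Outcome.NEGATIVE
    else:
        if pap < 1.6:
            return Outcome.NEGATIVE
    panel = (a1 is P) + (a2 is P)
    disease = (a1 is not W) + (a2 is not W)
    if panel == 2:
        return Outcome.CF_REFERRAL
    if panel == 0 and not (irt >= 100.0 and pap >= 1.6):
        return Outcome.NEGATIVE
    # sequencing sees every disease allele
    if disease == 2:
        return Outcome.CF_REFERRAL
    if disease == 1:
        return Outcome.CARRIER_REPORT
    return Outcome.NEGATIVE_AFTER_EGA


BOUNDARY_IRT = [59.0, 60.0, 99.0, 100.0, 101.0]
BOUNDARY_PAP = [1.5, 1.6, 2.9, 3.0]
ALLELE_PAIRS = list(itertools.product([W, P, N], repeat=2))


class TestNationalProtocol:
    @pytest.mark.parametrize("irt", BOUNDARY_IRT)
    @pytest.mark.parametrize("pap", BOUNDARY_PAP)
    @pytest.mark.parametrize("alleles", ALLELE_PAIRS)
    def test_matches_truth_table_on_boundary_grid(self, irt, pap, alleles):
        """Engine output equals the hand-enumerated Fig-1-style oracle on
        every boundary combination, including IRT=100 and PAP=1.6 edges."""
        a1, a2 = alleles
        result = screen_national(make_newborn(irt, pap, a1, a2))
        assert result.outcome is four_step_oracle(irt, pap, a1, a2)

    def test_low_irt_negative_after_one_step(self):
        result = screen_national(make_newborn(55.0, 10.0, P, P))
        assert result.outcome is Outcome.NEGATIVE
        assert result.steps == (Step.IRT,)

    def test_mid_band_pap_below_cutoff_negative(self):
        result = screen_national(make_newborn(70.0, 2.9, P, P))
        assert result.outcome is Outcome.NEGATIVE
        assert result.steps == (Step.IRT, Step.PAP)

    def test_failsafe_catches_non_panel_cf(self):
        """IRT 120, PAP 1.7, both alleles outside the panel: sequencing via
        the failsafe still refers."""
        result = screen_national(make_newborn(120.0, 1.7, N, N))
        assert result.outcome is Outcome.CF_REFERRAL
        assert result.via_failsafe
        assert result.steps == (Step.IRT, Step.PAP, Step.PANEL, Step.EGA)
        assert result.panel_mutations_found == 0
        assert result.ega_mutations_found == 2

    def test_single_panel_allele_becomes_carrier_report(self):
        result = screen_national(make_newborn(80.0, 3.5, P, W))
        assert result.outcome is Outcome.CARRIER_REPORT
        assert result.steps == (Step.IRT, Step.PAP, Step.PANEL, Step.EGA)
        assert result.panel_mutations_found == 1
        assert result.ega_mutations_found == 1

    def test_failsafe_on_wildtype_ends_negative_after_ega(self):
        result = screen_national(make_newborn(120.0, 1.7, W, W))
        assert result.outcome is Outcome.NEGATIVE_AFTER_EGA
        assert result.via_failsafe

    def test_two_panel_mutations_refer_without_ega(self):
        result = screen_national(make_newborn(120.0, 5.0, P, P))
        assert result.outcome is Outcome.CF_REFERRAL
        assert Step.EGA not in result.steps

    def test_carrier_opt_out_relabels_report(self):
        cfg = ProtocolConfig(carrier_reporting=False)
        result = screen_national(make_newborn(80.0, 3.5, P, W), cfg)
        assert result.outcome is Outcome.NEGATIVE_AFTER_EGA

    def test_disabled_failsafe_misses_non_panel_cf(self):
        cfg = ProtocolConfig(failsafe_enabled=False)
        result = screen_national(make_newborn(120.0, 1.7, N, N), cfg)
        assert result.outcome is Outcome.NEGATIVE

    def test_no_dna_below_irt_cutoff(self):
        """Cost contract: sub-cutoff IRT never consumes a DNA test."""
        for irt in (1.0, 30.0, 59.999):
            result = screen_national(make_newborn(irt, 100.0, P, P))
            assert Step.PANEL not in result.steps
            assert Step.EGA not in result.steps

    @given(
        irt=st.floats(1.0, 300.0),
        pap=st.floats(0.0, 30.0),
        a1=st.sampled_from([W, P, N]),
        a2=st.sampled_from([W, P, N]),
        delta=st.floats(0.1, 39.0),  # keep the cutoff below irt_high
    )
    @settings(derandomize=True, max_examples=200)
    def test_raising_irt_cutoff_never_creates_positives(self, irt, pap, a1, a2, delta):
        """Threshold monotonicity, pointwise per newborn."""
        newborn = make_newborn(irt, pap, a1, a2)
        base = screen_national(newborn, ProtocolConfig(irt_cutoff=60.0))
        raised = screen_national(newborn, ProtocolConfig(irt_cutoff=60.0 + delta))
        if base.outcome is Outcome.NEGATIVE:
            assert raised.outcome is Outcome.NEGATIVE

    @given(
        irt=st.floats(1.0, 300.0),
        pap=st.floats(0.0, 30.0),
        a1=st.sampled_from([W, P, N]),
        a2=st.sampled_from([W, P, N]),
    )
    @settings(derandomize=True, max_examples=200)
    def test_failsafe_monotonicity(self, irt, pap, a1, a2):
        """Enabling the failsafe never loses a CF referral and never
        changes the outcome when the panel already saw a mutation."""
        newborn = make_newborn(irt, pap, a1, a2)
        without = screen_national(newborn, ProtocolConfig(failsafe_enabled=False))
        with_fs = screen_national(newborn, ProtocolConfig(failsafe_enabled=True))
        if without.outcome is Outcome.CF_REFERRAL:
            assert with_fs.outcome is Outcome.CF_REFERRAL
        if (a1 is P) + (a2 is P) >= 1:
            assert with_fs.outcome is without.outcome


class TestPilotStrategies:
    def test_irt_pap_first_clause(self):
        cfg = PilotStrategyConfig(
            variant=PilotVariant.IRT_PAP, cohort_pap_is_corrected=False
        )
        assert screen_pilot(make_newborn(55.0, 1.9), cfg).outcome is Outcome.CF_REFERRAL

    def test_irt_pap_second_clause(self):
        cfg = PilotStrategyConfig(
            variant=PilotVariant.IRT_PAP, cohort_pap_is_corrected=False
        )
        assert screen_pilot(make_newborn(102.0, 1.1), cfg).outcome is Outcome.CF_REFERRAL

    def test_below_entry_negative_under_all_variants(self):
        for variant in PilotVariant:
            cfg = PilotStrategyConfig(variant=variant)
            result = screen_pilot(make_newborn(49.9, 100.0, P, P), cfg)
            assert result.outcome is Outcome.NEGATIVE

    def test_corrected_scale_thresholds(self):
        """On a post-correction cohort the pilot PAP cutoff 1.8 acts at 3.0."""
        cfg = PilotStrategyConfig(variant=PilotVariant.IRT_PAP)
        assert cfg.effective_pap_entry == pytest.approx(3.0)
        assert screen_pilot(make_newborn(55.0, 2.9), cfg).outcome is Outcome.NEGATIVE
        assert screen_pilot(make_newborn(55.0, 3.0), cfg).outcome is Outcome.CF_REFERRAL

    def test_dna_strategy_ignores_pap(self):
        cfg = PilotStrategyConfig(variant=PilotVariant.IRT_DNA_EGA)
        result = screen_pilot(make_newborn(55.0, 0.0, P, P), cfg)
        assert result.outcome is Outcome.CF_REFERRAL
        assert Step.PAP not in result.steps

    def test_dna_strategy_reports_carriers(self):
        cfg = PilotStrategyConfig(variant=PilotVariant.IRT_DNA_EGA)
        result = screen_pilot(make_newborn(55.0, 0.0, P, W), cfg)
        assert result.outcome is Outcome.CARRIER_REPORT

    def test_combined_requires_both_rules(self):
        cfg = PilotStrategyConfig(variant=PilotVariant.COMBINED)
        # passes IRT/PAP but has no panel mutation -> negative (no failsafe)
        assert screen_pilot(make_newborn(120.0, 9.0, N, N), cfg).outcome is Outcome.NEGATIVE
        # fails IRT/PAP despite panel genotype -> negative
        assert screen_pilot(make_newborn(70.0, 0.1, P, P), cfg).outcome is Outcome.NEGATIVE
        # passes both -> referral
        assert screen_pilot(make_newborn(120.0, 9.0, P, P), cfg).outcome is Outcome.CF_REFERRAL


class TestRecalibratePap:
    def test_exact_values(self):
        assert recalibrate_pap(3.0) == 5.0
        assert recalibrate_pap(0.0) == 0.0
        assert recalibrate_pap(1.8) == pytest.approx(3.0, abs=1e-15)
        assert recalibrate_pap(Fraction(9, 5)) == Fraction(3)

    def test_exact_rational_factor(self):
        assert recalibrate_pap(Fraction(3)) == Fraction(5)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            recalibrate_pap(-0.1)


class TestScreenCohort:
    def test_empty_cohort_gives_empty_results(self, small_cohort):
        results = screen_cohort(small_cohort.iloc[:0], ProtocolConfig())
        assert len(results) == 0

    def test_order_invariance(self, small_cohort):
        head = small_cohort.head(500)
        forward = screen_cohort(head, ProtocolConfig())
        backward = screen_cohort(head.iloc[::-1], ProtocolConfig())
        merged = forward.set_index("newborn_id").join(
            backward.set_index("newborn_id"), lsuffix="_f", rsuffix="_b"
        )
        assert (merged["outcome_f"] == merged["outcome_b"]).all()
        assert (merged["steps_f"] == merged["steps_b"]).all()

    def test_determinism(self, small_cohort):
        a = screen_cohort(small_cohort, ProtocolConfig())
        b = screen_cohort(small_cohort, ProtocolConfig())
        assert a.equals(b)


class TestConfigValidation:
    def test_cutoff_ordering_enforced(self):
        with pytest.raises(ValueError):
            ProtocolConfig(irt_cutoff=100.0, irt_high=60.0)
        with pytest.raises(ValueError):
            ProtocolConfig(pap_cutoff_mid=1.0, pap_cutoff_high=2.0)

    def test_reduced_ega_sensitivity_requires_rng(self):
        cfg = ProtocolConfig(ega_sensitivity=0.9)
        with pytest.raises(ValueError):
            screen_national(make_newborn(80.0, 3.5, P, W), cfg)
        rng = np.random.default_rng(0)
        result = screen_national(make_newborn(80.0, 3.5, P, W), cfg, rng)
        assert result.ega_mutations_found in (0, 1)
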