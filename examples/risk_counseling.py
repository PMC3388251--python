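"""Carrier-risk calculus after screening finds a healthy carrier child.

With a population carrier frequency of 1:30 the allele frequency is 1:60
and the CF birth prevalence 1/3600.  Once a child is known to be a carrier,
the parents' next-pregnancy risk jumps to 1/240 — fifteen times the
population prevalence — and a negative parental test shrinks it again.
"""

from fractions import Fraction

from cfscreen import ParentTest, RiskInputs, full_risk_report

untested = full_risk_report(RiskInputs(Fraction(1, 30)))
print("No parental testing:")
print(f"  allele frequency            : {untested.allele_frequency}")
print(f"  birth prevalence            : {untested.birth_prevalence}")
print(f"  risk after a carrier child  : {untested.risk_given_carrier_child}")
print(f"  fold increase over baseline : "
      f"{untested.risk_given_carrier_child / untested.birth_prevalence}")

panel = full_risk_report(
    RiskInputs(Fraction(1, 30), ParentTest.PANEL_NEGATIVE, Fraction(95, 100))
)
print("\nAfter a negative parental mutation panel (sensitivity 95%):")
print(f"  residual partner carrier probability : {panel.residual_parent_carrier_prob}"
      f" = {float(panel.residual_parent_carrier_prob):.6f}")
print(f"  residual next-pregnancy risk         : {panel.residual_risk_next_pregnancy}"
      f" = {float(panel.residual_risk_next_pregnancy):.2e}")
print("  (sequencing, sensitivity ~1, would drive this to ~0, far below the"
      " population prevalence)")
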