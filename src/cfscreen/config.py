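"""Configuration loading, validation, and the annotated default file.

One YAML file configures the whole pipeline: population (strata, cohort
size, seed), biomarker model (tail constraints + per-class log-normal
parameters) and protocol cutoffs.  Validation aggregates every problem
into a single field-addressed report instead of failing on the first.

Probabilities may be written as decimals or as rational strings like
"1/30".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import yaml

from .biomarkers import (
    BiomarkerModel,
    ClassParams,
    DEFAULT_CARRIER_IRT_MEDIAN_RATIO,
    TailConstraint,
    default_biomarker_model,
)
from .core import Marker, Phenotype
from .population import (
    AncestryStratum,
    DEFAULT_FRACTION_NON_CLASSICAL,
    DEFAULT_MECONIUM_ILEUS_RATE,
    DEFAULT_STRATA,
    PopulationConfig,
)
from .protocol import ProtocolConfig

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "default_run_config",
    "render_default_config",
    "write_default_config",
    "parse_probability",
]


class ConfigError(ValueError):
    """Aggregated, field-addressed configuration problems."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__(
            "invalid configuration:\n" + "\n".join(f"  - {p}" for p in problems)
        )


def parse_probability(value) -> float:
    """Accept 0.0333 or '1/30'."""
    if isinstance(value, str):
        return float(Fraction(value))
    return float(value)


@dataclass(frozen=True)
class RunConfig:
    population: PopulationConfig
    biomarkers: BiomarkerModel
    protocol: ProtocolConfig


def default_run_config(cohort_size: int = 200_000, seed: int = 0) -> RunConfig:
    return RunConfig(
        population=PopulationConfig(cohort_size=cohort_size, seed=seed),
        biomarkers=default_biomarker_model(),
        protocol=ProtocolConfig(),
    )


def _build_population(raw: dict, problems: list[str]) -> PopulationConfig | None:
    strata = []
    for i, s in enumerate(raw.get("strata") or []):
        try:
            strata.append(
                AncestryStratum(
                    name=str(s["name"]),
                    fraction_of_births=parse_probability(s["fraction_of_births"]),
                    carrier_frequency=parse_probability(s["carrier_frequency"]),
                    panel_detectability=parse_probability(s["panel_detectability"]),
                )
            )
        except (KeyError, TypeError, ValueError, ZeroDivisionError) as exc:
            problems.append(f"population.strata[{i}]: {exc}")
    try:
        return PopulationConfig(
            cohort_size=int(raw.get("cohort_size", 200_000)),
            strata=tuple(strata) if strata else DEFAULT_STRATA,
            fraction_non_classical_given_cf=parse_probability(
                raw.get("fraction_non_classical_given_cf", DEFAULT_FRACTION_NON_CLASSICAL)
            ),
            meconium_ileus_rate_given_cf=parse_probability(
                raw.get("meconium_ileus_rate_given_cf", DEFAULT_MECONIUM_ILEUS_RATE)
            ),
            seed=int(raw.get("seed", 0)),
        )
    except (TypeError, ValueError) as exc:
        problems.append(f"population: {exc}")
        return None


def _build_biomarkers(raw: dict, problems: list[str]) -> BiomarkerModel | None:
    try:
        constraints = tuple(
            TailConstraint(
                threshold=float(c["threshold_ugl"]),
                exceedance_probability=parse_probability(c["exceedance_probability"]),
            )
            for c in raw.get("irt_tail_constraints")
            or [
                {"threshold_ugl": 50.0, "exceedance_probability": 0.0243},
                {"threshold_ugl": 60.0, "exceedance_probability": 0.0103},
            ]
        )
        if len(constraints) != 2:
            raise ValueError("exactly two IRT tail constraints are required")
        model = default_biomarker_model(
            irt_tail_constraints=constraints,  # type: ignore[arg-type]
            carrier_irt_median_ratio=float(
                raw.get("carrier_irt_median_ratio", DEFAULT_CARRIER_IRT_MEDIAN_RATIO)
            ),
            log_correlation=float(raw.get("log_correlation", 0.0)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        problems.append(f"biomarkers: {exc}")
        return None

    overrides: dict[tuple[Phenotype, Marker], ClassParams] = {}
    for cls_name, markers in (raw.get("classes") or {}).items():
        for marker_name, params in (markers or {}).items():
            key = f"biomarkers.classes.{cls_name}.{marker_name}"
            try:
                phenotype = Phenotype(cls_name)
                marker = Marker(marker_name)
                if "median_ugl" in params:
                    mu = math.log(float(params["median_ugl"]))
                else:
                    mu = float(params["mu_log"])
                overrides[(phenotype, marker)] = ClassParams(
                    mu=mu, sigma=float(params["sigma_log"])
                )
            except (KeyError, TypeError, ValueError) as exc:
                problems.append(f"{key}: {exc}")
    return model.with_params(overrides) if overrides else model


def _build_protocol(raw: dict, problems: list[str]) -> ProtocolConfig | None:
    try:
        return ProtocolConfig(
            irt_cutoff=float(raw.get("irt_cutoff_ugl", 60.0)),
            irt_high=float(raw.get("irt_high_ugl", 100.0)),
            pap_cutoff_mid=float(raw.get("pap_cutoff_mid_ugl", 3.0)),
            pap_cutoff_high=float(raw.get("pap_cutoff_high_ugl", 1.6)),
            failsafe_enabled=bool(raw.get("failsafe_enabled", True)),
            carrier_reporting=bool(raw.get("carrier_reporting", True)),
            ega_sensitivity=float(raw.get("ega_sensitivity", 1.0)),
        )
    except (TypeError, ValueError) as exc:
        problems.append(f"protocol: {exc}")
        return None


def load_config(path) -> RunConfig:
    """Load and fully validate a YAML run configuration.

    Raises :class:`ConfigError` listing every detected problem with its
    field address; nothing is simulated from a config that fails here.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(["top level must be a mapping"])

    problems: list[str] = []
    population = _build_population(raw.get("population") or {}, problems)
    biomarkers = _build_biomarkers(raw.get("biomarkers") or {}, problems)
    protocol = _build_protocol(raw.get("protocol") or {}, problems)
    if problems:
        raise ConfigError(problems)
    assert population is not None and biomarkers is not None and protocol is not None
    return RunConfig(population=population, biomarkers=biomarkers, protocol=protocol)


def render_default_config(cohort_size: int = 200_000, seed: int = 0) -> str:
    """The annotated default configuration as YAML text."""
    return f"""\
# cfscreen run configuration (annotated defaults).
# Probabilities may be decimals or rational strings such as "1/30".

population:
  cohort_size: {cohort_size}        # newborns to simulate
  seed: {seed}                   # root seed; all randomness derives from it
  # P(non-classical | two disease alleles); assumption, not a published value
  fraction_non_classical_given_cf: 0.28
  # 4 meconium-ileus diagnoses per 29 CF births per year
  meconium_ileus_rate_given_cf: "4/29"
  strata:                   # fractions must sum to 1
    - name: dutch_general
      fraction_of_births: 0.90
      carrier_frequency: "1/30"
      panel_detectability: 0.95   # assumption: panel covers "all common" mutations
    - name: turkish
      fraction_of_births: 0.05
      carrier_frequency: "1/50"
      panel_detectability: 0.44   # published panel sensitivity, Turkish ancestry
    - name: north_african
      fraction_of_births: 0.05
      carrier_frequency: "1/50"
      panel_detectability: 0.69   # published panel sensitivity, North African ancestry

biomarkers:
  # The unaffected IRT log-normal is solved from these two published
  # population quantiles; everything else is a documented default.
  irt_tail_constraints:
    - {{threshold_ugl: 50.0, exceedance_probability: 0.0243}}
    - {{threshold_ugl: 60.0, exceedance_probability: 0.0103}}
  carrier_irt_median_ratio: 1.15  # carriers run mildly elevated IRT
  log_correlation: 0.0            # IRT-PAP log-scale correlation within class
  classes:                        # medians in ug/l, sigmas on the log scale
    CLASSICAL_CF:
      IRT: {{median_ugl: 130.0, sigma_log: 0.40}}
      PAP: {{median_ugl: 14.0, sigma_log: 0.60}}
    NON_CLASSICAL_CF:
      IRT: {{median_ugl: 105.0, sigma_log: 0.45}}
      PAP: {{median_ugl: 10.0, sigma_log: 0.60}}
    UNAFFECTED:
      PAP: {{median_ugl: 0.4, sigma_log: 0.85}}
    CARRIER:
      PAP: {{median_ugl: 0.4, sigma_log: 0.85}}

protocol:                         # national four-step cutoffs, ug/l
  irt_cutoff_ugl: 60.0
  irt_high_ugl: 100.0
  pap_cutoff_mid_ugl: 3.0        # applies when 60 <= IRT < 100
  pap_cutoff_high_ugl: 1.6       # applies when IRT >= 100
  failsafe_enabled: true         # panel-negative + IRT>=100 + PAP>=1.6 -> sequencing
  carrier_reporting: true        # parents may opt out: set false
  ega_sensitivity: 1.0           # per-allele detection probability of sequencing
"""


def write_default_config(path, cohort_size: int = 200_000, seed: int = 0) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(render_default_config(cohort_size=cohort_size, seed=seed))
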