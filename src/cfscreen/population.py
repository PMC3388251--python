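"""Synthetic newborn cohorts with CFTR genotype and ancestry structure.

Genotypes follow Hardy–Weinberg sampling: within a stratum with carrier
frequency c, each allele is independently a disease allele with probability
q = c/2, and each disease allele is independently panel-detectable with the
stratum's detectability.  Ancestry strata capture the screening-relevant
heterogeneity: migrant strata have lower carrier frequency but far lower
panel detectability, which is what the protocol's failsafe exists for.

Cohorts are plain pandas DataFrames with a fixed column set and a lossless
TSV representation, so simulated and user-supplied cohorts are
interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biomarkers import BiomarkerModel
from .core import AlleleState, Phenotype, PHENOTYPE_ORDER

__all__ = [
    "AncestryStratum",
    "Newborn",
    "PopulationConfig",
    "CohortFormatError",
    "DEFAULT_STRATA",
    "DEFAULT_FRACTION_NON_CLASSICAL",
    "DEFAULT_MECONIUM_ILEUS_RATE",
    "COHORT_COLUMNS",
    "sample_genotype",
    "generate_cohort",
    "generate_affected_cohort",
    "write_cohort",
    "read_cohort",
]

COHORT_COLUMNS = [
    "id",
    "stratum",
    "allele1",
    "allele2",
    "phenotype",
    "meconium_ileus",
    "irt_ugl",
    "pap_ugl",
]


class CohortFormatError(ValueError):
    """Raised for malformed cohort tables, naming the offending row."""


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class AncestryStratum:
    """One ancestry group with its own carrier frequency and panel coverage.

    ``panel_detectability`` is the per-allele probability that a disease
    allele belongs to the mutation panel (allele-level, so patient-level
    panel sensitivity emerges from the two alleles independently).
    """

    name: str
    fraction_of_births: float
    carrier_frequency: float
    panel_detectability: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("stratum name must be non-empty")
        _check_prob("fraction_of_births", self.fraction_of_births)
        _check_prob("carrier_frequency", self.carrier_frequency)
        _check_prob("panel_detectability", self.panel_detectability)

    @property
    def allele_frequency(self) -> float:
        return self.carrier_frequency / 2.0


#: Shipped strata: general Dutch population plus the two migrant groups
#: whose low panel detectability motivates the failsafe.  The general-panel
#: detectability 0.95 is an assumption (the panel covers "all common"
#: mutations without a published figure) and is configurable.
DEFAULT_STRATA: tuple[AncestryStratum, ...] = (
    AncestryStratum("dutch_general", 0.90, 1.0 / 30.0, 0.95),
    AncestryStratum("turkish", 0.05, 1.0 / 50.0, 0.44),
    AncestryStratum("north_african", 0.05, 1.0 / 50.0, 0.69),
)

DEFAULT_FRACTION_NON_CLASSICAL = 0.28
#: 4 meconium-ileus diagnoses per 25 screened CF patients per year.
DEFAULT_MECONIUM_ILEUS_RATE = 4.0 / 29.0


@dataclass(frozen=True)
class Newborn:
    """One simulated newborn with genotype, phenotype and biomarkers."""

    id: int
    stratum: str
    allele1: AlleleState
    allele2: AlleleState
    phenotype: Phenotype
    meconium_ileus: bool
    irt: float  # µg/l
    pap: float  # µg/l

    def __post_init__(self) -> None:
        n_disease = self.allele1.is_disease + self.allele2.is_disease
        expected = {
            0: (Phenotype.UNAFFECTED,),
            1: (Phenotype.CARRIER,),
            2: (Phenotype.CLASSICAL_CF, Phenotype.NON_CLASSICAL_CF),
        }[n_disease]
        if self.phenotype not in expected:
            raise ValueError(
                f"phenotype {self.phenotype.value} inconsistent with "
                f"{n_disease} disease allele(s)"
            )
        if self.meconium_ileus and not self.phenotype.is_cf:
            raise ValueError("meconium_ileus requires a CF phenotype")
        if not self.irt > 0:
            raise ValueError(f"irt must be positive, got {self.irt}")
        if not self.pap >= 0:
            raise ValueError(f"pap must be non-negative, got {self.pap}")

    @property
    def n_disease_alleles(self) -> int:
        return self.allele1.is_disease + self.allele2.is_disease

    @property
    def n_panel_alleles(self) -> int:
        return self.allele1.is_panel_detectable + self.allele2.is_panel_detectable


@dataclass(frozen=True)
class PopulationConfig:
    """Cohort-level simulation settings."""

    cohort_size: int
    strata: tuple[AncestryStratum, ...] = DEFAULT_STRATA
    fraction_non_classical_given_cf: float = DEFAULT_FRACTION_NON_CLASSICAL
    meconium_ileus_rate_given_cf: float = DEFAULT_MECONIUM_ILEUS_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cohort_size < 1:
            raise ValueError(f"cohort_size must be >= 1, got {self.cohort_size}")
        if not self.strata:
            raise ValueError("at least one stratum is required")
        object.__setattr__(self, "strata", tuple(self.strata))
        total = sum(s.fraction_of_births for s in self.strata)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(
                f"stratum fractions must sum to 1 (got {total!r})"
            )
        _check_prob(
            "fraction_non_classical_given_cf", self.fraction_non_classical_given_cf
        )
        _check_prob(
            "meconium_ileus_rate_given_cf", self.meconium_ileus_rate_given_cf
        )


def sample_genotype(
    stratum: AncestryStratum, rng: np.random.Generator
) -> tuple[AlleleState, AlleleState]:
    """Draw one genotype under Hardy–Weinberg within a stratum.

    Each allele is a disease allele with probability q = carrier_frequency/2,
    and each disease allele is independently PANEL_MUTATION with the
    stratum's panel detectability.  Always consumes four uniforms so the
    stream layout does not depend on the outcome.
    """
    q = stratum.allele_frequency
    u = rng.random(4)
    alleles = []
    for u_mut, u_panel in ((u[0], u[1]), (u[2], u[3])):
        if u_mut < q:
            alleles.append(
                AlleleState.PANEL_MUTATION
                if u_panel < stratum.panel_detectability
                else AlleleState.NON_PANEL_MUTATION
            )
        else:
            alleles.append(AlleleState.WILDTYPE)
    return alleles[0], alleles[1]


def _assemble(
    ids: np.ndarray,
    stratum_idx: np.ndarray,
    strata: tuple[AncestryStratum, ...],
    mut1: np.ndarray,
    panel1: np.ndarray,
    mut2: np.ndarray,
    panel2: np.ndarray,
    u_nc: np.ndarray,
    u_mi: np.ndarray,
    frac_nc: float,
    mi_rate: float,
    model: BiomarkerModel,
    z: np.ndarray,
) -> pd.DataFrame:
    """Turn raw per-newborn draws into the canonical cohort DataFrame."""
    n_disease = mut1.astype(np.int8) + mut2.astype(np.int8)
    codes = np.zeros(len(ids), dtype=np.int64)  # UNAFFECTED
    codes[n_disease == 1] = 1  # CARRIER
    is_cf = n_disease == 2
    non_classical = is_cf & (u_nc < frac_nc)
    codes[is_cf] = 2  # CLASSICAL_CF
    codes[non_classical] = 3  # NON_CLASSICAL_CF
    meconium = is_cf & (u_mi < mi_rate)

    irt, pap = model.sample_given_normals(codes, z)

    def allele_labels(mut: np.ndarray, panel: np.ndarray) -> np.ndarray:
        out = np.full(len(ids), AlleleState.WILDTYPE.value, dtype=object)
        out[mut & panel] = AlleleState.PANEL_MUTATION.value
        out[mut & ~panel] = AlleleState.NON_PANEL_MUTATION.value
        return out

    stratum_names = np.array([s.name for s in strata], dtype=object)
    phenotype_labels = np.array([p.value for p in PHENOTYPE_ORDER], dtype=object)
    return pd.DataFrame(
        {
            "id": ids.astype(np.int64),
            "stratum": stratum_names[stratum_idx],
            "allele1": allele_labels(mut1, panel1),
            "allele2": allele_labels(mut2, panel2),
            "phenotype": phenotype_labels[codes],
            "meconium_ileus": meconium.astype(np.int8),
            "irt_ugl": irt,
            "pap_ugl": pap,
        }
    )


def _stage_streams(seed: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-newborn randomness as fixed-width rows of two stage streams.

    Row i of the uniform matrix and of the normal matrix together form
    newborn i's private sub-stream, so cohort content is invariant to
    generation order and prefix-stable when the cohort grows.
    """
    root = np.random.SeedSequence(seed)
    ss_u, ss_z = root.spawn(2)
    u = np.random.default_rng(ss_u).random((n, 7))
    z = np.random.default_rng(ss_z).standard_normal((n, 2))
    return u, z


def generate_cohort(config: PopulationConfig, model: BiomarkerModel) -> pd.DataFrame:
    """Generate a full birth cohort as a DataFrame with COHORT_COLUMNS.

    Deterministic under a fixed (config, model): same seed gives a
    bit-identical table.
    """
    model.require_calibrated()
    n = config.cohort_size
    u, z = _stage_streams(config.seed, n)

    fractions = np.array([s.fraction_of_births for s in config.strata])
    cum = np.cumsum(fractions)
    cum[-1] = 1.0  # guard the float edge
    stratum_idx = np.searchsorted(cum, u[:, 0], side="right")

    q = np.array([s.allele_frequency for s in config.strata])[stratum_idx]
    det = np.array([s.panel_detectability for s in config.strata])[stratum_idx]
    mut1 = u[:, 1] < q
    panel1 = u[:, 2] < det
    mut2 = u[:, 3] < q
    panel2 = u[:, 4] < det

    return _assemble(
        np.arange(n),
        stratum_idx,
        config.strata,
        mut1,
        panel1 & mut1,
        mut2,
        panel2 & mut2,
        u[:, 5],
        u[:, 6],
        config.fraction_non_classical_given_cf,
        config.meconium_ileus_rate_given_cf,
        model,
        z,
    )


def generate_affected_cohort(
    config: PopulationConfig, n_cases: int, model: BiomarkerModel
) -> pd.DataFrame:
    """Generate newborns conditioned on carrying two disease alleles.

    Strata are sampled with probability proportional to
    fraction_of_births x allele_frequency^2, i.e. the distribution of
    ancestry among affected births, so the plain detected fraction in this
    cohort estimates population-level sensitivity among CF births.  Used to
    study sensitivity without simulating millions of unaffected newborns.
    """
    model.require_calibrated()
    if n_cases < 1:
        raise ValueError(f"n_cases must be >= 1, got {n_cases}")
    u, z = _stage_streams(config.seed, n_cases)

    weights = np.array(
        [s.fraction_of_births * s.allele_frequency**2 for s in config.strata]
    )
    if weights.sum() <= 0:
        raise ValueError("no stratum can produce an affected newborn")
    cum = np.cumsum(weights / weights.sum())
    cum[-1] = 1.0
    stratum_idx = np.searchsorted(cum, u[:, 0], side="right")

    det = np.array([s.panel_detectability for s in config.strata])[stratum_idx]
    ones = np.ones(n_cases, dtype=bool)
    panel1 = u[:, 1] < det
    panel2 = u[:, 2] < det

    return _assemble(
        np.arange(n_cases),
        stratum_idx,
        config.strata,
        ones,
        panel1,
        ones,
        panel2,
        u[:, 3],
        u[:, 4],
        config.fraction_non_classical_given_cf,
        config.meconium_ileus_rate_given_cf,
        model,
        z,
    )


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort to tab-separated UTF-8 with 10 significant digits."""
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise CohortFormatError(f"cohort is missing columns: {missing}")
    cohort.to_csv(
        path,
        sep="\t",
        index=False,
        columns=COHORT_COLUMNS,
        float_format="%.10g",
        encoding="utf-8",
    )


_ALLELE_LABELS = {a.value for a in AlleleState}
_PHENOTYPE_LABELS = {p.value for p in Phenotype}


def validate_cohort(df: pd.DataFrame) -> None:
    """Check every cohort invariant, raising with a 1-based data-row number."""
    if list(df.columns) != COHORT_COLUMNS:
        raise CohortFormatError(
            f"expected columns {COHORT_COLUMNS}, got {list(df.columns)}"
        )
    if len(df) == 0:
        return

    def fail_first(bad_mask: np.ndarray, message: str) -> None:
        if bad_mask.any():
            row = int(np.flatnonzero(bad_mask)[0]) + 1
            raise CohortFormatError(f"row {row}: {message}")

    fail_first(~df["allele1"].isin(_ALLELE_LABELS).to_numpy(), "unknown allele1 label")
    fail_first(~df["allele2"].isin(_ALLELE_LABELS).to_numpy(), "unknown allele2 label")
    fail_first(
        ~df["phenotype"].isin(_PHENOTYPE_LABELS).to_numpy(), "unknown phenotype label"
    )
    fail_first(~df["meconium_ileus"].isin([0, 1]).to_numpy(), "meconium_ileus not 0/1")
    irt = df["irt_ugl"].to_numpy(dtype=float)
    pap = df["pap_ugl"].to_numpy(dtype=float)
    fail_first(~(irt > 0) | ~np.isfinite(irt), "irt_ugl must be positive and finite")
    fail_first(~(pap >= 0) | ~np.isfinite(pap), "pap_ugl must be non-negative and finite")

    n_disease = (
        (df["allele1"] != AlleleState.WILDTYPE.value).to_numpy().astype(int)
        + (df["allele2"] != AlleleState.WILDTYPE.value).to_numpy().astype(int)
    )
    pheno = df["phenotype"].to_numpy()
    is_cf = np.isin(pheno, [Phenotype.CLASSICAL_CF.value, Phenotype.NON_CLASSICAL_CF.value])
    expected_cf = n_disease == 2
    expected_carrier = n_disease == 1
    fail_first(is_cf & ~expected_cf, "CF phenotype without two disease alleles")
    fail_first(
        (pheno == Phenotype.CARRIER.value) & ~expected_carrier,
        "CARRIER phenotype without exactly one disease allele",
    )
    fail_first(
        (pheno == Phenotype.UNAFFECTED.value) & (n_disease > 0),
        "UNAFFECTED phenotype with disease alleles",
    )
    fail_first(
        (df["meconium_ileus"].to_numpy() == 1) & ~is_cf,
        "meconium_ileus set for a non-CF phenotype",
    )


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort TSV written by :func:`write_cohort`."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            encoding="utf-8",
            dtype={
                "id": np.int64,
                "stratum": object,
                "allele1": object,
                "allele2": object,
                "phenotype": object,
                "meconium_ileus": np.int8,
                "irt_ugl": float,
                "pap_ugl": float,
            },
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise CohortFormatError(f"malformed cohort file {path}: {exc}") from exc
    validate_cohort(df)
    return df


def cohort_to_newborns(df: pd.DataFrame) -> list[Newborn]:
    """Materialise a cohort table as validated :class:`Newborn` records."""
    return [
        Newborn(
            id=int(r.id),
            stratum=r.stratum,
            allele1=AlleleState(r.allele1),
            allele2=AlleleState(r.allele2),
            phenotype=Phenotype(r.phenotype),
            meconium_ileus=bool(r.meconium_ileus),
            irt=float(r.irt_ugl),
            pap=float(r.pap_ugl),
        )
        for r in df.itertuples(index=False)
    ]
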