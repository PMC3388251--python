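"""Genotype-conditional IRT and PAP concentration models.

Both markers are modelled log-normally within each phenotype class.  The
unaffected IRT distribution is not chosen freely: it is calibrated so that
its upper tail reproduces two published population quantiles (by default
2.43% of newborns at or above 50 µg/l and 1.03% at or above 60 µg/l).  Two
tail constraints pin down the two log-normal parameters exactly::

    log(t_i) = mu + z_i * sigma,   z_i = Phi^{-1}(1 - p_i)

The affected-class parameters cannot be anchored to published population
quantiles and are shipped as documented defaults (see docs/methods.md for
the calibration argument behind them).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from .core import Marker, Phenotype, PHENOTYPE_ORDER

__all__ = [
    "TailConstraint",
    "ClassParams",
    "BiomarkerModel",
    "CalibrationError",
    "ModelNotCalibratedError",
    "calibrate_unaffected_irt",
    "default_biomarker_model",
    "sample_biomarkers",
    "DEFAULT_IRT_TAIL_CONSTRAINTS",
]


class CalibrationError(ValueError):
    """Raised when tail constraints cannot define a log-normal."""


class ModelNotCalibratedError(RuntimeError):
    """Raised when sampling from a model whose calibration never ran."""


@dataclass(frozen=True)
class TailConstraint:
    """One exceedance constraint: P(X >= threshold) = exceedance_probability."""

    threshold: float  # µg/l
    exceedance_probability: float

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError(f"threshold must be positive, got {self.threshold}")
        if not 0.0 < self.exceedance_probability < 1.0:
            raise ValueError(
                "exceedance_probability must lie in (0, 1), got "
                f"{self.exceedance_probability}"
            )


#: Published unaffected-population IRT quantiles used for calibration.
DEFAULT_IRT_TAIL_CONSTRAINTS: tuple[TailConstraint, TailConstraint] = (
    TailConstraint(50.0, 0.0243),
    TailConstraint(60.0, 0.0103),
)


def calibrate_unaffected_irt(
    c1: TailConstraint, c2: TailConstraint
) -> tuple[float, float]:
    """Solve for the (mu, sigma) of a log-normal hitting two tail constraints.

    Returns log-scale mean and standard deviation such that
    ``P(X >= c.threshold) == c.exceedance_probability`` for both constraints.

    Raises :class:`CalibrationError` for degenerate or non-monotone
    constraints (a proper survival function must decrease with the
    threshold).
    """
    lo, hi = sorted((c1, c2), key=lambda c: c.threshold)
    if lo.threshold == hi.threshold:
        raise CalibrationError("constraints must use two distinct thresholds")
    if lo.exceedance_probability <= hi.exceedance_probability:
        raise CalibrationError(
            "non-monotone tail: the larger threshold must have the smaller "
            f"exceedance probability (got {lo} and {hi})"
        )
    z_lo = norm.ppf(1.0 - lo.exceedance_probability)
    z_hi = norm.ppf(1.0 - hi.exceedance_probability)
    sigma = (math.log(hi.threshold) - math.log(lo.threshold)) / (z_hi - z_lo)
    mu = math.log(lo.threshold) - z_lo * sigma
    return mu, sigma


@dataclass(frozen=True)
class ClassParams:
    """Log-scale location and scale of one (phenotype, marker) pair.

    sigma == 0 is allowed as the degenerate point-mass limit at exp(mu).
    """

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mu):
            raise ValueError(f"mu must be finite, got {self.mu}")
        if not (math.isfinite(self.sigma) and self.sigma >= 0.0):
            raise ValueError(f"sigma must be finite and >= 0, got {self.sigma}")

    @property
    def median(self) -> float:
        return math.exp(self.mu)

    def tail_probability(self, threshold: float) -> float:
        """P(X >= threshold) under this log-normal."""
        if threshold <= 0:
            return 1.0
        if self.sigma == 0.0:
            return 1.0 if self.median >= threshold else 0.0
        return float(norm.sf((math.log(threshold) - self.mu) / self.sigma))


# Shipped defaults for the classes that published quantiles cannot anchor.
# Medians in µg/l; sigmas on the log scale.  See docs/methods.md.
_DEFAULT_CLASS_MEDIANS_SIGMAS: dict[tuple[Phenotype, Marker], tuple[float, float]] = {
    (Phenotype.CLASSICAL_CF, Marker.IRT): (130.0, 0.40),
    (Phenotype.NON_CLASSICAL_CF, Marker.IRT): (105.0, 0.45),
    (Phenotype.CLASSICAL_CF, Marker.PAP): (14.0, 0.60),
    (Phenotype.NON_CLASSICAL_CF, Marker.PAP): (10.0, 0.60),
    (Phenotype.UNAFFECTED, Marker.PAP): (0.4, 0.85),
    (Phenotype.CARRIER, Marker.PAP): (0.4, 0.85),
}

#: Carriers run mildly elevated IRT; default median ratio over unaffected.
DEFAULT_CARRIER_IRT_MEDIAN_RATIO = 1.15


@dataclass
class BiomarkerModel:
    """Per-class, per-marker log-normal parameters plus calibration state.

    IRT and PAP are conditionally independent given the phenotype class by
    default; ``log_correlation`` injects a common log-scale Gaussian
    correlation if the user wants coupled markers.
    """

    params: dict[tuple[Phenotype, Marker], ClassParams] = field(default_factory=dict)
    log_correlation: float = 0.0
    calibrated: bool = False

    def __post_init__(self) -> None:
        if not -1.0 <= self.log_correlation <= 1.0:
            raise ValueError(
                f"log_correlation must lie in [-1, 1], got {self.log_correlation}"
            )

    def require_calibrated(self) -> None:
        if not self.calibrated:
            raise ModelNotCalibratedError(
                "biomarker model is not calibrated; build it with "
                "default_biomarker_model() or set every class parameter and "
                "mark it calibrated"
            )

    def class_params(self, phenotype: Phenotype, marker: Marker) -> ClassParams:
        try:
            return self.params[(phenotype, marker)]
        except KeyError:
            raise KeyError(f"no parameters for ({phenotype.value}, {marker.value})")

    def tail_probability(
        self, phenotype: Phenotype, marker: Marker, threshold: float
    ) -> float:
        """P(marker >= threshold | phenotype) under the model."""
        return self.class_params(phenotype, marker).tail_probability(threshold)

    def with_params(
        self, updates: dict[tuple[Phenotype, Marker], ClassParams]
    ) -> "BiomarkerModel":
        merged = dict(self.params)
        merged.update(updates)
        return replace(self, params=merged)

    def _arrays(self, marker: Marker) -> tuple[np.ndarray, np.ndarray]:
        """(mu, sigma) arrays indexed by PHENOTYPE_ORDER position."""
        mus = np.array([self.params[(p, marker)].mu for p in PHENOTYPE_ORDER])
        sigmas = np.array([self.params[(p, marker)].sigma for p in PHENOTYPE_ORDER])
        return mus, sigmas

    def sample_given_normals(
        self, phenotype_codes: np.ndarray, z: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised biomarker draw from standard normals.

        ``phenotype_codes`` indexes :data:`PHENOTYPE_ORDER`; ``z`` is an
        (n, 2) array of independent standard normals, one column per marker.
        Returns (irt, pap) arrays in µg/l.
        """
        self.require_calibrated()
        mu_i, sd_i = self._arrays(Marker.IRT)
        mu_p, sd_p = self._arrays(Marker.PAP)
        rho = self.log_correlation
        z_irt = z[:, 0]
        z_pap = rho * z[:, 0] + math.sqrt(1.0 - rho * rho) * z[:, 1]
        irt = np.exp(mu_i[phenotype_codes] + sd_i[phenotype_codes] * z_irt)
        pap = np.exp(mu_p[phenotype_codes] + sd_p[phenotype_codes] * z_pap)
        return irt, pap


def default_biomarker_model(
    irt_tail_constraints: tuple[TailConstraint, TailConstraint] = DEFAULT_IRT_TAIL_CONSTRAINTS,
    carrier_irt_median_ratio: float = DEFAULT_CARRIER_IRT_MEDIAN_RATIO,
    log_correlation: float = 0.0,
) -> BiomarkerModel:
    """Build the shipped model: calibrated unaffected IRT plus defaults.

    The unaffected IRT parameters are solved from the two tail constraints;
    the carrier IRT shares sigma with a median shifted by
    ``carrier_irt_median_ratio``; the remaining classes use the shipped
    default medians and sigmas.
    """
    mu_u, sigma_u = calibrate_unaffected_irt(*irt_tail_constraints)
    params: dict[tuple[Phenotype, Marker], ClassParams] = {
        (Phenotype.UNAFFECTED, Marker.IRT): ClassParams(mu_u, sigma_u),
        (Phenotype.CARRIER, Marker.IRT): ClassParams(
            mu_u + math.log(carrier_irt_median_ratio), sigma_u
        ),
    }
    for key, (median, sigma) in _DEFAULT_CLASS_MEDIANS_SIGMAS.items():
        params[key] = ClassParams(math.log(median), sigma)
    return BiomarkerModel(
        params=params, log_correlation=log_correlation, calibrated=True
    )


def sample_biomarkers(
    phenotype: Phenotype, model: BiomarkerModel, rng: np.random.Generator
) -> tuple[float, float]:
    """Draw one (IRT, PAP) pair in µg/l for a newborn of the given class."""
    model.require_calibrated()
    code = PHENOTYPE_ORDER.index(phenotype)
    z = rng.standard_normal(2).reshape(1, 2)
    irt, pap = model.sample_given_normals(np.array([code]), z)
    return float(irt[0]), float(pap[0])
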