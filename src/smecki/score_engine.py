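"""Coefficient sets and the S-MECKI logistic scoring rule.

The MECKI score predicts the 2-year composite endpoint (cardiovascular
death, urgent heart transplant, or LVAD implantation) in HFrEF patients
from six covariates measured at enrolment: peak VO2 as a percent of
predicted, the VE/VCO2 slope, hemoglobin, serum sodium, LVEF, and MDRD
eGFR.  The sex-recalibrated variant (S-MECKI) keeps the same logistic
functional form but uses a separate intercept and separate covariate
weights for women and men:

    esp  = intercept + sum_i beta_i * x_i        (the linear predictor)
    risk = exp(esp) / (1 + exp(esp))

This module holds the two published sex-specific coefficient sets at
full printed precision, evaluates the linear predictor and the event
probability, and computes standardized coefficients (beta times the
covariate's standard deviation).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Mapping

import numpy as np
import yaml
from scipy.special import expit, logit  # noqa: F401  (logit re-exported for round-trips)

logger = logging.getLogger(__name__)

#: Canonical covariate order used everywhere a coefficient vector appears.
COVARIATES: tuple[str, ...] = (
    "peakvo2_pct",
    "vevco2_slope",
    "hb",
    "na",
    "lvef",
    "mdrd",
)

#: Coefficient vector order: intercept first, then the six betas.
COEFFICIENT_NAMES: tuple[str, ...] = ("intercept",) + COVARIATES


class Sex(str, Enum):
    """Patient sex as recorded in the registry schema."""

    F = "F"
    M = "M"


# Plausibility bands used for warnings only; the score applies no exclusions.
_PLAUSIBILITY = {
    "lvef": (0.0, 100.0),
    "hb": (0.0, math.inf),
    "mdrd": (0.0, math.inf),
    "na": (100.0, 160.0),
    "vevco2_slope": (0.0, math.inf),
    "peakvo2_pct": (0.0, math.inf),
}


@dataclass(frozen=True)
class PatientRecord:
    """One patient's six score covariates, sex, and binary 2-year event.

    Units: ``lvef`` percent, ``hb`` g/dl, ``mdrd`` ml/min/1.73 m^2,
    ``na`` mmol/L, ``vevco2_slope`` dimensionless, ``peakvo2_pct``
    percent of the predicted peak VO2.
    """

    sex: Sex
    lvef: float
    hb: float
    mdrd: float
    na: float
    vevco2_slope: float
    peakvo2_pct: float
    event: int = 0
    id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex(self.sex))
        for name in COVARIATES:
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"covariate {name!r} is not finite: {value!r}")
            lo, hi = _PLAUSIBILITY[name]
            if not (lo <= value <= hi):
                logger.warning(
                    "covariate %s=%g outside plausibility band [%g, %g]",
                    name, value, lo, hi,
                )
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event!r}")

    def covariate_vector(self) -> np.ndarray:
        """Covariates in canonical order, as a length-6 float array."""
        return np.array([getattr(self, name) for name in COVARIATES], dtype=float)


@dataclass(frozen=True)
class CoefficientSet:
    """Intercept plus six covariate weights of one logistic scoring rule.

    ``sex_label`` is ``"F"``, ``"M"``, or ``"pooled"`` (a single rule fit
    to both sexes, the comparator for the recalibrated score).
    """

    sex_label: str
    intercept: float
    beta_peakvo2_pct: float
    beta_vevco2: float
    beta_hb: float
    beta_na: float
    beta_lvef: float
    beta_mdrd: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.sex_label not in ("F", "M", "pooled"):
            raise ValueError(f"sex_label must be F, M or pooled, got {self.sex_label!r}")
        for value in self.as_vector():
            if not math.isfinite(value):
                raise ValueError("all seven coefficients must be finite")

    def as_vector(self) -> np.ndarray:
        """(intercept, beta_peakvo2_pct, beta_vevco2, beta_hb, beta_na,
        beta_lvef, beta_mdrd) as a length-7 float array."""
        return np.array(
            [
                self.intercept,
                self.beta_peakvo2_pct,
                self.beta_vevco2,
                self.beta_hb,
                self.beta_na,
                self.beta_lvef,
                self.beta_mdrd,
            ],
            dtype=float,
        )

    @classmethod
    def from_vector(
        cls, vector, sex_label: str = "pooled", provenance: str = ""
    ) -> "CoefficientSet":
        v = np.asarray(vector, dtype=float)
        if v.shape != (7,):
            raise ValueError(f"coefficient vector must have length 7, got shape {v.shape}")
        return cls(sex_label, *v, provenance=provenance)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "CoefficientSet":
        return cls(**dict(data))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CoefficientSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CoefficientSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


#: Published S-MECKI coefficients for women, at full printed precision.
FEMALE_COEFFICIENTS = CoefficientSet(
    sex_label="F",
    intercept=4.1116831,
    beta_peakvo2_pct=-0.0341452,
    beta_vevco2=0.0252531,
    beta_hb=-0.1724513,
    beta_na=-0.0175751,
    beta_lvef=-0.0279113,
    beta_mdrd=-0.0090766,
    provenance="published S-MECKI female weights",
)

#: Published S-MECKI coefficients for men, at full printed precision.
MALE_COEFFICIENTS = CoefficientSet(
    sex_label="M",
    intercept=9.790738,
    beta_peakvo2_pct=-0.0472631,
    beta_vevco2=0.0285722,
    beta_hb=-0.0789262,
    beta_na=-0.0597067,
    beta_lvef=-0.0368194,
    beta_mdrd=-0.0110881,
    provenance="published S-MECKI male weights",
)

BUILTIN_COEFFICIENTS: dict[Sex, CoefficientSet] = {
    Sex.F: FEMALE_COEFFICIENTS,
    Sex.M: MALE_COEFFICIENTS,
}


def linear_predictor(patient: PatientRecord, coeffs: CoefficientSet) -> float:
    """Log-odds of the 2-year event: intercept + sum(beta_i * x_i).

    Exact floating arithmetic in canonical covariate order, no clipping.
    """
    x = patient.covariate_vector()
    v = coeffs.as_vector()
    esp = v[0]
    for beta, value in zip(v[1:], x):
        esp += beta * value
    return float(esp)


def event_probability(esp: float) -> float:
    """Logistic transform exp(esp)/(1+exp(esp)), overflow-safe.

    Strictly inside (0, 1) for any finite ``esp`` with ``|esp|`` up to
    roughly 700 (beyond that the closer bound is returned by expit).
    """
    esp = float(esp)
    if not math.isfinite(esp):
        raise ValueError(f"linear predictor must be finite, got {esp!r}")
    p = float(expit(esp))
    # keep the output strictly inside (0,1): beyond |esp| ~ 37 the logistic
    # saturates past double precision, so return the nearest representable
    # neighbour instead of an exact 0 or 1
    if p == 0.0:
        return math.nextafter(0.0, 1.0)
    if p == 1.0:
        return math.nextafter(1.0, 0.0)
    return p


def s_mecki_score(patient: PatientRecord) -> float:
    """2-year event probability under the sex-specific published weights."""
    coeffs = BUILTIN_COEFFICIENTS[Sex(patient.sex)]
    return event_probability(linear_predictor(patient, coeffs))


def standardized_beta(beta: float, covariate_sd: float) -> float:
    """Coefficient rescaled to a one-SD covariate change: beta * SD.

    Makes weights comparable across covariates with different units.
    """
    if not (covariate_sd > 0):
        raise ValueError(f"covariate SD must be positive, got {covariate_sd!r}")
    return float(beta) * float(covariate_sd)
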