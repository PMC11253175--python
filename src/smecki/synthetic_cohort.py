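"""Synthetic HFrEF cohorts with registry-like covariate distributions.

Generates per-sex patient tables whose six score covariates follow
truncated (optionally correlated) normal distributions matching the
published per-sex moments of the MECKI registry population (1,444 women
and 6,456 men), and whose binary 2-year events are drawn from the
logistic model under a specified "true" coefficient set per sex.  All
downstream stages — cross-validated weight estimation, discrimination
and calibration — are thereby testable against a known generative truth
without access to the registry itself.

The default truth is the published sex-specific S-MECKI coefficient
sets, so the default generator reproduces the study's covariate
landscape and its event-rate asymmetry (roughly twice the event risk in
men as in women).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .score_engine import (
    BUILTIN_COEFFICIENTS,
    COVARIATES,
    CoefficientSet,
    PatientRecord,
    Sex,
)

#: CSV schema shared by every cohort table the package reads or writes.
COHORT_COLUMNS: tuple[str, ...] = (
    "id", "sex", "lvef", "hb", "mdrd", "na", "vevco2_slope", "peakvo2_pct", "event",
)

# Per-sex covariate means and SDs of the MECKI registry population,
# canonical covariate order (peakvo2_pct, vevco2_slope, hb, na, lvef, mdrd).
FEMALE_MOMENTS: dict[str, tuple[float, float]] = {
    "peakvo2_pct": (63.2, 18.3),
    "vevco2_slope": (33.5, 7.7),
    "hb": (12.7, 1.4),
    "na": (139.6, 3.0),
    "lvef": (36.4, 11.4),
    "mdrd": (68.6, 24.6),
}
MALE_MOMENTS: dict[str, tuple[float, float]] = {
    "peakvo2_pct": (54.6, 17.0),
    "vevco2_slope": (33.2, 7.9),
    "hb": (13.7, 1.7),
    "na": (139.4, 3.3),
    "lvef": (32.3, 10.0),
    "mdrd": (72.3, 24.2),
}

# Physiologic ranges intersected with mean +/- 4 SD to form default
# truncation bounds: all covariates positive, Na in [110, 160] mmol/L,
# LVEF in (0, 100] percent.
_PHYSIOLOGIC: dict[str, tuple[float, float]] = {
    "peakvo2_pct": (0.0, np.inf),
    "vevco2_slope": (0.0, np.inf),
    "hb": (0.0, np.inf),
    "na": (110.0, 160.0),
    "lvef": (0.0, 100.0),
    "mdrd": (0.0, np.inf),
}

#: Registry sample sizes, used as generator defaults.
N_FEMALE_DEFAULT = 1444
N_MALE_DEFAULT = 6456


def default_truncation_bounds(moments: dict[str, tuple[float, float]]) -> dict[str, tuple[float, float]]:
    """Mean +/- 4 SD clipped to physiologic ranges, per covariate."""
    bounds = {}
    for name, (mean, sd) in moments.items():
        lo, hi = _PHYSIOLOGIC[name]
        bounds[name] = (max(mean - 4.0 * sd, lo), min(mean + 4.0 * sd, hi))
    return bounds


@dataclass
class CohortSpec:
    """Everything needed to simulate one two-sex cohort reproducibly."""

    n_female: int = N_FEMALE_DEFAULT
    n_male: int = N_MALE_DEFAULT
    female_moments: dict = field(default_factory=lambda: dict(FEMALE_MOMENTS))
    male_moments: dict = field(default_factory=lambda: dict(MALE_MOMENTS))
    female_bounds: dict | None = None
    male_bounds: dict | None = None
    female_correlation: np.ndarray | None = None  # 6x6, canonical order; None = identity
    male_correlation: np.ndarray | None = None
    true_coefficients: dict | None = None  # {"F": CoefficientSet, "M": CoefficientSet}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_female < 0 or self.n_male < 0:
            raise ValueError("cohort sizes must be non-negative")
        for moments in (self.female_moments, self.male_moments):
            for name, (mean, sd) in moments.items():
                if sd <= 0:
                    raise ValueError(f"SD for {name!r} must be positive, got {sd}")
        if self.female_bounds is None:
            self.female_bounds = default_truncation_bounds(self.female_moments)
        if self.male_bounds is None:
            self.male_bounds = default_truncation_bounds(self.male_moments)
        for moments, bounds in (
            (self.female_moments, self.female_bounds),
            (self.male_moments, self.male_bounds),
        ):
            for name, (mean, _) in moments.items():
                lo, hi = bounds[name]
                if not (lo <= mean <= hi):
                    raise ValueError(
                        f"truncation bounds for {name!r} must contain the mean "
                        f"({mean} not in [{lo}, {hi}])"
                    )
        if self.true_coefficients is None:
            self.true_coefficients = {
                "F": BUILTIN_COEFFICIENTS[Sex.F],
                "M": BUILTIN_COEFFICIENTS[Sex.M],
            }

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("female_correlation", "male_correlation"):
            if data.get(key) is not None:
                data[key] = np.asarray(data[key], dtype=float)
        if data.get("true_coefficients") is not None:
            data["true_coefficients"] = {
                sex: CoefficientSet.from_dict(c)
                for sex, c in data["true_coefficients"].items()
            }
        return cls(**data)


def _check_correlation(corr: np.ndarray) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (6, 6):
        raise ValueError(f"correlation matrix must be 6x6, got {corr.shape}")
    if not np.allclose(corr, corr.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
        raise ValueError("correlation matrix must have unit diagonal")
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-10:
        raise ValueError("correlation matrix must be positive semi-definite")
    return corr


def _sample_covariates(
    n: int,
    moments: dict[str, tuple[float, float]],
    bounds: dict[str, tuple[float, float]],
    correlation: np.ndarray | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Truncated-normal sample (n x 6, canonical order) by rejection.

    Rows of the untruncated multivariate normal are redrawn until every
    covariate lies inside its bounds; at the default +/- 4 SD bounds the
    acceptance rate is essentially 1, so rejection is cheap and leaves
    the within-bounds distribution exact.
    """
    if n == 0:
        return np.empty((0, 6))
    mu = np.array([moments[c][0] for c in COVARIATES])
    sd = np.array([moments[c][1] for c in COVARIATES])
    lo = np.array([bounds[c][0] for c in COVARIATES])
    hi = np.array([bounds[c][1] for c in COVARIATES])
    if correlation is None:
        chol = None
    else:
        corr = _check_correlation(correlation)
        # small jitter only if exactly singular, to allow cholesky
        try:
            chol = np.linalg.cholesky(corr)
        except np.linalg.LinAlgError:
            chol = np.linalg.cholesky(corr + 1e-10 * np.eye(6))

    out = np.empty((n, 6))
    filled = 0
    while filled < n:
        draw = rng.standard_normal(size=(n - filled, 6))
        if chol is not None:
            draw = draw @ chol.T
        x = mu + sd * draw
        ok = np.all((x >= lo) & (x <= hi), axis=1)
        accepted = x[ok]
        out[filled : filled + len(accepted)] = accepted
        filled += len(accepted)
    return out


def _events_from_truth(
    x: np.ndarray, coeffs: CoefficientSet, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    from scipy.special import expit

    v = coeffs.as_vector()
    esp = v[0] + x @ v[1:]
    p = expit(esp)
    events = (rng.random(len(p)) < p).astype(int)
    return events, p


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate one cohort; deterministic given ``spec.seed``.

    Returns a DataFrame with the standard cohort schema, women first.
    """
    ss = np.random.SeedSequence(spec.seed)
    child_f, child_m = ss.spawn(2)
    frames = []
    for sex, n, moments, bounds, corr, child in (
        ("F", spec.n_female, spec.female_moments, spec.female_bounds,
         spec.female_correlation, child_f),
        ("M", spec.n_male, spec.male_moments, spec.male_bounds,
         spec.male_correlation, child_m),
    ):
        rng = np.random.default_rng(child)
        x = _sample_covariates(n, moments, bounds, corr, rng)
        events, _ = _events_from_truth(x, spec.true_coefficients[sex], rng)
        frame = pd.DataFrame(x, columns=list(COVARIATES))
        frame["sex"] = sex
        frame["event"] = events
        frames.append(frame)
    cohort = pd.concat(frames, ignore_index=True)
    cohort["id"] = [f"S{i:06d}" for i in range(len(cohort))]
    return cohort[list(COHORT_COLUMNS)]


def cohort_to_records(cohort: pd.DataFrame) -> list[PatientRecord]:
    """Convert a cohort table to typed patient records (validates rows)."""
    records = []
    for row in cohort.itertuples(index=False):
        records.append(
            PatientRecord(
                sex=Sex(row.sex),
                lvef=row.lvef,
                hb=row.hb,
                mdrd=row.mdrd,
                na=row.na,
                vevco2_slope=row.vevco2_slope,
                peakvo2_pct=row.peakvo2_pct,
                event=int(row.event),
                id=getattr(row, "id", None),
            )
        )
    return records


def write_cohort_csv(cohort: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write the cohort CSV plus a ``.meta.json`` sidecar (seed etc.)."""
    path = Path(path)
    cohort.to_csv(path, index=False)
    if metadata is not None:
        with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
            json.dump(metadata, fh, indent=2)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort CSV against the standard schema."""
    cohort = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - {"id"} - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort CSV missing required columns: {sorted(missing)}")
    bad_sex = ~cohort["sex"].isin(["F", "M"])
    if bad_sex.any():
        lines = (cohort.index[bad_sex] + 2).tolist()[:10]
        raise ValueError(f"unrecognized sex labels at CSV lines {lines}")
    bad_event = ~cohort["event"].isin([0, 1])
    if bad_event.any():
        lines = (cohort.index[bad_event] + 2).tolist()[:10]
        raise ValueError(f"event must be 0/1; offending CSV lines {lines}")
    if "id" not in cohort.columns:
        cohort.insert(0, "id", [f"R{i:06d}" for i in range(len(cohort))])
    return cohort[list(COHORT_COLUMNS)]
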