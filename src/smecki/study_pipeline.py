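"""End-to-end study orchestration.

Reproduces the full analysis on a synthetic or user-supplied cohort:
per-sex descriptives with between-sex tests, sex-specific half-split
cross-validated weight recalibration with sex-difference symbols,
standardized coefficients, native-vs-recalibrated discrimination
(DeLong-compared paired AUCs), and decile calibration of both scores.

The "native" comparator score defaults to a single pooled logistic fit
on the input cohort when no published pooled coefficient set is
supplied, so the pipeline is runnable self-contained.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2_contingency, ttest_ind

from .evaluation import RocComparison, calibration_curve, delong_compare, hosmer_lemeshow
from .score_engine import COEFFICIENT_NAMES, COVARIATES, CoefficientSet, standardized_beta
from .synthetic_cohort import CohortSpec, generate_cohort, read_cohort_csv
from .weight_estimation import CVResult, comparison_symbols, cv_recalibrate, fit_logistic

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Inputs and knobs of one full study run; exactly one input source."""

    cohort_spec: CohortSpec | None = None
    csv_path: str | None = None
    native_coefficients: CoefficientSet | None = None
    n_reps: int = 200
    master_seed: int = 0
    out_dir: str | None = None
    interval_method: str = "percentile"
    hl_groups: int = 10
    stratified_splits: bool = False

    def __post_init__(self) -> None:
        if (self.cohort_spec is None) == (self.csv_path is None):
            raise ValueError("exactly one of cohort_spec or csv_path must be set")
        if self.n_reps < 1:
            raise ValueError("n_reps must be at least 1")

    def digest(self) -> str:
        """Short stable hash of the configuration, stamped on outputs."""
        payload = {
            "csv_path": self.csv_path,
            "n_reps": self.n_reps,
            "master_seed": self.master_seed,
            "interval_method": self.interval_method,
            "hl_groups": self.hl_groups,
            "stratified_splits": self.stratified_splits,
            "native": None
            if self.native_coefficients is None
            else self.native_coefficients.to_dict(),
            "spec": None
            if self.cohort_spec is None
            else {
                "n_female": self.cohort_spec.n_female,
                "n_male": self.cohort_spec.n_male,
                "seed": self.cohort_spec.seed,
                "female_moments": self.cohort_spec.female_moments,
                "male_moments": self.cohort_spec.male_moments,
            },
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def describe_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-sex covariate summary with between-sex tests.

    Continuous covariates: mean +/- SD per sex and a Welch t-test p
    value.  The binary event: counts/percent per sex and a chi-square
    test (no continuity correction) p value.  P values are unadjusted.
    """
    females = cohort[cohort["sex"] == "F"]
    males = cohort[cohort["sex"] == "M"]
    if len(females) == 0 or len(males) == 0:
        raise ValueError("describe_cohort needs both sexes present")
    can_test = len(females) >= 2 and len(males) >= 2
    if not can_test:
        warnings.warn("a sex has fewer than 2 records; reporting descriptives without tests")

    rows = []
    for name in COVARIATES:
        f, m = females[name].to_numpy(), males[name].to_numpy()
        p = float(ttest_ind(f, m, equal_var=False).pvalue) if can_test else np.nan
        rows.append(
            {
                "variable": name,
                "female_mean": f.mean(),
                "female_sd": f.std(ddof=1) if len(f) > 1 else np.nan,
                "male_mean": m.mean(),
                "male_sd": m.std(ddof=1) if len(m) > 1 else np.nan,
                "p_value": p,
            }
        )
    f_events = int(females["event"].sum())
    m_events = int(males["event"].sum())
    if can_test and 0 < f_events + m_events < len(cohort):
        table = np.array(
            [[f_events, len(females) - f_events], [m_events, len(males) - m_events]]
        )
        p = float(chi2_contingency(table, correction=False).pvalue)
    else:
        p = np.nan
    rows.append(
        {
            "variable": "event",
            "female_mean": f_events / len(females),
            "female_sd": np.nan,
            "male_mean": m_events / len(males),
            "male_sd": np.nan,
            "p_value": p,
        }
    )
    return pd.DataFrame(rows)


def fit_pooled_native(cohort: pd.DataFrame) -> CoefficientSet:
    """Single logistic fit on both sexes: the default native comparator."""
    beta = fit_logistic(cohort[list(COVARIATES)].to_numpy(), cohort["event"].to_numpy())
    return CoefficientSet.from_vector(beta, sex_label="pooled", provenance="pooled fit on input cohort")


def _apply(cohort: pd.DataFrame, coeffs: CoefficientSet) -> np.ndarray:
    v = coeffs.as_vector()
    return expit(v[0] + cohort[list(COVARIATES)].to_numpy() @ v[1:])


def score_cohort(
    cohort: pd.DataFrame,
    coeffs_f: CoefficientSet,
    coeffs_m: CoefficientSet,
) -> np.ndarray:
    """Sex-dispatched event probabilities for every row of the cohort."""
    p = np.empty(len(cohort))
    is_f = (cohort["sex"] == "F").to_numpy()
    p[is_f] = _apply(cohort[is_f], coeffs_f)
    p[~is_f] = _apply(cohort[~is_f], coeffs_m)
    return p


@dataclass
class StudyResult:
    """Everything one run produces, ready for export."""

    config_digest: str
    master_seed: int
    descriptives: pd.DataFrame
    cv_female: CVResult
    cv_male: CVResult
    symbols: dict[str, str]
    recalibrated: dict[str, CoefficientSet]
    standardized: pd.DataFrame
    native_coefficients: CoefficientSet
    native_scores: np.ndarray
    recalibrated_scores: np.ndarray
    roc_overall: RocComparison
    roc_by_sex: dict[str, RocComparison]
    calibration: dict[str, "pd.DataFrame | object"]

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stamp = {"config_digest": self.config_digest, "master_seed": self.master_seed}
        with open(out / "run_metadata.json", "w") as fh:
            json.dump(stamp, fh, indent=2)
        self.descriptives.to_csv(out / "descriptives.csv", index=False)
        self.cv_female.to_csv(out / "cv_female_repetitions.csv")
        self.cv_male.to_csv(out / "cv_male_repetitions.csv")
        summary = {
            "female": self.cv_female.summary(),
            "male": self.cv_male.summary(),
            "symbols": self.symbols,
            **stamp,
        }
        with open(out / "cv_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        for sex, coeffs in self.recalibrated.items():
            coeffs.to_json(out / f"recalibrated_{sex}.json")
        self.native_coefficients.to_json(out / "native_coefficients.json")
        self.standardized.to_csv(out / "standardized_betas.csv", index=False)
        roc = {"overall": self.roc_overall.to_dict()}
        roc.update({k: v.to_dict() for k, v in self.roc_by_sex.items()})
        with open(out / "roc_comparisons.json", "w") as fh:
            json.dump(roc, fh, indent=2)
        for name, table in self.calibration.items():
            table.groups.to_csv(out / f"calibration_{name}.csv", index=False)
        with open(out / "calibration_summary.json", "w") as fh:
            json.dump({k: v.summary() for k, v in self.calibration.items()}, fh, indent=2)


def recovery_experiment(
    sex: str,
    n: int,
    n_replicates: int,
    n_reps: int = 200,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Replicate the weight-estimation procedure on fresh synthetic cohorts.

    Each replicate draws a new single-sex cohort of size ``n`` from the
    registry-like generator (events under the published sex-specific
    truth) and runs the ``n_reps``-repetition half-split CV on it.  The
    returned frame has one row per replicate with the CV mean
    coefficients, so its column means estimate the expected recovered
    weights under the generative truth — the single-cohort CV mean is
    dominated by cohort-level sampling noise (for 1,444 women the
    per-cohort SD of the recovered intercept is ~6), which averaging
    over replicates removes.
    """
    if sex not in ("F", "M"):
        raise ValueError("sex must be 'F' or 'M'")
    rows = []
    for rep in range(n_replicates):
        seeds = np.random.default_rng(
            np.random.SeedSequence((base_seed, rep))
        ).integers(2**31, size=2)
        spec = CohortSpec(
            n_female=n if sex == "F" else 0,
            n_male=n if sex == "M" else 0,
            seed=int(seeds[0]),
        )
        cohort = generate_cohort(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv = cv_recalibrate(cohort, n_reps, int(seeds[1]))
        rows.append(cv.mean_betas)
    return pd.DataFrame(np.asarray(rows), columns=list(COEFFICIENT_NAMES))


def run_study(config: StudyConfig) -> StudyResult:
    """Run the complete analysis for one configuration (pure function)."""
    if config.cohort_spec is not None:
        cohort = generate_cohort(config.cohort_spec)
    else:
        cohort = read_cohort_csv(config.csv_path)
    logger.info(
        "cohort: n=%d (%d F / %d M), events=%d, seed=%d",
        len(cohort), (cohort["sex"] == "F").sum(), (cohort["sex"] == "M").sum(),
        cohort["event"].sum(), config.master_seed,
    )

    descriptives = describe_cohort(cohort)

    females = cohort[cohort["sex"] == "F"].reset_index(drop=True)
    males = cohort[cohort["sex"] == "M"].reset_index(drop=True)
    # distinct per-sex seed offsets keep the two CV streams independent
    cv_f = cv_recalibrate(
        females, config.n_reps, config.master_seed,
        stratified=config.stratified_splits, interval_method=config.interval_method,
    )
    cv_m = cv_recalibrate(
        males, config.n_reps, config.master_seed + 1,
        stratified=config.stratified_splits, interval_method=config.interval_method,
    )
    symbols = comparison_symbols(cv_f, cv_m)

    recal = {
        "F": CoefficientSet.from_vector(cv_f.mean_betas, "F", "half-split CV mean"),
        "M": CoefficientSet.from_vector(cv_m.mean_betas, "M", "half-split CV mean"),
    }

    std_rows = []
    for sex, frame, cv in (("F", females, cv_f), ("M", males, cv_m)):
        for i, name in enumerate(COVARIATES):
            sd = float(frame[name].std(ddof=1))
            std_rows.append(
                {
                    "sex": sex,
                    "variable": name,
                    "beta": float(cv.mean_betas[i + 1]),
                    "covariate_sd": sd,
                    "standardized_beta": standardized_beta(cv.mean_betas[i + 1], sd),
                }
            )
    standardized = pd.DataFrame(std_rows)

    native = config.native_coefficients or fit_pooled_native(cohort)
    native_scores = _apply(cohort, native)
    recal_scores = score_cohort(cohort, recal["F"], recal["M"])
    y = cohort["event"].to_numpy()

    roc_overall = delong_compare(recal_scores, native_scores, y)
    roc_by_sex = {}
    for sex, frame in (("F", females), ("M", males)):
        mask = (cohort["sex"] == sex).to_numpy()
        roc_by_sex[sex] = delong_compare(recal_scores[mask], native_scores[mask], y[mask])

    calibration = {
        "native": hosmer_lemeshow(native_scores, y, config.hl_groups),
        "recalibrated": hosmer_lemeshow(recal_scores, y, config.hl_groups),
    }

    result = StudyResult(
        config_digest=config.digest(),
        master_seed=config.master_seed,
        descriptives=descriptives,
        cv_female=cv_f,
        cv_male=cv_m,
        symbols=symbols,
        recalibrated=recal,
        standardized=standardized,
        native_coefficients=native,
        native_scores=native_scores,
        recalibrated_scores=recal_scores,
        roc_overall=roc_overall,
        roc_by_sex=roc_by_sex,
        calibration=calibration,
    )
    if config.out_dir is not None:
        result.write(config.out_dir)
    return result
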