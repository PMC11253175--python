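"""Repeated half-split cross-validated estimation of score weights.

The recalibration procedure: a single-sex cohort is randomly divided in
half 200 times; on each training half a six-covariate logistic model of
the 2-year composite event is fit by maximum likelihood, and the fitted
linear predictor is scored on the held-out half by its AUC.  The mean of
the 200 per-repetition coefficient vectors is the recalibrated weight
for each variable; sex differences between weights are read off by
comparing 95% intervals of the repetition distributions.

The logistic fitter is a plain Newton/IRLS maximum-likelihood solver.
With ~30 events per female training half, occasional quasi-complete
separation is expected; a flagged repetition is refit with a small L2
penalty (1e-4 on the non-intercept terms) rather than dropped, because
dropping exactly the separated splits would bias the mean weight.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import auc
from .score_engine import COEFFICIENT_NAMES, COVARIATES

logger = logging.getLogger(__name__)


class DegenerateOutcomeError(ValueError):
    """All outcomes are events or all are non-events; no logistic fit exists."""


class ConvergenceError(RuntimeError):
    """Newton iteration did not converge (often complete/quasi-separation)."""


class ProcedureError(RuntimeError):
    """Too many failed repetitions: the cohort is too small or degenerate."""


def half_split(
    cohort: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random disjoint partition into a training and a testing half.

    Simple random assignment without outcome stratification; for odd n
    the training half receives the extra record.
    """
    n = len(cohort)
    if n < 2:
        raise ValueError(f"need at least 2 records to split, got {n}")
    perm = rng.permutation(n)
    n_train = (n + 1) // 2
    train = cohort.iloc[perm[:n_train]]
    test = cohort.iloc[perm[n_train:]]
    return train, test


def _stratified_half_split(
    cohort: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Half split preserving the event rate in both halves (optional mode)."""
    parts_train, parts_test = [], []
    for _, group in cohort.groupby("event", sort=True):
        perm = rng.permutation(len(group))
        n_train = (len(group) + 1) // 2
        parts_train.append(group.iloc[perm[:n_train]])
        parts_test.append(group.iloc[perm[n_train:]])
    return pd.concat(parts_train), pd.concat(parts_test)


def fit_logistic(
    covariate_rows,
    outcomes,
    *,
    ridge: float = 0.0,
    max_iter: int = 100,
    score_tol: float = 1e-8,
    step_tol: float = 1e-10,
) -> np.ndarray:
    """Maximum-likelihood logistic coefficients (intercept first).

    Newton/IRLS on the design [1 | X]; converged when every score-equation
    component is below ``score_tol`` or the parameter step is below
    ``step_tol``.  ``ridge`` > 0 adds an L2 penalty on the non-intercept
    terms (used as the separation fallback).

    Raises
    ------
    DegenerateOutcomeError
        if the outcomes are all 0 or all 1.
    ConvergenceError
        if the iteration does not converge within ``max_iter`` steps.
    """
    X = np.asarray(covariate_rows, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(outcomes, dtype=float)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("covariate rows and outcomes disagree in length")
    if y.sum() == 0 or y.sum() == n:
        raise DegenerateOutcomeError("outcomes are all one class; logistic MLE undefined")

    design = np.column_stack([np.ones(n), X])
    p_dim = design.shape[1]
    if np.linalg.matrix_rank(design) < p_dim:
        raise ValueError("covariate matrix is not full column rank")

    penalty = np.zeros(p_dim)
    penalty[1:] = ridge

    beta = np.zeros(p_dim)
    # start from the intercept-only MLE for fewer Newton steps
    rate = y.mean()
    beta[0] = np.log(rate / (1.0 - rate))

    for _ in range(max_iter):
        eta = design @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        score = design.T @ (y - mu) - penalty * beta
        w = mu * (1.0 - mu)
        hess = (design * w[:, None]).T @ design + np.diag(penalty)
        try:
            step = np.linalg.solve(hess, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular Hessian: {exc}") from exc
        # step-halving keeps the iteration inside the well-behaved region
        new_beta = beta + step
        for _halving in range(30):
            eta_new = design @ new_beta
            ll_new = np.sum(y * eta_new - np.logaddexp(0.0, eta_new)) - 0.5 * np.sum(
                penalty * new_beta**2
            )
            ll_old = np.sum(y * eta - np.logaddexp(0.0, eta)) - 0.5 * np.sum(
                penalty * beta**2
            )
            if np.isfinite(ll_new) and ll_new >= ll_old - 1e-12:
                break
            new_beta = (beta + new_beta) / 2.0
        max_step = np.max(np.abs(new_beta - beta))
        beta = new_beta
        if np.max(np.abs(score)) < score_tol or max_step < step_tol:
            if ridge == 0.0:
                # saturated fitted probabilities at an apparent optimum are
                # the footprint of complete/quasi-complete separation: the
                # unpenalized MLE is at infinity
                mu_final = 1.0 / (1.0 + np.exp(-(design @ beta)))
                if np.any(mu_final < 1e-8) or np.any(mu_final > 1 - 1e-8):
                    raise ConvergenceError(
                        "fitted probabilities saturated: complete or "
                        "quasi-complete separation"
                    )
            return beta
    raise ConvergenceError(
        f"no convergence in {max_iter} iterations (possible quasi-separation)"
    )


@dataclass
class CVResult:
    """Outcome of the repeated half-split cross-validation for one sex."""

    n_reps: int
    beta_matrix: np.ndarray  # successful repetitions x 7, canonical order
    mean_betas: np.ndarray  # length 7
    ci_lower: np.ndarray  # selected interval method, length 7
    ci_upper: np.ndarray
    ci_pct_lower: np.ndarray  # empirical 2.5/97.5 percentiles of repetitions
    ci_pct_upper: np.ndarray
    ci_mean_lower: np.ndarray  # normal-theory CI of the mean of repetitions
    ci_mean_upper: np.ndarray
    test_aucs: np.ndarray
    n_failed: int
    seed: int
    interval_method: str = "percentile"

    def to_frame(self) -> pd.DataFrame:
        """One row per successful repetition: 7 betas plus the held-out AUC."""
        frame = pd.DataFrame(self.beta_matrix, columns=list(COEFFICIENT_NAMES))
        frame["test_auc"] = self.test_aucs
        return frame

    def summary(self) -> dict:
        return {
            "n_reps": int(self.n_reps),
            "n_failed": int(self.n_failed),
            "seed": int(self.seed),
            "interval_method": self.interval_method,
            "mean_betas": dict(zip(COEFFICIENT_NAMES, map(float, self.mean_betas))),
            "ci_lower": dict(zip(COEFFICIENT_NAMES, map(float, self.ci_lower))),
            "ci_upper": dict(zip(COEFFICIENT_NAMES, map(float, self.ci_upper))),
            "mean_test_auc": float(np.mean(self.test_aucs)) if len(self.test_aucs) else None,
        }

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def _repetition_rng(master_seed: int, rep: int) -> np.random.Generator:
    # each repetition gets its own stream so repetitions are
    # order-independent and individually reproducible
    return np.random.default_rng(np.random.SeedSequence((master_seed, rep)))


def cv_recalibrate(
    cohort: pd.DataFrame,
    n_reps: int = 200,
    master_seed: int = 0,
    *,
    stratified: bool = False,
    interval_method: str = "percentile",
    ridge_fallback: float = 1e-4,
) -> CVResult:
    """Repeated half-split CV weights for one single-sex cohort.

    For each repetition: split in half, fit the six-covariate logistic
    model on the training half, score the testing half by the AUC of the
    fitted linear predictor.  The mean coefficient vector over the
    successful repetitions is the recalibrated weight vector; 95%
    intervals are empirical 2.5/97.5 percentiles of the repetition
    distribution by default (``interval_method="mean"`` switches to a
    normal-theory interval of the mean).
    """
    if interval_method not in ("percentile", "mean"):
        raise ValueError(f"unknown interval method {interval_method!r}")
    if cohort["sex"].nunique() > 1:
        raise ValueError("cv_recalibrate expects a single-sex cohort")
    n_events = int(cohort["event"].sum())
    if n_events < 10 * 7 * 2:
        warnings.warn(
            f"only {n_events} events for 7 parameters per training half; "
            "coefficient estimates may be unstable",
            stacklevel=2,
        )

    splitter = _stratified_half_split if stratified else half_split
    betas, aucs = [], []
    n_failed = 0
    for rep in range(n_reps):
        rng = _repetition_rng(master_seed, rep)
        train, test = splitter(cohort, rng)
        x_train = train[list(COVARIATES)].to_numpy()
        y_train = train["event"].to_numpy()
        try:
            try:
                beta = fit_logistic(x_train, y_train)
            except ConvergenceError:
                logger.info("repetition %d flagged: refitting with L2 %g", rep, ridge_fallback)
                beta = fit_logistic(x_train, y_train, ridge=ridge_fallback)
                n_failed += 1
                betas.append(beta)
                continue  # flagged repetitions contribute betas but no AUC
        except (DegenerateOutcomeError, ConvergenceError):
            logger.warning("repetition %d dropped: unfittable training half", rep)
            n_failed += 1
            continue
        betas.append(beta)
        eta_test = beta[0] + test[list(COVARIATES)].to_numpy() @ beta[1:]
        aucs.append(auc(eta_test, test["event"].to_numpy()))

    if n_failed > 0.25 * n_reps:
        raise ProcedureError(
            f"{n_failed}/{n_reps} repetitions failed; cohort too small or degenerate"
        )

    beta_matrix = np.asarray(betas)
    mean_betas = beta_matrix.mean(axis=0)
    pct_lo = np.percentile(beta_matrix, 2.5, axis=0)
    pct_hi = np.percentile(beta_matrix, 97.5, axis=0)
    se_mean = beta_matrix.std(axis=0, ddof=1) / np.sqrt(len(beta_matrix))
    mean_lo = mean_betas - 1.959963984540054 * se_mean
    mean_hi = mean_betas + 1.959963984540054 * se_mean
    ci_lo, ci_hi = (pct_lo, pct_hi) if interval_method == "percentile" else (mean_lo, mean_hi)
    return CVResult(
        n_reps=n_reps,
        beta_matrix=beta_matrix,
        mean_betas=mean_betas,
        ci_lower=ci_lo,
        ci_upper=ci_hi,
        ci_pct_lower=pct_lo,
        ci_pct_upper=pct_hi,
        ci_mean_lower=mean_lo,
        ci_mean_upper=mean_hi,
        test_aucs=np.asarray(aucs),
        n_failed=n_failed,
        seed=master_seed,
        interval_method=interval_method,
    )


def compare_weights(
    ci_female: tuple[float, float],
    ci_male: tuple[float, float],
    mean_f: float,
    mean_m: float,
) -> str:
    """Sex-difference symbol for one weight: '=', '>' or '<'.

    '=' if the two 95% intervals overlap (touching endpoints count as
    overlap); otherwise '>' when the female weight is larger in absolute
    value, '<' when the male weight is.
    """
    lo_f, hi_f = sorted(map(float, ci_female))
    lo_m, hi_m = sorted(map(float, ci_male))
    for lo, hi, mean in ((lo_f, hi_f, mean_f), (lo_m, hi_m, mean_m)):
        if not np.isfinite([lo, hi, mean]).all():
            raise ValueError("interval endpoints and means must be finite")
        if not (lo <= mean <= hi):
            raise ValueError(f"interval [{lo}, {hi}] does not contain its mean {mean}")
    if lo_f <= hi_m and lo_m <= hi_f:
        return "="
    return ">" if abs(mean_f) > abs(mean_m) else "<"


def comparison_symbols(result_f: CVResult, result_m: CVResult) -> dict[str, str]:
    """Per-coefficient sex-difference symbols from two CV results."""
    out = {}
    for i, name in enumerate(COEFFICIENT_NAMES):
        out[name] = compare_weights(
            (result_f.ci_lower[i], result_f.ci_upper[i]),
            (result_m.ci_lower[i], result_m.ci_upper[i]),
            result_f.mean_betas[i],
            result_m.mean_betas[i],
        )
    return out
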