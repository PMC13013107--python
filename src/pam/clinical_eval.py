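"""Predictor evaluation: logistic models, ROC/AUC, DeLong, correlations.

A candidate feature from the discovery stage is evaluated as a clinical
predictor.  To keep observations independent, each patient contributes
one row: event patients their in-window sample (the one closest to 24 h
pre-event when two exist), control patients the within-patient average
of their matched samples (or one drawn at random for the Monte Carlo
sensitivity analysis).  Logistic models use z-scored predictors so odds
ratios are per 1 SD; performance is summarized by McFadden pseudo-R2,
AIC and AUC with outcome-stratified bootstrap confidence intervals, and
AUCs are compared with DeLong's paired test implemented from structural
components (placement values).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .align_stratify import AlignedSample, WindowStratum
from .cohort_io import FeatureMatrix, PatientRecord, SampleRecord
from .errors import ConfigError, ValidationError
from .match_controls import MatchSet

__all__ = [
    "ModelReport", "TermStats", "DeLongResult",
    "build_patient_observations", "fit_logistic_standardized",
    "roc_auc_bootstrap", "roc_points", "delong_auc_variance", "delong_compare",
    "spearman_outcome_correlations", "monte_carlo_single_sample", "auc_mann_whitney",
]


# ---------------------------------------------------------------------------
# patient-level observations


def build_patient_observations(matrix: FeatureMatrix,
                               patients: Mapping[str, PatientRecord],
                               samples: Mapping[str, SampleRecord],
                               stratum: WindowStratum,
                               match_sets: Sequence[MatchSet],
                               aligned: Mapping[str, AlignedSample],
                               feature_ids: Sequence[str],
                               clinical_scores: Sequence[str] = ("mfisher",),
                               mode: str = "average",
                               rng: np.random.Generator | None = None,
                               ) -> pd.DataFrame:
    """One independent observation per patient for regression modelling.

    Event patients contribute their in-window sample (closest to 24 h
    pre-event when several fall in the window); control patients their
    matched samples, combined per ``mode``: ``"average"`` (default) or
    ``"single_random"`` (uniform draw, used by the Monte Carlo
    sensitivity analysis; requires ``rng``).  Predictors are the
    feature's log2 level plus any requested clinical scores; they are
    standardized later by the model fit, not here.
    """
    if not matrix.log_transformed:
        raise ValidationError("observations are built from the log2 matrix")
    if mode not in ("average", "single_random"):
        raise ConfigError(f"unknown mode {mode!r}")
    if mode == "single_random" and rng is None:
        raise ConfigError("single_random mode requires an rng")

    case_by_patient: dict[str, list[str]] = {}
    for sid in stratum.case_samples:
        case_by_patient.setdefault(samples[sid].patient_id, []).append(sid)
    control_by_patient: dict[str, list[str]] = {}
    matched_controls = sorted({c for m in match_sets for c in m.control_sample_ids})
    for sid in matched_controls:
        control_by_patient.setdefault(samples[sid].patient_id, []).append(sid)

    rows = []
    for pid in sorted(set(case_by_patient) | set(control_by_patient)):
        patient = patients[pid]
        if patient.event_status:
            sids = sorted(case_by_patient[pid],
                          key=lambda s: (abs(aligned[s].hours_pre_event - 24.0), s))
            chosen = [sids[0]]
        else:
            sids = sorted(control_by_patient[pid])
            if mode == "single_random":
                chosen = [sids[int(rng.integers(len(sids)))]]
            else:
                chosen = sids
        vals = matrix.data.loc[chosen, list(feature_ids)].mean(axis=0)
        row = {"patient_id": pid, "outcome": int(patient.event_status),
               "n_samples_averaged": len(chosen)}
        row.update({fid: float(vals[fid]) for fid in feature_ids})
        for score in clinical_scores:
            row[score] = getattr(patient, score)
        for f in ("gos_discharge", "gos_1w", "gos_1m", "gos_12m", "mrs_12m"):
            row[f] = getattr(patient, f)
        rows.append(row)
    if not rows:
        warnings.warn("no patients with eligible samples in this stratum",
                      stacklevel=2)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# logistic regression


@dataclass(frozen=True)
class TermStats:
    coef: float
    se: float
    odds_ratio: float
    or_ci_low: float
    or_ci_high: float
    p: float


@dataclass
class ModelReport:
    """Fitted standardized-logistic summary for one model."""

    model_id: str
    terms: dict[str, TermStats]
    mcfadden_pseudo_r2: float
    aic: float
    n_obs: int
    converged: bool
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    predicted: pd.Series | None = None


def fit_logistic_standardized(observations: pd.DataFrame,
                              terms: Sequence[str],
                              model_id: str | None = None,
                              n_boot: int = 2000,
                              seed: int | None = 0) -> ModelReport:
    """Maximum-likelihood logistic fit with z-scored predictors.

    Odds ratios are per 1 SD of the predictor (standardization on the
    analysis set).  McFadden pseudo-R2 is ``1 - ll_model / ll_null``;
    AIC is ``2 (k + 1) - 2 ll_model``.  When ``n_boot > 0`` the model's
    predicted event probability is scored by ROC with a stratified
    bootstrap CI.  Perfect separation is reported as non-converged
    rather than silently returned.
    """
    y = observations["outcome"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2 or min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValidationError("need >= 2 observations per outcome class")
    X = observations[list(terms)].astype(float)
    Xz = (X - X.mean()) / X.std(ddof=1)
    Xz = sm.add_constant(Xz, prepend=True, has_constant="add")
    if not terms:  # intercept-only null model
        Xz = pd.DataFrame({"const": np.ones(len(y))},
                          index=observations.index)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, Xz).fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", True))
            if np.any(np.abs(fit.params) > 50):
                converged = False   # runaway coefficients = separation
        except Exception:
            return ModelReport(model_id or "+".join(terms), {}, np.nan, np.nan,
                               len(y), converged=False)
    ci = fit.conf_int(alpha=0.05)
    term_stats = {}
    for name in terms:
        term_stats[name] = TermStats(
            coef=float(fit.params[name]), se=float(fit.bse[name]),
            odds_ratio=float(np.exp(fit.params[name])),
            or_ci_low=float(np.exp(ci.loc[name, 0])),
            or_ci_high=float(np.exp(ci.loc[name, 1])),
            p=float(fit.pvalues[name]),
        )
    report = ModelReport(
        model_id=model_id or "+".join(terms),
        terms=term_stats,
        mcfadden_pseudo_r2=(0.0 if not terms or fit.llnull == 0
                            else float(1.0 - fit.llf / fit.llnull)),
        aic=float(fit.aic),
        n_obs=len(y),
        converged=converged,
        predicted=pd.Series(np.asarray(fit.predict(Xz)),
                            index=observations["patient_id"].to_numpy()),
    )
    if n_boot > 0 and converged:
        auc, auc_ci, pts = roc_auc_bootstrap(y, report.predicted.to_numpy(),
                                             n_boot=n_boot, seed=seed)
        report.auc, report.auc_ci, report.roc_points = auc, auc_ci, pts
    return report


# ---------------------------------------------------------------------------
# ROC / AUC


def auc_mann_whitney(outcomes: np.ndarray, scores: np.ndarray) -> float:
    """Empirical AUC via the rank (Mann-Whitney) formulation, ties count 1/2."""
    y = np.asarray(outcomes, dtype=int)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = int(len(y) - n1)
    if n1 == 0 or n0 == 0:
        raise ValidationError("AUC undefined with a single outcome class")
    ranks = stats.rankdata(s, method="average")
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_points(outcomes: np.ndarray, scores: np.ndarray) -> list[tuple[float, float]]:
    """(FPR, TPR) pairs at every distinct threshold, descending score."""
    y = np.asarray(outcomes, dtype=int)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="stable")
    y = y[order]
    s = s[order]
    n1 = max(int(y.sum()), 1)
    n0 = max(int(len(y) - y.sum()), 1)
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    distinct = np.r_[np.diff(s) != 0, True]
    pts = [(0.0, 0.0)]
    pts += [(float(fp[i]) / n0, float(tp[i]) / n1)
            for i in np.flatnonzero(distinct)]
    return pts


def roc_auc_bootstrap(outcomes: np.ndarray, scores: np.ndarray,
                      n_boot: int = 2000, seed: int | None = 0,
                      ci_flavor: str = "percentile",
                      ) -> tuple[float, tuple[float, float], list[tuple[float, float]]]:
    """AUC with an outcome-stratified bootstrap confidence interval.

    Cases and controls are resampled separately so every replicate keeps
    the original class counts.  ``ci_flavor`` selects the percentile
    (default) or basic bootstrap interval.
    """
    y = np.asarray(outcomes, dtype=int)
    s = np.asarray(scores, dtype=float)
    auc = auc_mann_whitney(y, s)
    if n_boot <= 0:
        return auc, (np.nan, np.nan), roc_points(y, s)
    rng = np.random.default_rng(seed)
    case_scores = s[y == 1]
    ctrl_scores = s[y == 0]
    n1, n0 = len(case_scores), len(ctrl_scores)
    boot_case = case_scores[rng.integers(0, n1, size=(n_boot, n1))]
    boot_ctrl = ctrl_scores[rng.integers(0, n0, size=(n_boot, n0))]
    pooled = np.concatenate([boot_case, boot_ctrl], axis=1)
    ranks = stats.rankdata(pooled, axis=1, method="average")
    u = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0
    boot_aucs = u / (n1 * n0)
    lo, hi = np.percentile(boot_aucs, [2.5, 97.5])
    if ci_flavor == "basic":
        lo, hi = 2 * auc - hi, 2 * auc - lo
    elif ci_flavor != "percentile":
        raise ConfigError(f"unknown ci_flavor {ci_flavor!r}")
    return auc, (float(lo), float(hi)), roc_points(y, s)


# ---------------------------------------------------------------------------
# DeLong


def _placements(case_scores: np.ndarray, ctrl_scores: np.ndarray,
                ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus per-observation placement values (structural components)."""
    n1, n0 = len(case_scores), len(ctrl_scores)
    all_scores = np.concatenate([case_scores, ctrl_scores])
    mid = stats.rankdata(all_scores, method="average")
    mid_case = stats.rankdata(case_scores, method="average")
    mid_ctrl = stats.rankdata(ctrl_scores, method="average")
    # V10_i = P(score_i > random control) with ties at 1/2
    v10 = (mid[:n1] - mid_case) / n0
    v01 = 1.0 - (mid[n1:] - mid_ctrl) / n1
    auc = float(v10.mean())
    return auc, v10, v01


def delong_auc_variance(outcomes: np.ndarray, scores: np.ndarray,
                        ) -> tuple[float, float]:
    """(AUC, DeLong variance) for one score on one outcome vector."""
    y = np.asarray(outcomes, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValidationError("DeLong variance undefined with one class")
    auc, v10, v01 = _placements(s[y == 1], s[y == 0])
    n1, n0 = len(v10), len(v01)
    var = v10.var(ddof=1) / n1 + v01.var(ddof=1) / n0
    return auc, float(var)


@dataclass(frozen=True)
class DeLongResult:
    model_pair: tuple[str, str]
    auc_a: float
    auc_b: float
    delta_auc: float
    var_delta: float
    p: float


def delong_compare(outcomes: np.ndarray, score_a: np.ndarray,
                   score_b: np.ndarray,
                   labels: tuple[str, str] = ("a", "b")) -> DeLongResult:
    """DeLong's paired test for the difference of two correlated AUCs.

    Both scores must be measured on the same observations.  The variance
    of the difference uses the placement-value covariance; the p-value is
    a two-sided normal tail on the standardized difference.
    """
    y = np.asarray(outcomes, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValidationError("DeLong comparison undefined with one class")
    sa = np.asarray(score_a, dtype=float)
    sb = np.asarray(score_b, dtype=float)
    auc_a, v10a, v01a = _placements(sa[y == 1], sa[y == 0])
    auc_b, v10b, v01b = _placements(sb[y == 1], sb[y == 0])
    n1, n0 = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1 \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n0
    delta = auc_a - auc_b
    if var <= 0:
        p = 1.0 if delta == 0 else 0.0
    else:
        p = float(2 * stats.norm.sf(abs(delta) / np.sqrt(var)))
    return DeLongResult(labels, auc_a, auc_b, float(delta), float(var), p)


# ---------------------------------------------------------------------------
# Spearman outcome correlations


def spearman_outcome_correlations(observations: pd.DataFrame, predictor: str,
                                  outcome_fields: Sequence[str],
                                  min_n: int = 5) -> pd.DataFrame:
    """Spearman rho of a predictor against ordinal outcome scores.

    Pairwise-complete: rows missing either value are dropped per outcome.
    Outcomes with fewer than ``min_n`` complete pairs are skipped with a
    warning.
    """
    rows = []
    for fieldname in outcome_fields:
        sub = observations[[predictor, fieldname]].dropna()
        if len(sub) < min_n:
            warnings.warn(f"outcome {fieldname}: only {len(sub)} complete pairs; "
                          "skipped", stacklevel=2)
            continue
        rho, p = stats.spearmanr(sub[predictor], sub[fieldname])
        rows.append({"outcome": fieldname, "rho": float(rho), "p": float(p),
                     "n": int(len(sub))})
    return pd.DataFrame(rows, columns=["outcome", "rho", "p", "n"])


# ---------------------------------------------------------------------------
# Monte Carlo single-sample sensitivity


def monte_carlo_single_sample(matrix: FeatureMatrix,
                              patients: Mapping[str, PatientRecord],
                              samples: Mapping[str, SampleRecord],
                              stratum: WindowStratum,
                              match_sets: Sequence[MatchSet],
                              aligned: Mapping[str, AlignedSample],
                              feature_id: str,
                              n_iter: int = 1000,
                              seed: int | None = 0,
                              ) -> tuple[float, float, np.ndarray, int]:
    """Sensitivity of the averaged-control design to single-sample selection.

    Each iteration redraws one sample per control patient (instead of
    averaging), refits the predictor-only logistic model and records its
    AUC.  Returns (mean AUC, SD, full distribution, n non-converged).
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_iter)
    aucs = np.full(n_iter, np.nan)
    n_fail = 0
    for i in range(n_iter):
        rng = np.random.default_rng(child_seeds[i])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # repeat drop warnings
            obs = build_patient_observations(
                matrix, patients, samples, stratum, match_sets, aligned,
                feature_ids=[feature_id], mode="single_random", rng=rng)
        report = fit_logistic_standardized(obs, [feature_id], n_boot=0)
        if not report.converged or report.predicted is None:
            n_fail += 1
            continue
        aucs[i] = auc_mann_whitney(obs["outcome"].to_numpy(),
                                   report.predicted.to_numpy())
    valid = aucs[~np.isnan(aucs)]
    return float(valid.mean()), float(valid.std(ddof=1)), aucs, n_fail
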