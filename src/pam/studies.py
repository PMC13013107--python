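"""Repeated-simulation studies over the synthetic generator.

These drive the package's calibration checks: recovery of the planted
log2 fold change and its temporal specificity, type-I control of the FDR
screen on spike-free cohorts, null behaviour of the predictor
evaluation, agreement of the DeLong variance with the bootstrap, and the
aligned-vs-fixed-timepoint design comparison.  Each study returns one
row per replicate so callers can summarize however they need.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .align_stratify import (W24_48, W48_72, align_to_event, build_strata,
                             fixed_timepoint_strata)
from .clinical_eval import (delong_auc_variance, fit_logistic_standardized,
                            roc_auc_bootstrap)
from .cohort_io import log2_transform
from .discovery_stats import run_discovery, two_group_tests
from .match_controls import MatchConfig, select_matched_controls
from .synth_cohort import SynthConfig, canonical_study_config, generate_cohort

__all__ = ["spike_recovery_study", "null_discovery_study",
           "null_predictor_study", "delong_bootstrap_agreement"]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)


def spike_recovery_study(n_reps: int = 200, seed: int = 0,
                         feature_id: str = "ARG",
                         config_factory=canonical_study_config) -> pd.DataFrame:
    """Recover the planted effect across replicate canonical cohorts.

    Per replicate: generate a cohort, align, match, run the 24-48 h and
    48-72 h screens, and record the spiked feature's estimated log2FC,
    p/q, per-test ranks, and the best fixed-calendar-day p for the design
    comparison (ratio > 1 means alignment beat every fixed day).
    """
    seeds = _child_seeds(seed, n_reps)
    rows = []
    for rep, s in enumerate(seeds):
        cfg = config_factory(seed=int(s))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            patients, samples, matrix, _ = generate_cohort(cfg)
            log2m = log2_transform(matrix)
            aligned = align_to_event(patients, samples)
            strata = build_strata(aligned, patients, samples)
            res = {}
            for w in (W24_48, W48_72):
                ms = select_matched_controls(strata[w], patients, samples,
                                             MatchConfig())
                res[w] = run_discovery(log2m, ms, strata[w]) if ms else None
            best_fixed_p = np.nan
            for day in range(cfg.study_days + 1):
                case_ids, ctrl_ids = fixed_timepoint_strata(
                    patients, samples, day, cfg.study_days)
                if len(case_ids) < 2 or len(ctrl_ids) < 2:
                    continue
                p = two_group_tests(log2m.data.loc[case_ids, feature_id],
                                    log2m.data.loc[ctrl_ids, feature_id]).p_student
                best_fixed_p = np.nanmin([best_fixed_p, p])
        row = {"rep": rep}
        r24 = res[W24_48]
        if r24 is not None:
            hit = r24.set_index("feature_id").loc[feature_id]
            row.update(log2_fc=hit["log2_fc"], p_student=hit["p_student"],
                       q_w24_48=hit["q"], rank_student=hit["rank_student"],
                       rank_welch=hit["rank_welch"], rank_mwu=hit["rank_mwu"])
        r72 = res[W48_72]
        if r72 is not None:
            hit72 = r72.set_index("feature_id").loc[feature_id]
            row.update(q_w48_72=hit72["q"], p_w48_72=hit72["p_student"])
        row["best_fixed_p"] = best_fixed_p
        if "p_student" in row and np.isfinite(best_fixed_p):
            row["p_ratio_fixed_over_pam"] = best_fixed_p / row["p_student"]
        rows.append(row)
    return pd.DataFrame(rows)


def null_discovery_study(n_reps: int = 60, seed: int = 0,
                         n_features: int = 500,
                         n_patients: int = 60) -> pd.DataFrame:
    """Type-I behaviour of the screen on cohorts with no planted effects.

    Records the number of FDR-significant (q < 0.05) and nominally
    significant features in the 24-48 h screen of each spike-free cohort.
    """
    seeds = _child_seeds(seed, n_reps)
    rows = []
    for rep, s in enumerate(seeds):
        cfg = SynthConfig(n_patients=n_patients, n_features=n_features,
                          spikes=[], seed=int(s))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            patients, samples, matrix, _ = generate_cohort(cfg)
            log2m = log2_transform(matrix)
            aligned = align_to_event(patients, samples)
            strata = build_strata(aligned, patients, samples)
            ms = select_matched_controls(strata[W24_48], patients, samples,
                                         MatchConfig())
            res = run_discovery(log2m, ms, strata[W24_48])
        rows.append({"rep": rep,
                     "n_fdr_hits": int((res["q"] < 0.05).sum()),
                     "n_nominal_hits": int((res["p_student"] < 0.05).sum()),
                     "n_features": len(res)})
    return pd.DataFrame(rows)


def null_predictor_study(n_reps: int = 100, seed: int = 0,
                         n_case: int = 16, n_control: int = 29,
                         n_boot: int = 1000) -> pd.DataFrame:
    """Null calibration of the predictor evaluation machinery.

    Each replicate draws a predictor independent of outcome at the
    study's observation counts, fits the standardized logistic model and
    records McFadden pseudo-R2, whether the odds-ratio CI covers 1,
    whether the stratified-bootstrap AUC CI covers 0.5, and whether
    DeLong's test (against a second independent null score) rejects at
    alpha = 0.05.
    """
    from .clinical_eval import delong_compare

    seeds = _child_seeds(seed, n_reps)
    rows = []
    y = np.r_[np.ones(n_case, dtype=int), np.zeros(n_control, dtype=int)]
    for rep, s in enumerate(seeds):
        rng = np.random.default_rng(int(s))
        x = rng.normal(size=y.size)
        x2 = rng.normal(size=y.size)
        obs = pd.DataFrame({"patient_id": [f"P{i}" for i in range(y.size)],
                            "outcome": y, "x": x})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = fit_logistic_standardized(obs, ["x"], n_boot=0)
            auc, (lo, hi), _ = roc_auc_bootstrap(y, x, n_boot=n_boot,
                                                 seed=int(s))
            dl = delong_compare(y, x, x2)
        ts = report.terms.get("x")
        rows.append({
            "rep": rep,
            "pseudo_r2": report.mcfadden_pseudo_r2,
            "or_ci_covers_1": (ts is not None
                               and ts.or_ci_low <= 1.0 <= ts.or_ci_high),
            "auc": auc, "ci_low": lo, "ci_high": hi,
            "ci_covers_half": lo <= 0.5 <= hi,
            "delong_reject": dl.p < 0.05,
            "converged": report.converged,
        })
    return pd.DataFrame(rows)


def delong_bootstrap_agreement(n_sets: int = 8, seed: int = 0, n: int = 40,
                               n_boot: int = 2000,
                               effect: float = 1.0) -> pd.DataFrame:
    """Compare the DeLong single-AUC variance with the bootstrap variance.

    Simulated sets of ``n`` observations (half cases, scores shifted by
    ``effect`` SD); both estimators target the sampling variance of the
    empirical AUC, so their averages should agree closely.
    """
    seeds = _child_seeds(seed, n_sets)
    n1 = n // 2
    rows = []
    for rep, s in enumerate(seeds):
        rng = np.random.default_rng(int(s))
        y = np.r_[np.ones(n1, dtype=int), np.zeros(n - n1, dtype=int)]
        scores = rng.normal(size=n) + effect * y
        auc, var_delong = delong_auc_variance(y, scores)
        case = scores[y == 1]
        ctrl = scores[y == 0]
        bi = rng.integers(0, n1, size=(n_boot, n1))
        bj = rng.integers(0, n - n1, size=(n_boot, n - n1))
        from scipy.stats import rankdata
        pooled = np.concatenate([case[bi], ctrl[bj]], axis=1)
        ranks = rankdata(pooled, axis=1, method="average")
        u = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0
        var_boot = float(np.var(u / (n1 * (n - n1)), ddof=1))
        rows.append({"rep": rep, "auc": auc, "var_delong": var_delong,
                     "var_boot": var_boot,
                     "ratio": var_delong / var_boot})
    return pd.DataFrame(rows)
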