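"""QC and the per-feature differential screen.

The screen follows the study's analysis plan: log2 peak areas, Pareto-
scaled PCA with Hotelling's T-squared outlier exclusion (alpha = 0.001),
then per feature a Student t-test (primary), Welch t-test and
Mann-Whitney U as variance/distribution-robust companions, Levene's test
(Brown-Forsythe variant) as the heteroscedasticity trigger, Benjamini-
Hochberg FDR across the scoped feature set, per-test ascending-p ranks,
log2-space metabolite ratios, an exact paired Wilcoxon for the few
patients sampled in both windows, and an outlier-drop sensitivity
re-test.

All two-group machinery is vectorized across features so a full
2,022-feature screen costs milliseconds; the scalar
:func:`two_group_tests` exposes the same computation for one feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import FeatureMatrix
from .errors import ConfigError, IntegrityError, QcError, StateError, ValidationError
from .match_controls import MatchSet

__all__ = [
    "PcaQcResult", "TwoGroupResult", "WilcoxonExactResult",
    "pareto_scale", "pca_hotelling_exclude",
    "two_group_tests", "bh_fdr", "run_discovery", "rank_concordance",
    "make_ratio_features", "run_ratio_discovery",
    "exact_wilcoxon_paired", "outlier_sensitivity_retest",
    "discovery_summary",
]

#: Levene p-value below which the variance-robust companions are flagged.
LEVENE_TRIGGER = 0.1


# ---------------------------------------------------------------------------
# Pareto scaling + Hotelling T2 QC


def pareto_scale(matrix: FeatureMatrix | pd.DataFrame,
                 ) -> tuple[pd.DataFrame, list[str]]:
    """Center each feature and divide by the square root of its SD.

    Pareto scaling shrinks the dominance of high-variance features in PCA
    less aggressively than unit-variance scaling.  Zero-variance features
    are dropped with a warning (they carry no direction).  Returns the
    scaled grid and the dropped feature ids.
    """
    if isinstance(matrix, FeatureMatrix):
        if not matrix.log_transformed:
            raise StateError("pareto_scale expects a log2-transformed matrix")
        df = matrix.data
    else:
        df = matrix
    sd = df.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = list(df.columns[~keep])
    if not keep.any():
        raise QcError("all features have zero variance; nothing to scale")
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance feature(s) "
                      "before Pareto scaling", stacklevel=2)
    sub = df.loc[:, keep]
    scaled = (sub - sub.mean(axis=0)) / np.sqrt(sd[keep])
    return scaled, dropped


@dataclass
class PcaQcResult:
    """PCA scores, Hotelling T2 statistics and the excluded samples."""

    scores: pd.DataFrame
    explained_variance_fractions: list[float]
    t2: pd.Series
    t2_critical: float
    excluded_sample_ids: list[str]
    alpha: float
    n_components: int


def pca_hotelling_exclude(scaled: pd.DataFrame, alpha: float = 0.001,
                          n_components: int = 5) -> PcaQcResult:
    """Flag multivariate outliers via Hotelling's T2 on PCA scores.

    T2 for sample i is the sum over retained components of the squared
    score divided by the component's score variance.  The critical value
    is ``A (n - 1) / (n - A) * F_{1 - alpha}(A, n - A)``.  The exclusion
    is applied once (no iterative re-exclusion).
    """
    if n_components < 1:
        raise ConfigError("n_components must be >= 1")
    X = scaled.to_numpy(dtype=float)
    n, m = X.shape
    A = min(n_components, n - 1, m)
    if A < 1:
        raise QcError("not enough samples for even one principal component")
    Xc = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    total_var = float((S ** 2).sum())
    if total_var <= 0 or S[A - 1] <= 1e-12 * max(S[0], 1.0):
        raise QcError("zero variance in retained components; T2 undefined")
    scores = U[:, :A] * S[:A]
    score_var = (S[:A] ** 2) / (n - 1)
    t2 = (scores ** 2 / score_var).sum(axis=1)
    if n <= A:
        raise QcError("need n > n_components for the T2 critical value")
    crit = A * (n - 1) / (n - A) * stats.f.ppf(1 - alpha, A, n - A)
    t2_series = pd.Series(t2, index=scaled.index, name="t2")
    excluded = list(scaled.index[t2 > crit])
    return PcaQcResult(
        scores=pd.DataFrame(scores, index=scaled.index,
                            columns=[f"PC{a + 1}" for a in range(A)]),
        explained_variance_fractions=[float(s ** 2 / total_var) for s in S[:A]],
        t2=t2_series,
        t2_critical=float(crit),
        excluded_sample_ids=excluded,
        alpha=alpha,
        n_components=A,
    )


# ---------------------------------------------------------------------------
# two-group testing


def _brown_forsythe(case: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Vectorized Levene test with median centering, per column."""
    n1, n0 = case.shape[0], control.shape[0]
    z1 = np.abs(case - np.median(case, axis=0))
    z0 = np.abs(control - np.median(control, axis=0))
    m1, m0 = z1.mean(axis=0), z0.mean(axis=0)
    grand = (n1 * m1 + n0 * m0) / (n1 + n0)
    between = n1 * (m1 - grand) ** 2 + n0 * (m0 - grand) ** 2
    within = ((z1 - m1) ** 2).sum(axis=0) + ((z0 - m0) ** 2).sum(axis=0)
    dof = n1 + n0 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        W = between * dof / within
        p = stats.f.sf(W, 1, dof)
    p = np.where(within > 0, p, np.nan)
    return np.asarray(p, dtype=float)


def _mwu_method(n1: int, n0: int, pooled: np.ndarray) -> str:
    """Exact enumeration for small untied groups, else tie-corrected normal."""
    if max(n1, n0) <= 25:
        m = pooled.shape[1] if pooled.ndim == 2 else 1
        flat = pooled.reshape(-1, m) if pooled.ndim == 2 else pooled[:, None]
        has_ties = any(len(np.unique(flat[:, j])) < flat.shape[0]
                       for j in range(m))
        if not has_ties:
            return "exact"
    return "asymptotic"


def _vectorized_two_group(case: np.ndarray, control: np.ndarray) -> dict[str, np.ndarray]:
    """All four tests plus means/log2FC, columns = features."""
    n1, n0 = case.shape[0], control.shape[0]
    if n1 < 2 or n0 < 2:
        raise ValidationError("each group needs at least 2 values")
    mean_case = case.mean(axis=0)
    mean_control = control.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p_student = stats.ttest_ind(case, control, axis=0, equal_var=True).pvalue
        p_welch = stats.ttest_ind(case, control, axis=0, equal_var=False).pvalue
        method = _mwu_method(n1, n0, np.vstack([case, control]))
        p_mwu = stats.mannwhitneyu(case, control, axis=0, method=method,
                                   alternative="two-sided").pvalue
    p_levene = _brown_forsythe(case, control)
    # degenerate pooled variance -> undefined parametric p
    pooled_var = case.var(axis=0, ddof=1) + control.var(axis=0, ddof=1)
    degenerate = pooled_var == 0
    for arr in (p_student, p_welch):
        arr[...] = np.where(degenerate, np.nan, arr)
    # identical groups: scipy reports t=0 -> p=1 already; keep as-is
    return {
        "n_case": np.full(case.shape[1], n1), "n_control": np.full(case.shape[1], n0),
        "mean_case": mean_case, "mean_control": mean_control,
        "log2_fc": mean_case - mean_control,
        "p_student": np.atleast_1d(np.asarray(p_student, dtype=float)),
        "p_welch": np.atleast_1d(np.asarray(p_welch, dtype=float)),
        "p_mwu": np.atleast_1d(np.asarray(p_mwu, dtype=float)),
        "p_levene": np.atleast_1d(p_levene),
    }


@dataclass(frozen=True)
class TwoGroupResult:
    n_case: int
    n_control: int
    mean_case: float
    mean_control: float
    log2_fc: float
    p_student: float
    p_welch: float
    p_mwu: float
    p_levene: float

    @property
    def robustness_flagged(self) -> bool:
        return bool(self.p_levene < LEVENE_TRIGGER)


def two_group_tests(case_values: Sequence[float],
                    control_values: Sequence[float]) -> TwoGroupResult:
    """Student, Welch, Mann-Whitney and Levene tests for one feature.

    Values are expected in log2 units; ``log2_fc`` is
    ``mean(case) - mean(control)``.  Mann-Whitney uses exact enumeration
    for untied groups of at most 25 each, else the tie-corrected normal
    approximation.  A Levene (median-centered) p below 0.1 flags the
    feature for variance-robust reporting.
    """
    case = np.asarray(case_values, dtype=float)[:, None]
    control = np.asarray(control_values, dtype=float)[:, None]
    r = _vectorized_two_group(case, control)
    return TwoGroupResult(
        n_case=int(r["n_case"][0]), n_control=int(r["n_control"][0]),
        mean_case=float(r["mean_case"][0]), mean_control=float(r["mean_control"][0]),
        log2_fc=float(r["log2_fc"][0]),
        p_student=float(r["p_student"][0]), p_welch=float(r["p_welch"][0]),
        p_mwu=float(r["p_mwu"][0]), p_levene=float(r["p_levene"][0]),
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (original order preserved).

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over the sorted p-values; NaN
    entries are excluded from m and returned as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    mask = ~np.isnan(p)
    if np.any((p[mask] < 0) | (p[mask] > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    ps = p[mask]
    m = ps.size
    if m == 0:
        return q
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / np.arange(1, m + 1)
    qs = np.minimum.accumulate(ranked[::-1])[::-1]
    qs = np.clip(qs, 0.0, 1.0)
    out = np.empty(m)
    out[order] = qs
    q[mask] = out
    return q


def _rank_ascending(p: np.ndarray) -> np.ndarray:
    """Ascending-p ranks, minimum-rank ties, NaN ranked NaN."""
    ranks = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        ranks[mask] = stats.rankdata(p[mask], method="min")
    return ranks


def run_discovery(matrix: FeatureMatrix, match_sets: list[MatchSet],
                  stratum=None, feature_scope: str = "annotated_only",
                  primary_test: str = "student") -> pd.DataFrame:
    """Per-feature differential screen of a window's cases vs matched controls.

    Cases are the match sets' case samples; controls are the distinct
    union of their matched controls.  BH correction runs across the
    scoped feature set (annotated-only vs all features reproduces the two
    multiple-testing burdens of the study design), with per-test
    ascending-p ranks and the Levene robustness flag.
    """
    if not matrix.log_transformed:
        raise StateError("run_discovery expects a log2-transformed matrix")
    case_ids = sorted({m.case_sample_id for m in match_sets})
    control_ids = sorted({sid for m in match_sets for sid in m.control_sample_ids})
    overlap = set(case_ids) & set(control_ids)
    if overlap:
        raise IntegrityError(f"samples appear as both case and control: {sorted(overlap)}")
    features = [f for f in matrix.feature_scope(feature_scope)
                if f in matrix.data.columns]
    case = matrix.data.loc[case_ids, features].to_numpy(dtype=float)
    control = matrix.data.loc[control_ids, features].to_numpy(dtype=float)
    return _build_results(features, case, control, primary_test)


def _build_results(features, case, control, primary_test) -> pd.DataFrame:
    r = _vectorized_two_group(case, control)
    primary_col = f"p_{primary_test}"
    if primary_col not in ("p_student", "p_welch", "p_mwu"):
        raise ConfigError(f"unknown primary test {primary_test!r}")
    df = pd.DataFrame({"feature_id": features, **r})
    df["q"] = bh_fdr(df[primary_col].to_numpy())
    for t in ("student", "welch", "mwu"):
        df[f"rank_{t}"] = _rank_ascending(df[f"p_{t}"].to_numpy())
    df["robustness_flagged"] = df["p_levene"] < LEVENE_TRIGGER
    return df


def discovery_summary(results: pd.DataFrame, primary_test: str = "student",
                      alpha: float = 0.05) -> dict[str, int]:
    """Counts of nominal (p < alpha) and FDR (q < alpha) hits."""
    p = results[f"p_{primary_test}"]
    return {
        "n_features": int(len(results)),
        "n_nominal": int((p < alpha).sum()),
        "n_fdr": int((results["q"] < alpha).sum()),
    }


def rank_concordance(results: pd.DataFrame, k: int = 1) -> pd.DataFrame:
    """Cross-method rank agreement per feature.

    ``all_tests_top_k`` is true when the feature's worst rank across
    Student/Welch/Mann-Whitney is within the top k — the "top-ranked
    across all methods" summary.
    """
    ranks = results[["rank_student", "rank_welch", "rank_mwu"]].to_numpy()
    out = pd.DataFrame({
        "feature_id": results["feature_id"].to_numpy(),
        "min_rank": np.nanmin(ranks, axis=1),
        "max_rank": np.nanmax(ranks, axis=1),
    })
    out[f"all_tests_top_{k}"] = out["max_rank"] <= k
    return out


# ---------------------------------------------------------------------------
# ratios


def make_ratio_features(matrix: FeatureMatrix,
                        pairs: Mapping[str, tuple[str, str]]) -> pd.DataFrame:
    """Per-sample log2 ratios: log2(numerator) - log2(denominator)."""
    if not matrix.log_transformed:
        raise StateError("ratios are computed on the log2 matrix")
    cols = {}
    for ratio_id, (num, den) in pairs.items():
        for fid in (num, den):
            if fid not in matrix.data.columns:
                raise ConfigError(f"ratio {ratio_id!r}: unknown feature {fid!r}")
        cols[ratio_id] = matrix.data[num] - matrix.data[den]
    return pd.DataFrame(cols, index=matrix.data.index)


def run_ratio_discovery(ratio_values: pd.DataFrame, match_sets: list[MatchSet],
                        primary_test: str = "student") -> pd.DataFrame:
    """Differential screen over ratio features; BH across the ratio set only."""
    case_ids = sorted({m.case_sample_id for m in match_sets})
    control_ids = sorted({sid for m in match_sets for sid in m.control_sample_ids})
    case = ratio_values.loc[case_ids].to_numpy(dtype=float)
    control = ratio_values.loc[control_ids].to_numpy(dtype=float)
    return _build_results(list(ratio_values.columns), case, control, primary_test)


# ---------------------------------------------------------------------------
# exact paired Wilcoxon


@dataclass(frozen=True)
class WilcoxonExactResult:
    w_statistic: float
    n_used: int
    p: float
    method: str


def exact_wilcoxon_paired(differences: Sequence[float],
                          exact_limit: int = 25) -> WilcoxonExactResult:
    """Two-sided paired Wilcoxon signed-rank test with an exact null.

    Zero differences are dropped (Wilcoxon's original convention); ties
    among |differences| share average ranks.  For n <= ``exact_limit``
    the null distribution of W (sum of positive ranks) is built exactly
    over all 2^n sign assignments via a generating-function convolution;
    the two-sided p is the null probability of a |W - E[W]| at least as
    extreme as observed.  Larger n falls back to the tie-corrected
    normal approximation.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all differences are zero; p = 1", stacklevel=2)
        return WilcoxonExactResult(0.0, 0, 1.0, "degenerate")
    ranks = stats.rankdata(np.abs(d), method="average")
    w = float(ranks[d > 0].sum())
    total = float(ranks.sum())
    mu = total / 2.0
    if n <= exact_limit:
        # integer arithmetic on doubled ranks (midranks can be half-integers)
        r2 = np.round(ranks * 2).astype(int)
        counts = np.zeros(r2.sum() + 1, dtype=float)
        counts[0] = 1.0
        for r in r2:
            counts[r:] += counts[:-r or None].copy()
        dev = abs(2 * w - 2 * mu)
        support = np.arange(counts.size)
        extreme = np.abs(support - 2 * mu) >= dev - 1e-9
        p = float(counts[extreme].sum() / 2.0 ** n)
        return WilcoxonExactResult(w, n, min(p, 1.0), "exact")
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts ** 3 - tie_counts).sum()) / 48.0
    z = (w - mu) / np.sqrt(var)
    return WilcoxonExactResult(w, n, float(2 * stats.norm.sf(abs(z))), "normal")


# ---------------------------------------------------------------------------
# outlier sensitivity re-test


def outlier_sensitivity_retest(
        values_by_window: Mapping[str, tuple[Sequence[float], Sequence[float]]],
        drop_rules: Mapping[str, tuple[str, str]]) -> pd.DataFrame:
    """Re-run the two-group tests after dropping named extreme values.

    ``values_by_window`` maps a window label to (case_values,
    control_values); ``drop_rules`` maps a window to ``(which, group)``
    with ``which`` in {"min", "max"} and ``group`` in {"case",
    "control"}.  Windows without a rule are reported unchanged.  If a
    drop would leave a group with fewer than 2 values the re-test for
    that window is skipped with a warning.
    """
    rows = []
    for window, (case_vals, ctrl_vals) in values_by_window.items():
        case = np.asarray(case_vals, dtype=float)
        ctrl = np.asarray(ctrl_vals, dtype=float)
        before = two_group_tests(case, ctrl)
        rows.append({"window": window, "phase": "before",
                     **_retest_row(before)})
        rule = drop_rules.get(window)
        if rule is None:
            rows.append({"window": window, "phase": "after", **_retest_row(before)})
            continue
        which, group = rule
        if which not in ("min", "max") or group not in ("case", "control"):
            raise ConfigError(f"bad drop rule {rule!r} for window {window!r}")
        target = case if group == "case" else ctrl
        idx = int(np.argmin(target)) if which == "min" else int(np.argmax(target))
        kept = np.delete(target, idx)
        new_case, new_ctrl = (kept, ctrl) if group == "case" else (case, kept)
        if len(new_case) < 2 or len(new_ctrl) < 2:
            warnings.warn(f"window {window}: dropping the {which} {group} value "
                          "leaves fewer than 2 values; re-test skipped", stacklevel=2)
            continue
        after = two_group_tests(new_case, new_ctrl)
        rows.append({"window": window, "phase": "after", **_retest_row(after)})
    return pd.DataFrame(rows, columns=["window", "phase", "n_case", "n_control",
                                       "log2_fc", "p_student", "p_welch",
                                       "p_mwu", "p_levene"])


def _retest_row(r: TwoGroupResult) -> dict:
    return {"n_case": r.n_case, "n_control": r.n_control, "log2_fc": r.log2_fc,
            "p_student": r.p_student, "p_welch": r.p_welch,
            "p_mwu": r.p_mwu, "p_levene": r.p_levene}
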