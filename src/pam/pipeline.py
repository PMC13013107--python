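"""End-to-end orchestration: load/generate -> align -> match -> QC ->
discover -> ratios -> evaluate -> fixed-timepoint comparator.

A :class:`RunConfig` either points at the three cohort CSVs or requests a
synthetic cohort; :func:`run_pipeline` executes every stage, collects all
result tables into a bundle, and writes them plus a run manifest (config
echo, library versions, seeds, warnings, per-stage record counts) so a
run is self-describing and exactly repeatable.
"""

from __future__ import annotations

import json
import platform
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .align_stratify import (W24_48, W48_72, WINDOWS, align_to_event,
                             aligned_frame, build_strata, fixed_timepoint_strata)
from .clinical_eval import (build_patient_observations, delong_compare,
                            fit_logistic_standardized, monte_carlo_single_sample,
                            spearman_outcome_correlations)
from .cohort_io import (FeatureMatrix, load_cohort, load_feature_matrix,
                        log2_transform, write_cohort, write_feature_matrix,
                        write_results)
from .discovery_stats import (discovery_summary, exact_wilcoxon_paired,
                              make_ratio_features, pareto_scale,
                              pca_hotelling_exclude, rank_concordance,
                              run_discovery, run_ratio_discovery,
                              two_group_tests)
from .errors import ConfigError, PamError
from .match_controls import (MatchConfig, balance_table, matches_frame,
                             select_matched_controls)
from .synth_cohort import (CANONICAL_RATIO_PAIRS, SynthConfig,
                           canonical_study_config, generate_cohort)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "compare_designs"]

_OUTCOME_FIELDS = ("gos_discharge", "gos_1w", "gos_1m", "gos_12m", "mrs_12m")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Exactly one of ``input_dir`` (directory with patients.csv,
    samples.csv, features.csv and optionally feature_annotations.csv)
    or ``synthetic`` must be set.
    """

    input_dir: str | None = None
    synthetic: bool = False
    synth: SynthConfig | None = None
    study_days: int = 7
    match: MatchConfig = field(default_factory=MatchConfig)
    feature_scopes: tuple[str, ...] = ("annotated_only",)
    primary_test: str = "student"
    qc_alpha: float = 0.001
    qc_components: int = 5
    ratio_pairs: dict[str, tuple[str, str]] | None = None
    predictor_feature: str | None = None       # default: top W24_48 hit
    clinical_score: str = "mfisher"
    evaluation_window: str = W24_48
    n_boot: int = 2000
    mc_iterations: int = 1000
    tracked_features: tuple[str, ...] = ()
    matrix_orientation: str = "samples"
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        if bool(self.input_dir) == bool(self.synthetic):
            raise ConfigError("exactly one of input_dir or synthetic must be set")
        if self.evaluation_window not in WINDOWS:
            raise ConfigError(f"unknown evaluation window {self.evaluation_window!r}")

    @classmethod
    def canonical(cls, seed: int = 0, out_dir: str | None = None,
                  **overrides) -> "RunConfig":
        """Canonical synthetic run mirroring the study conditions."""
        cfg = cls(synthetic=True, synth=canonical_study_config(seed=seed),
                  ratio_pairs=dict(CANONICAL_RATIO_PAIRS),
                  predictor_feature="ARG", tracked_features=("ARG",),
                  seed=seed, out_dir=out_dir)
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg


@dataclass
class PipelineResult:
    tables: dict[str, pd.DataFrame]
    manifest: dict
    out_dir: Path | None
    paths: dict[str, Path] = field(default_factory=dict)


def _stage(manifest: dict, name: str, **counts) -> None:
    manifest["stages"].append({"stage": name, **counts})


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage and return (and optionally write) the bundle."""
    config.validate()
    manifest: dict = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__, "pandas": pd.__version__,
        "seed": config.seed,
        "config": _config_echo(config),
        "stages": [],
        "warnings": [],
    }
    tables: dict[str, pd.DataFrame] = {}
    cohort: dict = {}
    stage = "load"
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            _run_stages(config, manifest, tables, cohort)
        manifest["warnings"] = sorted({str(w.message) for w in caught})
    except PamError as exc:
        stage = manifest["stages"][-1]["stage"] if manifest["stages"] else stage
        manifest["error"] = {"stage": stage, "message": str(exc)}
        _write_bundle(config, tables, manifest, cohort)
        raise

    return _write_bundle(config, tables, manifest, cohort)


def _run_stages(config: RunConfig, manifest: dict,
                tables: dict[str, pd.DataFrame], cohort: dict) -> None:
    # 1. load or generate ------------------------------------------------
    if config.synthetic:
        synth = config.synth or canonical_study_config(seed=config.seed)
        patients, samples, matrix, truth = generate_cohort(synth)
        tables["truth"] = truth
    else:
        root = Path(config.input_dir)
        patients, samples = load_cohort(root / "patients.csv", root / "samples.csv",
                                        study_days=config.study_days)
        ann = root / "feature_annotations.csv"
        matrix = load_feature_matrix(root / "features.csv",
                                     annotations_path=ann if ann.exists() else None,
                                     orientation=config.matrix_orientation)
    cohort.update(patients=patients, samples=samples, matrix=matrix)
    _stage(manifest, "load", n_patients=len(patients), n_samples=len(samples),
           n_features=matrix.n_features)

    log2m = log2_transform(matrix)
    _stage(manifest, "log2_transform", n_features=log2m.n_features)

    # 2. align + stratify ------------------------------------------------
    aligned = align_to_event(patients, samples)
    tables["aligned_samples"] = aligned_frame(aligned)
    strata = build_strata(aligned, patients, samples)
    _stage(manifest, "align",
           n_case_w24_48=len(strata[W24_48].case_samples),
           n_case_w48_72=len(strata[W48_72].case_samples),
           n_dual_window_patients=strata.n_dual_window_patients)

    # 3. QC on the analysis samples --------------------------------------
    analysis_ids = sorted(
        set(strata[W24_48].case_samples) | set(strata[W48_72].case_samples)
        | {sid for sid, _ in strata[W24_48].control_pool})
    scaled, dropped = pareto_scale(log2m.data.loc[analysis_ids])
    qc = pca_hotelling_exclude(scaled, alpha=config.qc_alpha,
                               n_components=config.qc_components)
    tables["qc_pca"] = pd.DataFrame({
        "sample_id": qc.t2.index, "t2": qc.t2.to_numpy(),
        "t2_critical": qc.t2_critical,
        "excluded": [sid in qc.excluded_sample_ids for sid in qc.t2.index]})
    excluded = set(qc.excluded_sample_ids)
    for w in WINDOWS:
        strata[w].case_samples = [s for s in strata[w].case_samples
                                  if s not in excluded]
        strata[w].control_pool = [(s, d) for s, d in strata[w].control_pool
                                  if s not in excluded]
    _stage(manifest, "qc", n_excluded=len(excluded),
           n_zero_variance_dropped=len(dropped),
           t2_critical=round(qc.t2_critical, 4))

    # 4. matching --------------------------------------------------------
    match_sets = {}
    match_rows, balance_rows = [], []
    for w in WINDOWS:
        ms = select_matched_controls(strata[w], patients, samples, config.match)
        match_sets[w] = ms
        mf = matches_frame(ms)
        mf.insert(0, "window", w)
        match_rows.append(mf)
        if not strata[w].is_empty:
            bt = balance_table(strata[w], ms, patients, samples)
            bt.insert(0, "window", w)
            balance_rows.append(bt)
    tables["matches"] = pd.concat(match_rows, ignore_index=True)
    if balance_rows:
        tables["balance"] = pd.concat(balance_rows, ignore_index=True)
    _stage(manifest, "match",
           **{f"n_matches_{w.lower()}": len(match_sets[w]) for w in WINDOWS})

    # 5. discovery -------------------------------------------------------
    disc_rows, conc_rows = [], []
    for w in WINDOWS:
        if not match_sets[w]:
            continue
        for scope in config.feature_scopes:
            res = run_discovery(log2m, match_sets[w], strata[w],
                                feature_scope=scope,
                                primary_test=config.primary_test)
            summary = discovery_summary(res, config.primary_test)
            _stage(manifest, f"discover_{w}_{scope}", **summary)
            res.insert(0, "scope", scope)
            res.insert(0, "window", w)
            disc_rows.append(res)
            conc = rank_concordance(res)
            conc.insert(0, "scope", scope)
            conc.insert(0, "window", w)
            conc_rows.append(conc)
    discovery = pd.concat(disc_rows, ignore_index=True)
    tables["discovery_results"] = discovery
    tables["rank_concordance"] = pd.concat(conc_rows, ignore_index=True)

    # 5b. paired analysis for dual-window patients -----------------------
    tracked_for_pairs = config.tracked_features or ()
    pair_rows = []
    for fid in tracked_for_pairs:
        if fid not in log2m.data.columns:
            continue
        diffs, n_pat = _dual_window_differences(log2m, samples, strata, fid)
        if len(diffs) >= 1:
            wres = exact_wilcoxon_paired(diffs)
            pair_rows.append({"feature_id": fid, "n_patients": n_pat,
                              "mean_log2_diff": float(np.mean(diffs)),
                              "w_statistic": wres.w_statistic,
                              "p_wilcoxon": wres.p, "method": wres.method})
    if pair_rows:
        tables["paired_dual_window"] = pd.DataFrame(pair_rows)
        _stage(manifest, "paired_analysis", n_features=len(pair_rows))

    # 6. ratios ----------------------------------------------------------
    if config.ratio_pairs:
        ratio_vals = make_ratio_features(log2m, config.ratio_pairs)
        ratio_rows = []
        for w in WINDOWS:
            if not match_sets[w]:
                continue
            rres = run_ratio_discovery(ratio_vals, match_sets[w],
                                       primary_test=config.primary_test)
            rres.insert(0, "window", w)
            ratio_rows.append(rres)
        tables["ratios"] = pd.concat(ratio_rows, ignore_index=True)
        _stage(manifest, "ratios", n_ratios=len(config.ratio_pairs))

    # 7. clinical evaluation --------------------------------------------
    eval_w = config.evaluation_window
    predictor = config.predictor_feature
    if predictor is None:
        top = discovery[discovery["window"] == eval_w].nsmallest(1, "q")
        predictor = str(top["feature_id"].iloc[0])
    if match_sets[eval_w]:
        _evaluate(config, manifest, tables, log2m, patients, samples,
                  strata[eval_w], match_sets[eval_w], aligned, predictor)

    # 8. fixed-timepoint comparator --------------------------------------
    tracked = list(config.tracked_features) or [predictor]
    tracked = [f for f in tracked if f in log2m.data.columns]
    fixed_rows = []
    for day in range(config.study_days + 1):
        case_ids, ctrl_ids = fixed_timepoint_strata(patients, samples, day,
                                                    config.study_days)
        if len(case_ids) < 2 or len(ctrl_ids) < 2:
            continue
        for fid in tracked:
            r = two_group_tests(log2m.data.loc[case_ids, fid],
                                log2m.data.loc[ctrl_ids, fid])
            fixed_rows.append({"day": day, "feature_id": fid,
                               "n_case": r.n_case, "n_control": r.n_control,
                               "p_student": r.p_student, "log2_fc": r.log2_fc})
    tables["fixed_day_screens"] = pd.DataFrame(
        fixed_rows, columns=["day", "feature_id", "n_case", "n_control",
                             "p_student", "log2_fc"])
    _stage(manifest, "fixed_timepoint", n_rows=len(fixed_rows))

    tables["design_comparison"] = compare_designs(tables, tracked)
    _stage(manifest, "compare_designs", n_features=len(tracked))


def _evaluate(config, manifest, tables, log2m, patients, samples, stratum,
              match_sets, aligned, predictor) -> None:
    obs = build_patient_observations(
        log2m, patients, samples, stratum, match_sets, aligned,
        feature_ids=[predictor], clinical_scores=[config.clinical_score])
    tables["patient_observations"] = obs.drop(columns=list(_OUTCOME_FIELDS))
    seed = config.seed
    models = {
        "predictor_only": [predictor],
        "score_only": [config.clinical_score],
        "combined": [predictor, config.clinical_score],
    }
    reports = {}
    model_rows, roc_rows = [], []
    for model_id, terms in models.items():
        rep = fit_logistic_standardized(obs, terms, model_id=model_id,
                                        n_boot=config.n_boot, seed=seed)
        reports[model_id] = rep
        for term, ts in rep.terms.items():
            model_rows.append({
                "model_id": model_id, "term": term, "coef": ts.coef,
                "odds_ratio": ts.odds_ratio, "or_ci_low": ts.or_ci_low,
                "or_ci_high": ts.or_ci_high, "p": ts.p,
                "mcfadden_pseudo_r2": rep.mcfadden_pseudo_r2, "aic": rep.aic,
                "auc": rep.auc,
                "auc_ci_low": None if rep.auc_ci is None else rep.auc_ci[0],
                "auc_ci_high": None if rep.auc_ci is None else rep.auc_ci[1],
                "n_obs": rep.n_obs, "converged": rep.converged})
        roc_rows.extend({"model_id": model_id, "fpr": f, "tpr": t}
                        for f, t in rep.roc_points)
    tables["models"] = pd.DataFrame(model_rows)
    tables["roc_points"] = pd.DataFrame(roc_rows, columns=["model_id", "fpr", "tpr"])

    y = obs["outcome"].to_numpy()
    delong_rows = []
    for a, b in (("predictor_only", "score_only"), ("combined", "score_only"),
                 ("combined", "predictor_only")):
        if reports[a].predicted is None or reports[b].predicted is None:
            continue
        d = delong_compare(y, reports[a].predicted.to_numpy(),
                           reports[b].predicted.to_numpy(), labels=(a, b))
        delong_rows.append({"model_a": a, "model_b": b, "auc_a": d.auc_a,
                            "auc_b": d.auc_b, "delta_auc": d.delta_auc, "p": d.p})
    tables["delong"] = pd.DataFrame(delong_rows)

    corr_obs = obs.copy()
    tables["spearman"] = spearman_outcome_correlations(
        corr_obs, predictor, list(_OUTCOME_FIELDS) + [config.clinical_score])

    if config.mc_iterations > 0:
        mean_auc, sd_auc, dist, n_fail = monte_carlo_single_sample(
            log2m, patients, samples, stratum, match_sets, aligned,
            predictor, n_iter=config.mc_iterations, seed=seed)
        tables["montecarlo"] = pd.DataFrame({
            "iteration": np.arange(len(dist)), "auc": dist})
        _stage(manifest, "monte_carlo", n_iter=config.mc_iterations,
               n_nonconverged=n_fail, mean_auc=round(mean_auc, 4),
               sd_auc=round(sd_auc, 4))
    _stage(manifest, "evaluate", predictor=predictor, n_obs=len(obs))


def _dual_window_differences(log2m, samples, strata, feature_id):
    """Per-patient early-minus-late window log2 differences (first sample
    per window) for patients sampled in both pre-event windows."""
    by_patient: dict[str, dict[str, str]] = {}
    for w in WINDOWS:
        for sid in strata[w].case_samples:
            by_patient.setdefault(samples[sid].patient_id, {}).setdefault(w, sid)
    diffs = []
    for pid in sorted(by_patient):
        got = by_patient[pid]
        if len(got) == 2:
            diffs.append(float(log2m.data.loc[got[W24_48], feature_id]
                               - log2m.data.loc[got[W48_72], feature_id]))
    return np.array(diffs), len(diffs)


def compare_designs(bundle: Mapping[str, pd.DataFrame],
                    tracked: list[str] | None = None) -> pd.DataFrame:
    """Contrast the aligned-window screen with the best fixed-day screen.

    For each tracked feature: the aligned p/q/log2FC per window against
    the smallest fixed-calendar-day p (and its fold change), plus the
    ratio best_fixed_p / aligned_p — values above 1 mean alignment
    strengthened the signal.
    """
    if "discovery_results" not in bundle or "fixed_day_screens" not in bundle:
        raise ConfigError("bundle lacks discovery or fixed-timepoint results")
    disc = bundle["discovery_results"]
    fixed = bundle["fixed_day_screens"]
    if tracked is None:
        tracked = sorted(fixed["feature_id"].unique())
    rows = []
    for fid in tracked:
        fsub = fixed[fixed["feature_id"] == fid]
        if fsub.empty:
            continue
        best = fsub.loc[fsub["p_student"].idxmin()]
        for w in WINDOWS:
            dsub = disc[(disc["feature_id"] == fid) & (disc["window"] == w)]
            if dsub.empty:
                continue
            d = dsub.iloc[0]
            rows.append({
                "feature_id": fid, "window": w,
                "pam_p": d["p_student"], "pam_q": d["q"],
                "pam_log2_fc": d["log2_fc"],
                "best_fixed_day": int(best["day"]),
                "best_fixed_p": best["p_student"],
                "best_fixed_log2_fc": best["log2_fc"],
                "p_ratio_fixed_over_pam": best["p_student"] / d["p_student"]})
    return pd.DataFrame(rows, columns=[
        "feature_id", "window", "pam_p", "pam_q", "pam_log2_fc",
        "best_fixed_day", "best_fixed_p", "best_fixed_log2_fc",
        "p_ratio_fixed_over_pam"])


def _config_echo(config: RunConfig) -> dict:
    echo = asdict(config)
    if echo.get("synth") and echo["synth"].get("spikes") is not None:
        pass  # asdict already expanded SpikeSpec dataclasses
    return json.loads(json.dumps(echo, default=str))


def _write_bundle(config: RunConfig, tables, manifest, cohort) -> PipelineResult:
    out_dir = Path(config.out_dir) if config.out_dir else None
    paths = {}
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = write_results(tables, out_dir)
        if config.synthetic and "patients" in cohort:
            paths.update(write_cohort(cohort["patients"], cohort["samples"], out_dir))
            paths.update(write_feature_matrix(cohort["matrix"], out_dir))
        mpath = out_dir / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                    default=str))
        paths["manifest"] = mpath
        manifest["outputs"] = {k: str(v) for k, v in paths.items()}
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                    default=str))
    return PipelineResult(tables=tables, manifest=manifest, out_dir=out_dir,
                          paths=paths)
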