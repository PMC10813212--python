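"""End-to-end study pipeline: ingestion → indices → events → Markov → statistics.

``simulate`` writes a synthetic cohort to disk in the same formats a real
study would provide (hypnogram CSVs, diary JSON, signal CSVs); ``analyze``
consumes such a directory — synthetic or real — and produces the study
report: a per-subject parameter table, group comparisons, correlations, the
backward-stepwise regression, and per-subject sleep-onset transition
matrices.  Runs are deterministic: the same configuration and seed yield
byte-identical report files, and the manifest records the configuration hash
so reruns can be audited.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import __version__
from .diary import SleepDiary, read_diaries_json
from .errors import SleepSSMError
from .events import (
    AlphaParams,
    ArousalParams,
    KCParams,
    alpha_density,
    detect_kcomplexes,
    detect_rem_arousals,
    first_kc_latency,
    read_signal_csv,
    rem_arousal_density,
)
from .hypnogram import (
    SLEEP_STAGES,
    Hypnogram,
    Stage,
    objective_sleep_params,
    read_hypnogram_csv,
    stage_latency,
)
from .markov import (
    TransitionMatrix,
    compare_transition,
    matrices_to_frame,
    subjective_sl_matrix,
)
from .misperception import HIGH, LOW, compute_indices
from .stats import backward_stepwise, mann_whitney, shapiro_wilk_gate, spearman
from .synthetic import CohortConfig, generate_cohort, write_cohort

__all__ = ["AnalysisParams", "RunConfig", "StudyReport", "simulate", "analyze", "run_pipeline", "load_config"]


@dataclass(frozen=True)
class AnalysisParams:
    """All tunable analysis settings (detector thresholds, cutoffs, stats options)."""

    alpha: AlphaParams = field(default_factory=AlphaParams)
    kc: KCParams = field(default_factory=KCParams)
    arousal: ArousalParams = field(default_factory=ArousalParams)
    cutoff_min: float = 10.0
    ties_to: str = LOW
    group_order: Tuple[str, str] = (LOW, HIGH)
    stepwise_criterion: str = "bic"
    exact_max_n: int = 8
    waso_to_end_of_recording: bool = False


@dataclass(frozen=True)
class RunConfig:
    """One reproducible run: a synthetic cohort config (or an existing input
    directory with real data) plus analysis parameters."""

    synthetic: Optional[CohortConfig] = None
    input_dir: Optional[str] = None
    analysis: AnalysisParams = field(default_factory=AnalysisParams)

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.input_dir is None):
            raise SleepSSMError("exactly one of synthetic config or input_dir is required")


@dataclass
class StudyReport:
    """All computed study outputs plus the run manifest."""

    subjects: pd.DataFrame
    transitions: pd.DataFrame
    stats: dict
    manifest: dict


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def simulate(cfg: CohortConfig, outdir: Union[str, Path]) -> Path:
    """Generate and write a synthetic cohort; returns the cohort directory."""
    return write_cohort(generate_cohort(cfg), outdir)


# ---------------------------------------------------------------------------
# analyze
# ---------------------------------------------------------------------------

def _analyze_subject(
    subdir: Path, diary: SleepDiary, params: AnalysisParams
) -> Tuple[dict, Optional[TransitionMatrix]]:
    hyp = read_hypnogram_csv(subdir / "hypnogram.csv")
    obj = objective_sleep_params(hyp, params.waso_to_end_of_recording)
    row: dict = {
        "subject_id": diary.subject_id,
        "sl_obj_min": obj.sl_obj_min,
        "tst_obj_min": obj.tst_obj_min,
        "waso_obj_min": obj.waso_obj_min,
        "nawk_obj": obj.nawk_obj,
        "sl_subj_min": diary.sl_subj_min,
        "tst_subj_min": diary.tst_subj_min,
        "waso_subj_min": diary.waso_subj_min,
        "nawk_subj": diary.nawk_subj,
        "lat_n1_min": stage_latency(hyp, Stage.N1),
        "lat_n3_min": stage_latency(hyp, Stage.N3),
    }
    for s in SLEEP_STAGES:
        row[f"pct_{s.value.lower()}"] = obj.stage_pct.get(s, np.nan)

    onset_path = subdir / "onset.csv"
    lat_kc = None
    alpha_prop = np.nan
    if onset_path.exists():
        onset = read_signal_csv(onset_path)
        lat_kc = first_kc_latency(detect_kcomplexes(onset, params.kc))
        if obj.sl_obj_min and obj.sl_obj_min * 60.0 >= params.alpha.micro_epoch_s:
            window_end = min(obj.sl_obj_min, onset.t0_s / 60.0 + onset.duration_s / 60.0)
            alpha_prop = alpha_density(onset, (0.0, window_end), params.alpha).alpha_prop
    row["lat_kc_min"] = lat_kc
    row["alpha_prop"] = alpha_prop

    arousals = []
    for seg_path in sorted(subdir.glob("rem_*.csv")):
        seg = read_signal_csv(seg_path)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            arousals.extend(detect_rem_arousals(seg, hyp, params.arousal))
    aremd = rem_arousal_density(arousals, hyp) if any(
        s is Stage.REM for s in hyp.epochs
    ) else None
    row["aremd"] = np.nan if aremd is None else aremd
    row["n_rem_arousals"] = len(arousals)

    idx = compute_indices(
        diary.subject_id,
        diary.sl_subj_min,
        obj.sl_obj_min,
        diary.tst_subj_min,
        obj.tst_obj_min,
        cutoff_min=params.cutoff_min,
        ties_to=params.ties_to,
    )
    row["slm_pct"] = idx.slm_pct
    row["tstm_pct"] = idx.tstm_pct
    row["sl_discrepancy_min"] = idx.sl_discrepancy_min
    row["discrepancy_group"] = idx.discrepancy_group

    tm = subjective_sl_matrix(hyp, diary)
    return row, tm


def _spearman_entry(df: pd.DataFrame, xcol: str, ycol: str, exact_max_n: int) -> Optional[dict]:
    sub = df[[xcol, ycol]].dropna()
    if len(sub) < 3:
        return None
    try:
        res = spearman(sub[xcol], sub[ycol], exact_max_n=exact_max_n)
    except SleepSSMError:
        return None
    return {
        "x": xcol,
        "y": ycol,
        "rho": res.rho,
        "p_two_sided": res.p_two_sided,
        "n": res.n,
        "method": res.method,
    }


def analyze(
    cohort_dir: Union[str, Path],
    outdir: Union[str, Path],
    params: AnalysisParams = AnalysisParams(),
    manifest_extra: Optional[dict] = None,
) -> StudyReport:
    """Run the full analysis over a cohort directory and write report files.

    Per-subject failures are isolated: the subject is flagged in the table
    (``error`` column) and excluded from group analyses; the run continues.
    """
    cohort_dir = Path(cohort_dir)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    diaries = {d.subject_id: d for d in read_diaries_json(cohort_dir / "diaries.json")}
    rows: List[dict] = []
    matrices: List[Tuple[str, Optional[TransitionMatrix]]] = []
    for sid in sorted(diaries):
        subdir = cohort_dir / sid
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                row, tm = _analyze_subject(subdir, diaries[sid], params)
            row["error"] = ""
        except Exception as exc:  # noqa: BLE001 - per-subject isolation
            row = {"subject_id": sid, "error": f"{type(exc).__name__}: {exc}"}
            tm = None
        rows.append(row)
        matrices.append((sid, tm))

    subjects = pd.DataFrame(rows)
    ok = subjects[subjects["error"] == ""].copy() if "error" in subjects else subjects

    stats_report: dict = {"n_subjects": len(subjects), "n_failed": int((subjects.get("error", "") != "").sum())}

    gate_vars = {
        name: ok[name].dropna().to_numpy()
        for name in ("slm_pct", "tstm_pct", "alpha_prop", "aremd")
        if name in ok
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stats_report["normality"] = shapiro_wilk_gate(gate_vars)

    correlations = []
    for xcol, ycol in [
        ("alpha_prop", "slm_pct"),
        ("lat_n1_min", "slm_pct"),
        ("lat_kc_min", "slm_pct"),
        ("lat_n3_min", "slm_pct"),
        ("aremd", "tstm_pct"),
        ("alpha_prop", "tstm_pct"),
        ("pct_n1", "tstm_pct"),
        ("pct_n2", "tstm_pct"),
        ("pct_n3", "tstm_pct"),
        ("pct_rem", "tstm_pct"),
    ]:
        if xcol in ok and ycol in ok:
            entry = _spearman_entry(ok, xcol, ycol, params.exact_max_n)
            if entry is not None:
                correlations.append(entry)
    stats_report["spearman"] = correlations

    # between-group comparisons (group order fixed and logged for the
    # rank-biserial sign convention)
    g1, g2 = params.group_order
    stats_report["group_order"] = list(params.group_order)
    grouped = {g: ok[ok["discrepancy_group"] == g] for g in (g1, g2)}
    comparisons = {}
    if all(len(g) > 0 for g in grouped.values()):
        for var in ("alpha_prop", "slm_pct", "tstm_pct"):
            a = grouped[g1][var].dropna().to_numpy()
            b = grouped[g2][var].dropna().to_numpy()
            if len(a) and len(b):
                t = mann_whitney(a, b, exact_max_n=params.exact_max_n)
                comparisons[var] = {
                    "u_stat": t.u_stat,
                    "p_two_sided": t.p_two_sided,
                    "rank_biserial": t.rank_biserial,
                    "n": [t.n1, t.n2],
                    "method": t.method,
                    "mean": [float(np.mean(a)), float(np.mean(b))],
                    "sd": [
                        float(np.std(a, ddof=1)) if len(a) > 1 else 0.0,
                        float(np.std(b, ddof=1)) if len(b) > 1 else 0.0,
                    ],
                }
        tm_by_sid = dict(matrices)
        tms = {
            g: [tm_by_sid[s] for s in grouped[g]["subject_id"] if tm_by_sid.get(s) is not None]
            for g in (g1, g2)
        }
        try:
            comp = compare_transition(tms[g1], tms[g2], Stage.N1, Stage.W)
            comparisons["p_n1_to_w"] = {
                "u_stat": comp.test.u_stat,
                "p_two_sided": comp.test.p_two_sided,
                "rank_biserial": comp.test.rank_biserial,
                "n": [comp.n_a, comp.n_b],
                "n_excluded": [comp.n_excluded_a, comp.n_excluded_b],
                "method": comp.test.method,
                "mean": [comp.mean_a, comp.mean_b],
                "sd": [comp.sd_a, comp.sd_b],
            }
        except SleepSSMError as exc:
            comparisons["p_n1_to_w"] = {"error": str(exc)}
    stats_report["group_comparisons"] = comparisons

    # backward-stepwise regression: TSTm on A-REMd, alpha density, %N3
    reg_data = ok[["aremd", "alpha_prop", "pct_n3", "tstm_pct"]].dropna()
    if len(reg_data) >= 6:
        fit = backward_stepwise(
            reg_data[["aremd", "alpha_prop", "pct_n3"]],
            reg_data["tstm_pct"],
            criterion=params.stepwise_criterion,
        )
        stats_report["regression"] = {
            "response": "tstm_pct",
            "criterion": params.stepwise_criterion,
            "coefficients": fit.coefficients,
            "r2": fit.r2,
            "adj_r2": fit.adj_r2,
            "f_stat": fit.f_stat,
            "f_pvalue": fit.f_pvalue,
            "n": fit.n,
            "term_p": fit.term_p,
            "dropped": list(fit.drop_log),
        }

    transitions = matrices_to_frame(matrices)
    manifest = {
        "package": "sleepssm",
        "version": __version__,
        "analysis_params": _params_dict(params),
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    manifest["config_sha256"] = hashlib.sha256(
        json.dumps(manifest.get("analysis_params"), sort_keys=True).encode()
    ).hexdigest()

    report = StudyReport(subjects=subjects, transitions=transitions, stats=stats_report, manifest=manifest)
    _write_report(report, outdir)
    return report


def _params_dict(params: AnalysisParams) -> dict:
    d = dataclasses.asdict(params)

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    return _clean(d)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _write_report(report: StudyReport, outdir: Path) -> None:
    report.subjects.to_csv(outdir / "subjects.csv", index=False)
    report.transitions.to_csv(outdir / "transitions.csv", index=False)
    with open(outdir / "stats.json", "wt", encoding="utf-8") as fh:
        json.dump(report.stats, fh, indent=1, sort_keys=True, default=_json_default)
    with open(outdir / "manifest.json", "wt", encoding="utf-8") as fh:
        json.dump(report.manifest, fh, indent=1, sort_keys=True, default=_json_default)


def run_pipeline(cfg: RunConfig, outdir: Union[str, Path]) -> StudyReport:
    """Simulate (when configured) then analyze; returns the study report."""
    outdir = Path(outdir)
    if cfg.synthetic is not None:
        cohort_dir = simulate(cfg.synthetic, outdir / "cohort")
        extra = {"seed": cfg.synthetic.seed, "mode": "synthetic"}
    else:
        cohort_dir = Path(cfg.input_dir)
        extra = {"mode": "real"}
    return analyze(cohort_dir, outdir / "report", cfg.analysis, manifest_extra=extra)


# ---------------------------------------------------------------------------
# config loading
# ---------------------------------------------------------------------------

def load_config(path: Union[str, Path]) -> RunConfig:
    """Load a YAML run configuration.

    Recognised top-level keys: ``input_dir`` (real data) or ``synthetic``
    (generator settings, scalar fields of :class:`CohortConfig` plus a nested
    ``misperception_model``), and ``analysis`` (scalar fields of
    :class:`AnalysisParams` plus nested ``alpha``/``kc``/``arousal`` detector
    parameter overrides).
    """
    import yaml

    from .synthetic import MisperceptionModel

    with open(path, "rt", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}

    synthetic = None
    if "synthetic" in raw:
        syn = dict(raw["synthetic"] or {})
        if "misperception_model" in syn:
            syn["misperception_model"] = MisperceptionModel(**syn["misperception_model"])
        for key in ("onset_chain_low", "onset_chain_high"):
            if key in syn:
                syn[key] = np.asarray(syn[key], dtype=float)
        for key in (
            "alpha_prop_range_low",
            "alpha_prop_range_high",
            "aremd_range",
            "kc_first_latency_range_min",
        ):
            if key in syn:
                syn[key] = tuple(syn[key])
        synthetic = CohortConfig(**syn)

    ana = dict(raw.get("analysis") or {})
    for key, cls in (("alpha", AlphaParams), ("kc", KCParams), ("arousal", ArousalParams)):
        if key in ana:
            sub = dict(ana[key])
            for k, v in sub.items():
                if isinstance(v, list):
                    sub[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
            ana[key] = cls(**sub)
    if "group_order" in ana:
        ana["group_order"] = tuple(ana["group_order"])
    analysis = AnalysisParams(**ana)

    return RunConfig(synthetic=synthetic, input_dir=raw.get("input_dir"), analysis=analysis)
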