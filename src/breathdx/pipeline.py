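"""End-to-end orchestration: simulate, train, evaluate.

Ties the stages together in the fixed order

    QC -> split -> normalize -> screen -> rank -> select -> tune -> fit
       -> threshold -> evaluate

with a single master seed fanned out to deterministic per-stage seeds, and
writes every artifact as plain text (JSON / CSV / TSV).  The training path
only ever reads discovery-set samples: normalization constants, screening
statistics, feature selection, hyperparameters and the decision threshold
are all learned on the training split and merely *applied* to test and
post-operative samples.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import eval_stats, modeling, qc, screening, synth
from .tables import (PeakTable, SnrTable, read_matrix_tsv, read_sample_sheet,
                     write_sample_sheet)

__all__ = ["PipelineConfig", "TrainResult", "run_simulate", "run_train",
           "run_evaluate", "prepost_by_group"]

log = logging.getLogger("breathdx")


@dataclass
class PipelineConfig:
    """All knobs of the pipeline; defaults are the protocol's printed values."""

    peaks_path: str | None = None
    snr_path: str | None = None
    sheet_path: str | None = None
    exclusion_path: str | None = None
    out_dir: str | None = None

    snr_min: float = qc.SNR_MIN
    sample_response_min: float = qc.SAMPLE_RESPONSE_MIN
    compound_response_min: float = qc.COMPOUND_RESPONSE_MIN
    normalization: str = "median"

    train_fraction: float = 0.6
    alpha: float = 0.05
    vip_cutoff: float = 1.0
    n_orthogonal: int = 1

    delta: float = 0.005
    patience: int = 2
    cv_folds: int = 5
    grid: list | None = None
    ci_level: float = 0.95
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0,1)")
        if not 0 < self.alpha < 1 or not 0 < self.ci_level < 1:
            raise ValueError("alpha and ci_level must be in (0,1)")
        if self.vip_cutoff < 0 or self.n_orthogonal < 0:
            raise ValueError("vip_cutoff and n_orthogonal must be >= 0")
        if self.delta < 0 or self.patience < 1 or self.cv_folds < 2:
            raise ValueError("invalid selection parameters")
        if self.normalization not in ("median", "total"):
            raise ValueError("normalization must be 'median' or 'total'")

    def manifest(self) -> dict:
        d = asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str)
        return {"config": d,
                "config_sha256": hashlib.sha256(blob.encode()).hexdigest()}


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, default=_jsonable) + "\n")


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_simulate(synth_config: synth.SyntheticConfig, out_dir: str | Path,
                 overwrite: bool = False) -> dict[str, Path]:
    """Generate a synthetic cohort, write its files and a config manifest."""
    out_dir = Path(out_dir)
    peaks, snr, sheet, truth = synth.generate_cohort(synth_config)
    paths = synth.write_cohort(peaks, snr, sheet, truth, out_dir,
                               overwrite=overwrite)
    blob = json.dumps(asdict(synth_config), sort_keys=True)
    _write_json({"synthetic_config": asdict(synth_config),
                 "config_sha256": hashlib.sha256(blob.encode()).hexdigest()},
                out_dir / "manifest.json")
    paths["manifest"] = out_dir / "manifest.json"
    log.info("simulate: wrote %d samples x %d compounds to %s",
             len(peaks.sample_ids), len(peaks.compound_ids), out_dir)
    return paths


@dataclass
class TrainResult:
    qc_report: qc.QcReport
    split: modeling.SplitSpec
    normalized: qc.NormalizedMatrix
    sheet: pd.DataFrame                   # retained samples only
    screening_table: pd.DataFrame
    trace: modeling.SelectionTrace
    hyperparams: dict
    model: modeling.FittedClassifier
    train_report: eval_stats.PerfReport


def _load_inputs(config: PipelineConfig):
    peaks = PeakTable(read_matrix_tsv(config.peaks_path))
    snr = SnrTable(read_matrix_tsv(config.snr_path))
    sheet = read_sample_sheet(config.sheet_path)
    exclusion: list[str] = []
    if config.exclusion_path:
        text = Path(config.exclusion_path).read_text()
        exclusion = [ln.strip() for ln in text.splitlines()
                     if ln.strip() and not ln.startswith("#")]
    return peaks, snr, sheet, exclusion


def train_from_tables(peaks: PeakTable, snr: SnrTable, sheet: pd.DataFrame,
                      exclusion: list[str], config: PipelineConfig,
                      candidate_override: list[str] | None = None) -> TrainResult:
    """The full training path on in-memory tables.

    ``candidate_override`` replaces the screening-derived candidate list for
    ranking/selection (e.g. an externally curated biomarker panel); screened
    exclusions still apply.
    """
    config.validate()
    try:
        report, valid = qc.apply_qc(peaks, snr)
    except ValueError as e:
        raise RuntimeError(f"qc stage failed: {e}") from e
    log.info("qc: samples %d -> %d, compounds %d -> %d",
             len(peaks.sample_ids), len(report.retained_samples),
             len(peaks.compound_ids), len(report.retained_compounds))

    sheet = sheet[sheet["sample_id"].isin(report.retained_samples)].reset_index(drop=True)
    split = modeling.stratified_split(sheet, config.train_fraction, config.seed)
    log.info("split: %d train / %d test", len(split.train_ids), len(split.test_ids))

    norm = qc.normalize(valid, reference_samples=split.train_ids,
                        method=config.normalization)

    y_by_id = sheet.set_index("sample_id")["class"]
    X_train = norm.values.loc[split.train_ids]
    y_train = (y_by_id.loc[split.train_ids] == "malignant").to_numpy()
    table = screening.screen(X_train, np.where(y_train, "malignant", "benign"),
                             exclusion_list=exclusion,
                             n_orthogonal=config.n_orthogonal,
                             p_threshold=config.alpha,
                             vip_threshold=config.vip_cutoff)
    candidates = (list(candidate_override) if candidate_override is not None
                  else list(table.index[table["candidate"]]))
    candidates = [c for c in candidates if c not in set(exclusion)]
    log.info("screening: %d candidate compound(s)", len(candidates))
    if not candidates:
        raise RuntimeError("screening stage produced no candidate biomarkers")

    ranked = modeling.rank_features(X_train, y_train, candidates,
                                    p_values=table["p_value"])
    trace = modeling.forward_select(X_train, y_train, ranked,
                                    cv_folds=config.cv_folds,
                                    delta=config.delta, patience=config.patience,
                                    seed=config.seed + 1)
    feats = trace.chosen_features
    log.info("selection: chose %d feature(s)", len(feats))
    hp = modeling.grid_search_cv(X_train, y_train, feats, grid=config.grid,
                                 cv_folds=config.cv_folds, seed=config.seed + 2)
    model = modeling.fit_final(X_train, y_train, feats, hp)
    train_report = eval_stats.performance_report(
        model.predict_risk(X_train), y_train, model.threshold,
        subgroup="train", level=config.ci_level)
    return TrainResult(qc_report=report, split=split, normalized=norm,
                       sheet=sheet, screening_table=table, trace=trace,
                       hyperparams=hp, model=model, train_report=train_report)


def run_train(config: PipelineConfig,
              candidate_override: list[str] | None = None) -> TrainResult:
    """Read input files, run the training path, write the six artifacts."""
    peaks, snr, sheet, exclusion = _load_inputs(config)
    res = train_from_tables(peaks, snr, sheet, exclusion, config,
                            candidate_override=candidate_override)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_json(res.qc_report.to_dict(), out / "qc_report.json")
        _write_json(asdict(res.split), out / "split.json")
        res.screening_table.round(6).to_csv(out / "screening.csv",
                                            lineterminator="\n")
        _write_json(asdict(res.trace), out / "selection_trace.json")
        res.model.to_json(out / "model.json")
        _write_json(res.train_report.to_dict(), out / "train_report.json")
        _write_json(config.manifest(), out / "manifest.json")
    return res


def prepost_by_group(model: modeling.FittedClassifier, values: pd.DataFrame,
                     sheet: pd.DataFrame, group_mask=None,
                     alternative_test: bool = False):
    """Paired pre/post predicted-risk comparison for a diagnosis subgroup.

    Pairs are defined by ``pair_id``; ``group_mask`` is a boolean over the
    sheet rows selecting subjects (applied to the pre-op member).
    Returns ``(mean_drop, t, p, n_pairs)``.
    """
    s = sheet if group_mask is None else sheet[np.asarray(group_mask, dtype=bool)]
    pre = s[(s["timepoint"] == "preop") & (s["pair_id"] != "")]
    post = sheet[sheet["timepoint"] == "postop"].set_index("pair_id")
    pre_ids, post_ids = [], []
    for _, row in pre.iterrows():
        if row["pair_id"] in post.index:
            pre_ids.append(row["sample_id"])
            post_ids.append(post.loc[row["pair_id"], "sample_id"])
    if len(pre_ids) < 2:
        raise ValueError("fewer than two pre/post pairs in this subgroup")
    r_pre = model.predict_risk(values.loc[pre_ids])
    r_post = model.predict_risk(values.loc[post_ids])
    return eval_stats.prepost_comparison(r_pre, r_post,
                                         alternative_test=alternative_test)


def run_evaluate(config: PipelineConfig, result: TrainResult) -> dict:
    """Test-set, subgroup, serum-panel and pre/post monitoring reports."""
    model = result.model
    sheet = result.sheet
    values = result.normalized.values
    y_by_id = sheet.set_index("sample_id")["class"]
    test_ids = result.split.test_ids

    X_test = values.loc[test_ids]
    y_test = (y_by_id.loc[test_ids] == "malignant").to_numpy()
    scores = model.predict_risk(X_test)
    reports = {"test": eval_stats.performance_report(
        scores, y_test, model.threshold, subgroup="test", level=config.ci_level)}

    info = sheet.set_index("sample_id").loc[test_ids]
    subtype = info["subtype"].to_numpy()
    stage = info["stage"].to_numpy()
    benign = ~y_test
    for st in ("LC", "thymoma", "EC"):
        mask = (subtype == st) | benign
        if (subtype == st).sum() > 0:
            reports[f"{st}_vs_benign"] = eval_stats.performance_report(
                scores, y_test, model.threshold, subgroup_mask=mask,
                subgroup=f"{st}_vs_benign", level=config.ci_level)
    early = np.isin(stage, ("0", "I", "II"))
    late = np.isin(stage, ("III", "IV"))
    for name, smask in (("stage_0_I_II", early), ("stage_III_IV", late)):
        mask = smask | benign
        if smask.sum() > 0:
            reports[name] = eval_stats.performance_report(
                scores, y_test, model.threshold, subgroup_mask=mask,
                subgroup=name, level=config.ci_level)

    out: dict = {"reports": reports}

    # serum-panel comparison on test-set malignant samples with any marker value
    panel = eval_stats.serum_panel_classify(sheet)
    mal_test = [sid for sid, is_pos in zip(test_ids, y_test) if is_pos]
    usable = [sid for sid in mal_test if not panel.loc[sid, "excluded"]]
    if usable:
        voc_correct = model.predict_risk(values.loc[usable]) >= model.threshold
        panel_correct = panel.loc[usable, "panel_positive"].to_numpy()
        b, c, p = eval_stats.mcnemar_test(voc_correct, panel_correct)
        out["serum_comparison"] = {
            "n": len(usable),
            "voc_sensitivity": float(np.mean(voc_correct)),
            "panel_sensitivity": float(np.mean(panel_correct)),
            "mcnemar_b": b, "mcnemar_c": c, "mcnemar_p": p,
            "n_excluded_all_markers_missing": int(len(mal_test) - len(usable)),
        }

    # pre/post monitoring
    monitoring = {}
    for name, mask in (("malignant", (sheet["class"] == "malignant").to_numpy()),
                       ("benign", (sheet["class"] == "benign").to_numpy())):
        try:
            drop, t, p, n = prepost_by_group(model, values, sheet, mask)
        except ValueError:
            continue
        monitoring[name] = {"mean_drop": drop, "t": t, "p": p, "n_pairs": n}
    if monitoring:
        out["monitoring"] = monitoring

    if config.out_dir:
        outdir = Path(config.out_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        payload = {k: (v.to_dict() if hasattr(v, "to_dict") else v)
                   for k, v in reports.items()}
        _write_json({"reports": payload,
                     **{k: v for k, v in out.items() if k != "reports"}},
                    outdir / "evaluation.json")
        rows = []
        for name, rep in reports.items():
            d = rep.to_dict()
            for metric in ("auc", "sensitivity", "specificity", "accuracy", "f1"):
                ci = d[f"{metric}_ci"] or (None, None)
                rows.append({"subgroup": name, "metric": metric,
                             "estimate": d[metric], "lower": ci[0],
                             "upper": ci[1], "n": d["n"]})
        pd.DataFrame(rows).to_csv(outdir / "subgroup_summary.csv", index=False,
                                  lineterminator="\n")
    return out
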