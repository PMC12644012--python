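"""Evaluation metrics, stratified splitting, cross-validation, and the
end-to-end pipeline.

Metric definitions (positive class = ictal, everywhere):

    ACC = (TP + TN) / (TP + TN + FP + FN)
    SEN = TP / (TP + FN)          SPE = TN / (TN + FP)
    PRE = TP / (TP + FP)          F1  = 2 TP / (2 TP + FN + FP)

Degenerate 0/0 denominators yield 0 with a warning so that fold reports
are always well-formed. AUC is the trapezoidal area under the ROC curve
over all score thresholds, which equals the Mann-Whitney U statistic
divided by n_pos * n_neg (ties contribute 1/2).

The pipeline (``run_pipeline``) wires the stages end to end: generate or
load segments, band-pass filter, DWT feature extraction, then either a
stratified 80/20 holdout or stratified fivefold cross-validation, with
min-max normalization and two-stage balancing fitted inside each
training split only.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

from .balancing import BalanceConfig, two_stage_balance
from .features import (FeatureTable, FuzzyEnSpec, apply_normalizer,
                       build_feature_table, fit_normalizer)
from .model import (ClassifierConfig, CsaeConfig, build_classifier,
                    predict_proba, pretrain_csae, save_bundle,
                    train_classifier)
from .signal_io import FilterSpec, bandpass_filter

__all__ = [
    "ConfusionCounts", "EvalReport", "confusion_counts", "classification_metrics",
    "roc_auc", "stratified_split", "kfold_cross_validate", "make_default_runner",
    "run_pipeline",
]

log = logging.getLogger("szpipe")

METRIC_NAMES = ("ACC", "SEN", "SPE", "PRE", "F1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvalReport:
    """Per-fold confusion counts, metrics, ROC points and their averages."""

    per_fold: list = field(default_factory=list)  # dicts with counts/metrics/roc
    mean: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    config_hash: str = ""

    def finalize(self) -> None:
        keys = list(METRIC_NAMES) + ["AUC"]
        self.mean = {k: float(np.mean([f[k] for f in self.per_fold])) for k in keys}


def confusion_counts(y_true, y_pred, positive_label=1) -> ConfusionCounts:
    """Tally TP/FP/TN/FN for binary label vectors."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    labels = set(np.unique(y_true)) | set(np.unique(y_pred))
    if len(labels) > 2:
        raise ValueError(f"labels are not binary: {sorted(map(str, labels))}")
    t = y_true == positive_label
    p = y_pred == positive_label
    return ConfusionCounts(
        tp=int(np.sum(t & p)), fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)), fn=int(np.sum(t & ~p)),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: 0/0 denominator, reporting 0")
        return 0.0
    return num / den


def classification_metrics(c: ConfusionCounts) -> dict:
    """ACC/SEN/SPE/PRE/F1 from confusion counts; 0/0 denominators give 0."""
    if c.n == 0:
        raise ValueError("empty confusion counts")
    return {
        "ACC": (c.tp + c.tn) / c.n,
        "SEN": _ratio(c.tp, c.tp + c.fn, "SEN"),
        "SPE": _ratio(c.tn, c.tn + c.fp, "SPE"),
        "PRE": _ratio(c.tp, c.tp + c.fp, "PRE"),
        "F1": _ratio(2 * c.tp, 2 * c.tp + c.fn + c.fp, "F1"),
    }


def roc_auc(y_true, scores, positive_label=1):
    """Trapezoidal AUC over all thresholds plus the ROC points.

    Returns ``(auc, fpr, tpr)``. Equals the tie-corrected Mann-Whitney
    statistic U / (n_pos * n_neg).
    """
    y = np.asarray(y_true) == positive_label
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("roc_auc needs both classes present")
    fpr, tpr, _ = roc_curve(y.astype(int), s)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, fpr, tpr


def stratified_split(table: FeatureTable, test_frac: float = 0.2, seed: int = 0):
    """Stratified holdout; the test table keeps the natural class mix."""
    if not (0 < test_frac < 1):
        raise ValueError("test_frac must be in (0, 1)")
    labels, counts = np.unique(table.labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError(f"every class needs >= 2 rows, got {dict(zip(labels, counts))}")
    idx = np.arange(table.n_rows)
    tr, te = train_test_split(idx, test_size=test_frac, random_state=seed,
                              stratify=table.labels)
    return table.subset(np.sort(tr), role="train"), table.subset(np.sort(te), role="test")


def _fold_result(y_true01, y_pred01, scores, fold: int) -> dict:
    c = confusion_counts(y_true01, y_pred01, positive_label=1)
    res = {"fold": fold, "TP": c.tp, "FP": c.fp, "TN": c.tn, "FN": c.fn}
    res.update(classification_metrics(c))
    auc, fpr, tpr = roc_auc(y_true01, scores, positive_label=1)
    res["AUC"] = auc
    res["roc"] = {"fpr": fpr.tolist(), "tpr": tpr.tolist()}
    return res


def kfold_cross_validate(table: FeatureTable, k: int = 5, runner=None,
                         seed: int = 0) -> EvalReport:
    """Stratified k-fold CV; ``runner(train_table, test_table, fold_seed)``
    must return ``(y_true01, y_pred01, scores)`` for the test rows.

    Normalization and balancing happen inside the runner on the training
    fold only; the test fold keeps its natural distribution.
    """
    if runner is None:
        raise ValueError("kfold_cross_validate needs a runner")
    labels, counts = np.unique(table.labels, return_counts=True)
    if k > table.n_rows:
        raise ValueError("k exceeds the number of rows")
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the smallest class count {counts.min()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    report = EvalReport(seeds={"cv_seed": seed})
    for fold, (tr, te) in enumerate(skf.split(table.values, table.labels)):
        train_t = table.subset(tr, role="train")
        test_t = table.subset(te, role="test")
        fold_seed = (seed + 1009 * (fold + 1)) % (2 ** 31)
        y_true, y_pred, scores = runner(train_t, test_t, fold_seed)
        report.per_fold.append(_fold_result(y_true, y_pred, scores, fold))
        log.info("fold %d: %s", fold,
                 {k_: round(report.per_fold[-1][k_], 4) for k_ in METRIC_NAMES})
    report.finalize()
    return report


def make_default_runner(balance_cfg: BalanceConfig = BalanceConfig(),
                        csae_cfg: CsaeConfig = CsaeConfig(),
                        clf_cfg: ClassifierConfig = ClassifierConfig(),
                        collect: dict | None = None):
    """The canonical training recipe as a CV runner.

    Per training split: fit the min-max normalizer, normalize, two-stage
    balance, pretrain the CSAE, transfer the encoder, train the GRU
    head; then normalize the test split with the *training* map and
    predict. ``collect``, if given, accumulates balance reports and the
    last trained bundle for artifact dumping.
    """
    from dataclasses import replace

    def runner(train_t: FeatureTable, test_t: FeatureTable, fold_seed: int):
        mm = fit_normalizer(train_t)
        train_n = apply_normalizer(train_t, mm)
        test_n = apply_normalizer(test_t, mm)
        balanced, bal_report = two_stage_balance(train_n, balance_cfg)
        csae, ae_hist = pretrain_csae(balanced.values, csae_cfg, seed=fold_seed)
        cfg = replace(clf_cfg, seed=fold_seed)
        bundle = build_classifier(csae, cfg)
        train_classifier(bundle, balanced, cfg)
        proba = predict_proba(bundle, test_n)
        y_pred = np.argmax(proba, axis=1)
        pos = bundle.class_labels[1]
        y_true = (test_n.labels == pos).astype(int)
        if collect is not None:
            collect.setdefault("balance_reports", []).append(bal_report)
            collect["bundle"] = bundle
            collect.setdefault("ae_histories", []).append(ae_hist)
        return y_true, y_pred, proba[:, 1]

    return runner


# ---------------------------------------------------------------------------
# end-to-end pipeline


DEFAULT_CONFIG = {
    "synth": {},           # SynthConfig fields
    "filter": {"low_hz": 0.5, "high_hz": 60.0, "order": 5, "zero_phase": True},
    "features": {"m": 2, "r": 0.2, "grad": 2.0},
    "balance": {},         # BalanceConfig fields
    "csae": {},            # CsaeConfig fields
    "classifier": {},      # ClassifierConfig fields
    "eval": {"mode": "cv5", "k": 5, "test_frac": 0.2, "seed": 0},
    "output": {"dir": "szpipe_out"},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if k not in base:
            raise ValueError(f"unknown config section or key: {k}")
        out[k] = {**base[k], **(v or {})} if isinstance(base[k], dict) else v
    return out


def _validate_config(cfg: dict) -> None:
    mode = cfg["eval"].get("mode", "cv5")
    if mode not in ("cv5", "holdout"):
        raise ValueError(f"eval.mode must be 'cv5' or 'holdout', got {mode!r}")
    tf = cfg["eval"].get("test_frac", 0.2)
    if not (0 < tf < 1):
        raise ValueError(f"eval.test_frac must be in (0, 1), got {tf}")
    if cfg["eval"].get("k", 5) < 2:
        raise ValueError("eval.k must be >= 2")


def _metrics_csv(report: EvalReport, path) -> None:
    rows = []
    for f in report.per_fold:
        rows.append({"fold": f["fold"],
                     **{k: f"{f[k]:.6f}" for k in list(METRIC_NAMES) + ["AUC"]}})
    rows.append({"fold": "mean",
                 **{k: f"{report.mean[k]:.6f}" for k in list(METRIC_NAMES) + ["AUC"]}})
    pd.DataFrame(rows).to_csv(path, index=False)


def run_pipeline(config, outdir=None) -> EvalReport:
    """Run the full detection pipeline from a config dict or YAML path.

    Writes metrics CSV, JSON report, model checkpoint, balance report and
    a log file into the output directory, and returns the
    :class:`EvalReport`.
    """
    from pathlib import Path

    from .synthdata import SynthConfig, gen_dataset

    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = _merge(DEFAULT_CONFIG, config)
    _validate_config(cfg)

    out = Path(outdir if outdir is not None else cfg["output"]["dir"])
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        stage = "synthesize"
        synth_cfg = SynthConfig(**cfg["synth"])
        segments = gen_dataset(synth_cfg)
        log.info("generated %d segments (%s)", len(segments),
                 {k: v for k, v in cfg["synth"].items()})

        stage = "filter"
        fspec = FilterSpec(**cfg["filter"])
        segments = [bandpass_filter(s, fspec) for s in segments]

        stage = "features"
        fz = FuzzyEnSpec(**cfg["features"])
        table = build_feature_table(segments, fuzzy_spec=fz)
        log.info("feature table %d x %d", table.n_rows, table.n_features)

        stage = "evaluate"
        bal = BalanceConfig(**cfg["balance"])
        csae_cfg = CsaeConfig(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in cfg["csae"].items()})
        clf_cfg = ClassifierConfig(**cfg["classifier"])
        seed = int(cfg["eval"]["seed"])
        collect: dict = {}
        runner = make_default_runner(bal, csae_cfg, clf_cfg, collect=collect)
        if cfg["eval"]["mode"] == "cv5":
            report = kfold_cross_validate(table, k=int(cfg["eval"]["k"]),
                                          runner=runner, seed=seed)
        else:
            train_t, test_t = stratified_split(table, cfg["eval"]["test_frac"], seed)
            y_true, y_pred, scores = runner(train_t, test_t, seed)
            report = EvalReport(seeds={"holdout_seed": seed})
            report.per_fold.append(_fold_result(y_true, y_pred, scores, 0))
            report.finalize()
        report.config_hash = hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]
        report.seeds["pipeline_seed"] = seed

        stage = "artifacts"
        _metrics_csv(report, out / "metrics.csv")
        with open(out / "report.json", "w") as fh:
            json.dump({"per_fold": report.per_fold, "mean": report.mean,
                       "seeds": report.seeds, "config_hash": report.config_hash},
                      fh, indent=2)
        with open(out / "balance_report.json", "w") as fh:
            json.dump(collect.get("balance_reports", []), fh, indent=2)
        if "bundle" in collect:
            save_bundle(out / "model.npz", collect["bundle"])
        log.info("mean metrics: %s", {k: round(v, 4) for k, v in report.mean.items()})
        return report
    except Exception as err:
        log.error("pipeline failed at stage %r: %s", stage, err)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    finally:
        log.removeHandler(handler)
        handler.close()
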