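"""End-to-end orchestration: read records -> extract features ->
quantize -> coalition game -> ranking -> optional cross-validated
evaluation.

Everything here is thin glue over the library modules; each ``run_*``
step reads/writes delimited text in a run directory and drops the fully
resolved configuration next to its outputs so a run can be reproduced
bit-for-bit (exact paths) or distributionally (Monte-Carlo paths).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB

from . import banzhaf, infotheory, synth, wavelets

__all__ = [
    "RunConfig",
    "run_extract",
    "run_select",
    "run_evaluate",
    "select_with_banzhaf",
    "select_with_mi",
    "evaluate_features",
]

log = logging.getLogger("banzhafselect")

DEFAULT_K = 20
DEFAULT_CV_FOLDS = 10


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run."""

    records_dir: str | None = None
    features_path: str | None = None
    ranking_path: str | None = None
    out_dir: str = "run"
    channel_wavelets: dict[str, str] = field(
        default_factory=lambda: {"ECGII": "db8", "ABP": "db4", "PLETH": "db4"}
    )
    levels: int = 6
    grouping_mode: str = "details_plus_final_approx"
    boundary_mode: str = "symmetric"
    n_quant_levels: int = 5
    k: int = DEFAULT_K
    method: str = "auto"
    mc_samples: int = banzhaf.DEFAULT_MC_SAMPLES
    seed: int = 0
    cv_folds: int = DEFAULT_CV_FOLDS

    def wavelet_config(self) -> wavelets.WaveletConfig:
        return wavelets.WaveletConfig(
            wavelet_by_channel=self.channel_wavelets,
            levels=self.levels,
            grouping_mode=self.grouping_mode,
            boundary_mode=self.boundary_mode,
        )

    def save(self, path) -> None:
        from . import __version__

        payload = dataclasses.asdict(self)
        payload["software_version"] = __version__
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def load(cls, path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        payload.pop("software_version", None)
        return cls(**payload)


def _prepare_out(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.json")
    return out


def run_extract(config: RunConfig) -> Path:
    """Read records from ``config.records_dir``, extract the wavelet
    feature table, and write ``features.csv``.

    Per-record failures are collected and logged; the run continues as
    long as at least one record succeeds and raises only if all fail.
    """
    if config.records_dir is None:
        raise ValueError("records_dir is required for extraction")
    records = synth.read_records(config.records_dir)
    if not records:
        raise RuntimeError(f"no records found in {config.records_dir}")
    out = _prepare_out(config)
    wconfig = config.wavelet_config()
    good, failures = [], []
    for rec in records:
        try:
            wavelets.decompose_record(rec, wconfig)  # validation pass
            good.append(rec)
        except Exception as exc:  # noqa: BLE001 - per-record isolation
            failures.append((rec.record_id, str(exc)))
            log.warning("record %s failed: %s", rec.record_id, exc)
    if not good:
        raise RuntimeError(f"all {len(records)} records failed extraction: {failures}")
    table = wavelets.build_feature_table(good, wconfig)
    path = out / "features.csv"
    table.to_csv(path)
    status = pd.DataFrame(
        [{"record_id": r.record_id, "status": "ok", "error": ""} for r in good]
        + [{"record_id": rid, "status": "failed", "error": err} for rid, err in failures]
    )
    status.to_csv(out / "extract_status.csv", index=False)
    log.info("extracted %d/%d records -> %s", len(good), len(records), path)
    return path


def run_select(config: RunConfig, persist_matrix: bool = False) -> Path:
    """Discretize the feature table, build the interdependency matrix,
    rank features by Banzhaf power, and write ``ranking.csv``."""
    features_path = config.features_path or str(Path(config.out_dir) / "features.csv")
    table = pd.read_csv(features_path, index_col=0)
    if "label" not in table.columns:
        raise ValueError(f"{features_path} has no 'label' column")
    out = _prepare_out(config)
    dtable = infotheory.discretize_table(table, n_levels=config.n_quant_levels)
    r, D = infotheory.interdependency_matrix(dtable)
    ranking = banzhaf.rank_features(
        D,
        k=config.k,
        method=config.method,
        feature_names=dtable.feature_names,
        n_samples=config.mc_samples,
        seed=config.seed,
    )
    path = out / "ranking.csv"
    ranking.to_csv(path, index=False)
    if persist_matrix:
        pd.DataFrame(D, index=dtable.feature_names, columns=dtable.feature_names).to_csv(
            out / "interdependency.csv"
        )
        pd.Series(r, index=dtable.feature_names, name="relevance_bits").to_csv(out / "relevance.csv")
    log.info("ranked %d features -> %s", len(dtable.feature_names), path)
    return path


def run_evaluate(config: RunConfig, classifier=None) -> Path:
    """Stratified k-fold cross-validation of a classifier on the selected
    features; writes ``metrics.json``."""
    features_path = config.features_path or str(Path(config.out_dir) / "features.csv")
    ranking_path = config.ranking_path or str(Path(config.out_dir) / "ranking.csv")
    table = pd.read_csv(features_path, index_col=0)
    ranking = pd.read_csv(ranking_path)
    selected = [f for f in ranking["feature"] if f in table.columns]
    out = _prepare_out(config)
    metrics = evaluate_features(
        table, selected, seed=config.seed, classifier=classifier, n_folds=config.cv_folds
    )
    path = out / "metrics.json"
    path.write_text(json.dumps(metrics, indent=2) + "\n")
    log.info("evaluation -> %s", path)
    return path


# ---------------------------------------------------------------------------
# library-level selection and evaluation helpers
# ---------------------------------------------------------------------------

def select_with_banzhaf(
    table: pd.DataFrame,
    k: int = DEFAULT_K,
    n_quant_levels: int = infotheory.DEFAULT_LEVELS,
    method: str = "auto",
    mc_samples: int = banzhaf.DEFAULT_MC_SAMPLES,
    seed: int | None = None,
) -> pd.DataFrame:
    """Full selection pass on a labeled table: Lloyd discretization,
    interdependency matrix, Banzhaf ranking.  Returns the top-``k``
    ranking DataFrame."""
    dtable = infotheory.discretize_table(table, n_levels=n_quant_levels)
    _, D = infotheory.interdependency_matrix(dtable)
    return banzhaf.rank_features(
        D, k=k, method=method, feature_names=dtable.feature_names,
        n_samples=mc_samples, seed=seed,
    )


def select_with_mi(
    table: pd.DataFrame, k: int = DEFAULT_K, n_quant_levels: int = infotheory.DEFAULT_LEVELS
) -> pd.DataFrame:
    """Univariate baseline: rank features by plug-in I(F;C) on the same
    Lloyd-discretized codes.  Ties broken by ascending column order."""
    dtable = infotheory.discretize_table(table, n_levels=n_quant_levels)
    lab = dtable.label.to_numpy()
    mi = np.array(
        [infotheory.mutual_information(dtable.codes[c].to_numpy(), lab) for c in dtable.feature_names]
    )
    order = np.argsort(-mi, kind="stable")
    names = dtable.feature_names
    full = pd.DataFrame(
        {
            "rank": np.arange(1, len(names) + 1),
            "feature": [names[i] for i in order],
            "mi_bits": mi[order],
        }
    )
    return full.head(k)


def evaluate_features(
    table: pd.DataFrame,
    features: Sequence[str],
    seed: int = 0,
    classifier=None,
    n_folds: int = DEFAULT_CV_FOLDS,
) -> dict:
    """Stratified cross-validated accuracy / sensitivity / specificity /
    AUC on the given feature columns.

    Positive class is the true alarm (label 1): sensitivity is the
    fraction of true alarms recognized, specificity the fraction of
    false alarms recognized.  The default classifier is Gaussian naive
    Bayes; pass any sklearn-style estimator to swap it (interaction-aware
    models are needed to exploit synergistic features).
    """
    features = list(features)
    if not features:
        raise ValueError("no features selected")
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise ValueError(f"features not in table: {missing}")
    X = table[features].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=np.int64)
    if classifier is None:
        classifier = GaussianNB()
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    prob = np.full(y.size, np.nan)
    pred = np.zeros(y.size, dtype=np.int64)
    degenerate_folds = 0
    import sklearn.base

    for train, test in skf.split(X, y):
        if np.unique(y[train]).size < 2:
            degenerate_folds += 1
            continue
        model = sklearn.base.clone(classifier)
        model.fit(X[train], y[train])
        prob[test] = model.predict_proba(X[test])[:, 1]
        pred[test] = model.predict(X[test])
    scored = ~np.isnan(prob)
    tp = int(np.sum((pred == 1) & (y == 1) & scored))
    fn = int(np.sum((pred == 0) & (y == 1) & scored))
    tn = int(np.sum((pred == 0) & (y == 0) & scored))
    fp = int(np.sum((pred == 1) & (y == 0) & scored))
    return {
        "n_samples": int(scored.sum()),
        "n_features": len(features),
        "accuracy": (tp + tn) / max(tp + tn + fp + fn, 1),
        "sensitivity": tp / max(tp + fn, 1),
        "specificity": tn / max(tn + fp, 1),
        "auc": float(roc_auc_score(y[scored], prob[scored])) if np.unique(y[scored]).size == 2 else float("nan"),
        "degenerate_folds": degenerate_folds,
        "cv_folds": n_folds,
        "seed": seed,
    }


def interaction_classifier(seed: int = 0) -> RandomForestClassifier:
    """An interaction-aware classifier for benchmarks where the signal is
    synergistic (a naive-Bayes model is additive per feature and cannot
    represent an XOR decision boundary)."""
    return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
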