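"""Experiment orchestration: classical baselines, end-to-end benchmark runs.

The classical reference ensembles are a random forest tuned with
RandomizedSearchCV and XGBoost tuned with an exhaustive GridSearchCV, each
over the study's published search spaces. ``run_experiment`` wires one
configuration end to end: generate or load data, split, scale (and
optionally PCA-reduce), train the requested classifier on every split, and
aggregate the metrics.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import evalstats, qcc, qec, synthdata
from .aggregate import bagging_fit, boosting_fit, soft_vote_fit
from .evalstats import MetricRecord, aggregate_splits, score_split
from .synthdata import BlobConfig, ExpressionSimConfig, LabeledDataset
from .varqc import TrainingConfig

logger = logging.getLogger("qensemble")

#: randomized-search space for the random forest baseline
RF_SEARCH_SPACE = {
    "n_estimators": list(range(100, 1001, 100)),
    "max_depth": list(range(5, 21)),
    "min_samples_split": list(range(2, 11)),
    "min_samples_leaf": list(range(1, 6)),
    "max_features": ["sqrt", "log2"],
}

#: exhaustive grid for the XGBoost baseline (486 combinations)
XGB_SEARCH_SPACE = {
    "n_estimators": [100, 200],
    "max_depth": [3, 5, 7],
    "learning_rate": [0.01, 0.1, 0.2],
    "subsample": [0.7, 0.8, 1.0],
    "colsample_bytree": [0.7, 0.8, 1.0],
    "min_child_weight": [1, 3, 5],
}

RF_N_ITER = 50
BASELINE_CV_FOLDS = 4


def xgb_grid_size(space: dict | None = None) -> int:
    space = XGB_SEARCH_SPACE if space is None else space
    return int(np.prod([len(v) for v in space.values()]))


def rf_baseline(X: np.ndarray, y: np.ndarray, seed: int | None = None,
                n_iter: int = RF_N_ITER, cv: int = BASELINE_CV_FOLDS,
                search_space: dict | None = None):
    """Randomized-search-tuned random forest; returns the refit best model."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import RandomizedSearchCV

    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty training data")
    search = RandomizedSearchCV(
        RandomForestClassifier(random_state=seed),
        search_space or RF_SEARCH_SPACE,
        n_iter=n_iter,
        cv=cv,
        random_state=seed,
        n_jobs=1,
    )
    search.fit(X, y)
    return search.best_estimator_


def xgb_baseline(X: np.ndarray, y: np.ndarray, seed: int | None = None,
                 cv: int = BASELINE_CV_FOLDS, search_space: dict | None = None):
    """Grid-search-tuned XGBoost classifier; returns the refit best model."""
    from sklearn.model_selection import GridSearchCV
    from xgboost import XGBClassifier

    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty training data")
    search = GridSearchCV(
        XGBClassifier(random_state=seed, eval_metric="logloss"),
        search_space or XGB_SEARCH_SPACE,
        cv=cv,
        n_jobs=1,
    )
    search.fit(X, y)
    return search.best_estimator_


@dataclass
class RunConfig:
    """One benchmark run: a dataset spec, a classifier spec, and protocol knobs."""

    classifier: str
    dataset: dict[str, Any] = field(default_factory=lambda: {"kind": "blobs"})
    n_splits: int = 10
    train_frac: float = 0.8
    shots: int | None = None
    pca_components: int | None = None
    seed: int = 0
    outdir: str | None = None
    params: dict[str, Any] = field(default_factory=dict)

    KNOWN = ("qcc", "qec", "qecru", "soft_vote", "bagging", "boosting", "rf", "xgboost")

    def __post_init__(self) -> None:
        if self.classifier not in self.KNOWN:
            raise ValueError(
                f"unknown classifier {self.classifier!r}; expected one of {self.KNOWN}"
            )


def _load_dataset(spec: dict[str, Any], rng: np.random.Generator) -> LabeledDataset:
    kind = spec.get("kind", "blobs")
    if kind == "blobs":
        cfg = BlobConfig(
            cluster_std=spec.get("cluster_std", 0.3),
            p1=spec.get("p1", 0.3),
            p2=spec.get("p2", 1.0),
            n_samples=spec.get("n_samples", 100),
            seed=int(rng.integers(2**31 - 1)),
        )
        return synthdata.make_blob_dataset(cfg)
    if kind == "expression":
        cfg = ExpressionSimConfig(
            n_samples=spec.get("n_samples", 150),
            n_genes=spec.get("n_genes", 2000),
            n_informative=spec.get("n_informative", 8),
            effect_size=spec.get("effect_size", 1.0),
            responder_fraction=spec.get("responder_fraction", 0.35),
            seed=int(rng.integers(2**31 - 1)),
        )
        return synthdata.simulate_expression(cfg)[0]
    if kind == "tsv":
        return synthdata.read_tsv(spec["path"], name=str(spec["path"]))
    raise ValueError(f"unknown dataset kind {kind!r}")


def _split_probabilities(cfg: RunConfig, X_tr, y_tr, X_te, rng) -> np.ndarray:
    """Class-1 probabilities for one split under the configured classifier."""
    p = cfg.params
    seed = int(rng.integers(2**31 - 1))
    if cfg.classifier == "qcc":
        idx = rng.integers(X_tr.shape[0])  # randomly selected training sample
        return np.array([
            qcc.predict_qcc(
                qcc.QCCInstance(X_tr[idx], int(y_tr[idx]), xt),
                shots=cfg.shots, rng=rng,
            )
            for xt in X_te
        ])
    if cfg.classifier in ("qec", "qecru"):
        qcfg = qec.QECConfig(
            d=p.get("d", 1),
            n_train=p.get("n_train", 2),
            n_feature=X_tr.shape[1],
            n_swap=p.get("n_swap", 1),
            variant="haar" if cfg.classifier == "qecru" else "swap",
            seed=seed,
        )
        sel = rng.choice(X_tr.shape[0], size=qcfg.n_train, replace=False)
        traj = qec.draw_trajectories(qcfg, np.random.default_rng(seed))
        return np.array([
            qec.predict_qec(qcfg, X_tr[sel], y_tr[sel], xt, traj,
                            shots=cfg.shots, rng=rng)
            for xt in X_te
        ])
    if cfg.classifier in ("soft_vote", "bagging", "boosting"):
        tcfg = TrainingConfig(
            learning_rate=p.get("learning_rate", 1e-1),
            batch_size=p.get("batch_size", 4),
            ensemble_size=p.get("ensemble_size", 3),
            epochs=p.get("epochs", 30),
            seed=seed,
        )
        k = tcfg.ensemble_size
        if cfg.classifier == "soft_vote":
            ens = soft_vote_fit(X_tr, y_tr, tcfg)
        elif cfg.classifier == "bagging":
            ens = bagging_fit(X_tr, y_tr, k, tcfg)
        else:
            ens = boosting_fit(X_tr, y_tr, k, tcfg)
        return np.array([ens.predict_proba(xt) for xt in X_te])
    if cfg.classifier == "rf":
        model = rf_baseline(X_tr, y_tr, seed=seed,
                            n_iter=p.get("n_iter", RF_N_ITER),
                            search_space=p.get("search_space"))
    else:
        model = xgb_baseline(X_tr, y_tr, seed=seed,
                             search_space=p.get("search_space"))
    return model.predict_proba(X_te)[:, 1]


def run_experiment(cfg: RunConfig) -> dict[str, Any]:
    """Execute one full benchmark run; returns (and optionally writes) the bundle."""
    rng = np.random.default_rng(cfg.seed)
    t0 = time.time()
    dataset = _load_dataset(cfg.dataset, rng)
    splits = synthdata.make_splits(dataset, n_splits=cfg.n_splits,
                                   train_frac=cfg.train_frac,
                                   seed=int(rng.integers(2**31 - 1)))
    logger.info("dataset %s: %s samples, %s splits",
                dataset.name, dataset.X.shape[0], len(splits))

    records: list[MetricRecord] = []
    predictions = []
    quantum = cfg.classifier not in ("rf", "xgboost")
    for split_id, (tr, te) in enumerate(splits):
        X_tr, X_te = synthdata.minmax_scale(dataset.X[tr], dataset.X[te])
        y_tr, y_te = dataset.y[tr], dataset.y[te]
        if quantum and cfg.pca_components:
            X_tr, X_te, _ = synthdata.pca_reduce(
                X_tr, X_te, cfg.pca_components, seed=cfg.seed)
        probs = _split_probabilities(cfg, X_tr, y_tr, X_te, rng)
        records.append(score_split(cfg.classifier, split_id, y_te, probs))
        for sample, prob in zip(te, probs):
            predictions.append({
                "split": split_id, "sample": int(sample),
                "p_class1": float(prob), "predicted": int(prob >= 0.5),
                "label": int(dataset.y[sample]),
            })
        logger.info("split %d: acc=%.3f f1=%.3f brier=%.3f", split_id,
                    records[-1].accuracy, records[-1].weighted_f1,
                    records[-1].brier)

    summary = aggregate_splits(records)
    bundle = {
        "classifier": cfg.classifier,
        "dataset": dataset.name,
        "seed": cfg.seed,
        "n_splits": cfg.n_splits,
        "elapsed_s": round(time.time() - t0, 3),
        "summary": summary.to_dict(orient="records"),
        "records": [r.__dict__ for r in records],
    }
    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        evalstats.records_frame(records).to_csv(out / "metrics.tsv", sep="\t",
                                                index=False)
        import pandas as pd

        pd.DataFrame(predictions).to_csv(out / "predictions.tsv", sep="\t",
                                         index=False)
        (out / "summary.json").write_text(json.dumps(bundle, indent=2, sort_keys=True))
    return bundle
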