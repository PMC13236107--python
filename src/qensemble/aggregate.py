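"""Ensemble constructions over variational learners.

Three classical aggregation schemes over the shallow variational weak
learners: soft voting (every learner sees all training data, predictions are
averaged), bagging (learners train on disjoint near-equal partitions), and
AdaBoost-style boosting (sample weights increase on misclassified examples,
each round trains on a weight-proportional subset). A soft-voting ensemble
of l learners on n qubits each can also be instantiated as one joint
tensor-product circuit of n*l qubits, which is how its hardware footprint is
sized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .varqc import (
    TrainingConfig,
    VariationalLearner,
    n_qubits_for_features,
    predict_proba,
    random_learner,
    train_learner,
)

EPS_ERR = 1e-6


@dataclass
class Ensemble:
    """A trained ensemble: learners, aggregation kind, weights, data partition."""

    learners: list[VariationalLearner]
    kind: str
    learner_weights: np.ndarray | None = None
    partition: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("soft_vote", "bagging", "boosting"):
            raise ValueError(f"unknown ensemble kind {self.kind!r}")
        if not self.learners:
            raise ValueError("ensemble has no learners")
        if self.learner_weights is not None:
            w = np.asarray(self.learner_weights, dtype=float)
            if np.any(w < 0) or not np.all(np.isfinite(w)):
                raise ValueError("learner weights must be finite and nonnegative")
            self.learner_weights = w

    def predict_proba(self, x: Sequence[float]) -> float:
        probs = np.array([predict_proba(lrn, x) for lrn in self.learners])
        if self.kind == "soft_vote" or self.learner_weights is None:
            return float(probs.mean())
        w = self.learner_weights
        if w.sum() == 0:
            return float(probs.mean())
        return float(np.average(probs, weights=w))

    def predict(self, x: Sequence[float]) -> int:
        return 1 if self.predict_proba(x) >= 0.5 else 0


def soft_vote_predict(ensemble: Ensemble, x: Sequence[float]) -> float:
    """Unweighted mean of the member probabilities, (1/K) sum_k p_k(y=1)."""
    if ensemble.kind != "soft_vote":
        raise ValueError("soft_vote_predict requires a soft_vote ensemble")
    probs = [predict_proba(lrn, x) for lrn in ensemble.learners]
    return float(np.mean(probs))


def instantiate_joint(ensemble: Ensemble) -> int:
    """Qubit width of the tensor-product joint circuit: n qubits x l learners."""
    widths = {lrn.n_qubits for lrn in ensemble.learners}
    if len(widths) != 1:
        raise ValueError("joint instantiation requires homogeneous learner widths")
    return widths.pop() * len(ensemble.learners)


def _new_learners(n_features: int, k: int, rng: np.random.Generator
                  ) -> list[VariationalLearner]:
    n_qubits = n_qubits_for_features(n_features)
    return [random_learner(n_qubits, rng) for _ in range(k)]


def soft_vote_fit(X: np.ndarray, y: np.ndarray, cfg: TrainingConfig,
                  rng: np.random.Generator | int | None = None) -> Ensemble:
    """Train cfg.ensemble_size learners, each on the full training data."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(cfg.seed if rng is None else rng) if not isinstance(
        rng, np.random.Generator
    ) else rng
    learners = []
    for lrn in _new_learners(X.shape[1], cfg.ensemble_size, rng):
        trained, _ = train_learner(lrn, X, y, cfg, rng=rng)
        learners.append(trained)
    return Ensemble(learners, "soft_vote")


def partition_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Disjoint covering partition into k near-equal subsets (sizes differ by
    at most 1; the remainder goes to the earliest subsets)."""
    if k > n:
        raise ValueError("cannot partition into more subsets than samples")
    order = rng.permutation(n)
    base, rem = divmod(n, k)
    sizes = [base + (1 if i < rem else 0) for i in range(k)]
    out, start = [], 0
    for s in sizes:
        out.append(np.sort(order[start : start + s]))
        start += s
    return out


def bagging_fit(X: np.ndarray, y: np.ndarray, k: int, cfg: TrainingConfig,
                rng: np.random.Generator | int | None = None) -> Ensemble:
    """k learners on a disjoint partition; inference by (uniform) weighted mean."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(cfg.seed if rng is None else rng) if not isinstance(
        rng, np.random.Generator
    ) else rng
    parts = partition_indices(X.shape[0], k, rng)
    learners = []
    for lrn, idx in zip(_new_learners(X.shape[1], k, rng), parts):
        trained, _ = train_learner(lrn, X[idx], y[idx], cfg, rng=rng)
        learners.append(trained)
    return Ensemble(learners, "bagging", learner_weights=np.ones(k), partition=parts)


def boosting_fit(X: np.ndarray, y: np.ndarray, k: int, cfg: TrainingConfig,
                 rng: np.random.Generator | int | None = None) -> Ensemble:
    """AdaBoost-style sequential training of k weak variational learners.

    Samples start equally weighted (1/N). Each round trains a learner on a
    subset of floor(N/k) samples drawn without replacement proportionally to
    the weights, measures its error on the full training set, assigns it the
    coefficient alpha = (1/2) ln((1-eps)/eps) (eps clipped away from {0, 1}),
    and multiplies misclassified-sample weights by exp(2 alpha) before
    renormalizing. Rounds with error >= 0.5 stop the ensemble early with a
    warning, keeping the rounds completed so far.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    if k < 1:
        raise ValueError("boosting needs at least one round")
    rng = np.random.default_rng(cfg.seed if rng is None else rng) if not isinstance(
        rng, np.random.Generator
    ) else rng
    n = X.shape[0]
    weights = np.full(n, 1.0 / n)
    subset_size = max(1, n // k)
    learners: list[VariationalLearner] = []
    alphas: list[float] = []
    partition: list[np.ndarray] = []
    for _round in range(k):
        idx = rng.choice(n, size=subset_size, replace=False, p=weights)
        lrn = random_learner(n_qubits_for_features(X.shape[1]), rng)
        trained, _ = train_learner(lrn, X[idx], y[idx], cfg, rng=rng)
        preds = np.array([1 if predict_proba(trained, xi) >= 0.5 else 0 for xi in X])
        miss = preds != y
        eps = float(np.clip(np.sum(weights[miss]), EPS_ERR, 1.0 - EPS_ERR))
        if eps >= 0.5:
            warnings.warn(
                f"boosting stopped after {len(learners)} completed rounds: "
                f"weak-learner error {eps:.3f} >= 0.5",
                stacklevel=2,
            )
            if not learners:  # keep one voiceless learner so predict() works
                learners.append(trained)
                alphas.append(0.0)
                partition.append(np.sort(idx))
            break
        alpha = 0.5 * np.log((1.0 - eps) / eps)
        learners.append(trained)
        alphas.append(alpha)
        partition.append(np.sort(idx))
        weights = weights * np.exp(2.0 * alpha * miss)
        weights /= weights.sum()
    if not learners:
        raise RuntimeError("boosting produced no usable learner")
    return Ensemble(learners, "boosting",
                    learner_weights=np.asarray(alphas), partition=partition)
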