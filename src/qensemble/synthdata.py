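"""Synthetic benchmarks and preprocessing.

Two generators: the 18-configuration two-dimensional Gaussian-blob grid
(two classes with mirrored centers (p1, p2) / (p2, p1)), and a synthetic
log-scale gene-expression cohort emulating a 150-patient immunotherapy
response study with a small planted panel of informative genes. Shared
preprocessing: stratified 80/20 train/test splits, train-fit min-max scaling
to [0, 1] (a requirement of amplitude encoding), and PCA reduction to f
components for the high-dimensional case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.datasets import make_blobs
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedShuffleSplit

#: blob-generation domain; features are affinely mapped from here onto [0,1]
BLOB_DOMAIN = (-0.85, 2.55)

CLUSTER_STDS = (0.3, 0.5)
CENTER_COORDS = (0.3, 0.5, 1.0)


@dataclass(frozen=True)
class BlobConfig:
    """One blob configuration: class-0 center (p1, p2), class-1 center (p2, p1)."""

    cluster_std: float
    p1: float
    p2: float
    n_samples: int = 100
    seed: int | None = None


@dataclass(frozen=True)
class LabeledDataset:
    """Sample x feature matrix in [0, 1] with binary labels."""

    X: np.ndarray
    y: np.ndarray
    name: str = ""
    feature_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        y = np.asarray(self.y, dtype=int)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        if X.shape[0] != y.size:
            raise ValueError("X and y disagree on the number of samples")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("labels must be binary")

    def to_frame(self) -> pd.DataFrame:
        cols = self.feature_names or tuple(f"f{i}" for i in range(self.X.shape[1]))
        df = pd.DataFrame(self.X, columns=list(cols))
        df["label"] = self.y
        return df


def make_blob_dataset(cfg: BlobConfig) -> LabeledDataset:
    """100 samples, 50/50 classes, mapped from the generation domain to [0,1]."""
    half = cfg.n_samples // 2
    X, y = make_blobs(
        n_samples=[cfg.n_samples - half, half],
        centers=[(cfg.p1, cfg.p2), (cfg.p2, cfg.p1)],
        cluster_std=cfg.cluster_std,
        random_state=cfg.seed,
    )
    lo, hi = BLOB_DOMAIN
    X = np.clip((X - lo) / (hi - lo), 0.0, 1.0)
    name = f"blobs_std{cfg.cluster_std}_p1{cfg.p1}_p2{cfg.p2}"
    return LabeledDataset(X, y, name=name, feature_names=("x", "y"))


def make_blob_grid(seed: int | None = None) -> list[LabeledDataset]:
    """All 18 configurations: cluster_std in {0.3, 0.5} x p1, p2 in {0.3, 0.5, 1.0}."""
    rng = np.random.default_rng(seed)
    datasets = []
    for std, p1, p2 in product(CLUSTER_STDS, CENTER_COORDS, CENTER_COORDS):
        cfg = BlobConfig(cluster_std=std, p1=p1, p2=p2,
                         seed=int(rng.integers(2**31 - 1)))
        datasets.append(make_blob_dataset(cfg))
    return datasets


def make_splits(dataset: LabeledDataset, n_splits: int = 10,
                train_frac: float = 0.8,
                seed: int | None = None) -> list[tuple[np.ndarray, np.ndarray]]:
    """n_splits stratified (train_idx, test_idx) pairs at the given fraction."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")
    n = dataset.X.shape[0]
    if n < 2 or min(train_frac, 1 - train_frac) * n < 1:
        raise ValueError("dataset too small to split")
    sss = StratifiedShuffleSplit(n_splits=n_splits, train_size=train_frac,
                                 random_state=seed)
    return [(np.sort(tr), np.sort(te)) for tr, te in sss.split(dataset.X, dataset.y)]


def minmax_scale(train_X: np.ndarray, other_X: np.ndarray | None = None
                 ) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-feature (x - min)/(max - min) with statistics fit on train only.

    Constant features map to 0; out-of-range values in ``other_X`` are
    clipped to [0, 1] so downstream amplitude encoding stays valid.
    """
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    lo = train_X.min(axis=0)
    hi = train_X.max(axis=0)
    span = hi - lo
    safe = np.where(span == 0, 1.0, span)

    def transform(X: np.ndarray) -> np.ndarray:
        scaled = (X - lo) / safe
        scaled[:, span == 0] = 0.0
        return np.clip(scaled, 0.0, 1.0)

    other = None
    if other_X is not None:
        other = transform(np.atleast_2d(np.asarray(other_X, dtype=float)))
    return transform(train_X), other


def pca_reduce(train_X: np.ndarray, other_X: np.ndarray | None, f: int,
               seed: int | None = None
               ) -> tuple[np.ndarray, np.ndarray | None, PCA]:
    """Top-f principal components fit on train, re-scaled onto [0, 1]."""
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    if f > min(train_X.shape):
        raise ValueError(
            f"cannot extract {f} components from a {train_X.shape} matrix"
        )
    pca = PCA(n_components=f, random_state=seed)
    train_p = pca.fit_transform(train_X)
    other_p = pca.transform(np.atleast_2d(other_X)) if other_X is not None else None
    train_s, other_s = minmax_scale(train_p, other_p)
    return train_s, other_s, pca


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Synthetic log-expression cohort emulating a small response study.

    Expression is drawn directly on a variance-stabilized log scale: gene g
    has baseline mu_g ~ N(6, 2) and dispersion sigma_g ~ U(0.5, 1.5); the
    n_informative response genes receive a class-conditional mean shift of
    effect_size * sigma_g. responder_fraction sets the class balance.
    """

    n_samples: int = 150
    n_genes: int = 2000
    n_informative: int = 8
    effect_size: float = 1.0
    responder_fraction: float = 0.35
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_informative > self.n_genes:
            raise ValueError("more informative genes than genes")
        if not 0.0 < self.responder_fraction < 1.0:
            raise ValueError("responder_fraction must lie in (0, 1)")


def simulate_expression(cfg: ExpressionSimConfig
                        ) -> tuple[LabeledDataset, list[str]]:
    """Simulate the cohort; returns the dataset and the planted gene names."""
    rng = np.random.default_rng(cfg.seed)
    n, g = cfg.n_samples, cfg.n_genes
    n_resp = max(1, round(cfg.responder_fraction * n))
    y = np.zeros(n, dtype=int)
    y[rng.choice(n, size=n_resp, replace=False)] = 1

    mu = rng.normal(6.0, 2.0, size=g)
    sigma = rng.uniform(0.5, 1.5, size=g)
    X = rng.normal(mu, sigma, size=(n, g))
    informative = rng.choice(g, size=cfg.n_informative, replace=False)
    shift = cfg.effect_size * sigma[informative]
    X[np.ix_(y == 1, informative)] += shift
    if cfg.noise_sd > 0:
        X += rng.normal(0.0, cfg.noise_sd, size=X.shape)

    names = tuple(f"gene{i}" for i in range(g))
    dataset = LabeledDataset(minmax_scale(X)[0], y, name="synthetic_expression",
                             feature_names=names)
    return dataset, [names[i] for i in sorted(informative)]


def write_tsv(dataset: LabeledDataset, path) -> None:
    dataset.to_frame().to_csv(path, sep="\t", index=False)


def read_tsv(path, name: str = "") -> LabeledDataset:
    df = pd.read_csv(path, sep="\t")
    if "label" not in df.columns:
        raise ValueError("TSV must have a 'label' column")
    y = df.pop("label").to_numpy()
    df = df.drop(columns=[c for c in ("split", "role") if c in df.columns])
    return LabeledDataset(df.to_numpy(dtype=float), y, name=name,
                          feature_names=tuple(df.columns))
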