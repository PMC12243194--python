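"""Z-score scaling and 3-component PCA shared by all trait models.

Feature subsets per trait are frozen:

* chaffiness uses all eight descriptors,
* chalky-kernel classification uses (f2, f3, f4, f6),
* head-rice-recovery classification uses (f1, f3, f4, f5, f7).

Population statistics (divide by n) are used throughout for consistency
with the population standard deviation of feature f4.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .features import FEATURE_NAMES

__all__ = [
    "Scaler",
    "PCAModel",
    "FEATURE_SUBSETS",
    "fit_scaler",
    "fit_pca",
    "project",
    "subset_columns",
    "save_embedding",
    "load_embedding",
]

FEATURE_SUBSETS: dict[str, tuple[str, ...]] = {
    "chaffiness": FEATURE_NAMES,
    "crk": ("f2", "f3", "f4", "f6"),
    "hrr": ("f1", "f3", "f4", "f5", "f7"),
}

N_COMPONENTS = 3


def subset_columns(table: np.ndarray, subset: str) -> np.ndarray:
    """Select the trait-specific feature columns from a full f1..f8 table."""
    names = FEATURE_SUBSETS[subset]
    idx = [FEATURE_NAMES.index(n) for n in names]
    return np.asarray(table, dtype=np.float64)[:, idx]


@dataclass(frozen=True)
class Scaler:
    feature_names: tuple[str, ...]
    mu: np.ndarray
    sigma: np.ndarray

    def transform(self, table: np.ndarray) -> np.ndarray:
        table = np.asarray(table, dtype=np.float64)
        if table.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} feature columns, got {table.shape[1]}"
            )
        return (table - self.mu) / self.sigma


@dataclass(frozen=True)
class PCAModel:
    feature_names: tuple[str, ...]
    component_matrix: np.ndarray       # (n_components, n_features), orthonormal rows
    center: np.ndarray                 # mean in scaled space
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.component_matrix.shape[0]


def fit_scaler(table: np.ndarray, feature_names: Sequence[str]) -> Scaler:
    """Column-wise z-transform ``f' = (f - mu) / sigma`` (population SD).

    Zero-variance columns get sigma = 1 so they scale to zeros instead of
    raising a division error.
    """
    table = np.asarray(table, dtype=np.float64)
    if table.shape[0] < 2:
        raise ValueError("fit_scaler needs at least 2 rows")
    mu = table.mean(axis=0)
    sigma = table.std(axis=0)
    sigma = np.where(sigma > 0, sigma, 1.0)
    return Scaler(tuple(feature_names), mu, sigma)


def fit_pca(scaled_table: np.ndarray, n_components: int = N_COMPONENTS,
            feature_names: Sequence[str] | None = None) -> PCAModel:
    """Top eigenvectors of the population covariance of the scaled table.

    Sign convention: the largest-magnitude loading of each component is
    positive, so refits and reloads project identically.
    """
    X = np.asarray(scaled_table, dtype=np.float64)
    n, p = X.shape
    if n < n_components + 1:
        raise ValueError(f"need at least {n_components + 1} rows to fit {n_components} components")
    center = X.mean(axis=0)
    cov = np.cov(X - center, rowvar=False, bias=True).reshape(p, p)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.maximum(eigvals[order], 0.0)
    components = eigvecs[:, order].T

    k = min(n_components, p)
    rank = int(np.sum(eigvals > 1e-12 * max(eigvals.max(), 1.0)))
    if rank < n_components <= p:
        warnings.warn(
            f"covariance rank {rank} below requested {n_components} components; "
            "trailing variance ratios are ~0",
            stacklevel=2,
        )
    total = eigvals.sum()
    ratio = eigvals[:k] / total if total > 0 else np.zeros(k)
    if k < n_components:          # pad when fewer features than components
        pad = n_components - k
        components = np.vstack([components[:k], np.zeros((pad, p))])
        ratio = np.concatenate([ratio, np.zeros(pad)])
    else:
        components = components[:n_components]

    for i in range(components.shape[0]):
        j = np.argmax(np.abs(components[i]))
        if components[i, j] < 0:
            components[i] = -components[i]

    names = tuple(feature_names) if feature_names is not None else tuple(
        f"x{i}" for i in range(p)
    )
    return PCAModel(names, components, center, ratio)


def project(scaler: Scaler, pca: PCAModel, feature_table: np.ndarray) -> np.ndarray:
    """Map raw feature rows to PC coordinates (n x n_components)."""
    if scaler.feature_names != pca.feature_names:
        raise ValueError("scaler and PCA were fitted on different feature sets")
    scaled = scaler.transform(feature_table)
    return (scaled - pca.center) @ pca.component_matrix.T


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_embedding(path, scaler: Scaler, pca: PCAModel) -> None:
    payload = {
        "feature_names": list(scaler.feature_names),
        "mu": scaler.mu.tolist(),
        "sigma": scaler.sigma.tolist(),
        "component_matrix": pca.component_matrix.tolist(),
        "center": pca.center.tolist(),
        "explained_variance_ratio": pca.explained_variance_ratio.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_embedding(path) -> tuple[Scaler, PCAModel]:
    payload = json.loads(Path(path).read_text())
    names = tuple(payload["feature_names"])
    scaler = Scaler(names, np.array(payload["mu"]), np.array(payload["sigma"]))
    pca = PCAModel(
        names,
        np.array(payload["component_matrix"]),
        np.array(payload["center"]),
        np.array(payload["explained_variance_ratio"]),
    )
    return scaler, pca
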