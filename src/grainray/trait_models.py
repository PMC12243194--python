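"""Per-grain trait classifiers operating in PC space.

Three traits are predicted from the 3-component embedding of the blob
features:

* chaffiness — Mahalanobis distance from the non-chaffy cluster, flagged
  beyond a fixed threshold (default 17, strict ``>``);
* chalky kernel status — linear SVM hyperplane trained on de-husked
  kernels, applied to whole grains after a "virtual de-husking" shift of
  the (f2, f3, f4, f6) features;
* head-rice-recovery class — one-vs-rest logistic decision functions over
  the five classes {100, 80, 60, 40, 20} %, max-probability rule.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .phantom import HRR_CLASS_VALUES

__all__ = [
    "ChaffyClusterModel",
    "HyperplaneModel",
    "HRRModel",
    "SampleTraitReport",
    "DEFAULT_THETA_CHAFFY",
    "mahalanobis_distance",
    "fit_chaffy_cluster",
    "classify_chaffy",
    "virtual_dehusk",
    "fit_chalky_hyperplane",
    "classify_chalky",
    "fit_hrr_model",
    "predict_hrr_probabilities",
    "predict_grain_hrr",
    "aggregate_sample_hrr",
    "hrr_ground_truth",
    "evaluate",
]

#: Mahalanobis threshold separating chaffy from non-chaffy in PC space.
DEFAULT_THETA_CHAFFY = 17.0


# ---------------------------------------------------------------------------
# T1: chaffiness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChaffyClusterModel:
    """Gaussian cluster of non-chaffy grains in PC space."""

    mean_pc: np.ndarray
    covariance_pc: np.ndarray
    theta_chaffy: float = DEFAULT_THETA_CHAFFY
    _inv_cov: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.theta_chaffy <= 0:
            raise ValueError("theta_chaffy must be > 0")
        cov = np.asarray(self.covariance_pc, dtype=np.float64)
        try:
            inv = np.linalg.inv(cov)
        except np.linalg.LinAlgError as err:
            raise ValueError("covariance matrix is singular") from err
        object.__setattr__(self, "_inv_cov", inv)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.covariance_pc))


def mahalanobis_distance(x: np.ndarray, model: ChaffyClusterModel) -> float:
    """sqrt((x - mean)^T Sigma^-1 (x - mean))."""
    d = np.asarray(x, dtype=np.float64) - model.mean_pc
    return float(np.sqrt(d @ model._inv_cov @ d))


def fit_chaffy_cluster(
    coords_non_chaffy: np.ndarray,
    theta: float = DEFAULT_THETA_CHAFFY,
    ridge: float = 1e-8,
) -> ChaffyClusterModel:
    """Sample mean and covariance of the non-chaffy training cloud.

    A small ridge is added when the sample covariance is singular
    (e.g. fewer points than dimensions); a warning is issued.
    """
    X = np.asarray(coords_non_chaffy, dtype=np.float64)
    if X.shape[0] < 4:
        raise ValueError("need at least 4 non-chaffy grains to fit the cluster")
    mean = X.mean(axis=0)
    cov = np.cov(X, rowvar=False)
    if np.linalg.matrix_rank(cov) < cov.shape[0]:
        warnings.warn("singular training covariance; adding ridge", stacklevel=2)
        cov = cov + ridge * np.eye(cov.shape[0])
    return ChaffyClusterModel(mean_pc=mean, covariance_pc=cov, theta_chaffy=theta)


def classify_chaffy(
    coords: np.ndarray, model: ChaffyClusterModel
) -> tuple[np.ndarray, np.ndarray]:
    """Flag grains with distance strictly above theta; returns (flags, distances)."""
    coords = np.atleast_2d(np.asarray(coords, dtype=np.float64))
    distances = np.array([mahalanobis_distance(x, model) for x in coords])
    return distances > model.theta_chaffy, distances


# ---------------------------------------------------------------------------
# T2: chalky rice kernel percentage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HyperplaneModel:
    """Linear SVM separator in PC space plus the de-husking feature shift."""

    normal_pc: np.ndarray
    offset: float
    dehusk_shift: np.ndarray        # over (f2, f3, f4, f6): mu_grain - mu_kernel
    C: float = 1.0

    def __post_init__(self) -> None:
        if np.linalg.norm(self.normal_pc) == 0:
            raise ValueError("hyperplane normal must be nonzero")

    def decision_values(self, coords: np.ndarray) -> np.ndarray:
        coords = np.atleast_2d(np.asarray(coords, dtype=np.float64))
        return coords @ self.normal_pc + self.offset


def virtual_dehusk(
    features: np.ndarray, mu_source: np.ndarray, mu_target: np.ndarray
) -> np.ndarray:
    """Translate features by the population offset: ``x - (mu_source - mu_target)``.

    Applied with ``mu_source`` the mean of the husked-grain population and
    ``mu_target`` the de-husked kernel ground-truth mean, the shifted
    population mean equals ``mu_target`` exactly, so a classifier trained
    on kernels applies to whole grains.  Equal means give the identity map.
    """
    features = np.asarray(features, dtype=np.float64)
    return features - (np.asarray(mu_source, dtype=np.float64)
                       - np.asarray(mu_target, dtype=np.float64))


def fit_chalky_hyperplane(
    kernel_coords: np.ndarray,
    chalky_labels: Sequence[bool],
    dehusk_shift: Optional[np.ndarray] = None,
    C: float = 1.0,
) -> HyperplaneModel:
    """Maximum-margin linear separator of chalky vs non-chalky kernels.

    Soft margin with fixed regularization ``C``; positive decision values
    mean chalky.
    """
    X = np.asarray(kernel_coords, dtype=np.float64)
    y = np.asarray(chalky_labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both chalky and non-chalky kernels are required for training")
    svm = SVC(kernel="linear", C=C)
    svm.fit(X, y)
    shift = (np.zeros(X.shape[1]) if dehusk_shift is None
             else np.asarray(dehusk_shift, dtype=np.float64))
    return HyperplaneModel(
        normal_pc=svm.coef_.ravel().copy(),
        offset=float(svm.intercept_[0]),
        dehusk_shift=shift,
        C=C,
    )


def classify_chalky(
    grain_features: np.ndarray,
    model: HyperplaneModel,
    scaler,
    pca,
    dehusk: bool = True,
) -> tuple[np.ndarray, float]:
    """Per-grain chalky flags and the sample CRK% (100 * chalky / total).

    ``grain_features`` are raw (f2, f3, f4, f6) rows of whole grains; when
    ``dehusk`` is set the stored shift is removed before scaling and PCA
    projection.  The decision boundary itself (value exactly 0) counts as
    non-chalky.
    """
    from .embedding import project

    X = np.atleast_2d(np.asarray(grain_features, dtype=np.float64))
    if dehusk:
        X = X - model.dehusk_shift
    coords = project(scaler, pca, X)
    flags = model.decision_values(coords) > 0
    crk_percent = 100.0 * flags.sum() / len(flags) if len(flags) else 0.0
    return flags, float(crk_percent)


# ---------------------------------------------------------------------------
# T3: head rice recovery percentage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HRRModel:
    """One-vs-rest linear decision functions with logistic calibration."""

    class_values: tuple[int, ...]           # subset of HRR_CLASS_VALUES present
    coefficients: np.ndarray                # (n_classes, n_dims)
    intercepts: np.ndarray                  # (n_classes,)


def fit_hrr_model(
    grain_coords: np.ndarray,
    subset_labels: Sequence[int],
    C: float = 1.0,
) -> HRRModel:
    """Fit one calibrated linear decision function per HRR class present."""
    X = np.asarray(grain_coords, dtype=np.float64)
    y = np.asarray(subset_labels, dtype=int)
    present = [c for c in HRR_CLASS_VALUES if c in set(y.tolist())]
    if len(present) < 2:
        raise ValueError("need at least 2 HRR classes to train")
    coefs, icepts = [], []
    for cls in present:
        clf = LogisticRegression(C=C, max_iter=2000)
        clf.fit(X, (y == cls).astype(int))
        coefs.append(clf.coef_.ravel().copy())
        icepts.append(float(clf.intercept_[0]))
    return HRRModel(tuple(present), np.vstack(coefs), np.array(icepts))


def predict_hrr_probabilities(coords: np.ndarray, model: HRRModel) -> np.ndarray:
    """Per-grain probabilities over the five classes (absent classes get 0).

    Columns follow ``HRR_CLASS_VALUES`` order (100, 80, 60, 40, 20).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=np.float64))
    raw = coords @ model.coefficients.T + model.intercepts
    probs_present = 1.0 / (1.0 + np.exp(-raw))
    probs = np.zeros((coords.shape[0], len(HRR_CLASS_VALUES)))
    for j, cls in enumerate(HRR_CLASS_VALUES):
        if cls in model.class_values:
            probs[:, j] = probs_present[:, model.class_values.index(cls)]
    return probs


def predict_grain_hrr(probabilities: Sequence[float]) -> tuple[int, float]:
    """Max-probability rule over the five class probabilities.

    ``probabilities`` align with classes (100, 80, 60, 40, 20) % and lie in
    [0, 1]; they need not sum to one (independent per-class memberships).
    Returns (class value, reliability in %); ties resolve to the lowest
    class value, a conservative recovery estimate.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    if p.shape != (len(HRR_CLASS_VALUES),):
        raise ValueError(f"expected {len(HRR_CLASS_VALUES)} probabilities")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must be in [0, 1]")
    best = p.max()
    cls = min(c for c, q in zip(HRR_CLASS_VALUES, p) if q == best)
    return cls, float(100.0 * best)


def aggregate_sample_hrr(per_grain_classes: Sequence[int]) -> float:
    """Sample-level HRR% as the mean of per-grain class values."""
    classes = np.asarray(per_grain_classes, dtype=np.float64)
    if classes.size == 0:
        raise ValueError("cannot aggregate an empty sample")
    return float(classes.mean())


def hrr_ground_truth(w_pg: float, w_op: float) -> float:
    """Reference HRR% from milling weights: ``100 * W_pg / W_op``.

    ``w_pg`` is the weight of polished grains retaining more than 75 % of
    the grain length, ``w_op`` the original paddy weight.
    """
    if w_op <= 0:
        raise ValueError("original paddy weight must be > 0")
    if not 0 <= w_pg <= w_op:
        raise ValueError("polished weight must lie in [0, W_op]")
    return 100.0 * w_pg / w_op


# ---------------------------------------------------------------------------
# evaluation and reporting
# ---------------------------------------------------------------------------

def evaluate(
    predicted: Sequence[float], observed: Sequence[float]
) -> tuple[float, float, float, float]:
    """(R^2, RMSE, slope, intercept) of predicted regressed on observed.

    RMSE is the root mean squared prediction error (predicted vs observed,
    not regression residuals).
    """
    pred = np.asarray(predicted, dtype=np.float64)
    obs = np.asarray(observed, dtype=np.float64)
    if pred.shape != obs.shape or pred.ndim != 1 or pred.size < 2:
        raise ValueError("predicted and observed must be equal-length vectors (n >= 2)")
    if np.ptp(obs) == 0:
        raise ValueError("observed values are constant; R^2 undefined")
    fit = stats.linregress(obs, pred)
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    return float(fit.rvalue**2), rmse, float(fit.slope), float(fit.intercept)


@dataclass(frozen=True)
class SampleTraitReport:
    n_grains: int
    chaffy_count: int
    crk_percent: float
    hrr_percent_predicted: float
    per_grain: list[dict]           # label, chaffy, chalky, hrr_class, hrr_reliability

    def __post_init__(self) -> None:
        if not 0 <= self.crk_percent <= 100:
            raise ValueError("crk_percent must be in [0, 100]")
        if self.chaffy_count > self.n_grains:
            raise ValueError("chaffy_count cannot exceed n_grains")

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_grains": self.n_grains,
                "chaffy_count": self.chaffy_count,
                "crk_percent": self.crk_percent,
                "hrr_percent_predicted": self.hrr_percent_predicted,
                "per_grain": self.per_grain,
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# model (de)serialization
# ---------------------------------------------------------------------------

def save_models(
    path,
    chaffy: Optional[ChaffyClusterModel] = None,
    chalky: Optional[HyperplaneModel] = None,
    hrr: Optional[HRRModel] = None,
) -> None:
    payload: dict = {}
    if chaffy is not None:
        payload["chaffy"] = {
            "mean_pc": chaffy.mean_pc.tolist(),
            "covariance_pc": np.asarray(chaffy.covariance_pc).tolist(),
            "theta_chaffy": chaffy.theta_chaffy,
        }
    if chalky is not None:
        payload["chalky"] = {
            "normal_pc": chalky.normal_pc.tolist(),
            "offset": chalky.offset,
            "dehusk_shift": chalky.dehusk_shift.tolist(),
            "C": chalky.C,
        }
    if hrr is not None:
        payload["hrr"] = {
            "class_values": list(hrr.class_values),
            "coefficients": hrr.coefficients.tolist(),
            "intercepts": hrr.intercepts.tolist(),
        }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_models(path) -> dict:
    payload = json.loads(Path(path).read_text())
    models: dict = {}
    if "chaffy" in payload:
        d = payload["chaffy"]
        models["chaffy"] = ChaffyClusterModel(
            np.array(d["mean_pc"]), np.array(d["covariance_pc"]), d["theta_chaffy"]
        )
    if "chalky" in payload:
        d = payload["chalky"]
        models["chalky"] = HyperplaneModel(
            np.array(d["normal_pc"]), d["offset"], np.array(d["dehusk_shift"]), d["C"]
        )
    if "hrr" in payload:
        d = payload["hrr"]
        models["hrr"] = HRRModel(
            tuple(d["class_values"]),
            np.array(d["coefficients"]),
            np.array(d["intercepts"]),
        )
    return models
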