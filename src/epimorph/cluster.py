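"""Gaussian-mixture clustering of jsPC1 scores, AIC model selection, cluster
transfer, signatures, and the AP-symmetrized two-cluster variant.

Clustering is one-dimensional: the pooled jsPC1 scores of the training cohort
are fit with a k-component Gaussian mixture (EM, multiple seeded restarts);
k is selected by minimizing AIC = 2(3k−1) − 2 log L.  Components are labeled
1..k by ascending mean, so cluster identity is stable across runs.  Cells
from other conditions are assigned by maximum posterior under the *frozen*
training mixture (no refitting) after per-sample standardization and
projection on the training jsPC1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .angles import axial_mean, axial_std, symmetrize_axial
from .errors import ParameterError, StatisticsError

__all__ = [
    "ClusterModel",
    "fit_gmm",
    "select_k",
    "assign",
    "cluster_signatures",
    "symmetrize",
    "SYMMETRIZED_FEATURES",
]

#: angle columns replaced by their AP-symmetrized versions
SYMMETRIZED_FEATURES = ("orientation", "stress_direction")


@dataclass
class ClusterModel:
    """1-D Gaussian mixture with components ordered by ascending mean."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihood: float
    aic: float
    training_id: str = "training"

    @property
    def k(self) -> int:
        return len(self.weights)

    def log_responsibilities(self, scores: np.ndarray) -> np.ndarray:
        x = np.asarray(scores, dtype=float)[:, None]
        log_pdf = (
            -0.5 * np.log(2.0 * np.pi * self.variances)
            - (x - self.means) ** 2 / (2.0 * self.variances)
        )
        return np.log(self.weights) + log_pdf

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "training_id": self.training_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterModel":
        return cls(
            weights=np.asarray(d["weights"], float),
            means=np.asarray(d["means"], float),
            variances=np.asarray(d["variances"], float),
            log_likelihood=float(d["log_likelihood"]),
            aic=float(d["aic"]),
            training_id=d.get("training_id", "training"),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "ClusterModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_gmm(
    scores: np.ndarray,
    k: int,
    restarts: int = 20,
    seed: int = 0,
    variance_floor: float = 1e-6,
    training_id: str = "training",
) -> ClusterModel:
    """EM fit of a k-component 1-D Gaussian mixture (best of ``restarts``).

    Free per-component variances with a floor of ``variance_floor`` (applied
    with a warning if any component collapses onto it).
    """
    x = np.asarray(scores, dtype=float).reshape(-1, 1)
    if len(x) < 10 * k:
        raise ParameterError(f"need at least {10 * k} points to fit k={k}")
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        n_init=restarts,
        reg_covar=variance_floor,
        random_state=np.random.default_rng(seed).integers(0, 2**31 - 1),
        max_iter=500,
    ).fit(x)
    weights = gm.weights_.copy()
    means = gm.means_.ravel().copy()
    variances = gm.covariances_.reshape(-1).copy()
    if np.any(variances <= variance_floor * (1 + 1e-9)):
        warnings.warn("GMM component variance hit the floor", RuntimeWarning)
        variances = np.maximum(variances, variance_floor)
    order = np.argsort(means, kind="stable")
    loglik = float(gm.score(x) * len(x))
    aic = 2.0 * (3 * k - 1) - 2.0 * loglik
    return ClusterModel(
        weights=weights[order],
        means=means[order],
        variances=variances[order],
        log_likelihood=loglik,
        aic=aic,
        training_id=training_id,
    )


def select_k(
    scores: np.ndarray,
    k_range=range(1, 7),
    restarts: int = 20,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """k* = argmin AIC over k_range (ties -> smaller k); returns the AIC table."""
    k_range = list(k_range)
    if not k_range:
        raise ParameterError("k_range must be non-empty")
    rows = []
    best_k, best_aic = None, np.inf
    for k in k_range:
        model = fit_gmm(scores, k, restarts=restarts, seed=seed)
        rows.append({"k": k, "aic": model.aic, "log_likelihood": model.log_likelihood})
        if model.aic < best_aic:
            best_k, best_aic = k, model.aic
    return best_k, pd.DataFrame(rows)


def assign(model: ClusterModel, scores: np.ndarray):
    """Maximum-posterior cluster labels (1..k) and posterior probabilities.

    Equidistant ties go to the lower-index (lower-mean) component.  The model
    is applied frozen; nothing is refit.
    """
    x = np.asarray(scores, dtype=float)
    if x.size == 0:
        return np.array([], dtype=int), np.empty((0, model.k))
    logr = model.log_responsibilities(x)
    logr -= logr.max(axis=1, keepdims=True)
    post = np.exp(logr)
    post /= post.sum(axis=1, keepdims=True)
    labels = np.argmax(post, axis=1) + 1  # argmax picks lowest index on ties
    return labels, post


def cluster_signatures(
    features: pd.DataFrame,
    labels: np.ndarray,
    feature_set: list[str] = None,
    angle_columns=SYMMETRIZED_FEATURES,
) -> pd.DataFrame:
    """Per-cluster mean ± SD of each feature on the raw (unstandardized) scale.

    For axial-angle columns the axial (mod-180°) circular mean and SD are
    reported alongside the plain ones, since plain averages are meaningless
    across the ±90° wrap.  Empty clusters yield NaN rows (flagged).
    """
    labels = np.asarray(labels)
    if len(labels) != len(features):
        raise StatisticsError("labels not aligned with feature table")
    if feature_set is None:
        feature_set = [
            c
            for c in features.columns
            if c not in ("sample_id", "cell_id", "boundary", "region_label")
            and pd.api.types.is_numeric_dtype(features[c])
        ]
    rows = []
    for lab in sorted(set(labels.tolist())):
        sel = features.loc[labels == lab]
        row = {"cluster": lab, "n_cells": len(sel), "empty": len(sel) == 0}
        for col in feature_set:
            v = sel[col].to_numpy(dtype=float)
            row[f"{col}_mean"] = v.mean() if v.size else np.nan
            row[f"{col}_sd"] = v.std() if v.size else np.nan
            if col in angle_columns:
                row[f"{col}_axial_mean"] = axial_mean(v) if v.size else np.nan
                row[f"{col}_axial_sd"] = axial_std(v) if v.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def symmetrize(features: pd.DataFrame) -> pd.DataFrame:
    """AP-symmetrize: orientation ← axial distance to the AP axis, stress
    direction ← axial distance to the LR axis (|ϑ₁|); both in [0, 90].

    Left/right mirror-image patterns become identical: θ = 45° and θ = −45°
    both map to 45; θ = −80° (axially 10° from the AP axis) maps to 10.
    """
    out = features.copy()
    if "orientation" in out.columns:
        out["orientation"] = symmetrize_axial(out["orientation"].to_numpy(), 90.0)
    if "stress_direction" in out.columns:
        out["stress_direction"] = symmetrize_axial(
            out["stress_direction"].to_numpy(), 0.0
        )
    return out


def two_cluster_pipeline(
    features: pd.DataFrame,
    graphs: dict,
    seed: int = 0,
    feature_set: list[str] = None,
    restarts: int = 20,
):
    """AP-symmetrized two-cluster classification (anterior vs posterior).

    Runs the full jsPCA → GMM(k=2) pipeline on features whose orientation and
    stress-direction columns have been AP-symmetrized, so mirror-image
    left/right populations fall into one anterior cluster.  ``graphs`` maps
    sample_id -> :class:`~epimorph.spatial.AdjacencyGraph`.

    Returns (labels aligned with ``features`` rows, jspca model, gmm model).
    """
    from .jspca import fit_jspca, project
    from .spatial import DEFAULT_FEATURES, prepare_analysis_table, standardize

    feature_set = list(feature_set or DEFAULT_FEATURES)
    sym = symmetrize(features)
    # "lr" keeps the symmetrized values as-is; this also imputes any cells
    # with an undefined anisotropy ratio at their sample median
    table = prepare_analysis_table(sym, feature_set, angle_reference="lr")
    samples = standardize(table, feature_set)
    graph_list = [graphs[s.sample_id] for s in samples]
    model = fit_jspca(samples, graph_list)
    scores = {s.sample_id: project(s, model, 0) for s in samples}
    pooled = np.concatenate([scores[s.sample_id] for s in samples])
    gmm = fit_gmm(pooled, k=2, restarts=restarts, seed=seed)
    labels = np.empty(len(features), dtype=int)
    for s in samples:
        lab, _ = assign(gmm, scores[s.sample_id])
        labels[(features["sample_id"] == s.sample_id).to_numpy()] = lab
    return labels, model, gmm
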