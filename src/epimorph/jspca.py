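"""Joint spatial PCA: approximate joint diagonalization of per-sample
covariance×Moran product matrices, component ranking, and projection.

Because the product matrix depends on each sample's own adjacency matrix, the
per-sample matrices M_k cannot be pooled directly; instead an orthogonal V is
sought that approximately diagonalizes all of them at once (Jacobi 2×2
rotations, sweeping index pairs in a fixed lexicographic order).  Components
are ranked by the mean of diag(VᵀM_kV) across samples; the top-ranked
component is jsPC1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError
from .spatial import AdjacencyGraph, SampleMatrix, product_matrix

__all__ = [
    "JsPCAModel",
    "off_criterion",
    "joint_diagonalize",
    "rank_components",
    "fit_jspca",
    "project",
]


def off_criterion(matrices, V) -> float:
    """Σ_k of squared off-diagonal entries of VᵀM_kV."""
    total = 0.0
    for M in matrices:
        D = V.T @ M @ V
        total += float(np.sum(D**2) - np.sum(np.diag(D) ** 2))
    return total


def joint_diagonalize(
    matrices,
    tol: float = 1e-12,
    max_sweeps: int = 100,
) -> np.ndarray:
    """Orthogonal V minimizing the joint off-diagonal criterion.

    Jacobi rotations over lexicographically ordered index pairs; each 2×2
    rotation is the closed-form optimum for its pair, so the criterion is
    non-increasing across sweeps.  For a single matrix this reduces to its
    eigendecomposition; for exactly commuting families the criterion reaches
    numerical zero.  Deterministic given the input order.
    """
    mats = [np.asarray(M, dtype=float) for M in matrices]
    if not mats:
        raise SchemaError("need at least one matrix")
    p = mats[0].shape[0]
    for M in mats:
        if M.shape != (p, p):
            raise SchemaError("matrices must share a common square shape")
        if not np.allclose(M, M.T, atol=1e-10 * max(1.0, np.abs(M).max())):
            raise SchemaError("matrices must be symmetric")
    mats = [(M + M.T) / 2.0 for M in mats]

    V = np.eye(p)
    prev = off_criterion(mats, np.eye(p))
    for _ in range(max_sweeps):
        for i in range(p - 1):
            for j in range(i + 1, p):
                # closed-form best rotation for pair (i, j)
                alpha = np.array([M[i, i] - M[j, j] for M in mats])
                beta = np.array([2.0 * M[i, j] for M in mats])
                if float(alpha @ alpha + beta @ beta) < 1e-300:
                    continue  # pair already diagonal for all matrices
                G = np.array(
                    [
                        [alpha @ alpha, alpha @ beta],
                        [alpha @ beta, beta @ beta],
                    ]
                )
                evals, evecs = np.linalg.eigh(G)
                x, y = evecs[:, 1]
                if x < 0:
                    x, y = -x, -y
                c = np.sqrt((1.0 + x) / 2.0)
                s = y / (2.0 * c) if c > 0 else 0.0
                if abs(s) < 1e-16:
                    continue
                R = np.array([[c, -s], [s, c]])
                for M in mats:
                    M[[i, j], :] = R.T @ M[[i, j], :]
                    M[:, [i, j]] = M[:, [i, j]] @ R
                V[:, [i, j]] = V[:, [i, j]] @ R
        cur = sum(
            float(np.sum(M**2) - np.sum(np.diag(M) ** 2)) for M in mats
        )
        if prev - cur < tol:
            break
        prev = cur
    return V


def rank_components(V: np.ndarray, matrices, aggregate: str = "mean"):
    """Order components by decreasing aggregated eigenvalue across samples.

    Returns (ordering, eigenvalue_table) where eigenvalue_table[k, c] =
    (VᵀM_kV)_{cc}.  Ties are broken by component index (stable sort).
    """
    table = np.array([np.diag(V.T @ np.asarray(M, float) @ V) for M in matrices])
    agg = {"mean": np.mean, "median": np.median, "min": np.min}[aggregate]
    scores = agg(table, axis=0)
    order = np.argsort(-scores, kind="stable")
    return order, table


@dataclass
class JsPCAModel:
    """Persisted joint spatial PCA model.

    V holds the joint eigenvectors in raw (unranked) column order; ``ranking``
    maps rank r -> column of V; ``signs`` orients each ranked component so its
    loading on the orientation feature is ≥ 0 (fallback: first nonzero loading
    positive).  Per-sample scaling parameters of the training cohort are kept
    for transfer bookkeeping.
    """

    V: np.ndarray
    ranking: np.ndarray
    signs: np.ndarray
    eigenvalue_table: np.ndarray  # samples × components (raw column order)
    feature_names: list[str]
    sample_ids: list[str]
    scaling: dict  # sample_id -> {"means": [...], "sds": [...]}
    aggregate: str = "mean"

    def component(self, rank: int = 0) -> np.ndarray:
        """Loadings of the rank-th component (jsPC1 is rank 0), sign-fixed."""
        return self.signs[rank] * self.V[:, self.ranking[rank]]

    def loadings(self) -> pd.DataFrame:
        cols = {
            f"jsPC{r + 1}": self.component(r) for r in range(self.V.shape[1])
        }
        return pd.DataFrame(cols, index=self.feature_names)

    def eigenvalues(self) -> pd.DataFrame:
        ranked = self.eigenvalue_table[:, self.ranking]
        return pd.DataFrame(
            ranked,
            index=self.sample_ids,
            columns=[f"jsPC{r + 1}" for r in range(ranked.shape[1])],
        )

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "V": self.V.tolist(),
            "ranking": self.ranking.tolist(),
            "signs": self.signs.tolist(),
            "eigenvalue_table": self.eigenvalue_table.tolist(),
            "feature_names": list(self.feature_names),
            "sample_ids": list(self.sample_ids),
            "scaling": self.scaling,
            "aggregate": self.aggregate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "JsPCAModel":
        return cls(
            V=np.asarray(d["V"], float),
            ranking=np.asarray(d["ranking"], int),
            signs=np.asarray(d["signs"], float),
            eigenvalue_table=np.asarray(d["eigenvalue_table"], float),
            feature_names=list(d["feature_names"]),
            sample_ids=list(d["sample_ids"]),
            scaling=d["scaling"],
            aggregate=d.get("aggregate", "mean"),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "JsPCAModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _component_signs(V, ranking, feature_names):
    signs = np.ones(len(ranking))
    try:
        oidx = feature_names.index("orientation")
    except ValueError:
        oidx = None
    for r, c in enumerate(ranking):
        v = V[:, c]
        if oidx is not None and abs(v[oidx]) > 1e-12:
            signs[r] = 1.0 if v[oidx] >= 0 else -1.0
        else:
            nz = np.flatnonzero(np.abs(v) > 1e-12)
            if nz.size:
                signs[r] = 1.0 if v[nz[0]] > 0 else -1.0
    return signs


def fit_jspca(
    samples: list[SampleMatrix],
    graphs: list[AdjacencyGraph],
    tol: float = 1e-12,
    max_sweeps: int = 100,
    aggregate: str = "mean",
) -> JsPCAModel:
    """Fit the joint spatial PCA model on a cohort of standardized samples."""
    if len(samples) != len(graphs) or not samples:
        raise SchemaError("need one adjacency graph per sample")
    names = samples[0].feature_names
    for s in samples:
        if s.feature_names != names:
            raise SchemaError("samples disagree on the feature set")
    mats = [product_matrix(s, g) for s, g in zip(samples, graphs)]
    V = joint_diagonalize(mats, tol=tol, max_sweeps=max_sweeps)
    ranking, table = rank_components(V, mats, aggregate=aggregate)
    signs = _component_signs(V, ranking, names)
    scaling = {
        s.sample_id: {"means": s.means.tolist(), "sds": s.sds.tolist()}
        for s in samples
    }
    return JsPCAModel(
        V=V,
        ranking=np.asarray(ranking, int),
        signs=signs,
        eigenvalue_table=table,
        feature_names=list(names),
        sample_ids=[s.sample_id for s in samples],
        scaling=scaling,
        aggregate=aggregate,
    )


def project(sample: SampleMatrix, model: JsPCAModel, component: int = 0) -> np.ndarray:
    """Score vector of one (individually standardized) sample on a component."""
    if sample.feature_names != model.feature_names:
        raise SchemaError(
            "sample feature set does not match the model: "
            f"{sample.feature_names} vs {model.feature_names}"
        )
    return sample.X @ model.component(component)
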