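"""Cell adjacency, Moran's index, per-sample standardization and the
covariance × spatial-autocorrelation product matrix.

The product matrix M = Xᵀ(L + Lᵀ)X / (2n), with L the row-normalized cell
adjacency matrix and X the per-sample standardized feature matrix, plays the
role of the covariance matrix in classical PCA: eigenvectors with the largest
eigenvalues maximize variance *and* spatial autocorrelation jointly.  With
L = I it reduces exactly to the (population) covariance of X.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .angles import ap_reference
from .errors import SchemaError, StatisticsError
from .mesh import Tessellation

__all__ = [
    "AdjacencyGraph",
    "SampleMatrix",
    "DEFAULT_FEATURES",
    "ANGLE_FEATURES",
    "build_adjacency",
    "morans_index",
    "prepare_analysis_table",
    "standardize",
    "apply_standardization",
    "product_matrix",
    "classical_pca",
]

#: The default 8-feature analysis set (nucleus-to-Golgi polarity, analyzed
#: separately in 3-D in the source workflow, is excluded but configurable).
DEFAULT_FEATURES = [
    "orientation",
    "area",
    "perimeter",
    "eccentricity",
    "n_neighbors",
    "pressure",
    "stress_direction",
    "stress_anisotropy",
]

#: Axial-angle columns that are re-referenced to the AP axis before analysis.
ANGLE_FEATURES = ("orientation", "stress_direction")


@dataclass
class AdjacencyGraph:
    """Shared-edge neighbor relation of one sample.

    W is the symmetric binary (hollow) neighbor matrix, L its row-normalized
    form; rows of isolated cells are all-zero and flagged.
    """

    W: sp.csr_matrix
    L: sp.csr_matrix
    n: int
    isolated: np.ndarray

    def neighbor_edge_list(self) -> pd.DataFrame:
        coo = sp.triu(self.W, k=1).tocoo()
        return pd.DataFrame({"cell_i": coo.row, "cell_j": coo.col})


@dataclass
class SampleMatrix:
    """Standardized per-sample feature matrix with its scaling parameters."""

    sample_id: str
    X: np.ndarray  # (n, p), column mean 0, population SD 1
    feature_names: list[str]
    means: np.ndarray
    sds: np.ndarray


def build_adjacency(tess: Tessellation) -> AdjacencyGraph:
    """W_ij = 1 iff cells i and j share at least one mesh edge."""
    n = tess.n_cells
    rows, cols = [], []
    for inc in tess.edge_cells():
        if len(inc) == 2:
            i, j = inc
            rows += [i, j]
            cols += [j, i]
    W = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    W.data[:] = 1.0  # collapse multi-edge adjacency to binary
    W = sp.csr_matrix((W > 0).astype(float))
    deg = np.asarray(W.sum(axis=1)).ravel()
    isolated = deg == 0
    inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
    L = sp.diags(inv) @ W
    return AdjacencyGraph(W=W, L=sp.csr_matrix(L), n=n, isolated=isolated)


def morans_index(z: np.ndarray, graph: AdjacencyGraph) -> float:
    """Moran's index MI = zᵀLz / zᵀz for a centered per-cell scalar."""
    z = np.asarray(z, dtype=float)
    if z.shape != (graph.n,):
        raise SchemaError("z length does not match graph size")
    denom = float(z @ z)
    if denom <= 0:
        raise StatisticsError("Moran's index undefined for zero-variance z")
    if abs(z.mean()) > 1e-8 * max(1.0, float(np.abs(z).max())):
        raise StatisticsError("z must be centered")
    return float(z @ (graph.L @ z)) / denom


def prepare_analysis_table(
    features: pd.DataFrame,
    feature_set: list[str] = None,
    angle_reference: str = "ap",
) -> pd.DataFrame:
    """Select analysis columns, re-referencing axial angles to the AP axis.

    With ``angle_reference="ap"`` (default) the orientation and stress
    direction columns become wrap(θ − 90°): 0 means "along the AP axis", so
    AP-oriented cell populations stay unimodal instead of straddling the ±90°
    axial wrap of the left-right-referenced convention.  ``"lr"`` keeps the
    stored convention.
    """
    feature_set = list(feature_set or DEFAULT_FEATURES)
    missing = [c for c in feature_set if c not in features.columns]
    if missing:
        raise SchemaError(f"feature table missing columns: {missing}")
    out = features[["sample_id"] + feature_set].copy()
    if angle_reference == "ap":
        for col in ANGLE_FEATURES:
            if col in feature_set:
                out[col] = ap_reference(out[col].to_numpy())
    elif angle_reference != "lr":
        raise SchemaError(f"unknown angle_reference {angle_reference!r}")
    # cells with an undefined statistic (e.g. anisotropy ratio when the whole
    # stress tensor is compressive) are imputed at their sample median so the
    # analysis matrix stays complete
    for col in feature_set:
        v = out[col].to_numpy(float)
        if not np.all(np.isfinite(v)):
            med = out.groupby("sample_id")[col].transform("median")
            out[col] = np.where(np.isfinite(v), v, med.to_numpy(float))
    return out


def standardize(
    features: pd.DataFrame,
    feature_set: list[str] = None,
) -> list[SampleMatrix]:
    """Center and scale each feature column per sample (population SD).

    Raises :class:`StatisticsError` naming the column if a sample has a
    zero-variance feature.
    """
    feature_set = list(feature_set or DEFAULT_FEATURES)
    missing = [c for c in feature_set if c not in features.columns]
    if missing:
        raise SchemaError(f"feature table missing columns: {missing}")
    out = []
    for sid, grp in features.groupby("sample_id", sort=False):
        if len(grp) < 2:
            raise StatisticsError(f"sample {sid!r} has fewer than 2 cells")
        Xr = grp[feature_set].to_numpy(dtype=float)
        means = Xr.mean(axis=0)
        sds = Xr.std(axis=0)  # population convention (1/n)
        zero = np.flatnonzero(sds == 0)
        if zero.size:
            raise StatisticsError(
                f"zero-variance column {feature_set[zero[0]]!r} in sample {sid!r}"
            )
        out.append(
            SampleMatrix(
                sample_id=str(sid),
                X=(Xr - means) / sds,
                feature_names=feature_set,
                means=means,
                sds=sds,
            )
        )
    return out


def apply_standardization(raw: np.ndarray, sm: SampleMatrix) -> np.ndarray:
    """Apply a stored sample's scaling parameters to a raw feature matrix."""
    return (np.asarray(raw, dtype=float) - sm.means) / sm.sds


def product_matrix(X, graph: AdjacencyGraph) -> np.ndarray:
    """M = Xᵀ(L + Lᵀ)X / (2n) — the spatially weighted covariance."""
    Xm = X.X if isinstance(X, SampleMatrix) else np.asarray(X, dtype=float)
    if Xm.ndim == 1:
        Xm = Xm[:, None]
    if Xm.shape[0] != graph.n:
        raise SchemaError(
            f"matrix has {Xm.shape[0]} rows but graph has {graph.n} cells"
        )
    LX = graph.L @ Xm
    M = (Xm.T @ LX + LX.T @ Xm) / (2.0 * graph.n)
    return (M + M.T) / 2.0


def classical_pca(
    samples: list[SampleMatrix],
    graphs: list[AdjacencyGraph] = None,
):
    """Classical PCA of the pooled standardized matrix, with per-PC Moran's I.

    Returns (components (p×p, columns), explained-variance fractions,
    per-sample Moran's-index table or None).  Warns via the returned rank
    if there are fewer pooled cells than features.
    """
    Xp = np.vstack([s.X for s in samples])
    n, p = Xp.shape
    cov = (Xp.T @ Xp) / n
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evr = evals / evals.sum()
    mi_table = None
    if graphs is not None:
        rows = []
        for s, g in zip(samples, graphs):
            scores = s.X @ evecs
            scores = scores - scores.mean(axis=0)
            rows.append(
                {"sample_id": s.sample_id}
                | {f"PC{k + 1}": morans_index(scores[:, k], g) for k in range(p)}
            )
        mi_table = pd.DataFrame(rows)
    return evecs, evr, mi_table
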