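"""Bayesian force inference on polygonal cell meshes (straight-edge model).

Estimates edge tensions T_j and cell pressures P_i from junction geometry
alone, assuming static force balance at every interior vertex:

    Σ_j T_j û_j + Σ_i P_i ∂A_i/∂p = 0

(the pressure term is the straight-edge lever-arm form, P n̂ ℓ/2 per incident
cell edge).  The homogeneous system Ax = 0 is scale-free in T and blind to a
constant pressure shift, so the inversion is regularized by a Gaussian prior
(T ~ N(1, σ²/μ), P ~ N(0, σ²/μ)) and the prior weight μ is selected on a grid
by maximizing the marginal likelihood (minimizing the ABIC-style score
N·log S(μ) + log det(AᵀA + μB) − M·log μ).  Gauges are applied post hoc:
tensions rescaled to mean 1, pressures shifted to mean 0.

Per-cell stress is the Batchelor cell average
σ_i = −P_i I + (1/2A_i) Σ_{j∈i} T_j (ℓ_j ⊗ ℓ_j)/|ℓ_j| with principal
amplitudes λ₁ ≥ λ₂, principal direction ϑ₁ (axial degrees) and anisotropy
ratio r = λ₂/λ₁ (≈1 isotropic, ≈0 anisotropic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .angles import wrap_axial
from .errors import GeometryError, ParameterError, UnderdeterminedError
from .mesh import Tessellation

__all__ = [
    "BalanceSystem",
    "ForceSolution",
    "build_balance_system",
    "solve_bayesian",
    "cell_stress_tensor",
    "classify_anisotropy",
    "attach_mechanics",
    "DEFAULT_MU_GRID",
]

DEFAULT_MU_GRID = tuple(10.0 ** np.arange(-6.0, 1.5, 0.5))


@dataclass
class BalanceSystem:
    """Sparse force-balance operator over unknowns x = (T_1..T_E, P_1..P_C)."""

    A: sp.csr_matrix
    n_edges: int
    n_cells: int
    interior_vertices: np.ndarray


@dataclass
class ForceSolution:
    """Inferred tensions/pressures and the inversion diagnostics."""

    tensions: np.ndarray
    pressures: np.ndarray
    mu: float
    residual_norm: float
    abic_table: pd.DataFrame = field(default=None, repr=False)


def build_balance_system(tess: Tessellation) -> BalanceSystem:
    """Two balance equations (x, y) per interior vertex.

    Boundary vertices are pinned by the substrate/neighboring tissue and
    contribute no equations.  Raises :class:`UnderdeterminedError` when the
    mesh has no interior vertex.
    """
    interior = np.flatnonzero(~tess.boundary_vertex_mask())
    if interior.size == 0:
        raise UnderdeterminedError("mesh has no interior vertex; system empty")
    row_of = {int(v): 2 * k for k, v in enumerate(interior)}

    rows, cols, vals = [], [], []
    pos = tess.vertices

    a, b = tess.edges[:, 0], tess.edges[:, 1]
    d = pos[b] - pos[a]
    ln = np.linalg.norm(d, axis=1)
    if np.any(ln <= 0):
        raise GeometryError("zero-length edge")
    u = d / ln[:, None]
    for j in range(tess.n_edges):
        for v, sgn in ((int(a[j]), 1.0), (int(b[j]), -1.0)):
            r = row_of.get(v)
            if r is None:
                continue
            rows += [r, r + 1]
            cols += [j, j]
            vals += [sgn * u[j, 0], sgn * u[j, 1]]

    for i, cyc in enumerate(tess.cells):
        p = pos[cyc]
        nxt = np.roll(p, -1, axis=0)
        prv = np.roll(p, 1, axis=0)
        dAdp = 0.5 * np.column_stack([nxt[:, 1] - prv[:, 1], prv[:, 0] - nxt[:, 0]])
        for k, v in enumerate(cyc):
            r = row_of.get(int(v))
            if r is None:
                continue
            rows += [r, r + 1]
            cols += [tess.n_edges + i, tess.n_edges + i]
            vals += [dAdp[k, 0], dAdp[k, 1]]

    A = sp.csr_matrix(
        (vals, (rows, cols)),
        shape=(2 * interior.size, tess.n_edges + tess.n_cells),
    )
    return BalanceSystem(A=A, n_edges=tess.n_edges, n_cells=tess.n_cells,
                         interior_vertices=interior)


def solve_bayesian(
    system: BalanceSystem,
    t0: float = 1.0,
    mu_grid=DEFAULT_MU_GRID,
    pressure_prior_weight: float = 1.0,
) -> ForceSolution:
    """Ridge-regularized least squares with marginal-likelihood μ selection.

    Minimizes ‖Ax‖² + μ‖x − x₀‖²_B with x₀ = (t0,…,t0, 0,…,0) and
    B = diag(1,…,1, w_P,…,w_P).  Ties in the score are broken toward the
    larger μ (stronger prior).
    """
    mu_grid = np.asarray(sorted(mu_grid), dtype=float)
    if mu_grid.size == 0 or np.any(mu_grid <= 0):
        raise ParameterError("mu_grid must be non-empty and positive")

    A = system.A
    n_eq, m = A.shape
    E = system.n_edges
    x0 = np.concatenate([np.full(E, t0), np.zeros(system.n_cells)])
    bdiag = np.concatenate(
        [np.ones(E), np.full(system.n_cells, pressure_prior_weight)]
    )
    B = sp.diags(bdiag)
    AtA = (A.T @ A).tocsc()

    records = []
    best = None
    for mu in mu_grid:
        H = (AtA + mu * B).tocsc()
        try:
            lu = splu(H)
        except RuntimeError:
            records.append({"mu": mu, "abic": np.nan, "S": np.nan})
            continue
        x = lu.solve(mu * (bdiag * x0))
        r = A @ x
        S = float(r @ r + mu * np.dot(bdiag, (x - x0) ** 2))
        # log det of the SPD matrix H from its sparse LU factors
        logdet = float(
            np.sum(np.log(np.abs(lu.U.diagonal()))) + np.sum(np.log(np.abs(lu.L.diagonal())))
        )
        abic = n_eq * np.log(max(S, 1e-300)) + logdet - m * np.log(mu)
        records.append({"mu": mu, "abic": abic, "S": S})
        if best is None or abic <= best[0]:
            best = (abic, mu, x)

    if best is None:
        raise RuntimeError(
            "normal equations singular at every mu; diagnostics: "
            + str(records)
        )

    _, mu, x = best
    T = x[:E].copy()
    P = x[E:].copy()
    scale = T.mean()
    if abs(scale) < 1e-12:
        raise RuntimeError("inferred tensions have zero mean; gauge undefined")
    T /= scale
    P /= scale
    P -= P.mean()
    resid = float(np.linalg.norm(A @ np.concatenate([T, P])))
    return ForceSolution(
        tensions=T,
        pressures=P,
        mu=float(mu),
        residual_norm=resid,
        abic_table=pd.DataFrame.from_records(records),
    )


def cell_stress_tensor(tess: Tessellation, solution: ForceSolution, cell_id: int):
    """Batchelor stress of one cell: (σ, λ₁, λ₂, ϑ₁, r, degenerate_flag).

    r = λ₂/λ₁ is defined only for λ₁ > 0 (NaN otherwise); for an isotropic
    tensor (λ₁ = λ₂) the principal direction is undefined and ϑ₁ is reported
    as 0 with the degenerate flag set.
    """
    poly = tess.cell_polygon(cell_id)
    x, y = poly[:, 0], poly[:, 1]
    area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area <= 0:
        raise GeometryError(f"cell {cell_id} has non-positive area")

    sigma = -solution.pressures[cell_id] * np.eye(2)
    acc = np.zeros((2, 2))
    for j in tess.cell_edge_ids(cell_id):
        a, b = tess.edges[j]
        l = tess.vertices[b] - tess.vertices[a]
        ln = np.linalg.norm(l)
        if ln <= 0:
            continue
        acc += solution.tensions[j] * np.outer(l, l) / ln
    sigma = sigma + acc / (2.0 * area)

    evals, evecs = np.linalg.eigh(sigma)
    lam2, lam1 = float(evals[0]), float(evals[1])
    degenerate = (lam1 - lam2) <= 1e-12 * max(abs(lam1), 1.0)
    if degenerate:
        theta1 = 0.0
    else:
        v = evecs[:, 1]
        theta1 = wrap_axial(np.rad2deg(np.arctan2(v[1], v[0])))
    r = lam2 / lam1 if lam1 > 0 else np.nan
    return sigma, lam1, lam2, theta1, float(r), bool(degenerate)


def classify_anisotropy(r: float, threshold: float = 0.3) -> str:
    """'anisotropic' iff r < threshold (strict); NaN r is 'undefined'."""
    if not np.isfinite(r):
        return "undefined"
    return "anisotropic" if r < threshold else "isotropic-leaning"


def attach_mechanics(
    features: pd.DataFrame,
    tess: Tessellation,
    solution: ForceSolution,
) -> pd.DataFrame:
    """Append pressure, stress_direction, stress_anisotropy (+λ columns)."""
    out = features.copy()
    lam1 = np.empty(tess.n_cells)
    lam2 = np.empty(tess.n_cells)
    th = np.empty(tess.n_cells)
    rr = np.empty(tess.n_cells)
    for i in range(tess.n_cells):
        _, l1, l2, t1, r, _ = cell_stress_tensor(tess, solution, i)
        lam1[i], lam2[i], th[i], rr[i] = l1, l2, t1, r
    out["pressure"] = solution.pressures[out["cell_id"].to_numpy()]
    out["stress_direction"] = th[out["cell_id"].to_numpy()]
    out["stress_anisotropy"] = rr[out["cell_id"].to_numpy()]
    out["lambda1"] = lam1[out["cell_id"].to_numpy()]
    out["lambda2"] = lam2[out["cell_id"].to_numpy()]
    return out
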