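"""Adjacency, Moran's index, standardization and the product matrix."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from epimorph.errors import SchemaError, StatisticsError
from epimorph.spatial import (
    AdjacencyGraph,
    build_adjacency,
    classical_pca,
    morans_index,
    prepare_analysis_table,
    product_matrix,
    standardize,
)


def graph_from_w(W):
    W = sp.csr_matrix(np.asarray(W, dtype=float))
    deg = np.asarray(W.sum(axis=1)).ravel()
    inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
    return AdjacencyGraph(W=W, L=sp.csr_matrix(sp.diags(inv) @ W), n=W.shape[0],
                          isolated=deg == 0)


@pytest.fixture
def path_graph():
    W = np.zeros((4, 4))
    for i in range(3):
        W[i, i + 1] = W[i + 1, i] = 1
    return graph_from_w(W)


def test_adjacency_matches_bruteforce(voronoi_sheet):
    graph = build_adjacency(voronoi_sheet)
    tess = voronoi_sheet
    cell_edges = [
        {tuple(sorted((cyc[k], cyc[(k + 1) % len(cyc)]))) for k in range(len(cyc))}
        for cyc in tess.cells
    ]
    W = graph.W.toarray()
    assert np.allclose(W, W.T)
    assert np.all(np.diag(W) == 0)
    for i in range(tess.n_cells):
        for j in range(i + 1, tess.n_cells):
            expected = 1.0 if cell_edges[i] & cell_edges[j] else 0.0
            assert W[i, j] == expected
    rowsums = np.asarray(graph.L.sum(axis=1)).ravel()
    assert np.all((np.isclose(rowsums, 1)) | (np.isclose(rowsums, 0)))


def test_hex_lattice_interior_row(hex_lattice):
    graph = build_adjacency(hex_lattice)
    interior = np.flatnonzero(~hex_lattice.cell_boundary_flag)
    row = graph.L[interior[0]].toarray().ravel()
    nz = row[row > 0]
    assert len(nz) == 6
    assert np.allclose(nz, 1 / 6)


def test_morans_index_path_graph_hand_value(path_graph):
    """MI of (−1.5,−0.5,0.5,1.5) on the 1-2-3-4 path is exactly 0.4."""
    z = np.array([-1.5, -0.5, 0.5, 1.5])
    assert morans_index(z, path_graph) == pytest.approx(0.4, abs=1e-12)


def test_morans_index_checkerboard_is_minus_one():
    # two-coloring of a 4x4 grid lattice: every neighbor average equals -z_i
    n = 4
    W = np.zeros((n * n, n * n))
    for i in range(n):
        for j in range(n):
            a = i * n + j
            if i + 1 < n:
                W[a, (i + 1) * n + j] = W[(i + 1) * n + j, a] = 1
            if j + 1 < n:
                W[a, a + 1] = W[a + 1, a] = 1
    z = np.array([(-1.0) ** (i + j) for i in range(n) for j in range(n)])
    assert morans_index(z, graph_from_w(W)) == pytest.approx(-1.0, abs=1e-12)


def test_morans_permutation_null(voronoi_sheet):
    """Under random relabeling E[MI] = −1/(n−1)."""
    graph = build_adjacency(voronoi_sheet)
    rng = np.random.default_rng(42)
    z = rng.normal(size=graph.n)
    z -= z.mean()
    vals = []
    for _ in range(1000):
        zp = rng.permutation(z)
        zp -= zp.mean()
        vals.append(morans_index(zp, graph))
    vals = np.asarray(vals)
    expected = -1.0 / (graph.n - 1)
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean() - expected) < 3 * se


def test_morans_index_scale_invariance(path_graph):
    z = np.array([-1.5, -0.5, 0.5, 1.5])
    assert morans_index(3.7 * z, path_graph) == pytest.approx(
        morans_index(z, path_graph)
    )


def test_morans_index_zero_variance_rejected(path_graph):
    with pytest.raises(StatisticsError):
        morans_index(np.zeros(4), path_graph)


def _toy_table(n=30, seed=0, sample_id="a"):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "orientation": rng.uniform(-90, 90, n),
            "area": rng.uniform(20, 80, n),
            "perimeter": rng.uniform(15, 40, n),
            "eccentricity": rng.uniform(0, 1, n),
            "n_neighbors": rng.integers(4, 9, n).astype(float),
            "pressure": rng.normal(0, 0.02, n),
            "stress_direction": rng.uniform(-90, 90, n),
            "stress_anisotropy": rng.uniform(0.1, 1, n),
        }
    )


def test_standardize_moments_and_transfer():
    table = _toy_table()
    sm = standardize(table)[0]
    assert np.allclose(sm.X.mean(axis=0), 0, atol=1e-9)
    assert np.allclose(sm.X.std(axis=0), 1, atol=1e-9)  # population SD
    # reapplying the stored parameters reproduces X exactly
    raw = table[sm.feature_names].to_numpy(float)
    assert np.allclose((raw - sm.means) / sm.sds, sm.X)


def test_standardize_per_sample_blocks():
    a = _toy_table(sample_id="a")
    b = _toy_table(sample_id="b")
    pooled = pd.concat([a, b], ignore_index=True)
    out = standardize(pooled)
    assert [s.sample_id for s in out] == ["a", "b"]
    assert np.allclose(out[0].X, out[1].X)  # identical copies standardize alike


def test_standardize_zero_variance_column_named():
    table = _toy_table()
    table["area"] = 5.0
    with pytest.raises(StatisticsError, match="area"):
        standardize(table)


def test_product_matrix_hand_value(path_graph):
    """p=1 path-graph value: zᵀ(L+Lᵀ)z/(2·4) = 0.5."""
    z = np.array([-1.5, -0.5, 0.5, 1.5])
    M = product_matrix(z[:, None], path_graph)
    assert M.shape == (1, 1)
    assert M[0, 0] == pytest.approx(0.5, abs=1e-12)


def test_product_matrix_identity_reduces_to_covariance():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(50, 4))
    X -= X.mean(axis=0)
    eye = graph_from_w(np.zeros((50, 50)))
    eye.L = sp.identity(50, format="csr")
    M = product_matrix(X, eye)
    assert np.allclose(M, X.T @ X / 50, atol=1e-12)


def test_product_matrix_permutation_equivariance(voronoi_sheet):
    graph = build_adjacency(voronoi_sheet)
    rng = np.random.default_rng(5)
    X = rng.normal(size=(graph.n, 3))
    M = product_matrix(X, graph)
    perm = rng.permutation(graph.n)
    P = sp.csr_matrix((np.ones(graph.n), (np.arange(graph.n), perm)))
    Wp = P @ graph.W @ P.T
    gp = AdjacencyGraph(
        W=Wp,
        L=sp.csr_matrix(
            sp.diags(
                np.divide(1.0, np.asarray(Wp.sum(axis=1)).ravel(),
                          out=np.zeros(graph.n),
                          where=np.asarray(Wp.sum(axis=1)).ravel() > 0)
            )
            @ Wp
        ),
        n=graph.n,
        isolated=np.zeros(graph.n, bool),
    )
    Mp = product_matrix((P @ X), gp)
    assert np.allclose(M, Mp, atol=1e-10)


def test_product_matrix_shrinks_under_spatial_permutation(voronoi_sheet):
    """Randomizing cell positions destroys the spatial signal in M."""
    graph = build_adjacency(voronoi_sheet)
    centroids = voronoi_sheet.cell_centroids()
    z = centroids[:, 1] - centroids[:, 1].mean()  # smooth spatial gradient
    z /= z.std()
    m_obs = product_matrix(z[:, None], graph)[0, 0]
    rng = np.random.default_rng(11)
    null = []
    for _ in range(1000):
        zp = rng.permutation(z)
        null.append(product_matrix((zp - zp.mean())[:, None], graph)[0, 0])
    assert abs(np.mean(null)) < abs(m_obs) / 5
    assert m_obs > np.percentile(null, 99.9)


def test_classical_pca_correlated_columns_and_gradient(voronoi_sheet):
    graph = build_adjacency(voronoi_sheet)
    rng = np.random.default_rng(9)
    n = graph.n
    centroids = voronoi_sheet.cell_centroids()
    grad = centroids[:, 1] / centroids[:, 1].std()  # spatially smooth signal
    table = pd.DataFrame(
        {
            "sample_id": "s",
            # two features share the smooth gradient -> a dominant PC exists
            "f_grad1": grad + 0.3 * rng.normal(size=n),
            "f_grad2": grad + 0.3 * rng.normal(size=n),
            "f_noise": rng.normal(size=n),
        }
    )
    samples = standardize(table, ["f_grad1", "f_grad2", "f_noise"])
    comps, evr, mi = classical_pca(samples, [graph])
    assert evr.sum() == pytest.approx(1.0)
    # PC1 is the shared-gradient direction and carries the highest Moran's I
    assert np.abs(comps[0, 0]) > 0.5 and np.abs(comps[1, 0]) > 0.5
    mi_vals = mi.iloc[0, 1:].to_numpy(float)
    assert np.argmax(mi_vals) == 0


def test_prepare_analysis_table_ap_reference():
    table = _toy_table()
    table.loc[0, "orientation"] = 90.0   # along AP axis
    table.loc[1, "orientation"] = -80.0  # axially 10 deg past the AP axis
    out = prepare_analysis_table(table)
    assert out.loc[0, "orientation"] == pytest.approx(0.0)
    assert out.loc[1, "orientation"] == pytest.approx(10.0)
    lr = prepare_analysis_table(table, angle_reference="lr")
    assert lr.loc[0, "orientation"] == pytest.approx(90.0)
    with pytest.raises(SchemaError):
        prepare_analysis_table(table, angle_reference="polar")
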