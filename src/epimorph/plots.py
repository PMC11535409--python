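"""Map and heatmap rendering.

All renderers are pure functions of their input tables/meshes returning a
matplotlib Figure; :func:`save_figure` writes SVG or PNG.  Palettes follow
the conventions of the analysis: cluster 1 green, cluster 2 orange, cluster 3
purple; anisotropy on a continuous red (isotropic, r≈1) → yellow
(anisotropic, r≈0) colormap.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.collections import LineCollection, PolyCollection
from matplotlib.colors import LinearSegmentedColormap

from .mesh import Tessellation

__all__ = [
    "feature_map",
    "orientation_map",
    "stress_map",
    "anisotropy_map",
    "cluster_map",
    "loadings_heatmap",
    "eigenvalue_heatmap",
    "save_figure",
]

CLUSTER_COLORS = {1: "tab:green", 2: "tab:orange", 3: "tab:purple",
                  4: "tab:cyan", 5: "tab:brown"}

# red = isotropic (r near 1) -> yellow = anisotropic (r near 0)
ANISOTROPY_CMAP = LinearSegmentedColormap.from_list("aniso", ["yellow", "red"])


def _polys(tess: Tessellation):
    return [tess.cell_polygon(i) for i in range(tess.n_cells)]


def _base_axes(tess, title):
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.set_aspect("equal")
    ax.set_title(title)
    ax.set_xlabel("x (left-right, µm)")
    ax.set_ylabel("y (anterior-posterior, µm)")
    ax.invert_yaxis()  # anterior (low y) at the top, as in frontal views
    return fig, ax


def feature_map(tess: Tessellation, values, title: str = "", cmap: str = "viridis"):
    """Cells colored by a continuous per-cell value."""
    fig, ax = _base_axes(tess, title)
    pc = PolyCollection(_polys(tess), array=np.asarray(values, float),
                        cmap=cmap, edgecolor="k", linewidth=0.2)
    ax.add_collection(pc)
    ax.autoscale_view()
    fig.colorbar(pc, ax=ax, shrink=0.8)
    return fig


def _axial_bars(tess, angles_deg, lengths=None):
    centroids = tess.cell_centroids()
    if lengths is None:
        med = np.median([np.sqrt(a) for a in np.abs(tess.cell_signed_areas())])
        lengths = np.full(tess.n_cells, 0.8 * med)
    ang = np.deg2rad(np.asarray(angles_deg, float))
    d = 0.5 * np.asarray(lengths, float)[:, None] * np.column_stack(
        [np.cos(ang), np.sin(ang)]
    )
    return np.stack([centroids - d, centroids + d], axis=1)


def orientation_map(tess: Tessellation, theta_deg, title: str = "cell orientation"):
    """Axial bars along each cell's main elongation axis."""
    fig, ax = _base_axes(tess, title)
    pc = PolyCollection(_polys(tess), facecolor="none", edgecolor="0.8",
                        linewidth=0.2)
    ax.add_collection(pc)
    ax.add_collection(LineCollection(_axial_bars(tess, theta_deg), colors="k",
                                     linewidths=1.0))
    ax.autoscale_view()
    return fig


def stress_map(tess: Tessellation, theta1_deg, lam1, title: str = "principal stress"):
    """Principal-stress bars scaled by the major amplitude λ₁."""
    lam1 = np.asarray(lam1, float)
    med = np.median([np.sqrt(a) for a in np.abs(tess.cell_signed_areas())])
    scale = 0.8 * med / max(np.nanmax(np.abs(lam1)), 1e-12)
    fig, ax = _base_axes(tess, title)
    pc = PolyCollection(_polys(tess), facecolor="none", edgecolor="0.8",
                        linewidth=0.2)
    ax.add_collection(pc)
    ax.add_collection(
        LineCollection(_axial_bars(tess, theta1_deg, scale * np.abs(lam1)),
                       colors="crimson", linewidths=1.0)
    )
    ax.autoscale_view()
    return fig


def anisotropy_map(tess: Tessellation, ratio, title: str = "stress anisotropy"):
    """Cells colored red (isotropic, r≈1) to yellow (anisotropic, r≈0)."""
    fig, ax = _base_axes(tess, title)
    pc = PolyCollection(_polys(tess), array=np.clip(np.asarray(ratio, float), 0, 1),
                        cmap=ANISOTROPY_CMAP, edgecolor="k", linewidth=0.2)
    pc.set_clim(0, 1)
    ax.add_collection(pc)
    ax.autoscale_view()
    fig.colorbar(pc, ax=ax, shrink=0.8, label="λ₂/λ₁")
    return fig


def cluster_map(tess: Tessellation, labels, title: str = "clusters"):
    """Cells colored by cluster label (1 green, 2 orange, 3 purple)."""
    fig, ax = _base_axes(tess, title)
    colors = [CLUSTER_COLORS.get(int(l), "0.5") for l in labels]
    pc = PolyCollection(_polys(tess), facecolors=colors, edgecolor="k",
                        linewidth=0.2)
    ax.add_collection(pc)
    ax.autoscale_view()
    return fig


def loadings_heatmap(model, title: str = "jsPCA loadings"):
    """Feature × component heatmap of the joint eigenvector coefficients."""
    ld = model.loadings()
    fig, ax = plt.subplots(figsize=(1.2 * ld.shape[1] + 2, 0.5 * ld.shape[0] + 2))
    im = ax.imshow(ld.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(ld.shape[1]), ld.columns)
    ax.set_yticks(range(ld.shape[0]), ld.index)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    return fig


def eigenvalue_heatmap(model, title: str = "per-sample eigenvalues"):
    """Sample × component heatmap of diag(VᵀM_kV), ranked order."""
    ev = model.eigenvalues()
    fig, ax = plt.subplots(figsize=(1.2 * ev.shape[1] + 2, 0.5 * ev.shape[0] + 2))
    im = ax.imshow(ev.to_numpy(), cmap="magma", aspect="auto")
    ax.set_xticks(range(ev.shape[1]), ev.columns)
    ax.set_yticks(range(ev.shape[0]), ev.index)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    return fig


def save_figure(fig, path) -> None:
    fig.savefig(path, bbox_inches="tight", metadata=_stable_metadata(str(path)))
    plt.close(fig)


def _stable_metadata(path: str):
    # strip volatile timestamps so identical inputs give identical bytes
    if path.endswith(".svg"):
        return {"Date": None}
    if path.endswith(".png"):
        return {"Software": None}
    return None
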