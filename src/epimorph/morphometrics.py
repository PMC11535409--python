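"""Per-cell apical morphometrics from polygonal cell outlines.

Features follow the standard apical descriptors of epithelial segmentation:
area, perimeter, orientation of the main elongation axis, eccentricity of the
area-moment-equivalent ellipse, number of neighbors and (optionally) the
nucleus-to-Golgi polarity angle.  All features are computed on planar
polygons in µm; angles follow the conventions of :mod:`epimorph.angles`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .angles import wrap_axial, wrap_directional
from .errors import GeometryError
from .mesh import Tessellation

__all__ = [
    "polygon_area_perimeter",
    "polygon_moments",
    "cell_orientation",
    "cell_eccentricity",
    "count_neighbors",
    "golgi_polarity",
    "compute_features",
    "MORPHOLOGY_COLUMNS",
]

MORPHOLOGY_COLUMNS = [
    "orientation",
    "area",
    "perimeter",
    "eccentricity",
    "n_neighbors",
]


def _check_simple(poly: np.ndarray) -> None:
    from shapely.geometry import Polygon

    if len(poly) < 3:
        raise GeometryError("polygon needs at least 3 vertices")
    if not Polygon(poly).is_valid:
        raise GeometryError("polygon is self-intersecting or degenerate")


def polygon_area_perimeter(poly, validate: bool = True) -> tuple[float, float]:
    """Shoelace area (absolute value) and perimeter of a simple polygon."""
    p = np.asarray(poly, dtype=float)
    if validate:
        _check_simple(p)
    x, y = p[:, 0], p[:, 1]
    area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    perimeter = float(np.sum(np.linalg.norm(np.roll(p, -1, axis=0) - p, axis=1)))
    if area <= 0:
        raise GeometryError("polygon has zero area")
    return float(area), perimeter


def polygon_moments(poly, validate: bool = True):
    """Area, centroid and central second-moment (covariance) matrix.

    Closed-form per-edge (triangle decomposition) formulas; the covariance is
    the normalized central second moment ∫(r−c)(r−c)ᵀ dA / A, the moment
    tensor of the shape treated as a uniform lamina.
    """
    p = np.asarray(poly, dtype=float)
    if validate:
        _check_simple(p)
    x, y = p[:, 0], p[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    if abs(a) < 1e-300:
        raise GeometryError("polygon has zero area")
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    ixx = ((x * x + x * xn + xn * xn) * cross).sum() / 12.0
    iyy = ((y * y + y * yn + yn * yn) * cross).sum() / 12.0
    ixy = ((2 * x * y + x * yn + xn * y + 2 * xn * yn) * cross).sum() / 24.0
    # central moments normalized by signed area -> orientation-independent
    cov = np.array(
        [
            [ixx / a - cx * cx, ixy / a - cx * cy],
            [ixy / a - cx * cy, iyy / a - cy * cy],
        ]
    )
    return abs(a), np.array([cx, cy]), cov


def cell_orientation(poly, validate: bool = True) -> float:
    """Axial angle (degrees, (−90, 90]) of the main elongation axis.

    Principal axis of the polygon's second-order area moments; 0° lies along
    the embryonic left–right (x) axis.  For moment-isotropic shapes (regular
    polygons) the orientation is undefined and reported as 0.
    """
    _, _, cov = polygon_moments(poly, validate=validate)
    evals, evecs = np.linalg.eigh(cov)
    if (evals[1] - evals[0]) <= 1e-12 * max(evals[1], 1e-300):
        return 0.0
    v = evecs[:, 1]  # eigenvector of the larger moment
    return wrap_axial(np.rad2deg(np.arctan2(v[1], v[0])))


def cell_eccentricity(poly, validate: bool = True) -> float:
    """Eccentricity e = √(1 − (b/a)²) of the moment-equivalent ellipse.

    0 for moment-isotropic (round) shapes, approaching 1 for needle-like
    cells; always < 1 for non-degenerate polygons.
    """
    _, _, cov = polygon_moments(poly, validate=validate)
    evals = np.linalg.eigvalsh(cov)
    if evals[1] <= 0:
        raise GeometryError("degenerate polygon (zero second moment)")
    ratio = max(evals[0], 0.0) / evals[1]  # (b/a)^2
    return float(np.sqrt(1.0 - ratio))


def count_neighbors(tess: Tessellation, cell_id: int) -> int:
    """Number of distinct cells sharing at least one edge with ``cell_id``."""
    if not 0 <= cell_id < tess.n_cells:
        raise LookupError(f"unknown cell id {cell_id}")
    ec = tess.edge_cells()
    neigh = set()
    for j in tess.cell_edge_ids(cell_id):
        for i in ec[j]:
            if i != cell_id:
                neigh.add(i)
    return len(neigh)


def golgi_polarity(nucleus_center, golgi_center) -> float:
    """Directional angle (degrees, (−180, 180]) of the nucleus→Golgi vector.

    Measured against the +x (embryonic left–right) axis.
    """
    d = np.asarray(golgi_center, dtype=float) - np.asarray(nucleus_center, dtype=float)
    if np.allclose(d, 0.0):
        raise GeometryError("nucleus and Golgi centers coincide; angle undefined")
    return wrap_directional(np.rad2deg(np.arctan2(d[1], d[0])))


def compute_features(tess: Tessellation) -> pd.DataFrame:
    """Morphological feature table for every cell of a tessellation.

    Columns: sample_id, cell_id, centroid_x/y, orientation, area, perimeter,
    eccentricity, n_neighbors, boundary.  Mechanical columns are appended by
    :func:`epimorph.forces.attach_mechanics`.
    """
    rows = []
    ec = tess.edge_cells()
    neighbor_count = np.zeros(tess.n_cells, dtype=int)
    seen = [set() for _ in range(tess.n_cells)]
    for inc in ec:
        if len(inc) == 2:
            i, j = inc
            if j not in seen[i]:
                seen[i].add(j)
                seen[j].add(i)
    neighbor_count = np.array([len(s) for s in seen])

    for i in range(tess.n_cells):
        poly = tess.cell_polygon(i)
        area, perim = polygon_area_perimeter(poly, validate=False)
        _, centroid, cov = polygon_moments(poly, validate=False)
        evals, evecs = np.linalg.eigh(cov)
        if (evals[1] - evals[0]) <= 1e-12 * max(evals[1], 1e-300):
            theta = 0.0
        else:
            v = evecs[:, 1]
            theta = wrap_axial(np.rad2deg(np.arctan2(v[1], v[0])))
        ecc = float(np.sqrt(1.0 - max(evals[0], 0.0) / evals[1])) if evals[1] > 0 else 0.0
        rows.append(
            {
                "sample_id": tess.sample_id,
                "cell_id": i,
                "centroid_x": centroid[0],
                "centroid_y": centroid[1],
                "orientation": theta,
                "area": area,
                "perimeter": perim,
                "eccentricity": ecc,
                "n_neighbors": int(neighbor_count[i]),
                "boundary": bool(tess.cell_boundary_flag[i]),
            }
        )
    return pd.DataFrame(rows)
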