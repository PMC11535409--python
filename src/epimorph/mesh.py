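"""Planar cell mesh (tessellation) container, validation and JSON round trip.

A :class:`Tessellation` is the segmentation-level description of an epithelial
sheet: vertex positions in µm, unordered edges (vertex-index pairs) and cells
as counter-clockwise vertex cycles.  Every edge belongs to one cell (sheet
boundary) or two cells (interior junction); for a simply connected sheet the
planar Euler relation V − E + C = 1 holds (outer face excluded).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

SCHEMA_VERSION = 1


class MeshError(ValueError):
    """Raised for structurally invalid tessellations."""


@dataclass
class Tessellation:
    """Polygonal tessellation of a planar epithelial sheet.

    Attributes
    ----------
    vertices : (V, 2) float array, µm
    edges : (E, 2) int array of vertex indices, each row sorted
    cells : list of int lists, counter-clockwise vertex cycles
    cell_boundary_flag : (C,) bool array, True if the cell touches the sheet
        boundary
    sample_id : label of the sample/embryo this sheet belongs to
    """

    vertices: np.ndarray
    edges: np.ndarray
    cells: list[list[int]]
    cell_boundary_flag: np.ndarray
    sample_id: str = "sample"
    _edge_index: dict = field(default=None, repr=False, compare=False)
    _edge_cells: list = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.edges = np.asarray(self.edges, dtype=int)
        if self.edges.size:
            self.edges = np.sort(self.edges, axis=1)
        self.cells = [list(map(int, c)) for c in self.cells]
        self.cell_boundary_flag = np.asarray(self.cell_boundary_flag, dtype=bool)

    # -- derived structure -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def edge_index(self) -> dict:
        """Map (lo, hi) vertex pair -> edge id."""
        if self._edge_index is None:
            self._edge_index = {
                (int(a), int(b)): j for j, (a, b) in enumerate(self.edges)
            }
        return self._edge_index

    def cell_edge_ids(self, cell_id: int) -> list[int]:
        idx = self.edge_index()
        cyc = self.cells[cell_id]
        return [
            idx[tuple(sorted((cyc[k], cyc[(k + 1) % len(cyc)])))]
            for k in range(len(cyc))
        ]

    def edge_cells(self) -> list[list[int]]:
        """For each edge, the list of incident cell ids (length 1 or 2)."""
        if self._edge_cells is None:
            ec = [[] for _ in range(self.n_edges)]
            for i in range(self.n_cells):
                for j in self.cell_edge_ids(i):
                    ec[j].append(i)
            self._edge_cells = ec
        return self._edge_cells

    def cell_arrays(self):
        """Flattened cell-cycle index arrays for vectorized geometry.

        Returns (flat, nxt, prv, cell_of): vertex ids of all cycles
        concatenated, the next/previous vertex id within each cycle, and the
        owning cell id per entry.
        """
        if getattr(self, "_cell_arrays", None) is None:
            flat, nxt, prv, owner = [], [], [], []
            for i, cyc in enumerate(self.cells):
                m = len(cyc)
                flat.extend(cyc)
                nxt.extend(cyc[1:] + cyc[:1])
                prv.extend(cyc[-1:] + cyc[:-1])
                owner.extend([i] * m)
            self._cell_arrays = (
                np.asarray(flat, dtype=int),
                np.asarray(nxt, dtype=int),
                np.asarray(prv, dtype=int),
                np.asarray(owner, dtype=int),
            )
        return self._cell_arrays

    def boundary_edge_mask(self) -> np.ndarray:
        return np.array([len(c) == 1 for c in self.edge_cells()], dtype=bool)

    def boundary_vertex_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_vertices, dtype=bool)
        for (a, b), cells in zip(self.edges, self.edge_cells()):
            if len(cells) == 1:
                mask[a] = mask[b] = True
        return mask

    def cell_polygon(self, cell_id: int) -> np.ndarray:
        return self.vertices[self.cells[cell_id]]

    def cell_centroids(self) -> np.ndarray:
        """Area centroids of all cell polygons, shape (C, 2)."""
        out = np.empty((self.n_cells, 2))
        for i in range(self.n_cells):
            p = self.cell_polygon(i)
            x, y = p[:, 0], p[:, 1]
            xn, yn = np.roll(x, -1), np.roll(y, -1)
            cross = x * yn - xn * y
            a = cross.sum() / 2.0
            if abs(a) < 1e-300:
                out[i] = p.mean(axis=0)
            else:
                out[i, 0] = ((x + xn) * cross).sum() / (6.0 * a)
                out[i, 1] = ((y + yn) * cross).sum() / (6.0 * a)
        return out

    # -- invariants ---------------------------------------------------------
    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_edges + self.n_cells

    def cell_signed_areas(self) -> np.ndarray:
        areas = np.empty(self.n_cells)
        for i in range(self.n_cells):
            p = self.cell_polygon(i)
            x, y = p[:, 0], p[:, 1]
            areas[i] = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        return areas

    def validate(self, check_simple: bool = False) -> None:
        """Check structural invariants; raise :class:`MeshError` on failure."""
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise MeshError("vertices must be (V, 2)")
        for c in self.cells:
            if len(c) < 3:
                raise MeshError("cell with fewer than 3 vertices")
        counts = [len(c) for c in self.edge_cells()]
        if any(k not in (1, 2) for k in counts):
            raise MeshError("edge incident to 0 or >2 cells")
        if np.any(self.cell_signed_areas() <= 0):
            raise MeshError("cell with non-positive signed area (not CCW/simple)")
        if self.euler_characteristic() != 1:
            raise MeshError(
                f"Euler relation violated: V-E+C = {self.euler_characteristic()}"
            )
        if check_simple:
            from shapely.geometry import Polygon

            for i in range(self.n_cells):
                if not Polygon(self.cell_polygon(i)).is_valid:
                    raise MeshError(f"cell {i} polygon is not simple")

    # -- serialization -------------------------------------------------------
    def to_dict(self, ground_truth=None) -> dict:
        d = {
            "schema_version": SCHEMA_VERSION,
            "sample_id": self.sample_id,
            "vertices": self.vertices.tolist(),
            "edges": self.edges.tolist(),
            "cells": self.cells,
            "cell_boundary_flag": self.cell_boundary_flag.astype(int).tolist(),
        }
        if ground_truth is not None:
            d["ground_truth"] = (
                ground_truth if isinstance(ground_truth, dict)
                else ground_truth.to_dict()
            )
        return d

    @classmethod
    def from_dict(cls, d: dict):
        if d.get("schema_version") != SCHEMA_VERSION:
            raise MeshError(f"unsupported mesh schema version {d.get('schema_version')}")
        tess = cls(
            vertices=np.asarray(d["vertices"], dtype=float),
            edges=np.asarray(d["edges"], dtype=int).reshape(-1, 2),
            cells=d["cells"],
            cell_boundary_flag=np.asarray(d["cell_boundary_flag"], dtype=bool),
            sample_id=d.get("sample_id", "sample"),
        )
        gt = d.get("ground_truth")
        return (tess, gt) if gt is not None else (tess, None)

    def save(self, path, ground_truth=None) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(ground_truth), fh)

    @classmethod
    def load(cls, path):
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def hexagonal_lattice(n_rows: int, n_cols: int, side: float = 1.0,
                      sample_id: str = "hex") -> Tessellation:
    """Regular hexagonal lattice of ``n_rows × n_cols`` cells.

    A uniform-tension, zero-pressure force balance holds exactly at every
    interior (3-valent, 120°) vertex, which makes this the reference mesh for
    force-inference sanity checks.
    """
    vdict: dict[tuple[int, int], int] = {}
    verts: list[tuple[float, float]] = []

    def vid(key, xy):
        if key not in vdict:
            vdict[key] = len(verts)
            verts.append(xy)
        return vdict[key]

    w = np.sqrt(3.0) * side  # hexagon width (flat-top horizontal extent)
    cells = []
    for r in range(n_rows):
        for c in range(n_cols):
            cx = c * w + (r % 2) * (w / 2.0)
            cy = r * 1.5 * side
            cyc = []
            for k in range(6):
                ang = np.pi / 2 + k * np.pi / 3  # pointy-top hexagon, CCW
                x = cx + side * np.cos(ang)
                y = cy + side * np.sin(ang)
                key = (round(x * 4 / side), round(y * 4 / side))
                cyc.append(vid(key, (x, y)))
            cells.append(cyc)

    verts = np.asarray(verts)
    edges = set()
    for cyc in cells:
        for k in range(len(cyc)):
            a, b = cyc[k], cyc[(k + 1) % len(cyc)]
            edges.add((min(a, b), max(a, b)))
    edges = np.array(sorted(edges), dtype=int)

    tess = Tessellation(
        vertices=verts,
        edges=edges,
        cells=cells,
        cell_boundary_flag=np.zeros(len(cells), dtype=bool),
        sample_id=sample_id,
    )
    # flag boundary cells from boundary edges
    bflag = np.zeros(tess.n_cells, dtype=bool)
    for j, inc in enumerate(tess.edge_cells()):
        if len(inc) == 1:
            bflag[inc[0]] = True
    tess.cell_boundary_flag = bflag
    return tess
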