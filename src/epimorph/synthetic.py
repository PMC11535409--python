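"""Synthetic dorsal-pericardial-wall-like epithelia with known mechanics.

The generator produces planar polygonal sheets at mechanical equilibrium with
per-cell ground-truth region labels, orientation targets, edge tensions and
cell pressures, so that the whole morphometrics → force-inference → jsPCA →
clustering pipeline can be exercised and validated without imaging data.

Coordinate frame: x is the embryonic left–right axis, y the anterior–posterior
axis with y increasing posteriorly (the arterial pole / anterior edge is at
low y, the venous pole at high y).  The anterior edge carries a semicircular
notch standing in for the inferior outflow tract; it is cosmetic and
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import Voronoi, cKDTree
from shapely.geometry import Point, Polygon, box

from .angles import wrap_axial
from .errors import EquilibrationError, GeometryError, ParameterError
from .mesh import Tessellation

__all__ = [
    "DomainSpec",
    "RegionSpec",
    "GroundTruth",
    "TensionModel",
    "generate_voronoi_sheet",
    "dpw_pattern",
    "apply_dpw_stretch",
    "apply_region_stretch",
    "impose_region_pattern",
    "randomize_pattern",
    "assign_mechanics",
    "relax_to_equilibrium",
    "vertex_forces",
    "generate_sample",
]


# --------------------------------------------------------------------------
# domain geometry
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class DomainSpec:
    """Rectangle with an optional semicircular notch on the anterior edge.

    width/height in µm; the notch is centred on the anterior (low-y) edge.
    """

    width: float = 300.0
    height: float = 300.0
    notch_radius: float = 60.0
    notch_segments: int = 24

    def polygon(self) -> Polygon:
        if self.width <= 0 or self.height <= 0:
            raise GeometryError("domain has zero or negative area")
        rect = box(0.0, 0.0, self.width, self.height)
        if self.notch_radius > 0:
            notch = Point(self.width / 2.0, 0.0).buffer(
                self.notch_radius, quad_segs=self.notch_segments
            )
            rect = rect.difference(notch)
        if rect.is_empty or rect.area <= 0:
            raise GeometryError("domain has zero area after notch subtraction")
        return rect


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------
@dataclass
class GroundTruth:
    """Per-cell labels and per-edge/per-cell forward mechanics.

    Gauge conventions: mean(edge_tension) = 1, mean(cell_pressure) = 0.
    """

    region_label: np.ndarray  # (C,) str
    orientation_target: np.ndarray  # (C,) axial degrees
    edge_tension: np.ndarray | None = None  # (E,) > 0
    cell_pressure: np.ndarray | None = None  # (C,)

    def to_dict(self) -> dict:
        d = {
            "region_label": [str(s) for s in self.region_label],
            "orientation_target": np.asarray(self.orientation_target, float).tolist(),
        }
        if self.edge_tension is not None:
            d["edge_tension"] = np.asarray(self.edge_tension, float).tolist()
        if self.cell_pressure is not None:
            d["cell_pressure"] = np.asarray(self.cell_pressure, float).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            region_label=np.asarray(d["region_label"], dtype=object),
            orientation_target=np.asarray(d["orientation_target"], float),
            edge_tension=(
                np.asarray(d["edge_tension"], float) if "edge_tension" in d else None
            ),
            cell_pressure=(
                np.asarray(d["cell_pressure"], float) if "cell_pressure" in d else None
            ),
        )


# --------------------------------------------------------------------------
# Voronoi sheet
# --------------------------------------------------------------------------
def _sample_points_in(polygon: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    """Stratified (jittered-grid) sampling of n points inside the polygon.

    Plain uniform sampling carries long-wavelength density fluctuations that
    survive Lloyd relaxation and leave a spatially smooth cell-size field;
    one jittered point per grid stratum suppresses them, so cell area varies
    locally rather than in patches.
    """
    minx, miny, maxx, maxy = polygon.bounds
    # grid sized so that ~n strata fall inside the polygon
    step = float(np.sqrt(polygon.area / n))
    xs = np.arange(minx + step / 2, maxx, step)
    ys = np.arange(miny + step / 2, maxy, step)
    gx, gy = np.meshgrid(xs, ys)
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    jitter = rng.uniform(-step / 2, step / 2, size=centers.shape)
    cand = centers + jitter
    inside = np.array([polygon.contains(Point(p)) for p in cand])
    pts = cand[inside]
    if len(pts) > n:
        keep = rng.choice(len(pts), size=n, replace=False)
        pts = pts[np.sort(keep)]
    while len(pts) < n:
        extra = rng.uniform((minx, miny), (maxx, maxy), size=(n, 2))
        ok = np.array([polygon.contains(Point(p)) for p in extra])
        pts = np.vstack([pts, extra[ok]])[:n]
    return np.asarray(pts)


def _guard_points(polygon: Polygon, m: int = 64) -> np.ndarray:
    cx, cy = polygon.centroid.x, polygon.centroid.y
    minx, miny, maxx, maxy = polygon.bounds
    r = 3.0 * max(maxx - minx, maxy - miny)
    ang = np.linspace(0, 2 * np.pi, m, endpoint=False)
    return np.column_stack([cx + r * np.cos(ang), cy + r * np.sin(ang)])


def _clipped_regions(points: np.ndarray, domain: Polygon) -> list[Polygon]:
    """Voronoi cell of each point, clipped to the domain."""
    guards = _guard_points(domain)
    vor = Voronoi(np.vstack([points, guards]))
    polys = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            raise GeometryError("unbounded Voronoi region; guard ring too small")
        cell = Polygon(vor.vertices[region])
        clipped = cell.intersection(domain)
        if clipped.geom_type == "MultiPolygon":  # nonconvex domain edge case
            clipped = max(clipped.geoms, key=lambda g: g.area)
        if clipped.is_empty or clipped.area <= 0:
            raise GeometryError(f"seed point {i} produced an empty clipped cell")
        polys.append(clipped)
    return polys


def _mesh_from_polygons(polys: list[Polygon], sample_id: str,
                        merge_tol: float = 1e-9) -> Tessellation:
    """Merge polygon soup into a shared-vertex mesh.

    Coordinates of shared junctions agree to floating precision between
    adjacent clipped cells; a KD-tree union-find with a tiny tolerance snaps
    any last-ulp differences.
    """
    rings = []
    for poly in polys:
        ring = np.asarray(poly.exterior.coords[:-1], dtype=float)
        # enforce CCW
        x, y = ring[:, 0], ring[:, 1]
        if 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y) < 0:
            ring = ring[::-1]
        rings.append(ring)

    pts = np.vstack(rings)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=merge_tol, output_type="ndarray")
    parent = np.arange(len(pts))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    roots = np.array([find(i) for i in range(len(pts))])
    uniq, inverse = np.unique(roots, return_inverse=True)
    vertices = pts[uniq]

    cells = []
    k = 0
    for ring in rings:
        ids = [int(inverse[k + j]) for j in range(len(ring))]
        # drop consecutive duplicates created by snapping
        cyc = [ids[0]]
        for v in ids[1:]:
            if v != cyc[-1]:
                cyc.append(v)
        if cyc[-1] == cyc[0]:
            cyc.pop()
        if len(cyc) < 3:
            raise GeometryError("degenerate cell after vertex merging")
        cells.append(cyc)
        k += len(ring)

    edges = set()
    for cyc in cells:
        for j in range(len(cyc)):
            a, b = cyc[j], cyc[(j + 1) % len(cyc)]
            edges.add((min(a, b), max(a, b)))
    edges = np.array(sorted(edges), dtype=int)

    tess = Tessellation(
        vertices=vertices,
        edges=edges,
        cells=cells,
        cell_boundary_flag=np.zeros(len(cells), dtype=bool),
        sample_id=sample_id,
    )
    bflag = np.zeros(tess.n_cells, dtype=bool)
    for j, inc in enumerate(tess.edge_cells()):
        if len(inc) == 1:
            for i in inc:
                bflag[i] = True
    tess.cell_boundary_flag = bflag
    return tess


def generate_voronoi_sheet(
    domain: DomainSpec,
    n_cells: int,
    lloyd_iters: int = 3,
    seed: int = 0,
    sample_id: str | None = None,
) -> Tessellation:
    """Lloyd-relaxed clipped Voronoi tessellation of the domain.

    Each of the ``n_cells`` seed points yields exactly one clipped cell;
    ``lloyd_iters`` centroidal-relaxation sweeps regularize cell areas.
    Deterministic given ``seed``.
    """
    if n_cells < 16:
        raise ParameterError("n_cells must be at least 16")
    if lloyd_iters < 0:
        raise ParameterError("lloyd_iters must be non-negative")
    poly = domain.polygon()
    rng = np.random.default_rng(seed)
    points = _sample_points_in(poly, n_cells, rng)
    for _ in range(lloyd_iters):
        regions = _clipped_regions(points, poly)
        points = np.array([[r.centroid.x, r.centroid.y] for r in regions])
    regions = _clipped_regions(points, poly)
    sid = sample_id if sample_id is not None else f"synthetic-{seed}"
    tess = _mesh_from_polygons(regions, sid)
    # clean up the tiny sliver edges that Voronoi clipping leaves along the
    # domain boundary; they would degenerate under downstream deformation
    med = float(np.median(np.linalg.norm(
        tess.vertices[tess.edges[:, 1]] - tess.vertices[tess.edges[:, 0]],
        axis=1)))
    while True:
        cleaned, _ = _collapse_short_edges(
            tess, np.ones(tess.n_edges), 0.02 * med, allow_pinned=True
        )
        if cleaned is None:
            break
        tess = cleaned
    tess.validate()
    return tess


# --------------------------------------------------------------------------
# region pattern
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class RegionSpec:
    """A named region with an orientation target; membership by centroid.

    ``contains(x, y)`` is boundary-inclusive, and regions are evaluated in
    list order, so a centroid exactly on a shared boundary goes to the region
    listed first.  ``stretch`` is the area-preserving elongation factor of
    the regional pre-stretch along the target axis (1 = none).
    """

    name: str
    orientation_target: float  # axial degrees, 0 = LR axis
    polygon: Polygon = None
    stretch: float = 1.0

    def contains(self, x: float, y: float) -> bool:
        if self.polygon is None:  # catch-all
            return True
        return self.polygon.covers(Point(x, y))


def dpw_pattern(
    domain: DomainSpec,
    posterior_fraction: float = 0.4,
    anterior_angle: float = 45.0,
    posterior_angle: float = 90.0,
    anterior_stretch: float = 1.8,
    posterior_stretch: float = 2.0,
    tongue_width: float = 25.0,
) -> list[RegionSpec]:
    """The default DPW-like layout: bilateral anterior domains, posterior band
    with a midline tongue.

    Anterior-left cells target +``anterior_angle``, anterior-right cells the
    mirror angle, posterior cells ``posterior_angle`` (the AP axis); the
    posterior region extends anteriorly along the midline as a tongue of
    half-width ``tongue_width`` (AP-oriented cells reach the midline between
    the bilateral anterior populations, which alternate around the
    outflow-tract notch).  The embryonic left is at high x in this
    frontal-view frame.  The stretch factors emulate the regional pull toward
    the arterial/venous poles that elongates cells along their target axes.
    """
    y_split = domain.height * (1.0 - posterior_fraction)
    xc = domain.width / 2.0
    big = 10.0 * max(domain.width, domain.height)
    posterior = box(-big, y_split, big, big).union(
        box(xc - tongue_width, -big, xc + tongue_width, big)
    )
    ant_left = box(xc + tongue_width, -big, big, y_split)
    ant_right = box(-big, -big, xc - tongue_width, y_split)
    return [
        RegionSpec("posterior", posterior_angle, posterior, posterior_stretch),
        RegionSpec("anterior_left", anterior_angle, ant_left, anterior_stretch),
        RegionSpec("anterior_right", -anterior_angle, ant_right, anterior_stretch),
    ]


def apply_region_stretch(
    tess: Tessellation,
    pattern: list[RegionSpec],
    blend_width: float = 12.0,
    n_steps: int = 30,
) -> Tessellation:
    """Warp the mesh by the flow of a blended regional stretch field.

    Each region r contributes the traceless velocity L_r (p − c_r) with
    L_r = ln(s)·(n̂n̂ᵀ − m̂m̂ᵀ) (n̂ along the orientation target, m̂ ⊥ n̂, c_r
    the region centroid), so its pure flow is the area-preserving stretch by
    s along the target axis.  Vertices are advected through the softly
    blended field (weights decay over ``blend_width`` µm outside each region)
    with RK4 over unit pseudo-time.  Because the blended field is smooth, the
    flow map is a diffeomorphism: narrow blends cannot fold the mesh.  This
    emulates the regional tissue-scale pull that elongates cells along their
    target axes; the warped boundary is subsequently held by its elastic
    anchors the way the surrounding tissue holds the real sheet.
    """
    from shapely.geometry import MultiPoint
    from shapely.prepared import prep

    pos0 = tess.vertices
    hull = MultiPoint([tuple(p) for p in pos0]).convex_hull
    gens = []  # (L_r, c_r, prepared polygon or None)
    for region in pattern:
        if region.polygon is not None:
            clipped = region.polygon.intersection(hull)
            c = np.array([clipped.centroid.x, clipped.centroid.y])
        else:
            c = np.array([hull.centroid.x, hull.centroid.y])
        a = np.deg2rad(region.orientation_target)
        nhat = np.array([np.cos(a), np.sin(a)])
        mhat = np.array([-np.sin(a), np.cos(a)])
        L = np.log(region.stretch) * (np.outer(nhat, nhat) - np.outer(mhat, mhat))
        gens.append((L, c, region.polygon))

    tau = max(blend_width, 1e-9)

    def region_distance(poly, p):
        # analytic distance for rectangular regions, shapely fallback
        if poly is None:
            return np.zeros(len(p))
        if poly.geom_type == "Polygon" and len(poly.exterior.coords) == 5:
            minx, miny, maxx, maxy = poly.bounds
            corners = {(minx, miny), (minx, maxy), (maxx, miny), (maxx, maxy)}
            if set(map(tuple, poly.exterior.coords[:-1])) == corners:
                dx = np.maximum(np.maximum(minx - p[:, 0], p[:, 0] - maxx), 0.0)
                dy = np.maximum(np.maximum(miny - p[:, 1], p[:, 1] - maxy), 0.0)
                return np.hypot(dx, dy)
        return np.array([poly.distance(Point(q)) for q in p])

    # material weights: each vertex keeps the regional identity of where it
    # started, so cells do not switch generators while they are advected
    w = np.empty((len(gens), len(pos0)))
    for k, (_L, _c, poly) in enumerate(gens):
        w[k] = np.exp(-region_distance(poly, pos0) / tau)
    w /= w.sum(axis=0, keepdims=True)

    def velocity(p):
        v = np.zeros((len(gens), len(p), 2))
        for k, (L, c, _poly) in enumerate(gens):
            v[k] = (p - c) @ L.T
        return np.einsum("kn,knd->nd", w, v)

    pos = pos0.copy()
    h = 1.0 / n_steps
    for _ in range(n_steps):
        k1 = velocity(pos)
        k2 = velocity(pos + 0.5 * h * k1)
        k3 = velocity(pos + 0.5 * h * k2)
        k4 = velocity(pos + h * k3)
        pos = pos + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)

    out = Tessellation(pos, tess.edges.copy(), [list(c) for c in tess.cells],
                       tess.cell_boundary_flag.copy(), tess.sample_id)
    if np.any(out.cell_signed_areas() <= 0):
        raise GeometryError("regional stretch folded the mesh; increase "
                            "n_steps or blend_width")
    return out


def apply_dpw_stretch(
    tess: Tessellation,
    domain: DomainSpec,
    y_split: float,
    anterior_stretch: float = 1.8,
    posterior_stretch: float = 2.0,
    tongue_width: float = 25.0,
    tongue_compression: float = 2.0,
    tongue_elongation: float = 1.75,
    posterior_inflation: float = 1.08,
    border_width: float = 10.0,
    n_steps: int = 40,
) -> Tessellation:
    """Warp the sheet by the analytic DPW deformation.

    Two fold-free stages emulate the tissue-scale pull toward the arterial
    and venous poles:

    1. An RK4-integrated smooth flow (a diffeomorphism by construction)
       blending three local generators: a uniform area-preserving scaling
       diag(a, 1/a) in the bilateral anterior domains, an area-preserving
       stretch by ``posterior_stretch`` along the AP axis in the posterior
       band (blended over ``border_width`` µm around ``y_split``), and a pure
       x-compression by ``tongue_compression`` in the posterior midline
       tongue (half-width ``tongue_width``), which elongates tongue cells
       along the AP axis without displacing them axially.
    2. A closed-form vertical "deck of cards" shear y += k·S(x−xc) applied to
       the whole sheet outside the tongue.  x is never changed and the shift
       is y-independent, so the map cannot fold.  Composed with the anterior
       scaling, the shear leaves anterior cells elongated exactly along ±45°
       with axis ratio s² (k = (s⁴−1)/(s⁴+1), a = (1−k²)^(−1/4)); posterior
       cells, already stretched along the AP axis, end a few degrees off 90°
       laterally — the fan of the posterior region around the venous pole.
    """
    xc = domain.width / 2.0
    gp = float(np.log(posterior_stretch))
    # the boosted posterior/tongue tensions shrink those cells during
    # relaxation; a slight area inflation in the warp keeps regional mean
    # areas comparable, as in the tissue
    gpx = gp - float(np.log(posterior_inflation))
    gt = float(np.log(tongue_compression))
    gty = float(np.log(tongue_elongation))
    ya = y_split / 2.0  # anterior mid-height, center of the uniform scaling
    yt = (y_split + domain.notch_radius) / 2.0  # tongue mid-height

    s4 = float(anterior_stretch) ** 4
    k_shear = (s4 - 1.0) / (s4 + 1.0)
    alpha = -0.25 * float(np.log1p(-k_shear**2))  # ln a

    tw = max(tongue_width, 1e-9)

    def ant_weight(y):
        return 1.0 / (1.0 + np.exp(np.clip((y - y_split) / border_width, -50, 50)))

    def tongue_weight(x):
        return 1.0 / (1.0 + np.exp(np.clip((np.abs(x - xc) - tw) / (tw / 3.0),
                                           -50, 50)))

    def velocity(p):
        x, y = p[:, 0], p[:, 1]
        ant = ant_weight(y)
        m = tongue_weight(x)
        w_ant = ant * (1.0 - m)
        w_post = 1.0 - ant
        w_tongue = ant * m
        vx = (
            w_ant * alpha * (x - xc)
            - w_post * gpx * (x - xc)
            - w_tongue * gt * (x - xc)
        )
        vy = (
            w_ant * (-alpha) * (y - ya)
            + w_post * gp * (y - y_split)
            + w_tongue * gty * (y - yt)
        )
        return np.column_stack([vx, vy])

    pos = tess.vertices.copy()
    h = 1.0 / n_steps
    for _ in range(n_steps):
        k1 = velocity(pos)
        k2 = velocity(pos + 0.5 * h * k1)
        k3 = velocity(pos + 0.5 * h * k2)
        k4 = velocity(pos + h * k3)
        pos = pos + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)

    # stage 2: material shear, gated only in x (the tongue is spared)
    d = pos[:, 0] - xc
    soft = np.sqrt(d * d + (tw / 3.0) ** 2) - tw / 3.0
    pos = pos + np.column_stack(
        [np.zeros(len(pos)), k_shear * soft * (1.0 - tongue_weight(pos[:, 0]))]
    )

    out = Tessellation(pos, tess.edges.copy(), [list(c) for c in tess.cells],
                       tess.cell_boundary_flag.copy(), tess.sample_id)
    if np.any(out.cell_signed_areas() <= 0):
        raise GeometryError("stretch flow folded the mesh; increase n_steps")
    return out


def impose_region_pattern(tess: Tessellation, pattern: list[RegionSpec]) -> GroundTruth:
    """Assign region labels and orientation targets by cell centroid."""
    centroids = tess.cell_centroids()
    labels = np.empty(tess.n_cells, dtype=object)
    targets = np.empty(tess.n_cells, dtype=float)
    for i, (x, y) in enumerate(centroids):
        for region in pattern:
            if region.contains(x, y):
                labels[i] = region.name
                targets[i] = wrap_axial(region.orientation_target)
                break
        else:
            raise GeometryError(
                f"pattern does not cover centroid of cell {i} at ({x:.2f}, {y:.2f})"
            )
    return GroundTruth(region_label=labels, orientation_target=targets)


def randomize_pattern(truth: GroundTruth, seed: int = 0) -> GroundTruth:
    """Spatially scramble region labels (negative control).

    Cells keep the cohort-level label proportions but lose all spatial
    coherence; orientation targets move with their labels.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(truth.region_label))
    return replace(
        truth,
        region_label=truth.region_label[perm],
        orientation_target=truth.orientation_target[perm],
    )


# --------------------------------------------------------------------------
# forward mechanics
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class TensionModel:
    """Heterogeneous edge tensions with region-aligned anisotropy.

    base_cv: coefficient of variation of the log-normal tension noise.
    anisotropy_gain: tension boost of posterior edges aligned with the
        region's target axis — an edge at axial angle β in a region with
        orientation target α is multiplied by (1 + gain·cos²(β − α)).  With
        the sheet boundary pinned, the tense aligned junctions carry the
        excess stress, so both the principal stress direction and the cell
        elongation axis follow the target (for the posterior target α = 90°,
        stress and orientation along the AP axis).
    alignment_gain: same mechanism in the non-posterior (anterior) regions,
        weaker by default so anterior stress stays closer to isotropic.
    pressure_sd / pressure_max: zero-mean cell pressure perturbations, kept
        small so the sheet stays near a pure tension-network equilibrium.
    """

    base_cv: float = 0.2
    anisotropy_gain: float = 1.0
    alignment_gain: float = 0.3
    pressure_sd: float = 0.02
    pressure_max: float = 0.05
    area_stiffness: float = 1.0  # dimensionless; K = area_stiffness / mean cell area


def assign_mechanics(
    tess: Tessellation,
    truth: GroundTruth,
    tension_model: TensionModel = TensionModel(),
    seed: int = 0,
) -> GroundTruth:
    """Draw edge tensions and cell pressures; apply gauge normalisation.

    Tensions are log-normal with mean 1 and CV ``base_cv``, multiplied by the
    region-aligned anisotropy factor of :class:`TensionModel`; the boost of an
    edge between two regions is the average of the two cells' factors.
    Gauges: mean tension 1, mean pressure 0.  Deterministic given ``seed``.
    """
    tm = tension_model
    if tm.base_cv < 0 or tm.anisotropy_gain < 0 or tm.alignment_gain < 0:
        raise ParameterError("base_cv and gains must be non-negative")
    rng = np.random.default_rng(seed)

    if tm.base_cv == 0:
        tensions = np.ones(tess.n_edges)
    else:
        sigma2 = np.log1p(tm.base_cv**2)
        tensions = rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2),
                                 size=tess.n_edges)

    vec = tess.vertices[tess.edges[:, 1]] - tess.vertices[tess.edges[:, 0]]
    beta = np.rad2deg(np.arctan2(vec[:, 1], vec[:, 0]))  # axial up to mod 180

    gain_by_cell = np.where(
        np.asarray(truth.region_label) == "posterior",
        tm.anisotropy_gain,
        tm.alignment_gain,
    )
    factor = np.ones(tess.n_edges)
    for j, inc in enumerate(tess.edge_cells()):
        f = [
            1.0
            + gain_by_cell[i]
            * np.cos(np.deg2rad(beta[j] - truth.orientation_target[i])) ** 2
            for i in inc
        ]
        factor[j] = float(np.mean(f))
    tensions = tensions * factor
    tensions /= tensions.mean()

    pressures = rng.normal(0.0, tm.pressure_sd, size=tess.n_cells)
    np.clip(pressures, -tm.pressure_max, tm.pressure_max, out=pressures)
    pressures -= pressures.mean()

    return replace(truth, edge_tension=tensions, cell_pressure=pressures)


# --------------------------------------------------------------------------
# force evaluation and relaxation
# --------------------------------------------------------------------------
def vertex_forces(
    tess: Tessellation,
    tensions: np.ndarray,
    pressures: np.ndarray,
    vertices: np.ndarray | None = None,
) -> np.ndarray:
    """Net force on every vertex under the straight-edge tension/pressure model.

    Tension T_j pulls each endpoint of edge j toward the other along the edge;
    cell pressure P_i pushes each cell vertex outward with the lever-arm form
    P_i ∂A_i/∂p (equivalently P_i n̂ ℓ/2 per incident cell edge).
    """
    pos = tess.vertices if vertices is None else vertices
    n = len(pos)

    a, b = tess.edges[:, 0], tess.edges[:, 1]
    d = pos[b] - pos[a]
    ln = np.linalg.norm(d, axis=1)
    ln = np.where(ln < 1e-300, 1e-300, ln)
    u = d / ln[:, None]
    tu = tensions[:, None] * u

    flat, nxt, prv, owner = tess.cell_arrays()
    pw = pressures[owner]
    fx = (
        np.bincount(a, weights=tu[:, 0], minlength=n)
        - np.bincount(b, weights=tu[:, 0], minlength=n)
        + np.bincount(flat, weights=pw * 0.5 * (pos[nxt, 1] - pos[prv, 1]),
                      minlength=n)
    )
    fy = (
        np.bincount(a, weights=tu[:, 1], minlength=n)
        - np.bincount(b, weights=tu[:, 1], minlength=n)
        + np.bincount(flat, weights=pw * 0.5 * (pos[prv, 0] - pos[nxt, 0]),
                      minlength=n)
    )
    return np.column_stack([fx, fy])


def cell_areas(tess: Tessellation, vertices: np.ndarray | None = None) -> np.ndarray:
    """Signed areas of all cells (vectorized shoelace)."""
    pos = tess.vertices if vertices is None else vertices
    flat, nxt, _, owner = tess.cell_arrays()
    seg = pos[flat, 0] * pos[nxt, 1] - pos[nxt, 0] * pos[flat, 1]
    return 0.5 * np.bincount(owner, weights=seg, minlength=tess.n_cells)


def _live_pressures(tess, pos, K, A0):
    return -K * (cell_areas(tess, pos) - A0)


def _energy_and_grad(x, tess, tensions, K, A0, kbw, anchors):
    pos = x.reshape(-1, 2)
    a, b = tess.edges[:, 0], tess.edges[:, 1]
    ln = np.linalg.norm(pos[b] - pos[a], axis=1)
    areas = cell_areas(tess, pos)
    disp = pos - anchors
    energy = float(
        np.dot(tensions, ln)
        + 0.5 * K * np.sum((areas - A0) ** 2)
        + 0.5 * np.sum(kbw[:, None] * disp**2)
    )
    F = vertex_forces(tess, tensions, -K * (areas - A0), pos)
    F -= kbw[:, None] * disp
    return energy, -F.ravel()


def _collapse_short_edges(tess: Tessellation, tensions: np.ndarray, eps: float,
                          allow_pinned: bool = False):
    """Merge endpoints of edges shorter than ``eps`` (rosette formation).

    Returns (new_tess, new_tensions) or (None, None) if nothing collapsed.
    Heterogeneous tension generically drives some junctions through T1-type
    collapse; merging the endpoints lets the constrained equilibrium (a
    higher-valent vertex) satisfy force balance exactly.  Edges of triangular
    cells and fully pinned (boundary–boundary) edges are never collapsed.
    """
    pos = tess.vertices
    el = np.linalg.norm(pos[tess.edges[:, 1]] - pos[tess.edges[:, 0]], axis=1)
    bmask = tess.boundary_vertex_mask()
    ec = tess.edge_cells()
    v2c: list[set] = [set() for _ in range(tess.n_vertices)]
    for i, cyc in enumerate(tess.cells):
        for v in cyc:
            v2c[v].add(i)
    order = np.argsort(el)
    touched = set()
    locked_cells: set = set()  # one merge per cell and sweep, so no cell can
    # lose two edges at once and degenerate
    merges = []  # (survivor, removed)
    kept = np.ones(tess.n_edges, dtype=bool)
    for j in order:
        if el[j] >= eps:
            break
        a, b = int(tess.edges[j, 0]), int(tess.edges[j, 1])
        if a in touched or b in touched:
            continue
        if (v2c[a] | v2c[b]) & locked_cells:
            continue
        if bmask[a] and bmask[b] and not allow_pinned:
            continue  # both pinned; static edge
        if any(len(tess.cells[i]) <= 3 for i in ec[j]):
            continue  # collapsing a triangle side would degenerate the cell
        if (v2c[a] & v2c[b]) - set(ec[j]):
            continue  # a third cell touches both endpoints: merging would
            # pinch its cycle into a non-simple polygon
        survivor, removed = (a, b) if bmask[a] or not bmask[b] else (b, a)
        merges.append((survivor, removed, j))
        touched.update((a, b))
        locked_cells |= v2c[a] | v2c[b]
        kept[j] = False
    if not merges:
        return None, None

    new_pos = pos.copy()
    remap = np.arange(tess.n_vertices)
    for survivor, removed, _j in merges:
        remap[removed] = survivor
        if not bmask[survivor]:
            new_pos[survivor] = (pos[survivor] + pos[removed]) / 2.0

    cells = []
    for cyc in tess.cells:
        ids = [int(remap[v]) for v in cyc]
        out = [ids[0]]
        for v in ids[1:]:
            if v != out[-1]:
                out.append(v)
        if out[-1] == out[0]:
            out.pop()
        cells.append(out)

    tension_of: dict[tuple, list] = {}
    for (a, b), keep, t in zip(tess.edges, kept, tensions):
        if not keep:
            continue
        key = tuple(sorted((int(remap[a]), int(remap[b]))))
        tension_of.setdefault(key, []).append(float(t))
    # compact vertex indices (drop orphans) to preserve the Euler relation
    used = sorted({v for cyc in cells for v in cyc})
    newid = {v: k for k, v in enumerate(used)}
    vertices = new_pos[used]
    cells = [[newid[v] for v in cyc] for cyc in cells]
    edges = np.array(
        sorted((newid[a], newid[b]) for a, b in tension_of), dtype=int
    )
    new_T = np.array(
        [float(np.mean(tension_of[(used[a], used[b])])) for a, b in edges]
    )

    out = Tessellation(vertices, edges, cells,
                       np.zeros(len(cells), dtype=bool), tess.sample_id)
    bflag = np.zeros(out.n_cells, dtype=bool)
    for jj, inc in enumerate(out.edge_cells()):
        if len(inc) == 1:
            bflag[inc[0]] = True
    out.cell_boundary_flag = bflag
    return out, new_T


def _extrude_small_triangles(tess: Tessellation, tensions: np.ndarray,
                             eps_len: float):
    """T2 transition: remove triangular cells smaller than ~eps_len.

    A triangle squeezed below the collapse scale is extruded: its three
    vertices merge into one at the centroid, its three edges and the cell
    itself disappear (V−2, E−3, C−1 keeps the Euler relation).  Returns
    (new_tess, new_tensions, kept_cell_mask) or (None, None, None).
    Triangles touching the pinned boundary or another triangle are left
    alone.
    """
    pos = tess.vertices
    bmask = tess.boundary_vertex_mask()
    areas = tess.cell_signed_areas()
    ec = tess.edge_cells()
    v2c: list[set] = [set() for _ in range(tess.n_vertices)]
    for i, cyc in enumerate(tess.cells):
        for v in cyc:
            v2c[v].add(i)
    target = None
    for i, cyc in enumerate(tess.cells):
        if len(cyc) != 3 or abs(areas[i]) > eps_len**2 * 3.0:
            continue
        if any(bmask[v] for v in cyc):
            continue
        neighbor_tri = False
        for j in tess.cell_edge_ids(i):
            for other in ec[j]:
                if other != i and len(tess.cells[other]) <= 3:
                    neighbor_tri = True
        if neighbor_tri:
            continue
        # any cell touching two triangle vertices must share the joining
        # edge, otherwise merging would pinch its cycle
        edge_sharers = {i}
        for j in tess.cell_edge_ids(i):
            edge_sharers.update(ec[j])
        pinch = False
        for u, v in ((cyc[0], cyc[1]), (cyc[1], cyc[2]), (cyc[0], cyc[2])):
            if (v2c[u] & v2c[v]) - edge_sharers:
                pinch = True
        if pinch:
            continue
        target = i
        break
    if target is None:
        return None, None, None

    cyc = tess.cells[target]
    u = cyc[0]
    centroid = pos[cyc].mean(axis=0)
    remap = np.arange(tess.n_vertices)
    for v in cyc[1:]:
        remap[v] = u
    new_pos = pos.copy()
    new_pos[u] = centroid

    drop_edges = set(tess.cell_edge_ids(target))
    tension_of: dict[tuple, list] = {}
    for j, (a, b) in enumerate(tess.edges):
        if j in drop_edges:
            continue
        key = tuple(sorted((int(remap[a]), int(remap[b]))))
        tension_of.setdefault(key, []).append(float(tensions[j]))

    cells = []
    kept_cells = np.ones(tess.n_cells, dtype=bool)
    kept_cells[target] = False
    for i, c in enumerate(tess.cells):
        if i == target:
            continue
        ids = [int(remap[v]) for v in c]
        out = [ids[0]]
        for v in ids[1:]:
            if v != out[-1]:
                out.append(v)
        if out[-1] == out[0]:
            out.pop()
        cells.append(out)

    used = sorted({v for c in cells for v in c})
    newid = {v: k for k, v in enumerate(used)}
    vertices = new_pos[used]
    cells = [[newid[v] for v in c] for c in cells]
    edges = np.array(sorted((newid[a], newid[b]) for a, b in tension_of),
                     dtype=int)
    new_T = np.array(
        [float(np.mean(tension_of[(used[a], used[b])])) for a, b in edges]
    )
    out = Tessellation(vertices, edges, cells,
                       np.zeros(len(cells), dtype=bool), tess.sample_id)
    bflag = np.zeros(out.n_cells, dtype=bool)
    for jj, inc in enumerate(out.edge_cells()):
        if len(inc) == 1:
            bflag[inc[0]] = True
    out.cell_boundary_flag = bflag
    return out, new_T, kept_cells


def relax_to_equilibrium(
    tess: Tessellation,
    truth: GroundTruth,
    tol: float = 1e-4,
    max_iters: int = 20000,
    area_stiffness: float = 1.0,
    boundary_stiffness: float = 5.0,
    return_info: bool = False,
):
    """Relax the sheet to static force balance at every interior vertex.

    The forward model is the standard tension + area-elasticity vertex model:
    E = Σ T_j ℓ_j + (K/2) Σ (A_i − A₀_i)², with preferred areas A₀ chosen so
    that the requested ground-truth pressures emerge at the start
    (P_i = −K(A_i − A₀_i)); this energy is bounded below and coercive, so the
    equilibrium is a genuine minimum.  Boundary vertices are anchored to
    their input positions by stiff springs (``boundary_stiffness``, force per
    µm of displacement) standing in for the surrounding tissue; they carry no
    balance requirement.  Junctions driven to zero length undergo T1-type
    collapse (rosette formation) and vanishing triangles are extruded (T2),
    as in epithelial tissue.  L-BFGS minimization alternates with these
    topology moves, followed by a damped force-descent polish whose accepted
    steps have non-increasing residual.  The reported residual is the
    maximum per-interior-vertex force norm under the tension/pressure model.

    Returns ``(tessellation, ground_truth)`` where the ground truth carries
    the realized cell pressures (gauged to mean 0; the shift leaves every
    interior-vertex balance untouched) and drops extruded cells.  Raises
    :class:`EquilibrationError` on failure, carrying the final residual.
    """
    if truth.edge_tension is None or truth.cell_pressure is None:
        raise ParameterError("ground truth lacks tensions/pressures")

    A_init = cell_areas(tess)
    # K scaled by mean cell area so |P| ≈ area_stiffness × relative deviation
    K = area_stiffness / float(np.mean(A_init))
    A0 = A_init + truth.cell_pressure / K
    # floor the preferred areas: cells squeezed far below the typical size
    # push back instead of being crushed into degenerate slivers by their
    # neighbors' tension
    A0 = np.maximum(A0, 0.4 * float(np.median(A_init)))
    kb = boundary_stiffness

    def max_residual(cur, T, pos):
        interior = ~cur.boundary_vertex_mask()
        if not interior.any():
            return 0.0
        P = _live_pressures(cur, pos, K, A0)
        F = vertex_forces(cur, T, P, pos)
        return float(np.max(np.linalg.norm(F[interior], axis=1)))

    if np.isinf(tol):
        out = Tessellation(tess.vertices.copy(), tess.edges.copy(),
                           [list(c) for c in tess.cells],
                           tess.cell_boundary_flag.copy(), tess.sample_id)
        if return_info:
            return out, truth, {
                "residual": max_residual(tess, truth.edge_tension, tess.vertices),
                "iterations": 0, "history": [], "collapsed_edges": 0,
            }
        return out, truth

    cur = tess
    T = truth.edge_tension.copy()
    pos = tess.vertices.copy()
    eps = 0.02 * float(np.median(np.linalg.norm(
        pos[tess.edges[:, 1]] - pos[tess.edges[:, 0]], axis=1)))
    n_collapsed = 0
    history: list[float] = []
    it = 0

    def total_force(cur, pos, kbw, anchors):
        F = vertex_forces(cur, T, _live_pressures(cur, pos, K, A0), pos)
        F -= kbw[:, None] * (pos - anchors)
        return F

    def polish(cur, pos, kbw, anchors):
        # damped force-descent with monotone L2 norm of the total force
        nonlocal it
        F = total_force(cur, pos, kbw, anchors)
        l2 = float(np.linalg.norm(F))
        history.append(l2)
        step = 0.05
        while max_residual(cur, T, pos) > tol and it < max_iters:
            it += 1
            trial = pos + step * F
            Ft = total_force(cur, trial, kbw, anchors)
            l2t = float(np.linalg.norm(Ft))
            if l2t < l2:
                pos, F, l2 = trial, Ft, l2t
                history.append(l2)
                step *= 1.2
            else:
                step *= 0.5
                if step < 1e-14:
                    break
        return pos

    from shapely.geometry import Polygon as _ShPolygon

    cell_keep = np.ones(tess.n_cells, dtype=bool)
    released = np.zeros(tess.n_cells, dtype=bool)  # anchors freed near cells
    # that converged into twisted shapes, so they can untwist

    def spring_weights(cur):
        kbw = kb * cur.boundary_vertex_mask().astype(float)
        for i in np.flatnonzero(released):
            kbw[cur.cells[i]] = 0.0
        return kbw

    for attempt in range(8):
        for _round in range(40):
            kbw = spring_weights(cur)
            anchors = pos.copy()
            if max_residual(cur, T, pos) > tol:
                res = minimize(
                    _energy_and_grad,
                    pos.ravel(),
                    args=(cur, T, K, A0, kbw, anchors),
                    method="L-BFGS-B",
                    jac=True,
                    options={"maxiter": min(5000, max_iters), "gtol": 0.3 * tol,
                             "ftol": 1e-18, "maxfun": 10 * max_iters,
                             "maxcor": 25},
                )
                pos = res.x.reshape(-1, 2)
            cur = Tessellation(pos, cur.edges.copy(),
                               [list(c) for c in cur.cells],
                               cur.cell_boundary_flag.copy(), cur.sample_id)
            eps_now = eps * (1.5 ** min(attempt, 4))
            collapsed, new_T = _collapse_short_edges(cur, T, eps_now,
                                                     allow_pinned=True)
            if collapsed is not None:
                n_collapsed += cur.n_edges - collapsed.n_edges
                cur, T = collapsed, new_T
                pos = cur.vertices.copy()
                continue
            ex, exT, kept = _extrude_small_triangles(cur, T, 2.0 * eps_now)
            if ex is None:
                break
            alive = np.flatnonzero(cell_keep)
            cell_keep[alive[~kept]] = False
            A0 = A0[kept]
            released = released[kept]
            cur, T = ex, exT
            pos = cur.vertices.copy()
        cur = Tessellation(pos, cur.edges.copy(), [list(c) for c in cur.cells],
                           cur.cell_boundary_flag.copy(), cur.sample_id)
        pos = polish(cur, pos, spring_weights(cur), pos.copy())
        cur = Tessellation(pos, cur.edges.copy(), [list(c) for c in cur.cells],
                           cur.cell_boundary_flag.copy(), cur.sample_id)
        invalid = [
            i for i in range(cur.n_cells)
            if not _ShPolygon(cur.cell_polygon(i)).is_valid
        ]
        if invalid:
            released[invalid] = True
            continue
        if max_residual(cur, T, pos) <= tol:
            break
    interior = ~cur.boundary_vertex_mask()

    out = Tessellation(pos, cur.edges.copy(), [list(c) for c in cur.cells],
                       cur.cell_boundary_flag.copy(), cur.sample_id)
    P_real = _live_pressures(out, pos, K, A0)
    # gauges: tensions to mean 1 (pressures co-scaled; equilibrium is
    # invariant under joint scaling), pressures to mean 0 (the shift leaves
    # every interior-vertex balance untouched)
    scale = float(T.mean())
    T = T / scale
    P_real = P_real / scale - (P_real / scale).mean()
    Ffin = vertex_forces(out, T, P_real)
    Ffin[~interior] = 0.0
    final = float(np.max(np.linalg.norm(Ffin, axis=1))) if interior.any() else 0.0
    if final > tol:
        raise EquilibrationError(
            f"relaxation stalled at residual {final:.3e} > tol {tol:.3e}", final
        )
    if np.any(out.cell_signed_areas() <= 0) or any(
        not _ShPolygon(out.cell_polygon(i)).is_valid for i in range(out.n_cells)
    ):
        raise EquilibrationError("relaxation produced a non-simple cell", final)
    truth_out = replace(
        truth,
        region_label=np.asarray(truth.region_label)[cell_keep],
        orientation_target=np.asarray(truth.orientation_target)[cell_keep],
        edge_tension=T,
        cell_pressure=P_real,
    )
    if return_info:
        return out, truth_out, {"residual": final, "iterations": it,
                                "history": history,
                                "collapsed_edges": n_collapsed}
    return out, truth_out


# --------------------------------------------------------------------------
# one-call sample generation
# --------------------------------------------------------------------------
def generate_sample(
    seed: int,
    n_cells: int = 1600,
    domain: DomainSpec = DomainSpec(),
    pattern: list[RegionSpec] | None = None,
    tension_model: TensionModel = TensionModel(),
    lloyd_iters: int = 3,
    tol: float = 1e-4,
    randomize: bool = False,
    sample_id: str | None = None,
    max_retries: int = 3,
):
    """Generate one equilibrated DPW-like sample.

    Returns ``(tessellation, ground_truth)``.  With ``randomize=True`` the
    region labels (and their orientation targets) are spatially scrambled
    before mechanics are assigned — the negative control for all downstream
    pattern detection.

    A small fraction of random tessellations relaxes into a locally
    degenerate state under the regional deformation; those draws are
    discarded and regenerated from a deterministic offset of ``seed``
    (still fully reproducible), up to ``max_retries`` times.
    """
    last_err = None
    for retry in range(max_retries + 1):
        try:
            return _generate_sample_once(
                seed + 7919 * retry, n_cells, domain, pattern, tension_model,
                lloyd_iters, tol, randomize, sample_id,
            )
        except (EquilibrationError, GeometryError) as err:
            last_err = err
    raise last_err


def _generate_sample_once(
    seed, n_cells, domain, pattern, tension_model, lloyd_iters, tol,
    randomize, sample_id,
):
    tess = generate_voronoi_sheet(domain, n_cells, lloyd_iters, seed,
                                  sample_id=sample_id)
    if pattern is None:
        pattern = dpw_pattern(domain)
    truth = impose_region_pattern(tess, pattern)
    if randomize:
        # a scrambled pattern has no coherent regional pull: labels are
        # permuted and the tissue-scale stretch is omitted
        truth = randomize_pattern(truth, seed=seed + 1)
    elif any(r.stretch != 1.0 for r in pattern):
        by_name = {r.name: r for r in pattern}
        if set(by_name) == {"posterior", "anterior_left", "anterior_right"}:
            ant_left = by_name["anterior_left"]
            y_split = ant_left.polygon.bounds[3]
            tongue_w = ant_left.polygon.bounds[0] - domain.width / 2.0
            tess = apply_dpw_stretch(
                tess,
                domain,
                y_split=y_split,
                anterior_stretch=ant_left.stretch,
                posterior_stretch=by_name["posterior"].stretch,
                tongue_width=max(tongue_w, 1.0),
            )
        else:
            tess = apply_region_stretch(tess, pattern)
    truth = assign_mechanics(tess, truth, tension_model, seed=seed + 2)
    tess, truth = relax_to_equilibrium(
        tess, truth, tol=tol, area_stiffness=tension_model.area_stiffness
    )
    return tess, truth
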