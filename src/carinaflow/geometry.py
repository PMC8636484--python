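"""Parametric Y-bifurcation geometries and planar triangular meshing.

The fluid domain is the 2-D mid-plane of a symmetric Y-shaped vessel
bifurcation: a straight parent channel of width equal to the vessel
calibre that splits into two daughter channels of the same width, whose
centrelines open by the bifurcation angle ``alpha``.  The apex of the
wedge between the daughter branches (the *carina*) may be sharp or
filleted with a circular arc ("blunt").

All coordinates are SI metres.  The parent axis lies along ``+x``, the
geometry is mirror-symmetric about the x-axis and the carina apex sits
on the axis downstream of the junction.  Meshes are built by meshing the
upper half-domain (Delaunay on a graded point cloud, filtered to the
polygon) and mirroring it, so the final triangulation is exactly
symmetric — a property the flow solver's symmetry checks rely on.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import shapely
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import Polygon

__all__ = [
    "CrossSection",
    "BifurcationGeometry",
    "StraightChannel",
    "Mesh",
    "build_bifurcation",
    "build_straight_channel",
    "generate_mesh",
    "hydraulic_diameter",
    "mirror_node_map",
    "GeometryError",
]

_AXIS_TOL = 1e-12  # snap tolerance for points meant to lie on y = 0


class GeometryError(ValueError):
    """Invalid geometric parameters or a meshing failure."""


# ---------------------------------------------------------------------------
# Cross sections and hydraulic diameter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossSection:
    """Duct cross-section used for 3-D Reynolds diagnostics.

    Parameters
    ----------
    shape:
        ``"semicircle"`` (the vessel-like section, characteristic
        dimension = diameter of the full circle), ``"circle"``
        (dimension = diameter) or ``"rectangle"`` (dimensions =
        width, height).
    """

    shape: str
    dimensions: tuple[float, ...]

    def __post_init__(self):
        if self.shape not in ("semicircle", "circle", "rectangle"):
            raise GeometryError(f"unknown cross-section shape {self.shape!r}")
        if any(d <= 0 for d in self.dimensions):
            raise GeometryError("cross-section dimensions must be positive")
        n_expected = 2 if self.shape == "rectangle" else 1
        if len(self.dimensions) != n_expected:
            raise GeometryError(
                f"{self.shape} needs {n_expected} dimension(s), got {len(self.dimensions)}"
            )

    @property
    def area(self) -> float:
        if self.shape == "semicircle":
            r = self.dimensions[0] / 2.0
            return math.pi * r * r / 2.0
        if self.shape == "circle":
            r = self.dimensions[0] / 2.0
            return math.pi * r * r
        w, h = self.dimensions
        return w * h

    @property
    def wetted_perimeter(self) -> float:
        if self.shape == "semicircle":
            r = self.dimensions[0] / 2.0
            return math.pi * r + 2.0 * r
        if self.shape == "circle":
            return math.pi * self.dimensions[0]
        w, h = self.dimensions
        return 2.0 * (w + h)


def hydraulic_diameter(cross_section: CrossSection) -> float:
    """Hydraulic diameter ``D_h = 4 A / P`` of a duct cross-section.

    For the 2-mm semicircular vessel section this evaluates to
    ``1.222 mm``, the length scale entering the channel Reynolds number.
    """
    p = cross_section.wetted_perimeter
    if p <= 0:
        raise GeometryError("zero wetted perimeter")
    return 4.0 * cross_section.area / p


# ---------------------------------------------------------------------------
# Parametric geometries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BifurcationGeometry:
    """Symmetric planar Y-bifurcation.

    ``angle_deg`` is the full opening angle between the daughter
    centrelines; each daughter is inclined by ``angle_deg / 2`` from the
    parent axis.  ``calibre`` is both the parent width and the daughter
    width.  The carina apex (sharp case) lies at
    ``x = (calibre/2) / sin(angle/2)`` on the axis; daughter centrelines
    emanate from the origin.
    """

    angle_deg: float
    calibre: float
    parent_length: float
    branch_length: float
    carina_shape: str = "sharp"
    blunt_radius: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.angle_deg < 180.0:
            raise GeometryError(f"angle_deg must be in (0, 180), got {self.angle_deg}")
        if self.calibre <= 0:
            raise GeometryError("calibre must be positive")
        if self.parent_length < 5.0 * self.calibre or self.branch_length < 5.0 * self.calibre:
            raise GeometryError("parent/branch lengths must be >= 5 x calibre")
        if self.carina_shape not in ("sharp", "blunt"):
            raise GeometryError(f"carina_shape must be 'sharp' or 'blunt', got {self.carina_shape!r}")
        if self.carina_shape == "blunt":
            if not 0.0 < self.blunt_radius < self.calibre / 2.0:
                raise GeometryError("blunt_radius must lie in (0, calibre/2)")

    # -- derived frame quantities ------------------------------------------
    @property
    def half_angle(self) -> float:
        return math.radians(self.angle_deg) / 2.0

    @property
    def apex(self) -> np.ndarray:
        """Carina apex (sharp vertex position, also the blunt-arc wedge vertex)."""
        return np.array([(self.calibre / 2.0) / math.sin(self.half_angle), 0.0])

    @property
    def carina_point(self) -> np.ndarray:
        """Most upstream material point of the carina wall (apex or arc nose)."""
        if self.carina_shape == "sharp":
            return self.apex
        t = self.blunt_radius / math.sin(self.half_angle)
        centre_x = self.apex[0] + t
        return np.array([centre_x - self.blunt_radius, 0.0])

    def daughter_direction(self, branch: int) -> np.ndarray:
        s = 1.0 if branch == 1 else -1.0
        return np.array([math.cos(self.half_angle), s * math.sin(self.half_angle)])

    def outlet_centre(self, branch: int) -> np.ndarray:
        return self.branch_length * self.daughter_direction(branch)

    # -- boundary description ----------------------------------------------
    def _upper_half_loop(self, arc_pts: int = 24) -> list[tuple[str, np.ndarray]]:
        """Tagged boundary polylines of the upper half-domain, CCW.

        Tags: ``axis`` (symmetry line), ``inner_wall``, ``outlet_1``,
        ``outer_wall``, ``parent_wall``, ``inlet``.
        """
        w = self.calibre
        th = self.half_angle
        d = self.daughter_direction(1)
        n = np.array([-d[1], d[0]])
        apex = self.apex
        D = self.branch_length * d - (w / 2.0) * n    # outlet inner corner
        C = self.branch_length * d + (w / 2.0) * n    # outlet outer corner
        s_sh = (w / 2.0) * (1.0 - math.cos(th)) / math.sin(th)
        B = s_sh * d + (w / 2.0) * n                  # shoulder on parent top wall
        A = np.array([-self.parent_length, w / 2.0])
        inlet_bottom = np.array([-self.parent_length, 0.0])

        if self.carina_shape == "sharp":
            axis = np.array([inlet_bottom, apex])
            inner = np.array([apex, D])
        else:
            t = self.blunt_radius / math.sin(th)
            centre = apex + np.array([t, 0.0])
            nose = centre - np.array([self.blunt_radius, 0.0])
            # tangency point on the upper inner wall line through apex along d
            T = apex + (t * math.cos(th)) * d
            phi_T = math.atan2(T[1] - centre[1], T[0] - centre[0])
            phis = np.linspace(math.pi, phi_T, arc_pts)
            arc = centre + self.blunt_radius * np.column_stack([np.cos(phis), np.sin(phis)])
            arc[0] = nose
            axis = np.array([inlet_bottom, nose])
            inner = np.vstack([arc, D[None, :]])
        return [
            ("axis", axis),
            ("inner_wall", inner),
            ("outlet_1", np.array([D, C])),
            ("outer_wall", np.array([C, B])),
            ("parent_wall", np.array([B, A])),
            ("inlet", np.array([A, inlet_bottom])),
        ]

    def outline_segments(self) -> list[tuple[str, np.ndarray]]:
        """Full tagged outline, tags in {inlet, outlet_1, outlet_2, wall}."""
        upper = dict(self._upper_half_loop())

        def m(poly):  # mirror about the x-axis
            return poly * np.array([1.0, -1.0])

        inner_u = upper["inner_wall"]      # apex/arc nose -> D
        outer_u = upper["outer_wall"]      # C -> B (shoulder)
        parent_u = upper["parent_wall"]    # B -> A
        inlet_u = upper["inlet"]           # A -> (-Lp, 0)
        D, C = inner_u[-1], outer_u[0]
        return [
            ("wall", inner_u),
            ("outlet_1", np.array([D, C])),
            ("wall", outer_u),
            ("wall", parent_u),
            ("inlet", np.vstack([inlet_u, m(inlet_u)[::-1][1:]])),  # A -> axis -> A'
            ("wall", m(parent_u)[::-1]),
            ("wall", m(outer_u)[::-1]),
            ("outlet_2", np.array([m(C), m(D)])),
            ("wall", m(inner_u)[::-1]),
        ]

    def outline_polygon(self) -> Polygon:
        pts = [p for _tag, seg in self.outline_segments() for p in seg[:-1]]
        poly = Polygon(np.array(pts))
        if not poly.is_valid:
            raise GeometryError("geometry outline self-intersects")
        return shapely.geometry.polygon.orient(poly)

    # -- serialisation -----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "type": "bifurcation",
            "angle_deg": self.angle_deg,
            "calibre_m": self.calibre,
            "parent_length_m": self.parent_length,
            "branch_length_m": self.branch_length,
            "carina_shape": self.carina_shape,
            "blunt_radius_m": self.blunt_radius,
            "outline": [
                {"tag": tag, "points": poly.tolist()}
                for tag, poly in self.outline_segments()
            ],
        }
        return json.dumps(payload, indent=1)

    @staticmethod
    def from_json(text: str) -> "BifurcationGeometry":
        d = json.loads(text)
        return BifurcationGeometry(
            angle_deg=d["angle_deg"],
            calibre=d["calibre_m"],
            parent_length=d["parent_length_m"],
            branch_length=d["branch_length_m"],
            carina_shape=d["carina_shape"],
            blunt_radius=d["blunt_radius_m"],
        )


@dataclass(frozen=True)
class StraightChannel:
    """Straight 2-D channel (the degenerate no-bifurcation geometry).

    Used for solver validation against plane Poiseuille flow.  The inlet
    is at ``x = 0``, the single outlet (tagged ``outlet_1``) at
    ``x = length``; the channel is symmetric about the x-axis.
    """

    length: float
    width: float

    def __post_init__(self):
        if self.length <= 0 or self.width <= 0:
            raise GeometryError("length and width must be positive")

    calibre = property(lambda self: self.width)
    apex = None

    def _upper_half_loop(self) -> list[tuple[str, np.ndarray]]:
        L, w = self.length, self.width
        return [
            ("axis", np.array([[0.0, 0.0], [L, 0.0]])),
            ("outlet_1", np.array([[L, 0.0], [L, w / 2.0]])),
            ("parent_wall", np.array([[L, w / 2.0], [0.0, w / 2.0]])),
            ("inlet", np.array([[0.0, w / 2.0], [0.0, 0.0]])),
        ]

    def outline_segments(self) -> list[tuple[str, np.ndarray]]:
        L, w = self.length, self.width
        return [
            ("inlet", np.array([[0.0, -w / 2], [0.0, w / 2]])),
            ("wall", np.array([[0.0, w / 2], [L, w / 2]])),
            ("outlet_1", np.array([[L, w / 2], [L, -w / 2]])),
            ("wall", np.array([[L, -w / 2], [0.0, -w / 2]])),
        ]

    def outline_polygon(self) -> Polygon:
        L, w = self.length, self.width
        return Polygon([(0, -w / 2), (L, -w / 2), (L, w / 2), (0, w / 2)])


def build_bifurcation(angle_deg: float, calibre: float, parent_length: float,
                      branch_length: float, carina_shape: str = "sharp",
                      blunt_radius: float = 0.0) -> BifurcationGeometry:
    """Construct and validate a planar Y-bifurcation geometry."""
    return BifurcationGeometry(angle_deg, calibre, parent_length, branch_length,
                               carina_shape, blunt_radius)


def build_straight_channel(length: float, width: float) -> StraightChannel:
    return StraightChannel(length, width)


# ---------------------------------------------------------------------------
# Mesh
# ---------------------------------------------------------------------------

@dataclass
class Mesh:
    """Triangular mesh with tagged boundary edges.

    ``boundary_edges`` holds vertex index pairs of edges lying on the
    domain boundary; ``boundary_tags`` assigns exactly one tag (one of
    ``inlet``, ``outlet_1``, ``outlet_2``, ``wall``) to each.
    """

    points: np.ndarray            # (np, 2)
    triangles: np.ndarray         # (nt, 3), CCW
    boundary_edges: np.ndarray    # (nb, 2)
    boundary_tags: np.ndarray     # (nb,) str
    target_cell_size: float = 0.0
    wall_layers: int = 0
    geometry: object = field(default=None, repr=False)

    @property
    def num_cells(self) -> int:
        return len(self.triangles)

    def triangle_areas(self) -> np.ndarray:
        p = self.points
        a, b, c = (p[self.triangles[:, i]] for i in range(3))
        return 0.5 * ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                      - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1]))

    def cell_sizes(self) -> np.ndarray:
        """Per-cell size metric: square root of twice the cell area."""
        return np.sqrt(2.0 * self.triangle_areas())

    def boundary_edges_for(self, tag: str) -> np.ndarray:
        hits = self.boundary_edges[self.boundary_tags == tag]
        if len(hits) == 0:
            raise KeyError(f"no boundary edges tagged {tag!r}")
        return hits


# -- point-cloud helpers -----------------------------------------------------

def _resample_polyline(poly: np.ndarray, spacing_fn) -> np.ndarray:
    """March along a polyline placing points at locally-defined spacing."""
    seg = np.diff(poly, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    total = seg_len.sum()
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])

    def point_at(s):
        i = np.searchsorted(cum, s, side="right") - 1
        i = min(i, len(seg) - 1)
        f = (s - cum[i]) / seg_len[i] if seg_len[i] > 0 else 0.0
        return poly[i] + f * seg[i]

    out = [poly[0]]
    s = 0.0
    while True:
        h = spacing_fn(point_at(s))
        s_next = s + h
        if s_next >= total - 0.45 * h:
            break
        out.append(point_at(s_next))
        s = s_next
    out.append(poly[-1])
    return np.array(out)


def _hex_lattice(bbox, h) -> np.ndarray:
    (x0, y0), (x1, y1) = bbox
    dy = h * math.sqrt(3.0) / 2.0
    rows = []
    j = 0
    y = y0
    while y <= y1 + 1e-15:
        xs = np.arange(x0 + (0.5 * h if j % 2 else 0.0), x1 + 1e-15, h)
        rows.append(np.column_stack([xs, np.full_like(xs, y)]))
        y += dy
        j += 1
    return np.vstack(rows) if rows else np.empty((0, 2))


def _dedup(points: np.ndarray, min_dist: float, n_protected: int) -> np.ndarray:
    """Drop points closer than ``min_dist`` to an earlier point.

    The first ``n_protected`` points (boundary nodes) are never dropped.
    """
    tree = cKDTree(points)
    pairs = tree.query_pairs(min_dist, output_type="ndarray")
    drop = np.zeros(len(points), dtype=bool)
    order = np.argsort(pairs.max(axis=1))
    for i, j in pairs[order]:
        a, b = (i, j) if i < j else (j, i)
        if b < n_protected:
            continue
        if not drop[a]:
            drop[b] = True
    return points[~drop]


def generate_mesh(geometry, target_cell_size: float, wall_layers: int = 2,
                  apex_refine_factor: float = 3.0,
                  apex_refine_radius: Optional[float] = None) -> Mesh:
    """Triangulate a geometry's 2-D domain with an exactly symmetric mesh.

    The upper half-domain is covered with boundary points, near-wall
    offset layers, a graded hexagonal interior lattice and (for
    bifurcations) a refinement disc around the carina apex; a Delaunay
    triangulation filtered to the half-polygon is then mirrored about
    the x-axis.  ``target_cell_size`` is the nominal point spacing away
    from walls and apex.

    Raises
    ------
    GeometryError
        If ``target_cell_size`` exceeds ``calibre / 10`` or the outline
        self-intersects.
    """
    h = float(target_cell_size)
    w = geometry.calibre
    if h > w / 10.0 + 1e-15:
        raise GeometryError("target_cell_size must be <= calibre/10")

    apex = getattr(geometry, "apex", None)
    if apex_refine_radius is None:
        apex_refine_radius = 0.2 * w
    h_fine = h / apex_refine_factor

    def h_loc(p):
        if apex is None:
            return h
        r = math.hypot(p[0] - apex[0], p[1] - apex[1])
        if r < apex_refine_radius:
            return h_fine
        if r < 2.0 * apex_refine_radius:
            f = (r - apex_refine_radius) / apex_refine_radius
            return h_fine + f * (h - h_fine)
        return h

    loop = geometry._upper_half_loop()
    loop_pts = []
    for _tag, poly in loop:
        loop_pts.extend(poly[:-1])
    half_poly = Polygon(np.array(loop_pts))
    if not half_poly.is_valid:
        raise GeometryError("half-domain outline self-intersects")
    half_poly = shapely.geometry.polygon.orient(half_poly)

    # boundary points (protected in dedup), exact on the outline
    bnd_pts = []
    for tag, poly in loop:
        pts = _resample_polyline(poly, h_loc)[:-1]  # next segment supplies endpoint
        if tag == "axis":
            pts[:, 1] = 0.0
        bnd_pts.append(pts)
    bnd = np.vstack(bnd_pts)
    bnd[np.abs(bnd[:, 1]) < _AXIS_TOL, 1] = 0.0
    n_bnd = len(bnd)

    # wall offset layers (boundary-layer-style grading near no-slip walls)
    wall_polys = [poly for tag, poly in loop if tag.endswith("wall")]
    layer_pts = []
    boundary_ring = shapely.LineString(np.vstack([np.array(loop_pts), loop_pts[0]]))
    walls_ls = shapely.MultiLineString([ln.tolist() for ln in wall_polys])
    for k in range(1, wall_layers + 1):
        frac = k / (wall_layers + 1.0)
        for poly in wall_polys:
            # inward normal: domain interior is left of the CCW boundary
            base = _resample_polyline(poly, lambda p: max(h_loc(p), 1e-12))
            t = np.gradient(base, axis=0)
            t /= np.maximum(np.hypot(t[:, 0], t[:, 1])[:, None], 1e-300)
            normal = np.column_stack([-t[:, 1], t[:, 0]])
            cand = base + frac * np.array([h_loc(p) for p in base])[:, None] * normal
            layer_pts.append(cand)
    layers = np.vstack(layer_pts) if layer_pts else np.empty((0, 2))

    # interior lattice(s)
    minx, miny, maxx, maxy = half_poly.bounds
    coarse = _hex_lattice(((minx, max(miny, 0.0)), (maxx, maxy)), h)
    interior = [coarse]
    if apex is not None:
        fine = _hex_lattice((tuple(apex - 2 * apex_refine_radius),
                             tuple(apex + 2 * apex_refine_radius)), h_fine)
        r = np.hypot(fine[:, 0] - apex[0], fine[:, 1] - apex[1])
        interior.append(fine[r < 2.0 * apex_refine_radius])
        r = np.hypot(coarse[:, 0] - apex[0], coarse[:, 1] - apex[1])
        interior[0] = coarse[r >= 2.0 * apex_refine_radius]
    interior = np.vstack(interior)
    interior = interior[interior[:, 1] > 0.25 * h_fine]  # axis row comes from bnd

    # keep interior/layer points inside with clearance from the true boundary
    def filter_inside(pts, clearance_frac):
        if len(pts) == 0:
            return pts
        inside = shapely.contains_xy(half_poly, pts[:, 0], pts[:, 1])
        pts = pts[inside]
        if len(pts) == 0:
            return pts
        dist = shapely.distance(shapely.points(pts), boundary_ring)
        hh = np.array([h_loc(p) for p in pts])
        return pts[dist > clearance_frac * hh]

    clearance = (wall_layers + 0.55) / (wall_layers + 1.0)
    interior = filter_inside(interior, clearance)
    layers = filter_inside(layers, 0.45 / (wall_layers + 1.0))
    if len(layers):
        # layer points must hug walls only; drop any drifting near inlet/outlets
        d_wall = shapely.distance(shapely.points(layers), walls_ls)
        hh = np.array([h_loc(p) for p in layers])
        layers = layers[d_wall < 1.05 * hh * wall_layers / (wall_layers + 1.0)]

    pts = np.vstack([bnd, layers, interior])
    pts = _dedup(pts, 0.35 * h_fine if apex is not None else 0.35 * h, n_bnd)

    tri = Delaunay(pts)
    cent = pts[tri.simplices].mean(axis=1)
    keep = shapely.contains_xy(half_poly, cent[:, 0], cent[:, 1])
    simplices = tri.simplices[keep]
    if len(simplices) == 0:
        raise GeometryError("triangulation produced no interior cells")

    # drop unreferenced points, orient CCW
    used = np.unique(simplices)
    remap = -np.ones(len(pts), dtype=int)
    remap[used] = np.arange(len(used))
    half_points = pts[used]
    half_tris = remap[simplices]
    a = half_points[half_tris[:, 0]]
    b = half_points[half_tris[:, 1]]
    c = half_points[half_tris[:, 2]]
    area2 = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
    flip = area2 < 0
    half_tris[flip] = half_tris[flip][:, [0, 2, 1]]

    # ---- mirror about y = 0 (axis nodes were snapped to exactly 0) ----
    on_axis = np.abs(half_points[:, 1]) <= 1e-15
    n_half = len(half_points)
    mirror_idx = np.full(n_half, -1, dtype=int)
    mirror_idx[on_axis] = np.flatnonzero(on_axis)
    off = np.flatnonzero(~on_axis)
    mirror_idx[off] = n_half + np.arange(len(off))
    mirrored = half_points[off] * np.array([1.0, -1.0])
    points = np.vstack([half_points, mirrored])
    tris_lower = mirror_idx[half_tris][:, [0, 2, 1]]  # reflection flips orientation
    triangles = np.vstack([half_tris, tris_lower])

    # ---- boundary edges and tags ----
    edges = np.sort(np.vstack([triangles[:, [0, 1]], triangles[:, [1, 2]],
                               triangles[:, [2, 0]]]), axis=1)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    es = edges[order]
    dup_prev = np.zeros(len(es), dtype=bool)
    dup_prev[1:] = (es[1:] == es[:-1]).all(axis=1)
    dup_next = np.zeros(len(es), dtype=bool)
    dup_next[:-1] = dup_prev[1:]
    boundary = es[~(dup_prev | dup_next)]

    segs = geometry.outline_segments()
    seg_lines = [shapely.LineString(poly) for _t, poly in segs]
    seg_tags = [t for t, _p in segs]
    mids = shapely.points(0.5 * (points[boundary[:, 0]] + points[boundary[:, 1]]))
    dists = np.column_stack([shapely.distance(mids, ln) for ln in seg_lines])
    tags = np.array(seg_tags, dtype=object)[np.argmin(dists, axis=1)]

    return Mesh(points=points, triangles=triangles, boundary_edges=boundary,
                boundary_tags=tags.astype(str), target_cell_size=h,
                wall_layers=wall_layers, geometry=geometry)


def mirror_node_map(mesh: Mesh, tol: float = 1e-12) -> np.ndarray:
    """Index map sending each node to its mirror image about the x-axis.

    Exists by construction for meshes from :func:`generate_mesh`; raises
    ``GeometryError`` if the mesh is not point-symmetric.
    """
    tree = cKDTree(mesh.points)
    mirrored = mesh.points * np.array([1.0, -1.0])
    d, idx = tree.query(mirrored)
    if d.max() > tol + 1e-9 * np.abs(mesh.points).max():
        raise GeometryError("mesh is not mirror-symmetric")
    return idx
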