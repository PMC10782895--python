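"""Device geometry for the vascularized islet micro-organ (islet-VMO).

The islet-VMO is a microfluidic device in which a central tissue chamber,
loaded with fibrin hydrogel, islets, endothelial and stromal cells, is
flanked by two medium channels: C1 (functional arteriole) and C2
(functional venule).  Reservoirs V_A–V_D at the channel ends are filled to
different heights of medium, so flow is driven hydrostatically in a net
direction from V_A, through the living vessel network in the chamber, to
V_D.

This module holds the continuous geometric description (chamber rectangle,
channels, boundary ports, vessel skeleton graph with per-edge diameters,
islet discs), its validation, the rasterization onto a uniform labeled
grid used by the flow and transport solvers, and the skeleton
morphometrics used to characterize traced vessel networks (total length,
branch points, diameters sampled at fixed arclength intervals).

Conventions
-----------
* All lengths are micrometres unless a name says otherwise
  (``head_mm``).  Origin is at the chamber lower-left corner, x rightward,
  y upward.  The arteriole channel C1 sits below the chamber, the venule
  channel C2 above it.
* Raster cells are indexed ``(ix, iy)`` with cell centers at
  ``origin + ((ix + 0.5) h, (iy + 0.5) h)`` for spacing ``h`` (half-open
  cell ownership).
* The out-of-plane depth is uniform (single SU-8 layer, default 200 µm);
  the model is strictly two-dimensional.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree
from shapely import contains_xy
from shapely.geometry import LineString, box

# --------------------------------------------------------------------------
# Material labels
# --------------------------------------------------------------------------

WALL = 0
GEL = 1
ISLET = 2
LUMEN = 3

MATERIAL_NAMES = {WALL: "WALL", GEL: "GEL", ISLET: "ISLET", LUMEN: "LUMEN"}

#: maximum islet diameter admitted by the hand-selection rule (µm)
MAX_ISLET_DIAMETER_UM = 200.0

#: default out-of-plane device depth (µm), one SU-8 layer
DEFAULT_DEPTH_UM = 200.0

#: default node-merge tolerance for branch-point counting (µm)
DEFAULT_MERGE_TOL_UM = 10.0


class GeometryError(ValueError):
    """Raised when a device geometry violates its invariants."""


class ResolutionError(ValueError):
    """Raised when a raster spacing is too coarse for the geometry."""


class ParseError(ValueError):
    """Raised on malformed geometry documents; carries the failing field path."""

    def __init__(self, path: str, message: str):
        self.field_path = path
        super().__init__(f"{path}: {message}")


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PortSpec:
    """A medium reservoir port on the domain boundary.

    ``rect`` is a degenerate (zero-thickness) axis-aligned segment
    ``(x0, y0, x1, y1)`` lying on the boundary of the chamber+channel
    domain.  ``head_mm`` is the height of the medium column in the
    reservoir; a blocked port carries no flux regardless of head.
    """

    name: str
    rect: tuple[float, float, float, float]
    head_mm: float = 0.0
    blocked: bool = False

    def __post_init__(self):
        if self.head_mm < 0:
            raise GeometryError(f"port {self.name}: head must be >= 0")


@dataclass(frozen=True)
class VesselEdge:
    """One vessel segment: a polyline midline with a constant diameter."""

    nodes: tuple[int, int]
    polyline: np.ndarray  # (k, 2) float µm
    diameter_um: float

    def __post_init__(self):
        object.__setattr__(self, "polyline", np.asarray(self.polyline, dtype=float))
        if self.polyline.ndim != 2 or self.polyline.shape[1] != 2 or len(self.polyline) < 2:
            raise GeometryError("edge polyline must be an (k>=2, 2) array")
        if not self.diameter_um > 0:
            raise GeometryError("edge diameter must be > 0")

    @property
    def length(self) -> float:
        d = np.diff(self.polyline, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass
class VesselGraph:
    """Undirected multigraph of vessel midlines.

    ``nodes`` holds junction/endpoint positions; each edge's polyline runs
    from ``nodes[i]`` to ``nodes[j]``.
    """

    nodes: np.ndarray  # (N, 2) float µm
    edges: list[VesselEdge] = field(default_factory=list)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 2)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def validate(self, endpoint_tol: float = 1e-6) -> None:
        for k, e in enumerate(self.edges):
            i, j = e.nodes
            if not (0 <= i < len(self.nodes) and 0 <= j < len(self.nodes)):
                raise GeometryError(f"edge {k}: node index out of range")
            if np.linalg.norm(e.polyline[0] - self.nodes[i]) > endpoint_tol:
                raise GeometryError(f"edge {k}: polyline start does not coincide with node {i}")
            if np.linalg.norm(e.polyline[-1] - self.nodes[j]) > endpoint_tol:
                raise GeometryError(f"edge {k}: polyline end does not coincide with node {j}")
            if not LineString(e.polyline).is_simple:
                raise GeometryError(f"edge {k}: polyline self-intersects")


@dataclass
class IsletSet:
    """Islet discs: centers (µm) and diameters (µm)."""

    centers: np.ndarray  # (M, 2)
    diameters: np.ndarray  # (M,)

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        self.diameters = np.asarray(self.diameters, dtype=float).reshape(-1)
        if len(self.centers) != len(self.diameters):
            raise GeometryError("centers and diameters length mismatch")

    def __len__(self) -> int:
        return len(self.diameters)

    @property
    def radii(self) -> np.ndarray:
        return self.diameters / 2.0

    def validate(self) -> None:
        if len(self) == 0:
            return
        if np.any(self.diameters <= 0) or np.any(self.diameters >= MAX_ISLET_DIAMETER_UM):
            raise GeometryError(
                f"islet diameters must lie in (0, {MAX_ISLET_DIAMETER_UM}) µm "
                "(sub-200 µm hand-selection rule)"
            )
        # pairwise non-overlap
        if len(self) > 1:
            tree = cKDTree(self.centers)
            rmax = float(self.radii.max())
            for i, j in tree.query_pairs(2 * rmax):
                if (
                    np.linalg.norm(self.centers[i] - self.centers[j])
                    < self.radii[i] + self.radii[j]
                ):
                    raise GeometryError(f"islets {i} and {j} overlap")


def empty_vessels() -> VesselGraph:
    return VesselGraph(nodes=np.empty((0, 2)), edges=[])


def empty_islets() -> IsletSet:
    return IsletSet(centers=np.empty((0, 2)), diameters=np.empty((0,)))


@dataclass
class DeviceGeometry:
    """Complete continuous description of one islet-VMO device.

    The flow domain is the union of the chamber rectangle and the two
    channel rectangles; everything else is wall (PDMS/SU-8).
    """

    chamber_origin: tuple[float, float]
    chamber_width: float
    chamber_height: float
    depth: float
    channel_c1: tuple[float, float, float, float]  # (x0, y0, x1, y1)
    channel_c2: tuple[float, float, float, float]
    ports: list[PortSpec]
    vessels: VesselGraph = field(default_factory=empty_vessels)
    islets: IsletSet = field(default_factory=empty_islets)

    # -- geometry helpers ---------------------------------------------------

    @property
    def chamber_rect(self) -> tuple[float, float, float, float]:
        x0, y0 = self.chamber_origin
        return (x0, y0, x0 + self.chamber_width, y0 + self.chamber_height)

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        rects = [self.chamber_rect, self.channel_c1, self.channel_c2]
        x0 = min(r[0] for r in rects)
        y0 = min(r[1] for r in rects)
        x1 = max(r[2] for r in rects)
        y1 = max(r[3] for r in rects)
        return (x0, y0, x1, y1)

    def port(self, name: str) -> PortSpec:
        for p in self.ports:
            if p.name == name:
                return p
        raise KeyError(name)

    def with_ports(self, **updates: dict) -> "DeviceGeometry":
        """Return a copy with per-port field updates, e.g.
        ``with_ports(V_A={"head_mm": 5}, V_B={"blocked": True})``."""
        new_ports = []
        for p in self.ports:
            if p.name in updates:
                new_ports.append(replace(p, **updates[p.name]))
            else:
                new_ports.append(p)
        return replace(self, ports=new_ports)

    def validate(self) -> None:
        if not (self.chamber_width > 0 and self.chamber_height > 0 and self.depth > 0):
            raise GeometryError("chamber dimensions and depth must be > 0")
        domain = self._domain_polygon()
        cx0, cy0, cx1, cy1 = self.chamber_rect
        self.islets.validate()
        for k in range(len(self.islets)):
            x, y = self.islets.centers[k]
            if not (cx0 < x < cx1 and cy0 < y < cy1):
                raise GeometryError(f"islet {k}: center outside chamber")
        self.vessels.validate()
        for k, e in enumerate(self.vessels.edges):
            line = LineString(e.polyline)
            if not domain.buffer(1e-6).contains(line):
                raise GeometryError(f"vessel edge {k}: polyline leaves chamber+channel domain")
        bx0, by0, bx1, by1 = self.bbox
        for p in self.ports:
            x0, y0, x1, y1 = p.rect
            on_boundary = (
                math.isclose(x0, x1) and (math.isclose(x0, bx0) or math.isclose(x0, bx1))
            ) or (math.isclose(y0, y1) and (math.isclose(y0, by0) or math.isclose(y0, by1)))
            if not on_boundary:
                raise GeometryError(f"port {p.name}: rect not on the domain boundary")

    def _domain_polygon(self):
        return box(*self.chamber_rect).union(box(*self.channel_c1)).union(box(*self.channel_c2))


# --------------------------------------------------------------------------
# Default device shell
# --------------------------------------------------------------------------


def default_shell(
    chamber_width: float = 6000.0,
    chamber_height: float = 2000.0,
    depth: float = DEFAULT_DEPTH_UM,
    channel_width: float = 200.0,
    head_va_mm: float = 10.0,
    gsis_mode: bool = True,
) -> DeviceGeometry:
    """Default device: chamber with channels C1 (bottom) / C2 (top) along
    the long sides and ports V_A, V_B (ends of C1) and V_C, V_D (ends of C2).

    In GSIS mode V_B and V_C are blocked so all perfusate crosses the
    tissue chamber from arteriole to venule; V_A carries the driving head
    and V_D is the collection outlet at zero head.
    """
    w, h, cw = chamber_width, chamber_height, channel_width
    c1 = (0.0, -cw, w, 0.0)
    c2 = (0.0, h, w, h + cw)
    ports = [
        PortSpec("V_A", (0.0, -cw, 0.0, 0.0), head_mm=head_va_mm, blocked=False),
        PortSpec("V_B", (w, -cw, w, 0.0), head_mm=0.0, blocked=gsis_mode),
        PortSpec("V_C", (0.0, h, 0.0, h + cw), head_mm=0.0, blocked=gsis_mode),
        PortSpec("V_D", (w, h, w, h + cw), head_mm=0.0, blocked=False),
    ]
    return DeviceGeometry(
        chamber_origin=(0.0, 0.0),
        chamber_width=w,
        chamber_height=h,
        depth=depth,
        channel_c1=c1,
        channel_c2=c2,
        ports=ports,
    )


# --------------------------------------------------------------------------
# Rasterization
# --------------------------------------------------------------------------


@dataclass
class LabeledGrid:
    """Uniform material raster of a device.

    ``labels[ix, iy]`` is one of WALL/GEL/ISLET/LUMEN; ``islet_id`` maps
    each ISLET cell to the index of its islet (-1 elsewhere).  ``origin``
    is the position of the lower-left corner of cell (0, 0).
    """

    spacing: float
    origin: tuple[float, float]
    labels: np.ndarray  # (nx, ny) int8
    islet_id: np.ndarray  # (nx, ny) int32, -1 where not islet
    depth: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nx, ny = self.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.spacing
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.spacing
        return xs, ys

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        ix = int(math.floor((x - self.origin[0]) / self.spacing))
        iy = int(math.floor((y - self.origin[1]) / self.spacing))
        return ix, iy

    def label_at(self, x: float, y: float) -> int:
        ix, iy = self.cell_of(x, y)
        nx, ny = self.shape
        if not (0 <= ix < nx and 0 <= iy < ny):
            raise GeometryError(f"point ({x}, {y}) outside raster domain")
        return int(self.labels[ix, iy])

    def cell_area_um2(self) -> float:
        return self.spacing**2

    def cell_volume_m3(self) -> float:
        # spacing² (µm²) × depth (µm) → m³
        return self.spacing * self.spacing * self.depth * 1e-18


def _paint_rect(labels, origin, spacing, rect, value, only_over=None):
    x0, y0, x1, y1 = rect
    nx, ny = labels.shape
    ix0 = max(0, int(np.floor((x0 - origin[0]) / spacing + 0.5)))
    ix1 = min(nx, int(np.floor((x1 - origin[0]) / spacing + 0.5)))
    iy0 = max(0, int(np.floor((y0 - origin[1]) / spacing + 0.5)))
    iy1 = min(ny, int(np.floor((y1 - origin[1]) / spacing + 0.5)))
    if only_over is None:
        labels[ix0:ix1, iy0:iy1] = value
    else:
        block = labels[ix0:ix1, iy0:iy1]
        block[np.isin(block, only_over)] = value


def rasterize(geometry: DeviceGeometry, spacing: float) -> LabeledGrid:
    """Rasterize a device onto a uniform grid of the given spacing (µm).

    Cell ownership is by cell center.  Label precedence (low to high):
    WALL < GEL < ISLET < LUMEN — vessels stay open where a midline strip
    clips an islet boundary, because lumenized vessels do not penetrate
    islet tissue and flow integrity comes first.  Vessel strips are
    clipped to the chamber+channel domain.
    """
    geometry.validate()
    if geometry.vessels.n_edges:
        dmin = min(e.diameter_um for e in geometry.vessels.edges)
        if spacing > dmin / 2.0 + 1e-9:
            raise ResolutionError(
                f"spacing {spacing} µm too coarse for minimum vessel diameter {dmin} µm "
                "(require spacing <= diameter/2)"
            )
    bx0, by0, bx1, by1 = geometry.bbox
    nx = int(round((bx1 - bx0) / spacing))
    ny = int(round((by1 - by0) / spacing))
    origin = (bx0, by0)
    labels = np.full((nx, ny), WALL, dtype=np.int8)
    islet_id = np.full((nx, ny), -1, dtype=np.int32)

    _paint_rect(labels, origin, spacing, geometry.chamber_rect, GEL)
    _paint_rect(labels, origin, spacing, geometry.channel_c1, LUMEN)
    _paint_rect(labels, origin, spacing, geometry.channel_c2, LUMEN)

    xs, ys = (
        origin[0] + (np.arange(nx) + 0.5) * spacing,
        origin[1] + (np.arange(ny) + 0.5) * spacing,
    )

    # islets over gel
    for k in range(len(geometry.islets)):
        cx, cy = geometry.islets.centers[k]
        r = geometry.islets.radii[k]
        ix0 = max(0, int((cx - r - origin[0]) / spacing) - 1)
        ix1 = min(nx, int((cx + r - origin[0]) / spacing) + 2)
        iy0 = max(0, int((cy - r - origin[1]) / spacing) - 1)
        iy1 = min(ny, int((cy + r - origin[1]) / spacing) + 2)
        X, Y = np.meshgrid(xs[ix0:ix1], ys[iy0:iy1], indexing="ij")
        inside = (X - cx) ** 2 + (Y - cy) ** 2 <= r * r
        block = labels[ix0:ix1, iy0:iy1]
        paint = inside & (block == GEL)
        block[paint] = ISLET
        islet_id[ix0:ix1, iy0:iy1][paint] = k

    # vessel lumen strips over everything but wall
    for e in geometry.vessels.edges:
        r = e.diameter_um / 2.0
        poly = LineString(e.polyline).buffer(r, cap_style="round")
        px0, py0, px1, py1 = poly.bounds
        ix0 = max(0, int((px0 - origin[0]) / spacing) - 1)
        ix1 = min(nx, int((px1 - origin[0]) / spacing) + 2)
        iy0 = max(0, int((py0 - origin[1]) / spacing) - 1)
        iy1 = min(ny, int((py1 - origin[1]) / spacing) + 2)
        if ix1 <= ix0 or iy1 <= iy0:
            continue
        X, Y = np.meshgrid(xs[ix0:ix1], ys[iy0:iy1], indexing="ij")
        inside = contains_xy(poly, X.ravel(), Y.ravel()).reshape(X.shape)
        block = labels[ix0:ix1, iy0:iy1]
        paint = inside & (block != WALL)
        block[paint] = LUMEN
        islet_id[ix0:ix1, iy0:iy1][paint] = -1

    return LabeledGrid(
        spacing=spacing, origin=origin, labels=labels, islet_id=islet_id, depth=geometry.depth
    )


# --------------------------------------------------------------------------
# Morphometrics
# --------------------------------------------------------------------------


def total_vessel_length(vessels: VesselGraph) -> float:
    """Total network length (µm): sum of polyline arclengths over all edges."""
    return float(sum(e.length for e in vessels.edges))


def count_branch_points(
    vessels: VesselGraph, merge_tol: float = DEFAULT_MERGE_TOL_UM
) -> int:
    """Number of branch points: nodes of degree >= 3 after merging nodes
    closer than ``merge_tol`` (traced junctions are imprecise)."""
    n = len(vessels.nodes)
    if n == 0:
        return 0
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    tree = cKDTree(vessels.nodes)
    for i, j in tree.query_pairs(merge_tol):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    degree: dict[int, int] = {}
    for e in vessels.edges:
        for v in e.nodes:
            r = find(v)
            degree[r] = degree.get(r, 0) + 1
    return int(sum(1 for d in degree.values() if d >= 3))


def sample_diameters(
    vessels: VesselGraph, interval: float = 50.0
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Diameters sampled along each edge at arclength 0, interval, 2·interval, …
    strictly below the edge length (half-open convention; an edge shorter
    than the interval yields a single sample at position 0).

    Returns (pooled samples, per-edge samples).
    """
    if interval <= 0:
        raise ValueError("interval must be > 0")
    per_edge: list[np.ndarray] = []
    for e in vessels.edges:
        n = len(np.arange(0.0, max(e.length, 1e-12), interval))
        n = max(n, 1)
        per_edge.append(np.full(n, e.diameter_um))
    pooled = np.concatenate(per_edge) if per_edge else np.empty((0,))
    return pooled, per_edge


def network_stats(
    vessels: VesselGraph,
    merge_tol: float = DEFAULT_MERGE_TOL_UM,
    interval: float = 50.0,
) -> dict:
    """Summary morphometrics: total length, branch count, diameter mean/SD."""
    pooled, _ = sample_diameters(vessels, interval)
    return {
        "total_length_um": total_vessel_length(vessels),
        "n_branch_points": count_branch_points(vessels, merge_tol),
        "diameter_mean_um": float(pooled.mean()) if len(pooled) else float("nan"),
        "diameter_sd_um": float(pooled.std(ddof=1)) if len(pooled) > 1 else float("nan"),
        "n_diameter_samples": int(len(pooled)),
    }


# --------------------------------------------------------------------------
# Geometry JSON I/O
# --------------------------------------------------------------------------


def _req(d: dict, key: str, path: str):
    if not isinstance(d, dict) or key not in d:
        raise ParseError(f"{path}.{key}" if path else key, "missing required field")
    return d[key]


def geometry_to_dict(g: DeviceGeometry) -> dict:
    return {
        "chamber": {
            "origin": list(g.chamber_origin),
            "width": g.chamber_width,
            "height": g.chamber_height,
            "depth": g.depth,
        },
        "channels": {"C1": list(g.channel_c1), "C2": list(g.channel_c2)},
        "ports": [
            {"name": p.name, "rect": list(p.rect), "head_mm": p.head_mm, "blocked": p.blocked}
            for p in g.ports
        ],
        "vessels": {
            "nodes": g.vessels.nodes.tolist(),
            "edges": [
                {
                    "nodes": list(e.nodes),
                    "polyline": e.polyline.tolist(),
                    "diameter_um": e.diameter_um,
                }
                for e in g.vessels.edges
            ],
        },
        "islets": [
            {"center": g.islets.centers[k].tolist(), "diameter_um": float(g.islets.diameters[k])}
            for k in range(len(g.islets))
        ],
    }


def geometry_from_dict(doc: dict) -> DeviceGeometry:
    ch = _req(doc, "chamber", "")
    channels = _req(doc, "channels", "")
    ports_doc = _req(doc, "ports", "")
    vessels_doc = _req(doc, "vessels", "")
    islets_doc = _req(doc, "islets", "")
    try:
        ports = [
            PortSpec(
                name=_req(p, "name", f"ports[{i}]"),
                rect=tuple(_req(p, "rect", f"ports[{i}]")),
                head_mm=float(_req(p, "head_mm", f"ports[{i}]")),
                blocked=bool(_req(p, "blocked", f"ports[{i}]")),
            )
            for i, p in enumerate(ports_doc)
        ]
        nodes = np.asarray(_req(vessels_doc, "nodes", "vessels"), dtype=float).reshape(-1, 2)
        edges = [
            VesselEdge(
                nodes=tuple(_req(e, "nodes", f"vessels.edges[{i}]")),
                polyline=np.asarray(_req(e, "polyline", f"vessels.edges[{i}]"), dtype=float),
                diameter_um=float(_req(e, "diameter_um", f"vessels.edges[{i}]")),
            )
            for i, e in enumerate(vessels_doc.get("edges", []))
        ]
        islets = IsletSet(
            centers=np.asarray(
                [_req(s, "center", f"islets[{i}]") for i, s in enumerate(islets_doc)], dtype=float
            ).reshape(-1, 2),
            diameters=np.asarray(
                [_req(s, "diameter_um", f"islets[{i}]") for i, s in enumerate(islets_doc)],
                dtype=float,
            ),
        )
        return DeviceGeometry(
            chamber_origin=tuple(_req(ch, "origin", "chamber")),
            chamber_width=float(_req(ch, "width", "chamber")),
            chamber_height=float(_req(ch, "height", "chamber")),
            depth=float(_req(ch, "depth", "chamber")),
            channel_c1=tuple(_req(channels, "C1", "channels")),
            channel_c2=tuple(_req(channels, "C2", "channels")),
            ports=ports,
            vessels=VesselGraph(nodes=nodes, edges=edges),
            islets=islets,
        )
    except ParseError:
        raise
    except (TypeError, ValueError) as err:
        raise ParseError("<document>", str(err)) from err


def write_geometry(geometry: DeviceGeometry, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(geometry_to_dict(geometry), fh, indent=1)


def read_geometry(path) -> DeviceGeometry:
    with open(path, "r", encoding="utf-8") as fh:
        return geometry_from_dict(json.load(fh))


# --------------------------------------------------------------------------
# SWC-style skeleton import
# --------------------------------------------------------------------------


def read_swc_skeleton(path) -> VesselGraph:
    """Import a traced skeleton from SWC-style records
    ``id type x y z radius parent`` (whitespace-separated, ``#`` comments,
    z ignored, parent -1 for roots).  Each parent link becomes one edge
    whose diameter is the mean of the two endpoint diameters."""
    ids: list[int] = []
    pos: dict[int, np.ndarray] = {}
    rad: dict[int, float] = {}
    par: dict[int, int] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 7:
                raise ParseError(f"line {lineno}", "expected 7 whitespace-separated fields")
            nid = int(parts[0])
            ids.append(nid)
            pos[nid] = np.array([float(parts[2]), float(parts[3])])
            rad[nid] = float(parts[5])
            par[nid] = int(parts[6])
    index = {nid: k for k, nid in enumerate(ids)}
    nodes = np.array([pos[nid] for nid in ids]).reshape(-1, 2)
    edges = []
    for nid in ids:
        p = par[nid]
        if p == -1:
            continue
        if p not in index:
            raise ParseError(f"record {nid}", f"parent {p} not defined")
        i, j = index[p], index[nid]
        edges.append(
            VesselEdge(
                nodes=(i, j),
                polyline=np.array([nodes[i], nodes[j]]),
                diameter_um=rad[par[nid]] + rad[nid],  # mean radius × 2
            )
        )
    return VesselGraph(nodes=nodes, edges=edges)
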