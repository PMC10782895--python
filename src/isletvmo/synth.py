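"""Synthetic islet-VMO data generators.

Real devices are characterized by traced FITC-dextran vessel skeletons,
hand-selected islet loadings and segmented microscopy point sets, none of
which ship with this package.  The generators here emulate those inputs
statistically so every downstream stage — flow, transport, GSIS,
quantification — runs end to end on data with known ground truth:

* :func:`generate_network` grows a planar capillary-bed-like skeleton
  spanning the arteriole channel C1 to the venule channel C2, with
  lognormal edge diameters and controllable total length / branch count.
* :func:`generate_islets` emulates hydrogel loading at 20–25 islets µl⁻¹
  with the sub-200 µm hand-selection size filter (lognormal diameters,
  truncated mean calibrated to the observed ≈88 µm cohort mean).
* :func:`generate_pbmc_scene` and :func:`generate_deadlive_scene` build
  labeled point scenes (immune-cell positions, live/dead nuclei) with
  truth labels valid by construction, used to exercise the quantification
  procedures.

All generators are pure functions of (seed, parameters): identical seeds
give bitwise-identical outputs.  Independent sub-streams are split per
purpose (positions vs diameters) so, e.g., requesting more islets does not
perturb the diameters already drawn.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import Delaunay
from shapely.geometry import LineString, Point

from .geometry import (
    LUMEN,
    WALL,
    DeviceGeometry,
    IsletSet,
    LabeledGrid,
    VesselEdge,
    VesselGraph,
    default_shell,
)

MAX_REJECTION_RETRIES = 10_000


class GenerationError(RuntimeError):
    """Raised when rejection sampling cannot satisfy the constraints."""


def _rng(seed: int, purpose: int) -> np.random.Generator:
    """Deterministic sub-stream: one generator per (seed, purpose) pair."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(purpose)]))


# --------------------------------------------------------------------------
# Vessel network generator
# --------------------------------------------------------------------------


@dataclass
class NetworkGenParams:
    """Targets and knobs for the synthetic vessel skeleton.

    Total length and branch count are generation targets hit
    approximately (±15% over seeds); diameters are lognormal on the µm
    scale, clipped to the physiological (5, 150) µm window.  The defaults
    are mutually consistent on the default chamber: growing the network
    to the length target yields the branch target.
    """

    seed: int = 0
    target_total_length: float = 25_000.0  # µm
    branch_density: float = 1.33  # branch points per mm² of chamber
    diameter_log_mean: float = 3.55  # ln µm; exp(3.55) ≈ 35 µm
    diameter_log_sd: float = 0.22
    diameter_min: float = 25.0  # µm, capillary floor (also bounds raster spacing)
    diameter_max: float = 150.0  # µm
    lattice_spacing: float = 400.0  # µm, candidate-node lattice
    jitter_frac: float = 0.30  # node jitter as fraction of lattice spacing
    n_backbone: int = 4  # guaranteed C1→C2 crossing paths
    max_edge_factor: float = 2.2  # drop Delaunay edges longer than this × lattice


def generate_network(params: NetworkGenParams, geometry_shell: DeviceGeometry) -> VesselGraph:
    """Grow a synthetic vessel skeleton across the tissue chamber.

    Candidate nodes are a jittered lattice plus anchor nodes on the
    C1/C2 chamber interfaces; candidate edges come from a Delaunay
    triangulation.  A backbone of shortest C1→C2 paths guarantees
    perfusability, then shuffled candidate edges touching the growing
    network are added until the total-length target is reached.
    """
    cx0, cy0, cx1, cy1 = geometry_shell.chamber_rect
    rng_pos = _rng(params.seed, 1)
    rng_dia = _rng(params.seed, 2)

    s = params.lattice_spacing
    margin = 0.4 * s
    gx = np.arange(cx0 + margin, cx1 - margin + 1e-9, s)
    gy = np.arange(cy0 + margin, cy1 - margin + 1e-9, s)
    X, Y = np.meshgrid(gx, gy, indexing="ij")
    interior = np.column_stack([X.ravel(), Y.ravel()])
    interior = interior + rng_pos.uniform(
        -params.jitter_frac * s, params.jitter_frac * s, interior.shape
    )
    interior[:, 0] = np.clip(interior[:, 0], cx0 + 20.0, cx1 - 20.0)
    interior[:, 1] = np.clip(interior[:, 1], cy0 + 20.0, cy1 - 20.0)

    anchor_x = np.arange(cx0 + 0.75 * s, cx1 - 0.25 * s, 1.5 * s)
    bottom = np.column_stack([anchor_x, np.full_like(anchor_x, cy0)])
    top = np.column_stack([anchor_x, np.full_like(anchor_x, cy1)])
    nodes = np.vstack([interior, bottom, top])
    n_int = len(interior)
    bottom_ids = list(range(n_int, n_int + len(bottom)))
    top_ids = list(range(n_int + len(bottom), len(nodes)))

    tri = Delaunay(nodes)
    cand: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            if i > j:
                i, j = j, i
            cand.add((i, j))
    boundary = set(bottom_ids) | set(top_ids)
    max_len = params.max_edge_factor * s
    cand_list = []
    for i, j in sorted(cand):
        if i in boundary and j in boundary:
            continue  # no edges running along a channel interface
        if np.linalg.norm(nodes[i] - nodes[j]) <= max_len:
            cand_list.append((i, j))

    G = nx.Graph()
    G.add_nodes_from(range(len(nodes)))
    for i, j in cand_list:
        G.add_edge(i, j, weight=float(np.linalg.norm(nodes[i] - nodes[j])))

    chosen: set[tuple[int, int]] = set()

    def _add_path(path):
        for a, b in zip(path[:-1], path[1:]):
            chosen.add((min(a, b), max(a, b)))

    # backbone: evenly spaced C1 anchors routed to the venule side
    starts = [
        bottom_ids[int(round(k * (len(bottom_ids) - 1) / max(params.n_backbone - 1, 1)))]
        for k in range(params.n_backbone)
    ]
    for sid in dict.fromkeys(starts):
        try:
            lengths, paths = nx.single_source_dijkstra(G, sid)
        except nx.NetworkXError as err:  # pragma: no cover - degenerate shells
            raise GenerationError("candidate graph is empty") from err
        reachable = [t for t in top_ids if t in paths]
        if not reachable:
            raise GenerationError("no C1→C2 path in candidate graph")
        best = min(reachable, key=lambda t: lengths[t])
        _add_path(paths[best])

    def _length(edge):
        i, j = edge
        return float(np.linalg.norm(nodes[i] - nodes[j]))

    total = sum(_length(e) for e in chosen)
    attached = {v for e in chosen for v in e} | boundary
    pool = [e for e in cand_list if e not in chosen]
    rng_pos.shuffle(pool)
    def _branch_count() -> int:
        deg: dict[int, int] = {}
        for a, b2 in chosen:
            deg[a] = deg.get(a, 0) + 1
            deg[b2] = deg.get(b2, 0) + 1
        return sum(1 for d in deg.values() if d >= 3)

    area_mm2 = (cx1 - cx0) * (cy1 - cy0) * 1e-6
    branch_target = params.branch_density * area_mm2

    def _grow(stop) -> None:
        stalled = False
        while not stop() and not stalled:
            stalled = True
            for e in pool:
                if stop():
                    break
                if e in chosen:
                    continue
                if e[0] in attached or e[1] in attached:
                    chosen.add(e)
                    attached.update(e)
                    nonlocal total
                    total += _length(e)
                    stalled = False

    _grow(lambda: total >= params.target_total_length)
    # top up anastomoses if the emergent branch count undershoots
    _grow(lambda: _branch_count() >= 0.95 * branch_target)

    # keep only nodes that are used; re-index
    used = sorted({v for e in chosen for v in e})
    remap = {old: new for new, old in enumerate(used)}
    out_nodes = nodes[used]
    edges = []
    diam = np.exp(
        rng_dia.normal(params.diameter_log_mean, params.diameter_log_sd, size=len(chosen))
    )
    diam = np.clip(diam, params.diameter_min, params.diameter_max)
    for k, (i, j) in enumerate(sorted(chosen)):
        edges.append(
            VesselEdge(
                nodes=(remap[i], remap[j]),
                polyline=np.array([nodes[i], nodes[j]]),
                diameter_um=float(diam[k]),
            )
        )
    graph = VesselGraph(nodes=out_nodes, edges=edges)
    graph.validate()
    return graph


def network_spans_channels(graph: VesselGraph, geometry_shell: DeviceGeometry, tol=1.0) -> bool:
    """Graph-search check that a path of vessel edges connects the C1
    interface (chamber bottom) to the C2 interface (chamber top)."""
    _, cy0, _, cy1 = geometry_shell.chamber_rect
    G = nx.Graph()
    G.add_edges_from(e.nodes for e in graph.edges)
    bottom = {i for i, p in enumerate(graph.nodes) if abs(p[1] - cy0) <= tol}
    top = {i for i, p in enumerate(graph.nodes) if abs(p[1] - cy1) <= tol}
    return any(
        nx.has_path(G, b, t) for b in bottom for t in top if b in G and t in G
    )


# --------------------------------------------------------------------------
# Islet loading generator
# --------------------------------------------------------------------------


@dataclass
class IsletGenParams:
    """Islet-loading emulation.

    ``density`` is the loading density (islets per µl hydrogel, 20–25 in
    practice).  ``gel_volume_ul`` is the effective loaded gel volume per
    chamber; its default is calibrated so density × volume equals the
    observed mean of 20 islets per chamber.  Diameters follow a lognormal
    truncated at ``max_diameter`` (the hand-selection filter), with the
    truncated mean calibrated to the observed 87.9 µm cohort mean.
    """

    seed: int = 0
    density: float = 22.5  # islets per µl
    gel_volume_ul: float = 20.0 / 22.5  # µl; density × volume = 20 islets
    size_log_mean: float = 4.4247  # ln µm; truncated mean = 87.9 µm
    size_log_sd: float = 0.35
    max_diameter: float = 200.0  # µm, hand-selection cutoff
    wall_clearance: float = 10.0  # µm between islet rim and chamber wall
    lumen_clearance: float = 5.0  # µm between islet rim and vessel lumen

    @property
    def expected_count(self) -> float:
        return self.density * self.gel_volume_ul


def sample_islet_diameters(params: IsletGenParams, n: int, rng=None) -> np.ndarray:
    """Draw n diameters from the truncated lognormal size model."""
    if rng is None:
        rng = _rng(params.seed, 11)
    out = np.empty(n)
    have = 0
    tries = 0
    while have < n:
        draw = np.exp(rng.normal(params.size_log_mean, params.size_log_sd, size=n - have))
        keep = draw[draw < params.max_diameter]
        out[have : have + len(keep)] = keep
        have += len(keep)
        tries += 1
        if tries > MAX_REJECTION_RETRIES:
            raise GenerationError("diameter sampling failed to satisfy the size cutoff")
    return out


def generate_islets(
    params: IsletGenParams,
    geometry_shell: DeviceGeometry,
    vessels: VesselGraph | None = None,
) -> IsletSet:
    """Place a Poisson(density × gel volume) number of islets uniformly in
    the chamber, rejecting islet–islet and islet–lumen overlaps.

    Diameters are drawn from their own sub-stream before placement, so
    the size cohort is independent of how hard placement was.
    """
    rng_n = _rng(params.seed, 10)
    rng_dia = _rng(params.seed, 11)
    rng_pos = _rng(params.seed, 12)

    n = int(rng_n.poisson(params.expected_count))
    diameters = sample_islet_diameters(params, n, rng_dia)
    # place large islets first: tightest constraints while the chamber is empty
    diameters = np.sort(diameters)[::-1]

    cx0, cy0, cx1, cy1 = geometry_shell.chamber_rect
    lumen_lines = None
    lumen_radii = None
    if vessels is not None and vessels.n_edges:
        lumen_lines = [LineString(e.polyline) for e in vessels.edges]
        lumen_radii = np.array([e.diameter_um / 2.0 for e in vessels.edges])

    centers = np.empty((n, 2))
    for k in range(n):
        r = diameters[k] / 2.0
        m = r + params.wall_clearance
        placed = False
        for _ in range(MAX_REJECTION_RETRIES):
            x = rng_pos.uniform(cx0 + m, cx1 - m)
            y = rng_pos.uniform(cy0 + m, cy1 - m)
            if k and np.any(
                np.hypot(centers[:k, 0] - x, centers[:k, 1] - y)
                < diameters[:k] / 2.0 + r
            ):
                continue
            if lumen_lines is not None:
                p = Point(x, y)
                clear = r + lumen_radii + params.lumen_clearance
                if any(line.distance(p) < c for line, c in zip(lumen_lines, clear)):
                    continue
            centers[k] = (x, y)
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"could not place islet {k} (diameter {diameters[k]:.0f} µm) "
                f"after {MAX_REJECTION_RETRIES} tries"
            )
    islets = IsletSet(centers=centers, diameters=diameters)
    islets.validate()
    return islets


def default_device(
    seed: int = 1,
    network: NetworkGenParams | None = None,
    islets: IsletGenParams | None = None,
    shell: DeviceGeometry | None = None,
) -> DeviceGeometry:
    """One-call synthetic device: shell + vessel network + islet loading.

    The per-device seed feeds both generators (each still splits its own
    sub-streams), so seed k fully determines device k.
    """
    from dataclasses import replace

    if shell is None:
        shell = default_shell()
    net_p = replace(network or NetworkGenParams(), seed=seed)
    isl_p = replace(islets or IsletGenParams(), seed=seed)
    vessels = generate_network(net_p, shell)
    islet_set = generate_islets(isl_p, shell, vessels)
    shell = replace(shell, vessels=vessels, islets=islet_set)
    shell.validate()
    return shell


# --------------------------------------------------------------------------
# Labeled point scenes
# --------------------------------------------------------------------------

PBMC_CLASSES = ("adherent", "invasive", "adjacent", "background")


@dataclass
class PointScene:
    """Labeled points standing in for a segmented microscopy scene.

    Channels: ``PBMC`` (CellTracker-labeled immune cells), ``HOECHST``
    (all nuclei), ``DEAD`` (dead-stain positive nuclei).  ``truth_label``
    carries the construction-time class for PBMC points, or the islet
    index (as a string) for nuclei.
    """

    x: np.ndarray
    y: np.ndarray
    channel: np.ndarray  # str per point
    truth_label: np.ndarray  # str per point

    def __len__(self) -> int:
        return len(self.x)

    def select(self, channel: str) -> "PointScene":
        m = self.channel == channel
        return PointScene(self.x[m], self.y[m], self.channel[m], self.truth_label[m])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_um": self.x,
                "y_um": self.y,
                "channel": self.channel,
                "truth_label": self.truth_label,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PointScene":
        return cls(
            x=df["x_um"].to_numpy(float),
            y=df["y_um"].to_numpy(float),
            channel=df["channel"].to_numpy(str),
            truth_label=df["truth_label"].to_numpy(str),
        )

    @classmethod
    def from_csv(cls, path) -> "PointScene":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def concatenate(cls, scenes) -> "PointScene":
        return cls(
            x=np.concatenate([s.x for s in scenes]),
            y=np.concatenate([s.y for s in scenes]),
            channel=np.concatenate([s.channel for s in scenes]),
            truth_label=np.concatenate([s.truth_label for s in scenes]),
        )


def _dist_to_islet_boundaries(x, y, islets: IsletSet) -> np.ndarray:
    """Signed distances to each islet boundary (negative inside)."""
    d = np.hypot(islets.centers[:, 0] - x, islets.centers[:, 1] - y)
    return d - islets.radii


def generate_pbmc_scene(
    seed: int,
    grid: LabeledGrid,
    islets: IsletSet,
    counts: dict[str, int],
    adjacency_radius: float = 100.0,
    margin: float = 2.0,
) -> PointScene:
    """Place PBMC points whose truth labels hold by construction.

    adherent: inside a vessel/channel lumen cell; invasive: inside an
    islet disc; adjacent: within (0, adjacency_radius] µm of the nearest
    islet boundary and extravascular; background: farther than the
    adjacency radius from every islet and extravascular.  Points keep a
    ``margin`` µm clearance from every class boundary so classification
    is unambiguous.
    """
    bad = set(counts) - set(PBMC_CLASSES)
    if bad:
        raise ValueError(f"unknown PBMC classes: {sorted(bad)}")
    rng = _rng(seed, 20)
    nx_, ny_ = grid.shape
    xs_lo = grid.origin[0]
    ys_lo = grid.origin[1]
    lumen_cells = np.argwhere(grid.labels == LUMEN)

    pts_x, pts_y, labels = [], [], []

    def _sample_label(label: str):
        if label == "adherent":
            if len(lumen_cells) == 0:
                raise GenerationError("no lumen cells for adherent points")
            k = rng.integers(len(lumen_cells))
            ix, iy = lumen_cells[k]
            jx, jy = rng.uniform(0.2, 0.8, size=2)
            return (xs_lo + (ix + jx) * grid.spacing, ys_lo + (iy + jy) * grid.spacing)
        for _ in range(MAX_REJECTION_RETRIES):
            if label == "invasive":
                if len(islets) == 0:
                    raise GenerationError("no islets for invasive points")
                k = int(rng.integers(len(islets)))
                r = islets.radii[k]
                if r <= margin:
                    continue
                rad = (r - margin) * np.sqrt(rng.uniform())
                th = rng.uniform(0, 2 * np.pi)
                x = islets.centers[k, 0] + rad * np.cos(th)
                y = islets.centers[k, 1] + rad * np.sin(th)
                if grid.label_at(x, y) == LUMEN:
                    continue
                return (x, y)
            if label == "adjacent":
                if len(islets) == 0:
                    raise GenerationError("no islets for adjacent points")
                k = int(rng.integers(len(islets)))
                r = islets.radii[k]
                lo, hi = r + margin, r + adjacency_radius - margin
                rad = np.sqrt(rng.uniform(lo**2, hi**2))
                th = rng.uniform(0, 2 * np.pi)
                x = islets.centers[k, 0] + rad * np.cos(th)
                y = islets.centers[k, 1] + rad * np.sin(th)
                try:
                    lab = grid.label_at(x, y)
                except Exception:
                    continue
                if lab in (LUMEN, WALL):
                    continue
                d = _dist_to_islet_boundaries(x, y, islets)
                if d.min() < margin:  # inside or hugging some islet
                    continue
                return (x, y)
            if label == "background":
                bx0, by0 = xs_lo, ys_lo
                bx1 = bx0 + nx_ * grid.spacing
                by1 = by0 + ny_ * grid.spacing
                x = rng.uniform(bx0, bx1)
                y = rng.uniform(by0, by1)
                lab = grid.label_at(x, y)
                if lab in (LUMEN, WALL):
                    continue
                if len(islets):
                    d = _dist_to_islet_boundaries(x, y, islets)
                    if d.min() <= adjacency_radius + margin:
                        continue
                return (x, y)
        raise GenerationError(f"could not place a '{label}' point")

    for label in PBMC_CLASSES:
        for _ in range(int(counts.get(label, 0))):
            x, y = _sample_label(label)
            pts_x.append(x)
            pts_y.append(y)
            labels.append(label)

    n = len(pts_x)
    return PointScene(
        x=np.asarray(pts_x, float),
        y=np.asarray(pts_y, float),
        channel=np.full(n, "PBMC"),
        truth_label=np.asarray(labels, dtype=object).astype(str)
        if n
        else np.empty(0, dtype=str),
    )


def generate_deadlive_scene(
    seed: int,
    islets: IsletSet,
    dead_fraction,
    nuclei_per_islet: int = 200,
) -> PointScene:
    """Nuclei scenes for viability quantification.

    HOECHST points are uniform in each islet disc; DEAD points are an
    exact subset of the HOECHST positions at the requested per-islet
    fraction (count = round(fraction × nuclei)).
    """
    frac = np.broadcast_to(np.asarray(dead_fraction, float), (len(islets),))
    if np.any((frac < 0) | (frac > 1)):
        raise ValueError("dead_fraction must lie in [0, 1]")
    rng = _rng(seed, 30)
    scenes = []
    for k in range(len(islets)):
        r = islets.radii[k]
        rad = r * np.sqrt(rng.uniform(size=nuclei_per_islet))
        th = rng.uniform(0, 2 * np.pi, size=nuclei_per_islet)
        hx = islets.centers[k, 0] + rad * np.cos(th)
        hy = islets.centers[k, 1] + rad * np.sin(th)
        n_dead = int(round(frac[k] * nuclei_per_islet))
        dead_idx = rng.choice(nuclei_per_islet, size=n_dead, replace=False)
        scenes.append(
            PointScene(
                x=np.concatenate([hx, hx[dead_idx]]),
                y=np.concatenate([hy, hy[dead_idx]]),
                channel=np.concatenate(
                    [np.full(nuclei_per_islet, "HOECHST"), np.full(n_dead, "DEAD")]
                ),
                truth_label=np.concatenate(
                    [np.full(nuclei_per_islet, str(k)), np.full(n_dead, str(k))]
                ),
            )
        )
    if not scenes:
        e = np.empty(0)
        return PointScene(e, e, np.empty(0, dtype=str), np.empty(0, dtype=str))
    return PointScene.concatenate(scenes)
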