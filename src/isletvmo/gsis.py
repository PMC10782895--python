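"""Glucose-stimulated insulin secretion (GSIS) protocol on the simulator.

Drives the device through the standard perfusion protocol — one hour of
basal 5.5 mM glucose, one hour of 16.7 mM high glucose, two hours of
recovery, one hour of 30 mM KCl depolarization — with the venule-side
reservoirs V_B/V_C blocked so all perfusate crosses the vessel network.
Effluent at V_D is integrated into 10-minute bins starting 30 minutes
before the high-glucose step (t = 0 at stimulation onset); insulin fold
change is each bin's insulin divided by the mean insulin of the −20–0 min
starvation bins.

Also implements the two in-silico experiments: per-islet attribution
(secretion silenced for all but one islet at a time, consumption left
intact so the oxygen/glucose fields are identical across runs — which is
what makes the runs exactly superpose) and vessel addition (a new vessel
drawn to a chosen islet, comparing outlet insulin and the peri-islet
extravascular insulin pool), plus model-vs-experiment comparison of
binned effluent series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .flow import FlowField, FlowParams, solve_flow
from .geometry import (
    GEL,
    LUMEN,
    DeviceGeometry,
    GeometryError,
    LabeledGrid,
    VesselEdge,
    rasterize,
)
from .transport import (
    KineticParams,
    SpeciesState,
    TransientResult,
    TransportParams,
    TransportSystem,
    run_transient,
)

MOL_TO_PMOL = 1e12


class FoldChangeError(ValueError):
    """Raised when fold change is undefined (zero/absent baseline)."""


class AlignmentError(ValueError):
    """Raised when two effluent series are on different bin grids."""


# --------------------------------------------------------------------------
# Inlet schedule
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ScheduleSegment:
    start_min: float
    end_min: float
    glucose_mM: float
    kcl: bool = False


@dataclass
class InletSchedule:
    """Piecewise-constant inlet composition; t = 0 at high-glucose onset.

    Segments are half-open [start, end) minutes, contiguous and
    non-overlapping.
    """

    segments: list[ScheduleSegment]

    def __post_init__(self):
        segs = sorted(self.segments, key=lambda s: s.start_min)
        for s in segs:
            if s.glucose_mM < 0:
                raise ValueError("glucose must be >= 0")
            if s.end_min <= s.start_min:
                raise ValueError("segment end must exceed start")
        for a, b in zip(segs[:-1], segs[1:]):
            if abs(a.end_min - b.start_min) > 1e-9:
                raise ValueError("segments must be contiguous and non-overlapping")
        self.segments = segs

    @property
    def t_min(self) -> float:
        return self.segments[0].start_min

    @property
    def t_max(self) -> float:
        return self.segments[-1].end_min

    def at(self, t_min: float) -> tuple[float, bool]:
        for s in self.segments:
            if s.start_min <= t_min < s.end_min:
                return s.glucose_mM, s.kcl
        # clamp to the edges for the half-open final instant
        if abs(t_min - self.t_max) < 1e-9:
            s = self.segments[-1]
            return s.glucose_mM, s.kcl
        raise ValueError(f"t = {t_min} min outside the schedule")

    def truncated(self, t_end_min: float) -> "InletSchedule":
        segs = []
        for s in self.segments:
            if s.start_min >= t_end_min:
                break
            segs.append(replace(s, end_min=min(s.end_min, t_end_min)))
        return InletSchedule(segs)


def default_protocol() -> InletSchedule:
    """The standard device GSIS protocol: 1 h basal 5.5 mM, 1 h high
    16.7 mM, 2 h recovery, 1 h KCl; effluent collected from −30 min."""
    return InletSchedule(
        [
            ScheduleSegment(-60.0, 0.0, 5.5, False),
            ScheduleSegment(0.0, 60.0, 16.7, False),
            ScheduleSegment(60.0, 180.0, 5.5, False),
            ScheduleSegment(180.0, 240.0, 5.5, True),
        ]
    )


# --------------------------------------------------------------------------
# Effluent series and fold change
# --------------------------------------------------------------------------


BASELINE_WINDOW = (-20.0, 0.0)


def fold_change(
    insulin_per_bin: np.ndarray,
    bin_start_min: np.ndarray,
    bin_end_min: np.ndarray,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
) -> np.ndarray:
    """Per-bin insulin divided by the mean insulin of the bins inside the
    starvation baseline window (default −20–0 min)."""
    insulin_per_bin = np.asarray(insulin_per_bin, dtype=float)
    lo, hi = baseline_window
    base = (bin_start_min >= lo - 1e-9) & (bin_end_min <= hi + 1e-9)
    if not base.any():
        raise FoldChangeError("no bins inside the baseline window")
    mean = float(insulin_per_bin[base].mean())
    if mean <= 0:
        raise FoldChangeError("baseline insulin is zero; fold change undefined")
    return insulin_per_bin / mean


@dataclass
class EffluentSeries:
    """10-minute-binned effluent at the collection outlet V_D.

    ``glucose_mM`` is the bin's throughput-weighted mean concentration
    (binned amount over binned volume — what a glucometer on pooled
    fractions reads); insulin is reported as amount per bin (pmol).
    ``fold_change`` is None with ``fold_error`` set when the baseline
    secretion is identically zero.
    """

    t_start_min: np.ndarray
    t_end_min: np.ndarray
    glucose_mM: np.ndarray
    insulin_pmol: np.ndarray
    fold_change: np.ndarray | None = None
    fold_error: str | None = None
    baseline_window: tuple[float, float] = BASELINE_WINDOW

    @property
    def n_bins(self) -> int:
        return len(self.t_start_min)

    def bin_containing(self, t_min: float) -> int:
        return int(np.searchsorted(self.t_end_min, t_min + 1e-9))

    def peak_fold_bin(self) -> tuple[int, float]:
        """(index, fold) of the maximal-fold bin at or after t = 0."""
        if self.fold_change is None:
            raise FoldChangeError(self.fold_error or "fold change unavailable")
        m = self.t_start_min >= -1e-9
        k = int(np.argmax(np.where(m, self.fold_change, -np.inf)))
        return k, float(self.fold_change[k])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "t_start_min": self.t_start_min,
                "t_end_min": self.t_end_min,
                "glucose_mM": self.glucose_mM,
                "insulin_pmol": self.insulin_pmol,
            }
        )
        if self.fold_change is not None:
            df["fold_change"] = self.fold_change
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EffluentSeries":
        return cls(
            t_start_min=df["t_start_min"].to_numpy(float),
            t_end_min=df["t_end_min"].to_numpy(float),
            glucose_mM=df["glucose_mM"].to_numpy(float),
            insulin_pmol=df["insulin_pmol"].to_numpy(float),
            fold_change=df["fold_change"].to_numpy(float) if "fold_change" in df else None,
        )

    @classmethod
    def from_csv(cls, path) -> "EffluentSeries":
        return cls.from_frame(pd.read_csv(path))


def bin_effluent(
    times_s: np.ndarray,
    glc_flux: np.ndarray,
    ins_flux: np.ndarray,
    dt: float,
    q_out_m3s: float,
    t_start_min: float,
    bin_minutes: float = 10.0,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
) -> EffluentSeries:
    """Integrate per-step outlet fluxes (mol/s) into collection bins."""
    t_min = times_s / 60.0
    n_bins = int(np.floor((t_min[-1] - t_start_min) / bin_minutes + 1e-9))
    edges = t_start_min + bin_minutes * np.arange(n_bins + 1)
    which = np.digitize(t_min - 1e-9, edges) - 1
    ok = (which >= 0) & (which < n_bins)
    glc_amount = np.bincount(which[ok], weights=glc_flux[ok] * dt, minlength=n_bins)
    ins_amount = np.bincount(which[ok], weights=ins_flux[ok] * dt, minlength=n_bins)
    bin_volume = q_out_m3s * bin_minutes * 60.0  # m³ collected per bin
    glucose_mM = glc_amount / bin_volume  # mol / m³ ≡ mM
    insulin_pmol = ins_amount * MOL_TO_PMOL
    fold = None
    err = None
    try:
        fold = fold_change(insulin_pmol, edges[:-1], edges[1:], baseline_window)
    except FoldChangeError as e:
        err = str(e)
    return EffluentSeries(
        t_start_min=edges[:-1],
        t_end_min=edges[1:],
        glucose_mM=glucose_mM,
        insulin_pmol=insulin_pmol,
        fold_change=fold,
        fold_error=err,
        baseline_window=baseline_window,
    )


# --------------------------------------------------------------------------
# Run configuration and the main GSIS run
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Bundle of solver controls and model parameters for one GSIS run.

    ``collection_start_min`` is when effluent fractions begin (−30 min);
    ``t_end_min`` truncates the protocol (the full protocol runs to
    +240 min; shorter windows are routine for in-silico experiments).
    The device is initialized at the steady state of the first schedule
    segment, standing in for the basal pre-perfusion hour.
    """

    spacing: float = 10.0  # µm
    dt: float = 1.0  # s
    collection_start_min: float = -30.0
    t_end_min: float = 240.0
    bin_minutes: float = 10.0
    schedule: InletSchedule = field(default_factory=default_protocol)
    flow: FlowParams = field(default_factory=FlowParams)
    transport: TransportParams = field(default_factory=TransportParams)
    kinetics: KineticParams = field(default_factory=KineticParams)
    baseline_window: tuple[float, float] = BASELINE_WINDOW
    snapshot_times_min: tuple = ()


def survey_run_config(t_end_min: float = 60.0) -> RunConfig:
    """Solver controls for multi-device surveys (ensembles of synthetic
    devices): 12.5 µm raster (resolves the 25 µm minimum vessel caliber),
    5 s implicit steps, protocol truncated after the high-glucose hour.

    These are the problem sizes used for ensemble statistics; single-run
    analyses can afford the finer defaults in :class:`RunConfig`.
    """
    return RunConfig(spacing=12.5, dt=5.0, t_end_min=t_end_min)


@dataclass
class GsisResult:
    series: EffluentSeries
    snapshots: dict
    grid: LabeledGrid
    flow: FlowField
    system: TransportSystem
    transient: TransientResult
    q_out_m3s: float


def _outflow_rate(system: TransportSystem) -> float:
    return float(sum(q for outs in system.outflow_faces.values() for _, q in outs))


def run_gsis(
    geometry: DeviceGeometry,
    config: RunConfig | None = None,
    islet_columns: np.ndarray | None = None,
) -> GsisResult:
    """Solve flow once, run the transport protocol, bin the effluent.

    ``islet_columns`` (optional) advances one insulin field per column
    with that column's islet-cell secretion weights — the machinery
    behind per-islet attribution; the default is the physical all-islet
    run.
    """
    config = config or RunConfig()
    geometry.validate()
    grid = rasterize(geometry, config.spacing)
    flow_field = solve_flow(grid, geometry.ports, config.flow)
    system = TransportSystem(
        grid,
        flow_field,
        config.transport,
        config.kinetics,
        dt=config.dt,
        # GSIS runs start from the steady oxygen field; with glucose→O2
        # coupling off the oxygen problem is autonomous and stays there
        freeze_o2=not config.kinetics.o2_glucose_modulation,
    )
    schedule = config.schedule.truncated(config.t_end_min)
    t0_min = config.collection_start_min
    if t0_min < schedule.t_min:
        raise ValueError("collection starts before the schedule begins")
    glc0, _ = schedule.at(schedule.t_min)
    state0 = system.steady_state(glc0, islet_columns)
    state0 = SpeciesState(
        time=t0_min * 60.0,
        c_O2=state0.c_O2,
        c_GLC=state0.c_GLC,
        c_INS=state0.c_INS,
        dglc_dt=state0.dglc_dt,
    )
    result = run_transient(
        system,
        state0,
        lambda t_s: schedule.at(min(t_s / 60.0, schedule.t_max)),
        t_end=schedule.t_max * 60.0,
        islet_columns=islet_columns,
        snapshot_times=tuple(t * 60.0 for t in config.snapshot_times_min),
    )
    q_out = _outflow_rate(system)
    series = bin_effluent(
        result.times,
        result.outlet_flux["GLC"],
        result.outlet_flux["INS"]
        if result.outlet_flux["INS"].ndim == 1
        else result.outlet_flux["INS"][:, -1],
        config.dt,
        q_out,
        t0_min,
        config.bin_minutes,
        config.baseline_window,
    )
    snaps = {t_s / 60.0: f for t_s, f in result.snapshots.items()}
    return GsisResult(
        series=series,
        snapshots=snaps,
        grid=grid,
        flow=flow_field,
        system=system,
        transient=result,
        q_out_m3s=q_out,
    )


# --------------------------------------------------------------------------
# In-silico experiment 1: per-islet attribution
# --------------------------------------------------------------------------


@dataclass
class AttributionResult:
    """Outlet-insulin decomposition over islets.

    ``islet_series_pmol[k]`` is the binned outlet insulin of the run in
    which only islet k secretes (consumption stays on for all islets, so
    oxygen and glucose fields — hence each islet's secretion drive — are
    identical across runs).  ``total_series_pmol`` is the all-islet run.
    """

    bins: EffluentSeries  # all-islet series (with fold change)
    islet_series_pmol: np.ndarray  # (n_islets, n_bins)
    total_series_pmol: np.ndarray  # (n_bins,)
    cumulative_pmol: np.ndarray  # (n_islets,)
    distance_to_lumen_um: np.ndarray  # (n_islets,) islet rim to nearest perfused lumen
    centers: np.ndarray
    diameters: np.ndarray

    def superposition_error(self) -> float:
        """Relative L2 mismatch between Σ single-islet series and the
        all-islet series (exact up to round-off: insulin is linear)."""
        s = self.islet_series_pmol.sum(axis=0)
        denom = np.linalg.norm(self.total_series_pmol)
        return float(np.linalg.norm(s - self.total_series_pmol) / denom) if denom else 0.0


def distance_to_perfused_lumen(
    geometry: DeviceGeometry,
    grid: LabeledGrid,
    flow_field: FlowField,
    speed_threshold: float = 1e-6,
) -> np.ndarray:
    """Distance (µm) from each islet rim to the nearest lumen cell with
    depth-averaged speed above the threshold (i.e. actually perfused)."""
    speed = flow_field.velocity_magnitude()
    perfused = (grid.labels == LUMEN) & (speed >= speed_threshold)
    cells = np.argwhere(perfused)
    if len(cells) == 0:
        return np.full(len(geometry.islets), np.inf)
    xs, ys = grid.cell_centers()
    pts = np.column_stack([xs[cells[:, 0]], ys[cells[:, 1]]])
    tree = cKDTree(pts)
    d, _ = tree.query(geometry.islets.centers)
    return np.maximum(d - geometry.islets.radii, 0.0)


def attribute_islets(
    geometry: DeviceGeometry, config: RunConfig | None = None
) -> AttributionResult:
    """Repeat the GSIS run once per islet with every other islet's
    secretion shut down (consumption untouched).

    All runs share identical flow, oxygen and glucose fields by
    construction, so they are advanced in one pass as independent
    insulin fields against the common operator.
    """
    config = config or RunConfig()
    n_islets = len(geometry.islets)
    if n_islets == 0:
        raise GeometryError("attribution requires at least one islet")
    # column weights straight from the raster: one insulin field per islet
    # plus the all-islet field
    grid = rasterize(geometry, config.spacing)
    active = grid.labels != 0
    ids = grid.islet_id[active]
    columns = np.zeros((int(active.sum()), n_islets + 1))
    for k in range(n_islets):
        columns[ids == k, k] = 1.0
    columns[ids >= 0, n_islets] = 1.0
    res = run_gsis(geometry, config, islet_columns=columns)
    raw = res.transient.outlet_flux["INS"]  # (steps, n_islets+1)
    series = bin_effluent(
        res.transient.times,
        res.transient.outlet_flux["GLC"],
        raw[:, -1],
        config.dt,
        res.q_out_m3s,
        config.collection_start_min,
        config.bin_minutes,
        config.baseline_window,
    )
    per_islet = []
    for k in range(n_islets):
        s_k = bin_effluent(
            res.transient.times,
            res.transient.outlet_flux["GLC"],
            raw[:, k],
            config.dt,
            res.q_out_m3s,
            config.collection_start_min,
            config.bin_minutes,
            config.baseline_window,
        )
        per_islet.append(s_k.insulin_pmol)
    islet_series = np.asarray(per_islet)
    return AttributionResult(
        bins=series,
        islet_series_pmol=islet_series,
        total_series_pmol=series.insulin_pmol,
        cumulative_pmol=islet_series.sum(axis=1),
        distance_to_lumen_um=distance_to_perfused_lumen(geometry, res.grid, res.flow),
        centers=geometry.islets.centers.copy(),
        diameters=geometry.islets.diameters.copy(),
    )


# --------------------------------------------------------------------------
# In-silico experiment 2: vessel addition
# --------------------------------------------------------------------------


def peri_islet_insulin_pool(
    system: TransportSystem,
    state: SpeciesState,
    center: np.ndarray,
    radius_islet: float,
    halo_um: float = 100.0,
) -> float:
    """Extravascular insulin (pmol) in GEL cells within ``halo_um`` of the
    islet rim — the local pool that a nearby vessel would wash out."""
    grid = system.grid
    xs, ys = grid.cell_centers()
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    d = np.hypot(X - center[0], Y - center[1]) - radius_islet
    sel = (grid.labels == GEL) & (d > 0) & (d <= halo_um)
    c_ins = state.c_INS if state.c_INS.ndim == 1 else state.c_INS[:, -1]
    c_grid = system.field_on_grid(c_ins, fill=0.0)
    return float(c_grid[sel].sum() * grid.cell_volume_m3() * MOL_TO_PMOL)


def add_vessel_experiment(
    geometry: DeviceGeometry,
    new_edge_polyline: np.ndarray,
    new_edge_diameter: float,
    target_islet: int,
    config: RunConfig | None = None,
    halo_um: float = 100.0,
    connection_tol: float = 15.0,
) -> dict:
    """Paired simulation: the original device vs the same device with one
    added vessel, reporting cumulative outlet insulin and the peri-islet
    extravascular pool for the target islet in both.

    The new edge must attach to the existing perfused network (an
    endpoint within ``connection_tol`` µm of a vessel midline or a
    channel interface).
    """
    config = config or RunConfig()
    poly = np.asarray(new_edge_polyline, dtype=float)
    if not new_edge_diameter > 0:
        raise GeometryError("new vessel diameter must be > 0")
    from shapely.geometry import LineString, Point

    anchors = [LineString(e.polyline) for e in geometry.vessels.edges]
    cx0, cy0, cx1, cy1 = geometry.chamber_rect
    anchors.append(LineString([(cx0, cy0), (cx1, cy0)]))  # C1 interface
    anchors.append(LineString([(cx0, cy1), (cx1, cy1)]))  # C2 interface
    connected = any(
        line.distance(Point(*p)) <= connection_tol for p in (poly[0], poly[-1]) for line in anchors
    )
    if not connected:
        raise GeometryError("new vessel does not connect to the perfused network")

    vessels = geometry.vessels
    n0 = len(vessels.nodes)
    new_nodes = np.vstack([vessels.nodes, poly[0], poly[-1]])
    new_edges = vessels.edges + [
        VesselEdge(nodes=(n0, n0 + 1), polyline=poly, diameter_um=float(new_edge_diameter))
    ]
    augmented = replace(
        geometry,
        vessels=type(vessels)(nodes=new_nodes, edges=new_edges),
    )

    center = geometry.islets.centers[target_islet]
    r_islet = geometry.islets.radii[target_islet]
    out = {}
    for name, geom in (("original", geometry), ("augmented", augmented)):
        res = run_gsis(geom, config)
        pool = peri_islet_insulin_pool(
            res.system, res.transient.final_state, center, r_islet, halo_um
        )
        out[name] = {
            "outlet_cumulative_pmol": float(res.series.insulin_pmol.sum()),
            "peri_islet_pool_pmol": pool,
            "series": res.series,
        }
    out["target_islet"] = int(target_islet)
    return out


# --------------------------------------------------------------------------
# Model-vs-experiment comparison
# --------------------------------------------------------------------------


def compare_to_experiment(sim: EffluentSeries, observed: EffluentSeries | pd.DataFrame) -> dict:
    """Per-species RMSE and peak-bin agreement between a simulated and an
    observed binned effluent series on the same bin grid."""
    if isinstance(observed, pd.DataFrame):
        observed = EffluentSeries.from_frame(observed)
    if sim.n_bins != observed.n_bins or not np.allclose(
        sim.t_start_min, observed.t_start_min
    ):
        raise AlignmentError("bin grids differ; resample before comparing")
    rmse_glc = float(np.sqrt(np.mean((sim.glucose_mM - observed.glucose_mM) ** 2)))
    rmse_ins = float(np.sqrt(np.mean((sim.insulin_pmol - observed.insulin_pmol) ** 2)))
    peak_sim = int(np.argmax(sim.insulin_pmol))
    peak_obs = int(np.argmax(observed.insulin_pmol))
    out = {
        "rmse_glucose_mM": rmse_glc,
        "rmse_insulin_pmol": rmse_ins,
        "peak_bin_agreement": peak_sim == peak_obs,
        "overlay": pd.DataFrame(
            {
                "t_end_min": sim.t_end_min,
                "sim_glucose_mM": sim.glucose_mM,
                "obs_glucose_mM": observed.glucose_mM,
                "sim_insulin_pmol": sim.insulin_pmol,
                "obs_insulin_pmol": observed.insulin_pmol,
            }
        ),
    }
    if sim.fold_change is not None and observed.fold_change is not None:
        out["rmse_fold_change"] = float(
            np.sqrt(np.mean((sim.fold_change - observed.fold_change) ** 2))
        )
    return out
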