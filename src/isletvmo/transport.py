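"""Transient oxygen / glucose / insulin transport with islet kinetics.

Over a frozen steady flow field the three species obey

    ∂c/∂t + ∇·(u c) = ∇·(D(x) ∇c) ± r(x, c)

on the material raster, with per-material diffusivities, inlet Dirichlet
concentrations at inflow port faces, advective outflow at outflow port
faces, no-flux walls for glucose and insulin, and an oxygen wall
condition standing in for the oxygen-permeable PDMS (Dirichlet at the
atmospheric-equilibrium concentration by default, Robin optionally).

Islet kinetics (volumetric rates inside islet tissue only):

* oxygen consumption   r_O2  = R_O2,max · c_O2/(c_O2 + K_M,O2)
* glucose consumption  r_GLC = R_GLC,max · c_GLC/(c_GLC + K_M,GLC)
* insulin secretion    r_INS = R_INS,max · [b + (1−b) · Hill(c_GLC)]
                       + k_1 · max(∂c_GLC/∂t, 0)

with Hill(c) = cⁿ/(cⁿ + K_INSⁿ), basal fraction b, and everything gated
by a hypoxic cutoff (all rates vanish where c_O2 ≤ c_crit).  The
rate-of-change term is the first-phase component of the classical
glucose–insulin kinetic family: it converts a rapid local rise in
glucose into a transient burst of release and is what places the peak
effluent bin immediately after the glucose step.  KCl depolarization is
modeled as a schedule flag that forces release at the maximal rate
(releasable-insulin assay); no KCl transport is simulated.  Granule-store
depletion is deliberately not modeled.

Numerics: first-order upwind advection and harmonic-mean diffusion,
integrated with backward Euler on a single factorized operator per
species (reaction split off and handled pointwise-implicitly), which is
unconditionally stable and positivity-preserving; the time step is an
accuracy knob, not a stability constraint.  Units are SI internally —
conveniently, mol·m⁻³ ≡ mM for concentrations.  Insulin feeds back on
nothing, so the insulin sub-problem is linear in its sources; the solver
therefore supports advancing many insulin fields (one per islet subset)
against the same oxygen/glucose fields in a single pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .flow import FlowField
from .geometry import GEL, ISLET, LUMEN, WALL, LabeledGrid

SPECIES = ("O2", "GLC", "INS")


class StabilityError(RuntimeError):
    """Raised when a transport step produces non-finite concentrations."""


class KineticsError(ValueError):
    """Raised on invalid kinetic inputs (negative concentrations)."""


@dataclass
class TransportParams:
    """Diffusivities (m² s⁻¹) per species and material, and the oxygen
    boundary condition.

    Defaults follow the molecular-size ordering D_INS < D_GLC < D_O2 in
    every material, with hindered diffusion in gel and tissue.
    ``c_atm`` is the atmospheric-equilibrium dissolved-oxygen
    concentration of the medium (≈0.2 mM at 37 °C); inflowing medium is
    assumed equilibrated with it.
    """

    diffusivity: dict = field(
        default_factory=lambda: {
            "O2": {LUMEN: 3.0e-9, GEL: 2.5e-9, ISLET: 2.0e-9},
            "GLC": {LUMEN: 9.0e-10, GEL: 6.0e-10, ISLET: 3.0e-10},
            "INS": {LUMEN: 1.5e-10, GEL: 1.0e-10, ISLET: 5.0e-11},
        }
    )
    pdms_o2_mode: str = "dirichlet"  # "dirichlet" | "robin" | "none"
    c_atm: float = 0.2  # mM dissolved O2
    robin_coefficient: float = 1.0e-5  # m/s, PDMS mass-transfer coefficient
    inlet_o2: float | None = None  # default: c_atm

    def validate(self) -> None:
        for mat in (LUMEN, GEL, ISLET):
            ds = [self.diffusivity[s][mat] for s in SPECIES]
            if not all(d > 0 for d in ds):
                raise ValueError("diffusivities must be positive")
            if not ds[2] < ds[1] < ds[0]:
                raise ValueError("expect D_INS < D_GLC < D_O2 in every material")
        if self.pdms_o2_mode not in ("dirichlet", "robin", "none"):
            raise ValueError(f"unknown pdms_o2_mode {self.pdms_o2_mode!r}")


@dataclass
class KineticParams:
    """Islet consumption/secretion constants (volumetric, per islet tissue).

    Consumption follows Michaelis–Menten saturation with a hypoxic
    cutoff; secretion is a basal fraction plus a Hill-sigmoidal
    glucose-dependent fraction, with an additive first-phase term
    proportional to the positive local rate of change of glucose.  The
    secretion constants are calibrated so that the steady stimulated/
    basal secretion ratio and the first-bin burst reproduce the
    fold-change response observed in perfused devices.
    """

    R_O2_max: float = 0.034  # mol·m⁻³·s⁻¹
    K_M_O2: float = 1.0e-3  # mM
    c_O2_crit: float = 1.0e-4  # mM; below this all islet activity stops
    R_GLC_max: float = 3.0e-3  # mol·m⁻³·s⁻¹
    K_M_GLC: float = 1.0  # mM
    R_INS_max: float = 1.5e-5  # mol·m⁻³·s⁻¹
    K_INS: float = 10.0  # mM glucose at half-maximal secretion
    n_hill: float = 4.0
    basal_secretion_fraction: float = 0.2
    kcl_mode_rate_fraction: float = 1.0
    first_phase_gain: float = 1.15e-3  # dimensionless; r₁ = gain · (∂c_GLC/∂t)₊
    o2_glucose_modulation: bool = False

    def validate(self) -> None:
        if min(self.R_O2_max, self.R_GLC_max, self.R_INS_max) < 0:
            raise ValueError("rates must be >= 0")
        if self.n_hill < 1:
            raise ValueError("n_hill must be >= 1")
        if not 0 <= self.basal_secretion_fraction < 1:
            raise ValueError("basal_secretion_fraction must lie in [0, 1)")
        if not 5.0 < self.K_INS < 16.7:
            raise ValueError("K_INS should lie between basal and stimulatory glucose")

    def hill(self, c_glc):
        cn = np.power(np.maximum(c_glc, 0.0), self.n_hill)
        return cn / (cn + self.K_INS**self.n_hill)


def islet_rates(c_O2, c_GLC, kp: KineticParams, kcl_active: bool = False):
    """Volumetric islet rates (r_O2, r_GLC, r_INS), all >= 0, per the
    saturating-consumption / Hill-secretion model with hypoxic cutoff.

    Under KCl depolarization the glucose-dependent secretion factor is
    replaced by the maximal-release fraction.
    """
    c_O2 = np.asarray(c_O2, dtype=float)
    c_GLC = np.asarray(c_GLC, dtype=float)
    if np.any(c_O2 < 0) or np.any(c_GLC < 0):
        raise KineticsError("concentrations must be >= 0")
    alive = (c_O2 > kp.c_O2_crit).astype(float)
    r_o2 = kp.R_O2_max * c_O2 / (c_O2 + kp.K_M_O2) * alive
    if kp.o2_glucose_modulation:
        r_o2 = r_o2 * c_GLC / (c_GLC + kp.K_M_GLC)
    r_glc = kp.R_GLC_max * c_GLC / (c_GLC + kp.K_M_GLC) * alive
    if kcl_active:
        secretion_factor = kp.kcl_mode_rate_fraction
    else:
        b = kp.basal_secretion_fraction
        secretion_factor = b + (1.0 - b) * kp.hill(c_GLC)
    r_ins = kp.R_INS_max * secretion_factor * alive
    return r_o2, r_glc, r_ins


@dataclass
class SpeciesState:
    """Concentration fields on the active cells at one instant.

    ``c_INS`` may be a matrix (n_cells, n_sources) when several insulin
    source configurations are advanced simultaneously.  ``dglc_dt``
    stores the last transport-step rate of change of glucose, used by
    the first-phase secretion term.
    """

    time: float  # s
    c_O2: np.ndarray
    c_GLC: np.ndarray
    c_INS: np.ndarray
    dglc_dt: np.ndarray | None = None

    def copy(self) -> "SpeciesState":
        return SpeciesState(
            self.time,
            self.c_O2.copy(),
            self.c_GLC.copy(),
            self.c_INS.copy(),
            None if self.dglc_dt is None else self.dglc_dt.copy(),
        )


@dataclass
class StepRecord:
    """Per-step boundary and reaction bookkeeping (mol/s, species-wise)."""

    time: float
    outlet_flux: dict  # species -> float or ndarray (per insulin column)
    inlet_flux: dict  # species -> float
    consumed: dict  # species -> float (O2, GLC); secreted for INS


class TransportSystem:
    """Assembled transport operators for one grid + flow field.

    Builds, once, the per-species implicit operator
    ``M = I/dt + A_advection + A_diffusion + boundaries`` and its sparse
    LU factorization; stepping is then a matter of right-hand sides.
    """

    def __init__(
        self,
        grid: LabeledGrid,
        flow_field: FlowField,
        tp: TransportParams | None = None,
        kp: KineticParams | None = None,
        dt: float = 1.0,
        freeze_o2: bool = False,
    ):
        self.grid = grid
        self.flow = flow_field
        self.tp = tp or TransportParams()
        self.kp = kp or KineticParams()
        self.tp.validate()
        self.kp.validate()
        self.dt = float(dt)
        # With glucose→O2 coupling off and a constant inlet, nothing in the
        # oxygen problem changes during a run: a state initialized at the
        # steady oxygen field stays there, so the solve can be skipped.
        self.freeze_o2 = bool(freeze_o2) and not self.kp.o2_glucose_modulation

        nx, ny = grid.shape
        labels = grid.labels
        self.active = labels != WALL
        self.n = int(self.active.sum())
        self.idx = -np.ones((nx, ny), dtype=np.int64)
        self.idx[self.active] = np.arange(self.n)
        self.cell_volume = grid.cell_volume_m3()  # m³
        self.dx_m = grid.spacing * 1e-6
        self.labels_active = labels[self.active]

        self.islet_mask = self.labels_active == ISLET  # per active cell
        self.islet_ids = grid.islet_id[self.active]  # -1 where not islet

        self._build_advection()
        self._build_boundaries()
        self._ops: dict[str, sp.csr_matrix] = {}
        self._lu_step: dict = {}
        self._lu_steady: dict = {}
        self._b_in_adv: dict[str, np.ndarray] = {}
        self._b_in_diff: dict[str, np.ndarray] = {}
        self._b_wall: dict[str, np.ndarray] = {}
        for s in SPECIES:
            A = self._assemble_species(s)
            self._ops[s] = A
            M = sp.eye(self.n, format="csr") / self.dt + A
            self._lu_step[s] = spla.splu(M.tocsc())

    # -- assembly -----------------------------------------------------------

    def _interior_faces(self):
        """(iL, iR, F, matL, matR) for all faces between two active cells."""
        grid, idx = self.grid, self.idx
        out = []
        fx = self.flow.face_flux_x[1:-1, :]  # faces between (ix-1) and (ix)
        L, R = idx[:-1, :], idx[1:, :]
        m = (L >= 0) & (R >= 0)
        out.append((L[m], R[m], fx[m], self.grid.labels[:-1, :][m], self.grid.labels[1:, :][m]))
        fy = self.flow.face_flux_y[:, 1:-1]
        L, R = idx[:, :-1], idx[:, 1:]
        m = (L >= 0) & (R >= 0)
        out.append((L[m], R[m], fy[m], self.grid.labels[:, :-1][m], self.grid.labels[:, 1:][m]))
        iL = np.concatenate([o[0] for o in out])
        iR = np.concatenate([o[1] for o in out])
        F = np.concatenate([o[2] for o in out])
        mL = np.concatenate([o[3] for o in out])
        mR = np.concatenate([o[4] for o in out])
        return iL, iR, F, mL, mR

    def _build_advection(self):
        iL, iR, F, mL, mR = self._interior_faces()
        self._faces = (iL, iR, F, mL, mR)
        V = self.cell_volume
        rows, cols, vals = [], [], []
        pos = F > 0
        neg = F < 0
        # F > 0: upwind cell L loses F·c_L, R gains it
        rows.extend([iL[pos], iR[pos]])
        cols.extend([iL[pos], iL[pos]])
        vals.extend([F[pos] / V, -F[pos] / V])
        # F < 0: upwind cell R
        rows.extend([iR[neg], iL[neg]])
        cols.extend([iR[neg], iR[neg]])
        vals.extend([-F[neg] / V, F[neg] / V])
        self._adv = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n, self.n),
        )

    def _build_boundaries(self):
        """Classify port faces into inflow/outflow; count wall faces."""
        grid = self.grid
        nx, ny = grid.shape
        V = self.cell_volume
        self.inflow_faces: list[tuple[int, float]] = []  # (active idx, F_in m³/s)
        self.outflow_faces: dict[str, list[tuple[int, float]]] = {}
        open_port_face_count = np.zeros(self.n)
        for name, faces in self.flow.port_faces.items():
            if name not in self.flow.open_ports:
                continue  # blocked ports carry no flux: their faces act as walls
            p_res = self.flow.port_pressures[name]
            outs = []
            for f in faces:
                if f.transmissibility == 0:
                    continue
                k = self.idx[f.ix, f.iy]
                q = f.transmissibility * (p_res - self.flow.pressure[f.ix, f.iy])
                open_port_face_count[k] += 1
                if q > 0:
                    self.inflow_faces.append((k, q))
                elif q < 0:
                    outs.append((k, -q))
            if outs:
                self.outflow_faces[name] = outs

        # wall faces per active cell = boundary faces minus open-port faces
        padded = np.zeros((nx + 2, ny + 2), dtype=bool)
        padded[1:-1, 1:-1] = self.active
        nbr_wall = (
            (~padded[:-2, 1:-1]).astype(int)
            + (~padded[2:, 1:-1]).astype(int)
            + (~padded[1:-1, :-2]).astype(int)
            + (~padded[1:-1, 2:]).astype(int)
        )
        self.wall_face_count = nbr_wall[self.active].astype(float) - open_port_face_count
        self.wall_face_count = np.maximum(self.wall_face_count, 0.0)

    def _diffusivity_per_cell(self, species: str) -> np.ndarray:
        table = self.tp.diffusivity[species]
        d = np.empty(self.n)
        for mat, val in table.items():
            d[self.labels_active == mat] = val
        return d

    def _assemble_species(self, species: str) -> sp.csr_matrix:
        iL, iR, F, mL, mR = self._faces
        table = self.tp.diffusivity[species]
        dL = np.vectorize(table.__getitem__)(mL).astype(float)
        dR = np.vectorize(table.__getitem__)(mR).astype(float)
        Df = 2.0 * dL * dR / (dL + dR)
        T = Df / self.dx_m**2
        rows = np.concatenate([iL, iL, iR, iR])
        cols = np.concatenate([iL, iR, iR, iL])
        vals = np.concatenate([T, -T, T, -T])
        A = self._adv + sp.csr_matrix((vals, (rows, cols)), shape=(self.n, self.n))

        d_cell = self._diffusivity_per_cell(species)
        diag = np.zeros(self.n)
        b_in_adv = np.zeros(self.n)  # × c_inlet
        b_in_diff = np.zeros(self.n)
        V = self.cell_volume
        for k, q in self.inflow_faces:
            # advective influx carries the reservoir concentration (upwind
            # value at an inflow face): RHS only, no diagonal term
            b_in_adv[k] += q / V
            Tg = 2.0 * d_cell[k] / self.dx_m**2
            diag[k] += Tg
            b_in_diff[k] += Tg
        for outs in self.outflow_faces.values():
            for k, q in outs:
                diag[k] += q / V
        wall = np.zeros(self.n)
        if species == "O2" and self.tp.pdms_o2_mode == "dirichlet":
            wall = self.wall_face_count * 2.0 * d_cell / self.dx_m**2
        elif species == "O2" and self.tp.pdms_o2_mode == "robin":
            wall = self.wall_face_count * self.tp.robin_coefficient / self.dx_m
        diag += wall
        self._b_in_adv[species] = b_in_adv
        self._b_in_diff[species] = b_in_diff
        self._b_wall[species] = wall
        return A + sp.diags(diag)

    # -- boundary RHS -------------------------------------------------------

    def inlet_concentration(self, species: str, glc_in: float) -> float:
        if species == "GLC":
            return glc_in
        if species == "O2":
            return self.tp.c_atm if self.tp.inlet_o2 is None else self.tp.inlet_o2
        return 0.0

    def boundary_rhs(self, species: str, glc_in: float) -> np.ndarray:
        c_in = self.inlet_concentration(species, glc_in)
        b = (self._b_in_adv[species] + self._b_in_diff[species]) * c_in
        if species == "O2":
            b = b + self._b_wall[species] * self.tp.c_atm
        return b

    # -- kinetics -----------------------------------------------------------

    def _reaction_substep(self, c_o2, c_glc):
        """Pointwise-implicit Michaelis–Menten consumption in islet cells.

        Solving c + Δt·R·c/(c+K) = c₀ per cell (positive quadratic root)
        is unconditionally stable and cannot undershoot zero.  Returns
        updated fields and the consumed amounts (mol).
        """
        kp, dt = self.kp, self.dt
        m = self.islet_mask
        alive = m & (c_o2 > kp.c_O2_crit)
        consumed = {"O2": 0.0, "GLC": 0.0}
        for name, c, Rmax, Km in (
            ("O2", c_o2, kp.R_O2_max, kp.K_M_O2),
            ("GLC", c_glc, kp.R_GLC_max, kp.K_M_GLC),
        ):
            if Rmax <= 0:
                continue
            R_eff = Rmax
            if name == "O2" and kp.o2_glucose_modulation:
                R_eff = Rmax * c_glc[alive] / (c_glc[alive] + kp.K_M_GLC)
            c0 = c[alive]
            B = Km + dt * R_eff - c0
            c_new = 0.5 * (-B + np.sqrt(B * B + 4.0 * Km * c0))
            consumed[name] = float((c0 - c_new).sum()) * self.cell_volume
            c[alive] = c_new
        return c_o2, c_glc, consumed

    def _reaction_substep_glc_only(self, c_o2, c_glc):
        kp, dt = self.kp, self.dt
        if kp.R_GLC_max <= 0:
            return c_o2, c_glc, 0.0
        alive = self.islet_mask & (c_o2 > kp.c_O2_crit)
        c0 = c_glc[alive]
        Km = kp.K_M_GLC
        B = Km + dt * kp.R_GLC_max - c0
        c_new = 0.5 * (-B + np.sqrt(B * B + 4.0 * Km * c0))
        consumed = float((c0 - c_new).sum()) * self.cell_volume
        c_glc[alive] = c_new
        return c_o2, c_glc, consumed

    def insulin_source(self, c_o2, c_glc, kcl_active: bool, dglc_dt=None) -> np.ndarray:
        """Volumetric insulin secretion rate per active cell (mol·m⁻³·s⁻¹)."""
        kp = self.kp
        r = np.zeros(self.n)
        m = self.islet_mask
        _, _, r_ins = islet_rates(c_o2[m], c_glc[m], kp, kcl_active)
        r[m] = r_ins
        if not kcl_active and dglc_dt is not None and kp.first_phase_gain > 0:
            alive = m & (c_o2 > kp.c_O2_crit)
            r[alive] += kp.first_phase_gain * np.maximum(dglc_dt[alive], 0.0)
        return r

    # -- stepping -----------------------------------------------------------

    def step(
        self,
        state: SpeciesState,
        glc_in: float,
        kcl_active: bool = False,
        islet_columns: np.ndarray | None = None,
    ) -> tuple[SpeciesState, StepRecord]:
        """Advance one Δt: reaction substep, then implicit transport.

        ``islet_columns`` — optional (n_cells, k) weight matrix; column j
        masks which islet cells secrete into insulin field j (1.0 = full
        secretion).  Defaults to the single all-islet column.
        """
        dt = self.dt
        c_o2 = state.c_O2.copy()
        c_glc = state.c_GLC.copy()
        if self.freeze_o2:
            # stationary O2: account for consumption at the MM rate only
            m = self.islet_mask & (c_o2 > self.kp.c_O2_crit)
            r_o2, _, _ = islet_rates(c_o2[m], c_glc[m], self.kp, kcl_active)
            consumed = {"O2": float(r_o2.sum()) * self.cell_volume * dt, "GLC": 0.0}
            _, c_glc, consumed_glc = self._reaction_substep_glc_only(c_o2, c_glc)
            consumed["GLC"] = consumed_glc
        else:
            c_o2, c_glc, consumed = self._reaction_substep(c_o2, c_glc)

        r_ins = self.insulin_source(c_o2, c_glc, kcl_active, state.dglc_dt)
        secreted_per_vol = r_ins  # mol·m⁻³·s⁻¹

        new = {}
        if self.freeze_o2:
            new["O2"] = state.c_O2
        for s, c in (("O2", c_o2), ("GLC", c_glc)):
            if s in new:
                continue
            rhs = c / dt + self.boundary_rhs(s, glc_in)
            new[s] = self._lu_step[s].solve(rhs)
        c_ins = state.c_INS
        if c_ins.ndim == 1:
            src = r_ins if islet_columns is None else r_ins * np.asarray(islet_columns).ravel()
        else:
            cols = (
                islet_columns
                if islet_columns is not None
                else np.ones((self.n, c_ins.shape[1]))
            )
            src = r_ins[:, None] * cols
        new["INS"] = self._lu_step["INS"].solve(c_ins / dt + src)

        for s in SPECIES:
            if not np.all(np.isfinite(new[s])):
                raise StabilityError(
                    f"non-finite {s} concentration; reduce dt or check the flow field"
                )

        out_flux = {s: 0.0 for s in SPECIES}
        for outs in self.outflow_faces.values():
            for k, q in outs:
                out_flux["O2"] += q * new["O2"][k]
                out_flux["GLC"] += q * new["GLC"][k]
                out_flux["INS"] = out_flux["INS"] + q * new["INS"][k]
        # inlet mass flux: advective plus the Dirichlet-ghost diffusive
        # exchange, both evaluated consistently with the implicit step so
        # the species mass balance closes to round-off
        q_adv = float(sum(q for _, q in self.inflow_faces))
        in_flux = {}
        for s in SPECIES:
            c_in = self.inlet_concentration(s, glc_in)
            c_new_s = new[s] if s != "INS" or new[s].ndim == 1 else new[s][:, -1]
            diff_exchange = float(
                np.sum(self._b_in_diff[s] * (c_in - c_new_s)) * self.cell_volume
            )
            in_flux[s] = q_adv * c_in + diff_exchange
        secreted = float(secreted_per_vol.sum()) * self.cell_volume
        rec = StepRecord(
            time=state.time + dt,
            outlet_flux=out_flux,
            inlet_flux=in_flux,
            consumed={"O2": consumed["O2"] / dt, "GLC": consumed["GLC"] / dt, "INS": secreted},
        )
        dglc = (new["GLC"] - state.c_GLC) / dt
        return (
            SpeciesState(state.time + dt, new["O2"], new["GLC"], new["INS"], dglc),
            rec,
        )

    # -- steady states ------------------------------------------------------

    def _steady_lu(self, species: str):
        if species not in self._lu_steady:
            self._lu_steady[species] = spla.splu(self._ops[species].tocsc())
        return self._lu_steady[species]

    def _steady_mm(
        self,
        species: str,
        c_in: float,
        Rmax: float,
        Km: float,
        sink_mask: np.ndarray,
        modulation: np.ndarray | None = None,
        tol: float = 1e-9,
        max_iter: int = 500,
    ) -> np.ndarray:
        """Steady field with a Michaelis–Menten sink, by damped Picard
        iteration on the sink strength against a single factorized
        operator.  Damping (θ = 0.5) settles cells where demand exceeds
        supply, which would otherwise toggle between full consumption and
        shutdown; the solve itself reuses the cached LU of the steady
        advection–diffusion operator."""
        lu = self._steady_lu(species)
        b0 = self.boundary_rhs(species, c_in)
        if Rmax <= 0 or not sink_mask.any():
            return lu.solve(b0)
        s = np.zeros(self.n)
        theta = 0.5
        c = np.full(self.n, c_in)
        for _ in range(max_iter):
            c = np.maximum(lu.solve(b0 - s), 0.0)
            s_new = np.zeros(self.n)
            s_new[sink_mask] = Rmax * c[sink_mask] / (c[sink_mask] + Km)
            if modulation is not None:
                s_new[sink_mask] *= modulation[sink_mask]
            delta = float(np.abs(s_new - s).max()) / Rmax
            s = s + theta * (s_new - s)
            if delta < tol:
                return c
        raise RuntimeError(f"steady {species} Picard iteration did not converge")

    def oxygen_steady_state(self, c_glc: np.ndarray | None = None) -> np.ndarray:
        """Steady advection–diffusion–consumption oxygen field."""
        kp = self.kp
        modulation = None
        if kp.o2_glucose_modulation and c_glc is not None:
            modulation = c_glc / (c_glc + kp.K_M_GLC)
        return self._steady_mm(
            "O2", self.tp.c_atm, kp.R_O2_max, kp.K_M_O2, self.islet_mask, modulation
        )

    def glucose_steady_state(self, glc_in: float, c_o2: np.ndarray) -> np.ndarray:
        kp = self.kp
        alive = self.islet_mask & (c_o2 > kp.c_O2_crit)
        return self._steady_mm("GLC", glc_in, kp.R_GLC_max, kp.K_M_GLC, alive)

    def steady_state(
        self, glc_in: float, islet_columns: np.ndarray | None = None
    ) -> SpeciesState:
        """Coupled steady fields at a constant inlet glucose — the state
        of a device perfused long enough at one medium composition.

        Used as the initial condition for GSIS runs, standing in for the
        basal pre-perfusion hour.
        """
        c_o2 = self.oxygen_steady_state()
        c_glc = self.glucose_steady_state(glc_in, c_o2)
        if self.kp.o2_glucose_modulation:
            c_o2 = self.oxygen_steady_state(c_glc)
            c_glc = self.glucose_steady_state(glc_in, c_o2)
        r = self.insulin_source(c_o2, c_glc, kcl_active=False, dglc_dt=None)
        lu = self._steady_lu("INS")
        if islet_columns is None:
            c_ins = lu.solve(r)
        else:
            c_ins = lu.solve(r[:, None] * islet_columns)
        c_ins = np.maximum(c_ins, 0.0)
        return SpeciesState(0.0, c_o2, c_glc, c_ins, np.zeros(self.n))

    # -- convenience --------------------------------------------------------

    def field_on_grid(self, values: np.ndarray, fill=np.nan) -> np.ndarray:
        out = np.full(self.grid.shape, fill)
        out[self.active] = values
        return out

    def islet_column_matrix(self, n_islets: int) -> np.ndarray:
        """(n_cells, n_islets+1) weights: column k isolates islet k's
        secretion; the last column is the all-islet configuration."""
        cols = np.zeros((self.n, n_islets + 1))
        for k in range(n_islets):
            cols[self.islet_ids == k, k] = 1.0
        cols[self.islet_mask, n_islets] = 1.0
        return cols


@dataclass
class TransientResult:
    """Raw transient output: per-step effluent fluxes and snapshots."""

    times: np.ndarray  # s, end of each step
    outlet_flux: dict  # species -> (n_steps,) or (n_steps, k) mol/s
    inlet_flux: dict  # species -> (n_steps,) mol/s
    reaction_rate: dict  # species -> (n_steps,) mol/s (consumption; secretion for INS)
    final_state: SpeciesState
    snapshots: dict  # time (s) -> {"O2": grid array, ...}


def run_transient(
    system: TransportSystem,
    initial: SpeciesState,
    schedule_fn,
    t_end: float,
    islet_columns: np.ndarray | None = None,
    snapshot_times: tuple = (),
) -> TransientResult:
    """Integrate from ``initial.time`` to ``t_end`` (seconds).

    ``schedule_fn(t)`` must return ``(inlet glucose mM, kcl_active)``; it
    is evaluated at each step's midpoint so a composition switch takes
    effect for the step that starts at the switch time, not the one
    ending there.  Outlet advective fluxes are recorded at every step
    for downstream 10-minute binning.
    """
    state = initial
    dt = system.dt
    n_steps = int(round((t_end - initial.time) / dt))
    times = np.empty(n_steps)
    k_cols = 1 if state.c_INS.ndim == 1 else state.c_INS.shape[1]
    out = {
        "O2": np.empty(n_steps),
        "GLC": np.empty(n_steps),
        "INS": np.empty((n_steps, k_cols)) if k_cols > 1 else np.empty(n_steps),
    }
    inn = {s: np.empty(n_steps) for s in SPECIES}
    rxn = {s: np.empty(n_steps) for s in SPECIES}
    snaps = {}
    snap_left = sorted(snapshot_times)
    for i in range(n_steps):
        glc_in, kcl = schedule_fn(state.time + 0.5 * dt)
        state, rec = system.step(state, glc_in, kcl, islet_columns)
        times[i] = rec.time
        for s in SPECIES:
            if s == "INS" and k_cols > 1:
                out[s][i] = rec.outlet_flux[s]
            else:
                out[s][i] = float(np.asarray(rec.outlet_flux[s]).sum())
            inn[s][i] = rec.inlet_flux[s]
            rxn[s][i] = rec.consumed.get(s, 0.0)
        while snap_left and rec.time >= snap_left[0] - 1e-9:
            t_snap = snap_left.pop(0)
            c_ins = state.c_INS if state.c_INS.ndim == 1 else state.c_INS[:, -1]
            snaps[t_snap] = {
                "O2": system.field_on_grid(state.c_O2),
                "GLC": system.field_on_grid(state.c_GLC),
                "INS": system.field_on_grid(c_ins),
            }
    return TransientResult(
        times=times,
        outlet_flux=out,
        inlet_flux=inn,
        reaction_rate=rxn,
        final_state=state,
        snapshots=snaps,
    )
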