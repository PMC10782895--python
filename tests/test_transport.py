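"""Transport solver: kinetics, closed-form oracles, conservation."""

import numpy as np
import pytest
from scipy.special import erfc

import isletvmo as vmo
from isletvmo.flow import FlowField, solve_flow
from isletvmo.geometry import GEL, ISLET, LUMEN
from isletvmo.transport import (
    KineticParams,
    KineticsError,
    SpeciesState,
    TransportSystem,
    islet_rates,
    run_transient,
)

from conftest import end_ports, make_slab_grid


def still_flow(grid) -> FlowField:
    """Zero-velocity flow field on a closed (all-wall-boundary) grid."""
    nx, ny = grid.shape
    return FlowField(
        grid=grid,
        pressure=np.zeros((nx, ny)),
        face_flux_x=np.zeros((nx + 1, ny)),
        face_flux_y=np.zeros((nx, ny + 1)),
        port_fluxes={},
        port_faces={},
        port_pressures={},
        open_ports=frozenset(),
    )


class TestIsletRates:
    def test_hypoxic_shutdown(self):
        kp = KineticParams()
        r = islet_rates(0.0, 16.7, kp)
        assert r == (0.0, 0.0, 0.0)

    def test_hill_half_max_identity(self):
        kp = KineticParams(basal_secretion_fraction=0.0)
        _, _, r_ins = islet_rates(0.2, kp.K_INS, kp)
        assert r_ins == pytest.approx(kp.R_INS_max / 2.0)

    def test_saturation_limits(self):
        kp = KineticParams(basal_secretion_fraction=0.0)
        _, r_glc, r_ins = islet_rates(0.2, 1e6, kp)
        assert r_ins == pytest.approx(kp.R_INS_max, rel=1e-6)
        assert r_glc == pytest.approx(kp.R_GLC_max, rel=1e-4)

    def test_kcl_forces_max_release(self):
        kp = KineticParams()
        _, _, r_low = islet_rates(0.2, 0.0, kp, kcl_active=True)
        assert r_low == pytest.approx(kp.R_INS_max * kp.kcl_mode_rate_fraction)

    def test_negative_input_rejected(self):
        with pytest.raises(KineticsError):
            islet_rates(-0.1, 5.0, KineticParams())

    def test_o2_consumption_michaelis_menten(self):
        kp = KineticParams()
        r_o2, _, _ = islet_rates(kp.K_M_O2, 5.5, kp)
        assert r_o2 == pytest.approx(kp.R_O2_max / 2.0)


class TestStepBasics:
    def test_uniform_state_is_stationary(self):
        # no islets, no flow, closed walls: nothing changes
        grid = make_slab_grid(40, 10, GEL)
        sys_ = TransportSystem(grid, still_flow(grid), dt=2.0)
        c0 = np.full(sys_.n, 3.3)
        state = SpeciesState(0.0, c0.copy(), c0.copy(), c0.copy())
        for _ in range(5):
            state, _ = sys_.step(state, glc_in=0.0)
        assert np.allclose(state.c_GLC, 3.3, rtol=1e-12)
        assert np.allclose(state.c_INS, 3.3, rtol=1e-12)

    def test_positivity(self):
        grid = make_slab_grid(40, 10, GEL)
        sys_ = TransportSystem(grid, still_flow(grid), dt=2.0)
        c = np.zeros(sys_.n)
        c[:20] = 10.0  # sharp front
        state = SpeciesState(0.0, np.full(sys_.n, 0.2), c.copy(), c.copy())
        for _ in range(20):
            state, _ = sys_.step(state, glc_in=0.0)
            assert state.c_GLC.min() >= -1e-12
            assert state.c_INS.min() >= -1e-12


class TestClosedForms:
    def test_erfc_diffusion_profile(self):
        # half-domain step in still gel vs the self-similar erfc solution
        nx, ny, spacing = 400, 3, 10.0
        grid = make_slab_grid(nx, ny, GEL, spacing=spacing)
        dt, t_end, c0 = 1.0, 200.0, 10.0
        sys_ = TransportSystem(grid, still_flow(grid), dt=dt)
        D = sys_.tp.diffusivity["GLC"][GEL]
        c = np.zeros((nx, ny))
        c[: nx // 2, :] = c0
        state = SpeciesState(0.0, np.full(sys_.n, 0.2), c[sys_.active], c[sys_.active] * 0)
        for _ in range(int(t_end / dt)):
            state, _ = sys_.step(state, glc_in=0.0)
        x = (np.arange(nx) + 0.5) * spacing * 1e-6
        x0 = (nx // 2) * spacing * 1e-6
        analytic = 0.5 * c0 * erfc((x - x0) / (2 * np.sqrt(D * t_end)))
        numeric = sys_.field_on_grid(state.c_GLC)[:, 1]
        interior = (analytic > 0.02 * c0) & (analytic < 0.98 * c0)
        assert np.max(np.abs(numeric[interior] - analytic[interior])) < 0.02 * c0

    def test_advected_pulse_centroid(self):
        # top-hat pulse in a uniform lumen channel moves at |u|·t
        nx, ny, spacing = 400, 6, 10.0
        grid = make_slab_grid(nx, ny, LUMEN, spacing=spacing)
        ports = end_ports(nx, ny, spacing, 1.22e-2, 0.0)  # u ≈ 1e-4 m/s
        fld = solve_flow(grid, ports)
        area = ny * spacing * 1e-6 * grid.depth * 1e-6
        u = fld.face_flux_x[nx // 2, :].sum() / area
        dt, t_end = 0.5, 10.0
        sys_ = TransportSystem(grid, fld, dt=dt)
        xs = (np.arange(nx) + 0.5) * spacing
        c = np.where((xs >= 500) & (xs < 600), 5.0, 0.0)[:, None] * np.ones((1, ny))
        state = SpeciesState(0.0, np.full(sys_.n, 0.2), c[sys_.active], c[sys_.active] * 0)
        m0 = (sys_.field_on_grid(state.c_GLC)[:, 0] * xs).sum() / c[:, 0].sum()
        for _ in range(int(t_end / dt)):
            state, _ = sys_.step(state, glc_in=0.0)
        prof = sys_.field_on_grid(state.c_GLC)[:, 0]
        m1 = (prof * xs).sum() / prof.sum()
        assert abs((m1 - m0) * 1e-6 - u * t_end) < spacing * 1e-6

    def test_conservative_tracer_washout(self):
        # constant inlet, after >=5 residence times outlet ≈ inlet
        nx, ny, spacing = 200, 6, 10.0
        grid = make_slab_grid(nx, ny, LUMEN, spacing=spacing)
        ports = end_ports(nx, ny, spacing, 0.1, 0.0)
        fld = solve_flow(grid, ports)
        sys_ = TransportSystem(grid, fld, dt=1.0)
        state = SpeciesState(0.0, np.full(sys_.n, 0.2), np.zeros(sys_.n), np.zeros(sys_.n))
        area = ny * spacing * 1e-6 * grid.depth * 1e-6
        u = fld.face_flux_x[nx // 2, :].sum() / area
        residence = nx * spacing * 1e-6 / u
        res = run_transient(sys_, state, lambda t: (7.0, False), t_end=8 * residence)
        q_out = sum(q for outs in sys_.outflow_faces.values() for _, q in outs)
        c_out = res.outlet_flux["GLC"][-1] / q_out
        assert c_out == pytest.approx(7.0, rel=0.01)

    def test_glucose_mass_audit(self, small_device, small_grid, small_flow):
        # inlet − outlet − consumption − accumulation = 0 (to round-off,
        # well inside the 0.5% contract)
        sys_ = TransportSystem(small_grid, small_flow, dt=5.0)
        state0 = sys_.steady_state(5.5)
        V = sys_.cell_volume
        m0 = state0.c_GLC.sum() * V
        res = run_transient(sys_, state0, lambda t: (16.7, False), t_end=600.0)
        m1 = res.final_state.c_GLC.sum() * V
        dt = sys_.dt
        inlet = res.inlet_flux["GLC"].sum() * dt
        outlet = res.outlet_flux["GLC"].sum() * dt
        consumed = res.reaction_rate["GLC"].sum() * dt
        residual = inlet - outlet - consumed - (m1 - m0)
        assert abs(residual) < 0.005 * inlet
        assert abs(residual) < 1e-9 * inlet  # conservative discretization


class TestOxygenSteadyState:
    def test_no_islets_uniform_atmospheric(self):
        grid = make_slab_grid(60, 20, GEL)
        sys_ = TransportSystem(grid, still_flow(grid))
        c = sys_.oxygen_steady_state()
        assert np.allclose(c, sys_.tp.c_atm, rtol=1e-8)

    def _one_islet_system(self, Rmax=None):
        nx, ny, spacing = 80, 80, 10.0
        grid = make_slab_grid(nx, ny, GEL, spacing=spacing)
        X, Y = np.meshgrid(
            (np.arange(nx) + 0.5) * spacing, (np.arange(ny) + 0.5) * spacing, indexing="ij"
        )
        disc = (X - 400) ** 2 + (Y - 400) ** 2 <= 60.0**2
        grid.labels[disc] = ISLET
        grid.islet_id[disc] = 0
        kp = KineticParams() if Rmax is None else KineticParams(R_O2_max=Rmax)
        return grid, TransportSystem(grid, still_flow(grid), kp=kp)

    def test_minimum_inside_islet(self):
        grid, sys_ = self._one_islet_system()
        c = sys_.oxygen_steady_state()
        field = sys_.field_on_grid(c)
        kmin = np.unravel_index(np.nanargmin(field), field.shape)
        assert grid.labels[kmin] == ISLET

    def test_doubling_consumption_lowers_oxygen(self):
        _, sys1 = self._one_islet_system()
        _, sys2 = self._one_islet_system(Rmax=2 * KineticParams().R_O2_max)
        c1 = sys1.oxygen_steady_state()
        c2 = sys2.oxygen_steady_state()
        assert np.all(c2 <= c1 + 1e-10)


class TestOxygenWallModes:
    def test_robin_wall_bounded_by_dirichlet(self):
        """A finite PDMS film coefficient supplies less oxygen than the
        equilibrium wall, so islet oxygen is lower but still positive."""
        nx, ny, spacing = 60, 60, 10.0

        def build(mode):
            grid = make_slab_grid(nx, ny, GEL, spacing=spacing)
            X, Y = np.meshgrid(
                (np.arange(nx) + 0.5) * spacing,
                (np.arange(ny) + 0.5) * spacing,
                indexing="ij",
            )
            disc = (X - 300) ** 2 + (Y - 300) ** 2 <= 50.0**2
            grid.labels[disc] = ISLET
            grid.islet_id[disc] = 0
            from isletvmo.transport import TransportParams

            tp = TransportParams(pdms_o2_mode=mode, robin_coefficient=1e-6)
            return TransportSystem(grid, still_flow(grid), tp=tp)

        c_dir = build("dirichlet").oxygen_steady_state()
        c_rob = build("robin").oxygen_steady_state()
        assert np.all(c_rob <= c_dir + 1e-9)
        assert c_rob.min() >= 0.0
        assert c_rob.max() <= build("robin").tp.c_atm + 1e-9


class TestInsulinLinearity:
    def test_outlet_insulin_additive_over_sources(self, small_device, small_grid, small_flow):
        """Multi-column advance: per-islet columns sum to the all-islet
        column exactly (insulin feeds back on nothing)."""
        n_islets = len(small_device.islets)
        sys_ = TransportSystem(small_grid, small_flow, dt=5.0)
        cols = sys_.islet_column_matrix(n_islets)
        state = sys_.steady_state(5.5, islet_columns=cols)
        state = SpeciesState(0.0, state.c_O2, state.c_GLC, state.c_INS, state.dglc_dt)
        res = run_transient(
            sys_, state, lambda t: (16.7, False), t_end=300.0, islet_columns=cols
        )
        flux = res.outlet_flux["INS"]  # (steps, n_islets+1)
        total = flux[:, -1]
        summed = flux[:, :-1].sum(axis=1)
        denom = np.linalg.norm(total)
        assert np.linalg.norm(summed - total) / denom < 1e-10

    def test_single_column_matches_separate_run(self, small_device, small_grid, small_flow):
        """A column advanced in the multi-field pass equals an actual
        separate run with the other islets' secretion zeroed."""
        n_islets = len(small_device.islets)
        sys_ = TransportSystem(small_grid, small_flow, dt=5.0)
        cols = sys_.islet_column_matrix(n_islets)
        st = sys_.steady_state(5.5, islet_columns=cols)
        res_multi = run_transient(
            sys_, st, lambda t: (16.7, False), t_end=200.0, islet_columns=cols
        )
        # separate single-field run: only islet 0 secretes
        single_col = cols[:, [0]]
        st1 = sys_.steady_state(5.5, islet_columns=single_col)
        st1 = SpeciesState(st1.time, st1.c_O2, st1.c_GLC, st1.c_INS[:, 0], st1.dglc_dt)
        res_single = run_transient(
            sys_,
            st1,
            lambda t: (16.7, False),
            t_end=200.0,
            islet_columns=cols[:, [0]],
        )
        assert np.allclose(
            res_multi.outlet_flux["INS"][:, 0], res_single.outlet_flux["INS"], rtol=1e-12
        )
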