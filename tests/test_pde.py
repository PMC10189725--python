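"""Simulator correctness: grid construction, maximum principle, analytic limits."""

import numpy as np
import pytest

from cuticle_uptake import (
    ConcentrationField,
    ConfigurationError,
    DiskCylinderGeom,
    GridSpec,
    build_grid,
    cottrell_rate,
    crank_rate,
    cylinder_rate,
    shoup_szabo_rate,
    simulate_1d,
    simulate_uptake,
    step_implicit,
)

SPEC_SMALL = GridSpec(T_min=1e-2, T_max=1.0, steps_per_decade=20)


class TestGridSpec:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"T_min": 1e-2, "T_max": 1e-3},
            {"T_min": 1e-2, "T_max": 1.0, "n_z": 4},
            {"T_min": 1e-2, "T_max": 1.0, "r_expansion": 1.5},
            {"T_min": 1e-2, "T_max": 1.0, "solver": "gmres"},
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            GridSpec(**kwargs)

    def test_ramp_starts_two_decades_early(self):
        assert SPEC_SMALL.T_start == pytest.approx(1e-4)


class TestBuildGrid:
    def test_node_set_structure(self):
        grid = build_grid(1.0, SPEC_SMALL)
        r, z = grid.r, grid.z
        assert r[0] == 0.0 and z[0] == 0.0
        assert np.any(np.isclose(r, 1.0))
        assert r[-1] >= 1.0 + 6.0 * np.sqrt(SPEC_SMALL.T_max) - 1e-9
        assert z[-1] == pytest.approx(1.0)
        assert np.all(np.diff(r) > 0) and np.all(np.diff(z) > 0)
        # geometric growth away from the edge never exceeds the expansion factor
        dr = np.diff(r)
        ratios = dr[1:] / dr[:-1]
        # within [0, 1] spacing shrinks toward the edge; within [1, R_max] it grows
        seg_in = r[1:-1] <= 1.0
        assert np.all(1.0 / ratios[seg_in] < SPEC_SMALL.r_expansion + 1e-9)
        seg_out = r[1:-1] > 1.0
        assert np.all(ratios[seg_out] < SPEC_SMALL.r_expansion + 1e-9)

    def test_thin_cuticle_node_budget(self):
        spec = GridSpec(T_min=1e-10, T_max=1e-4, steps_per_decade=40)
        grid = build_grid(1.1111e-4, spec)
        assert len(grid.z) >= 9  # at least 8 layers
        assert grid.n_nodes < 5e5

    def test_rejects_coarse_h_min(self):
        with pytest.raises(ConfigurationError):
            build_grid(1.0, GridSpec(T_min=1e-2, T_max=1.0, h_min=0.5))

    def test_rejects_small_R_max(self):
        with pytest.raises(ConfigurationError):
            build_grid(1.0, GridSpec(T_min=1e-2, T_max=1.0, R_max=2.0))

    def test_grid_convergence_of_final_mass(self):
        """Doubling n_z and halving h_min moves M(T_end) by < 0.5%."""
        Z = 1e-3
        spec = GridSpec(
            T_min=1e-6, T_max=1e-4, steps_per_decade=30, richardson=False
        )
        coarse = simulate_uptake(Z, spec)
        fine_spec = GridSpec(
            T_min=1e-6, T_max=1e-4, steps_per_decade=30, richardson=False,
            n_z=2 * spec.n_z, h_min=min(Z / 4, 1e-3) / 2,
        )
        fine = simulate_uptake(Z, fine_spec)
        assert coarse.M[-1] == pytest.approx(fine.M[-1], rel=5e-3)


class TestStepImplicit:
    def test_saturated_state_is_stationary(self):
        grid = build_grid(0.5, SPEC_SMALL)
        field = ConcentrationField(grid, np.ones(grid.shape))
        out = step_implicit(field, dT=0.1)
        assert np.allclose(out.values, 1.0, atol=1e-12)

    def test_maximum_principle_from_zero_start(self):
        grid = build_grid(0.5, SPEC_SMALL)
        field = ConcentrationField.initial(grid)
        out = step_implicit(field, dT=0.05)
        out.validate()
        assert out.values.min() >= -1e-12
        assert out.values.max() <= 1.0 + 1e-12

    def test_two_half_steps_beat_one_full_step(self):
        """Halving the step shrinks the full-vs-two-half-steps defect."""
        grid = build_grid(0.5, SPEC_SMALL)
        # smooth the impulsive start before measuring consistency
        f0 = ConcentrationField.initial(grid)
        for dT in (0.01, 0.02, 0.05, 0.1):
            f0 = step_implicit(f0, dT)

        def defect(dT):
            full = step_implicit(f0, dT)
            half = step_implicit(step_implicit(f0, dT / 2), dT / 2)
            return np.max(np.abs(full.values - half.values))

        assert defect(0.1) < defect(0.2)

    def test_first_order_convergence_in_time(self):
        """Global rate error vs the plane-sheet series halves with the step
        (the premise of the Richardson pass)."""
        from cuticle_uptake import crank_rate, simulate_1d

        g = DiskCylinderGeom(1.0)

        def max_err(spd):
            spec = GridSpec(
                T_min=1e-2, T_max=0.3, steps_per_decade=spd,
                richardson=False, dT_cap_factor=np.inf,
            )
            c = simulate_1d(1.0, spec)
            return np.max(np.abs(c.rate / crank_rate(c.T, g) - 1))

        ratio = max_err(20) / max_err(40)
        assert 1.5 < ratio < 3.0

    def test_rejects_nonpositive_step(self):
        grid = build_grid(0.5, SPEC_SMALL)
        with pytest.raises(Exception):
            step_implicit(ConcentrationField.initial(grid), dT=0.0)


class TestSimulate2D:
    def test_thick_cuticle_matches_shoup_szabo(self, sim_z10):
        """Z_max = 10 reproduces disk-into-half-space kinetics within 1%."""
        err = np.abs(sim_z10.rate / shoup_szabo_rate(sim_z10.T) - 1)
        assert err.max() < 0.01

    def test_thin_cuticle_long_time_matches_cylinder(self, sim_thin):
        """Z_max = 0.01 rate converges to the rim-cylinder limit within 2%."""
        g = DiskCylinderGeom(0.01)
        sel = sim_thin.T >= 0.01
        err = np.abs(sim_thin.rate[sel] / cylinder_rate(sim_thin.T[sel], g) - 1)
        assert err.max() < 0.02

    def test_mass_exceeds_saturated_column(self, sim_thin):
        """Radial spread carries M beyond the saturated-cylinder volume pi*Z."""
        assert sim_thin.M[-1] > np.pi * 0.01

    def test_monotone_mass_positive_rate(self, sim_thin):
        sim_thin.validate()
        assert np.all(np.diff(sim_thin.M) >= 0)
        assert np.all(sim_thin.rate > 0)

    def test_mass_balance_identity(self, sim_thin, sim_z10):
        for c in (sim_thin, sim_z10):
            assert c.diagnostics["mass_balance_residual"] < 1e-6

    def test_rate_extraction_routes_agree(self, sim_z10):
        """Boundary-flux and dM/dT rate estimates coincide where significant."""
        assert sim_z10.diagnostics["rate_agreement_max_reldiff"] < 0.1

    def test_transition_ratio_at_half_Zsq(self, sim_thin, sim_z1e3_transition):
        """Rate/Cottrell at T = 0.5 Z^2 sits near the theta-series value 0.73."""
        for Z, sim in ((0.01, sim_thin), (1e-3, sim_z1e3_transition)):
            T_tr = 0.5 * Z**2
            ratio = sim.rate_at(T_tr) / cottrell_rate(T_tr)
            assert 0.65 < ratio < 0.80


class TestSimulate1D:
    def test_matches_crank_series(self, curve_1d_unit):
        """Plane-sheet mode agrees with the analytic series within 0.5%."""
        g = DiskCylinderGeom(1.0)
        err = np.abs(curve_1d_unit.rate / crank_rate(curve_1d_unit.T, g) - 1)
        assert err.max() < 0.005

    def test_final_mass_saturates_slab(self, curve_1d_unit):
        """M(infinity) -> A_d * Z_max (the fully saturated column under the disk)."""
        assert curve_1d_unit.M[-1] == pytest.approx(np.pi * 1.0, rel=1e-3)

    def test_rate_at_transition(self, curve_1d_unit):
        T_tr = 0.5
        ratio = curve_1d_unit.rate_at(T_tr) / cottrell_rate(T_tr)
        assert ratio == pytest.approx(0.730, abs=0.01)


class TestBicgstabSolver:
    def test_alternative_solver_agrees_with_direct(self):
        spec_d = GridSpec(T_min=1e-2, T_max=0.1, steps_per_decade=10, richardson=False)
        spec_k = GridSpec(
            T_min=1e-2, T_max=0.1, steps_per_decade=10,
            richardson=False, solver="bicgstab",
        )
        a = simulate_uptake(0.5, spec_d)
        b = simulate_uptake(0.5, spec_k)
        assert np.allclose(a.rate, b.rate, rtol=1e-6)
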