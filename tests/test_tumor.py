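"""Nodule transport: Starling sink terms and the axisymmetric solver."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import erfc

from hipecpk.boundary import generate_boundary
from hipecpk.metrics import auc
from hipecpk.tumor import (
    NoduleGeometry,
    axis_profile,
    peclet_factor,
    peclet_number,
    sink,
    solve_host_column,
    solve_nodule,
    vascular_rate_coefficient,
)

from .conftest import constant_boundary


class TestPecletNumber:
    def test_tabulated_tumor_constants_give_small_negative_peclet(self, tumor_params):
        """Direct arithmetic on the printed constants: the elevated
        interstitial pressure of the 2 mm nodule slightly exceeds the
        Starling driving pressure, so the transvascular Péclet number is
        a small negative value (net resorption)."""
        expected = 2.10e-11 * (2080.0 - 1400.0 - 0.82 * (2670.0 - 1330.0)) * 0.05 / 1.43e-6
        pe = peclet_number(tumor_params)
        assert pe == pytest.approx(expected)
        assert pe == pytest.approx(-3.1e-4, rel=0.02)

    def test_perfect_reflection_zeroes_convection(self, tumor_params):
        assert peclet_number(dataclasses.replace(tumor_params, sigma=1.0)) == 0.0

    def test_zero_driving_pressure_zeroes_peclet(self, tumor_params):
        p_i = tumor_params.P_v - tumor_params.c_osm * (tumor_params.pi_v - tumor_params.pi_i)
        assert peclet_number(dataclasses.replace(tumor_params, P_i=p_i)) == pytest.approx(0.0)

    def test_undefined_without_permeability(self, tumor_params):
        with pytest.raises(ValueError):
            peclet_number(dataclasses.replace(tumor_params, P_c=0.0))


class TestPecletFactor:
    def test_removable_singularity(self):
        assert peclet_factor(0.0) == 1.0

    def test_unit_peclet(self):
        assert peclet_factor(1.0) == pytest.approx(1.0 / (np.e - 1.0))

    def test_series_branch_continuous(self):
        assert peclet_factor(9.9e-7) == pytest.approx(peclet_factor(1.1e-6), rel=1e-6)

    @given(
        p1=st.floats(min_value=-20.0, max_value=20.0),
        p2=st.floats(min_value=-20.0, max_value=20.0),
    )
    def test_strictly_decreasing(self, p1, p2):
        lo, hi = sorted((p1, p2))
        if hi - lo > 1e-9:
            assert peclet_factor(lo) > peclet_factor(hi)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            peclet_factor(float("inf"))


class TestSinkTerm:
    def test_linear_in_concentration(self, tumor_params):
        assert sink(0.0, tumor_params, 40.0) == 0.0
        s1 = sink(0.08, tumor_params, 40.0)
        assert sink(0.16, tumor_params, 40.0) == pytest.approx(2.0 * s1)

    def test_pure_cellular_elimination_without_permeability(self, tumor_params):
        p = dataclasses.replace(tumor_params, P_c=0.0)
        assert sink(0.16, p, 40.0) == pytest.approx(7.32e-4 * 0.16)

    def test_hyperthermia_reduces_vascular_washout_by_y_ratio(self, tumor_params):
        p = dataclasses.replace(tumor_params, beta=0.0)  # isolate the vascular term
        ratio = sink(0.16, p, 43.0) / sink(0.16, p, 37.0)
        assert ratio == pytest.approx(0.717105 / 1.000005, rel=1e-9)

    def test_avascular_tissue_has_no_washout(self, tumor_params):
        p = dataclasses.replace(tumor_params, S_over_V=0.0)
        assert vascular_rate_coefficient(p, 40.0) == 0.0

    def test_negative_concentration_rejected(self, tumor_params):
        with pytest.raises(ValueError):
            sink(-0.1, tumor_params, 40.0)


class TestGeometry:
    def test_tumor_volume_is_exact_sphere(self, control_field):
        """The boundary-fitted mesh tiles the tumor sphere exactly."""
        a = control_field.geometry.radius
        assert control_field.tumor_volume == pytest.approx(4.0 / 3.0 * np.pi * a**3, rel=1e-12)

    def test_axis_profile_spans_pole_to_far_host(self, control_field):
        depth, conc = axis_profile(control_field)
        assert np.all(np.diff(depth) > 0)
        assert depth[0] < control_field.geometry.mesh_spacing
        assert depth[-1] > control_field.geometry.tumor_diameter
        assert conc[0] > conc[depth < 2e-3][-1]  # decays into the nodule

    def test_overly_coarse_mesh_rejected(self):
        with pytest.raises(ValueError):
            NoduleGeometry(mesh_spacing=5.0e-4)


class TestNoduleSolver:
    def test_zero_boundary_yields_zero_field(self, small_geometry, tumor_params, host_params):
        fld = solve_nodule(
            small_geometry, tumor_params, host_params, constant_boundary(0.0),
            t_f=60.0, dt=5.0,
        )
        assert np.all(fld.concentration == 0.0)
        assert auc(fld) == 0.0

    def test_linearity_in_perfusate_dose(self, small_geometry, tumor_params, host_params):
        """Doubling the boundary concentration doubles the concentration
        at every node and time (the transport PDE is linear)."""
        f1 = solve_nodule(small_geometry, tumor_params, host_params,
                          constant_boundary(0.16), t_f=300.0, dt=5.0, snapshot_every=30)
        f2 = solve_nodule(small_geometry, tumor_params, host_params,
                          constant_boundary(0.32), t_f=300.0, dt=5.0, snapshot_every=30)
        np.testing.assert_allclose(f2.concentration, 2.0 * f1.concentration, rtol=1e-10)

    def test_discrete_mass_balance(self, control_field):
        """Boundary influx − sink losses = content change, within 0.5 %."""
        assert control_field.mass_residual <= 5e-3

    def test_early_time_axis_matches_semi_infinite_erfc(self, sinkless_params):
        """Pure diffusion from a constant boundary follows the half-space
        closed form C0 erfc(x / 2 sqrt(D t)). Evaluated on a nodule large
        enough that the exposed pole is locally flat (depths much smaller
        than the radius), where the 1-D solution applies."""
        tp, hp = sinkless_params
        geom = NoduleGeometry(tumor_diameter=4.0e-2, mesh_spacing=2.5e-4, host_extent=2.0e-3)
        fld = solve_nodule(geom, tp, hp, constant_boundary(0.16), t_f=60.0, dt=0.2,
                           snapshot_every=300)
        depth, conc = axis_profile(fld)
        m = (depth > 0) & (depth <= 3.0e-4)
        exact = 0.16 * erfc(depth[m] / (2.0 * np.sqrt(3.0e-9 * 60.0)))
        assert np.max(np.abs(conc[m] - exact) / exact) <= 0.02

    @pytest.mark.parametrize("attr,factor,direction", [
        ("P_c", 2.0, "down"), ("beta", 2.0, "down"), ("S_over_V", 2.0, "down"),
        ("D", 2.0, "up"),
    ])
    def test_exposure_monotone_in_transport_parameters(
        self, small_geometry, tumor_params, host_params, intestine_boundary,
        attr, factor, direction,
    ):
        """Stronger washout or elimination lowers tumor exposure; faster
        diffusion raises it (drug enters through the exposed surface)."""
        base = solve_nodule(small_geometry, tumor_params, host_params,
                            intestine_boundary, dt=4.0, snapshot_every=450)
        mod = dataclasses.replace(tumor_params, **{attr: getattr(tumor_params, attr) * factor})
        out = solve_nodule(small_geometry, mod, host_params,
                           intestine_boundary, dt=4.0, snapshot_every=450)
        if direction == "down":
            assert auc(out) < auc(base)
        else:
            assert auc(out) > auc(base)

    def test_hyperthermia_raises_exposure_at_fixed_boundary(
        self, small_geometry, tumor_params, host_params, intestine_boundary
    ):
        """Raising tissue temperature from 37 to 43 °C shrinks the washout
        factor y(T) below 1 and strictly increases tumor AUC."""
        cold = solve_nodule(small_geometry, tumor_params, host_params,
                            intestine_boundary, dt=4.0, temperature=37.0, snapshot_every=450)
        hot = solve_nodule(small_geometry, tumor_params, host_params,
                           intestine_boundary, dt=4.0, temperature=43.0, snapshot_every=450)
        assert auc(hot) > auc(cold)

    def test_host_shields_less_than_hindered_tumor(
        self, small_geometry, tumor_params, host_params, intestine_boundary
    ):
        """Next to a high-hindrance (dense-collagen) nodule the adjacent
        normal tissue ends up holding more drug than the tumor core."""
        from hipecpk.params import apply_stiffness

        dense = apply_stiffness(tumor_params, "high")
        fld = solve_nodule(small_geometry, dense, host_params, intestine_boundary,
                           dt=4.0, snapshot_every=450)
        C = fld.concentration[-1]
        rad = np.sqrt(fld.r**2 + fld.z**2)
        core = C[(fld.region == 1) & (rad < 0.3e-3)].mean()
        adjacent = C[(fld.region == 2) & (rad < 1.3e-3)].max()
        assert adjacent > core

    def test_grid_refinement_convergence(self, tumor_params, host_params, intestine_boundary):
        """Halving the mesh spacing moves tumor AUC by less than 1 %."""
        aucs = []
        for mesh in (1.0e-4, 5.0e-5):
            geom = NoduleGeometry(mesh_spacing=mesh, host_extent=3.0e-3)
            fld = solve_nodule(geom, tumor_params, host_params, intestine_boundary,
                               dt=2.0, snapshot_every=900)
            aucs.append(auc(fld))
        assert abs(aucs[1] - aucs[0]) / aucs[0] < 0.01

    def test_boundary_must_cover_horizon(self, small_geometry, tumor_params, host_params):
        short = constant_boundary(0.16)
        short = dataclasses.replace(
            short, times=np.array([0.0, 600.0]),
            surface_concentration=np.array([0.16, 0.16]),
        )
        with pytest.raises(ValueError):
            solve_nodule(small_geometry, tumor_params, host_params, short, t_f=1800.0)
        with pytest.raises(ValueError):
            solve_nodule(small_geometry, tumor_params, host_params,
                         constant_boundary(0.16), dt=-1.0)


class TestHostColumnOracle:
    def test_production_column_matches_forward_euler_brute_force(self, tumor_params):
        """On a coarse 10-node 1-D reduction, the implicit production
        solver and an independently written explicit brute-force stepper
        agree within 0.1 %."""
        n, depth, t_f = 10, 1.0e-3, 300.0
        h = depth / n
        cb, T = 0.16, 40.1
        # independent re-derivation of the first-order loss coefficient
        pe = 2.10e-11 * (2080.0 - 1400.0 - 0.82 * 1340.0) * 0.05 / 1.43e-6
        y = -0.04715 * T + 2.744555
        k = 7.32e-4 + 1.43e-6 * 2.0e4 * (pe / np.expm1(pe)) * y
        D = 3.0e-9
        dt_fe = 0.02
        C = np.zeros(n)
        for _ in range(int(t_f / dt_fe)):
            dC = np.zeros(n)
            dC[0] = D * (C[1] - C[0]) / h**2 + 2.0 * D * (cb - C[0]) / h**2 - k * C[0]
            dC[1:-1] = D * np.diff(C, 2) / h**2 - k * C[1:-1]
            dC[-1] = D * (C[-2] - C[-1]) / h**2 - k * C[-1]
            C = C + dt_fe * dC
        col = solve_host_column(
            tumor_params, constant_boundary(cb, T), t_f=t_f, dt=0.05,
            depth=depth, n_cells=n,
        )
        np.testing.assert_allclose(col["conc"], C, rtol=1e-3)
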