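"""Monodomain solver: geometry, stability, limits and strand CV."""

import numpy as np
import pytest

from atrisim.ionic import (
    CellParameters, DomainError, REFERENCE_ELECTROLYTES, rest_state,
)
from atrisim.monodomain import (
    ConfigurationError, Geometry1D, Geometry2D, StimulusEvent, TissueResult,
    solve_monodomain, strand_cv, strand_cv_protocol,
)


class TestGeometry:
    def test_one_cm_strand_at_100um_has_101_nodes(self):
        assert Geometry1D(length_cm=1.0, dx_um=100.0).n_nodes == 101

    def test_noninteger_node_count_rejected(self):
        with pytest.raises(ConfigurationError):
            Geometry1D(length_cm=1.0, dx_um=130.0)

    def test_region_ids_must_cover_nodes(self):
        with pytest.raises(ConfigurationError):
            Geometry2D(nx=5, ny=5, spacing_um=500.0,
                       region_id=np.zeros(7, dtype=int))


class TestSolverGuards:
    def test_cfl_violation_raises_before_stepping(self):
        geom = Geometry1D(length_cm=0.5, dx_um=100.0)
        mask = np.zeros(geom.n_nodes, bool)
        mask[0] = True
        with pytest.raises(ConfigurationError):
            solve_monodomain(geom, CellParameters(), REFERENCE_ELECTROLYTES,
                             [StimulusEvent(mask, 0.0, 2.0, 30.0)],
                             t_end=10.0, dt=0.5)

    def test_empty_stimulus_mask_rejected(self):
        with pytest.raises(DomainError):
            StimulusEvent(np.zeros(5, bool), 0.0, 2.0, 30.0)


class TestDecoupledLimit:
    def test_zero_coupling_reproduces_0d(self, healthy_params):
        """With zero conductivity and a simultaneous global stimulus, every
        node follows the 0-D trace."""
        from atrisim.protocols0d import PacingSpec, record_ap
        geom = Geometry1D(length_cm=0.2, dx_um=200.0)
        n = geom.n_nodes
        mask = np.ones(n, bool)
        res = solve_monodomain(
            geom, healthy_params, REFERENCE_ELECTROLYTES,
            [StimulusEvent(mask, 10.0, 2.0, 23.0)], t_end=400.0, dt=0.025,
            record_window=(0.0, 400.0), out_dt=0.5,
            strand_conductivity=1e-12)
        tr = record_ap(rest_state(), healthy_params, REFERENCE_ELECTROLYTES,
                       PacingSpec(cl_ms=400.0, n_beats=1), n_beats=1,
                       out_dt=0.5, pre_ms=10.0)
        nt = min(res.vm.shape[0], tr.V.size)
        for node in range(n):
            assert np.max(np.abs(res.vm[:nt, node] - tr.V[:nt])) < 0.5

    def test_no_flux_conservation(self):
        """Zero ionic current, no stimulus: the spatial mean of Vm is
        conserved by the no-flux diffusion operator."""
        passive = CellParameters(g_na=0, g_k1=0, g_to=0, g_kur=0, g_kr=0,
                                 g_ks=0, g_cal=0, g_bca=0, g_bna=0,
                                 i_nak_max=0, i_naca_max=0, i_cap_max=0)
        geom = Geometry2D(nx=21, ny=21, spacing_um=500.0)
        rng = np.random.default_rng(0)
        Y = np.tile(rest_state(), (geom.n_nodes, 1))
        Y[:, 0] = rng.uniform(-90.0, 0.0, geom.n_nodes)
        res = solve_monodomain(geom, passive, REFERENCE_ELECTROLYTES, [],
                               t_end=50.0, dt=0.05, initial_states=Y,
                               record_window=(0.0, 50.0), out_dt=5.0)
        means = res.vm.astype(np.float64).mean(axis=1)
        assert np.max(np.abs(means - Y[:, 0].mean())) < 1e-4


class TestStrandCV:
    def test_synthetic_plane_wave_exact(self):
        """LAT(x) = x / theta yields CV = theta exactly."""
        geom = Geometry1D(length_cm=1.0, dx_um=100.0)
        theta = 0.7  # m/s = mm/ms
        t = np.arange(0.0, 40.0, 0.1)
        x_mm = geom.x_cm * 10.0
        lat = x_mm / theta
        vm = np.where(t[:, None] >= lat[None, :], 20.0, -80.0).astype(np.float32)
        res = TissueResult(geometry=geom, t=t, vm=vm, dt=0.1,
                           act_times=np.empty((0, 0)), act_count=np.empty(0),
                           final_max_v=np.empty(0))
        cv, blocked = strand_cv(res)
        assert not blocked
        assert cv == pytest.approx(theta, rel=0.02)

    def test_two_point_matches_regression(self, healthy_strand):
        """The two-point CV equals the least-squares LAT-vs-x slope within
        1 % for uniform propagation."""
        from atrisim.biomarkers import lat_from_vm
        cv, blocked, res = healthy_strand
        assert not blocked
        lat = lat_from_vm(res)
        x_mm = res.geometry.x_cm * 10.0
        sel = (x_mm >= 2.0) & (x_mm <= 8.0) & np.isfinite(lat)
        slope = np.polyfit(lat[sel], x_mm[sel], 1)[0]
        assert abs(slope - cv) / cv < 0.01

    def test_healthy_cv_in_physiological_band(self, healthy_strand):
        cv, blocked, _ = healthy_strand
        assert 0.6 <= cv <= 0.8

    def test_block_reported_as_flag(self, healthy_params):
        """A stimulus too weak to capture yields the block flag, not a CV."""
        geom = Geometry1D(length_cm=0.5, dx_um=100.0)
        mask = geom.x_cm <= 0.05
        res = solve_monodomain(geom, healthy_params, REFERENCE_ELECTROLYTES,
                               [StimulusEvent(mask, 0.0, 0.5, 1.0)],
                               t_end=60.0, dt=0.02, record_window=(0.0, 60.0),
                               out_dt=0.5)
        cv, blocked = strand_cv(res, probes_cm=(0.125, 0.375))
        assert blocked and np.isnan(cv)

    def test_dx_halving_changes_cv_below_2pc(self, healthy_params,
                                             baseline_lc):
        """Spatial convergence: halving dx moves the measured CV < 2 %."""
        _, _, pre = baseline_lc
        cv_fine = {}
        for dx in (100.0, 50.0):  # same dt so only dx varies
            cv, blocked, _ = strand_cv_protocol(
                healthy_params, REFERENCE_ELECTROLYTES, cl_ms=1000.0,
                geometry=Geometry1D(length_cm=1.0, dx_um=dx), dt=0.005,
                n_beats=1, prepaced_state=pre.state)
            assert not blocked
            cv_fine[dx] = cv
        assert abs(cv_fine[50.0] - cv_fine[100.0]) / cv_fine[100.0] < 0.02


class TestSymmetry:
    def test_mirrored_substrate_mirrors_lat(self, healthy_params):
        """Mirror-symmetric sheet + stimulus gives a mirror-symmetric LAT
        map."""
        from atrisim.biomarkers import lat_from_vm
        geom = Geometry2D(nx=31, ny=21, spacing_um=500.0)
        mask = np.zeros((21, 31), bool)
        mask[:, 14:17] = True  # symmetric central stripe
        res = solve_monodomain(geom, healthy_params, REFERENCE_ELECTROLYTES,
                               [StimulusEvent(mask.reshape(-1), 0.0, 2.0, 60.0)],
                               t_end=80.0, dt=0.05,
                               record_window=(0.0, 80.0), out_dt=0.5)
        lat = lat_from_vm(res).reshape(21, 31)
        assert np.allclose(lat, lat[:, ::-1], atol=1e-9, equal_nan=True)
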