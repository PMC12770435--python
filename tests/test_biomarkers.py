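"""Activation/repolarisation maps, CV maps and QoI summaries."""

import numpy as np
import pytest

from atrisim.biomarkers import (
    ActivationMaps, activation_repolarisation_maps, cv_map_from_lat,
    lat_from_vm, summarise_qoi,
)
from atrisim.ionic import DomainError
from atrisim.monodomain import Geometry1D, Geometry2D, TissueResult


def _plane_wave_result(theta=0.6, apd=200.0):
    """Synthetic strand recording: plane wave at speed theta (mm/ms) with a
    sigmoid upstroke/repolarisation AP of duration ``apd``."""
    geom = Geometry1D(length_cm=1.0, dx_um=100.0)
    t = np.arange(0.0, 400.0, 0.5)
    x_mm = geom.x_cm * 10.0
    lat = 5.0 + x_mm / theta
    up = 1.0 / (1.0 + np.exp(-(t[:, None] - lat[None, :]) / 0.6))
    down = 1.0 / (1.0 + np.exp(-(t[:, None] - lat[None, :] - apd) / 2.0))
    vm = (-80.0 + 95.0 * (up - down)).astype(np.float32)
    return geom, t, vm, lat


class TestActivationMaps:
    def test_plane_wave_lat_linear(self):
        geom, t, vm, lat_true = _plane_wave_result()
        res = TissueResult(geom, t, vm, 0.5, np.empty((0, 0)), np.empty(0),
                           np.empty(0))
        maps = activation_repolarisation_maps(res)
        interior = slice(2, -2)
        fit = np.polyfit(geom.x_cm[interior], maps.lat[interior], 1)
        assert fit[0] == pytest.approx(10.0 / 0.6 / 1.0, rel=0.02)  # ms per cm

    def test_apd90_equals_lrt_minus_lat(self, healthy_strand):
        _, _, res = healthy_strand
        maps = activation_repolarisation_maps(res)
        ok = maps.valid
        assert np.allclose(maps.apd90[ok], maps.lrt[ok] - maps.lat[ok],
                           atol=1e-9)

    def test_lat_agrees_with_threshold_crossing(self, healthy_strand):
        """argmax dV/dt agrees with the -40 mV upstroke crossing within
        1 ms on healthy tissue."""
        _, _, res = healthy_strand
        lat = lat_from_vm(res)
        vm = res.vm.astype(np.float64)
        t = res.t
        for node in range(5, res.geometry.n_nodes - 5, 10):
            above = np.flatnonzero(vm[:, node] >= -40.0)
            t_thr = t[above[0]]
            assert abs(lat[node] - t_thr) < 1.0

    def test_empty_window_rejected(self, healthy_strand):
        _, _, res = healthy_strand
        with pytest.raises(DomainError):
            activation_repolarisation_maps(res, window=(1e6, 2e6))


class TestCvMap:
    def test_constant_speed_field(self):
        geom, t, vm, _ = _plane_wave_result(theta=0.5)
        res = TissueResult(geom, t, vm, 0.5, np.empty((0, 0)), np.empty(0),
                           np.empty(0))
        maps = activation_repolarisation_maps(res)
        cv = cv_map_from_lat(maps, geom)
        interior = cv[2:-2]
        assert np.nanmedian(interior) == pytest.approx(0.5, rel=0.05)

    def test_point_stimulus_radial_speed(self, healthy_params):
        """Circular wave from a point stimulus: the CV map approximates the
        radial propagation speed from an LAT-vs-radius regression."""
        from atrisim.ionic import REFERENCE_ELECTROLYTES
        from atrisim.monodomain import StimulusEvent, solve_monodomain
        iso = tuple((0.28, 0.28) for _ in range(6))  # circular wavefront
        geom = Geometry2D(nx=41, ny=41, spacing_um=500.0, conductivities=iso)
        mask = np.zeros((41, 41), bool)
        mask[19:22, 19:22] = True
        res = solve_monodomain(geom, healthy_params, REFERENCE_ELECTROLYTES,
                               [StimulusEvent(mask.reshape(-1), 0.0, 2.0, 60.0)],
                               t_end=120.0, dt=0.05, record_window=(0.0, 120.0),
                               out_dt=0.5)
        maps = activation_repolarisation_maps(res)
        cv = cv_map_from_lat(maps, geom)
        xs = (np.arange(41) - 20) * 0.5
        R = np.hypot(xs[None, :], xs[:, None]).reshape(-1)
        sel = (R > 3.0) & (R < 8.0) & np.isfinite(maps.lat)
        slope = np.polyfit(maps.lat[sel], R[sel], 1)[0]  # radial speed mm/ms
        assert np.nanmedian(cv[sel]) == pytest.approx(slope, rel=0.15)

    def test_all_invalid_rejected(self):
        maps = ActivationMaps(lat=np.full(9, np.nan), lrt=np.full(9, np.nan),
                              apd90=np.full(9, np.nan), cv=None,
                              valid=np.zeros(9, bool))
        with pytest.raises(DomainError):
            cv_map_from_lat(maps, Geometry2D(nx=3, ny=3, spacing_um=500.0))


class TestSummaries:
    def _maps(self, apd, cv):
        n = apd.size
        return ActivationMaps(lat=np.zeros(n), lrt=apd.copy(), apd90=apd,
                              cv=cv, valid=np.ones(n, bool))

    def test_constant_apd_zero_dispersion(self):
        maps = self._maps(np.full(50, 210.0), np.full(50, 0.7))
        s = summarise_qoi(maps)
        assert s.DAPD == 0.0
        assert s.mAPD == 210.0

    def test_percentiles_match_bruteforce(self):
        rng = np.random.default_rng(3)
        apd = rng.uniform(150, 300, 501)
        cv = rng.uniform(0.3, 0.9, 501)
        s = summarise_qoi(self._maps(apd, cv))
        # brute force: sort and linearly interpolate order statistics
        def brute(x, q):
            xs = np.sort(x)
            pos = q / 100.0 * (xs.size - 1)
            i = int(np.floor(pos))
            f = pos - i
            return xs[i] * (1 - f) + xs[min(i + 1, xs.size - 1)] * f
        assert s.mAPD == pytest.approx(brute(apd, 50.0), abs=1e-9)
        assert s.DAPD == pytest.approx(brute(apd, 97.5) - brute(apd, 2.5), abs=1e-9)
        assert s.DCV == pytest.approx(brute(cv, 97.5) - brute(cv, 2.5), abs=1e-9)

    def test_node_permutation_invariance(self):
        rng = np.random.default_rng(5)
        apd = rng.uniform(150, 300, 100)
        cv = rng.uniform(0.3, 0.9, 100)
        s1 = summarise_qoi(self._maps(apd, cv))
        perm = rng.permutation(100)
        s2 = summarise_qoi(self._maps(apd[perm], cv[perm]))
        assert s1.as_dict() == s2.as_dict()

    def test_relative_qoi_of_baseline_is_zero(self):
        rng = np.random.default_rng(7)
        maps = self._maps(rng.uniform(150, 300, 60), rng.uniform(0.3, 0.9, 60))
        base = summarise_qoi(maps)
        s = summarise_qoi(maps, baseline=base)
        assert (s.rel_mAPD, s.rel_mCV, s.rel_DAPD, s.rel_DCV) == (0, 0, 0, 0)

    def test_exactly_four_qois(self):
        maps = self._maps(np.full(20, 200.0), np.full(20, 0.6))
        base_keys = [k for k in summarise_qoi(maps).as_dict() if not k.startswith("rel_")]
        assert base_keys == ["mAPD", "mCV", "DAPD", "DCV"]

    def test_too_few_valid_nodes_rejected(self):
        maps = self._maps(np.full(5, 200.0), np.full(5, 0.6))
        with pytest.raises(DomainError):
            summarise_qoi(maps)
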