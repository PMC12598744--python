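"""Fixation-plane geometry, the two-density dart-throwing sampler, the
evaluation loop and continuous map construction."""

import numpy as np
import pytest

from ocugaze.errors import FeasibilityError, MapError, OptimizationError
from ocugaze.fixation import angles_from_plane, plane_from_angles
from ocugaze.geometry import feasible_disk_radius
from ocugaze.sampler import (EvaluationRecord, EvaluationSettings, SamplerConfig,
                             build_map, evaluate_fixation, run_optimization,
                             sample_candidates)

RMAX = feasible_disk_radius()


class TestPlaneAngles:
    def test_axis_point(self):
        fx = plane_from_angles(0.0, 123.0)
        assert (fx.x, fx.y) == (0.0, 0.0)

    def test_polar_limit_point(self):
        fx = plane_from_angles(25.0, 0.0)
        assert fx.x == pytest.approx(132.5 * np.tan(np.radians(25.0)), abs=1e-9)
        assert fx.x == pytest.approx(61.79, abs=0.01)
        assert fx.y == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("polar,azimuth", [(5, 10), (17.3, 212.7), (25, 359.9)])
    def test_round_trip(self, polar, azimuth):
        fx = plane_from_angles(polar, azimuth)
        back = angles_from_plane(fx.x, fx.y)
        assert back.polar == pytest.approx(polar, abs=1e-9)
        assert back.azimuth == pytest.approx(azimuth, abs=1e-9)

    def test_outside_disk_rejected(self):
        with pytest.raises(FeasibilityError):
            angles_from_plane(RMAX + 1.0, 0.0)


class TestSampleCandidates:
    @pytest.mark.parametrize("seed", range(100))
    def test_spacing_constraints_hold(self, seed):
        cfg = SamplerConfig(seed=seed)
        pred = plane_from_angles(22.0, (seed * 37) % 360)
        cands = sample_candidates(pred, cfg)
        pts = np.array([[c.x, c.y] for c in cands])
        d_pred = np.linalg.norm(pts - pred.xy, axis=1)
        n_dense = int(np.sum(d_pred <= cfg.dense_radius + 1e-9))
        dense, sparse = pts[:n_dense], pts[n_dense:]
        # all candidates feasible
        assert np.all(np.linalg.norm(pts, axis=1) <= RMAX + 1e-9)
        # dense block precedes sparse block and is ordered nearest-first
        assert np.all(np.diff(d_pred[:n_dense]) >= -1e-9)
        if len(sparse):
            assert np.all(np.linalg.norm(sparse - pred.xy, axis=1) > cfg.dense_radius)
        # pairwise spacings
        def min_pair(a, b=None):
            b = a if b is None else b
            d = np.linalg.norm(a[:, None] - b[None], axis=2)
            if a is b:
                d = d + np.eye(len(a)) * 1e9
            return d.min() if d.size else np.inf
        assert min_pair(dense) >= cfg.dense_spacing - 1e-9
        if len(sparse) > 1:
            assert min_pair(sparse) >= cfg.sparse_spacing - 1e-9
        if len(sparse) and len(dense):
            assert min_pair(sparse, dense) >= cfg.cross_spacing - 1e-9

    def test_first_candidate_is_the_prediction(self):
        pred = plane_from_angles(20.0, 100.0)
        cands = sample_candidates(pred, SamplerConfig(seed=1))
        assert cands[0].x == pytest.approx(pred.x)
        assert cands[0].y == pytest.approx(pred.y)

    def test_mean_count_near_thirtyfive(self):
        counts = []
        for seed in range(50):
            pred = plane_from_angles(20 + (seed % 5), (seed * 53) % 360)
            counts.append(len(sample_candidates(pred, SamplerConfig(seed=seed))))
        assert 28 <= np.mean(counts) <= 42

    def test_halving_spacings_roughly_quadruples(self):
        big, small = [], []
        for seed in range(20):
            pred = plane_from_angles(20.0, seed * 18.0)
            big.append(len(sample_candidates(pred, SamplerConfig(seed=seed))))
            small.append(len(sample_candidates(pred, SamplerConfig(
                seed=seed, dense_spacing=4.5, sparse_spacing=12.5, cross_spacing=4.5,
                dense_attempts=800, sparse_attempts=600))))
        assert np.mean(small) > 2.5 * np.mean(big)


class TestRunOptimization:
    def test_single_candidate_is_best(self, small_patient, coarse_settings):
        pred = plane_from_angles(20.0, 30.0)
        cfg = SamplerConfig(seed=0, max_evaluations=1)
        res = run_optimization(small_patient, prediction=pred,
                               settings=coarse_settings, config=cfg)
        assert len(res.records) == 1
        assert res.best is res.records[0]

    def test_best_is_argmin_of_evaluations(self, small_patient, coarse_settings):
        """Oracle identity: without early stopping the optimizer's best equals
        the argmin over every treatable candidate it evaluated."""
        pred = plane_from_angles(20.0, 300.0)
        res = run_optimization(small_patient, prediction=pred,
                               settings=coarse_settings, config=SamplerConfig(seed=3))
        costs = [r.cost for r in res.treatable_records]
        assert res.best.cost == min(costs)
        assert all(res.best.cost <= c for c in costs)

    def test_record_order_is_queue_order(self, small_patient, coarse_settings):
        res = run_optimization(small_patient, prediction=plane_from_angles(15, 10),
                               settings=coarse_settings, config=SamplerConfig(seed=5))
        assert [r.index for r in res.records] == list(range(len(res.records)))

    def test_untreatable_everywhere_raises_with_diagnostics(self, small_patient,
                                                            coarse_settings):
        from dataclasses import replace

        s = replace(coarse_settings, beam_kwargs={"distal_margin": 30.0})
        with pytest.raises(OptimizationError) as exc:
            run_optimization(small_patient, prediction=plane_from_angles(15, 10),
                             settings=s, config=SamplerConfig(seed=2))
        assert len(exc.value.reasons) > 0
        assert all("range" in r for r in exc.value.reasons.values())

    def test_early_stop_truncates(self, small_patient, coarse_settings):
        cfg_full = SamplerConfig(seed=9)
        cfg_stop = SamplerConfig(seed=9, early_stop_patience=3)
        pred = plane_from_angles(20.0, 120.0)
        full = run_optimization(small_patient, prediction=pred,
                                settings=coarse_settings, config=cfg_full)
        stopped = run_optimization(small_patient, prediction=pred,
                                   settings=coarse_settings, config=cfg_stop)
        assert len(stopped.records) <= len(full.records)


class TestGazeMap:
    def _records(self, values):
        rng = np.random.default_rng(0)
        recs = []
        for i, v in enumerate(values):
            r, phi = 40 * np.sqrt(rng.uniform()), rng.uniform(0, 2 * np.pi)
            fx = angles_from_plane(r * np.cos(phi), r * np.sin(phi))
            recs.append(EvaluationRecord(fixation=fx, treatable=True, index=i,
                                         cost=float(v),
                                         ntcp={"maculopathy": float(v)}))
        return recs

    def test_constant_field(self):
        gm = build_map(self._records(np.full(12, 7.0)), "cost")
        assert gm(5.0, -3.0) == pytest.approx(7.0)
        assert gm(55.0, 30.0) == pytest.approx(7.0)   # outside hull: nearest

    def test_exact_at_samples(self):
        vals = np.arange(12, dtype=float)
        recs = self._records(vals)
        gm = build_map(recs, "cost")
        for r in recs:
            assert gm(r.fixation.x, r.fixation.y) == pytest.approx(r.cost, abs=1e-9)

    def test_edge_midpoint_is_mean_of_endpoints(self):
        """Linear interpolation along a triangulation edge."""
        from scipy.spatial import Delaunay

        vals = np.arange(15, dtype=float) ** 1.5
        recs = self._records(vals)
        gm = build_map(recs, "cost")
        tri = Delaunay(gm.points)
        i, j = tri.simplices[0][0], tri.simplices[0][1]
        mid = (gm.points[i] + gm.points[j]) / 2
        assert gm(mid[0], mid[1]) == pytest.approx((gm.values[i] + gm.values[j]) / 2,
                                                   abs=1e-9)

    def test_ntcp_quantity_and_errors(self):
        recs = self._records(np.linspace(0, 10, 8))
        gm = build_map(recs, "maculopathy")
        assert gm.quantity == "maculopathy"
        with pytest.raises(MapError):
            build_map(recs[:2], "cost")
        with pytest.raises(MapError):
            build_map(recs, "no_such_quantity")

    def test_raster_export_shape(self):
        gm = build_map(self._records(np.linspace(1, 5, 10)), "cost")
        raster = gm.raster(spacing=10.0)
        assert raster.shape[1] == 3
        assert np.all(np.hypot(raster[:, 0], raster[:, 1]) <= RMAX + 1e-9)
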