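"""The registration potential, its gradients, the minimizer, and anchors."""

import numpy as np
import pytest
from scipy.spatial import Delaunay

from retmap.mesh import FlatMap
from retmap.registration import (AnchorSet, AnchorWeightConfig,
                                 MinimizerConfig, RegistrationSystem,
                                 SingularityError, anchor_potential,
                                 angle_potential, build_anchors,
                                 edge_potential, minimize,
                                 perimeter_potential, total_gradient,
                                 total_potential)


def random_system(seed, n=30, spread=3.0):
    rng = np.random.default_rng(seed)
    pts = rng.random((n, 2)) * spread
    tri = Delaunay(pts)
    # drop slivers that would start close to the angle singularity
    fm = FlatMap(pts, tri.simplices)
    from retmap.mesh import corner_angles
    a = corner_angles(pts, fm.angle_triples)
    if a.min() < 0.05:
        return None
    return RegistrationSystem(fm)


def some_system(seed=0, n=30):
    s = None
    while s is None:
        s = random_system(seed, n)
        seed += 1
    return s


class Bare:
    """Minimal stand-in system for single-element hand evaluations."""

    def __init__(self, **kw):
        self.edges = kw.get("edges", np.empty((0, 2), int))
        self.r0 = kw.get("r0", np.empty(0))
        self.q0 = kw.get("q0", 0.0)
        self.q1 = kw.get("q1", np.empty(0))
        self.triples = kw.get("triples", np.empty((0, 3), int))
        self.a0 = kw.get("a0", np.empty(0))
        self.perimeter = kw.get("perimeter", np.empty(0, int))
        self.x0 = kw.get("x0", np.zeros((0, 2)))


class TestHandEvaluableCases:
    def test_reference_configuration_is_zero(self):
        sys = some_system(0)
        assert total_potential(sys.x0, sys, AnchorSet.empty()) == 0.0
        assert np.all(total_gradient(sys.x0, sys, AnchorSet.empty()) == 0.0)

    def test_harmonic_edge_term(self):
        # single edge stretched from 1 to 2 with both walls pushed far
        # away: only the harmonic part remains, 1/2 * (2-1)^2 = 0.5
        sys = Bare(edges=np.array([[0, 1]]), r0=np.array([1.0]),
                   q0=-1e9, q1=np.array([1e9]))
        x = np.array([[0.0, 0.0], [2.0, 0.0]])
        v, _ = edge_potential(x, sys)
        assert abs(v - 0.5) < 1e-6

    def test_infinite_well_edge_term(self):
        # r0=1, r=1.5, q0=0, q1=2 -> Ge = 1/2 [ (1/1.5-1)^2 + (1/0.5-1)^2 ]
        sys = Bare(edges=np.array([[0, 1]]), r0=np.array([1.0]),
                   q1=np.array([2.0]))
        x = np.array([[0.0, 0.0], [1.5, 0.0]])
        v, _ = edge_potential(x, sys)
        he = 0.5 * 0.25
        ge = 5.0 / 9.0
        assert abs(v - (he + ge)) < 1e-12

    def test_angle_terms(self):
        # corner of pi/3 deformed to pi/2:
        # harmonic 1/2 (pi/6)^2, well 1/2[(1/3)^2+(1/3)^2] = 1/9
        sys = Bare(triples=np.array([[0, 1, 2]]), a0=np.array([np.pi / 3]))
        x = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        v, _ = angle_potential(x, sys)
        expect = 0.5 * (np.pi / 6) ** 2 + 1.0 / 9.0
        assert abs(v - expect) < 1e-9

    def test_perimeter_term(self):
        sys = Bare(perimeter=np.array([0]),
                   x0=np.array([[0.0, 0.0], [1.0, 1.0]]))
        x = np.array([[0.3, 0.4], [5.0, 5.0]])  # vertex 1 is interior: free
        v, g = perimeter_potential(x, sys)
        assert abs(v - 0.125) < 1e-15
        assert np.allclose(g[1], 0.0)

    def test_anchor_well(self):
        a = AnchorSet(np.array([0]), np.array([[0.0, 0.0]]),
                      np.array([1.0]), np.array([1.0]))
        v0, _ = anchor_potential(np.array([[0.0, 0.0]]), a)
        assert v0 == -1.0
        v1, _ = anchor_potential(np.array([[1.0, 0.0]]), a)
        assert abs(v1 + np.exp(-1)) < 1e-12
        vfar, _ = anchor_potential(np.array([[50.0, 0.0]]), a)
        assert -1e-12 < vfar <= 0.0

    def test_additivity(self):
        sys = some_system(3)
        rng = np.random.default_rng(0)
        anchors = AnchorSet(np.arange(5), sys.x0[:5] + 0.05,
                            np.full(5, 0.5), rng.random(5))
        x = sys.x0 + rng.normal(0, 0.002, sys.x0.shape)
        parts = (edge_potential(x, sys)[0] + angle_potential(x, sys)[0]
                 + perimeter_potential(x, sys)[0]
                 + anchor_potential(x, anchors)[0])
        assert abs(total_potential(x, sys, anchors) - parts) < 1e-12

    def test_singularity_signals(self):
        sys = Bare(edges=np.array([[0, 1]]), r0=np.array([1.0]),
                   q1=np.array([2.0]))
        with pytest.raises(SingularityError):
            edge_potential(np.array([[0.0, 0.0], [2.5, 0.0]]), sys)
        asys = Bare(triples=np.array([[0, 1, 2]]), a0=np.array([np.pi / 3]))
        with pytest.raises(SingularityError):
            # clockwise (inverted) corner
            angle_potential(np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0]]),
                            asys)


class TestGradients:
    @pytest.mark.parametrize("seed", range(12))
    def test_total_gradient_matches_finite_differences(self, seed):
        sys = some_system(seed * 7, n=10 + (seed * 13) % 40)
        rng = np.random.default_rng(seed)
        k = min(6, sys.n_vertices)
        anchors = AnchorSet(np.arange(k), sys.x0[:k] + 0.03,
                            np.full(k, 0.4), rng.random(k) + 0.1)
        x = sys.x0 + rng.normal(0, 0.002, sys.x0.shape)
        g = total_gradient(x, sys, anchors)
        h = 1e-6
        idx = rng.choice(sys.n_vertices, size=min(8, sys.n_vertices),
                         replace=False)
        for i in idx:
            for c in (0, 1):
                xp = x.copy(); xp[i, c] += h
                xm = x.copy(); xm[i, c] -= h
                fd = (total_potential(xp, sys, anchors)
                      - total_potential(xm, sys, anchors)) / (2 * h)
                denom = max(abs(fd), np.abs(g).max(), 1e-8)
                assert abs(g[i, c] - fd) / denom < 1e-5


class TestMinimizer:
    def test_no_anchors_is_stationary(self):
        sys = some_system(1)
        res = minimize(sys, AnchorSet.empty(),
                       MinimizerConfig(steps=50, noise_scale=0.0))
        assert np.array_equal(res.coordinates, sys.x0)
        assert np.all(res.potential == 0.0)

    def test_single_free_vertex_reaches_anchor(self):
        """One interior vertex, one nearby anchor, negligible deformation
        weight: the vertex settles at the scalar-potential minimum, which a
        1-D line-search oracle places at the anchor point."""
        # star mesh: center vertex 0 surrounded by a hexagon (perimeter)
        ang = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        pts = np.vstack([[0.0, 0.0], np.column_stack([np.cos(ang),
                                                      np.sin(ang)])])
        faces = np.array([[0, 1 + i, 1 + (i + 1) % 6] for i in range(6)])
        fm = FlatMap(pts, faces)
        sys = RegistrationSystem(fm, q1_factor=50.0)
        target = np.array([0.12, 0.05])
        anchors = AnchorSet(np.array([0]), target[None, :],
                            np.array([0.5]), np.array([1e6]))
        res = minimize(sys, anchors,
                       MinimizerConfig(steps=3000, noise_scale=0.0,
                                       max_step=0.01))
        # 1-D oracle along the line from x0 to the anchor
        ts = np.linspace(0, 1.2, 2001)
        vals = [total_potential(
            np.vstack([t * target, pts[1:]]), sys, anchors) for t in ts]
        t_best = ts[int(np.argmin(vals))]
        oracle = t_best * target
        assert np.linalg.norm(res.coordinates[0] - oracle) < 1e-3

    def test_potential_non_increasing_without_noise(self):
        sys = some_system(5)
        rng = np.random.default_rng(2)
        k = min(8, sys.n_vertices)
        anchors = AnchorSet(np.arange(k), sys.x0[:k] + 0.1,
                            np.full(k, 0.3), rng.random(k))
        res = minimize(sys, anchors,
                       MinimizerConfig(steps=300, noise_scale=0.0))
        assert np.all(np.diff(res.potential) <= 0.0)

    def test_seeded_trajectory_is_bit_identical(self):
        sys = some_system(9)
        anchors = AnchorSet(np.arange(4), sys.x0[:4] + 0.08,
                            np.full(4, 0.4), np.full(4, 0.7))
        cfg = MinimizerConfig(steps=120, noise_scale=1.0, seed=77)
        r1 = minimize(sys, anchors, cfg)
        r2 = minimize(sys, anchors, cfg)
        assert np.array_equal(r1.coordinates, r2.coordinates)
        assert np.array_equal(r1.potential, r2.potential)

    def test_admissibility_throughout(self):
        sys = some_system(11)
        rng = np.random.default_rng(3)
        k = min(10, sys.n_vertices)
        anchors = AnchorSet(np.arange(k), sys.x0[:k] + rng.normal(0, 0.2, (k, 2)),
                            np.full(k, 0.3), rng.random(k))
        res = minimize(sys, anchors, MinimizerConfig(steps=400, seed=1))
        adm = res.admissibility
        assert np.all(adm[:, 0] > 0) and np.all(adm[:, 1] < np.pi)
        assert np.all(adm[:, 2] > sys.q0) and np.all(adm[:, 3] < 1.0)

    def test_anchor_weight_monotonicity(self):
        """Heavier anchors pull the single free vertex strictly closer."""
        ang = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        pts = np.vstack([[0.0, 0.0], np.column_stack([np.cos(ang),
                                                      np.sin(ang)])])
        faces = np.array([[0, 1 + i, 1 + (i + 1) % 6] for i in range(6)])
        sys = RegistrationSystem(FlatMap(pts, faces), q1_factor=10.0)
        target = np.array([[0.3, 0.0]])
        dists = []
        for w in (0.05, 0.5, 5.0, 500.0):
            anchors = AnchorSet(np.array([0]), target, np.array([0.4]),
                                np.array([w]))
            res = minimize(sys, anchors,
                           MinimizerConfig(steps=1200, noise_scale=0.0,
                                           max_step=0.01))
            dists.append(np.linalg.norm(res.coordinates[0] - target[0]))
        assert all(b <= a + 1e-12 for a, b in zip(dists, dists[1:]))

    def test_harmonic_term_quadratic_scaling(self):
        """He scales quadratically when a single edge's stretch doubles."""
        sys = Bare(edges=np.array([[0, 1]]), r0=np.array([1.0]),
                   q0=-1e9, q1=np.array([1e9]))
        v1, _ = edge_potential(np.array([[0.0, 0.0], [1.1, 0.0]]), sys)
        v2, _ = edge_potential(np.array([[0.0, 0.0], [1.2, 0.0]]), sys)
        assert abs(v2 / v1 - 4.0) < 1e-9


class TestBuildAnchors:
    def test_anchor_count_per_area(self, small_model, small_dataset):
        from retmap.inference import prepare_subject
        ds = small_dataset
        rs, rdata = prepare_subject(ds.subject, ds.scans[0], resolution=0.35)
        sys = RegistrationSystem(rs)
        anchors = build_anchors(rdata, model=ds.model, sys=sys)
        # every measured vertex gets one anchor per area representing its
        # coordinates; with quarterfield bands that is between 3 and 5
        counts = np.bincount(anchors.vertex, minlength=sys.n_vertices)
        measured = rdata.above(0.1)
        assert counts[measured].min() >= 2
        assert counts[measured].max() <= len(ds.model.areas)
        assert counts[~measured].sum() == 0

    def test_low_variance_vertex_gets_no_anchor(self, small_model):
        from retmap.inference import RetinotopyData
        n = small_model.mesh.n_vertices
        data = RetinotopyData(theta=np.full(n, 90.0), rho=np.full(n, 3.0),
                              size=np.full(n, 1.0), omega=np.full(n, 0.05))
        sys = RegistrationSystem(small_model.mesh)
        anchors = build_anchors(data, small_model, sys)
        assert len(anchors) == 0

    def test_sigma_capped_at_20_epsilon(self, small_model):
        from retmap.inference import RetinotopyData
        n = small_model.mesh.n_vertices
        omega = np.zeros(n)
        omega[0] = 0.9
        # a V1-center measurement: anchors in other areas are far away
        data = RetinotopyData(theta=np.full(n, 90.0), rho=np.full(n, 3.0),
                              size=np.full(n, 0.6), omega=omega)
        sys = RegistrationSystem(small_model.mesh)
        anchors = build_anchors(data, small_model, sys)
        assert len(anchors) >= 2
        assert np.all(anchors.sigma <= 20.0 * sys.epsilon + 1e-12)
        assert np.any(anchors.sigma < 20.0 * sys.epsilon)

    def test_out_of_range_eccentricity_skipped(self, small_model):
        from retmap.inference import RetinotopyData
        n = small_model.mesh.n_vertices
        omega = np.zeros(n)
        omega[0] = 0.9
        data = RetinotopyData(theta=np.full(n, 90.0), rho=np.full(n, 500.0),
                              size=np.full(n, 1.0), omega=omega)
        sys = RegistrationSystem(small_model.mesh)
        anchors = build_anchors(data, small_model, sys)
        assert len(anchors) == 0

    def test_field_sign_mismatch_reduces_weight(self, small_model,
                                                small_dataset):
        from retmap.inference import prepare_subject
        ds = small_dataset
        rs, rdata = prepare_subject(ds.subject, ds.scans[0], resolution=0.35)
        sys = RegistrationSystem(rs)
        with_f = build_anchors(rdata, ds.model, sys,
                               AnchorWeightConfig(use_size=False))
        without = build_anchors(rdata, ds.model, sys,
                                AnchorWeightConfig(use_size=False,
                                                   use_field_sign=False))
        assert len(with_f) == len(without)
        ratio = with_f.weight / without.weight
        assert set(np.round(np.unique(ratio), 6)) <= {0.25, 1.0}
        assert (ratio == 0.25).any()
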