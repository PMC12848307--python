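"""Cortex model: virial-stress oracle, alignment sum rule, mechanics
sanity (fixed point, energy decay, Newton's third law), geometry and
reproducibility."""

import numpy as np
import pytest

from vesselmech.cortex import (
    Region,
    SimParams,
    compute_alignment,
    compute_forces,
    compute_stress,
    default_params,
    init_state,
    potential_energy,
    run,
    step,
    vessel_width,
)
from vesselmech.cortex.engine import seed_engine


def quiet_params(**kw):
    """Small inert parameter set: no anchors, no kinetics, no noise."""
    defaults = dict(
        n_filaments=5, n_motors=0, n_crosslinkers=0, n_anchored=0,
        anchoring_mode="none", thermal_noise=False,
        turnover_rate=0.0, poly_rate=0.0, depoly_rate=0.0,
    )
    defaults.update(kw)
    return SimParams(**defaults)


def state_from_filaments(filaments, params=None):
    """Build a state holding the given bead chains (list of (x, y) arrays)."""
    p = params or quiet_params(n_filaments=len(filaments))
    st = init_state(p.replace(n_filaments=len(filaments)))
    for f, (xs, ys) in enumerate(filaments):
        n = len(xs)
        st.fn[f] = n
        st.fx[f, :n] = xs
        st.fy[f, :n] = ys
    return st


class TestStressOracle:
    def test_single_horizontal_spring_closed_form(self):
        # one segment stretched to 1.05 um (rest 0.5): tension k*(d-l0)
        p = quiet_params(n_filaments=1)
        st = state_from_filaments([([1.0, 2.05], [5.0, 5.0])], p)
        region = Region(0.0, p.Lx, 4.5, 5.5)  # area Lx*1
        s = compute_stress(st, region)
        tension = p.stretch_stiffness * (1.05 - p.segment_rest_length)
        expect = tension * 1.05 / region.area
        assert s.sigma_xx == pytest.approx(expect, rel=1e-12)
        assert s.sigma_yy == pytest.approx(0.0, abs=1e-14)
        assert s.sigma_xy == pytest.approx(0.0, abs=1e-14)

    def test_rotated_configuration_swaps_components(self):
        p = quiet_params(n_filaments=1, Lx=10.0, Ly=10.0)
        st_h = state_from_filaments([([4.0, 5.1], [5.0, 5.0])], p)
        st_v = state_from_filaments([([5.0, 5.0], [4.0, 5.1])], p)
        region = Region(0.0, 10.0, 0.0, 10.0)
        sh = compute_stress(st_h, region)
        sv = compute_stress(st_v, region)
        assert sh.sigma_xx == pytest.approx(sv.sigma_yy, rel=1e-12)
        assert sh.sigma_yy == pytest.approx(sv.sigma_xx, rel=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_pairwise_sum(self, seed):
        # random small networks incl. bound motors/crosslinkers; oracle is
        # an explicit O(n^2) double loop over all interacting bead pairs
        rng = np.random.default_rng(seed)
        p = quiet_params(n_filaments=4, n_motors=3, n_crosslinkers=3)
        fils = []
        for _ in range(4):
            n = int(rng.integers(2, 5))
            # y-span below Ly/2 (raw = minimum-image separations) and
            # x chosen so every bead stays inside the domain
            x0, y0 = rng.uniform(2.5, 5.5), rng.uniform(10, 18)
            th = rng.uniform(0, np.pi)
            tt = np.arange(n) * 0.55
            fils.append((x0 + tt * np.cos(th), y0 + tt * np.sin(th)))
        st = state_from_filaments(fils, p)
        for m in range(3):
            st.mo_f[m] = rng.choice(4, size=2, replace=False)
            st.mo_s[m] = rng.uniform(0, 0.5, size=2)
            st.cl_f[m] = rng.choice(4, size=2, replace=False)
            st.cl_s[m] = rng.uniform(0, 0.5, size=2)
        region = Region(0.0, p.Lx, 0.0, p.Ly)
        s = compute_stress(st, region)

        # oracle: enumerate every pair interaction by hand
        def hooke(pa, pb, k, r0):
            d = np.hypot(pb[0] - pa[0], pb[1] - pa[1])
            u = ((pb[0] - pa[0]) / d, (pb[1] - pa[1]) / d)
            f = k * (d - r0)
            return f * u[0], f * u[1]  # force on a, toward b when stretched

        sxx = syy = sxy = 0.0

        def add_pair(pa, pb, k, r0):
            nonlocal sxx, syy, sxy
            fax, fay = hooke(pa, pb, k, r0)
            # f_ij = force on j(=a) by i(=b); r_ij = r_i - r_j
            rx, ry = pb[0] - pa[0], pb[1] - pa[1]
            sxx += fax * rx
            syy += fay * ry
            sxy += 0.5 * (fax * ry + fay * rx)

        for f, (xs, ys) in enumerate(fils):
            for i in range(len(xs) - 1):
                add_pair((xs[i], ys[i]), (xs[i + 1], ys[i + 1]),
                         p.stretch_stiffness, p.segment_rest_length)

        def head_pos(f, s):
            xs, ys = fils[f]
            seg = min(int(s / 0.5), len(xs) - 2)
            t = s / 0.5 - seg
            return (xs[seg] * (1 - t) + xs[seg + 1] * t,
                    ys[seg] * (1 - t) + ys[seg + 1] * t)

        for ent_f, ent_s in ((st.mo_f, st.mo_s), (st.cl_f, st.cl_s)):
            for m in range(3):
                if ent_f[m, 0] < 0:
                    continue
                pa = head_pos(int(ent_f[m, 0]), float(ent_s[m, 0]))
                pb = head_pos(int(ent_f[m, 1]), float(ent_s[m, 1]))
                add_pair(pa, pb, p.link_stiffness, p.link_rest_length)

        A = region.area
        assert s.sigma_xx == pytest.approx(sxx / A, abs=1e-10)
        assert s.sigma_yy == pytest.approx(syy / A, abs=1e-10)
        assert s.sigma_xy == pytest.approx(sxy / A, abs=1e-10)

    def test_region_additivity(self):
        rng = np.random.default_rng(4)
        p = quiet_params(n_filaments=8)
        fils = []
        for _ in range(8):
            n = int(rng.integers(2, 6))
            x0, y0 = rng.uniform(1, 6), rng.uniform(2, 28)
            th = rng.uniform(0, np.pi)
            tt = np.arange(n) * 0.6
            fils.append((x0 + tt * np.cos(th), y0 + tt * np.sin(th)))
        st = state_from_filaments(fils, p)
        whole = Region(0.0, p.Lx, 0.0, p.Ly)
        sw = compute_stress(st, whole)
        tiles = [Region(0.0, p.Lx, y, y + p.Ly / 4) for y in
                 np.arange(0, p.Ly, p.Ly / 4)]
        acc_xx = sum(compute_stress(st, t).sigma_xx * t.area for t in tiles)
        acc_yy = sum(compute_stress(st, t).sigma_yy * t.area for t in tiles)
        assert acc_xx / whole.area == pytest.approx(sw.sigma_xx, abs=1e-12)
        assert acc_yy / whole.area == pytest.approx(sw.sigma_yy, abs=1e-12)

    def test_empty_region_raises(self):
        st = init_state(quiet_params())
        with pytest.raises(ValueError, match="empty region"):
            compute_stress(st, Region(1.0, 1.0, 0.0, 1.0))


class TestAlignment:
    def test_sum_rule_and_limits(self):
        p = quiet_params(n_filaments=6)
        horiz = state_from_filaments(
            [(np.array([1.0, 1.5, 2.0]), np.array([y, y, y]))
             for y in np.linspace(5, 25, 6)], p)
        region = Region(0.0, 8.0, 0.0, 30.0)
        nx2, S = compute_alignment(horiz, region)
        assert nx2 == pytest.approx(S)
        vert = state_from_filaments(
            [(np.array([x, x]), np.array([5.0, 5.5]))
             for x in np.linspace(1, 7, 6)], p)
        nx2v, Sv = compute_alignment(vert, region)
        assert nx2v == pytest.approx(0.0, abs=1e-12)

    def test_sum_rule_exact_for_random_configuration(self):
        rng = np.random.default_rng(0)
        n = 500
        th = rng.uniform(0, np.pi, n)
        fils = [(np.array([4 + 0.5 * np.cos(t), 4 - 0.5 * np.cos(t)]),
                 np.array([15 + 0.5 * np.sin(t), 15 - 0.5 * np.sin(t)]))
                for t in th]
        st = state_from_filaments(fils, quiet_params(n_filaments=n))
        region = Region(0.0, 8.0, 0.0, 30.0)
        nx2, S = compute_alignment(st, region)
        # N_x^2 + N_y^2 = S exactly for unit orientations
        x0, y0, x1, y1 = st.segments()
        d = np.hypot(x1 - x0, y1 - y0)
        ny2 = float(np.sum(((y1 - y0) / d) ** 2))
        assert nx2 + ny2 == pytest.approx(S, rel=1e-12)

    def test_isotropic_monte_carlo_expectation(self):
        rng = np.random.default_rng(1)
        n = 10_000
        th = rng.uniform(0, np.pi, n)
        fils = [(np.array([4 + 0.25 * np.cos(t), 4 - 0.25 * np.cos(t)]),
                 np.array([15 + 0.25 * np.sin(t), 15 - 0.25 * np.sin(t)]))
                for t in th]
        st = state_from_filaments(fils, quiet_params(n_filaments=n))
        nx2, S = compute_alignment(st, Region(0.0, 8.0, 0.0, 30.0))
        assert S == n
        assert nx2 / S == pytest.approx(0.5, abs=0.02)

    def test_empty_region_returns_zero(self):
        st = init_state(quiet_params())
        nx2, S = compute_alignment(st, Region(0.0, 0.001, 0.0, 0.001))
        assert (nx2, S) == (0.0, 0)


class TestMechanics:
    def test_relaxed_straight_filament_is_fixed_point(self):
        p = quiet_params(n_filaments=1)
        st = state_from_filaments([(np.array([3.0, 3.5, 4.0]),
                                    np.array([15.0, 15.0, 15.0]))], p)
        before = st.fx.copy(), st.fy.copy()
        step(st, 10)
        assert np.allclose(st.fx, before[0], atol=1e-12)
        assert np.allclose(st.fy, before[1], atol=1e-12)

    def test_stretched_filament_energy_strictly_decreases(self):
        p = quiet_params(n_filaments=1)
        st = state_from_filaments([(np.array([3.0, 3.8]),
                                    np.array([15.0, 15.0]))], p)
        energies = [potential_energy(st)]
        for _ in range(20):
            step(st, 5)
            energies.append(potential_energy(st))
        # strictly decreasing until numerically converged, never increasing
        for a, b in zip(energies, energies[1:]):
            assert b <= a
            if a > 1e-12:
                assert b < a
        assert energies[-1] < 1e-6

    def test_internal_forces_sum_to_zero(self):
        # no anchors; beads away from walls so confinement is inactive
        rng = np.random.default_rng(5)
        p = quiet_params(n_filaments=5, n_motors=4, n_crosslinkers=4)
        fils = []
        for _ in range(5):
            n = int(rng.integers(3, 6))
            x0, y0 = rng.uniform(2, 5), rng.uniform(5, 25)
            th = rng.uniform(0, np.pi)
            tt = np.arange(n) * 0.6
            fils.append((x0 + tt * np.cos(th) * 0.3, y0 + tt * np.sin(th)))
        st = state_from_filaments(fils, p)
        for m in range(4):
            st.mo_f[m] = rng.choice(5, size=2, replace=False)
            st.mo_s[m] = rng.uniform(0, 0.8, size=2)
            st.cl_f[m] = rng.choice(5, size=2, replace=False)
            st.cl_s[m] = rng.uniform(0, 0.8, size=2)
        ffx, ffy = compute_forces(st)
        assert abs(ffx.sum()) < 1e-9
        assert abs(ffy.sum()) < 1e-9


class TestGeometryAndDeterminism:
    def test_default_domain_and_anchoring(self):
        p = default_params("paper_like")
        assert (p.Lx, p.Ly) == (8.0, 30.0)
        assert p.anchored_length == 2.0
        assert p.n_anchored <= 0.01 * p.n_filaments
        assert p.dt < p.stability_bound()
        st = init_state(p)
        assert int((st.anchor_code == 1).sum()) == 2  # two per side
        assert int((st.anchor_code == 2).sum()) == 2

    def test_reduced_preset_shares_physics_constants(self):
        a, b = default_params("paper_like"), default_params("reduced_test")
        for name in ("dt", "drag", "kT", "stretch_stiffness", "motor_speed",
                     "motor_stall_force", "turnover_rate", "Lx", "Ly"):
            assert getattr(a, name) == getattr(b, name)
        assert b.n_filaments < a.n_filaments

    def test_anchoring_none_has_no_anchors(self):
        st = init_state(default_params("reduced_test", anchoring_mode="none"))
        assert int((st.anchor_code != 0).sum()) == 0

    def test_anchored_fraction_enforced(self):
        with pytest.raises(ValueError, match="1%"):
            SimParams(n_filaments=100, n_anchored=2)

    def test_same_seed_same_init(self):
        p = default_params("reduced_test", seed=9)
        s1, s2 = init_state(p), init_state(p)
        assert np.array_equal(s1.fx, s2.fx)
        assert np.array_equal(s1.fy, s2.fy)

    def test_run_is_reproducible_per_seed(self):
        p = default_params("reduced_test", seed=4)
        r1 = run(p, duration=10.0, record_every=2.0)
        r2 = run(p, duration=10.0, record_every=2.0)
        assert np.array_equal(r1.sigma_xx, r2.sigma_xx)
        assert np.array_equal(r1.nx2_central, r2.nx2_central)
        assert np.array_equal(r1.width, r2.width)

    def test_filament_count_and_lengths_conserved_under_kinetics(self):
        p = default_params("reduced_test", seed=2)
        st = init_state(p)
        seed_engine(2)
        step(st, 4000)  # 20 s with full kinetics
        assert st.fn.shape[0] == p.n_filaments
        assert np.all(st.fn >= p.min_segments + 1)
        assert np.all(st.fn <= p.max_segments + 1)
        # bound heads reference valid filaments and arcs within length
        for ent_f, ent_s in ((st.mo_f, st.mo_s), (st.cl_f, st.cl_s)):
            bound = ent_f >= 0
            assert np.all(ent_f[bound] < p.n_filaments)
            lengths = (st.fn[ent_f[bound]] - 1) * p.segment_rest_length
            assert np.all(ent_s[bound] <= lengths + 1e-9)
            assert np.all(ent_s[bound] >= -1e-9)


class TestVesselWidth:
    def test_fixed_walls_return_lx(self):
        st = init_state(quiet_params())
        assert vessel_width(st) == 8.0

    def test_flat_membranes(self):
        p = quiet_params(boundary_mode="deformable_membrane")
        st = init_state(p)
        assert vessel_width(st) == pytest.approx(8.0)

    def test_symmetric_bumps_reduce_width(self):
        p = quiet_params(boundary_mode="deformable_membrane")
        st = init_state(p)
        region = Region(0.0, p.Lx, 13.0, 17.0)
        sel = (st.mem_y >= 13.0) & (st.mem_y <= 17.0)
        st.mem_left[sel] += 1.0
        st.mem_right[sel] -= 1.0
        assert vessel_width(st, region) == pytest.approx(6.0)

    def test_random_perturbation_matches_trapezoid_oracle(self):
        rng = np.random.default_rng(8)
        p = quiet_params(boundary_mode="deformable_membrane")
        st = init_state(p)
        st.mem_left[:] = 0.3 * np.sin(st.mem_y / 3.0) + 0.1 * rng.standard_normal(
            st.mem_y.size)
        st.mem_right[:] = 8.0 - 0.2 * np.cos(st.mem_y / 4.0)
        region = Region(0.0, p.Lx, 5.0, 25.0)
        got = vessel_width(st, region)
        yy = np.linspace(5.0, 25.0, 20001)
        gap = np.interp(yy, st.mem_y, st.mem_right) - np.interp(
            yy, st.mem_y, st.mem_left)
        oracle = np.trapezoid(gap, yy) / 20.0
        assert got == pytest.approx(oracle, rel=1e-4)

    def test_membrane_collision_detected(self):
        p = quiet_params(boundary_mode="deformable_membrane")
        st = init_state(p)
        st.mem_left[:] = 5.0
        st.mem_right[:] = 4.0
        with pytest.raises(ValueError, match="collision"):
            vessel_width(st, Region(0.0, 8.0, 10.0, 20.0))
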