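"""Initialization, reflecting boundaries, proliferation, stepping, recording."""

import numpy as np
import pytest

from mesocondense import (
    MorphogenSource,
    SimulationParams,
    initialize_state,
    regular_polygon,
    run,
)
from mesocondense.engine import (
    InitializationError,
    Streams,
    count_in_region,
    interaction_forces,
    proliferate,
    reflect,
    step,
)
from mesocondense.forces import pair_repulsion


class TestReflect:
    @pytest.mark.parametrize(
        "pos,expected",
        [
            ((-0.3, 5.0), (0.3, 5.0)),
            ((20.5, 5.0), (19.5, 5.0)),
            ((10.0, 10.0), (10.0, 10.0)),
            ((-1.0, 21.0), (1.0, 19.0)),
        ],
    )
    def test_mirroring(self, pos, expected):
        assert np.allclose(reflect(np.array(pos), 20.0), expected)

    def test_batch_reflection_stays_in_domain(self, rng):
        pos = rng.uniform(-5, 25, size=(500, 2))
        out = reflect(pos, 20.0)
        assert np.all(out >= 0) and np.all(out <= 20)


class TestInitialization:
    def test_requested_count_inside_box(self, params):
        st = initialize_state(params, n_cells=100)
        assert st.n_cells == 100
        assert np.all(st.positions >= 0) and np.all(st.positions <= params.box_length)
        assert np.all(st.thetas > -np.pi) and np.all(st.thetas <= np.pi)
        assert np.all(st.birth_steps == -1)

    def test_same_seed_is_identical(self, params):
        a = initialize_state(params, n_cells=50)
        b = initialize_state(params, n_cells=50)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.thetas, b.thetas)

    def test_cells_avoid_bead_and_chain_interiors(self, params):
        src = MorphogenSource((10, 10), bead_radius=1.0, region_radius=3.0)
        poly = regular_polygon([5, 5], 2.0, 24)
        st = initialize_state(params, n_cells=300, source=src, chains=[poly])
        d_bead = np.hypot(st.positions[:, 0] - 10, st.positions[:, 1] - 10)
        assert np.all(d_bead > 1.0)
        d_poly = np.hypot(st.positions[:, 0] - 5, st.positions[:, 1] - 5)
        # polygon interior is within the circumradius; apothem is the safe bound
        assert np.all(d_poly > 2.0 * np.cos(np.pi / 24) - 1e-9)

    def test_infeasible_packing_raises(self):
        p = SimulationParams(box_length=2.0)
        src = MorphogenSource((1.0, 1.0), bead_radius=1.55, region_radius=1.6)
        with pytest.raises(InitializationError):
            initialize_state(p, n_cells=100000, source=src, max_attempts=3)


class TestNeighborListOracle:
    """KD-tree interaction forces must equal direct all-pairs summation."""

    def test_matches_brute_force_on_random_configs(self, rng):
        p = SimulationParams(box_length=4.0)
        for trial in range(50):
            n = int(rng.integers(2, 200))
            st = initialize_state(p, n_cells=n, rng=rng)
            F = interaction_forces(st, p, rng)
            # independent O(N^2) oracle
            expected = np.zeros((n, 2))
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    r = np.linalg.norm(st.positions[i] - st.positions[j])
                    if 0 < r < p.d_c:
                        expected[i] += pair_repulsion(
                            st.positions[i], st.positions[j], p.k_rep, p.d_c, p.lam
                        )
            assert np.max(np.abs(F - expected)) <= 1e-12

    def test_momentum_conservation(self, rng):
        p = SimulationParams(box_length=3.0)
        st = initialize_state(p, n_cells=150, rng=rng)
        F = interaction_forces(st, p, rng)
        assert np.allclose(F.sum(axis=0), 0, atol=1e-11)

    def test_adjacent_chain_vertices_do_not_repel(self, rng):
        # tight polygon whose edge length is below d_c: only bonded pairs exist
        p = SimulationParams()
        poly = regular_polygon([10, 10], 1.0, 24)  # edge ~0.26 < 0.6
        st = initialize_state(p, n_cells=0, chains=[poly])
        F = interaction_forces(st, p, rng)
        # non-adjacent second neighbors are ~0.52 < d_c and do repel;
        # compare against the explicit non-adjacent pair sum
        v = poly.vertices
        n = len(v)
        expected = np.zeros((n, 2))
        for i in range(n):
            for j in range(n):
                if i == j or (abs(i - j) in (1, n - 1)):
                    continue
                r = np.linalg.norm(v[i] - v[j])
                if 0 < r < p.d_c:
                    expected[i] += pair_repulsion(v[i], v[j], p.k_rep, p.d_c, p.lam)
        assert np.max(np.abs(F - expected)) <= 1e-12


class TestProliferation:
    def _state(self, n_in_region, n_out, params):
        src = MorphogenSource((10, 10), bead_radius=0.0, region_radius=3.0)
        st = initialize_state(params, n_cells=0, source=src)
        rng = np.random.default_rng(7)
        inside = 10 + rng.uniform(-1, 1, size=(n_in_region, 2))
        outside = rng.uniform(0, 3, size=(n_out, 2))
        st.positions = np.vstack([inside, outside])
        st.thetas = np.zeros(len(st.positions))
        st.ids = np.arange(len(st.positions), dtype=np.int64)
        st.birth_steps = np.full(len(st.positions), -1, dtype=np.int64)
        st.next_id = len(st.positions)
        return st

    @pytest.mark.parametrize("n_region,p,expected", [(10, 0.5, 5), (7, 0.5, 3), (10, 0.0, 0)])
    def test_floor_rule(self, n_region, p, expected):
        prm = SimulationParams(p=p)
        st = self._state(n_region, 5, prm)
        assert count_in_region(st) == n_region
        added = proliferate(st, prm, np.random.default_rng(0))
        assert added == expected
        assert st.n_cells == n_region + 5 + expected

    def test_daughters_are_near_mothers_and_tagged(self):
        prm = SimulationParams(p=0.5)
        st = self._state(10, 0, prm)
        st.step = 42
        mothers = st.positions.copy()
        proliferate(st, prm, np.random.default_rng(1))
        daughters = st.positions[10:]
        assert np.all(st.birth_steps[10:] == 42)
        assert len(np.unique(st.ids)) == st.n_cells
        for d in daughters:
            assert np.min(np.hypot(*(mothers - d).T)) <= prm.d_c / 2 + 1e-12

    def test_empty_region_adds_nothing(self):
        prm = SimulationParams(p=0.9)
        st = self._state(0, 8, prm)
        assert proliferate(st, prm, np.random.default_rng(2)) == 0


class TestStep:
    def test_zero_dt_freezes_positions(self):
        prm = SimulationParams(dt=0.0, seed=5)
        st = initialize_state(prm, n_cells=40)
        before = st.positions.copy()
        out = step(st, prm, Streams.from_seed(5))
        assert np.array_equal(out.positions, before)

    def test_free_cell_euler_displacement(self):
        prm = SimulationParams(
            dt=0.01, v0=1.0, gamma_m=1.0, D_theta=0.0, alpha=0.0, p=0.0
        )
        st = initialize_state(prm, n_cells=1)
        st.positions[0] = [10.0, 10.0]
        st.thetas[0] = 0.0
        out = step(st, prm, Streams.from_seed(0))
        assert np.allclose(out.positions[0], [10.01, 10.0], atol=1e-15)

    def test_cell_count_conserved_without_proliferation(self):
        prm = SimulationParams(p=0.0, n_steps=200, seed=3)
        traj = run(prm, n_cells=60, snapshot_stride=50)
        assert all(s.n_cells == 60 for s in traj.snapshots)

    def test_synchronous_forces(self):
        """Two interacting cells must move by each other's start-of-step force."""
        prm = SimulationParams(dt=0.01, v0=0.0, D_theta=0.0, alpha=0.0, p=0.0)
        st = initialize_state(prm, n_cells=2)
        st.positions = np.array([[10.0, 10.0], [10.3, 10.0]])
        st.thetas = np.zeros(2)
        f = pair_repulsion([10.0, 10.0], [10.3, 10.0], prm.k_rep, prm.d_c, prm.lam)
        out = step(st, prm, Streams.from_seed(0))
        assert np.allclose(out.positions[0], [10.0, 10.0] + prm.dt * f, atol=1e-14)
        assert np.allclose(out.positions[1], [10.3, 10.0] - prm.dt * f, atol=1e-14)


class TestRun:
    def test_zero_steps_yields_single_snapshot(self):
        prm = SimulationParams(n_steps=0)
        traj = run(prm, n_cells=10)
        assert len(traj.snapshots) == 1 and traj.snapshots[0].step == 0

    def test_determinism_bit_for_bit(self):
        prm = SimulationParams(n_steps=120, seed=9, p=0.05)
        src_kw = dict(n_cells=80, snapshot_stride=40)
        a = run(prm, **src_kw)
        b = run(prm, **src_kw)
        assert a.snapshot_steps() == b.snapshot_steps()
        for sa, sb in zip(a.snapshots, b.snapshots):
            assert np.array_equal(sa.positions, sb.positions)
            assert np.array_equal(sa.thetas, sb.thetas)
        assert a.events == b.events

    def test_containment_over_trajectory(self):
        prm = SimulationParams(n_steps=400, seed=11)
        traj = run(prm, n_cells=200, snapshot_stride=50)
        for s in traj.snapshots:
            assert np.all(s.positions >= 0)
            assert np.all(s.positions <= prm.box_length)

    def test_proliferation_events_match_floor_rule(self):
        prm = SimulationParams(n_steps=300, seed=2, p=0.1, prolif_interval=50)
        src = MorphogenSource((10, 10), bead_radius=0.5, region_radius=3.0)
        traj = run(prm, n_cells=300, source=src, snapshot_stride=50)
        assert traj.events, "expected proliferation events"
        for ev in traj.events:
            assert ev["added"] == int(np.floor(prm.p * ev["n_region"]))
        counts = [s.n_cells for s in traj.snapshots]
        assert counts == sorted(counts)

    def test_chain_vertex_count_and_order_preserved(self):
        prm = SimulationParams(n_steps=150, seed=4)
        poly = regular_polygon([10, 10], 3.0, 24)
        traj = run(prm, n_cells=100, chains=[poly], snapshot_stride=50)
        for s in traj.snapshots:
            assert len(s.chains) == 1 and s.chains[0].n == 24
            from mesocondense.chains import edge_lengths

            per = edge_lengths(s.chains[0].vertices).sum()
            assert np.isfinite(per) and per > 0

    def test_rest_polygon_without_pressure_is_stationary(self):
        prm = SimulationParams(
            n_steps=1000, seed=0, k_p=0.0, D_theta=0.0, p=0.0
        )
        poly = regular_polygon([10, 10], 3.0, 32)
        ref = poly.vertices.copy()
        traj = run(prm, n_cells=0, chains=[poly], snapshot_stride=200)
        drift = max(
            np.max(np.abs(s.chains[0].vertices - ref)) for s in traj.snapshots
        )
        assert drift <= 1e-12
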