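import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from liquidnet.dynamics import (NullGuard, PlanarGuard, attempt_t1,
                                close_loops, langevin_step, simulate,
                                tension_velocity)
from liquidnet.network import (LiquidNetwork, init_honeycomb, network_length,
                               validate)
from liquidnet.params import DomainBoundary, SimParams

from conftest import make_two_gon


def _params(**kw):
    kw.setdefault("b", 0.02)
    kw.setdefault("k", 0.005)
    kw.setdefault("domain", DomainBoundary("none"))
    return SimParams(**kw).resolved()


class TestTensionVelocity:
    def test_symmetric_junction_is_balanced(self):
        net = LiquidNetwork()
        c = net.add_node((0, 0))
        for a in (0, 2 * math.pi / 3, 4 * math.pi / 3):
            n = net.add_node((math.cos(a), math.sin(a)))
            net.add_edge(c, n)
        v = tension_velocity(net, c, b=1.0)
        assert np.allclose(v, 0.0, atol=1e-12)

    def test_unit_vector_sum(self):
        net = LiquidNetwork()
        c = net.add_node((0, 0))
        n1 = net.add_node((1, 0))
        n2 = net.add_node((0, 1))
        net.add_edge(c, n1)
        net.add_edge(c, n2)
        v = tension_velocity(net, c, b=1.0)
        assert np.allclose(v, (1, 1))
        assert math.isclose(np.linalg.norm(v), math.sqrt(2))

    def test_doubly_connected_pair_pulls_double(self):
        # each parallel edge contributes separately, so the inward pull is
        # 2b minus the single external pull b: the pair approaches
        net = make_two_gon(sep=1.0, ext=2.0)
        i, j = 1, 2
        vi = tension_velocity(net, i, b=1.0)
        vj = tension_velocity(net, j, b=1.0)
        assert math.isclose(vi[0], 2.0 - 1.0)   # 2 toward j, 1 toward n1
        assert math.isclose(vj[0], -(2.0 - 1.0))

    def test_zero_length_edge_contributes_nothing(self):
        net = LiquidNetwork()
        a = net.add_node((0, 0))
        b = net.add_node((0, 0))
        net.add_edge(a, b)
        assert np.allclose(tension_velocity(net, a, 1.0), 0.0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(1, 5), st.integers(0, 999))
    def test_speed_bounded_by_degree(self, deg, seed):
        rng = np.random.default_rng(seed)
        net = LiquidNetwork()
        c = net.add_node((0, 0))
        for _ in range(deg):
            n = net.add_node(rng.uniform(-3, 3, 2))
            if net.parallel_count(c, n) < 2:
                net.add_edge(c, n)
        v = tension_velocity(net, c, b=0.7)
        assert np.linalg.norm(v) <= 0.7 * deg + 1e-9


class TestLangevinStep:
    def test_deterministic_symmetric_junction_stays(self):
        net = LiquidNetwork()
        c = net.add_node((0, 0))
        for a in (0, 2 * math.pi / 3, 4 * math.pi / 3):
            n = net.add_node((math.cos(a), math.sin(a)), boundary=True)
            net.add_edge(c, n)
        p = _params(D=0.0)
        langevin_step(net, p, np.random.default_rng(0))
        assert np.allclose(net.pos[c], 0.0, atol=1e-12)

    def test_hexagon_ring_contracts_monotonically(self, single_hexagon):
        p = _params(D=0.0)
        rng = np.random.default_rng(0)
        last = network_length(single_hexagon)
        for _ in range(50):
            langevin_step(single_hexagon, p, rng)
            L = network_length(single_hexagon)
            assert L < last
            last = L

    def test_free_diffusion_msd(self):
        # b irrelevant for isolated nodes: MSD must follow 4·D·t
        net = LiquidNetwork()
        n = 400
        for _ in range(n):
            net.add_node((0.0, 0.0))
        D = 1e-3
        p = _params(D=D, dt=0.1, d_t1=1.0)
        rng = np.random.default_rng(42)
        steps = 200
        for _ in range(steps):
            langevin_step(net, p, rng)
        t = steps * p.dt
        msd = float((net.pos[:n] ** 2).sum(1).mean())
        se = 4 * D * t * math.sqrt(2.0 / n)  # chi^2 spread of the mean
        assert abs(msd - 4 * D * t) < 3 * se

    def test_pinned_nodes_do_not_move(self):
        net = LiquidNetwork()
        a = net.add_node((0, 0), pinned=True)
        b = net.add_node((1, 0))
        net.add_edge(a, b)
        p = _params(D=1e-4)
        langevin_step(net, p, np.random.default_rng(0))
        assert np.allclose(net.pos[a], (0, 0))
        assert not np.allclose(net.pos[b], (1, 0))


def _t1_quad(top_heavy: bool):
    """Horizontal near-contact pair; i holds both top externals if top_heavy."""
    net = LiquidNetwork()
    i = net.add_node((-0.05, 0.0))
    j = net.add_node((0.05, 0.0))
    tl = net.add_node((-1.0, 0.5), boundary=True)
    tr = net.add_node((1.0, 0.5), boundary=True)
    bl = net.add_node((-1.0, -0.5), boundary=True)
    br = net.add_node((1.0, -0.5), boundary=True)
    net.add_edge(i, j)
    if top_heavy:  # length-reducible configuration
        net.add_edge(i, tl)
        net.add_edge(i, tr)
        net.add_edge(j, bl)
        net.add_edge(j, br)
    else:  # left/right split: already minimal
        net.add_edge(i, tl)
        net.add_edge(i, bl)
        net.add_edge(j, tr)
        net.add_edge(j, br)
    return net, i, j


def _local_length(net, i, j):
    tot = 0.0
    seen = set()
    for n in (i, j):
        for _, e in net.adj[n]:
            if e not in seen:
                seen.add(e)
                a, b = net.edges[e]
                tot += float(np.linalg.norm(net.pos[a] - net.pos[b]))
    return tot


class TestT1:
    def test_swap_applied_when_it_shortens(self):
        net, i, j = _t1_quad(top_heavy=True)
        before = _local_length(net, i, j)
        # brute-force oracle: enumerate both alternative pairings
        assert attempt_t1(net, d_t1=0.2) == 1
        after = _local_length(net, i, j)
        assert after < before
        # i and j now each hold one top and one bottom external
        tops = {2, 3}
        assert len(set(net.neighbors(i)) & tops) == 1
        assert len(set(net.neighbors(j)) & tops) == 1

    def test_swap_rejected_when_it_lengthens(self):
        net, i, j = _t1_quad(top_heavy=False)
        edges_before = {tuple(sorted(map(int, net.edges[e])))
                        for e in net.edge_ids()}
        assert attempt_t1(net, d_t1=0.2) == 0
        edges_after = {tuple(sorted(map(int, net.edges[e])))
                       for e in net.edge_ids()}
        assert edges_before == edges_after

    def test_far_pairs_untouched(self):
        net, i, j = _t1_quad(top_heavy=True)
        assert attempt_t1(net, d_t1=0.05) == 0  # pair separation is 0.1

    def test_brute_force_agreement(self, rng):
        # the chosen pairing must be the minimum-length one among all three
        for trial in range(40):
            net = LiquidNetwork()
            i = net.add_node(rng.normal(0, 0.02, 2))
            j = net.add_node(rng.normal(0, 0.02, 2))
            ext = [net.add_node(3 * rng.normal(0, 1, 2), boundary=True)
                   for _ in range(4)]
            net.add_edge(i, j)
            net.add_edge(i, ext[0])
            net.add_edge(i, ext[1])
            net.add_edge(j, ext[2])
            net.add_edge(j, ext[3])
            p = net.pos

            def cost(pair_i):
                pair_j = [e for e in ext if e not in pair_i]
                return (sum(np.linalg.norm(p[i] - p[x]) for x in pair_i)
                        + sum(np.linalg.norm(p[j] - p[x]) for x in pair_j))

            costs = [cost([ext[0], ext[1]]), cost([ext[0], ext[2]]),
                     cost([ext[0], ext[3]])]
            swapped = attempt_t1(net, d_t1=1.0, guard=NullGuard())
            if swapped:
                assert min(costs[1], costs[2]) < costs[0] - 1e-12
                assert _local_length(net, i, j) < sum(
                    [costs[0], float(np.linalg.norm(p[i] - p[j]))])


class TestCloseLoops:
    def test_two_gon_merges_into_single_edge(self):
        net = make_two_gon(sep=0.05, ext=2.0)
        assert close_loops(net, d_close=0.1) == 1
        rep = validate(net)
        assert rep.ok, rep.first_violation
        # a single straight edge joins the two external neighbors
        assert net.n_edges == 1
        assert math.isclose(network_length(net), 4.0, rel_tol=1e-12)

    def test_distant_two_gon_untouched(self):
        net = make_two_gon(sep=1.0)
        assert close_loops(net, d_close=0.1) == 0
        assert net.n_edges == 4

    def test_two_gon_contracts_then_closes(self):
        # under tension the pair approaches at ~2b−... and merges; afterwards
        # total length equals the external span
        net = make_two_gon(sep=0.5, ext=2.0)
        p = _params(D=0.0, dt=0.1, d_t1=0.05, d_close=0.05)
        rng = np.random.default_rng(0)
        for _ in range(2000):
            langevin_step(net, p, rng)
            if close_loops(net, p.d_close):
                break
        else:
            pytest.fail("loop never closed")
        assert math.isclose(network_length(net), 4.0, rel_tol=1e-3)


class TestSimulate:
    def test_identical_seed_identical_trajectory(self):
        dom = DomainBoundary("circle", radius=6.0)
        runs = []
        for _ in range(2):
            net = init_honeycomb(1.0, dom)
            p = SimParams(b=0.02, k=0.01, domain=dom, seed=77)
            traj = simulate(net, p, t_max=30.0)
            runs.append((traj.lengths.copy(), net.compact().pos.copy()))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert np.array_equal(runs[0][1], runs[1][1])

    def test_pure_tension_shrinks_network(self):
        # no spawning, negligible noise: total length non-increasing
        dom = DomainBoundary("circle", radius=6.0)
        net = init_honeycomb(1.0, dom)
        p = SimParams(b=0.02, k=1e-9, D=0.0, domain=dom, seed=0)
        traj = simulate(net, p, t_max=100.0)
        assert np.all(np.diff(traj.lengths) <= 1e-9)

    def test_stability_guard_aborts(self):
        dom = DomainBoundary("circle", radius=6.0)
        net = init_honeycomb(1.0, dom)
        p = SimParams(b=0.02, k=0.005, dt=50.0, d_t1=0.1, domain=dom)
        with pytest.raises(ValueError, match="stability guard"):
            simulate(net, p, t_max=10.0)


class TestEventInvariants:
    """Euler's formula and face accounting across individual events."""

    def test_fusion_splits_exactly_one_face(self, rng):
        from liquidnet import growth
        from liquidnet.faces import count_faces

        net = init_honeycomb(1.0, DomainBoundary("circle", radius=6.0))
        p = SimParams(b=0.02, k=0.005, domain=DomainBoundary("circle", radius=6.0)).resolved()
        done = 0
        for _ in range(200):
            events = growth.sample_spawn_events(net, k=0.05, dt=1.0, rng=rng)
            for eid, frac in events:
                if not net.edge_alive[eid]:
                    continue
                V, E, F = net.n_nodes, net.n_edges, count_faces(net)
                fused, _ = growth.grow_tip_instantaneous(net, eid, frac, p, rng)
                V2, E2, F2 = net.n_nodes, net.n_edges, count_faces(net)
                assert V2 - E2 + F2 == 2
                if fused:
                    assert (V2 - V, E2 - E, F2 - F) == (2, 3, 1)
                    done += 1
                else:
                    assert (V2, E2, F2) == (V, E, F)
            if done > 30:
                break
        assert done > 30

    def test_t1_and_closure_preserve_euler(self):
        from liquidnet.faces import count_faces

        net, i, j = _t1_quad(top_heavy=True)
        attempt_t1(net, d_t1=0.2)
        assert net.n_nodes - net.n_edges + count_faces(net) == 2

        net2 = make_two_gon(sep=0.05)
        close_loops(net2, d_close=0.1)
        assert net2.n_nodes - net2.n_edges + count_faces(net2) == 2
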