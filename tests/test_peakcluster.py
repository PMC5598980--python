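"""Clustering methods vs brute-force oracles and their invariants."""

import numpy as np
import pytest

from imspeak import (
    Scaling,
    cluster_dbscan,
    cluster_editing,
    cluster_em,
    cluster_grid_squares,
)
from imspeak.peakcluster import (
    cluster_editing_cost,
    solve_cluster_editing_exact,
    solve_cluster_editing_greedy,
)
from conftest import make_peaklist

# scaling with no relative rt term: normalised distance is a plain ellipse,
# convenient for constructing instances with exact distances
SC = Scaling(tol_ik0=0.01, tol_rt_abs=1.0, tol_rt_rel=0.0)


def random_peaklists(rng, n_peaks, n_measurements=4, rt_span=10.0, ik0_span=0.1):
    pls = []
    per = [n_peaks // n_measurements] * n_measurements
    for i in range(n_peaks % n_measurements):
        per[i] += 1
    for i, k in enumerate(per):
        pos = [
            (rng.uniform(0, rt_span), 0.4 + rng.uniform(0, ik0_span))
            for _ in range(k)
        ]
        # ensure distinct positions within a measurement
        pls.append(make_peaklist(f"m{i}", pos))
    return pls


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def dbscan_oracle(points, eps, min_pts):
    """Literal density-reachability closure.

    Returns (core labels, noise set).  Core points with distance <= eps
    are linked; border points are density-reachable from >= 1 core;
    everything else is noise.  Border points may be reachable from
    several clusters, so only core structure and noise are compared.
    """
    n = len(points)
    d = np.array([[SC.distance(*points[i], *points[j]) for j in range(n)] for i in range(n)])
    neighbours = [set(np.where(d[i] <= eps)[0]) for i in range(n)]  # includes self
    core = {i for i in range(n) if len(neighbours[i]) >= min_pts}
    # connected components of cores under eps-adjacency
    label = {}
    cur = 0
    for i in sorted(core):
        if i in label:
            continue
        stack = [i]
        while stack:
            u = stack.pop()
            if u in label:
                continue
            label[u] = cur
            stack.extend(v for v in neighbours[u] if v in core and v not in label)
        cur += 1
    noise = {
        i for i in range(n)
        if i not in core and not any(j in core for j in neighbours[i])
    }
    return label, noise


def set_partitions(items):
    """All partitions of a list (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


# ---------------------------------------------------------------------------
# Grid squares
# ---------------------------------------------------------------------------


class TestGridSquares:
    def test_coincident_peaks_meet_min_count(self):
        pls = [make_peaklist(f"m{i}", [(5.0, 0.45)]) for i in range(5)]
        res = cluster_grid_squares(pls, cell_rt=1.0, cell_ik0=0.01, min_count=3)
        assert res.n_clusters == 1
        c = res.consensus[0]
        assert (c.rt, c.ik0) == (5.0, 0.45)
        assert c.support == 5

    def test_min_count_above_membership_gives_nothing(self):
        pls = [make_peaklist(f"m{i}", [(5.0, 0.45)]) for i in range(5)]
        res = cluster_grid_squares(pls, cell_rt=1.0, cell_ik0=0.01, min_count=6)
        assert res.n_clusters == 0
        assert all(v is None for v in res.assignment.values())

    def test_cell_boundary_straddle(self):
        # origin anchors at the global minimum: peaks at rt .1,.2,.3 share the
        # first 0.5-wide cell, peaks at .6,.7 the second; min_count 3 keeps
        # only the left cell
        pos = [0.1, 0.2, 0.3, 0.6, 0.7]
        pls = [make_peaklist(f"m{i}", [(p, 0.45)]) for i, p in enumerate(pos)]
        res = cluster_grid_squares(pls, cell_rt=0.5, cell_ik0=0.01, min_count=3)
        assert res.n_clusters == 1
        assert res.consensus[0].rt == pytest.approx(np.mean([0.1, 0.2, 0.3]))

    def test_consensus_is_member_average(self, rng):
        pos = [(1.0 + rng.uniform(0, 0.2), 0.45) for _ in range(4)]
        pls = [make_peaklist(f"m{i}", [p]) for i, p in enumerate(pos)]
        res = cluster_grid_squares(pls, cell_rt=1.0, cell_ik0=0.01, min_count=2)
        assert res.n_clusters == 1
        assert res.consensus[0].rt == pytest.approx(np.mean([p[0] for p in pos]))


# ---------------------------------------------------------------------------
# DBSCAN
# ---------------------------------------------------------------------------


class TestDBSCAN:
    def test_two_well_separated_groups(self, rng):
        g1 = [(5.0 + rng.uniform(-0.1, 0.1), 0.45) for _ in range(5)]
        g2 = [(9.0 + rng.uniform(-0.1, 0.1), 0.45) for _ in range(5)]
        pls = [make_peaklist(f"m{i}", [a, b]) for i, (a, b) in enumerate(zip(g1, g2))]
        res = cluster_dbscan(pls, eps=1.0, min_pts=3, scaling=SC)
        assert res.n_clusters == 2
        centroids = sorted(c.rt for c in res.consensus)
        assert centroids[0] == pytest.approx(np.mean([p[0] for p in g1]), abs=0.2)
        assert centroids[1] == pytest.approx(np.mean([p[0] for p in g2]), abs=0.2)

    def test_all_isolated_is_all_noise(self):
        pls = [make_peaklist(f"m{i}", [(float(10 * i), 0.45)]) for i in range(5)]
        res = cluster_dbscan(pls, eps=1.0, min_pts=2, scaling=SC)
        assert res.n_clusters == 0
        assert all(v is None for v in res.assignment.values())

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_density_reachability_closure(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 21))
        pls = random_peaklists(rng, n, rt_span=6.0, ik0_span=0.03)
        res = cluster_dbscan(pls, eps=1.0, min_pts=3, scaling=SC)

        keys, points = [], []
        for pl in sorted(pls, key=lambda p: p.measurement_id):
            for i, p in enumerate(pl.peaks):
                keys.append((pl.measurement_id, i))
                points.append((p.rt, p.ik0))
        core_label, noise = dbscan_oracle(points, eps=1.0, min_pts=3)

        # noise sets agree
        got_noise = {i for i, k in enumerate(keys) if res.assignment[k] is None}
        assert got_noise == noise
        # core points grouped identically (same partition of cores)
        by_truth = {}
        for i, lab in core_label.items():
            by_truth.setdefault(lab, set()).add(res.assignment[keys[i]])
        assert all(len(v) == 1 for v in by_truth.values())
        got_labels = [next(iter(v)) for v in by_truth.values()]
        assert len(set(got_labels)) == len(got_labels)


# ---------------------------------------------------------------------------
# Cluster editing
# ---------------------------------------------------------------------------


def ce_weight_matrix(points, thr=1.0):
    n = len(points)
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                W[i, j] = thr - SC.distance(*points[i], *points[j])
    return W


class TestClusterEditing:
    def test_three_peak_instance_vs_bell_enumeration(self):
        points = [(0.0, 0.45), (0.1, 0.45), (10.0, 0.45)]  # a,b close; c far
        pls = [make_peaklist(f"m{i}", [p]) for i, p in enumerate(points)]
        res = cluster_editing(pls, sim_threshold=1.0, scaling=SC)
        assert res.n_clusters == 2
        supports = sorted(c.support for c in res.consensus)
        assert supports == [1, 2]

        W = ce_weight_matrix(points)
        _, cost = solve_cluster_editing_exact(W)
        best = min(cluster_editing_cost(W, p) for p in set_partitions(range(3)))
        assert cost == pytest.approx(best)

    def test_all_beyond_threshold_all_singletons(self):
        points = [(float(5 * i), 0.45) for i in range(4)]
        pls = [make_peaklist(f"m{i}", [p]) for i, p in enumerate(points)]
        res = cluster_editing(pls, sim_threshold=1.0, scaling=SC)
        assert res.n_clusters == 4
        _, cost = solve_cluster_editing_exact(ce_weight_matrix(points))
        assert cost == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_solver_equals_partition_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        points = [(rng.uniform(0, 4), 0.4 + rng.uniform(0, 0.02)) for _ in range(8)]
        W = ce_weight_matrix(points)
        _, cost = solve_cluster_editing_exact(W)
        best = min(cluster_editing_cost(W, p) for p in set_partitions(range(8)))
        assert cost == pytest.approx(best)

    def test_greedy_never_beats_exact(self, rng):
        points = [(rng.uniform(0, 4), 0.4 + rng.uniform(0, 0.02)) for _ in range(9)]
        W = ce_weight_matrix(points)
        _, exact_cost = solve_cluster_editing_exact(W)
        _, greedy_cost = solve_cluster_editing_greedy(W)
        assert greedy_cost >= exact_cost - 1e-12


# ---------------------------------------------------------------------------
# EM with merging
# ---------------------------------------------------------------------------


class TestEM:
    def test_single_peak_fixed_point(self):
        pls = [make_peaklist("m0", [(7.0, 0.47)])]
        res = cluster_em(pls, sigma_rt=1.0, sigma_ik0=0.01)
        assert res.n_clusters == 1
        c = res.consensus[0]
        assert c.rt == pytest.approx(7.0, abs=1e-9)
        assert c.ik0 == pytest.approx(0.47, abs=1e-12)

    @staticmethod
    def two_cloud_instance(seed, n=30, sep=5.0, sigma_rt=1.0, sigma_ik0=0.01):
        rng = np.random.default_rng(seed)
        a = [(-sep * sigma_rt + rng.normal(0, sigma_rt), 0.5 + rng.normal(0, sigma_ik0))
             for _ in range(n)]
        b = [(+sep * sigma_rt + rng.normal(0, sigma_rt), 0.5 + rng.normal(0, sigma_ik0))
             for _ in range(n)]
        pls = [make_peaklist(f"m{i}", [pa, pb]) for i, (pa, pb) in enumerate(zip(a, b))]
        return pls, (-sep * sigma_rt, 0.5), (sep * sigma_rt, 0.5)

    def test_two_cloud_centre_recovery(self):
        ok = 0
        n_seeds = 20
        for seed in range(n_seeds):
            pls, c1, c2 = self.two_cloud_instance(seed)
            res = cluster_em(pls, sigma_rt=1.0, sigma_ik0=0.01)
            if res.n_clusters != 2:
                continue
            got = sorted((c.rt, c.ik0) for c in res.consensus)
            tol = 3.0 / np.sqrt(30)  # 3 sigma / sqrt(n) in each dimension
            if (
                abs(got[0][0] - c1[0]) < tol * 1.0
                and abs(got[1][0] - c2[0]) < tol * 1.0
                and abs(got[0][1] - c1[1]) < tol * 0.01
                and abs(got[1][1] - c2[1]) < tol * 0.01
            ):
                ok += 1
        assert ok >= 0.95 * n_seeds

    def test_overcomplete_init_collapses_by_merging(self):
        # grid-squares seeding starts with many components; merging must
        # collapse them to the two real clouds
        pls, _, _ = self.two_cloud_instance(0)
        res = cluster_em(pls, sigma_rt=1.0, sigma_ik0=0.01)
        assert res.n_clusters == 2

    def test_loglik_monotone_between_merges(self):
        pls, _, _ = self.two_cloud_instance(3)
        trace = []
        cluster_em(pls, sigma_rt=1.0, sigma_ik0=0.01, merge_dist=1.0, trace=trace)
        for (k0, ll0), (k1, ll1) in zip(trace, trace[1:]):
            if k0 == k1:  # no merge in between: EM guarantee applies
                assert ll1 >= ll0 - 1e-9


# ---------------------------------------------------------------------------
# Cross-method invariants
# ---------------------------------------------------------------------------


CLUSTERERS = {
    "gs": lambda pls: cluster_grid_squares(pls, cell_rt=1.0, cell_ik0=0.01, min_count=2),
    "dbscan": lambda pls: cluster_dbscan(pls, eps=1.0, min_pts=2, scaling=SC),
    "ce": lambda pls: cluster_editing(pls, sim_threshold=1.0, scaling=SC),
    "em": lambda pls: cluster_em(pls, sigma_rt=0.5, sigma_ik0=0.005),
}


class TestClusterInvariants:
    @pytest.mark.parametrize("method", list(CLUSTERERS))
    def test_partition_property(self, method, rng):
        pls = random_peaklists(rng, 16)
        res = CLUSTERERS[method](pls)
        keys = [(pl.measurement_id, i) for pl in pls for i in range(len(pl))]
        assert set(res.assignment) == set(keys)
        members = [m for c in res.consensus for m in c.members]
        assert len(members) == len(set(members))  # disjoint
        assigned = {k for k, v in res.assignment.items() if v is not None}
        assert assigned == set(members)
        for c in res.consensus:
            assert c.support == len(c.members) >= 1

    @pytest.mark.parametrize("method", list(CLUSTERERS))
    def test_permutation_invariance(self, method, rng):
        pls = random_peaklists(rng, 14)
        res1 = CLUSTERERS[method](pls)
        shuffled = list(pls)
        rng.shuffle(shuffled)
        res2 = CLUSTERERS[method](shuffled)
        pos1 = sorted((c.rt, c.ik0) for c in res1.consensus)
        pos2 = sorted((c.rt, c.ik0) for c in res2.consensus)
        assert len(pos1) == len(pos2)
        for (a, b), (c, d) in zip(pos1, pos2):
            assert abs(a - c) < 1e-9 and abs(b - d) < 1e-9

    @pytest.mark.parametrize("method", ["dbscan", "ce"])
    def test_scale_consistency(self, method, rng):
        pls = random_peaklists(rng, 12)
        factor = 3.0
        scaled = [
            make_peaklist(pl.measurement_id, [(p.rt * factor, 0.4 + (p.ik0 - 0.4) * factor)
                                              for p in pl.peaks])
            for pl in pls
        ]
        sc2 = Scaling(tol_ik0=SC.tol_ik0 * factor, tol_rt_abs=SC.tol_rt_abs * factor,
                      tol_rt_rel=0.0)
        if method == "dbscan":
            r1 = cluster_dbscan(pls, eps=1.0, min_pts=2, scaling=SC)
            r2 = cluster_dbscan(scaled, eps=1.0, min_pts=2, scaling=sc2)
        else:
            r1 = cluster_editing(pls, sim_threshold=1.0, scaling=SC)
            r2 = cluster_editing(scaled, sim_threshold=1.0, scaling=sc2)
        part1 = sorted(sorted(c.members) for c in r1.consensus)
        part2 = sorted(sorted(c.members) for c in r2.consensus)
        assert part1 == part2


class TestScaling:
    def test_metric_axioms_on_samples(self, rng):
        sc = Scaling()
        for _ in range(20):
            a = (rng.uniform(0, 100), rng.uniform(0.4, 1.0))
            b = (rng.uniform(0, 100), rng.uniform(0.4, 1.0))
            assert sc.distance(*a, *b) == pytest.approx(sc.distance(*b, *a))
            assert sc.distance(*a, *a) == 0.0
            assert sc.distance(*a, *b) >= 0.0

    def test_bad_tolerances_rejected(self):
        with pytest.raises(ValueError):
            Scaling(tol_ik0=-1.0)
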