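"""Cross-measurement clustering of peak positions into consensus peaks.

Peaks picked independently in each measurement of a cohort must be
aligned so that detections of the same analyte become one feature.  Four
clustering strategies are provided: grid squares (GS), DBSCAN, weighted
cluster editing (CE), and an EM Gaussian-mixture variant with component
merging (EM).  Each returns a :class:`ClusterResult` holding the
consensus peaks (cluster representatives) and the per-peak assignment.

Distances mix two physical scales — retention time in seconds and 1/K0
in Vs/cm² — so all methods except GS work in the normalised coordinates
defined by :class:`Scaling`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from sklearn.cluster import DBSCAN as _SKDBSCAN

from .core_data import ConsensusPeak, PeakList

__all__ = [
    "Scaling",
    "ClusterResult",
    "cluster_grid_squares",
    "cluster_dbscan",
    "cluster_editing",
    "cluster_em",
    "partition_weight_matrix",
    "solve_cluster_editing_exact",
    "solve_cluster_editing_greedy",
    "cluster_editing_cost",
]

NOISE = None  # assignment value for unclustered peaks


@dataclass(frozen=True)
class Scaling:
    """Tolerance-based normalisation of (rt, ik0) distances.

    The drift dimension has a roughly constant instrumental tolerance,
    while retention-time spread grows along the column, so the rt
    tolerance has an absolute and a relative part.  The normalised
    distance between peaks u and v is

        d(u, v) = sqrt( (Δik0 / tol_ik0)²
                      + (Δrt / (tol_rt_abs + tol_rt_rel · mean(rt_u, rt_v)))² )

    so d == 1 means "one tolerance ellipse apart".
    """

    tol_ik0: float = 0.003
    tol_rt_abs: float = 3.0
    tol_rt_rel: float = 0.01

    def __post_init__(self) -> None:
        if self.tol_ik0 <= 0 or self.tol_rt_abs <= 0 or self.tol_rt_rel < 0:
            raise ValueError("tolerances must be positive (tol_rt_rel may be 0)")

    def distance(self, rt1, ik01, rt2, ik02) -> np.ndarray:
        rt_tol = self.tol_rt_abs + self.tol_rt_rel * 0.5 * (np.asarray(rt1) + np.asarray(rt2))
        return np.sqrt(
            ((np.asarray(ik01) - np.asarray(ik02)) / self.tol_ik0) ** 2
            + ((np.asarray(rt1) - np.asarray(rt2)) / rt_tol) ** 2
        )

    def pairwise(self, rt: np.ndarray, ik0: np.ndarray) -> np.ndarray:
        """Full symmetric matrix of normalised distances."""
        return self.distance(rt[:, None], ik0[:, None], rt[None, :], ik0[None, :])


@dataclass
class ClusterResult:
    """Consensus peaks plus the peak → feature assignment.

    ``assignment`` maps ``(measurement_id, peak_index)`` to a feature id,
    or to ``None`` for peaks left as noise.
    """

    consensus: list[ConsensusPeak]
    assignment: dict[tuple[str, int], str | None] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.consensus)


def _flatten(peaklists: Sequence[PeakList]):
    """Deterministic flat view of all peaks, sorted by (measurement, index)."""
    recs = []
    for pl in sorted(peaklists, key=lambda p: p.measurement_id):
        for i, p in enumerate(pl.peaks):
            recs.append((pl.measurement_id, i, p.rt, p.ik0, p.intensity))
    keys = [(r[0], r[1]) for r in recs]
    rt = np.array([r[2] for r in recs], dtype=float)
    ik0 = np.array([r[3] for r in recs], dtype=float)
    return keys, rt, ik0


def _build_result(
    keys, rt: np.ndarray, ik0: np.ndarray, member_label: np.ndarray, positions=None
) -> ClusterResult:
    """Assemble a ClusterResult from integer labels (-1 = noise).

    Feature ids are assigned in (rt, ik0) order of the cluster positions
    so the output is invariant to input peak order.  ``positions``
    overrides the default member-centroid positions (used by EM, whose
    representatives are model means rather than centroids).
    """
    labels = sorted(set(member_label[member_label >= 0]))
    clusters = []
    for lab in labels:
        idx = np.where(member_label == lab)[0]
        if positions is not None:
            pos = positions[lab]
        else:
            pos = (float(np.mean(rt[idx])), float(np.mean(ik0[idx])))
        clusters.append((pos, idx))
    clusters.sort(key=lambda c: (c[0][0], c[0][1]))

    consensus: list[ConsensusPeak] = []
    assignment: dict[tuple[str, int], str | None] = {k: NOISE for k in keys}
    for j, (pos, idx) in enumerate(clusters):
        fid = f"F{j:04d}"
        members = [keys[i] for i in idx]
        consensus.append(ConsensusPeak(feature_id=fid, rt=pos[0], ik0=pos[1], members=members))
        for k in members:
            assignment[k] = fid
    return ClusterResult(consensus=consensus, assignment=assignment)


# ---------------------------------------------------------------------------
# Grid squares
# ---------------------------------------------------------------------------


def cluster_grid_squares(
    peaklists: Sequence[PeakList],
    cell_rt: float = 6.0,
    cell_ik0: float = 0.006,
    min_count: int = 2,
) -> ClusterResult:
    """Partition the (rt, ik0) plane into rectangles and keep crowded cells.

    The grid origin is anchored at the global minimum peak position, so
    binning does not depend on arbitrary absolute offsets.  A cell with
    at least ``min_count`` member peaks yields one consensus peak at the
    mean member position; peaks in sparser cells are noise.
    """
    if cell_rt <= 0 or cell_ik0 <= 0:
        raise ValueError("cell sizes must be > 0")
    keys, rt, ik0 = _flatten(peaklists)
    if not keys:
        return ClusterResult(consensus=[], assignment={})
    origin_rt, origin_ik0 = rt.min(), ik0.min()
    bins_rt = np.floor((rt - origin_rt) / cell_rt).astype(int)
    bins_ik0 = np.floor((ik0 - origin_ik0) / cell_ik0).astype(int)

    label = np.full(len(keys), -1, dtype=int)
    next_label = 0
    cells: dict[tuple[int, int], list[int]] = {}
    for i, cell in enumerate(zip(bins_rt, bins_ik0)):
        cells.setdefault(cell, []).append(i)
    for cell in sorted(cells):
        idx = cells[cell]
        if len(idx) >= min_count:
            label[idx] = next_label
            next_label += 1
    return _build_result(keys, rt, ik0, label)


# ---------------------------------------------------------------------------
# DBSCAN
# ---------------------------------------------------------------------------


def cluster_dbscan(
    peaklists: Sequence[PeakList],
    eps: float = 1.0,
    min_pts: int = 3,
    scaling: Scaling = Scaling(),
) -> ClusterResult:
    """Density-based clustering in normalised coordinates.

    Core peaks have at least ``min_pts`` neighbours (themselves included)
    within ``eps``; clusters are the density-reachability closures of the
    cores, border peaks join the first core cluster that reaches them in
    sorted peak order, and everything else is noise.  Consensus peaks are
    cluster centroids.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    keys, rt, ik0 = _flatten(peaklists)
    if not keys:
        return ClusterResult(consensus=[], assignment={})
    dmat = scaling.pairwise(rt, ik0)
    labels = _SKDBSCAN(eps=eps, min_samples=min_pts, metric="precomputed").fit_predict(dmat)
    return _build_result(keys, rt, ik0, labels)


# ---------------------------------------------------------------------------
# Weighted cluster editing
# ---------------------------------------------------------------------------


def cluster_editing_cost(W: np.ndarray, partition: Sequence[Sequence[int]]) -> float:
    """Editing cost of a partition under weight matrix W.

    Pairs in the same clique with negative weight pay the insertion cost
    |w|; pairs in different cliques with positive weight pay the deletion
    cost w.
    """
    n = W.shape[0]
    block = np.empty(n, dtype=int)
    for b, members in enumerate(partition):
        for i in members:
            block[i] = b
    cost = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            w = W[i, j]
            if block[i] == block[j]:
                if w < 0:
                    cost -= w
            elif w > 0:
                cost += w
    return cost


def solve_cluster_editing_greedy(W: np.ndarray) -> tuple[list[list[int]], float]:
    """Greedy agglomerative heuristic: start from singletons, repeatedly
    merge the pair of cliques with the largest cost reduction."""
    n = W.shape[0]
    cliques: list[list[int]] = [[i] for i in range(n)]
    # delta of merging cliques a, b = sum over cross pairs of -w  (joining
    # turns deletion cost w>0 into 0 and adds insertion cost -w for w<0)
    while len(cliques) > 1:
        best_delta, best_pair = 0.0, None
        for a, b in itertools.combinations(range(len(cliques)), 2):
            delta = -float(np.sum(W[np.ix_(cliques[a], cliques[b])]))
            if delta < best_delta - 1e-12:
                best_delta, best_pair = delta, (a, b)
        if best_pair is None:
            break
        a, b = best_pair
        cliques[a] = cliques[a] + cliques[b]
        del cliques[b]
    return cliques, cluster_editing_cost(W, cliques)


def solve_cluster_editing_exact(W: np.ndarray) -> tuple[list[list[int]], float]:
    """Exact minimum-cost clique partition by branch and bound.

    Elements are assigned one at a time to an existing clique or a new
    one; the partial cost is incremental and monotone, so branches whose
    cost reaches the incumbent (initialised from the greedy solution)
    are pruned.  Intended for components of modest size (the search
    space is the Bell number of n).
    """
    n = W.shape[0]
    best_partition, best_cost = solve_cluster_editing_greedy(W)
    # positive-weight row sums let us prune
    Wpos = np.where(W > 0, W, 0.0)
    Wneg = np.where(W < 0, -W, 0.0)

    def recurse(t: int, blocks: list[list[int]], cost: float) -> None:
        nonlocal best_partition, best_cost
        if cost >= best_cost - 1e-12:
            return
        if t == n:
            best_partition, best_cost = [list(b) for b in blocks], cost
            return
        assigned = [i for b in blocks for i in b]
        pos_to_assigned = float(np.sum(Wpos[t, assigned])) if assigned else 0.0
        for b in blocks:
            # join b: pay insertions inside b, deletions to all other assigned
            inc = float(np.sum(Wneg[t, b])) + (pos_to_assigned - float(np.sum(Wpos[t, b])))
            b.append(t)
            recurse(t + 1, blocks, cost + inc)
            b.pop()
        # open a new clique: pay deletions to every assigned element
        blocks.append([t])
        recurse(t + 1, blocks, cost + pos_to_assigned)
        blocks.pop()

    recurse(0, [], 0.0)
    return best_partition, best_cost


def partition_weight_matrix(W: np.ndarray, exact_limit: int = 12) -> list[list[int]]:
    """Minimum-cost clique partition of a full weight matrix.

    Connected components of the positive-weight graph are independent in
    the editing objective and are solved separately: exactly up to
    ``exact_limit`` elements, greedily above.
    """
    n = W.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    ii, jj = np.where(np.triu(W, 1) > 0)
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))

    cliques: list[list[int]] = []
    for comp in sorted(nx.connected_components(g), key=min):
        comp = sorted(comp)
        if len(comp) == 1:
            cliques.append(comp)
            continue
        sub = W[np.ix_(comp, comp)]
        if len(comp) <= exact_limit:
            partition, _ = solve_cluster_editing_exact(sub)
        else:
            partition, _ = solve_cluster_editing_greedy(sub)
        cliques.extend([comp[local] for local in block] for block in partition)
    return cliques


def cluster_editing(
    peaklists: Sequence[PeakList],
    sim_threshold: float = 1.0,
    scaling: Scaling = Scaling(),
    exact_limit: int = 12,
) -> ClusterResult:
    """Weighted cluster editing of the peak similarity graph.

    Edge weight is ``sim_threshold − d(u, v)``: positive for similar
    pairs, negative for dissimilar ones.  The graph is edited into
    disjoint cliques at minimum total |weight| of deleted-positive and
    inserted-negative edges.  Connected components of the positive graph
    are solved independently — exactly (branch and bound) up to
    ``exact_limit`` peaks, greedily above.  Consensus peaks are clique
    centroids; no peak is noise (singletons form their own clique but
    cliques of size 1 produce no consensus feature only when requested
    downstream — here every clique is reported).
    """
    if sim_threshold <= 0:
        raise ValueError("sim_threshold must be > 0")
    keys, rt, ik0 = _flatten(peaklists)
    if not keys:
        return ClusterResult(consensus=[], assignment={})
    n = len(keys)
    dmat = scaling.pairwise(rt, ik0)
    W = sim_threshold - dmat
    np.fill_diagonal(W, 0.0)

    label = np.full(n, -1, dtype=int)
    for lab, clique in enumerate(partition_weight_matrix(W, exact_limit)):
        label[clique] = lab
    return _build_result(keys, rt, ik0, label)


# ---------------------------------------------------------------------------
# EM with merging
# ---------------------------------------------------------------------------


def cluster_em(
    peaklists: Sequence[PeakList],
    sigma_rt: float = 3.0,
    sigma_ik0: float = 0.003,
    merge_dist: float = 2.0,
    max_iter: int = 200,
    tol: float = 1e-8,
    prune_frac: float = 0.2,
    trace: list | None = None,
) -> ClusterResult:
    """Gaussian mixture clustering with fixed axis-aligned spread and merging.

    Peaks are modelled as draws from axis-aligned Gaussians with known
    standard deviations (sigma_rt, sigma_ik0) around unknown consensus
    positions.  EM updates component means and mixture weights only;
    after every iteration, components whose mean separation (normalised
    by the sigmas) falls below ``merge_dist`` are merged with
    weight-averaged means, letting the initial one-component-per-grid-
    cell overestimate of K collapse to the true number of analytes.
    Components whose mixture weight drops below ``prune_frac`` of the
    uniform share 1/K are annihilated (their mass reassigned by the next
    E-step), so stray single-point components do not survive as spurious
    consensus peaks.  Initialisation is a coarse deterministic
    grid-squares pass, so the result does not depend on peak order.
    """
    if sigma_rt <= 0 or sigma_ik0 <= 0:
        raise ValueError("sigmas must be > 0")
    keys, rt, ik0 = _flatten(peaklists)
    if not keys:
        return ClusterResult(consensus=[], assignment={})
    n = len(keys)
    # normalised coordinates: unit = one sigma in each dimension
    X = np.column_stack([rt / sigma_rt, ik0 / sigma_ik0])

    init = cluster_grid_squares(peaklists, cell_rt=2 * sigma_rt, cell_ik0=2 * sigma_ik0, min_count=1)
    mu = np.array([[c.rt / sigma_rt, c.ik0 / sigma_ik0] for c in init.consensus])
    K = mu.shape[0]
    w = np.full(K, 1.0 / K)

    prev_ll = -np.inf
    for _ in range(max_iter):
        # E-step in log space; constant 2πσ_rtσ_ik0 omitted (cancels)
        sq = ((X[:, None, :] - mu[None, :, :]) ** 2).sum(axis=2)  # (n, K)
        logp = -0.5 * sq + np.log(np.maximum(w, 1e-300))[None, :]
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        resp = np.exp(logp - lse[:, None])
        ll = float(lse.sum())
        if trace is not None:
            trace.append((K, ll))

        # M-step: means and weights only (sigmas are known)
        nk = resp.sum(axis=0)
        keep = nk > 1e-12
        resp, nk, w = resp[:, keep], nk[keep], w[keep]
        mu = (resp.T @ X) / nk[:, None]
        w = nk / n
        K = mu.shape[0]

        # merge components closer than merge_dist (normalised units);
        # transitive chains merge via connected components
        merged = False
        if K > 1:
            sep = np.sqrt(((mu[:, None, :] - mu[None, :, :]) ** 2).sum(axis=2))
            close = nx.Graph()
            close.add_nodes_from(range(K))
            iu, ju = np.triu_indices(K, 1)
            near = sep[iu, ju] < merge_dist
            close.add_edges_from(zip(iu[near].tolist(), ju[near].tolist()))
            groups = sorted((sorted(c) for c in nx.connected_components(close)), key=min)
            if len(groups) < K:
                merged = True
                new_mu, new_w = [], []
                for grp in groups:
                    gw = w[grp]
                    new_w.append(gw.sum())
                    new_mu.append((mu[grp] * gw[:, None]).sum(axis=0) / gw.sum())
                mu, w = np.array(new_mu), np.array(new_w)
                K = mu.shape[0]

        # annihilate components far below the uniform weight share
        if K > 1:
            keep = w >= prune_frac / K
            if keep.any() and not keep.all():
                mu, w = mu[keep], w[keep] / w[keep].sum()
                K = mu.shape[0]
                merged = True

        if not merged and abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    else:
        import warnings

        warnings.warn("EM clustering did not converge within max_iter", RuntimeWarning)

    # final hard assignment by maximum responsibility
    sq = ((X[:, None, :] - mu[None, :, :]) ** 2).sum(axis=2)
    logp = -0.5 * sq + np.log(np.maximum(w, 1e-300))[None, :]
    label = logp.argmax(axis=1)
    # drop empty components, relabel densely
    used = sorted(set(label.tolist()))
    remap = {old: new for new, old in enumerate(used)}
    label = np.array([remap[v] for v in label])
    positions = {
        remap[k]: (float(mu[k, 0] * sigma_rt), float(mu[k, 1] * sigma_ik0)) for k in used
    }
    return _build_result(keys, rt, ik0, label, positions=positions)
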