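"""Signed modularity, a signed Louvain optimizer, and consensus clustering.

Negative (repulsive) edges break ordinary modularity, so partition
quality is scored with the two-layer extension

    Q = 1 / (2 (v+ + v-)) * sum_{ij} [ (w+_ij - e+_ij) - (w-_ij - e-_ij) ] δ(M_i, M_j)

where the sum runs over ordered node pairs, v± are the total
positive/negative edge weights (each undirected edge counted once),
and e±_ij = s±_i s±_j / (2 v±) is the sign-separated configuration-model
expectation.  On an all-positive network this reduces exactly to
Newman–Girvan modularity; within-module positive weight is rewarded and
within-module negative weight penalized.  Q of the all-in-one partition
is 0 by construction.

The optimizer is the classic two-phase Louvain heuristic (greedy local
moves, then aggregation) with the gain function decomposed by sign
layer.  Because Louvain is stochastic in its node-visit order, modules
are defined by consensus: many restarts vote through a co-classification
matrix, which is thresholded and re-clustered until all restarts agree.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .cooccurrence import SignedNetwork
from .datatypes import ValidationError

__all__ = [
    "Partition",
    "LouvainResult",
    "ConsensusResult",
    "expected_weights",
    "signed_modularity",
    "louvain_signed",
    "consensus_cluster",
]

_EPS = 1e-12


@dataclass(frozen=True)
class Partition:
    """A node -> module assignment with contiguous module ids from 0."""

    membership: dict[str, int]

    def __post_init__(self):
        ids = sorted(set(self.membership.values()))
        if ids != list(range(len(ids))):
            # renumber to contiguous ids, preserving order of first use
            remap = {old: new for new, old in enumerate(ids)}
            object.__setattr__(
                self,
                "membership",
                {n: remap[m] for n, m in self.membership.items()},
            )

    @property
    def n_modules(self) -> int:
        return len(set(self.membership.values())) if self.membership else 0

    def labels(self, nodes) -> np.ndarray:
        return np.array([self.membership[n] for n in nodes], dtype=np.int64)

    def module_members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, m in self.membership.items():
            out.setdefault(m, []).append(node)
        return {m: sorted(v) for m, v in sorted(out.items())}

    def canonical(self) -> tuple:
        """Relabeling-invariant form (for comparing partitions)."""
        first_seen: dict[int, int] = {}
        out = []
        for node in sorted(self.membership):
            m = self.membership[node]
            out.append(first_seen.setdefault(m, len(first_seen)))
        return tuple(out)

    @classmethod
    def from_labels(cls, nodes, labels) -> "Partition":
        return cls(membership={n: int(m) for n, m in zip(nodes, labels)})


def _check_cover(net: SignedNetwork, partition: Partition) -> None:
    missing = set(net.nodes) - set(partition.membership)
    if missing:
        raise ValidationError(f"partition does not cover nodes {sorted(missing)[:5]}")


def expected_weights(net: SignedNetwork, i: str, j: str, sign: str) -> float:
    """Chance-expected weight between two nodes in one sign layer.

    Degree-preserving null model within the layer:
    e±_ij = s±_i s±_j / (2 v±); zero when the layer is empty.
    """
    if sign not in ("+", "-"):
        raise ValueError("sign must be '+' or '-'")
    for node in (i, j):
        if node not in net.frequencies:
            raise KeyError(f"node {node!r} not in network")
    sp, sm = net.strengths()
    if sign == "+":
        v = net.v_plus
        return sp[i] * sp[j] / (2.0 * v) if v > 0 else 0.0
    v = net.v_minus
    return sm[i] * sm[j] / (2.0 * v) if v > 0 else 0.0


def _modularity_from_arrays(wp: np.ndarray, wm: np.ndarray, labels: np.ndarray) -> float:
    """Q from dense layer matrices; diagonal entries hold twice the
    internal weight of an aggregated node (ordered-pair convention)."""
    tot_p = wp.sum()  # = 2 v+
    tot_m = wm.sum()
    denom = tot_p + tot_m  # = 2 (v+ + v-)
    if denom == 0:
        return 0.0
    sp = wp.sum(axis=1)
    sm = wm.sum(axis=1)
    q = 0.0
    for mod in np.unique(labels):
        idx = np.flatnonzero(labels == mod)
        q += wp[np.ix_(idx, idx)].sum()
        q -= wm[np.ix_(idx, idx)].sum()
        if tot_p > 0:
            q -= sp[idx].sum() ** 2 / tot_p
        if tot_m > 0:
            q += sm[idx].sum() ** 2 / tot_m
    return q / denom


def signed_modularity(net: SignedNetwork, partition: Partition) -> float:
    """Evaluate the signed modularity Q of a partition; Q in [-1, 1]."""
    if net.n_nodes == 0:
        raise ValidationError("modularity undefined on an empty network")
    _check_cover(net, partition)
    nodes, wp, wm = net.to_arrays()
    return _modularity_from_arrays(wp, wm, partition.labels(nodes))


def _local_move(
    wp: np.ndarray,
    wm: np.ndarray,
    labels: np.ndarray,
    rng: np.random.Generator,
) -> bool:
    """One local-moving phase, in place.  Returns True if anything moved.

    Moving node i into module c changes Q (up to the constant
    2/(2(v+ + v-)) factor) by

        [k+_{i,c} - s+_i S+_c / 2v+] - [k-_{i,c} - s-_i S-_c / 2v-]

    with i first removed from its module; k±_{i,c} is i's weight to c and
    S±_c the module's total strength.  Best gain wins; ties go to the
    lowest module id, and staying put wins ties against moving.
    """
    n = wp.shape[0]
    tot_p = wp.sum()
    tot_m = wm.sum()
    sp = wp.sum(axis=1)
    sm = wm.sum(axis=1)
    n_mod = labels.max() + 1
    comm_sp = np.bincount(labels, weights=sp, minlength=n_mod)
    comm_sm = np.bincount(labels, weights=sm, minlength=n_mod)

    moved_any = False
    improved = True
    while improved:
        improved = False
        order = rng.permutation(n)
        for i in order:
            current = labels[i]
            # weights from i to each module, excluding the self-loop
            kp = np.bincount(labels, weights=wp[i], minlength=n_mod)
            km = np.bincount(labels, weights=wm[i], minlength=n_mod)
            kp[current] -= wp[i, i]
            km[current] -= wm[i, i]
            # remove i from its module
            comm_sp[current] -= sp[i]
            comm_sm[current] -= sm[i]
            gain = kp - km
            if tot_p > 0:
                gain = gain - sp[i] * comm_sp / tot_p
            if tot_m > 0:
                gain = gain + sm[i] * comm_sm / tot_m
            best = int(np.argmax(gain))  # argmax takes the lowest id on ties
            if gain[best] > gain[current] + _EPS and best != current:
                labels[i] = best
                improved = True
                moved_any = True
            comm_sp[labels[i]] += sp[i]
            comm_sm[labels[i]] += sm[i]
    return moved_any


def _compress_labels(labels: np.ndarray) -> np.ndarray:
    _, compact = np.unique(labels, return_inverse=True)
    return compact.astype(np.int64)


def _aggregate(wp: np.ndarray, wm: np.ndarray, labels: np.ndarray):
    """Collapse modules into super-nodes, summing weights per sign layer.

    The diagonal of the aggregated matrices accumulates the ordered-pair
    internal weight (each internal undirected edge twice), which keeps
    strengths and totals invariant across levels.
    """
    k = labels.max() + 1
    m = np.zeros((wp.shape[0], k))
    m[np.arange(wp.shape[0]), labels] = 1.0
    return m.T @ wp @ m, m.T @ wm @ m


@dataclass
class LouvainResult:
    partition: Partition
    modularity: float
    phase_modularity: list[float] = field(default_factory=list)


def louvain_signed(net: SignedNetwork, seed: int | np.random.SeedSequence = 0) -> LouvainResult:
    """Greedy signed-modularity maximization (Louvain heuristic).

    Deterministic given ``seed``: the only stochastic ingredient is the
    node-visit order in the local-moving phases.  The reported Q never
    decreases from one phase to the next; an edgeless network yields the
    all-singleton partition.
    """
    if net.n_nodes == 0:
        raise ValidationError("cannot cluster an empty network")
    rng = np.random.default_rng(seed)
    nodes, wp0, wm0 = net.to_arrays()
    wp, wm = wp0.copy(), wm0.copy()
    # node_map[i] = module of original node i at the current level
    node_map = np.arange(len(nodes), dtype=np.int64)
    labels = np.arange(wp.shape[0], dtype=np.int64)
    phase_q = [_modularity_from_arrays(wp0, wm0, node_map)]

    while True:
        moved = _local_move(wp, wm, labels, rng)
        labels = _compress_labels(labels)
        node_map = labels[node_map]
        q = _modularity_from_arrays(wp0, wm0, node_map)
        phase_q.append(q)
        if not moved or labels.max() + 1 == wp.shape[0]:
            break
        wp, wm = _aggregate(wp, wm, labels)
        labels = np.arange(wp.shape[0], dtype=np.int64)

    partition = Partition.from_labels(nodes, _compress_labels(node_map))
    return LouvainResult(
        partition=partition, modularity=phase_q[-1], phase_modularity=phase_q
    )


@dataclass
class ConsensusResult:
    """Outcome of consensus clustering.

    ``co_classification`` is the node-by-node fraction of first-round
    restarts placing the two nodes in one module (symmetric, unit
    diagonal); ``final_partition`` is the agreed partition, and
    ``converged`` is False if the iteration cap was hit before all
    restarts agreed.
    """

    co_classification: np.ndarray
    node_order: tuple[str, ...]
    final_partition: Partition
    modularity: float
    runs: int
    threshold: float
    iterations: int
    converged: bool


def _coassignment_matrix(partitions: list[Partition], nodes) -> np.ndarray:
    mats = np.stack([p.labels(nodes) for p in partitions])
    same = (mats[:, :, None] == mats[:, None, :]).mean(axis=0)
    return same


def _consensus_graph(c: np.ndarray, threshold: float, nodes) -> SignedNetwork:
    edges = {}
    k = len(nodes)
    for i in range(k):
        for j in range(i + 1, k):
            if c[i, j] >= threshold:
                edges[(nodes[i], nodes[j])] = float(c[i, j])
    freqs = {n: 1 for n in nodes}
    return SignedNetwork(nodes=tuple(nodes), frequencies=freqs, edges=edges)


def consensus_cluster(
    net: SignedNetwork,
    runs: int = 100,
    threshold: float = 0.40,
    seed: int = 0,
    max_iter: int = 20,
) -> ConsensusResult:
    """Consensus clustering over repeated signed-Louvain restarts.

    Each round runs Louvain ``runs`` times with distinct sub-seeds and
    builds the co-classification fraction matrix.  If all restarts agree
    the partition is final; otherwise entries below ``threshold`` are
    zeroed and the remaining fractions form an all-positive consensus
    graph that is clustered in the next round.  Hitting ``max_iter``
    before agreement flags ``converged=False`` instead of raising.
    """
    if runs < 2:
        raise ValidationError("consensus needs at least 2 runs")
    if not 0.0 < threshold < 1.0:
        raise ValidationError("threshold must lie in (0, 1)")
    nodes = net.nodes
    ss = np.random.SeedSequence(seed)
    first_matrix: np.ndarray | None = None
    current = net
    partitions: list[Partition] = []
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        children = ss.spawn(runs)
        results = [louvain_signed(current, child) for child in children]
        partitions = [r.partition for r in results]
        c = _coassignment_matrix(partitions, nodes)
        if first_matrix is None:
            first_matrix = c
        canon = Counter(p.canonical() for p in partitions)
        if len(canon) == 1:
            converged = True
            break
        current = _consensus_graph(c, threshold, nodes)

    # final partition: the agreed one, or the modal partition of the last round
    modal = Counter(p.canonical() for p in partitions).most_common(1)[0][0]
    final = next(p for p in partitions if p.canonical() == modal)
    q = signed_modularity(net, final)
    return ConsensusResult(
        co_classification=first_matrix,
        node_order=nodes,
        final_partition=final,
        modularity=q,
        runs=runs,
        threshold=threshold,
        iterations=iteration,
        converged=converged,
    )
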