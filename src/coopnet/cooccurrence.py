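"""Signed statistical co-occurrence networks over a filtered corpus.

Every unordered token pair gets the 2x2 log-likelihood ratio statistic
(Dunning's G) comparing the observed joint mention pattern against
independence of the two tokens across participants:

    G = 2 * sum_cells O * ln(O / E),   E = row_margin * col_margin / N

The edge weight is +G when the pair co-occurs more often than expected
(attractive) and -G when less often (repulsive); pairs exactly at their
expectation carry no edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

from .datatypes import Corpus, ValidationError

__all__ = [
    "UndefinedStatisticError",
    "DegenerateNetworkError",
    "PairTable",
    "pair_table",
    "loglikelihood_ratio",
    "signed_weight",
    "SignedNetwork",
    "build_network",
]


class UndefinedStatisticError(ValueError):
    """The G statistic is undefined (a zero margin leaves nothing to test)."""


class DegenerateNetworkError(ValueError):
    """Fewer than two retained tokens: no pairs to score."""


@dataclass(frozen=True)
class PairTable:
    """2x2 participant counts for a token pair.

    n11 mention both tokens, n10 only the first, n01 only the second,
    n00 neither; N = n11 + n10 + n01 + n00.
    """

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self):
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValidationError("pair-table counts must be non-negative")

    @property
    def N(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def expected11(self) -> float:
        """Expected joint count under independence of the two tokens."""
        return (self.n11 + self.n10) * (self.n11 + self.n01) / self.N

    def as_array(self) -> np.ndarray:
        return np.array([[self.n11, self.n10], [self.n01, self.n00]], dtype=float)


def pair_table(corpus: Corpus, token_i: str, token_j: str) -> PairTable:
    """Cross-tabulate two tokens over retained participants.

    Counts use duplicate-collapsed token sets: a participant contributes
    at most one unit to any cell.  Self-pairs are undefined.
    """
    if token_i == token_j:
        raise ValidationError(f"self-pair {token_i!r} is undefined")
    for tok in (token_i, token_j):
        if tok not in corpus.lexicon:
            raise KeyError(f"token {tok!r} not in retained lexicon")
    if not corpus.records:
        raise ValidationError("empty corpus")
    n11 = n10 = n01 = n00 = 0
    for rec in corpus.records:
        toks = rec.token_set()
        has_i, has_j = token_i in toks, token_j in toks
        if has_i and has_j:
            n11 += 1
        elif has_i:
            n10 += 1
        elif has_j:
            n01 += 1
        else:
            n00 += 1
    return PairTable(n11, n10, n01, n00)


def loglikelihood_ratio(t: PairTable) -> float:
    """Dunning's G for a 2x2 table: twice the log-likelihood ratio
    between the saturated multinomial and the independence model.

    Terms with O = 0 contribute nothing.  A zero margin (a token
    mentioned by nobody, or by everybody) makes independence untestable
    and raises :class:`UndefinedStatisticError`.  G >= 0 always.
    """
    obs = t.as_array()
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    n = obs.sum()
    if n == 0 or np.any(rows == 0) or np.any(cols == 0):
        raise UndefinedStatisticError(f"zero margin in table {obs.tolist()}")
    expected = np.outer(rows, cols) / n
    g = 2.0 * float(np.sum(xlogy(obs, obs) - xlogy(obs, expected)))
    return max(g, 0.0)  # clip tiny negative round-off


def signed_weight(t: PairTable) -> float:
    """Signed edge weight: +G for attraction, -G for repulsion.

    The sign compares the observed joint count with its independence
    expectation; a pair exactly at expectation gets weight 0 (no edge).
    """
    g = loglikelihood_ratio(t)
    e11 = t.expected11
    if t.n11 > e11:
        return g
    if t.n11 < e11:
        return -g
    return 0.0


@dataclass
class SignedNetwork:
    """Tokens with participant frequencies and signed weighted edges.

    ``edges`` maps lexicographically ordered token pairs to nonzero
    signed weights.  Strengths and layer totals are derived from edges:
    v+ is the total positive weight and v- the total magnitude of
    negative weight, each undirected edge counted once.
    """

    nodes: tuple[str, ...]
    frequencies: dict[str, int]
    edges: dict[tuple[str, str], float]
    n_participants: int = 0

    def __post_init__(self):
        for (u, v), w in self.edges.items():
            if u == v:
                raise ValidationError(f"self-edge on {u!r}")
            if u not in self.frequencies or v not in self.frequencies:
                raise ValidationError(f"edge ({u!r}, {v!r}) references unknown node")
            if not np.isfinite(w):
                raise ValidationError(f"non-finite weight on ({u!r}, {v!r})")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def v_plus(self) -> float:
        return sum(w for w in self.edges.values() if w > 0)

    @property
    def v_minus(self) -> float:
        return sum(-w for w in self.edges.values() if w < 0)

    def strengths(self) -> tuple[dict[str, float], dict[str, float]]:
        """Per-node positive and negative strengths (s+, s-)."""
        sp = {n: 0.0 for n in self.nodes}
        sm = {n: 0.0 for n in self.nodes}
        for (u, v), w in self.edges.items():
            if w > 0:
                sp[u] += w
                sp[v] += w
            else:
                sm[u] -= w
                sm[v] -= w
        return sp, sm

    def to_arrays(self) -> tuple[tuple[str, ...], np.ndarray, np.ndarray]:
        """Dense symmetric positive/negative weight matrices (node order)."""
        index = {n: i for i, n in enumerate(self.nodes)}
        k = len(self.nodes)
        wp = np.zeros((k, k))
        wm = np.zeros((k, k))
        for (u, v), w in self.edges.items():
            i, j = index[u], index[v]
            if w > 0:
                wp[i, j] = wp[j, i] = w
            else:
                wm[i, j] = wm[j, i] = -w
        return self.nodes, wp, wm

    def summary(self) -> dict:
        n_pos = sum(1 for w in self.edges.values() if w > 0)
        n_neg = len(self.edges) - n_pos
        return {
            "n_nodes": self.n_nodes,
            "n_edges_positive": n_pos,
            "n_edges_negative": n_neg,
            "v_plus": self.v_plus,
            "v_minus": self.v_minus,
        }


def build_network(corpus: Corpus) -> SignedNetwork:
    """Score every unordered token pair and assemble the signed network.

    All pairs of retained tokens are evaluated; only nonzero signed
    weights become edges, so isolated nodes are possible.  Pairs whose
    2x2 table has a zero margin (a token mentioned by every retained
    participant) carry no measurable deviation and contribute no edge.
    """
    tokens = tuple(sorted(corpus.lexicon))
    if len(tokens) < 2:
        raise DegenerateNetworkError(
            f"need at least 2 retained tokens, have {len(tokens)}"
        )
    n = corpus.n_participants
    index = {t: k for k, t in enumerate(tokens)}
    incidence = np.zeros((n, len(tokens)), dtype=np.int64)
    for r, rec in enumerate(corpus.records):
        for tok in rec.token_set():
            incidence[r, index[tok]] = 1

    counts = incidence.sum(axis=0)  # participants per token
    joint = incidence.T @ incidence  # n11 for every pair
    ci = counts[:, None].astype(float)
    cj = counts[None, :].astype(float)
    n11 = joint.astype(float)
    n10 = ci - n11
    n01 = cj - n11
    n00 = n - ci - cj + n11
    e11 = ci * cj / n

    with np.errstate(invalid="ignore", divide="ignore"):
        g = 2.0 * (
            xlogy(n11, n11) + xlogy(n10, n10) + xlogy(n01, n01) + xlogy(n00, n00)
            - xlogy(n11, e11)
            - xlogy(n10, ci * (n - cj) / n)
            - xlogy(n01, (n - ci) * cj / n)
            - xlogy(n00, (n - ci) * (n - cj) / n)
        )
    g = np.clip(g, 0.0, None)
    sign = np.sign(n11 - e11)
    weights = sign * g
    # zero-margin pairs (token mentioned by all or none) carry no edge
    degenerate = (ci == 0) | (cj == 0) | (ci == n) | (cj == n)
    weights[degenerate] = 0.0

    edges: dict[tuple[str, str], float] = {}
    iu, ju = np.triu_indices(len(tokens), k=1)
    for i, j in zip(iu, ju):
        w = weights[i, j]
        if w != 0.0:
            edges[(tokens[i], tokens[j])] = float(w)
    freqs = {tok: int(counts[index[tok]]) for tok in tokens}
    return SignedNetwork(
        nodes=tokens, frequencies=freqs, edges=edges, n_participants=n
    )
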