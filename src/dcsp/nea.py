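"""Network enrichment analysis (NEA) between gene-set pairs.

The enrichment statistic is the standardized link count

    z = (d_AF - mean_null(d_AF)) / sd_null(d_AF)

where ``d_AF`` is the number of functional-network edges joining an altered
gene set (AGS) and a functional gene set (FGS).  The null distribution of the
link count is taken over degree-preserving randomizations of the network,
either by explicit double-edge-swap permutation or by a closed-form
configuration-model approximation.  The z-scores are converted to probability
weights through the standard normal CDF, so w = Phi(z) lies in (0, 1) with 0.5
at z = 0, increasing with the strength of connectivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
from scipy.stats import norm

from .errors import NetworkSupportError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "NEAResult",
    "ConnectivityWeights",
    "count_links",
    "null_link_distribution",
    "nea_z",
    "weights_from_z",
]


@dataclass(frozen=True)
class NEAResult:
    """Observed link count, its null moments and the enrichment z-score."""

    d_af: int
    null_mean: float
    null_sd: float
    z: float


@dataclass(frozen=True)
class ConnectivityWeights:
    """NEA z-scores and probability weights for the three gene-set pairs
    (targets<->drivers, drivers<->pathway, targets<->pathway)."""

    z1: float
    z2: float
    z3: float
    w1: float
    w2: float
    w3: float

    @property
    def factor(self) -> float:
        """The multiplicative pathway-score factor 1 + w1 + w2 + w3."""
        return 1.0 + self.w1 + self.w2 + self.w3


NEUTRAL_WEIGHTS = ConnectivityWeights(0.0, 0.0, 0.0, 0.5, 0.5, 0.5)


def _restrict(network: nx.Graph, ags: Iterable[str], fgs: Iterable[str]):
    a = frozenset(ags) & set(network.nodes)
    f = frozenset(fgs) & set(network.nodes)
    return a, f


def count_links(network: nx.Graph, ags: Iterable[str], fgs: Iterable[str]) -> int:
    """Count undirected edges with one endpoint in AGS and the other in FGS.

    Each qualifying edge is counted exactly once, including edges whose two
    endpoints both lie in the intersection of the sets.  Set members absent
    from the network are dropped before counting; an error is raised only when
    both sets lose all support in the network.
    """
    a, f = _restrict(network, ags, fgs)
    if not a and not f:
        raise NetworkSupportError("neither gene set has any member in the network")
    count = 0
    for u, v in network.edges(a | f):
        if u == v:
            continue
        if (u in a and v in f) or (v in a and u in f):
            count += 1
    return count


def _eligible_pairs(a: frozenset, f: frozenset) -> set[frozenset]:
    """Unordered node pairs {x, y} with x in AGS, y in FGS, x != y."""
    return {frozenset((x, y)) for x in a for y in f if x != y}


def _analytic_null(network: nx.Graph, a: frozenset, f: frozenset) -> tuple[float, float]:
    e = network.number_of_edges()
    deg = dict(network.degree())
    mean = 0.0
    for pair in _eligible_pairs(a, f):
        x, y = tuple(pair)
        mean += deg[x] * deg[y] / (2.0 * e)
    # Poisson approximation to the permutation null
    return mean, float(np.sqrt(mean))


def _double_edge_swap(edges: np.ndarray, attempts: int, rng: np.random.Generator,
                      edge_set: set[tuple[int, int]]) -> None:
    """In-place lazy double-edge-swap chain on an integer edge array.

    Two edges are drawn uniformly; the proposed swap (a,b),(c,d) -> (a,d),(c,b)
    is applied only if it creates neither a self-loop nor a multi-edge, else the
    chain stays in place.  This lazy chain has the uniform distribution over
    simple graphs with the given degree sequence as its stationary law.
    """
    n_edges = len(edges)
    picks = rng.integers(0, n_edges, size=(attempts, 2))
    flips = rng.random(attempts) < 0.5
    for (i, j), flip in zip(picks, flips):
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if flip:
            c, d = d, c
        # propose (a,d) and (c,b)
        if a == d or c == b:
            continue
        e1 = (a, d) if a < d else (d, a)
        e2 = (c, b) if c < b else (b, c)
        if e1 in edge_set or e2 in edge_set:
            continue
        old1 = (a, b) if a < b else (b, a)
        old2 = (c, d) if c < d else (d, c)
        edge_set.discard(old1)
        edge_set.discard(old2)
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = e1
        edges[j] = e2


def null_link_distribution(network: nx.Graph, ags: Iterable[str], fgs: Iterable[str],
                           mode: str = "analytic", n_perm: int = 1000,
                           seed: int | None = None,
                           swap_factor: int = 10) -> tuple[float, float]:
    """Null mean and standard deviation of the AGS-FGS link count.

    ``mode="permute_network"`` draws ``n_perm`` degree-preserving rewirings of
    the network (``swap_factor * |E|`` lazy double-edge-swap attempts per
    replicate) and returns the empirical mean/sd of the link count.
    ``mode="analytic"`` returns the configuration-model expectation
    ``sum k_x k_y / (2E)`` over eligible pairs with a Poisson-approximation sd
    of ``sqrt(mean)``; this is an approximation to the permutation null.
    """
    if mode not in ("permute_network", "analytic"):
        raise ValidationError(f"unknown null mode {mode!r}")
    if network.number_of_edges() < 2:
        raise ValidationError("null distribution needs a network with >= 2 edges")
    a, f = _restrict(network, ags, fgs)
    if not a and not f:
        raise NetworkSupportError("neither gene set has any member in the network")
    if not a or not f:
        return 0.0, 0.0  # degenerate: no cross links are possible
    if mode == "analytic":
        return _analytic_null(network, a, f)

    if n_perm < 100:
        raise ValidationError("permute_network requires n_perm >= 100")
    rng = np.random.default_rng(seed)
    nodes = sorted(network.nodes)
    index = {g: i for i, g in enumerate(nodes)}
    base = np.array(sorted(tuple(sorted((index[u], index[v]))) for u, v in network.edges()),
                    dtype=np.int64)
    in_a = np.zeros(len(nodes), dtype=bool)
    in_f = np.zeros(len(nodes), dtype=bool)
    in_a[[index[g] for g in a]] = True
    in_f[[index[g] for g in f]] = True
    attempts = swap_factor * len(base)
    counts = np.empty(n_perm)
    for r in range(n_perm):
        edges = base.copy()
        edge_set = {tuple(e) for e in edges}
        _double_edge_swap(edges, attempts, rng, edge_set)
        u, v = edges[:, 0], edges[:, 1]
        counts[r] = np.count_nonzero((in_a[u] & in_f[v]) | (in_f[u] & in_a[v]))
    return float(counts.mean()), float(counts.std(ddof=1))


def nea_z(network: nx.Graph, ags: Iterable[str], fgs: Iterable[str],
          mode: str = "analytic", n_perm: int = 1000, seed: int | None = None,
          swap_factor: int = 10) -> NEAResult:
    """Enrichment z-score between two gene sets; z = 0 on a degenerate null."""
    a, f = _restrict(network, ags, fgs)
    if not a and not f:
        raise NetworkSupportError("neither gene set has any member in the network")
    d = count_links(network, a, f) if (a and f) else 0
    mean, sd = null_link_distribution(network, a, f, mode=mode, n_perm=n_perm,
                                      seed=seed, swap_factor=swap_factor)
    z = (d - mean) / sd if sd > 0 else 0.0
    return NEAResult(d_af=d, null_mean=mean, null_sd=sd, z=float(z))


def weights_from_z(z1: float, z2: float, z3: float) -> ConnectivityWeights:
    """Convert the three enrichment z-scores to normal probability weights.

    w_i = Phi(z_i): strictly increasing in z_i, 0.5 at z = 0, approaching 0
    (no functional interaction) and 1 (high interaction) in the tails.
    """
    for z in (z1, z2, z3):
        if not np.isfinite(z):
            raise ValidationError("z-scores must be finite")
    w1, w2, w3 = norm.cdf([z1, z2, z3])
    return ConnectivityWeights(z1=float(z1), z2=float(z2), z3=float(z3),
                               w1=float(w1), w2=float(w2), w3=float(w3))
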