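"""Gene-gene interaction network: loading, filtering, and randomization tests.

The network is an undirected :class:`networkx.Graph` whose nodes are gene
identifiers and whose edges carry a ``confidence`` attribute in [0, 1]
(STRING-style scores on the 0-999 integer scale are normalized by 1000).
All statistics that compare a gene set against "random genes" draw uniform
same-size node sets and report empirical p-values with the (r+1)/(n+1)
estimator, which can never return zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

#: The interaction network type: an undirected graph with a ``confidence``
#: edge attribute. Kept as a plain networkx graph so the whole networkx
#: toolbox applies.
InteractionNetwork = nx.Graph


@dataclass(frozen=True)
class DegreeConstraint:
    """Connectivity profile for degree-matched random gene sets.

    ``median_degree`` is matched to within ``tolerance`` (absolute, in degree
    units) and every sampled gene must have degree >= ``min_degree``.
    """

    set_size: int
    median_degree: float
    min_degree: int
    tolerance: float = 0.0

    def __post_init__(self) -> None:
        if self.set_size < 1:
            raise ValueError("set_size must be positive")
        if self.min_degree > self.median_degree:
            raise ValueError("min_degree must not exceed median_degree")
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")


def load_network(
    path: str | Path,
    score_threshold: float = 0.7,
    score_scale: str = "unit",
) -> InteractionNetwork:
    """Load an edge-list TSV (gene_a, gene_b, score) keeping edges at or above a confidence cutoff.

    Parameters
    ----------
    path:
        Tab-separated file with at least three columns. A header row whose
        third field is not numeric is skipped.
    score_threshold:
        Minimum normalized confidence in [0, 1] for an edge to be kept.
    score_scale:
        ``"unit"`` for scores already in [0, 1]; ``"string999"`` for STRING's
        0-999 integers, divided by 1000.

    Self-loops are dropped (logged); duplicate pairs keep the maximum score.
    """
    if not 0.0 <= score_threshold <= 1.0:
        raise ValueError(f"score_threshold must be in [0, 1], got {score_threshold}")
    if score_scale not in ("unit", "string999"):
        raise ValueError(f"unknown score_scale {score_scale!r}")

    net: InteractionNetwork = nx.Graph()
    n_self, n_dup = 0, 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            a, b, raw = fields[0], fields[1], fields[2]
            try:
                score = float(raw)
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ValueError(f"{path}:{lineno}: non-numeric score {raw!r}") from None
            if score_scale == "string999":
                score /= 1000.0
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"{path}:{lineno}: confidence {score} outside [0, 1]")
            if a == b:
                n_self += 1
                continue
            if score < score_threshold:
                continue
            if net.has_edge(a, b):
                n_dup += 1
                score = max(score, net[a][b]["confidence"])
            net.add_edge(a, b, confidence=score)
    if n_self:
        logger.info("dropped %d self-loop row(s) from %s", n_self, path)
    if n_dup:
        logger.info("merged %d duplicate edge row(s) (kept max score)", n_dup)
    return net


def write_network(net: InteractionNetwork, path: str | Path) -> None:
    """Write the network as a gene_a/gene_b/score TSV with a header row."""
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tscore\n")
        for a, b, data in sorted(net.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data.get('confidence', 1.0):g}\n")


def largest_connected_component(net: InteractionNetwork) -> InteractionNetwork:
    """Induced subgraph on the largest connected component.

    Ties on size are broken toward the component whose sorted node list is
    lexicographically smallest, making the result deterministic.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network has no connected component")
    components = list(nx.connected_components(net))
    max_size = max(len(c) for c in components)
    best = min((c for c in components if len(c) == max_size), key=sorted)
    return net.subgraph(best).copy()


def _check_members(net: InteractionNetwork, genes: Iterable[str]) -> list[str]:
    genes = list(genes)
    missing = [g for g in genes if g not in net]
    if missing:
        raise KeyError(f"genes absent from network: {sorted(missing)}")
    return genes


def degree_summary(net: InteractionNetwork, genes: Iterable[str]) -> tuple[float, int]:
    """(median degree, minimum degree) of ``genes``, degrees taken in the full network."""
    members = _check_members(net, genes)
    if not members:
        raise ValueError("empty gene set")
    degrees = np.array([net.degree[g] for g in members])
    return float(np.median(degrees)), int(degrees.min())


def internal_edge_count(net: InteractionNetwork, genes: Iterable[str]) -> int:
    """Number of network edges with both endpoints inside ``genes``."""
    members = set(_check_members(net, genes))
    return sum(1 for a, b in net.edges(members) if a in members and b in members)


def connectivity_permutation_test(
    net: InteractionNetwork,
    genes: Iterable[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[int, float, float]:
    """Test whether ``genes`` are more internally connected than random same-size sets.

    Returns ``(observed, null_mean, p)`` where the null draws uniform node
    sets of the same size and ``p = (r+1)/(n_perm+1)`` with
    ``r = #{null internal-edge counts >= observed}``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    members = _check_members(net, genes)
    observed = internal_edge_count(net, members)
    nodes = np.array(sorted(net.nodes()))
    rng = np.random.default_rng(seed)
    k = len(members)
    null = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        draw = nodes[rng.choice(len(nodes), size=k, replace=False)]
        null[i] = internal_edge_count(net, draw)
    r = int((null >= observed).sum())
    p = (r + 1) / (n_perm + 1)
    return observed, float(null.mean()), p


def mean_shortest_path_test(
    net: InteractionNetwork,
    genes: Iterable[str],
    n_random: int = 1000,
    seed: int = 0,
) -> tuple[float, list[float], float]:
    """Compare the mean pairwise shortest-path length of ``genes`` against random sets.

    Operates inside the largest connected component; ``genes`` are restricted
    to it. Path lengths are unweighted hop counts. The p-value is the
    one-sided empirical rank of the observed mean within the null means
    (smaller mean = more clustered = significant).
    """
    if n_random < 2:
        raise ValueError("n_random must be >= 2")
    comp = largest_connected_component(net)
    members = sorted(set(genes) & set(comp.nodes()))
    if len(members) < 2:
        raise ValueError("fewer than 2 genes fall inside the largest connected component")

    def mean_pairwise(sub: Sequence[str]) -> float:
        total, pairs = 0, 0
        for i, src in enumerate(sub):
            dist = nx.single_source_shortest_path_length(comp, src)
            for tgt in sub[i + 1 :]:
                total += dist[tgt]
                pairs += 1
        return total / pairs

    observed_mean = mean_pairwise(members)
    nodes = np.array(sorted(comp.nodes()))
    rng = np.random.default_rng(seed)
    null_means = []
    for _ in range(n_random):
        draw = list(nodes[rng.choice(len(nodes), size=len(members), replace=False)])
        null_means.append(mean_pairwise(draw))
    r = sum(1 for m in null_means if m <= observed_mean)
    p = (r + 1) / (n_random + 1)
    return observed_mean, null_means, p
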