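"""Disease-module detection by permutation-weighted maximal cliques.

A disease module is built in four steps:

1. enumerate all maximal cliques of the interaction network (Bron-Kerbosch
   with pivoting, via networkx);
2. weigh each clique by the sum of -log10 P over its member genes, taking
   the per-gene P-values from a differential-expression contrast (genes in
   the network but never measured contribute P = 1, i.e. weight 0);
3. compare each clique's weight against a null built by globally shuffling
   the gene -> P assignment over the whole gene universe, recomputing every
   clique weight on the same shuffle (one shuffle per permutation, shared by
   all cliques, preserving the null's inter-clique correlation);
   empirical P = (r+1)/(n_perm+1);
4. take the union of the cliques with empirical P below a fixed threshold
   (default 0.01) as the module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

from .interactome import InteractionNetwork

logger = logging.getLogger(__name__)


@dataclass
class CliqueScore:
    """A maximal clique with its differential-expression weight and empirical P."""

    genes: frozenset[str]
    weight: float | None = None
    empirical_p: float | None = None

    def sorted_genes(self) -> list[str]:
        return sorted(self.genes)


@dataclass
class DiseaseModule:
    """Union of the significantly heavy cliques for one disease contrast."""

    disease_name: str
    genes: frozenset[str]
    source_cliques: list[CliqueScore] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "disease_name": self.disease_name,
            "genes": sorted(self.genes),
            "cliques": [
                {
                    "genes": c.sorted_genes(),
                    "weight": c.weight,
                    "empirical_p": c.empirical_p,
                }
                for c in self.source_cliques
            ],
        }


def enumerate_maximal_cliques(
    net: InteractionNetwork, min_size: int = 2
) -> list[CliqueScore]:
    """All maximal cliques of size >= ``min_size``, in deterministic order.

    Ordering: decreasing size, then lexicographic on the sorted gene list.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    cliques = [frozenset(c) for c in nx.find_cliques(net) if len(c) >= min_size]
    cliques.sort(key=lambda c: (-len(c), sorted(c)))
    return [CliqueScore(genes=c) for c in cliques]


def _neglog10_p(de: pd.DataFrame) -> pd.Series:
    p = de["p"].astype(float)
    if (p <= 0).any():
        bad = de.index[p <= 0].tolist()
        raise ValueError(f"non-positive P-values for genes: {bad[:10]}")
    if (p > 1).any():
        bad = de.index[p > 1].tolist()
        raise ValueError(f"P-values above 1 for genes: {bad[:10]}")
    return -np.log10(p)


def weigh_cliques(cliques: list[CliqueScore], de: pd.DataFrame) -> list[CliqueScore]:
    """Set each clique's weight to the sum of -log10 P over its genes.

    Genes with no measured P-value are treated as P = 1 (contribute 0).
    """
    nlp = _neglog10_p(de)
    out = []
    for c in cliques:
        weight = float(sum(nlp.get(g, 0.0) for g in c.genes))
        out.append(CliqueScore(genes=c.genes, weight=weight, empirical_p=c.empirical_p))
    return out


def _clique_membership(
    cliques: list[CliqueScore], universe: list[str]
) -> sparse.csr_matrix:
    """Sparse (cliques x universe) 0/1 membership matrix."""
    index = {g: i for i, g in enumerate(universe)}
    rows, cols = [], []
    for ci, c in enumerate(cliques):
        for g in c.genes:
            rows.append(ci)
            cols.append(index[g])
    data = np.ones(len(rows))
    return sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(cliques), len(universe))
    )


def clique_significance(
    cliques: list[CliqueScore],
    de: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
    extra_universe_genes: set[str] | None = None,
    batch_size: int = 2000,
) -> list[CliqueScore]:
    """Empirical P per clique under global gene->P shuffling.

    Each permutation shuffles the gene -> P map once across the whole
    universe (clique genes plus measured genes plus ``extra_universe_genes``)
    and recomputes every clique weight on that shuffle;
    ``empirical_p = (r+1)/(n_perm+1)`` with r the number of permutations whose
    weight reaches the real weight. Weights are set on the returned cliques.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    nlp = _neglog10_p(de)
    universe = set(nlp.index) | {g for c in cliques for g in c.genes}
    if extra_universe_genes:
        universe |= set(extra_universe_genes)
    universe = sorted(universe)
    values = np.array([nlp.get(g, 0.0) for g in universe])

    M = _clique_membership(cliques, universe)
    observed = M @ values  # real weights

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(cliques), dtype=np.int64)
    done = 0
    while done < n_perm:
        b = min(batch_size, n_perm - done)
        perms = np.empty((len(universe), b))
        for j in range(b):
            perms[:, j] = values[rng.permutation(len(universe))]
        null_weights = M @ perms  # cliques x b
        exceed += (null_weights >= observed[:, None]).sum(axis=1)
        done += b
    pvals = (exceed + 1) / (n_perm + 1)
    return [
        CliqueScore(genes=c.genes, weight=float(observed[i]), empirical_p=float(pvals[i]))
        for i, c in enumerate(cliques)
    ]


def assemble_module(
    cliques: list[CliqueScore], alpha: float = 0.01, disease_name: str = ""
) -> DiseaseModule:
    """Union of the cliques with empirical P < ``alpha`` (fixed per-clique threshold)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    significant = [c for c in cliques if c.empirical_p is not None and c.empirical_p < alpha]
    genes: set[str] = set()
    for c in significant:
        genes |= c.genes
    return DiseaseModule(
        disease_name=disease_name, genes=frozenset(genes), source_cliques=significant
    )


def detect_disease_module(
    net: InteractionNetwork,
    de: pd.DataFrame,
    n_perm: int = 10_000,
    alpha: float = 0.01,
    seed: int = 0,
    min_size: int = 2,
    disease_name: str = "",
    cliques: list[CliqueScore] | None = None,
) -> DiseaseModule:
    """Full detection pipeline: enumerate, weigh, permute, assemble.

    ``cliques`` may carry a pre-enumerated clique list (the network does not
    change between diseases, so enumeration can be shared).
    """
    if cliques is None:
        cliques = enumerate_maximal_cliques(net, min_size=min_size)
    logger.info("%s: %d maximal cliques (size >= %d)", disease_name or "disease", len(cliques), min_size)
    scored = clique_significance(
        cliques, de, n_perm=n_perm, seed=seed, extra_universe_genes=set(net.nodes())
    )
    module = assemble_module(scored, alpha=alpha, disease_name=disease_name)
    logger.info(
        "%s: %d significant cliques -> %d module genes",
        disease_name or "disease",
        len(module.source_cliques),
        len(module.genes),
    )
    return module
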