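"""Cross-disease pleiotropy: module intersection, randomized null, gene-level P.

The pleiotropic module is the intersection of all per-disease modules. Its
significance comes from repeating the whole detection analysis (default 100
times) with each disease's gene -> P map independently shuffled, recording
the null intersection sizes and per-gene module counts. Fold enrichment of
the intersection is its observed size over the mean null size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .interactome import InteractionNetwork
from .module_detection import (
    CliqueScore,
    assemble_module,
    clique_significance,
    enumerate_maximal_cliques,
)

logger = logging.getLogger(__name__)


@dataclass
class PleiotropyResult:
    """Observed intersection, per-gene module counts, and the randomized null."""

    diseases: list[str]
    intersection: frozenset[str]
    module_count: dict[str, int]
    null_intersection_sizes: list[int] = field(default_factory=list)
    fold_enrichment: float | None = None  # None iff the null mean is 0
    p: float | None = None
    per_gene_p: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "diseases": self.diseases,
            "intersection": sorted(self.intersection),
            "module_count": dict(sorted(self.module_count.items())),
            "null_intersection_sizes": self.null_intersection_sizes,
            "fold_enrichment": self.fold_enrichment,
            "p": self.p,
            "per_gene_p": dict(sorted(self.per_gene_p.items())),
        }


@dataclass
class CorrelationSummary:
    """Per-module-count annotation fractions and their Pearson correlation."""

    levels: list[int]
    fractions: list[float]
    pcc: float | None  # None when the fractions have zero variance
    p: float | None


def intersect_modules(modules: list) -> tuple[frozenset[str], dict[str, int]]:
    """Intersection of disease modules and the per-gene module-membership count.

    ``module_count`` covers every gene appearing in at least one module; the
    intersection is exactly the genes with count equal to the number of modules.
    """
    if len(modules) < 2:
        raise ValueError("need >=2 modules to intersect")
    gene_sets = [set(m.genes) for m in modules]
    counts: dict[str, int] = {}
    for gs in gene_sets:
        for g in gs:
            counts[g] = counts.get(g, 0) + 1
    intersection = frozenset(g for g, c in counts.items() if c == len(modules))
    return intersection, counts


def _shuffle_de(de: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Randomize the gene -> P assignment by permuting the table rows over genes."""
    perm = rng.permutation(len(de))
    out = de.iloc[perm].copy()
    out.index = de.index
    return out


def pleiotropy_null(
    net: InteractionNetwork,
    de_list: list[pd.DataFrame],
    n_repeats: int = 100,
    n_perm: int = 1000,
    alpha: float = 0.01,
    min_size: int = 2,
    seed: int = 0,
    disease_names: list[str] | None = None,
    cliques: list[CliqueScore] | None = None,
) -> PleiotropyResult:
    """Observed cross-disease intersection against the randomized-P null.

    Each of the ``n_repeats`` null rounds independently shuffles every
    disease's gene -> P map, reruns the full module detection for all
    diseases (reusing the one-time clique enumeration; ``n_perm``
    permutations inside each detection), and records the null intersection
    size and per-gene module counts. Reported:

    - ``p`` = (r+1)/(n_repeats+1), r = #{null intersection size >= observed};
    - ``per_gene_p`` = fraction of repeats whose null placed the gene in at
      least as many modules as observed (same (r+1)/(n+1) estimator);
    - ``fold_enrichment`` = observed size / mean null size (None if the null
      mean is 0).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if len(de_list) < 2:
        raise ValueError("need >=2 disease contrasts")
    universes = [frozenset(de.index) for de in de_list]
    if len(set(universes)) > 1:
        raise ValueError("disease DE tables have mismatched gene universes")
    names = disease_names or [f"disease_{i+1}" for i in range(len(de_list))]
    if cliques is None:
        cliques = enumerate_maximal_cliques(net, min_size=min_size)
    net_genes = set(net.nodes())

    rng = np.random.default_rng(seed)

    def detect_all(tables: list[pd.DataFrame], det_rng: np.random.Generator):
        modules = []
        for name, de in zip(names, tables):
            scored = clique_significance(
                cliques,
                de,
                n_perm=n_perm,
                seed=int(det_rng.integers(2**31)),
                extra_universe_genes=net_genes,
            )
            modules.append(assemble_module(scored, alpha=alpha, disease_name=name))
        return modules

    observed_modules = detect_all(de_list, rng)
    intersection, counts = intersect_modules(observed_modules)

    null_sizes: list[int] = []
    ge_count = {g: 0 for g in counts}
    intersection_exceed = 0
    for rep in range(n_repeats):
        shuffled = [_shuffle_de(de, rng) for de in de_list]
        null_modules = detect_all(shuffled, rng)
        null_inter, null_counts = intersect_modules(null_modules)
        null_sizes.append(len(null_inter))
        if len(null_inter) >= len(intersection):
            intersection_exceed += 1
        for g, c in counts.items():
            if null_counts.get(g, 0) >= c:
                ge_count[g] += 1
        logger.debug("null repeat %d: intersection size %d", rep + 1, len(null_inter))

    p = (intersection_exceed + 1) / (n_repeats + 1)
    per_gene_p = {g: (ge_count[g] + 1) / (n_repeats + 1) for g in counts}
    null_mean = float(np.mean(null_sizes)) if null_sizes else 0.0
    fe = (len(intersection) / null_mean) if null_mean > 0 else None
    return PleiotropyResult(
        diseases=names,
        intersection=intersection,
        module_count=counts,
        null_intersection_sizes=null_sizes,
        fold_enrichment=fe,
        p=p,
        per_gene_p=per_gene_p,
    )


def annotation_fraction_by_module_count(
    module_count: dict[str, int],
    annotation: set[str],
    universe: set[str],
    n_diseases: int | None = None,
) -> CorrelationSummary:
    """Pearson correlation between module-participation level and annotation fraction.

    For each level d = 0..D, the fraction of genes in exactly d modules that
    carry the annotation; genes in the universe but in no module sit at level
    0. Levels with no genes are skipped. Returns the PCC across levels with
    its two-sided p-value (``pcc=None`` when the fractions are constant).
    """
    stray = set(module_count) - universe
    if stray:
        raise ValueError(f"module_count genes outside universe: {sorted(stray)[:10]}")
    if not annotation <= universe:
        raise ValueError("annotation genes outside universe")
    D = n_diseases if n_diseases is not None else (max(module_count.values()) if module_count else 0)
    levels, fractions = [], []
    for d in range(D + 1):
        if d == 0:
            members = universe - set(module_count)
            members |= {g for g, c in module_count.items() if c == 0}
        else:
            members = {g for g, c in module_count.items() if c == d}
        if not members:
            continue
        levels.append(d)
        fractions.append(len(members & annotation) / len(members))
    if len(levels) < 3:
        raise ValueError("fewer than 3 non-empty levels; correlation undefined")
    if np.ptp(fractions) == 0.0:
        return CorrelationSummary(levels=levels, fractions=fractions, pcc=None, p=None)
    pcc, p = stats.pearsonr(levels, fractions)
    return CorrelationSummary(levels=levels, fractions=fractions, pcc=float(pcc), p=float(p))
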