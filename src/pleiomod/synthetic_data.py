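"""Synthetic inputs with planted modular-pleiotropy structure.

The generator emulates the statistical shape the analysis assumes: a sparse
scale-free interactome with dense planted cliques, a collection of disease
contrasts that all perturb a shared "core" module plus one disease-specific
module each, annotation sets enriched in a target set at a chosen fold
enrichment, and paired pre/post responder cohorts where the drug perturbs
one responder group more than the other.

Every generator is deterministic for a fixed seed; a :class:`TruthRecord`
carries all planted memberships so recovery can be scored without hidden
state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .classification import HR, LR, ResponderCohort
from .diffexpr import CASE, CONTROL, ExpressionStudy
from .interactome import InteractionNetwork


@dataclass
class ResponderConfig:
    """Paired-cohort layout: group sizes, perturbed genes, per-label drug effects.

    The drug shifts the effect genes by ``effect_hr`` / ``effect_lr``
    standard deviations between the paired pre and post measurements; with
    the defaults the low responders are perturbed by 1.5 SD and the high
    responders not at all, so the post-treatment expression both separates
    the groups and yields a higher LR perturbation statistic.
    """

    n_hr: int = 8
    n_lr: int = 8
    n_effect_genes: int = 10
    effect_hr: float = 0.0
    effect_lr: float = 1.5
    #: correlation between the paired pre and post measurements; post keeps a
    #: unit marginal SD so effect sizes stay in within-group SD units
    pre_post_correlation: float = 0.9


@dataclass
class SimulationScenario:
    """Planted-structure study conditions for the full pipeline.

    Defaults describe the desk-scale benchmark: a 300-gene scale-free
    interactome carrying a 20-gene core clique shared by 4 diseases plus an
    8-gene disease-specific clique each, differential expression of 2
    within-group standard deviations, and 10 cases vs 10 controls per disease.
    """

    n_genes: int = 300
    topology: str = "scale_free"  # or "erdos_renyi"
    attachment: int = 5  # scale-free: edges per new node; ER: expected degree
    n_diseases: int = 4
    core_size: int = 20
    specific_size: int = 8
    effect_size: float = 2.0
    n_case: int = 10
    n_control: int = 10
    annotation_fe_target: float = 3.0
    annotation_size: int = 40
    responder: ResponderConfig = field(default_factory=ResponderConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        needed = self.core_size + self.n_diseases * self.specific_size
        if needed > self.n_genes:
            raise ValueError(
                f"core + specific genes ({needed}) exceed n_genes ({self.n_genes})"
            )
        if self.topology not in ("scale_free", "erdos_renyi"):
            raise ValueError(f"unknown topology {self.topology!r}")


@dataclass
class TruthRecord:
    """Planted memberships, sufficient to score recovery."""

    core_genes: list[str]
    specific_genes: dict[str, list[str]]
    planted_cliques: list[list[str]]

    def to_dict(self) -> dict:
        return {
            "core_genes": self.core_genes,
            "specific_genes": self.specific_genes,
            "planted_cliques": self.planted_cliques,
        }


def _gene_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{i:0{width}d}" for i in range(n)]


def planted_gene_sets(scenario: SimulationScenario) -> TruthRecord:
    """Deterministic assignment of core and per-disease specific genes."""
    genes = _gene_names(scenario.n_genes)
    core = genes[: scenario.core_size]
    specific: dict[str, list[str]] = {}
    offset = scenario.core_size
    for d in range(scenario.n_diseases):
        name = f"disease_{d+1}"
        specific[name] = genes[offset : offset + scenario.specific_size]
        offset += scenario.specific_size
    cliques = [core] + list(specific.values())
    return TruthRecord(core_genes=core, specific_genes=specific, planted_cliques=cliques)


def simulate_interactome(scenario: SimulationScenario) -> tuple[InteractionNetwork, TruthRecord]:
    """Scale-free (or Erdos-Renyi) base graph with all planted cliques' edges added.

    Planted edges carry confidence 0.9 (above the default 0.7 filter);
    background edges draw confidence uniformly from [0.7, 1).
    """
    truth = planted_gene_sets(scenario)
    genes = _gene_names(scenario.n_genes)
    rng = np.random.default_rng(scenario.seed)
    if scenario.topology == "scale_free":
        base = nx.barabasi_albert_graph(
            scenario.n_genes, scenario.attachment, seed=int(rng.integers(2**31))
        )
    else:
        p = min(1.0, scenario.attachment / max(scenario.n_genes - 1, 1))
        base = nx.gnp_random_graph(scenario.n_genes, p, seed=int(rng.integers(2**31)))
    net: InteractionNetwork = nx.Graph()
    net.add_nodes_from(genes)
    for i, j in base.edges():
        net.add_edge(genes[i], genes[j], confidence=float(rng.uniform(0.7, 1.0)))
    for clique in truth.planted_cliques:
        for a_idx, a in enumerate(clique):
            for b in clique[a_idx + 1 :]:
                net.add_edge(a, b, confidence=0.9)
    return net, truth


def simulate_disease_collection(
    net: InteractionNetwork, scenario: SimulationScenario
) -> tuple[list[ExpressionStudy], TruthRecord]:
    """One case/control expression study per disease with planted mean shifts.

    Expression is unit-variance Gaussian noise on the log scale; cases are
    shifted by ``effect_size`` standard deviations on the core genes and on
    that disease's specific genes.
    """
    truth = planted_gene_sets(scenario)
    missing = [g for g in truth.core_genes if g not in net]
    if missing:
        raise ValueError(f"core genes absent from network: {missing[:5]}")
    genes = _gene_names(scenario.n_genes)
    rng = np.random.default_rng(scenario.seed + 1)
    studies = []
    for name, specific in truth.specific_genes.items():
        n_case, n_ctrl = scenario.n_case, scenario.n_control
        cols = [f"{name}_case_{i+1}" for i in range(n_case)] + [
            f"{name}_ctrl_{i+1}" for i in range(n_ctrl)
        ]
        X = rng.standard_normal((scenario.n_genes, n_case + n_ctrl))
        shifted = set(truth.core_genes) | set(specific)
        rows = [i for i, g in enumerate(genes) if g in shifted]
        X[np.ix_(rows, range(n_case))] += scenario.effect_size
        labels = pd.Series([CASE] * n_case + [CONTROL] * n_ctrl, index=cols)
        studies.append(
            ExpressionStudy(pd.DataFrame(X, index=genes, columns=cols), labels)
        )
    return studies, truth


def simulate_annotations(
    universe: set[str],
    target_set: set[str],
    fe_target: float = 3.0,
    K: int = 40,
    seed: int = 0,
) -> set[str]:
    """Annotation set of size K whose expected overlap with ``target_set`` gives FE ~ fe_target.

    The in-target inclusion probability is ``fe_target * K / N`` so that the
    expected annotated fraction inside the target is ``fe_target`` times the
    universe frequency ``K/N``.
    """
    universe_l = sorted(universe)
    N = len(universe_l)
    if K > N:
        raise ValueError("annotation size exceeds universe")
    target = sorted(set(target_set) & universe)
    if fe_target * K / N > 1.0:
        raise ValueError("infeasible fold-enrichment target: fe_target*K/N > 1")
    if fe_target * len(target) > N:
        raise ValueError("target set too large for requested enrichment")
    rng = np.random.default_rng(seed)
    p_in = fe_target * K / N
    chosen = [g for g in target if rng.random() < p_in]
    if len(chosen) > K:
        chosen = [chosen[i] for i in rng.choice(len(chosen), size=K, replace=False)]
    rest = [g for g in universe_l if g not in set(target)]
    fill = rng.choice(len(rest), size=K - len(chosen), replace=False)
    chosen.extend(rest[i] for i in fill)
    return set(chosen)


def simulate_cohort(scenario: SimulationScenario) -> tuple[ResponderCohort, list[str]]:
    """Paired pre/post responder cohort; returns the cohort and the true effect genes.

    Pre-treatment expression carries no group difference (cohort samples are
    drawn before treatment); the drug shifts the post-treatment values of
    the effect genes by ``effect_hr`` / ``effect_lr`` per label, so a
    differential drug response both separates the groups after treatment and
    produces a higher perturbation statistic for the more-affected group.
    """
    cfg = scenario.responder
    if cfg.n_hr + cfg.n_lr < 4:
        raise ValueError("need at least 4 responder samples")
    genes = _gene_names(scenario.n_genes)
    effect_genes = genes[: cfg.n_effect_genes]
    rng = np.random.default_rng(scenario.seed + 2)
    samples = [f"HR_{i+1}" for i in range(cfg.n_hr)] + [f"LR_{i+1}" for i in range(cfg.n_lr)]
    labels = pd.Series([HR] * cfg.n_hr + [LR] * cfg.n_lr, index=samples)
    n = len(samples)
    pre = rng.standard_normal((scenario.n_genes, n))
    rows = np.arange(cfg.n_effect_genes)
    rho = cfg.pre_post_correlation
    post = rho * pre + np.sqrt(1.0 - rho**2) * rng.standard_normal((scenario.n_genes, n))
    post[np.ix_(rows, np.arange(cfg.n_hr))] += cfg.effect_hr
    post[np.ix_(rows, np.arange(cfg.n_hr, n))] += cfg.effect_lr
    pre_df = pd.DataFrame(pre, index=genes, columns=samples)
    post_df = pd.DataFrame(post, index=genes, columns=samples)
    cohort = ResponderCohort(
        pre=ExpressionStudy(pre_df), post=ExpressionStudy(post_df), labels=labels
    )
    return cohort, effect_genes
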