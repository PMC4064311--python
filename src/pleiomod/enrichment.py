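"""Enrichment statistics: fold enrichment, Fisher tests, BH FDR, and
degree-matched random-set nulls that remove hub bias from interactome
enrichment tests, plus the random-gene-set drug-response correlation screen.

Fold enrichment of a feature in a test set is the frequency of the feature
in the set divided by its frequency in the universe:

    FE = (k / n) / (K / N)

with k annotated genes among the n tested and K among the N in the universe.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diffexpr import ExpressionStudy
from .interactome import DegreeConstraint, InteractionNetwork

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    k: int
    n: int
    K: int
    N: int
    fold_enrichment: float
    p: float
    q: float | None = None


def _check_counts(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= k <= min(n, K) and 0 < n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """(k/n) / (K/N): feature frequency in the test set over the universe frequency."""
    _check_counts(k, n, K, N)
    if K == 0:
        raise ValueError("feature absent from universe (K = 0): FE undefined")
    return (k / n) / (K / N)


def fisher_enrichment(k: int, n: int, K: int, N: int) -> float:
    """One-sided Fisher exact (hypergeometric upper tail) P(X >= k)."""
    _check_counts(k, n, K, N)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must be in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def enrichment_test(
    test_set: set[str], annotation: set[str], universe: set[str]
) -> EnrichmentResult:
    """Fold enrichment and one-sided Fisher p of ``annotation`` in ``test_set``."""
    if not test_set <= universe:
        raise ValueError("test set not contained in universe")
    ann = annotation & universe
    k = len(test_set & ann)
    n, K, N = len(test_set), len(ann), len(universe)
    return EnrichmentResult(
        k=k, n=n, K=K, N=N,
        fold_enrichment=fold_enrichment(k, n, K, N),
        p=fisher_enrichment(k, n, K, N),
    )


def degree_matched_sets(
    net: InteractionNetwork,
    constraint: DegreeConstraint,
    n_sets: int,
    seed: int = 0,
    max_tries_per_set: int = 1000,
) -> list[list[str]]:
    """Random gene sets matching a connectivity profile.

    Each set has ``constraint.set_size`` genes, all with degree >=
    ``min_degree``, and a median degree within ``tolerance`` of
    ``median_degree``. Sampling stratifies each draw: half the genes come
    from the pool at or above the target median, half from below, followed by
    rejection on the realized median. Raises with diagnostics when the
    constraint keeps rejecting.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    degrees = dict(net.degree())
    pool = np.array(sorted(g for g, d in degrees.items() if d >= constraint.min_degree))
    if pool.size < constraint.set_size:
        raise ValueError(
            f"only {pool.size} genes have degree >= {constraint.min_degree}; "
            f"need {constraint.set_size}"
        )
    pool_deg = np.array([degrees[g] for g in pool], dtype=float)
    # overlapping halves: genes at the target degree belong to both, so the
    # realized median can land exactly on the target
    hi_idx = np.flatnonzero(pool_deg >= constraint.median_degree)
    lo_idx = np.flatnonzero(pool_deg <= constraint.median_degree)
    size = constraint.set_size
    n_hi = size // 2
    n_lo = size - n_hi
    stratified = hi_idx.size >= n_hi and lo_idx.size >= n_lo

    rng = np.random.default_rng(seed)
    out: list[list[str]] = []
    for i in range(n_sets):
        for _ in range(max_tries_per_set):
            if stratified:
                hi_draw = rng.choice(hi_idx, size=n_hi, replace=False)
                taken = set(hi_draw.tolist())
                lo_avail = lo_idx[~np.isin(lo_idx, hi_draw)]
                if lo_avail.size < n_lo:
                    continue
                lo_draw = rng.choice(lo_avail, size=n_lo, replace=False)
                draw = np.concatenate([hi_draw, lo_draw])
            else:
                draw = rng.choice(pool.size, size=size, replace=False)
            med = float(np.median(pool_deg[draw]))
            if abs(med - constraint.median_degree) <= constraint.tolerance:
                out.append(sorted(pool[draw].tolist()))
                break
        else:
            raise RuntimeError(
                f"degree-matched sampling failed for set {i + 1}: no draw within "
                f"median tolerance {constraint.tolerance} of {constraint.median_degree} "
                f"after {max_tries_per_set} tries (pool {pool.size}, "
                f"hi/lo {hi_idx.size}/{lo_idx.size})"
            )
    return out


def degree_controlled_enrichment(
    net: InteractionNetwork,
    test_set: set[str],
    annotation: set[str],
    constraint: DegreeConstraint,
    n_sets: int = 1000,
    seed: int = 0,
) -> tuple[int, float]:
    """Empirical enrichment p against degree-matched random sets.

    Returns ``(observed_k, p)`` with p = (r+1)/(n_sets+1), r = number of
    null sets with at least ``observed_k`` annotated members.
    """
    observed_k = len(test_set & annotation)
    null_sets = degree_matched_sets(net, constraint, n_sets, seed=seed)
    ann = annotation
    r = sum(1 for s in null_sets if len(ann.intersection(s)) >= observed_k)
    return observed_k, (r + 1) / (n_sets + 1)


def geneset_correlation_screen(
    expr: ExpressionStudy,
    responses: pd.DataFrame,
    genes: set[str],
    n_random: int = 1000,
    fdr: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Screen agents (drugs) whose response correlates with a gene set's expression.

    ``responses`` is samples x agents (one response value per sample per
    agent, e.g. log IC50). Per agent the score is the mean absolute Pearson
    correlation between each member gene's expression and the response across
    samples; the empirical p compares it with scores of ``n_random``
    same-size gene sets drawn uniformly from the measured universe, and
    agents are flagged at BH FDR < ``fdr``. Constant-response agents are
    skipped with a warning.

    Returns a DataFrame indexed by agent with columns score, p, q, flagged.
    """
    if n_random < 2:
        raise ValueError("n_random must be >= 2")
    samples = list(expr.matrix.columns)
    if list(responses.index) != samples:
        responses = responses.reindex(samples)
        if responses.isna().any().any():
            raise ValueError("responses not aligned with expression samples")
    member = sorted(genes & set(expr.matrix.index))
    if not member:
        raise ValueError("no screen genes are measured")
    X = expr.matrix.to_numpy(dtype=float)  # genes x samples
    gene_index = {g: i for i, g in enumerate(expr.matrix.index)}
    member_idx = np.array([gene_index[g] for g in member])

    # standardize rows once; correlation = standardized dot product
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = Xc.std(axis=1)
    sd[sd == 0] = np.inf  # constant genes correlate 0 with everything
    Z = Xc / sd[:, None]

    rng = np.random.default_rng(seed)
    null_idx = np.stack(
        [rng.choice(X.shape[0], size=len(member_idx), replace=False) for _ in range(n_random)]
    )

    rows = []
    for agent in responses.columns:
        y = responses[agent].to_numpy(dtype=float)
        if np.ptp(y) == 0.0:
            warnings.warn(f"agent {agent!r} has a constant response; skipped")
            continue
        yz = (y - y.mean()) / y.std()
        corr = Z @ yz / len(y)  # per-gene PCC with this agent's response
        abscorr = np.abs(corr)
        score = float(abscorr[member_idx].mean())
        null_scores = abscorr[null_idx].mean(axis=1)
        r = int((null_scores >= score).sum())
        rows.append({"agent": agent, "score": score, "p": (r + 1) / (n_random + 1)})
    if not rows:
        raise ValueError("all agents had constant responses")
    report = pd.DataFrame(rows).set_index("agent")
    report["q"] = bh_fdr(report["p"])
    report["flagged"] = report["q"] < fdr
    return report
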