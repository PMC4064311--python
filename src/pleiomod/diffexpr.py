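"""Expression preprocessing and differential-expression statistics.

Implements quantile normalization, median probe-to-gene collapse, pooled
two-sample t statistics per gene, the mean-squared-t gene-set statistic with
its label-permutation p-value, and a generalized-Pareto tail approximation
for p-values beyond the permutation resolution.

The set statistic for a gene set S is

    T(S) = (1/|S|) * sum_{g in S} t_g^2

where ``t_g`` is the two-sample t statistic of gene g. For m independent
null genes and large group sizes, ``m * T`` is approximately chi-square with
m degrees of freedom, which makes the effect size easy to read off; the
p-value is nevertheless always computed by permuting the sample group labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CASE, CONTROL = "case", "control"


@dataclass
class ExpressionStudy:
    """A features x samples expression matrix with per-sample group labels.

    ``matrix`` rows are probes or genes, columns are samples; ``labels`` maps
    each sample to ``"case"`` or ``"control"`` (absent labels are allowed
    for operations that do not test groups).
    """

    matrix: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.matrix.index.has_duplicates:
            dup = self.matrix.index[self.matrix.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dup[:5]}")
        if self.matrix.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.labels is not None:
            self.labels = self.labels.reindex(self.matrix.columns)
            if self.labels.isna().any():
                missing = self.matrix.columns[self.labels.isna()].tolist()
                raise ValueError(f"samples without labels: {missing}")
            bad = set(self.labels.unique()) - {CASE, CONTROL}
            if bad:
                raise ValueError(f"labels must be case/control, got {sorted(bad)}")

    def group_columns(self) -> tuple[np.ndarray, np.ndarray]:
        if self.labels is None:
            raise ValueError("study has no group labels")
        case = self.matrix.loc[:, self.labels == CASE].to_numpy()
        ctrl = self.matrix.loc[:, self.labels == CONTROL].to_numpy()
        return case, ctrl


def quantile_normalize(study: ExpressionStudy) -> ExpressionStudy:
    """Force every sample (column) onto the common distribution of row means of sorted columns.

    Ties within a column receive the mean of the target values of the ranks
    they span, so constant columns map to the overall mean target value.
    """
    X = study.matrix.to_numpy(dtype=float)
    if X.size == 0:
        raise ValueError("empty expression matrix")
    target = np.sort(X, axis=0).mean(axis=1)  # length n_rows
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = target
        # tied values share the mean of the target values their ranks span
        _, inv = np.unique(col, return_inverse=True)
        sums = np.bincount(inv, weights=assigned)
        counts = np.bincount(inv)
        out[:, j] = (sums / counts)[inv]
    return ExpressionStudy(
        pd.DataFrame(out, index=study.matrix.index, columns=study.matrix.columns),
        study.labels,
    )


def log_transform(study: ExpressionStudy, pseudocount: float = 1.0) -> ExpressionStudy:
    """log2(x + pseudocount) for raw-intensity input."""
    if (study.matrix.to_numpy() + pseudocount <= 0).any():
        raise ValueError("log transform requires values > -pseudocount")
    return ExpressionStudy(np.log2(study.matrix + pseudocount), study.labels)


def collapse_probes_median(
    study: ExpressionStudy, probe_to_gene: Mapping[str, str]
) -> ExpressionStudy:
    """Collapse probe-level rows to gene-level rows by the per-sample median.

    Probes absent from the mapping are dropped (count logged); each probe
    may map to at most one gene.
    """
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene mapping")
    mapped = study.matrix.index.map(lambda p: probe_to_gene.get(p))
    keep = mapped.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d unmapped probe(s)", n_dropped)
    sub = study.matrix.loc[keep]
    genes = pd.Index(mapped[keep], name="gene")
    collapsed = sub.groupby(genes).median()
    return ExpressionStudy(collapsed, study.labels)


def _pooled_t(case: np.ndarray, ctrl: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Vectorized pooled-variance two-sample t per row; zero-variance rows get t=0, p=1."""
    n1, n2 = case.shape[1], ctrl.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >=2 samples per group")
    m1, m2 = case.mean(axis=1), ctrl.mean(axis=1)
    v1 = case.var(axis=1, ddof=1)
    v2 = ctrl.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    denom = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (m1 - m2) / np.where(denom > 0, denom, 1.0), 0.0)
    p = np.where(denom > 0, 2.0 * stats.t.sf(np.abs(t), df), 1.0)
    return t, np.clip(p, np.finfo(float).tiny, 1.0), float(df)


def per_gene_ttest(study: ExpressionStudy) -> pd.DataFrame:
    """Two-sided pooled-variance two-sample t-test per gene (case minus control).

    Returns a DataFrame indexed by gene with columns ``t``, ``p``, ``df``.
    """
    case, ctrl = study.group_columns()
    t, p, df = _pooled_t(case, ctrl)
    return pd.DataFrame({"t": t, "p": p, "df": df}, index=study.matrix.index.rename("gene"))


def mean_squared_t(de: pd.DataFrame, genes: Iterable[str]) -> float:
    """Arithmetic mean of squared t statistics over ``genes``."""
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene set")
    missing = [g for g in genes if g not in de.index]
    if missing:
        raise KeyError(f"genes absent from DE table: {sorted(missing)[:10]}")
    t = de.loc[genes, "t"].to_numpy(dtype=float)
    return float(np.mean(t**2))


def permutation_set_pvalue(
    study: ExpressionStudy,
    genes: Iterable[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Label-permutation p-value for the mean-squared-t statistic of a gene set.

    The null permutes the sample group labels, re-computes every t, and takes
    the set statistic; one-sided (large statistic = differentially expressed),
    p = (r+1)/(n_perm+1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene set")
    missing = [g for g in genes if g not in study.matrix.index]
    if missing:
        raise KeyError(f"genes absent from study: {sorted(missing)[:10]}")
    if study.labels is None:
        raise ValueError("study has no group labels")

    sub = study.matrix.loc[genes].to_numpy(dtype=float)
    is_case = (study.labels == CASE).to_numpy()
    n_case = int(is_case.sum())

    def statistic(case_mask: np.ndarray) -> float:
        t, _, _ = _pooled_t(sub[:, case_mask], sub[:, ~case_mask])
        return float(np.mean(t**2))

    observed = statistic(is_case)
    rng = np.random.default_rng(seed)
    n_samples = sub.shape[1]
    r = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_samples)
        mask = np.zeros(n_samples, dtype=bool)
        mask[perm[:n_case]] = True
        if statistic(mask) >= observed:
            r += 1
    return observed, (r + 1) / (n_perm + 1)


def gpd_tail_pvalue(
    null_statistics: Iterable[float],
    observed: float,
    tail_fraction: float = 0.1,
) -> float:
    """Permutation p-value with a generalized-Pareto tail for extreme observations.

    If at least 10 null statistics reach ``observed`` the empirical
    (r+1)/(n+1) estimate is returned unchanged. Otherwise a GPD is fit by
    maximum likelihood to the null exceedances above the (1 - tail_fraction)
    quantile and the p-value is ``tail_fraction * SF_GPD(observed - threshold)``,
    which can resolve p-values far below 1/n.
    """
    null = np.asarray(list(null_statistics), dtype=float)
    if null.size == 0:
        raise ValueError("null_statistics must be non-empty")
    if not 0.0 < tail_fraction <= 0.5:
        raise ValueError("tail_fraction must be in (0, 0.5]")
    n = null.size
    r = int((null >= observed).sum())
    empirical = (r + 1) / (n + 1)
    if r >= 10:
        return empirical
    if np.ptp(null) == 0.0:
        warnings.warn("degenerate (constant) null distribution; returning empirical p")
        return empirical
    threshold = float(np.quantile(null, 1.0 - tail_fraction))
    exceed = null[null > threshold] - threshold
    if exceed.size < 10 or observed <= threshold:
        return empirical
    shape, _, scale = stats.genpareto.fit(exceed, floc=0.0)
    tail_p = exceed.size / n * float(stats.genpareto.sf(observed - threshold, shape, 0.0, scale))
    return float(max(tail_p, np.finfo(float).tiny))
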