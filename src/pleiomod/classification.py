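"""Responder stratification with L1-penalized logistic classification.

The workflow mirrors a prospective pre/post-treatment cohort: genes whose
expression the drug perturbs (paired t-test, P < 0.05) are optionally
restricted to disease-module members, then an L1-penalized logistic
regression separates high responders (HR) from low responders (LR). The
penalty weight is chosen by minimum mean binomial deviance over
leave-one-out cross-validation; reported per-sample probabilities come from
an outer leave-one-out loop in which the penalty is re-selected inside each
training fold, so every probability is a genuinely held-out prediction.
Significance of the classification is a label-permutation test on the
number of correct 0.5-threshold calls.

The penalized fits are computed by an internal proximal-gradient (FISTA)
path solver that handles all leave-one-out folds of a training set in one
vectorized batch; its solutions match scikit-learn's
``LogisticRegression(penalty="l1")`` at the equivalent regularization
``C = 1/(n * lambda)``.

The group perturbation statistic summarizes how strongly the drug moves a
label group: the mean over genes of the squared paired t statistic between
pre- and post-treatment expression within that group's samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numba
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import ExpressionStudy

logger = logging.getLogger(__name__)

HR, LR = "HR", "LR"


@dataclass
class ResponderCohort:
    """Paired pre/post-treatment expression with HR/LR labels.

    ``pre`` and ``post`` must share identical sample ids (same patients
    before and after in-vitro drug exposure) and gene universes.
    """

    pre: ExpressionStudy
    post: ExpressionStudy
    labels: pd.Series  # sample -> {"HR", "LR"}

    def __post_init__(self) -> None:
        if list(self.pre.matrix.columns) != list(self.post.matrix.columns):
            raise ValueError("pre/post sample ids differ or are misordered")
        if list(self.pre.matrix.index) != list(self.post.matrix.index):
            raise ValueError("pre/post gene universes differ")
        self.labels = self.labels.reindex(self.pre.matrix.columns)
        if self.labels.isna().any():
            missing = self.pre.matrix.columns[self.labels.isna()].tolist()
            raise ValueError(f"samples without responder labels: {missing}")
        bad = set(self.labels.unique()) - {HR, LR}
        if bad:
            raise ValueError(f"labels must be HR/LR, got {sorted(bad)}")


@dataclass
class ClassifierReport:
    """Cross-validated responder probabilities and permutation significance."""

    genes_used: list[str]
    lam: float | None
    probabilities: pd.Series  # per sample, P(HR), held-out
    calls: pd.Series  # "HR" iff probability > 0.5
    permutation_p: float | None = None
    fold_lambdas: list[float] = field(default_factory=list)

    def n_correct(self, truth: pd.Series) -> int:
        return int((self.calls == truth.reindex(self.calls.index)).sum())

    def to_dict(self) -> dict:
        return {
            "genes_used": self.genes_used,
            "lambda": self.lam,
            "probabilities": self.probabilities.round(6).to_dict(),
            "calls": self.calls.to_dict(),
            "permutation_p": self.permutation_p,
        }


_T_SATURATION = 1e6  # stands in for an infinite t when the paired SD is exactly 0


def _paired_t(post: np.ndarray, pre: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized paired t per row.

    Zero-variance differences are degenerate: an exactly-zero difference
    vector gives t=0, p=1, while a nonzero constant shift is maximal
    evidence (t saturated at +-1e6, p at the smallest positive float).
    """
    d = post - pre
    n = d.shape[1]
    if n < 2:
        raise ValueError("need >=2 paired samples")
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (np.where(sd > 0, sd, 1.0) / np.sqrt(n)), 0.0)
    p = np.where(sd > 0, 2.0 * stats.t.sf(np.abs(t), n - 1), 1.0)
    constant_shift = (sd == 0) & (mean != 0)
    t = np.where(constant_shift, np.sign(mean) * _T_SATURATION, t)
    p = np.where(constant_shift, np.finfo(float).tiny, p)
    return t, p


def drug_responsive_genes(cohort: ResponderCohort, alpha: float = 0.05) -> set[str]:
    """Genes the drug perturbs: paired pre-vs-post t-test P < alpha over all samples."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    _, p = _paired_t(cohort.post.matrix.to_numpy(float), cohort.pre.matrix.to_numpy(float))
    genes = cohort.pre.matrix.index[p < alpha]
    return set(genes)


def restrict_to_modules(
    genes: set[str],
    module_count: Mapping[str, int] | None = None,
    min_modules: int = 0,
    named_module: Iterable[str] | None = None,
) -> set[str]:
    """Keep genes participating in >= ``min_modules`` disease modules.

    Alternatively (``named_module``) restrict to membership in one module's
    gene set. An empty result warns rather than raising.
    """
    if named_module is not None:
        out = genes & set(named_module)
    else:
        if module_count is None:
            raise ValueError("module_count required unless named_module is given")
        out = {g for g in genes if module_count.get(g, 0) >= min_modules}
    if not out:
        warnings.warn("module restriction left no genes")
    return out


# ---------------------------------------------------------------------------
# L1-penalized logistic path solver
# ---------------------------------------------------------------------------


def lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int = 100, ratio: float = 1e-2) -> np.ndarray:
    """Descending log-spaced penalty grid from lambda_max down to lambda_max * ratio.

    The default ratio of 1e-2 follows the glmnet convention for problems
    with fewer samples than predictors, which is always the case here.

    ``lambda_max`` is the smallest penalty at which every coefficient is zero:
    max_j |x_j^T (y - ybar)| / n for centered predictors.
    """
    n = len(y)
    resid = y - y.mean()
    lam_max = float(np.max(np.abs(X.T @ resid)) / n)
    if lam_max <= 0:
        lam_max = 1e-3  # no signal at all; grid still needs to exist
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


@numba.njit(cache=True)
def _path_single(X, y, lambdas, step, max_iter, tol):  # pragma: no cover - compiled
    """FISTA path for one training set, warm-started along a descending grid.

    Minimizes (1/m) * sum_i logloss_i + lam * ||w||_1 with an unpenalized
    intercept; momentum is reset whenever it points against the descent
    direction (gradient restart), which keeps the tail convergence fast.
    """
    m, g = X.shape
    K = len(lambdas)
    W_out = np.zeros((K, g))
    b_out = np.zeros(K)
    w = np.zeros(g)
    b = 0.0
    grad_w = np.zeros(g)
    for k in range(K):
        lam = lambdas[k]
        t_mom = 1.0
        wv = w.copy()
        bv = b
        w_prev = w.copy()
        b_prev = b
        for _ in range(max_iter):
            grad_b = 0.0
            for j in range(g):
                grad_w[j] = 0.0
            for i in range(m):
                z = bv
                for j in range(g):
                    z += X[i, j] * wv[j]
                if z > 30.0:
                    p = 1.0
                elif z < -30.0:
                    p = 0.0
                else:
                    p = 1.0 / (1.0 + np.exp(-z))
                r = p - y[i]
                grad_b += r
                for j in range(g):
                    grad_w[j] += r * X[i, j]
            grad_b /= m
            thr = step * lam
            delta = 0.0
            restart = 0.0
            b_new = bv - step * grad_b
            restart += (bv - b_new) * (b_new - b_prev)
            d = abs(b_new - b_prev)
            if d > delta:
                delta = d
            t_next = (1.0 + np.sqrt(1.0 + 4.0 * t_mom * t_mom)) / 2.0
            mom = (t_mom - 1.0) / t_next
            for j in range(g):
                wj = wv[j] - step * grad_w[j] / m
                if wj > thr:
                    wj -= thr
                elif wj < -thr:
                    wj += thr
                else:
                    wj = 0.0
                restart += (wv[j] - wj) * (wj - w_prev[j])
                d = abs(wj - w_prev[j])
                if d > delta:
                    delta = d
                wv[j] = wj + mom * (wj - w_prev[j])
                w_prev[j] = wj
            bv = b_new + mom * (b_new - b_prev)
            b_prev = b_new
            if restart > 0.0:  # momentum opposes descent: reset
                t_mom = 1.0
                for j in range(g):
                    wv[j] = w_prev[j]
                bv = b_prev
            else:
                t_mom = t_next
            if delta < tol:
                break
        w = w_prev.copy()
        b = b_prev
        for j in range(g):
            W_out[k, j] = w[j]
        b_out[k] = b
    return W_out, b_out


def _l1_logistic_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    train_masks: np.ndarray | None = None,
    max_iter: int = 250,
    tol: float = 1e-5,
):
    """L1-logistic path over folds: (n_lambda, F, g) coefficients, (n_lambda, F) intercepts.

    Each fold's training rows are ``X[train_masks[f]]``; default is one fold
    using every sample. The objective per fold is
    ``(1/n_f) * sum logloss + lam * ||w||_1`` (intercept unpenalized).
    """
    m, g = X.shape
    if train_masks is None:
        train_masks = np.ones((1, m), dtype=bool)
    F = train_masks.shape[0]
    n_f = train_masks.sum(axis=1)
    if (n_f < 2).any():
        raise ValueError("every training fold needs >=2 samples")
    W_out = np.empty((len(lambdas), F, g))
    B_out = np.empty((len(lambdas), F))
    lambdas = np.ascontiguousarray(lambdas, dtype=np.float64)
    for f in range(F):
        Xf = np.ascontiguousarray(X[train_masks[f]], dtype=np.float64)
        yf = np.ascontiguousarray(y[train_masks[f]], dtype=np.float64)
        aug = np.hstack([np.ones((Xf.shape[0], 1)), Xf])
        smax2 = float(np.linalg.norm(aug, 2) ** 2)
        step = 1.0 / (smax2 / (4.0 * Xf.shape[0]) + 1e-12)
        Wf, bf = _path_single(Xf, yf, lambdas, step, max_iter, tol)
        W_out[:, f, :] = Wf
        B_out[:, f] = bf
    return W_out, B_out


def _standardize(train: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, mu, sd


def _loo_deviance_select(
    X: np.ndarray, y: np.ndarray, lambdas: np.ndarray
) -> tuple[int, np.ndarray, np.ndarray]:
    """Select lambda by minimum mean leave-one-out binomial deviance.

    Returns (best index, full-data coefficient path W, intercept path B).
    The batch contains one fold per left-out sample plus a final fold using
    all samples, whose path supplies the refit coefficients.
    """
    m = len(y)
    masks = np.ones((m + 1, m), dtype=bool)
    for i in range(m):
        masks[i, i] = False
    W, B = _l1_logistic_path(X, y, lambdas, train_masks=masks)
    # held-out probability of sample i under fold i, per lambda
    logits = np.einsum("mg,kmg->km", X, W[:, :m, :]) + B[:, :m]  # (k, m)
    P = 1.0 / (1.0 + np.exp(-logits))
    P = np.clip(P, 1e-10, 1 - 1e-10)
    dev = -2.0 * (y * np.log(P) + (1 - y) * np.log(1 - P))  # (k, m)
    mean_dev = dev.mean(axis=1)
    best = int(np.argmin(mean_dev))  # grid descends, so ties go to larger lambda
    return best, W[:, m, :], B[:, m]


def _encode(labels: pd.Series) -> np.ndarray:
    return (labels == HR).to_numpy(dtype=float)


def fit_lasso_loocv(
    X: pd.DataFrame,
    y: pd.Series,
    n_lambda: int = 100,
    ratio: float = 1e-2,
) -> tuple[float, pd.Series]:
    """Fit L1-logistic regression with the penalty chosen by LOOCV deviance.

    ``X`` is samples x genes, ``y`` maps sample -> HR/LR. Returns the chosen
    ``lambda`` and the coefficients on the original feature scale (index =
    gene names plus ``"(intercept)"``). Ties in deviance resolve toward the
    larger (sparser) penalty.
    """
    yv = _encode(y.reindex(X.index))
    if len(np.unique(yv)) < 2:
        raise ValueError("both classes must be present")
    if len(yv) < 4:
        raise ValueError("need >=4 samples")
    Z, mu, sd = _standardize(X.to_numpy(float))
    lambdas = lambda_grid(Z, yv, n_lambda=n_lambda, ratio=ratio)
    best, W_full, B_full = _loo_deviance_select(Z, yv, lambdas)
    w_std, b_std = W_full[best], float(B_full[best])
    w = w_std / sd
    intercept = b_std - float(np.sum(w_std * mu / sd))
    coef = pd.Series(np.append(w, intercept), index=[*X.columns, "(intercept)"])
    return float(lambdas[best]), coef


def cv_probabilities(
    X: pd.DataFrame,
    y: pd.Series,
    n_lambda: int = 100,
    ratio: float = 1e-2,
) -> ClassifierReport:
    """Held-out P(HR) per sample by nested leave-one-out cross-validation.

    The outer loop leaves each sample out in turn; within each training fold
    the predictors are re-standardized and the penalty re-selected by inner
    LOOCV deviance, so the held-out sample never influences normalization or
    penalty choice. Calls are HR iff probability > 0.5.
    """
    y = y.reindex(X.index)
    yv = _encode(y)
    if len(np.unique(yv)) < 2:
        raise ValueError("both classes must be present")
    m = len(yv)
    if m < 4:
        raise ValueError("need >=4 samples")
    Xv = X.to_numpy(float)
    probs = np.empty(m)
    fold_lambdas = []
    for i in range(m):
        keep = np.arange(m) != i
        Z, mu, sd = _standardize(Xv[keep])
        lambdas = lambda_grid(Z, yv[keep], n_lambda=n_lambda, ratio=ratio)
        best, W_full, B_full = _loo_deviance_select(Z, yv[keep], lambdas)
        z_i = (Xv[i] - mu) / sd
        logit = float(z_i @ W_full[best] + B_full[best])
        probs[i] = 1.0 / (1.0 + np.exp(-logit))
        fold_lambdas.append(float(lambdas[best]))
    prob_series = pd.Series(probs, index=X.index, name="p_HR")
    calls = pd.Series(np.where(probs > 0.5, HR, LR), index=X.index, name="call")
    return ClassifierReport(
        genes_used=list(X.columns),
        lam=None,
        probabilities=prob_series,
        calls=calls,
        fold_lambdas=fold_lambdas,
    )


def classifier_permutation_test(
    X: pd.DataFrame,
    y: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
    n_lambda: int = 100,
    ratio: float = 1e-2,
    statistic: str = "accuracy",
) -> tuple[ClassifierReport, float]:
    """Label-permutation significance of the cross-validated classification.

    The default statistic is the number of correct 0.5-threshold calls
    (``"deviance"`` uses the negated held-out deviance instead); the null
    reruns the entire nested-CV pipeline on permuted labels.
    Returns the observed report (with ``permutation_p`` filled) and the p.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if statistic not in ("accuracy", "deviance"):
        raise ValueError(f"unknown statistic {statistic!r}")
    y = y.reindex(X.index)

    def score(labels: pd.Series) -> tuple[float, ClassifierReport]:
        report = cv_probabilities(X, labels, n_lambda=n_lambda, ratio=ratio)
        if statistic == "accuracy":
            s = float((report.calls == labels).sum())
        else:
            p = np.clip(report.probabilities.to_numpy(), 1e-10, 1 - 1e-10)
            t = _encode(labels)
            s = float(2.0 * (t * np.log(p) + (1 - t) * np.log(1 - p)).sum())
        return s, report

    observed, report = score(y)
    rng = np.random.default_rng(seed)
    r = 0
    values = y.to_numpy()
    for _ in range(n_perm):
        perm = pd.Series(rng.permutation(values), index=y.index)
        s, _ = score(perm)
        if s >= observed:
            r += 1
    p = (r + 1) / (n_perm + 1)
    report.permutation_p = p
    return report, p


def group_perturbation(cohort: ResponderCohort, genes: Iterable[str]) -> dict[str, float]:
    """Per-label drug perturbation: mean over genes of the squared paired t statistic.

    The paired t compares pre vs post expression within each label's samples;
    a label whose post equals its pre scores exactly 0.
    """
    genes = sorted(set(genes))
    if not genes:
        raise ValueError("empty gene set")
    missing = [g for g in genes if g not in cohort.pre.matrix.index]
    if missing:
        raise KeyError(f"genes absent from cohort: {missing[:10]}")
    out: dict[str, float] = {}
    for label in (LR, HR):
        cols = cohort.labels.index[cohort.labels == label]
        if len(cols) < 2:
            raise ValueError(f"label {label} has <2 samples")
        t, _ = _paired_t(
            cohort.post.matrix.loc[genes, cols].to_numpy(float),
            cohort.pre.matrix.loc[genes, cols].to_numpy(float),
        )
        out[label] = float(np.mean(t**2))
    return out
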