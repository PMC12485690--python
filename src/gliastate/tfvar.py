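"""Variance of a signature score explained by signature transcription factors.

With one response variable the constrained-ordination variance partitioning
reduces to partial linear regression: the unique fraction for a focus TF is
adjR2(focus + condition) - adjR2(condition), adjusted R^2 by the Ezekiel
formula; negative fractions are clamped to 0 and their p-values suppressed.
Significance comes from a residual-permutation pseudo-F test (residuals of
the condition-only model are permuted), with exhaustive enumeration when n!
does not exceed the requested permutation count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd

from .composition import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "VariancePartition",
    "residualize",
    "partial_r2",
    "permutation_partial_test",
    "tf_partition",
]


@dataclass
class VariancePartition:
    table: pd.DataFrame      # per focus: fraction, clamped, p, fdr
    combined: float          # adjusted R^2 of all focus TFs jointly
    combined_p: float


def _with_intercept(X: np.ndarray | None, n: int) -> np.ndarray:
    if X is None or X.size == 0:
        return np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        X = X.T
    return np.column_stack([np.ones(n), X])


def _ols_rss(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Returns (fitted, residuals, RSS)."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    return fitted, resid, float(resid @ resid)


def residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """OLS residuals of y on the covariates (plus intercept); orthogonal to
    the covariate columns."""
    y = np.asarray(y, dtype=float)
    X = _with_intercept(covariates, len(y))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate design is rank-deficient")
    _, resid, _ = _ols_rss(y, X)
    return resid


def _adj_r2(y: np.ndarray, X: np.ndarray) -> float:
    """Ezekiel adjusted R^2; X includes the intercept."""
    n = len(y)
    p = X.shape[1] - 1
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        return 0.0
    _, _, rss = _ols_rss(y, X)
    r2 = 1.0 - rss / tss
    if n - p - 1 <= 0:
        raise ValueError("too few samples for the number of predictors")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def partial_r2(
    y: np.ndarray,
    focus: np.ndarray,
    condition: np.ndarray | None = None,
) -> tuple[float, bool]:
    """Unique adjusted-R^2 fraction of the focus variable(s) given the
    conditioning variables; returns (fraction, clamped_flag)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    focus = np.atleast_2d(np.asarray(focus, dtype=float))
    if focus.shape[0] != n:
        focus = focus.T
    Xc = _with_intercept(condition, n)
    Xf = np.column_stack([Xc, focus])
    if np.linalg.matrix_rank(Xf) < Xf.shape[1]:
        logger.warning("focus collinear with conditioning set; fraction = 0")
        return 0.0, True
    frac = _adj_r2(y, Xf) - _adj_r2(y, Xc)
    if frac < 0:
        return 0.0, True
    return float(frac), False


def _pseudo_f(y: np.ndarray, Xc: np.ndarray, Xf: np.ndarray) -> float:
    _, _, rss_c = _ols_rss(y, Xc)
    _, _, rss_f = _ols_rss(y, Xf)
    q = Xf.shape[1] - Xc.shape[1]
    dof = len(y) - Xf.shape[1]
    if dof <= 0 or rss_f <= 0:
        return np.inf
    return ((rss_c - rss_f) / q) / (rss_f / dof)


def permutation_partial_test(
    y: np.ndarray,
    focus: np.ndarray,
    condition: np.ndarray | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Residual-permutation pseudo-F test of the focus given the condition.

    The null is built by permuting the residuals of the condition-only model
    and adding them back to its fitted values.  When n! <= n_perm all
    permutations are enumerated exactly.  Returns (F, p).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    focus = np.atleast_2d(np.asarray(focus, dtype=float))
    if focus.shape[0] != n:
        focus = focus.T
    Xc = _with_intercept(condition, n)
    Xf = np.column_stack([Xc, focus])
    f_obs = _pseudo_f(y, Xc, Xf)
    fitted, resid, _ = _ols_rss(y, Xc)

    if factorial(n) <= n_perm:
        perms = list(permutations(range(n)))
        f_null = np.array([
            _pseudo_f(fitted + resid[list(p)], Xc, Xf) for p in perms
        ])
        p = float(np.mean(f_null >= f_obs))  # observed included (identity perm)
        return f_obs, max(p, 1.0 / len(perms))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        yp = fitted + rng.permutation(resid)
        if _pseudo_f(yp, Xc, Xf) >= f_obs:
            count += 1
    return f_obs, (1.0 + count) / (1.0 + n_perm)


def tf_partition(
    score: np.ndarray | pd.Series,
    tf_expression: pd.DataFrame,
    tf_names: list[str],
    comparators: list[str] | None = None,
    covariates: pd.DataFrame | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> VariancePartition:
    """Per-TF unique variance fractions, the combined fraction, permutation
    p-values and BH FDR.

    `score` should come from a PCA on a signature matrix with the TFs removed
    beforehand.  Each TF's unique fraction is conditioned on the remaining
    TFs plus covariates; the combined fraction of all `tf_names` conditions
    only on covariates; comparator TFs are conditioned on the signature TFs
    (specificity test).  Negative fractions are clamped to 0 with the p-value
    suppressed.
    """
    y = np.asarray(score.values if isinstance(score, pd.Series) else score, dtype=float)
    missing = [t for t in tf_names if t not in tf_expression.columns]
    if missing:
        raise KeyError(f"TF(s) absent from expression table: {missing}")
    cov = covariates.values.astype(float) if covariates is not None else None
    E = tf_expression[tf_names].values.astype(float)

    rows = []
    for i, tf in enumerate(tf_names):
        others = np.delete(E, i, axis=1)
        cond = others if cov is None else np.column_stack([others, cov])
        frac, clamped = partial_r2(y, E[:, [i]], cond)
        if clamped:
            p = np.nan
        else:
            _, p = permutation_partial_test(
                y, E[:, [i]], cond, n_perm=n_perm, seed=seed + i
            )
        rows.append({"focus": tf, "fraction": frac, "clamped": clamped, "p": p,
                     "kind": "unique"})

    comb_frac, comb_clamped = partial_r2(y, E, cov)
    if comb_clamped:
        comb_p = np.nan
    else:
        _, comb_p = permutation_partial_test(y, E, cov, n_perm=n_perm, seed=seed + 100)

    for j, tf in enumerate(comparators or []):
        if tf not in tf_expression.columns:
            raise KeyError(f"comparator TF {tf!r} absent from expression table")
        cond = E if cov is None else np.column_stack([E, cov])
        x = tf_expression[[tf]].values.astype(float)
        frac, clamped = partial_r2(y, x, cond)
        p = np.nan
        if not clamped:
            _, p = permutation_partial_test(y, x, cond, n_perm=n_perm, seed=seed + 200 + j)
        rows.append({"focus": tf, "fraction": frac, "clamped": clamped, "p": p,
                     "kind": "comparator"})

    table = pd.DataFrame(rows).set_index("focus")
    table["fdr"] = np.nan
    ps = table["p"].values
    all_p = np.append(ps, comb_p)
    tested = np.isfinite(all_p)
    if tested.any():
        adj = np.full(len(all_p), np.nan)
        adj[tested] = bh_adjust(all_p[tested])
        table["fdr"] = adj[:-1]
        comb_fdr = adj[-1]
    else:
        comb_fdr = np.nan
    vp = VariancePartition(table=table, combined=float(comb_frac), combined_p=float(comb_p)
                           if np.isfinite(comb_p) else np.nan)
    vp.table.attrs["combined_fdr"] = comb_fdr
    return vp
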