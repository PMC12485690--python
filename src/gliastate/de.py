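"""Pseudobulk differential expression with data-driven unwanted-variance
covariates.

Pipeline: filter genes detected in >= 0.5% of cells, TMM-normalize donor
pseudobulks, estimate latent unwanted-variance components from the SVD of
residuals after regressing out disease (k = floor(donors/2)), pick how many
components to keep from the maximal inflection of the residual-variance
elbow curve, fit a per-gene negative-binomial GLM
(counts ~ disease + W_1..W_k*, log link, offset = log(libsize * TMM factor)),
and z-score log2 fold-changes within each comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import t as t_dist

from .atlas import PseudobulkMatrix
from .composition import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationFactors",
    "UnwantedVariance",
    "ElbowCurve",
    "filter_genes",
    "tmm_factors",
    "log2_cpm",
    "ruv_components",
    "residual_variance_curve",
    "inflection_k",
    "nb_glm_de",
    "zscore_lfc",
]

LN2 = float(np.log(2.0))


@dataclass
class NormalizationFactors:
    factors: pd.Series  # per-sample TMM factor, geometric mean 1
    reference: str


@dataclass
class UnwantedVariance:
    W: np.ndarray  # samples x k, orthonormal columns
    singular_values: np.ndarray
    k_selected: int | None = None
    samples: list[str] | None = None


@dataclass
class ElbowCurve:
    residual_fraction: np.ndarray  # index k = 0..k_max
    k_selected: int | None = None


def filter_genes(
    cell_counts: np.ndarray, min_cell_frac: float = 0.005
) -> np.ndarray:
    """Boolean mask of genes detected (count > 0) in at least `min_cell_frac`
    of cells (inclusive boundary)."""
    frac = (np.asarray(cell_counts) > 0).mean(axis=0)
    keep = frac >= min_cell_frac
    if not keep.any():
        raise ValueError("no genes pass the expression filter")
    return keep


def tmm_factors(
    pb: PseudobulkMatrix | pd.DataFrame,
    logratio_trim: float = 0.3,
    abs_trim: float = 0.05,
) -> NormalizationFactors:
    """Trimmed mean of M-values scaling factors.

    Reference = sample whose upper quartile of library-size-scaled counts is
    closest to the mean upper quartile; per-sample factor = 2^(precision-
    weighted mean of doubly trimmed M-values vs the reference); factors are
    rescaled to geometric mean 1.
    """
    counts = pb.counts if isinstance(pb, PseudobulkMatrix) else pb
    Y = counts.values.astype(float)
    if Y.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    N = Y.sum(axis=0)
    if np.any(N == 0):
        raise ValueError("sample with all-zero counts")
    scaled = Y / N
    uq = np.array([np.quantile(scaled[:, j][Y[:, j] > 0], 0.75) for j in range(Y.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    logf = np.zeros(Y.shape[1])
    yr, Nr = Y[:, ref], N[ref]
    for j in range(Y.shape[1]):
        if j == ref:
            continue
        yk, Nk = Y[:, j], N[j]
        ok = (yk > 0) & (yr > 0)
        if ok.sum() < 1:
            continue
        m = np.log2((yk[ok] / Nk) / (yr[ok] / Nr))
        a = 0.5 * np.log2((yk[ok] / Nk) * (yr[ok] / Nr))
        w = (Nk - yk[ok]) / (Nk * yk[ok]) + (Nr - yr[ok]) / (Nr * yr[ok])
        lo_m, hi_m = np.quantile(m, [logratio_trim, 1 - logratio_trim])
        lo_a, hi_a = np.quantile(a, [abs_trim, 1 - abs_trim])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if keep.sum() == 0 or w[keep].sum() == 0:
            continue
        logf[j] = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    f = 2.0**logf
    f = f / np.exp(np.mean(np.log(f)))
    return NormalizationFactors(
        factors=pd.Series(f, index=counts.columns), reference=str(counts.columns[ref])
    )


def log2_cpm(
    pb: PseudobulkMatrix | pd.DataFrame,
    factors: NormalizationFactors | None = None,
    prior: float = 0.5,
) -> pd.DataFrame:
    """log2 counts-per-million on TMM-effective library sizes."""
    counts = pb.counts if isinstance(pb, PseudobulkMatrix) else pb
    lib = counts.sum(axis=0).astype(float)
    if factors is not None:
        lib = lib * factors.factors
    return np.log2((counts + prior).div(lib + 1.0, axis=1) * 1e6)


def _design(disease: np.ndarray, W: np.ndarray | None, k: int) -> np.ndarray:
    cols = [np.ones(len(disease)), np.asarray(disease, dtype=float)]
    if W is not None and k > 0:
        cols.extend(W[:, j] for j in range(k))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    return X


def ruv_components(
    pb: PseudobulkMatrix,
    disease_labels: np.ndarray,
    k: int | None = None,
    factors: NormalizationFactors | None = None,
) -> UnwantedVariance:
    """Latent unwanted-variance components from residuals.

    Per-gene OLS of log2-CPM on disease; the gene-centered residual matrix
    (samples x genes) is SVD'd and the first k left singular vectors are the
    component scores.  Default k = floor(n_samples / 2), the donors/2 rule.
    """
    disease = np.asarray(pd.Categorical(disease_labels).codes, dtype=float)
    n = len(disease)
    if k is None:
        k = max(1, n // 2)
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    if factors is None:
        factors = tmm_factors(pb)
    Y = log2_cpm(pb, factors).values.T  # samples x genes
    X = _design(disease, None, 0)
    H = X @ np.linalg.solve(X.T @ X, X.T)
    E = Y - H @ Y
    E = E - E.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(E, full_matrices=False)
    return UnwantedVariance(
        W=U[:, :k], singular_values=s[:k], samples=list(pb.counts.columns)
    )


def residual_variance_curve(
    pb: PseudobulkMatrix,
    disease_labels: np.ndarray,
    W: np.ndarray,
    k_max: int | None = None,
    factors: NormalizationFactors | None = None,
) -> ElbowCurve:
    """Mean over genes of RSS/TSS for designs [disease, W_1..W_k], k = 0..k_max."""
    disease = np.asarray(pd.Categorical(disease_labels).codes, dtype=float)
    if k_max is None:
        k_max = W.shape[1]
    if W.shape[1] < k_max:
        raise ValueError("W has fewer columns than k_max")
    if factors is None:
        factors = tmm_factors(pb)
    Y = log2_cpm(pb, factors).values.T  # samples x genes
    tss = np.sum((Y - Y.mean(axis=0, keepdims=True)) ** 2, axis=0)
    keep = tss > 1e-12
    fracs = []
    for k in range(k_max + 1):
        X = _design(disease, W, k)
        H = X @ np.linalg.solve(X.T @ X, X.T)
        R = Y - H @ Y
        rss = np.sum(R**2, axis=0)
        fracs.append(float(np.mean(rss[keep] / tss[keep])))
    return ElbowCurve(residual_fraction=np.asarray(fracs))


def inflection_k(curve: ElbowCurve | np.ndarray, tol: float = 1e-9) -> int:
    """Maximal inflection of the elbow curve.

    Chord from (0, y_0) to (k_max, y_kmax); d_k = y_k - chord(k).  If d
    changes sign the curve is sigmoid-like and k* is the rounded midpoint of
    argmin(d) and argmax(d); otherwise k* = argmax|d| (knee of a monotone
    convex/concave curve).  Ties break to the smaller k; a constant or exactly
    linear curve yields k* = 0 with a warning.
    """
    y = curve.residual_fraction if isinstance(curve, ElbowCurve) else np.asarray(curve, float)
    if len(y) < 3:
        raise ValueError("curve must have at least 3 points")
    x = np.arange(len(y), dtype=float)
    chord = y[0] + (y[-1] - y[0]) * x / x[-1]
    d = y - chord
    has_pos = np.any(d > tol)
    has_neg = np.any(d < -tol)
    if not has_pos and not has_neg:
        warnings.warn("elbow curve is linear/constant; k* = 0")
        return 0
    if has_pos and has_neg:
        return int(round((int(np.argmin(d)) + int(np.argmax(d))) / 2))
    return int(np.argmax(np.abs(d)))


def nb_glm_de(
    pb: PseudobulkMatrix,
    disease_labels: np.ndarray,
    W: np.ndarray | None = None,
    k: int = 0,
    factors: NormalizationFactors | None = None,
    dispersion: float | None = None,
    max_se: float = 10.0,
) -> pd.DataFrame:
    """Per-gene NB GLM Wald test for the disease term.

    Log link, offset log(library size x TMM factor); per-gene dispersion by
    method of moments on the Poisson-fit means of the disease-only model
    (floored at 1e-8) unless `dispersion` overrides it — estimating the
    dispersion under the reduced model keeps the latent covariates, which
    are themselves fit to residual variance, from shrinking the variance
    estimate and inflating the Wald test.  Non-convergent genes and genes with SE >
    `max_se` (natural-log scale) are flagged and excluded from the BH
    adjustment.  Returns a DataFrame with log2fc, se (log2 units), z, p,
    p_adj, dispersion and an `ok` flag.
    """
    disease = np.asarray(pd.Categorical(disease_labels).codes, dtype=float)
    if factors is None:
        factors = tmm_factors(pb)
    X = _design(disease, W, k)
    X0 = _design(disease, None, 0)
    lib = pb.counts.sum(axis=0).values.astype(float) * factors.factors.values
    offset = np.log(lib)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for gene in pb.counts.index:
            y = pb.counts.loc[gene].values.astype(float)
            rec = {"gene": gene, "log2fc": np.nan, "se": np.nan, "z": np.nan,
                   "p": np.nan, "dispersion": np.nan, "ok": False}
            try:
                pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
                if dispersion is None:
                    # method of moments under the disease-only model, with a
                    # df correction for the fitted mean parameters
                    if X.shape[1] > X0.shape[1]:
                        mu = sm.GLM(
                            y, X0, family=sm.families.Poisson(), offset=offset
                        ).fit().fittedvalues
                        dof = max(len(y) - X0.shape[1], 1)
                    else:
                        mu = pois.fittedvalues
                        dof = max(len(y) - X.shape[1], 1)
                    num = np.sum((y - mu) ** 2) * len(y) / dof - np.sum(mu)
                    den = np.sum(mu**2)
                    alpha = max(num / den if den > 0 else 0.0, 1e-8)
                else:
                    alpha = max(dispersion, 1e-8)
                fit = sm.GLM(
                    y, X, family=sm.families.NegativeBinomial(alpha=alpha),
                    offset=offset,
                ).fit(start_params=pois.params)
                beta = float(fit.params[1])
                se = float(fit.bse[1])
                ok = bool(fit.converged) and np.isfinite(se) and 0 < se <= max_se
                # Wald test against a t reference with residual df: the
                # plug-in dispersion makes the normal reference anti-
                # conservative at pseudobulk sample sizes
                dof_t = max(len(y) - X.shape[1], 1)
                rec.update(
                    log2fc=beta / LN2, se=se / LN2, z=beta / se,
                    p=float(2 * t_dist.sf(abs(beta / se), dof_t)),
                    dispersion=alpha, ok=ok,
                )
            except Exception as exc:  # non-convergent / separated gene
                logger.debug("gene %s failed: %s", gene, exc)
            rows.append(rec)
    out = pd.DataFrame(rows).set_index("gene")
    out["p_adj"] = np.nan
    ok = out["ok"] & out["p"].notna()
    if ok.any():
        out.loc[ok, "p_adj"] = bh_adjust(out.loc[ok, "p"].values)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("%d genes flagged (non-convergence or SE > %.3g)", n_bad, max_se)
    return out


def zscore_lfc(results: pd.DataFrame, column: str = "log2fc") -> pd.DataFrame:
    """Add a z-scored log2FC column (mean 0, sd 1 within the comparison)."""
    x = results[column].values.astype(float)
    finite = np.isfinite(x)
    sd = np.nanstd(x[finite], ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("zero variance in log2 fold-changes")
    out = results.copy()
    out[column + "_zscore"] = (x - np.nanmean(x[finite])) / sd
    return out


def run_de_with_latent_covariates(
    pb: PseudobulkMatrix,
    disease_labels: np.ndarray,
    k: int | None = None,
    dispersion: float | None = None,
) -> tuple[pd.DataFrame, ElbowCurve, UnwantedVariance]:
    """Full comparison: TMM -> RUV components (donors/2) -> elbow -> NB GLM
    with the selected components -> z-scored log2FC."""
    factors = tmm_factors(pb)
    ruv = ruv_components(pb, disease_labels, factors=factors, k=k)
    curve = residual_variance_curve(pb, disease_labels, ruv.W, factors=factors)
    k_star = inflection_k(curve)
    curve.k_selected = k_star
    ruv.k_selected = k_star
    res = nb_glm_de(
        pb, disease_labels, W=ruv.W, k=k_star, factors=factors, dispersion=dispersion
    )
    res = zscore_lfc(res.loc[res["ok"]]) if res["ok"].any() else res
    return res, curve, ruv
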