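"""Cell subtype proportion analysis.

Per-sample (donor x region) subcluster proportions, logit transformation with
a boundary offset, a Gaussian GLM on the logit scale testing disease vs
control with sex and standardized age as covariates, Welch's t-test for
region-class contrasts, and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "SampleProportions",
    "ProportionEffect",
    "compute_proportions",
    "logit_transform",
    "proportion_glm",
    "welch_test",
    "bh_adjust",
]


@dataclass
class SampleProportions:
    counts: pd.DataFrame      # subclusters x samples
    proportions: pd.DataFrame  # subclusters x samples, columns sum to 1
    totals: pd.Series          # per-sample total cells
    sample_meta: pd.DataFrame | None = None


@dataclass
class ProportionEffect:
    subcluster: str
    comparison: str
    beta: float
    se: float
    p: float
    p_adj: float = float("nan")
    dropped_covariates: tuple[str, ...] = field(default_factory=tuple)


def compute_proportions(
    counts_by_sample: pd.DataFrame, sample_meta: pd.DataFrame | None = None
) -> SampleProportions:
    """Per-sample proportions: count / per-sample total.

    `counts_by_sample` is subclusters x samples, non-negative integers.
    A sample with zero total is an error naming the sample.
    """
    counts = counts_by_sample.astype(float)
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total cells: {list(zero.index)}")
    props = counts / totals
    return SampleProportions(
        counts=counts_by_sample, proportions=props, totals=totals,
        sample_meta=sample_meta,
    )


def logit_transform(p: float | np.ndarray, offset: float = 1e-6) -> float | np.ndarray:
    """logit with boundary nudging: p=0 -> p+offset, p=1 -> p-offset."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("proportions must lie in [0, 1]")
    q = np.where(p == 0, p + offset, np.where(p == 1, p - offset, p))
    out = np.log(q / (1 - q))
    return float(out) if out.ndim == 0 else out


def welch_test(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float, float]:
    """Welch's t-test with Satterthwaite df; returns (t, df, two-sided p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-values cannot be BH-adjusted")
    return multipletests(p, method="fdr_bh")[1]


def proportion_glm(
    props: SampleProportions,
    subcluster: str,
    disease_pair: tuple[str, str],
    covariates: tuple[str, ...] = ("sex", "age"),
    offset: float = 1e-6,
    comparison: str | None = None,
) -> ProportionEffect:
    """OLS on logit-proportions: proportion ~ disease + sex + scaled age.

    `disease_pair` is (control, disease); the reported beta is the disease
    coefficient (logit units).  Age is standardized within the comparison.
    Rank-deficient covariates (e.g. a single-sex comparison) are dropped with
    a logged warning.
    """
    if props.sample_meta is None:
        raise ValueError("sample metadata is required for the GLM")
    meta = props.sample_meta
    control, disease = disease_pair
    mask = meta["disease"].isin([control, disease]).values
    sub_meta = meta.loc[mask]
    samples = sub_meta.index
    for grp in (control, disease):
        if (sub_meta["disease"] == grp).sum() < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 samples")

    y = logit_transform(props.proportions.loc[subcluster, samples].values, offset=offset)
    X = pd.DataFrame(index=samples)
    X["disease"] = (sub_meta["disease"] == disease).astype(float)
    dropped = []
    for cov in covariates:
        if cov not in sub_meta.columns:
            continue
        col = sub_meta[cov]
        if col.dtype == object or str(col.dtype) == "category":
            codes = pd.Categorical(col).codes.astype(float)
        else:
            codes = col.astype(float).values
            if cov == "age":
                sd = codes.std(ddof=1)
                codes = (codes - codes.mean()) / sd if sd > 0 else codes * 0.0
        if np.std(codes) == 0:
            dropped.append(cov)
            logger.warning("covariate %r constant within comparison; dropped", cov)
            continue
        X[cov] = codes
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design.values) < design.shape[1]:
        # drop collinear covariates one at a time, never the disease term
        for cov in list(X.columns[1:]):
            trial = design.drop(columns=[cov])
            if np.linalg.matrix_rank(trial.values) == trial.shape[1]:
                logger.warning("covariate %r collinear; dropped", cov)
                dropped.append(cov)
                design = trial
                break
    fit = sm.OLS(y, design).fit()
    return ProportionEffect(
        subcluster=subcluster,
        comparison=comparison or f"{disease}_vs_{control}",
        beta=float(fit.params["disease"]),
        se=float(fit.bse["disease"]),
        p=float(fit.pvalues["disease"]),
        dropped_covariates=tuple(dropped),
    )


def proportion_scan(
    props: SampleProportions,
    control: str,
    diseases: list[str] | None = None,
    covariates: tuple[str, ...] = ("sex", "age"),
    offset: float = 1e-6,
) -> pd.DataFrame:
    """All (subcluster x disease-vs-control) GLMs with BH adjustment across tests."""
    meta = props.sample_meta
    if diseases is None:
        diseases = [d for d in meta["disease"].unique() if d != control]
    rows = []
    for disease in diseases:
        for sub in props.proportions.index:
            eff = proportion_glm(
                props, sub, (control, disease), covariates=covariates, offset=offset
            )
            rows.append(
                {
                    "subcluster": sub, "comparison": eff.comparison,
                    "beta": eff.beta, "se": eff.se, "p": eff.p,
                }
            )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].values)
    return out
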