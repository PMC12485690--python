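"""Two-step signature validation.

PCA-based: TMM + log2-CPM pseudobulk expression restricted to the signature
genes, gene-centered and unit-scaled, PC1 per sample as the signature score;
iterative Rosner (generalized extreme studentized deviate) outlier removal on
PC1 with PCA recomputation until no outliers remain; then an OLS GLM
PC1 ~ disease_variable + covariates.  The score is inherently directionless,
so PC1 is oriented to correlate non-negatively with mean signature
expression and the association test is orientation-invariant.

GSEA-based: genes ranked by sign(log2FC) * -log10(p); weighted
Kolmogorov-Smirnov running-sum enrichment of the signature with a seeded
gene-label permutation null, normalized enrichment scores and permutation
p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .atlas import PseudobulkMatrix
from .de import NormalizationFactors, log2_cpm, tmm_factors

logger = logging.getLogger(__name__)

__all__ = [
    "PCAScore",
    "ScoreAssociation",
    "RankedList",
    "GseaResult",
    "pca_score",
    "rosner_outliers",
    "iterative_score",
    "rank_metric",
    "gsea_preranked",
]


@dataclass
class PCAScore:
    pc1: pd.Series                 # per retained sample
    var_explained: float
    removed: list[tuple[int, str]] = field(default_factory=list)  # (iteration, sample)
    dropped_genes: list[str] = field(default_factory=list)
    flipped: bool = False


@dataclass
class ScoreAssociation:
    beta: float
    se: float
    p: float
    fdr: float = float("nan")
    n: int = 0


@dataclass
class RankedList:
    metric: pd.Series  # descending; ties broken by gene id


@dataclass
class GseaResult:
    es: float
    nes: float
    p: float
    fdr: float = float("nan")
    leading_edge: list[str] = field(default_factory=list)
    n_perm: int = 0
    seed: int = 0


def pca_score(
    pb: PseudobulkMatrix | pd.DataFrame,
    signature_genes: list[str],
    factors: NormalizationFactors | None = None,
) -> PCAScore:
    """PC1 of TMM/log2-CPM expression of the signature genes across samples."""
    counts = pb.counts if isinstance(pb, PseudobulkMatrix) else pb
    if counts.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if factors is None:
        factors = tmm_factors(counts)
    expr = log2_cpm(counts, factors)
    present = [g for g in signature_genes if g in expr.index]
    nonzero = counts.loc[present].sum(axis=1) > 0
    present = [g for g in present if nonzero[g]]
    if len(present) < 2:
        raise ValueError("fewer than 2 signature genes present with nonzero counts")
    M = expr.loc[present].T  # samples x genes
    sd = M.std(axis=0, ddof=1)
    dropped = list(sd.index[sd == 0])
    M = M.loc[:, sd > 0]
    if M.shape[1] < 2:
        raise ValueError("all signature genes have zero variance")
    Z = (M - M.mean(axis=0)) / M.std(axis=0, ddof=1)
    U, s, _ = np.linalg.svd(Z.values, full_matrices=False)
    pc1 = pd.Series(U[:, 0] * s[0], index=M.index, name="PC1")
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    mean_expr = M.mean(axis=1)
    flipped = False
    r = np.corrcoef(pc1.values, mean_expr.values)[0, 1]
    if np.isfinite(r) and r < 0:
        pc1 = -pc1
        flipped = True
    return PCAScore(pc1=pc1, var_explained=var_explained, dropped_genes=dropped,
                    flipped=flipped)


def rosner_lambda(n: int, i: int, alpha: float) -> float:
    """Critical value of the generalized ESD test for the i-th outlier (1-based)."""
    p = 1.0 - alpha / (2.0 * (n - i + 1))
    t = stats.t.ppf(p, n - i - 1)
    return (n - i) * t / np.sqrt((n - i - 1 + t**2) * (n - i + 1))


def rosner_outliers(
    values: np.ndarray, alpha: float = 0.05, k_max: int | None = None
) -> list[int]:
    """Generalized extreme studentized deviate (Rosner) test.

    Iteratively removes the most extreme point and compares each R_i to its
    critical value lambda_i; the declared outliers are the first i points for
    the largest i with R_i > lambda_i.  Returns indices into `values`.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError("Rosner test needs at least 5 observations")
    if np.std(x, ddof=1) == 0:
        raise ValueError("zero variance")
    if k_max is None:
        k_max = max(1, n // 10)
    remaining = list(range(n))
    removed: list[int] = []
    stats_r: list[float] = []
    lambdas: list[float] = []
    for i in range(1, k_max + 1):
        xs = x[remaining]
        s = np.std(xs, ddof=1)
        if s == 0:
            break
        dev = np.abs(xs - xs.mean())
        j = int(np.argmax(dev))
        stats_r.append(float(dev[j] / s))
        lambdas.append(rosner_lambda(n, i, alpha))
        removed.append(remaining.pop(j))
    n_out = 0
    for i in range(len(stats_r), 0, -1):
        if stats_r[i - 1] > lambdas[i - 1]:
            n_out = i
            break
    return removed[:n_out]


def iterative_score(
    pb: PseudobulkMatrix,
    signature_genes: list[str],
    disease_var: str,
    covariates: tuple[str, ...] = ("sex", "age"),
    alpha: float = 0.05,
    min_samples: int = 5,
) -> tuple[PCAScore, ScoreAssociation]:
    """PCA score -> Rosner outlier removal -> recompute, until no outliers;
    then OLS PC1 ~ disease_variable + covariates (Wald test)."""
    counts = pb.counts.copy()
    meta = pb.sample_meta.copy()
    removed: list[tuple[int, str]] = []
    iteration = 0
    while True:
        if counts.shape[1] < min_samples:
            raise ValueError(
                f"outlier loop reduced the cohort below {min_samples} samples; "
                f"removed: {[s for _, s in removed]}"
            )
        score = pca_score(counts, signature_genes)
        out_idx = rosner_outliers(score.pc1.values, alpha=alpha)
        if not out_idx:
            break
        iteration += 1
        bad = [score.pc1.index[i] for i in out_idx]
        removed.extend((iteration, str(s)) for s in bad)
        logger.info("iteration %d: removing outlier samples %s", iteration, bad)
        counts = counts.drop(columns=bad)
        meta = meta.drop(index=bad)
    score.removed = removed

    y = score.pc1.values
    X = pd.DataFrame(index=score.pc1.index)
    dv = meta.loc[score.pc1.index, disease_var]
    if dv.dtype == object or str(dv.dtype) == "category":
        X["disease"] = pd.Categorical(dv).codes.astype(float)
    else:
        X["disease"] = dv.astype(float).values
    for cov in covariates:
        if cov not in meta.columns:
            continue
        col = meta.loc[score.pc1.index, cov]
        vals = (
            pd.Categorical(col).codes.astype(float)
            if col.dtype == object or str(col.dtype) == "category"
            else col.astype(float).values
        )
        if np.std(vals) > 0:
            X[cov] = vals
    design = sm.add_constant(X)
    fit = sm.OLS(y, design).fit()
    assoc = ScoreAssociation(
        beta=float(fit.params["disease"]),
        se=float(fit.bse["disease"]),
        p=float(fit.pvalues["disease"]),
        n=len(y),
    )
    return score, assoc


def rank_metric(de: pd.DataFrame, lfc_col: str = "log2fc", p_col: str = "p") -> RankedList:
    """Signed -log10(p) ranking: sign(log2FC) * -log10(p), descending order,
    ties broken by gene id (p floored at 1e-300)."""
    p = np.maximum(de[p_col].values.astype(float), 1e-300)
    metric = np.sign(de[lfc_col].values.astype(float)) * (-np.log10(p))
    s = pd.Series(metric, index=de.index, name="metric")
    s = s.iloc[np.lexsort((s.index.astype(str), -s.values))]
    return RankedList(metric=s)


def _es_from_positions(
    pos: np.ndarray, absmetric: np.ndarray, N: int
) -> tuple[float, int]:
    """Signed max-deviation ES given sorted hit positions; also returns the
    position index of the extremum (for the leading edge)."""
    n = len(pos)
    w = absmetric[pos]
    tot = w.sum()
    cumw = np.cumsum(w) / tot if tot > 0 else np.arange(1, n + 1) / n
    miss = 1.0 / (N - n)
    after = cumw - (pos + 1 - np.arange(1, n + 1)) * miss
    before = np.concatenate([[0.0], cumw[:-1]]) - (pos - np.arange(n)) * miss
    hi = float(after.max())
    lo = float(before.min())
    if hi >= -lo:
        return hi, int(np.argmax(after))
    return lo, int(np.argmin(before))


def gsea_preranked(
    ranks: RankedList,
    geneset: list[str] | set[str],
    n_perm: int = 10000,
    seed: int = 0,
) -> GseaResult:
    """Weighted KS preranked GSEA (weight exponent 1) with a gene-label
    permutation null.

    ES is the signed maximum deviation of the running sum (hit increments
    proportional to |metric|, miss decrements 1/(N-n)); NES = ES divided by
    the mean |null ES| of matching sign; p is the permutation fraction of
    same-sign nulls at least as extreme, lower-bounded by 1/(1+n_perm).
    """
    metric = ranks.metric
    genes = list(metric.index)
    N = len(genes)
    hits = sorted(set(geneset) & set(genes))
    if len(hits) < 2:
        raise ValueError("gene set intersects fewer than 2 ranked genes")
    n = len(hits)
    if n >= N:
        raise ValueError("gene set must be a strict subset of the ranked list")
    absm = np.abs(metric.values)
    gene_pos = {g: i for i, g in enumerate(genes)}
    pos = np.sort(np.array([gene_pos[g] for g in hits]))
    es, ext = _es_from_positions(pos, absm, N)
    if es >= 0:
        le = [genes[p] for p in pos[: ext + 1]]
    else:
        le = [genes[p] for p in pos[ext:]]

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm_pos = np.sort(rng.choice(N, size=n, replace=False))
        null[b], _ = _es_from_positions(perm_pos, absm, N)

    same = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if len(same) == 0:
        nes = np.nan
        p = 1.0 / (1.0 + n_perm)
    else:
        nes = float(es / np.mean(np.abs(same)))
        p = (1.0 + np.sum(np.abs(same) >= abs(es))) / (1.0 + len(same))
    return GseaResult(
        es=float(es), nes=float(nes), p=float(p), leading_edge=le,
        n_perm=n_perm, seed=seed,
    )


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")
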