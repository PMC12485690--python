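"""Consensus NMF discovery of gene expression programs (GEPs) and the
cross-dataset consensus signature rule.

Per dataset: library-size normalize, select highly variable genes, scale by
per-gene sd (no centering, non-negativity preserved), factorize with
multiplicative-update Frobenius NMF over many random restarts, filter
low-density replicate spectra, k-means cluster the survivors and take cluster
medians as consensus spectra.  Usages are refit by non-negative least
squares; full-gene spectra scores ("eigenvalues") come from regressing all
genes' normalized expression on the usages.

Across datasets: genes detected everywhere are z-scored within each chosen
GEP's score vector, averaged, and those above the z threshold (default 5)
form the consensus signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

__all__ = [
    "FactorizationInput",
    "ConsensusGEPs",
    "SignatureDefinition",
    "prepare_input",
    "nmf_once",
    "consensus",
    "consensus_nmf",
    "stability_error_curve",
    "gep_usage_by_group",
    "consensus_signature",
]


@dataclass
class FactorizationInput:
    X: np.ndarray              # cells x HVG, >= 0, sd-scaled
    hvg: list[str]
    gene_scale: np.ndarray     # per-HVG sd used for scaling
    X_full: np.ndarray         # cells x all detected genes, normalized + scaled
    gene_names: list[str]


@dataclass
class ConsensusGEPs:
    spectra: np.ndarray        # k x HVG consensus spectra (L2-normalized)
    usages: np.ndarray         # cells x k (NNLS refit)
    gene_scores: pd.DataFrame  # k x all genes ("eigenvalues" from usage regression)
    hvg: list[str]
    silhouette: float
    error: float               # relative Frobenius reconstruction error (consensus)
    replicate_error: float     # best single-replicate relative error
    seeds: list[int] = field(default_factory=list)


@dataclass
class SignatureDefinition:
    genes: list[str]
    average_z: pd.Series       # over all intersected genes
    per_dataset_z: pd.DataFrame
    threshold: float
    source_geps: Mapping[str, str] = field(default_factory=dict)


def prepare_input(
    counts: np.ndarray | pd.DataFrame,
    gene_names: Sequence[str] | None = None,
    n_hvg: int = 2000,
) -> FactorizationInput:
    """Library-size normalize, rank genes by variance-to-mean ratio, keep the
    top `n_hvg`, and scale genes by their standard deviation."""
    if isinstance(counts, pd.DataFrame):
        gene_names = list(counts.columns)
        counts = counts.values
    C = np.asarray(counts, dtype=float)
    if np.any(C < 0):
        raise ValueError("counts must be non-negative")
    if gene_names is None:
        gene_names = [f"gene{g}" for g in range(C.shape[1])]
    lib = C.sum(axis=1)
    if np.any(lib == 0):
        raise ValueError("cells with zero counts are not allowed")
    norm = C / lib[:, None] * np.median(lib)
    mean = norm.mean(axis=0)
    var = norm.var(axis=0)
    expressed = (mean > 0) & (var > 0)
    vmr = np.where(expressed, var / np.maximum(mean, 1e-12), -np.inf)
    n_avail = int(expressed.sum())
    if n_avail < n_hvg:
        logger.warning("only %d variable genes available (< %d); using all", n_avail, n_hvg)
        n_hvg = n_avail
    order = np.argsort(-vmr)[:n_hvg]
    order = np.sort(order)
    sd = np.sqrt(var[order])
    X = norm[:, order] / sd[None, :]
    sd_full = np.sqrt(np.where(expressed, var, 1.0))
    X_full = norm[:, expressed] / sd_full[expressed][None, :]
    return FactorizationInput(
        X=X,
        hvg=[gene_names[i] for i in order],
        gene_scale=sd,
        X_full=X_full,
        gene_names=[g for g, e in zip(gene_names, expressed) if e],
    )


def nmf_once(
    X: np.ndarray, k: int, seed: int, max_iter: int = 500, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """One multiplicative-update Frobenius NMF run.

    Returns (W usage, H spectra, frobenius error, objective trace); the
    objective is non-increasing per update and the run is deterministic in
    the seed.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("X must be non-negative")
    n, g = X.shape
    if k > min(n, g):
        raise ValueError("k exceeds matrix dimensions")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(X.mean() / k)
    W = rng.uniform(1e-4, 1.0, size=(n, k)) * scale
    H = rng.uniform(1e-4, 1.0, size=(k, g)) * scale
    eps = 1e-12
    trace = []
    prev = None
    for _ in range(max_iter):
        W *= (X @ H.T) / (W @ (H @ H.T) + eps)
        H *= (W.T @ X) / ((W.T @ W) @ H + eps)
        err = float(np.linalg.norm(X - W @ H, "fro"))
        trace.append(err)
        if prev is not None and (prev - err) < tol * max(prev, 1.0):
            break
        prev = err
    return W, H, trace[-1], np.asarray(trace)


def consensus(
    spectra_replicates: Sequence[np.ndarray],
    k: int,
    density_quantile: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Cluster replicate spectra into k consensus spectra.

    All replicate spectra are L2-normalized; spectra whose mean distance to
    their K nearest neighbors (K = number of replicates) exceeds the
    `density_quantile` quantile of that distance distribution are filtered as
    outliers; survivors are k-means clustered and cluster medians
    (re-normalized) are the consensus spectra.  Returns (spectra k x genes,
    silhouette of the clustering).
    """
    n_rep = len(spectra_replicates)
    if n_rep < 2:
        raise ValueError("need at least 2 replicates")
    S = np.vstack(spectra_replicates)
    norms = np.linalg.norm(S, axis=1)
    S = S[norms > 0] / norms[norms > 0, None]

    K = min(n_rep, S.shape[0] - 1)
    from scipy.spatial.distance import cdist

    D = cdist(S, S)
    np.fill_diagonal(D, np.inf)
    knn_mean = np.sort(D, axis=1)[:, :K].mean(axis=1)
    thr = np.quantile(knn_mean, density_quantile)
    keep = knn_mean <= thr
    if keep.sum() < k:
        logger.warning("density filter left < k spectra; disabling the filter")
        keep = np.ones(len(S), dtype=bool)
    Sf = S[keep]

    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(Sf)
    labels = km.labels_
    for c in range(k):
        if not np.any(labels == c):
            logger.warning("empty consensus cluster after filtering; refit on all spectra")
            km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(S)
            Sf, labels = S, km.labels_
            break
    cons = np.vstack([np.median(Sf[labels == c], axis=0) for c in range(k)])
    cons = np.maximum(cons, 0.0)
    cons /= np.maximum(np.linalg.norm(cons, axis=1, keepdims=True), 1e-12)
    sil = float(silhouette_score(Sf, labels)) if k > 1 and len(Sf) > k else 1.0
    return cons, sil


def _nnls_usages(X: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Per-cell non-negative least squares of X on the spectra H (k x genes)."""
    A = H.T
    return np.vstack([nnls(A, x)[0] for x in X])


def consensus_nmf(
    fi: FactorizationInput,
    k: int,
    n_replicates: int = 30,
    seed: int = 0,
    density_quantile: float = 0.5,
) -> ConsensusGEPs:
    """Full per-dataset consensus factorization at one k."""
    seeds = [seed + 1000 * r for r in range(n_replicates)]
    reps = []
    rep_errs = []
    for s in seeds:
        _, H, err, _ = nmf_once(fi.X, k, seed=s)
        reps.append(H)
        rep_errs.append(err / max(np.linalg.norm(fi.X, "fro"), 1e-12))
    cons, sil = consensus(reps, k, density_quantile=density_quantile, seed=seed)
    W = _nnls_usages(fi.X, cons)
    err = float(np.linalg.norm(fi.X - W @ cons, "fro") / np.linalg.norm(fi.X, "fro"))
    # full-gene spectra scores: OLS of all-gene normalized expression on usages
    WtW = W.T @ W
    scores = np.linalg.solve(WtW + 1e-10 * np.eye(k), W.T @ fi.X_full)
    gene_scores = pd.DataFrame(
        scores, index=[f"GEP{i + 1}" for i in range(k)], columns=fi.gene_names
    )
    return ConsensusGEPs(
        spectra=cons,
        usages=W,
        gene_scores=gene_scores,
        hvg=fi.hvg,
        silhouette=sil,
        error=err,
        replicate_error=float(min(rep_errs)),
        seeds=seeds,
    )


def stability_error_curve(
    fi: FactorizationInput,
    k_range: Sequence[int],
    n_replicates: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-k stability (silhouette) and reconstruction error; the choice of k
    is the caller's, balancing high stability against low error."""
    rows = []
    for k in k_range:
        geps = consensus_nmf(fi, k, n_replicates=n_replicates, seed=seed)
        rows.append(
            {"k": k, "silhouette": geps.silhouette, "error": geps.error,
             "replicate_error": geps.replicate_error}
        )
    return pd.DataFrame(rows).set_index("k")


def gep_usage_by_group(usages: np.ndarray, labels: Sequence[str]) -> pd.DataFrame:
    """Mean GEP usage per group (e.g. per subcluster); groups x k."""
    labels = pd.Series(list(labels))
    if len(labels) != usages.shape[0]:
        raise ValueError("labels must cover all cells")
    df = pd.DataFrame(usages, columns=[f"GEP{i + 1}" for i in range(usages.shape[1])])
    out = df.groupby(labels.values).mean()
    if (pd.Series(labels).value_counts() == 0).any():
        raise ValueError("empty group")
    return out


def consensus_signature(
    gep_scores: Mapping[str, pd.Series],
    z_threshold: float = 5.0,
    source_geps: Mapping[str, str] | None = None,
) -> SignatureDefinition:
    """Cross-dataset consensus signature.

    `gep_scores` maps dataset name -> full-gene score vector of that
    dataset's chosen GEP (index = genes detected in the dataset).  Genes are
    restricted to those detected in every dataset, z-scored within each GEP,
    averaged across datasets, and kept when the average exceeds z_threshold.
    Deterministic given the scores.
    """
    if len(gep_scores) < 2:
        raise ValueError("need at least 2 datasets")
    common: set[str] | None = None
    for s in gep_scores.values():
        common = set(s.index) if common is None else common & set(s.index)
    if not common:
        raise ValueError("no genes detected in all datasets")
    genes = sorted(common)
    zs = {}
    for ds, s in gep_scores.items():
        v = s.loc[genes].astype(float)
        sd = v.std(ddof=1)
        zs[ds] = (v - v.mean()) / sd if sd > 0 else v * 0.0
    per_ds = pd.DataFrame(zs)
    avg = per_ds.mean(axis=1)
    members = list(avg.index[avg > z_threshold])
    return SignatureDefinition(
        genes=members,
        average_z=avg.sort_values(ascending=False),
        per_dataset_z=per_ds,
        threshold=z_threshold,
        source_geps=dict(source_geps or {}),
    )
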