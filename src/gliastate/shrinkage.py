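"""Empirical-Bayes multivariate shrinkage across conditions ("mash-lite").

Per-feature effect estimates observed in R conditions are modeled as

    b-hat_j ~ sum_{k,l} pi_{kl} N(0, omega_l * U_k + diag(s-hat_j^2)),

a mixture over covariance patterns U_k (canonical and data-driven) and a
geometric scale grid omega_l, plus an exact null point mass.  The mixture
weights pi are fit by EM on the marginal likelihood; because the component
covariances are fixed, the per-feature per-component log-likelihood matrix is
computed once and the EM iterates only the weights (monotone by construction).

Posterior summaries per feature x condition: shrunken mean, sd, and the local
false sign rate LFSR = min{P(b >= 0 | D), P(b <= 0 | D)} with null mass
counted on both sides.

Data-driven covariances follow the PCA + extreme-deconvolution recipe: PCA of
the strong-signal subset, rank-1 components for each principal component
explaining > 5% of overall variance plus their pooled "tPCA" sum, each refined
by a zero-mean MVN-mixture extreme-deconvolution EM with per-feature noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.special import logsumexp, ndtr
from sklearn.cluster import KMeans

from .atlas import EffectTable

logger = logging.getLogger(__name__)

__all__ = [
    "CovarianceComponent",
    "ScaleGrid",
    "MashFit",
    "canonical_covariances",
    "scale_grid",
    "fit_mixture",
    "posterior_lfsr",
    "strong_subset",
    "data_driven_covariances",
    "extreme_deconvolution",
    "mixture_summary",
    "pattern_genes",
    "kmeans_patterns",
    "chord_knee",
]

_JITTER = 1e-8
_PSD_TOL = 1e-10


@dataclass
class CovarianceComponent:
    name: str
    matrix: np.ndarray
    origin: str = "canonical"  # canonical | pca | ed

    def __post_init__(self) -> None:
        U = np.asarray(self.matrix, dtype=float)
        U = (U + U.T) / 2
        ev = np.linalg.eigvalsh(U)
        if ev.min() < -_PSD_TOL:
            raise ValueError(f"component {self.name!r} is not PSD (min eig {ev.min():.3g})")
        self.matrix = U


@dataclass
class ScaleGrid:
    """Geometric sd grid (ratio sqrt(2)); omegas are variances, null handled
    as a separate point mass in the mixture."""

    sds: np.ndarray

    @property
    def omegas(self) -> np.ndarray:
        return self.sds**2


@dataclass
class MashFit:
    components: list[CovarianceComponent]
    grid: ScaleGrid
    pi: np.ndarray                     # len = 1 (null) + K*L
    entry_component: np.ndarray        # per mixture entry: component index (-1 = null)
    entry_omega: np.ndarray            # per mixture entry: omega (0 for null)
    loglik_matrix: np.ndarray          # features x entries (fixed across EM)
    loglik_trace: np.ndarray
    conditions: list[str]
    features: list[str]

    @property
    def responsibilities(self) -> np.ndarray:
        logw = np.log(np.maximum(self.pi, 1e-300))
        logr = self.loglik_matrix + logw[None, :]
        logr -= logsumexp(logr, axis=1, keepdims=True)
        return np.exp(logr)

    def component_responsibilities(self) -> pd.DataFrame:
        """Per-feature responsibilities summed over scales, one column per
        component plus 'null'."""
        resp = self.responsibilities
        names = ["null"] + [c.name for c in self.components]
        out = np.zeros((resp.shape[0], len(names)))
        out[:, 0] = resp[:, self.entry_component == -1].sum(axis=1)
        for k in range(len(self.components)):
            out[:, k + 1] = resp[:, self.entry_component == k].sum(axis=1)
        return pd.DataFrame(out, index=self.features, columns=names)


def canonical_covariances(R: int) -> list[CovarianceComponent]:
    """Canonical sharing patterns: identity (independent effects), per-
    condition singletons, equal effects (all ones), and heterogeneous sharing
    at rho in {0.25, 0.5, 0.75}.

    Duplicate matrices are removed, except that 'identity' and 'equal_effects'
    (the no-sharing and full-sharing anchors) are always retained even when
    they coincide numerically (R = 1).
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    comps = [CovarianceComponent("identity", np.eye(R))]
    for r in range(R):
        m = np.zeros((R, R))
        m[r, r] = 1.0
        comps.append(CovarianceComponent(f"singleton_{r}", m))
    comps.append(CovarianceComponent("equal_effects", np.ones((R, R))))
    for rho in (0.25, 0.5, 0.75):
        m = np.full((R, R), rho)
        np.fill_diagonal(m, 1.0)
        comps.append(CovarianceComponent(f"het_{rho}", m))
    keep: list[CovarianceComponent] = []
    anchors = {"identity", "equal_effects"}
    for c in comps:
        dup = any(np.allclose(c.matrix, k.matrix) for k in keep)
        if dup and c.name not in anchors:
            continue
        keep.append(c)
    return keep


def scale_grid(effects: EffectTable) -> ScaleGrid:
    """sd grid from min(s-hat)/10 to 2*max|b-hat|, geometric with ratio sqrt 2."""
    bmax = float(np.max(np.abs(effects.bhat)))
    if bmax == 0:
        return ScaleGrid(sds=np.zeros(0))
    lo = float(np.min(effects.shat)) / 10.0
    hi = 2.0 * bmax
    if hi <= lo:
        return ScaleGrid(sds=np.array([lo]))
    n = int(np.ceil(np.log(hi / lo) / np.log(np.sqrt(2.0))))
    sds = lo * np.sqrt(2.0) ** np.arange(n + 1)
    return ScaleGrid(sds=sds)


def _group_rows(shat: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group features by identical standard-error rows; returns
    (row indices, noise diagonal) per group."""
    uniq, inverse = np.unique(shat, axis=0, return_inverse=True)
    return [(np.where(inverse == g)[0], uniq[g] ** 2) for g in range(len(uniq))]


def _mvn_loglik(B: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """log N(B_j; 0, sigma) for rows of B, with jitter fallback."""
    R = sigma.shape[0]
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        logger.debug("singular covariance; adding jitter %.0e", _JITTER)
        L = np.linalg.cholesky(sigma + _JITTER * np.eye(R))
    y = solve_triangular(L, B.T, lower=True)
    quad = np.sum(y**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (quad + logdet + R * np.log(2 * np.pi))


def _build_entries(
    components: list[CovarianceComponent], grid: ScaleGrid
) -> tuple[np.ndarray, np.ndarray]:
    comp_idx = [-1]
    omegas = [0.0]
    for k in range(len(components)):
        for w in grid.omegas:
            comp_idx.append(k)
            omegas.append(float(w))
    return np.asarray(comp_idx), np.asarray(omegas)


def _loglik_matrix(
    effects: EffectTable,
    components: list[CovarianceComponent],
    entry_component: np.ndarray,
    entry_omega: np.ndarray,
) -> np.ndarray:
    n, R = effects.bhat.shape
    L = np.empty((n, len(entry_component)))
    groups = _group_rows(effects.shat)
    for m, (k, w) in enumerate(zip(entry_component, entry_omega)):
        U = np.zeros((R, R)) if k == -1 else w * components[k].matrix
        for idx, vdiag in groups:
            L[idx, m] = _mvn_loglik(effects.bhat[idx], U + np.diag(vdiag))
    return L


def fit_mixture(
    effects: EffectTable,
    components: list[CovarianceComponent],
    grid: ScaleGrid | None = None,
    max_iter: int = 2000,
    tol: float = 1e-8,
) -> MashFit:
    """EM fit of the mixture weights pi over (component, scale) pairs plus
    the exact null; the likelihood trace is monotone non-decreasing."""
    if grid is None:
        grid = scale_grid(effects)
    entry_component, entry_omega = _build_entries(components, grid)
    L = _loglik_matrix(effects, components, entry_component, entry_omega)
    M = L.shape[1]
    pi = np.full(M, 1.0 / M)
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        logw = np.log(np.maximum(pi, 1e-300))
        logr = L + logw[None, :]
        per_feat = logsumexp(logr, axis=1)
        ll = float(per_feat.sum())
        trace.append(ll)
        resp = np.exp(logr - per_feat[:, None])
        pi = resp.mean(axis=0)
        pi /= pi.sum()
        if ll - prev < tol * max(1.0, abs(ll)) and len(trace) > 1:
            break
        prev = ll
    return MashFit(
        components=components,
        grid=grid,
        pi=pi,
        entry_component=entry_component,
        entry_omega=entry_omega,
        loglik_matrix=L,
        loglik_trace=np.asarray(trace),
        conditions=list(effects.conditions),
        features=list(effects.features),
    )


def posterior_lfsr(
    effects: EffectTable, fit: MashFit
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Posterior mean, posterior sd, and LFSR per feature x condition.

    Each mixture entry contributes a conditional Gaussian posterior
    b | b-hat ~ N(U1 (U1+V)^-1 b-hat, U1 - U1 (U1+V)^-1 U1), U1 = omega*U_k,
    mixed by the entry responsibilities; entries with zero posterior variance
    in a condition (the null, and patterns silent in that condition) are point
    masses at zero counted on both sides of the sign probabilities.
    """
    B = effects.bhat
    n, R = B.shape
    resp = fit.responsibilities
    groups = _group_rows(effects.shat)

    post_mean = np.zeros((n, R))
    post_m2 = np.zeros((n, R))
    p_geq = np.zeros((n, R))
    p_leq = np.zeros((n, R))

    for m, (k, w) in enumerate(zip(fit.entry_component, fit.entry_omega)):
        g = resp[:, m]
        if np.all(g < 1e-15):
            continue
        if k == -1 or w == 0.0:
            p_geq += g[:, None]
            p_leq += g[:, None]
            continue
        U1 = w * fit.components[k].matrix
        for idx, vdiag in groups:
            V = np.diag(vdiag)
            try:
                A = np.linalg.solve((U1 + V).T, U1.T).T  # U1 (U1+V)^-1
            except np.linalg.LinAlgError:
                A = np.linalg.solve((U1 + V + _JITTER * np.eye(R)).T, U1.T).T
            mu = B[idx] @ A.T
            C = U1 - A @ U1
            cdiag = np.maximum(np.diag(C), 0.0)
            gg = g[idx, None]
            post_mean[idx] += gg * mu
            post_m2[idx] += gg * (mu**2 + cdiag[None, :])
            sd = np.sqrt(cdiag)
            pos = np.zeros_like(mu)
            neg = np.zeros_like(mu)
            nz = sd > 1e-10
            pos[:, nz] = ndtr(mu[:, nz] / sd[None, nz])
            neg[:, nz] = ndtr(-mu[:, nz] / sd[None, nz])
            # zero-variance conditions: point mass at mu (= 0 there)
            pos[:, ~nz] = 1.0
            neg[:, ~nz] = 1.0
            p_geq[idx] += gg * pos
            p_leq[idx] += gg * neg

    post_sd = np.sqrt(np.maximum(post_m2 - post_mean**2, 0.0))
    lfsr = np.minimum(np.clip(p_geq, 0, 1), np.clip(p_leq, 0, 1))
    return post_mean, post_sd, lfsr


def strong_subset(
    effects: EffectTable, lfsr_threshold: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Condition-by-condition univariate shrinkage (R = 1 special case of the
    same mixture machinery); returns (indices of strong features, per-feature
    min-over-conditions LFSR)."""
    n, R = effects.bhat.shape
    min_lfsr = np.ones(n)
    for r in range(R):
        sub = EffectTable(
            bhat=effects.bhat[:, [r]], shat=effects.shat[:, [r]],
            conditions=[effects.conditions[r]], features=list(effects.features),
        )
        comps = [CovarianceComponent("identity", np.eye(1))]
        fit = fit_mixture(sub, comps)
        _, _, lfsr = posterior_lfsr(sub, fit)
        min_lfsr = np.minimum(min_lfsr, lfsr[:, 0])
    idx = np.where(min_lfsr < lfsr_threshold)[0]
    if len(idx) == 0:
        logger.warning(
            "no features met the strong-subset LFSR threshold %.3g; caller "
            "should fall back to canonical-only covariances", lfsr_threshold,
        )
    return idx, min_lfsr


def extreme_deconvolution(
    B: np.ndarray,
    shat: np.ndarray,
    initial: list[np.ndarray],
    max_iter: int = 500,
    tol: float = 1e-6,
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """Zero-mean MVN-mixture extreme deconvolution with per-feature diagonal
    noise; returns (refined covariances, weights, log-likelihood trace)."""
    n, R = B.shape
    K = len(initial)
    Us = [np.asarray(U, dtype=float).copy() + _JITTER * np.eye(R) for U in initial]
    w = np.full(K, 1.0 / K)
    groups = _group_rows(shat)
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        logl = np.empty((n, K))
        for k, U in enumerate(Us):
            for idx, vdiag in groups:
                logl[idx, k] = _mvn_loglik(B[idx], U + np.diag(vdiag))
        logr = logl + np.log(np.maximum(w, 1e-300))[None, :]
        per_feat = logsumexp(logr, axis=1)
        ll = float(per_feat.sum())
        trace.append(ll)
        resp = np.exp(logr - per_feat[:, None])
        for k in range(K):
            U = Us[k]
            num = np.zeros((R, R))
            den = resp[:, k].sum()
            if den < 1e-12:
                continue
            for idx, vdiag in groups:
                T = np.linalg.inv(U + np.diag(vdiag))
                A = U @ T
                mu = B[idx] @ A.T
                C = U - A @ U
                g = resp[idx, k]
                num += (mu * g[:, None]).T @ mu + g.sum() * C
            Unew = num / den
            Us[k] = (Unew + Unew.T) / 2
        w = resp.mean(axis=0)
        w /= w.sum()
        if ll - prev < tol * max(1.0, abs(ll)) and len(trace) > 1:
            break
        prev = ll
    return Us, w, np.asarray(trace)


def data_driven_covariances(
    strong: EffectTable, var_explained_min: float = 0.05
) -> list[CovarianceComponent]:
    """PCA of the strong-subset estimates -> rank-1 components for each PC
    explaining > var_explained_min of overall variance, plus the pooled tPCA
    component; all refined by extreme deconvolution."""
    B = strong.bhat
    n, R = B.shape
    if n < 2:
        raise ValueError("need at least 2 strong features for data-driven covariances")
    if n < R:
        logger.warning("fewer strong features (%d) than conditions (%d)", n, R)
    _, s, Vt = np.linalg.svd(B, full_matrices=False)
    var_frac = s**2 / np.sum(s**2)
    retained = np.where(var_frac > var_explained_min)[0]
    if len(retained) == 0:
        retained = np.array([0])
    inits = []
    names = []
    for p in retained:
        v = Vt[p]
        inits.append(np.outer(v, v))
        names.append(f"ED_PCA{p + 1}")
    t = sum(s[p] ** 2 * np.outer(Vt[p], Vt[p]) for p in retained)
    t = t / np.trace(t)
    inits.append(t)
    names.append("ED_tPCA")
    refined, _, trace = extreme_deconvolution(B, strong.shat, inits)
    if not np.all(np.diff(trace) >= -1e-6 * np.maximum(1.0, np.abs(trace[:-1]))):
        logger.warning("ED log-likelihood decreased; numerical issue")
    out = []
    for name, U in zip(names, refined):
        tr = np.trace(U)
        U = U / tr if tr > 0 else U
        ev = np.linalg.eigvalsh(U)
        if ev.min() < 0:
            # project to PSD cone (numerical cleanup only)
            w_, Q = np.linalg.eigh(U)
            U = (Q * np.maximum(w_, 0.0)) @ Q.T
        out.append(CovarianceComponent(name, U, origin="ed"))
    return out


def mixture_summary(fit: MashFit, null_sd: float = 0.0) -> pd.Series:
    """pi summed over scales per component (plus null), sorted descending.

    Mixture entries whose effect sd is <= `null_sd` are counted toward the
    null: scales far below the observation noise are statistically
    indistinguishable from the exact null, so per-component totals are only
    identifiable above a noise-relative floor (e.g. null_sd = 0.3 * SE adds
    under 10% to the observed variance).
    """
    names = ["null"] + [c.name for c in fit.components]
    agg = np.zeros(len(names))
    sds = np.sqrt(fit.entry_omega)
    null_like = (fit.entry_component == -1) | (sds <= null_sd)
    agg[0] = fit.pi[null_like].sum()
    for k in range(len(fit.components)):
        agg[k + 1] = fit.pi[(fit.entry_component == k) & ~null_like].sum()
    return pd.Series(agg, index=names).sort_values(ascending=False)


def pattern_genes(fit: MashFit, component_name: str) -> list[str]:
    """Features whose scale-summed responsibility is maximal for the named
    component; ties go to the lowest component index (logged)."""
    cr = fit.component_responsibilities()
    if component_name not in cr.columns:
        raise KeyError(f"unknown component {component_name!r}")
    vals = cr.values
    best = np.argmax(vals, axis=1)  # argmax takes first on ties
    ties = (vals == vals[np.arange(len(vals)), best][:, None]).sum(axis=1) > 1
    if ties.any():
        logger.info("%d features had tied responsibilities; lowest index kept", ties.sum())
    target = list(cr.columns).index(component_name)
    return [f for f, b in zip(cr.index, best) if b == target]


def chord_knee(y: np.ndarray) -> int:
    """Knee of a monotone curve: index of maximal perpendicular distance from
    the chord joining the endpoints."""
    y = np.asarray(y, dtype=float)
    x = np.arange(len(y), dtype=float)
    p0 = np.array([x[0], y[0]])
    p1 = np.array([x[-1], y[-1]])
    d = p1 - p0
    nrm = np.hypot(*d)
    if nrm == 0:
        return 0
    dist = np.abs(d[1] * (x - p0[0]) - d[0] * (y - p0[1])) / nrm
    return int(np.argmax(dist))


def kmeans_patterns(
    betas: np.ndarray,
    k_range: range = range(1, 11),
    seed: int = 0,
    n_restarts: int = 25,
) -> tuple[np.ndarray, pd.Series, int]:
    """k-means over pattern-gene effect profiles with a within-SS elbow.

    Lloyd's algorithm with `n_restarts` restarts per k; returns (labels at the
    chosen k, the WSS curve, chosen k).  The chosen k is the chord-distance
    knee of the WSS curve.
    """
    X = np.asarray(betas, dtype=float)
    ks = [k for k in k_range if k <= X.shape[0]]
    if not ks:
        raise ValueError("k_range exceeds the number of features")
    wss = {}
    labels = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(X)
        wss[k] = float(km.inertia_)
        labels[k] = km.labels_
    curve = pd.Series(wss)
    k_star = ks[chord_knee(curve.values)]
    return labels[k_star], curve, k_star
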