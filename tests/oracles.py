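"""Independent oracles used by the test suite.

The posterior oracle works in the latent coordinates b = A s with
s ~ N(0, I_rank) per mixture entry (A from the eigendecomposition of the
entry covariance): Gauss-Hermite quadrature for the moments and the
latent-Gaussian closed form (posterior precision I + A'V^-1 A) for the sign
probabilities.  This is a different parameterization and matrix algebra from
the implementation's U1 (U1+V)^-1 route.
"""

import numpy as np
from scipy.stats import norm


def posterior_oracle(bhat_row, shat_row, fit):
    """Posterior mean, sd, and LFSR for one feature of an R=2 mash fit."""
    b_obs = np.asarray(bhat_row, dtype=float)
    s = np.asarray(shat_row, dtype=float)
    R = len(b_obs)
    V = np.diag(s**2)
    nodes, weights = np.polynomial.hermite_e.hermegauss(80)

    post_w, post_m, post_m2, post_pgeq, post_pleq = [], [], [], [], []
    for k, w in zip(fit.entry_component, fit.entry_omega):
        if k == -1:
            lik = float(
                np.exp(-0.5 * b_obs @ np.linalg.solve(V, b_obs))
                / ((2 * np.pi) ** (R / 2) * np.sqrt(np.linalg.det(V)))
            )
            post_w.append(lik)
            post_m.append(np.zeros(R))
            post_m2.append(np.zeros(R))
            post_pgeq.append(np.ones(R))
            post_pleq.append(np.ones(R))
            continue
        U1 = w * fit.components[k].matrix
        lam, Q = np.linalg.eigh(U1)
        keep = lam > 1e-12
        A = Q[:, keep] * np.sqrt(lam[keep])
        rank = A.shape[1]
        if rank == 1:
            S = nodes[:, None]
            qw = weights
        else:
            S = np.array([[a, b] for a in nodes for b in nodes])
            qw = np.array([wa * wb for wa in weights for wb in weights])
        B = S @ A.T
        resid = b_obs[None, :] - B
        loglik = -0.5 * np.sum(resid**2 / s[None, :] ** 2, axis=1)
        f = qw * np.exp(loglik) / ((2 * np.pi) ** (R / 2) * np.prod(s))
        Z = f.sum() / (2 * np.pi) ** (rank / 2)
        m = (f[:, None] * B).sum(axis=0) / f.sum()
        m2 = (f[:, None] * B**2).sum(axis=0) / f.sum()

        P = np.eye(rank) + A.T @ np.linalg.solve(V, A)
        Pinv = np.linalg.inv(P)
        mu_s = Pinv @ (A.T @ np.linalg.solve(V, b_obs))
        pgeq = np.empty(R)
        pleq = np.empty(R)
        for r in range(R):
            a_r = A[r]
            var_r = float(a_r @ Pinv @ a_r)
            mean_r = float(a_r @ mu_s)
            if var_r < 1e-20:
                pgeq[r] = pleq[r] = 1.0
            else:
                pgeq[r] = norm.cdf(mean_r / np.sqrt(var_r))
                pleq[r] = norm.cdf(-mean_r / np.sqrt(var_r))
        post_w.append(Z)
        post_m.append(m)
        post_m2.append(m2)
        post_pgeq.append(pgeq)
        post_pleq.append(pleq)

    post_w = np.array(post_w) * fit.pi
    post_w /= post_w.sum()
    mean = (post_w[:, None] * np.array(post_m)).sum(axis=0)
    m2 = (post_w[:, None] * np.array(post_m2)).sum(axis=0)
    sd = np.sqrt(np.maximum(m2 - mean**2, 0.0))
    pgeq = (post_w[:, None] * np.array(post_pgeq)).sum(axis=0)
    pleq = (post_w[:, None] * np.array(post_pleq)).sum(axis=0)
    lfsr = np.minimum(pgeq, pleq)
    return mean, sd, lfsr


def brute_force_es(metric, geneset):
    """Enumerate the weighted running sum position by position."""
    hits = [g in set(geneset) for g in metric.index]
    w = np.abs(metric.values)
    tot = w[hits].sum() if any(hits) else 1.0
    miss = 1.0 / (len(metric) - sum(hits))
    run, best = 0.0, 0.0
    for i, h in enumerate(hits):
        run += w[i] / tot if h else -miss
        if abs(run) > abs(best):
            best = run
    return best
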