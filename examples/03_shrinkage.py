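"""Empirical-Bayes multivariate shrinkage across conditions.

Simulates per-feature effects in 3 conditions from a 50% null / 50%
equal-effects mixture, fits the covariance-mixture model, and reports the
recovered mixture weights and the local false sign rate (LFSR) — the
posterior probability that an effect's sign is wrong.
"""

import numpy as np

import gliastate as gs

R = 3
mix = [(np.zeros((R, R)), 0.5), (np.ones((R, R)), 0.5)]
table, truth = gs.simulate_effect_table(R, 2000, mix, noise_se=1.0, seed=5)

fit = gs.fit_mixture(table, gs.canonical_covariances(R))
summary = gs.mixture_summary(fit, null_sd=0.3)
print("aggregated mixture weights (true: null 0.5, equal_effects 0.5):")
print(summary.head(4).round(3))

mean, sd, lfsr = gs.posterior_lfsr(table, fit)
true_null = truth["assignments"] == 0
strong = np.abs(truth["true_effects"]).min(axis=1) > 1.5
print(f"null features with LFSR < 0.05:   {(lfsr[true_null] < 0.05).mean():.3f}")
print(f"strong features with LFSR < 0.05: {(lfsr[strong] < 0.05).mean():.3f}")
# the null rate stays below 0.05 (sign-error control) while features with
# large shared effects are confidently signed

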