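"""Fit sn-spMF on simulated multi-tissue eQTL effects and score recovery.

Simulates 100 eQTLs over 10 tissues driven by 5 known factors (one
ubiquitous, four tissue-group-specific), fits the weighted semi-nonnegative
sparse factorization, and compares the learned factors to the truth after
the best column permutation.
"""

import numpy as np

from snspmf import align_and_score, fit_snspmf_restarts, rrmse, simulate_dataset

effects, truth = simulate_dataset(N=100, T=10, K=5, sigma2=0.001, seed=1)
model = fit_snspmf_restarts(effects, K=5, alpha=1.0, lam=1.0, seed=1, n_restarts=10)

score = align_and_score(model.F, model.L, truth)
err = rrmse(model.L @ model.F.T, effects.X)

print(f"learned factors: {model.n_factors} (requested {model.K_input})")
print(f"converged: {model.converged} after {model.n_iter} iterations")
print(f"final objective: {model.objective_trace[-1]:.3f}")
print(f"mean factor correlation vs truth:  {score.factor_corr:.3f}")
print(f"mean loading correlation vs truth: {score.loading_corr:.3f}")
print(f"reconstruction RRMSE: {err:.4f}")
print()
print("factor support (tissues with nonzero weight per factor):")
for k in range(model.n_factors):
    support = np.flatnonzero(model.F[:, k] > 0)
    print(f"  factor {k + 1}: tissues {[int(t) for t in support]}")
# A correlation near 1 for factors and loadings means the sparsity pattern
# and effect directions of the simulated eQTL sharing structure were
# recovered; RRMSE near 0 means X is reconstructed up to the noise floor.
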