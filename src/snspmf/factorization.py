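"""Weighted semi-nonnegative sparse matrix factorization (sn-spMF).

The model decomposes a D×T matrix X of multi-tissue eQTL effect sizes as
X ≈ L Fᵀ, with a nonnegative T×K tissue-factor matrix F and an unconstrained
D×K loading matrix L, by minimizing

    (1/(2D)) · ||(X − L Fᵀ) ⊙ W||²_F  +  α·||L||₁  +  λ·||F||₁ ,

where W holds the reciprocal standard errors of the effect estimates
(weight 0 marks an untested tissue, which then contributes nothing). The
objective is biconvex, and it is optimized by alternating least squares:
with F fixed, each row of L solves an independent weighted lasso; with L
fixed, each row of F solves a weighted nonnegative lasso. Each half-step is
solved by cyclic coordinate descent with exact soft-thresholding (clamped at
zero for F), so the objective is non-increasing at every half-step.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .datatypes import FactorModel, MultiTissueEffects

#: inner coordinate-descent tolerance on the largest coordinate change
INNER_TOL = 1e-10
#: cap on coordinate-descent sweeps per half-step; generous because cyclic
#: coordinate descent converges slowly on near-collinear designs
INNER_MAX_SWEEPS = 20000


def compute_objective(
    effects: MultiTissueEffects,
    F: np.ndarray,
    L: np.ndarray,
    alpha: float,
    lam: float,
) -> float:
    """Evaluate the penalized sn-spMF objective.

    Unobserved cells carry weight 0 and contribute nothing to the residual
    term. F need not be nonnegative here — the objective is evaluable at any
    point, e.g. mid-optimization.
    """
    F = np.asarray(F, dtype=float)
    L = np.asarray(L, dtype=float)
    X, W = effects.X, effects.W
    D, T = X.shape
    if F.shape[0] != T or L.shape[0] != D or F.shape[1] != L.shape[1]:
        raise ValueError(
            f"shape mismatch: X is {X.shape}, F is {F.shape}, L is {L.shape}"
        )
    R = (X - L @ F.T) * W
    return float(
        R.ravel() @ R.ravel() / (2.0 * D)
        + alpha * np.abs(L).sum()
        + lam * np.abs(F).sum()
    )


@njit(cache=True)
def _cd_kernel(X, W2, B, C, penalty, nonnegative, tol, max_sweeps):  # pragma: no cover
    """Cyclic coordinate descent for the weighted (nonnegative) lasso.

    Solves min_C (1/2)·||(X − C Bᵀ) ⊙ W||²_F + penalty·||C||₁ rowwise, with
    an optional elementwise C ≥ 0 clamp. C is updated in place.
    """
    D, T = X.shape
    K = B.shape[1]
    R = X - C @ B.T  # running residual
    # per-row curvature of each coordinate: A[d,k] = sum_t W2[d,t]·B[t,k]²
    A = W2 @ (B**2)
    for _ in range(max_sweeps):
        max_delta = 0.0
        for k in range(K):
            for d in range(D):
                a = A[d, k]
                if a <= 0.0:
                    new = 0.0  # no observed support for this coordinate
                else:
                    b = a * C[d, k]
                    for t in range(T):
                        b += W2[d, t] * R[d, t] * B[t, k]
                    if nonnegative:
                        new = (b - penalty) / a if b > penalty else 0.0
                    elif b > penalty:
                        new = (b - penalty) / a
                    elif b < -penalty:
                        new = (b + penalty) / a
                    else:
                        new = 0.0
                delta = C[d, k] - new
                if delta != 0.0:
                    for t in range(T):
                        R[d, t] += delta * B[t, k]
                    C[d, k] = new
                    if abs(delta) > max_delta:
                        max_delta = abs(delta)
        if max_delta < tol:
            break
    return C


def _cd_update(
    X: np.ndarray,
    W2: np.ndarray,
    B: np.ndarray,
    C_init: np.ndarray,
    penalty: float,
    nonnegative: bool,
) -> np.ndarray:
    """Exact soft-thresholding coordinate descent (see :func:`_cd_kernel`).

    Rows of C are independent weighted lasso problems sharing the design B;
    with ``nonnegative=True`` each coordinate solves the 1-D nonnegative
    lasso (soft-threshold clamped at zero). Rows with all-zero weights get
    all-zero solutions.
    """
    return _cd_kernel(
        np.ascontiguousarray(X, dtype=np.float64),
        np.ascontiguousarray(W2, dtype=np.float64),
        np.ascontiguousarray(B, dtype=np.float64),
        np.ascontiguousarray(C_init, dtype=np.float64).copy(),
        float(penalty),
        nonnegative,
        INNER_TOL,
        INNER_MAX_SWEEPS,
    )


def update_loadings(
    effects: MultiTissueEffects,
    F: np.ndarray,
    alpha: float,
    L_init: np.ndarray | None = None,
) -> np.ndarray:
    """ALS half-step: refit the loading matrix L with F held fixed.

    Each row d of L minimizes (1/(2D))·Σ_t W[d,t]²(X[d,t] − (F l)_t)² +
    α·||l||₁ over unconstrained l. Rows whose weights are all zero come back
    as all zeros.
    """
    F = np.asarray(F, dtype=float)
    X, W = effects.X, effects.W
    D = X.shape[0]
    K = F.shape[1]
    if L_init is None:
        L_init = np.zeros((D, K))
    # Scaling: the per-row objective times D turns (1/(2D))Σw²r² + α|l| into
    # (1/2)Σw²r² + (D·α)|l|, the form _cd_update solves.
    return _cd_update(X, W**2, F, np.asarray(L_init, dtype=float), D * alpha, False)


def update_factors(
    effects: MultiTissueEffects,
    L: np.ndarray,
    lam: float,
    F_init: np.ndarray | None = None,
) -> np.ndarray:
    """ALS half-step: refit the nonnegative factor matrix F with L fixed.

    Each row t of F minimizes the weighted residual of tissue column t plus
    λ·||f||₁ subject to f ≥ 0.
    """
    L = np.asarray(L, dtype=float)
    X, W = effects.X, effects.W
    D, T = X.shape
    K = L.shape[1]
    if F_init is None:
        F_init = np.zeros((T, K))
    return _cd_update(X.T, (W**2).T, L, np.asarray(F_init, dtype=float), D * lam, True)


def fit_snspmf(
    effects: MultiTissueEffects,
    K: int,
    alpha: float,
    lam: float,
    seed: int = 1,
    max_iter: int = 100,
    tol: float = 0.01,
) -> FactorModel:
    """Fit sn-spMF by alternating least squares.

    F is initialized with Uniform(0,1) entries from ``seed``; L is solved
    from the first half-step. Iterations stop when the Frobenius norm of the
    change in F drops below ``tol`` (default 0.01) or after ``max_iter``
    full iterations. Factors that end up all-zero (emptied by the sparsity
    penalty) are dropped from the returned model, together with their
    loading columns, so the returned rank K' may be below the requested K.

    The same seed always yields the bit-identical model.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    T = effects.n_tissues
    if K > T:
        import warnings

        warnings.warn(
            f"requested rank K={K} exceeds the number of tissues T={T}; "
            "sparsity may empty the surplus factors",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    F = rng.uniform(0.0, 1.0, size=(T, K))
    L = np.zeros((effects.n_eqtls, K))

    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        L = update_loadings(effects, F, alpha, L)
        F_new = update_factors(effects, L, lam, F)
        obj = compute_objective(effects, F_new, L, alpha, lam)
        if not np.isfinite(obj):
            raise FloatingPointError(
                f"non-finite objective at iteration {n_iter} "
                f"(K={K}, alpha={alpha}, lam={lam}, seed={seed})"
            )
        trace.append(obj)
        delta = float(np.linalg.norm(F_new - F))
        F = F_new
        if delta < tol:
            converged = True
            break

    keep = np.any(F != 0.0, axis=0)
    return FactorModel(
        F=F[:, keep],
        L=L[:, keep],
        K_input=K,
        alpha=alpha,
        lam=lam,
        objective_trace=trace,
        converged=converged,
        seed=seed,
        n_iter=n_iter,
    )


def fit_snspmf_restarts(
    effects: MultiTissueEffects,
    K: int,
    alpha: float,
    lam: float,
    seed: int = 1,
    n_restarts: int = 10,
    max_iter: int = 100,
    tol: float = 0.01,
) -> FactorModel:
    """Fit from several random initializations and keep the best objective.

    The objective is biconvex, so single runs can land in different local
    minima; for a point estimate (as opposed to the stability analysis,
    which wants the raw run-to-run variation) the standard remedy is a
    handful of restarts keeping the lowest final objective. Restart seeds
    are derived deterministically from ``seed``.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_restarts) % (2**31)
    best: FactorModel | None = None
    for s in seeds:
        model = fit_snspmf(
            effects, K, alpha, lam, seed=int(s), max_iter=max_iter, tol=tol
        )
        if best is None or model.objective_trace[-1] < best.objective_trace[-1]:
            best = model
    return best
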