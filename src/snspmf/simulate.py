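"""Synthetic multi-tissue eQTL generator and factorization scoring metrics.

The generator emulates the structure the factorization is built to recover:
N eQTLs over T tissues driven by K nonnegative tissue factors — one dense
(ubiquitous) factor supported on every tissue and K−1 sparse factors, each
supported on a small group of tissues. Loadings are sparse with non-zero
entries drawn standard normal (so they carry both signs), and observation
noise is i.i.d. Gaussian with variance σ². The standard-error matrix is the
constant √σ², giving the factorization weights W = 1/√σ².

Scoring aligns learned factor columns to the truth by exhaustive permutation
search (exact for the ranks used here) and reports mean column-wise Pearson
correlations plus precision/recall of u-/ts-eQTL label recovery.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .datatypes import MultiTissueEffects, SimulationTruth

#: per-(eQTL, factor) activation probability of the sparse loading pattern
LOADING_ACTIVATION_P = 0.3
#: non-zero factor entries are drawn Uniform on this interval
FACTOR_ENTRY_RANGE = (0.5, 1.5)


def simulate_dataset(
    N: int = 100,
    T: int = 10,
    K: int = 5,
    sigma2: float = 0.01,
    seed: int = 1,
    activation_p: float = LOADING_ACTIVATION_P,
    support_size: int | None = None,
) -> tuple[MultiTissueEffects, SimulationTruth]:
    """Simulate X = L·Fᵀ + E with one dense and K−1 sparse factors.

    Parameters
    ----------
    N, T, K
        Number of eQTLs, tissues, and factors. K must not exceed T.
    sigma2
        Variance of the i.i.d. Gaussian noise E.
    activation_p
        Probability that an eQTL loads on each factor (at least one factor
        is forced per eQTL so no row is empty).
    support_size
        Tissues per sparse factor; default ⌈T/(K−1)⌉, placed disjointly
        while tissues remain.
    """
    if K > T:
        raise ValueError(f"K={K} factors cannot exceed T={T} tissues")
    if K < 2:
        raise ValueError("need at least a dense and one sparse factor (K >= 2)")
    rng = np.random.default_rng(seed)

    if support_size is None:
        support_size = int(np.ceil(T / (K - 1)))
    lo, hi = FACTOR_ENTRY_RANGE
    F = np.zeros((T, K))
    F[:, 0] = rng.uniform(lo, hi, size=T)  # dense factor, full support
    unused = list(rng.permutation(T))
    for k in range(1, K):
        if len(unused) >= support_size:
            support = [unused.pop() for _ in range(support_size)]
        else:
            support = list(unused)
            unused = []
            extra = support_size - len(support)
            if extra > 0:
                pool = [t for t in range(T) if t not in support]
                support += list(rng.choice(pool, size=extra, replace=False))
        F[support, k] = rng.uniform(lo, hi, size=len(support))

    active = rng.random((N, K)) < activation_p
    empty = ~active.any(axis=1)
    if empty.any():
        forced = rng.integers(0, K, size=int(empty.sum()))
        active[np.flatnonzero(empty), forced] = True
    L = np.where(active, rng.standard_normal((N, K)), 0.0)

    E = rng.normal(0.0, np.sqrt(sigma2), size=(N, T)) if sigma2 > 0 else 0.0
    X = L @ F.T + E
    SE = np.full((N, T), max(np.sqrt(sigma2), 1e-6))
    effects = MultiTissueEffects(
        eqtl_ids=[f"gene{d}:var{d}" for d in range(N)],
        tissue_ids=[f"tissue{t}" for t in range(T)],
        X=X,
        SE=SE,
        observed=np.ones((N, T), dtype=bool),
    )
    truth = SimulationTruth(F_true=F, L_true=L, sigma2=sigma2, seed=seed, dense_index=0)
    return effects, truth


def rrmse(X_hat: np.ndarray, X: np.ndarray) -> float:
    """Relative root mean squared error √(Σ(X̂−X)² / ΣX²)."""
    X_hat = np.asarray(X_hat, dtype=float)
    X = np.asarray(X, dtype=float)
    if X_hat.shape != X.shape:
        raise ValueError(f"shape mismatch: {X_hat.shape} vs {X.shape}")
    denom = float(np.sum(X**2))
    if denom == 0.0:
        raise ValueError("RRMSE undefined for an all-zero reference matrix")
    return float(np.sqrt(np.sum((X_hat - X) ** 2) / denom))


def _column_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two columns; 0 when either has no variance."""
    if a.std() == 0.0 or b.std() == 0.0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _pad_columns(M: np.ndarray, K: int) -> np.ndarray:
    if M.shape[1] >= K:
        return M[:, :K]
    pad = np.zeros((M.shape[0], K - M.shape[1]))
    return np.hstack([M, pad])


@dataclass
class AlignmentScore:
    permutation: tuple[int, ...]
    factor_corr: float
    loading_corr: float
    per_factor_corr: np.ndarray
    u_precision: float = float("nan")
    u_recall: float = float("nan")
    ts_precision: float = float("nan")
    ts_recall: float = float("nan")


def align_factors(
    F_learned: np.ndarray, F_true: np.ndarray
) -> tuple[tuple[int, ...], np.ndarray]:
    """Best column permutation of the learned factors against the truth.

    Exhaustive search over permutations, maximizing the mean column-wise
    Pearson correlation; exact (it enumerates) for the K ≤ 8 used here.
    Learned matrices with fewer columns are padded with zeros. Returns the
    permutation p (true column k is matched by learned column p[k]) and the
    per-column correlations under it.
    """
    K = F_true.shape[1]
    Fl = _pad_columns(np.asarray(F_learned, dtype=float), K)
    if K > 8:
        raise ValueError("exhaustive permutation search is limited to K <= 8")
    corr = np.array(
        [
            [_column_corr(Fl[:, j], F_true[:, k]) for j in range(K)]
            for k in range(K)
        ]
    )
    best_perm, best_mean = None, -np.inf
    for perm in itertools.permutations(range(K)):
        mean = float(np.mean([corr[k, perm[k]] for k in range(K)]))
        if mean > best_mean:
            best_mean, best_perm = mean, perm
    return best_perm, np.array([corr[k, best_perm[k]] for k in range(K)])


def align_and_score(
    F_learned: np.ndarray,
    L_learned: np.ndarray,
    truth: SimulationTruth,
    learned_u: np.ndarray | None = None,
    learned_ts: np.ndarray | None = None,
    assignments=None,
) -> AlignmentScore:
    """Score a factorization against the simulation truth.

    Factors are aligned by the best permutation; the mean factor and loading
    correlations are reported under that single alignment. Learned u-/ts-
    labels can be supplied directly (boolean arrays over eQTLs), or derived
    here from fitted :class:`~snspmf.assignment.EqtlAssignment` objects: the
    learned factor matched to the true dense factor defines the u label,
    the factors matched to the sparse truth columns define the ts label.
    (Using the truth alignment sidesteps support-based ubiquitous-factor
    detection, which is brittle when an L1-thresholded entry lands exactly
    on zero.) Precision and recall against the truth labels are reported.
    """
    K = truth.F_true.shape[1]
    perm, per_factor = align_factors(F_learned, truth.F_true)
    if assignments is not None:
        K_learned = np.asarray(F_learned).shape[1]
        kept = np.array(
            [
                np.pad(a.kept, (0, K - a.n_factors))
                if a.kept is not None and a.n_factors < K
                else (a.kept if a.kept is not None else np.zeros(K, bool))
                for a in assignments
            ],
            dtype=bool,
        )
        u_col = perm[truth.dense_index]
        learned_u = kept[:, u_col] if u_col < K_learned else np.zeros(len(kept), bool)
        ts_cols = [
            perm[k] for k in range(K) if k != truth.dense_index and perm[k] < K_learned
        ]
        learned_ts = kept[:, ts_cols].any(axis=1) if ts_cols else np.zeros(len(kept), bool)
    Ll = _pad_columns(np.asarray(L_learned, dtype=float), K)
    loading_corr = float(
        np.mean(
            [_column_corr(Ll[:, perm[k]], truth.L_true[:, k]) for k in range(K)]
        )
    )
    score = AlignmentScore(
        permutation=perm,
        factor_corr=float(np.mean(per_factor)),
        loading_corr=loading_corr,
        per_factor_corr=per_factor,
    )
    if learned_u is not None:
        score.u_precision, score.u_recall = precision_recall(
            np.asarray(learned_u, bool), truth.u_labels
        )
    if learned_ts is not None:
        score.ts_precision, score.ts_recall = precision_recall(
            np.asarray(learned_ts, bool), truth.ts_labels
        )
    return score


def precision_recall(predicted: np.ndarray, actual: np.ndarray) -> tuple[float, float]:
    tp = int(np.sum(predicted & actual))
    precision = tp / predicted.sum() if predicted.any() else float("nan")
    recall = tp / actual.sum() if actual.any() else float("nan")
    return float(precision), float(recall)
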