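"""Hyper-parameter selection by factorization stability and factor independence.

Matrix factorization with random initialization is stochastic, so a good
hyper-parameter setting is one whose solutions are *stable*: across repeated
runs, the same pairs of tissues end up dominated by the same factor. The
consensus-clustering approach quantifies this with a tissue×tissue consensus
matrix C (fraction of runs co-assigning two tissues) and its cophenetic
correlation; a cophenetic correlation near 1 means the co-assignment pattern
is essentially hierarchical and reproducible. Among the stable settings, the
one whose factors are least correlated (most independent) is preferred.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from .datatypes import FactorModel, MultiTissueEffects
from .factorization import fit_snspmf

#: settings (or K' groups) whose cophenetic correlation falls below this are
#: considered unstable and eliminated
STABILITY_THRESHOLD = 0.9


def assign_tissues(F: np.ndarray) -> np.ndarray:
    """Assign each tissue to the factor holding its row maximum.

    Ties go to the lowest-index factor; a tissue whose row is all zero is
    unassigned (code −1) and is never co-assigned with anything.
    """
    F = np.asarray(F, dtype=float)
    if F.size == 0 or F.shape[1] == 0:
        return np.full(F.shape[0], -1)
    labels = np.argmax(F, axis=1)
    labels[np.all(F == 0.0, axis=1)] = -1
    return labels


def consensus_matrix(runs: list[FactorModel]) -> np.ndarray:
    """Fraction of runs in which each pair of tissues shares a factor."""
    if len(runs) < 2:
        raise ValueError("need at least two runs for a consensus matrix")
    T = runs[0].F.shape[0]
    if any(r.F.shape[0] != T for r in runs):
        raise ValueError("all runs must cover the same tissues")
    C = np.zeros((T, T))
    for run in runs:
        labels = assign_tissues(run.F)
        same = (labels[:, None] == labels[None, :]) & (labels[:, None] >= 0)
        C += same
    C /= len(runs)
    np.fill_diagonal(C, 1.0)
    return C


def cophenetic_correlation(C: np.ndarray) -> float:
    """Cophenetic correlation of the consensus matrix.

    Average-linkage hierarchical clustering is run on the dissimilarity
    1 − C; the returned value is the Pearson correlation between the
    original dissimilarities and the cophenetic (ultrametric) distances of
    the dendrogram. If all off-diagonal dissimilarities are equal the
    correlation is undefined, and the matrix is perfectly stable by
    construction: 1.0 is returned.
    """
    C = np.asarray(C, dtype=float)
    T = C.shape[0]
    if T < 3:
        raise ValueError("cophenetic correlation needs at least 3 tissues")
    dist = squareform(1.0 - C, checks=False)
    if np.allclose(dist, dist[0]):
        return 1.0
    Z = linkage(dist, method="average")
    coph_dist = cophenet(Z)
    r = np.corrcoef(dist, coph_dist)[0, 1]
    return float(r)


def factor_independence_score(runs: list[FactorModel]) -> float:
    """Mean (over runs) Frobenius norm of the off-diagonal factor correlations.

    For each run, the Pearson correlation is computed for every pair of
    distinct factor columns of F; the score is the Frobenius norm of the
    off-diagonal of that correlation matrix. Lower means more independent
    factors. Constant (zero-variance) columns correlate with nothing and
    contribute 0, with a warning.
    """
    scores = []
    for run in runs:
        F = run.F
        K = F.shape[1]
        if K < 2:
            raise ValueError("factor independence needs >= 2 non-empty factors")
        sd = F.std(axis=0)
        if np.any(sd == 0.0):
            warnings.warn(
                "constant factor column; its correlations are set to 0",
                stacklevel=2,
            )
        total = 0.0
        for i, j in itertools.combinations(range(K), 2):
            if sd[i] == 0.0 or sd[j] == 0.0:
                r = 0.0
            else:
                r = float(np.corrcoef(F[:, i], F[:, j])[0, 1])
            total += 2.0 * r * r  # (i,j) and (j,i) entries
        scores.append(np.sqrt(total))
    return float(np.mean(scores))


@dataclass
class GridReport:
    """Evaluation of one (K, alpha, lam) setting over repeated runs."""

    K: int
    alpha: float
    lam: float
    runs: list[FactorModel]
    consensus: np.ndarray
    cophenetic: float
    mean_nonempty_K: float
    factor_corr_score: float
    eliminated_at_stage: int = 0  # 0 = survived

    @classmethod
    def from_runs(
        cls, K: int, alpha: float, lam: float, runs: list[FactorModel]
    ) -> "GridReport":
        consensus = consensus_matrix(runs)
        # runs collapsed to <2 factors carry no pairwise correlation; a
        # setting where every run collapsed scores inf (never preferred)
        usable = [r for r in runs if r.n_factors >= 2]
        return cls(
            K=K,
            alpha=alpha,
            lam=lam,
            runs=runs,
            consensus=consensus,
            cophenetic=cophenetic_correlation(consensus),
            mean_nonempty_K=float(np.mean([r.n_factors for r in runs])),
            factor_corr_score=(
                factor_independence_score(usable) if usable else float("inf")
            ),
        )

    @property
    def K_prime(self) -> int:
        """Integer stability group: rounded mean non-empty factor count."""
        return int(round(self.mean_nonempty_K))


def evaluate_setting(
    effects: MultiTissueEffects,
    K: int,
    alpha: float,
    lam: float,
    n_runs: int = 30,
    seeds: list[int] | None = None,
    max_iter: int = 100,
    tol: float = 0.01,
) -> GridReport:
    """Fit ``n_runs`` randomly initialized models and summarize stability."""
    if seeds is None:
        seeds = list(range(1, n_runs + 1))
    runs = [
        fit_snspmf(effects, K, alpha, lam, seed=s, max_iter=max_iter, tol=tol)
        for s in seeds
    ]
    return GridReport.from_runs(K, alpha, lam, runs)


def select_model(grid: list[GridReport]) -> tuple[GridReport, list[GridReport]]:
    """Three-stage elimination over a hyper-parameter grid.

    1. Group settings by K' (rounded mean non-empty factor count) and drop
       every group whose *median* cophenetic correlation is below 0.9.
    2. Drop remaining individual settings with cophenetic correlation < 0.9.
    3. Among the survivors, pick the setting with the minimum factor
       correlation score (most independent factors); ties break toward
       smaller K', then larger alpha+lam (sparser solutions).

    Returns the chosen report and the full grid with
    ``eliminated_at_stage`` annotated (0 means the setting survived).
    """
    if not grid:
        raise ValueError("empty grid")
    for g in grid:
        g.eliminated_at_stage = 0

    groups: dict[int, list[GridReport]] = {}
    for g in grid:
        groups.setdefault(g.K_prime, []).append(g)
    for kp, members in groups.items():
        if np.median([g.cophenetic for g in members]) < STABILITY_THRESHOLD:
            for g in members:
                g.eliminated_at_stage = 1

    for g in grid:
        if g.eliminated_at_stage == 0 and g.cophenetic < STABILITY_THRESHOLD:
            g.eliminated_at_stage = 2

    survivors = [g for g in grid if g.eliminated_at_stage == 0]
    if not survivors:
        raise ValueError(
            "all hyper-parameter settings were eliminated as unstable; "
            "expand the grid (try other K or weaker penalties)"
        )
    chosen = min(
        survivors,
        key=lambda g: (g.factor_corr_score, g.K_prime, -(g.alpha + g.lam)),
    )
    return chosen, grid
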