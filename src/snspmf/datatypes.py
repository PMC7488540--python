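"""Domain containers for multi-tissue eQTL factorization.

The central object is :class:`MultiTissueEffects`: a D×T matrix of eQTL
effect sizes (regression slopes from per-tissue association tests) together
with their standard errors and the derived weight matrix W. Entries where a
variant–gene pair was never tested in a tissue are *unobserved* and carry
weight 0, so they contribute nothing to the factorization objective —
missingness is handled by weighting, not by imputation or row removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class MultiTissueEffects:
    """eQTL × tissue effect sizes with standard errors and weights.

    Parameters
    ----------
    eqtl_ids
        Row labels, conventionally ``"<gene>:<variant>"``; must be unique.
    tissue_ids
        Column labels (tissue names).
    X
        D×T effect sizes (slopes). Values in unobserved cells are ignored.
    SE
        D×T standard errors; must be positive and finite wherever observed.
    observed
        D×T boolean mask of tested (gene, variant, tissue) triples.

    The weight matrix ``W`` is derived: ``W = 1/SE`` where observed, 0
    elsewhere.
    """

    eqtl_ids: list[str]
    tissue_ids: list[str]
    X: np.ndarray
    SE: np.ndarray
    observed: np.ndarray
    W: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.SE = np.asarray(self.SE, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        D, T = len(self.eqtl_ids), len(self.tissue_ids)
        for name, arr in (("X", self.X), ("SE", self.SE), ("observed", self.observed)):
            if arr.shape != (D, T):
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected ({D}, {T}) "
                    "from the id lists"
                )
        if len(set(self.eqtl_ids)) != D:
            raise ValueError("eqtl_ids must be unique")
        obs = self.observed
        if not np.all(np.isfinite(self.X[obs])):
            raise ValueError("non-finite effect size on an observed entry")
        bad = obs & ~(np.isfinite(self.SE) & (self.SE > 0))
        if np.any(bad):
            d, t = np.argwhere(bad)[0]
            raise ValueError(
                f"non-positive or non-finite SE for eqtl "
                f"{self.eqtl_ids[d]!r} in tissue {self.tissue_ids[t]!r}"
            )
        W = np.zeros((D, T))
        W[obs] = 1.0 / self.SE[obs]
        self.W = W

    @property
    def n_eqtls(self) -> int:
        return len(self.eqtl_ids)

    @property
    def n_tissues(self) -> int:
        return len(self.tissue_ids)


@dataclass
class FactorModel:
    """Result of one sn-spMF fit.

    ``F`` is the T×K' nonnegative tissue-factor matrix, ``L`` the D×K' real
    loading matrix; K' ≤ K_input because all-zero factors are dropped at
    convergence. ``objective_trace`` holds the penalized objective after
    every full ALS iteration.
    """

    F: np.ndarray
    L: np.ndarray
    K_input: int
    alpha: float
    lam: float
    objective_trace: list[float]
    converged: bool
    seed: int
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        if self.F.ndim != 2 or self.L.ndim != 2:
            raise ValueError("F and L must be matrices")
        if self.F.shape[1] != self.L.shape[1]:
            raise ValueError("F and L must have aligned columns")
        if self.F.size and self.F.min() < 0:
            raise ValueError("F must be nonnegative")

    @property
    def n_factors(self) -> int:
        return self.F.shape[1]


@dataclass
class VariantRecord:
    """A candidate causal variant for one gene, with per-tissue statistics."""

    variant_id: str
    chrom: str
    pos: int  # 1-based
    gene_id: str
    maf: float
    tss_distance: int
    pvals: dict[str, float] = field(default_factory=dict)
    in_credible_set: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.maf <= 0.5:
            raise ValueError(f"maf must be in (0, 0.5], got {self.maf}")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        for t, p in self.pvals.items():
            if not 0 <= p <= 1:
                raise ValueError(f"p-value out of [0,1] for tissue {t!r}")

    @property
    def credible_tissues(self) -> set[str]:
        return {t for t, v in self.in_credible_set.items() if v}


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int  # 0-based, half-open
    end: int
    label: str = "."
    tissue: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )


@dataclass
class IntervalSet:
    """BED-style 0-based half-open intervals carrying a label and a tissue."""

    records: list[Interval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def sorted(self) -> "IntervalSet":
        return IntervalSet(sorted(self.records, key=lambda r: (r.chrom, r.start)))

    def subset(self, label: str | None = None, tissue: str | None = None) -> "IntervalSet":
        recs = [
            r
            for r in self.records
            if (label is None or r.label == label)
            and (tissue is None or r.tissue == tissue)
        ]
        return IntervalSet(recs)

    @property
    def labels(self) -> set[str]:
        return {r.label for r in self.records}

    @property
    def tissues(self) -> set[str]:
        return {r.tissue for r in self.records}


class LdTable:
    """Pairwise LD lookups, symmetric on query."""

    def __init__(self, pairs=()):
        self._r2: dict[tuple[str, str], float] = {}
        for a, b, r2 in pairs:
            self.add(a, b, r2)

    def add(self, a: str, b: str, r2: float) -> None:
        if not 0 <= r2 <= 1:
            raise ValueError(f"r2 must be in [0,1], got {r2}")
        self._r2[self._key(a, b)] = r2

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def r2(self, a: str, b: str) -> float | None:
        return self._r2.get(self._key(a, b))

    def pairs(self):
        for (a, b), r2 in self._r2.items():
            yield a, b, r2

    def __len__(self) -> int:
        return len(self._r2)


@dataclass
class SimulationTruth:
    """Ground truth of a simulated multi-tissue eQTL dataset."""

    F_true: np.ndarray  # T×K, nonnegative; column dense_index has full support
    L_true: np.ndarray  # D×K sparse real
    sigma2: float
    seed: int
    dense_index: int = 0

    @property
    def u_labels(self) -> np.ndarray:
        """True ubiquitous-eQTL indicator: nonzero loading on the dense factor."""
        return self.L_true[:, self.dense_index] != 0

    @property
    def ts_labels(self) -> np.ndarray:
        """True tissue-specific indicator: nonzero loading on any sparse factor."""
        sparse = np.ones(self.L_true.shape[1], dtype=bool)
        sparse[self.dense_index] = False
        return np.any(self.L_true[:, sparse] != 0, axis=1)
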