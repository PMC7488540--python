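"""Per-eQTL assignment to learned factors.

Once a tissue-factor matrix F is learned, every tested eQTL (not only the
lead variants used for learning) can be decomposed: its effect-size vector x
across tissues is regressed onto the factors by weighted least squares,
x ≈ F·l, with per-tissue weight (1/se_t)² in the normal equations so the
fitted criterion matches the factorization's weighted squared residual. A
standard t-test per coefficient, BH correction across the batch, and two
sign-consistency filters then decide which factors an eQTL truly loads on.
An eQTL loading on the ubiquitous (full-support) factor is a u-eQTL; one
loading on any other factor is a ts-eQTL for those factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats

from .datatypes import LdTable, MultiTissueEffects


class DropReason(str, Enum):
    NONE = "none"
    FDR = "fdr"
    SIGN_MISMATCH = "sign_mismatch"
    OPPOSITE_SMALL_Z = "opposite_small_z"
    COLLINEAR_NA = "collinear_na"
    UNTESTABLE = "untestable"


#: |Z| threshold of the opposite-sign filter; |Z| < 3 is equivalent to a
#: two-sided p-value > 0.00135
SMALL_Z = 3.0


@dataclass
class EqtlAssignment:
    """Fitted factor decomposition of one eQTL."""

    eqtl_id: str
    coef: np.ndarray
    coef_se: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    df: int
    q_value: np.ndarray | None = None
    kept: np.ndarray | None = None
    drop_reason: list[DropReason] = field(default_factory=list)
    u_eqtl: bool = False
    ts_factors: set[int] = field(default_factory=set)
    testable: bool = True

    @property
    def n_factors(self) -> int:
        return len(self.coef)


def prune_perfect_ld(
    eqtl_ids: list[str], ld: LdTable
) -> tuple[list[str], dict[str, list[str]]]:
    """Collapse eQTLs whose variants are in perfect LD (r² = 1), per gene.

    Within each gene, variants connected by r²=1 edges (transitively) form a
    group; the representative is the group's smallest variant id. Returns
    the representative eqtl ids and a map from representative to all member
    eqtl ids, used later to propagate q-values back.
    """
    by_gene: dict[str, list[tuple[str, str]]] = {}
    for eid in eqtl_ids:
        gene, _, variant = eid.partition(":")
        by_gene.setdefault(gene, []).append((variant, eid))

    representatives: list[str] = []
    groups: dict[str, list[str]] = {}
    for gene, members in by_gene.items():
        parent = {v: v for v, _ in members}

        def find(v: str) -> str:
            while parent[v] != v:
                parent[v] = parent[parent[v]]
                v = parent[v]
            return v

        variants = [v for v, _ in members]
        for i, a in enumerate(variants):
            for b in variants[i + 1 :]:
                if ld.r2(a, b) == 1.0:
                    ra, rb = find(a), find(b)
                    if ra != rb:
                        parent[max(ra, rb)] = min(ra, rb)
        clusters: dict[str, list[str]] = {}
        eid_of = dict(members)
        for v in variants:
            clusters.setdefault(find(v), []).append(v)
        for root, vs in clusters.items():
            rep_variant = min(vs)
            rep = eid_of[rep_variant]
            representatives.append(rep)
            groups[rep] = sorted(eid_of[v] for v in vs)
    return sorted(representatives), groups


def assign_factors(
    x: np.ndarray,
    se: np.ndarray,
    F: np.ndarray,
    observed: np.ndarray | None = None,
    eqtl_id: str = "",
) -> EqtlAssignment:
    """Weighted least squares of one eQTL's effects onto the factors.

    Solves (FᵀW²F)·l = FᵀW²x over the observed tissues, with W = diag(1/se).
    The coefficient covariance is σ̂²·(FᵀW²F)⁻¹ with σ̂² = weighted
    RSS/(T_obs − K), and each coefficient gets a two-sided t-test on
    T_obs − K degrees of freedom. Needs at least K+1 observed tissues;
    otherwise the eQTL is flagged untestable. If the design is collinear the
    dependent coefficients are reported NaN (reason ``collinear_na``) and
    the rest are fitted on the reduced design.
    """
    x = np.asarray(x, dtype=float)
    se = np.asarray(se, dtype=float)
    F = np.asarray(F, dtype=float)
    T, K = F.shape
    if observed is None:
        observed = np.isfinite(x) & np.isfinite(se) & (se > 0)
    obs = np.asarray(observed, dtype=bool)
    n_obs = int(obs.sum())

    nan = np.full(K, np.nan)
    if n_obs < K + 1:
        a = EqtlAssignment(eqtl_id, nan, nan.copy(), nan.copy(), nan.copy(), df=0)
        a.testable = False
        a.drop_reason = [DropReason.UNTESTABLE] * K
        return a

    w = 1.0 / se[obs]
    Fw = F[obs] * w[:, None]
    xw = x[obs] * w

    # Rank detection via pivoted QR on the weighted design
    keep = _independent_columns(Fw)
    dfree = n_obs - int(keep.sum())
    coef = nan.copy()
    cse = nan.copy()
    tstat = nan.copy()
    pval = nan.copy()
    reasons = [DropReason.COLLINEAR_NA] * K

    Fk = Fw[:, keep]
    G = Fk.T @ Fk
    beta = np.linalg.solve(G, Fk.T @ xw)
    resid = xw - Fk @ beta
    if dfree >= 1:
        sigma2 = float(resid @ resid) / dfree
        cov = sigma2 * np.linalg.inv(G)
        se_beta = np.sqrt(np.diag(cov))
        idx = np.flatnonzero(keep)
        coef[idx] = beta
        cse[idx] = se_beta
        with np.errstate(invalid="ignore", divide="ignore"):
            tstat[idx] = beta / se_beta
        pval[idx] = 2.0 * stats.t.sf(np.abs(tstat[idx]), dfree)
        for i in idx:
            reasons[i] = DropReason.NONE
    return EqtlAssignment(
        eqtl_id, coef, cse, tstat, pval, df=dfree, drop_reason=reasons
    )


def _independent_columns(A: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Greedy left-to-right selection of linearly independent columns."""
    K = A.shape[1]
    keep = np.zeros(K, dtype=bool)
    basis: list[np.ndarray] = []
    for k in range(K):
        col = A[:, k]
        resid = col.copy()
        for b in basis:
            resid = resid - (b @ resid) * b
        norm = np.linalg.norm(resid)
        if norm > rtol * max(1.0, np.linalg.norm(col)):
            keep[k] = True
            basis.append(resid / norm)
    return keep


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order preserved.

    NaNs pass through unchanged and do not count toward the number of
    tests m.
    """
    p = np.asarray(pvals, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pm = p[mask]
    m = pm.size
    if m == 0:
        return q
    order = np.argsort(pm, kind="stable")
    ranked = pm[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qm = np.empty(m)
    qm[order] = np.minimum(ranked, 1.0)
    q[mask] = qm
    return q


def apply_fdr(
    assignments: list[EqtlAssignment], fdr: float = 0.05
) -> list[EqtlAssignment]:
    """BH-correct all p-values in the batch (one family) and mark kept factors."""
    flat = np.concatenate(
        [a.p_value for a in assignments if a.testable]
        or [np.empty(0)]
    )
    qflat = bh_adjust(flat)
    pos = 0
    for a in assignments:
        if not a.testable:
            a.q_value = np.full(a.n_factors, np.nan)
            a.kept = np.zeros(a.n_factors, dtype=bool)
            continue
        K = a.n_factors
        a.q_value = qflat[pos : pos + K]
        pos += K
        a.kept = np.where(np.isnan(a.q_value), False, a.q_value < fdr)
        for k in range(K):
            if a.drop_reason[k] is DropReason.NONE and not a.kept[k]:
                a.drop_reason[k] = DropReason.FDR
    return assignments


def filter_discrepant_factors(
    assignment: EqtlAssignment,
    x: np.ndarray,
    se: np.ndarray,
    F: np.ndarray,
    observed: np.ndarray | None = None,
) -> EqtlAssignment:
    """Drop significant factors whose sign contradicts the observed effects.

    Collinearity between factors can hand a factor a coefficient whose sign
    disagrees with the eQTL's actual effects in that factor's tissues; such
    coefficients are artifacts and are dropped:

    (a) ``sign_mismatch`` — a kept factor k whose coefficient sign differs
        from the sign of the weighted mean of the observed effects over its
        support tissues (weights F[t,k]/se_t).
    (b) ``opposite_small_z`` — relative to the kept factor k* with the
        largest |t| (the eQTL's strongest effect), any kept factor of
        opposite coefficient sign is dropped when all of its observed
        support tissues have |Z| < 3: an apparent opposite effect made
        entirely of weak signals, more likely allelic heterogeneity or LD
        contamination than a true flip.
    """
    a = assignment
    if a.kept is None or not a.testable or not np.any(a.kept):
        return a
    x = np.asarray(x, dtype=float)
    se = np.asarray(se, dtype=float)
    F = np.asarray(F, dtype=float)
    if observed is None:
        observed = np.isfinite(x) & np.isfinite(se) & (se > 0)
    obs = np.asarray(observed, dtype=bool)
    z = np.zeros_like(x)
    z[obs] = x[obs] / se[obs]

    for k in np.flatnonzero(a.kept):
        support = (F[:, k] > 0) & obs
        if not support.any():
            continue
        wts = F[support, k] / se[support]
        wmean = float(wts @ x[support] / wts.sum())
        if np.sign(a.coef[k]) != np.sign(wmean) and wmean != 0.0:
            a.kept[k] = False
            a.drop_reason[k] = DropReason.SIGN_MISMATCH

    kept_idx = np.flatnonzero(a.kept)
    if kept_idx.size >= 2:
        k_star = kept_idx[np.argmax(np.abs(a.t_stat[kept_idx]))]
        for k in kept_idx:
            if k == k_star or np.sign(a.coef[k]) == np.sign(a.coef[k_star]):
                continue
            support = (F[:, k] > 0) & obs
            if support.any() and np.all(np.abs(z[support]) < SMALL_Z):
                a.kept[k] = False
                a.drop_reason[k] = DropReason.OPPOSITE_SMALL_Z
    return a


def find_ubiquitous_factor(F: np.ndarray) -> int | None:
    """Index of the factor with full tissue support (all entries > 0).

    If several qualify, the one with the smallest coefficient of variation
    across tissues (the flattest, most truly ubiquitous pattern) wins.
    Returns None when no factor covers every tissue.
    """
    F = np.asarray(F, dtype=float)
    full = np.flatnonzero(np.all(F > 0, axis=0))
    if full.size == 0:
        return None
    if full.size == 1:
        return int(full[0])
    cv = F[:, full].std(axis=0) / F[:, full].mean(axis=0)
    return int(full[np.argmin(cv)])


def classify_eqtls(
    assignments: list[EqtlAssignment], ubiquitous_factor: int | None
) -> list[EqtlAssignment]:
    """Label each eQTL as u-eQTL and/or ts-eQTL from its kept factors.

    A u-eQTL keeps the ubiquitous factor at q < FDR; its ts_factors are the
    kept non-ubiquitous factors. The two labels are not exclusive — an eQTL
    with a broad shared effect plus a stronger effect in one tissue carries
    both. With no full-support factor the u label is disabled.
    """
    if ubiquitous_factor is None:
        import warnings

        warnings.warn(
            "no factor has full tissue support; the u-eQTL label is disabled "
            "and every kept factor is reported as tissue-specific",
            stacklevel=2,
        )
    for a in assignments:
        if a.kept is None:
            raise ValueError("run apply_fdr before classify_eqtls")
        kept = set(np.flatnonzero(a.kept).tolist())
        a.u_eqtl = ubiquitous_factor in kept if ubiquitous_factor is not None else False
        a.ts_factors = kept - ({ubiquitous_factor} if ubiquitous_factor is not None else set())
    return assignments


def propagate_q_values(
    groups: dict[str, list[str]], assignments: list[EqtlAssignment]
) -> list[EqtlAssignment]:
    """Expand representative assignments back to full perfect-LD groups.

    Every non-representative member inherits its representative's q-values,
    flags, and labels; only the eqtl id differs.
    """
    by_id = {a.eqtl_id: a for a in assignments}
    out: list[EqtlAssignment] = []
    for rep, members in groups.items():
        a = by_id[rep]
        for member in members:
            if member == rep:
                out.append(a)
            else:
                out.append(
                    EqtlAssignment(
                        eqtl_id=member,
                        coef=a.coef.copy(),
                        coef_se=a.coef_se.copy(),
                        t_stat=a.t_stat.copy(),
                        p_value=a.p_value.copy(),
                        df=a.df,
                        q_value=None if a.q_value is None else a.q_value.copy(),
                        kept=None if a.kept is None else a.kept.copy(),
                        drop_reason=list(a.drop_reason),
                        u_eqtl=a.u_eqtl,
                        ts_factors=set(a.ts_factors),
                        testable=a.testable,
                    )
                )
    return out


def assign_all(
    effects: MultiTissueEffects,
    F: np.ndarray,
    ld: LdTable | None = None,
    fdr: float = 0.05,
) -> list[EqtlAssignment]:
    """Full assignment pipeline over a dataset.

    Perfect-LD pruning (if an LD table is given) → per-eQTL WLS → batch BH →
    discrepancy filters → u-/ts-classification → q-value propagation back to
    all LD-group members.
    """
    ids = effects.eqtl_ids
    if ld is not None:
        reps, groups = prune_perfect_ld(ids, ld)
    else:
        reps, groups = list(ids), {i: [i] for i in ids}
    index = {eid: i for i, eid in enumerate(ids)}

    assignments = []
    for rep in reps:
        d = index[rep]
        assignments.append(
            assign_factors(
                effects.X[d], effects.SE[d], F, effects.observed[d], eqtl_id=rep
            )
        )
    apply_fdr(assignments, fdr=fdr)
    for a in assignments:
        d = index[a.eqtl_id]
        filter_discrepant_factors(
            a, effects.X[d], effects.SE[d], F, effects.observed[d]
        )
    classify_eqtls(assignments, find_ubiquitous_factor(F))
    return propagate_q_values(groups, assignments)
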