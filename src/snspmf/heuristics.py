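"""Threshold-based baselines for calling u- and ts-eQTLs.

These are the standard single-tissue heuristics the factorization is
compared against. Both operate on per-tissue nominal p-values and
credible-set membership; neither involves any model fitting, so the labels
are deterministic functions of the input table.

The printed thresholds come from a 49-tissue study; they generalize to T
tissues as follows: the "quiet elsewhere" count 44 becomes T − 5, and for a
subset of N_k tissues the count becomes T − N_k − 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

from .datatypes import VariantRecord

#: an eQTL is "quiet" in a tissue when its nominal p-value exceeds this
QUIET_P = 0.001
#: "strong" in the focal tissue: p < 100 × the eGene's most extreme p there
STRONG_FOLD = 100.0
#: u-eQTL: credible-set membership in at least this many tissues (or subsets)
U_MIN_SUPPORT = 5


@dataclass
class HeuristicLabels:
    """Labels for one eQTL (variant–gene pair)."""

    gene_id: str
    variant_id: str
    u_eqtl: bool = False
    ts_tissues: set[str] = field(default_factory=set)  # heuristic 1
    ts_subsets: set[str] = field(default_factory=set)  # heuristic 2


def _egene_min_p(
    variants: list[VariantRecord],
) -> dict[tuple[str, str], float]:
    """Most extreme nominal p per (gene, tissue) over all candidate variants."""
    best: dict[tuple[str, str], float] = {}
    for v in variants:
        for tissue, p in v.pvals.items():
            key = (v.gene_id, tissue)
            if p < best.get(key, float("inf")):
                best[key] = p
    return best


def heuristic1_classify(
    variants: list[VariantRecord], n_tissues: int
) -> list[HeuristicLabels]:
    """Single-tissue thresholding baseline.

    ts-eQTL in tissue t requires all of:
      * p > 0.001 in at least (n_tissues − 5) *other* tested tissues —
        untested tissues count toward neither the tally nor its denominator;
      * p in t below 100× the eGene's most extreme p in t;
      * credible-set membership in t.
    u-eQTL: credible-set membership in at least 5 tissues. An eQTL can be ts
    in several tissues; the labels are not exclusive.
    """
    quiet_needed = n_tissues - U_MIN_SUPPORT
    egene_p = _egene_min_p(variants)
    out = []
    for v in variants:
        lab = HeuristicLabels(v.gene_id, v.variant_id)
        lab.u_eqtl = len(v.credible_tissues) >= U_MIN_SUPPORT
        for tissue, p in v.pvals.items():
            if not v.in_credible_set.get(tissue, False):
                continue
            best = egene_p.get((v.gene_id, tissue))
            if best is None or p >= STRONG_FOLD * best:
                continue
            others = [t for t in v.pvals if t != tissue]
            quiet = sum(v.pvals[t] > QUIET_P for t in others)
            # untested tissues count toward neither side, so the requirement
            # is capped at the number of tested other tissues
            if quiet >= min(quiet_needed, len(others)):
                lab.ts_tissues.add(tissue)
        out.append(lab)
    return out


def heuristic2_classify(
    variants: list[VariantRecord],
    subsets: dict[str, set[str]],
    n_tissues: int,
) -> list[HeuristicLabels]:
    """Grouped-tissue thresholding baseline.

    Tissues are manually grouped into disjoint subsets of similar biology
    (brain regions, digestive tissues, ...). For a subset S of N_k tissues:
      * quiet (p > 0.001) in at least (n_tissues − N_k − 5) tested tissues
        outside S;
      * strong (p < 100× the eGene's most extreme p in that tissue) in at
        least ⌈N_k/2⌉ tissues of S.
    u-eQTL: credible-set membership in tissues of at least 5 distinct
    subsets.
    """
    seen: dict[str, str] = {}
    for name, tissues in subsets.items():
        for t in tissues:
            if t in seen:
                raise ValueError(
                    f"tissue {t!r} appears in subsets {seen[t]!r} and "
                    f"{name!r}; subsets must be disjoint"
                )
            seen[t] = name

    egene_p = _egene_min_p(variants)
    out = []
    for v in variants:
        lab = HeuristicLabels(v.gene_id, v.variant_id)
        supported = {
            seen[t]
            for t in v.credible_tissues
            if t in seen
        }
        lab.u_eqtl = len(supported) >= U_MIN_SUPPORT
        for name, tissues in subsets.items():
            n_k = len(tissues)
            strong = 0
            for t in tissues:
                p = v.pvals.get(t)
                best = egene_p.get((v.gene_id, t))
                if p is not None and best is not None and p < STRONG_FOLD * best:
                    strong += 1
            if strong < ceil(n_k / 2):
                continue
            outside = [t for t in v.pvals if t not in tissues]
            quiet = sum(v.pvals[t] > QUIET_P for t in outside)
            needed = min(n_tissues - n_k - U_MIN_SUPPORT, len(outside))
            if quiet >= needed:
                lab.ts_subsets.add(name)
        out.append(lab)
    return out
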