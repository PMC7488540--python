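"""Downstream interpretation statistics for u-/ts-eQTL sets.

Given factor-assigned eQTL variants, these routines ask where those
variants sit in the genome: whether they fall in particular chromatin
states, in transcription-factor binding sites, or show allele-specific
ChIP-seq read imbalance. Enrichment is always measured against background
variants matched on minor-allele frequency, signed TSS distance, and
variants-per-gene — the three axes that otherwise confound genomic
annotation overlap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .assignment import bh_adjust
from .datatypes import IntervalSet, VariantRecord

#: half-width of the window centered on each SNP (total width 5 bp)
WINDOW_BP = 5


@dataclass
class EnrichmentTable:
    """A 2×2 contingency table with its test results.

    Row 1 is the focal set (a, in annotation; b, outside), row 2 the
    background (c, d). The odds ratio is (a·d)/(b·c), with the Haldane 0.5
    correction applied to every cell when any cell is zero; the p-value is
    always from the uncorrected exact test.
    """

    a: int
    b: int
    c: int
    d: int
    factor: str = ""
    annotation: str = ""
    tissue: str = ""
    unit: str = "variant"
    p_value: float = field(init=False)
    odds_ratio: float = field(init=False)
    q_value: float = float("nan")

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be nonnegative")
        self.odds_ratio, self.p_value = fisher_exact(
            [[self.a, self.b], [self.c, self.d]], alternative="greater"
        )

    def log_or_and_se(self) -> tuple[float, float]:
        """log-OR and its Woolf SE, Haldane-corrected on zero cells."""
        cells = np.array([self.a, self.b, self.c, self.d], dtype=float)
        if np.any(cells == 0):
            cells = cells + 0.5
        a, b, c, d = cells
        return math.log(a * d / (b * c)), math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)


def fisher_exact(table, alternative: str = "greater") -> tuple[float, float]:
    """Fisher's exact test with the ad/bc odds ratio.

    The p-value comes from exact hypergeometric enumeration over all tables
    with the observed margins (scipy). The returned odds ratio is the sample
    estimate (a·d)/(b·c), Haldane-corrected (0.5 to every cell) when any
    cell is zero. A zero margin makes the table degenerate: p = 1 and the
    OR is NaN.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("contingency cells must be nonnegative")
    if alternative not in ("greater", "two_sided", "two-sided"):
        raise ValueError(f"unsupported alternative {alternative!r}")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return float("nan"), 1.0
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells == 0):
        cells = cells + 0.5
    odds = float(cells[0] * cells[3] / (cells[1] * cells[2]))
    alt = "greater" if alternative == "greater" else "two-sided"
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative=alt).pvalue)
    return odds, p


def _interval_trees(intervals: IntervalSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in intervals:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r)
    return trees


def window_overlap(
    variants: list[VariantRecord],
    intervals: IntervalSet,
    window_bp: int = WINDOW_BP,
    tissue: str | None = None,
) -> np.ndarray:
    """Flag variants whose centered window touches any interval.

    A window of ``window_bp`` (odd) is centered on the 1-based variant
    position: for the default 5 bp this is positions pos−2 .. pos+2
    inclusive, i.e. the 0-based half-open range [pos−3, pos+2). Overlap is
    tested against the BED intervals, optionally restricted to one tissue.
    """
    if window_bp % 2 == 0:
        raise ValueError("window_bp must be odd (the window is centered)")
    half = window_bp // 2
    if tissue is not None:
        intervals = intervals.subset(tissue=tissue)
    trees = _interval_trees(intervals)
    flags = np.zeros(len(variants), dtype=bool)
    for i, v in enumerate(variants):
        tree = trees.get(v.chrom)
        if tree is None:
            continue
        start0 = v.pos - half - 1  # 1-based closed -> 0-based half-open
        end0 = v.pos + half
        flags[i] = bool(tree.overlap(max(start0, 0), end0))
    return flags


def _maf_bin(maf: float) -> int:
    """MAF bins of width 0.05 over (0, 0.5]."""
    return min(int(maf / 0.05), 9)


def _tss_bin(tss: int) -> tuple[int, int]:
    """Signed log10-decade bins of |TSS distance|."""
    sign = 0 if tss == 0 else (1 if tss > 0 else -1)
    mag = 0 if tss == 0 else int(math.log10(abs(tss)))
    return sign, mag


def _snps_per_gene_bin(n: int) -> int:
    """Exact up to 10, then 11–20, 21–50, >50."""
    if n <= 10:
        return n
    if n <= 20:
        return 11
    if n <= 50:
        return 12
    return 13


def _stratum(v: VariantRecord, gene_counts: dict[str, int]) -> tuple:
    return (
        _maf_bin(v.maf),
        _tss_bin(v.tss_distance),
        _snps_per_gene_bin(gene_counts.get(v.gene_id, 1)),
    )


def sample_matched_background(
    focal: list[VariantRecord],
    pool: list[VariantRecord],
    n_per: int = 1,
    seed: int = 1,
) -> tuple[list[VariantRecord], int]:
    """Sample background variants matched to the focal set.

    Sampling is stratified without replacement on (i) MAF bin (width 0.05),
    (ii) signed log10-decade TSS-distance bin, and (iii) variants-per-gene
    bin. When a stratum runs dry the requirement is relaxed one matching
    criterion at a time (gene-count bin first, then TSS bin, then MAF bin);
    the number of relaxed draws is returned alongside the sample.
    """
    rng = np.random.default_rng(seed)
    focal_ids = {(v.gene_id, v.variant_id) for v in focal}
    pool = [v for v in pool if (v.gene_id, v.variant_id) not in focal_ids]

    focal_counts: dict[str, int] = {}
    for v in focal:
        focal_counts[v.gene_id] = focal_counts.get(v.gene_id, 0) + 1
    pool_counts: dict[str, int] = {}
    for v in pool:
        pool_counts[v.gene_id] = pool_counts.get(v.gene_id, 0) + 1

    available: dict[tuple, list[int]] = {}
    strata = [_stratum(v, pool_counts) for v in pool]
    for i, s in enumerate(strata):
        available.setdefault(s, []).append(i)
    taken = np.zeros(len(pool), dtype=bool)

    def draw(indices: list[int]) -> int | None:
        free = [i for i in indices if not taken[i]]
        if not free:
            return None
        i = free[int(rng.integers(0, len(free)))]
        taken[i] = True
        return i

    sample: list[VariantRecord] = []
    relaxations = 0
    for v in focal:
        target = _stratum(v, focal_counts)
        for _ in range(n_per):
            i = draw(available.get(target, []))
            if i is None:
                # progressively drop matching criteria
                for match in (
                    lambda s: s[:2] == target[:2],  # drop gene-count bin
                    lambda s: s[0] == target[0],  # drop TSS bin too
                    lambda s: True,  # any variant at all
                ):
                    candidates = [
                        j
                        for stratum, idxs in available.items()
                        if match(stratum)
                        for j in idxs
                    ]
                    i = draw(candidates)
                    if i is not None:
                        relaxations += 1
                        break
            if i is None:
                warnings.warn("background pool exhausted", stacklevel=2)
                break
            sample.append(pool[i])
    return sample, relaxations


def chromatin_state_enrichment(
    focal: list[VariantRecord],
    background: list[VariantRecord],
    states: IntervalSet,
    tissues: list[str] | None = None,
    factor: str = "",
    window_bp: int = WINDOW_BP,
) -> list[EnrichmentTable]:
    """Per (state, tissue) 2×2 enrichment of focal vs background variants.

    Membership uses the 5-bp window overlap; the test is one-sided Fisher
    (enrichment), and BH correction runs across all tables produced by the
    call (one family per run).
    """
    if tissues is None:
        tissues = sorted(states.tissues)
    tables: list[EnrichmentTable] = []
    for tissue in tissues:
        tissue_states = states.subset(tissue=tissue)
        if len(tissue_states) == 0:
            warnings.warn(
                f"tissue {tissue!r} absent from the annotation; skipped",
                stacklevel=2,
            )
            continue
        for state in sorted(tissue_states.labels):
            sub = tissue_states.subset(label=state)
            fin = window_overlap(focal, sub, window_bp)
            bin_ = window_overlap(background, sub, window_bp)
            tables.append(
                EnrichmentTable(
                    a=int(fin.sum()),
                    b=int(len(focal) - fin.sum()),
                    c=int(bin_.sum()),
                    d=int(len(background) - bin_.sum()),
                    factor=factor,
                    annotation=state,
                    tissue=tissue,
                    unit="variant",
                )
            )
    _attach_q_values(tables)
    return tables


def tfbs_enrichment(
    focal: list[VariantRecord],
    background: list[VariantRecord],
    tfbs: IntervalSet,
    factor: str = "",
    min_genes: int = 10,
    window_bp: int = WINDOW_BP,
) -> list[EnrichmentTable]:
    """Gene-level TFBS enrichment, one table per TF.

    The unit is the gene: a gene qualifies for a TF when at least one of its
    variants overlaps that TF's binding sites (the caller is expected to
    have intersected TFBS with tissue-matched regulatory regions already).
    Only genes with at least one variant in *any* TFBS enter the analysis,
    and TFs touching fewer than ``min_genes`` such genes are excluded.
    """
    tfs = sorted(tfbs.labels)
    any_hit_focal = window_overlap(focal, tfbs, window_bp)
    any_hit_bg = window_overlap(background, tfbs, window_bp)
    focal_genes = {v.gene_id for v, h in zip(focal, any_hit_focal) if h}
    bg_genes = {v.gene_id for v, h in zip(background, any_hit_bg) if h}

    tables: list[EnrichmentTable] = []
    for tf in tfs:
        sub = tfbs.subset(label=tf)
        fhit = window_overlap(focal, sub, window_bp)
        bhit = window_overlap(background, sub, window_bp)
        f_qual = {v.gene_id for v, h in zip(focal, fhit) if h}
        b_qual = {v.gene_id for v, h in zip(background, bhit) if h}
        if len(f_qual | b_qual) < min_genes:
            continue
        a = len(f_qual)
        b = len(focal_genes - f_qual)
        c = len(b_qual)
        d = len(bg_genes - b_qual)
        tables.append(
            EnrichmentTable(
                a=a, b=b, c=c, d=d, factor=factor, annotation=tf, unit="gene"
            )
        )
    _attach_q_values(tables)
    return tables


def _attach_q_values(tables: list[EnrichmentTable]) -> None:
    if tables:
        q = bh_adjust([t.p_value for t in tables])
        for t, qv in zip(tables, q):
            t.q_value = float(qv)


def filter_expressed_tfs(
    tf_tpm: dict[str, dict[str, float]],
    factor_tissues: list[str],
) -> list[str]:
    """TFs with median TPM > 1 in at least half of the factor's tissues.

    ``tf_tpm`` maps TF → tissue → median TPM; tissues without data for a TF
    are dropped from that TF's denominator. A TF with no data in any factor
    tissue is ineligible.
    """
    eligible = []
    for tf, tpm in sorted(tf_tpm.items()):
        avail = [t for t in factor_tissues if t in tpm]
        if not avail:
            warnings.warn(f"TF {tf!r} has no expression data; ineligible", stacklevel=2)
            continue
        n_expr = sum(tpm[t] > 1.0 for t in avail)
        if n_expr >= math.ceil(len(avail) / 2):
            eligible.append(tf)
    return eligible


def random_effects_combine(
    log_ors, ses
) -> tuple[float, float, float]:
    """DerSimonian–Laird random-effects combination of log odds ratios.

    Returns (combined log-OR, combined SE, τ²). With a single study the
    inputs pass through with τ² = 0; with homogeneous studies (Q ≤ df) the
    estimate reduces to inverse-variance fixed effects.
    """
    y = np.asarray(log_ors, dtype=float)
    se = np.asarray(ses, dtype=float)
    if y.size == 0:
        raise ValueError("need at least one study")
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    if y.size == 1:
        return float(y[0]), float(se[0]), 0.0
    w = 1.0 / se**2
    y_fe = float(w @ y / w.sum())
    Q = float(w @ (y - y_fe) ** 2)
    df = y.size - 1
    c = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (Q - df) / c)
    w_star = 1.0 / (se**2 + tau2)
    combined = float(w_star @ y / w_star.sum())
    combined_se = float(1.0 / math.sqrt(w_star.sum()))
    return combined, combined_se, tau2


@dataclass
class AsbSite:
    """Allele-specific binding test for one variant."""

    variant_id: str
    ref_reads: int
    alt_reads: int
    p_value: float = field(init=False)
    tested: bool = field(init=False)
    q_value: float = float("nan")
    significant: bool = False

    def __post_init__(self) -> None:
        self.p_value, self.tested = asb_binomial_test(self.ref_reads, self.alt_reads)


def asb_binomial_test(ref_reads: int, alt_reads: int) -> tuple[float, bool]:
    """Two-tailed exact binomial test of allelic read balance.

    A site is tested only with more than 10 reads total (strict). The null
    is Binomial(n, 0.5); the two-tailed p sums the probabilities of all
    outcomes no more likely than the observed one. Untested sites report
    p = NaN.
    """
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError("read counts must be nonnegative")
    n = ref_reads + alt_reads
    if n <= 10:
        return float("nan"), False
    p = float(stats.binomtest(ref_reads, n, 0.5, alternative="two-sided").pvalue)
    return p, True


def call_asb_sites(
    counts: list[tuple[str, int, int]], fdr: float = 0.05
) -> list[AsbSite]:
    """Run the ASB test over a batch and BH-correct across tested sites."""
    sites = [AsbSite(v, r, a) for v, r, a in counts]
    pvals = [s.p_value if s.tested else float("nan") for s in sites]
    qvals = bh_adjust(pvals)
    for s, q in zip(sites, qvals):
        s.q_value = float(q)
        s.significant = bool(s.tested and q < fdr)
    return sites
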