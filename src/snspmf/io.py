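"""Readers and writers for the tabular formats used throughout.

All tables are plain TSV with headers. Matrices round-trip bit-identically:
the writer emits 17 significant digits (enough to reconstruct any float64
exactly). Genomic intervals use the BED convention (0-based, half-open);
variants are stored 1-based, and the conversion happens only at the interval
boundary (see :mod:`snspmf.enrichment`).
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import Interval, IntervalSet, LdTable, MultiTissueEffects, VariantRecord

SUMMARY_COLUMNS = ["gene_id", "variant_id", "slope", "slope_se", "pval_nominal"]

#: p-values of exactly zero are floored here before taking logs
P_FLOOR = 1e-300


def load_summary_stats(
    paths: dict[str, str | Path] | list[str | Path],
    tissue_ids: list[str] | None = None,
) -> MultiTissueEffects:
    """Assemble the factorization input from per-tissue summary statistics.

    Each file must carry at least the columns ``gene_id, variant_id, slope,
    slope_se, pval_nominal`` (extras ignored). Rows are the union of
    gene:variant keys over all tissues; a key absent from a tissue's file is
    unobserved there and gets weight 0.
    """
    if isinstance(paths, dict):
        items = list(paths.items())
    else:
        if tissue_ids is None or len(tissue_ids) != len(paths):
            raise ValueError("tissue_ids must be given, one per path")
        items = list(zip(tissue_ids, paths))

    frames = {}
    for tissue, path in items:
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in SUMMARY_COLUMNS[:4] if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        key = df["gene_id"].astype(str) + ":" + df["variant_id"].astype(str)
        dup = key[key.duplicated()]
        if len(dup):
            raise ValueError(
                f"{path}: duplicate (gene, variant) row for {dup.iloc[0]!r} "
                f"in tissue {tissue!r}"
            )
        se = df["slope_se"].to_numpy(dtype=float)
        bad = ~(np.isfinite(se) & (se > 0))
        if bad.any():
            i = int(np.argmax(bad))
            raise ValueError(
                f"{path}: non-positive or non-finite slope_se for "
                f"{key.iloc[i]!r} in tissue {tissue!r}"
            )
        frames[tissue] = pd.DataFrame(
            {"slope": df["slope"].to_numpy(dtype=float), "se": se},
            index=key,
        )

    tissues = [t for t, _ in items]
    all_keys = sorted(set().union(*[set(f.index) for f in frames.values()]))
    D, T = len(all_keys), len(tissues)
    X = np.zeros((D, T))
    SE = np.ones((D, T))
    observed = np.zeros((D, T), dtype=bool)
    for j, tissue in enumerate(tissues):
        f = frames[tissue].reindex(all_keys)
        obs = f["slope"].notna().to_numpy()
        observed[:, j] = obs
        X[obs, j] = f["slope"].to_numpy()[obs]
        SE[obs, j] = f["se"].to_numpy()[obs]
    return MultiTissueEffects(all_keys, tissues, X, SE, observed)


def select_lead_variants(variants: list[VariantRecord]) -> list[str]:
    """Pick one lead variant per gene by most extreme geometric-mean p-value.

    Candidates must sit in a 95% credible set for at least one tissue; genes
    without any credible-set candidate are skipped with a warning. The
    geometric mean runs over the tissues where the variant was actually
    tested (untested is not evidence), and exact ties break toward the
    lexicographically smallest variant id so the choice is deterministic.

    Returns ``"<gene>:<variant>"`` keys, one per eligible gene, in sorted
    gene order.
    """
    by_gene: dict[str, list[VariantRecord]] = {}
    for v in variants:
        by_gene.setdefault(v.gene_id, []).append(v)

    leads = []
    for gene in sorted(by_gene):
        candidates = [v for v in by_gene[gene] if v.credible_tissues]
        if not candidates:
            warnings.warn(
                f"gene {gene!r} has no credible-set variant; excluded",
                stacklevel=2,
            )
            continue
        best = min(
            candidates,
            key=lambda v: (_log_geometric_mean_p(v), v.variant_id),
        )
        leads.append(f"{gene}:{best.variant_id}")
    return leads


def _log_geometric_mean_p(v: VariantRecord) -> float:
    if not v.pvals:
        return 0.0  # geometric mean of an empty set: treat as p=1
    logs = [math.log(max(p, P_FLOOR)) for p in v.pvals.values()]
    return sum(logs) / len(logs)


def read_bed(path: str | Path) -> IntervalSet:
    """Read BED3+2 (label in column 4, tissue in column 5; both optional)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED line ({line!r})")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            label = fields[3] if len(fields) > 3 else "."
            tissue = fields[4] if len(fields) > 4 else "."
            records.append(Interval(chrom, start, end, label, tissue))
    return IntervalSet(records)


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in intervals:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\t{r.tissue}\n")


def write_matrix(
    values: np.ndarray,
    path: str | Path,
    row_ids: list[str],
    col_ids: list[str],
    index_name: str = "eqtl_id",
) -> None:
    """Write a labeled matrix as TSV at full float64 precision."""
    df = pd.DataFrame(np.asarray(values), index=row_ids, columns=col_ids)
    df.index.name = index_name
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a matrix written by :func:`write_matrix`; bit-exact round trip."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return df.to_numpy(dtype=float), [str(i) for i in df.index], list(df.columns)


def write_effects(effects: MultiTissueEffects, x_path, se_path) -> None:
    """Write X and SE tables; unobserved cells are emitted as NA."""
    X = effects.X.copy()
    SE = effects.SE.copy()
    X[~effects.observed] = np.nan
    SE[~effects.observed] = np.nan
    for arr, path in ((X, x_path), (SE, se_path)):
        df = pd.DataFrame(arr, index=effects.eqtl_ids, columns=effects.tissue_ids)
        df.index.name = "eqtl_id"
        df.to_csv(path, sep="\t", float_format="%.17g")


def read_effects(x_path, se_path) -> MultiTissueEffects:
    xdf = pd.read_csv(x_path, sep="\t", index_col=0, float_precision="round_trip")
    sedf = pd.read_csv(se_path, sep="\t", index_col=0, float_precision="round_trip")
    if list(xdf.index) != list(sedf.index) or list(xdf.columns) != list(sedf.columns):
        raise ValueError("X and SE tables must share row and column labels")
    X = xdf.to_numpy(dtype=float)
    SE = sedf.to_numpy(dtype=float)
    observed = np.isfinite(X) & np.isfinite(SE)
    X = np.where(observed, X, 0.0)
    SE = np.where(observed, SE, 1.0)
    return MultiTissueEffects(
        [str(i) for i in xdf.index], list(xdf.columns), X, SE, observed
    )


def read_ld_table(path: str | Path) -> LdTable:
    """Read an LD table TSV with columns variant_a, variant_b, r2."""
    df = pd.read_csv(path, sep="\t")
    for col in ("variant_a", "variant_b", "r2"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    table = LdTable()
    for a, b, r2 in zip(df["variant_a"], df["variant_b"], df["r2"]):
        table.add(str(a), str(b), float(r2))
    return table


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a long-format variant table.

    Columns: variant_id, chrom, pos, gene_id, maf, tss_distance, tissue,
    pval_nominal, in_credible_set. One row per (variant, gene, tissue).
    """
    df = pd.read_csv(path, sep="\t")
    records: dict[tuple[str, str], VariantRecord] = {}
    for row in df.itertuples(index=False):
        key = (str(row.gene_id), str(row.variant_id))
        rec = records.get(key)
        if rec is None:
            rec = VariantRecord(
                variant_id=str(row.variant_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                gene_id=str(row.gene_id),
                maf=float(row.maf),
                tss_distance=int(row.tss_distance),
            )
            records[key] = rec
        tissue = str(row.tissue)
        if not math.isnan(row.pval_nominal):
            rec.pvals[tissue] = float(row.pval_nominal)
        rec.in_credible_set[tissue] = bool(row.in_credible_set)
    return list(records.values())
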