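"""Mutation-table IO, post-calling filters, mappability and sliding bins.

Coordinates follow the VCF convention for mutations (1-based positions) and
the BED convention for every interval type (0-based, half-open).
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
import pysam

log = logging.getLogger(__name__)

#: metric columns a fully annotated call table carries
METRIC_COLUMNS = [
    "VariantAlleleCount", "VariantAlleleCountControl", "VariantMapQualMedian",
    "MapQualDiffMedian", "LowMapQual", "VariantBaseQualMedian",
    "VariantStrandBias", "ReferenceStrandBias",
    "DistanceToAlignmentEndMedian", "DistanceToAlignmentEndMAD",
]

CORE_COLUMNS = ["chrom", "pos", "ref", "alt", "vaf", "alt_count", "depth", "sample_id"]


def _check_calls(df: pd.DataFrame) -> None:
    if (df.ref == df.alt).any():
        bad = df.index[df.ref == df.alt][0]
        raise ValueError(f"record {bad}: ref equals alt")
    if ((df.vaf < 0) | (df.vaf > 1)).any():
        raise ValueError("vaf outside [0, 1]")
    if (df.alt_count > df.depth).any():
        raise ValueError("alt_count exceeds depth")


# ---------------------------------------------------------------------------
# readers / writers

def read_mutations(path, fmt: str = "auto") -> pd.DataFrame:
    """Read a mutation table from VCF v4.2 or the documented TSV layout."""
    p = str(path)
    if fmt == "auto":
        fmt = "vcf" if p.endswith((".vcf", ".vcf.gz")) else "tsv"
    if fmt == "tsv":
        df = pd.read_csv(p, sep="\t", dtype={"chrom": str})
    elif fmt == "vcf":
        rows = []
        with pysam.VariantFile(p) as vf:
            for rec in vf:
                info = dict(rec.info)
                rows.append({
                    "chrom": rec.chrom, "pos": rec.pos,
                    "ref": rec.ref, "alt": rec.alts[0],
                    "vaf": float(info.get("VAF", np.nan)),
                    "alt_count": int(info.get("AC_ALT", 0)),
                    "depth": int(info.get("DP", 0)),
                    "sample_id": info.get("SAMPLE", "NA"),
                    **{k: info[k] for k in METRIC_COLUMNS if k in info},
                    **{k: info[k] for k in ("ORIGIN", "HOMOLOG", "GEN") if k in info},
                })
        df = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    missing = [c for c in ("chrom", "pos", "ref", "alt") if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table lacks columns {missing}")
    _check_calls(df) if {"vaf", "alt_count", "depth"} <= set(df.columns) else None
    return df


def write_mutations(df: pd.DataFrame, path, fmt: str = "auto") -> None:
    """Write a mutation table as TSV or VCF v4.2 (INFO keys VAF/AC_ALT/DP/...)."""
    p = str(path)
    if fmt == "auto":
        fmt = "vcf" if p.endswith(".vcf") else "tsv"
    if fmt == "tsv":
        df.to_csv(p, sep="\t", index=False)
        return
    if fmt != "vcf":
        raise ValueError(f"unknown format {fmt!r}")
    header = pysam.VariantHeader()
    for chrom in pd.unique(df.chrom):
        sub = df[df.chrom == chrom]
        header.contigs.add(str(chrom), length=int(sub.pos.max()) + 1000)
    for key, typ in [("VAF", "Float"), ("AC_ALT", "Integer"), ("DP", "Integer"),
                     ("SAMPLE", "String"), ("ORIGIN", "String"),
                     ("HOMOLOG", "Integer"), ("GEN", "Integer")]:
        header.info.add(key, 1, typ, key)
    for key in METRIC_COLUMNS:
        header.info.add(key, 1, "Float", key)
    with pysam.VariantFile(p, "w", header=header) as vf:
        for row in df.itertuples(index=False):
            rec = vf.new_record(contig=str(row.chrom), start=int(row.pos) - 1,
                                alleles=(row.ref, row.alt))
            rec.info["VAF"] = float(row.vaf)
            rec.info["AC_ALT"] = int(row.alt_count)
            rec.info["DP"] = int(row.depth)
            rec.info["SAMPLE"] = str(getattr(row, "sample_id", "NA"))
            if hasattr(row, "origin"):
                rec.info["ORIGIN"] = str(row.origin)
            if hasattr(row, "homolog"):
                rec.info["HOMOLOG"] = int(row.homolog)
            if hasattr(row, "generation"):
                rec.info["GEN"] = int(row.generation)
            for key in METRIC_COLUMNS:
                if hasattr(row, key):
                    v = getattr(row, key)
                    if v == v:   # skip NaN
                        rec.info[key] = float(v)
            vf.write(rec)


# ---------------------------------------------------------------------------
# post-calling filter

#: (clause label, required metrics, vectorised predicate returning "remove")
FILTER_CLAUSES = [
    ("VariantAlleleCount<4", ["VariantAlleleCount"],
     lambda d: d.VariantAlleleCount < 4),
    ("VariantAlleleCountControl>1", ["VariantAlleleCountControl"],
     lambda d: d.VariantAlleleCountControl > 1),
    ("VariantMapQualMedian<40", ["VariantMapQualMedian"],
     lambda d: d.VariantMapQualMedian < 40),
    ("MapQualDiffMedian<-5", ["MapQualDiffMedian"],
     lambda d: d.MapQualDiffMedian < -5.0),
    ("MapQualDiffMedian>5", ["MapQualDiffMedian"],
     lambda d: d.MapQualDiffMedian > 5.0),
    ("LowMapQual>0.05", ["LowMapQual"],
     lambda d: d.LowMapQual > 0.05),
    ("VariantBaseQualMedian<30", ["VariantBaseQualMedian"],
     lambda d: d.VariantBaseQualMedian < 30),
    ("StrandBiasConjunction", ["VariantAlleleCount", "VariantStrandBias", "ReferenceStrandBias"],
     lambda d: (d.VariantAlleleCount >= 7) & (d.VariantStrandBias < 0.05)
               & (d.ReferenceStrandBias >= 0.2)),
    ("DistanceToAlignmentEndMedian<10", ["DistanceToAlignmentEndMedian"],
     lambda d: d.DistanceToAlignmentEndMedian < 10),
    ("DistanceToAlignmentEndMAD<3", ["DistanceToAlignmentEndMAD"],
     lambda d: d.DistanceToAlignmentEndMAD < 3),
]


def filter_mutations(calls: pd.DataFrame):
    """Apply the post-calling removal clauses.

    Returns ``(kept, removed)`` where ``removed`` carries a ``reason`` column
    naming the first failing clause. A clause whose metric column is absent
    is skipped (and logged): simulated tables may omit alignment metrics.
    """
    reason = pd.Series("", index=calls.index, dtype=object)
    for label, needed, pred in FILTER_CLAUSES:
        missing = [c for c in needed if c not in calls.columns]
        if missing:
            log.info("filter clause %s skipped: missing metrics %s", label, missing)
            continue
        vals = calls[needed]
        evaluable = vals.notna().all(axis=1)
        hit = pd.Series(False, index=calls.index)
        hit[evaluable] = pred(calls[evaluable]).astype(bool)
        reason = reason.where((reason != "") | ~hit, label)
    kept = calls[reason == ""].copy()
    removed = calls[reason != ""].copy()
    removed["reason"] = reason[reason != ""]
    return kept, removed


def remove_snp_overlaps(calls: pd.DataFrame, snp_positions: dict) -> pd.DataFrame:
    """Drop calls whose 1-based position coincides with a germline SNP."""
    keep = np.ones(len(calls), dtype=bool)
    for i, (chrom, pos) in enumerate(zip(calls.chrom, calls.pos)):
        snp = snp_positions.get(chrom)
        if snp is None:
            continue
        pos0 = pos - 1
        j = np.searchsorted(snp, pos0)
        if j < len(snp) and snp[j] == pos0:
            keep[i] = False
    return calls[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# mappability

def mappable_windows(counts: pd.DataFrame, x_chrom_name: str = "chrX") -> pd.DataFrame:
    """Excluded-interval set from triplicate 1-kb control read counts.

    X-chromosome counts are doubled before statistics (single copy); a window
    is excluded iff its count deviates from the replicate mean by at least
    one standard deviation in two or more of the three replicates. Adjacent
    excluded windows are merged. Expects columns chrom, start, end, and three
    replicate count columns.
    """
    rep_cols = [c for c in counts.columns if c not in ("chrom", "start", "end")]
    if len(rep_cols) != 3:
        raise ValueError(f"expected 3 replicate columns, found {rep_cols}")
    vals = counts[rep_cols].to_numpy(dtype=float)
    is_x = (counts.chrom == x_chrom_name).to_numpy()
    vals = np.where(is_x[:, None], vals * 2, vals)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    flag = (np.abs(vals - mean) >= sd).sum(axis=1) >= 2

    out = []
    for chrom, sub in counts.assign(excluded=flag).groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur = None
        for row in sub.itertuples(index=False):
            if not row.excluded:
                continue
            if cur is not None and row.start <= cur[1]:
                cur = (cur[0], max(cur[1], row.end))
            else:
                if cur is not None:
                    out.append((chrom, *cur))
                cur = (row.start, row.end)
        if cur is not None:
            out.append((chrom, *cur))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def _merged(excluded: pd.DataFrame, chrom: str):
    sub = excluded[excluded.chrom == chrom].sort_values("start")
    starts, ends = [], []
    for row in sub.itertuples(index=False):
        if starts and row.start <= ends[-1]:
            ends[-1] = max(ends[-1], row.end)
        else:
            starts.append(row.start)
            ends.append(row.end)
    return np.array(starts, dtype=float), np.array(ends, dtype=float)


def _overlap(starts, ends, a, b) -> float:
    """Total excluded bases within [a, b) given merged sorted intervals."""
    if starts.size == 0:
        return 0.0
    lo = np.clip(starts, a, b)
    hi = np.clip(ends, a, b)
    return float(np.maximum(hi - lo, 0).sum())


def sliding_bins(chrom_sizes: dict, width: int = 10_000_000, step: int = 100_000,
                 excluded: Optional[pd.DataFrame] = None,
                 min_mappable: float = 0.95) -> pd.DataFrame:
    """Sliding genomic bins, retained only when sufficiently mappable.

    A chromosome shorter than ``width`` contributes zero bins (logged). Bins
    are half-open [start, end) and retained iff at least ``min_mappable`` of
    their bases fall outside the excluded intervals.
    """
    if width < step:
        raise ValueError("width must be >= step")
    rows = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        if size < width:
            log.info("chromosome %s (%d bp) shorter than bin width; no bins", chrom, size)
            continue
        ex = _merged(excluded, chrom) if excluded is not None else (np.array([]), np.array([]))
        for start in range(0, size - width + 1, step):
            end = start + width
            bad = _overlap(*ex, start, end)
            if (width - bad) / width >= min_mappable:
                rows.append((chrom, start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
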