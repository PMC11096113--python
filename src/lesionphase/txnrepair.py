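"""Transcription-coupled repair and accessibility analyses.

Gene models carry an expression bin (1 = not expressed, 2-4 = expressed
tertiles of log2(TPM + 0.1)); mutations inside gene bodies split into
template- and non-template-strand events per class, and stranded rates are
doubled and divided by the genome-average class rate so that 1.0 means "at
the genomic rate".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simgen import GenomeModel
from . import spectra

# template-strand rules per class: (gene strand, plus-strand mutation id)
_TEMPLATE = {
    "UV": {("-", "C>T"), ("+", "G>A")},
    "ROS": {("-", "G>T"), ("+", "C>A")},
}
_CLASS_IDS = {"UV": ["C>T", "G>A"], "ROS": ["C>A", "G>T"]}


def build_gene_models(annotation: pd.DataFrame, tpm: pd.DataFrame,
                      atac_signal=None, min_length: int = 1000,
                      min_gap: int = 1000) -> pd.DataFrame:
    """Gene models with expression bins from transcripts and TPM.

    ``annotation`` needs gene_id, chrom, strand, start, end (one row per
    transcript or per gene). Genes on multiple chromosomes or both strands
    are dropped; when several transcripts exist the start is taken from the
    transcript with maximal ATAC signal in (-1000, +500) around its TSS
    (``atac_signal(chrom, lo, hi) -> float``), falling back to the longest
    isoform; the end is the longest transcript end. Genes shorter than
    ``min_length`` or closer than ``min_gap`` to the nearest retained gene
    are removed; genes without a TPM entry are excluded (logged). Bin 1 is
    log2(TPM + 0.1) <= 0; the remaining genes split into tertiles (bins 2-4,
    ties broken by gene id order).
    """
    import logging
    log = logging.getLogger(__name__)
    tpm_map = dict(zip(tpm.gene_id, tpm.tpm))

    rows = []
    for gene_id, sub in annotation.groupby("gene_id", sort=True):
        if sub.chrom.nunique() > 1 or sub.strand.nunique() > 1:
            continue
        if gene_id not in tpm_map:
            log.info("gene %s has no TPM; excluded", gene_id)
            continue
        t = tpm_map[gene_id]
        if len(sub) > 1 and atac_signal is not None and t > 0:
            def tss_score(row):
                tss = row.start if row.strand == "+" else row.end
                return atac_signal(row.chrom, tss - 1000, tss + 500)
            best = max(sub.itertuples(index=False), key=tss_score)
        else:
            best = max(sub.itertuples(index=False), key=lambda r: r.end - r.start)
        start = best.start if best.strand == "+" else int(sub.start.min())
        if best.strand == "+":
            start, end = best.start, int(sub.end.max())
        else:
            start, end = int(sub.start.min()), best.end
        rows.append({"gene_id": gene_id, "chrom": best.chrom, "strand": best.strand,
                     "start": int(start), "end": int(end), "tpm": float(t)})
    genes = pd.DataFrame(rows)
    if genes.empty:
        return genes

    genes = genes[genes.end - genes.start >= min_length]
    # neighbour distance on the retained set
    keep = []
    for chrom, sub in genes.groupby("chrom"):
        sub = sub.sort_values("start")
        starts, ends = sub.start.to_numpy(), sub.end.to_numpy()
        gap_prev = np.r_[np.inf, starts[1:] - ends[:-1]]
        gap_next = np.r_[starts[1:] - ends[:-1], np.inf]
        keep.append(sub[(gap_prev >= min_gap) & (gap_next >= min_gap)])
    genes = pd.concat(keep, ignore_index=True)

    genes["log2_tpm"] = np.log2(genes.tpm + 0.1)
    genes = genes.sort_values("gene_id").reset_index(drop=True)
    genes["bin"] = 1
    expressed = genes[genes.log2_tpm > 0]
    if len(expressed):
        order = expressed.sort_values(["log2_tpm", "gene_id"], kind="stable").index
        tert = np.array_split(np.arange(len(order)), 3)
        for b, chunk in zip((2, 3, 4), tert):
            genes.loc[order[chunk], "bin"] = b
    return genes


def assign_template_strand(calls: pd.DataFrame, genes: pd.DataFrame,
                           mutation_class: str) -> pd.Series:
    """Label each call TEMPLATE / NON_TEMPLATE / NA for a mutation class.

    The template strand of a plus-strand gene is the minus strand, so for
    the UV class a C>T inside a minus-strand gene (damaged C on the template)
    is TEMPLATE, as is G>A inside a plus-strand gene; the inverse pairs are
    NON_TEMPLATE. Calls outside gene bodies or outside the class are NA.
    """
    tmpl = _TEMPLATE[mutation_class]
    class_ids = _CLASS_IDS[mutation_class]
    labels = np.full(len(calls), "NA", dtype=object)
    ids_all = (calls.ref + ">" + calls.alt).to_numpy()
    chroms = calls.chrom.to_numpy()
    pos0_all = calls.pos.to_numpy() - 1
    for chrom, gsub in genes.groupby("chrom"):
        gsub = gsub.sort_values("start")
        starts, ends = gsub.start.to_numpy(), gsub.end.to_numpy()
        strands = gsub.strand.to_numpy()
        mask = chroms == chrom
        if not mask.any():
            continue
        pos0 = pos0_all[mask]
        idx = np.searchsorted(starts, pos0, side="right") - 1
        safe = np.clip(idx, 0, len(ends) - 1)
        inside = (idx >= 0) & (pos0 < ends[safe])
        ids = ids_all[mask]
        is_class = np.isin(ids, class_ids)
        is_tmpl = np.array([(s, m) in tmpl for s, m in zip(strands[safe], ids)])
        labels[mask] = np.where(inside & is_class,
                                np.where(is_tmpl, "TEMPLATE", "NON_TEMPLATE"), "NA")
    return pd.Series(labels, index=calls.index, dtype=object)


def stranded_rates(calls: pd.DataFrame, genes: pd.DataFrame, genome: GenomeModel,
                   mutation_class: str,
                   weight_source: str = "genome") -> pd.DataFrame:
    """Template / non-template relative mutation rates per expression bin.

    Class-restricted trinucleotide-weighted rates per strand per bin are
    multiplied by 2 (each strand sees half the opportunity) and divided by
    the genome-average class rate, giving rates relative to the genome.
    """
    calls = calls.reset_index(drop=True)
    labels = assign_template_strand(calls, genes, mutation_class)
    class_ids = _CLASS_IDS[mutation_class]
    genome_rate = spectra.mutation_rate(calls, genome, regions=None,
                                        classes=class_ids, weight_source="genome")
    if genome_rate == 0:
        raise ValueError("zero genome-average class rate")
    rows = []
    for b in sorted(genes["bin"].unique()):
        territory = genes[genes["bin"] == b][["chrom", "start", "end"]]
        for side in ("TEMPLATE", "NON_TEMPLATE"):
            sub = calls[labels == side]
            rate = spectra.mutation_rate(sub, genome, regions=territory,
                                         classes=class_ids,
                                         weight_source=weight_source)
            rows.append({"bin": b, "strand": side,
                         "relative_rate": 2.0 * rate / genome_rate})
    return pd.DataFrame(rows)


def accessibility_rates(calls: pd.DataFrame, peaks: pd.DataFrame,
                        genome: GenomeModel, mutation_class: str) -> float:
    """Observed class rate inside accessibility peaks over the genome rate."""
    if peaks.empty or (peaks.end - peaks.start).sum() == 0:
        raise ValueError("zero peak territory")
    class_ids = _CLASS_IDS[mutation_class]
    peak_rate = spectra.mutation_rate(calls, genome, regions=peaks,
                                      classes=class_ids, weight_source="genome")
    genome_rate = spectra.mutation_rate(calls, genome, regions=None,
                                        classes=class_ids, weight_source="genome")
    if genome_rate == 0:
        raise ValueError("zero genome-average class rate")
    return peak_rate / genome_rate


def accessibility_metaplot(mutation_positions: pd.DataFrame, coverage: dict,
                           flank: int = 2000, smooth: int = 201,
                           pseudocount: float = 1.0) -> pd.DataFrame:
    """Mean log2 accessibility coverage around mutations, boxcar smoothed.

    ``coverage`` maps chrom -> per-base read-count array. Mutation flanks
    that run off a chromosome contribute their covered part only. Smoothing
    averages over ``smooth`` bp (1 = identity); log2 uses ``pseudocount``.
    """
    width = 2 * flank + 1
    acc = np.zeros(width)
    n = np.zeros(width)
    for row in mutation_positions.itertuples(index=False):
        cov = coverage.get(row.chrom)
        if cov is None:
            continue
        center = int(row.pos) - 1
        lo = max(center - flank, 0)
        hi = min(center + flank + 1, len(cov))
        a = lo - (center - flank)
        acc[a:a + hi - lo] += cov[lo:hi]
        n[a:a + hi - lo] += 1
    mean = np.where(n > 0, acc / np.maximum(n, 1), 0.0)
    logged = np.log2(mean + pseudocount)
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        pad = smooth // 2
        padded = np.pad(logged, pad, mode="edge")
        logged = np.convolve(padded, kernel, mode="valid")
    return pd.DataFrame({"offset": np.arange(-flank, flank + 1), "log2_coverage": logged})
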