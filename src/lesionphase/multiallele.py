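"""Tandem dinucleotide mutation analysis.

A pyrimidine-dimer lesion retained across more than one replication cycle
fixes independent bypass outcomes in successive cell cycles, producing more
than one alternative allele at the same CC site, with the earlier event at
twice the VAF of the later one. This module identifies tandem sites from a
call table, computes per-base and per-allele read-level VAFs from reads that
cover both bases, flags multiallelic sites, orders events by VAF, verifies
allele counts alignment-free by exact 22-mer matching, and tests flanking
base composition enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .simgen import BASES, GenomeModel

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


@dataclass
class TandemSite:
    chrom: str
    pos5: int                      # 1-based; pos3 = pos5 + 1
    ref_pair: str
    allele_read_counts: dict = field(default_factory=dict)
    n_dual_reads: int = 0
    vaf5: float = np.nan
    vaf3: float = np.nan
    multiallelic: bool = False
    ordered_events: list = field(default_factory=list)   # [(allele, rank)]
    overlapping_triple: bool = False
    scored: bool = False

    @property
    def pos3(self) -> int:
        return self.pos5 + 1


def find_tandems(calls: pd.DataFrame, genome: Optional[GenomeModel] = None) -> list:
    """Candidate tandem sites: call pairs at intermutation distance 0.

    Mutation triples at three consecutive positions yield two overlapping
    tandems, both returned and flagged. The reference pair is taken from the
    genome when given, else from the calls' ref alleles.
    """
    out = []
    for chrom, sub in calls.groupby("chrom", sort=True):
        sub = sub.sort_values("pos").drop_duplicates("pos")
        pos = sub.pos.to_numpy()
        refs = sub.ref.to_numpy()
        adjacent = np.nonzero(np.diff(pos) == 1)[0]
        for i in adjacent:
            if genome is not None:
                seq = genome.seqs[chrom]
                ref_pair = BASES[seq[pos[i] - 1]] + BASES[seq[pos[i]]]
            else:
                ref_pair = refs[i] + refs[i + 1]
            site = TandemSite(chrom=chrom, pos5=int(pos[i]), ref_pair=ref_pair)
            # flag members of runs of >= 3 consecutive mutated positions
            prev_adj = i - 1 in adjacent
            next_adj = i + 1 in adjacent
            site.overlapping_triple = bool(prev_adj or next_adj)
            out.append(site)
    return out


def site_read_vafs(site: TandemSite, reads: pd.DataFrame) -> TandemSite:
    """Score a tandem site from dual-covering reads.

    Only reads with sequence information at both bases count; per-base VAFs
    are the fractions of dual-covering reads that are non-reference at the
    5' and 3' base, and allele counts tally unique reads per (base1, base2)
    pair. A site with no dual-covering reads stays unscored.
    """
    dual = reads.dropna(subset=["base1", "base2"]).drop_duplicates("read_id")
    n = len(dual)
    if n == 0:
        site.scored = False
        return site
    alleles = dual.base1.str.cat(dual.base2)
    site.allele_read_counts = alleles.value_counts().to_dict()
    site.n_dual_reads = n
    site.vaf5 = float((dual.base1 != site.ref_pair[0]).mean())
    site.vaf3 = float((dual.base2 != site.ref_pair[1]).mean())
    site.scored = True
    return site


def call_multiallelic(site: TandemSite, min_reads: int = 3) -> bool:
    """A scored site is multiallelic iff >= 2 distinct non-reference alleles
    each have at least ``min_reads`` unique dual-covering reads."""
    if not site.scored:
        raise ValueError("site not scored; run site_read_vafs first")
    alt = {a: c for a, c in site.allele_read_counts.items()
           if a != site.ref_pair and c >= min_reads}
    site.multiallelic = len(alt) >= 2
    return site.multiallelic


def order_alleles(site: TandemSite) -> list:
    """Rank non-reference alleles by descending VAF; rank 1 is the first event.

    Equal read counts leave the order unresolved: the tied alleles share a
    rank and the site is classified simultaneous/biallelic. Each event also
    receives a transition label such as ``CC>TT``.
    """
    alt = [(a, c) for a, c in site.allele_read_counts.items() if a != site.ref_pair]
    alt.sort(key=lambda t: -t[1])
    events = []
    rank = 1
    for j, (allele, count) in enumerate(alt):
        if j > 0 and count == alt[j - 1][1]:
            pass                      # tie: same rank, order unresolved
        elif j > 0:
            rank = j + 1
        events.append({"allele": allele, "rank": rank, "reads": count,
                       "vaf": count / site.n_dual_reads,
                       "label": f"{site.ref_pair}>{allele}"})
    tied = len({e["rank"] for e in events}) < len(events)
    site.ordered_events = events
    site.tie = tied
    return events


def vaf_ratio(site: TandemSite) -> float:
    """VAF ratio of the rank-1 to rank-2 allele at a multiallelic site."""
    ev = site.ordered_events or order_alleles(site)
    if len(ev) < 2 or ev[1]["vaf"] == 0:
        return np.nan
    return ev[0]["vaf"] / ev[1]["vaf"]


# ---------------------------------------------------------------------------
# alignment-free verification

def tandem_queries(genome: GenomeModel, site: TandemSite, flank: int = 10) -> dict:
    """The 8 exact-match queries for a tandem site: 4 dinucleotide alleles
    (reference, two single-base, one double) in both orientations, each
    ``2*flank + 2`` bases long (22 bp at the default flank)."""
    seq = genome.seqs[site.chrom]
    lo = site.pos5 - 1 - flank
    hi = site.pos5 + 1 + flank
    if lo < 0 or hi > seq.size:
        raise ValueError("flank extends past chromosome end")
    left = "".join(BASES[seq[lo:site.pos5 - 1]])
    right = "".join(BASES[seq[site.pos5 + 1:hi]])
    r5, r3 = site.ref_pair[0], site.ref_pair[1]
    a5 = "T" if r5 == "C" else "A"      # canonical UV transition product
    a3 = "T" if r3 == "C" else "A"
    alleles = [r5 + r3, a5 + r3, r5 + a3, a5 + a3]
    out = {}
    for al in alleles:
        q = left + al + right
        out[al] = (q, _revcomp(q))
    return out


def grep_verify(genome: GenomeModel, site: TandemSite, read_seqs,
                flank: int = 10, alt_alleles: Optional[list] = None):
    """Alignment-free allele counts by exact string matching.

    Builds the 8 queries for the site (optionally using the observed
    alternate alleles instead of the canonical transition products), rejects
    the site when any alternate-allele query has an exact match elsewhere in
    the genome or when no read matches at all, and otherwise returns
    ``{allele: n_reads_matching}`` over the supplied raw read sequences.
    """
    queries = tandem_queries(genome, site, flank)
    if alt_alleles:
        seq = genome.seqs[site.chrom]
        left = "".join(BASES[seq[site.pos5 - 1 - flank:site.pos5 - 1]])
        right = "".join(BASES[seq[site.pos5 + 1:site.pos5 + 1 + flank]])
        queries = {al: (left + al + right, _revcomp(left + al + right))
                   for al in set(alt_alleles) | {site.ref_pair}}

    genome_strs = {c: "".join(BASES[s]) for c, s in genome.seqs.items()}

    def genome_hits(q: str) -> int:
        total = 0
        for s in genome_strs.values():
            start = 0
            while True:
                j = s.find(q, start)
                if j < 0:
                    break
                total += 1
                start = j + 1
        return total

    for allele, (fwd, rev) in queries.items():
        if allele == site.ref_pair:
            continue
        if genome_hits(fwd) + genome_hits(rev) > 0:
            return None            # alternate allele pre-exists elsewhere
    counts = {}
    for allele, (fwd, rev) in queries.items():
        n = sum(1 for r in read_seqs if r is not None and (fwd in r or rev in r))
        counts[allele] = n
    if sum(counts.values()) == 0:
        return None                # nearby variation defeated exact matching
    return counts


# ---------------------------------------------------------------------------
# flank composition

def flank_enrichment(multiallelic_sites: list, background_sites: list,
                     genome: GenomeModel, flank_width: int = 5) -> pd.DataFrame:
    """Per-position pyrimidine enrichment versus a background site group.

    For each flank offset a 2x2 pyrimidine-vs-purine table is tested with a
    two-sided Fisher exact test; p-values are Benjamini-Hochberg corrected
    across offsets. Offsets are relative to the 5' base of the tandem pair
    (negative upstream, positive downstream of the 3' base).
    """
    for group, name in ((multiallelic_sites, "test"), (background_sites, "background")):
        if len(group) < 10:
            raise ValueError(f"{name} group has fewer than 10 sites")

    def pyr_counts(sites, off):
        pyr = tot = 0
        for s in sites:
            seq = genome.seqs[s.chrom]
            i = (s.pos5 - 1 + off) if off < 0 else (s.pos5 + off)  # skip the pair itself
            if 0 <= i < seq.size:
                pyr += int(seq[i] in (1, 3))
                tot += 1
        return pyr, tot

    offsets = [o for o in range(-flank_width, flank_width + 1) if o != 0]
    rows = []
    for off in offsets:
        p1, t1 = pyr_counts(multiallelic_sites, off)
        p2, t2 = pyr_counts(background_sites, off)
        _, p = stats.fisher_exact([[p1, t1 - p1], [p2, t2 - p2]], alternative="two-sided")
        rows.append({"offset": off, "pyr_test": p1, "n_test": t1,
                     "pyr_background": p2, "n_background": t2, "p": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = benjamini_hochberg(out.p.to_numpy())
    return out


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH-adjusted p-values (step-up)."""
    return stats.false_discovery_control(np.asarray(pvals, dtype=float), method="bh")
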