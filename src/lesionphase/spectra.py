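"""Trinucleotide-context machinery: 96-class signatures, cosine similarity,
opportunity-weighted mutation rates, and Pearson's median skewness.

Two distinct context foldings coexist on purpose. Signatures use the
conventional 96-class pyrimidine fold (mutations with an A/G reference are
reverse complemented). Mutation rates use 64 stranded trinucleotide contexts
as written on the plus strand, with alternate alleles pooled per context, so
that strand-resolved rates (template versus non-template) remain expressible.
"""

from __future__ import annotations

from itertools import product
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .simgen import BASES, GenomeModel

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUBSTITUTIONS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]

#: canonical 96-class labels, e.g. "A[C>A]A", grouped by substitution
CONTEXTS_96 = [f"{f}[{s}]{t}" for s in SUBSTITUTIONS
               for f, t in product("ACGT", "ACGT")]

TRINUCS_64 = ["".join(t) for t in product("ACGT", repeat=3)]


def _revcomp(s: str) -> str:
    return "".join(COMP[b] for b in reversed(s))


def signature_96(calls: pd.DataFrame, genome: GenomeModel) -> pd.Series:
    """96-class frequency spectrum of a call set.

    Mutations whose reference base is A or G are folded to the pyrimidine
    strand by reverse complementing the trinucleotide and both alleles.
    Calls at chromosome ends with an unresolvable flank are excluded; their
    number is recorded in ``result.attrs["n_excluded"]``.
    """
    counts = pd.Series(0.0, index=CONTEXTS_96)
    n_excluded = 0
    for row in calls.itertuples(index=False):
        seq = genome.seqs[row.chrom]
        i = int(row.pos) - 1
        if i - 1 < 0 or i + 1 >= seq.size:
            n_excluded += 1
            continue
        tri = "".join(BASES[seq[i - 1:i + 2]])
        ref, alt = row.ref, row.alt
        if tri[1] != ref:
            raise ValueError(f"reference mismatch at {row.chrom}:{row.pos}")
        if ref in "AG":
            tri, ref, alt = _revcomp(tri), COMP[ref], COMP[alt]
        label = f"{tri[0]}[{ref}>{alt}]{tri[2]}"
        counts[label] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no usable mutations for a signature")
    out = counts / total
    out.attrs["n_excluded"] = n_excluded
    out.attrs["n_used"] = int(total)
    return out


def cosine_to_reference(spectrum: pd.Series, reference: pd.DataFrame) -> pd.Series:
    """Cosine similarity of a 96-vector to each reference signature, descending."""
    v = spectrum.reindex(CONTEXTS_96).to_numpy(dtype=float)
    if np.linalg.norm(v) == 0:
        raise ValueError("zero spectrum vector")
    sims = {}
    for name in reference.columns:
        w = reference[name].reindex(CONTEXTS_96).to_numpy(dtype=float)
        if np.linalg.norm(w) == 0:
            raise ValueError(f"zero reference vector {name!r}")
        sims[name] = float(v @ w / (np.linalg.norm(v) * np.linalg.norm(w)))
    return pd.Series(sims).sort_values(ascending=False)


def read_signature_matrix(path, exclude: Optional[Iterable[str]] = None) -> pd.DataFrame:
    """Read a COSMIC-style signature TSV (Type/Subtype or combined key dialect).

    ``exclude`` drops named signatures (e.g. a user-supplied artefact list).
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "type" in cols and "subtype" in cols:
        sub = df[cols["type"]]
        tri = df[cols["subtype"]]
        idx = [f"{t[0]}[{s}]{t[2]}" for s, t in zip(sub, tri)]
        df = df.drop(columns=[cols["type"], cols["subtype"]])
        df.index = idx
    else:
        first = df.columns[0]
        df = df.set_index(first)
    df = df.reindex(CONTEXTS_96)
    df.index.name = None
    if df.isna().any().any():
        raise ValueError("signature matrix does not cover all 96 contexts")
    if exclude:
        df = df.drop(columns=[c for c in exclude if c in df.columns])
    return df


# ---------------------------------------------------------------------------
# rates

def _trinuc_codes(seq: np.ndarray) -> np.ndarray:
    return (seq[:-2].astype(np.int64) * 16 + seq[1:-1].astype(np.int64) * 4
            + seq[2:].astype(np.int64))


def trinuc_opportunities(genome: GenomeModel,
                         regions: Optional[pd.DataFrame] = None) -> np.ndarray:
    """Occurrence counts of the 64 plus-strand trinucleotides in a territory."""
    counts = np.zeros(64, dtype=np.int64)
    if regions is None:
        for seq in genome.seqs.values():
            counts += np.bincount(_trinuc_codes(seq), minlength=64)
        return counts
    for row in regions.itertuples(index=False):
        seq = genome.seqs[row.chrom]
        a = max(int(row.start), 1)
        b = min(int(row.end), seq.size - 1)
        if b <= a:
            continue
        # trinucleotides centered at [a, b)
        counts += np.bincount(_trinuc_codes(seq[a - 1:b + 1]), minlength=64)
    return counts


def _calls_in_regions(calls: pd.DataFrame, regions: Optional[pd.DataFrame]) -> pd.DataFrame:
    if regions is None:
        return calls
    keep = np.zeros(len(calls), dtype=bool)
    for chrom, sub in regions.groupby("chrom"):
        starts = sub.start.to_numpy()
        ends = sub.end.to_numpy()
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        mask = (calls.chrom == chrom).to_numpy()
        pos0 = calls.pos.to_numpy() - 1
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, len(ends) - 1)])
        keep |= mask & ok
    return calls[keep]


def mutation_rate(calls: pd.DataFrame, genome: GenomeModel,
                  regions: Optional[pd.DataFrame] = None,
                  classes: Optional[Iterable[str]] = None,
                  weight_source: str = "genome") -> float:
    """Trinucleotide-weighted mutation rate in mutations per megabase.

    Per 64-context counts are divided by per-context opportunity in the
    territory, then averaged with weights equal to the relative trinucleotide
    representation of ``weight_source`` ("region" or "genome"), and scaled by
    1e6. ``classes`` restricts both mutations and admissible central bases,
    e.g. ``["C>T", "G>A"]`` for the UV class or a single orientation for
    stranded rates.
    """
    sub = _calls_in_regions(calls, regions)
    if classes is not None:
        classes = list(classes)
        ids = sub.ref + ">" + sub.alt
        sub = sub[ids.isin(classes)]
        centers = {c[0] for c in classes}
    else:
        centers = set("ACGT")

    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    m = np.zeros(64, dtype=np.int64)
    for row in sub.itertuples(index=False):
        seq = genome.seqs[row.chrom]
        i = int(row.pos) - 1
        if i - 1 < 0 or i + 1 >= seq.size:
            continue
        m[int(seq[i - 1]) * 16 + int(seq[i]) * 4 + int(seq[i + 1])] += 1

    opp = trinuc_opportunities(genome, regions)
    if weight_source == "region":
        w_src = opp.astype(float)
    elif weight_source == "genome":
        w_src = trinuc_opportunities(genome, None).astype(float)
    else:
        raise ValueError("weight_source must be 'region' or 'genome'")

    allowed = np.array([TRINUCS_64[k][1] in centers for k in range(64)])
    usable = allowed & (opp > 0)
    if not usable.any():
        raise ValueError("no trinucleotide opportunity in territory")
    w = w_src * usable
    if w.sum() == 0:
        raise ValueError("weight source has no mass on admissible contexts")
    w = w / w.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        per_ctx = np.where(usable, m / np.where(opp > 0, opp, 1), 0.0)
    return float((w * per_ctx).sum() * 1e6)


def pearson_median_skew(values) -> float:
    """Pearson's median skewness coefficient, 3*(mean - median)/sd."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation")
    return float(3.0 * (x.mean() - np.median(x)) / sd)
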