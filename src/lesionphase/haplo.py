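"""Read-level haplotype assignment of somatic mutations.

Reads tagged by upstream N-masked alignment splitting vote for the parental
haplotype of each mutation; the hemizygous X chromosome, where every true
mutation lies on a single haplotype, calibrates the false-assignment rate;
and per-haplotype segmentation turns mixed autosomal segments into two fully
phased single-haplotype segments.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from . import phasing


def assign_haplotype(reads: pd.DataFrame, cutoff: int = 2, min_reads: int = 2,
                     conflict_floor: int = 2) -> pd.DataFrame:
    """Per-mutation haplotype calls from tagged alt-supporting reads.

    Unique reads tagged A or B are tallied per mutation; a mutation is
    assigned when it has at least ``min_reads`` assignable reads and
    ``|n_A - n_B| >= cutoff``, unless both haplotypes reach
    ``conflict_floor`` reads (a conflict: likely mapping trouble), in which
    case it stays ND. Zero reads on the minority haplotype never count as a
    conflict.
    """
    uniq = reads.drop_duplicates("read_id")
    counts = (uniq[uniq.hap_tag.isin(["A", "B"])]
              .groupby(["mutation_id", "hap_tag"]).size().unstack(fill_value=0))
    all_ids = pd.Index(uniq.mutation_id.unique(), name="mutation_id")
    n_a = counts.get("A", pd.Series(0, index=counts.index)).reindex(all_ids, fill_value=0)
    n_b = counts.get("B", pd.Series(0, index=counts.index)).reindex(all_ids, fill_value=0)
    delta = n_a - n_b
    assignable = n_a + n_b
    conflict = (n_a >= conflict_floor) & (n_b >= conflict_floor)
    label = np.where(
        (assignable >= min_reads) & (np.abs(delta) >= cutoff) & ~conflict,
        np.where(delta > 0, "HAP_A", "HAP_B"), "ND")
    return pd.DataFrame({"mutation_id": all_ids, "n_hapA": n_a.to_numpy(),
                         "n_hapB": n_b.to_numpy(), "delta": delta.to_numpy(),
                         "label": label})


def x_false_assignment_rate(hap_calls: pd.DataFrame, true_haplotype: str = "HAP_A") -> float:
    """Fraction of assigned X-chromosome mutations on the wrong haplotype.

    X mutations can only reside on the single parental X, so any assignment
    to the other haplotype is an error. ``hap_calls`` should already be
    restricted to the X chromosome.
    """
    assigned = hap_calls[hap_calls.label != "ND"]
    if len(assigned) == 0:
        raise ValueError("no assigned X-chromosome mutations")
    wrong = (assigned.label != true_haplotype).sum()
    return float(wrong / len(assigned))


def haplotype_phase_agreement(calls: pd.DataFrame, hap_calls: pd.DataFrame,
                              mutation_class: str = "UV",
                              segment_kwargs: Optional[dict] = None):
    """Phase agreement of haplotype-resolved mutations with their segments.

    Calls are split by assigned haplotype and each haplotype's class codes
    are segmented independently; for every phased segment the agreement is
    the fraction of member mutations whose orientation matches the segment
    polarity. Returns ``(per_segment, genome_wide)`` where ``genome_wide``
    pools all phased segments. Raises when a haplotype yields no segments.
    """
    segment_kwargs = segment_kwargs or {}
    merged = calls.drop(columns=["label"], errors="ignore").merge(
        hap_calls[["mutation_id", "label"]], on="mutation_id")
    per_seg_rows = []
    agree = total = 0
    for hap in ("HAP_A", "HAP_B"):
        sub = merged[merged.label == hap]
        codes = phasing.orientation_codes(sub, mutation_class)
        if not codes:
            raise ValueError(f"no informative mutations for {hap}")
        segments = phasing.segment_genome(codes, **segment_kwargs)
        if segments.empty:
            raise ValueError(f"unsegmented haplotype {hap}")
        for seg in segments.itertuples(index=False):
            if seg.state == "MIXED":
                continue
            pos, c = codes[seg.chrom]
            in_seg = (pos - 1 >= seg.start) & (pos <= seg.end)
            if in_seg.sum() == 0:
                continue
            polarity = 1 if seg.state == "C_PHASED" else -1
            n_agree = int((c[in_seg] == polarity).sum())
            per_seg_rows.append({"haplotype": hap, "chrom": seg.chrom,
                                 "start": seg.start, "end": seg.end,
                                 "state": seg.state, "n_mut": int(in_seg.sum()),
                                 "agreement": n_agree / in_seg.sum()})
            agree += n_agree
            total += int(in_seg.sum())
    per_segment = pd.DataFrame(per_seg_rows)
    if total == 0:
        raise ValueError("no phased segments")
    return per_segment, agree / total


def resolve_mixed_segments(calls: pd.DataFrame, hap_calls: pd.DataFrame,
                           bulk_segments: pd.DataFrame,
                           mutation_class: str = "UV",
                           tau: float = 0.5, min_mut: int = 10) -> pd.DataFrame:
    """Check that bulk mixed segments split into two opposed phased haplotypes.

    For every MIXED bulk segment, the class mutations assigned to each
    haplotype within the segment are reduced to a mean orientation; the
    segment ``resolved`` flag requires both haplotypes phased (|mean| >= tau
    with >= ``min_mut`` mutations) in opposite directions.
    """
    merged = calls.drop(columns=["label"], errors="ignore").merge(
        hap_calls[["mutation_id", "label"]], on="mutation_id")
    rows = []
    for seg in bulk_segments[bulk_segments.state == "MIXED"].itertuples(index=False):
        in_seg = ((merged.chrom == seg.chrom) & (merged.pos - 1 >= seg.start)
                  & (merged.pos <= seg.end))
        sub = merged[in_seg]
        means, ns = {}, {}
        for hap in ("HAP_A", "HAP_B"):
            codes = phasing.orientation_codes(sub[sub.label == hap], mutation_class)
            c = np.concatenate([v[1] for v in codes.values()]) if codes else np.array([])
            means[hap] = float(c.mean()) if c.size else np.nan
            ns[hap] = int(c.size)
        resolved = (ns["HAP_A"] >= min_mut and ns["HAP_B"] >= min_mut
                    and abs(means["HAP_A"]) >= tau and abs(means["HAP_B"]) >= tau
                    and np.sign(means["HAP_A"]) != np.sign(means["HAP_B"]))
        rows.append({"chrom": seg.chrom, "start": seg.start, "end": seg.end,
                     "skew_hapA": means["HAP_A"], "skew_hapB": means["HAP_B"],
                     "n_hapA": ns["HAP_A"], "n_hapB": ns["HAP_B"],
                     "resolved": bool(resolved)})
    return pd.DataFrame(rows)
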