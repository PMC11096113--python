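"""Sister-chromatid-exchange detection and strand-resolved density profiles.

An SCE at the first post-burst mitosis reciprocally exchanges chromatid
segments, so the phasing state of a chromosome switches at the breakpoint —
and the sister clone shows the complementary switch at the same place.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

_COMPLEMENT_STATE = {"C_PHASED": "G_PHASED", "G_PHASED": "C_PHASED", "MIXED": "MIXED"}


def detect_sce(segments: pd.DataFrame,
               sister_segments: Optional[pd.DataFrame] = None,
               reciprocal_tol: float = 2_000_000,
               sample_id: str = "NA") -> pd.DataFrame:
    """SCE candidates from within-chromosome segment-state switches.

    Every boundary between adjacent segments of different state is an event;
    its position is the boundary coordinate (midpoint between the flanking
    segments' nearest informative mutations). Boundaries where neither flank
    is phased are not called. ``phased_to_phased`` flags direct
    C_PHASED|G_PHASED switches with no intervening mixed segment, which are
    detected but flagged distinctly. When sister segments are supplied,
    ``reciprocal_in_sister`` marks events whose sister shows the
    complementary state change within ``reciprocal_tol`` bp.
    """
    rows = []
    for chrom, sub in segments.groupby("chrom", sort=True):
        sub = sub.sort_values("start").reset_index(drop=True)
        for i in range(len(sub) - 1):
            left, right = sub.iloc[i], sub.iloc[i + 1]
            if left.state == right.state:
                continue
            if left.state == "MIXED" and right.state == "MIXED":
                continue
            if bool(left.get("low_confidence", False)) or bool(right.get("low_confidence", False)):
                continue
            rows.append({
                "chrom": chrom,
                "position": int((left.end + right.start) // 2),
                "left_state": left.state,
                "right_state": right.state,
                "phased_to_phased": "MIXED" not in (left.state, right.state),
                "sample_id": sample_id,
                "reciprocal_in_sister": False,
            })
    events = pd.DataFrame(rows, columns=["chrom", "position", "left_state",
                                         "right_state", "phased_to_phased",
                                         "sample_id", "reciprocal_in_sister"])
    if sister_segments is not None and len(events):
        sister_events = detect_sce(sister_segments, None, sample_id=sample_id + "_sister")
        for i, ev in events.iterrows():
            match = sister_events[
                (sister_events.chrom == ev.chrom)
                & (np.abs(sister_events.position - ev.position) <= reciprocal_tol)
                & (sister_events.left_state == _COMPLEMENT_STATE[ev.left_state])
                & (sister_events.right_state == _COMPLEMENT_STATE[ev.right_state])
            ]
            events.at[i, "reciprocal_in_sister"] = bool(len(match))
    return events


def assign_recombined_strand(calls: pd.DataFrame, segments: pd.DataFrame,
                             event: pd.Series) -> pd.Series:
    """Label mixed-segment mutations around one SCE event.

    The mixed side is the flanking segment with the smaller absolute skew;
    mutations there with orientation opposite to the adjacent phased
    segment's polarity arose on the recombined strand. Returns a Series of
    {RECOMBINED, NON_RECOMBINED} indexed like the mixed-segment calls; raises
    when both flanks are phased (rule precondition) and returns empty with a
    warning when both are mixed.
    """
    sub = segments[segments.chrom == event.chrom].sort_values("start").reset_index(drop=True)
    # flanking pair around the boundary closest to the event
    right = sub[sub.start >= event.position].head(1)
    left = sub[sub.end <= event.position + 1].tail(1)
    if len(left) == 0 or len(right) == 0:
        raise ValueError("event has no flanking segment pair")
    left, right = left.iloc[0], right.iloc[0]
    skews = np.abs([left.mean_skew, right.mean_skew])
    if np.isclose(skews[0], skews[1]) and left.state == right.state == "MIXED":
        import logging
        logging.getLogger(__name__).warning("both flanks mixed at %s:%d; skipped",
                                            event.chrom, event.position)
        return pd.Series(dtype=object)
    mixed, phased = (left, right) if skews[0] < skews[1] else (right, left)
    if phased.state == "MIXED":
        import logging
        logging.getLogger(__name__).warning("no phased flank at %s:%d; skipped",
                                            event.chrom, event.position)
        return pd.Series(dtype=object)
    polarity = 1 if phased.mean_skew > 0 else -1
    in_mixed = (calls.chrom == event.chrom) & (calls.pos - 1 >= mixed.start) & (calls.pos <= mixed.end)
    sub_calls = calls[in_mixed]
    ids = sub_calls.ref + ">" + sub_calls.alt
    code = ids.map({"C>T": 1, "G>A": -1, "C>A": 1, "G>T": -1})
    labels = pd.Series(np.where(code == -polarity, "RECOMBINED", "NON_RECOMBINED"),
                       index=sub_calls.index, dtype=object)
    return labels[code.notna()]


def sce_density_profile(calls: pd.DataFrame, events: pd.DataFrame,
                        labels_by_event: Optional[list] = None,
                        flank: int = 10_000_000, window: int = 1_000_000,
                        step: int = 100_000,
                        chrom_sizes: Optional[dict] = None) -> pd.DataFrame:
    """Mutation density (mu/Mb) in sliding windows centred on SCE sites.

    Windows of ``window`` bp advance by ``step`` over ±``flank`` around each
    event (20 Mb total at defaults); densities are averaged across events
    aligned at offset 0. When per-event labels are given, densities are
    reported per class (RECOMBINED / NON_RECOMBINED / unassigned); windows
    truncated by a chromosome end contribute their covered fraction.
    """
    if len(events) == 0:
        raise ValueError("no SCE events supplied")
    offsets = np.arange(-flank, flank - window + step + 1, step)
    classes = ["RECOMBINED", "NON_RECOMBINED", "unassigned"]
    acc = {c: np.zeros(offsets.size) for c in classes}
    weight = np.zeros(offsets.size)

    for ei, ev in events.reset_index(drop=True).iterrows():
        sub = calls[calls.chrom == ev.chrom]
        lab = pd.Series("unassigned", index=sub.index, dtype=object)
        if labels_by_event is not None and labels_by_event[ei] is not None:
            lab.update(labels_by_event[ei])
        pos = sub.pos.to_numpy()
        size = chrom_sizes.get(ev.chrom) if chrom_sizes else None
        for k, off in enumerate(offsets):
            a = ev.position + off
            b = a + window
            lo, hi = a, b
            if size is not None:
                lo, hi = max(a, 0), min(b, size)
            if hi <= lo:
                continue
            span_mb = (hi - lo) / 1e6
            in_win = (pos > lo) & (pos <= hi)
            weight[k] += 1
            for c in classes:
                acc[c][k] += (in_win & (lab == c).to_numpy()).sum() / span_mb

    out = pd.DataFrame({"offset": offsets})
    for c in classes:
        out[c] = np.where(weight > 0, acc[c] / np.maximum(weight, 1), 0.0)
    return out
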