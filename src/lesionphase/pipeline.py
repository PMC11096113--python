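"""End-to-end orchestration of the sister-pair and F1 analyses."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, haplo, multiallele, mutio, phasing, sce, simgen, spectra, txnrepair

log = logging.getLogger(__name__)

SHARED_KEYS = ["chrom", "pos", "ref", "alt"]


def config_hash(config: simgen.SimConfig) -> str:
    payload = yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def partition_shared(calls_a: pd.DataFrame, calls_b: pd.DataFrame):
    """Split two sisters' calls into shared and unique sets.

    Shared means an exact (chrom, pos, ref, alt) match in both tables.
    Returns ``(shared_a, unique_a, shared_b, unique_b)``.
    """
    key_a = pd.MultiIndex.from_frame(calls_a[SHARED_KEYS])
    key_b = pd.MultiIndex.from_frame(calls_b[SHARED_KEYS])
    in_b = key_a.isin(key_b)
    in_a = key_b.isin(key_a)
    return calls_a[in_b], calls_a[~in_b], calls_b[in_a], calls_b[~in_a]


def _vaf_stats(calls: pd.DataFrame) -> dict:
    if len(calls) < 3:
        return {"n": int(len(calls)), "mean_vaf": np.nan, "skew": np.nan}
    return {"n": int(len(calls)),
            "mean_vaf": float(calls.vaf.mean()),
            "skew": float(spectra.pearson_median_skew(calls.vaf))}


def run_sisters(config: simgen.SimConfig, outdir: Optional[str] = None,
                sim: Optional[simgen.SisterPair] = None,
                bin_width: int = 1_000_000, bin_step: int = 100_000) -> dict:
    """Sister-pair pipeline: filter, partition, signatures, VAF statistics,
    phasing, segmentation, mirror correlation, SCE, multiallelic tandems and
    transcription-coupled repair, from one simulated (or supplied) pair."""
    if sim is None:
        sim = simgen.simulate_sister_pair(config)
    report: dict = {"manifest": {
        "config_hash": config_hash(config), "seed": config.seed,
        "version": __version__,
    }}
    stage_counts = {}

    kept_a, removed_a = mutio.filter_mutations(sim.calls_a)
    kept_b, removed_b = mutio.filter_mutations(sim.calls_b)
    stage_counts["filter"] = {"kept_a": len(kept_a), "removed_a": len(removed_a),
                              "kept_b": len(kept_b), "removed_b": len(removed_b)}

    shared_a, unique_a, shared_b, unique_b = partition_shared(kept_a, kept_b)
    stage_counts["partition"] = {"shared": len(shared_a),
                                 "unique_a": len(unique_a), "unique_b": len(unique_b)}

    report["signatures"] = {}
    for name, sub in (("shared", shared_a), ("unique_a", unique_a), ("unique_b", unique_b)):
        try:
            sig = spectra.signature_96(sub, sim.genome)
            report["signatures"][name] = {"n": int(sig.attrs["n_used"]),
                                          "top_context": sig.idxmax(),
                                          "top_fraction": float(sig.max())}
        except ValueError:
            report["signatures"][name] = {"n": 0}

    ros_ids_a = kept_a.ref + ">" + kept_a.alt
    report["vaf"] = {
        "shared": _vaf_stats(shared_a),
        "unique_ros_a": _vaf_stats(unique_a[(unique_a.ref + ">" + unique_a.alt)
                                            .isin(["C>A", "G>T"])]),
        "unique_uv_a": _vaf_stats(unique_a[(unique_a.ref + ">" + unique_a.alt)
                                           .isin(["C>T", "G>A"])]),
    }

    report["phasing"] = {}
    segments = {}
    skew_tracks = {}
    # bin geometry defaults to the desk-scale simulated genomes; pass the
    # 10 Mb / 100 kb geometry for full-size genomes
    bins = mutio.sliding_bins(sim.genome.chrom_sizes, width=bin_width, step=bin_step)
    for label, calls in (("sister1", kept_a), ("sister2", kept_b)):
        codes = phasing.orientation_codes(calls, "UV")
        if not codes:
            continue
        st = phasing.rl20(codes)
        report["phasing"][label] = {
            "rl20": st.rl20, "n1": st.n1, "n2": st.n2,
            "n_runs": st.n_runs, "p_value": st.p_value,
        }
        segments[label] = phasing.segment_genome(codes)
        skew_tracks[label] = phasing.skew_track(codes, bins)
    stage_counts["segments"] = {k: len(v) for k, v in segments.items()}

    null_over, null_matched = None, None
    if skew_tracks:
        counts = skew_tracks["sister1"].query("n_informative >= 10").n_informative
        if len(counts):
            null_over, null_matched = phasing.bernoulli_null(
                len(counts), counts.to_numpy(), config.f_background,
                rng=np.random.default_rng(config.seed + 11))
            report["bernoulli_null"] = {
                "phased_probs": phasing.bernoulli_phased_probs(config.f_background),
                "n_bins": int(len(counts)),
            }

    if len(skew_tracks) == 2:
        try:
            report["mirror_R"] = phasing.mirror_correlation(
                skew_tracks["sister1"], skew_tracks["sister2"])
        except ValueError as exc:
            report["mirror_R"] = None
            log.warning("mirror correlation unavailable: %s", exc)

    if segments:
        ev = sce.detect_sce(segments["sister1"],
                            segments.get("sister2"), sample_id="sister1")
        report["sce"] = {"n_events": int(len(ev)),
                         "n_reciprocal": int(ev.reciprocal_in_sister.sum())}
        stage_counts["sce"] = {"events": len(ev)}

    tandems = multiallele.find_tandems(kept_a, sim.genome)
    report["multiallele"] = {"n_tandem_candidates": len(tandems)}

    report["tcr"] = {}
    for cls in ("UV", "ROS"):
        try:
            rates = txnrepair.stranded_rates(kept_a, sim.genome.genes, sim.genome, cls)
            report["tcr"][cls] = rates.to_dict(orient="records")
        except ValueError as exc:
            report["tcr"][cls] = None
            log.warning("stranded rates unavailable for %s: %s", cls, exc)

    report["manifest"]["stage_counts"] = stage_counts
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        mutio.write_mutations(kept_a, out / "sister1.calls.tsv")
        mutio.write_mutations(kept_b, out / "sister2.calls.tsv")
        for label, seg in segments.items():
            seg.to_csv(out / f"{label}.segments.bed", sep="\t", index=False, header=False)
        for label, track in skew_tracks.items():
            track.to_csv(out / f"{label}.skew.tsv", sep="\t", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report


def run_f1(config: simgen.SimConfig, outdir: Optional[str] = None) -> dict:
    """F1 pipeline: haplotype assignment, per-haplotype segmentation,
    phase-agreement statistics and the X false-assignment rate."""
    if not config.f1_mode:
        config = dataclasses.replace(config, f1_mode=True)
    sim = simgen.simulate_sister_pair(config)
    calls = sim.calls_a.copy().reset_index(drop=True)
    calls["mutation_id"] = [f"m{i:06d}" for i in range(len(calls))]
    kept, _ = mutio.filter_mutations(calls)
    if sim.genome.snps is not None:
        kept = mutio.remove_snp_overlaps(kept, {c: p for c, (p, _a) in sim.genome.snps.items()})

    reads = simgen.emit_hap_reads(kept, config, np.random.default_rng(config.seed + 7))
    hap_calls = haplo.assign_haplotype(reads)
    merged = kept.merge(hap_calls, on="mutation_id")
    report: dict = {"manifest": {"config_hash": config_hash(config),
                                 "seed": config.seed, "version": __version__}}
    report["assignment"] = {
        "n_total": int(len(merged)),
        "n_assigned": int((merged.label != "ND").sum()),
        "fraction_assigned": float((merged.label != "ND").mean()) if len(merged) else np.nan,
    }

    on_x = merged[merged.chrom == config.x_chrom]
    if (on_x.label != "ND").any():
        truth = "HAP_A"          # simulator places X mutations on homolog 0
        report["x_false_assignment_rate"] = haplo.x_false_assignment_rate(
            on_x[["mutation_id", "label"]].assign(label=on_x.label), truth)
    else:
        report["x_false_assignment_rate"] = None

    try:
        per_seg, genome_wide = haplo.haplotype_phase_agreement(merged, hap_calls, "UV")
        report["phase_agreement"] = {"genome_wide": float(genome_wide),
                                     "n_segments": int(len(per_seg))}
    except ValueError as exc:
        report["phase_agreement"] = None
        log.warning("phase agreement unavailable: %s", exc)

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        merged.to_csv(out / "haplotype_calls.tsv", sep="\t", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report
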