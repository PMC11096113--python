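"""Gene models, template-strand assignment, stranded and accessibility rates."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from lesionphase import mutio, simgen, txnrepair


class TestGeneModels:
    def _annotation(self):
        return pd.DataFrame([
            {"gene_id": "g1", "chrom": "chr1", "strand": "+", "start": 10_000, "end": 20_000},
            {"gene_id": "g2", "chrom": "chr1", "strand": "-", "start": 50_000, "end": 70_000},
            {"gene_id": "g3", "chrom": "chr1", "strand": "+", "start": 100_000, "end": 100_800},
            {"gene_id": "g4", "chrom": "chr1", "strand": "+", "start": 200_000, "end": 230_000},
            {"gene_id": "g5", "chrom": "chr1", "strand": "+", "start": 300_000, "end": 320_000},
        ])

    def _tpm(self, vals):
        return pd.DataFrame({"gene_id": list(vals), "tpm": list(vals.values())})

    def test_zero_tpm_is_bin_one(self):
        genes = txnrepair.build_gene_models(
            self._annotation(), self._tpm({"g1": 0.0, "g2": 5.0, "g4": 1.0, "g5": 8.0}))
        assert genes.set_index("gene_id").loc["g1", "bin"] == 1

    def test_tpm_one_is_expressed(self):
        genes = txnrepair.build_gene_models(
            self._annotation(), self._tpm({"g1": 0.0, "g2": 5.0, "g4": 1.0, "g5": 8.0}))
        # log2(1 + 0.1) > 0, so TPM = 1 lands in an expressed bin
        assert genes.set_index("gene_id").loc["g4", "bin"] >= 2

    def test_short_gene_filtered(self):
        genes = txnrepair.build_gene_models(
            self._annotation(), self._tpm({"g1": 1, "g2": 1, "g3": 1, "g4": 1, "g5": 1}))
        assert "g3" not in set(genes.gene_id)      # 800 bp < 1 kb

    def test_missing_tpm_excluded(self):
        genes = txnrepair.build_gene_models(
            self._annotation(), self._tpm({"g1": 1.0, "g4": 1.0, "g5": 1.0}))
        assert "g2" not in set(genes.gene_id)

    def test_close_neighbours_removed(self):
        ann = pd.concat([self._annotation(), pd.DataFrame([
            {"gene_id": "g6", "chrom": "chr1", "strand": "+",
             "start": 20_500, "end": 30_000}])])
        genes = txnrepair.build_gene_models(
            ann, self._tpm({"g1": 1, "g2": 1, "g4": 1, "g5": 1, "g6": 1}))
        # g1 ends at 20,000 and g6 starts at 20,500: both inside the 1 kb gap
        assert {"g1", "g6"} & set(genes.gene_id) == set()

    def test_tss_from_max_atac_transcript(self):
        ann = pd.DataFrame([
            {"gene_id": "g1", "chrom": "chr1", "strand": "+", "start": 10_000, "end": 30_000},
            {"gene_id": "g1", "chrom": "chr1", "strand": "+", "start": 14_000, "end": 30_000},
        ])
        atac = lambda chrom, lo, hi: 100.0 if lo < 14_000 <= hi else 1.0
        genes = txnrepair.build_gene_models(ann, self._tpm({"g1": 5.0}), atac_signal=atac)
        assert genes.start.iloc[0] == 14_000

    def test_expressed_tertiles(self):
        ann = pd.DataFrame([{"gene_id": f"g{i:02d}", "chrom": "chr1", "strand": "+",
                             "start": i * 10_000, "end": i * 10_000 + 5_000}
                            for i in range(12)])
        tpm = {f"g{i:02d}": 0.0 for i in range(3)}
        tpm.update({f"g{i:02d}": float(2 ** i) for i in range(3, 12)})
        genes = txnrepair.build_gene_models(ann, self._tpm(tpm))
        counts = genes["bin"].value_counts()
        assert counts[1] == 3 and counts[2] == counts[3] == counts[4] == 3


class TestTemplateStrand:
    def _genes(self):
        return pd.DataFrame([
            {"gene_id": "gp", "chrom": "chr1", "strand": "+", "start": 0, "end": 10_000, "bin": 3},
            {"gene_id": "gm", "chrom": "chr1", "strand": "-", "start": 20_000, "end": 30_000, "bin": 3},
        ])

    @pytest.mark.parametrize("pos,ref,alt,cls,expected", [
        (25_000, "C", "T", "UV", "TEMPLATE"),       # C>T in a minus-strand gene
        (5_000, "C", "T", "UV", "NON_TEMPLATE"),    # C>T in a plus-strand gene
        (5_000, "G", "A", "UV", "TEMPLATE"),        # G>A in a plus-strand gene
        (25_000, "G", "T", "ROS", "TEMPLATE"),      # G>T in a minus-strand gene
        (5_000, "C", "A", "ROS", "TEMPLATE"),       # C>A in a plus-strand gene
        (15_000, "C", "T", "UV", "NA"),             # intergenic
        (5_000, "T", "A", "UV", "NA"),              # outside the class
    ])
    def test_rules(self, pos, ref, alt, cls, expected):
        calls = pd.DataFrame([{"chrom": "chr1", "pos": pos, "ref": ref, "alt": alt}])
        labels = txnrepair.assign_template_strand(calls, self._genes(), cls)
        assert labels.iloc[0] == expected

    def test_strand_swap_swaps_labels(self):
        rng = np.random.default_rng(0)
        calls = pd.DataFrame({
            "chrom": "chr1",
            "pos": rng.integers(1, 30_000, size=200),
            "ref": rng.choice(["C", "G"], size=200),
        })
        calls["alt"] = np.where(calls.ref == "C", "T", "A")
        genes = self._genes()
        flipped = genes.assign(strand=genes.strand.map({"+": "-", "-": "+"}))
        a = txnrepair.assign_template_strand(calls, genes, "UV")
        b = txnrepair.assign_template_strand(calls, flipped, "UV")
        swap = {"TEMPLATE": "NON_TEMPLATE", "NON_TEMPLATE": "TEMPLATE", "NA": "NA"}
        assert (a.map(swap) == b).all()

    def test_partition_of_class_calls(self):
        rng = np.random.default_rng(1)
        calls = pd.DataFrame({
            "chrom": "chr1", "pos": rng.integers(1, 40_000, size=300),
            "ref": rng.choice(["C", "G", "T"], size=300)})
        calls["alt"] = calls.ref.map({"C": "T", "G": "A", "T": "G"})
        labels = txnrepair.assign_template_strand(calls, self._genes(), "UV")
        assert set(labels.unique()) <= {"TEMPLATE", "NON_TEMPLATE", "NA"}
        assert len(labels) == len(calls)


class TestRates:
    def test_symmetric_simulation_near_unity(self, small_config):
        """Without any repair, template and non-template rates match the
        genome average."""
        cfg = dataclasses.replace(small_config, seed=201, uv_lesion_rate=6e-3,
                                  ros_rate=0.0, gens_pre_split=0,
                                  repair_global=0.0,
                                  repair_tcr_by_bin={1: 0., 2: 0., 3: 0., 4: 0.})
        sim = simgen.simulate_sister_pair(cfg)
        calls = pd.concat([mutio.filter_mutations(sim.calls_a)[0],
                           mutio.filter_mutations(sim.calls_b)[0]])
        rates = txnrepair.stranded_rates(calls, sim.genome.genes, sim.genome, "UV")
        assert np.allclose(rates.relative_rate, 1.0, atol=0.25)

    def test_whole_genome_peaks_ratio_one(self, default_sim, default_kept):
        kept_a, _ = default_kept
        peaks = pd.DataFrame([{"chrom": c, "start": 0, "end": s}
                              for c, s in default_sim.genome.chrom_sizes.items()])
        ratio = txnrepair.accessibility_rates(kept_a, peaks, default_sim.genome, "ROS")
        assert ratio == pytest.approx(1.0, abs=1e-9)

    def test_no_calls_in_peaks_zero(self, default_sim, default_kept):
        kept_a, _ = default_kept
        # a peak territory guaranteed free of calls
        sub = kept_a[kept_a.chrom == "chr1"]
        free = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 0}])
        lo = int(sub.pos.min())
        if lo > 100:
            free = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": lo - 50}])
        ratio = txnrepair.accessibility_rates(kept_a, free, default_sim.genome, "ROS")
        assert ratio == 0.0

    def test_zero_peak_territory_rejected(self, default_sim, default_kept):
        kept_a, _ = default_kept
        with pytest.raises(ValueError):
            txnrepair.accessibility_rates(kept_a, pd.DataFrame(columns=["chrom", "start", "end"]),
                                          default_sim.genome, "ROS")


class TestMetaplot:
    def test_flat_coverage_constant(self):
        cov = {"chr1": np.full(10_000, 7.0)}
        muts = pd.DataFrame({"chrom": "chr1", "pos": [5_000, 6_000]})
        out = txnrepair.accessibility_metaplot(muts, cov, flank=500, smooth=1,
                                               pseudocount=0.0)
        assert np.allclose(out.log2_coverage, np.log2(7.0))

    def test_dip_at_mutations(self):
        cov = np.full(10_000, 50.0)
        for c in (3_000, 7_000):
            cov[c - 100:c + 100] = 5.0
        muts = pd.DataFrame({"chrom": "chr1", "pos": [3_001, 7_001]})
        out = txnrepair.accessibility_metaplot(muts, {"chr1": cov}, flank=1_000)
        center = out.loc[out.offset.abs() < 50, "log2_coverage"].mean()
        edge = out.loc[out.offset.abs() > 800, "log2_coverage"].mean()
        assert center < edge

    def test_smooth_one_is_identity(self):
        rng = np.random.default_rng(2)
        cov = {"chr1": rng.poisson(20, size=5_000).astype(float)}
        muts = pd.DataFrame({"chrom": "chr1", "pos": [2_500]})
        raw = txnrepair.accessibility_metaplot(muts, cov, flank=100, smooth=1)
        sm = txnrepair.accessibility_metaplot(muts, cov, flank=100, smooth=21)
        assert not np.allclose(raw.log2_coverage, sm.log2_coverage)
        expected = np.log2(cov["chr1"][2_399:2_600] + 1.0)
        assert np.allclose(raw.log2_coverage, expected)
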