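"""Forward simulator of burst (UV-like) and chronic (ROS-like) mutagenesis.

The simulator follows a diploid genome through a single acute burst of
strand-specific pyrimidine-dimer lesions in G1 of a penned founder cell, the
first mitosis that separates the two lesion-bearing strand sets into the two
mitotic sisters (lesion segregation), optional sister-chromatid exchange at
that mitosis, lesion persistence across further cycles (the source of
multiallelic tandem variation), and a chronic strand-agnostic G>T process
running both before and after the sister split. It emits mutation tables with
binomially sampled VAFs, read-level observations at tandem sites, and
haplotype-tagged reads for F1-style phasing, all with ground-truth labels.

Strand-level VAF bookkeeping
----------------------------
A mutation fixed by translesion bypass at division ``d`` of the clone
(``d=0`` is the division that creates the two sisters) first exists on a
single nascent strand; one further replication turns it into a stable
heterozygous lineage occupying a cell fraction of ``2**-(d+1)``, i.e. an
expected VAF of ``2**-(d+2)``. Ancestral chronic mutations are duplex-fixed
heterozygotes in the penned founder and therefore sit at VAF 0.5 in both
sisters; that gap (0.5 versus 0.25) is what separates shared from unique
mutations in the VAF dimension. A lesion that persists one extra cycle fixes
its second event one division later, hence the 2:1 VAF ratio at multiallelic
tandem sites.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

# base encoding: A=0, C=1, G=2, T=3; complement is 3 - code
BASES = np.array(["A", "C", "G", "T"])
CODE = {b: i for i, b in enumerate(BASES)}

# alignment-style metrics emitted for simulated calls; all pass the default
# post-calling filter so that filtering decisions are driven by real fields
PASSING_METRICS = {
    "VariantAlleleCountControl": 0,
    "VariantMapQualMedian": 60.0,
    "MapQualDiffMedian": 0.0,
    "LowMapQual": 0.0,
    "VariantBaseQualMedian": 37.0,
    "VariantStrandBias": 0.5,
    "ReferenceStrandBias": 0.5,
    "DistanceToAlignmentEndMedian": 25.0,
    "DistanceToAlignmentEndMAD": 10.0,
}


def _default_chroms() -> dict[str, int]:
    sizes = {f"chr{i}": 10_000_000 for i in range(1, 6)}
    sizes["chrX"] = 6_000_000
    return sizes


@dataclass
class SimConfig:
    """All simulator rates and bookkeeping parameters.

    Rates are per-site or per-genome probabilities/expectations as noted.
    Defaults emulate the acute-UV + chronic-ROS sister-pair experiment at
    desk scale: a ~56 Mb genome calibrated to carry several thousand UV-class
    mutations per sister and ~100 chronic G>T events per generation.
    """

    seed: int = 0
    chrom_sizes: dict = field(default_factory=_default_chroms)
    gc_fraction: float = 0.42
    # --- acute burst ---
    uv_lesion_rate: float = 8e-4       # lesions per dipyrimidine site per strand
    repair_global: float = 0.5         # pre-S removal probability, everywhere
    repair_tcr_by_bin: dict = field(default_factory=lambda: {1: 0.5, 2: 0.7, 3: 0.8, 4: 0.9})
    persistence: float = 0.15          # lesion survives to the next cycle
    bypass_mut_prob: float = 0.8       # error-prone bypass fixes a mutation
    cc_three_prime_bias: float = 0.8   # 3' C of a CC dimer mutates first
    cc_tt_prob: float = 0.25           # a CC bypass mutates both bases (CC>TT)
    bypass_spectrum: dict = field(default_factory=lambda: {"T": 0.92, "A": 0.05, "G": 0.03})
    # --- chronic process ---
    ros_rate: float = 100.0            # G>T per genome per generation
    ros_txn_suppression_by_bin: dict = field(default_factory=lambda: {1: 1.0, 2: 0.8, 3: 0.65, 4: 0.5})
    ros_access_multiplier: float = 1.0
    # --- lineage ---
    sce_rate: float = 0.92             # crossovers per chromosome at the first mitosis
    gens_pre_split: int = 20
    gens_post_split: int = 10
    retention_mode: str = "random"     # random | opposite | same (strand retention across homologs)
    # --- sequencing ---
    coverage: float = 60.0
    read_len: int = 100
    insert_len: int = 300
    vaf_floor: float = 0.02            # events below this expected VAF are not tracked
    # --- annotation scale ---
    genes_per_mb: float = 6.0
    gene_len_range: tuple = (5_000, 40_000)
    peaks_per_mb: float = 10.0
    peak_len: int = 1_000
    # --- null-model / F1 ---
    f_background: float = 0.0          # background fraction of UV-class calls
    f1_mode: bool = False
    snp_density: float = 0.0074        # SNPs per bp between the two haplotypes
    hap_tag_error: float = 0.0         # per-site probability all tags are flipped
    x_chrom: str = "chrX"

    def __post_init__(self) -> None:
        if not self.chrom_sizes:
            raise ValueError("chrom_sizes must be nonempty")
        for name, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"zero-length chromosome {name!r}")
        for name in ("repair_global", "persistence", "bypass_mut_prob",
                     "cc_three_prime_bias", "cc_tt_prob", "f_background",
                     "hap_tag_error", "gc_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("uv_lesion_rate", "ros_rate", "sce_rate", "snp_density", "coverage"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.gens_pre_split < 0 or self.gens_post_split < 0:
            raise ValueError("generation counts must be >= 0")
        if abs(sum(self.bypass_spectrum.values()) - 1.0) > 1e-9:
            raise ValueError("bypass_spectrum must sum to 1")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["gene_len_range"] = list(d["gene_len_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "gene_len_range" in d:
            d["gene_len_range"] = tuple(d["gene_len_range"])
        return cls(**d)


@dataclass
class GenomeModel:
    """Synthetic diploid reference: sequences, gene models, peaks, SNPs."""

    seqs: dict                       # chrom -> uint8 array (A=0,C=1,G=2,T=3)
    genes: pd.DataFrame              # gene_id, chrom, strand, start, end, tpm, bin
    peaks: pd.DataFrame              # chrom, start, end
    snps: Optional[dict]             # chrom -> (positions, alt_codes) or None
    chrom_sizes: dict

    def sequence(self, chrom: str) -> str:
        return "".join(BASES[self.seqs[chrom]])

    def write_fasta(self, path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.seqs.items():
                fh.write(f">{chrom}\n")
                s = "".join(BASES[seq])
                for i in range(0, len(s), width):
                    fh.write(s[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# genome construction

def _place_intervals(rng, size: int, n: int, lengths, gap: int = 1000):
    """Greedy non-overlapping placement of n intervals, >= gap apart."""
    starts = np.sort(rng.integers(0, max(size - int(np.max(lengths)) - 1, 1), size=n))
    out = []
    prev_end = -gap
    for s, ln in zip(starts, lengths):
        e = min(s + int(ln), size)
        if s >= prev_end + gap and e - s >= 1000:
            out.append((s, e))
            prev_end = e
    return out


def build_genome(config: SimConfig, rng: Optional[np.random.Generator] = None) -> GenomeModel:
    """Sample a random genome with genes, accessibility peaks and (F1) SNPs.

    Gene TPM values are drawn per expression bin so that the binning rules of
    the transcription-repair module (log2(TPM+0.1) <= 0 -> bin 1; expressed
    tertiles -> bins 2-4) recover the generating bins.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    gc = config.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    seqs, gene_rows, peak_rows = {}, [], []
    snps = {} if config.f1_mode else None
    gid = 0
    for chrom, size in config.chrom_sizes.items():
        seqs[chrom] = rng.choice(4, size=size, p=p).astype(np.uint8)

        n_genes = rng.poisson(config.genes_per_mb * size / 1e6)
        if n_genes:
            lengths = rng.integers(config.gene_len_range[0], config.gene_len_range[1], size=n_genes)
            for s, e in _place_intervals(rng, size, n_genes, lengths):
                gbin = int(rng.choice([1, 2, 3, 4], p=[0.55, 0.15, 0.15, 0.15]))
                # tpm ranges chosen so log2(tpm + 0.1) <= 0 exactly for bin 1
                tpm = {1: rng.uniform(0.0, 0.85),
                       2: rng.uniform(1.0, 4.0),
                       3: rng.uniform(4.0, 20.0),
                       4: rng.uniform(20.0, 400.0)}[gbin]
                gene_rows.append((f"g{gid:05d}", chrom, rng.choice(["+", "-"]), s, e, tpm, gbin))
                gid += 1

        n_peaks = rng.poisson(config.peaks_per_mb * size / 1e6)
        if n_peaks:
            lengths = np.full(n_peaks, config.peak_len)
            for s, e in _place_intervals(rng, size, n_peaks, lengths, gap=2000):
                peak_rows.append((chrom, s, e))

        if snps is not None:
            n_snp = rng.poisson(config.snp_density * size)
            pos = np.sort(rng.choice(size, size=min(n_snp, size), replace=False))
            alts = (seqs[chrom][pos] + rng.integers(1, 4, size=pos.size)) % 4
            snps[chrom] = (pos, alts.astype(np.uint8))

    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "strand", "start", "end", "tpm", "bin"])
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end"])
    return GenomeModel(seqs=seqs, genes=genes, peaks=peaks, snps=snps,
                       chrom_sizes=dict(config.chrom_sizes))


def _interval_lookup(starts: np.ndarray, ends: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Index of the sorted non-overlapping interval containing each pos, else -1."""
    if starts.size == 0:
        return np.full(pos.shape, -1, dtype=np.int64)
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, ends.size - 1)])
    return np.where(ok, idx, -1)


# ---------------------------------------------------------------------------
# acute burst

def dipyrimidine_candidates(seq: np.ndarray, strand: str) -> np.ndarray:
    """0-based start positions of dipyrimidine pairs containing >= 1 cytosine.

    Positions index the plus strand; for the Crick strand the pair occupies
    the same two plus-strand positions but reads as its reverse complement.
    TT (plus AA for Crick) dimers are omitted: under a C-targeted bypass
    spectrum they never yield a call.
    """
    a, b = seq[:-1], seq[1:]
    if strand == "W":
        pyr = ((a == 1) | (a == 3)) & ((b == 1) | (b == 3))
        has_c = (a == 1) | (b == 1)
    elif strand == "C":
        pyr = ((a == 0) | (a == 2)) & ((b == 0) | (b == 2))
        has_c = (a == 2) | (b == 2)   # plus G is a C on the Crick strand
    else:
        raise ValueError(f"strand must be W or C, got {strand!r}")
    return np.nonzero(pyr & has_c)[0]


def apply_uv_burst(genome: GenomeModel, config: SimConfig,
                   rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Place pyrimidine-dimer lesions on every strand of every homolog.

    Lesions land independently at dipyrimidine-capable sites with per-site
    probability ``uv_lesion_rate``; template-strand lesions inside gene bodies
    are then removed with the per-expression-bin transcription-coupled repair
    probability, all other lesions with ``repair_global``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    rows = []
    genes = genome.genes
    if config.uv_lesion_rate == 0:
        return pd.DataFrame(columns=["chrom", "homolog", "strand", "pos0", "pair", "span"])
    for chrom, seq in genome.seqs.items():
        n_homologs = 1 if (config.f1_mode and chrom == config.x_chrom) else 2
        g = genes[genes.chrom == chrom].sort_values("start")
        g_start = g.start.to_numpy()
        g_end = g.end.to_numpy()
        g_strand = g.strand.to_numpy()
        g_bin = g["bin"].to_numpy()
        for strand in ("W", "C"):
            cand = dipyrimidine_candidates(seq, strand)
            if cand.size == 0:
                continue
            for hom in range(n_homologs):
                hit = cand[rng.random(cand.size) < config.uv_lesion_rate]
                if hit.size == 0:
                    continue
                gi = _interval_lookup(g_start, g_end, hit)
                in_gene = gi >= 0
                # template strand: Crick for + genes, Watson for - genes
                tmpl = np.zeros(hit.size, dtype=bool)
                if in_gene.any():
                    gs = g_strand[np.clip(gi, 0, max(g_strand.size - 1, 0))]
                    tmpl = in_gene & (((gs == "+") & (strand == "C")) |
                                      ((gs == "-") & (strand == "W")))
                p_rep = np.full(hit.size, config.repair_global)
                if tmpl.any():
                    bins = g_bin[np.clip(gi, 0, max(g_bin.size - 1, 0))]
                    tcr = np.array([config.repair_tcr_by_bin.get(int(b), config.repair_global)
                                    for b in bins])
                    p_rep = np.where(tmpl, tcr, p_rep)
                keep = rng.random(hit.size) >= p_rep
                for pos in hit[keep]:
                    rows.append((chrom, hom, strand, int(pos)))
    lesions = pd.DataFrame(rows, columns=["chrom", "homolog", "strand", "pos0"])
    if len(lesions):
        # on-strand 5'->3' dinucleotide
        pairs = []
        for chrom, pos, strand in zip(lesions.chrom, lesions.pos0, lesions.strand):
            b5, b3 = genome.seqs[chrom][pos], genome.seqs[chrom][pos + 1]
            if strand == "C":
                b5, b3 = 3 - b3, 3 - b5
            pairs.append(BASES[b5] + BASES[b3])
        lesions["pair"] = pairs
        lesions["span"] = 2
    return lesions


# ---------------------------------------------------------------------------
# lineage

@dataclass
class LineageResult:
    truth_a: pd.DataFrame
    truth_b: pd.DataFrame
    sce_truth: pd.DataFrame          # chrom, homolog, pos0
    retained: dict                   # (chrom, homolog) -> strand retained by sister A proximally


def _retained_strand(base: str, breaks: np.ndarray, pos: int) -> str:
    flips = int(np.searchsorted(breaks, pos))
    if flips % 2 == 0:
        return base
    return "C" if base == "W" else "W"


def _bypass_outcome(rng, pair: str, config: SimConfig):
    """Which base(s) of an on-strand dipyrimidine mutate in one bypass.

    Returns a list of (offset_on_strand, alt_base) for the mutated cytosines;
    empty when the bypass is error-free.
    """
    if rng.random() >= config.bypass_mut_prob:
        return []
    spec_bases = list(config.bypass_spectrum)
    spec_p = np.array([config.bypass_spectrum[b] for b in spec_bases])
    c_offsets = [i for i, b in enumerate(pair) if b == "C"]
    if not c_offsets:
        return []
    if len(c_offsets) == 2 and rng.random() < config.cc_tt_prob:
        chosen = c_offsets
    elif len(c_offsets) == 2:
        chosen = [1] if rng.random() < config.cc_three_prime_bias else [0]
    else:
        chosen = c_offsets
    return [(off, rng.choice(spec_bases, p=spec_p)) for off in chosen]


def _plus_mutation(chrom: str, pos0: int, strand: str, offset: int, alt: str):
    """Convert an on-strand event to plus-strand (pos0, ref, alt)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if strand == "W":
        return pos0 + offset, "C", alt
    return pos0 + (1 - offset), "G", comp[alt]


def run_lineage(genome: GenomeModel, lesions: pd.DataFrame, config: SimConfig,
                rng: Optional[np.random.Generator] = None) -> LineageResult:
    """Segregate lesion-bearing strands into two sisters and fix mutations.

    At the first mitosis each homolog's two chromatids — one built on the
    Watson strand, one on the Crick strand — segregate randomly; all UV
    mutations a sister carries on a homolog therefore share one orientation.
    SCE events (Poisson per chromosome) reciprocally exchange distal segments
    between the chromatids, flipping the retained strand beyond the
    breakpoint in both sisters. Surviving lesions are re-bypassed each later
    cycle while they persist, fixing deeper (lower-VAF) events.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)

    # strand retention and SCE breakpoints per (chrom, homolog)
    retained, breaks = {}, {}
    sce_rows = []
    for chrom, size in genome.chrom_sizes.items():
        n_homologs = 1 if (config.f1_mode and chrom == config.x_chrom) else 2
        n_sce = rng.poisson(config.sce_rate)
        sce_pos = np.sort(rng.integers(0, size, size=n_sce))
        sce_hom = rng.integers(0, n_homologs, size=n_sce)
        for hom in range(n_homologs):
            if config.retention_mode == "random":
                base = "W" if rng.random() < 0.5 else "C"
            elif config.retention_mode == "opposite":
                base = "W" if hom == 0 else "C"
            elif config.retention_mode == "same":
                base = "W"
            else:
                raise ValueError(f"unknown retention_mode {config.retention_mode!r}")
            retained[(chrom, hom)] = base
            breaks[(chrom, hom)] = sce_pos[sce_hom == hom]
        for pos, hom in zip(sce_pos, sce_hom):
            sce_rows.append((chrom, int(hom), int(pos)))

    d_max = max(0, int(np.floor(-np.log2(config.vaf_floor) - 2)))
    truth = {"A": [], "B": []}
    for row in lesions.itertuples(index=False):
        ret_a = _retained_strand(retained[(row.chrom, row.homolog)],
                                 breaks[(row.chrom, row.homolog)], row.pos0)
        sister = "A" if ret_a == row.strand else "B"
        # bypass chain: division d = 0, 1, ... while the lesion survives
        d = 0
        while True:
            for off, alt in _bypass_outcome(rng, row.pair, config):
                pos0, ref, alt_p = _plus_mutation(row.chrom, row.pos0, row.strand, off, alt)
                if ref == alt_p:
                    continue
                truth[sister].append((row.chrom, pos0 + 1, row.homolog, ref, alt_p,
                                      "UV", row.strand, d, 2.0 ** -(d + 2)))
            if d >= d_max or rng.random() >= config.persistence:
                break
            d += 1

    # chronic process: ancestral (shared, duplex-fixed, VAF 0.5) and post-split
    chroms = list(genome.chrom_sizes)
    sizes = np.array([genome.chrom_sizes[c] for c in chroms], dtype=float)
    chrom_p = sizes / sizes.sum()
    gene_iv, gene_bin, peak_iv = {}, {}, {}
    for c in chroms:
        g = genome.genes[genome.genes.chrom == c].sort_values("start")
        gene_iv[c] = (g.start.to_numpy(), g.end.to_numpy())
        gene_bin[c] = g["bin"].to_numpy()
        pk = genome.peaks[genome.peaks.chrom == c].sort_values("start")
        peak_iv[c] = (pk.start.to_numpy(), pk.end.to_numpy())
    w_max = max(1.0, config.ros_access_multiplier)

    bin_mult = np.array([config.ros_txn_suppression_by_bin.get(b, 1.0) for b in (1, 2, 3, 4)])

    def _ros_positions(n_target: int):
        out = []
        guard = 0
        while len(out) < n_target and guard < 500:
            guard += 1
            m = max(256, 3 * (n_target - len(out)))
            ci = rng.choice(len(chroms), size=m, p=chrom_p)
            for k in np.nonzero(np.bincount(ci, minlength=len(chroms)))[0]:
                chrom = chroms[k]
                n_c = int((ci == k).sum())
                pos = rng.integers(0, genome.chrom_sizes[chrom], size=n_c)
                base = genome.seqs[chrom][pos]
                gc_site = (base == 1) | (base == 2)   # 8-oxo-G chemistry needs a G:C pair
                w = np.ones(n_c)
                gi = _interval_lookup(*gene_iv[chrom], pos)
                in_gene = gi >= 0
                if in_gene.any():
                    bins = gene_bin[chrom][np.clip(gi, 0, None)]
                    w = np.where(in_gene, bin_mult[np.clip(bins - 1, 0, 3)], w)
                in_peak = _interval_lookup(*peak_iv[chrom], pos) >= 0
                w = np.where(in_peak, w * config.ros_access_multiplier, w)
                acc = gc_site & (rng.random(n_c) < w / w_max)
                for p, b in zip(pos[acc], base[acc]):
                    out.append((chrom, int(p), int(b)))
                    if len(out) >= n_target:
                        break
                if len(out) >= n_target:
                    break
        return out[:n_target]

    def _ros_rows(n: int, gen: int, vaf: float):
        rows = []
        for chrom, pos, base in _ros_positions(n):
            hom = 0 if (config.f1_mode and chrom == config.x_chrom) else int(rng.integers(0, 2))
            ref, alt = ("G", "T") if base == 2 else ("C", "A")
            strand = "W" if base == 2 else "C"   # strand carrying the damaged G
            rows.append((chrom, pos + 1, hom, ref, alt, "ROS", strand, gen, vaf))
        return rows

    # strand-agnostic background calls inside the UV class (C>T / G>A looks
    # UV-like but derives from the chronic process); fraction f of the class
    if config.f_background > 0:
        f = config.f_background
        for sister in ("A", "B"):
            n_uv = sum(1 for r in truth[sister] if r[5] == "UV")
            n_bg = rng.poisson(f / (1.0 - f) * n_uv) if f < 1 else 0
            for chrom, pos, base in _ros_positions(n_bg):
                hom = 0 if (config.f1_mode and chrom == config.x_chrom) else int(rng.integers(0, 2))
                ref, alt = ("C", "T") if base == 1 else ("G", "A")
                strand = "W" if base == 1 else "C"
                truth[sister].append((chrom, pos + 1, hom, ref, alt, "BG",
                                      strand, 1, 0.25))

    n_anc = rng.poisson(config.ros_rate * config.gens_pre_split)
    anc = _ros_rows(n_anc, -1, 0.5)
    truth["A"].extend(anc)
    truth["B"].extend(anc)

    g_cap = int(np.floor(-np.log2(config.vaf_floor) - 1))
    for sister in ("A", "B"):
        for g in range(1, min(config.gens_post_split, g_cap) + 1):
            n = rng.poisson(config.ros_rate * 2 ** (g - 1))
            truth[sister].extend(_ros_rows(n, g, 2.0 ** -(g + 1)))

    cols = ["chrom", "pos", "homolog", "ref", "alt", "origin",
            "damaged_strand", "generation", "vaf_exp"]
    out = {}
    for sister in ("A", "B"):
        df = pd.DataFrame(truth[sister], columns=cols)
        df = df.sort_values(["chrom", "pos"]).reset_index(drop=True)
        df["founder_clone"] = sister
        out[sister] = df
    sce_truth = pd.DataFrame(sce_rows, columns=["chrom", "homolog", "pos0"])
    return LineageResult(truth_a=out["A"], truth_b=out["B"],
                         sce_truth=sce_truth, retained=retained)


# ---------------------------------------------------------------------------
# sampling

def expand_and_sample(truth: pd.DataFrame, config: SimConfig,
                      rng: Optional[np.random.Generator] = None,
                      sample_id: str = "sim", min_alt: int = 1) -> pd.DataFrame:
    """Sequence a clone: binomial alt counts at Poisson depth per true mutation."""
    if config.coverage <= 0:
        raise ValueError("coverage must be > 0")
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    n = len(truth)
    depth = rng.poisson(config.coverage, size=n)
    depth = np.maximum(depth, 1)
    alt = rng.binomial(depth, truth.vaf_exp.to_numpy())
    calls = truth.copy()
    calls["depth"] = depth
    calls["alt_count"] = alt
    calls["vaf"] = alt / depth
    calls["sample_id"] = sample_id
    calls["VariantAlleleCount"] = alt
    for k, v in PASSING_METRICS.items():
        calls[k] = v
    calls = calls[calls.alt_count >= min_alt].reset_index(drop=True)
    return calls


@dataclass
class SisterPair:
    genome: GenomeModel
    lesions: pd.DataFrame
    lineage: LineageResult
    calls_a: pd.DataFrame
    calls_b: pd.DataFrame
    config: SimConfig


def simulate_sister_pair(config: SimConfig,
                         genome: Optional[GenomeModel] = None) -> SisterPair:
    """End-to-end simulation of one penned founder and its two sister clones."""
    rng = np.random.default_rng(config.seed)
    if genome is None:
        genome = build_genome(config, rng)
    lesions = apply_uv_burst(genome, config, rng)
    lineage = run_lineage(genome, lesions, config, rng)
    calls_a = expand_and_sample(lineage.truth_a, config, rng, sample_id="sister1")
    calls_b = expand_and_sample(lineage.truth_b, config, rng, sample_id="sister2")
    return SisterPair(genome=genome, lesions=lesions, lineage=lineage,
                      calls_a=calls_a, calls_b=calls_b, config=config)


# ---------------------------------------------------------------------------
# read-level emissions

def _read_seq(genome: GenomeModel, chrom: str, pos0: int, allele: str,
              flank: int) -> Optional[str]:
    seq = genome.seqs[chrom]
    lo, hi = pos0 - flank, pos0 + 2 + flank
    if lo < 0 or hi > seq.size:
        return None
    s = "".join(BASES[seq[lo:hi]])
    return s[:flank] + allele + s[flank + 2:]


def simulate_tandem_sites(config: SimConfig, n_sites: int, extra_cycles: int = 1,
                          genome: Optional[GenomeModel] = None,
                          rng: Optional[np.random.Generator] = None,
                          read_flank: int = 30):
    """Simulate tandem CC dimer sites whose lesion persists ``extra_cycles``.

    Each site receives one bypass event per cycle (division 0 plus
    ``extra_cycles`` further divisions), drawn independently from the CC
    bypass rules, then dual-covering reads are emitted at the configured
    coverage. Returns ``(sites, reads)``: a site table with true event VAFs
    and a read table with per-read base calls, haplotype tags and sequence.
    """
    if config.bypass_mut_prob <= 0:
        raise ValueError("tandem simulation needs bypass_mut_prob > 0")
    if rng is None:
        rng = np.random.default_rng(config.seed + 4)
    if genome is None:
        genome = build_genome(config, rng)

    # CC pairs on the Watson strand, one homolog, well inside the chromosome
    site_rows, read_rows = [], []
    chroms = list(genome.seqs)
    cc_pool = []
    for chrom in chroms:
        seq = genome.seqs[chrom]
        cc = np.nonzero((seq[:-1] == 1) & (seq[1:] == 1))[0]
        cc = cc[(cc > read_flank + 2) & (cc < seq.size - read_flank - 4)]
        cc_pool.extend((chrom, int(p)) for p in cc)
    if len(cc_pool) < n_sites:
        raise ValueError("genome too small for requested tandem site count")
    pick = rng.choice(len(cc_pool), size=n_sites, replace=False)

    p_assign = 1.0 - np.exp(-config.snp_density * (2 * config.read_len + config.insert_len))
    for si, idx in enumerate(pick):
        chrom, pos0 = cc_pool[idx]
        site_id = f"ts{si:04d}"
        hom = int(rng.integers(0, 2))
        # one bypass outcome per cycle; alleles as dinucleotides vs ref CC
        alleles, vafs = [], []
        for d in range(extra_cycles + 1):
            events = []
            while not events:     # a persisting lesion is bypassed every cycle
                events = _bypass_outcome(rng, "CC", config)
            ab = list("CC")
            for off, alt in events:
                ab[off] = alt
            alleles.append("".join(ab))
            vafs.append(2.0 ** -(d + 2))
        # allele fractions among reads; overlapping events of later cycles
        # never co-occur on a cell with earlier alleles (distinct lineages)
        frac = {}
        for a, v in zip(alleles, vafs):
            frac[a] = frac.get(a, 0.0) + 2 * v * 0.5    # cell fraction * het
        ref_frac = 1.0 - sum(frac.values())
        allele_list = list(frac) + ["CC"]
        probs = np.array([frac[a] for a in frac] + [max(ref_frac, 0.0)])
        probs = probs / probs.sum()
        depth = max(int(rng.poisson(config.coverage)), 1)
        counts = rng.multinomial(depth, probs)
        flip_site = config.f1_mode and rng.random() < config.hap_tag_error
        ri = 0
        for a, c in zip(allele_list, counts):
            for _ in range(c):
                if config.f1_mode and rng.random() < p_assign:
                    tag = "AB"[hom] if not flip_site else "AB"[1 - hom]
                else:
                    tag = "unassignable"
                read_rows.append((f"{site_id}_r{ri:03d}", site_id, a[0], a[1], tag,
                                  _read_seq(genome, chrom, pos0, a, read_flank)))
                ri += 1
        site_rows.append((site_id, chrom, pos0 + 1, pos0 + 2, "CC", hom,
                          ";".join(alleles), ";".join(f"{v:g}" for v in vafs)))

    sites = pd.DataFrame(site_rows, columns=["site_id", "chrom", "pos5", "pos3",
                                             "ref_pair", "homolog",
                                             "true_alleles", "true_vafs"])
    reads = pd.DataFrame(read_rows, columns=["read_id", "site_id", "base1",
                                             "base2", "hap_tag", "seq"])
    return sites, reads


def emit_hap_reads(calls: pd.DataFrame, config: SimConfig,
                   rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Haplotype-tagged alt-supporting reads for each mutation call.

    Each alt read is assignable with the probability that a read pair of the
    configured geometry overlaps at least one strain-discriminating SNP;
    assignable reads carry the tag of the mutation's true homolog, except at
    sites hit by locus-level tag swapping (``hap_tag_error``), where every
    tag at the site is flipped.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 5)
    p_assign = 1.0 - np.exp(-config.snp_density * (2 * config.read_len + config.insert_len))
    has_ids = "mutation_id" in calls.columns
    rows = []
    for i, row in enumerate(calls.itertuples(index=False)):
        mut_id = row.mutation_id if has_ids else f"m{i:06d}"
        flip = rng.random() < config.hap_tag_error
        for r in range(int(row.alt_count)):
            if rng.random() < p_assign:
                tag = "AB"[int(row.homolog)] if not flip else "AB"[1 - int(row.homolog)]
            else:
                tag = "unassignable"
            rows.append((f"{mut_id}_r{r:03d}", mut_id, row.alt, tag,
                         row.chrom, row.pos))
    return pd.DataFrame(rows, columns=["read_id", "mutation_id", "allele",
                                       "hap_tag", "chrom", "pos"])
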