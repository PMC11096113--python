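"""Strand-phasing analytics.

Informative mutations of a class (UV: C>T/G>A, ROS: C>A/G>T) are coded +1
for the cytosine-reference member and -1 for the guanine-reference member.
Under lesion segregation every homolog retains one lesion-bearing strand, so
codes form chromosome-scale runs; under chronic accumulation they are
exchangeable coin flips. The module provides the binned skew track, the rl20
run-length statistic with Wald-Wolfowitz runs-test significance, the 1:2:1
three-component Bernoulli null for the skew distribution, penalised
changepoint segmentation into phased/mixed segments, and the mirror-image
correlation between mitotic sisters.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

CLASS_MEMBERS = {
    "UV": {"C>T": 1, "G>A": -1},
    "ROS": {"C>A": 1, "G>T": -1},
}


def orientation_codes(calls: pd.DataFrame, mutation_class: str) -> dict:
    """Per-chromosome coordinate-ordered +/-1 orientation codes.

    Returns ``{chrom: (positions, codes)}`` with positions 1-based ascending.
    Calls outside the class are excluded; an empty class yields an empty dict.
    """
    members = CLASS_MEMBERS[mutation_class]
    ids = calls.ref + ">" + calls.alt
    sub = calls[ids.isin(members)].copy()
    if sub.empty:
        return {}
    sub["code"] = (sub.ref + ">" + sub.alt).map(members)
    out = {}
    for chrom, grp in sub.groupby("chrom", sort=True):
        grp = grp.sort_values("pos")
        out[chrom] = (grp.pos.to_numpy(), grp.code.to_numpy(dtype=np.int8))
    return out


def skew_track(codes: dict, bins: pd.DataFrame, min_informative: int = 10) -> pd.DataFrame:
    """Mean orientation code per genomic bin; bins with too few mutations unscored.

    Adds ``n_informative`` and ``skew`` (NaN when below ``min_informative``)
    to a copy of the bin table.
    """
    out = bins.copy()
    n_col = np.zeros(len(bins), dtype=int)
    v_col = np.full(len(bins), np.nan)
    for i, row in enumerate(bins.itertuples(index=False)):
        if row.chrom not in codes:
            continue
        pos, c = codes[row.chrom]
        lo = np.searchsorted(pos, row.start + 1)      # pos is 1-based
        hi = np.searchsorted(pos, row.end, side="right")
        n = hi - lo
        n_col[i] = n
        if n >= min_informative:
            v_col[i] = c[lo:hi].mean()
    out["n_informative"] = n_col
    out["skew"] = v_col
    return out


# ---------------------------------------------------------------------------
# rl20 and the runs test

@dataclass
class PhasingStats:
    rl20: int
    n1: int            # +1 codes
    n2: int            # -1 codes
    n_runs: int
    p_value: float


def _run_lengths(codes: np.ndarray) -> np.ndarray:
    if codes.size == 0:
        return np.array([], dtype=int)
    change = np.nonzero(np.diff(codes))[0]
    bounds = np.concatenate([[-1], change, [codes.size - 1]])
    return np.diff(bounds)


def rl20(codes: dict, top_fraction: float = 0.2) -> PhasingStats:
    """Run-length statistic: smallest run among the largest runs that jointly
    cover ``top_fraction`` of informative mutations.

    Runs are computed per chromosome, pooled over the genome, sorted by
    decreasing length and accumulated until at least 20% of informative
    mutations are covered; rl20 is the length of the last (smallest) run
    included. Significance is a two-sided Wald-Wolfowitz runs test on the
    pooled orientation counts and total observed runs.
    """
    all_runs, n1, n2 = [], 0, 0
    ordered = [codes[k][1] for k in sorted(codes)]
    for c in ordered:
        all_runs.append(_run_lengths(c))
        n1 += int((c == 1).sum())
        n2 += int((c == -1).sum())
    total = n1 + n2
    if total == 0:
        raise ValueError("no informative mutations")
    # the test statistic counts runs over the genome-wide concatenation so
    # that its null matches an exchangeable +/-1 sequence exactly
    n_runs = int(_run_lengths(np.concatenate(ordered)).size)
    runs = np.sort(np.concatenate(all_runs))[::-1]
    target = top_fraction * total
    cum = np.cumsum(runs)
    k = int(np.searchsorted(cum, target))          # first index reaching target
    k = min(k, runs.size - 1)
    value = int(runs[k])
    p = runs_test(n1, n2, n_runs) if (n1 and n2) else np.nan
    return PhasingStats(rl20=value, n1=n1, n2=n2, n_runs=n_runs, p_value=p)


def runs_test(n1: int, n2: int, n_runs: int) -> float:
    """Two-sided Wald-Wolfowitz runs test, normal approximation.

    mu_R = 2 n1 n2/(n1+n2) + 1;
    var_R = 2 n1 n2 (2 n1 n2 - n1 - n2) / ((n1+n2)^2 (n1+n2-1)).
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("runs test undefined when one orientation is absent")
    n = n1 + n2
    mu = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n * n * (n - 1.0))
    if var <= 0:
        return 1.0
    z = (n_runs - mu) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def runs_distribution(n1: int, n2: int) -> dict:
    """Exact null distribution of the number of runs for n1 +1s and n2 -1s."""
    total = comb(n1 + n2, n1)
    dist = {}
    for k in range(1, min(n1, n2) + 1):
        dist[2 * k] = 2 * comb(n1 - 1, k - 1) * comb(n2 - 1, k - 1) / total
        p_odd = (comb(n1 - 1, k) * comb(n2 - 1, k - 1)
                 + comb(n1 - 1, k - 1) * comb(n2 - 1, k)) / total
        if p_odd:
            dist[2 * k + 1] = p_odd
    return dist


def runs_test_exact(n1: int, n2: int, n_runs: int) -> float:
    """Two-sided exact runs test by enumeration of the run-count distribution.

    The two-sided p-value sums the probability of all run counts at least as
    far from the expectation as the observed one.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("runs test undefined when one orientation is absent")
    dist = runs_distribution(n1, n2)
    mu = 2.0 * n1 * n2 / (n1 + n2) + 1.0
    d = abs(n_runs - mu)
    return float(min(1.0, sum(p for r, p in dist.items() if abs(r - mu) >= d - 1e-12)))


# ---------------------------------------------------------------------------
# Bernoulli null

def bernoulli_phased_probs(f_background: float) -> tuple:
    """Success probabilities (C-phased, mixed, G-phased) under background f.

    A background fraction f of class calls is strand-agnostic, so phased-bin
    success probabilities shift from {1, 0} by f/2 to {1 - f/2, f/2}.
    """
    if not 0.0 <= f_background <= 1.0:
        raise ValueError("f_background outside [0, 1]")
    return 1.0 - f_background / 2.0, 0.5, f_background / 2.0


def bernoulli_null(n_bins_observed: int, per_bin_mutation_counts,
                   f_background: float = 0.0, oversample: int = 100,
                   rng: Optional[np.random.Generator] = None):
    """Simulated skew distribution under the 1:2:1 lesion-segregation null.

    Bins are allocated C-phased : mixed : G-phased in 1:2:1 proportion; each
    bin draws its trial count by resampling the observed per-bin mutation
    counts and its successes from the component's Bernoulli probability.
    Returns ``(oversampled, matched)`` skew arrays with ``oversample * n``
    and exactly ``n`` bins for QQ comparison; skew = 2*successes/trials - 1.
    """
    counts = np.asarray(per_bin_mutation_counts, dtype=int)
    if counts.size == 0:
        raise ValueError("empty per-bin mutation count distribution")
    if rng is None:
        rng = np.random.default_rng(0)
    p_c, p_m, p_g = bernoulli_phased_probs(f_background)

    def sample(n: int) -> np.ndarray:
        n_c = n // 4
        n_g = n // 4
        n_m = n - n_c - n_g
        probs = np.concatenate([np.full(n_c, p_c), np.full(n_m, p_m), np.full(n_g, p_g)])
        probs = rng.permutation(probs)         # exchangeable bin order
        trials = rng.choice(counts, size=n, replace=True)
        trials = np.maximum(trials, 1)
        succ = rng.binomial(trials, probs)
        return 2.0 * succ / trials - 1.0

    return sample(oversample * n_bins_observed), sample(n_bins_observed)


# ---------------------------------------------------------------------------
# segmentation

def _pelt_mean(x: np.ndarray, penalty: float, min_size: int) -> list:
    """Changepoint indices for a mean-shift model with an L2 cost (PELT)."""
    n = x.size
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def cost(i: int, j: int) -> float:
        s = cs[j] - cs[i]
        return (cs2[j] - cs2[i]) - s * s / (j - i)

    f = np.full(n + 1, np.inf)
    f[0] = -penalty
    prev = np.zeros(n + 1, dtype=int)
    cands = np.array([0], dtype=int)
    for t in range(min_size, n + 1):
        open_s = cands[t - cands >= min_size]
        gated = cands[t - cands < min_size]
        seg = t - open_s
        s_sum = cs[t] - cs[open_s]
        v = f[open_s] + (cs2[t] - cs2[open_s]) - s_sum * s_sum / seg + penalty
        k = int(np.argmin(v))
        f[t] = v[k]
        prev[t] = open_s[k]
        # prune candidates that can never win again; keep gated ones
        keep = open_s[v - penalty <= f[t]]
        cands = np.concatenate([keep, gated, [t]]) if np.isfinite(f[t]) \
            else np.concatenate([keep, gated])
    cps = []
    t = n
    while t > 0:
        s = prev[t]
        if s > 0:
            cps.append(s)
        t = s
    return sorted(cps)


def _binseg_mean(x: np.ndarray, penalty: float, min_size: int) -> list:
    """Greedy binary segmentation fallback with the same cost and penalty."""
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def cost(i, j):
        s = cs[j] - cs[i]
        return (cs2[j] - cs2[i]) - s * s / (j - i)

    out = []

    def split(a, b):
        if b - a < 2 * min_size:
            return
        full = cost(a, b)
        best_gain, best_k = 0.0, None
        for k in range(a + min_size, b - min_size + 1):
            gain = full - cost(a, k) - cost(k, b)
            if gain > best_gain:
                best_gain, best_k = gain, k
        if best_k is not None and best_gain > penalty:
            split(a, best_k)
            out.append(best_k)
            split(best_k, b)

    split(0, x.size)
    return sorted(out)


def segment_chromosome(positions: np.ndarray, codes: np.ndarray, chrom: str,
                       tau: float = 0.5, min_seg_mutations: int = 20,
                       penalty: Optional[float] = None,
                       method: str = "pelt") -> pd.DataFrame:
    """Segment a chromosome's orientation codes into phased/mixed segments.

    Changepoints are found on the +/-1 sequence by penalised mean-shift
    segmentation (PELT by default, binary segmentation as fallback); each
    segment is classified C_PHASED when its mean code >= tau, G_PHASED when
    <= -tau, MIXED otherwise. Segment bounds are the first/last member
    mutation positions; interior bounds are midpoints between the flanking
    mutations. With fewer than ``min_seg_mutations`` mutations a single
    low-confidence MIXED segment is returned.
    """
    x = codes.astype(float)
    n = x.size
    cols = ["chrom", "start", "end", "state", "mean_skew", "n_mut", "low_confidence"]
    if n < min_seg_mutations:
        if n == 0:
            return pd.DataFrame(columns=cols)
        return pd.DataFrame([[chrom, int(positions[0]) - 1, int(positions[-1]),
                              "MIXED", float(x.mean()) if n else 0.0, n, True]],
                            columns=cols)
    if penalty is None:
        # 1.5x the BIC rate for a unit-variance mean shift: rejects the
        # one-sided runs that interleaved Poisson processes produce by chance
        # while detecting order-1 shifts spanning ~log(n) mutations
        penalty = 3.0 * np.log(max(n, 2))
    fn = _pelt_mean if method == "pelt" else _binseg_mean
    cps = fn(x, penalty, min_seg_mutations)
    bounds = [0] + cps + [n]
    rows = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        mean = float(x[a:b].mean())
        state = "C_PHASED" if mean >= tau else "G_PHASED" if mean <= -tau else "MIXED"
        start = int(positions[a]) - 1 if a == 0 else int((positions[a - 1] + positions[a]) // 2)
        end = int(positions[b - 1]) if b == n else int((positions[b - 1] + positions[b]) // 2)
        rows.append([chrom, start, end, state, mean, b - a, False])
    return pd.DataFrame(rows, columns=cols)


def segment_genome(codes: dict, **kwargs) -> pd.DataFrame:
    """Run :func:`segment_chromosome` over every chromosome with codes."""
    parts = [segment_chromosome(pos, c, chrom, **kwargs)
             for chrom, (pos, c) in sorted(codes.items())]
    if not parts:
        return pd.DataFrame(columns=["chrom", "start", "end", "state",
                                     "mean_skew", "n_mut", "low_confidence"])
    return pd.concat(parts, ignore_index=True)


def mirror_correlation(skew_sister1: pd.DataFrame, skew_sister2: pd.DataFrame,
                       min_shared: int = 10) -> float:
    """Pearson correlation of per-bin skew over bins scored in both sisters.

    Mitotic sisters are expected strongly negative (mirror-image phasing);
    unrelated clones are expected near zero.
    """
    m = skew_sister1.merge(skew_sister2, on=["chrom", "start", "end"],
                           suffixes=("_1", "_2"))
    m = m.dropna(subset=["skew_1", "skew_2"])
    if len(m) < min_shared:
        raise ValueError(f"only {len(m)} shared scored bins (< {min_shared})")
    a, b = m.skew_1.to_numpy(), m.skew_2.to_numpy()
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("constant skew track; correlation undefined")
    return float(stats.pearsonr(a, b)[0])
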