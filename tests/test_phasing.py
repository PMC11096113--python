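"""Phasing statistics: orientation codes, skew, rl20, runs test, the 1:2:1
Bernoulli null, segmentation and mirror correlation."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lesionphase import phasing


def _codes_df(ids, chrom="chr1"):
    rows = []
    for i, mid in enumerate(ids):
        ref, alt = mid.split(">")
        rows.append({"chrom": chrom, "pos": 100 * (i + 1), "ref": ref, "alt": alt})
    return pd.DataFrame(rows)


class TestOrientationCodes:
    def test_uv_convention(self):
        codes = phasing.orientation_codes(_codes_df(["C>T", "G>A", "C>T"]), "UV")
        assert list(codes["chr1"][1]) == [1, -1, 1]

    def test_non_class_excluded(self):
        calls = _codes_df(["T>A", "C>T"])
        assert list(phasing.orientation_codes(calls, "UV")["chr1"][1]) == [1]
        assert phasing.orientation_codes(_codes_df(["T>A"]), "UV") == {}

    def test_ros_uses_c_reference_convention(self):
        codes = phasing.orientation_codes(_codes_df(["C>A", "G>T"]), "ROS")
        assert list(codes["chr1"][1]) == [1, -1]


class TestSkewTrack:
    def test_bin_mean(self):
        ids = ["C>T"] * 6 + ["G>A"] * 4
        codes = phasing.orientation_codes(_codes_df(ids), "UV")
        bins = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [2000]})
        track = phasing.skew_track(codes, bins)
        assert track["skew"].iloc[0] == pytest.approx(0.2)
        assert track.n_informative.iloc[0] == 10

    def test_all_plus_is_one(self):
        codes = phasing.orientation_codes(_codes_df(["C>T"] * 12), "UV")
        bins = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [2000]})
        assert phasing.skew_track(codes, bins)["skew"].iloc[0] == 1.0

    def test_sparse_bin_unscored(self):
        codes = phasing.orientation_codes(_codes_df(["C>T"] * 9), "UV")
        bins = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [2000]})
        assert np.isnan(phasing.skew_track(codes, bins)["skew"].iloc[0])


def _rl20_oracle(runs_by_chrom, total):
    """Brute-force cumulative scan over descending pooled run lengths."""
    pooled = sorted([r for runs in runs_by_chrom for r in runs], reverse=True)
    acc = 0
    for r in pooled:
        acc += r
        if acc >= 0.2 * total:
            return r
    return pooled[-1]


def _runs_of(seq):
    out, cur = [], 1
    for a, b in zip(seq[:-1], seq[1:]):
        if a == b:
            cur += 1
        else:
            out.append(cur)
            cur = 1
    out.append(cur)
    return out


class TestRL20:
    def test_worked_example(self):
        # runs 5,3,2,1,1 over 12 mutations; 20% of 12 = 2.4 -> the largest
        # run alone covers it
        seq = [1] * 5 + [-1] * 3 + [1] * 2 + [-1, 1]
        codes = {"chr1": (np.arange(1, 13) * 10, np.array(seq))}
        assert phasing.rl20(codes).rl20 == 5

    def test_alternating_and_single_run(self):
        alt = np.array([1, -1] * 5)
        assert phasing.rl20({"c": (np.arange(1, 11), alt)}).rl20 == 1
        mono = np.ones(17, dtype=int)
        st_ = phasing.rl20({"c": (np.arange(1, 18), mono)})
        assert st_.rl20 == 17

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            phasing.rl20({})

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_chrom = int(rng.integers(1, 4))
        runs_by_chrom, codes = [], {}
        total = 0
        for c in range(n_chrom):
            n = int(rng.integers(1, 201))
            seq = rng.choice([-1, 1], size=n)
            codes[f"chr{c}"] = (np.arange(1, n + 1) * 7, seq)
            runs_by_chrom.append(_runs_of(list(seq)))
            total += n
        assert phasing.rl20(codes).rl20 == _rl20_oracle(runs_by_chrom, total)


class TestRunsTest:
    def test_expected_runs_closed_form(self):
        # mu_R = 2*5*5/10 + 1 = 6; a sequence with exactly 6 runs sits at the mean
        assert phasing.runs_test(5, 5, 6) == pytest.approx(1.0, abs=1e-9)

    def test_one_sided_orientation_rejected(self):
        with pytest.raises(ValueError):
            phasing.runs_test(0, 5, 1)

    def test_alternating_sequence_close_to_exact(self):
        # CGCGCGCGCG: n1 = n2 = 5, R = 10
        p_norm = phasing.runs_test(5, 5, 10)
        p_exact = phasing.runs_test_exact(5, 5, 10)
        assert abs(p_norm - p_exact) < 0.02

    def test_two_long_runs_extreme(self):
        assert phasing.runs_test(5000, 5000, 2) < 1e-15

    def test_exact_distribution_sums_to_one(self):
        for n1, n2 in [(3, 3), (5, 7), (2, 9)]:
            assert sum(phasing.runs_distribution(n1, n2).values()) == pytest.approx(1.0)

    def test_exact_matches_full_enumeration(self):
        """Closed-form run-count distribution versus explicit enumeration of
        every arrangement, for all n1+n2 <= 12."""
        for n1 in range(1, 11):
            for n2 in range(1, 13 - n1):
                n = n1 + n2
                counts = {}
                for ones in combinations(range(n), n1):
                    seq = np.full(n, -1)
                    seq[list(ones)] = 1
                    r = len(_runs_of(list(seq)))
                    counts[r] = counts.get(r, 0) + 1
                total = sum(counts.values())
                dist = phasing.runs_distribution(n1, n2)
                for r, c in counts.items():
                    assert dist.get(r, 0) == pytest.approx(c / total)
                # and the exact two-sided p agrees with enumeration
                mu = 2 * n1 * n2 / n + 1
                for r_obs in counts:
                    p_enum = sum(c for r, c in counts.items()
                                 if abs(r - mu) >= abs(r_obs - mu) - 1e-12) / total
                    assert phasing.runs_test_exact(n1, n2, r_obs) == pytest.approx(p_enum)


class TestBernoulliNull:
    def test_background_shifts_phased_probability(self):
        assert phasing.bernoulli_phased_probs(0.12) == pytest.approx((0.94, 0.5, 0.06))
        assert phasing.bernoulli_phased_probs(0.0) == pytest.approx((1.0, 0.5, 0.0))

    def test_one_two_one_allocation(self):
        rng = np.random.default_rng(0)
        over, matched = phasing.bernoulli_null(4000, [50], f_background=0.0,
                                               oversample=1, rng=rng)
        assert over.size == 4000 and matched.size == 4000
        # deterministic trials at f=0: exactly 1000 bins at +1, 1000 at -1
        assert (over == 1.0).sum() == 1000
        assert (over == -1.0).sum() == 1000

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            phasing.bernoulli_null(10, [], 0.0)

    def test_trimodal_at_f_zero(self):
        over, _ = phasing.bernoulli_null(2000, [100, 120, 140], 0.0,
                                         rng=np.random.default_rng(1))
        phased = np.abs(over) == 1.0
        assert phased.mean() == pytest.approx(0.5, abs=0.01)
        assert np.abs(over[~phased]).max() < 0.6


class TestSegmentation:
    def test_uniform_plus_single_segment(self):
        pos = np.arange(1, 101) * 1000
        seg = phasing.segment_chromosome(pos, np.ones(100, dtype=int), "chr1")
        assert len(seg) == 1
        assert seg.state.iloc[0] == "C_PHASED"

    def test_fair_coin_is_mixed(self):
        rng = np.random.default_rng(2)
        pos = np.arange(1, 501) * 1000
        seg = phasing.segment_chromosome(pos, rng.choice([-1, 1], 500), "chr1")
        assert (seg.state == "MIXED").all()

    def test_few_mutations_low_confidence(self):
        seg = phasing.segment_chromosome(np.array([10, 20, 30]),
                                         np.array([1, 1, 1]), "chr1")
        assert len(seg) == 1 and seg.low_confidence.iloc[0]
        assert seg.state.iloc[0] == "MIXED"

    def test_breakpoint_localised(self):
        """A phase switch is found within +/-2 Mb of truth in >= 95% of
        replicates at realistic mutation density."""
        hits = 0
        n_rep = 100
        for s in range(n_rep):
            rng = np.random.default_rng(1000 + s)
            # 10 Mb chromosome, 5 mutations per Mb, switch at 5 Mb
            pos = np.sort(rng.integers(1, 10_000_000, size=50))
            codes = np.where(pos < 5_000_000, 1, -1)
            seg = phasing.segment_chromosome(pos, codes, "chr1")
            bounds = seg.end.to_numpy()[:-1]
            if any(abs(b - 5_000_000) <= 2_000_000 for b in bounds):
                hits += 1
        assert hits >= 95

    def test_binseg_agrees_on_clean_shift(self):
        pos = np.arange(1, 201) * 1000
        codes = np.concatenate([np.ones(100), -np.ones(100)]).astype(int)
        a = phasing.segment_chromosome(pos, codes, "c", method="pelt")
        b = phasing.segment_chromosome(pos, codes, "c", method="binseg")
        assert list(a.state) == list(b.state) == ["C_PHASED", "G_PHASED"]


class TestMirrorCorrelation:
    def _track(self, skews):
        n = len(skews)
        return pd.DataFrame({"chrom": "chr1", "start": np.arange(n) * 10,
                             "end": (np.arange(n) + 1) * 10,
                             "n_informative": 50, "skew": skews})

    def test_exact_mirror_is_minus_one(self):
        rng = np.random.default_rng(3)
        s = rng.uniform(-1, 1, 40)
        assert phasing.mirror_correlation(self._track(s), self._track(-s)) == pytest.approx(-1.0)

    def test_identical_is_plus_one(self):
        s = np.random.default_rng(4).uniform(-1, 1, 40)
        assert phasing.mirror_correlation(self._track(s), self._track(s)) == pytest.approx(1.0)

    def test_independent_bins_uncorrelated(self):
        rng = np.random.default_rng(5)
        a, _ = phasing.bernoulli_null(500, [50], 0.0, oversample=1, rng=rng)
        b, _ = phasing.bernoulli_null(500, [50], 0.0, oversample=1, rng=rng)
        r = phasing.mirror_correlation(self._track(a), self._track(b))
        assert abs(r) < 0.2

    def test_constant_track_rejected(self):
        with pytest.raises(ValueError):
            phasing.mirror_correlation(self._track(np.ones(20)), self._track(np.ones(20)))

    def test_too_few_shared_bins_rejected(self):
        with pytest.raises(ValueError):
            phasing.mirror_correlation(self._track([0.1] * 5), self._track([0.2] * 5))
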