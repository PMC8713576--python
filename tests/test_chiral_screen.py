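"""Screen decoding: demultiplex, trimming, counting, exact test, consistency."""

import itertools
import random

import numpy as np
import pytest
from scipy.stats import binom

from stereocleave.chiral_screen import (
    DifferentialResult,
    MotifCountTable,
    WINDOWS,
    call_consistent_motifs,
    demultiplex,
    estimate_common_dispersion,
    extract_window_trimers,
    filter_and_count,
    test_differential as differential_abundance,
    trim_screen_read,
)
from stereocleave.core_stereo import SCHEMES

A5 = SCHEMES["L1"].adapter_5p  # TATCTGTGCATCC
A3 = SCHEMES["L1"].adapter_3p  # CAGTCAGCTGGAT


def _read(insert, a5=A5, a3=A3, tail="GTCAGTCAGG"):
    return a5 + insert + a3 + tail


class TestDemultiplex:
    def test_exact_index_routed_mismatch_discarded(self):
        records = [
            ("r1 1:N:0:AAAA", "ACGT", "IIII"),
            ("r2 1:N:0:AAAT", "ACGT", "IIII"),  # one mismatch -> discarded
            ("r3 1:N:0:CCCC", "ACGT", "IIII"),
        ]
        routed, discarded = demultiplex(records, {"s1": "AAAA", "s2": "CCCC"})
        assert [r[0].split()[0] for r in routed["s1"]] == ["r1"]
        assert [r[0].split()[0] for r in routed["s2"]] == ["r3"]
        assert discarded == 1

    def test_empty_input(self):
        routed, discarded = demultiplex([], {"s1": "AAAA"})
        assert routed == {"s1": []} and discarded == 0

    def test_duplicate_index_is_config_error(self):
        with pytest.raises(ValueError, match="duplicate"):
            demultiplex([], {"s1": "AAAA", "s2": "AAAA"})


class TestTrimming:
    def test_clean_read_yields_insert(self):
        insert, reason = trim_screen_read(_read("AAGTTAGTA"), SCHEMES["L1"])
        assert (insert, reason) == ("AAGTTAGTA", "ok")

    def test_read_starting_mid_adapter_rejected(self):
        read = _read("AAGTTAGTA")[4:]
        assert trim_screen_read(read, SCHEMES["L1"]) == (None, "no-5p-adapter")

    def test_missing_3p_adapter_rejected(self):
        read = A5 + "AAGTTAGTA" + "GGGGGGGGGGGGGGG"
        assert trim_screen_read(read, SCHEMES["L1"]) == (None, "no-3p-adapter")

    def test_single_substitution_boundary_matches_hamming_oracle(self):
        """floor(0.1 * 13) = 1 mismatch is allowed in the anchored 13-nt
        5' adapter; every single-substitution variant must pass and every
        double-substitution variant must fail (substitutions only)."""
        insert = "AAGTTAGTA"
        for i in range(len(A5)):
            for b in "ACGT":
                if b == A5[i]:
                    continue
                variant = A5[:i] + b + A5[i + 1:]
                got, reason = trim_screen_read(variant + insert + A3, SCHEMES["L1"])
                assert (got, reason) == (insert, "ok")
        rng = random.Random(0)
        for _ in range(25):
            i, j = rng.sample(range(len(A5)), 2)
            variant = list(A5)
            variant[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[variant[i]]
            variant[j] = {"A": "C", "C": "A", "G": "T", "T": "G"}[variant[j]]
            got, reason = trim_screen_read("".join(variant) + insert + A3, SCHEMES["L1"])
            assert (got, reason) == (None, "no-5p-adapter")


class TestFilterAndCount:
    def test_alphabet_and_length_rules(self):
        inserts = ["AAGTTAGTA", "AACTTAGTA", "AAGTTAGT", "AAGTTAGTAA"]
        counts1, discards1 = filter_and_count(inserts, SCHEMES["L1"])
        assert counts1 == {"AAGTTAGTA": 1}  # C-containing insert excluded
        assert discards1 == {"alphabet": 1, "length": 2}
        counts2, _ = filter_and_count(["AACTTATTA"], SCHEMES["L2"])
        assert counts2 == {"AACTTATTA": 1}  # C is legal under the CS2 alphabet
        counts3, discards3 = filter_and_count(["AACTTATTA"], SCHEMES["L1"])
        assert not counts3 and discards3 == {"alphabet": 1}

    def test_count_conservation(self):
        inserts = ["AAGTTAGTA"] * 3 + ["TTTTTTTT"] * 2 + ["CCCCCCCCC"]
        counts, discards = filter_and_count(inserts, SCHEMES["L1"])
        assert sum(counts.values()) + sum(discards.values()) == len(inserts)


class TestWindowExtraction:
    def test_window_slices_direct(self):
        table = extract_window_trimers({"ATAGTTAAT": 4})
        assert table.get("pos1-3", "ATA") == 4
        assert table.get("pos5-7", "TTA") == 4

    def test_per_window_exclusion(self):
        # G inside window 1 excludes the read from window 1 only
        table = extract_window_trimers({"ATGGTTAAT": 2})
        assert sum(c for (w, _m), c in table.counts.items() if w == "pos1-3") == 0
        assert table.get("pos5-7", "TTA") == 2

    def test_matches_brute_force_over_all_l1_nonamers(self):
        """Oracle: direct slicing of every 3^9 nonamer over the L1 alphabet."""
        alphabet = sorted(SCHEMES["L1"].alphabet)
        counts = {"".join(t): 1 for t in itertools.product(alphabet, repeat=9)}
        table = extract_window_trimers(counts)
        expected = {}
        for nonamer in counts:
            for name, sl in (("pos1-3", slice(0, 3)), ("pos5-7", slice(4, 7))):
                tri = nonamer[sl]
                if set(tri) <= set("AT"):
                    expected[(name, tri)] = expected.get((name, tri), 0) + 1
        assert table.counts == expected
        assert table.total_nonamers == 3**9
        for window, _ in WINDOWS:
            wsum = sum(c for (w, _m), c in table.counts.items() if w == window)
            assert wsum <= table.total_nonamers


def _table(counts, total, **kw):
    return MotifCountTable(counts, total, **kw)


class TestDifferential:
    def test_symmetric_counts_give_null(self):
        t = _table({("pos1-3", "TTT"): 10}, 1000)
        c = _table({("pos1-3", "TTT"): 10}, 1000)
        (res,) = differential_abundance(t, c)
        assert res.log2_fold_change == 0.0
        assert res.p_value == 1.0

    def test_extreme_split_matches_enumeration(self):
        """0 vs 20 at equal library size: the two-sided exact p-value is
        2 * (1/2)^20 (only k = 0 and k = 20 have as small a likelihood)."""
        t = _table({("pos1-3", "TTT"): 0}, 1000)
        c = _table({("pos1-3", "TTT"): 20}, 1000)
        (res,) = differential_abundance(t, c)
        assert res.p_value == pytest.approx(2 * 0.5**20, rel=1e-9)
        assert res.direction == "down"

    @pytest.mark.parametrize(
        "k_t,k_c,n_t,n_c",
        [(3, 17, 1000, 1000), (12, 8, 500, 1500), (0, 9, 2000, 1000),
         (25, 25, 800, 800), (1, 40, 3000, 1000)],
    )
    def test_exact_p_matches_brute_force(self, k_t, k_c, n_t, n_c):
        """Independent oracle: enumerate all splits of n = k_t + k_c and sum
        binomial probabilities no larger than the observed one."""
        t = _table({("pos1-3", "TTT"): k_t}, n_t)
        c = _table({("pos1-3", "TTT"): k_c}, n_c)
        (res,) = differential_abundance(t, c)
        n, p0 = k_t + k_c, n_t / (n_t + n_c)
        pmf = [binom.pmf(k, n, p0) for k in range(n + 1)]
        brute = sum(q for q in pmf if q <= pmf[k_t] * (1 + 1e-9))
        assert res.p_value == pytest.approx(brute, rel=1e-6)

    def test_bh_step_up_matches_hand_application(self):
        """The reported FDRs are the Benjamini-Hochberg step-up transform:
        q_(i) = min_{j >= i} p_(j) * m / j, applied by hand to the raw
        p-values the exact test produced."""
        counts_t = {("pos1-3", "TTT"): 40, ("pos1-3", "AAA"): 25, ("pos1-3", "TAT"): 18}
        counts_c = {("pos1-3", "TTT"): 10, ("pos1-3", "AAA"): 14, ("pos1-3", "TAT"): 13}
        res = differential_abundance(_table(counts_t, 1000), _table(counts_c, 1000))
        ordered = sorted(res, key=lambda r: r.p_value)
        m = len(ordered)
        hand = [min(ordered[j].p_value * m / (j + 1) for j in range(i, m))
                for i in range(m)]
        hand = [min(1.0, q) for q in hand]
        assert [r.fdr for r in ordered] == pytest.approx(hand)

    def test_fdr_permutation_invariant_and_monotone(self):
        rng = np.random.default_rng(4)
        counts_t = {("pos1-3", f"m{i}"): int(k) for i, k in
                    enumerate(rng.integers(0, 200, 16))}
        counts_c = {("pos1-3", f"m{i}"): int(k) for i, k in
                    enumerate(rng.integers(0, 200, 16))}
        res = differential_abundance(_table(counts_t, 5000), _table(counts_c, 5000))
        shuffled_t = dict(reversed(list(counts_t.items())))
        res2 = differential_abundance(_table(shuffled_t, 5000), _table(counts_c, 5000))
        m1 = {(r.window, r.motif): (r.p_value, r.fdr) for r in res}
        m2 = {(r.window, r.motif): (r.p_value, r.fdr) for r in res2}
        assert m1 == m2
        by_p = sorted(res, key=lambda r: r.p_value)
        assert all(r.fdr <= 1.0 for r in res)
        # BH-adjusted values, sorted by p, are non-decreasing
        assert all(a.fdr <= b.fdr + 1e-12 for a, b in zip(by_p, by_p[1:]))

    def test_zero_total_names_sample(self):
        t = _table({}, 0, library_id="L1", fraction="circular")
        c = _table({("pos1-3", "TTT"): 5}, 100)
        with pytest.raises(ValueError, match="treated.*L1"):
            differential_abundance(t, c)

    def test_dispersion_inflates_p(self):
        t = _table({("pos1-3", "TTT"): 40}, 1000)
        c = _table({("pos1-3", "TTT"): 10}, 1000)
        (p0,) = differential_abundance(t, c)
        (p1,) = differential_abundance(t, c, dispersion=0.01)
        assert p1.p_value > p0.p_value

    def test_common_dispersion_estimate_nonnegative(self):
        reps = [
            _table({("pos1-3", "TTT"): 50 + 30 * i, ("pos1-3", "AAA"): 60 - 20 * i}, 1000)
            for i in range(3)
        ]
        assert estimate_common_dispersion(reps) >= 0.0
        assert estimate_common_dispersion(reps[:1]) == 0.0


def _diff(motif, lfc, fdr, window="pos1-3"):
    d = "up" if lfc > 0 else ("down" if lfc < 0 else "none")
    return DifferentialResult(window, motif, 0, 0, lfc, fdr, fdr, d)


class TestConsistency:
    def test_strong_moderate_none_rules(self):
        # SpSpSp is TTT under L1 (ENC1) and AAA under L3 (ENC2)
        a = [_diff("TTT", 1.0, 0.005), _diff("TAT", 1.0, 0.005), _diff("ATA", 1.0, 0.2)]
        b = [_diff("AAA", 1.0, 0.005), _diff("ATA", 1.0, 0.03), _diff("TAT", -1.0, 0.001)]
        calls = {c.motif_str: c.consistency for c in call_consistent_motifs(
            a, SCHEMES["L1"], b, SCHEMES["L3"])}
        assert calls["SpSpSp"] == "strong"
        # TAT(L1) = SpRpSp pairs with ATA(L3) = SpRpSp: fdr 0.005 & 0.03 -> moderate
        assert calls["SpRpSp"] == "moderate"
        # ATA(L1) = RpSpRp pairs with TAT(L3) = RpSpRp: opposite direction -> none
        assert calls["RpSpRp"] == "none"

    def test_same_encoding_class_is_config_error(self):
        with pytest.raises(ValueError, match="encoding class"):
            call_consistent_motifs([], SCHEMES["L1"], [], SCHEMES["L4"])
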