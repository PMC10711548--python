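"""Demultiplexing: pools, reference, strand, two rounds, UMIs, metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from regionvelo import demux as dx
from regionvelo import synthkit as sk


def dp_levenshtein(a, b):
    """Textbook dynamic-programming edit distance (test oracle)."""
    m, n = len(a), len(b)
    D = np.zeros((m + 1, n + 1), dtype=int)
    D[:, 0] = np.arange(m + 1)
    D[0, :] = np.arange(n + 1)
    for x in range(1, m + 1):
        for y in range(1, n + 1):
            D[x, y] = min(D[x - 1, y] + 1, D[x, y - 1] + 1,
                          D[x - 1, y - 1] + (a[x - 1] != b[y - 1]))
    return int(D[m, n])


class TestDistances:
    @pytest.mark.parametrize("a,b,d", [
        ("AC", "A", 1), ("ACGT", "TGCA", 4), ("AAA", "AAA", 0),
        ("", "ACG", 3), ("AAAA", "AATA", 1),
    ])
    def test_levenshtein_examples(self, a, b, d):
        assert dx.levenshtein(a, b) == d
        assert dp_levenshtein(a, b) == d

    @settings(max_examples=40, deadline=None)
    @given(st.text(alphabet="ACGT", max_size=12),
           st.text(alphabet="ACGT", max_size=12))
    def test_levenshtein_matches_dp_oracle(self, a, b):
        assert dx.levenshtein(a, b) == dp_levenshtein(a, b)

    def test_hamming(self):
        assert dx.hamming("AAA", "AAT") == 1
        with pytest.raises(ValueError):
            dx.hamming("AA", "AAA")

    def test_pool_distance_stats_examples(self):
        s = dx.pool_distance_stats(["AAA", "AAT"])
        assert s["hamming_min"] == s["hamming_mean"] == 1
        s = dx.pool_distance_stats(["AAA", "AAA"])
        assert s["levenshtein_min"] == 0
        with pytest.raises(ValueError):
            dx.pool_distance_stats(["AAA"])


class TestPools:
    def test_tiny_pools_meet_constraint_by_enumeration(self):
        pools = dx.build_barcode_pools(n=2, length=3,
                                       min_pairwise_levenshtein=2,
                                       min_pairwise_hamming=0, seed=1)
        all_bcs = [b for p in pools for b in p.barcodes]
        assert len(all_bcs) == 6
        for i in range(6):
            for j in range(i + 1, 6):
                assert dp_levenshtein(all_bcs[i], all_bcs[j]) >= 2

    def test_full_pools_meet_constraints(self, full_pools):
        rng = np.random.default_rng(0)
        all_bcs = [b for p in full_pools for b in p.barcodes]
        assert len(all_bcs) == 288 == len(set(all_bcs))
        # exhaustive verification is O(n^2); check a random subsample of
        # pairs against the DP oracle and all pairs with the fast metric
        idx = rng.choice(288, 40, replace=False)
        for i in idx:
            for j in idx:
                if i < j:
                    assert dp_levenshtein(all_bcs[i], all_bcs[j]) >= 2
                    assert dx.hamming(all_bcs[i], all_bcs[j]) >= 4

    def test_vendor_like_separation_stats(self, full_pools):
        all_bcs = [b for p in full_pools for b in p.barcodes]
        s = dx.pool_distance_stats(all_bcs)
        assert s["hamming_min"] >= 4
        assert s["levenshtein_min"] >= 2
        assert 5.5 <= s["hamming_mean"] <= 7.5

    def test_unsatisfiable_raises(self):
        with pytest.raises(RuntimeError):
            dx.build_barcode_pools(n=50, length=3,
                                   min_pairwise_levenshtein=3,
                                   max_tries=2000)


class TestReference:
    def test_single_label(self):
        pools = [dx.BarcodePool(k + 1, ["ACGTACGTA"]) for k in range(3)]
        ref = dx.compose_reference(pools)
        assert ref.n_labels == 1
        assert len(ref.all_labels()) == 1

    def test_eight_labels_contain_barcodes_in_order(self, small_pools):
        pools = [dx.BarcodePool(p.position, p.barcodes[:2])
                 for p in small_pools]
        ref = dx.compose_reference(pools)
        assert ref.n_labels == 8
        labels = ref.all_labels()
        assert len(labels) == 8
        for lab in labels:
            assert lab[:9] in pools[0].barcodes
            assert lab[9:18] in pools[1].barcodes
            assert lab[18:] in pools[2].barcodes

    def test_label_segment_is_52bp(self, small_reference):
        assert small_reference.design.label_segment_len() == 52

    def test_reference_length_is_98(self, small_reference):
        assert small_reference.reference_length == 98

    def test_reference_sequence_padded_with_ns(self, small_pools):
        ref = dx.compose_reference(small_pools)
        seq = ref.reference_sequence(*[p.barcodes[0] for p in small_pools])
        assert seq.startswith("N" * 10) and seq.endswith("N" * 10)
        assert len(seq) == 98 + 20


class TestStrand:
    def test_forward_by_construction(self, small_whitelist, small_reference):
        records, truth = sk.generate_reads(
            small_whitelist, 20, sk.ErrorModel(), small_reference.design,
            seed=0, strand_probs=(1.0, 0.0, 0.0))
        for _, seq in records:
            assert dx.detect_strand(seq) == "forward"

    def test_reverse_by_symmetry(self, small_whitelist, small_reference):
        records, _ = sk.generate_reads(
            small_whitelist, 20, sk.ErrorModel(), small_reference.design,
            seed=0, strand_probs=(1.0, 0.0, 0.0))
        for _, seq in records:
            assert dx.detect_strand(sk.reverse_complement(seq)) == "reverse"

    def test_random_sequence_has_no_strand(self, rng):
        # scan for homopolymer runs >= threshold: absent in this fixture
        n_none = 0
        for _ in range(50):
            seq = sk.random_sequence(300, rng)
            called = dx.detect_strand(seq, run_threshold=9)
            t_run = max(len(r) for r in
                        "".join("T" if c == "T" else " " for c in seq).split())
            a_run = max(len(r) for r in
                        "".join("A" if c == "A" else " " for c in seq).split())
            if max(t_run, a_run) < 9:
                assert called == "none"
                n_none += 1
        assert n_none > 30

    def test_empty_read_raises(self):
        with pytest.raises(ValueError):
            dx.detect_strand("")


class TestFirstRound:
    def test_error_free_reads_fully_assigned(self, small_whitelist,
                                             small_reference):
        records, truth = sk.generate_reads(
            small_whitelist, 60, sk.ErrorModel(), small_reference.design,
            seed=1, strand_probs=(0.5, 0.5, 0.0))
        res = dx.demux_first_round(records, small_reference)
        m = dx.evaluate_demux(res, truth)
        assert m.tpr == 1.0 and m.fpr == 0.0
        assert (res["round"] == 1).all()
        merged = res.merge(truth, on="read_id", suffixes=("", "_t"))
        assert (merged["umi"] == merged["umi_t"]).all()

    def test_two_substitutions_in_barcodes_still_assigned(self, small_pools):
        ref = dx.compose_reference(small_pools)
        d = ref.design
        bc1, bc2, bc3 = (p.barcodes[0] for p in small_pools)
        # one substitution in bc1, one in bc3 (pools at min Hamming 4)
        mut1 = ("G" if bc1[4] != "G" else "C")
        mut3 = ("G" if bc3[4] != "G" else "C")
        read = (d.anchor5 + bc1[:4] + mut1 + bc1[5:] + d.linker1 + bc2
                + d.linker2 + bc3[:4] + mut3 + bc3[5:] + "A" * 8
                + "T" * 20 + "C" * 100)
        res = dx.demux_first_round([("r", read)], ref)
        row = res.iloc[0]
        assert row["round"] == 1
        assert (row.bc1, row.bc2, row.bc3) == (bc1, bc2, bc3)

    def test_random_reads_unassigned(self, small_reference, rng):
        records = [(f"r{k}", sk.random_sequence(400, rng)) for k in range(40)]
        res = dx.demux_first_round(records, small_reference)
        assert (res["round"] == 0).all()

    def test_margin_monotonicity_on_fpr(self, full_pools):
        """Raising the margin threshold never increases the FPR."""
        ref = dx.compose_reference(full_pools)
        wl = [tuple(p.barcodes[k] for p in full_pools) for k in range(96)]
        records, truth = sk.generate_reads(
            wl, 400, sk.ErrorModel.uniform(0.12), ref.design, seed=4)
        fprs = []
        for margin in (1, 2, 3):
            res = dx.demux_first_round(records, ref, min_margin=margin,
                                       strict_dist=-1)
            fprs.append(dx.evaluate_demux(res, truth).fpr)
        assert fprs[0] >= fprs[1] >= fprs[2]

    def test_empty_reference_raises(self):
        pools = [dx.BarcodePool(k + 1, ["ACGTACGTA"]) for k in range(3)]
        ref = dx.compose_reference(pools)
        ref.pools[0].barcodes = []
        with pytest.raises(ValueError):
            dx.demux_first_round([("r", "ACGT")], ref)


class TestSecondRound:
    def test_linker_insertion_rescued(self, small_pools):
        """A 3 bp insertion in linker1 shifts the label out of the strict
        round-1 geometry but the gap stays within the rescue window."""
        ref = dx.compose_reference(small_pools)
        d = ref.design
        bc1, bc2, bc3 = (p.barcodes[2] for p in small_pools)
        read = (d.anchor5 + bc1 + d.linker1[:6] + "GGG" + d.linker1[6:]
                + bc2 + d.linker2 + bc3 + "ACGTACGT" + "T" * 20 + "C" * 150)
        res = dx.demux_second_round([("r", read)], ref)
        row = res.iloc[0]
        assert row["round"] == 2
        assert (row.bc1, row.bc2, row.bc3) == (bc1, bc2, bc3)
        assert row.umi == "ACGTACGT"

    def test_two_of_three_barcodes_not_rescued(self, small_pools):
        ref = dx.compose_reference(small_pools)
        d = ref.design
        bc1, bc2 = small_pools[0].barcodes[0], small_pools[1].barcodes[0]
        read = (d.anchor5 + bc1 + d.linker1 + bc2 + d.linker2
                + "T" * 29 + "C" * 150)
        res = dx.demux_second_round([("r", read)], ref)
        assert res.iloc[0]["round"] == 0

    def test_rounds_disjoint_and_rates_add(self, full_pools):
        ref = dx.compose_reference(full_pools)
        wl = [tuple(p.barcodes[k] for p in full_pools) for k in range(96)]
        records, truth = sk.generate_reads(
            wl, 500, sk.ErrorModel.uniform(0.10), ref.design, seed=6)
        both = dx.demux_reads(records, ref, preset="conservative")
        r1 = set(both[both["round"] == 1].read_id)
        r2 = set(both[both["round"] == 2].read_id)
        assert not (r1 & r2)
        m = dx.evaluate_demux(both, truth)
        assert m.demux_rate == pytest.approx((len(r1) + len(r2)) / 500)


class TestUMICorrection:
    def test_identical_umis_collapse(self):
        assert dx.dedup_umis(["AAAA"] * 3) == {"AAAA": 3}

    def test_directional_merge_absorbs_minor(self):
        reps = dx.dedup_umis(["AAAA"] * 5 + ["AAAT"])
        assert reps == {"AAAA": 6}

    def test_distant_umis_stay_separate(self):
        reps = dx.dedup_umis(["AAAA", "TTTT"])
        assert set(reps) == {"AAAA", "TTTT"}

    def test_correct_umis_table(self):
        df = pd.DataFrame({
            "bc1": ["A"] * 6, "bc2": ["C"] * 6, "bc3": ["G"] * 6,
            "gene": ["g1"] * 4 + ["g2"] * 2,
            "umi": ["AAAA", "AAAA", "AAAT", "CCCC", "AAAA", ""],
        })
        mol = dx.correct_umis(df)
        g1 = mol[mol.gene == "g1"]
        assert len(g1) == 2  # AAAA cluster (3 reads) + CCCC
        assert mol.attrs["n_missing_umi"] == 1


class TestEvaluate:
    def test_all_correct(self, small_whitelist, small_reference):
        records, truth = sk.generate_reads(
            small_whitelist, 30, sk.ErrorModel(), small_reference.design,
            seed=8, strand_probs=(1.0, 0.0, 0.0))
        res = dx.demux_first_round(records, small_reference)
        m = dx.evaluate_demux(res, truth)
        assert (m.tpr, m.fpr, m.precision) == (1.0, 0.0, 1.0)

    def test_printed_confusion_quadruple_consistency(self):
        """TP=725, FP=64, FN=211 of 1000 reads gives TPR 0.725, FPR 0.064
        and precision 725/789 ~ 0.919 under the metric definitions."""
        rows = []
        truth_rows = []
        k = 0
        for n, kind in ((725, "tp"), (64, "fp"), (211, "fn")):
            for _ in range(n):
                rid = f"r{k}"
                truth_rows.append((rid, "AAA", "CCC", "GGG", "ACGT",
                                   "forward", True))
                if kind == "tp":
                    rows.append((rid, "AAA", "CCC", "GGG", "ACGT",
                                 "forward", 0.0, 1.0, 1))
                elif kind == "fp":
                    rows.append((rid, "TTT", "CCC", "GGG", "ACGT",
                                 "forward", 0.0, 1.0, 1))
                else:
                    rows.append((rid, "", "", "", "", "none",
                                 np.nan, np.nan, 0))
                k += 1
        cols = ["read_id", "bc1", "bc2", "bc3", "umi", "strand", "score",
                "margin", "round"]
        a = pd.DataFrame(rows, columns=cols)
        t = pd.DataFrame(truth_rows, columns=["read_id", "bc1", "bc2", "bc3",
                                              "umi", "strand", "barcoded"])
        m = dx.evaluate_demux(a, t)
        assert m.tpr == pytest.approx(0.725)
        assert m.fpr == pytest.approx(0.064)
        assert m.precision == pytest.approx(725 / 789)

    def test_hand_counted_small_fixture(self):
        cols = ["read_id", "bc1", "bc2", "bc3", "umi", "strand", "score",
                "margin", "round"]
        a = pd.DataFrame([
            ("r0", "A", "B", "C", "U", "forward", 0, 1, 1),   # TP
            ("r1", "X", "B", "C", "U", "forward", 0, 1, 1),   # FP
            ("r2", "", "", "", "", "none", np.nan, np.nan, 0),  # FN
            ("r3", "A", "B", "C", "U", "forward", 0, 1, 2),   # FP (junk)
            ("r4", "", "", "", "", "none", np.nan, np.nan, 0),  # TN
        ], columns=cols)
        t = pd.DataFrame([
            ("r0", "A", "B", "C", "U", "forward", True),
            ("r1", "A", "B", "C", "U", "forward", True),
            ("r2", "A", "B", "C", "U", "forward", True),
            ("r3", "", "", "", "", "none", False),
            ("r4", "", "", "", "", "none", False),
        ], columns=["read_id", "bc1", "bc2", "bc3", "umi", "strand",
                    "barcoded"])
        m = dx.evaluate_demux(a, t)
        assert (m.tp, m.fp, m.fn) == (1, 2, 1)
        assert m.tpr == pytest.approx(1 / 3)
        assert m.fpr == pytest.approx(2 / 5)
        assert m.demux_rate == pytest.approx(3 / 5)

    def test_mismatched_read_sets_raise(self):
        cols = ["read_id", "bc1", "bc2", "bc3", "umi", "strand", "score",
                "margin", "round"]
        a = pd.DataFrame([("r0", "", "", "", "", "none", 0, 0, 0)],
                         columns=cols)
        t = pd.DataFrame([("r1", "", "", "", "", "none", False)],
                         columns=["read_id", "bc1", "bc2", "bc3", "umi",
                                  "strand", "barcoded"])
        with pytest.raises(ValueError):
            dx.evaluate_demux(a, t)
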