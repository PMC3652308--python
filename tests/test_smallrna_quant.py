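"""Trimming, isomiR-tolerant alignment, count merging and CPM filtering."""

import numpy as np
import pandas as pd
import pytest

from leukosplice import smallrna_quant as sq
from leukosplice import synthetic_data as sd
from leukosplice.synthetic_data import DEFAULT_ADAPTER_3P, DEFAULT_ADAPTER_5P


class TestTrimReads:
    def test_no_adapter_read_loses_tag_and_5p_base(self):
        # 50 bases, no adapter content: 50 - 15 (tag end) - 1 (5' base) = 34
        res = sq.trim_reads([("r1", "A" * 50)])
        assert len(res.reads) == 1
        assert len(res.reads[0][1]) == 34
        assert res.n_adapter == 0

    def test_posttrim_length_15_discarded(self):
        insert = "ACGTTGCAACGTGGCA"  # 16 nt -> 15 after the 5'-base drop
        core = DEFAULT_ADAPTER_5P + insert + DEFAULT_ADAPTER_3P[:11]
        read = core + "T" * 15
        assert len(read) == 50
        res = sq.trim_reads([("r1", read)])
        assert res.reads == []
        assert res.n_short == 1

    def test_adapter_flanked_insert_recovered(self):
        # brute-force oracle: the output must equal the insert minus its
        # 5' base, for every insert length the layout allows
        rng = np.random.default_rng(0)
        for length in range(17, 26):
            insert = "".join(rng.choice(list("ACGT"), size=length))
            l5, l3 = 8, 35 - 8 - length
            if 0 < l3 < 3:  # layout keeps 3' fragments detectable (>= 3)
                l5 -= 3 - l3
                l3 = 3
            core = DEFAULT_ADAPTER_5P[8 - l5 :] + insert + DEFAULT_ADAPTER_3P[:l3]
            read = core + "G" * 15
            res = sq.trim_reads([("r1", read)])
            assert res.reads[0][1] == insert[1:], f"insert length {length}"
            assert res.n_adapter == 1

    def test_non_acgtn_rejected_and_logged(self):
        res = sq.trim_reads([("bad", "AXGT" * 12 + "AC")], keep_audit=True)
        assert res.reads == []
        assert res.n_rejected == 1
        assert any("reject" in line for line in res.audit)

    def test_trimming_never_lengthens(self, clean_readset):
        for lib, reads in clean_readset.reads.items():
            res = sq.trim_reads(reads[:100])
            assert len(res.reads) <= 100
            for (_rid_in, seq_in), (_rid_out, seq_out) in zip(reads, res.reads):
                assert len(seq_out) <= len(seq_in)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            sq.TrimParams(end_trim=-1)
        with pytest.raises(ValueError):
            sq.TrimParams(min_length=0)


def _dna(ref, mature_id):
    return ref.mature_sequences()[mature_id].replace("U", "T")


class TestAlignAndCount:
    def test_templated_3p_extension_counted(self, small_reference):
        mid = sorted(small_reference.mature_sequences())[0]
        read = _dna(small_reference, mid) + "CA"
        matrix, unmapped, _ = sq.align_and_count(
            {"L1": [("r1", read)]}, small_reference
        )
        ann = matrix.annotations
        assert matrix.counts.loc[ann["mature_id"] == mid, "L1"].sum() == 1
        assert unmapped["L1"] == []

    def test_four_substitutions_unmapped(self, small_reference):
        mid = sorted(small_reference.mature_sequences())[0]
        seq = list(_dna(small_reference, mid))
        for pos in (2, 7, 11, 15):
            seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
        _matrix, unmapped, _ = sq.align_and_count(
            {"L1": [("r1", "".join(seq))]}, small_reference
        )
        assert len(unmapped["L1"]) == 1

    def test_exact_match_increments_perfect_fraction(self, small_reference):
        mid = sorted(small_reference.mature_sequences())[0]
        _m, _u, stats = sq.align_and_count(
            {"L1": [("r1", _dna(small_reference, mid))]}, small_reference
        )
        assert stats.loc["L1", "perfect_fraction"] == 1.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            sq.align_and_count({"L1": []}, sd.MiRNAReference([]))

    def test_read_conservation(self, clean_readset, small_reference):
        trimmed = {
            lib: sq.trim_reads(reads).reads
            for lib, reads in clean_readset.reads.items()
        }
        matrix, unmapped, stats = sq.align_and_count(trimmed, small_reference)
        for lib in trimmed:
            assert (
                matrix.counts[lib].sum() + len(unmapped[lib]) == len(trimmed[lib])
            )
            assert stats.loc[lib, "total"] == len(trimmed[lib])

    def test_clean_reads_recover_generator_counts_exactly(
        self, clean_readset, small_reference
    ):
        trimmed = {
            lib: sq.trim_reads(reads).reads
            for lib, reads in clean_readset.reads.items()
        }
        matrix, _, _ = sq.align_and_count(trimmed, small_reference)
        merged = sq.merge_counts(matrix)
        truth = clean_readset.truth_counts
        got = (
            merged.counts.reindex(index=truth.index, columns=truth.columns)
            .fillna(0)
            .astype(int)
        )
        assert got.equals(truth)


class TestFilterDb:
    def test_disjoint_reads_zero_percent(self, small_reference):
        filter_ref = sd.generate_mirna_reference(10, 0, seed=99, n_shared=0)
        reads = {"L1": [("r1", "A" * 22)]}
        _m, _u, report = sq.align_filter_db(reads, filter_ref)
        assert report.loc["L1", "mapped_percent"] == 0.0

    def test_same_reference_gives_identical_counts(self, small_reference):
        mids = sorted(small_reference.mature_sequences())
        reads = {
            "L1": [(f"r{i}", _dna(small_reference, m)) for i, m in enumerate(mids)]
        }
        m1, _, _ = sq.align_and_count(reads, small_reference)
        m2, _, _ = sq.align_filter_db(reads, small_reference)
        assert m1.counts.equals(m2.counts)

    def test_trna_fragments_map_only_to_filter_db(self, small_reference):
        filter_ref = sd.generate_mirna_reference(10, 0, seed=123, n_shared=0)
        frags = {
            "L1": [
                (f"t{i}", s.replace("U", "T"))
                for i, s in enumerate(filter_ref.mature_sequences().values())
            ]
        }
        _m, unmapped, _ = sq.align_and_count(frags, small_reference)
        assert len(unmapped["L1"]) == len(frags["L1"])
        _fm, still, report = sq.align_filter_db(unmapped, filter_ref)
        assert still["L1"] == []
        assert report.loc["L1", "mapped_percent"] == 100.0


def _count_matrix(counts: dict, annotations: pd.DataFrame) -> sq.CountMatrix:
    return sq.CountMatrix(
        counts=pd.DataFrame(counts, index=annotations.index),
        annotations=annotations,
    )


class TestMergeCounts:
    def test_shared_mature_rows_sum(self):
        ann = pd.DataFrame(
            {
                "precursor_id": ["P1", "P2"],
                "mature_id": ["M", "M"],
                "star_flag": [False, False],
            },
            index=["P1|M", "P2|M"],
        )
        matrix = _count_matrix({"L1": [5, 7]}, ann)
        merged = sq.merge_counts(matrix)
        assert merged.counts.loc["M", "L1"] == 12

    def test_no_sharing_is_identity(self):
        ann = pd.DataFrame(
            {
                "precursor_id": ["P1", "P2"],
                "mature_id": ["M1", "M2"],
                "star_flag": [False, True],
            },
            index=["P1|M1", "P2|M2"],
        )
        matrix = _count_matrix({"L1": [5, 7], "L2": [1, 2]}, ann)
        merged = sq.merge_counts(matrix)
        assert sorted(merged.counts.index) == ["M1", "M2"]
        assert merged.counts.to_numpy().sum() == matrix.counts.to_numpy().sum()

    def test_column_sums_conserved(self, clean_readset, small_reference):
        trimmed = {
            lib: sq.trim_reads(reads).reads
            for lib, reads in clean_readset.reads.items()
        }
        matrix, _, _ = sq.align_and_count(trimmed, small_reference)
        merged = sq.merge_counts(matrix)
        assert merged.counts.sum(axis=0).equals(matrix.counts.sum(axis=0))


class TestCpmFilter:
    @staticmethod
    def _matrix(rows: dict) -> sq.CountMatrix:
        counts = pd.DataFrame(rows).T
        counts.columns = [f"L{i + 1}" for i in range(counts.shape[1])]
        ann = pd.DataFrame(
            {
                "precursor_id": list(rows),
                "mature_id": list(rows),
                "star_flag": False,
            },
            index=list(rows),
        )
        return sq.CountMatrix(counts=counts, annotations=ann)

    def test_boundary_feature_retained(self):
        # CPM exactly 1 in three libraries meets the >= 1 in >= 3 gate
        m = self._matrix({"keep": [1, 1, 1, 0], "depth": [999999] * 4})
        out = sq.cpm_filter(m, min_cpm=1.0, min_libraries=3)
        assert "keep" in out.counts.index

    def test_sparse_feature_dropped(self):
        m = self._matrix({"drop": [2, 0, 0, 0], "depth": [999998, 10**6, 10**6, 10**6]})
        out = sq.cpm_filter(m, min_cpm=1.0, min_libraries=3)
        assert "drop" not in out.counts.index

    def test_zero_threshold_is_identity(self):
        m = self._matrix({"a": [5, 0, 1], "b": [0, 1, 2]})
        out = sq.cpm_filter(m, min_cpm=0.0, min_libraries=3)
        assert list(out.counts.index) == ["a", "b"]

    def test_min_libraries_exceeding_libraries_rejected(self):
        m = self._matrix({"a": [5, 1]})
        with pytest.raises(ValueError):
            sq.cpm_filter(m, min_libraries=3)

    @pytest.mark.parametrize("stricter", [(2.0, 3), (1.0, 4)])
    def test_monotone_in_thresholds(self, stricter):
        rng = np.random.default_rng(5)
        rows = {f"f{i}": rng.integers(0, 50, size=4).tolist() for i in range(30)}
        rows["depth"] = [10**4] * 4
        m = self._matrix(rows)
        base = set(sq.cpm_filter(m, 1.0, 3).counts.index)
        tight = set(sq.cpm_filter(m, *stricter).counts.index)
        assert tight <= base
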