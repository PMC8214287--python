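"""Feature extraction: spec'd worked examples, oracle equivalence, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers_bruteforce import (
    bf_bin_tops,
    bf_counts,
    bf_longest_run,
    bf_softclips,
    expand_columns,
    random_cigar_md,
)
from svpipe.alignment import (
    FEATURE_NAMES,
    AlignmentRecord,
    bin_top_counts,
    count_edit_ops,
    extract_features,
    is_split,
    longest_run,
    parse_cigar,
    read_feature_table,
    softclip_ends,
    write_feature_table,
)
from svpipe.errors import CigarError, MDFormatError, SchemaError


class TestParseCigar:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("50M", [("M", 50)]),
            (
                "5S10M2I8M3D10M4S",
                [("S", 5), ("M", 10), ("I", 2), ("M", 8), ("D", 3), ("M", 10), ("S", 4)],
            ),
            ("*", []),
        ],
    )
    def test_tokenization(self, text, expected):
        assert parse_cigar(text) == expected

    @pytest.mark.parametrize("bad", ["50", "M50", "10M3", "10M#5S", "1OM"])
    def test_malformed_raises_with_position(self, bad):
        with pytest.raises(CigarError, match="position"):
            parse_cigar(bad)

    @given(
        st.lists(
            st.tuples(st.sampled_from("MIDS"), st.integers(1, 500)),
            min_size=1,
            max_size=20,
        )
    )
    @settings(derandomize=True, deadline=None, max_examples=50)
    def test_roundtrip_serialization(self, ops):
        text = "".join(f"{n}{op}" for op, n in ops)
        assert parse_cigar(text) == ops


class TestEditCounts:
    @pytest.mark.parametrize(
        "cigar,md,expected",
        [
            ("5S10M2I8M3D10M4S", "18^ACG10", (2, 3, 0)),
            ("50M", "50", (0, 0, 0)),
            ("120M5I130M", "10A9C229", (5, 0, 2)),
        ],
    )
    def test_worked_examples(self, cigar, md, expected):
        rec = AlignmentRecord("r", cigar=cigar, tags={"MD": md})
        assert count_edit_ops(rec) == expected

    def test_nm_fallback_without_md(self):
        rec = AlignmentRecord("r", cigar="40M2I8M", tags={"NM": 7})
        # NM counts mismatches and gaps: mismatches = 7 - 2 ins
        assert count_edit_ops(rec) == (2, 0, 5)

    def test_unmapped_record_yields_zeros(self, caplog):
        rec = AlignmentRecord("r", flags=4, cigar=[], seq_len=100)
        with caplog.at_level("WARNING"):
            assert count_edit_ops(rec) == (0, 0, 0)
        assert "unmapped" in caplog.text

    @pytest.mark.parametrize("md", ["17^ACG10", "18^AC10", "18^ACG11"])
    def test_inconsistent_md_raises(self, md):
        rec = AlignmentRecord("r", cigar="5S10M2I8M3D10M4S", tags={"MD": md})
        with pytest.raises(MDFormatError):
            count_edit_ops(rec)


class TestLongestRun:
    @pytest.mark.parametrize(
        "cigar,md,kind,gap1,expected",
        [
            ("4M1D1M2D5M", "4^A1^CC5", "del", False, 2),
            ("4M1D1M2D5M", "4^A1^CC5", "del", True, 3),
            ("50M", "50", "del", False, 0),
            ("50M", "50", "ins", True, 0),
            ("50M", "50", "mismatch", False, 0),
            # two matches between runs: no join even with the gap flag
            ("4M1D2M2D5M", "4^A2^CC5", "del", True, 2),
            ("10M3I1M2I10M", "21", "ins", True, 5),
            ("5M1I5M", "10", "ins", False, 1),
        ],
    )
    def test_run_joining(self, cigar, md, kind, gap1, expected):
        rec = AlignmentRecord("r", cigar=cigar, tags={"MD": md})
        assert longest_run(rec, kind, gap1) == expected

    def test_mismatch_runs_from_md(self):
        rec = AlignmentRecord("r", cigar="20M", tags={"MD": "5AC1T11"})
        assert longest_run(rec, "mismatch", False) == 2
        assert longest_run(rec, "mismatch", True) == 3

    def test_invalid_kind(self):
        rec = AlignmentRecord("r", cigar="10M", tags={"MD": "10"})
        with pytest.raises(ValueError):
            longest_run(rec, "clip")


class TestSoftclipAndBins:
    @pytest.mark.parametrize(
        "cigar,expected",
        [
            ("5S10M2I8M3D10M4S", (5, 4)),
            ("50M", (0, 0)),
            ("7S43M", (7, 0)),
            ("10H5S35M", (5, 0)),
        ],
    )
    def test_softclip_ends(self, cigar, expected):
        assert softclip_ends(AlignmentRecord("r", cigar=cigar)) == expected

    def test_bin_tops_worked_example(self):
        rec = AlignmentRecord("r", cigar="120M5I130M", tags={"MD": "10A9C229"})
        assert rec.seq_len == 255
        assert bin_top_counts(rec) == [5, 2, 0, 0]

    def test_bin_tops_padded_and_sorted(self):
        rec = AlignmentRecord("r", cigar="50M", tags={"MD": "50"})
        assert bin_top_counts(rec) == [0, 0, 0, 0]

    def test_bad_arguments(self):
        rec = AlignmentRecord("r", cigar="50M")
        with pytest.raises(ValueError):
            bin_top_counts(rec, bin_size=0)
        with pytest.raises(ValueError):
            bin_top_counts(rec, k=0)


class TestOracleEquivalence:
    """Run-length implementation vs an independent per-base walk."""

    def test_random_records_match_bruteforce(self):
        rng = np.random.default_rng(20240917)
        for _ in range(300):
            cigar, md, seq_len = random_cigar_md(rng)
            rec = AlignmentRecord("r", cigar=cigar, tags={"MD": md})
            cols = expand_columns(cigar, md)
            assert rec.seq_len == seq_len
            assert count_edit_ops(rec) == bf_counts(cols)
            assert softclip_ends(rec) == bf_softclips(cols)
            for kind in ("ins", "del", "mismatch"):
                for gap1 in (False, True):
                    assert longest_run(rec, kind, gap1) == bf_longest_run(
                        cols, kind, gap1
                    ), (cigar, md, kind, gap1)
            assert bin_top_counts(rec) == bf_bin_tops(cols, seq_len)

    def test_bin_totals_sum_to_edit_totals(self):
        from svpipe.alignment import bin_counts

        rng = np.random.default_rng(7)
        for _ in range(100):
            cigar, md, _ = random_cigar_md(rng)
            rec = AlignmentRecord("r", cigar=cigar, tags={"MD": md})
            ins, dele, mism = count_edit_ops(rec)
            assert bin_counts(rec).sum() == ins + dele + mism

    def test_gap1_bounds(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            cigar, md, _ = random_cigar_md(rng)
            rec = AlignmentRecord("r", cigar=cigar, tags={"MD": md})
            ins, dele, mism = count_edit_ops(rec)
            totals = {"ins": ins, "del": dele, "mismatch": mism}
            for kind in totals:
                plain = longest_run(rec, kind, False)
                joined = longest_run(rec, kind, True)
                assert 0 <= plain <= joined <= totals[kind]


class TestExtractFeatures:
    def test_tagged_perfect_alignment(self):
        rec = AlignmentRecord(
            "r",
            cigar="50M",
            tags={"MD": "50", "s1": 100, "s2": 0, "cm": 12, "NM": 0, "AS": 90},
        )
        fv = extract_features([rec])
        expected = [100, 0, 12, 0, 90] + [0] * 15 + [50]
        assert fv.values.tolist() == [float(v) for v in expected]

    def test_missing_tags_default_to_zero(self):
        fv = extract_features([AlignmentRecord("r", cigar="50M", tags={"MD": "50"})])
        assert fv.values[:5].tolist() == [0, 0, 0, 0, 0]

    def test_location_independence(self):
        tags = {"MD": "18^ACG10", "NM": 5, "AS": 20}
        a = AlignmentRecord("r", cigar="5S10M2I8M3D10M4S", ref_name="chr1",
                            pos=100, tags=dict(tags))
        b = AlignmentRecord("r", cigar="5S10M2I8M3D10M4S", ref_name="chr9",
                            pos=987654, tags=dict(tags, XX="noise"))
        assert extract_features([a]).values.tolist() == extract_features([b]).values.tolist()

    def test_features_use_primary_record_only(self):
        primary = AlignmentRecord("r", flags=0, cigar="100M", tags={"MD": "100"})
        supp = AlignmentRecord("r", flags=2048, cigar="80S20M", tags={"MD": "20"})
        fv = extract_features([supp, primary])
        assert fv["softclip_left"] == 0
        assert fv["read_length"] == 100

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            extract_features([])

    def test_nm_falls_back_to_edit_sum(self):
        rec = AlignmentRecord("r", cigar="10M2I8M3D10M", tags={"MD": "5A12^ACG10"})
        fv = extract_features([rec])
        assert fv["NM"] == 2 + 3 + 1


class TestIsSplit:
    def test_primary_only_is_not_split(self):
        assert not is_split([AlignmentRecord("r", cigar="50M")])

    def test_sa_tag_or_supplementary_flag(self):
        primary = AlignmentRecord("r", cigar="50M", tags={"SA": "chr1,1,+,50M,60,0;"})
        supp = AlignmentRecord("r", flags=2048, cigar="25H25M")
        assert is_split([primary, supp])
        assert is_split([primary])

    def test_secondary_is_not_split(self):
        assert not is_split(
            [AlignmentRecord("r", cigar="50M"), AlignmentRecord("r", flags=256, cigar="50M")]
        )


class TestFeatureTable:
    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 100, size=(5, len(FEATURE_NAMES))).astype(float)
        names = [f"r{i}" for i in range(5)]
        path = str(tmp_path / "feat.tsv")
        write_feature_table(path, names, X, labels=[0, 1, 0, 0, 1])
        names2, X2, labels = read_feature_table(path)
        assert names2 == names
        np.testing.assert_array_equal(X2, X)
        assert labels.tolist() == [0, 1, 0, 0, 1]

    def test_missing_columns_rejected(self, tmp_path):
        path = str(tmp_path / "bad.tsv")
        with open(path, "w") as fh:
            fh.write("read_name\ts1\nr0\t1\n")
        with pytest.raises(SchemaError):
            read_feature_table(path)
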