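"""SV call filtering, cross-caller merging, truth matching, VCF parsing."""

import textwrap

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svpipe.svmerge import (
    SVCall,
    filter_min_support,
    match_to_truth,
    merge_calls,
    min_support_threshold,
    parse_sv_vcf,
    unique_support,
    write_sv_vcf,
)


def dcall(pos=1000, end=1500, sv_type="DEL", chrom="chr1", support=None,
          count=0, caller="A", chrom2=None):
    return SVCall(
        sv_type=sv_type,
        chrom=chrom,
        pos=pos,
        end=end,
        length=max(0, end - pos),
        support_reads=frozenset(support or ()),
        support_count=count,
        caller=caller,
        chrom2=chrom2,
    )


class TestUniqueSupport:
    def test_duplicate_names_count_once(self):
        assert unique_support(dcall(support=["r1", "r2", "r1"])) == 2

    def test_count_fallback_without_names(self):
        assert unique_support(dcall(count=7)) == 7

    def test_single_name(self):
        assert unique_support(dcall(support=["r1"])) == 1


class TestMinSupportThreshold:
    @pytest.mark.parametrize("coverage,expected", [(10, 5), (8, 4), (9, 5), (1, 1)])
    def test_half_coverage_ceiling(self, coverage, expected):
        assert min_support_threshold(coverage) == expected

    @pytest.mark.parametrize("bad", [0, -3])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            min_support_threshold(bad)


class TestFilterMinSupport:
    def test_threshold_is_inclusive(self):
        calls = [dcall(count=5), dcall(count=4), dcall(count=6)]
        assert len(filter_min_support(calls, 5)) == 2

    def test_min_one_is_identity_on_supported_calls(self):
        calls = [dcall(count=1), dcall(count=3)]
        assert filter_min_support(calls, 1) == calls

    def test_empty_input(self):
        assert filter_min_support([], 5) == []

    def test_idempotent_and_monotone(self):
        calls = [dcall(count=c) for c in (1, 3, 5, 8)]
        once = filter_min_support(calls, 4)
        assert filter_min_support(once, 4) == once
        assert len(filter_min_support(calls, 6)) <= len(once)


class TestMergeCalls:
    def test_nearby_same_type_unified_to_higher_support(self):
        a = dcall(pos=1000, end=1500, support=["r1", "r2", "r3"], caller="A")
        b = dcall(pos=1030, end=1530, support=["r4", "r5"], caller="B")
        merged = merge_calls([a], [b])
        assert len(merged) == 1
        assert merged[0].pos == 1000  # A had more support
        assert merged[0].support_reads == frozenset("r%d" % i for i in (1, 2, 3, 4, 5))
        assert merged[0].info["CALLERS"] == "A,B"

    def test_distance_boundary_is_strict(self):
        a = dcall(pos=1000, end=1500, count=3)
        b = dcall(pos=1050, end=1550, count=2, caller="B")
        assert len(merge_calls([a], [b], window=50)) == 2

    def test_type_mismatch_never_merges(self):
        a = dcall(pos=1000, end=1000, sv_type="DEL")
        b = dcall(pos=1000, end=1000, sv_type="INS", caller="B")
        assert len(merge_calls([a], [b])) == 2

    def test_both_coordinates_must_be_close(self):
        # nested events share a start but not an end: kept distinct
        a = dcall(pos=1000, end=1500, count=3)
        b = dcall(pos=1010, end=3000, count=2, caller="B")
        assert len(merge_calls([a], [b])) == 2

    def test_same_caller_calls_never_pair(self):
        a1 = dcall(pos=1000, end=1500, count=3, caller="A")
        a2 = dcall(pos=1010, end=1510, count=2, caller="A")
        assert len(merge_calls([a1, a2], [])) == 2

    def test_tra_requires_both_breakpoints_and_partner_chrom(self):
        t1 = dcall(pos=1000, end=5000, sv_type="TRA", chrom2="chr2", caller="A")
        t2 = dcall(pos=1010, end=5010, sv_type="TRA", chrom2="chr2", caller="B")
        t3 = dcall(pos=1010, end=5010, sv_type="TRA", chrom2="chr3", caller="B")
        assert len(merge_calls([t1], [t2])) == 1
        assert len(merge_calls([t1], [t3])) == 2

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            merge_calls([], [], window=-1)

    def test_dedup_identity_for_duplicated_call_set(self):
        """Two redundant copies of one call set collapse back to the original."""
        original = [
            dcall(pos=1000, end=1500, support=["r1", "r2", "r3", "r1"]),
            dcall(pos=8000, end=8000, sv_type="INS", support=["r4", "r5"]),
            dcall(pos=20000, end=21000, sv_type="INV", support=["r6", "r7", "r8"]),
        ]
        copy_b = [
            SVCall(c.sv_type, c.chrom, c.pos, c.end, length=c.length,
                   support_reads=c.support_reads, caller="B")
            for c in original
        ]
        merged = merge_calls(original, copy_b)
        assert len(merged) == len(original)
        for m, o in zip(merged, sorted(original, key=lambda c: c.pos)):
            assert (m.sv_type, m.pos, m.end) == (o.sv_type, o.pos, o.end)
            assert unique_support(m) == unique_support(o)

    @given(st.integers(0, 60), st.integers(0, 60))
    @settings(derandomize=True, deadline=None, max_examples=30)
    def test_output_never_exceeds_input(self, d1, d2):
        a = [dcall(pos=1000 + d1, end=1500 + d1, count=2)]
        b = [dcall(pos=1000, end=1500, count=3, caller="B"),
             dcall(pos=5000 + d2, end=5400 + d2, sv_type="INV", count=4, caller="B")]
        merged = merge_calls(a, b)
        assert len(merged) <= len(a) + len(b)
        should_merge = d1 < 50
        assert len(merged) == (2 if should_merge else 3)


class TestMatchToTruth:
    def test_tolerance_boundary(self):
        truth = [dcall(pos=1000, end=1500, caller="truth")]
        near = dcall(pos=1009, end=1509, count=5)
        far = dcall(pos=1010, end=1510, count=5)
        res = match_to_truth([near], truth)
        assert (len(res.tp), len(res.fp), len(res.fn)) == (1, 0, 0)
        res = match_to_truth([far], truth)
        assert (len(res.tp), len(res.fp), len(res.fn)) == (0, 1, 1)

    def test_identity_gives_perfect_scores(self, simple_truth):
        res = match_to_truth(simple_truth, simple_truth)
        assert res.recall == 1.0 and res.fdr == 0.0
        assert set(res.per_type_recall) == {"DEL", "INS", "INV"}

    def test_type_must_match(self):
        truth = [dcall(pos=1000, end=1500, sv_type="DEL", caller="truth")]
        res = match_to_truth([dcall(pos=1000, end=1500, sv_type="DUP")], truth)
        assert res.recall == 0.0 and res.fdr == 1.0

    def test_counts_partition(self, simple_truth):
        calls = [
            dcall(pos=1003, end=1503, count=5),          # TP
            dcall(pos=40000, end=40500, count=5),        # FP
        ]
        res = match_to_truth(calls, simple_truth)
        assert len(res.tp) + len(res.fn) == len(simple_truth)
        assert len(res.tp) + len(res.fp) == len(calls)
        assert 0.0 <= res.recall <= 1.0 and 0.0 <= res.fdr <= 1.0

    def test_empty_call_set_has_zero_fdr(self, simple_truth):
        res = match_to_truth([], simple_truth)
        assert res.fdr == 0.0 and res.recall == 0.0

    def test_one_truth_matches_at_most_one_call(self):
        truth = [dcall(pos=1000, end=1500, caller="truth")]
        calls = [dcall(pos=1001, end=1501, count=9), dcall(pos=999, end=1499, count=3)]
        res = match_to_truth(calls, truth)
        assert (len(res.tp), len(res.fp)) == (1, 1)
        assert unique_support(res.tp[0][0]) == 9  # greedy: best-supported first


class TestParseSvVcf:
    header = textwrap.dedent(
        """\
        ##fileformat=VCFv4.2
        ##contig=<ID=chr1,length=1000000>
        ##contig=<ID=chr2,length=1000000>
        ##INFO=<ID=SVTYPE,Number=1,Type=String,Description="x">
        ##INFO=<ID=END,Number=1,Type=Integer,Description="x">
        ##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="x">
        ##INFO=<ID=RNAMES,Number=.,Type=String,Description="x">
        ##INFO=<ID=RE,Number=1,Type=Integer,Description="x">
        ##INFO=<ID=MATEID,Number=1,Type=String,Description="x">
        #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
        """
    )

    def _write(self, tmp_path, body):
        path = str(tmp_path / "calls.vcf")
        with open(path, "w") as fh:
            fh.write(self.header + body)
        return path

    def test_del_with_read_names(self, tmp_path):
        path = self._write(
            tmp_path,
            "chr1\t1000\tv1\tN\t<DEL>\t.\t.\tSVTYPE=DEL;END=1500;RNAMES=r1,r2\n",
        )
        calls = parse_sv_vcf(path, "callerA")
        assert len(calls) == 1
        c = calls[0]
        assert (c.sv_type, c.pos, c.end) == ("DEL", 1000, 1500)
        assert c.support_reads == frozenset({"r1", "r2"})
        assert c.caller == "callerA"

    def test_count_only_dialect(self, tmp_path):
        path = self._write(
            tmp_path, "chr1\t2000\tv1\tN\t<INS>\t.\t.\tSVTYPE=INS;END=2000;RE=7\n"
        )
        c = parse_sv_vcf(path, "callerB")[0]
        assert c.support_reads == frozenset()
        assert c.support_count == 7 and unique_support(c) == 7

    def test_empty_body(self, tmp_path):
        assert parse_sv_vcf(self._write(tmp_path, ""), "c") == []

    def test_record_without_svtype_skipped(self, tmp_path):
        path = self._write(
            tmp_path,
            "chr1\t100\tv0\tA\tT\t.\t.\tRE=9\n"
            "chr1\t1000\tv1\tN\t<DEL>\t.\t.\tSVTYPE=DEL;END=1500;RE=5\n",
        )
        calls = parse_sv_vcf(path, "c")
        assert len(calls) == 1 and calls[0].sv_type == "DEL"

    def test_bnd_pair_collapses_to_one_tra(self, tmp_path):
        path = self._write(
            tmp_path,
            "chr1\t5000\tb1\tN\tN[chr2:7000[\t.\t.\tSVTYPE=BND;MATEID=b2;RE=6\n"
            "chr2\t7000\tb2\tN\t]chr1:5000]N\t.\t.\tSVTYPE=BND;MATEID=b1;RE=6\n",
        )
        calls = parse_sv_vcf(path, "c")
        assert len(calls) == 1
        c = calls[0]
        assert c.sv_type == "TRA" and c.chrom == "chr1" and c.chrom2 == "chr2"
        assert (c.pos, c.end) == (5000, 7000)

    def test_write_then_parse_roundtrip(self, tmp_path, simple_truth):
        path = str(tmp_path / "out.vcf")
        write_sv_vcf(simple_truth, path, contigs={"chr1": 1_000_000})
        back = parse_sv_vcf(path, "truth")
        assert [(c.sv_type, c.pos, c.end) for c in back] == [
            (c.sv_type, c.pos, c.end) for c in simple_truth
        ]
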