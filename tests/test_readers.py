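import random

import pytest

from svmeld.core import CallSet, DataError, MergeParams, SVRecord, effective_size
from svmeld.readers import (
    read_breakdancer,
    read_cnvnator,
    read_delly,
    read_lumpy,
    read_pindel,
    read_softsearch,
    read_svseq,
    resolve_self_overlaps,
)
from svmeld.readers._common import ReaderReport

from conftest import make_record

BD_HEADER = ("#Chr1\tPos1\tOrientation1\tChr2\tPos2\tOrientation2\t"
             "Type\tSize\tScore\tnum_Reads\tnum_Reads_lib\n")


def bd_line(chrom="chr05", pos1=65575, pos2=65949, type_="DEL", size=353,
            score=88, reads=5, chrom2=None):
    c2 = chrom2 or chrom
    return (f"{chrom}\t{pos1}\t5+5-\t{c2}\t{pos2}\t5+5-\t{type_}\t{size}\t"
            f"{score}\t{reads}\tlib|{reads}\n")


def write_bd(tmp_path, lines, name="bd.txt"):
    p = tmp_path / name
    p.write_text(BD_HEADER + "".join(lines))
    return p


VCF_PRELUDE = """##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">
##INFO=<ID=END,Number=1,Type=Integer,Description="e">
##INFO=<ID=PE,Number=1,Type=Integer,Description="pe">
##INFO=<ID=SR,Number=1,Type=Integer,Description="sr">
##INFO=<ID=SU,Number=1,Type=Integer,Description="su">
##INFO=<ID=nSC,Number=1,Type=Integer,Description="sc">
##INFO=<ID=lDisc,Number=1,Type=Integer,Description="d">
##ALT=<ID=DEL,Description="d">
##ALT=<ID=DUP,Description="d">
##ALT=<ID=INV,Description="i">
##contig=<ID=chr05,length=30000000>
##contig=<ID=chr10,length=30000000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(tmp_path, rows, name="calls.vcf"):
    p = tmp_path / name
    p.write_text(VCF_PRELUDE + "".join(rows))
    return p


def vcf_row(chrom="chr05", pos=10_000, svtype="DEL", end=14_999, info=""):
    extra = f";{info}" if info else ""
    return (f"{chrom}\t{pos}\tid1\tN\t<{svtype}>\t.\tPASS\t"
            f"SVTYPE={svtype};END={end}{extra}\n")


class TestBreakDancer:
    def test_retained_record_matches_demo(self, tmp_path):
        cs, report = read_breakdancer(write_bd(tmp_path, [bd_line()]))
        (rec,) = cs.records["del"]
        assert (rec.chrom, rec.pos1, rec.pos2) == ("chr05", 65575, 65949)
        assert rec.info == "score=88;PE=5"
        assert rec.size == 353

    def test_low_score_filtered(self, tmp_path):
        cs, report = read_breakdancer(
            write_bd(tmp_path, [bd_line(score=59, reads=10)]))
        assert not cs.records["del"]
        assert report.raw_count["del"] == 1
        assert any("score" in s.reason for s in report.skipped)

    def test_low_support_filtered(self, tmp_path):
        cs, _ = read_breakdancer(write_bd(tmp_path, [bd_line(score=99, reads=2)]))
        assert not cs.records["del"]

    def test_negative_size_inversion_retained(self, tmp_path):
        line = bd_line(pos1=1291603, pos2=1291649, type_="INV", size=-105,
                       score=99, reads=3)
        cs, _ = read_breakdancer(write_bd(tmp_path, [line]))
        (rec,) = cs.records["inv"]
        assert rec.info == "score=99;PE=3"
        assert effective_size(rec) == 105  # span is only 47

    def test_interchromosomal_skipped(self, tmp_path):
        cs, report = read_breakdancer(
            write_bd(tmp_path, [bd_line(type_="CTX", chrom2="chr10")]))
        assert len(cs) == 0
        assert any("interchromosomal" in s.reason for s in report.skipped)

    def test_swaps_inverted_coordinates(self, tmp_path):
        cs, _ = read_breakdancer(
            write_bd(tmp_path, [bd_line(pos1=65949, pos2=65575)]))
        (rec,) = cs.records["del"]
        assert (rec.pos1, rec.pos2) == (65575, 65949)

    def test_truncated_row_is_hard_error(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text(BD_HEADER + "chr05\t100\t200\n")
        with pytest.raises(ValueError, match="bad.txt:2"):
            read_breakdancer(p)

    def test_line_order_insensitive(self, tmp_path):
        lines = [bd_line(pos1=p, pos2=p + 400, size=401, score=s, reads=r)
                 for p, s, r in [(1000, 88, 5), (9000, 59, 9), (5000, 99, 2),
                                 (20000, 70, 7), (40000, 95, 12)]]
        cs1, _ = read_breakdancer(write_bd(tmp_path, lines, "a.txt"))
        random.Random(3).shuffle(lines)
        cs2, _ = read_breakdancer(write_bd(tmp_path, lines, "b.txt"))
        assert cs1.records == cs2.records


def pindel_block(idx=0, label="D", chrom="chr05", pos1=65575, pos2=65949,
                 sr=11, score=12):
    size = pos2 - pos1 + 1
    return (
        "#" * 60 + "\n"
        f"{idx}\t{label} {size}\tNT 0 \"\"\tChrID {chrom}\t"
        f"BP {pos1 - 1}\t{pos2 + 1}\tBP_range {pos1 - 1}\t{pos2 + 1}\t"
        f"Supports {sr}\t{sr}\t+ 5\t5\t- 6\t6\tS1 {score}\tSUM_MS 300\n"
        "  ACGTACGT supporting read\n"
    )


class TestPindel:
    def test_deletion_block(self, tmp_path):
        (tmp_path / "sim_D").write_text(pindel_block())
        cs, _ = read_pindel(tmp_path)
        (rec,) = cs.records["del"]
        assert (rec.pos1, rec.pos2) == (65575, 65949)
        assert rec.info == "SR=11;score=12"

    def test_low_support_filtered(self, tmp_path):
        (tmp_path / "sim_D").write_text(pindel_block(sr=2))
        cs, report = read_pindel(tmp_path)
        assert len(cs) == 0
        assert report.raw_count["del"] == 1

    def test_small_tandem_duplication_filtered_by_size(self, tmp_path):
        (tmp_path / "sim_TD").write_text(
            pindel_block(label="TD", pos1=1000, pos2=1049, sr=5))
        cs, report = read_pindel(tmp_path)
        assert len(cs) == 0
        assert any("size" in s.reason for s in report.skipped)

    def test_malformed_header_skipped_not_fatal(self, tmp_path):
        (tmp_path / "sim_D").write_text(
            "5\tD 100\tno coordinates here\n" + pindel_block())
        cs, report = read_pindel(tmp_path)
        assert len(cs) == 1
        assert any("malformed" in s.reason for s in report.skipped)

    def test_empty_directory_warns(self, tmp_path):
        cs, report = read_pindel(tmp_path)
        assert len(cs) == 0
        assert any("no Pindel output" in s.reason for s in report.skipped)


class TestCnvnator:
    def _write(self, tmp_path, lines, name="chr05.calls"):
        d = tmp_path / "cnv"
        d.mkdir(exist_ok=True)
        (d / name).write_text("".join(lines))
        return d

    @staticmethod
    def _line(type_="deletion", chrom="chr05", pos1=104101, pos2=110700):
        size = pos2 - pos1 + 1
        return (f"{type_}\t{chrom}:{pos1}-{pos2}\t{size}\t0.42\t"
                "0.0169421\t0\t0.00545604\t0\t0\n")

    def test_deletion_retained_with_derived_size(self, tmp_path):
        cs, _ = read_cnvnator(self._write(tmp_path, [self._line()]))
        (rec,) = cs.records["del"]
        assert (rec.pos1, rec.pos2, rec.size) == (104101, 110700, 6599)

    def test_duplication_info_carries_evalues(self, tmp_path):
        cs, _ = read_cnvnator(self._write(tmp_path, [self._line("duplication")]))
        (rec,) = cs.records["dup"]
        assert rec.info.startswith("eval1=0.0169421;eval2=0;")

    def test_oversize_call_filtered(self, tmp_path):
        cs, report = read_cnvnator(
            self._write(tmp_path, [self._line(pos1=1, pos2=12_000_000)]))
        assert len(cs) == 0
        assert any("max_size" in s.reason for s in report.skipped)

    def test_stray_file_is_hard_error(self, tmp_path):
        d = self._write(tmp_path, [self._line()])
        (d / "README.txt").write_text("not a call file\n")
        with pytest.raises(DataError, match="README.txt"):
            read_cnvnator(d)


class TestDelly:
    def test_retained(self, tmp_path):
        p = write_vcf(tmp_path, [vcf_row(pos=10_000, end=14_999, info="PE=5")])
        cs, _ = read_delly(p)
        (rec,) = cs.records["del"]
        assert (rec.pos1, rec.pos2) == (10_000, 14_999)
        assert rec.info == "PE=5"

    def test_support_sum_gate(self, tmp_path):
        p = write_vcf(tmp_path, [
            vcf_row(svtype="INV", pos=10_000, end=20_000, info="PE=2;SR=0"),
            vcf_row(svtype="INV", pos=50_000, end=60_000, info="PE=2;SR=1"),
        ])
        cs, _ = read_delly(p)
        assert [r.info for r in cs.records["inv"]] == ["PE=2;SR=1"]

    def test_small_dup_filtered(self, tmp_path):
        p = write_vcf(tmp_path, [
            vcf_row(svtype="DUP", pos=10_000, end=10_063, info="PE=9")])
        cs, _ = read_delly(p)
        assert len(cs) == 0

    def test_bnd_records_skipped(self, tmp_path):
        p = write_vcf(tmp_path, [
            "chr05\t100\tb\tN\t<DEL>\t.\tPASS\tSVTYPE=BND;END=200\n"])
        cs, report = read_delly(p)
        assert len(cs) == 0 and len(report.skipped) == 1


class TestSvseq:
    def _write(self, tmp_path, rows):
        p = tmp_path / "svseq.del"
        p.write_text("#chrom\tstart\tend\tsplit_reads\n" + "".join(rows))
        return p

    def test_retained(self, tmp_path):
        cs, _ = read_svseq(self._write(tmp_path, ["chr05\t1000\t1499\t4\n"]))
        (rec,) = cs.records["del"]
        assert rec.info == "SR=4"
        assert not cs.records["dup"] and not cs.records["inv"]

    def test_low_support_filtered(self, tmp_path):
        cs, _ = read_svseq(self._write(tmp_path, ["chr05\t1000\t1499\t2\n"]))
        assert len(cs) == 0

    def test_short_deletion_filtered(self, tmp_path):
        cs, _ = read_svseq(self._write(tmp_path, ["chr05\t1000\t1089\t9\n"]))
        assert len(cs) == 0


class TestLumpy:
    def test_retained(self, tmp_path):
        p = write_vcf(tmp_path, [vcf_row(pos=10_000, end=14_999, info="SU=21")])
        cs, _ = read_lumpy(p)
        (rec,) = cs.records["del"]
        assert rec.info == "SU=21"

    def test_low_support_filtered(self, tmp_path):
        p = write_vcf(tmp_path, [
            vcf_row(svtype="INV", pos=10_000, end=20_000, info="SU=2")])
        cs, _ = read_lumpy(p)
        assert len(cs) == 0

    def test_oversize_filtered(self, tmp_path):
        p = write_vcf(tmp_path, [vcf_row(pos=1, end=10_000_001, info="SU=9")])
        cs, _ = read_lumpy(p)
        assert len(cs) == 0

    def test_bedpe_route(self, tmp_path):
        p = tmp_path / "calls.bedpe"
        p.write_text("chr05\t999\t1000\tchr05\t1499\t1500\t1\t.\t+\t-\t"
                     "TYPE:DELETION\tIDS:1;SU:7\n")
        cs, _ = read_lumpy(p)
        (rec,) = cs.records["del"]
        assert (rec.pos1, rec.pos2, rec.info) == (1000, 1500, "SU=7")


class TestSoftSearch:
    def test_both_gates_pass(self, tmp_path):
        p = write_vcf(tmp_path, [
            vcf_row(pos=10_000, end=14_999, info="nSC=4;lDisc=5")])
        cs, _ = read_softsearch(p)
        (rec,) = cs.records["del"]
        assert rec.info == "nSC=4;lDisc=5"

    @pytest.mark.parametrize("info", ["nSC=4;lDisc=2", "nSC=2;lDisc=9"])
    def test_conjunctive_rule(self, tmp_path, info):
        p = write_vcf(tmp_path, [
            vcf_row(svtype="DUP", pos=10_000, end=14_999, info=info)])
        cs, _ = read_softsearch(p)
        assert len(cs) == 0


class TestResolveSelfOverlaps:
    @staticmethod
    def _cs(records):
        cs = CallSet(method="BreakDancer")
        for r in records:
            cs.add(r)
        cs.sort()
        return cs

    def test_best_supported_record_wins(self, params):
        a = make_record(pos1=100, pos2=199, info="score=90;PE=5")
        b = make_record(pos1=100, pos2=199, info="score=80;PE=9")
        out = resolve_self_overlaps(self._cs([a, b]), params)
        assert out.records["del"] == [b]

    def test_below_threshold_pair_both_kept(self, params):
        a = make_record(pos1=100, pos2=199)
        b = make_record(pos1=150, pos2=249)  # RO 0.5
        out = resolve_self_overlaps(self._cs([a, b]), params)
        assert len(out.records["del"]) == 2

    def test_single_record_unchanged(self, params):
        a = make_record()
        out = resolve_self_overlaps(self._cs([a]), params)
        assert out.records["del"] == [a]

    def test_exhaustive_small_instances(self, params):
        # on <=5 records the greedy result must leave no overlapping pair and
        # every dropped record must overlap a kept one with >= support
        from svmeld.core import primary_support, reciprocal_overlap
        rng = random.Random(11)
        for _ in range(200):
            recs = []
            for i in range(rng.randint(1, 5)):
                p1 = rng.randint(1, 300)
                ln = rng.randint(80, 160)
                recs.append(make_record(pos1=p1, pos2=p1 + ln - 1,
                                        info=f"score=90;PE={rng.randint(1, 9)}"))
            kept = resolve_self_overlaps(self._cs(recs), params).records["del"]
            for i, a in enumerate(kept):
                for b in kept[i + 1:]:
                    assert reciprocal_overlap(a.interval, b.interval) <= 0.8
            for r in recs:
                if r in kept:
                    continue
                assert any(
                    reciprocal_overlap(r.interval, k.interval) > 0.8
                    and primary_support(k) >= primary_support(r)
                    for k in kept
                )


class TestConservation:
    def test_raw_equals_kept_plus_skipped(self, sim_callsets):
        for name, (cs, report) in sim_callsets.items():
            for sv_type in ("del", "dup", "inv"):
                skipped = sum(1 for s in report.skipped if s.sv_type == sv_type)
                assert report.raw_count[sv_type] == \
                    report.kept_count[sv_type] + skipped, name

    def test_every_kept_record_passes_size_window(self, sim_callsets, params):
        for name, (cs, _) in sim_callsets.items():
            for recs in cs.records.values():
                for r in recs:
                    assert params.min_size <= effective_size(r) <= params.max_size
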