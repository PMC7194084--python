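"""Reader for SoftSearch VCF output.

SoftSearch reports soft-clipped (split) read counts as ``nSC`` and
discordant read-pair counts as ``lDisc``, either in INFO or in the first
sample's FORMAT fields.  The retained-record gate is conjunctive:
nSC >= 3 AND lDisc >= 3 by default.  Info strings are ``nSC=A;lDisc=B``.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pysam

from ..core import (
    CallSet,
    DataError,
    MergeParams,
    SVRecord,
    UnknownSVTypeError,
    normalize_type,
)
from ._common import CALLER_NAMES, ReaderReport, finalize, size_gate_reason
from ._vcf import _scalar

METHOD = CALLER_NAMES["softsearch"]


def _support(rec) -> tuple[int, int]:
    nsc = _scalar(rec.info.get("nSC"))
    ldisc = _scalar(rec.info.get("lDisc"))
    if (nsc is None or ldisc is None) and rec.samples:
        sample = rec.samples[0]
        if nsc is None:
            nsc = _scalar(sample.get("nSC"))
        if ldisc is None:
            ldisc = _scalar(sample.get("lDisc"))
    if nsc is None or ldisc is None:
        raise DataError(f"record {rec.chrom}:{rec.pos} lacks nSC/lDisc support")
    return int(nsc), int(ldisc)


def parse_softsearch(path: str | Path, report: ReaderReport | None = None) -> list[SVRecord]:
    if report is None:
        report = ReaderReport(method=METHOD)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise DataError(f"cannot open VCF {path}: {exc}") from exc
    records: list[SVRecord] = []
    with vf:
        for i, rec in enumerate(vf, 1):
            svtype = _scalar(rec.info.get("SVTYPE"))
            if svtype is None:
                raise DataError(f"{path}: record {i} lacks INFO/SVTYPE")
            try:
                sv_type = normalize_type(str(svtype), METHOD)
            except UnknownSVTypeError as exc:
                report.skip(path, i, str(exc))
                continue
            nsc, ldisc = _support(rec)
            pos1, pos2 = rec.pos, rec.stop
            if pos2 < pos1:
                raise DataError(f"{path}: record {i}: END {pos2} < POS {pos1}")
            records.append(
                SVRecord(rec.chrom, pos1, pos2, pos2 - pos1 + 1,
                         f"nSC={nsc};lDisc={ldisc}", sv_type, METHOD)
            )
            report.raw_count[sv_type] += 1
    return records


def read_softsearch(
    path: str | Path,
    params: MergeParams | None = None,
    resolve: bool = True,
) -> tuple[CallSet, ReaderReport]:
    params = params or MergeParams()
    th = params.thresholds_for("softsearch")
    report = ReaderReport(method=METHOD)
    cs = CallSet(method=METHOD)
    for rec in parse_softsearch(path, report):
        kv = dict(p.split("=", 1) for p in rec.info.split(";"))
        nsc, ldisc = int(kv["nSC"]), int(kv["lDisc"])
        if th.min_split_reads is not None and nsc < th.min_split_reads:
            report.skip("<softsearch>", None,
                        f"nSC {nsc} < {th.min_split_reads}", rec.sv_type)
            continue
        if th.min_read_pairs is not None and ldisc < th.min_read_pairs:
            report.skip("<softsearch>", None,
                        f"lDisc {ldisc} < {th.min_read_pairs}", rec.sv_type)
            continue
        reason = size_gate_reason(rec, params)
        if reason:
            report.skip("<softsearch>", None, reason, rec.sv_type)
            continue
        cs.add(rec)
    return finalize(cs, report, params, resolve)
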