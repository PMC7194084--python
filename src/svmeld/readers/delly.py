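"""Reader for DELLY VCF output (symbolic alleles, SVTYPE/END in INFO).

DELLY carries paired-end support in INFO/PE and split-read support in
INFO/SR.  The retained-record gate sums both: total support >= 3 by
default (the per-caller ``min_support`` threshold).  The info string keeps
whichever of ``PE=``/``SR=`` the record carried.
"""

from __future__ import annotations

from pathlib import Path

from ..core import CallSet, MergeParams, SVRecord
from ._common import CALLER_NAMES, ReaderReport, finalize, size_gate_reason
from ._vcf import iter_sv_vcf

METHOD = CALLER_NAMES["delly"]


def _info_string(info: dict) -> str:
    parts = []
    for key in ("PE", "SR"):
        if info.get(key) is not None:
            parts.append(f"{key}={int(info[key])}")
    return ";".join(parts) if parts else "PE=0"


def parse_delly(paths, report: ReaderReport | None = None) -> list[SVRecord]:
    if report is None:
        report = ReaderReport(method=METHOD)
    if isinstance(paths, (str, Path)):
        paths = [paths]
    records: list[SVRecord] = []
    for path in paths:
        for chrom, pos1, pos2, sv_type, info, _ in iter_sv_vcf(path, METHOD, report):
            records.append(
                SVRecord(chrom, pos1, pos2, pos2 - pos1 + 1,
                         _info_string(info), sv_type, METHOD)
            )
            report.raw_count[sv_type] += 1
    return records


def read_delly(
    paths,
    params: MergeParams | None = None,
    resolve: bool = True,
) -> tuple[CallSet, ReaderReport]:
    params = params or MergeParams()
    th = params.thresholds_for("delly")
    report = ReaderReport(method=METHOD)
    cs = CallSet(method=METHOD)
    for rec in parse_delly(paths, report):
        kv = dict(p.split("=", 1) for p in rec.info.split(";"))
        total = sum(int(v) for k, v in kv.items() if k in ("PE", "SR"))
        if th.min_support is not None and total < th.min_support:
            report.skip("<delly>", None,
                        f"PE+SR {total} < {th.min_support}", rec.sv_type)
            continue
        reason = size_gate_reason(rec, params)
        if reason:
            report.skip("<delly>", None, reason, rec.sv_type)
            continue
        cs.add(rec)
    return finalize(cs, report, params, resolve)
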