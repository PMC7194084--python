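"""Reader for Lumpy output: VCF (SVTYPE/END/SU) or simple BEDPE.

The VCF route reads INFO/SU (total supporting evidence); the BEDPE route
expects the classic layout with breakpoint intervals in columns 1–6, a
``TYPE:...`` token in column 11 and an ``SU:N`` token in a later column.
BEDPE is 0-based half-open: ``pos1 = start1 + 1`` and ``pos2 = end2``.
Info strings are ``SU=N``; the retained-record gate is SU >= 3 by default.
"""

from __future__ import annotations

from pathlib import Path

from ..core import (
    CallSet,
    MergeParams,
    SVRecord,
    UnknownSVTypeError,
    normalize_type,
)
from ._common import CALLER_NAMES, ReaderReport, finalize, size_gate_reason
from ._vcf import iter_sv_vcf

METHOD = CALLER_NAMES["lumpy"]


def _parse_bedpe(path: str | Path, report: ReaderReport) -> list[SVRecord]:
    records: list[SVRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 11:
                raise ValueError(f"{path}:{lineno}: expected >= 11 BEDPE columns")
            chrom1, chrom2 = cols[0], cols[3]
            if chrom1 != chrom2:
                report.skip(path, lineno, "interchromosomal prediction")
                continue
            label = next((c.split(":", 1)[1] for c in cols[10:]
                          if c.startswith("TYPE:")), None)
            if label is None:
                raise ValueError(f"{path}:{lineno}: no TYPE: token")
            try:
                sv_type = normalize_type(label, METHOD)
            except UnknownSVTypeError as exc:
                report.skip(path, lineno, str(exc))
                continue
            su = 0
            for c in cols[10:]:
                for tok in c.replace(";", "\t").split("\t"):
                    if tok.startswith("SU:"):
                        su = int(tok.split(":", 1)[1])
            pos1 = int(cols[1]) + 1
            pos2 = int(cols[5])
            if pos1 > pos2:
                pos1, pos2 = pos2, pos1
            records.append(
                SVRecord(chrom1, pos1, pos2, pos2 - pos1 + 1,
                         f"SU={su}", sv_type, METHOD)
            )
            report.raw_count[sv_type] += 1
    return records


def parse_lumpy(path: str | Path, report: ReaderReport | None = None) -> list[SVRecord]:
    if report is None:
        report = ReaderReport(method=METHOD)
    if str(path).endswith(".bedpe"):
        return _parse_bedpe(path, report)
    records: list[SVRecord] = []
    for chrom, pos1, pos2, sv_type, info, _ in iter_sv_vcf(path, METHOD, report):
        su = int(info.get("SU") or 0)
        records.append(
            SVRecord(chrom, pos1, pos2, pos2 - pos1 + 1,
                     f"SU={su}", sv_type, METHOD)
        )
        report.raw_count[sv_type] += 1
    return records


def read_lumpy(
    path: str | Path,
    params: MergeParams | None = None,
    resolve: bool = True,
) -> tuple[CallSet, ReaderReport]:
    params = params or MergeParams()
    th = params.thresholds_for("lumpy")
    report = ReaderReport(method=METHOD)
    cs = CallSet(method=METHOD)
    for rec in parse_lumpy(path, report):
        su = int(rec.info.split("=", 1)[1])
        if th.min_support is not None and su < th.min_support:
            report.skip("<lumpy>", None, f"SU {su} < {th.min_support}",
                        rec.sv_type)
            continue
        reason = size_gate_reason(rec, params)
        if reason:
            report.skip("<lumpy>", None, reason, rec.sv_type)
            continue
        cs.add(rec)
    return finalize(cs, report, params, resolve)
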