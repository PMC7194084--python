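"""Reader for SVseq2 deletion output.

SVseq2 predicts deletions only.  The supported layout is a tab-delimited
deletion summary, one record per line::

    chrom  start  end  split_read_count

with ``#`` comment lines ignored.  Info strings are ``SR=N``; the
retained-record gate is split reads >= 3 by default.
"""

from __future__ import annotations

from pathlib import Path

from ..core import CallSet, MergeParams, SVRecord
from ._common import CALLER_NAMES, ReaderReport, finalize, size_gate_reason

METHOD = CALLER_NAMES["svseq"]


def parse_svseq(path: str | Path, report: ReaderReport | None = None) -> list[SVRecord]:
    if report is None:
        report = ReaderReport(method=METHOD)
    records: list[SVRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 columns "
                    "(chrom, start, end, split reads)"
                )
            try:
                pos1, pos2, sr = int(cols[1]), int(cols[2]), int(cols[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if pos1 > pos2:
                pos1, pos2 = pos2, pos1
            records.append(
                SVRecord(cols[0], pos1, pos2, pos2 - pos1 + 1,
                         f"SR={sr}", "del", METHOD)
            )
            report.raw_count["del"] += 1
    return records


def read_svseq(
    path: str | Path,
    params: MergeParams | None = None,
    resolve: bool = True,
) -> tuple[CallSet, ReaderReport]:
    params = params or MergeParams()
    th = params.thresholds_for("svseq")
    report = ReaderReport(method=METHOD)
    cs = CallSet(method=METHOD)
    for rec in parse_svseq(path, report):
        sr = int(rec.info.split("=", 1)[1])
        if th.min_split_reads is not None and sr < th.min_split_reads:
            report.skip("<svseq>", None, f"SR {sr} < {th.min_split_reads}",
                        rec.sv_type)
            continue
        reason = size_gate_reason(rec, params)
        if reason:
            report.skip("<svseq>", None, reason, rec.sv_type)
            continue
        cs.add(rec)
    return finalize(cs, report, params, resolve)
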