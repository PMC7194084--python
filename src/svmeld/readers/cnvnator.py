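"""Reader for CNVnator call files (one file per chromosome).

Each line of a call file is::

    deletion|duplication  chrom:start-end  size  normalized_RD  e1 e2 e3 e4 [q0]

The printed region is taken as 1-based inclusive; the record size is
computed as ``end - start`` (the convention of the integrated output this
package reproduces) rather than the file's own size column.  CNVnator is a
read-depth caller, so no read-support gate applies — only the size window.
A file in the directory whose lines do not parse is a hard error, guarding
against stray non-CNVnator files.
"""

from __future__ import annotations

import os
from pathlib import Path

from ..core import (
    CallSet,
    DataError,
    MergeParams,
    SVRecord,
    UnknownSVTypeError,
    normalize_type,
)
from ._common import CALLER_NAMES, ReaderReport, finalize, size_gate_reason

METHOD = CALLER_NAMES["cnvnator"]


def parse_cnvnator(dir_path: str | Path, report: ReaderReport | None = None) -> list[SVRecord]:
    if report is None:
        report = ReaderReport(method=METHOD)
    dir_path = Path(dir_path)
    if not dir_path.is_dir():
        raise DataError(f"{dir_path} is not a directory of CNVnator call files")
    records: list[SVRecord] = []
    for name in sorted(os.listdir(dir_path)):
        path = dir_path / name
        if not path.is_file():
            continue
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                cols = line.split("\t")
                try:
                    if len(cols) < 8:
                        raise ValueError(f"expected >= 8 columns, got {len(cols)}")
                    region = cols[1]
                    chrom, rng = region.split(":", 1)
                    start_s, end_s = rng.split("-", 1)
                    pos1, pos2 = int(start_s), int(end_s)
                    evals = [float(c) for c in cols[4:8]]
                except ValueError as exc:
                    raise DataError(
                        f"{path}:{lineno}: not a CNVnator call line ({exc}); "
                        "the directory must contain only final CNVnator output"
                    ) from exc
                try:
                    sv_type = normalize_type(cols[0], METHOD)
                except UnknownSVTypeError as exc:
                    report.skip(path, lineno, str(exc))
                    continue
                info = ";".join(f"eval{i + 1}={cols[4 + i]}" for i in range(4))
                records.append(
                    SVRecord(chrom, pos1, pos2, pos2 - pos1, info, sv_type, METHOD)
                )
                report.raw_count[sv_type] += 1
    return records


def read_cnvnator(
    dir_path: str | Path,
    params: MergeParams | None = None,
    resolve: bool = True,
) -> tuple[CallSet, ReaderReport]:
    params = params or MergeParams()
    report = ReaderReport(method=METHOD)
    cs = CallSet(method=METHOD)
    for rec in parse_cnvnator(dir_path, report):
        reason = size_gate_reason(rec, params)
        if reason:
            report.skip("<cnvnator>", None, reason, rec.sv_type)
            continue
        cs.add(rec)
    return finalize(cs, report, params, resolve)
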