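"""Reader for BreakDancer tab-delimited output.

BreakDancer writes all predictions to a single file.  Header lines start
with ``#``; data columns are::

    chr1 pos1 orient1 chr2 pos2 orient2 type size score num_reads [...]

Only intrachromosomal deletions and inversions are kept (the only SV types
this caller reports within our del/dup/inv universe).  Retained records get
an info string ``score=S;PE=N``.
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

METHOD = CALLER_NAMES["breakdancer"]

_MIN_COLS = 10


def parse_breakdancer(path: str | Path, report: ReaderReport | None = None) -> list[SVRecord]:
    """Parse raw records without applying any quality filter.

    Unknown-type and interchromosomal rows are skipped (logged on
    ``report``); truncated rows raise a hard parse error naming the line.
    """
    if report is None:
        report = ReaderReport(method=METHOD)
    records: list[SVRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < _MIN_COLS:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {_MIN_COLS} columns, "
                    f"got {len(cols)}"
                )
            chrom1, chrom2 = cols[0], cols[3]
            if chrom1 != chrom2:
                report.skip(path, lineno, "interchromosomal prediction")
                continue
            try:
                sv_type = normalize_type(cols[6], METHOD)
            except UnknownSVTypeError as exc:
                report.skip(path, lineno, str(exc))
                continue
            try:
                pos1, pos2 = int(cols[1]), int(cols[4])
                size = int(float(cols[7]))
                score = float(cols[8])
                pe = int(cols[9])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if pos1 > pos2:
                pos1, pos2 = pos2, pos1
            score_s = f"{score:g}"
            records.append(
                SVRecord(chrom1, pos1, pos2, size,
                         f"score={score_s};PE={pe}", sv_type, METHOD)
            )
            report.raw_count[sv_type] += 1
    return records


def read_breakdancer(
    path: str | Path,
    params: MergeParams | None = None,
    resolve: bool = True,
) -> tuple[CallSet, ReaderReport]:
    """Read, quality-filter and (optionally) self-resolve BreakDancer output.

    Gates: score >= ``min_score`` (default 60), discordant read pairs >=
    ``min_read_pairs`` (default 3), effective size inside the global window.
    """
    params = params or MergeParams()
    th = params.thresholds_for("breakdancer")
    report = ReaderReport(method=METHOD)
    cs = CallSet(method=METHOD)
    for rec in parse_breakdancer(path, report):
        kv = dict(p.split("=", 1) for p in rec.info.split(";"))
        if th.min_score is not None and float(kv["score"]) < th.min_score:
            report.skip(path, None, f"score {kv['score']} < {th.min_score}",
                        rec.sv_type)
            continue
        if th.min_read_pairs is not None and int(kv["PE"]) < th.min_read_pairs:
            report.skip(path, None, f"PE {kv['PE']} < {th.min_read_pairs}",
                        rec.sv_type)
            continue
        reason = size_gate_reason(rec, params)
        if reason:
            report.skip(path, None, reason, rec.sv_type)
            continue
        cs.add(rec)
    return finalize(cs, report, params, resolve)
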