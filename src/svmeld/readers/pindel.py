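"""Reader for Pindel per-type output files (``*_D``, ``*_TD``, ``*_INV``).

Each Pindel record is a multi-line block: a ``####...`` separator, a
tab-delimited summary line, then the supporting read alignments.  The
summary line carries tokens such as::

    17  D 374  NT 0 ""  ChrID chr05  BP 65574  65950  BP_range ...  \
        Supports 11  11  + 6 6  - 5 5  S1 12  SUM_MS 330 ...

Pindel breakpoints flank the event: ``BP a b`` denotes the bases just
outside it, so the event occupies ``[a+1, b-1]``; ingest converts to the
package's 1-based inclusive convention.  Supporting reads come from the
``Supports`` token and the score from ``S1``; the info string is
``SR=N;score=S``.
"""

from __future__ import annotations

import glob
import logging
import os
from pathlib import Path

from ..core import (
    CallSet,
    MergeParams,
    SVRecord,
    UnknownSVTypeError,
    normalize_type,
)
from ._common import CALLER_NAMES, ReaderReport, finalize, size_gate_reason

log = logging.getLogger("svmeld.readers")

METHOD = CALLER_NAMES["pindel"]

_SUFFIXES = ("_D", "_TD", "_INV")


def _collect_files(dir_or_files) -> list[Path]:
    if isinstance(dir_or_files, (str, Path)) and os.path.isdir(dir_or_files):
        found = []
        for suf in _SUFFIXES:
            found.extend(sorted(glob.glob(os.path.join(dir_or_files, f"*{suf}"))))
        return [Path(p) for p in found]
    if isinstance(dir_or_files, (str, Path)):
        return [Path(dir_or_files)]
    return [Path(p) for p in dir_or_files]


def _parse_summary(line: str):
    """Extract (type_label, chrom, bp1, bp2, supports, score) from a summary line."""
    fields = line.split("\t")
    int(fields[0])  # leading index validates this as a summary line
    type_label = fields[1].split()[0]
    chrom = bp1 = bp2 = supports = score = None
    for i, f in enumerate(fields):
        toks = f.split()
        if not toks:
            continue
        if toks[0] == "ChrID":
            chrom = toks[1]
        elif toks[0] == "BP" and len(toks) > 1:
            bp1 = int(toks[1])
            bp2 = int(fields[i + 1].split()[0])
        elif toks[0] == "Supports":
            supports = int(toks[1])
        elif toks[0] == "S1":
            score = int(toks[1])
    if None in (chrom, bp1, bp2, supports):
        raise ValueError("summary line lacks ChrID/BP/Supports tokens")
    return type_label, chrom, bp1, bp2, supports, score if score is not None else 0


def parse_pindel(dir_or_files, report: ReaderReport | None = None) -> list[SVRecord]:
    """Parse raw Pindel records (no quality filter).

    Malformed block headers are skipped with a logged reason; an input set
    with no Pindel files yields an empty list with a warning.
    """
    if report is None:
        report = ReaderReport(method=METHOD)
    files = _collect_files(dir_or_files)
    if not files:
        log.warning("no Pindel output files found under %r", dir_or_files)
        report.skip(str(dir_or_files), None, "no Pindel output files found")
        return []
    records: list[SVRecord] = []
    for path in files:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                first = line.split("\t")[0]
                if not first.strip().isdigit():
                    continue  # supporting-read alignment line
                try:
                    label, chrom, bp1, bp2, sr, score = _parse_summary(line)
                    sv_type = normalize_type(label, METHOD)
                except UnknownSVTypeError as exc:
                    report.skip(path, lineno, str(exc))
                    continue
                except (ValueError, IndexError) as exc:
                    report.skip(path, lineno, f"malformed block header: {exc}")
                    continue
                pos1, pos2 = bp1 + 1, bp2 - 1
                if pos1 > pos2:
                    report.skip(path, lineno, "degenerate breakpoints")
                    continue
                records.append(
                    SVRecord(chrom, pos1, pos2, pos2 - pos1 + 1,
                             f"SR={sr};score={score}", sv_type, METHOD)
                )
                report.raw_count[sv_type] += 1
    return records


def read_pindel(
    dir_or_files,
    params: MergeParams | None = None,
    resolve: bool = True,
) -> tuple[CallSet, ReaderReport]:
    """Read and filter Pindel output: split reads >= 3, global size window."""
    params = params or MergeParams()
    th = params.thresholds_for("pindel")
    report = ReaderReport(method=METHOD)
    cs = CallSet(method=METHOD)
    for rec in parse_pindel(dir_or_files, report):
        kv = dict(p.split("=", 1) for p in rec.info.split(";"))
        if th.min_split_reads is not None and int(kv["SR"]) < th.min_split_reads:
            report.skip("<pindel>", None, f"SR {kv['SR']} < {th.min_split_reads}",
                        rec.sv_type)
            continue
        reason = size_gate_reason(rec, params)
        if reason:
            report.skip("<pindel>", None, reason, rec.sv_type)
            continue
        cs.add(rec)
    return finalize(cs, report, params, resolve)
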