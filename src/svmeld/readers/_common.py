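"""Shared reader machinery: reports, gate checks, self-overlap resolution."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from ..core import (
    CallSet,
    MergeParams,
    SVRecord,
    SV_TYPES,
    effective_size,
    primary_support,
    reciprocal_overlap,
)

log = logging.getLogger("svmeld.readers")

#: canonical caller key -> display name used in merged methods strings
CALLER_NAMES = {
    "breakdancer": "BreakDancer",
    "pindel": "Pindel",
    "cnvnator": "CNVnator",
    "delly": "Delly",
    "svseq": "SVseq2",
    "lumpy": "Lumpy",
    "softsearch": "SoftSearch",
}


@dataclass(slots=True)
class SkippedRecord:
    file: str
    line: int | None
    reason: str
    sv_type: str | None = None  # None when the type itself was unrecognized


@dataclass(slots=True)
class ReaderReport:
    """Raw-vs-kept accounting for one caller's read pass.

    ``raw_count[t] == kept_count[t] + len(skips of type t)`` for every
    recognized SV type; skips with ``sv_type=None`` (unknown type,
    interchromosomal, unparsable line) are outside the per-type ledger.
    """

    method: str
    raw_count: dict[str, int] = field(default_factory=lambda: {t: 0 for t in SV_TYPES})
    kept_count: dict[str, int] = field(default_factory=lambda: {t: 0 for t in SV_TYPES})
    skipped: list[SkippedRecord] = field(default_factory=list)

    def skip(self, file: str, line: int | None, reason: str,
             sv_type: str | None = None) -> None:
        self.skipped.append(SkippedRecord(str(file), line, reason, sv_type))
        log.debug("%s: skipped %s:%s (%s)", self.method, file, line, reason)

    def summary(self) -> str:
        lines = [f"[{self.method}]"]
        for t in SV_TYPES:
            lines.append(f"  {t}: raw={self.raw_count[t]} kept={self.kept_count[t]}")
        for s in self.skipped:
            loc = f"{s.file}:{s.line}" if s.line is not None else s.file
            lines.append(f"  skipped {loc}: {s.reason}")
        return "\n".join(lines)


def size_gate_reason(rec: SVRecord, params: MergeParams) -> str | None:
    size = effective_size(rec)
    if size < params.min_size:
        return f"size {size} < min_size {params.min_size}"
    if size > params.max_size:
        return f"size {size} > max_size {params.max_size}"
    return None


def finalize(
    cs: CallSet,
    report: ReaderReport,
    params: MergeParams,
    resolve: bool,
) -> tuple[CallSet, ReaderReport]:
    """Sort a filtered callset and optionally resolve self-overlaps."""
    cs.sort()
    if resolve:
        cs = resolve_self_overlaps(cs, params, report)
    for t in SV_TYPES:
        report.kept_count[t] = len(cs.records.get(t, []))
    return cs, report


def resolve_self_overlaps(
    cs: CallSet,
    params: MergeParams,
    report: ReaderReport | None = None,
) -> CallSet:
    """Drop within-caller predictions that reciprocally overlap a better one.

    Greedy non-maximum suppression per SV type: records are visited by
    decreasing primary support (ties: smaller pos1, then pos2) and kept only
    if they do not overlap (RO > ``overlap_frac``) an already-kept record.
    The retained set therefore contains no overlapping pair, and every
    dropped record overlaps a kept record with support >= its own.
    """
    out = CallSet(method=cs.method)
    for sv_type, recs in cs.records.items():
        order = sorted(
            recs, key=lambda r: (-primary_support(r), r.chrom, r.pos1, r.pos2)
        )
        kept: list[SVRecord] = []
        for r in order:
            clash = any(
                k.chrom == r.chrom
                and reciprocal_overlap(k.interval, r.interval) > params.overlap_frac
                for k in kept
            )
            if clash:
                if report is not None:
                    report.skip("<self-overlap>", None,
                                "overlaps a better-supported prediction", sv_type)
            else:
                kept.append(r)
        out.records[sv_type] = sorted(kept, key=lambda r: (r.chrom, r.pos1, r.pos2))
    return out
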