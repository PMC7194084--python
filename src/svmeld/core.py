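"""Shared domain types and interval arithmetic.

Coordinates are 1-based and inclusive everywhere in this package; format
readers and writers convert to/from other conventions (0-based half-open
BED/BEDPE, Pindel breakpoint offsets) at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "SV_TYPES",
    "SVRecord",
    "CallSet",
    "CallerThresholds",
    "MergeParams",
    "ConfigurationError",
    "DataError",
    "UnknownSVTypeError",
    "span",
    "effective_size",
    "reciprocal_overlap",
    "normalize_type",
    "parse_info",
    "primary_support",
    "read_chrom_sizes",
]

#: Canonical structural-variant types handled by the pipeline.
SV_TYPES = ("del", "dup", "inv")


class ConfigurationError(Exception):
    """Bad user configuration (unknown caller, impossible thresholds...)."""


class DataError(Exception):
    """Malformed or inconsistent input data."""


class UnknownSVTypeError(DataError):
    """A caller label that does not map onto del/dup/inv."""


@dataclass(slots=True)
class SVRecord:
    """A single prediction from one caller.

    Parameters
    ----------
    chrom : str
        Chromosome identifier.
    pos1, pos2 : int
        Start and end coordinate (1-based, inclusive, bp); ``pos1 <= pos2``.
    size : int or float or None
        Caller-reported event length in bp.  May be negative (some callers
        sign inversions) or differ from the coordinate span; ``None`` when
        the caller reports no size.
    info : str
        Semicolon-separated ``key=value`` support string, e.g.
        ``"score=88;PE=5"``.
    sv_type : str
        One of ``del``, ``dup``, ``inv``.
    method : str
        Display name of the source caller, e.g. ``"BreakDancer"``.
    """

    chrom: str
    pos1: int
    pos2: int
    size: float | int | None
    info: str
    sv_type: str
    method: str

    def __post_init__(self) -> None:
        if self.pos1 > self.pos2:
            raise ValueError(f"pos1 > pos2 ({self.pos1} > {self.pos2})")
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if not self.method:
            raise ValueError("method must be non-empty")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.pos1, self.pos2)


@dataclass(slots=True)
class CallSet:
    """All retained predictions of one caller, grouped by SV type."""

    method: str
    records: dict[str, list[SVRecord]] = field(
        default_factory=lambda: {t: [] for t in SV_TYPES}
    )

    def add(self, rec: SVRecord) -> None:
        if rec.method != self.method:
            raise ValueError(f"record method {rec.method!r} != {self.method!r}")
        self.records.setdefault(rec.sv_type, []).append(rec)

    def sort(self) -> None:
        for recs in self.records.values():
            recs.sort(key=lambda r: (r.chrom, r.pos1, r.pos2))

    def counts(self) -> dict[str, int]:
        return {t: len(v) for t, v in self.records.items()}

    def __len__(self) -> int:
        return sum(len(v) for v in self.records.values())


@dataclass(slots=True)
class CallerThresholds:
    """Per-caller support gates; ``None`` disables a gate."""

    min_score: float | None = None
    min_read_pairs: int | None = None
    min_split_reads: int | None = None
    min_support: int | None = None  # summed/total support (e.g. PE+SR)


def _default_thresholds() -> dict[str, CallerThresholds]:
    return {
        "breakdancer": CallerThresholds(min_score=60, min_read_pairs=3),
        "pindel": CallerThresholds(min_split_reads=3),
        "cnvnator": CallerThresholds(),  # read-depth caller: no support gate
        "delly": CallerThresholds(min_support=3),
        "svseq": CallerThresholds(min_split_reads=3),
        "lumpy": CallerThresholds(min_support=3),
        "softsearch": CallerThresholds(min_split_reads=3, min_read_pairs=3),
    }


@dataclass(slots=True)
class MergeParams:
    """Thresholds governing filtering and merging.

    ``overlap_frac`` is compared strictly: two calls cluster only when their
    reciprocal overlap exceeds it.
    """

    overlap_frac: float = 0.8
    min_methods: int = 2
    min_size: int = 100
    max_size: int = 10_000_000
    per_caller: dict[str, CallerThresholds] = field(
        default_factory=_default_thresholds
    )

    def __post_init__(self) -> None:
        if not 0 < self.overlap_frac <= 1:
            raise ConfigurationError("overlap_frac must be in (0, 1]")
        if self.min_methods < 1:
            raise ConfigurationError("min_methods must be >= 1")
        if not 0 < self.min_size < self.max_size:
            raise ConfigurationError("need 0 < min_size < max_size")

    def thresholds_for(self, caller: str) -> CallerThresholds:
        key = caller.lower()
        key = {"svseq2": "svseq"}.get(key, key)
        return self.per_caller.get(key, CallerThresholds())

    @classmethod
    def from_dict(cls, d: Mapping) -> "MergeParams":
        callers = dict(_default_thresholds())
        for name, sub in (d.get("callers") or {}).items():
            base = callers.get(name.lower(), CallerThresholds())
            callers[name.lower()] = replace(base, **dict(sub))
        kwargs = {
            k: d[k]
            for k in ("overlap_frac", "min_methods", "min_size", "max_size")
            if k in d
        }
        return cls(per_caller=callers, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MergeParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ConfigurationError(f"config {path} is not a mapping")
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# interval arithmetic


def span(r: SVRecord | tuple[int, int]) -> int:
    """1-based inclusive length of a record or ``(start, end)`` interval."""
    p1, p2 = (r.pos1, r.pos2) if isinstance(r, SVRecord) else r
    return p2 - p1 + 1


def effective_size(r: SVRecord) -> int:
    """Length used by the size filter.

    The magnitude of the caller-reported size when present, otherwise the
    coordinate span.  Callers may sign inversions negatively or report a
    size that differs from the span; the filter acts on the reported value.
    """
    if r.size is not None:
        return abs(int(r.size))
    return span(r)


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Reciprocal overlap of two 1-based inclusive intervals.

    ``min(o/len(a), o/len(b))`` with ``o`` the intersection length (0 when
    disjoint).  Chromosome equality is the caller's responsibility.
    """
    o = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if o <= 0:
        return 0.0
    return min(o / (a[1] - a[0] + 1), o / (b[1] - b[0] + 1))


# ---------------------------------------------------------------------------
# caller vocabulary

_LABELS = {
    "del": "del",
    "deletion": "del",
    "d": "del",
    "dup": "dup",
    "duplication": "dup",
    "td": "dup",
    "tandem_duplication": "dup",
    "dup:tandem": "dup",
    "inv": "inv",
    "inversion": "inv",
}


def normalize_type(caller_label: str, method: str = "") -> str:
    """Map a caller's native SV-type label onto del/dup/inv.

    Raises :class:`UnknownSVTypeError` for labels outside the supported
    universe (translocations, insertions, breakends...); readers catch this
    and log the record as skipped.
    """
    sv_type = _LABELS.get(caller_label.strip().lower())
    if sv_type is None:
        raise UnknownSVTypeError(
            f"unsupported SV type label {caller_label!r}"
            + (f" from {method}" if method else "")
        )
    return sv_type


# ---------------------------------------------------------------------------
# support strings

def parse_info(info: str) -> dict[str, str]:
    """Split a ``key=value;key=value`` support string into a dict."""
    out: dict[str, str] = {}
    for part in info.split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise DataError(f"info field {part!r} is not key=value")
        k, v = part.split("=", 1)
        out[k] = v
    return out


# key carrying the primary evidence count, per caller
_PRIMARY_KEY = {
    "breakdancer": ("PE",),
    "pindel": ("SR",),
    "svseq2": ("SR",),
    "lumpy": ("SU",),
    "softsearch": ("nSC",),
    "delly": ("PE", "SR"),  # summed
    "cnvnator": (),
}


def primary_support(rec: SVRecord) -> float:
    """Primary read-support value of a record (0 for read-depth callers).

    Used to pick the best-supported record when resolving within-caller
    overlaps and when collapsing same-caller duplicates inside a cluster.
    """
    kv = parse_info(rec.info)
    keys = _PRIMARY_KEY.get(rec.method.lower())
    if keys is None:
        keys = tuple(k for k in ("PE", "SR", "SU", "nSC") if k in kv)
    total = 0.0
    for k in keys:
        if k in kv:
            try:
                total += float(kv[k])
            except ValueError:
                pass
    return total


# ---------------------------------------------------------------------------
# plumbing

def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column headerless TSV of (chromosome, length-bp)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataError(f"{path}:{lineno}: expected 2 columns")
            try:
                length = int(parts[1])
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: bad length {parts[1]!r}") from exc
            if length <= 0:
                raise DataError(f"{path}:{lineno}: non-positive length")
            sizes[parts[0]] = length
    return sizes


def sort_records(records: Iterable[SVRecord]) -> list[SVRecord]:
    return sorted(records, key=lambda r: (r.chrom, r.pos1, r.pos2))
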