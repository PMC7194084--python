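"""Shared helpers for VCF-based caller outputs (DELLY, Lumpy, SoftSearch).

POS is taken as the first affected base and INFO/END as the last affected
base, both 1-based inclusive — matching how symbolic-allele SV records are
written by the supported callers.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pysam

from ..core import DataError, UnknownSVTypeError, normalize_type
from ._common import ReaderReport


def _scalar(value):
    if isinstance(value, (tuple, list)):
        return value[0] if value else None
    return value


def iter_sv_vcf(path: str | Path, method: str, report: ReaderReport):
    """Yield ``(chrom, pos1, pos2, sv_type, info_dict, lineno)`` per record.

    Records without SVTYPE/END, or with END < POS, raise a hard parse
    error; SVTYPEs outside del/dup/inv (BND, INS, TRA...) are skipped with
    a logged reason.
    """
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # pysam warns on absent contigs
            vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise DataError(f"cannot open VCF {path}: {exc}") from exc
    with vf:
        for i, rec in enumerate(vf.fetch() if vf.index else vf, 1):
            svtype = _scalar(rec.info.get("SVTYPE"))
            if svtype is None:
                raise DataError(f"{path}: record {i} ({rec.chrom}:{rec.pos}) "
                                "lacks INFO/SVTYPE")
            if "END" not in rec.info and rec.stop == rec.start + 1:
                # pysam defaults stop to pos when END is absent; reject SVs
                # spanning a single base only when END was truly missing
                raise DataError(f"{path}: record {i} ({rec.chrom}:{rec.pos}) "
                                "lacks INFO/END")
            try:
                sv_type = normalize_type(str(svtype), method)
            except UnknownSVTypeError as exc:
                report.skip(path, i, str(exc))
                continue
            pos1, pos2 = rec.pos, rec.stop
            if pos2 < pos1:
                raise DataError(f"{path}: record {i}: END {pos2} < POS {pos1}")
            info = {k: _scalar(v) for k, v in rec.info.items()}
            yield rec.chrom, pos1, pos2, sv_type, info, i
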