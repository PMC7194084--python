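"""Intersect merged SVs with gene models and report overlapped elements.

Gene models come from GFF3 (1-based inclusive).  Introns are derived as
the gaps between consecutive exons of each transcript and deduplicated per
gene by coordinates.  Optional upstream/downstream flanks (strand-aware,
clipped at chromosome bounds) can be emitted for promoter-proximal
annotation.  An SV overlaps an element as soon as they share one base; no
minimum-fraction rule applies here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import gffutils

from .core import DataError
from .merge import MergedSV

log = logging.getLogger("svmeld.annotate")

__all__ = [
    "GeneElement",
    "AnnotatedSV",
    "read_gene_models",
    "annotate_svs",
    "count_affected_genes",
    "write_annotated",
]

#: closed vocabulary of element tags
ELEMENT_TAGS = (
    "gene", "exon", "intron", "five_prime_UTR", "three_prime_UTR",
    "CDS", "upstream", "downstream",
)

_TRANSCRIPT_TYPES = ("mRNA", "transcript")
_SUBFEATURE_TYPES = ("exon", "CDS", "five_prime_UTR", "three_prime_UTR")


@dataclass(slots=True)
class GeneElement:
    """One annotated genomic feature."""

    tag: str
    chrom: str
    start: int
    end: int
    strand: str
    id: str
    parent_gene: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"element start {self.start} > end {self.end}")
        if self.tag not in ELEMENT_TAGS:
            raise ValueError(f"unknown element tag {self.tag!r}")
        if self.tag != "gene" and not self.parent_gene:
            raise ValueError("sub-gene element without parent_gene")


@dataclass(slots=True)
class AnnotatedSV:
    """One (SV, overlapped element) pair; element fields empty when the SV
    overlaps nothing."""

    chrom: str
    pos1: int
    pos2: int
    info: str
    sv_type: str
    tag: str = ""
    start: int | None = None
    end: int | None = None
    strand: str = ""
    id: str = ""
    parent_gene: str = ""


def _validate_gff3(path: str | Path) -> None:
    # gffutils silently drops malformed lines; fail loudly with a line number
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise DataError(f"{path}:{lineno}: GFF3 line has {len(cols)} "
                                "columns, expected 9")
            if not cols[3].isdigit() or not cols[4].isdigit():
                raise DataError(f"{path}:{lineno}: non-numeric coordinates")


def read_gene_models(
    path: str | Path,
    flank_bp: int = 2000,
    chrom_sizes: dict[str, int] | None = None,
) -> list[GeneElement]:
    """Load gene/exon/intron/UTR/CDS elements from a GFF3 file.

    Set ``flank_bp=0`` to suppress upstream/downstream elements.  Features
    whose gene parent cannot be resolved are skipped with a warning.
    """
    _validate_gff3(path)
    try:
        db = gffutils.create_db(
            str(path), ":memory:",
            merge_strategy="create_unique", keep_order=True,
        )
    except Exception as exc:  # gffutils raises bare ValueError on bad lines
        raise DataError(f"cannot parse GFF3 {path}: {exc}") from exc

    elements: list[GeneElement] = []
    transcript_gene: dict[str, str] = {}

    for gene in db.features_of_type("gene"):
        elements.append(GeneElement("gene", gene.seqid, gene.start, gene.end,
                                    gene.strand or ".", gene.id, gene.id))
        if flank_bp > 0:
            elements.extend(_flanks(gene, flank_bp, chrom_sizes))

    for ftype in _TRANSCRIPT_TYPES:
        for tx in db.features_of_type(ftype):
            parents = [g.id for g in db.parents(tx, featuretype="gene")]
            if not parents:
                log.warning("transcript %s has no gene parent; skipped", tx.id)
                continue
            transcript_gene[tx.id] = parents[0]

    for ftype in _SUBFEATURE_TYPES:
        for feat in db.features_of_type(ftype):
            gene_ids = {g.id for g in db.parents(feat, featuretype="gene")}
            if not gene_ids:
                txs = feat.attributes.get("Parent", [])
                gene_ids = {transcript_gene[t] for t in txs if t in transcript_gene}
            if not gene_ids:
                log.warning("%s %s has no resolvable gene parent; skipped",
                            ftype, feat.id)
                continue
            for gid in sorted(gene_ids):
                elements.append(GeneElement(ftype, feat.seqid, feat.start,
                                            feat.end, feat.strand or ".",
                                            feat.id, gid))

    elements.extend(_derive_introns(db, transcript_gene))
    elements.sort(key=lambda e: (e.chrom, e.start, e.end, e.tag, e.id))
    return elements


def _flanks(gene, flank_bp: int, chrom_sizes) -> list[GeneElement]:
    chrom_len = (chrom_sizes or {}).get(gene.seqid)
    out = []
    left = (max(1, gene.start - flank_bp), gene.start - 1)
    right = (gene.end + 1, gene.end + flank_bp if chrom_len is None
             else min(chrom_len, gene.end + flank_bp))
    # upstream is 5' of the gene: left side for '+', right side for '-'
    if gene.strand == "-":
        sides = (("downstream", left), ("upstream", right))
    else:
        sides = (("upstream", left), ("downstream", right))
    for tag, (s, e) in sides:
        if s <= e:
            out.append(GeneElement(tag, gene.seqid, s, e, gene.strand or ".",
                                   f"{gene.id}.{tag}", gene.id))
    return out


def _derive_introns(db, transcript_gene: dict[str, str]) -> list[GeneElement]:
    per_gene: dict[str, set[tuple]] = {}
    out: list[GeneElement] = []
    for ftype in _TRANSCRIPT_TYPES:
        for tx in db.features_of_type(ftype):
            gid = transcript_gene.get(tx.id)
            if gid is None:
                continue
            exons = sorted(db.children(tx, featuretype="exon"),
                           key=lambda e: (e.start, e.end))
            for i in range(len(exons) - 1):
                s, e = exons[i].end + 1, exons[i + 1].start - 1
                if s > e:
                    continue  # abutting/overlapping exons leave no gap
                key = (tx.seqid, s, e)
                seen = per_gene.setdefault(gid, set())
                if key in seen:
                    continue
                seen.add(key)
                out.append(GeneElement(
                    "intron", tx.seqid, s, e, tx.strand or ".",
                    f"{tx.id}.intron{len(seen)}", gid,
                ))
    return out


def annotate_svs(
    merged: list[MergedSV],
    elements: list[GeneElement],
) -> list[AnnotatedSV]:
    """Emit one row per (SV, element) overlap, in SV order then element
    start order; SVs overlapping nothing yield one row with empty element
    fields."""
    by_chrom: dict[str, list[GeneElement]] = {}
    for e in elements:
        by_chrom.setdefault(e.chrom, []).append(e)
    for lst in by_chrom.values():
        lst.sort(key=lambda e: (e.start, e.end, e.tag, e.id))

    rows: list[AnnotatedSV] = []
    for sv in merged:
        hits = [
            e for e in by_chrom.get(sv.chrom, [])
            if e.start <= sv.pos2 and e.end >= sv.pos1
        ]
        if not hits:
            rows.append(AnnotatedSV(sv.chrom, sv.pos1, sv.pos2, sv.info,
                                    sv.sv_type))
            continue
        for e in hits:
            rows.append(AnnotatedSV(sv.chrom, sv.pos1, sv.pos2, sv.info,
                                    sv.sv_type, e.tag, e.start, e.end,
                                    e.strand, e.id, e.parent_gene))
    return rows


def count_affected_genes(annotated: list[AnnotatedSV]) -> dict[str, int]:
    """Distinct genes touched by at least one SV, per SV type."""
    genes: dict[str, set[str]] = {}
    for row in annotated:
        if row.parent_gene:
            genes.setdefault(row.sv_type, set()).add(row.parent_gene)
    return {t: len(s) for t, s in genes.items()}


_HEADER = ["Chromosome", "Pos1", "Pos2", "info", "tag", "start", "end",
           "strand", "ID"]


def write_annotated(annotated: list[AnnotatedSV], path: str | Path) -> Path:
    """Write the nine-column annotation TSV."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for r in annotated:
            fh.write("\t".join([
                r.chrom, str(r.pos1), str(r.pos2), r.info, r.tag,
                "" if r.start is None else str(r.start),
                "" if r.end is None else str(r.end),
                r.strand, r.id,
            ]) + "\n")
    return path
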