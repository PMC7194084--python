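"""Cluster same-type SVs across callers and merge concordant clusters.

Pairwise distance between two same-type calls is 0 when they lie on the
same chromosome and reciprocally overlap by strictly more than the
threshold, else 1.  Single-linkage hierarchical clustering of such a 0/1
matrix cut below height 1 yields exactly the connected components of the
zero-distance graph, so the default implementation is union-find over a
coordinate sweep; a dense scipy-linkage path is retained for cross-checks.
Clusters contributed to by fewer than ``min_methods`` distinct callers are
discarded; the rest become one merged SV each, with start/end the rounded
means of member starts/ends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    CallSet,
    ConfigurationError,
    MergeParams,
    SVRecord,
    SV_TYPES,
    primary_support,
    reciprocal_overlap,
)

__all__ = [
    "SVCluster",
    "MergedSV",
    "build_distance_matrix",
    "cluster_svs",
    "merge_cluster",
    "methods_merge",
    "write_merged",
    "read_merged_tsv",
]


@dataclass(slots=True)
class SVCluster:
    sv_type: str
    members: list[SVRecord]

    @property
    def methods(self) -> set[str]:
        return {m.method for m in self.members}

    @property
    def chrom(self) -> str:
        return self.members[0].chrom


@dataclass(slots=True)
class MergedSV:
    """One integrated SV: mean coordinates plus provenance.

    ``methods`` is the ":"-joined list of distinct contributing callers in
    first-appearance order; ``info`` joins one support string per listed
    method, in the same order.
    """

    chrom: str
    pos1: int
    pos2: int
    methods: str
    info: str
    sv_type: str

    @property
    def interval(self) -> tuple[int, int]:
        return (self.pos1, self.pos2)

    @property
    def method_list(self) -> list[str]:
        return self.methods.split(":")


def build_distance_matrix(records: list[SVRecord], overlap_frac: float = 0.8) -> np.ndarray:
    """Dense 0/1 distance matrix: 0 iff same chrom and RO > threshold."""
    n = len(records)
    d = np.ones((n, n))
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = records[i], records[j]
            if a.chrom == b.chrom and \
                    reciprocal_overlap(a.interval, b.interval) > overlap_frac:
                d[i, j] = d[j, i] = 0.0
    return d


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def cluster_svs(
    records: list[SVRecord],
    overlap_frac: float = 0.8,
    method: str = "components",
) -> list[SVCluster]:
    """Partition same-type records into overlap clusters.

    ``method="components"`` (default) runs union-find over a sorted
    coordinate sweep; ``method="linkage"`` builds the dense matrix and cuts
    a scipy single-linkage dendrogram below height 1 — provably the same
    partition, kept as an oracle path.
    """
    if not records:
        return []
    types = {r.sv_type for r in records}
    if len(types) > 1:
        raise ConfigurationError(f"mixed sv_types in one clustering call: {types}")

    if method == "linkage":
        labels = _linkage_labels(records, overlap_frac)
    elif method == "components":
        labels = _component_labels(records, overlap_frac)
    else:
        raise ConfigurationError(f"unknown clustering method {method!r}")

    groups: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(lab, []).append(idx)
    clusters = [
        SVCluster(records[0].sv_type, [records[i] for i in sorted(idxs)])
        for idxs in groups.values()
    ]
    clusters.sort(key=lambda c: (c.chrom, min(m.pos1 for m in c.members),
                                 min(m.pos2 for m in c.members)))
    return clusters


def _component_labels(records: list[SVRecord], overlap_frac: float) -> list[int]:
    n = len(records)
    uf = _UnionFind(n)
    order = sorted(range(n), key=lambda i: (records[i].chrom, records[i].pos1,
                                            records[i].pos2))
    active: list[int] = []
    for i in order:
        r = records[i]
        still = []
        for j in active:
            q = records[j]
            if q.chrom != r.chrom or q.pos2 < r.pos1:
                continue
            still.append(j)
            if reciprocal_overlap(q.interval, r.interval) > overlap_frac:
                uf.union(i, j)
        active = still + [i]
    return [uf.find(i) for i in range(n)]


def _linkage_labels(records: list[SVRecord], overlap_frac: float) -> list[int]:
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    if len(records) == 1:
        return [0]
    d = build_distance_matrix(records, overlap_frac)
    z = linkage(squareform(d, checks=False), method="single")
    return list(fcluster(z, t=0.5, criterion="distance"))


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def merge_cluster(cluster: SVCluster, min_methods: int = 2) -> MergedSV | None:
    """Merge a cluster into one SV, or return None when under-supported.

    All member coordinates enter the means; a caller contributing several
    members is listed once in the methods string, represented by its
    best-supported member's info (ties: smaller pos1, then pos2).
    """
    best: dict[str, SVRecord] = {}
    order: list[str] = []
    for m in cluster.members:
        cur = best.get(m.method)
        if cur is None:
            best[m.method] = m
            order.append(m.method)
        else:
            key_new = (-primary_support(m), m.pos1, m.pos2)
            key_cur = (-primary_support(cur), cur.pos1, cur.pos2)
            if key_new < key_cur:
                best[m.method] = m
    if len(order) < min_methods:
        return None
    pos1 = _round_half_up(sum(m.pos1 for m in cluster.members) / len(cluster.members))
    pos2 = _round_half_up(sum(m.pos2 for m in cluster.members) / len(cluster.members))
    return MergedSV(
        chrom=cluster.chrom,
        pos1=pos1,
        pos2=pos2,
        methods=":".join(order),
        info=":".join(best[m].info for m in order),
        sv_type=cluster.sv_type,
    )


def methods_merge(
    callsets: list[CallSet],
    params: MergeParams | None = None,
) -> dict[str, list[MergedSV]]:
    """Combine, cluster and merge the callsets of >= 2 callers.

    Returns a mapping sv_type -> merged SVs sorted by (chrom, pos1).
    Cluster membership order — hence methods-string order — follows the
    caller input order.
    """
    params = params or MergeParams()
    if len(callsets) < 2:
        raise ConfigurationError("methods_merge needs at least two callsets")
    out: dict[str, list[MergedSV]] = {}
    for sv_type in SV_TYPES:
        combined: list[SVRecord] = []
        for cs in callsets:
            combined.extend(cs.records.get(sv_type, []))
        merged: list[MergedSV] = []
        for cluster in cluster_svs(combined, params.overlap_frac):
            m = merge_cluster(cluster, params.min_methods)
            if m is not None:
                merged.append(m)
        merged.sort(key=lambda m: (m.chrom, m.pos1, m.pos2))
        out[sv_type] = merged
    return out


# ---------------------------------------------------------------------------
# output formats

_TSV_HEADER = ["chromosome", "pos1", "pos2", "methods", "info", "type"]

_VCF_ALT = {"del": "<DEL>", "dup": "<DUP>", "inv": "<INV>"}


def _all_merged(merged: dict[str, list[MergedSV]]) -> list[MergedSV]:
    rows = [m for t in SV_TYPES for m in merged.get(t, [])]
    rows.sort(key=lambda m: (m.chrom, m.pos1, m.pos2, m.sv_type))
    return rows


def write_merged(merged: dict[str, list[MergedSV]], path: str | Path,
                 format: str = "tsv") -> Path:
    """Write the integrated SV list as a single TSV, VCF or BED file."""
    path = Path(path)
    if format == "tsv":
        _write_tsv(merged, path)
    elif format == "vcf":
        _write_vcf(merged, path)
    elif format == "bed":
        _write_bed(merged, path)
    else:
        raise ConfigurationError(f"unknown output format {format!r}")
    return path


def _write_tsv(merged, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_HEADER) + "\n")
        for m in _all_merged(merged):
            fh.write(f"{m.chrom}\t{m.pos1}\t{m.pos2}\t{m.methods}\t"
                     f"{m.info}\t{m.sv_type}\n")


def _vcf_escape(s: str) -> str:
    return s.replace("%", "%25").replace(";", "%3B").replace("=", "%3D") \
            .replace(",", "%2C").replace(":", "%3A")


def _write_vcf(merged, path: Path) -> None:
    rows = _all_merged(merged)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,'
                 'Description="Type of structural variant">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,'
                 'Description="End position of the variant">\n')
        fh.write('##INFO=<ID=METHODS,Number=1,Type=String,'
                 'Description="Colon-joined contributing callers">\n')
        fh.write('##INFO=<ID=SUPP,Number=1,Type=String,'
                 'Description="Percent-encoded per-caller support strings">\n')
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##ALT=<ID=DUP,Description="Duplication">\n')
        fh.write('##ALT=<ID=INV,Description="Inversion">\n')
        for chrom in sorted({m.chrom for m in rows}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, m in enumerate(rows, 1):
            info = (f"SVTYPE={m.sv_type.upper()};END={m.pos2};"
                    f"METHODS={_vcf_escape(m.methods)};SUPP={_vcf_escape(m.info)}")
            fh.write(f"{m.chrom}\t{m.pos1}\tsv{i}\tN\t{_VCF_ALT[m.sv_type]}\t"
                     f".\tPASS\t{info}\n")


def _write_bed(merged, path: Path) -> None:
    with open(path, "w") as fh:
        for m in _all_merged(merged):
            fh.write(f"{m.chrom}\t{m.pos1 - 1}\t{m.pos2}\t"
                     f"{m.sv_type}:{m.methods}\n")


def read_merged_tsv(path: str | Path) -> dict[str, list[MergedSV]]:
    """Inverse of the TSV writer (round-trip identity)."""
    out: dict[str, list[MergedSV]] = {t: [] for t in SV_TYPES}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TSV_HEADER:
            raise ConfigurationError(f"{path}: unexpected merged-TSV header")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            chrom, pos1, pos2, methods, info, sv_type = line.split("\t")
            out[sv_type].append(
                MergedSV(chrom, int(pos1), int(pos2), methods, info, sv_type)
            )
    return out
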