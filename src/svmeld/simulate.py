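"""Synthetic ground truth and native-dialect caller outputs.

The simulator plants non-overlapping truth SVs on a toy genome, then writes
one file set per requested caller in that caller's native format: each
truth SV appears (with bounded boundary jitter and supra-threshold support)
in the outputs of its reporting callers, alongside caller-unique false
positives and optional sub-threshold records that each violate exactly one
quality gate.  A TSV manifest records every emitted record, making the
whole simulate → read → merge chain verifiable against planted truth.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    ConfigurationError,
    DataError,
    MergeParams,
    reciprocal_overlap,
    span,
)
from .merge import MergedSV

__all__ = [
    "GenomeSpec",
    "TruthSV",
    "Manifest",
    "EvalResult",
    "CALLER_TYPES",
    "simulate_truth",
    "emit_caller_outputs",
    "evaluate_against_truth",
    "read_manifest",
    "write_chrom_sizes",
]

#: SV types each supported caller can report
CALLER_TYPES = {
    "breakdancer": ("del", "inv"),
    "pindel": ("del", "dup", "inv"),
    "cnvnator": ("del", "dup"),
    "delly": ("del", "dup", "inv"),
    "svseq": ("del",),
    "lumpy": ("del", "dup", "inv"),
    "softsearch": ("del", "dup", "inv"),
}

_MANIFEST_COLS = ["kind", "id", "caller", "sv_type", "chrom", "pos1", "pos2",
                  "support", "score", "reason"]


@dataclass(slots=True)
class GenomeSpec:
    """Toy genome: chromosome names/lengths plus the master seed."""

    chrom_sizes: dict[str, int]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chrom_sizes:
            raise ConfigurationError("genome needs at least one chromosome")
        if any(v <= 0 for v in self.chrom_sizes.values()):
            raise ConfigurationError("chromosome lengths must be positive")


@dataclass(slots=True)
class TruthSV:
    id: str
    chrom: str
    pos1: int
    pos2: int
    sv_type: str
    reporting_callers: list[str] = field(default_factory=list)
    jitter_bp: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.pos1, self.pos2)


@dataclass(slots=True)
class ManifestRow:
    kind: str  # truth | call | fp | sub
    id: str
    caller: str
    sv_type: str
    chrom: str
    pos1: int
    pos2: int
    support: int | None
    score: float | None
    reason: str


@dataclass(slots=True)
class Manifest:
    truth: list[TruthSV]
    rows: list[ManifestRow]
    path: Path | None = None

    def rows_of(self, kind: str, caller: str | None = None) -> list[ManifestRow]:
        return [r for r in self.rows
                if r.kind == kind and (caller is None or r.caller == caller)]


# ---------------------------------------------------------------------------
# truth simulation

class _Placer:
    """Rejection-samples intervals that share no base with prior placements."""

    def __init__(self, spec: GenomeSpec, rng: np.random.Generator, pad: int = 1):
        self.spec = spec
        self.rng = rng
        self.pad = pad
        self.occupied: dict[str, list[tuple[int, int]]] = {
            c: [] for c in spec.chrom_sizes
        }
        names = sorted(spec.chrom_sizes)
        sizes = np.array([spec.chrom_sizes[c] for c in names], dtype=float)
        self._names = names
        self._probs = sizes / sizes.sum()

    def place(self, size: int, tries: int = 500) -> tuple[str, int, int]:
        for _ in range(tries):
            chrom = str(self.rng.choice(self._names, p=self._probs))
            length = self.spec.chrom_sizes[chrom]
            if length < size:
                continue
            pos1 = int(self.rng.integers(1, length - size + 2))
            pos2 = pos1 + size - 1
            lo, hi = pos1 - self.pad, pos2 + self.pad
            if all(e < lo or s > hi for s, e in self.occupied[chrom]):
                self.occupied[chrom].append((pos1, pos2))
                return chrom, pos1, pos2
        raise DataError(
            f"could not place a {size} bp interval after {tries} tries; "
            "genome too dense"
        )


def simulate_truth(
    spec: GenomeSpec,
    n_per_type: dict[str, int],
    size_range: tuple[int, int] = (150, 20_000),
    seed: int | None = None,
    params: MergeParams | None = None,
) -> list[TruthSV]:
    """Plant non-overlapping truth SVs, sizes log-uniform in ``size_range``.

    Deterministic under a fixed seed (defaults to the genome spec's seed).
    """
    params = params or MergeParams()
    lo, hi = size_range
    if not params.min_size <= lo <= hi <= params.max_size:
        raise ConfigurationError(
            f"size_range {size_range} outside filter window "
            f"[{params.min_size}, {params.max_size}]"
        )
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    # pad placements by the worst-case jitter so jittered copies of distinct
    # truth SVs can never reciprocally overlap above threshold
    placer = _Placer(spec, rng, pad=max(1, int(0.1 * hi)))
    truth: list[TruthSV] = []
    i = 0
    for sv_type in ("del", "dup", "inv"):
        for _ in range(int(n_per_type.get(sv_type, 0))):
            size = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
            size = min(max(size, lo), hi)
            chrom, pos1, pos2 = placer.place(size)
            i += 1
            truth.append(TruthSV(f"truth{i:04d}", chrom, pos1, pos2, sv_type))
    truth.sort(key=lambda t: (t.chrom, t.pos1, t.pos2))
    return truth


# ---------------------------------------------------------------------------
# caller-output emission

def emit_caller_outputs(
    truth: list[TruthSV],
    callers: list[str],
    out_dir: str | Path,
    spec: GenomeSpec,
    jitter_frac: float = 0.05,
    fp_per_caller: int = 20,
    sub_threshold_frac: float = 0.0,
    seed: int | None = None,
    overlap_frac: float = 0.8,
    min_reporting: int = 2,
) -> Manifest:
    """Write per-caller native output files plus a manifest TSV.

    Every truth SV is assigned >= ``min_reporting`` reporting callers drawn
    from those able to call its type; each reporting caller's record jitters
    both boundaries by at most ``jitter_frac`` of the SV length, which (for
    ``jitter_frac < (1 - overlap_frac) / 2``) guarantees the jittered calls
    still exceed the reciprocal-overlap threshold against the truth and
    against each other.  False positives are caller-unique and placed clear
    of everything else; sub-threshold records each violate exactly one gate.
    """
    for c in callers:
        if c not in CALLER_TYPES:
            raise ConfigurationError(f"unknown caller {c!r}")
    if not 0 <= jitter_frac < (1 - overlap_frac) / 2:
        raise ConfigurationError(
            f"jitter_frac {jitter_frac} must be < (1 - overlap_frac)/2 "
            f"= {(1 - overlap_frac) / 2:.3f} to keep jittered calls clustered"
        )
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows: list[ManifestRow] = []
    per_caller: dict[str, list[ManifestRow]] = {c: [] for c in callers}

    # --- truth calls with jitter
    for t in truth:
        capable = [c for c in callers if t.sv_type in CALLER_TYPES[c]]
        if len(capable) < min_reporting:
            raise ConfigurationError(
                f"only {len(capable)} caller(s) can report type {t.sv_type}; "
                f"need >= {min_reporting}"
            )
        k = int(rng.integers(min_reporting, len(capable) + 1))
        reporting = sorted(rng.choice(capable, size=k, replace=False).tolist(),
                           key=callers.index)
        t.reporting_callers = reporting
        j = int(jitter_frac * span(t.interval))
        for c in reporting:
            d1 = int(rng.integers(-j, j + 1)) if j else 0
            d2 = int(rng.integers(-j, j + 1)) if j else 0
            t.jitter_bp[c] = (d1, d2)
            p1, p2 = t.pos1 + d1, t.pos2 + d2
            support, score = _supra_support(c, rng)
            row = ManifestRow("call", t.id, c, t.sv_type, t.chrom, p1, p2,
                              support, score, "")
            rows.append(row)
            per_caller[c].append(row)
        rows.append(ManifestRow("truth", t.id, ":".join(reporting), t.sv_type,
                                t.chrom, t.pos1, t.pos2, None, None, ""))

    # --- caller-unique false positives (pass all gates, single-method)
    placer = _Placer(spec, rng, pad=max(1, int(0.3 * 20_000)))
    for t in truth:
        placer.occupied[t.chrom].append((t.pos1, t.pos2))
    fp_i = 0
    for c in callers:
        for _ in range(fp_per_caller):
            sv_type = str(rng.choice(CALLER_TYPES[c]))
            size = int(rng.integers(200, 8000))
            chrom, p1, p2 = placer.place(size)
            support, score = _supra_support(c, rng)
            fp_i += 1
            row = ManifestRow("fp", f"fp{fp_i:04d}", c, sv_type, chrom,
                              p1, p2, support, score, "")
            rows.append(row)
            per_caller[c].append(row)

    # --- sub-threshold records, each violating exactly one gate
    sub_i = 0
    for c in callers:
        n_sub = int(round(sub_threshold_frac * len(per_caller[c])))
        for _ in range(n_sub):
            sub_i += 1
            row = _sub_threshold_row(c, f"sub{sub_i:04d}", placer, rng, spec)
            if row is not None:
                rows.append(row)
                per_caller[c].append(row)

    for c in callers:
        per_caller[c].sort(key=lambda r: (r.chrom, r.pos1, r.pos2))
        _EMITTERS[c](per_caller[c], out_dir, spec, rng)

    write_chrom_sizes(spec, out_dir / "chrom_sizes.tsv")
    manifest = Manifest(truth=truth, rows=rows, path=out_dir / "manifest.tsv")
    _write_manifest(manifest)
    return manifest


def _supra_support(caller: str, rng) -> tuple[int, float | None]:
    s = int(rng.integers(3, 31))
    if caller == "breakdancer":
        return s, float(rng.integers(60, 100))
    if caller == "pindel":
        return s, float(rng.integers(3, 41))
    return s, None


def _sub_threshold_row(caller, rid, placer, rng, spec) -> ManifestRow | None:
    gates = ["min_size"]
    if caller == "breakdancer":
        gates += ["score", "support"]
    elif caller != "cnvnator":
        gates += ["support"]
    if caller == "softsearch":
        gates += ["support2"]
    if max(spec.chrom_sizes.values()) > 10_000_000 + 10:
        gates += ["max_size"]
    gate = str(rng.choice(gates))

    support, score = _supra_support(caller, rng)
    if gate == "min_size":
        size = int(rng.integers(40, 100))
        chrom, p1, p2 = placer.place(size)
    elif gate == "max_size":
        chrom = max(spec.chrom_sizes, key=spec.chrom_sizes.get)
        p1, p2 = 1, 10_000_002
    else:
        size = int(rng.integers(200, 8000))
        chrom, p1, p2 = placer.place(size)
        if gate == "score":
            score = float(rng.integers(10, 60))
        elif gate == "support":
            support = int(rng.integers(0, 3))
        # gate == "support2": primary support stays fine; the SoftSearch
        # emitter writes a sub-threshold lDisc instead
    sv_type = str(rng.choice(CALLER_TYPES[caller]))
    return ManifestRow("sub", rid, caller, sv_type, chrom, p1, p2,
                       support, score, gate)


# ---------------------------------------------------------------------------
# per-caller dialect emitters

_BD_TYPE = {"del": "DEL", "inv": "INV", "dup": "ITX"}  # dup never emitted


def _emit_breakdancer(calls, out_dir: Path, spec, rng) -> None:
    path = out_dir / "breakdancer.txt"
    with open(path, "w") as fh:
        fh.write("#Software: breakdancer (simulated)\n")
        fh.write("#Chr1\tPos1\tOrientation1\tChr2\tPos2\tOrientation2\t"
                 "Type\tSize\tScore\tnum_Reads\tnum_Reads_lib\n")
        for r in calls:
            size = r.pos2 - r.pos1 + 1
            if r.sv_type == "inv" and rng.random() < 0.5:
                size = -size  # BreakDancer signs some inversions
            fh.write(f"{r.chrom}\t{r.pos1}\t{r.support}+{r.support}-\t"
                     f"{r.chrom}\t{r.pos2}\t{r.support}+{r.support}-\t"
                     f"{_BD_TYPE[r.sv_type]}\t{size}\t{r.score:g}\t"
                     f"{r.support}\tsim|{r.support}\n")


_PINDEL_TYPE = {"del": "D", "dup": "TD", "inv": "INV"}


def _emit_pindel(calls, out_dir: Path, spec, rng) -> None:
    pdir = out_dir / "pindel"
    pdir.mkdir(exist_ok=True)
    by_type = {"del": [], "dup": [], "inv": []}
    for r in calls:
        by_type[r.sv_type].append(r)
    for sv_type, suffix in (("del", "_D"), ("dup", "_TD"), ("inv", "_INV")):
        with open(pdir / f"sim{suffix}", "w") as fh:
            for i, r in enumerate(by_type[sv_type]):
                label = _PINDEL_TYPE[sv_type]
                size = r.pos2 - r.pos1 + 1
                bp1, bp2 = r.pos1 - 1, r.pos2 + 1
                fh.write("#" * 60 + "\n")
                fh.write(
                    f"{i}\t{label} {size}\tNT 0 \"\"\tChrID {r.chrom}\t"
                    f"BP {bp1}\t{bp2}\tBP_range {bp1}\t{bp2}\t"
                    f"Supports {r.support}\t{r.support}\t"
                    f"+ {r.support // 2}\t{r.support // 2}\t"
                    f"- {r.support - r.support // 2}\t"
                    f"{r.support - r.support // 2}\t"
                    f"S1 {int(r.score)}\tSUM_MS {r.support * 30}\n"
                )
                fh.write(f"  simulated supporting read block ({r.id})\n")


def _emit_cnvnator(calls, out_dir: Path, spec, rng) -> None:
    cdir = out_dir / "cnvnator"
    cdir.mkdir(exist_ok=True)
    by_chrom: dict[str, list] = {c: [] for c in spec.chrom_sizes}
    for r in calls:
        by_chrom[r.chrom].append(r)
    label = {"del": "deletion", "dup": "duplication"}
    for chrom in sorted(spec.chrom_sizes):
        with open(cdir / f"{chrom}.calls", "w") as fh:
            for r in by_chrom[chrom]:
                size = r.pos2 - r.pos1 + 1
                rd = 0.4 if r.sv_type == "del" else 1.8
                evals = [f"{rng.uniform(1e-8, 1e-3):.6g}" for _ in range(4)]
                fh.write(f"{label[r.sv_type]}\t{r.chrom}:{r.pos1}-{r.pos2}\t"
                         f"{size}\t{rd:.3f}\t" + "\t".join(evals) + "\t0\n")


def _vcf_header(spec, info_lines: list[str], sample: str | None = None) -> str:
    out = ["##fileformat=VCFv4.2"]
    out += info_lines
    out += ['##ALT=<ID=DEL,Description="Deletion">',
            '##ALT=<ID=DUP,Description="Duplication">',
            '##ALT=<ID=INV,Description="Inversion">']
    for chrom in sorted(spec.chrom_sizes):
        out.append(f"##contig=<ID={chrom},length={spec.chrom_sizes[chrom]}>")
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if sample:
        cols += f"\tFORMAT\t{sample}"
    out.append(cols)
    return "\n".join(out) + "\n"


_VCF_ALT = {"del": "<DEL>", "dup": "<DUP>", "inv": "<INV>"}


def _emit_delly(calls, out_dir: Path, spec, rng) -> None:
    header = _vcf_header(spec, [
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">',
        '##INFO=<ID=PE,Number=1,Type=Integer,Description="Paired-end support">',
        '##INFO=<ID=SR,Number=1,Type=Integer,Description="Split-read support">',
    ])
    with open(out_dir / "delly.vcf", "w") as fh:
        fh.write(header)
        for i, r in enumerate(calls, 1):
            # split total support between PE and SR evidence
            sr = int(rng.integers(0, r.support + 1))
            pe = r.support - sr
            fh.write(f"{r.chrom}\t{r.pos1}\tDEL{i:05d}\tN\t"
                     f"{_VCF_ALT[r.sv_type]}\t.\tPASS\t"
                     f"SVTYPE={r.sv_type.upper()};END={r.pos2};"
                     f"PE={pe};SR={sr}\n")


def _emit_svseq(calls, out_dir: Path, spec, rng) -> None:
    with open(out_dir / "svseq.del", "w") as fh:
        fh.write("#chrom\tstart\tend\tsplit_reads\n")
        for r in calls:
            fh.write(f"{r.chrom}\t{r.pos1}\t{r.pos2}\t{r.support}\n")


def _emit_lumpy(calls, out_dir: Path, spec, rng) -> None:
    header = _vcf_header(spec, [
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">',
        '##INFO=<ID=SU,Number=1,Type=Integer,Description="Supporting evidence">',
    ])
    with open(out_dir / "lumpy.vcf", "w") as fh:
        fh.write(header)
        for i, r in enumerate(calls, 1):
            fh.write(f"{r.chrom}\t{r.pos1}\t{i}\tN\t{_VCF_ALT[r.sv_type]}\t"
                     f".\t.\tSVTYPE={r.sv_type.upper()};END={r.pos2};"
                     f"SU={r.support}\n")


def _emit_softsearch(calls, out_dir: Path, spec, rng) -> None:
    header = _vcf_header(spec, [
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">',
        '##INFO=<ID=nSC,Number=1,Type=Integer,Description="Soft-clipped reads">',
        '##INFO=<ID=lDisc,Number=1,Type=Integer,Description="Discordant pairs">',
    ])
    with open(out_dir / "softsearch.vcf", "w") as fh:
        fh.write(header)
        for i, r in enumerate(calls, 1):
            nsc = r.support
            if r.reason == "support2":
                ldisc = int(rng.integers(0, 3))  # pairs gate fails alone
            elif r.reason == "support":
                ldisc = 5  # split-read gate fails alone
            else:
                ldisc = r.support
            fh.write(f"{r.chrom}\t{r.pos1}\t{i}\tN\t{_VCF_ALT[r.sv_type]}\t"
                     f".\tPASS\tSVTYPE={r.sv_type.upper()};END={r.pos2};"
                     f"nSC={nsc};lDisc={ldisc}\n")


_EMITTERS = {
    "breakdancer": _emit_breakdancer,
    "pindel": _emit_pindel,
    "cnvnator": _emit_cnvnator,
    "delly": _emit_delly,
    "svseq": _emit_svseq,
    "lumpy": _emit_lumpy,
    "softsearch": _emit_softsearch,
}


# ---------------------------------------------------------------------------
# manifest I/O

def _write_manifest(manifest: Manifest) -> None:
    with open(manifest.path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_MANIFEST_COLS)
        for r in manifest.rows:
            w.writerow([r.kind, r.id, r.caller, r.sv_type, r.chrom, r.pos1,
                        r.pos2,
                        "" if r.support is None else r.support,
                        "" if r.score is None else f"{r.score:g}",
                        r.reason])


def read_manifest(path: str | Path) -> Manifest:
    rows: list[ManifestRow] = []
    truth: list[TruthSV] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header != _MANIFEST_COLS:
            raise DataError(f"{path}: unexpected manifest header")
        for cols in reader:
            kind, rid, caller, sv_type, chrom, p1, p2, supp, score, reason = cols
            row = ManifestRow(kind, rid, caller, sv_type, chrom, int(p1),
                              int(p2), int(supp) if supp else None,
                              float(score) if score else None, reason)
            rows.append(row)
            if kind == "truth":
                truth.append(TruthSV(rid, chrom, int(p1), int(p2), sv_type,
                                     caller.split(":") if caller else []))
    return Manifest(truth=truth, rows=rows, path=Path(path))


def write_chrom_sizes(spec: GenomeSpec, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for chrom in sorted(spec.chrom_sizes):
            fh.write(f"{chrom}\t{spec.chrom_sizes[chrom]}\n")
    return path


# ---------------------------------------------------------------------------
# evaluation

@dataclass(slots=True)
class EvalResult:
    precision: float
    recall: float
    mean_boundary_error: float
    n_merged: int
    n_truth: int
    n_matched: int
    matches: list[tuple[str, str, float]]  # (truth id, merged key, RO)


def evaluate_against_truth(
    merged: dict[str, list[MergedSV]],
    manifest: Manifest | str | Path,
    overlap_frac: float = 0.8,
) -> EvalResult:
    """Greedy 1-to-1 matching of merged SVs to truth by descending RO.

    A merged SV matches a truth SV iff same type, same chromosome and
    RO > ``overlap_frac``.  Precision is over merged SVs, recall over truth
    SVs; the boundary error averages |pos1 offset| and |pos2 offset| across
    matched pairs.
    """
    if not isinstance(manifest, Manifest):
        manifest = read_manifest(manifest)
    truth = manifest.truth
    merged_all = [(t, i, m) for t in merged for i, m in enumerate(merged[t])]

    candidates = []
    for tr in truth:
        for sv_type, i, m in merged_all:
            if sv_type != tr.sv_type or m.chrom != tr.chrom:
                continue
            ro = reciprocal_overlap(m.interval, tr.interval)
            if ro > overlap_frac:
                candidates.append((ro, tr.id, (sv_type, i)))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))

    matched_truth: set[str] = set()
    matched_merged: set[tuple[str, int]] = set()
    matches: list[tuple[str, str, float]] = []
    errors: list[float] = []
    truth_by_id = {t.id: t for t in truth}
    for ro, tid, mkey in candidates:
        if tid in matched_truth or mkey in matched_merged:
            continue
        matched_truth.add(tid)
        matched_merged.add(mkey)
        matches.append((tid, f"{mkey[0]}[{mkey[1]}]", ro))
        tr, m = truth_by_id[tid], merged[mkey[0]][mkey[1]]
        errors.append((abs(m.pos1 - tr.pos1) + abs(m.pos2 - tr.pos2)) / 2)

    n_merged = len(merged_all)
    n_truth = len(truth)
    return EvalResult(
        precision=len(matched_merged) / n_merged if n_merged else 1.0,
        recall=len(matched_truth) / n_truth if n_truth else 1.0,
        mean_boundary_error=float(np.mean(errors)) if errors else 0.0,
        n_merged=n_merged,
        n_truth=n_truth,
        n_matched=len(matches),
        matches=matches,
    )
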