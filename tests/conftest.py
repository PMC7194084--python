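"""Shared fixtures: a small simulated benchmark reused across test modules."""

from __future__ import annotations

import random

import pytest

from svmeld.core import MergeParams, SVRecord
from svmeld.readers import READERS
from svmeld.simulate import GenomeSpec, emit_caller_outputs, simulate_truth

ALL_CALLERS = ["breakdancer", "pindel", "cnvnator", "delly", "svseq",
               "lumpy", "softsearch"]

CALLER_INPUT = {
    "breakdancer": "breakdancer.txt",
    "pindel": "pindel",
    "cnvnator": "cnvnator",
    "delly": "delly.vcf",
    "svseq": "svseq.del",
    "lumpy": "lumpy.vcf",
    "softsearch": "softsearch.vcf",
}


def make_record(chrom="chr1", pos1=100, pos2=199, size=None, info="PE=5",
                sv_type="del", method="BreakDancer") -> SVRecord:
    return SVRecord(chrom, pos1, pos2, size, info, sv_type, method)


def random_records(rng: random.Random, n: int, sv_type: str = "del",
                   chroms=("chr1", "chr2"), max_pos=10_000) -> list[SVRecord]:
    recs = []
    for i in range(n):
        p1 = rng.randint(1, max_pos)
        length = rng.randint(50, 400)
        recs.append(SVRecord(rng.choice(list(chroms)), p1, p1 + length - 1,
                             None, f"PE={rng.randint(1, 30)}", sv_type,
                             f"caller{rng.randint(1, 4)}"))
    return recs


@pytest.fixture(scope="session")
def sim_genome() -> GenomeSpec:
    return GenomeSpec({"chrA": 15_000_000, "chrB": 12_000_000}, seed=7)


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory, sim_genome):
    """Simulated outputs for all seven callers, with sub-threshold records."""
    out = tmp_path_factory.mktemp("sim")
    truth = simulate_truth(sim_genome, {"del": 40, "dup": 15, "inv": 10})
    manifest = emit_caller_outputs(
        truth, ALL_CALLERS, out, sim_genome,
        jitter_frac=0.05, fp_per_caller=8, sub_threshold_frac=0.2,
    )
    return {"dir": out, "manifest": manifest, "truth": truth,
            "genome": sim_genome}


@pytest.fixture(scope="session")
def sim_callsets(sim_dir):
    params = MergeParams()
    out = {}
    for name in ALL_CALLERS:
        path = sim_dir["dir"] / CALLER_INPUT[name]
        cs, report = READERS[name][1](path, params)
        out[name] = (cs, report)
    return out


@pytest.fixture()
def params() -> MergeParams:
    return MergeParams()
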