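"""Shared fixtures: one moderately sized synthetic benchmark is run once per
session and reused by the mapping, discovery, expression and acceptance
tests."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from poncirna import discovery, mapping, reads, simulate

BENCH_SEED = 7
ADAPTER3 = "TCGTATGCCGTCTTCTGCTTG"
TOTAL_READS = 50_000
ERROR_RATE = 0.001


@dataclass
class BenchmarkRun:
    loci: list
    genome: object
    sim: object
    clean_by_lib: dict
    tags: list
    hits: list
    tally: object
    labels: dict
    candidates: list
    novel: list
    rejections: dict

    @property
    def true_matures(self) -> set[str]:
        return {
            self.genome.designs[l.locus_id].mature
            for l in self.loci
            if l.kind == "miRNA"
        }


@pytest.fixture(scope="session")
def benchmark() -> BenchmarkRun:
    """The default study-condition simulation (20 miRNA loci among decoys,
    0.1% substitution errors, 50k reads per library) run end to end."""
    loci, slen = simulate.default_benchmark_loci(seed=BENCH_SEED, n_mirna=20)
    genome = simulate.generate_genome(loci, slen, seed=BENCH_SEED)
    sim = simulate.simulate_libraries(
        genome, total_reads=TOTAL_READS, adapter3=ADAPTER3,
        error_rate=ERROR_RATE, seed=BENCH_SEED + 1,
    )
    clean_by_lib = {}
    for lib, rds in sim.reads.items():
        trimmed = []
        for r in rds:
            insert, ok = reads.trim_adapter(r, ADAPTER3)
            if ok:
                trimmed.append(insert)
        clean_by_lib[lib] = reads.filter_reads(trimmed)[0]
    tags = reads.collapse(clean_by_lib)
    hits = mapping.map_tags(tags, genome.scaffolds)
    features = [
        mapping.Feature(l.scaffold, l.start - 1, l.end, l.kind)
        for l in loci
        if l.kind in ("rRNA", "tRNA", "snRNA", "repeat")
    ]
    tally, labels = mapping.classify_tags(hits, features)
    candidates = mapping.candidate_hits(hits, labels)
    novel, rejections = discovery.discover_novel(candidates, genome.scaffolds)
    return BenchmarkRun(
        loci=loci, genome=genome, sim=sim, clean_by_lib=clean_by_lib,
        tags=tags, hits=hits, tally=tally, labels=labels,
        candidates=candidates, novel=novel, rejections=rejections,
    )


@pytest.fixture(scope="session")
def catalog():
    return simulate.load_novel_mirna_catalog()
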