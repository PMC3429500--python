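"""Pipeline orchestration: configuration, stage execution, reporting.

A run is driven by a single YAML config naming inputs, outputs, stage
toggles and every threshold. Stages execute in dependency order
(simulate -> clean -> map/classify -> discover -> express -> targets ->
rapcr -> report); each stage writes its outputs under the work directory
and the final report gathers every stage's headline numbers into one JSON
document, logging the thresholds used. Functional-annotation roll-ups
count genes per term from user-supplied gene->term mappings; no live
database is ever queried.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import discovery, expression, mapping, rapcr, reads, simulate
from .simulate import LIBRARIES

log = logging.getLogger("poncirna")


@dataclass
class RunConfig:
    """Validated run configuration; every threshold has a documented default."""

    workdir: str = "poncirna_run"
    seed: int = 0
    stages: list[str] = field(
        default_factory=lambda: ["simulate", "clean", "map", "discover", "express", "report"]
    )
    # inputs (optional where the simulate stage provides them)
    genome_fasta: str | None = None
    annotation: str | None = None
    fastq: dict[str, str] = field(default_factory=dict)  # library -> path
    mature_reference: str | None = None
    transcripts_fasta: str | None = None
    transcripts_gff3: str | None = None
    rapcr_tsv: str | None = None
    go_mapping: str | None = None
    # simulation scale
    total_reads: int = 50_000
    n_mirna_loci: int = 20
    error_rate: float = 0.001
    adapter3: str = "TCGTATGCCGTCTTCTGCTTG"
    adapter5: str | None = None
    # thresholds
    max_mismatch: int = 1
    min_len: int = 18
    max_len: int = 30
    min_quality: int = 10
    multiplicity_cap: int = mapping.MULTIPLICITY_CAP
    exclude_repeats: bool = True
    known_max_mismatch: int = 3
    mfe_max: float = discovery.MFE_MAX_DEFAULT
    flank: int = discovery.FLANK_DEFAULT
    fold_threshold: float = 2.0
    penalty_max: float = 2.0
    rapcr_threshold: float = rapcr.SUPPORT_THRESHOLD

    def validate(self) -> None:
        known = {
            "simulate", "clean", "map", "classify", "discover",
            "express", "targets", "rapcr", "report",
        }
        bad = set(self.stages) - known
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        if self.max_mismatch not in (0, 1):
            raise ValueError("max_mismatch must be 0 or 1")
        if not 0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate out of range [0, 0.05]")
        if self.mfe_max > 0:
            raise ValueError("mfe_max must be <= 0")
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")
        if not 0 < self.rapcr_threshold < 1:
            raise ValueError("rapcr_threshold must be in (0, 1)")
        if "simulate" not in self.stages:
            for lib, path in self.fastq.items():
                if not Path(path).exists():
                    raise ValueError(f"missing FASTQ for {lib}: {path}")
            if "clean" in self.stages and set(self.fastq) != set(LIBRARIES):
                raise ValueError("fastq must name all four libraries")
            if ("map" in self.stages or "discover" in self.stages) and (
                self.genome_fasta is None or not Path(self.genome_fasta).exists()
            ):
                raise ValueError("genome_fasta required for mapping/discovery")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg


def go_rollup(
    genes: list[str], mapping_path: str | Path | pd.DataFrame, namespace: str | None = None
) -> pd.DataFrame:
    """Count genes per functional term from a gene->term mapping.

    The mapping is tab-separated (gene, term, namespace). A gene with
    several terms counts once under each; genes absent from the mapping are
    tallied under the "unannotated" term. Counts are returned sorted
    descending within each namespace.
    """
    if isinstance(mapping_path, pd.DataFrame):
        m = mapping_path.copy()
        m.columns = ["gene", "term", "namespace"]
    else:
        m = pd.read_csv(
            mapping_path, sep="\t", names=["gene", "term", "namespace"], header=None
        )
    genes = list(dict.fromkeys(genes))
    m = m[m["gene"].isin(genes)]
    if namespace is not None:
        m = m[m["namespace"] == namespace]
    rows = []
    for (ns, term), grp in m.groupby(["namespace", "term"]):
        rows.append({"namespace": ns, "term": term, "genes": grp["gene"].nunique()})
    mapped = set(m["gene"])
    unmapped = [g for g in genes if g not in mapped]
    if unmapped:
        rows.append(
            {
                "namespace": namespace or "unannotated",
                "term": "unannotated",
                "genes": len(unmapped),
            }
        )
    out = pd.DataFrame(rows, columns=["namespace", "term", "genes"])
    return out.sort_values(
        ["namespace", "genes", "term"], ascending=[True, False, True]
    ).reset_index(drop=True)


def fixture_summary() -> dict:
    """Headline statistics of the packaged novel-miRNA catalog."""
    records = simulate.load_novel_mirna_catalog()
    summary = discovery.summarize_precursors(records)
    counts = discovery.catalog_counts(records)
    presence = expression.presence_pattern(counts)
    return {
        "records": summary["count"],
        "precursor_length": {
            "min": summary["length_min"],
            "max": summary["length_max"],
            "mean": round(summary["length_mean"]),
        },
        "mfe": {"min": summary["mfe_min"], "max": summary["mfe_max"]},
        "presence": {k: len(v) for k, v in presence.items()},
        "max_library_count": int(counts.values.max()),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return the run report (also written to
    ``<workdir>/report.json``)."""
    config.validate()
    work = Path(config.workdir)
    work.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: v for k, v in asdict(config).items()}}
    state: dict = {}

    if "simulate" in config.stages:
        loci, scaffold_lengths = simulate.default_benchmark_loci(
            seed=config.seed, n_mirna=config.n_mirna_loci
        )
        genome = simulate.generate_genome(loci, scaffold_lengths, seed=config.seed)
        sim = simulate.simulate_libraries(
            genome,
            total_reads=config.total_reads,
            adapter3=config.adapter3,
            error_rate=config.error_rate,
            seed=config.seed + 1,
        )
        genome.write_fasta(work / "genome.fa")
        genome.write_truth_gff3(work / "truth.gff3")
        genome.write_structural_annotation(work / "annotation.gff3")
        for lib in LIBRARIES:
            simulate.write_fastq(sim.reads[lib], work / f"{lib}.fastq")
        sim.truth.to_csv(work / "truth_reads.tsv", sep="\t", index=False)
        state["genome"] = genome.scaffolds
        state["truth"] = sim.truth
        config.fastq = {lib: str(work / f"{lib}.fastq") for lib in LIBRARIES}
        config.genome_fasta = str(work / "genome.fa")
        config.annotation = str(work / "annotation.gff3")
        log.info("simulate: %d loci, %d reads/library", len(loci), config.total_reads)
        report["simulate"] = {"loci": len(loci), "reads_per_library": config.total_reads}

    if "clean" in config.stages:
        if not config.fastq:
            raise RuntimeError("clean stage needs FASTQ inputs (run simulate or set fastq)")
        clean_by_lib: dict[str, list[str]] = {}
        stats_list = []
        for lib in LIBRARIES:
            clean, stats = reads.clean_library(
                config.fastq[lib],
                adapter3=config.adapter3,
                adapter5=config.adapter5,
                min_len=config.min_len,
                max_len=config.max_len,
                min_quality=config.min_quality,
                library=lib,
            )
            clean_by_lib[lib] = clean
            stats_list.append(stats)
        tags = reads.collapse(clean_by_lib)
        for s in stats_list:
            reads.finalize_stats(s, tags)
        reads.write_tags_tsv(tags, work / "tags.tsv")
        reads.write_tags_fasta(tags, work / "tags.fa")
        reads.write_stats_json(stats_list, work / "library_stats.json")
        state["tags"] = tags
        state["stats"] = stats_list
        log.info("clean: %d unique tags", len(tags))
        report["clean"] = {
            s.library: {"raw": s.raw, "clean": s.clean, "unique": s.unique}
            for s in stats_list
        }

    if "map" in config.stages or "classify" in config.stages:
        if "tags" not in state:
            if not (work / "tags.tsv").exists():
                raise RuntimeError("map stage needs collapsed tags (run clean first)")
            state["tags"] = reads.read_tags_tsv(work / "tags.tsv")
        if "genome" not in state:
            from Bio import SeqIO

            state["genome"] = {
                r.id: str(r.seq).upper()
                for r in SeqIO.parse(config.genome_fasta, "fasta")
            }
        hits = mapping.map_tags(
            state["tags"],
            state["genome"],
            max_mismatch=config.max_mismatch,
            multiplicity_cap=config.multiplicity_cap,
        )
        features = (
            mapping.load_annotation(config.annotation) if config.annotation else []
        )
        tally, labels = mapping.classify_tags(hits, features)
        mapping.write_alignments_tsv(hits, work / "alignments.tsv")
        tally.to_csv(work / "category_tally.tsv", sep="\t")
        state["hits"] = hits
        state["labels"] = labels
        log.info("map: %d tags, %d mapped", len(hits), sum(h.mapped for h in hits))
        report["map"] = {
            "tags": len(hits),
            "mapped": int(sum(h.mapped for h in hits)),
            "tally_reads": {
                cat: {lib: int(tally.loc[cat, lib]) for lib in LIBRARIES}
                for cat in tally.index
            },
        }

    if "discover" in config.stages:
        if "hits" not in state:
            raise RuntimeError("discover stage needs mapped tags (run map first)")
        candidates = mapping.candidate_hits(
            state["hits"], state["labels"], exclude_repeats=config.exclude_repeats
        )
        novel, rejections = discovery.discover_novel(
            candidates,
            state["genome"],
            flank=config.flank,
            mfe_max=config.mfe_max,
        )
        conserved = []
        if config.mature_reference:
            refs = discovery.load_mature_reference(config.mature_reference)
            conserved = discovery.call_conserved(
                candidates,
                refs,
                state["genome"],
                max_mismatch=config.known_max_mismatch,
                mfe_max=config.mfe_max,
            )
        catalog = discovery.compose_catalog(conserved, novel)
        discovery.write_catalog_tsv(catalog, work / "catalog.tsv")
        discovery.write_precursor_gff3(novel, work / "precursors.gff3")
        discovery.write_structures(novel, work / "structures.txt")
        state["catalog"] = catalog
        state["novel"] = novel
        log.info(
            "discover: %d novel, %d conserved (mfe_max=%.1f)",
            len(novel), len(conserved), config.mfe_max,
        )
        report["discover"] = {
            "novel": len(novel),
            "conserved": len(conserved),
            "rejections": rejections,
        }
        if novel:
            report["discover"]["precursor_summary"] = discovery.summarize_precursors(novel)

    if "express" in config.stages:
        if "catalog" not in state:
            raise RuntimeError("express stage needs a catalog (run discover first)")
        counts = pd.DataFrame(
            {lib: {r.mirna_id: r.counts.get(lib, 0) for r in state["catalog"]}
             for lib in LIBRARIES}
        ).fillna(0)
        lib_sizes = pd.Series(
            {
                lib: (
                    state["stats"][i].clean
                    if "stats" in state
                    else max(1, int(counts[lib].sum()))
                )
                for i, lib in enumerate(LIBRARIES)
            }
        )
        matrix = expression.ExpressionMatrix(counts, lib_sizes)
        calls_mt = expression.genotype_calls(matrix, "MT", fold=config.fold_threshold)
        calls_wt = expression.genotype_calls(matrix, "WT", fold=config.fold_threshold)
        frame = pd.concat(
            [expression.calls_to_frame(calls_mt), expression.calls_to_frame(calls_wt)]
        )
        frame.to_csv(work / "regulation_calls.tsv", sep="\t", index=False)
        expression.clustering_export(matrix).to_csv(work / "log2_rpm.tsv", sep="\t")
        presence = expression.presence_pattern(counts)
        report["express"] = {
            "MT": expression.regulation_census(calls_mt),
            "WT": expression.regulation_census(calls_wt),
            "presence": {k: len(v) for k, v in presence.items()},
            "inverse": len(expression.inverse_pattern(calls_mt, calls_wt)),
        }
        log.info("express: %d rows profiled", len(counts))

    if "targets" in config.stages:
        if not (config.transcripts_fasta and state.get("catalog")):
            raise RuntimeError("targets stage needs transcripts and a catalog")
        from . import targets as targets_mod

        transcripts = targets_mod.load_transcripts(
            config.transcripts_fasta, config.transcripts_gff3
        )
        mirnas = {r.mirna_id: r.mature for r in state["catalog"]}
        sites = targets_mod.scan_transcriptome(
            mirnas, transcripts, penalty_max=config.penalty_max
        )
        targets_mod.sites_to_frame(sites).to_csv(
            work / "target_sites.tsv", sep="\t", index=False
        )
        agg = targets_mod.aggregate_targets(sites)
        report["targets"] = {
            "total_sites": agg["total_sites"],
            "total_genes": agg["total_genes"],
            "multi_site_genes": agg["multi_site_genes"],
            "multi_mirna_genes": agg["multi_mirna_genes"],
        }
        if config.go_mapping:
            genes = sorted({s.transcript_id for s in sites})
            rollup = go_rollup(genes, config.go_mapping)
            rollup.to_csv(work / "go_rollup.tsv", sep="\t", index=False)
            report["targets"]["go_terms"] = int(len(rollup))
        log.info("targets: %d sites", agg["total_sites"])

    if "rapcr" in config.stages:
        if not config.rapcr_tsv:
            raise RuntimeError("rapcr stage needs a region-quantity TSV")
        quants = rapcr.read_quants_tsv(config.rapcr_tsv)
        calls = rapcr.cleavage_call(quants, threshold=config.rapcr_threshold)
        rapcr.write_calls_tsv(calls, work / "rapcr_calls.tsv")
        report["rapcr"] = {
            c.transcript_id: {
                "supported": c.supported,
                "range": [c.ratio_min, c.ratio_max],
            }
            for c in calls
        }
        log.info("rapcr: %d transcripts", len(calls))

    if "report" in config.stages:
        report["fixture_summary"] = fixture_summary()

    (work / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
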