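"""Synthetic-data generator: hairpin construction, genome embedding, read
simulation, and the packaged novel-miRNA catalog."""

import math

import numpy as np
import pytest

import helpers
from poncirna import simulate
from poncirna.simulate import (
    EmbeddedLocusSpec,
    FixtureParseError,
    build_hairpin_precursor,
    generate_genome,
    load_novel_mirna_catalog,
    simulate_libraries,
    write_novel_mirna_catalog,
)

MATURE = "TAGCCAAGGATGACTTGCCTGA"  # 22 nt


class TestHairpinDesign:
    def test_length_and_arm_complementarity(self):
        d = build_hairpin_precursor(MATURE, loop_len=15, seed=0)
        assert len(d.precursor) == 2 * 22 + 15
        assert d.precursor[:22] == MATURE
        # the 3' arm is the reverse complement of the mature shifted by the
        # 2-nt overhang rule: star[0:m-2] == revcomp(mature[0:m-2])
        assert d.star[:20] == helpers.revcomp(MATURE[:20])
        assert d.precursor[d.star_start : d.star_end] == d.star

    def test_duplex_has_two_nt_overhangs_by_construction(self):
        d = build_hairpin_precursor(MATURE, loop_len=20, seed=1)
        m = len(MATURE)
        # mature[i] pairs star[m-3-i]: both 3' ends protrude by 2
        for i in range(m - 2):
            assert helpers.can_pair(d.mature[i], d.star[m - 3 - i])

    def test_loop_too_short_rejected(self):
        with pytest.raises(ValueError):
            build_hairpin_precursor(MATURE, loop_len=2)

    def test_too_many_mismatches_rejected(self):
        with pytest.raises(ValueError):
            build_hairpin_precursor(MATURE, loop_len=15, n_mismatches=5)

    def test_designed_lengths_span_published_range(self):
        rng = np.random.default_rng(5)
        for _ in range(75):
            length = int(rng.integers(74, 344))
            loop = length - 2 * 21
            d = build_hairpin_precursor(
                "".join(rng.choice(list("ACGT"), size=21)), loop_len=loop, seed=2
            )
            assert 74 <= len(d.precursor) <= 343

    def test_mismatched_star_positions_do_not_complement(self):
        d = build_hairpin_precursor(MATURE, loop_len=15, n_mismatches=3, seed=4)
        m = len(MATURE)
        diffs = [
            j
            for j in range(m - 2)
            if d.star[j] != helpers.revcomp(MATURE[m - 3 - j])
        ]
        assert len(diffs) == 3


def _one_locus(mature=MATURE, start=101, star_fraction=0.0, kind="miRNA", **kw):
    return EmbeddedLocusSpec(
        locus_id="L1",
        kind=kind,
        scaffold="s1",
        start=start,
        end=start + 2 * len(mature) + 15 - 1 if kind == "miRNA" else kw.pop("end"),
        mature_seq=mature if kind == "miRNA" else None,
        loop_len=15,
        star_fraction=star_fraction,
        **kw,
    )


class TestGenomeGeneration:
    def test_embedded_precursor_retrievable_at_coordinates(self):
        locus = _one_locus()
        g = generate_genome([locus], {"s1": 1000}, seed=9)
        assert g.locus_sequence(locus) == g.designs["L1"].precursor

    def test_minus_strand_locus_is_reverse_complemented(self):
        locus = _one_locus(strand="-")
        g = generate_genome([locus], {"s1": 1000}, seed=9)
        fwd = g.scaffolds["s1"][locus.start - 1 : locus.end]
        assert helpers.revcomp(fwd) == g.designs["L1"].precursor

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        locus = _one_locus()
        paths = []
        for tag in ("a", "b"):
            g = generate_genome([locus], {"s1": 1000}, seed=11)
            fa, gff = tmp_path / f"{tag}.fa", tmp_path / f"{tag}.gff3"
            g.write_fasta(fa)
            g.write_truth_gff3(gff)
            paths.append((fa.read_bytes(), gff.read_bytes()))
        assert paths[0] == paths[1]

    def test_mixed_kinds_preserved_in_truth(self, tmp_path):
        kinds = ["miRNA", "rRNA", "tRNA", "snRNA", "repeat", "random"] + ["rRNA"] * 4
        loci = []
        pos = 100
        for i, kind in enumerate(kinds):
            if kind == "miRNA":
                loci.append(_one_locus(start=pos))
            else:
                loci.append(
                    EmbeddedLocusSpec(
                        locus_id=f"L{i + 1}" if kind != "miRNA" else "L1",
                        kind=kind, scaffold="s1", start=pos, end=pos + 99,
                    )
                )
            pos += 300
        g = generate_genome(loci, {"s1": 5000}, seed=1)
        gff = tmp_path / "t.gff3"
        g.write_truth_gff3(gff)
        rows = [l.split("\t") for l in gff.read_text().splitlines()[1:]]
        assert len(rows) == 10
        assert sorted(r[2] for r in rows) == sorted(kinds)

    def test_overlapping_loci_rejected_with_ids(self):
        a = _one_locus()
        b = EmbeddedLocusSpec(
            locus_id="L2", kind="rRNA", scaffold="s1", start=120, end=260
        )
        with pytest.raises(ValueError, match="L1.*L2|L2.*L1"):
            generate_genome([a, b], {"s1": 1000}, seed=0)

    def test_locus_exceeding_scaffold_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            generate_genome([_one_locus(start=990)], {"s1": 1000}, seed=0)


class TestLocusSpecValidation:
    def test_star_fraction_bounds(self):
        with pytest.raises(ValueError, match="star_fraction"):
            _one_locus(star_fraction=0.5)

    def test_interval_must_match_design(self):
        with pytest.raises(ValueError, match="loop_len"):
            EmbeddedLocusSpec(
                locus_id="X", kind="miRNA", scaffold="s1", start=1, end=50,
                mature_seq=MATURE, loop_len=15,
            )


class TestReadSimulation:
    def test_error_free_single_locus_reads_equal_mature(self):
        g = generate_genome([_one_locus()], {"s1": 1000}, seed=3)
        sim = simulate_libraries(
            g, total_reads={"WT1": 100, "WT2": 0, "MT1": 0, "MT2": 0},
            error_rate=0.0, seed=5,
        )
        assert len(sim.reads["WT1"]) == 100
        assert sim.inserts["WT1"] == {MATURE: 100}
        adapter = "TCGTATGCCGTCTTCTGCTTG"
        for read in sim.reads["WT1"]:
            assert read.startswith(MATURE)
            rest = read[len(MATURE):]
            assert adapter.startswith(rest) or rest.startswith(adapter[: len(rest)])

    def test_star_emission_within_binomial_bound(self):
        g = generate_genome([_one_locus(star_fraction=0.1)], {"s1": 1000}, seed=3)
        n = 1000
        sim = simulate_libraries(
            g, total_reads={"WT1": n, "WT2": 0, "MT1": 0, "MT2": 0},
            error_rate=0.0, seed=6,
        )
        star = g.designs["L1"].star
        emitted = sim.inserts["WT1"].get(star, 0)
        sigma = math.sqrt(n * 0.1 * 0.9)
        assert abs(emitted - n * 0.1) <= 3 * sigma

    def test_total_reads_conserved_exactly(self):
        loci = [
            _one_locus(),
            EmbeddedLocusSpec(
                locus_id="R1", kind="rRNA", scaffold="s1", start=500, end=700,
                per_library_abundance=(5, 5, 5, 5),
            ),
        ]
        g = generate_genome(loci, {"s1": 1000}, seed=3)
        sim = simulate_libraries(g, total_reads=5000, error_rate=0.01, seed=7)
        for lib, rds in sim.reads.items():
            assert len(rds) == 5000
            assert sim.truth[sim.truth.library == lib]["count"].sum() == 5000

    def test_empty_truth_rejected(self):
        g = generate_genome([_one_locus()], {"s1": 1000}, seed=3)
        g.loci = []
        with pytest.raises(ValueError):
            simulate_libraries(g, total_reads=10)

    def test_determinism_per_seed(self):
        g = generate_genome([_one_locus(star_fraction=0.2)], {"s1": 1000}, seed=3)
        a = simulate_libraries(g, total_reads=500, error_rate=0.01, seed=8)
        b = simulate_libraries(g, total_reads=500, error_rate=0.01, seed=8)
        assert a.reads == b.reads


class TestNovelMirnaCatalog:
    def test_exactly_75_records(self, catalog):
        assert len(catalog) == 75

    def test_published_worked_examples(self, catalog):
        by_id = {r.mirna_id: r for r in catalog}
        novel24 = by_id["Novel24"]
        assert (novel24.scaffold, novel24.start, novel24.end) == (
            "scaffold_14", 4093405, 4093478,
        )
        assert novel24.length == 74
        assert by_id["Novel56"].counts == (3993830, 1867066, 4155155, 2288840)

    def test_round_trip_field_for_field(self, catalog, tmp_path):
        p = tmp_path / "catalog.tsv"
        write_novel_mirna_catalog(catalog, p)
        again = load_novel_mirna_catalog(p)
        assert again == catalog

    @pytest.mark.parametrize(
        "bad_line",
        [
            "Novel99\tscaffold_1:10\t-20\tACGT\tACGT\t1\t1\t1\t1",
            "Novel99\tscaffold_1:10:200\t20\tACGT\tACGT\t1\t1\t1\t1",
            "Novel99\tscaffold_1:10:200\t-20\tACGT\tACGT\t1\t1\t1",
            "Novel99\tscaffold_1:300:200\t-20\tACGT\tACGT\t1\t1\t1\t1",
        ],
    )
    def test_malformed_lines_reported_with_line_number(self, tmp_path, bad_line):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "mirna_id\tlocation\tmfe\tarm5\tarm3\twt1\twt2\tmt1\tmt2\n" + bad_line + "\n"
        )
        with pytest.raises(FixtureParseError, match="line 2"):
            load_novel_mirna_catalog(p)


def test_benchmark_loci_fit_and_are_deterministic():
    loci_a, slen = simulate.default_benchmark_loci(seed=3)
    loci_b, _ = simulate.default_benchmark_loci(seed=3)
    assert loci_a == loci_b
    assert sum(1 for l in loci_a if l.kind == "miRNA") == 20
    for l in loci_a:
        if l.kind == "miRNA":
            assert all(
                a == 0 or a >= 50 for a in l.per_library_abundance
            )
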