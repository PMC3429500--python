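"""miRNA discovery: homology matching, excision, hairpin validation,
precursor summaries and the composed catalog."""

import numpy as np
import pytest

import helpers
from poncirna import discovery
from poncirna.discovery import (
    ConservedCall,
    PlacedTag,
    Rejection,
    TagCluster,
    compose_catalog,
    excise_candidates,
    family_of,
    match_known,
    summarize_precursors,
    validate_hairpin,
)
from poncirna.fold import fold
from poncirna.reads import CleanTag
from poncirna.simulate import build_hairpin_precursor

REFS = [
    ("miR156a", "TGACAGAAGAGAGTGAGCAC"),
    ("miR166a", "TCGGACCAGGCTTCATTCCCC"),
    ("miR166e", "TCGGACCAGGCTTCATTCCTC"),
]


class TestMatchKnown:
    def test_identical_matches_with_zero_mismatches(self):
        assert match_known(REFS[0][1], REFS) == ("miR156a", 0)

    def test_three_substitutions_at_threshold(self):
        tag = list(REFS[0][1])
        for i in (3, 8, 13):
            tag[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[tag[i]]
        ref_id, mism = match_known("".join(tag), REFS)
        assert (ref_id, mism) == ("miR156a", 3)

    def test_four_substitutions_rejected(self):
        tag = list(REFS[0][1])
        for i in (3, 8, 13, 17):
            tag[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[tag[i]]
        assert match_known("".join(tag), REFS) is None

    def test_tie_broken_by_sorted_reference_order(self):
        # equidistant from miR166a and miR166e (each 1 mismatch)
        tag = "TCGGACCAGGCTTCATTCCGC"
        assert match_known(tag, REFS) == ("miR166a", 1)

    def test_length_difference_beyond_two_excluded(self):
        assert match_known(REFS[0][1] + "ACG", [REFS[0]]) is None

    def test_mismatch_count_is_symmetric(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 25))))
            b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 25))))
            if abs(len(a) - len(b)) > 2:
                continue
            ra = match_known(a, [("x", b)], max_mismatch=25)
            rb = match_known(b, [("x", a)], max_mismatch=25)
            assert (ra and ra[1]) == (rb and rb[1])

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            match_known("ACGT" * 5, [])


class TestExcision:
    def _cluster(self, start=1000, end=1022):
        tag = CleanTag("A" * 22, {"WT1": 5})
        return TagCluster("s0", start, end, [(tag, start, end, "+")])

    def test_single_mid_scaffold_tag_yields_four_windows(self):
        windows = excise_candidates([self._cluster()], {"s0": "ACGT" * 1000})
        assert len(windows) == 4
        assert {w.strand for w in windows} == {"+", "-"}
        starts = {w.start for w in windows}
        assert starts == {750, 980}

    def test_window_near_scaffold_start_is_clipped(self):
        windows = excise_candidates([self._cluster(30, 52)], {"s0": "ACGT" * 1000})
        assert windows
        assert all(w.start >= 0 for w in windows)
        assert min(w.start for w in windows) == 0

    def test_windows_never_exceed_precursor_bounds(self):
        windows = excise_candidates([self._cluster()], {"s0": "ACGT" * 1000})
        for w in windows:
            assert 50 <= w.end - w.start <= 400
            assert len(w.sequence) == w.end - w.start

    def test_designed_locus_contained_in_some_window(self, benchmark):
        """For every recovered simulated miRNA locus, at least one excised
        window fully contains the designed precursor."""
        clusters = discovery.cluster_alignments(benchmark.candidates)
        windows = excise_candidates(clusters, benchmark.genome.scaffolds)
        covered = 0
        mir = [l for l in benchmark.loci if l.kind == "miRNA"]
        for l in mir:
            if any(
                w.scaffold == l.scaffold and w.start <= l.start - 1 and w.end >= l.end
                for w in windows
            ):
                covered += 1
        assert covered >= 0.9 * len(mir)


def _placed_hairpin(n_mismatches=0, loop_len=15, seed=0, star_shift=0,
                    mature_count=100, star_count=12):
    mature_seq = "TAGCCAAGGATGACTTGCCTGA"
    d = build_hairpin_precursor(mature_seq, loop_len, n_mismatches, seed=seed)
    structure = fold(d.precursor)
    placed = [
        PlacedTag(CleanTag(d.mature, {"MT1": mature_count}), d.mature_start, d.mature_end),
        PlacedTag(
            CleanTag(d.star, {"MT1": star_count}),
            d.star_start + star_shift,
            d.star_end + star_shift,
        ),
    ]
    return structure, placed, d


class TestValidateHairpin:
    @pytest.mark.parametrize("mm,loop", [(0, 10), (0, 20), (1, 12), (2, 15), (2, 20)])
    def test_designed_hairpins_accepted(self, mm, loop):
        structure, placed, d = _placed_hairpin(n_mismatches=mm, loop_len=loop, seed=mm + loop)
        result = validate_hairpin(structure, placed)
        assert not isinstance(result, Rejection), result
        mature, star, (lo, hi) = result
        assert mature.tag.sequence == d.mature
        assert star.tag.sequence == d.star
        assert lo == 0 and hi == len(d.precursor)

    def test_zero_overhang_star_rejected(self):
        structure, placed, _ = _placed_hairpin(star_shift=2)
        result = validate_hairpin(structure, placed)
        assert isinstance(result, Rejection)
        assert result.reason == "overhang"

    def test_unpaired_duplex_rejected(self):
        # six non-pairing substitutions leave > 4 mature bases unpaired
        mature_seq = "TAGCCAAGGATGACTTGCCTGA"
        d = build_hairpin_precursor(mature_seq, 15, 0, seed=1)
        star = list(d.star)
        m = len(mature_seq)
        for j in range(4, 10):
            partner = mature_seq[m - 3 - j]
            star[j] = next(
                b for b in "ACGT" if not helpers.can_pair(partner, b)
            )
        hacked = d.precursor[: d.star_start] + "".join(star)
        structure = fold(hacked)
        placed = [
            PlacedTag(CleanTag(d.mature, {"MT1": 100}), 0, m),
            PlacedTag(CleanTag("".join(star), {"MT1": 10}), d.star_start, d.star_end),
        ]
        result = validate_hairpin(structure, placed)
        assert isinstance(result, Rejection)
        assert result.reason == "duplex_pairing"

    def test_no_tags_rejected_unsupported(self):
        structure, _, _ = _placed_hairpin()
        result = validate_hairpin(structure, [])
        assert isinstance(result, Rejection) and result.reason == "unsupported"

    def test_no_opposite_arm_tag_rejected(self):
        structure, placed, _ = _placed_hairpin()
        result = validate_hairpin(structure, placed[:1])
        assert isinstance(result, Rejection) and result.reason == "no_star"

    def test_weak_hairpin_rejected_on_energy(self):
        structure, placed, _ = _placed_hairpin()
        weak = type(structure)(
            structure.sequence, structure.pairing, -10.0, structure.pairs
        )
        result = validate_hairpin(weak, placed)
        assert isinstance(result, Rejection) and result.reason == "mfe"

    def test_accepted_candidates_revalidate(self, benchmark):
        """Recomputing the duplex geometry from each accepted call's stored
        pairing reproduces the acceptance."""
        for n in benchmark.novel:
            partner = n.structure.partner()
            seq = n.structure.sequence
            a = seq.find(n.mature.sequence)
            c = seq.find(n.star.sequence)
            assert a >= 0 and c >= 0
            ok, reason, _ = discovery._duplex_geometry(
                partner,
                PlacedTag(n.mature, a, a + len(n.mature.sequence)),
                PlacedTag(n.star, c, c + len(n.star.sequence)),
            )
            assert ok, (n.mirna_id, reason)


class TestPrecursorSummary:
    def test_published_catalog_statistics(self, catalog):
        s = summarize_precursors(catalog)
        assert s["count"] == 75
        assert s["length_min"] == 74
        assert s["length_max"] == 343
        assert round(s["length_mean"]) == 132
        assert s["mfe_min"] == -140.2
        assert s["mfe_max"] == -18.0

    def test_single_record_degenerate(self, catalog):
        s = summarize_precursors(catalog[:1])
        assert s["length_min"] == s["length_max"] == s["length_mean"]

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            summarize_precursors([])


class TestCatalogComposition:
    def test_family_grouping_strips_variant_suffix(self):
        assert family_of("csi-miR166e") == "miR166"
        assert family_of("miR166a") == "miR166"
        assert family_of("csi-miR482a*") == "miR482"
        assert family_of("PtmiR93") == "miR93"

    def test_two_variants_one_family(self):
        calls = [
            ConservedCall(CleanTag(REFS[1][1], {"WT1": 5}), "miR166a", 0),
            ConservedCall(CleanTag(REFS[2][1], {"WT1": 2}), "miR166e", 0),
        ]
        records = compose_catalog(calls, [])
        assert len(records) == 2
        assert {r.family for r in records} == {"miR166"}

    def test_disjoint_sets_concatenate(self, benchmark):
        calls = [ConservedCall(CleanTag(REFS[0][1], {"WT1": 5}), "miR156a", 0)]
        records = compose_catalog(calls, benchmark.novel)
        assert len(records) == 1 + len(benchmark.novel)

    def test_conserved_wins_on_conflict(self, benchmark):
        novel = benchmark.novel
        conflict = ConservedCall(
            CleanTag(novel[0].mature.sequence, {"WT1": 5}), "miR9999a", 1
        )
        with pytest.warns(UserWarning, match="conserved"):
            records = compose_catalog([conflict], novel)
        assert len(records) == len(novel)
        rec = next(r for r in records if r.mature == novel[0].mature.sequence)
        assert rec.cls == "conserved"


class TestNovelRecovery:
    def test_sensitivity_and_fdr_on_default_benchmark(self, benchmark):
        called = {n.mature.sequence for n in benchmark.novel}
        truth = benchmark.true_matures
        tp = len(called & truth)
        fp = len(called - truth)
        assert tp / len(truth) >= 0.9
        assert fp / max(1, len(benchmark.novel)) <= 0.05

    def test_calls_carry_star_and_interval(self, benchmark):
        for n in benchmark.novel:
            assert n.star is not None
            assert n.end > n.start
            assert 50 <= n.length <= 400
            assert n.mfe <= discovery.MFE_MAX_DEFAULT
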