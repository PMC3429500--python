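"""Tag-to-genome mapping and annotation-based classification.

Tags are aligned ungapped to both genome strands with at most one mismatch
using a seed-and-verify index: two non-overlapping 9-mer seeds per tag
guarantee (by pigeonhole) that every <=1-mismatch locus is found, so the
index is exactly equivalent to a brute-force scan of all offsets. Mapped
tags are then classified against a structural-RNA/repeat annotation by a
fixed precedence order, partitioning every library's clean reads into the
standard small-RNA categories.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

from ._seq import revcomp
from .reads import CleanTag
from .simulate import LIBRARIES

SEED_K = 9
MULTIPLICITY_CAP = 20

# classification precedence, most authoritative first
CATEGORY_PRECEDENCE = (
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "other_ncRNA",
    "repeat",
    "miRNA_candidate",
)
CATEGORIES = CATEGORY_PRECEDENCE + ("unannotated", "unmapped")

# GFF3/BED feature types folded into each category
_TYPE_TO_CATEGORY = {
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "snRNA": "snRNA",
    "snoRNA": "snoRNA",
    "ncRNA": "other_ncRNA",
    "repeat": "repeat",
    "repeat_region": "repeat",
    "dispersed_repeat": "repeat",
    "miRNA": "miRNA_candidate",
    "miRNA_primary_transcript": "miRNA_candidate",
}


@dataclass
class TagAlignment:
    """One genomic locus of a tag (0-based half-open coordinates)."""

    scaffold: str
    start: int
    end: int
    strand: str
    mismatches: int


@dataclass
class TagHits:
    """All alignments of one tag, plus the hyper-repetitive flag."""

    tag: CleanTag
    alignments: list[TagAlignment] = field(default_factory=list)
    hyper_repetitive: bool = False

    @property
    def multiplicity(self) -> int:
        return len(self.alignments)

    @property
    def mapped(self) -> bool:
        return bool(self.alignments)


class GenomeIndex:
    """Seed index over the plus strand of every scaffold."""

    def __init__(self, scaffolds: dict[str, str], k: int = SEED_K):
        if not scaffolds or all(len(s) == 0 for s in scaffolds.values()):
            raise ValueError("empty genome")
        self.scaffolds = {n: s.upper() for n, s in scaffolds.items()}
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in self.scaffolds.items():
            for i in range(len(seq) - k + 1):
                self.index[seq[i : i + k]].append((name, i))

    def _candidates(self, query: str) -> set[tuple[str, int]]:
        """Candidate (scaffold, offset) starts from the two pigeonhole seeds."""
        k = self.k
        out: set[tuple[str, int]] = set()
        for seed_off in (0, k):
            seed = query[seed_off : seed_off + k]
            if len(seed) < k:
                continue
            for name, pos in self.index.get(seed, ()):
                start = pos - seed_off
                if start >= 0 and start + len(query) <= len(self.scaffolds[name]):
                    out.add((name, start))
        return out

    def find(self, query: str, max_mismatch: int) -> list[tuple[str, int, int]]:
        """All (scaffold, start, mismatches) plus-strand occurrences."""
        hits = []
        for name, start in self._candidates(query):
            ref = self.scaffolds[name][start : start + len(query)]
            mism = sum(a != b for a, b in zip(query, ref))
            if mism <= max_mismatch:
                hits.append((name, start, mism))
        return sorted(hits)


def map_tags(
    tags: list[CleanTag],
    genome: dict[str, str] | GenomeIndex,
    max_mismatch: int = 1,
    multiplicity_cap: int = MULTIPLICITY_CAP,
) -> list[TagHits]:
    """Align tags to both strands with <= ``max_mismatch`` substitutions.

    Tags mapping to more loci than ``multiplicity_cap`` are flagged
    hyper-repetitive (all loci are still reported); downstream discovery
    excludes them from miRNA candidacy.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    results = []
    for tag in tags:
        seq = tag.sequence.upper()
        alns = [
            TagAlignment(name, start, start + len(seq), "+", mism)
            for name, start, mism in index.find(seq, max_mismatch)
        ]
        for name, start, mism in index.find(revcomp(seq), max_mismatch):
            alns.append(TagAlignment(name, start, start + len(seq), "-", mism))
        alns.sort(key=lambda a: (a.scaffold, a.start, a.strand))
        results.append(
            TagHits(
                tag=tag,
                alignments=alns,
                hyper_repetitive=len(alns) > multiplicity_cap,
            )
        )
    return results


# ---------------------------------------------------------------------------
# annotation loading


@dataclass
class Feature:
    scaffold: str
    start: int  # 0-based half-open
    end: int
    ftype: str


def load_annotation(path: str | Path) -> list[Feature]:
    """Load features from GFF3 (via gffutils) or 6-column BED."""
    path = Path(path)
    if path.suffix.lower() == ".bed":
        feats = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.rstrip("\n").split("\t")
                feats.append(Feature(f[0], int(f[1]), int(f[2]), f[3]))
        return feats
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    return [
        Feature(f.seqid, f.start - 1, f.end, f.featuretype)
        for f in db.all_features()
    ]


# ---------------------------------------------------------------------------
# classification


def _category_of(ftype: str) -> str:
    if ftype in _TYPE_TO_CATEGORY:
        return _TYPE_TO_CATEGORY[ftype]
    warnings.warn(f"unknown feature type {ftype!r}; treated as other ncRNA")
    return "other_ncRNA"


def classify_tags(
    hits: list[TagHits],
    features: list[Feature],
    min_overlap_fraction: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Assign each tag exactly one category and tally reads per library.

    A tag inherits a feature's category when any of its alignments overlaps
    the feature by at least ``min_overlap_fraction`` of the tag length; with
    several qualifying features the fixed precedence order
    rRNA > tRNA > snRNA > snoRNA > other ncRNA > repeat > miRNA-candidate
    decides. Mapped tags overlapping nothing are "unannotated"; unmapped
    tags are "unmapped". The tally partitions each library's read total.

    Returns ``(tally, labels)``: a DataFrame indexed by category with
    per-library read counts plus a tag count column, and the per-tag labels
    keyed by tag sequence.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for f in features:
        if f.end > f.start:
            trees[f.scaffold].addi(f.start, f.end, _category_of(f.ftype))
    rank = {c: i for i, c in enumerate(CATEGORY_PRECEDENCE)}
    labels: dict[str, str] = {}
    tally = pd.DataFrame(
        0, index=list(CATEGORIES), columns=list(LIBRARIES) + ["tags"]
    )
    for h in hits:
        if not h.mapped:
            cat = "unmapped"
        else:
            best = None
            min_ov = min_overlap_fraction * len(h.tag.sequence)
            for a in h.alignments:
                for iv in trees[a.scaffold].overlap(a.start, a.end):
                    ov = min(a.end, iv.end) - max(a.start, iv.begin)
                    if ov >= min_ov:
                        if best is None or rank[iv.data] < rank[best]:
                            best = iv.data
            cat = best if best is not None else "unannotated"
        labels[h.tag.sequence] = cat
        tally.loc[cat, "tags"] += 1
        for lib in LIBRARIES:
            tally.loc[cat, lib] += h.tag.counts.get(lib, 0)
    return tally, labels


def candidate_hits(
    hits: list[TagHits],
    labels: dict[str, str],
    exclude_repeats: bool = True,
) -> list[TagHits]:
    """Tags eligible for miRNA discovery: mapped, not hyper-repetitive, not
    structural RNA (and, by default, not repeat-derived)."""
    excluded = {"rRNA", "tRNA", "snRNA", "snoRNA", "other_ncRNA", "unmapped"}
    if exclude_repeats:
        excluded.add("repeat")
    return [
        h
        for h in hits
        if h.mapped
        and not h.hyper_repetitive
        and labels.get(h.tag.sequence, "unannotated") not in excluded
    ]


def write_alignments_tsv(hits: list[TagHits], path: str | Path) -> None:
    """SAM-like TSV export of all alignments."""
    with open(path, "w") as fh:
        fh.write("tag\tscaffold\tstart\tend\tstrand\tmismatches\tmultiplicity\n")
        for h in hits:
            for a in h.alignments:
                fh.write(
                    f"{h.tag.sequence}\t{a.scaffold}\t{a.start}\t{a.end}\t"
                    f"{a.strand}\t{a.mismatches}\t{h.multiplicity}\n"
                )
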