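"""Read cleanup and collapsing for small-RNA libraries.

Raw reads are 3'-adapter-trimmed, screened for quality, length and 5'
contamination, then collapsed to unique tags carrying a per-library read
count ("read-count score"). Length distributions are summarised read-weighted
over the 18-30 nt analysis window.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .simulate import LIBRARIES

MIN_LEN = 18
MAX_LEN = 30


@dataclass
class CleanTag:
    """A unique small-RNA sequence with per-library read counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LibraryStats:
    library: str
    raw: int = 0
    clean: int = 0
    unique: int = 0
    rejected: dict[str, int] = field(default_factory=dict)
    length_proportions: dict[int, float] = field(default_factory=dict)


def trim_adapter(read: str, adapter3: str, min_overlap: int = 7):
    """Remove the 3' adapter from a read.

    The longest read suffix matching a prefix of ``adapter3`` with at least
    ``min_overlap`` nt of overlap and at most one mismatch per 7 nt of
    overlap is removed (equivalently: the earliest admissible adapter start
    wins, which also truncates at full internal adapter occurrences).

    Returns ``(insert, trimmed)`` where ``trimmed`` is False when no
    admissible match exists and the read is returned unchanged.
    """
    if not adapter3:
        raise ValueError("adapter3 must be non-empty")
    read = read.upper()
    adapter3 = adapter3.upper()
    n = len(read)
    for p in range(0, n - min_overlap + 1):
        overlap = min(n - p, len(adapter3))
        if overlap < min_overlap:
            break
        allowed = overlap // 7
        mism = 0
        for a, b in zip(read[p : p + overlap], adapter3[:overlap]):
            if a != b:
                mism += 1
                if mism > allowed:
                    break
        if mism <= allowed:
            return read[:p], True
    return read, False


def filter_reads(
    reads: list[str], min_len: int = MIN_LEN, max_len: int = MAX_LEN
) -> tuple[list[str], Counter]:
    """Keep reads within the length window and free of ambiguous bases."""
    kept: list[str] = []
    tally: Counter = Counter()
    for r in reads:
        if "N" in r:
            tally["ambiguous"] += 1
        elif len(r) < min_len:
            tally["too_short"] += 1
        elif len(r) > max_len:
            tally["too_long"] += 1
        else:
            kept.append(r)
    return kept, tally


def is_contaminant(read: str, adapter5: str | None, min_prefix: int = 10) -> bool:
    """5' contaminant: read begins with >= ``min_prefix`` exact nt of the
    5' adapter."""
    if adapter5 is None or len(adapter5) < min_prefix:
        return False
    return read.upper().startswith(adapter5.upper()[:min_prefix])


def collapse(reads_per_library: dict[str, list[str]]) -> list[CleanTag]:
    """Collapse identical clean reads into unique tags with per-library counts.

    Tags are sorted by total count (descending), then sequence, so ordering
    is deterministic. Per library, tag counts sum to that library's clean
    read total.
    """
    counts: dict[str, dict[str, int]] = {}
    for lib, reads in reads_per_library.items():
        for seq, c in Counter(reads).items():
            counts.setdefault(seq, {})[lib] = c
    tags = [CleanTag(seq, libs) for seq, libs in counts.items()]
    tags.sort(key=lambda t: (-t.total, t.sequence))
    return tags


def length_distribution(tags: list[CleanTag], library: str) -> dict[int, float]:
    """Read-weighted proportion of clean reads at each length, one library."""
    weights: Counter = Counter()
    for t in tags:
        c = t.counts.get(library, 0)
        if c:
            weights[len(t)] += c
    total = sum(weights.values())
    if total == 0:
        raise ValueError(f"library {library!r} has no reads")
    return {length: weights[length] / total for length in sorted(weights)}


def clean_library(
    fastq_path: str | Path,
    adapter3: str,
    adapter5: str | None = None,
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
    min_quality: int = 10,
    library: str = "",
) -> tuple[list[str], LibraryStats]:
    """Run the full cleanup on one FASTQ library.

    Order of operations: quality screen (any base below ``min_quality`` drops
    the read), 5' contaminant screen, 3' adapter trim (untrimmed reads are
    dropped as adapter-less), then the length/ambiguity filter.
    """
    stats = LibraryStats(library=library or str(fastq_path))
    trimmed: list[str] = []
    for rec in SeqIO.parse(str(fastq_path), "fastq"):
        stats.raw += 1
        quals = rec.letter_annotations.get("phred_quality", [])
        if quals and min(quals) < min_quality:
            stats.rejected["low_quality"] = stats.rejected.get("low_quality", 0) + 1
            continue
        seq = str(rec.seq).upper()
        if is_contaminant(seq, adapter5):
            stats.rejected["contaminant_5p"] = (
                stats.rejected.get("contaminant_5p", 0) + 1
            )
            continue
        insert, ok = trim_adapter(seq, adapter3)
        if not ok:
            stats.rejected["no_adapter"] = stats.rejected.get("no_adapter", 0) + 1
            continue
        trimmed.append(insert)
    clean, tally = filter_reads(trimmed, min_len, max_len)
    stats.rejected.update(tally)
    stats.clean = len(clean)
    stats.unique = len(set(clean))
    return clean, stats


def finalize_stats(stats: LibraryStats, tags: list[CleanTag]) -> LibraryStats:
    if stats.clean:
        stats.length_proportions = length_distribution(tags, stats.library)
    return stats


def write_tags_fasta(tags: list[CleanTag], path: str | Path) -> None:
    """Collapsed tags as FASTA, counts encoded in the header."""
    with open(path, "w") as fh:
        for i, t in enumerate(tags, 1):
            parts = "_".join(f"{lib}:{t.counts.get(lib, 0)}" for lib in LIBRARIES)
            fh.write(f">tag{i}_{parts}\n{t.sequence}\n")


def write_tags_tsv(tags: list[CleanTag], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\t" + "\t".join(LIBRARIES) + "\n")
        for t in tags:
            fh.write(
                t.sequence
                + "\t"
                + "\t".join(str(t.counts.get(lib, 0)) for lib in LIBRARIES)
                + "\n"
            )


def read_tags_tsv(path: str | Path) -> list[CleanTag]:
    tags = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        libs = header[1:]
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            counts = {
                lib: int(c) for lib, c in zip(libs, parts[1:]) if int(c) > 0
            }
            tags.append(CleanTag(parts[0], counts))
    return tags


def write_stats_json(stats: list[LibraryStats], path: str | Path) -> None:
    payload = [
        {
            "library": s.library,
            "raw": s.raw,
            "clean": s.clean,
            "unique": s.unique,
            "rejected": s.rejected,
            "length_proportions": {str(k): v for k, v in s.length_proportions.items()},
        }
        for s in stats
    ]
    Path(path).write_text(json.dumps(payload, indent=2))
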