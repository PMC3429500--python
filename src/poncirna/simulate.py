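"""Synthetic genomes, hairpin loci and four-library small-RNA read sets.

The generator emulates the structure of the study design the analysis
assumes: two genotypes (early-flowering mutant MT, wild type WT) sampled at a
juvenile and an adult stage, giving four libraries (WT1, WT2, MT1, MT2).
Genomic scaffolds carry embedded loci of several kinds -- miRNA hairpins,
structural RNAs (rRNA/tRNA/snRNA), repeats and plain random loci -- and each
library draws reads multinomially according to per-locus expected
abundances. miRNA loci emit the mature sequence, a minority of star-strand
reads, and optional substitution errors; structural and random loci shed
uniformly positioned 18-30 nt degradation fragments. Every read carries the
3' sequencing adapter (possibly truncated by the read length).

The module also packages a catalog of 75 published novel miRNA loci from
precocious trifoliate orange (id, precursor coordinates, folding energy,
5'/3' arm sequences and per-library read counts), used as a worked example
throughout the package.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._seq import DNA_BASES, is_valid, random_seq, revcomp, to_dna

LIBRARIES = ("WT1", "WT2", "MT1", "MT2")

LOCUS_KINDS = ("miRNA", "rRNA", "tRNA", "snRNA", "repeat", "random")


class FixtureParseError(ValueError):
    """Raised when the packaged catalog file is malformed."""


# ---------------------------------------------------------------------------
# hairpin construction


@dataclass
class HairpinDesign:
    """A designed precursor with mature/star placements (0-based half-open)."""

    precursor: str
    mature: str
    star: str
    mature_start: int
    mature_end: int
    star_start: int
    star_end: int


def _non_pairing_base(rng: np.random.Generator, partner: str) -> str:
    """A base that neither Watson-Crick- nor wobble-pairs with ``partner``."""
    from ._seq import pairs_with

    choices = [b for b in DNA_BASES if not pairs_with(b, partner)]
    return str(rng.choice(choices))


def build_hairpin_precursor(
    mature: str,
    loop_len: int,
    n_mismatches: int = 0,
    seed: int = 0,
) -> HairpinDesign:
    """Design a fold-back precursor around a mature miRNA sequence.

    The precursor is ``mature + loop + star`` (5'->3'), where the star strand
    is the reverse complement of the mature region positioned so the excised
    mature/star duplex carries the canonical 2-nt 3' overhang on both
    strands: mature position ``i`` pairs with star position ``m-3-i``, the
    last two bases of each strand protrude. ``n_mismatches`` substitutions
    are placed in the interior of the star's paired region to mimic the
    imperfect stems of real precursors.

    Precursor length is ``2 * len(mature) + loop_len``.
    """
    mature = to_dna(mature)
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3 to form a hairpin loop")
    if n_mismatches > 4:
        raise ValueError("at most 4 designed mismatches are supported")
    if not is_valid(mature):
        raise ValueError("mature sequence contains invalid characters")
    m = len(mature)
    if m < 18:
        raise ValueError("mature sequence shorter than 18 nt")
    rng = np.random.default_rng(seed)
    loop = random_seq(rng, loop_len)
    star = [""] * m
    for j in range(m - 2):
        star[j] = revcomp(mature[m - 3 - j])
    # free 3' tail of the star (the overhang bases)
    star[m - 2] = str(rng.choice(list(DNA_BASES)))
    star[m - 1] = str(rng.choice(list(DNA_BASES)))
    # designed mismatches: any non-complementary base (so G:U wobbles, the
    # commonest imperfection of real stems, arise naturally); kept away from
    # the duplex ends so the overhang geometry survives folding
    if n_mismatches:
        interior = list(range(2, m - 6))
        for j in rng.choice(interior, size=n_mismatches, replace=False):
            options = [x for x in DNA_BASES if x != revcomp(mature[m - 3 - j])]
            star[j] = str(rng.choice(options))
    star_seq = "".join(star)
    precursor = mature + loop + star_seq
    return HairpinDesign(
        precursor=precursor,
        mature=mature,
        star=star_seq,
        mature_start=0,
        mature_end=m,
        star_start=m + loop_len,
        star_end=2 * m + loop_len,
    )


# ---------------------------------------------------------------------------
# locus specs and genome generation


@dataclass
class EmbeddedLocusSpec:
    """One locus to embed in a synthetic scaffold.

    Coordinates are 1-based inclusive, as in the truth GFF3. For miRNA loci
    the interval length must equal ``2 * len(mature_seq) + loop_len``.
    ``per_library_abundance`` holds the expected read counts in
    (WT1, WT2, MT1, MT2); ``star_fraction`` is the probability that an
    emitted read is the star strand rather than the mature.
    """

    locus_id: str
    kind: str
    scaffold: str
    start: int
    end: int
    strand: str = "+"
    mature_seq: str | None = None
    loop_len: int = 15
    designed_mismatches: int = 0
    per_library_abundance: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    star_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in LOCUS_KINDS:
            raise ValueError(f"unknown locus kind {self.kind!r}")
        if self.end < self.start:
            raise ValueError(f"{self.locus_id}: end < start")
        if self.strand not in "+-":
            raise ValueError(f"{self.locus_id}: bad strand {self.strand!r}")
        if not (0 <= self.star_fraction < 0.5):
            raise ValueError(f"{self.locus_id}: star_fraction must be in [0, 0.5)")
        if any(a < 0 for a in self.per_library_abundance):
            raise ValueError(f"{self.locus_id}: negative abundance")
        if self.kind == "miRNA":
            if self.mature_seq is None:
                raise ValueError(f"{self.locus_id}: miRNA locus needs mature_seq")
            self.mature_seq = to_dna(self.mature_seq)
            if not 20 <= len(self.mature_seq) <= 24:
                raise ValueError(f"{self.locus_id}: mature length must be 20-24 nt")
            if self.length != 2 * len(self.mature_seq) + self.loop_len:
                raise ValueError(
                    f"{self.locus_id}: interval length {self.length} != "
                    f"2*|mature| + loop_len"
                )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SyntheticGenome:
    """Scaffold sequences plus the truth features embedded in them."""

    scaffolds: dict[str, str]
    loci: list[EmbeddedLocusSpec]
    designs: dict[str, HairpinDesign] = field(default_factory=dict)

    def locus_sequence(self, locus: EmbeddedLocusSpec) -> str:
        s = self.scaffolds[locus.scaffold][locus.start - 1 : locus.end]
        return revcomp(s) if locus.strand == "-" else s

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.scaffolds):
                fh.write(f">{name}\n")
                seq = self.scaffolds[name]
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    def write_truth_gff3(self, path: str | Path) -> None:
        _write_gff3(path, self.loci)

    def write_structural_annotation(self, path: str | Path) -> None:
        """Truth GFF3 restricted to structural-RNA and repeat features,
        i.e. what a real annotation track would provide to the classifier."""
        keep = [l for l in self.loci if l.kind in ("rRNA", "tRNA", "snRNA", "repeat")]
        _write_gff3(path, keep)


def _write_gff3(path: str | Path, loci: list[EmbeddedLocusSpec]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for l in sorted(loci, key=lambda x: (x.scaffold, x.start)):
            fh.write(
                f"{l.scaffold}\tponcirna\t{l.kind}\t{l.start}\t{l.end}\t.\t"
                f"{l.strand}\t.\tID={l.locus_id}\n"
            )


def generate_genome(
    loci: list[EmbeddedLocusSpec],
    scaffold_lengths: dict[str, int],
    seed: int = 0,
) -> SyntheticGenome:
    """Build random scaffolds with the given loci embedded at their coordinates.

    Deterministic for a fixed seed. Overlapping loci on the same scaffold are
    rejected. miRNA loci are materialised through
    :func:`build_hairpin_precursor`; repeats are tandem copies of a short
    unit; the remaining kinds are plain random sequence distinguished only by
    their truth annotation.
    """
    # decorrelate from any caller that derived locus sequences from the same
    # integer seed (otherwise the background would replay those draws)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x67]))
    by_scaffold: dict[str, list[EmbeddedLocusSpec]] = {}
    for l in loci:
        if l.scaffold not in scaffold_lengths:
            raise ValueError(f"{l.locus_id}: unknown scaffold {l.scaffold}")
        if l.end > scaffold_lengths[l.scaffold]:
            raise ValueError(f"{l.locus_id}: locus exceeds scaffold bounds")
        by_scaffold.setdefault(l.scaffold, []).append(l)
    for name, group in by_scaffold.items():
        group.sort(key=lambda x: x.start)
        for a, b in zip(group, group[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping loci on {name}: {a.locus_id}, {b.locus_id}"
                )
    scaffolds: dict[str, str] = {}
    designs: dict[str, HairpinDesign] = {}
    for name in sorted(scaffold_lengths):
        base = list(random_seq(rng, scaffold_lengths[name]))
        for l in by_scaffold.get(name, []):
            if l.kind == "miRNA":
                design = build_hairpin_precursor(
                    l.mature_seq,
                    l.loop_len,
                    l.designed_mismatches,
                    seed=int(rng.integers(2**31)),
                )
                designs[l.locus_id] = design
                ins = design.precursor
            elif l.kind == "repeat":
                unit = random_seq(rng, 10)
                ins = (unit * (l.length // 10 + 1))[: l.length]
            else:
                ins = random_seq(rng, l.length)
            if l.strand == "-":
                ins = revcomp(ins)
            base[l.start - 1 : l.end] = list(ins)
        scaffolds[name] = "".join(base)
    return SyntheticGenome(scaffolds=scaffolds, loci=list(loci), designs=designs)


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class SimulatedLibraries:
    """Reads per library plus the per-locus truth emission table."""

    reads: dict[str, list[str]]
    truth: "pd.DataFrame"  # noqa: F821 - imported lazily below
    inserts: dict[str, dict[str, int]]  # library -> insert sequence -> count


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
    for i in hits:
        out[i] = str(rng.choice([b for b in DNA_BASES if b != out[i]]))
    return "".join(out)


def simulate_libraries(
    genome: SyntheticGenome,
    total_reads: dict[str, int] | int,
    adapter3: str = "TCGTATGCCGTCTTCTGCTTG",
    error_rate: float = 0.0,
    read_length: int = 49,
    seed: int = 0,
) -> SimulatedLibraries:
    """Draw four read libraries from the truth loci.

    Per library, reads are allocated to loci by a single multinomial draw
    over the normalised per-library abundances, so the emitted reads sum
    exactly to the requested total. miRNA loci emit mature or star inserts
    (star with probability ``star_fraction``); other kinds shed uniformly
    positioned 18-30 nt fragments. Each read is insert + 3' adapter,
    truncated to ``read_length``, with i.i.d. substitution errors at
    ``error_rate``.
    """
    import pandas as pd

    if not genome.loci:
        raise ValueError("cannot simulate from an empty truth set")
    if not 0 <= error_rate <= 0.05:
        raise ValueError("error_rate must be in [0, 0.05]")
    if isinstance(total_reads, int):
        total_reads = {lib: total_reads for lib in LIBRARIES}
    rng = np.random.default_rng(seed)
    loci = genome.loci
    reads: dict[str, list[str]] = {}
    inserts: dict[str, dict[str, int]] = {}
    truth_rows = []
    for li, lib in enumerate(LIBRARIES):
        n = int(total_reads.get(lib, 0))
        weights = np.array([l.per_library_abundance[li] for l in loci], float)
        if n > 0 and weights.sum() <= 0:
            raise ValueError(f"abundances for {lib} not normalizable")
        alloc = (
            rng.multinomial(n, weights / weights.sum())
            if n > 0
            else np.zeros(len(loci), int)
        )
        lib_reads: list[str] = []
        lib_inserts: dict[str, int] = {}
        for l, count in zip(loci, alloc):
            if count == 0:
                continue
            if l.kind == "miRNA":
                design = genome.designs[l.locus_id]
                n_star = int(rng.binomial(count, l.star_fraction))
                for arm, arm_seq, c in (
                    ("mature", design.mature, count - n_star),
                    ("star", design.star, n_star),
                ):
                    if c:
                        truth_rows.append((l.locus_id, lib, arm, c, arm_seq))
                        lib_inserts[arm_seq] = lib_inserts.get(arm_seq, 0) + c
                        for _ in range(c):
                            lib_reads.append(
                                _mutate(
                                    (arm_seq + adapter3)[:read_length],
                                    rng,
                                    error_rate,
                                )
                            )
            else:
                locus_seq = genome.locus_sequence(l)
                frag_counts: dict[str, int] = {}
                for _ in range(count):
                    flen = int(rng.integers(18, 31))
                    flen = min(flen, len(locus_seq))
                    pos = int(rng.integers(0, len(locus_seq) - flen + 1))
                    frag = locus_seq[pos : pos + flen]
                    frag_counts[frag] = frag_counts.get(frag, 0) + 1
                    lib_inserts[frag] = lib_inserts.get(frag, 0) + 1
                    lib_reads.append(
                        _mutate((frag + adapter3)[:read_length], rng, error_rate)
                    )
                truth_rows.append((l.locus_id, lib, "fragment", count, ""))
        reads[lib] = lib_reads
        inserts[lib] = lib_inserts
    truth = pd.DataFrame(
        truth_rows, columns=["locus_id", "library", "arm", "count", "insert"]
    )
    return SimulatedLibraries(reads=reads, truth=truth, inserts=inserts)


def write_fastq(reads: list[str], path: str | Path, quality: str = "I") -> None:
    """Write simulated reads as Phred+33 FASTQ with a fixed base quality."""
    with open(path, "w") as fh:
        for i, seq in enumerate(reads, 1):
            fh.write(f"@read{i}\n{seq}\n+\n{quality * len(seq)}\n")


# ---------------------------------------------------------------------------
# default study-condition scenario


def sample_expectations(
    rng: np.random.Generator, n: int, mu: float = 3.0, sigma: float = 1.5
) -> np.ndarray:
    """Convenience log-normal sampler for per-locus expected read counts."""
    return np.exp(rng.normal(mu, sigma, size=n))


def default_benchmark_loci(
    seed: int = 0,
    n_mirna: int = 20,
    min_expected: float = 50.0,
    scaffold_lengths: dict[str, int] | None = None,
) -> tuple[list[EmbeddedLocusSpec], dict[str, int]]:
    """The standard synthetic benchmark: miRNA hairpins among decoys.

    20 miRNA loci (each with expected abundance >= ``min_expected`` in every
    library), plus rRNA/tRNA/snRNA, repeat and random loci that together
    soak up roughly half of the reads, mirroring the structural-RNA fraction
    typical of plant small-RNA libraries.
    """
    rng = np.random.default_rng(seed)
    if scaffold_lengths is None:
        scaffold_lengths = {"scaffold_1": 120_000, "scaffold_2": 120_000}
    names = sorted(scaffold_lengths)
    loci: list[EmbeddedLocusSpec] = []
    cursor = {name: 500 for name in names}

    def place(kind, locus_id, length, **kw):
        name = names[len(loci) % len(names)]
        start = cursor[name]
        cursor[name] += length + 700  # generous spacing, no overlaps
        if cursor[name] > scaffold_lengths[name]:
            raise ValueError("scaffolds too small for benchmark loci")
        loci.append(
            EmbeddedLocusSpec(
                locus_id=locus_id,
                kind=kind,
                scaffold=name,
                start=start,
                end=start + length - 1,
                **kw,
            )
        )

    for i in range(n_mirna):
        m = int(rng.choice([20, 21, 21, 21, 22, 23, 24]))
        mature = random_seq(rng, m)
        loop = int(rng.integers(15, 61))
        expect = float(min_expected + rng.exponential(200))
        fold_dir = rng.random() < 0.5
        # genotype/stage structure: some loci genotype-exclusive, some with
        # stage-dependent fold changes
        r = rng.random()
        if r < 0.15:
            ab = (0.0, 0.0, expect, expect * 2)  # MT-exclusive
        elif r < 0.3:
            ab = (expect * 2, expect, 0.0, 0.0)  # WT-exclusive
        elif r < 0.65:
            # 4-fold stage effect; the lower stage stays at >= min_expected
            if fold_dir:
                ab = (expect, expect * 4, expect, expect * 4)
            else:
                ab = (expect * 4, expect, expect * 4, expect)
        else:
            ab = (expect, expect, expect, expect)
        place(
            "miRNA",
            f"mir{i + 1:02d}",
            2 * m + loop,
            strand="+" if rng.random() < 0.5 else "-",
            mature_seq=mature,
            loop_len=loop,
            designed_mismatches=int(rng.integers(0, 3)),
            per_library_abundance=ab,
            star_fraction=0.12,
        )
    total_mirna = sum(sum(l.per_library_abundance) / 4 for l in loci)
    # decoys: structural RNAs shedding degradation fragments (~50% of reads)
    for i, kind in enumerate(["rRNA"] * 4 + ["tRNA"] * 3 + ["snRNA"] * 2):
        place(
            kind,
            f"{kind.lower()}{i + 1:02d}",
            int(rng.integers(120, 2000)),
            per_library_abundance=(total_mirna / 9,) * 4,
        )
    for i in range(3):
        place(
            "repeat",
            f"rep{i + 1:02d}",
            int(rng.integers(200, 600)),
            per_library_abundance=(total_mirna / 30,) * 4,
        )
    for i in range(6):
        place(
            "random",
            f"rand{i + 1:02d}",
            int(rng.integers(300, 1500)),
            per_library_abundance=(total_mirna / 60,) * 4,
        )
    return loci, scaffold_lengths


# ---------------------------------------------------------------------------
# packaged novel-miRNA catalog


@dataclass(frozen=True)
class NovelMirnaRecord:
    """One published novel miRNA locus (coordinates 1-based inclusive)."""

    mirna_id: str
    scaffold: str
    start: int
    end: int
    mfe: float
    arm5: str
    arm3: str
    counts: tuple[int, int, int, int]  # WT1, WT2, MT1, MT2

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _parse_catalog_line(line: str, lineno: int) -> NovelMirnaRecord:
    parts = line.rstrip("\n").split("\t")
    if len(parts) != 9:
        raise FixtureParseError(f"line {lineno}: expected 9 fields, got {len(parts)}")
    mirna_id, location, mfe, arm5, arm3, *counts = parts
    try:
        scaffold, start, end = location.split(":")
        start, end = int(start), int(end)
        mfe_v = float(mfe)
        counts_v = tuple(int(c) for c in counts)
    except ValueError as exc:
        raise FixtureParseError(f"line {lineno}: {exc}") from None
    rec = NovelMirnaRecord(mirna_id, scaffold, start, end, mfe_v, arm5, arm3, counts_v)
    if rec.end <= rec.start:
        raise FixtureParseError(f"line {lineno}: end <= start")
    if rec.mfe >= 0:
        raise FixtureParseError(f"line {lineno}: MFE must be negative")
    if any(c < 0 for c in rec.counts):
        raise FixtureParseError(f"line {lineno}: negative count")
    return rec


def load_novel_mirna_catalog(path: str | Path | None = None) -> list[NovelMirnaRecord]:
    """Load the packaged catalog of 75 published novel miRNA loci.

    Arm sequences are stored verbatim in DNA spelling (T, not U); consumers
    convert to RNA where needed. Strand is not recorded in the source table
    and is left unset.
    """
    if path is None:
        ref = importlib.resources.files("poncirna") / "data" / "novel_mirnas.tsv"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    lines = text.splitlines()
    header = "mirna_id\tlocation\tmfe\tarm5\tarm3\twt1\twt2\tmt1\tmt2"
    if not lines or lines[0] != header:
        raise FixtureParseError("line 1: bad or missing header")
    records = [
        _parse_catalog_line(l, i) for i, l in enumerate(lines[1:], start=2) if l.strip()
    ]
    if path is None and len(records) != 75:
        raise FixtureParseError(f"expected 75 records, found {len(records)}")
    return records


def write_novel_mirna_catalog(records: list[NovelMirnaRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\tlocation\tmfe\tarm5\tarm3\twt1\twt2\tmt1\tmt2\n")
        for r in records:
            fh.write(
                f"{r.mirna_id}\t{r.scaffold}:{r.start}:{r.end}\t{r.mfe:g}\t"
                f"{r.arm5}\t{r.arm3}\t" + "\t".join(map(str, r.counts)) + "\n"
            )
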