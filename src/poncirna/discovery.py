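"""Conserved and novel miRNA discovery.

Conserved miRNAs are called by ungapped homology to a reference set of known
mature miRNAs (at most 3 mismatches), backed by a perfect genome match and a
folding precursor. Novel miRNAs are called from expressed tag clusters by
excising candidate precursor windows, folding them with the built-in engine,
and applying the community annotation criteria: a hairpin whose most
abundant 20-24 nt tag (the mature) sits on one arm, a detected star tag on
the opposite arm, a mature/star duplex with 2-nt 3' overhangs (+/-1 nt
tolerance), limited unpaired mature bases and bulge asymmetry, and a folding
energy at or below a configurable ceiling.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from ._seq import revcomp
from .fold import HairpinStructure, fold
from .mapping import TagHits
from .reads import CleanTag
from .simulate import LIBRARIES, NovelMirnaRecord

MFE_MAX_DEFAULT = -18.0  # kcal/mol
PRECURSOR_MIN = 50
PRECURSOR_MAX = 400
FLANK_DEFAULT = 250
CLUSTER_GAP = 30
MATURE_LEN_RANGE = (20, 24)
OVERHANG_TOLERANCE = 1
MAX_UNPAIRED_MATURE = 4
MAX_BULGE_ASYMMETRY = 2


# ---------------------------------------------------------------------------
# homology matching


def _overlap_mismatches(a: str, b: str) -> int:
    """Fewest mismatches over any ungapped full-overlap alignment of the
    shorter sequence inside the longer one."""
    if len(a) > len(b):
        a, b = b, a
    best = len(a)
    for off in range(len(b) - len(a) + 1):
        m = sum(x != y for x, y in zip(a, b[off : off + len(a)]))
        best = min(best, m)
    return best


def match_known(
    tag: str,
    references: list[tuple[str, str]],
    max_mismatch: int = 3,
    max_len_diff: int = 2,
) -> tuple[str, int] | None:
    """Best reference assignment for a tag, or None beyond the threshold.

    Comparison is ungapped over the aligned overlap, restricted to
    references within ``max_len_diff`` nt of the tag length. Ties on
    mismatch count go to the first reference in sorted id order.
    """
    if not references:
        raise ValueError("reference set is empty")
    from ._seq import to_dna

    tag_d = to_dna(tag)
    best: tuple[int, str] | None = None
    for ref_id, ref_seq in sorted(references):
        if abs(len(ref_seq) - len(tag_d)) > max_len_diff:
            continue
        m = _overlap_mismatches(tag_d, to_dna(ref_seq))
        if m <= max_mismatch and (best is None or m < best[0]):
            best = (m, ref_id)
    if best is None:
        return None
    return best[1], best[0]


# ---------------------------------------------------------------------------
# excision


@dataclass
class TagCluster:
    """Expressed tags whose alignments fall in one genomic neighbourhood."""

    scaffold: str
    start: int  # 0-based half-open over all member alignments
    end: int
    members: list[tuple[CleanTag, int, int, str]] = field(default_factory=list)
    # members: (tag, aln_start, aln_end, aln_strand)

    @property
    def anchor(self) -> tuple[CleanTag, int, int, str]:
        return max(self.members, key=lambda m: (m[0].total, -m[1]))


@dataclass
class CandidateWindow:
    """An excised genomic window to be folded (0-based half-open)."""

    scaffold: str
    start: int
    end: int
    strand: str
    sequence: str


def cluster_alignments(hits: list[TagHits], max_gap: int = CLUSTER_GAP) -> list[TagCluster]:
    """Group candidate tag alignments into genomic clusters.

    Alignments on the same scaffold (either strand -- a hairpin yields tags
    on one genomic strand, but candidates may fold on either) are merged
    when separated by at most ``max_gap`` nt.
    """
    placements: dict[str, list[tuple[int, int, str, CleanTag]]] = defaultdict(list)
    for h in hits:
        for a in h.alignments:
            placements[a.scaffold].append((a.start, a.end, a.strand, h.tag))
    clusters: list[TagCluster] = []
    for scaffold in sorted(placements):
        rows = sorted(placements[scaffold], key=lambda r: r[:2])
        current: TagCluster | None = None
        for start, end, strand, tag in rows:
            if current is not None and start <= current.end + max_gap:
                current.end = max(current.end, end)
                current.members.append((tag, start, end, strand))
            else:
                current = TagCluster(scaffold, start, end, [(tag, start, end, strand)])
                clusters.append(current)
    return clusters


def excise_candidates(
    clusters: list[TagCluster],
    scaffolds: dict[str, str],
    flank: int = FLANK_DEFAULT,
) -> list[CandidateWindow]:
    """Two anchored windows per strand for every cluster.

    Each cluster's most abundant tag anchors an upstream-flanked and a
    downstream-flanked window; both are emitted on both strands, clipped to
    the scaffold and to ``PRECURSOR_MAX``; windows shorter than
    ``PRECURSOR_MIN`` after clipping are dropped.
    """
    windows: list[CandidateWindow] = []
    for cl in clusters:
        tag, a_start, a_end, _ = cl.anchor
        seqlen = len(scaffolds[cl.scaffold])
        for w_start, w_end in (
            (a_start - flank, a_end + 20),
            (a_start - 20, a_end + flank),
        ):
            w_start, w_end = max(0, w_start), min(seqlen, w_end)
            if w_end - w_start > PRECURSOR_MAX:
                w_end = w_start + PRECURSOR_MAX
            if w_end - w_start < PRECURSOR_MIN:
                continue
            plus = scaffolds[cl.scaffold][w_start:w_end].upper()
            for strand, seq in (("+", plus), ("-", revcomp(plus))):
                windows.append(
                    CandidateWindow(cl.scaffold, w_start, w_end, strand, seq)
                )
    return windows


# ---------------------------------------------------------------------------
# hairpin validation


@dataclass
class PlacedTag:
    """A tag located inside a candidate window (window coordinates)."""

    tag: CleanTag
    start: int
    end: int


@dataclass
class NovelCandidate:
    """An accepted novel miRNA call."""

    mature: CleanTag
    star: CleanTag
    scaffold: str
    start: int  # 1-based inclusive precursor interval
    end: int
    strand: str
    structure: HairpinStructure
    mfe: float
    mirna_id: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Rejection:
    reason: str
    detail: str = ""


def _duplex_geometry(partner, mature: PlacedTag, star: PlacedTag):
    """Check the mature/star duplex inferred from the pairing.

    In a clean antiparallel duplex i + partner(i) is constant (the duplex
    *register*); the canonical 2-nt 3' overhangs fix that constant relative
    to the two tag intervals. The register is estimated as the median of
    i + partner(i) over mature bases pairing into the star interval, which
    tolerates helix drift at the duplex ends in the minimum-energy fold.
    Pairs more than MAX_BULGE_ASYMMETRY off the register are treated as
    outside the duplex.

    Returns (ok, reason, register).
    """
    a, b = mature.start, mature.end
    c, d = star.start, star.end
    pairs_in = [
        (i, partner[i])
        for i in range(a, b)
        if partner[i] is not None and c - 2 <= partner[i] < d + 2
    ]
    if not pairs_in:
        return False, "duplex_pairing", None
    registers = sorted(i + j for i, j in pairs_in)
    r = registers[len(registers) // 2]
    good = [i for i, j in pairs_in if abs(i + j - r) <= MAX_BULGE_ASYMMETRY]
    # unpaired mature bases within the duplex (3' overhang positions excluded)
    unpaired = sum(1 for i in range(a, b - 2) if i not in good)
    if unpaired > MAX_UNPAIRED_MATURE:
        return False, "duplex_pairing", None
    # projected 3' overhangs: star 3' end beyond the partner of mature[a],
    # mature 3' end beyond the partner row of star[c]
    overhang_star = (d - 1) - (r - a)
    overhang_mature = c - (r - (b - 1))
    tol = OVERHANG_TOLERANCE
    if not (2 - tol <= overhang_star <= 2 + tol) or not (
        2 - tol <= overhang_mature <= 2 + tol
    ):
        return False, "overhang", None
    spread = max(i + partner[i] for i in good) - min(i + partner[i] for i in good)
    if spread > MAX_BULGE_ASYMMETRY:
        return False, "asymmetry", None
    return True, "", r


def validate_hairpin(
    structure: HairpinStructure,
    placed: list[PlacedTag],
    mfe_max: float = MFE_MAX_DEFAULT,
    mature_len_range: tuple[int, int] = MATURE_LEN_RANGE,
):
    """Apply the annotation criteria to a folded window with expressed tags.

    Returns ``(mature, star, (lo, hi))`` with the precursor span in window
    coordinates on acceptance, or a :class:`Rejection` naming the first
    failed criterion.
    """
    if not placed:
        return Rejection("unsupported", "no expressed tag in window")
    lo_len, hi_len = mature_len_range
    supported = sorted(placed, key=lambda p: (-p.tag.total, p.start))
    mature = next((p for p in supported if lo_len <= len(p.tag.sequence) <= hi_len), None)
    if mature is None:
        return Rejection("mature_length", "no 20-24 nt tag in window")
    if structure.mfe > mfe_max:
        return Rejection("mfe", f"{structure.mfe:.2f} > {mfe_max:.2f}")
    partner = structure.partner()
    star_candidates = [
        p
        for p in supported
        if p is not mature
        and (p.end <= mature.start or p.start >= mature.end)
    ]
    if not star_candidates:
        return Rejection("no_star", "no tag on the opposite arm")
    last_reason = "no_star"
    for cand in star_candidates:
        ok, reason, _ = _duplex_geometry(partner, mature, cand)
        if ok:
            lo = min(mature.start, cand.start)
            hi = max(mature.end, cand.end)
            # extend outward along the closing stem
            outer_pairs = [
                (i, partner[i])
                for i in range(mature.start, mature.end)
                if partner[i] is not None
            ]
            if outer_pairs:
                i, j = min(outer_pairs, key=lambda ij: ij[0])
                o, q = min(i, j), max(i, j)
                while o - 1 >= 0 and q + 1 < len(partner) and partner[o - 1] == q + 1:
                    o, q = o - 1, q + 1
                lo, hi = min(lo, o), max(hi, q + 1)
            if not (PRECURSOR_MIN <= hi - lo <= PRECURSOR_MAX):
                last_reason = "precursor_length"
                continue
            return mature, cand, (lo, hi)
        last_reason = reason
    return Rejection(last_reason)


# ---------------------------------------------------------------------------
# novel discovery driver


def _tags_in_window(
    all_hits: list[TagHits], window: CandidateWindow
) -> list[PlacedTag]:
    """Every candidate tag whose alignment falls fully inside the window on
    the window's strand -- regardless of which cluster anchored the window,
    since the opposite arm of a hairpin is usually a separate cluster."""
    placed = []
    for h in all_hits:
        for a in h.alignments:
            if (
                a.scaffold == window.scaffold
                and a.start >= window.start
                and a.end <= window.end
                and a.strand == window.strand
            ):
                if window.strand == "+":
                    s, e = a.start - window.start, a.end - window.start
                else:
                    s, e = window.end - a.end, window.end - a.start
                placed.append(PlacedTag(h.tag, s, e))
    return placed


def discover_novel(
    hits: list[TagHits],
    scaffolds: dict[str, str],
    flank: int = FLANK_DEFAULT,
    mfe_max: float = MFE_MAX_DEFAULT,
    min_read_support: int = 1,
) -> tuple[list[NovelCandidate], dict[str, int]]:
    """Full novel-miRNA discovery from candidate tag hits.

    Clusters expressed alignments, excises and folds candidate windows,
    validates hairpins, and deduplicates accepted calls by mature sequence
    (keeping the lowest-energy precursor). Returns the accepted candidates
    (ids assigned in genomic order) and a tally of rejection reasons.
    """
    hits = [h for h in hits if h.tag.total >= min_read_support]
    clusters = cluster_alignments(hits)
    rejections: dict[str, int] = defaultdict(int)
    accepted: dict[str, NovelCandidate] = {}
    for cl in clusters:
        for window in excise_candidates([cl], scaffolds, flank=flank):
            placed = _tags_in_window(hits, window)
            if not placed:
                rejections["unsupported"] += 1
                continue
            structure = fold(window.sequence)
            result = validate_hairpin(structure, placed, mfe_max=mfe_max)
            if isinstance(result, Rejection):
                rejections[result.reason] += 1
                continue
            mature, star, (lo, hi) = result
            if window.strand == "+":
                g_lo, g_hi = window.start + lo, window.start + hi
            else:
                g_lo, g_hi = window.end - hi, window.end - lo
            cand = NovelCandidate(
                mature=mature.tag,
                star=star.tag,
                scaffold=window.scaffold,
                start=g_lo + 1,
                end=g_hi,
                strand=window.strand,
                structure=structure,
                mfe=structure.mfe,
            )
            key = mature.tag.sequence
            if key not in accepted or cand.mfe < accepted[key].mfe:
                accepted[key] = cand
    # one call per genomic locus: a hairpin read in reverse complement is
    # also a hairpin, so the same locus can validate on both strands with
    # the arms swapped; keep the call with the more abundant mature
    keep: list[NovelCandidate] = []
    for cand in sorted(
        accepted.values(), key=lambda c: (-c.mature.total, c.mfe, c.scaffold, c.start)
    ):
        if not any(
            k.scaffold == cand.scaffold and k.start <= cand.end and cand.start <= k.end
            for k in keep
        ):
            keep.append(cand)
    calls = sorted(keep, key=lambda c: (c.scaffold, c.start, c.strand))
    for i, c in enumerate(calls, 1):
        c.mirna_id = f"Novel{i:02d}"
    return calls, dict(rejections)


# ---------------------------------------------------------------------------
# conserved calls and the composed catalog


@dataclass
class ConservedCall:
    tag: CleanTag
    reference_id: str
    mismatches: int
    cls: str = "conserved"  # or "known_specific"


def call_conserved(
    hits: list[TagHits],
    references: list[tuple[str, str]],
    scaffolds: dict[str, str] | None = None,
    max_mismatch: int = 3,
    mfe_max: float = MFE_MAX_DEFAULT,
    cls: str = "conserved",
) -> list[ConservedCall]:
    """Homology calls against a known-miRNA reference set.

    A call requires a reference match within ``max_mismatch`` substitutions
    plus, when a genome is supplied, a perfect genome alignment whose
    flanking window folds into a hairpin at or below ``mfe_max``.
    """
    calls = []
    for h in hits:
        m = match_known(h.tag.sequence, references, max_mismatch=max_mismatch)
        if m is None:
            continue
        if scaffolds is not None:
            perfect = [a for a in h.alignments if a.mismatches == 0]
            if not perfect:
                continue
            folds = False
            for a in perfect[:4]:
                seq = scaffolds[a.scaffold]
                lo = max(0, a.start - 100)
                hi = min(len(seq), a.end + 100)
                window = seq[lo:hi].upper()
                if a.strand == "-":
                    window = revcomp(window)
                if fold(window).mfe <= mfe_max:
                    folds = True
                    break
            if not folds:
                continue
        calls.append(ConservedCall(h.tag, m[0], m[1], cls=cls))
    return calls


@dataclass
class MiRNARecord:
    mirna_id: str
    cls: str  # conserved | known_specific | novel
    family: str
    mature: str
    counts: dict[str, int]
    star: str | None = None
    precursor: tuple[str, int, int, str] | None = None  # scaffold, start, end, strand
    mismatches_to_reference: int | None = None
    is_star: bool = False


_FAMILY_RE = re.compile(r"(?i)mir[-]?0*(\d+)")


def family_of(reference_id: str) -> str:
    """Family label from a reference id: species prefix and variant suffix
    letters are stripped (csi-miR166e -> miR166); star records keep the
    family of their mature strand."""
    m = _FAMILY_RE.search(reference_id)
    if m:
        return f"miR{m.group(1)}"
    return reference_id.rstrip("*").rstrip("abcdefghij")


def compose_catalog(
    conserved: list[ConservedCall],
    novel: list[NovelCandidate],
) -> list[MiRNARecord]:
    """Merge conserved/known-specific and novel calls into one catalog.

    Calls are deduplicated by mature sequence; when the same mature is both
    a homology call and a novel call, the homology (conserved) call wins.
    Families group reference variants (miR166a/miR166e -> miR166); novel ids
    are kept as assigned in discovery order.
    """
    records: dict[str, MiRNARecord] = {}
    for c in conserved:
        seq = c.tag.sequence
        if seq in records:
            continue
        records[seq] = MiRNARecord(
            mirna_id=c.reference_id,
            cls=c.cls,
            family=family_of(c.reference_id),
            mature=seq,
            counts=dict(c.tag.counts),
            mismatches_to_reference=c.mismatches,
            is_star=c.reference_id.endswith("*"),
        )
    for n in novel:
        seq = n.mature.sequence
        if seq in records:
            import warnings

            warnings.warn(
                f"{n.mirna_id}: mature sequence already called "
                f"{records[seq].mirna_id}; conserved call wins"
            )
            continue
        records[seq] = MiRNARecord(
            mirna_id=n.mirna_id,
            cls="novel",
            family=n.mirna_id,
            mature=seq,
            counts=dict(n.mature.counts),
            star=n.star.sequence,
            precursor=(n.scaffold, n.start, n.end, n.strand),
        )
    return list(records.values())


# ---------------------------------------------------------------------------
# summaries and exports


def summarize_precursors(records) -> dict[str, float]:
    """Length and MFE summary over precursor records.

    Accepts any records exposing ``length`` (from 1-based inclusive
    coordinates) and ``mfe`` attributes, e.g. the packaged novel-miRNA
    catalog or accepted :class:`NovelCandidate` calls.
    """
    records = list(records)
    if not records:
        raise ValueError("empty record set")
    lengths = [r.length for r in records]
    mfes = [r.mfe for r in records]
    return {
        "count": len(records),
        "length_min": min(lengths),
        "length_max": max(lengths),
        "length_mean": sum(lengths) / len(lengths),
        "mfe_min": min(mfes),
        "mfe_max": max(mfes),
        "mfe_mean": sum(mfes) / len(mfes),
    }


def catalog_counts(records: list[NovelMirnaRecord]):
    """Per-library count matrix for the packaged catalog."""
    import pandas as pd

    return pd.DataFrame(
        [r.counts for r in records],
        index=[r.mirna_id for r in records],
        columns=list(LIBRARIES),
    )


def load_mature_reference(path: str | Path) -> list[tuple[str, str]]:
    """Mature reference FASTA (miRBase dialect: id then free description;
    U spelling accepted)."""
    from Bio import SeqIO

    refs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        refs.append((rec.id, str(rec.seq).upper().replace("U", "T")))
    if not refs:
        raise ValueError(f"no sequences in {path}")
    return refs


def write_catalog_tsv(records: list[MiRNARecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "mirna_id\tclass\tfamily\tmature\tstar\tprecursor\tmismatches\t"
            + "\t".join(LIBRARIES)
            + "\n"
        )
        for r in records:
            prec = (
                f"{r.precursor[0]}:{r.precursor[1]}:{r.precursor[2]}:{r.precursor[3]}"
                if r.precursor
                else "."
            )
            fh.write(
                f"{r.mirna_id}\t{r.cls}\t{r.family}\t{r.mature}\t"
                f"{r.star or '.'}\t{prec}\t"
                f"{'' if r.mismatches_to_reference is None else r.mismatches_to_reference}\t"
                + "\t".join(str(r.counts.get(lib, 0)) for lib in LIBRARIES)
                + "\n"
            )


def write_precursor_gff3(novel: list[NovelCandidate], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for n in novel:
            fh.write(
                f"{n.scaffold}\tponcirna\tmiRNA_primary_transcript\t{n.start}\t"
                f"{n.end}\t.\t{n.strand}\t.\tID={n.mirna_id}\n"
            )


def write_structures(novel: list[NovelCandidate], path: str | Path) -> None:
    """Dot-bracket text export of accepted precursor windows."""
    with open(path, "w") as fh:
        for n in novel:
            fh.write(f">{n.mirna_id} {n.scaffold}:{n.start}:{n.end}({n.strand})\n")
            fh.write(n.structure.sequence + "\n")
            fh.write(f"{n.structure.pairing} ({n.mfe:.2f})\n")
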