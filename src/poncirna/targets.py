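"""Complementarity-based miRNA target prediction on transcripts.

Every transcript window the length of the miRNA is scored position by
position against the miRNA (antiparallel, no gaps): Watson-Crick pairs are
free, G:U wobbles cost 0.5, mismatches 1.0. A window is an accepted target
site when the total penalty is at most 2 and the positional mismatch rules
hold: at most one mismatch opposite miRNA positions 2-11, none at the
cleavage site (positions 10-11), at most three in positions 12-21 with no
more than two consecutive, and at most four mismatches overall. Positions
count from the miRNA 5' end (position 1). Accepted sites are labelled
5'UTR / ORF / 3'UTR by their midpoint and annotated with a duplex energy
from the folding module's pair-stacking model, reported alongside the ratio
to the perfect-duplex energy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ._seq import revcomp, to_dna

PENALTY_MAX = 2.0
_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}
_STACK_E = {("A", "T"): -2.0, ("T", "A"): -2.0, ("G", "C"): -3.0, ("C", "G"): -3.0,
            ("G", "T"): -1.0, ("T", "G"): -1.0}


@dataclass
class TargetAlignment:
    """Scored miRNA/site duplex.

    ``pattern`` is indexed from miRNA position 1 (5' end): '|' Watson-Crick
    pair, 'o' G:U wobble, 'x' mismatch. ``site`` is the transcript window in
    its 5'->3' orientation; the duplex itself is antiparallel (miRNA
    position i faces site position L-1-i).
    """

    mirna: str
    site: str
    pattern: str
    penalty: float


@dataclass
class TargetSite:
    mirna_id: str
    transcript_id: str
    start: int  # 0-based half-open on the transcript
    end: int
    region: str  # 5'UTR | ORF | 3'UTR
    alignment: TargetAlignment
    delta_g: float
    energy_ratio: float


def score_site(mirna: str, site: str) -> TargetAlignment:
    """Score one window against a miRNA (both given 5'->3', equal length)."""
    mirna_d, site_d = to_dna(mirna), to_dna(site)
    if len(mirna_d) != len(site_d):
        raise ValueError("site and miRNA must have equal length")
    n = len(mirna_d)
    pattern = []
    penalty = 0.0
    for i in range(n):
        pair = (mirna_d[i], site_d[n - 1 - i])
        if pair in _WC:
            pattern.append("|")
        elif pair in _WOBBLE:
            pattern.append("o")
            penalty += 0.5
        else:
            pattern.append("x")
            penalty += 1.0
    return TargetAlignment(mirna_d, site_d, "".join(pattern), penalty)


def positional_constraints(
    alignment: TargetAlignment, penalty_max: float = PENALTY_MAX
) -> tuple[bool, str]:
    """Accept/reject a scored alignment under the positional mismatch rules.

    Position 1 is the miRNA 5' nucleotide. The 2-12 and 12-21 windows
    overlap at 12 in their usual statement; position 12 is assigned to the
    12-21 regime here and excluded from the 2-12 count.
    """
    p = alignment.pattern
    n = len(p)
    if alignment.penalty > penalty_max:
        return False, "penalty"
    x_at = [i + 1 for i, ch in enumerate(p) if ch == "x"]  # 1-based positions
    if any(pos in (10, 11) for pos in x_at):
        return False, "cleavage site"
    if sum(1 for pos in x_at if 2 <= pos <= 11) > 1:
        return False, "5' region mismatches"
    tail = [pos for pos in x_at if 12 <= pos <= min(21, n)]
    if len(tail) > 3:
        return False, "3' region mismatches"
    run = 0
    for pos in range(12, min(21, n) + 1):
        if pos <= n and p[pos - 1] == "x":
            run += 1
            if run > 2:
                return False, "consecutive"
        else:
            run = 0
    if len(x_at) > 4:
        return False, "total mismatches"
    return True, ""


def duplex_energy(alignment: TargetAlignment) -> tuple[float, float]:
    """Hybridisation energy of the duplex and its ratio to a perfect duplex.

    Uses the folding module's stacking model: a paired position ('|' or 'o')
    contributes its pair's stacking energy when the preceding position is
    also paired. The ratio dG(site)/dG(perfect) is 1 for a perfect
    complement, 0 when nothing stacks, and never increases as pairs are
    lost.
    """
    n = len(alignment.mirna)

    def energy(pattern: str, site: str) -> float:
        e = 0.0
        for i in range(1, n):
            if pattern[i] != "x" and pattern[i - 1] != "x":
                pair = (alignment.mirna[i], site[n - 1 - i])
                e += _STACK_E.get(pair, 0.0)
        return e

    dg = energy(alignment.pattern, alignment.site)
    perfect_site = revcomp(alignment.mirna)
    dg_perfect = energy("|" * n, perfect_site)
    ratio = dg / dg_perfect if dg_perfect < 0 else 0.0
    return dg, ratio


def _region_of(midpoint: int, utr5_end: int | None, utr3_start: int | None) -> str:
    if utr5_end is not None and midpoint < utr5_end:
        return "5'UTR"
    if utr3_start is not None and midpoint >= utr3_start:
        return "3'UTR"
    return "ORF"


def scan_transcript(
    mirna_id: str,
    mirna: str,
    transcript_id: str,
    transcript: str,
    utr5_end: int | None = None,
    utr3_start: int | None = None,
    penalty_max: float = PENALTY_MAX,
) -> list[TargetSite]:
    """All accepted target sites of one miRNA on one transcript.

    ``utr5_end`` / ``utr3_start`` are 0-based transcript offsets of the
    ORF boundaries (end of the 5'UTR, start of the 3'UTR); when absent all
    sites are labelled ORF with a warning. Multiple sites per transcript
    are allowed.
    """
    mirna_d, tr = to_dna(mirna), to_dna(transcript)
    L = len(mirna_d)
    if len(tr) < L:
        raise ValueError("transcript shorter than the miRNA")
    if utr5_end is None and utr3_start is None:
        warnings.warn(
            f"{transcript_id}: no UTR annotation; labelling all sites ORF"
        )
    sites = []
    for s in range(len(tr) - L + 1):
        aln = score_site(mirna_d, tr[s : s + L])
        ok, _ = positional_constraints(aln, penalty_max=penalty_max)
        if not ok:
            continue
        dg, ratio = duplex_energy(aln)
        mid = s + L // 2
        sites.append(
            TargetSite(
                mirna_id=mirna_id,
                transcript_id=transcript_id,
                start=s,
                end=s + L,
                region=_region_of(mid, utr5_end, utr3_start),
                alignment=aln,
                delta_g=dg,
                energy_ratio=ratio,
            )
        )
    return sites


def load_transcripts(
    fasta_path: str | Path, gff3_path: str | Path | None = None
) -> dict[str, tuple[str, int | None, int | None]]:
    """Transcripts with ORF boundaries in transcript coordinates.

    The GFF3 is expected to annotate five_prime_UTR / CDS / three_prime_UTR
    features whose seqid is the transcript id.
    """
    from Bio import SeqIO

    seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    bounds: dict[str, list[int | None]] = {tid: [None, None] for tid in seqs}
    if gff3_path is not None:
        from .mapping import load_annotation

        for f in load_annotation(gff3_path):
            if f.scaffold not in bounds:
                continue
            if f.ftype == "five_prime_UTR":
                b = bounds[f.scaffold]
                b[0] = f.end if b[0] is None else max(b[0], f.end)
            elif f.ftype == "three_prime_UTR":
                b = bounds[f.scaffold]
                b[1] = f.start if b[1] is None else min(b[1], f.start)
    return {tid: (seq, bounds[tid][0], bounds[tid][1]) for tid, seq in seqs.items()}


def scan_transcriptome(
    mirnas: dict[str, str],
    transcripts: dict[str, tuple[str, int | None, int | None]],
    penalty_max: float = PENALTY_MAX,
) -> list[TargetSite]:
    sites = []
    for mid in sorted(mirnas):
        for tid in sorted(transcripts):
            seq, u5, u3 = transcripts[tid]
            if len(seq) < len(mirnas[mid]):
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sites.extend(
                    scan_transcript(
                        mid, mirnas[mid], tid, seq, u5, u3, penalty_max=penalty_max
                    )
                )
    return sites


def aggregate_targets(sites: list[TargetSite]) -> dict[str, pd.DataFrame | int]:
    """Per-gene and per-miRNA roll-ups of accepted sites."""
    df = sites_to_frame(sites)
    if df.empty:
        empty = pd.DataFrame()
        return {
            "sites_per_gene": empty,
            "genes_per_mirna": empty,
            "multi_site_genes": 0,
            "multi_mirna_genes": 0,
            "total_sites": 0,
            "total_genes": 0,
        }
    sites_per_gene = df.groupby("transcript_id").size().sort_values(ascending=False)
    genes_per_mirna = (
        df.groupby("mirna_id")["transcript_id"].nunique().sort_values(ascending=False)
    )
    mirnas_per_gene = df.groupby("transcript_id")["mirna_id"].nunique()
    return {
        "sites_per_gene": sites_per_gene.to_frame("sites"),
        "genes_per_mirna": genes_per_mirna.to_frame("genes"),
        "multi_site_genes": int((sites_per_gene >= 2).sum()),
        "multi_mirna_genes": int((mirnas_per_gene >= 2).sum()),
        "total_sites": int(len(df)),
        "total_genes": int(df["transcript_id"].nunique()),
    }


def sites_to_frame(sites: list[TargetSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": s.mirna_id,
                "transcript_id": s.transcript_id,
                "start": s.start,
                "end": s.end,
                "region": s.region,
                "pattern": s.alignment.pattern,
                "penalty": s.alignment.penalty,
                "delta_g": s.delta_g,
                "energy_ratio": s.energy_ratio,
            }
            for s in sites
        ]
    )
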