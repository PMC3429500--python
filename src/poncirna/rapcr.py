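"""Regional-amplification qPCR (RA-PCR) cleavage-evidence analysis.

After miRNA-guided cleavage only the 3' fragment of a target mRNA retains
the poly(A) tail, so oligo(dT)-primed cDNA under-represents regions at and
upstream of the cleavage site. Three amplicons per transcript (5', middle --
spanning the predicted target site -- and 3') are compared as relative
quantities; depletion of the middle amplicon relative to the 3' amplicon
across all assayed samples supports cleavage. Quantities are expected
post-normalisation (relative to a reference gene); raw Cq processing is out
of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

SUPPORT_THRESHOLD = 0.6


@dataclass
class RegionQuant:
    """Relative amplicon quantities for one transcript in one sample.

    ``q5`` may be None when the target site lies in the 5'UTR and no
    upstream amplicon exists.
    """

    transcript_id: str
    sample_id: str
    q5: float | None
    qmid: float
    q3: float

    def __post_init__(self) -> None:
        for v in (self.q5, self.qmid, self.q3):
            if v is not None and v < 0:
                raise ValueError("quantities must be non-negative")


def region_ratios(quant: RegionQuant) -> dict[str, float]:
    """middle/3' (and, when measured, 5'/3') amplicon ratios."""
    if quant.q3 <= 0:
        raise ValueError(
            f"{quant.transcript_id}/{quant.sample_id}: 3' quantity must be > 0"
        )
    out = {"mid_3p": quant.qmid / quant.q3}
    if quant.q5 is not None:
        out["5p_3p"] = quant.q5 / quant.q3
    return out


@dataclass
class CleavageCall:
    transcript_id: str
    supported: bool
    ratio_min: float
    ratio_max: float
    n_samples: int


def cleavage_call(
    quants: list[RegionQuant], threshold: float = SUPPORT_THRESHOLD
) -> list[CleavageCall]:
    """Per-transcript cleavage support over all assayed samples.

    A transcript is supported when the middle/3' ratio is below
    ``threshold`` in every provided sample; the observed min-max ratio
    range is reported either way.
    """
    if not quants:
        raise ValueError("at least one sample is required")
    by_transcript: dict[str, list[float]] = {}
    for q in quants:
        by_transcript.setdefault(q.transcript_id, []).append(
            region_ratios(q)["mid_3p"]
        )
    calls = []
    for tid in sorted(by_transcript):
        ratios = by_transcript[tid]
        calls.append(
            CleavageCall(
                transcript_id=tid,
                supported=all(r < threshold for r in ratios),
                ratio_min=min(ratios),
                ratio_max=max(ratios),
                n_samples=len(ratios),
            )
        )
    return calls


def read_quants_tsv(path: str | Path) -> list[RegionQuant]:
    """TSV columns: transcript, sample, q5, qmid, q3 ('' or NA for a
    missing 5' amplicon)."""
    df = pd.read_csv(path, sep="\t")
    quants = []
    for _, row in df.iterrows():
        q5 = row["q5"]
        q5 = None if pd.isna(q5) else float(q5)
        quants.append(
            RegionQuant(
                str(row["transcript"]), str(row["sample"]), q5,
                float(row["qmid"]), float(row["q3"]),
            )
        )
    return quants


def write_calls_tsv(calls: list[CleavageCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript\tsupported\tratio_min\tratio_max\tn_samples\n")
        for c in calls:
            fh.write(
                f"{c.transcript_id}\t{str(c.supported).lower()}\t"
                f"{c.ratio_min:.4g}\t{c.ratio_max:.4g}\t{c.n_samples}\n"
            )
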