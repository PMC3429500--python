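"""Four-library expression profiling of miRNAs.

Counts are compared between the juvenile (stage 1) and adult (stage 2)
libraries of each genotype. Two framings coexist, as both are standard:
a strict up/down census on raw count comparison, and a two-fold
differential flag on the RPM ratio (ratio > 2 or < 0.5). Detection in one
stage only yields a stage-only class instead of an infinite ratio; both
stages at zero is "absent". Presence/absence across genotypes and inverse
regulation between genotypes are derived set operations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import LIBRARIES

GENOTYPE_STAGES = {"WT": ("WT1", "WT2"), "MT": ("MT1", "MT2")}


@dataclass
class ExpressionMatrix:
    """Raw counts (rows: miRNA ids, columns: WT1, WT2, MT1, MT2) plus
    library sizes; RPM is derived on demand."""

    counts: pd.DataFrame
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.reindex(columns=list(LIBRARIES))
        if (self.counts.fillna(0) < 0).any().any():
            raise ValueError("negative counts")
        self.counts = self.counts.fillna(0).astype(int)
        self.library_sizes = self.library_sizes.reindex(list(LIBRARIES))

    @property
    def rpm(self) -> pd.DataFrame:
        return normalize_rpm(self)


def normalize_rpm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Reads-per-million: count * 1e6 / library size, per library."""
    sizes = matrix.library_sizes
    if (sizes <= 0).any() or sizes.isna().any():
        raise ValueError("library sizes must be positive")
    return matrix.counts * 1e6 / sizes


@dataclass
class RegulationCall:
    mirna_id: str
    genotype: str
    direction: str  # up | down | unchanged | stage1-only | stage2-only | absent
    ratio: float | None  # stage2/stage1 on RPM; None for stage-only/absent
    differential: bool


def regulation_call(
    mirna_id: str,
    genotype: str,
    count1: int,
    count2: int,
    rpm1: float,
    rpm2: float,
    fold: float = 2.0,
) -> RegulationCall:
    """Stage-2 vs stage-1 regulation for one miRNA in one genotype.

    Direction follows the strict raw-count comparison (down if stage2 <
    stage1, up if greater, unchanged if equal); the ``differential`` flag
    applies the fold-change rule to the RPM ratio. Zero in exactly one stage
    gives a stage-only class (differential by definition); zero in both is
    "absent".
    """
    if count1 < 0 or count2 < 0:
        raise ValueError("negative counts")
    if count1 == 0 and count2 == 0:
        return RegulationCall(mirna_id, genotype, "absent", None, False)
    if count1 == 0:
        return RegulationCall(mirna_id, genotype, "stage2-only", None, True)
    if count2 == 0:
        return RegulationCall(mirna_id, genotype, "stage1-only", None, True)
    ratio = rpm2 / rpm1
    if count2 < count1:
        direction = "down"
    elif count2 > count1:
        direction = "up"
    else:
        direction = "unchanged"
    differential = ratio > fold or ratio < 1.0 / fold
    return RegulationCall(mirna_id, genotype, direction, ratio, differential)


def genotype_calls(
    matrix: ExpressionMatrix, genotype: str, fold: float = 2.0
) -> list[RegulationCall]:
    lib1, lib2 = GENOTYPE_STAGES[genotype]
    rpm = matrix.rpm
    return [
        regulation_call(
            str(idx),
            genotype,
            int(matrix.counts.at[idx, lib1]),
            int(matrix.counts.at[idx, lib2]),
            float(rpm.at[idx, lib1]),
            float(rpm.at[idx, lib2]),
            fold=fold,
        )
        for idx in matrix.counts.index
    ]


def presence_pattern(counts: pd.DataFrame) -> dict[str, set[str]]:
    """Partition rows into MT-only / WT-only / shared / absent sets.

    MT-only: zero in both WT libraries, detected in at least one MT library;
    WT-only symmetric; shared: detected in both genotypes; absent: zero
    everywhere.
    """
    counts = counts.reindex(columns=list(LIBRARIES)).fillna(0)
    wt = counts["WT1"] + counts["WT2"]
    mt = counts["MT1"] + counts["MT2"]
    out = {
        "MT-only": set(counts.index[(wt == 0) & (mt > 0)].astype(str)),
        "WT-only": set(counts.index[(mt == 0) & (wt > 0)].astype(str)),
        "shared": set(counts.index[(mt > 0) & (wt > 0)].astype(str)),
        "absent": set(counts.index[(mt == 0) & (wt == 0)].astype(str)),
    }
    return out


def inverse_pattern(
    calls_mt: list[RegulationCall], calls_wt: list[RegulationCall]
) -> set[str]:
    """Ids regulated in opposite directions in the two genotypes.

    Only strict up/down directions participate; stage-only, unchanged and
    absent calls are excluded.
    """
    mt = {c.mirna_id: c.direction for c in calls_mt}
    wt = {c.mirna_id: c.direction for c in calls_wt}
    out = set()
    for mid, d_mt in mt.items():
        d_wt = wt.get(mid)
        if {d_mt, d_wt} == {"up", "down"}:
            out.add(mid)
    return out


def regulation_census(calls: list[RegulationCall]) -> dict[str, int]:
    """Counts of calls per direction plus the differential total."""
    out: dict[str, int] = {}
    for c in calls:
        out[c.direction] = out.get(c.direction, 0) + 1
    out["differential"] = sum(1 for c in calls if c.differential)
    return out


def clustering_export(matrix: ExpressionMatrix) -> pd.DataFrame:
    """log2(RPM + 1) matrix for external heatmap/clustering tools."""
    return np.log2(matrix.rpm + 1.0)


def calls_to_frame(calls: list[RegulationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": c.mirna_id,
                "genotype": c.genotype,
                "direction": c.direction,
                "ratio": c.ratio,
                "differential": c.differential,
            }
            for c in calls
        ]
    )
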