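"""MIMAG quality tiers and basic assembly statistics.

Completeness and contamination arrive as metadata (CheckM-style estimates);
this module only applies the MIMAG tier rules, all with strict inequalities:

* high quality (HQ): completeness > 90%, contamination < 5%, all three rRNA
  genes (5S, 16S, 23S) present, and ≥ 18 tRNA genes;
* medium quality (MQ): completeness > 50% and contamination < 10%;
* low quality (LQ): everything else.

"Almost complete" (> 90% completeness and < 5% contamination) is tracked
separately: an HQ genome is always almost complete, but an almost-complete
genome missing an rRNA gene is only MQ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

HQ, MQ, LQ = "HQ", "MQ", "LQ"


@dataclass(frozen=True)
class QualityRecord:
    """Per-genome quality metadata consumed from upstream estimators."""

    completeness: float
    contamination: float
    rrna_5s: bool = False
    rrna_16s: bool = False
    rrna_23s: bool = False
    trna_count: int = 0
    n50: int = 0
    gc: float | None = None
    total_length: int | None = None
    contig_count: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.completeness <= 100:
            raise ValueError(f"completeness {self.completeness} outside [0, 100]")
        if not 0 <= self.contamination <= 100:
            raise ValueError(f"contamination {self.contamination} outside [0, 100]")
        if self.trna_count < 0:
            raise ValueError("tRNA count must be non-negative")


@dataclass(frozen=True)
class Tier:
    tier: str  # HQ | MQ | LQ
    almost_complete: bool

    def __post_init__(self) -> None:
        if self.tier == HQ and not self.almost_complete:
            raise ValueError("HQ implies almost_complete")


def is_almost_complete(q: QualityRecord) -> bool:
    """Strict: completeness > 90 and contamination < 5; 90.0/5.0 fail."""
    return q.completeness > 90 and q.contamination < 5


def classify_tier(q: QualityRecord) -> Tier:
    """Assign the MIMAG tier for one quality record (total function)."""
    almost = is_almost_complete(q)
    if (
        almost
        and q.rrna_5s
        and q.rrna_16s
        and q.rrna_23s
        and q.trna_count >= 18
    ):
        return Tier(HQ, True)
    if q.completeness > 50 and q.contamination < 10:
        return Tier(MQ, almost)
    return Tier(LQ, almost)


def classify_table(metadata: pd.DataFrame) -> pd.DataFrame:
    """Append ``tier`` and ``almost_complete`` (0/1) columns to a metadata table."""
    out = metadata.copy()
    tiers, almost = [], []
    for r in metadata.itertuples():
        t = classify_tier(
            QualityRecord(
                completeness=float(r.completeness),
                contamination=float(r.contamination),
                rrna_5s=bool(r.rrna_5s),
                rrna_16s=bool(r.rrna_16s),
                rrna_23s=bool(r.rrna_23s),
                trna_count=int(r.trna_count),
            )
        )
        tiers.append(t.tier)
        almost.append(int(t.almost_complete))
    out["tier"] = tiers
    out["almost_complete"] = almost
    return out


def assembly_stats(contigs: list[str]) -> dict[str, float | int]:
    """N50, GC fraction, total length, and contig count for one assembly.

    N50 is the smallest length among the longest contigs whose cumulative
    length reaches half of the total. GC excludes ambiguous (non-ACGT) bases
    from the denominator.
    """
    if not contigs:
        raise ValueError("empty contig set")
    lengths = np.sort(np.array([len(c) for c in contigs]))[::-1]
    total = int(lengths.sum())
    cum = np.cumsum(lengths)
    n50 = int(lengths[np.searchsorted(cum, total / 2.0)])
    gc = at = 0
    for c in contigs:
        arr = np.frombuffer(c.upper().encode("ascii"), dtype=np.uint8)
        gc += int(np.count_nonzero((arr == ord("G")) | (arr == ord("C"))))
        at += int(np.count_nonzero((arr == ord("A")) | (arr == ord("T"))))
    denom = gc + at
    return {
        "n50": n50,
        "gc": gc / denom if denom else float("nan"),
        "total_length": total,
        "contig_count": len(contigs),
    }
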