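"""Cohort-style summary arithmetic.

All percentages are 100·part/whole rounded half-up to two decimals (matching
conventional reporting precision); full-precision counts are always kept so
every printed fraction is recomputable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 → 0.01), unlike Python's bankers rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(part: int | float, whole: int | float, ndigits: int = 2) -> float:
    """100·part/whole, rounded half-up."""
    if whole <= 0:
        raise ValueError("denominator must be positive")
    if part < 0:
        raise ValueError("part must be non-negative")
    return round_half_up(100.0 * part / whole, ndigits)


@dataclass
class CohortSummary:
    """Headline counts and derived percentages for a MAG cohort."""

    n_mags: int
    n_samples: int
    n_almost_complete: int
    n_species: int
    n_novel_species: int
    tier_counts: dict[str, int] = field(default_factory=dict)
    merged_source_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_species < 0:
            raise ValueError("invalid denominators")
        if min(self.n_mags, self.n_almost_complete, self.n_novel_species) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def mags_per_sample(self) -> float:
        return round_half_up(self.n_mags / self.n_samples, 2)

    @property
    def almost_complete_pct(self) -> float:
        return percent(self.n_almost_complete, self.n_mags)

    @property
    def novel_species_pct(self) -> float:
        return percent(self.n_novel_species, self.n_species)

    @property
    def tier_pct(self) -> dict[str, float]:
        total = sum(self.tier_counts.values())
        return {t: percent(c, total) for t, c in self.tier_counts.items()}

    @property
    def merged_source_pct(self) -> dict[str, float]:
        total = sum(self.merged_source_counts.values())
        return {s: percent(c, total) for s, c in self.merged_source_counts.items()}

    def as_dict(self) -> dict:
        out = {
            "n_mags": self.n_mags,
            "n_samples": self.n_samples,
            "mags_per_sample": self.mags_per_sample,
            "n_almost_complete": self.n_almost_complete,
            "almost_complete_pct": self.almost_complete_pct,
            "n_species": self.n_species,
            "n_novel_species": self.n_novel_species,
            "novel_species_pct": self.novel_species_pct if self.n_species else None,
            "tier_counts": dict(self.tier_counts),
            "tier_pct": self.tier_pct,
        }
        if self.merged_source_counts:
            out["merged_source_counts"] = dict(self.merged_source_counts)
            out["merged_source_pct"] = self.merged_source_pct
        return out


def summarize_collection(
    n_mags: int,
    n_samples: int,
    n_almost_complete: int,
    n_species: int,
    n_novel_species: int,
    tier_counts: dict[str, int] | None = None,
    merged_source_counts: dict[str, int] | None = None,
) -> CohortSummary:
    """Assemble the cohort summary from raw counts."""
    return CohortSummary(
        n_mags=n_mags,
        n_samples=n_samples,
        n_almost_complete=n_almost_complete,
        n_species=n_species,
        n_novel_species=n_novel_species,
        tier_counts=tier_counts or {},
        merged_source_counts=merged_source_counts or {},
    )
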