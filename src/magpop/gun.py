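"""Genome unit number (GUN) and normalized GUN (nGUN).

GUN counts the genome units (99% ANI clusters) identified for a species;
nGUN scales it to units per 100 recovered genomes:

    nGUN = GUN / (number of MAGs) × 100%

Low nGUN means many genomes collapse into few units — limited within-species
diversity and therefore enough carriers per unit for within-species
association testing. High nGUN (up to 100, every genome its own unit) makes
such testing intractable. Candidate species for within-species analysis are
ranked by (low nGUN, high MAG count).

Two MAG-count presets reflect common usage: reporting across species with
> 10 MAGs, and a stricter > 100 MAGs regime for the metric itself; both are
plain config values here (``min_mags``).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import GenomeUnit, SpeciesCluster


def compute_gun(units: Sequence[GenomeUnit]) -> int:
    """Number of genome units for one species."""
    if not units:
        raise ValueError("species has no genome units")
    return len(units)


def compute_ngun(gun: int, n_mags: int) -> float:
    """Normalized GUN: genome units per 100 MAGs (full precision)."""
    if gun < 1:
        raise ValueError("GUN must be at least 1")
    if gun > n_mags:
        raise ValueError(f"GUN {gun} exceeds MAG count {n_mags}")
    return 100.0 * gun / n_mags


def gun_table(
    clusters: Sequence[SpeciesCluster],
    n_samples: int,
    phylum: Mapping[str, str] | None = None,
    min_mags: int = 10,
) -> pd.DataFrame:
    """Per-species GUN report for species with MAG count strictly above ``min_mags``.

    Columns: species_id, taxonomy, phylum, n_mags, gun, ngun (one decimal),
    prevalence (fraction of samples with at least one recovered MAG). Rows
    sorted by MAG count descending, then species id.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    rows = []
    for c in clusters:
        n_mags = len(c.members)
        if n_mags <= min_mags:
            continue
        gun = compute_gun(c.units)
        carriers = {s for u in c.units for s in u.carrier_samples}
        rows.append(
            {
                "species_id": c.cluster_id,
                "taxonomy": c.taxonomy if c.taxonomy is not None else "",
                "phylum": (phylum or {}).get(c.cluster_id, ""),
                "n_mags": n_mags,
                "gun": gun,
                "ngun": round(compute_ngun(gun, n_mags), 1),
                "prevalence": len(carriers) / n_samples,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["species_id", "taxonomy", "phylum", "n_mags", "gun", "ngun", "prevalence"],
    )
    return df.sort_values(["n_mags", "species_id"], ascending=[False, True]).reset_index(
        drop=True
    )


def select_candidates(
    report: pd.DataFrame, max_ngun: float = 10.0, min_mags: int = 100
) -> pd.DataFrame:
    """Rank species suitable for within-species association.

    Keeps rows with nGUN ≤ ``max_ngun`` and MAG count ≥ ``min_mags``; sorts
    by nGUN ascending, MAG count descending, species id.
    """
    kept = report[(report["ngun"] <= max_ngun) & (report["n_mags"] >= min_mags)]
    return kept.sort_values(
        ["ngun", "n_mags", "species_id"], ascending=[True, False, True]
    ).reset_index(drop=True)


def phylum_summary(report: pd.DataFrame, min_species: int = 10) -> pd.DataFrame:
    """nGUN distribution per phylum, restricted to phyla with ≥ ``min_species``.

    Columns: phylum, n_species, ngun_q1, ngun_median, ngun_q3.
    """
    rows = []
    for phylum, grp in report.groupby("phylum"):
        if phylum == "" or len(grp) < min_species:
            continue
        q1, med, q3 = np.percentile(grp["ngun"], [25, 50, 75])
        rows.append(
            {
                "phylum": phylum,
                "n_species": len(grp),
                "ngun_q1": q1,
                "ngun_median": med,
                "ngun_q3": q3,
            }
        )
    return pd.DataFrame(
        rows, columns=["phylum", "n_species", "ngun_q1", "ngun_median", "ngun_q3"]
    ).sort_values("phylum").reset_index(drop=True)
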