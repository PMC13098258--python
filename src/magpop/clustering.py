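"""Hierarchical ANI clustering of genomes into species and genome units.

Species clusters are cut at 95% ANI and genome units — the within-species
grouping — at 99% ANI, by average-linkage agglomerative clustering on the
distance 1 − ANI (linkage configurable). Genomes are always processed in
sorted-id order, so dendrogram tie-breaks are reproducible.

Representatives are chosen by a configurable quality score
``completeness − 5·contamination − 0.1·strain_heterogeneity + 0.5·log10(N50)``
(the usual dereplication trade-off: contamination is penalized hard, assembly
contiguity enters logarithmically), ties broken by smallest id.

``merge_collections`` deduplicates two representative collections (e.g. a
cohort-specific catalog A against a global reference B) at 95% ANI, keeping
the higher-scoring genome per shared species and recording provenance:
``novel`` (A-only, no taxonomy label), ``known_absent_from_B`` (A-only,
labelled), ``higher_quality_replacement`` (shared, A wins), ``B_only``
(B-only, or shared with B winning).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .ani import ANIMatrix

DEFAULT_SCORE_WEIGHTS = {
    "contamination": 5.0,
    "strain_heterogeneity": 0.1,
    "log10_n50": 0.5,
}


@dataclass
class GenomeUnit:
    unit_id: str
    members: list[str]
    carrier_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("genome unit must be nonempty")


@dataclass
class SpeciesCluster:
    cluster_id: str
    members: list[str]
    representative: str | None = None
    taxonomy: str | None = None
    units: list[GenomeUnit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.representative is not None and self.representative not in self.members:
            raise ValueError("representative must be a member")
        unit_members = [m for u in self.units for m in u.members]
        if self.units and sorted(unit_members) != sorted(self.members):
            raise ValueError("units must partition the cluster members")

    @property
    def is_novel(self) -> bool:
        return self.taxonomy is None


@dataclass
class MergedSpecies:
    species_id: str
    representative: str
    source: str  # "A" | "B"
    category: str  # novel | known_absent_from_B | higher_quality_replacement | B_only
    members: list[str] = field(default_factory=list)


@dataclass
class MergedReference:
    species: list[MergedSpecies]

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for sp in self.species:
            counts[sp.category] = counts.get(sp.category, 0) + 1
        return counts

    def source_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for sp in self.species:
            counts[sp.source] = counts.get(sp.source, 0) + 1
        return counts


def cluster_at_threshold(
    ani: ANIMatrix, t: float, method: str = "average"
) -> list[list[str]]:
    """Partition genomes so members of one block exceed ANI ``t`` on average.

    Average-linkage agglomeration on 1 − ANI, cut at 1 − t. Returns blocks
    of sorted member ids, ordered by descending size then smallest member id.
    """
    if not 0.0 < t < 1.0:
        raise ValueError(f"threshold {t} outside (0, 1)")
    order = np.argsort(ani.ids)
    ids = [ani.ids[i] for i in order]
    vals = ani.values[np.ix_(order, order)]
    if len(ids) == 1:
        return [[ids[0]]]
    dist = np.clip(1.0 - vals, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    labels = fcluster(linkage(condensed, method=method), 1.0 - t, criterion="distance")
    blocks: dict[int, list[str]] = {}
    for gid, lab in zip(ids, labels):
        blocks.setdefault(int(lab), []).append(gid)
    members = [sorted(b) for b in blocks.values()]
    members.sort(key=lambda b: (-len(b), b[0]))
    return members


def cluster_genome_units(
    members: Sequence[str],
    ani: ANIMatrix,
    species_id: str = "S1",
    t: float = 0.99,
    carriers: Mapping[str, str] | None = None,
    method: str = "average",
) -> list[GenomeUnit]:
    """Split one species cluster into genome units at 99% ANI.

    Units are sorted by descending size then member id and labelled
    ``<species_id>_U<i>``. ``carriers`` maps mag_id → sample_id.
    """
    if not members:
        raise ValueError("empty species cluster")
    sub = ani.submatrix(sorted(members))
    blocks = cluster_at_threshold(sub, t, method=method)
    units = []
    for i, block in enumerate(blocks, start=1):
        samples = sorted({carriers[m] for m in block}) if carriers else []
        units.append(GenomeUnit(f"{species_id}_U{i}", block, samples))
    return units


def score_genome(
    completeness: float,
    contamination: float,
    strain_heterogeneity: float = 0.0,
    n50: float = 1.0,
    weights: Mapping[str, float] = DEFAULT_SCORE_WEIGHTS,
) -> float:
    """Dereplication quality score used for representative selection."""
    if not 0 <= completeness <= 100:
        raise ValueError("completeness outside [0, 100]")
    if contamination < 0:
        raise ValueError("contamination must be non-negative")
    if n50 <= 0:
        raise ValueError("N50 must be positive")
    return (
        completeness
        - weights["contamination"] * contamination
        - weights["strain_heterogeneity"] * strain_heterogeneity
        + weights["log10_n50"] * math.log10(n50)
    )


def select_representative(members: Sequence[str], scores: Mapping[str, float]) -> str:
    """Highest-scoring member; ties broken by lexicographically smallest id."""
    if not members:
        raise ValueError("empty cluster")
    return min(members, key=lambda m: (-scores[m], m))


def scores_from_metadata(metadata: pd.DataFrame) -> dict[str, float]:
    """Quality scores per mag_id from a metadata table."""
    return {
        str(r.mag_id): score_genome(
            float(r.completeness),
            float(r.contamination),
            float(getattr(r, "strain_het", 0.0)),
            float(r.n50),
        )
        for r in metadata.itertuples()
    }


def build_species_clusters(
    ani: ANIMatrix,
    metadata: pd.DataFrame,
    t_species: float = 0.95,
    t_unit: float = 0.99,
    method: str = "average",
) -> list[SpeciesCluster]:
    """Full nested partition: species at ``t_species``, units at ``t_unit``.

    ``metadata`` needs columns mag_id, sample_id, completeness, contamination,
    strain_het, n50 and (optionally) taxonomy; the representative's taxonomy
    labels the cluster (missing label ⇒ novel species).
    """
    meta = metadata.set_index(metadata["mag_id"].astype(str))
    scores = scores_from_metadata(metadata)
    carriers = {str(r.mag_id): str(r.sample_id) for r in metadata.itertuples()}
    blocks = cluster_at_threshold(ani, t_species, method=method)
    clusters = []
    for i, members in enumerate(blocks, start=1):
        sid = f"S{i}"
        rep = select_representative(members, scores)
        taxonomy = None
        if "taxonomy" in meta.columns:
            label = meta.loc[rep, "taxonomy"]
            if pd.notna(label) and str(label) != "":
                taxonomy = str(label)
        units = cluster_genome_units(
            members, ani, species_id=sid, t=t_unit, carriers=carriers, method=method
        )
        clusters.append(SpeciesCluster(sid, members, rep, taxonomy, units))
    return clusters


def clusters_to_table(clusters: Sequence[SpeciesCluster]) -> pd.DataFrame:
    """Flat assignment table: mag_id, species_cluster_id, genome_unit_id, is_representative."""
    rows = []
    for c in clusters:
        for u in c.units:
            for m in u.members:
                rows.append(
                    {
                        "mag_id": m,
                        "species_cluster_id": c.cluster_id,
                        "genome_unit_id": u.unit_id,
                        "is_representative": int(m == c.representative),
                    }
                )
    return pd.DataFrame(rows).sort_values("mag_id").reset_index(drop=True)


def merge_collections(
    reps_a: Mapping[str, str | None],
    reps_b: Mapping[str, str | None],
    ani: ANIMatrix,
    scores: Mapping[str, float],
    t: float = 0.95,
    method: str = "average",
) -> MergedReference:
    """Deduplicate two representative collections at species level.

    ``reps_a``/``reps_b`` map mag_id → taxonomy label (None ⇒ unlabelled);
    ``ani`` must cover the union of ids; ``scores`` are quality scores.
    """
    overlap = set(reps_a) & set(reps_b)
    if overlap:
        raise ValueError(f"collections share genome ids: {sorted(overlap)[:3]}")
    all_ids = sorted(set(reps_a) | set(reps_b))
    blocks = cluster_at_threshold(ani.submatrix(all_ids), t, method=method)
    merged = []
    for i, members in enumerate(blocks, start=1):
        a_side = [m for m in members if m in reps_a]
        b_side = [m for m in members if m in reps_b]
        rep = select_representative(members, scores)
        if a_side and not b_side:
            source = "A"
            category = "novel" if reps_a[rep] is None else "known_absent_from_B"
        elif b_side and not a_side:
            source, category = "B", "B_only"
        else:
            if rep in reps_a:
                source, category = "A", "higher_quality_replacement"
            else:
                source, category = "B", "B_only"
        merged.append(MergedSpecies(f"G{i}", rep, source, category, members))
    return MergedReference(merged)
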