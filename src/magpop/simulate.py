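"""Synthetic MAG cohorts with known ground truth.

Generates everything the downstream pipeline consumes — genome collections
with a planted species / genome-unit hierarchy, per-genome quality metadata,
zero-inflated log-normal abundance tables, and binary phenotypes with
planted species-level and unit-level effects — so every stage is testable
without external data.

Genomes evolve on a star phylogeny by independent per-site substitutions
(no indels), which keeps pairwise distances analytically controllable and
makes the per-site Hamming identity an exact ANI oracle:

* species ancestors at rate ``d_between_species/2`` from a common root
  (pairwise identity ≲ 1 − d_between_species, below the 95% species bound);
* unit centers at ``d_between_units/2`` from their species ancestor
  (between-unit identity ≈ 1 − d_between_units, inside the 95–99% band);
* members at ``d_within_unit/2`` from their unit center (within-unit
  identity ≈ 1 − d_within_unit > 99%).

Each genome is attributed to a distinct sample of its unit; the recovery
table records which (sample, species, unit) produced a genome, defining
unit carriers. Diseases are drawn from a logistic model with the intercept
calibrated to a target prevalence, a planted log-odds-ratio on carriers of
one genome unit, and mild age/sex/BMI covariate effects; a planted
species-level effect multiplies that species' abundance load by exp(beta)
in cases, which shifts its CLR abundance by ~beta in the association stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_PHYLA = (
    "Bacillota",
    "Bacteroidota",
    "Bacillota_A",
    "Pseudomonadota",
    "Verrucomicrobiota",
    "Cyanobacteriota",
)


@dataclass(frozen=True)
class GenomeRecord:
    """One simulated (or loaded) MAG."""

    mag_id: str
    contigs: tuple[str, ...]
    sample_id: str
    taxonomy: str | None = None
    phylum: str | None = None

    @property
    def sequence(self) -> str:
        return "".join(self.contigs)


@dataclass(frozen=True)
class DiseaseConfig:
    """One planted binary phenotype.

    ``species_beta`` shifts the CLR abundance of ``species_index`` in cases;
    ``unit_log_or`` is the planted carrier log-odds-ratio for genome unit
    ``unit_index`` of ``species_index``.
    """

    name: str
    prevalence: float
    species_beta: float = 0.0
    unit_log_or: float = 0.0
    species_index: int = 0
    unit_index: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence {self.prevalence} outside (0, 1)")


@dataclass
class SimConfig:
    """Stated world of the synthetic cohort.

    Distance defaults place within-unit pairs above 99% identity, between-unit
    pairs inside (95%, 99%), and between-species pairs below 95%.
    """

    n_species: int = 5
    units_per_species: int | Sequence[int] = 2
    mags_per_unit: int | Sequence[int] = 5
    genome_length: int = 20_000
    d_between_units: float = 0.015
    d_within_unit: float = 0.002
    d_between_species: float = 0.10
    n_samples: int = 30
    novel_fraction: float = 0.15
    disease_configs: tuple[DiseaseConfig, ...] = field(
        default_factory=lambda: (
            DiseaseConfig("disease_planted", 0.30, species_beta=1.0, unit_log_or=np.log(0.56)),
            DiseaseConfig("disease_null", 0.30),
        )
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if 2 * self.d_within_unit >= 0.01:
            raise ValueError("2*d_within_unit must stay below 0.01 (ANI > 99% within units)")
        if not 0.01 < self.d_between_units < 0.05:
            raise ValueError("d_between_units must lie strictly inside (0.01, 0.05)")
        if self.d_between_species <= 0.05:
            raise ValueError("d_between_species must exceed 0.05")
        if self.n_species < 1 or self.n_samples < 1 or self.genome_length < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.novel_fraction <= 1.0:
            raise ValueError("novel_fraction outside [0, 1]")
        if self.n_samples < max(self.mags_per_unit_list):
            raise ValueError("n_samples must be at least mags_per_unit (one sample per MAG)")

    @property
    def units_per_species_list(self) -> list[int]:
        u = self.units_per_species
        out = [u] * self.n_species if isinstance(u, int) else list(u)
        if len(out) != self.n_species or min(out) < 1:
            raise ValueError("units_per_species must give a positive count per species")
        return out

    @property
    def mags_per_unit_list(self) -> list[int]:
        m = self.mags_per_unit
        n_units = sum(self.units_per_species_list)
        out = [m] * n_units if isinstance(m, int) else list(m)
        if len(out) != n_units or min(out) < 1:
            raise ValueError("mags_per_unit must give a positive count per unit")
        return out


@dataclass
class TruthAssignment:
    """Ground-truth labels for a simulated collection."""

    mag_to_group: dict[str, tuple[int, int, str]]  # mag_id -> (species, unit, sample)
    species_taxonomy: dict[int, str | None]
    species_phylum: dict[int, str]

    def species_partition(self) -> list[list[str]]:
        blocks: dict[int, list[str]] = {}
        for mag, (sp, _, _) in self.mag_to_group.items():
            blocks.setdefault(sp, []).append(mag)
        return [sorted(blocks[k]) for k in sorted(blocks)]

    def unit_partition(self) -> list[list[str]]:
        blocks: dict[tuple[int, int], list[str]] = {}
        for mag, (sp, u, _) in self.mag_to_group.items():
            blocks.setdefault((sp, u), []).append(mag)
        return [sorted(blocks[k]) for k in sorted(blocks)]


def random_genome(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def mutate_sequence(seq: str, d: float, rng: np.random.Generator) -> str:
    """Substitute each site independently with probability ``d``.

    A substituted site becomes one of the three other bases uniformly;
    length is preserved (no indels).
    """
    if not 0.0 <= d < 0.75:
        raise ValueError(f"substitution rate {d} outside [0, 0.75)")
    if not seq:
        raise ValueError("empty sequence")
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < d)[0]
    if hit.size:
        # shift by 1..3 positions in base order, mod 4: uniform over other bases
        idx = np.searchsorted(_BASES, arr[hit])
        arr[hit] = _BASES[(idx + rng.integers(1, 4, size=hit.size)) % 4]
    return arr.tobytes().decode("ascii")


def simulate_genome_collection(
    cfg: SimConfig,
) -> tuple[list[GenomeRecord], TruthAssignment]:
    """Generate the planted MAG collection and its truth labels."""
    rng = np.random.default_rng(cfg.rng_seed)
    units_per_sp = cfg.units_per_species_list
    mags_per_unit = cfg.mags_per_unit_list
    root = random_genome(cfg.genome_length, rng)

    n_novel = int(round(cfg.novel_fraction * cfg.n_species))
    novel_species = set(rng.choice(cfg.n_species, size=n_novel, replace=False).tolist())
    taxonomy = {
        sp: (None if sp in novel_species else f"s__Species_{sp:03d}")
        for sp in range(cfg.n_species)
    }
    phylum = {
        sp: _PHYLA[int(rng.integers(0, len(_PHYLA)))] for sp in range(cfg.n_species)
    }

    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    records: list[GenomeRecord] = []
    truth: dict[str, tuple[int, int, str]] = {}
    unit_idx = 0
    for sp in range(cfg.n_species):
        ancestor = mutate_sequence(root, cfg.d_between_species / 2.0, rng)
        for u in range(units_per_sp[sp]):
            center = mutate_sequence(ancestor, cfg.d_between_units / 2.0, rng)
            n_mags = mags_per_unit[unit_idx]
            unit_idx += 1
            origin = rng.choice(cfg.n_samples, size=n_mags, replace=False)
            for m, s_idx in enumerate(sorted(origin.tolist())):
                seq = mutate_sequence(center, cfg.d_within_unit / 2.0, rng)
                mag_id = f"sp{sp:03d}_u{u:02d}_m{m:03d}"
                records.append(
                    GenomeRecord(
                        mag_id,
                        (seq,),
                        samples[s_idx],
                        taxonomy[sp],
                        phylum[sp],
                    )
                )
                truth[mag_id] = (sp, u, samples[s_idx])
    records.sort(key=lambda r: r.mag_id)
    return records, TruthAssignment(truth, taxonomy, phylum)


@dataclass
class QualityParams:
    """Marginals for simulated quality metadata.

    Defaults target a tier mix resembling large MAG surveys: roughly a fifth
    of genomes high-quality, most medium, a small residue low-quality.
    """

    completeness_mean: float = 85.0
    completeness_sd: float = 10.0
    contamination_scale: float = 2.0
    strain_het_scale: float = 5.0
    n50_log_mean: float = np.log(45_000.0)
    n50_log_sd: float = 0.8
    rrna_p: float = 0.92
    trna_mean: float = 25.0


def simulate_quality_metadata(
    truth: TruthAssignment,
    rng: np.random.Generator,
    params: QualityParams | None = None,
) -> pd.DataFrame:
    """Per-MAG quality metadata with the configured marginals.

    completeness ~ normal truncated to (50, 100]; contamination ~ exponential
    clipped to [0, 15); strain heterogeneity ~ exponential clipped to
    [0, 100]; N50 ~ log-normal; each rRNA gene ~ Bernoulli; tRNA ~ Poisson.
    """
    if not truth.mag_to_group:
        raise ValueError("empty truth assignment")
    p = params or QualityParams()
    mags = sorted(truth.mag_to_group)
    n = len(mags)

    completeness = p.completeness_mean + p.completeness_sd * rng.standard_normal(n)
    for _ in range(100):  # resample into the truncation window
        out = (completeness <= 50) | (completeness > 100)
        if not out.any():
            break
        completeness[out] = p.completeness_mean + p.completeness_sd * rng.standard_normal(
            int(out.sum())
        )
    completeness = np.clip(completeness, 50.0 + 1e-9, 100.0)

    contamination = np.clip(rng.exponential(p.contamination_scale, n), 0.0, 15.0 - 1e-9)
    strain_het = np.clip(rng.exponential(p.strain_het_scale, n), 0.0, 100.0)
    n50 = np.exp(p.n50_log_mean + p.n50_log_sd * rng.standard_normal(n)).astype(int) + 1
    rrna = rng.random((n, 3)) < p.rrna_p
    trna = rng.poisson(p.trna_mean, n)

    return pd.DataFrame(
        {
            "mag_id": mags,
            "sample_id": [truth.mag_to_group[m][2] for m in mags],
            "completeness": np.round(completeness, 2),
            "contamination": np.round(contamination, 2),
            "strain_het": np.round(strain_het, 2),
            "n50": n50,
            "rrna_5s": rrna[:, 0].astype(int),
            "rrna_16s": rrna[:, 1].astype(int),
            "rrna_23s": rrna[:, 2].astype(int),
            "trna_count": trna,
            "taxonomy": [
                truth.species_taxonomy[truth.mag_to_group[m][0]] or "" for m in mags
            ],
            "phylum": [truth.species_phylum[truth.mag_to_group[m][0]] for m in mags],
        }
    )


def calibrate_intercept(offset: np.ndarray, prevalence: float) -> float:
    """Intercept b0 such that mean(expit(b0 + offset)) equals ``prevalence``."""
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence {prevalence} outside (0, 1)")
    return float(brentq(lambda b0: expit(b0 + offset).mean() - prevalence, -30.0, 30.0))


def simulate_phenotype_covariates(
    n_samples: int, rng: np.random.Generator, female_fraction: float = 0.70
) -> pd.DataFrame:
    """Cohort covariates: age ~ U(23, 89), sex ~ Bernoulli (1 = female), BMI ~ N(26, 4)."""
    return pd.DataFrame(
        {
            "age": rng.uniform(23.0, 89.0, n_samples),
            "sex": (rng.random(n_samples) < female_fraction).astype(int),
            "bmi": 26.0 + 4.0 * rng.standard_normal(n_samples),
        },
        index=[f"S{i:04d}" for i in range(n_samples)],
    )


def simulate_disease(
    carrier: np.ndarray,
    covariates: pd.DataFrame,
    prevalence: float,
    log_or: float,
    rng: np.random.Generator,
    beta_age: float = 0.01,
    beta_sex: float = 0.2,
    beta_bmi: float = 0.03,
) -> np.ndarray:
    """Binary disease from a logistic model with a planted carrier log-OR.

    Covariate effects are centered so the intercept calibration hits the
    target prevalence.
    """
    offset = (
        log_or * carrier.astype(float)
        + beta_age * (covariates["age"].to_numpy() - 56.0)
        + beta_sex * (covariates["sex"].to_numpy() - 0.7)
        + beta_bmi * (covariates["bmi"].to_numpy() - 26.0)
    )
    b0 = calibrate_intercept(offset, prevalence)
    return (rng.random(carrier.size) < expit(b0 + offset)).astype(int)


def recovery_table(truth: TruthAssignment) -> pd.DataFrame:
    """Which (sample, species, unit) produced a MAG."""
    rows = [
        {"sample_id": s, "species_index": sp, "unit_index": u, "mag_id": mag}
        for mag, (sp, u, s) in sorted(truth.mag_to_group.items())
    ]
    return pd.DataFrame(rows, columns=["sample_id", "species_index", "unit_index", "mag_id"])


def simulate_cohort_tables(
    truth: TruthAssignment,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Abundance, phenotype, and MAG-recovery tables for the cohort.

    Abundances are zero-inflated log-normal loads normalized per sample.
    Planted unit effects act on carriers from the recovery table; planted
    species effects multiply the species' load by exp(beta) in cases.
    """
    n, k = cfg.n_samples, cfg.n_species
    samples = [f"S{i:04d}" for i in range(n)]
    species_cols = [f"sp{sp:03d}" for sp in range(k)]

    pheno = simulate_phenotype_covariates(n, rng)

    presence_p = rng.uniform(0.4, 0.95, k)
    present = rng.random((n, k)) < presence_p
    # no sample may be an all-zero composition
    empty = ~present.any(axis=1)
    if empty.any():
        present[np.nonzero(empty)[0], rng.integers(0, k, int(empty.sum()))] = True
    mu = rng.normal(0.0, 1.0, k)
    loads = np.where(present, np.exp(mu + rng.standard_normal((n, k))), 0.0)

    recov = recovery_table(truth)
    carrier_sets: dict[tuple[int, int], set[str]] = {}
    for r in recov.itertuples():
        carrier_sets.setdefault((int(r.species_index), int(r.unit_index)), set()).add(
            str(r.sample_id)
        )

    disease_cols = {}
    for dc in cfg.disease_configs:
        carriers = carrier_sets.get((dc.species_index, dc.unit_index), set())
        carrier_vec = np.array([s in carriers for s in samples], dtype=float)
        y = simulate_disease(carrier_vec, pheno, dc.prevalence, dc.unit_log_or, rng)
        disease_cols[dc.name] = y
        if dc.species_beta != 0.0 and dc.species_index < k:
            col = dc.species_index
            loads[:, col] = np.where(
                (y == 1) & (loads[:, col] > 0),
                loads[:, col] * np.exp(dc.species_beta),
                loads[:, col],
            )

    abundance = pd.DataFrame(
        loads / loads.sum(axis=1, keepdims=True), index=samples, columns=species_cols
    )
    for name, y in disease_cols.items():
        pheno[name] = y
    return abundance, pheno, recov


def write_collection(
    outdir: str | Path,
    records: Sequence[GenomeRecord],
    metadata: pd.DataFrame,
    abundance: pd.DataFrame,
    phenotypes: pd.DataFrame,
    truth: TruthAssignment,
) -> dict[str, Path]:
    """Write FASTA (one file per MAG) and the four TSV tables."""
    outdir = Path(outdir)
    fasta_dir = outdir / "fasta"
    fasta_dir.mkdir(parents=True, exist_ok=True)
    for rec in records:
        with open(fasta_dir / f"{rec.mag_id}.fasta", "w") as fh:
            for i, contig in enumerate(rec.contigs):
                fh.write(f">{rec.mag_id}_c{i}\n")
                for pos in range(0, len(contig), 80):
                    fh.write(contig[pos : pos + 80] + "\n")
    paths = {
        "fasta_dir": fasta_dir,
        "metadata": outdir / "metadata.tsv",
        "abundance": outdir / "abundance.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "truth": outdir / "truth.tsv",
    }
    metadata.to_csv(paths["metadata"], sep="\t", index=False)
    abundance.to_csv(paths["abundance"], sep="\t", index_label="sample_id")
    phenotypes.to_csv(paths["phenotypes"], sep="\t", index_label="sample_id")
    recovery_table(truth).to_csv(paths["truth"], sep="\t", index=False)
    return paths
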