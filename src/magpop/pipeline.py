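"""End-to-end pipeline driver.

Sequences the stages downstream of assembly/binning: sketch → pairwise ANI →
species clusters → genome units → MIMAG tiers → representatives → GUN report
→ species-level MWAS → nGUN-guided within-species MWAS → cohort summary.
Inputs are either a synthetic-cohort configuration (everything generated with
a known truth) or paths to real FASTA + TSV inputs. Every stage writes a TSV
into the output directory and the run ends with a machine-readable manifest
(parameters, seed, versions, per-file SHA-256) sufficient to reproduce the
run byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .ani import DEFAULT_K, DEFAULT_SKETCH_SIZE, pairwise_ani_matrix, sketch, write_sketches
from .association import (
    accumulation_curve,
    clr_transform,
    filter_diseases,
    filter_species,
    results_to_table,
    species_mwas,
    unit_presence_matrix,
    within_species_mwas,
)
from .clustering import build_species_clusters, clusters_to_table
from .gun import gun_table, select_candidates
from .quality import classify_table
from .report import summarize_collection
from .simulate import (
    GenomeRecord,
    SimConfig,
    recovery_table,
    simulate_cohort_tables,
    simulate_genome_collection,
    simulate_quality_metadata,
    write_collection,
)

log = logging.getLogger("magpop")

NON_DISEASE_COLS = {"sample_id", "age", "sex", "bmi"}


@dataclass
class PipelineConfig:
    """Everything a run needs; either ``sim`` or the real-data paths."""

    outdir: str = "magpop_out"
    seed: int = 0
    sim: SimConfig | None = None
    fasta_dir: str | None = None
    metadata_path: str | None = None
    abundance_path: str | None = None
    phenotype_path: str | None = None
    # module parameters
    k: int = DEFAULT_K
    sketch_size: int = DEFAULT_SKETCH_SIZE
    ani_method: str = "sketch"
    t_species: float = 0.95
    t_unit: float = 0.99
    linkage: str = "average"
    min_mags_gun: int = 10
    max_ngun: float = 10.0
    min_mags_candidate: int = 100
    min_prevalence: float = 0.01
    min_cases: int = 100
    min_carriers: int = 100
    alpha: float = 0.05
    pseudocount: str | float = "half-min"
    n_permutations: int = 20
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        real = all(
            p is not None
            for p in (self.fasta_dir, self.metadata_path, self.abundance_path,
                      self.phenotype_path)
        )
        if self.sim is None and not real:
            raise ValueError("config needs either synthetic mode (sim) or all real-data paths")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        sim = raw.pop("sim", None)
        if sim is not None and not isinstance(sim, SimConfig):
            sim = SimConfig(**sim)
        return cls(sim=sim, **raw)

    def to_jsonable(self) -> dict:
        out = dataclasses.asdict(self)
        return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_real_inputs(cfg: PipelineConfig):
    records = []
    meta = pd.read_csv(cfg.metadata_path, sep="\t", dtype={"mag_id": str, "sample_id": str})
    tax = {}
    if "taxonomy" in meta.columns:
        tax = {
            str(r.mag_id): (str(r.taxonomy) if pd.notna(r.taxonomy) and str(r.taxonomy) else None)
            for r in meta.itertuples()
        }
    sample_of = {str(r.mag_id): str(r.sample_id) for r in meta.itertuples()}
    for fasta in sorted(Path(cfg.fasta_dir).glob("*.fasta")):
        mag_id = fasta.stem
        contigs = tuple(str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta"))
        if mag_id not in sample_of:
            raise ValueError(f"stage load_inputs: MAG {mag_id!r} missing from metadata")
        records.append(
            GenomeRecord(mag_id, contigs, sample_of[mag_id], tax.get(mag_id))
        )
    abundance = pd.read_csv(cfg.abundance_path, sep="\t", index_col="sample_id")
    phenotypes = pd.read_csv(cfg.phenotype_path, sep="\t", index_col="sample_id")
    return records, meta, abundance, phenotypes, None


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dict (also written as JSON)."""
    logging.basicConfig(level=cfg.log_level, format="%(levelname)s %(name)s: %(message)s")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stages: dict[str, dict] = {}

    def stage_done(name: str, t_start: float, **counts) -> None:
        stages[name] = {"wall_s": round(time.time() - t_start, 3), **counts}
        log.info("stage %s done in %.2fs %s", name, time.time() - t_start, counts)

    # -- inputs -------------------------------------------------------------
    t = time.time()
    if cfg.sim is not None:
        sim = dataclasses.replace(cfg.sim, rng_seed=cfg.seed)
        records, truth = simulate_genome_collection(sim)
        rng = np.random.default_rng(cfg.seed + 1)
        metadata = simulate_quality_metadata(truth, rng)
        abundance, phenotypes, recovery = simulate_cohort_tables(truth, sim, rng)
        write_collection(outdir, records, metadata, abundance, phenotypes, truth)
    else:
        records, metadata, abundance, phenotypes, recovery = _load_real_inputs(cfg)
        if recovery is None:
            recovery = metadata[["sample_id", "mag_id"]].copy()
    missing = abundance.index.difference(phenotypes.index)
    if len(missing):
        raise ValueError(
            f"stage load_inputs: sample {missing[0]!r} present in abundance "
            "but absent from phenotypes"
        )
    stage_done("inputs", t, n_mags=len(records), n_samples=len(abundance))

    genomes = {r.mag_id: r.contigs for r in records}

    # -- sketches and ANI ---------------------------------------------------
    t = time.time()
    sketches = [
        sketch(genomes[g], k=cfg.k, s=cfg.sketch_size, genome_id=g) for g in sorted(genomes)
    ]
    write_sketches(sketches, outdir / "sketches.tsv")
    ani = pairwise_ani_matrix(genomes, method=cfg.ani_method, k=cfg.k, s=cfg.sketch_size)
    ani.to_dataframe().to_csv(outdir / "ani_matrix.tsv", sep="\t", index_label="genome_id")
    stage_done("ani", t, n_pairs=len(ani.ids) * (len(ani.ids) - 1) // 2)

    # -- clustering and tiers -----------------------------------------------
    t = time.time()
    clusters = build_species_clusters(
        ani, metadata, t_species=cfg.t_species, t_unit=cfg.t_unit, method=cfg.linkage
    )
    ctable = clusters_to_table(clusters)
    ctable.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    tiers = classify_table(metadata)
    tiers.to_csv(outdir / "metadata_tiers.tsv", sep="\t", index=False)
    stage_done("cluster", t, n_species=len(clusters),
               n_units=sum(len(c.units) for c in clusters))

    # -- GUN report ---------------------------------------------------------
    t = time.time()
    phylum_of = {}
    if "phylum" in metadata.columns:
        pmap = {str(r.mag_id): str(r.phylum) for r in metadata.itertuples()}
        phylum_of = {c.cluster_id: pmap.get(c.representative, "") for c in clusters}
    gtable = gun_table(clusters, n_samples=len(abundance), phylum=phylum_of,
                       min_mags=cfg.min_mags_gun)
    gtable.to_csv(outdir / "gun_report.tsv", sep="\t", index=False)
    candidates = select_candidates(gtable, max_ngun=cfg.max_ngun,
                                   min_mags=cfg.min_mags_candidate)
    candidates.to_csv(outdir / "gun_candidates.tsv", sep="\t", index=False)
    stage_done("gun", t, n_reported=len(gtable), n_candidates=len(candidates))

    # -- species-level MWAS -------------------------------------------------
    t = time.time()
    diseases_all = [c for c in phenotypes.columns if c not in NON_DISEASE_COLS]
    diseases = filter_diseases(phenotypes, diseases_all, min_cases=cfg.min_cases)
    kept_species = filter_species(abundance, min_prevalence=cfg.min_prevalence)
    results = []
    if diseases and kept_species:
        clr = clr_transform(abundance[kept_species], pseudocount=cfg.pseudocount)
        results.extend(species_mwas(clr, phenotypes, diseases, alpha=cfg.alpha))
    stage_done("species_mwas", t, n_species=len(kept_species), n_diseases=len(diseases))

    # -- within-species MWAS on the top nGUN candidate ----------------------
    t = time.time()
    n_unit_tests = 0
    if len(candidates) and diseases:
        target = str(candidates.iloc[0]["species_id"])
        unit_of_mag = {
            str(r.mag_id): str(r.genome_unit_id)
            for r in ctable.itertuples()
            if str(r.species_cluster_id) == target
        }
        presence = unit_presence_matrix(recovery, unit_of_mag, list(abundance.index))
        unit_results = within_species_mwas(
            presence, phenotypes, diseases, min_carriers=cfg.min_carriers, alpha=cfg.alpha
        )
        n_unit_tests = len(unit_results)
        results.extend(unit_results)
    results_to_table(results).to_csv(outdir / "associations.tsv", sep="\t", index=False)
    stage_done("within_species_mwas", t, n_unit_tests=n_unit_tests)

    # -- novel-species accumulation ------------------------------------------
    t = time.time()
    novel_ids = {c.cluster_id for c in clusters if c.is_novel}
    novel_by_sample: dict[str, set[str]] = {s: set() for s in abundance.index}
    for c in clusters:
        if c.cluster_id not in novel_ids:
            continue
        for u in c.units:
            for s in u.carrier_samples:
                if s in novel_by_sample:
                    novel_by_sample[s].add(c.cluster_id)
    curve, slope500, r2 = accumulation_curve(
        novel_by_sample, n_permutations=cfg.n_permutations, seed=cfg.seed + 2
    )
    pd.DataFrame({"n_samples": np.arange(1, len(curve) + 1), "mean_novel": curve}).to_csv(
        outdir / "accumulation.tsv", sep="\t", index=False
    )
    stage_done("accumulation", t, slope_per_500=round(slope500, 3), r2=round(r2, 4))

    # -- summary ------------------------------------------------------------
    t = time.time()
    rep_ids = {c.representative for c in clusters}
    rep_tiers = tiers[tiers["mag_id"].astype(str).isin(rep_ids)]
    tier_counts = rep_tiers["tier"].value_counts().to_dict()
    summary = summarize_collection(
        n_mags=len(records),
        n_samples=len(abundance),
        n_almost_complete=int(tiers["almost_complete"].sum()),
        n_species=len(clusters),
        n_novel_species=len(novel_ids),
        tier_counts={k: int(v) for k, v in tier_counts.items()},
    )
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary.as_dict(), fh, indent=2, sort_keys=True)
    stage_done("summary", t)

    # -- manifest -----------------------------------------------------------
    manifest = {
        "package": "magpop",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "config": json.loads(json.dumps(cfg.to_jsonable(), default=str)),
        "stages": stages,
        "wall_s": round(time.time() - t0, 3),
        "outputs": {},
    }
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(outdir))] = _sha256(path)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
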