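"""End-to-end orchestration: simulate/load -> ORFs -> cluster -> screen.

Every stage reads and writes the documented plain-text contracts (FASTA,
GFF3, TSV), so stages are independently runnable and testable; a JSON
manifest records parameters, input checksums and per-stage record counts,
sufficient to re-run the pipeline identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .cluster import (
    DEFAULT_CLUSTER_THRESHOLD,
    ClusterAssignment,
    ScoringScheme,
    build_distance_matrix,
    single_linkage_cluster,
)
from .cooccurrence import (
    DEFAULT_SCREEN_THRESHOLD,
    PhenotypeTable,
    ScreenOutput,
    build_pan_matrix,
    join_annotations,
    results_to_tsv,
    screen,
)
from .orfs import (
    OrfParams,
    find_orfs_in_genome,
    genome_of,
    read_fasta,
    write_gff3,
    write_protein_fasta,
)
from .simulate import SimConfig, default_config, generate_dataset, write_dataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs; defaults are the documented stage defaults."""

    mode: str = "simulate"  # simulate | genomes | proteins
    outdir: Path = Path("pancooc_out")
    seed: int = 0
    genome_paths: Mapping[str, Path] = field(default_factory=dict)  # strain -> fasta
    protein_paths: Mapping[str, Path] = field(default_factory=dict)
    phenotype_path: Path | None = None
    annotation_path: Path | None = None
    sim_config: SimConfig | None = None
    orf_params: OrfParams = OrfParams()
    scoring: ScoringScheme = ScoringScheme()
    prefilter_k: int | None = 4
    cluster_threshold: float = DEFAULT_CLUSTER_THRESHOLD
    screen_threshold: float = DEFAULT_SCREEN_THRESHOLD
    screen_mode: str = "counts"
    signed: bool = True
    write_distances: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "genomes", "proteins"):
            raise ValueError("mode must be simulate, genomes or proteins")
        if self.mode == "genomes" and not self.genome_paths:
            raise ValueError("genomes mode needs genome_paths")
        if self.mode == "proteins" and not self.protein_paths:
            raise ValueError("proteins mode needs protein_paths")
        if self.mode != "simulate" and self.phenotype_path is None:
            raise ValueError(f"{self.mode} mode needs a phenotype table")


def config_from_toml(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a TOML document mirroring its fields."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    base = Path(path).parent
    kwargs: dict = {}
    for key in (
        "mode",
        "seed",
        "prefilter_k",
        "cluster_threshold",
        "screen_threshold",
        "screen_mode",
        "signed",
        "write_distances",
    ):
        if key in doc:
            kwargs[key] = doc[key]
    if "outdir" in doc:
        kwargs["outdir"] = base / doc["outdir"]
    for key in ("genome_paths", "protein_paths"):
        if key in doc:
            kwargs[key] = {k: base / v for k, v in doc[key].items()}
    for key in ("phenotype_path", "annotation_path"):
        if key in doc:
            kwargs[key] = base / doc[key]
    if "orf" in doc:
        orf = dict(doc["orf"])
        if "start_codons" in orf:
            orf["start_codons"] = frozenset(orf["start_codons"])
        kwargs["orf_params"] = OrfParams(**orf)
    if "scoring" in doc:
        kwargs["scoring"] = ScoringScheme(**doc["scoring"])
    if "simulate" in doc:
        sim = dict(doc["simulate"])
        seed = sim.pop("seed", doc.get("seed", 0))
        n_background = sim.pop("n_background", 30)
        kwargs["sim_config"] = default_config(seed=seed, n_background=n_background)
    return PipelineConfig(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _read_annotations(path: Path) -> dict[str, str]:
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, header=None,
        names=["cluster_id", "annotation"],
    )
    return dict(zip(df["cluster_id"], df["annotation"]))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the pipeline and return the run manifest (also written).

    Stages: simulate? -> findorfs -> cluster -> panmatrix -> screen ->
    annotate.  Re-running with identical config and inputs reproduces
    byte-identical result files.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "pancooc",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "mode": config.mode,
            "orf_min_protein_length": config.orf_params.min_protein_length,
            "orf_start_codons": sorted(config.orf_params.start_codons),
            "orf_require_stop": config.orf_params.require_stop,
            "scoring_matrix": config.scoring.matrix_name,
            "gap_open": config.scoring.gap_open,
            "gap_extend": config.scoring.gap_extend,
            "prefilter_k": config.prefilter_k,
            "cluster_threshold": config.cluster_threshold,
            "screen_threshold": config.screen_threshold,
            "screen_mode": config.screen_mode,
            "signed": config.signed,
        },
        "inputs": {},
        "stages": {},
        "complete": False,
    }
    stage = "simulate"
    try:
        # --- inputs -------------------------------------------------------
        if config.mode == "simulate":
            sim_config = config.sim_config or default_config(seed=config.seed)
            dataset = generate_dataset(sim_config)
            simdir = outdir / "genomes"
            paths = write_dataset(dataset, simdir)
            phenotype = dataset.phenotype
            genome_paths = {s: paths[s] for s in sim_config.strains}
            manifest["stages"]["simulate"] = {
                "n_strains": len(sim_config.strains),
                "n_families": len(sim_config.families),
                "n_genes_planted": int(
                    sum(sum(f.copy_counts) for f in sim_config.families)
                ),
            }
        else:
            phenotype = PhenotypeTable.from_tsv(config.phenotype_path)
            genome_paths = dict(config.genome_paths)
        for name, p in sorted(genome_paths.items()):
            manifest["inputs"][name] = _sha256(Path(p))
        if config.phenotype_path:
            manifest["inputs"]["phenotype"] = _sha256(Path(config.phenotype_path))

        # --- ORF prediction ----------------------------------------------
        stage = "findorfs"
        orfdir = outdir / "orfs"
        orfdir.mkdir(exist_ok=True)
        proteins: dict[str, str] = {}
        orf_to_genome: dict[str, str] = {}
        if config.mode == "proteins":
            for strain in phenotype.strains:
                if strain not in config.protein_paths:
                    raise ValueError(f"no protein FASTA for strain {strain!r}")
                for pid, seq in read_fasta(config.protein_paths[strain]).items():
                    if pid in proteins:
                        raise ValueError(f"duplicate protein id {pid!r}")
                    proteins[pid] = seq
                    orf_to_genome[pid] = strain
            manifest["stages"]["findorfs"] = {
                "skipped": "pre-predicted proteins supplied",
                "n_proteins": len(proteins),
            }
        else:
            n_orfs = {}
            for strain in phenotype.strains:
                if strain not in genome_paths:
                    raise ValueError(f"no genome FASTA for strain {strain!r}")
                contigs = read_fasta(genome_paths[strain])
                records = find_orfs_in_genome(contigs, config.orf_params, strain)
                write_protein_fasta(records, orfdir / f"{strain}.faa")
                write_gff3(records, orfdir / f"{strain}.gff3")
                for rec in records:
                    proteins[rec.orf_id] = rec.protein
                    orf_to_genome[rec.orf_id] = strain
                n_orfs[strain] = len(records)
            manifest["stages"]["findorfs"] = {"n_orfs": n_orfs}

        # --- clustering ---------------------------------------------------
        stage = "cluster"
        dm = build_distance_matrix(proteins, config.scoring, config.prefilter_k)
        if config.write_distances:
            dm.to_tsv(outdir / "distances.tsv")
        assignment = single_linkage_cluster(dm, config.cluster_threshold)
        assignment.to_tsv(outdir / "clusters.tsv")
        manifest["stages"]["cluster"] = {
            "n_sequences": len(dm.ids),
            "n_clusters": len(set(assignment.mapping.values())),
        }

        # --- pan-matrix ----------------------------------------------------
        stage = "panmatrix"
        pan = build_pan_matrix(assignment.mapping, orf_to_genome, phenotype)
        pan.to_tsv(outdir / "panmatrix.tsv")
        manifest["stages"]["panmatrix"] = {
            "n_clusters": len(pan.cluster_ids),
            "total_members": int(pan.counts.sum()),
        }

        # --- screen + annotate --------------------------------------------
        stage = "screen"
        out = screen(
            pan,
            phenotype,
            threshold=config.screen_threshold,
            mode=config.screen_mode,
            signed=config.signed,
            members=assignment.members(),
        )
        annotations = (
            _read_annotations(Path(config.annotation_path))
            if config.annotation_path
            else {}
        )
        passing = join_annotations(out.passing, annotations)
        undefined = join_annotations(out.undefined, annotations)
        results_to_tsv(passing, outdir / "results.tsv")
        results_to_tsv(undefined, outdir / "undefined.tsv")
        manifest["stages"]["screen"] = {
            "n_passing": len(passing),
            "n_undefined": len(undefined),
            "n_total": len(out.all_results),
        }
        manifest["complete"] = True
    except Exception:
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        raise
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    logger.info(
        "pipeline complete: %d/%d clusters pass threshold %.2f",
        manifest["stages"]["screen"]["n_passing"],
        manifest["stages"]["screen"]["n_total"],
        config.screen_threshold,
    )
    return manifest
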