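"""Pipeline orchestration and standard-format I/O.

Coordinates the stages — synthetic generation, qPCR T/S quantification,
per-CpG association, promoter enrichment, positional/imprinted statistics
and the motif scan — writing every intermediate as TSV/BED/JSON so each
stage can also be run stand-alone from files.  Coordinates are 0-based
half-open internally and in BED output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cpg_association import MethylationMatrix
from .positional_stats import (
    CENTROMERE_WINDOW_BP,
    SUBTELOMERE_WINDOW_BP,
    ChromosomeLayout,
)
from .synthetic_data import SimulationConfig

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_methylation_matrix(
    values_tsv: str | Path, cpg_bed: str | Path, value_kind: str = "M"
) -> MethylationMatrix:
    values = pd.read_csv(values_tsv, sep="\t", index_col=0)
    values.index.name = "cpg_id"
    values.columns.name = "sample_id"
    bed = pd.read_csv(
        cpg_bed, sep="\t", header=None, usecols=[0, 1, 3],
        names=["chrom", "pos", "cpg_id"],
    ).set_index("cpg_id")
    coords = bed.loc[values.index, ["chrom", "pos"]]
    return MethylationMatrix(values=values, coords=coords, value_kind=value_kind)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    if "ts_ratio" not in table.columns:
        raise ValueError("sample table must have a ts_ratio column")
    return table


def read_tss_bed(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
    )
    return pd.DataFrame(
        {
            "gene_id": bed["gene_id"],
            "chrom": bed["chrom"],
            "tss": bed["start"].astype(int),
            "strand": bed["strand"].fillna("+"),
        }
    )


def read_imprinted_list(path: str | Path) -> set:
    return {
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    }


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    plate = pd.read_csv(path, dtype={"sample_id": str})
    plate["sample_id"] = plate["sample_id"].fillna("")
    return plate


def write_association_tsv(associations: pd.DataFrame, path: str | Path) -> None:
    associations.to_csv(path, sep="\t")


def read_association_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_gene_enrichment_tsv(genes: pd.DataFrame, path: str | Path) -> None:
    genes.to_csv(path, sep="\t")


def write_sites(sites: pd.DataFrame, tsv_path: str | Path,
                bed_path: str | Path | None = None,
                coords: pd.DataFrame | None = None) -> None:
    sites.to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None and coords is not None:
        merged = sites.merge(coords, left_on="cpg_id", right_index=True)
        bed = pd.DataFrame(
            {
                "chrom": merged["chrom"],
                "start": merged["pos"],
                "end": merged["pos"] + 1,
                "name": merged["cpg_id"],
                "score": 0,
                "strand": np.where(merged["direction"] == "positive", "+", "-"),
            }
        ).sort_values(["chrom", "start"], kind="stable")
        bed.to_csv(bed_path, sep="\t", header=False, index=False)


def atomic_write_json(payload: dict, path: str | Path) -> None:
    """Write JSON via a temp file + rename so readers never see partial output."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            json.dump(payload, fh, indent=2, default=_json_default)
            fh.write("\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    out_dir: str = "telomethyl_run"
    gene_q_threshold: float = 0.05
    site_p_threshold: float = 0.05
    telomere_window: int = SUBTELOMERE_WINDOW_BP
    centromere_window: int = CENTROMERE_WINDOW_BP
    moderate_variance: bool = True
    include_unassigned_background: bool = True
    primary_chromosomes_only: bool = False
    n_permutations: int = 100_000
    run_motif_scan: bool = True
    genome_n_chromosomes: int = 1
    genome_chrom_length: int = 12_000_000
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        for name in ("gene_q_threshold", "site_p_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the global seed."""
    import zlib

    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full synthetic-scenario pipeline and write all outputs.

    Stages: simulate -> qPCR T/S -> per-CpG association (using the *measured*
    T/S as the regressor) -> promoter enrichment -> positional + imprinted
    tests -> motif scan on the synthetic genome.  Returns the run manifest
    (also written atomically to ``manifest.json`` in the output directory).
    """
    from . import (
        cpg_association,
        motif_scan,
        positional_stats,
        promoter_enrichment,
        qpcr_telomere,
        synthetic_data,
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    manifest: dict = {"config": config.to_dict(), "seed": config.seed,
                      "stages": {}, "warnings": []}

    def stage(name):
        logger.info("stage: %s", name)
        return manifest["stages"].setdefault(name, {})

    try:
        # --- simulate ---------------------------------------------------
        info = stage("simulate")
        layout, genes, imprinted, samples, matrix, truth = (
            synthetic_data.simulate_study(sim)
        )
        layout.write(out / "chrom.sizes", out / "centromeres.bed")
        synthetic_data.write_tss_bed(genes, out / "tss.bed")
        synthetic_data.write_cpg_bed(matrix.coords, out / "cpgs.bed")
        synthetic_data.write_methylation_tsv(matrix, out / "methylation.tsv")
        synthetic_data.write_imprinted_list(imprinted, out / "imprinted.txt")
        truth.to_json(out / "ground_truth.json")
        info.update(n_genes=len(genes), n_cpgs=len(matrix.cpg_ids),
                    n_samples=len(samples), n_imprinted=len(imprinted))

        # --- qPCR -------------------------------------------------------
        info = stage("qpcr")
        plate = synthetic_data.simulate_qpcr_plate(
            truth.ts_true, seed=child_seed(config.seed, "qpcr")
        )
        synthetic_data.write_plate_csv(plate, out / "plate.csv")
        measurements = qpcr_telomere.compute_ts_ratios(plate, reference_sample_id="REF")
        ts_table = qpcr_telomere.measurements_to_frame(measurements)
        measured = ts_table.drop(index="REF")
        measured.to_csv(out / "ts_ratios.tsv", sep="\t")
        info.update(
            n_samples=len(measured),
            mean_cv=float(qpcr_telomere.plate_cv_summary(measurements)),
        )

        # --- association ------------------------------------------------
        info = stage("associate")
        sample_table = measured[["ts_ratio"]].loc[samples.index]
        synthetic_data.write_sample_table(sample_table, out / "samples.tsv")
        associations = cpg_association.fit_cpg_associations(
            matrix, sample_table, moderate_variance=config.moderate_variance
        )
        write_association_tsv(associations, out / "associations.tsv")
        info.update(n_cpgs=len(associations),
                    n_undefined=int(associations["t"].isna().sum()))

        # --- enrichment -------------------------------------------------
        info = stage("enrich")
        cpg_map = promoter_enrichment.assign_nearest_tss(matrix.coords, genes)
        gene_results = promoter_enrichment.test_gene_enrichment(
            associations, cpg_map,
            include_unassigned_background=config.include_unassigned_background,
        )
        gene_results["q_value"] = promoter_enrichment.bh_fdr(
            gene_results["wilcoxon_p"]
        )
        sites = promoter_enrichment.call_significant_sites(
            associations, cpg_map, gene_results,
            config.gene_q_threshold, config.site_p_threshold,
        )
        gene_table = promoter_enrichment.enrichment_table(gene_results, sites)
        write_gene_enrichment_tsv(gene_table, out / "gene_enrichment.tsv")
        write_sites(sites, out / "sites.tsv", out / "sites.bed", matrix.coords)
        summary = promoter_enrichment.summarize_counts(sites, gene_results)
        atomic_write_json(summary, out / "site_summary.json")
        info.update(
            {k: v for k, v in summary.items()
             if isinstance(v, (int, float)) and v is not None}
        )

        # --- positional + imprinted ------------------------------------
        info = stage("positional")
        regions = positional_stats.classify_gene_regions(
            genes[genes["gene_id"].isin(gene_results.index)], layout,
            config.telomere_window, config.centromere_window,
        )
        sig_genes = set(sites["gene_id"])
        pos_genes = set(sites.loc[sites["direction"] == "positive", "gene_id"])
        neg_genes = set(sites.loc[sites["direction"] == "negative", "gene_id"])
        fisher = positional_stats.positional_enrichment_tests(
            regions, {"all": sig_genes, "positive": pos_genes, "negative": neg_genes}
        )
        fisher.to_csv(out / "positional_tests.tsv", sep="\t", index=False)

        counts = positional_stats.nearest_counts(cpg_map, gene_results.index)
        perm = positional_stats.imprinted_permutation_test(
            sorted(sig_genes), counts, imprinted,
            n_permutations=config.n_permutations,
            seed=child_seed(config.seed, "imprint"),
        )
        atomic_write_json(perm.to_dict(), out / "imprinted_permutation.json")
        info.update(n_significant_genes=len(sig_genes),
                    imprinted_observed=perm.observed,
                    imprinted_p=perm.p_value)

        # --- motif scan -------------------------------------------------
        if config.run_motif_scan:
            info = stage("motif_scan")
            gl = config.genome_chrom_length
            genome_layout = ChromosomeLayout.from_dict(
                {
                    f"chrM{i + 1}": (gl, gl // 2 - 250_000, gl // 2 + 250_000)
                    for i in range(config.genome_n_chromosomes)
                }
            )
            sequences, planted = synthetic_data.simulate_genome(
                genome_layout, seed=child_seed(config.seed, "genome")
            )
            synthetic_data.write_genome_fasta(sequences, out / "genome.fa")
            hits = motif_scan.scan_motif(sequences)
            motif_scan.hits_to_bed(hits, out / "motif_hits.bed")
            report = motif_scan.region_report(
                hits, genome_layout, config.telomere_window, config.centromere_window
            )
            report["planted"] = json.loads(planted.to_json(orient="records"))
            atomic_write_json(report, out / "motif_report.json")
            info.update(total_hits=report["total_hits"],
                        subtelomeric_hits=report["subtelomeric_hits"],
                        centromeric_hits=report["centromeric_hits"])
    except Exception as exc:
        failed = list(manifest["stages"])[-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline failed in stage {failed!r}: {exc}") from exc

    atomic_write_json(manifest, out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Cohort-level summaries
# ---------------------------------------------------------------------------


def cross_tissue_correlation(
    ts_a: pd.Series, ts_b: pd.Series
) -> tuple[float, float, int]:
    """Spearman correlation of paired T/S measurements from two tissues.

    Pairs on the sample-id index; unpaired samples are dropped with a logged
    count.  Requires at least 3 pairs.  Returns (rho, p, n_pairs).
    """
    a, b = ts_a.align(ts_b, join="inner")
    dropped = (len(ts_a) - len(a)) + (len(ts_b) - len(b))
    if dropped:
        logger.info("cross_tissue_correlation: %d unpaired measurements dropped", dropped)
    if len(a) < 3:
        raise ValueError(f"need >=3 paired samples, got {len(a)}")
    rho, p = stats.spearmanr(a.to_numpy(), b.to_numpy())
    return float(rho), float(p), int(len(a))
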