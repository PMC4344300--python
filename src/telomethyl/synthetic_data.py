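"""Synthetic cohorts, methylation matrices, qPCR plates and genomes.

Every downstream stage of the pipeline is exercised against data generated
here, with a recorded ground truth.  The generator emulates a small adult
cohort (two dozen samples) profiled on a promoter-focused methylation array:

* telomere T/S ratios drawn from a truncated normal (mean 1.0, SD 0.29 by
  default, floor 0.1 — observed cohorts of this design bottom out well above
  zero);
* genes with uniformly placed TSSs on equal-length chromosomes whose
  centromeres sit mid-chromosome, so subtelomeric (4 Mb) and centromeric
  (1.5 Mb) windows are well defined and disjoint;
* CpGs clustered within +/-2 kb of each TSS, counts drawn from a negative
  binomial so the per-gene "nearest count" varies (the matched permutation
  test needs that variation);
* baseline M-values from a two-component (low/high methylation) mixture,
  mimicking the bimodal beta distribution of array data;
* a planted fraction of genes whose CpG M-values depend linearly on T/S with
  a gene-constant slope sign;
* qPCR plates built from per-target standard curves with Gaussian Cq noise;
* chromosomes whose background sequence is free of the Zfp57 motif on both
  strands (enforced by rejection of offending windows) with motif
  occurrences planted at recorded positions and strands.

All randomness flows from ``SimulationConfig.seed`` through fixed-purpose
child streams, so the same seed reproduces every output byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .positional_stats import (
    CENTROMERE_WINDOW_BP,
    SUBTELOMERE_WINDOW_BP,
    ChromosomeLayout,
    classify_gene_regions,
)
from . import motif_scan as _motif

# child-stream tags: one fixed purpose per op so ops are independently
# reproducible from the one config seed
_STREAM_LAYOUT = 0
_STREAM_COHORT = 1
_STREAM_PLATE = 2
_STREAM_GENOME = 3

DEFAULT_CURVE_PARAMS = {
    # intercept (cycles at 1 ng), slope (cycles per log10 ng); perfect doubling
    "TEL": (28.0, -1.0 / np.log10(2.0)),
    "SCG": (30.0, -3.45),
}

MIN_MOTIF_SPACING_BP = 13  # planted 7-mers may not overlap or abut


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults follow the emulated design: 24 samples, T/S ~ N(1.0, 0.29)
    truncated at 0.1, 200 promoter-CpG clusters over 4 chromosomes, planted
    effects of 1.0 M-value unit per unit T/S against residual noise of
    SD 0.5 M-units.
    """

    n_samples: int = 24
    n_chromosomes: int = 4
    chrom_length: int = 30_000_000
    centromere_halfwidth: int = 1_500_000
    n_genes: int = 200
    cpgs_per_gene_mean: float = 8.0
    cpgs_per_gene_dispersion: float = 4.0
    cpgs_per_gene_fixed: bool = False  # exactly round(mean) CpGs per gene
    fraction_planted_genes: float = 0.05
    effect_size_mean: float = 1.0  # M-value units per unit T/S
    effect_size_sd: float = 0.25
    noise_sd: float = 0.5  # M-value units
    ts_mean: float = 1.0
    ts_sd: float = 0.29
    ts_floor: float = 0.1
    fraction_imprinted: float = 0.05
    n_motifs_subtelomeric: int = 7
    n_motifs_centromeric: int = 3
    n_motifs_interstitial: int = 3
    baseline_low_mean: float = -3.0
    baseline_high_mean: float = 3.0
    baseline_sd: float = 0.5
    baseline_high_weight: float = 0.5
    cpg_spread_bp: int = 2_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_planted_genes", "fraction_imprinted", "baseline_high_weight"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "n_samples", "n_chromosomes", "chrom_length", "centromere_halfwidth",
            "n_genes", "cpgs_per_gene_mean", "cpgs_per_gene_dispersion",
            "ts_mean", "ts_sd", "ts_floor", "cpg_spread_bp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0 or self.effect_size_sd < 0:
            raise ValueError("noise_sd and effect_size_sd must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


@dataclass
class GroundTruth:
    """What the generator actually planted, for downstream comparison."""

    planted_genes: set = field(default_factory=set)
    gene_slopes: dict = field(default_factory=dict)  # gene -> signed slope
    cpg_slopes: "pd.Series | None" = None  # per-CpG true slope (0 if unplanted)
    cpg_gene: "pd.Series | None" = None  # generating gene of each CpG
    ts_true: "pd.Series | None" = None
    motif_positions: "pd.DataFrame | None" = None  # chrom, start, strand, region

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_genes": sorted(self.planted_genes),
            "gene_slopes": {k: float(v) for k, v in sorted(self.gene_slopes.items())},
            "cpg_slopes": (
                {k: float(v) for k, v in self.cpg_slopes.items()}
                if self.cpg_slopes is not None
                else None
            ),
            "ts_true": (
                {k: float(v) for k, v in self.ts_true.items()}
                if self.ts_true is not None
                else None
            ),
            "motif_positions": (
                json.loads(self.motif_positions.to_json(orient="records"))
                if self.motif_positions is not None
                else None
            ),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# Layout and annotation
# ---------------------------------------------------------------------------


def simulate_layout(
    config: SimulationConfig,
) -> tuple[ChromosomeLayout, pd.DataFrame, set]:
    """Chromosomes, gene TSSs with region labels, and an imprinted gene set.

    Chromosomes are equal length with a centred centromere; the config is
    rejected when the subtelomeric and centromere-proximal windows would
    overlap.  TSSs are uniform over the genome; ``fraction_imprinted`` of
    genes get an imprinted label.
    """
    L = config.chrom_length
    cen_lo = L // 2 - config.centromere_halfwidth
    cen_hi = L // 2 + config.centromere_halfwidth
    if cen_lo - CENTROMERE_WINDOW_BP <= SUBTELOMERE_WINDOW_BP or (
        cen_hi + CENTROMERE_WINDOW_BP >= L - SUBTELOMERE_WINDOW_BP
    ):
        raise ValueError(
            f"chromosome length {L} too short for disjoint subtelomeric and "
            "centromeric windows"
        )
    layout = ChromosomeLayout.from_dict(
        {f"chr{i + 1}": (L, cen_lo, cen_hi) for i in range(config.n_chromosomes)}
    )

    rng = config.rng(_STREAM_LAYOUT)
    chrom = rng.integers(0, config.n_chromosomes, size=config.n_genes)
    tss = rng.integers(0, L, size=config.n_genes)
    strand = rng.choice(["+", "-"], size=config.n_genes)
    width = len(str(config.n_genes))
    genes = pd.DataFrame(
        {
            "gene_id": [f"G{i + 1:0{width}d}" for i in range(config.n_genes)],
            "chrom": [f"chr{c + 1}" for c in chrom],
            "tss": tss,
            "strand": strand,
        }
    )
    regions = classify_gene_regions(genes, layout)
    genes["subtelomeric"] = regions["subtelomeric"].to_numpy()
    genes["centromeric"] = regions["centromeric"].to_numpy()

    n_imprinted = int(round(config.fraction_imprinted * config.n_genes))
    imprinted = set(
        rng.choice(genes["gene_id"].to_numpy(), size=n_imprinted, replace=False)
    ) if n_imprinted else set()
    genes["imprinted"] = genes["gene_id"].isin(imprinted)
    return layout, genes, imprinted


# ---------------------------------------------------------------------------
# Cohort: samples + methylation matrix
# ---------------------------------------------------------------------------


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, floor: float, size: int
) -> np.ndarray:
    out = np.empty(size)
    need = np.arange(size)
    while len(need):
        draw = rng.normal(mean, sd, size=len(need))
        ok = draw > floor
        out[need[ok]] = draw[ok]
        need = need[~ok]
    return out


def simulate_cohort(
    config: SimulationConfig,
    layout: ChromosomeLayout,
    genes: pd.DataFrame,
):
    """Sample table, methylation matrix and ground truth.

    For CpG j of a planted gene, M_ij = baseline_j + slope_j * TS_i + noise;
    non-planted CpGs have slope 0.  The slope sign is constant within a gene.
    """
    from .cpg_association import MethylationMatrix

    rng = config.rng(_STREAM_COHORT)
    n = config.n_samples
    ts = _truncated_normal(rng, config.ts_mean, config.ts_sd, config.ts_floor, n)
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    samples = pd.DataFrame({"ts_ratio": ts}, index=pd.Index(sample_ids, name="sample_id"))

    # CpG counts per gene: negative binomial shifted to >= 1 so the per-gene
    # "nearest count" varies (or a fixed count for power studies)
    if config.cpgs_per_gene_fixed:
        counts = np.full(len(genes), int(round(config.cpgs_per_gene_mean)))
    else:
        r = config.cpgs_per_gene_dispersion
        mu = max(config.cpgs_per_gene_mean - 1.0, 1e-9)
        p_nb = r / (r + mu)
        counts = rng.negative_binomial(r, p_nb, size=len(genes)) + 1

    n_planted = int(round(config.fraction_planted_genes * len(genes)))
    planted_idx = (
        rng.choice(len(genes), size=n_planted, replace=False) if n_planted else np.array([], dtype=int)
    )
    gene_slope = np.zeros(len(genes))
    if n_planted:
        sign = rng.choice([-1.0, 1.0], size=n_planted)
        mag = np.abs(rng.normal(config.effect_size_mean, config.effect_size_sd, size=n_planted))
        gene_slope[planted_idx] = sign * mag

    cpg_rows = []
    slopes = []
    gene_of_cpg = []
    for gi, (gene_id, chrom, tss) in enumerate(
        zip(genes["gene_id"], genes["chrom"], genes["tss"])
    ):
        L = layout.length(chrom)
        offs = rng.integers(-config.cpg_spread_bp, config.cpg_spread_bp + 1, size=counts[gi])
        pos = np.clip(tss + offs, 0, L - 1)
        for p in pos:
            cpg_rows.append((chrom, int(p)))
            slopes.append(gene_slope[gi])
            gene_of_cpg.append(gene_id)

    n_cpgs = len(cpg_rows)
    cpg_ids = [f"cg{i + 1:08d}" for i in range(n_cpgs)]
    coords = pd.DataFrame(cpg_rows, columns=["chrom", "pos"], index=pd.Index(cpg_ids, name="cpg_id"))
    slopes = np.asarray(slopes)

    high = rng.random(n_cpgs) < config.baseline_high_weight
    baseline = np.where(
        high,
        rng.normal(config.baseline_high_mean, config.baseline_sd, size=n_cpgs),
        rng.normal(config.baseline_low_mean, config.baseline_sd, size=n_cpgs),
    )
    noise = (
        rng.normal(0.0, config.noise_sd, size=(n_cpgs, n))
        if config.noise_sd > 0
        else np.zeros((n_cpgs, n))
    )
    M = baseline[:, None] + slopes[:, None] * ts[None, :] + noise

    matrix = MethylationMatrix(
        values=pd.DataFrame(M, index=coords.index, columns=samples.index),
        coords=coords,
        value_kind="M",
    )
    truth = GroundTruth(
        planted_genes=set(genes["gene_id"].iloc[planted_idx]),
        gene_slopes={
            genes["gene_id"].iloc[i]: float(gene_slope[i]) for i in planted_idx
        },
        cpg_slopes=pd.Series(slopes, index=coords.index, name="true_slope"),
        ts_true=pd.Series(ts, index=samples.index, name="ts_true"),
    )
    truth.cpg_gene = pd.Series(gene_of_cpg, index=coords.index, name="gene_id")
    return samples, matrix, truth


def simulate_study(config: SimulationConfig):
    """Convenience wrapper: layout + annotation + cohort in one call."""
    layout, genes, imprinted = simulate_layout(config)
    samples, matrix, truth = simulate_cohort(config, layout, genes)
    return layout, genes, imprinted, samples, matrix, truth


# ---------------------------------------------------------------------------
# qPCR plate
# ---------------------------------------------------------------------------


def simulate_qpcr_plate(
    ts_true: Mapping[str, float] | pd.Series,
    curve_params: Mapping[str, tuple[float, float]] = None,
    noise_sd_cq: float = 0.05,
    seed: int = 0,
    input_ng: float = 20.0,
    reference_id: str = "REF",
    n_replicates: int = 2,
) -> pd.DataFrame:
    """One plate: standards for both targets, unknowns in duplicate, NTCs.

    Standards: 5 dilution points spanning 5-50 ng, in triplicate, per target.
    Unknown Cq = intercept + slope * log10(quantity) + N(0, noise_sd_cq),
    where the TEL quantity of a sample is input_ng * its true T/S and the
    SCG quantity is input_ng.  The reference sample is included with true
    T/S = 1, so noise-free plates invert exactly to the supplied truths.
    """
    if curve_params is None:
        curve_params = DEFAULT_CURVE_PARAMS
    for target, (_, slope) in curve_params.items():
        if slope >= 0:
            raise ValueError(f"curve slope for {target} must be negative")
    if noise_sd_cq < 0:
        raise ValueError("noise_sd_cq must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM_PLATE]))

    ts_map = dict(pd.Series(ts_true).items())
    ts_map[reference_id] = 1.0
    dilutions = np.geomspace(5.0, 50.0, 5)

    rows = []
    well = 0

    def cq_for(target: str, quantity: float) -> float:
        intercept, slope = curve_params[target]
        noise = rng.normal(0.0, noise_sd_cq) if noise_sd_cq > 0 else 0.0
        return intercept + slope * np.log10(quantity) + noise

    for target in ("TEL", "SCG"):
        for mass in dilutions:
            for rep in range(3):
                well += 1
                rows.append(
                    (f"W{well:03d}", "STD", target, "standard", float(mass), rep + 1,
                     cq_for(target, mass))
                )
    for target in ("TEL", "SCG"):
        for sample_id, ts in ts_map.items():
            for rep in range(n_replicates):
                well += 1
                quantity = input_ng * ts if target == "TEL" else input_ng
                rows.append(
                    (f"W{well:03d}", sample_id, target, "unknown", np.nan, rep + 1,
                     cq_for(target, quantity))
                )
    for target in ("TEL", "SCG"):
        well += 1
        rows.append((f"W{well:03d}", "", target, "ntc", np.nan, 1, np.nan))

    return pd.DataFrame(
        rows,
        columns=["well", "sample_id", "target", "role", "input_ng", "replicate", "Cq"],
    )


# ---------------------------------------------------------------------------
# Genome with planted motifs
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _class_intervals(layout: ChromosomeLayout, chrom: str) -> dict[str, list[tuple[int, int]]]:
    """Half-open intervals of motif-start positions per region class."""
    L = layout.length(chrom)
    w_t, w_c = SUBTELOMERE_WINDOW_BP, CENTROMERE_WINDOW_BP
    cs = int(layout.table.at[chrom, "cen_start"])
    ce = int(layout.table.at[chrom, "cen_end"])
    last = L - 6  # exclusive bound so the 7-mer fits inside the chromosome
    subtel = [(0, min(w_t + 1, last)), (max(0, L - w_t), last)]
    cen = [(max(0, cs - w_c), min(ce + w_c, last))]
    inter = [(w_t + 1, cs - w_c), (ce + w_c, min(L - w_t, last))]
    clean = lambda ivs: [(a, b) for a, b in ivs if b > a]
    return {"subtelomeric": clean(subtel), "centromeric": clean(cen), "interstitial": clean(inter)}


def simulate_genome(
    layout: ChromosomeLayout,
    n_subtelomeric: int = 7,
    n_centromeric: int = 3,
    n_interstitial: int = 3,
    seed: int = 0,
    max_cleanup_rounds: int = 100,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random chromosomes with an exact number of planted motif occurrences.

    The background is made motif-free on both strands by re-randomising every
    spontaneous 7-mer hit until none remain; motifs (TGCCGCA or TGCCGCG,
    random strand) are then planted at recorded positions with >= 13 bp
    spacing.  Raises when the requested counts cannot fit.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM_GENOME]))
    wanted = {
        "subtelomeric": n_subtelomeric,
        "centromeric": n_centromeric,
        "interstitial": n_interstitial,
    }

    # choose planting sites up front, spread over chromosomes
    chroms = layout.chromosomes
    sites: list[tuple[str, int, str, str]] = []  # chrom, start, strand, region
    intervals = {c: _class_intervals(layout, c) for c in chroms}
    for region, n_needed in wanted.items():
        capacity = sum(
            b - a for c in chroms for a, b in intervals[c][region]
        )
        if n_needed * MIN_MOTIF_SPACING_BP > capacity:
            raise ValueError(
                f"cannot plant {n_needed} motifs in {region} regions "
                f"({capacity} bp available)"
            )
        placed = 0
        attempts = 0
        while placed < n_needed:
            attempts += 1
            if attempts > 1000 * max(n_needed, 1):
                raise ValueError(f"planting density infeasible in {region}")
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            ivs = intervals[chrom][region]
            if not ivs:
                continue
            a, b = ivs[int(rng.integers(0, len(ivs)))]
            pos = int(rng.integers(a, b))
            if any(
                c == chrom and abs(pos - s) < MIN_MOTIF_SPACING_BP
                for c, s, _, _ in sites
            ):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            sites.append((chrom, pos, strand, region))
            placed += 1

    planted = pd.DataFrame(sites, columns=["chrom", "start", "strand", "region"])
    planted["motif"] = [
        ("TGCCGCA" if rng.random() < 0.5 else "TGCCGCG") for _ in range(len(planted))
    ]

    sequences: dict[str, str] = {}
    for chrom in chroms:
        L = layout.length(chrom)
        arr = _random_sequence(rng, L)
        chrom_sites = planted[planted["chrom"] == chrom]
        protected = np.zeros(L, dtype=bool)
        for _, row in chrom_sites.iterrows():
            text = row["motif"] if row["strand"] == "+" else _motif.reverse_complement(row["motif"])
            s = int(row["start"])
            arr[s : s + 7] = np.frombuffer(text.encode(), dtype=np.uint8)
            protected[s : s + 7] = True

        expected = {(int(r["start"]), r["strand"]) for _, r in chrom_sites.iterrows()}
        for _ in range(max_cleanup_rounds):
            seq = arr.tobytes().decode()
            hits = _motif.scan_sequence(chrom, seq)
            stray = [h for h in hits if (h.start, h.strand) not in expected]
            if not stray:
                break
            for h in stray:
                window = np.arange(h.start, h.start + 7)
                editable = window[~protected[window]]
                if len(editable) == 0:  # overlaps a planted site entirely: impossible by spacing
                    raise RuntimeError("stray hit inside protected window")
                arr[editable] = _random_sequence(rng, len(editable))
        else:
            raise RuntimeError("motif cleanup did not converge")
        sequences[chrom] = arr.tobytes().decode()

    planted = planted.sort_values(["chrom", "start"]).reset_index(drop=True)
    return sequences, planted[["chrom", "start", "strand", "region", "motif"]]


# ---------------------------------------------------------------------------
# Writers (plain-text formats only)
# ---------------------------------------------------------------------------


def write_methylation_tsv(matrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t")


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t")


def write_cpg_bed(coords: pd.DataFrame, path: str | Path) -> None:
    bed = pd.DataFrame(
        {
            "chrom": coords["chrom"],
            "start": coords["pos"],
            "end": coords["pos"] + 1,
            "name": coords.index,
        }
    ).sort_values(["chrom", "start"], kind="stable")
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_tss_bed(genes: pd.DataFrame, path: str | Path) -> None:
    bed = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["tss"],
            "end": genes["tss"] + 1,
            "name": genes["gene_id"],
            "score": 0,
            "strand": genes.get("strand", "+"),
        }
    ).sort_values(["chrom", "start"], kind="stable")
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_imprinted_list(imprinted: set, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(imprinted)))


def write_plate_csv(plate: pd.DataFrame, path: str | Path) -> None:
    plate.to_csv(path, index=False)


def write_genome_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def config_to_json(config: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(config), indent=2) + "\n")
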