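"""Positional and imprinted-gene enrichment statistics.

Tests whether genes whose promoter methylation tracks telomere length cluster
near chromosome ends (subtelomeric, within 4 Mb of a telomere) or near
centromeres (within 1.5 Mb of the centromere interval), via Fisher's exact
test on 2x2 tables, and whether they are over-represented among imprinted
genes, via a permutation test matched on each gene's "nearest count" (the
number of array CpGs whose nearest TSS is that gene).  The matching is the
point of the permutation test: imprinted genes sit near unusually many array
probes, so an unmatched null would overstate enrichment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Subtelomeric window: a position within this many bp of either chromosome
#: end is subtelomeric (boundary inclusive).
SUBTELOMERE_WINDOW_BP = 4_000_000

#: Centromeric window: a position within this many bp of the centromere
#: interval (distance 0 inside it) is centromeric (boundary inclusive).
CENTROMERE_WINDOW_BP = 1_500_000


class LayoutError(ValueError):
    """Invalid chromosome layout (bad lengths or centromere intervals)."""


@dataclass
class ChromosomeLayout:
    """Chromosome lengths and centromere intervals.

    ``table`` is indexed by chromosome name with columns ``length``,
    ``cen_start`` and ``cen_end`` (0-based half-open; the centromere columns
    may be NaN for chromosomes without a centromere annotation).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"length", "cen_start", "cen_end"}
        missing = required - set(self.table.columns)
        if missing:
            raise LayoutError(f"layout table missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise LayoutError("duplicate chromosome names in layout")
        if (self.table["length"] <= 0).any():
            raise LayoutError("chromosome lengths must be positive")
        has_cen = self.table["cen_start"].notna()
        sub = self.table.loc[has_cen]
        bad = (
            (sub["cen_start"] < 0)
            | (sub["cen_start"] >= sub["cen_end"])
            | (sub["cen_end"] > sub["length"])
        )
        if bad.any():
            raise LayoutError(
                f"invalid centromere interval on: {list(sub.index[bad])}"
            )

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_dict(
        cls, chroms: Mapping[str, tuple]
    ) -> "ChromosomeLayout":
        """Build from ``{name: (length,)}`` or ``{name: (length, cen_start, cen_end)}``."""
        rows = {}
        for name, vals in chroms.items():
            if len(vals) == 1:
                rows[name] = (int(vals[0]), np.nan, np.nan)
            else:
                rows[name] = (int(vals[0]), float(vals[1]), float(vals[2]))
        table = pd.DataFrame.from_dict(
            rows, orient="index", columns=["length", "cen_start", "cen_end"]
        )
        table.index.name = "chrom"
        return cls(table)

    @classmethod
    def from_files(
        cls, chrom_sizes: str | Path, centromeres_bed: str | Path | None = None
    ) -> "ChromosomeLayout":
        """Read a UCSC-style chrom.sizes file and an optional centromere BED."""
        sizes = pd.read_csv(
            chrom_sizes, sep="\t", header=None, names=["chrom", "length"]
        ).set_index("chrom")
        table = sizes.assign(cen_start=np.nan, cen_end=np.nan)
        if centromeres_bed is not None:
            cen = pd.read_csv(
                centromeres_bed,
                sep="\t",
                header=None,
                usecols=[0, 1, 2],
                names=["chrom", "start", "end"],
            )
            for _, row in cen.iterrows():
                if row["chrom"] in table.index:
                    table.loc[row["chrom"], ["cen_start", "cen_end"]] = (
                        float(row["start"]),
                        float(row["end"]),
                    )
        return cls(table)

    def write(
        self, chrom_sizes: str | Path, centromeres_bed: str | Path | None = None
    ) -> None:
        self.table["length"].to_csv(chrom_sizes, sep="\t", header=False)
        if centromeres_bed is not None:
            has_cen = self.table["cen_start"].notna()
            bed = self.table.loc[has_cen, ["cen_start", "cen_end"]].astype(int)
            bed.to_csv(centromeres_bed, sep="\t", header=False)

    # -- geometry -----------------------------------------------------------

    @property
    def chromosomes(self) -> list[str]:
        return list(self.table.index)

    @property
    def genome_size(self) -> int:
        return int(self.table["length"].sum())

    def length(self, chrom: str) -> int:
        return int(self.table.at[chrom, "length"])

    def has_centromere(self, chrom: str) -> bool:
        return bool(pd.notna(self.table.at[chrom, "cen_start"]))

    def telomere_distance(self, chrom: str, pos) -> np.ndarray | float:
        """Distance to the nearer chromosome end: ``min(pos, length - pos)``."""
        length = self.length(chrom)
        pos = np.asarray(pos)
        return np.minimum(pos, length - pos)

    def centromere_distance(self, chrom: str, pos) -> np.ndarray | float:
        """Distance to the centromere interval; 0 inside, NaN if unannotated.

        The interval is half-open: the last centromeric base is ``cen_end - 1``.
        """
        pos = np.asarray(pos, dtype=float)
        if not self.has_centromere(chrom):
            return np.full_like(pos, np.nan, dtype=float)
        cs = float(self.table.at[chrom, "cen_start"])
        ce = float(self.table.at[chrom, "cen_end"])
        below = np.maximum(cs - pos, 0.0)
        above = np.maximum(pos - (ce - 1.0), 0.0)
        return np.maximum(below, above)


def classify_gene_regions(
    genes: pd.DataFrame,
    layout: ChromosomeLayout,
    telomere_window: int = SUBTELOMERE_WINDOW_BP,
    centromere_window: int = CENTROMERE_WINDOW_BP,
) -> pd.DataFrame:
    """Label each gene subtelomeric / centromeric by TSS position.

    Parameters
    ----------
    genes
        DataFrame with columns ``gene_id``, ``chrom``, ``tss``.
    layout
        Chromosome lengths and centromere intervals.

    Returns a DataFrame indexed like ``genes`` with boolean ``subtelomeric``
    and nullable-boolean ``centromeric`` (NA when the chromosome has no
    centromere annotation; such genes are excluded from centromere tests),
    plus the underlying distances.  Both window boundaries are inclusive.
    """
    out = genes[["gene_id", "chrom", "tss"]].copy()
    tel_d = np.empty(len(out), dtype=float)
    cen_d = np.empty(len(out), dtype=float)
    for chrom, idx in out.groupby("chrom").groups.items():
        if chrom not in layout.table.index:
            raise LayoutError(f"chromosome {chrom!r} absent from layout")
        pos = out.loc[idx, "tss"].to_numpy()
        length = layout.length(chrom)
        if (pos < 0).any() or (pos >= length).any():
            raise ValueError(f"TSS outside chromosome bounds on {chrom}")
        tel_d[out.index.get_indexer(idx)] = layout.telomere_distance(chrom, pos)
        cen_d[out.index.get_indexer(idx)] = layout.centromere_distance(chrom, pos)
    out["telomere_distance"] = tel_d
    out["centromere_distance"] = cen_d
    out["subtelomeric"] = out["telomere_distance"] <= telomere_window
    centro = pd.array(out["centromere_distance"] <= centromere_window, dtype="boolean")
    centro[out["centromere_distance"].isna().to_numpy()] = pd.NA
    out["centromeric"] = centro
    n_na = int(out["centromeric"].isna().sum())
    if n_na:
        logger.warning(
            "%d genes on chromosomes without centromere annotation; "
            "excluded from centromere tests",
            n_na,
        )
    return out


# ---------------------------------------------------------------------------
# Fisher's exact test on 2x2 tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float  # conditional MLE; NaN when undefined (zero margin)
    p_value: float


def build_contingency(in_class: pd.Series, significant: pd.Series) -> np.ndarray:
    """2x2 table [[in&sig, in&not], [out&sig, out&not]] from aligned booleans."""
    in_class, significant = in_class.align(significant, join="inner")
    a = int((in_class & significant).sum())
    b = int((in_class & ~significant).sum())
    c = int((~in_class & significant).sum())
    d = int((~in_class & ~significant).sum())
    return np.array([[a, b], [c, d]], dtype=int)


def fisher_enrichment(
    table: np.ndarray, alternative: str = "two-sided"
) -> FisherResult:
    """Fisher's exact test; zero-margin tables return p = 1, OR = NaN."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("contingency table must be 2x2 with non-negative counts")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return FisherResult(odds_ratio=float("nan"), p_value=1.0)
    _, p = stats.fisher_exact(table, alternative=alternative)
    try:
        orr = stats.contingency.odds_ratio(table, kind="conditional").statistic
    except ValueError:
        orr = float("nan")
    return FisherResult(odds_ratio=float(orr), p_value=float(p))


def positional_enrichment_tests(
    regions: pd.DataFrame,
    significant_sets: Mapping[str, Iterable[str]],
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Subtelomere and centromere Fisher tests for each significant gene set.

    ``regions`` is the output of :func:`classify_gene_regions` over the
    universe of tested genes; ``significant_sets`` maps a label (e.g.
    ``"positive"``, ``"negative"``, ``"all"``) to the gene ids called
    significant.  Returns one row per (set, region class).
    """
    rows = []
    universe = regions.set_index("gene_id")
    for name, genes in significant_sets.items():
        sig = pd.Series(universe.index.isin(set(genes)), index=universe.index)
        for region in ("subtelomeric", "centromeric"):
            labels = universe[region]
            mask = labels.notna()
            table = build_contingency(
                labels[mask].astype(bool), sig[mask].astype(bool)
            )
            res = fisher_enrichment(table, alternative=alternative)
            rows.append(
                {
                    "gene_set": name,
                    "region": region,
                    "n_in_sig": table[0, 0],
                    "n_in_not": table[0, 1],
                    "n_out_sig": table[1, 0],
                    "n_out_not": table[1, 1],
                    "odds_ratio": res.odds_ratio,
                    "p_value": res.p_value,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Nearest counts and the matched permutation test
# ---------------------------------------------------------------------------


def nearest_counts(cpg_map: pd.DataFrame, universe: Iterable[str]) -> pd.Series:
    """Per-gene count of CpGs whose nearest TSS is that gene.

    ``cpg_map`` is the output of ``promoter_enrichment.assign_nearest_tss``.
    Genes in ``universe`` with no assigned CpG get count 0; the counts sum to
    the number of assigned CpGs in the universe.
    """
    assigned = cpg_map["gene_id"].dropna()
    counts = assigned.value_counts()
    universe = list(universe)
    out = counts.reindex(universe, fill_value=0).astype(int)
    out.name = "nearest_count"
    return out


@dataclass
class PermutationResult:
    observed: int
    n_permutations: int
    null_mean: float
    null_max: int
    p_value: float
    seed: int
    n_strata: int
    widened: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "n_permutations": self.n_permutations,
            "null_mean": self.null_mean,
            "null_max": self.null_max,
            "p_value": self.p_value,
            "seed": self.seed,
            "n_strata": self.n_strata,
            "widened": list(self.widened),
        }


def _count_bin(c: int) -> int:
    # doubling bins over nearest counts: 0 | 1 | 2 | 3-4 | 5-8 | 9-16 | ...
    if c <= 0:
        return -1
    return int(math.ceil(math.log2(c))) if c > 1 else 0


def _build_strata(
    counts: pd.Series, observed: Sequence[str], min_exact: int = 5
) -> tuple[list[tuple[np.ndarray, int]], list[str]]:
    """Partition the universe into nearest-count strata and tally draws.

    A count value with >= ``min_exact`` universe genes forms its own exact
    stratum; remaining genes fall into doubling count bins.  Returns
    ``[(member gene-id array, n_draws), ...]`` for strata with at least one
    draw, plus a log of any bin widenings.
    """
    vc = counts.value_counts()
    exact = {int(c) for c, n in vc.items() if n >= min_exact}

    def key(c: int):
        c = int(c)
        return ("exact", c) if c in exact else ("bin", _count_bin(c))

    members: dict[tuple, list[str]] = {}
    for gene, c in counts.items():
        members.setdefault(key(c), []).append(gene)
    needed: dict[tuple, int] = {}
    for gene in observed:
        k = key(counts[gene])
        needed[k] = needed.get(k, 0) + 1

    widened: list[str] = []
    # Guard: merge an undersized bin into its nearest neighbouring bin.  With
    # observed genes drawn from the universe this cannot trigger, but external
    # callers may pass a foreign significant set.
    bin_keys = sorted(k for k in set(members) | set(needed) if k[0] == "bin")
    for k in list(needed):
        if k[0] != "bin":
            continue
        while needed.get(k, 0) > len(members.get(k, [])):
            pos = bin_keys.index(k)
            neighbour = bin_keys[pos - 1] if pos > 0 else bin_keys[pos + 1]
            members.setdefault(k, []).extend(members.pop(neighbour, []))
            needed[k] = needed.get(k, 0) + needed.pop(neighbour, 0)
            bin_keys.remove(neighbour)
            widened.append(f"merged stratum {neighbour} into {k}")
            logger.warning("widened nearest-count stratum: %s -> %s", neighbour, k)

    strata = [
        (np.asarray(members[k], dtype=object), needed[k])
        for k in needed
        if needed[k] > 0
    ]
    return strata, widened


def imprinted_permutation_test(
    significant_genes: Iterable[str],
    counts: pd.Series,
    imprinted_genes: Iterable[str],
    n_permutations: int = 100_000,
    seed: int = 0,
    min_exact_stratum: int = 5,
) -> PermutationResult:
    """Matched permutation test for imprinted-gene excess.

    Repeatedly draws gene sets of the same size and nearest-count distribution
    as the significant set (one universe gene per significant gene from the
    same nearest-count stratum, without replacement within a draw) and counts
    imprinted members.  Because strata partition the universe, the imprinted
    count of each stratum's without-replacement draw is a hypergeometric
    variate, which is what is sampled.  p uses the add-one estimator
    ``(1 + #{null >= observed}) / (1 + n_permutations)`` and is never 0.
    """
    significant = list(dict.fromkeys(significant_genes))
    if n_permutations < 1_000:
        raise ValueError("n_permutations must be >= 1000")
    missing = [g for g in significant if g not in counts.index]
    if missing:
        raise ValueError(f"significant genes absent from universe: {missing[:5]}")
    imprinted = set(imprinted_genes)
    observed = sum(1 for g in significant if g in imprinted)

    strata, widened = _build_strata(counts, significant, min_exact_stratum)
    rng = np.random.default_rng(seed)
    null = np.zeros(n_permutations, dtype=np.int64)
    for member_genes, k in strata:
        ngood = int(sum(1 for g in member_genes if g in imprinted))
        nbad = len(member_genes) - ngood
        null += rng.hypergeometric(ngood, nbad, k, size=n_permutations)

    p = (1 + int((null >= observed).sum())) / (1 + n_permutations)
    return PermutationResult(
        observed=observed,
        n_permutations=n_permutations,
        null_mean=float(null.mean()),
        null_max=int(null.max()),
        p_value=float(p),
        seed=seed,
        n_strata=len(strata),
        widened=widened,
    )
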