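"""Gene-promoter enrichment from per-CpG association statistics.

The discovery procedure: each array CpG is assigned to the gene with the
nearest TSS within 10 kb; for each gene, the t-statistics of its CpGs are
compared with those of all other CpGs by a two-sided Wilcoxon rank-sum test;
gene p-values are converted to Q values by Benjamini-Hochberg; and an
individual CpG is called a significant site when its gene's Q < 0.05 and its
own unadjusted p < 0.05, signed by the direction of its t-statistic.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MAX_TSS_DISTANCE_BP = 10_000

#: Largest combined sample size at which the rank-sum p is computed by exact
#: enumeration; above it, normal approximation with tie and continuity
#: correction.
EXACT_RANKSUM_MAX_N = 25


def tss_positions(genes: pd.DataFrame) -> pd.Series:
    """TSS per gene: ``start`` for + strand, ``end - 1`` for - strand.

    Accepts a frame with an explicit ``tss`` column, or with
    ``start``/``end``/``strand`` (BED-style half-open intervals).
    """
    if "tss" in genes.columns:
        return genes["tss"].astype(int)
    minus = genes["strand"] == "-"
    tss = genes["start"].where(~minus, genes["end"] - 1)
    return tss.astype(int)


def assign_nearest_tss(
    cpgs: pd.DataFrame,
    genes: pd.DataFrame,
    max_distance: int = MAX_TSS_DISTANCE_BP,
) -> pd.DataFrame:
    """Assign each CpG to the gene with the nearest TSS within ``max_distance``.

    Parameters
    ----------
    cpgs
        DataFrame indexed by CpG id with columns ``chrom``, ``pos``.
    genes
        DataFrame with ``gene_id``, ``chrom`` and either ``tss`` or
        ``start``/``end``/``strand``.
    max_distance
        Assignment requires |cpg - tss| <= this (a TSS 10,001 bp away is out).

    Ties (two genes exactly equidistant, including co-located TSSs) go to the
    lexicographically smallest gene id, which is deterministic and
    independent of annotation row order.  CpGs on chromosomes absent from
    the annotation are left unassigned and counted in a log summary.

    Returns a DataFrame indexed by CpG id with ``gene_id`` (None when
    unassigned) and signed ``distance`` (cpg pos - tss; NaN when unassigned).
    """
    genes = genes.assign(_tss=tss_positions(genes))
    gene_id = np.full(len(cpgs), None, dtype=object)
    distance = np.full(len(cpgs), np.nan)

    n_no_chrom = 0
    cpg_pos_all = cpgs["pos"].to_numpy()
    for chrom, idx in cpgs.groupby("chrom").groups.items():
        rows = cpgs.index.get_indexer(idx)
        sub = genes[genes["chrom"] == chrom]
        if sub.empty:
            n_no_chrom += len(rows)
            continue
        # per unique TSS position keep the lexicographically smallest gene id
        best = sub.groupby("_tss")["gene_id"].min()
        positions = best.index.to_numpy()
        ids = best.to_numpy()
        pos = cpg_pos_all[rows]
        right = np.searchsorted(positions, pos)
        left = right - 1
        left_ok = left >= 0
        right_ok = right < len(positions)
        d_left = np.where(left_ok, np.abs(pos - positions[np.clip(left, 0, None)]), np.inf)
        d_right = np.where(
            right_ok, np.abs(positions[np.clip(right, None, len(positions) - 1)] - pos), np.inf
        )
        take_left = (d_left < d_right) | (
            (d_left == d_right)
            & left_ok
            & right_ok
            & (ids[np.clip(left, 0, None)] <= ids[np.clip(right, None, len(positions) - 1)])
        )
        nearest_idx = np.where(take_left, np.clip(left, 0, None), np.clip(right, None, len(positions) - 1))
        d = np.minimum(d_left, d_right)
        within = d <= max_distance
        sel = rows[within]
        gene_id[sel] = ids[nearest_idx[within]]
        tss_sel = positions[nearest_idx[within]]
        distance[sel] = pos[within] - tss_sel

    if n_no_chrom:
        logger.warning(
            "%d CpGs on chromosomes absent from the annotation left unassigned",
            n_no_chrom,
        )
    out = pd.DataFrame({"gene_id": gene_id, "distance": distance}, index=cpgs.index)
    out.index.name = "cpg_id"
    return out


# ---------------------------------------------------------------------------
# Gene-level Wilcoxon rank-sum enrichment
# ---------------------------------------------------------------------------


def _ranksum_normal_p(
    u1: np.ndarray, n1: np.ndarray, n_total: int, tie_term: float
) -> np.ndarray:
    """Two-sided normal-approximation p for Mann-Whitney U with tie and
    continuity corrections; degenerate (zero-variance) inputs get p = 1."""
    n2 = n_total - n1
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n_total + 1) - tie_term / (n_total * (n_total - 1.0)))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (u1 - mu - 0.5 * np.sign(u1 - mu)) / np.sqrt(var)
    p = np.where(var > 0, 2 * stats.norm.sf(np.abs(z)), 1.0)
    return np.minimum(p, 1.0)


def test_gene_enrichment(
    associations: pd.DataFrame,
    cpg_map: pd.DataFrame,
    include_unassigned_background: bool = True,
    exact_max_n: int = EXACT_RANKSUM_MAX_N,
) -> pd.DataFrame:
    """Wilcoxon rank-sum test of each gene's CpG t-statistics vs the rest.

    ``associations`` is the per-CpG fit table (needs column ``t``);
    ``cpg_map`` the nearest-TSS assignment.  The background for a gene is
    every other CpG with a defined t — including CpGs assigned to no gene
    unless ``include_unassigned_background`` is off.  Genes with zero
    assigned CpGs are absent from the output; all-tied degenerate input
    yields p = 1.

    Returns a DataFrame indexed by gene id with ``n_cpgs`` and ``wilcoxon_p``.
    """
    t = associations["t"]
    gene = cpg_map["gene_id"].reindex(t.index)
    defined = t.notna()
    if include_unassigned_background:
        universe = defined
    else:
        universe = defined & gene.notna()
    t_u = t[universe].to_numpy()
    gene_u = gene[universe]
    n_total = len(t_u)
    if n_total == 0:
        return pd.DataFrame(columns=["n_cpgs", "wilcoxon_p"])

    ranks = stats.rankdata(t_u)
    _, tie_counts = np.unique(t_u, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    has_ties = bool((tie_counts > 1).any())

    grouped = pd.DataFrame({"gene": gene_u.to_numpy(), "rank": ranks}).dropna(
        subset=["gene"]
    )
    agg = grouped.groupby("gene")["rank"].agg(["count", "sum"])
    n1 = agg["count"].to_numpy(dtype=float)
    u1 = agg["sum"].to_numpy() - n1 * (n1 + 1) / 2.0

    p = _ranksum_normal_p(u1, n1, n_total, tie_term)

    if n_total <= exact_max_n and not has_ties:
        # small enough for the exact null distribution of U
        for i, g in enumerate(agg.index):
            in_gene = gene_u.to_numpy() == g
            res = stats.mannwhitneyu(
                t_u[in_gene], t_u[~in_gene], alternative="two-sided", method="exact"
            )
            p[i] = min(float(res.pvalue), 1.0)

    out = pd.DataFrame(
        {"n_cpgs": agg["count"].astype(int), "wilcoxon_p": p}, index=agg.index
    )
    out.index.name = "gene_id"
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values; NaN inputs
    give NaN and are excluded from m.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(pv)
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    adj = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    qv = np.empty(m)
    qv[order] = np.minimum(adj, 1.0)
    q[ok] = qv
    return q


def call_significant_sites(
    associations: pd.DataFrame,
    cpg_map: pd.DataFrame,
    gene_results: pd.DataFrame,
    gene_q_threshold: float = 0.05,
    site_p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Dual-threshold site calls: gene Q < gene_q AND site p < site_p.

    Both thresholds are strict (a gene at Q exactly 0.05 yields no sites).
    Returns a DataFrame with ``cpg_id``, ``gene_id``, ``direction``
    (``positive``/``negative`` by sign of t), ``t``, ``p``.
    """
    for name, thr in (("gene_q_threshold", gene_q_threshold), ("site_p_threshold", site_p_threshold)):
        if not 0 < thr < 1:
            raise ValueError(f"{name} must be in (0, 1)")
    if "q_value" not in gene_results.columns:
        raise ValueError("gene_results must carry a q_value column (run bh_fdr)")
    sig_genes = set(gene_results.index[gene_results["q_value"] < gene_q_threshold])
    df = associations[["t", "p_value"]].copy()
    df["gene_id"] = cpg_map["gene_id"].reindex(df.index)
    keep = (
        df["gene_id"].notna()
        & df["gene_id"].isin(sig_genes)
        & df["p_value"].notna()
        & (df["p_value"] < site_p_threshold)
    )
    df = df[keep]
    out = pd.DataFrame(
        {
            "cpg_id": df.index,
            "gene_id": df["gene_id"].to_numpy(),
            "direction": np.where(df["t"] > 0, "positive", "negative"),
            "t": df["t"].to_numpy(dtype=float),
            "p": df["p_value"].to_numpy(dtype=float),
        }
    )
    return out.reset_index(drop=True)


def gene_site_counts(
    sites: pd.DataFrame, gene_results: pd.DataFrame
) -> pd.DataFrame:
    """Attach per-gene positive/negative site counts and a sign class.

    A gene with sites of both signs is classed ``mixed`` and counted in both
    tallies downstream.
    """
    out = gene_results.copy()
    out["n_sites_positive"] = 0
    out["n_sites_negative"] = 0
    if len(sites):
        pos = sites[sites["direction"] == "positive"]["gene_id"].value_counts()
        neg = sites[sites["direction"] == "negative"]["gene_id"].value_counts()
        out.loc[pos.index, "n_sites_positive"] = pos.to_numpy()
        out.loc[neg.index, "n_sites_negative"] = neg.to_numpy()
    def classify(row):
        if row["n_sites_positive"] and row["n_sites_negative"]:
            return "mixed"
        if row["n_sites_positive"]:
            return "positive"
        if row["n_sites_negative"]:
            return "negative"
        return "none"
    out["sign_class"] = out.apply(classify, axis=1)
    return out


def summarize_counts(sites: pd.DataFrame, gene_results: pd.DataFrame) -> dict:
    """Cohort summary: associated genes and signed site counts with percentages.

    Percentages are of all associated sites, rounded to whole percent and
    formatted like ``"364 (78%)"``; with zero sites they are reported as NA.
    """
    n_pos = int((sites["direction"] == "positive").sum()) if len(sites) else 0
    n_neg = int((sites["direction"] == "negative").sum()) if len(sites) else 0
    total = n_pos + n_neg
    genes_with_sites = sites["gene_id"].nunique() if len(sites) else 0

    def fmt(n: int) -> str:
        if total == 0:
            return f"{n} (NA)"
        return f"{n} ({round(100 * n / total)}%)"

    return {
        "n_genes_associated": int(genes_with_sites),
        "n_genes_tested": int(len(gene_results)),
        "n_sites_total": total,
        "n_sites_positive": n_pos,
        "n_sites_negative": n_neg,
        "pct_positive": round(100 * n_pos / total) if total else None,
        "pct_negative": round(100 * n_neg / total) if total else None,
        "positive_formatted": fmt(n_pos),
        "negative_formatted": fmt(n_neg),
    }


def enrichment_table(
    gene_results: pd.DataFrame, sites: pd.DataFrame
) -> pd.DataFrame:
    """Full gene-enrichment table (n_cpgs, p, q, signed site counts)."""
    return gene_site_counts(sites, gene_results)
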