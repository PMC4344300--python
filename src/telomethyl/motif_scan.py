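"""Genome-wide scan for the methyl-sensitive Zfp57 recognition motif.

Zfp57 binds the methylated form of TGCCGC[A/G].  This module finds every
occurrence of that 7-mer on both strands of a genome (methylation status is
not assessed), classifies hits as subtelomeric / centromeric, and tests
regional enrichment or depletion with a hypergeometric tail computed in log
space so genome-scale tails (p << 1e-300) survive.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .positional_stats import (
    CENTROMERE_WINDOW_BP,
    SUBTELOMERE_WINDOW_BP,
    ChromosomeLayout,
)

MOTIF = "TGCCGC[AG]"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Overlapping matches via lookahead.  Reverse-strand occurrences are found as
# the reverse complement pattern on the forward text: revcomp(TGCCGC[AG]) =
# [TC]GCGGCA.
_FWD_RE = re.compile(r"(?=(TGCCGC[AG]))")
_REV_RE = re.compile(r"(?=([TC]GCGGCA))")
_INVALID_RE = re.compile(r"[^ACGTN]")

#: Primary-assembly chromosome names accepted when scanning a real genome.
PRIMARY_CHROMOSOMES = tuple(
    [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]
)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# The motif is non-palindromic, so a forward and a reverse hit can never be
# the same 7-mer and nothing is double-counted.
for _m in ("TGCCGCA", "TGCCGCG"):
    assert reverse_complement(_m) != _m, "motif unexpectedly palindromic"


class MotifHit(NamedTuple):
    chrom: str
    start: int  # 0-based forward-strand start of the 7-mer window
    strand: str  # "+" or "-"
    motif: str  # the matched motif in TGCCGC[AG] orientation


def scan_sequence(chrom: str, sequence: str) -> list[MotifHit]:
    """All motif occurrences in one sequence, both strands.

    Case-insensitive (soft-masked bases are scanned); N never matches.
    Raises ``ValueError`` naming the first non-nucleotide character.
    """
    seq = str(sequence).upper()
    bad = _INVALID_RE.search(seq)
    if bad:
        raise ValueError(
            f"non-nucleotide character {bad.group()!r} at {chrom}:{bad.start()}"
        )
    hits = [MotifHit(chrom, m.start(), "+", m.group(1)) for m in _FWD_RE.finditer(seq)]
    hits += [
        MotifHit(chrom, m.start(), "-", reverse_complement(m.group(1)))
        for m in _REV_RE.finditer(seq)
    ]
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_motif(
    sequences: "Mapping[str, str] | str | Path",
    primary_only: bool = False,
) -> pd.DataFrame:
    """Scan a genome for TGCCGC[A/G] on both strands.

    ``sequences`` is a mapping of chromosome name to sequence, or a FASTA
    path (read with pyfaidx).  With ``primary_only`` set, only chr1-22/X/Y
    are scanned (the convention for real assemblies, where unplaced and alt
    contigs would otherwise inflate counts).

    Returns a DataFrame with columns ``chrom``, ``start``, ``strand``,
    ``motif``; reverse-strand hits are anchored at the forward-strand start
    of the 7-mer window (half-open [start, start+7)).
    """
    if isinstance(sequences, (str, Path)):
        import pyfaidx

        fasta = pyfaidx.Fasta(str(sequences))
        items = ((name, str(fasta[name][:])) for name in fasta.keys())
    else:
        items = sequences.items()

    rows: list[MotifHit] = []
    for chrom, seq in items:
        if primary_only and chrom not in PRIMARY_CHROMOSOMES:
            continue
        rows.extend(scan_sequence(chrom, seq))
    return pd.DataFrame(rows, columns=["chrom", "start", "strand", "motif"])


def hits_to_bed(hits: pd.DataFrame, path: str | Path) -> None:
    """Write hits as BED6 (0-based half-open, score 0)."""
    bed = pd.DataFrame(
        {
            "chrom": hits["chrom"],
            "start": hits["start"],
            "end": hits["start"] + 7,
            "name": hits["motif"],
            "score": 0,
            "strand": hits["strand"],
        }
    ).sort_values(["chrom", "start", "strand"], kind="stable")
    bed.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Regional counts and hypergeometric tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionCounts:
    total: int
    subtelomeric: int
    centromeric: int
    subtelomere_size: int  # bp classified subtelomeric across the genome
    centromere_size: int  # bp classified centromeric (annotated chroms only)
    genome_size: int
    n_hits_without_centromere: int  # hits excluded from centromere class


def _interval_positions(lo: float, hi: float, length: int) -> int:
    """Number of integer positions p in [0, length) with lo <= p <= hi."""
    a = max(0, math.ceil(lo))
    b = min(length - 1, math.floor(hi))
    return max(0, b - a + 1)


def _subtelomere_size(length: int, window: int) -> int:
    # positions with min(p, length - p) <= window
    left = _interval_positions(0, window, length)
    right = _interval_positions(length - window, length - 1, length)
    overlap = _interval_positions(max(0, length - window), min(window, length - 1), length)
    return left + right - overlap


def _centromere_size(length: int, cs: float, ce: float, window: int) -> int:
    # positions within `window` of the half-open interval [cs, ce)
    return _interval_positions(cs - window, ce - 1 + window, length)


def count_regions(
    hits: pd.DataFrame,
    layout: ChromosomeLayout,
    telomere_window: int = SUBTELOMERE_WINDOW_BP,
    centromere_window: int = CENTROMERE_WINDOW_BP,
) -> RegionCounts:
    """Classify hits by region and compute the matching region sizes.

    A hit is subtelomeric iff its start is within ``telomere_window`` of
    either chromosome end, centromeric iff within ``centromere_window`` of
    the centromere interval.  Hits on chromosomes without a centromere
    annotation are excluded from the centromere classification (counted and
    reported, never silently dropped from the total).
    """
    unknown = set(hits["chrom"]) - set(layout.chromosomes)
    if unknown:
        raise ValueError(f"hits on chromosomes absent from layout: {sorted(unknown)}")

    n_subtel = 0
    n_cen = 0
    n_no_cen = 0
    for chrom, group in hits.groupby("chrom"):
        pos = group["start"].to_numpy()
        n_subtel += int((layout.telomere_distance(chrom, pos) <= telomere_window).sum())
        if layout.has_centromere(chrom):
            cen_d = layout.centromere_distance(chrom, pos)
            n_cen += int((cen_d <= centromere_window).sum())
        else:
            n_no_cen += len(group)

    subtel_size = 0
    cen_size = 0
    for chrom in layout.chromosomes:
        length = layout.length(chrom)
        subtel_size += _subtelomere_size(length, telomere_window)
        if layout.has_centromere(chrom):
            cs = float(layout.table.at[chrom, "cen_start"])
            ce = float(layout.table.at[chrom, "cen_end"])
            cen_size += _centromere_size(length, cs, ce, centromere_window)

    return RegionCounts(
        total=int(len(hits)),
        subtelomeric=n_subtel,
        centromeric=n_cen,
        subtelomere_size=subtel_size,
        centromere_size=cen_size,
        genome_size=layout.genome_size,
        n_hits_without_centromere=n_no_cen,
    )


@dataclass(frozen=True)
class RegionTestResult:
    p_value: float  # may underflow to 0.0; use log10_p for extreme tails
    log10_p: float
    alternative: str


def hypergeometric_region_test(
    region_hits: int,
    total_hits: int,
    region_size: int,
    genome_size: int,
    alternative: str = "enriched",
) -> RegionTestResult:
    """Hypergeometric tail test for regional motif enrichment/depletion.

    Population = genome positions, successes = region positions, draws =
    total hits, observed = region hits.  ``enriched`` tests P(X >= observed),
    ``depleted`` tests P(X <= observed); both are evaluated in log space.
    """
    if region_hits > total_hits:
        raise ValueError("region_hits cannot exceed total_hits")
    if region_size > genome_size:
        raise ValueError("region_size cannot exceed genome_size")
    if region_size == 0:
        import warnings

        warnings.warn("degenerate region of size 0; p = 1", stacklevel=2)
        return RegionTestResult(1.0, 0.0, alternative)
    dist = stats.hypergeom(genome_size, region_size, total_hits)
    if alternative == "enriched":
        log_p = dist.logsf(region_hits - 1)
    elif alternative == "depleted":
        log_p = dist.logcdf(region_hits)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    log_p = float(min(log_p, 0.0))
    return RegionTestResult(
        p_value=float(np.exp(log_p)),
        log10_p=log_p / math.log(10),
        alternative=alternative,
    )


def region_report(
    hits: pd.DataFrame,
    layout: ChromosomeLayout,
    telomere_window: int = SUBTELOMERE_WINDOW_BP,
    centromere_window: int = CENTROMERE_WINDOW_BP,
) -> dict:
    """Counts plus subtelomeric-enrichment and centromeric-depletion tests."""
    counts = count_regions(hits, layout, telomere_window, centromere_window)
    subtel = hypergeometric_region_test(
        counts.subtelomeric, counts.total, counts.subtelomere_size,
        counts.genome_size, "enriched",
    )
    cen = hypergeometric_region_test(
        counts.centromeric, counts.total, counts.centromere_size,
        counts.genome_size, "depleted",
    )
    return {
        "total_hits": counts.total,
        "subtelomeric_hits": counts.subtelomeric,
        "centromeric_hits": counts.centromeric,
        "subtelomere_size_bp": counts.subtelomere_size,
        "centromere_size_bp": counts.centromere_size,
        "genome_size_bp": counts.genome_size,
        "hits_without_centromere_annotation": counts.n_hits_without_centromere,
        "subtelomere_enrichment": {
            "p_value": subtel.p_value,
            "log10_p": subtel.log10_p,
        },
        "centromere_depletion": {"p_value": cen.p_value, "log10_p": cen.log10_p},
    }


def write_region_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
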