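"""Gene-diversity (expected-heterozygosity) genome scans across cycles.

Gene diversity of a biallelic SNP at allele frequency p is
``D = 1 - (p^2 + q^2) = 2pq`` (maximum 0.5).  The scan tracks D per SNP per
selection cycle, summarizes genome-wide and regional reductions, and offers
the neutral-drift closed form ``D_t = D_0 (1 - 1/(2 Ne))^t`` for
comparison.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genio import AlleleFrequencyTable

__all__ = [
    "GenomicRegion",
    "DiversityScan",
    "gene_diversity",
    "diversity_scan",
    "region_reduction_summary",
    "expected_drift_diversity",
    "wqs_regions",
]


def gene_diversity(p):
    """D = 1 - (p^2 + q^2) for allele frequency p (scalar or array)."""
    p = np.asarray(p, dtype=float)
    if np.any((p[~np.isnan(p)] < 0) | (p[~np.isnan(p)] > 1)):
        raise ValueError("allele frequency must lie in [0, 1]")
    d = 1.0 - (p ** 2 + (1.0 - p) ** 2)
    return float(d) if d.ndim == 0 else d


@dataclass(frozen=True)
class GenomicRegion:
    """A 1-based, inclusive physical interval on one chromosome."""

    chromosome: str
    start_bp: int
    end_bp: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")


def wqs_regions(half_width_bp: int = 15_000_000) -> list[GenomicRegion]:
    """Default high-diversity-loss regions: windows centered on ~132 Mbp of
    chromosome 2, ~55 Mbp of chromosome 3 and ~78 Mbp of chromosome 4."""
    centers = [("chr2", 132_000_000), ("chr3", 55_000_000), ("chr4", 78_000_000)]
    return [
        GenomicRegion(c, max(1, m - half_width_bp), m + half_width_bp,
                      label=f"{c}:{m // 1_000_000}Mb")
        for c, m in centers
    ]


@dataclass
class DiversityScan:
    """Per-SNP, per-cycle gene diversity with genome-wide summaries.

    ``d`` is a DataFrame indexed by locus id with one column per cycle;
    ``summary`` holds each cycle's genome-wide mean and SD of D (plain
    averages over loci with a defined frequency).
    """

    d: pd.DataFrame
    summary: pd.DataFrame
    loci: pd.DataFrame | None = None  # id, chromosome, bp when available

    @property
    def cycles(self) -> list[str]:
        return list(self.d.columns)

    def write(self, path) -> None:
        out = self.d.reset_index()
        if self.loci is not None:
            meta = self.loci.set_index("id")
            out.insert(1, "chromosome", meta["chromosome"].reindex(self.d.index).to_numpy())
            out.insert(2, "bp", meta["bp"].reindex(self.d.index).to_numpy())
        out.to_csv(path, sep="\t", index=False)


def diversity_scan(freqs: AlleleFrequencyTable, cycles: Sequence[str],
                   loci: pd.DataFrame | None = None) -> DiversityScan:
    """Gene diversity locus-wise for each requested cycle, plus per-cycle
    genome-wide mean and SD."""
    cycles = list(cycles)
    for c in cycles:
        if c not in freqs.p.columns:
            raise KeyError(f"cycle {c!r} not present in the frequency table")
    d = freqs.p[cycles].apply(lambda col: gene_diversity(col.to_numpy()))
    d = pd.DataFrame(d, index=freqs.p.index, columns=cycles)
    summary = pd.DataFrame({
        "mean_d": d.mean(axis=0, skipna=True),
        "sd_d": d.std(axis=0, ddof=1),
    })
    return DiversityScan(d=d, summary=summary, loci=loci)


def region_reduction_summary(
    scan: DiversityScan,
    regions: Sequence[GenomicRegion],
    cycle_from: str,
    cycle_to: str,
) -> pd.DataFrame:
    """Mean gene diversity per region in two cycles and the percent
    reduction between them.

    Percent reduction is ``100 (D_from - D_to) / D_from``; the
    ``percent_reduction`` column is rounded to the nearest integer percent
    for reporting while ``percent_reduction_raw`` keeps full precision.
    """
    if scan.loci is None:
        raise ValueError("scan carries no locus coordinates; pass loci to diversity_scan")
    meta = scan.loci.set_index("id")
    chrom = meta["chromosome"].reindex(scan.d.index).to_numpy()
    bp = meta["bp"].reindex(scan.d.index).to_numpy()
    rows = []
    for region in regions:
        mask = ((chrom == region.chromosome)
                & (bp >= region.start_bp) & (bp <= region.end_bp))
        if not mask.any():
            raise ValueError(f"region {region.label or region.chromosome} contains no loci")
        d_from = float(scan.d.loc[mask, cycle_from].mean())
        d_to = float(scan.d.loc[mask, cycle_to].mean())
        if d_from == 0:
            raise ValueError(
                f"region {region.label or region.chromosome} has zero diversity in {cycle_from}")
        raw = 100.0 * (d_from - d_to) / d_from
        rows.append({
            "region": region.label or f"{region.chromosome}:{region.start_bp}-{region.end_bp}",
            "chromosome": region.chromosome,
            "n_loci": int(mask.sum()),
            "mean_d_from": d_from,
            "mean_d_to": d_to,
            "percent_reduction_raw": raw,
            "percent_reduction": int(round(raw)),
        })
    return pd.DataFrame(rows)


def expected_drift_diversity(d0: float, ne: float, t: int):
    """Neutral-drift expectation ``D_t = D_0 (1 - 1/(2 Ne))^t``."""
    if ne <= 0:
        raise ValueError("effective size must be positive")
    if t < 0:
        raise ValueError("t must be >= 0")
    return d0 * (1.0 - 1.0 / (2.0 * ne)) ** t
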