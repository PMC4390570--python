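"""Genotype matrices: containers, I/O, filtering, allele frequencies.

The central container is :class:`GenotypeMatrix` — samples x loci alternate-
allele dosages in {0, 1, 2} with NaN for missing calls, a locus map
(id, chromosome, bp) and a per-sample selection-cycle label.  Allele
frequencies are maximum-likelihood estimates: observed allele copies divided
by twice the number of individuals with an observed genotype.

Formats: a tab-delimited matrix dialect (samples as rows; first column
sample id, second column cycle label; missing coded ``NA``; an optional
``<path>.map`` sidecar carries chromosome/cM/bp) and VCF (GT field only,
biallelic records, via cyvcf2).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "AlleleFrequencyTable",
    "FilterReport",
    "read_genotypes",
    "write_genotypes",
    "estimate_allele_frequencies",
    "filter_loci",
    "impute_missing",
]


class GenotypeMatrix:
    """Samples x loci dosage matrix with locus map and cycle labels.

    Dosages count copies of the alternate allele (0, 1, 2); missing values
    are NaN.  Locus ids must be unique.  ``bp = 0`` marks an unknown
    physical position.
    """

    def __init__(
        self,
        dosages,
        locus_ids: Sequence[str],
        sample_ids: Sequence[str],
        cycles: Sequence[str],
        chromosomes: Sequence | None = None,
        bp: Sequence[int] | None = None,
        cm: Sequence[float] | None = None,
    ) -> None:
        self.dosages = np.asarray(dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x loci)")
        n, L = self.dosages.shape
        observed = self.dosages[~np.isnan(self.dosages)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        self.locus_ids = np.asarray(locus_ids, dtype=object)
        self.sample_ids = np.asarray(sample_ids, dtype=object)
        self.cycles = np.asarray(cycles, dtype=object)
        if len(self.locus_ids) != L:
            raise ValueError("locus_ids length mismatch")
        if len(self.sample_ids) != n or len(self.cycles) != n:
            raise ValueError("sample_ids/cycles length mismatch")
        if len(set(self.locus_ids)) != L:
            raise ValueError("duplicate locus id")
        self.chromosomes = (np.asarray(chromosomes, dtype=object)
                            if chromosomes is not None
                            else np.full(L, "NA", dtype=object))
        self.bp = (np.asarray(bp, dtype=np.int64)
                   if bp is not None else np.zeros(L, dtype=np.int64))
        self.cm = (np.asarray(cm, dtype=float)
                   if cm is not None else np.full(L, np.nan))
        if not (len(self.chromosomes) == len(self.bp) == len(self.cm) == L):
            raise ValueError("locus map length mismatch")

    # -- basic facts ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def cycle_order(self) -> list[str]:
        """Distinct cycle labels in first-appearance order."""
        return list(dict.fromkeys(self.cycles))

    @property
    def loci(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.locus_ids, "chromosome": self.chromosomes,
            "cm": self.cm, "bp": self.bp,
        })

    @property
    def samples(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.sample_ids, "cycle": self.cycles})

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def take_loci(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.dosages[:, index], self.locus_ids[index], self.sample_ids,
            self.cycles, self.chromosomes[index], self.bp[index], self.cm[index],
        )

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.dosages[index], self.locus_ids, self.sample_ids[index],
            self.cycles[index], self.chromosomes, self.bp, self.cm,
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            np.array_equal(self.dosages, other.dosages, equal_nan=True)
            and np.array_equal(self.locus_ids, other.locus_ids)
            and np.array_equal(self.sample_ids, other.sample_ids)
            and np.array_equal(self.cycles, other.cycles)
            and np.array_equal(self.chromosomes, other.chromosomes)
            and np.array_equal(self.bp, other.bp)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<GenotypeMatrix {self.n_samples} samples x {self.n_loci} loci, "
                f"cycles {self.cycle_order}>")


@dataclass
class AlleleFrequencyTable:
    """Per-locus (x cycle) alternate-allele frequencies and observation counts.

    ``p`` and ``n_obs`` are DataFrames indexed by locus id with one column
    per cycle (a single column ``"all"`` for pooled estimates).  A locus
    with zero observed genotypes in a cycle has ``n_obs = 0`` and an
    undefined (NaN) frequency.
    """

    p: pd.DataFrame
    n_obs: pd.DataFrame

    @property
    def cycles(self) -> list[str]:
        return list(self.p.columns)

    @property
    def undefined(self) -> pd.DataFrame:
        return self.n_obs == 0


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_retained: int
    removed_maf: int
    removed_missing: int


def estimate_allele_frequencies(g: GenotypeMatrix, by_cycle: bool = False) -> AlleleFrequencyTable:
    """Maximum-likelihood allele frequencies: observed alternate-allele
    copies over twice the count of non-missing genotypes, per locus and —
    with ``by_cycle`` — per selection cycle."""
    groups = ([(c, np.asarray(g.cycles == c)) for c in g.cycle_order]
              if by_cycle else [("all", np.ones(g.n_samples, dtype=bool))])
    p_cols, n_cols = {}, {}
    for label, mask in groups:
        sub = g.dosages[mask]
        n_obs = (~np.isnan(sub)).sum(axis=0)
        with np.errstate(invalid="ignore"):
            p = np.nansum(sub, axis=0) / (2.0 * n_obs)
        p[n_obs == 0] = np.nan
        p_cols[label] = p
        n_cols[label] = n_obs
    idx = pd.Index(g.locus_ids, name="locus")
    return AlleleFrequencyTable(
        p=pd.DataFrame(p_cols, index=idx),
        n_obs=pd.DataFrame(n_cols, index=idx),
    )


def filter_loci(g: GenotypeMatrix, maf_min: float = 0.025,
                max_missing: float = 0.20) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep loci whose pooled minor-allele frequency is strictly greater
    than ``maf_min`` and whose missing proportion is at most ``max_missing``.

    The minor allele is determined from the pooled dataset so allele
    orientation is stable across cycles.  Loci with no observed genotype
    fail both criteria.
    """
    if not (0.0 <= maf_min <= 0.5):
        raise ValueError("maf_min must lie in [0, 0.5]")
    if not (0.0 <= max_missing <= 1.0):
        raise ValueError("max_missing must lie in [0, 1]")
    freqs = estimate_allele_frequencies(g)
    p = freqs.p["all"].to_numpy()
    with np.errstate(invalid="ignore"):
        maf = np.fmin(p, 1.0 - p)
    ok_maf = np.where(np.isnan(maf), False, maf > maf_min)
    ok_miss = g.missing_rate() <= max_missing
    keep = ok_maf & ok_miss
    report = FilterReport(
        n_input=g.n_loci,
        n_retained=int(keep.sum()),
        removed_maf=int((~ok_maf).sum()),
        removed_missing=int((~ok_miss).sum()),
    )
    return g.take_loci(np.flatnonzero(keep)), report


def impute_missing(g: GenotypeMatrix, method: str = "locus_mean", rng=None) -> GenotypeMatrix:
    """Fill missing dosages.

    ``locus_mean`` writes the rounded expected dosage ``round(2 p_hat)``;
    ``frequency_draw`` samples a genotype from Hardy-Weinberg proportions at
    the locus frequency.  Every locus must have at least one observed
    genotype.
    """
    miss = np.isnan(g.dosages)
    if not miss.any():
        return g
    if np.any(miss.all(axis=0)):
        bad = g.locus_ids[miss.all(axis=0)][0]
        raise ValueError(f"locus {bad} has no observed genotypes; cannot impute")
    p = estimate_allele_frequencies(g).p["all"].to_numpy()
    dosages = g.dosages.copy()
    rows, cols = np.nonzero(miss)
    if method == "locus_mean":
        fill = np.round(2.0 * p[cols])
    elif method == "frequency_draw":
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        pm = p[cols]
        u = rng.random(cols.size)
        fill = np.where(u < (1 - pm) ** 2, 0.0,
                        np.where(u < (1 - pm) ** 2 + 2 * pm * (1 - pm), 1.0, 2.0))
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    dosages[rows, cols] = fill
    return GenotypeMatrix(dosages, g.locus_ids, g.sample_ids, g.cycles,
                          g.chromosomes, g.bp, g.cm)


# ---------------------------------------------------------------------------
# I/O

_MISSING = "NA"


def write_genotypes(g: GenotypeMatrix, path, format: str = "delimited") -> None:
    """Write a genotype matrix; ``read_genotypes`` round-trips it exactly.

    The delimited dialect has samples as rows (columns: sample id, cycle
    label, one column per locus; missing ``NA``).  If the matrix carries
    physical positions a 4-column ``<path>.map`` sidecar (chromosome, id,
    cM, bp) is written alongside.
    """
    if format != "delimited":
        raise ValueError(f"unsupported write format {format!r}")
    path = str(path)
    with open(path, "w") as fh:
        fh.write("\t".join(["sample", "cycle", *map(str, g.locus_ids)]) + "\n")
        for i in range(g.n_samples):
            cells = [_MISSING if np.isnan(v) else str(int(v)) for v in g.dosages[i]]
            fh.write("\t".join([str(g.sample_ids[i]), str(g.cycles[i]), *cells]) + "\n")
    if (g.bp != 0).any():
        cm = np.where(np.isnan(g.cm), 0.0, g.cm)
        pd.DataFrame({
            "chromosome": g.chromosomes, "id": g.locus_ids,
            "cm": cm, "bp": g.bp,
        }).to_csv(path + ".map", sep="\t", header=False, index=False)


def _read_delimited(path) -> GenotypeMatrix:
    import os

    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str},
                     na_values=[_MISSING], keep_default_na=False)
    if df.shape[1] < 2 or list(df.columns[:2]) != ["sample", "cycle"]:
        raise ValueError("malformed genotype file: expected 'sample' and 'cycle' columns")
    locus_ids = list(df.columns[2:])
    dosages = df.iloc[:, 2:].to_numpy(dtype=float)
    kwargs = {}
    map_path = str(path) + ".map"
    if os.path.exists(map_path):
        m = pd.read_csv(map_path, sep="\t", header=None,
                        names=["chromosome", "id", "cm", "bp"])
        m = m.set_index("id").loc[locus_ids]
        kwargs = {"chromosomes": m["chromosome"].to_numpy(),
                  "bp": m["bp"].to_numpy(), "cm": m["cm"].to_numpy()}
    return GenotypeMatrix(dosages, locus_ids, df["sample"].to_numpy(),
                          df["cycle"].to_numpy(), **kwargs)


def _read_vcf(path, cycles: Mapping[str, str] | None) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, ids, chroms, bps = [], [], [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(
                f"non-biallelic record at {v.CHROM}:{v.POS} ({len(v.ALT)} ALT alleles)")
        gt = np.asarray(v.gt_types, dtype=float)
        gt[gt == 3] = np.nan
        rows.append(gt)
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}")
        chroms.append(v.CHROM)
        bps.append(v.POS)
    dosages = np.asarray(rows).T if rows else np.empty((len(samples), 0))
    cyc = [cycles.get(s, "NA") if cycles else "NA" for s in samples]
    return GenotypeMatrix(dosages, ids, samples, cyc, chroms, bps)


def read_genotypes(path, format: str = "delimited",
                   cycles: Mapping[str, str] | None = None) -> GenotypeMatrix:
    """Read genotypes from the delimited dialect or a VCF.

    VCF GT fields map ``./.`` to missing and ``0/0, 0/1, 1/1`` to dosages
    0, 1, 2; multi-allelic records are rejected.  ``cycles`` optionally maps
    VCF sample names to cycle labels (delimited files carry their own).
    """
    if format == "delimited":
        return _read_delimited(path)
    if format == "vcf":
        return _read_vcf(path, cycles)
    raise ValueError(f"unsupported read format {format!r}")
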