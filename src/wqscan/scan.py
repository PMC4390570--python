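"""SNP-wise F_ST selection mapping with drift-simulation thresholds.

F_ST between two selection cycles is computed per SNP as

    F_ST = s^2 / (p_bar (1 - p_bar) + s^2 / r)

with ``s^2`` the sample variance (denominator r - 1) of the allele
frequency across the r populations and ``p_bar`` their mean.  Significance
is judged against forward drift simulations of the breeding protocol: the
family-wise threshold is a quantile of the per-replicate maximum F_ST
across all loci, and per-locus quantiles pooled over loci and replicates
calibrate an enrichment analysis (under drift alone 5% and 1% of loci are
expected to exceed the pooled 95% and 99% quantiles).

Quantiles use the empirical inverse-CDF convention and exceedance is
strict, so a q-level empirical outlier threshold on M loci flags exactly
floor((1 - q) * M) loci when values are distinct.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import AlleleFrequencyTable, GenotypeMatrix
from .protocol import BreedingProtocol
from .sim import simulate_drift_trajectories

__all__ = [
    "FstScan",
    "NullDistribution",
    "EnrichmentResult",
    "snp_fst",
    "fst_scan",
    "drift_null_thresholds",
    "empirical_outlier_threshold",
    "enrichment_analysis",
    "effective_marker_number",
]


def _quantile(values: np.ndarray, q: float) -> float:
    return float(np.quantile(values, q, method="inverted_cdf"))


def _fst_formula(p: np.ndarray, axis: int = -1) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized F_ST; returns (fst, s2, p_bar) with NaN where undefined
    (monomorphic for the same allele in every population)."""
    p = np.asarray(p, dtype=float)
    r = p.shape[axis]
    p_bar = p.mean(axis=axis)
    s2 = p.var(axis=axis, ddof=1)
    denom = p_bar * (1.0 - p_bar) + s2 / r
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(denom > 0, s2 / np.where(denom > 0, denom, 1.0), np.nan)
    # no variation anywhere but segregating: differentiation is exactly 0
    fst = np.where((s2 == 0) & (denom > 0), 0.0, fst)
    return fst, s2, p_bar


def snp_fst(p_by_pop, r: int | None = None) -> float:
    """F_ST for one SNP from per-population allele frequencies.

    Returns NaN (unusable) when the SNP is fixed for the same allele in all
    populations (0/0); 0 when frequencies are equal but the SNP segregates.
    """
    p = np.asarray(p_by_pop, dtype=float)
    if r is None:
        r = p.size
    if r < 2 or p.size != r:
        raise ValueError("need frequencies for r >= 2 populations")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    fst, _, _ = _fst_formula(p[None, :])
    return float(fst[0])


@dataclass
class FstScan:
    """Per-SNP F_ST between two cycles plus its building blocks."""

    table: pd.DataFrame  # columns: locus, chromosome, bp, fst, s2, p_bar, usable
    cycle_a: str
    cycle_b: str

    @property
    def fst(self) -> np.ndarray:
        return self.table["fst"].to_numpy()

    @property
    def usable(self) -> np.ndarray:
        return self.table["usable"].to_numpy()

    @property
    def usable_fst(self) -> np.ndarray:
        return self.fst[self.usable]

    @property
    def n_usable(self) -> int:
        return int(self.usable.sum())

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def fst_scan(freqs: AlleleFrequencyTable, cycle_a: str, cycle_b: str,
             loci: pd.DataFrame | None = None) -> FstScan:
    """Locus-wise F_ST (r = 2) between two cycles of an allele-frequency
    table.  Loci monomorphic for the same allele in both cycles, or with an
    undefined frequency in either cycle, are marked unusable."""
    for c in (cycle_a, cycle_b):
        if c not in freqs.p.columns:
            raise KeyError(f"cycle {c!r} not present in the frequency table")
    p = freqs.p[[cycle_a, cycle_b]].to_numpy()
    fst, s2, p_bar = _fst_formula(p)
    usable = ~np.isnan(fst)
    table = pd.DataFrame({
        "locus": freqs.p.index,
        "fst": fst,
        "s2": s2,
        "p_bar": p_bar,
        "usable": usable,
    })
    if loci is not None:
        meta = loci.set_index("id")
        table.insert(1, "chromosome", meta["chromosome"].reindex(table["locus"]).to_numpy())
        table.insert(2, "bp", meta["bp"].reindex(table["locus"]).to_numpy())
    return FstScan(table=table, cycle_a=cycle_a, cycle_b=cycle_b)


@dataclass
class NullDistribution:
    """Drift-null F_ST ensemble summaries.

    ``fwer_threshold`` is the (1 - fwer) quantile of the per-replicate
    maximum F_ST across loci (family-wise control); ``perlocus_q95`` /
    ``perlocus_q99`` are pooled per-locus quantiles over all simulated
    locus-level F_ST values (one genome-wide pair, used for enrichment).
    """

    max_fst_sample: np.ndarray
    fwer_threshold: float
    perlocus_q95: float
    perlocus_q99: float
    n_reps: int
    fwer: float = 0.05
    meff_used: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "fwer": self.fwer,
            "fwer_threshold": self.fwer_threshold,
            "perlocus_q95": self.perlocus_q95,
            "perlocus_q99": self.perlocus_q99,
            "n_reps": self.n_reps,
            "meff_used": self.meff_used,
            "seed": self.seed,
        }


def drift_null_thresholds(
    p0,
    protocol: BreedingProtocol,
    rng,
    n_reps: int = 1000,
    fwer: float = 0.05,
    meff: int | None = None,
    initial_inbreeding: float = 0.0,
    sample_size: int | None = None,
    seed_note: int | None = None,
) -> NullDistribution:
    """Simulate the drift-only F_ST null for an observed starting-frequency
    spectrum and extract significance thresholds.

    Each replicate simulates final frequencies for every locus through the
    whole protocol (unlinked fast engine), computes per-locus F_ST against
    its own starting frequency, and records the maximum across loci.  The
    family-wise threshold is the (1 - fwer) quantile of the maxima; the
    pooled per-locus 95%/99% quantiles come from the same ensemble.  With
    ``meff`` set, each replicate instead simulates ``meff`` loci resampled
    from the starting spectrum (effective-number-of-markers variant).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    p0 = np.asarray(p0, dtype=float).ravel()
    if p0.size == 0:
        raise ValueError("p0 must be non-empty")
    base = p0
    if meff is not None:
        base = rng.choice(p0, size=int(meff), replace=True)
    final = simulate_drift_trajectories(
        base, protocol, n_reps, rng,
        initial_inbreeding=initial_inbreeding, sample_size=sample_size)
    fst = null_fst(base, final)
    maxima = np.nanmax(fst, axis=0)
    pooled = fst[~np.isnan(fst)]
    return NullDistribution(
        max_fst_sample=maxima,
        fwer_threshold=_quantile(maxima, 1.0 - fwer),
        perlocus_q95=_quantile(pooled, 0.95),
        perlocus_q99=_quantile(pooled, 0.99),
        n_reps=n_reps,
        fwer=fwer,
        meff_used=meff,
        seed=seed_note,
    )


def null_fst(p0: np.ndarray, final: np.ndarray) -> np.ndarray:
    """Per-locus F_ST of simulated final frequencies against the starting
    frequencies; ``final`` is (loci, reps)."""
    p0 = np.asarray(p0, dtype=float)[:, None]
    stacked = np.stack([np.broadcast_to(p0, final.shape), final], axis=-1)
    fst, _, _ = _fst_formula(stacked)
    return fst


def empirical_outlier_threshold(scan: FstScan, quantile: float = 0.99) -> tuple[float, int]:
    """Empirical outlier threshold on the scan's own usable F_ST values.

    Returns the inverse-CDF quantile and the count of loci strictly above
    it — floor((1 - quantile) * M) when values are distinct.
    """
    values = scan.usable_fst
    if values.size == 0:
        raise ValueError("scan has no usable loci")
    thr = _quantile(values, quantile)
    return thr, int((values > thr).sum())


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed vs expected exceedance of the pooled drift quantiles."""

    observed_prop95: float
    observed_prop99: float
    expected_prop95: float = 0.05
    expected_prop99: float = 0.01

    def to_dict(self) -> dict:
        return {
            "observed_prop95": self.observed_prop95,
            "observed_prop99": self.observed_prop99,
            "expected_prop95": self.expected_prop95,
            "expected_prop99": self.expected_prop99,
        }


def enrichment_analysis(scan: FstScan, null: NullDistribution) -> EnrichmentResult:
    """Proportions of usable scan loci exceeding the pooled per-locus 95%
    and 99% drift quantiles (expected 0.05 and 0.01 under drift alone)."""
    values = scan.usable_fst
    if values.size == 0:
        return EnrichmentResult(0.0, 0.0)
    return EnrichmentResult(
        observed_prop95=float((values > null.perlocus_q95).mean()),
        observed_prop99=float((values > null.perlocus_q99).mean()),
    )


def effective_marker_number(g: GenotypeMatrix, pca_cutoff: float = 0.99,
                            window_size: int = 200) -> int:
    """Effective number of independent markers from the eigenvalue spectrum
    of the locus x locus (composite-LD) correlation matrix.

    Per window of ``window_size`` consecutive loci, the count is the
    smallest k whose top-k eigenvalues sum to at least ``pca_cutoff`` of the
    total; window counts are summed and capped at min(n_loci,
    n_samples - 1).  Genotypes must be complete (impute first) and no locus
    may be constant.
    """
    if not (0.0 < pca_cutoff <= 1.0):
        raise ValueError("pca_cutoff must lie in (0, 1]")
    if g.n_samples < 2:
        raise ValueError("need at least 2 samples")
    X = g.dosages
    if np.isnan(X).any():
        raise ValueError("genotypes contain missing values; impute first")
    if np.any(X.std(axis=0) == 0):
        bad = g.locus_ids[X.std(axis=0) == 0][0]
        raise ValueError(f"constant locus {bad}; remove monomorphic loci first")
    total = 0
    for lo in range(0, g.n_loci, window_size):
        block = X[:, lo:lo + window_size]
        corr = np.corrcoef(block, rowvar=False)
        corr = np.atleast_2d(corr)
        evals = np.linalg.eigvalsh(corr)[::-1]
        evals = np.clip(evals, 0.0, None)
        cum = np.cumsum(evals) / evals.sum()
        total += int(np.searchsorted(cum, pca_cutoff - 1e-12) + 1)
    return min(total, g.n_loci, g.n_samples - 1)
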