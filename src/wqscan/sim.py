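"""Forward-in-time simulation of a WQS-style recurrent-selection program.

Two engines share one demographic model (:class:`~wqscan.protocol.BreedingProtocol`):

* a fast, exact *unlinked* engine (:func:`simulate_drift_trajectories`) that
  tracks per-locus genotype-class proportions and serves as the drift-null
  machine for F_ST significance thresholds;
* an *individual-based* engine (:func:`advance_cycle`,
  :func:`simulate_wqs_genomes`) that carries whole genotypes — optionally as
  linked haplotypes with Haldane recombination — and supports truncation
  selection on a simulated trait, for synthetic-data generation and
  power checks.

One cycle of the protocol is: draw S0 founders from the current population
(with replacement), self each lineage by single-seed descent, screen the S1
families, select the top families (at random under the drift null, by a
ranking function otherwise), and intermate the selected families by the bulk
entry method — each offspring receives one gamete from each of two distinct
selected families, so every family contributes equally in expectation.

The fast engine exploits an exact distributional equivalence: under the
drift null the screening and selection steps are uniform subsets of
exchangeable with-replacement founder draws, so the selected family founders
are i.i.d. draws from the current population and the bulk-entry offspring
are multinomial with closed-form genotype-class probabilities.  Selfing is
modeled on genotype classes, not allele frequencies, so the extra drift
variance caused by selfing-induced homozygosity is captured exactly.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .protocol import BreedingProtocol, CycleSpec, GeneticMap, TraitArchitecture

__all__ = [
    "PopulationState",
    "meiosis_gamete",
    "self_single_seed_descent",
    "advance_cycle",
    "simulate_drift_trajectories",
    "simulate_wqs_genomes",
    "simulate_phenotypes",
    "make_truncation_fn",
    "hwe_population",
]

# channel chunk for the vectorized unlinked engine (memory ceiling only;
# results for a given seed do not depend on the number of chunks executed
# because a single stream is consumed sequentially)
_CHUNK = 1 << 20


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# population containers


@dataclass
class PopulationState:
    """A finite diploid population at one point in the breeding scheme.

    ``dosages`` is an (n_individuals, n_loci) array of alternate-allele
    counts in {0, 1, 2}.  In linked mode ``haplotypes`` additionally holds
    the phased (n_individuals, 2, n_loci) 0/1 array and ``gmap`` the genetic
    map used for meiosis; ``dosages`` is then derived and kept in sync.
    """

    dosages: np.ndarray
    cycle_label: str = "C0"
    haplotypes: np.ndarray | None = None
    gmap: GeneticMap | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2 or self.dosages.shape[0] == 0:
            raise ValueError("population must be a non-empty individuals x loci matrix")
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValueError("genotypes must be 0, 1 or 2 at every locus")
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            if self.haplotypes.shape != (self.n_individuals, 2, self.n_loci):
                raise ValueError("haplotypes must be (n_individuals, 2, n_loci)")
            if self.gmap is None:
                raise ValueError("linked populations need a genetic map")
            if self.gmap.n_loci != self.n_loci:
                raise ValueError("map/haplotype length mismatch")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def linked(self) -> bool:
        return self.haplotypes is not None

    def allele_frequencies(self) -> np.ndarray:
        return self.dosages.mean(axis=0) / 2.0


def hwe_population(
    p: Sequence[float],
    n_individuals: int,
    rng,
    cycle_label: str = "C0",
    gmap: GeneticMap | None = None,
) -> PopulationState:
    """Found a population at linkage equilibrium and Hardy-Weinberg
    proportions with per-locus allele frequencies ``p``.

    With a map, phased haplotypes are stored so the population can be
    advanced in linked mode.
    """
    rng = _as_rng(rng)
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    haps = (rng.random((n_individuals, 2, p.size)) < p).astype(np.int8)
    dos = haps.sum(axis=1, dtype=np.int8)
    if gmap is not None:
        return PopulationState(dos, cycle_label, haplotypes=haps, gmap=gmap)
    return PopulationState(dos, cycle_label)


# ---------------------------------------------------------------------------
# meiosis (linked mode)


def _switch_probabilities(gmap: GeneticMap) -> np.ndarray:
    """Per-locus probability that a gamete switches parental haplotype
    relative to the previous locus.

    First locus of every chromosome: 1/2 (independent assortment).  Within a
    chromosome: the Haldane map function r = (1 - exp(-2d/100)) / 2 for a
    gap of d cM, i.e. the probability of an odd number of crossovers under a
    no-interference (Poisson) crossover process.
    """
    d = np.diff(gmap.cm)
    same = gmap.chromosome[1:] == gmap.chromosome[:-1]
    r = np.where(same, 0.5 * (1.0 - np.exp(-2.0 * d / 100.0)), 0.5)
    return np.concatenate(([0.5], r))


def _meiose_batch(haplotypes: np.ndarray, gmap: GeneticMap, rng: np.random.Generator) -> np.ndarray:
    """One gamete per individual from an (N, 2, L) haplotype array."""
    n, two, L = haplotypes.shape
    if L != gmap.n_loci:
        raise ValueError("map/haplotype length mismatch")
    switch = rng.random((n, L)) < _switch_probabilities(gmap)
    # global cumulative parity: each chromosome starts with a fresh fair
    # switch, which makes parities independent across chromosomes
    chooser = np.cumsum(switch, axis=1) & 1
    return np.take_along_axis(haplotypes, chooser[:, None, :], axis=1)[:, 0, :]


def meiosis_gamete(parent_haplotypes: np.ndarray, gmap: GeneticMap, rng) -> np.ndarray:
    """Draw one recombinant gamete from a (2, n_loci) phased parent.

    Crossovers follow a no-interference Poisson process on the genetic map
    (expected count per chromosome = cM length / 100); chromosomes assort
    independently.
    """
    rng = _as_rng(rng)
    parent = np.asarray(parent_haplotypes, dtype=np.int8)
    if parent.shape != (2, gmap.n_loci):
        raise ValueError("map/haplotype length mismatch")
    return _meiose_batch(parent[None, :, :], gmap, rng)[0]


# ---------------------------------------------------------------------------
# selfing


def _self_dosages_once(dosages: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Single-seed-descent selfing of unlinked dosage genotypes: each locus
    transmits two independent Bernoulli(d/2) gametes."""
    p = dosages / 2.0
    shape = dosages.shape
    a = rng.random(shape) < p
    b = rng.random(shape) < p
    return (a.astype(np.int8) + b.astype(np.int8))


def self_single_seed_descent(genotype: np.ndarray, generations: int, rng) -> np.ndarray:
    """Genotype of one random selfed descendant after ``generations`` rounds
    of self-pollination with single-seed descent.

    Loci are treated as unlinked; per-locus expected heterozygosity halves
    each generation (Mendelian 1:2:1 segregation at heterozygous loci).
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    rng = _as_rng(rng)
    g = np.asarray(genotype, dtype=np.int8)
    scalar = g.ndim == 0
    g = np.atleast_1d(g)
    for _ in range(generations):
        g = _self_dosages_once(g, rng)
    return g[0] if scalar else g


def _self_haplotypes_once(haps: np.ndarray, gmap: GeneticMap, rng: np.random.Generator) -> np.ndarray:
    gam1 = _meiose_batch(haps, gmap, rng)
    gam2 = _meiose_batch(haps, gmap, rng)
    return np.stack([gam1, gam2], axis=1)


# ---------------------------------------------------------------------------
# individual-based cycle advance


def make_truncation_fn(arch: TraitArchitecture, favor: str = "high") -> Callable:
    """Build a family-ranking function applying truncation selection on an
    additive criterion with narrow-sense heritability ``arch.h2_target``.

    The returned callable maps (family_dosages (F, L), rng) to scores; the
    non-genetic component is Gaussian noise scaled so the criterion's
    heritability among the evaluated families equals ``h2_target``.
    """
    sign = 1.0 if favor == "high" else -1.0
    loci = np.asarray(arch.qtl_loci, dtype=int)
    effects = np.asarray(arch.qtl_effects, dtype=float)

    def score(family_dosages: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        g = sign * (family_dosages[:, loci] @ effects)
        h2 = arch.h2_target
        if h2 >= 1.0:
            return g
        vg = np.var(g)
        if h2 <= 0.0 or vg == 0.0:
            return rng.normal(size=g.size)
        return g + rng.normal(scale=np.sqrt(vg * (1.0 - h2) / h2), size=g.size)

    return score


def _family_representatives(
    founder_idx: np.ndarray,
    pop: PopulationState,
    spec: CycleSpec,
    plants_per_family: int,
    rng: np.random.Generator,
):
    """Self each founder lineage and return per-family representative plants.

    Returns ``(dosages, haplotypes)`` with shapes (F, k, L) and
    (F, k, 2, L) (haplotypes ``None`` in unlinked mode); the k sibling
    plants of a family are independent selfed offspring of the same
    generation-(g-1) plant, so ``plants_per_family`` > 1 only takes effect
    when ``selfing_generations`` >= 1.
    """
    g = spec.selfing_generations
    k = plants_per_family
    F = founder_idx.size
    if pop.linked:
        haps = pop.haplotypes[founder_idx]
        for _ in range(max(g - 1, 0)):
            haps = _self_haplotypes_once(haps, pop.gmap, rng)
        if g >= 1:
            haps = np.repeat(haps, k, axis=0)
            haps = _self_haplotypes_once(haps, pop.gmap, rng)
        else:
            haps = np.repeat(haps, k, axis=0)
        reps = haps.reshape(F, k, 2, pop.n_loci)
        dos = reps.sum(axis=2, dtype=np.int8)
        return dos, reps
    dos = pop.dosages[founder_idx]
    for _ in range(max(g - 1, 0)):
        dos = _self_dosages_once(dos, rng)
    if g >= 1:
        dos = np.repeat(dos, k, axis=0)
        dos = _self_dosages_once(dos, rng)
        dos = dos.reshape(F, k, pop.n_loci)
    else:
        dos = np.repeat(dos[:, None, :], k, axis=1)
    return dos, None


def advance_cycle(
    pop: PopulationState,
    spec: CycleSpec,
    protocol: BreedingProtocol,
    rng,
    selection_fn: Callable | None = None,
    return_selected: bool = False,
):
    """Advance a population through one full cycle of the breeding scheme.

    Founders are drawn from ``pop`` with replacement, selfed by single-seed
    descent, screened to ``spec.n_after_screen`` families (a uniform random
    subset — the agronomic screen is treated as selectively neutral), and
    ``spec.n_selected`` families are picked uniformly at random (drift null)
    or as the top-ranked families under ``selection_fn(family_dosages, rng)``.
    Bulk-entry recombination then forms ``protocol.next_cycle_pop_size``
    offspring, each from one gamete of each of two distinct selected
    families, so expected contributions are equal across families.

    With ``return_selected=True`` also returns the selected families'
    representative genotypes (the plants a genotyping experiment would
    sample), as an (n_selected, n_loci) dosage array.
    """
    rng = _as_rng(rng)
    if spec.n_s0_plants < 1 or pop.n_individuals == 0:
        raise ValueError("population and founder draw must be non-empty")
    k = protocol.plants_per_family

    founder_idx = rng.integers(0, pop.n_individuals, size=spec.n_s0_plants)
    fam_dos, fam_haps = _family_representatives(founder_idx, pop, spec, k, rng)

    screened = rng.permutation(spec.n_s0_plants)[: spec.n_after_screen]
    if selection_fn is None:
        selected = screened[rng.permutation(spec.n_after_screen)[: spec.n_selected]]
    else:
        scores = np.asarray(
            selection_fn(fam_dos[screened].mean(axis=1), rng), dtype=float
        )
        if scores.shape != (len(screened),):
            raise ValueError("selection_fn must return one score per family")
        # random tie-break: permute before the stable argsort
        order = rng.permutation(len(screened))
        top = order[np.argsort(-scores[order], kind="stable")[: spec.n_selected]]
        selected = screened[top]

    S = spec.n_selected
    n_next = protocol.next_cycle_pop_size
    fam_a = rng.integers(0, S, size=n_next)
    fam_b = (fam_a + 1 + rng.integers(0, S - 1, size=n_next)) % S
    plant_a = rng.integers(0, k, size=n_next)
    plant_b = rng.integers(0, k, size=n_next)

    sel_dos = fam_dos[selected]  # (S, k, L)
    if pop.linked:
        sel_haps = fam_haps[selected]  # (S, k, 2, L)
        gam1 = _meiose_batch(sel_haps[fam_a, plant_a], pop.gmap, rng)
        gam2 = _meiose_batch(sel_haps[fam_b, plant_b], pop.gmap, rng)
        haps = np.stack([gam1, gam2], axis=1)
        state = PopulationState(
            haps.sum(axis=1, dtype=np.int8),
            cycle_label=_bump_label(pop.cycle_label),
            haplotypes=haps,
            gmap=pop.gmap,
        )
    else:
        pa = sel_dos[fam_a, plant_a] / 2.0
        pb = sel_dos[fam_b, plant_b] / 2.0
        gam1 = rng.random(pa.shape) < pa
        gam2 = rng.random(pb.shape) < pb
        state = PopulationState(
            gam1.astype(np.int8) + gam2.astype(np.int8),
            cycle_label=_bump_label(pop.cycle_label),
        )
    if return_selected:
        # single representative plant per family, as genotyped in practice
        return state, sel_dos[:, 0, :].copy()
    return state


def _bump_label(label: str) -> str:
    if label and label[0] in "Cc" and label[1:].isdigit():
        return f"{label[0]}{int(label[1:]) + 1}"
    return label + "+1"


# ---------------------------------------------------------------------------
# fast unlinked drift engine


def _categorical3(prop0: np.ndarray, prop01: np.ndarray, size: int,
                  rng: np.random.Generator) -> np.ndarray:
    """(C, size) draws of genotype classes from per-channel proportions."""
    u = rng.random((prop0.size, size), dtype=np.float32)
    return (u >= prop0[:, None]).astype(np.int8) + (u >= prop01[:, None]).astype(np.int8)


def _self_classes(classes: np.ndarray, generations: int,
                  rng: np.random.Generator) -> np.ndarray:
    for _ in range(generations):
        u = rng.random(classes.shape, dtype=np.float32)
        segregated = np.where(u < 0.25, 0, np.where(u < 0.75, 1, 2)).astype(np.int8)
        classes = np.where(classes == 1, segregated, classes)
    return classes


def _drift_one_cycle(
    prop: np.ndarray,  # (C, 3) genotype-class proportions per channel
    spec: CycleSpec,
    protocol: BreedingProtocol,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance every channel one cycle; exact count-based bulk-entry step."""
    S, k = spec.n_selected, protocol.plants_per_family
    g = spec.selfing_generations
    prop0 = prop[:, 0]
    prop01 = prop[:, 0] + prop[:, 1]

    # selected-family founders are i.i.d. draws from the population (see
    # module docstring for the exchangeability argument)
    classes = _categorical3(prop0, prop01, S, rng)
    if g >= 1 and k > 1:
        parents = _self_classes(classes, g - 1, rng)
        plants = _self_classes(np.repeat(parents, k, axis=1), 1, rng)
        f = plants.reshape(-1, S, k).mean(axis=2) / 2.0
    else:
        f = _self_classes(classes, g, rng) / 2.0

    # bulk entry: offspring classes are i.i.d. multinomial over channels with
    # probabilities averaged over ordered distinct family pairs
    s1 = f.sum(axis=1)
    s2 = np.square(f).sum(axis=1)
    t1 = S - s1
    t2 = np.square(1.0 - f).sum(axis=1)
    denom = S * (S - 1)
    pi2 = np.clip((s1 * s1 - s2) / denom, 0.0, 1.0)
    pi0 = np.clip((t1 * t1 - t2) / denom, 0.0, 1.0)

    N = protocol.next_cycle_pop_size
    n0 = rng.binomial(N, pi0)
    rest = N - n0
    with np.errstate(divide="ignore", invalid="ignore"):
        p1r = np.where(pi0 < 1.0, np.clip(pi2 / np.maximum(1.0 - pi0, 1e-300), 0.0, 1.0), 0.0)
    n2 = rng.binomial(rest, p1r)
    n1 = rest - n2
    out = np.empty_like(prop)
    out[:, 0] = n0 / N
    out[:, 1] = n1 / N
    out[:, 2] = n2 / N
    return out


def simulate_drift_trajectories(
    p0: Sequence[float],
    protocol: BreedingProtocol,
    n_reps: int,
    rng,
    initial_inbreeding: float = 0.0,
    sample_size: int | None = None,
) -> np.ndarray:
    """Simulate drift-only final allele frequencies, locus x replicate.

    Every locus evolves independently (linkage equilibrium between markers)
    from a base population at frequency ``p0`` with genotype proportions
    generalized-HWE at inbreeding ``initial_inbreeding``.  Genotype-class
    counts are tracked exactly through selfing, selection and bulk-entry
    recombination.  The returned matrix has shape (n_loci, n_reps); final
    frequencies are those of the full final population, or of a random
    sample of ``sample_size`` individuals when given.
    """
    rng = _as_rng(rng)
    p0 = np.asarray(p0, dtype=float).ravel()
    if p0.size == 0:
        raise ValueError("p0 must be non-empty")
    if np.any((p0 < 0) | (p0 > 1)):
        raise ValueError("starting frequencies must lie in [0, 1]")
    F = initial_inbreeding
    if not (0.0 <= F <= 1.0):
        raise ValueError("initial_inbreeding must lie in [0, 1]")

    L = p0.size
    out = np.empty((L, n_reps), dtype=float)
    flat = np.broadcast_to(p0[:, None], (L, n_reps)).ravel()
    C = flat.size
    for lo in range(0, C, _CHUNK):
        hi = min(lo + _CHUNK, C)
        p = flat[lo:hi]
        q = 1.0 - p
        prop = np.column_stack([
            q * q + F * p * q,
            2.0 * p * q * (1.0 - F),
            p * p + F * p * q,
        ])
        for spec in protocol.cycles:
            prop = _drift_one_cycle(prop, spec, protocol, rng)
        pf = prop[:, 1] / 2.0 + prop[:, 2]
        if sample_size is not None:
            N = protocol.next_cycle_pop_size
            m = min(sample_size, N)
            # sample m individuals without replacement from the final pop
            n2 = rng.hypergeometric(
                np.round(prop[:, 2] * N).astype(np.int64),
                N - np.round(prop[:, 2] * N).astype(np.int64), m)
            n1pool = np.round(prop[:, 1] * N).astype(np.int64)
            n1 = rng.hypergeometric(
                n1pool, N - np.round(prop[:, 2] * N).astype(np.int64) - n1pool,
                m - n2)
            pf = (2 * n2 + n1) / (2.0 * m)
        out.ravel()[lo:hi] = pf
    return out


# ---------------------------------------------------------------------------
# linked whole-genome synthetic data


def _resolve_spectrum(founder_spectrum, n_loci: int, rng: np.random.Generator) -> np.ndarray:
    if founder_spectrum is None:
        return rng.uniform(0.025, 0.975, size=n_loci)
    if callable(founder_spectrum):
        p = np.asarray(founder_spectrum(n_loci, rng), dtype=float)
    else:
        p = np.asarray(founder_spectrum, dtype=float)
    if p.size != n_loci:
        raise ValueError("founder spectrum must provide one frequency per locus")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("founder frequencies must lie in [0, 1]")
    return p


def simulate_wqs_genomes(
    protocol: BreedingProtocol,
    gmap: GeneticMap,
    rng,
    founder_spectrum=None,
    base_cycle_label: str = "C2",
    selection_fn: Callable | None = None,
):
    """Run the full linked-genome protocol and emit a multi-cycle
    :class:`~wqscan.genio.GenotypeMatrix` of the selected families.

    Founder haplotypes are drawn at linkage equilibrium from
    ``founder_spectrum`` (default Uniform(0.025, 0.975), mean gene diversity
    ~0.35).  For each cycle transition the ``n_selected`` S2 family
    representatives are recorded under the source-cycle label; after the
    final transition, ``n_selected`` random S1 families of the last cycle
    are recorded (the last cycle is genotyped one selfing generation
    earlier, as in the motivating program).
    """
    from .genio import GenotypeMatrix

    rng = _as_rng(rng)
    if gmap.n_loci == 0 or protocol.n_cycles == 0:
        raise ValueError("map and protocol must be non-empty")
    p = _resolve_spectrum(founder_spectrum, gmap.n_loci, rng)
    pop = hwe_population(p, protocol.next_cycle_pop_size, rng,
                         cycle_label=base_cycle_label, gmap=gmap)

    blocks, labels = [], []
    for spec in protocol.cycles:
        label = pop.cycle_label
        pop, selected = advance_cycle(
            pop, spec, protocol, rng, selection_fn=selection_fn,
            return_selected=True)
        blocks.append(selected)
        labels.extend([label] * selected.shape[0])

    # final cycle: S1 families from random plants of the final population
    n_final = protocol.cycles[-1].n_selected
    idx = rng.permutation(pop.n_individuals)[:n_final]
    if pop.linked:
        s1 = _self_haplotypes_once(pop.haplotypes[idx], gmap, rng).sum(axis=1, dtype=np.int8)
    else:
        s1 = _self_dosages_once(pop.dosages[idx], rng)
    blocks.append(s1)
    labels.extend([pop.cycle_label] * n_final)

    dosages = np.concatenate(blocks, axis=0)
    sample_ids = [f"{lab}_F{i:03d}" for i, lab in enumerate(labels)]
    return GenotypeMatrix(
        dosages=dosages.astype(float),
        locus_ids=gmap.locus_id,
        chromosomes=gmap.chromosome,
        bp=gmap.bp,
        sample_ids=sample_ids,
        cycles=labels,
    )


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotypes(
    geno,
    arch: TraitArchitecture | None,
    n_environments: int,
    n_replicates: int,
    varcomps: tuple[float, float, float],
    rng,
    trait: str = "trait",
    intercept: float = 10.0,
    env_effect_scale: float = 1.0,
    rep_effect_scale: float = 0.5,
):
    """Simulate a family x environment x replicate phenotype table.

    ``varcomps = (sigma2_G, sigma2_GE, sigma2_e)``.  Each genotype-matrix
    sample is one family; its genetic value comes from the QTL dosages in
    ``arch`` rescaled so the realized among-family variance equals
    ``sigma2_G`` (or is an i.i.d. Gaussian family effect when ``arch`` has
    no QTL).  Environment and replicate-within-environment effects are fixed
    (drawn once); family-by-environment deviations and plot residuals are
    Gaussian with the stated variances.
    """
    import pandas as pd

    rng = _as_rng(rng)
    s2g, s2ge, s2e = (float(v) for v in varcomps)
    if min(s2g, s2ge, s2e) < 0:
        raise ValueError("variance components must be >= 0")
    nF = geno.n_samples
    if arch is not None and len(arch.qtl_loci):
        loci = np.asarray(arch.qtl_loci, dtype=int)
        if loci.max() >= geno.n_loci:
            raise ValueError("QTL index outside the genotype matrix")
        dos = np.nan_to_num(geno.dosages[:, loci], nan=1.0)
        raw = dos @ np.asarray(arch.qtl_effects, dtype=float)
        sd = raw.std()
        gvals = (raw - raw.mean()) * (np.sqrt(s2g) / sd) if sd > 0 else np.zeros(nF)
    else:
        gvals = rng.normal(scale=np.sqrt(s2g), size=nF) if s2g > 0 else np.zeros(nF)

    env_eff = rng.normal(scale=env_effect_scale, size=n_environments) \
        if env_effect_scale > 0 else np.zeros(n_environments)
    rep_eff = rng.normal(scale=rep_effect_scale, size=(n_environments, n_replicates)) \
        if rep_effect_scale > 0 else np.zeros((n_environments, n_replicates))
    ge = rng.normal(scale=np.sqrt(s2ge), size=(nF, n_environments)) if s2ge > 0 \
        else np.zeros((nF, n_environments))
    eps = rng.normal(scale=np.sqrt(s2e), size=(nF, n_environments, n_replicates)) if s2e > 0 \
        else np.zeros((nF, n_environments, n_replicates))

    y = (intercept + gvals[:, None, None] + env_eff[None, :, None]
         + ge[:, :, None] + rep_eff[None, :, :] + eps)
    fam_ids = np.asarray(geno.sample_ids)
    records = {
        "family": np.repeat(fam_ids, n_environments * n_replicates),
        "environment": np.tile(np.repeat([f"E{j+1}" for j in range(n_environments)],
                                         n_replicates), nF),
        "replicate": np.tile([f"R{k+1}" for k in range(n_replicates)],
                             nF * n_environments),
        trait: y.ravel(),
    }
    return pd.DataFrame(records)
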