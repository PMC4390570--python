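"""Breeding-protocol descriptions for recurrent-selection simulations.

A recurrent-selection cycle in the Wisconsin Quality Synthetic (WQS) style
proceeds: a pool of S0 plants founds S1 families, families are screened
agronomically, the survivors are evaluated as selfed (S2) topcross families,
the best few are selected, and the selected families are intermated by the
bulk entry method to found the next cycle.  :class:`CycleSpec` captures the
census numbers of one such cycle and :class:`BreedingProtocol` chains them.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CycleSpec",
    "BreedingProtocol",
    "GeneticMap",
    "TraitArchitecture",
    "wqs_preset",
]


@dataclass(frozen=True)
class CycleSpec:
    """Census numbers for one cycle of recurrent selection.

    Parameters
    ----------
    n_s0_plants
        Number of S0 plants initiating S1 families.
    n_after_screen
        S1 families kept after the agronomic stress screen.  Defaults to
        ``ceil(n_s0_plants / 2)`` (roughly half the families discarded).
    n_selected
        Families selected on the evaluation index and recombined.
    selfing_generations
        Self-pollination steps from the S0 plant to the family
        representative contributing gametes at recombination (2 for an
        S2-per-se program).
    """

    n_s0_plants: int
    n_selected: int
    selfing_generations: int = 2
    n_after_screen: int | None = None

    def __post_init__(self) -> None:
        screen = self.n_after_screen
        if screen is None:
            screen = math.ceil(self.n_s0_plants / 2)
            object.__setattr__(self, "n_after_screen", screen)
        if not (1 <= self.n_selected <= screen <= self.n_s0_plants):
            raise ValueError(
                "require 1 <= n_selected <= n_after_screen <= n_s0_plants, got "
                f"{self.n_selected} <= {screen} <= {self.n_s0_plants}"
            )
        if self.selfing_generations < 0:
            raise ValueError("selfing_generations must be >= 0")
        if self.n_selected < 2:
            raise ValueError("bulk-entry recombination needs n_selected >= 2")


@dataclass(frozen=True)
class BreedingProtocol:
    """An ordered chain of selection cycles plus the recombination scheme.

    ``next_cycle_pop_size`` is the number of offspring formed by bulk-entry
    recombination of each cycle's selected families; it is the S0 pool from
    which the following cycle draws its founders.  ``plants_per_family``
    controls how many sibling plants represent a selected family when
    contributing gametes (1 = single representative, the maximal-drift
    reading).
    """

    cycles: tuple[CycleSpec, ...]
    next_cycle_pop_size: int = 450
    plants_per_family: int = 1
    recombination_scheme: str = "bulk_entry_diallel"

    def __init__(
        self,
        cycles: Sequence[CycleSpec],
        next_cycle_pop_size: int = 450,
        plants_per_family: int = 1,
        recombination_scheme: str = "bulk_entry_diallel",
    ) -> None:
        cycles = tuple(cycles)
        if not cycles:
            raise ValueError("protocol needs at least one cycle")
        if next_cycle_pop_size < 1:
            raise ValueError("next_cycle_pop_size must be >= 1")
        if plants_per_family < 1:
            raise ValueError("plants_per_family must be >= 1")
        if recombination_scheme != "bulk_entry_diallel":
            raise ValueError(f"unknown recombination scheme {recombination_scheme!r}")
        object.__setattr__(self, "cycles", cycles)
        object.__setattr__(self, "next_cycle_pop_size", next_cycle_pop_size)
        object.__setattr__(self, "plants_per_family", plants_per_family)
        object.__setattr__(self, "recombination_scheme", recombination_scheme)

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)


def wqs_preset() -> BreedingProtocol:
    """The WQS C2->C5 demographic preset.

    Three cycles: 450 S1 families screened for the first two advances, 200
    for the last; 20 families selected and bulk-entry recombined each cycle;
    two selfing generations (S0 -> S1 -> S2 family representative).
    """
    return BreedingProtocol(
        cycles=(
            CycleSpec(n_s0_plants=450, n_selected=20, selfing_generations=2),
            CycleSpec(n_s0_plants=450, n_selected=20, selfing_generations=2),
            CycleSpec(n_s0_plants=200, n_selected=20, selfing_generations=2),
        ),
        next_cycle_pop_size=450,
    )


class GeneticMap:
    """Per-locus chromosome assignment plus genetic (cM) and physical (bp) position.

    Within a chromosome cM must be non-decreasing and bp unique.  Loci are
    kept in input order; all simulator genotype arrays are column-indexed in
    this order.
    """

    def __init__(
        self,
        chromosome: Sequence,
        cm: Sequence[float],
        bp: Sequence[int],
        locus_id: Sequence[str] | None = None,
    ) -> None:
        self.chromosome = np.asarray(chromosome)
        self.cm = np.asarray(cm, dtype=float)
        self.bp = np.asarray(bp, dtype=np.int64)
        n = len(self.chromosome)
        if not (len(self.cm) == len(self.bp) == n):
            raise ValueError("chromosome, cm, bp must have equal length")
        if n == 0:
            raise ValueError("map must contain at least one locus")
        if locus_id is None:
            locus_id = [f"L{i:06d}" for i in range(n)]
        self.locus_id = np.asarray(locus_id, dtype=object)
        if len(self.locus_id) != n:
            raise ValueError("locus_id length mismatch")
        for chrom in np.unique(self.chromosome):
            sel = self.chromosome == chrom
            if np.any(np.diff(self.cm[sel]) < 0):
                raise ValueError(f"cM positions decrease within chromosome {chrom}")
            if len(np.unique(self.bp[sel])) != sel.sum():
                raise ValueError(f"duplicate bp within chromosome {chrom}")

    def __len__(self) -> int:
        return len(self.cm)

    @property
    def n_loci(self) -> int:
        return len(self.cm)

    @classmethod
    def uniform(
        cls,
        n_loci: int,
        n_chromosomes: int = 10,
        chrom_length_cm: float = 150.0,
        bp_per_cm: int = 1_000_000,
    ) -> "GeneticMap":
        """Evenly spaced loci across equally sized chromosomes (maize-like
        defaults: 10 chromosomes of 150 cM)."""
        per = [n_loci // n_chromosomes] * n_chromosomes
        for i in range(n_loci % n_chromosomes):
            per[i] += 1
        chroms, cms, bps = [], [], []
        for c, k in enumerate(per, start=1):
            if k == 0:
                continue
            pos = np.linspace(0.0, chrom_length_cm, k, endpoint=False)
            chroms.extend([f"chr{c}"] * k)
            cms.extend(pos)
            bps.extend((pos * bp_per_cm).astype(np.int64) + 1)
        return cls(chroms, cms, bps)

    @classmethod
    def read(cls, path) -> "GeneticMap":
        """Read a 4-column delimited map file: chromosome, locus id, cM, bp."""
        import pandas as pd

        df = pd.read_csv(path, sep=r"\s+", header=None,
                         names=["chromosome", "id", "cm", "bp"], comment="#")
        return cls(df["chromosome"], df["cm"], df["bp"], locus_id=df["id"])

    def write(self, path) -> None:
        import pandas as pd

        pd.DataFrame({
            "chromosome": self.chromosome,
            "id": self.locus_id,
            "cm": self.cm,
            "bp": self.bp,
        }).to_csv(path, sep="\t", header=False, index=False)


@dataclass(frozen=True)
class TraitArchitecture:
    """Additive QTL architecture of the selection criterion.

    ``h2_target`` is the narrow-sense heritability of the criterion used to
    rank families when truncation selection is switched on; effects are per
    alternate-allele copy.
    """

    qtl_loci: tuple[int, ...] = ()
    qtl_effects: tuple[float, ...] = ()
    h2_target: float = 1.0

    def __post_init__(self) -> None:
        if len(self.qtl_loci) != len(self.qtl_effects):
            raise ValueError("qtl_loci and qtl_effects must align")
        if not (0.0 <= self.h2_target <= 1.0):
            raise ValueError("h2_target must lie in [0, 1]")
        if not np.all(np.isfinite(self.qtl_effects)):
            raise ValueError("qtl_effects must be finite")
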