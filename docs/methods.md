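# Methods

`wqscan` re-implements, as a tested pipeline, the analysis of a maize
recurrent-selection population genotyped across selection cycles: SNP-wise
F_ST selection mapping with significance thresholds calibrated by forward
drift simulation of the breeding protocol, a per-cycle gene-diversity scan
with regional reduction summaries, and a quantitative-genetic layer (family
variance components and broad-sense heritability, G-BLUP genomic
heritability, and a per-marker mixed-model association scan).  Because the
motivating study's genotypes and phenotypes are not publicly deposited, a
synthetic-data generator that reproduces the structure the analysis assumes
is a first-class component.

## The breeding model

One cycle of the modeled program (the Wisconsin Quality Synthetic protocol)
is:

1. **Founding.** `n_s0_plants` S0 plants are drawn (with replacement) from
   the current population and each initiates an S1 family.
2. **Selfing.** Each lineage is advanced `selfing_generations` times by
   single-seed descent (default 2: S0 plant → S1 → S2 family
   representative).  Heterozygous loci segregate 1:2:1; expected
   heterozygosity halves each generation.
3. **Screening.** A subset of `n_after_screen` families survives the
   agronomic stress screen.  Under the drift null this subset is uniform at
   random; the default is half the families (the program discarded 50–67%,
   and the milder figure was chosen — the choice is irrelevant under the
   null, where any uniform subset of exchangeable lineages leaves the
   selected families i.i.d. draws from the population).
4. **Selection.** `n_selected` families (default 20) are chosen — uniformly
   at random in drift mode, or as the top-ranked families under a supplied
   ranking function (truncation selection on an additive criterion with a
   configurable heritability) in signal-injection mode.
5. **Bulk-entry recombination.** `next_cycle_pop_size` offspring (default
   450) are formed; each receives one gamete from each of two distinct
   selected families drawn uniformly, so every family contributes equally
   in expectation without materializing all pairwise crosses.  Each family
   is represented by a single selfed plant when contributing gametes (the
   maximal-drift reading; `plants_per_family` generalizes this).

The default three-cycle preset uses 450, 450 and 200 S1 families with 20
selected per cycle — every census number the program recorded.

Two engines implement this model:

* **Unlinked fast engine** (`simulate_drift_trajectories`).  Loci evolve
  independently (linkage equilibrium).  Per locus the engine tracks the
  three genotype-class proportions exactly: the selected families' founder
  classes are i.i.d. draws from the population (see the exchangeability
  argument above), selfing acts on classes, and the bulk-entry offspring
  are a single multinomial draw whose class probabilities average the
  gamete products over ordered distinct family pairs in closed form.
  Tracking classes rather than allele frequencies matters: two selfing
  generations raise the founder-genotype variance by a factor 1 + F = 1.75,
  and a frequency-only simulation would understate drift by that much.
  The engine is distributionally exact (verified against the
  individual-based engine) and vectorizes over loci × replicates.
* **Individual-based engine** (`advance_cycle`, `simulate_wqs_genomes`).
  Carries whole genotypes, literally performing
  found → self → screen → select → recombine.  In linked mode genotypes are
  phased haplotypes and meioses follow a no-interference (Poisson)
  crossover process: between adjacent loci the haplotype-switch probability
  is the Haldane map function r = (1 − e^(−2d/100))/2, and each
  chromosome starts with a fair switch (independent assortment).  The
  Haldane choice is standard and gives closed-form recombinant fractions
  for testing.

A base population is founded at Hardy–Weinberg proportions and linkage
equilibrium at the requested allele frequencies (optionally with
inbreeding F for the initial genotype proportions; default 0, appropriate
because each cycle's S0 pool descends from a random-mated recombination
block).

### What the generator emulates, and what it does not

The synthetic data reproduce: the multi-cycle family structure (the
selected families of each cycle are the genotyped samples, 20 per cycle by
default, with the final cycle genotyped at S1 as in the source program), a
founder allele-frequency spectrum Uniform(0.025, 0.975) whose mean gene
diversity is 2·E[pq] ≈ 0.35, per-locus missingness with mean 0.07 ranging
over 0–0.20 (scaled Beta), and phenotypes with family / family×environment
/ residual variance structure.  They do **not** emulate: ascertainment bias
of the SNP array, linkage disequilibrium inherited from the pre-program
breeding history (founders are at LE), genotyping error, tester genomes
(testers act only through the selection criterion), mutation or migration.
Passing tests therefore demonstrate the correctness and calibration of the
machinery under the stated demographic model, not robustness to array
ascertainment or historical LD.

## Selection mapping

Allele frequencies are maximum-likelihood estimates: observed allele copies
over twice the number of non-missing genotypes, per cycle, with allele
orientation fixed by the pooled dataset.  Per SNP,

    F_ST = s² / ( p̄(1−p̄) + s²/r ),   r = 2 cycles,

with s² the sample variance of frequency across the two cycles (r − 1
denominator, the standard reading of "sample variance") and p̄ their mean.
Loci fixed for the same allele in both cycles are 0/0 and marked unusable;
otherwise F_ST ∈ [0, 1] with F_ST = 0 exactly when the frequencies are
equal and the SNP segregates.

Significance thresholds come from the drift null: the starting cycle's
observed frequencies are propagated through the protocol by the fast
engine; per replicate the maximum F_ST across loci is recorded; the
family-wise threshold is the 95% quantile of these maxima over 1,000
replicates.  Pooled per-locus 95%/99% quantiles over the whole ensemble
calibrate the enrichment analysis (under drift alone, 5% and 1% of loci are
expected to exceed them).  An effective-number-of-markers variant resamples
M_eff loci from the starting spectrum; M_eff comes from the eigenvalue
spectrum of the locus×locus correlation matrix (smallest k whose top-k
eigenvalues reach the PCA cutoff), computed in non-overlapping windows
(default 200 loci) with window counts summed and capped at
min(n_loci, n_samples − 1).

Quantiles use the empirical inverse-CDF convention and exceedance is
strict, which makes the empirical outlier threshold flag exactly
⌊(1−q)·M⌋ loci when values are distinct (175 at q = 0.99 on a
17,590-locus scan) and flag nothing when all values tie.

Simulated final frequencies are taken from the full final population;
optional subsampling mimics finite genotyping.  Whether the original
analysis added genotyping sampling noise to the simulated final cycle is
not stated; the calibration properties tested here are internal and do not
depend on that choice.

## Gene diversity

D = 1 − (p² + q²) per SNP per cycle, with per-cycle genome-wide mean and
SD, and regional summaries reporting percent reduction
100·(D_from − D_to)/D_from, rounded to integer percent for display with
full precision retained.  Default regions are ±15 Mbp windows centered on
the approximate coordinates where the strongest diversity losses were
reported (chr2 ≈ 132 Mbp, chr3 ≈ 55 Mbp, chr4 ≈ 78 Mbp) — the original
regions were delimited visually, so only their centers are anchorable; the
boundaries are fully configurable.  `expected_drift_diversity` provides the
neutral closed form D_t = D_0 (1 − 1/(2Ne))^t for comparison; inverting it
on a simulated run yields an implied Ne well below the S0 census size,
reflecting the 20-family bottleneck.

## Quantitative genetics

**Family model.**  y_ijk = μ + g_i + l_j + gl_ij + b_k(j) + ε_ijk with
environment and replicate-within-environment fixed, family and
family×environment random.  Broad-sense heritability on a family-mean
basis is H = σ²_G / (σ²_G + σ²_GE/e + σ²_ε/(re)).  With a single
environment σ²_GE is structurally zero and flagged.

**REML.**  Variance components are estimated by an EM-started
Average-Information (AI) REML on Henderson's mixed-model equations: the
coefficient matrix C (order p + q, far smaller than n) is factorized once
per iteration and every REML quantity follows from MME identities
(û_i = σ_i² Z_i'Py; tr(P Z_iZ_i') = (q_i − λ_i tr C^{ii})/σ_i²;
−2l_R = (n−p−q)ln σ²_ε + Σ q_i ln σ_i² + ln|C| + y'ê/σ²_ε).  A few EM steps
stabilize the start; AI steps then converge quadratically, with components
proposed non-positive pinned at a small floor and the reduced AI system
re-solved (an AI step that would decrease the likelihood falls back to the
always-ascending EM step).  Convergence is declared at relative parameter
change < 1e-10 (max 500 iterations); components at the floor are reported
as exactly 0, bounding H and h²_G to [0, 1].  Plain EM alone was rejected
as the finishing algorithm: its linear convergence cannot reliably deliver
the 1e-6 agreement with the balanced-design ANOVA solution that the test
suite (and any user comparing against textbook expected mean squares)
demands.  On balanced data the REML optimum coincides with the ANOVA
estimators whenever those are non-negative; the suite asserts agreement to
1e-6 (observed: machine precision).

A note on null behavior: with components truncated at zero, the sampling
distribution of Ĥ under σ²_G = 0 is a zero-inflated positive quantity with
mean ≈ 0.4·√(2(1+1/(e−1))/(F−1)) — about 0.05–0.07 for 150–300 families at
e = 2 — independent of the variance components.  "Recovering H ≈ 0" on
null data therefore means a mean below ~0.1 with a large fraction of exact
zeros, not a mean below the truncation bias floor.

**G-BLUP.**  G = W_C W_C'/(2Σp_l q_l) with W_C the dosage matrix centered
by 2p_l (frequencies from the same samples; monomorphic loci dropped; mean
diagonal ≈ 1 for unrelated HWE samples and rows summing to 0 by
construction).  The model ŷ = Xb + Zu + e, u ~ N(0, G σ²_u) is fitted by
rotating once with the eigenvectors of G and profiling the REML likelihood
over the single ratio λ = σ²_u/σ²_ε (bounded scalar minimization on log λ,
tolerance 1e-10, with an explicit boundary check for σ²_u → 0).  Genomic
heritability is h²_G = σ²_u/(σ²_u + σ²_ε).  Note h²_G is only identifiable
when G departs from the identity; with family-structured samples
(selfed-sib families across cycles) it is well estimated, whereas for
unrelated HWE samples with G ≈ I the likelihood is nearly flat in the
split — the across-cycle analysis relies on the family structure.

**Association scan.**  Each marker enters the G-BLUP model as a fixed
covariate.  Variance components are re-used from the marker-free null fit
(the population-parameters-previously-determined scheme; exact per-marker
re-estimation is available behind `exact=True`).  After whitening with the
null covariance, the marker coefficient is tested with the residual scale
re-estimated per marker and a t reference with n − p − 1 degrees of
freedom — this finite-sample treatment is what keeps null p-values uniform
at the far tail probed by the declared threshold P < 1e-4 with only a few
hundred families.  Monomorphic markers are skipped (`monomorphic`), markers
collinear with the fixed design are skipped (`collinear`).  No further
multiple-testing correction is applied at this stage by design; the
drift-simulation thresholds are the selection-mapping answer to
multiplicity.

Family BLUPs feed the across-cycle G-BLUP with fixed cycle effects; BLUPs
are not standardized per cycle by default (a switch exists), since the
cycle means are already absorbed by the fixed effects.

## Pipeline, seeds, determinism

The `wqscan` CLI chains simulate → filter → scan → diversity → quantgen
from one TOML config; every stage writes its tables plus a JSON summary,
and the run report aggregates them.  A master seed recorded in the config
spawns one deterministic substream per stage, so identical config + seed
give byte-identical reports and a single stage can be re-run
reproducibly.  The filter stage logs counts removed by each criterion
separately (MAF ≤ threshold, strict inequality per the quoted rule;
missingness > threshold), since the motivating dataset's own published
counts (17,719 genotyped / 15,646 polymorphic at MAF > 0.025 / 17,590
tested) cannot all be produced by one filter.

Imputation is deliberately simple — rounded expected dosage (2p̂) or a
Hardy–Weinberg draw — standing in for haplotype-based imputation, which is
out of scope; imputed data are used only where completeness is required
(G, M_eff, association), never for frequency, F_ST or diversity estimates,
which exclude missing values instead.

## Problem sizes and tolerances

The calibration checks run at 2,000 unlinked loci × 1,000 null replicates
(per-locus quantile self-calibration, tolerance ±1 and ±0.5 percentage
points), 200 fresh whole-genome replicates for family-wise coverage
(95% ± 3%), 20,000 replicates for drift closed forms (3 Monte-Carlo SEs),
50 replicates for heritability recovery (±0.1 around the true value) and
association power/type-I, and 100 runs for signal injection (≥ 80% power
at the per-locus 99% quantile with ~1% neutral exceedance).  These sizes
make the full suite complete in a few minutes on one core while keeping
Monte-Carlo error well inside every stated tolerance.  Stochastic checks
are seeded; single-replicate fractions at these sizes carry ~0.5-point
standard errors, so calibration tests average a handful of independent
replicates rather than relying on one.

## Known limitations

* The drift null conditions on observed starting frequencies rather than
  modeling their estimation error; with ≥ 160 genotyped individuals in the
  base cycle this is small compared to three cycles of 20-family
  bottlenecks.
* Linked-mode founders are at linkage equilibrium, so simulated LD is
  entirely program-generated; M_eff on synthetic data will exceed that of
  real array data at equal marker density.
* The family model assumes i.i.d. family and interaction effects and
  balanced or near-balanced layouts; severely unbalanced historical trials
  would call for the full pedigree/spatial machinery that is out of scope.
* `plants_per_family` > 1 assumes the sibling plants descend from one
  generation-(g−1) plant; other nursery topologies are not modeled.
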