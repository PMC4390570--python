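"""End-to-end pipeline: simulate -> filter -> scan -> diversity -> quantgen -> report.

A run is described by a :class:`RunConfig` (flat TOML sections) and executed
stage by stage; every stage writes its tables next to a machine-readable
JSON summary in the output directory, and :func:`run_pipeline` assembles a
:class:`RunReport`.  Identical config + seed give byte-identical reports.

The mirrored workflow is: estimate per-cycle allele frequencies, scan
F_ST between a base and a final cycle, calibrate thresholds by drift
simulation of the breeding protocol, track per-cycle gene diversity with
region summaries, fit per-cycle family variance components (broad-sense H),
and fit a G-BLUP across cycles on family BLUPs (genomic heritability) with
a per-marker association scan.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .protocol import BreedingProtocol, CycleSpec, GeneticMap, TraitArchitecture, wqs_preset
from .sim import make_truncation_fn, simulate_phenotypes, simulate_wqs_genomes
from .genio import (GenotypeMatrix, estimate_allele_frequencies, filter_loci,
                    impute_missing, read_genotypes, write_genotypes)
from .scan import (drift_null_thresholds, empirical_outlier_threshold,
                   enrichment_analysis, fst_scan)
from .diversity import (GenomicRegion, diversity_scan, region_reduction_summary,
                        wqs_regions)
from .quantgen import (GBLUP, association_scan, fit_family_varcomps,
                       genomic_relationship_matrix)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "generate_fixture_dataset"]

log = logging.getLogger("wqscan")

_STAGES = ("simulate", "filter", "scan", "diversity", "quantgen")


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Exactly one of simulation settings (``simulate`` section) or input
    paths (``input`` section) drives a run; the seed is always recorded.
    """

    outdir: Path
    seed: int
    stages: tuple[str, ...] = _STAGES
    simulate: dict = field(default_factory=dict)
    input: dict = field(default_factory=dict)
    filter: dict = field(default_factory=dict)
    scan: dict = field(default_factory=dict)
    diversity: dict = field(default_factory=dict)
    quantgen: dict = field(default_factory=dict)

    @classmethod
    def from_toml(cls, path, overrides: dict | None = None,
                  seed: int | None = None) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        for key, value in (overrides or {}).items():
            section, _, name = key.partition(".")
            if not name:
                raise ValueError(f"override {key!r} must look like section.key")
            raw.setdefault(section, {})[name] = value
        run = raw.get("run", {})
        cfg = cls(
            outdir=Path(run.get("outdir", "wqscan_out")),
            seed=int(seed if seed is not None else run.get("seed", 0)),
            stages=tuple(run.get("stages", _STAGES)),
            simulate=raw.get("simulate", {}),
            input=raw.get("input", {}),
            filter=raw.get("filter", {}),
            scan=raw.get("scan", {}),
            diversity=raw.get("diversity", {}),
            quantgen=raw.get("quantgen", {}),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        has_sim = bool(self.simulate)
        has_input = bool(self.input)
        if has_sim == has_input:
            raise ValueError(
                "exactly one of the [simulate] and [input] sections must be given")
        if has_input:
            geno = self.input.get("genotypes")
            if not geno:
                raise ValueError("[input] needs a 'genotypes' path")
            if not Path(geno).exists():
                raise FileNotFoundError(f"genotype file not found: {geno}")
            pheno = self.input.get("phenotypes")
            if pheno and not Path(pheno).exists():
                raise FileNotFoundError(f"phenotype file not found: {pheno}")
        if has_sim and "simulate" not in self.stages:
            raise ValueError("[simulate] section given but simulate stage disabled")


@dataclass
class RunReport:
    """Aggregated per-stage summaries; every number traces to a stage
    output file in ``outdir``."""

    seed: int
    version: str
    stages: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.seed, "version": self.version, "stages": self.stages},
            indent=2, sort_keys=True)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _protocol_from_config(sim: dict) -> BreedingProtocol:
    if sim.get("preset", "wqs") == "wqs" and "cycles" not in sim:
        return wqs_preset()
    cycles = [CycleSpec(n_s0_plants=c["n_s0_plants"], n_selected=c["n_selected"],
                        selfing_generations=c.get("selfing_generations", 2),
                        n_after_screen=c.get("n_after_screen"))
              for c in sim["cycles"]]
    return BreedingProtocol(cycles,
                            next_cycle_pop_size=sim.get("next_cycle_pop_size", 450),
                            plants_per_family=sim.get("plants_per_family", 1))


def _apply_missingness(geno: GenotypeMatrix, rng, max_rate: float = 0.20,
                       mean_rate: float = 0.07) -> GenotypeMatrix:
    """Mask genotypes at per-locus rates drawn from a Beta distribution
    scaled to [0, max_rate] with the given mean (emulating array
    missingness: mean 0.07, range 0-0.20)."""
    if max_rate <= 0:
        return geno
    a = 1.4
    b = a * (max_rate - mean_rate) / mean_rate
    rates = max_rate * rng.beta(a, b, size=geno.n_loci)
    mask = rng.random(geno.dosages.shape) < rates
    dosages = geno.dosages.copy()
    dosages[mask] = np.nan
    return GenotypeMatrix(dosages, geno.locus_ids, geno.sample_ids, geno.cycles,
                          geno.chromosomes, geno.bp, geno.cm)


def _stage_simulate(cfg: RunConfig, rng, out: Path) -> dict:
    sim = cfg.simulate
    protocol = _protocol_from_config(sim)
    n_loci = int(sim.get("n_loci", 2000))
    gmap = GeneticMap.uniform(n_loci)
    qtl = sim.get("qtl_loci", [])
    arch = None
    selection_fn = None
    if qtl:
        arch = TraitArchitecture(
            qtl_loci=tuple(int(q) for q in qtl),
            qtl_effects=tuple(sim.get("qtl_effects", [1.0] * len(qtl))),
            h2_target=float(sim.get("h2_target", 1.0)))
        selection_fn = make_truncation_fn(arch)
    geno = simulate_wqs_genomes(protocol, gmap, rng,
                                base_cycle_label=sim.get("base_cycle", "C2"),
                                selection_fn=selection_fn)
    truth_freqs = estimate_allele_frequencies(geno, by_cycle=True)
    geno = _apply_missingness(geno, rng,
                              max_rate=float(sim.get("max_missing_rate", 0.20)),
                              mean_rate=float(sim.get("mean_missing_rate", 0.07)))
    write_genotypes(geno, out / "genotypes.tsv")

    varcomps = tuple(sim.get("varcomps", (3.0, 2.0, 6.0)))
    pheno = simulate_phenotypes(
        geno, arch, int(sim.get("n_environments", 2)),
        int(sim.get("n_replicates", 3)), varcomps, rng,
        trait=sim.get("trait", "trait"))
    pheno = pheno.merge(geno.samples.rename(columns={"id": "family"}), on="family")
    pheno.to_csv(out / "phenotypes.csv", index=False)

    truth = {
        "founder_frequencies_file": "truth_frequencies.tsv",
        "qtl_loci": list(map(int, qtl)),
        "qtl_effects": [float(x) for x in (arch.qtl_effects if arch else [])],
        "varcomps": {"sigma2_G": varcomps[0], "sigma2_GE": varcomps[1],
                     "sigma2_e": varcomps[2]},
    }
    truth_freqs.p.round(6).to_csv(out / "truth_frequencies.tsv", sep="\t")
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return {"n_samples": geno.n_samples, "n_loci": geno.n_loci,
            "cycles": geno.cycle_order,
            "mean_missing": round(float(geno.missing_rate().mean()), 4)}


def _load_genotypes(cfg: RunConfig, out: Path) -> GenotypeMatrix:
    if cfg.input:
        path = cfg.input["genotypes"]
        fmt = cfg.input.get("format", "delimited")
        return read_genotypes(path, format=fmt)
    return read_genotypes(out / ("genotypes_filtered.tsv"
                                 if (out / "genotypes_filtered.tsv").exists()
                                 and "filter" not in cfg.stages
                                 else "genotypes.tsv"))


def _stage_filter(cfg: RunConfig, geno: GenotypeMatrix, out: Path) -> tuple[GenotypeMatrix, dict]:
    kept, report = filter_loci(
        geno, maf_min=float(cfg.filter.get("maf_min", 0.025)),
        max_missing=float(cfg.filter.get("max_missing", 0.20)))
    write_genotypes(kept, out / "genotypes_filtered.tsv")
    summary = dataclasses.asdict(report)
    (out / "filter.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return kept, summary


def _stage_scan(cfg: RunConfig, geno: GenotypeMatrix, rng, out: Path) -> dict:
    order = geno.cycle_order
    cycle_a = cfg.scan.get("cycle_a", order[0])
    cycle_b = cfg.scan.get("cycle_b", order[-1])
    freqs = estimate_allele_frequencies(geno, by_cycle=True)
    scan = fst_scan(freqs, cycle_a, cycle_b, loci=geno.loci)
    scan.write(out / "fst_scan.tsv")

    p0 = freqs.p[cycle_a].to_numpy()
    usable_p0 = p0[scan.usable & ~np.isnan(p0)]
    protocol = _protocol_from_config(cfg.simulate) if cfg.simulate else wqs_preset()
    null = drift_null_thresholds(
        usable_p0, protocol, rng,
        n_reps=int(cfg.scan.get("n_reps", 1000)),
        fwer=float(cfg.scan.get("fwer", 0.05)),
        meff=cfg.scan.get("meff"))
    outlier_q = float(cfg.scan.get("outlier_quantile", 0.99))
    thr, flagged = empirical_outlier_threshold(scan, outlier_q)
    enrich = enrichment_analysis(scan, null)
    summary = {
        "cycle_a": cycle_a, "cycle_b": cycle_b,
        "n_loci_tested": scan.n_usable,
        "null": {k: (round(v, 6) if isinstance(v, float) else v)
                 for k, v in null.to_dict().items()},
        "n_above_fwer": int((scan.usable_fst > null.fwer_threshold).sum()),
        "outlier_quantile": outlier_q,
        "outlier_threshold": round(thr, 6),
        "n_outliers": flagged,
        "enrichment": {k: round(v, 6) for k, v in enrich.to_dict().items()},
    }
    (out / "null.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


def _stage_diversity(cfg: RunConfig, geno: GenotypeMatrix, out: Path) -> dict:
    order = cfg.diversity.get("cycles", geno.cycle_order)
    freqs = estimate_allele_frequencies(geno, by_cycle=True)
    scan = diversity_scan(freqs, order, loci=geno.loci)
    scan.write(out / "diversity.tsv")
    regions = [GenomicRegion(r["chromosome"], int(r["start_bp"]), int(r["end_bp"]),
                             r.get("label", ""))
               for r in cfg.diversity.get("regions", [])]
    summary = {
        "cycles": list(order),
        "mean_d": {c: round(float(scan.summary.loc[c, "mean_d"]), 6) for c in order},
        "sd_d": {c: round(float(scan.summary.loc[c, "sd_d"]), 6) for c in order},
    }
    # genome-wide reduction computed directly from the per-cycle means
    c_from, c_to = order[0], order[-1]
    d_from, d_to = summary["mean_d"][c_from], summary["mean_d"][c_to]
    if d_from > 0:
        summary["genomewide_percent_reduction"] = int(round(100 * (d_from - d_to) / d_from))
    if regions:
        reg = region_reduction_summary(scan, regions, c_from, c_to)
        reg.to_csv(out / "region_reduction.tsv", sep="\t", index=False)
        summary["regions"] = reg.round(6).to_dict(orient="records")
    (out / "diversity.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


def _stage_quantgen(cfg: RunConfig, geno: GenotypeMatrix, rng, out: Path) -> dict:
    pheno_path = (cfg.input.get("phenotypes") if cfg.input
                  else out / "phenotypes.csv")
    if pheno_path is None or not Path(pheno_path).exists():
        return {"skipped": "no phenotypes available"}
    pheno = pd.read_csv(pheno_path)
    trait = cfg.quantgen.get("trait", [c for c in pheno.columns
                                       if c not in ("family", "environment",
                                                    "replicate", "cycle")][0])
    rows, blup_frames = [], []
    for cycle, block in pheno.groupby("cycle", sort=False):
        if block["family"].nunique() < 2:
            continue
        vc = fit_family_varcomps(block, trait)
        rows.append({"cycle": cycle, "trait": trait,
                     "sigma2_G": vc.sigma2_G, "sigma2_GE": vc.sigma2_GE,
                     "sigma2_e": vc.sigma2_e, "H": vc.H})
        blup_frames.append(pd.DataFrame({
            "family": vc.blups.index, "cycle": cycle, "blup": vc.blups.to_numpy()}))
    herit = pd.DataFrame(rows)
    herit.round(6).to_csv(out / "heritability.tsv", sep="\t", index=False)
    summary = {"trait": trait,
               "per_cycle_H": {r["cycle"]: round(r["H"], 4) for r in rows}}

    if blup_frames:
        blups = pd.concat(blup_frames, ignore_index=True)
        sample_cycle = geno.samples.set_index("id")["cycle"]
        keep = blups["family"].isin(sample_cycle.index)
        blups = blups[keep]
        idx = [list(geno.sample_ids).index(f) for f in blups["family"]]
        sub = geno.take_samples(np.asarray(idx, dtype=int))
        sub = impute_missing(sub, "locus_mean")
        poly = (estimate_allele_frequencies(sub).p["all"].to_numpy() * 1.0)
        polymask = (poly > 0) & (poly < 1)
        sub = sub.take_loci(np.flatnonzero(polymask))
        G = genomic_relationship_matrix(sub)
        Xcyc = pd.get_dummies(pd.Categorical(blups["cycle"]), drop_first=False)
        fit = GBLUP(blups["blup"].to_numpy(), G, X=Xcyc).fit()
        assoc = association_scan(
            blups["blup"].to_numpy(), sub, G, fixed=Xcyc,
            alpha=float(cfg.quantgen.get("alpha", 1e-4)), null_fit=fit)
        assoc.write(out / "association.tsv")
        summary["h2_g_across_cycles"] = round(fit.h2_g, 4)
        summary["n_markers_tested"] = int((assoc.table["status"] == "ok").sum())
        summary["n_significant"] = assoc.n_significant
    (out / "quantgen.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages in dependency order and assemble the
    report.  A stage failure aborts the run with the stage named; outputs
    of completed stages are retained."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    # one deterministic substream per stage, independent of stage selection
    streams = {name: np.random.default_rng(child)
               for name, child in zip(_STAGES, master.spawn(len(_STAGES)))}
    report = RunReport(seed=config.seed, version=__version__)
    geno = None
    for stage in _STAGES:
        if stage not in config.stages:
            continue
        log.info("stage %s started", stage)
        try:
            if stage == "simulate":
                report.stages[stage] = _stage_simulate(config, streams[stage], out)
            else:
                if geno is None:
                    geno = _load_genotypes(config, out)
                if stage == "filter":
                    geno, report.stages[stage] = _stage_filter(config, geno, out)
                elif stage == "scan":
                    report.stages[stage] = _stage_scan(config, geno, streams[stage], out)
                elif stage == "diversity":
                    report.stages[stage] = _stage_diversity(config, geno, out)
                elif stage == "quantgen":
                    report.stages[stage] = _stage_quantgen(config, geno, streams[stage], out)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        log.info("stage %s done", stage)
    report.write(out / "report.json")
    return report


def assemble_report(outdir, seed: int) -> RunReport:
    """Rebuild the run report from the stage JSON files present in
    ``outdir`` (the ``report`` subcommand)."""
    out = Path(outdir)
    report = RunReport(seed=seed, version=__version__)
    for stage, fname in [("filter", "filter.json"), ("scan", "null.json"),
                         ("diversity", "diversity.json"),
                         ("quantgen", "quantgen.json")]:
        path = out / fname
        if path.exists():
            report.stages[stage] = json.loads(path.read_text())
    report.write(out / "report.json")
    return report


# ---------------------------------------------------------------------------
# fixture presets


_PRESETS = {
    "wqs_like_small": {"n_loci": 2000, "qtl": 0},
    "wqs_like_full": {"n_loci": 17590, "qtl": 0},
    "selection_injected": {"n_loci": 2000, "qtl": 5},
}


def generate_fixture_dataset(preset: str, seed: int, outdir) -> Path:
    """Write a self-contained synthetic dataset for one of the presets.

    ``wqs_like_small``: 2,000 SNPs, 4 cycles x 20 families per cycle.
    ``wqs_like_full``: 17,590 SNPs at the same family structure.
    ``selection_injected``: as small, plus 5 loci under truncation
    selection.  Emits genotypes (+map), phenotypes, and truth files (true
    per-cycle frequencies, QTL, variance components).
    """
    if preset not in _PRESETS:
        raise KeyError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
    spec = _PRESETS[preset]
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sim_cfg = {"n_loci": spec["n_loci"]}
    if spec["qtl"]:
        qtl = sorted(rng.choice(spec["n_loci"], size=spec["qtl"], replace=False))
        sim_cfg["qtl_loci"] = [int(q) for q in qtl]
        sim_cfg["qtl_effects"] = [1.0] * spec["qtl"]
        sim_cfg["h2_target"] = 1.0
    cfg = RunConfig(outdir=out, seed=seed, stages=("simulate",), simulate=sim_cfg)
    run_pipeline(cfg)
    return out
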