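"""End-to-end orchestration on synthetic or user-supplied data.

``run_all`` executes simulate -> differential expression -> GO
classification -> heritability -> conservation -> overlap -> morphology
with one config and one root seed, writing per-stage TSVs, a summary JSON
and a run manifest.  Re-running with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import conservation as conservation_mod
from . import go_classify, heritability, morphology, overlap, synthetic_data
from .diffexpr import call_responsive_genes, rpkm
from .synthetic_data import SimulationConfig

log = logging.getLogger("evoko")

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """All stage thresholds plus the simulation block; defaults are the
    study's published cutoffs (DE: adjusted P < 0.05, FC > 1.5; GO:
    adjusted P < 0.01, FE > 2, term size < 200; overlap: >= 20 clustered
    effects per line, 1000 resamplings, 99% interval)."""

    simulation: SimulationConfig
    alpha: float = 0.05
    min_fc: float = 1.5
    padj_cut: float = 0.01
    fe_cut: float = 2.0
    max_term_size: int = 200
    min_clustered: int = 20
    n_iter: int = 1000
    ci: float = 0.99
    morph_alpha: float = 0.05
    morph_min_rel_diff: float = 0.05
    n_complex_lines: int = 4
    run_conservation: bool = True
    run_overlap: bool = True
    run_morphology: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.padj_cut < 1 and 0 < self.ci < 1):
            raise ValueError("alpha, padj_cut and ci must lie in (0, 1)")
        if self.min_fc <= 1 or self.fe_cut <= 0:
            raise ValueError("min_fc must exceed 1 and fe_cut must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)


def _seeds(root: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(root)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_all(config: PipelineConfig, outdir) -> dict:
    """Run every configured stage on synthetic data; return the summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    seeds = _seeds(config.seed, 12)
    summary: dict = {}

    # --- simulate universe + truth ---------------------------------------
    universe = synthetic_data.generate_go_universe(
        sim.n_genes, sim.n_terms, sim.term_size_range, sim.large_term_fraction, seed=seeds[0]
    )
    truth = synthetic_data.generate_truth(
        universe,
        n_native=sim.n_native,
        n_spurious=sim.n_spurious,
        n_focus_terms=sim.n_focus_terms,
        lfc_magnitude=sim.lfc_magnitude,
        seed=seeds[1],
    )
    genes = sorted(universe.class_background("BP"))
    universe.to_tsv(outdir / "annotation.tsv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {
                "native_genes": sorted(truth.native_genes),
                "spurious_genes": sorted(truth.spurious_genes),
                "focus_terms": truth.focus_terms,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    summary["n_planted_responsive"] = len(truth.responsive)
    summary["n_planted_native"] = len(truth.native_genes)
    summary["n_planted_spurious"] = len(truth.spurious_genes)

    # --- differential expression ------------------------------------------
    log.info("simulating counts and calling responsive genes")
    wt, mut = synthetic_data.simulate_counts(
        truth,
        genes,
        replicates=sim.replicates_per_line,
        nb_dispersion=sim.nb_dispersion,
        library_size=sim.library_size,
        seed=seeds[2],
    )
    effects = call_responsive_genes(wt, mut, alpha=config.alpha, min_fc=config.min_fc)
    effects.to_csv(outdir / "effects_reference.tsv", sep="\t", index=False)
    responsive = set(effects.loc[effects["significant"], "gene"])
    summary["n_responsive"] = len(responsive)
    recall = len(responsive & truth.responsive) / max(len(truth.responsive), 1)
    summary["responsive_recall"] = round(recall, 4)

    # --- GO classification -------------------------------------------------
    enr = go_classify.enrich(
        responsive, universe, config.padj_cut, config.fe_cut, config.max_term_size
    )
    go_classify.enrichment_to_frame(enr).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    classification = go_classify.classify_effects(responsive, enr, universe)
    classification.to_tsv(outdir / "classification.tsv")
    summary["n_clustered"] = len(classification.clustered)
    summary["n_distributed"] = len(classification.distributed)

    # --- heritability ------------------------------------------------------
    pop = synthetic_data.simulate_segregants(
        truth, n_tetrads=sim.n_tetrads, noise_sd=sim.segregant_noise_sd, seed=seeds[3]
    )
    h2_tab = heritability.estimate_h2_table(pop, alpha=config.alpha)
    h2_tab.to_csv(outdir / "heritability.tsv", sep="\t", index=False)
    h2 = dict(zip(h2_tab["gene"], h2_tab["h2"]))
    h2_c = [h2[g] for g in sorted(classification.clustered & set(h2))]
    h2_d = [h2[g] for g in sorted(classification.distributed & set(h2))]
    if h2_c and h2_d:
        summary["h2_mwu_p"] = heritability.compare_h2_groups(h2_c, h2_d)
        summary["h2_mean_clustered"] = float(np.mean(h2_c))
        summary["h2_mean_distributed"] = float(np.mean(h2_d))

    # --- conservation ------------------------------------------------------
    if config.run_conservation:
        wt2, mut2 = synthetic_data.simulate_counts(
            truth,
            genes,
            species="target_species",
            strain="target_species",
            replicates=sim.replicates_per_line,
            nb_dispersion=sim.nb_dispersion,
            library_size=sim.library_size,
            seed=seeds[4],
        )
        target = call_responsive_genes(wt2, mut2, alpha=config.alpha, min_fc=config.min_fc)
        target.to_csv(outdir / "effects_target.tsv", sep="\t", index=False)
        rates = {}
        counts = {}
        for label, gene_set in (
            ("clustered", classification.clustered),
            ("distributed", classification.distributed),
        ):
            sub = effects[effects["gene"].isin(gene_set)]
            res = conservation_mod.call_conserved(sub, target)
            rates[label] = {"rate": res["rate"], "se": res["se"], "n": res["n"]}
            n_cons = int(res["calls"]["conserved"].sum()) if res["n"] else 0
            counts[label] = (n_cons, res["n"])
        summary["conservation"] = rates
        if counts["clustered"][1] and counts["distributed"][1]:
            summary["conservation_contrast_p"] = conservation_mod.conservation_contrast(
                counts["clustered"], counts["distributed"]
            )
        with open(outdir / "conservation.json", "w") as fh:
            json.dump(rates, fh, indent=1, sort_keys=True)

    # --- overlap across a synthetic complex --------------------------------
    if config.run_overlap:
        lines = _synthetic_complex_lines(truth, genes, config, seeds[5])
        lines = overlap.filter_lines(lines, config.min_clustered)
        if len(lines) >= 2:
            res = overlap.resample_null(
                lines, n_iter=config.n_iter, seed=seeds[6], group_id="complex_1", ci=config.ci
            )
            summary["overlap"] = {
                "observed": res.observed_overlap,
                "null_mean": res.null_mean,
                "ci99": list(res.ci99),
                "fold": res.fold,
                "significant": res.significant,
            }
            with open(outdir / "overlap.json", "w") as fh:
                json.dump(summary["overlap"], fh, indent=1, sort_keys=True)

    # --- morphology ---------------------------------------------------------
    if config.run_morphology:
        rng = np.random.default_rng(seeds[7])
        n_traits = sim.morphology_n_traits
        traits = [f"T{i:03d}" for i in range(n_traits)]
        focal_affected = rng.choice(n_traits, size=40, replace=False)
        shared = set(focal_affected[:15])  # planted shared core across lines
        affected = {"focal": {traits[i]: 1.0 for i in focal_affected}}
        for k in range(3):
            others = set(rng.choice(n_traits, size=25, replace=False)) | shared
            affected[f"partner_{k+1}"] = {traits[i]: 1.0 for i in others}
        tables = synthetic_data.simulate_morphology(affected, n_traits=n_traits, seed=seeds[8])
        calls = {
            line: morphology.call_trait_effects(
                tables["wild_type"], tbl, config.morph_alpha, config.morph_min_rel_diff
            )
            for line, tbl in tables.items()
            if line != "wild_type"
        }
        for line, tab in calls.items():
            tab.to_csv(outdir / f"morphology_{line}.tsv", sep="\t", index=False)
        affected_sets = {
            line: set(tab.loc[tab["affected"], "trait"]) for line, tab in calls.items()
        }
        summary["morphology_affected"] = {k: len(v) for k, v in affected_sets.items()}

    summary_path = outdir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=float)
    manifest = {
        "config": {**asdict(config), "simulation": asdict(sim)},
        "stage_seeds": seeds,
        "outputs": sorted(p.name for p in outdir.iterdir()),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return summary


def _synthetic_complex_lines(truth, genes, config: PipelineConfig, seed: int) -> list[overlap.LineEffects]:
    """Member lines of a synthetic complex: a shared clustered core plus
    distributed effects drawn from a common background pool (lines of a
    compendium share common stress responders, so the null overlap is not
    degenerate)."""
    rng = np.random.default_rng(seed)
    core = sorted(truth.native_genes)
    background = np.array(sorted(set(genes) - truth.responsive))
    shared_pool = rng.choice(background, size=min(300, len(background)), replace=False)
    pool_dirs = dict(zip(shared_pool, rng.choice([-1, 1], size=len(shared_pool))))
    lines = []
    for i in range(config.n_complex_lines):
        extra = rng.choice(shared_pool, size=min(2 * len(core), len(shared_pool)), replace=False)
        clustered = {g: int(np.sign(truth.planted_lfc.get(g, 1.0)) or 1) for g in core}
        distributed = {g: int(pool_dirs[g]) for g in extra}
        lines.append(
            overlap.LineEffects(line_id=f"member_{i+1}", clustered=clustered, distributed=distributed)
        )
    return lines
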