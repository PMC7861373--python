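"""End-to-end orchestration: isolates in, results bundle out.

Runs the full strain-level population analysis — genotype reading, Bruvo
distances, strain delineation (fixed or auto threshold), reference
matching, rarefaction, composition/diversity, PERMANOVA/PERMDISP/PCoA,
allele-frequency statistics, admixture inference across K with DIC,
chain alignment, dominant-ancestor calls, and the bootstrapped NJ tree —
writing every stage's outputs plus a manifest of parameters and seeds to
a bundle directory, so any stage can be re-examined or re-run.

Defaults mirror the study-scale settings (threshold 0.3, rarefaction to
32 isolates, K = 1..12 with 5 chains, 999 permutations, 1000 bootstrap
replicates).  The MCMC sweep counts are the one knob desk runs should
lower (see ``n_burnin`` / ``n_iter``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import ancestry, delineation, diversity, phylogeny, popgen
from .bruvo import distance_matrix
from .genotype_io import (GenotypeTable, LocusConfig, read_isolates,
                          read_locus_config, read_reference_strains,
                          write_strain_table)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    isolates_path: str = ""
    locus_config_path: str = ""
    reference_path: str = ""          # optional reference strain MLG table
    out_dir: str = "results"
    threshold: float | str = 0.3      # or "auto"
    linkage: str = "farthest"
    rarefaction_n: int = 32
    seed: int = 0
    k_range: tuple[int, int] = (1, 12)
    n_chains: int = 5
    n_burnin: int = 500_000
    n_iter: int = 100_000
    n_permutations: int = 999
    n_bootstrap: int = 1000
    n_align_orders: int = 100
    dominant_cutoff: float = 0.75
    dominant_abundance: float = 0.10  # report rule: >=10% ...
    dominant_min_samples: int = 2     # ... in at least 2 samples
    vintage: str = "2017"
    keep_incomplete: bool = False     # retain isolates with missing loci

    def to_dict(self) -> dict:
        d = asdict(self)
        d["k_range"] = list(self.k_range)
        return d


def _write_json(obj, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(cfg: PipelineConfig,
                 table: GenotypeTable | None = None,
                 locus_config: LocusConfig | None = None,
                 reference: GenotypeTable | None = None) -> dict:
    """Execute all stages; returns the manifest (also written to the
    bundle).  ``table``/``reference`` may be passed directly instead of
    file paths (e.g. straight from the simulator)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg.to_dict(), "artifacts": {}, "stats": {}}
    art = manifest["artifacts"]

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("read")
        if table is None:
            locus_config = read_locus_config(cfg.locus_config_path)
            table = read_isolates(cfg.isolates_path, locus_config)
        if reference is None and cfg.reference_path:
            reference = read_reference_strains(cfg.reference_path,
                                               locus_config)
        if not cfg.keep_incomplete:
            table = delineation.exclude_incomplete(table)
        manifest["stats"]["n_isolates_typed"] = len(table)

        stage("distance")
        # deterministic isolate order: by sample then id
        order = table.metadata.sort_values(
            ["vineyard", "barrel", "stage", "isolate_id"]).index.to_numpy()
        table = table.subset(order)
        dm = distance_matrix(table)
        dm.to_csv(out / "bruvo_distances.csv")
        art["bruvo_distances"] = "bruvo_distances.csv"

        stage("delineate")
        if cfg.threshold == "auto":
            sug = delineation.suggest_threshold(dm, cfg.linkage)
            threshold = sug.threshold
            manifest["stats"]["auto_threshold"] = threshold
            manifest["stats"]["threshold_gap"] = list(sug.gap)
            manifest["stats"]["histogram_bimodal"] = sug.histogram_bimodal
        else:
            threshold = float(cfg.threshold)
        scan = delineation.threshold_scan(dm, cfg.linkage)
        scan.to_frame().to_csv(out / "threshold_scan.csv", index=False)
        art["threshold_scan"] = "threshold_scan.csv"
        assignment = delineation.collapse_mlgs(dm, threshold, cfg.linkage,
                                               table)
        manifest["stats"]["threshold"] = threshold
        manifest["stats"]["n_strains"] = assignment.n_strains

        stage("match_references")
        if reference is not None:
            names = delineation.match_to_reference(assignment, reference,
                                                   threshold, cfg.vintage)
        else:
            names = {s: f"{cfg.vintage} Strain {s + 1}"
                     for s in assignment.representatives}
        manifest["stats"]["n_matched_to_reference"] = sum(
            1 for v in names.values()
            if not v.startswith(f"{cfg.vintage} Strain"))

        rep_ids = [assignment.representatives[s]
                   for s in sorted(assignment.representatives)]
        pos = {iid: i for i, iid in enumerate(table.ids)}
        rep_table = table.subset([pos[i] for i in rep_ids])
        rep_table = GenotypeTable(
            [names[s] for s in sorted(assignment.representatives)],
            rep_table.loci, rep_table.alleles, rep_table.metadata)
        write_strain_table(rep_table, out / "strain_mlgs.csv",
                           config=locus_config)
        art["strain_mlgs"] = "strain_mlgs.csv"

        adf = assignment.to_frame(table.metadata, table.ids)
        adf["strain_name"] = adf["strain_id"].map(names)
        adf.to_csv(out / "strain_assignment.csv", index=False)
        art["strain_assignment"] = "strain_assignment.csv"

        stage("rarefy")
        rarefied = delineation.rarefy_isolates(table, cfg.rarefaction_n,
                                               seed=cfg.seed)
        manifest["stats"]["n_isolates_rarefied"] = len(rarefied)
        manifest["stats"]["n_strains_after_rarefaction"] = int(
            len({assignment.isolate_to_strain[i] for i in rarefied.ids}))

        stage("abundance_diversity")
        counts = diversity.strain_abundance(rarefied, assignment, names)
        counts.to_csv(out / "strain_counts.csv")
        art["strain_counts"] = "strain_counts.csv"
        props = diversity.relative_abundance(counts)
        props.to_csv(out / "strain_relative_abundance.csv")
        art["strain_relative_abundance"] = "strain_relative_abundance.csv"
        div = diversity.diversity_table(counts)
        div.to_csv(out / "diversity.csv")
        art["diversity"] = "diversity.csv"

        stage("ordination_tests")
        bc = diversity.bray_curtis_matrix(counts)
        groups = [s.split("|")[0] for s in counts.index]  # vineyard
        coords = diversity.pcoa(bc)
        coords.to_frame().to_csv(out / "pcoa_coordinates.csv",
                                 index_label="sample")
        art["pcoa_coordinates"] = "pcoa_coordinates.csv"
        perma = diversity.permanova(bc, groups, cfg.n_permutations,
                                    seed=cfg.seed + 1)
        disp = diversity.permdisp(bc, groups, cfg.n_permutations,
                                  seed=cfg.seed + 2)
        _write_json({"permanova": perma.to_dict(),
                     "permdisp": disp.to_dict()},
                    out / "composition_tests.json")
        art["composition_tests"] = "composition_tests.json"
        manifest["stats"]["permanova_pseudo_F"] = perma.statistic
        manifest["stats"]["permanova_R2"] = perma.r_squared
        manifest["stats"]["permanova_p"] = perma.p_value

        stage("popgen")
        vineyards = table.metadata["vineyard"].to_numpy()
        het = popgen.heterozygosity(table)
        freqs = popgen.AlleleFrequencies.from_table(table)
        pi_locus, pi_overall = popgen.probability_of_identity(freqs)
        fix = popgen.fixation_indices(table, vineyards)
        per_locus = het.join(fix).join(pi_locus)
        per_locus["n_alleles"] = pd.Series(
            popgen.allele_counts_per_locus(table))
        per_locus.to_csv(out / "popgen_per_locus.csv")
        art["popgen_per_locus"] = "popgen_per_locus.csv"
        summary = {"isolate_level": {
            **popgen.heterozygosity_summary(table),
            **popgen.fixation_summary(fix),
            "PI_overall": pi_overall,
        }}
        # strain-level mirror (one representative per strain)
        rep_vineyard = [assignment.to_frame(table.metadata, table.ids)
                        .set_index("isolate_id").loc[r, "vineyard"]
                        for r in rep_ids]
        sfreqs = popgen.AlleleFrequencies.from_table(rep_table)
        _, spi = popgen.probability_of_identity(sfreqs)
        summary["strain_level"] = {
            **popgen.heterozygosity_summary(rep_table),
            "PI_overall": spi,
        }
        if len(set(rep_vineyard)) >= 2:
            sfix = popgen.fixation_indices(rep_table,
                                           np.asarray(rep_vineyard))
            summary["strain_level"].update(popgen.fixation_summary(sfix))
        else:
            logger.warning("all strain representatives come from one "
                           "vineyard; skipping strain-level F-statistics")
        _write_json(summary, out / "popgen_summary.json")
        art["popgen_summary"] = "popgen_summary.json"
        manifest["stats"]["F_IS"] = summary["isolate_level"]["F_IS"]
        manifest["stats"]["F_ST"] = summary["isolate_level"]["F_ST"]

        stage("structure")
        k_lo, k_hi = cfg.k_range
        strain_pops = rep_vineyard
        runs: dict[int, list] = {}
        for K in range(k_lo, k_hi + 1):
            runs[K] = [ancestry.run_chain(
                rep_table, K, cfg.n_burnin, cfg.n_iter,
                seed=cfg.seed + 1000 * K + c)
                for c in range(cfg.n_chains)]
        dic_df = ancestry.dic_table(runs)
        dic_df.to_csv(out / "dic_table.csv", index=False)
        art["dic_table"] = "dic_table.csv"
        best_k = int(dic_df.groupby("K")["DIC"].mean().idxmin())
        manifest["stats"]["best_K_by_DIC"] = best_k
        aligned, consensus, H = ancestry.align_runs(
            [c.Q for c in runs[best_k]], cfg.n_align_orders,
            seed=cfg.seed + 3)
        manifest["stats"]["alignment_H"] = H
        ancestry.write_q_matrix(consensus, rep_table.ids, strain_pops,
                                out / f"q_matrix_K{best_k}.txt")
        art["q_matrix"] = f"q_matrix_K{best_k}.txt"
        dom = ancestry.dominant_ancestor(consensus, cfg.dominant_cutoff)
        dom_df = pd.DataFrame({"strain": rep_table.ids,
                               "dominant_ancestor":
                                   [d if d is None else f"K{d + 1}"
                                    for d in dom]})
        dom_df.to_csv(out / "dominant_ancestors.csv", index=False)
        art["dominant_ancestors"] = "dominant_ancestors.csv"
        if len(set(strain_pops)) >= 2:
            r2, p_r2, contrib = ancestry.structure_r2(
                consensus, strain_pops, cfg.n_permutations,
                seed=cfg.seed + 4)
        else:
            logger.warning("all strain representatives come from one "
                           "vineyard; ancestry-vs-population R2 undefined")
            r2, p_r2, contrib = None, None, {}
        _write_json({"R2": r2, "p": p_r2, "leave_one_out": contrib},
                    out / "structure_r2.json")
        art["structure_r2"] = "structure_r2.json"
        manifest["stats"]["structure_R2"] = r2

        stage("tree")
        tree = phylogeny.bootstrap_support(rep_table, cfg.n_bootstrap,
                                           seed=cfg.seed + 5)
        dom_map = {rep_table.ids[i]: dom[i] for i in range(len(rep_table))}
        colours = {k: f"C{k}" for k in range(best_k)}
        phylogeny.annotate_ancestry(tree, dom_map, colours)
        with open(out / "nj_tree.nwk", "w", encoding="utf-8") as fh:
            fh.write(phylogeny.to_newick(tree) + "\n")
        art["nj_tree"] = "nj_tree.nwk"
        phylogeny.colour_table(tree).to_csv(out / "tree_colours.csv",
                                            index=False)
        art["tree_colours"] = "tree_colours.csv"

    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise PipelineError(
            f"pipeline failed at stage with error: {exc}") from exc

    _write_json(manifest, out / "manifest.json")
    return manifest


REQUIRED_ARTIFACTS = (
    "strain_counts", "diversity", "composition_tests", "popgen_per_locus",
    "dic_table", "q_matrix", "nj_tree",
)


def dominant_strains(props: pd.DataFrame, min_abundance: float = 0.10,
                     min_samples: int = 2) -> list[str]:
    """Strains reaching >= ``min_abundance`` relative abundance in at
    least ``min_samples`` samples; everything else is a 'minor strain'."""
    hits = (props >= min_abundance).sum(axis=0)
    return sorted(props.columns[hits >= min_samples].tolist())


def summarize(bundle_dir) -> str:
    """Human-readable markdown report over a completed results bundle."""
    out = Path(bundle_dir)
    with open(out / "manifest.json", encoding="utf-8") as fh:
        manifest = json.load(fh)
    missing = [k for k in REQUIRED_ARTIFACTS
               if k not in manifest["artifacts"]
               or not (out / manifest["artifacts"][k]).exists()]
    if missing:
        raise PipelineError(f"incomplete bundle; missing: {missing}")
    stats = manifest["stats"]
    cfg = manifest["config"]

    lines = ["# Strain population analysis report", ""]
    lines.append(f"- isolates typed: {stats['n_isolates_typed']}")
    lines.append(f"- strains (before rarefaction): {stats['n_strains']}")
    lines.append("- strains (after rarefaction): "
                 f"{stats['n_strains_after_rarefaction']}")
    lines.append(f"- delineation threshold: {stats['threshold']}"
                 + (" (auto)" if "auto_threshold" in stats else ""))

    props = pd.read_csv(out / manifest["artifacts"]
                        ["strain_relative_abundance"], index_col=0)
    dom = dominant_strains(props, cfg["dominant_abundance"],
                           cfg["dominant_min_samples"])
    pct = int(round(100 * cfg["dominant_abundance"]))
    lines.append("")
    if len(props.columns) == 0 or stats["n_strains"] == 0:
        lines.append("No strains identified.")
    else:
        lines.append(f"## Dominant strains (>= {pct}% relative abundance in "
                     f">= {cfg['dominant_min_samples']} samples)")
        if dom:
            for s in dom:
                lines.append(f"- {s}")
        else:
            lines.append("- none (all strains are minor)")

    div = pd.read_csv(out / manifest["artifacts"]["diversity"], index_col=0)
    div.index = div.index.astype(str)
    stage_of = pd.Series([s.split("|")[-1] for s in div.index],
                         index=div.index)
    lines.append("")
    lines.append("## Diversity per fermentation stage (mean over samples)")
    for stage, grp in div.groupby(stage_of):
        lines.append(f"- {stage}: Simpson 1-D = {grp['simpson'].mean():.3f}, "
                     f"Shannon H = {grp['shannon'].mean():.3f}, "
                     f"richness = {grp['richness'].mean():.1f}")

    lines.append("")
    lines.append("## Composition and structure")
    lines.append(f"- PERMANOVA (vineyard): pseudo-F = "
                 f"{stats['permanova_pseudo_F']:.3g}, "
                 f"R2 = {stats['permanova_R2']:.3g}, "
                 f"p = {stats['permanova_p']:.3g}")
    lines.append(f"- fixation indices (isolate level): "
                 f"F_ST = {stats['F_ST']:.3g}, F_IS = {stats['F_IS']:.3g}")
    lines.append(f"- best K by DIC: {stats['best_K_by_DIC']} "
                 f"(alignment H = {stats['alignment_H']:.3g})")
    r2 = stats.get("structure_R2")
    lines.append("- ancestry vs vineyard R2 = "
                 + (f"{r2:.3g}" if r2 is not None else "undefined "
                    "(all strain representatives from one vineyard)"))

    dom_anc = pd.read_csv(out / manifest["artifacts"]["dominant_ancestors"])
    n_dom = dom_anc["dominant_ancestor"].notna().sum()
    lines.append(f"- strains with a dominant (>= "
                 f"{int(100 * cfg['dominant_cutoff'])}%) inferred ancestor: "
                 f"{n_dom} of {len(dom_anc)}")
    return "\n".join(lines) + "\n"
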