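"""End-to-end pipeline: generate (or load) data, run every analysis stage,
and write a structured report bundle.

Stage order: cohort -> indices -> parasitology -> mercury QC -> risk ->
statistics -> histology -> phylogeny. Each stage writes its own tables into
the output directory; stages are individually toggleable and isolated (the
generator substreams mean disabling one never changes another's output).
Reruns with the same config and seed produce identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from . import histology as histo
from . import indices, io, mercury_qc, parasitology, phylo, risk, stats
from .defaults import DEFAULT_CONSUMERS, DEFAULT_RFD
from .errors import FishHealthError
from .model import LESION_CATEGORIES, Season, TreeNode
from .synthetic import (
    GeneratorConfig,
    generate_cohort,
    generate_histology,
    generate_qc_run,
    simulate_alignment,
)

log = logging.getLogger(__name__)

ALL_STAGES = ("cohort", "indices", "parasitology", "qc", "risk", "stats",
              "histology", "phylogeny")

#: Reference topology used when no alignment is supplied: six ingroup
#: isolates plus two outgroups, synthetic stand-ins for short mitochondrial
#: rRNA amplicons.
def default_phylo_tree() -> TreeNode:
    def leaf(name, ln):
        return TreeNode(name=name, length=ln)

    inner1 = TreeNode(length=0.02, children=[leaf("M1", 0.01), leaf("M2", 0.01)])
    inner2 = TreeNode(length=0.02, children=[leaf("M3", 0.01), leaf("M4", 0.01)])
    ingroupA = TreeNode(length=0.03, children=[inner1, inner2])
    ingroupB = TreeNode(length=0.03, children=[leaf("M5", 0.02), leaf("M6", 0.02)])
    return TreeNode(children=[
        TreeNode(length=0.02, children=[ingroupA, ingroupB]),
        leaf("OUT1", 0.12),
        leaf("OUT2", 0.15),
    ])


@dataclass
class RunConfig:
    out_dir: str = "fishhealth_out"
    seed: int = 0
    rfd: float = DEFAULT_RFD
    alpha: float = 0.05
    stages: tuple[str, ...] = ALL_STAGES
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    specimen_table: str | None = None    # read instead of generating
    alignment_fasta: str | None = None   # read instead of simulating
    bootstrap_replicates: int = 200
    alignment_length: int = 485
    histology_per_species: int = 4
    make_figures: bool = True

    def __post_init__(self) -> None:
        if self.rfd <= 0:
            raise FishHealthError("RfD must be positive")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise FishHealthError(f"unknown stage(s) {sorted(unknown)}")


def run_pipeline(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.generator.seed = config.seed
    summary: dict = {"seed": config.seed, "stages": list(config.stages)}

    specimens = None
    if "cohort" in config.stages or any(
        s in config.stages for s in ("indices", "parasitology", "risk", "stats")
    ):
        if config.specimen_table:
            specimens = io.read_specimen_table(config.specimen_table)
        else:
            specimens = generate_cohort(config.generator)
        io.write_specimen_table(specimens, out / "specimens.csv")
        summary["n_specimens"] = len(specimens)

    if "indices" in config.stages:
        idx = indices.summarize_indices(specimens)
        pd.DataFrame([dataclasses.asdict(r) for r in idx]).to_csv(
            out / "indices.csv", index=False, float_format="%.6g")

    if "parasitology" in config.stages:
        summaries = parasitology.summarize_parasitology(specimens)
        rows = []
        for s in summaries:
            rows.append({
                "species": s.species, "season": s.season,
                "n_examined": s.n_examined, "n_infected": s.n_infected,
                "total_parasites": s.total_parasites,
                "prevalence": s.prevalence, "mean_abundance": s.mean_abundance,
                "se_abundance": s.se_abundance,
                "mean_intensity": s.mean_intensity,
            })
        pd.DataFrame(rows).to_csv(out / "parasitology.csv", index=False,
                                  float_format="%.6g")
        by_key = {(s.species, s.season): s for s in summaries}
        tests = []
        for sp in sorted({s.species for s in specimens}):
            a = by_key.get((sp, "rainy"))
            b = by_key.get((sp, "dry"))
            if a and b:
                res = parasitology.compare_prevalence(a, b, config.alpha)
                tests.append({"species": sp, "p_value": res.p_value,
                              "significant": res.significant})
        pd.DataFrame(tests).to_csv(out / "prevalence_tests.csv", index=False,
                                   float_format="%.6g")
        overall = summaries[-1]
        summary["overall_prevalence"] = overall.prevalence
        summary["overall_abundance"] = overall.mean_abundance
        if config.make_figures:
            _parasitology_figure(rows, out / "parasitology.png")

    if "qc" in config.stages:
        qc_table = generate_qc_run(n_blanks=10, n_crm=5, crm_reference=0.382,
                                   noise_sd=0.005, seed=config.seed)
        io.write_qc_table(qc_table, out / "qc_run.csv")
        report = mercury_qc.qc_evaluate(qc_table)
        (out / "qc_report.json").write_text(json.dumps({
            "lod_ugg": report.lod_ugg,
            "rsd_pct": report.rsd_pct,
            "calibration_r2": report.calibration_r2,
            "recovery_pct": report.recovery_pct,
            "below_lod": report.below_lod,
            "flags": [[rule, bool(ok)] for rule, ok in report.flags],
            "passed": report.passed,
        }, indent=2))
        summary["qc_passed"] = report.passed

    if "risk" in config.stages:
        if all(s.thg_ugg is None for s in specimens):
            raise FishHealthError(
                "risk stage requires the thg_ugg column; none present"
            )
        results = risk.assess_cohort(specimens, DEFAULT_CONSUMERS, config.rfd)
        pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
            out / "risk.csv", index=False, float_format="%.6g")
        adult = [r for r in results if r.profile == "adult"]
        summary["max_adult_hq"] = max(r.hq for r in adult)
        summary["min_adult_hq"] = min(r.hq for r in adult)
        if config.make_figures:
            _risk_figure(adult, out / "risk_adult.png")

    if "stats" in config.stages:
        summary["stats"] = _stats_stage(specimens, config, out)

    if "histology" in config.stages:
        species = sorted({s.species for s in specimens}) if specimens else []
        profiles = generate_histology(species, config.histology_per_species,
                                      seed=config.seed)
        io.write_histology_table(profiles, out / "histology.csv")
        occ = histo.occurrence_percentages(profiles)
        order, Z, labels = histo.cluster_profiles(profiles, k=2)
        pd.DataFrame({
            "specimen_id": [p.specimen_id for p in profiles],
            "species": [p.species for p in profiles],
            "mean_score": [float(np.mean(p.vector())) for p in profiles],
            "severity": [histo.bin_severity(float(np.mean(p.vector())))
                         for p in profiles],
            "cluster": labels,
        }).to_csv(out / "histology_clusters.csv", index=False,
                  float_format="%.6g")
        io.write_newick(histo.dendrogram_tree(profiles, Z),
                        out / "histology_dendrogram.nwk")
        (out / "histology_occurrence.json").write_text(json.dumps(occ, indent=2))
        summary["histology_clusters"] = int(labels.max())
        if config.make_figures:
            _histology_heatmap(profiles, order, out / "histology_heatmap.png")

    if "phylogeny" in config.stages:
        if config.alignment_fasta:
            seqs = io.read_fasta(config.alignment_fasta)
        else:
            seqs = simulate_alignment(default_phylo_tree(),
                                      config.alignment_length, config.seed)
            io.write_fasta(seqs, out / "alignment.fasta")
        tree = phylo.bootstrap_support(seqs, config.bootstrap_replicates,
                                       seed=config.seed)
        io.write_newick(tree, out / "nj_tree.nwk")
        supports = [n.support for n in _internal_nodes(tree)
                    if n.support is not None]
        summary["nj_supports"] = supports
        if config.make_figures:
            _tree_figure(tree, out / "nj_tree.png")

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    log.info("pipeline complete; bundle at %s", out)
    return summary


def _internal_nodes(tree: TreeNode):
    if not tree.is_leaf:
        yield tree
        for c in tree.children:
            yield from _internal_nodes(c)


def _stats_stage(specimens, config: RunConfig, out: Path) -> dict:
    frame = pd.DataFrame({
        "A": [s.parasite_count for s in specimens],
        "Hg": [s.thg_ugg for s in specimens],
        "CF": [indices.condition_factor(s.length_cm, s.weight_g)
               for s in specimens],
        "TL": [s.trophic_level for s in specimens],
        "L": [s.length_cm for s in specimens],
        "W": [s.weight_g for s in specimens],
        "HSI": [indices.hepatosomatic_index(s.liver_weight_g, s.weight_g)
                for s in specimens],
        "season": [s.season.value for s in specimens],
    })
    result: dict = {}
    for season in ("rainy", "dry"):
        sub = frame[frame["season"] == season].drop(columns="season")
        rho, pv = stats.spearman_matrix(sub)
        rho.to_csv(out / f"spearman_rho_{season}.csv", float_format="%.4f")
        pv.to_csv(out / f"spearman_p_{season}.csv", float_format="%.4g")

    hg_rainy = frame.loc[frame["season"] == "rainy", "Hg"].dropna().tolist()
    hg_dry = frame.loc[frame["season"] == "dry", "Hg"].dropna().tolist()
    seasonal = stats.compare_two_groups(hg_rainy, hg_dry, config.alpha)
    result["thg_seasonal"] = {
        "test": seasonal.test_name, "statistic": seasonal.statistic,
        "p_value": seasonal.p_value, "path": seasonal.decision_path,
    }

    rho_p, p_p = stats.partial_spearman(frame["A"], frame["Hg"], frame["TL"])
    result["partial_spearman_A_Hg_given_TL"] = {"rho": rho_p, "p": p_p}

    pca_res = stats.pca(frame.drop(columns="season"))
    pca_res.loadings.to_csv(out / "pca_loadings.csv", float_format="%.4f")
    result["pca_explained_pct"] = [
        round(100 * f, 1) for f in pca_res.explained_fraction
    ]
    if config.make_figures:
        _pca_biplot(pca_res, out / "pca_biplot.png")

    path, best = stats.mlr_backward_aic(frame, "A", ["Hg", "CF", "TL"])
    result["mlr"] = {
        "path": [{"terms": list(f.terms), "aic": f.aic} for f in path],
        "best_terms": list(best.terms),
        "coefficients": best.coefficients,
        "adjusted_r2": best.adjusted_r2,
    }
    (out / "stats.json").write_text(json.dumps(result, indent=2, default=float))
    return result


def _parasitology_figure(rows, path):
    strata = [r for r in rows if r["species"] != "overall"]
    labels = [f"{r['species'].split()[0][0]}. {r['species'].split()[1]}"
              f" ({r['season'][0]})" for r in strata]
    fig, axes = plt.subplots(3, 1, figsize=(10, 9), sharex=True)
    for ax, key, title in zip(
        axes, ("prevalence", "mean_abundance", "mean_intensity"),
        ("Prevalence", "Mean abundance", "Mean intensity"),
    ):
        vals = [r[key] if r[key] is not None else 0.0 for r in strata]
        ax.bar(range(len(strata)), vals, color="steelblue")
        ax.set_ylabel(title)
    axes[-1].set_xticks(range(len(strata)))
    axes[-1].set_xticklabels(labels, rotation=90, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _risk_figure(adult_results, path):
    labels = [f"{r.species.split()[-1]} ({r.season[0]})" for r in adult_results]
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(12, 4))
    ax1.bar(labels, [r.hq for r in adult_results], color="firebrick")
    ax1.axhline(1.0, color="k", ls="--")
    ax1.set_ylabel("Hazard quotient (adult)")
    ax1.tick_params(axis="x", rotation=90, labelsize=7)
    ax2.bar(labels, [r.crmw_raw for r in adult_results], color="seagreen")
    ax2.set_ylabel("CRmw (meals/week, adult)")
    ax2.tick_params(axis="x", rotation=90, labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _histology_heatmap(profiles, order, path):
    X = np.vstack([profiles[i].vector() for i in order])
    fig, ax = plt.subplots(figsize=(6, 8))
    im = ax.imshow(X, aspect="auto", cmap="YlOrRd", vmin=0, vmax=3)
    ax.set_xticks(range(len(LESION_CATEGORIES)))
    ax.set_xticklabels(LESION_CATEGORIES, fontsize=7)
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels([profiles[i].specimen_id for i in order], fontsize=5)
    fig.colorbar(im, label="severity score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _pca_biplot(pca_res, path):
    fig, ax = plt.subplots(figsize=(6, 6))
    sc = pca_res.scores
    ax.scatter(sc["PC1"], sc["PC2"], s=6, alpha=0.4, color="gray")
    scale = float(np.abs(sc[["PC1", "PC2"]].to_numpy()).max())
    for var in pca_res.loadings.index:
        x, y = pca_res.loadings.loc[var, ["PC1", "PC2"]] * scale
        ax.annotate(var, (x, y), color="firebrick", fontsize=9)
        ax.arrow(0, 0, x * 0.9, y * 0.9, color="firebrick",
                 head_width=0.02 * scale)
    ev = pca_res.explained_fraction
    ax.set_xlabel(f"PC1 ({100 * ev[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * ev[1]:.1f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _tree_figure(tree: TreeNode, path):
    from io import StringIO

    from Bio import Phylo

    handle = StringIO(tree.newick())
    btree = Phylo.read(handle, "newick")
    fig, ax = plt.subplots(figsize=(6, 5))
    Phylo.draw(btree, axes=ax, do_show=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
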