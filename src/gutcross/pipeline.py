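"""End-to-end orchestration with reproducible configuration and reports.

``run_full_analysis`` drives one cohort through depth filtering, alpha/beta
diversity, compositional differential abundance and nested-CV machine
learning; ``run_cross_study`` runs the paired-cohort transfer experiment.
Every random draw traces to the config seeds and identical configs produce
byte-identical ``summary.json`` files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import __version__
from .diffabund import aldex_clr, ancom_w
from .diversity import (
    alpha_diversity,
    bray_curtis,
    correlation_ellipse,
    kruskal_wallis,
    pcoa,
    permanova,
)
from .ml import LearnerSpec, FAMILIES, aggregate_ranks, nested_cv_multi
from .simulate import (
    SimulationConfig,
    derive_pathway_table,
    random_genome_content,
    simulate_cohort,
    simulate_paired_cohorts,
)
from .tables import (
    min_depth_filter,
    prevalence_filter,
    rarefy,
    to_relative,
    write_metadata,
    write_table,
)
from .transfer import (
    align_features,
    permutation_importance,
    pooled_stratified_auc,
    transfer_predict,
)

log = logging.getLogger("gutcross")

__all__ = ["RunConfig", "run_full_analysis", "run_cross_study"]


@dataclass(frozen=True)
class RunConfig:
    """Flat configuration of one cohort analysis.

    Thresholds default to the pipeline's study-style values: depth filter
    1000 reads, 10% prevalence before differential abundance, ANCOM W >= 0.7,
    ALDEx q < 0.05, rarefaction to 1000 (taxa) and 10000 (pathways) reads.
    """

    # simulation (used when no input paths are given)
    n_exposed: int = 23
    n_control: int = 60
    n_taxa: int = 20
    n_pathways: int = 60
    concentration: float = 100.0
    focal_effect: float = SimulationConfig.focal_effect
    covariate_rate: float | None = None
    seed: int = 0
    # filtering / diversity
    min_depth: int = 1000
    prevalence: float = 0.10
    rarefy_depth_taxa: int = 1000
    rarefy_depth_pathways: int = 10000
    beta_on_rarefied: bool = True
    n_perm: int = 999
    # differential abundance
    ancom_threshold: float = 0.7
    ancom_alpha: float = 0.05
    aldex_q: float = 0.05
    aldex_n_mc: int = 128
    # machine learning
    outer_k: int = 5
    inner_k: int = 3
    n_repeats: int = 40
    grid_scale: str = "default"  # "default" or "small"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a flat ``key = value`` config file."""
        kwargs: dict = {}
        hints = cls.__dataclass_fields__
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, raw = (s.strip() for s in line.split("=", 1))
            if key not in hints:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            kwargs[key] = _coerce(raw)
        return cls(**kwargs)

    def learner_specs(self) -> dict[str, LearnerSpec]:
        if self.grid_scale == "small":
            grids = {
                "random_forest": {"n_estimators": [100], "max_depth": [None]},
                "extra_trees": {"n_estimators": [100], "max_depth": [None]},
                "adaboost": {"n_estimators": [50], "learning_rate": [1.0]},
            }
            return {f: LearnerSpec(f, grids[f], seed=self.seed) for f in FAMILIES}
        return {f: LearnerSpec(f, seed=self.seed) for f in FAMILIES}

    def simulation_config(self, prefix: str = "S") -> SimulationConfig:
        return SimulationConfig(
            n_exposed=self.n_exposed, n_control=self.n_control,
            n_taxa=self.n_taxa, n_pathways=self.n_pathways,
            concentration=self.concentration, focal_effect=self.focal_effect,
            covariate_rate=self.covariate_rate, seed=self.seed,
            sample_prefix=prefix,
        )


def _coerce(raw: str):
    low = raw.lower()
    if low in ("true", "false"):
        return low == "true"
    if low in ("none", ""):
        return None
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            pass
    return raw


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 10)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _write_summary(summary: dict, path: Path) -> None:
    path.write_text(json.dumps(_jsonify(summary), sort_keys=True, indent=1) + "\n")


def _analyze_representation(name: str, table, meta, config: RunConfig,
                            outdir: Path, rarefy_depth: int,
                            seed_offset: int) -> dict:
    """Diversity, differential abundance and ML for one feature table."""
    stages: dict = {}
    base_seed = config.seed + seed_offset

    # alpha diversity on the rarefied table
    rare = rarefy(table, rarefy_depth, seed=base_seed + 11)
    rare_meta = meta.subset(rare.sample_ids)
    alpha = alpha_diversity(rare)
    y_alpha = rare_meta.exposure_for(rare.sample_ids)
    h, p = kruskal_wallis(alpha.to_numpy(), y_alpha)
    alpha.to_csv(outdir / f"alpha_shannon_{name}.tsv", sep="\t", header=True)
    stages["alpha"] = {
        "rarefy_depth": rarefy_depth,
        "n_samples": len(alpha), "kruskal_h": h, "kruskal_p": p,
        "mean_shannon_exposed": float(alpha.to_numpy()[y_alpha == 1].mean()),
        "mean_shannon_control": float(alpha.to_numpy()[y_alpha == 0].mean()),
    }

    # beta diversity: Bray-Curtis, PERMANOVA, PCoA with ellipses
    beta_table = rare if config.beta_on_rarefied else table
    beta_meta = meta.subset(beta_table.sample_ids)
    dm = bray_curtis(beta_table)
    design = {"exposure": beta_meta.exposure_for(beta_table.sample_ids)}
    cov = beta_meta.covariate_for(beta_table.sample_ids)
    if cov is not None:
        design["covariate"] = cov
    perm = permanova(dm, design, n_perm=config.n_perm, seed=base_seed + 13)
    ord_res = pcoa(dm)
    ellipses = correlation_ellipse(
        ord_res.coordinates.iloc[:, :2],
        beta_meta.exposure_for(beta_table.sample_ids),
    )
    ord_res.coordinates.to_csv(outdir / f"pcoa_{name}.tsv", sep="\t")
    stages["beta"] = {
        "permanova": perm.to_dict(),
        "proportion_explained_pc1": float(ord_res.proportion_explained[0]),
        "proportion_explained_pc2": float(ord_res.proportion_explained[1]),
        "ellipses": {
            str(g): {"center": list(e.center), "semi_major": e.semi_major,
                     "semi_minor": e.semi_minor, "angle_deg": e.angle_deg,
                     "pearson_r": e.pearson_r, "degenerate": e.degenerate}
            for g, e in ellipses.items()
        },
    }

    # differential abundance on the prevalence-filtered count table
    filt = prevalence_filter(table, config.prevalence)
    stages["prevalence_filter"] = {
        "threshold": config.prevalence,
        "features_in": len(table.feature_ids),
        "features_out": len(filt.feature_ids),
    }
    log.info("%s prevalence filter: %d -> %d features",
             name, len(table.feature_ids), len(filt.feature_ids))
    adjust = meta.covariate_for(filt.sample_ids) is not None
    ancom = ancom_w(filt, meta, covariate_adjust=adjust,
                    alpha=config.ancom_alpha, threshold=config.ancom_threshold)
    aldex = aldex_clr(filt, meta, n_mc=config.aldex_n_mc,
                      seed=base_seed + 17, q_threshold=config.aldex_q)
    ancom.frame.to_csv(outdir / f"ancom_w_{name}.tsv", sep="\t")
    aldex.frame.to_csv(outdir / f"aldex_{name}.tsv", sep="\t")
    stages["diffabund"] = {
        "covariate_adjusted": adjust,
        "ancom_significant": ancom.significant_features(),
        "ancom_w": {f: float(w) for f, w in ancom.frame["w_proportion"].items()},
        "aldex_significant": aldex.significant_features(),
        "aldex_effect": {f: float(e) for f, e in aldex.frame["effect"].items()},
    }

    # nested-CV machine learning on relative abundances
    rel = to_relative(filt)
    cv = nested_cv_multi(rel, meta, config.learner_specs(),
                         outer_k=config.outer_k, inner_k=config.inner_k,
                         n_repeats=config.n_repeats, seed=base_seed + 19)
    agg = aggregate_ranks(cv.importance_vectors(), rel.feature_ids)
    agg.median_rank.rename("median_rank").to_csv(
        outdir / f"feature_ranks_{name}.tsv", sep="\t")
    stages["ml"] = {
        "n_repeats": config.n_repeats,
        "auc": {f: {"mean": cv.mean_auc(f), "sd": cv.sd_auc(f)}
                for f in cv.families},
        "n_ranks_per_feature": agg.n_fits,
        "top_features": list(agg.median_rank.index[:10]),
        "median_rank": {f: float(r) for f, r in agg.median_rank.items()},
    }
    return stages


def run_full_analysis(config: RunConfig, outdir,
                      taxa=None, pathways=None, meta=None) -> dict:
    """Run the single-cohort analysis and write its report bundle.

    When ``taxa``/``meta`` are not given, a synthetic cohort is generated
    from the config's simulation parameters and the pathway table is derived
    through a seeded random genome-content matrix. Every stage runs for both
    the taxon and the predicted-pathway representation.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": asdict(config), "version": __version__, "stages": {}}

    if taxa is None:
        sim = config.simulation_config()
        taxa, meta = simulate_cohort(sim)
        gcm = random_genome_content(
            config.n_taxa, config.n_pathways,
            focal_taxon_index=sim.focal_taxon_index,
            block=range(min(10, config.n_pathways)),
            seed=config.seed + 1,
        )
        pathways, strat = derive_pathway_table(taxa, gcm)
        write_table(taxa, outdir / "taxa.tsv")
        write_table(pathways, outdir / "pathways.tsv")
        write_metadata(meta, outdir / "metadata.tsv")
    elif meta is None:
        raise ValueError("metadata required with explicit tables")

    # depth filter on the taxon table; pathway columns follow the kept samples
    kept = min_depth_filter(taxa, config.min_depth)
    summary["stages"]["min_depth_filter"] = {
        "min_depth": config.min_depth,
        "samples_in": len(taxa.sample_ids),
        "samples_out": len(kept.sample_ids),
    }
    log.info("depth filter: %d -> %d samples",
             len(taxa.sample_ids), len(kept.sample_ids))
    taxa = kept
    meta = meta.subset(taxa.sample_ids)
    if pathways is not None:
        pathways = type(pathways)(pathways.data.loc[:, taxa.sample_ids])

    summary["stages"]["taxa"] = _analyze_representation(
        "taxa", taxa, meta, config, outdir, config.rarefy_depth_taxa, 0)
    if pathways is not None:
        summary["stages"]["pathways"] = _analyze_representation(
            "pathways", pathways, meta, config, outdir,
            config.rarefy_depth_pathways, 1000)

    _write_summary(summary, outdir / "summary.json")
    return summary


def run_cross_study(config_a: RunConfig, config_b: RunConfig, outdir,
                    threshold_taxa: float = 0.30,
                    threshold_pathways: float = 0.50,
                    shared_block_size: int = 10,
                    subsample_frac: float = 0.8,
                    n_shuffles: int = 10,
                    n_importance_ensembles: int = 3,
                    focal_b_index: int = 1) -> dict:
    """Paired-cohort transfer experiment, both directions, taxa and pathways.

    Cohort A depletes focal taxon 0, cohort B focal taxon ``focal_b_index``;
    both focal taxa load on a shared block of pathways, so the pathway
    representation carries a transferable signal while the taxon
    representation does not.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_a = replace(config_a.simulation_config(prefix="A"),
                    replacement_taxon_index=2)
    sim_b = replace(config_b.simulation_config(prefix="B"),
                    focal_taxon_index=focal_b_index,
                    replacement_taxon_index=3)
    block = range(shared_block_size)
    gcm_a = random_genome_content(sim_a.n_taxa, sim_a.n_pathways,
                                  focal_taxon_index=sim_a.focal_taxon_index,
                                  block=block, seed=config_a.seed + 1)
    gcm_b = random_genome_content(sim_b.n_taxa, sim_b.n_pathways,
                                  focal_taxon_index=sim_b.focal_taxon_index,
                                  block=block, seed=config_b.seed + 2)
    bundle_a, bundle_b = simulate_paired_cohorts(sim_a, sim_b, gcm_a, gcm_b,
                                                 shared_pathway_block=block)

    summary: dict = {
        "config_a": asdict(config_a), "config_b": asdict(config_b),
        "version": __version__, "directions": {},
    }
    reps = {
        "taxa": (bundle_a.taxa, bundle_b.taxa, threshold_taxa),
        "pathways": (bundle_a.pathways, bundle_b.pathways, threshold_pathways),
    }
    for rep_name, (ta, tb, thr) in reps.items():
        fa, fb = align_features(ta, tb, thr)
        ra, rb = to_relative(fa), to_relative(fb)
        for direction, (tr_x, tr_m, te_x, te_m) in {
            "A->B": (ra, bundle_a.metadata, rb, bundle_b.metadata),
            "B->A": (rb, bundle_b.metadata, ra, bundle_a.metadata),
        }.items():
            report = transfer_predict(
                tr_x, tr_m, te_x, te_m,
                specs=config_a.learner_specs(),
                outer_k=config_a.outer_k, inner_k=config_a.inner_k,
                n_repeats=config_a.n_repeats,
                subsample_frac=subsample_frac,
                seed=config_a.seed + 23, direction=direction,
            )
            imp = permutation_importance(report.ensembles[:n_importance_ensembles],
                                         te_x, te_m,
                                         n_shuffles=n_shuffles,
                                         seed=config_a.seed + 29)
            imp.to_csv(outdir / f"importance_{rep_name}_"
                                f"{direction.replace('->', 'to')}.tsv", sep="\t")
            entry = report.to_dict()
            entry["n_features"] = len(tr_x.feature_ids)
            entry["top_feature"] = imp.index[0]
            entry["importance_top5"] = {
                f: {"mean_drop": float(r["mean_drop"]), "sd": float(r["sd"])}
                for f, r in imp.head(5).iterrows()
            }
            cov = te_m.covariate_for(report.pooled_sample_ids)
            if cov is not None:
                labels = te_m.exposure_for(report.pooled_sample_ids)
                entry["pooled_stratified_auc"] = pooled_stratified_auc(
                    report.pooled_scores, labels, cov)
            summary["directions"].setdefault(rep_name, {})[direction] = entry

    _write_summary(summary, outdir / "cross_study_summary.json")
    return summary
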