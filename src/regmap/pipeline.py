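"""End-to-end orchestration on a synthetic dataset.

``run_pipeline`` simulates a genome, elements and signal from the config
seed, then runs peak calling, transcription evidence, classification,
dynamics and enrichment, writing four schema-stable TSV tables.  Identical
config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from regmap import classify as cl
from regmap import dynamics as dyn
from regmap import enrichment as en
from regmap import peaks as pk
from regmap import transcription as tr
from regmap.config import PipelineConfig
from regmap.io import write_table
from regmap.stages import AGEING_STAGES, DEV_STAGES, STAGES
from regmap.synthetic import (
    plant_elements,
    simulate_genome,
    simulate_signal,
    simulate_tf_and_expression,
)

log = logging.getLogger("regmap")

ATAC_READ_LENGTH = 150  # coverage-to-count conversion for the NB tests


@dataclass
class PipelineResult:
    genome: object
    elements: list
    bundle: object
    sites: pd.DataFrame
    annot: pd.DataFrame
    dynamics: pd.DataFrame
    enrichment: pd.DataFrame
    dev_clusters: pd.DataFrame
    age_clusters: pd.DataFrame


def call_sites_from_bundle(bundle, config: PipelineConfig) -> pd.DataFrame:
    """Concavity candidates + per-stage consistency filtering for one bundle."""
    frames = []
    for chrom, length in bundle.chromosomes:
        tracks = {
            stage: [
                bundle.atac[(stage, rep)][chrom] for rep in range(bundle.n_reps)
            ]
            for stage in STAGES
        }
        mean_cov = np.mean(
            [t for reps in tracks.values() for t in reps], axis=0
        )
        d2 = pk.smoothed_second_derivative(mean_cov, config.bandwidth)
        candidates = pk.find_concave_regions(
            d2,
            mean_cov,
            chrom=chrom,
            min_size=config.min_region,
            edge_exclusion=int(4 * config.bandwidth),
        )
        log.info("%s: %d candidate concave regions", chrom, len(candidates))
        stage_scores = {
            stage: (
                pk.score_candidates(candidates, reps[0], config.bandwidth),
                pk.score_candidates(candidates, reps[1], config.bandwidth),
            )
            for stage, reps in tracks.items()
        }
        sites, _ = pk.call_peaks(
            candidates,
            stage_scores,
            tracks,
            idr_cutoff=config.idr_cutoff,
            flank=config.boundary_flank,
            source="atac_wt_pe",
            chrom_length=length,
        )
        frames.append(sites)
    return pd.concat(frames, ignore_index=True)


def site_counts(sites: pd.DataFrame, bundle) -> pd.DataFrame:
    """ATAC read-count equivalents per site x (stage, replicate)."""
    cols = {}
    for stage in STAGES:
        for rep in range(bundle.n_reps):
            vals = []
            for _, s in sites.iterrows():
                track = bundle.atac[(stage, rep)][s["chrom"]]
                vals.append(track[int(s["start"]): int(s["end"])].sum())
            cols[f"{stage}|rep{rep}"] = np.round(
                np.array(vals) / ATAC_READ_LENGTH
            ).astype(int)
    return pd.DataFrame(cols, index=sites.index)


def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineResult:
    """Run everything on a freshly simulated dataset (single chromosome)."""
    config.validate()
    genome = simulate_genome(config.n_genes, config.chrom_length, config.seed)
    elements = plant_elements(genome, config.class_counts, config.seed + 1)
    bundle = simulate_signal(
        genome,
        elements,
        depth=config.depth,
        dispersion=config.dispersion,
        seed=config.seed + 2,
    )
    if len(bundle.chromosomes) != 1:
        raise NotImplementedError("run_pipeline drives one chromosome at a time")
    chrom = bundle.chromosomes[0][0]

    # --- peaks -------------------------------------------------------------
    sites = call_sites_from_bundle(bundle, config)
    log.info("called %d accessible sites", len(sites))

    # --- transcription evidence -------------------------------------------
    scap_tracks = {
        strand: [
            bundle.shortcap_5p[(rep, strand)][chrom]
            for rep in range(bundle.scap_reps)
        ]
        for strand in ("+", "-")
    }
    lcap_tracks = {
        (stage, strand): [
            bundle.longcap_5p[(stage, rep, strand)][chrom]
            for rep in range(bundle.n_reps)
        ]
        for stage in STAGES
        for strand in ("+", "-")
    }
    evidence = tr.evidence_table(sites, list(STAGES), scap_tracks, lcap_tracks)

    # --- classification ----------------------------------------------------
    lcap_cov = {
        (stage, strand): np.maximum.reduce(
            [
                bundle.longcap_cov[(stage, rep, strand)][chrom]
                for rep in range(bundle.n_reps)
            ]
        )
        for stage in STAGES
        for strand in ("+", "-")
    }
    ccfg = cl.ClassifyConfig(
        exon_distance=config.exon_distance, rescue_min_lfc=config.rescue_lfc
    )
    annot = cl.classify_sites(sites, evidence, genome, lcap_cov, ccfg)

    # --- dynamics ----------------------------------------------------------
    counts = site_counts(sites, bundle)
    dev = dyn.differential_accessibility(
        counts, "development", config.regulated_fold, config.regulated_padj
    )
    age = dyn.differential_accessibility(
        counts, "ageing", config.regulated_fold, config.regulated_padj
    )
    is_promoter = annot["annot"].isin(["coding_promoter", "pseudogene_promoter"])
    dyn_table = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "start": sites["start"],
            "end": sites["end"],
            "devel_is_dynamic": dev["regulated"],
            "ageing_is_dynamic": age["regulated"],
        }
    )
    dev_members = sites.index[is_promoter & dev["regulated"]]
    age_members = sites.index[is_promoter & age["regulated"]]
    dev_clusters = dyn.cluster_course(
        dyn.normalized_stage_coverage(counts.loc[dev_members], "development"),
        "development",
        k=min(config.synthetic_k, max(1, len(dev_members))),
        merge_map=config.merge_map_dev or None,
    )
    age_clusters = dyn.cluster_course(
        dyn.normalized_stage_coverage(counts.loc[age_members], "ageing"),
        "ageing",
        k=min(config.synthetic_k, max(1, len(age_members))),
        merge_map=config.merge_map_age or None,
    )
    dyn_table["devel_prom_cluster_label"] = ""
    dyn_table["ageing_prom_cluster_label"] = ""
    if not dev_clusters.empty:
        dyn_table.loc[dev_clusters.index, "devel_prom_cluster_label"] = [
            f"dev_{c}" for c in dev_clusters["cluster"]
        ]
    if not age_clusters.empty:
        dyn_table.loc[age_clusters.index, "ageing_prom_cluster_label"] = [
            f"age_{c}" for c in age_clusters["cluster"]
        ]

    # --- enrichment --------------------------------------------------------
    tf_peaks, expr = simulate_tf_and_expression(
        elements,
        None,
        config.n_tfs,
        config.n_tissues,
        config.seed + 3,
        genome=genome,
        hot_tf_count=config.hot_threshold,
    )
    binding = en.assign_tf_peaks(
        sites, tf_peaks, window=config.tf_window, hot_threshold=config.hot_threshold
    )
    dyn_table["factor_count"] = binding.factor_count
    dyn_table["hotness"] = binding.hotness
    dyn_table["factor_names"] = binding.factor_names()
    if not dev_clusters.empty:
        clusters = pd.Series(
            [f"dev_{c}" for c in dev_clusters["cluster"]], index=dev_clusters.index
        )
        enr = en.tf_enrichment(
            clusters,
            binding,
            min_peaks=config.synthetic_tf_min_peaks,
            p_cutoff=config.tf_p,
            min_or=config.tf_min_or,
        )
        enrich_table = enr.odds_ratio.reset_index(names="factor").melt(
            id_vars="factor", var_name="cluster", value_name="odds_ratio"
        )
        pvals = enr.p.reset_index(names="factor").melt(
            id_vars="factor", var_name="cluster", value_name="p"
        )
        enrich_table["p"] = pvals["p"]
        enrich_table["kept"] = enrich_table["factor"].map(enr.kept)
    else:
        enrich_table = pd.DataFrame(
            columns=["factor", "cluster", "odds_ratio", "p", "kept"]
        )

    # --- write -------------------------------------------------------------
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        h = config.hash()
        write_table(sites, out / "sites.tsv", h)
        write_table(annot, out / "annot.tsv", h)
        write_table(dyn_table, out / "dynamics.tsv", h)
        write_table(enrich_table, out / "enrichment.tsv", h)
        config.to_yaml(out / "config.yaml")

    return PipelineResult(
        genome=genome,
        elements=elements,
        bundle=bundle,
        sites=sites,
        annot=annot,
        dynamics=dyn_table,
        enrichment=enrich_table,
        dev_clusters=dev_clusters,
        age_clusters=age_clusters,
    )
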