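"""Simulate TF peak sets and a gene x tissue expression table.

Enriched TFs bind elements of one target cluster at elevated odds; a
designated HOT subset of elements is bound by >= ``hot_tf_count`` factors;
each planted cluster's target genes get one dominant tissue with a fold
>= 3 over the runner-up.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from regmap.genome import GenomeModel
from regmap.synthetic.elements import PlantedElement


def simulate_tf_and_expression(
    elements: list[PlantedElement],
    clusters: dict[str, int] | None,
    n_tfs: int,
    n_tissues: int,
    seed: int,
    *,
    genome: GenomeModel | None = None,
    n_enriched: int = 3,
    odds_ratio: float = 4.0,
    background_bound_p: float = 0.2,
    hot_fraction: float = 0.05,
    hot_tf_count: int = 19,
    n_random_peaks: int = 50,
    n_expr_reps: int = 2,
    dominant_tpm: float = 30.0,
    other_tpm: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (TF peak table, replicate-level gene x tissue TPM table).

    ``clusters`` maps element_id -> cluster label; defaults to the planted
    ``true_cluster``.  The peak table has BED6-style columns plus ``summit``;
    the expression table is indexed by gene (planted target genes plus one
    pseudo-gene per TF) with one column per (tissue, replicate).
    """
    if n_tfs < n_enriched:
        raise ValueError("n_tfs smaller than the number of enriched TFs")
    if n_tissues < 2:
        raise ValueError("need >= 2 tissues")
    rng = np.random.default_rng(seed)
    if clusters is None:
        clusters = {
            e.element_id: e.true_cluster
            for e in elements
            if e.true_cluster is not None
        }
    cluster_labels = sorted({c for c in clusters.values()})
    factors = [f"tf_{i:03d}" for i in range(n_tfs)]
    enriched = {
        factors[i]: cluster_labels[i % len(cluster_labels)] if cluster_labels else None
        for i in range(n_enriched)
    }

    p0 = background_bound_p
    odds1 = odds_ratio * p0 / (1.0 - p0)
    p1 = odds1 / (1.0 + odds1)

    chrom = elements[0].chrom if elements else "chrI"
    if genome is not None:
        chrom_len = genome.chromosomes[0][1]
    else:
        chrom_len = max((e.center for e in elements), default=10_000) + 10_000

    hot_ids: set[str] = set()
    if n_tfs >= hot_tf_count and elements:
        n_hot = int(round(hot_fraction * len(elements)))
        idx = rng.choice(len(elements), size=n_hot, replace=False) if n_hot else []
        hot_ids = {elements[int(i)].element_id for i in idx}

    rows = []
    for factor in factors:
        target = enriched.get(factor)
        for el in elements:
            if el.element_id in hot_ids:
                continue
            p = p1 if (target is not None and clusters.get(el.element_id) == target) else p0
            if rng.random() < p:
                summit = int(el.center + rng.integers(-150, 151))
                rows.append((chrom, summit - 100, summit + 100, factor, summit))
        # off-element background peaks
        for pos in rng.integers(0, chrom_len, size=n_random_peaks):
            summit = int(pos)
            rows.append((chrom, max(0, summit - 100), summit + 100, factor, summit))
    # HOT elements: bound by the first `hot_tf_count` factors
    for el in elements:
        if el.element_id in hot_ids:
            for factor in factors[:hot_tf_count]:
                rows.append((chrom, el.center - 100, el.center + 100, factor, el.center))

    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "factor", "summit"])
    peaks["score"] = 0
    peaks["strand"] = "."
    peaks = peaks.sort_values(["chrom", "start", "end", "factor"], kind="stable")
    peaks = peaks.reset_index(drop=True)

    # ------------------- expression table ----------------------------------
    tissues = [f"tissue_{t}" for t in range(n_tissues)]
    gene_rows = {}

    def expr_row(dominant_tissue: int | None) -> np.ndarray:
        vals = np.empty((n_tissues, n_expr_reps))
        for t in range(n_tissues):
            base = other_tpm
            if dominant_tissue is not None and t == dominant_tissue:
                base = dominant_tpm
            vals[t] = base * rng.uniform(0.85, 1.15, size=n_expr_reps)
        return vals

    for el in elements:
        if el.target_gene_id is None:
            continue
        c = clusters.get(el.element_id)
        dom = (c % n_tissues) if c is not None else None
        gene_rows[el.target_gene_id] = expr_row(dom)
    if genome is not None:
        for g in genome.genes:
            if g.gene_id not in gene_rows:
                gene_rows[g.gene_id] = expr_row(None)
    for factor, target in ((f, enriched.get(f)) for f in factors):
        dom = (target % n_tissues) if target is not None else None
        gene_rows[factor] = expr_row(dom)

    cols = [f"{t}|rep{r}" for t in tissues for r in range(n_expr_reps)]
    expr = pd.DataFrame(
        {g: v.reshape(-1) for g, v in gene_rows.items()}, index=cols
    ).T
    expr.columns = cols
    expr.index.name = "gene_id"
    return peaks, expr


def tpm_from_replicates(expr: pd.DataFrame) -> pd.DataFrame:
    """Average ``tissue|repN`` columns into one TPM column per tissue."""
    tissues = sorted({c.split("|")[0] for c in expr.columns})
    out = pd.DataFrame(index=expr.index)
    for t in tissues:
        cols = [c for c in expr.columns if c.split("|")[0] == t]
        out[t] = expr[cols].mean(axis=1)
    return out
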