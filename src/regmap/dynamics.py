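"""Temporal accessibility analysis: regulated sites, profiles, clustering.

Relative accessibility at time point t is ``log2(c_t + 1) - log2(mean(c) +
1)`` with the mean taken within the course.  Clustering uses partitioning
around medoids (PAM: greedy BUILD seeding plus steepest-descent SWAP),
deterministic with lowest-index tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from regmap.nbstats import bh_adjust, nb_two_group_test
from regmap.stages import course_stages

REGULATED_FOLD = 2.0
REGULATED_PADJ = 0.01
K_DEFAULTS = {"development": 16, "ageing": 10}


def differential_accessibility(
    counts: pd.DataFrame,
    course: str,
    fold: float = REGULATED_FOLD,
    padj_cutoff: float = REGULATED_PADJ,
) -> pd.DataFrame:
    """Test every time-point pair within a course for a change in counts.

    ``counts`` columns are named ``{stage}|rep{r}``; rows are sites.  BH
    correction is applied across sites within each pair.  A site is
    ``regulated`` when some pair shows |fold change| >= ``fold`` with
    adjusted p < ``padj_cutoff``.
    """
    stages = [s for s in course_stages(course)]
    rep_cols = {
        s: [c for c in counts.columns if c.split("|")[0] == s] for s in stages
    }
    min_lfc = np.log2(fold)
    regulated = np.zeros(len(counts), dtype=bool)
    records = {}
    for sa, sb in combinations(stages, 2):
        a = counts[rep_cols[sa]].to_numpy(dtype=float)
        b = counts[rep_cols[sb]].to_numpy(dtype=float)
        res = nb_two_group_test(a, b)
        padj = bh_adjust(res.p_twosided)
        hit = (np.abs(res.lfc) >= min_lfc) & (padj < padj_cutoff)
        regulated |= hit
        records[f"lfc_{sa}_vs_{sb}"] = res.lfc
        records[f"padj_{sa}_vs_{sb}"] = padj
    out = pd.DataFrame(records, index=counts.index)
    out.insert(0, "regulated", regulated)
    out.insert(0, "course", course)
    return out


def relative_accessibility(coverage: np.ndarray) -> np.ndarray:
    """log2(c + 1) - log2(mean(c) + 1), rowwise for a 2-D input."""
    c = np.asarray(coverage, dtype=float)
    if c.ndim == 1:
        return np.log2(c + 1.0) - np.log2(c.mean() + 1.0)
    return np.log2(c + 1.0) - np.log2(c.mean(axis=1, keepdims=True) + 1.0)


def _pam_build(d: np.ndarray, k: int) -> list[int]:
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        nearest = d[:, medoids].min(axis=1)
        gains = np.maximum(nearest[:, None] - d, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    return medoids


def _swap_descent(d: np.ndarray, medoids: list[int]) -> tuple[list[int], float]:
    """Steepest-descent SWAP: repeatedly apply the single best strictly
    improving medoid/non-medoid exchange (ties: lowest medoid index, then
    lowest candidate index) until a local optimum."""
    n = d.shape[0]
    medoids = list(medoids)
    cost = d[:, medoids].min(axis=1).sum()
    while True:
        best = None
        for mi, _ in enumerate(medoids):
            others = [x for j, x in enumerate(medoids) if j != mi]
            dmin_rest = (
                d[:, others].min(axis=1) if others else np.full(n, np.inf)
            )
            cand = np.array(
                [h for h in range(n) if h not in medoids], dtype=int
            )
            if cand.size == 0:
                continue
            new_costs = np.minimum(dmin_rest[:, None], d[:, cand]).sum(axis=0)
            j = int(np.argmin(new_costs))
            if best is None or new_costs[j] < best[0] - 1e-12:
                if new_costs[j] < cost - 1e-12:
                    best = (float(new_costs[j]), mi, int(cand[j]))
        if best is None:
            break
        cost, mi, h = best
        medoids[mi] = h
    return medoids, float(cost)


def pam(
    d: np.ndarray, k: int, n_restarts: int = 10, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, float]:
    """PAM on a precomputed distance matrix.

    Returns (medoid indices, labels as indices into the medoid list, total
    cost).  The greedy BUILD seeding plus ``n_restarts - 1`` seeded random
    initializations each run SWAP descent to a local optimum; the best local
    optimum wins.  Deterministic for fixed ``seed``.
    """
    n = d.shape[0]
    if not 1 <= k <= n:
        raise ValueError("need 1 <= k <= n")
    starts = [_pam_build(d, k)]
    rng = np.random.default_rng(seed)
    for _ in range(max(0, n_restarts - 1)):
        starts.append(sorted(rng.choice(n, size=k, replace=False).tolist()))
    best: tuple[float, list[int]] | None = None
    for start in starts:
        medoids, cost = _swap_descent(d, start)
        if best is None or cost < best[0] - 1e-12:
            best = (cost, sorted(medoids))
    cost, medoids = best
    labels = np.argmin(d[:, medoids], axis=1)
    cost = float(d[np.arange(n), np.asarray(medoids)[labels]].sum())
    return np.asarray(medoids), labels, cost


def kmedoids(
    profiles: np.ndarray, k: int, seed: int | None = None
) -> pd.DataFrame:
    """Cluster profile rows by PAM with Euclidean distance.

    Deterministic for fixed ``seed`` (which drives the restart
    initializations).  Returns a frame with ``cluster`` (1-based),
    ``is_medoid`` and the total cost as an attribute.
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("profiles must be a nonempty 2-D matrix")
    if k > X.shape[0]:
        raise ValueError("k cannot exceed the number of profiles")
    d = cdist(X, X)
    medoids, labels, cost = pam(d, k, seed=seed if seed is not None else 0)
    out = pd.DataFrame(
        {
            "cluster": labels + 1,
            "is_medoid": np.isin(np.arange(X.shape[0]), medoids),
        }
    )
    out.attrs["cost"] = cost
    out.attrs["medoids"] = medoids.tolist()
    return out


def pam_brute_force(d: np.ndarray, k: int) -> float:
    """Exhaustive minimum PAM objective over all medoid subsets (oracle)."""
    n = d.shape[0]
    best = np.inf
    for subset in combinations(range(n), k):
        cost = d[:, subset].min(axis=1).sum()
        best = min(best, cost)
    return float(best)


def cluster_course(
    coverage: pd.DataFrame,
    course: str,
    k: int | None = None,
    merge_map: dict[int, int] | None = None,
) -> pd.DataFrame:
    """Relative-accessibility profiles + PAM for the promoters of one course.

    ``coverage`` has one depth-normalized column per course time point (rows
    = regulated promoters).  ``merge_map`` optionally collapses cluster
    labels post hoc (e.g. {10: 9}).  Empty input returns an empty frame.
    """
    stages = list(course_stages(course))
    if k is None:
        k = K_DEFAULTS[course]
    if coverage.empty:
        import warnings

        warnings.warn(f"no regulated promoters to cluster for {course}")
        return pd.DataFrame(columns=["cluster", "is_medoid"] + stages)
    profiles = relative_accessibility(coverage[stages].to_numpy())
    res = kmedoids(profiles, k)
    res.index = coverage.index
    if merge_map:
        res["cluster"] = res["cluster"].replace(merge_map)
    prof = pd.DataFrame(profiles, columns=stages, index=coverage.index)
    return pd.concat([res, prof], axis=1)


def cluster_expression_correlation(
    assignments: pd.DataFrame,
    expression: pd.DataFrame,
    promoter_gene: dict,
    course: str,
) -> tuple[pd.DataFrame, float, float, int]:
    """Mean Pearson r between promoter accessibility and gene expression.

    ``assignments`` is a ``cluster_course`` result; ``expression`` holds
    replicate-averaged expression per gene with one column per course time
    point (transformed here with the same relative formula).  Members whose
    gene is missing or has a constant profile are dropped and tallied.
    Returns (per-cluster table, across-cluster mean, sd, n_dropped).
    """
    stages = list(course_stages(course))
    dropped = 0
    rows = []
    expr_rel = pd.DataFrame(
        relative_accessibility(expression[stages].to_numpy()),
        index=expression.index,
        columns=stages,
    )
    for idx, row in assignments.iterrows():
        gene = promoter_gene.get(idx)
        if gene is None or gene not in expr_rel.index:
            dropped += 1
            continue
        acc = row[stages].to_numpy(dtype=float)
        exp = expr_rel.loc[gene].to_numpy(dtype=float)
        if np.std(acc) == 0 or np.std(exp) == 0:
            dropped += 1
            continue
        r = float(np.corrcoef(acc, exp)[0, 1])
        rows.append({"cluster": row["cluster"], "r": r})
    if not rows:
        return pd.DataFrame(columns=["cluster", "mean_r", "n"]), np.nan, np.nan, dropped
    df = pd.DataFrame(rows)
    per_cluster = (
        df.groupby("cluster")["r"].agg(mean_r="mean", n="size").reset_index()
    )
    mean = float(per_cluster["mean_r"].mean())
    sd = float(per_cluster["mean_r"].std(ddof=1)) if len(per_cluster) > 1 else 0.0
    return per_cluster, mean, sd, dropped


def normalized_stage_coverage(
    counts: pd.DataFrame, course: str
) -> pd.DataFrame:
    """Replicate-mean, size-factor-scaled coverage per course time point.

    Size factors come from the full site x sample count matrix of the
    course (median-of-ratios), matching the shared normalization used by
    the differential tests.
    """
    from regmap.nbstats import size_factors

    stages = list(course_stages(course))
    cols = [c for c in counts.columns if c.split("|")[0] in stages]
    mat = counts[cols].to_numpy(dtype=float)
    sf = size_factors(mat)
    normed = mat / sf
    out = {}
    for s in stages:
        idx = [i for i, c in enumerate(cols) if c.split("|")[0] == s]
        out[s] = normed[:, idx].mean(axis=1)
    return pd.DataFrame(out, index=counts.index)
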