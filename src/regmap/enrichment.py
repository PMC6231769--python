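"""TF-binding enrichment, tissue bias, motif scanning and CpG density."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from regmap.nbstats import bh_adjust, nb_two_group_test

HOT_THRESHOLD = 19
TF_MIN_PEAKS = 200
TF_P_CUTOFF = 0.01
TF_MIN_OR = 2.0
TF_WINDOW = 400
TISSUE_FOLD = 3.0
TISSUE_PADJ = 0.01
TPM_PSEUDO = 0.1

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "W": "AT", "S": "CG", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYWSKMBDHVN", "TGCAYRWSMKVHDBN")


@dataclass
class TFBindingMatrix:
    """Element x factor peak-count matrix with hotness annotation."""

    counts: pd.DataFrame            # integer peak counts per element x factor
    hot_threshold: int = HOT_THRESHOLD

    @property
    def bound(self) -> pd.DataFrame:
        return self.counts > 0

    @property
    def factor_count(self) -> pd.Series:
        return self.bound.sum(axis=1)

    @property
    def hotness(self) -> pd.Series:
        fc = self.factor_count
        out = pd.Series("none", index=fc.index)
        out[(fc >= 1) & (fc < self.hot_threshold)] = "cold"
        out[fc >= self.hot_threshold] = "HOT"
        return out

    def factor_names(self) -> pd.Series:
        b = self.bound
        return b.apply(lambda row: ",".join(b.columns[row.to_numpy()]), axis=1)


def assign_tf_peaks(
    elements: pd.DataFrame,
    peaks: pd.DataFrame,
    window: int = TF_WINDOW,
    hot_threshold: int = HOT_THRESHOLD,
) -> TFBindingMatrix:
    """Assign TF peaks to elements by summit overlap with the centered window.

    The window is the half-open ``[midpoint - window/2, midpoint + window/2)``
    region around the element midpoint.
    """
    half = window // 2
    mids = ((elements["start"].to_numpy() + elements["end"].to_numpy()) // 2).astype(int)
    factors = sorted(peaks["factor"].unique())
    counts = np.zeros((len(elements), len(factors)), dtype=int)
    for fi, factor in enumerate(factors):
        sub = peaks[peaks["factor"] == factor]
        for chrom in sub["chrom"].unique():
            summits = np.sort(
                sub.loc[sub["chrom"] == chrom, "summit"].to_numpy(dtype=int)
            )
            on_chrom = elements["chrom"].to_numpy() == chrom
            lo = np.searchsorted(summits, mids - half, side="left")
            hi = np.searchsorted(summits, mids + half - 1, side="right")
            counts[:, fi] += np.where(on_chrom, hi - lo, 0)
    df = pd.DataFrame(counts, index=elements.index, columns=factors)
    return TFBindingMatrix(df, hot_threshold=hot_threshold)


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> float:
    """(a*d)/(b*c) with Haldane +0.5 correction only when a zero cell occurs."""
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]]."""
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


@dataclass
class EnrichmentResult:
    odds_ratio: pd.DataFrame   # factors x clusters
    p: pd.DataFrame
    kept: pd.Series
    n_universe: int
    peaks_on_universe: pd.Series


def tf_enrichment(
    clusters: pd.Series,
    binding: TFBindingMatrix,
    min_peaks: int = TF_MIN_PEAKS,
    p_cutoff: float = TF_P_CUTOFF,
    min_or: float = TF_MIN_OR,
) -> EnrichmentResult:
    """Per factor x cluster odds-ratio enrichment over non-HOT elements.

    ``clusters`` maps element index -> cluster label for the clustered
    promoters.  HOT elements are removed first; factors need more than
    ``min_peaks`` peaks on the remaining universe; kept factors must reach
    p < ``p_cutoff`` somewhere and a maximum odds ratio > ``min_or``.
    """
    hot = binding.hotness == "HOT"
    universe = clusters.index[~hot.reindex(clusters.index, fill_value=False)]
    labels = clusters.loc[universe]
    bound = binding.bound.loc[universe]
    peak_counts = binding.counts.loc[universe].sum(axis=0)
    factors = [f for f in bound.columns if peak_counts[f] > min_peaks]
    cluster_names = sorted(labels.unique())
    n = len(universe)

    ors = pd.DataFrame(np.nan, index=factors, columns=cluster_names)
    ps = pd.DataFrame(np.nan, index=factors, columns=cluster_names)
    for f in factors:
        fb = bound[f]
        for cl in cluster_names:
            in_cl = labels == cl
            a = int((fb & in_cl).sum())          # bound, in cluster
            b = int((~fb & in_cl).sum())         # unbound, in cluster
            c = int((fb & ~in_cl).sum())         # bound, elsewhere
            d = n - a - b - c
            ors.loc[f, cl] = odds_ratio_2x2(a, b, c, d)
            ps.loc[f, cl] = fisher_p(a, b, c, d)
    kept = pd.Series(
        [
            bool(((ps.loc[f] < p_cutoff) & (ors.loc[f] > min_or)).any())
            for f in factors
        ],
        index=factors,
    )
    return EnrichmentResult(ors, ps, kept, n, peak_counts)


def tissue_bias(
    expr_replicates: pd.DataFrame,
    fold_cutoff: float = TISSUE_FOLD,
    padj_cutoff: float = TISSUE_PADJ,
    pseudo: float = TPM_PSEUDO,
) -> pd.DataFrame:
    """Tissue-biased expression calls from a replicate-level gene table.

    Columns are ``{tissue}|rep{r}``.  Fold change compares the highest and
    second-highest tissue means (both pseudo-counted); the p-value comes
    from the NB two-group test on the two tissues' replicate values, BH
    adjusted across genes.
    """
    tissues = sorted({c.split("|")[0] for c in expr_replicates.columns})
    if len(tissues) < 2:
        raise ValueError("need >= 2 tissues")
    cols = {t: [c for c in expr_replicates.columns if c.split("|")[0] == t] for t in tissues}
    means = pd.DataFrame(
        {t: expr_replicates[cols[t]].mean(axis=1) for t in tissues}
    )
    order = np.argsort(-means.to_numpy(), axis=1)
    top_idx, second_idx = order[:, 0], order[:, 1]
    tissue_arr = np.array(tissues)
    top = tissue_arr[top_idx]
    second = tissue_arr[second_idx]
    top_val = means.to_numpy()[np.arange(len(means)), top_idx]
    second_val = means.to_numpy()[np.arange(len(means)), second_idx]
    fold = (top_val + pseudo) / (second_val + pseudo)

    counts_top = np.array(
        [
            expr_replicates.iloc[i][cols[t]].to_numpy(dtype=float)
            for i, t in enumerate(top)
        ]
    )
    counts_second = np.array(
        [
            expr_replicates.iloc[i][cols[t]].to_numpy(dtype=float)
            for i, t in enumerate(second)
        ]
    )
    res = nb_two_group_test(np.round(counts_second), np.round(counts_top))
    padj = bh_adjust(res.p_twosided)
    return pd.DataFrame(
        {
            "top_tissue": top,
            "fold": fold,
            "padj": padj,
            "biased": (fold >= fold_cutoff) & (padj < padj_cutoff),
        },
        index=expr_replicates.index,
    )


def cluster_tissue_composition(
    clusters: pd.Series,
    bias: pd.DataFrame,
    promoter_gene: dict,
) -> pd.DataFrame:
    """Percentage of cluster genes biased toward each tissue."""
    tissues = sorted(bias["top_tissue"].unique())
    rows = {}
    for cl in sorted(clusters.unique()):
        members = clusters.index[clusters == cl]
        genes = [promoter_gene.get(m) for m in members]
        genes = [g for g in genes if g is not None]
        total = len(genes)
        row = {}
        for t in tissues:
            biased = [
                g
                for g in genes
                if g in bias.index
                and bool(bias.loc[g, "biased"])
                and bias.loc[g, "top_tissue"] == t
            ]
            row[t] = 100.0 * len(biased) / total if total else 0.0
        rows[cl] = row
    return pd.DataFrame(rows).T


def relative_tf_expression(
    tpm: pd.DataFrame, pseudo: float = TPM_PSEUDO
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-factor per-tissue log2 relative expression plus TPM deciles.

    The relative value is ``log2((TPM + pseudo) / rowmean(TPM + pseudo))``.
    Deciles (1..10) are calibrated per tissue over entries with TPM >= 1;
    smaller TPMs get no decile (NaN).
    """
    vals = tpm.to_numpy(dtype=float) + pseudo
    rel = np.log2(vals / vals.mean(axis=1, keepdims=True))
    rel_df = pd.DataFrame(rel, index=tpm.index, columns=tpm.columns)
    deciles = pd.DataFrame(np.nan, index=tpm.index, columns=tpm.columns)
    for col in tpm.columns:
        v = tpm[col].to_numpy(dtype=float)
        eligible = v >= 1.0
        if eligible.sum() == 0:
            continue
        qs = np.quantile(v[eligible], np.linspace(0.1, 0.9, 9))
        dec = 1 + np.searchsorted(qs, v[eligible], side="right")
        deciles.loc[eligible, col] = dec
    return rel_df, deciles


def scan_consensus(sequence: str, iupac_pattern: str) -> dict[str, list[int]]:
    """Zero-mismatch IUPAC consensus scan of both strands.

    Returns 0-based start positions (on the forward coordinate system) of
    matches on each strand, including overlapping matches.
    """
    import re

    if not iupac_pattern:
        raise ValueError("empty pattern")
    seq = sequence.upper()
    pat = "".join(
        f"[{IUPAC[ch]}]" if len(IUPAC.get(ch, ch)) > 1 else IUPAC.get(ch, ch)
        for ch in iupac_pattern.upper()
    )
    fwd = [m.start() for m in re.finditer(f"(?={pat})", seq)]
    rc_pattern = iupac_pattern.upper().translate(_COMPLEMENT)[::-1]
    pat_rc = "".join(
        f"[{IUPAC[ch]}]" if len(IUPAC.get(ch, ch)) > 1 else IUPAC.get(ch, ch)
        for ch in rc_pattern
    )
    rev = [m.start() for m in re.finditer(f"(?={pat_rc})", seq)]
    return {"+": fwd, "-": rev}


def cpg_density(sequence: str, window: int) -> np.ndarray:
    """CG-dinucleotide start density in a centered window, per bp.

    Stand-in definition: count of CG starts within the centered window
    divided by the window length.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    seq = sequence.upper()
    n = len(seq)
    cg = np.zeros(n)
    for i in range(n - 1):
        if seq[i] == "C" and seq[i + 1] == "G":
            cg[i] = 1.0
    if n == 0:
        return cg
    kernel = np.ones(window)
    counts = np.convolve(cg, kernel, mode="same")
    return counts / window
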