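"""Concavity-based accessible-site calling.

Candidate peaks are maximal runs of negative smoothed second derivative of
the cross-stage mean ATAC coverage.  Each candidate is scored per sample by
the magnitude of that sample's smoothed second derivative at the summit,
replicate score pairs are passed through the copula-mixture consistency fit
per stage, and candidates reproducible (IDR <= cutoff) in at least one
stage become accessible sites with fixed summit +- flank boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import oaconvolve

from regmap.idr import IdrModel, fit_idr

DEFAULT_BANDWIDTH = 50.0
DEFAULT_MIN_REGION = 20
DEFAULT_FLANK = 75
DEFAULT_IDR_CUTOFF = 0.001

SOURCES = ("atac_wt_pe", "atac_wt_se", "atac_glp1_se")


@dataclass
class CandidatePeak:
    chrom: str
    start: int
    end: int
    summit: int

    def __post_init__(self) -> None:
        if not self.start <= self.summit < self.end:
            raise ValueError("summit must lie inside the candidate interval")


def smoothed_second_derivative(coverage: np.ndarray, bandwidth: float) -> np.ndarray:
    """Convolution with the second derivative of a Gaussian kernel.

    ``bandwidth`` is the kernel standard deviation in bp; edges are
    zero-padded.  Linear in the input.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    coverage = np.asarray(coverage, dtype=float)
    if coverage.size == 0:
        raise ValueError("empty track")
    half = max(1, int(4 * bandwidth))
    x = np.arange(-half, half + 1, dtype=float)
    g = np.exp(-0.5 * (x / bandwidth) ** 2)
    g /= g.sum()
    kernel = g * (x**2 - bandwidth**2) / bandwidth**4
    kernel -= kernel.mean()  # exact zero response to constant input
    return oaconvolve(coverage, kernel, mode="same")


def find_concave_regions(
    d2_track: np.ndarray,
    mean_coverage: np.ndarray,
    chrom: str = "chrI",
    min_size: int = DEFAULT_MIN_REGION,
    edge_exclusion: int = 0,
) -> list[CandidatePeak]:
    """Maximal runs of strictly negative second derivative, min length filter.

    The summit is the leftmost position of maximal mean coverage in the run.
    Negativity is assessed against a tiny relative epsilon so convolution
    round-off on flat stretches does not fabricate runs; regions overlapping
    the first/last ``edge_exclusion`` bp (zero-padding artifacts) are
    dropped.
    """
    d2 = np.asarray(d2_track, dtype=float)
    if d2.size != np.asarray(mean_coverage).size:
        raise ValueError("track length mismatch")
    if d2.size == 0:
        return []
    eps = 1e-9 * np.max(np.abs(d2), initial=0.0)
    neg = d2 < -eps
    edges = np.flatnonzero(np.diff(neg.astype(np.int8)))
    starts = list(edges[~neg[edges]] + 1)
    ends = list(edges[neg[edges]] + 1)
    if neg[0]:
        starts = [0] + starts
    if neg[-1]:
        ends = ends + [neg.size]
    out = []
    for s, e in zip(starts, ends):
        if e - s < min_size:
            continue
        if edge_exclusion and (s < edge_exclusion or e > neg.size - edge_exclusion):
            continue
        summit = s + int(np.argmax(mean_coverage[s:e]))
        out.append(CandidatePeak(chrom, int(s), int(e), summit))
    return out


def score_candidates(
    candidates: list[CandidatePeak],
    sample_coverage: np.ndarray,
    bandwidth: float = DEFAULT_BANDWIDTH,
) -> np.ndarray:
    """Per-candidate score: max(0, -d2_sample(summit)); 0 without local concavity."""
    d2 = smoothed_second_derivative(sample_coverage, bandwidth)
    summits = np.array([c.summit for c in candidates], dtype=int)
    return np.maximum(0.0, -d2[summits]) if summits.size else np.zeros(0)


def call_peaks(
    candidates: list[CandidatePeak],
    stage_scores: dict[str, tuple[np.ndarray, np.ndarray]],
    stage_coverage: dict[str, list[np.ndarray]],
    idr_cutoff: float = DEFAULT_IDR_CUTOFF,
    flank: int = DEFAULT_FLANK,
    source: str = "atac_wt_pe",
    chrom_length: int | None = None,
) -> tuple[pd.DataFrame, dict[str, IdrModel]]:
    """Retain candidates reproducible in >= 1 stage; fix boundaries and heights.

    ``stage_scores`` maps stage -> (replicate-1 scores, replicate-2 scores)
    over the same candidates; ``stage_coverage`` maps stage -> replicate
    coverage tracks used for the per-stage height columns.  Returns the site
    table plus the per-stage fitted consistency models.

    Heights are the maximum depth-normalized (reads-per-million-equivalent)
    mean-of-replicates coverage within the site boundary.
    """
    if not 0 < idr_cutoff < 1:
        raise ValueError("idr_cutoff must be in (0, 1)")
    n = len(candidates)
    models: dict[str, IdrModel] = {}
    min_idr = np.full(n, np.inf)
    for stage, (s1, s2) in stage_scores.items():
        model = fit_idr(np.asarray(s1), np.asarray(s2))
        models[stage] = model
        min_idr = np.minimum(min_idr, model.idr)

    keep = np.flatnonzero(min_idr <= idr_cutoff)
    # precompute normalized replicate-mean coverage per stage lazily per window
    scales = {
        stage: [1e6 / max(track.sum(), 1.0) for track in tracks]
        for stage, tracks in stage_coverage.items()
    }
    rows = []
    for i in keep:
        c = candidates[i]
        start = c.summit - flank
        end = c.summit + flank + 1
        if chrom_length is not None:
            if start < 0 or end > chrom_length:
                continue  # sites running off the chromosome are dropped
        row = {
            "chrom": c.chrom,
            "start": int(start),
            "end": int(end),
            "summit": int(c.summit),
            "idr": float(min_idr[i]),
            "atac_source": source,
        }
        for stage, tracks in stage_coverage.items():
            win = slice(max(0, start), end)
            norm = np.mean(
                [t[win] * s for t, s in zip(tracks, scales[stage])], axis=0
            )
            row[f"atac_{stage}_height"] = float(norm.max()) if norm.size else 0.0
        rows.append(row)
    cols = ["chrom", "start", "end", "summit", "idr", "atac_source"] + [
        f"atac_{stage}_height" for stage in stage_coverage
    ]
    df = pd.DataFrame(rows, columns=cols)
    return df, models


def merge_peak_sets(
    primary: pd.DataFrame,
    secondary: pd.DataFrame,
    tertiary: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Successive merge: keep later-set sites only if they overlap nothing kept.

    Overlap means >= 1 shared bp on the same chromosome.  Source tags are
    preserved from each input table.
    """
    if tertiary is None:
        tertiary = primary.iloc[0:0]
    kept = primary.copy()
    for extra in (secondary, tertiary):
        if extra is None or extra.empty:
            continue
        add = []
        for _, site in extra.iterrows():
            if kept.empty:
                overlaps = False
            else:
                same = kept[kept["chrom"] == site["chrom"]]
                overlaps = (
                    (same["start"] < site["end"]) & (site["start"] < same["end"])
                ).any()
            if not overlaps:
                add.append(site)
        if add:
            kept = pd.concat([kept, pd.DataFrame(add)], ignore_index=True)
    return kept.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
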