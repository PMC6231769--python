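"""Per-site transcription evidence: elongation (jump/incr) and initiation.

Windows are anchored at the site summit and strand-relative: an offset
``o = (pos - summit) * sign`` with sign +1/-1 for +/- strands.  The
upstream window is offsets [-250, -75), the downstream window [+75, +250),
both 175 bp under the half-open convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from regmap.nbstats import bh_adjust, nb_two_group_test

JUMP_WINDOWS = ((-250, -75), (75, 250))
JUMP_LFC = 1.5
JUMP_PADJ = 0.1
INCR_MIN_TOTAL = 3
INITIATION_WINDOW = 125
BEST_GUESS_OFFSET = 60


@dataclass
class JumpResult:
    upstream: tuple[int, ...]
    downstream: tuple[int, ...]
    lfc: float
    p: float
    padj: float
    lfc_cutoff: float = JUMP_LFC
    padj_cutoff: float = JUMP_PADJ

    @property
    def passed(self) -> bool:
        return self.lfc > self.lfc_cutoff and self.padj < self.padj_cutoff


@dataclass
class IncrResult:
    upstream: tuple[int, ...]
    downstream: tuple[int, ...]

    @property
    def passed(self) -> bool:
        return (
            sum(self.upstream) == 0
            and all(d >= 1 for d in self.downstream)
            and sum(self.downstream) >= INCR_MIN_TOTAL
        )


@dataclass
class InitiationCall:
    passed: bool
    mode: int
    mode_provenance: str  # "observed" | "best_guess"
    reproducible_positions: np.ndarray = field(
        default_factory=lambda: np.zeros(0, dtype=int)
    )


def _window_slice(summit: int, strand: str, offsets: tuple[int, int], length: int):
    """Half-open genomic slice for a strand-relative offset window."""
    a, b = offsets
    if strand == "+":
        lo, hi = summit + a, summit + b
    elif strand == "-":
        # mirror: offsets o in [a, b) with o = summit - pos
        lo, hi = summit - b + 1, summit - a + 1
    else:
        raise ValueError(f"bad strand {strand!r}")
    truncated = lo < 0 or hi > length
    return slice(max(0, lo), min(length, hi)), truncated


def window_counts(
    rep_tracks: list[np.ndarray], summit: int, strand: str
) -> tuple[tuple[int, ...], tuple[int, ...], bool]:
    """5'-end counts per replicate in the upstream and downstream windows."""
    length = rep_tracks[0].size
    up_sl, t1 = _window_slice(summit, strand, JUMP_WINDOWS[0], length)
    dn_sl, t2 = _window_slice(summit, strand, JUMP_WINDOWS[1], length)
    up = tuple(int(t[up_sl].sum()) for t in rep_tracks)
    dn = tuple(int(t[dn_sl].sum()) for t in rep_tracks)
    return up, dn, (t1 or t2)


def jump_test_batch(
    summits: np.ndarray,
    strand: str,
    rep_tracks: list[np.ndarray],
    lfc_cutoff: float = JUMP_LFC,
    padj_cutoff: float = JUMP_PADJ,
) -> list[JumpResult]:
    """Jump test for all sites of one stage x strand.

    The NB Wald test runs on the sites x windows count matrix; BH correction
    is applied across all sites tested here, matching a per-contrast run.
    """
    ups, dns = [], []
    for summit in np.asarray(summits, dtype=int):
        up, dn, _ = window_counts(rep_tracks, int(summit), strand)
        ups.append(up)
        dns.append(dn)
    up_mat = np.array(ups, dtype=float)
    dn_mat = np.array(dns, dtype=float)
    if up_mat.size == 0:
        return []
    res = nb_two_group_test(up_mat, dn_mat)
    padj = bh_adjust(res.p_greater)
    return [
        JumpResult(
            tuple(map(int, u)),
            tuple(map(int, d)),
            float(l),
            float(p),
            float(q),
            lfc_cutoff,
            padj_cutoff,
        )
        for u, d, l, p, q in zip(ups, dns, res.lfc, res.p_greater, padj)
    ]


def incr_test(
    upstream: tuple[int, ...], downstream: tuple[int, ...]
) -> IncrResult:
    """Deterministic weak-signal elongation rule."""
    return IncrResult(tuple(upstream), tuple(downstream))


def pool_shortcap(rep_tracks: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Pool replicate 5'-end tracks and build the reproducibility mask.

    Returns (pooled sum, mask) where mask(bp) is True iff >= 2 replicates
    have a nonzero count at bp.
    """
    stack = np.stack([np.asarray(t) for t in rep_tracks])
    pooled = stack.sum(axis=0, dtype=np.int64)
    mask = (stack > 0).sum(axis=0) >= 2
    return pooled, mask


def initiation_call(
    summit: int,
    strand: str,
    pooled: np.ndarray,
    mask: np.ndarray,
    window: int = INITIATION_WINDOW,
    best_guess_offset: int = BEST_GUESS_OFFSET,
) -> InitiationCall:
    """Reproducible-initiation call and representative mode for one site/strand.

    The search window is [summit-window, summit+window] inclusive.  The mode
    is the masked bp with maximal pooled signal; ties go to the bp closest
    to the summit, then strand-relative downstream.  Without reproducible
    signal the mode is extrapolated ``best_guess_offset`` bp downstream.
    """
    sign = 1 if strand == "+" else -1
    lo = max(0, summit - window)
    hi = min(pooled.size, summit + window + 1)
    idx = np.flatnonzero(mask[lo:hi]) + lo
    if idx.size:
        vals = pooled[idx]
        # sort: max pooled, then min distance, then downstream side first
        order = sorted(
            range(idx.size),
            key=lambda i: (
                -vals[i],
                abs(int(idx[i]) - summit),
                -sign * int(idx[i]),
            ),
        )
        best = int(idx[order[0]])
        return InitiationCall(True, best, "observed", reproducible_positions=idx)
    return InitiationCall(False, summit + sign * best_guess_offset, "best_guess")


_STRAND_KEY = {"+": "fwd", "-": "rev"}
_KEY_STRAND = {v: k for k, v in _STRAND_KEY.items()}


def evidence_to_frame(
    evidence: dict[tuple[int, str], dict], n_sites: int, stages: list[str]
) -> pd.DataFrame:
    """Flatten the evidence mapping into one row per site."""
    rows = []
    for i in range(n_sites):
        row: dict = {}
        for strand, key in _STRAND_KEY.items():
            ev = evidence[(i, strand)]
            init = ev["initiation"]
            row[f"scap_{key}_passed"] = init.passed
            row[f"tss_{key}"] = init.mode
            row[f"tss_{key}_provenance"] = init.mode_provenance
            for stage in stages:
                j = ev["jump"][stage]
                pre = f"lcap_{stage}_{key}"
                row[f"{pre}_up"] = ",".join(map(str, j.upstream))
                row[f"{pre}_down"] = ",".join(map(str, j.downstream))
                row[f"{pre}_lfc"] = j.lfc
                row[f"{pre}_padj"] = j.padj
                row[f"{pre}_passed_jump"] = j.passed
                row[f"{pre}_passed_incr"] = ev["incr"][stage].passed
        rows.append(row)
    return pd.DataFrame(rows)


def evidence_from_frame(
    frame: pd.DataFrame, stages: list[str]
) -> dict[tuple[int, str], dict]:
    """Inverse of :func:`evidence_to_frame` (counts, stats and calls)."""
    out: dict[tuple[int, str], dict] = {}
    for i, (_, row) in enumerate(frame.iterrows()):
        for key, strand in _KEY_STRAND.items():
            init = InitiationCall(
                bool(row[f"scap_{key}_passed"]),
                int(row[f"tss_{key}"]),
                str(row[f"tss_{key}_provenance"]),
            )
            jumps, incrs = {}, {}
            for stage in stages:
                pre = f"lcap_{stage}_{key}"
                up = tuple(int(x) for x in str(row[f"{pre}_up"]).split(","))
                dn = tuple(int(x) for x in str(row[f"{pre}_down"]).split(","))
                jumps[stage] = JumpResult(
                    up, dn, float(row[f"{pre}_lfc"]), np.nan, float(row[f"{pre}_padj"])
                )
                incrs[stage] = IncrResult(up, dn)
            out[(i, strand)] = {"initiation": init, "jump": jumps, "incr": incrs}
    return out


def evidence_table(
    sites: pd.DataFrame,
    stages: list[str],
    scap_tracks: dict[str, list[np.ndarray]],
    lcap_tracks: dict[tuple[str, str], list[np.ndarray]],
) -> dict[tuple[int, str], dict]:
    """Compute all evidence for every site x strand.

    ``scap_tracks``: strand -> pooled-replicate short-cap 5' tracks.
    ``lcap_tracks``: (stage, strand) -> replicate long-cap 5' tracks.
    Returns a mapping (site index, strand) -> dict with keys ``initiation``,
    ``jump`` (stage -> JumpResult) and ``incr`` (stage -> IncrResult).
    """
    out: dict[tuple[int, str], dict] = {}
    summits = sites["summit"].to_numpy()
    pooled_masks = {
        strand: pool_shortcap(tracks) for strand, tracks in scap_tracks.items()
    }
    for strand in ("+", "-"):
        pooled, mask = pooled_masks[strand]
        jump_by_stage = {
            stage: jump_test_batch(summits, strand, lcap_tracks[(stage, strand)])
            for stage in stages
        }
        for i, summit in enumerate(summits):
            init = initiation_call(int(summit), strand, pooled, mask)
            jumps = {stage: jump_by_stage[stage][i] for stage in stages}
            incrs = {
                stage: incr_test(jumps[stage].upstream, jumps[stage].downstream)
                for stage in stages
            }
            out[(i, strand)] = {"initiation": init, "jump": jumps, "incr": incrs}
    return out
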