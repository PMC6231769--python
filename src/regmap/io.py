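"""Readers and writers for bedGraph tracks, BED6 peaks and output tables.

All intervals are 0-based half-open.  bedGraph reading validates interval
sanity (end > start, within chromosome bounds when known, no overlaps on a
track) and tolerates unsorted input with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def write_bedgraph(track: np.ndarray, chrom: str, path) -> None:
    """Run-length encode a dense per-bp track; zero runs are omitted."""
    arr = np.asarray(track)
    with open(path, "w") as fh:
        if arr.size == 0:
            return
        change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [arr.size]])
        for s, e in zip(starts, ends):
            v = arr[s]
            if v != 0:
                val = int(v) if float(v).is_integer() else float(v)
                fh.write(f"{chrom}\t{s}\t{e}\t{val}\n")


def read_bedgraph(
    path, chrom_lengths: dict[str, int], dtype=np.float64
) -> dict[str, np.ndarray]:
    """Parse a bedGraph file into dense per-chromosome arrays."""
    tracks = {c: np.zeros(n, dtype=dtype) for c, n in chrom_lengths.items()}
    seen: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    prev_key = None
    unsorted = False
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, s, e, v = line.split()[:4]
            s, e = int(s), int(e)
            if e <= s:
                raise ValueError(f"{path}: interval end <= start at {chrom}:{s}-{e}")
            if chrom not in tracks:
                raise ValueError(f"{path}: unknown chromosome {chrom}")
            if e > chrom_lengths[chrom]:
                raise ValueError(f"{path}: interval past chromosome end {chrom}:{e}")
            if prev_key is not None and (chrom, s) < prev_key:
                unsorted = True
            prev_key = (chrom, s)
            seen[chrom].append((s, e))
            tracks[chrom][s:e] += dtype(v) if dtype is not np.float64 else float(v)
    if unsorted:
        warnings.warn(f"{path}: unsorted bedGraph, sorted internally")
    for chrom, ivals in seen.items():
        ivals.sort()
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValueError(
                    f"{path}: overlapping intervals {chrom}:{s1}-{e1} / {s2}-{e2}"
                )
    return tracks


def write_bed6(df: pd.DataFrame, path, summit_col: str = "summit") -> None:
    """BED6 with the summit encoded in thickStart (column 7)."""
    with open(path, "w") as fh:
        for _, r in df.iterrows():
            name = r.get("name", r.get("factor", "."))
            fh.write(
                f"{r['chrom']}\t{int(r['start'])}\t{int(r['end'])}\t{name}\t"
                f"{int(r.get('score', 0))}\t{r.get('strand', '.')}\t"
                f"{int(r[summit_col])}\n"
            )


def read_bed6(path) -> pd.DataFrame:
    """Read BED6(+summit); a missing summit column falls back to the midpoint."""
    rows = []
    fell_back = False
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, s, e = parts[0], int(parts[1]), int(parts[2])
            if e <= s:
                raise ValueError(f"{path}: interval end <= start")
            name = parts[3] if len(parts) > 3 else "."
            score = int(float(parts[4])) if len(parts) > 4 else 0
            strand = parts[5] if len(parts) > 5 else "."
            if len(parts) > 6:
                summit = int(parts[6])
            else:
                summit = (s + e) // 2
                fell_back = True
            rows.append((chrom, s, e, name, score, strand, summit))
    if fell_back:
        warnings.warn(f"{path}: no summit column, using interval midpoints")
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "factor", "score", "strand", "summit"]
    )


def write_table(df: pd.DataFrame, path, config_hash: str | None = None) -> None:
    """Tab-separated table with an optional config-hash header comment."""
    with open(path, "w") as fh:
        if config_hash is not None:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
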