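"""Simulate per-stage/replicate signal tracks for planted elements.

Track semantics match what the analysis consumes:

* ``atac``: nonnegative real coverage per bp, one track per (stage,
  replicate).  Each active element contributes a unimodal Gaussian bump
  (sd ~75 bp) whose per-replicate amplitude is negative-binomial around
  ``depth * stage_profile``.
* ``shortcap_5p``: stranded integer 5'-end counts per (replicate, strand);
  replicates are pooled across stages downstream, so stages do not index
  these tracks.  Initiation-positive elements get counts concentrated at
  fixed mode positions within +-40 bp of the center.
* ``longcap_5p`` / ``longcap_cov``: stranded integer 5'-end counts and
  coverage per (stage, replicate, strand).  Promoter elements get 5' ends
  downstream (strand-relative) of the center and continuous coverage from
  the center through the outron to the gene end; enhancers get neither.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from regmap.genome import GenomeModel
from regmap.stages import STAGES
from regmap.synthetic.elements import PlantedElement

STRANDS = ("+", "-")

_PROMOTER_CLASSES = {"coding_promoter", "pseudogene_promoter"}
_INITIATION_CLASSES = _PROMOTER_CLASSES | {"enhancer", "ncRNA_site"}


@dataclass
class SignalBundle:
    """All simulated tracks, keyed by chromosome inside each entry."""

    chromosomes: list[tuple[str, int]]
    stages: list[str]
    n_reps: int
    scap_reps: int
    atac: dict = field(default_factory=dict)         # (stage, rep) -> {chrom: f32}
    longcap_5p: dict = field(default_factory=dict)   # (stage, rep, strand) -> {chrom: i32}
    longcap_cov: dict = field(default_factory=dict)  # (stage, rep, strand) -> {chrom: i32}
    shortcap_5p: dict = field(default_factory=dict)  # (rep, strand) -> {chrom: i32}

    def validate(self) -> None:
        sizes = dict(self.chromosomes)
        for tracks in (self.atac, self.longcap_5p, self.longcap_cov, self.shortcap_5p):
            for key, per_chrom in tracks.items():
                for chrom, arr in per_chrom.items():
                    if arr.shape != (sizes[chrom],):
                        raise ValueError(f"track {key}/{chrom} has wrong length")
                    if arr.min() < 0:
                        raise ValueError(f"track {key}/{chrom} has negative values")


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size=None):
    """NB(mean, dispersion) with var = mean + dispersion * mean^2."""
    if mean <= 0:
        return np.zeros(size or (), dtype=np.int64) if size else 0
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def _gaussian_bump(sd: float) -> np.ndarray:
    half = int(4 * sd)
    x = np.arange(-half, half + 1)
    return np.exp(-0.5 * (x / sd) ** 2)


def simulate_signal(
    genome: GenomeModel,
    elements: list[PlantedElement],
    depth: float = 50.0,
    dispersion: float = 0.05,
    seed: int = 0,
    *,
    n_reps: int = 2,
    scap_reps: int = 4,
    peak_sd: float = 75.0,
    atac_background: float = 1.0,
    fivep_background: float = 0.01,
    longcap_cov_background: float = 0.05,
    scap_rate: float = 0.06,
    scap_antisense_rate: float = 0.25,
    lcap_5p_rate: float = 0.4,
    lcap_cov_rate: float = 0.04,
) -> SignalBundle:
    """Simulate all tracks; deterministic for a fixed seed.

    ``depth`` scales every element-derived rate, so ``depth=0`` leaves pure
    background.  Element signal rates default to: ATAC bump amplitude
    ``depth * profile``; short-cap mode rate ``scap_rate * depth *
    mean(profile)`` per replicate; long-cap 5'-end window rate ``lcap_5p_rate
    * depth * profile``; long-cap coverage fill ``1 + Poisson(lcap_cov_rate *
    depth * profile)`` per bp.
    """
    if depth < 0 or dispersion < 0 or n_reps < 2 or scap_reps < 2:
        raise ValueError("invalid simulation parameters")
    rng = np.random.default_rng(seed)
    bundle = SignalBundle(
        chromosomes=list(genome.chromosomes),
        stages=list(STAGES),
        n_reps=n_reps,
        scap_reps=scap_reps,
    )
    bump = _gaussian_bump(peak_sd)
    half = len(bump) // 2
    genes = {g.gene_id: g for g in genome.genes}

    for chrom, length in genome.chromosomes:
        els = [e for e in elements if e.chrom == chrom]

        # ---------------- ATAC ------------------------------------------------
        for si, stage in enumerate(STAGES):
            for rep in range(n_reps):
                track = rng.poisson(atac_background, length).astype(np.float32)
                for el in els:
                    mean_amp = depth * el.stage_profile[si]
                    if mean_amp <= 0:
                        continue
                    amp = float(_nb_draw(rng, mean_amp, dispersion))
                    lo = max(0, el.center - half)
                    hi = min(length, el.center + half + 1)
                    track[lo:hi] += (
                        amp * bump[lo - (el.center - half): hi - (el.center - half)]
                    ).astype(np.float32)
                bundle.atac.setdefault((stage, rep), {})[chrom] = track

        # ---------------- short-cap 5' ends ----------------------------------
        for rep in range(scap_reps):
            for strand in STRANDS:
                track = rng.poisson(fivep_background, length).astype(np.int32)
                # int32 is ample: per-bp 5'-end counts stay tiny
                for el in els:
                    if el.true_class not in _INITIATION_CLASSES:
                        continue
                    mean_prof = float(el.stage_profile.mean())
                    base = scap_rate * depth * mean_prof
                    if base <= 0:
                        continue
                    for pos, rate in _scap_modes(el, strand, base, genes):
                        if 0 <= pos < length and rate > 0:
                            track[pos] += rng.poisson(rate)
                bundle.shortcap_5p.setdefault((rep, strand), {})[chrom] = track

        # ---------------- long-cap --------------------------------------------
        for si, stage in enumerate(STAGES):
            for rep in range(n_reps):
                for strand in STRANDS:
                    fivep = rng.poisson(fivep_background, length).astype(np.int32)
                    cov = rng.poisson(longcap_cov_background, length).astype(np.int32)
                    # 88 stranded long-cap tracks exist at once; int32 keeps the
                    # 2 Mb default fixture under ~1 GiB total
                    for el in els:
                        if el.true_class not in _PROMOTER_CLASSES:
                            continue
                        gene = genes[el.target_gene_id]
                        if gene.strand != strand:
                            continue
                        prof = float(el.stage_profile[si])
                        rate5 = lcap_5p_rate * depth * prof
                        if rate5 > 0:
                            n5 = rng.poisson(rate5)
                            sign = 1 if strand == "+" else -1
                            offs = rng.integers(75, 250, size=n5)
                            pos = el.center + sign * offs
                            pos = pos[(pos >= 0) & (pos < length)]
                            np.add.at(fivep, pos, 1)
                        fill_rate = lcap_cov_rate * depth * prof
                        if depth * prof > 0:
                            lo = min(el.center, gene.gene_end_3p)
                            hi = max(el.center, gene.gene_end_3p) + 1
                            lo, hi = max(0, lo), min(length, hi)
                            cov[lo:hi] += (
                                1 + rng.poisson(fill_rate, hi - lo)
                            ).astype(np.int32)
                    bundle.longcap_5p.setdefault((stage, rep, strand), {})[chrom] = fivep
                    bundle.longcap_cov.setdefault((stage, rep, strand), {})[chrom] = cov

    bundle.validate()
    return bundle


def _scap_modes(el, strand, base, genes):
    """(position, Poisson rate) pairs of fixed initiation modes for an element."""
    sign = 1 if strand == "+" else -1
    if el.true_class in _PROMOTER_CLASSES:
        gene = genes[el.target_gene_id]
        if gene.strand == strand:
            # main sense mode slightly upstream of the center
            return [(el.center - 10 * sign, base), (el.center - 10 * sign + 1, 0.4 * base)]
        # weak divergent antisense initiation
        return [(el.center - 60 * sign, 0.25 * base)]
    if el.true_class == "enhancer":
        return [(el.center + 25 * sign, base), (el.center - 25 * sign, 0.5 * base)]
    if el.true_class == "ncRNA_site":
        if el.strand_active.get(strand):
            return [(el.center - 5 * sign, base)]
        return []
    return []
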