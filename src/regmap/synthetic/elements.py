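"""Plant regulatory elements with known classes and temporal profiles."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from regmap.genome import NCRNA_BIOTYPES, Gene, GenomeModel
from regmap.stages import STAGES

ELEMENT_CLASSES = (
    "coding_promoter",
    "pseudogene_promoter",
    "enhancer",
    "ncRNA_site",
    "inactive",
)

#: default temporal archetypes over the 11 stages (6 development + 5 ageing):
#: early-development, late-development, mid-development peak, ageing-rising.
_ARCHETYPES = np.array(
    [
        [1.6, 1.3, 1.0, 0.7, 0.5, 0.4, 0.4, 0.4, 0.3, 0.3, 0.3],
        [0.3, 0.4, 0.6, 0.9, 1.2, 1.6, 1.4, 1.2, 1.0, 0.9, 0.8],
        [0.4, 0.9, 1.6, 1.5, 0.8, 0.4, 0.5, 0.5, 0.5, 0.5, 0.5],
        [0.6, 0.6, 0.6, 0.6, 0.6, 0.6, 0.4, 0.6, 0.9, 1.3, 1.6],
    ]
)


def archetype_profiles(n_profiles: int = 4) -> np.ndarray:
    """The first ``n_profiles`` stage-profile archetypes (rows sum over 11 stages)."""
    if not 1 <= n_profiles <= len(_ARCHETYPES):
        raise ValueError(f"n_profiles must be in 1..{len(_ARCHETYPES)}")
    return _ARCHETYPES[:n_profiles].copy()


@dataclass
class PlantedElement:
    """Ground-truth regulatory element."""

    element_id: str
    true_class: str
    chrom: str
    center: int
    strand_active: dict[str, bool] = field(default_factory=lambda: {"+": True, "-": True})
    target_gene_id: str | None = None
    stage_profile: np.ndarray = field(default_factory=lambda: np.zeros(len(STAGES)))
    true_cluster: int | None = None

    def __post_init__(self) -> None:
        self.stage_profile = np.asarray(self.stage_profile, dtype=float)
        if self.true_class not in ELEMENT_CLASSES:
            raise ValueError(f"unknown class {self.true_class!r}")
        if self.stage_profile.shape != (len(STAGES),):
            raise ValueError("stage_profile must have one entry per stage")
        if np.any(self.stage_profile < 0):
            raise ValueError("stage_profile multipliers must be >= 0")
        if self.true_class == "coding_promoter" and self.target_gene_id is None:
            raise ValueError("coding_promoter elements need a target gene")


def plant_elements(
    genome: GenomeModel,
    class_counts: dict[str, int],
    seed: int,
    *,
    n_profiles: int = 4,
    min_separation: int = 600,
    exon5p_clearance: int = 251,
) -> list[PlantedElement]:
    """Place elements of the requested classes on the genome.

    Coding/pseudogene promoters sit at gene outron starts (distal case) or
    first-exon 5' ends; ncRNA sites at ncRNA gene 5' ends; enhancers in
    intergenic space or large introns, clear of all exon 5' ends; inactive
    elements in intergenic space with an all-zero profile.

    Raises ``ValueError`` when placement is infeasible.
    """
    unknown = set(class_counts) - set(ELEMENT_CLASSES)
    if unknown:
        raise ValueError(f"unknown element classes: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    profiles = archetype_profiles(n_profiles)
    chrom = genome.chromosomes[0][0]
    genes = [g for g in genome.genes if g.chrom == chrom]

    elements: list[PlantedElement] = []
    used_centers: list[int] = []

    def far_enough(pos: int) -> bool:
        return all(abs(pos - c) >= min_separation for c in used_centers)

    def add(true_class, center, strand_active, gene_id, profile_idx):
        if profile_idx is None:
            profile = np.zeros(len(STAGES))
        else:
            profile = profiles[profile_idx].copy()
        elements.append(
            PlantedElement(
                element_id=f"el_{len(elements):04d}",
                true_class=true_class,
                chrom=chrom,
                center=int(center),
                strand_active=strand_active,
                target_gene_id=gene_id,
                stage_profile=profile,
                true_cluster=profile_idx,
            )
        )
        used_centers.append(int(center))

    # --- promoters at gene 5' geometry -------------------------------------
    for cls, biotype in (
        ("coding_promoter", "protein_coding"),
        ("pseudogene_promoter", "pseudogene"),
    ):
        want = class_counts.get(cls, 0)
        pool = [g for g in genes if g.biotype == biotype]
        rng.shuffle(pool)
        placed = 0
        for g in pool:
            if placed >= want:
                break
            center = g.outron_start if g.outron_start is not None else g.tss
            if not far_enough(center):
                continue
            add(
                cls,
                center,
                {"+": g.strand == "+", "-": g.strand == "-"},
                g.gene_id,
                int(rng.integers(len(profiles))),
            )
            placed += 1
        if placed < want:
            raise ValueError(
                f"cannot place {want} {cls} elements: only {placed} eligible genes"
            )

    # --- ncRNA sites --------------------------------------------------------
    want = class_counts.get("ncRNA_site", 0)
    pool = [g for g in genes if g.biotype in NCRNA_BIOTYPES]
    rng.shuffle(pool)
    placed = 0
    for g in pool:
        if placed >= want:
            break
        if not far_enough(g.tss):
            continue
        add(
            "ncRNA_site",
            g.tss,
            {"+": g.strand == "+", "-": g.strand == "-"},
            None,
            int(rng.integers(len(profiles))),
        )
        placed += 1
    if placed < want:
        raise ValueError(f"cannot place {want} ncRNA_site elements")

    # --- enhancers and inactive elements in open space ----------------------
    exon5p = np.sort(
        np.array(
            [p for g in genes for p in g.first_exon_5p + g.nonfirst_exon_5p],
            dtype=int,
        )
    )
    gene_bounds = [(g.start, g.end) for g in genes]

    def clear_of_exon5p(pos: int) -> bool:
        i = np.searchsorted(exon5p, pos)
        for j in (i - 1, i):
            if 0 <= j < exon5p.size and abs(int(exon5p[j]) - pos) <= exon5p_clearance:
                return False
        return True

    def intergenic(pos: int) -> bool:
        return not any(s - 300 <= pos < e + 300 for s, e in gene_bounds)

    chrom_len = genome.chromosomes[0][1]
    for cls in ("enhancer", "inactive"):
        want = class_counts.get(cls, 0)
        placed = 0
        attempts = 0
        max_attempts = 2000 * max(want, 1)
        while placed < want:
            attempts += 1
            if attempts > max_attempts:
                raise ValueError(f"cannot place {want} {cls} elements")
            pos = int(rng.integers(500, chrom_len - 500))
            if not (far_enough(pos) and clear_of_exon5p(pos) and intergenic(pos)):
                continue
            profile_idx = int(rng.integers(len(profiles))) if cls == "enhancer" else None
            add(cls, pos, {"+": True, "-": True}, None, profile_idx)
            placed += 1

    return elements
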