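"""Simulate a toy annotated genome.

Genes are placed left to right with randomized gaps, so they never
overlap.  A configurable fraction of protein-coding genes is trans-spliced:
their transcription unit starts at an outron 200-1500 bp upstream of the
first exon.  Small non-coding genes (one of each supported biotype) and a
few pseudogenes are included when the gene count permits.
"""

from __future__ import annotations

import numpy as np

from regmap.genome import Gene, GenomeModel

NCRNA_ORDER = ("tRNA", "snRNA", "snoRNA", "rRNA", "miRNA")


def simulate_genome(
    n_genes: int,
    chrom_length: int,
    seed: int,
    *,
    chrom_name: str = "chrI",
    min_gap: int = 2000,
    max_gap: int = 4000,
    outron_fraction: float = 0.7,
    utr_fraction: float = 0.5,
    pseudogene_fraction: float = 0.05,
) -> GenomeModel:
    """Place ``n_genes`` non-overlapping genes on one chromosome.

    Raises ``ValueError`` if the genes cannot be placed within
    ``chrom_length`` at the configured spacing.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)

    # decide biotypes; ncRNAs and pseudogenes only for reasonably big genomes
    biotypes = ["protein_coding"] * n_genes
    if n_genes >= 12:
        for i, bt in enumerate(NCRNA_ORDER):
            biotypes[i] = bt
        n_pseudo = max(1, int(round(pseudogene_fraction * n_genes)))
        for i in range(len(NCRNA_ORDER), len(NCRNA_ORDER) + n_pseudo):
            biotypes[i] = "pseudogene"
    order = rng.permutation(n_genes)
    biotypes = [biotypes[i] for i in order]

    genes: list[Gene] = []
    cursor = int(rng.integers(min_gap, max_gap))
    for i, biotype in enumerate(biotypes):
        strand = "+" if rng.random() < 0.5 else "-"
        if biotype in NCRNA_ORDER:
            unit = _build_ncrna(rng, cursor, strand, biotype, i, chrom_name)
        else:
            has_outron = biotype == "protein_coding" and rng.random() < outron_fraction
            has_utr = rng.random() < utr_fraction
            unit = _build_coding(
                rng, cursor, strand, biotype, i, has_outron, has_utr, chrom_name
            )
        genes.append(unit)
        cursor = unit.end + int(rng.integers(min_gap, max_gap))
        if unit.end > chrom_length:
            raise ValueError(
                f"cannot place {n_genes} genes in {chrom_length} bp at the "
                f"configured spacing (ran out at gene {i})"
            )
    model = GenomeModel(chromosomes=[(chrom_name, int(chrom_length))], genes=genes)
    model.validate()
    return model


def _build_coding(
    rng: np.random.Generator,
    start: int,
    strand: str,
    biotype: str,
    idx: int,
    has_outron: bool,
    has_utr: bool,
    chrom_name: str,
) -> Gene:
    """Three-exon gene, optional outron and 5' UTR, laid out left to right
    then mirrored for the minus strand."""
    outron_len = int(rng.integers(300, 1500)) if has_outron else 0
    exon_lens = rng.integers(300, 700, size=3)
    intron_lens = rng.integers(700, 1200, size=2)
    utr_len = int(rng.integers(50, 150)) if has_utr else 0

    # strand-agnostic layout coordinates (left to right), flipped below for '-'
    pos = start + outron_len
    exons: list[tuple[int, int]] = []
    for j in range(3):
        exons.append((pos, pos + int(exon_lens[j])))
        pos += int(exon_lens[j])
        if j < 2:
            pos += int(intron_lens[j])
    end = pos

    if strand == "+":
        first5 = exons[0][0]
        nonfirst5 = [e[0] for e in exons[1:]]
        utr5 = (first5, first5 + utr_len) if has_utr else None
        outron_start = start if has_outron else None
        span = (start, end)
    else:
        # mirror the layout so the outron sits on the right; the mirrored
        # image of the original leftmost exon is the (rightmost) first exon
        span = (start, end)
        exons = [(start + (end - e), start + (end - s)) for s, e in exons]
        first5 = exons[0][1] - 1
        nonfirst5 = [e[1] - 1 for e in exons[1:]]
        utr5 = (first5 - utr_len + 1, first5 + 1) if has_utr else None
        outron_start = end - 1 if has_outron else None
    return Gene(
        gene_id=f"gene_{idx:04d}",
        locus_id=f"locus_{idx:04d}",
        chrom=chrom_name,
        biotype=biotype,
        strand=strand,
        start=span[0],
        end=span[1],
        first_exon_5p=[first5],
        nonfirst_exon_5p=nonfirst5,
        exons=sorted(exons),
        utr5=utr5,
        outron_start=outron_start,
    )


def _build_ncrna(
    rng: np.random.Generator,
    start: int,
    strand: str,
    biotype: str,
    idx: int,
    chrom_name: str,
) -> Gene:
    length = int(rng.integers(80, 300))
    end = start + length
    first5 = start if strand == "+" else end - 1
    return Gene(
        gene_id=f"gene_{idx:04d}",
        locus_id=f"locus_{idx:04d}",
        chrom=chrom_name,
        biotype=biotype,
        strand=strand,
        start=start,
        end=end,
        first_exon_5p=[first5],
        nonfirst_exon_5p=[],
        exons=[(start, end)],
        utr5=None,
        outron_start=None,
    )
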