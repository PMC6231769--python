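"""Genome annotation model: chromosomes, genes, exon geometry.

All coordinates are 0-based half-open.  Strand-relative helpers return
positions such that "downstream" means increasing coordinate on ``+`` and
decreasing coordinate on ``-``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

NCRNA_BIOTYPES = frozenset({"tRNA", "snRNA", "snoRNA", "rRNA", "miRNA"})
BIOTYPES = frozenset({"protein_coding", "pseudogene"}) | NCRNA_BIOTYPES


@dataclass
class Gene:
    """One gene with transcript-level 5' geometry.

    ``start``/``end`` span the full transcribed unit including the outron
    when one is annotated.  ``first_exon_5p`` holds the 5' ends of
    annotated first exons (one per transcript isoform), ``nonfirst_exon_5p``
    the 5' ends of all downstream exons.
    """

    gene_id: str
    locus_id: str
    chrom: str
    biotype: str
    strand: str
    start: int
    end: int
    first_exon_5p: list[int] = field(default_factory=list)
    nonfirst_exon_5p: list[int] = field(default_factory=list)
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: tuple[int, int] | None = None
    outron_start: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"bad biotype {self.biotype!r} for {self.gene_id}")
        if not self.start < self.end:
            raise ValueError(f"empty span for {self.gene_id}")

    @property
    def tss(self) -> int:
        """Primary first-exon 5' end (the most upstream one, strand-relative)."""
        if not self.first_exon_5p:
            raise ValueError(f"{self.gene_id} has no first exon")
        return min(self.first_exon_5p) if self.strand == "+" else max(self.first_exon_5p)

    @property
    def gene_end_3p(self) -> int:
        """Strand-relative 3' terminus of the gene span."""
        return self.end - 1 if self.strand == "+" else self.start

    def downstream_of(self, pos: int, ref: int) -> bool:
        """True if ``pos`` is strictly downstream of ``ref`` on this strand."""
        return pos > ref if self.strand == "+" else pos < ref


@dataclass
class GenomeModel:
    """Chromosome sizes plus a gene list; the coordinate frame for everything."""

    chromosomes: list[tuple[str, int]]
    genes: list[Gene]

    def chrom_length(self, name: str) -> int:
        for cname, length in self.chromosomes:
            if cname == name:
                return length
        raise KeyError(name)

    def validate(self) -> None:
        """Check interval bounds and outron geometry; raise on violation."""
        sizes = dict(self.chromosomes)
        for g in self.genes:
            n = sizes.get(g.chrom)
            if n is None:
                raise ValueError(f"{g.gene_id}: unknown chromosome {g.chrom}")
            if not (0 <= g.start < g.end <= n):
                raise ValueError(f"{g.gene_id}: span outside chromosome bounds")
            for p in g.first_exon_5p:
                if not (g.start <= p < g.end):
                    raise ValueError(f"{g.gene_id}: first-exon 5' end outside span")
            for s, e in g.exons:
                if not (0 <= s < e <= n):
                    raise ValueError(f"{g.gene_id}: exon outside chromosome")
            if g.outron_start is not None:
                if not g.downstream_of(g.tss, g.outron_start):
                    raise ValueError(
                        f"{g.gene_id}: outron start not upstream of first exon"
                    )

    # ------------------------------------------------------------------
    # tabular round-trip

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.genes:
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "locus_id": g.locus_id,
                    "chrom": g.chrom,
                    "biotype": g.biotype,
                    "strand": g.strand,
                    "start": g.start,
                    "end": g.end,
                    "first_exon_5p": ",".join(map(str, g.first_exon_5p)),
                    "nonfirst_exon_5p": ",".join(map(str, g.nonfirst_exon_5p)),
                    "exons": ",".join(f"{s}-{e}" for s, e in g.exons),
                    "utr5": "" if g.utr5 is None else f"{g.utr5[0]}-{g.utr5[1]}",
                    "outron_start": "" if g.outron_start is None else str(g.outron_start),
                }
            )
        return pd.DataFrame(rows)

    def write_table(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self.chromosomes:
                fh.write(f"#chromosome\t{name}\t{length}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_table(cls, path) -> "GenomeModel":
        chroms: list[tuple[str, int]] = []
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#chromosome\t"):
                _, name, length = line.rstrip("\n").split("\t")
                chroms.append((name, int(length)))
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
        genes = []
        for _, r in df.iterrows():
            genes.append(
                Gene(
                    gene_id=r["gene_id"],
                    locus_id=r["locus_id"],
                    chrom=r["chrom"],
                    biotype=r["biotype"],
                    strand=r["strand"],
                    start=int(r["start"]),
                    end=int(r["end"]),
                    first_exon_5p=[int(x) for x in r["first_exon_5p"].split(",") if x],
                    nonfirst_exon_5p=[
                        int(x) for x in r["nonfirst_exon_5p"].split(",") if x
                    ],
                    exons=[
                        tuple(map(int, x.split("-")))
                        for x in r["exons"].split(",")
                        if x
                    ],
                    utr5=(
                        tuple(map(int, r["utr5"].split("-"))) if r["utr5"] else None
                    ),
                    outron_start=(
                        int(r["outron_start"]) if r["outron_start"] else None
                    ),
                )
            )
        model = cls(chromosomes=chroms, genes=genes)
        model.validate()
        return model
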