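"""Element taxonomy from per-strand transcription evidence and gene geometry.

Per strand, each site receives one of six labels ranked from highest to
lowest priority: coding_promoter, pseudogene_promoter, non-coding_RNA,
unassigned_promoter, transcription_initiation, no_transcription.  Labels
are aggregated across stages by taking the highest-priority one, the two
strand labels are combined into the final element type, and promoters are
linked to genes through the closest-first-exon search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from regmap.genome import NCRNA_BIOTYPES, Gene, GenomeModel

LABELS = (
    "coding_promoter",
    "pseudogene_promoter",
    "non-coding_RNA",
    "unassigned_promoter",
    "transcription_initiation",
    "no_transcription",
)
LABEL_RANK = {name: i for i, name in enumerate(LABELS)}

FINAL_TYPES = (
    "coding_promoter",
    "pseudogene_promoter",
    "non-coding_RNA",
    "unassigned_promoter",
    "putative_enhancer",
    "other_element",
)

EXON_DISTANCE = 250
RESCUE_MIN_LFC = 1.0

_PROMOTER_BIOTYPES = ("protein_coding", "pseudogene")


@dataclass
class ClassifyConfig:
    exon_distance: int = EXON_DISTANCE
    rescue_min_lfc: float = RESCUE_MIN_LFC
    continuity_min_cov: int = 1


@dataclass
class StrandCall:
    """Scratch record for one site x strand during classification."""

    label: str = "no_transcription"
    gene_id: str | None = None
    low_confidence: bool = False
    geometry_pass: bool = False      # criteria 2-4 w.r.t. the closest first exon
    closest_gene: Gene | None = None
    closest_fe: int | None = None
    crit1_stages: list[str] = field(default_factory=list)
    max_jump_lfc: float = -np.inf
    tss: int | None = None
    tss_provenance: str = "best_guess"


def closest_first_exon(
    summit: int,
    strand: str,
    chrom: str,
    genome: GenomeModel,
    exon_distance: int = EXON_DISTANCE,
) -> tuple[Gene, int] | None:
    """Closest eligible same-strand first exon (gene, 5' end position).

    Eligible first-exon 5' ends lie at most ``exon_distance`` bp upstream
    (strand-relative) of the summit, or anywhere downstream; the closest by
    absolute distance wins, ties to the smaller coordinate.
    """
    sign = 1 if strand == "+" else -1
    best: tuple[int, int, Gene] | None = None
    for g in genome.genes:
        if g.chrom != chrom or g.strand != strand:
            continue
        if g.biotype not in _PROMOTER_BIOTYPES:
            continue
        for p in g.first_exon_5p:
            offset = (p - summit) * sign  # >0 means the exon is downstream
            if offset < -exon_distance:
                continue
            key = (abs(p - summit), p)
            if best is None or key < (best[0], best[1]):
                best = (key[0], key[1], g)
    if best is None:
        return None
    return best[2], best[1]


def _intergenic(summit: int, chrom: str, genome: GenomeModel) -> bool:
    return not any(
        g.chrom == chrom and g.start <= summit < g.end for g in genome.genes
    )


def _near_exon(summit: int, chrom: str, genome: GenomeModel, dist: int) -> bool:
    """True if the summit is within ``dist`` bp of any annotated exon interval."""
    for g in genome.genes:
        if g.chrom != chrom:
            continue
        for s, e in g.exons:
            if s - dist <= summit < e + dist:
                return True
    return False


def _near_ncrna(summit: int, chrom: str, genome: GenomeModel, dist: int) -> bool:
    for g in genome.genes:
        if g.chrom == chrom and g.biotype in NCRNA_BIOTYPES:
            if abs(g.tss - summit) <= dist:
                return True
    return False


def promoter_criteria(
    summit: int,
    strand: str,
    chrom: str,
    evidence: dict,
    genome: GenomeModel,
    coverage_by_stage: dict[str, np.ndarray],
    config: ClassifyConfig = ClassifyConfig(),
) -> StrandCall:
    """Evaluate promoter criteria 1-4 for one site x strand.

    ``evidence`` holds ``initiation`` (InitiationCall), ``jump`` and ``incr``
    (stage-keyed results).  ``coverage_by_stage`` maps stage -> long-cap
    coverage on this strand (replicate maximum), used for the distal-site
    continuity requirement.
    """
    call = StrandCall()
    init = evidence["initiation"]
    call.tss = init.mode
    call.tss_provenance = init.mode_provenance
    jumps = evidence["jump"]
    incrs = evidence["incr"]
    call.crit1_stages = [
        s
        for s in jumps
        if (init.passed and (jumps[s].passed or incrs[s].passed))
        or (jumps[s].passed and incrs[s].passed)
    ]
    finite = [jumps[s].lfc for s in jumps]
    call.max_jump_lfc = max(finite) if finite else -np.inf

    found = closest_first_exon(summit, strand, chrom, genome, config.exon_distance)
    if found is None:
        return call
    gene, fe = found
    call.closest_gene, call.closest_fe = gene, fe
    sign = 1 if strand == "+" else -1

    # criterion 2: initiation mode upstream of the first exon, or inside an
    # annotated 5' UTR at most 250 bp downstream of it
    mode = init.mode
    mode_offset = (mode - fe) * sign
    crit2 = mode_offset < 0
    if not crit2 and gene.utr5 is not None:
        in_utr = gene.utr5[0] <= mode < gene.utr5[1]
        crit2 = in_utr and mode_offset <= config.exon_distance

    # criterion 3: no non-first exon 5' end strictly between summit and exon
    lo, hi = min(summit, fe), max(summit, fe)
    crit3 = not any(
        g.chrom == chrom
        and g.strand == strand
        and any(lo < q < hi for q in g.nonfirst_exon_5p)
        for g in genome.genes
    )

    # criterion 4 for distal sites only
    crit4 = True
    if abs(fe - summit) > config.exon_distance:
        span_from = summit + sign * config.exon_distance
        lo4, hi4 = min(span_from, fe), max(span_from, fe) + 1
        lo4 = max(0, lo4)
        cov_ok = False
        if call.crit1_stages:
            # a bp is covered if any criterion-1-passing stage reaches it
            best = None
            for stage in call.crit1_stages:
                seg = coverage_by_stage[stage][lo4:hi4]
                best = seg if best is None else np.maximum(best, seg)
            cov_ok = best.size > 0 and int(best.min()) >= config.continuity_min_cov
        near_nonfirst = any(
            g.chrom == chrom
            and g.strand == strand
            and any(abs(q - summit) <= config.exon_distance for q in g.nonfirst_exon_5p)
            for g in genome.genes
        )
        crit4 = cov_ok and not near_nonfirst

    call.geometry_pass = crit2 and crit3 and crit4
    if call.crit1_stages and call.geometry_pass:
        call.label = (
            "coding_promoter"
            if gene.biotype == "protein_coding"
            else "pseudogene_promoter"
        )
        call.gene_id = gene.gene_id
    return call


def strand_label(
    summit: int,
    strand: str,
    chrom: str,
    call: StrandCall,
    evidence: dict,
    genome: GenomeModel,
    config: ClassifyConfig = ClassifyConfig(),
) -> str:
    """Apply the non-promoter precedence rules to an undecided strand call."""
    if call.label in ("coding_promoter", "pseudogene_promoter"):
        return call.label
    init = evidence["initiation"]
    if _near_ncrna(summit, chrom, genome, config.exon_distance):
        return "non-coding_RNA"
    any_jump = any(j.passed for j in evidence["jump"].values())
    if (
        _intergenic(summit, chrom, genome)
        and not _near_exon(summit, chrom, genome, config.exon_distance)
        and init.passed
        and any_jump
    ):
        return "unassigned_promoter"
    return "transcription_initiation" if init.passed else "no_transcription"


def aggregate_labels(labels: list[str]) -> str:
    """Highest-priority (minimum-rank) label."""
    if not labels:
        return "no_transcription"
    return min(labels, key=lambda l: LABEL_RANK[l])


def combine_strands(fwd: str, rev: str) -> str:
    """Final element type from the two aggregated strand labels."""
    top = aggregate_labels([fwd, rev])
    if top == "transcription_initiation":
        return "putative_enhancer"
    if top == "no_transcription":
        return "other_element"
    return top


def rescue_low_confidence(
    calls: dict[tuple[int, str], StrandCall],
    sites: pd.DataFrame,
    config: ClassifyConfig = ClassifyConfig(),
    genome: GenomeModel | None = None,
) -> None:
    """Assign one low-confidence promoter to genes still lacking one.

    Eligible sites fulfilled criteria 2-4 for the gene and are either
    intergenic or within 250 bp of the closest first exon; the site with
    the largest jump-test log2 fold change is assigned if that is > 1.
    Existing assignments are never demoted.
    """
    assigned_genes = {
        c.gene_id for c in calls.values() if c.gene_id is not None
    }
    candidates: dict[str, list[tuple]] = {}
    for (i, strand), call in calls.items():
        if call.label in ("coding_promoter", "pseudogene_promoter"):
            continue
        if not call.geometry_pass or call.closest_gene is None:
            continue
        g = call.closest_gene
        if g.gene_id in assigned_genes:
            continue
        summit = int(sites.iloc[i]["summit"])
        chrom = sites.iloc[i]["chrom"]
        proximal = abs(call.closest_fe - summit) <= config.exon_distance
        if not proximal and genome is not None:
            if not _intergenic(summit, chrom, genome):
                continue
        candidates.setdefault(g.gene_id, []).append(
            (
                -call.max_jump_lfc,
                abs(call.closest_fe - summit),
                summit,
                (i, strand),
                call,
                g,
            )
        )
    for gene_id, cands in candidates.items():
        cands.sort(key=lambda t: t[:3])
        neg_lfc, _, _, key, call, g = cands[0]
        if -neg_lfc > config.rescue_min_lfc:
            call.label = (
                "coding_promoter"
                if g.biotype == "protein_coding"
                else "pseudogene_promoter"
            )
            call.gene_id = gene_id
            call.low_confidence = True


def classify_sites(
    sites: pd.DataFrame,
    evidence: dict[tuple[int, str], dict],
    genome: GenomeModel,
    lcap_coverage: dict[tuple[str, str], np.ndarray],
    config: ClassifyConfig = ClassifyConfig(),
    stages: list[str] | None = None,
) -> pd.DataFrame:
    """Full classification of a site table.

    ``lcap_coverage`` maps (stage, strand) -> replicate-max long-cap
    coverage for the chromosome of the sites.  Returns the annotation table
    with per-strand labels, the final type, gene links, directionality and
    low-confidence flags.
    """
    calls: dict[tuple[int, str], StrandCall] = {}
    for i, site in sites.iterrows():
        summit, chrom = int(site["summit"]), site["chrom"]
        for strand in ("+", "-"):
            ev = evidence[(i, strand)]
            cov = {
                stage: lcap_coverage[(stage, strand)]
                for stage in ev["jump"]
            }
            call = promoter_criteria(summit, strand, chrom, ev, genome, cov, config)
            call.label = strand_label(summit, strand, chrom, call, ev, genome, config)
            calls[(i, strand)] = call

    rescue_low_confidence(calls, sites, config, genome)

    rows = []
    for i, site in sites.iterrows():
        fwd, rev = calls[(i, "+")], calls[(i, "-")]
        final = combine_strands(fwd.label, rev.label)
        directionality = "not_promoter"
        if final == "coding_promoter":
            both = (
                fwd.label == "coding_promoter"
                and rev.label == "coding_promoter"
                and fwd.gene_id is not None
                and rev.gene_id is not None
                and fwd.gene_id != rev.gene_id
            )
            directionality = "divergent" if both else "unidirectional"
        rows.append(
            {
                "chrom": site["chrom"],
                "start": site["start"],
                "end": site["end"],
                "summit": site["summit"],
                "annot": final,
                "annot_fwd": fwd.label,
                "annot_rev": rev.label,
                "promoter_gene_id_fwd": fwd.gene_id or "",
                "promoter_gene_id_rev": rev.gene_id or "",
                "tss_fwd": fwd.tss,
                "tss_rev": rev.tss,
                "tss_fwd_provenance": fwd.tss_provenance,
                "tss_rev_provenance": rev.tss_provenance,
                "directionality": directionality,
                "low_confidence": fwd.low_confidence or rev.low_confidence,
            }
        )
    annot = pd.DataFrame(rows)
    annot["associated_gene_id"] = assign_genes(annot, genome)
    return annot


def assign_genes(annot: pd.DataFrame, genome: GenomeModel) -> pd.Series:
    """Overlap-based gene association for non-promoter-linked elements.

    Enhancers are associated with genes whose span from the most upstream
    promoter to the gene end overlaps the element; unassigned promoters and
    other elements with genes whose body/outron span overlaps the element.
    Promoter elements carry their criteria-derived genes and get no overlap
    association here.
    """
    # most upstream promoter summit per gene (strand-relative)
    upstream_prom: dict[str, int] = {}
    for _, row in annot.iterrows():
        for strand_key in ("fwd", "rev"):
            gid = row[f"promoter_gene_id_{strand_key}"]
            if not gid:
                continue
            s = int(row["summit"])
            cur = upstream_prom.get(gid)
            gene = next(g for g in genome.genes if g.gene_id == gid)
            better = cur is None or (
                s < cur if gene.strand == "+" else s > cur
            )
            if better:
                upstream_prom[gid] = s

    out = []
    for _, row in annot.iterrows():
        kind = row["annot"]
        start, end, chrom = int(row["start"]), int(row["end"]), row["chrom"]
        hits: list[str] = []
        if kind == "putative_enhancer":
            for g in genome.genes:
                if g.chrom != chrom or g.gene_id not in upstream_prom:
                    continue
                p = upstream_prom[g.gene_id]
                if g.strand == "+":
                    lo, hi = min(p, g.start), g.end
                else:
                    lo, hi = g.start, max(p + 1, g.end)
                if lo < end and start < hi:
                    hits.append(g.gene_id)
        elif kind in ("unassigned_promoter", "other_element"):
            for g in genome.genes:
                if g.chrom == chrom and g.start < end and start < g.end:
                    hits.append(g.gene_id)
        out.append(",".join(sorted(set(hits))))
    return pd.Series(out, index=annot.index)


def per_gene_counts(annot: pd.DataFrame) -> pd.DataFrame:
    """Per-gene promoter and assigned-enhancer counts."""
    prom: dict[str, int] = {}
    enh: dict[str, int] = {}
    for _, row in annot.iterrows():
        for key in ("fwd", "rev"):
            gid = row[f"promoter_gene_id_{key}"]
            if gid:
                prom[gid] = prom.get(gid, 0) + 1
        if row["annot"] == "putative_enhancer" and row["associated_gene_id"]:
            for gid in row["associated_gene_id"].split(","):
                enh[gid] = enh.get(gid, 0) + 1
    genes = sorted(set(prom) | set(enh))
    return pd.DataFrame(
        {
            "gene_id": genes,
            "n_promoters": [prom.get(g, 0) for g in genes],
            "n_enhancers": [enh.get(g, 0) for g in genes],
        }
    )
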