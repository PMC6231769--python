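import numpy as np
import pandas as pd
import pytest

from regmap.classify import (
    ClassifyConfig,
    StrandCall,
    aggregate_labels,
    assign_genes,
    closest_first_exon,
    combine_strands,
    per_gene_counts,
    promoter_criteria,
    rescue_low_confidence,
    strand_label,
)
from regmap.genome import Gene, GenomeModel
from regmap.transcription import IncrResult, InitiationCall, JumpResult

STAGES2 = ["s1", "s2"]


def toy_genome() -> GenomeModel:
    genes = [
        Gene(  # trans-spliced plus-strand gene with UTR
            "gA", "lA", "chrI", "protein_coding", "+",
            4000, 7400,
            first_exon_5p=[5000, 5100],
            nonfirst_exon_5p=[6000, 7000],
            exons=[(5000, 5400), (6000, 6400), (7000, 7400)],
            utr5=(5000, 5100),
            outron_start=4000,
        ),
        Gene("gB", "lB", "chrI", "tRNA", "+", 9000, 9100,
             first_exon_5p=[9000], exons=[(9000, 9100)]),
        Gene(  # minus-strand gene, outron on the right
            "gC", "lC", "chrI", "protein_coding", "-",
            11000, 13500,
            first_exon_5p=[12399],
            nonfirst_exon_5p=[11399],
            exons=[(11000, 11400), (12000, 12400)],
            outron_start=13499,
        ),
        Gene("gD", "lD", "chrI", "protein_coding", "+", 16000, 17400,
             first_exon_5p=[16000], nonfirst_exon_5p=[17000],
             exons=[(16000, 16400), (17000, 17400)], utr5=(16000, 16100)),
        Gene("gE", "lE", "chrI", "protein_coding", "+", 18000, 19000,
             first_exon_5p=[18000], nonfirst_exon_5p=[18800],
             exons=[(18000, 18200), (18800, 19000)]),
    ]
    model = GenomeModel([("chrI", 20000)], genes)
    model.validate()
    return model


def make_evidence(
    init_passed=True,
    mode=0,
    jump_stages=(),
    incr_stages=(),
    lfc=3.0,
):
    jumps, incrs = {}, {}
    for s in STAGES2:
        if s in jump_stages:
            jumps[s] = JumpResult((0, 0), (9, 9), lfc, 1e-4, 1e-3)
        else:
            jumps[s] = JumpResult((0, 0), (0, 0), 0.0, 1.0, 1.0)
        incrs[s] = IncrResult((0, 0), (2, 1) if s in incr_stages else (0, 0))
    init = InitiationCall(init_passed, mode, "observed" if init_passed else "best_guess")
    return {"initiation": init, "jump": jumps, "incr": incrs}


def flat_coverage(value=1, length=20000):
    return {s: np.full(length, value, dtype=int) for s in STAGES2}


class TestClosestFirstExon:
    def test_downstream_exon_returned(self):
        g = toy_genome()
        gene, fe = closest_first_exon(4900, "+", "chrI", g)
        assert gene.gene_id == "gA" and fe == 5000

    def test_far_upstream_only_absent(self):
        g = toy_genome()
        assert closest_first_exon(19500, "+", "chrI", g) is None

    def test_closest_of_two_isoforms(self):
        g = toy_genome()
        gene, fe = closest_first_exon(4950, "+", "chrI", g)
        assert fe == 5000  # 50 bp beats 150 bp

    def test_250_upstream_boundary(self):
        g = toy_genome()
        gene, fe = closest_first_exon(5250, "+", "chrI", g)
        assert fe == 5100  # 150 bp upstream still eligible
        # 300 bp upstream of the only nearby exon: next eligible is gD
        gene, fe = closest_first_exon(5400, "+", "chrI", g)
        assert fe == 16000

    def test_minus_strand(self):
        g = toy_genome()
        gene, fe = closest_first_exon(12500, "-", "chrI", g)
        assert gene.gene_id == "gC" and fe == 12399


class TestPromoterCriteria:
    def test_proximal_promoter_passes(self):
        g = toy_genome()
        ev = make_evidence(init_passed=True, mode=4990, jump_stages=("s1",))
        call = promoter_criteria(5000, "+", "chrI", ev, g, flat_coverage())
        assert call.label == "coding_promoter" and call.gene_id == "gA"

    def test_criterion1_requires_both_without_initiation(self):
        g = toy_genome()
        ev = make_evidence(init_passed=False, mode=5060, jump_stages=("s1",))
        call = promoter_criteria(5000, "+", "chrI", ev, g, flat_coverage())
        assert call.label != "coding_promoter"
        ev = make_evidence(
            init_passed=False, mode=5060, jump_stages=("s1",), incr_stages=("s1",)
        )
        call = promoter_criteria(5000, "+", "chrI", ev, g, flat_coverage())
        assert call.label == "coding_promoter"

    def test_criterion2_utr_window(self):
        g = toy_genome()
        # mode inside the UTR, downstream of the first exon: allowed
        ev = make_evidence(mode=5050, jump_stages=("s1",))
        assert (
            promoter_criteria(5000, "+", "chrI", ev, g, flat_coverage()).label
            == "coding_promoter"
        )
        # mode downstream past the UTR: rejected
        ev = make_evidence(mode=5150, jump_stages=("s1",))
        assert (
            promoter_criteria(5000, "+", "chrI", ev, g, flat_coverage()).label
            != "coding_promoter"
        )

    def test_criterion3_intervening_nonfirst_exon(self):
        g = toy_genome()
        # summit 16900: closest eligible first exon is gE at 18000, but
        # gD's non-first exon 5' end (17000) lies in between
        ev = make_evidence(mode=16890, jump_stages=("s1",))
        call = promoter_criteria(16900, "+", "chrI", ev, g, flat_coverage())
        assert not call.geometry_pass

    def test_criterion4a_coverage_gap(self):
        g = toy_genome()
        ev = make_evidence(mode=4010, jump_stages=("s1",))
        call = promoter_criteria(4000, "+", "chrI", ev, g, flat_coverage())
        assert call.label == "coding_promoter"  # continuous coverage
        gapped = flat_coverage()
        for s in STAGES2:
            gapped[s][4600] = 0  # 1-bp gap in the outron span
        call = promoter_criteria(4000, "+", "chrI", ev, g, gapped)
        assert call.label != "coding_promoter"

    def test_distal_minus_strand_promoter(self):
        g = toy_genome()
        ev = make_evidence(mode=13490, jump_stages=("s1",))
        call = promoter_criteria(13499, "-", "chrI", ev, g, flat_coverage())
        assert call.label == "coding_promoter" and call.gene_id == "gC"


class TestStrandLabel:
    def test_ncrna_proximity(self):
        g = toy_genome()
        ev = make_evidence(init_passed=False, mode=9160)
        call = StrandCall()
        assert strand_label(9100, "+", "chrI", call, ev, g) == "non-coding_RNA"

    def test_unassigned_promoter(self):
        g = toy_genome()
        ev = make_evidence(init_passed=True, mode=14510, jump_stages=("s1",))
        call = StrandCall()
        assert strand_label(14500, "+", "chrI", call, ev, g) == "unassigned_promoter"

    def test_initiation_inside_gene_body(self):
        g = toy_genome()
        ev = make_evidence(init_passed=True, mode=6610)
        call = StrandCall()
        assert strand_label(6600, "+", "chrI", call, ev, g) == "transcription_initiation"

    def test_no_transcription(self):
        g = toy_genome()
        ev = make_evidence(init_passed=False, mode=14560)
        call = StrandCall()
        # intergenic and far from exons, but no initiation at all
        assert strand_label(14500, "+", "chrI", call, ev, g) == "no_transcription"


class TestAggregationAndCombination:
    def test_aggregate_ranking(self):
        labels = ["no_transcription"] * 10 + ["coding_promoter"]
        assert aggregate_labels(labels) == "coding_promoter"
        assert aggregate_labels(["no_transcription"] * 3) == "no_transcription"
        assert (
            aggregate_labels(["transcription_initiation", "unassigned_promoter"])
            == "unassigned_promoter"
        )

    def test_combine_strands(self):
        assert combine_strands("coding_promoter", "transcription_initiation") == "coding_promoter"
        assert combine_strands("transcription_initiation", "no_transcription") == "putative_enhancer"
        assert combine_strands("no_transcription", "no_transcription") == "other_element"
        assert combine_strands("pseudogene_promoter", "transcription_initiation") == "pseudogene_promoter"
        assert combine_strands("no_transcription", "non-coding_RNA") == "non-coding_RNA"

    def test_commutative(self):
        for a in ("coding_promoter", "transcription_initiation", "no_transcription"):
            for b in ("unassigned_promoter", "no_transcription"):
                assert combine_strands(a, b) == combine_strands(b, a)


class TestRescue:
    def _calls(self, lfc):
        g = toy_genome()
        # candidate site for gD (no promoter yet): geometry ok, crit1 failed
        ev = make_evidence(init_passed=False, mode=15890, jump_stages=())
        for s in STAGES2:
            ev["jump"][s] = JumpResult((0, 0), (3, 2), lfc, 0.2, 0.4)
        call = promoter_criteria(15900, "+", "chrI", ev, g, flat_coverage())
        assert call.geometry_pass
        sites = pd.DataFrame({"chrom": ["chrI"], "summit": [15900]})
        calls = {(0, "+"): call}
        return g, sites, calls, call

    def test_assigned_when_lfc_above_one(self):
        g, sites, calls, call = self._calls(lfc=1.2)
        rescue_low_confidence(calls, sites, genome=g)
        assert call.label == "coding_promoter"
        assert call.gene_id == "gD"
        assert call.low_confidence

    def test_not_assigned_below_one(self):
        g, sites, calls, call = self._calls(lfc=0.9)
        rescue_low_confidence(calls, sites, genome=g)
        assert call.label != "coding_promoter"

    def test_existing_assignment_untouched(self):
        g = toy_genome()
        ev = make_evidence(mode=4990, jump_stages=("s1",))
        strong = promoter_criteria(5000, "+", "chrI", ev, g, flat_coverage())
        assert strong.label == "coding_promoter"
        ev2 = make_evidence(init_passed=False, mode=4890)
        for s in STAGES2:
            ev2["jump"][s] = JumpResult((0, 0), (3, 2), 5.0, 0.2, 0.4)
        weak = promoter_criteria(4900, "+", "chrI", ev2, g, flat_coverage())
        sites = pd.DataFrame({"chrom": ["chrI", "chrI"], "summit": [5000, 4900]})
        calls = {(0, "+"): strong, (1, "+"): weak}
        rescue_low_confidence(calls, sites, genome=g)
        assert strong.label == "coding_promoter" and not strong.low_confidence
        assert weak.gene_id is None  # gA already has a promoter


class TestAssignGenes:
    def _annot(self, rows):
        base = {
            "chrom": "chrI",
            "annot": "other_element",
            "promoter_gene_id_fwd": "",
            "promoter_gene_id_rev": "",
            "summit": 0,
        }
        return pd.DataFrame([{**base, **r} for r in rows])

    def test_enhancer_in_intron_with_upstream_promoter(self):
        g = toy_genome()
        annot = self._annot(
            [
                {"annot": "coding_promoter", "start": 3925, "end": 4076,
                 "summit": 4000, "promoter_gene_id_fwd": "gA"},
                {"annot": "putative_enhancer", "start": 6500, "end": 6651,
                 "summit": 6575},
            ]
        )
        out = assign_genes(annot, g)
        assert out.iloc[1] == "gA"

    def test_enhancer_upstream_of_promoter_not_associated(self):
        g = toy_genome()
        annot = self._annot(
            [
                {"annot": "coding_promoter", "start": 3925, "end": 4076,
                 "summit": 4000, "promoter_gene_id_fwd": "gA"},
                {"annot": "putative_enhancer", "start": 3000, "end": 3151,
                 "summit": 3075},
            ]
        )
        out = assign_genes(annot, g)
        assert out.iloc[1] == ""

    def test_nested_genes_both_reported(self):
        genes = [
            Gene("big", "lb", "chrI", "protein_coding", "+", 1000, 5000,
                 first_exon_5p=[1000], exons=[(1000, 5000)]),
            Gene("small", "ls", "chrI", "protein_coding", "-", 2000, 3000,
                 first_exon_5p=[2999], exons=[(2000, 3000)]),
        ]
        g = GenomeModel([("chrI", 10000)], genes)
        annot = self._annot([{"annot": "other_element", "start": 2500, "end": 2651}])
        out = assign_genes(annot, g)
        assert out.iloc[0] == "big,small"

    def test_per_gene_counts(self):
        g = toy_genome()
        annot = self._annot(
            [
                {"annot": "coding_promoter", "start": 3925, "end": 4076,
                 "summit": 4000, "promoter_gene_id_fwd": "gA"},
                {"annot": "putative_enhancer", "start": 6500, "end": 6651,
                 "summit": 6575},
            ]
        )
        annot["associated_gene_id"] = assign_genes(annot, g)
        counts = per_gene_counts(annot)
        row = counts[counts["gene_id"] == "gA"].iloc[0]
        assert row["n_promoters"] == 1 and row["n_enhancers"] == 1
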