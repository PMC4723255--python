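import numpy as np
import pytest
from Bio.Seq import Seq

from radmarker import fixtures
from radmarker.annotate import (
    AnnotationParams,
    Effect,
    GeneModel,
    Region,
    annotate_variants,
    coding_effect,
    indel_length_summary,
    locate_variant,
    parse_gff3,
    select_linked_markers,
    summarize_annotation,
)
from radmarker.variant_call import Genotype, VariantCall, VariantType


def snp(chrom, pos, ref, alt):
    return VariantCall(chrom, pos, ref, alt, VariantType.SNP, 20, 15, 0.75, Genotype.HET)


def write_gff(tmp_path, body):
    path = tmp_path / "genes.gff3"
    path.write_text("##gff-version 3\n" + body)
    return path


SINGLE_EXON_PLUS = (
    "chr1\tsim\tgene\t1001\t2000\t.\t+\t.\tID=g1\n"
    "chr1\tsim\tmRNA\t1001\t2000\t.\t+\t.\tID=t1;Parent=g1\n"
    "chr1\tsim\texon\t1001\t2000\t.\t+\t.\tID=t1.e1;Parent=t1\n"
    "chr1\tsim\tCDS\t1101\t1900\t.\t+\t0\tID=t1.c1;Parent=t1\n"
    "chr1\tsim\tfive_prime_UTR\t1001\t1100\t.\t+\t.\tID=t1.u5;Parent=t1\n"
    "chr1\tsim\tthree_prime_UTR\t1901\t2000\t.\t+\t.\tID=t1.u3;Parent=t1\n"
)


class TestParseGff3:
    def test_single_exon_plus_strand(self, tmp_path):
        models = parse_gff3(write_gff(tmp_path, SINGLE_EXON_PLUS))
        assert len(models) == 1
        m = models[0]
        assert (m.tss, m.tts) == (1001, 2000)
        assert m.gene_id == "g1"
        assert m.exons == [(1001, 2000)]
        assert m.cds == [(1101, 1900)]

    def test_minus_strand_flips_tss_tts(self, tmp_path):
        body = SINGLE_EXON_PLUS.replace("\t+\t", "\t-\t")
        models = parse_gff3(write_gff(tmp_path, body))
        assert (models[0].tss, models[0].tts) == (2000, 1001)

    def test_fixture_gff_round_trip(self, toy_dataset, toy_spec):
        models = parse_gff3(toy_dataset["gff3"])
        assert len(models) == toy_spec.n_genes
        for m in models:
            assert len(m.exons) == 2
            assert m.cds_length % 3 == 0


class TestLocateVariant:
    @pytest.fixture()
    def models(self, tmp_path):
        return parse_gff3(write_gff(tmp_path, SINGLE_EXON_PLUS))

    def test_cds_containment(self, models):
        annotated = locate_variant(snp("chr1", 1500, "A", "G"), models)
        assert annotated.region is Region.CDS
        assert annotated.gene_id == "g1"

    def test_utr5_and_utr3(self, models):
        assert locate_variant(snp("chr1", 1050, "A", "G"), models).region is Region.EXON_UTR5
        assert locate_variant(snp("chr1", 1950, "A", "G"), models).region is Region.EXON_UTR3

    def test_tss_window_upstream(self, models):
        annotated = locate_variant(snp("chr1", 501, "A", "G"), models)
        assert annotated.region is Region.TSS_REGION

    def test_tts_window_downstream(self, models):
        annotated = locate_variant(snp("chr1", 2400, "A", "G"), models)
        assert annotated.region is Region.TTS_REGION

    def test_intergenic_far_away(self, models):
        annotated = locate_variant(snp("chr1", 100_000, "A", "G"), models)
        assert annotated.region is Region.INTERGENIC
        assert annotated.gene_id is None

    def test_intron(self, tmp_path):
        body = (
            "chr1\tsim\tgene\t1000\t3000\t.\t+\t.\tID=g2\n"
            "chr1\tsim\tmRNA\t1000\t3000\t.\t+\t.\tID=t2;Parent=g2\n"
            "chr1\tsim\texon\t1000\t1500\t.\t+\t.\tID=t2.e1;Parent=t2\n"
            "chr1\tsim\texon\t2500\t3000\t.\t+\t.\tID=t2.e2;Parent=t2\n"
            "chr1\tsim\tCDS\t1000\t1500\t.\t+\t0\tID=t2.c1;Parent=t2\n"
            "chr1\tsim\tCDS\t2500\t3000\t.\t+\t0\tID=t2.c2;Parent=t2\n"
        )
        models = parse_gff3(write_gff(tmp_path, body))
        assert locate_variant(snp("chr1", 2000, "A", "G"), models).region is Region.INTRON

    def test_gene_body_beats_neighbor_tss_window(self, tmp_path):
        body = SINGLE_EXON_PLUS + (
            "chr1\tsim\tgene\t2100\t2600\t.\t+\t.\tID=g3\n"
            "chr1\tsim\tmRNA\t2100\t2600\t.\t+\t.\tID=t3;Parent=g3\n"
            "chr1\tsim\texon\t2100\t2600\t.\t+\t.\tID=t3.e1;Parent=t3\n"
        )
        models = parse_gff3(write_gff(tmp_path, body))
        # 1950 is inside g1's 3'UTR and within 1000 bp of g3's TSS
        annotated = locate_variant(snp("chr1", 1950, "A", "G"), models)
        assert annotated.region is Region.EXON_UTR3
        assert annotated.gene_id == "g1"

    def test_absent_chromosome_intergenic(self, models):
        annotated = locate_variant(snp("chrZ", 1500, "A", "G"), models)
        assert annotated.region is Region.INTERGENIC

    def test_strand_aware_tss_window(self, tmp_path):
        body = SINGLE_EXON_PLUS.replace("\t+\t", "\t-\t")
        models = parse_gff3(write_gff(tmp_path, body))
        # minus strand: TSS at 2000, upstream means larger coordinates
        assert locate_variant(snp("chr1", 2500, "A", "G"), models).region is Region.TSS_REGION
        assert locate_variant(snp("chr1", 600, "A", "G"), models).region is Region.TTS_REGION


class TestCodingEffect:
    def build(self, cds_seq, strand="+"):
        genomic = cds_seq if strand == "+" else str(Seq(cds_seq).reverse_complement())
        chrom_seq = "T" * 10 + genomic + "T" * 10
        model = GeneModel(
            "t", "g", "chrT", strand, 11, 10 + len(genomic),
            exons=[(11, 10 + len(genomic))], cds=[(11, 10 + len(genomic))],
        )
        return {"chrT": chrom_seq}, model

    def test_synonymous(self):
        genome, model = self.build("ATGGAATGA")
        # codon 2 GAA -> GAG, both Glu
        v = snp("chrT", 16, "A", "G")
        assert coding_effect(v, model, genome) is Effect.SYNONYMOUS

    def test_stop_gain(self):
        genome, model = self.build("ATGTGGTAA")
        # TGG -> TGA
        v = snp("chrT", 16, "G", "A")
        assert coding_effect(v, model, genome) is Effect.STOP_GAIN

    def test_stop_loss_terminal_codon(self):
        genome, model = self.build("ATGGAATAA")
        v = snp("chrT", 17, "T", "C")  # TAA -> CAA
        assert coding_effect(v, model, genome) is Effect.STOP_LOSS

    def test_nonsynonymous(self):
        genome, model = self.build("ATGGAATGA")
        v = snp("chrT", 14, "G", "C")  # GAA -> CAA, Glu -> Gln
        assert coding_effect(v, model, genome) is Effect.NONSYNONYMOUS

    def test_minus_strand_matches_hand_translation(self):
        genome, model = self.build("ATGCATTAA", strand="-")
        # genomic pos 16 is G (transcript C of CAT/His); G->A reads T: TAT/Tyr
        assert genome["chrT"][15] == "G"
        v = snp("chrT", 16, "G", "A")
        assert coding_effect(v, model, genome) is Effect.NONSYNONYMOUS

    def test_reference_mismatch_error(self):
        genome, model = self.build("ATGGAATGA")
        with pytest.raises(ValueError, match="disagrees"):
            coding_effect(snp("chrT", 16, "C", "G"), model, genome)

    def test_agrees_with_full_cds_translation_oracle(self, toy_dataset):
        """200 random CDS SNPs on both strands vs translate-everything oracle."""
        from radmarker.digest import iter_fasta

        genome = dict(iter_fasta(toy_dataset["genome"]))
        models = parse_gff3(toy_dataset["gff3"])
        rng = np.random.default_rng(777)
        checked = 0
        while checked < 200:
            model = models[int(rng.integers(len(models)))]
            s, e = model.cds[int(rng.integers(len(model.cds)))]
            pos = int(rng.integers(s, e + 1))
            ref = genome[model.chrom][pos - 1]
            alt = "ACGT"[int(rng.integers(4))]
            if alt == ref:
                continue
            effect = coding_effect(snp(model.chrom, pos, ref, alt), model, genome)
            # oracle: mutate the chromosome, translate ref and alt CDS fully
            chrom_seq = genome[model.chrom]
            mutated = chrom_seq[: pos - 1] + alt + chrom_seq[pos:]
            prot_ref = str(Seq(model.spliced_cds_sequence(chrom_seq)).translate())
            prot_alt = str(Seq(model.spliced_cds_sequence(mutated)).translate())
            if prot_ref == prot_alt:
                expected = Effect.SYNONYMOUS
            else:
                diffs = [
                    (a, b) for a, b in zip(prot_ref, prot_alt) if a != b
                ]
                a, b = diffs[0]
                if b == "*":
                    expected = Effect.STOP_GAIN
                elif a == "*":
                    expected = Effect.STOP_LOSS
                else:
                    expected = Effect.NONSYNONYMOUS
            assert effect is expected, (model.transcript_id, pos, ref, alt)
            checked += 1


class TestSummaries:
    def test_all_intergenic_fraction_one(self):
        variants = [snp("chr1", 100 * i, "A", "G") for i in range(1, 11)]
        annotated = annotate_variants(variants, [])
        table = summarize_annotation(annotated)
        row = table[(table.partition == "region") & (table.category == "INTERGENIC")]
        assert row.fraction.iloc[0] == pytest.approx(1.0)

    def test_fractions_sum_to_one(self, toy_dataset, toy_sites):
        from radmarker.digest import iter_fasta
        from radmarker.somatic import somatic_bidirectional

        a, b = toy_sites
        records = somatic_bidirectional(a.values(), b.values())
        genome = dict(iter_fasta(toy_dataset["genome"]))
        models = parse_gff3(toy_dataset["gff3"])
        annotated = annotate_variants(records, models, AnnotationParams(), genome)
        table = summarize_annotation(annotated)
        region = table[table.partition == "region"]
        assert region.fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_input_no_division_by_zero(self):
        table = summarize_annotation([])
        assert table.empty

    def test_planted_region_fractions(self, tmp_path):
        models = parse_gff3(write_gff(tmp_path, SINGLE_EXON_PLUS))
        inside = [snp("chr1", 1200 + i * 7, "A", "G") for i in range(40)]
        outside = [snp("chr1", 50_000 + i * 31, "A", "G") for i in range(60)]
        annotated = annotate_variants(inside + outside, models)
        table = summarize_annotation(annotated)
        frac = dict(zip(table.category, table.fraction))
        assert frac["CDS"] == pytest.approx(0.4)
        assert frac["INTERGENIC"] == pytest.approx(0.6)


class TestIndelLengthSummary:
    def indel(self, pos, length, kind):
        if kind == "INS":
            return VariantCall("chr1", pos, "A", "A" + "T" * length, VariantType.INS,
                              20, 15, 0.75, Genotype.HOM)
        return VariantCall("chr1", pos, "A" + "T" * length, "A", VariantType.DEL,
                           20, 15, 0.75, Genotype.HOM)

    def test_mixed_lengths(self):
        indels = [self.indel(10 * i, 1, "INS") for i in range(5)]
        indels += [self.indel(1000 + 10 * i, 3, "DEL") for i in range(5)]
        summary = indel_length_summary(indels)
        assert summary["frac_1bp"] == pytest.approx(0.5)
        assert summary["frac_2_5bp"] == pytest.approx(0.5)
        assert summary["insertions"] == {1: 5}
        assert summary["deletions"] == {3: 5}

    def test_no_indels(self):
        summary = indel_length_summary([snp("chr1", 5, "A", "G")])
        assert summary["n_indels"] == 0
        assert summary["insertions"] == {}

    def test_single_long_insertion(self):
        summary = indel_length_summary([self.indel(10, 30, "INS")])
        assert max(summary["insertions"]) == 30
        assert summary["frac_gt22bp"] == pytest.approx(1.0)


class TestSelectLinkedMarkers:
    def test_physical_to_cm_conversion(self):
        markers = [snp("chr8", 20_100_000, "A", "G")]
        selected = select_linked_markers(
            markers, "chr8", 20_000_000, 20_005_000, max_cm=1.5, cm_per_mb=4.0
        )
        assert len(selected) == 1
        assert selected[0].distance_cm == pytest.approx(0.38)

    def test_other_chromosome_excluded(self):
        markers = [snp("chr9", 20_100_000, "A", "G")]
        assert select_linked_markers(markers, "chr8", 20_000_000, 20_005_000, max_cm=1.5) == []

    def test_empty_window(self):
        markers = [snp("chr8", 30_000_000, "A", "G")]
        assert select_linked_markers(markers, "chr8", 20_000_000, 20_005_000, max_cm=1.5) == []

    def test_ranked_by_distance(self):
        markers = [snp("chr8", p, "A", "G") for p in (20_300_000, 20_010_000, 19_900_000)]
        selected = select_linked_markers(markers, "chr8", 20_000_000, 20_005_000, window_bp=500_000)
        assert [lm.marker.pos for lm in selected] == [20_010_000, 19_900_000, 20_300_000]

    def test_inside_target_distance_zero(self):
        markers = [snp("chr8", 20_002_000, "A", "G")]
        selected = select_linked_markers(markers, "chr8", 20_000_000, 20_005_000, max_cm=1.5)
        assert selected[0].distance_bp == 0
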