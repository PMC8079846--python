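"""Mutation classes, isoaccepting relation, codon context, SNP annotation."""

import numpy as np
import pytest

from codonsel import classify, genome_io
from codonsel.classify import (
    CTX_DISCARDED,
    CTX_ISO,
    CTX_NONISO,
    CTX_NSY,
    NONSENSE,
    NONSYNONYMOUS,
    STOP_RELATED,
    SYNONYMOUS,
    CodingIndex,
    annotate_mutation,
    build_isoacceptor_map,
    codon_context,
    context_census,
    is_isoaccepting,
    mutation_class,
    translate,
)
from codonsel.genome_io import CDSSegment, GenomeAnnotation, Gene, SNPRecord, Transcript
from codonsel.tai import GENETIC_CODE, SENSE_CODONS, revcomp


class TestTranslate:
    def test_alanine_and_stop(self):
        assert translate("GCA") == "A"
        assert translate("TAA") == "*"

    def test_all_64_codons(self):
        aas = {translate(a + b + c) for a in "ACGT" for b in "ACGT" for c in "ACGT"}
        assert len(aas) == 21  # 20 amino acids + stop
        stops = sum(
            translate(a + b + c) == "*" for a in "ACGT" for b in "ACGT" for c in "ACGT"
        )
        assert stops == 3


class TestMutationClass:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("GCC", "GCG", SYNONYMOUS),
            ("GCC", "ACC", NONSYNONYMOUS),
            ("TGG", "TGA", NONSENSE),
            ("TAA", "TCA", STOP_RELATED),
        ],
    )
    def test_classes(self, ref, alt, expected):
        assert mutation_class(ref, alt) == expected

    def test_identical_or_multi_position_rejected(self):
        with pytest.raises(ValueError):
            mutation_class("GCC", "GCC")
        with pytest.raises(ValueError):
            mutation_class("GCC", "ATC")


class TestIsoacceptorMap:
    def test_alanine_example(self, toy_trnas):
        m = build_isoacceptor_map(toy_trnas)
        assert m.primary["GCA"] == m.primary["GCC"] == m.primary["GCT"] == "AGC"
        assert m.primary["GCG"] == "CGC"

    def test_single_anticodon_organism(self):
        trnas = genome_io.TRNAGeneSet(copies={"AGC": 2})
        m = build_isoacceptor_map(trnas)
        assert set(m.primary.values()) == {"AGC"}

    def test_deterministic_under_input_permutation(self, default_trnas, rng):
        m1 = build_isoacceptor_map(default_trnas)
        items = list(default_trnas.items())
        for _ in range(5):
            shuffled = dict(
                (items[i][0], items[i][1]) for i in rng.permutation(len(items))
            )
            m2 = build_isoacceptor_map(genome_io.TRNAGeneSet(copies=shuffled))
            assert m1.primary == m2.primary
            assert m1.decoders == m2.decoders

    def test_every_sense_codon_decoded_by_default_set(self, isomap):
        assert set(isomap.primary) == set(SENSE_CODONS)


class TestIsIsoaccepting:
    def test_alanine_relations(self, isomap):
        assert is_isoaccepting("GCA", "GCT", isomap) is True
        assert is_isoaccepting("GCC", "GCG", isomap) is False
        assert is_isoaccepting("GCA", "GCA", isomap) is True

    def test_non_synonymous_pair_rejected(self, isomap):
        with pytest.raises(ValueError):
            is_isoaccepting("GCA", "ACA", isomap)

    def test_equivalence_relation_within_each_family(self, isomap):
        by_aa: dict[str, list[str]] = {}
        for codon in SENSE_CODONS:
            by_aa.setdefault(GENETIC_CODE[codon], []).append(codon)
        for family in by_aa.values():
            for a in family:
                assert is_isoaccepting(a, a, isomap)
                for b in family:
                    assert is_isoaccepting(a, b, isomap) == is_isoaccepting(
                        b, a, isomap
                    )
                    for c in family:
                        if is_isoaccepting(a, b, isomap) and is_isoaccepting(
                            b, c, isomap
                        ):
                            assert is_isoaccepting(a, c, isomap)


class TestCodonContext:
    def test_isoaccepting_and_non_isoaccepting_previous(self, isomap):
        codons = ["ATG", "AAA", "GCA", "GCC", "TAA"]
        assert codon_context(codons, 3, isomap) == CTX_ISO
        codons[2] = "GCG"
        assert codon_context(codons, 3, isomap) == CTX_NONISO
        codons[2] = "ACC"  # Thr next to Ala
        assert codon_context(codons, 3, isomap) == CTX_NSY

    def test_start_and_stop_discarded(self, isomap):
        codons = ["ATG", "GCC", "GCA", "TAA"]
        assert codon_context(codons, 0, isomap) == CTX_DISCARDED
        assert codon_context(codons, 1, isomap) == CTX_DISCARDED  # after initiator
        assert codon_context(codons, 3, isomap) == CTX_DISCARDED  # stop codon

    def test_out_of_range(self, isomap):
        with pytest.raises(IndexError):
            codon_context(["ATG", "TAA"], 5, isomap)

    def test_census_partitions_all_codons(self, bundle, isomap):
        for gene in bundle.model.genes[:10]:
            counts = context_census(gene.codons, isomap)
            assert sum(counts.values()) == len(gene.codons)


def _single_gene_setup(seq: str, strand: str):
    """Genome with one gene covering `seq` (given in transcript orientation)."""
    genomic = seq if strand == "+" else revcomp(seq)
    genome = {"c": "NNNN" + genomic + "NNNN"}
    tx = Transcript(
        id="t1", gene_id="g1", chrom="c", strand=strand,
        segments=[CDSSegment(4, 4 + len(seq))],
    )
    ann = GenomeAnnotation(
        chromosomes={"c": len(genome["c"])},
        genes=[Gene(id="g1", chrom="c", strand=strand, transcripts=[tx])],
    )
    return genome, ann


class TestAnnotateMutation:
    SEQ = "ATGAAAGCAGCCTAA"  # ATG AAA GCA GCC TAA

    def test_composed_example_gcc_to_gcg_after_gca(self, weights, isomap):
        genome, ann = _single_gene_setup(self.SEQ, "+")
        index = CodingIndex(ann, genome)
        # third base of the GCC codon: transcript position 12 -> genomic 4+11
        snp = SNPRecord(
            chrom="c", pos=16, ref="C", alt="G",
            genotypes=np.array([0, 1], dtype=np.int8),
        )
        (m,) = annotate_mutation(snp, index, genome, weights, isomap)
        assert (m.ref_codon, m.alt_codon) == ("GCC", "GCG")
        assert m.mclass == SYNONYMOUS
        assert m.isoaccepting is False
        assert m.context == CTX_ISO  # previous codon GCA

    def test_first_codon_context_discarded(self, weights, isomap):
        genome, ann = _single_gene_setup(self.SEQ, "+")
        index = CodingIndex(ann, genome)
        snp = SNPRecord(
            chrom="c", pos=8, ref="A", alt="G",
            genotypes=np.array([0, 1], dtype=np.int8),
        )
        (m,) = annotate_mutation(snp, index, genome, weights, isomap)
        assert m.codon_index == 1
        assert m.context == CTX_DISCARDED

    def test_strand_mirror_equivalence(self, weights, isomap):
        """Identical classification for a gene and its reverse-complement mirror."""
        genome_p, ann_p = _single_gene_setup(self.SEQ, "+")
        genome_m, ann_m = _single_gene_setup(self.SEQ, "-")
        index_p = CodingIndex(ann_p, genome_p)
        index_m = CodingIndex(ann_m, genome_m)
        L = len(genome_p["c"])
        for k in range(len(self.SEQ)):
            base = self.SEQ[k]
            for alt_t in "ACGT":
                if alt_t == base:
                    continue
                snp_p = SNPRecord(
                    chrom="c", pos=5 + k, ref=base, alt=alt_t,
                    genotypes=np.array([0], dtype=np.int8),
                )
                # mirrored genomic coordinates and complemented alleles
                snp_m = SNPRecord(
                    chrom="c", pos=L - (5 + k) + 1,
                    ref=revcomp(base), alt=revcomp(alt_t),
                    genotypes=np.array([0], dtype=np.int8),
                )
                (mp,) = annotate_mutation(snp_p, index_p, genome_p, weights, isomap)
                (mm,) = annotate_mutation(snp_m, index_m, genome_m, weights, isomap)
                assert (mp.ref_codon, mp.alt_codon) == (mm.ref_codon, mm.alt_codon)
                assert mp.mclass == mm.mclass
                assert mp.context == mm.context
                assert mp.isoaccepting == mm.isoaccepting

    def test_ref_mismatch_rejected(self, weights, isomap):
        genome, ann = _single_gene_setup(self.SEQ, "+")
        index = CodingIndex(ann, genome)
        snp = SNPRecord(
            chrom="c", pos=16, ref="T", alt="G",
            genotypes=np.array([0], dtype=np.int8),
        )
        with pytest.raises(ValueError, match="disagrees"):
            annotate_mutation(snp, index, genome, weights, isomap)


class TestPartitions:
    def test_functional_class_partition_on_bundle(self, bundle):
        truth = bundle.truth
        n_syn = (truth.mclass == SYNONYMOUS).sum()
        n_iso = (truth.isoaccepting == True).sum()  # noqa: E712
        n_noniso = (truth.isoaccepting == False).sum()  # noqa: E712
        assert n_iso + n_noniso == n_syn
        assert set(truth.mclass) <= {SYNONYMOUS, NONSYNONYMOUS, NONSENSE, STOP_RELATED}
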