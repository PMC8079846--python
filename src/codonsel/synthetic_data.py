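"""Ground-truth-labelled synthetic input bundles for the whole pipeline.

The generator emulates the structure of a re-sequenced inbred plant panel:
a small reference genome of protein-coding genes (FASTA + GFF3), a tRNA
gene copy-number table, a population VCF of homozygous lines, and per-gene
pre-aligned ortholog CDS triples (focal species plus two outgroups evolved
independently from the known ancestral sequence).  Every simulated SNP is
recorded in a truth table with its functional class, codon context, true
ancestral allele and realised derived allele frequency, so each pipeline
stage can be tested against ground truth without external downloads.

Derived allele counts are drawn from the stationary Wright-Fisher law under
genic selection with scaled coefficient gamma,

    P(count = i) ~ (1 - exp(-2 gamma (1 - x))) / ((1 - exp(-2 gamma)) x (1 - x)),
    x = i / n,  i = 1 .. n - 1,

which reduces to the neutral 1/x spectrum as gamma -> 0.  Selection classes
(tAI direction, isoaccepting type x codon context, nonsynonymous, nonsense)
each carry their own gamma; a mutation's total gamma is the sum of its
tAI-direction term and its context-cell term (nonsynonymous and nonsense
mutations use their own single terms).
"""

from __future__ import annotations

import math
import shutil
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import classify as _classify
from . import genome_io
from .classify import (
    CTX_ISO,
    CTX_NONISO,
    CTX_NSY,
    NONSENSE,
    NONSYNONYMOUS,
    STOP_RELATED,
    SYNONYMOUS,
    IsoacceptorMap,
    build_isoacceptor_map,
    codon_context,
    mutation_class,
    translate,
)
from .genome_io import TRNAGeneSet, write_fasta, write_trna_table
from .tai import (
    SENSE_CODONS,
    STOP_CODONS,
    TAIWeights,
    WobbleRules,
    compute_weights,
    delta_tai,
    revcomp,
    tai_direction,
)

# ---------------------------------------------------------------------------
# Default tRNA gene set
# ---------------------------------------------------------------------------

#: Synthetic anticodon -> copy number table.  Four-codon boxes carry an
#: I34 (A34) anticodon reading NNU/NNC/NNA plus a C34 anticodon for NNG, so
#: the classic alanine pattern holds (GCA/GCC/GCT isoaccepting, GCG apart);
#: two-codon pyrimidine boxes use a single G34 anticodon (isoaccepting
#: pairs); two-codon purine boxes use U34 + C34 anticodons (non-isoaccepting
#: pairs).  Copy numbers are in the realistic single-digit to low-teens
#: range of a compact plant genome.
DEFAULT_TRNA_COPIES: dict[str, int] = {
    # 4-codon boxes: I34 anticodon + C34 anticodon
    "AGC": 10, "CGC": 4,   # Ala
    "ACC": 8,  "CCC": 3,   # Gly
    "AGG": 6,  "CGG": 3,   # Pro
    "AGT": 7,  "CGT": 3,   # Thr
    "AAC": 9,  "CAC": 4,   # Val
    "AGA": 7,  "CGA": 3,   # Ser TCN
    "AAG": 7,  "CAG": 3,   # Leu CTN
    "ACG": 6,  "CCG": 2,   # Arg CGN
    # 2-codon pyrimidine boxes: single G34 anticodon
    "GAA": 6,              # Phe
    "GTT": 7,              # Asn
    "GTC": 8,              # Asp
    "GCA": 4,              # Cys
    "GTA": 5,              # Tyr
    "GTG": 5,              # His
    "GCT": 4,              # Ser AGT/AGC
    # 2-codon purine boxes: U34 + C34 anticodons
    "TTG": 4,  "CTG": 2,   # Gln
    "TTC": 7,  "CTC": 3,   # Glu
    "TTT": 8,  "CTT": 4,   # Lys
    "TAA": 3,  "CAA": 2,   # Leu TTA/TTG
    "TCT": 3,  "CCT": 2,   # Arg AGA/AGG
    # singles
    "AAT": 8,              # Ile (I34 reads ATT/ATC/ATA)
    "CAT": 6,              # Met
    "CCA": 4,              # Trp
}


def default_trna_set() -> TRNAGeneSet:
    return TRNAGeneSet(copies=dict(DEFAULT_TRNA_COPIES))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults describe a desk-scale panel with the population structure of
    the real study: ~1,000 inbred homozygous lines, coding SNPs of every
    functional class, and two outgroups at unequal divergence from the
    common ancestor (a close congener and a more distant crucifer).
    """

    seed: int = 0
    n_genes: int = 60
    codons_per_gene: tuple[int, int] = (80, 200)
    n_lines: int = 1135
    n_chromosomes: int = 2
    spacer_range: tuple[int, int] = (100, 300)
    #: expected SNPs per kb of CDS
    mutation_density: float = 25.0
    #: outgroup divergences in substitutions/site
    d2: float = 0.05
    d3: float = 0.15
    #: probability that the next codon repeats the previous isoacceptor group
    isoaccepting_enrichment: float = 0.2
    #: slope of E[delta-tAI sign preference] in gene conservation score;
    #: negative couples high dN/dS to tAI-decreasing synonymous mutations
    dnds_delta_tai_slope: float = 0.0
    #: selection intensities (scaled gamma) by class
    gamma_tai_up: float = 0.0
    gamma_tai_down: float = 0.0
    gamma_nonsynonymous: float = 0.0
    gamma_nonsense: float = 0.0
    #: (iso|noniso, iso_ctx|noniso_ctx|nsy_ctx) -> gamma
    gamma_context: dict[tuple[str, str], float] = field(default_factory=dict)
    #: fraction of sites whose VCF REF carries the DERIVED allele
    p_ref_derived: float = 0.3
    fraction_missing: float = 0.02
    fraction_het: float = 0.0
    #: decoy records exercising reader edge cases
    n_indels: int = 0
    n_multiallelic: int = 0
    #: fraction of genes receiving a one-codon deletion in outgroup2
    gap_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("need at least two lines")
        for d in (self.d2, self.d3):
            if not 0.0 <= d < 0.75:
                raise ValueError(f"divergence {d} outside [0, 0.75)")


# ---------------------------------------------------------------------------
# SFS under selection
# ---------------------------------------------------------------------------


def sfs_pmf(gamma: float, n_lines: int) -> np.ndarray:
    """Discretized stationary frequency law over derived counts 1..n-1."""
    i = np.arange(1, n_lines)
    x = i / n_lines
    if abs(gamma) < 1e-9:
        weights = 1.0 / x
    else:
        weights = -np.expm1(-2.0 * gamma * (1.0 - x)) / (
            -math.expm1(-2.0 * gamma) * x * (1.0 - x)
        )
    return weights / weights.sum()


def sample_derived_count(gamma: float, n_lines: int, rng: np.random.Generator) -> int:
    return int(rng.choice(np.arange(1, n_lines), p=sfs_pmf(gamma, n_lines)))


def sample_daf(
    gamma: float, n_sites: int, n_lines: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised draw of derived allele frequencies for many sites."""
    counts = rng.choice(np.arange(1, n_lines), size=n_sites, p=sfs_pmf(gamma, n_lines))
    return counts / n_lines


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------


@dataclass
class SimGene:
    id: str
    chrom: str
    strand: str
    #: 0-based genomic start of the CDS region (includes the simulated intron)
    start: int
    #: CDS codons in transcript orientation, ancestral state
    codons: list[str]
    #: ordered (start, end) 0-based half-open genomic CDS segments
    segments: list[tuple[int, int]]
    conservation: float  # in (0, 1); scales nonsynonymous acceptance


@dataclass
class SimGenome:
    config: SimConfig
    trnas: TRNAGeneSet
    weights: TAIWeights
    isomap: IsoacceptorMap
    #: ancestral chromosome sequences (before any derived allele enters REF)
    ancestral: dict[str, str]
    genes: list[SimGene]

    def gene_by_id(self) -> dict[str, SimGene]:
        return {g.id: g for g in self.genes}


def _isoacceptor_groups(isomap: IsoacceptorMap) -> dict[str, list[str]]:
    """codon -> synonymous codons sharing its primary decoder (incl. itself)."""
    groups: dict[str, list[str]] = {}
    for codon in SENSE_CODONS:
        if codon not in isomap.primary:
            continue
        groups[codon] = [
            other
            for other in SENSE_CODONS
            if other in isomap.primary
            and translate(other) == translate(codon)
            and isomap.same_decoder(codon, other)
        ]
    return groups


_BODY_CODONS = tuple(c for c in SENSE_CODONS if c != "ATG")


def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None) -> SimGenome:
    """Build the ancestral genome model: chromosomes, genes, tRNA set.

    Genes are ATG + body + stop, on either strand, each split into 1-3 CDS
    segments by short simulated introns.  With positive
    ``isoaccepting_enrichment`` the next body codon repeats the previous
    codon's isoacceptor group with that probability, emulating the
    co-occurrence bias of real coding sequences.
    """
    rng = rng or np.random.default_rng(config.seed)
    trnas = default_trna_set()
    weights = compute_weights(trnas)
    isomap = build_isoacceptor_map(trnas)
    groups = _isoacceptor_groups(isomap)

    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    parts: dict[str, list[str]] = {c: [] for c in chroms}
    lengths: dict[str, int] = {c: 0 for c in chroms}
    genes: list[SimGene] = []

    def random_dna(n: int) -> str:
        return "".join(rng.choice(list("ACGT"), size=n))

    for gi in range(config.n_genes):
        chrom = chroms[gi % len(chroms)]
        strand = "+" if rng.random() < 0.5 else "-"
        n_codons = int(rng.integers(config.codons_per_gene[0], config.codons_per_gene[1] + 1))
        codons = ["ATG"]
        prev = None
        for _ in range(n_codons - 2):
            if (
                prev is not None
                and prev in groups
                and rng.random() < config.isoaccepting_enrichment
            ):
                codon = str(rng.choice(groups[prev]))
            else:
                codon = str(rng.choice(_BODY_CODONS))
            codons.append(codon)
            prev = codon
        codons.append(str(rng.choice(["TAA", "TGA", "TAG"])))
        cds = "".join(codons)

        # split into 1-3 exon segments with short introns between them
        n_exons = int(rng.integers(1, 4))
        cuts = sorted(rng.choice(np.arange(1, len(cds)), size=n_exons - 1, replace=False)) if n_exons > 1 else []
        exon_spans: list[tuple[int, int]] = []
        last = 0
        for cut in list(cuts) + [len(cds)]:
            exon_spans.append((last, int(cut)))
            last = int(cut)

        spacer = int(rng.integers(config.spacer_range[0], config.spacer_range[1] + 1))
        parts[chrom].append(random_dna(spacer))
        lengths[chrom] += spacer
        gene_start = lengths[chrom]

        genomic_cds = cds if strand == "+" else revcomp(cds)
        # genomic-order exon lengths
        exon_lengths = [b - a for a, b in exon_spans]
        if strand == "-":
            exon_lengths = exon_lengths[::-1]
        segments_genomic: list[tuple[int, int]] = []
        offset = gene_start
        chunks: list[str] = []
        pos = 0
        for k, elen in enumerate(exon_lengths):
            seg_seq = genomic_cds[pos : pos + elen]
            pos += elen
            chunks.append(seg_seq)
            segments_genomic.append((offset, offset + elen))
            offset += elen
            if k < len(exon_lengths) - 1:
                intron = int(rng.integers(30, 80))
                chunks.append(random_dna(intron))
                offset += intron
        parts[chrom].append("".join(chunks))
        lengths[chrom] = offset

        # transcript-order segments
        segs = segments_genomic if strand == "+" else segments_genomic[::-1]
        genes.append(
            SimGene(
                id=f"g{gi + 1:04d}",
                chrom=chrom,
                strand=strand,
                start=gene_start,
                codons=codons,
                segments=segs,
                conservation=float(rng.uniform(0.05, 0.95)),
            )
        )

    for chrom in chroms:
        tail = int(rng.integers(config.spacer_range[0], config.spacer_range[1] + 1))
        parts[chrom].append(random_dna(tail))
        lengths[chrom] += tail

    ancestral = {c: "".join(parts[c]) for c in chroms}
    return SimGenome(
        config=config,
        trnas=trnas,
        weights=weights,
        isomap=isomap,
        ancestral=ancestral,
        genes=genes,
    )


def _gene_positions(gene: SimGene) -> np.ndarray:
    """1-based genomic position of each transcript CDS base, in order."""
    pos_parts = []
    for start, end in gene.segments:
        if gene.strand == "+":
            pos_parts.append(np.arange(start + 1, end + 1, dtype=np.int64))
        else:
            pos_parts.append(np.arange(end, start, -1, dtype=np.int64))
    return np.concatenate(pos_parts)


# ---------------------------------------------------------------------------
# Population simulation
# ---------------------------------------------------------------------------


@dataclass
class SimSNP:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    ancestral: str  # genomic frame
    derived: str
    gene_id: str
    codon_index: int
    offset: int
    ref_codon: str
    alt_codon: str
    mclass: str
    isoaccepting: bool | None
    delta: float | None
    context: str
    gamma: float
    derived_count: int
    genotypes: np.ndarray  # int8 codes as in genome_io
    true_daf: float = 0.0
    n_called: int = 0


def _gamma_for(
    config: SimConfig, mclass: str, iso: bool | None, delta: float | None, context: str
) -> float:
    if mclass == NONSYNONYMOUS:
        return config.gamma_nonsynonymous
    if mclass == NONSENSE:
        return config.gamma_nonsense
    if mclass != SYNONYMOUS:
        return 0.0
    gamma = 0.0
    if delta is not None:
        if delta > 0:
            gamma += config.gamma_tai_up
        elif delta < 0:
            gamma += config.gamma_tai_down
    if iso is not None and context in (CTX_ISO, CTX_NONISO, CTX_NSY):
        kind = "iso" if iso else "noniso"
        ctx = {CTX_ISO: "iso_ctx", CTX_NONISO: "noniso_ctx", CTX_NSY: "nsy_ctx"}[context]
        gamma += config.gamma_context.get((kind, ctx), 0.0)
    return gamma


def simulate_population(
    config: SimConfig, model: SimGenome, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[SimSNP]]:
    """Place SNPs on the CDSs and draw genotypes for the inbred panel.

    Returns the FINAL reference chromosome sequences (a configurable
    fraction of sites carries the derived allele as REF) and the truth
    records.  Classes and contexts are computed on the final reference, the
    same frame the pipeline sees.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    bases = "ACGT"

    # 1) choose sites and derived bases on the ancestral sequences
    proto: list[dict] = []
    used: set[tuple[str, int]] = set()
    for gene in model.genes:
        positions = _gene_positions(gene)
        cds_len = len(positions)
        n_snps = rng.poisson(config.mutation_density * cds_len / 1000.0)
        n_snps = min(n_snps, cds_len)
        if n_snps == 0:
            continue
        picks = rng.choice(cds_len, size=n_snps, replace=False)
        for k in sorted(int(p) for p in picks):
            pos1 = int(positions[k])
            if (gene.chrom, pos1) in used:
                continue
            used.add((gene.chrom, pos1))
            anc_genomic = model.ancestral[gene.chrom][pos1 - 1]
            derived_genomic = bases[int(rng.integers(0, 4))]
            while derived_genomic == anc_genomic:
                derived_genomic = bases[int(rng.integers(0, 4))]
            proto.append(
                {
                    "gene": gene,
                    "k": k,
                    "pos": pos1,
                    "anc": anc_genomic,
                    "der": derived_genomic,
                    "ref_is_derived": rng.random() < config.p_ref_derived,
                }
            )

    # optional coupling between gene conservation and delta-tAI sign:
    # re-pick the derived base of synonymous candidates toward the preferred
    # tAI direction of the host gene
    if config.dnds_delta_tai_slope != 0.0:
        for rec in proto:
            gene: SimGene = rec["gene"]
            k = rec["k"]
            codon_idx, off = k // 3, k % 3
            anc_codon = gene.codons[codon_idx]
            strand_base = rec["der"] if gene.strand == "+" else revcomp(rec["der"])
            candidates: dict[str, float] = {}
            for b in bases:
                if (gene.strand == "+" and b == rec["anc"]) or (
                    gene.strand == "-" and revcomp(b) == revcomp(rec["anc"])
                ):
                    continue
                b_t = b if gene.strand == "+" else revcomp(b)
                mut = anc_codon[:off] + b_t + anc_codon[off + 1 :]
                if mut == anc_codon or mut in STOP_CODONS or anc_codon in STOP_CODONS:
                    continue
                if translate(mut) == translate(anc_codon):
                    candidates[b] = delta_tai(anc_codon, mut, model.weights)
            ups = [b for b, d in candidates.items() if d > 0]
            downs = [b for b, d in candidates.items() if d < 0]
            if not ups or not downs:
                continue
            c = gene.conservation
            p_up = min(0.95, max(0.05, 0.5 + config.dnds_delta_tai_slope * (c - 0.5)))
            want_up = rng.random() < p_up
            # the analysis measures delta on the REF -> ALT direction; when the
            # reference carries the derived allele that direction is reversed
            if rec["ref_is_derived"]:
                want_up = not want_up
            rec["der"] = str(rng.choice(ups if want_up else downs))

    # 2) build the final reference sequences
    reference = {c: list(s) for c, s in model.ancestral.items()}
    for rec in proto:
        if rec["ref_is_derived"]:
            reference[rec["gene"].chrom][rec["pos"] - 1] = rec["der"]
    reference_str = {c: "".join(s) for c, s in reference.items()}

    # 3) classify each SNP on the final reference, draw frequencies/genotypes
    snps: list[SimSNP] = []
    for rec in proto:
        gene: SimGene = rec["gene"]
        k = rec["k"]
        codon_idx, off = k // 3, k % 3
        ref_base = reference_str[gene.chrom][rec["pos"] - 1]
        alt_base = rec["der"] if ref_base == rec["anc"] else rec["anc"]
        # reference codon in transcript frame, read from the final reference
        positions = _gene_positions(gene)
        codon_pos = positions[3 * codon_idx : 3 * codon_idx + 3]
        ref_codon = "".join(
            reference_str[gene.chrom][int(p) - 1] for p in codon_pos
        )
        if gene.strand == "-":
            ref_codon = "".join(revcomp(reference_str[gene.chrom][int(p) - 1]) for p in codon_pos)
        alt_t = alt_base if gene.strand == "+" else revcomp(alt_base)
        alt_codon = ref_codon[:off] + alt_t + ref_codon[off + 1 :]
        mclass = mutation_class(ref_codon, alt_codon)
        iso = None
        delta = None
        if mclass == SYNONYMOUS:
            delta = delta_tai(ref_codon, alt_codon, model.weights)
            if ref_codon in model.isomap.primary and alt_codon in model.isomap.primary:
                iso = model.isomap.same_decoder(ref_codon, alt_codon)
        # context from the final reference, transcript frame
        full = "".join(
            reference_str[gene.chrom][int(p) - 1] for p in positions
        )
        if gene.strand == "-":
            full = "".join(revcomp(reference_str[gene.chrom][int(p) - 1]) for p in positions)
        codons = [full[i : i + 3] for i in range(0, len(full), 3)]
        context = codon_context(codons, codon_idx, model.isomap)
        gamma = _gamma_for(config, mclass, iso, delta, context)

        n = config.n_lines
        derived_count = sample_derived_count(gamma, n, rng)
        derived_is_alt = rec["der"] == alt_base
        carriers = rng.choice(n, size=derived_count, replace=False)
        gt = np.full(n, genome_io.GT_REF if derived_is_alt else genome_io.GT_ALT, dtype=np.int8)
        gt[carriers] = genome_io.GT_ALT if derived_is_alt else genome_io.GT_REF
        if config.fraction_het > 0:
            het_mask = rng.random(n) < config.fraction_het
            gt[het_mask] = genome_io.GT_HET
        if config.fraction_missing > 0:
            miss_mask = rng.random(n) < config.fraction_missing
            gt[miss_mask] = genome_io.GT_MISSING
        called = gt != genome_io.GT_MISSING
        called &= gt != genome_io.GT_HET
        n_called = int(called.sum())
        if n_called == 0:
            continue
        n_derived_called = int(
            np.count_nonzero(gt[called] == (genome_io.GT_ALT if derived_is_alt else genome_io.GT_REF))
        )
        snps.append(
            SimSNP(
                chrom=gene.chrom,
                pos=rec["pos"],
                ref=ref_base,
                alt=alt_base,
                ancestral=rec["anc"],
                derived=rec["der"],
                gene_id=gene.id,
                codon_index=codon_idx,
                offset=off,
                ref_codon=ref_codon,
                alt_codon=alt_codon,
                mclass=mclass,
                isoaccepting=iso,
                delta=delta,
                context=context,
                gamma=gamma,
                derived_count=derived_count,
                genotypes=gt,
                true_daf=n_derived_called / n_called,
                n_called=n_called,
            )
        )
    snps.sort(key=lambda s: (s.chrom, s.pos))
    return reference_str, snps


# ---------------------------------------------------------------------------
# Outgroup simulation
# ---------------------------------------------------------------------------


def _evolve_cds(
    cds: str,
    divergence: float,
    conservation: float,
    rng: np.random.Generator,
) -> str:
    """Jukes-Cantor evolution of one lineage from the ancestral CDS.

    Each site substitutes with the JC probability implied by ``divergence``;
    proposals that change the amino acid are accepted with probability
    ``conservation`` (low values emulate purifying selection, lowering the
    gene's realised dN/dS).
    """
    p_sub = 0.75 * -math.expm1(-4.0 * divergence / 3.0)
    seq = list(cds)
    bases = "ACGT"
    for i in range(len(seq)):
        if rng.random() >= p_sub:
            continue
        old = seq[i]
        new = bases[int(rng.integers(0, 4))]
        while new == old:
            new = bases[int(rng.integers(0, 4))]
        codon_start = 3 * (i // 3)
        old_codon = "".join(seq[codon_start : codon_start + 3])
        new_codon = old_codon[: i % 3] + new + old_codon[i % 3 + 1 :]
        if old_codon in STOP_CODONS or new_codon in STOP_CODONS:
            continue  # keep reading frame biologically plausible
        if translate(old_codon) != translate(new_codon) and rng.random() >= conservation:
            continue
        seq[i] = new
    return "".join(seq)


def simulate_outgroups(
    config: SimConfig,
    model: SimGenome,
    reference: Mapping[str, str],
    rng: np.random.Generator | None = None,
) -> dict[str, genome_io.OrthologAlignment]:
    """Evolve two outgroup CDSs per gene from the TRUE ancestral sequence.

    The focal row of each alignment is the gene's CDS as read from the final
    reference (so it matches what the pipeline extracts); the outgroups
    evolve independently from the ancestor at divergences d2 and d3.  With
    ``gap_fraction > 0`` a random codon is deleted from outgroup2 in that
    fraction of genes, producing gap columns.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    alignments: dict[str, genome_io.OrthologAlignment] = {}
    for gene in model.genes:
        positions = _gene_positions(gene)
        anc = "".join(model.ancestral[gene.chrom][int(p) - 1] for p in positions)
        focal = "".join(reference[gene.chrom][int(p) - 1] for p in positions)
        if gene.strand == "-":
            anc = "".join(revcomp(model.ancestral[gene.chrom][int(p) - 1]) for p in positions)
            focal = "".join(revcomp(reference[gene.chrom][int(p) - 1]) for p in positions)
        out2 = _evolve_cds(anc, config.d2, gene.conservation, rng)
        out3 = _evolve_cds(anc, config.d3, gene.conservation, rng)
        if config.gap_fraction > 0 and rng.random() < config.gap_fraction:
            start = 3 * int(rng.integers(1, len(anc) // 3 - 1))
            out2 = out2[:start] + "---" + out2[start + 3 :]
        alignments[gene.id] = genome_io.OrthologAlignment.from_sequences(
            gene.id, focal, out2, out3
        )
    return alignments


# ---------------------------------------------------------------------------
# Writers and the bundle
# ---------------------------------------------------------------------------


def write_gff3(model: SimGenome, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, seq in model.ancestral.items():
            fh.write(f"##sequence-region {chrom} 1 {len(seq)}\n")
        for gene in model.genes:
            segs = sorted(gene.segments)
            g_start, g_end = segs[0][0] + 1, segs[-1][1]
            fh.write(
                f"{gene.chrom}\tcodonsel\tgene\t{g_start}\t{g_end}\t.\t{gene.strand}\t.\tID={gene.id}\n"
            )
            mrna = f"{gene.id}.1"
            fh.write(
                f"{gene.chrom}\tcodonsel\tmRNA\t{g_start}\t{g_end}\t.\t{gene.strand}\t.\tID={mrna};Parent={gene.id}\n"
            )
            # phase per GFF3: bases to skip to reach the next codon start
            ordered = gene.segments  # transcript order
            cum = 0
            phases = []
            for s, e in ordered:
                phases.append((3 - cum % 3) % 3)
                cum += e - s
            for (s, e), ph in sorted(zip(ordered, phases)):
                fh.write(
                    f"{gene.chrom}\tcodonsel\tCDS\t{s + 1}\t{e}\t.\t{gene.strand}\t{ph}\tID=cds-{mrna};Parent={mrna}\n"
                )


def write_vcf(
    snps: list[SimSNP],
    chrom_lengths: Mapping[str, int],
    n_lines: int,
    path,
    decoys: list[str] | None = None,
) -> None:
    samples = [f"L{i + 1:04d}" for i in range(n_lines)]
    gt_strings = {
        genome_io.GT_REF: "0|0",
        genome_io.GT_ALT: "1|1",
        genome_io.GT_HET: "0|1",
        genome_io.GT_MISSING: ".|.",
    }
    lines_out = []
    for s in snps:
        gts = "\t".join(gt_strings[int(g)] for g in s.genotypes)
        lines_out.append(
            (s.chrom, s.pos, f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t.\tGT\t{gts}")
        )
    for decoy in decoys or []:
        fields = decoy.split("\t")
        lines_out.append((fields[0], int(fields[1]), decoy))
    lines_out.sort(key=lambda t: (t[0], t[1]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for _, _, line in lines_out:
            fh.write(line + "\n")


def _decoy_records(
    config: SimConfig,
    reference: Mapping[str, str],
    used: set[tuple[str, int]],
    n_lines: int,
    rng: np.random.Generator,
) -> list[str]:
    """Indel and multi-allelic records for reader edge-case exercise."""
    decoys = []
    chroms = list(reference)
    gts_ref = "\t".join(["0|0"] * n_lines)

    def free_position() -> tuple[str, int]:
        while True:
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            pos = int(rng.integers(1, len(reference[chrom])))
            if (chrom, pos) not in used and (chrom, pos + 1) not in used:
                used.add((chrom, pos))
                return chrom, pos

    for _ in range(config.n_indels):
        chrom, pos = free_position()
        ref = reference[chrom][pos - 1 : pos + 1]
        decoys.append(f"{chrom}\t{pos}\t.\t{ref}\t{ref[0]}\t.\tPASS\t.\tGT\t{gts_ref}")
    for _ in range(config.n_multiallelic):
        chrom, pos = free_position()
        ref = reference[chrom][pos - 1]
        alts = [b for b in "ACGT" if b != ref][:2]
        decoys.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{','.join(alts)}\t.\tPASS\t.\tGT\t{gts_ref}"
        )
    return decoys


def truth_frame(snps: list[SimSNP]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "pos": s.pos,
                "ref": s.ref,
                "alt": s.alt,
                "ancestral": s.ancestral,
                "derived": s.derived,
                "gene_id": s.gene_id,
                "codon_index": s.codon_index,
                "offset": s.offset,
                "ref_codon": s.ref_codon,
                "alt_codon": s.alt_codon,
                "mclass": s.mclass,
                "isoaccepting": s.isoaccepting,
                "delta_tai": s.delta,
                "tai_direction": tai_direction(s.delta) if s.delta is not None else "",
                "context": s.context,
                "gamma": s.gamma,
                "derived_count": s.derived_count,
                "true_daf": s.true_daf,
                "n_called": s.n_called,
            }
            for s in snps
        ]
    )


@dataclass
class FixtureBundle:
    """Paths of a written synthetic bundle plus its in-memory ground truth."""

    root: Path
    fasta: Path
    gff3: Path
    vcf: Path
    trna_tsv: Path
    alignments_dir: Path
    truth_tsv: Path
    truth: pd.DataFrame
    model: SimGenome
    reference: dict[str, str]
    snps: list[SimSNP]


def generate_fixture_bundle(config: SimConfig, outdir) -> FixtureBundle:
    """Run all simulators, write every file, and validate by re-reading."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        rng = np.random.default_rng(config.seed)
        model = simulate_genome(config, rng)
        reference, snps = simulate_population(config, model, rng)
        alignments = simulate_outgroups(config, model, reference, rng)

        fasta = outdir / "genome.fa"
        gff3 = outdir / "annotation.gff3"
        vcf = outdir / "population.vcf"
        trna_tsv = outdir / "trna.tsv"
        aln_dir = outdir / "alignments"
        truth_tsv = outdir / "truth.tsv"
        aln_dir.mkdir(exist_ok=True)

        write_fasta(reference, fasta)
        write_gff3(model, gff3)
        used = {(s.chrom, s.pos) for s in snps}
        decoys = _decoy_records(
            config, reference, used, config.n_lines, np.random.default_rng(config.seed + 3)
        )
        chrom_lengths = {c: len(s) for c, s in reference.items()}
        write_vcf(snps, chrom_lengths, config.n_lines, vcf, decoys)
        write_trna_table(model.trnas, trna_tsv)
        for gene_id, aln in alignments.items():
            write_fasta(
                {
                    "focal": aln.focal,
                    "outgroup2": aln.outgroup2,
                    "outgroup3": aln.outgroup3,
                },
                aln_dir / f"{gene_id}.fa",
            )
        truth = truth_frame(snps)
        truth.to_csv(truth_tsv, sep="\t", index=False)

        # self-consistency: the emitted files re-read to the same objects
        reread = genome_io.read_fasta(fasta)
        if reread != reference:
            raise RuntimeError("FASTA round-trip mismatch")
        stats = genome_io.VCFStats()
        n_reread = sum(1 for _ in genome_io.read_vcf_snps(vcf, stats=stats))
        if n_reread != len(snps):
            raise RuntimeError("VCF round-trip SNP count mismatch")
    except Exception:
        shutil.rmtree(outdir, ignore_errors=True)
        raise
    return FixtureBundle(
        root=outdir,
        fasta=fasta,
        gff3=gff3,
        vcf=vcf,
        trna_tsv=trna_tsv,
        alignments_dir=aln_dir,
        truth_tsv=truth_tsv,
        truth=truth,
        model=model,
        reference=reference,
        snps=snps,
    )
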