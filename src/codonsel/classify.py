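"""Functional class, isoaccepting relation and codon context of coding SNPs.

A coding substitution is synonymous, nonsynonymous or nonsense.  Synonymous
substitutions split further by whether the codon before and after mutation
are decoded by the same tRNA anticodon (isoaccepting) or by different
anticodons (non-isoaccepting).  Independently, every codon sits in a codon
context defined by its immediate 5' neighbour: isoaccepting (synonymous
neighbour, same primary anticodon), non-isoaccepting (synonymous neighbour,
different anticodon) or nonsynonymous (neighbour encodes a different amino
acid).  Initiator codons, stop codons and codons directly after the
initiator are discarded from context analyses.

The isoaccepting relation uses equality of each codon's PRIMARY decoding
anticodon — the anticodon with the largest wobble-discounted copy-number
contribution ``(1 - s) * tGCN``.  With the classic eukaryotic wobble rules
and an I34 alanine tRNA this reproduces the textbook alanine pattern:
GCA/GCC/GCT share one decoder while GCG is read by another.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from . import genome_io
from .genome_io import CodingSequence, GenomeAnnotation, SNPRecord
from .tai import (
    GENETIC_CODE,
    SENSE_CODONS,
    STOP_CODONS,
    TAIWeights,
    WobbleRules,
    anticodon_contributions,
    delta_tai,
    tai_direction,
)

# functional classes
SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
NONSENSE = "nonsense"
STOP_RELATED = "stop_related_other"

# codon-context labels
CTX_ISO = "isoaccepting"
CTX_NONISO = "non_isoaccepting"
CTX_NSY = "nonsynonymous"
CTX_DISCARDED = "discarded"

_COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}


def translate(codon: str) -> str:
    """Standard nuclear genetic code; returns one-letter amino acid or '*'."""
    codon = codon.upper()
    if codon not in GENETIC_CODE:
        raise ValueError(f"cannot translate codon {codon!r}")
    return GENETIC_CODE[codon]


def mutation_class(ref_codon: str, alt_codon: str) -> str:
    """Functional class of a single-base codon substitution."""
    if ref_codon == alt_codon:
        raise ValueError("identical codons have no mutation class")
    if sum(a != b for a, b in zip(ref_codon, alt_codon)) != 1:
        raise ValueError(f"codons {ref_codon}/{alt_codon} differ at > 1 position")
    if ref_codon in STOP_CODONS:
        return STOP_RELATED
    if alt_codon in STOP_CODONS:
        return NONSENSE
    return SYNONYMOUS if translate(ref_codon) == translate(alt_codon) else NONSYNONYMOUS


# ---------------------------------------------------------------------------
# Isoacceptor map
# ---------------------------------------------------------------------------


@dataclass
class IsoacceptorMap:
    """Primary decoding anticodon and full decoder set per sense codon."""

    primary: dict[str, str]
    decoders: dict[str, frozenset[str]]
    #: mode used to compare codons: "primary" or "set"
    mode: str = "primary"

    def same_decoder(self, codon_a: str, codon_b: str) -> bool:
        if self.mode == "set":
            return self.decoders.get(codon_a) == self.decoders.get(codon_b)
        return self.primary.get(codon_a) == self.primary.get(codon_b)


def build_isoacceptor_map(
    trnas,
    rules: WobbleRules | None = None,
    weights: TAIWeights | None = None,
    mode: str = "primary",
) -> IsoacceptorMap:
    """Assign each sense codon its decoder anticodon set and primary decoder.

    The primary decoder maximises the contribution ``(1 - s) * tGCN``; ties
    break toward the higher raw copy number, then the lexicographically
    smaller anticodon.  Codons with no positive contribution get no entry
    and are excluded from isoaccepting logic downstream.
    """
    if mode not in ("primary", "set"):
        raise ValueError(f"unknown isoacceptor mode {mode!r}")
    rules = rules or WobbleRules.default()
    contrib = anticodon_contributions(trnas, rules)
    copies = {
        a.strip().upper().replace("U", "T"): n for a, n in trnas.items()
    }
    primary: dict[str, str] = {}
    decoders: dict[str, frozenset[str]] = {}
    for codon in SENSE_CODONS:
        per = contrib[codon]
        if not per:
            continue
        decoders[codon] = frozenset(per)
        primary[codon] = max(
            per, key=lambda ac: (per[ac], copies.get(ac, 0), _lex_desc(ac))
        )
    return IsoacceptorMap(primary=primary, decoders=decoders, mode=mode)


def _lex_desc(anticodon: str) -> tuple[int, ...]:
    # max() picks the largest key, so invert character order for the
    # "lexicographically smaller wins" tie-break
    return tuple(-ord(c) for c in anticodon)


def is_isoaccepting(codon_a: str, codon_b: str, isomap: IsoacceptorMap) -> bool:
    """True iff two synonymous codons are decoded by the same anticodon."""
    if translate(codon_a) != translate(codon_b):
        raise ValueError(f"{codon_a}/{codon_b} are not synonymous")
    if codon_a in STOP_CODONS:
        raise ValueError("stop codons have no isoaccepting relation")
    if codon_a not in isomap.primary or codon_b not in isomap.primary:
        raise ValueError(f"codon without decoder: {codon_a} or {codon_b}")
    return isomap.same_decoder(codon_a, codon_b)


def codon_context(codons, focal_index: int, isomap: IsoacceptorMap) -> str:
    """Context label of the focal codon from its immediate 5' neighbour.

    ``codons`` is a list of codon strings or an object with ``.codons``.
    Returns one of {isoaccepting, non_isoaccepting, nonsynonymous, discarded}.
    """
    codons = getattr(codons, "codons", codons)
    if not 0 <= focal_index < len(codons):
        raise IndexError(f"codon index {focal_index} out of range")
    if focal_index <= 1:  # initiator itself, or neighbour is the initiator
        return CTX_DISCARDED
    focal = codons[focal_index]
    prev = codons[focal_index - 1]
    if focal in STOP_CODONS or prev in STOP_CODONS:
        return CTX_DISCARDED
    if focal not in GENETIC_CODE or prev not in GENETIC_CODE:
        return CTX_DISCARDED  # ambiguity bases
    if translate(focal) != translate(prev):
        return CTX_NSY
    if focal not in isomap.primary or prev not in isomap.primary:
        return CTX_DISCARDED  # no decoder information
    return CTX_ISO if isomap.same_decoder(focal, prev) else CTX_NONISO


def context_census(codons, isomap: IsoacceptorMap) -> dict[str, int]:
    """Count every codon of a CDS by context label (exact partition)."""
    codons = getattr(codons, "codons", codons)
    counts = {CTX_ISO: 0, CTX_NONISO: 0, CTX_NSY: 0, CTX_DISCARDED: 0}
    for i in range(len(codons)):
        counts[codon_context(codons, i, isomap)] += 1
    return counts


# ---------------------------------------------------------------------------
# SNP annotation
# ---------------------------------------------------------------------------


@dataclass
class AnnotatedMutation:
    """A coding SNP projected onto one transcript."""

    snp: SNPRecord
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    codon_index: int
    offset: int  # within-codon, 0-2, transcript frame
    ref_codon: str
    alt_codon: str
    mclass: str
    isoaccepting: bool | None  # defined iff synonymous
    delta_tai: float | None
    context: str

    @property
    def tai_direction(self) -> str | None:
        if self.delta_tai is None:
            return None
        return tai_direction(self.delta_tai)

    @property
    def position(self) -> int:
        return self.snp.pos


class CodingIndex:
    """Genomic position -> (CodingSequence, codon index, offset) lookup."""

    def __init__(self, annotation: GenomeAnnotation, genome: Mapping[str, str]):
        self.cds_by_transcript: dict[str, CodingSequence] = {}
        self._index: dict[tuple[str, int], list[tuple[str, int, int]]] = {}
        for tx in annotation.transcripts(accepted_only=True):
            cds = genome_io.extract_cds(tx, genome)
            self.cds_by_transcript[tx.id] = cds
            for k, pos in enumerate(cds.positions):
                key = (cds.chrom, int(pos))
                self._index.setdefault(key, []).append((tx.id, k // 3, k % 3))

    def lookup(self, chrom: str, pos: int) -> list[tuple[str, int, int]]:
        return self._index.get((chrom, pos), [])


def annotate_mutation(
    snp: SNPRecord,
    index: CodingIndex,
    genome: Mapping[str, str],
    weights: TAIWeights,
    isomap: IsoacceptorMap,
) -> list[AnnotatedMutation]:
    """Annotate one SNP against every transcript whose CDS overlaps it.

    The reference codon comes from the reference genome; the alternate codon
    substitutes the (strand-complemented, on minus-strand transcripts) ALT
    allele at the within-codon offset.  A SNP whose REF allele disagrees with
    the genome is excluded with a ``ValueError``.
    """
    genome_base = genome[snp.chrom][snp.pos - 1]
    if genome_base != snp.ref:
        raise ValueError(
            f"REF allele {snp.ref} at {snp.chrom}:{snp.pos} "
            f"disagrees with genome base {genome_base}"
        )
    out: list[AnnotatedMutation] = []
    for tid, codon_idx, offset in index.lookup(snp.chrom, snp.pos):
        cds = index.cds_by_transcript[tid]
        if codon_idx in cds.ambiguous:
            continue
        if cds.strand == "-":
            alt_t = _COMPLEMENT_BASE[snp.alt]
        else:
            alt_t = snp.alt
        ref_codon = cds.codons[codon_idx]
        alt_codon = ref_codon[:offset] + alt_t + ref_codon[offset + 1 :]
        mclass = mutation_class(ref_codon, alt_codon)
        iso: bool | None = None
        dtai: float | None = None
        if mclass == SYNONYMOUS:
            dtai = delta_tai(ref_codon, alt_codon, weights)
            if ref_codon in isomap.primary and alt_codon in isomap.primary:
                iso = isomap.same_decoder(ref_codon, alt_codon)
        context = codon_context(cds.codons, codon_idx, isomap)
        out.append(
            AnnotatedMutation(
                snp=snp,
                transcript_id=tid,
                gene_id=cds.gene_id,
                chrom=cds.chrom,
                strand=cds.strand,
                codon_index=codon_idx,
                offset=offset,
                ref_codon=ref_codon,
                alt_codon=alt_codon,
                mclass=mclass,
                isoaccepting=iso,
                delta_tai=dtai,
                context=context,
            )
        )
    return out


def annotate_all(
    snps: Iterable[SNPRecord],
    annotation: GenomeAnnotation,
    genome: Mapping[str, str],
    weights: TAIWeights,
    isomap: IsoacceptorMap,
    index: CodingIndex | None = None,
) -> tuple[list[AnnotatedMutation], dict[str, int]]:
    """Annotate a stream of SNPs; returns mutations and skip tallies."""
    index = index or CodingIndex(annotation, genome)
    skipped = {"non_coding": 0, "ref_mismatch": 0, "ambiguous_codon": 0}
    out: list[AnnotatedMutation] = []
    for snp in snps:
        hits = index.lookup(snp.chrom, snp.pos)
        if not hits:
            skipped["non_coding"] += 1
            continue
        try:
            annotated = annotate_mutation(snp, index, genome, weights, isomap)
        except ValueError:
            skipped["ref_mismatch"] += 1
            continue
        if not annotated:
            skipped["ambiguous_codon"] += 1
            continue
        out.extend(annotated)
    return out, skipped


def dedupe_per_gene(mutations: list[AnnotatedMutation]) -> list[AnnotatedMutation]:
    """Keep one (SNP, transcript) record per (gene, site): first transcript by id."""
    best: dict[tuple[str, str, int], AnnotatedMutation] = {}
    for m in mutations:
        key = (m.gene_id, m.chrom, m.position)
        if key not in best or m.transcript_id < best[key].transcript_id:
            best[key] = m
    return list(best.values())
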