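"""Ancestral-state inference from two outgroups and derived allele frequencies.

For each segregating site the orthologous bases of two outgroup species are
read off a pre-computed CDS alignment.  When both outgroups agree and the
shared base is one of the two segregating alleles, that base is taken as the
ancestral state (parsimony consensus) and the other allele is derived; any
other configuration — outgroup disagreement, a third base, an alignment gap,
or a gene without an accepted ortholog triple — excludes the site.  The
derived allele frequency (DAF) is the fraction of derived alleles among
lines with a genotype call.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .classify import AnnotatedMutation
from .genome_io import (
    GT_ALT,
    GT_HET,
    GT_MISSING,
    GT_REF,
    CodingSequence,
    OrthologAlignment,
    SNPRecord,
)

_COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}

# exclusion reasons
EXCL_NO_ORTHOLOG = "no_ortholog"
EXCL_GAP = "outgroup_gap"
EXCL_DISAGREEMENT = "outgroup_disagreement"
EXCL_THIRD_BASE = "third_base"
EXCL_FOCAL_MISMATCH = "focal_mismatch"
EXCL_NO_CALLS = "no_called_lines"


@dataclass
class PolarizedMutation:
    """An annotated mutation with ancestral/derived assignment and DAF."""

    mutation: AnnotatedMutation
    ancestral: str  # transcript-frame allele
    derived: str
    daf: float
    n_called: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.daf <= 1.0:
            raise ValueError(f"DAF {self.daf} outside [0, 1]")


def infer_ancestral(
    ref_allele: str, alt_allele: str, outgroup2_base: str, outgroup3_base: str
) -> str | None:
    """Parsimony consensus: the shared outgroup base if it segregates, else None."""
    b2, b3 = outgroup2_base.upper(), outgroup3_base.upper()
    if b2 in "-N." or b3 in "-N." or not b2 or not b3:
        return None
    if b2 != b3:
        return None
    if b2 not in (ref_allele, alt_allele):
        return None
    return b2


def map_snp_to_alignment(
    mutation: AnnotatedMutation,
    cds: CodingSequence,
    alignment: OrthologAlignment,
) -> tuple[str, str] | None:
    """Outgroup bases at the mutation's alignment column, or None on gaps.

    Raises ``ValueError`` when the alignment's ungapped focal sequence does
    not match the CDS (the whole gene is then excluded by the caller).
    """
    if alignment.focal_ungapped != cds.sequence:
        raise ValueError(
            f"alignment focal sequence mismatch for gene {alignment.gene_id}"
        )
    focal_pos = 3 * mutation.codon_index + mutation.offset
    b2, b3 = alignment.outgroup_bases(focal_pos)
    if b2 == "-" or b3 == "-":
        return None
    return b2, b3


def compute_daf(
    snp: SNPRecord, derived_is_alt: bool, het_policy: str = "missing"
) -> tuple[float, int]:
    """Derived allele frequency over lines with a genotype call.

    ``het_policy``: "missing" drops heterozygous calls (the panel is inbred);
    "half" counts each heterozygous line as half an allele of each kind.
    Raises ``ValueError`` when no line has a call.
    """
    gt = snp.genotypes
    n_ref = int(np.count_nonzero(gt == GT_REF))
    n_alt = int(np.count_nonzero(gt == GT_ALT))
    n_het = int(np.count_nonzero(gt == GT_HET))
    if het_policy == "missing":
        called = n_ref + n_alt
        alt_count = float(n_alt)
    elif het_policy == "half":
        called = n_ref + n_alt + n_het
        alt_count = n_alt + 0.5 * n_het
    else:
        raise ValueError(f"unknown heterozygote policy {het_policy!r}")
    if called == 0:
        raise ValueError(f"no called lines at {snp.chrom}:{snp.pos}")
    daf = alt_count / called if derived_is_alt else 1.0 - alt_count / called
    return daf, called


def polarize_mutations(
    mutations: Iterable[AnnotatedMutation],
    alignments: Mapping[str, OrthologAlignment],
    cds_by_transcript: Mapping[str, CodingSequence],
    het_policy: str = "missing",
) -> tuple[list[PolarizedMutation], Counter]:
    """Polarize annotated mutations against ortholog triples.

    Returns the polarized subset and a tally of exclusion reasons; excluded
    sites are a valid outcome, not an error.
    """
    out: list[PolarizedMutation] = []
    exclusions: Counter = Counter()
    bad_genes: set[str] = set()
    for m in mutations:
        aln = alignments.get(m.gene_id)
        if aln is None or m.gene_id in bad_genes:
            exclusions[EXCL_NO_ORTHOLOG if aln is None else EXCL_FOCAL_MISMATCH] += 1
            continue
        cds = cds_by_transcript[m.transcript_id]
        try:
            bases = map_snp_to_alignment(m, cds, aln)
        except ValueError:
            bad_genes.add(m.gene_id)
            exclusions[EXCL_FOCAL_MISMATCH] += 1
            continue
        if bases is None:
            exclusions[EXCL_GAP] += 1
            continue
        b2, b3 = bases
        # transcript-frame alleles
        if m.strand == "-":
            ref_t = _COMPLEMENT_BASE[m.snp.ref]
            alt_t = _COMPLEMENT_BASE[m.snp.alt]
        else:
            ref_t, alt_t = m.snp.ref, m.snp.alt
        ancestral = infer_ancestral(ref_t, alt_t, b2, b3)
        if ancestral is None:
            exclusions[EXCL_DISAGREEMENT if b2 != b3 else EXCL_THIRD_BASE] += 1
            continue
        derived = alt_t if ancestral == ref_t else ref_t
        try:
            daf, n_called = compute_daf(m.snp, derived == alt_t, het_policy)
        except ValueError:
            exclusions[EXCL_NO_CALLS] += 1
            continue
        out.append(
            PolarizedMutation(
                mutation=m,
                ancestral=ancestral,
                derived=derived,
                daf=daf,
                n_called=n_called,
            )
        )
    return out, exclusions
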