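"""Readers for the standard inputs: FASTA, GFF3, VCF, tRNA table, alignments.

Coordinate conventions: GFF3 and VCF are 1-based inclusive on disk; internal
segment coordinates are 0-based half-open.  ``CodingSequence`` is the single
conversion point between codon coordinates and genomic positions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
from Bio import SeqIO

from .tai import revcomp

log = logging.getLogger("codonsel")

# genotype codes used throughout: per-sample int8
GT_REF = 0
GT_ALT = 1
GT_HET = 2
GT_MISSING = -1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into name -> uppercased sequence.

    Names are the first whitespace-delimited token.  Duplicate names and
    empty records raise ``ValueError``.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        seq = str(record.seq).upper()
        if name in sequences:
            raise ValueError(f"duplicate FASTA record name {name!r} in {path}")
        if not seq:
            raise ValueError(f"empty FASTA record {name!r} in {path}")
        sequences[name] = seq
    return sequences


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CDSSegment:
    """One CDS interval, 0-based half-open on the genome."""

    start: int
    end: int
    phase: int = 0

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Transcript:
    id: str
    gene_id: str
    chrom: str
    strand: str
    #: ordered 5'->3' in transcript orientation
    segments: list[CDSSegment] = field(default_factory=list)

    @property
    def spliced_length(self) -> int:
        return sum(len(s) for s in self.segments)

    @property
    def accepted(self) -> bool:
        """Usable downstream: has CDS and spliced length is a multiple of 3."""
        return self.spliced_length > 0 and self.spliced_length % 3 == 0


@dataclass
class Gene:
    id: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)


@dataclass
class GenomeAnnotation:
    chromosomes: dict[str, int]
    genes: list[Gene]

    def transcripts(self, accepted_only: bool = False) -> Iterator[Transcript]:
        for gene in self.genes:
            for tx in gene.transcripts:
                if accepted_only and not tx.accepted:
                    continue
                yield tx


def read_gff3(path) -> GenomeAnnotation:
    """Parse a GFF3 gene/mRNA/CDS hierarchy into a ``GenomeAnnotation``.

    CDS segments are attached to their parent mRNA and ordered 5'->3' in
    transcript orientation (descending genomic coordinate on the minus
    strand).  A CDS whose Parent is not a known mRNA raises ``ValueError``,
    as do coordinates outside a declared ``##sequence-region``.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )

    chromosomes: dict[str, int] = {}
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            chromosomes[parts[1]] = int(parts[3])

    transcripts: dict[str, Transcript] = {}
    genes: dict[str, Gene] = {}
    for g in db.features_of_type("gene"):
        gene = Gene(id=g.id, chrom=g.seqid, strand=g.strand)
        genes[g.id] = gene
        for m in db.children(g, featuretype="mRNA", level=1):
            tx = Transcript(id=m.id, gene_id=g.id, chrom=m.seqid, strand=m.strand)
            transcripts[m.id] = tx
            gene.transcripts.append(tx)

    for c in db.features_of_type("CDS"):
        parents = [p.id for p in db.parents(c, featuretype="mRNA")]
        if not parents:
            raise ValueError(f"CDS feature {c.id!r} has no mRNA parent")
        if c.seqid in chromosomes and c.end > chromosomes[c.seqid]:
            raise ValueError(
                f"CDS {c.id!r} end {c.end} exceeds length of {c.seqid}"
            )
        for pid in parents:
            seg = CDSSegment(start=c.start - 1, end=c.end, phase=int(c.frame) if c.frame != "." else 0)
            transcripts[pid].segments.append(seg)

    for tx in transcripts.values():
        tx.segments.sort(key=lambda s: s.start, reverse=(tx.strand == "-"))
        starts = sorted((s.start, s.end) for s in tx.segments)
        for (s1, e1), (s2, _e2) in zip(starts, starts[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping CDS segments in transcript {tx.id}")
        if not tx.accepted:
            log.warning(
                "transcript %s spliced CDS length %d not a multiple of 3; excluded",
                tx.id,
                tx.spliced_length,
            )

    return GenomeAnnotation(chromosomes=chromosomes, genes=list(genes.values()))


# ---------------------------------------------------------------------------
# Spliced coding sequences
# ---------------------------------------------------------------------------


@dataclass
class CodingSequence:
    """Spliced CDS of one transcript plus its codon <-> genome coordinate map.

    ``positions[k]`` is the 1-based genomic position of transcript CDS base
    ``k`` (k = 3 * codon_index + offset); on the minus strand the transcript
    base is the complement of the genomic base at that position.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    codons: list[str]
    positions: np.ndarray  # int64, length 3 * len(codons)
    #: codon indices containing ambiguity bases, excluded from counts
    ambiguous: frozenset[int] = frozenset()
    _locator: dict[int, int] | None = None

    @property
    def sequence(self) -> str:
        return "".join(self.codons)

    def genomic_position(self, codon_index: int, offset: int) -> tuple[str, int, str]:
        k = 3 * codon_index + offset
        return self.chrom, int(self.positions[k]), self.strand

    def locate(self, position: int) -> tuple[int, int] | None:
        """Map a 1-based genomic position to (codon_index, offset), else None."""
        if self._locator is None:
            self._locator = {int(p): k for k, p in enumerate(self.positions)}
        k = self._locator.get(position)
        if k is None:
            return None
        return k // 3, k % 3


def extract_cds(transcript: Transcript, genome: Mapping[str, str]) -> CodingSequence:
    """Build the spliced, strand-oriented coding sequence of a transcript."""
    if not transcript.accepted:
        raise ValueError(
            f"transcript {transcript.id} not accepted "
            f"(spliced length {transcript.spliced_length})"
        )
    chrom_seq = genome[transcript.chrom]
    parts: list[str] = []
    pos_parts: list[np.ndarray] = []
    for seg in transcript.segments:
        if seg.end > len(chrom_seq):
            raise ValueError(
                f"CDS segment {seg.start}-{seg.end} outside {transcript.chrom}"
            )
        sub = chrom_seq[seg.start : seg.end]
        if transcript.strand == "-":
            parts.append(revcomp(sub))
            pos_parts.append(np.arange(seg.end, seg.start, -1, dtype=np.int64))
        else:
            parts.append(sub)
            pos_parts.append(np.arange(seg.start + 1, seg.end + 1, dtype=np.int64))
    seq = "".join(parts)
    positions = np.concatenate(pos_parts)
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    ambiguous = frozenset(
        i for i, c in enumerate(codons) if any(b not in "ACGT" for b in c)
    )
    if ambiguous:
        log.warning(
            "transcript %s: %d codon(s) with ambiguity bases excluded",
            transcript.id,
            len(ambiguous),
        )
    return CodingSequence(
        transcript_id=transcript.id,
        gene_id=transcript.gene_id,
        chrom=transcript.chrom,
        strand=transcript.strand,
        codons=codons,
        positions=positions,
        ambiguous=ambiguous,
    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


@dataclass
class SNPRecord:
    """A biallelic single-nucleotide variant with per-sample genotype codes."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    #: int8 per sample: 0 hom-ref, 1 hom-alt, 2 het, -1 missing
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("REF equals ALT")


@dataclass
class VCFStats:
    n_snps: int = 0
    n_indels: int = 0
    n_multiallelic: int = 0
    n_malformed: int = 0
    samples: list[str] = field(default_factory=list)


def read_vcf_snps(
    path, stats: VCFStats | None = None, multiallelic: str = "skip"
) -> Iterator[SNPRecord]:
    """Stream biallelic SNPs from a VCF 4.x file.

    Indels are counted and skipped; multi-allelic SNP sites are skipped by
    default (``multiallelic="split"`` emits one record per alternate allele).
    Records whose genotype field cannot be parsed are skipped with a warning.
    """
    from cyvcf2 import VCF

    if multiallelic not in ("skip", "split"):
        raise ValueError(f"unknown multiallelic policy {multiallelic!r}")
    vcf = VCF(str(path), gts012=True)
    if stats is not None:
        stats.samples = list(vcf.samples)
    # cyvcf2 gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
    code_map = np.array([GT_REF, GT_HET, GT_ALT, GT_MISSING], dtype=np.int8)
    for variant in vcf:
        alts = variant.ALT
        if not alts:
            continue
        if len(variant.REF) != 1 or any(len(a) != 1 for a in alts):
            if stats is not None:
                stats.n_indels += 1
            continue
        if len(alts) > 1:
            if stats is not None:
                stats.n_multiallelic += 1
            if multiallelic == "skip":
                log.debug("multi-allelic site %s:%d skipped", variant.CHROM, variant.POS)
                continue
        try:
            gt_types = variant.gt_types
        except Exception:  # malformed genotype field
            if stats is not None:
                stats.n_malformed += 1
            warnings.warn(
                f"malformed genotypes at {variant.CHROM}:{variant.POS}; record skipped"
            )
            continue
        if len(alts) == 1:
            if stats is not None:
                stats.n_snps += 1
            yield SNPRecord(
                chrom=variant.CHROM,
                pos=variant.POS,
                ref=variant.REF,
                alt=alts[0],
                genotypes=code_map[gt_types],
            )
        else:  # split: per-allele genotype codes from the raw GT tuples
            if stats is not None:
                stats.n_snps += 1
            raw = variant.genotypes  # [a1, a2, phased] per sample
            for ai, alt in enumerate(alts, start=1):
                codes = np.full(len(raw), GT_MISSING, dtype=np.int8)
                for si, g in enumerate(raw):
                    a, b = g[0], g[1]
                    if a < 0 or b < 0:
                        continue
                    hits = (a == ai) + (b == ai)
                    if hits == 2:
                        codes[si] = GT_ALT
                    elif hits == 1:
                        codes[si] = GT_HET
                    else:
                        codes[si] = GT_REF
                yield SNPRecord(
                    chrom=variant.CHROM,
                    pos=variant.POS,
                    ref=variant.REF,
                    alt=alt,
                    genotypes=codes,
                )


# ---------------------------------------------------------------------------
# tRNA gene copy-number table
# ---------------------------------------------------------------------------


@dataclass
class TRNAGeneSet:
    """Anticodon -> tRNA gene copy number (tGCN)."""

    copies: dict[str, int]

    def __post_init__(self) -> None:
        for anticodon, n in self.copies.items():
            if n < 0:
                raise ValueError(f"negative copy number for {anticodon!r}")

    def items(self):
        return self.copies.items()

    def keys(self):
        return self.copies.keys()

    def values(self):
        return self.copies.values()

    def __getitem__(self, key):
        return self.copies[key]

    def __len__(self):
        return len(self.copies)


def read_trna_table(path) -> TRNAGeneSet:
    """Read a two-column TSV (anticodon, copy number); '#' lines are comments.

    A header row is tolerated.  Duplicate anticodons and non-integer copy
    numbers raise ``ValueError``.
    """
    copies: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            anticodon = fields[0].strip().upper().replace("U", "T")
            is_valid_anticodon = len(anticodon) == 3 and all(
                b in "ACGT" for b in anticodon
            )
            if lineno == 1 and not is_valid_anticodon and not fields[1].strip().lstrip("-").isdigit():
                continue  # header row
            if len(anticodon) != 3 or any(b not in "ACGT" for b in anticodon):
                raise ValueError(f"{path}:{lineno}: invalid anticodon {fields[0]!r}")
            try:
                n = int(fields[1])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer copy number {fields[1]!r}"
                ) from None
            if anticodon in copies:
                raise ValueError(f"{path}:{lineno}: duplicate anticodon {anticodon}")
            copies[anticodon] = n
    return TRNAGeneSet(copies=copies)


def write_trna_table(trnas: TRNAGeneSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("anticodon\tcopies\n")
        for anticodon, n in sorted(trnas.items()):
            fh.write(f"{anticodon}\t{n}\n")


# ---------------------------------------------------------------------------
# Ortholog CDS alignments (focal + two outgroups)
# ---------------------------------------------------------------------------


@dataclass
class OrthologAlignment:
    """Pre-aligned CDS triple: focal species plus two outgroups.

    ``site_map[k]`` is the alignment column of ungapped focal position ``k``.
    """

    gene_id: str
    focal: str
    outgroup2: str
    outgroup3: str
    site_map: np.ndarray

    @classmethod
    def from_sequences(
        cls, gene_id: str, focal: str, outgroup2: str, outgroup3: str
    ) -> "OrthologAlignment":
        if not (len(focal) == len(outgroup2) == len(outgroup3)):
            raise ValueError(f"unequal aligned lengths for gene {gene_id}")
        site_map = np.array(
            [i for i, b in enumerate(focal) if b != "-"], dtype=np.int64
        )
        return cls(
            gene_id=gene_id,
            focal=focal.upper(),
            outgroup2=outgroup2.upper(),
            outgroup3=outgroup3.upper(),
            site_map=site_map,
        )

    @property
    def focal_ungapped(self) -> str:
        return self.focal.replace("-", "")

    def outgroup_bases(self, focal_position: int) -> tuple[str, str]:
        """Outgroup bases at the column of ungapped focal position (0-based)."""
        col = int(self.site_map[focal_position])
        return self.outgroup2[col], self.outgroup3[col]


def read_alignment_fasta(path, gene_id: str | None = None) -> OrthologAlignment:
    """Read one aligned FASTA triple (records ordered focal, outgroup2, outgroup3)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 3:
        raise ValueError(f"{path}: expected 3 aligned records, found {len(records)}")
    gid = gene_id or Path(path).stem
    return OrthologAlignment.from_sequences(
        gid, str(records[0].seq), str(records[1].seq), str(records[2].seq)
    )


def read_alignment_dir(directory) -> dict[str, OrthologAlignment]:
    """Read every ``*.fa`` / ``*.fasta`` ortholog triple in a directory."""
    alignments: dict[str, OrthologAlignment] = {}
    for path in sorted(Path(directory).iterdir()):
        if path.suffix not in (".fa", ".fasta"):
            continue
        aln = read_alignment_fasta(path)
        alignments[aln.gene_id] = aln
    return alignments
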