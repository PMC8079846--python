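# Methods notes

## Model and procedure

The pipeline asks whether synonymous coding variants are neutral by
comparing derived-allele-frequency (DAF) spectra between mutation classes.
It runs in four stages over standard inputs (FASTA + GFF3 + VCF + tRNA
copy-number TSV + per-gene aligned ortholog triples):

1. **Annotation.** Every biallelic coding SNP is projected onto each
   overlapping accepted transcript (spliced CDS length a positive multiple
   of 3).  The reference codon comes from the reference genome; the
   alternate codon substitutes the strand-complemented ALT allele at the
   within-codon offset.  Classes: synonymous / nonsynonymous / nonsense
   (sense→stop); variants whose reference codon is already a stop are set
   aside as `stop_related_other`.
2. **tAI and isoacceptor structure.** Codon weights follow the classical
   weighted-sum formulation: `W(codon) = Σ (1 − s) · tGCN` over pairing
   anticodons, normalised by the best codon.  Each codon's *primary
   decoder* is the anticodon with the largest `(1 − s) · tGCN`
   contribution; two synonymous codons are *isoaccepting* when their
   primary decoders coincide.  The codon *context* compares a focal codon
   with its immediate 5′ neighbour: isoaccepting / non-isoaccepting
   (synonymous neighbour with same / different primary decoder) or
   nonsynonymous; initiator codons, codons directly after the initiator
   and stop codons are discarded from context tallies.
3. **Polarization.** Parsimony consensus of two outgroups read off the
   ortholog alignment: the shared outgroup base is ancestral when it is one
   of the two segregating alleles; disagreement, third bases, gaps and
   missing ortholog triples exclude the site (reasons are tallied, and
   polarized + excluded = total by construction).  DAF is the derived
   fraction among called lines; heterozygous calls in the inbred panel are
   treated as missing by default (a `half` policy exists).
4. **Comparative statistics.** Two-sided Wilcoxon rank-sum tests compare
   DAF between classes (tAI-up vs tAI-down; nonsynonymous and nonsense vs
   all synonymous; six contrasts of isoaccepting/non-isoaccepting mutations
   across contexts), Bonferroni-corrected with length = tests performed in
   the run.  Gene conservation is NG86 dN/dS (focal vs the closer
   outgroup) with Jukes–Cantor correction; synonymous mutations are sorted
   by host-gene dN/dS into 50 rank bins of near-equal size and the Spearman
   correlation between bin rank and mean Δ-tAI is reported (a per-mutation
   Spearman is reported alongside, since either convention is defensible).
   The LD control keeps one mutation per gene — the most 5′ in transcript
   orientation — and re-runs the comparisons on that subset.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| wobble penalties `s` | G:U 0.41, I:C 0.28, I:A 0.9999, U:G 0.68 | canonical eukaryotic constants of the weighted-sum tAI; configurable per pairing, and the inosine (A34) rule can be disabled |
| isoaccepting mode | `primary` | equality of primary decoders; a `set` mode (equality of full decoder sets) exists.  Primary-decoder equality is the variant that reproduces the alanine pattern (GCA/GCC/GCT together, GCG apart) under an I34 + C34 anticodon complement |
| heterozygote policy | `missing` | inbred panel; `half` counts each het line as half an allele of each kind |
| multi-allelic sites | `skip` | counted and skipped; `split` emits one record per ALT |
| rank-sum exact branch | min(n) ≤ 8 and ≤ 5·10⁵ assignments | full enumeration over rank assignments with midranks; otherwise tie-corrected normal approximation with continuity correction |
| bins | 50 | rank-equal partition; bin sizes differ by ≤ 1 |

## The synthetic-data generator

`synthetic_data` emits a complete bundle (FASTA, GFF3, VCF, tRNA TSV,
aligned triples, `truth.tsv`) whose every SNP carries ground-truth class,
context, ancestral allele and realised DAF.

* **Genome.** 1–3-exon genes on both strands (ATG + body + stop) separated
  by random spacers; body codons are drawn uniformly, with probability
  `isoaccepting_enrichment` (default 0.2) of repeating the previous
  codon's isoacceptor group, emulating the observed clustering of
  isoaccepting codons.
* **tRNA set.** A fixed 36-anticodon table with single-digit-to-low-teens
  copy numbers: four-codon boxes carry an I34 anticodon (reads NNU/NNC/NNA)
  plus a C34 anticodon (NNG); two-codon pyrimidine boxes a single G34
  anticodon; two-codon purine boxes U34 + C34.  Every sense codon is
  decodable and both isoaccepting and non-isoaccepting synonymous pairs
  exist in most families.
* **Population.** Default 1,135 homozygous lines (the panel structure of a
  large inbred resequencing project); desk-scale runs use 60–100.  Derived
  counts follow the stationary Wright–Fisher fixation-flux law
  `P(i) ∝ (1 − e^{−2γ(1−x)}) / ((1 − e^{−2γ}) x (1−x))`, `x = i/n`, which
  is the neutral `1/x` spectrum at γ = 0.  A mutation's γ is the sum of a
  tAI-direction term and a context-cell term (nonsynonymous and nonsense
  classes have their own single terms); all default to 0.  30 % of sites
  put the derived allele into the reference (and hence VCF REF) so
  polarization is non-trivial; 2 % of genotype calls are missing.
* **Outgroups.** Two lineages evolve independently from the true ancestor
  under Jukes–Cantor substitution at divergences d2 = 0.05 and d3 = 0.15
  (a close congener and a more distant relative); nonsynonymous proposals
  are accepted with the gene's conservation score `c ∈ (0.05, 0.95)`, so
  realised dN/dS varies between genes.  A `dnds_delta_tai_slope` couples
  that score to the sign of synonymous Δ-tAI measured on the REF→ALT
  direction (sites where the reference carries the derived allele flip the
  preferred direction so the *measured* quantity is coupled).
* **What it does not emulate.** No recombination or linkage structure (the
  per-gene picker is tested for correctness, not for LD removal efficacy),
  no demography, no indels or multi-allelic SNPs except as optional decoy
  records for the readers, no alignment error beyond optional single-codon
  gap injection.  Passing tests therefore demonstrate correctness and
  calibration of the machinery under the stated generative model, not
  robustness to the full complexity of real resequencing data.

## Numerical and design choices

* Internal coordinates are 0-based half-open; GFF3/VCF stay 1-based on
  disk.  `CodingSequence` is the single conversion point, and its map is
  checked exhaustively in tests.
* Zero-weight codons take the geometric mean of non-zero weights so gene
  geometric means stay defined; Δ-tAI = 0 mutations form a `tai_neutral`
  class kept out of the up-vs-down comparison.
* Primary-decoder ties break toward the higher raw copy number, then the
  lexicographically smaller anticodon, making the map deterministic under
  input permutation.
* Context is evaluated on the reference sequence; adjacent segregating
  sites are not composed into haplotypes.
* NG86 skips gap- or stop-containing codon pairs; multi-hit codons average
  over substitution pathways, excluding pathways through stop codons when
  any stop-free pathway exists.  dS is reported as NaN when `p_s ≥ 3/4`
  (Jukes–Cantor saturation) — note a single synonymous-different codon
  pair saturates by construction.  An external per-gene dN/dS TSV can
  replace the internal estimator.
* The exact rank-sum two-sided p is `2 · min(P(W ≤ w), P(W ≥ w))`, capped
  at 1; degenerate all-tied inputs return p = 1.
* Spearman on constant vectors is reported as NaN rather than 0.
* Desk-scale problem sizes used by the test-suite calibration studies:
  1,000 replicates of 1,000 sites/class over 100 lines for the null; 20
  seeds of 5,000 sites/class for directional power; 20 bundles of 120
  genes for correlation recovery.  These sizes give the binomial/rank-sum
  margins quoted in the tests.

## Known limitations

* The isoaccepting relation is a model choice; decoder-set equality (the
  `set` mode) gives a stricter relation and slightly different context
  tallies.
* Polarization is parsimony consensus; at high outgroup divergence the
  double-hit error grows as the product of the two lineages' substitution
  probabilities, and no probabilistic ancestral reconstruction or SFS
  correction is attempted.
* Real annotations with overlapping transcripts produce one record per
  (SNP, transcript); the per-gene deduplication flag keeps the first
  transcript by id, which may not be the canonical isoform.
* The CLI exposes plots' underlying tables (group summaries, bin series,
  distance summaries) as TSV; figure drawing is left to downstream tools.
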