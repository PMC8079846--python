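"""Comparative statistics on polarized coding mutations.

Covers the four analyses run on the classified, polarized SNP set:

* DAF spectrum comparisons between mutation classes with two-sided Wilcoxon
  rank-sum tests (exact enumeration for small groups, tie-corrected normal
  approximation otherwise) and Bonferroni correction sized to the number of
  tests actually performed;
* per-gene dN/dS by the Nei–Gojobori (1986) counting method with
  Jukes–Cantor multiple-hit correction, and the 50-bin correlation between
  host-gene dN/dS rank and mean delta-tAI of synonymous mutations;
* distances between adjacent mutations of a class (per chromosome);
* the one-mutation-per-gene linkage-disequilibrium control, keeping the most
  5'-ward mutation of each gene in transcript orientation.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import (
    CTX_ISO,
    CTX_NONISO,
    CTX_NSY,
    NONSENSE,
    NONSYNONYMOUS,
    SYNONYMOUS,
    AnnotatedMutation,
)
from .polarize import PolarizedMutation
from .tai import GENETIC_CODE as _CODE, STOP_CODONS


# ---------------------------------------------------------------------------
# Rank-sum test
# ---------------------------------------------------------------------------

_EXACT_MIN_N = 8
_EXACT_MAX_COMBINATIONS = 500_000


@dataclass
class TestResult:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float  # Mann-Whitney U of group A
    pvalue: float
    p_adjusted: float | None = None
    direction: str = "none"  # "a_greater" / "b_greater" / "none"
    method: str = "asymptotic"

    def __post_init__(self) -> None:
        if self.p_adjusted is not None and self.p_adjusted < self.pvalue - 1e-12:
            raise ValueError("adjusted p below raw p")


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], label_a: str = "x", label_b: str = "y"
) -> TestResult:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test with midranks for ties.

    Uses exact enumeration of rank assignments when the smaller group has at
    most 8 observations and the assignment count stays feasible; otherwise a
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("rank-sum test requires two non-empty groups")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w_obs = float(ranks[:n1].sum())  # rank sum of group A
    u_obs = w_obs - n1 * (n1 + 1) / 2.0

    n = n1 + n2
    n_small = min(n1, n2)
    exact = (
        n_small <= _EXACT_MIN_N
        and math.comb(n, n_small) <= _EXACT_MAX_COMBINATIONS
    )
    if exact:
        pvalue = _exact_rank_sum_p(ranks, n1, w_obs)
        method = "exact"
    else:
        pvalue = _normal_rank_sum_p(ranks, n1, n2, u_obs)
        method = "asymptotic"

    mu_u = n1 * n2 / 2.0
    if u_obs > mu_u:
        direction = "a_greater"
    elif u_obs < mu_u:
        direction = "b_greater"
    else:
        direction = "none"
    return TestResult(
        group_a=label_a,
        group_b=label_b,
        n_a=n1,
        n_b=n2,
        statistic=u_obs,
        pvalue=pvalue,
        direction=direction,
        method=method,
    )


def _exact_rank_sum_p(ranks: np.ndarray, n1: int, w_obs: float) -> float:
    """Two-sided exact p by full enumeration of the smaller group's ranks."""
    n = len(ranks)
    n2 = n - n1
    # enumerate over the smaller group; W of group A is recoverable either way
    if n1 <= n2:
        k, total_needed = n1, w_obs
        sums = _combination_rank_sums(ranks, k)
    else:
        k = n2
        total = ranks.sum()
        sums = total - _combination_rank_sums(ranks, k)
        total_needed = w_obs
    eps = 1e-9
    n_le = int(np.count_nonzero(sums <= total_needed + eps))
    n_ge = int(np.count_nonzero(sums >= total_needed - eps))
    m = len(sums)
    return min(1.0, 2.0 * min(n_le, n_ge) / m)


def _combination_rank_sums(ranks: np.ndarray, k: int) -> np.ndarray:
    idx = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(len(ranks)), k)),
        dtype=np.intp,
    ).reshape(-1, k)
    return ranks[idx].sum(axis=1)


def _normal_rank_sum_p(ranks: np.ndarray, n1: int, n2: int, u_obs: float) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0.0:  # all observations tied
        return 1.0
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    return min(1.0, 2.0 * float(sps.norm.sf(z)))


def adjust_pvalues(pvals: Sequence[float], n_tests: int | None = None) -> list[float]:
    """Bonferroni correction with length set to the number of tests performed."""
    pvals = list(pvals)
    if n_tests is None:
        n_tests = len(pvals)
    if n_tests < len(pvals):
        raise ValueError("n_tests smaller than the number of p-values")
    for p in pvals:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
    return [min(1.0, p * n_tests) for p in pvals]


# ---------------------------------------------------------------------------
# DAF spectrum report
# ---------------------------------------------------------------------------

#: canonical group labels
GROUP_SYNONYMOUS = "synonymous"
GROUP_NONSYNONYMOUS = "nonsynonymous"
GROUP_NONSENSE = "nonsense"
GROUP_TAI_UP = "tai_up"
GROUP_TAI_DOWN = "tai_down"


def _context_cell(iso: bool, context: str) -> str:
    kind = "iso" if iso else "noniso"
    ctx = {CTX_ISO: "iso_ctx", CTX_NONISO: "noniso_ctx", CTX_NSY: "nsy_ctx"}[context]
    return f"{kind}@{ctx}"


#: the comparisons run by default: three headline DAF contrasts plus the six
#: context-stratified contrasts of synonymous mutation types
DEFAULT_COMPARISONS: tuple[tuple[str, str], ...] = (
    (GROUP_TAI_UP, GROUP_TAI_DOWN),
    (GROUP_NONSYNONYMOUS, GROUP_SYNONYMOUS),
    (GROUP_NONSENSE, GROUP_SYNONYMOUS),
    ("iso@iso_ctx", "noniso@iso_ctx"),
    ("iso@iso_ctx", "iso@noniso_ctx"),
    ("noniso@noniso_ctx", "iso@noniso_ctx"),
    ("noniso@noniso_ctx", "noniso@iso_ctx"),
    ("iso@nsy_ctx", "noniso@nsy_ctx"),
    ("iso@iso_ctx", "noniso@noniso_ctx"),
)


def group_daf(polarized: Iterable[PolarizedMutation]) -> dict[str, list[float]]:
    """Collect DAF values under every canonical group label."""
    groups: dict[str, list[float]] = defaultdict(list)
    for p in polarized:
        m = p.mutation
        if m.mclass == SYNONYMOUS:
            groups[GROUP_SYNONYMOUS].append(p.daf)
            if m.delta_tai is not None and m.delta_tai != 0.0:
                groups[GROUP_TAI_UP if m.delta_tai > 0 else GROUP_TAI_DOWN].append(p.daf)
            if m.isoaccepting is not None and m.context in (CTX_ISO, CTX_NONISO, CTX_NSY):
                groups[_context_cell(m.isoaccepting, m.context)].append(p.daf)
        elif m.mclass == NONSYNONYMOUS:
            groups[GROUP_NONSYNONYMOUS].append(p.daf)
        elif m.mclass == NONSENSE:
            groups[GROUP_NONSENSE].append(p.daf)
    return dict(groups)


def daf_spectrum_report(
    polarized: Iterable[PolarizedMutation],
    comparisons: Sequence[tuple[str, str]] = DEFAULT_COMPARISONS,
    min_group_size: int = 2,
) -> tuple[pd.DataFrame, list[TestResult]]:
    """Group summary table and Bonferroni-adjusted pairwise rank-sum tests.

    Comparisons with a group below ``min_group_size`` are skipped (logged in
    the returned summary via NaN-free omission); the correction length is
    the number of tests actually performed.
    """
    groups = group_daf(polarized)
    summary = pd.DataFrame(
        [
            {
                "group": name,
                "n": len(values),
                "mean_daf": float(np.mean(values)),
                "median_daf": float(np.median(values)),
            }
            for name, values in sorted(groups.items())
        ]
    )
    results: list[TestResult] = []
    for a, b in comparisons:
        if len(groups.get(a, ())) < min_group_size or len(groups.get(b, ())) < min_group_size:
            continue
        results.append(rank_sum_test(groups[a], groups[b], label_a=a, label_b=b))
    adjusted = adjust_pvalues([r.pvalue for r in results], n_tests=len(results))
    for r, p_adj in zip(results, adjusted):
        r.p_adjusted = p_adj
    return summary, results


# ---------------------------------------------------------------------------
# NG86 dN/dS
# ---------------------------------------------------------------------------


@dataclass
class Ng86Result:
    dn: float
    ds: float  # NaN when the JC correction is undefined (p >= 3/4)
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    n_codons: int

    @property
    def dn_ds(self) -> float:
        if not math.isfinite(self.ds) or self.ds == 0.0:
            return math.nan
        return self.dn / self.ds


def _codon_site_counts(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site counts of one sense codon.

    At each position the synonymous fraction is taken among the non-stop
    alternative codons.
    """
    aa = _CODE[codon]
    n_sites = 0.0
    s_sites = 0.0
    for pos in range(3):
        syn = 0
        denom = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            denom += 1
            if _CODE[mutant] == aa:
                syn += 1
        if denom:
            s_sites += syn / denom
            n_sites += 1.0 - syn / denom
        else:
            n_sites += 1.0
    return n_sites, s_sites


def _pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (nonsynonymous, synonymous) difference counts."""
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    fallback: list[tuple[int, int]] = []
    for order in itertools.permutations(diff):
        current = codon_a
        nd = sd = 0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
                nd += 1  # step to/through a stop counted as nonsynonymous
            elif current in STOP_CODONS:
                through_stop = True
                nd += 1
            elif _CODE[current] == _CODE[nxt]:
                sd += 1
            else:
                nd += 1
            current = nxt
        (fallback if through_stop else valid).append((nd, sd))
    chosen = valid if valid else fallback
    nd = sum(p[0] for p in chosen) / len(chosen)
    sd = sum(p[1] for p in chosen) / len(chosen)
    return nd, sd


def jukes_cantor(p: float) -> float:
    """JC69 distance d = -(3/4) ln(1 - 4p/3); NaN when p >= 3/4."""
    if p < 0.0:
        raise ValueError("proportion below 0")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_dnds(seq_a: str, seq_b: str) -> Ng86Result:
    """Nei–Gojobori dN and dS between two aligned coding sequences.

    Gap-containing and stop-containing codon pairs are skipped; sequences
    must have equal lengths divisible by 3 with at least one comparable
    codon pair.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences of unequal length")
    if len(seq_a) % 3:
        raise ValueError("aligned length not a multiple of 3")
    n_sites = s_sites = nd = sd = 0.0
    n_codons = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if "-" in ca or "-" in cb:
            continue
        if any(b not in "ACGT" for b in ca + cb):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        na, sa = _codon_site_counts(ca)
        nb, sb = _codon_site_counts(cb)
        n_sites += (na + nb) / 2.0
        s_sites += (sa + sb) / 2.0
        d_n, d_s = _pathway_differences(ca, cb)
        nd += d_n
        sd += d_s
        n_codons += 1
    if n_codons == 0:
        raise ValueError("no comparable codon pairs")
    pn = nd / n_sites if n_sites else 0.0
    ps = sd / s_sites if s_sites else 0.0
    return Ng86Result(
        dn=jukes_cantor(pn),
        ds=jukes_cantor(ps),
        n_sites=n_sites,
        s_sites=s_sites,
        nd=nd,
        sd=sd,
        n_codons=n_codons,
    )


@dataclass
class ConservationTable:
    """Per-gene dN, dS and their ratio (NaN where dS is undefined or zero)."""

    table: pd.DataFrame  # columns gene_id, dn, ds, dn_ds

    @classmethod
    def from_alignments(cls, alignments: Mapping[str, "object"]) -> "ConservationTable":
        rows = []
        for gene_id, aln in alignments.items():
            res = ng86_dnds(aln.focal, aln.outgroup2)
            rows.append(
                {"gene_id": gene_id, "dn": res.dn, "ds": res.ds, "dn_ds": res.dn_ds}
            )
        return cls(table=pd.DataFrame(rows))

    @classmethod
    def from_tsv(cls, path) -> "ConservationTable":
        df = pd.read_csv(path, sep="\t")
        required = {"gene_id", "dn_ds"}
        if not required.issubset(df.columns):
            raise ValueError(f"dN/dS table must contain columns {sorted(required)}")
        if "dn" not in df.columns:
            df["dn"] = np.nan
        if "ds" not in df.columns:
            df["ds"] = np.nan
        return cls(table=df[["gene_id", "dn", "ds", "dn_ds"]])

    def ratio_by_gene(self) -> dict[str, float]:
        return {
            r.gene_id: r.dn_ds
            for r in self.table.itertuples()
            if math.isfinite(r.dn_ds)
        }


# ---------------------------------------------------------------------------
# 50-bin delta-tAI vs conservation
# ---------------------------------------------------------------------------


@dataclass
class BinSeries:
    """Mean delta-tAI per dN/dS rank bin (near-equal bin sizes)."""

    table: pd.DataFrame  # columns bin, n, mean_delta_tai, se_delta_tai
    rho: float
    pvalue: float
    rho_per_mutation: float
    pvalue_per_mutation: float


def bin_and_correlate(
    deltas: Sequence[float],
    gene_ids: Sequence[str],
    conservation: ConservationTable | Mapping[str, float],
    n_bins: int = 50,
) -> BinSeries:
    """Bin synonymous delta-tAI values by host-gene dN/dS rank and correlate.

    Mutations are sorted by their host gene's dN/dS and split into
    ``n_bins`` rank bins whose sizes differ by at most one.  The reported
    Spearman correlation is between bin rank (1..n_bins) and bin mean
    delta-tAI; the per-mutation Spearman (dN/dS vs delta-tAI) is reported
    alongside.  Correlations on constant vectors are NaN.
    """
    ratios = (
        conservation.ratio_by_gene()
        if isinstance(conservation, ConservationTable)
        else dict(conservation)
    )
    pairs = [
        (ratios[g], float(d))
        for g, d in zip(gene_ids, deltas, strict=True)
        if g in ratios
    ]
    if len(pairs) < n_bins:
        raise ValueError(f"{len(pairs)} usable mutations for {n_bins} bins")
    pairs.sort(key=lambda t: t[0])
    values = np.array([d for _, d in pairs])
    ratios_sorted = np.array([r for r, _ in pairs])
    chunks = np.array_split(values, n_bins)
    rows = []
    for b, chunk in enumerate(chunks, start=1):
        rows.append(
            {
                "bin": b,
                "n": len(chunk),
                "mean_delta_tai": float(chunk.mean()),
                "se_delta_tai": float(chunk.std(ddof=1) / math.sqrt(len(chunk)))
                if len(chunk) > 1
                else math.nan,
            }
        )
    table = pd.DataFrame(rows)
    means = table["mean_delta_tai"].to_numpy()
    if np.allclose(means, means[0]):
        rho, p = math.nan, math.nan
    else:
        rho, p = sps.spearmanr(table["bin"], means)
    if np.allclose(values, values[0]) or np.allclose(ratios_sorted, ratios_sorted[0]):
        rho_m, p_m = math.nan, math.nan
    else:
        rho_m, p_m = sps.spearmanr(ratios_sorted, values)
    return BinSeries(
        table=table,
        rho=float(rho),
        pvalue=float(p),
        rho_per_mutation=float(rho_m),
        pvalue_per_mutation=float(p_m),
    )


# ---------------------------------------------------------------------------
# LD controls
# ---------------------------------------------------------------------------


def adjacent_distances(positions: Iterable[tuple[str, int]]) -> list[int]:
    """Distances (bp) between adjacent sites, per chromosome, never bridged."""
    by_chrom: dict[str, list[int]] = defaultdict(list)
    for chrom, pos in positions:
        by_chrom[chrom].append(pos)
    distances: list[int] = []
    for chrom in sorted(by_chrom):
        ps = sorted(by_chrom[chrom])
        distances.extend(b - a for a, b in zip(ps, ps[1:]))
    return distances


def pick_per_gene(mutations: Sequence[PolarizedMutation]) -> list[PolarizedMutation]:
    """Keep, per gene, the mutation closest to the transcript 5' end.

    5'-most is strand-aware: the smallest transcript coordinate, i.e. the
    largest genomic position on minus-strand genes.  Ties (same site seen on
    several transcripts) break by transcript id.
    """
    best: dict[str, PolarizedMutation] = {}

    def key(p: PolarizedMutation) -> tuple[int, int, str]:
        m = p.mutation
        return (3 * m.codon_index + m.offset, m.position, m.transcript_id)

    for p in mutations:
        g = p.mutation.gene_id
        if g not in best or key(p) < key(best[g]):
            best[g] = p
    return sorted(best.values(), key=lambda p: (p.mutation.chrom, p.mutation.position))
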