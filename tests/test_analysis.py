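"""Rank-sum tests, Bonferroni, NG86 dN/dS, binning, LD controls."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from codonsel import analysis, classify
from codonsel.analysis import (
    ConservationTable,
    adjacent_distances,
    adjust_pvalues,
    bin_and_correlate,
    daf_spectrum_report,
    ng86_dnds,
    pick_per_gene,
    rank_sum_test,
)
from codonsel.classify import AnnotatedMutation
from codonsel.polarize import PolarizedMutation
from codonsel.synthetic_data import _evolve_cds


def enumeration_oracle(x, y):
    """Independent two-sided exact rank-sum p by enumerating rank assignments."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    sums = [
        sum(ranks[i] for i in combo)
        for combo in itertools.combinations(range(len(pooled)), n1)
    ]
    n_le = sum(s <= w_obs + 1e-9 for s in sums)
    n_ge = sum(s >= w_obs - 1e-9 for s in sums)
    return min(1.0, 2.0 * min(n_le, n_ge) / len(sums))


class TestRankSum:
    def test_disjoint_groups_exact_value(self):
        r = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert r.method == "exact"
        assert r.pvalue == pytest.approx(0.1)
        assert r.direction == "b_greater"

    def test_identical_multisets_give_p_one(self):
        r = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.pvalue == 1.0
        assert r.direction == "none"

    def test_exact_branch_matches_enumeration_with_ties(self, rng):
        for _ in range(60):
            n1 = int(rng.integers(1, 9))
            n2 = int(rng.integers(1, 9))
            x = rng.integers(0, 5, size=n1).astype(float)
            y = rng.integers(0, 5, size=n2).astype(float)
            r = rank_sum_test(x, y)
            assert r.method == "exact"
            assert r.pvalue == pytest.approx(enumeration_oracle(x, y), abs=1e-12)

    def test_asymptotic_matches_reference_implementation(self, rng):
        for loc in (0.0, 0.3):
            x = rng.normal(size=400)
            y = rng.normal(loc, size=350)
            r = rank_sum_test(x, y)
            assert r.method == "asymptotic"
            expected = sps.mannwhitneyu(x, y, method="asymptotic").pvalue
            assert r.pvalue == pytest.approx(expected, abs=1e-6)

    def test_asymptotic_tie_correction_matches_reference(self, rng):
        x = rng.integers(0, 8, size=300).astype(float)
        y = rng.integers(0, 8, size=280).astype(float)
        r = rank_sum_test(x, y)
        expected = sps.mannwhitneyu(x, y, method="asymptotic").pvalue
        assert r.pvalue == pytest.approx(expected, abs=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestAdjustPvalues:
    def test_bonferroni(self):
        assert adjust_pvalues([0.01], 3) == [pytest.approx(0.03)]
        assert adjust_pvalues([0.9], 3) == [1.0]
        assert adjust_pvalues([0.4]) == [0.4]

    def test_validation(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.1, 0.2], 1)
        with pytest.raises(ValueError):
            adjust_pvalues([1.5])


def make_polarized(daf, mclass="synonymous", delta=0.1, iso=True, context="isoaccepting"):
    m = AnnotatedMutation(
        snp=None, transcript_id="t", gene_id="g", chrom="1", strand="+",
        codon_index=2, offset=0, ref_codon="GCC", alt_codon="GCT",
        mclass=mclass, isoaccepting=iso if mclass == "synonymous" else None,
        delta_tai=delta if mclass == "synonymous" else None, context=context,
    )
    return PolarizedMutation(mutation=m, ancestral="C", derived="T", daf=daf, n_called=100)


class TestDafSpectrumReport:
    def test_direction_and_adjustment(self, rng):
        ups = [make_polarized(d, delta=0.2) for d in rng.uniform(0.3, 0.9, 300)]
        downs = [make_polarized(d, delta=-0.2) for d in rng.uniform(0.0, 0.4, 300)]
        summary, tests = daf_spectrum_report(ups + downs)
        by_pair = {(t.group_a, t.group_b): t for t in tests}
        t = by_pair[("tai_up", "tai_down")]
        assert t.direction == "a_greater"
        assert t.p_adjusted == pytest.approx(min(1.0, t.pvalue * len(tests)))
        assert set(summary.columns) == {"group", "n", "mean_daf", "median_daf"}

    def test_single_mutation_group_skipped(self):
        pols = [make_polarized(0.1, delta=0.2)] + [
            make_polarized(d, delta=-0.2) for d in (0.1, 0.2, 0.3)
        ]
        _, tests = daf_spectrum_report(pols)
        assert ("tai_up", "tai_down") not in {(t.group_a, t.group_b) for t in tests}


class TestNg86:
    def test_identical_sequences(self):
        r = ng86_dnds("ATGGCAGCT", "ATGGCAGCT")
        assert (r.dn, r.ds) == (0.0, 0.0)

    def test_hand_counted_synonymous_pair(self):
        # GCC and GCG each have exactly 1 synonymous site (3rd position);
        # with a second identical codon: S=2, Sd=1, pS=1/2 -> JC distance
        r = ng86_dnds("GCCGCC", "GCGGCC")
        assert r.s_sites == pytest.approx(2.0)
        assert r.n_sites == pytest.approx(4.0)
        assert (r.nd, r.sd) == (0.0, 1.0)
        assert r.dn == 0.0
        assert r.ds == pytest.approx(-0.75 * math.log(1 - 2 / 3))

    def test_single_codon_pair_saturates_jc(self):
        # pS = 1 >= 3/4: the correction is undefined by construction
        r = ng86_dnds("GCC", "GCG")
        assert r.dn == 0.0
        assert math.isnan(r.ds)

    def test_symmetry(self, rng):
        a = "ATGGCATTGCGATGGTTTAAAGGG"
        b = "ATGGGATTGCGTTGGTTCAAAGGA"
        r1, r2 = ng86_dnds(a, b), ng86_dnds(b, a)
        assert r1.dn == pytest.approx(r2.dn)
        assert r1.ds == pytest.approx(r2.ds)

    def test_monotone_in_divergence_and_neutral_ratio(self, rng):
        base = "".join(
            rng.choice([c for c in classify.SENSE_CODONS if c != "ATG"], size=2000)
        )
        prev_dn = prev_ds = -1.0
        for d in (0.02, 0.08, 0.2):
            evolved = _evolve_cds(base, d, 1.0, rng)
            r = ng86_dnds(base, evolved)
            assert r.dn > prev_dn and r.ds > prev_ds
            prev_dn, prev_ds = r.dn, r.ds
        # under equal acceptance of all changes dN/dS is near neutral
        assert r.dn_ds == pytest.approx(1.0, abs=0.25)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            ng86_dnds("ATG", "ATGGCA")
        with pytest.raises(ValueError):
            ng86_dnds("---", "---")


class TestBinAndCorrelate:
    def _conservation(self, genes):
        return {g: i / len(genes) for i, g in enumerate(genes)}

    def test_constant_deltas_yield_nan(self):
        genes = [f"g{i}" for i in range(100)]
        series = bin_and_correlate([0.5] * 100, genes, self._conservation(genes), n_bins=10)
        assert math.isnan(series.rho)

    def test_monotone_construction_gives_perfect_negative_rho(self):
        genes = [f"g{i:03d}" for i in range(200)]
        cons = {g: i / 200 for i, g in enumerate(genes)}
        deltas = [-cons[g] for g in genes]
        series = bin_and_correlate(deltas, genes, cons, n_bins=50)
        assert series.rho == pytest.approx(-1.0)

    def test_spearman_equals_rank_then_pearson_oracle(self, rng):
        genes = [f"g{i:03d}" for i in range(120)]
        cons = {g: float(r) for g, r in zip(genes, rng.uniform(0, 1, 120))}
        deltas = rng.normal(size=120)
        series = bin_and_correlate(deltas, genes, cons, n_bins=30)
        means = series.table["mean_delta_tai"].to_numpy()
        expected = sps.pearsonr(
            sps.rankdata(np.arange(1, 31)), sps.rankdata(means)
        ).statistic
        assert series.rho == pytest.approx(expected, abs=1e-12)

    def test_bin_sizes_and_weighted_mean_invariants(self, rng):
        n = 437
        genes = [f"g{i:04d}" for i in range(n)]
        cons = {g: float(r) for g, r in zip(genes, rng.uniform(0, 1, n))}
        deltas = rng.normal(size=n)
        series = bin_and_correlate(deltas, genes, cons, n_bins=50)
        sizes = series.table["n"]
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == n
        weighted = (series.table["n"] * series.table["mean_delta_tai"]).sum() / n
        assert weighted == pytest.approx(deltas.mean(), abs=1e-9)

    def test_too_few_mutations_rejected(self):
        with pytest.raises(ValueError):
            bin_and_correlate([0.1], ["g"], {"g": 0.5}, n_bins=50)


class TestLdControls:
    def test_adjacent_distances(self):
        assert adjacent_distances([("c1", 100), ("c1", 250), ("c1", 400)]) == [150, 150]
        assert adjacent_distances([("c1", 5), ("c2", 9)]) == []
        shuffled = adjacent_distances([("c1", 400), ("c1", 100), ("c1", 250)])
        assert shuffled == [150, 150]

    def _mut(self, gene, chrom, pos, strand, codon_index):
        from codonsel.genome_io import SNPRecord

        snp = SNPRecord(
            chrom=chrom, pos=pos, ref="C", alt="T",
            genotypes=np.zeros(4, dtype=np.int8),
        )
        m = AnnotatedMutation(
            snp=snp, transcript_id=f"{gene}.1", gene_id=gene, chrom=chrom,
            strand=strand, codon_index=codon_index, offset=0, ref_codon="GCC",
            alt_codon="GCT", mclass="synonymous", isoaccepting=True,
            delta_tai=0.1, context="nonsynonymous",
        )
        return PolarizedMutation(mutation=m, ancestral="C", derived="T", daf=0.1, n_called=10)

    def test_minus_strand_keeps_downstream_genomic_position(self):
        # codon_index encodes transcript order: on "-" the 5'-most mutation
        # has the larger genomic coordinate
        a = self._mut("g1", "c1", 100, "-", codon_index=50)
        b = self._mut("g1", "c1", 500, "-", codon_index=3)
        (kept,) = pick_per_gene([a, b])
        assert kept.mutation.position == 500

    def test_at_most_one_per_gene(self, rng):
        muts = [
            self._mut(f"g{int(g)}", "c1", int(p), "+", codon_index=int(p))
            for g, p in zip(rng.integers(0, 20, 200), rng.integers(1, 10_000, 200))
        ]
        kept = pick_per_gene(muts)
        genes = [p.mutation.gene_id for p in kept]
        assert len(genes) == len(set(genes))
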