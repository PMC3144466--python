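"""dN/dS estimation, QC boundaries, LRTs, selection verdicts, statistics."""

import warnings
from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as scipy_stats

from plugprot.evolve import (
    fisher_exact_2x2,
    five_species_qc,
    lrt_pvalue,
    ng86_dnds,
    pairwise_qc,
    selection_verdict,
    verdict_table,
    wilcoxon_rank_sum,
)


class TestNg86:
    def test_identical_sequences(self):
        result = ng86_dnds("TTTGCG", "TTTGCG")
        assert result.dn == 0.0 and result.ds == 0.0
        assert result.omega is None

    def test_single_synonymous_difference(self):
        result = ng86_dnds("GGA", "GGG")  # Gly -> Gly
        assert result.dn == 0.0
        assert result.ds > 0.0

    def test_single_nonsynonymous_difference(self):
        result = ng86_dnds("AAA", "GAA")  # Lys -> Glu
        assert result.dn > 0.0
        assert result.ds == 0.0

    def test_symmetry(self):
        a, b = "TTTGCGAAAGGC", "TTAGCAAAAGGA"
        fwd, rev = ng86_dnds(a, b), ng86_dnds(b, a)
        assert fwd.dn == pytest.approx(rev.dn, abs=1e-12)
        assert fwd.ds == pytest.approx(rev.ds, abs=1e-12)

    def test_matches_independent_pathway_oracle(self):
        """Random codon pairs agree with the reference NG86 implementation
        (Bio.codonalign) to 1e-9."""
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        rng = np.random.default_rng(0)
        bases = list("ACGT")
        stops = {"TAA", "TAG", "TGA"}

        def random_cds(n_codons):
            while True:
                codons = [
                    "".join(rng.choice(bases, 3)) for _ in range(n_codons)
                ]
                if not any(c in stops for c in codons):
                    return "".join(codons)

        def mutate(seq, k):
            while True:
                chars = list(seq)
                for pos in rng.choice(len(chars), size=k, replace=False):
                    chars[pos] = rng.choice([b for b in bases if b != chars[pos]])
                candidate = "".join(chars)
                codons = [candidate[i : i + 3] for i in range(0, len(candidate), 3)]
                if not any(c in stops for c in codons):
                    return candidate

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(5):
                a = random_cds(25)
                b = mutate(a, 4)
                mine = ng86_dnds(a, b)
                dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
                assert mine.dn == pytest.approx(dn, abs=1e-9)
                assert mine.ds == pytest.approx(ds, abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ng86_dnds("TTT", "TTTGGG")

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            ng86_dnds("TAAGGG", "TTTGGG")


class TestPairwiseQc:
    @pytest.mark.parametrize(
        "codons,dn,ds,kept,reason",
        [
            (99, 0.1, 0.2, False, "codons"),
            (100, 0.1, 0.2, True, ""),
            (150, 1.0, 0.2, True, ""),  # dN = 1 kept (strict > 1 removed)
            (150, 1.01, 0.2, False, "dn"),
            (150, 0.1, 0.381, False, "ds"),  # dS = 0.381 removed (>= boundary)
            (150, 0.1, 0.380, True, ""),
        ],
    )
    def test_printed_boundary_semantics(self, codons, dn, ds, kept, reason):
        table = pd.DataFrame(
            [{"gene_id": "g", "aligned_codons": codons, "dN": dn, "dS": ds}]
        )
        kept_table, removed_table = pairwise_qc(table)
        if kept:
            assert len(kept_table) == 1 and removed_table.empty
        else:
            assert kept_table.empty and len(removed_table) == 1
            assert reason in removed_table.loc[0, "qc_reasons"]

    def test_negative_rates_rejected(self):
        table = pd.DataFrame(
            [{"gene_id": "g", "aligned_codons": 200, "dN": -0.1, "dS": 0.2}]
        )
        with pytest.raises(ValueError, match="negative"):
            pairwise_qc(table)


class TestFiveSpeciesQc:
    @pytest.mark.parametrize(
        "ratio,kept", [(2.1, False), (2.0, True), (0.5, True)]
    )
    def test_twice_genome_median_boundary(self, ratio, kept):
        fits = pd.DataFrame([{"gene_id": "g", "pairwise_dS_max_ratio": ratio}])
        kept_table, removed_table = five_species_qc(fits)
        assert (len(kept_table) == 1) is kept
        assert (len(removed_table) == 1) is not kept


class TestLrt:
    def test_zero_gap_gives_p_one(self):
        two_dl, p = lrt_pvalue(-100.0, -100.0, df=1)
        assert two_dl == 0.0 and p == 1.0

    def test_p_strictly_decreasing_in_statistic(self):
        ps = [lrt_pvalue(0.0, g, df=2)[1] for g in (0.0, 1.0, 5.0, 15.0)]
        assert all(b < a for a, b in zip(ps, ps[1:]))

    def test_reported_statistics_fall_below_printed_bounds(self):
        assert lrt_pvalue(0.0, 29.8 / 2, df=2)[1] < 1e-6
        assert lrt_pvalue(0.0, 22.9 / 2, df=1)[1] < 1e-5
        assert lrt_pvalue(0.0, 9.81 / 2, df=2)[1] < 0.01

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            lrt_pvalue(0.0, 1.0, df=0)

    def test_large_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            lrt_pvalue(0.0, -1.0, df=1)


def make_fit(**overrides):
    fit = {
        "gene_id": "gene",
        "lnL_M7": -1000.0,
        "lnL_M8": -1000.0 + 29.8 / 2,
        "lnL_M8a": -1000.0 + 29.8 / 2 - 22.9 / 2,
        "omega_extra": 3.8,
        "prop_extra": 0.049,
        "fel_sites": 2,
    }
    fit.update(overrides)
    return fit


class TestSelectionVerdict:
    def test_lactotransferrin_style_fit_is_selected(self):
        verdict = selection_verdict(make_fit())
        assert verdict.selected
        assert all(
            [verdict.c1_m7_vs_m8, verdict.c2_m8a_vs_m8, verdict.c3_omega_gt,
             verdict.c4_prop_ge, verdict.c5_fel_sites]
        )

    def test_omega_at_or_below_threshold_fails_c3(self):
        verdict = selection_verdict(make_fit(omega_extra=1.05))
        assert not verdict.c3_omega_gt and not verdict.selected

    def test_small_extra_class_fails_c4(self):
        verdict = selection_verdict(make_fit(prop_extra=0.005))
        assert not verdict.c4_prop_ge and not verdict.selected

    def test_prop_exactly_one_percent_passes_c4(self):
        assert selection_verdict(make_fit(prop_extra=0.01)).c4_prop_ge

    def test_no_fel_sites_fails_c5(self):
        verdict = selection_verdict(make_fit(fel_sites=0))
        assert not verdict.c5_fel_sites and not verdict.selected

    def test_missing_likelihood_rejected(self):
        with pytest.raises(ValueError, match="lnL_M8a"):
            selection_verdict(make_fit(lnL_M8a=float("nan")))

    def test_table_conjunction_invariant(self):
        fits = pd.DataFrame(
            [make_fit(), make_fit(omega_extra=0.9), make_fit(fel_sites=0)]
        )
        table = verdict_table(fits)
        expected = table[["c1", "c2", "c3", "c4", "c5"]].all(axis=1)
        assert (table["selected"] == expected).all()


class TestWilcoxon:
    def test_complete_separation_small_sample(self):
        w, p = wilcoxon_rank_sum([3, 4], [1, 2])
        assert w == 4
        assert p == pytest.approx(2 / 6)

    def test_tied_singletons(self):
        w, p = wilcoxon_rank_sum([1.0], [1.0])
        assert w == 0.5
        assert p == 1.0

    @staticmethod
    def enumeration_oracle(x, y):
        """Exact two-sided p by full enumeration of rank assignments."""
        n1, n2 = len(x), len(y)
        pooled = np.concatenate([x, y])
        ranks = scipy_stats.rankdata(pooled)
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
        offset = n1 * (n1 + 1) / 2.0
        u_all = np.array(
            [sum(c) - offset for c in combinations(range(1, n1 + n2 + 1), n1)]
        )
        p_low = np.mean(u_all <= u_obs + 1e-9)
        p_high = np.mean(u_all >= u_obs - 1e-9)
        return min(1.0, 2.0 * min(p_low, p_high))

    @pytest.mark.parametrize("n1,n2,seed", [(3, 5, 1), (4, 4, 2), (2, 6, 3), (6, 5, 4)])
    def test_exact_p_matches_full_enumeration(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        _, p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(self.enumeration_oracle(x, y), rel=1e-9)

    def test_exact_null_is_super_uniform(self):
        """Full enumeration at n = m = 4: P(p <= a) <= a for every a."""
        values = np.arange(1, 9, dtype=float)
        pvals = []
        for first in combinations(range(8), 4):
            x = values[list(first)]
            y = values[[i for i in range(8) if i not in first]]
            pvals.append(wilcoxon_rank_sum(x, y)[1])
        pvals = np.array(pvals)
        for alpha in (0.05, 0.1, 0.2, 0.35, 0.5, 0.75, 1.0):
            assert np.mean(pvals <= alpha) <= alpha + 1e-12

    def test_power_under_one_sd_shift(self):
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(100):
            x = rng.normal(1.0, 1.0, size=50)
            y = rng.normal(0.0, 1.0, size=50)
            hits += wilcoxon_rank_sum(x, y)[1] < 0.01
        assert hits >= 95

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


def fisher_oracle(a, b, c, d):
    """Exact rational two-sided Fisher p (point-probability rule)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(a2):
        return Fraction(
            comb(r1, a2) * comb(r2, c1 - a2), comb(n, c1)
        )

    p_obs = prob(a)
    total = Fraction(0)
    for a2 in range(max(0, c1 - r2), min(r1, c1) + 1):
        if prob(a2) <= p_obs:
            total += prob(a2)
    return float(total)


class TestFisherExact:
    def test_diagonal_table(self):
        assert fisher_exact_2x2(2, 0, 0, 2) == pytest.approx(1 / 3)

    def test_balanced_table_p_one(self):
        assert fisher_exact_2x2(1, 1, 1, 1) == 1.0

    def test_printed_ortholog_table_below_bound(self):
        assert fisher_exact_2x2(29, 25, 303, 126) < 0.02

    @pytest.mark.parametrize(
        "table",
        [(2, 3, 4, 1), (0, 5, 5, 0), (3, 3, 3, 3), (1, 4, 2, 5), (6, 0, 2, 4)],
    )
    def test_matches_enumeration_oracle(self, table):
        assert fisher_exact_2x2(*table) == pytest.approx(
            fisher_oracle(*table), rel=1e-9
        )

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(0, 0, 0, 0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 1, 1, 1)
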