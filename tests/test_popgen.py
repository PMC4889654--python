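"""Diversity/differentiation statistics against independent brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

import radpop
from radpop.popgen import (
    hwe_exact, hwe_exact_pvalue, nucleotide_diversity, observed_heterozygosity,
    pairwise_fst, snp_density, tajimas_d, tajimas_d_value, wc_fst,
)
from conftest import make_gm


# ---------------------------------------------------------------------------
# independent oracles

def tajima_oracle(haplotypes):
    """Tajima's D computed directly from a haplotype list: mean pairwise
    differences vs Watterson, with the 1989 constants transcribed afresh."""
    H = np.asarray(haplotypes)
    n, _ = H.shape
    seg = [j for j in range(H.shape[1]) if 0 < H[:, j].sum() < n]
    S = len(seg)
    if S == 0 or n < 4:
        return float("nan")
    k = np.mean([np.sum(H[i] != H[j]) for i, j in itertools.combinations(range(n), 2)])
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (k - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def hwe_enumeration_oracle(n_het, n_hom1, n_hom2):
    """Exact HWE p by enumerating every heterozygote count of matching parity."""
    n = n_het + n_hom1 + n_hom2
    n_a = 2 * n_hom1 + n_het          # copies of the "hom1" allele
    rare = min(n_a, 2 * n - n_a)

    def prob(h):
        hr = (rare - h) // 2
        hc = n - h - hr
        if hr < 0 or hc < 0:
            return 0.0
        return float(np.exp(
            gammaln(n + 1) - gammaln(h + 1) - gammaln(hr + 1) - gammaln(hc + 1)
            + h * np.log(2) - (gammaln(2 * n + 1) - gammaln(rare + 1)
                               - gammaln(2 * n - rare + 1))
        ))

    hets = range(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    probs = {h: prob(h) for h in hets}
    total = sum(probs.values())
    obs = probs[n_het] / total
    return sum(p for p in probs.values() if p / total <= obs * (1 + 1e-12)) / total


def hand_bh(pvals):
    """Benjamini–Hochberg step-up, written out directly."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = m - rank_from_top          # 1-based rank
        running = min(running, pvals[idx] * m / i)
        adj[idx] = running
    return adj


# ---------------------------------------------------------------------------

class TestHeterozygosity:
    def test_all_het_and_all_hom(self):
        ho, _ = observed_heterozygosity(make_gm(np.ones((3, 5), dtype=int)))
        assert (ho == 1.0).all()
        ho, _ = observed_heterozygosity(make_gm(np.full((3, 5), 2)))
        assert (ho == 0.0).all()

    def test_hand_counted_fractions(self):
        calls = np.array([
            [1, 1, 0, 2],              # 2/4 het
            [1, 0, 0, 0],              # 1/4
            [-1, 1, 1, 1],             # 3/3
            [-1, -1, -1, -1],          # no calls -> NaN
        ])
        popmap = pd.DataFrame({"sample_id": [f"s{i}" for i in range(4)],
                               "population": ["A", "A", "B", "B"]})
        ho, ho_pop = observed_heterozygosity(make_gm(calls), popmap)
        assert ho.tolist()[:3] == [0.5, 0.25, 1.0]
        assert np.isnan(ho.iloc[3])
        assert ho_pop["A"] == pytest.approx(0.375)
        assert ho_pop["B"] == pytest.approx(1.0)  # NaN individual excluded


class TestNucleotideDiversity:
    def test_single_site_formula(self):
        # p=0.5, 10 alleles, one 1000-bp window
        calls = np.array([[1], [1], [0], [2], [1]])
        windows, avg = nucleotide_diversity(make_gm(calls, positions=[100]),
                                            1000, {"chr1": 1000})
        expected = (2 * 0.5 * 0.5 * 10 / 9) / 1000
        assert windows["value"].iloc[0] == pytest.approx(expected, rel=1e-12)
        assert avg == pytest.approx(expected, rel=1e-12)

    def test_empty_window_zero(self):
        calls = np.array([[1], [0]])
        windows, _ = nucleotide_diversity(make_gm(calls, positions=[1500]),
                                          1000, {"chr1": 2000})
        assert windows["value"].iloc[0] == 0.0
        assert windows["n_snps"].iloc[1] == 1

    def test_invariant_under_sample_permutation(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 3, (8, 20))
        _, a = nucleotide_diversity(make_gm(calls), 100)
        _, b = nucleotide_diversity(make_gm(calls[rng.permutation(8)]), 100)
        assert a == pytest.approx(b, rel=1e-12)


class TestTajimasD:
    def test_matches_brute_force_oracle(self):
        """Genotype-based windowed D equals the haplotype-pairwise-difference
        oracle on a 10-haplotype window, to 1e-9."""
        rng = np.random.default_rng(11)
        for trial in range(5):
            haps = rng.integers(0, 2, (10, 6))
            if not any(0 < haps[:, j].sum() < 10 for j in range(6)):
                continue
            calls = haps[0::2] + haps[1::2]
            gm = make_gm(calls, positions=np.arange(1, 7) * 10)
            windows, _, _ = tajimas_d(gm, 1000, {"chr1": 1000})
            assert windows["value"].iloc[0] == pytest.approx(
                tajima_oracle(haps), abs=1e-9)

    def test_zero_when_estimators_agree(self):
        # when theta_pi exactly equals Watterson's S/a1 the numerator vanishes
        for n, S in [(10, 3), (20, 7)]:
            a1 = sum(1.0 / i for i in range(1, n))
            assert tajimas_d_value(S / a1, S, n) == pytest.approx(0.0, abs=1e-12)

    def test_no_snps_undefined(self):
        windows, avg_all, avg_snp = tajimas_d(
            make_gm(np.array([[1, 0], [1, 2]]), positions=[10, 20]),
            100, {"chr1": 300})
        assert not windows["defined"].iloc[2]
        assert np.isnan(windows["value"].iloc[2])

    def test_two_averages(self):
        # one defined window (D) and empty windows counted as 0 in avg_all
        calls = np.array([[1, 1, 0], [0, 1, 2], [1, 0, 1], [2, 1, 0], [0, 0, 2]])
        windows, avg_all, avg_snp = tajimas_d(
            make_gm(calls, positions=[10, 20, 30]), 100, {"chr1": 500})
        d = windows["value"].iloc[0]
        assert avg_snp == pytest.approx(d)
        assert avg_all == pytest.approx(d / 5)

    def test_too_few_sequences_undefined(self):
        assert np.isnan(tajimas_d_value(1.0, 2, 3))


class TestHweExact:
    def test_perfect_proportions_p_one(self):
        assert hwe_exact_pvalue(50, 25, 25) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("counts", [(0, 5, 5), (2, 4, 4), (10, 0, 0),
                                        (3, 7, 2), (6, 1, 13)])
    def test_matches_full_enumeration(self, counts):
        het, h1, h2 = counts
        assert hwe_exact_pvalue(het, h1, h2) == pytest.approx(
            hwe_enumeration_oracle(het, h1, h2), abs=1e-10)

    def test_all_het_extreme_significant(self):
        for n in (10, 20, 50):
            assert hwe_exact_pvalue(n, 0, 0) < 0.05

    def test_monomorphic_p_one(self):
        assert hwe_exact_pvalue(0, 10, 0) == 1.0

    def test_bh_flags_superset_of_bonferroni(self):
        rng = np.random.default_rng(2)
        calls = rng.integers(0, 3, (30, 60))
        calls[:, :5] = 1               # strongly out of HWE
        res = hwe_exact(make_gm(calls))
        assert (res["p_hwe"] > 0).all() and (res["p_hwe"] <= 1).all()
        bonf = set(res.index[res["flag_bonferroni"]])
        bh = set(res.index[res["flag_bh"]])
        assert bonf <= bh
        assert len(bonf) >= 1

    def test_bh_adjustment_matches_hand_step_up(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 3, (20, 40))
        res = hwe_exact(make_gm(calls))
        assert np.allclose(res["p_bh"], hand_bh(res["p_hwe"].to_numpy()))


class TestWcFst:
    def _popmap(self, gm, pops):
        return pd.DataFrame({"sample_id": gm.sample_ids, "population": pops})

    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(4)
        col = rng.integers(0, 3, 200)
        # both populations carry the exact same genotype column
        gm = make_gm(np.concatenate([col, col]).reshape(-1, 1))
        res = wc_fst(gm, self._popmap(gm, ["A"] * 200 + ["B"] * 200))
        assert abs(res.weighted_fst) < 0.01

    def test_fixed_difference_is_one(self):
        gm = make_gm(np.array([[0], [0], [0], [2], [2], [2]]))
        res = wc_fst(gm, self._popmap(gm, ["A"] * 3 + ["B"] * 3))
        assert res.per_site[0] == pytest.approx(1.0)
        assert res.weighted_fst == pytest.approx(1.0)

    def test_mean_equals_weighted_when_denominators_equal(self):
        # duplicated site -> identical components -> the two summaries agree
        calls = np.array([[0, 0], [1, 1], [2, 2], [2, 2], [0, 0], [1, 1]])
        gm = make_gm(calls)
        res = wc_fst(gm, self._popmap(gm, ["A"] * 3 + ["B"] * 3))
        assert res.mean_fst == pytest.approx(res.weighted_fst, rel=1e-12)

    def test_per_site_bounded_by_one(self):
        rng = np.random.default_rng(6)
        calls = rng.integers(0, 3, (40, 100))
        gm = make_gm(calls)
        res = wc_fst(gm, self._popmap(gm, ["A"] * 20 + ["B"] * 20))
        ps = res.per_site
        assert np.nanmax(ps) <= 1.0 + 1e-12
        assert -0.2 < res.weighted_fst < 1.0

    def test_empty_population_rejected(self):
        gm = make_gm(np.array([[0], [1], [-1], [-1]]))
        with pytest.raises(ValueError, match="zero calls"):
            wc_fst(gm, self._popmap(gm, ["A", "A", "B", "B"]))

    def test_pairwise_matrix_layout(self, fixture_run):
        cfg, panel, paths = fixture_run
        gm = radpop.read_vcf(paths["vcf"])
        popmap = radpop.read_popmap(paths["popmap"])
        mat = pairwise_fst(gm, popmap)
        pops = list(mat.index)
        assert len(pops) == cfg.n_populations
        for i, p1 in enumerate(pops):
            for p2 in pops[i + 1:]:
                assert np.isfinite(mat.loc[p1, p2])   # mean above diagonal
                assert np.isfinite(mat.loc[p2, p1])   # weighted below
            assert np.isnan(mat.loc[p1, p1])


class TestSnpDensity:
    def test_two_snps_per_10kb(self):
        gm = make_gm(np.array([[1, 1], [0, 2]]), positions=[100, 5000])
        windows, summary = snp_density(gm, 10_000, {"chr1": 10_000})
        assert summary["mean"] == 2.0

    def test_empty_contig_all_zero(self):
        gm = make_gm(np.array([[1], [0]]), positions=[5])
        windows, _ = snp_density(gm, 100, {"chr1": 100, "chr2": 500})
        chr2 = windows[windows["contig"] == "chr2"]
        assert len(chr2) == 5 and (chr2["n_snps"] == 0).all()

    def test_known_positions_exact_counts(self):
        pos = [1, 99, 100, 101, 250, 999]
        calls = np.vstack([np.ones(len(pos)), np.zeros(len(pos))]).astype(int)
        windows, _ = snp_density(make_gm(calls, positions=pos), 100, {"chr1": 1000})
        # 1-based windows 1-100, 101-200, ...: pos 100 still falls in the first
        assert windows["n_snps"].tolist() == [3, 1, 1, 0, 0, 0, 0, 0, 0, 1]
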