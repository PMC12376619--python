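"""Frequencies, Weir-Cockerham FST, windowed FST and the di selection scan."""

import numpy as np
import pytest
from scipy import stats

from svpopgen.io import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix
from svpopgen.popgen import (
    DiResult,
    allele_freq,
    carrier_freq,
    di_outliers,
    di_scan,
    di_statistic,
    wc_fst,
    wc_fst_site,
    windowed_fst,
)
from tests.conftest import make_manifest, make_matrix


def wc_oracle(counts):
    """Independent scalar coding of the 1984 variance components.

    ``counts``: per population (n_hom_ref, n_het, n_hom_alt).  Kept free of
    any array machinery so it cannot share a bug with the implementation.
    """
    r = len(counts)
    n = [sum(c) for c in counts]
    p = [(c[1] + 2 * c[2]) / (2 * nn) for c, nn in zip(counts, n)]
    h = [c[1] / nn for c, nn in zip(counts, n)]
    nbar = sum(n) / r
    nc = (sum(n) - sum(x * x for x in n) / sum(n)) / (r - 1)
    pbar = sum(nn * pp for nn, pp in zip(n, p)) / sum(n)
    s2 = sum(nn * (pp - pbar) ** 2 for nn, pp in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(nn * hh for nn, hh in zip(n, h)) / sum(n)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return a, b, c


class TestFrequencies:
    def test_all_het_gives_half(self):
        m = make_matrix({"a": [HET] * 10})
        assert allele_freq(m)[0] == 0.5

    def test_balanced_homozygotes(self):
        m = make_matrix({"a": [HOM_ALT] * 5 + [HOM_REF] * 5})
        assert allele_freq(m)[0] == 0.5

    def test_counting_oracle(self):
        m = make_matrix({"a": [HOM_ALT] * 3 + [HET] + [HOM_REF] * 6})
        assert allele_freq(m)[0] == pytest.approx(7 / 20)

    def test_missing_excluded(self):
        m = make_matrix({"a": [HOM_ALT, MISSING, MISSING, MISSING]})
        assert allele_freq(m)[0] == 1.0
        assert np.isnan(allele_freq(make_matrix({"a": [MISSING, MISSING]}))[0])

    def test_carrier_percent_rounding(self):
        # 13 of 36 carriers -> 36%; 36 of 112 -> 32% (integer percent style)
        m = make_matrix({"a": [HET] * 13 + [HOM_REF] * 23})
        assert carrier_freq(m, as_percent=True)[0] == 36
        m2 = make_matrix({"a": [HOM_ALT] * 36 + [HOM_REF] * 76})
        assert carrier_freq(m2, as_percent=True)[0] == 32

    def test_zero_carriers(self):
        m = make_matrix({"a": [HOM_REF] * 4})
        assert carrier_freq(m, as_percent=True)[0] == 0


class TestWcFst:
    def test_identical_pops_near_zero(self):
        g = [HOM_REF] * 5 + [HET] * 3 + [HOM_ALT] * 2
        res = wc_fst_site([g, g])
        assert res.theta[0] <= 0  # estimator noise around zero, never positive here

    def test_fixed_difference_is_one(self):
        res = wc_fst_site([[HOM_ALT] * 10, [HOM_REF] * 10])
        assert res.theta[0] == pytest.approx(1.0)
        for na, nb in [(2, 2), (2, 17), (8, 3)]:
            res = wc_fst_site([[HOM_ALT] * na, [HOM_REF] * nb])
            assert res.theta[0] == pytest.approx(1.0), (na, nb)

    def test_textbook_example_matches_oracle(self):
        res = wc_fst_site([[HOM_REF] * 5 + [HET] * 5, [HET] * 10])
        a, b, c = wc_oracle([(5, 5, 0), (0, 10, 0)])
        assert res.a[0] == pytest.approx(a, abs=1e-12)
        assert res.b[0] == pytest.approx(b, abs=1e-12)
        assert res.c[0] == pytest.approx(c, abs=1e-12)

    def test_monomorphic_site_flagged(self):
        res = wc_fst_site([[HOM_REF] * 4, [HOM_REF] * 4])
        assert np.isnan(res.theta[0])
        assert res.a[0] == res.b[0] == res.c[0] == 0

    def test_random_configurations_match_oracle(self):
        rng = np.random.default_rng(1234)
        for _ in range(200):
            r = int(rng.integers(2, 5))
            pops, counts = [], []
            for _ in range(r):
                n = int(rng.integers(2, 25))
                g = rng.integers(0, 3, size=n)
                pops.append(g.tolist())
                counts.append(
                    (int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))
                )
            res = wc_fst_site(pops)
            a, b, c = wc_oracle(counts)
            if a + b + c == 0 or (a, b, c) != (a, b, c):  # skip degenerate NaN configs
                continue
            assert abs(res.a[0] - a) < 1e-10
            assert abs(res.b[0] - b) < 1e-10
            assert abs(res.c[0] - c) < 1e-10

    def test_needs_two_pops(self):
        m = make_matrix({"a": [HET, HET]})
        with pytest.raises(ValueError):
            wc_fst(m, {"only": ["s1", "s2"]})


class TestWindowedFst:
    def _comps(self, a, bc):
        from svpopgen.popgen import FstComponents
        a = np.asarray(a, float)
        bc = np.asarray(bc, float)
        return FstComponents(a=a, b=bc, c=np.zeros_like(a))

    def test_single_site_window_equals_site_theta(self):
        comps = self._comps([0.2], [0.3])
        out = windowed_fst([10_000], comps, window=50_000, step=25_000)
        assert out["fst"].iloc[0] == pytest.approx(0.2 / 0.5)

    def test_ratio_of_sums_not_mean_of_ratios(self):
        # components (a=1, b+c=1) and (a=0, b+c=3): window value 1/5, not mean(1/2, 0)
        comps = self._comps([1.0, 0.0], [1.0, 3.0])
        out = windowed_fst([100, 200], comps, window=50_000, step=50_000)
        assert out["fst"].iloc[0] == pytest.approx(1 / 5)

    def test_empty_windows_omitted(self):
        comps = self._comps([0.1], [0.4])
        out = windowed_fst([1_000_000], comps, window=50_000, step=25_000)
        assert (out["n_sites"] > 0).all()

    def test_bad_window(self):
        with pytest.raises(ValueError):
            windowed_fst([1], self._comps([1.0], [1.0]), window=0)


class TestDiStatistic:
    def test_single_pair_collapses_to_zscore(self):
        theta = np.array([0.1, 0.2, 0.3, 0.4, 0.9])
        res = di_statistic({"ctrl": theta})
        expected = (theta - theta.mean()) / theta.std(ddof=1)
        np.testing.assert_allclose(res.di, expected)

    def test_toy_table_matches_spreadsheet_recomputation(self):
        table = {
            "c1": np.array([0.10, 0.05, 0.30, 0.00, 0.55]),
            "c2": np.array([0.20, 0.10, 0.25, 0.05, 0.60]),
            "c3": np.array([0.00, 0.02, 0.10, 0.01, 0.40]),
        }
        res = di_statistic(table)
        expected = np.zeros(5)
        for name in table:
            col = table[name]
            mu = sum(col) / 5
            sd = (sum((x - mu) ** 2 for x in col) / 4) ** 0.5
            expected += (col - mu) / sd
        np.testing.assert_allclose(res.di, expected, rtol=1e-12)
        assert (res.n_pairs == 3).all()

    def test_shift_invariance_per_pair(self):
        rng = np.random.default_rng(0)
        t1 = rng.random(50)
        t2 = rng.random(50)
        base = di_statistic({"a": t1, "b": t2}).di
        shifted = di_statistic({"a": t1 + 0.37, "b": t2}).di
        np.testing.assert_allclose(base, shifted, atol=1e-10)

    def test_nan_theta_excluded_pairwise(self):
        t1 = np.array([0.1, np.nan, 0.3, 0.2])
        t2 = np.array([0.2, 0.1, 0.0, 0.3])
        res = di_statistic({"a": t1, "b": t2})
        assert res.n_pairs.tolist() == [2, 1, 2, 2]
        finite = ~np.isnan(t1)
        mu, sd = t1[finite].mean(), t1[finite].std(ddof=1)
        assert res.pair_means["a"] == pytest.approx(mu)
        assert res.pair_sds["a"] == pytest.approx(sd)

    def test_constant_pair_is_error(self):
        with pytest.raises(ValueError, match="'flat'"):
            di_statistic({"flat": np.full(10, 0.2)})


class TestDiOutliers:
    def _result(self, di):
        di = np.asarray(di, float)
        return DiResult(di=di, n_pairs=np.ones(len(di), int),
                        pair_means={}, pair_sds={}, pair_z={})

    def test_alpha_threshold_is_3_09(self):
        assert stats.norm.isf(0.001) == pytest.approx(3.0902, abs=1e-4)

    def test_extreme_value_flagged(self):
        rng = np.random.default_rng(2)
        di = np.concatenate([rng.normal(0, 1, 2000), [7.0]])
        flags, z, p = di_outliers(self._result(di))
        assert flags[-1]
        assert z[-1] > 3.0902

    def test_constant_di_errors(self):
        with pytest.raises(ValueError):
            di_outliers(self._result(np.full(10, 1.0)))

    def test_empirical_mode_flags_top_fraction(self):
        rng = np.random.default_rng(3)
        di = rng.normal(0, 1, 10_000)
        flags, _, _ = di_outliers(self._result(di), alpha=0.01, method="empirical")
        assert flags.sum() == pytest.approx(100, abs=2)


class TestDiScan:
    def test_pooled_scan_flags_planted_differentiation(self):
        rng = np.random.default_rng(9)
        n_sv, shift_idx = 400, [5, 17]
        samples = [f"t{i}" for i in range(20)] + [f"c{i}" for i in range(20)]
        manifest = make_manifest(
            [(f"t{i}", "T", "target") for i in range(20)]
            + [(f"c{i}", "C1" if i < 10 else "C2", "control") for i in range(20)]
        )
        gt = rng.binomial(2, 0.4, size=(n_sv, 40)).astype(np.int8)
        for i in shift_idx:  # near-fixed difference
            gt[i, :20] = HOM_ALT
            gt[i, 20:] = HOM_REF
        matrix = GenotypeMatrix([f"sv{i}" for i in range(n_sv)], samples, gt)
        out = di_scan(matrix, manifest)
        assert out["outlier"].iloc[shift_idx].all()
        assert out["outlier"].sum() <= len(shift_idx) + 5

    def test_per_population_mode_has_one_scan_per_target_pop(self):
        manifest = make_manifest(
            [("t1", "TA", "target"), ("t2", "TA", "target"),
             ("t3", "TB", "target"), ("t4", "TB", "target"),
             ("c1", "C", "control"), ("c2", "C", "control")]
        )
        rng = np.random.default_rng(4)
        gt = rng.binomial(2, 0.5, size=(100, 6)).astype(np.int8)
        matrix = GenotypeMatrix([f"sv{i}" for i in range(100)],
                                ["t1", "t2", "t3", "t4", "c1", "c2"], gt)
        out = di_scan(matrix, manifest, mode="per_population")
        assert "TA_di" in out.columns and "TB_di" in out.columns
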