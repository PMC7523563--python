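import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from radzone.sexscan import (
    ScanParams,
    default_param_grid,
    optimize_params,
    permutation_test,
    radsex_distribution,
    radsex_test,
    scan_method_I,
    scan_method_II,
    scan_method_III,
)

from conftest import genotype_matrix, sexed_meta


# ---------------------------------------------------------------------------
# independent brute-force re-implementations (test oracles)

def brute_method_I(dosage, sex, system, params):
    het_sex = "M" if system == "XY" else "F"
    hits = []
    for i in range(dosage.shape[0]):
        freqs = {}
        counts = {}
        for s in ("M", "F"):
            vals = [d for d, x in zip(dosage[i], sex) if x == s and not math.isnan(d)]
            counts[s] = len(vals)
            freqs[s] = sum(vals) / (2 * len(vals)) if vals else float("nan")
        if min(counts.values()) < params.min_informative_per_sex:
            continue
        hom_sex = "F" if het_sex == "M" else "M"
        for fh, fo in ((freqs[het_sex], freqs[hom_sex]),
                       (1 - freqs[het_sex], 1 - freqs[hom_sex])):
            if 0.5 - params.het_freq_tol <= fh <= 0.5 and fo <= params.hom_freq_max:
                hits.append(i)
                break
    return hits


def brute_method_II(dosage, sex, system, params):
    het_sex = "M" if system == "XY" else "F"
    hom_sex = "F" if het_sex == "M" else "M"
    hits = []
    for i in range(dosage.shape[0]):
        frac = {}
        counts = {}
        for s in ("M", "F"):
            vals = [d for d, x in zip(dosage[i], sex) if x == s and not math.isnan(d)]
            counts[s] = len(vals)
            frac[s] = sum(1 for v in vals if v == 1) / len(vals) if vals else float("nan")
        if min(counts.values()) < params.min_informative_per_sex:
            continue
        if frac[het_sex] >= params.het_het_min and frac[hom_sex] <= params.hom_het_max:
            hits.append(i)
    return hits


def brute_method_III(presence, sex, system, params):
    het_sex = "M" if system == "XY" else "F"
    hits = []
    for i in range(presence.shape[0]):
        het = [p for p, x in zip(presence[i], sex) if x == het_sex]
        hom = [p for p, x in zip(presence[i], sex) if x != het_sex]
        if sum(hom) == 0 and sum(het) / len(het) >= params.specificity_min:
            hits.append(i)
    return hits


def brute_yates(table):
    """Textbook Yates-corrected chi-squared for a 2x2 table.

    The correction shrinks |O - E| by 0.5 but never past zero.
    """
    a, b = table[0]
    c, d = table[1]
    n = a + b + c + d
    expected = [
        [(a + b) * (a + c) / n, (a + b) * (b + d) / n],
        [(c + d) * (a + c) / n, (c + d) * (b + d) / n],
    ]
    chi2 = 0.0
    for o_row, e_row in zip(table, expected):
        for o, e in zip(o_row, e_row):
            chi2 += max(0.0, abs(o - e) - 0.5) ** 2 / e
    return chi2


def random_instance(seed, n_loci=20, n_males=6, n_females=6, missing=0.1):
    rng = np.random.default_rng(seed)
    dosage = rng.choice([0.0, 1.0, 2.0], size=(n_loci, n_males + n_females))
    dosage[rng.random(dosage.shape) < missing] = np.nan
    return dosage, np.array(["M"] * n_males + ["F"] * n_females)


# ---------------------------------------------------------------------------

class TestMethodI:
    def test_ideal_xy_pattern_flagged_only_under_xy(self, meta_10m10f):
        g = genotype_matrix([[1.0] * 10 + [0.0] * 10])
        params = ScanParams(het_freq_tol=0.05, hom_freq_max=0.05)
        assert scan_method_I(g, meta_10m10f, "XY", params) == ["L1"]
        assert scan_method_I(g, meta_10m10f, "ZW", params) == []

    @pytest.mark.parametrize("tol,expected", [(0.02, []), (0.05, ["L1"]), (0.1, ["L1"])])
    def test_tolerance_boundary_at_male_freq_045(self, meta_10m10f, tol, expected):
        # 9 males dosage 1, 1 male dosage 0 -> sex-limited allele at 9/20 = 0.45
        g = genotype_matrix([[1.0] * 9 + [0.0] + [0.0] * 10])
        params = ScanParams(het_freq_tol=tol, hom_freq_max=0.05)
        assert scan_method_I(g, meta_10m10f, "XY", params) == expected


class TestMethodII:
    def test_fully_heterozygous_males_flagged(self, meta_10m10f):
        g = genotype_matrix([[1.0] * 10 + [0.0] * 10])
        params = ScanParams(het_het_min=0.9, hom_het_max=0.1)
        assert scan_method_II(g, meta_10m10f, "XY", params) == ["L1"]

    @pytest.mark.parametrize("het_min,expected", [(0.9, []), (0.75, ["L1"])])
    def test_heterozygote_fraction_threshold(self, meta_10m10f, het_min, expected):
        g = genotype_matrix([[1.0] * 8 + [0.0, 2.0] + [0.0] * 10])
        params = ScanParams(het_het_min=het_min, hom_het_max=0.1)
        assert scan_method_II(g, meta_10m10f, "XY", params) == expected

    def test_z_polymorphism_mimics_xy_at_relaxed_homogametic_threshold(self):
        # ZW sibship where the father's two Z alleles differ: all sons (ZZ)
        # heterozygous, daughters (ZW) heterozygous for half -- looks XY-like
        # only once the homogametic threshold is relaxed
        sons = [1.0] * 10
        daughters = [1.0] * 5 + [0.0] * 5
        g = genotype_matrix([sons + daughters])
        meta = sexed_meta(10, 10)
        strict = ScanParams(het_het_min=0.9, hom_het_max=0.1)
        relaxed = ScanParams(het_het_min=0.9, hom_het_max=0.5)
        assert scan_method_II(g, meta, "XY", strict) == []
        assert scan_method_II(g, meta, "XY", relaxed) == ["L1"]


class TestMethodIII:
    def make(self, presence, n_m, n_f):
        presence = np.asarray(presence, dtype=bool)
        samples = [f"s{i + 1}" for i in range(n_m + n_f)]
        return presence, sexed_meta(n_m, n_f), samples

    def test_female_specific_tag_flagged_zw(self):
        pres, meta, samples = self.make([[False] * 21 + [True] * 20], 21, 20)
        params = ScanParams(specificity_min=0.9)
        assert scan_method_III(pres, ["t1"], meta, samples, "ZW", params) == ["t1"]
        assert scan_method_III(pres, ["t1"], meta, samples, "XY", params) == []

    def test_boundary_19_of_20_at_specificity_095(self):
        pres, meta, samples = self.make([[False] * 21 + [True] * 19 + [False]], 21, 20)
        params = ScanParams(specificity_min=0.95)
        assert scan_method_III(pres, ["t1"], meta, samples, "ZW", params) == ["t1"]

    def test_single_presence_in_other_sex_disqualifies(self):
        row = [True] + [False] * 20 + [True] * 19 + [False]
        pres, meta, samples = self.make([row], 21, 20)
        params = ScanParams(specificity_min=0.5)
        assert scan_method_III(pres, ["t1"], meta, samples, "ZW", params) == []


class TestScanProperties:
    @settings(max_examples=350, derandomize=True, deadline=None)
    @given(st.integers(0, 10**6))
    def test_methods_I_II_match_brute_force(self, seed):
        dosage, sex = random_instance(seed)
        g = genotype_matrix(dosage)
        meta = sexed_meta(6, 6)
        rng = np.random.default_rng(seed + 1)
        params = ScanParams(
            het_freq_tol=float(rng.uniform(0, 0.5)),
            hom_freq_max=float(rng.uniform(0, 0.5)),
            het_het_min=float(rng.uniform(0.5, 1.0)),
            hom_het_max=float(rng.uniform(0, 0.45)),
            min_informative_per_sex=int(rng.integers(1, 5)),
        )
        for system in ("XY", "ZW"):
            expect_I = [f"L{i + 1}" for i in brute_method_I(dosage, sex, system, params)]
            expect_II = [f"L{i + 1}" for i in brute_method_II(dosage, sex, system, params)]
            assert scan_method_I(g, meta, system, params) == expect_I
            assert scan_method_II(g, meta, system, params) == expect_II

    @settings(max_examples=250, derandomize=True, deadline=None)
    @given(st.integers(0, 10**6))
    def test_method_III_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        presence = rng.random((15, 12)) < 0.6
        sex = np.array(["M"] * 6 + ["F"] * 6)
        meta = sexed_meta(6, 6)
        samples = meta["sample_id"].tolist()
        params = ScanParams(specificity_min=float(rng.uniform(0.3, 1.0)))
        tags = [f"t{i}" for i in range(15)]
        for system in ("XY", "ZW"):
            expect = [tags[i] for i in brute_method_III(presence, sex, system, params)]
            assert scan_method_III(presence, tags, meta, samples, system, params) == expect

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.integers(0, 10**6))
    def test_xy_zw_symmetry_under_sex_relabeling(self, seed):
        dosage, sex = random_instance(seed)
        g = genotype_matrix(dosage)
        meta = sexed_meta(6, 6)
        flipped = meta.copy()
        flipped["sex"] = flipped["sex"].map({"M": "F", "F": "M"})
        params = ScanParams(het_freq_tol=0.2, hom_freq_max=0.2,
                            het_het_min=0.6, hom_het_max=0.3,
                            min_informative_per_sex=1)
        assert scan_method_I(g, meta, "XY", params) == scan_method_I(g, flipped, "ZW", params)
        assert scan_method_II(g, meta, "ZW", params) == scan_method_II(g, flipped, "XY", params)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.integers(0, 10**6))
    def test_candidate_sets_shrink_as_thresholds_tighten(self, seed):
        dosage, sex = random_instance(seed, n_loci=40)
        g = genotype_matrix(dosage)
        meta = sexed_meta(6, 6)
        loose = ScanParams(het_freq_tol=0.3, hom_freq_max=0.3,
                           het_het_min=0.6, hom_het_max=0.3,
                           min_informative_per_sex=1)
        tight = ScanParams(het_freq_tol=0.1, hom_freq_max=0.1,
                           het_het_min=0.9, hom_het_max=0.1,
                           min_informative_per_sex=1)
        assert set(scan_method_I(g, meta, "XY", tight)) <= set(scan_method_I(g, meta, "XY", loose))
        assert set(scan_method_II(g, meta, "XY", tight)) <= set(scan_method_II(g, meta, "XY", loose))


class TestPermutation:
    def test_p_value_formula_when_observed_beats_all_nulls(self):
        g = genotype_matrix(
            np.vstack([[1.0] * 10 + [0.0] * 10] * 5)
        )
        meta = sexed_meta(10, 10)
        params = ScanParams()
        pr = permutation_test(
            lambda m: scan_method_I(g, m, "XY", params), meta, n_permutations=100, seed=0
        )
        assert pr.observed_count == 5
        assert max(pr.null_counts) < 5
        assert pr.p_value == pytest.approx(1 / 101)
        assert pr.significant

    def test_pre_shuffled_labels_are_not_significant(self):
        rng = np.random.default_rng(3)
        g, _, meta, _ = _simulated_xy(seed=3)
        shuffled = meta.copy()
        shuffled["sex"] = rng.permutation(shuffled["sex"].to_numpy())
        params = ScanParams()
        pr = permutation_test(
            lambda m: scan_method_I(g, m, "XY", params), shuffled, 100, seed=4
        )
        assert not pr.significant

    def test_strong_signal_is_significant(self):
        g, truth, meta, _ = _simulated_xy(seed=5)
        params = ScanParams()
        pr = permutation_test(
            lambda m: scan_method_I(g, m, "XY", params), meta, 100, seed=6
        )
        assert pr.observed_count >= 15
        assert pr.significant and pr.p_value == pytest.approx(1 / 101)


def _simulated_xy(seed):
    from radzone.synthdata import SexLinkSimConfig, simulate_sexlinked

    g, t, meta, truth = simulate_sexlinked(
        SexLinkSimConfig(n_autosomal=500, n_sexlinked_snps=20,
                         genotyping_error_rate=0.01, seed=seed)
    )
    return g, truth, meta, t


class TestOptimizeParams:
    def test_setting_with_zero_observed_loses(self):
        g, truth, meta, _ = _simulated_xy(seed=7)
        grid = [
            # no locus reaches 21 informative samples per sex: flags nothing
            ScanParams(het_freq_tol=0.1, hom_freq_max=0.05, min_informative_per_sex=21),
            ScanParams(het_freq_tol=0.1, hom_freq_max=0.05),
        ]
        best, table = optimize_params(g, meta, "XY", grid, method="I",
                                      n_permutations=20, seed=0)
        assert best == grid[1]

    def test_all_zero_observed_returns_none_found(self):
        g = genotype_matrix(np.zeros((5, 20)))
        meta = sexed_meta(10, 10)
        grid = [ScanParams(), ScanParams(het_freq_tol=0.1)]
        best, table = optimize_params(g, meta, "XY", grid, method="I",
                                      n_permutations=10, seed=0)
        assert best is None
        assert len(table) == 2

    def test_tie_breaks_by_observed_count_then_grid_order(self):
        g, truth, meta, _ = _simulated_xy(seed=8)
        # identical settings: scores tie exactly; grid order must decide
        grid = [ScanParams(het_freq_tol=0.1), ScanParams(het_freq_tol=0.1)]
        best, table = optimize_params(g, meta, "XY", grid, method="I",
                                      n_permutations=10, seed=0)
        assert best is grid[0]

    def test_default_grid_has_expected_shape(self):
        grid = default_param_grid()
        assert len(grid) == 36
        assert len({p.specificity_min for p in grid}) == 6


class TestRadsexDistribution:
    def test_all_present_tags_in_single_cell(self):
        presence = np.ones((3, 8), dtype=bool)
        meta = sexed_meta(5, 3)
        dist = radsex_distribution(presence, meta, meta["sample_id"].tolist())
        assert dist.loc[5, 3] == 3
        assert dist.to_numpy().sum() == 3

    def test_marginals_are_preserved(self):
        rng = np.random.default_rng(0)
        presence = rng.random((50, 10)) < 0.5
        meta = sexed_meta(6, 4)
        samples = meta["sample_id"].tolist()
        dist = radsex_distribution(presence, meta, samples)
        assert dist.to_numpy().sum() == 50
        n_m = presence[:, :6].sum(axis=1)
        for k in range(7):
            assert dist.loc[k].sum() == (n_m == k).sum()

    def test_simulated_w_tags_concentrate_on_female_edge(self):
        from radzone.io_formats import tag_presence
        from radzone.synthdata import SexLinkSimConfig, simulate_sexlinked

        _, t, meta, truth = simulate_sexlinked(
            SexLinkSimConfig(n_males=21, n_females=20, n_autosomal=0,
                             n_sexlinked_snps=0, n_sex_specific_tags=30,
                             n_background_tags=0, system="ZW", seed=9)
        )
        dist = radsex_distribution(tag_presence(t, 5), meta, t.samples)
        assert dist.loc[0, 15:].sum() == 30  # zero males, high female counts


class TestRadsexTest:
    def test_yates_chi2_matches_textbook_formula(self):
        # the female-specific W-tag pattern: present 19/20 F, 0/21 M
        presence = np.array([[False] * 21 + [True] * 19 + [False]])
        meta = sexed_meta(21, 20)
        res = radsex_test(presence, meta, meta["sample_id"].tolist())
        expected = brute_yates([[0, 19], [21, 1]])
        assert res["chi2_yates"].iloc[0] == pytest.approx(expected, abs=1e-9)

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(st.integers(0, 10**6))
    def test_yates_chi2_matches_formula_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n_m, n_f = int(rng.integers(2, 30)), int(rng.integers(2, 30))
        m_pres = int(rng.integers(0, n_m + 1))
        f_pres = int(rng.integers(0, n_f + 1))
        total = m_pres + f_pres
        if total == 0 or total == n_m + n_f:
            return
        presence = np.array(
            [[True] * m_pres + [False] * (n_m - m_pres)
             + [True] * f_pres + [False] * (n_f - f_pres)]
        )
        meta = sexed_meta(n_m, n_f)
        res = radsex_test(presence, meta, meta["sample_id"].tolist())
        expected = brute_yates([[m_pres, f_pres], [n_m - m_pres, n_f - f_pres]])
        assert res["chi2_yates"].iloc[0] == pytest.approx(expected, abs=1e-9)

    def test_degenerate_tags_get_chi2_zero(self):
        presence = np.array([[True] * 8, [False] * 8])
        meta = sexed_meta(4, 4)
        res = radsex_test(presence, meta, meta["sample_id"].tolist())
        assert (res["chi2_yates"] == 0).all()
        assert (res["p_raw"] == 1).all()
        assert not res["significant"].any()
        assert res.attrs["n_tests"] == 0

    def test_equal_presence_is_not_significant(self):
        presence = np.array([[True] * 10 + [False] * 10 + [True] * 10 + [False] * 10])
        meta = sexed_meta(20, 20)
        res = radsex_test(presence, meta, meta["sample_id"].tolist())
        assert res["chi2_yates"].iloc[0] < 0.5
        assert not res["significant"].iloc[0]

    def test_bonferroni_uses_testable_tag_count(self):
        presence = np.array([[True] * 8, [False] * 8, [True] * 4 + [False] * 4])
        meta = sexed_meta(4, 4)
        res = radsex_test(presence, meta, meta["sample_id"].tolist())
        assert res.attrs["n_tests"] == 1
        assert res["p_bonferroni"].iloc[2] == pytest.approx(res["p_raw"].iloc[2])
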