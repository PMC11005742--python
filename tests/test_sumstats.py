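"""Unit tests for the summary-statistic registry against hand oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sweepdann import sumstats
from sweepdann.haplotypes import HaplotypeWindow
from sweepdann.sumstats import (
    HapFreqSpectrum,
    compute_stat_vector,
    default_registry,
    delta_af,
    ehh_curve,
    ehh_family,
    fay_wu_h,
    garud_h_stats,
    haf_scores,
    hap_spectrum,
    nucleotide_diversity,
    safe_family,
    sfs_moments,
    site_frequency_spectrum,
    standardize_ihs,
    theta_h,
    theta_l,
    watterson_theta,
)

from conftest import random_window


def win_from(rows, positions=None):
    rows = np.asarray(rows, dtype=np.int8)
    if positions is None:
        positions = np.arange(rows.shape[1], dtype=float) * 10.0
    return HaplotypeWindow(rows, positions)


# ---------------------------------------------------------------------------
# pairwise-difference oracle


def pi_oracle(matrix):
    n = matrix.shape[0]
    tot = 0
    for i in range(n):
        for j in range(i + 1, n):
            tot += np.sum(matrix[i] != matrix[j])
    return tot / (n * (n - 1) / 2)


class TestDiversity:
    def test_monomorphic_zero(self):
        w = win_from(np.zeros((4, 3)))
        assert nucleotide_diversity(w) == 0.0
        assert watterson_theta(w) == 0.0
        assert theta_h(w) == 0.0
        assert fay_wu_h(w) == 0.0

    def test_single_site_derived_two_of_four(self):
        w = win_from([[1, ], [1, ], [0, ], [0, ]])
        assert nucleotide_diversity(w) == pytest.approx(2 * 2 * 2 / 12)

    def test_additivity_over_sites(self):
        w = win_from([[1, 1], [1, 1], [0, 0], [0, 0]])
        assert nucleotide_diversity(w) == pytest.approx(2 * 0.6666666667, rel=1e-9)

    def test_watterson_examples(self):
        w = win_from([[1, 0, 1], [0, 1, 0], [0, 0, 1], [1, 1, 0]])
        assert watterson_theta(w) == pytest.approx(3 / (1 + 0.5 + 1 / 3), rel=1e-9)
        w2 = win_from(np.array([[1, 0, 1, 0, 1], [0, 1, 0, 1, 0]]))
        assert watterson_theta(w2) == pytest.approx(5.0)

    def test_theta_h_single_site_count3(self):
        w = win_from([[1], [1], [1], [0]])
        assert theta_h(w) == pytest.approx(2 * 1 * 9 / 12)

    def test_theta_h_all_singletons(self):
        w = win_from(np.eye(4, 3, dtype=int))
        n, s = 4, 3
        assert theta_h(w) == pytest.approx(2 * s / (n * (n - 1)))
        assert fay_wu_h(w) == pytest.approx(nucleotide_diversity(w) - theta_h(w))

    def test_pi_matches_pairwise_oracle_random(self, rng):
        for _ in range(30):
            w = random_window(rng)
            assert nucleotide_diversity(w) == pytest.approx(
                pi_oracle(w.matrix), rel=1e-10
            )


class TestSFS:
    def test_entropy_degenerate_cases(self):
        w = win_from([[1, 1], [1, 1], [0, 0], [0, 0]])  # both sites at count 2
        m = sfs_moments(site_frequency_spectrum(w))
        assert m[5] == pytest.approx(0.0)

    def test_entropy_two_equal_classes(self):
        w = win_from([[1, 1], [1, 0], [0, 0], [0, 0]])  # counts 2 and 1
        m = sfs_moments(site_frequency_spectrum(w))
        assert m[5] == pytest.approx(np.log(2))

    def test_first_moment_weighted_mean(self):
        # counts (2,2) at derived freqs 0.25 and 0.5 -> mean 0.375
        rows = np.zeros((4, 4), dtype=int)
        rows[0, 0] = rows[0, 1] = 1  # two singleton sites: freq 0.25
        rows[0, 2] = rows[1, 2] = 1
        rows[0, 3] = rows[1, 3] = 1  # two doubleton sites: freq 0.5
        m = sfs_moments(site_frequency_spectrum(win_from(rows)))
        assert m[0] == pytest.approx(0.375)

    def test_theta_l_oracle(self, rng):
        for _ in range(20):
            w = random_window(rng)
            c = w.matrix.sum(axis=0)
            c = c[(c > 0) & (c < w.n_hap)]
            assert theta_l(w) == pytest.approx(c.sum() / (w.n_hap - 1), rel=1e-10)


class TestHapSpectrum:
    def test_all_identical(self):
        hfs = hap_spectrum(win_from([[1, 0], [1, 0], [1, 0]]))
        assert hfs.freqs.tolist() == [1.0]
        assert garud_h_stats(hfs) == (1, 1, 1, 0, 0)

    def test_two_pairs(self):
        hfs = hap_spectrum(win_from([[1, 0], [1, 0], [0, 1], [0, 1]]))
        assert hfs.freqs.tolist() == [0.5, 0.5]

    def test_multiplicities_2_1_1(self):
        hfs = hap_spectrum(win_from([[1, 0], [1, 0], [0, 1], [1, 1]]))
        assert hfs.freqs.tolist() == [0.5, 0.25, 0.25]

    def test_garud_enumeration_example(self):
        h1, h12, h123, h2h1, het = garud_h_stats(HapFreqSpectrum([0.5, 0.25, 0.25]))
        assert h1 == pytest.approx(0.375)
        assert h12 == pytest.approx(0.625)
        assert h123 == pytest.approx(1.0)
        assert h2h1 == pytest.approx((0.375 - 0.25) / 0.375)
        assert het == pytest.approx(0.625)

    def test_equifrequent_symmetry(self):
        for k in (2, 4, 5):
            h1, _, _, _, het = garud_h_stats(HapFreqSpectrum(np.full(k, 1 / k)))
            assert h1 == pytest.approx(1 / k)
            assert het == pytest.approx(1 - 1 / k)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_h_ordering_and_het_identity(self, seed):
        w = random_window(np.random.default_rng(seed))
        h1, h12, h123, h2h1, het = garud_h_stats(hap_spectrum(w))
        assert h123 >= h12 >= h1 > 0
        assert h123 <= 1 and h12 <= 1 and h1 <= 1
        assert h1 + het == pytest.approx(1.0, abs=1e-12)


class TestHafSafe:
    def test_haf_example(self):
        haf = haf_scores(win_from([[1, 1], [1, 0], [0, 0]]))
        assert haf.tolist() == [3.0, 2.0, 0.0]

    def test_haf_brute_force_oracle(self, rng):
        for _ in range(30):
            w = random_window(rng)
            c = w.matrix.sum(axis=0)
            expect = [sum(c[j] for j in range(w.n_sites) if w.matrix[h, j]) for h in range(w.n_hap)]
            np.testing.assert_allclose(haf_scores(w), expect, rtol=1e-12)

    def test_phi_example(self):
        out = safe_family(win_from([[1, 1], [1, 0], [0, 0]]))
        assert out["phi"][1] == pytest.approx(3 / 5)

    def test_phi_kappa_full_carrier(self):
        w = win_from([[1, 1], [1, 0], [1, 0]])  # site 0 carried by all
        out = safe_family(w)
        assert out["phi"][0] == pytest.approx(1.0)
        assert out["kappa"][0] == pytest.approx(1.0)

    def test_kappa_one_of_three_distinct(self):
        # carriers of last site are two copies of one haplotype; 3 distinct overall
        w = win_from([[1, 0, 1], [1, 0, 1], [0, 1, 0], [0, 0, 0]])
        out = safe_family(w)
        assert out["kappa"][2] == pytest.approx(1 / 3)

    def test_phi_kappa_bounds(self, rng):
        for _ in range(20):
            w = random_window(rng)
            out = safe_family(w)
            assert ((out["phi"] > 0) & (out["phi"] <= 1)).all()
            assert ((out["kappa"] > 0) & (out["kappa"] <= 1)).all()


def ehh_brute(matrix, rows, core, j):
    """Homozygosity of sub-haplotypes spanning core..j for carrier rows."""
    lo, hi = min(core, j), max(core, j)
    sub = matrix[np.asarray(rows)][:, lo : hi + 1]
    _, counts = np.unique(sub, axis=0, return_counts=True)
    nc = len(rows)
    return np.sum(counts * (counts - 1)) / (nc * (nc - 1))


class TestEHH:
    def test_symmetric_carrier_structure_gives_zero(self):
        # derived and ancestral carriers have mirrored sharing patterns
        m = np.array(
            [[1, 1, 1, 1, 1],
             [1, 1, 1, 1, 1],
             [0, 0, 0, 0, 0],
             [0, 0, 0, 0, 0]])
        w = win_from(m)
        ihs, nsl, dihh = ehh_family(w, 2)
        assert ihs == pytest.approx(0.0, abs=1e-12)
        assert dihh == pytest.approx(0.0, abs=1e-12)

    def test_homogeneous_derived_class_negative_ihs(self):
        rng = np.random.default_rng(5)
        n, s = 12, 21
        matrix = rng.integers(0, 2, size=(n, s)).astype(np.int8)
        core = s // 2
        matrix[:6] = matrix[0]  # derived carriers all identical
        matrix[:6, core] = 1
        matrix[6:, core] = 0
        w = win_from(matrix)
        ihs, _, dihh = ehh_family(w, core)
        assert ihs < 0
        assert dihh < 0

    def test_trapezoid_integration_matches_hand_computation(self):
        # 4 haplotypes, explicit EHH step functions either side of the core
        m = np.array(
            [[1, 1, 1, 0],
             [0, 1, 1, 1],
             [1, 0, 1, 0],
             [0, 0, 0, 1]])
        pos = np.array([0.0, 10.0, 20.0, 40.0])
        w = win_from(m, pos)
        core = 1
        offs, vals = ehh_curve(m, np.array([0, 1]), core)
        for o, v in zip(offs, vals):
            if o != 0:
                assert v == pytest.approx(ehh_brute(m, [0, 1], core, core + o), rel=1e-12)
        ihs, nsl, dihh = ehh_family(w, core)
        # derived {0,1}: right EHH steps 1 then 0 -> 10 + 10; left EHH 0 -> 5; D = 25
        # ancestral {2,3}: right EHH 0 -> 5; left EHH 0 -> 5; A = 10
        assert dihh == pytest.approx(10 - 25, rel=1e-12)
        assert ihs == pytest.approx(np.log(10 / 25), rel=1e-12)
        # SNP-count scale: D = 1 + 0.5 + 0.5 = 2, A = 0.5 + 0.5 = 1
        assert nsl == pytest.approx(np.log(1 / 2), rel=1e-12)

    def test_label_swap_antisymmetry(self, rng):
        for _ in range(10):
            w = random_window(rng, n_hap=8, n_sites=9)
            core = 4
            col = w.matrix[:, core]
            if col.sum() < 2 or col.sum() > 6:
                continue
            ihs1, nsl1, d1 = ehh_family(w, core)
            flipped = w.matrix.copy()
            flipped[:, core] = 1 - flipped[:, core]
            w2 = win_from(flipped, w.positions)
            ihs2, nsl2, d2 = ehh_family(w2, core)
            assert ihs1 == pytest.approx(-ihs2, rel=1e-9)
            assert d1 == pytest.approx(-d2, rel=1e-9)

    def test_too_few_carriers_nan(self):
        w = win_from([[1, 1], [0, 1], [0, 0]])
        assert np.isnan(ehh_family(w, 0)[0])

    def test_standardize_ihs_bins(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=500)
        freqs = rng.uniform(0.05, 0.95, size=500)
        z = standardize_ihs(vals, freqs)
        assert np.nanmean(z) == pytest.approx(0.0, abs=0.1)


class TestVector:
    def test_delta_af(self):
        w = win_from([[1, 1], [1, 1], [0, 0], [0, 0]])
        assert delta_af(w, 0.5) == pytest.approx(0.0)
        assert delta_af(w, 0.2) == pytest.approx(0.3)

    def test_registry_has_40_fixed_order_entries(self):
        reg = default_registry()
        assert len(reg) == 40
        assert list(reg) == list(default_registry())

    def test_vector_matches_individual_ops(self, rng):
        w = random_window(rng, n_hap=8, n_sites=9)
        v = compute_stat_vector(w, baseline_af=0.1)
        names = list(default_registry())
        assert v.shape == (40,)
        assert v[names.index("pi")] == pytest.approx(nucleotide_diversity(w))
        assert v[names.index("theta_w")] == pytest.approx(watterson_theta(w))
        assert v[names.index("delta_af")] == pytest.approx(delta_af(w, 0.1))
        h1, h12, h123, h2h1, het = garud_h_stats(hap_spectrum(w))
        assert v[names.index("h12")] == pytest.approx(h12)
        assert v[names.index("haf_max")] == pytest.approx(haf_scores(w).max())

    def test_monomorphic_window_zero_vector_with_warning(self):
        w = win_from(np.zeros((4, 3)))
        with pytest.warns(UserWarning):
            v = compute_stat_vector(w)
        assert np.all(v == 0)

    def test_row_permutation_invariance(self, rng):
        w = random_window(rng, n_hap=8, n_sites=9)
        perm = rng.permutation(w.n_hap)
        w2 = HaplotypeWindow(w.matrix[perm], w.positions, w.span)
        np.testing.assert_allclose(
            compute_stat_vector(w), compute_stat_vector(w2), rtol=1e-10, atol=1e-12
        )

    def test_site_permutation_invariance_of_sfs_stats(self, rng):
        w = random_window(rng, n_hap=6, n_sites=8)
        perm = rng.permutation(w.n_sites)
        w2 = HaplotypeWindow(w.matrix[:, perm], np.sort(w.positions), w.span)
        for fn in (nucleotide_diversity, watterson_theta, theta_h):
            assert fn(w) == pytest.approx(fn(w2), rel=1e-12)
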