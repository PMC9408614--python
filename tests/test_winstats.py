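import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from islescan.genotypes import MISSING, CohortDesign
from islescan.simcohort import SimConfig, simulate_study
from islescan.winstats import (
    WindowSpec,
    scan_table,
    site_pi,
    site_theta,
    tajimas_d,
    weir_components,
    weir_fst,
    window_frame,
    window_pi,
    z_transform,
)

from conftest import make_gm
from oracles import (
    brute_tajimas_d,
    brute_weighted_theta,
    brute_weir_site,
    brute_window_pi,
)


class TestWindowSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            WindowSpec(0, 1)
        with pytest.raises(ValueError):
            WindowSpec(100, 200)
        WindowSpec(100_000, 10_000)
        WindowSpec(50_000, 1_000)

    def test_tiling(self):
        gm = make_gm(np.ones((2, 3), dtype=np.int8),
                     pos=np.array([5_000, 60_000, 120_000]))
        wf = window_frame(gm, WindowSpec(50_000, 10_000))
        assert wf["start"].iloc[0] == 1
        assert wf["start"].iloc[1] == 10_001
        assert (wf["end"] - wf["start"] == 49_999).all()
        # last window truncated to the chromosome end for bp coverage
        assert wf["covered_bp"].iloc[-1] <= 50_000


class TestSitePi:
    def test_worked_example(self):
        assert site_pi(2, 4) == pytest.approx(2 / 3)

    def test_monomorphic(self):
        assert site_pi(0, 10) == 0
        assert site_pi(10, 10) == 0

    def test_undefined_below_two_alleles(self):
        assert np.isnan(site_pi(0, 1))

    @settings(max_examples=50, deadline=None)
    @given(n=st.integers(2, 40), data=st.data())
    def test_matches_allele_enumeration(self, n, data):
        c = data.draw(st.integers(0, n))
        alleles = [1] * c + [0] * (n - c)
        from oracles import brute_site_pi
        assert site_pi(c, n) == pytest.approx(brute_site_pi(alleles), abs=1e-12)


class TestWindowPi:
    def test_empty_window_zero(self):
        gm = make_gm(np.zeros((3, 2), dtype=np.int8), pos=np.array([10, 160_000]))
        wp = window_pi(gm, gm.samples, WindowSpec(50_000, 50_000))
        assert wp["pi"].iloc[0] == 0.0

    def test_single_site_arithmetic(self):
        # one site with pi 0.5 in a full 50 kb window
        calls = np.array([[1], [1], [0], [2]], dtype=np.int8)  # c=4, n=8 -> 0.5714
        gm = make_gm(np.column_stack([calls, np.zeros((4, 1), np.int8)]),
                     pos=np.array([100, 50_000]))
        # use c=2,n=4 for exactly 2/3: two het samples
        calls2 = np.array([[1, 0], [1, 0]], dtype=np.int8)
        gm2 = make_gm(calls2, pos=np.array([100, 50_000]))
        wp = window_pi(gm2, gm2.samples, WindowSpec(50_000, 50_000))
        assert wp["pi"].iloc[0] == pytest.approx((2 / 3) / 50_000)

    def test_matches_bruteforce_on_fixture(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(-1, 3, size=(6, 10)).astype(np.int8)
        gm = make_gm(calls, pos=np.arange(1, 11) * 900)
        spec = WindowSpec(10_000, 10_000)
        wp = window_pi(gm, gm.samples, spec, chrom_lengths={"chr1": 10_000})
        expected = brute_window_pi(gm, range(6), range(10), 10_000)
        assert wp["pi"].iloc[0] == pytest.approx(expected, abs=1e-12)


class TestWeirFst:
    def test_fixed_difference_theta_one(self):
        # equal n, p=1 vs p=0, no hets: a=0.5, b=c=0 -> theta exactly 1
        calls = np.vstack([np.full((4, 1), 2), np.zeros((4, 1))]).astype(np.int8)
        gm = make_gm(np.column_stack([calls]), pos=np.array([100]))
        a, b, c = weir_components(gm, np.arange(4), np.arange(4, 8))
        assert a[0] == pytest.approx(0.5, abs=1e-12)
        assert b[0] == pytest.approx(0.0, abs=1e-12)
        assert c[0] == pytest.approx(0.0, abs=1e-12)
        theta = site_theta(gm, np.arange(4), np.arange(4, 8))
        assert theta[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(-1, 3, size=(12, 20)).astype(np.int8)
        gm = make_gm(calls, pos=np.arange(1, 21) * 400)
        idx_a, idx_b = np.arange(6), np.arange(6, 12)
        a, b, c = weir_components(gm, idx_a, idx_b)
        for s in range(20):
            expected = brute_weir_site(gm, s, idx_a, idx_b)
            if expected is None:
                assert np.isnan(a[s])
            else:
                assert a[s] == pytest.approx(expected[0], abs=1e-12)
                assert b[s] == pytest.approx(expected[1], abs=1e-12)
                assert c[s] == pytest.approx(expected[2], abs=1e-12)
        _, win = weir_fst(gm, gm.samples[:6], gm.samples[6:],
                          WindowSpec(10_000, 10_000))
        expected_w = brute_weighted_theta(gm, range(20), idx_a, idx_b)
        assert win["fst"].iloc[0] == pytest.approx(expected_w, abs=1e-12)

    def test_null_duplicated_population(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.1, 0.9, 1000)
        calls = (rng.binomial(1, p, (16, 1000))
                 + rng.binomial(1, p, (16, 1000))).astype(np.int8)
        gm = make_gm(calls, spacing=900)
        _, win = weir_fst(gm, gm.samples[:8], gm.samples[8:],
                          WindowSpec(1_000_000, 1_000_000))
        assert win["fst"].iloc[0] <= 0.05

    def test_equal_freq_and_het_theta_nonpositive(self):
        # identical genotype columns in both cohorts: S^2 = 0 forces a <= 0
        col = np.array([0, 1, 2, 1], dtype=np.int8)
        gm = make_gm(np.vstack([col, col]).reshape(8, 1), pos=np.array([50]))
        theta = site_theta(gm, np.arange(4), np.arange(4, 8))
        assert np.isnan(theta[0]) or theta[0] <= 0

    def test_label_swap_symmetric(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 3, size=(10, 30)).astype(np.int8)
        gm = make_gm(calls)
        t_ab = site_theta(gm, np.arange(5), np.arange(5, 10))
        t_ba = site_theta(gm, np.arange(5, 10), np.arange(5))
        assert np.allclose(t_ab, t_ba, equal_nan=True)


class TestTajimasD:
    def test_zero_when_pi_equals_s_over_a1(self):
        # n=4 alleles: a1 = 1 + 1/2 + 1/3 = 11/6. Build a window whose
        # pi-hat equals S/a1 by mixing singletons and midfrequency sites.
        # With n=4: singleton pi = 2*(1/4)*(3/4)*(4/3) = 0.5;
        # doubleton pi = 2*(1/2)^2*(4/3) = 2/3.
        # 11 sites: k doubletons, 11-k singletons; S=11, S/a1=6.0
        # pi-hat = (11-k)*0.5 + k*2/3 = 6.0 -> k = 3
        calls = []
        for _ in range(3):   # doubletons: one hom-alt sample (c=2)
            calls.append([2, 0])
        for _ in range(8):   # singletons: one het sample (c=1)
            calls.append([1, 0])
        arr = np.array(calls, dtype=np.int8).T  # 2 samples x 11 sites
        gm = make_gm(arr, spacing=100)
        d = tajimas_d(gm, gm.samples, WindowSpec(10_000, 10_000))
        assert d["tajd"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(4)
        calls = rng.integers(-1, 3, size=(8, 15)).astype(np.int8)
        gm = make_gm(calls, spacing=500)
        d = tajimas_d(gm, gm.samples, WindowSpec(10_000, 10_000))
        expected = brute_tajimas_d(gm, range(15), range(8))
        assert d["tajd"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_all_singletons_negative(self):
        # excess of rare variants drives D below zero
        calls = np.zeros((10, 12), dtype=np.int8)
        for s in range(12):
            calls[s % 10, s] = 1
        gm = make_gm(calls, spacing=700)
        d = tajimas_d(gm, gm.samples, WindowSpec(10_000, 10_000))
        assert d["tajd"].iloc[0] < 0

    def test_no_segregating_sites_nan(self):
        gm = make_gm(np.zeros((5, 4), dtype=np.int8))
        d = tajimas_d(gm, gm.samples, WindowSpec(10_000, 10_000))
        assert np.isnan(d["tajd"].iloc[0])

    def test_cohort_must_have_two_individuals(self):
        gm = make_gm(np.ones((3, 4), dtype=np.int8))
        with pytest.raises(ValueError):
            tajimas_d(gm, gm.samples[:1], WindowSpec(1000, 1000))


class TestZTransform:
    def test_hand_arithmetic(self):
        assert z_transform([1.0, 2.0, 3.0]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_vector_error(self):
        with pytest.raises(ValueError):
            z_transform([2.0, 2.0, 2.0])

    def test_too_few_finite_error(self):
        with pytest.raises(ValueError):
            z_transform([1.0, np.nan])

    def test_nan_propagates(self):
        z = z_transform([1.0, np.nan, 3.0])
        assert np.isnan(z[1])
        assert np.isfinite(z[[0, 2]]).all()

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=50, unique=True))
    def test_normalization_property(self, values):
        z = z_transform(values)
        assert np.mean(z) == pytest.approx(0.0, abs=1e-8)
        assert np.std(z, ddof=1) == pytest.approx(1.0, rel=1e-8)


@pytest.fixture(scope="module")
def null_scan():
    res = simulate_study(SimConfig(
        n_sites=8000, n_chrom=2, chrom_length=4_000_000,
        island_divergence=0.05, n_causal=0, missing_rate=0.0, seed=21))
    return scan_table(res.gm, res.design, WindowSpec(100_000, 10_000))


class TestScanTable:
    def test_z_columns_normalized(self, null_scan):
        for col in ("z_fst", "z_delta_pi", "z_delta_tajd"):
            vals = null_scan[col].dropna()
            assert vals.mean() == pytest.approx(0.0, abs=1e-8)
            assert vals.std(ddof=1) == pytest.approx(1.0, rel=1e-8)

    def test_null_tail_fraction(self, null_scan):
        for col in ("z_fst", "z_delta_pi", "z_delta_tajd"):
            vals = null_scan[col].dropna()
            assert (vals > 2.33).mean() < 0.02

    def test_planted_locus_is_top_fst_window(self, causal_sim):
        tab = scan_table(causal_sim.gm, causal_sim.design, WindowSpec(100_000, 10_000))
        top = tab.loc[tab["z_fst"].idxmax()]
        truth = causal_sim.truth.loci
        hit = (
            (truth["chrom"] == top["chrom"])
            & (truth["pos"] >= top["start"])
            & (truth["pos"] <= top["end"])
        )
        assert hit.any()

    def test_both_window_specs_supported(self, causal_sim):
        for spec in (WindowSpec(100_000, 10_000), WindowSpec(50_000, 1_000)):
            tab = scan_table(causal_sim.gm, causal_sim.design, spec)
            assert len(tab) > 0
            assert (tab["end"] - tab["start"] + 1 == spec.size).all()

    def test_delta_orientation(self, causal_sim):
        tab = scan_table(causal_sim.gm, causal_sim.design, WindowSpec(100_000, 10_000))
        assert np.allclose(
            tab["delta_pi"], tab["pi_control"] - tab["pi_case"], equal_nan=True)
        assert np.allclose(
            tab["delta_tajd"], tab["tajd_control"] - tab["tajd_case"],
            equal_nan=True)

    def test_pooled_controls(self, causal_sim):
        tab = scan_table(
            causal_sim.gm, causal_sim.design, WindowSpec(100_000, 10_000),
            control=["control_a", "control_b"])
        assert len(tab) > 0

    def test_empty_cohort_error(self, causal_sim):
        design = CohortDesign({s: "case" for s in causal_sim.gm.samples})
        with pytest.raises(ValueError):
            scan_table(causal_sim.gm, design, WindowSpec(100_000, 10_000))
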