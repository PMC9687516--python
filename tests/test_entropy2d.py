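import math

import numpy as np
import pytest

from eotrh_texture import (
    DegenerateInputWarning,
    EntropyParams,
    ValidationError,
    disp_en_2d,
    dist_en_2d,
    entropy_suite,
    fuzz_en_2d,
    perm_en_2d,
    samp_en_2d,
    windows,
)
from eotrh_texture.entropy2d import block_downsample

from .oracles import (
    dispen2d_brute,
    disten2d_brute,
    fuzzen2d_brute,
    permen2d_brute,
    sampen2d_brute,
)

P_SMALL = EntropyParams(m=2, r_coeff=0.2, M=512)


class TestWindows:
    def test_counts(self):
        img = np.arange(9.0).reshape(3, 3)
        assert windows(img, 2, 2).shape == (4, 4)
        img2 = np.arange(4.0).reshape(2, 2)
        w = windows(img2, 2, 2)
        assert w.shape == (1, 4)
        np.testing.assert_array_equal(w[0], [0, 1, 2, 3])

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValidationError):
            windows(np.zeros((2, 2)), 3, 3)

    def test_row_major_scan_order(self):
        img = np.arange(12.0).reshape(3, 4)
        w = windows(img, 2, 2)
        np.testing.assert_array_equal(w[0], [0, 1, 4, 5])
        np.testing.assert_array_equal(w[1], [1, 2, 5, 6])


class TestDegenerateInputs:
    def test_constant_image_all_measures_zero(self):
        img = np.full((8, 8), 5.0)
        with pytest.warns(DegenerateInputWarning):
            results = entropy_suite(img, P_SMALL)
        assert [r.measure for r in results] == [
            "SampEn2D",
            "FuzzEn2D",
            "PermEn2D",
            "DispEn2D",
            "DistEn2D",
        ]
        assert all(r.value == 0.0 for r in results)

    def test_sampen_zero_matches_is_undefined_not_exception(self):
        # a single valid (m+1)-position => no ordered pairs at all
        img = np.array([[1.0, 10.0], [100.0, 1000.0]])
        res = samp_en_2d(img, EntropyParams(m=1, r_coeff=0.001))
        assert res.value is None and not res.defined

    def test_gradient_permutation_entropy_zero(self):
        img = np.arange(30.0).reshape(5, 6)
        assert perm_en_2d(img, P_SMALL).value == pytest.approx(0.0)


class TestOracleEquivalence:
    """Each measure equals an independent pure-Python enumeration."""

    @pytest.mark.parametrize("seed", range(12))
    def test_all_measures_on_random_small_matrices(self, seed):
        rng = np.random.default_rng(seed)
        rows, cols = rng.integers(4, 7, size=2)
        img = rng.choice([0.0, 1.0, 2.0], size=(rows, cols))
        lst = img.tolist()
        p = P_SMALL
        impl = {
            "SampEn2D": samp_en_2d(img, p).value,
            "FuzzEn2D": fuzz_en_2d(img, p).value,
            "PermEn2D": perm_en_2d(img, p).value,
            "DispEn2D": disp_en_2d(img, p).value,
            "DistEn2D": dist_en_2d(img, p).value,
        }
        brute = {
            "SampEn2D": sampen2d_brute(lst, p.m, p.r_coeff),
            "FuzzEn2D": fuzzen2d_brute(lst, p.m, p.r_coeff, p.nf),
            "PermEn2D": permen2d_brute(lst, p.dm, p.dn),
            "DispEn2D": dispen2d_brute(lst, p.c, p.dm, p.dn),
            "DistEn2D": disten2d_brute(lst, p.m, p.M, normalize=True),
        }
        for name in impl:
            if brute[name] is None:
                assert impl[name] is None, name
            else:
                assert impl[name] == pytest.approx(brute[name], abs=1e-9), name

    def test_checkerboard_sampen_matches_pair_count_oracle(self, checkerboard4):
        p = EntropyParams(m=1, r_coeff=0.2)
        got = samp_en_2d(checkerboard4, p).value
        want = sampen2d_brute(checkerboard4.tolist(), 1, 0.2)
        assert got == pytest.approx(want, abs=1e-12)

    def test_checkerboard_fuzzen_matches_oracle(self, checkerboard4):
        p = EntropyParams(m=1, r_coeff=0.2, nf=2.0)
        got = fuzz_en_2d(checkerboard4, p).value
        want = fuzzen2d_brute(checkerboard4.tolist(), 1, 0.2, 2.0)
        assert got == pytest.approx(want, abs=1e-12)

    def test_checkerboard_disten_matches_histogram_oracle(self, checkerboard4):
        p = EntropyParams(m=2, M=8)
        got = dist_en_2d(checkerboard4, p).value
        want = disten2d_brute(checkerboard4.tolist(), 2, 8, normalize=True)
        assert got == pytest.approx(want, abs=1e-12)


class TestConstructedValues:
    def test_two_equal_frequency_ordinal_patterns_give_ln2(self):
        # 2xN strip of alternating 2x2 motifs [1,2;3,4] and [2,1;4,3]:
        # exactly two ordinal patterns, two windows each
        img = np.array([[1.0, 2.0, 1.0, 2.0, 1.0], [3.0, 4.0, 3.0, 4.0, 3.0]])
        h = perm_en_2d(img, P_SMALL).value
        assert h == pytest.approx(math.log(2), abs=1e-12)
        # cross-check the construction with the direct tally oracle
        assert permen2d_brute(img.tolist()) == pytest.approx(math.log(2), abs=1e-12)

    def test_uniform_distance_strip_reaches_normalized_one(self):
        # 1 x 4 strip, m=1: windows are the scalars 0,1,2,3 and the pairwise
        # distance multiset is {1,1,1,2,2,3}; with M=2 bins over [0,3] the
        # halves [0,1.5) and [1.5,3] hold three distances each -> uniform ePDF
        img = np.array([[0.0, 1.0, 2.0, 3.0]])
        p = EntropyParams(m=1, M=2, normalize_dist=True)
        assert dist_en_2d(img, p).value == pytest.approx(1.0, abs=1e-12)
        assert disten2d_brute(img.tolist(), 1, 2) == pytest.approx(1.0, abs=1e-12)

    def test_striped_dispersion_patterns_match_hand_tally(self):
        # two-valued stripes far apart => two dispersion classes, rows
        # alternate, dm=dn=2 windows all show the same class pattern per offset
        img = np.tile(np.array([[0.0], [10.0]]), (3, 5))[:5, :]
        p = EntropyParams(c=6)
        got = disp_en_2d(img, p).value
        want = dispen2d_brute(img.tolist(), 6, 2, 2)
        assert got == pytest.approx(want, abs=1e-12)

    def test_printed_window_count_prefactor_divides_by_window_count(self):
        img = np.random.default_rng(3).uniform(size=(6, 6))
        base = perm_en_2d(img, EntropyParams()).value
        pref = perm_en_2d(img, EntropyParams(window_count_prefactor=True)).value
        n_windows = 5 * 5
        assert pref == pytest.approx(base / n_windows, rel=1e-12)


class TestInvariances:
    @pytest.mark.parametrize("shift", [7.5, -3.0])
    def test_shift_invariance(self, rng, shift):
        img = rng.uniform(0, 10, size=(10, 10))
        p = P_SMALL
        funcs = [samp_en_2d, fuzz_en_2d, perm_en_2d, disp_en_2d, dist_en_2d]
        for f in funcs:
            a, b = f(img, p).value, f(img + shift, p).value
            if f is perm_en_2d:
                assert a == b
            else:
                assert a == pytest.approx(b, abs=1e-9)

    @pytest.mark.parametrize("scale", [3.0, 0.25])
    def test_scale_invariance(self, rng, scale):
        # FuzzEn2D is excluded: its similarity exp(-d^nf/r) scales d^nf by
        # a^nf but r only by a, so it is scale invariant only for nf = 1
        img = rng.uniform(0, 10, size=(10, 10))
        p = P_SMALL
        for f in [samp_en_2d, perm_en_2d, disp_en_2d, dist_en_2d]:
            a, b = f(img, p).value, f(img * scale, p).value
            assert a == pytest.approx(b, abs=1e-9)

    def test_fuzzen_scale_invariant_for_unit_exponent(self, rng):
        img = rng.uniform(0, 10, size=(10, 10))
        p = EntropyParams(nf=1.0)
        a = fuzz_en_2d(img, p).value
        b = fuzz_en_2d(img * 4.0, p).value
        assert a == pytest.approx(b, abs=1e-9)

    def test_noise_scores_at_least_periodic(self):
        """i.i.d. noise is at least as irregular as a periodic pattern of the
        same size and variance, on average over 20 seeds, for every measure."""
        p = EntropyParams(m=2, M=64)
        period = np.tile(np.array([[0.0, 1.0], [1.0, 0.0]]), (16, 16))
        period = (period - period.mean()) / period.std()
        sums = {name: 0.0 for name in ("SampEn2D", "FuzzEn2D", "PermEn2D", "DispEn2D", "DistEn2D")}
        n_seeds = 20
        for seed in range(n_seeds):
            noise = np.random.default_rng(seed).uniform(size=(32, 32))
            noise = (noise - noise.mean()) / noise.std()
            for res_n, res_p in zip(entropy_suite(noise, p), entropy_suite(period, p)):
                sums[res_n.measure] += (res_n.value or 0.0) - (res_p.value or 0.0)
        for name, total in sums.items():
            assert total / n_seeds >= 0.0, name

    def test_normalized_disten_in_unit_interval(self, rng):
        for _ in range(10):
            img = rng.uniform(size=(8, 8))
            v = dist_en_2d(img, EntropyParams(M=16)).value
            assert 0.0 <= v <= 1.0


class TestPixelBudget:
    def test_small_image_untouched(self):
        img = np.arange(16.0).reshape(4, 4)
        out, k = block_downsample(img, (64, 64))
        assert k == 1
        np.testing.assert_array_equal(out, img)

    def test_large_image_block_mean(self):
        img = np.arange(128.0 * 128).reshape(128, 128)
        out, k = block_downsample(img, (64, 64))
        assert k == 2 and out.shape == (64, 64)
        assert out[0, 0] == pytest.approx(np.mean([0, 1, 128, 129]))

    def test_downsample_noted_on_result(self):
        img = np.random.default_rng(0).uniform(size=(130, 70))
        res = dist_en_2d(img, EntropyParams())
        assert "downsampled" in res.note


class TestSuite:
    def test_five_results_fixed_order(self, rng):
        # coarse-valued image so repeated windows exist and SampEn2D is defined
        img = rng.choice([0.0, 1.0], size=(10, 10))
        results = entropy_suite(img, P_SMALL)
        assert [r.measure for r in results] == [
            "SampEn2D",
            "FuzzEn2D",
            "PermEn2D",
            "DispEn2D",
            "DistEn2D",
        ]
        assert all(r.defined for r in results)

    def test_undefined_marker_propagates_without_abort(self):
        img = np.array([[1.0, 10.0], [100.0, 1000.0]])
        results = entropy_suite(img, EntropyParams(m=1, r_coeff=0.001))
        by_name = {r.measure: r for r in results}
        assert not by_name["SampEn2D"].defined
        assert by_name["PermEn2D"].defined
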