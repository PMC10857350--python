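"""Per-spectrum preprocessing: SNV, detrend, derivatives, replicate handling."""

import numpy as np
import pytest

from soilsqi.preprocess import (
    DEFAULT_PLAN,
    PreprocessPlan,
    SpectralSet,
    apply_plan,
    average_replicates,
    first_derivative,
    gap_derivative,
    read_spectra,
    savitzky_golay,
    second_derivative,
    snv,
    snv_detrend,
    trim_wavelengths,
    write_spectra,
)


def make_set(wl, values, ids=None):
    values = np.atleast_2d(values)
    n = values.shape[0]
    ids = np.arange(n) if ids is None else np.asarray(ids)
    return SpectralSet(wl, values, ids, np.zeros(n, dtype=int))


class TestContainerAndIO:
    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError, match="increasing|unsorted"):
            make_set(np.array([500.0, 400.0]), np.ones((1, 2)))

    def test_duplicate_scan_rejected(self):
        with pytest.raises(ValueError, match="duplicated"):
            SpectralSet(
                np.array([1.0, 2.0]), np.ones((2, 2)), ["a", "a"], [0, 0]
            )

    def test_round_trip_preserves_values(self, tiny_spectra, tmp_path):
        p = tmp_path / "spec.csv"
        write_spectra(tiny_spectra, p)
        back = read_spectra(p)
        np.testing.assert_array_equal(back.values, tiny_spectra.values)
        np.testing.assert_array_equal(back.wavelengths, tiny_spectra.wavelengths)
        assert list(back.sample_ids) == list(tiny_spectra.sample_ids)

    def test_read_shape_contract(self, tmp_path):
        p = tmp_path / "two.csv"
        p.write_text("sample_id,rep,400,410,420\na,0,1,2,3\nb,0,4,5,6\n")
        s = read_spectra(p)
        assert s.values.shape == (2, 3)

    def test_unsorted_header_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("sample_id,rep,500,400\na,0,1,2\n")
        with pytest.raises(ValueError, match="unsorted"):
            read_spectra(p)

    def test_non_numeric_header_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("sample_id,rep,400,greenish\na,0,1,2\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_spectra(p)


class TestAverageReplicates:
    def test_arithmetic_mean(self):
        wl = np.array([400.0])
        s = SpectralSet(wl, [[1.0], [2.0], [3.0]], ["a"] * 3, [0, 1, 2])
        out = average_replicates(s)
        assert out.values[0, 0] == 2.0
        assert list(out.rep_ids) == [0]

    def test_single_replicate_identity(self, tiny_spectra):
        one = SpectralSet(
            tiny_spectra.wavelengths,
            tiny_spectra.values[:3],
            ["a", "b", "c"],
            [0, 0, 0],
        )
        out = average_replicates(one)
        np.testing.assert_array_equal(out.values, one.values)

    def test_symmetric_perturbations_cancel(self):
        wl = np.linspace(400, 500, 11)
        rng = np.random.default_rng(0)
        v = rng.normal(size=11)
        d = rng.normal(size=11)
        s = SpectralSet(wl, np.vstack([v, v + d, v - d]), ["x"] * 3, [0, 1, 2])
        out = average_replicates(s)
        np.testing.assert_allclose(out.values[0], v, atol=1e-12)


class TestTrim:
    def test_default_span(self):
        wl = np.arange(350.0, 2501.0)
        s = make_set(wl, np.zeros((1, wl.size)))
        out = trim_wavelengths(s)
        assert out.wavelengths[0] == 399.0
        assert out.wavelengths[-1] == 2451.0
        assert out.n_bands == 2053

    def test_identity_when_inside(self):
        wl = np.arange(400.0, 2451.0)
        s = make_set(wl, np.zeros((1, wl.size)))
        assert trim_wavelengths(s).n_bands == wl.size

    def test_empty_result_rejected(self):
        s = make_set(np.array([100.0, 200.0]), np.zeros((1, 2)))
        with pytest.raises(ValueError, match="no bands"):
            trim_wavelengths(s)


class TestSNV:
    def test_known_row(self):
        s = make_set(np.array([1.0, 2.0, 3.0]), [[10.0, 20.0, 30.0]])
        np.testing.assert_allclose(snv(s).values[0], [-1.0, 0.0, 1.0])

    def test_idempotent(self, tiny_spectra):
        once = snv(tiny_spectra)
        twice = snv(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-10)

    def test_zero_variance_names_sample(self):
        s = make_set(np.array([1.0, 2.0, 3.0]), [[1.0, 1.0, 1.0]], ids=["flat"])
        with pytest.raises(ValueError, match="flat"):
            snv(s)

    def test_mean_zero_unit_sd(self, tiny_spectra):
        out = snv(tiny_spectra)
        np.testing.assert_allclose(out.values.mean(axis=1), 0, atol=1e-10)
        np.testing.assert_allclose(out.values.std(axis=1, ddof=1), 1, atol=1e-10)

    def test_row_permutation_commutes(self, tiny_spectra):
        perm = np.array([3, 1, 5, 0, 2, 4])
        permuted = SpectralSet(
            tiny_spectra.wavelengths,
            tiny_spectra.values[perm],
            tiny_spectra.sample_ids[perm],
            tiny_spectra.rep_ids[perm],
        )
        np.testing.assert_allclose(
            snv(permuted).values, snv(tiny_spectra).values[perm]
        )


class TestSNVDetrend:
    def test_annihilates_quadratic(self):
        wl = np.linspace(400, 2400, 50)
        quad = 3.0 + 0.002 * wl + 1e-6 * wl**2
        s = make_set(wl, quad[None, :])
        out = snv_detrend(s, poly_degree=2)
        np.testing.assert_allclose(out.values, 0, atol=1e-8)

    def test_degree_zero_recenters(self, tiny_spectra):
        out = snv_detrend(tiny_spectra, poly_degree=0)
        np.testing.assert_allclose(out.values.mean(axis=1), 0, atol=1e-10)

    def test_peak_survives_detrending(self):
        # quadratic background + a narrow Gaussian peak: detrending removes
        # the background but must keep the peak height at its center
        wl = np.linspace(400, 2400, 2001)
        peak = 0.8 * np.exp(-((wl - 1500) ** 2) / (2 * 15.0**2))
        base = 1.0 + 5e-4 * wl + 2e-7 * wl**2
        with_peak = snv_detrend(make_set(wl, (base + peak)[None, :]), 2)
        without = snv_detrend(make_set(wl, base[None, :]), 2)
        c = np.argmin(np.abs(wl - 1500))
        got = with_peak.values[0, c] - without.values[0, c]
        # compare to the directly constructed peak, SNV-scaled
        sd = (base + peak).std(ddof=1)
        expected = peak[c] / sd
        assert abs(got - expected) / expected < 0.05


class TestDerivatives:
    def test_first_derivative_of_linear_is_constant(self):
        wl = np.arange(400.0, 500.0)
        s = make_set(wl, (2.0 + 0.03 * wl)[None, :])
        out = first_derivative(s)
        np.testing.assert_allclose(out.values, 0.03, atol=1e-12)

    def test_second_derivative_of_linear_is_zero(self):
        wl = np.arange(400.0, 500.0)
        s = make_set(wl, (2.0 + 0.03 * wl)[None, :])
        out = second_derivative(s)
        np.testing.assert_allclose(out.values, 0, atol=1e-10)

    def test_gap_derivative_quadratic(self):
        # x(lam) = lam^2, gap 2, step 1: (12^2 - 8^2) / 4 = 20 at lam = 10
        wl = np.arange(0.0, 21.0)
        s = make_set(wl, (wl**2)[None, :])
        out = gap_derivative(s, gap=2)
        at10 = np.where(out.wavelengths == 10.0)[0][0]
        assert out.values[0, at10] == pytest.approx(20.0)

    def test_savgol_window_too_large_rejected(self):
        s = make_set(np.arange(400.0, 405.0), np.zeros((1, 5)))
        with pytest.raises(ValueError, match="window"):
            savitzky_golay(s, window=7, polyorder=2)

    def test_savgol_truncates_edges(self):
        wl = np.arange(400.0, 450.0)
        s = make_set(wl, np.random.default_rng(1).normal(size=(2, 50)))
        out = savitzky_golay(s, window=11, polyorder=2)
        assert out.n_bands == 50 - 10


class TestPlan:
    def test_unknown_step_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            PreprocessPlan(steps=["mystery"])

    def test_order_matters(self):
        wl = np.arange(350.0, 2501.0, 10)
        rng = np.random.default_rng(3)
        s = make_set(wl, rng.normal(size=(3, wl.size)))
        a = snv(trim_wavelengths(s)).values
        b = trim_wavelengths(snv(s)).values
        assert not np.allclose(a, b)

    def test_default_plan_applies_trim_then_snv(self):
        wl = np.arange(350.0, 2501.0, 10)
        s = make_set(wl, np.random.default_rng(4).normal(size=(2, wl.size)))
        out = apply_plan(s, DEFAULT_PLAN)
        assert out.wavelengths[0] >= 399.0 and out.wavelengths[-1] <= 2451.0
        np.testing.assert_allclose(out.values.mean(axis=1), 0, atol=1e-10)
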