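"""Window loading, histogramming, the WHAM solver and profile measures."""

import numpy as np
import pytest

import scramblekit as sk
from scramblekit.constants import kt
from scramblekit.errors import (ConnectivityError, ConvergenceError,
                                DomainError, ParseError, RangeError,
                                ValidationError)
from scramblekit.wham import FreeEnergyProfile, UmbrellaWindow


def window_file(path, times, values, header=()):
    with open(path, "w") as fh:
        for line in header:
            fh.write(line + "\n")
        for t, v in zip(times, values):
            fh.write(f"{t:.1f} {v:.6f}\n")
    return path


class TestLoadWindow:
    def test_discard_boundary_keeps_samples_at_discard(self, tmp_path):
        times = 10_000.0 + 10.0 * np.arange(1000)
        w = sk.load_window(window_file(tmp_path / "w.tsv", times,
                                       np.zeros(1000)),
                           center=0.0, k=1000.0, discard=10_000.0)
        assert w.n == 1000  # times start at the discard: nothing removed

    def test_discard_removes_equilibration(self, tmp_path):
        times = 10.0 * np.arange(2000)
        w = sk.load_window(window_file(tmp_path / "w.tsv", times,
                                       np.ones(2000)),
                           center=0.0, k=1000.0, discard=10_000.0)
        assert w.n == 1000

    def test_discard_beyond_span_is_error(self, tmp_path):
        path = window_file(tmp_path / "w.tsv", [0.0, 10.0], [0.0, 0.0])
        with pytest.raises(ValidationError):
            sk.load_window(path, 0.0, 1000.0, discard=1e6)

    def test_xmgrace_headers_ignored(self, tmp_path):
        times = 10_000.0 + 10.0 * np.arange(5)
        bare = sk.load_window(
            window_file(tmp_path / "a.tsv", times, np.arange(5.0)),
            0.0, 1000.0)
        deco = sk.load_window(
            window_file(tmp_path / "b.tsv", times, np.arange(5.0),
                        header=["@ title \"pullx\"", "# comment",
                                "@ xaxis label \"t\""]),
            0.0, 1000.0)
        np.testing.assert_array_equal(bare.samples, deco.samples)

    def test_non_numeric_row_names_line(self, tmp_path):
        path = tmp_path / "w.tsv"
        path.write_text("10000.0 0.1\nbogus row\n")
        with pytest.raises(ParseError) as exc:
            sk.load_window(path, 0.0, 1000.0, discard=0.0)
        assert exc.value.line == 2

    def test_metadata_round_trip(self, tmp_path):
        times = 10_000.0 + 10.0 * np.arange(10)
        for i, c in enumerate((-0.1, 0.0, 0.1)):
            window_file(tmp_path / f"w{i}.tsv", times, np.full(10, c))
        meta = tmp_path / "meta.txt"
        meta.write_text("# path center k\n" + "\n".join(
            f"w{i}.tsv {c} 1000.0" for i, c in enumerate((-0.1, 0.0, 0.1)))
            + "\n")
        windows = sk.load_windows(meta)
        assert [w.center for w in windows] == [-0.1, 0.0, 0.1]
        assert all(w.k == 1000.0 for w in windows)


class TestHistograms:
    def test_edge_convention(self):
        """Half-open bins with the final bin closed:
        {-0.01, 0.0, 0.01} on bins [-0.02, 0), [0, 0.02] -> [1, 2]."""
        w = UmbrellaWindow(np.array([-0.01, 0.0, 0.01]), 0.0, 1000.0)
        hists = sk.build_histograms([w], 0.02, (-0.02, 0.02))
        np.testing.assert_array_equal(hists.counts[0], [1, 2])

    def test_sample_on_upper_edge_kept(self):
        w = UmbrellaWindow(np.array([0.02]), 0.0, 1000.0)
        hists = sk.build_histograms([w], 0.02, (-0.02, 0.02))
        np.testing.assert_array_equal(hists.counts[0], [0, 1])

    def test_count_conservation(self, rng):
        windows = [UmbrellaWindow(rng.uniform(-1, 1, size=n), 0.0, 100.0)
                   for n in (10, 257, 4001)]
        hists = sk.build_histograms(windows, 0.05, (-1.0, 1.0))
        np.testing.assert_array_equal(hists.counts.sum(axis=1),
                                      [10, 257, 4001])

    def test_matches_brute_force_binning(self, rng):
        samples = rng.uniform(-1.0, 1.0, size=500)
        w = UmbrellaWindow(samples, 0.0, 100.0)
        hists = sk.build_histograms([w], 0.1, (-1.0, 1.0))
        edges = hists.bin_edges
        brute = np.zeros(len(edges) - 1, dtype=int)
        for x in samples:  # direct loop over half-open bins
            for j in range(len(brute)):
                closed = j == len(brute) - 1
                if edges[j] <= x < edges[j + 1] or (closed and x == edges[-1]):
                    brute[j] += 1
                    break
        np.testing.assert_array_equal(hists.counts[0], brute)

    def test_out_of_range_sample_is_error(self):
        w = UmbrellaWindow(np.array([0.0, 3.0]), 0.0, 100.0, name="w7")
        with pytest.raises(RangeError, match="w7"):
            sk.build_histograms([w], 0.1, (-1.0, 1.0))


class TestWhamSolver:
    def test_unbiased_single_window_closed_form(self, rng):
        """k = 0: WHAM must reduce exactly to -kT ln(histogram)."""
        samples = rng.normal(0.0, 0.4, size=20_000)
        w = UmbrellaWindow(samples, 0.0, 0.0)
        model = sk.WHAM([w], bin_width=0.05, cv_range=(-2.0, 2.0))
        profile = model.fit()
        hists = model.histograms
        counts = hists.counts[0][hists.counts[0] > 0].astype(float)
        expected = -model.kT * np.log(counts / counts.sum())
        expected -= expected.min()
        np.testing.assert_allclose(profile.F, expected, atol=1e-10)

    def test_duplicate_windows_change_nothing(self, rng):
        samples = rng.normal(0.5, 0.1, size=5000)
        w = UmbrellaWindow(samples, 0.5, 500.0)
        base = sk.WHAM([w], cv_range=(-1.0, 1.5), bin_width=0.05).fit()
        dup = sk.WHAM([UmbrellaWindow(samples[:2500], 0.5, 500.0),
                       UmbrellaWindow(samples[2500:], 0.5, 500.0)],
                      cv_range=(-1.0, 1.5), bin_width=0.05).fit()
        np.testing.assert_array_equal(base.F, dup.F)  # bit-identical

    def test_window_permutation_bit_identical(self):
        pmf = sk.PMFSpec(barrier=10.0)
        windows = sk.simulate_umbrella_set(pmf, np.linspace(-2.2, 2.2, 9),
                                           200.0, n_samples=2000, seed=4)
        fwd = sk.WHAM(windows).fit()
        rev = sk.WHAM(windows[::-1]).fit()
        np.testing.assert_array_equal(fwd.F, rev.F)
        np.testing.assert_array_equal(fwd.f_i, rev.f_i[::-1])

    def test_residual_non_increasing_on_mild_fixture(self):
        pmf = sk.PMFSpec(barrier=10.0)
        windows = sk.simulate_umbrella_set(pmf, np.linspace(-2.3, 2.3, 12),
                                           200.0, n_samples=2000, seed=3)
        profile = sk.WHAM(windows).fit()
        assert np.all(np.diff(profile.residual_history) <= 0)

    def test_nonconvergence_raises_with_residual(self):
        pmf = sk.PMFSpec(barrier=30.0)
        windows = sk.simulate_umbrella_set(pmf, np.linspace(-2.3, 2.3, 20),
                                           500.0, n_samples=1000, seed=1)
        with pytest.raises(ConvergenceError) as exc:
            sk.WHAM(windows).fit(max_iter=3)
        assert exc.value.residual > 0

    def test_disconnected_sampling_raises(self):
        left = UmbrellaWindow(np.full(100, -1.5), -1.5, 1000.0)
        right = UmbrellaWindow(np.full(100, 1.5), 1.5, 1000.0)
        with pytest.raises(ConnectivityError):
            sk.WHAM([left, right], bin_width=0.1, cv_range=(-2.0, 2.0)).fit()

    def test_double_well_recovery_small(self):
        """Scaled-down end-to-end recovery: 21 windows, 5000 samples."""
        pmf = sk.PMFSpec(barrier=20.0)
        windows = sk.simulate_umbrella_set(pmf, np.linspace(-2.3, 2.3, 21),
                                           500.0, n_samples=5000, seed=6)
        profile = sk.WHAM(windows).fit()
        assert profile.barrier((2.0, 2.3)) == pytest.approx(20.0, abs=1.0)


class TestProfileMeasures:
    @staticmethod
    def _profile(s, F, kT=kt(310.0)):
        return FreeEnergyProfile(np.asarray(s, dtype=float),
                                 np.asarray(F, dtype=float),
                                 f_i=np.zeros(1), kT=kT)

    def test_barrier_of_constructed_profile(self):
        s = np.linspace(-2.3, 2.3, 231)
        F = 62.0 * np.exp(-(s / 0.5) ** 2)  # bulk ~0, peak 62
        F[np.abs(s) >= 2.0] = 0.0           # exactly flat reference
        profile = self._profile(s, F)
        assert profile.barrier((2.0, 2.3)) == pytest.approx(62.0, abs=1e-9)

    def test_flat_profile_zero_barrier(self):
        s = np.linspace(-2.3, 2.3, 100)
        assert self._profile(s, np.zeros(100)).barrier((2.0, 2.3)) == 0.0

    def test_barrier_requires_bulk_coverage(self):
        s = np.linspace(-1.0, 1.0, 50)
        with pytest.raises(DomainError):
            self._profile(s, np.zeros(50)).barrier((2.0, 2.3))

    def test_asymmetry_zero_for_symmetric_profile(self):
        s = np.linspace(-2.3, 2.3, 231)
        F = 30.0 * (1 - (s / 1.9) ** 2) ** 2
        assert self._profile(s, F).asymmetry_error() == pytest.approx(
            0.0, abs=1e-12)

    def test_asymmetry_single_point_deviation(self):
        """F(s) - F(-s) = 2 kJ/mol at one interior point -> error 1."""
        s = np.linspace(-2.3, 2.3, 231)
        F = np.zeros(231)
        i = np.argmin(np.abs(s - 1.0))
        F[i] += 2.0
        assert self._profile(s, F).asymmetry_error() == pytest.approx(1.0)

    def test_asymmetry_needs_symmetric_coverage(self):
        s = np.linspace(0.5, 2.3, 50)
        with pytest.raises(DomainError):
            self._profile(s, np.zeros(50)).asymmetry_error()

    def test_summary_mentions_key_quantities(self):
        pmf = sk.PMFSpec(barrier=10.0)
        windows = sk.simulate_umbrella_set(pmf, np.linspace(-2.3, 2.3, 12),
                                           200.0, n_samples=2000, seed=3)
        profile = sk.WHAM(windows).fit()
        text = profile.summary()
        assert "kT" in text and "iterations" in text


class TestBootstrapError:
    def test_shapes_and_positivity(self):
        pmf = sk.PMFSpec(barrier=10.0)
        windows = sk.simulate_umbrella_set(pmf, np.linspace(-2.3, 2.3, 12),
                                           200.0, n_samples=2000, seed=3)
        grid, err = sk.block_bootstrap_error(windows, n_boot=5, seed=0)
        assert grid.shape == err.shape
        assert np.all(err >= 0) and err.max() > 0

    def test_seed_reproducible(self):
        pmf = sk.PMFSpec(barrier=5.0)
        windows = sk.simulate_umbrella_set(pmf, np.linspace(-2.0, 2.0, 12),
                                           100.0, n_samples=2000, seed=9)
        _, a = sk.block_bootstrap_error(windows, n_boot=3, seed=42)
        _, b = sk.block_bootstrap_error(windows, n_boot=3, seed=42)
        np.testing.assert_array_equal(a, b)
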