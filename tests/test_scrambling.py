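"""Leaflet assignment, scrambled-lipid series, events and rates."""

import numpy as np
import pytest

import scramblekit as sk
from scramblekit.errors import ParameterError
from scramblekit.scrambling import (DOWN_TO_UP, UP_TO_DOWN, running_average,
                                    series_from_cv)


class TestLeafletAssignment:
    def test_two_clean_leaflets(self, flat_bilayer):
        structure, frame = flat_bilayer
        labels = sk.assign_leaflets(frame, structure)
        assert labels.sum() == 10 and (~labels).sum() == 10

    def test_tie_at_first_snapshot_is_upper(self, flat_bilayer):
        structure, frame = flat_bilayer
        tied = frame.copy()
        tied.coords[0, 2] = sk.membrane_midplane(frame, structure)
        labels = sk.assign_leaflets(tied, structure,
                                    midplane=sk.membrane_midplane(
                                        frame, structure))
        assert labels[0]  # documented convention: ties start upper

    def test_tie_inherits_previous_label(self, flat_bilayer):
        structure, frame = flat_bilayer
        mid = sk.membrane_midplane(frame, structure)
        prev = sk.assign_leaflets(frame, structure, midplane=mid)
        tied = frame.copy()
        tied.coords[10, 2] = mid  # lipid 11 was lower
        labels = sk.assign_leaflets(tied, structure, midplane=mid,
                                    previous=prev)
        assert not labels[10]

    def test_matches_sign_oracle(self, rng):
        """200-lipid random fixture: labels equal the sign of
        z - (brute-force mean phosphate z)."""
        structure, frames, _ = sk.build_membrane_fixture(
            n_lipids=200, jitter=0.3, seed=8)
        frame = frames[0]
        z = frame.coords[structure.headgroup_ids, 2]
        mid = np.mean(z)
        labels = sk.assign_leaflets(frame, structure)
        np.testing.assert_array_equal(labels, z > mid)


class TestScramblingSeries:
    def _scripted(self):
        times = 10_000.0 * np.arange(11)
        crossings = [(i, 10_000.0 * (2 * i - 1) + 5_000.0)
                     for i in range(1, 6)]
        return sk.build_membrane_fixture(n_lipids=20, times=times,
                                         crossings=crossings, seed=2)

    def test_scripted_crossings_reproduced_exactly(self):
        structure, frames, ledger = self._scripted()
        series = sk.scrambling_series(frames, structure, stride_ps=10_000.0)
        assert series.n_events == len(ledger) == 5
        assert sorted(series.events) == sorted(ledger)
        assert series.scrambled_count[-1] == 5
        assert series.scrambled_count[0] == 0

    def test_no_crossings_counts_zero(self):
        """Proteinless-style static membrane: scrambling stays zero."""
        structure, frames, _ = sk.build_membrane_fixture(
            n_lipids=30, jitter=0.1, seed=5,
            times=10_000.0 * np.arange(6))
        series = sk.scrambling_series(frames, structure)
        assert series.n_events == 0
        np.testing.assert_array_equal(series.scrambled_count, 0)

    def test_round_trip_two_events_zero_count(self):
        times = 10_000.0 * np.arange(5)
        structure, frames, ledger = sk.build_membrane_fixture(
            n_lipids=10, times=times,
            crossings=[(3, 15_000.0), (3, 35_000.0)])
        series = sk.scrambling_series(frames, structure)
        assert series.n_events == 2
        assert series.scrambled_count[-1] == 0
        dirs = [d for _, _, d in sorted(series.events, key=lambda e: e[1])]
        assert dirs == [d for _, _, d in ledger]
        assert dirs[0] != dirs[1]

    def test_count_recomputable_from_labels(self):
        """Event-ledger reconstruction equals direct recount at every t."""
        structure, frames, _ = self._scripted()
        series = sk.scrambling_series(frames, structure)
        # rebuild labels from the ledger alone
        labels = np.tile(series.labels[0], (len(series.times), 1))
        id_col = {int(lid): j for j, lid in enumerate(series.lipid_ids)}
        for lid, t, _ in series.events:
            i = np.searchsorted(series.times, t)
            labels[i:, id_col[lid]] = ~labels[i - 1, id_col[lid]]
        np.testing.assert_array_equal(
            np.sum(labels != labels[0], axis=1), series.scrambled_count)

    def test_z_flip_swaps_leaflets_keeps_counts(self):
        structure, frames, _ = self._scripted()
        direct = sk.scrambling_series(frames, structure)
        flipped_frames = []
        for f in frames:
            g = f.copy()
            g.coords[:, 2] = -g.coords[:, 2]
            flipped_frames.append(g)
        flipped = sk.scrambling_series(flipped_frames, structure)
        np.testing.assert_array_equal(direct.labels, ~flipped.labels)
        np.testing.assert_array_equal(direct.scrambled_count,
                                      flipped.scrambled_count)

    def test_stride_subsamples_frames(self):
        structure, frames, _ = sk.build_membrane_fixture(
            n_lipids=10, times=5_000.0 * np.arange(9))
        series = sk.scrambling_series(frames, structure, stride_ps=10_000.0)
        np.testing.assert_allclose(series.times, 10_000.0 * np.arange(5))


class TestRunningAverage:
    def test_constant_series_unchanged(self):
        times = 10_000.0 * np.arange(50)
        counts = np.full(50, 7.0)
        np.testing.assert_allclose(
            running_average((times, counts), 200_000.0), 7.0)

    def test_full_window_averages_twenty_samples(self):
        """200 ns window at 10 ns stride spans exactly 20 samples."""
        times = 10_000.0 * np.arange(60)
        counts = np.arange(60, dtype=float)
        avg = running_average((times, counts), 200_000.0)
        i = 40
        np.testing.assert_allclose(avg[i],
                                   np.mean(counts[i - 19:i + 1]))

    def test_step_series_matches_direct_mean(self):
        times = 10_000.0 * np.arange(80)
        counts = (times >= 300_000.0).astype(float)
        avg = running_average((times, counts), 200_000.0)
        expected = [np.mean(counts[(times > t - 200_000.0) & (times <= t)])
                    for t in times]
        np.testing.assert_allclose(avg, expected)
        # unit step smooths into a linear ramp over one window
        ramp = avg[(times >= 300_000.0) & (times < 500_000.0)]
        assert np.all(np.diff(ramp) > 0)

    def test_window_shorter_than_stride_rejected(self):
        times = 10_000.0 * np.arange(5)
        with pytest.raises(ParameterError):
            running_average((times, np.zeros(5)), 5_000.0)


class TestRate:
    def test_arithmetic(self):
        times = np.linspace(0.0, 1e7, 101)  # 10 us
        s = np.zeros((101, 12))
        s[:, 0] = 1.0
        series = series_from_cv(times, s)
        series.events = [(0, float(t), UP_TO_DOWN)
                         for t in times[1:56]] + \
                        [(1, float(t), DOWN_TO_UP) for t in times[1:56]]
        rates = sk.scrambling_rate(series, duration_us=10.0)
        assert rates["total"] == pytest.approx(11.0)
        assert rates[UP_TO_DOWN] == pytest.approx(5.5)

    def test_zero_events(self):
        series = series_from_cv(np.array([0.0, 1e6]), np.ones((2, 3)))
        assert sk.scrambling_rate(series)["total"] == 0.0

    def test_invariant_under_consistent_time_rescaling(self):
        rng = np.random.default_rng(3)
        s = np.sign(rng.standard_normal((40, 6)))
        times = 10_000.0 * np.arange(40)
        a = series_from_cv(times, s)
        b = series_from_cv(times * 2.0, s)
        dur_a = (times[-1] - times[0]) / 1e6
        assert a.rate(dur_a)["total"] == pytest.approx(
            b.rate(2 * dur_a)["total"] * 2)

    def test_zero_duration_rejected(self):
        series = series_from_cv(np.array([0.0, 1.0]), np.ones((2, 2)))
        with pytest.raises(ParameterError):
            sk.scrambling_rate(series, duration_us=0.0)
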