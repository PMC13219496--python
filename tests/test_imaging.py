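"""Thresholded co-localization and the continuous contact-frequency estimator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cici_cal.imaging import (
    colocalized_fraction,
    continuous_contact_frequency,
    distance_histogram,
    xy_distance,
)
from cici_cal.population import sample_population
from cici_cal.timelapse import simulate_timelapse


def _tracks_from_distances(per_cell_frame_dist, detected=None):
    """Build a track table where cell i at frame f has xy dot distance d[i][f]."""
    rows = []
    for cell, dists in enumerate(per_cell_frame_dist):
        for frame, d in enumerate(dists):
            det = True if detected is None else detected[cell][frame]
            rows.append((cell, frame, frame * 240.0, 1, 0.0, 0.0, 0.0, det))
            rows.append((cell, frame, frame * 240.0, 2, d, 0.0, 0.0, det))
    return pd.DataFrame(
        rows,
        columns=["cell_id", "frame", "time_s", "channel", "x_um", "y_um", "z_um", "detected"],
    )


class TestXYDistance:
    def test_z_is_ignored(self):
        # 3-4-5 triangle in the plane; a huge z offset must not matter
        assert xy_distance((0, 0, 0), (0.3, 0.4, 5.0)) == pytest.approx(0.5)

    def test_identity_and_symmetry(self):
        assert xy_distance((1, 2, 3), (1, 2, 3)) == 0.0
        a, b = (0.1, 0.9, 0.0), (0.7, 0.2, 1.0)
        assert xy_distance(a, b) == xy_distance(b, a)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            xy_distance((np.nan, 0, 0), (0, 0, 0))


class TestColocalizedFraction:
    def test_hand_enumeration(self):
        tracks = _tracks_from_distances([[0.1], [0.39], [0.41], [0.8]])
        assert colocalized_fraction(tracks, 0) == 0.5

    def test_all_touching(self):
        tracks = _tracks_from_distances([[0.0]] * 3)
        assert colocalized_fraction(tracks, 0) == 1.0

    def test_boundary_is_strict(self):
        tracks = _tracks_from_distances([[0.400]])
        assert colocalized_fraction(tracks, 0) == 0.0

    def test_no_detectable_cells_rejected(self):
        tracks = _tracks_from_distances([[0.1]], detected=[[False]])
        with pytest.raises(ValueError):
            colocalized_fraction(tracks, 0)


class TestContinuousFrequency:
    def test_hand_enumeration_three_frames(self):
        # per-frame co-localization patterns {111, 110, 011, 111, 000} -> 2/5
        patterns = ["111", "110", "011", "111", "000"]
        dists = [[0.1 if c == "1" else 0.9 for c in p] for p in patterns]
        est = continuous_contact_frequency(_tracks_from_distances(dists))
        assert est.p_hat == pytest.approx(2 / 5)
        assert est.n_cells_included == 5

    def test_all_colocalized(self):
        est = continuous_contact_frequency(_tracks_from_distances([[0.1] * 3] * 4))
        assert est.p_hat == 1.0

    def test_k1_equals_single_frame_fraction(self):
        dists = [[0.1, 0.9], [0.5, 0.2], [0.3, 0.3]]
        tracks = _tracks_from_distances(dists)
        est = continuous_contact_frequency(tracks, k_frames=1)
        assert est.p_hat == pytest.approx(colocalized_fraction(tracks, 0))

    def test_monotone_in_k_and_threshold(self):
        rng = np.random.default_rng(0)
        dists = rng.uniform(0.0, 1.0, size=(200, 3)).tolist()
        tracks = _tracks_from_distances(dists)
        p_k = [
            continuous_contact_frequency(tracks, k_frames=k).p_hat for k in (1, 2, 3)
        ]
        assert p_k[0] >= p_k[1] >= p_k[2]
        p_t = [
            continuous_contact_frequency(tracks, threshold_um=t).p_hat
            for t in (0.2, 0.4, 0.6)
        ]
        assert p_t[0] <= p_t[1] <= p_t[2]

    def test_undetected_cells_excluded_from_denominator(self):
        detected = [[True] * 3, [True, False, True], [True] * 3]
        dists = [[0.1] * 3] * 3
        est = continuous_contact_frequency(_tracks_from_distances(dists, detected))
        assert est.n_cells_included == 2

    def test_lenient_mode_keeps_partially_detected_cells(self):
        detected = [[True, False, True], [True, True, True]]
        dists = [[0.1, 0.9, 0.1], [0.9] * 3]
        est = continuous_contact_frequency(
            _tracks_from_distances(dists, detected), lenient=True
        )
        # cell 0: co-localized on both detected frames -> contact
        assert est.n_cells_included == 2
        assert est.p_hat == pytest.approx(0.5)

    def test_short_tracks_rejected(self):
        with pytest.raises(ValueError):
            continuous_contact_frequency(_tracks_from_distances([[0.1, 0.2]]), k_frames=3)

    def test_recovery_on_simulated_population(self, inter_pair, model):
        pop = sample_population(inter_pair, 0.65, 2000, model, seed=21)
        tracks = simulate_timelapse(pop, seed=22)
        est = continuous_contact_frequency(tracks)
        assert est.ci_low <= 0.65 <= est.ci_high

    def test_threshold_robustness_on_intra_pair(self, intra_pair, model):
        # widening the threshold 0.4 -> 0.5 um shifts the estimate only mildly
        pop = sample_population(intra_pair, 0.65, 2000, model, seed=23)
        tracks = simulate_timelapse(pop, seed=24)
        p04 = continuous_contact_frequency(tracks, threshold_um=0.4).p_hat
        p05 = continuous_contact_frequency(tracks, threshold_um=0.5).p_hat
        assert 0.0 <= p05 - p04 < 0.05


class TestDistanceHistogram:
    def test_single_cell_lands_in_right_bin(self):
        edges, counts = distance_histogram(_tracks_from_distances([[0.25]]), 0, 0.1)
        assert counts.sum() == 1
        assert counts[2] == 1  # [0.2, 0.3)

    def test_counts_conserve_cells(self):
        rng = np.random.default_rng(1)
        dists = rng.uniform(0, 1.2, size=(50, 1)).tolist()
        _, counts = distance_histogram(_tracks_from_distances(dists), 0, 0.05)
        assert counts.sum() == 50

    def test_free_population_follows_rayleigh(self, inter_pair, model):
        # projected distances of a free population are Rayleigh distributed
        pop = sample_population(inter_pair, 0.0, 10_000, model, seed=25)
        tracks = simulate_timelapse(
            pop, n_frames=1, loc_noise_nm=0.0, detect_prob=1.0, seed=26
        )
        wide = tracks.pivot_table(
            index="cell_id", columns="channel", values=["x_um", "y_um"]
        )
        d = np.hypot(
            wide[("x_um", 2)] - wide[("x_um", 1)], wide[("y_um", 2)] - wide[("y_um", 1)]
        )
        ks = stats.kstest(d, "rayleigh", args=(0, model.inter_sigma_nm / 1000.0))
        assert ks.pvalue > 0.01

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            distance_histogram(_tracks_from_distances([[0.2]]), 0, 0.0)
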