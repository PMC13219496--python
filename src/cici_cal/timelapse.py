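"""Time-lapse two-channel dot-track simulation.

Emulates fluorescence imaging of the two labelled arrays over a few frames
(default three frames, 240 s apart).  Per axis, each cell's true separation
follows a stationary mean-zero Ornstein-Uhlenbeck process whose stationary sd
equals the population draw's per-axis sd, so looped cells fluctuate around the
tether scale and free cells around the chain scale:

    d(t + dt) = d(t) * exp(-dt/tau) + N(0, sigma^2 * (1 - exp(-2 dt/tau)))

The default relaxation time tau = 60 s makes 240 s frames only weakly
correlated, so transient encounters of free cells rarely persist across three
frames -- the rationale for the continuous co-localization criterion.
Observed dot coordinates add independent Gaussian localization noise per axis
and each dot is detected per frame with probability ``detect_prob``.

Tracks are tidy tables with one row per (cell, frame, channel):
cell_id, frame, time_s, channel, x_um, y_um, z_um, detected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .population import CellPopulation

__all__ = ["simulate_timelapse", "read_tracks", "write_tracks", "TRACK_COLUMNS"]

TRACK_COLUMNS = ["cell_id", "frame", "time_s", "channel", "x_um", "y_um", "z_um", "detected"]

# Nominal stage position (um) of the first dot; only separations carry signal.
_CENTER_UM = np.array([2.0, 2.0, 1.0])


def simulate_timelapse(
    population: CellPopulation,
    n_frames: int = 3,
    interval_s: float = 240.0,
    tau_s: float = 60.0,
    loc_noise_nm: float = 50.0,
    detect_prob: float = 0.9,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate dot tracks for every cell of a population.

    Returns a tidy DataFrame in the :data:`TRACK_COLUMNS` schema with two
    channels per cell per frame (channel 1 and 2, the two labelled arrays).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    if not 0.0 < detect_prob <= 1.0:
        raise ValueError("detect_prob must be in (0, 1]")
    if loc_noise_nm < 0:
        raise ValueError("loc_noise_nm must be non-negative")

    rng = np.random.default_rng(seed)
    n = population.n_cells
    sigma = population.sigma_nm[:, None]  # (n, 1), per-axis stationary sd

    decay = np.exp(-interval_s / tau_s)
    innovation_sd = np.sqrt(np.maximum(0.0, 1.0 - decay**2))

    sep = population.separation.copy()  # (n, 3) nm, stationary start
    rows = []
    for frame in range(n_frames):
        if frame > 0:
            sep = sep * decay + rng.normal(0.0, 1.0, size=(n, 3)) * sigma * innovation_sd
        # dot positions (nm): dot 1 at -sep/2 around the nominal center, dot 2 at +sep/2
        for channel, sign in ((1, -0.5), (2, 0.5)):
            pos_nm = _CENTER_UM * 1000.0 + sign * sep
            obs_nm = pos_nm + rng.normal(0.0, loc_noise_nm, size=(n, 3))
            detected = rng.random(n) < detect_prob
            rows.append(
                pd.DataFrame(
                    {
                        "cell_id": np.arange(n),
                        "frame": frame,
                        "time_s": frame * interval_s,
                        "channel": channel,
                        "x_um": obs_nm[:, 0] / 1000.0,
                        "y_um": obs_nm[:, 1] / 1000.0,
                        "z_um": obs_nm[:, 2] / 1000.0,
                        "detected": detected,
                    }
                )
            )
    tracks = pd.concat(rows, ignore_index=True)
    return tracks.sort_values(["cell_id", "frame", "channel"], ignore_index=True)


def write_tracks(tracks: pd.DataFrame, path) -> None:
    tracks.to_csv(path, sep="\t", index=False)


def read_tracks(path) -> pd.DataFrame:
    tracks = pd.read_csv(path, sep="\t")
    missing = set(TRACK_COLUMNS) - set(tracks.columns)
    if missing:
        raise ValueError(f"{path}: missing track columns {sorted(missing)}")
    tracks["detected"] = tracks["detected"].astype(bool)
    return tracks
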