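"""Absolute contact frequency from two-channel dot tracks.

The estimator mirrors the imaging definition of absolute contact frequency:
a cell is counted as "in contact" when the x-y projected distance between the
two labelled dots stays below a threshold (default 0.4 um, strict ``<``) in
``k`` consecutive frames (default 3).  Requiring temporal continuity
suppresses false positives from transient encounters of untethered loci,
whose separations decorrelate between 240 s frames.

Because axial resolution is the limiting factor in the source imaging setup,
all distances are x-y projections; z is carried in the track schema but
ignored by the estimator.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ContactFrequencyEstimate",
    "xy_distance",
    "colocalized_fraction",
    "continuous_contact_frequency",
    "distance_histogram",
]


@dataclass(frozen=True)
class ContactFrequencyEstimate:
    """Fraction of cells in continuous contact, with a 95% binomial interval."""

    p_hat: float
    n_cells_included: int
    n_cells_contact: int
    ci_low: float
    ci_high: float
    threshold_um: float
    k_frames: int

    def to_dict(self) -> dict:
        return asdict(self)


def xy_distance(dot_a, dot_b) -> float:
    """Euclidean distance of the x-y projections of two dots (um); z is ignored."""
    ax, ay = float(dot_a[0]), float(dot_a[1])
    bx, by = float(dot_b[0]), float(dot_b[1])
    if not all(math.isfinite(v) for v in (ax, ay, bx, by)):
        raise ValueError("undetected or non-finite dot coordinates have no distance")
    return math.hypot(ax - bx, ay - by)


def _track_arrays(tracks: pd.DataFrame):
    """Pivot tidy tracks into (cells, frames) arrays of xy distance and joint detection."""
    if tracks.empty:
        raise ValueError("empty track table")
    wide = tracks.pivot_table(
        index=["cell_id", "frame"],
        columns="channel",
        values=["x_um", "y_um", "detected"],
        aggfunc="first",
    )
    cells = wide.index.get_level_values("cell_id").unique()
    frames = np.sort(tracks["frame"].unique())
    idx = pd.MultiIndex.from_product([cells, frames], names=["cell_id", "frame"])
    wide = wide.reindex(idx)
    shape = (len(cells), len(frames))
    # NaNs from reindexing (missing rows) must read as "not detected"
    det1 = wide[("detected", 1)].to_numpy(float).reshape(shape)
    det2 = wide[("detected", 2)].to_numpy(float).reshape(shape)
    det = (det1 > 0.5) & (det2 > 0.5)
    dx = (wide[("x_um", 1)] - wide[("x_um", 2)]).to_numpy(float).reshape(shape)
    dy = (wide[("y_um", 1)] - wide[("y_um", 2)]).to_numpy(float).reshape(shape)
    dist = np.hypot(dx, dy)
    det &= np.isfinite(dist)
    return np.asarray(cells), dist, det


def colocalized_fraction(tracks: pd.DataFrame, frame_index: int, threshold_um: float = 0.4) -> float:
    """Fraction of cells with xy distance strictly below threshold at one frame.

    Only cells with both dots detected at that frame enter the denominator.
    """
    _, dist, det = _track_arrays(tracks)
    if frame_index < 0 or frame_index >= dist.shape[1]:
        raise ValueError(f"frame_index {frame_index} out of range")
    included = det[:, frame_index]
    if not included.any():
        raise ValueError("no cells with both dots detected at this frame")
    return float(np.mean(dist[included, frame_index] < threshold_um))


def continuous_contact_frequency(
    tracks: pd.DataFrame,
    threshold_um: float = 0.4,
    k_frames: int = 3,
    ci_method: str = "wilson",
    window: str = "first",
    lenient: bool = False,
) -> ContactFrequencyEstimate:
    """Estimate the absolute contact frequency from temporal co-localization.

    A cell is in contact iff both dots are detected and closer than
    ``threshold_um`` (x-y, strict) in ``k_frames`` consecutive frames.  By
    default the first ``k_frames`` frames are evaluated and a cell enters the
    denominator only if both dots are detected in all of them; ``window="any"``
    accepts any run of ``k_frames`` consecutive frames instead.  With
    ``lenient=True`` co-localization is required only on frames where both
    dots are detected (at least two such frames), tolerating dot loss.

    The 95% interval is Wilson by default (``ci_method="beta"`` gives
    Clopper-Pearson).
    """
    _, dist, det = _track_arrays(tracks)
    n_frames = dist.shape[1]
    if k_frames < 1:
        raise ValueError("k_frames must be >= 1")
    if n_frames < k_frames:
        raise ValueError(f"tracks have {n_frames} frames, need at least {k_frames}")

    coloc = det & (dist < threshold_um)
    if lenient:
        window_det = det[:, :k_frames] if window == "first" else det
        included = window_det.sum(axis=1) >= 2
        contact = included & np.all(~window_det | coloc[:, : window_det.shape[1]], axis=1)
    elif window == "first":
        included = det[:, :k_frames].all(axis=1)
        contact = coloc[:, :k_frames].all(axis=1)
    elif window == "any":
        runs = np.stack(
            [det[:, i : i + k_frames].all(axis=1) for i in range(n_frames - k_frames + 1)]
        )
        cruns = np.stack(
            [coloc[:, i : i + k_frames].all(axis=1) for i in range(n_frames - k_frames + 1)]
        )
        included = runs.any(axis=0)
        contact = cruns.any(axis=0)
    else:
        raise ValueError(f"unknown window mode {window!r}")

    n_inc = int(included.sum())
    if n_inc == 0:
        raise ValueError("no cells satisfy the inclusion rule")
    n_contact = int((contact & included).sum())
    ci_low, ci_high = proportion_confint(n_contact, n_inc, alpha=0.05, method=ci_method)
    return ContactFrequencyEstimate(
        p_hat=n_contact / n_inc,
        n_cells_included=n_inc,
        n_cells_contact=n_contact,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        threshold_um=threshold_um,
        k_frames=k_frames,
    )


def distance_histogram(tracks: pd.DataFrame, frame_index: int, bin_width_um: float):
    """Histogram of xy dot distances at one frame over included cells.

    Returns ``(edges, counts)``; counts sum to the number of included cells.
    """
    if bin_width_um <= 0:
        raise ValueError("bin width must be positive")
    _, dist, det = _track_arrays(tracks)
    if frame_index < 0 or frame_index >= dist.shape[1]:
        raise ValueError(f"frame_index {frame_index} out of range")
    included = det[:, frame_index]
    if not included.any():
        raise ValueError("no cells with both dots detected at this frame")
    d = dist[included, frame_index]
    n_bins = int(np.ceil((d.max() + 1e-12) / bin_width_um)) or 1
    edges = np.arange(n_bins + 1) * bin_width_um
    counts, _ = np.histogram(d, bins=edges)
    return edges, counts
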