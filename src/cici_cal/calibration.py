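"""Linear calibration of Hi-C junction signals against contact frequencies.

Each titration sample contributes a calibration point (f, s): f is the
absolute contact frequency measured by imaging, s the mean Hi-C signal of the
window centered on the junction.  An ordinary-least-squares line per locus
pair gives the signal-per-unit-frequency slope; the average slope of the
intra-chromosomal pairs converts genome-wide signals into absolute contact
frequencies.  A bootstrap ratio of inter to intra slopes tests for a
class-level sensitivity bias, and a simulation power analysis locates the
smallest loop fraction the 3-SD junction difference rule can detect at a
given sequencing depth.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import statsmodels.api as sm

from .hicops import junction_signal, normalize_to_smallest, restriction_site_correction
from .hicsim import JunctionSpec, simulate_hic
from .loci import LocusPair
from .matrix import GenomeBins
from .polymer import PolymerModel

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationPoint",
    "CalibrationFit",
    "fit_linear",
    "background_subtract",
    "average_intra_slope",
    "signal_to_frequency",
    "slope_bias_test",
    "detection_limit",
    "junction_window_detected",
]


@dataclass(frozen=True)
class CalibrationPoint:
    """One titration sample: measured frequency vs junction Hi-C signal."""

    pair_id: str
    replicate_id: int
    contact_frequency: float
    signal: float
    background_signal: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.contact_frequency <= 1.0:
            raise ValueError("contact_frequency outside [0, 1]")


@dataclass(frozen=True)
class CalibrationFit:
    """OLS fit of junction signal on contact frequency for one pair."""

    pair_id: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    residual_sd: float
    slope_se: float
    intercept_se: float

    def to_dict(self) -> dict:
        return asdict(self)


def fit_linear(points: list[CalibrationPoint]) -> CalibrationFit:
    """OLS of signal on frequency with free intercept; replicates are points."""
    if len(points) < 2:
        raise ValueError("need at least two calibration points")
    f = np.array([p.contact_frequency for p in points])
    s = np.array([p.signal for p in points])
    if np.allclose(f, f[0]):
        raise ValueError("degenerate design: all frequencies equal")
    if len(points) == 2:  # exact interpolation, no residual dof
        slope = (s[1] - s[0]) / (f[1] - f[0])
        return CalibrationFit(
            pair_id=points[0].pair_id,
            slope=float(slope),
            intercept=float(s[0] - slope * f[0]),
            r_squared=1.0,
            n_points=2,
            residual_sd=0.0,
            slope_se=0.0,
            intercept_se=0.0,
        )
    model = sm.OLS(s, sm.add_constant(f)).fit()
    return CalibrationFit(
        pair_id=points[0].pair_id,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        n_points=len(points),
        residual_sd=float(np.sqrt(model.scale)),
        slope_se=float(model.bse[1]),
        intercept_se=float(model.bse[0]),
    )


def background_subtract(points: list[CalibrationPoint]) -> list[CalibrationPoint]:
    """Subtract each point's uninduced background signal (may go negative)."""
    out = []
    for p in points:
        if p.background_signal is None:
            raise ValueError(f"point ({p.pair_id}, rep {p.replicate_id}) has no background signal")
        out.append(
            CalibrationPoint(
                pair_id=p.pair_id,
                replicate_id=p.replicate_id,
                contact_frequency=p.contact_frequency,
                signal=p.signal - p.background_signal,
                background_signal=p.background_signal,
            )
        )
    return out


def average_intra_slope(fits: list[CalibrationFit], intra_pair_ids) -> float:
    """Unweighted mean slope over the intra-chromosomal pairs."""
    intra = [f.slope for f in fits if f.pair_id in set(intra_pair_ids)]
    if not intra:
        raise ValueError("no intra-chromosomal fits")
    return float(np.mean(intra))


def signal_to_frequency(
    signal, mean_slope: float, intercept: float | None = None
):
    """Convert Hi-C signal to absolute contact frequency.

    Default is the through-origin conversion f = s / slope; passing an
    ``intercept`` switches to f = (s - b) / slope.  Results are clipped to
    [0, 1] with a logged note when clipping occurs.
    """
    if mean_slope <= 0:
        raise ValueError("mean slope must be positive")
    s = np.asarray(signal, dtype=float)
    f = (s - (intercept or 0.0)) / mean_slope
    clipped = np.clip(f, 0.0, 1.0)
    n_clip = int(np.sum(clipped != f))
    if n_clip:
        logger.info("signal_to_frequency: clipped %d values into [0, 1]", n_clip)
    return clipped[()]


def slope_bias_test(
    fits: list[CalibrationFit],
    intra_ids,
    inter_ids,
    points_by_pair: dict[str, list[CalibrationPoint]] | None = None,
    n_boot: int = 2000,
    seed: int = 0,
):
    """Ratio of mean inter-chromosomal to mean intra-chromosomal slope.

    With per-pair replicate points supplied, a percentile bootstrap CI is
    computed by resampling replicate-level points within each pair and
    refitting.  Returns (ratio, ci) where ci is None without points.
    """
    intra_ids, inter_ids = set(intra_ids), set(inter_ids)
    intra = [f.slope for f in fits if f.pair_id in intra_ids]
    inter = [f.slope for f in fits if f.pair_id in inter_ids]
    if not intra or not inter:
        raise ValueError("need at least one fit in each class")
    ratio = float(np.mean(inter) / np.mean(intra))
    if points_by_pair is None:
        return ratio, None

    rng = np.random.default_rng(seed)
    ratios = np.empty(n_boot)
    for b in range(n_boot):
        intra_slopes, inter_slopes = [], []
        for pid, pts in points_by_pair.items():
            # resample replicates within each frequency level to keep the design
            by_f: dict[float, list[CalibrationPoint]] = {}
            for p in pts:
                by_f.setdefault(p.contact_frequency, []).append(p)
            resampled = []
            for level in by_f.values():
                idx = rng.integers(0, len(level), size=len(level))
                resampled.extend(level[i] for i in idx)
            slope = fit_linear(resampled).slope
            if pid in intra_ids:
                intra_slopes.append(slope)
            elif pid in inter_ids:
                inter_slopes.append(slope)
        ratios[b] = np.mean(inter_slopes) / np.mean(intra_slopes)
    ci = (float(np.percentile(ratios, 2.5)), float(np.percentile(ratios, 97.5)))
    return ratio, ci


# ---------------------------------------------------------------------------
# detection power analysis


def junction_window_detected(
    plus_raw,
    minus_raw,
    pair: LocusPair,
    half_window_bp: float = 15_000,
    guard_bp: float = 100_000,
    n_sd: float = 3.0,
) -> bool:
    """3-SD detection rule on the junction window mean difference.

    Matrices are normalized to equal totals and site-corrected, the
    difference map is formed, and the junction window mean is compared with
    the mean + ``n_sd`` SD of window means at matched positions: same
    genomic-separation stratum on the same chromosome for intra pairs, the
    whole chromosome pair for inter pairs, excluding a guard zone around the
    junction loci.
    """
    plus, minus = normalize_to_smallest([plus_raw, minus_raw])
    plus = restriction_site_correction(plus)
    minus = restriction_site_correction(minus)
    bins = plus.bins
    diff = plus.counts - minus.counts
    h = int(half_window_bp // bins.bin_size)
    ia = bins.bin_index(pair.chrom_a, pair.pos_a)
    ib = bins.bin_index(pair.chrom_b, pair.pos_b)
    guard_bins = int(guard_bp // bins.bin_size)

    def window_mean(i, j):
        return diff[i - h : i + h + 1, j - h : j + h + 1].mean()

    target = window_mean(ia, ib)
    bg = []
    if pair.is_intra:
        sl = bins.chrom_slice(pair.chrom_a)
        d = abs(ib - ia)
        for i in range(sl.start + h, sl.stop - d - h):
            j = i + d
            if abs(i - ia) <= guard_bins and abs(j - ib) <= guard_bins:
                continue
            bg.append(window_mean(i, j))
    else:
        sl_a = bins.chrom_slice(pair.chrom_a)
        sl_b = bins.chrom_slice(pair.chrom_b)
        for i in range(sl_a.start + h, sl_a.stop - h):
            for j in range(sl_b.start + h, sl_b.stop - h):
                if abs(i - ia) <= guard_bins and abs(j - ib) <= guard_bins:
                    continue
                bg.append(window_mean(i, j))
    if len(bg) < 3:
        raise ValueError("background window set too small")
    bg = np.array(bg)
    return bool(target > bg.mean() + n_sd * bg.std(ddof=1))


def detection_limit(
    bins: GenomeBins,
    pair: LocusPair,
    model: PolymerModel,
    p_grid,
    n_contacts: int = 18_000_000,
    n_reps: int = 10,
    bias_sd: float = 0.2,
    seed: int = 0,
    half_window_bp: float = 15_000,
):
    """Smallest loop fraction detected by the 3-SD junction rule.

    For each p in the ascending grid, ``n_reps`` replicate pairs of libraries
    are simulated (junction frequency p vs 0) and the junction window tested;
    p counts as detected when at least half the replicates are significant.
    Returns (limit, report) where report maps p -> detected replicate count;
    limit is None when no grid point is detected.
    """
    p_grid = list(p_grid)
    if sorted(p_grid) != p_grid:
        raise ValueError("p_grid must be sorted ascending")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    ss = np.random.SeedSequence(seed)
    report: dict[float, int] = {}
    limit = None
    for p in p_grid:
        detected = 0
        for rep in range(n_reps):
            s_plus, s_minus = ss.spawn(2)
            plus = simulate_hic(
                bins, [JunctionSpec(pair, p)], model, n_contacts, bias_sd,
                seed=s_plus.generate_state(1)[0] % (2**31),
            )
            minus = simulate_hic(
                bins, [JunctionSpec(pair, 0.0)], model, n_contacts, bias_sd,
                seed=s_minus.generate_state(1)[0] % (2**31),
            )
            if junction_window_detected(plus, minus, pair, half_window_bp):
                detected += 1
        report[p] = detected
        if limit is None and detected >= n_reps / 2:
            limit = p
    return limit, report
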