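"""Contact-matrix operations: normalization, correction, balancing, and the
junction-level statistics used to compare induced and uninduced populations.

The processing order mirrors the study pipeline: replicates are merged and
read-count normalized to the smallest library; counts are corrected for
restriction-site density per bin; residual multiplicative biases are removed
with Knight-Ruiz matrix balancing.  On the processed maps the package computes
junction-window signals, difference-significance maps (3 SD above a
distance-matched background), multi-depth insulation scores, and the
contact-vs-distance decay curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .loci import LocusPair
from .matrix import ContactMatrix, GenomeBins

logger = logging.getLogger(__name__)

__all__ = [
    "bin_contact_pairs",
    "normalize_to_smallest",
    "restriction_site_correction",
    "kr_balance",
    "merge_replicates",
    "log2_fold_change",
    "junction_signal",
    "difference_significance",
    "insulation_score",
    "distance_decay",
    "DifferenceMap",
    "InsulationTrack",
    "KRConvergenceError",
]


# ---------------------------------------------------------------------------
# matrix building and normalization


def bin_contact_pairs(contact_pairs, bins: GenomeBins) -> ContactMatrix:
    """Accumulate (chrom1, pos1, chrom2, pos2) contact pairs into a matrix.

    Pairs with coordinates outside the genome are rejected (logged, counted,
    not raised).  Pair order is irrelevant: both orderings land in the same
    symmetric cell.
    """
    n = bins.n_bins
    counts = np.zeros((n, n))
    rejected = 0
    for chrom1, pos1, chrom2, pos2 in contact_pairs:
        try:
            i = bins.bin_index(chrom1, pos1)
            j = bins.bin_index(chrom2, pos2)
        except ValueError:
            rejected += 1
            continue
        counts[i, j] += 1
        if i != j:
            counts[j, i] += 1
    if rejected:
        logger.warning("bin_contact_pairs: rejected %d out-of-range pairs", rejected)
    return ContactMatrix(bins=bins, counts=counts)


def normalize_to_smallest(
    matrices: list[ContactMatrix], mode: str = "scale", seed: int | None = None
) -> list[ContactMatrix]:
    """Normalize libraries to the smallest read count.

    Default mode scales each matrix by ``min_total / total`` (preserving
    within-matrix ratios); ``mode="downsample"`` instead draws a without-
    replacement subsample of contacts down to the smallest total (requires a
    seed and integer counts).
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    totals = [m.total_contacts for m in matrices]
    if any(t <= 0 for t in totals):
        raise ValueError("cannot normalize a matrix with zero total contacts")
    target = min(totals)
    out = []
    if mode == "scale":
        for m, t in zip(matrices, totals):
            out.append(m.copy_with(counts=m.counts * (target / t)))
    elif mode == "downsample":
        if seed is None:
            raise ValueError("downsampling requires a seed")
        rng = np.random.default_rng(seed)
        for m, t in zip(matrices, totals):
            iu = np.triu_indices(m.n_bins)
            vals = np.round(m.counts[iu]).astype(np.int64)
            sub = rng.multivariate_hypergeometric(vals, int(round(target)), method="marginals")
            counts = np.zeros_like(m.counts)
            counts[iu] = sub
            counts = np.triu(counts) + np.triu(counts, 1).T
            out.append(m.copy_with(counts=counts))
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return out


def restriction_site_correction(matrix: ContactMatrix, bins: GenomeBins | None = None) -> ContactMatrix:
    """Divide counts by the product of per-bin restriction-site counts.

    Bins with zero sites are masked.  After correction the matrix is rescaled
    so the total contact count is preserved; site counts are normalized by
    their mean so an all-equal site vector is a no-op.
    """
    bins = bins or matrix.bins
    if bins.restriction_sites is None:
        raise ValueError("bins carry no restriction-site counts")
    sites = bins.restriction_sites
    valid = matrix.mask & (sites > 0)
    if not valid.any():
        raise ValueError("all bins have zero restriction sites")
    rel = np.where(valid, sites / sites[valid].mean(), np.nan)
    corrected = matrix.counts / np.outer(rel, rel)
    corrected[~valid, :] = 0.0
    corrected[:, ~valid] = 0.0
    total_before = np.triu(np.where(np.outer(valid, valid), matrix.counts, 0.0)).sum()
    total_after = np.triu(corrected).sum()
    if total_after > 0:
        corrected *= total_before / total_after
    return matrix.copy_with(counts=corrected, mask=valid, weights=None)


class KRConvergenceError(RuntimeError):
    """Knight-Ruiz balancing failed to converge; carries iteration diagnostics."""

    def __init__(self, message: str, outer_iterations: int, residual: float):
        super().__init__(message)
        self.outer_iterations = outer_iterations
        self.residual = residual


def kr_balance(matrix: ContactMatrix, tol: float = 1e-6, max_iter: int = 1000) -> np.ndarray:
    """Knight-Ruiz balancing weights for a symmetric non-negative matrix.

    Solves diag(w) M diag(w) e = c e (equal row sums over unmasked bins) with
    the inner-outer Newton iteration of the fast balancing algorithm, then
    rescales so the mean balanced row sum is 1.  All-zero rows are masked and
    receive weight 0.  Convergence is declared when the coefficient of
    variation of balanced row sums is <= tol; otherwise a
    :class:`KRConvergenceError` is raised.

    The weights are also stored on ``matrix.weights``.
    """
    A_full = matrix.counts
    valid = matrix.mask & (A_full.sum(axis=1) > 0)
    if not valid.any():
        raise ValueError("no valid bins to balance")
    A = A_full[np.ix_(valid, valid)]
    # pre-scale so row sums are O(1); the Newton iteration targets row sums = 1
    scale = A.sum(axis=1).mean()
    A = A / scale
    n = A.shape[0]

    x = np.ones(n)
    delta, Delta = 0.1, 3.0
    g, etamax = 0.9, 0.1
    eta = etamax
    stop_tol = tol * 0.5
    rt = tol**2
    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rout = rho_km1
    rold = rout
    outer = 0
    while rout > rt:
        outer += 1
        if outer > max_iter:
            raise KRConvergenceError(
                f"KR balancing did not converge in {max_iter} outer iterations "
                f"(residual {np.sqrt(rout):.3e})",
                outer_iterations=outer,
                residual=float(np.sqrt(rout)),
            )
        k = 0
        y = np.ones(n)
        innertol = max(eta**2 * rout, rt)
        rho_km2 = rho_km1
        while rho_km1 > innertol:  # CG inner loop
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            alpha = rho_km1 / (p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                if delta == 0:
                    break
                ind = ap < 0
                gamma = ((delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                ind = ynew > Delta
                gamma = ((Delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
        x = x * y
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        rat = rout / rold
        rold = rout
        res_norm = np.sqrt(rout)
        eta_o = eta
        eta = g * rat
        if g * eta_o**2 > 0.1:  # safeguard from the reference scheme
            eta = max(eta, g * eta_o**2)
        eta = max(min(eta, etamax), stop_tol / max(res_norm, 1e-300))

    # rescale so the mean balanced row sum over valid bins equals 1
    x = x / np.sqrt(scale)
    rowsums = x * (A_full[np.ix_(valid, valid)] @ x)
    x = x / np.sqrt(rowsums.mean())

    weights = np.zeros(matrix.n_bins)
    weights[valid] = x
    cv = _rowsum_cv(A_full, weights, valid)
    if cv > tol:
        raise KRConvergenceError(
            f"balanced row-sum CV {cv:.3e} exceeds tolerance {tol:.1e}",
            outer_iterations=outer,
            residual=float(cv),
        )
    matrix.weights = weights
    matrix.mask = valid
    return weights


def _rowsum_cv(counts: np.ndarray, weights: np.ndarray, valid: np.ndarray) -> float:
    w = np.where(valid, weights, 0.0)
    rs = (counts * np.outer(w, w)).sum(axis=1)[valid]
    return float(rs.std() / rs.mean())


def merge_replicates(matrices: list[ContactMatrix]) -> ContactMatrix:
    """Element-wise sum of replicate matrices on identical bins."""
    if not matrices:
        raise ValueError("need at least one matrix")
    first = matrices[0]
    for m in matrices[1:]:
        if (
            m.bins.chromsizes != first.bins.chromsizes
            or m.bins.bin_size != first.bins.bin_size
        ):
            raise ValueError("replicates are binned on different genomes")
    counts = sum(m.counts for m in matrices)
    mask = np.logical_and.reduce([m.mask for m in matrices])
    return first.copy_with(counts=counts, mask=mask, weights=None)


def log2_fold_change(
    plus: ContactMatrix, minus: ContactMatrix, pseudocount: float = 1.0
) -> np.ndarray:
    """log2((plus + eps) / (minus + eps)) per bin pair."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if plus.counts.shape != minus.counts.shape:
        raise ValueError("matrices have different shapes")
    return np.log2((plus.counts + pseudocount) / (minus.counts + pseudocount))


# ---------------------------------------------------------------------------
# junction-level statistics


def _junction_window(
    bins: GenomeBins, pair: LocusPair, half_window_bp: float
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Bin-index ranges of the square window centered on the junction.

    Returns (rows, cols, clipped); ranges are clipped to the chromosomes.
    """
    ia = bins.bin_index(pair.chrom_a, pair.pos_a)
    ib = bins.bin_index(pair.chrom_b, pair.pos_b)
    h = int(half_window_bp // bins.bin_size)
    sl_a = bins.chrom_slice(pair.chrom_a)
    sl_b = bins.chrom_slice(pair.chrom_b)
    rows = np.arange(max(ia - h, sl_a.start), min(ia + h + 1, sl_a.stop))
    cols = np.arange(max(ib - h, sl_b.start), min(ib + h + 1, sl_b.stop))
    clipped = len(rows) != 2 * h + 1 or len(cols) != 2 * h + 1
    return rows, cols, clipped


def junction_signal(
    matrix: ContactMatrix,
    pair: LocusPair,
    half_window_bp: float = 15_000,
    use_weights: bool = False,
) -> float:
    """Mean signal of the square window centered on the junction bin pair.

    The default +-15 kb half-window yields a 30 kb x 30 kb (3x3 bins at
    10 kb) square.  Windows reaching past a chromosome end are clipped with a
    logged warning.  With ``use_weights=True`` the balanced matrix is read.
    """
    rows, cols, clipped = _junction_window(matrix.bins, pair, half_window_bp)
    if clipped:
        logger.warning(
            "junction window for pair %s clipped at a chromosome edge", pair.pair_id
        )
    data = matrix.balanced() if use_weights else matrix.counts
    return float(data[np.ix_(rows, cols)].mean())


@dataclass
class InsulationTrack:
    """Multi-depth insulation scores per bin.

    ``per_depth[d]`` holds the raw diamond means at depth ``d`` bp;
    ``score`` is the aggregated log2-ratio track; NaN marks bins within
    ``max_depth`` of a chromosome end (undefined).
    """

    bins: GenomeBins
    per_depth: dict[int, np.ndarray]
    score: np.ndarray
    defined: np.ndarray

    def to_bedgraph(self, path) -> None:
        tbl = self.bins.table()
        tbl["score"] = self.score
        tbl.loc[~self.defined, "score"] = np.nan
        tbl[["chrom", "start", "end", "score"]].dropna().to_csv(
            path, sep="\t", index=False, header=False
        )


def insulation_score(
    matrix: ContactMatrix,
    min_depth: int = 30_000,
    max_depth: int = 100_000,
    step: int = 10_000,
    use_weights: bool = False,
) -> InsulationTrack:
    """Multi-depth diamond insulation scores.

    For bin i and depth d (bins), the raw score is the mean of the diamond
    submatrix [i-d, i) x (i, i+d] restricted to the bin's chromosome; the
    aggregated score is the mean over depths of log2(raw / chromosome-wide
    mean raw at that depth).  Bins within ``max_depth`` of either chromosome
    end are flagged undefined.
    """
    bs = matrix.bins.bin_size
    if min_depth < bs:
        raise ValueError("min_depth must be at least one bin")
    depths_bp = list(range(int(min_depth), int(max_depth) + 1, int(step)))
    data = matrix.balanced() if use_weights else matrix.counts
    n = matrix.n_bins
    per_depth = {d: np.full(n, np.nan) for d in depths_bp}
    defined = np.zeros(n, dtype=bool)
    max_d_bins = int(max_depth) // bs

    for chrom in matrix.bins.chromsizes:
        sl = matrix.bins.chrom_slice(chrom)
        block = data[sl, sl]
        nb = block.shape[0]
        for d_bp in depths_bp:
            d = d_bp // bs
            for i in range(max_d_bins, nb - max_d_bins):
                per_depth[d_bp][sl.start + i] = block[i - d : i, i + 1 : i + d + 1].mean()
        for i in range(max_d_bins, nb - max_d_bins):
            defined[sl.start + i] = True

    score = np.zeros(n)
    n_depths = 0
    chrom_idx = matrix.bins.chrom_of_bins()
    for d_bp, raw in per_depth.items():
        ratio = np.full(n, np.nan)
        for k in np.unique(chrom_idx):
            sel = (chrom_idx == k) & defined & np.isfinite(raw) & (raw > 0)
            if sel.any():
                ratio[sel] = np.log2(raw[sel] / raw[sel].mean())
        score = score + np.where(np.isfinite(ratio), ratio, np.nan)
        n_depths += 1
    score = score / n_depths
    defined = defined & np.isfinite(score)
    score[~defined] = np.nan
    return InsulationTrack(bins=matrix.bins, per_depth=per_depth, score=score, defined=defined)


@dataclass
class DifferenceMap:
    """Local difference map around a junction with 3-SD significance calls."""

    pair: LocusPair
    rows: np.ndarray  # bin ids along the first locus axis
    cols: np.ndarray  # bin ids along the second locus axis
    difference: np.ndarray  # (len(rows), len(cols)) plus - minus
    zscores: np.ndarray
    background_mean: np.ndarray  # broadcast to the map shape
    background_sd: np.ndarray
    significant: np.ndarray  # bool mask: difference > mean + 3 SD
    footprint_bp: dict = field(default_factory=dict)

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())


def _near_junction(i, j, ia: int, ib: int, guard_bins: int):
    """True for bin pairs inside the guarded square around the junction.

    A pair is guarded only when its two ends are jointly close to the two
    junction loci (either orientation) — that is where loop signal can leak;
    pairs sharing just one bin with the junction neighbourhood are valid
    background.
    """
    i = np.asarray(i)
    j = np.asarray(j)
    return (
        (np.abs(i - ia) <= guard_bins) & (np.abs(j - ib) <= guard_bins)
    ) | ((np.abs(i - ib) <= guard_bins) & (np.abs(j - ia) <= guard_bins))


def _background_stats_intra(
    diff: np.ndarray,
    bins: GenomeBins,
    chrom: str,
    rows: np.ndarray,
    cols: np.ndarray,
    ia: int,
    ib: int,
    guard_bins: int,
):
    """Distance-stratified background mean/SD on one chromosome.

    For each genomic separation occurring in the local window, statistics are
    taken over all bin pairs of the chromosome at that separation outside the
    guarded junction square.
    """
    sl = bins.chrom_slice(chrom)
    strata = {}
    for d in np.unique(np.abs(rows[:, None] - cols[None, :])):
        i = np.arange(sl.start, sl.stop - d)
        j = i + d
        keep = ~_near_junction(i, j, ia, ib, guard_bins)
        vals = diff[i[keep], j[keep]]
        if vals.size < 2:
            raise ValueError(f"background empty at separation {d} bins")
        strata[int(d)] = (float(vals.mean()), float(vals.std(ddof=1)))
    return strata


def difference_significance(
    plus: ContactMatrix,
    minus: ContactMatrix,
    pair: LocusPair,
    local_span_bp: float = 100_000,
    guard_bp: float = 100_000,
    n_sd: float = 3.0,
) -> DifferenceMap:
    """Per-bin-pair difference map (plus - minus) with 3-SD significance.

    Both matrices must be normalized to equal totals.  The local span is the
    square +-``local_span_bp`` around the junction.  Background statistics
    come from bin pairs at the same genomic separation on the same chromosome
    (intra pairs) or from all bin pairs of the same chromosome pair (inter
    pairs), excluding a guard zone of ``guard_bp`` around each junction locus.
    A bin pair is significant when its difference exceeds background mean +
    ``n_sd`` SD.  Contiguous significant runs along the two axes through the
    junction give the footprint extents.
    """
    if abs(plus.total_contacts - minus.total_contacts) > 1e-6 * max(
        plus.total_contacts, 1.0
    ):
        raise ValueError("matrices must be normalized to equal totals first")
    bins = plus.bins
    diff = plus.counts - minus.counts
    rows, cols, _ = _junction_window(bins, pair, local_span_bp)
    ia = bins.bin_index(pair.chrom_a, pair.pos_a)
    ib = bins.bin_index(pair.chrom_b, pair.pos_b)
    guard_bins = int(guard_bp // bins.bin_size)

    local = diff[np.ix_(rows, cols)]
    bg_mean = np.empty_like(local)
    bg_sd = np.empty_like(local)
    if pair.is_intra:
        strata = _background_stats_intra(
            diff, bins, pair.chrom_a, rows, cols, ia, ib, guard_bins
        )
        for a, i in enumerate(rows):
            for b, j in enumerate(cols):
                m, s = strata[int(abs(i - j))]
                bg_mean[a, b] = m
                bg_sd[a, b] = s
    else:
        sl_a = bins.chrom_slice(pair.chrom_a)
        sl_b = bins.chrom_slice(pair.chrom_b)
        block = diff[sl_a, sl_b]
        ii = np.arange(sl_a.start, sl_a.stop)
        jj = np.arange(sl_b.start, sl_b.stop)
        keep = ~_near_junction(ii[:, None], jj[None, :], ia, ib, guard_bins)
        vals = block[keep]
        if vals.size < 2:
            raise ValueError("background region empty")
        bg_mean[:] = vals.mean()
        bg_sd[:] = vals.std(ddof=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        z = (local - bg_mean) / bg_sd
    significant = local > bg_mean + n_sd * bg_sd

    # footprint: contiguous significant extent along each axis through the junction
    r0 = int(np.where(rows == ia)[0][0]) if ia in rows else None
    c0 = int(np.where(cols == ib)[0][0]) if ib in cols else None
    footprint = {}
    if r0 is not None and c0 is not None:
        footprint["axis_a_upstream_bp"] = _run_length(significant[:, c0], r0, -1) * bins.bin_size
        footprint["axis_a_downstream_bp"] = _run_length(significant[:, c0], r0, +1) * bins.bin_size
        footprint["axis_b_upstream_bp"] = _run_length(significant[r0, :], c0, -1) * bins.bin_size
        footprint["axis_b_downstream_bp"] = _run_length(significant[r0, :], c0, +1) * bins.bin_size
    return DifferenceMap(
        pair=pair,
        rows=rows,
        cols=cols,
        difference=local,
        zscores=z,
        background_mean=bg_mean,
        background_sd=bg_sd,
        significant=significant,
        footprint_bp=footprint,
    )


def _run_length(mask_1d: np.ndarray, start: int, direction: int) -> int:
    """Number of contiguous True entries walking from ``start`` (exclusive)."""
    n = 0
    i = start + direction
    while 0 <= i < len(mask_1d) and mask_1d[i]:
        n += 1
        i += direction
    return n


def distance_decay(
    matrices: list[ContactMatrix] | ContactMatrix,
    exclusion_windows: list[tuple[str, int, int]] | None = None,
    use_weights: bool = False,
) -> pd.DataFrame:
    """Mean signal per genomic separation over intra-chromosomal bin pairs.

    ``exclusion_windows`` are (chrom, start, end) intervals (e.g. around
    engineered arrays) whose bins are dropped.  Returns a DataFrame with
    separation_bp, mean_signal and n_pairs, averaged across input matrices.
    """
    if isinstance(matrices, ContactMatrix):
        matrices = [matrices]
    if not matrices:
        raise ValueError("need at least one matrix")
    bins = matrices[0].bins
    excluded = np.zeros(bins.n_bins, dtype=bool)
    for chrom, start, end in exclusion_windows or []:
        sl = bins.chrom_slice(chrom)
        for b in range(sl.start, sl.stop):
            b_start = (b - sl.start) * bins.bin_size
            if b_start < end and b_start + bins.bin_size > start:
                excluded[b] = True

    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for m in matrices:
        data = m.balanced() if use_weights else m.counts
        ok = m.mask & ~excluded
        for chrom in bins.chromsizes:
            sl = bins.chrom_slice(chrom)
            block = data[sl, sl]
            ok_c = ok[sl]
            nb = block.shape[0]
            for d in range(nb):
                i = np.arange(nb - d)
                keep = ok_c[i] & ok_c[i + d]
                if not keep.any():
                    continue
                vals = block[i[keep], i[keep] + d]
                sums[d] = sums.get(d, 0.0) + vals.sum()
                counts[d] = counts.get(d, 0) + vals.size
    rows = [
        (d * bins.bin_size, sums[d] / counts[d], counts[d]) for d in sorted(sums)
    ]
    return pd.DataFrame(rows, columns=["separation_bp", "mean_signal", "n_pairs"])
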