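"""Genome-wide Hi-C count simulation with a known junction contact frequency.

Expected contact weights follow the Gaussian-chain capture model: intra pairs
decay with genomic separation via the Maxwell capture probability, inter
pairs sit at a flat baseline, and the engineered junction (a small square of
bins around the array pair) carries the two-component mixture

    P = p * P_loop + (1 - p) * P_free

where p is the fraction of cells holding the stable loop.  Each bin also
carries a multiplicative log-normal bias and a restriction-site density
factor; reads are drawn multinomially with a fixed total (default emulates a
~18 M contact library).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .loci import LocusPair
from .matrix import ContactMatrix, GenomeBins
from .polymer import PolymerModel, gaussian_contact_probability

__all__ = ["simulate_hic", "expected_weights", "JunctionSpec"]


@dataclass(frozen=True)
class JunctionSpec:
    """An engineered pair together with its ground-truth contact frequency."""

    pair: LocusPair
    p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"contact frequency {self.p} outside [0, 1]")


def expected_weights(
    bins: GenomeBins,
    junctions: list[JunctionSpec],
    model: PolymerModel,
    bias: np.ndarray | None = None,
    junction_half_bins: int = 1,
) -> np.ndarray:
    """Expected (unnormalized) contact weight per bin pair.

    Without bias and site factors this is the pure capture-probability
    surface; the junction squares get the loop mixture applied on top of the
    local free baseline.
    """
    n = bins.n_bins
    if n == 0:
        raise ValueError("empty genome")
    bs = bins.bin_size
    chrom_idx = bins.chrom_of_bins()
    idx = np.arange(n)
    sep_bins = np.abs(idx[:, None] - idx[None, :])
    # effective genomic separation: same-bin pairs average ~half a bin apart
    sep_bp = np.maximum(sep_bins * bs, bs / 2.0)
    sigma_intra = model.rms_separation(sep_bp) / np.sqrt(3.0)
    p_intra = gaussian_contact_probability(sigma_intra, model.capture_radius_nm)
    p_inter = float(
        gaussian_contact_probability(model.inter_sigma_nm, model.capture_radius_nm)
    )
    same_chrom = chrom_idx[:, None] == chrom_idx[None, :]
    weights = np.where(same_chrom, p_intra, p_inter)

    p_loop = model.loop_contact_probability()
    for spec in junctions:
        ia = bins.bin_index(spec.pair.chrom_a, spec.pair.pos_a)
        ib = bins.bin_index(spec.pair.chrom_b, spec.pair.pos_b)
        h = junction_half_bins
        sl_a = bins.chrom_slice(spec.pair.chrom_a)
        sl_b = bins.chrom_slice(spec.pair.chrom_b)
        rows = np.arange(max(ia - h, sl_a.start), min(ia + h + 1, sl_a.stop))
        cols = np.arange(max(ib - h, sl_b.start), min(ib + h + 1, sl_b.stop))
        block = np.ix_(rows, cols)
        mixed = spec.p * p_loop + (1.0 - spec.p) * weights[block]
        weights[block] = mixed
        weights[np.ix_(cols, rows)] = mixed.T

    if bins.restriction_sites is not None:
        sites = bins.restriction_sites
        ok = sites > 0
        rel = np.where(ok, sites / max(sites[ok].mean(), 1e-300), 0.0)
        weights = weights * np.outer(rel, rel)
    if bias is not None:
        weights = weights * np.outer(bias, bias)
    return weights


def simulate_hic(
    bins: GenomeBins,
    pairs_with_p: list[JunctionSpec] | list[tuple[LocusPair, float]],
    model: PolymerModel,
    n_contacts: int = 18_000_000,
    bias_sd: float = 0.2,
    seed: int = 0,
    junction_half_bins: int = 1,
    bias: np.ndarray | None = None,
) -> ContactMatrix:
    """Draw a symmetric contact-count matrix with exactly ``n_contacts`` reads.

    Per-bin biases are log-normal with log-sd ``bias_sd``, drawn per call so
    separately prepared libraries get independent bias vectors; pass a fixed
    ``bias`` vector instead to emulate replicates of the same library family
    sharing systematic biases.  Counts are multinomial over the upper
    triangle of the expected-weight surface.
    """
    if n_contacts < 1:
        raise ValueError("n_contacts must be >= 1")
    junctions = [
        spec if isinstance(spec, JunctionSpec) else JunctionSpec(*spec)
        for spec in pairs_with_p
    ]
    rng = np.random.default_rng(seed)
    n = bins.n_bins
    if bias is None:
        bias = np.exp(rng.normal(0.0, bias_sd, size=n)) if bias_sd > 0 else np.ones(n)
    else:
        bias = np.asarray(bias, dtype=float)
    weights = expected_weights(bins, junctions, model, bias, junction_half_bins)

    iu = np.triu_indices(n)
    w = weights[iu]
    probs = w / w.sum()
    draws = rng.multinomial(int(n_contacts), probs)
    counts = np.zeros((n, n))
    counts[iu] = draws
    counts = np.triu(counts) + np.triu(counts, 1).T
    mask = (
        bins.restriction_sites > 0
        if bins.restriction_sites is not None
        else np.ones(n, dtype=bool)
    )
    return ContactMatrix(bins=bins, counts=counts, mask=mask)
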