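"""Gaussian-chain geometry and Hi-C capture probabilities.

The statistical stand-in for chromatin used throughout the package is an
isotropic Gaussian chain: the 3D separation vector of two loci ``s`` bp apart
on the same chromosome is mean-zero Gaussian with root-mean-square length

    R(s) = R0 * (s / s0) ** nu

anchored at ``s0`` = 40 kb, where imaging of budding-yeast chromatin places
R at roughly 250-350 nm (default R0 = 300 nm, the midpoint).  ``nu`` = 0.5 is
the ideal-chain exponent.  Three special separation scales complete the model:

* ``tether_rms_nm`` -- RMS separation of a stably looped (tethered) pair,
  default 100 nm, well inside the 0.4 um imaging co-localization threshold;
* ``inter_rms_nm`` -- RMS separation of unlinked loci on different
  chromosomes, default 1400 nm (order of the yeast nuclear diameter);
* ``capture_radius_nm`` -- the 3D radius within which two loci can be
  crosslinked and ligated in Hi-C, estimated at 100-400 nm (default 250 nm,
  the midpoint).

Contact probabilities follow in closed form: for an isotropic 3D Gaussian
separation with per-axis standard deviation sigma, the radial distance is
Maxwell-distributed and

    P(||D|| <= r_c) = erf(x) - (2x/sqrt(pi)) * exp(-x^2),   x = r_c/(sigma*sqrt(2)).

The analogous 2D law for microscope x-y projections is the Rayleigh CDF
``1 - exp(-t^2 / (2 sigma^2))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "INTER",
    "PolymerModel",
    "pair_separation_sigma",
    "gaussian_contact_probability",
    "rayleigh_colocalization_probability",
]

#: Sentinel genomic separation for loci on different chromosomes.
INTER = "inter"


@dataclass(frozen=True)
class PolymerModel:
    """Parameters of the Gaussian-chain contact model.

    All lengths are in nanometres, genomic distances in base pairs.
    """

    reference_distance_bp: float = 40_000.0
    reference_rms_nm: float = 300.0
    scaling_exponent: float = 0.5
    tether_rms_nm: float = 100.0
    inter_rms_nm: float = 1400.0
    capture_radius_nm: float = 250.0

    def __post_init__(self) -> None:
        if self.reference_distance_bp <= 0:
            raise ValueError("reference_distance_bp must be positive")
        if self.reference_rms_nm <= 0:
            raise ValueError("reference_rms_nm must be positive")
        if not 0 < self.scaling_exponent <= 1:
            raise ValueError("scaling_exponent must be in (0, 1]")
        if not 0 < self.tether_rms_nm < self.inter_rms_nm:
            raise ValueError("require 0 < tether_rms_nm < inter_rms_nm")
        if self.capture_radius_nm <= 0:
            raise ValueError("capture_radius_nm must be positive")

    def rms_separation(self, genomic_separation_bp):
        """3D RMS separation R(s) of an intra-chromosomal pair, in nm."""
        s = np.asarray(genomic_separation_bp, dtype=float)
        if np.any(s <= 0):
            raise ValueError("genomic separation must be positive for intra pairs")
        return self.reference_rms_nm * (s / self.reference_distance_bp) ** self.scaling_exponent

    @property
    def tether_sigma_nm(self) -> float:
        """Per-axis sd of a looped pair's separation vector."""
        return self.tether_rms_nm / math.sqrt(3.0)

    @property
    def inter_sigma_nm(self) -> float:
        """Per-axis sd of an inter-chromosomal pair's separation vector."""
        return self.inter_rms_nm / math.sqrt(3.0)

    def loop_contact_probability(self) -> float:
        """Capture probability of a stably looped pair."""
        return float(gaussian_contact_probability(self.tether_sigma_nm, self.capture_radius_nm))

    def free_contact_probability(self, genomic_separation_bp):
        """Capture probability of an untethered pair (``INTER`` for inter-chromosomal)."""
        sigma = pair_separation_sigma(genomic_separation_bp, self)
        return gaussian_contact_probability(sigma, self.capture_radius_nm)


def pair_separation_sigma(genomic_separation, model: PolymerModel):
    """Per-axis standard deviation (nm) of a locus pair's 3D separation.

    ``genomic_separation`` is either a positive bp distance (intra pair) or the
    sentinel :data:`INTER` for a pair on different chromosomes.  For an intra
    pair sigma = R(s)/sqrt(3); for an inter pair sigma = inter_rms/sqrt(3).
    """
    if isinstance(genomic_separation, str):
        if genomic_separation != INTER:
            raise ValueError(f"unknown separation sentinel {genomic_separation!r}")
        return model.inter_sigma_nm
    return model.rms_separation(genomic_separation) / math.sqrt(3.0)


def gaussian_contact_probability(sigma, r_c):
    """P(||D|| <= r_c) for an isotropic 3D Gaussian D with per-axis sd sigma.

    This is the Maxwell-distribution CDF; it is 0 at r_c = 0, tends to 1 as
    r_c grows, and is monotone increasing in r_c.
    """
    sigma = np.asarray(sigma, dtype=float)
    r_c = np.asarray(r_c, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    if np.any(r_c < 0):
        raise ValueError("capture radius must be non-negative")
    x = r_c / (sigma * math.sqrt(2.0))
    p = special.erf(x) - (2.0 * x / math.sqrt(math.pi)) * np.exp(-(x**2))
    return np.clip(p, 0.0, 1.0)[()]


def rayleigh_colocalization_probability(sigma, threshold):
    """P(x-y projected distance < threshold) for per-axis sd sigma (2D Rayleigh CDF)."""
    sigma = np.asarray(sigma, dtype=float)
    threshold = np.asarray(threshold, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    if np.any(threshold < 0):
        raise ValueError("threshold must be non-negative")
    return (1.0 - np.exp(-(threshold**2) / (2.0 * sigma**2)))[()]
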