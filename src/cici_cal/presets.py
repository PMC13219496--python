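"""Default study conditions for the desk-scale demonstration genome.

These presets define the synthetic counterpart of the experimental design:
a yeast-scale genome binned at 10 kb, engineered intra-chromosomal pairs at
400 kb separation and one inter-chromosomal pair, induced loop fraction 0.65
against a 0.02 background, titration ratios {0, 0.25, 0.5, 0.75, 1}, 2000
imaged cells per condition, and ~18 M contacts per Hi-C library.

The 400 kb intra separation is chosen so that, under the default polymer
model plus 50 nm localization noise, untethered pairs co-localize (<0.4 um,
x-y) in ~23% of single frames and ~1% of cells over three consecutive
frames -- the uninduced background regime the imaging estimator is built to
reject.  The induced loop fraction 0.65 and the 0.02 stable background are
mid-range values of the continuously co-localized fractions the engineered
system produces with and without induction.
"""

from __future__ import annotations

from .loci import LocusPair
from .matrix import GenomeBins
from .polymer import PolymerModel

__all__ = [
    "demo_chromsizes",
    "demo_bins",
    "demo_pairs",
    "demo_model",
    "DEMO_P_PLUS",
    "DEMO_P_MINUS",
    "DEMO_RATIOS",
    "DEMO_N_CELLS",
    "DEMO_N_CONTACTS",
    "DEMO_BIN_SIZE",
    "DEMO_MEAN_SITES_PER_BIN",
    "DEMO_BIAS_SD",
]

DEMO_BIN_SIZE = 10_000
#: DpnII is a 4-cutter: ~1 site per 256 bp, ~39 sites per 10 kb bin.
DEMO_MEAN_SITES_PER_BIN = 39.0
DEMO_P_PLUS = 0.65
DEMO_P_MINUS = 0.02
DEMO_RATIOS = (0.0, 0.25, 0.5, 0.75, 1.0)
DEMO_N_CELLS = 2000
DEMO_N_CONTACTS = 18_000_000
DEMO_BIAS_SD = 0.2


def demo_chromsizes() -> dict[str, int]:
    """Four chromosomes, 3.3 Mb total: yeast-scale but desk-sized."""
    return {"chrI": 900_000, "chrII": 800_000, "chrIII": 700_000, "chrIV": 900_000}


def demo_bins(seed: int = 7, with_sites: bool = True) -> GenomeBins:
    bins = GenomeBins(demo_chromsizes(), DEMO_BIN_SIZE)
    if with_sites:
        bins = bins.with_poisson_sites(DEMO_MEAN_SITES_PER_BIN, seed)
    return bins


def demo_pairs() -> dict[str, LocusPair]:
    """Engineered pairs: two intra (400 kb separation) and one inter."""
    return {
        "pair1": LocusPair("pair1", "chrI", 200_000, "chrI", 600_000),
        "pair2": LocusPair("pair2", "chrII", 400_000, "chrIII", 350_000),
        "pair3": LocusPair("pair3", "chrIV", 200_000, "chrIV", 600_000),
    }


def demo_model() -> PolymerModel:
    return PolymerModel()
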