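"""Binned genome-wide contact matrices and their plain-text formats.

:class:`GenomeBins` tiles each chromosome with fixed-size bins (0-based,
half-open; the last bin of a chromosome may be short) and carries per-bin
restriction-site counts, the covariate used for fragment-density correction.

:class:`ContactMatrix` stores symmetric contact counts densely (yeast-scale
genomes stay small) together with a per-bin validity mask and optional
balancing weights.  On disk a matrix is a COO TSV of the upper triangle
(bin1_id, bin2_id, count) next to a bins TSV (chrom, start, end, sites).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GenomeBins", "ContactMatrix", "read_matrix", "write_matrix"]


@dataclass(frozen=True)
class GenomeBins:
    """Fixed-size binning of an ordered set of chromosomes."""

    chromsizes: dict[str, int]
    bin_size: int
    restriction_sites: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if not self.chromsizes:
            raise ValueError("empty genome")
        if self.restriction_sites is not None:
            sites = np.asarray(self.restriction_sites, dtype=float)
            if sites.shape != (self.n_bins,):
                raise ValueError("restriction_sites length must equal bin count")
            if np.any(sites < 0):
                raise ValueError("restriction_sites must be non-negative")
            object.__setattr__(self, "restriction_sites", sites)

    @property
    def chrom_n_bins(self) -> dict[str, int]:
        return {
            c: -(-length // self.bin_size) for c, length in self.chromsizes.items()
        }

    @property
    def n_bins(self) -> int:
        return sum(self.chrom_n_bins.values())

    @property
    def chrom_offsets(self) -> dict[str, int]:
        offsets, total = {}, 0
        for c, n in self.chrom_n_bins.items():
            offsets[c] = total
            total += n
        return offsets

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global bin id of a genomic position (0-based)."""
        if chrom not in self.chromsizes:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos < self.chromsizes[chrom]:
            raise ValueError(f"position {chrom}:{pos} outside chromosome")
        return self.chrom_offsets[chrom] + pos // self.bin_size

    def chrom_slice(self, chrom: str) -> slice:
        off = self.chrom_offsets[chrom]
        return slice(off, off + self.chrom_n_bins[chrom])

    def chrom_of_bins(self) -> np.ndarray:
        """Chromosome index (order of chromsizes) of every bin."""
        out = np.empty(self.n_bins, dtype=int)
        for k, chrom in enumerate(self.chromsizes):
            out[self.chrom_slice(chrom)] = k
        return out

    def table(self) -> pd.DataFrame:
        rows = []
        for chrom, length in self.chromsizes.items():
            for start in range(0, length, self.bin_size):
                rows.append((chrom, start, min(start + self.bin_size, length)))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        if self.restriction_sites is not None:
            df["sites"] = self.restriction_sites
        return df

    def with_poisson_sites(self, mean_sites_per_bin: float, seed: int) -> "GenomeBins":
        """Attach Poisson-distributed restriction-site counts (e.g. ~39/10 kb for a 4-cutter)."""
        rng = np.random.default_rng(seed)
        sites = rng.poisson(mean_sites_per_bin, size=self.n_bins).astype(float)
        # short terminal bins carry proportionally fewer sites
        frac = np.array(
            [
                (row.end - row.start) / self.bin_size
                for row in self.table().itertuples()
            ]
        )
        sites = np.round(sites * frac)
        return GenomeBins(self.chromsizes, self.bin_size, sites)


@dataclass
class ContactMatrix:
    """Symmetric binned contact counts with mask and optional balancing weights."""

    bins: GenomeBins
    counts: np.ndarray  # (n, n) symmetric, non-negative
    mask: np.ndarray = field(default=None)  # (n,) bool, True = valid bin
    weights: np.ndarray | None = None  # per-bin balancing weights

    def __post_init__(self) -> None:
        n = self.bins.n_bins
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (n, n):
            raise ValueError(f"counts must be ({n}, {n})")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(self.counts, self.counts.T, rtol=0, atol=1e-8):
            raise ValueError("counts must be symmetric")
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.bins.n_bins

    @property
    def total_contacts(self) -> float:
        """Sum of counts over unique bin pairs (upper triangle incl. diagonal)."""
        return float(np.triu(self.counts).sum())

    def copy_with(self, counts=None, mask=None, weights="keep") -> "ContactMatrix":
        return ContactMatrix(
            bins=self.bins,
            counts=self.counts.copy() if counts is None else counts,
            mask=self.mask.copy() if mask is None else mask,
            weights=(self.weights if weights == "keep" else weights),
        )

    def balanced(self) -> np.ndarray:
        """Counts scaled by the balancing weights (requires prior balancing)."""
        if self.weights is None:
            raise ValueError("matrix has no balancing weights; run kr_balance first")
        w = np.where(self.mask, self.weights, 0.0)
        return self.counts * np.outer(w, w)


def write_matrix(matrix: ContactMatrix, prefix) -> None:
    """Write ``<prefix>.coo.tsv`` (upper triangle, nonzero) and ``<prefix>.bins.tsv``."""
    prefix = Path(prefix)
    iu = np.triu_indices(matrix.n_bins)
    vals = matrix.counts[iu]
    nz = vals != 0
    pd.DataFrame(
        {"bin1_id": iu[0][nz], "bin2_id": iu[1][nz], "count": vals[nz]}
    ).to_csv(Path(str(prefix) + ".coo.tsv"), sep="\t", index=False)
    matrix.bins.table().to_csv(Path(str(prefix) + ".bins.tsv"), sep="\t", index=False)


def read_matrix(prefix) -> ContactMatrix:
    """Read a matrix written by :func:`write_matrix`."""
    prefix = Path(prefix)
    bins_df = pd.read_csv(Path(str(prefix) + ".bins.tsv"), sep="\t")
    chromsizes: dict[str, int] = {}
    for chrom, grp in bins_df.groupby("chrom", sort=False):
        chromsizes[chrom] = int(grp["end"].max())
    bin_size = int((bins_df["end"] - bins_df["start"]).max())
    sites = bins_df["sites"].to_numpy(float) if "sites" in bins_df else None
    bins = GenomeBins(chromsizes, bin_size, sites)
    coo = pd.read_csv(Path(str(prefix) + ".coo.tsv"), sep="\t")
    counts = np.zeros((bins.n_bins, bins.n_bins))
    i = coo["bin1_id"].to_numpy(int)
    j = coo["bin2_id"].to_numpy(int)
    counts[i, j] = coo["count"].to_numpy(float)
    counts[j, i] = counts[i, j]
    return ContactMatrix(bins=bins, counts=counts)
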