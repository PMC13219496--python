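"""Genome and locus-pair definitions plus their plain-text formats.

A genome is an ordered mapping of chromosome name -> length (bp), read from a
two-column ``chrom.sizes`` file.  Engineered array-insertion pairs are held as
:class:`LocusPair` records and serialized as a BEDPE-like TSV
(pair_id, chrom_a, pos_a, chrom_b, pos_b, 0-based coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .polymer import INTER

__all__ = ["LocusPair", "read_chrom_sizes", "write_chrom_sizes", "read_pairs", "write_pairs"]


@dataclass(frozen=True)
class LocusPair:
    """A pair of engineered loci, the ends of an inducible chromosomal loop."""

    pair_id: str
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int

    @property
    def is_intra(self) -> bool:
        return self.chrom_a == self.chrom_b

    @property
    def genomic_separation(self):
        """bp separation for an intra pair, :data:`INTER` otherwise."""
        if not self.is_intra:
            return INTER
        sep = abs(self.pos_b - self.pos_a)
        if sep == 0:
            raise ValueError(f"pair {self.pair_id}: loci coincide")
        return sep


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column chrom.sizes file into an ordered name->length dict."""
    sizes: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        name, length = line.split()[:2]
        sizes[name] = int(length)
    if not sizes:
        raise ValueError(f"{path}: no chromosomes found")
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    Path(path).write_text("".join(f"{c}\t{l}\n" for c, l in sizes.items()))


def read_pairs(path) -> list[LocusPair]:
    df = pd.read_csv(path, sep="\t", dtype={"pair_id": str})
    required = {"pair_id", "chrom_a", "pos_a", "chrom_b", "pos_b"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        LocusPair(r.pair_id, r.chrom_a, int(r.pos_a), r.chrom_b, int(r.pos_b))
        for r in df.itertuples()
    ]


def write_pairs(pairs: list[LocusPair], path) -> None:
    pd.DataFrame(
        [(p.pair_id, p.chrom_a, p.pos_a, p.chrom_b, p.pos_b) for p in pairs],
        columns=["pair_id", "chrom_a", "pos_a", "chrom_b", "pos_b"],
    ).to_csv(path, sep="\t", index=False)
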