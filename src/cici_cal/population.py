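"""Cell populations with a known fraction of stably looped cells.

A :class:`CellPopulation` is the simulation's ground truth: each cell either
carries a stable loop between the engineered loci (probability ``true_p``) or
is free, and its 3D locus-pair separation vector is drawn from the matching
Gaussian scale (tether scale when looped, chain/inter scale when free).
Mixing two populations at a ratio r emulates combining fixed +rapamycin and
-rapamycin cells, the titration that generates intermediate contact
frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .loci import LocusPair
from .polymer import PolymerModel, pair_separation_sigma

__all__ = ["CellPopulation", "MixtureDesign", "sample_population", "mix_populations"]


@dataclass(frozen=True)
class CellPopulation:
    """Per-cell loop state and 3D separations (nm) for one locus pair."""

    pair_id: str
    loop_state: np.ndarray  # (n_cells,) bool
    separation: np.ndarray  # (n_cells, 3) nm
    sigma_nm: np.ndarray  # (n_cells,) per-axis stationary sd of each cell
    true_p: float
    seed: int | None = None

    @property
    def n_cells(self) -> int:
        return int(self.loop_state.shape[0])

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("population must contain at least one cell")
        if not np.all(np.isfinite(self.separation)):
            raise ValueError("separations must be finite")
        if self.separation.shape != (self.n_cells, 3):
            raise ValueError("separation must be (n_cells, 3)")


@dataclass(frozen=True)
class MixtureDesign:
    """Titration ratios of +induction cells into a -induction background."""

    ratios: tuple[float, ...]
    p_plus: float
    p_minus: float

    def __post_init__(self) -> None:
        for r in self.ratios:
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"ratio {r} outside [0, 1]")
        for p in (self.p_plus, self.p_minus):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"fraction {p} outside [0, 1]")

    def expected_frequency(self, ratio: float) -> float:
        return ratio * self.p_plus + (1.0 - ratio) * self.p_minus


def sample_population(
    pair: LocusPair,
    p_loop: float,
    n_cells: int,
    model: PolymerModel,
    seed: int,
) -> CellPopulation:
    """Draw a population of cells, each independently looped with probability p_loop.

    Looped cells get isotropic Gaussian separations at the tether scale
    (per-axis sd ``tether_rms/sqrt(3)``); free cells at the chain scale for the
    pair's genomic separation (or the inter-chromosomal scale).
    """
    if not 0.0 <= p_loop <= 1.0:
        raise ValueError(f"p_loop {p_loop} outside [0, 1]")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    looped = rng.random(n_cells) < p_loop
    sigma_free = pair_separation_sigma(pair.genomic_separation, model)
    sigma = np.where(looped, model.tether_sigma_nm, sigma_free)
    separation = rng.normal(0.0, 1.0, size=(n_cells, 3)) * sigma[:, None]
    return CellPopulation(
        pair_id=pair.pair_id,
        loop_state=looped,
        separation=separation,
        sigma_nm=sigma,
        true_p=float(p_loop),
        seed=int(seed),
    )


def mix_populations(
    pop_plus: CellPopulation,
    pop_minus: CellPopulation,
    ratio: float,
    seed: int,
) -> CellPopulation:
    """Mix two populations of the same pair: each cell comes from ``pop_plus``
    with probability ``ratio``, else from ``pop_minus``.

    The output has ``n_cells = min(n_plus, n_minus)`` cells and ground truth
    ``true_p = r*p_plus + (1-r)*p_minus``.
    """
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"ratio {ratio} outside [0, 1]")
    if pop_plus.pair_id != pop_minus.pair_id:
        raise ValueError(
            f"cannot mix populations of different pairs "
            f"({pop_plus.pair_id!r} vs {pop_minus.pair_id!r})"
        )
    rng = np.random.default_rng(seed)
    n = min(pop_plus.n_cells, pop_minus.n_cells)
    take_plus = rng.random(n) < ratio
    loop_state = np.where(take_plus, pop_plus.loop_state[:n], pop_minus.loop_state[:n])
    separation = np.where(take_plus[:, None], pop_plus.separation[:n], pop_minus.separation[:n])
    sigma = np.where(take_plus, pop_plus.sigma_nm[:n], pop_minus.sigma_nm[:n])
    true_p = ratio * pop_plus.true_p + (1.0 - ratio) * pop_minus.true_p
    return CellPopulation(
        pair_id=pop_plus.pair_id,
        loop_state=loop_state,
        separation=separation,
        sigma_nm=sigma,
        true_p=float(true_p),
        seed=int(seed),
    )
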