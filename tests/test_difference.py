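"""3-SD difference-significance maps around engineered junctions."""

import numpy as np
import pytest

from cici_cal.hicops import difference_significance, normalize_to_smallest
from cici_cal.hicsim import JunctionSpec, simulate_hic


def test_identical_matrices_give_no_significance(bins, model, intra_pair):
    m = simulate_hic(bins, [JunctionSpec(intra_pair, 0.0)], model, 2_000_000, 0.2, seed=1)
    dm = difference_significance(m, m, intra_pair)
    assert dm.n_significant == 0


def test_unequal_totals_rejected(bins, model, intra_pair):
    a = simulate_hic(bins, [JunctionSpec(intra_pair, 0.0)], model, 2_000_000, 0.2, seed=2)
    b = simulate_hic(bins, [JunctionSpec(intra_pair, 0.0)], model, 1_000_000, 0.2, seed=3)
    with pytest.raises(ValueError):
        difference_significance(a, b, intra_pair)


def test_injected_square_recovered_exactly(bins, intra_pair):
    # deterministic distance-decay surface + a strong uniform boost on a
    # 30 kb square: the significant footprint must be exactly that square
    n = bins.n_bins
    idx = np.arange(n)
    same = bins.chrom_of_bins()[:, None] == bins.chrom_of_bins()[None, :]
    base_counts = np.where(same, 100.0 / (1.0 + np.abs(idx[:, None] - idx[None, :])), 0.5)
    from cici_cal.matrix import ContactMatrix

    base = ContactMatrix(bins=bins, counts=base_counts)
    ia = bins.bin_index(intra_pair.chrom_a, intra_pair.pos_a)
    ib = bins.bin_index(intra_pair.chrom_b, intra_pair.pos_b)
    boosted = base.counts.copy()
    boosted[ia - 1 : ia + 2, ib - 1 : ib + 2] += 50.0
    boosted[ib - 1 : ib + 2, ia - 1 : ia + 2] += 50.0
    plus = base.copy_with(counts=boosted)
    # park the same boost mass on a far-away inter-chromosomal cell so both
    # libraries carry identical totals and the background difference is zero
    off_counts = base.counts.copy()
    x, y = bins.bin_index("chrII", 100_000), bins.bin_index("chrIV", 300_000)
    off_counts[x, y] += 9 * 50.0
    off_counts[y, x] += 9 * 50.0
    minus = base.copy_with(counts=off_counts)
    dm = difference_significance(plus, minus, intra_pair)
    sig_cells = {
        (int(dm.rows[a]), int(dm.cols[b]))
        for a, b in zip(*np.where(dm.significant))
    }
    expected = {(i, j) for i in range(ia - 1, ia + 2) for j in range(ib - 1, ib + 2)}
    assert sig_cells == expected
    assert dm.footprint_bp == {
        "axis_a_upstream_bp": 10_000,
        "axis_a_downstream_bp": 10_000,
        "axis_b_upstream_bp": 10_000,
        "axis_b_downstream_bp": 10_000,
    }


def test_null_significance_rate_is_small(bins, model, intra_pair):
    # two replicate libraries of the same family (shared bias vector) from
    # the same population: the one-sided 3-SD rule should flag at most
    # ~0.5% of local bin pairs
    rng = np.random.default_rng(50)
    n_sig = n_tot = 0
    for seed in ((5, 6), (7, 8)):
        bias = np.exp(rng.normal(0.0, 0.2, size=bins.n_bins))
        a = simulate_hic(
            bins, [JunctionSpec(intra_pair, 0.0)], model, 18_000_000, seed=seed[0], bias=bias
        )
        b = simulate_hic(
            bins, [JunctionSpec(intra_pair, 0.0)], model, 18_000_000, seed=seed[1], bias=bias
        )
        na, nb = normalize_to_smallest([a, b])
        dm = difference_significance(na, nb, intra_pair)
        n_sig += dm.n_significant
        n_tot += dm.significant.size
    assert n_sig / n_tot <= 0.005


def test_induced_junction_detected_on_intra_and_inter(bins, model, pairs):
    for pair in (pairs["pair1"], pairs["pair2"]):
        plus = simulate_hic(bins, [JunctionSpec(pair, 0.65)], model, 18_000_000, 0.2, seed=9)
        minus = simulate_hic(bins, [JunctionSpec(pair, 0.0)], model, 18_000_000, 0.2, seed=10)
        np_, nm = normalize_to_smallest([plus, minus])
        dm = difference_significance(np_, nm, pair)
        # the boosted 3x3 square sits at the center of the footprint
        assert dm.n_significant >= 9
        assert dm.footprint_bp["axis_a_upstream_bp"] >= 10_000
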