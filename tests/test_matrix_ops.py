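"""Contact-matrix building, normalization, correction, merging, fold-change, IO."""

import numpy as np
import pytest

from cici_cal.hicops import (
    bin_contact_pairs,
    log2_fold_change,
    merge_replicates,
    normalize_to_smallest,
    restriction_site_correction,
)
from cici_cal.matrix import ContactMatrix, GenomeBins, read_matrix, write_matrix


@pytest.fixture()
def small_bins():
    return GenomeBins({"chrI": 100_000, "chrII": 60_000}, 10_000)


def _random_matrix(bins, seed=0, scale=50):
    rng = np.random.default_rng(seed)
    n = bins.n_bins
    counts = rng.poisson(scale, size=(n, n)).astype(float)
    counts = np.triu(counts) + np.triu(counts, 1).T
    return ContactMatrix(bins=bins, counts=counts)


class TestBinContactPairs:
    def test_single_pair_lands_in_expected_cell(self, small_bins):
        m = bin_contact_pairs([("chrI", 5_000, "chrI", 25_000)], small_bins)
        assert m.counts[0, 2] == 1 and m.counts[2, 0] == 1
        assert m.total_contacts == 1

    def test_reversed_pair_is_symmetric(self, small_bins):
        a = bin_contact_pairs([("chrI", 5_000, "chrII", 15_000)], small_bins)
        b = bin_contact_pairs([("chrII", 15_000, "chrI", 5_000)], small_bins)
        assert np.array_equal(a.counts, b.counts)

    def test_total_conservation_and_rejects(self, small_bins):
        rng = np.random.default_rng(3)
        good = [
            ("chrI", int(rng.integers(0, 100_000)), "chrII", int(rng.integers(0, 60_000)))
            for _ in range(10_000)
        ]
        bad = [("chrI", 200_000, "chrI", 10), ("chrX", 5, "chrI", 5)]
        m = bin_contact_pairs(good + bad, small_bins)
        assert m.total_contacts == 10_000  # out-of-range pairs rejected, not binned


class TestNormalizeToSmallest:
    def test_single_matrix_unchanged(self, small_bins):
        m = _random_matrix(small_bins)
        (out,) = normalize_to_smallest([m])
        assert np.allclose(out.counts, m.counts)

    def test_totals_equalized_and_ratios_preserved(self, small_bins):
        a = _random_matrix(small_bins, seed=1, scale=20)
        b = _random_matrix(small_bins, seed=2, scale=40)
        na, nb = normalize_to_smallest([a, b])
        assert na.total_contacts == pytest.approx(nb.total_contacts)
        assert na.total_contacts == pytest.approx(min(a.total_contacts, b.total_contacts))
        nz = b.counts > 0
        ratio = nb.counts[nz] / b.counts[nz]
        assert np.allclose(ratio, ratio.flat[0])

    def test_downsampling_reaches_target_exactly(self, small_bins):
        a = _random_matrix(small_bins, seed=3, scale=20)
        b = _random_matrix(small_bins, seed=4, scale=40)
        na, nb = normalize_to_smallest([a, b], mode="downsample", seed=5)
        assert nb.total_contacts == a.total_contacts
        assert np.all(nb.counts <= b.counts + 1e-9)

    def test_zero_total_rejected(self, small_bins):
        z = ContactMatrix(bins=small_bins, counts=np.zeros((16, 16)))
        with pytest.raises(ValueError):
            normalize_to_smallest([z])


class TestRestrictionSiteCorrection:
    def test_uniform_sites_are_noop(self, small_bins):
        bins = GenomeBins(small_bins.chromsizes, 10_000, np.full(16, 40.0))
        m = _random_matrix(bins, seed=6)
        out = restriction_site_correction(m)
        assert np.allclose(out.counts, m.counts)

    def test_double_site_bin_halved_before_rescale(self):
        bins = GenomeBins({"chrI": 30_000}, 10_000, np.array([40.0, 80.0, 40.0]))
        counts = np.full((3, 3), 8.0)
        m = ContactMatrix(bins=bins, counts=counts)
        out = restriction_site_correction(m)
        # row 1 is divided by 2 relative to rows 0/2 (up to global rescale)
        assert out.counts[0, 1] / out.counts[0, 0] == pytest.approx(0.5)
        assert out.counts[1, 1] / out.counts[0, 0] == pytest.approx(0.25)
        assert out.total_contacts == pytest.approx(m.total_contacts)

    def test_zero_site_bins_masked(self):
        bins = GenomeBins({"chrI": 30_000}, 10_000, np.array([40.0, 0.0, 40.0]))
        m = ContactMatrix(bins=bins, counts=np.full((3, 3), 4.0))
        out = restriction_site_correction(m)
        assert not out.mask[1]
        assert np.all(out.counts[1, :] == 0)

    def test_site_bias_removed_from_junction_signal(self, bins, model, intra_pair):
        # simulate with site-driven bias only; correction must recover the
        # bias-free junction expectation
        from cici_cal.hicops import junction_signal
        from cici_cal.hicsim import JunctionSpec, simulate_hic

        flat_bins = GenomeBins(bins.chromsizes, bins.bin_size)
        spec = [JunctionSpec(intra_pair, 0.5)]
        biased = simulate_hic(bins, spec, model, 2_000_000, bias_sd=0.0, seed=7)
        flat = simulate_hic(flat_bins, spec, model, 2_000_000, bias_sd=0.0, seed=8)
        corrected = restriction_site_correction(biased)
        s_corr = junction_signal(corrected, intra_pair)
        s_flat = junction_signal(flat, intra_pair)
        assert s_corr == pytest.approx(s_flat, rel=0.1)


class TestMergeAndFoldChange:
    def test_merge_identity_and_additivity(self, small_bins):
        a = _random_matrix(small_bins, seed=9)
        b = _random_matrix(small_bins, seed=10)
        assert np.array_equal(merge_replicates([a]).counts, a.counts)
        ab = merge_replicates([a, b])
        ba = merge_replicates([b, a])
        assert np.array_equal(ab.counts, ba.counts)
        assert ab.total_contacts == pytest.approx(a.total_contacts + b.total_contacts)

    def test_merge_rejects_bin_mismatch(self, small_bins):
        other = GenomeBins({"chrI": 100_000}, 10_000)
        with pytest.raises(ValueError):
            merge_replicates([_random_matrix(small_bins), _random_matrix(other)])

    def test_lfc_zero_doubling_antisymmetry(self, small_bins):
        a = _random_matrix(small_bins, seed=11)
        double = a.copy_with(counts=2 * a.counts)
        assert np.allclose(log2_fold_change(a, a), 0.0)
        lfc = log2_fold_change(double, a, pseudocount=1e-9)
        assert np.allclose(lfc, 1.0, atol=1e-6)
        assert np.allclose(
            log2_fold_change(a, double, 1e-9), -log2_fold_change(double, a, 1e-9)
        )
        with pytest.raises(ValueError):
            log2_fold_change(a, a, pseudocount=-1.0)


def test_coo_tsv_roundtrip(tmp_path, small_bins):
    bins = small_bins.with_poisson_sites(40.0, seed=12)
    m = _random_matrix(bins, seed=13)
    write_matrix(m, tmp_path / "mat")
    back = read_matrix(tmp_path / "mat")
    assert np.allclose(back.counts, m.counts)
    assert back.bins.chromsizes == m.bins.chromsizes
    assert np.allclose(back.bins.restriction_sites, m.bins.restriction_sites)


def test_genome_bins_indexing(small_bins):
    assert small_bins.n_bins == 16
    assert small_bins.bin_index("chrI", 0) == 0
    assert small_bins.bin_index("chrII", 0) == 10
    assert small_bins.bin_index("chrII", 59_999) == 15
    with pytest.raises(ValueError):
        small_bins.bin_index("chrII", 60_000)
    with pytest.raises(ValueError):
        small_bins.bin_index("chrX", 0)
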