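"""Index construction: centering/splitting, quantization, build, persistence."""

import numpy as np
import pytest
from scipy.special import ndtri

from conftest import matrix_from, naive_tripartition
from spliceindex.ef_index import (
    build_index,
    center_and_split,
    dequantize,
    ef_decode,
    load_index,
    quantize_values,
    save_index,
)
from spliceindex.synthetic import random_psi_matrix


class TestCenterAndSplit:
    def test_three_pool_worked_example(self):
        # PSI [0.1, 0.5, 0.9], tau 0.2: mean 0.5, one pool on each side at 40
        m = matrix_from([[0.1], [0.5], [0.9]])
        kept, stats, apos, aval, bpos, bval, mpos = center_and_split(m, tau=0.2)
        assert kept == [0]
        assert stats[0].mean_psi == pytest.approx(0.5)
        assert apos[0].tolist() == [2] and aval[0] == pytest.approx([40.0])
        assert bpos[0].tolist() == [0] and bval[0] == pytest.approx([40.0])
        assert mpos[0].tolist() == [1]

    def test_within_tau_all_masked(self):
        m = matrix_from([[0.5], [0.6]])
        _, _, apos, _, bpos, _, mpos = center_and_split(m, tau=0.2)
        assert apos[0].size == 0 and bpos[0].size == 0
        assert mpos[0].tolist() == [0, 1]

    def test_tie_at_threshold_goes_to_mask(self):
        m = matrix_from([[0.3], [0.7]])  # |dPSI| exactly 0.2
        _, _, apos, _, bpos, _, mpos = center_and_split(m, tau=0.2)
        assert apos[0].size == 0 and bpos[0].size == 0 and mpos[0].size == 2

    def test_matches_naive_dense_scan(self):
        m = random_psi_matrix(50, 200, rng=np.random.default_rng(7))
        kept, stats, apos, aval, bpos, bval, mpos = center_and_split(m, tau=0.2)
        oracle = naive_tripartition(m, tau=0.2)
        assert len(kept) == len(oracle)
        for i, j in enumerate(kept):
            a, b, mask = oracle[m.nodes[j].label]
            assert set(apos[i].tolist()) == a
            assert set(bpos[i].tolist()) == b
            assert set(mpos[i].tolist()) == mask

    def test_tripartition_and_tau_monotonicity(self):
        m = random_psi_matrix(40, 100, rng=np.random.default_rng(8))
        quantified = [set(np.flatnonzero(~np.isnan(m.values[:, j])).tolist()) for j in range(100)]
        prev_sizes = None
        for tau in (0.1, 0.2, 0.3, 0.5, 0.9):
            kept, _, apos, _, bpos, _, mpos = center_and_split(m, tau=tau)
            sizes = []
            for i, j in enumerate(kept):
                a, b, mk = set(apos[i].tolist()), set(bpos[i].tolist()), set(mpos[i].tolist())
                assert a | b | mk == quantified[j]
                assert not (a & b) and not (a & mk) and not (b & mk)
                sizes.append(len(a) + len(b))
            if prev_sizes is not None:
                assert all(s <= p for s, p in zip(sizes, prev_sizes))
            prev_sizes = sizes

    def test_invalid_tau_rejected(self):
        m = matrix_from([[0.5]])
        for tau in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                center_and_split(m, tau=tau)


class TestQuantizer:
    def test_constant_values_dequantize_exactly(self):
        idx, mu, sigma, reps = quantize_values([30.0, 30.0, 30.0], bits=2)
        assert sigma == 0.0
        assert np.all(dequantize(idx, reps) == 30.0)

    def test_bin_assignment_matches_lognormal_cutpoint_oracle(self):
        values = np.array([21, 22, 59, 61, 79, 81, 95, 97], dtype=float)
        idx, mu, sigma, reps = quantize_values(values, bits=2)
        # independent oracle: cut points from ln-moments, bins by counting
        logs = np.log(values)
        cuts = np.exp(logs.mean() + logs.std() * ndtri([0.25, 0.5, 0.75]))
        expected = np.array([np.sum(cuts <= v) for v in values])
        assert idx.tolist() == expected.tolist()
        assert np.all(np.diff(idx[np.argsort(values)]) >= 0)  # order preserved
        assert np.all(np.diff(reps) >= 0)  # representatives non-decreasing

    def test_error_bounded_by_bin_range_and_shrinks_with_bits(self):
        rng = np.random.default_rng(11)
        values = rng.lognormal(3.0, 0.6, size=1000)
        errors = {}
        for bits in (2, 8):
            idx, _, _, reps = quantize_values(values, bits=bits)
            dq = dequantize(idx, reps)
            for k in np.unique(idx):
                sel = idx == k
                bin_range = values[sel].max() - values[sel].min()
                assert np.abs(dq[sel] - values[sel]).max() <= bin_range + 1e-12
            errors[bits] = np.abs(dq - values)
        assert errors[8].max() <= errors[2].max()
        assert np.median(errors[8]) < np.median(errors[2])

    def test_bits_out_of_range_rejected(self):
        for bits in (0, 9):
            with pytest.raises(ValueError):
                quantize_values([1.0], bits=bits)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            quantize_values([0.0, 1.0])


class TestBuildIndex:
    def test_toy_encoded_entry_counts(self, toy_matrix, toy_index):
        # node 1: one above + one below; node 2: none; node 3 (mean .55): one of each
        by_label = {n.label: j for j, n in enumerate(toy_index.nodes)}
        j1, j2, j3 = by_label["G1_1"], by_label["G1_2"], by_label["G1_3"]
        assert toy_index.above[j1].ef.m == 1 and toy_index.below[j1].ef.m == 1
        assert toy_index.above[j2].ef.m == 0 and toy_index.below[j2].ef.m == 0
        assert toy_index.above[j3].ef.m + toy_index.below[j3].ef.m == 2
        assert toy_index.encoded_node_count() == 2

    def test_nodes_without_deviation_keep_stats_and_mask(self, toy_index):
        j = toy_index.node_index("G1_2")
        assert toy_index.stats[j].n_quantified == 3
        assert toy_index.mask_positions(j).tolist() == [0, 1, 2]

    def test_extreme_tau_empties_all_sides(self, toy_matrix):
        index = build_index(toy_matrix, tau=0.99)
        assert index.encoded_node_count() == 0

    def test_build_is_deterministic(self, random_matrix):
        a = build_index(random_matrix)
        b = build_index(random_matrix)
        for j in range(a.n_nodes):
            assert a.above[j].ef == b.above[j].ef
            assert a.below[j].ef == b.below[j].ef
            assert np.array_equal(a.above[j].value_bins, b.above[j].value_bins)
            assert np.array_equal(a.above[j].bin_reps, b.above[j].bin_reps)


class TestPersistence:
    def test_round_trip_is_field_exact(self, random_index, tmp_path):
        path = tmp_path / "index.saf"
        save_index(random_index, path)
        back = load_index(path)
        assert back.tau == random_index.tau
        assert back.bits == random_index.bits
        assert back.min_reads == random_index.min_reads
        assert back.pool_ids == random_index.pool_ids
        assert back.cell_types == random_index.cell_types
        assert [n.label for n in back.nodes] == [n.label for n in random_index.nodes]
        for j in range(random_index.n_nodes):
            assert back.stats[j] == random_index.stats[j]
            for side in ("above", "below"):
                s0 = getattr(random_index, side)[j]
                s1 = getattr(back, side)[j]
                assert s1.ef == s0.ef
                assert np.array_equal(s1.value_bins, s0.value_bins)
                assert s1.log_mu == s0.log_mu and s1.log_sigma == s0.log_sigma
                assert np.array_equal(s1.bin_reps, s0.bin_reps)
            assert random_index.mask[j] == back.mask[j]
            assert np.array_equal(
                ef_decode(back.mask[j]), random_index.mask_positions(j)
            )

    def test_version_mismatch_raises(self, toy_index, tmp_path):
        import h5py

        path = tmp_path / "index.saf"
        save_index(toy_index, path)
        with h5py.File(path, "a") as f:
            f.attrs["format_version"] = "other-9"
        with pytest.raises(ValueError, match="other-9"):
            load_index(path)

    def test_truncated_container_raises(self, toy_index, tmp_path):
        path = tmp_path / "index.saf"
        save_index(toy_index, path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 3])
        with pytest.raises(Exception):
            load_index(path)

    def test_index_file_smaller_than_dense_tsv(self, tmp_path):
        """Qualitative compression check on a 90%-sparse 200 x 5000 matrix."""
        matrix = random_psi_matrix(200, 5000, na_rate=0.9, rng=np.random.default_rng(77))
        tsv = tmp_path / "dense.tsv"
        import pandas as pd

        pd.DataFrame(
            matrix.values, index=matrix.pool_ids, columns=matrix.node_labels
        ).to_csv(tsv, sep="\t", float_format="%.6f")
        index_path = tmp_path / "index.saf"
        save_index(build_index(matrix), index_path)
        assert index_path.stat().st_size < tsv.stat().st_size
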