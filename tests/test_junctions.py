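import numpy as np
import pytest

from eccmirkit.io_formats import EccRecord, GenomeSequence
from eccmirkit.junctions import (
    JunctionStats,
    bin_mh_lengths,
    extract_flanks,
    junction_pfm,
    measure_many,
    measure_microhomology,
    mh_size_correlation,
)

TOY = GenomeSequence({"chr1": "AAAAACCCCCTGCGGGGGGGTGCTTTTTTT"})


def circle(chrom="chr1", start=10, end=20, sample="s1"):
    return EccRecord(f"{chrom}:{start}-{end}", sample, chrom, start, end)


class TestFlanks:
    def test_hand_indexed_windows(self):
        s = extract_flanks(circle(), TOY, k=3)
        assert s.flank_5p_up == "CCC"
        assert s.flank_5p_down == "TGC"
        assert s.flank_3p_up == "GGG"
        assert s.flank_3p_down == "TGC"
        assert not s.truncated

    def test_chromosome_start_truncates(self):
        s = extract_flanks(circle(start=0, end=10), TOY, k=5)
        assert s.flank_5p_up == ""
        assert s.truncated

    def test_flank_lengths_bounded_by_k(self):
        s = extract_flanks(circle(start=28, end=30), TOY, k=6)
        assert all(
            len(f) <= 6
            for f in (s.flank_5p_up, s.flank_5p_down, s.flank_3p_up, s.flank_3p_down)
        )

    def test_unknown_chromosome_is_error(self):
        with pytest.raises(KeyError):
            extract_flanks(circle(chrom="chrX"), TOY)


class TestMicrohomology:
    def test_hand_example_right_flush_three(self):
        s = measure_microhomology(circle(), TOY)
        assert (s.mh_right, s.mh_left, s.mh_total) == (3, 0, 3)

    def test_no_shared_bases_gives_zero(self):
        g = GenomeSequence({"chr1": "ACACACACACGTGTGTGTGTCACACACACA"})
        s = measure_microhomology(circle(), g)
        assert s.mh_total == 0

    def test_n_in_flank_nulls_mh(self):
        g = GenomeSequence({"chr1": "AAAAACCCCCTGNGGGGGGGTGCTTTTTTT"})
        s = measure_microhomology(circle(), g)
        assert s.has_n and s.mh_total is None

    def test_matches_brute_force_substring_scan(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=4000))
        genome = GenomeSequence({"chr1": seq})
        for _ in range(1000):
            start = int(rng.integers(25, 1900))
            end = start + int(rng.integers(60, 2000))
            rec = circle(start=start, end=end)
            s = measure_microhomology(rec, genome)
            bf_right = max(
                m for m in range(0, 21) if seq[start : start + m] == seq[end : end + m]
            )
            bf_left = max(
                m for m in range(0, 21)
                if seq[start - m : start] == seq[end - m : end]
            )
            assert (s.mh_right, s.mh_left) == (bf_right, bf_left)

    def test_planted_mh_recovered_exactly(self, small_dataset):
        truth = small_dataset.truth.frame.set_index("ecc_id")
        stats = measure_many(small_dataset.records, small_dataset.genome)
        assert len(stats) == len(truth)
        for s in stats:
            assert s.mh_right == truth.loc[s.ecc_id, "planted_mh"]

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        comp = str.maketrans("ACGT", "TGCA")
        rc = seq.translate(comp)[::-1]
        g_fwd = GenomeSequence({"chr1": seq})
        g_rev = GenomeSequence({"chr1": rc})
        L = len(seq)
        for _ in range(200):
            start = int(rng.integers(25, 900))
            end = start + int(rng.integers(60, 1000))
            fwd = measure_microhomology(circle(start=start, end=end), g_fwd)
            rev = measure_microhomology(circle(start=L - end, end=L - start), g_rev)
            assert fwd.mh_total == rev.mh_total
            assert (fwd.mh_right, fwd.mh_left) == (rev.mh_left, rev.mh_right)


def _stats_with_flanks(up, down, ecc_id="e", mh=None):
    s = JunctionStats(
        ecc_id=ecc_id,
        flank_5p_up=up,
        flank_5p_down=down,
        flank_3p_up=up,
        flank_3p_down=down,
        truncated=False,
    )
    if mh is not None:
        s.mh_left, s.mh_right = 0, mh
    return s


class TestPfm:
    def test_degenerate_all_g(self):
        stats = [_stats_with_flanks("G" * 20, "G" * 20, f"e{i}") for i in range(3)]
        pfm = junction_pfm(stats, side="start")
        assert (pfm.freqs["G"] == 1.0).all()
        assert pfm.gc_fraction == pytest.approx(1.0)

    def test_two_record_hand_count(self):
        stats = [
            _stats_with_flanks("A" * 20, "A" + "C" * 19, "e1"),
            _stats_with_flanks("A" * 20, "G" + "C" * 19, "e2"),
        ]
        pfm = junction_pfm(stats, side="start")
        row = pfm.freqs.loc[1]
        assert row["A"] == pytest.approx(0.5)
        assert row["G"] == pytest.approx(0.5)

    def test_rows_are_column_stochastic(self, small_dataset):
        stats = measure_many(small_dataset.records, small_dataset.genome)
        pfm = junction_pfm(stats, side="end")
        assert np.allclose(pfm.freqs.sum(axis=1), 1.0, rtol=1e-9)

    def test_window_gc_tracks_genome_gc(self):
        from eccmirkit.simulate import SimConfig, simulate_sample_set

        cfg = SimConfig(seed=3, n_circles=300, n_mir_circles=0, gc_fraction=0.7,
                        pathway_weights=(0.0, 1.0, 0.0),
                        chrom_lengths=(600_000, 600_000))
        ds = simulate_sample_set(cfg)
        stats = measure_many(ds.records, ds.genome)
        pfm = junction_pfm(stats, side="start")
        assert pfm.gc_fraction == pytest.approx(0.7, abs=0.05)

    def test_all_unusable_is_error(self):
        s = _stats_with_flanks("G" * 20, "G" * 20)
        s.truncated = True
        with pytest.raises(ValueError):
            junction_pfm([s], side="start")


class TestBinning:
    def test_hand_binned_counts(self):
        stats = [_stats_with_flanks("A" * 20, "A" * 20, f"e{i}", mh=v)
                 for i, v in enumerate([0, 3, 7, 15])]
        binning = bin_mh_lengths({"g": stats})
        assert binning.counts.loc["g"].tolist() == [1, 1, 1, 1]
        assert binning.proportions.loc["g"].sum() == pytest.approx(1.0)

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            bin_mh_lengths({"g": []})

    def test_overflow_values_keep_proportions_normalised(self):
        stats = [_stats_with_flanks("A" * 20, "A" * 20, "e0", mh=20)]
        stats[0].mh_left = 15  # mh_total = 35, beyond the last default bin
        binning = bin_mh_lengths({"g": stats})
        assert binning.proportions.loc["g"].sum() == pytest.approx(1.0)


class TestCorrelation:
    def _pairs_to_inputs(self, pairs):
        stats, records = [], []
        for i, (mh, length) in enumerate(pairs):
            rec = EccRecord(f"e{i}", "s", "chr1", 1000 * i, 1000 * i + length)
            records.append(rec)
            stats.append(_stats_with_flanks("A" * 20, "A" * 20, f"e{i}", mh=mh))
        return stats, records

    def test_perfect_monotone(self):
        stats, records = self._pairs_to_inputs([(1, 100), (2, 1000), (3, 10000)])
        res = mh_size_correlation(stats, records)
        assert res.rho == pytest.approx(1.0)
        assert res.method == "exact"

    def test_reversed_monotone(self):
        stats, records = self._pairs_to_inputs([(3, 100), (2, 1000), (1, 10000)])
        assert mh_size_correlation(stats, records).rho == pytest.approx(-1.0)

    def test_zero_variance_signalled(self):
        stats, records = self._pairs_to_inputs([(2, 100), (2, 1000), (2, 10000)])
        with pytest.raises(ValueError, match="variance"):
            mh_size_correlation(stats, records)

    def test_exact_p_matches_scipy_on_tie_free_case(self):
        from scipy import stats as sps

        pairs = [(1, 400), (4, 150), (2, 900), (6, 700), (3, 300), (5, 1200), (7, 250)]
        stats, records = self._pairs_to_inputs(pairs)
        res = mh_size_correlation(stats, records)
        ref = sps.spearmanr([p[0] for p in pairs], [np.log10(p[1]) for p in pairs])
        assert res.rho == pytest.approx(float(ref.statistic))

    def test_planted_dependence_detected_and_permutation_oracle_agrees(self):
        from eccmirkit.simulate import SimConfig, simulate_sample_set

        cfg = SimConfig(seed=9, n_circles=500, n_mir_circles=0, mh_size_coupling=True,
                        chrom_lengths=(900_000, 900_000))
        ds = simulate_sample_set(cfg)
        stats = measure_many(ds.records, ds.genome)
        res = mh_size_correlation(stats, ds.records)
        assert res.rho > 0 and res.pvalue < 0.05
        # permutation oracle on the same pairs
        from scipy.stats import rankdata

        lengths = {r.ecc_id: r.length for r in ds.records}
        mh = np.array([s.mh_total for s in stats], dtype=float)
        size = np.array([np.log10(lengths[s.ecc_id]) for s in stats])
        xr, yr = rankdata(mh), rankdata(size)
        xc, yc = xr - xr.mean(), yr - yr.mean()
        denom = np.sqrt((xc**2).sum() * (yc**2).sum())
        obs = (xc * yc).sum() / denom
        rng = np.random.default_rng(0)
        perm = np.array([
            (xc[rng.permutation(len(xc))] * yc).sum() / denom for _ in range(10_000)
        ])
        p_perm = (np.abs(perm) >= abs(obs)).mean()
        assert p_perm < 0.05
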