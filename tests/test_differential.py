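import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eccmirkit.differential import (
    DiffThresholds,
    benjamini_hochberg,
    differential_abundance,
    find_eccmirs,
    wilcoxon_rank_sum,
)
from eccmirkit.differential import test_eccmir_upregulation as flag_eccmir_upregulation
from eccmirkit.io_formats import EccRecord, PreMiR, SampleSheet
from eccmirkit.quantify import AbundanceMatrix, compute_tpm


def exact_rank_sum_p(x, y):
    """Independent oracle: two-sided exact Mann-Whitney p by enumerating
    every assignment of the pooled values to the two groups."""
    pooled = list(x) + list(y)
    nx = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj) + 0.5 * sum(
        1 for xi in x for yj in y if xi == yj
    )
    n_xy = nx * (len(pooled) - nx)
    u_hi = max(u_obs, n_xy - u_obs)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = sum(1 for xi in xs for yj in ys if xi > yj) + 0.5 * sum(
            1 for xi in xs for yj in ys if xi == yj
        )
        total += 1
        if u >= u_hi or u <= n_xy - u_hi:
            count += 1
    return count / total


class TestWilcoxon:
    def test_extreme_separation_three_vs_three(self):
        u, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_identical_multisets_degenerate(self):
        _, p = wilcoxon_rank_sum([5, 5, 5], [5, 5, 5])
        assert p == 1.0

    def test_exact_matches_enumeration_all_3v3_and_5v5_splits(self):
        for n in (3, 5):
            values = list(range(1, 2 * n + 1))
            for combo in itertools.combinations(values, n):
                x = list(combo)
                y = [v for v in values if v not in combo]
                _, p = wilcoxon_rank_sum(x, y)
                assert p == pytest.approx(exact_rank_sum_p(x, y), abs=1e-12)

    def test_exact_and_asymptotic_agree_within_002(self):
        from scipy.stats import mannwhitneyu

        values = list(range(1, 11))
        for combo in itertools.combinations(values, 5):
            x = list(combo)
            y = [v for v in values if v not in combo]
            p_exact = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            p_asym = mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
            assert abs(p_exact - min(p_asym, 1.0)) <= 0.02

    def test_null_rejection_rate_calibrated(self):
        # 10,000 5v5 null draws; exact p computed from the enumerated null
        # distribution of U, spot-checked against wilcoxon_rank_sum
        rng = np.random.default_rng(0)
        n = 5
        null_u = []
        values = list(range(2 * n))
        for combo in itertools.combinations(range(2 * n), n):
            xs = set(combo)
            u = sum(1 for i in combo for j in values if j not in xs and i > j)
            null_u.append(u)
        null_u = np.array(null_u)
        n_xy = n * n
        rejections = 0
        reps = 10_000
        for i in range(reps):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            u = sum(1 for xi in x for yj in y if xi > yj)
            u_hi = max(u, n_xy - u)
            p = ((null_u >= u_hi) | (null_u <= n_xy - u_hi)).mean()
            if i < 50:
                _, p_impl = wilcoxon_rank_sum(list(x), list(y))
                assert p_impl == pytest.approx(p, abs=1e-12)
            if p < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07


class TestBH:
    def test_hand_computed_step_up(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.3])[0] == pytest.approx(0.3)

    def test_all_ones_stay_ones(self):
        assert (benjamini_hochberg([1.0, 1.0, 1.0]) == 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(deadline=None)
    def test_stepup_properties(self, pvals):
        q = benjamini_hochberg(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-12)
        assert np.all((q >= 0) & (q <= 1))
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)  # monotone along sorted p

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=15),
           st.randoms(use_true_random=False))
    @settings(deadline=None)
    def test_permutation_invariance(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        q = benjamini_hochberg(pvals)
        q_perm = benjamini_hochberg([pvals[i] for i in perm])
        assert np.allclose([q[i] for i in perm], q_perm)


def matrix_from_tpm(tpm: pd.DataFrame) -> AbundanceMatrix:
    lengths = pd.Series(1000, index=tpm.index)
    return AbundanceMatrix(
        total_count=(tpm > 0).astype(int),
        rpk=tpm.copy(),
        tpm=tpm,
        log_tpm=np.log10(tpm + 1),
        lengths=lengths,
    )


class TestDifferentialAbundance:
    def test_hand_log2fc_with_pseudocount(self):
        tpm = pd.DataFrame(
            {"t1": [800.0], "t2": [800.0], "n1": [200.0], "n2": [200.0]},
            index=["e1"],
        )
        sheet = SampleSheet({"t1": "tumour", "t2": "tumour", "n1": "normal", "n2": "normal"})
        (res,) = differential_abundance(matrix_from_tpm(tpm), sheet)
        assert res.log2fc == pytest.approx(math.log2(801 / 201))

    def test_identical_groups_all_ns(self):
        rng = np.random.default_rng(3)
        data = rng.uniform(10, 100, size=(20, 3))
        tpm = pd.DataFrame(
            np.hstack([data, data]), columns=["t1", "t2", "t3", "n1", "n2", "n3"],
            index=[f"e{i}" for i in range(20)],
        )
        sheet = SampleSheet({s: ("tumour" if s.startswith("t") else "normal")
                             for s in tpm.columns})
        results = differential_abundance(matrix_from_tpm(tpm), sheet)
        assert all(r.direction == "ns" for r in results)

    def test_swapping_groups_negates_log2fc_and_keeps_p(self):
        rng = np.random.default_rng(4)
        tpm = pd.DataFrame(
            rng.uniform(1, 500, size=(15, 6)),
            columns=["t1", "t2", "t3", "n1", "n2", "n3"],
            index=[f"e{i}" for i in range(15)],
        )
        sheet = SampleSheet({s: ("tumour" if s.startswith("t") else "normal")
                             for s in tpm.columns})
        fwd = differential_abundance(matrix_from_tpm(tpm), sheet, contrast=("tumour", "normal"))
        rev = differential_abundance(matrix_from_tpm(tpm), sheet, contrast=("normal", "tumour"))
        for a, b in zip(fwd, rev):
            assert a.log2fc == pytest.approx(-b.log2fc)
            assert a.p == pytest.approx(b.p)
            assert a.q == pytest.approx(b.q)

    def test_q_never_below_p(self, small_dataset):
        m = compute_tpm(small_dataset.records)
        results = differential_abundance(m, small_dataset.sheet)
        for r in results:
            assert r.q >= r.p - 1e-12


class TestEccMir:
    def test_full_containment_is_called(self):
        rec = EccRecord("chr1:50-1000", "s1", "chr1", 50, 1000)
        mir = PreMiR("mir-1", "chr1", "+", 100, 190)
        (call,) = find_eccmirs([rec], [mir])
        assert call.mir_ids == ("mir-1",)

    def test_partial_overlap_is_not_called(self):
        rec = EccRecord("chr1:50-150", "s1", "chr1", 50, 150)
        mir = PreMiR("mir-1", "chr1", "+", 100, 190)
        assert find_eccmirs([rec], [mir]) == []

    def test_simulation_yields_planted_mir_circle_count(self, small_dataset):
        calls = find_eccmirs(small_dataset.records, small_dataset.truth.premirs())
        assert len(calls) == small_dataset.truth.config.n_mir_circles

    def test_agrees_with_double_loop(self):
        rng = np.random.default_rng(8)
        records = []
        for i in range(200):
            s = int(rng.integers(0, 50_000))
            records.append(EccRecord(f"e{i}", "s1", f"chr{rng.integers(1, 4)}",
                                     s, s + int(rng.integers(50, 3_000))))
        mirs = []
        for i in range(60):
            s = int(rng.integers(0, 52_000))
            mirs.append(PreMiR(f"m{i}", f"chr{rng.integers(1, 4)}", "+", s, s + 90))
        calls = {c.ecc_id: set(c.mir_ids) for c in find_eccmirs(records, mirs)}
        expected = {}
        for rec in records:
            contained = {
                m.mir_id for m in mirs
                if m.chrom == rec.chrom and rec.start <= m.start and m.end <= rec.end
            }
            if contained:
                expected[rec.ecc_id] = contained
        assert calls == expected

    def test_small_n_exact_p_blocks_flagging(self):
        tpm = pd.DataFrame(
            {"t1": [100.0], "t2": [110.0], "t3": [120.0],
             "n1": [1.0], "n2": [2.0], "n3": [3.0]},
            index=["chr1:50-1000"],
        )
        sheet = SampleSheet({"t1": "tumour", "t2": "tumour", "t3": "tumour",
                             "n1": "normal", "n2": "normal", "n3": "normal"})
        rec = EccRecord("chr1:50-1000", "t1", "chr1", 50, 1000)
        mir = PreMiR("mir-1", "chr1", "+", 100, 190)
        calls = find_eccmirs([rec], [mir])
        (call,) = flag_eccmir_upregulation(calls, matrix_from_tpm(tpm), sheet)
        assert call.wilcoxon_p == pytest.approx(0.1)
        assert call.is_upregulated is False

    def test_equal_groups_not_flagged(self):
        tpm = pd.DataFrame(
            {"t1": [10.0], "t2": [20.0], "n1": [10.0], "n2": [20.0]},
            index=["chr1:50-1000"],
        )
        sheet = SampleSheet({"t1": "tumour", "t2": "tumour", "n1": "normal", "n2": "normal"})
        rec = EccRecord("chr1:50-1000", "t1", "chr1", 50, 1000)
        calls = find_eccmirs([rec], [PreMiR("mir-1", "chr1", "+", 100, 190)])
        (call,) = flag_eccmir_upregulation(calls, matrix_from_tpm(tpm), sheet)
        assert call.is_upregulated is False

    def test_planted_eightfold_eccmirs_mostly_flagged(self):
        from eccmirkit.simulate import SimConfig, simulate_sample_set

        cfg = SimConfig(seed=6, n_circles=120, n_mir_circles=120,
                        n_samples_per_group=5, planted_log2fc=3.0,
                        n_up_circles=40, chrom_lengths=(400_000, 400_000))
        ds = simulate_sample_set(cfg)
        m = compute_tpm(ds.records)
        calls = find_eccmirs(ds.records, ds.truth.premirs())
        calls = flag_eccmir_upregulation(calls, m, ds.sheet, contrast=("tumour", "normal"))
        truth = ds.truth.frame.set_index("ecc_id")
        planted = [c for c in calls if truth.loc[c.ecc_id, "is_elevated"]]
        flagged = sum(1 for c in planted if c.is_upregulated)
        assert flagged / len(planted) >= 0.8
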