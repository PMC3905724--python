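"""Tests for surrogate-parent Viterbi haplotype sharing."""

import numpy as np
import pytest
from scipy import stats

from isoshare.containers import GeneticMap
from isoshare.sharing import (
    LRPConfig,
    SharingProfile,
    compare_carriers,
    estimate_generations,
    excess_relatedness_decay,
    generations_to_years,
    maximal_identity_pair,
    segments_at,
    sharing_profile,
    viterbi_surrogate_parents,
)
from tests.conftest import make_matrix
from tests.oracle_viterbi import brute_force_best_path


def run_viterbi(geno, cm_positions, error_rate=0.02, switch_rate=1.0):
    """Target = row 0, candidates = remaining rows; map spans the given cM."""
    n_all, m = geno.shape
    bp = np.round(np.asarray(cm_positions) * 1e4).astype(np.int64) + 1
    g = make_matrix(geno, positions=bp)
    total_cm = float(np.max(cm_positions)) + 1.0
    gmap = GeneticMap.uniform("1", int(total_cm * 1e4) + 2, 100.0)  # 1 cM per 10 kb
    cfg = LRPConfig(
        error_rate=error_rate,
        switch_rate=switch_rate,
        candidate_set=[f"s{i}" for i in range(1, n_all)],
    )
    return viterbi_surrogate_parents(g, "s0", gmap, cfg), g, gmap


class TestViterbi:
    def test_matches_brute_force_randomised(self, rng):
        for trial in range(40):
            n_cand = int(rng.integers(2, 5))
            m = int(rng.integers(2, 6))
            geno = rng.integers(0, 3, size=(n_cand + 1, m)).astype(np.int8)
            if rng.random() < 0.3:
                geno[rng.integers(n_cand + 1), rng.integers(m)] = -1
            cm = np.sort(rng.uniform(0, 50, m))
            err = float(rng.uniform(0.01, 0.1))
            vp, _, _ = run_viterbi(geno, cm, error_rate=err)
            lp, path, unordered_unique = brute_force_best_path(
                geno[0], geno[1:], np.asarray(vp.positions_cm), err, 1.0
            )
            assert vp.log_prob == pytest.approx(lp, abs=1e-8), trial
            if unordered_unique:
                got = tuple(frozenset(p) for p in map(tuple, vp.path))
                assert got == tuple(frozenset(p) for p in path), trial

    def test_true_trio_recovered(self, rng):
        # target is a real child of candidates 0 and 1; decoys are random.
        m = 40
        p = rng.uniform(0.2, 0.8, m)
        par = (rng.random((2, 2, m)) < p).astype(np.int8)  # 2 parents x 2 haps
        child = par[0, rng.integers(2, size=m), np.arange(m)] + par[
            1, rng.integers(2, size=m), np.arange(m)
        ]
        decoys = rng.binomial(2, p, size=(4, m)).astype(np.int8)
        geno = np.vstack([child, par.sum(axis=1), decoys])
        cm = np.linspace(0, 20, m)
        vp, g, gmap = run_viterbi(geno, cm, error_rate=0.01)
        chosen = {frozenset(pair) for pair in map(tuple, vp.path)}
        assert chosen == {frozenset({0, 1})}
        left, right = segments_at(vp, int(g.positions[m // 2]))
        assert left.start_bp == g.positions[0] and left.end_bp == g.positions[-1]
        assert left.contains_focal

    def test_identical_candidates_deterministic_tie_break(self):
        geno = np.vstack([np.ones((1, 6)), np.tile([1, 1, 0, 2, 1, 0], (3, 1))]).astype(
            np.int8
        )
        cm = np.linspace(0, 10, 6)
        vp, _, _ = run_viterbi(geno, cm)
        assert np.all(vp.path == 0)  # lowest candidate index on every tie

    def test_missing_target_genotypes_uninformative(self, rng):
        geno = rng.integers(0, 3, size=(4, 5)).astype(np.int8)
        geno[0, :] = -1
        cm = np.linspace(0, 10, 5)
        vp, _, _ = run_viterbi(geno, cm)
        assert np.isfinite(vp.log_prob)

    def test_map_must_cover_variants(self, rng):
        geno = rng.integers(0, 3, size=(4, 5)).astype(np.int8)
        g = make_matrix(geno, positions=np.arange(1, 6) * 1000)
        short_map = GeneticMap.uniform("1", 3000, 1.0)
        with pytest.raises(ValueError, match="map does not cover"):
            viterbi_surrogate_parents(g, "s0", short_map, LRPConfig())


class TestMaximalIdentityPair:
    def test_identical_samples_whole_chromosome(self, rng, uniform_map):
        row = rng.integers(0, 3, size=(1, 20)).astype(np.int8)
        g = make_matrix(np.vstack([row, row]), positions=np.arange(1, 21) * 1000)
        seg = maximal_identity_pair(g, "s0", "s1", 10_000, uniform_map)
        assert seg.start_bp == 1000 and seg.end_bp == 20_000

    def test_flanking_opposite_homozygotes(self, uniform_map):
        geno = np.array([[0, 1, 2], [2, 1, 0]], dtype=np.int8)
        g = make_matrix(geno, positions=[1000, 2000, 3000])
        seg = maximal_identity_pair(g, "s0", "s1", 2000, uniform_map, max_mismatch=0)
        assert seg.start_bp == seg.end_bp == 2000

    def test_mismatch_budget_extends_segment(self, uniform_map):
        geno = np.array([[0, 1, 0, 1, 2], [0, 1, 2, 1, 2]], dtype=np.int8)
        g = make_matrix(geno, positions=np.arange(1, 6) * 1000)
        strict = maximal_identity_pair(g, "s0", "s1", 1500, uniform_map, 0)
        loose = maximal_identity_pair(g, "s0", "s1", 1500, uniform_map, 1)
        assert strict.end_bp == 2000
        assert loose.end_bp == 5000

    def test_focal_outside_range_rejected(self, rng, uniform_map):
        g = make_matrix(rng.integers(0, 3, (2, 5)).astype(np.int8))
        with pytest.raises(ValueError, match="focal position"):
            maximal_identity_pair(g, "s0", "s1", 10_000_000, uniform_map)

    def test_marker_density_refinement_monotone(self, rng, uniform_map):
        # adding markers can only add incompatibilities, never lengthen
        geno = rng.integers(0, 3, size=(2, 40)).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 900_000), 40, replace=False))
        g_fine = make_matrix(geno, positions=pos)
        g_coarse = g_fine.take_variants(np.arange(0, 40, 2))
        focal = int(pos[20])
        fine = maximal_identity_pair(g_fine, "s0", "s1", focal, uniform_map, 0)
        coarse = maximal_identity_pair(g_coarse, "s0", "s1", focal, uniform_map, 0)
        assert coarse.length_bp >= fine.length_bp


class TestAgainstSimulationTruth:
    def test_pair_scan_covers_true_ibd_segments(self, small_cohort):
        g, truth, gmap = small_cohort
        checked = 0
        for _, row in truth.ibd_segments.head(15).iterrows():
            if row["sample_i"] == row["sample_j"]:
                continue
            seg = maximal_identity_pair(
                g, row["sample_i"], row["sample_j"], truth.focal_pos, gmap, 0
            )
            true_len = row["end_bp"] - row["start_bp"]
            if true_len <= 0:
                continue
            inter = max(
                0,
                min(seg.end_bp, row["end_bp"]) - max(seg.start_bp, row["start_bp"]),
            )
            assert inter / true_len > 0.9  # detected segment covers the truth
            checked += 1
        assert checked >= 5

    def test_hmm_segment_agrees_with_pair_scan(self, small_cohort):
        g, truth, gmap = small_cohort
        carriers = [g.samples[i] for i in np.flatnonzero(truth.carrier_status > 0)]
        cfg = LRPConfig(error_rate=0.001)
        agree = 0
        for target in carriers[:4]:
            vp = viterbi_surrogate_parents(g, target, gmap, cfg)
            left, right = segments_at(vp, truth.focal_pos)
            seg = left if left.length_cm >= right.length_cm else right
            oracle = maximal_identity_pair(
                g, target, seg.surrogate, truth.focal_pos, gmap, 0
            )
            inter = max(
                0,
                min(seg.end_bp, oracle.end_bp) - max(seg.start_bp, oracle.start_bp),
            )
            if (
                inter >= 0.9 * max(seg.length_bp, 1)
                and inter >= 0.9 * max(oracle.length_bp, 1)
            ):
                agree += 1
        assert agree >= 3  # >= 90% reciprocal overlap for nearly all targets


class TestSharingProfile:
    @staticmethod
    def _tiny_cohort(rng):
        from isoshare.simulate import IsolateConfig, simulate_isolate

        cfg = IsolateConfig(
            n_founders=12,
            n_generations=5,
            pop_size_trajectory=[14, 18, 22, 28, 34],
            n_variants=60,
            chrom_length_bp=5_000_000,
            map_model={"type": "uniform", "cm_per_mb": 10.0},
            carrier_target_freq=None,
            genotype_error_rate=0.0,
            seed=5,
        )
        return simulate_isolate(cfg)

    def test_single_grid_point_equals_direct_segments(self, rng):
        g, truth, gmap = self._tiny_cohort(rng)
        cfg = LRPConfig(error_rate=0.001)
        targets = g.samples[:3]
        prof = sharing_profile(
            g, gmap, cfg, grid=np.array([truth.focal_pos]), targets=targets
        )
        for i, t in enumerate(targets):
            vp = viterbi_surrogate_parents(g, t, gmap, cfg)
            left, right = segments_at(vp, truth.focal_pos)
            want = max(left.length_cm, right.length_cm)
            assert prof.lengths_cm[i, 0] == pytest.approx(want)

    def test_empty_grid_rejected(self, rng):
        g, _, gmap = self._tiny_cohort(rng)
        with pytest.raises(ValueError, match="grid"):
            sharing_profile(g, gmap, LRPConfig(), grid=np.array([]))


class TestCompareCarriers:
    @staticmethod
    def _profile(car_lengths, non_lengths):
        lengths = np.concatenate([car_lengths, non_lengths])[:, None].astype(float)
        n = len(lengths)
        return SharingProfile(
            grid_bp=np.array([500]),
            grid_cm=np.array([0.05]),
            targets=[f"t{i}" for i in range(n)],
            lengths_bp=lengths * 1e4,
            lengths_cm=lengths,
            carrier=np.array([True] * len(car_lengths) + [False] * len(non_lengths)),
        )

    def test_identical_distributions(self):
        prof = self._profile([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        d, p = compare_carriers(prof, 500)
        assert d == 0.0 and p == 1.0

    def test_disjoint_distributions(self):
        prof = self._profile([0.001, 0.001, 0.001], [1.0, 1.0, 1.0])
        d, _ = compare_carriers(prof, 500)
        assert d == 1.0

    def test_matches_double_loop_ecdf(self, rng):
        x = rng.exponential(1.0, 20)
        y = rng.exponential(1.5, 25)
        prof = self._profile(x, y)
        d, p = compare_carriers(prof, 500)
        # direct two-sided ECDF sup-distance
        grid = np.concatenate([x, y])
        dmax = max(
            abs((x <= v).mean() - (y <= v).mean()) for v in grid
        )
        assert d == pytest.approx(dmax, abs=1e-12)
        ref = stats.ks_2samp(x, y)
        assert p == pytest.approx(ref.pvalue)

    def test_empty_group_rejected(self):
        prof = self._profile([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            compare_carriers(prof, 500)


class TestEstimateGenerations:
    def test_mean_one_morgan(self):
        est = estimate_generations([100.0, 100.0, 100.0])
        assert est["g_hat"] == pytest.approx(1.0)

    def test_background_sharing_scale(self):
        # lengths averaging 15.3 cM imply ~6.5 generations to the ancestor
        est = estimate_generations([15.3] * 50)
        assert est["g_hat"] == pytest.approx(100 / 15.3, rel=1e-9)
        assert est["ci_low"] < est["g_hat"] < est["ci_high"]

    def test_scale_consistency(self, rng):
        lengths = rng.exponential(10.0, 100)
        a = estimate_generations(lengths)["g_hat"]
        b = estimate_generations(lengths * 3.0)["g_hat"]
        assert b == pytest.approx(a / 3.0)

    def test_recovery_from_gamma_lengths(self, rng):
        g_true = 4.1
        hits = 0
        for _ in range(50):
            lengths = (
                rng.exponential(1 / (2 * g_true), 500)
                + rng.exponential(1 / (2 * g_true), 500)
            ) * 100.0
            est = estimate_generations(lengths)
            hits += 3.6 <= est["g_hat"] <= 4.6
            assert est["ci_low"] < est["ci_high"]
        assert hits >= 48

    def test_positive_lengths_required(self):
        with pytest.raises(ValueError):
            estimate_generations([1.0, 0.0])

    def test_generations_to_years(self):
        assert generations_to_years(4.1, 25.0) == pytest.approx(102.5)


class TestExcessDecay:
    @staticmethod
    def _decay_profile(rate, n_car=6, n_non=30, amp=8.0, background=5.0):
        grid_cm = np.linspace(0, 40, 81)
        dist = np.abs(grid_cm - 20.0)
        excess = amp * np.exp(-rate * dist)
        lengths_car = np.tile(background + excess, (n_car, 1))
        lengths_non = np.tile(background, (n_non, len(grid_cm)))
        return SharingProfile(
            grid_bp=(grid_cm * 1e5).astype(np.int64),
            grid_cm=grid_cm,
            targets=[f"t{i}" for i in range(n_car + n_non)],
            lengths_bp=np.vstack([lengths_car, lengths_non]) * 1e4,
            lengths_cm=np.vstack([lengths_car, lengths_non]),
            carrier=np.array([True] * n_car + [False] * n_non),
        )

    def test_exact_exponential_rate_recovered(self):
        prof = self._decay_profile(rate=0.25)
        table, rate = excess_relatedness_decay(prof, 2_000_000, n_bins=40)
        assert rate == pytest.approx(0.25, rel=0.05)
        assert (table["excess_cm"] > 0).all()

    def test_monotone_decay_in_distance(self):
        prof = self._decay_profile(rate=0.3)
        table, _ = excess_relatedness_decay(prof, 2_000_000, n_bins=10)
        assert np.all(np.diff(table["excess_cm"]) <= 1e-9)

    def test_no_signal_no_rate(self, rng):
        grid_cm = np.linspace(0, 40, 41)
        lengths = np.tile(5.0, (20, len(grid_cm)))
        prof = SharingProfile(
            grid_bp=(grid_cm * 1e5).astype(np.int64),
            grid_cm=grid_cm,
            targets=[f"t{i}" for i in range(20)],
            lengths_bp=lengths * 1e4,
            lengths_cm=lengths,
            carrier=np.array([True] * 5 + [False] * 15),
        )
        table, rate = excess_relatedness_decay(prof, 2_000_000)
        assert rate is None
        assert np.allclose(table["excess_cm"], 0.0)
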