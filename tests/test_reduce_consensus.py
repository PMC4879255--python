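"""Line matching, consensus fusion, and interrater agreement statistics."""

import itertools

import numpy as np
import pytest
from scipy import stats as sstats

from crowdoct.reduce_consensus import (GAP_WEIGHT, consensus_line,
                                       interrater_stats, match_lines,
                                       reduce_task)
from crowdoct.synth_retina import RaterModel, SegmentationSet, simulate_rater

from conftest import make_trace


HEIGHT = 496.0


def _cost(ya, yb):
    if ya.std() == 0 and yb.std() == 0:
        r = 1.0
    elif ya.std() == 0 or yb.std() == 0:
        r = 0.0
    else:
        r = np.corrcoef(ya, yb)[0, 1]
    return (1 - r) + GAP_WEIGHT * np.abs(ya - yb).mean() / HEIGHT


class TestMatchLines:
    def test_constant_shift_gives_identity_pairing(self):
        rng = np.random.default_rng(0)
        base = [rng.uniform(20, 40, 64).cumsum() / 10 + 50 * k
                for k in range(5)]
        a = [make_trace(y) for y in base]
        b = [make_trace(y + 4.0) for y in base]
        pairing = match_lines(a, b, HEIGHT)
        assert [(i, j) for i, j, *_ in pairing.matches] == \
               [(k, k) for k in range(5)]
        assert all(r == pytest.approx(1.0) for *_, r, _g in pairing.matches)

    def test_matches_permutation_oracle_on_three_lines(self):
        """Optimal assignment equals exhaustive search over all 3!
        pairings of a small constructed set."""
        rng = np.random.default_rng(8)
        truth = [30 + 5 * np.sin(np.linspace(0, 3, 80)),
                 90 + 8 * np.cos(np.linspace(0, 2, 80)),
                 150 + np.linspace(0, 10, 80)]
        a = [make_trace(y + rng.normal(0, 1, 80)) for y in truth]
        b_perm = [2, 0, 1]  # B's lines stored shuffled
        b = [make_trace(truth[k] + rng.normal(0, 1, 80)) for k in b_perm]
        pairing = match_lines(a, b, HEIGHT)

        best, best_cost = None, np.inf
        for perm in itertools.permutations(range(3)):
            c = sum(_cost(a[i].y, b[perm[i]].y) for i in range(3))
            if c < best_cost:
                best, best_cost = perm, c
        assert {(i, j) for i, j, *_ in pairing.matches} == \
               {(i, best[i]) for i in range(3)}
        # the oracle must recover the construction: b[j] holds truth b_perm[j]
        assert {(i, j) for i, j, *_ in pairing.matches} == \
               {(b_perm[j], j) for j in range(3)}

    def test_spurious_duplicate_left_unmatched(self):
        rng = np.random.default_rng(4)
        truth = [50.0 + 50 * k + 3 * np.sin(np.linspace(0, 4, 96) + k)
                 for k in range(5)]
        a = [make_trace(t + rng.normal(0, 1, 96)) for t in truth]
        a.append(make_trace(truth[2] + 12.0 + rng.normal(0, 1, 96)))
        b = [make_trace(t + rng.normal(0, 1, 96)) for t in truth]
        pairing = match_lines(a, b, HEIGHT)
        assert len(pairing.matches) == 5
        assert pairing.unmatched_a == (5,)
        assert [(i, j) for i, j, *_ in pairing.matches] == \
               [(k, k) for k in range(5)]

    def test_exchangeability(self):
        rng = np.random.default_rng(12)
        a = [make_trace(40.0 + 45 * k + rng.normal(0, 2, 64))
             for k in range(5)]
        b = [make_trace(40.0 + 45 * k + rng.normal(0, 2, 64))
             for k in range(5)]
        ab = match_lines(a, b, HEIGHT)
        ba = match_lines(b, a, HEIGHT)
        assert {(i, j) for i, j, *_ in ab.matches} == \
               {(j, i) for i, j, *_ in ba.matches}


class TestConsensusLine:
    def test_idempotent_on_identical_contributors(self):
        t = make_trace(np.linspace(30, 40, 50))
        c = consensus_line([t, t])
        np.testing.assert_array_equal(c.y_px, t.y)

    def test_midpoint_of_constants(self):
        c = consensus_line([make_trace(np.full(20, 10.0)),
                            make_trace(np.full(20, 20.0))])
        np.testing.assert_array_equal(c.y_px, np.full(20, 15.0))

    def test_domain_is_intersection(self):
        a = make_trace(np.full(30, 10.0), x0=0)
        b = make_trace(np.full(30, 20.0), x0=10)
        c = consensus_line([a, b])
        assert c.x[0] == 10 and c.x[-1] == 29

    def test_empty_shared_domain_errors(self):
        a = make_trace(np.full(10, 10.0), x0=0)
        b = make_trace(np.full(10, 20.0), x0=100)
        with pytest.raises(ValueError, match="share no columns"):
            consensus_line([a, b])

    def test_averaging_reduces_error(self):
        """Variance reduction: over 100 simulated pairs the consensus line
        is closer to truth than a single trace in >= 95 cases."""
        rng = np.random.default_rng(2)
        truth = np.full(512, 100.0)
        wins = 0
        for _ in range(100):
            noise_a = rng.normal(0, 2.0, 512)
            noise_b = rng.normal(0, 2.0, 512)
            a = make_trace(truth + noise_a)
            b = make_trace(truth + noise_b)
            cons = consensus_line([a, b])
            rmse_cons = np.sqrt(np.mean((cons.y_px - truth) ** 2))
            rmse_single = np.sqrt(np.mean((a.y - truth) ** 2))
            wins += rmse_cons < rmse_single
        assert wins >= 95


class TestInterraterStats:
    def test_perfect_agreement(self):
        ya = np.linspace(10, 40, 50)
        rep = interrater_stats([(ya, ya.copy()), (ya + 50, ya + 50)], 3.87)
        assert rep.pearson_r == pytest.approx(1.0, abs=1e-12)
        assert rep.bias_um == 0.0
        assert rep.loa_um == (0.0, 0.0)

    def test_constant_offset_propagates_to_microns(self):
        ya1 = np.linspace(100, 130, 40)
        ya2 = np.linspace(200, 220, 40)
        pairs = [(ya1, ya1 + 2.0), (ya2, ya2 + 2.0)]
        rep = interrater_stats(pairs, axial_um_per_px=3.87)
        assert rep.pearson_r == pytest.approx(1.0, abs=1e-12)
        assert rep.bias_um == pytest.approx(-7.74, abs=1e-9)
        assert rep.loa_um[0] == pytest.approx(rep.loa_um[1], abs=1e-9)
        assert rep.r_squared == pytest.approx(rep.pearson_r ** 2, abs=1e-15)

    def test_pearson_matches_sum_formula_oracle(self):
        """Implementation r equals a from-scratch sum-formula evaluation on
        a 10-point table, and the p-value matches the t transform."""
        ya = np.array([3.1, 4.2, 5.5, 6.1, 7.0, 8.2, 9.9, 11.0, 12.5, 13.1])
        yb = np.array([2.9, 4.8, 5.1, 6.9, 6.8, 8.8, 9.1, 11.9, 12.0, 13.9])
        n = 10
        sx, sy = ya.sum(), yb.sum()
        sxx, syy, sxy = (ya ** 2).sum(), (yb ** 2).sum(), (ya * yb).sum()
        r_oracle = (n * sxy - sx * sy) / np.sqrt(
            (n * sxx - sx ** 2) * (n * syy - sy ** 2))
        t = r_oracle * np.sqrt((n - 2) / (1 - r_oracle ** 2))
        p_oracle = 2 * sstats.t.sf(abs(t), n - 2)

        rep = interrater_stats([(ya, yb)], 1.0)
        assert rep.pearson_r == pytest.approx(r_oracle, abs=1e-12)
        assert rep.p_value == pytest.approx(p_oracle, rel=1e-6)

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            interrater_stats([(np.array([1.0, 2.0]), np.array([1.0, 2.0]))],
                             1.0)


class TestReduceTask:
    def _segset(self, truth, worker, seed, **kw):
        model = RaterModel(worker_id=worker, extra_line_prob=0.0, **kw)
        return simulate_rater(truth, model, 0, seed=seed)

    def test_consensus_error_shrinks_by_sqrt2(self, flat_truth):
        """With two zero-bias raters of noise SD sigma, the consensus error
        approaches sigma/sqrt(2) (averaging independent errors)."""
        errs = []
        for seed in range(8):
            a = self._segset(flat_truth, "a", seed * 2, noise_sd_px=2.0,
                             click_spacing_px=1)
            b = self._segset(flat_truth, "b", seed * 2 + 1, noise_sd_px=2.0,
                             click_spacing_px=1)
            cons, _ = reduce_task([a, b], height=256.0, image_ref=0)
            for k, ln in enumerate(cons.lines):
                errs.append(ln.y_px - flat_truth.curves[k][ln.x])
        rmse = np.sqrt(np.mean(np.concatenate(errs) ** 2))
        assert rmse == pytest.approx(2.0 / np.sqrt(2), rel=0.10)

    def test_consensus_preserves_ordering(self, flat_truth):
        for seed in range(10):
            a = self._segset(flat_truth, "a", seed * 2, noise_sd_px=2.0)
            b = self._segset(flat_truth, "b", seed * 2 + 1, noise_sd_px=2.0)
            cons, _ = reduce_task([a, b], height=256.0, image_ref=0)
            ys = np.stack([ln.y_px for ln in cons.lines])
            assert np.all(np.diff(ys, axis=0) >= 0)

    def test_single_submission_unreduced(self, flat_truth):
        a = self._segset(flat_truth, "a", 1)
        with pytest.raises(ValueError, match="fewer than 2"):
            reduce_task([a], height=256.0, image_ref=0)

    def test_extra_contributors_enter_consensus(self, flat_truth):
        sets = [self._segset(flat_truth, f"w{k}", 10 + k, noise_sd_px=1.0)
                for k in range(3)]
        cons, _ = reduce_task(sets, height=256.0, image_ref=0)
        assert cons.n_raters == 3
        assert all(ln.n_contributors == 3 for ln in cons.lines)
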