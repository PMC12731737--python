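import numpy as np
import pytest

from entroseg import (GrayImage, NoValidThresholdError, binarize,
                      compute_histogram, grid_search_param, kapur_threshold,
                      linou_threshold, make_two_region_constant,
                      masi_threshold, misclassification_error,
                      proposed_threshold, threshold_by_method,
                      tsallis_threshold)
from conftest import histogram_from_counts
from oracles import bf_objective, bf_threshold, random_histogram_counts

METHODS = [
    ("shannon", None, 1),
    ("tsallis", 0.8, 1),
    ("tsallis", 0.3, 1),
    ("masi", 1.2, 1),
    ("masi", 0.8, 1),
    ("linou", 0.8, 1),
    ("linou", 0.5, 2),
    ("maxmin_masi", 1.2, 1),
    ("maxmin_masi", 0.9, 2),
]


class TestAgainstBruteForce:
    @pytest.mark.parametrize("method,param,form", METHODS)
    def test_random_histograms(self, method, param, form):
        rng = np.random.default_rng(777)
        for _ in range(40):
            counts = random_histogram_counts(rng, n_levels=48)
            h = histogram_from_counts(counts)
            expected = bf_threshold(h.probs, method, param, form)
            if expected is None:
                with pytest.raises(NoValidThresholdError):
                    threshold_by_method(h, method, param, form)
            else:
                res = threshold_by_method(h, method, param, form)
                assert res.t_opt == expected

    def test_trace_matches_objective_pointwise(self):
        rng = np.random.default_rng(5)
        counts = random_histogram_counts(rng, n_levels=32)
        h = histogram_from_counts(counts)
        res = proposed_threshold(h, 1.15, 1)
        for t in np.flatnonzero(res.valid):
            bf = bf_objective(h.probs, int(t), "maxmin_masi", 1.15, 1)
            assert res.objective_trace[t] == pytest.approx(float(bf), rel=1e-10)

    def test_trace_export_is_lossless(self):
        rng = np.random.default_rng(6)
        h = histogram_from_counts(random_histogram_counts(rng, 64))
        res = masi_threshold(h, 1.1)
        assert res.objective_trace[res.t_opt] == res.objective_at_opt


class TestTieBreaking:
    def test_two_spike_flat_plateau(self):
        """Between two spikes the Kapur objective is flat; smallest t wins."""
        counts = np.zeros(256, dtype=int)
        counts[50] = counts[200] = 8
        h = histogram_from_counts(counts)
        res = kapur_threshold(h)
        assert res.t_opt == 50
        assert set(res.ties) == set(range(50, 200))
        np.testing.assert_allclose(res.objective_trace[list(res.ties)], 0.0)

    def test_three_spike_matches_oracle(self):
        counts = np.zeros(256, dtype=int)
        counts[0], counts[128], counts[255] = 1, 2, 1
        h = histogram_from_counts(counts)
        assert kapur_threshold(h).t_opt == bf_threshold(h.probs, "shannon")


class TestLimitsAndForms:
    def test_tsallis_limit_equals_kapur(self, rng):
        h = histogram_from_counts(random_histogram_counts(rng, 64))
        assert tsallis_threshold(h, 1 + 1e-7).t_opt == kapur_threshold(h).t_opt

    def test_masi_limit_equals_kapur(self, rng):
        h = histogram_from_counts(random_histogram_counts(rng, 64))
        assert masi_threshold(h, 1 + 1e-7).t_opt == kapur_threshold(h).t_opt

    def test_maxmin_limit_is_shannon_maxmin(self, rng):
        """As r -> 1 both proposal forms reduce to argmax min(S(A), S(B))."""
        h = histogram_from_counts(random_histogram_counts(rng, 64))
        for form in (1, 2):
            got = proposed_threshold(h, 1 + 1e-7, form).t_opt
            # independent Shannon-only max-min oracle
            best_t, best_v = None, None
            for t in range(h.max_level):
                v = bf_objective(h.probs, t, "maxmin_masi", 1.0 + 1e-12, form)
                if v is not None and (best_v is None or v > best_v):
                    best_t, best_v = t, v
            assert got == best_t

    def test_symmetric_histogram_forms_agree(self):
        counts = np.array([5, 1, 0, 0, 1, 5])
        h = histogram_from_counts(counts)
        assert linou_threshold(h, 0.8, 1).t_opt == linou_threshold(h, 0.8, 2).t_opt

    def test_single_level_histogram_rejected(self):
        h = histogram_from_counts([0, 9, 0, 0])
        with pytest.raises(NoValidThresholdError):
            kapur_threshold(h)

    def test_masi_all_invalid_signalled(self):
        counts = np.ones(256, dtype=int)  # near-uniform: S(class) large
        h = histogram_from_counts(counts)
        with pytest.raises(NoValidThresholdError):
            masi_threshold(h, 1.9)


class TestTwoRegionRecovery:
    @pytest.mark.parametrize("method,param,form", METHODS)
    def test_threshold_in_gap_and_exact_mask(self, method, param, form):
        img, gt = make_two_region_constant((8, 8), 50, 200)
        h = compute_histogram(img)
        res = threshold_by_method(h, method, param, form)
        assert 50 <= res.t_opt <= 199
        me, wrong = misclassification_error(gt, binarize(img, res.t_opt))
        assert me == 0.0 and wrong == 0


class TestGridSearch:
    def test_singleton_grid(self, bimodal_fixture):
        img, gt = bimodal_fixture
        res = grid_search_param(img, gt, "masi", [0.5])
        assert res.best_param == 0.5

    def test_perfect_value_wins(self):
        img, gt = make_two_region_constant((8, 8), 50, 200)
        res = grid_search_param(img, gt, "masi", [0.7, 1.0 + 1e-7, 1.3])
        assert res.score_per_param[res.grid.index(res.best_param)] == 0.0

    def test_tie_prefers_smaller_param(self):
        img, gt = make_two_region_constant((8, 8), 50, 200)
        # every grid value achieves ME = 0 here -> smallest param returned
        res = grid_search_param(img, gt, "masi", [1.3, 0.7, 1.1])
        assert res.best_param == 0.7

    def test_refinement_never_worse(self, bimodal_fixture):
        img, gt = bimodal_fixture
        coarse = grid_search_param(img, gt, "maxmin_masi", [0.8, 1.0 + 1e-7, 1.2])
        fine = grid_search_param(img, gt, "maxmin_masi", [0.8, 1.0 + 1e-7, 1.2],
                                 refine=True)
        best = lambda r: min(s for s in r.score_per_param if not np.isnan(s))
        assert best(fine) <= best(coarse)
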