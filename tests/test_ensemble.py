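"""χ² scoring, filtering, P(Rg), representative picking and weight search."""

import warnings

import numpy as np
import pytest

import saxsbm as sb
from saxsbm import ensemble as ens
from saxsbm.curve import ScatteringCurve
from saxsbm.structure import ConformationSet
from tests.conftest import ANCHOR_IDX


def _curve(i, sigma=None, q=None):
    i = np.asarray(i, dtype=float)
    q = np.arange(1, len(i) + 1) * 0.01 if q is None else q
    return ScatteringCurve(q, i, sigma)


class TestChiSquare:
    def test_hand_arithmetic_example(self):
        exp = _curve([2, 4, 6], sigma=[1, 1, 1])
        theo = _curve([1, 3, 5])
        chi2, c = ens.chi_square(exp, theo, fit_scale=False)
        assert chi2 == pytest.approx(1.0)
        assert c == 1.0

    def test_identical_curves_give_zero(self):
        exp = _curve([2, 4, 6], sigma=[0.1, 0.1, 0.1])
        assert ens.chi_square(exp, _curve([2, 4, 6]), False)[0] == 0.0

    def test_scale_fit_absorbs_proportional_curves(self):
        exp = _curve([2, 4, 6], sigma=[0.1, 0.2, 0.1])
        chi2, c = ens.chi_square(exp, _curve([4, 8, 12]), fit_scale=True)
        assert c == pytest.approx(0.5)
        assert chi2 == pytest.approx(0.0, abs=1e-24)

    def test_scale_invariance_under_theoretical_rescaling(self):
        rng = np.random.default_rng(0)
        exp = _curve(rng.uniform(1, 10, 20), sigma=rng.uniform(0.1, 0.5, 20))
        theo = rng.uniform(1, 10, 20)
        base = ens.chi_square(exp, _curve(theo), True)[0]
        for k in (0.1, 3.0, 250.0):
            assert ens.chi_square(exp, _curve(k * theo), True)[0] == pytest.approx(base)

    def test_grid_mismatch_rejected(self):
        exp = _curve([1, 2, 3], sigma=[1, 1, 1])
        theo = ScatteringCurve(np.array([0.02, 0.03, 0.04]), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="grids"):
            ens.chi_square(exp, theo)

    def test_missing_errors_rejected(self):
        with pytest.raises(ValueError, match="σ"):
            ens.chi_square(_curve([1, 2, 3]), _curve([1, 2, 3]))


def _candidates(chi2, rg=None, frame_index=None, n_atoms=4):
    """CandidateSet scaffold with controllable χ² and Rg metadata."""
    n = len(chi2)
    template = sb.Structure(
        elements=np.full(n_atoms, "C"),
        residue_index=np.arange(1, n_atoms + 1),
        chain_ids=np.full(n_atoms, "A"),
        coords=np.arange(3 * n_atoms, dtype=float).reshape(n_atoms, 3),
        domain_labels=np.full(n_atoms, "D1"),
    )
    frames = np.repeat(template.coords[None], n, axis=0)
    cs = ConformationSet(
        template,
        frames,
        frame_index=np.arange(n) if frame_index is None else np.asarray(frame_index),
        rg=np.ones(n) if rg is None else np.asarray(rg, dtype=float),
    )
    q = np.linspace(0.01, 0.1, 5)
    return ens.CandidateSet(cs, np.ones((n, 5)), q, np.asarray(chi2, float), np.ones(n))


class TestFilterLowest:
    def test_keeps_the_five_smallest_of_100(self):
        rng = np.random.default_rng(1)
        chi2 = rng.uniform(1, 100, size=100)
        kept = ens.filter_lowest(_candidates(chi2), 0.05)
        assert len(kept) == 5
        assert set(kept.chi2) == set(np.sort(chi2)[:5])

    def test_forty_thousand_candidates_keep_two_thousand(self):
        chi2 = np.linspace(1, 2, 40_000)
        kept = ens.filter_lowest(_candidates(chi2), 0.05)
        assert len(kept) == 2_000

    def test_ties_resolved_toward_earlier_frames(self):
        kept = ens.filter_lowest(_candidates(np.ones(10)), 0.3)
        assert kept.frame_index.tolist() == [0, 1, 2]

    def test_zero_survivors_is_an_error(self):
        with pytest.raises(ValueError, match="zero"):
            ens.filter_lowest(_candidates(np.ones(3)), 0.05)

    def test_fractions_give_nested_subsets(self):
        rng = np.random.default_rng(2)
        cands = _candidates(rng.uniform(0, 1, 400))
        frames = {
            f: set(ens.filter_lowest(cands, f).frame_index.tolist())
            for f in (0.025, 0.05, 0.075)
        }
        assert frames[0.025] <= frames[0.05] <= frames[0.075]


class TestPrgHistogram:
    def test_identical_rg_gives_single_full_bin_and_one_peak(self):
        h = ens.prg_histogram(np.full(50, 21.3))
        assert len(h.prob) == 1
        assert h.prob[0] == 1.0
        assert len(h.peak_centers) == 1

    def test_trimodal_sample_yields_three_peaks_at_component_means(self):
        rng = np.random.default_rng(3)
        sample = np.concatenate(
            [rng.normal(mu, 0.4, size=1000) for mu in (34.0, 37.5, 41.0)]
        )
        h = ens.prg_histogram(sample, bin_width=0.25)
        top3 = np.sort(h.peak_centers[:3])
        assert len(h.peak_centers) >= 3
        assert np.all(np.abs(top3 - np.array([34.0, 37.5, 41.0])) <= 0.5)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(4)
        h = ens.prg_histogram(rng.uniform(10, 30, 500))
        assert h.prob.sum() == pytest.approx(1.0)


class TestSelectRepresentatives:
    def _jitter_candidates(self, toy, family, chi2, near_duplicate=False):
        """All frames share one P(Rg) peak; frames are RMSD-distinct unless
        a near-duplicate of the best is requested."""
        base = toy.with_coords(family.frames[20])
        cl = sb.domain_rotation_jitter(base, len(chi2), max_angle=1.2, seed=13)
        frames = cl.frames.copy()
        if near_duplicate:
            frames[1] = frames[0] + 1e-4  # within min_rmsd of the best
        cs = ConformationSet(toy, frames)
        q = np.linspace(0.01, 0.1, 5)
        return ens.CandidateSet(
            cs, np.ones((len(chi2), 5)), q, np.asarray(chi2, float), np.ones(len(chi2))
        )

    def test_lowest_chi2_taken_when_all_distinct(self, toy, family):
        chi2 = np.arange(10.0)
        cands = self._jitter_candidates(toy, family, chi2)
        h = ens.prg_histogram(cands)
        groups = ens.select_representatives(cands, h, k_per_peak=4, n_peaks=1)
        assert groups[0].tolist() == [0, 1, 2, 3]

    def test_near_duplicate_of_best_is_skipped(self, toy, family):
        chi2 = np.arange(10.0)
        cands = self._jitter_candidates(toy, family, chi2, near_duplicate=True)
        h = ens.prg_histogram(cands)
        groups = ens.select_representatives(cands, h, k_per_peak=4, n_peaks=1)
        assert groups[0].tolist() == [0, 2, 3, 4]  # index 1 excluded

    def test_selection_is_deterministic(self, state_pool, state_pool_curves, qgrid, family):
        members = state_pool.subset(np.array([50, 150, 250]))
        exp, _ = sb.mock_experiment(
            members, [0.5, 0.3, 0.2], qgrid, sb.NoiseModel(seed=3),
            member_curves=state_pool_curves[[50, 150, 250]],
        )
        ids = []
        for _ in range(2):
            cands = ens.score_candidates(state_pool, exp, curves=state_pool_curves)
            kept = ens.filter_lowest(cands, 0.7)
            h = ens.prg_histogram(kept)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                groups = ens.select_representatives(kept, h)
            ids.append([kept.frame_index[g].tolist() for g in groups])
        assert ids[0] == ids[1]


class TestEnumerateWeights:
    def test_three_members_give_66_vectors(self):
        got = ens.enumerate_weights(3, 0.1)
        # stars-and-bars oracle by explicit enumeration
        oracle = [
            (a / 10, b / 10, (10 - a - b) / 10)
            for a in range(11)
            for b in range(11 - a)
        ]
        assert len(got) == len(oracle) == 66

    def test_single_member(self):
        assert ens.enumerate_weights(1).tolist() == [[1.0]]

    def test_two_members_coarse_step(self):
        got = {tuple(w) for w in ens.enumerate_weights(2, 0.5)}
        assert got == {(0.0, 1.0), (0.5, 0.5), (1.0, 0.0)}

    def test_all_vectors_sum_exactly_to_one(self):
        for k in (2, 3, 4):
            w = ens.enumerate_weights(k, 0.1)
            assert np.all(w.sum(axis=1) == 1.0)
            assert np.all(w >= 0)

    def test_lexicographic_order(self):
        w = ens.enumerate_weights(2, 0.5)
        assert w.tolist() == sorted(w.tolist())


class TestFitEnsemble:
    def test_noise_free_single_member_gets_full_weight(self, family_curves, qgrid):
        exp = ScatteringCurve(qgrid, family_curves[5], 0.01 * family_curves[5])
        fit = ens.fit_ensemble(exp, family_curves[[5, 20, 35]])
        assert fit.weights.tolist() == [1.0, 0.0, 0.0]
        assert fit.chi2 == pytest.approx(0.0, abs=1e-20)

    def test_mixture_weights_recovered_in_at_least_19_of_20_seeds(
        self, toy, family, family_curves, qgrid
    ):
        idx = np.array(ANCHOR_IDX)
        members = ConformationSet(toy, family.frames[idx])
        curves = family_curves[idx]
        hits = 0
        for seed in range(20):
            exp, _ = sb.mock_experiment(
                members, [0.4, 0.3, 0.3], qgrid, sb.NoiseModel(seed=seed), member_curves=curves
            )
            fit = ens.fit_ensemble(exp, curves)
            hits += np.allclose(fit.weights, [0.4, 0.3, 0.3])
        assert hits >= 19

    def test_returned_chi2_is_the_grid_minimum(self, family_curves, qgrid):
        rng = np.random.default_rng(6)
        curves = family_curves[[0, 20, 39]]
        mix = np.array([0.6, 0.2, 0.2]) @ curves
        sigma = 0.02 * mix
        exp = ScatteringCurve(qgrid, mix + rng.normal(0, sigma), sigma)
        fit = ens.fit_ensemble(exp, curves)
        for w in ens.enumerate_weights(3, 0.1):
            chi2, _ = ens.chi_square(exp, ScatteringCurve(qgrid, w @ curves), True)
            assert fit.chi2 <= chi2 + 1e-12


class TestCombinationSearch:
    def test_three_groups_of_four_evaluate_64_ensembles(self, family_curves, qgrid):
        exp = ScatteringCurve(qgrid, family_curves[10], 0.01 * family_curves[10])
        groups = [family_curves[0:4], family_curves[18:22], family_curves[36:40]]
        _, n_eval = ens.combination_search(exp, groups)
        assert n_eval == 64

    def test_single_member_groups_reduce_to_fit_ensemble(self, family_curves, qgrid):
        mix = np.array([0.5, 0.5]) @ family_curves[[0, 39]]
        exp = ScatteringCurve(qgrid, mix, 0.01 * mix)
        best, n_eval = ens.combination_search(
            exp, [family_curves[0:1], family_curves[39:40]]
        )
        direct = ens.fit_ensemble(exp, family_curves[[0, 39]])
        assert n_eval == 1
        assert best.chi2 == pytest.approx(direct.chi2)
        assert np.array_equal(best.weights, direct.weights)

    def test_planted_generating_conformers_recovered(self, family_curves, qgrid):
        gen = list(ANCHOR_IDX)
        w_true = np.array([0.5, 0.3, 0.2])
        mix = w_true @ family_curves[gen]
        sigma = 0.01 * mix
        rng = np.random.default_rng(17)
        exp = ScatteringCurve(qgrid, mix + rng.normal(0, sigma), sigma)
        groups = [family_curves[[g, g - 1 if g else g + 1]] for g in gen]
        ids = [np.array([g, g - 1 if g else g + 1]) for g in gen]
        best, _ = ens.combination_search(exp, groups, ids)
        assert best.member_ids == tuple(gen)
        assert np.allclose(best.weights, w_true)

    def test_empty_group_rejected(self, family_curves, qgrid):
        exp = ScatteringCurve(qgrid, family_curves[0], 0.01 * family_curves[0])
        with pytest.raises(ValueError, match="at least one"):
            ens.combination_search(exp, [family_curves[0:2], family_curves[0:0]])


class TestCrossTable:
    def _fits_and_exps(self, family_curves, qgrid):
        truths = [(0.9, 0.1, 0.0), (0.4, 0.3, 0.3), (0.3, 0.3, 0.4)]
        idx = list(ANCHOR_IDX)
        fits, exps = [], []
        for i, w in enumerate(truths):
            mix = np.array(w) @ family_curves[idx]
            sigma = 0.01 * mix
            rng = np.random.default_rng(30 + i)
            exp = ScatteringCurve(qgrid, mix + rng.normal(0, sigma), sigma)
            exps.append(exp)
            fits.append(ens.fit_ensemble(exp, family_curves[idx]))
        return fits, exps

    def test_diagonal_equals_each_fits_own_chi2(self, family_curves, qgrid):
        fits, exps = self._fits_and_exps(family_curves, qgrid)
        table = ens.cross_table(fits, exps)
        for i, fit in enumerate(fits):
            assert table[i, i] == pytest.approx(fit.chi2)

    def test_diagonal_is_row_minimum_for_distinct_ensembles(self, family_curves, qgrid):
        fits, exps = self._fits_and_exps(family_curves, qgrid)
        table = ens.cross_table(fits, exps)
        for i in range(len(fits)):
            assert table[i, i] == pytest.approx(table[i].min())

    def test_shape_is_fits_by_datasets(self, family_curves, qgrid):
        fits, exps = self._fits_and_exps(family_curves, qgrid)
        assert ens.cross_table(fits[:2], exps).shape == (2, 3)
        single = ens.cross_table(fits[:1], exps[:1])
        assert single.shape == (1, 1)
        assert single[0, 0] == pytest.approx(fits[0].chi2)
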