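"""Solvent-content estimation: expectation, cutoffs, conflation, Eq-style
three-case combination, Matthews candidates."""

import numpy as np
import pytest

from mapseg.map_io import ProbabilityGrid, UnitCell
from mapseg.solvent import (
    CombineConfig,
    EmpiricalLogitDistribution,
    MatthewsPrediction,
    build_empirical_pu,
    combine_estimates,
    conflate_centroid,
    expected_solvent,
    find_logit_cutoff,
    matthews_candidates,
    pm_interpolate,
    pu_of_solvent,
    solvent_at_cutoff,
    symmetrize_grid,
)


def prob_grid(values, cell_edge=24.0, ops=None):
    g = ProbabilityGrid(np.asarray(values, dtype=float),
                        UnitCell(cell_edge, cell_edge, cell_edge))
    if ops is not None:
        g.symmetry_ops = ops
    return g


def logit(p):
    return np.log(p / (1 - p))


class TestExpectedSolvent:
    def test_uniform(self):
        assert expected_solvent(prob_grid(np.full((4, 4, 4), 0.6))) == \
            pytest.approx(0.6)

    def test_half_and_half(self):
        v = np.zeros((4, 4, 4))
        v[:2] = 1.0
        assert expected_solvent(prob_grid(v)) == pytest.approx(0.5)

    def test_matches_brute_force_sum(self, random_prob_grid):
        brute = float(np.sum(random_prob_grid.values) / random_prob_grid.n_voxels)
        assert expected_solvent(random_prob_grid) == pytest.approx(brute, abs=1e-12)

    def test_symmetrized_mean_equals_full_cell_mean(self, rng):
        """A 2-fold axis: mean over the symmetrized grid = plain mean."""
        v = rng.random((8, 8, 8))
        two_fold = [(np.eye(3), np.zeros(3)),
                    (np.diag([-1.0, 1.0, -1.0]), np.array([0.0, 0.5, 0.0]))]
        g = prob_grid(v, ops=two_fold)
        sym = symmetrize_grid(g)
        assert expected_solvent(g) == pytest.approx(float(sym.mean()), abs=1e-12)
        assert expected_solvent(g) == pytest.approx(float(v.mean()), abs=1e-12)


class TestSolventAtCutoff:
    def test_sign_split(self):
        g = prob_grid(np.array([0.9, 0.9, 0.1, 0.1] * 128).reshape(8, 8, 8))
        assert solvent_at_cutoff(g, 0.0) == pytest.approx(0.5)

    def test_extreme_cutoffs(self):
        g = prob_grid(np.full((4, 4, 4), 0.7))
        assert solvent_at_cutoff(g, -50.0) == 1.0
        assert solvent_at_cutoff(g, 50.0) == 0.0

    def test_matches_sort_oracle_everywhere(self, random_prob_grid):
        lg = np.sort(logit(np.clip(random_prob_grid.values.ravel(),
                                   1e-9, 1 - 1e-9)))
        for q in (0.1, 0.25, 0.5, 0.9):
            cut = float(np.quantile(lg, q))
            frac = float((lg > cut).mean())
            assert solvent_at_cutoff(random_prob_grid, cut) == pytest.approx(frac)

    def test_non_increasing_in_cutoff(self, random_prob_grid):
        cuts = np.linspace(-6, 6, 25)
        fracs = [solvent_at_cutoff(random_prob_grid, c) for c in cuts]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))


class TestFindLogitCutoff:
    def test_four_voxel_example(self):
        g = prob_grid(np.array([0.9, 0.9, 0.1, 0.1] * 128).reshape(8, 8, 8))
        lc = find_logit_cutoff(g, 0.5)
        assert logit(0.1) < lc < logit(0.9)
        assert solvent_at_cutoff(g, lc) == pytest.approx(0.5)

    def test_target_zero_classifies_nothing(self):
        g = prob_grid(np.random.default_rng(0).random((6, 6, 6)))
        lc = find_logit_cutoff(g, 0.0)
        assert solvent_at_cutoff(g, lc) == 0.0

    def test_target_one_classifies_everything(self):
        g = prob_grid(np.random.default_rng(0).random((6, 6, 6)))
        lc = find_logit_cutoff(g, 1.0)
        assert solvent_at_cutoff(g, lc) == 1.0

    def test_recovers_target_within_one_voxel(self, random_prob_grid):
        """Quantile oracle: achieved fraction within 1/N of the request."""
        n = random_prob_grid.n_voxels
        for target in (0.47, 0.2, 0.83):
            lc = find_logit_cutoff(random_prob_grid, target)
            achieved = solvent_at_cutoff(random_prob_grid, lc)
            assert abs(achieved - target) <= 1.0 / n + 1e-12

    def test_degenerate_grid_warns(self):
        g = prob_grid(np.full((4, 4, 4), 0.5))
        with pytest.warns(UserWarning, match="equal"):
            find_logit_cutoff(g, 0.3)


class TestEmpiricalPu:
    def test_identical_cutoffs_concentrate_in_one_bin(self, rng):
        items = []
        for _ in range(5):
            v = np.array([0.2, 0.8] * 32).reshape(4, 4, 4)
            items.append((prob_grid(v), 0.5))
        dist = build_empirical_pu(items, bins=20, logit_range=(-4, 4))
        assert dist.probs.max() == pytest.approx(1.0)
        assert dist.probs.sum() == pytest.approx(1.0)

    def test_normalization_for_random_inputs(self, rng):
        items = [(prob_grid(rng.random((6, 6, 6))), float(rng.uniform(0.2, 0.8)))
                 for _ in range(12)]
        dist = build_empirical_pu(items, bins=30)
        assert dist.probs.sum() == pytest.approx(1.0)
        assert (dist.probs >= 0).all()

    def test_recovers_known_normal_cutoff_distribution(self, rng):
        """Items engineered so l_c equals a draw from N(1.0, 0.5)."""
        true_mean, true_sd, n_items = 1.0, 0.5, 100
        draws = rng.normal(true_mean, true_sd, size=n_items)
        items = []
        for l in draws:
            lo = 1.0 / (1.0 + np.exp(-(l - 0.2)))
            hi = 1.0 / (1.0 + np.exp(-(l + 0.2)))
            v = np.array([lo, hi] * 32).reshape(4, 4, 4)
            items.append((prob_grid(v), 0.5))  # cutoff = midpoint = l
        dist = build_empirical_pu(items, bins=400, logit_range=(-8, 8))
        centers = 0.5 * (dist.edges[:-1] + dist.edges[1:])
        est_mean = float((centers * dist.probs).sum())
        se = true_sd / np.sqrt(n_items)
        assert abs(est_mean - draws.mean()) <= 3 * se + 16.0 / 400

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            build_empirical_pu([])

    def test_json_round_trip(self):
        dist = EmpiricalLogitDistribution.uniform(-4, 4, 10)
        back = EmpiricalLogitDistribution.from_json(dist.to_json())
        assert np.allclose(back.edges, dist.edges)
        assert np.allclose(back.probs, dist.probs)


class TestPuOfSolvent:
    def test_concentrated_distribution(self, rng):
        g = prob_grid(rng.random((6, 6, 6)))
        lc = find_logit_cutoff(g, 0.4)
        # first bin [lc - 1, lc + 0.5) contains the cutoff and all the mass
        edges = np.array([lc - 1.0, lc + 0.5, lc + 1.0])
        dist = EmpiricalLogitDistribution(edges, np.array([1.0, 0.0]))
        assert pu_of_solvent(g, dist, 0.4) == pytest.approx(1.0)

    def test_solvent_to_cutoff_map_is_non_increasing(self, rng):
        g = prob_grid(rng.random((8, 8, 8)))
        cuts = [find_logit_cutoff(g, s) for s in (0.2, 0.4, 0.6, 0.8)]
        assert all(a >= b for a, b in zip(cuts, cuts[1:]))

    def test_uniform_distribution_is_flat(self, rng):
        g = prob_grid(rng.random((6, 6, 6)))
        dist = EmpiricalLogitDistribution.uniform(-8, 8, 16)
        vals = [pu_of_solvent(g, dist, s) for s in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(v == pytest.approx(1.0 / 16) for v in vals)


class TestPmInterpolate:
    def test_exact_at_knots_and_edges(self):
        m = MatthewsPrediction(np.array([0.3, 0.5, 0.7]),
                               np.array([0.2, 0.6, 0.2]))
        for s, p in zip(m.solvent, m.prob):
            assert pm_interpolate(m, float(s)) == pytest.approx(p)
        assert pm_interpolate(m, 0.0) == 0.0
        assert pm_interpolate(m, 1.0) == 0.0

    def test_linear_midpoint(self):
        m = MatthewsPrediction(np.array([0.5]), np.array([0.8]))
        assert pm_interpolate(m, 0.25) == pytest.approx(0.4)

    def test_continuous_and_nonnegative(self):
        m = MatthewsPrediction(np.array([0.35, 0.62]), np.array([0.9, 0.4]))
        s = np.linspace(0, 1, 2001)
        y = pm_interpolate(m, s)
        assert (y >= 0).all()
        assert np.abs(np.diff(y)).max() < 0.01  # no jumps at this resolution


class TestConflateCentroid:
    def test_uniform_pu_reduces_to_pm_centroid(self, rng):
        g = prob_grid(rng.random((8, 8, 8)))
        m = MatthewsPrediction(np.array([0.3, 0.6]), np.array([0.5, 0.9]))
        dist = EmpiricalLogitDistribution.uniform(-12, 12, 8)
        got = conflate_centroid(g, m, dist, step=0.001)
        # independent fine-grid integration of P_M alone
        s = np.linspace(0, 1, 100001)
        pm = pm_interpolate(m, s)
        expect = np.trapezoid(s * pm, s) / np.trapezoid(pm, s)
        assert got == pytest.approx(expect, abs=0.002)

    def test_narrow_triangle_centroid(self, rng):
        g = prob_grid(rng.random((8, 8, 8)))
        m = MatthewsPrediction(np.array([0.49, 0.5, 0.51]),
                               np.array([1e-9, 1.0, 1e-9]))
        dist = EmpiricalLogitDistribution.uniform(-12, 12, 8)
        got = conflate_centroid(g, m, dist, step=0.001)
        assert got == pytest.approx(0.5, abs=0.002)

    def test_zero_product_falls_back_to_expectation(self, rng):
        # probabilities in [0.4, 0.6]: every achievable cutoff lies in [-1.5, 1.5]
        g = prob_grid(0.4 + 0.2 * rng.random((8, 8, 8)))
        m = MatthewsPrediction(np.array([0.5]), np.array([1.0]))
        # all P_U mass in a bin around logit 6, which no cutoff reaches
        probs = np.zeros(32)
        probs[28] = 1.0
        dist = EmpiricalLogitDistribution(np.linspace(-8, 8, 33), probs)
        with pytest.warns(UserWarning, match="zero"):
            got = conflate_centroid(g, m, dist)
        assert got == pytest.approx(expected_solvent(g))


class TestCombineEstimates:
    def test_consistent_case_returns_candidate_bitwise(self, rng):
        v = np.full((6, 6, 6), 0.49)
        g = prob_grid(v + 0.001 * rng.random((6, 6, 6)))
        m = MatthewsPrediction(np.array([0.50, 0.65]), np.array([0.9, 0.1]))
        est = combine_estimates(g, m)
        assert est.method == "matthews"
        assert est.value == 0.50  # exact, no arithmetic drift

    def test_inconsistent_case_returns_expectation_exactly(self, rng):
        g = prob_grid(np.full((6, 6, 6), 0.20))
        m = MatthewsPrediction(np.array([0.60, 0.70]), np.array([0.5, 0.5]))
        est = combine_estimates(g, m)
        assert est.method == "segmentation-expectation"
        assert est.value == expected_solvent(g)

    def test_partial_case_uses_conflation_centroid(self, rng):
        vals = np.clip(0.42 + 0.2 * rng.standard_normal((8, 8, 8)), 0.01, 0.99)
        g = prob_grid(vals)
        m = MatthewsPrediction(np.array([0.30]), np.array([1.0]))
        dist = EmpiricalLogitDistribution.uniform(-8, 8, 32)
        cfg = CombineConfig()
        est = combine_estimates(g, m, dist, cfg)
        assert est.method == "conflation-centroid"
        expect = conflate_centroid(g, m, dist, step=cfg.centroid_step)
        assert est.value == pytest.approx(expect, abs=1e-12)

    def test_no_matthews_gives_expectation(self, rng):
        g = prob_grid(rng.random((6, 6, 6)))
        est = combine_estimates(g, None)
        assert est.method == "segmentation-expectation"
        assert est.value == expected_solvent(g)

    def test_tie_breaks_prefer_nearest_then_probability(self):
        g = prob_grid(np.full((6, 6, 6), 0.50))
        m = MatthewsPrediction(np.array([0.47, 0.52]), np.array([0.6, 0.9]))
        est = combine_estimates(g, m)
        assert est.value == 0.52  # nearer to S_U = 0.50

    def test_estimate_is_flagged_final(self, rng):
        est = combine_estimates(prob_grid(rng.random((4, 4, 4))), None)
        assert est.final is True


class TestEndToEndRecovery:
    def test_combination_beats_misleading_matthews_on_average(self, rng):
        """With a misleading Matthews list, folding in the segmentation
        expectation must reduce the mean solvent-content error."""
        err_combined, err_matthews = [], []
        dist = EmpiricalLogitDistribution.uniform(-8, 8, 32)
        for i in range(20):
            true_s = float(rng.uniform(0.35, 0.65))
            # a plausible segmentation: probabilities noisily tracking truth
            truth = (rng.random((10, 10, 10)) < true_s).astype(float)
            probs = np.clip(truth * 0.75 + 0.12 + 0.08 * rng.standard_normal(
                (10, 10, 10)), 0.001, 0.999)
            g = prob_grid(probs)
            # misleading: top candidate far from the truth
            far = true_s + 0.25 if true_s < 0.5 else true_s - 0.25
            near = true_s + float(rng.uniform(-0.05, 0.05))
            cands = np.sort(np.array([far, near]))
            probs_m = np.array([0.9, 0.1]) if cands[0] == far else \
                np.array([0.1, 0.9])
            m = MatthewsPrediction(cands, probs_m)
            est = combine_estimates(g, m, dist)
            err_combined.append(abs(est.value - true_s))
            err_matthews.append(abs(m.solvent[m.j_max] - true_s))
        assert np.mean(err_combined) <= np.mean(err_matthews)


class TestMatthewsCandidates:
    def test_hand_formula_toy(self):
        """V = 1e6 A^3, 1 symop, 25 kDa: S_z = 1 - z * 0.030723..."""
        got = matthews_candidates(1e6, 1, 25000.0, max_monomers=8)
        per_monomer = 25000.0 * 0.74 / (1e6 * 6.02214076e-1)
        expect = np.sort([1 - z * per_monomer for z in range(1, 9)])
        assert np.allclose(got, expect, atol=1e-12)

    def test_doubling_mw_doubles_protein_fraction(self):
        s1 = matthews_candidates(1e6, 1, 25000.0, max_monomers=1)
        s2 = matthews_candidates(1e6, 1, 50000.0, max_monomers=1)
        assert (1 - s2[0]) == pytest.approx(2 * (1 - s1[0]), rel=1e-12)

    def test_out_of_range_monomer_counts_excluded(self):
        got = matthews_candidates(4e5, 4, 25000.0, max_monomers=10)
        assert (got > 0).all() and (got < 1).all()
        per = 4 * 25000.0 * 0.74 / (4e5 * 6.02214076e-1)
        assert len(got) == sum(1 for z in range(1, 11) if 0 < 1 - z * per < 1)

    def test_nothing_in_range_is_an_error(self):
        with pytest.raises(ValueError, match="solvent"):
            matthews_candidates(1e4, 8, 100000.0)


class TestMatthewsPredictionValidation:
    def test_requires_increasing_candidates(self):
        with pytest.raises(ValueError):
            MatthewsPrediction(np.array([0.5, 0.4]), np.array([0.5, 0.5]))

    def test_j_max(self):
        m = MatthewsPrediction(np.array([0.3, 0.5, 0.7]),
                               np.array([0.1, 0.2, 0.9]))
        assert m.j_max == 2

    def test_uniform_fallback(self):
        m = MatthewsPrediction.uniform(np.array([0.5, 0.3]))
        assert np.allclose(m.prob, 0.5)
        assert list(m.solvent) == [0.3, 0.5]
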