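"""Subprofile decomposition exactness and branch-and-bound optimality."""

import itertools

import numpy as np
import pytest

from ionsaxs.ionselect import (SelectionConfig, assemble, branch_and_bound,
                               precompute)
from ionsaxs.probes import generate_surface_probes
from ionsaxs.saxs import debye_intensity, fit_chi2, ScatteringProfile
from ionsaxs.structures import assign_accessibility
from ionsaxs.synthetic import NoiseModel, add_ions, make_helix, simulate_profile


@pytest.fixture(scope="module")
def rna():
    return assign_accessibility(make_helix(6))


@pytest.fixture(scope="module")
def candidates(rna):
    probes = generate_surface_probes(rna)
    rng = np.random.default_rng(0)
    return probes.positions[rng.choice(len(probes), 6, replace=False)]


@pytest.fixture(scope="module")
def cache(rna, candidates, q_grid):
    return precompute(rna, candidates, q_grid)


class TestDecomposition:
    def test_empty_subset_is_rna_profile(self, rna, cache, q_grid):
        assert np.array_equal(assemble(cache, []).I, cache.I_rna)
        direct = debye_intensity(rna, q_grid).I
        assert np.allclose(cache.I_rna, direct, rtol=1e-12)

    @pytest.mark.parametrize("subset", [(0,), (3,), (1, 4), (0, 2, 5),
                                        (0, 1, 2, 3, 4, 5)])
    def test_matches_direct_debye(self, rna, candidates, cache, q_grid, subset):
        combined = add_ions(rna, candidates[list(subset)])
        direct = debye_intensity(combined, q_grid).I
        assert np.allclose(assemble(cache, subset).I, direct, rtol=1e-8)

    def test_permutation_invariant(self, cache):
        assert np.allclose(assemble(cache, (0, 3, 5)).I,
                           assemble(cache, (5, 0, 3)).I, rtol=1e-14)

    def test_duplicate_index_rejected(self, cache):
        with pytest.raises(ValueError, match="duplicate"):
            assemble(cache, (1, 1))

    def test_too_close_candidate_rejected_with_warning(self, rna, q_grid):
        near = rna.positions[0] + np.array([0.3, 0.0, 0.0])
        far = rna.positions.mean(axis=0) + np.array([30.0, 0, 0])
        with pytest.warns(UserWarning, match="rejecting"):
            cache = precompute(rna, [near, far], q_grid)
        assert cache.n_candidates == 1
        assert list(cache.kept_indices) == [1]


class TestBranchAndBound:
    def planted_exp(self, rna, candidates, q_grid, subset):
        return simulate_profile(rna, q_grid, NoiseModel(0, 0),
                                ions=candidates[list(subset)])

    def test_planted_pair_recovered_exactly(self, rna, candidates, cache, q_grid):
        exp = self.planted_exp(rna, candidates, q_grid, (2, 5))
        res = branch_and_bound(exp, cache, SelectionConfig(K=None))
        assert res.subset == (2, 5)
        assert res.fit.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_exhaustive_K_matches_brute_force(self, rna, candidates, cache, q_grid):
        exp = self.planted_exp(rna, candidates, q_grid, (0, 2, 4))
        res = branch_and_bound(exp, cache, SelectionConfig(K=None, max_ions=3))
        best = min(
            (s for n in range(4) for s in itertools.combinations(range(6), n)),
            key=lambda s: fit_chi2(exp, assemble(cache, s)).chi2)
        assert res.subset == best == (0, 2, 4)

    def test_trajectory_non_increasing(self, rna, candidates, cache, q_grid):
        exp = self.planted_exp(rna, candidates, q_grid, (0, 2, 4))
        res = branch_and_bound(exp, cache, SelectionConfig(K=2))
        scores = [lv.score for lv in res.trajectory]
        assert all(a >= b for a, b in zip(scores, scores[1:]))
        assert res.trajectory[0].subset == ()

    def test_beam_bracketed_by_exhaustive_and_greedy(self, rna, candidates,
                                                     cache, q_grid):
        exp = self.planted_exp(rna, candidates, q_grid, (1, 3, 5))
        exact = branch_and_bound(exp, cache, SelectionConfig(K=None)).fit.chi2
        greedy = branch_and_bound(exp, cache, SelectionConfig(K=1)).fit.chi2
        beam = branch_and_bound(exp, cache, SelectionConfig(K=3)).fit.chi2
        assert exact - 1e-12 <= beam <= greedy + 1e-12

    def test_no_improving_candidate_returns_empty(self, rna, cache, q_grid):
        # the RNA alone is the truth: no ion can improve a zero-noise match
        exp = simulate_profile(rna, q_grid, NoiseModel(0, 0))
        res = branch_and_bound(exp, cache)
        assert res.subset == ()
        assert res.fit.chi2 == pytest.approx(0.0, abs=1e-15)
        assert len(res.trajectory) == 1

    def test_max_ions_cap_respected(self, rna, candidates, cache, q_grid):
        exp = self.planted_exp(rna, candidates, q_grid, (0, 2, 4))
        res = branch_and_bound(exp, cache, SelectionConfig(K=None, max_ions=2))
        assert len(res.subset) <= 2
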