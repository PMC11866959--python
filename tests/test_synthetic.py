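import numpy as np
import pytest
from scipy.spatial.distance import pdist
from sklearn.metrics import roc_auc_score

from ionsaxs.saxs import debye_intensity, fit_chi2
from ionsaxs.probes import FEATURE_ELEMENTS
from ionsaxs.synthetic import (NoiseModel, make_binding_pockets, make_helix,
                               make_neighborhoods, perturb_ensemble,
                               simulate_profile)
from ionsaxs.structures import assign_accessibility


class TestHelix:
    def test_atom_count_per_base_pair(self):
        assert len(make_helix(1, atoms_per_nt=6)) == 12
        assert len(make_helix(1, atoms_per_nt=3)) == 6
        assert len(make_helix(7, atoms_per_nt=6)) == 84

    def test_rg_grows_with_length(self):
        def rg(model):
            pos = model.positions
            return np.sqrt(np.mean(np.sum((pos - pos.mean(0)) ** 2, axis=1)))
        values = [rg(make_helix(n)) for n in (5, 10, 20, 35, 50)]
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_deterministic_distance_multiset(self):
        d1 = np.sort(pdist(make_helix(4).positions))
        d2 = np.sort(pdist(make_helix(4).positions))
        assert np.array_equal(d1, d2)

    def test_rejects_empty_helix(self):
        with pytest.raises(ValueError):
            make_helix(0)


class TestPerturbEnsemble:
    def test_zero_magnitude_is_identity(self):
        base = make_helix(5)
        ens = perturb_ensemble(base, 3, magnitude=0.0, seed=1)
        for m in ens:
            assert np.allclose(m.positions, base.positions, atol=1e-12)

    def test_rmsd_grows_with_magnitude(self):
        base = make_helix(5)
        def mean_rmsd(mag):
            ens = perturb_ensemble(base, 40, magnitude=mag, seed=7)
            return np.mean([np.sqrt(np.mean(np.sum(
                (m.positions - base.positions) ** 2, axis=1))) for m in ens])
        assert mean_rmsd(2.0) > mean_rmsd(0.5) > 0.0

    def test_intra_segment_distances_preserved(self):
        # the hinge rotations are rigid, so the last few atoms (always in the
        # final segment) keep their mutual distances exactly
        base = make_helix(5)
        ens = perturb_ensemble(base, 5, magnitude=1.0, seed=3,
                               hinges_per_conformation=1)
        tail = slice(-5, None)
        ref = pdist(base.positions[tail])
        for m in ens:
            assert np.allclose(pdist(m.positions[tail]), ref, atol=1e-9)

    def test_same_seed_reproduces(self):
        base = make_helix(4)
        e1 = perturb_ensemble(base, 3, magnitude=0.8, seed=5)
        e2 = perturb_ensemble(base, 3, magnitude=0.8, seed=5)
        for a, b in zip(e1, e2):
            assert np.array_equal(a.positions, b.positions)


class TestSimulateProfile:
    def test_zero_noise_equals_debye_with_zero_chi2(self, helix_acc, q_grid):
        prof = simulate_profile(helix_acc, q_grid, NoiseModel(0, 0))
        calc = debye_intensity(helix_acc, q_grid)
        assert np.array_equal(prof.I, calc.I)
        assert fit_chi2(prof, calc).chi2 == pytest.approx(0.0, abs=1e-20)

    def test_same_seed_identical_profile(self, helix_acc, q_grid):
        p1 = simulate_profile(helix_acc, q_grid, NoiseModel(seed=4))
        p2 = simulate_profile(helix_acc, q_grid, NoiseModel(seed=4))
        assert np.array_equal(p1.I, p2.I)

    def test_sigma_positive_everywhere(self, helix_acc, q_grid):
        prof = simulate_profile(helix_acc, q_grid, NoiseModel())
        assert np.all(prof.sigma > 0)


class TestNeighborhoodGenerator:
    def test_class_counts_exact(self):
        data = make_neighborhoods(13, 7, seed=0)
        labels = [g.label for g in data]
        assert labels.count(1) == 13 and labels.count(0) == 7

    def test_positives_have_oxygen_rich_inner_shell(self):
        o_col = FEATURE_ELEMENTS.index("O")
        d_col = len(FEATURE_ELEMENTS)
        for g in make_neighborhoods(50, 0, seed=1):
            f = g.node_features
            close_o = (f[:, o_col] == 1.0) & (f[:, d_col] * 8.0 <= 2.3)
            assert close_o.sum() >= 4

    def test_negatives_have_no_close_contacts(self):
        d_col = len(FEATURE_ELEMENTS)
        for g in make_neighborhoods(0, 50, seed=2):
            assert np.all(g.node_features[:, d_col] * 8.0 >= 2.6 - 1e-9)

    def test_one_rule_oracle_separates_classes(self):
        # "at least 4 oxygens within 2.3 A" is the floor any learner must beat
        data = make_neighborhoods(500, 500, seed=0)
        o_col = FEATURE_ELEMENTS.index("O")
        d_col = len(FEATURE_ELEMENTS)
        scores = [float(np.sum((g.node_features[:, o_col] == 1.0)
                               & (g.node_features[:, d_col] * 8.0 <= 2.3)) >= 4)
                  for g in data]
        y = [g.label for g in data]
        assert roc_auc_score(y, scores) >= 0.99


class TestBindingPockets:
    def test_centers_have_coordinating_oxygens(self):
        model, centers = make_binding_pockets(make_helix(8), n_pockets=3, seed=1)
        pos = model.positions
        elements = np.array(model.elements)
        for c in centers:
            d = np.linalg.norm(pos - c[None, :], axis=1)
            close_o = (d <= 2.3) & (elements == "O")
            assert close_o.sum() >= 4

    def test_pocket_atoms_do_not_clash(self):
        model, _ = make_binding_pockets(make_helix(8), n_pockets=2, seed=4)
        d = pdist(model.positions)
        assert d.min() > 0.8
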