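import numpy as np
import pytest

from ionsaxs.ionnet import (ClassifierModel, Hyperparameters, InferenceConfig,
                            SchemaMismatchError, pack, select_sites, train)
from ionsaxs.probes import ProbeSet, extract_neighborhood
from ionsaxs.synthetic import make_neighborhoods


class TestBackprop:
    def test_gradients_match_numeric_differentiation(self):
        batch = pack(make_neighborhoods(4, 4, seed=7))
        model = ClassifierModel(Hyperparameters(hidden=8, seed=1))
        _, grads = model.loss_and_grads(batch)
        rng = np.random.default_rng(0)
        for key, g in grads.items():
            flat = model.params[key].ravel()
            for idx in rng.choice(flat.size, min(4, flat.size), replace=False):
                eps, orig = 1e-6, flat[idx]
                flat[idx] = orig + eps
                lp, _ = model.loss_and_grads(batch)
                flat[idx] = orig - eps
                lm, _ = model.loss_and_grads(batch)
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(g.ravel()[idx], rel=1e-4, abs=1e-8), key


class TestTraining:
    def test_separable_set_reaches_high_auroc(self, small_training_result):
        assert small_training_result.auroc_mean >= 0.95

    def test_loss_decreases_over_epochs(self, small_training_result):
        losses = small_training_result.model.epoch_losses
        assert losses[-1] < losses[0]

    def test_identical_seed_reproduces_fold_aurocs(self):
        data = make_neighborhoods(60, 60, seed=2)
        hyper = Hyperparameters(epochs=5, seed=3)
        r1 = train(data, folds=2, seed=3, hyper=hyper)
        r2 = train(data, folds=2, seed=3, hyper=hyper)
        assert np.array_equal(r1.fold_aurocs, r2.fold_aurocs)

    def test_single_class_dataset_rejected(self):
        data = make_neighborhoods(10, 0, seed=0)
        with pytest.raises(ValueError, match="both classes"):
            train(data, folds=2, seed=0)

    def test_unlabeled_graphs_rejected(self):
        data = make_neighborhoods(5, 5, seed=0)
        data[0].label = None
        with pytest.raises(ValueError, match="labeled"):
            train(data, folds=2, seed=0)


class TestPrediction:
    def test_probabilities_in_unit_interval(self, classifier):
        data = make_neighborhoods(50, 50, seed=8)
        p = classifier.predict_proba(data)
        assert np.all((p >= 0) & (p <= 1))

    def test_positives_score_above_negatives(self, classifier):
        data = make_neighborhoods(100, 100, seed=9)
        p = classifier.predict_proba(data)
        y = np.array([g.label for g in data])
        assert np.median(p[y == 1]) > np.median(p[y == 0])

    def test_invariant_to_rigid_motion_of_source(self, classifier, helix_acc):
        probe = helix_acc.positions.mean(axis=0) + np.array([11.0, 0, 0])
        g1 = extract_neighborhood(helix_acc, probe)
        theta = 0.6
        R = np.array([[1, 0, 0], [0, np.cos(theta), -np.sin(theta)],
                      [0, np.sin(theta), np.cos(theta)]])
        t = np.array([-4.0, 9.0, 2.0])
        g2 = extract_neighborhood(helix_acc.transformed(rotation=R, translation=t),
                                  probe @ R.T + t)
        assert classifier.predict(g1) == pytest.approx(classifier.predict(g2),
                                                       abs=1e-9)

    def test_checkpoint_round_trip(self, classifier, tmp_path):
        path = tmp_path / "model.npz"
        classifier.save(path)
        loaded = ClassifierModel.load(path)
        data = make_neighborhoods(10, 10, seed=5)
        assert np.allclose(loaded.predict_proba(data),
                           classifier.predict_proba(data))

    def test_schema_mismatch_detected(self, classifier):
        data = make_neighborhoods(1, 0, seed=0)
        g = data[0]
        g.node_features = np.hstack([g.node_features,
                                     np.zeros((g.n_nodes, 1))])
        with pytest.raises((SchemaMismatchError, ValueError)):
            classifier.predict(g)


class TestStructureImporter:
    def test_mg_and_waters_become_labeled_neighborhoods(self, helix_acc):
        from ionsaxs.ionnet import neighborhoods_from_structure
        from ionsaxs.structures import Atom, AtomicModel, AtomRole
        surface = helix_acc.positions.mean(axis=0) + np.array([11.0, 0, 0])
        extra = [
            Atom(element="MG", position=surface, role=AtomRole.MG),
            Atom(element="O", position=surface + np.array([0, 3.0, 0]),
                 role=AtomRole.WATER, resname="HOH"),
            Atom(element="MG", position=np.array([500.0, 0, 0]),
                 role=AtomRole.MG),  # isolated: skipped
        ]
        model = AtomicModel(list(helix_acc.atoms) + extra)
        graphs = neighborhoods_from_structure(model)
        assert sorted(g.label for g in graphs) == [0, 1]
        assert all(g.n_nodes >= 1 for g in graphs)


class TestSiteSelection:
    def probe_set(self, positions):
        return ProbeSet(np.asarray(positions, dtype=float))

    def test_close_pair_collapses_to_stronger_probe(self):
        probes = self.probe_set([[0, 0, 0], [1, 0, 0]])
        sites = select_sites(probes, [0.8, 0.9],
                             InferenceConfig(min_separation=2.0))
        assert len(sites) == 1
        assert sites[0].probability == pytest.approx(0.9)

    def test_all_below_threshold_yields_empty(self):
        probes = self.probe_set([[0, 0, 0], [10, 0, 0]])
        assert select_sites(probes, [0.2, 0.4], InferenceConfig()) == []

    def test_distant_confident_probes_all_kept_sorted(self):
        probes = self.probe_set([[0, 0, 0], [10, 0, 0], [0, 10, 0]])
        sites = select_sites(probes, [0.6, 0.95, 0.7],
                             InferenceConfig(min_separation=3.0))
        assert [s.probe_index for s in sites] == [1, 2, 0]
        assert [s.probability for s in sites] == sorted(
            (s.probability for s in sites), reverse=True)

    def test_pairwise_separation_respected(self):
        rng = np.random.default_rng(4)
        probes = self.probe_set(rng.uniform(0, 20, size=(200, 3)))
        p = rng.uniform(0, 1, size=200)
        config = InferenceConfig(threshold=0.3, min_separation=4.0)
        sites = select_sites(probes, p, config)
        pos = np.array([s.position for s in sites])
        for i in range(len(sites)):
            for j in range(i + 1, len(sites)):
                assert np.linalg.norm(pos[i] - pos[j]) >= config.min_separation

    def test_site_count_monotone_in_threshold(self):
        rng = np.random.default_rng(6)
        probes = self.probe_set(rng.uniform(0, 30, size=(300, 3)))
        p = rng.uniform(0, 1, size=300)
        counts = [len(select_sites(probes, p, InferenceConfig(threshold=t)))
                  for t in (0.3, 0.5, 0.7, 0.9)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_max_sites_cap(self):
        rng = np.random.default_rng(1)
        probes = self.probe_set(rng.uniform(0, 50, size=(100, 3)))
        sites = select_sites(probes, np.full(100, 0.9),
                             InferenceConfig(max_sites=5, min_separation=1.0))
        assert len(sites) == 5
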