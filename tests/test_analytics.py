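import numpy as np
import pytest

from ionsaxs.saxs import (GuinierError, ScatteringProfile, debye_from_factors,
                          dimensionless_kratky, guinier_rg, model_pr)
from ionsaxs.structures import Atom, AtomicModel


def ideal_guinier(rg, i0=100.0, qmax=0.3, n=300, q0=0.002):
    q = np.linspace(q0, qmax, n)
    I = i0 * np.exp(-(q * rg) ** 2 / 3.0)
    return ScatteringProfile(q, I, np.full(n, i0 * 1e-3))


class TestGuinier:
    def test_recovers_generating_rg_exactly(self):
        res = guinier_rg(ideal_guinier(20.0))
        assert res.rg == pytest.approx(20.0, rel=1e-4)
        assert res.rg_err < 1e-6
        assert res.i0 == pytest.approx(100.0, rel=1e-6)

    def test_solid_sphere_point_cloud(self):
        # uniform ball of radius R has Rg = sqrt(3/5) R
        rng = np.random.default_rng(2)
        R = 30.0
        pts = rng.uniform(-R, R, size=(12000, 3))
        pts = pts[np.linalg.norm(pts, axis=1) <= R][:2000]
        q = np.linspace(0.002, 0.05, 40)
        I = debye_from_factors(pts, np.ones((pts.shape[0], q.size)), q)
        prof = ScatteringProfile(q, I, 1e-4 * I)
        # a tight window limits the systematic Guinier bias of a sharp sphere
        res = guinier_rg(prof, qmax_rg=1.0)
        assert res.rg == pytest.approx(np.sqrt(3.0 / 5.0) * R, rel=0.02)

    def test_window_respects_q_rg_limit(self):
        res = guinier_rg(ideal_guinier(25.0), qmax_rg=1.3)
        assert res.q_rg_max <= 1.3 + 1e-9

    def test_error_when_lowest_q_already_beyond_window(self):
        prof = ideal_guinier(20.0, q0=0.08)  # q0 * 20 = 1.6 > 1.3
        with pytest.raises(GuinierError):
            guinier_rg(prof)

    def test_error_on_rising_low_q(self):
        q = np.linspace(0.002, 0.1, 50)
        I = 10.0 * (1 + (q * 20) ** 2)  # positive slope in ln I vs q^2
        with pytest.raises(GuinierError):
            guinier_rg(ScatteringProfile(q, I, 0.01 * I))


class TestKratky:
    def test_globular_guidelines(self):
        curve = dimensionless_kratky(ideal_guinier(20.0, qmax=0.25))
        assert curve.peak_x == pytest.approx(np.sqrt(3.0), rel=1e-3)
        assert curve.peak_y == pytest.approx(3.0 / np.e, rel=1e-3)

    def test_zero_at_origin(self):
        q = np.linspace(0.0, 0.2, 100)
        I = 50 * np.exp(-(q * 18) ** 2 / 3)
        prof = ScatteringProfile(q, I, np.full(q.size, 0.05))
        curve = dimensionless_kratky(prof)
        assert curve.y[0] == 0.0

    def test_invariant_to_intensity_scaling(self):
        prof = ideal_guinier(22.0)
        c1 = dimensionless_kratky(prof)
        scaled = ScatteringProfile(prof.q, 123.0 * prof.I, 123.0 * prof.sigma)
        c2 = dimensionless_kratky(scaled)
        assert np.allclose(c1.y, c2.y, rtol=1e-12)
        assert c1.peak_y == pytest.approx(c2.peak_y, rel=1e-12)


class TestPairDistribution:
    def test_two_atoms_single_peak(self):
        atoms = [Atom(element="C", position=np.array([0.0, 0, 0])),
                 Atom(element="C", position=np.array([10.0, 0, 0]))]
        pr = model_pr(AtomicModel(atoms), bin_width=0.5)
        peak_bin = np.argmax(pr.p)
        assert pr.r[peak_bin] == pytest.approx(10.0, abs=0.25)
        assert pr.d_max == pytest.approx(10.0)
        assert np.count_nonzero(pr.p) == 1

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        elements = rng.choice(["C", "N", "O", "P"], size=50)
        pos = rng.uniform(-20, 20, size=(50, 3))
        model = AtomicModel([Atom(element=e, position=p)
                             for e, p in zip(elements, pos)])
        pr = model_pr(model, bin_width=1.0)
        # direct O(N^2) histogram with the same f(0) weights
        from ionsaxs.elements import vacuum_form_factor
        f0 = np.array([vacuum_form_factor(e, np.array([0.0]))[0]
                       for e in elements])
        expected = np.zeros_like(pr.p)
        for i in range(50):
            for j in range(i + 1, 50):
                d = np.linalg.norm(pos[i] - pos[j])
                b = min(int(d // 1.0), expected.size - 1)
                expected[b] += 2 * f0[i] * f0[j]
        assert np.allclose(pr.p, expected, rtol=1e-10)
        # total weight: (sum f)^2 minus self terms
        assert pr.p.sum() == pytest.approx(f0.sum() ** 2 - (f0 ** 2).sum(), rel=1e-12)

    def test_dmax_is_maximum_pairwise_distance(self, helix):
        from scipy.spatial.distance import pdist
        pr = model_pr(helix)
        assert pr.d_max == pytest.approx(pdist(helix.positions).max())
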