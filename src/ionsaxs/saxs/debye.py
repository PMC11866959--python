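"""Debye-formula intensity calculation.

The orientationally averaged intensity of a rigid particle is the double sum

    I(q) = sum_i sum_j f_i(q) f_j(q) sin(q d_ij) / (q d_ij)

over atom pairs, with d_ij the inter-atomic distance and the i = j and
q -> 0 limits of the sinc kernel equal to 1.  For fitting with adjustable
(c1, c2) the intensity decomposes exactly into six partial intensities
(vacuum/dummy/hydration auto- and cross-terms), so a parameter scan costs
O(S) per point instead of a fresh O(N^2 S) double sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from ..structures import AtomicModel, AtomRole
from .formfactors import (component_matrices, excluded_volume_adjustment,
                          mean_dummy_radius, validate_c1c2)
from .profile import ScatteringProfile

__all__ = ["debye_intensity", "debye_from_factors", "compute_partials",
           "PartialIntensities", "effective_factor_matrix"]

_PAIR_CHUNK = 8192


def _sinc(qd: np.ndarray) -> np.ndarray:
    """sin(x)/x with the x -> 0 limit taken as 1."""
    return np.sinc(qd / np.pi)


def _scattering_atoms(model: AtomicModel) -> AtomicModel:
    """Solute atoms only: waters and probe pseudo-atoms never scatter here."""
    roles = {a.role for a in model.atoms}
    if roles & {AtomRole.WATER, AtomRole.PROBE}:
        return model.with_role(AtomRole.RNA, AtomRole.MG)
    return model


def debye_from_factors(positions: np.ndarray, factors: np.ndarray,
                       q: np.ndarray) -> np.ndarray:
    """Debye double sum for explicit per-atom factors (N x S) and positions."""
    positions = np.asarray(positions, dtype=float)
    factors = np.asarray(factors, dtype=float)
    q = np.asarray(q, dtype=float)
    n = positions.shape[0]
    intensity = (factors ** 2).sum(axis=0)  # i = j terms, sinc = 1
    if n == 1:
        return intensity
    d = pdist(positions)
    iu, ju = np.triu_indices(n, k=1)
    for start in range(0, d.size, _PAIR_CHUNK):
        sl = slice(start, start + _PAIR_CHUNK)
        sinc = _sinc(d[sl, None] * q[None, :])
        intensity = intensity + 2.0 * np.einsum(
            "ps,ps->s", factors[iu[sl]] * factors[ju[sl]], sinc)
    return intensity


def effective_factor_matrix(model: AtomicModel, q: np.ndarray, c1: float = 1.0,
                            c2: float = 1.0) -> np.ndarray:
    """Per-atom effective form factors (N x S) at fixed c1, c2."""
    validate_c1c2(c1, c2)
    A, B, W = component_matrices(model, q)
    g = excluded_volume_adjustment(np.asarray(q, dtype=float), c1,
                                   mean_dummy_radius(model))
    return A - g[None, :] * B + c2 * W


def debye_intensity(model: AtomicModel, q: np.ndarray, c1: float = 1.0,
                    c2: float = 1.0) -> ScatteringProfile:
    """Theoretical profile of a model by the Debye formula.

    Hydration contributes only through atoms with assigned solvent
    accessibility (see :func:`ionsaxs.structures.assign_accessibility`).
    """
    solute = _scattering_atoms(model)
    q = np.asarray(q, dtype=float)
    F = effective_factor_matrix(solute, q, c1, c2)
    return ScatteringProfile(q, debye_from_factors(solute.positions, F, q))


@dataclass(frozen=True)
class PartialIntensities:
    """Six-term decomposition of I(q, c1, c2) for fast parameter scans.

    With per-atom components A (vacuum), B (dummy) and W (hydration) the
    effective factor is f = A - g(q,c1) B + c2 W, so

        I = I_AA + g^2 I_BB + c2^2 I_WW - 2 g I_AB + 2 c2 I_AW - 2 g c2 I_BW.
    """

    q: np.ndarray
    I_AA: np.ndarray
    I_BB: np.ndarray
    I_WW: np.ndarray
    I_AB: np.ndarray
    I_AW: np.ndarray
    I_BW: np.ndarray
    r_m: float

    def evaluate(self, c1: float = 1.0, c2: float = 1.0) -> ScatteringProfile:
        validate_c1c2(c1, c2)
        g = excluded_volume_adjustment(self.q, c1, self.r_m)
        I = (self.I_AA + g ** 2 * self.I_BB + c2 ** 2 * self.I_WW
             - 2.0 * g * self.I_AB + 2.0 * c2 * self.I_AW
             - 2.0 * g * c2 * self.I_BW)
        return ScatteringProfile(self.q, I)


def compute_partials(model: AtomicModel, q: np.ndarray) -> PartialIntensities:
    """Precompute the six partial intensities of a model on a q grid."""
    solute = _scattering_atoms(model)
    q = np.asarray(q, dtype=float)
    A, B, W = component_matrices(solute, q)
    pos = solute.positions
    n = pos.shape[0]

    combos = [("AA", A, A), ("BB", B, B), ("WW", W, W),
              ("AB", A, B), ("AW", A, W), ("BW", B, W)]
    totals = {name: (X * Y).sum(axis=0) for name, X, Y in combos}  # diagonal
    if n > 1:
        d = pdist(pos)
        iu, ju = np.triu_indices(n, k=1)
        for start in range(0, d.size, _PAIR_CHUNK):
            sl = slice(start, start + _PAIR_CHUNK)
            sinc = _sinc(d[sl, None] * q[None, :])
            i, j = iu[sl], ju[sl]
            for name, X, Y in combos:
                cross = X[i] * Y[j] + X[j] * Y[i]
                totals[name] = totals[name] + np.einsum("ps,ps->s", cross, sinc)
    return PartialIntensities(q=q, I_AA=totals["AA"], I_BB=totals["BB"],
                              I_WW=totals["WW"], I_AB=totals["AB"],
                              I_AW=totals["AW"], I_BW=totals["BW"],
                              r_m=mean_dummy_radius(solute))
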