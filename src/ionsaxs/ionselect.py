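"""Selecting the Mg2+ subset that best fits an experimental profile.

Recomputing a full Debye sum for every candidate ion subset would cost
O(N^2 S) per subset.  Instead the intensity of RNA plus any ion subset A
decomposes exactly as

    I(A) = I_rna + sum_{k in A} (I_kk + X_k) + sum_{k<l in A} C_kl

with X_k the RNA-ion cross term and C_kl the ion-ion cross terms, all
precomputed once.  Assembling a subset profile is then independent of RNA
size, and subsets are enumerated with a branch-and-bound beam search that
stops when adding another ion no longer improves chi^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .beam import BeamLevel, beam_subsets
from .elements import dummy_form_factor, vacuum_form_factor
from .saxs.debye import _scattering_atoms, _sinc, effective_factor_matrix
from .saxs.fitting import FitResult, fit_chi2
from .saxs.formfactors import (excluded_volume_adjustment, mean_dummy_radius,
                               validate_c1c2)
from .saxs.profile import ProfileError, ScatteringProfile

__all__ = ["SubprofileCache", "SelectionConfig", "IonSelectionResult",
           "precompute", "assemble", "branch_and_bound"]

#: Candidates closer than this to an RNA atom are rejected, Angstrom.
_MIN_CANDIDATE_DISTANCE = 1.0


@dataclass(frozen=True)
class SubprofileCache:
    """Decomposed partial intensities for O(1)-per-ion profile assembly."""

    q: np.ndarray                 # (S,)
    I_rna: np.ndarray             # (S,) RNA-only intensity
    I_self: np.ndarray            # (S,) per-ion self term f_mg(q)^2
    X: np.ndarray                 # (M, S) RNA-ion cross terms
    C: np.ndarray                 # (M, M, S) ion-ion cross terms, zero diagonal
    positions: np.ndarray         # (M, 3) kept candidate positions
    kept_indices: np.ndarray      # (M,) indices into the original candidate list
    c1: float = 1.0
    c2: float = 1.0

    @property
    def n_candidates(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class SelectionConfig:
    """Beam width K, ion cap, and the fixed c1/c2 policy."""

    K: int | None = 50            # None = exhaustive
    max_ions: int | None = None   # None = min(M, 30)
    c1: float = 1.0
    c2: float = 1.0

    def __post_init__(self):
        if self.K is not None and self.K < 1:
            raise ValueError("K must be at least 1")
        if self.max_ions is not None and self.max_ions < 0:
            raise ValueError("max_ions must be non-negative")


@dataclass(frozen=True)
class IonSelectionResult:
    """Best ion subset, its fit, and the best-chi^2-per-level trajectory."""

    subset: tuple[int, ...]       # indices into the cache's candidate list
    fit: FitResult
    trajectory: list[BeamLevel]   # level 0 = RNA only

    def manifest(self) -> str:
        lines = ["# level\tchi2\tsubset"]
        for lv in self.trajectory:
            lines.append(f"{lv.size}\t{lv.score:.6f}\t"
                         + (",".join(map(str, lv.subset)) or "-"))
        return "\n".join(lines)


def precompute(rna, candidates, q_grid, c1: float = 1.0,
               c2: float = 1.0) -> SubprofileCache:
    """Build the subprofile cache for an RNA model and candidate ion sites.

    Candidates within 1 A of an RNA atom are rejected with a warning.  Ions
    scatter with the Mg form factor and no hydration term; the
    excluded-volume adjustment uses the RNA's mean dummy radius so that the
    decomposition is exact under the fixed-c1 policy.
    """
    cand = np.atleast_2d(np.asarray(candidates, dtype=float))
    if cand.size == 0:
        raise ValueError("candidate list must be non-empty")
    validate_c1c2(c1, c2)
    q = np.asarray(q_grid, dtype=float)
    solute = _scattering_atoms(rna)
    pos = solute.positions

    dmin = cdist(cand, pos).min(axis=1)
    bad = dmin < _MIN_CANDIDATE_DISTANCE
    if bad.any():
        warnings.warn(f"rejecting {int(bad.sum())} candidate(s) closer than "
                      f"{_MIN_CANDIDATE_DISTANCE} A to an RNA atom")
    kept = np.flatnonzero(~bad)
    cand = cand[kept]
    m = cand.shape[0]

    F = effective_factor_matrix(solute, q, c1, c2)
    g = excluded_volume_adjustment(q, c1, mean_dummy_radius(solute))
    f_mg = vacuum_form_factor("MG", q) - g * dummy_form_factor("MG", q)

    # RNA-only intensity from the same factor matrix
    from .saxs.debye import debye_from_factors
    I_rna = debye_from_factors(pos, F, q)

    I_self = f_mg ** 2
    X = np.empty((m, q.size))
    for k in range(m):
        d = np.linalg.norm(pos - cand[k][None, :], axis=1)
        sinc = _sinc(d[:, None] * q[None, :])
        X[k] = 2.0 * f_mg * (F * sinc).sum(axis=0)

    C = np.zeros((m, m, q.size))
    if m > 1:
        dmat = squareform(pdist(cand))
        iu, ju = np.triu_indices(m, k=1)
        vals = 2.0 * I_self[None, :] * _sinc(dmat[iu, ju][:, None] * q[None, :])
        C[iu, ju] = vals
        C[ju, iu] = vals

    return SubprofileCache(q=q, I_rna=I_rna, I_self=I_self, X=X, C=C,
                           positions=cand, kept_indices=kept, c1=c1, c2=c2)


def _assemble_intensity(cache: SubprofileCache, subset) -> np.ndarray:
    idx = list(subset)
    if len(set(idx)) != len(idx):
        raise ValueError("duplicate candidate index in subset")
    if idx and (min(idx) < 0 or max(idx) >= cache.n_candidates):
        raise IndexError("candidate index out of range")
    I = cache.I_rna.copy()
    if idx:
        I += len(idx) * cache.I_self + cache.X[idx].sum(axis=0)
        I += 0.5 * cache.C[np.ix_(idx, idx)].sum(axis=(0, 1))
    return I


def assemble(cache: SubprofileCache, subset) -> ScatteringProfile:
    """Profile of RNA plus the given ion subset, from the cache alone.

    Exactly equals the direct Debye intensity of the combined model;
    permutation-invariant in the subset; cost independent of RNA size.
    """
    return ScatteringProfile(cache.q, _assemble_intensity(cache, subset))


def branch_and_bound(exp: ScatteringProfile, cache: SubprofileCache,
                     config: SelectionConfig | None = None) -> IonSelectionResult:
    """Find the ion subset minimizing chi^2 against an experimental profile.

    Level n keeps the K best subsets of size n and extends each by one
    unused candidate; the search stops when the best chi^2 stops improving
    or the ion cap is reached.  The trajectory starts at the RNA-only fit
    (level 0) and is non-increasing by construction.
    """
    config = config or SelectionConfig()
    if exp.sigma is None:
        raise ProfileError("experimental profile must carry errors")
    if exp.q.shape != cache.q.shape or not np.allclose(exp.q, cache.q):
        raise ProfileError("experimental profile and cache must share a q grid")

    w = 1.0 / exp.sigma ** 2

    def chi2_of(I_calc: np.ndarray) -> float:
        denom = float(np.sum(w * I_calc ** 2))
        c = float(np.sum(w * exp.I * I_calc) / denom)
        return float(np.mean(((exp.I - c * I_calc) / exp.sigma) ** 2))

    memo: dict[tuple[int, ...], np.ndarray] = {(): cache.I_rna}
    pending: dict[tuple[int, ...], np.ndarray] = {}

    def score(child: tuple[int, ...], parent: tuple[int, ...]) -> float:
        (k,) = set(child) - set(parent)
        I = memo[parent] + cache.I_self + cache.X[k]
        if parent:
            I = I + cache.C[k, list(parent)].sum(axis=0)
        pending[child] = I
        return chi2_of(I)

    def on_level(kept):
        nonlocal memo, pending
        memo = {s: pending[s] for s in kept}
        pending = {}

    m = cache.n_candidates
    max_ions = config.max_ions if config.max_ions is not None else min(m, 30)
    empty_chi2 = chi2_of(cache.I_rna)
    if m == 0 or max_ions == 0:
        c = optimal_c(exp, cache.I_rna)
        fit = FitResult(chi2=empty_chi2, c=c, c1=cache.c1, c2=cache.c2)
        return IonSelectionResult(subset=(), fit=fit,
                                  trajectory=[BeamLevel(0, (), empty_chi2)])

    subset, best_chi2, levels = beam_subsets(
        m, score, K=config.K, max_size=max_ions, stop_when_worse=True,
        empty_score=empty_chi2, on_level=on_level)

    I_best = _assemble_intensity(cache, subset)
    fit = fit_chi2(ScatteringProfile(exp.q, exp.I, exp.sigma),
                   ScatteringProfile(cache.q, I_best))
    fit = FitResult(chi2=fit.chi2, c=fit.c, c1=cache.c1, c2=cache.c2)
    return IonSelectionResult(subset=subset, fit=fit, trajectory=levels)


def optimal_c(exp: ScatteringProfile, I_calc: np.ndarray) -> float:
    w = 1.0 / exp.sigma ** 2
    return float(np.sum(w * exp.I * I_calc) / np.sum(w * I_calc ** 2))
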