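"""Multistate ensemble fitting: conformer subsets with optimal weights.

A flexible RNA in solution is rarely a single conformation; the measured
profile is then a weighted average over states.  Given a pool of computed
conformer profiles, the weights minimizing chi^2 are found by non-negative
least squares on the sigma-normalized design matrix (convex, deterministic),
and conformer subsets are enumerated with the same beam machinery as the
ion selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import nnls

from .beam import beam_subsets
from .saxs.fitting import FitResult
from .saxs.profile import ProfileError, ScatteringProfile

__all__ = ["MultistateModel", "fit_weights", "enumerate_states"]


@dataclass(frozen=True)
class MultistateModel:
    """A set of conformer indices with weights summing to 1, and its fit."""

    members: tuple[int, ...]
    weights: np.ndarray
    fit: FitResult

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if len(self.members) != w.size or len(set(self.members)) != w.size:
            raise ValueError("members must be distinct and match the weights")
        if np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        object.__setattr__(self, "weights", w)

    @property
    def n_states(self) -> int:
        return len(self.members)


def _stack_intensities(exp: ScatteringProfile,
                       profiles: Sequence[ScatteringProfile]) -> np.ndarray:
    cols = []
    for p in profiles:
        if p.q.shape == exp.q.shape and np.allclose(p.q, exp.q):
            cols.append(p.I)
        else:
            cols.append(p.interpolated(exp.q).I)
    return np.column_stack(cols)


def fit_weights(exp: ScatteringProfile,
                profiles: Sequence[ScatteringProfile],
                members: Sequence[int] | None = None) -> MultistateModel:
    """Optimal non-negative weights for a set of conformer profiles.

    Minimizes chi^2 of c * sum_m w_m I_m(q) via NNLS on sigma-weighted
    residuals; the overall scale c absorbs the solution norm so the
    returned weights sum to 1.  A single profile reduces exactly to the
    scalar chi^2 fit.
    """
    if exp.sigma is None:
        raise ProfileError("experimental profile must carry errors")
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one profile")
    members = tuple(members) if members is not None else tuple(range(len(profiles)))
    A = _stack_intensities(exp, profiles)
    if not A.any():
        raise ValueError("all profiles are identically zero")
    x, _ = nnls(A / exp.sigma[:, None], exp.I / exp.sigma)
    total = x.sum()
    if total <= 0:
        # NNLS can only return the zero vector if no profile correlates
        # positively with the data; report a uniform zero-scale fit.
        raise ValueError("no profile has positive overlap with the data")
    w = x / total
    I_mix = A @ x
    chi2 = float(np.mean(((exp.I - I_mix) / exp.sigma) ** 2))
    return MultistateModel(members=members, weights=w,
                           fit=FitResult(chi2=chi2, c=float(total)))


def enumerate_states(exp: ScatteringProfile,
                     profile_pool: Sequence[ScatteringProfile],
                     max_states: int = 4,
                     K: int | None = 50) -> dict[int, MultistateModel]:
    """Best multistate model for each state count 1..max_states.

    Branch-and-bound over conformer subsets with :func:`fit_weights` as the
    scorer.  Because weights may vanish, the optimal chi^2 is non-increasing
    in the state count (verified exactly for exhaustive K).
    """
    pool = list(profile_pool)
    if not pool:
        raise ValueError("empty profile pool")
    if max_states < 1 or max_states > len(pool):
        raise ValueError("max_states must lie in [1, pool size]")

    models: dict[tuple[int, ...], MultistateModel] = {}

    def score(child: tuple[int, ...], parent: tuple[int, ...]) -> float:
        m = fit_weights(exp, [pool[i] for i in child], members=child)
        models[child] = m
        return m.fit.chi2

    _, _, levels = beam_subsets(len(pool), score, K=K, max_size=max_states,
                                stop_when_worse=False)
    return {lv.size: models[lv.subset] for lv in levels}
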