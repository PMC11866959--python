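"""Chi-square fitting of computed profiles to experimental ones.

The goodness of fit is

    chi^2 = (1/S) * sum_i ((I_exp(q_i) - c * I(q_i, c1, c2)) / sigma(q_i))^2

with the scale factor c solved analytically by weighted least squares at
every evaluation, and (c1, c2) either fixed at 1.0 (the default, which
avoids overfitting the hydration layer) or optimized by a deterministic grid
search over their conventional bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .debye import PartialIntensities
from .formfactors import C1_BOUNDS, C2_BOUNDS
from .profile import ProfileError, ScatteringProfile

__all__ = ["FitResult", "fit_chi2", "optimal_scale", "write_fit"]

_C1_STEP = 0.005
_C2_STEP = 0.05


@dataclass(frozen=True)
class FitResult:
    """Best-fit chi^2 and the parameters that achieve it."""

    chi2: float
    c: float
    c1: float = 1.0
    c2: float = 1.0

    def __post_init__(self):
        if self.chi2 < 0:
            raise ValueError("chi2 must be non-negative")

    def summary(self) -> str:
        return (f"chi2 = {self.chi2:.4f}  c = {self.c:.6g}  "
                f"c1 = {self.c1:.3f}  c2 = {self.c2:.3f}")


def optimal_scale(I_exp: np.ndarray, I_calc: np.ndarray,
                  sigma: np.ndarray) -> float:
    """Analytic weighted-least-squares scale minimizing chi^2."""
    w = 1.0 / sigma ** 2
    denom = float(np.sum(w * I_calc ** 2))
    if denom == 0.0:
        raise ValueError("computed profile is identically zero")
    return float(np.sum(w * I_exp * I_calc) / denom)


def _chi2_at_scale(exp: ScatteringProfile, I_calc: np.ndarray) -> tuple[float, float]:
    c = optimal_scale(exp.I, I_calc, exp.sigma)
    chi2 = float(np.mean(((exp.I - c * I_calc) / exp.sigma) ** 2))
    return chi2, c

def _aligned_intensity(exp: ScatteringProfile, calc: ScatteringProfile) -> np.ndarray:
    if calc.S == exp.S and np.allclose(calc.q, exp.q):
        return calc.I
    return calc.interpolated(exp.q).I


def fit_chi2(exp: ScatteringProfile,
             calc: ScatteringProfile | PartialIntensities,
             optimize_c1c2: bool = False) -> FitResult:
    """Fit a computed profile to an experimental one.

    ``calc`` may be a plain profile (scale-only fit; c1 = c2 = 1 is implied)
    or a :class:`PartialIntensities` decomposition, which also enables the
    (c1, c2) grid search when ``optimize_c1c2`` is set.  The computed profile
    is evaluated or interpolated on the experimental grid.
    """
    if exp.sigma is None:
        raise ProfileError("the experimental profile must carry errors sigma(q)")

    if isinstance(calc, PartialIntensities):
        def intensity(c1, c2):
            prof = calc.evaluate(c1, c2)
            return _aligned_intensity(exp, prof)
    else:
        if optimize_c1c2:
            raise ValueError("optimizing c1/c2 needs a PartialIntensities "
                             "decomposition, not a single computed curve")
        def intensity(c1, c2):
            return _aligned_intensity(exp, calc)

    if not optimize_c1c2:
        chi2, c = _chi2_at_scale(exp, intensity(1.0, 1.0))
        return FitResult(chi2=chi2, c=c, c1=1.0, c2=1.0)

    c1_grid = np.round(np.arange(C1_BOUNDS[0], C1_BOUNDS[1] + _C1_STEP / 2, _C1_STEP), 6)
    c2_grid = np.round(np.arange(C2_BOUNDS[0], C2_BOUNDS[1] + _C2_STEP / 2, _C2_STEP), 6)
    best: FitResult | None = None
    for c1 in c1_grid:
        for c2 in c2_grid:
            chi2, c = _chi2_at_scale(exp, intensity(float(c1), float(c2)))
            if best is None or chi2 < best.chi2 - 1e-15:
                best = FitResult(chi2=chi2, c=c, c1=float(c1), c2=float(c2))
    return best


def write_fit(exp: ScatteringProfile, calc: ScatteringProfile, fit: FitResult,
              path) -> None:
    """4-column fit file (q, I_exp, sigma, c*I_model) with a summary header."""
    I_model = fit.c * _aligned_intensity(exp, calc)
    with open(path, "w") as fh:
        fh.write(f"# {fit.summary()}\n")
        fh.write("#      q            I_exp           sigma         c*I_model\n")
        for i in range(exp.S):
            fh.write(f"{exp.q[i]:.6e}  {exp.I[i]:.6e}  "
                     f"{exp.sigma[i]:.6e}  {I_model[i]:.6e}\n")
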