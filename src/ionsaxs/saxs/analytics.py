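"""Model-free and model-based SAXS analytics.

Guinier analysis fits ln I vs q^2 at low angle, where I(q) ~ I(0)
exp(-q^2 Rg^2 / 3); the fit window is iterated until q_max * Rg <= 1.3.
The dimensionless Kratky representation (q Rg)^2 I(q)/I(0) vs q Rg peaks at
(sqrt(3), 3/e) for an ideal globular (Guinier-like) particle.  The
pair-distance distribution P(r) is computed here from an atomic model, as a
weighted histogram of its interatomic distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from ..elements import vacuum_form_factor
from ..structures import AtomicModel
from .profile import ScatteringProfile

__all__ = ["GuinierResult", "GuinierError", "guinier_rg", "KratkyCurve",
           "dimensionless_kratky", "PairDistribution", "model_pr"]

_MIN_POINTS = 5


class GuinierError(ValueError):
    """Raised when no valid Guinier window exists."""


@dataclass(frozen=True)
class GuinierResult:
    rg: float          # radius of gyration, Angstrom
    rg_err: float      # standard error from the linear fit
    i0: float          # extrapolated forward intensity
    q_min: float
    q_max: float
    n_points: int

    @property
    def q_rg_max(self) -> float:
        return self.q_max * self.rg


def _linear_fit(x, y, w):
    """Weighted least squares y = a + b x; returns a, b, var(b)."""
    W = np.sum(w)
    xm = np.sum(w * x) / W
    ym = np.sum(w * y) / W
    sxx = np.sum(w * (x - xm) ** 2)
    if sxx == 0:
        raise GuinierError("degenerate q window")
    b = np.sum(w * (x - xm) * (y - ym)) / sxx
    a = ym - b * xm
    resid = y - (a + b * x)
    dof = max(x.size - 2, 1)
    var_b = np.sum(w * resid ** 2) / dof / sxx
    return a, b, var_b


def guinier_rg(exp: ScatteringProfile, qmax_rg: float = 1.3,
               max_iter: int = 30) -> GuinierResult:
    """Estimate Rg (and I(0)) from the low-q Guinier region.

    Starts from the lowest-q points and iterates the window until
    q_max * Rg <= qmax_rg is self-consistent.  Requires at least 5 usable
    points with positive intensity in the window.
    """
    pos = exp.I > 0
    q = exp.q[pos]
    I = exp.I[pos]
    sigma = exp.sigma[pos] if exp.sigma is not None else None
    if q.size < _MIN_POINTS:
        raise GuinierError("not enough positive-intensity points")

    # weights for ln I: var(ln I) ~ (sigma / I)^2
    w_all = (I / sigma) ** 2 if sigma is not None else np.ones_like(I)
    x_all = q ** 2
    y_all = np.log(I)

    n = min(q.size, max(_MIN_POINTS, 10))
    rg = None
    for _ in range(max_iter):
        x, y, w = x_all[:n], y_all[:n], w_all[:n]
        a, b, var_b = _linear_fit(x, y, w)
        if b >= 0:
            raise GuinierError("non-negative Guinier slope; Rg undefined")
        rg_new = float(np.sqrt(-3.0 * b))
        n_new = int(np.searchsorted(q, qmax_rg / rg_new, side="right"))
        if n_new < _MIN_POINTS:
            raise GuinierError(
                f"fewer than {_MIN_POINTS} points satisfy q*Rg <= {qmax_rg}")
        if n_new == n and rg is not None and abs(rg_new - rg) < 1e-12:
            break
        rg, n = rg_new, n_new
    else:
        rg_new = rg
    x, y, w = x_all[:n], y_all[:n], w_all[:n]
    a, b, var_b = _linear_fit(x, y, w)
    if b >= 0:
        raise GuinierError("non-negative Guinier slope; Rg undefined")
    rg = float(np.sqrt(-3.0 * b))
    rg_err = float(3.0 / (2.0 * rg) * np.sqrt(max(var_b, 0.0)))
    return GuinierResult(rg=rg, rg_err=rg_err, i0=float(np.exp(a)),
                         q_min=float(q[0]), q_max=float(q[n - 1]), n_points=n)


@dataclass(frozen=True)
class KratkyCurve:
    """Dimensionless Kratky curve (q Rg, (q Rg)^2 I / I(0)) with its peak."""

    x: np.ndarray       # q * Rg
    y: np.ndarray       # (q Rg)^2 I(q) / I(0)
    peak_x: float
    peak_y: float


def dimensionless_kratky(exp: ScatteringProfile, rg: float | None = None) -> KratkyCurve:
    """Normalized Kratky transform of a profile.

    I(0) is taken from the Guinier fit; for a globular particle the curve
    peaks near (sqrt(3) ~ 1.73, 3/e ~ 1.1).  The curve is invariant to any
    positive rescaling of the intensities.
    """
    gr = guinier_rg(exp)
    if rg is None:
        rg = gr.rg
    if rg <= 0:
        raise ValueError("rg must be positive")
    x = exp.q * rg
    y = x ** 2 * exp.I / gr.i0
    k = int(np.argmax(y))
    # parabolic refinement of the sampled peak
    if 0 < k < x.size - 1:
        x0, x1, x2 = x[k - 1:k + 2]
        y0, y1, y2 = y[k - 1:k + 2]
        denom = (y0 - 2 * y1 + y2)
        if denom != 0:
            dx = 0.5 * (y0 - y2) / denom
            peak_x = x1 + dx * (x2 - x1)
            peak_y = y1 - 0.25 * (y0 - y2) * dx
        else:
            peak_x, peak_y = x[k], y[k]
    else:
        peak_x, peak_y = x[k], y[k]
    return KratkyCurve(x=x, y=y, peak_x=float(peak_x), peak_y=float(peak_y))


@dataclass(frozen=True)
class PairDistribution:
    """P(r) histogram: bin centers r, weights p, and the maximum distance."""

    r: np.ndarray
    p: np.ndarray
    d_max: float


def model_pr(model: AtomicModel, bin_width: float = 0.5) -> PairDistribution:
    """Pair-distance distribution of an atomic model.

    Histogram of all interatomic distances weighted by f_i(0) * f_j(0)
    (each unordered pair counted twice); the total weight equals
    (sum_i f_i(0))^2 minus the self terms, and the support ends at the
    maximum pairwise distance D_max.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    f0 = np.array([float(vacuum_form_factor(el, np.array([0.0]))[0])
                   for el in model.elements])
    if len(model) == 1:
        return PairDistribution(r=np.array([0.0]), p=np.array([0.0]), d_max=0.0)
    d = pdist(model.positions)
    iu, ju = np.triu_indices(len(model), k=1)
    weights = 2.0 * f0[iu] * f0[ju]
    d_max = float(d.max())
    n_bins = max(1, int(np.ceil(d_max / bin_width)))
    hist, edges = np.histogram(d, bins=n_bins, range=(0.0, n_bins * bin_width),
                               weights=weights)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return PairDistribution(r=centers, p=hist, d_max=d_max)
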