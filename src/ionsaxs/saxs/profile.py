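"""Scattering profiles and 3-column text I/O.

A profile is the orientationally averaged intensity I(q) on a grid of
momentum transfer q = 4 pi sin(theta)/lambda (Angstrom^-1, with 2 theta the
scattering angle and lambda the X-ray wavelength).  Experimental profiles
carry per-point errors sigma(q); computed profiles do not.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["ScatteringProfile", "ProfileError", "read_profile", "write_profile",
           "default_q_grid"]


class ProfileError(ValueError):
    """Raised for malformed profiles (non-monotonic q, bad errors, ...)."""


def default_q_grid(q_max: float = 0.5, n_points: int = 501) -> np.ndarray:
    """The default computed-profile grid: 0 to q_max with n_points samples."""
    return np.linspace(0.0, q_max, n_points)


@dataclass(frozen=True)
class ScatteringProfile:
    """I(q) on a q grid, with experimental errors when measured."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        I = np.asarray(self.I, dtype=float)
        if q.ndim != 1 or q.shape != I.shape:
            raise ProfileError("q and I must be 1-d arrays of equal length")
        if q.size == 0:
            raise ProfileError("empty profile")
        if np.any(q < 0) or np.any(np.diff(q) <= 0):
            raise ProfileError("q must be non-negative and strictly increasing")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "I", I)
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            if s.shape != q.shape:
                raise ProfileError("sigma must match the q grid")
            if np.any(s <= 0):
                raise ProfileError("experimental errors must be positive")
            object.__setattr__(self, "sigma", s)

    @property
    def S(self) -> int:
        """Number of points."""
        return self.q.size

    @property
    def is_experimental(self) -> bool:
        return self.sigma is not None

    def interpolated(self, q_new: np.ndarray) -> "ScatteringProfile":
        """Linear interpolation onto a new grid (within the current range)."""
        q_new = np.asarray(q_new, dtype=float)
        if q_new.min() < self.q.min() - 1e-12 or q_new.max() > self.q.max() + 1e-12:
            raise ProfileError("interpolation target extends beyond the profile range")
        I = np.interp(q_new, self.q, self.I)
        sigma = np.interp(q_new, self.q, self.sigma) if self.sigma is not None else None
        return ScatteringProfile(q_new, I, sigma)


def read_profile(path) -> ScatteringProfile:
    """Read a whitespace-delimited SAXS text file (q, I[, sigma]).

    Lines starting with '#' are comments.  A missing third column yields a
    computed (error-free) profile.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                rows.append([float(x) for x in parts[:3]])
            except ValueError as exc:
                raise ProfileError(f"{path}: bad line {line!r}") from exc
    if not rows:
        raise ProfileError(f"{path}: no data rows")
    ncol = min(len(r) for r in rows)
    if ncol < 2:
        raise ProfileError(f"{path}: need at least q and I columns")
    data = np.array([r[:ncol] for r in rows])
    sigma = data[:, 2] if ncol >= 3 else None
    return ScatteringProfile(data[:, 0], data[:, 1], sigma)


def write_profile(profile: ScatteringProfile, path, header: str | None = None) -> None:
    """Write a profile as 3-column (or 2-column) text, q in Angstrom^-1."""
    buf = io.StringIO()
    if header:
        for line in header.splitlines():
            buf.write(f"# {line}\n")
    buf.write("#      q              I(q)" +
              ("             sigma\n" if profile.sigma is not None else "\n"))
    for i in range(profile.S):
        if profile.sigma is not None:
            buf.write(f"{profile.q[i]:.6e}  {profile.I[i]:.6e}  {profile.sigma[i]:.6e}\n")
        else:
            buf.write(f"{profile.q[i]:.6e}  {profile.I[i]:.6e}\n")
    Path(path).write_text(buf.getvalue())
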