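"""Per-element constants used by scattering and surface calculations.

Covers the element set relevant to RNA solutes plus magnesium: H, C, N, O, P, MG.
Water oxygens from input files are carried with the same O parameters.
"""

from __future__ import annotations

import numpy as np

#: Elements the package knows how to scatter from.
SUPPORTED_ELEMENTS = ("H", "C", "N", "O", "P", "MG")

#: Bondi van der Waals radii, Angstrom.
VDW_RADIUS = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "P": 1.80,
    "MG": 1.73,
}

#: Solvent-displaced atomic volumes, Angstrom^3 (Fraser/CRYSOL convention).
#: MG has no published Fraser value; a Bondi-radius sphere is used.
DISPLACED_VOLUME = {
    "H": 5.15,
    "C": 16.44,
    "N": 2.49,
    "O": 9.13,
    "P": 5.73,
    "MG": 4.0 / 3.0 * np.pi * 1.73 ** 3,
}

#: Electron counts (neutral atoms).
ELECTRON_COUNT = {"H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "MG": 12}

#: Mean electron density of bulk water, e/A^3.
WATER_DENSITY = 0.334

# Cromer-Mann coefficients (a1..a4, b1..b4, c), International Tables vol. C.
# f0(q) = sum_k a_k exp(-b_k (q/4pi)^2) + c, with q = 4 pi sin(theta)/lambda.
_CROMER_MANN = {
    "H": ([0.489918, 0.262003, 0.196767, 0.049879],
          [20.6593, 7.74039, 49.5519, 2.20159], 0.001305),
    "C": ([2.31000, 1.02000, 1.58860, 0.865000],
          [20.8439, 10.2075, 0.568700, 51.6512], 0.215600),
    "N": ([12.2126, 3.13220, 2.01250, 1.16630],
          [0.005700, 9.89330, 28.9975, 0.582600], -11.529),
    "O": ([3.04850, 2.28680, 1.54630, 0.867000],
          [13.2771, 5.70110, 0.323900, 32.9089], 0.250800),
    "P": ([6.43450, 4.17910, 1.78000, 1.49080],
          [1.90670, 27.1570, 0.526000, 68.1645], 1.11490),
    "MG": ([5.42042, 2.17349, 1.22693, 2.30730],
           [2.82751, 79.2611, 0.380754, 7.19370], 0.858584),
}


def vacuum_form_factor(element: str, q: np.ndarray) -> np.ndarray:
    """Cromer-Mann vacuum form factor f_v(q) for one element.

    f_v(0) equals the element's electron count to the precision of the
    published coefficients (~1e-2 e).
    """
    try:
        a, b, c = _CROMER_MANN[element]
    except KeyError:
        raise KeyError(f"no form factor for element {element!r}") from None
    q = np.asarray(q, dtype=float)
    s2 = (q / (4.0 * np.pi)) ** 2  # (sin(theta)/lambda)^2
    f = np.full_like(q, c, dtype=float)
    for ak, bk in zip(a, b):
        f += ak * np.exp(-bk * s2)
    return f


def dummy_form_factor(element: str, q: np.ndarray) -> np.ndarray:
    """Excluded-volume (dummy solvent) form factor f_s(q).

    Gaussian sphere of the element's displaced volume at bulk water density:
    f_s(q) = rho_w * V * exp(-q^2 V^(2/3) / (4 pi)).
    """
    v = DISPLACED_VOLUME[element]
    q = np.asarray(q, dtype=float)
    return WATER_DENSITY * v * np.exp(-(q ** 2) * v ** (2.0 / 3.0) / (4.0 * np.pi))


def water_form_factor(q: np.ndarray) -> np.ndarray:
    """Composite water form factor f_w(q) = f_O(q) + 2 f_H(q) (vacuum)."""
    return vacuum_form_factor("O", q) + 2.0 * vacuum_form_factor("H", q)


def dummy_radius(element: str) -> float:
    """Radius of the Gaussian dummy sphere, (3V/4pi)^(1/3), Angstrom."""
    return float((3.0 * DISPLACED_VOLUME[element] / (4.0 * np.pi)) ** (1.0 / 3.0))
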