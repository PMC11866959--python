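"""Per-atom effective form factors in solution.

The in-solution form factor of atom i combines three contributions:

    f_i(q) = f_v(q) - g(q, c1) * f_s(q) + c2 * s_i * f_w(q)

with f_v the vacuum (Cromer-Mann) factor, f_s the dummy-solvent factor of the
displaced volume, f_w the water factor, s_i the atom's fractional solvent
accessibility, and g the excluded-volume adjustment

    g(q, c1) = c1^3 * exp(-(4 pi / 3)^(3/2) * r_m^2 * (c1^2 - 1) * q^2 / (4 pi))

where r_m is the mean dummy-atom radius of the model.  c1 scales the excluded
volume (conventional bounds [0.95, 1.05]); c2 scales the hydration-layer
density (bounds [-2, 4]; negative values model a depleted shell).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..elements import (SUPPORTED_ELEMENTS, dummy_form_factor, dummy_radius,
                        vacuum_form_factor, water_form_factor)
from ..structures import Atom, AtomicModel

__all__ = ["C1_BOUNDS", "C2_BOUNDS", "FormFactorTable", "effective_form_factor",
           "excluded_volume_adjustment", "validate_c1c2"]

C1_BOUNDS = (0.95, 1.05)
C2_BOUNDS = (-2.0, 4.0)


def validate_c1c2(c1: float, c2: float) -> None:
    if not C1_BOUNDS[0] <= c1 <= C1_BOUNDS[1]:
        raise ValueError(f"c1={c1} outside bounds {C1_BOUNDS}")
    if not C2_BOUNDS[0] <= c2 <= C2_BOUNDS[1]:
        raise ValueError(f"c2={c2} outside bounds {C2_BOUNDS}")


@dataclass(frozen=True)
class FormFactorTable:
    """Vacuum, dummy-solvent and water form factors tabulated on a q grid."""

    q: np.ndarray
    vacuum: dict  # element -> f_v(q)
    dummy: dict   # element -> f_s(q)
    water: np.ndarray

    @classmethod
    def on_grid(cls, q: np.ndarray) -> "FormFactorTable":
        q = np.asarray(q, dtype=float)
        return cls(
            q=q,
            vacuum={el: vacuum_form_factor(el, q) for el in SUPPORTED_ELEMENTS},
            dummy={el: dummy_form_factor(el, q) for el in SUPPORTED_ELEMENTS},
            water=water_form_factor(q),
        )


def excluded_volume_adjustment(q: np.ndarray, c1: float, r_m: float) -> np.ndarray:
    """g(q, c1): q-dependent scaling of the dummy-solvent term."""
    q = np.asarray(q, dtype=float)
    if c1 == 1.0:
        return np.ones_like(q)
    coef = (4.0 * np.pi / 3.0) ** 1.5 * r_m ** 2 * (c1 ** 2 - 1.0) / (4.0 * np.pi)
    return c1 ** 3 * np.exp(-coef * q ** 2)


def mean_dummy_radius(model: AtomicModel) -> float:
    return float(np.mean([dummy_radius(el) for el in model.elements]))


def effective_form_factor(atom: Atom, q_grid: np.ndarray, c1: float = 1.0,
                          c2: float = 0.0, r_m: float | None = None) -> np.ndarray:
    """The solution form factor of one atom on a q grid.

    ``r_m`` defaults to the atom's own dummy radius; pass the model mean when
    evaluating atoms in context.
    """
    validate_c1c2(c1, c2)
    q = np.asarray(q_grid, dtype=float)
    if r_m is None:
        r_m = dummy_radius(atom.element)
    f = vacuum_form_factor(atom.element, q)
    f = f - excluded_volume_adjustment(q, c1, r_m) * dummy_form_factor(atom.element, q)
    if c2 != 0.0 and atom.solvent_accessibility > 0.0:
        f = f + c2 * atom.solvent_accessibility * water_form_factor(q)
    return f


def component_matrices(model: AtomicModel, q: np.ndarray):
    """Per-atom component factors (N x S each): vacuum A, dummy B, hydration W.

    The effective factor of atom i is A_i - g(q,c1) B_i + c2 W_i, where
    W_i = s_i * f_w(q).  Used by the partial-intensity decomposition.
    """
    q = np.asarray(q, dtype=float)
    table = FormFactorTable.on_grid(q)
    elements = model.elements
    A = np.stack([table.vacuum[el] for el in elements])
    B = np.stack([table.dummy[el] for el in elements])
    s = model.accessibilities
    W = s[:, None] * table.water[None, :]
    return A, B, W
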