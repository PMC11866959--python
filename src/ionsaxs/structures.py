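"""Atomistic models: PDB I/O, atom roles, and solvent accessibility.

An :class:`AtomicModel` is an ordered list of atoms, each carrying element,
position, van der Waals radius, a solvent-accessibility fraction (the per-atom
weight of the hydration-layer scattering term) and a role that separates the
RNA solute from Mg ions, waters and surface probes.  PDB reading and writing
is done through gemmi; multi-MODEL files become an :class:`Ensemble`.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .elements import SUPPORTED_ELEMENTS, VDW_RADIUS

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRole",
    "Atom",
    "AtomicModel",
    "Ensemble",
    "PDBFormatError",
    "read_pdb",
    "write_pdb",
    "assign_accessibility",
    "fibonacci_sphere",
]


class PDBFormatError(ValueError):
    """Raised when a PDB file cannot be parsed or contains no usable atoms."""


class AtomRole(enum.Enum):
    RNA = "RNA"
    MG = "MG"
    WATER = "WATER"
    PROBE = "PROBE"


@dataclass(frozen=True)
class Atom:
    """A single atom with the attributes scattering and surface code need."""

    element: str
    position: np.ndarray  # shape (3,), Angstrom
    vdw_radius: float = 0.0
    solvent_accessibility: float = 0.0
    role: AtomRole = AtomRole.RNA
    name: str = ""
    resname: str = ""
    resseq: int = 1
    chain: str = "A"

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("atom position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if self.element not in SUPPORTED_ELEMENTS:
            raise ValueError(f"unsupported element {self.element!r}")
        radius = self.vdw_radius if self.vdw_radius > 0 else VDW_RADIUS[self.element]
        object.__setattr__(self, "vdw_radius", float(radius))
        if not 0.0 <= self.solvent_accessibility <= 1.0:
            raise ValueError("solvent_accessibility must lie in [0, 1]")


class AtomicModel:
    """An ordered collection of atoms with cached coordinate arrays."""

    def __init__(self, atoms: Sequence[Atom], label: str = ""):
        atoms = list(atoms)
        if not atoms:
            raise ValueError("an AtomicModel needs at least one atom")
        self.atoms: list[Atom] = atoms
        self.label = label

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms])

    @property
    def accessibilities(self) -> np.ndarray:
        return np.array([a.solvent_accessibility for a in self.atoms])

    def with_role(self, *roles: AtomRole) -> "AtomicModel":
        kept = [a for a in self.atoms if a.role in roles]
        if not kept:
            raise ValueError(f"no atoms with role in {roles}")
        return AtomicModel(kept, label=self.label)

    def scattering_model(self) -> "AtomicModel":
        """The solute used for profile calculation: RNA plus any bound ions.

        Crystallographic waters and probe pseudo-atoms are excluded.
        """
        return self.with_role(AtomRole.RNA, AtomRole.MG)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "AtomicModel":
        """A copy under a rigid motion (used heavily by invariance tests)."""
        pos = self.positions
        if rotation is not None:
            pos = pos @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            pos = pos + np.asarray(translation, dtype=float)
        atoms = [replace(a, position=p) for a, p in zip(self.atoms, pos)]
        return AtomicModel(atoms, label=self.label)

    def __repr__(self) -> str:
        return f"<AtomicModel {self.label!r}: {len(self)} atoms>"


@dataclass
class Ensemble:
    """Conformations of one molecule sharing atom count and ordering."""

    conformations: list[AtomicModel] = field(default_factory=list)

    def __post_init__(self):
        if not self.conformations:
            raise ValueError("an Ensemble needs at least one conformation")
        ref = self.conformations[0]
        for m in self.conformations[1:]:
            if len(m) != len(ref) or m.elements != ref.elements:
                raise ValueError("ensemble members must share atom count and ordering")

    def __len__(self) -> int:
        return len(self.conformations)

    def __iter__(self):
        return iter(self.conformations)

    def __getitem__(self, i) -> AtomicModel:
        return self.conformations[i]


# ---------------------------------------------------------------------------
# PDB I/O

_WATER_RESNAMES = {"HOH", "WAT", "H2O", "DOD"}


def _element_of(atom: gemmi.Atom, resname: str) -> str | None:
    el = atom.element.name.upper().strip()
    if not el or el == "X":
        # fall back to the first letter of the atom name
        el = "".join(c for c in atom.name if c.isalpha())[:1].upper()
    if el == "MG" or (resname.strip() == "MG"):
        return "MG"
    if el in SUPPORTED_ELEMENTS:
        return el
    return None


def read_pdb(path) -> AtomicModel | Ensemble:
    """Read a PDB file into an AtomicModel, or an Ensemble for multi-MODEL files.

    HETATM records for MG and waters are recognised and tagged with their
    roles; atoms of unsupported elements are skipped with a logged warning.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(f"cannot parse {path}: {exc}") from exc

    models = []
    for gm in st:
        atoms: list[Atom] = []
        for chain in gm:
            for res in chain:
                resname = res.name.strip()
                if resname in _WATER_RESNAMES:
                    role = AtomRole.WATER
                elif resname == "MG":
                    role = AtomRole.MG
                else:
                    role = AtomRole.RNA
                for ga in res:
                    el = _element_of(ga, resname)
                    if el is None:
                        logger.warning("skipping unsupported element %r (atom %s/%s)",
                                       ga.element.name, resname, ga.name)
                        continue
                    if el == "MG" and role is AtomRole.RNA:
                        role = AtomRole.MG
                    atoms.append(Atom(
                        element="O" if role is AtomRole.WATER and el == "O" else el,
                        position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        role=role,
                        name=ga.name,
                        resname=resname,
                        resseq=res.seqid.num,
                        chain=chain.name,
                    ))
        if atoms:
            models.append(AtomicModel(atoms, label=path.stem))
    if not models:
        raise PDBFormatError(f"{path}: no usable atoms")
    if len(models) == 1:
        return models[0]
    return Ensemble(models)


def write_pdb(model: AtomicModel, ions: Iterable[np.ndarray] | None, path) -> None:
    """Write a model plus optional Mg ion positions as a PDB file.

    Ions become ``HETATM`` MG records (occupancy 1.00) appended after the
    model's own atoms; the output reads back with :func:`read_pdb`.
    """
    ions = [np.asarray(p, dtype=float) for p in (ions or [])]
    for p in ions:
        if p.shape != (3,) or not np.all(np.isfinite(p)):
            raise ValueError("ion coordinates must be finite 3-vectors")

    st = gemmi.Structure()
    st.name = model.label or "model"
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for i, a in enumerate(model.atoms):
        ch = chains.setdefault(a.chain, gemmi.Chain(a.chain))
        res = gemmi.Residue()
        res.name = a.resname or ("HOH" if a.role is AtomRole.WATER else "UNK")
        res.seqid = gemmi.SeqId(a.resseq, " ")
        res.het_flag = "H" if a.role in (AtomRole.MG, AtomRole.WATER, AtomRole.PROBE) else "A"
        ga = gemmi.Atom()
        ga.name = a.name or a.element
        ga.element = gemmi.Element(a.element)
        ga.pos = gemmi.Position(*a.position)
        ga.occ = 1.0
        res.add_atom(ga)
        # merge consecutive atoms of the same residue
        if (len(ch) and ch[-1].name == res.name and ch[-1].seqid.num == res.seqid.num):
            ch[-1].add_atom(ga)
        else:
            ch.add_residue(res)
    ion_chain = chains.setdefault("M", gemmi.Chain("M"))
    for k, p in enumerate(ions, start=1):
        res = gemmi.Residue()
        res.name = "MG"
        res.seqid = gemmi.SeqId(9000 + k, " ")
        res.het_flag = "H"
        ga = gemmi.Atom()
        ga.name = "MG"
        ga.element = gemmi.Element("MG")
        ga.pos = gemmi.Position(*p)
        ga.occ = 1.0
        res.add_atom(ga)
        ion_chain.add_residue(res)
    for ch in chains.values():
        if len(ch):
            gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except OSError as exc:
        raise OSError(f"cannot write PDB to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Solvent accessibility (Shrake-Rupley dot sampling)

def fibonacci_sphere(n: int) -> np.ndarray:
    """A deterministic, nearly uniform set of n unit vectors (golden spiral)."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _principal_frame(positions: np.ndarray) -> np.ndarray:
    """A rotation matrix aligning the dot sphere with the molecule.

    Principal axes of the coordinate covariance, signs fixed by the third
    moment along each axis, handedness enforced.  Because the frame
    co-rotates with the molecule, dot-sampled quantities become invariant
    under rigid motions of the model.
    """
    centered = positions - positions.mean(axis=0)
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    for k in range(3):
        skew = np.sum((centered @ vecs[:, k]) ** 3)
        if skew < 0:
            vecs[:, k] = -vecs[:, k]
    if np.linalg.det(vecs) < 0:
        vecs[:, 0] = -vecs[:, 0]
    return vecs


def assign_accessibility(model: AtomicModel, probe_radius: float = 1.4,
                         n_dots: int = 100) -> AtomicModel:
    """Assign each atom a solvent-accessibility fraction in [0, 1].

    Shrake-Rupley dot sampling: each atom's extended sphere (vdW radius +
    probe radius) is covered with a fixed deterministic point set and the
    fraction of dots outside every other atom's extended sphere is the
    accessibility.  The point set is oriented in the molecule's principal
    frame, so the result is invariant under rigid motion of the model.
    An isolated atom gets 1 by construction.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    pos = model.positions
    radii = model.vdw_radii + probe_radius
    n = len(model)
    if n == 1:
        return AtomicModel([replace(model.atoms[0], solvent_accessibility=1.0)],
                           label=model.label)

    sphere = fibonacci_sphere(n_dots) @ _principal_frame(pos).T
    tree = cKDTree(pos)
    max_r = radii.max()
    fractions = np.empty(n)
    for i in range(n):
        dots = pos[i] + radii[i] * sphere
        # neighbours whose extended sphere could cover any dot of atom i
        nbr = [j for j in tree.query_ball_point(pos[i], radii[i] + max_r) if j != i]
        if not nbr:
            fractions[i] = 1.0
            continue
        d2 = ((dots[:, None, :] - pos[nbr][None, :, :]) ** 2).sum(axis=2)
        covered = (d2 < (radii[nbr] ** 2)[None, :]).any(axis=1)
        fractions[i] = 1.0 - covered.mean()
    atoms = [replace(a, solvent_accessibility=float(f))
             for a, f in zip(model.atoms, fractions)]
    return AtomicModel(atoms, label=model.label)
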