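"""Synthetic fixtures: toy RNA helices, perturbed ensembles, noisy profiles
and labeled classifier neighborhoods.

These generators stand in for the external parts of a real study — a
predicted starting structure, a kinematics-based conformational sampler,
SEC-SAXS error bars, and a curated corpus of Mg2+ / water coordination
shells — at scattering-level rather than chemical realism.  Everything is
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .probes import NEIGHBORHOOD_RADIUS, NeighborhoodGraph, build_neighborhood_graph
from .saxs.debye import debye_intensity
from .saxs.profile import ScatteringProfile
from .structures import Atom, AtomicModel, AtomRole, Ensemble

__all__ = ["NoiseModel", "make_helix", "perturb_ensemble", "simulate_profile",
           "make_neighborhoods", "add_ions", "make_binding_pockets"]

# Per-nucleotide pseudo-atom template in cylindrical coordinates
# (radius A, angular offset deg, axial offset A): a phosphate, two backbone
# sugar carbons, a sugar oxygen, and two base atoms reaching the helix axis.
_NT_TEMPLATE = [
    ("P", 9.4, 0.0, 0.0),
    ("O", 8.8, 9.0, 0.6),
    ("C", 8.0, 18.0, 1.0),
    ("C", 6.2, 32.0, 1.3),
    ("N", 4.2, 46.0, 1.5),
    ("O", 2.8, 58.0, 1.7),
]
_RISE = 2.81     # axial rise per base pair, A
_TWIST = 32.7    # twist per base pair, deg


@dataclass(frozen=True)
class NoiseModel:
    """SEC-SAXS-like error model: sigma(q) = floor*I(q) + growth*I(0)*q/qmax.

    The defaults give ~1% relative error at low q growing toward high q.
    A zero model (floor = growth = 0) yields an exact profile with unit
    errors attached, so chi^2 against the truth is exactly 0.
    """

    relative_floor: float = 0.01
    growth: float = 0.002
    seed: int = 0

    def sigma(self, q: np.ndarray, I: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        s = self.relative_floor * np.abs(I) + self.growth * np.abs(I[0]) * (
            q / q.max() if q.max() > 0 else q)
        if np.all(s <= 0):
            return np.ones_like(q)
        # guard the q=0 point of an otherwise valid model
        s[s <= 0] = s[s > 0].min()
        return s


def make_helix(n_bp: int, atoms_per_nt: int = 6, label: str = "helix") -> AtomicModel:
    """An idealized A-form-like double helix of pseudo-atoms.

    Two antiparallel strands of ``n_bp`` nucleotides each, built from a
    fixed per-nucleotide template (``atoms_per_nt`` <= 6 atoms of it),
    rise 2.81 A and twist 32.7 deg per base pair.  Deterministic.
    """
    if n_bp < 1:
        raise ValueError("n_bp must be at least 1")
    if not 1 <= atoms_per_nt <= len(_NT_TEMPLATE):
        raise ValueError(f"atoms_per_nt must lie in [1, {len(_NT_TEMPLATE)}]")
    template = _NT_TEMPLATE[:atoms_per_nt]
    atoms: list[Atom] = []

    def strand(phase_deg: float, mirror: int, chain: str):
        # both strands wind in the same sense; the antiparallel strand has
        # its intra-nucleotide offsets mirrored
        for i in range(n_bp):
            base_angle = phase_deg + i * _TWIST
            z0 = i * _RISE
            for k, (el, r, dth, dz) in enumerate(template):
                th = np.deg2rad(base_angle + mirror * dth)
                atoms.append(Atom(
                    element=el,
                    position=np.array([r * np.cos(th), r * np.sin(th),
                                       z0 + mirror * dz]),
                    role=AtomRole.RNA,
                    name=f"{el}{k + 1}",
                    resname="N",
                    resseq=i + 1,
                    chain=chain,
                ))

    strand(0.0, +1, "A")
    strand(165.0, -1, "B")  # second strand offset across the groove
    return AtomicModel(atoms, label=label)


def perturb_ensemble(model: AtomicModel, n_conformations: int,
                     magnitude: float = 0.5, seed: int = 0,
                     hinges_per_conformation: int = 2) -> Ensemble:
    """Hinge-perturbed conformations of a model (sampler stand-in).

    Each conformation applies a few rigid rotations: a random pivot atom is
    chosen and all atoms after it (in atom order) rotate about a random
    axis through the pivot by an angle drawn uniformly from
    [-magnitude, magnitude] radians.  Atom count and ordering are
    preserved, and geometry within each rigid segment is exact.
    """
    if n_conformations < 1:
        raise ValueError("need at least one conformation")
    if magnitude < 0:
        raise ValueError("magnitude must be non-negative")
    rng = np.random.default_rng(seed)
    n = len(model)
    members = []
    for _ in range(n_conformations):
        pos = model.positions.copy()
        for _ in range(hinges_per_conformation):
            pivot = int(rng.integers(1, n)) if n > 1 else 0
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = float(rng.uniform(-magnitude, magnitude))
            R = _rotation_matrix(axis, angle)
            center = pos[pivot]
            pos[pivot:] = (pos[pivot:] - center) @ R.T + center
        atoms = [Atom(element=a.element, position=p, role=a.role, name=a.name,
                      resname=a.resname, resseq=a.resseq, chain=a.chain,
                      solvent_accessibility=a.solvent_accessibility)
                 for a, p in zip(model.atoms, pos)]
        members.append(AtomicModel(atoms, label=model.label))
    return Ensemble(members)


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


def add_ions(model: AtomicModel, ion_positions) -> AtomicModel:
    """A copy of the model with Mg ions appended (role MG, no hydration)."""
    ions = [Atom(element="MG", position=np.asarray(p, dtype=float),
                 role=AtomRole.MG, name="MG", resname="MG", resseq=9000 + i,
                 chain="M")
            for i, p in enumerate(np.atleast_2d(ion_positions))]
    return AtomicModel(list(model.atoms) + ions, label=model.label)


def simulate_profile(model: AtomicModel, q_grid: np.ndarray,
                     noise: NoiseModel | None = None,
                     ions=None, c1: float = 1.0, c2: float = 1.0) -> ScatteringProfile:
    """A synthetic 'experimental' profile with known ground truth.

    Debye intensity of the model (plus optional Mg ions) with Gaussian
    noise of the stated sigma(q) added and the sigma column attached.
    """
    noise = noise or NoiseModel()
    solute = add_ions(model, ions) if ions is not None and len(ions) else model
    calc = debye_intensity(solute, q_grid, c1=c1, c2=c2)
    sigma = noise.sigma(calc.q, calc.I)
    rng = np.random.default_rng(noise.seed)
    scale = noise.relative_floor + noise.growth
    eps = rng.normal(0.0, sigma) if scale > 0 else np.zeros_like(sigma)
    return ScatteringProfile(calc.q, calc.I + eps, sigma)


def make_binding_pockets(model: AtomicModel, n_pockets: int = 2, seed: int = 0,
                         n_oxygens: int = 5,
                         shell_radius: tuple[float, float] = (2.14, 2.20)
                         ) -> tuple[AtomicModel, np.ndarray]:
    """Decorate a model with Mg2+-like oxygen pockets; returns (model, centers).

    Each pocket is an open octahedral cage of ``n_oxygens`` oxygen atoms at
    coordination distance around a point just outside the surface (the
    vertex facing the RNA is omitted so the site stays solvent-reachable).
    The returned centers are ground-truth ion positions: a probe reaching a
    center sees an oxygen-rich inner shell like the positive class of
    :func:`make_neighborhoods`.
    """
    if n_pockets < 1:
        raise ValueError("need at least one pocket")
    rng = np.random.default_rng(seed)
    pos = model.positions
    centroid = pos.mean(axis=0)
    radial = np.linalg.norm(pos - centroid, axis=1)
    surface_idx = np.argsort(radial)[-max(4 * n_pockets, 12):]
    anchors = rng.choice(surface_idx, size=n_pockets, replace=False)

    octahedron = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                           [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float)
    atoms = list(model.atoms)
    occupied = pos
    centers = []
    for a in anchors:
        outward = pos[a] - centroid
        outward /= np.linalg.norm(outward)
        # align the octahedron so one vertex points back at the anchor, drop it
        frame = _frame_with_axis(-outward)
        verts = octahedron @ frame.T
        inward = np.argmax(verts @ (-outward))
        verts = np.delete(verts, inward, axis=0)[:n_oxygens]
        verts = verts + rng.normal(0.0, 0.03, size=verts.shape)
        verts /= np.linalg.norm(verts, axis=1, keepdims=True)
        radii = rng.uniform(*shell_radius, size=verts.shape[0])
        # push the pocket outward until its oxygens clear everything else
        for offset in np.arange(4.0, 9.1, 0.5):
            center = pos[a] + outward * offset
            shell = center + verts * radii[:, None]
            gap = np.linalg.norm(shell[:, None, :] - occupied[None, :, :],
                                 axis=2).min()
            if gap >= 1.8:
                break
        occupied = np.vstack([occupied, shell])
        for k, p in enumerate(shell):
            atoms.append(Atom(element="O", position=p, role=AtomRole.RNA,
                              name=f"OP{k + 1}", resname="SIT",
                              resseq=8000 + len(centers), chain="S"))
        centers.append(center)
    return AtomicModel(atoms, label=model.label), np.array(centers)


def _frame_with_axis(axis: np.ndarray) -> np.ndarray:
    """An orthonormal frame whose third column is the given unit vector."""
    z = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(z @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    x = np.cross(helper, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


# ---------------------------------------------------------------------------
# Labeled neighborhoods for classifier training

def make_neighborhoods(n_pos: int, n_neg: int, seed: int = 0,
                       radius: float = NEIGHBORHOOD_RADIUS) -> list[NeighborhoodGraph]:
    """Labeled probe neighborhoods emulating Mg2+ vs water coordination.

    Positives put 4-6 oxygens at 2.0-2.2 A in a jittered octahedral shell
    around the probe (Mg2+-like inner sphere) plus random background atoms
    out to the neighborhood radius.  Negatives are looser element-mixed
    shells whose nearest atom sits at 2.6-3.5 A (water-like).  Every graph
    carries its label; generation is fully seeded.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    graphs: list[NeighborhoodGraph] = []

    octahedron = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                           [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float)
    background_elements = np.array(["C", "N", "O", "P"])

    def background(n, r_min):
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        radii = rng.uniform(r_min, radius, size=n)
        return dirs * radii[:, None], rng.choice(background_elements, size=n)

    for label in ([1] * n_pos + [0] * n_neg):
        if label == 1:
            n_coord = int(rng.integers(4, 7))
            shell_dirs = octahedron[rng.permutation(6)[:n_coord]]
            shell_dirs = shell_dirs + rng.normal(0.0, 0.12, size=shell_dirs.shape)
            shell_dirs /= np.linalg.norm(shell_dirs, axis=1, keepdims=True)
            shell_r = rng.uniform(2.0, 2.2, size=n_coord)
            shell_pos = shell_dirs * shell_r[:, None]
            shell_el = ["O"] * n_coord
            bg_pos, bg_el = background(int(rng.integers(5, 16)), 3.0)
        else:
            nearest = float(rng.uniform(2.6, 3.5))
            n_shell = int(rng.integers(3, 9))
            dirs = rng.normal(size=(n_shell, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            radii = np.concatenate([[nearest],
                                    rng.uniform(nearest, radius, size=n_shell - 1)])
            shell_pos = dirs * radii[:, None]
            shell_el = list(rng.choice(background_elements, size=n_shell))
            bg_pos, bg_el = background(int(rng.integers(5, 16)), nearest)
        positions = np.vstack([shell_pos, bg_pos])
        elements = list(shell_el) + list(bg_el)
        acc = rng.uniform(0.0, 1.0, size=len(elements))
        graphs.append(build_neighborhood_graph(
            elements=elements, relative_positions=positions,
            accessibilities=acc, label=label, radius=radius))
    return graphs
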