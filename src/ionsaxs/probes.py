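"""Candidate ion positions on the RNA surface and their atomic neighborhoods.

Probes are seeded on the solvent-accessible surface: dots on each atom's
extended sphere (vdW + probe radius) that no other atom's extended sphere
covers.  Around every probe an 8 A atomic neighborhood is extracted as a
graph whose nodes are RNA atoms (element one-hot, distance to the probe,
solvent accessibility) and whose edges carry inter-atom distances.  Because
only distances enter the representation, the graphs are invariant to any
rigid motion of the structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structures import Atom, AtomicModel, AtomRole, fibonacci_sphere

__all__ = ["ProbeSet", "NeighborhoodGraph", "generate_surface_probes",
           "extract_neighborhood", "build_neighborhood_graph",
           "FEATURE_ELEMENTS", "NODE_FEATURE_DIM", "NEIGHBORHOOD_RADIUS",
           "EDGE_CUTOFF", "feature_schema"]

#: One-hot element channel order for node features.
FEATURE_ELEMENTS = ("H", "C", "N", "O", "P")
#: one-hot + distance-to-probe + solvent accessibility
NODE_FEATURE_DIM = len(FEATURE_ELEMENTS) + 2
#: Default neighborhood radius around a probe, Angstrom.
NEIGHBORHOOD_RADIUS = 8.0
#: Atom pairs closer than this are connected by a graph edge, Angstrom.
EDGE_CUTOFF = 5.0


def feature_schema() -> str:
    """A stable description of the node-feature layout (for checkpoints)."""
    return "onehot:" + ",".join(FEATURE_ELEMENTS) + "|probe_distance|accessibility"


@dataclass(frozen=True)
class ProbeSet:
    """Candidate ion positions on the surface of one model."""

    positions: np.ndarray  # (M, 3)
    source_model: str = ""

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return self.positions.shape[0]

    def as_model(self) -> AtomicModel:
        """Probes as pseudo-atoms (for PDB export / visualization)."""
        atoms = [Atom(element="O", position=p, role=AtomRole.PROBE,
                      name="PRB", resname="PRB", resseq=i + 1, chain="P")
                 for i, p in enumerate(self.positions)]
        return AtomicModel(atoms, label=f"probes:{self.source_model}")


@dataclass
class NeighborhoodGraph:
    """A probe's atomic neighborhood as a distance-attributed graph."""

    node_features: np.ndarray          # (n, NODE_FEATURE_DIM)
    edges: np.ndarray                  # (E, 2) int, undirected unique pairs
    edge_distances: np.ndarray         # (E,)
    label: Optional[int] = None        # 1 = Mg site, 0 = water site
    probe_index: int = -1

    def __post_init__(self):
        self.node_features = np.atleast_2d(np.asarray(self.node_features, float))
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.edge_distances = np.asarray(self.edge_distances, dtype=float)
        if self.node_features.shape[0] < 1:
            raise ValueError("a neighborhood graph needs at least one node")
        if self.node_features.shape[1] != NODE_FEATURE_DIM:
            raise ValueError("bad node feature width")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]


def generate_surface_probes(model: AtomicModel, probe_radius: float = 1.5,
                            density: float = 0.25,
                            dedup_spacing: float = 1.0) -> ProbeSet:
    """Seed candidate ion positions on the solvent-accessible surface.

    Each atom's extended sphere is covered with a deterministic dot set at
    the requested surface density (probes per A^2); dots inside any other
    atom's extended sphere are removed, and survivors closer than
    ``dedup_spacing`` are merged by grid snapping.
    """
    if probe_radius <= 0 or density <= 0:
        raise ValueError("probe_radius and density must be positive")
    solute = model.with_role(AtomRole.RNA, AtomRole.MG) \
        if any(a.role is not AtomRole.RNA for a in model.atoms) else model
    pos = solute.positions
    radii = solute.vdw_radii + probe_radius
    tree = cKDTree(pos)
    max_r = radii.max()

    dots_all = []
    for i in range(pos.shape[0]):
        r = radii[i]
        n_dots = max(8, int(np.ceil(density * 4.0 * np.pi * r * r)))
        dots = pos[i] + r * fibonacci_sphere(n_dots)
        nbr = [j for j in tree.query_ball_point(pos[i], r + max_r) if j != i]
        if nbr:
            d2 = ((dots[:, None, :] - pos[nbr][None, :, :]) ** 2).sum(axis=2)
            keep = ~(d2 < (radii[nbr] ** 2)[None, :] * (1 - 1e-12)).any(axis=1)
            dots = dots[keep]
        if dots.size:
            dots_all.append(dots)
    if not dots_all:
        return ProbeSet(np.empty((0, 3)), source_model=solute.label)
    dots = np.concatenate(dots_all)

    if dedup_spacing > 0:
        # snap to a grid; keep the first probe in each occupied cell
        cells = np.floor(dots / dedup_spacing).astype(np.int64)
        _, first = np.unique(cells, axis=0, return_index=True)
        dots = dots[np.sort(first)]
    return ProbeSet(dots, source_model=solute.label)


def build_neighborhood_graph(elements: Sequence[str],
                             relative_positions: np.ndarray,
                             accessibilities: Sequence[float] | None = None,
                             label: Optional[int] = None,
                             probe_index: int = -1,
                             radius: float = NEIGHBORHOOD_RADIUS) -> NeighborhoodGraph:
    """Build a graph from atoms given in probe-centered coordinates.

    Shared by :func:`extract_neighborhood` and the synthetic training-set
    generator so both produce identical feature layouts.
    """
    rel = np.atleast_2d(np.asarray(relative_positions, dtype=float))
    n = rel.shape[0]
    if accessibilities is None:
        accessibilities = np.zeros(n)
    acc = np.asarray(accessibilities, dtype=float)
    dist = np.linalg.norm(rel, axis=1)
    if np.any(dist > radius + 1e-9):
        raise ValueError("atom outside the neighborhood radius")

    feats = np.zeros((n, NODE_FEATURE_DIM))
    for k, el in enumerate(elements):
        if el in FEATURE_ELEMENTS:
            feats[k, FEATURE_ELEMENTS.index(el)] = 1.0
    feats[:, len(FEATURE_ELEMENTS)] = dist / radius      # normalized
    feats[:, len(FEATURE_ELEMENTS) + 1] = acc

    if n > 1:
        from scipy.spatial.distance import pdist, squareform
        dmat = squareform(pdist(rel))
        iu, ju = np.triu_indices(n, k=1)
        close = dmat[iu, ju] <= EDGE_CUTOFF
        edges = np.column_stack([iu[close], ju[close]])
        edist = dmat[iu[close], ju[close]]
    else:
        edges = np.empty((0, 2), dtype=int)
        edist = np.empty(0)
    return NeighborhoodGraph(node_features=feats, edges=edges,
                             edge_distances=edist, label=label,
                             probe_index=probe_index)


def extract_neighborhood(model: AtomicModel, probe: np.ndarray,
                         radius: float = NEIGHBORHOOD_RADIUS,
                         probe_index: int = -1) -> NeighborhoodGraph | None:
    """Graph of the RNA atoms within ``radius`` of a probe position.

    Returns ``None`` when no atom falls inside the radius (the caller must
    skip such probes).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    probe = np.asarray(probe, dtype=float)
    rna = [a for a in model.atoms if a.role is AtomRole.RNA]
    if not rna:
        return None
    pos = np.array([a.position for a in rna])
    d = np.linalg.norm(pos - probe[None, :], axis=1)
    inside = d <= radius
    if not inside.any():
        return None
    sel = np.flatnonzero(inside)
    return build_neighborhood_graph(
        elements=[rna[i].element for i in sel],
        relative_positions=pos[sel] - probe[None, :],
        accessibilities=[rna[i].solvent_accessibility for i in sel],
        probe_index=probe_index,
        radius=radius,
    )
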