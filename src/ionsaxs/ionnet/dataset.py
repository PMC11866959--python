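"""Building labeled training data from deposited structures.

Structures that contain both bound Mg ions and crystallographic waters can
serve as a training corpus: the neighborhood of each deposited Mg position
is a positive example, the neighborhood of each water oxygen a negative.
This importer is optional — the test suite trains exclusively on the
synthetic shell generator — but gives the classifier a path to real data.
"""

from __future__ import annotations

from ..probes import NeighborhoodGraph, extract_neighborhood
from ..structures import AtomicModel, AtomRole

__all__ = ["neighborhoods_from_structure"]


def neighborhoods_from_structure(model: AtomicModel) -> list[NeighborhoodGraph]:
    """Labeled neighborhoods from a model with MG and water records.

    Positives are extracted at Mg positions (label 1), negatives at water
    oxygen positions (label 0); the neighborhoods themselves contain only
    RNA atoms.  Positions with no RNA atom within the neighborhood radius
    are skipped.
    """
    graphs: list[NeighborhoodGraph] = []
    for atom in model.atoms:
        if atom.role is AtomRole.MG:
            label = 1
        elif atom.role is AtomRole.WATER:
            label = 0
        else:
            continue
        g = extract_neighborhood(model, atom.position)
        if g is not None:
            g.label = label
            graphs.append(g)
    return graphs
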