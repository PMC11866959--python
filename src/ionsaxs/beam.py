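"""Level-wise beam search over candidate subsets.

Shared by ion-subset selection and multistate enumeration.  Level n holds
subsets of size n; each kept subset is extended by every unused candidate
(branch), children are canonicalized and deduplicated, scored, and the K
best survive (bound).  With K = None the search is exhaustive.  Ties in the
score are broken by lexicographic subset order, so the search is fully
deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

__all__ = ["BeamLevel", "beam_subsets"]

_TOL = 1e-12


@dataclass(frozen=True)
class BeamLevel:
    """Best subset found at one level (subset size)."""

    size: int
    subset: tuple[int, ...]
    score: float


def beam_subsets(
    n_candidates: int,
    score_fn: Callable[[tuple[int, ...], tuple[int, ...]], float],
    K: int | None = None,
    max_size: int | None = None,
    stop_when_worse: bool = True,
    empty_score: float | None = None,
    on_level: Callable[[Sequence[tuple[int, ...]]], None] | None = None,
) -> tuple[tuple[int, ...], float, list[BeamLevel]]:
    """Run the search and return (best subset, best score, per-level bests).

    ``score_fn(child, parent)`` scores a canonical (sorted) child subset;
    ``parent`` is one generating parent from the previous beam, which lets
    callers score incrementally.  When ``stop_when_worse`` is set the search
    terminates as soon as a level fails to improve on the previous best, and
    that level is not reported.
    """
    if K is not None and K < 1:
        raise ValueError("K must be at least 1")
    max_size = n_candidates if max_size is None else min(max_size, n_candidates)

    levels: list[BeamLevel] = []
    if empty_score is not None:
        levels.append(BeamLevel(0, (), float(empty_score)))
    beam: list[tuple[int, ...]] = [()]

    for size in range(1, max_size + 1):
        children: dict[tuple[int, ...], tuple[int, ...]] = {}
        for parent in beam:
            used = set(parent)
            for c in range(n_candidates):
                if c in used:
                    continue
                child = tuple(sorted(parent + (c,)))
                children.setdefault(child, parent)
        if not children:
            break
        scored = sorted(((float(score_fn(child, parent)), child)
                         for child, parent in children.items()),
                        key=lambda t: (t[0], t[1]))
        best_score, best_subset = scored[0]
        prev = levels[-1].score if levels else math.inf
        if stop_when_worse and best_score >= prev - _TOL:
            break
        levels.append(BeamLevel(size, best_subset, best_score))
        beam = [s for _, s in (scored if K is None else scored[:K])]
        if on_level is not None:
            on_level(beam)

    if not levels:
        return (), math.inf, []
    best = min(levels, key=lambda lv: (lv.score, lv.subset))
    return best.subset, best.score, levels
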