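"""Turning per-probe probabilities into a ranked list of binding sites.

Confident probes cluster on the surface; iterative greedy clustering keeps
the highest-probability probe and discards everything within the minimum
separation, so accepted sites are mutually distant.  Raising the
probability threshold can only shrink the accepted set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..probes import ProbeSet

__all__ = ["InferenceConfig", "Site", "select_sites"]


@dataclass(frozen=True)
class InferenceConfig:
    """Probe acceptance policy: 0.5 is the permissive default, 0.9 strict."""

    threshold: float = 0.5
    min_separation: float = 3.5   # Angstrom between accepted sites
    max_sites: int | None = None

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.min_separation < 0:
            raise ValueError("min_separation must be non-negative")


@dataclass(frozen=True)
class Site:
    position: np.ndarray
    probability: float
    probe_index: int


def select_sites(probes: ProbeSet, probabilities: np.ndarray,
                 config: InferenceConfig | None = None) -> list[Site]:
    """Greedy iterative clustering of probe predictions into sites.

    Repeatedly accepts the highest-probability probe above the threshold
    and discards all probes within ``min_separation`` of it (ties broken by
    probe index); stops at ``max_sites`` or exhaustion.  The result is
    sorted by probability, descending.
    """
    config = config or InferenceConfig()
    p = np.asarray(probabilities, dtype=float)
    if p.shape[0] != len(probes):
        raise ValueError("probabilities must align with the probe set")
    alive = p >= config.threshold
    pos = probes.positions
    sites: list[Site] = []
    # stable order: by descending probability, then ascending index
    order = np.lexsort((np.arange(p.size), -p))
    for idx in order:
        if not alive[idx]:
            continue
        sites.append(Site(position=pos[idx].copy(), probability=float(p[idx]),
                          probe_index=int(idx)))
        if config.max_sites is not None and len(sites) >= config.max_sites:
            break
        d = np.linalg.norm(pos - pos[idx][None, :], axis=1)
        alive &= d >= config.min_separation
    return sites
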