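"""Flexible member extraction: from exact markers to the target member set T.

Approximate markers are the approximate neighbors of the exact markers.
Their abundances are not used verbatim: each is weighted by its sequence
similarity to the nearest (most similar) exact marker, so a stand-in taxon
contributes almost-full evidence when it is almost indistinguishable from a
marker and proportionally less otherwise.  Exact markers keep weight 1, and
a feature that is both exact and a neighbor of another marker stays exact
(its own abundance is already evidence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import FeatureTable
from .marker_selection import MarkerSet
from .reference_index import NeighborIndex

__all__ = ["TargetMemberSet", "build_target_set", "extract_weighted_vector",
           "weighted_matrix"]

EXACT = "exact"
APPROXIMATE = "approximate"


@dataclass
class TargetMemberSet:
    """Members of the local alignment with their weights and provenance."""

    weights: dict[str, float]
    provenance: dict[str, str]

    def __post_init__(self) -> None:
        for fid, w in self.weights.items():
            if not 0 < w <= 1:
                raise ValueError(f"weight for {fid!r} outside (0,1]: {w}")
            if self.provenance.get(fid) not in (EXACT, APPROXIMATE):
                raise ValueError(f"member {fid!r} lacks a valid provenance")

    @property
    def members(self) -> list[str]:
        return sorted(self.weights)

    @property
    def exact(self) -> set[str]:
        return {f for f, p in self.provenance.items() if p == EXACT}

    @property
    def approximate(self) -> set[str]:
        return {f for f, p in self.provenance.items() if p == APPROXIMATE}

    def __len__(self) -> int:
        return len(self.weights)


def build_target_set(markers: MarkerSet, index: NeighborIndex | None) -> TargetMemberSet:
    """T = exact markers (weight 1) plus their approximate neighbors.

    An approximate member indexed from several exact markers takes the
    maximum similarity (its nearest exact marker).  With no index, T reduces
    to the exact markers — the "exact markers only" baseline.
    """
    if not markers.exact:
        raise ValueError("empty marker set")
    weights = {m: 1.0 for m in markers.exact}
    provenance = {m: EXACT for m in markers.exact}
    if index is not None:
        for m in sorted(markers.exact):
            for nid, sim in index.of(m):
                if nid in markers.exact:
                    continue  # exact status wins
                if sim > weights.get(nid, 0.0):
                    weights[nid] = float(sim)
                provenance[nid] = APPROXIMATE
    return TargetMemberSet(weights=weights, provenance=provenance)


def extract_weighted_vector(sample: pd.Series, target: TargetMemberSet) -> pd.Series:
    """Weighted abundances of one sample restricted to T.

    Members absent from the sample's feature list contribute 0.
    """
    members = target.members
    vals = np.array(
        [target.weights[m] * float(sample.get(m, 0.0)) for m in members]
    )
    return pd.Series(vals, index=members)


def weighted_matrix(table: FeatureTable, target: TargetMemberSet) -> pd.DataFrame:
    """Weighted T-restricted abundances for every sample (members x samples)."""
    members = target.members
    present = [m for m in members if m in table.data.index]
    sub = pd.DataFrame(0.0, index=members, columns=table.sample_ids)
    if present:
        w = pd.Series({m: target.weights[m] for m in present})
        sub.loc[present] = table.data.loc[present].mul(w, axis=0)
    return sub
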