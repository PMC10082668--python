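"""Quantitative relations among features: the approximate-neighbor index.

For every feature the index records which other features are close enough —
simultaneously in 16S sequence identity, taxonomy and predicted metabolic
function — to stand in for it during local alignment.  Three screens are
combined:

* phylogeny neighbors  PN(i) = { j : identity(i,j) >= t_s  and  same lineage }
* functional neighbors FN(i) = { j : functional_distance(i,j) <= d_f }
* approximate neighbors AN(i) = PN(i) ∩ FN(i)

``t_s`` and ``d_f`` default to 0.92 and 0.11 (the values derived from the
Greengenes v13-8 reference at the top-0.1% percentile rule) but both can be
re-derived for any candidate pool with :func:`derive_thresholds`.

Sequence identity is a parameter-free global-alignment identity
(Needleman–Wunsch maximizing matches, identity = matches / alignment
columns).  The functional distance is a level-weighted Bray–Curtis over the
KO hierarchy (KO, pathway, super-pathway), a proper [0, 1] dissimilarity.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis

from .io_formats import FormatError, FunctionProfile

__all__ = [
    "NeighborIndex",
    "sequence_similarity",
    "functional_distance",
    "phylogeny_neighbors",
    "functional_neighbors",
    "approximate_neighbors",
    "derive_thresholds",
    "build_index",
    "read_neighbor_index",
    "write_neighbor_index",
]

#: Similarity / functional-distance thresholds from the Greengenes v13-8
#: reference build (top-0.1% percentile rule).
DEFAULT_T_S = 0.92
DEFAULT_D_F = 0.11

#: Weight of each hierarchy level (KO, level-2 pathway, level-1 category)
#: in the functional distance; must sum to 1.
DEFAULT_LEVEL_WEIGHTS = (1.0 / 3, 1.0 / 3, 1.0 / 3)


@dataclass
class NeighborIndex:
    """Per-feature approximate neighbors with their sequence similarities."""

    t_s: float = DEFAULT_T_S
    d_f: float = DEFAULT_D_F
    neighbors: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fid, nbrs in self.neighbors.items():
            for nid, sim in nbrs:
                if nid == fid:
                    raise FormatError(f"feature {fid!r} lists itself as a neighbor")
                if sim < self.t_s - 1e-12:
                    raise FormatError(
                        f"stored similarity {sim} for ({fid},{nid}) below t_s={self.t_s}"
                    )
        # canonical order: descending similarity, then lexicographic ID
        self.neighbors = {
            fid: sorted(nbrs, key=lambda p: (-p[1], p[0]))
            for fid, nbrs in self.neighbors.items()
        }

    def of(self, feature_id: str) -> list[tuple[str, float]]:
        return self.neighbors.get(feature_id, [])


# ---------------------------------------------------------------------------
# Sequence identity
# ---------------------------------------------------------------------------

def sequence_similarity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity between two DNA sequences, in [0, 1].

    Needleman–Wunsch with match=1, mismatch=0, gap=0: the DP maximizes the
    number of matched columns, breaking score ties toward alignments with the
    most aligned (non-gap) columns, i.e. the fewest gaps.  Identity is
    matches / alignment columns where columns = len_a + len_b - aligned
    pairs.  Symmetric and deterministic.
    """
    a, b = seq_a.upper(), seq_b.upper()
    if not a or not b:
        raise ValueError("empty sequence")
    la, lb = len(a), len(b)
    # DP over (matches, aligned_pairs), maximized lexicographically.
    matches = np.zeros((la + 1, lb + 1), dtype=np.int64)
    aligned = np.zeros((la + 1, lb + 1), dtype=np.int64)
    for i in range(1, la + 1):
        ai = a[i - 1]
        mi, mi1 = matches[i], matches[i - 1]
        gi, gi1 = aligned[i], aligned[i - 1]
        for j in range(1, lb + 1):
            dm = mi1[j - 1] + (1 if ai == b[j - 1] else 0)
            da = gi1[j - 1] + 1
            best_m, best_a = mi1[j], gi1[j]  # gap in b
            if mi[j - 1] > best_m or (mi[j - 1] == best_m and gi[j - 1] > best_a):
                best_m, best_a = mi[j - 1], gi[j - 1]  # gap in a
            if dm > best_m or (dm == best_m and da > best_a):
                best_m, best_a = dm, da
            mi[j], gi[j] = best_m, best_a
    n_match = int(matches[la, lb])
    n_aligned = int(aligned[la, lb])
    columns = la + lb - n_aligned
    return n_match / columns


# ---------------------------------------------------------------------------
# Functional distance (hierarchical Bray–Curtis over the KO tree)
# ---------------------------------------------------------------------------

def _aggregate(vec: pd.Series, mapping: pd.Series | None) -> np.ndarray:
    if mapping is None:
        return vec.to_numpy(dtype=float)
    return vec.groupby(mapping).sum().sort_index().to_numpy(dtype=float)


def functional_distance(
    p_i: pd.Series,
    p_j: pd.Series,
    hierarchy: pd.DataFrame,
    level_weights: Sequence[float] = DEFAULT_LEVEL_WEIGHTS,
) -> float:
    """Level-weighted Bray–Curtis dissimilarity between two KO profiles.

    Each profile is renormalized to sum 1, aggregated to the KO, level-2 and
    level-1 strata of the hierarchy, and the per-level Bray–Curtis values are
    combined with ``level_weights`` (which must sum to 1).  Result is in
    [0, 1], symmetric, and 0 iff the profiles agree at every level.
    """
    w = np.asarray(level_weights, dtype=float)
    if w.size != 3 or not np.isclose(w.sum(), 1.0):
        raise ValueError("level_weights must be 3 values summing to 1")
    p_i, p_j = p_i.align(p_j, fill_value=0.0)
    si, sj = p_i.sum(), p_j.sum()
    if si == 0 or sj == 0:
        raise ValueError("function profile sums to zero")
    p_i, p_j = p_i / si, p_j / sj
    kos = p_i.index
    missing = [k for k in kos if k not in hierarchy.index]
    if missing:
        warnings.warn(
            f"KOs not in hierarchy, using 'unclassified': {missing[:5]}", stacklevel=2
        )
    lv2 = pd.Series(
        [hierarchy["level2"].get(k, "unclassified") for k in kos], index=kos
    )
    lv1 = pd.Series(
        [hierarchy["level1"].get(k, "unclassified") for k in kos], index=kos
    )
    total = 0.0
    for weight, mapping in zip(w, (None, lv2, lv1)):
        u, v = _aggregate(p_i, mapping), _aggregate(p_j, mapping)
        total += weight * float(braycurtis(u, v))
    return min(max(total, 0.0), 1.0)


# ---------------------------------------------------------------------------
# Neighbor screens
# ---------------------------------------------------------------------------

def phylogeny_neighbors(
    feature_id: str,
    sims: Mapping[str, Mapping[str, float]],
    taxonomy: Mapping[str, str],
    t_s: float = DEFAULT_T_S,
) -> set[str]:
    """PN(i): features with identity >= t_s (inclusive) and identical lineage."""
    if feature_id not in taxonomy:
        raise KeyError(f"feature {feature_id!r} missing from taxonomy")
    lineage = taxonomy[feature_id]
    out: set[str] = set()
    for j, sim in sims.get(feature_id, {}).items():
        if j == feature_id or sim < t_s:
            continue
        if j not in taxonomy:
            raise KeyError(f"feature {j!r} missing from taxonomy")
        if taxonomy[j] == lineage:
            out.add(j)
    return out


def functional_neighbors(
    feature_id: str,
    fdists: Mapping[str, Mapping[str, float]],
    d_f: float = DEFAULT_D_F,
) -> set[str]:
    """FN(i): features with functional distance <= d_f (inclusive)."""
    return {
        j
        for j, d in fdists.get(feature_id, {}).items()
        if j != feature_id and d <= d_f
    }


def approximate_neighbors(
    pn: set[str], fn: set[str], sims: Mapping[str, float]
) -> list[tuple[str, float]]:
    """AN = PN ∩ FN, each with its sequence similarity.

    Ordered by descending similarity then lexicographic ID so index files
    and downstream weights are reproducible.
    """
    inter = pn & fn
    return sorted(((j, float(sims[j])) for j in inter), key=lambda p: (-p[1], p[0]))


# ---------------------------------------------------------------------------
# Threshold derivation (top-0.1% percentile rule)
# ---------------------------------------------------------------------------

def derive_thresholds(
    all_sims: Iterable[float],
    all_fdists: Iterable[float],
    q: float = 0.001,
) -> tuple[float, float]:
    """Nearest-rank percentile thresholds from pooled pairwise values.

    ``t_s`` is the similarity such that the top ``q`` fraction of pairs lie
    at or above it (the k-th largest similarity, k = floor(q*N)); ``d_f``
    mirrors it on the low tail of the functional distances.  With fewer than
    1/q values the rule degenerates to max/min, with a warning.
    """
    sims = np.sort(np.asarray(list(all_sims), dtype=float))
    fds = np.sort(np.asarray(list(all_fdists), dtype=float))
    if sims.size == 0 or fds.size == 0:
        raise ValueError("empty value list")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")

    def _rank(n: int) -> int:
        k = int(np.floor(q * n))
        if k < 1:
            warnings.warn(
                f"fewer than 1/q={1 / q:.0f} values; falling back to extreme",
                stacklevel=3,
            )
            k = 1
        return k

    t_s = float(sims[-_rank(sims.size)])
    d_f = float(fds[_rank(fds.size) - 1])
    return t_s, d_f


# ---------------------------------------------------------------------------
# Index construction and serialization
# ---------------------------------------------------------------------------

def build_index(
    sequences: Mapping[str, str],
    taxonomy: Mapping[str, str],
    functions: FunctionProfile,
    t_s: float | None = None,
    d_f: float | None = None,
    q: float = 0.001,
    level_weights: Sequence[float] = DEFAULT_LEVEL_WEIGHTS,
) -> NeighborIndex:
    """All-vs-all neighbor index over a candidate feature pool.

    Thresholds not given explicitly are derived from the pooled pairwise
    values by the percentile rule.  Intended for desk-scale pools; the
    published Greengenes-scale index is precomputed once and loaded from
    file instead.
    """
    ids = sorted(sequences)
    missing_tax = [i for i in ids if i not in taxonomy]
    if missing_tax:
        raise KeyError(f"features missing from taxonomy: {missing_tax[:5]}")
    sims: dict[str, dict[str, float]] = {i: {} for i in ids}
    fdists: dict[str, dict[str, float]] = {i: {} for i in ids}
    sim_pool: list[float] = []
    fd_pool: list[float] = []
    for i, j in itertools.combinations(ids, 2):
        s = sequence_similarity(sequences[i], sequences[j])
        d = functional_distance(
            functions.vector(i), functions.vector(j), functions.hierarchy, level_weights
        )
        sims[i][j] = sims[j][i] = s
        fdists[i][j] = fdists[j][i] = d
        sim_pool.append(s)
        fd_pool.append(d)
    if t_s is None or d_f is None:
        dt_s, dd_f = derive_thresholds(sim_pool, fd_pool, q=q)
        t_s = dt_s if t_s is None else t_s
        d_f = dd_f if d_f is None else d_f
    neighbors: dict[str, list[tuple[str, float]]] = {}
    for i in ids:
        pn = phylogeny_neighbors(i, sims, taxonomy, t_s)
        fn = functional_neighbors(i, fdists, d_f)
        an = approximate_neighbors(pn, fn, sims[i])
        if an:
            neighbors[i] = an
    return NeighborIndex(t_s=t_s, d_f=d_f, neighbors=neighbors)


def read_neighbor_index(path: str | Path) -> NeighborIndex:
    """Load an index file: ``#t_s=``/``#d_f=`` headers then TSV triples."""
    t_s, d_f = DEFAULT_T_S, DEFAULT_D_F
    neighbors: dict[str, list[tuple[str, float]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            stripped = line[1:].strip()
            if stripped.startswith("t_s="):
                t_s = float(stripped[4:])
            elif stripped.startswith("d_f="):
                d_f = float(stripped[4:])
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(
                f"{path}:{lineno}: expected feature_id<TAB>neighbor_id<TAB>similarity"
            )
        fid, nid, sim = parts[0], parts[1], float(parts[2])
        neighbors.setdefault(fid, []).append((nid, sim))
    return NeighborIndex(t_s=t_s, d_f=d_f, neighbors=neighbors)


def write_neighbor_index(index: NeighborIndex, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#t_s={index.t_s:.6g}\n#d_f={index.d_f:.6g}\n")
        fh.write("#FeatureID\tNeighborID\tSimilarity\n")
        for fid in sorted(index.neighbors):
            for nid, sim in index.neighbors[fid]:
                fh.write(f"{fid}\t{nid}\t{sim:.6f}\n")
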