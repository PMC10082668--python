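"""Readers, writers and validated in-memory containers.

Every file format the tool touches is plain text (UTF-8, tab-delimited,
``#`` comment lines): feature tables, sample metadata, Newick trees,
Greengenes-style taxonomy maps, KO function profiles with their hierarchy,
neighbor-index dumps and square distance matrices.  All loaders validate and
normalize on the way in so downstream code can assume clean inputs.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "FeatureTable",
    "PhyloTree",
    "FunctionProfile",
    "Metadata",
    "read_feature_table",
    "write_feature_table",
    "read_newick",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "write_metadata",
    "read_function_profiles",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_fasta",
]

_COLUMN_SUM_TOL = 1e-6


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Relative-abundance table, features x samples.

    ``data`` holds one column per sample; every column sums to 1 (inputs
    given as raw counts are renormalized at construction).  Feature and
    sample identifiers must be unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature IDs: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample IDs: {dups}")
        vals = df.to_numpy(dtype=float)
        if np.isnan(vals).any():
            r, c = np.argwhere(np.isnan(vals))[0]
            raise FormatError(
                f"missing value at feature {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise FormatError(
                f"negative abundance {vals[r, c]} at feature "
                f"{df.index[r]!r}, sample {df.columns[c]!r}"
            )
        sums = vals.sum(axis=0)
        zero = np.nonzero(sums == 0)[0]
        if zero.size:
            raise FormatError(
                f"sample {df.columns[zero[0]]!r} has zero total abundance"
            )
        if not np.allclose(sums, 1.0, atol=_COLUMN_SUM_TOL):
            vals = vals / sums
        self.data = pd.DataFrame(vals, index=df.index, columns=df.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def column(self, sample_id: str) -> pd.Series:
        """Relative abundances of one sample (features indexed)."""
        return self.data[sample_id]


def read_feature_table(path: str | Path, features_as_rows: bool = True) -> FeatureTable:
    """Load a TSV abundance table (header = sample IDs, first column = feature IDs).

    Counts are accepted and renormalized so every sample sums to 1.  Set
    ``features_as_rows=False`` for tables oriented samples x features.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric value in feature table {path}: {exc}") from exc
    if not features_as_rows:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return FeatureTable(df)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="FeatureID", float_format="%.10g")


# ---------------------------------------------------------------------------
# Phylogenetic tree
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """Rooted phylogeny with non-negative branch lengths, leaves = feature IDs."""

    tree: TreeNode
    leaf_names: list[str] = field(init=False)

    def __post_init__(self) -> None:
        names = [tip.name for tip in self.tree.tips()]
        if any(n is None for n in names):
            raise FormatError("tree contains unnamed leaves")
        seen: set[str] = set()
        for n in names:
            if n in seen:
                raise FormatError(f"duplicate leaf name in tree: {n!r}")
            seen.add(n)
        for node in self.tree.traverse(include_self=True):
            if node.length is None:
                node.length = 0.0
            elif node.length < 0:
                raise FormatError(
                    f"negative branch length {node.length} at node {node.name!r}"
                )
        self.leaf_names = names

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)


def read_newick(source: str | Path) -> PhyloTree:
    """Parse a Newick tree (file path or literal string).

    Missing branch lengths default to 0; duplicate leaf names and malformed
    strings are hard errors.
    """
    if isinstance(source, Path) or (isinstance(source, str) and "(" not in source):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        tree = TreeNode.read(io.StringIO(text), convert_underscores=False)
    except Exception as exc:  # skbio raises several parse error types
        raise FormatError(f"invalid newick: {exc}") from exc
    return PhyloTree(tree)


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

def read_taxonomy(path: str | Path) -> dict[str, str]:
    """TSV of (feature_id, lineage string) -> mapping.

    Lineages are Greengenes-style ``k__...;p__...;...`` strings; they are
    stored verbatim (whitespace-stripped) since neighbor screening compares
    full lineage strings for equality.
    """
    tax: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected feature_id<TAB>lineage")
        fid, lineage = parts[0].strip(), parts[1].strip()
        if fid in tax:
            raise FormatError(f"duplicate taxonomy entry for {fid!r}")
        tax[fid] = lineage
    return tax


def write_taxonomy(tax: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# feature_id -> lineage\n")
        for fid, lineage in tax.items():
            fh.write(f"{fid}\t{lineage}\n")


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

@dataclass
class Metadata:
    """Per-sample metadata; extra columns are preserved untouched."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise FormatError("duplicate sample IDs in metadata")

    def groups(self, group_col: str, sample_ids: list[str] | None = None) -> pd.Series:
        """Group label per sample; errors if any requested sample lacks one."""
        if group_col not in self.data.columns:
            raise FormatError(f"metadata has no column {group_col!r}")
        labels = self.data[group_col]
        if sample_ids is not None:
            missing = [s for s in sample_ids if s not in labels.index]
            if missing:
                raise FormatError(f"samples missing from metadata: {missing}")
            labels = labels.loc[sample_ids]
        if labels.isna().any():
            bad = labels.index[labels.isna()].tolist()
            raise FormatError(f"samples without group label: {bad}")
        return labels.astype(str)


def read_metadata(path: str | Path) -> Metadata:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    df.index = df.index.astype(str)
    return Metadata(df)


def write_metadata(meta: Metadata, path: str | Path) -> None:
    meta.data.to_csv(path, sep="\t", index_label="SampleID")


# ---------------------------------------------------------------------------
# Function profiles (KO) and hierarchy
# ---------------------------------------------------------------------------

@dataclass
class FunctionProfile:
    """Per-feature KO abundance vectors plus the KO hierarchy.

    ``profiles``: DataFrame features x KOs, non-negative.
    ``hierarchy``: DataFrame indexed by KO with columns ``level2``/``level1``
    giving each KO's pathway category and super-category.
    """

    profiles: pd.DataFrame
    hierarchy: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.profiles.to_numpy() < 0).any():
            raise FormatError("negative KO abundance in function profiles")
        for col in ("level2", "level1"):
            if col not in self.hierarchy.columns:
                raise FormatError(f"KO hierarchy missing column {col!r}")
        missing = [k for k in self.profiles.columns if k not in self.hierarchy.index]
        if missing:
            warnings.warn(
                f"{len(missing)} KOs absent from hierarchy, mapped to 'unclassified': "
                f"{missing[:5]}",
                stacklevel=2,
            )
            extra = pd.DataFrame(
                {"level2": "unclassified", "level1": "unclassified"}, index=missing
            )
            self.hierarchy = pd.concat([self.hierarchy, extra])

    def vector(self, feature_id: str) -> pd.Series:
        if feature_id not in self.profiles.index:
            raise KeyError(f"no function profile for feature {feature_id!r}")
        return self.profiles.loc[feature_id]


def read_function_profiles(
    profiles_path: str | Path, hierarchy_path: str | Path
) -> FunctionProfile:
    prof = pd.read_csv(profiles_path, sep="\t", index_col=0, comment="#")
    prof.index = prof.index.astype(str)
    hier = pd.read_csv(hierarchy_path, sep="\t", index_col=0, comment="#", dtype=str)
    hier.index = hier.index.astype(str)
    return FunctionProfile(prof.astype(float), hier)


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise FormatError("distance matrix rows and columns disagree")
    return DistanceMatrix(
        np.ascontiguousarray(df.to_numpy(dtype=float)), ids=list(df.index)
    )


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    """Full square TSV, 6 decimal places, header row + first column = IDs."""
    with open(path, "w") as fh:
        fh.write("\t".join(["SampleID", *dm.ids]) + "\n")
        for i, sid in enumerate(dm.ids):
            row = "\t".join(f"{v:.6f}" for v in dm.data[i])
            fh.write(f"{sid}\t{row}\n")


# ---------------------------------------------------------------------------
# FASTA (reference sequences for index building)
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {id: uppercase sequence}; IDs must be unique."""
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate FASTA ID {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise FormatError(f"no sequences in {path}")
    return seqs
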