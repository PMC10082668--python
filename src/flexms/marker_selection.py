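"""Exact-marker selection by rank tests, or from a user-supplied list.

Markers are the features whose relative abundance differs between groups:
two-sided Wilcoxon rank-sum for two groups, Kruskal–Wallis for three or
more, selected at p < alpha (strict, default 0.01) with no multiple-testing
correction by default.  Alternatively any list of features of interest can
be loaded verbatim.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import FeatureTable, FormatError, Metadata

__all__ = ["MarkerSet", "select_exact_markers", "load_marker_list"]


@dataclass
class MarkerSet:
    """Exact markers, optionally with the per-feature test p-values."""

    exact: frozenset[str]
    p_values: dict[str, float] | None = None
    alpha: float | None = None

    def __post_init__(self) -> None:
        self.exact = frozenset(self.exact)
        if self.p_values is not None:
            bad = {f: p for f, p in self.p_values.items() if not 0 <= p <= 1}
            if bad:
                raise ValueError(f"p-values outside [0,1]: {bad}")


def select_exact_markers(
    table: FeatureTable,
    metadata: Metadata,
    group_col: str,
    alpha: float = 0.01,
    fdr: bool = False,
) -> MarkerSet:
    """Rank-test every feature between groups; keep those with p < alpha.

    Two groups: two-sided Wilcoxon rank-sum (normal approximation with tie
    correction).  Three or more: Kruskal–Wallis.  Features that are zero in
    every sample are skipped.  ``fdr=True`` applies Benjamini–Hochberg to
    the p-values before thresholding (off by default).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    labels = metadata.groups(group_col, table.sample_ids)
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    by_group = [table.data.loc[:, labels[labels == g].index] for g in groups]
    small = [g for g, part in zip(groups, by_group) if part.shape[1] < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 samples: {small}")

    pvals: dict[str, float] = {}
    for fid in table.feature_ids:
        vals = [part.loc[fid].to_numpy() for part in by_group]
        if all((v == 0).all() for v in vals):
            continue
        if np.ptp(np.concatenate(vals)) == 0:
            pvals[fid] = 1.0  # constant feature: no rank separation
            continue
        if len(groups) == 2:
            res = stats.mannwhitneyu(
                vals[0], vals[1], alternative="two-sided", method="asymptotic"
            )
        else:
            res = stats.kruskal(*vals)
        pvals[fid] = float(res.pvalue)

    if fdr and pvals:
        from statsmodels.stats.multitest import multipletests

        ids = list(pvals)
        adj = multipletests([pvals[i] for i in ids], method="fdr_bh")[1]
        pvals = dict(zip(ids, adj.astype(float)))

    exact = frozenset(f for f, p in pvals.items() if p < alpha)
    return MarkerSet(exact=exact, p_values=pvals, alpha=alpha)


def load_marker_list(path: str | Path, table: FeatureTable) -> MarkerSet:
    """One feature ID per line; validated against the table, de-duplicated."""
    ids: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.append(line)
    if not ids:
        raise FormatError(f"no markers in {path}")
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        warnings.warn(f"duplicate marker IDs de-duplicated: {dups}", stacklevel=2)
    known = set(table.feature_ids)
    unknown = sorted(set(ids) - known)
    if unknown:
        raise FormatError(f"marker IDs not in feature table: {unknown}")
    return MarkerSet(exact=frozenset(ids))
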