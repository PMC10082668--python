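"""Two-group synthetic communities with planted low-abundance markers.

The generator emulates the scenario motivating local alignment: two groups
of microbiomes share a set of abundant background taxa drawn from one
compositional distribution, so their whole-community beta-diversity is
indistinguishable, while the true group signal sits in a handful of
low-abundance marker taxa.  Each marker has a close phylogenetic relative
(a cherry partner on the tree with near-identical taxonomy and function);
in the opposite group a marker is either strongly depleted or — mimicking
profiling sparsity — replaced entirely by its relative carrying comparable
mass.  A matching taxonomy map, KO function profiles, neighbor index and
metadata are produced alongside, so every pipeline stage can run without
external references.

Everything is driven by one integer seed and is fully reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    FeatureTable,
    FunctionProfile,
    Metadata,
    PhyloTree,
    read_newick,
    write_feature_table,
    write_metadata,
    write_taxonomy,
)
from .reference_index import NeighborIndex, write_neighbor_index

__all__ = ["ScenarioConfig", "PlantedTruth", "SyntheticBundle",
           "simulate_dataset", "write_fixture_bundle", "tiny_config"]


@dataclass
class ScenarioConfig:
    """Knobs of the planted-marker scenario.

    Defaults reproduce the artificial-experiment conditions: 100 samples in
    two balanced groups over 40 shared abundant background taxa, with 4
    planted group-differential markers at ~0.5% mean abundance each, half of
    which (in expectation) are replaced in the opposite group by their
    cherry relatives.
    """

    n_per_group: int = 50
    n_background: int = 40
    n_markers: int = 4
    #: mean relative abundance of one marker in its home group
    marker_mean_abundance: float = 0.005
    #: lognormal sigma of per-sample marker mass (biological noise)
    marker_sigma: float = 0.4
    #: per-sample probability a marker lineage is observed at all
    marker_presence_prob: float = 0.9
    #: fraction of markers that are replaced in the opposite group by their
    #: relatives (round(fraction * n_markers) markers, chosen at random);
    #: the remainder are depleted but still observed on their own leaf
    relative_presence: float = 0.5
    #: abundance of a non-replaced marker in the opposite group, as a
    #: fraction of its home-group mean (depletion, still rank-testable)
    marker_fold_change: float = 0.2
    #: Dirichlet concentration of the shared background composition
    background_concentration: float = 50.0
    #: multiplies all background branch lengths
    branch_scale: float = 1.0
    #: thresholds recorded in the generated neighbor index
    t_s: float = 0.92
    d_f: float = 0.11
    #: cherry similarities are drawn uniformly from this range (>= t_s)
    sim_range: tuple[float, float] = (0.93, 0.98)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1 or self.n_background < 1 or self.n_markers < 0:
            raise ValueError("counts must be positive (n_markers may be 0)")
        for name in ("marker_mean_abundance", "relative_presence",
                     "marker_presence_prob", "marker_fold_change"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_markers and (
            self.n_markers * self.marker_mean_abundance >= 0.5
        ):
            raise ValueError(
                "marker mass must stay a small fraction of the community"
            )
        if self.sim_range[0] < self.t_s:
            raise ValueError("cherry similarities must be >= t_s")


@dataclass
class PlantedTruth:
    """Ground truth of the simulation, for test bookkeeping."""

    markers: list[str]
    relatives: list[str]
    similarities: list[float]
    replaced: list[bool]  # marker replaced by its relative in group B?

    @property
    def pairs(self) -> list[tuple[str, str, float]]:
        return list(zip(self.markers, self.relatives, self.similarities))


@dataclass
class SyntheticBundle:
    table: FeatureTable
    tree: PhyloTree
    taxonomy: dict[str, str]
    functions: FunctionProfile
    index: NeighborIndex
    metadata: Metadata
    truth: PlantedTruth
    #: optional 16S-like sequences concordant with the index similarities
    sequences: dict[str, str] | None = None


def _random_topology(tokens: list[str], rng: np.random.Generator,
                     scale: float) -> str:
    """Join subtree tokens pairwise at random into one rooted newick string."""
    tokens = list(tokens)
    while len(tokens) > 1:
        i = int(rng.integers(len(tokens)))
        a = tokens.pop(i)
        j = int(rng.integers(len(tokens)))
        b = tokens.pop(j)
        la, lb = rng.uniform(0.05, 0.30, size=2) * scale
        tokens.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    return tokens[0] + ";"


def simulate_dataset(cfg: ScenarioConfig, with_sequences: bool = False) -> SyntheticBundle:
    """Generate one dataset under the planted-marker scenario.

    ``with_sequences=True`` additionally emits random nucleotide sequences
    whose pairwise identities are concordant with the generated index
    (cherry pairs differ at ~(1-s)*L sites), enabling end-to-end
    index-building tests without external references.
    """
    rng = np.random.default_rng(cfg.seed)
    bg_ids = [f"BG{i + 1:03d}" for i in range(cfg.n_background)]
    mk_ids = [f"MK{k + 1}" for k in range(cfg.n_markers)]
    rl_ids = [f"RL{k + 1}" for k in range(cfg.n_markers)]

    # --- tree: random background topology + marker/relative cherries ------
    sims = rng.uniform(*cfg.sim_range, size=cfg.n_markers)
    tokens = list(bg_ids)
    for mk, rl, s in zip(mk_ids, rl_ids, sims):
        d = (1.0 - s) / 2.0  # leaf edges consistent with sequence identity
        tokens.append(f"({mk}:{d:.6f},{rl}:{d:.6f})")
    tree = read_newick(_random_topology(tokens, rng, cfg.branch_scale))

    # --- taxonomy: unique background lineages, shared cherry lineage ------
    taxonomy: dict[str, str] = {}
    for i, fid in enumerate(bg_ids):
        taxonomy[fid] = (
            f"k__Bacteria;p__P{i % 6 + 1};c__C{i % 12 + 1};o__O{i};"
            f"f__F{i};g__G{i};s__bg{i}"
        )
    for k, (mk, rl) in enumerate(zip(mk_ids, rl_ids)):
        lineage = (
            f"k__Bacteria;p__Pm;c__Cm;o__Om{k};f__Fm{k};g__Gm{k};s__marker{k}"
        )
        taxonomy[mk] = lineage
        taxonomy[rl] = lineage

    # --- KO function profiles: cherries near-identical --------------------
    n_kos = 30
    kos = [f"K{i + 1:05d}" for i in range(n_kos)]
    hierarchy = pd.DataFrame(
        {
            "level2": [f"pathway_{i % 6 + 1}" for i in range(n_kos)],
            "level1": [f"category_{i % 3 + 1}" for i in range(n_kos)],
        },
        index=kos,
    )
    prof_rows: dict[str, np.ndarray] = {}
    for fid in bg_ids:
        prof_rows[fid] = rng.gamma(0.5, 1.0, size=n_kos)
    for mk, rl in zip(mk_ids, rl_ids):
        base = rng.gamma(0.5, 1.0, size=n_kos)
        prof_rows[mk] = base
        prof_rows[rl] = base * rng.lognormal(0.0, 0.02, size=n_kos)
    functions = FunctionProfile(
        profiles=pd.DataFrame(prof_rows, index=kos).T, hierarchy=hierarchy
    )

    # --- neighbor index: each cherry pair, similarity >= t_s --------------
    neighbors = {}
    for mk, rl, s in zip(mk_ids, rl_ids, sims):
        neighbors[mk] = [(rl, float(s))]
        neighbors[rl] = [(mk, float(s))]
    index = NeighborIndex(t_s=cfg.t_s, d_f=cfg.d_f, neighbors=neighbors)

    # --- abundances -------------------------------------------------------
    base_bg = rng.lognormal(0.0, 1.0, size=cfg.n_background)
    base_bg /= base_bg.sum()
    replaced = np.zeros(cfg.n_markers, dtype=bool)
    n_replaced = int(round(cfg.relative_presence * cfg.n_markers))
    if n_replaced:
        replaced[rng.choice(cfg.n_markers, size=n_replaced, replace=False)] = True
    n_total = 2 * cfg.n_per_group
    sample_ids = [f"A{i + 1:02d}" for i in range(cfg.n_per_group)] + [
        f"B{i + 1:02d}" for i in range(cfg.n_per_group)
    ]
    groups = ["A"] * cfg.n_per_group + ["B"] * cfg.n_per_group
    feat_ids = bg_ids + [x for pair in zip(mk_ids, rl_ids) for x in pair]
    mat = np.zeros((len(feat_ids), n_total))
    row = {f: i for i, f in enumerate(feat_ids)}
    mu = -0.5 * cfg.marker_sigma**2  # lognormal mean-1 correction
    for s_i, grp in enumerate(groups):
        bg = rng.dirichlet(cfg.background_concentration * base_bg)
        marker_mass = np.zeros(len(feat_ids))
        for k, (mk, rl) in enumerate(zip(mk_ids, rl_ids)):
            level = cfg.marker_mean_abundance * rng.lognormal(mu, cfg.marker_sigma)
            present = rng.random() < cfg.marker_presence_prob
            if not present:
                continue
            if grp == "A":
                marker_mass[row[mk]] = level
            elif replaced[k]:
                marker_mass[row[rl]] = level
            else:
                marker_mass[row[mk]] = level * cfg.marker_fold_change
        total_marker = marker_mass.sum()
        mat[: cfg.n_background, s_i] = bg * (1.0 - total_marker)
        mat[cfg.n_background:, s_i] = marker_mass[cfg.n_background:]
    table = FeatureTable(pd.DataFrame(mat, index=feat_ids, columns=sample_ids))
    metadata = Metadata(
        pd.DataFrame({"Group": groups}, index=pd.Index(sample_ids, name="SampleID"))
    )
    truth = PlantedTruth(
        markers=mk_ids,
        relatives=rl_ids,
        similarities=[float(s) for s in sims],
        replaced=[bool(r) for r in replaced],
    )
    sequences = None
    if with_sequences:
        seq_len = 150
        alphabet = np.array(list("ACGT"))
        sequences = {}
        for fid in bg_ids:
            sequences[fid] = "".join(rng.choice(alphabet, size=seq_len))
        for mk, rl, s in zip(mk_ids, rl_ids, sims):
            base = rng.choice(alphabet, size=seq_len)
            sequences[mk] = "".join(base)
            n_mut = int(round((1.0 - s) * seq_len))
            pos = rng.choice(seq_len, size=n_mut, replace=False)
            mutant = base.copy()
            for p in pos:
                choices = [b for b in "ACGT" if b != mutant[p]]
                mutant[p] = choices[int(rng.integers(3))]
            sequences[rl] = "".join(mutant)
    return SyntheticBundle(
        table, tree, taxonomy, functions, index, metadata, truth, sequences
    )


def tiny_config(seed: int = 42) -> ScenarioConfig:
    """Pinned 8-sample / 12-taxa configuration for fast unit tests."""
    return ScenarioConfig(
        n_per_group=4, n_background=8, n_markers=2, seed=seed
    )


def write_fixture_bundle(cfg: ScenarioConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate and write all artifacts in the package's text dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = simulate_dataset(cfg)
    paths = {
        "table": outdir / "table.tsv",
        "tree": outdir / "tree.nwk",
        "taxonomy": outdir / "taxonomy.tsv",
        "functions": outdir / "functions.tsv",
        "hierarchy": outdir / "ko_hierarchy.tsv",
        "index": outdir / "index.tsv",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.json",
        "config": outdir / "config.json",
    }
    write_feature_table(bundle.table, paths["table"])
    paths["tree"].write_text(str(bundle.tree.tree) )
    write_taxonomy(bundle.taxonomy, paths["taxonomy"])
    bundle.functions.profiles.to_csv(
        paths["functions"], sep="\t", index_label="FeatureID", float_format="%.10g"
    )
    bundle.functions.hierarchy.to_csv(paths["hierarchy"], sep="\t", index_label="KO")
    write_neighbor_index(bundle.index, paths["index"])
    write_metadata(bundle.metadata, paths["metadata"])
    paths["truth"].write_text(json.dumps(asdict(bundle.truth), indent=1) + "\n")
    paths["config"].write_text(json.dumps(asdict(cfg), indent=1) + "\n")
    return paths
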