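"""Stage-resolved expression summaries.

Downstream FPKM math for a four-timepoint lifecycle RNA-seq design
(1.5 h germling, 13 h mitotic sporangium, 17.5 h ciliating sporangium,
22 h new zoospores): expressed-set construction at an FPKM threshold, Venn
partition of the stage sets, gene-group stage averaging, the
ln/center/unit-variance row transform, average-linkage (UPGMA) clustering of
the transformed matrix, and heatmap export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Lifecycle timepoints in order, hours after plating zoospores.
STAGES = ("1.5h", "13h", "17.5h", "22h")

DEFAULT_FPKM_THRESHOLD = 1.0


@dataclass
class ExpressionTable:
    """Gene x (stage, replicate) FPKM table with a fixed stage order."""

    data: pd.DataFrame            # columns: MultiIndex (stage, replicate)
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        if not isinstance(self.data.columns, pd.MultiIndex):
            raise ValueError("expected MultiIndex (stage, replicate) columns")
        missing = [s for s in self.stages if s not in self.data.columns.get_level_values(0)]
        if missing:
            raise ValueError(f"stages missing from table: {missing}")
        if (self.data.values < 0).any():
            raise ValueError("FPKM values must be non-negative")
        if self.data.isna().any().any():
            raise ValueError("table has missing stage x replicate values")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    def stage_means(self) -> pd.DataFrame:
        """Per-gene mean FPKM over replicates, one column per stage in order."""
        means = self.data.T.groupby(level=0).mean().T
        return means[list(self.stages)]

    # -- I/O ----------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Long-form CSV: gene,stage,replicate,fpkm."""
        long = self.data.stack([0, 1], future_stack=True).reset_index()
        long.columns = ["gene", "stage", "replicate", "fpkm"]
        long.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, stages: Sequence[str] = STAGES) -> "ExpressionTable":
        """Read long form (gene,stage,replicate,fpkm) or wide form (gene, stage_rep...)."""
        df = pd.read_csv(path)
        if set(df.columns[:4]) >= {"gene", "stage", "replicate", "fpkm"}:
            wide = df.pivot(index="gene", columns=["stage", "replicate"], values="fpkm")
        else:
            df = df.set_index(df.columns[0])
            cols = pd.MultiIndex.from_tuples(
                [tuple(c.rsplit("_", 1)) for c in df.columns], names=["stage", "replicate"])
            df.columns = cols
            wide = df
        wide = wide.sort_index(axis=1)
        return cls(data=wide, stages=tuple(stages))


@dataclass
class GeneGroup:
    """A named gene set (e.g. cilium, centriole, distal appendage)."""

    name: str
    members: set[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene group {self.name!r} is empty")

    def present_members(self, table: ExpressionTable) -> tuple[set[str], set[str]]:
        """(members in the table, members missing from it) — missing are reported, not dropped."""
        present = self.members & set(table.genes)
        return present, self.members - present


def read_gene_groups(path: str | Path) -> list[GeneGroup]:
    """Two-column TSV ``group<TAB>gene`` into GeneGroup objects (group order of first appearance)."""
    df = pd.read_csv(path, sep="\t", names=["group", "gene"], header=None, comment="#")
    groups: dict[str, set[str]] = {}
    for g, gene in zip(df["group"], df["gene"]):
        groups.setdefault(str(g), set()).add(str(gene))
    return [GeneGroup(name=g, members=m) for g, m in groups.items()]


# ---------------------------------------------------------------------------
# Expressed sets and Venn partition

def expressed_sets(table: ExpressionTable,
                   threshold: float = DEFAULT_FPKM_THRESHOLD) -> dict[str, set[str]]:
    """Genes expressed above the FPKM threshold at each stage.

    A gene is expressed at a stage when its replicate-mean FPKM is *strictly*
    above the threshold.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    means = table.stage_means()
    return {s: set(means.index[means[s] > threshold]) for s in table.stages}


@dataclass
class StagePartition:
    """Disjoint Venn regions over stage sets, keyed by frozenset of stage labels."""

    regions: dict[frozenset[str], set[str]]
    stage_order: tuple[str, ...]

    def count(self, *stages: str) -> int:
        return len(self.regions.get(frozenset(stages), set()))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in sorted(self.regions, key=lambda k: (len(k), tuple(sorted(k)))):
            rows.append({"region": "&".join(s for s in self.stage_order if s in k),
                         "n_genes": len(self.regions[k])})
        return pd.DataFrame(rows)


def venn_partition(sets: Mapping[str, set[str]]) -> StagePartition:
    """Partition the union of 2-4 stage sets into all nonempty-combination regions.

    Regions are pairwise disjoint; a gene lands in the region of exactly the
    stages whose sets contain it, so region counts sum to the union size.
    """
    names = list(sets)
    if not 2 <= len(names) <= 4:
        raise ValueError(f"venn_partition takes 2-4 sets, got {len(names)}")
    regions: dict[frozenset[str], set[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            regions[frozenset(combo)] = set()
    for gene in set().union(*sets.values()):
        signature = frozenset(n for n in names if gene in sets[n])
        regions[signature].add(gene)
    return StagePartition(regions=regions, stage_order=tuple(names))


# ---------------------------------------------------------------------------
# Group averages and the heatmap transform

def group_stage_means(table: ExpressionTable, groups: Sequence[GeneGroup]) -> pd.DataFrame:
    """Group x stage matrix of mean FPKM (mean over members of replicate-mean FPKM)."""
    means = table.stage_means()
    rows = {}
    for g in groups:
        present, missing = g.present_members(table)
        if not present:
            raise ValueError(f"gene group {g.name!r} has no members in the table "
                             f"(missing: {sorted(missing)})")
        rows[g.name] = means.loc[sorted(present)].mean(axis=0)
    return pd.DataFrame(rows).T[list(table.stages)]


@dataclass
class TransformResult:
    matrix: pd.DataFrame
    zero_variance_rows: list[str] = field(default_factory=list)


def clustvis_transform(matrix: pd.DataFrame, pseudocount: float = 0.0) -> TransformResult:
    """ln-transform, row-center, and unit-variance scale a positive matrix.

    ``y = ln(x + pseudocount)``; each row is then centered to mean 0 and
    divided by its sample standard deviation (n-1 denominator). Rows with
    zero variance are centered, left unscaled, and flagged. Nonpositive
    entries with pseudocount 0 are an error suggesting a pseudocount.
    """
    x = matrix.to_numpy(dtype=float) + pseudocount
    if (x <= 0).any():
        raise ValueError("matrix has entries <= 0 after pseudocount; "
                         "pass pseudocount > 0 to shift zeros")
    y = np.log(x)
    y = y - y.mean(axis=1, keepdims=True)
    sd = y.std(axis=1, ddof=1)
    flat = sd == 0
    sd_safe = np.where(flat, 1.0, sd)
    y = y / sd_safe[:, None]
    out = pd.DataFrame(y, index=matrix.index, columns=matrix.columns)
    return TransformResult(matrix=out, zero_variance_rows=list(matrix.index[flat]))


# ---------------------------------------------------------------------------
# UPGMA clustering

def upgma_linkage(matrix: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Average-linkage (UPGMA) agglomeration on Euclidean row distances.

    Implements the literal definition: the distance between two clusters is
    the mean of all pairwise Euclidean distances between their original rows,
    recomputed from the original distance matrix at every merge. Ties are
    broken by the smallest original (then-cluster) index, making the
    dendrogram fully deterministic. Returns a scipy-format (n-1) x 4 linkage
    matrix [id_a, id_b, height, size].
    """
    x = np.asarray(matrix, dtype=float)
    if np.isnan(x).any():
        raise ValueError("matrix contains NaN")
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows to cluster")
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    # active clusters: id -> sorted list of original leaf indices
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    next_id = n
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        best = None
        ids = sorted(clusters)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                pair_d = [d[i, j] for i in clusters[a] for j in clusters[b]]
                h = float(np.mean(pair_d))
                if best is None or h < best[0]:
                    best = (h, a, b)
        h, a, b = best
        Z[step] = [a, b, h, len(clusters[a]) + len(clusters[b])]
        clusters[next_id] = sorted(clusters.pop(a) + clusters.pop(b))
        next_id += 1
    return Z


@dataclass
class ClusterResult:
    row_linkage: np.ndarray | None
    row_order: list[int]
    col_linkage: np.ndarray | None
    col_order: list[int]

    def row_newick(self, labels: Sequence[str]) -> str:
        if self.row_linkage is None:
            raise ValueError("rows were not clustered")
        return linkage_to_newick(self.row_linkage, labels)


def _leaf_order(Z: np.ndarray, n: int) -> list[int]:
    from scipy.cluster.hierarchy import leaves_list
    return [int(i) for i in leaves_list(Z)]


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a linkage matrix as a Newick string with branch lengths from merge heights."""
    n = Z.shape[0] + 1
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        # ultrametric: a node at merge height h sits h/2 above its leaves
        la = h / 2 - heights[a] / 2
        lb = h / 2 - heights[b] / 2
        nodes[n + k] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + k] = h
    return nodes[n + Z.shape[0] - 1] + ";"


def cluster_rows_cols(matrix: pd.DataFrame, cluster_cols: bool = True) -> ClusterResult:
    """UPGMA-cluster rows (and optionally columns) of a transformed matrix.

    Per-gene heatmaps bypass clustering entirely — call with the identity by
    not invoking this function; here at least 2 rows are required.
    """
    Z_row = upgma_linkage(matrix.to_numpy())
    row_order = _leaf_order(Z_row, matrix.shape[0])
    Z_col = None
    col_order = list(range(matrix.shape[1]))
    if cluster_cols:
        Z_col = upgma_linkage(matrix.to_numpy().T)
        col_order = _leaf_order(Z_col, matrix.shape[1])
    return ClusterResult(row_linkage=Z_row, row_order=row_order,
                         col_linkage=Z_col, col_order=col_order)


# ---------------------------------------------------------------------------
# Heatmap

def render_heatmap(matrix: pd.DataFrame, path: str | Path,
                   row_order: Sequence[int] | None = None,
                   col_order: Sequence[int] | None = None,
                   cmap: str = "RdBu_r") -> Path:
    """Deterministic heatmap; identity orders keep input (lifecycle) order."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ro = list(row_order) if row_order is not None else list(range(matrix.shape[0]))
    co = list(col_order) if col_order is not None else list(range(matrix.shape[1]))
    if sorted(ro) != list(range(matrix.shape[0])) or sorted(co) != list(range(matrix.shape[1])):
        raise ValueError("row/col orders must be permutations of the matrix axes")
    m = matrix.iloc[ro, co]
    with plt.rc_context({"svg.hashsalt": "mtoc-atlas"}):
        fig, ax = plt.subplots(figsize=(1.5 + 0.5 * m.shape[1], 1.0 + 0.3 * m.shape[0]))
        im = ax.imshow(m.to_numpy(), aspect="auto", cmap=cmap)
        ax.set_xticks(range(m.shape[1]))
        ax.set_xticklabels(m.columns, rotation=45, ha="right", fontsize=8)
        ax.set_yticks(range(m.shape[0]))
        ax.set_yticklabels(m.index, fontsize=8)
        fig.colorbar(im, ax=ax, shrink=0.8)
        fig.tight_layout()
        path = Path(path)
        fig.savefig(path, metadata={"Date": None} if path.suffix == ".svg" else None)
        plt.close(fig)
    return path
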