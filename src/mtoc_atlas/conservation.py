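"""Bait-anchored orthogroup merging and presence/absence conservation mapping.

Post-orthology-inference pipeline: drop low-completeness proteomes, anchor
sequence-based orthogroups with curated bait clusters, merge the anchored
orthogroups into one family per bait cluster, remove protein fragments shorter
than half the mean bait length, and binarize the result into a species-level
(and clade-rolled-up) conservation matrix rendered as a dot plot.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .orthogroups import BAIT_CATEGORIES, BaitCluster, OrthogroupTable

logger = logging.getLogger(__name__)

DEFAULT_BUSCO_THRESHOLD = 80.0
DEFAULT_LENGTH_FRACTION = 0.5


@dataclass
class MergedOrthogroup:
    """Union of bait-anchored orthogroups after the length-fraction filter."""

    name: str
    category: str
    source_orthogroups: set[str]
    members: dict[str, set[str]]             # species -> post-filter proteins
    length_threshold: float                  # residues; strict "shorter than"
    filtered_out: dict[str, set[str]] = field(default_factory=dict)

    @property
    def n_members(self) -> int:
        return sum(len(v) for v in self.members.values())

    @property
    def n_filtered(self) -> int:
        return sum(len(v) for v in self.filtered_out.values())


@dataclass
class ConservationMatrix:
    """Boolean presence matrix, rows = merged orthogroups, columns = species or clades."""

    data: pd.DataFrame                       # bool dtype
    level: str                               # "species" | "clade"
    categories: dict[str, str] = field(default_factory=dict)  # row -> bait category

    def __post_init__(self) -> None:
        if self.level not in ("species", "clade"):
            raise ValueError(f"level must be 'species' or 'clade', got {self.level!r}")
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("row/column labels must be unique")
        self.data = self.data.astype(bool)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.astype(int)
        out.index.name = "merged_orthogroup"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, level: str) -> "ConservationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0).astype(bool)
        return cls(data=df, level=level)


def filter_by_busco(scores: Mapping[str, float], threshold: float = DEFAULT_BUSCO_THRESHOLD,
                    species: Iterable[str] | None = None) -> set[str]:
    """Retain species with BUSCO completeness >= ``threshold`` percent.

    Removal is the strict complement of the paper-style rule "remove datasets
    with completeness less than the threshold": a species exactly at the
    threshold is retained. If ``species`` is given, every one of them must
    have a score.
    """
    if not 0 <= threshold <= 100:
        raise ValueError(f"threshold must be in [0, 100], got {threshold}")
    for sp, sc in scores.items():
        if not 0 <= sc <= 100:
            raise ValueError(f"BUSCO score for {sp!r} out of [0, 100]: {sc}")
    if species is not None:
        missing = sorted(set(species) - set(scores))
        if missing:
            raise ValueError(f"species missing a BUSCO score: {missing}")
    retained = {sp for sp, sc in scores.items() if sc >= threshold}
    removed = {sp: sc for sp, sc in scores.items() if sc < threshold}
    if removed:
        logger.info("BUSCO filter (<%g%%) removed %d species: %s",
                    threshold, len(removed),
                    ", ".join(f"{s}={v:g}" for s, v in sorted(removed.items())))
    if not retained:
        warnings.warn(f"BUSCO threshold {threshold} retained no species", stacklevel=2)
    return retained


def anchor_orthogroups(bait: BaitCluster, table: OrthogroupTable) -> set[str]:
    """Orthogroups containing at least one exact (species, protein) bait member.

    An empty result means the bait cluster is unplaced in this table; that is
    reported, not raised, since curated baits may predate the proteome set.
    """
    if not table.groups:
        raise ValueError("orthogroup table is empty")
    anchored: set[str] = set()
    unplaced: list[str] = []
    for sp, prot, _ in bait.members:
        hits = table.orthogroups_of(sp, prot)
        if hits:
            anchored.update(hits)
        else:
            unplaced.append(f"{sp}|{prot}")
    if unplaced:
        logger.info("bait %s: %d member(s) not in any orthogroup: %s",
                    bait.name, len(unplaced), ", ".join(unplaced))
    return anchored


def merge_and_filter(bait: BaitCluster, anchored: set[str], table: OrthogroupTable,
                     fraction: float = DEFAULT_LENGTH_FRACTION) -> MergedOrthogroup:
    """Union anchored orthogroups and drop members shorter than fraction x mean bait length.

    The threshold is ``fraction`` times the arithmetic mean of bait member
    lengths; removal is strict (< threshold), so a member exactly at the
    threshold is retained. An empty anchored set yields an empty merged
    orthogroup (the bait is simply unplaced).
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    threshold = fraction * bait.mean_length
    members: dict[str, set[str]] = {}
    filtered: dict[str, set[str]] = {}
    for og in sorted(anchored):
        if og not in table.groups:
            raise KeyError(f"anchored orthogroup {og!r} not in table")
        for sp, prots in table.groups[og].items():
            for p in prots:
                if table.length_of(p) < threshold:
                    filtered.setdefault(sp, set()).add(p)
                else:
                    members.setdefault(sp, set()).add(p)
    for sp in sorted(filtered):
        logger.info("merged orthogroup %s: filtered %d fragment(s) from %s "
                    "(threshold %.1f residues)", bait.name, len(filtered[sp]), sp, threshold)
    return MergedOrthogroup(name=bait.name, category=bait.category,
                            source_orthogroups=set(anchored), members=members,
                            length_threshold=threshold, filtered_out=filtered)


def merge_all(baits: Sequence[BaitCluster], table: OrthogroupTable,
              fraction: float = DEFAULT_LENGTH_FRACTION) -> list[MergedOrthogroup]:
    """Anchor and merge every bait cluster; warn when clusters share an orthogroup."""
    merged: list[MergedOrthogroup] = []
    claimed: dict[str, str] = {}
    for bait in baits:
        anchored = anchor_orthogroups(bait, table)
        for og in anchored:
            if og in claimed and claimed[og] != bait.name:
                warnings.warn(
                    f"orthogroup {og} anchored by both {claimed[og]!r} and "
                    f"{bait.name!r}; rows will share members", stacklevel=2)
            claimed.setdefault(og, bait.name)
        merged.append(merge_and_filter(bait, anchored, table, fraction=fraction))
    return merged


def binarize(merged: Sequence[MergedOrthogroup], species: Sequence[str]) -> ConservationMatrix:
    """Species-level presence matrix: true iff >=1 post-filter member in that species."""
    species = list(species)
    known = set(species)
    rows = {}
    categories = {}
    for m in merged:
        unknown = sorted(set(m.members) - known)
        if unknown:
            raise ValueError(f"merged orthogroup {m.name}: member species not in "
                             f"species list: {unknown}")
        rows[m.name] = [bool(m.members.get(sp)) for sp in species]
        categories[m.name] = m.category
    order = sorted(rows, key=lambda n: (BAIT_CATEGORIES.index(categories[n]), n))
    df = pd.DataFrame.from_dict(rows, orient="index", columns=species).loc[order]
    return ConservationMatrix(data=df, level="species", categories=categories)


def rollup_clades(matrix: ConservationMatrix, clade_map: Mapping[str, str],
                  clade_order: Sequence[str],
                  outgroups: Sequence[str] = ()) -> ConservationMatrix:
    """Clade-level matrix: a clade is present iff any of its species is present.

    Outgroup species keep their own columns (placed first); every other matrix
    species must map to exactly one clade, and every clade in ``clade_order``
    must own at least one species column.
    """
    if matrix.level != "species":
        raise ValueError("rollup_clades expects a species-level matrix")
    outgroups = [s for s in outgroups if s in matrix.data.columns]
    clade_species: dict[str, list[str]] = {c: [] for c in clade_order}
    for sp in matrix.data.columns:
        if sp in outgroups:
            continue
        if sp not in clade_map:
            raise ValueError(f"species {sp!r} has no clade assignment")
        clade = clade_map[sp]
        if clade not in clade_species:
            raise ValueError(f"species {sp!r} maps to clade {clade!r} not in clade_order")
        clade_species[clade].append(sp)
    empty = [c for c, sps in clade_species.items() if not sps]
    if empty:
        raise ValueError(f"clades with zero species: {empty}")
    cols = {}
    for sp in outgroups:
        cols[sp] = matrix.data[sp]
    for clade in clade_order:
        cols[clade] = matrix.data[clade_species[clade]].any(axis=1)
    df = pd.DataFrame(cols)
    return ConservationMatrix(data=df, level="clade", categories=dict(matrix.categories))


CATEGORY_COLORS = {
    "centriole structure and duplication": "#9ccc65",
    "PCM and centriole satellites": "#43a047",
    "distal appendages": "#26a69a",
    "accessory structures/fibrous linkers": "#5c6bc0",
    "microtubule nucleation": "#8e24aa",
}


def render_matrix(matrix: ConservationMatrix, path: str | Path,
                  category_colors: Mapping[str, str] | None = None) -> Path:
    """Dot-matrix conservation figure: one colored dot per present (row, clade) cell.

    Rows are grouped by bait category and colored by it; output is
    deterministic (fixed SVG hash salt, no date metadata).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if matrix.level != "clade":
        raise ValueError("render_matrix expects a clade-level matrix")
    colors = dict(category_colors or CATEGORY_COLORS)
    for row in matrix.data.index:
        cat = matrix.categories.get(row)
        if cat not in colors:
            raise ValueError(f"row {row!r}: unknown category {cat!r}")

    with plt.rc_context({"svg.hashsalt": "mtoc-atlas"}):
        nrow, ncol = matrix.data.shape
        fig, ax = plt.subplots(figsize=(1.2 + 0.35 * ncol, 1.0 + 0.28 * nrow))
        for i, row in enumerate(matrix.data.index):
            c = colors[matrix.categories[row]]
            for j, col in enumerate(matrix.data.columns):
                if matrix.data.iloc[i, j]:
                    ax.scatter(j, nrow - 1 - i, s=60, color=c, edgecolors="none")
        ax.set_xticks(range(ncol))
        ax.set_xticklabels(matrix.data.columns, rotation=90, fontsize=7)
        ax.set_yticks(range(nrow))
        ax.set_yticklabels(list(matrix.data.index)[::-1], fontsize=7)
        ax.set_xlim(-0.5, ncol - 0.5)
        ax.set_ylim(-0.5, nrow - 0.5)
        ax.xaxis.set_ticks_position("top")
        fig.tight_layout()
        path = Path(path)
        fig.savefig(path, metadata={"Date": None} if path.suffix == ".svg" else None)
        plt.close(fig)
    return path


def write_provenance(merged: Sequence[MergedOrthogroup], path: str | Path) -> None:
    """Per-family merge/filter log: sources, threshold, member and fragment counts."""
    rows = []
    for m in merged:
        rows.append({
            "merged_orthogroup": m.name,
            "category": m.category,
            "source_orthogroups": ";".join(sorted(m.source_orthogroups)),
            "length_threshold": round(m.length_threshold, 3),
            "n_members": m.n_members,
            "n_filtered": m.n_filtered,
            "filtered_proteins": ";".join(
                p for sp in sorted(m.filtered_out) for p in sorted(m.filtered_out[sp])),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
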