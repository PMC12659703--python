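"""Orthogroup tables and bait clusters.

Containers and file I/O for the tabular output of a sequence-based orthology
inference run (OrthoFinder's ``Orthogroups.tsv`` dialect) and for manually
curated *bait clusters* — small sets of proteins accepted as orthologs from
structural and experimental evidence, used downstream to anchor and merge
orthogroups into named, category-labelled gene families.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml
from Bio import SeqIO

#: Functional categories used for centriole/centrosome gene families.
BAIT_CATEGORIES = (
    "centriole structure and duplication",
    "PCM and centriole satellites",
    "distal appendages",
    "accessory structures/fibrous linkers",
    "microtubule nucleation",
)


@dataclass
class OrthogroupTable:
    """Orthogroup membership: orthogroup -> species -> protein IDs.

    ``species`` fixes the column order; every orthogroup row has an entry
    (possibly empty) for every species. ``protein_lengths`` maps protein ID to
    residue count and is populated from the per-species FASTA proteomes.
    """

    species: list[str]
    groups: dict[str, dict[str, list[str]]]
    protein_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for og, by_sp in self.groups.items():
            for sp in by_sp:
                if sp not in self.species:
                    raise ValueError(f"orthogroup {og} names unknown species {sp!r}")
            for prots in by_sp.values():
                for p in prots:
                    if p in seen:
                        raise ValueError(f"protein ID {p!r} occurs in more than one orthogroup")
                    seen.add(p)
        for p, n in self.protein_lengths.items():
            if n < 1:
                raise ValueError(f"protein {p!r} has non-positive length {n}")

    # -- queries -----------------------------------------------------------

    def members(self, orthogroup: str) -> dict[str, list[str]]:
        return {sp: list(self.groups[orthogroup].get(sp, [])) for sp in self.species}

    def orthogroups_of(self, species: str, protein: str) -> list[str]:
        """Orthogroup IDs containing the exact (species, protein) pair."""
        return [
            og
            for og, by_sp in self.groups.items()
            if protein in by_sp.get(species, [])
        ]

    def length_of(self, protein: str) -> int:
        try:
            return self.protein_lengths[protein]
        except KeyError:
            raise KeyError(f"no length recorded for protein {protein!r}") from None

    def restrict_species(self, keep: Iterable[str]) -> "OrthogroupTable":
        """Drop columns for species not in ``keep`` (e.g. after a BUSCO filter)."""
        keep_set = set(keep)
        species = [s for s in self.species if s in keep_set]
        groups = {
            og: {sp: list(prots) for sp, prots in by_sp.items() if sp in keep_set}
            for og, by_sp in self.groups.items()
        }
        return OrthogroupTable(species=species, groups=groups,
                               protein_lengths=dict(self.protein_lengths))

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write the OrthoFinder ``Orthogroups.tsv`` dialect.

        Header row ``Orthogroup<TAB>species...``; cells are comma+space
        separated protein IDs, empty cell meaning the species is absent.
        """
        path = Path(path)
        with path.open("w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["Orthogroup", *self.species])
            for og in sorted(self.groups):
                row = [og]
                for sp in self.species:
                    row.append(", ".join(self.groups[og].get(sp, [])))
                w.writerow(row)

    @classmethod
    def from_tsv(cls, path: str | Path,
                 protein_lengths: Mapping[str, int] | None = None) -> "OrthogroupTable":
        path = Path(path)
        with path.open(newline="") as fh:
            rows = list(csv.reader(fh, delimiter="\t"))
        if not rows or rows[0][0] != "Orthogroup":
            raise ValueError(f"{path}: not an Orthogroups.tsv file (bad header)")
        species = rows[0][1:]
        groups: dict[str, dict[str, list[str]]] = {}
        for row in rows[1:]:
            if not row or not row[0]:
                continue
            og = row[0]
            cells = row[1:] + [""] * (len(species) - len(row[1:]))
            by_sp: dict[str, list[str]] = {}
            for sp, cell in zip(species, cells):
                if cell.strip():
                    by_sp[sp] = [p.strip() for p in cell.split(",") if p.strip()]
            groups[og] = by_sp
        return cls(species=species, groups=groups,
                   protein_lengths=dict(protein_lengths or {}))


@dataclass
class BaitCluster:
    """A named, categorised reference protein set anchoring one merged orthogroup."""

    name: str
    category: str
    members: list[tuple[str, str, int]]  # (species_id, protein_id, length)

    def __post_init__(self) -> None:
        if self.category not in BAIT_CATEGORIES:
            raise ValueError(
                f"bait cluster {self.name!r}: unknown category {self.category!r}; "
                f"expected one of {BAIT_CATEGORIES}"
            )
        if not self.members:
            raise ValueError(f"bait cluster {self.name!r} has no members")
        for sp, prot, n in self.members:
            if n < 1:
                raise ValueError(f"bait member {sp}|{prot} has non-positive length {n}")

    @property
    def mean_length(self) -> float:
        return sum(n for _, _, n in self.members) / len(self.members)


def read_protein_lengths(fasta_paths: Iterable[str | Path]) -> dict[str, int]:
    """Residue counts from per-species proteome FASTAs (headers ``species|protein``)."""
    lengths: dict[str, int] = {}
    for path in fasta_paths:
        for rec in SeqIO.parse(str(path), "fasta"):
            protein = rec.id.split("|", 1)[1] if "|" in rec.id else rec.id
            lengths[protein] = len(rec.seq)
    return lengths


def read_bait_clusters(bait_dir: str | Path,
                       category_map: str | Path | Mapping[str, str]) -> list[BaitCluster]:
    """Load bait clusters from one FASTA per cluster plus a YAML category map.

    FASTA headers follow the ``species|protein`` convention; the category map
    is ``{cluster_name: category}``.
    """
    bait_dir = Path(bait_dir)
    if isinstance(category_map, (str, Path)):
        with Path(category_map).open() as fh:
            category_map = yaml.safe_load(fh)
    clusters: list[BaitCluster] = []
    for fasta in sorted(bait_dir.glob("*.fasta")):
        name = fasta.stem
        if name not in category_map:
            raise ValueError(f"bait cluster {name!r} missing from category map")
        members = []
        for rec in SeqIO.parse(str(fasta), "fasta"):
            sp, prot = rec.id.split("|", 1)
            members.append((sp, prot, len(rec.seq)))
        clusters.append(BaitCluster(name=name, category=category_map[name], members=members))
    return clusters


def write_bait_clusters(clusters: Iterable[BaitCluster], out_dir: str | Path,
                        sequences: Mapping[str, str]) -> Path:
    """Write one FASTA per cluster plus ``categories.yaml``; returns the map path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cats: dict[str, str] = {}
    for cl in clusters:
        cats[cl.name] = cl.category
        with (out_dir / f"{cl.name}.fasta").open("w") as fh:
            for sp, prot, _ in cl.members:
                fh.write(f">{sp}|{prot}\n{sequences[prot]}\n")
    map_path = out_dir / "categories.yaml"
    with map_path.open("w") as fh:
        yaml.safe_dump(cats, fh, sort_keys=True)
    return map_path
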