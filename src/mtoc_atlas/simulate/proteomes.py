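"""Synthetic proteome / orthogroup generator with planted ground truth.

Emulates the tabular inputs of a bait-anchored orthology pipeline without
running any sequence search: ortholog families are planted directly in an
orthogroup table, with optional clade-structured gene loss, orthogroup
over-splitting (one family emitted as 2-3 orthogroups) and fragment
contamination (a member replaced by a sub-threshold fragment). Protein
sequences are random amino-acid strings labeled by family; orthology lives
in the table, not in sequence similarity.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ..orthogroups import BAIT_CATEGORIES, BaitCluster, OrthogroupTable

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class PlantedFamilyTruth:
    """Ground truth for one planted ortholog family.

    ``present_in`` lists species carrying at least one *full-length* member:
    a species whose only member was replaced by a fragment is recorded
    absent, because fragments must never create presence downstream.
    """

    family_id: str
    category: str
    present_in: set[str]
    split_into: list[str]
    fragment_members: set[str] = field(default_factory=set)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["present_in"] = sorted(self.present_in)
        d["fragment_members"] = sorted(self.fragment_members)
        return d

    @classmethod
    def from_jsonable(cls, d: Mapping) -> "PlantedFamilyTruth":
        return cls(family_id=d["family_id"], category=d["category"],
                   present_in=set(d["present_in"]), split_into=list(d["split_into"]),
                   fragment_members=set(d["fragment_members"]))


@dataclass
class ProteomeSimResult:
    roster: dict[str, str]                       # species -> clade
    truths: list[PlantedFamilyTruth]
    table: OrthogroupTable
    baits: list[BaitCluster]
    busco_scores: dict[str, float]
    sequences: dict[str, str]                    # protein -> AA string

    def write(self, outdir: str | Path) -> Path:
        """Write FASTAs, Orthogroups.tsv, BUSCO TSV, clade map, baits, truth JSON."""
        from ..orthogroups import write_bait_clusters

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta_dir = outdir / "proteomes"
        fasta_dir.mkdir(exist_ok=True)
        by_species: dict[str, list[str]] = {sp: [] for sp in self.roster}
        for og, by_sp in self.table.groups.items():
            for sp, prots in by_sp.items():
                by_species[sp].extend(prots)
        for sp in sorted(by_species):
            with (fasta_dir / f"{sp}.fasta").open("w") as fh:
                for prot in sorted(by_species[sp]):
                    fh.write(f">{sp}|{prot}\n{self.sequences[prot]}\n")
        self.table.to_tsv(outdir / "Orthogroups.tsv")
        with (outdir / "busco_scores.tsv").open("w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["species", "completeness_percent"])
            for sp in sorted(self.busco_scores):
                w.writerow([sp, f"{self.busco_scores[sp]:.1f}"])
        with (outdir / "clade_map.tsv").open("w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            for sp in sorted(self.roster):
                w.writerow([sp, self.roster[sp]])
        write_bait_clusters(self.baits, outdir / "baits", self.sequences)
        with (outdir / "truth.json").open("w") as fh:
            json.dump({"families": [t.to_jsonable() for t in self.truths]},
                      fh, indent=1, sort_keys=True)
        return outdir


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def gen_proteome_set(
    roster: Mapping[str, str] | Sequence[tuple[str, str]],
    n_families: int,
    loss_spec: Mapping[str, Sequence[str]] | None = None,
    split_prob: float = 0.0,
    fragment_prob: float = 0.0,
    seed: int = 0,
    *,
    bait_species: Sequence[str] | None = None,
    family_length: tuple[int, int] = (200, 600),
    busco_range: tuple[float, float] = (85.0, 99.5),
    busco_fail: Mapping[str, float] | None = None,
    split_families: set[str] | None = None,
    fragment_families: set[str] | None = None,
) -> ProteomeSimResult:
    """Plant ortholog families and emit proteomes, orthogroup table, baits, BUSCO scores.

    Parameters
    ----------
    roster
        species -> clade map (a sequence of pairs is checked for duplicate
        species IDs). Needs at least 2 clades.
    n_families
        number of families to plant (>= 1).
    loss_spec
        family_id -> clades from which the family is absent. Unknown clade
        names are an error. Bait species are exempt from loss so every bait
        can be placed.
    split_prob, fragment_prob
        per-family probabilities of orthogroup over-splitting (into 2-3
        orthogroups) and of one member being replaced by a fragment shorter
        than 50% of the family's bait mean length. ``split_families`` /
        ``fragment_families`` pin the choice to an explicit family set
        instead of a Bernoulli draw.
    bait_species
        species contributing 2-5 full-length bait members per family;
        defaults to the first two roster species.
    busco_fail
        species -> completeness score overriding the sampled ``busco_range``
        (used to force at least one species below a filtering threshold).
    """
    if isinstance(roster, Mapping):
        roster = dict(roster)
    else:
        pairs = list(roster)
        ids = [sp for sp, _ in pairs]
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        if dupes:
            raise ValueError(f"duplicate species IDs in roster: {dupes}")
        roster = dict(pairs)
    clades = sorted(set(roster.values()))
    if len(clades) < 2:
        raise ValueError("roster must span at least 2 clades")
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    for p, name in ((split_prob, "split_prob"), (fragment_prob, "fragment_prob")):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    loss_spec = {k: list(v) for k, v in (loss_spec or {}).items()}
    for fam, lost in loss_spec.items():
        unknown = sorted(set(lost) - set(clades))
        if unknown:
            raise ValueError(f"loss_spec for {fam!r} names unknown clades: {unknown}")

    species = sorted(roster)
    bait_species = list(bait_species) if bait_species is not None else species[:2]
    for sp in bait_species:
        if sp not in roster:
            raise ValueError(f"bait species {sp!r} not in roster")

    rng = np.random.default_rng(seed)
    truths: list[PlantedFamilyTruth] = []
    groups: dict[str, dict[str, list[str]]] = {}
    lengths: dict[str, int] = {}
    sequences: dict[str, str] = {}
    baits: list[BaitCluster] = []
    og_counter = 0

    for k in range(n_families):
        fam = f"FAM{k:03d}"
        category = BAIT_CATEGORIES[k % len(BAIT_CATEGORIES)]
        base_len = int(rng.integers(family_length[0], family_length[1] + 1))
        lost_clades = set(loss_spec.get(fam, ()))
        present = [sp for sp in species
                   if roster[sp] not in lost_clades or sp in bait_species]

        # full-length members, one per present species
        members: dict[str, str] = {}
        for sp in present:
            prot = f"{sp}_{fam}"
            members[sp] = prot
            lengths[prot] = base_len
            sequences[prot] = _random_protein(rng, base_len)

        # bait cluster: 2-5 full-length members from the designated bait species
        n_bait = int(min(max(2, len(bait_species)), 5, len(bait_species)))
        bait_members = [(sp, members[sp], lengths[members[sp]])
                        for sp in bait_species[:n_bait]]
        baits.append(BaitCluster(name=fam, category=category, members=bait_members))
        bait_mean = sum(n for _, _, n in bait_members) / len(bait_members)

        # fragment contamination: replace one non-bait member by a fragment
        fragment_ids: set[str] = set()
        do_frag = (fam in fragment_families) if fragment_families is not None \
            else bool(rng.random() < fragment_prob)
        non_bait = [sp for sp in present if sp not in bait_species]
        if do_frag and non_bait:
            victim = non_bait[int(rng.integers(len(non_bait)))]
            prot = members[victim]
            frag_len = max(1, int(rng.uniform(0.10, 0.45) * bait_mean))
            assert frag_len < 0.5 * bait_mean
            lengths[prot] = frag_len
            sequences[prot] = sequences[prot][:frag_len]
            fragment_ids.add(prot)

        # over-splitting into 2-3 orthogroups
        do_split = (fam in split_families) if split_families is not None \
            else bool(rng.random() < split_prob)
        member_species = sorted(members)
        bait_present = [sp for sp in bait_species if sp in members]
        if do_split and len(member_species) >= 2 and len(bait_present) >= 2:
            # every split part keeps >=1 bait member: over-split orthogroups are
            # only discoverable downstream because curated baits span them
            n_parts = int(rng.integers(2, min(3, len(bait_present)) + 1))
            parts: list[list[str]] = [[] for _ in range(n_parts)]
            for i, sp in enumerate(bait_present):
                parts[i % n_parts].append(sp)
            for sp in member_species:
                if sp not in bait_present:
                    parts[int(rng.integers(n_parts))].append(sp)
            parts = [sorted(p) for p in parts]
        else:
            parts = [member_species]

        og_ids = []
        for part in parts:
            og = f"OG{og_counter:07d}"
            og_counter += 1
            og_ids.append(og)
            groups[og] = {sp: [members[sp]] for sp in part}
        truths.append(PlantedFamilyTruth(
            family_id=fam, category=category,
            present_in={sp for sp in present if members[sp] not in fragment_ids},
            split_into=og_ids, fragment_members=fragment_ids))

    busco = {sp: float(np.round(rng.uniform(*busco_range), 1)) for sp in species}
    busco.update({sp: float(v) for sp, v in (busco_fail or {}).items()})
    table = OrthogroupTable(species=species, groups=groups, protein_lengths=lengths)
    return ProteomeSimResult(roster=roster, truths=truths, table=table,
                             baits=baits, busco_scores=busco, sequences=sequences)


def truth_presence_matrix(truths: Sequence[PlantedFamilyTruth],
                          roster: Mapping[str, str],
                          clade_order: Sequence[str],
                          outgroups: Sequence[str] = (),
                          retained_species: set[str] | None = None):
    """Expected clade-level presence from planted truth, restricted to retained species."""
    import pandas as pd

    retained = set(roster) if retained_species is None else set(retained_species)
    cols = [*outgroups, *clade_order]
    rows = {}
    order = {c: i for i, c in enumerate(BAIT_CATEGORIES)}
    for t in sorted(truths, key=lambda t: (order[t.category], t.family_id)):
        present = t.present_in & retained
        row = []
        for sp in outgroups:
            row.append(sp in present)
        for clade in clade_order:
            row.append(any(roster[sp] == clade and sp not in outgroups
                           for sp in present))
        rows[t.family_id] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)
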