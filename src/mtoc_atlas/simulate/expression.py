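"""Stage-programmed synthetic FPKM tables.

Each gene carries a baseline abundance and a fold-change profile over the
four lifecycle timepoints; observed FPKM is baseline x profile x
multiplicative lognormal noise (unit mean, given CV). Default group programs
follow the lifecycle transcription pattern: cilium genes peak at the
ciliogenesis stage (17.5 h), centriole genes are elevated during mitosis and
ciliogenesis (13 h and 17.5 h), accessory/distal-maturation genes rise at
ciliogenesis, housekeeping genes are flat, and stage-unique genes fire at a
single stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ..expression import STAGES, ExpressionTable, GeneGroup

#: Default fold-change programs per group label, over STAGES.
GROUP_PROFILES: dict[str, tuple[float, float, float, float]] = {
    "cilium": (1.0, 1.0, 8.0, 2.0),
    "centriole": (1.0, 4.0, 4.0, 1.0),
    "accessory": (1.0, 1.0, 6.0, 2.0),
    "housekeeping": (1.0, 1.0, 1.0, 1.0),
    "stage_unique:1.5h": (8.0, 1.0, 1.0, 1.0),
    "stage_unique:13h": (1.0, 8.0, 1.0, 1.0),
    "stage_unique:17.5h": (1.0, 1.0, 8.0, 1.0),
    "stage_unique:22h": (1.0, 1.0, 1.0, 8.0),
}


@dataclass
class ExpressionTruth:
    """Ground-truth program for one gene."""

    gene_id: str
    group: str
    baseline: float                                   # FPKM
    fold_change_profile: tuple[float, float, float, float]
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if len(self.fold_change_profile) != len(STAGES):
            raise ValueError(f"profile must cover the {len(STAGES)} stages {STAGES}")
        if any(f <= 0 for f in self.fold_change_profile):
            raise ValueError("fold-change entries must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    def stage_means(self) -> np.ndarray:
        return self.baseline * np.asarray(self.fold_change_profile)


def default_truths(n_per_group: Mapping[str, int], noise_cv: float = 0.3,
                   baseline_range: tuple[float, float] = (5.0, 200.0),
                   seed: int = 0) -> list[ExpressionTruth]:
    """Build gene programs from per-group counts using the default profiles."""
    rng = np.random.default_rng(seed)
    truths = []
    for group in n_per_group:
        if group not in GROUP_PROFILES:
            raise ValueError(f"unknown group {group!r}; known: {sorted(GROUP_PROFILES)}")
        for i in range(n_per_group[group]):
            truths.append(ExpressionTruth(
                gene_id=f"{group.replace(':', '_')}_{i:03d}", group=group,
                baseline=float(np.round(rng.uniform(*baseline_range), 2)),
                fold_change_profile=GROUP_PROFILES[group], noise_cv=noise_cv,
                seed=seed))
    return truths


def gen_expression_table(truths: Sequence[ExpressionTruth], n_replicates: int = 3,
                         seed: int = 0) -> tuple[ExpressionTable, list[GeneGroup]]:
    """Sample an FPKM table from gene programs.

    FPKM(gene, stage, rep) = baseline x profile[stage] x lognormal(CV) with
    the lognormal parameterised to unit mean, so with noise_cv = 0 the table
    is exactly the programmed stage means in every replicate.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    cols = pd.MultiIndex.from_product(
        [list(STAGES), [f"rep{r + 1}" for r in range(n_replicates)]],
        names=["stage", "replicate"])
    rows = {}
    for t in truths:
        means = np.repeat(t.stage_means(), n_replicates)
        if t.noise_cv > 0:
            sigma = np.sqrt(np.log1p(t.noise_cv ** 2))
            noise = rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma, size=means.size)
        else:
            noise = 1.0
        rows[t.gene_id] = means * noise
    data = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    groups: dict[str, set[str]] = {}
    for t in truths:
        groups.setdefault(t.group, set()).add(t.gene_id)
    return (ExpressionTable(data=data),
            [GeneGroup(name=g, members=m) for g, m in sorted(groups.items())])


def write_expression_run(table: ExpressionTable, groups: Sequence[GeneGroup],
                         truths: Sequence[ExpressionTruth], outdir: str | Path) -> Path:
    """Write the FPKM CSV, group membership TSV, and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "fpkm.csv")
    with (outdir / "gene_groups.tsv").open("w") as fh:
        for g in groups:
            for gene in sorted(g.members):
                fh.write(f"{g.name}\t{gene}\n")
    with (outdir / "truth.json").open("w") as fh:
        json.dump({"genes": [asdict(t) for t in truths]}, fh, indent=1, sort_keys=True)
    return outdir
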