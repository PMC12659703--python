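"""End-to-end synthetic runs: simulate -> conserve / morph / expr -> report.

A single YAML config drives every stage; each run writes a provenance
manifest (parameters, seed, SHA-256 of every data output) so results are
reproducible and auditable. Data outputs are deterministic for a fixed
seed/config; the manifest carries the only timestamp.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

logger = logging.getLogger(__name__)

DEFAULT_ROSTER: dict[str, str] = {
    # two outgroups plus four clades x three chytrid-grade species
    "Hsap": "outgroup", "Ngru": "outgroup",
    "Chy1": "Chytridiomycota", "Chy2": "Chytridiomycota", "Chy3": "Chytridiomycota",
    "Mon1": "Monoblepharidomycota", "Mon2": "Monoblepharidomycota", "Mon3": "Monoblepharidomycota",
    "Bla1": "Blastocladiomycota", "Bla2": "Blastocladiomycota", "Bla3": "Blastocladiomycota",
    "Neo1": "Neocallimastigomycota", "Neo2": "Neocallimastigomycota", "Neo3": "Neocallimastigomycota",
}
DEFAULT_OUTGROUPS = ("Hsap", "Ngru")
DEFAULT_CLADE_ORDER = ("Chytridiomycota", "Monoblepharidomycota",
                       "Blastocladiomycota", "Neocallimastigomycota")


@dataclass
class RunConfig:
    """Validated configuration for an end-to-end synthetic run."""

    seed: int = 0
    outdir: str = "mtoc_atlas_run"
    stages: dict[str, bool] = field(default_factory=lambda: {
        "proteomes": True, "conservation": True,
        "volumes": True, "morphometry": True, "expression": True})
    conservation: dict[str, Any] = field(default_factory=lambda: {
        "busco_threshold": 80.0, "length_fraction": 0.5,
        "n_families": 10, "split_prob": 0.25, "fragment_prob": 0.25})
    morphometry: dict[str, Any] = field(default_factory=lambda: {
        "n_scenes": 3, "length_nm": 2000.0, "width_nm": 200.0,
        "expansion_factor": 5.5, "psf_sigma_nm": 90.0, "voxel_size_nm": 130.0,
        "snr": 10.0, "linescan_width_px": 5})
    expression: dict[str, Any] = field(default_factory=lambda: {
        "fpkm_threshold": 1.0, "n_replicates": 3, "noise_cv": 0.3,
        "n_per_group": {"cilium": 12, "centriole": 12, "accessory": 8,
                        "housekeeping": 12}})

    _RANGES = {
        ("conservation", "busco_threshold"): (0.0, 100.0),
        ("conservation", "length_fraction"): (1e-9, 1.0),
        ("expression", "fpkm_threshold"): (0.0, float("inf")),
        ("morphometry", "expansion_factor"): (1.0, float("inf")),
    }

    def validate(self) -> None:
        for (block, key), (lo, hi) in self._RANGES.items():
            val = getattr(self, block)[key]
            if not lo <= float(val) <= hi:
                raise ValueError(f"{block}.{key} = {val} outside [{lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        known = {"seed", "outdir", "stages", "conservation", "morphometry", "expression"}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        for key in ("seed", "outdir"):
            if key in raw:
                setattr(cfg, key, raw[key])
        for block in ("stages", "conservation", "morphometry", "expression"):
            if block in raw:
                current = getattr(cfg, block)
                bad = sorted(set(raw[block]) - set(current))
                if bad:
                    raise ValueError(f"unknown config keys in {block!r}: {bad}")
                current.update(raw[block])
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> Path:
    """Execute enabled stages in order and write a provenance manifest.

    On a stage failure, that stage's partial outputs are quarantined under
    ``failed/`` and the error re-raised (nonzero exit through the CLI).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items() if not k.startswith("_")},
        "created": datetime.now(timezone.utc).isoformat(),
        "stages": {},
        "outputs": {},
    }
    order = ["proteomes", "conservation", "volumes", "morphometry", "expression"]
    runners = {
        "proteomes": _stage_proteomes,
        "conservation": _stage_conservation,
        "volumes": _stage_volumes,
        "morphometry": _stage_morphometry,
        "expression": _stage_expression,
    }
    state: dict[str, Any] = {}
    for stage in order:
        if not config.stages.get(stage, False):
            manifest["stages"][stage] = "skipped"
            continue
        stage_dir = outdir / stage
        try:
            runners[stage](config, stage_dir, state)
            manifest["stages"][stage] = "ok"
        except Exception:
            logger.exception("stage %s failed; quarantining partial outputs", stage)
            failed = outdir / "failed"
            failed.mkdir(exist_ok=True)
            if stage_dir.exists():
                shutil.move(str(stage_dir), str(failed / stage))
            manifest["stages"][stage] = "failed"
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
            raise
    for f in sorted(outdir.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][str(f.relative_to(outdir))] = _sha256(f)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir


# -- stages ------------------------------------------------------------------

def _stage_proteomes(config: RunConfig, stage_dir: Path, state: dict) -> None:
    from .simulate import gen_proteome_set

    p = config.conservation
    sim = gen_proteome_set(
        roster=DEFAULT_ROSTER, n_families=int(p["n_families"]),
        split_prob=float(p["split_prob"]), fragment_prob=float(p["fragment_prob"]),
        seed=config.seed, bait_species=list(DEFAULT_OUTGROUPS),
        busco_fail={"Neo3": 62.0})
    sim.write(stage_dir)
    state["proteomes"] = sim


def _stage_conservation(config: RunConfig, stage_dir: Path, state: dict) -> None:
    from .conservation import (binarize, filter_by_busco, merge_all,
                               render_matrix, rollup_clades, write_provenance)

    sim = state["proteomes"]
    p = config.conservation
    stage_dir.mkdir(parents=True, exist_ok=True)
    retained = filter_by_busco(sim.busco_scores, float(p["busco_threshold"]),
                               species=sim.table.species)
    table = sim.table.restrict_species(sorted(retained))
    merged = merge_all(sim.baits, table, fraction=float(p["length_fraction"]))
    species_matrix = binarize(merged, table.species)
    clade_matrix = rollup_clades(
        species_matrix, {sp: cl for sp, cl in sim.roster.items() if cl != "outgroup"},
        DEFAULT_CLADE_ORDER,
        outgroups=[s for s in DEFAULT_OUTGROUPS if s in retained])
    species_matrix.to_tsv(stage_dir / "conservation_species.tsv")
    clade_matrix.to_tsv(stage_dir / "conservation_clades.tsv")
    write_provenance(merged, stage_dir / "provenance.tsv")
    render_matrix(clade_matrix, stage_dir / "conservation_dotplot.svg")
    state["clade_matrix"] = clade_matrix


def _stage_volumes(config: RunConfig, stage_dir: Path, state: dict) -> None:
    from .simulate import CentrioleSpec, SceneTruth, gen_centriole_volume

    p = config.morphometry
    stage_dir.mkdir(parents=True, exist_ok=True)
    voxel = float(p["voxel_size_nm"])
    E = float(p["expansion_factor"])
    L, W = float(p["length_nm"]), float(p["width_nm"])
    shape = (24,
             int(np.ceil(3 * W * E / voxel)) + 16,
             int(np.ceil((L * E) / voxel)) + 24)
    center = tuple(((np.asarray(shape) - 1) * voxel / 2))
    read_sigma = 1.0 / float(p["snr"])
    truths = []
    for i in range(int(p["n_scenes"])):
        truth = SceneTruth(
            centrioles=[CentrioleSpec(length=L, width=W,
                                      axis_unit_vector=(0.0, 0.0, 1.0),
                                      center=center)],
            expansion_factor=E, psf_sigma=float(p["psf_sigma_nm"]),
            noise_model="gauss_poisson", noise_params={"read_sigma": read_sigma},
            seed=config.seed + i)
        gen_centriole_volume(truth, voxel, shape,
                             stage_dir / f"scene_{i:02d}.tif",
                             stage_dir / f"scene_{i:02d}.json")
        truths.append(truth)
    state["volume_truths"] = truths
    state["volume_dir"] = stage_dir
    state["volume_shape"] = shape


def _stage_morphometry(config: RunConfig, stage_dir: Path, state: dict) -> None:
    import pandas as pd

    from .morphometry import aspect_ratio, measure_cylinder, summarize
    from .simulate import read_volume

    p = config.morphometry
    stage_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    E = float(p["expansion_factor"])
    for i, truth in enumerate(state["volume_truths"]):
        vol, voxel = read_volume(state["volume_dir"] / f"scene_{i:02d}.tif")
        c = truth.centrioles[0]
        length_exp, width_exp = measure_cylinder(
            vol, voxel, np.asarray(c.center), np.asarray(c.axis_unit_vector),
            scan_half_length=c.length * E / 2 + 4 * truth.psf_sigma + 500.0,
            scan_half_width=c.width * E / 2 + 4 * truth.psf_sigma + 500.0,
            width_px=int(p["linescan_width_px"]))
        rows.append({
            "scene": i, "modality": "U-ExM", "stage": "mitotic_sporangium",
            "length_nm": length_exp / E, "width_nm": width_exp / E,
            "aspect_ratio": aspect_ratio(length_exp, width_exp),
            "true_length_nm": c.length, "true_width_nm": c.width,
        })
    df = pd.DataFrame(rows)
    df.to_csv(stage_dir / "measurements.csv", index=False)
    summary = []
    for col in ("length_nm", "width_nm", "aspect_ratio"):
        s = summarize(df[col])
        summary.append({"quantity": col, "n": s.n, "mean": s.mean,
                        "std": s.std, "sem": s.sem})
    pd.DataFrame(summary).to_csv(stage_dir / "summary.csv", index=False)
    state["morphometry"] = df


def _stage_expression(config: RunConfig, stage_dir: Path, state: dict) -> None:
    from .expression import (clustvis_transform, cluster_rows_cols,
                             expressed_sets, group_stage_means, render_heatmap,
                             venn_partition)
    from .simulate import default_truths, gen_expression_table, write_expression_run

    p = config.expression
    truths = default_truths(p["n_per_group"], noise_cv=float(p["noise_cv"]),
                            seed=config.seed)
    table, groups = gen_expression_table(truths, n_replicates=int(p["n_replicates"]),
                                         seed=config.seed)
    write_expression_run(table, groups, truths, stage_dir)
    sets = expressed_sets(table, threshold=float(p["fpkm_threshold"]))
    venn_partition(sets).to_frame().to_csv(stage_dir / "venn_regions.tsv",
                                           sep="\t", index=False)
    means = group_stage_means(table, groups)
    transformed = clustvis_transform(means).matrix
    transformed.to_csv(stage_dir / "group_means_transformed.csv")
    clusters = cluster_rows_cols(transformed, cluster_cols=True)
    (stage_dir / "group_dendrogram.nwk").write_text(
        clusters.row_newick(list(transformed.index)) + "\n")
    render_heatmap(transformed, stage_dir / "group_heatmap.svg",
                   row_order=clusters.row_order, col_order=clusters.col_order)
    state["expression"] = transformed
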