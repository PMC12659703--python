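"""Shared fixtures: small planted rosters and rendered scenes."""

from __future__ import annotations

import numpy as np
import pytest

from mtoc_atlas.simulate import CentrioleSpec, SceneTruth, gen_proteome_set, render_scene

ROSTER = {
    "Hsap": "outgroup", "Ngru": "outgroup",
    "Chy1": "CladeA", "Chy2": "CladeA", "Chy3": "CladeA",
    "Mon1": "CladeB", "Mon2": "CladeB", "Mon3": "CladeB",
    "Bla1": "CladeC", "Bla2": "CladeC", "Bla3": "CladeC",
    "Neo1": "CladeD", "Neo2": "CladeD", "Neo3": "CladeD",
}
OUTGROUPS = ("Hsap", "Ngru")
CLADE_ORDER = ("CladeA", "CladeB", "CladeC", "CladeD")


@pytest.fixture(scope="session")
def roster() -> dict[str, str]:
    return dict(ROSTER)


@pytest.fixture(scope="session")
def clean_sim():
    """Planted families with no splits, fragments or losses."""
    return gen_proteome_set(ROSTER, n_families=6, split_prob=0.0, fragment_prob=0.0,
                            seed=11, bait_species=list(OUTGROUPS))


@pytest.fixture(scope="session")
def messy_sim():
    """Planted families with splits, fragments and clade-structured loss."""
    return gen_proteome_set(
        ROSTER, n_families=12,
        loss_spec={"FAM000": ["CladeD"], "FAM001": ["CladeB", "CladeC"]},
        split_prob=0.4, fragment_prob=0.4, seed=5, bait_species=list(OUTGROUPS))


def make_barrel_scene(length=2000.0, width=200.0, expansion=1.0, psf=60.0,
                      voxel=50.0, noise="none", read_sigma=0.0, seed=0):
    """Render one axis-aligned barrel with the volume sized to fit margins."""
    margin = 4 * psf + 8 * voxel
    hx = length * expansion / 2 + margin
    hy = width * expansion / 2 + margin
    shape = (25, 2 * int(np.ceil(hy / voxel)) + 3, 2 * int(np.ceil(hx / voxel)) + 3)
    center = tuple((np.asarray(shape) - 1) * voxel / 2)
    truth = SceneTruth(
        centrioles=[CentrioleSpec(length=length, width=width,
                                  axis_unit_vector=(0.0, 0.0, 1.0), center=center)],
        expansion_factor=expansion, psf_sigma=psf, noise_model=noise,
        noise_params={"read_sigma": read_sigma}, seed=seed)
    vol = render_scene(truth, voxel, shape)
    return vol, truth, np.asarray(center), voxel, (hx, hy)
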