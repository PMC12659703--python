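"""Synthetic 3D centriole-scene volumes with known geometry.

Renders centrioles as cylinders at their physically expanded size (length and
width scaled by the gel expansion factor), convolves with an isotropic
Gaussian point-spread proxy, and adds shot + read noise. Optional curved
microtubule-bundle filaments emanate from an MTOC center. Every volume pairs
with a truth JSON that round-trips the full scene description.

Axis order is (z, y, x), 0-based; physical coordinates are nm. Voxels are
isotropic by default; anisotropic (z != xy) spacing is supported because real
confocal stacks use coarser z-spacing (0.4 um) than in-plane sampling.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
from scipy import ndimage


@dataclass
class CentrioleSpec:
    """One centriole: pre-expansion size (nm), unit axis and center in nm (z, y, x)."""

    length: float
    width: float
    axis_unit_vector: tuple[float, float, float]
    center: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ValueError("centriole length and width must be positive")
        norm = float(np.linalg.norm(self.axis_unit_vector))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"axis vector must have unit norm, got |v| = {norm}")


@dataclass
class SceneTruth:
    """Full ground truth of one rendered scene (round-trips through JSON)."""

    centrioles: list[CentrioleSpec]
    expansion_factor: float = 1.0
    spindle_axis_unit_vector: tuple[float, float, float] | None = None
    n_bundles: int = 0
    psf_sigma: float = 90.0                     # nm
    noise_model: str = "gauss_poisson"
    noise_params: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.expansion_factor < 1:
            raise ValueError("expansion_factor must be >= 1")
        if self.n_bundles < 0:
            raise ValueError("n_bundles must be >= 0")
        if self.spindle_axis_unit_vector is not None:
            norm = float(np.linalg.norm(self.spindle_axis_unit_vector))
            if abs(norm - 1.0) > 1e-9:
                raise ValueError("spindle axis must have unit norm")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        with Path(path).open("w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SceneTruth":
        with Path(path).open() as fh:
            d = json.load(fh)
        cents = [CentrioleSpec(length=c["length"], width=c["width"],
                               axis_unit_vector=tuple(c["axis_unit_vector"]),
                               center=tuple(c["center"]))
                 for c in d.pop("centrioles")]
        sax = d.pop("spindle_axis_unit_vector")
        return cls(centrioles=cents,
                   spindle_axis_unit_vector=tuple(sax) if sax is not None else None,
                   **d)


def _voxel_triple(voxel_size: float | Sequence[float]) -> np.ndarray:
    v = np.atleast_1d(np.asarray(voxel_size, dtype=float))
    if v.size == 1:
        v = np.repeat(v, 3)
    if v.size != 3 or np.any(v <= 0):
        raise ValueError("voxel_size must be a positive scalar or (z, y, x) triple")
    return v


def render_scene(truth: SceneTruth, voxel_size: float | Sequence[float],
                 shape: tuple[int, int, int], amplitude: float = 1.0) -> np.ndarray:
    """Render a scene to a float32 (z, y, x) volume.

    Each centriole becomes a filled cylinder of expanded size
    ``length * E`` x ``width * E``, blurred by an isotropic Gaussian of
    ``psf_sigma`` nm. Bundles (if any) are curved tubes growing outward from
    the first centriole's center. Noise (per ``noise_model``) is added last.
    A cylinder poking outside the volume is an error naming the centriole.
    """
    voxel = _voxel_triple(voxel_size)
    shape = tuple(int(s) for s in shape)
    E = truth.expansion_factor
    rng = np.random.default_rng(truth.seed)

    zz, yy, xx = np.meshgrid(*(np.arange(s) * v for s, v in zip(shape, voxel)),
                             indexing="ij")
    coords = np.stack([zz, yy, xx], axis=-1)           # nm
    vol = np.zeros(shape, dtype=np.float64)
    extent = (np.asarray(shape) - 1) * voxel

    for i, c in enumerate(truth.centrioles):
        L, R = c.length * E, c.width * E / 2.0
        if R < 1.5 * min(voxel):
            raise ValueError(
                f"centriole {i}: rendered width {2 * R:g} nm spans fewer than 3 voxels")
        axis = np.asarray(c.axis_unit_vector, dtype=float)
        center = np.asarray(c.center, dtype=float)
        for end in (center - axis * L / 2, center + axis * L / 2):
            if np.any(end - R < 0) or np.any(end + R > extent):
                raise ValueError(
                    f"centriole {i} extends outside the volume (endpoint {end} nm, "
                    f"radius {R:g} nm, volume extent {extent} nm)")
        rel = coords - center
        t = rel @ axis                                  # axial coordinate
        radial = np.linalg.norm(rel - t[..., None] * axis, axis=-1)
        # anti-aliased edges: one-voxel linear ramp centered on the true
        # boundary, so the half-intensity level sits exactly at the surface
        w = float(min(voxel))
        axial_cov = np.clip((L / 2 - np.abs(t)) / w + 0.5, 0.0, 1.0)
        radial_cov = np.clip((R - radial) / w + 0.5, 0.0, 1.0)
        vol += amplitude * axial_cov * radial_cov

    if truth.n_bundles:
        vol += _render_bundles(truth, coords, extent, amplitude, rng)

    if truth.psf_sigma > 0:
        vol = ndimage.gaussian_filter(vol, sigma=truth.psf_sigma / voxel)

    vol = _apply_noise(vol, truth, rng)
    return vol.astype(np.float32)


def _render_bundles(truth: SceneTruth, coords: np.ndarray, extent: np.ndarray,
                    amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Curved tube filaments radiating from the first centriole's center."""
    origin = np.asarray(truth.centrioles[0].center, dtype=float)
    radius = truth.noise_params.get("bundle_radius", 120.0) * truth.expansion_factor / 5.5
    reach = 0.45 * float(extent.min())
    out = np.zeros(coords.shape[:-1])
    for _ in range(truth.n_bundles):
        d0 = rng.normal(size=3)
        d0 /= np.linalg.norm(d0)
        bend = rng.normal(scale=0.3, size=3)
        # quadratic bezier control points: origin -> mid (bent) -> tip
        tip = np.clip(origin + d0 * reach, radius, extent - radius)
        mid = np.clip(origin + d0 * reach / 2 + bend * reach / 4, radius, extent - radius)
        ts = np.linspace(0, 1, 40)
        pts = ((1 - ts)[:, None] ** 2 * origin + 2 * (ts * (1 - ts))[:, None] * mid
               + (ts ** 2)[:, None] * tip)
        for p in pts:
            dist2 = ((coords - p) ** 2).sum(axis=-1)
            out = np.maximum(out, 0.7 * amplitude * (dist2 <= radius ** 2))
    return out


def _apply_noise(vol: np.ndarray, truth: SceneTruth,
                 rng: np.random.Generator) -> np.ndarray:
    if truth.noise_model == "none":
        return vol
    if truth.noise_model == "gauss_poisson":
        photons = truth.noise_params.get("photons_per_unit", 0.0)
        read_sigma = truth.noise_params.get("read_sigma", 0.0)
        out = vol
        if photons > 0:
            out = rng.poisson(np.clip(out, 0, None) * photons).astype(float) / photons
        if read_sigma > 0:
            out = out + rng.normal(scale=read_sigma, size=out.shape)
        return out
    raise ValueError(f"unknown noise model {truth.noise_model!r}")


def gen_centriole_volume(truth: SceneTruth, voxel_size: float | Sequence[float],
                         shape: tuple[int, int, int],
                         out_tiff: str | Path, out_json: str | Path,
                         amplitude: float = 1.0) -> tuple[Path, Path]:
    """Render a scene and write the TIFF volume plus its truth JSON.

    The TIFF is 32-bit float with ImageJ-style metadata carrying the voxel
    size (``spacing`` for z in um, x/y resolution in pixels per um).
    """
    voxel = _voxel_triple(voxel_size)
    vol = render_scene(truth, voxel, shape, amplitude=amplitude)
    out_tiff, out_json = Path(out_tiff), Path(out_json)
    tifffile.imwrite(
        out_tiff, vol, imagej=True,
        resolution=(1000.0 / voxel[2], 1000.0 / voxel[1]),
        metadata={"spacing": voxel[0] / 1000.0, "unit": "um", "axes": "ZYX"},
    )
    truth.to_json(out_json)
    return out_tiff, out_json


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a TIFF volume and its (z, y, x) voxel size in nm from ImageJ metadata."""
    with tifffile.TiffFile(str(path)) as tf:
        vol = tf.asarray()
        meta = tf.imagej_metadata or {}
        spacing_um = float(meta.get("spacing", 1.0))
        page = tf.pages[0]
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
        vx = 1000.0 * xres[1] / xres[0]
        vy = 1000.0 * yres[1] / yres[0]
    return vol, np.array([spacing_um * 1000.0, vy, vx])
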