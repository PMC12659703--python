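"""Centriole and microtubule-architecture morphometry.

Quantitative measurement chain for expansion-microscopy (U-ExM) and TEM data:
linescan extraction from 3D volumes, background-anchored intensity
normalization, FWHM extent measurement, aspect ratio, expansion factor,
centriole-pair length asymmetry, centriole-to-spindle-axis angles,
microtubule-bundle classification, and mean +/- SEM summaries.

Conventions: volumes are (z, y, x) arrays; physical coordinates are nm
3-vectors in the same (z, y, x) order; angles are degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage


# ---------------------------------------------------------------------------
# Linescans

@dataclass
class LineScan:
    """Intensity profile sampled along a line segment in a single z-plane."""

    samples: np.ndarray          # ordered intensities, arbitrary units
    spacing: float               # nm per sample
    width_px: int                # perpendicular averaging width, pixels
    endpoints: tuple[np.ndarray, np.ndarray]   # (z, y, x) nm
    z_plane: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < 2:
            raise ValueError("a linescan needs at least 2 samples")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.width_px < 1:
            raise ValueError("width_px must be >= 1")

    @property
    def positions(self) -> np.ndarray:
        """Sample positions along the line in nm."""
        return np.arange(self.samples.size) * self.spacing


def _as_zyx_voxel(voxel_size: float | Sequence[float]) -> np.ndarray:
    v = np.atleast_1d(np.asarray(voxel_size, dtype=float))
    if v.size == 1:
        v = np.repeat(v, 3)
    if v.size != 3 or np.any(v <= 0):
        raise ValueError(f"voxel_size must be a positive scalar or (z, y, x) triple, got {voxel_size!r}")
    return v


def extract_linescan(volume: np.ndarray, voxel_size: float | Sequence[float],
                     p0: Sequence[float], p1: Sequence[float],
                     width_px: int = 1) -> LineScan:
    """Sample an intensity profile between two in-plane points of a 3D volume.

    Mirrors a Fiji line scan: both endpoints must lie in the same z-plane
    (measurements are taken in the single plane of best focus); intensities
    are bilinearly interpolated in that plane at <= half-voxel spacing and
    averaged over ``width_px`` one-pixel-spaced perpendicular offsets
    centered on the line.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError("volume must be 3D (z, y, x)")
    voxel = _as_zyx_voxel(voxel_size)
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    if p0.shape != (3,) or p1.shape != (3,):
        raise ValueError("endpoints must be (z, y, x) nm 3-vectors")
    if np.allclose(p0, p1):
        raise ValueError("endpoints coincide")
    z0, z1 = p0[0] / voxel[0], p1[0] / voxel[0]
    if abs(z0 - z1) > 0.5:
        raise ValueError(
            f"endpoints lie in different z-planes (z = {p0[0]:g} nm vs {p1[0]:g} nm); "
            "linescans are taken in a single z-plane")
    zi = int(round((z0 + z1) / 2))
    if not 0 <= zi < volume.shape[0]:
        raise ValueError(f"z-plane {zi} outside volume of depth {volume.shape[0]}")
    for name, p in (("p0", p0), ("p1", p1)):
        idx = p / voxel
        if np.any(idx < 0) or np.any(idx > np.asarray(volume.shape) - 1):
            raise ValueError(f"endpoint {name} at {p} nm falls outside the volume")

    plane = volume[zi]
    # In-plane pixel coordinates (y, x); assume square in-plane pixels for the
    # perpendicular offset direction (checked below).
    if not math.isclose(voxel[1], voxel[2], rel_tol=1e-9):
        raise ValueError("in-plane voxel size must be isotropic for linescans")
    px = voxel[1]
    a = np.array([p0[1], p0[2]]) / px
    b = np.array([p1[1], p1[2]]) / px
    length_px = float(np.linalg.norm(b - a))
    n_samples = max(2, int(math.ceil(length_px * 2)) + 1)   # <= half-voxel spacing
    t = np.linspace(0.0, 1.0, n_samples)
    line = a[None, :] + t[:, None] * (b - a)[None, :]
    direction = (b - a) / length_px
    perp = np.array([-direction[1], direction[0]])
    offsets = (np.arange(width_px) - (width_px - 1) / 2.0)
    profiles = np.empty((width_px, n_samples))
    for k, off in enumerate(offsets):
        pts = line + off * perp[None, :]
        profiles[k] = ndimage.map_coordinates(plane, pts.T, order=1, mode="nearest")
    samples = profiles.mean(axis=0)
    spacing = length_px * px / (n_samples - 1)
    return LineScan(samples=samples, spacing=spacing, width_px=width_px,
                    endpoints=(p0, p1), z_plane=zi)


def normalize_linescan(ls: LineScan | np.ndarray) -> np.ndarray:
    """Background-subtract the minimum gray value and divide by the largest difference.

    Output spans [0, 1] exactly; a flat profile has zero dynamic range and is
    an error rather than a silent NaN.
    """
    x = ls.samples if isinstance(ls, LineScan) else np.asarray(ls, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        raise ValueError("zero dynamic range: linescan is flat")
    return (x - lo) / (hi - lo)


def measure_extent(ls: LineScan) -> float:
    """FWHM extent (nm) of the normalized profile.

    Operational replacement for a manual endpoint call: the extent is the
    distance between the two *outermost* crossings of the half-height level
    of the min/max-normalized profile, with linear interpolation between
    samples. Requires the profile to rise above half height and return below
    it on both flanks.
    """
    y = normalize_linescan(ls)
    half = 0.5
    above = y >= half
    if not above.any():
        raise ValueError("profile never reaches half height")
    first = int(np.argmax(above))
    last = int(len(y) - 1 - np.argmax(above[::-1]))
    if first == 0 or last == len(y) - 1:
        raise ValueError("no half-height crossing on one side; profile truncated")
    # interpolate the crossing position on each flank
    x_left = (first - 1) + (half - y[first - 1]) / (y[first] - y[first - 1])
    x_right = last + (half - y[last]) / (y[last + 1] - y[last])
    return float((x_right - x_left) * ls.spacing)


# ---------------------------------------------------------------------------
# Scalar measurements

@dataclass
class CentrioleMeasurement:
    """One centriole's length/width (nm) with role, lifecycle stage and modality."""

    length: float
    width: float
    role: str                     # "basal_body" | "centriole"
    stage: str
    modality: str                 # "U-ExM" | "TEM"
    aspect_ratio: float = field(init=False)

    def __post_init__(self) -> None:
        if self.role not in ("basal_body", "centriole"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.modality not in ("U-ExM", "TEM"):
            raise ValueError(f"unknown modality {self.modality!r}")
        self.aspect_ratio = aspect_ratio(self.length, self.width)


def aspect_ratio(length: float, width: float) -> float:
    """Barrel length divided by barrel width (dimensionless)."""
    if length <= 0 or width <= 0:
        raise ValueError(f"length and width must be positive, got {length}, {width}")
    return length / width


def pair_relative_length(l1: float, l2: float) -> float:
    """Length asymmetry of a centriole pair: min/max, in (0, 1]; 1 = equal pair."""
    if l1 <= 0 or l2 <= 0:
        raise ValueError(f"lengths must be positive, got {l1}, {l2}")
    return min(l1, l2) / max(l1, l2)


@dataclass
class CentriolePair:
    lengths: tuple[float, float]      # nm
    orientation: str                  # "parallel" | "orthogonal"
    stage: str

    def __post_init__(self) -> None:
        if self.orientation not in ("parallel", "orthogonal"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def relative_length(self) -> float:
        return pair_relative_length(*self.lengths)


@dataclass
class SummaryStat:
    n: int
    mean: float
    std: float

    @property
    def sem(self) -> float:
        return self.std / math.sqrt(self.n)

    def __str__(self) -> str:
        return f"{self.mean:.3g} ± {self.sem:.2g} (mean ± SEM, n={self.n})"


def summarize(values: Iterable[float]) -> SummaryStat:
    """Mean, sample standard deviation (n-1 denominator) and SEM."""
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty list")
    std = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return SummaryStat(n=int(x.size), mean=float(np.mean(x)), std=std)


def expansion_factor(exm_widths: Sequence[float], tem_widths: Sequence[float],
                     method: str = "ratio_of_means") -> SummaryStat:
    """Gel expansion factor from raw centriole widths.

    Point estimate is the ratio of the mean U-ExM width to the mean TEM width
    (``method="mean_of_ratios"`` pairs sorted samples instead); the spread is
    the first-order propagation of the two sample standard deviations,
    reported as mean +/- std in the SummaryStat (n = n_exm + n_tem).
    """
    exm = np.asarray(exm_widths, dtype=float)
    tem = np.asarray(tem_widths, dtype=float)
    if exm.size == 0 or tem.size == 0:
        raise ValueError("both width lists must be nonempty")
    mx, my = float(exm.mean()), float(tem.mean())
    sx = float(np.std(exm, ddof=1)) if exm.size > 1 else 0.0
    sy = float(np.std(tem, ddof=1)) if tem.size > 1 else 0.0
    if method == "ratio_of_means":
        est = mx / my
    elif method == "mean_of_ratios":
        n = min(exm.size, tem.size)
        est = float(np.mean(np.sort(exm)[:n] / np.sort(tem)[:n]))
    else:
        raise ValueError(f"unknown method {method!r}")
    rel = math.sqrt((sx / mx) ** 2 + (sy / my) ** 2) if mx and my else 0.0
    return SummaryStat(n=int(exm.size + tem.size), mean=est, std=est * rel)


# ---------------------------------------------------------------------------
# Angles

def line_angle_deg(p0: Sequence[float], p1: Sequence[float]) -> float:
    """Angle of a 2D line to the horizontal in (-180, 180] degrees (Fiji convention).

    Points are (y, x); the angle is measured counter-clockwise with y up, so
    it matches what an annotator reads off an image measurement tool.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    if np.allclose(d, 0):
        raise ValueError("zero-length line")
    ang = math.degrees(math.atan2(-d[0], d[1]))   # image y-axis points down
    if ang <= -180.0:
        ang += 360.0
    return ang


def angle_to_spindle(centriole_line: tuple[Sequence[float], Sequence[float]],
                     spindle_line: tuple[Sequence[float], Sequence[float]]) -> float:
    """Angle (degrees, in [0, 90]) between a centriole axis and the spindle pole-pole axis.

    Each line's angle to horizontal is taken in (-180, 180]; the result is
    ``||theta_c| - |theta_s||``, folded to 180 - x when it exceeds 90 so that
    a line is compared with the spindle *axis*, not a directed vector.
    """
    tc = line_angle_deg(*centriole_line)
    ts = line_angle_deg(*spindle_line)
    a = abs(abs(tc) - abs(ts))
    if a > 90.0:
        a = 180.0 - a
    return a


@dataclass
class SpindleAngleRecord:
    """Angles of both pair members to the spindle axis; member "1" has the smaller angle."""

    theta_c1: float
    theta_c2: float
    centriole1_index: int          # 0-based index into the input pair
    tie: bool = False

    def __post_init__(self) -> None:
        for name, th in (("theta_c1", self.theta_c1), ("theta_c2", self.theta_c2)):
            if not 0 <= th <= 90:
                raise ValueError(f"{name} must be in [0, 90], got {th}")
        if self.theta_c1 > self.theta_c2:
            raise ValueError("theta_c1 must be the smaller angle")


def assign_centriole_one(pair_angles: tuple[float, float]) -> SpindleAngleRecord:
    """Score centriole "1" as the pair member with the smaller spindle angle.

    Ties are broken in favor of the first-listed member and flagged.
    """
    a, b = pair_angles
    if a <= b:
        return SpindleAngleRecord(theta_c1=a, theta_c2=b, centriole1_index=0, tie=(a == b))
    return SpindleAngleRecord(theta_c1=b, theta_c2=a, centriole1_index=1)


# ---------------------------------------------------------------------------
# Microtubule-bundle architecture

ARCHITECTURE_CLASSES = ("no_bundles", "single_bundle", "multiple_bundles")


def classify_architecture(filaments: Sequence[np.ndarray],
                          mtoc_center: Sequence[float],
                          stage: str,
                          spindle_axis: Sequence[float] | None = None,
                          shell: tuple[float, float] = (500.0, 5000.0),
                          cone_deg: float = 30.0) -> str:
    """Classify microtubule architecture around an MTOC from filament traces.

    Filaments are (N, 3) polylines in nm; a filament counts as a bundle when
    any of its points falls in the spherical shell ``shell`` (inner, outer
    radius in nm) around the MTOC center. At metaphase, filaments gathered
    into the spindle — those whose shell points lie within ``cone_deg`` of
    the spindle axis — are excluded, since only non-spindle microtubules are
    scored. Counts 0/1/>=2 map to no/single/multiple bundles.
    """
    if stage == "metaphase" and spindle_axis is None:
        raise ValueError("metaphase classification requires a spindle axis")
    r_in, r_out = shell
    if not 0 <= r_in < r_out:
        raise ValueError(f"invalid shell radii {shell}")
    center = np.asarray(mtoc_center, dtype=float)
    axis = None
    if spindle_axis is not None:
        axis = np.asarray(spindle_axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
    cos_cone = math.cos(math.radians(cone_deg))

    n_bundles = 0
    for fil in filaments:
        pts = np.asarray(fil, dtype=float).reshape(-1, 3)
        rel = pts - center[None, :]
        r = np.linalg.norm(rel, axis=1)
        in_shell = (r >= r_in) & (r <= r_out)
        if not in_shell.any():
            continue
        if stage == "metaphase" and axis is not None:
            with np.errstate(invalid="ignore"):
                cosang = np.abs(rel[in_shell] @ axis) / np.where(r[in_shell] > 0, r[in_shell], np.inf)
            if np.all(cosang >= cos_cone):
                continue                      # gathered into the spindle pole
        n_bundles += 1
    if n_bundles == 0:
        return "no_bundles"
    if n_bundles == 1:
        return "single_bundle"
    return "multiple_bundles"


def filaments_from_volume(volume: np.ndarray, voxel_size: float | Sequence[float],
                          threshold: float) -> list[np.ndarray]:
    """Connected supra-threshold components of a volume as point clouds in nm."""
    voxel = _as_zyx_voxel(voxel_size)
    mask = np.asarray(volume) > threshold
    labels, n = ndimage.label(mask)
    out = []
    for i in range(1, n + 1):
        coords = np.argwhere(labels == i).astype(float) * voxel[None, :]
        out.append(coords)
    return out


# ---------------------------------------------------------------------------
# Volume-level convenience: measure a rendered centriole along a known axis

def measure_cylinder(volume: np.ndarray, voxel_size: float | Sequence[float],
                     center: Sequence[float], axis: Sequence[float],
                     scan_half_length: float, scan_half_width: float,
                     width_px: int = 1) -> tuple[float, float]:
    """FWHM length and width (nm) of a barrel at a known center/axis.

    Length is scanned along the axis through the center; width on the
    perpendicular (in-plane) scan at the longitudinal midpoint. Both scans
    stay in the center's z-plane, so the axis must be in-plane.
    """
    voxel = _as_zyx_voxel(voxel_size)
    center = np.asarray(center, dtype=float)
    axis = np.asarray(axis, dtype=float)
    if abs(axis[0]) > 1e-6:
        raise ValueError("measure_cylinder expects an in-plane (z-constant) axis")
    axis = axis / np.linalg.norm(axis)
    perp = np.array([0.0, -axis[2], axis[1]])
    ls_len = extract_linescan(volume, voxel, center - scan_half_length * axis,
                              center + scan_half_length * axis, width_px=width_px)
    ls_wid = extract_linescan(volume, voxel, center - scan_half_width * perp,
                              center + scan_half_width * perp, width_px=width_px)
    return measure_extent(ls_len), measure_extent(ls_wid)
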