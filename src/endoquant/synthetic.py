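"""Synthetic confocal scenes with exhaustive ground truth.

This module generates 2D multi-channel images that emulate live-cell
co-staining experiments: a cell whose plasma membrane (PM) carries a
lipophilic reference dye (an FM4-64 / CellMask analog) together with a
membrane protein channel, dim cytosolic fluorescence excluded from the
nucleus, and endocytic vesicles whose membrane carries the reference dye at
PM-equal density and the protein at a configurable fraction ``rho`` of PM
density.  Because every vesicle's true relative density is recorded, the
downstream ratiometric estimator can be validated against known truth.

The forward model is deliberately simple and exactly ratio-preserving:

* membranes are 1D curves (the PM contour; vesicles as circles, i.e.
  equatorial sections of spheres) carrying a line density of photons per μm;
* the cytosol is a uniform area source inside the PM and outside the
  nucleus (vesicle lumens are treated as cytosol-filled unless an explicit
  lumen level is set — a second-order simplification);
* the noiseless field is the rasterized line/area integral convolved with an
  isotropic Gaussian PSF and scaled by the detector gain;
* noise is Poisson shot noise plus additive Gaussian read noise, clipped to
  the configured bit depth.

All channels share the *same* rasterized geometry, scaled per channel, so
the per-pixel ratio of membrane contributions equals the density ratio
exactly, independent of PSF width, vesicle radius, and rasterization error.
That property is what makes the PM-normalized peak-ratio estimator
geometry-free.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter
from shapely.geometry import Point, Polygon
from skimage.draw import polygon2mask

from .errors import CapacityError, DatasetIOError, ParameterError

__all__ = [
    "Vesicle",
    "CellScene",
    "ImagingConfig",
    "MultiChannelImage",
    "GeometryConfig",
    "VesicleSpec",
    "build_cell_geometry",
    "place_vesicles",
    "render_field",
    "render_image",
    "write_dataset",
    "read_dataset",
    "scene_to_dict",
    "scene_from_dict",
]

# Channel roles used throughout the pipeline.
ROLE_PROTEIN = "protein"
ROLE_REFERENCE = "reference_dye"
ROLE_RECEPTOR = "receptor"
ROLE_MARKER = "marker"

#: Default PM line densities, photons per μm of membrane (per frame, at unit
#: detector gain).  Chosen so the blurred PM peak is ~500 counts at default
#: optics — comfortably above noise, well below 16-bit saturation.
DEFAULT_PM_DENSITY = {ROLE_PROTEIN: 2.0e4, ROLE_REFERENCE: 2.0e4, ROLE_RECEPTOR: 2.0e4}

#: Default cytosol area levels, photons per μm².  The tagged protein has a
#: dim cytosolic pool (~5% of the PM peak per pixel); lipophilic dyes and
#: surface-labeled receptors have none.
DEFAULT_CYTOSOL_LEVEL = {ROLE_PROTEIN: 2.7e3, ROLE_REFERENCE: 0.0, ROLE_RECEPTOR: 0.0}


@dataclass
class Vesicle:
    """A circular endocytic vesicle with per-channel ground-truth density.

    ``membrane_density`` maps channel role -> rho, the membrane density as a
    fraction of the PM density in the same channel (the reference dye has
    rho = 1 by construction: the dye reports membrane surface area at
    PM-equal density).  ``lumen_level`` is an optional additional area
    source inside the vesicle (photons per μm²).
    """

    center: tuple[float, float]
    radius: float
    membrane_density: dict[str, float]
    lumen_level: dict[str, float] = field(default_factory=dict)
    kind_label: str = "constitutive"

    def __post_init__(self):
        if self.radius <= 0:
            raise ParameterError(f"radius must be > 0, got {self.radius}")
        for role, rho in self.membrane_density.items():
            if rho < 0:
                raise ParameterError(f"membrane_density[{role!r}] must be >= 0, got {rho}")


@dataclass
class CellScene:
    """Vectorized ground truth for one simulated cell.

    Coordinates are in μm in the image frame (origin top-left, x rightward,
    y downward).  ``pm_contour`` is a closed polyline of shape (N, 2); the
    first vertex is not repeated.
    """

    pm_contour: np.ndarray
    nucleus_center: tuple[float, float]
    nucleus_radius: float
    vesicles: list[Vesicle]
    cytosol_level: dict[str, float]
    pm_density: dict[str, float]
    cell_center: tuple[float, float]
    cell_radius: float
    field_extent: float  # square field of view, μm

    def polygon(self) -> Polygon:
        poly = getattr(self, "_poly", None)
        if poly is None:
            poly = Polygon(self.pm_contour)
            self._poly = poly
        return poly

    def validate(self) -> None:
        poly = self.polygon()
        if not poly.is_simple or not poly.is_valid:
            raise ParameterError("pm_contour must be a simple closed curve")
        if not poly.contains(Point(*self.nucleus_center)):
            raise ParameterError("pm_contour must enclose the nucleus")
        for v in self.vesicles:
            if not poly.contains(Point(*v.center)):
                raise ParameterError("pm_contour must enclose every vesicle center")
        for name, table in (("pm_density", self.pm_density), ("cytosol_level", self.cytosol_level)):
            for role, val in table.items():
                if val < 0:
                    raise ParameterError(f"{name}[{role!r}] must be >= 0, got {val}")

    @property
    def channels(self) -> list[str]:
        return list(self.pm_density)


@dataclass
class GeometryConfig:
    """Parameters for :func:`build_cell_geometry`.

    The cell outline is a circle of ``cell_radius`` with a smooth random
    radial perturbation of fractional amplitude ``irregularity`` (low-order
    Fourier modes), so cells are organic-looking but remain simple curves.
    """

    cell_radius: float = 10.0
    nucleus_radius: float = 4.0
    nucleus_offset: float = 1.5
    irregularity: float = 0.03
    n_contour_points: int = 720
    margin: float = 1.8  # free space between the cell and the image border, μm
    channels: tuple[str, ...] = (ROLE_PROTEIN, ROLE_REFERENCE)
    pm_density: dict[str, float] | None = None
    cytosol_level: dict[str, float] | None = None


@dataclass
class VesicleSpec:
    """Request for :func:`place_vesicles`.

    ``rho`` maps channel role to the ground-truth membrane density fraction;
    each value may be a scalar (shared by all vesicles) or a sequence of
    length ``count`` (per-vesicle truth).
    """

    count: int
    rho: dict[str, float | np.ndarray]
    radius_range: tuple[float, float] = (0.25, 0.6)
    kind_label: str = "constitutive"
    lumen_level: dict[str, float] = field(default_factory=dict)
    pm_clearance: float = 1.2     # min distance from contour; at least one diameter is enforced
    nucleus_clearance: float = 0.4
    separation: float = 0.8       # extra gap between vesicle rims
    max_attempts_per_vesicle: int = 300


@dataclass
class ImagingConfig:
    """Forward-optics and detector parameters.

    ``photon_scale`` is the detector gain: expected photons (counts) per
    unit photon rate.  ``channel_roles`` maps role -> channel index in the
    rendered raster.
    """

    pixel_size: float = 0.1
    psf_sigma: float = 0.15
    photon_scale: float = 1.0
    read_noise_sd: float = 3.0
    bit_depth: int = 16
    channel_roles: dict[str, int] = field(
        default_factory=lambda: {ROLE_PROTEIN: 0, ROLE_REFERENCE: 1}
    )

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ParameterError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.psf_sigma < 0:
            raise ParameterError(f"psf_sigma must be >= 0, got {self.psf_sigma}")
        if self.bit_depth not in (8, 16):
            raise ParameterError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        idx = sorted(self.channel_roles.values())
        if idx != list(range(len(idx))):
            raise ParameterError(f"channel_roles indices must be 0..C-1, got {idx}")

    @classmethod
    def for_roles(cls, roles, **kwargs) -> "ImagingConfig":
        return cls(channel_roles={r: i for i, r in enumerate(roles)}, **kwargs)


@dataclass
class MultiChannelImage:
    """A (channels, height, width) raster plus the metadata needed to read it.

    ``pixels`` is an unsigned integer raster for noisy renders; noiseless
    renders keep float64 expected counts (the bit-depth invariant applies to
    detector output, not to the ideal field).
    """

    pixels: np.ndarray
    pixel_size: float
    channel_roles: dict[str, int]
    scene_truth: CellScene | None = None

    def __post_init__(self):
        if self.pixels.ndim != 3:
            raise ParameterError(f"pixels must be (C, H, W), got shape {self.pixels.shape}")
        if self.pixels.shape[0] != len(self.channel_roles):
            raise ParameterError(
                f"{self.pixels.shape[0]} channels but {len(self.channel_roles)} declared roles"
            )

    def channel(self, role: str) -> np.ndarray:
        return self.pixels[self.channel_roles[role]]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]


# ---------------------------------------------------------------------------
# Scene construction
# ---------------------------------------------------------------------------

def build_cell_geometry(config: GeometryConfig, seed: int) -> CellScene:
    """Build a cell scene (no vesicles yet) with a mildly irregular outline.

    Deterministic for a fixed seed.  Raises :class:`ParameterError` when
    radii are inconsistent (e.g. nucleus larger than the cell).
    """
    if config.cell_radius <= 0:
        raise ParameterError(f"cell_radius must be > 0, got {config.cell_radius}")
    if config.nucleus_radius <= 0:
        raise ParameterError(f"nucleus_radius must be > 0, got {config.nucleus_radius}")
    if config.nucleus_radius >= config.cell_radius:
        raise ParameterError(
            f"nucleus_radius ({config.nucleus_radius}) must be smaller than "
            f"cell_radius ({config.cell_radius})"
        )
    min_cell_r = config.cell_radius * (1.0 - 2.0 * config.irregularity)
    if config.nucleus_offset + config.nucleus_radius >= min_cell_r:
        raise ParameterError(
            "nucleus_offset + nucleus_radius must leave the nucleus inside the cell"
        )

    rng = np.random.default_rng(seed)
    half = config.cell_radius * (1.0 + 2.0 * config.irregularity) + config.margin
    center = (half, half)

    theta = np.linspace(0.0, 2.0 * np.pi, config.n_contour_points, endpoint=False)
    radial = np.ones_like(theta)
    for k in (2, 3, 4, 5):
        amp = rng.uniform(-config.irregularity, config.irregularity) / np.sqrt(k)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        radial += amp * np.cos(k * theta + phase)
    r = config.cell_radius * radial
    contour = np.column_stack([center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)])

    nuc_angle = rng.uniform(0.0, 2.0 * np.pi)
    nuc_center = (
        center[0] + config.nucleus_offset * np.cos(nuc_angle),
        center[1] + config.nucleus_offset * np.sin(nuc_angle),
    )

    pm_density = dict(config.pm_density) if config.pm_density is not None else {
        c: DEFAULT_PM_DENSITY.get(c, DEFAULT_PM_DENSITY[ROLE_PROTEIN]) for c in config.channels
    }
    cytosol = dict(config.cytosol_level) if config.cytosol_level is not None else {
        c: DEFAULT_CYTOSOL_LEVEL.get(c, 0.0) for c in config.channels
    }

    scene = CellScene(
        pm_contour=contour,
        nucleus_center=nuc_center,
        nucleus_radius=config.nucleus_radius,
        vesicles=[],
        cytosol_level=cytosol,
        pm_density=pm_density,
        cell_center=center,
        cell_radius=config.cell_radius,
        field_extent=2.0 * half,
    )
    scene.validate()
    return scene


def _rho_for(spec: VesicleSpec, i: int) -> dict[str, float]:
    out = {}
    for role, val in spec.rho.items():
        arr = np.asarray(val, dtype=float)
        if arr.ndim == 0:
            out[role] = float(arr)
        else:
            if arr.shape[0] != spec.count:
                raise ParameterError(
                    f"rho[{role!r}] has length {arr.shape[0]}, expected {spec.count}"
                )
            out[role] = float(arr[i])
    return out


def place_vesicles(scene: CellScene, spec: VesicleSpec, seed: int) -> CellScene:
    """Return a new scene with ``spec.count`` vesicles added.

    Vesicles are placed uniformly at random in the cytosol, at least one
    diameter (and ``spec.pm_clearance``) away from the PM contour, outside
    the nucleus, and pairwise non-overlapping with an extra ``separation``
    gap.  Raises :class:`CapacityError` reporting the achieved count when
    the retry budget is exhausted.  Deterministic for a fixed seed.
    """
    if spec.count < 0:
        raise ParameterError(f"count must be >= 0, got {spec.count}")
    lo, hi = spec.radius_range
    if not (0 < lo <= hi):
        raise ParameterError(f"radius_range must satisfy 0 < lo <= hi, got {spec.radius_range}")

    new_vesicles = list(scene.vesicles)
    if spec.count == 0:
        return dataclasses.replace(scene, vesicles=new_vesicles)

    rng = np.random.default_rng(seed)
    poly = scene.polygon()
    boundary = poly.exterior
    cx, cy = scene.cell_center
    reach = scene.cell_radius

    placed = 0
    for i in range(spec.count):
        radius = float(rng.uniform(lo, hi))
        ok = False
        for _ in range(spec.max_attempts_per_vesicle):
            x = rng.uniform(cx - reach, cx + reach)
            y = rng.uniform(cy - reach, cy + reach)
            p = Point(x, y)
            if not poly.contains(p):
                continue
            if boundary.distance(p) < max(2.0 * radius, spec.pm_clearance):
                continue
            d_nuc = np.hypot(x - scene.nucleus_center[0], y - scene.nucleus_center[1])
            if d_nuc < scene.nucleus_radius + radius + spec.nucleus_clearance:
                continue
            if any(
                np.hypot(x - v.center[0], y - v.center[1]) < v.radius + radius + spec.separation
                for v in new_vesicles
            ):
                continue
            new_vesicles.append(
                Vesicle(
                    center=(float(x), float(y)),
                    radius=radius,
                    membrane_density=_rho_for(spec, i),
                    lumen_level=dict(spec.lumen_level),
                    kind_label=spec.kind_label,
                )
            )
            placed += 1
            ok = True
            break
        if not ok:
            raise CapacityError(requested=spec.count, achieved=placed)

    return dataclasses.replace(scene, vesicles=new_vesicles)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _deposit_curve(acc: np.ndarray, pts: np.ndarray, pixel_size: float, closed: bool) -> None:
    """Accumulate the line integral of a unit-density polyline into ``acc``.

    The curve is resampled at ~pixel_size/6 steps; each sample deposits its
    arclength bilinearly into the four surrounding pixels, so the total
    deposited weight equals the curve length (in μm) exactly.
    """
    if closed:
        pts = np.vstack([pts, pts[:1]])
    seg = np.diff(pts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    if total == 0.0:
        return
    n = max(8, int(np.ceil(total / (pixel_size / 6.0))))
    s = (np.arange(n) + 0.5) * (total / n)
    x = np.interp(s, cum, pts[:, 0])
    y = np.interp(s, cum, pts[:, 1])
    w = total / n  # arclength per sample

    fx = x / pixel_size - 0.5
    fy = y / pixel_size - 0.5
    ix = np.floor(fx).astype(int)
    iy = np.floor(fy).astype(int)
    dx = fx - ix
    dy = fy - iy
    H, W = acc.shape
    for ox, oy, wt in (
        (0, 0, (1 - dx) * (1 - dy)),
        (1, 0, dx * (1 - dy)),
        (0, 1, (1 - dx) * dy),
        (1, 1, dx * dy),
    ):
        cols = ix + ox
        rows = iy + oy
        keep = (rows >= 0) & (rows < H) & (cols >= 0) & (cols < W)
        np.add.at(acc, (rows[keep], cols[keep]), w * wt[keep])


def _circle_points(center, radius, pixel_size) -> np.ndarray:
    n = max(24, int(np.ceil(2.0 * np.pi * radius / (pixel_size / 6.0))))
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)])


def _pixel_center_grid(shape, pixel_size):
    H, W = shape
    ys = (np.arange(H) + 0.5) * pixel_size
    xs = (np.arange(W) + 0.5) * pixel_size
    return np.meshgrid(xs, ys)  # X, Y


def _inside_mask(scene: CellScene, shape, px, X, Y) -> np.ndarray:
    """Boolean mask of pixel centers inside the PM contour.

    Fast path: contours from :func:`build_cell_geometry` are star-shaped
    about the cell center, so "inside" reduces to r < r_contour(theta),
    evaluated by periodic interpolation of the vertex radii.  Arbitrary
    simple polygons fall back to rasterization.
    """
    cx, cy = scene.cell_center
    rel = scene.pm_contour - np.array([cx, cy])
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    unwrapped = np.unwrap(theta)
    if np.all(np.diff(unwrapped) > 0) or np.all(np.diff(unwrapped) < 0):
        if unwrapped[1] < unwrapped[0]:  # orient counter-clockwise in theta
            unwrapped = unwrapped[::-1]
            rel = rel[::-1]
        t0 = unwrapped - unwrapped[0]
        r_vertex = np.hypot(rel[:, 0], rel[:, 1])
        pt = np.mod(np.arctan2(Y - cy, X - cx) - unwrapped[0], 2.0 * np.pi)
        r_edge = np.interp(pt.ravel(), t0, r_vertex, period=2.0 * np.pi).reshape(pt.shape)
        return np.hypot(X - cx, Y - cy) < r_edge
    poly_rc = np.column_stack(
        [scene.pm_contour[:, 1] / px - 0.5, scene.pm_contour[:, 0] / px - 0.5]
    )
    return polygon2mask(shape, poly_rc)


def render_field(scene: CellScene, imaging: ImagingConfig) -> np.ndarray:
    """Noiseless expected-count field, shape (C, H, W), float64.

    Equals ``photon_scale`` times the PSF-blurred rasterized photon rate.
    Membrane deposits are computed once and reused for every channel, so
    channels with identical geometry are exactly proportional pixel for
    pixel.
    """
    for role in imaging.channel_roles:
        if role not in scene.pm_density:
            raise ParameterError(f"scene carries no channel {role!r}")
    px = imaging.pixel_size
    npix = int(np.ceil(scene.field_extent / px))
    shape = (npix, npix)

    pm_deposit = np.zeros(shape)
    _deposit_curve(pm_deposit, scene.pm_contour, px, closed=True)

    ves_deposits = []
    for v in scene.vesicles:
        d = np.zeros(shape)
        _deposit_curve(d, _circle_points(v.center, v.radius, px), px, closed=True)
        ves_deposits.append(d)

    # cytosol mask: inside PM contour, outside nucleus (vesicle lumens count
    # as cytosol; explicit lumen levels add on top)
    X, Y = _pixel_center_grid(shape, px)
    cyt_mask = _inside_mask(scene, shape, px, X, Y)
    nuc = (X - scene.nucleus_center[0]) ** 2 + (Y - scene.nucleus_center[1]) ** 2 \
        <= scene.nucleus_radius ** 2
    cyt_mask &= ~nuc
    cyt_area = cyt_mask * (px * px)

    lumen_masks = []
    for v in scene.vesicles:
        if any(lv > 0 for lv in v.lumen_level.values()):
            m = (X - v.center[0]) ** 2 + (Y - v.center[1]) ** 2 <= v.radius ** 2
            lumen_masks.append(m * (px * px))
        else:
            lumen_masks.append(None)

    sigma_px = imaging.psf_sigma / px
    channels = sorted(imaging.channel_roles, key=imaging.channel_roles.get)
    field = np.empty((len(channels),) + shape)
    for role in channels:
        f = scene.pm_density[role] * pm_deposit
        for v, d in zip(scene.vesicles, ves_deposits):
            rho = v.membrane_density.get(role, 0.0)
            if rho:
                f = f + rho * scene.pm_density[role] * d
        f = f + scene.cytosol_level.get(role, 0.0) * cyt_area
        for v, m in zip(scene.vesicles, lumen_masks):
            lv = v.lumen_level.get(role, 0.0)
            if lv and m is not None:
                f = f + lv * m
        if sigma_px > 0:
            f = gaussian_filter(f, sigma_px, mode="constant")
        field[imaging.channel_roles[role]] = f
    return imaging.photon_scale * field


def render_image(
    scene: CellScene, imaging: ImagingConfig, seed: int, noise: bool = True
) -> MultiChannelImage:
    """Render the scene to a detector raster.

    With ``noise=True`` (default): Poisson shot noise on the expected-count
    field plus Gaussian read noise, rounded and clipped to the bit depth
    (uint8/uint16).  With ``noise=False`` the float64 noiseless field is
    returned unquantized.  Deterministic for a fixed seed.
    """
    field = render_field(scene, imaging)
    if not noise:
        return MultiChannelImage(
            pixels=field, pixel_size=imaging.pixel_size,
            channel_roles=dict(imaging.channel_roles), scene_truth=scene,
        )
    rng = np.random.default_rng(seed)
    counts = np.zeros(field.shape, dtype=np.float64)
    lit = field > 0  # dark pixels are Poisson(0) = 0; skip drawing them
    counts[lit] = rng.poisson(field[lit])
    if imaging.read_noise_sd > 0:
        counts += imaging.read_noise_sd * rng.standard_normal(
            field.shape, dtype=np.float32
        )
    maxval = 2 ** imaging.bit_depth - 1
    dtype = np.uint8 if imaging.bit_depth == 8 else np.uint16
    pixels = np.clip(np.rint(counts), 0, maxval).astype(dtype)
    return MultiChannelImage(
        pixels=pixels, pixel_size=imaging.pixel_size,
        channel_roles=dict(imaging.channel_roles), scene_truth=scene,
    )


# ---------------------------------------------------------------------------
# Dataset I/O (multi-channel TIFF + ground-truth JSON)
# ---------------------------------------------------------------------------

def scene_to_dict(scene: CellScene) -> dict:
    return {
        "pm_contour": scene.pm_contour.tolist(),
        "nucleus_center": list(scene.nucleus_center),
        "nucleus_radius": scene.nucleus_radius,
        "cell_center": list(scene.cell_center),
        "cell_radius": scene.cell_radius,
        "field_extent": scene.field_extent,
        "cytosol_level": scene.cytosol_level,
        "pm_density": scene.pm_density,
        "vesicles": [
            {
                "center": list(v.center),
                "radius": v.radius,
                "membrane_density": v.membrane_density,
                "lumen_level": v.lumen_level,
                "kind_label": v.kind_label,
            }
            for v in scene.vesicles
        ],
    }


def scene_from_dict(d: dict) -> CellScene:
    return CellScene(
        pm_contour=np.asarray(d["pm_contour"], dtype=float),
        nucleus_center=tuple(d["nucleus_center"]),
        nucleus_radius=float(d["nucleus_radius"]),
        vesicles=[
            Vesicle(
                center=tuple(v["center"]),
                radius=float(v["radius"]),
                membrane_density={k: float(x) for k, x in v["membrane_density"].items()},
                lumen_level={k: float(x) for k, x in v.get("lumen_level", {}).items()},
                kind_label=v.get("kind_label", "constitutive"),
            )
            for v in d["vesicles"]
        ],
        cytosol_level={k: float(x) for k, x in d["cytosol_level"].items()},
        pm_density={k: float(x) for k, x in d["pm_density"].items()},
        cell_center=tuple(d["cell_center"]),
        cell_radius=float(d["cell_radius"]),
        field_extent=float(d["field_extent"]),
    )


def write_dataset(
    image: MultiChannelImage,
    truth: CellScene | None,
    out_prefix: str | Path,
    seeds: dict | None = None,
    config_echo: dict | None = None,
) -> dict[str, Path]:
    """Write ``<prefix>.tif`` (channels as pages, pixel size in the image
    description) and ``<prefix>.json`` (ground truth, seeds, config echo).

    The TIFF round-trips bit-exactly through :func:`read_dataset`.
    """
    out_prefix = Path(out_prefix)
    tif_path = out_prefix.with_suffix(".tif")
    json_path = out_prefix.with_suffix(".json")
    description = json.dumps(
        {
            "pixel_size_um": image.pixel_size,
            "channel_roles": image.channel_roles,
            "axes": "CYX",
        }
    )
    try:
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(tif_path, image.pixels, description=description)
    except OSError as exc:
        raise DatasetIOError(tif_path, f"failed to write TIFF ({exc})") from exc

    payload = {
        "pixel_size_um": image.pixel_size,
        "channel_roles": image.channel_roles,
        "seeds": seeds or {},
        "config": config_echo or {},
        "scene": scene_to_dict(truth) if truth is not None else None,
    }
    try:
        json_path.write_text(json.dumps(payload, indent=1))
    except OSError as exc:
        raise DatasetIOError(json_path, f"failed to write truth JSON ({exc})") from exc
    return {"tif": tif_path, "json": json_path}


def read_dataset(prefix: str | Path) -> MultiChannelImage:
    """Read a dataset written by :func:`write_dataset`.

    The returned image carries the ground-truth scene when the sidecar JSON
    records one.
    """
    prefix = Path(prefix)
    tif_path = prefix.with_suffix(".tif")
    json_path = prefix.with_suffix(".json")
    try:
        with tifffile.TiffFile(tif_path) as tf:
            pixels = tf.asarray()
            meta = json.loads(tf.pages[0].description)
    except (OSError, ValueError, json.JSONDecodeError) as exc:
        raise DatasetIOError(tif_path, f"failed to read TIFF ({exc})") from exc
    if pixels.ndim == 2:
        pixels = pixels[None]
    scene = None
    if json_path.exists():
        truth = json.loads(json_path.read_text())
        if truth.get("scene") is not None:
            scene = scene_from_dict(truth["scene"])
    return MultiChannelImage(
        pixels=pixels,
        pixel_size=float(meta["pixel_size_um"]),
        channel_roles={k: int(v) for k, v in meta["channel_roles"].items()},
        scene_truth=scene,
    )
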