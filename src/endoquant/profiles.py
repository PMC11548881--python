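"""Line-profile measurement layer and the density-ratio estimator.

The estimator answers: what fraction of the plasma-membrane (PM) surface
density of a protein is present on the membrane of an endocytic vesicle?
Per vesicle and channel, a 3 μm line profile centered on the vesicle yields
a peak intensity; the peak is normalized to a PM reference taken from a
nearby PM-crossing profile, a cytosol background (similarly normalized) is
subtracted, and the protein channel is divided by the lipophilic
reference-dye channel, which reports membrane surface area at PM-equal
density:

    D = (peak_protein/PM_protein − bg_protein/PM_protein)
        / (peak_ref/PM_ref − bg_ref/PM_ref)

Because both channels see the same geometry and PSF, everything geometric
cancels and D estimates the true density fraction rho directly.  Negative
protein numerators are clipped to zero (vesicles with no detectable protein
are data, not failures); a non-positive reference numerator makes the
vesicle unmeasurable and raises.

Coordinates are in μm, image origin top-left, x rightward, y downward,
pixel centers at (i + 0.5) * pixel_size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from . import stats as _stats
from .errors import (
    DegenerateReferenceError,
    GeometryError,
    InsufficientDataError,
    ParameterError,
    UnmeasurableVesicleError,
)
from .synthetic import ROLE_PROTEIN, ROLE_RECEPTOR, ROLE_REFERENCE, MultiChannelImage

__all__ = [
    "LineProfile",
    "RoiMeasure",
    "RectRoi",
    "DiscRoi",
    "VesicleMeasurement",
    "DensitySummary",
    "extract_line_profile",
    "pm_reference",
    "roi_mean",
    "signal_background_ratio",
    "vesicle_density_ratio",
    "enrichment_ratio",
    "summarize_density",
]


@dataclass
class LineProfile:
    """Intensity samples along a line, centered at offset 0."""

    positions: np.ndarray  # μm offsets, strictly increasing, symmetric about 0
    intensity: np.ndarray
    line_length: float
    center: tuple[float, float]
    angle: float

    def peak(self, window_fraction: float = 1.0 / 3.0) -> float:
        """Maximum intensity within the central ``window_fraction`` of the line."""
        half = self.line_length * window_fraction / 2.0
        sel = np.abs(self.positions) <= half + 1e-12
        return float(self.intensity[sel].max())


@dataclass
class RectRoi:
    center: tuple[float, float]
    width: float   # along `angle`, μm
    height: float  # across `angle`, μm
    angle: float = 0.0


@dataclass
class DiscRoi:
    center: tuple[float, float]
    radius: float


@dataclass
class RoiMeasure:
    mean_signal: float
    mean_background: float
    roi_kind: str  # pm_rect | vesicle_disc | cytosol_background

    @property
    def ratio(self) -> float:
        return self.mean_signal / self.mean_background


@dataclass
class VesicleMeasurement:
    """Per-vesicle normalized peaks and the derived density ratio D."""

    peak_norm: dict[str, float]
    bg_norm: dict[str, float]
    density_ratio: float
    vesicle_id: str = ""
    numerator_role: str = ROLE_PROTEIN


@dataclass
class DensitySummary:
    mean: float
    ci95_halfwidth: float
    n: int
    per_vesicle: list = field(default_factory=list)


def _sample_bilinear(image: MultiChannelImage, role: str, xs, ys) -> np.ndarray:
    px = image.pixel_size
    fx = np.asarray(xs) / px - 0.5
    fy = np.asarray(ys) / px - 0.5
    H, W = image.shape
    if fx.min() < 0 or fy.min() < 0 or fx.max() > W - 1 or fy.max() > H - 1:
        raise GeometryError(
            "sampling positions exit the image interior "
            f"(x: {np.min(xs):.2f}..{np.max(xs):.2f} μm, y: {np.min(ys):.2f}..{np.max(ys):.2f} μm)"
        )
    plane = image.channel(role).astype(np.float64)
    return map_coordinates(plane, np.vstack([fy.ravel(), fx.ravel()]), order=1).reshape(fx.shape)


def extract_line_profile(
    image: MultiChannelImage,
    channel: str,
    center: tuple[float, float],
    angle: float,
    length: float = 3.0,
) -> LineProfile:
    """Bilinear intensity profile along a line of ``length`` μm.

    Samples at pixel pitch: floor(length / pixel_size) + 1 positions,
    symmetric about the line center.  Raises :class:`GeometryError` if any
    sample falls outside the image interior.
    """
    if length <= 0:
        raise ParameterError(f"length must be > 0, got {length}")
    px = image.pixel_size
    n = int(np.floor(length / px)) + 1
    offsets = (np.arange(n) - (n - 1) / 2.0) * px
    ux, uy = np.cos(angle), np.sin(angle)
    xs = center[0] + offsets * ux
    ys = center[1] + offsets * uy
    intensity = _sample_bilinear(image, channel, xs, ys)
    return LineProfile(
        positions=offsets, intensity=intensity, line_length=length,
        center=tuple(center), angle=float(angle),
    )


def pm_reference(
    image: MultiChannelImage,
    channel: str,
    center: tuple[float, float],
    angle: float,
    length: float = 3.0,
    mode: str = "peak",
    window_fraction: float = 1.0 / 3.0,
) -> float:
    """PM normalization constant from a PM-crossing line profile.

    ``center`` must lie on the PM contour and ``angle`` point across it.
    The peak is searched within the central ``window_fraction`` of the line
    so that bright structures deeper in the cytosol (or outside the cell)
    cannot masquerade as the membrane.  ``mode='peak'`` (default) returns
    that windowed maximum — the same operator applied to vesicles, so both
    structures are treated symmetrically.  ``mode='mean'`` returns the mean
    within ±0.25 μm of the windowed peak position, an alternative reading
    of "mean intensity of a nearby section of plasma membrane".
    """
    prof = extract_line_profile(image, channel, center, angle, length)
    half = length * window_fraction / 2.0
    window = np.abs(prof.positions) <= half + 1e-12
    peak = float(prof.intensity[window].max())
    if peak <= 0:
        raise DegenerateReferenceError(
            f"PM reference profile for channel {channel!r} carries no signal"
        )
    if mode == "peak":
        return peak
    if mode == "mean":
        inwin = prof.positions[window]
        t0 = inwin[int(np.argmax(prof.intensity[window]))]
        sel = np.abs(prof.positions - t0) <= 0.25
        return float(prof.intensity[sel].mean())
    raise ParameterError(f"mode must be 'peak' or 'mean', got {mode!r}")


def roi_mean(image: MultiChannelImage, channel: str, roi, oversample: int = 2) -> float:
    """Mean intensity over a rectangular or disc ROI (bilinear supersampling)."""
    px = image.pixel_size
    step = px / oversample
    if isinstance(roi, RectRoi):
        nu = max(1, int(round(roi.width / step)))
        nv = max(1, int(round(roi.height / step)))
        u = (np.arange(nu) + 0.5) / nu - 0.5
        v = (np.arange(nv) + 0.5) / nv - 0.5
        U, V = np.meshgrid(u * roi.width, v * roi.height)
        ca, sa = np.cos(roi.angle), np.sin(roi.angle)
        xs = roi.center[0] + U * ca - V * sa
        ys = roi.center[1] + U * sa + V * ca
        vals = _sample_bilinear(image, channel, xs, ys)
        return float(vals.mean())
    if isinstance(roi, DiscRoi):
        n = max(2, int(round(2 * roi.radius / step)))
        g = (np.arange(n) + 0.5) / n - 0.5
        U, V = np.meshgrid(g * 2 * roi.radius, g * 2 * roi.radius)
        mask = U**2 + V**2 <= roi.radius**2
        xs = roi.center[0] + U[mask]
        ys = roi.center[1] + V[mask]
        vals = _sample_bilinear(image, channel, xs, ys)
        return float(vals.mean())
    raise ParameterError(f"unsupported ROI type {type(roi).__name__}")


def signal_background_ratio(
    image: MultiChannelImage,
    channel: str,
    structure_roi,
    background_roi,
    roi_kind: str = "vesicle_disc",
) -> RoiMeasure:
    """Mean structure-ROI intensity over mean nearby-cytosol intensity."""
    sig = roi_mean(image, channel, structure_roi)
    bg = roi_mean(image, channel, background_roi)
    if bg <= 0:
        raise DegenerateReferenceError("background ROI mean is not positive")
    return RoiMeasure(mean_signal=sig, mean_background=bg, roi_kind=roi_kind)


def _density_ratio(
    profiles: dict[str, LineProfile],
    pm_refs: dict[str, float],
    backgrounds: dict[str, float],
    numerator_role: str,
    reference_role: str,
    peak_window_fraction: float,
    vesicle_id: str,
) -> VesicleMeasurement:
    for role in (numerator_role, reference_role):
        if role not in profiles:
            raise ParameterError(f"missing profile for channel {role!r}")
        if role not in pm_refs:
            raise ParameterError(f"missing PM reference for channel {role!r}")
        if pm_refs[role] <= 0:
            raise DegenerateReferenceError(f"PM reference for {role!r} must be > 0")

    peak_norm = {
        role: profiles[role].peak(peak_window_fraction) / pm_refs[role]
        for role in profiles
        if role in pm_refs
    }
    bg_norm = {
        role: backgrounds.get(role, 0.0) / pm_refs[role] for role in peak_norm
    }
    ref_num = peak_norm[reference_role] - bg_norm[reference_role]
    if ref_num <= 0:
        raise UnmeasurableVesicleError(
            f"vesicle {vesicle_id or '<unnamed>'}: reference-dye numerator "
            f"{ref_num:.4g} <= 0; vesicle excluded"
        )
    num = max(peak_norm[numerator_role] - bg_norm[numerator_role], 0.0)
    return VesicleMeasurement(
        peak_norm=peak_norm,
        bg_norm=bg_norm,
        density_ratio=num / ref_num,
        vesicle_id=vesicle_id,
        numerator_role=numerator_role,
    )


def vesicle_density_ratio(
    profiles: dict[str, LineProfile],
    pm_refs: dict[str, float],
    backgrounds: dict[str, float],
    protein_role: str = ROLE_PROTEIN,
    reference_role: str = ROLE_REFERENCE,
    peak_window_fraction: float = 1.0 / 3.0,
    vesicle_id: str = "",
) -> VesicleMeasurement:
    """Background-subtracted, PM-normalized peak ratio D for one vesicle.

    The peak is taken within the central third of the profile so the line
    ends (which may graze the PM or neighboring structures) cannot win.
    """
    return _density_ratio(
        profiles, pm_refs, backgrounds, protein_role, reference_role,
        peak_window_fraction, vesicle_id,
    )


def enrichment_ratio(
    profiles: dict[str, LineProfile],
    pm_refs: dict[str, float],
    backgrounds: dict[str, float],
    receptor_role: str = ROLE_RECEPTOR,
    reference_role: str = ROLE_REFERENCE,
    peak_window_fraction: float = 1.0 / 3.0,
    vesicle_id: str = "",
) -> VesicleMeasurement:
    """Receptor-channel analog of :func:`vesicle_density_ratio`.

    Values above 1 mean the receptor is enriched on the vesicle membrane
    relative to the plasma membrane.
    """
    return _density_ratio(
        profiles, pm_refs, backgrounds, receptor_role, reference_role,
        peak_window_fraction, vesicle_id,
    )


def summarize_density(measurements) -> DensitySummary:
    """Mean, t-based 95% CI half-width, and n over vesicle measurements.

    Accepts :class:`VesicleMeasurement` objects or bare ratios.
    """
    values = [
        m.density_ratio if isinstance(m, VesicleMeasurement) else float(m)
        for m in measurements
    ]
    if len(values) < 2:
        raise InsufficientDataError(
            f"need at least 2 vesicle measurements to summarize, got {len(values)}"
        )
    mean, hw = _stats.mean_ci95(values)
    return DensitySummary(mean=mean, ci95_halfwidth=hw, n=len(values), per_vesicle=values)
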