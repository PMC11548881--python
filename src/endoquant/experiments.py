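"""Experiment presets and end-to-end pipelines.

This module chains the synthetic generator, the profile-based density
estimator, and the statistics layer into the three headline imaging
experiments and the bystander-BRET panel experiment:

``constitutive``
    45 cells, one measured vesicle each, true mean protein density 0.20 of
    the plasma membrane (constitutive endocytosis of the tagged G-protein
    beta subunit).
``receptor``
    91 cells, true mean density 0.28, plus a receptor channel enriched
    threefold on vesicles (agonist-driven receptor internalization).
``hras_ct``
    78 cells, true mean density 0.64 (a small lipid-anchored membrane
    probe, the HRas C-terminal anchor).
``bystander_panel``
    Net-BRET panels for endosomal compartments under agonist vs control,
    analyzed with paired t-tests under two-stage FDR control at 1%.

Per-vesicle ground-truth densities are drawn from a Beta distribution
scaled to a bounded support: densities are nonnegative, physically capped,
and strongly dispersed — the spread is calibrated so the t-based 95% CI
half-width of each condition matches the reported uncertainty of the
emulated experiment (±8, ±8 and ±17 percentage points respectively), which
also reproduces the observed excess of vesicles carrying no detectable
protein.

Seeding: one master seed per run; ``numpy.random.SeedSequence(master)`` is
spawned into per-cell sequences, each of which is spawned again into
(geometry, densities, placement, noise) streams, so every stage is
independently and reproducibly seeded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import bret as _bret
from . import profiles as _prof
from . import stats as _stats
from . import synthetic as _syn
from .errors import (
    GeometryError,
    InsufficientDataError,
    ParameterError,
    UnmeasurableVesicleError,
)
from .synthetic import (
    ROLE_PROTEIN,
    ROLE_RECEPTOR,
    ROLE_REFERENCE,
    GeometryConfig,
    ImagingConfig,
    MultiChannelImage,
    VesicleSpec,
)

__all__ = [
    "DensityModel",
    "ConditionConfig",
    "MeasurementConfig",
    "RunConfig",
    "PRESETS",
    "condition_config",
    "simulate_cell",
    "measure_cell",
    "run_condition",
    "run_experiment",
    "replicate_summaries",
    "coverage_fraction",
    "signal_background_experiment",
    "nonsignificance_proportion",
    "bystander_null_fdr",
    "unpaired_t_type_i_error",
    "get_logger",
    "config_hash",
]

LOGGER_NAME = "endoquant"


def get_logger(logfile: Path | None = None) -> logging.Logger:
    """Structured-ish logger to stderr (and optionally a file)."""
    logger = logging.getLogger(LOGGER_NAME)
    logger.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(levelname)s %(name)s | %(message)s"))
        logger.addHandler(h)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(logging.Formatter("%(levelname)s %(name)s | %(message)s"))
        logger.addHandler(fh)
    return logger


def _child_seed(seq: np.random.SeedSequence) -> int:
    # documented splitting rule: first 32-bit word, masked below 2**31
    return int(seq.generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# Condition configuration
# ---------------------------------------------------------------------------

@dataclass
class DensityModel:
    """Per-vesicle ground-truth density distribution: Beta on [0, upper]."""

    mean: float
    sd: float
    upper: float

    def __post_init__(self):
        if not (0.0 < self.mean < self.upper):
            raise ParameterError(f"mean must lie in (0, upper), got {self.mean}")
        m = self.mean / self.upper
        if self.sd**2 >= m * (1.0 - m) * self.upper**2:
            raise ParameterError(
                f"sd {self.sd} too large for mean {self.mean} on [0, {self.upper}]"
            )

    def _beta_params(self) -> tuple[float, float]:
        m = self.mean / self.upper
        v = (self.sd / self.upper) ** 2
        nu = m * (1.0 - m) / v - 1.0
        return m * nu, (1.0 - m) * nu

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        a, b = self._beta_params()
        return self.upper * rng.beta(a, b, size=size)


@dataclass
class MeasurementConfig:
    """Parameters of the measurement layer (all lengths in μm)."""

    profile_length: float = 3.0
    peak_window_fraction: float = 1.0 / 3.0
    pm_mode: str = "peak"
    background_offset: float = 1.0
    background_radius: float = 0.25
    protein_role: str = ROLE_PROTEIN
    reference_role: str = ROLE_REFERENCE
    receptor_role: str = ROLE_RECEPTOR


@dataclass
class ConditionConfig:
    """Everything needed to simulate and measure one imaging condition."""

    name: str
    n_cells: int
    density: DensityModel
    channels: tuple[str, ...] = (ROLE_PROTEIN, ROLE_REFERENCE)
    receptor_density: DensityModel | None = None
    vesicles_per_cell: int = 4
    radius_range: tuple[float, float] = (0.25, 0.6)
    cell_radius_range: tuple[float, float] = (7.5, 9.5)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    imaging_kwargs: dict = field(default_factory=dict)
    measurement: MeasurementConfig = field(default_factory=MeasurementConfig)
    noise: bool = True

    def imaging(self) -> ImagingConfig:
        return ImagingConfig.for_roles(self.channels, **self.imaging_kwargs)


# Dispersion sd back-solved from the emulated experiments' reported 95% CI
# half-widths: sd = hw * sqrt(n) / t(0.975, n-1).
_PRESET_TABLE = {
    "constitutive": dict(n_cells=45, density=DensityModel(0.20, 0.266, 1.2)),
    "receptor": dict(
        n_cells=91,
        density=DensityModel(0.28, 0.384, 1.6),
        receptor_density=DensityModel(3.0, 0.9, 6.0),
        channels=(ROLE_PROTEIN, ROLE_REFERENCE, ROLE_RECEPTOR),
    ),
    "hras_ct": dict(n_cells=78, density=DensityModel(0.64, 0.754, 2.2)),
}

PRESETS = tuple(_PRESET_TABLE) + ("bystander_panel",)


def condition_config(preset: str, **overrides) -> ConditionConfig:
    """Build the :class:`ConditionConfig` for a named imaging preset."""
    if preset not in _PRESET_TABLE:
        raise ParameterError(
            f"unknown imaging preset {preset!r}; choose from {sorted(_PRESET_TABLE)}"
        )
    kwargs = dict(_PRESET_TABLE[preset])
    kwargs.update(overrides)
    channels = kwargs.get("channels", (ROLE_PROTEIN, ROLE_REFERENCE))
    kwargs.setdefault("geometry", GeometryConfig(channels=tuple(channels)))
    return ConditionConfig(name=preset, **kwargs)


# ---------------------------------------------------------------------------
# Per-cell simulate + measure
# ---------------------------------------------------------------------------

def simulate_cell(
    cfg: ConditionConfig, cell_seq: np.random.SeedSequence
) -> MultiChannelImage:
    """Simulate one cell: geometry, vesicles with drawn truths, rendering."""
    geo_seq, rho_seq, place_seq, noise_seq = cell_seq.spawn(4)
    rng = np.random.default_rng(rho_seq)

    gcfg = dataclasses.replace(
        cfg.geometry,
        cell_radius=float(rng.uniform(*cfg.cell_radius_range)),
        channels=tuple(cfg.channels),
    )
    scene = _syn.build_cell_geometry(gcfg, _child_seed(geo_seq))

    n = cfg.vesicles_per_cell
    rho = {
        cfg.measurement.protein_role: cfg.density.draw(rng, n),
        cfg.measurement.reference_role: 1.0,
    }
    if cfg.receptor_density is not None:
        rho[cfg.measurement.receptor_role] = cfg.receptor_density.draw(rng, n)
    spec = VesicleSpec(count=n, rho=rho, radius_range=cfg.radius_range)
    scene = _syn.place_vesicles(scene, spec, _child_seed(place_seq))
    return _syn.render_image(scene, cfg.imaging(), _child_seed(noise_seq), noise=cfg.noise)


def _frame_at_vertex(contour: np.ndarray, i: int):
    nxt = contour[(i + 1) % len(contour)]
    prv = contour[(i - 1) % len(contour)]
    tangent = nxt - prv
    tangent = tangent / np.hypot(*tangent)
    normal = np.array([-tangent[1], tangent[0]])
    return contour[i], tangent, normal


def _nearest_pm(scene: _syn.CellScene, point) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nearest PM vertex plus unit tangent and normal there."""
    contour = scene.pm_contour
    d2 = ((contour - np.asarray(point)) ** 2).sum(axis=1)
    return _frame_at_vertex(contour, int(np.argmin(d2)))


def _clean_pm_section(
    scene: _syn.CellScene, vesicle: _syn.Vesicle, clearance: float = 0.7
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A PM point near the vesicle whose crossing line is clear of vesicles.

    Mirrors manual practice: the reference section of membrane is the
    nearest stretch that no endosome overlaps.  Candidate vertices are
    scanned outward from the nearest one; the crossing line's central
    window (±0.5 μm) must keep ``clearance`` from every vesicle membrane.
    Falls back to the nearest vertex if no candidate qualifies.
    """
    contour = scene.pm_contour
    centers = np.array([v.center for v in scene.vesicles])
    radii = np.array([v.radius for v in scene.vesicles])
    d2 = ((contour - np.asarray(vesicle.center)) ** 2).sum(axis=1)
    for i in np.argsort(d2, kind="stable"):
        point, tangent, normal = _frame_at_vertex(contour, int(i))
        ts = np.array([-0.5, -0.25, 0.0, 0.25, 0.5])
        samples = point[None, :] + ts[:, None] * normal[None, :]
        gaps = (
            np.hypot(
                samples[:, None, 0] - centers[None, :, 0],
                samples[:, None, 1] - centers[None, :, 1],
            )
            - radii[None, :]
        )
        if gaps.min() >= clearance:
            return point, tangent, normal
    return _nearest_pm(scene, vesicle.center)


def find_background_point(
    scene: _syn.CellScene, vesicle: _syn.Vesicle, mcfg: MeasurementConfig
) -> tuple[float, float]:
    """A cytosol point near the vesicle, clear of membranes and the nucleus.

    Candidates ring the vesicle at increasing offsets, starting in the
    direction of the cell center (away from the PM); the first candidate
    clear of the PM, the nucleus, and every vesicle wins.
    """
    from shapely.geometry import Point

    poly = scene.polygon()
    boundary = poly.exterior
    vx, vy = vesicle.center
    toward_center = np.arctan2(scene.cell_center[1] - vy, scene.cell_center[0] - vx)
    pm_clear = mcfg.background_radius + 0.6
    ves_clear = mcfg.background_radius + 0.35
    base = max(mcfg.background_offset, vesicle.radius + ves_clear + 0.05)
    for offset in (base, base + 0.4, base + 0.8, base + 1.2):
        for dtheta in np.linspace(0.0, 2.0 * np.pi, 16, endpoint=False):
            ang = toward_center + dtheta
            x = vx + offset * np.cos(ang)
            y = vy + offset * np.sin(ang)
            p = Point(x, y)
            if not poly.contains(p) or boundary.distance(p) < pm_clear:
                continue
            d_nuc = np.hypot(x - scene.nucleus_center[0], y - scene.nucleus_center[1])
            if d_nuc < scene.nucleus_radius + mcfg.background_radius + 0.2:
                continue
            if any(
                np.hypot(x - v.center[0], y - v.center[1]) < v.radius + ves_clear
                for v in scene.vesicles
            ):
                continue
            return (float(x), float(y))
    raise GeometryError(
        f"no clear cytosol background point near vesicle at {vesicle.center}"
    )


def measure_cell(
    image: MultiChannelImage,
    mcfg: MeasurementConfig | None = None,
    vesicle_index: int = 0,
) -> dict:
    """Measure the designated vesicle of one annotated image.

    The vesicle profile runs parallel to the local PM tangent (the
    orientation that maximizes distance to the PM); the PM reference is a
    crossing profile at the nearest PM point; the background is a cytosol
    disc near the vesicle.  Returns one row of per-vesicle results.
    """
    mcfg = mcfg or MeasurementConfig()
    scene = image.scene_truth
    if scene is None:
        raise ParameterError("image carries no scene truth / annotations")
    if not (0 <= vesicle_index < len(scene.vesicles)):
        raise ParameterError(
            f"vesicle_index {vesicle_index} out of range ({len(scene.vesicles)} vesicles)"
        )
    vesicle = scene.vesicles[vesicle_index]
    _, tangent, _ = _nearest_pm(scene, vesicle.center)
    pm_point, _, pm_normal = _clean_pm_section(scene, vesicle)
    ves_angle = float(np.arctan2(tangent[1], tangent[0]))
    pm_angle = float(np.arctan2(pm_normal[1], pm_normal[0]))
    bg_center = find_background_point(scene, vesicle, mcfg)

    roles = list(image.channel_roles)
    profiles = {
        r: _prof.extract_line_profile(
            image, r, vesicle.center, ves_angle, mcfg.profile_length
        )
        for r in roles
    }
    pm_refs = {
        r: _prof.pm_reference(
            image, r, tuple(pm_point), pm_angle, mcfg.profile_length,
            mode=mcfg.pm_mode, window_fraction=mcfg.peak_window_fraction,
        )
        for r in roles
    }
    backgrounds = {
        r: _prof.roi_mean(image, r, _prof.DiscRoi(bg_center, mcfg.background_radius))
        for r in roles
    }

    meas = _prof.vesicle_density_ratio(
        profiles, pm_refs, backgrounds,
        protein_role=mcfg.protein_role, reference_role=mcfg.reference_role,
        peak_window_fraction=mcfg.peak_window_fraction,
    )
    row = {
        "vesicle_id": f"v{vesicle_index}",
        "radius_um": vesicle.radius,
        "true_rho": vesicle.membrane_density.get(mcfg.protein_role, np.nan),
        "density_ratio": meas.density_ratio,
    }
    for r in roles:
        row[f"peak_norm_{r}"] = meas.peak_norm.get(r, np.nan)
        row[f"bg_norm_{r}"] = meas.bg_norm.get(r, np.nan)
    if mcfg.receptor_role in roles:
        enr = _prof.enrichment_ratio(
            profiles, pm_refs, backgrounds,
            receptor_role=mcfg.receptor_role, reference_role=mcfg.reference_role,
            peak_window_fraction=mcfg.peak_window_fraction,
        )
        row["true_receptor_rho"] = vesicle.membrane_density.get(mcfg.receptor_role, np.nan)
        row["enrichment_ratio"] = enr.density_ratio
    return row


# ---------------------------------------------------------------------------
# Condition runs and replicate experiments
# ---------------------------------------------------------------------------

def run_condition(
    cfg: ConditionConfig, seed: int, n_cells: int | None = None
) -> pd.DataFrame:
    """Simulate and measure ``n_cells`` cells (one vesicle each).

    Vesicles excluded as unmeasurable (non-positive reference numerator —
    rare at default noise) are logged and dropped, mirroring manual
    analysis practice.
    """
    logger = get_logger()
    n = cfg.n_cells if n_cells is None else n_cells
    root = np.random.SeedSequence(seed)
    rows = []
    for i, cell_seq in enumerate(root.spawn(n)):
        image = simulate_cell(cfg, cell_seq)
        try:
            row = measure_cell(image, cfg.measurement)
        except UnmeasurableVesicleError as exc:
            logger.info("condition=%s cell=%d excluded: %s", cfg.name, i, exc)
            continue
        row["cell"] = i
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_condition(df: pd.DataFrame) -> dict:
    """Density (and, when present, enrichment) summaries for one condition."""
    if "density_ratio" not in df.columns or len(df) < 2:
        raise InsufficientDataError(
            f"need at least 2 measured vesicles to summarize, got {len(df)}"
        )
    summary = _prof.summarize_density(df["density_ratio"].to_numpy())
    out = {
        "n": summary.n,
        "mean": summary.mean,
        "ci95_halfwidth": summary.ci95_halfwidth,
        "mean_percent": 100.0 * summary.mean,
        "ci95_halfwidth_percent": 100.0 * summary.ci95_halfwidth,
    }
    if "enrichment_ratio" in df.columns:
        enr = _prof.summarize_density(df["enrichment_ratio"].to_numpy())
        out["enrichment_mean"] = enr.mean
        out["enrichment_ci95_halfwidth"] = enr.ci95_halfwidth
    return out


def replicate_summaries(
    cfg: ConditionConfig, n_replicates: int, seed: int
) -> list[dict]:
    """Run ``n_replicates`` independent datasets of one condition."""
    root = np.random.SeedSequence(seed)
    out = []
    for rep_seq in root.spawn(n_replicates):
        df = run_condition(cfg, _child_seed(rep_seq))
        s = summarize_condition(df)
        s["df"] = df
        out.append(s)
    return out


def coverage_fraction(summaries: list[dict], truth: float) -> float:
    """Fraction of replicate 95% CIs that cover the true mean density."""
    hits = [
        abs(s["mean"] - truth) <= s["ci95_halfwidth"] for s in summaries
    ]
    return float(np.mean(hits))


def signal_background_experiment(
    n_images: int,
    seed: int,
    cfg: ConditionConfig | None = None,
    rho: float = 0.2,
) -> pd.DataFrame:
    """Per-image PM and vesicle signal/background ratios, shared background.

    Emulates ROI-based S/B measurement: a rectangular ROI over a PM section
    (1.0 x 0.4 μm, oriented along the membrane), a disc ROI surrounding the
    designated vesicle, and a nearby cytosol disc as the shared background.
    Vesicles carry a fixed density ``rho`` so the contrast between PM and
    vesicle S/B is attributable to membrane density, not vesicle-to-vesicle
    variation.
    """
    if cfg is None:
        cfg = condition_config("constitutive")
    mcfg = cfg.measurement
    root = np.random.SeedSequence(seed)
    rows = []
    for i, cell_seq in enumerate(root.spawn(n_images)):
        fixed = dataclasses.replace(
            cfg, density=DensityModel(rho, 1e-6, max(1.0, 2 * rho))
        )
        image = simulate_cell(fixed, cell_seq)
        scene = image.scene_truth
        vesicle = scene.vesicles[0]
        pm_point, tangent, _ = _nearest_pm(scene, vesicle.center)
        bg_center = find_background_point(scene, vesicle, mcfg)
        bg_roi = _prof.DiscRoi(bg_center, 0.3)
        pm_roi = _prof.RectRoi(
            tuple(pm_point), width=1.0, height=0.4,
            angle=float(np.arctan2(tangent[1], tangent[0])),
        )
        ves_roi = _prof.DiscRoi(vesicle.center, vesicle.radius + 0.3)
        role = mcfg.protein_role
        pm_sb = _prof.signal_background_ratio(image, role, pm_roi, bg_roi, "pm_rect")
        ves_sb = _prof.signal_background_ratio(image, role, ves_roi, bg_roi, "vesicle_disc")
        rows.append(
            {"image": i, "pm_sb": pm_sb.ratio, "vesicle_sb": ves_sb.ratio}
        )
    return pd.DataFrame(rows)


def nonsignificance_proportion(
    n_replicates: int, seed: int, alpha: float = 0.05
) -> tuple[float, list[float]]:
    """Monte-Carlo proportion of replicate pairs with p > alpha.

    Each replicate simulates the receptor condition (truth 0.28, n=91) and
    the constitutive condition (truth 0.20, n=45) and compares recovered
    per-vesicle densities with an unpaired t-test, mirroring the reported
    non-significant contrast between the two experiments.
    """
    root = np.random.SeedSequence(seed)
    receptor = condition_config("receptor")
    constitutive = condition_config("constitutive")
    pvals = []
    for rep_seq in root.spawn(n_replicates):
        s1, s2 = rep_seq.spawn(2)
        d_r = run_condition(receptor, _child_seed(s1))["density_ratio"].to_numpy()
        d_c = run_condition(constitutive, _child_seed(s2))["density_ratio"].to_numpy()
        pvals.append(_stats.unpaired_t(d_r, d_c).p_value)
    prop = float(np.mean([p > alpha for p in pvals]))
    return prop, pvals


def bystander_null_fdr(
    n_panels: int,
    seed: int,
    q: float = 0.01,
    n_replicates: int = 4,
    compartments: tuple[str, ...] = ("EE", "RE", "LE"),
    agonists: tuple[str, ...] = ("iso", "DA", "ACh"),
) -> float:
    """Fraction of all-null bystander panels with >= 1 (false) discovery.

    Simulates the agonist-vs-control endosomal panel with every agonist
    effect set to zero, runs paired t-tests with two-stage FDR at ``q``,
    and reports the panel-wise false-discovery proportion, which should not
    exceed ``q`` by more than Monte-Carlo error.
    """
    root = np.random.SeedSequence(seed)
    fractions = {c: _bret.DEFAULT_FRACTIONS[c] for c in compartments}
    treatments = {"control": {}, **{a: {} for a in agonists}}
    any_rejection = 0
    for panel_seq in root.spawn(n_panels):
        study = _bret.simulate_bystander_study(
            fractions, treatments, n_experiments=n_replicates,
            seed=_child_seed(panel_seq),
        )
        pairs = [
            (study[(comp, agonist)], study[(comp, "control")])
            for agonist in agonists for comp in compartments
        ]
        _, decision = _stats.paired_t_fdr(pairs, q=q)
        if decision.n_rejected > 0:
            any_rejection += 1
    return any_rejection / n_panels


def unpaired_t_type_i_error(
    n_reps: int = 10_000, n_per_group: int = 8, alpha: float = 0.05, seed: int = 0
) -> float:
    """Vectorized null simulation of the pooled t-test's type-I error rate."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_reps, n_per_group))
    b = rng.standard_normal((n_reps, n_per_group))
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    df = 2 * n_per_group - 2
    sp2 = ((n_per_group - 1) * (va + vb)) / df
    t = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(sp2 * (2.0 / n_per_group))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return float(np.mean(p < alpha))


# ---------------------------------------------------------------------------
# RunConfig / run_experiment (preset front end)
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """A fully seeded, reproducible experiment request."""

    preset: str
    seed: int
    out_dir: Path | None = None
    n_cells: int | None = None
    write_images: bool = False
    overrides: dict = field(default_factory=dict)


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable config echo."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def _condition_echo(cfg: ConditionConfig) -> dict:
    echo = dataclasses.asdict(cfg)
    return json.loads(json.dumps(echo, default=str))


def run_experiment(config: RunConfig) -> dict:
    """Execute a preset end to end; returns (and optionally writes) the bundle.

    The summary JSON carries the mean, CI, n, every seed, and a hash of the
    full config echo, so any run can be reproduced exactly from its output.
    """
    if config.preset == "bystander_panel":
        return _run_bystander_experiment(config)
    cfg = condition_config(config.preset, **config.overrides)
    logger = get_logger()
    try:
        df = run_condition(cfg, config.seed, n_cells=config.n_cells)
        summary = summarize_condition(df)
    except Exception as exc:
        raise type(exc)(
            f"[stage: simulate/measure, preset={config.preset}, seed={config.seed}] {exc}"
        ) from exc
    echo = _condition_echo(cfg)
    bundle = {
        "preset": config.preset,
        "seed": config.seed,
        "config_hash": config_hash(echo),
        "summary": summary,
        "config": echo,
    }
    logger.info(
        "preset=%s seed=%d n=%d mean=%.4f ci95=%.4f",
        config.preset, config.seed, summary["n"], summary["mean"],
        summary["ci95_halfwidth"],
    )
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "vesicles.csv", index=False)
        (out / "summary.json").write_text(json.dumps(bundle, sort_keys=True, indent=1))
        if config.write_images:
            _write_condition_images(cfg, config.seed, out / "images",
                                    n_cells=config.n_cells)
    bundle["per_vesicle"] = df
    return bundle


def _run_bystander_experiment(config: RunConfig) -> dict:
    agonists = ("iso", "DA", "ACh")
    compartments = ("EE", "RE", "LE")
    fractions = {c: _bret.DEFAULT_FRACTIONS[c] for c in compartments}
    treatments = {"control": {}, **{a: {} for a in agonists}}
    study = _bret.simulate_bystander_study(
        fractions, treatments, n_experiments=4, seed=config.seed
    )
    pairs, labels = [], []
    for agonist in agonists:
        for comp in compartments:
            pairs.append((study[(comp, agonist)], study[(comp, "control")]))
            labels.append(f"{comp}:{agonist}")
    results, decision = _stats.paired_t_fdr(pairs, q=0.01)
    table = pd.DataFrame(
        {
            "hypothesis": labels,
            "test_kind": [r.test_kind for r in results],
            "statistic": [r.statistic for r in results],
            "df": [r.df for r in results],
            "p_value": [r.p_value for r in results],
            "rejected": decision.rejected,
        }
    )
    echo = {"preset": "bystander_panel", "agonists": agonists,
            "compartments": compartments, "q": 0.01}
    bundle = {
        "preset": config.preset,
        "seed": config.seed,
        "config_hash": config_hash(echo),
        "summary": {
            "n_hypotheses": len(labels),
            "n_rejected": decision.n_rejected,
            "q": 0.01,
        },
        "config": echo,
        "tests": table,
    }
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "bystander_tests.csv", index=False)
        slim = {k: v for k, v in bundle.items() if k != "tests"}
        (out / "summary.json").write_text(json.dumps(slim, sort_keys=True, indent=1))
    return bundle


def _write_condition_images(cfg, seed, out_dir, n_cells=None):
    n = cfg.n_cells if n_cells is None else n_cells
    root = np.random.SeedSequence(seed)
    for i, cell_seq in enumerate(root.spawn(n)):
        image = simulate_cell(cfg, cell_seq)
        _syn.write_dataset(
            image, image.scene_truth, Path(out_dir) / f"cell{i:03d}",
            seeds={"master": seed, "cell": i},
            config_echo=_condition_echo(cfg),
        )
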