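"""BRET ratio arithmetic and generative models of plate-reader experiments.

Bioluminescence resonance energy transfer (BRET) between a nanoluciferase
donor and a fluorescent-protein acceptor is read as two spectral windows on
a photon-counting plate reader.  The arithmetic implemented here:

* raw BRET  = acceptor-window counts (520–545 nm) / donor-window counts
  (475–495 nm) — scale-invariant in luciferase expression;
* net BRET  = raw BRET − raw BRET of donor-only cells (zero for donor-only
  wells by construction; may legitimately be negative and is not clipped);
* agonist delta = mean raw BRET in a response window minus the mean in a
  pre-injection baseline window of a kinetic trace.

"Bystander" BRET pairs the tagged protein with an inert membrane marker of
a compartment, reporting co-residence on that membrane.  The simulator
models a compartment's net BRET as amplitude x colocalization-fraction
plus Gaussian well noise; absolute amplitudes are free parameters, so only
within-compartment contrasts (e.g. agonist vs control) are meaningful —
bystander signals cannot be compared between compartments.  Kinetic traces
are piecewise-exponential approaches to a new steady state after each
injection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateReferenceError, ParameterError, WindowError

__all__ = [
    "LuminescenceReading",
    "BretTrace",
    "BystanderPanel",
    "raw_bret",
    "net_bret",
    "agonist_delta",
    "simulate_kinetic_trace",
    "simulate_bystander_panel",
    "simulate_bystander_study",
    "read_plate_csv",
    "write_plate_csv",
]

#: Default colocalization fractions per compartment, emulating the observed
#: ordering PM >> late > recycling > early endosomes >> ER ~ mitochondria.
DEFAULT_FRACTIONS = {
    "PM": 1.0, "LE": 0.35, "RE": 0.25, "EE": 0.18, "MT": 0.02, "ER": 0.02,
}


@dataclass
class LuminescenceReading:
    """Dual-window photon counts from one well at one timepoint."""

    donor_counts: float   # 475–495 nm window
    acceptor_counts: float  # 520–545 nm window
    well_id: str = ""
    condition: str = ""

    def __post_init__(self):
        if self.donor_counts < 0 or self.acceptor_counts < 0:
            raise ParameterError("photon counts must be >= 0")


@dataclass
class BretTrace:
    """A kinetic BRET time series with injection events."""

    times: np.ndarray
    readings: list[LuminescenceReading]
    injections: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size != len(self.readings):
            raise ParameterError("times and readings must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ParameterError("times must be strictly increasing")
        for t, label in self.injections:
            if self.times.size and not (self.times[0] <= t <= self.times[-1]):
                raise ParameterError(f"injection {label!r} at t={t} outside the trace span")

    def raw_series(self) -> np.ndarray:
        return np.array([raw_bret(r) for r in self.readings])


@dataclass
class BystanderPanel:
    """Net-BRET replicates for one (compartment, treatment) cell."""

    compartment: str
    net_bret_replicates: np.ndarray
    treatment: str = "control"

    def __post_init__(self):
        self.net_bret_replicates = np.asarray(self.net_bret_replicates, dtype=float)
        if self.net_bret_replicates.size < 1:
            raise ParameterError("a panel needs at least one replicate")


def raw_bret(reading: LuminescenceReading) -> float:
    """Acceptor-window counts divided by donor-window counts."""
    if reading.donor_counts <= 0:
        raise DegenerateReferenceError(
            f"well {reading.well_id or '<unnamed>'}: donor counts must be > 0"
        )
    return reading.acceptor_counts / reading.donor_counts


def net_bret(raw: float, donor_only_raw: float) -> float:
    """Raw BRET minus the donor-only raw BRET.  May be negative; not clipped."""
    if not (np.isfinite(raw) and np.isfinite(donor_only_raw)):
        raise ParameterError("raw BRET values must be finite")
    return raw - donor_only_raw


def _window_mean(trace: BretTrace, window: tuple[float, float], name: str) -> float:
    t0, t1 = window
    if t1 <= t0:
        raise WindowError(f"{name} window must have t0 < t1, got {window}")
    if t0 < trace.times[0] or t1 > trace.times[-1]:
        raise WindowError(f"{name} window {window} exceeds the trace span")
    sel = (trace.times >= t0) & (trace.times <= t1)
    if not sel.any():
        raise WindowError(f"{name} window {window} contains no samples")
    return float(trace.raw_series()[sel].mean())


def agonist_delta(
    trace: BretTrace,
    baseline_window: tuple[float, float],
    response_window: tuple[float, float],
) -> float:
    """Mean raw BRET in the response window minus the baseline-window mean.

    The baseline must end before the first injection, and the two windows
    must not overlap.
    """
    if response_window[0] < baseline_window[1]:
        raise WindowError("response window must start after the baseline window ends")
    if trace.injections:
        first = min(t for t, _ in trace.injections)
        if baseline_window[1] > first:
            raise WindowError(
                f"baseline window must end before the first injection at t={first}"
            )
    base = _window_mean(trace, baseline_window, "baseline")
    resp = _window_mean(trace, response_window, "response")
    return resp - base


def simulate_kinetic_trace(
    injections: list[tuple[float, str, float, float]],
    duration: float = 300.0,
    dt: float = 2.0,
    baseline_raw: float = 0.60,
    donor_counts: float = 2.0e5,
    noise_sd: float = 0.003,
    seed: int = 0,
) -> BretTrace:
    """Simulate a kinetic BRET trace with sequential injections.

    Each injection is (time, label, delta, tau): after ``time`` the raw
    BRET relaxes exponentially (time constant ``tau`` s) toward the current
    steady state shifted by ``delta`` — e.g. an agonist step up followed by
    an antagonist/GDP step back down.  Gaussian noise of ``noise_sd`` is
    added to the raw ratio of each read.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration + dt / 2, dt)
    r = np.full_like(times, baseline_raw)
    target = baseline_raw
    for t_inj, _, delta, tau in sorted(injections, key=lambda e: e[0]):
        if tau <= 0:
            raise ParameterError(f"tau must be > 0, got {tau}")
        after = times >= t_inj
        start = r[after][0] if after.any() else target
        target = target + delta
        r[after] = target + (start - target) * np.exp(-(times[after] - t_inj) / tau)
    r_noisy = r + rng.normal(0.0, noise_sd, size=r.shape)
    readings = [
        LuminescenceReading(
            donor_counts=donor_counts,
            acceptor_counts=max(ri, 0.0) * donor_counts,
            well_id=f"kin{i:03d}",
            condition="kinetic",
        )
        for i, ri in enumerate(r_noisy)
    ]
    return BretTrace(times=times, readings=readings,
                     injections=[(t, lbl) for t, lbl, _, _ in injections])


def simulate_bystander_panel(
    fractions: dict[str, float] | None = None,
    n_replicates: int = 4,
    amplitude: float = 0.45,
    treatment_effects: dict[str, float] | None = None,
    treatment: str = "control",
    donor_only_raw: float = 0.60,
    donor_counts: float = 2.0e5,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> tuple[list[BystanderPanel], list[LuminescenceReading]]:
    """Simulate net-BRET bystander panels plus matched donor-only wells.

    Each replicate's net BRET is ``amplitude * fraction + effect + noise``;
    wells are generated as dual-window counts so the full raw -> net
    arithmetic is exercised, with donor-only wells providing the baseline.
    ``treatment_effects`` shifts compartments additively (all zero for a
    control / null panel).  Deterministic per seed.
    """
    fractions = dict(DEFAULT_FRACTIONS if fractions is None else fractions)
    effects = treatment_effects or {}
    for comp, f in fractions.items():
        if not (0.0 <= f <= 1.0):
            raise ParameterError(f"fraction for {comp!r} must lie in [0, 1], got {f}")
    if noise_sd < 0:
        raise ParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    if n_replicates < 1:
        raise ParameterError(f"n_replicates must be >= 1, got {n_replicates}")

    rng = np.random.default_rng(seed)
    donor_wells = [
        LuminescenceReading(
            donor_counts=donor_counts,
            acceptor_counts=(donor_only_raw + rng.normal(0.0, noise_sd)) * donor_counts,
            well_id=f"donor{i:02d}",
            condition="donor_only",
        )
        for i in range(n_replicates)
    ]
    donor_baseline = float(np.mean([raw_bret(w) for w in donor_wells]))

    panels = []
    for comp in sorted(fractions):
        raws = (
            donor_only_raw
            + amplitude * fractions[comp]
            + effects.get(comp, 0.0)
            + rng.normal(0.0, noise_sd, size=n_replicates)
        )
        wells = [
            LuminescenceReading(
                donor_counts=donor_counts,
                acceptor_counts=max(ri, 0.0) * donor_counts,
                well_id=f"{comp}{i:02d}",
                condition=f"{comp}:{treatment}",
            )
            for i, ri in enumerate(raws)
        ]
        nets = [net_bret(raw_bret(w), donor_baseline) for w in wells]
        panels.append(BystanderPanel(comp, np.array(nets), treatment=treatment))
    return panels, donor_wells


def simulate_bystander_study(
    fractions: dict[str, float],
    treatments: dict[str, dict[str, float]],
    n_experiments: int = 4,
    amplitude: float = 0.45,
    donor_only_raw: float = 0.60,
    donor_counts: float = 2.0e5,
    noise_sd: float = 0.01,
    n_donor_wells: int = 3,
    seed: int = 0,
) -> dict[tuple[str, str], np.ndarray]:
    """Simulate a multi-treatment bystander study of independent experiments.

    ``treatments`` maps treatment label -> per-compartment additive effects
    (empty dict = no effect, e.g. a control or a null agonist).  Each
    independent experiment measures its own donor-only wells, and that
    baseline is shared by every condition of the experiment — as in a real
    plate — so it cancels exactly in paired within-experiment contrasts.

    Returns ``{(compartment, treatment): net BRET across experiments}``.
    """
    for comp, f in fractions.items():
        if not (0.0 <= f <= 1.0):
            raise ParameterError(f"fraction for {comp!r} must lie in [0, 1], got {f}")
    rng = np.random.default_rng(seed)
    out = {
        (comp, tr): np.empty(n_experiments)
        for comp in fractions for tr in treatments
    }
    for e in range(n_experiments):
        donor_raws = donor_only_raw + rng.normal(0.0, noise_sd, size=n_donor_wells)
        baseline = float(
            np.mean([
                raw_bret(LuminescenceReading(donor_counts, max(r, 0.0) * donor_counts))
                for r in donor_raws
            ])
        )
        for comp in sorted(fractions):
            for tr, effects in treatments.items():
                raw = (
                    donor_only_raw
                    + amplitude * fractions[comp]
                    + effects.get(comp, 0.0)
                    + rng.normal(0.0, noise_sd)
                )
                well = LuminescenceReading(donor_counts, max(raw, 0.0) * donor_counts)
                out[(comp, tr)][e] = net_bret(raw_bret(well), baseline)
    return out


# ---------------------------------------------------------------------------
# Plate CSV I/O
# ---------------------------------------------------------------------------

PLATE_COLUMNS = ["well_id", "condition", "time", "donor_counts", "acceptor_counts"]


def write_plate_csv(readings, path, times=None) -> None:
    """Write readings to the plate CSV format (time column optional)."""
    rows = []
    for i, r in enumerate(readings):
        rows.append(
            {
                "well_id": r.well_id,
                "condition": r.condition,
                "time": None if times is None else times[i],
                "donor_counts": r.donor_counts,
                "acceptor_counts": r.acceptor_counts,
            }
        )
    pd.DataFrame(rows, columns=PLATE_COLUMNS).to_csv(path, index=False)


def read_plate_csv(path) -> pd.DataFrame:
    """Read a plate CSV; validates the required columns."""
    df = pd.read_csv(path)
    missing = {"well_id", "condition", "donor_counts", "acceptor_counts"} - set(df.columns)
    if missing:
        raise ParameterError(f"plate CSV missing columns: {sorted(missing)}")
    return df
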