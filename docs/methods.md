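# Methods

## The measurement problem

A peripheral membrane protein (here a tagged G-protein β subunit) is visible
at the plasma membrane (PM) and, more dimly, on endocytic vesicles. Raw
fluorescence cannot say whether a vesicle carries a lower *surface density*
of the protein or simply presents less membrane to the microscope: a
sub-resolution vesicle's signal scales with the membrane area inside the
point-spread function (PSF), not with density alone. The estimator
implemented here removes the geometry by co-staining with a lipophilic dye
(an FM4-64 / CellMask analog) that partitions into membranes at a density
proportional to surface area, identically at the PM and on vesicles. For
each vesicle and channel c ∈ {protein, reference dye}:

    S_c  = peak of a 3 μm line profile centered on the vesicle
    P_c  = peak of a 3 μm profile crossing a nearby clear PM section
    B_c  = mean of a nearby cytosol disc

    D = (S_p/P_p − B_p/P_p) / (S_r/P_r − B_r/P_r)

Because the two channels share the vesicle's geometry and the PSF, every
geometric factor cancels and D estimates ρ, the vesicle membrane density of
the protein as a fraction of its PM density. PM normalization also cancels
per-channel gain, laser power, and label brightness.

## Forward optics model (synthetic scenes)

Scenes are 2D single confocal planes. Membranes are 1D curves carrying a
line density of photons per μm — the PM contour (a circle with smooth
low-order radial perturbation, star-shaped about the cell center) and
vesicles as circles (equatorial sections of spheres). The cytosol is a
uniform area source inside the PM and outside the nucleus; vesicle lumens
are treated as cytosol-filled unless an explicit lumen level is set. The
noiseless field is the rasterized line/area integral convolved with an
isotropic Gaussian PSF and scaled by the detector gain; noise is Poisson on
the expected counts plus Gaussian read noise, rounded and clipped to the
bit depth.

All channels reuse the *same* rasterized geometry scaled per channel, so
the per-pixel ratio of membrane contributions equals the density ratio to
machine precision for any PSF width, vesicle radius, or rasterization
error. This makes the estimator's geometry-cancellation property testable
exactly: on noiseless, cytosol-free renders the pipeline returns D = ρ to
better than 1e-6 relative error across PSF σ ∈ {0.10, 0.15, 0.25} μm and
radii ∈ {0.25, 0.4, 0.6} μm. Cytosol-free is the right condition for that
test: the cancellation property is defined net of the cytosol contribution,
which background subtraction removes only approximately near membrane
edges (see "Known biases").

### Default parameters

| parameter | default | why |
|---|---|---|
| pixel size | 0.1 μm | typical sampling for a 63×/1.40 NA confocal |
| PSF σ | 0.15 μm | ≈ lateral resolution of that objective at ~510 nm |
| bit depth | 16 | photon-counting detector raster |
| PM line density | 2·10⁴ photons/μm | blurred PM peak ≈ 530 counts: bright, far from saturation |
| protein cytosol level | 2.7·10³ photons/μm² | ≈ 5% of the PM peak per pixel — "dim cytosolic fluorescence" |
| dye/receptor cytosol | 0 | membrane-partitioned dye; surface-labeled receptor |
| read noise | 3 counts (sd) | small relative to shot noise at these intensities |
| cell radius | 7.5–9.5 μm | HEK 293-like (~15–19 μm diameter) |
| nucleus radius | 4 μm, offset 1.5 μm | excluded from fluorescence |
| vesicle radius | 0.25–0.6 μm | sub-resolution to near-resolution endosomes |
| vesicles per image | 4; one measured | one vesicle sampled per cell/image |

None of the optics values is taken from a measurement; they are declared,
plausible assumptions, overridable in `ImagingConfig`/`GeometryConfig`.

### Per-vesicle density dispersion

The emulated experiments report means with wide 95% confidence intervals
(±8, ±8, ±17 percentage points at n = 45, 91, 78), implying large
vesicle-to-vesicle variability — including vesicles with no detectable
protein. The generator therefore draws each vesicle's true ρ from a Beta
distribution scaled to a bounded support (densities are nonnegative and
physically capped), with the sd back-solved from the reported half-width,
sd = hw·√n / t₀.₉₇₅,ₙ₋₁:

| condition | mean ρ | sd | support |
|---|---|---|---|
| constitutive | 0.20 | 0.266 | [0, 1.2] |
| receptor (protein) | 0.28 | 0.384 | [0, 1.6] |
| receptor (receptor channel) | 3.0 | 0.9 | [0, 6] |
| hras_ct | 0.64 | 0.754 | [0, 2.2] |

With these draws the pipeline's own 95% CI half-widths land on the reported
values, and the recovered means cover the truth in ≥95% of replicate
datasets (up to binomial Monte-Carlo error — a perfectly calibrated
interval misses a strict 95% threshold in a 50-replicate set about half
the time, so coverage tests subtract a two-standard-error margin).

## Measurement-layer choices

- **Peak window.** The peak is the maximum within the central third of the
  3 μm profile, so line ends grazing the PM or neighboring structures
  cannot win.
- **Profile orientation.** The vesicle line runs parallel to the local PM
  tangent — the orientation that maximizes distance to the PM. On real
  data the angle is caller-supplied.
- **PM reference.** The same peak operator on a PM-crossing profile, so
  both structures are treated symmetrically; a mean-based alternative
  ("mean within ±0.25 μm of the peak") is available via `pm_mode="mean"`.
  The peak search is restricted to the central window of the crossing
  profile, and the pipeline selects the nearest PM section whose crossing
  window is clear of every annotated vesicle — otherwise a bright
  (e.g. receptor-enriched) vesicle 1–1.5 μm under the membrane can
  masquerade as the PM and corrupt the normalization. This mirrors the
  manual practice of drawing the reference on a clean membrane stretch.
- **Background.** A 0.25 μm cytosol disc near the vesicle, placed
  truth-aware: candidates ring the vesicle starting toward the cell center
  and must clear the PM, the nucleus, and every vesicle. Normalization and
  subtraction commute; the code normalizes both signal and background by
  the PM reference, then subtracts.
- **Clipping.** Negative protein numerators are clipped to 0 rather than
  discarded — vesicles without detectable protein are data, not failures.
  A non-positive reference-dye numerator makes the vesicle unmeasurable;
  it is excluded and logged.
- **Summary statistic.** Mean with a two-sided Student-t 95% CI half-width,
  the standard small-n choice.
- **Coordinates.** Image origin top-left, x rightward, y downward, μm
  units, pixel centers at (i + 0.5)·pixel_size.

### Known biases (all small at default settings)

- The protein channel's cytosolic pool contaminates its PM reference peak
  by about half the cytosol level (the cytosol is a half-plane edge under
  the PSF at the PM), deflating D by ~2–3% relative. The real assay shares
  this property; it is why the high-density condition recovers ~62–64%
  rather than exactly 64%.
- Taking the maximum of a noisy profile biases near-zero vesicles slightly
  upward (~+0.5 points at default noise), partially offsetting the above.
- Pixel-pitch sampling can miss the true profile maximum by up to half a
  pixel (a few percent); this cancels between channels.

## BRET layer

Raw BRET is the acceptor-window count (520–545 nm) divided by the
donor-window count (475–495 nm); net BRET subtracts the donor-only raw
ratio and may legitimately be negative. Spectral windows are treated as
pre-integrated counts — plate readers report windowed intensities directly.
Kinetic traces are piecewise-exponential approaches to new steady states
after each injection, with configurable time constants.

Bystander panels model a compartment's net BRET as amplitude ×
colocalization fraction plus Gaussian well noise. The amplitude is a free
scale parameter: absolute bystander signals are *not* comparable between
compartments (acceptor expression and geometry differ), so the simulator
and tests only exercise within-compartment contrasts. For multi-treatment
studies, `simulate_bystander_study` generates independent experiments that
each share one donor-only baseline across all conditions, as on a real
plate; the baseline cancels exactly in paired within-experiment contrasts.
(Giving each arm its own baseline instead adds a shared offset to the
paired differences and inflates the paired-t type-I error — measured as a
3% panel-wise false-discovery rate at a nominal 1% before this design was
adopted.)

## Statistics

Classical two-sided t-tests: pooled-variance unpaired by default (Welch via
a flag; the emulated analysis did not state which), paired for
within-experiment contrasts. Multiple testing uses the two-stage linear
step-up FDR procedure of Benjamini, Krieger and Yekutieli at q = 0.01,
implemented directly: stage one runs the linear step-up at q' = q/(1+q) to
estimate the number of true nulls, stage two re-runs it at q'·m/(m−r₁).
Under the all-null panel simulation the panel-wise false-discovery
proportion measures ~1%, and the pooled t-test's type-I error at α = 0.05
is within [0.04, 0.06] at 10⁴ null replicates.

## What the generator does and does not emulate

It emulates: PM-bright cells with dim nucleus-excluded cytosol, membrane
surface-area reporting by a lipophilic dye, sub-resolution vesicles with
heterogeneous protein loading, receptor enrichment, PSF blur, shot and read
noise, and the plate-reader arithmetic of bystander/kinetic BRET.

It does not emulate: 3D optics or axial sectioning, spectral bleed-through,
chromatic offsets, vesicle motion during acquisition, lysosomal lumen dye
uptake kinetics, endocytosis time courses, or absolute BRET efficiencies.
Passing recovery tests therefore shows the *estimator* is unbiased and
calibrated under the stated imaging model — not that any particular
biological value is correct, nor that the method is robust to artifacts the
model excludes.

## Problem sizes

Recovery tests run 50 replicate datasets per condition (45/91/78 cells
each, one measured vesicle per cell); the non-significance contrast uses 20
replicate pairs; the null-FDR simulation 2000 panels; type-I calibration
10⁴ null tests. The acceptance script averages 24 replicate datasets per
condition. A full test run and an acceptance run each complete in a few
minutes on one CPU.
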