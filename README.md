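# endoquant

Ratiometric quantification of membrane-protein density on endocytic
vesicles from multi-channel confocal images, with BRET plate analytics and
the matching statistical layer — exercised end to end on synthetic images
with known ground truth.

## The problem

How much of a peripheral membrane protein ends up on the membrane of a
newly internalized endocytic vesicle, relative to its density at the plasma
membrane (PM)? Raw fluorescence cannot answer this: a sub-resolution
vesicle's brightness confounds protein density with the amount of membrane
surface area inside the imaging volume. The solution is to co-stain with a
lipophilic dye (FM4-64 / CellMask style) that reports membrane surface area
at PM-equal density, and form a dye-normalized ratio per vesicle:

    D = (S_p/P_p − B_p/P_p) / (S_r/P_r − B_r/P_r)

where S is the peak of a 3 μm line profile centered on the vesicle, P the
peak of a profile crossing a nearby clear PM section, B a nearby cytosol
background, for the protein (p) and reference-dye (r) channels. Geometry
and the point-spread function are shared by both channels and cancel, so D
estimates the vesicle membrane density ρ as a fraction of PM density.
Condition means are reported with Student-t 95% confidence intervals;
contrasts use an unpaired t-test; multi-compartment bystander-BRET panels
use paired t-tests with two-stage Benjamini–Krieger–Yekutieli FDR control
at 1%.

Because no real images ship with the package, a synthetic-imaging module
generates confocal-like cells (PM contour, nucleus-excluded cytosol,
vesicles with recorded per-channel ground-truth densities, Gaussian PSF,
Poisson + read noise) so every pipeline stage is testable against known
truth. The forward model shares one rasterized geometry across channels,
making the geometry cancellation exact by construction — on noiseless
renders the pipeline recovers D = ρ to machine precision for any PSF width
and vesicle size.

For who: anyone quantifying relative membrane densities from line profiles
(or validating such a pipeline), and anyone needing honest BRET arithmetic
(raw, net, kinetic deltas, bystander panels) with calibrated statistics.

## Worked example

Run the constitutive-endocytosis experiment preset: 45 simulated cells at
true vesicle density ρ = 0.20 of the PM (drawn per vesicle from a
calibrated dispersion), one measured vesicle per cell, full line-profile
pipeline:

```python
import endoquant as eq
from endoquant import experiments as ex

bundle = ex.run_experiment(eq.RunConfig(preset="constitutive", seed=7))
print(bundle["summary"])
```

prints

```
{'n': 45, 'mean': 0.2006, 'ci95_halfwidth': 0.085,
 'mean_percent': 20.0558, 'ci95_halfwidth_percent': 8.4993}
```

i.e. this dataset recovers 20.1 ± 8.5% (mean ± 95% CI, n = 45): the
vesicles carry about one-fifth of the PM density, and the CI half-width
matches the dispersion the preset was calibrated to. Presets `receptor`
(ρ = 0.28, n = 91, plus a ~3× enriched receptor channel) and `hras_ct`
(ρ = 0.64, n = 78) work the same way. `bundle["per_vesicle"]` holds the
per-vesicle table (peaks, backgrounds, D, ground truth).

The same pipeline is scriptable from the shell:

```sh
endoquant simulate --preset constitutive --n-cells 3 --seed 4 --out cells/
endoquant measure --image cells/cell000.tif --out results/
endoquant summarize --per-vesicle results/vesicles.csv
endoquant run --preset receptor --seed 1 --out results/receptor/
```

## Layout

- `endoquant.synthetic` — scene geometry, vesicle placement, forward
  optics, TIFF + ground-truth-JSON I/O
- `endoquant.profiles` — line profiles, PM reference, S/B ratios, the
  density-ratio estimator and summaries
- `endoquant.bret` — raw/net/kinetic BRET, bystander panel and study
  simulators, plate CSV I/O
- `endoquant.stats` — t-based CIs, pooled/Welch/paired t-tests, BKY
  two-stage FDR
- `endoquant.experiments` — presets, seed-splitting, the simulate →
  measure → summarize → test pipelines
- `endoquant.cli` — `endoquant` command-line verbs over the above

See `docs/methods.md` for the model, parameter defaults and their
rationale, calibration details, and known limitations.
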