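# colonyscan

High-throughput microbial phenomics on solid medium: from time series of
transmissive gray-scale plate images of pinned colony arrays (96, 384 or
1536 format) to calibrated colony population-size growth curves, minimum
population doubling times, and spatially normalized relative growth
phenotypes.

Quantifying fitness for tens of thousands of strains in parallel on agar
plates faces two coupled problems. First, raw scanner pixel intensities
are neither comparable between instruments nor proportional to cells, so
the pipeline calibrates pixels against a gray-scale strip of known
opacities and converts background-subtracted *pixel opacity* into cells
per pixel with a second calibration polynomial; summing over colony
pixels yields population sizes, and a sliding five-point log-linear
regression on the smoothed growth curve yields the minimum population
doubling time

&nbsp;&nbsp;&nbsp;&nbsp; *dt*<sub>min</sub> = 1 / max<sub>w</sub> slope( log₂ *N*(t) over window *w* ).

Second, colonies at different plate positions grow systematically
differently (edge effects, agar gradients, pinning variation).  With an
isogenic control strain pinned at every fourth position — the lower-right
position of every 2×2 tetrad — the control doubling times form an evenly
spaced reference grid that is interpolated into a per-position
*normalization surface*, and each colony's relative phenotype is

&nbsp;&nbsp;&nbsp;&nbsp; rel = log₂( *dt*<sub>surface</sub> / *dt*<sub>observed</sub> ),

negative for growth defects.  An adjacency false-positive diagnostic
(per-colony one-sample t-test of neighbors against non-neighbors)
measures how much spatial bias remains: 5% rejections at α = 0.05 means
none.

A synthetic-plate simulator with full ground truth (sigmoid growth in
cell counts, smooth multiplicative spatial bias on growth rate, pinning
and measurement noise, opacity-dome image rendering) makes every stage
testable without instrument data.

## Worked example

```python
import numpy as np
import colonyscan as cs

layout = cs.make_layout(384)
truth, curves = cs.simulate_growth_curves(layout, cs.SimParams(), seed=7)
images = cs.render_plate_series(truth, curves, cs.RenderParams(), seed=8)

acurves, table = cs.analyze_series(images, layout, cs.CellCountCalibration.identity())
feats = [cs.extract_features(cs.smooth_curve(cu)) for cu in acurves]

dt = np.array([f.dt_min for f in feats]).reshape(layout.rows, layout.cols)
print(f"median doubling time {np.median(dt):.2f} hr, plate CV {cs.plate_cv(dt):.1f}%")

surface = cs.surface_from_features(layout, feats)
phenotypes = cs.normalize_plate(feats, surface)
rel = phenotypes.frame["rel_phenotype_log2"]
print(f"relative phenotypes: mean {rel.mean():+.3f}, sd {rel.std():.3f} log2")

pre  = cs.adjacency_fp_rate(layout, dt).fp_rate
post = cs.adjacency_fp_rate(layout, np.log2(surface.expected_dt / dt)).fp_rate
print(f"adjacency false positives: {pre:.1%} before, {post:.1%} after normalization")
```

prints

```
median doubling time 1.99 hr, plate CV 3.9%
relative phenotypes: mean -0.001, sd 0.030 log2
adjacency false positives: 48.6% before, 10.8% after normalization
```

The simulated plate carries a smooth spatial bias field multiplying
growth rates (log₂ sd 0.05), so unnormalized doubling times make about
half of all colonies look significantly different from the rest of the
plate; reference-grid normalization collapses that toward the 5% chance
level (the remainder is the surface's own estimation noise, shared
between neighbors), and the residual phenotype scatter (≈0.03 log₂ ≈ 2%)
is the measurement noise floor.

The same stages are exposed as shell subcommands (`colonyscan simulate |
analyze | features | normalize | diagnose | pipeline`); run
`colonyscan --help` for details.

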