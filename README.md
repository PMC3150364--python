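# pmscan

Radial-scan quantification of plasma-membrane (PM) translocation in
live-cell fluorescence imaging.

Many signaling events read out as a protein moving between cellular
compartments: Raf is recruited to GTP-loaded Ras at the plasma membrane,
Erk accumulates in the nucleus, Akt touches the membrane on growth-factor
stimulation.  In an equatorial confocal section such recruitment appears
as a subtle brightening of the thin PM ring relative to the cytoplasmic
pool — often only a few percent, well below what whole-cell intensity
statistics can resolve across a plate of heterogeneously expressing
cells.  `pmscan` implements an automated, object-based analysis of this
readout for high-content screening: it segments cells, masks the PM, and
measures *local* intensity ratios so that large-scale intensity variation
(expression level, illumination) cancels out.

## The measurement

For each cell, 360 rays (1° apart) are cast outward from the nuclear
centroid.  Each ray stops at its first crossing of the PM mask, where a
local pixel-intensity ratio is recorded:

```
r(θ) = I_PM(θ) / I_cyto(θ)
```

with `I_PM` the peak reporter intensity within ±1.5 px of the crossing
and `I_cyto` the mean over a 5 px window of adjacent cytoplasm just
interior to it.  The per-cell PM/cytoplasmic ratio is the mean of the
valid ray ratios; fields report mean ± SEM over QC-passing cells.
Downstream layers provide:

* four-parameter logistic dose–response fits on log10 dose
  (`y = bottom + (top − bottom) / (1 + 10^((log EC50 − log x)·h))`),
* delayed single-exponential kinetics fits
  (`y = y0 + A (1 − e^{−k (t − t_lag)})`, onset lag profiled over the
  frame grid then refined continuously),
* the screening-window Z-factor
  (`z = 1 − 3(σ₊ + σ₋)/|μ₊ − μ₋|`), Welch t-tests, SEM,
* nuclear/cytoplasmic ratios (per-cell-first) and bulk pooled-pixel
  nuclear vs cytoplasmic intensities.

Because raw microscope data are rarely shareable, the package ships a
synthetic confocal-section generator (`pmscan.synth`) that renders
multi-channel fields of ring-and-disk cells with exact ground truth —
per-cell PM enrichment, nuclear/cytoplasmic ratio, dose- and
time-dependent response curves, camera noise — so every stage of the
pipeline is testable end to end.  Named presets
(`pmscan.presets.preset_names()`) capture the benchmark scenarios:
subtle serum-dependent recruitment (means 1.11 vs 1.08), a 10-point
inhibitor dilution (EC50 5.1 µM), stable/transient screening-window
populations (Z = 0.69 / 0.09), and delayed-onset kinetics (lags 0, 1,
7.5, 36 min; a 28.5 min sequential-addition gap).

## Worked example

Render a 400-cell serum-stimulated field, quantify it, and compare with
a serum-starved field:

```python
from pmscan import (get_preset, render_field, segment, radial_scan,
                    qc_filter, aggregate_cells, compare_groups)

img, gt = render_field(get_preset("akt-serum", seed=11))
records = radial_scan(img, segment(img))
qc_filter(records)
summary = aggregate_cells(records)
print(f"field mean PM/cyto ratio: {summary.mean_ratio:.4f} "
      f"+/- {summary.sem_ratio:.4f} (SEM)")
```

prints

```
cells detected: 400  pass QC: 400
field mean PM/cyto ratio: 1.1060 +/- 0.0022 (SEM)
ground-truth mean enrichment: 1.1078
starved mean: 1.0828;  Welch t = 7.49, p = 1.86e-13
```

— the measured field mean reproduces the true population mean to ~0.002,
and the 0.03 difference between stimulated and starved populations is
resolved decisively at n = 400 cells/group.  A ratio of 1.11 means the
reporter is 11% brighter at the membrane than in adjacent cytoplasm.

The same flows are available from the shell:

```sh
pmscan simulate --preset mcp110 --seed 1 --out-dir out/sim   # TIFF + truth
pmscan run-endpoint --preset mcp110 --seed 1 --out out/dose  # EC50 fit
pmscan run-timelapse --preset kin-meki --seed 1 --out out/kin  # onset fit
pmscan quantify out/sim/dose00/field00.tif --out cells.csv   # one field
```

`run-endpoint` prints the per-dose condition table and, e.g.,
`mcp110: EC50 = 5.21e-06 M, R^2 = 1.000` (the generating EC50 is
5.1 µM); `run-timelapse` on the delayed-recruitment preset prints
`kin-meki: t_lag = 35.80 min, k = 0.095/min, R^2 = 0.999`.

## Layout

| module | contents |
| --- | --- |
| `pmscan.synth` | synthetic field / dose-series / time-lapse generator, ground truth |
| `pmscan.presets` | named benchmark scenarios |
| `pmscan.segment` | centroid strategies, PM ridge mask, nuclear mask, territories |
| `pmscan.quantify` | 360-ray radial scan, QC, aggregation, nuclear readouts |
| `pmscan.models` | sigmoid / delayed-exponential fits, Z-factor, t-test, SEM |
| `pmscan.pipeline` / `pmscan.cli` | end-to-end runs, tables, CLI |

See `docs/methods.md` for the measurement model, parameter choices and
known limitations.
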