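# porodisc

Poroelastic simulation and inverse material identification for
intervertebral disks under cyclic compression.

The intervertebral disk is a fluid-saturated porous tissue: its
mechanical response to repetitive loading is governed by the interplay
of a deformable solid skeleton (collagen/proteoglycan matrix, drained
modulus `E`) and pressure-driven interstitial fluid flow (hydraulic
permeability `k`). Degeneration degrades the matrix and lowers the water
content, changing both parameters. Neither can be measured directly on
an intact motion segment — but both leave fingerprints in a
pressure-controlled cyclic compression test.

`porodisc` implements the full analysis pipeline around that idea:

- **`porodisc.fem`** — an axisymmetric Biot (u–p) finite-element solver
  for a two-region disk (nucleus pulposus core, anulus fibrosus ring)
  under preload + sinusoidal pressure protocols: 8-node quadrilaterals
  with quadratic displacement / bilinear pressure, backward Euler in
  time, exact Schur-complement stepping, verified against Terzaghi's
  consolidation closed form and a per-step fluid-mass balance.
- **`porodisc.metamodel`** — backward identification of `(E_NP, k)`
  from peak-to-peak deformations measured across a frequency sweep
  (0.01–6.3 Hz, 0.1–0.8 MPa): a 5×5 full-factorial design of
  experiments over the search window, a quadratic response surface
  (QRS) fitted to the normalized RMS error
  `100·sqrt(mean_f (sim−obs)²)/mean(obs)`, exact box minimization,
  re-simulation at the optimum, and window expansion until the
  re-simulated RMS is below 5%. The anulus is tied to the nucleus by
  `E_AF = 1.67·E_NP`, `k_AF = k_NP`. Exposed as a scikit-learn style
  estimator, `DiskParameterIdentifier`.
- **`porodisc.synthetic`** — seeded synthetic cohorts with the study's
  structure (9 intact + 9 enzyme-degenerated disks, truncated-Gaussian
  geometry/material from the published group means and SDs,
  multiplicative measurement noise), so the whole pipeline is testable
  without any data download.
- **`porodisc.stats`** — porosity from water content and density,
  pooled two-sample t-tests (from raw values or directly from
  mean (SD) summaries), and two-group LDA on `(E_NP, k)` with
  resubstitution accuracy.
- **`porodisc.freq_study`** — the loading-frequency parametric study
  (0.01/0.1/1/10 Hz): intradiscal pressure, total fluid loss and
  maximum axial effective stress, normalized to the intact disk at
  0.01 Hz, with figure/CSV export.

See `docs/methods.md` for the model, its assumptions and its limits —
including why `k` is only weakly identifiable from 0.01–10 Hz data.

## Worked example

Simulate the frequency-sweep test on the mean intact disk (radius
13.18 mm, height 4.21 mm, porosities 0.80/0.92, `E_NP` = 1.41 MPa,
`k` = 2.17·10⁻¹⁶ m⁴/(N·s)):

```python
import porodisc as pdc

disk = pdc.mean_specimen("intact")
out = pdc.simulate_sweep(disk.geometry, disk.true_material)
for f, d in zip(out.frequencies, out.peak_to_peak):
    print(f"  {f:5.3f} Hz : {d:.3f} mm")
print(f"IDP {out.idp:.3f} MPa | fluid loss {out.total_fluid_loss:.2f} mm^3 | "
      f"max axial stress {out.max_axial_stress:.3f} MPa")
```

```
  0.010 Hz : 1.266 mm
  0.063 Hz : 1.264 mm
  0.100 Hz : 1.264 mm
  0.630 Hz : 1.264 mm
  1.000 Hz : 1.264 mm
  6.300 Hz : 1.264 mm
IDP 0.501 MPa | fluid loss 25.50 mm^3 | max axial stress 0.761 MPa
```

The peak-to-peak deformation barely changes across the sweep — at these
frequencies the disk is nearly undrained (its consolidation time
constant is hours), which is why the deformation level pins the modulus
sharply while the permeability is identified only weakly. Identifying
the parameters back from (noisy) observations:

```python
specimen = pdc.simulate_observations(disk, noise_cv=0.02, seed=1)
ident = pdc.DiskParameterIdentifier(
    geometry=specimen.geometry, window=pdc.default_window("intact")
).fit(specimen.frequencies, specimen.observed)
print(ident.e_np_, ident.k_, ident.rms_pct_final_, ident.converged_)
```

which converges below the 5% RMS acceptance threshold in one
25-simulation round (about half a minute on one core).

Reproducing the published group comparison directly from summary
statistics — e.g. the permeability row (intact 2.17 (0.36)·10⁻¹⁶ vs
degenerated 1.39 (0.29)·10⁻¹⁶, n = 9/9):

```python
from porodisc.stats import SummaryStat, t_test_from_summary
r = t_test_from_summary(SummaryStat("intact", 9, 2.17e-16, 0.36e-16),
                        SummaryStat("degenerated", 9, 1.39e-16, 0.29e-16))
print(f"k: t = {r.t_statistic:.2f}, df = {r.degrees_of_freedom}, p = {r.p_two_tailed:.2e}")
```

```
k: t = 5.06, df = 16, p = 1.16e-04
```

## Command line

```sh
porodisc simulate   --config run.yaml --out results/
porodisc identify   --observed obs.csv --geometry geom.json --out ident/
porodisc synth      --group intact --n 9 --seed 42 --out cohort/
porodisc cohort     --in cohort/cohort.csv --report report.json
porodisc freq-study --out fig3/
```

Every run writes a `manifest.json` (config echo + hash, seed, package
version, wall time) beside its outputs.

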