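# cranioflow

Quantification of intracranial blood flow from cardiac-gated phase-contrast
MRI (PC-MRI), for researchers studying cerebral haemodynamics — e.g. the
elevated arterial pulsatility seen in cerebral small vessel disease — who
need volumetric flow waveforms, pulsatility indices and rigorous
repeatability statistics from 2D PC-MRI and 4D flow acquisitions.

A 4D flow scan stores three velocity components **v** = (v_x, v_y, v_z)
(cm/s) plus a magnitude image on a 3D grid for each reconstructed cardiac
timeframe. `cranioflow` implements the full measurement chain:

1. **Reslicing** — extract a plane perpendicular to a vessel (centre point +
   direction vector) by trilinear interpolation and project velocities onto
   the vessel's unit vector *u*: `v_∥ = v · u`.
2. **Correction** — velocity-aliasing unwrapping (any ROI velocity ≥
   median + v_enc shifted by −2·v_enc, ≤ median − v_enc by +2·v_enc, per
   timeframe) and static background-phase subtraction (mean velocity over a
   background ROI).
3. **Quantification** — per timeframe, `Q(t) = Σ_ROI v_∥ · A_pixel`
   (cm/s · mm² · 0.01 → ml/s); summary parameters: mean flow and the adapted
   Gosling pulsatility index **PI = (Q_max − Q_min) / Q_mean**, computed
   from the lumen-summed volumetric waveform, never from per-pixel PIs.
   A mass-conservation check compares total arterial inflow (internal
   carotid + basilar) with total cerebral outflow.
4. **Statistics** — test-retest/intra-rater/inter-method agreement:
   two-way absolute-agreement single-measurement ICC(A,1) with Koo–Li
   grading (<0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good, >0.9 excellent),
   Bland–Altman limits of agreement (mean ± 1.96·SD), paired t-tests,
   Pearson correlation, and the lumen-area-vs-repeatability analysis.

Because no scan data ships with the package, a first-class synthetic
generator (`cranioflow.synth`) produces cardiac-gated phantoms with known
ground truth: pulsatile Poiseuille/plug tubes, venc wrapping, background
phase offsets, Gaussian velocity noise, and two intravoxel signal models
(ideal volume-averaging, and complex-signal magnitude weighting that
reproduces the partial-volume flow overestimation of coarse acquisitions).

## Worked example

Recover the pulsatility index of a 3 mm-radius vessel rasterised at the 4D
protocol's resolution (1 mm isotropic, 25 timeframes, v_enc 100 cm/s):

```python
from cranioflow import studies

r = studies.pi_recovery_study(voxel_mm=1.0, seed=0)
print(r)
```

```
{'voxel_mm': 1.0, 'realized_pi': 0.7913, 'recovered_pi': 0.7913,
 'pi_rel_err_pct': 0.0, 'realized_mean_flow': 3.0,
 'recovered_mean_flow': 2.8356, 'mean_flow_rel_err_pct': -5.4808}
```

The ground-truth waveform targets PI = 0.8; sampling it at 25 discrete
frames misses the systolic peak, so the *realized* PI is 0.7913 — and the
pipeline recovers exactly that, because PI is a ratio of flows and the
resolution-induced gain is constant over the cycle.  Mean flow through the
exact lumen mask is biased −5.5% at 1 mm (velocity smeared beyond the mask);
the threshold-mask flux protocol in the studies removes most of that bias.

Mass conservation on the nine-vessel circle-of-Willis phantom at SNR ≈ 10:

```python
c = studies.conservation_study(noise_sigma=4.5, seed=0)
print(c["balance"])
```

```
MassBalance(difference=-0.198, percent=-2.87,
            total_inflow=6.913, total_outflow=7.111)
```

Measured cerebral outflow exceeds inflow by 2.9% of inflow (ground truth
conserves mass exactly at every timeframe), gauging the pipeline's
precision at that noise level.

A complete two-session study (simulate → extract → quantify →
repeatability) is configured in `examples/demo_study.yaml`:

```bash
cranioflow run examples/demo_study.yaml
```

which writes NIfTI volumes and slices, tidy CSV waveform/metric tables, and
a repeatability table (ICC + grade, Bland–Altman, paired t) under
`demo_out/`.  The same steps are available as individual subcommands
(`cranioflow simulate | extract | quantify | repeatability | compare`).

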