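# striatospect

Quantitative striatal SPECT at the desk: a simulation and analysis pipeline
for studying how attenuation correction and collimator-blur correction
affect dopamine-transporter (DAT) SPECT quantification.

Striatal SPECT with tracers such as I-123 FP-CIT is read through the
**specific uptake ratio**

```
SUR = (striatal activity − background activity) / background activity
```

Reconstruction choices change that number substantially.  Photon
attenuation depresses counts from deep structures; the finite collimator
resolution blurs the small caudate and putamen into the background
(partial-volume effect).  Modern iterative reconstruction can compensate
for both — with a uniform attenuation map fitted as an ellipse around the
head ("Chang-style" uniform AC, μ = 0.11/cm) or a measured CT-based μ-map,
and with a constant or depth-dependent Gaussian model of the collimator
point-spread function — but each compensation also changes the noise in
the image, so methods can only be compared fairly at matched noise.

`striatospect` packages that whole experimental loop for anyone studying
reconstruction protocols for striatal quantification:

* **phantom** — a digital anthropomorphic basal-ganglia phantom: ellipsoidal
  head with left/right caudate+putamen chambers at configurable uptake
  ratios over a uniform background, a co-registered attenuation map with a
  scalp/skull shell, exact ground-truth SUR, and VOIs defined on the known
  geometry.  Includes the attenuation coefficient of the NaI carrier
  solution computed from embedded elemental mass-attenuation tables.
* **projector** — attenuated parallel-beam forward/backprojection with
  distance-dependent collimator blur (120 views over 360°, 150 mm circular
  orbit) and seeded Poisson counting noise at a clinical count budget
  (3.2–3.8 M counts, scaled to grid resolution).  Forward and adjoint agree
  to machine precision.
* **recon** — OSEM (30 subsets × 10 iterations) with the six correction
  combinations {ellipse-uniform AC, CT-based AC} × {no, constant,
  depth-dependent PSF correction}, all applied inside the iterative loop;
  Gaussian post-smoothing; a first-order multiplicative uniform-AC factor
  as a cross-check.
* **quantify** — voxelwise SUR, per-VOI SUR_mean/SUR_SD, average recovery
  AR (bias), RMSCOV (noise), aSUR (truth-free surrogate), bias-noise curves
  over a 0–16 mm smoothing sweep, and matched-noise comparison of methods.
* **experiments** — the three orchestrated studies: a seven-acquisition
  phantom series spanning true SUR 2.08–14.70 with measured-vs-true
  regression, a μ-sensitivity sweep (0–0.5/cm), and deliberate SPECT–CT
  misregistration of the μ-map (translations/rotations) emulating patient
  movement between SPECT and CT.

## Worked example

One acquisition at true SUR 2.08 (left) / 14.70 (right), reconstructed six
ways, unsmoothed:

```python
import striatospect as ss

print(f"mu(0.1 M NaI, 159 keV) = {ss.nai_solution_mu(0.1, 159.0):.4f} /cm")

cfg = ss.StudyConfig(sur_pairs=((2.08, 14.70),), master_seed=1,
                     smoothing_fwhms=(0.0, 8.0))
res = ss.run_phantom_study(cfg)
cell = res.voi_stats[res.voi_stats.s == 0.0]
for _, row in cell.iterrows():
    true = res.refs[(row.v, row.p)]
    print(f"{row.r:16s} {row.v:14s} true SUR {true:5.2f}  "
          f"measured {row.sur_mean:5.2f}  SD {row.sur_sd:4.2f}")
```

prints

```
mu(0.1 M NaI, 159 keV) = 0.1535 /cm
ell+p0           left_striatum  true SUR  2.08  measured  0.48  SD 1.34
ell+p0           right_striatum true SUR 14.70  measured  4.41  SD 2.59
ell+pc(method2)  left_striatum  true SUR  2.08  measured  0.87  SD 0.66
ell+pc(method2)  right_striatum true SUR 14.70  measured 10.12  SD 7.33
ell+pd(method2)  left_striatum  true SUR  2.08  measured  0.84  SD 0.69
ell+pd(method2)  right_striatum true SUR 14.70  measured  9.90  SD 6.49
ct+p0            left_striatum  true SUR  2.08  measured  0.55  SD 1.43
ct+p0            right_striatum true SUR 14.70  measured  4.79  SD 2.81
ct+pc(method2)   left_striatum  true SUR  2.08  measured  1.06  SD 0.72
ct+pc(method2)   right_striatum true SUR 14.70  measured 11.36  SD 7.48
ct+pd(method2)   left_striatum  true SUR  2.08  measured  1.03  SD 0.75
ct+pd(method2)   right_striatum true SUR 14.70  measured 10.94  SD 6.72
```

Reading the table: the carrier-solution attenuation coefficient rounds to
the 0.15/cm seen on phantom CT maps.  Every reconstruction underestimates
the true SUR (partial-volume losses), collimator-blur correction (`pc`,
`pd`) roughly doubles the recovered SUR relative to no correction (`p0`),
CT-based AC (`ct`) recovers slightly more than the uniform ellipse (`ell`),
and the blur-corrected images also carry lower relative voxel noise — the
trade-off that the bias-noise curves make explicit.

The same pipeline is scriptable from the shell:

```sh
striatospect experiment phantom-study --out runs/study --seed 1 --plot
striatospect experiment mu-sweep       --out runs/musweep
striatospect experiment misregistration --out runs/misreg
```

Each run writes CSV tables (`voi_stats.csv`, `curves.csv`, `matched.csv`,
`regressions.csv`) plus a JSON manifest with the config hash and seeds;
identical config and seed reproduce byte-identical tables.

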