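# isletvmo

Simulation and quantification toolkit for the **vascularized islet
micro-organ (islet-VMO)** — a microfluidic device in which human
pancreatic islets are embedded in a fibrin gel alongside endothelial and
stromal cells that self-assemble into living, perfusable capillary
networks.  Medium is driven hydrostatically from reservoir V_A through
an arteriole-side channel, across the vessel network in the tissue
chamber, and out through the venule-side channel to reservoir V_D, where
effluent fractions are collected.

The package is aimed at groups building or analyzing such devices who
want a desk-scale counterpart to the bench assay: a transport model to
interrogate *why* an effluent trace looks the way it does (which islets
contribute, how vessel proximity matters, what a new vessel would
change), plus the standard quantification procedures for vessel
morphometry, immune-cell localization and islet viability.

## What it computes

* **Geometry** — device description (chamber, channels, ports, vessel
  skeleton graph, islet discs), JSON and SWC-style I/O, rasterization to
  a material grid, and skeleton morphometrics: total vessel length,
  branch points (degree ≥ 3 after junction merging), diameters sampled
  at 50 µm arclength intervals.
* **Flow** — steady depth-averaged pressure-driven flow: ∇·(m∇p) = 0
  with Hele-Shaw mobility m = h²/12µ in vessel/channel lumen and Darcy
  mobility κ/µ in gel and islet tissue; reservoir heads give Dirichlet
  pressures ρg·head at the ports.  Finite-volume, harmonic-mean face
  mobilities, exactly conservative.
* **Transport** — transient advection–diffusion–reaction for oxygen,
  glucose and insulin over the frozen flow, with islet kinetics:
  Michaelis–Menten oxygen and glucose uptake with a hypoxic cutoff, and
  insulin secretion R·[b + (1−b)·cⁿ/(cⁿ+Kⁿ)] plus a first-phase term
  proportional to (∂c_GLC/∂t)₊; KCl depolarization forces maximal
  release.  Fully implicit upwind/backward-Euler stepping on factorized
  operators (unconditionally stable, positivity-preserving).
* **GSIS** — the perfusion protocol (1 h basal 5.5 mM → 1 h 16.7 mM →
  2 h recovery → 1 h 30 mM KCl), 10-minute effluent bins from −30 min,
  fold change relative to the −20–0 min starvation bins, per-islet
  attribution by secretion silencing (exact superposition), the
  vessel-addition experiment, and model-vs-experiment comparison.
* **Quantification** — immune-cell classification (adherent / invasive /
  islet-adjacent within 100 µm / background, with translated control
  ROIs for background extravasation) and per-islet Dead⁺/Hoechst⁺
  percentages.
* **Synthetic data** — seeded generators for vessel networks, islet
  loadings (20–25 islets µl⁻¹, <200 µm selection, ≈88 µm mean diameter)
  and labeled point scenes, so the whole pipeline runs with no external
  data.

## Worked example

```python
import isletvmo as vmo
from isletvmo.gsis import run_gsis, survey_run_config

device = vmo.default_device(seed=1)          # synthetic vessels + islets
print(len(device.islets), "islets")
print(vmo.network_stats(device.vessels))

res = run_gsis(device, survey_run_config(t_end_min=70.0))
print(res.series.to_frame().to_string(index=False))
k, peak = res.series.peak_fold_bin()
print(f"peak fold {peak:.2f} in bin ending {res.series.t_end_min[k]:.0f} min")
```

prints (elided):

```
24 islets
{'total_length_um': 25012.508849503756, 'n_branch_points': 17,
 'diameter_mean_um': 37.11396374806744, 'diameter_sd_um': 8.77666753653069,
 'n_diameter_samples': 532}
 t_start_min  t_end_min  glucose_mM  insulin_pmol  fold_change
       -30.0      -20.0    5.499965      0.066980     1.000715
       -20.0      -10.0    5.499965      0.066940     1.000125
       -10.0        0.0    5.499965      0.066924     0.999875
         0.0       10.0   16.674389      0.305631     4.566300
        10.0       20.0   16.698872      0.240716     3.596434
        20.0       30.0   16.699827      0.231516     3.458975
        30.0       40.0   16.699943      0.228786     3.418200
        40.0       50.0   16.699958      0.228034     3.406963
        50.0       60.0   16.699960      0.227902     3.404991
        60.0       70.0    5.525536      0.179357     2.679702
peak fold 4.57 in bin ending 10 min
```

Read it as the bench assay would: outlet glucose tracks the inlet step
(5.5 → 16.7 mM and back); insulin rises as the glucose front reaches the
islets, with a first-phase burst that makes the 0–10 min bin the peak
(here 4.6-fold over the starvation baseline), relaxes toward the
steady stimulated level (~3.4-fold), and falls once basal medium
returns.  `attribute_islets(device, cfg)` decomposes the same trace into
per-islet contributions and their distances to the nearest perfused
vessel.

## Layout

```
src/isletvmo/
  geometry.py    device description, rasterization, morphometrics, I/O
  synth.py       seeded generators: networks, islet loadings, point scenes
  flow.py        depth-averaged Darcy/Hele-Shaw finite-volume solver
  transport.py   O2/glucose/insulin transport + islet kinetics
  gsis.py        protocol, effluent binning, fold change, experiments
  immune.py      PBMC classification, control ROIs, dead/live counts
  export.py      HDF5 / legacy-VTK field export
  cli.py         `vmo` command-line front end
docs/methods.md  model assumptions, parameters, numerics, limitations
```
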