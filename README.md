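# sbrt4d

Desk-scale comparison of two respiratory-motion-management strategies for
stereotactic body radiotherapy (SBRT) of pancreatic tumors: the **internal
target volume (ITV) concept**, which irradiates the whole envelope of tumor
motion, and **adaptive tumor tracking**, which follows the tumor with the
beam. The package is aimed at medical physicists and method developers who
want a fully testable, dependency-light model of the 4D planning workflow —
no patient scans, no commercial planning system.

It provides:

* **`phantom4d`** — synthetic 10-phase 4D abdominal phantoms (GTV, duodenum,
  stomach, bowel, kidneys, liver, cord on a ~2 mm grid) with cosine
  breathing, rigid-dominant motion largest along the superior-inferior axis,
  and ground-truth displacement fields to a mid-ventilation reference phase.
* **`structures`** — motion envelopes (ITV), isotropic PTV margins, volumes,
  center-of-volume motion quantification: per-axis maximal displacement and
  the 3D motion magnitude (LR² + AP² + SI²)^½.
* **`dose3d`** — a declared surrogate for VMAT planning: two full arcs,
  conformal per-angle apertures with a Gaussian penumbra and exponential
  depth attenuation, prescription of 5 × 5 Gy normalized so D95(PTV) = 25 Gy,
  a fluence boost through the tumor silhouette emulating prescription to a
  covering isodose, and simultaneous-integrated-protection handling of
  PTV/OAR overlap (window 25–27.5 Gy, iterative aperture blocking).
* **`dose4d`** — 4D dose accumulation: arcs segmented at breathing-phase
  transitions, per-phase sub-doses (with rigid isocenter shift under
  tracking), warping to the reference phase through the ground-truth fields,
  interplay averaging over five fractions.
* **`dosemetrics`** — cumulative DVHs and the reported dose parameters
  (Dmin, Dmax, Dmean, D2, D95, D98, D0.1cc) plus constraint reports.
* **`cohort`** — a packaged 12-patient motion/PTV table, the study's
  statistics from first principles (exact paired Wilcoxon signed-rank,
  Spearman rank correlation, OLS regression), and a virtual-cohort runner
  producing the two-arm comparison table.

## Worked example

```python
from sbrt4d.phantom4d import PhantomConfig, make_phantom
from sbrt4d.structures import build_structure_sets, volume_cc, ptv_reduction_percent
from sbrt4d.dose3d import DoseEngine, plan_itv, plan_track
from sbrt4d.dose4d import accumulate_4d

# a patient-1-like anatomy: 10.4 mm SI motion, duodenum adjacent
cfg = PhantomConfig(grid_shape=(48, 48, 48),
                    motion_amplitude_mm=(2.4, 10.4, 3.3),  # AP, SI, LR
                    gtv_semiaxes_mm=(12, 12, 14))
phantom = make_phantom(cfg)
ssets = build_structure_sets(phantom, margin_mm=5.0)

v_itv = volume_cc(ssets["itv"]["ptv"])
v_trk = volume_cc(ssets["tracking"]["ptv"])
print(f"PTV_itv {v_itv:.1f} cc, PTV_track {v_trk:.1f} cc, "
      f"reduction {ptv_reduction_percent(v_itv, v_trk):.1f}%")

engine = DoseEngine(phantom.grid, phantom.body_mask)
res_itv = plan_itv(phantom, ssets, engine=engine)
res_trk = plan_track(phantom, ssets, engine=engine)
print("ITV objectives met:", res_itv.objectives_met,
      "| tracking objectives met:", res_trk.objectives_met)

acc = accumulate_4d(engine, res_trk.plan, phantom, "tracking")
gtv = ssets["tracking"]["gtv"].data
print(f"GTV Dmean: 3D {res_trk.dose.data[gtv].mean():.1f} Gy, "
      f"4D {acc.dose.data[gtv].mean():.1f} Gy")
```

prints

```
PTV_itv 30.8 cc, PTV_track 21.8 cc, reduction -29.3%
ITV objectives met: False | tracking objectives met: True
GTV Dmean: 3D 37.2 Gy, 4D 37.0 Gy
```

Read: sweeping a 10 mm motion into the target inflates the PTV by ~40%;
with this duodenum-adjacent anatomy the ITV plan cannot satisfy all
protection objectives while the tracking plan can; and under perfect
tracking of rigid motion the accumulated 4D tumor dose reproduces the
static plan — the interplay between arc delivery and breathing averages
out.

The cohort-level numbers (PTV size summary rows, the 16.8% ± 8.4% mean
reduction, the reduction-versus-motion regression slope −2.28, Spearman
ρ = −0.46 with p = 0.131, and the exact Wilcoxon p = 2/4096) are recomputed
from the packaged table by `sbrt4d.cohort.reproduce_table1_report()` or
from the shell:

```sh
sbrt4d table1            # fixture statistics as JSON
sbrt4d cohort --grid 64  # full two-arm virtual cohort
sbrt4d stats data.csv    # paired tests on any two-column CSV
sbrt4d dose4d --mode tracking --amplitude 2.4,10.4,3.3
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the cohort-table statistics from the packaged fixture and runs a
compact three-patient virtual cohort through the complete pipeline
(phantom → structures → both plans → 4D accumulation → metrics), echoing
the recomputed quantities to stderr and writing the results file.

## Layout

```
src/sbrt4d/        phantom4d, structures, dose3d, dose4d, dosemetrics,
                   cohort, cli; packaged fixture under data/
tests/             unit + property tests and the acceptance suite
docs/methods.md    model assumptions, parameters, numerical choices, limits
```
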