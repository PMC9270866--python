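# rvk — right-ventricular kinematics from sonomicrometry crystal arrays

`rvk` analyses recordings from epicardial sonomicrometry: arrays of
piezoelectric crystals sutured to the beating heart whose pairwise ultrasound
transit times yield 3-D coordinates over time. It targets the 20-crystal
right-ventricular (RV) layout used in experimental studies of functional
tricuspid regurgitation and ring annuloplasty — 6 crystals around the
tricuspid annulus, 13 on the RV free wall along three parallels (basal, mid,
lower), and 1 at the apex — recorded at 128 Hz together with LV, RV and
central venous pressure and ECG, in two states per animal (`Baseline` and
`TRA`, after tricuspid ring annuloplasty).

It is written for cardiovascular biomechanics researchers who need a tested,
scriptable replacement for ad-hoc analysis code, and ships a synthetic
deforming-ellipsoid phantom with exact ground truth so every stage of the
pipeline can be validated without animal data.

## What it computes

**Cycle landmarks and beat averaging.** End-diastole (ED) is the R-wave peak
on the ECG; end-systole (ES) is the time of maximum negative dP/dt of LV
pressure. Beats are linearly resampled onto a common 0–100 % cycle grid and
the first 4 usable consecutive cycles are averaged.

**Geometry** at a chosen cycle time: tricuspid annular area (TAA, shoelace
area of the 6 annular crystals projected on their least-squares plane),
percent annular reduction `100·(1 − TAA_TRA/TAA_Baseline)`, RV volume as the
convex hull of all 20 crystals (ml), and per-parallel cross-sectional area
(chord-closed polygon) and radius of curvature (in-plane least-squares circle
fit).

**Strain.** The crystals are triangulated into a free-wall membrane mesh and
refined by modified Loop subdivision (standard boundary rules). Because the
subdivision operator is linear and connectivity-preserving, the same operator
maps reference and deformed crystal positions, giving corresponding fine
meshes. Per face, the 2×2 deformation gradient **F** maps reference tangent
coordinates to deformed ones, and the Green–Lagrange tensor

```
E = ½ (FᵀF − I)
```

yields circumferential (E_cc) and longitudinal (E_ll) strains along
directions derived from the ventricular long axis, plus areal strain
`det F − 1 = dA/dA₀ − 1`. Two references are supported: *cardiac* strain
(each state vs its own ED over the cycle) and *interventional* strain (TRA vs
Baseline at matched ED or ES).

**Statistics.** Paired Student's t-test across animals (each its own
control), Shapiro–Wilk normality screening, and an exact Wilcoxon signed-rank
test (full sign-flip distribution with mid-ranks, zeros dropped), assembled
into a cohort report table of mean ± SD per state with p-values.

## Worked example

Generate a phantom pair whose annular ring is reduced to 53 % of its baseline
area (a 47 % reduction), then run the paired geometry analysis:

```sh
rvk simulate --seed 17 --out ./phantom
rvk geometry ./phantom/baseline ./phantom/tra
```

prints

```
          variable    Baseline         TRA
    TAA area (mm2)  993.431863  531.035025
  TA reduction (%)         NaN   46.545400
       RV EDV (ml)  156.126582  142.853245
RV CSA basal (mm2) 3296.450266 3296.359643
  RV CSA mid (mm2) 1905.928349 1904.841702
RV CSA lower (mm2)  578.294060  578.026487
 RV ROC basal (mm)   48.302467   48.292085
   RV ROC mid (mm)   38.373212   38.267973
 RV ROC lower (mm)   21.077130   21.144622
```

The measured annular reduction (46.5 %) recovers the prescribed 47 % to
within the 0.1 mm coordinate noise; hull volume falls as the annulus is pulled
inward, while free-wall cross-sections and curvatures are untouched — the
annuloplasty acts on the annulus, not the wall. The same pair in Python:

```python
from rvk import PhantomConfig, generate_phantom, averaged_beat, \
    cardiac_strain_timecourse, regional_aggregate

cfg = PhantomConfig(noise_sd=0.0, seed=1)
baseline, tra, truth = generate_phantom(cfg)
beat = averaged_beat(baseline)                       # 4-beat average
result = cardiac_strain_timecourse(beat, truth.layout, levels=2)
print(regional_aggregate(result.field_at(beat.es_phase_pct)))
```

The basal circumferential strain at end-systole prints as −0.0767, the
closed-form value ½(0.92² − 1) of the phantom's prescribed peak
circumferential stretch λ_c = 0.92.

Interventional strain maps (`rvk strain <tra> --mode interventional
--baseline <baseline> --figure map.png`) colour faces red for compression and
blue for stretch.

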