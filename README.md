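# twibio

Quantitative machinery for small-animal mild-TBI biomarker studies:
track-weighted tractogram imaging, diffusion-tensor ROI metrics, a
serial-dilution reverse-phase protein microarray (RPPM) quantification
pipeline, and the two-sample group statistics that tie them together —
all exercised end to end on synthetic phantoms with known ground truth.

## What it computes

**Track-weighted imaging (TWI).** Given a tractogram (a set of streamlines
in world-mm coordinates) and a reference grid, each voxel of a
track-weighted map holds the mean, over all streamlines passing through
that voxel, of a whole-track scalar:

* *average pathlength* — the track's total length L = Σᵢ ‖pᵢ₊₁ − pᵢ‖ (mm);
* *mean curvature (TWI-MC)* — the mean over interior points of the Menger
  curvature κᵢ = 4·Area(pᵢ₋₁, pᵢ, pᵢ₊₁) / (|pᵢ₋₁pᵢ|·|pᵢpᵢ₊₁|·|pᵢ₋₁pᵢ₊₁|)
  (mm⁻¹), which is exactly 1/r for points on a circle of radius r.

Streamline-to-voxel membership uses exact traversal of the half-open voxel
cells a segment crosses (Amanatides–Woo-style grid walking), so a track
counts once per voxel regardless of re-entries. ROI summaries are medians
over voxels with at least one traversing streamline.

**Diffusion tensor metrics.** The tensor D solves ln S = ln S₀ − b gᵀDg by
log-linearised least squares per voxel; eigenvalues λ₁ ≥ λ₂ ≥ λ₃ give
AD = λ₁, RD = (λ₂+λ₃)/2, TR = λ₁+λ₂+λ₃ and
FA = √(3/2)·√Σ(λᵢ−λ̄)² / √Σλᵢ², with ROI medians and label volumetry.

**RPPM quantification.** Spot fluorescence vs 1:1 serial dilution follows a
five-parameter logistic in log-log space,
y(x) = D + (A−D)/(1 + 10^{B(x_mid−x)})^G. The pipeline filters spots
(SNR < 2 or net fluorescence < 10 excluded), fits a slide-wide master
curve, removes outliers by a ROUT-style robust-scale + Benjamini–Hochberg
FDR test (Q = 0.01), refits, then fits each sample with the shape
(A, D, B, G) shared and only x_mid free. The abundance readout is the
y-intercept of the tangent at the maximum-slope point
(x\* = x_mid + log₁₀G / B) extrapolated to the undiluted position x = 0.

**Group statistics.** Independent two-sample t-tests (Student pooled by
default, Welch optional), mean ± SEM summaries, and the two-sided
t→p conversion p = 2·(1 − F_t(|t|; df)).

**Synthetic phantoms.** Seeded generators produce streamline bundles with
analytic length/curvature, two-group cohort phantoms in which the injured
group's ipsilateral bundles are truncated and straightened, DWI signals
from known tensors under the study scheme (b = 1200 s/mm², 81 directions +
8 b0), and dilution plates from known 5PL curves with noise and gross
outliers.

## Worked example

A 10-vs-10 cohort phantom with 20% ipsilateral streamline truncation,
analysed exactly like a study cohort — per-subject average-pathlength
maps, ROI medians over traversed voxels, then a two-sample t-test:

```python
import numpy as np
from twibio import synthetic, track_weighted_map, twi_roi_stats, t_test

spec = synthetic.CohortSpec(n_per_group=10, effect_truncation=0.2, seed=1)
subjects = synthetic.make_cohort(spec)

medians = {"sham": [], "injured": []}
for subj in subjects:
    twm = track_weighted_map(subj.streamlines, subj.grid, "pathlength")
    stats = twi_roi_stats(twm, subj.mask)
    value = stats.loc[stats.roi == "ipsilateral_cortex", "median"].iloc[0]
    medians[subj.group].append(float(value))

cmp = t_test(medians["sham"], medians["injured"])
print(f"sham    {cmp.mean_a:.3f} ± {cmp.sem_a:.3f} mm (n={cmp.n_a})")
print(f"injured {cmp.mean_b:.3f} ± {cmp.sem_b:.3f} mm (n={cmp.n_b})")
print(f"t = {cmp.t:.3f}, df = {cmp.df:.0f}, p = {cmp.p:.3g}")
```

prints

```
sham    7.971 ± 0.081 mm (n=10)
injured 6.359 ± 0.066 mm (n=10)
t = 15.457, df = 18, p = 7.79e-12
```

The sham medians sit at the phantom's nominal 8 mm bundle length, the
injured medians at ≈ 0.8 × 8 mm, and the pooled-variance t-test (df =
10+10−2) flags the truncation decisively.

The same analyses are scriptable from the shell:

```sh
twibio simulate cohort --seed 1 --out cohort/
twibio twi --tck cohort/sham_01.tck --ref cohort/reference_grid.nii.gz \
       --stat pathlength --out apm.nii.gz --counts counts.nii.gz
twibio rppm --spots plate.csv --q 0.01 --out quants.csv
twibio compare --data outcomes.csv --out stats.csv
```

## Layout

| module | contents |
| --- | --- |
| `twibio.core_imaging` | volumes, masks, schemes, tensor fit, FA/AD/RD/TR, ROI stats |
| `twibio.tractometry` | streamline length/curvature, voxel traversal, TWI maps |
| `twibio.rppm` | spot filtering, 5PL fits, ROUT-FDR, y-intercept quantification |
| `twibio.group_stats` | t-tests, t→p, mean ± SEM, batch comparisons |
| `twibio.synthetic` | seeded bundle/cohort/DWI/plate generators with ground truth |
| `twibio.io` | TCK + NIfTI-1 + scheme + CSV I/O, config, pipeline runner |
| `twibio.cli` | the `twibio` command |

See `docs/methods.md` for the models, parameter choices and limitations.
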