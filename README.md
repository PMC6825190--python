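# oralpdt

Analyses for evaluating 3D-printed intraoral light applicators for
photodynamic therapy (PDT) of early oral lesions: how stably an applicator
holds its aim inside a conscious patient's mouth, whether the delivered
light field covered the tumor margins, and how comfortable the applicator
was to wear.

PDT of the oral mucosa needs the light spot held on the lesion for tens of
minutes. To measure applicator stability, an endoscope fixed to the
applicator records a small fiducial ink mark on the buccal mucosa; the
mark's apparent motion *is* the applicator's motion relative to the tissue.
Treatment coverage is assessed photochemically: ALA-induced protoporphyrin IX
(PpIX) fluoresces in the red and is irreversibly photobleached by the
treatment light, so comparing pre- and post-irradiation fluorescence
photographs maps where therapeutic dose was actually delivered. Comfort is
scored on an ordinal 1–5 questionnaire.

## What the package computes

**Marker tracking** (`oralpdt.tracking`). For each frame *t* of an
endoscope video the pixels are clustered in RGB space with k-means
(Lloyd's algorithm, k = 3 for the three scene classes: ink mark, healthy
tissue, applicator). The cluster whose mean color minimises
‖μ_j − c_ref‖₂ is selected, where c_ref is the mean color of a
user-drawn region of interest on the first frame; the largest 4-connected
component of that cluster gives the marker mask, and its unweighted pixel
centroid (x̄_t, ȳ_t) the trajectory. Occluded or unmatched frames are
flagged invalid, never interpolated.

**Stability statistics** (`oralpdt.stability`). Centroids are converted to
millimetres via the known physical size of the ink mark and referenced to
their mean, giving displacements (Δx_t, Δy_t). Per subject: the horizontal
and vertical range (max − min) and sample SD (n − 1). Per cohort and
intraoral position (anterior buccal, posterior buccal, retromolar): mean ±
SD across subjects and Tukey boxplot summaries (25–75 % bars, 1.5 × IQR
whiskers, outliers beyond).

**Photobleaching quantification** (`oralpdt.photobleach`). Lesion mask from
Otsu's threshold on the pre-irradiation fluorescence channel; bleached mask
from the relative drop (I_pre − I_post)/I_pre ≥ 0.3 on registered pairs;
areas A = (pixel count)/(px/cm)². The margin-coverage statistic is the
per-patient excess A_bleached − A_lesion summarised as mean ± SD. On the
packaged five-patient pilot cohort this reproduces an excess of
**3.7 ± 1.5 cm²** with every lesion fully covered. Helpers convert the
clinical protocol (100 J/cm² over ~35 min) to irradiance (≈ 47.6 mW/cm²).

**Comfort survey** (`oralpdt.comfort`). Validated 1–5 responses per
(subject, position, question); means, sample SDs, score histograms and
"no tolerance" (score 5) counts; plus an exhaustive-search utility that
reconstructs integer score multisets consistent with published mean ± SD
summaries.

**Synthetic data** (`oralpdt.synthetic`). The clinical videos and
photographs are not public, so a seeded generator produces
ground-truth-annotated stand-ins: a colored elliptical mark over tissue with
Gaussian jitter, slow drift and sporadic horizontal-dominant raised-cosine
"swallow" excursions; and fluorescence pairs in which a bright lesion
darkens over a larger, containing bleached field. Every downstream stage is
validated by parameter recovery against this ground truth.

## Worked example

```python
import numpy as np
from oralpdt import (MotionParams, SceneParams, RoiSeed, TrackingConfig,
                     simulate_trajectory, render_frames, track_sequence,
                     CalibrationScale, trajectory_displacements, subject_stability,
                     load_area_table, margin_coverage_stats)

# 20 s of synthetic endoscope video: 0.2 mm jitter, ~1 swallow event expected
motion = MotionParams(jitter_sd=2.0, swallow_rate=3.0, n_frames=300, seed=42)
truth = simulate_trajectory(motion)
frames = render_frames(truth, SceneParams())

x0, y0 = truth.positions[0]
roi = RoiSeed(rect=(int(x0) - 7, int(y0) - 7, 14, 14))
traj = track_sequence(frames, roi, TrackingConfig(k=3, seed=7))
print(f"tracked {traj.n_valid}/{len(traj.valid)} frames")

rmse = np.sqrt(np.mean(np.sum((traj.centroids - truth.positions) ** 2, axis=1)))
print(f"RMSE vs ground truth: {rmse:.2f} px")

scale = CalibrationScale(10.0)   # 10 px/mm: the 20 px mark is a 2 mm ink dot
disp = trajectory_displacements(traj, scale)
s = subject_stability(disp, "S01", "anterior_buccal")
print(f"range h/v: {s.range_h_mm:.2f}/{s.range_v_mm:.2f} mm, "
      f"SD h/v: {s.sd_h_mm:.2f}/{s.sd_v_mm:.2f} mm, "
      f"outlier frames: {len(s.outlier_frames)}")

mc = margin_coverage_stats(load_area_table())
print(f"margin excess: {mc.mean_excess_cm2:.1f} +/- {mc.sd_excess_cm2:.1f} cm2, "
      f"all covered: {mc.all_covered}")
```

Output:

```
tracked 300/300 frames
RMSE vs ground truth: 0.07 px
range h/v: 6.60/3.46 mm, SD h/v: 0.93/0.48 mm, outlier frames: 17
margin excess: 3.7 +/- 1.5 cm2, all covered: True
```

The tracker follows the mark to well under a pixel. This run contains
swallow excursions, so the ranges are dominated by the two events the
simulation produced — the horizontal range is about twice the vertical one,
matching the 2:1 excursion amplitudes — while the SDs reflect the baseline
jitter plus the excursions, and the excursion frames are listed as Tukey
outliers. The pilot-cohort photobleached field exceeded every lesion by
3.7 ± 1.5 cm² on average: light reached beyond the tumor margins in all
five patients.

The same workflow is available from the shell:

```sh
oralpdt simulate video --config sim.yaml --out vid/
oralpdt track --video vid/ --roi 313,233,14,14 --k 3 --seed 7 --out traj.csv
oralpdt stability --traj traj.csv --px-per-mm 10 --out report.json
oralpdt bleach pair --pre pre.png --post post.png --px-per-cm 100 --out rec.json
oralpdt bleach table --out summary.json
oralpdt comfort --csv survey.csv --out comfort.json
```

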