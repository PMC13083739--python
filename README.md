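# petmoco

Rigid head-motion estimation, correction and quality metrics for dynamic
brain PET.

## The problem

Head motion during a PET acquisition blurs the reconstructed image and
biases regional uptake values — a real concern in brain PET/MR studies of
epilepsy ([¹⁸F]FDG) and tumour recurrence ([¹¹C]MET), where the
abnormalities of interest are small. Frame-based, data-driven motion
correction reconstructs short frames, registers each one rigidly to a
reference frame, and applies the resulting transforms during
reconstruction. Evaluating such a pipeline needs a consistent set of
motion and image-quality metrics:

* **Probe-point displacement** — two virtual points 70 mm anterior and
  70 mm posterior of the brain centre are moved by each frame's rigid
  transform; the Euclidean distance from their reference position is the
  per-frame absolute displacement.
* **Automatic motion categorisation** — per probe, the median absolute
  displacement over frames; the larger of the two medians `m` decides:
  *low* if `m < 1 mm`, *high* if `m > 2 mm`, *medium* otherwise.
* **Cumulative displacement-time histogram (cDTH)** — the fraction of
  scan time spent at or below each displacement magnitude, per probe;
  makes brief-but-large versus sustained motion visible where a single
  median cannot.
* **Masked normalized cross-correlation (XC)** — per evaluation frame
  `a` against the reference frame `b`, within a brain mask `M`
  (reference Gaussian-filtered at 16 mm FWHM, thresholded at 30 % of the
  filtered maximum), after 3 mm FWHM filtering of both volumes:

  `XC = Σ_M (a−ā)(b−b̄) / √( Σ_M (a−ā)² · Σ_M (b−b̄)² )`

* **Relative signal difference** — per ROI,
  `(ddMC − noMC) / ddMC × 100 %` of the mean signal, where `ddMC`/`noMC`
  are the motion-corrected/uncorrected static images; group summaries as
  median and interquartile range, compared with exact Mann–Whitney U
  tests under Bonferroni correction.

Since clinical list-mode data cannot be redistributed, the package ships
a procedural brain phantom (cortical shell, subcortical nuclei,
cerebellum, white matter, ventricles; FDG-like and MET-like contrast
regimes) and a motion simulator (static / drift / step / jitter
trajectories, Poisson counting noise at constant expected counts per
frame) so the whole evaluation chain runs end-to-end on synthetic data,
and accepts real NIfTI volumes and transform TSVs through the same
interfaces.

## Worked example

```python
import json
from petmoco import RunConfig, run_pipeline

cfg = RunConfig(shape=(40, 40, 40), spacing_mm=3.5, pattern="drift",
                translation_mm=(0, 4, 0), rotation_deg=(1, 0, 0),
                n_frames=8, seed=1)
summary = run_pipeline(cfg, "report")
print(json.dumps(summary, indent=1, sort_keys=True))
```

prints

```json
{
 "category": "high",
 "config_seed": 1,
 "deciding_median_mm": 2.087243,
 "mask_voxels": 13903,
 "median_xc_ddmc": 0.949118,
 "median_xc_nomc": 0.885853,
 "n_frames": 8,
 "reference_index": 0,
 "rel_diff_pct": {
  "CER": 5.666271, "FC": -2.064527, "GM": 1.384322, "HIP": -1.297444,
  "OC": 5.83945, "PC": -0.057339, "STR": 0.604536, "TC": 0.208458,
  "THA": 3.965138, "WB": 0.712662, "WM": -1.23048
 }
}
```

The scan drifts 4 mm anteriorly with a 1° nod over eight 30-s frames, so
the deciding probe median (2.09 mm) lands in the *high* category. The
estimated correction raises the median XC of the frames from 0.886 to
0.949, gray matter gains signal after correction (+1.4 %) while white
matter loses it (−1.2 %) — the signature of undoing motion-induced
signal mixing. The report directory also contains the motion plot, cDTH
curve, XC-over-time plot, the trajectory TSVs and the noMC/ddMC image
pair.

The same operations are available from the shell:

```sh
petmoco simulate --seed 1 --pattern drift --translation 0 4 0 --frames 8 --out scenario/
petmoco estimate scenario/frames.nii scenario/timing.tsv --out est.tsv
petmoco categorize est.tsv --brain-center 68.25 68.25 68.25 --out category.json
petmoco report --seed 1 --out report/
```

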