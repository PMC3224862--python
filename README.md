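# megfc

Source-space functional connectivity for MEG-style array data, exercised
entirely on synthetic inputs. The package provides:

* **`megfc.forward`** — closed-form magnetic lead fields for current dipoles
  in a spherically symmetric conductor (single sphere by default, per-channel
  sphere centers as the multi-sphere variant), with a deterministic
  tangential-orientation parametrization `theta = [r, delta]`.
* **`megfc.beamformer`** — scalar minimum-variance (LCMV-type) beamformer:
  covariance estimation, noise floor (minimum singular value), regularized
  unit-gain weights (`mu = 4` default), closed-form orientation optimization,
  grid scans, pseudo-T localizer contrasts, and signal-leakage diagnostics
  (weights-correlation and lead-field-correlation maps, volume-above-threshold).
* **`megfc.spectral`** — zero-phase FIR band filtering (the seven canonical
  bands from delta to high gamma), Hilbert envelopes, segmentation and
  segment-averaged envelopes.
* **`megfc.fc_metrics`** — the four connectivity metrics: AEC (per-segment
  envelope correlation averaged across segments), CAE (correlation of
  segment-averaged envelopes), band-pooled coherence and absolute imaginary
  coherence, plus per-segment FC timecourses and cross-metric timecourse
  correlation.
* **`megfc.significance`** — the simulation-based null framework: colored
  noise sources, synthetic empty-room sensor noise, uncoupled dipole-pair
  datasets, per-voxel null FC images, the weights-correlation binned
  correction (bin width 0.05), upper-fifth-percentile thresholding,
  per-subject confidence limits from concatenated mean-corrected null pools,
  exact (enumerative) Wilcoxon signed-rank tests, and
  envelope-spectrum-matched surrogate sources.
* **`megfc.crossmodal`** — volumetric map comparison: Gaussian smoothing,
  spatial correlation (optional seed-neighborhood exclusion), mask overlap,
  seed-based correlation volumes for 4-D data, Bonferroni thresholds and peak
  location.
* **`megfc.synthetic`** — generators for sensor helmets, voxel grids, coupled
  dipole pairs with ground truth, full resting + localizer experiments, and
  matched 4-D "hemodynamic" volumes. Every generator is a pure function of
  its parameters and RNG seed.
* **`megfc.workflows`** — end-to-end pair-level and map-level analyses
  combining the above.

Volumetric maps are written as NIfTI-1; datasets and weights travel in HDF5
run containers; tabular results are CSV.

## CLI

The `megfc` entry point wraps the main workflows:

```sh
megfc simulate --recipe recipe.json --seed 1 --n-channels 64 --out run.h5
megfc beamform --run run.h5 --band beta_low --window all --spacing-mm 10 --out w.h5
megfc fc --run run.h5 --weights w.h5 --name beta_low_all \
         --metric aec --delta 1,4,10 --seed-voxel 123 --out fc.csv
megfc null --run run.h5 --weights w.h5 --seed-voxel 123 --iterations 1 \
           --seed 7 --out null.nii
megfc threshold --real fc.nii --null null.nii --weights-corr wc.nii \
                --weights w.h5 --quantile 0.95 --out mask.nii
megfc compare --ref hemo.nii --maps beta.nii alpha.nii --weights w.h5 \
              --smooth-fwhm 8 --out compare.csv
megfc wilcoxon 1 2 3 4 5 6
```

## Conventions

* SI units internally (meters, tesla, A·m); grids and maps exported in mm;
  volumes reported in cm³.
* Voxel grids are regular lattices clipped to an inner sphere; in-mask voxels
  are ordered by C-order linear index of the bounding box, and ties in map
  peaks break toward the smallest linear index.
* Quantiles use linear interpolation between order statistics.
* The FC analysis window (resting phase) is independent of the covariance
  window used for the weights (`resting_only` vs `all_data` policies).
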