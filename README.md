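# wmh-subclass

Sub-classification of white matter hyperintensities (WMHs) by
T1-weighted intensity and spatial location, with cluster rim/core
decomposition, brain-volume-adjusted volumetrics, DTI-metric summaries
and cognitive-association linear models.

WMHs — bright regions on FLAIR MRI — are radiological signs of cerebral
small vessel disease, but "total WMH volume" lumps together lesions that
likely differ in severity and clinical meaning. This package implements
an automated, objective post-processing of an existing WMH segmentation
that splits the lesion burden along two axes:

* **Intensity**: a WMH voxel is *T1-hypointense* when the co-registered
  white-matter partial volume estimate (PVE) is ≤ 0.5 there (tissue
  segmentation assigns dark, damaged tissue to grey matter or CSF);
  otherwise it is *non-hypointense*.
* **Location**: WMH voxels are grouped into 3D connected clusters; a
  cluster is *periventricular* if any of its voxels overlaps an extended
  ventricle mask, else *deep*.

Combining the axes gives four sub-classes (periventricular/deep ×
hypointense/non-hypointense) whose volumes, adjusted for total brain
volume and log transformed, serve as predictors of cognitive scores in
per-outcome general linear models with Type III sums of squares.
A complementary decomposition splits clusters into those with vs without
hypointense voxels, and the former into hypointense *cores* and
hyperintense *rims*, with exact reconciliation:
non-hypointense volume = volume of clusters without hypointense voxels +
rim volume; hypointense volume = core volume.

The intended users are neuroimaging researchers who already have
co-registered, per-subject NIfTI volumes (WMH probability map or mask,
white-matter PVE, extended ventricle mask, brain mask, optional
FA/MD/AD/RD maps). The package never segments, registers or resamples —
a grid mismatch is an error, not a silent interpolation. A phantom
module generates fully synthetic subjects and cohorts with known ground
truth, so the entire toolkit is exercisable (and tested) without any
imaging data.

## Worked example

Render a phantom subject and run the full pipeline:

```python
from wmh_subclass.phantom import PhantomSpec, generate_subject
from wmh_subclass import run_subject

bundle, truth = generate_subject(PhantomSpec(seed=42))
res = run_subject(bundle)

d = res.decomposition
print("clusters:", res.clusters.n_clusters)
print("counts:", res.subclass_map.counts())
print(f"with-hypo clusters: {d.n_with_hypo}/{d.n_clusters_total} "
      f"({100*d.fraction_volume_with_hypo:.0f}% of WMH volume)")
for m, s in res.dti.items():
    print(f"{m}: hypo {s['hypo'].mean:.3f}, nonhypo {s['nonhypo'].mean:.3f}")
```

prints

```
clusters: 8
counts: {'peri_hypo': 15, 'peri_nonhypo': 44, 'deep_hypo': 37, 'deep_nonhypo': 24}
with-hypo clusters: 6/8 (73% of WMH volume)
FA: hypo 0.256, nonhypo 0.367
MD: hypo 1.107, nonhypo 0.912
AD: hypo 1.418, nonhypo 1.288
RD: hypo 0.983, nonhypo 0.722
```

The phantom planted 4 periventricular and 4 deep lesions; the pipeline
recovered all 8 as clusters and assigned every WMH voxel to exactly one
of the four sub-class codes (the counts sum to the WMH mask size). Six
of the eight lesions carry a hypointense core, and those clusters hold
73% of the lesion volume. The DTI summaries show the planted contrast:
hypointense tissue has lower fractional anisotropy and higher
diffusivities (mm²/s × 10⁻³) than non-hypointense tissue, the signature
of more severe white-matter damage.

The same stages are available from the shell:

```bash
wmh-subclass simulate --seed 42 --n-subjects 1 --out-dir sim/
wmh-subclass classify --wmh sim/sub-001/wmh.nii.gz \
    --pve sim/sub-001/wm_pve.nii.gz \
    --ventricles sim/sub-001/ventricle_ext.nii.gz --out-prefix out/sub-001
wmh-subclass clusters --wmh sim/sub-001/wmh.nii.gz \
    --pve sim/sub-001/wm_pve.nii.gz \
    --ventricles sim/sub-001/ventricle_ext.nii.gz --out out/clusters.csv
```

plus `intensity`, `volumes`, `dti`, `stats` (cohort regressions from a
CSV) and `run-all` (full pipeline from a YAML config, with provenance
sidecars recording parameters, version and input checksums). See
`wmh-subclass --help`.

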