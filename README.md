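# facegeom

Searchlight multivariate decoding, permutation inference with
threshold-free cluster enhancement (TFCE), and second-order
representational geometry for run-wise fMRI beta patterns — together with
a synthetic-data generator that plants the signal structure the analyses
assume, so the full pipeline is testable end to end without any imaging
data.

## What it implements

- **`facegeom.volume`** — volumetric data model: grids with affines,
  brain masks, inclusive-boundary sphere neighborhoods (the radius-5
  searchlight sphere has 515 voxels), coverage-count union masks,
  spherical ROIs with nearest-center overlap reassignment, NIfTI and
  plain-text table I/O.
- **`facegeom.simulate`** — session designs (11 runs × 48 trials over
  9 identities: 4 familiar, 4 unfamiliar, self, plus blank/oddball/buffer
  trials, greedy first-order counterbalancing), run × condition × voxel
  beta patterns with planted familiarity-shared, identity-specific and
  view-dependent components plus smooth noise, and optional BOLD-like
  time series that round-trip through the GLM.
- **`facegeom.estimation`** — per-run OLS beta estimation against
  HRF-convolved condition regressors with nuisance columns, CompCor-style
  PCA noise components, within-run z-scoring, and the condition filter
  that keeps the 4+4 familiar/unfamiliar identities.
- **`facegeom.crossval`** — deterministic split generators:
  leave-two-identities-out (16 splits; test identities never seen in
  training) and leave-one-run-out (11 splits); exhaustive balanced
  familiarity relabelings (35 after complement deduplication) and seeded
  within-run identity shuffles for the null distributions.
- **`facegeom.decoding`** — linear C-SVM decoding (mean-norm-scaled C,
  one-vs-one multiclass) of familiarity and identity, and sphere
  searchlight accuracy maps. Two interchangeable solver engines: a fast
  in-package dual coordinate-descent solver (default; numba-JIT) and
  libsvm via scikit-learn, asserted to agree in the tests.
- **`facegeom.inference`** — TFCE, and group z-maps from per-subject
  permutation nulls (10,000 group draws by default): FWE-corrected
  max-statistic z (default; threshold 1.65 ≈ p < 0.05 one-tailed
  corrected), plus voxel-wise mean/SD and rank variants.
- **`facegeom.rsa`** — split-half cross-validated RDMs (462 partitions
  for 11 runs, Fisher-z averaging, informative diagonal), within-subject
  correlation-distance geometry across ROIs, between-subject geometry
  with the reliability-normalized dissimilarity index (55 subject pairs
  at 11 subjects), classical MDS, the RV coefficient, and a
  random-intercept mixed-model contrast of within- vs between-system
  correlations with parametric-bootstrap CIs (`facegeom.lme` holds the
  profiled-REML solver, validated against statsmodels).
- **`facegeom.pipeline` / `facegeom.cli`** — YAML-configured
  simulate → decode → infer → rsa orchestration with per-stage seeds and
  a SHA-256 manifest of every output.

## CLI

```sh
facegeom simulate --config config.yaml --seed 1 --out dataset/ [--timeseries]
facegeom estimate --dataset dataset/sub-00 --out betas/
facegeom splits --scheme l2io --out splits.jsonl
facegeom decode --analysis familiarity --radius-vox 5 \
    --betas dataset/sub-00 --out accmap.nii.gz
facegeom infer --observed 'maps/sub-*_acc.nii.gz' \
    --nulls 'maps/sub-%d_perm*.nii.gz' --mask mask.nii.gz \
    --draws 10000 --seed 1 --out zmap.nii.gz
facegeom rsa --betas dataset/sub-00 --rois rois.tsv --out rsa/
facegeom rsa-group --rdms rdms/ --rois rois.tsv --variant within --out geometry/
facegeom run --config config.yaml --out rundir/
```

A config file is a YAML mapping with a single top-level `seed` (expanded
deterministically into per-stage seeds), the design, grid, planted-signal
and classifier parameters, and inference settings; see
`tests/test_pipeline.py::yaml_config` for a complete example.

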