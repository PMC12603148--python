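# lucent

Detection of **radiolucent foreign body aspiration (FBA)** on chest CT by
airway morphology, at desk scale.

Radiolucent foreign bodies — food fragments, plant matter — have
soft-tissue attenuation and produce no bright object on CT, so a majority
of adult FBA cases are missed or misdiagnosed on imaging. What *is*
visible is indirect: an obstructed bronchus cannot be followed distally,
so the segmented airway tree is truncated. `lucent` implements the full
two-stage pipeline that exploits this:

1. **Airway segmentation** — a 3D encoder–decoder CNN (skip connections,
   residual blocks, channel attention) labels the tracheobronchial lumen
   voxel-wise, trained with the focal loss
   `L = −α_t (1−p_t)^γ log p_t` (γ = 2.0, α = 0.25) against the
   airway/background imbalance.
2. **Multi-view classification** — the binary mask becomes a triangulated
   surface; 12 orthographic snapshots (224×224, camera ring of radius
   150 mm, 30° apart) feed a residual 2D CNN with a 256-unit head,
   dropout 0.5 and SoftMax; patient-level probability is the arithmetic
   mean over views, thresholded at 0.5.

Around the two models the package provides everything needed to train,
evaluate and compare: the standardized CT preprocessing chain (1 mm
isotropic resampling, [−1000, +400] HU clip, min-max normalization, 128³
centroid crop, Gaussian σ = 1.0 smoothing), volumetric segmentation
metrics (DSC, VOE, RVD, ASSD, precision, FNR, FPR, mIoU), patient-level
classification metrics, McNemar and DeLong paired tests, bootstrap F1
confidence intervals, stratified patient-level 5-fold assignment — and a
**synthetic airway-phantom generator**, since clinical FBA cohorts are
private: parametric bronchial trees rasterized into CT-like volumes, with
a soft-tissue plug and distal truncation planted in positive cases.
Neural networks are implemented in NumPy with hand-written, finite-
difference-validated gradients, so the whole pipeline runs and trains on
one CPU with no deep-learning framework.

Intended users: researchers reproducing or extending airway-morphology
FBA detection, and anyone needing a self-contained, dependency-light
test bed for multi-view 3D-shape classification pipelines in medical
imaging.

## Worked example

`examples/06_paired_statistics.py` evaluates two readers of the same
70-patient cohort (14 FBA / 56 controls) from their confusion counts — a
deep model (TP 10, FN 4, TN 53, FP 3) against expert readers
(TP 5, FN 9, TN 56, FP 0):

```
   model: accuracy 90.0%  precision 76.9%  recall 71.4%  F1 74.1%
 readers: accuracy 87.1%  precision 100.0%  recall 35.7%  F1 52.6%

discordant pairs: model-only-right b=5, readers-only-right c=3
McNemar two-sided p = 0.7266 (exact binomial, b+c < 25)
model F1 74.1% with bootstrap 95% CI [51.8, 90.3]%
```

The model trades the readers' perfect precision for twice their recall,
which is what lifts its F1; with only 8 discordant patients the McNemar
test cannot distinguish overall error rates at this cohort size.

The other examples each exercise one capability end to end —
`01_generate_phantom_cohort.py` (synthetic cohorts),
`02_preprocess_volume.py` (CT preprocessing), `03_train_airway_segmentation.py`
(3D segmentation + metric suite), `04_render_views.py` (meshing and the
12-view snapshot ring), `05_multiview_classification.py` (classifier
training and patient-level evaluation). A thin CLI mirrors the stages
(`lucent phantom`, `lucent seg-train`, `lucent render`,
`lucent evaluate`, `lucent run --config run.yaml`, ...).

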