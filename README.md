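# calcinet

A multi-task fully convolutional network for mammographic calcification
analysis: a depth-5 U-Net-style encoder–decoder that *segments* calcified
regions and, from a convolutional branch attached at the bottleneck,
*classifies* the lesion as low-risk (grade I/II) vs high-risk (grade III
and/or occult invasive disease). The package also ships the surrounding
pipeline — DICOM/PNG/TIFF ingestion with vendor LUT support, the
augmentation stack, patient-level grade-stratified splitting with 5-fold
cross-validation, training with Adam and a step-decay schedule, and
evaluation (DICE, rank-based AUROC, PPV/NPV at a 0.5 likelihood threshold
with per-patient CC/MLO view averaging).

Because clinical mammograms are private, the package includes a first-class
**synthetic cohort generator** that renders phantom mammogram-like images
whose class signal is morphological: low-risk lesions are clusters of small
round blobs, high-risk lesions are denser elongated/branching linear
segments, with intensity distributions matched between classes. The
defaults mirror the target cohort structure (grade mix 30.0/41.6/28.4%,
upstage rate 14.7%, CC+MLO views per patient), making the whole pipeline
exercisable end-to-end at desk scale.

The neural network, backpropagation, and Adam are implemented in pure
NumPy (no GPU frameworks required), as are minimal single-frame DICOM and
NRRD codecs.

## Test

```bash
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which checks the loss and
metric implementations against brute-force oracles, partition and schedule
conformance, generator quota allocation, and an end-to-end learnability run
(three seeds, ~100 synthetic patients, depth-3 network at 128×128; about
5–6 minutes on one CPU core).

## CLI

```bash
# 1. generate a synthetic cohort (images, masks, manifest CSV)
calcinet synth --config run.yaml --out cohort/

# 2. patient-level grade-stratified 80/20 split + 5 folds
calcinet split --manifest cohort/manifest.csv --fraction 0.20 --folds 5 --seed 0

# 3. cross-validated training (checkpoints + per-epoch history per fold)
calcinet train --manifest cohort/manifest.csv --config run.yaml --out ckpt/

# 4. fold-averaged evaluation under a labeling scenario
calcinet evaluate --checkpoints ckpt/ --manifest cohort/manifest.csv \
    --scenario pure --config run.yaml --out report.json

# 5. single-image inference
calcinet predict --checkpoint ckpt/fold1.ckpt --image cohort/images/P0001_CC.png \
    --center 128 120 --out predicted_mask.png
```

Scenarios: `pure` excludes upstaged patients and labels grade III positive;
`upstage` labels grade III and/or upstaged positive. Exit codes: 2 config
error, 3 data error, 1 other failure.

A `run.yaml` holds nested sections (`synth`, `augment`, `network`, `loss`,
`train`) whose keys mirror the config dataclasses in `calcinet.config`;
all hyperparameters (learning rate 0.00025 halved every 150 iterations,
batch 16, 500 epochs, 1024×1024 crops perturbed by ≤150 px, flip p=0.5,
gamma 0.95–1.05, ≤5% Gaussian noise, ...) default to the reference values.

## Layout

```
src/calcinet/
  config.py      configuration dataclasses, YAML loading, seed derivation
  synthetic.py   phantom cohort generator + separability check
  manifest.py    manifest CSV I/O, image/mask readers, labels, split/folds
  formats/       minimal DICOM (Explicit VR LE) and NRRD codecs
  augment.py     preprocessing + stochastic training augmentations
  network.py     dual-branch U-Net (segmentation head + bottleneck classifier)
  nn/            NumPy layers with manual backprop; Adam
  losses.py      focal loss, top-k pixel cross-entropy, combined loss
  trainer.py     schedule, per-fold training, cross-validation
  metrics.py     DICE, AUROC, PPV/NPV, patient view averaging, reports
  cli.py         command-line entry points
```
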