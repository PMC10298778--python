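# leukofrac

Weakly-supervised differential leukocyte counting for label-free
multiphoton microscopy mosaics.

## The problem

Diagnosing interstitial lung disease involves a differential cell count
of bronchoalveolar lavage fluid (BALF): the percentages of neutrophils,
eosinophils, lymphocytes and macrophages/monocytes among its leukocytes.
The standard cytology workflow (cytospin, staining, manual counting) is
slow and observer-dependent. Label-free microscopy — third-harmonic
generation (THG) plus multiphoton-excited autofluorescence (2PEF) —
images fresh, unstained samples in minutes, and the four leukocyte
classes are distinguishable in those images by size, nuclear shape and
channel intensities: granulocytes are bright in THG, eosinophil granules
also fluoresce in 2PEF, lymphocytes are small and dim, macrophages large
and variable.

`leukofrac` implements the full analysis around that idea for people
working on label-free cytology and weak supervision: a fraction-
regression network trained only on image-level differential counts, the
preprocessing chain that feeds it, a synthetic-mosaic generator with
exact ground truth, an automated morphometry oracle, case-level
evaluation, and Grad-CAM auditing.

## The model

A mosaic `x` (two channels at a fixed 0.5 um/px) is mapped to fractions

    f(x) = softmax(W . GAP(phi(x)) + b)  in  Δ³,

where `phi` is a fully-convolutional trunk and GAP is global average
pooling — so any input size is accepted and the output always lies on
the probability simplex, as differential counts do. Training minimizes
the class-weighted mean absolute error

    L = (1/4) Σ_c w_c | f_c(x) − y_c |,   w_c ∝ 1 / (mean_c + ε),

with Adam, a one-cycle learning-rate schedule, a frozen trunk during the
first epoch, early stopping on validation MAE, and label-preserving
augmentation. Grad-CAM at the last convolutional block localizes what
drives each class output; on synthetic data the activation can be
audited quantitatively against the generator's cell masks.

## Worked example

Generate a small synthetic dataset, measure it with the morphometry
oracle, and run the full experiment:

```python
>>> from leukofrac.synthgen import MosaicSpec, render
>>> from leukofrac.morphometrics import detect_cells, summarize
>>> spec = MosaicSpec(width_px=2000, height_px=2000,  # 1 mm^2
...                   fractions=(0.05, 0.003, 0.353, 0.594),  # BAL1-like
...                   density=549, seed=3)
>>> mosaic = render(spec)
>>> cells = detect_cells(mosaic.image)
>>> len(mosaic.cells), len(cells)
(549, 549)
>>> summarize(cells, area_mm2=mosaic.image.area_mm2)[["n", "diameter_mean", "density_per_mm2"]]
     n  diameter_mean  density_per_mm2
0  549      14.303572            549.0
```

549 cells were requested at the BALF density of 549 cells/mm^2; the
oracle re-detects all of them, and the pooled mean diameter (~14.3 um)
reflects the macrophage-dominated composition (macrophages measure
19.6 um on average against 7-9 um for the other classes). The same loop runs from
the shell:

```sh
leukofrac e2e --out run/ --seed 0
```

which generates 31 BALF-like cases (93 mosaics), preprocesses them,
trains the desk-scale network for up to 30 epochs, and prints a summary
including the held-out test accuracy and the per-class Grad-CAM
cell-vs-background activation ratios. Commands `generate`, `preprocess`,
`morphometry`, `train`, `evaluate` and `explain` expose the individual
stages; all take `--seed` and record their resolved configuration.

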