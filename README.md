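# rbcmorph

Automated, high-throughput classification and shape quantification of red
blood cells (RBCs) in brightfield microscopy frames, aimed at the
heterogeneous morphologies seen in sickle cell disease. The pipeline:

1. **Synthetic scenes** (`rbcmorph.synthetic`) — microscopy-like frames with
   per-cell ground truth across 8 morphology classes (discocyte,
   echinocyte, elongated, granular, oval, reticulocyte, sickle,
   stomatocyte), including touching clusters and debris, so every stage is
   testable without patient data.
2. **ROI extraction** (`rbcmorph.roi`) — sliding-window grey-level entropy
   (threshold 5.0 bits by default), hole filling, a 600 px² debris area
   prior, then cell-level mask refinement and tagging of regions as
   single / touching / overlapped (overlapped regions are discarded).
3. **Touching-cell separation** (`rbcmorph.separation`) — Euclidean
   distance-transform seeding (h-maxima) plus a seeded random-walker
   solved on the pixel lattice; verified against a dense
   absorbing-Markov-chain oracle in the tests.
4. **Patch normalization** (`rbcmorph.normalization`) — variable-size cell
   patches are pasted at the center of a 100×100 pure-background mask whose
   intensity is shifted by the corner-median difference ΔM; net inputs are
   bilinear 78×78 resizes. Cell pixels are preserved exactly.
5. **Dataset machinery** (`rbcmorph.dataset`) — labeling schemes
   (`coarse5`, `refined8`, `oxydeoxy6`), exact six-variant augmentation
   (original, rot90/180/270, h/v reflection), and stratified 5-fold plans
   with a leakage guard that keeps augmented variants of one source patch
   in the same fold.
6. **CNN classifier** (`rbcmorph.cnn`) — a 10-layer conv/pool/dropout/dense
   network implemented directly on NumPy (im2col convolutions, manual
   backprop, SGD + weight decay, inverted dropout), gradient-checked
   against finite differences.
7. **Evaluation** (`rbcmorph.evaluation`) — confusion matrices, one-vs-rest
   precision/sensitivity/specificity/F-score/accuracy, ROC/AUC (tie-grouped
   sweep, equal to the Mann–Whitney rank statistic), k-fold reports.
8. **Shape factors** (`rbcmorph.shapes`) — contour tracing, smoothed-contour
   perimeter, convex hull, Feret calipers (1° steps), moments ellipse fit,
   and the derived factors ESF, CSF, Elongation, Convexity, Compactness.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (dataset-assembly
arithmetic, entropy closed forms, walker-vs-oracle equality, separation
quality on 20 synthetic clusters, normalization contracts, CNN gradient
check and a 600-patch synthetic training benchmark, metric identities,
shape-factor tolerances, k-fold properties). The full suite runs in a few
minutes on one CPU.

## CLI

```bash
# render synthetic frames with ground truth
rbcmorph generate --config scene.json --out frames/ --n-frames 5 --seed 1

# entropy ROI detection
rbcmorph extract --in frames/ --out rois/ --entropy-threshold 5.0 \
    --block 32 --stride 16 --min-area 600

# touching-cell separation into single-cell crops
rbcmorph separate --frames frames/ --rois rois/ --out cells/

# size-invariant normalization (100x100 mask, 78x78 net inputs)
rbcmorph normalize --cells cells/ --mask-source frames/frame_0000.tif --out norm/

# dataset assembly, training, evaluation
rbcmorph build-dataset --patches norm/net_inputs.npz --labels labels.csv \
    --scheme refined8 --augment --kfold 5 --seed 42 --out ds/
rbcmorph train --dataset ds/ --fold 0 --lr 0.01 --batch 20 \
    --weight-decay 0.01 --epochs 60 --seed 42 --out model.ckpt.npz
rbcmorph predict --model model.ckpt.npz --patches norm/net_inputs.npz --out preds.csv
rbcmorph evaluate --model model.ckpt.npz --dataset ds/ --fold 0 --out report/
rbcmorph cross-validate --dataset ds/ --epochs 60 --out cv.json

# shape quantification
rbcmorph shape-factors --cells cells/ --preds preds.csv --out shapes.csv

# end-to-end run (synthetic scene config JSON)
rbcmorph run --config run.json --out run/ --train
```

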