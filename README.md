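# ratpose

Markerless rodent landmark estimation and gait quantification.

Quantifying how a rat moves — joint heights, stride period, stance/swing
phases — matters in neuroscience and medicine (spinal cord injury,
Parkinson's and other movement-disorder models), but marker-based motion
capture requires surgery or tedious rigging.  `ratpose` estimates nine
anatomical landmarks (nose tip, eye, ear, front claw wrist, front claw
tip, back claw ankle, back claw palm, back claw tip, tail) directly from
side-view video frames of a rat on a treadmill, and derives joint-motion
statistics from the tracked coordinates.  Knee and hip are excluded: fur
makes them impossible to label reliably.

The estimator follows the cascade paradigm of human pose estimation:

* **Structures** — a shared convolutional backbone (feature maps 1/8 or
  1/4 of the input) feeding either a four-stage **cascade convolution
  network (CCN)**, where each stage refines the previous stage's
  prediction, or a two-stage **cascade hourglass network (CHN)** with
  encoder–decoder stages and residual skips.  Every stage is supervised
  during training (*intermediate supervision*); inference uses the last.
* **Decoders** — three ways to turn stage outputs into coordinates:
  **FCR** (direct fully connected regression, smooth-L1 loss), **HMP**
  (Gaussian label heatmaps + MSE, decoded by bicubic upsampling and
  argmax) and **HIR** (integral regression: joint softmax over the
  heatmap, probability-weighted expected index — the differentiable
  soft-argmax — trained with smooth L1 on the decoded coordinates).
* **Metric** — accuracy is normalised per image by the labelled nose–eye
  distance: `error_i = ||pred_i − label_i|| / ||nose − eye|| − p` with
  `p = 0.1`, correct iff `error_i ≤ 0`.  The Total is the mean of the
  nine per-landmark accuracies.

Since annotated rat-locomotion footage cannot be redistributed, the
package ships a synthetic generator (`ratpose.synth`): an articulated rat
silhouette with closed-form periodic gait kinematics and known sub-pixel
landmark positions, on which the whole pipeline — data, training,
evaluation, tracking, gait analysis — runs end-to-end.  The networks run
on a compact NumPy autodiff engine included in the package
(`ratpose.autodiff`), so there is no deep-learning framework dependency.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

`examples/quantify_gait.py` builds a 5-cycle synthetic gait video and
quantifies it from the ground-truth trajectory:

```text
video: 120 frames at 100 frames/s (24-frame stride period, 5 cycles)

stride peaks at frames [18, 42, 66, 90, 114]
estimated stride period: 24.0 frames (4.2 strides/s)
phase split: 85 falling / 35 lifting frames (duty factor 0.6: stance frames count as falling)

horizontal travel per phase (px):
  falling: fore  124.1  hind  147.7
  lifting: fore   45.8  hind   60.0
```

The detected period matches the configured 24 frames exactly; the hind
limb out-travels the forelimb during the falling phase, as expected from
its longer stride.  `examples/heatmap_codec.py` shows the decoders on
encoded heatmaps (stride 8, 256×128 scene):

```text
  nose_tip           HMP error  0.36 px | HIR error  0.32 px
  back_claw_ankle    HMP error  0.08 px | HIR error  0.18 px
```

`examples/train_small_model.py` trains a toy cascade in about a minute
and prints per-stage accuracies; `examples/generate_synthetic_data.py`
renders an annotated dataset.

There is also a thin CLI covering the same pipeline:

```bash
ratpose generate --n 400 --seed 7 --out data/
ratpose train --annotations data/annotations.json --out run/ --seed 7 --epochs 12
ratpose infer --model run/model.npz --annotations data/annotations.json --out preds/
ratpose eval --annotations data/annotations.json --predictions preds/predictions.json --out report/
ratpose quantify --model run/model.npz --frames video/ --out gait/
```

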