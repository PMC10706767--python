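# marginseg

Margin-aware tumor segmentation for intra-operative B-mode ultrasound.

During colorectal cancer surgery the excised specimen can be imaged with a
high-frequency transducer placed directly on the resection plane, so the
top of each image *is* the cut surface. Whether the operation succeeded
hinges on the **top tumor margin** — the distance, in millimeters, from
that surface down to the shallowest tumor pixel. `marginseg` is a library
and CLI for building and evaluating segmentation models around that
quantity, for researchers working on ultrasound-guided margin assessment:

* **Losses** — the generalized Dice loss

  `GenDice = 1 − 2 Σₖ wₖ Σₙ gₖₙ pₖₙ / Σₖ wₖ Σₙ (gₖₙ + pₖₙ)`, `wₖ = 1/(Σₙ gₖₙ)²`,

  and its depth-weighted extension (GWDice), which multiplies the tumor
  channel by a quadratic depth gradient `t(x) = ((x − maxM)/(maxM − minM))²`
  (1 at the shallowest tumor row, 0 at the deepest) so that the pixels
  that determine the surgical margin dominate training. Both come with
  analytic gradients.
* **Metrics** — Dice coefficient, the top-margin error
  `E = |TM_gt − TM_pred|` in mm, pooled pixel-wise ROC/AUC, and a
  threshold sweep that exposes the trade-off between the best-Dice and
  best-margin operating points.
* **Ensembles** — unweighted/weighted averaging, voting, and a logistic
  pixel combiner over multiple models' probability maps, with
  validation-split optimization of weights, vote counts and thresholds.
* **Training harness** — compact numpy encoder-decoder variants with a
  transfer-learning protocol: pre-train on a source domain, fine-tune all
  layers at a 10× smaller learning rate.
* **Phantom simulator** — seeded B-mode-like phantoms (hypoechoic lesions
  with margin depth 6.4 ± 3.7 mm, speckle, attenuation, patient-wise
  splits) so the entire pipeline is testable without clinical data.

## Worked example

```python
import numpy as np
from marginseg import (PhantomSpec, generate_phantom, gradient_weight_mask,
                       gen_dice_loss, gw_dice_loss, tumor_margin_error)

spec = PhantomSpec(seed=0, image_shape=(64, 64),
                   row_spacing_mm=0.2344, col_spacing_mm=0.586)
img, mask = generate_phantom(spec, patient_seed=5)

# a prediction that misses the top three tumor rows
pred = mask.astype(float)
top = np.nonzero(mask.any(axis=1))[0][0]
pred[top:top + 3] = 0.0

weights = gradient_weight_mask(mask)
print(f"margin error: {tumor_margin_error(mask, pred >= 0.5, spec.row_spacing_mm).error_mm:.3f} mm")
print(f"GenDice loss: {gen_dice_loss(mask, pred):.4f}")
print(f"GWDice  loss: {gw_dice_loss(mask, weights, pred):.4f}"
      f"  (perfect prediction scores {gw_dice_loss(mask, weights, mask.astype(float)):.4f})")
```

```
margin error: 0.703 mm
GenDice loss: 0.0290
GWDice  loss: 0.5404  (perfect prediction scores 0.4867)
```

The 29 missing shallow pixels cost 0.03 in plain generalized Dice but
raise GWDice by 0.054 above its perfect-prediction value — and erasing
the *same number* of pixels from the tumor bottom instead leaves GenDice
at exactly 0.0290 while GWDice drops to 0.4650, below the perfect score:
under the printed weighting, depth is everything. (GWDice's nonzero value
at the perfect prediction is inherent to its form — the weight field, not
the mask, fills its denominator; training compares candidates, not
absolute values.)

The same pipeline runs from the shell:

```bash
marginseg simulate --n-patients 74 --seed 7 --out data/
marginseg train --data data/ --variant ed8 --loss gw_dice --out ckpt.npz
marginseg predict --data data/ --checkpoint ckpt.npz --out maps/
marginseg evaluate --data data/ --maps maps/ --out report/
marginseg sweep --data data/ --maps maps/ --out sweep.csv
```

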