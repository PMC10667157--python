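# fatseg

Automated quantification of abdominal adipose tissue on axial MR series:
fully convolutional segmentation of subcutaneous (SAT) and visceral
(VAT) fat, slice-to-volume integration, and the agreement/reliability
statistics used to validate fat volumetry — packaged with a synthetic
abdominal phantom generator so the whole pipeline is trainable and
testable without patient data.

Intended for researchers in body-composition imaging who need either a
working SAT/VAT pipeline on NIfTI/DICOM series or a controlled synthetic
benchmark for segmentation and volumetry methods.

## What it computes

Each axial slice is segmented into background / SAT / VAT. For a series
with pixel area `A` and per-slice through-plane extent `d` (slice
thickness + interslice gap), compartment volumes are

    V_c = sum over slices of  (pixel count of class c) * A * d

Cohort-level agreement between predicted and reference volumes uses the
relative errors `e_i = (V_pred,i − V_true,i) / V_true,i` and reports
Pearson R, the bias MPE = mean(e), the variation SD = population std(e),
RMSPE = sqrt(mean(e²)) with the exact identity `RMSPE² = MPE² + SD²`,
the second Wasserstein distance of mean-normalised volumes, excess
kurtosis, ICC(2,1), a root-mean-square coefficient of variation, and
Bland–Altman limits `mu ± 1.96·SD`.

Three encoder–decoder networks are provided — UNet (skip
concatenation), DenseUNet (dense blocks), and CDFNet (competitive
fusion by element-wise maximum with max-unpooling index transfer) — in
a compact numpy implementation with explicit backpropagation, plus an
automated histogram-threshold baseline (body mask → Otsu with
intermeans refinement → SAT/VAT split by connectivity to the body
boundary).

## Worked example

```python
from fatseg import PhantomSpec, generate_subject, quantify_subject
from fatseg.baseline import segment_slice
from fatseg.metrics import segmentation_scores
import numpy as np

spec = PhantomSpec(image_size=192, n_slices=12, noise_sigma=0.0)
subject = generate_subject(spec, subject_seed=21)

pred = np.stack([
    segment_slice(sl, pixel_spacing_mm=spec.pixel_spacing_mm)
    for sl in subject.series.in_phase
])
scores = segmentation_scores(pred, subject.truth)
vols = quantify_subject(pred, subject.series.geometry)
true = subject.true_volumes

print(f"SAT Dice {scores.dice_sat:.3f}  VAT Dice {scores.dice_vat:.3f}")
print(f"SAT {vols.sat_l:.2f} L (true {true.sat_l:.2f})  "
      f"VAT {vols.vat_l:.2f} L (true {true.vat_l:.2f})")
```

Output:

    SAT Dice 1.000  VAT Dice 0.749
    SAT 3.65 L (true 3.65)  VAT 0.91 L (true 0.54)

The baseline recovers the subcutaneous ring essentially exactly on a
noiseless phantom but overcalls visceral fat, because the phantom's
kidney and bowel signals deliberately overlap the fat intensity tail —
the regional misclassification that affects intensity-threshold methods
on real abdominal MR, and the failure mode the trained networks learn
to avoid.

The same pipeline runs from the shell: `fatseg phantom`, `fatseg
baseline`, `fatseg train`, `fatseg crossval`, `fatseg predict`, `fatseg
quantify`, `fatseg evaluate` (see `fatseg --help`).

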