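# fissint — pulmonary fissure integrity quantification

Pulmonary fissures are the thin pleural folds that separate the lobes
of the lung. On CT they appear as faint bright sheets, and they are
frequently *incomplete*: part of the inter-lobar boundary carries no
fissure at all. Fissure completeness matters clinically — an incomplete
fissure is a candidate pathway for inter-lobar collateral ventilation,
which can defeat endobronchial-valve lung-volume-reduction treatment in
severe COPD.

`fissint` implements an automated fissure-integrity pipeline and the
cohort statistics used to study whether integrity varies with COPD
severity:

1. **Detection** — multi-scale Hessian plate-likeness filtering.
   With magnitude-ordered eigenvalues |λ₁| ≤ |λ₂| ≤ |λ₃| of the
   scale-normalized Hessian, the sheet response is

       P = exp(−R_sheet²/2α²) · (1 − exp(−R_blob²/2β²)) · (1 − exp(−S²/2c²))

   for λ₃ < 0, with R_sheet = |λ₂|/|λ₃|, R_blob = |2|λ₃|−|λ₂|−|λ₁||/|λ₃|
   and S the Frobenius norm; the response is thresholded, thinned to a
   one-voxel sheet, and verified against local image contrast.
2. **Anatomical labeling** — left-lung sheets are the left oblique
   fissure (LOF); right-lung sheets are split into the right oblique
   (ROF) and right horizontal (RHF) fissures by surface orientation
   (35° cone around the cranio-caudal axis) and position.
3. **Completion** — each detected patch is extrapolated to the full
   inter-lobar boundary with a thin-plate-spline height field over the
   patch's principal plane, clipped to the lung; the horizontal
   boundary additionally terminates at the oblique boundary.
4. **Integrity** — per fissure,

       integrity = 100 · area(detected fissure) / area(complete boundary)  [%]

   with an area-weighted aggregate over all three fissures for the
   entire lung (ELF). Values are assigned to six conventional levels
   ([0,20%], (20,40%], (40,60%], (60,80%], (80,90%], (90,100%]); only
   (90%,100%] counts as a *complete* fissure.
5. **Cohort statistics** — GOLD staging from post-bronchodilator
   spirometry (FEV₁/FVC < 70% ⇒ COPD; stages I–IV at FEV₁ %predicted
   80/50/30), group summaries, integrity-level distribution tables,
   Pearson correlation of integrity with FEV₁ and FEV₁/FVC, and
   Spearman correlation with severity.

No public CT cohort accompanies this problem, so validation rests on a
**synthetic phantom generator**: two ellipsoidal lungs, analytically
known fissure surfaces carved to requested integrity levels, CT-like
noise, and paired spirometry. Every stage is tested against this
ground truth, and a bundled reference table of a published
573-examination COPD cohort anchors the table logic.

## Worked example

```python
from fissint import PhantomSpec, generate_phantom, run_pipeline

spec = PhantomSpec(target_integrity=(70.0, 50.0, 80.0), noise_sd=30.0, seed=1)
volume, truth = generate_phantom(spec)
results = run_pipeline(volume, truth.lung_mask, phantom_mode=True)
for label in ("ROF", "RHF", "LOF", "ELF"):
    r = results[label]
    print(f"{label}: {r.integrity_pct:.1f}%  ({r.bin})")
```

prints

```
ROF: 67.6%  ((60%, 80%])
RHF: 49.8%  ((40%, 60%])
LOF: 77.8%  ((60%, 80%])
ELF: 67.9%  ((60%, 80%])
```

against true integrities of 70.1%, 50.0%, 80.1% and 69.9% — the
pipeline recovers each fissure's integrity to a couple of percentage
points. The `examples/` directory walks through each capability
(phantom generation, detection/labeling, completion and integrity,
cohort statistics, the reference tables); each script prints what it
computes and what the numbers mean. A thin CLI mirrors the pipeline
(`fissint simulate|detect|quantify|cohort|all`).

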