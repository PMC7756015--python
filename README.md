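# coaflow

Reduced-order hemodynamic characterization and non-invasive diagnosis of
aortic coarctation (CoA).

Coarctation of the aorta is a congenital narrowing of the aortic isthmus.
The clinical reference standard for a hemodynamically significant lesion is
a peak systolic pressure gradient (PSPG) ≥ 20 mmHg measured at cardiac
catheterization — an invasive procedure. This package implements and
evaluates, on virtual cohorts, a non-invasive alternative: characterize the
stenosis by the coefficients of its pressure–flow curve, obtained purely
from simulation under a sweep of imposed boundary conditions, and classify
patients from those coefficients.

It is aimed at researchers in computational hemodynamics and diagnostic
modelling who want a fully reproducible, end-to-end testbed for this class
of method without access to patient imaging.

## The method

The mean pressure drop across a stenosis follows

    Δp̄ = f·Q̄ + s·Q̄²

where `f` (mmHg·s/cm³) is the viscous friction and `s` (mmHg·s²/cm⁶) the
expansion loss of the narrowed section. Both are properties of the lesion
geometry, not of the imposed flow — which is what makes them usable as
diagnostic features when the true boundary conditions are unknown.

The pipeline:

1. **Steady network solver** — each aortic arch is a centerline network
   (one inlet, four outlets) with a single-resistance lumped-parameter
   model at every outlet. A static pressure of 80 mmHg is applied at the
   inlet; the total outlet resistance starts at 9.6 mmHg·s/cm³ and is
   scaled by 1, 1/2, …, 1/6, giving six steady solutions per patient.
2. **Characterization** — the six lesion (Q̄, Δp̄) pairs are fit by
   constrained linear least squares to recover (f, s).
3. **Diagnosis** — a logistic model `P(CoA) = 1/(1 + e^−(a·f + b·s + c))`
   is fit against the 20 mmHg catheterization label and evaluated by
   stratified 5-fold cross-validation (ROC/AUC with DeLong confidence
   intervals, Youden operating points), alongside the anatomical ESC
   criterion (≥ 50 % narrowing relative to the diaphragm-level aorta).
4. **Synthetic cohort** — a generator produces pediatric virtual patients
   (BSA-scaled arch geometries, variable-severity isthmus stenoses, noisy
   catheterization PSPG) with the severity prior calibrated by bisection to
   a 38/65 prevalence.

## Worked example

The analysis is organised as numbered drivers that write their tables under
`results/`:

```bash
python analysis/01_generate_cohort.py
python analysis/02_characterize_cohort.py
python analysis/03_cross_validate.py
python analysis/04_esc_comparison.py
```

On the default configuration (n = 65, seed 42) this prints:

```
Generated 65 patients (38 CoA / 27 non-CoA).
...
Worst relative deviation from geometric ground truth: 1.10e-14
...
Per-split averages over 5 folds:
split    model   auc  sensitivity  specificity  accuracy  n_folds
 test combined 0.901        0.771        0.853     0.800        5
 test      esc 0.956        0.407        1.000     0.646        5
 test   f_only 0.749        0.614        0.667     0.631        5
 test   s_only 0.861        0.825        0.853     0.831        5
```

Reading this: the sweep-and-fit characterization recovers the geometric
ground-truth (f, s) to machine precision (matched physics, noiseless
sweeps); the combined two-feature logistic model reaches a mean held-out
AUC of 0.90, above either feature alone; and the anatomical ESC narrowing
rule is perfectly specific but misses the majority of gradient-positive
patients (sensitivity 0.41 vs 0.77), because a moderate narrowing can still
carry a large peak-flow gradient.

The same pipeline is available as a single call:

```python
from coaflow import RunConfig, run_pipeline
result = run_pipeline(RunConfig(seed=42), outdir="results/run")
print(result.crossval.averages())
```

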