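# Methods

## Model

### Arch networks

A patient's aorta is a centerline network: vessel segments with
piecewise-linear radius profiles `r(x)`, joined in a chain from one inlet
(ascending aorta) through three branch junctions (brachiocephalic, left
common carotid, left subclavian outlets) to the isthmus — the lesion
segment — and the descending aorta, which ends in the fourth outlet.
Exactly one segment is marked as the lesion, with observer-defined start
and end planes. Units are cm, cm³/s and mmHg throughout, so resistances
are mmHg·s/cm³.

This reduced-order representation deliberately replaces 3-D
image-derived geometry: it preserves the quantities the inference chain
actually consumes (lumen caliber along the centerline, branch topology,
outlet calibers) while making the forward problem cheap enough to solve
thousands of times in tests.

### Segment and lesion laws

Every segment obeys an algebraic pressure-drop law

    Δp = f_seg·Q + s_seg·Q²,

with `f_seg` the Poiseuille integral `∫ 8μ/(π r(x)⁴) dx` (closed form per
linear profile piece, exact and additive) and `s_seg = 0` except at the
lesion. The lesion's expansion loss is Borda–Carnot:

    s = K_e · (ρ/2) · (1/A_min − 1/A_ref)²,

with `A_min` the minimal lumen area between the lesion planes, `A_ref`
the lumen area at the start plane, and `K_e` an expansion-loss factor
(default 1.0; values ≠ 1 inject controlled model mismatch). An optional
turbulent-friction mismatch term `m·Q^1.75` can be added to the lesion
law. `f` and `s` are pure functions of geometry and fluid properties —
the model's central premise is precisely that they do not depend on the
imposed flow or pressure.

Blood is Newtonian with μ = 0.004 Pa·s (3.0·10⁻⁵ mmHg·s) and
ρ = 1060 kg/m³ (7.95·10⁻⁴ mmHg·s²/cm²), standard literature values.

### Boundary conditions and the sweep protocol

The wall is rigid and the flow steady. A static pressure (default
80 mmHg) is prescribed at the inlet. Each outlet carries a
single-resistance lumped-parameter model draining to a reference pressure
of 0 mmHg (the reference is configurable; nothing in the pipeline is
sensitive to it because the features are slope/curvature properties of
the pressure-flow curve). The total resistance (parallel combination,
default 9.6 mmHg·s/cm³) is allocated to the four outlets with conductance
proportional to diameter (exponent 1, the "inverse diameter" rule); a
Murray-type `d³` allocation is available behind the `exponent` parameter,
and the characterization is insensitive to the choice (verified to 0.1 %
in tests). The sweep solves the steady state at scales
{1, 1/2, 1/3, 1/4, 1/5, 1/6} of the total resistance — scaling multiplies
every outlet resistance, preserving allocation ratios — and records the
lesion-plane (Q̄, Δp̄) pair at each level.

## Numerics

**Steady solver.** Unknowns are the junction-node pressures (≤ 5). A
damped Newton iteration with the analytic tridiagonal Jacobian runs from
a linearized-circuit initial guess; steps are backtracked until the
residual norm decreases and pressures are clipped to the physical box.
Convergence is declared at a maximum junction flow imbalance below 10⁻¹¹
relative to the inlet flow. Networks containing a (near-)lossless segment
(`f_seg < 10⁻⁹`, no quadratic term) make the pressure formulation
singular and are routed to the shooting formulation, as is any Newton
failure: a single bisection on the total inlet flow, propagating
pressures forward along the chain, whose terminal flow imbalance is
strictly monotone in the trial. The shooting path shares no code with the
Newton path and doubles as the brute-force oracle in the test suite.
Backflow is out of scope: a converged negative flow raises rather than
silently returning an unphysical state, and the shipped parameter ranges
never produce one.

**Curve fit.** Δp̄ = fQ̄ + sQ̄² is linear in (f, s); despite the
"iterative nonlinear regression" framing such fits are often given, the
least-squares problem is solved exactly on the design [Q̄, Q̄²] — by
non-negative least squares (active set) under the default f, s ≥ 0
constraint, so a non-stenotic vessel fits to exactly zero rather than a
small negative value. A Gauss–Newton path (`method="iterative"`) is kept
for parity and must agree to 10⁻⁸.

**Logistic fit.** Maximum likelihood by iteratively reweighted least
squares on internally standardized features (the MLE is invariant to the
affine rescaling; standardization only conditions the solve), with
step-halving on the log-likelihood and convergence at a log-likelihood
change below 10⁻¹⁰. Complete separation — every observation classified
correctly with a saturated margin — is detected, the iteration stops with
the coefficients capped at their current value, and a flag is set.

**ROC machinery.** AUC is the Mann–Whitney statistic with ties counted
1/2; its variance and confidence intervals use the DeLong placement-value
estimator, and paired model comparisons use the DeLong correlated-AUC
z-test (two-sided, α = 0.05). Operating thresholds are chosen by the
Youden index on the training split, with the cut placed at the midpoint
between the optimal candidate score and the next score below it — the
training confusion counts are unchanged but the cut is robust for unseen
scores near a saturated decision boundary. A fixed threshold of 0.5 is
available. The ESC comparator is threshold-free: positive iff the
narrowing rate `1 − d_min/d_diaphragm` is ≥ 0.50 (boundary inclusive).

**Cross-validation.** Folds are stratified exactly on the label (per-fold
positive counts within one) and approximately on sex and age: within each
label class patients are ordered by (sex, age, patient id) and dealt in
consecutive blocks of k, each block permuted across folds by the seeded
generator. Tie-breaking on patient id makes the assignment a pure
function of patient identities and the seed, invariant to the row order
of the cohort table. Per-fold averages are unweighted. A test fold
containing a single class is reported as degenerate and excluded from
averages with a warning.

## The synthetic cohort

The generator emulates the statistical structure a pediatric CoA study
cohort presents to this pipeline; defaults are fixed once and constitute
the study conditions.

| parameter | default | rationale |
|---|---|---|
| n / prevalence | 65, 38/65 | study-scale composition |
| age | log-normal, median 12 mo, σ = 1.0, clipped 1–168 mo | pediatric range, infant-heavy |
| sex | 54 % male | typical CoA cohort composition |
| BSA | 0.22 + 0.25·(age_y)^0.6 ± 8 % | ≈ 0.5 m² at one year |
| isthmus reference radius | 0.40 cm at BSA 0.5, ∝ √BSA | pediatric descending aorta caliber |
| severity (diameter narrowing) | normal, σ = 0.15, clipped [0.02, 0.85]; location calibrated | spans mild to severe |
| lesion length | 0.8 cm at BSA 0.5, log-normal σ = 0.45 | discrete vs long-segment lesions |
| throat fraction | uniform [0.2, 0.8] | decouples f (length-sensitive) from s (area-sensitive) |
| peak isthmus flow | 150 cm³/s per m² BSA, log-normal σ = 0.25 | peak-systolic flow scale with physiologic spread |
| PSPG noise | truncated Gaussian, σ = 2 mmHg | catheterization measurement error |

The diaphragm-level diameter equals the pre-lesion reference caliber, so
the ESC narrowing rate coincides with the drawn severity parameter.

**Labels vs features.** The reference PSPG is the lesion's true
pressure-flow law evaluated at the patient's *peak-systolic* flow; the
diagnostic features come from the *resting* steady sweep. This deliberate
asymmetry — the label knows the patient's flow, the features cannot — is
the irreducible noise source that makes classification imperfect, as it
is in practice. With matched physics and no measurement noise the
features themselves are recovered exactly.

**Prevalence calibration.** All patient-level random draws are made
first; the severity location parameter is then found by bisection so that
the realized positive count equals `round(n · prevalence)`. Each
patient's label is monotone in the location, so the count is a monotone
step function and the bisection is exact up to ties (38/27 exactly at the
defaults). A population-level calibration would leave the realized count
binomially distributed around the target, which at n = 65 misses the
intended composition on a substantial fraction of seeds.

**What the generator does not emulate.** Peak flow is prescribed
open-loop, independent of the stenosis — there is no cardiac or
collateral adaptation, so extreme severities produce reference gradients
far beyond anything survivable (only the exceedance of the 20 mmHg cutoff
matters for the binary label, but the PSPG tail is unphysiological).
Negative patients are simply mild arches; the comorbid congenital lesions
present in a real referral population, and their effect on arch
hemodynamics, are not modelled. There is no pulsatility, no wall
compliance, no imaging or segmentation error beyond the optional
lesion-plane jitter (default off, magnitude unspecified in the
literature). Consequently, passing tests demonstrate the internal
consistency and statistical behaviour of the inference chain under these
idealized conditions — not clinical performance.

## Problem sizes

Tests and the acceptance script run the full default cohort (65 patients,
6 steady solves each), 100-network solver/oracle comparisons, a
2000-replicate bootstrap check of the DeLong variance and a few hundred
Monte-Carlo curve fits; the complete suite executes in well under a
minute on one CPU, which is the scale this reduced-order design was
chosen to enable.

## Known limitations

Beyond the generator fidelity limits above: the network topology is the
fixed arch chain (junctions carry at most one downstream segment), the
solver rejects backflow rather than modelling it, and single-resistance
outlets ignore distal compliance — acceptable for steady sweeps, wrong
for pulsatile extensions. The cross-validated metrics at n = 65 carry
substantial realization variance (fold AUCs at test size 13 move by
±0.05 across seeds); conclusions should rest on the ordering of models,
which is stable, not on the third decimal of any single run.
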