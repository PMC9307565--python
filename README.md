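# radharm

Multi-centre cardiac MRI radiomics are notoriously unstable: MR magnitude
images carry no standard intensity scale, so texture features extracted
from scanners at different centres differ by construction, not biology.
`radharm` is a toolkit for quantifying and reducing that variability. It
implements, as one reproducible pipeline:

* **image-level intensity normalisation** — min–max rescaling (R),
  z-normalisation (N), histogram matching against a template subject (HM)
  and piecewise linear histogram matching / Nyúl–Udupa standardisation
  (PLHM), each applicable to the whole image or independently per region
  of interest (ROI);
* **radiomic feature extraction** — 88 features per ROI: 18 first-order
  intensity statistics plus texture features from the grey-level
  co-occurrence (GLCM, 24), dependence (GLDM, 14), run-length (GLRLM, 16)
  and size-zone (GLSZM, 16) matrices, with fixed-bin-width discretisation
  (`level(x) = ⌊(x − min)/W⌋ + 1`; W = 25 raw, 0.05 after normalisation);
* **feature-level harmonisation** — parametric empirical-Bayes ComBat:
  per-feature batch effects `γ_ig` (location) and `δ_ig` (scale) are
  estimated after per-centre quantile Gaussianisation, shrunk towards
  normal / inverse-gamma priors, and removed against a pooled "virtual
  reference" (`y* = σ_g (z − γ*_ig)/δ*_ig + α_g`), with no covariates;
* **variability scoring** — base-2 Jensen–Shannon divergence (JSD ∈ [0,1])
  between per-centre feature distributions for every centre pair, after
  greedy sequential de-correlation (drop features with R² ≥ 0.9 against
  any retained predecessor), summarised as the percentage of features
  below a similarity threshold τ = 0.01 and as per-family mean (sd)
  tables;
* **twin random-forest evaluations** — (1) *centre identification*:
  stratified 5-fold CV predicting the centre of origin (lower balanced
  accuracy = less centre signal); (2) *generalisation*: healthy-vs-HCM
  classification trained on a single centre and tested on all others,
  5 seeds × 5 folds (higher balanced accuracy = better transfer).

Because the matching clinical data cannot ship with the code, the package
includes a first-class synthetic cohort generator: 5 centres with raw
intensity ranges spanning hundreds to ten-thousands, 112 healthy and 106
HCM subjects, two cardiac phases, and a disease effect (thicker, more
coarsely textured myocardium) that survives intensity normalisation.
Everything downstream is exercised and tested against it.

Intended users: imaging scientists studying scanner/site harmonisation,
and anyone needing a transparent, dependency-light reference
implementation of PLHM, ComBat and texture-matrix features that is
cross-checked against independent oracles.

## Worked example

```python
from radharm import (CohortSpec, generate_cohort, resample_inplane,
                     extract_features, apply_normalisation, harmonise,
                     centre_id_protocol, generalisation_protocol)

spec = CohortSpec(seed=7, phases=("ED",))
cohort = [resample_inplane(s) for s in generate_cohort(spec)]

raw = extract_features(cohort, bin_width=25.0)
rescaled = extract_features(
    [apply_normalisation(s, "R", scope="roi") for s in cohort], bin_width=0.05)
harmonised, _ = harmonise(raw)

for name, table in [("original", raw), ("ROI-rescaled", rescaled),
                    ("original+ComBat", harmonised)]:
    rep = centre_id_protocol(table, order="first", roi="MYO", seed=0)
    print(f"centre identification, {name:>15}: "
          f"balanced accuracy {rep.mean_validation:.3f}")

for name, table in [("original", raw), ("ROI-rescaled", rescaled)]:
    rep = generalisation_protocol(table, train_centre="C3")
    print(f"generalisation,      {name:>15}: "
          f"validation {rep.mean_validation:.3f}, test {rep.mean_test:.3f}")
```

prints

```
centre identification,        original: balanced accuracy 1.000
centre identification,    ROI-rescaled: balanced accuracy 0.248
centre identification, original+ComBat: balanced accuracy 0.260
generalisation,             original: validation 1.000, test 0.716
generalisation,         ROI-rescaled: validation 0.987, test 0.995
```

Read: raw first-order myocardial features identify their centre of origin
perfectly (pure scanner signal); ROI rescaling or ComBat pushes that to
near chance (0.2 for five centres). A disease classifier trained on one
centre's raw features collapses on unseen centres (0.72 despite perfect
validation), while ROI-rescaled features transfer almost losslessly —
centre-information removal and generalisation are related but distinct
goals.

A `radharm` command-line tool wraps the same stages
(`simulate / normalise / extract / harmonise / variability / evaluate /
run / report`); `radharm run --out DIR --seed N` executes the full
normalisation-method grid and renders comparison tables.

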