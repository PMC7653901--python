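# beamdvh

Beam-informed DVH prediction and biologically related planning constraints
for radiotherapy organ-at-risk sparing.

## What it does

When planning volumetric modulated arc therapy (VMAT) for nasopharyngeal
carcinoma, the achievable dose-volume histogram (DVH) of each organ at risk
(OAR) is not known until the planner has already spent effort in the
treatment planning system.  `beamdvh` predicts it up front from dosimetric
information that is cheap to compute: the DVHs deposited in the organ by
nine static conformal beams at equally spaced gantry angles (160°, 120°,
80°, 40°, 0°, 320°, 280°, 240°, 200°; field indices FI = 1…9).

The pipeline:

1. **DVH representation** — every curve is resampled to dose-quantile form
   on a fixed percentage-volume grid (Δv = 0.1%, 1000 points): D_v is the
   dose below which the fraction v of the organ volume lies.  Curves of all
   organs become equal-length, comparable sequences.
2. **Prediction** — a stacked gated-recurrent-unit (GRU) sequence regressor
   with hidden sizes 18 → 9 → 1 reads the nine beam doses per volume bin
   and emits the composite-plan dose per bin.  One model is trained pooled
   over all organs by minimizing the mean squared curve error with Adam.
3. **Biological constraints** — predicted curves are reduced to the
   generalized equivalent uniform dose, EUD = (Σ_v Δv·D_v^k)^(1/k), with
   organ-specific power-law exponents (spinal cord 10.0; brainstem, optic
   nerves, chiasm 9.8; larynx 6.8; lens 2.0; parotid 3.9; PRVs inherit the
   parent organ's k; otherwise k = 0.15·D50).  Organ-specific prediction
   bias is removed by the training-set mean ratio c_OAR of true to
   predicted EUD, and the constraint is tightened by α = 0.97:
   cEUD′ = α·c_OAR·EUD′.  Corrected maximum-dose constraints are also
   emitted for spinal cord and lens.
4. **Evaluation** — per-organ accuracy δ (mean EUD error) and precision σ
   (sample SD) over test patients, dose-metric tables (D98, Dmax, Dmean,
   D1cc, EUD), Bland-Altman limits of agreement, and the Wilcoxon
   signed-rank test with exact small-sample enumeration.

Clinical beam/plan DVH exports (CSV/JSON) are the ingestion boundary.
Because no public dataset of per-beam plus composite DVHs exists, the
package ships a synthetic cohort generator whose composite curves are a
known smooth function of the beam curves (a sparing-damped power mean), so
every stage of the pipeline is testable against oracles; see
`docs/methods.md` for the model and its limits.

## Worked example

```python
import numpy as np
from beamdvh import (CohortConfig, generate_cohort, DVHSequenceModel,
                     PredictorConfig, default_registry, eud,
                     correction_factor, corrected_eud_constraint, summarize)

cohort = generate_cohort(CohortConfig(
    n_patients=30, organs=("brainstem", "spinal_cord", "parotid_l", "larynx"),
    dv=0.01, seed=42))
config = PredictorConfig(dv=0.01, epochs=30, seed=42)
results = DVHSequenceModel.from_samples(cohort.train, config).fit()
print(results.summary())

registry = default_registry()
preds = results.predict_many([bs for bs, _ in cohort.test])
errors = [eud(p, registry.resolve(p.structure_id))
          - eud(plan, registry.resolve(plan.structure_id))
          for p, (_, plan) in zip(preds, cohort.test)]
s = summarize(errors)
print(f"held-out EUD error: delta = {s.delta_gy:+.2f} Gy, sigma = {s.sigma_gy:.2f} Gy (n = {s.n})")

train_preds = results.predict_many([bs for bs, _ in cohort.train])
k = registry.resolve("spinal_cord")
pairs = [(eud(plan, k), eud(pred, k))
         for (bs, plan), pred in zip(cohort.train, train_preds)
         if bs.structure_id == "spinal_cord"]
c = correction_factor(pairs)
pred_eud = eud(preds[1], k)  # spinal cord of the first test patient
print(f"spinal cord: EUD' = {pred_eud:.2f} Gy, c_OAR = {c:.3f}, "
      f"cEUD' = {corrected_eud_constraint(pred_eud, c):.2f} Gy")
```

Output:

```
DVH sequence regressor (stacked GRU)
============================================
layers (input -> hidden):  9 -> 18 -> 9 -> 1
parameters:                2385
volume bins (dv):          100 (0.01)
dose normalization:        70.0 Gy
training samples:          96
epochs run:                30
learning rate / batch:     0.005 / 160
first-epoch MSE:           4.6573e-01
final MSE:                 4.9710e-03

held-out EUD error: delta = +1.91 Gy, sigma = 3.49 Gy (n = 24)
spinal cord: EUD' = 25.50 Gy, c_OAR = 0.892, cEUD' = 22.07 Gy
```

Reading it: training on 96 patient-organ samples (24 patients × 4 organs on
a coarse 1% grid, for speed) reduces the normalized curve MSE by two orders
of magnitude; on the 6 held-out patients the predicted EUDs are within a
couple of Gy of truth (δ is the signed mean, σ the spread); and for one
test patient's spinal cord, the predicted EUD of 25.50 Gy becomes a planner
constraint of 22.07 Gy after bias correction (c_OAR = 0.892, i.e. the model
over-predicts this organ by ~11% on the training set) and the α = 0.97
tightening.

The same pipeline is available from the shell:

```sh
beamdvh simulate --n-patients 100 --seed 1 --out-dir cohort
beamdvh train    --train cohort/cohort_train.csv --out-dir model
beamdvh predict  --checkpoint model/checkpoint.json --dvh cohort/cohort_test.csv --out-dir predicted
beamdvh constraints --checkpoint model/checkpoint.json --train cohort/cohort_train.csv \
                    --beams cohort/cohort_test.csv --out-dir constraints
beamdvh evaluate --checkpoint model/checkpoint.json --test cohort/cohort_test.csv --out-dir evaluation
```

Re-running any step with the same config and seed reproduces its outputs
byte for byte.

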