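# Methods

## Problem and scope

In knowledge-based radiotherapy planning for head-and-neck (nasopharyngeal)
cancer, one wants to know — before running the treatment planning system —
what dose-volume histogram (DVH) an organ at risk (OAR) can realistically
achieve in a volumetric modulated arc therapy (VMAT) plan.  This package
implements a beam-informed approach: the DVHs that nine static conformal
beams (equally spaced gantry angles, field indices FI = 1…9 at 160°, 120°,
80°, 40°, 0°, 320°, 280°, 240°, 200°) individually deposit in an organ are
used as the input from which the composite-plan DVH is predicted.  Predicted
curves are converted to equivalent uniform doses (EUD) and emitted as
bias-corrected constraints for inverse planning.  Plan optimization itself,
DICOM-RT parsing, contouring and structure Boolean operations are out of
scope; DVH curves are the ingestion boundary.

## DVH representation

All curves are stored in dose-quantile form on a fixed percentage-volume
grid: `doses[i]` is the dose D_v below which a fraction v = (i+1)·Δv of the
organ lies, with Δv = 0.1% (1000 points) by default.  Percentage-volume
binning makes every organ's curve the same length regardless of its absolute
volume, which is what lets one pooled sequence model handle all organs.

Conventions, chosen once and used everywhere:

* the grid is closed at v = 1.0, so the maximum dose is always represented;
* quantiles use the lower (infimum) convention: at a flat or jump region the
  lowest dose attaining the volume level is reported;
* D_x (e.g. D98) is the minimum dose of the hottest x% of the organ — the
  curve value at the first grid point strictly above v = 1 − x/100.  This
  step (order-statistic) convention reproduces voxel-list brute force
  exactly and is monotone in x; it differs from mid-bin interpolation by at
  most one volume bin (0.1%);
* conversions between the quantile form and the conventional dose-binned
  form (volume fraction ≥ dose) use exact step counting at the edges and
  linear interpolation in between.  Round trips are exact to 1e-6 Gy when
  the dose edges resolve the empirical jumps, and to within one volume bin
  on arbitrary edge grids;
* the mean dose is the equal-mass Riemann sum, i.e. the plain average of
  the grid values; it sits within one bin's worth of Dmax of the underlying
  voxel mean.

## Equivalent uniform dose and constraints

The generalized EUD of a curve is the power mean over the volume grid,

    EUD = (Σ_v Δv · D_v^k)^(1/k),

computed as Dmax·(Σ Δv (D_v/Dmax)^k)^(1/k) so that k ≈ 10 at ~70 Gy stays
far from floating-point overflow; an all-zero curve has EUD 0, and negative
(target-type) exponents are rejected.  Shipped exponents: spinal cord 10.0;
brainstem, optic nerves and chiasm 9.8; larynx 6.8; lens 2.0; parotid 3.9.
A planning organ-at-risk volume (PRV) shares its parent organ's exponent,
and bilateral organs share one entry.  Where no exponent is tabulated the
registry applies k = 0.15·D50 from a user-supplied D50 tolerance dose; no
D50 values are shipped.

Predicted EUDs carry organ-specific bias.  The constraint generator removes
it with the training-set mean ratio of true to predicted EUD,

    c_OAR = (1/N) Σ_P EUD_P / EUD'_P,

and tightens by α = 0.97 (slightly below 1, so the optimizer is pushed
marginally past the prediction): cEUD' = α·c_OAR·EUD'.  After correction
with α = 1 the training-set mean ratio of true EUD to constraint is exactly
1 by construction.  A maximum-dose constraint built by the same recipe is
emitted for the serial organs (spinal cord, lens); α is applied uniformly
to both constraint types and is exposed as configuration.

## The sequence regressor

The predictor is a stack of three gated recurrent unit (GRU) layers with
hidden sizes 18, 9 and 1.  The sequence axis is the volume-bin index (1000
steps); each step carries nine features — the per-beam doses at that volume
fraction, divided by the 70 Gy normalization (the highest prescription
level).  The size-1 last layer's state sequence is the predicted curve
directly; there is no extra projection layer and no output activation.
Predictions are rescaled, clipped at zero and projected onto the monotone
cone by a running maximum, so every output is a valid cumulative DVH.  An
alternative arrangement — nine sequence steps of 1000-dimensional beam
vectors — would also be plausible; the per-volume-bin arrangement was
chosen because it keeps the sequence length equal to the curve length and
the per-step feature count equal to the beam count, and it is the one
tested here.

One model is trained pooled across all organs; per-organ bias is handled
downstream by c_OAR.  Training minimizes the mean squared error between
predicted and true curves (equivalent, up to a constant factor, to the sum
of squared curve differences over patients and organs) with Adam.  The GRU
forward pass, backpropagation through time and Adam are implemented in
numpy in `beamdvh.gru`; gradient correctness is pinned to a central
finite-difference oracle in the test suite, and all arithmetic is float64,
so training is bit-for-bit reproducible given (seed, data, config).

Training defaults (configuration, not claims about optimality): learning
rate 5e-3 with cosine decay, 60 epochs, batch 160, optional global
gradient-norm clipping, one integer seed controlling initialization and
batch shuffling.  An optional `loss_tol` stops training once the epoch MSE
falls below it (used by the memorization sanity check).

## Synthetic cohort

No public beam/plan DVH dataset exists for this problem, so the cohort
generator produces the study conditions synthetically: 100 patients (80
train / 20 test, split by patient), 8 organ categories, nine beam curves
plus one composite per patient-organ.

Beam b deposits D_v^(b) = A·g_b·v^γ_b with patient-organ amplitude
A ~ U(0.3, 1.0)·70 Gy, beam strength g_b ~ U(0.2, 1.0) and shape
γ_b ~ U(0.5, 3.0).  The composite plan is a damped quadratic power mean of
the beams,

    plan_v = m_v · (Σ_b u_{b,v} (D_v^(b))²)^½,

with instantaneous dose-share weights u_{b,v} = D_v^(b)/Σ_c D_v^(c) and a
sparing factor m_v = lo + (hi − lo)·(mean_b D_v^(b) / max_b D_v^(b)) over
the configured sparing range (default 0.5–0.9): where a single beam
dominates, the optimizer can block that direction and spares aggressively;
where all beams contribute equally, little sparing is possible.  Because
the weights and the sparing factor are functions of the beam doses
themselves, the noiseless composite is an exact smooth deterministic
function of the nine input curves — the learnability premise of the method
holds by construction, so a predictor that fails to recover it is wrong
rather than data-limited — while patient-to-patient sparing variation
emerges from the beam-profile variation.  In the all-beams-equal symmetric
case the power mean collapses and the composite is exactly
hi·A·g·v^γ, giving a closed-form oracle.  Optional noise is a smooth
low-order random polynomial in v scaled to `noise_sd_gy` (white noise would
be asymmetrically flattened by the monotone projection); the default is
noiseless.  Latent parameters (A, g, γ, the dose-share weights and sparing
factor at v = 1) are persisted in a sidecar table so downstream tests are
oracle-checkable.

What the generator does NOT emulate: anatomy, beam geometry physics, voxel
dose grids, inter-organ correlation within a patient, realistic TPS
trade-offs between competing structures.  Passing tests therefore
demonstrate that the pipeline recovers a known beam-to-plan mapping under
realistic dose scales and curve shapes — not clinical prediction accuracy.

## Evaluation statistics

Per-organ accuracy over the test patients is summarized by δ (mean EUD
error) and precision by σ (sample standard deviation, n − 1).  The
per-patient error is signed (predicted − true) by default with the
absolute-value variant behind a flag: a strict reading of the error
definition uses |EUD' − EUD|, but negative per-organ means are meaningful
(systematic under-prediction) and are reported in practice, so both modes
are offered rather than silently resolving the discrepancy.  Bilateral
organs contribute one entry per side.

Agreement between paired dose measures uses Bland-Altman limits of
agreement, mean difference ± 1.96·SD (sample SD), plus the fraction of
differences inside the limits.  Paired comparisons use the two-sided
Wilcoxon signed-rank test: zero differences dropped, average ranks for
ties, the exact null distribution enumerated over all 2^n sign assignments
for up to 12 informative pairs, and a tie-corrected normal approximation
(no continuity correction) above that.

## Problem sizes used in tests

The analytic EUD suite runs on 200 random 100-bin curves (100 bins is the
coarsest grid at which a single hot bin already guarantees the k = 1000
power mean within 0.5% of the maximum dose).  Metric oracles use voxel
lists up to 10⁴.  The learnability experiment uses the full default cohort
(100 patients × 8 organs at Δv = 0.1%, seed 1) and the default training
configuration; it asserts that the pooled model at least halves the
held-out mean |ΔEUD| of a per-organ mean-training-curve baseline and stays
within 2 Gy on average.  The memorization check and the end-to-end
determinism check run on a 1% volume grid, which preserves every contract
being tested at a fraction of the cost.

## Known limitations

* The GRU is unidirectional; information about the curve tail cannot
  influence predictions at small v.  The composite map used by the
  generator is pointwise, so this does not bind here, but it may for maps
  with long-range structure.
* The correction factor assumes a multiplicative bias model; additive
  biases are only partially removed.
* The D50 → k rule is provided but unpopulated; temporal lobes have no
  shipped exponent and require a user-supplied k or D50.
* The exact signed-rank path is limited to 12 informative pairs (4096
  enumerations); larger samples use the asymptotic approximation.
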