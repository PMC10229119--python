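# Methods

## Conditions and canonicalization

The unit of data is one voxel's GLM coefficient in each of seven conditions,
per data half (odd/even runs).  Raw labels name the stimuli (B = body,
H = house) and the attended one (`at` suffix); the fixation-only baseline
block is assumed to have been consumed upstream for voxel selection and is
not representable.  Every voxel is assigned a preferred category from its
isolated *ignored* responses (B vs H with attention on fixation): the larger
response wins, and an exact tie breaks deterministically toward body with a
logged warning (ties occur on a measure-zero set of real-valued inputs, so
the choice is auditable and inconsequential).  Conditions are then relabeled
into the preference frame (`Pat, PatN, PNat, Nat, P, PN, N`); this is a pure
bijection on labels, so the multiset of values is conserved and, by
construction, R(P) ≥ R(N).

Preference is assigned from the **training half of each cross-validation
fold** (`preference_scope="fold"`), so no information from the held-out half
leaks into any quantity used to predict it.  A `pooled` option (preference
from the mean of both halves) exists for sensitivity analysis.

## Models

Let c_P, c_N ∈ {0, 1} flag stimulus presence and let the gain g equal β for
the attended stimulus and 1 otherwise (both 1 when fixation is attended).

* weighted sum: R = g_P c_P R_P + g_N c_N R_N
* weighted average EW: R = (g_P c_P R_P + g_N c_N R_N)/(c_P + c_N)
* weighted average UW: paired R = g_P α R_P + g_N (1−α) R_N with weights
  summing to one; isolated stimuli keep weight 1
* weighted average UWUB: R = g_P c_P α_P R_P + g_N c_N α_N R_N with
  unconstrained weights and separate gains β_P, β_N — an exact
  generalization of the weighted sum (α = 1) and, on paired conditions, of
  the equal-weights average (α = ½)
* UWUB saturation: the UWUB response clipped at min(R, s)
* normalization: R = (g_P c_P L_P + g_N c_N L_N)/(g_P c_P + g_N c_N + σ)

The linear models' R_P, R_N are **data** (the training half's isolated
ignored responses), not parameters.  The normalization model estimates its
latent drives L_P, L_N because pool suppression acts even on isolated
stimuli, so the measured isolated response is already normalized.

Design choice — isolated *attended* conditions: the paired-condition
equations of the sum/average families do not determine Pat and Nat.  We set
them to β·r for the WS/EW/UW models (attention scales the lone stimulus's
contribution) and to β_P·α_P·r_P (resp. β_N·α_N·r_N) for the UWUB variants,
keeping each model's own weighting logic.  Consequently the UWUB → EW
reduction at α = ½ is exact on paired conditions only; the UWUB → WS
reduction at α = 1 is exact on all seven.

## Fitting and cross-validation

Per voxel and model, parameters minimize the sum of squared errors under box
constraints (1 ≤ β ≤ 10, 10⁻⁶ ≤ σ ≤ 10, |L_P|, |L_N| ≤ 10, α ∈ [0, 1] for
UW, α_P, α_N ∈ [0, 10] for UWUB, s ∈ [−10, 10]), via trust-region-reflective
least squares with analytic Jacobians.  The open bounds β > 1 and σ > 0 are
closed at 1 and 10⁻⁶ for the solver.  The normalization objective is
non-convex, so each fit multi-starts from the box midpoint plus seeded
uniform draws: 20 restarts for normalization, 12 for the bilinear UWUB
variants, 3 for the convex one/two-parameter models.  More restarts can only
lower the training SSE (best-so-far).  A profile with zero variance over the
fit conditions is flagged degenerate rather than raising; voxels whose
restarts all fail to converge are flagged, not dropped silently.

The sum/average families are fit on the five modeled conditions (they
consume P and N as inputs); the normalization model is fit on all seven,
since its parameters predict the isolated conditions too (a five-condition
option exists).  Cross-validation is two-fold by run parity: fit on odd,
predict even, and mirrored; every quantity predicting the test half —
preference, parameters, and the linear models' r_P/r_N inputs — comes from
the training half (`rpn_source="train"`; a `test` option is provided because
the protocol choice is not forced by the mathematics).  Downstream
comparisons use the condition-wise average of the two held-out prediction
maps.

## Evaluation

Goodness of fit is the squared Pearson correlation between held-out observed
and predicted responses over the five modeled conditions, computed per fold
direction and averaged.  The metric is blind to sign and affine scale (an
anticorrelated prediction also scores 1); a zero-variance vector scores 0
and flags the voxel degenerate, which excludes it from ROI means while
keeping it counted.  The noise ceiling is the squared split-half correlation
of the observed profiles over the same five conditions, computed per voxel
(in each direction's preference frame) and averaged; NRD = ceiling − gof and
may be negative for single voxels.  AIC = n·ln(RSS/n) + 2k + C with n = 5
held-out residuals per direction, averaged over directions (held-out
residuals keep the comparison consistent with the cross-validation
emphasis; a train-side option is trivial to add since RSS is exposed).
Pearson correlation is the default (Spearman would be a one-line
sensitivity change); RSS = 0 maps to an AIC of −∞ rather than an error.

## Attention indices

Response change R(PatN) − R(PNat) and asymmetry
(R(PNat) − R(Nat)) − (R(Pat) − R(PatN)) are computed from the fold-averaged
*held-out* maps: observed test halves for the data index, cross-validated
predictions (never refits) for each model.  Closed forms used as oracles:
weighted-sum asymmetry = r_P + r_N; EW asymmetry = (1−β)(r_P + r_N)/2 ≤ 0
for β ≥ 1; normalization response change = (β−1)(L_P−L_N)/(β+1+σ), positive
whenever β > 1 and L_P > L_N, and normalization asymmetry is positive over
the full sweep L_P > L_N > 0, β ∈ (1, 10], σ ∈ (0, 10].

## Simulator

`synthetic_data` builds voxels bottom-up: 10⁴ neurons (half body-, half
house-preferring), each with preferred drive l_pref ~ U(10, 50) a.u., null
drive l_null = l_pref · U(0.1, 0.9) (always weaker than the preferred
drive), attention gain β ~ U(1.5, 4), and σ ~ U(0.5, 5) for normalizing
neurons — magnitudes chosen to span the selectivity and attention-gain
ranges reported in ventral-stream electrophysiology.  Each neuron responds
to the seven conditions by its population's rule (summing, averaging, or
normalizing).  A voxel is the mean of 200 neurons drawn with an ROI-specific
body fraction (defaults 0.5 for V1/LO/pFs, 0.9 for EBA, 0.1 for PPA),
replicated over 16 runs with additive Gaussian noise of sd = 0.2 × the
voxel's mean response (proportional noise keeps SNR comparable across
voxels; a constant-sd alternative would be a one-line change), then averaged
within the odd and even run halves; 30 voxels per ROI.

Because response units are arbitrary while the fitting bounds are fixed
numbers, each simulated dataset is rescaled so its grand mean response is 1
(`response_scale="auto"`), putting simulated voxels on the same O(1) scale
as GLM coefficients without touching correlation structure.  Disable with
`response_scale=1.0` (used by the single-neuron parameter-recovery check,
whose neuron parameters are drawn inside the fitting bounds).

What the simulator does **not** emulate: hemodynamic convolution,
autocorrelated or shared noise across voxels, spatial voxel geometry,
between-subject variability in tuning, or voxel selection effects.  Passing
recovery tests therefore show that the pipeline identifies the generating
computation under idealized noise, not that real BOLD data satisfy the
models' assumptions.

The model-recovery experiment defaults to a reduced design — 2,000 neurons
and three ROIs (one unbiased, two oppositely biased), 30 voxels each — which
keeps a multi-seed run at desk scale; the ROI ratio is the only thing an ROI
changes, so the reduced set spans the design.  One robust property of this
experiment is worth stating: models that consume the measured P/N responses
as fixed inputs (the weighted sum most of all, with its single free
parameter) are penalized by input noise on the training half, so their
flexible generalizations (UWUB) can out-predict them by a few hundredths of
r² on their *own* population at the default noise level, even though at zero
noise the generating model scores ≈ 1.  The diagnostic contrast — the
normalization model dominating every alternative only on the normalizing
population — is unaffected.

## Group statistics

Within-subject error bars use Cousineau centering (subtract each subject's
mean, restore the grand mean) without the Morey multiplier by default (flag
available).  Repeated-measures ANOVA (one or two within factors) stands on
pingouin: Greenhouse–Geisser ε is always reported; degrees of freedom and p
are corrected when Mauchly's test rejects sphericity at 0.05.  Mauchly's
test is unavailable for the two-way interaction term, where the policy falls
back to correcting whenever ε < 1 (conservative).  Two-level factors are
trivially spherical (ε = 1).  Dunn–Šidák adjustment is
p_adj = 1 − (1−p)^m, capped at 1; post-hoc paired t-tests are two-sided by
default.  The layer's Type-I error is validated by null simulation rather
than against any particular dataset.

## Problem sizes and determinism

Default test and acceptance runs use scaled-down simulations (hundreds of
neurons to a few thousand, 2–30 voxels per ROI) chosen so a complete run
takes minutes on one CPU; all sizes are plain `SimConfig` fields.  Every
stochastic component — population sampling, voxel assembly, run noise,
optimizer restarts — derives from a single integer seed, and the pipeline
writes byte-identical artifact tables for identical config + seed.
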