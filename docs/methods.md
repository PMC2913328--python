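# Methods

## Scope and model

`bcfkit` assesses continuous log10 BCF predictions for regulatory use.
It deliberately does **not** re-implement the hybrid SVM model whose
output it was designed around: such predictions enter as data
(`CompoundRecord.predicted_logbcf`). What the package owns is the
machinery around a prediction — baseline univariate models, the
conservative classification rule, the applicability-domain battery, and
the validation statistics.

### Baseline univariate models

Four published regressions of logBCF on a calculated logP are frozen as
constants (slope, intercept, R, R², F), one per logP program:

| name   | model                          | R²    |
|--------|--------------------------------|-------|
| acd    | logBCF = 0.305·logP_ACD + 0.767 | 0.336 |
| kowwin | logBCF = 0.357·logP_Kowwin + 0.605 | 0.432 |
| mdl    | logBCF = 0.481·logP_MDL + 0.290 | 0.543 |
| mlogp  | logBCF = 0.555·MLOGP + 0.117    | 0.556 |

They are frozen, not re-fitted, because the training data behind them
is not shipped; the printed statistics are stored verbatim as metadata.
One published row (acd) prints an R and R² that are mutually
inconsistent beyond rounding (0.605² = 0.366 ≠ 0.336);
`LinearModelSpec.consistency_gap()` exposes the discrepancy instead of
rejecting the constants, and the consistency check is enforced only on
freshly fitted specs. `fit_univariate` uses ordinary least squares
(scipy), with the conventional one-predictor ANOVA F = r²(n−2)/(1−r²);
a constant predictor raises a degenerate-design error.

### Conservative classification

REACH thresholds are strict-above: nB for logBCF ≤ 3.3, B for
3.3 < logBCF ≤ 3.7, vB above 3.7 ("greater than 2000" read literally,
so exactly 3.3 is nB). The offset rule maps raw predictions in
[2.8, 3.3] to 3.31 and raw predictions in (3.3, 3.7] — excluding the
3.31 target itself — to 3.71. Three properties follow, all enforced by
tests on a 10⁴-point grid:

- the map never decreases a value, hence never downgrades a class;
- it is idempotent (offset targets are fixed points — this is why 3.31
  is excluded from the upper band: a compound predicted at 3.31 is B,
  not vB);
- a single application upgrades by at most one class.

The lower band edge 2.8 is inclusive (the conservative reading of an
ambiguous boundary). The band (3.3, 3.31), left unassigned by the
"between 3.31 and 3.7" wording, maps upward to 3.71 — continuous
coverage of the risky interval, erring conservative.

The CLP scheme is two-class: threshold log10(500) ≈ 2.699, no vB tier,
offset band [log10(500) − 0.5, log10(500)] with the same +0.01 target
construction. `vb_threshold=None` encodes the missing tier. The logP
screen (`logp_screen`) is the ECHA rule: logP strictly below 4.5 screens
a substance non-bioaccumulative.

## Applicability domain

Three independent checks, combined worst-first:

1. **Descriptor ranges** (fatal). Per-descriptor [min, max] learned
   from the training set; any excursion (closed interval — a value at
   the boundary is inside) puts the compound out of domain.
2. **Structural alerts** (warning). SMARTS rules with count
   constraints. Counting uses unique atom sets, not embeddings: "at
   least six chlorines" counts atoms, and a symmetric pattern never
   double-counts a permuted match. A conjunctive rule requires every
   pattern to meet its own minimum. The packaged rule file ships the
   three alerts whose semantics are documented — A: ≥6 Cl; E:
   aromatic-bound oxygen AND ≥3 aromatic-bound Cl/Br; J: a count-based
   template defaulting to [Si] (flagging siloxane-type compounds),
   marked `template: true` because its intended fragment is
   configurable. Users extend the set via JSON; all SMARTS compile at
   load time, never at match time.
3. **Similarity neighbors** (warning). The six most similar training
   compounds are reported with experimental value, predicted value and
   absolute error. Similarity between descriptor vectors a, b is
   computed after min-max scaling each descriptor on the reference set
   and clipping into [0, 1]: sim = 1 − ‖a−b‖₂/√d, with d the descriptor
   count. This is a documented stand-in for the original (unpublished)
   index: it is bounded in [0, 1], symmetric, exactly 1 at identity,
   monotone in the scaled Euclidean metric, and compatible with the
   0.5 warning threshold. Warnings fire when the best similarity is
   below 0.5 or the mean neighbor |error| exceeds 1.0 log unit (the
   same cutoff used to mine the alert fragments).

Descriptors are pluggable: supplied per record (`desc_*` CSV columns)
or computed by an eight-descriptor structural fallback (molecular
weight, heavy atoms, halogens, aromatic atoms, Crippen logP, H-bond
donors/acceptors, rotatable bonds). The fallback exists because the
original proprietary descriptor set is unavailable; it exercises the
same machinery but does not reproduce the original domain boundaries.

Verdict logic: any range excursion ⇒ `out_of_domain`; otherwise any
warning ⇒ `warning`; else `in_domain`. Every contributing factor is
listed in `reasons`, and the verdict is monotone — adding a warning
never moves it toward `in_domain`. Out-of-domain compounds are still
classified but excluded (and counted) by `evaluate_split`; exclusion is
a reporting-layer decision, not a refusal to predict.

## Validation statistics

- SDEP = √(Σ(oᵢ−pᵢ)²/n); the identity SDEP²·n = Σ residuals² is
  fuzz-tested.
- R² is the squared Pearson correlation of observed vs predicted.
- External Q² = 1 − Σ(oᵢ−pᵢ)²/Σ(oᵢ−ȳ_train)², with the **training-set
  mean** in the denominator — the standard external-validation form,
  which reproduces the observed near-equality of Q² and R² on
  well-calibrated predictions. When no training mean is supplied,
  `evaluate_split` falls back to the split's own mean (adequate for a
  training split only).
- Confusion matrices are 3×3 with rows = predicted, columns = observed
  class; counts are authoritative, percentages are 100·count/n of the
  in-domain set rounded to 2 decimals for display only.
- False negatives = observed B/vB predicted nB; false positives =
  observed nB predicted B/vB. On any dataset, applying the offset can
  only decrease the FN rate and only increase the FP rate (property-
  tested over 20 seeded synthetic datasets).
- Experimental variability = mean over compounds with ≥2 measurements
  of (max − min) of their logBCF values. Single-valued compounds are
  excluded: a singleton's range is undefined, and counting it as zero
  would bias the estimate downward.

## Synthetic data

The generator emulates the statistical shape of a logP-driven BCF
dataset, not its chemistry: logP ~ U(0, 9); logBCF = 0.555·logP + 0.117
+ N(0, 0.5) (the published MLOGP relationship, with noise at the level
both model SDEP and experimental variability sit at); with probability
0.3 a second measurement ~ N(first, 0.45) mimics replicate variability
between data sources. `predicted_logbcf` is the noiseless model value,
so prediction residuals equal the generating noise and SDEP recovery is
exact in expectation. `make_three_splits` apportions n compounds
370:93:172 by largest remainder.

Under this recipe the per-compound range of a replicate pair is
|N(0, σ)|, so the expected experimental variability is σ·√(2/π) ≈ 0.359
at σ = 0.45 — verified by simulation before being frozen into the test.

Placeholder SMILES are decoupled from the numeric fields (descriptors
and logP are stored, not computed from the toy structures), keeping
statistical tests exact; `fixture_structures()` is the structure-aware
test surface, with hand-verified fragment counts for a plain aromatic,
chlorinated phenols/anisoles, hexachlorobenzene, carbon disulfide, a
cyclic siloxane and a long-chain alcohol. What passing tests on
synthetic data do **not** show: realistic chemical-space coverage,
metabolism-driven nonlinearity of BCF in logP, or the original model's
actual error surface.

## Numerical choices and degenerate inputs

- Offset targets are rounded at the 12th decimal so 3.3 + 0.01 prints
  as exactly 3.31.
- Similarity ties in neighbor retrieval break by reference order
  (stable sort); a reference smaller than k returns all compounds plus
  a short-list flag.
- A zero-width descriptor (constant on the reference) contributes 0 to
  every scaled distance.
- Salt inputs keep the largest organic fragment (carbon-containing
  preferred, then heavy-atom count); the action is logged.
- CSV reading merges duplicate ids by accumulating experimental values;
  unparseable SMILES rows are skipped, counted and reported, never
  fatal. Linear-unit BCF columns are log10-transformed on read;
  non-positive linear values are rejected rows.
- Degenerate statistics raise typed errors rather than returning NaN:
  constant vectors (R²), zero denominator (Q²), empty matrices, no
  multi-valued compound (variability).

## Problem sizes

Tests run the grid checks at 10⁴ points, property suites at 20 seeds ×
n = 250–1000, and parameter recovery at n = 1000; the full suite
completes in a few seconds. The acceptance script's sanity run uses one
seeded split at n = 500.

## Known limitations

- The shipped alert set is partial by necessity (the full published
  rule list is not machine-readable); rules B–D and F–K beyond the
  documented three must be supplied by the user.
- The similarity index is a principled stand-in, not the original
  algorithm; absolute similarity values are comparable only within one
  reference fit.
- The fallback descriptors do not reproduce the original model's
  domain: range checks against them are meaningful only relative to a
  reference set processed the same way.
- No logD, no 3D descriptors, no automatic mining of new alerts from
  model errors, and no re-computation of the original continuous-model
  statistics (the underlying dataset and model outputs are not
  shipped).
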