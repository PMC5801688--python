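# Methods

## The intra-association test

Each drug–gene association on a cell-line panel is scored as a binary
classification problem. Responses are logIC50 values (log10, μM), so a
difference of 1.0 is an order of magnitude in potency and negative values
are sub-micromolar. With MT and WT the mutant and wild-type groups among
the nᵢ cells tested with the drug:

- threshold: `thres = (median(MT) + median(WT)) / 2`;
- direction: sensitivity if `med(MT) < med(WT)`, else resistance (a tie
  falls to the resistance branch);
- observed positives: `logIC50 < thres` for sensitivity markers,
  `logIC50 ≥ thres` for resistance markers — the printed inequalities are
  applied verbatim, with no midpoint jitter, so ties at the threshold land
  on the resistant side;
- prediction: mutation status. TP/FN/FP/TN follow, discrimination is the
  φ coefficient (= MCC), and significance comes from Pearson's χ² with
  df = 1 via the survival function (accurate to ~1e-308, so extremely
  strong markers keep representable p-values).

No Yates continuity correction is applied: it would break the exact
identity χ² = n·φ², which the φ-cutoff computation (min significant
φ = √(χ²crit/n)) relies on. The implementation computes χ² by the
observed/expected sum and the identity is enforced only as a test
invariant, keeping the two routes independent.

Because the threshold lies strictly between the two group medians
whenever they differ, at least half of each group falls on its own side;
this guarantees every margin of the table is positive (φ is always
defined) and φ ≥ 0. In the degenerate tie case the result is still
reported, flagged, and φ ≥ 0 is no longer guaranteed; a table with a zero
margin (possible only in the tie case) is skipped and logged rather than
scored.

Group medians of even-sized groups use the midpoint-of-central-order-
statistics convention. Associations with zero mutant or zero wild-type
cells among a drug's tested cells are not scorable and appear in the skip
log with a reason.

## Multiple testing

Benjamini–Hochberg step-up runs once over all scored associations (the
denominator is the fixed universe of testable pairs, not per drug).
Significance is `p ≤ critical value` where the critical value is the
largest p(i) with p(i) ≤ i·q/m; q defaults to 0.20. The step-up is
hand-rolled because the critical value itself is a reported quantity; it
is cross-checked in the tests against an exhaustive brute-force oracle
and against statsmodels' `fdr_bh`.

## Held-out validation

For each drug shared between a training and a test release, the test set
is the cells screened in the test release only; train/test disjointness
is asserted per drug on every run. The per-drug sensitivity threshold is
the median of *all* training responses for the drug (invariant to test
content), cells strictly below it are sensitive, ties count as resistant
(mirroring the intra-association convention; at double precision exact
ties are vanishingly rare on real data). The marker's direction is frozen
from training and never re-estimated. Test performance is MCC; a zero
margin on the test table (the marker makes no prediction in one
direction) is recorded as MCC = 0 with a degenerate flag, while a test
set with no mutant cells at all makes the marker non-evaluable — it is
excluded from summaries rather than counted as 0. The headline summary
statistic is the fraction of evaluable markers with MCC > 0
(better than random).

## Consensus calls

An external per-association p-value table (e.g. from a parametric screen
shipped with the panel) gets its own BH adjustment over the scanned pairs
it covers; pairs it does not cover count as externally non-significant,
and pairs it covers but the scan cannot score are excluded rather than
imputed. The three disjoint call sets — consensus (significant under
both), χ²-only, external-only — are validated on identical splits by
`benchmark_methods`.

## Synthetic panels

The generator draws mutation flags per feature (Bernoulli at a prevalence
that is either fixed or log-uniform over a range), per-drug baselines,
additive mutant shifts for planted pairs, and i.i.d. noise, then masks a
fixed fraction of responses. Defaults emulate a release-1.0-like screen:
638 cells × 130 drugs × 71 features, 57.6% of pairs measured
(`missing_fraction = 0.424`), prevalence log-uniform on [0.02, 0.3]
(dominated by rare features, as mutation panels are), baselines uniform
on [−1, 2] log10 μM, noise sd 0.5 log10 units. Three noise families cover
the motivating data pathologies:

- `gaussian` — N(0, sd);
- `skewed` — a mean-centred log-normal rescaled to the requested sd
  (`skew` is the underlying σ, default 0.8); note its median is below 0;
- `contaminated` — a two-component scale mixture: with probability
  `outlier_fraction` (default 0.05) the draw comes from a component with
  sd multiplied by `outlier_scale` (default 5).

What the generator does **not** emulate: tissue-of-origin covariance
between features, correlated drugs (shared mechanism), dose–response
curve artefacts, and batch structure. Passing tests therefore demonstrate
correctness of the procedure and its behaviour under idealised
missingness and noise, not robustness to the full correlation structure
of real panels.

Everything is driven by one integer seed through `numpy`'s default PCG64
generator; fixed specs are bit-reproducible. Panels round-trip exactly
through the CSV dialect (`%.17g` floats, canonical `x::y` descriptors).

## The panel CSV dialect

Real releases ship mutation calls as `x::y` strings whose exact grammar
is not standardised; the canonical dialect here is: `x` ∈ {`wt`, `na`,
variant token}, `y` ∈ {`0<cn<8`, `cn=K`, `na`}. A call is mutated iff a
variant is named or the copy number is 0 (deletion) or ≥ 8
(amplification); the wild-type range is open on both sides. `wt` with
unknown copy number is wild-type (a negative variant scan is evidence),
`na::na` is missing (no evidence either way). Unrecognised copy-number
tokens degrade to "unknown" with a warning so real-world files parse;
a missing `::` separator is a hard format error naming the cell/gene.
Translocation and MSI columns hold plain tokens: `not-detected`/`wt`/
`mss`-style tokens are wild-type, any other non-blank token names the
detected fusion and is mutated. Responses may be shipped as natural-log
IC50 (the common convention) and are converted to log10 exactly once at
ingest under a dialect flag; a drug listed twice keeps the more broadly
tested instance (ties: first occurrence).

## Calibration of the test under the null — a known limitation

The threshold is estimated from the same data the table is built on, and
placing it midway between the two group medians maximises the apparent
separation. Under a Gaussian global null this inflates χ² relative to the
χ²₁ reference: on 1000-feature null panels at n = 300 the package's own
acceptance script measures a KS distance from uniformity of ≈ 0.05–0.10
(seed-dependent) with small-p enrichment, and the realised BH
false-discovery proportion at q = 0.2 averages ≈ 0.3 over 50 replicates.
The corresponding acceptance test asserts strict calibration and is
expected to fail; it is kept failing deliberately as an honest record.
Practical reading: the procedure's p-values are mildly optimistic near
the significance boundary, so borderline markers deserve extra scrutiny —
which is exactly what the held-out validation step provides.

## Problem sizes and numerical choices

Simulation-based checks use panels of 300–638 cells, up to 1000 features,
50–100 replicates — sizes at which group-median sampling error is small
relative to the planted effects studied (Δ of 1–3 log10 units against
noise sd 0.5). The BH oracle sweep enumerates all 87,380 p-value vectors
of length ≤ 8 over a 4-point grid. Monotonicity assertions on Monte-Carlo
detection rates allow a 0.15–0.25 slack for sampling noise at the chosen
replicate counts. Results CSVs store floats at 17 significant digits so
written and re-read values are bit-identical.
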