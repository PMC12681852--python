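# Methods

## The decision model

`evrank` implements a weighted-sum (simple additive weighting) multi-criteria
decision model over an alternatives × factors matrix X, where alternatives
are EV preparations (typically one per isolation method) and factors are
numeric characterization criteria. The model assumes:

- the matrix is complete — missing cells are a hard error, never imputed,
  because the quotient normalization and the weighted sum are both undefined
  on partial rows;
- every factor's preference direction is monotone (declared maximize /
  minimize / shifted-minimize); non-monotone preferences ("sizes near
  120 nm are best") are out of scope;
- factors are exchangeable after normalization — the score is a convex
  combination, so a unit of normalized performance on one factor trades
  one-for-one against any other at equal weights.

### Normalization

Maximize columns are divided by their maximum; minimize columns enter as
min/X. Both map into (0, 1], award exactly 1 to the best alternative, and
are invariant to positive rescaling of the column (so unit choices do not
matter). Shifted minimization adds a per-factor positive constant before the
min/X quotient; it exists for signed quantities, concretely zeta potential,
where more negative means more colloidally stable. The default shift of 100
corresponds to the conventional zeta range of (−100, +50) mV; it is stored
per factor so any other signed quantity can reuse the mechanism with its own
offset. The shifted form is deliberately **not** scale-invariant — the
offset is meaningful only on the original measurement scale — and the test
suite asserts this as an inequality rather than papering over it.

Degenerate inputs: a constant positive column normalizes to all ones (the
quotient is defined; the column simply carries no discriminating
information). Zero or negative values in minimize columns, or shifted values
≤ 0, are rejected at validation with the rule named — never silently turned
into NaN/Inf. Maximize columns are likewise required to be strictly positive
at normalization time so the (0, 1] range is provable; the bench-level
preprocessing helpers may *produce* negative derived values (negative
internal content, negative radical scavenging) and flag them with warnings,
but the decision-matrix validator is the enforcement point that keeps such
columns out of a scoring run unless the user resolves them.

### Scoring, ranking, ties

S_i = Σ_j w_j N_ij with w on the unit simplex (tolerance on Σw = 1 is 1e-6;
user weights not on the simplex are either rejected or — only on explicit
request — rescaled with a logged warning). Equal weights are the default
reference configuration. Ranks are descending competition ranks
(rank = 1 + number of strictly better scores): tied alternatives share the
smallest applicable rank and the next distinct score skips. Competition
ranking was chosen over fractional or ordinal schemes because it never
asserts an ordering the data cannot support; display order falls back to
input order, which keeps every output deterministic. Scores are printed to
3 decimals and carried at full precision internally.

### Closeness to ideal (TOPSIS)

The "proximity to best/worst case" view is formalized as classical TOPSIS on
the weighted normalized matrix V_ij = w_j N_ij: ideal and anti-ideal
profiles are the per-column extrema of V, distances are Euclidean, and the
closeness coefficient is C = D⁻/(D⁺ + D⁻). Two design choices deserve
emphasis. First, the ideal is defined per-dataset (column maxima of V), not
as the absolute all-ones vector — so 100 % closeness is attainable only by
an alternative that is per-factor best everywhere, which is exactly the
interpretation that makes "no method fully achieves the ideal" a meaningful
diagnostic rather than a tautology. Second, the closeness ordering is not
forced to agree with the score ordering; the two are complementary views and
the package never reconciles them. If all alternatives are identical both
distances vanish; closeness is then defined as 1 for all, with a warning.

## Rank-stability analysis

Weight perturbation uses a symmetric Dirichlet(α) over the weight simplex:
α = 1 (the default) is the uniform distribution over valid weight vectors —
an uninformative exploration — and α → ∞ concentrates at equal weights
(verified in the suite at α = 1e6, where all scenario ranks collapse to the
baseline). The default scenario count is 1,000. Stability is summarized as
rank *retention*: the fraction of scenarios in which an alternative holds
exactly its baseline rank, reported per alternative plus top-1 and bottom
summaries. Retention was chosen because it turns the qualitative claim
"the extremes are stable" into a number: a per-factor-dominant alternative
provably has top-1 retention 1.0 for any weights (the score is linear in w),
which doubles as a correctness oracle. The one-at-a-time sweep pins a single
factor's weight to a grid value in [0, 1) and rescales the remaining weights
proportionally; it is deterministic and exists to locate rank-flip
thresholds (for a 2×2 problem the flip point is computable by hand and the
suite checks the sweep brackets it). All sampling is seeded and the seed is
recorded in every report.

## Bioactivity correlation

Pearson r between each factor column and cell-viability percentages, per
(cell line, dose) condition, requires ≥ 3 paired preparations and nonzero
variance; p-values come from the exact t transform t = r√((n−2)/(1−r²)) on
n−2 degrees of freedom (computed via scipy). Stars: * p ≤ 0.05, ** p ≤ 0.01,
*** p ≤ 0.001, else ns, applied per cell with no multiplicity correction by
default — each condition is starred on its own, matching how such grids are
conventionally read; a Benjamini–Hochberg adjusted column is available
opt-in. With ~8 preparations per condition these correlations are
descriptive, not inferential: at n = 8 only |r| ≳ 0.71 reaches p ≤ 0.05.

## Synthetic data generator

The generator emulates small multi-method EV comparison datasets: a Gaussian
copula imposes a target correlation matrix (unit diagonal, entries in
[−1, 1], PSD within 1e-8, factorized by symmetric eigendecomposition so
exactly-singular targets are accepted) on user-chosen marginals — Gaussian
for continuous quantities, Poisson for particle counts, lognormal for
quantities spanning decades such as purity ratios. Poisson columns are
produced by pushing the latent normal through Φ and then the discrete
quantile, which preserves the copula ordering; the empirical correlation of
a discrete column is therefore slightly attenuated relative to the latent
target, and the correlation-recovery tests use a large-sample run of the
generator itself as the oracle rather than the latent number. Replicate
noise is multiplicative Gaussian, value × (1 + cv·ε), with a default CV of
5 % — a typical triplicate instrument CV — applied independently per
replicate before triplicate averaging, mirroring how bench values reach a
decision matrix. Columns with positivity constraints carry floors (explicit,
or derived from the direction); offending rows are redrawn whole, never
patched cell-wise, so the copula structure is preserved, with a hard error
after 1,000 rounds.

Two presets fix the study shapes: `ev15x11` (15 preparations × 11
physicochemical factors) and `ev8x13` (8 preparations × the same 11 plus
isolation time and cost as minimize criteria). Preset parameter choices are
field-realistic envelopes: mean size ~N(155, 15) nm (most mass in
110–200 nm), zeta ~N(−25, 8) mV (spanning roughly −49 to −2), recovery
~N(45, 12) %, particle count Poisson(100) in units of 1e9/mL, purity ratios
lognormal around 6e10 (per µg protein) and 3e11 (per ng nucleic acid)
spanning ~1e10–1e12, and moderate TPC/TFC/DPPH levels. The planted
correlation block encodes the yield–purity trade-off (recovery vs protein
purity −0.6, vs nucleic-acid purity −0.5, recovery vs particle count +0.6)
plus a positive phenolic–flavonoid–antioxidant cluster; the full matrix was
checked PSD (smallest eigenvalue ≈ 0.28). These presets reproduce *shape and
behavior* — realistic ranges, correlations, noise — not any particular
measured dataset.

What the generator does **not** emulate: instrument-specific artifacts
(NTA size-dependent detection bias, Zetasizer run-to-run drift), batch
effects between isolation days, non-Gaussian heavy-tailed noise, or missing
values. Passing tests on synthetic data therefore demonstrate algorithmic
correctness (normalization, scoring, ranking, stability and correlation
machinery behave as specified) and robustness to realistic correlation and
noise levels — not that any particular real preparation ranking is correct.

## Numerical and I/O choices

- Weight-sum tolerance 1e-6 at validation; resolved weight vectors sum to 1
  within 1e-12.
- No epsilon-flooring of denominators anywhere; strict positivity is
  enforced upstream instead, keeping N ∈ (0, 1] provable rather than
  approximate.
- Matrix CSV round-trips are bit-exact: floats are written with
  shortest-repr formatting and parsed with round-trip precision.
- Full-pipeline determinism (identical inputs + config + seed ⇒
  byte-identical numeric tables) is a tested contract; report timestamps
  live only in the human-readable report, never in numeric tables.
- Problem sizes in the test suite follow the study shapes (8–15
  alternatives, 11–13 factors); parameter-recovery checks scale n up to
  1,000–2,000 where 3-standard-error bounds become tight, and the
  planted-correlation check averages 500 seeded 8-preparation datasets.

## Known limitations

- The weighted-sum model is fully compensatory: a catastrophic value on one
  factor can be bought back by excellence elsewhere. Outranking methods that
  model veto thresholds are out of scope.
- Quotient normalization is sensitive to the extremes of the observed
  sample; adding or removing an alternative can change every normalized
  value in a column (rank reversal is possible, as in any min/max-anchored
  MCDA scheme). The sensitivity module probes weight perturbations, not
  alternative-set perturbations.
- Only Dirichlet sampling and one-at-a-time sweeps are provided for
  stability; analytic rank-stability regions (vertex enumeration of the
  weight simplex) are not computed.
- The direction profile for a given dataset is user configuration. A
  reasonable default for the standard 11-factor panel is: maximize recovery,
  both purities, protein and nucleic-acid content, particle count, TFC and
  antioxidant activity; minimize size and TPC; shifted-minimize zeta — but
  whether (for instance) protein concentration or TPC is desirable is a
  scientific judgement that the package never hard-codes.
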