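# Methods

## The transformation model

`symtrans` treats preprocessing as a per-variable re-expression problem:
find, for each column, a monotone map that makes its distribution across
subjects approximately symmetric.  Symmetry is the single target because
it is checkable variable-by-variable (cost linear in the number of
columns, unlike inspecting every pairwise relationship) and because it
carries most of the downstream benefits — stabler variance across groups,
more linear relationships, and distance matrices that are not dominated
by one stretched tail.

The search space is the ladder of powers x → xᵖ restricted to
p = m/n with n ∈ {1,2,3}, m ∈ {−2,…,2} — eleven rungs, with p = 0 meaning
the logarithm and negative rungs monotone decreasing.  A discrete grid is
a deliberate choice over a continuous (Box–Cox style) exponent: at the
preprocessing stage there is no single downstream objective to optimize,
and the rungs are individually interpretable (1/time is a speed, √count a
variance-stabilized rate).  `power == 1` is implemented as the identity
(pass-through) for every kind; the literal p = 1 member of each family is
affine in the raw values and therefore has identical quartile skewness,
so nothing is lost and "no transformation" stays exact.

Each of the ten variable kinds composes the ladder with its own
re-expression:

- **amount** (y ≥ C): power of (y − C + start);
- **count**: same with C = 0; √n stabilizes Poisson variance to ≈ 1/4;
- **ratio** x/y: xᵖ − yᵖ, log x − log y at p = 0;
- **fraction** r ∈ [0,1]: logit at p = 0, folded power rᵖ − (1−r)ᵖ
  otherwise — the folded family preserves the complement antisymmetry
  T(1−r) = −T(r), so measuring a fraction or its complement yields the
  same information up to sign;
- **counted fraction** (n of m): the started logit
  log((n+⅓)/(m−n+⅓)); the ⅓ start keeps the boundaries n = 0, m finite.
  Internally this is the p = 0 member of the folded-power family applied
  to the started fraction (n+⅓)/(m+⅔), which gives the counted kinds a
  full ladder to search;
- **bounded amount / bounded count / rank**: rewritten as (started)
  fractions of their ranges and handled as above; a rank out of N is the
  bounded count on [1, N];
- **difference**: the two component columns are transformed separately
  and subtracted; a strictly positive difference without available
  components is treated as an amount, anything else passes through with
  an advisory (monotone maps of a sign-changing difference rarely help);
- **ordinal**: categories are scored by the logit of the midpoint of
  their cumulative interval, logit(F₍k₋₁₎ + f_k/2) — mid-ranks against a
  logistic reference.  This is a single re-expression, not a ladder.

**Start policy for zeros.**  When an amount or count contains zeros and
the rung requires positivity (p ≤ 0), a start equal to half the smallest
positive observed value is added.  This is recorded in the transform spec
so re-application is exact.

**Reversal** (for variables whose direction should be flipped so that
"healthy" points the same way) is negation *after* transformation,
keeping direction orthogonal to shape.

## Deciding which variables need transformation

Asymmetry is measured by the quartile (Yule/Bowley) skewness
sk = [½(m₁+m₃) − m₂]/[½(m₃−m₁)], bounded in [−1,1], zero for symmetric
samples, resistant to outliers, and invariant under positive affine maps
(hence the testable corollary that z-scoring never changes it).
Quantiles use linear interpolation at rank p(n−1)+1; the convention is
fixed and documented because decisions near the threshold depend on it.

A variable is flagged when |sk| ≥ c(n) with the step rule c = 0.10 for
n > 180, 0.12 for 120 ≤ n ≤ 180, 0.15 below — small samples estimate
quartiles noisily, so they warrant a larger margin.  Only the three
anchors are prescribed; the step function avoids inventing an
interpolation law between them.

Heavily tied variables (bounded counts, ranks or ordinals over ≤ 7
distinct values, or any sample whose interquartile range collapses) route
to a less resistant fallback: the same formula on the eighths
(12.5th/50th/87.5th percentiles).  If even the eighths collapse, sk is
reported as 0 and the variable is declared untransformable by symmetry —
no monotone map can symmetrize a distribution whose bulk is one value.

## The semi-automated selection

For each flagged variable every admissible rung is evaluated on the data
(candidates that hit domain errors or produce non-finite values are
skipped) and scored by |post-transform sk|.  The chosen candidate is:

- the **logarithm**, whenever its residual |sk| is below
  min(c(n), raw |sk|) — i.e. when the log already achieves symmetry that
  the decision rule itself would call "no further transformation needed".
  Rationale: the sampling SD of the quartile skewness is ≈ 1.45/√n
  (about half the threshold at n ≈ 800), so differences between
  candidates that are all below threshold are noise, and among
  statistically indistinguishable options the canonical interpretable
  re-expression should win;
- otherwise the rung minimizing |post sk|, with near-ties (within 0.01)
  broken toward p closest to 1, then toward the classically
  interpretable rungs log, square root, inverse.

Because the identity is always in the candidate pool, the automatic
choice can never make symmetry worse.  The returned list contains the
winner, up to two ladder neighbors on each side, and the raw data as
reference — mirroring the histogram-panel display a reviewer uses to
override the automation (the classic trap being a double-humped variable
whose marginal skewness minimizer destroys the humps; the index cannot
see modes, a human can).  Choices land in a registry keyed by variable,
with a data fingerprint, chooser (auto/manual) and an audit trail of
overrides; re-applying a registry to the same table is byte-identical,
and the whole auto path is deterministic.

## The clustering simulation

The generator emulates a clinical cohort whose assigned diagnoses (A, B,
C, Normal) hide a finer truth: A has subtypes A1/A2, and B and C are
subtypes of one disease BC.  Six subgroups × 200 subjects, 100 features:

- **7 informative features**, unit-variance Gaussians whose group means
  follow a fixed binary codebook scaled by `effect_size`.  Every codebook
  column splits the six groups exactly 3/3, so each informative feature
  is *marginally symmetric* (an equal-weight two-hump mixture) and no
  single feature separates all six groups; jointly the six codewords are
  distinct with minimum pairwise Hamming distance 3, and BC sits
  equidistant from B and C.
- **93 noise features**, group-independent: 60% symmetric Gaussian, 20%
  Binomial(10, ½) (discrete), 20% Bernoulli(½) (binary).
- The 4-level *assigned* label collapses A1/A2 into A and splits BC
  members between B and C with equal probability (how such patients were
  originally diagnosed is unknowable, so a fair coin is the neutral
  choice).

The analysis pipeline, identical in every arm: per-feature one-way ANOVA
against the assigned labels with Benjamini–Hochberg FDR at q = 0.05
(marginal tests rather than a forward-stepwise screen: selection results
are insensitive to this choice here, and the interface allows swapping a
stepwise variant in), then K-medoids at k = 6 on the Manhattan distance
matrix of the selected features, then the Hubert–Arabie adjusted Rand
index against the six true subgroups and a confusion matrix whose cluster
columns are matched to groups by an optimal assignment.

The **damaged arm** replaces each informative (continuous) feature x by
exp(severity · z(x)) with z the within-feature standardization — a
monotone, rank-preserving map whose output is lognormal-shaped (quartile
skewness 0.325 at severity 1 for Gaussian input).  Discrete and binary
features are left intact.  The damage never touches the group structure —
only the marginal shape — yet it collapses cluster recovery, because the
Manhattan distances become dominated by the stretched tail.

**Calibration.**  The two free constants ship as fixed defaults,
calibrated once so the study reproduces its reference operating point:
`effect_size = 3.5` puts the symmetric arm at mean adjusted Rand ≈ 0.986
(a handful of misassignments out of 1200), and `skew_severity = 1.85`
puts the damaged arm near 0.68.  An optional third arm re-symmetrizes the
damaged table with the automatic search (each damaged column declared an
amount; columns with ≤ 10 distinct values skipped, since a monotone map
cannot symmetrize two-valued data) and recovers the symmetric-arm
performance.

**K-medoids solver.**  No installed library provides PAM, so the solver
is implemented here.  Problems with at most 1000 candidate medoid sets
are solved exactly by enumeration — so tiny instances are globally
optimal; larger problems use the classic deterministic heuristic: BUILD
(greedy seeding starting from the most central point) followed by SWAP
(repeatedly the single best medoid/non-medoid exchange until no exchange
lowers the objective), with ties resolved to the lowest index.  The SWAP
delta computation is vectorized over the precomputed distance matrix, so
a 1200-point, k = 6 run takes well under a second.  The heuristic is a
local optimizer: on roughly 10% of random ≤ 8-point instances BUILD+SWAP
(ours and R's `cluster::pam` alike, verified on a counterexample)
terminates one double-swap short of the global optimum, which is why the
exact path exists for small problems.

**Seeds.**  A single master seed fans out to per-stage streams via
`SeedSequence([seed, stage])`, so generation and label assignment are
independently reproducible; the selection and clustering stages are
deterministic given the data.

## What the simulation does and does not show

The generator produces exchangeable subjects, independent features,
exactly equal group sizes and Gaussian within-group noise.  Real cohorts
have correlated features, unbalanced and overlapping diagnoses, missing
values and measurement artifacts.  Passing the study therefore shows that
the pipeline's *contrast* — skew destroys distance-based recovery,
symmetry (restored or native) preserves it — holds under clean
conditions; it does not certify performance on any real cohort.  Missing
values propagate through transforms and are excluded from quantile
computations; variables above 50% missing are flagged but processed.

## Numerical and design notes

- Natural log internally everywhere; the base only rescales and reports
  may display base 2 or 10.
- Candidate evaluation reuses the scan's skewness machinery, including
  the eighths fallback, so "before" and "after" are measured identically.
- Degenerate inputs: fewer than 4 observations cannot be scanned; an
  all-constant column is reported untransformable; constant features get
  p = 1 in the ANOVA screen and are never selected.
- Registry equality ignores timestamps (kept for the audit trail), so
  identical inputs in auto mode compare equal across runs.
- Histogram panels use Freedman–Diaconis binning floored at 10 bins —
  purely presentational, fixed for reproducibility of report images.
- The test suite replicates the headline study over 20 seeds (~20 s) and
  checks the damaged arm at ±0.10 around its reference value, reflecting
  its across-seed spread (SD ≈ 0.06); the symmetric arm is much tighter
  (SD ≈ 0.005).
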