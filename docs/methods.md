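# Methods

## Model and assumptions

`netdea` scores decision-making units (DMUs) with a non-radial, slack-based
network DEA measure under weak disposability of undesirable outputs.  The
production-possibility set is the standard DEA envelope: convex combinations
of observed peers (variable returns to scale, VRS) or conical combinations
(constant returns, CRS).  Three axioms shape the constraint system:

1. **Non-radial contraction.** Inputs, outputs and links may adjust
   independently through slacks; nothing forces beds and staff hours to move
   proportionally.
2. **Weak disposability.** A benchmark cannot discard a peer's undesirable
   outputs for free: desirable and undesirable outputs of peer *j* are scaled
   jointly by an abatement factor θ_j ∈ [0, 1].  The bilinear product λθ is
   linearised by splitting the intensity vector, λ = μ + φ, with
   θ_j = φ_j/(φ_j + μ_j); μ_j carries the abated share of peer *j*, φ_j the
   active share.
3. **Network consistency.** For every link (k, h), the quantity the
   benchmark of division h consumes must equal the quantity the benchmark of
   division k produces: Z^(k,h)(μ^h + φ^h) = Z^(k,h)(μ^k + φ^k).  The link
   tie is the only inter-division coupling; the evaluated DMU's own link
   value enters only through the peers' data.  A `free_links=True` flag
   drops the ties entirely (each division then benchmarks independently),
   which can only lower scores further and is off by default.

Undesirable outputs are matched exactly (u_o = U φ).  On observed data this
is always satisfiable — setting μ = 0 and φ = e_o reproduces the DMU itself
with zero slack, which also proves every program feasible and every score
≤ 1.  If externally edited data makes the requirement unreachable, the
solver raises rather than silently relaxing the constraint.

## Objective convention

The slack-based objectives are stated as optimisations of score expressions
whose literal maximisation has a trivial zero-slack solution.  The package
uses the standard SBM convention: maximise the *mean relative slack* (a
linear objective), then report

* input-oriented division: score = 1 − (1/m_k) Σ_i s_i^−/x_io at the optimum,
* output-oriented division: score = 1 / (1 + (1/r_k) Σ_r s_r^+/v_ro).

This makes best-practice DMUs score exactly 1 and keeps all scores in
(0, 1].  By default the first division is input-oriented and all others
output-oriented; the orientation map is configurable per division.

## One LP per division

Each divisional score solves its own LP over the **full coupled system**
(all divisions' intensity vectors, slacks and link ties appear as
constraints; only the objective focuses on one division), and the overall
score is the unweighted arithmetic mean of the K divisional scores.  A
single jointly weighted program is a different estimator and is out of
scope.  Divisional LP values are unique even when the optimising slacks and
intensities are not; only scores are asserted in tests, never the vectors
pointwise.

A division whose objective side is empty (an input-oriented division with no
external inputs, or an output-oriented one with no desirable outputs) has an
empty objective sum; its score is defined as 1 and a warning is logged.

## Returns to scale and scale efficiency

VRS adds the convexity constraint Σ_j(μ_j^k + φ_j^k) = 1 per division;
removing it gives CRS.  Because CRS only enlarges the benchmark set,
ρ_CRS ≤ ρ_VRS, and scale efficiency ρ_CRS/ρ_VRS ∈ (0, 1] isolates the
inefficiency attributable to operating off the optimal scale.

## Numerical choices

* LPs are solved with HiGHS (dual simplex) through `scipy.optimize.linprog`
  at its default tolerances.  The constraint matrix depends only on the
  period and RTS regime, so it is assembled once and reused across DMUs and
  focus divisions.
* Zero cells are replaced at bind time by 1e-6 × the within-period column
  mean (absolute 1e-6 if the column is all zero): the score divides by the
  evaluated DMU's own observations, and exact zeros make SBM scores
  unstable.  Strictly positive cells are never modified.
* Optimal objective values are clipped at 0 from below (stray −1e−12 from
  the solver) and scores at 1 from above.
* Frontier classification uses overall ≥ 1 − tol with tol = 1e-6 by default.
* Ratio/percentage columns are rejected at ingestion by default
  (`counts_only=True`): the measure is only meaningful on absolute volumes.

## Screening

Pearson correlations are computed on the pooled (dmu, period) observations —
a single panel-wide matrix rather than per-period matrices, matching how the
clusters are used (one merge decision for the whole panel).  Only pairs
sharing a (division, role) context are clusterable, since only variables
with the same classification in the model are exchangeable; clusters are
connected components of the thresholded graph within each context, so
overlapping high-correlation pairs chain into one component (the pairwise r
values are reported per cluster for inspection).  Zero-variance columns have
undefined correlation and are excluded.  Merging is by cellwise **sum**
only — unit-safe for like-for-like quantities and exactly conservative;
other aggregation methods are rejected to avoid silent unit mixing.

## Scenario analysis

Each counterfactual replaces exactly one column and re-solves the model;
per-DMU impact is the ratio of scenario to baseline cross-period average
overall score, minus one.  The rule grammar covers the three bound types:
`epsilon` (near-zero), a volume column (cellwise copy), or a multiple of the
observed maximum.  The default table bounds undesirable event counts by
their volume column (Q4, Q5 by inpatients E7; Q6, Q7 by surgeries E9; A2 by
outpatient visits E8), desirable counts the other way around, and waiting
days (A3) by 2 × the observed maximum.  Only the pressure-ulcer (Q4) pair of
bounds follows a prescribed construction; the other defaults are this
package's reconstructions, recorded in the run output and fully
overridable.

The scenario `epsilon` is the absolute constant 1e-6 rather than the
relative bind-time epsilon: a data-dependent epsilon would make the edit
non-idempotent (re-applying the best case would keep shrinking the column).
It matches the synthetic generator's positivity floor, so a column already
at its best case is a genuine no-op.  One variable is changed at a time;
correlated columns are deliberately not propagated — the single-variable
design isolates each dimension's marginal effect and is a known limitation
for realism.

## Sensitivity analysis

Variants are the Cartesian product over clusters of single-representative
choices; clusters that do not intersect the spec are skipped, and a
partially present cluster is an error.  The reported statistic is the
per-DMU **max absolute pairwise difference** (max − min) of cross-period
average overall scores across variants — symmetric in variant order — with
DMUs flagged above 5 percentage points by default.  A baseline-referenced
comparison can be obtained by passing the chosen baseline first and reading
the summaries table directly.

## Synthetic generator

The generator emulates the structure the model assumes, not any real
distribution: a latent hospital scale (log-uniform, default spread 6×)
drives beds, staff hours track beds, costs track staff — reproducing the
input collinearity screening must find, with requested pairs (default
E2–E3 at r = 0.99) calibrated in log space to the target correlation;
production volumes are scale divided by a per-DMU inefficiency factor ≥ 1
(default U(1.0, 1.4)), so inefficiency is a multiplicative input excess;
event counts are binomial draws from their volume columns at configurable
rates (adverse events rare, appropriateness counts common), which enforces
the cellwise bound count ≤ volume by construction; waiting days are
lognormal around 90; all noise is mean-one lognormal (default CV 0.10),
keeping every value strictly positive before the 1e-6 floor.  Group labels
B–F are assigned round-robin by scale rank purely for the group-aggregation
machinery.

What it does **not** emulate: real marginal distributions or descriptive
statistics of any health system, case-mix differences between hospital
groups, serial correlation beyond a fixed per-DMU scale, or correlated
shocks between quality and efficiency variables.  Passing tests therefore
demonstrate the correctness and invariances of the method, not empirical
conclusions about any real hospital system.

## Problem sizes

The default panel is 27 DMUs × 4 periods × 19 variables, the scale the
method is intended for; each LP then has ~220 variables and ~25 equality
constraints and solves in milliseconds.  Unit and property tests use 1–8
DMU instances, where the LP can be checked against exhaustive independent
oracles: a simplex-grid search at 1e-3 resolution and an exact
basic-solution enumeration, both computing slacks in closed form.

## Known limitations

* Scores compare all DMUs in one pool; group labels aggregate results but do
  not restrict the benchmark set to within-group peers.
* The link ties are the only printed coupling; pinning benchmarks to the
  evaluated DMU's own link values ("fixed-value links") is not implemented.
* No statistical inference on scores (no bootstrap), no super-efficiency, no
  Malmquist or dynamic carry-over extensions.
* Alternate optima: slack and intensity vectors are not unique; anything
  built on them (θ, peer sets) should be read as *one* optimal
  certificate.
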