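# Methods

## Model

The tool is a discrete Bayesian network: a DAG over variables
`X_1 … X_n`, each with finitely many states, whose joint factors as
`P(X_1…X_n) = Π_i P(X_i | pa(X_i))`. Continuous quantities enter only
after discretization: airborne concentration and the OEL carry explicit
bin edges in μg/m³ and particle size in nm; a state denotes the half-open
interval `[lo, hi)` (last bin closed). Concentration uses 8 bins over
0–1000 μg/m³ whose widths double from left to right
(`make_concentration_bins(0, 1000, 8, growth=2)`), concentrating
resolution over the 1–50 μg/m³ range in which recommended nanomaterial
OELs fall. Expectations and ratio arithmetic collapse each bin onto a
representative: the geometric midpoint √(lo·hi) for positive bins
(natural for width-growing bins and less biased in ratios), the
arithmetic midpoint for the bin touching zero.

The shipped CNT/Ag/TiO₂ networks share one 14-node skeleton: 12
physicochemical characteristics, the airborne-concentration node
(parents: dispersibility, solubility) and the OEL node (parent: the CMR
flag). Coating, pH and contamination are parentless and uniform —
deliberate indifference where knowledge is lacking. The remaining edges
encode a conventional causal story (charge → agglomeration → size →
surface area, coating/contamination → reactivity, coating/agglomeration →
dispersibility) and their CPTs are constructed from two parametric
families: graded softmax-like rows over ordered states, and truncated
lognormal masses over binned scales. These parameterizations are
*editable defaults*, not measurements; the three materials differ only in
the priors for solubility, morphology and CMR and in the concentration
scale, chosen so mean HQ orders CNT < Ag < TiO₂ under empty evidence
(the ordering itself is a fixture convention, configurable in
`nanorisk.materials`).

## Inference

`posterior_marginals` runs variable elimination with min-fill ordering
(lexicographic tie-break, so runs are deterministic); evidence is applied
by factor reduction. `joint_enumeration` materializes the full joint
(≤ 10⁶ configurations) and is kept solely as a brute-force oracle; the
test suite certifies agreement to 1e-9 on 100 random networks. Evidence
with zero probability raises a distinct `ZeroProbabilityError` rather
than propagating NaNs, so impossible observations are distinguishable
from numerical failure.

## EM learning under missing data

Cells are assumed missing completely at random — the simplest mechanism
consistent with case tables aggregated from heterogeneous literature, and
the one under which conditioning each row on its observed cells yields
unbiased expected sufficient statistics. The E-step deduplicates rows by
missingness pattern and computes, per row and per family (child +
parents), the exact joint posterior: through one materialized joint table
when the state space is ≤ 5·10⁶ (a 14-node default network fits; ≲ 40 MB)
and through variable elimination otherwise. Fully observed rows bypass
inference entirely — their counts are indicators — which also keeps
counting well-defined when an interim MLE assigns a complete case zero
probability. The M-step sets each row to
`(expected counts + prior_strength) / normalizer` with `prior_strength`
a per-cell Dirichlet pseudo-count (default 1, add-one smoothing; zero
cells are absorbing under EM, so the default keeps them open; set 0 for
the pure MLE, which with complete data reduces exactly to relative
frequencies). Rows whose expected count and prior are both zero are left
unchanged.

Initialization: the network's current CPTs, with seeded jitter of
magnitude 0.01 added to exactly-uniform rows to break symmetry.
Convergence: relative change of the objective < `tol` (default 1e-6),
cap `max_iter = 200`. The recorded trace is the objective EM ascends —
log-likelihood plus the Dirichlet log-prior when `prior_strength > 0` —
because the raw likelihood alone is not guaranteed monotone under MAP-EM;
at prior 0 the trace is the pure log-likelihood. The trace is
non-decreasing within 1e-8 on every run, and the suite asserts it.

## Experience-weighted updating

Each CPT row carries an *experience* count: an equivalent sample size
measuring confidence in that row. Updating on a batch treats
`row × experience` as Dirichlet pseudo-counts, adds the batch's expected
counts (one exact E-pass under the current parameters; complete cases
contribute exactly 1, partially observed cases spread their posterior
mass fractionally across parent configurations), renormalizes, and grows
the experience by the absorbed count — after updating on complete data
the experience summed over a variable's parent configurations equals the
number of cases seen. Consequences asserted in tests: zero-experience
uniform networks jump straight to the MLE; sequential complete-data
batches equal their concatenation; and the L1 change a fixed batch causes
is non-increasing in prior experience — confident rows move little.

## Risk characterization

The OEL comes either from a dose-response configuration —
`OEL = POD / UF`, UF defaulting to the usual 100, an additional ÷10 when
the point of departure is a LOAEL, and in linear (carcinogenic) mode one
more documented ÷10 standing in for low-dose linear extrapolation (a full
slope-factor integration is an extension point) — or from the network's
OEL node posterior. Exposure and OEL distributions are combined as
independent when forming the ratio: in the default network they share no
active path once the physicochemical evidence and CMR are instantiated,
and the approximation is exact for a config-derived (point-mass) OEL.
The HQ forecast enumerates all pairwise ratios `c_i/o_j` with weights
`p_i q_j`; the mean and the equal-tailed 5%/95% quantiles are taken on
these atoms (quantile = smallest atom whose CDF reaches the level), and
the reported distribution is re-binned onto a geometric HQ grid. Banding
uses the mean HQ: negligible < 10%, caution up to and including 100%,
potential risk strictly above 100% (the ratio-1 inflection, exceeded
strictly) up to 1000%, high risk beyond. The 10% and 1000% edges are
reporting conventions for heat-map granularity; only the 100% inflection
is decision-theoretically meaningful. Margin of exposure is reported as a
synonym of HQ (exposure over limit); note the literature also uses the
reciprocal convention (NOAEL over predicted dose).

Heat-map coordinates are the estimated mean OEL (x) and mean
concentration (y) with the 90% credible endpoints of each axis drawn as
dashed/solid lines.

## Synthetic data and what passing tests show

`generate_cases` forward-samples complete cases from a ground-truth
network (ancestral order) and masks each cell independently with
probability `missing_rate` (default 0.30, echoing the heavy missingness
of literature-derived tables while keeping EM identifiable at the fixture
sizes of 46/39/55 rows); per-column masking weights are exposed for
skewed missingness. Generation is byte-reproducible from the seed.

The generator emulates the *statistical shape* of literature-derived
collections — row counts, discreteness, missingness — not their values:
real tables are not MCAR (absent variables cluster by study type), rows
are not i.i.d. (several rows per source), and the true data-generating
process is not a 14-node discrete network. Passing the recovery and
calibration suites therefore shows the machinery is correct under its own
assumptions, not that real CNT risk equals the fixture numbers.

Calibration is measured operationally: sample fresh cases from truth,
hide the concentration bin, condition on all other cells, and take the
smallest posterior-mass set reaching 0.90 (states added by decreasing
probability, ties by index). Because discrete mass arrives in lumps, the
attained level is ≥ nominal, so empirical coverage ≥ 90% is the correct
expectation — observed ≈ 97% with the truth as the fitted model. Problem
sizes used by the default suites: 1,000 test cases for calibration, 5,000
rows / 30% missing for parameter recovery (TV < 0.05 on rows with
expected count ≥ 20), 10⁶ draws for the Monte-Carlo ratio oracle.

## Numerical conventions and edge cases

- CPT rows must sum to 1 within 1e-9; validation renormalizes only rows
  off by more than 1e-12, making it idempotent to the last bit.
- `assign_bin` uses half-open bins, last bin closed; values outside the
  binned range are errors, not clamps.
- Posterior equality between elimination and enumeration is asserted at
  1e-9; EM monotonicity at 1e-8 per step; sequential-update additivity at
  1e-9.
- An OEL distribution with mass on a non-positive representative is
  rejected (the ratio would be undefined); the first concentration bin may
  touch zero since it only ever appears in the numerator.
- All randomness (sampling, masking, EM jitter) flows through
  `numpy.random.default_rng(seed)`; identical seeds give identical bytes.

## Known limitations

Structure is fixed by elicitation — no structure learning. Missingness
corrections beyond MCAR (MAR/MNAR) are out of scope, as are benchmark-dose
modelling, dermal/ingestion routes and environmental endpoints. XMLBIF
interchange preserves structure and CPTs but drops bin edges, tags and
experience (the format has no slots for them). The linear dose-response
mode is an effective divisor, not a slope-factor integration.
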