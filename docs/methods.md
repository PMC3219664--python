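# Methods

## The symptom graph

The raw object is a bipartite incidence structure: symptoms on one side,
disorders on the other, with a membership (s, d) whenever symptom *s* is
a diagnostic criterion of disorder *d*. Projecting onto the symptom side
joins two symptoms whenever some disorder lists both, so every disorder's
symptom set induces a clique and disorders become connected exactly when
they share *bridge symptoms*. The projection is a simple graph: repeated
co-occurrence across disorders collapses to one edge (the count is kept
as the `weight` edge attribute but no statistic uses it).

The package works throughout on the giant component of that graph
(`giant_component`, ties broken by smallest member label), because path
lengths between components are undefined.

## Small-world statistics

* **Clustering** is global transitivity, 3·(triangles)/(paths of length
  2), with the denominator counted as Σ_v C(deg v, 2). Watts–Strogatz
  local averaging is deliberately not the default; the transitivity form
  is the one entering the small-world index here.
* **Path structure**: geodesic lengths come from BFS (via
  `scipy.sparse.csgraph`); geodesic *counts* use the standard path-count
  recursion σ(s,v) = Σ_{u∈pred(v)} σ(s,u). Both are validated against an
  exhaustive simple-path enumeration oracle on small random graphs.
  Averages are over unordered distinct pairs; doubling the mean geodesic
  count converts to ordered-pair counting.
* **Random-graph baselines**: for a G(n,m) graph with mean degree
  ⟨k⟩ = 2m/n > 1,

      C_rnd = ⟨k⟩/n,
      L_rnd = (ln n − γ)/ln⟨k⟩ + 1/2   (γ = Euler–Mascheroni).

  These are mean-field expressions; at n = 208, ⟨k⟩ = 18.7 the L formula
  overshoots sampled G(n,m) ensembles by ≈ 2.3%, which the test suite
  treats as the formula's known finite-size bias (sampling agreement is
  asserted tightly at n = 1000, ⟨k⟩ = 10).
* **Small-world index**: SWI = (C/C_rnd)/(L/L_rnd), equal to 1 for a
  random graph and ≥ 3 under the conservative small-world criterion.
* **Degree-tail classification** fits the log survival function of the
  degree distribution linearly against k (exponential tail) and against
  log k (power-law tail) and compares R²; a ΔR² under 0.01 is reported as
  "indeterminate" rather than forcing a winner.
* **Betweenness**: the exact current-flow (random-walk) measure is the
  primary, deterministic output (networkx implementation); a Monte-Carlo
  walker estimator (uniform source/target, simple random walk absorbed at
  the target, endpoint visits excluded) is shipped for fidelity to the
  sampling description and is checked to track the exact measure in rank.

## Degree-preserving permutation null

The null reassorts symptoms over disorders while preserving every
symptom's membership count and every disorder's symptom count — uniform
sampling of fixed-margin binary matrices by checkerboard swaps (2×2
submatrix exchanges), with at least 10× the membership count of accepted
swaps per draw and an attempt cap for degenerate margins. Rejection
sampling is infeasible at realistic margins; swap chains are the standard
approach. Each permuted incidence is projected and analysed on its own
giant component by default (`restrict="full"` is available). On the
14-symptom MDE/GAD fixture the margins force the structure up to
relabeling, so the permutation ensemble is degenerate at the observed
SWI — a useful end-to-end identity check.

What the null isolates: disorders *re-using* symptom groups keeps the
projection sparse relative to its margins. The synthetic `families`
topology (several disorders per family sharing a core symptom group)
reproduces the qualitative finding — observed SWI above the permuted
ensemble, permuted density above observed. Chain topologies do *not*
show this (their path lengths are artificially long), which is why the
structured-null analyses use the family generator.

## Disorder distances and comorbidity

The distance between disorders A and B is the mean geodesic length over
all ordered symptom pairs (s ∈ A, t ∈ B); a shared symptom contributes
distance-0 self pairs, which is forced by the "randomly chosen symptom
from each" definition. The association with a comorbidity matrix
(tetrachoric correlations when supplied externally) is Pearson's r over
unordered disorder pairs, with a `no-shared-symptoms` subset that removes
the trivially-near bridged pairs, and a Spearman option.

Because the published correlations (−0.72, −0.66) require an external
incidence file and a published tetrachoric table, the shipped analyses
close the loop synthetically: `generate_comorbidity_scenario` simulates a
population on a chain of bridged disorders and uses phi coefficients of
the resulting diagnoses as the comorbidity matrix. Phi, not a tetrachoric
MLE, is deliberate: the pipeline consumes an association matrix and the
proxy keeps the generator free of external estimation machinery. On
these scenarios the distance–comorbidity correlation is reliably below
−0.4 (typically −0.5 to −0.7) and the matrix is a positive manifold
within sampling tolerance (entries below −0.02 count as violations).

## Activation dynamics

Each symptom i is binary and updated synchronously: with A the number of
neighbours active at t−1,

    p = a + (1 − a)·(σ(b_i·A − c_i) − a),   σ the logistic function.

* `a` (global, default 0.22) sets the spontaneous-onset floor a² = 0.0484
  and the activation ceiling a + (1−a)² = 0.8284; equivalently a symptom
  under full support still deactivates with probability a(1−a) = 0.1716
  per day. (A rounded recovery rate of .18 is sometimes quoted for
  a = 0.22; the analytic value 0.1716 rounds to .17 and is what the code
  reports.)
* `b_i ≥ 0` is the sensitivity per active neighbour, `c_i` the threshold.
  The update has no self-term; persistence arises only through neighbour
  feedback.
* The state starts all-off (no burn-in) — the conservative choice for a
  simulated year; day 0 of a panel is the first updated state.
* Per-person randomness is split from the master seed by a counter
  (person index), so `simulate_population` equals stacking
  `simulate_person(seed=[master, p])` bitwise and is schedule-independent.

**Parameter estimation** regresses each symptom's endorsement on the
count of the disorder's *other* endorsed symptoms (self excluded — the
literal total-count predictor is available via `include_self=True` but is
degenerate at the boundary since the outcome is part of the count);
b is the slope, c the negated intercept. Bridge symptoms are fit once per
disorder and averaged. Perfect separation caps parameters at ±10 with a
flag.

## Calibration and the MDE/GAD study conditions

The empirical per-symptom parameters behind the published simulation are
not available, so the package defines its study conditions as: fixed
sensitivities `DEFAULT_SENSITIVITIES`, and thresholds calibrated so each
symptom's marginal daily activation rate hits `DEFAULT_TARGET_RATES`
(joint per-symptom bisection on c, common random numbers across
iterations, rates measured over the second half of an n = 2000, T = 100
run). Rates are targeted at the symptom level — not prevalences —
because that is where the empirical regressions live; disorder-level
epidemiology then *emerges*.

The default regime is deliberately asymmetric:

* GAD core symptoms: high sensitivity (b = 1.32), high marginal rate
  (0.148) — long, chronic activation states that can satisfy a
  most-days-for-six-months criterion.
* Non-core MDE symptoms: moderate sensitivity (b = 1.03) — two-to-four
  week episodes.
* The two designated MDE cores (depressed mood, loss of interest) and the
  four bridges: weak sensitivity (b ≈ 0.8) — the cores gate the MDE
  diagnosis and the bridges gate cross-disorder transmission, and keeping
  both weakly reactive stops every episode from going network-wide.

Under these conditions a 50-replicate, 2000-person, 365-day study yields
MDE prevalence ≈ 0.07 (essentially always inside 0.05–0.15), GAD
prevalence ≈ 0.02, Cronbach's alpha ≈ 0.78, GAD symptoms more active than
MDE symptoms yet GAD diagnoses rarer (the duration-criterion asymmetry),
and an MDE/GAD odds ratio centred near 18–22.

**Known limitation — comorbidity strength.** Empirical yearly MDE/GAD
odds ratios sit around 7–10, and the plausible band used here is 5–15.
With node-level sensitivities and no individual differences, months of
bridge exposure during a GAD illness inevitably raise the chance of an
MDE episode, and extensive exploration of the (b, target-rate) space did
not find a regime holding the odds ratio under 15 while keeping both
prevalences and alpha in range; ≈ 20–40% of original-mode replicates land
fully inside all four bands. The specificity contrast that matters —
jointly-plausible replicates are several times more frequent under the
calibrated assignment than under per-replicate shuffles of the (b, c)
pairs (≈ 16–38% versus ≈ 0–8%) — is robust across seeds, but the margins
are far narrower than an empirically parameterised simulation would give.

**Parameter recovery** uses a separate scenario (`recovery_spec`):
sensitivities spread over 0.4–1.6 with each symptom group spanning the
range (`RECOVERY_SENSITIVITIES`), equal rate targets, estimation on three
well-separated cross-sections (days 75/112/150) of an n = 5000 panel
pooled into one persons × symptoms table. Rank correlation between true
and re-estimated b is then 0.85–0.95. With tied, group-clustered
sensitivities (the default MDE/GAD set) rank recovery is ill-posed and is
not asserted. Exact recovery is not expected anywhere: the estimator's
sum-score predictor mismatches the neighbour-count dynamics by design.

## Diagnosis rules

* MDE-style (`every-day`): some run of ≥ 14 consecutive days, each day
  with ≥ 5 of the 9 symptoms active and ≥ 1 of the designated cores
  active. Symptom identity may vary across days (`fixed_set=True` for the
  stricter same-five reading; `core_whole_window=True` relaxes the
  per-day core check).
* GAD-style (`most-days`): some 182-day window in which each of the three
  cores is active on a strict majority of days, and on a strict majority
  of days a strict majority of the 9 symptoms is active. "Most" is
  operationalised as the exclusive 0.5 threshold at both levels
  (`symptom_majority`, `day_majority` are configurable); cores count
  inside the symptom majority, not in addition to it. Histories shorter
  than the window diagnose false with a warning. Windows lie inside the
  simulated year (no wrap-around).
* Odds ratio: (n11·n00)/(n10·n01) with Haldane 0.5 added to all cells iff
  any cell is zero (logged); degenerate margins flag the estimate
  unstable. Cronbach's alpha is computed on the final-day cross-section.
* Plausibility intervals are closed: MDE prevalence 0.05–0.15, GAD
  0.01–0.05, odds ratio 5–15, alpha 0.6–1; "overall" is their
  conjunction.

## Numerical choices and degenerate inputs

* Transitivity raises (rather than returning 0) on graphs with no
  length-2 path; `summarize` refuses disconnected input and points to
  `giant_component`; unreachable disorder pairs are flagged missing, not
  coded as infinite distances.
* Calibration tolerance is ±0.02 on achieved rates by default; the
  MDE/GAD and recovery calibrations use ±0.03 because near the dynamics'
  first-order transition a marginal rate can jump discontinuously in c,
  and a target may sit inside the gap. Unreachable targets (below the
  floor a²) raise with diagnostics after the iteration budget.
* The simulation refuses panels above a configurable cell cap
  (n_persons × symptoms × days) with an explicit message.
* Checkerboard chains on margins admitting no swap return the input with
  a logged notice (the fixture's forced structure is the canonical case).

## What the synthetic data does and does not show

The generators emulate the *structure* of the study inputs — clique
projections with controlled bridge overlap, family-style symptom-group
re-use, activation parameters with known ground truth, comorbidity that
genuinely arises from simulated dynamics on the graph. They do not
emulate DSM-scale heterogeneity (439 symptoms, 148 disorders, broad
degree distribution), individual differences in parameters, or the
interview structure behind real tetrachoric matrices. Green tests
therefore certify the statistical machinery and the directional,
order-of-magnitude claims — not that the shipped parameter defaults are
empirically calibrated to any population.

Problem sizes in the default test and analysis runs (2000–5000 persons,
50 replicates, 200-replicate graph ensembles) are the package's chosen
scale for routine verification; all drivers expose the counts as flags.
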