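# Methods

## Model

One planning instance covers a single district over `M` construction cycles
(default five three-year cycles) and `N` institution grades (default five,
AAAAA highest to A lowest). The decision matrix `x[i, j]` counts new
institutions of grade `j` built in cycle `i`; counts are integers because an
institution cannot be built fractionally. Both objectives are linear:

* economic benefit `F1 = Σ_ij factor_i b_j x_ij`, with `b_j` ≥ 0 the income
  coefficient (accommodation fees, subsidies, tax effects per institution,
  abstract currency units) and `factor_i ∈ (0, 1]` a per-cycle multiplier;
* social cost `F2 = Σ_ij a_j x_ij`, with `a_j` ≥ 0 the construction-cost
  coefficient (floor-area-based units).

Internally every objective vector is stored in minimisation convention
`(−F1, F2)`; all public accessors undo the sign. Coefficients are constant
across cycles — the coefficient tables print one value per grade — and the
income factor is the only time variation (the smart scenario needs it).

Bed stocks convert from institutions through the bed coefficient `c_j`
(average beds per institution). Two reconciliations coexist deliberately:

* **initial stocks** use `d_0j = count_j · ceil(c_j)`. The published
  per-district stocks are integers that the raw fractional `c_j` cannot
  reproduce; the ceiling reproduces all 55 district×grade entries exactly;
* **constraint arithmetic** uses the raw `c_j`, the most faithful reading of
  the constraint formulas.

### Constraints

All constraints are expressed as slacks; a plan is feasible when the summed
shortfall `Σ max(0, −slack)` is zero (numerically, ≤ 1e−9 to absorb float
noise in sums of products).

*Horizon mode* (baseline): one bed floor at the end of the horizon,
`Σ_j d_0j + Σ_ij c_j x_ij ≥ rate · P_horizon` (default rate 0.06, i.e. 60
beds per 1000 elderly, against the 2.56 M projected elderly population), and
`N` grade-share floors on final stocks,
`beds_k ≥ p_k · total_beds` with `p_k = 0.15` for every grade. The shares
must sum to ≤ 1 or the parameters are rejected at load time.

*Per-cycle mode* (smart scenario): cumulative beds through each cycle must
reach `rate_i · P_ref`, and the share floors are applied to cumulative
stocks at every cycle (`M × N` slacks). As printed, the source constraint
uses a single reference population for all cycles; this is implemented
verbatim, with a per-cycle population vector accepted as a config option
since the printed form is likely a simplification. The packaged fixture
defaults the reference population to the horizon population; no separate
2023 population is published.

### Upper bounds

The search needs finite per-cell bounds; none are prescribed. The default is
`ceil(max additional beds required / c_j)` — the fewest institutions of
grade `j` that could close the largest bed-floor gap single-handedly — so
the all-max plan always has enough room to be feasible and no cap excludes
the policy-relevant region. Bounds are configurable per cell.

## Solver

An elitist non-dominated-sorting GA over integer genomes (the flattened
plan):

* **constraint handling** — constrained domination: feasible plans dominate
  infeasible ones, infeasible plans compare by total violation, feasible
  plans by standard Pareto dominance. Chosen over penalty terms because it
  needs no penalty-weight tuning and makes the feasible front exact.
* **selection** — roulette with fitness `1/rank` (ranks from non-dominated
  sorting). Rank-reciprocal weights are scale-invariant in the objective
  magnitudes, which differ by orders of magnitude across districts.
  Crowding distance is used only to break equal-rank ties in elitist
  truncation, not in the roulette weights.
* **operators** — uniform per-cell crossover (swap probability =
  `crossover_rate`, default 0.5) and mutation that resamples a cell
  uniformly within its bounds (per-cell probability `mutation_rate`,
  default 0.1). Both preserve integrality and bounds by construction; a
  `round_repair` (round-to-nearest with clipping) is provided for any
  real-coded operator a user might configure.
* **truncation** — merge parents and offspring, re-rank, keep the best
  `population_size` by (rank asc, crowding desc, genome lexicographic asc).
  The lexicographic tie-break makes runs bit-reproducible.
* **archive** — the distinct rank-1 genomes, capped at
  `round(pareto_fraction × population_size)` (default 0.8 × 100 = 80) by
  descending crowding distance.
* **termination** — generation cap (default 500) or stagnation: the
  archive's 2-D hypervolume (reference point = component-wise worst of the
  first feasible front) improves by less than `stagnation_tol` (1e−9) over
  `stagnation_window` (50) generations. Hypervolume operationalises "the
  fitness no longer trends upward" with a single scalar that is monotone
  under elitism.

All randomness flows through one `numpy.random.Generator` seeded from
`GAConfig.seed`; identical (problem, config, seed) triples give identical
archives. If no feasible plan is ever found the archive is returned with
every `feasible` flag False and the CLI exits with code 3.

## Plan selection (TOPSIS)

The archive's objective matrix (minimisation convention, so both columns are
cost-type and the ideal is the column-wise minimum) is vector-normalised,
weighted (default 0.5/0.5; weights must be positive and are renormalised to
sum to 1), and each row scored by relative closeness
`R = d⁻ / (d⁺ + d⁻)` to the ideal/anti-ideal points under Euclidean
distance. The arg-max of `R` is selected, ties to the lowest index. A
degenerate archive of identical rows gets `R = 0.5` everywhere and the
first member is selected. Only Euclidean distance is implemented: archive
members are fixed and independent, so neither rank reversal nor
inter-criterion correlation corrections apply. Because the columns are
already converted to cost-type, no benefit/cost flag is needed for the
standard pipeline, though the decision matrix may be assembled manually via
`rank_solutions` for other conventions.

## Smart-community scenario

`build_smart_problem` derives the variant from a baseline problem: income
factors 1 before the switch cycle (default 3, i.e. a 2+3 split of five
cycles) and `income_factor` (default 0.5) from it onward, per-cycle
bed-rate targets from a `RateSchedule` (base rate plus non-negative
per-cycle increments; base 45 with increments 3/3/4/4/4 gives
48/51/55/59/63 per 1000), and cumulative-stock share floors. The halving is
applied to the income coefficients `b_j` in the objective — not to the cost
coefficients — matching the modified objective formula. For any
non-negative plan, smart `F1` ≤ baseline `F1`, with equality iff nothing
with positive income is built at or after the switch or the factor is 1.

## Synthetic instances and the oracle

`generate_problem` draws horizon-mode instances whose structure mirrors the
real parameterization: strictly grade-decreasing `a`, `b`, `c` (so
benefit/cost ratios differ across grades and the front does not collapse),
non-negative integer initial stocks, small per-cell bounds, and a bed-floor
requirement drawn as a fraction (0.3–0.9) of the all-max plan's bed total.
Instances are rejection-sampled until the all-max plan is feasible, so the
solver and the oracle always have a non-empty target. The generator does
not attempt realistic demography — populations are scalar knobs — so
passing tests demonstrate algorithmic correctness on problems of the right
shape, not calibration to any real city.

`brute_force_pareto` enumerates every integer plan in bounds (capped at
10⁶ candidates), filters by feasibility, and returns the exact
non-dominated set via a sweep over lexicographically sorted objective
pairs. It shares only the objective/constraint evaluator with the solver,
never the search, so it serves as an independent oracle: on random
instances with ≤ 625 candidate plans, every solver archive must be a subset
of the enumerated Pareto set and 10 seeds together must cover ≥ 90% of the
true front. Coverage is measured on distinct objective pairs: in horizon
mode the objectives depend on the plan only through per-grade column sums,
so many plans share one front point and genome-level coverage would be
ill-posed.

## Problem sizes and defaults used in checks

The packaged checks run the solver at population 100 for 100 generations on
the Xuanwu district (archive sizing), and at population 30 for up to 200
generations on 2-grade × 2-cycle synthetic instances (oracle containment);
both finish in seconds and the stagnation rule usually stops the small runs
early. Larger populations and the full 500-generation default change the
archives' density, not the contracts checked.

## Known limitations

* Coefficients are cycle-constant; genuinely time-varying costs would need
  per-cycle coefficient tables.
* No geography: the model allocates counts per grade and cycle, not
  locations, and assumes no cross-district flow of residents.
* The bi-objective formulation is fixed at two objectives; the archive and
  hypervolume code assume exactly two.
* Population projections are inputs, never estimated.
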