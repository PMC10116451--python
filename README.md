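# bedplan

Capacity planning for graded elder-care institutions. Given a district's
existing stock of institutions in five quality grades (AAAAA down to A),
per-grade cost/income/bed coefficients, and beds-per-1000-elderly policy
targets, `bedplan` decides **how many institutions of each grade to build in
each multi-year construction cycle**. It is written for health-services
operations researchers and planners who need reproducible, constraint-aware
construction schedules rather than a single-objective cost optimum.

## The model

The decision variable is a non-negative integer matrix `x[i, j]`
(cycle `i = 1..M`, grade `j = 1..N`). Two linear objectives compete:

```
F1 = Σ_i Σ_j factor_i · b_j · x_ij    (economic benefit, maximised)
F2 = Σ_i Σ_j a_j · x_ij               (social cost, minimised)
```

with `b_j` the per-institution income coefficient, `a_j` the construction
cost coefficient, and `factor_i` a per-cycle income multiplier (all 1 in the
baseline). Constraints (as slacks that must be ≥ 0):

* **bed floor** — total beds (initial stock `d_0j` plus `c_j · x_ij`, where
  `c_j` is beds per institution) must reach `rate · P`, the policy
  beds-per-capita target times the projected elderly population;
* **grade shares** — every grade must hold at least a fraction `p_j` of all
  beds (default 15% each, i.e. 75% of beds committed across five grades), so
  each disposable-income group finds capacity at its price level.

Because the genuine optimum is a trade-off set, the solver is an elitist
non-dominated-sorting genetic algorithm on the integer-coded plans
(constrained domination, roulette selection on rank-reciprocal fitness,
uniform crossover, in-bounds resampling mutation), returning a Pareto
archive of up to `pareto_fraction × population_size` plans. A TOPSIS step
(distance to ideal, default weights 0.5/0.5 on `−F1` and `F2`) then selects
one plan from the archive.

The **smart-community scenario** halves the income coefficients from cycle 3
(robotic services substitute for staff) and replaces the single horizon bed
floor by escalating per-cycle targets, e.g. 48/51/55/59/63 beds per 1000.

The packaged `nanjing/<District>` fixtures carry the 2019 census of graded
institutions in the 11 districts of Nanjing, the per-grade coefficients, the
2.56-million elderly-population projection for 2035, and both cycle-target
schedules.

## Worked example

```python
from bedplan.io import load_problem
from bedplan.nsga import GAConfig, run
from bedplan.topsis import decide

problem = load_problem("nanjing/Xuanwu")
archive = run(problem, GAConfig(population_size=100, generations=100,
                                pareto_fraction=0.8, seed=1))
plan, result = decide(archive, (0.5, 0.5))
print(len(archive))                  # 80
print(result.selected)               # 36
print(result.closeness[result.selected])   # 0.5441...
```

The archive holds 80 mutually non-dominated feasible plans, spanning
economic benefit `F1` from 2.38e7 to 6.63e7 and social cost `F2` from
2.27e7 to 6.41e7 (abstract currency/area units). TOPSIS picks the plan
closest to the ideal corner — here index 36, closeness 0.544, with
`F1 = 4.15e7` and `F2 = 3.67e7`. `plan` is the 5×5 cycle-by-grade build
matrix; the heavy A-grade column reflects that low-cost institutions close
the bed gap most cheaply while the share floors keep every grade stocked.

The same workflow is available from a shell:

```sh
bedplan solve --config nanjing/Xuanwu --seed 1 --out runs/xuanwu
bedplan decide --config nanjing/Xuanwu --archive runs/xuanwu/archive.csv --out runs/xuanwu
bedplan scenario --config nanjing/Xuanwu --seed 1 --out runs/xuanwu-smart
bedplan synth --seed 0 --out synthetic.yaml && bedplan oracle --config synthetic.yaml --out runs/oracle
```

Archives are CSV (one flattened plan per row plus `F1`, `F2`), decisions are
JSON with every TOPSIS intermediate, and each output directory carries a
manifest (config digest, seed, version) for reproducibility. Exit codes:
0 success, 2 config error, 3 infeasible/empty.

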