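# Methods

## Model

The network is directed and unweighted over a fixed pool of N countries
(default 244); an edge (i, j) means *i imports from j*.  Self-loops are
excluded, reciprocal trade is two edges, and edges are never deleted by the
growth process itself — deletion happens only through shocks and through
Maslov–Sneppen swaps (which conserve every degree).  Growth is
edge-by-edge: a candidate ordered pair is drawn uniformly from the pool
and accepted with

    P_t = (α·x_i·x_j + ε) / (1 + β·x_i·x_j),    x_i = l_i / m,

where l_i is country i's total degree and m the current edge count.  The
fitness of every country is therefore re-read after each accepted edge.
On the empty network all fitnesses are defined as 0, so the first edges
enter with probability exactly ε.  A draw that proposes an existing edge, a
banned exporter, or a self-pair is a failed event; failed events leave the
state untouched.  This rejection-sampling event flow is one admissible
realisation of the formation process; it keeps the acceptance rule an exact
per-pair probability and admits a brute-force enumeration oracle on small
pools (the distribution of the first added edge equals P_t renormalised
over admissible pairs, which the test suite verifies by chi-square at 10^5
draws).

After each added edge the network is rewired: two distinct directed edges
(a←b), (c←d) are drawn uniformly and their exporters swapped to (a←d),
(c←b) unless that would create a self-loop or duplicate.  Accepted or not,
each draw counts against the attempt budget R(m) = C·e^(−λm), realised per
added edge by stochastic rounding (floor plus a Bernoulli on the fractional
part) so the expected budget continues to decay smoothly below one.

Calendar years are pure cumulative-edge checkpoints E(year); metrics are
recorded when m reaches E(year).  Growth schedules are linear interpolants
by default (an exponential form is available for empirical fits), with
integer, nondecreasing targets.

### Parameters

| parameter | meaning | units | default |
|---|---|---|---|
| α | scales the fitness-driven connection probability | — | 1.5 |
| β | damps the fitness dependence (saturation) | — | 1.0 |
| ε | baseline probability for zero-fitness pairs | — | 0.01 |
| C | rewiring attempts at m = 0 | attempts | 60 |
| λ | rewiring decay rate | per edge | 0.02 |

Validity requires (α·z + ε)/(1 + β·z) ∈ [0, 1] on z ∈ [0, 1]; since the
expression is a ratio of linear functions of z, checking the endpoints
(ε ≤ 1 and (α + ε)/(1 + β) ≤ 1) suffices, and construction fails otherwise.
The defaults above are the package's reference set: α near its validity
ceiling for β = 1 (strongly PA-driven), ε small enough that fitness matters
but large enough that the pool activates over a 26-year horizon, and a
rewiring budget that is strong below ~100 edges and negligible past ~400.

## Metric suite

All metrics are computed on the active subnetwork (total degree ≥ 1);
isolated pool members are ignored except in the pool size itself.
Degenerate inputs raise a typed `UndefinedMetricError`, which the tabulator
records as NaN — never as a silent zero.

* **assortativity** — Pearson correlation of total degrees over edge
  endpoint pairs, symmetrized (each edge contributes both orientations);
  undefined when degree variance is zero.
* **average path length** — mean directed shortest-path length over ordered
  pairs at finite distance; unreachable pairs are dropped, not imputed,
  the only convention that stays finite on fragmented young networks.
* **average clustering** — mean local clustering on the undirected
  projection over nodes with projected degree ≥ 2 (the igraph-style
  default).
* **giant components** — sizes of the largest strongly and weakly connected
  components (lower/upper bounds on the reach of a shock starting inside
  them).
* **density** — m / (n_active·(n_active − 1)).  The active-node denominator
  was chosen over the 244-pool denominator because only it produces
  empirical-scale density values; both readings are isolated in one
  function.
* **symmetry** — Pearson correlation of (in-degree, out-degree) over active
  nodes.
* **heterogeneity** — coefficient of variation (population SD / mean) of
  the in- and out-degree distributions; the population SD makes the CV
  exactly invariant under disjoint network duplication.  Symmetry and
  heterogeneity admit several formulations in the resilience literature;
  the simplest ones are used here and are deliberately keyed through
  single replaceable functions.
* **degree-distribution shape** — gated to networks with more than 100
  active nodes, below which the KS machinery is unreliable.  The power-law
  check is a Clauset-style fit (continuous-approximation MLE with
  KS-minimizing xmin and a semi-parametric bootstrap p-value).  The
  exponential check fixes the decay rate to 1/⟨k⟩.  Because degrees are
  integers with support k ≥ 1, a continuous-exponential KS test would
  reject any sample (it puts mass below 1), so the null is the discrete
  exponential P(K=k) ∝ e^(−k/⟨k⟩) — a geometric law — and the p-value
  comes from a parametric Monte Carlo that re-estimates the rate inside
  every replicate, which keeps the test correctly sized under parameter
  estimation.

## Calibration

A grid sweep over (α, β, ε, C, λ).  For each set, an ensemble (default 25
replicates, matching the replication used throughout the shock analyses)
is grown without shocks; per-year means of n_nodes, reciprocity and
assortativity are compared against the target series by mean squared error
over the calibration window (default 1986–2011).  Years where either side
is NaN (a metric undefined on a degenerate early network) are dropped
pairwise.  Each metric's MSE column is normalized by its maximum across
the grid (min-max and z-score variants available), the three normalized
columns are summed, and sets are ranked ascending with a stable tie-break
by grid order; the top 100 are selected by default.  An
assortativity-only fitting mode is available.  Replicate r of set s draws
from the derived stream SeedSequence(seed, spawn_key=(s, r)), so ensembles
are reproducible and independent across the grid; pseudo-empirical target
generation uses a reserved spawn key so it never shares streams with a
sweep run at the same root seed.

Parameter recovery is checked end to end by
`parameter_recovery_experiment`: a known set is embedded in a coarse
3×3×3×2×2 grid and calibrated against 5-replicate pseudo-empirical
trajectories generated under it, with a 25-replicate sweep (a 5-replicate
sweep is Monte-Carlo-noise dominated).  The experiment runs on a
40-country pool growing to 300 edges — the scale at which the parameters
are actually identifiable.  On a sparse 244-country pool with desk-scale
ε, the baseline acceptance mass ε·N² (~600·ε·10²) dwarfs the
preferential-attachment mass ≈ 4α, the process degenerates to uniform
random growth, and no grid axis is statistically distinguishable; at
N = 40 the two masses are comparable and α, β, ε and the rewiring
schedule all leave measurable fingerprints on the fit metrics.  Because
the target's 5-replicate noise still produces occasional unlucky
realizations, the recovery check reports the median truth rank over three
repetitions of the whole experiment; the median lands in the top decile.

## Shocks

A shock makes k countries cease exporting: their out-edges are removed
once, at the start of the shock year, and an export ban blocks new
out-edges for the duration (years y … y+d−1).  Imports are unaffected, and
removed edges are never restored — recovery happens only through continued
growth, which proceeds during the shock for non-banned exporters.  Errors
draw targets uniformly from countries with at least one export link (a ban
on a non-exporter would be a no-op; widening to all active nodes is a
config switch).  Attacks target the top-k by total degree (default) or
out-degree, ranked once for simultaneous attacks (ties broken uniformly at
random) or re-ranked after each removal for sequential attacks.  Severity
defaults are low = 3 / high = 15 countries; durations short = 1 / long = 5
years; repeated shocks keep a 2-year gap between the end of one ban and
the next start.

Shock impact is accounted two ways: `shock_delta` is the raw difference
between the metric record at the end of the shock year and the end of the
preceding year, reported only at shock years; `paired_adjusted_delta`
additionally subtracts the paired unshocked arm's same-year delta, netting
out ordinary temporal evolution.  Shock experiments run one shocked and
one unshocked arm per parameter set with identical random streams, so arms
are bit-identical until the first shock perturbs the state.

## Synthetic data

The trade-table generator drives each ordered country pair as a two-state
(dormant/active) Markov chain — initiation probability 0.005/year,
persistence 0.85 — with log-normal annual volumes (location 9, scale 2, in
tonnes).  These defaults produce the features the continuous-network
extraction must handle: sustained multi-year runs, gapped histories, late
entrants, and heavy-tailed volumes.  The generator does *not* emulate
gravity-like volume structure, geographic correlation, mirror-reporting
discrepancies, or common global shocks; passing tests therefore validate
the extraction and calibration machinery, not the realism of any
particular trade history.  The pseudo-empirical generator runs the growth
model itself under known parameters and emits replicate-mean fit metrics
tagged with the truth, enabling end-to-end parameter-recovery checks.

## Continuous-network extraction

A directed pair enters the continuous network once it has traded with
positive quantity in ≥ 3 consecutive years.  The entry year is the run's
completion year by default (`run_end`); back-filling to the run's first
year (`run_start`) is available, as both readings are defensible.  Once
entered, an edge persists in all later snapshots by default, mirroring the
model's no-deletion growth; `persist=False` gives sliding-window
membership for sensitivity analysis.  Extraction is invariant to row order
and to volume rescaling.  Growth schedules are fitted to the yearly edge
counts by OLS (linear default, exponential optional) and extrapolated to a
horizon (default 2050) with integer, nondecreasing targets.

## Study conditions (desk scale)

Simulation experiments in the test suite and acceptance script use: pool
244; linear schedule from 15 edges in 1986 to 400 edges in 2011 (the scale
of the observed 2013 continuous wheat network, 363 partnerships among 108
countries), extended at the same rate (to 2020–2025) for shock runs;
25-replicate ensembles for trajectory and calibration summaries; 40–50
paired runs for shock ensembles; shocks of low severity and short duration
starting in 2013, with repeats in 2016 and 2019.

## Numerical choices and degenerate inputs

* All randomness flows through numpy Generators; every experiment derives
  sub-streams from one root seed via SeedSequence spawn keys.
* Candidate draws in the growth loop are batched (the state is unchanged
  between failed attempts, so a batch against the frozen fitness vector is
  distributionally identical to sequential attempts).
* `grow_one_edge` stalls with a diagnostic error after 10^6 attempts
  (e.g. ε = 0 on an empty network, or a saturated/banned pool).
* MSE normalization of an all-zero column contributes 0 for every set;
  ranking ties break stably by grid order; attack-ranking ties break
  uniformly at random.
* Metric NaNs propagate to tidy outputs as empty cells, never zeros.

## Known limitations

* The event flow is a minimal rejection-sampling realisation; other flows
  (multiple draws per step, time-consuming failures) would change the time
  axis but not the acceptance rule.
* With the default ε, nearly the whole 244-country pool activates by the
  end of a 26-year run — faster participation growth than the observed
  continuous network (~108 countries by 2013).  Concentrating activity
  onto ~100 countries under uniform pair proposal requires ε ~ 10⁻⁵, which
  makes the ε-driven bootstrap phase computationally impractical; fits
  that weight the node-count trajectory heavily should bear this in mind.
* In repeated low/short attack ensembles, most metric responses dampen
  with each successive attack.  The giant strong component behaves
  differently, but its behaviour is accounting-sensitive at desk scale:
  the *immediate* pre/post-removal GSC drop consistently shrinks across
  attacks (each later attack hits a more redundant component), while the
  year-end shock-attributable GSC decrease — which folds in within-year
  regrowth — tends to grow with successive attacks but is noisy, and its
  strict ordering can break in individual 50-run ensembles.
* Trade volumes are unweighted throughout; no volume redistribution after
  shocks, no multi-commodity coupling, no GDP-driven (hidden-variable)
  fitness.
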