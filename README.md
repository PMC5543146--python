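# wheattrade

A dynamic preferential-attachment (PA) model of the global wheat trade
network, for researchers studying the resilience of agri-food trade systems.
The package grows a directed, unweighted trade network over a fixed world
pool of countries, calibrates the growth parameters against empirical
metric trajectories, and subjects the growing network to configurable
shocks — random *errors* and targeted *attacks* in which countries cease
exporting — so that multi-decade what-if experiments (e.g. 1986–2050) can
be run and interrogated.

## The model

The network state is an N×N adjacency matrix A (N = 244 countries by
default) with A(i, j) = 1 when country *i* imports from country *j*;
reciprocal trade is two distinct edges and self-loops are excluded.  With
*m* directed edges present, country *i*'s trade fitness is the fraction of
all partnerships it participates in,

    x_i(m) = l_i(m) / m,

where l_i(m) is its total degree.  A candidate ordered pair (i, j), drawn
uniformly, becomes an edge with probability

    P_t(x_i, x_j) = (α·x_i·x_j + ε) / (1 + β·x_i·x_j),

so well-connected countries attract partners ("rich get richer"), while the
small baseline ε lets countries with no trade enter the network.  After
each added edge the network undergoes Maslov–Sneppen degree-preserving
rewiring, whose attempt budget decays exponentially with network size,

    R(m) = C·e^(−λm),

so random partnership reassignment dominates the young network and
preferential attachment dominates the mature one.  Calendar years are
cumulative-edge checkpoints E(year), fitted to (or extrapolated from)
annual edge counts of the empirical *continuous* wheat trade network — the
backbone-like subnetwork of trade links sustained for at least 3
consecutive years.

Calibration is a grid sweep: per parameter set, an ensemble of networks is
grown, per-year means of active-node count, reciprocity and degree
assortativity are compared with the target trajectories by mean squared
error, MSE columns are normalized across the grid and summed, and the
lowest combined scores win.  The shock engine removes the outgoing edges of
selected countries (randomly for errors; by total- or out-degree centrality
for attacks, simultaneous or sequential) and bans them from exporting for
the shock's duration, while growth continues.

## Worked example

```python
import wheattrade as wt

pool = wt.CountryPool.default(244)
result = wt.run_growth(pool, wt.REFERENCE_PARAMS,
                       wt.reference_schedule(), seed=1)
cols = ["year", "n_nodes", "m", "reciprocity", "assortativity",
        "apl", "acc", "gsc_size", "gwc_size", "density"]
print(result.series[cols].tail(3).round(4).to_string(index=False))
```

prints

```
 year  n_nodes     m  reciprocity  assortativity    apl    acc  gsc_size  gwc_size  density
 2009    232.0 369.0       0.0108         0.0375 8.8349 0.0039      67.0     230.0   0.0069
 2010    235.0 385.0       0.0104         0.0215 8.7765 0.0035      75.0     233.0   0.0070
 2011    237.0 400.0       0.0100         0.0286 9.4761 0.0044      94.0     235.0   0.0072
```

By 2011 the simulated network has reached its 400-edge target with 237 of
the 244 countries trading; reciprocity is low (1% of partnerships are
two-way), the giant weak component spans nearly every active country while
the giant strong component (94 countries) is still consolidating, and
density remains below 1% of the possible directed links.  Single runs are
noisy; ensemble means with ±2 SD envelopes come from
`wheattrade.summarize_replicates` or the CLI:

```
wheattrade simulate --out runs/demo --seed 1 --n-rep 25
wheattrade shock --out runs/shock --seed 1 --preset attack-low-short-2017
wheattrade extract --input trades.csv --out runs/empirical
```

Shock presets follow the severity/duration taxonomy: low (3 countries) or
high (15) severity, short (1 year) or long (5) duration, with a 2-year gap
between repeated shocks.

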