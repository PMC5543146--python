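"""Synthetic fixtures: FAO-like bilateral trade tables and pseudo-empirical
calibration targets.

The table generator emulates the structural features the continuous-network
extraction relies on — persistent multi-year partnerships, heavy-tailed
annual volumes, and growing participation — with the minimal mechanism that
produces them: each ordered country pair is a two-state (dormant/active)
Markov chain with a per-year initiation probability and a persistence
probability, and active pairs draw log-normal volumes.

The pseudo-empirical generator runs the growth model itself under a known
parameter set and emits its replicate-mean calibration metrics, tagged with
the true parameters, so parameter-recovery experiments can verify the
calibration machinery end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import simulate_replicates
from .growth import GrowthParams, GrowthSchedule
from .network import CountryPool

__all__ = ["SyntheticTableSpec", "generate_trade_table",
           "PseudoEmpiricalSpec", "generate_pseudo_empirical",
           "parameter_recovery_experiment"]


@dataclass(frozen=True)
class SyntheticTableSpec:
    """Two-state Markov partnership dynamics with log-normal volumes.

    Defaults emulate a moderately sticky trade system: ~0.5% of dormant
    ordered pairs start trading each year and 85% of active pairs trade
    again the next year, giving a realistic mix of sustained partnerships
    (runs of 3+ years) and transient ones.  Volumes are log-normal
    (location 9 ≈ 8 kt median, scale 2 → heavy tail), in tonnes.
    """

    n_countries: int = 40
    start_year: int = 1986
    end_year: int = 2013
    initiation_rate: float = 0.005
    persistence: float = 0.85
    volume_location: float = 9.0
    volume_scale: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries < 2:
            raise ValueError("need at least 2 countries")
        for name in ("initiation_rate", "persistence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.end_year < self.start_year:
            raise ValueError("end_year before start_year")


def generate_trade_table(spec: SyntheticTableSpec) -> pd.DataFrame:
    """Simulate the annual bilateral table (reporter imports from partner).

    Deterministic under the spec's seed: the same spec always yields a
    byte-identical table.
    """
    rng = np.random.default_rng(spec.seed)
    pool = CountryPool.default(spec.n_countries)
    n = spec.n_countries
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    active = np.zeros(len(pairs), dtype=bool)
    records = []
    for year in range(spec.start_year, spec.end_year + 1):
        u = rng.random(len(pairs))
        stay = active & (u < spec.persistence)
        start = ~active & (u < spec.initiation_rate)
        active = stay | start
        idx = np.nonzero(active)[0]
        volumes = rng.lognormal(spec.volume_location, spec.volume_scale,
                                size=idx.size)
        for k, vol in zip(idx, volumes):
            i, j = pairs[k]
            records.append((pool.labels[i], pool.labels[j], year,
                            round(float(vol), 3)))
    return pd.DataFrame(records,
                        columns=["reporter", "partner", "year", "quantity"])


@dataclass(frozen=True)
class PseudoEmpiricalSpec:
    """Known-truth calibration target: replicate-mean fit metrics generated
    under ``true_params``."""

    true_params: GrowthParams
    schedule: GrowthSchedule
    n_rep: int = 5
    pool_size: int = 244
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rep < 1:
            raise ValueError("n_rep must be at least 1")


def generate_pseudo_empirical(
        spec: PseudoEmpiricalSpec) -> tuple[pd.DataFrame, dict]:
    """Return (target series indexed by year, provenance dict).

    The provenance dict records the true parameters, replication and seed so
    recovery experiments can round-trip them through report files.
    """
    pool = CountryPool.default(spec.pool_size)
    # reserved set_index keeps the target's random streams disjoint from any
    # grid sweep run with the same root seed
    series = simulate_replicates(spec.true_params, spec.schedule, pool,
                                 spec.n_rep, seed=spec.seed,
                                 set_index=1_000_000, record="fit")
    provenance = {"true_params": spec.true_params.as_dict(),
                  "n_rep": spec.n_rep, "seed": spec.seed,
                  "pool_size": spec.pool_size,
                  "years": [int(y) for y in spec.schedule.years]}
    return series, provenance


def parameter_recovery_experiment(seed: int = 0, n_rep_target: int = 5,
                                  n_rep_sweep: int = 25):
    """End-to-end check that grid-sweep calibration can recover known
    parameters.

    The experiment runs at a scale where the growth parameters are actually
    identifiable: a 40-country pool growing to 300 edges, where the
    baseline mass ``epsilon * N^2`` and the preferential-attachment mass
    are comparable, so alpha, beta, epsilon and the rewiring schedule all
    leave measurable fingerprints on the fit metrics.  (On a sparse
    244-country pool with desk-scale epsilon, the baseline term dominates
    every acceptance and the model degenerates to uniform random growth,
    leaving the grid statistically indistinguishable.)

    A known parameter set is embedded in a coarse 3x3x3x2x2 grid,
    pseudo-empirical targets are generated under it, and the grid is swept.
    Returns ``(rank of the truth, number of sets, calibration table)``.
    """
    from .calibration import calibrate

    truth = GrowthParams(alpha=1.5, beta=1.0, epsilon=0.005,
                         C=60.0, lam=0.02)
    pool = CountryPool.default(40)
    schedule = GrowthSchedule.linear(1986, 2011, 5, 300)
    target, _ = generate_pseudo_empirical(PseudoEmpiricalSpec(
        truth, schedule, n_rep=n_rep_target, pool_size=pool.size,
        seed=seed))
    from .calibration import ParameterGrid

    grid = ParameterGrid(alphas=(0.5, 1.5, 1.9), betas=(1.0, 3.0, 8.0),
                         epsilons=(0.0015, 0.005, 0.02),
                         Cs=(15.0, 60.0), lams=(0.02, 0.1))
    sets = grid.sets()
    result = calibrate(sets, target, schedule, pool, n_rep=n_rep_sweep,
                       seed=seed + 1, top_k=max(1, len(sets) // 10))
    rank = int(result.table.loc[[p == truth for p in sets], "rank"].iloc[0])
    return rank, len(sets), result.table
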