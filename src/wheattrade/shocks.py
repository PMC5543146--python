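"""Shock injection: export errors and attacks of configurable severity,
duration, targeting and repetition.

A shock makes a set of countries cease exporting: their outgoing (export)
edges are removed once, at the start of the shock year, and an export ban
prevents them from forming new out-edges for the shock's duration.  Imports
are unaffected — countries impose export restrictions while continuing to
import.  Removed edges are never restored; recovery happens only through
subsequent network growth.

*Errors* hit randomly selected exporters; *attacks* hit the most-connected
countries (by total- or out-degree centrality), either simultaneously
(centrality ranked once) or sequentially (re-ranked after each removal).
Default severities are low = 3 or high = 15 countries; default durations
short = 1 or long = 5 years; repeated shocks keep a 2-year gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .network import TradeNetwork

__all__ = [
    "LOW_SEVERITY", "HIGH_SEVERITY", "SHORT_DURATION", "LONG_DURATION",
    "ShockSpec", "ShockSchedule", "BanRegistry",
    "select_targets_error", "select_targets_attack",
    "apply_export_ban", "execute_shock", "shock_delta",
    "paired_adjusted_delta",
    "run_shock_experiment", "ShockExperimentResult",
]

LOW_SEVERITY = 3
HIGH_SEVERITY = 15
SHORT_DURATION = 1
LONG_DURATION = 5
DEFAULT_GAP_YEARS = 2


@dataclass(frozen=True)
class ShockSpec:
    """One shock: type, targeting, mode, severity (countries), duration
    (years) and start year."""

    shock_type: str               # "error" | "attack"
    severity: int
    duration: int
    start_year: int
    targeting: str = "total_degree"   # attacks: "total_degree" | "out_degree"
    mode: str = "simultaneous"        # attacks: "simultaneous" | "sequential"

    def __post_init__(self) -> None:
        if self.shock_type not in ("error", "attack"):
            raise ConfigError(f"unknown shock type {self.shock_type!r}")
        if self.targeting not in ("total_degree", "out_degree"):
            raise ConfigError(f"unknown targeting {self.targeting!r}")
        if self.mode not in ("simultaneous", "sequential"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.severity < 1:
            raise ConfigError("severity must be a positive country count")
        if self.duration < 1:
            raise ConfigError("duration must be a positive year count")

    @property
    def end_year(self) -> int:
        """First year after the ban lapses."""
        return self.start_year + self.duration


@dataclass(frozen=True)
class ShockSchedule:
    """Ordered shocks with a minimum gap (calendar years between the end of
    one ban and the start of the next)."""

    shocks: tuple[ShockSpec, ...]
    gap_years: int = DEFAULT_GAP_YEARS

    def __post_init__(self) -> None:
        ordered = sorted(self.shocks, key=lambda s: s.start_year)
        for a, b in zip(ordered, ordered[1:]):
            if b.start_year < a.end_year + self.gap_years:
                raise ConfigError(
                    f"shocks at {a.start_year} (duration {a.duration}) and "
                    f"{b.start_year} violate the {self.gap_years}-year gap")
        object.__setattr__(self, "shocks", tuple(ordered))

    def __iter__(self):
        return iter(self.shocks)

    def __len__(self) -> int:
        return len(self.shocks)

    @property
    def start_years(self) -> tuple[int, ...]:
        return tuple(s.start_year for s in self.shocks)


class BanRegistry:
    """Mapping country -> ban-expiry year.  A country banned in year y for
    duration d cannot export in years y .. y+d-1."""

    def __init__(self) -> None:
        self._expiry: dict[int, int] = {}

    def ban(self, country: int, until_year: int) -> None:
        current = self._expiry.get(country, until_year)
        self._expiry[country] = max(current, until_year)

    def active(self, year: int) -> frozenset:
        return frozenset(c for c, e in self._expiry.items() if e > year)

    def expire(self, year: int) -> None:
        self._expiry = {c: e for c, e in self._expiry.items() if e > year}

    def __contains__(self, country: int) -> bool:
        return country in self._expiry

    def as_dict(self) -> dict[int, int]:
        return dict(self._expiry)


# -- target selection ------------------------------------------------------


def select_targets_error(net: TradeNetwork, k: int,
                         rng: np.random.Generator,
                         eligible: str = "exporters") -> list[int]:
    """k distinct countries drawn uniformly for a random error.

    Eligibility defaults to countries with at least one export link (a ban
    on a non-exporter would be a no-op); ``eligible="active"`` widens the
    draw to all active nodes.
    """
    if eligible == "exporters":
        candidates = np.nonzero(net.out_degree > 0)[0]
    elif eligible == "active":
        candidates = np.nonzero(net.total_degree > 0)[0]
    else:
        raise ConfigError(f"unknown eligibility {eligible!r}")
    if candidates.size < k:
        raise ConfigError(
            f"only {candidates.size} eligible countries for an error of "
            f"severity {k}")
    return [int(c) for c in rng.choice(candidates, size=k, replace=False)]


def _ranked(net: TradeNetwork, targeting: str,
            rng: np.random.Generator) -> list[int]:
    active = np.asarray(sorted(net.active_nodes()))
    cent = (net.total_degree if targeting == "total_degree"
            else net.out_degree)[active]
    tiebreak = rng.random(active.size)
    order = np.lexsort((tiebreak, -cent))
    return [int(a) for a in active[order]]


def select_targets_attack(net: TradeNetwork, k: int, targeting: str,
                          mode: str, rng: np.random.Generator) -> list[int]:
    """Top-k most-connected countries for an attack.

    Simultaneous: centrality ranked once (not recalculated between
    removals), ties broken uniformly at random.  Sequential: after each
    pick the target's out-edges are removed from a scratch copy and the
    ranking recomputed, since one country's loss of exports shifts the
    centrality of the others.
    """
    if len(net.active_nodes()) < k:
        raise ConfigError(
            f"only {len(net.active_nodes())} active countries for an attack "
            f"of severity {k}")
    if mode == "simultaneous":
        return _ranked(net, targeting, rng)[:k]
    work = net.copy()
    targets: list[int] = []
    for _ in range(k):
        pool = [c for c in _ranked(work, targeting, rng)
                if c not in targets]
        if not pool:
            raise ConfigError("ran out of active countries mid-attack")
        choice = pool[0]
        targets.append(choice)
        for importer in work.successors(choice):
            work.remove_edge(importer, choice)
    return targets


def apply_export_ban(net: TradeNetwork, targets: Sequence[int],
                     duration: int, year: int,
                     registry: BanRegistry) -> int:
    """Remove every target's out-edges and register the ban.

    Returns the number of edges removed.  Imports of the targets are left
    intact; removed edges are not restored when the ban lifts.
    """
    if not targets:
        raise ConfigError("shock must target at least one country")
    removed = 0
    for t in targets:
        for importer in net.successors(t):
            net.remove_edge(importer, t)
            removed += 1
        registry.ban(t, until_year=year + duration)
    return removed


def execute_shock(net: TradeNetwork, spec: ShockSpec, year: int,
                  registry: BanRegistry,
                  rng: np.random.Generator) -> dict:
    """Select targets per the spec, apply the ban, and return an event log."""
    from .metrics import giant_components

    if spec.shock_type == "error":
        targets = select_targets_error(net, spec.severity, rng)
    else:
        targets = select_targets_attack(net, spec.severity, spec.targeting,
                                        spec.mode, rng)
    gsc_before, gwc_before = giant_components(net)
    removed = apply_export_ban(net, targets, spec.duration, year, registry)
    gsc_after, gwc_after = giant_components(net)
    return {"year": year, "shock_type": spec.shock_type,
            "targets": targets, "edges_removed": removed,
            "duration": spec.duration,
            "gsc_before": gsc_before, "gsc_after": gsc_after,
            "gwc_before": gwc_before, "gwc_after": gwc_after}


# -- shock accounting ------------------------------------------------------


def shock_delta(series: pd.DataFrame,
                shock_years: Iterable[int]) -> pd.DataFrame:
    """Per-metric change at each shock year: record at the end of the shock
    year minus the record at the end of the preceding year.  Changes caused
    by ordinary growth in unshocked years are not reported."""
    indexed = series.set_index("year")
    rows = {}
    for y in shock_years:
        if y not in indexed.index or (y - 1) not in indexed.index:
            raise ConfigError(
                f"series must cover shock year {y} and the year before")
        rows[y] = indexed.loc[y] - indexed.loc[y - 1]
    out = pd.DataFrame(rows).T
    out.index.name = "year"
    return out


def paired_adjusted_delta(shocked: pd.DataFrame, unshocked: pd.DataFrame,
                          shock_years: Iterable[int]) -> pd.DataFrame:
    """Shock-attributable per-metric change: the shocked arm's year-over-year
    delta minus the paired unshocked arm's, so changes caused by ordinary
    temporal evolution are netted out."""
    shock_years = list(shock_years)
    return shock_delta(shocked, shock_years) - shock_delta(unshocked,
                                                           shock_years)


@dataclass
class ShockExperimentResult:
    """Paired shocked/unshocked ensemble output."""

    arm_summary: pd.DataFrame       # year, arm, metric, mean, sd, lo, hi
    delta_mean: pd.DataFrame | None  # mean per-metric change at shock years
    shocked_series: list[pd.DataFrame] = field(default_factory=list)
    unshocked_series: list[pd.DataFrame] = field(default_factory=list)
    shock_logs: list[list[dict]] = field(default_factory=list)


def run_shock_experiment(param_sets, scenario, schedule, pool, *,
                         seed: int = 0,
                         record: str = "full") -> ShockExperimentResult:
    """For each parameter set, one shocked and one unshocked run with paired
    seeds (identical random streams, diverging only once the first shock
    perturbs the state); per-year mean/SD across sets for both arms, plus
    the mean shock-delta table."""
    from .growth import run_growth
    from .metrics import summarize_replicates

    shocked_frames: list[pd.DataFrame] = []
    unshocked_frames: list[pd.DataFrame] = []
    deltas: list[pd.DataFrame] = []
    logs: list[list[dict]] = []
    shock_years = scenario.start_years if scenario is not None else ()
    for s_index, params in enumerate(param_sets):
        seq = np.random.SeedSequence(seed, spawn_key=(s_index,))
        rng_shocked = np.random.default_rng(seq)
        rng_unshocked = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(s_index,)))
        shocked = run_growth(pool, params, schedule, scenario,
                             rng=rng_shocked, record=record)
        unshocked = run_growth(pool, params, schedule, None,
                               rng=rng_unshocked, record=record)
        shocked_frames.append(shocked.series)
        unshocked_frames.append(unshocked.series)
        logs.append(shocked.shock_log)
        if shock_years:
            deltas.append(shock_delta(shocked.series, shock_years))
    summaries = []
    for arm, frames in (("shocked", shocked_frames),
                        ("unshocked", unshocked_frames)):
        summary = summarize_replicates(frames)
        summary.insert(1, "arm", arm)
        summaries.append(summary)
    delta_mean = None
    if deltas:
        delta_mean = (pd.concat(deltas).groupby("year").mean()
                      .loc[list(shock_years)])
    return ShockExperimentResult(
        arm_summary=pd.concat(summaries, ignore_index=True),
        delta_mean=delta_mean,
        shocked_series=shocked_frames,
        unshocked_series=unshocked_frames,
        shock_logs=logs)
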