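"""The tick loop, snapshot recorders, and the multi-replication harness.

One tick is one asymmetric encounter.  A run of ``T`` ticks over ``N``
agents therefore gives each agent-lineage an expected ``T / N`` turns as the
focal agent.  The default engine (``method="array"``) advances flat numpy
arrays through a compiled kernel in snapshot-sized chunks; the naive
object-per-agent engine in :mod:`castesim.reference` consumes the identical
random stream and is kept as an executable cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import _kernel
from .model import N_CASTES, ModelConfig, Population, init_population
from .rng import SplitMix64, spawn_seed

_DEATH_COLUMNS = ["caste", "signal", "birth_tick", "death_tick", "age_at_death"]


def snapshot_tables(
    caste: np.ndarray, signal: np.ndarray, resources: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-(caste, signal) agent counts and mean resources, as 3x3 arrays.

    The mean is NaN for empty (caste, signal) cells.
    """
    key = caste.astype(np.int64) * N_CASTES + signal.astype(np.int64)
    counts = np.bincount(key, minlength=9).reshape(N_CASTES, N_CASTES)
    sums = np.bincount(key, weights=resources, minlength=9).reshape(N_CASTES, N_CASTES)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return counts, means


@dataclass
class RunResult:
    """Time series and death log of one run.

    ``counts`` and ``mean_resources`` are indexed ``[snapshot, caste, signal]``;
    ``snapshot_ticks[0]`` is always tick 0 (the initial population) and the
    last entry is the final tick.  ``focal_counts`` holds how many times each
    population slot (an agent together with the descendants that inherited
    its slot) was drawn as the focal agent.
    """

    config: ModelConfig
    snapshot_ticks: np.ndarray
    counts: np.ndarray
    mean_resources: np.ndarray
    deaths: pd.DataFrame
    focal_counts: np.ndarray

    @property
    def liar_counts(self) -> np.ndarray:
        """Per-caste deceptive-signaler counts, indexed [snapshot, caste]."""
        total = self.counts.sum(axis=2)
        honest = np.stack(
            [self.counts[:, c, c] for c in range(N_CASTES)], axis=1
        )
        return total - honest

    def death_count(self, caste: int) -> int:
        return int((self.deaths["caste"] == caste).sum())

    def mean_age_at_death(self, caste: int) -> float:
        ages = self.deaths.loc[self.deaths["caste"] == caste, "age_at_death"]
        return float(ages.mean()) if len(ages) else float("nan")

    def snapshots_frame(self, run_id: int = 0) -> pd.DataFrame:
        """Tidy long-format snapshot table: run_id, tick, caste, signal, count, mean_resources."""
        s, c, g = self.counts.shape
        ticks = np.repeat(self.snapshot_ticks, c * g)
        castes = np.tile(np.repeat(np.arange(c), g), s)
        signals = np.tile(np.arange(g), s * c)
        return pd.DataFrame(
            {
                "run_id": run_id,
                "tick": ticks,
                "caste": castes,
                "signal": signals,
                "count": self.counts.reshape(-1),
                "mean_resources": self.mean_resources.reshape(-1),
            }
        )

    def deaths_frame(self, run_id: int = 0) -> pd.DataFrame:
        """Death log with a run_id column: run_id, death_tick, caste, signal, age_at_death."""
        df = self.deaths[["death_tick", "caste", "signal", "age_at_death"]].copy()
        df.insert(0, "run_id", run_id)
        return df

    def final_summary(self) -> pd.DataFrame:
        """Per-caste summary of the final snapshot plus the death log."""
        rows = []
        for caste in range(N_CASTES):
            rows.append(
                {
                    "caste": caste,
                    "final_liar_count": int(self.liar_counts[-1, caste]),
                    "deaths": self.death_count(caste),
                    "mean_age_at_death": self.mean_age_at_death(caste),
                }
            )
        return pd.DataFrame(rows)


def step(pop: Population, params, config: ModelConfig, tick: int, rng: SplitMix64):
    """Execute exactly one encounter on a Population of Agent objects.

    Composition: draw pair, fight-or-flight, then flee cost or battle plus
    payoff, then the starvation/replacement check — all applied to the focal
    agent only.  Returns ``(death_record_or_None, EncounterOutcome)``.
    """
    from .encounter import (
        Action,
        EncounterOutcome,
        apply_flee_cost,
        battle_outcome,
        decide_engagement,
        draw_pair,
        resolve_fight,
    )
    from .evolution import replace_if_dead

    party, counterparty = draw_pair(pop, rng)
    action = decide_engagement(party, counterparty.signal, rng, config.flee_prob_form)
    if action is Action.FLEE:
        delta = apply_flee_cost(party, params[party.caste], config.flee_cost_base)
        outcome = EncounterOutcome(party.id, counterparty.id, Action.FLEE, None, delta)
    else:
        won = battle_outcome(party, counterparty, rng)
        outcome = resolve_fight(party, counterparty, won, params)
    record = replace_if_dead(
        pop, party, tick, rng, config.death_threshold_fraction
    )
    return record, outcome


def _arrays_from_population(pop: Population):
    caste = np.array([a.caste for a in pop.agents], dtype=np.int64)
    signal = np.array([a.signal for a in pop.agents], dtype=np.int64)
    resources = np.array([a.resources for a in pop.agents], dtype=np.float64)
    endowment = np.array([a.endowment for a in pop.agents], dtype=np.float64)
    birth = np.array([a.birth_tick for a in pop.agents], dtype=np.int64)
    return caste, signal, resources, endowment, birth


def run(config: ModelConfig, method: str = "array") -> RunResult:
    """Execute one full run: initialization, ``config.ticks`` encounters, recording.

    A snapshot is recorded at tick 0, after every ``snapshot_interval``
    ticks, and at the final tick.  ``run`` is a pure function of the config
    (including its seed): identical configs give bit-identical results, and
    the two engines (``method="array"`` and ``method="reference"``) agree
    exactly.
    """
    if method == "reference":
        from .reference import run_reference

        return run_reference(config)
    if method != "array":
        raise ValueError(f"unknown engine method {method!r}")

    if config.ticks > 0:
        if config.n_agents < 2:
            raise ValueError("need at least 2 agents to run encounters")
        # a death in a caste needs two tournament candidates besides the
        # dying agent, so any populated caste must hold at least 3 agents
        if any(0 < n < 3 for n in config.caste_sizes):
            raise ValueError("populated castes need at least 3 agents each")

    rng = SplitMix64(config.seed)
    pop = init_population(config, rng)
    caste, signal, resources, endowment, birth = _arrays_from_population(pop)

    params = config.scaled_params()
    caste_offset = np.zeros(N_CASTES + 1, dtype=np.int64)
    caste_offset[1:] = np.cumsum(config.caste_sizes)
    met_factor = np.array([p.met_cost_factor for p in params])
    honest_app = np.array([p.honest_appropriation for p in params])
    dishonest_app = np.array([p.dishonest_appropriation for p in params])
    caste_endowment = np.array([p.aggression_resources for p in params])
    threshold_abs = config.death_threshold_fraction * caste_endowment
    flee_cost_abs = met_factor * caste_endowment
    on_current = config.flee_cost_base == "current"
    deferent = config.flee_prob_form == "deferent"

    interval = config.snapshot_interval
    snap_ticks = [0]
    counts0, means0 = snapshot_tables(caste, signal, resources)
    counts = [counts0]
    means = [means0]

    death_caste = np.empty(interval, dtype=np.int64)
    death_signal = np.empty(interval, dtype=np.int64)
    death_birth = np.empty(interval, dtype=np.int64)
    death_tick = np.empty(interval, dtype=np.int64)
    deaths_parts = []
    focal_counts = np.zeros(len(pop), dtype=np.int64)

    state = np.uint64(rng.state)
    done = 0
    while done < config.ticks:
        chunk = min(interval, config.ticks - done)
        # numba hands the state back as a Python int; re-wrap so the kernel
        # always sees (and computes with) unsigned 64-bit arithmetic
        state, n_deaths = _kernel.run_chunk(
            np.uint64(state),
            done,
            chunk,
            caste,
            signal,
            resources,
            endowment,
            birth,
            caste_offset,
            met_factor,
            honest_app,
            dishonest_app,
            threshold_abs,
            flee_cost_abs,
            on_current,
            deferent,
            death_caste,
            death_signal,
            death_birth,
            death_tick,
            focal_counts,
        )
        if n_deaths:
            deaths_parts.append(
                np.column_stack(
                    [
                        death_caste[:n_deaths],
                        death_signal[:n_deaths],
                        death_birth[:n_deaths],
                        death_tick[:n_deaths],
                        death_tick[:n_deaths] - death_birth[:n_deaths],
                    ]
                )
            )
        done += chunk
        c, m = snapshot_tables(caste, signal, resources)
        snap_ticks.append(done)
        counts.append(c)
        means.append(m)

    if deaths_parts:
        deaths = pd.DataFrame(np.concatenate(deaths_parts), columns=_DEATH_COLUMNS)
    else:
        deaths = pd.DataFrame(
            np.empty((0, 5), dtype=np.int64), columns=_DEATH_COLUMNS
        )

    return RunResult(
        config=config,
        snapshot_ticks=np.array(snap_ticks, dtype=np.int64),
        counts=np.stack(counts),
        mean_resources=np.stack(means),
        deaths=deaths,
        focal_counts=focal_counts,
    )


def run_replications(
    config: ModelConfig, n_reps: int, base_seed: int, method: str = "array"
) -> list[RunResult]:
    """Run ``n_reps`` independent replicates with seeds derived from ``base_seed``.

    Replicate ``i`` uses ``spawn_seed(base_seed, i)``, so each replicate is
    reproducible in isolation; results are ordered by replicate index.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    results = []
    for i in range(n_reps):
        cfg = replace(config, seed=spawn_seed(base_seed, i))
        results.append(run(cfg, method=method))
    return results


def expected_focal_picks(ticks: int, pop_size: int) -> float:
    """Expected number of times each agent-lineage is drawn as focal: ticks / N."""
    if pop_size < 1:
        raise ValueError("pop_size must be >= 1")
    return ticks / pop_size
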