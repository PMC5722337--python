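"""Naive object-per-agent engine, kept as an executable oracle.

This engine runs the simulation by looping :func:`castesim.engine.step` over
a list of :class:`~castesim.model.Agent` objects, with no array tricks.  It
consumes the same splitmix64 stream in the same order as the compiled
kernel, so on any config the two produce bit-identical snapshot tables and
death logs — the test suite asserts this on a small population.  It is
orders of magnitude slower and intended only for verification and debugging.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import (
    RunResult,
    _DEATH_COLUMNS,
    _arrays_from_population,
    snapshot_tables,
    step,
)
from .model import ModelConfig, init_population
from .rng import SplitMix64


def run_reference(config: ModelConfig, event_log: str | Path | None = None) -> RunResult:
    """Run a config through the naive per-agent loop.

    If ``event_log`` is given, every encounter is appended to that file as a
    JSON line ``{tick, party_id, counterparty_id, action, party_won, delta}``
    — a per-tick trace for debugging and for auditing individual encounters.
    """
    if config.ticks > 0:
        if config.n_agents < 2:
            raise ValueError("need at least 2 agents to run encounters")
        if any(0 < n < 3 for n in config.caste_sizes):
            raise ValueError("populated castes need at least 3 agents each")

    rng = SplitMix64(config.seed)
    pop = init_population(config, rng)
    params = config.scaled_params()

    def snap():
        caste, signal, resources, _, _ = _arrays_from_population(pop)
        return snapshot_tables(caste, signal, resources)

    interval = config.snapshot_interval
    snap_ticks = [0]
    c0, m0 = snap()
    counts, means = [c0], [m0]
    deaths = []
    focal_counts = np.zeros(len(pop), dtype=np.int64)
    id_to_slot = {a.id: slot for slot, a in enumerate(pop.agents)}

    log_handle = open(event_log, "w") if event_log is not None else None
    try:
        for tick in range(1, config.ticks + 1):
            record, outcome = step(pop, params, config, tick, rng)
            focal_counts[id_to_slot[outcome.party_id]] += 1
            if record is not None:
                deaths.append(record)
            if log_handle is not None:
                log_handle.write(json.dumps({
                    "tick": tick,
                    "party_id": outcome.party_id,
                    "counterparty_id": outcome.counterparty_id,
                    "action": outcome.action.value,
                    "party_won": outcome.party_won,
                    "delta": outcome.party_resource_delta,
                }) + "\n")
            if tick % interval == 0 or tick == config.ticks:
                snap_ticks.append(tick)
                c, m = snap()
                counts.append(c)
                means.append(m)
    finally:
        if log_handle is not None:
            log_handle.close()

    if deaths:
        frame = pd.DataFrame(
            [
                (r.caste, r.signal, r.birth_tick, r.death_tick, r.age_at_death)
                for r in deaths
            ],
            columns=_DEATH_COLUMNS,
        ).astype(np.int64)
    else:
        frame = pd.DataFrame(np.empty((0, 5), dtype=np.int64), columns=_DEATH_COLUMNS)

    return RunResult(
        config=config,
        snapshot_ticks=np.array(snap_ticks, dtype=np.int64),
        counts=np.stack(counts),
        mean_resources=np.stack(means),
        deaths=frame,
        focal_counts=focal_counts,
    )
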