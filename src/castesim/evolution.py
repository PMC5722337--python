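"""Starvation, death, and replacement via within-caste binary tournaments.

An agent whose resources fall strictly below a fixed fraction (default 10%)
of its birth endowment starves.  It is immediately replaced, in the same
population slot, by a newborn of the same caste at full endowment whose
signaling strategy is copied from the winner of a binary tournament: two
distinct living agents of that caste (the dying agent excluded) are drawn,
and the richer one's signal is inherited.  Selection therefore acts only
through who survives and who is rich at replacement time — strategies are
never mutated, so a signal that goes extinct within a caste can never
reappear there.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import Agent, Population
from .rng import SplitMix64


@dataclass(frozen=True)
class DeathRecord:
    """One starvation/replacement event."""

    caste: int
    signal: int
    birth_tick: int
    death_tick: int

    @property
    def age_at_death(self) -> int:
        return self.death_tick - self.birth_tick


def is_starved(agent: Agent, threshold_fraction: float) -> bool:
    """True iff resources are strictly below the threshold fraction of the endowment."""
    return agent.resources < threshold_fraction * agent.endowment


def tournament_strategy(
    pop: Population, caste: int, rng: SplitMix64, exclude_id: int | None = None
) -> int:
    """Signal inherited by a newborn of ``caste`` via a binary tournament.

    Draws two distinct agents uniformly without replacement from the caste
    (skipping ``exclude_id``, the dying agent); the richer one's signal is
    returned, with an exact resource tie broken by a fair coin.

    Consumes two integer draws, plus one uniform draw on a tie.
    """
    members = [a for a in pop.caste_members(caste) if a.id != exclude_id]
    m = len(members)
    if m < 2:
        raise ValueError(f"tournament in caste {caste} needs >= 2 candidates, have {m}")
    a_idx = rng.randint(m)
    b_idx = rng.randint(m - 1)
    if b_idx >= a_idx:
        b_idx += 1
    a, b = members[a_idx], members[b_idx]
    if a.resources != b.resources:
        return a.signal if a.resources > b.resources else b.signal
    return a.signal if rng.random() < 0.5 else b.signal


def replace_if_dead(
    pop: Population,
    agent: Agent,
    tick: int,
    rng: SplitMix64,
    threshold_fraction: float,
) -> DeathRecord | None:
    """Replace a starved focal agent in place; no-op if it is still viable.

    The newborn keeps the slot and id, gets the full caste endowment,
    ``birth_tick = tick``, and a tournament-inherited signal.  Per-caste
    counts are thus invariant.  Returns the DeathRecord, or None.
    """
    if not is_starved(agent, threshold_fraction):
        return None
    record = DeathRecord(
        caste=agent.caste,
        signal=agent.signal,
        birth_tick=agent.birth_tick,
        death_tick=tick,
    )
    new_signal = tournament_strategy(pop, agent.caste, rng, exclude_id=agent.id)
    agent.signal = new_signal
    agent.resources = agent.endowment
    agent.birth_tick = tick
    return record
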