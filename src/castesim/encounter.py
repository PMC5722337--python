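"""One asymmetric encounter: pair draw, fight-or-flight, battle, payoff.

Each tick pairs a random focal agent ("the party") with a random counterparty.
The focal agent sees only the counterparty's signal — which may be a bluff
(weaker agent signaling strength) or a seduction (stronger agent signaling
weakness) — and decides to fight or flee.  Battles are resolved by *true*
aggression, so fighting reveals deception; the winner then appropriates a
caste-dependent fraction of the loser's resources, with a larger fraction
taken from dishonest losers.  Only the focal agent's stored resources are
ever updated: the counterparty acts purely as an opponent this tick and will
have its own resources settled on the ticks in which it is focal.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .model import Agent, CasteParams
from .rng import SplitMix64


class Action(Enum):
    FLEE = "flee"
    FIGHT = "fight"


@dataclass(frozen=True)
class EncounterOutcome:
    """Record of one encounter's effect on the focal agent."""

    party_id: int
    counterparty_id: int
    action: Action
    party_won: bool | None  # None when the party fled
    party_resource_delta: float


def draw_pair(pop, rng: SplitMix64) -> tuple[Agent, Agent]:
    """Draw a focal agent and a distinct counterparty, each uniformly.

    Consumes exactly two integer draws: the focal index over all N agents,
    then the counterparty index over the remaining N-1 (shifted past the
    focal slot).
    """
    n = len(pop.agents)
    if n < 2:
        raise ValueError("draw_pair needs a population of at least 2 agents")
    i = rng.randint(n)
    j = rng.randint(n - 1)
    if j >= i:
        j += 1
    return pop.agents[i], pop.agents[j]


def is_peaceable(signal: int, focal_caste: int) -> bool:
    """Whether a signal reads as peaceable to a focal agent of ``focal_caste``.

    A signal is peaceable iff it claims an aggression level strictly below
    the focal agent's own true level; an equal signal is not peaceable, so
    flight remains possible between apparent equals.
    """
    return signal < focal_caste


def fight_probability(party: Agent) -> float:
    """Resource-ratio fight probability against a non-peaceable opponent.

    The model ties willingness to fight to condition: the lower the ratio of
    current resources to birth endowment, the likelier flight.  The ratio is
    clamped to [0, 1] (resources can exceed the endowment after a string of
    wins).
    """
    r = party.resources / party.endowment
    return min(max(r, 0.0), 1.0)


def decide_engagement(
    party: Agent,
    counterparty_signal: int,
    rng: SplitMix64,
    form: str = "linear",
) -> Action:
    """Fight-or-flight decision of the focal agent.

    A peaceable signal (strictly below the focal agent's caste) always draws
    a fight and consumes no randomness.  For other signals the behavior
    depends on the configured form:

    ``linear``
        fight with probability :func:`fight_probability` (one uniform draw),
        whatever the signal claims.
    ``deferent``
        a signal strictly *above* the focal agent's own caste always causes
        flight (no randomness consumed); the resource-ratio rule applies
        only between apparent equals.

    ``deferent`` is the package default (see
    :class:`~castesim.model.ModelConfig`): deferring to an apparently
    stronger opponent is what makes bluffing profitable, and it is the
    variant whose mortality statistics match the published experiments.
    """
    if is_peaceable(counterparty_signal, party.caste):
        return Action.FIGHT
    if form == "deferent":
        if counterparty_signal > party.caste:
            return Action.FLEE
    elif form != "linear":
        raise ValueError(f"unknown flee_prob_form {form!r}")
    p_fight = fight_probability(party)
    return Action.FIGHT if rng.random() < p_fight else Action.FLEE


def flee_cost(party: Agent, params: CasteParams, base: str = "endowment") -> float:
    """Metabolic cost of one flee event.

    With the default ``endowment`` base the cost is a fixed per-caste amount,
    ``met_cost_factor * endowment``; the ``current`` base charges the same
    factor on the agent's current resources instead.  The cost exists to make
    perpetual flight unsustainable, not to model metabolism per se.
    """
    if base == "endowment":
        return params.met_cost_factor * party.endowment
    if base == "current":
        return params.met_cost_factor * party.resources
    raise ValueError(f"unknown flee_cost_base {base!r}")


def apply_flee_cost(
    party: Agent, params: CasteParams, base: str = "endowment"
) -> float:
    """Deduct the flee cost from the focal agent, flooring resources at 0.

    Returns the (non-positive) resource delta.  No other agent is affected.
    """
    cost = flee_cost(party, params, base)
    new = max(party.resources - cost, 0.0)
    delta = new - party.resources
    party.resources = new
    return delta


def battle_outcome(party: Agent, counterparty: Agent, rng: SplitMix64) -> bool:
    """Resolve a fight by true aggression; returns True iff the party won.

    Higher caste always wins; between same-caste opponents the richer agent
    wins, and an exact resource tie is broken by a fair coin (one uniform
    draw, party wins on the low half).
    """
    if party.caste != counterparty.caste:
        return party.caste > counterparty.caste
    if party.resources != counterparty.resources:
        return party.resources > counterparty.resources
    return rng.random() < 0.5


def appropriation_fraction(winner_params: CasteParams, loser_honest: bool) -> float:
    """Fraction of the loser's resources the winner takes.

    Dishonest losers forfeit more — this gap is the opportunistic punishment.
    """
    return (
        winner_params.honest_appropriation
        if loser_honest
        else winner_params.dishonest_appropriation
    )


def resolve_fight(
    party: Agent,
    counterparty: Agent,
    party_won: bool,
    params: Sequence[CasteParams],
) -> EncounterOutcome:
    """Apply the payoff (and punishment) of a decided battle to the focal agent.

    If the party won it gains ``f * counterparty.resources`` where ``f`` is
    its own caste's appropriation fraction against the counterparty's honesty;
    if it lost it forfeits ``f * party.resources`` to the winner's schedule
    against its own honesty.  The counterparty's stored resources are never
    modified — gains are not balanced by ledger deductions, which is the
    model's deliberate asymmetric update.
    """
    if party_won:
        f = appropriation_fraction(params[party.caste], counterparty.honest)
        delta = f * counterparty.resources
    else:
        f = appropriation_fraction(params[counterparty.caste], party.honest)
        delta = -f * party.resources
    party.resources += delta
    return EncounterOutcome(
        party_id=party.id,
        counterparty_id=counterparty.id,
        action=Action.FIGHT,
        party_won=party_won,
        party_resource_delta=delta,
    )
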