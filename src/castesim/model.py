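"""Domain types, default parameterization, parameter scaling, and population setup.

The society has three castes differing in true aggression level (0 = low,
1 = medium, 2 = high).  Each caste has four parameters: its birth endowment
of resources, a metabolic cost factor charged on fleeing, and the fractions
of a defeated opponent's resources a winner of that caste appropriates,
depending on whether the loser signaled honestly or deceptively.  The gap
between the two appropriation fractions is the opportunistic punishment:
punishing a liar pays the punisher.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import yaml

from .rng import SplitMix64

N_CASTES = 3
SIGNALS = (0, 1, 2)


@dataclass(frozen=True)
class CasteParams:
    """The four per-caste model parameters.

    Parameters
    ----------
    caste
        Aggression level in {0, 1, 2} (0 = low, 1 = medium, 2 = high).
    aggression_resources
        Birth endowment, in resource units.
    met_cost_factor
        Dimensionless fraction of the endowment paid each time an agent
        of this caste flees an encounter.
    honest_appropriation
        Fraction in [0, 1] a winner of this caste takes from a defeated
        honest opponent.
    dishonest_appropriation
        Fraction in [0, 1] a winner of this caste takes from a defeated
        dishonest opponent.
    """

    caste: int
    aggression_resources: float
    met_cost_factor: float
    honest_appropriation: float
    dishonest_appropriation: float

    def __post_init__(self):
        if self.caste not in (0, 1, 2):
            raise ValueError(f"caste must be 0, 1 or 2, got {self.caste}")
        if self.aggression_resources <= 0:
            raise ValueError("aggression_resources must be > 0")
        if self.met_cost_factor < 0:
            raise ValueError("met_cost_factor must be >= 0")
        for name in ("honest_appropriation", "dishonest_appropriation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def default_caste_params() -> list[CasteParams]:
    """The default three-caste setup.

    Low-aggression agents are endowed with 50 resource units, medium with 75,
    high with 100.  Winners take 25/50/75% of an honest loser's resources and
    50/75/100% of a dishonest loser's, by winner caste; flee-cost factors are
    0.05/0.075/0.1.
    """
    return [
        CasteParams(0, 50.0, 0.05, 0.25, 0.50),
        CasteParams(1, 75.0, 0.075, 0.50, 0.75),
        CasteParams(2, 100.0, 0.1, 0.75, 1.00),
    ]


def validate_scale(scale: Sequence[float]) -> tuple[float, float, float, float]:
    """Check a 4-vector of positive multipliers and return it as a tuple.

    Element i scales (endowment, met-cost factor, honest appropriation,
    dishonest appropriation) respectively, across all three castes.
    """
    vec = tuple(float(s) for s in scale)
    if len(vec) != 4:
        raise ValueError(f"scale vector must have exactly 4 entries, got {len(vec)}")
    if any(s <= 0 for s in vec):
        raise ValueError(f"scale entries must be > 0, got {vec}")
    return vec


def scale_params(
    params: Sequence[CasteParams], scale: Sequence[float]
) -> list[CasteParams]:
    """Multiply the four parameters of every caste by a 4-vector of factors.

    The input list is not modified.  Appropriation fractions are capped at
    1.0 after scaling (factors are <= 1 in all the sweeps this package runs,
    so the cap only matters for exploratory upscaling).
    """
    a, m, h, d = validate_scale(scale)
    return [
        replace(
            p,
            aggression_resources=p.aggression_resources * a,
            met_cost_factor=p.met_cost_factor * m,
            honest_appropriation=min(p.honest_appropriation * h, 1.0),
            dishonest_appropriation=min(p.dishonest_appropriation * d, 1.0),
        )
        for p in params
    ]


@dataclass
class Agent:
    """One individual: a fixed caste and signal, and a mutable resource level.

    The signal is fixed for life; an agent is honest iff ``signal == caste``.
    """

    id: int
    caste: int
    signal: int
    resources: float
    endowment: float
    birth_tick: int = 0

    @property
    def honest(self) -> bool:
        return self.signal == self.caste


@dataclass
class Population:
    """A fixed-size, caste-partitioned collection of agents.

    Agents are stored in caste-contiguous slot order (all caste-0 agents
    first, then caste 1, then caste 2); dead agents are replaced in place by
    same-caste newborns, so per-caste counts never change over a run.
    """

    agents: list[Agent]
    caste_sizes: tuple[int, int, int]

    def __len__(self) -> int:
        return len(self.agents)

    def caste_slice(self, caste: int) -> slice:
        start = sum(self.caste_sizes[:caste])
        return slice(start, start + self.caste_sizes[caste])

    def caste_members(self, caste: int) -> list[Agent]:
        return self.agents[self.caste_slice(caste)]

    def liar_count(self, caste: int) -> int:
        return sum(1 for a in self.caste_members(caste) if not a.honest)


_CONFIG_FIELDS = {
    "caste_sizes",
    "caste_params",
    "scale",
    "init_deceptive_fraction",
    "death_threshold_fraction",
    "ticks",
    "seed",
    "snapshot_interval",
    "flee_prob_form",
    "flee_cost_base",
}


@dataclass
class ModelConfig:
    """Full configuration of one simulation run.

    ``flee_prob_form`` and ``flee_cost_base`` select among the pluggable
    fight-or-flee rules (see :mod:`castesim.encounter`).  The shipped
    defaults — ``deferent`` (always defer to a signal above one's own caste,
    resource-ratio rule among apparent equals) with the flee cost charged on
    current resources — are the variant whose mortality statistics best
    match the published three-caste experiments; the plain ``linear`` ratio
    rule and the endowment-based cost are available as alternatives.
    """

    caste_sizes: tuple[int, int, int] = (1000, 1000, 1000)
    caste_params: list[CasteParams] = field(default_factory=default_caste_params)
    scale: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    init_deceptive_fraction: float = 0.85
    death_threshold_fraction: float = 0.10
    ticks: int = 2_000_000
    seed: int = 0
    snapshot_interval: int = 1000
    flee_prob_form: str = "deferent"
    flee_cost_base: str = "current"

    def __post_init__(self):
        self.caste_sizes = tuple(int(n) for n in self.caste_sizes)
        if len(self.caste_sizes) != 3 or any(n < 0 for n in self.caste_sizes):
            raise ValueError("caste_sizes must be 3 non-negative integers")
        if len(self.caste_params) != 3:
            raise ValueError("caste_params must list exactly 3 castes")
        self.scale = validate_scale(self.scale)
        if not 0.0 <= self.init_deceptive_fraction <= 1.0:
            raise ValueError("init_deceptive_fraction must lie in [0, 1]")
        if self.death_threshold_fraction < 0:
            raise ValueError("death_threshold_fraction must be >= 0")
        if self.ticks < 0:
            raise ValueError("ticks must be >= 0")
        if self.snapshot_interval < 1:
            raise ValueError("snapshot_interval must be >= 1")
        if self.flee_prob_form not in ("linear", "deferent"):
            raise ValueError(f"unknown flee_prob_form {self.flee_prob_form!r}")
        if self.flee_cost_base not in ("endowment", "current"):
            raise ValueError(f"unknown flee_cost_base {self.flee_cost_base!r}")

    @property
    def n_agents(self) -> int:
        return sum(self.caste_sizes)

    def scaled_params(self) -> list[CasteParams]:
        return scale_params(self.caste_params, self.scale)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "caste_sizes": list(self.caste_sizes),
            "caste_params": [
                {
                    "caste": p.caste,
                    "aggression_resources": p.aggression_resources,
                    "met_cost_factor": p.met_cost_factor,
                    "honest_appropriation": p.honest_appropriation,
                    "dishonest_appropriation": p.dishonest_appropriation,
                }
                for p in self.caste_params
            ],
            "scale": list(self.scale),
            "init_deceptive_fraction": self.init_deceptive_fraction,
            "death_threshold_fraction": self.death_threshold_fraction,
            "ticks": self.ticks,
            "seed": self.seed,
            "snapshot_interval": self.snapshot_interval,
            "flee_prob_form": self.flee_prob_form,
            "flee_cost_base": self.flee_cost_base,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ModelConfig":
        unknown = set(data) - _CONFIG_FIELDS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        if "caste_params" in data:
            parsed = []
            for entry in data["caste_params"]:
                extra = set(entry) - {
                    "caste",
                    "aggression_resources",
                    "met_cost_factor",
                    "honest_appropriation",
                    "dishonest_appropriation",
                }
                if extra:
                    raise ValueError(f"unknown caste_params keys: {sorted(extra)}")
                parsed.append(CasteParams(**entry))
            data["caste_params"] = parsed
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelConfig":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        return cls.from_dict(json.loads(text))


def deceptive_signals(caste: int) -> tuple[int, int]:
    """The two signals a member of ``caste`` can use deceptively, ascending."""
    return tuple(s for s in SIGNALS if s != caste)  # type: ignore[return-value]


def init_population(config: ModelConfig, rng: SplitMix64) -> Population:
    """Create the starting population.

    Every agent is born at tick 0 with its full (scaled) caste endowment.
    Within each caste, a fraction ``init_deceptive_fraction`` of the agents
    (rounded to the nearest count) signals deceptively; each deceptive agent
    picks one of its caste's two wrong signals with equal probability.  The
    per-caste application keeps all three castes starting near the same
    deception rate, which is how the model's initial condition is defined.

    Consumes one ``rng.random()`` per deceptive agent, castes in order.
    """
    agents: list[Agent] = []
    params = config.scaled_params()
    next_id = 0
    for caste in range(N_CASTES):
        size = config.caste_sizes[caste]
        endowment = params[caste].aggression_resources
        n_deceptive = int(math.floor(config.init_deceptive_fraction * size + 0.5))
        lo, hi = deceptive_signals(caste)
        for k in range(size):
            if k < n_deceptive:
                signal = lo if rng.random() < 0.5 else hi
            else:
                signal = caste
            agents.append(
                Agent(
                    id=next_id,
                    caste=caste,
                    signal=signal,
                    resources=endowment,
                    endowment=endowment,
                    birth_tick=0,
                )
            )
            next_id += 1
    return Population(agents=agents, caste_sizes=config.caste_sizes)
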