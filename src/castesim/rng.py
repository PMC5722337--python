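"""Deterministic random stream shared by the array engine and the reference engine.

The simulator's reproducibility contract is that the fast array-backed engine
and the naive object-per-agent reference engine, given the same seed, produce
bit-identical trajectories.  That requires a random generator whose state and
draw order are fully explicit on both sides, so we use a splitmix64 counter
stream rather than an opaque library generator.

Draw order per tick (both engines must follow it exactly):

1. one ``randint`` for the focal-agent index,
2. one ``randint`` for the counterparty index (drawn over the remaining
   agents, then shifted past the focal index),
3. if the counterparty's signal is not peaceable (and, under the
   ``deferent`` rule, not strictly above the focal agent's caste): one
   ``random`` for the fight-or-flee decision,
4. if a fight occurs between same-caste, equal-resource opponents: one
   ``random`` for the coin flip,
5. if the focal agent starves: one ``randint`` for each of the two tournament
   candidates, plus one ``random`` coin flip if they tie on resources.

Population initialization consumes one ``random`` per deceptive agent (caste
0 first, then 1, then 2) before the tick loop starts.
"""

from __future__ import annotations

_MASK64 = 0xFFFFFFFFFFFFFFFF
_GAMMA = 0x9E3779B97F4A7C15
_MIX1 = 0xBF58476D1CE4E5B9
_MIX2 = 0x94D049BB133111EB

#: 2**53, used to map 53 random bits onto [0, 1).
_DOUBLE_DENOM = 9007199254740992.0


def splitmix64_next(state: int) -> tuple[int, int]:
    """Advance a splitmix64 state by one step.

    Returns ``(new_state, output)`` where both are unsigned 64-bit values.
    """
    state = (state + _GAMMA) & _MASK64
    z = state
    z = ((z ^ (z >> 30)) * _MIX1) & _MASK64
    z = ((z ^ (z >> 27)) * _MIX2) & _MASK64
    z = z ^ (z >> 31)
    return state, z


class SplitMix64:
    """A splitmix64 stream with the three draw primitives the simulator uses."""

    __slots__ = ("state",)

    def __init__(self, seed: int):
        self.state = int(seed) & _MASK64

    def next_u64(self) -> int:
        self.state, z = splitmix64_next(self.state)
        return z

    def random(self) -> float:
        """Uniform float in [0, 1) from the top 53 bits of one draw."""
        return (self.next_u64() >> 11) / _DOUBLE_DENOM

    def randint(self, n: int) -> int:
        """Uniform integer in [0, n).

        Uses a plain modulo reduction; for the population sizes this model
        uses (n <= a few thousand) the bias is below 1e-15 and the identical
        reduction is easy to reproduce inside the compiled kernel.
        """
        if n <= 0:
            raise ValueError("randint() requires n >= 1")
        return self.next_u64() % n


def spawn_seed(base_seed: int, index: int) -> int:
    """Derive the seed for replicate ``index`` from ``base_seed``.

    The replicate seed is the ``index``-th output of a splitmix64 stream
    seeded with ``base_seed``, truncated to 31 bits so seeds stay in the
    portable positive-int32 range.  Each replicate is therefore reproducible
    in isolation: ``run(config with seed spawn_seed(b, i))`` equals the
    ``i``-th member of ``run_replications(config, n, b)``.
    """
    if index < 0:
        raise ValueError("replicate index must be >= 0")
    state = int(base_seed) & _MASK64
    out = 0
    for _ in range(index + 1):
        state, out = splitmix64_next(state)
    return out & 0x7FFFFFFF
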