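"""Compiled tick loop for the array-backed engine.

This reimplements, on flat numpy arrays, exactly the per-tick procedure that
the object-level primitives in :mod:`castesim.encounter` and
:mod:`castesim.evolution` define, consuming the splitmix64 stream in the
documented order.  Equivalence with the naive reference engine is asserted
bit-for-bit in the test suite, so any change here must be mirrored in the
primitives (and vice versa).

Agents are stored caste-contiguously; ``caste_offset`` holds the cumulative
slot offsets (length 4), so the tournament candidate pool of caste ``c`` is
the slot range ``[caste_offset[c], caste_offset[c+1])`` minus the dying slot.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)
_S30 = np.uint64(30)
_S27 = np.uint64(27)
_S31 = np.uint64(31)
_S11 = np.uint64(11)
_INV53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=True)
def _next_u64(state):
    state = state + _GAMMA
    z = state
    z = (z ^ (z >> _S30)) * _MIX1
    z = (z ^ (z >> _S27)) * _MIX2
    z = z ^ (z >> _S31)
    return state, z


@njit(cache=True)
def stream_u64(seed, n):
    """First ``n`` raw outputs of a splitmix64 stream (for cross-checking)."""
    out = np.empty(n, dtype=np.uint64)
    state = seed
    for k in range(n):
        state, z = _next_u64(state)
        out[k] = z
    return out


@njit(cache=True)
def run_chunk(
    state,
    tick0,
    n_ticks,
    caste,
    signal,
    resources,
    endowment,
    birth_tick,
    caste_offset,
    met_factor,
    honest_app,
    dishonest_app,
    threshold_abs,
    flee_cost_abs,
    flee_cost_on_current,
    defer_to_higher_signal,
    death_caste,
    death_signal,
    death_birth,
    death_tick,
    focal_counts,
):
    """Advance the population by ``n_ticks`` encounters, in place.

    Ticks are numbered ``tick0 + 1 .. tick0 + n_ticks``.  Death events are
    written into the four ``death_*`` buffers (each at least ``n_ticks``
    long; at most one death per tick).  Returns the advanced RNG state and
    the number of deaths recorded.
    """
    n = caste.shape[0]
    n_deaths = 0
    for t in range(n_ticks):
        tick = tick0 + t + 1

        # pair draw: focal uniform over all, counterparty over the rest
        state, z = _next_u64(state)
        i = np.int64(z % np.uint64(n))
        state, z = _next_u64(state)
        j = np.int64(z % np.uint64(n - 1))
        if j >= i:
            j += 1
        focal_counts[i] += 1

        ci = caste[i]
        sj = signal[j]

        # fight-or-flight from the (possibly deceptive) signal
        if sj < ci:
            fight = True  # peaceable signal: no randomness consumed
        elif defer_to_higher_signal and sj > ci:
            fight = False  # deferent rule: yield to an apparently stronger agent
        else:
            state, z = _next_u64(state)
            u = np.float64(z >> _S11) * _INV53
            r = resources[i] / endowment[i]
            if r > 1.0:
                r = 1.0
            fight = u < r

        if not fight:
            if flee_cost_on_current:
                cost = met_factor[ci] * resources[i]
            else:
                cost = flee_cost_abs[ci]
            nr = resources[i] - cost
            resources[i] = nr if nr > 0.0 else 0.0
        else:
            cj = caste[j]
            if ci != cj:
                won = ci > cj
            elif resources[i] != resources[j]:
                won = resources[i] > resources[j]
            else:
                state, z = _next_u64(state)
                won = np.float64(z >> _S11) * _INV53 < 0.5
            if won:
                if sj == cj:
                    f = honest_app[ci]
                else:
                    f = dishonest_app[ci]
                resources[i] += f * resources[j]
            else:
                if signal[i] == ci:
                    f = honest_app[cj]
                else:
                    f = dishonest_app[cj]
                resources[i] += -(f * resources[i])

        # starvation check for the focal agent only
        if resources[i] < threshold_abs[ci]:
            death_caste[n_deaths] = ci
            death_signal[n_deaths] = signal[i]
            death_birth[n_deaths] = birth_tick[i]
            death_tick[n_deaths] = tick
            n_deaths += 1

            off = caste_offset[ci]
            m = caste_offset[ci + 1] - off - 1  # pool size excluding the dying agent
            if m < 2:
                raise ValueError("tournament needs >= 2 same-caste candidates")
            x = i - off
            state, z = _next_u64(state)
            u_idx = np.int64(z % np.uint64(m))
            state, z = _next_u64(state)
            v_idx = np.int64(z % np.uint64(m - 1))
            if v_idx >= u_idx:
                v_idx += 1
            a_rel = u_idx if u_idx < x else u_idx + 1
            b_rel = v_idx if v_idx < x else v_idx + 1
            ra = resources[off + a_rel]
            rb = resources[off + b_rel]
            if ra > rb:
                new_sig = signal[off + a_rel]
            elif rb > ra:
                new_sig = signal[off + b_rel]
            else:
                state, z = _next_u64(state)
                if np.float64(z >> _S11) * _INV53 < 0.5:
                    new_sig = signal[off + a_rel]
                else:
                    new_sig = signal[off + b_rel]
            signal[i] = new_sig
            resources[i] = endowment[i]
            birth_tick[i] = tick

    return state, n_deaths
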