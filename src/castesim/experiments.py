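"""Experiment orchestration: named settings, sweeps, egalitarian societies, summaries.

The three named punishment regimes are the uniform scale vectors
``[1.0]*4`` (default, harshest punishment), ``[0.5]*4`` (intermediate) and
``[0.1]*4`` (minimal).  The full-factorial sweep crosses a grid of levels
over the four parameters (endowments, flee-cost factors, honest and
dishonest appropriations) independently.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import RunResult, run, run_replications
from .model import N_CASTES, ModelConfig
from .rng import spawn_seed

DEFAULT_SCALE = (1.0, 1.0, 1.0, 1.0)
INTERMEDIATE_SCALE = (0.5, 0.5, 0.5, 0.5)
MINIMAL_SCALE = (0.1, 0.1, 0.1, 0.1)


@dataclass
class SweepSpec:
    """Plan for a full-factorial sweep over per-parameter scale levels."""

    levels: tuple[float, ...] = (1.0, 0.5, 0.25, 0.1)
    full_factorial: bool = True
    n_reps: int = 30
    ticks: int = 2_000_000

    def __post_init__(self):
        self.levels = tuple(float(v) for v in self.levels)
        if not self.levels:
            raise ValueError("levels must be non-empty")
        if any(not 0.0 < v <= 1.0 for v in self.levels):
            raise ValueError("levels must lie in (0, 1]")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    def settings(self) -> list[tuple[float, float, float, float]]:
        """All scale vectors of the sweep (len(levels)**4 if full factorial,
        otherwise the uniform diagonal)."""
        if self.full_factorial:
            return list(itertools.product(self.levels, repeat=4))
        return [(v, v, v, v) for v in self.levels]


@dataclass
class SummaryTable:
    """Replicate-averaged summaries of one group of runs.

    ``per_replicate``: one row per (replicate, caste) with the death count,
    within-replicate mean age at death, and final liar count.
    ``per_caste``: replicate means of those columns (ages averaged within
    each replicate first, then across the replicates that had any deaths).
    ``per_caste_signal``: replicate-mean final count and final mean
    resources for every (caste, signal) cell.
    """

    per_replicate: pd.DataFrame
    per_caste: pd.DataFrame
    per_caste_signal: pd.DataFrame


def summarize(results: list[RunResult]) -> SummaryTable:
    """Aggregate a set of replicate runs that share a config (up to seed)."""
    if not results:
        raise ValueError("summarize needs at least one RunResult")
    ref = {k: v for k, v in results[0].config.to_dict().items() if k != "seed"}
    for r in results[1:]:
        other = {k: v for k, v in r.config.to_dict().items() if k != "seed"}
        if other != ref:
            raise ValueError("summarize requires identical configs up to seed")

    rep_rows = []
    cell_rows = []
    for rep, res in enumerate(results):
        final_counts = res.counts[-1]
        final_means = res.mean_resources[-1]
        for caste in range(N_CASTES):
            rep_rows.append(
                {
                    "replicate": rep,
                    "caste": caste,
                    "deaths": res.death_count(caste),
                    "mean_age_at_death": res.mean_age_at_death(caste),
                    "final_liar_count": int(res.liar_counts[-1, caste]),
                }
            )
            for signal in range(N_CASTES):
                cell_rows.append(
                    {
                        "replicate": rep,
                        "caste": caste,
                        "signal": signal,
                        "final_count": int(final_counts[caste, signal]),
                        "final_mean_resources": float(final_means[caste, signal]),
                    }
                )

    per_replicate = pd.DataFrame(rep_rows)
    per_caste = (
        per_replicate.groupby("caste")
        .agg(
            mean_deaths=("deaths", "mean"),
            mean_age_at_death=("mean_age_at_death", "mean"),
            mean_final_liar_count=("final_liar_count", "mean"),
        )
        .reset_index()
    )
    per_caste_signal = (
        pd.DataFrame(cell_rows)
        .groupby(["caste", "signal"])
        .agg(
            mean_final_count=("final_count", "mean"),
            mean_final_resources=("final_mean_resources", "mean"),
        )
        .reset_index()
    )
    return SummaryTable(per_replicate, per_caste, per_caste_signal)


def egalitarian_config(caste: int, n_agents: int, base: ModelConfig) -> ModelConfig:
    """A single-caste society: all agents in ``caste``, other castes empty.

    With only one caste present, no battle is decided by caste dominance;
    every fight is settled by resources or the coin flip, which removes the
    social-structure component of the dynamics.
    """
    if caste not in (0, 1, 2):
        raise ValueError("caste must be 0, 1 or 2")
    sizes = [0, 0, 0]
    sizes[caste] = int(n_agents)
    return replace(base, caste_sizes=tuple(sizes))


def _setting_tag(scale) -> str:
    return "x".join(f"{v:g}" for v in scale)


def full_factorial_sweep(
    spec: SweepSpec,
    base: ModelConfig,
    base_seed: int = 0,
    cache_dir: str | Path | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run every setting of the sweep and stack the per-caste summaries.

    Returns a tidy frame with the four scale columns plus the ``per_caste``
    summary columns.  Replicate seeds are spawned from ``base_seed`` per
    setting, so the sweep is deterministic and each (setting, replicate) can
    be recomputed in isolation.  If ``cache_dir`` is given, per-setting
    summaries are written there as JSON and reloaded on a rerun, giving
    cheap resume.
    """
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)

    frames = []
    settings = spec.settings()
    iterator = enumerate(settings)
    if progress:
        from tqdm import tqdm

        iterator = enumerate(tqdm(settings, desc="sweep"))
    for idx, scale in iterator:
        tag = _setting_tag(scale)
        cache_file = cache / f"setting_{tag}.json" if cache is not None else None
        if cache_file is not None and cache_file.exists():
            per_caste = pd.DataFrame(json.loads(cache_file.read_text()))
        else:
            cfg = replace(base, scale=scale, ticks=spec.ticks)
            setting_seed = spawn_seed(base_seed, idx)
            results = run_replications(cfg, spec.n_reps, setting_seed)
            per_caste = summarize(results).per_caste
            if cache_file is not None:
                cache_file.write_text(per_caste.to_json(orient="records"))
        block = per_caste.copy()
        for col, val in zip(
            ["scale_endowment", "scale_met_cost", "scale_honest", "scale_dishonest"],
            scale,
        ):
            block.insert(0, col, val)
        frames.append(block)
    return pd.concat(frames, ignore_index=True)


def write_run_outputs(results: list[RunResult], out_dir: str | Path) -> None:
    """Write tidy CSV snapshot/death tables and run-metadata JSON for a set of runs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    snaps = pd.concat(
        [r.snapshots_frame(run_id=i) for i, r in enumerate(results)],
        ignore_index=True,
    )
    deaths = pd.concat(
        [r.deaths_frame(run_id=i) for i, r in enumerate(results)],
        ignore_index=True,
    )
    snaps.to_csv(out / "snapshots.csv", index=False)
    deaths.to_csv(out / "deaths.csv", index=False)
    meta = {
        "n_runs": len(results),
        "configs": [r.config.to_dict() for r in results],
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2))


def load_run_outputs(out_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Load the CSV/JSON outputs written by :func:`write_run_outputs`."""
    out = Path(out_dir)
    snaps = pd.read_csv(out / "snapshots.csv")
    deaths = pd.read_csv(out / "deaths.csv")
    meta = json.loads((out / "meta.json").read_text())
    return snaps, deaths, meta


def mean_liar_trajectory(results: list[RunResult], caste: int) -> np.ndarray:
    """Across-replicate mean of a caste's liar-count trajectory."""
    return np.mean([r.liar_counts[:, caste] for r in results], axis=0)


def first_passage_tick(result: RunResult, caste: int, level: int = 0) -> float:
    """First snapshot tick at which a caste's liar count reaches ``level``
    (NaN if never)."""
    traj = result.liar_counts[:, caste]
    hits = np.nonzero(traj <= level)[0]
    if len(hits) == 0:
        return float("nan")
    return float(result.snapshot_ticks[hits[0]])
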