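"""Master-worker parallel execution with dividing-cycle stream assignment.

The master partitions the photon budget into near-equal per-worker counts
and cuts the single master random sequence into contiguous blocks of
``L = draw_budget * ceil(N / N_c)`` draws; worker ``i`` is seeded with the
first value of block ``i`` (located by jump-ahead) and may consume at most
``L`` draws — overrunning the block raises instead of silently reusing a
neighbour's numbers.  Workers run as same-host processes exchanging
pickled tasks and partial results (the master computes worker 0's share
in-process when only one worker is requested); partials are merged in
worker-index order, so the merged output is a pure function of
(master seed, N, N_c, config).

A single-worker run uses the master stream directly with no block bound:
with one stream there is nothing to overlap, and this keeps long serial
runs free of an artificial draw ceiling.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from multiprocessing import get_context
from typing import Optional

import numpy as np

from .config import RunConfig, config_hash
from .errors import ConfigurationError, MergeError
from .rng import MCGState, split_streams
from .tissue import ExitRecords, TissueResult, WeightLedger, run_tissue


@dataclass
class WorkerTask:
    """One worker's share: photon count, stream state, draw bound, config."""

    index: int
    n_photons: int
    stream_state: int  # MCG state whose next output starts the worker's block
    worker_seed: int  # first random number of the block (dividing-cycle seed)
    draw_limit: int  # 0 = unbounded (single-worker run)
    config: RunConfig


@dataclass
class WorkerPartial:
    index: int
    exits: ExitRecords
    ledger: WeightLedger
    draws: int
    n_photons: int
    wall_time: float
    config_hash: str


@dataclass
class MergedResult:
    """Merged output of all workers, ordered deterministically."""

    exits: ExitRecords
    ledger: WeightLedger
    config_hash: str
    diagnostics: list = field(default_factory=list)


def partition(
    n_photons: int,
    n_workers: int,
    master_seed: int,
    draw_budget: int,
    config: RunConfig,
) -> list[WorkerTask]:
    """Split N photons and the master stream into per-worker tasks.

    Counts differ by at most one (the first ``N mod N_c`` workers take the
    extra photon).  Worker stream seeds are the dividing-cycle block
    starts of the master sequence.
    """
    if n_photons < 1 or n_workers < 1:
        raise ConfigurationError("photon and worker counts must be >= 1")
    a = config.rng.multiplier
    m = config.rng.modulus
    if n_workers == 1:
        return [
            WorkerTask(
                index=0,
                n_photons=n_photons,
                stream_state=master_seed,
                worker_seed=(a * master_seed) % m,
                draw_limit=0,
                config=config,
            )
        ]
    block = draw_budget * math.ceil(n_photons / n_workers)
    part = split_streams(master_seed, n_workers, block, a, m)
    base, extra = divmod(n_photons, n_workers)
    tasks = []
    for i in range(n_workers):
        tasks.append(
            WorkerTask(
                index=i,
                n_photons=base + (1 if i < extra else 0),
                stream_state=part.worker_state(i).current,
                worker_seed=part.worker_seeds[i],
                draw_limit=block,
                config=config,
            )
        )
    return tasks


def execute_task(task: WorkerTask) -> WorkerPartial:
    """Run one worker's tissue-stage share (also the serial-replay oracle)."""
    cfg = task.config
    t0 = time.perf_counter()
    state = MCGState(cfg.rng.multiplier, cfg.rng.modulus, task.stream_state)
    props = cfg.phantom.optical.properties()
    pencil = (
        np.asarray(cfg.source.direction, dtype=float)
        if cfg.source.emission == "pencil"
        else None
    )
    # every worker uses the packet weight of the whole run (P / N_total)
    result: TissueResult = run_tissue(
        phantom_radius=cfg.phantom.radius,
        phantom_height=cfg.phantom.height,
        props=props,
        n_outside=cfg.phantom.n_outside,
        source=cfg.source_region(),
        total_power=cfg.source.total_power,
        n_photons=task.n_photons,
        packet_weight=cfg.source.total_power / cfg.photons,
        rng=state,
        pencil_direction=pencil,
        roulette_threshold_frac=cfg.roulette.threshold_frac,
        roulette_chance=cfg.roulette.chance,
        max_events=cfg.max_events,
        draw_limit=task.draw_limit,
    )
    return WorkerPartial(
        index=task.index,
        exits=result.exits,
        ledger=result.ledger,
        draws=result.draws,
        n_photons=task.n_photons,
        wall_time=time.perf_counter() - t0,
        config_hash=config_hash(cfg),
    )


def merge(partials: list[WorkerPartial]) -> MergedResult:
    """Merge worker partials in index order; ledgers sum fieldwise."""
    if not partials:
        raise MergeError("nothing to merge")
    hashes = {p.config_hash for p in partials}
    if len(hashes) != 1:
        raise MergeError("partial results come from different configurations")
    ordered = sorted(partials, key=lambda p: p.index)
    ledger = WeightLedger()
    for p in ordered:
        ledger = ledger.add(p.ledger)
    exits = ExitRecords.concatenate(p.exits for p in ordered)
    diagnostics = [
        {
            "worker": p.index,
            "photons": p.n_photons,
            "exits": len(p.exits),
            "draws": p.draws,
            "wall_time_s": p.wall_time,
        }
        for p in ordered
    ]
    return MergedResult(
        exits=exits,
        ledger=ledger,
        config_hash=ordered[0].config_hash,
        diagnostics=diagnostics,
    )


def run_parallel(config: RunConfig, n_workers: Optional[int] = None) -> MergedResult:
    """Execute the tissue stage on ``n_workers`` processes and merge."""
    n_workers = n_workers or config.workers
    tasks = partition(
        config.photons, n_workers, config.seed, config.rng.draw_budget, config
    )
    if n_workers == 1:
        partials = [execute_task(tasks[0])]
    else:
        ctx = get_context("fork")
        with ctx.Pool(processes=n_workers) as pool:
            partials = pool.map(execute_task, tasks)
    return merge(partials)
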