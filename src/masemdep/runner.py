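"""Orchestration of the simulation study.

Every replication draws one dataset and feeds the *same* dataset to every
requested strategy (paired comparison), so strategy contrasts are free of
between-dataset Monte-Carlo noise.  Seeds derive deterministically from
(master seed, condition id, replication index), which makes any cell of the
design independently reproducible and the results invariant to worker count
and evaluation order.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .metrics import PARAM_NAMES, ConditionSummary, ReplicationRecord, summarize
from .population_model import Condition
from .simulate import generate_meta_dataset
from .strategies import ALL_STRATEGIES, apply_strategy
from .tssem import STATUS_FAILED, Z_CRIT, pseudo_true_paths, stage1_fit, stage2_fit
from .wpl import wpl_stage1_fit


@dataclass
class RunConfig:
    conditions: Sequence[Condition]
    strategies: Sequence[str] = ALL_STRATEGIES
    replications: int = 1000
    seed: int = 0
    n_workers: int = 1
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        unknown = set(self.strategies) - set(ALL_STRATEGIES)
        if unknown:
            raise ValueError(f"unknown strategies {sorted(unknown)}")


def _seed_sequence(master: int, condition_id: str, rep: int, extra: int = 0):
    key = zlib.crc32(condition_id.encode())
    return np.random.SeedSequence([master, key, rep, extra])


def replication_seed(master: int, condition_id: str, rep: int) -> int:
    """Deterministic dataset seed below 2^31 for one design-cell replication."""
    return int(_seed_sequence(master, condition_id, rep).generate_state(1)[0] & 0x7FFFFFFF)


def run_replication(
    condition: Condition,
    rep: int,
    master_seed: int,
    strategies: Sequence[str],
) -> list[ReplicationRecord]:
    """Generate one dataset and fit both stages under every strategy."""
    seed = replication_seed(master_seed, condition.id, rep)
    dataset = generate_meta_dataset(condition, seed)
    nan6 = np.full(6, np.nan)
    records = []
    for s_idx, strategy in enumerate(strategies):
        rng = np.random.default_rng(
            _seed_sequence(master_seed, condition.id, rep, 1 + s_idx)
        )
        try:
            if strategy == "wpl":
                st1 = wpl_stage1_fit(dataset, rng=rng).as_stage1()
            else:
                reduced = apply_strategy(dataset, strategy, rng=rng)
                st1 = stage1_fit(reduced, rng=rng)
            st2 = stage2_fit(st1, rng=rng)
            rec = ReplicationRecord(
                condition_id=condition.id,
                strategy=strategy,
                replication=rep,
                estimates=st2.estimates,
                se=st2.se,
                ci_low=st2.ci_low,
                ci_high=st2.ci_high,
                reject=np.abs(st2.z) > Z_CRIT,
                stage1_status=st1.status,
                stage2_status=st2.status,
            )
        except Exception:
            rec = ReplicationRecord(
                condition_id=condition.id, strategy=strategy, replication=rep,
                estimates=nan6, se=nan6, ci_low=nan6, ci_high=nan6,
                reject=np.zeros(6, dtype=bool),
                stage1_status=STATUS_FAILED, stage2_status=STATUS_FAILED,
            )
        records.append(rec)
    return records


def run(config: RunConfig) -> tuple[pd.DataFrame, list[ReplicationRecord]]:
    """Execute the configured design; returns the tidy summary table (one row
    per condition x strategy x parameter) and all replication records."""
    all_records: list[ReplicationRecord] = []
    summaries: list[ConditionSummary] = []
    for condition in config.conditions:
        if config.n_workers > 1:
            from joblib import Parallel, delayed

            per_rep = Parallel(n_jobs=config.n_workers)(
                delayed(run_replication)(condition, rep, config.seed, config.strategies)
                for rep in range(config.replications)
            )
        else:
            per_rep = [
                run_replication(condition, rep, config.seed, config.strategies)
                for rep in range(config.replications)
            ]
        cond_records = [rec for batch in per_rep for rec in batch]
        all_records.extend(cond_records)
        truth = pseudo_true_paths(condition)
        for strategy in config.strategies:
            summaries.append(
                summarize(
                    [r for r in cond_records if r.strategy == strategy], truth
                )
            )
    summary_df = summaries_to_frame(summaries)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary_df.to_csv(out / "summaries.csv", index=False)
        records_to_frame(all_records).to_csv(out / "replications.csv", index=False)
    return summary_df, all_records


def summaries_to_frame(summaries: Sequence[ConditionSummary]) -> pd.DataFrame:
    frames = []
    for s in summaries:
        t = s.table.copy()
        t.insert(0, "condition", s.condition_id)
        t.insert(1, "strategy", s.strategy)
        t["convergence_rate"] = s.convergence_rate
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def records_to_frame(records: Sequence[ReplicationRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {
            "condition": rec.condition_id,
            "strategy": rec.strategy,
            "replication": rec.replication,
            "stage1_status": rec.stage1_status,
            "stage2_status": rec.stage2_status,
        }
        for i, name in enumerate(PARAM_NAMES):
            row[f"est_{name}"] = rec.estimates[i]
            row[f"se_{name}"] = rec.se[i]
            row[f"reject_{name}"] = bool(rec.reject[i])
        rows.append(row)
    return pd.DataFrame(rows)
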