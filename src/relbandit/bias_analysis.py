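"""Behavioral statistics: maximization accuracy, relative-value choice rates
against the ideal agent, congruency breakdowns, and cell-level summary tables.

*Relative value bias* is a higher-relative-value choice rate in the transfer
test that exceeds what an ideal EV-maximizing agent would produce; since the
ideal agent picks the frequent winner on every congruent pair and never on an
incongruent pair, bias can only arise from "wrong" choices on incongruent
pairs.  Rates are computed per run and pooled with equal weight per run; the
95% CI across runs is t-based, and a cell is flagged biased when the CI's
lower bound exceeds the ideal rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .task_designs import (
    CONGRUENT,
    INCONGRUENT,
    REL_TIED,
    TaskSpec,
    TransferPairClass,
    classify_transfer_pairs,
    expected_value,
    ideal_choice_rate,
)

__all__ = [
    "CellSummary",
    "BiasTest",
    "CongruencyBreakdown",
    "choice_accuracy",
    "per_session_rel_rates",
    "rel_value_choice_rate",
    "bias_test",
    "congruency_breakdown",
    "summarize_cells",
]


def _pair_lookup(classification) -> dict[frozenset, TransferPairClass]:
    return {frozenset(c.pair): c for c in classification}


def choice_accuracy(session, task: TaskSpec, phase: str) -> float | None:
    """Proportion of reward-maximizing choices among the session's valid
    trials in ``phase``.  Trials whose presented options tie on expected value
    are excluded; returns ``None`` when no trials remain (undefined, not 0)."""
    evs = {o.option_id: expected_value(o) for o in task.options}
    n = 0
    correct = 0
    for t in session.trials:
        if t.phase != phase or not t.valid:
            continue
        vals = [evs[o] for o in t.presented_option_ids]
        best = max(vals)
        if sum(math.isclose(v, best, rel_tol=1e-12, abs_tol=1e-12)
               for v in vals) > 1:
            continue  # equal-EV trial: maximizing choice undefined
        n += 1
        correct += int(math.isclose(evs[t.chosen_option_id], best,
                                    rel_tol=1e-12, abs_tol=1e-12))
    return correct / n if n else None


def per_session_rel_rates(sessions, classification) -> list[float]:
    """Per-run rate of choosing the higher-relative-value option on non-tied
    valid transfer trials (runs without such trials are skipped)."""
    lookup = _pair_lookup(classification)
    rates = []
    for s in sessions:
        n = 0
        hits = 0
        for t in s.trials:
            if t.phase != "transfer" or not t.valid:
                continue
            cls = lookup[frozenset(t.presented_option_ids)]
            if cls.label == REL_TIED or cls.rel_winner is None:
                continue
            n += 1
            hits += int(t.chosen_option_id == cls.rel_winner)
        if n:
            rates.append(hits / n)
    return rates


def rel_value_choice_rate(sessions, classification) -> float:
    """Mean across runs of the per-run higher-relative-value choice rate."""
    rates = per_session_rel_rates(sessions, classification)
    if not rates:
        raise ValueError("no transfer trials with distinct relative values")
    return float(np.mean(rates))


@dataclass(frozen=True)
class BiasTest:
    """Run-level mean choice rate with t-based 95% CI against the ideal rate."""

    mean: float
    ci_low: float
    ci_high: float
    ideal_rate: float
    n_runs: int
    biased: bool


def bias_test(rates, ideal_rate: float, confidence: float = 0.95) -> BiasTest:
    """Flag relative value bias when the CI lower bound exceeds the ideal rate.

    With zero variance across runs the CI degenerates to the point estimate
    and the flag falls back to a strict inequality.
    """
    rates = np.asarray(rates, dtype=float)
    n = rates.size
    if n < 2:
        raise ValueError("bias test needs at least 2 runs")
    mean = float(rates.mean())
    sd = float(rates.std(ddof=1))
    if sd == 0.0:
        lo = hi = mean
    else:
        half = stats.t.ppf(0.5 + confidence / 2.0, n - 1) * sd / math.sqrt(n)
        lo, hi = mean - half, mean + half
    return BiasTest(mean=mean, ci_low=lo, ci_high=hi, ideal_rate=ideal_rate,
                    n_runs=n, biased=lo > ideal_rate)


@dataclass(frozen=True)
class CongruencyBreakdown:
    """Maximization accuracy split by transfer-pair congruency (pooled trials)."""

    congruent_accuracy: float | None
    incongruent_accuracy: float | None
    n_congruent_trials: int
    n_incongruent_trials: int


def congruency_breakdown(sessions, classification) -> CongruencyBreakdown:
    """Accuracy on congruent vs incongruent transfer trials.  A task without
    incongruent pairs yields an explicitly empty incongruent cell."""
    lookup = _pair_lookup(classification)
    counts = {CONGRUENT: [0, 0], INCONGRUENT: [0, 0]}  # [n, correct]
    for s in sessions:
        for t in s.trials:
            if t.phase != "transfer" or not t.valid:
                continue
            cls = lookup[frozenset(t.presented_option_ids)]
            if cls.label not in counts:
                continue
            counts[cls.label][0] += 1
            counts[cls.label][1] += int(t.chosen_option_id == cls.ev_winner)
    n_c, ok_c = counts[CONGRUENT]
    n_i, ok_i = counts[INCONGRUENT]
    return CongruencyBreakdown(
        congruent_accuracy=ok_c / n_c if n_c else None,
        incongruent_accuracy=ok_i / n_i if n_i else None,
        n_congruent_trials=n_c,
        n_incongruent_trials=n_i)


@dataclass(frozen=True)
class CellSummary:
    """Summary of one task x agent x prompt-condition cell."""

    task: str
    agent: str
    prompt_condition: str
    n_runs: int
    learning_accuracy: float | None
    transfer_accuracy: float | None
    rel_rate_mean: float
    rel_rate_ci: tuple[float, float]
    ideal_rate: float
    biased: bool


def summarize_cells(sessions, tasks: dict[str, TaskSpec]) -> pd.DataFrame:
    """Table of per-cell accuracies and relative-value bias tests.

    ``tasks`` maps task names to their specs.  Cells with fewer than 2 runs
    are skipped (no CI is defined).
    """
    by_cell: dict[tuple, list] = {}
    for s in sessions:
        by_cell.setdefault((s.task_name, s.agent, s.prompt_condition), []).append(s)
    rows = []
    for (task_name, agent, cond), cell_sessions in sorted(by_cell.items()):
        task = tasks[task_name]
        if len(cell_sessions) < 2:
            continue
        classification = classify_transfer_pairs(task)
        ideal = ideal_choice_rate(task)
        rates = per_session_rel_rates(cell_sessions, classification)
        bt = bias_test(rates, ideal)
        learn = [a for a in (choice_accuracy(s, task, "learning")
                             for s in cell_sessions) if a is not None]
        transfer = [a for a in (choice_accuracy(s, task, "transfer")
                                for s in cell_sessions) if a is not None]
        rows.append({
            "prompt_condition": cond, "task": task_name, "agent": agent,
            "n_runs": len(cell_sessions),
            "learning_accuracy": float(np.mean(learn)) if learn else None,
            "transfer_accuracy": float(np.mean(transfer)) if transfer else None,
            "ideal_rate": ideal, "rel_rate_mean": bt.mean,
            "rel_rate_ci_low": bt.ci_low, "rel_rate_ci_high": bt.ci_high,
            "biased": bt.biased,
        })
    return pd.DataFrame(rows)
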