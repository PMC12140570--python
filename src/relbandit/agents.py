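"""Generative agents: run the cognitive models (plus ideal and uniform-random
reference agents) forward through a task to produce choice sessions with known
ground truth.

A session is one independent run: a seeded learning schedule with complete
feedback, followed by the transfer test in shuffled order, with the
presentation order of options randomized on every trial (the first-listed
option is the one receiving the softmax position bias).  Display letters A-J
are assigned per run; analysis code operates on stable option ids.

Synthetic agents do not emit text.  The ``prompt_condition`` tag is carried as
metadata so grids mirror the task x agent x prompt factorial of a text-based
experiment; the behavioral effect of explicit outcome comparisons is emulated
by raising the relative encoding weight of the generating agent, not by
changing the simulator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cogmodel import (
    Q_INIT,
    AgentParams,
    EncodingState,
    ModelSpec,
    choice_probabilities,
    encode_outcomes,
    update_expectancies,
)
from .task_designs import (
    TaskSpec,
    build_learning_schedule,
    build_transfer_schedule,
    expected_value,
)

__all__ = [
    "TrialRecord",
    "SessionData",
    "simulate_session",
    "simulate_ideal",
    "simulate_grid",
    "uniform_random_params",
    "emulated_llm_params",
    "save_sessions_jsonl",
    "load_sessions_jsonl",
]

LETTERS = "ABCDEFGHIJ"


@dataclass
class TrialRecord:
    """One trial of a session.  Learning records carry the complete-feedback
    outcome of every presented option; transfer records carry none."""

    phase: str  # "learning" | "transfer"
    presented_option_ids: tuple[str, ...]  # prompt order; first carries the bias
    chosen_option_id: str
    context_id: str | None = None
    outcomes: dict[str, float] | None = None
    valid: bool = True

    def __post_init__(self) -> None:
        if self.phase == "learning" and self.outcomes is not None:
            missing = set(self.presented_option_ids) - set(self.outcomes)
            if missing:
                raise ValueError(f"learning trial missing outcomes for {missing}")
        if self.phase == "transfer" and self.outcomes is not None:
            raise ValueError("transfer trials carry no outcomes")
        if self.chosen_option_id is not None \
                and self.chosen_option_id not in self.presented_option_ids:
            raise ValueError("chosen option must be among the presented options")


@dataclass
class SessionData:
    """One simulated (or ingested) run of a task."""

    task_name: str
    agent: str
    seed: int | None
    prompt_condition: str
    trials: list[TrialRecord]
    label_assignment: dict[str, str] = field(default_factory=dict)

    def phase_trials(self, phase: str) -> list[TrialRecord]:
        return [t for t in self.trials if t.phase == phase]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _assign_labels(task: TaskSpec, rng: np.random.Generator) -> dict[str, str]:
    letters = list(LETTERS[: task.n_options])
    rng.shuffle(letters)
    return dict(zip(task.option_ids, letters))


def _seed_repr(seed) -> int | None:
    if isinstance(seed, (int, np.integer)):
        return int(seed)
    if isinstance(seed, np.random.SeedSequence) and isinstance(seed.entropy, int):
        return int(seed.entropy) & 0x7FFFFFFF
    return None


def simulate_session(task: TaskSpec, agent: AgentParams, seed,
                     prompt_condition: str = "standard") -> SessionData:
    """Run one cognitive agent generatively through a task.

    Choices are sampled from the softmax stage; expectancies start at 0.5,
    evolve by the encoding/updating stages during learning only, and are
    frozen (with ``beta_transfer``) in the transfer test.
    """
    rng = _as_rng(seed)
    labels = _assign_labels(task, rng)
    schedule = build_learning_schedule(task, rng)
    q = {oid: Q_INIT for oid in task.option_ids}
    state = EncodingState()
    trials: list[TrialRecord] = []

    for plan in schedule:
        members = list(plan.outcomes.keys())
        order = [members[i] for i in rng.permutation(len(members))]
        probs = choice_probabilities([q[o] for o in order],
                                     agent.beta_learn, agent.position_bias)
        choice = order[rng.choice(len(order), p=probs)]
        trials.append(TrialRecord(phase="learning", context_id=plan.context_id,
                                  presented_option_ids=tuple(order),
                                  outcomes=dict(plan.outcomes),
                                  chosen_option_id=choice))
        v, state = encode_outcomes([plan.outcomes[o] for o in order],
                                   state, agent.omega)
        q = update_expectancies(q, dict(zip(order, v)), choice,
                                agent.alpha_con, agent.alpha_dis)

    pairs = build_transfer_schedule(task)
    for i in rng.permutation(len(pairs)):
        pair = list(pairs[i])
        order = [pair[j] for j in rng.permutation(len(pair))]
        probs = choice_probabilities([q[o] for o in order],
                                     agent.beta_transfer, agent.position_bias)
        choice = order[rng.choice(len(order), p=probs)]
        trials.append(TrialRecord(phase="transfer",
                                  presented_option_ids=tuple(order),
                                  chosen_option_id=choice))

    return SessionData(task_name=task.name, agent=agent.model.name,
                       seed=_seed_repr(seed), prompt_condition=prompt_condition,
                       trials=trials, label_assignment=labels)


def simulate_ideal(task: TaskSpec, seed,
                   prompt_condition: str = "standard") -> SessionData:
    """Reference agent that always picks the presented option with the highest
    expected value (seeded coin flip on exact EV ties)."""
    rng = _as_rng(seed)
    labels = _assign_labels(task, rng)
    evs = {o.option_id: expected_value(o) for o in task.options}
    trials: list[TrialRecord] = []

    def pick(order: list[str]) -> str:
        best = max(evs[o] for o in order)
        top = [o for o in order if evs[o] == best]
        return top[0] if len(top) == 1 else top[rng.integers(len(top))]

    for plan in build_learning_schedule(task, rng):
        members = list(plan.outcomes.keys())
        order = [members[i] for i in rng.permutation(len(members))]
        trials.append(TrialRecord(phase="learning", context_id=plan.context_id,
                                  presented_option_ids=tuple(order),
                                  outcomes=dict(plan.outcomes),
                                  chosen_option_id=pick(order)))
    pairs = build_transfer_schedule(task)
    for i in rng.permutation(len(pairs)):
        pair = list(pairs[i])
        order = [pair[j] for j in rng.permutation(len(pair))]
        trials.append(TrialRecord(phase="transfer",
                                  presented_option_ids=tuple(order),
                                  chosen_option_id=pick(order)))
    return SessionData(task_name=task.name, agent="ideal",
                       seed=_seed_repr(seed), prompt_condition=prompt_condition,
                       trials=trials, label_assignment=labels)


def uniform_random_params() -> AgentParams:
    """Agent choosing uniformly at random (beta = 0, no position bias)."""
    return AgentParams.create(ModelSpec(relative_encoding=False),
                              alpha=0.0, beta=0.0, position_bias=0.0)


def emulated_llm_params(omega: float = 0.11, *, alpha_con: float = 0.5,
                        alpha_dis: float = 0.16, beta_learn: float = 18.0,
                        beta_transfer: float = 11.0,
                        position_bias: float = 1.2) -> AgentParams:
    """Hybrid-encoding agent with magnitudes typical of instruction-tuned
    in-context learners on these tasks: confirmation-biased learning rates,
    a higher inverse temperature during learning than transfer, and a positive
    first-listed position bias.  The effect of explicit outcome comparisons in
    the prompt is emulated by raising ``omega`` (the default 0.11 reflects the
    standard prompt; around 0.26 reflects the comparison prompt)."""
    return AgentParams.create(ModelSpec(True, 2, 2), omega=omega,
                              alpha=alpha_con, alpha_dis=alpha_dis,
                              beta=beta_learn, beta_transfer=beta_transfer,
                              position_bias=position_bias)


def simulate_grid(tasks, agents, prompt_conditions, n_reps: int,
                  base_seed: int) -> tuple[list[SessionData], pd.DataFrame]:
    """One session per task x agent x prompt-condition x repetition.

    ``agents`` maps a descriptor name to an :class:`AgentParams`, the string
    ``"ideal"``, or a dict keyed by prompt condition (so an agent can use,
    e.g., a higher relative encoding weight under the comparison prompt).
    Per-session seeds derive from ``base_seed`` by spawning a
    :class:`numpy.random.SeedSequence`, so any cell is reproducible in
    isolation and the manifest is byte-identical across calls.
    """
    tasks = list(tasks)
    agent_items = list(agents.items())
    conditions = list(prompt_conditions)
    cells = [(t, name, cond, rep)
             for t in tasks for name, _ in agent_items
             for cond in conditions for rep in range(n_reps)]
    children = np.random.SeedSequence(base_seed).spawn(len(cells))
    sessions: list[SessionData] = []
    rows = []
    for sid, ((task, name, cond, rep), child) in enumerate(zip(cells, children)):
        spec = agents[name]
        if isinstance(spec, dict):
            spec = spec[cond]
        if isinstance(spec, str) and spec == "ideal":
            sess = simulate_ideal(task, child, prompt_condition=cond)
        else:
            sess = simulate_session(task, spec, child, prompt_condition=cond)
        sess.agent = name
        sessions.append(sess)
        rows.append({"session_id": sid, "task": task.name, "agent": name,
                     "prompt_condition": cond, "rep": rep,
                     "n_trials": len(sess.trials)})
    return sessions, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Serialization: JSONL session logs (also the ingest format for real LLM logs)
# ---------------------------------------------------------------------------

def save_sessions_jsonl(sessions, path) -> None:
    """One "session" record followed by one record per trial, per session."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in sessions:
            head = {"type": "session", "task": s.task_name, "agent": s.agent,
                    "seed": s.seed, "prompt_condition": s.prompt_condition,
                    "labels": s.label_assignment}
            fh.write(json.dumps(head) + "\n")
            for t in s.trials:
                rec = asdict(t)
                rec["type"] = "trial"
                rec["presented_option_ids"] = list(t.presented_option_ids)
                fh.write(json.dumps(rec) + "\n")


def load_sessions_jsonl(path) -> list[SessionData]:
    sessions: list[SessionData] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            rec = json.loads(line)
            if rec["type"] == "session":
                sessions.append(SessionData(
                    task_name=rec["task"], agent=rec["agent"],
                    seed=rec["seed"], prompt_condition=rec["prompt_condition"],
                    trials=[], label_assignment=rec.get("labels", {})))
            elif rec["type"] == "trial":
                sessions[-1].trials.append(TrialRecord(
                    phase=rec["phase"],
                    presented_option_ids=tuple(rec["presented_option_ids"]),
                    chosen_option_id=rec["chosen_option_id"],
                    context_id=rec.get("context_id"),
                    outcomes=rec.get("outcomes"),
                    valid=rec.get("valid", True)))
            else:
                raise ValueError(f"unknown record type {rec['type']!r}")
    return sessions
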