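"""Bandit task structures: options, learning contexts, schedules, and the
ideal-agent reference statistics.

A task consists of options grouped into fixed *learning contexts* (pairs or
triplets always presented together with complete feedback), followed by a
*transfer test* over all unordered option pairs without feedback.  Within a
context, the *frequent winner* — the option whose draws beat its partners'
draws more often than not — defines "higher relative value".  A transfer pair
is *congruent* when the frequent winner is also the expected-value maximizer
and *incongruent* when it is not; the rate at which an ideal (EV-maximizing)
agent picks the frequent winner over the non-tied pairs is the reference
against which relative value bias is measured.

Five tasks from the source studies ship as packaged YAML configs
(``builtin_task_names()``); arbitrary tasks load from the same format.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.stats import norm

__all__ = [
    "RewardModel",
    "OptionSpec",
    "ContextSpec",
    "TaskSpec",
    "TransferPairClass",
    "LearningTrialPlan",
    "TaskValidationError",
    "builtin_task_names",
    "load_task_spec",
    "expected_value",
    "win_probability",
    "relative_order",
    "relative_ranks",
    "build_learning_schedule",
    "build_transfer_schedule",
    "classify_transfer_pairs",
    "ideal_choice_rate",
]

BUILTIN_TASKS = ("B2018", "V2023", "HW2023a", "BP2023", "HW2023b")

# Congruency labels
CONGRUENT = "congruent"
INCONGRUENT = "incongruent"
REL_TIED = "rel_tied"
EV_TIED = "ev_tied"  # EV tied but relative ranks differ; no built-in task has one


class TaskValidationError(ValueError):
    """A task configuration violates a structural rule (the message names it)."""


@dataclass(frozen=True)
class RewardModel:
    """Outcome distribution of one option (Bernoulli two-point or Gaussian)."""

    kind: str
    win_prob: float | None = None
    hi_value: float | None = None
    lo_value: float | None = None
    mean: float | None = None
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "bernoulli":
            if self.win_prob is None or self.hi_value is None or self.lo_value is None:
                raise TaskValidationError(
                    "bernoulli reward requires win_prob, hi_value, lo_value")
            if not 0.0 <= self.win_prob <= 1.0:
                raise TaskValidationError(
                    f"win_prob must lie in [0, 1], got {self.win_prob}")
            if not self.hi_value > self.lo_value:
                raise TaskValidationError(
                    f"hi_value must exceed lo_value, got {self.hi_value} <= {self.lo_value}")
        elif self.kind == "gaussian":
            if self.mean is None or self.sd is None:
                raise TaskValidationError("gaussian reward requires mean and sd")
            if not self.sd > 0:
                raise TaskValidationError(f"sd must be positive, got {self.sd}")
        else:
            raise TaskValidationError(
                f"reward kind must be 'bernoulli' or 'gaussian', got {self.kind!r}")


@dataclass(frozen=True)
class OptionSpec:
    option_id: str
    reward: RewardModel


@dataclass(frozen=True)
class ContextSpec:
    context_id: str
    member_option_ids: tuple[str, ...]
    n_learning_trials: int

    def __post_init__(self) -> None:
        if len(self.member_option_ids) not in (2, 3):
            raise TaskValidationError(
                f"context {self.context_id!r} must have 2 or 3 members, "
                f"got {len(self.member_option_ids)}")
        if self.n_learning_trials < 1:
            raise TaskValidationError(
                f"context {self.context_id!r} needs n_learning_trials >= 1")


@dataclass(frozen=True)
class TaskSpec:
    """Full structural description of one bandit task."""

    name: str
    options: tuple[OptionSpec, ...]
    contexts: tuple[ContextSpec, ...]
    transfer_reps: int = 1
    currency: str = "points"

    def __post_init__(self) -> None:
        ids = [o.option_id for o in self.options]
        if len(set(ids)) != len(ids):
            raise TaskValidationError(f"duplicate option ids in task {self.name!r}")
        members = [m for c in self.contexts for m in c.member_option_ids]
        if sorted(members) != sorted(ids):
            raise TaskValidationError(
                f"contexts must partition the option set in task {self.name!r}")
        if self.transfer_reps < 1:
            raise TaskValidationError("transfer_reps must be >= 1")

    # -- convenience accessors -------------------------------------------
    @property
    def option_ids(self) -> tuple[str, ...]:
        return tuple(o.option_id for o in self.options)

    @property
    def n_options(self) -> int:
        return len(self.options)

    @property
    def n_learning_trials(self) -> int:
        return sum(c.n_learning_trials for c in self.contexts)

    def option(self, option_id: str) -> OptionSpec:
        for o in self.options:
            if o.option_id == option_id:
                return o
        raise KeyError(option_id)

    def context_of(self, option_id: str) -> ContextSpec:
        for c in self.contexts:
            if option_id in c.member_option_ids:
                return c
        raise KeyError(option_id)

    def with_learning_trials(self, n_per_context: int) -> "TaskSpec":
        """Copy of the task with every context's learning-trial count replaced."""
        return replace(
            self,
            contexts=tuple(replace(c, n_learning_trials=n_per_context)
                           for c in self.contexts),
        )


@dataclass(frozen=True)
class TransferPairClass:
    """Congruency classification of one unordered transfer pair."""

    pair: tuple[str, str]
    ev_winner: str | None
    rel_winner: str | None
    label: str
    ev_tied: bool


@dataclass(frozen=True)
class LearningTrialPlan:
    """One scheduled learning trial: the context shown and the pre-drawn
    outcome of every member option (complete feedback)."""

    context_id: str
    outcomes: dict[str, float] = field(hash=False)


# ---------------------------------------------------------------------------
# Loading / validation
# ---------------------------------------------------------------------------

def builtin_task_names() -> tuple[str, ...]:
    return BUILTIN_TASKS


def _parse_task_dict(doc: dict) -> TaskSpec:
    if not isinstance(doc, dict):
        raise TaskValidationError("task config must be a mapping")
    for key in ("name", "contexts"):
        if key not in doc:
            raise TaskValidationError(f"task config missing required key {key!r}")
    options: list[OptionSpec] = []
    contexts: list[ContextSpec] = []
    for ctx in doc["contexts"]:
        member_ids = []
        for opt in ctx.get("options", []):
            reward = RewardModel(**opt["reward"])
            options.append(OptionSpec(option_id=str(opt["id"]), reward=reward))
            member_ids.append(str(opt["id"]))
        contexts.append(ContextSpec(
            context_id=str(ctx["id"]),
            member_option_ids=tuple(member_ids),
            n_learning_trials=int(ctx["n_learning_trials"]),
        ))
    return TaskSpec(
        name=str(doc["name"]),
        options=tuple(options),
        contexts=tuple(contexts),
        transfer_reps=int(doc.get("transfer_reps", 1)),
        currency=str(doc.get("currency", "points")),
    )


def load_task_spec(source: str | Path | dict) -> TaskSpec:
    """Load a task by built-in name, from a YAML/JSON file path, or a dict.

    Raises
    ------
    TaskValidationError
        If the config violates a structural rule; the message names the rule.
    KeyError
        If ``source`` is a string that is neither a built-in name nor a path.
    """
    if isinstance(source, dict):
        return _parse_task_dict(source)
    if isinstance(source, Path) or (isinstance(source, str) and
                                    source.endswith((".yaml", ".yml", ".json"))):
        with open(source, "r", encoding="utf-8") as fh:
            return _parse_task_dict(yaml.safe_load(fh))
    if source in BUILTIN_TASKS:
        ref = resources.files("relbandit").joinpath(f"data/tasks/{source}.yaml")
        return _parse_task_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))
    raise KeyError(
        f"unknown task {source!r}; built-ins are {', '.join(BUILTIN_TASKS)}")


# ---------------------------------------------------------------------------
# Distribution-level statistics
# ---------------------------------------------------------------------------

def expected_value(option: OptionSpec) -> float:
    """Expected reward of one option in task currency."""
    r = option.reward
    if r.kind == "bernoulli":
        return r.win_prob * r.hi_value + (1.0 - r.win_prob) * r.lo_value
    return r.mean


def _support(r: RewardModel) -> list[tuple[float, float]]:
    """(value, probability) atoms of a Bernoulli reward."""
    return [(r.hi_value, r.win_prob), (r.lo_value, 1.0 - r.win_prob)]


def win_probability(opt_i: OptionSpec, opt_j: OptionSpec) -> float:
    """P(draw from ``opt_i`` strictly exceeds an independent draw from ``opt_j``)."""
    ri, rj = opt_i.reward, opt_j.reward
    if ri.kind == "bernoulli" and rj.kind == "bernoulli":
        return sum(pi * pj
                   for xi, pi in _support(ri)
                   for xj, pj in _support(rj)
                   if xi > xj)
    if ri.kind == "gaussian" and rj.kind == "gaussian":
        return float(norm.sf(0.0, loc=ri.mean - rj.mean,
                             scale=math.hypot(ri.sd, rj.sd)))
    if ri.kind == "bernoulli":  # discrete vs gaussian
        return sum(pi * float(norm.cdf(xi, loc=rj.mean, scale=rj.sd))
                   for xi, pi in _support(ri))
    # gaussian vs bernoulli
    return sum(pj * float(norm.sf(xj, loc=ri.mean, scale=ri.sd))
               for xj, pj in _support(rj))


def relative_order(context: ContextSpec, task: TaskSpec) -> dict[str, float]:
    """Within-context relative rank of each member option, scaled to [0, 1].

    Option i ranks above option j when it is the *frequent winner* of the
    pairing, i.e. P(i > j) > P(j > i) (draws that tie are ignored, so a
    Bernoulli option can be the frequent winner even when most trials tie).
    Binary contexts yield ranks {0, 1} (or {0.5, 0.5} when tied); ternary
    contexts yield {0, 0.5, 1} with analogous tie handling.

    Raises
    ------
    ValueError
        If the pairwise frequent-winner relation is intransitive (cannot
        happen in any built-in task).
    """
    members = context.member_option_ids
    opts = {m: task.option(m) for m in members}
    n = len(members)
    wins = {m: 0.0 for m in members}
    beats: dict[tuple[str, str], int] = {}
    for a, b in itertools.combinations(members, 2):
        p_ab = win_probability(opts[a], opts[b])
        p_ba = win_probability(opts[b], opts[a])
        if p_ab > p_ba:
            rel = 1
        elif p_ba > p_ab:
            rel = -1
        else:
            rel = 0
        beats[(a, b)] = rel
        beats[(b, a)] = -rel
        if rel == 1:
            wins[a] += 1.0
        elif rel == -1:
            wins[b] += 1.0
        else:
            wins[a] += 0.5
            wins[b] += 0.5
    ranks = {m: wins[m] / (n - 1) for m in members}
    # Consistency check: the win-count ordering must reproduce every pairwise
    # relation, otherwise the relation is cyclic.
    for (a, b), rel in beats.items():
        if rel == 1 and not ranks[a] > ranks[b]:
            raise ValueError(
                f"intransitive frequent-winner relation in context "
                f"{context.context_id!r}")
        if rel == 0 and ranks[a] != ranks[b]:
            raise ValueError(
                f"intransitive frequent-winner relation in context "
                f"{context.context_id!r}")
    return ranks


def relative_ranks(task: TaskSpec) -> dict[str, float]:
    """Relative rank of every option in the task, from its own context."""
    out: dict[str, float] = {}
    for ctx in task.contexts:
        out.update(relative_order(ctx, task))
    return out


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def build_learning_schedule(
    task: TaskSpec, seed: int | np.random.SeedSequence | np.random.Generator,
) -> list[LearningTrialPlan]:
    """Seeded learning-phase schedule with pre-drawn complete feedback.

    Context presentations are randomly interleaved.  Bernoulli outcome
    sequences are *exact-frequency*: each option's count of high outcomes over
    its trials equals ``round(win_prob * n)`` exactly (round-half-up with a
    warning when ``win_prob * n`` is not an integer; no built-in task triggers
    this).  Gaussian outcomes are independent draws.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    order = [c.context_id for c in task.contexts for _ in range(c.n_learning_trials)]
    rng.shuffle(order)

    streams: dict[str, list[float]] = {}
    for ctx in task.contexts:
        n = ctx.n_learning_trials
        for m in ctx.member_option_ids:
            r = task.option(m).reward
            if r.kind == "bernoulli":
                exact = r.win_prob * n
                k = _round_half_up(exact)
                if abs(exact - k) > 1e-9:
                    warnings.warn(
                        f"win_prob*n = {exact:.4g} is not an integer for option "
                        f"{m!r}; using {k} high outcomes (round half up)",
                        stacklevel=2)
                vals = np.array([r.hi_value] * k + [r.lo_value] * (n - k))
                rng.shuffle(vals)
            else:
                vals = rng.normal(r.mean, r.sd, size=n)
            streams[m] = list(vals)

    by_ctx = {c.context_id: c for c in task.contexts}
    cursor = {c.context_id: 0 for c in task.contexts}
    schedule = []
    for cid in order:
        i = cursor[cid]
        cursor[cid] = i + 1
        outcomes = {m: float(streams[m][i]) for m in by_ctx[cid].member_option_ids}
        schedule.append(LearningTrialPlan(context_id=cid, outcomes=outcomes))
    return schedule


def build_transfer_schedule(task: TaskSpec) -> list[tuple[str, str]]:
    """All unordered option pairs, repeated ``transfer_reps`` times, in a
    deterministic canonical order (per-session shuffling happens at
    simulation time)."""
    pairs = list(itertools.combinations(task.option_ids, 2))
    return pairs * task.transfer_reps


# ---------------------------------------------------------------------------
# Congruency classification and the ideal-agent reference rate
# ---------------------------------------------------------------------------

def classify_transfer_pairs(task: TaskSpec) -> list[TransferPairClass]:
    """Label every unordered transfer pair as congruent / incongruent /
    rel_tied (or ev_tied for the degenerate equal-EV case)."""
    ranks = relative_ranks(task)
    evs = {o.option_id: expected_value(o) for o in task.options}
    out = []
    for a, b in itertools.combinations(task.option_ids, 2):
        ev_tied = math.isclose(evs[a], evs[b], rel_tol=1e-12, abs_tol=1e-12)
        ev_winner = None if ev_tied else (a if evs[a] > evs[b] else b)
        if ranks[a] == ranks[b]:
            rel_winner = None
            label = REL_TIED
        else:
            rel_winner = a if ranks[a] > ranks[b] else b
            if ev_tied:
                label = EV_TIED
            else:
                label = CONGRUENT if ev_winner == rel_winner else INCONGRUENT
        out.append(TransferPairClass(pair=(a, b), ev_winner=ev_winner,
                                     rel_winner=rel_winner, label=label,
                                     ev_tied=ev_tied))
    return out


def ideal_choice_rate(task: TaskSpec) -> float:
    """Rate at which an ideal EV-maximizing agent picks the higher-relative-
    value option over the transfer pairs.

    Pairs with tied relative value are excluded (they have no higher-relative-
    value member), as are equal-EV pairs with differing relative value (the
    ideal agent is indifferent there).  The rate is per unordered pair, hence
    invariant to ``transfer_reps``.
    """
    labels = [c.label for c in classify_transfer_pairs(task)]
    n_cong = labels.count(CONGRUENT)
    n_incong = labels.count(INCONGRUENT)
    if n_cong + n_incong == 0:
        raise ValueError(
            f"task {task.name!r} has no transfer pairs with distinct relative "
            f"and expected values")
    return n_cong / (n_cong + n_incong)
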