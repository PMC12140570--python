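"""Text harness: render trial histories into prompts and parse constrained
responses.

Two prompt designs are supported.  The *standard* prompt lists the outcomes of
every past round neutrally; the *comparison* prompt appends an explicit
more/less clause relating each outcome to the other outcome(s) of the same
round.  Every prompt ends with the fixed response-format sentence, and
``parse_choice`` extracts the chosen label from the canonical answer sentence
(anything else is an invalid response — a value, not an error, mirroring how
non-conforming model responses are dropped from analysis).

No chat API is called here: ``ChatAdapter`` is the minimal contract an
external client would implement to run a live model through the harness.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Protocol

import pandas as pd

__all__ = [
    "RESPONSE_FORMAT",
    "PromptTemplate",
    "ChatAdapter",
    "render_prompt",
    "parse_choice",
    "filter_invalid",
]

RESPONSE_FORMAT = ("Which slot machine do you choose? Give your answer like "
                   "this: I would choose slot machine _. Do not explain why.")

_CURRENCY_FORMATS = {"dollars": "${amount:g}", "euros": "{amount:g} euros",
                     "points": "{amount:g} points"}


def _fmt_amount(value: float, currency: str) -> str:
    return _CURRENCY_FORMATS.get(currency, "{amount:g} " + currency).format(
        amount=value)


@dataclass(frozen=True)
class PromptTemplate:
    """Configurable wording of one prompt condition.

    The exact comparison wording used with live models is not fixed by the
    harness; the shipped default keeps its semantics ("..., which is more/less
    than the [amount] delivered by slot machine [Z]") while remaining a plain
    config value, so an exact replication can drop in its own text.
    """

    condition: str = "standard"
    instruction: str = ("You are going to play a game involving slot machines. "
                        "Each round you choose one slot machine and your goal "
                        "is to maximize the total payoff.")
    outcome_line: str = "In round {round}, {outcomes}."
    outcome_item: str = "slot machine {label} delivered {amount}"
    comparison_clause: str = (", which is {relation} the {other_amount} "
                              "delivered by slot machine {other_label}")
    choice_question: str = ("You now face a choice between {options}. "
                            "Your goal is to maximize payoffs.")

    def __post_init__(self) -> None:
        if self.condition not in ("standard", "comparison"):
            raise ValueError("condition must be 'standard' or 'comparison'")


class ChatAdapter(Protocol):
    """Contract for an external text-completion client (not implemented here)."""

    def send(self, prompt: str) -> str:  # pragma: no cover - interface only
        ...


def _option_phrase(labels: list[str]) -> str:
    parts = [f"slot machine {x}" for x in labels]
    if len(parts) == 2:
        return " and ".join(parts)
    return ", ".join(parts[:-1]) + f", and {parts[-1]}"


def _relation(a: float, b: float) -> str:
    if a > b:
        return "more than"
    if a < b:
        return "less than"
    return "the same as"


def render_prompt(history, current, template: PromptTemplate | None = None, *,
                  currency: str = "points",
                  labels: dict[str, str] | None = None) -> str:
    """Render the prompt for ``current`` given the past learning rounds.

    ``history`` is the ordered list of past trials; learning trials must carry
    complete-feedback outcomes, which appear once each in round order.  In the
    comparison condition each listed outcome after the first is followed by an
    explicit relation clause against the first-listed outcome of the round.

    Raises
    ------
    ValueError
        If the history contains a transfer trial carrying outcomes.
    """
    template = template or PromptTemplate()
    lab = labels or {}

    def label_of(oid: str) -> str:
        return lab.get(oid, oid)

    lines = [template.instruction, ""]
    round_no = 0
    for t in history:
        outcomes = getattr(t, "outcomes", None)
        if t.phase == "transfer":
            if outcomes:
                raise ValueError("history contains a transfer trial with outcomes")
            continue
        if outcomes is None:
            raise ValueError("learning trial in history has no outcomes")
        round_no += 1
        items = []
        order = list(t.presented_option_ids)
        for k, oid in enumerate(order):
            item = template.outcome_item.format(
                label=label_of(oid), amount=_fmt_amount(outcomes[oid], currency))
            if template.condition == "comparison" and k > 0:
                ref = order[0]
                item += template.comparison_clause.format(
                    relation=_relation(outcomes[oid], outcomes[ref]),
                    other_amount=_fmt_amount(outcomes[ref], currency),
                    other_label=label_of(ref))
            items.append(item)
        lines.append(template.outcome_line.format(
            round=round_no, outcomes=" and ".join(items)))
    lines.append("")
    lines.append(template.choice_question.format(
        options=_option_phrase([label_of(o)
                                for o in current.presented_option_ids])))
    lines.append(RESPONSE_FORMAT)
    return "\n".join(lines)


_CHOICE_RE = re.compile(
    r"\bI\s+would\s+choose\s+slot\s+machine\s+([A-Za-z])\s*[.!?]*\s*$",
    re.IGNORECASE)


def parse_choice(response: str, valid_labels) -> str | None:
    """Extract the chosen label from the canonical answer sentence.

    Case-insensitive and tolerant of trailing punctuation/whitespace; any
    response not matching the format, or naming a label that was not offered,
    returns ``None`` (invalid).
    """
    m = _CHOICE_RE.search(response.strip())
    if not m:
        return None
    label = m.group(1).upper()
    valid = {str(x).upper() for x in valid_labels}
    return label if label in valid else None


def filter_invalid(sessions) -> tuple[list, pd.DataFrame]:
    """Drop invalid trials from every session.

    Dropped learning trials contribute neither likelihood nor expectancy
    updates downstream (their outcomes leave the data entirely).  Returns the
    filtered sessions and a per-session removal report; aggregate per cell by
    grouping on (task, agent, prompt_condition).
    """
    from dataclasses import replace

    filtered = []
    rows = []
    for s in sessions:
        kept = [t for t in s.trials if t.valid]
        n_invalid = len(s.trials) - len(kept)
        filtered.append(replace(s, trials=kept))
        rows.append({"task": s.task_name, "agent": s.agent,
                     "prompt_condition": s.prompt_condition, "seed": s.seed,
                     "n_trials": len(s.trials), "n_invalid": n_invalid,
                     "removal_rate": (n_invalid / len(s.trials)
                                      if s.trials else 0.0)})
    return filtered, pd.DataFrame(rows)
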