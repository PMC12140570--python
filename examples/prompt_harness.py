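"""Render bandit prompts and parse constrained responses.

Builds a two-round outcome history, renders it under the standard and the
comparison prompt designs (the latter adds an explicit more/less clause
relating each round's outcomes), and parses a canonical answer sentence.
"""

from relbandit.agents import TrialRecord
from relbandit.prompt_io import PromptTemplate, parse_choice, render_prompt

history = [
    TrialRecord(phase="learning", presented_option_ids=("B", "E"),
                chosen_option_id="B", context_id="c1",
                outcomes={"B": 4.0, "E": 1.0}),
    TrialRecord(phase="learning", presented_option_ids=("E", "B"),
                chosen_option_id="E", context_id="c1",
                outcomes={"B": 4.0, "E": 7.0}),
]
current = TrialRecord(phase="transfer", presented_option_ids=("E", "B"),
                      chosen_option_id="E")

for condition in ("standard", "comparison"):
    prompt = render_prompt(history, current,
                           PromptTemplate(condition=condition),
                           currency="dollars")
    print(f"--- {condition} prompt ---\n{prompt}\n")

response = "I would choose slot machine E."
print(f"response {response!r} parses to: "
      f"{parse_choice(response, ['B', 'E'])}")
print(f"response 'E is my pick' parses to: "
      f"{parse_choice('E is my pick', ['B', 'E'])} (invalid format)")
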