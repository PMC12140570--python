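"""Relative value bias table on a synthetic grid.

Simulates a small factorial grid — two tasks x (an emulated in-context learner
+ the ideal agent) x two prompt conditions x 30 runs — and summarizes each
cell's higher-relative-value choice rate against the ideal reference.  The
comparison condition is emulated by a higher relative encoding weight, so it
should show clear bias flags (CI lower bound above the ideal rate) on the
Gaussian ladder task, while the ideal agent never does.
"""

import pandas as pd

from relbandit import bias_analysis, task_designs
from relbandit.agents import emulated_llm_params, simulate_grid

tasks = [task_designs.load_task_spec(n) for n in ("V2023", "HW2023a")]
agents = {
    "emulated-llm": {"standard": emulated_llm_params(omega=0.11),
                     "comparison": emulated_llm_params(omega=0.26)},
    "ideal": "ideal",
}
sessions, manifest = simulate_grid(tasks, agents, ["standard", "comparison"],
                                   n_reps=30, base_seed=2024)
print(f"simulated {len(sessions)} sessions "
      f"({manifest.groupby('task').size().to_dict()})\n")

table = bias_analysis.summarize_cells(sessions, {t.name: t for t in tasks})
with pd.option_context("display.width", 120):
    print(table.round(3).to_string(index=False))

print("\n'biased' is true when the 95% CI of the mean higher-relative-value "
      "choice rate\nacross runs lies entirely above the ideal agent's rate.")
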