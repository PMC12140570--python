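"""Inspect the five built-in bandit tasks and their ideal-agent references.

For each task this prints the option/context structure, the number of
incongruent transfer pairs (pairs where the within-context frequent winner has
the lower expected value), and the rate at which an ideal EV-maximizing agent
would pick the higher-relative-value option in the transfer test.  An
empirical choice rate above that ideal rate is the behavioral signature of
relative value bias.
"""

from relbandit import task_designs as td

print(f"{'task':9} {'options':>7} {'contexts':>8} {'learning':>8} "
      f"{'transfer':>8} {'incongruent':>11} {'ideal rate':>10}")
for name in td.builtin_task_names():
    task = td.load_task_spec(name)
    labels = [c.label for c in td.classify_transfer_pairs(task)]
    print(f"{name:9} {task.n_options:7d} {len(task.contexts):8d} "
          f"{task.n_learning_trials:8d} "
          f"{len(td.build_transfer_schedule(task)):8d} "
          f"{labels.count(td.INCONGRUENT):11d} "
          f"{td.ideal_choice_rate(task):10.3f}")

print("\nIdeal rate = fraction of rank-discordant transfer pairs on which the "
      "EV maximizer\nis also the frequent winner; bias can only exceed it via "
      "errors on incongruent pairs.")
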