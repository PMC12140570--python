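"""Simulate a hybrid-encoding agent and recover its parameters by pooled MLE.

Thirty sessions are generated on the Gaussian ladder task from a known
relative-encoding agent (omega = 0.5, confirmation-biased learning rates,
separate learning/transfer inverse temperatures).  The full hybrid model and
the matching absolute-encoding model are then fit to the pooled choices; the
hybrid model should recover omega within ~0.1 and win the BIC comparison.
"""

from relbandit import agents, task_designs
from relbandit.cogmodel import AgentParams, ModelSpec, fit_model

task = task_designs.load_task_spec("HW2023a")
rel_full = ModelSpec(relative_encoding=True, n_learning_rates=2, n_betas=2)
abs_full = ModelSpec(relative_encoding=False, n_learning_rates=2, n_betas=2)

truth = AgentParams.create(rel_full, omega=0.5, alpha=0.5, alpha_dis=0.15,
                           beta=10.0, beta_transfer=6.0, position_bias=0.5)
sessions = [agents.simulate_session(task, truth, seed=s) for s in range(30)]

for model in (rel_full, abs_full):
    fit = fit_model(model, sessions, n_starts=20, seed=1)
    p = fit.params
    print(f"{model.name:17} LL={fit.log_likelihood:8.1f}  BIC={fit.bic:7.1f}  "
          f"omega={p.omega:.3f}  a_con={p.alpha_con:.3f}  "
          f"a_dis={p.alpha_dis:.3f}  b={p.position_bias:.2f}")

print("\nGenerating values: omega=0.500, a_con=0.500, a_dis=0.150, b=0.50.")
print("The hybrid (REL) model should show the lower BIC: the data carry a "
      "relative-encoding\nsignature that the absolute model cannot express.")
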