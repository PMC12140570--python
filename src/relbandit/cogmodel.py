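"""Likelihood core for the eight-member family of contextual RL models.

The models share three stages.  Outcome encoding maps each observed reward x
onto a subjective value

    v(x) = (1 - omega) * x_ABS + omega * x_REL,

where ``x_ABS`` range-normalizes x by the running minimum/maximum of all
rewards observed so far in the run and ``x_REL`` range-normalizes by the
outcomes of the current trial only; ``omega`` in [0, 1] is the relative
encoding weight.  Learning is prediction-error driven,

    Q(a) <- Q(a) + alpha * (v(x) - Q(a)),

optionally with separate learning rates for confirmatory outcomes (chosen
option better than expected, or unchosen worse than expected) and
disconfirmatory outcomes.  Choice follows a softmax over ``beta * Q`` with an
additive position bias ``b`` for the first-listed option, optionally with
separate inverse temperatures for the learning phase and the transfer test.

Crossing {absolute, relative} encoding x {1, 2} learning rates x {1, 2}
inverse temperatures gives eight candidate models, fit by pooled maximum
likelihood and compared by BIC; ``model_recovery`` and ``loo_cv`` provide the
standard identifiability and out-of-sample checks.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import qmc

__all__ = [
    "ModelSpec",
    "AgentParams",
    "EncodingState",
    "FitResult",
    "RecoveryMatrix",
    "CvResult",
    "all_model_specs",
    "encode_outcomes",
    "classify_feedback",
    "update_expectancies",
    "choice_probabilities",
    "session_loglik",
    "fit_model",
    "compare_models",
    "model_recovery",
    "loo_cv",
    "default_recovery_sampler",
]

Q_INIT = 0.5  # expectancies reset to 0.5 on the first trial of each run

DEFAULT_BOUNDS = {
    "omega": (0.0, 1.0),
    "alpha": (0.0, 1.0),
    "beta": (0.0, 100.0),
    "bias": (-10.0, 10.0),
}


# ---------------------------------------------------------------------------
# Model family and parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """One member of the factorial model family."""

    relative_encoding: bool
    n_learning_rates: int = 1
    n_betas: int = 1

    def __post_init__(self) -> None:
        if self.n_learning_rates not in (1, 2) or self.n_betas not in (1, 2):
            raise ValueError("n_learning_rates and n_betas must be 1 or 2")

    @property
    def k(self) -> int:
        """Number of free parameters (base: alpha, beta, position bias)."""
        return (3 + int(self.relative_encoding)
                + int(self.n_learning_rates == 2) + int(self.n_betas == 2))

    @property
    def name(self) -> str:
        parts = ["REL" if self.relative_encoding else "ABS"]
        if self.n_learning_rates == 2:
            parts.append("2alpha")
        if self.n_betas == 2:
            parts.append("2beta")
        return "-".join(parts)


def all_model_specs() -> list[ModelSpec]:
    """The eight candidate models, simplest first."""
    return [ModelSpec(rel, nlr, nb)
            for rel, nlr, nb in itertools.product((False, True), (1, 2), (1, 2))]


@dataclass(frozen=True)
class AgentParams:
    """Parameter vector for one model variant.

    The reduced models are represented by equality constraints: ``omega = 0``
    without relative encoding, ``alpha_con = alpha_dis`` with one learning
    rate, ``beta_learn = beta_transfer`` with one inverse temperature.
    """

    model: ModelSpec
    omega: float
    alpha_con: float
    alpha_dis: float
    beta_learn: float
    beta_transfer: float
    position_bias: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError(f"omega must lie in [0, 1], got {self.omega}")
        if not self.model.relative_encoding and self.omega != 0.0:
            raise ValueError("omega must be 0 without relative encoding")
        if self.model.n_learning_rates == 1 and self.alpha_con != self.alpha_dis:
            raise ValueError("one-learning-rate models need alpha_con == alpha_dis")
        if self.model.n_betas == 1 and self.beta_learn != self.beta_transfer:
            raise ValueError("one-beta models need beta_learn == beta_transfer")
        if self.beta_learn < 0 or self.beta_transfer < 0:
            raise ValueError("inverse temperatures must be >= 0")

    @classmethod
    def create(cls, model: ModelSpec, *, omega: float = 0.0, alpha: float = 0.1,
               alpha_dis: float | None = None, beta: float = 5.0,
               beta_transfer: float | None = None,
               position_bias: float = 0.0) -> "AgentParams":
        """Build params from the model's free parameters, filling the tied ones."""
        a_dis = alpha if (model.n_learning_rates == 1 or alpha_dis is None) else alpha_dis
        b_tr = beta if (model.n_betas == 1 or beta_transfer is None) else beta_transfer
        return cls(model=model, omega=omega if model.relative_encoding else 0.0,
                   alpha_con=alpha, alpha_dis=a_dis,
                   beta_learn=beta, beta_transfer=b_tr,
                   position_bias=position_bias)


@dataclass
class EncodingState:
    """Running reward range over everything observed so far in a run."""

    running_min: float = math.inf
    running_max: float = -math.inf


# ---------------------------------------------------------------------------
# Stage operations (also used by the generative simulator)
# ---------------------------------------------------------------------------

def _normalize(x: float, lo: float, hi: float) -> float:
    if hi == lo:
        return 0.5  # degenerate range
    return (x - lo) / (hi - lo)


def encode_outcomes(
    outcomes, state: EncodingState, omega: float,
) -> tuple[np.ndarray, EncodingState]:
    """Subjective values of one trial's complete-feedback outcomes.

    The running range absorbs the current trial's outcomes *before* the
    absolute normalization, so the extremes of the first trial map to 0 and 1.
    Degenerate ranges (max == min) normalize to 0.5.
    """
    if not 0.0 <= omega <= 1.0:
        raise ValueError(f"omega must lie in [0, 1], got {omega}")
    x = np.asarray(outcomes, dtype=float)
    if x.size < 2:
        raise ValueError("complete feedback requires at least two outcomes")
    new_state = EncodingState(
        running_min=min(state.running_min, float(x.min())),
        running_max=max(state.running_max, float(x.max())),
    )
    x_abs = np.array([_normalize(xi, new_state.running_min, new_state.running_max)
                      for xi in x])
    x_rel = np.array([_normalize(xi, float(x.min()), float(x.max())) for xi in x])
    return (1.0 - omega) * x_abs + omega * x_rel, new_state


def classify_feedback(v: float, q: float, chosen: bool) -> str:
    """Confirmatory vs disconfirmatory outcome classification.

    Chosen option better than expected, or unchosen worse than expected, is
    confirmatory; the reverse is disconfirmatory.  When ``v == q`` the update
    is zero and the classification is immaterial (returns confirmatory).
    """
    if chosen:
        return "confirmatory" if v >= q else "disconfirmatory"
    return "confirmatory" if v <= q else "disconfirmatory"


def update_expectancies(
    q: dict[str, float], v: dict[str, float], chosen_id: str,
    alpha_con: float, alpha_dis: float,
) -> dict[str, float]:
    """Prediction-error update of every presented option's expectancy."""
    out = dict(q)
    for oid, vi in v.items():
        kind = classify_feedback(vi, out[oid], oid == chosen_id)
        alpha = alpha_con if kind == "confirmatory" else alpha_dis
        out[oid] = out[oid] + alpha * (vi - out[oid])
    return out


def choice_probabilities(q_values, beta: float, bias: float,
                         first_index: int = 0) -> np.ndarray:
    """Softmax choice probabilities with a position bias on the first-listed
    option.  Overflow-safe (log-domain) for utilities up to about +-700."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    q = np.asarray(q_values, dtype=float)
    if q.size not in (2, 3):
        raise ValueError("2 or 3 presented options required")
    u = beta * q
    u[first_index] += bias
    u -= u.max()
    e = np.exp(u)
    return e / e.sum()


# ---------------------------------------------------------------------------
# Session packing and the likelihood kernel
# ---------------------------------------------------------------------------

def _ll_kernel_py(omega, a_con, a_dis, beta_learn, beta_transfer, bias,
                  n_options, is_learn, n_opts, opt_idx, outcomes, chosen_pos):
    q = np.full(n_options, 0.5)
    rmin = np.inf
    rmax = -np.inf
    ll = 0.0
    n_trials = is_learn.shape[0]
    for t in range(n_trials):
        m = n_opts[t]
        beta = beta_learn if is_learn[t] else beta_transfer
        umax = -np.inf
        u0 = 0.0
        u1 = 0.0
        u2 = 0.0
        for k in range(m):
            uk = beta * q[opt_idx[t, k]]
            if k == 0:
                uk += bias
            if k == 0:
                u0 = uk
            elif k == 1:
                u1 = uk
            else:
                u2 = uk
            if uk > umax:
                umax = uk
        s = math.exp(u0 - umax) + math.exp(u1 - umax)
        if m == 3:
            s += math.exp(u2 - umax)
        c = chosen_pos[t]
        uc = u0 if c == 0 else (u1 if c == 1 else u2)
        lp = uc - umax - math.log(s)
        if not math.isfinite(lp):
            return math.nan, t
        ll += lp
        if is_learn[t]:
            tmin = np.inf
            tmax = -np.inf
            for k in range(m):
                x = outcomes[t, k]
                if x < tmin:
                    tmin = x
                if x > tmax:
                    tmax = x
            if tmin < rmin:
                rmin = tmin
            if tmax > rmax:
                rmax = tmax
            for k in range(m):
                x = outcomes[t, k]
                xa = 0.5 if rmax == rmin else (x - rmin) / (rmax - rmin)
                xr = 0.5 if tmax == tmin else (x - tmin) / (tmax - tmin)
                v = (1.0 - omega) * xa + omega * xr
                i = opt_idx[t, k]
                qi = q[i]
                if k == c:
                    alpha = a_con if v > qi else a_dis
                else:
                    alpha = a_con if v < qi else a_dis
                q[i] = qi + alpha * (v - qi)
    return ll, -1


try:  # jit-compile the kernel; fall back to plain Python if that fails
    from numba import njit

    _ll_kernel = njit(cache=False)(_ll_kernel_py)
except Exception:  # pragma: no cover
    _ll_kernel = _ll_kernel_py


@dataclass(frozen=True)
class PackedSession:
    """Array view of one session's valid trials, ready for the kernel."""

    option_index: dict[str, int]
    is_learn: np.ndarray
    n_opts: np.ndarray
    opt_idx: np.ndarray
    outcomes: np.ndarray
    chosen_pos: np.ndarray

    @property
    def n_trials(self) -> int:
        return int(self.is_learn.shape[0])


def pack_session(session) -> PackedSession:
    """Convert a ``SessionData`` into kernel arrays (invalid trials dropped,
    together with their outcomes — they contribute neither likelihood nor
    expectancy updates)."""
    trials = [t for t in session.trials if t.valid]
    ids = sorted({oid for t in trials for oid in t.presented_option_ids})
    index = {oid: i for i, oid in enumerate(ids)}
    n = len(trials)
    is_learn = np.zeros(n, dtype=np.bool_)
    n_opts = np.zeros(n, dtype=np.int64)
    opt_idx = np.zeros((n, 3), dtype=np.int64)
    outcomes = np.zeros((n, 3), dtype=np.float64)
    chosen_pos = np.zeros(n, dtype=np.int64)
    for t, tr in enumerate(trials):
        m = len(tr.presented_option_ids)
        is_learn[t] = tr.phase == "learning"
        n_opts[t] = m
        for k, oid in enumerate(tr.presented_option_ids):
            opt_idx[t, k] = index[oid]
            if tr.outcomes is not None:
                outcomes[t, k] = tr.outcomes[oid]
        chosen_pos[t] = tr.presented_option_ids.index(tr.chosen_option_id)
    return PackedSession(option_index=index, is_learn=is_learn, n_opts=n_opts,
                         opt_idx=opt_idx, outcomes=outcomes, chosen_pos=chosen_pos)


def _packed_loglik(params: AgentParams, packed: PackedSession) -> float:
    ll, bad = _ll_kernel(
        params.omega, params.alpha_con, params.alpha_dis,
        params.beta_learn, params.beta_transfer, params.position_bias,
        len(packed.option_index), packed.is_learn, packed.n_opts,
        packed.opt_idx, packed.outcomes, packed.chosen_pos)
    if bad >= 0:
        raise FloatingPointError(
            f"non-finite choice probability at trial index {bad}")
    return float(ll)


def session_loglik(params: AgentParams, session) -> float:
    """Log-likelihood of one session's valid choices under ``params``.

    Expectancies reset to 0.5 and the running reward range resets at the start
    of the session; learning trials use ``beta_learn`` and update expectancies,
    transfer trials use ``beta_transfer`` on the frozen expectancies.
    """
    return _packed_loglik(params, pack_session(session))


# ---------------------------------------------------------------------------
# Fitting, comparison, recovery, cross-validation
# ---------------------------------------------------------------------------

def _free_params(model: ModelSpec, bounds: dict | None = None):
    b = {**DEFAULT_BOUNDS, **(bounds or {})}
    free: list[tuple[str, tuple[float, float]]] = []
    if model.relative_encoding:
        free.append(("omega", b["omega"]))
    if model.n_learning_rates == 1:
        free.append(("alpha", b["alpha"]))
    else:
        free.append(("alpha_con", b["alpha"]))
        free.append(("alpha_dis", b["alpha"]))
    if model.n_betas == 1:
        free.append(("beta", b["beta"]))
    else:
        free.append(("beta_learn", b["beta"]))
        free.append(("beta_transfer", b["beta"]))
    free.append(("bias", b["bias"]))
    return free


def _theta_to_params(model: ModelSpec, names: list[str], theta) -> AgentParams:
    d = dict(zip(names, theta))
    alpha_con = d.get("alpha_con", d.get("alpha"))
    alpha_dis = d.get("alpha_dis", alpha_con)
    beta_learn = d.get("beta_learn", d.get("beta"))
    beta_transfer = d.get("beta_transfer", beta_learn)
    return AgentParams(model=model, omega=d.get("omega", 0.0),
                       alpha_con=alpha_con, alpha_dis=alpha_dis,
                       beta_learn=beta_learn, beta_transfer=beta_transfer,
                       position_bias=d["bias"])


@dataclass
class FitResult:
    """Pooled maximum-likelihood fit of one model to one dataset."""

    model: ModelSpec
    params: AgentParams
    log_likelihood: float
    n_observations: int
    bic: float
    diagnostics: dict = field(default_factory=dict)


def _pooled_neg_loglik(model, names, packed_sessions):
    def f(theta):
        params = _theta_to_params(model, names, theta)
        return -sum(_packed_loglik(params, p) for p in packed_sessions)
    return f


def fit_model(model: ModelSpec, sessions, *, n_starts: int = 20,
              seed: int | None = None, bounds: dict | None = None,
              tol: float = 1e-8) -> FitResult:
    """Pooled MLE over sessions (each with its own expectancy/range reset),
    via bounded multi-start L-BFGS-B from seeded Latin-hypercube starts."""
    if not sessions:
        raise ValueError("at least one session required")
    packed = [pack_session(s) for s in sessions]
    n_obs = sum(p.n_trials for p in packed)
    free = _free_params(model, bounds)
    names = [n for n, _ in free]
    lo = np.array([b[0] for _, b in free])
    hi = np.array([b[1] for _, b in free])
    sampler = qmc.LatinHypercube(d=len(free), seed=seed)
    starts = lo + sampler.random(n=n_starts) * (hi - lo)
    obj = _pooled_neg_loglik(model, names, packed)
    best = None
    diag = {"n_starts": n_starts, "converged": [], "fun": []}
    for x0 in starts:
        res = optimize.minimize(obj, x0, method="L-BFGS-B",
                                bounds=list(zip(lo, hi)), tol=tol)
        diag["converged"].append(bool(res.success))
        diag["fun"].append(float(res.fun))
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(f"all {n_starts} starts failed for model "
                           f"{model.name}: {diag}")
    ll = -float(best.fun)
    bic = model.k * math.log(n_obs) - 2.0 * ll
    return FitResult(model=model,
                     params=_theta_to_params(model, names, best.x),
                     log_likelihood=ll, n_observations=n_obs, bic=bic,
                     diagnostics=diag)


def compare_models(sessions, *, models: list[ModelSpec] | None = None,
                   n_starts: int = 20, seed: int | None = None) -> list[FitResult]:
    """Fit every candidate model and return results sorted by BIC (ties broken
    toward fewer parameters); the first entry is the winner."""
    models = models if models is not None else all_model_specs()
    results = [fit_model(m, sessions, n_starts=n_starts, seed=seed)
               for m in models]
    results.sort(key=lambda r: (r.bic, r.model.k))
    return results


def default_recovery_sampler(model: ModelSpec,
                             rng: np.random.Generator) -> AgentParams:
    """Generating-parameter prior for recovery simulations: magnitudes in the
    range typically estimated for in-context learners in these tasks
    (moderate-to-high inverse temperatures, confirmation-biased learning
    rates, a mild positive position bias, mid-range relative encoding)."""
    omega = rng.uniform(0.3, 0.9) if model.relative_encoding else 0.0
    if model.n_learning_rates == 2:
        alpha = rng.uniform(0.4, 0.8)
        alpha_dis = rng.uniform(0.05, 0.25)
    else:
        alpha = rng.uniform(0.2, 0.6)
        alpha_dis = None
    beta = rng.uniform(5.0, 20.0)
    beta_transfer = rng.uniform(5.0, 20.0) if model.n_betas == 2 else None
    bias = rng.uniform(-1.5, 1.5)
    return AgentParams.create(model, omega=omega, alpha=alpha,
                              alpha_dis=alpha_dis, beta=beta,
                              beta_transfer=beta_transfer, position_bias=bias)


@dataclass
class RecoveryMatrix:
    """Confusion matrix of recovery simulations: rows are generating models,
    columns are BIC-selected models."""

    models: list[ModelSpec]
    counts: np.ndarray

    @property
    def recovery_rate(self) -> float:
        """Mean diagonal share across generating models (chance = 1/8)."""
        row_sums = self.counts.sum(axis=1)
        return float(np.mean(np.diag(self.counts) / row_sums))


def model_recovery(tasks, *, sims_per_model: int = 5,
                   sessions_per_sim: int = 4, param_sampler=None,
                   seed: int | None = None, n_starts: int = 5,
                   n_fit_starts: int | None = None) -> RecoveryMatrix:
    """Simulate from each candidate model and check that BIC selection finds
    the generator.  Tasks are cycled across simulations."""
    from .agents import simulate_session  # local import: agents builds on cogmodel

    sampler = param_sampler or default_recovery_sampler
    n_fit_starts = n_fit_starts if n_fit_starts is not None else n_starts
    models = all_model_specs()
    counts = np.zeros((len(models), len(models)), dtype=int)
    ss = np.random.SeedSequence(seed)
    for gi, gen_model in enumerate(models):
        for sim in range(sims_per_model):
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(child)
            task = tasks[(gi * sims_per_model + sim) % len(tasks)]
            params = sampler(gen_model, rng)
            session_seeds = child.spawn(sessions_per_sim)
            sessions = [simulate_session(task, params, s)
                        for s in session_seeds]
            fit_seed = int(rng.integers(2**31))
            results = compare_models(sessions, n_starts=n_fit_starts,
                                     seed=fit_seed)
            winner = results[0].model
            counts[gi, models.index(winner)] += 1
    return RecoveryMatrix(models=models, counts=counts)


@dataclass
class CvResult:
    """Leave-one-run-out cross-validation summary for one model."""

    per_run_loglik: np.ndarray
    per_run_pseudo_r2: np.ndarray

    @property
    def mean_pseudo_r2(self) -> float:
        return float(np.mean(self.per_run_pseudo_r2))


def _chance_loglik(packed: PackedSession) -> float:
    """Log-likelihood of a null model predicting chance probabilities
    (1/2 binary, 1/3 ternary) on every valid trial.  Accumulated trial by
    trial in session order so a degenerate fitted model (beta = 0, b = 0)
    reproduces it bit-for-bit."""
    ll = 0.0
    for m in packed.n_opts:
        ll -= math.log(float(m))
    return ll


def loo_cv(model: ModelSpec, sessions, *, n_starts: int = 10,
           seed: int | None = None, bounds: dict | None = None) -> CvResult:
    """Fit the pooled data from all runs but one; score the held-out run.

    The out-of-sample log-likelihoods are converted to pseudo-R^2 via
    ``1 - LL_model / LL_chance``; 0 means chance-level prediction, 1 perfect.
    """
    if len(sessions) < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")
    lls = []
    r2s = []
    for i, held_out in enumerate(sessions):
        train = [s for j, s in enumerate(sessions) if j != i]
        fit = fit_model(model, train, n_starts=n_starts, seed=seed,
                        bounds=bounds)
        packed = pack_session(held_out)
        ll = _packed_loglik(fit.params, packed)
        ll0 = _chance_loglik(packed)
        lls.append(ll)
        r2s.append(1.0 - ll / ll0)
    return CvResult(per_run_loglik=np.array(lls), per_run_pseudo_r2=np.array(r2s))
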