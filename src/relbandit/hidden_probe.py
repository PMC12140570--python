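"""Value-probe regressions on hidden-unit activations.

Each hidden unit's trial-to-trial activation over the transfer test is
modeled by ordinary least squares on two trial-level regressors: the
difference in *absolute* values (expected values of the two presented
options) and the difference in *relative* values (within-context frequent-
winner ranks), both normalized to [0, 1].  Units with significant partial
coefficients for one, the other, or both regressors are counted after a
conservative multiple-comparison correction (Bonferroni over units x
regressors by default), and the unsigned coefficient magnitudes are contrasted
with a paired test across units.

``synth_activations`` plants known linear loadings plus Gaussian noise so the
whole stage is testable without any transformer: it emulates the final-layer
readout structure of a real model, not its representation geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .task_designs import (
    TaskSpec,
    build_transfer_schedule,
    expected_value,
    relative_ranks,
)

__all__ = [
    "ProbeDesign",
    "ProbeResult",
    "CoefficientContrast",
    "build_probe_design",
    "synth_activations",
    "unit_regressions",
    "apply_correction",
    "coefficient_contrast",
]

REGRESSORS = ("abs", "rel")


@dataclass(frozen=True)
class ProbeDesign:
    """Per-transfer-trial regressors, both normalized to [0, 1]."""

    delta_abs: np.ndarray
    delta_rel: np.ndarray

    def __post_init__(self) -> None:
        da = np.asarray(self.delta_abs, float)
        dr = np.asarray(self.delta_rel, float)
        if da.shape != dr.shape or da.ndim != 1:
            raise ValueError("delta_abs and delta_rel must be 1-D and equal length")
        for name, x in (("delta_abs", da), ("delta_rel", dr)):
            if x.min() < -1e-12 or x.max() > 1 + 1e-12:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def n_trials(self) -> int:
        return int(np.asarray(self.delta_abs).shape[0])

    def matrix(self) -> np.ndarray:
        """Design matrix with intercept column."""
        return np.column_stack([np.ones(self.n_trials),
                                np.asarray(self.delta_abs, float),
                                np.asarray(self.delta_rel, float)])


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def build_probe_design(task: TaskSpec, trial_pairs=None) -> ProbeDesign:
    """Regressors for a task's transfer trials.

    Absolute value is the min-max-normalized expected value across options;
    relative value is the within-context frequent-winner rank in {0, 0.5, 1}.
    Each trial's regressor is the unsigned difference between the two
    presented options' values, min-max normalized to [0, 1] across trials.
    ``trial_pairs`` defaults to the canonical transfer schedule.
    """
    pairs = trial_pairs if trial_pairs is not None else build_transfer_schedule(task)
    evs = {o.option_id: expected_value(o) for o in task.options}
    vals = np.array(list(evs.values()))
    lo, hi = vals.min(), vals.max()
    abs_val = {k: (v - lo) / (hi - lo) if hi > lo else 0.5 for k, v in evs.items()}
    rel_val = relative_ranks(task)
    da = np.array([abs(abs_val[a] - abs_val[b]) for a, b in pairs])
    dr = np.array([abs(rel_val[a] - rel_val[b]) for a, b in pairs])
    return ProbeDesign(delta_abs=_minmax(da), delta_rel=_minmax(dr))


def synth_activations(design: ProbeDesign, loadings, noise_sd: float, seed, *,
                      intercepts=None) -> np.ndarray:
    """Planted-signal activation matrix (trials x units).

    ``activations = intercepts + [delta_abs, delta_rel] @ loadings.T + noise``
    with seeded i.i.d. Gaussian noise; ``loadings`` is units x 2 (abs, rel).
    """
    rng = np.random.default_rng(seed)
    load = np.atleast_2d(np.asarray(loadings, float))
    if load.shape[1] != 2:
        raise ValueError("loadings must be units x 2 (abs, rel)")
    X = np.column_stack([np.asarray(design.delta_abs, float),
                         np.asarray(design.delta_rel, float)])
    mu = X @ load.T
    if intercepts is not None:
        mu = mu + np.asarray(intercepts, float)[None, :]
    return mu + rng.normal(0.0, noise_sd, size=mu.shape)


@dataclass(frozen=True)
class ProbeResult:
    """Per-unit partial coefficients and p-values for the two regressors.

    ``pvalues`` are raw after :func:`unit_regressions` and adjusted after
    :func:`apply_correction`; significance counts always use ``alpha`` against
    the stored p-values.
    """

    coef: np.ndarray        # units x 2 (abs, rel)
    pvalues: np.ndarray     # units x 2
    alpha: float = 0.05
    correction: str | None = None

    @property
    def n_units(self) -> int:
        return int(self.coef.shape[0])

    def significant(self) -> np.ndarray:
        """Boolean units x 2 mask at level ``alpha``."""
        return self.pvalues < self.alpha

    def counts(self) -> dict[str, int]:
        """Units significant for abs only, rel only, or both (disjoint)."""
        sig = self.significant()
        both = sig[:, 0] & sig[:, 1]
        return {"abs_only": int((sig[:, 0] & ~both).sum()),
                "rel_only": int((sig[:, 1] & ~both).sum()),
                "both": int(both.sum())}

    def mean_unsigned_coef(self) -> dict[str, float]:
        return {"abs": float(np.abs(self.coef[:, 0]).mean()),
                "rel": float(np.abs(self.coef[:, 1]).mean())}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "unit": np.arange(self.n_units),
            "coef_abs": self.coef[:, 0], "coef_rel": self.coef[:, 1],
            "p_abs": self.pvalues[:, 0], "p_rel": self.pvalues[:, 1]})


def unit_regressions(activations, design: ProbeDesign,
                     alpha: float = 0.05) -> ProbeResult:
    """OLS of every unit's activations on [1, delta_abs, delta_rel].

    Returns raw (uncorrected) two-sided p-values for the two partial
    coefficients of every unit; apply a correction before counting.
    """
    Y = np.asarray(activations, float)
    if Y.ndim != 2 or Y.shape[0] != design.n_trials:
        raise ValueError("activations must be trials x units matching the design")
    n, _ = Y.shape
    if n < 4:
        raise ValueError("at least 4 trials required (3 regression parameters)")
    X = design.matrix()
    cond = np.linalg.cond(X)
    if cond > 1e8:
        raise ValueError(
            f"collinear design: condition number {cond:.3g} exceeds 1e8")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y                      # 3 x units
    resid = Y - X @ beta
    df = n - X.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / df        # per unit
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))  # 3 x units
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pval = 2.0 * stats.t.sf(np.abs(tval), df)
    return ProbeResult(coef=beta[1:].T.copy(), pvalues=pval[1:].T.copy(),
                       alpha=alpha, correction=None)


def apply_correction(result: ProbeResult, method: str = "bonferroni",
                     family_size: int | None = None) -> ProbeResult:
    """Multiple-comparison correction over the units x regressors family.

    ``bonferroni`` multiplies p-values by ``family_size`` (default: number of
    tests, units x 2; a family size of 1 leaves them uncorrected).  Any other
    method name is delegated to
    :func:`statsmodels.stats.multitest.multipletests` over the full family.
    """
    p = result.pvalues
    if method == "bonferroni":
        m = family_size if family_size is not None else p.size
        adj = np.clip(p * m, 0.0, 1.0)
    else:
        try:
            adj = multipletests(p.ravel(), alpha=result.alpha,
                                method=method)[1].reshape(p.shape)
        except ValueError as err:
            raise ValueError(f"unknown correction method {method!r}") from err
    return replace(result, pvalues=adj, correction=method)


@dataclass(frozen=True)
class CoefficientContrast:
    """Mean unsigned coefficient per regressor with a paired test across units."""

    mean_abs: float
    mean_rel: float
    se_abs: float
    se_rel: float
    t_statistic: float
    p_value: float

    @property
    def rel_dominant(self) -> bool:
        return self.mean_rel > self.mean_abs


def coefficient_contrast(result: ProbeResult) -> CoefficientContrast:
    """Compare mean |abs coefficient| vs mean |rel coefficient| across units
    (paired t-test; units are the pairing)."""
    if result.n_units < 2:
        raise ValueError("contrast needs at least 2 units")
    a = np.abs(result.coef[:, 0])
    r = np.abs(result.coef[:, 1])
    t, p = stats.ttest_rel(r, a)
    n = result.n_units
    return CoefficientContrast(
        mean_abs=float(a.mean()), mean_rel=float(r.mean()),
        se_abs=float(a.std(ddof=1) / np.sqrt(n)),
        se_rel=float(r.std(ddof=1) / np.sqrt(n)),
        t_statistic=float(t), p_value=float(p))
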