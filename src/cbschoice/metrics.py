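"""Predictive evaluation and interpretive measures for fitted choice models.

Predictive side: hit-rate accuracy (a predicted probability of exactly 0.5
scores half a hit), Tjur's coefficient of discrimination D (difference of the
mean predicted probabilities across the two observed choice classes; 0 for a
random model, 1 for a perfect one), and leave-one-trial-out cross-validation
(LOOCV), with the eligibility rule that a session needs at least two trials
of each choice type.  LOOCV folds use only the fixed multi-start set — never
a warm start taken from the full-data fit — so a held-out trial cannot
influence its own prediction through the optimizer's choice among local
optima.

Interpretive side: the area under the fitted discounting/weighting curve
(AUC) with a delete-one jackknife standard error, the delay-specific
discount rate h(D) = ln(-ln f(D) / D) (constant and equal to ln k under
exponential discounting), the probability-specific risk aversion
q(p) = ln(f(p) / p) (the log odds of subjective to objective probability;
positive means risk-seeking at p), the average daily change in discount rate
used to group discounting curves, and the count of crossings of the identity
line (switches between risk aversion and risk seeking).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bezier import CBSCurve, curve_auc, eval_curve
from .fitting import ChoiceDataset, FitConfig, FitResult, fit_model
from .models import CBSModel, CBSSpec

__all__ = [
    "UndefinedMetricError",
    "IneligibleSessionError",
    "AUCEstimate",
    "tjurs_d",
    "accuracy",
    "in_sample_metrics",
    "loocv_evaluate",
    "check_loocv_eligible",
    "auc_with_jackknife",
    "jackknife_se",
    "discount_rate_at",
    "risk_aversion_at",
    "avg_discount_rate_change",
    "count_risk_switches",
]


class UndefinedMetricError(ValueError):
    """A metric is undefined for this input (e.g. a missing choice class)."""


class IneligibleSessionError(ValueError):
    """The session fails the >= 2 trials per choice type rule for LOOCV."""


@dataclass
class AUCEstimate:
    """AUC of a fitted curve with a delete-one jackknife standard error."""

    auc: float
    jackknife_se: float
    n_trials: int
    loo_aucs: np.ndarray | None = None


def tjurs_d(p_choice1: np.ndarray, choice: np.ndarray) -> float:
    """Tjur's D: mean p-hat over choice-1 trials minus mean over choice-2.

    Invariant to which option the probabilities refer to.  Raises
    :class:`UndefinedMetricError` if either choice class is absent.
    """
    p = np.asarray(p_choice1, dtype=float)
    c = np.asarray(choice)
    m1 = c == 1
    m2 = c == 2
    if not (np.any(m1) and np.any(m2)):
        raise UndefinedMetricError("Tjur's D needs both choice types present")
    return float(np.mean(p[m1]) - np.mean(p[m2]))


def accuracy(p_choice1: np.ndarray, choice: np.ndarray) -> float:
    """Hit rate with the tie rule: p-hat = 0.5 scores 0.5."""
    p = np.asarray(p_choice1, dtype=float)
    c = np.asarray(choice)
    score = np.where(p == 0.5, 0.5,
                     np.where((p > 0.5) == (c == 1), 1.0, 0.0))
    return float(np.mean(score))


def in_sample_metrics(fit: FitResult, data: ChoiceDataset) -> dict[str, float]:
    """Accuracy and Tjur's D of a fit evaluated on its own training data."""
    p1 = fit.predict_choice1_probability(data)
    c = data.arrays()["choice"]
    return {"accuracy": accuracy(p1, c), "tjurs_d": tjurs_d(p1, c)}


def check_loocv_eligible(data: ChoiceDataset) -> None:
    n1, n2 = data.n_choices()
    if n1 < 2 or n2 < 2:
        raise IneligibleSessionError(
            f"LOOCV needs at least two trials of each choice type; "
            f"got {n1} option-1 and {n2} option-2 choices"
        )


def _warm_config(config: FitConfig, fit: FitResult) -> FitConfig:
    warm = np.append(fit.theta, fit.sigma)
    return replace(config, extra_starts=tuple(config.extra_starts) + (warm,))


def loocv_evaluate(data: ChoiceDataset, spec, config: FitConfig | None = None,
                   ) -> dict:
    """Leave-one-trial-out cross-validation of a model specification.

    Fits the model n times, each time excluding one trial and recording the
    excluded trial's predicted choice probability; the held-out trial plays
    no part in the fold's fit — not even as a warm start, so the fold's
    prediction is a deterministic function of the other n-1 trials alone.
    Returns out-of-sample accuracy, Tjur's D and the per-trial prediction
    records.
    """
    check_loocv_eligible(data)
    config = config or FitConfig()
    full_fit = fit_model(data, spec, config)
    # folds deliberately do NOT reuse the full-data optimum as a warm start:
    # with a multimodal likelihood that would let the held-out trial steer
    # which optimum the fold converges to, leaking its choice into its own
    # prediction; each fold uses only the fixed start set
    p_holdout = np.empty(len(data))
    for i in range(len(data)):
        fold_fit = fit_model(data.without_trial(i), spec, config)
        p_holdout[i] = fold_fit.predict_choice1_probability(data.subset([i]))[0]
    c = data.arrays()["choice"]
    records = pd.DataFrame({"p_choice1": p_holdout, "choice": c})
    return {
        "accuracy": accuracy(p_holdout, c),
        "tjurs_d": tjurs_d(p_holdout, c),
        "records": records,
        "full_fit": full_fit,
    }


def jackknife_se(values: np.ndarray) -> float:
    """Delete-one jackknife SE: sqrt[ (n-1)/n * sum (v_i - mean v)^2 ]."""
    v = np.asarray(values, dtype=float)
    n = v.size
    return float(np.sqrt((n - 1) / n * np.sum((v - v.mean()) ** 2)))


def auc_with_jackknife(data: ChoiceDataset, spec: CBSSpec,
                       config: FitConfig | None = None) -> AUCEstimate:
    """AUC of the full-data CBS fit with a delete-one-trial jackknife SE."""
    config = config or FitConfig()
    full_fit = fit_model(data, spec, config)
    fold_config = _warm_config(config, full_fit)
    loo = np.empty(len(data))
    for i in range(len(data)):
        fold_fit = fit_model(data.without_trial(i), spec, fold_config)
        loo[i] = curve_auc(fold_fit.curve)
    return AUCEstimate(
        auc=curve_auc(full_fit.curve),
        jackknife_se=jackknife_se(loo),
        n_trials=len(data),
        loo_aucs=loo,
    )


def discount_rate_at(f, D: float) -> float:
    """Delay-specific discount rate h(D) = ln(-ln f(D) / D), in ln(1/day).

    ``f`` is any evaluable discount function (callable on a delay in days).
    Requires D > 0 and 0 < f(D) < 1.
    """
    D = float(D)
    if D <= 0:
        raise ValueError("discount rate is defined for D > 0")
    fd = float(f(D))
    if not 0.0 < fd < 1.0:
        raise ValueError(f"discount rate needs 0 < f(D) < 1, got f({D}) = {fd}")
    return math.log(-math.log(fd) / D)


def risk_aversion_at(f, p: float) -> float:
    """Probability-specific risk aversion q(p) = ln(f(p) / p).

    Zero means risk neutrality at p; positive means the probability is
    over-weighted (risk-seeking at p).  Requires 0 < p <= 1 and f(p) > 0.
    """
    p = float(p)
    if not 0.0 < p <= 1.0:
        raise ValueError("q(p) is defined for 0 < p <= 1")
    fp = float(f(p))
    if fp <= 0.0:
        raise ValueError(f"q(p) needs f(p) > 0, got f({p}) = {fp}")
    return math.log(fp / p)


def avg_discount_rate_change(curve: CBSCurve, spec: CBSSpec) -> float:
    """Average daily change of h(D) over the daily grid D = 1..x_scale.

    Computed as the endpoint slope (h at the last defined grid day minus h at
    the first, divided by the number of days between them); grid days where
    h is undefined (f = 1 plateaus near zero delay, or f = 0 floors) are
    skipped.  Negative for hyperbolic-like curves, roughly zero for
    exponential-like ones, positive for concave (increasingly impatient)
    curves.
    """
    if spec.task != "ITC":
        raise ValueError("the discount-rate trend applies to ITC curves")
    days = np.arange(1.0, spec.x_scale + 0.5)
    fvals = eval_curve(curve, days / spec.x_scale)
    ok = (fvals > 0.0) & (fvals < 1.0)
    if np.count_nonzero(ok) < 2:
        raise ValueError("discount rate undefined on (almost) the whole grid")
    d_ok = days[ok]
    h = np.log(-np.log(fvals[ok]) / d_ok)
    return float((h[-1] - h[0]) / (d_ok[-1] - d_ok[0]))


def count_risk_switches(f, dead_band: float = 1e-6) -> int:
    """Number of sign changes of q(p) on the grid p = 0.01 .. 0.99.

    ``f`` may be a :class:`CBSCurve` (evaluated on [0, 1]) or any callable
    weighting function.  Grid points with |q| < ``dead_band`` are ignored, so
    riding along the identity line does not count as crossings.
    """
    grid = np.arange(0.01, 0.995, 0.01)
    if isinstance(f, CBSCurve):
        fv = eval_curve(f, grid)
    elif isinstance(f, CBSModel):
        fv = f.f(grid)
    else:
        fv = np.asarray(f(grid), dtype=float)
    with np.errstate(divide="ignore"):
        q = np.log(np.maximum(fv, 0.0)) - np.log(grid)
    q = q[np.abs(q) >= dead_band]
    if q.size < 2:
        return 0
    signs = np.sign(q)
    return int(np.count_nonzero(signs[1:] != signs[:-1]))
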