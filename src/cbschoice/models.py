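"""Utility models: CBS curve parameterizations and the parametric family zoo.

Two kinds of models share the discounting form U = A * f(X):

* CBS models — a monotone cubic Bezier spline approximates f non-parametrically.
  For intertemporal choice (ITC) the curve is anchored at f(0) = 1 (the
  immediate option is undiscounted) and runs decreasing to a free terminal
  value at the normalized maximum delay.  For risky choice (RC) the curve is
  anchored at f(0) = 0 and f(1) = 1 (impossible and certain outcomes) and
  runs increasing.  The overall utility scale is absorbed by the logit noise
  parameter sigma, which is why both anchors can be fixed without loss.

* Parametric families — the standard discounting and probability-weighting
  models, all expressed in f(X) form, addressable by short codes:
  ITC: E (exponential), H (hyperbolic), Gh (generalized hyperbolic),
  Lt (log-time power), Q (quasi-hyperbolic), De (double exponential);
  RC: Eut (expected-utility power), H (probability hyperbola), Ge, T, P
  (Goldstein-Einhorn, Tversky-Kahneman and Prelec weighting in converted
  discounting form), Gh (generalized probability hyperbola), plus three
  non-discounting forms: R (risk-return/mean-variance), A (linear attribute),
  C (coefficient-of-variation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .bezier import (
    BezierDomainError,
    BezierPiece,
    CBSCurve,
    eval_curve,
    subdivide_piece,
)

__all__ = [
    "ConstraintError",
    "CBSSpec",
    "CBSModel",
    "ParametricSpec",
    "Family",
    "FAMILIES",
    "family",
    "family_codes",
    "build_cbs_curve",
    "unpack_cbs_curve",
    "discount_function",
    "option_utility",
    "recovery_parameter_sets",
    "two_piece_theta_from_curve",
]

_EPS = 1e-9  # slack on constraint checks, matching the fit engine's tolerance


class ConstraintError(ValueError):
    """A parameter vector violates a shape or box constraint."""


# ---------------------------------------------------------------------------
# CBS specifications

@dataclass(frozen=True)
class CBSSpec:
    """A CBS model family: task, number of pieces, and the delay scale.

    ``x_scale`` (ITC only) is the delay, in days, mapped to x = 1; delays are
    divided by it before curve evaluation and there is no extrapolation
    beyond it.  RC probabilities are already in [0, 1].
    """

    task: str  # "ITC" | "RC"
    n_pieces: int = 1
    x_scale: float | None = None

    def __post_init__(self) -> None:
        if self.task not in ("ITC", "RC"):
            raise ValueError(f"task must be 'ITC' or 'RC', got {self.task!r}")
        if self.n_pieces not in (1, 2):
            raise ValueError("only 1- and 2-piece CBS models are supported")
        if self.task == "ITC":
            scale = 180.0 if self.x_scale is None else float(self.x_scale)
            if scale <= 0:
                raise ValueError("x_scale must be positive")
            object.__setattr__(self, "x_scale", scale)
        elif self.x_scale is not None:
            raise ValueError("x_scale applies only to ITC")

    @property
    def direction(self) -> str:
        return "decreasing" if self.task == "ITC" else "increasing"

    @property
    def param_names(self) -> tuple[str, ...]:
        names = ["h1x", "h1y", "h2x", "h2y"]
        if self.n_pieces == 2:
            names += ["jx", "jy", "s", "h5x", "h5y"]
        if self.task == "ITC":
            names += ["y_end"]
        return tuple(names)

    @property
    def n_shape_params(self) -> int:
        return len(self.param_names)

    @property
    def code(self) -> str:
        return f"CBS{self.n_pieces}"


def _require(ok: bool, msg: str) -> None:
    if not ok:
        raise ConstraintError(msg)


def build_cbs_curve(theta: Sequence[float], spec: CBSSpec) -> CBSCurve:
    """Assemble a monotone-admissible curve from a shape-parameter vector.

    Two-piece curves take the outgoing handle as ``P4 = joint + s*(joint - P2)``
    with extension ``s >= 0``, which enforces the collinear smooth join by
    construction — one fewer free coordinate than raw control points.

    Raises :class:`ConstraintError` naming the violated bound for infeasible
    theta.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (spec.n_shape_params,):
        raise ConstraintError(
            f"{spec.code}/{spec.task} expects {spec.n_shape_params} shape "
            f"parameters {spec.param_names}, got {theta.shape}"
        )
    p = dict(zip(spec.param_names, (float(v) for v in theta)))
    decreasing = spec.task == "ITC"
    if decreasing:
        start = (0.0, 1.0)
        end = (1.0, p["y_end"])
        _require(-_EPS <= p["y_end"] <= 1.0 + _EPS, "y_end must lie in [0, 1]")
    else:
        start, end = (0.0, 0.0), (1.0, 1.0)

    def _box(name_x: str, name_y: str, xlo, xhi, ylo, yhi) -> tuple[float, float]:
        x, y = p[name_x], p[name_y]
        _require(xlo - _EPS <= x <= xhi + _EPS,
                 f"{name_x}={x:.6g} outside [{xlo:.6g}, {xhi:.6g}]")
        _require(min(ylo, yhi) - _EPS <= y <= max(ylo, yhi) + _EPS,
                 f"{name_y}={y:.6g} outside y-interval [{ylo:.6g}, {yhi:.6g}]")
        return x, y

    if spec.n_pieces == 1:
        h1 = _box("h1x", "h1y", start[0], end[0], start[1], end[1])
        h2 = _box("h2x", "h2y", start[0], end[0], start[1], end[1])
        piece = BezierPiece.from_points(start, h1, h2, end)
        return CBSCurve((piece,), spec.direction)

    jx, jy = p["jx"], p["jy"]
    _require(-_EPS <= jx <= 1.0 + _EPS, "jx must lie in [0, 1]")
    if decreasing:
        _require(end[1] - _EPS <= jy <= 1.0 + _EPS, "jy must lie in [y_end, 1]")
    else:
        _require(-_EPS <= jy <= 1.0 + _EPS, "jy must lie in [0, 1]")
    joint = (jx, jy)
    h1 = _box("h1x", "h1y", start[0], jx, start[1], jy)
    h2 = _box("h2x", "h2y", start[0], jx, start[1], jy)
    s = p["s"]
    _require(s >= -_EPS, "extension s must be non-negative")
    p4 = (jx + s * (jx - h2[0]), jy + s * (jy - h2[1]))
    _require(p4[0] <= end[0] + _EPS,
             f"extension s={s:.6g} pushes P4x={p4[0]:.6g} past x=1")
    if decreasing:
        _require(p4[1] >= end[1] - _EPS,
                 f"extension s={s:.6g} pushes P4y={p4[1]:.6g} below y_end")
    else:
        _require(p4[1] <= end[1] + _EPS,
                 f"extension s={s:.6g} pushes P4y={p4[1]:.6g} above 1")
    h5 = _box("h5x", "h5y", jx, end[0], jy, end[1])
    first = BezierPiece.from_points(start, h1, h2, joint)
    second = BezierPiece.from_points(joint, p4, h5, end)
    return CBSCurve((first, second), spec.direction)


def unpack_cbs_curve(curve: CBSCurve, spec: CBSSpec) -> np.ndarray:
    """Inverse of :func:`build_cbs_curve` on the feasible region."""
    if len(curve.pieces) != spec.n_pieces:
        raise ConstraintError(
            f"curve has {len(curve.pieces)} pieces, spec wants {spec.n_pieces}"
        )
    first = curve.pieces[0]
    vals = [first.points[1, 0], first.points[1, 1],
            first.points[2, 0], first.points[2, 1]]
    if spec.n_pieces == 2:
        second = curve.pieces[1]
        joint = first.points[3]
        v_in = joint - first.points[2]
        v_out = second.points[1] - joint
        # s from the better-conditioned coordinate of the collinear handles
        k = int(np.argmax(np.abs(v_in)))
        s = float(v_out[k] / v_in[k]) if abs(v_in[k]) > 1e-14 else 0.0
        vals += [joint[0], joint[1], max(s, 0.0),
                 second.points[2, 0], second.points[2, 1]]
    if spec.task == "ITC":
        vals.append(curve.pieces[-1].points[3, 1])
    return np.array(vals, dtype=float)


_SPLIT_LADDER = (0.5, 0.4, 0.6, 0.3, 0.7, 0.25, 0.75, 0.2, 0.8, 0.15, 0.85,
                 0.1, 0.9, 0.05, 0.95, 0.02, 0.98)


def two_piece_theta_from_curve(curve: CBSCurve, spec2: CBSSpec,
                               t: float | None = None) -> np.ndarray:
    """Two-piece parameters tracing exactly the same curve as a 1-piece one.

    Subdivides the single piece; the children meet collinearly by
    construction and trace the parent exactly, so the 2-piece family nests
    the 1-piece family.  Subdivision can leave a child's handle outside the
    child's endpoint box at extreme handle configurations (the box condition
    is sufficient, not necessary, for monotonicity), so when ``t`` is not
    given a ladder of split points is searched for one whose children keep
    the box certificate.  Used to warm-start the 2-piece fit at the 1-piece
    optimum.
    """
    if len(curve.pieces) != 1:
        raise ConstraintError("expected a 1-piece curve to subdivide")
    candidates = _SPLIT_LADDER if t is None else (float(t),)
    last_err: ConstraintError | None = None
    for tc in candidates:
        left, right = subdivide_piece(curve.pieces[0], tc)
        chain = CBSCurve((left, right), curve.direction)
        theta = unpack_cbs_curve(chain, spec2)
        try:
            build_cbs_curve(theta, spec2)
        except ConstraintError as err:
            last_err = err
            continue
        return theta
    raise ConstraintError(
        f"no split point keeps the children box-admissible: {last_err}"
    )


@dataclass(frozen=True)
class CBSModel:
    """A fitted/instantiated CBS discounting model: curve + spec."""

    curve: CBSCurve
    spec: CBSSpec

    @property
    def code(self) -> str:
        return self.spec.code

    def f(self, X):
        """Discount weight f(X); delays are normalized by x_scale first."""
        x = np.asarray(X, dtype=float)
        if self.spec.task == "ITC":
            if np.any(x < 0) or np.any(x > self.spec.x_scale):
                raise BezierDomainError(
                    f"delay outside [0, {self.spec.x_scale}] days; "
                    "CBS does not extrapolate"
                )
            x = x / self.spec.x_scale
        elif np.any(x < 0) or np.any(x > 1):
            raise BezierDomainError("probability outside [0, 1]")
        return eval_curve(self.curve, x)


# ---------------------------------------------------------------------------
# parametric families

@dataclass(frozen=True)
class Family:
    """One parametric family: closed-form f(X) or a full utility form.

    ``bounds`` are fitting boxes per parameter; ``log_scale`` marks strictly
    positive parameters optimized on the log scale.  ``discounting`` is False
    for the three RC forms (R, A, C) that cannot be written as U = A * f(p).
    ``fit_sigma`` is False where sigma is not separately identifiable (the
    linear attribute model, whose coefficients already carry the scale).
    """

    code: str
    task: str
    name: str
    param_names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]
    log_scale: tuple[bool, ...]
    discounting: bool = True
    fit_sigma: bool = True
    _f: Callable | None = None
    _utility: Callable | None = None

    def f(self, params: Mapping[str, float], X):
        if not self.discounting:
            raise ConstraintError(
                f"family {self.code} has no discounting form f(X); "
                "use option_utility instead"
            )
        x = np.asarray(X, dtype=float)
        if self.task == "ITC":
            if np.any(x < 0):
                raise ValueError("delays must be non-negative")
        elif np.any((x < 0) | (x > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        return self._f(params, x)

    def utility(self, params: Mapping[str, float], A, X):
        if self.discounting:
            return np.asarray(A, dtype=float) * self.f(params, X)
        return self._utility(params, np.asarray(A, dtype=float),
                             np.asarray(X, dtype=float))


@dataclass(frozen=True)
class ParametricSpec:
    """A parametric family together with (optionally) a parameter vector."""

    task: str
    code: str
    params: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        fam = family(self.task, self.code)
        if self.params is not None:
            p = dict(self.params)
            missing = set(fam.param_names) - set(p)
            if missing:
                raise ConstraintError(f"{self.code}: missing parameters {sorted(missing)}")
            for name, (lo, hi) in zip(fam.param_names, fam.bounds):
                if not (lo - _EPS <= p[name] <= hi + _EPS):
                    raise ConstraintError(
                        f"{self.code}: {name}={p[name]:.6g} outside [{lo:.6g}, {hi:.6g}]"
                    )
            object.__setattr__(self, "params", p)

    @property
    def family(self) -> Family:
        return family(self.task, self.code)

    def with_params(self, params: Mapping[str, float]) -> "ParametricSpec":
        return replace(self, params=dict(params))

    def f(self, X):
        if self.params is None:
            raise ConstraintError(f"{self.code}: parameters not set")
        return self.family.f(self.params, X)


def _with_zero_limit(expr: Callable, x: np.ndarray, at_zero: float) -> np.ndarray:
    """Evaluate a closed form, replacing x == 0 by its stated limit/convention."""
    out = np.empty_like(x)
    zero = x == 0
    if np.any(~zero):
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            out[~zero] = expr(x[~zero])
    out[zero] = at_zero
    return out


def _f_E(p, D):
    return np.exp(-math.exp(p["lnk"]) * D)


def _f_H_itc(p, D):
    return 1.0 / (1.0 + math.exp(p["lnk"]) * D)


def _f_Gh_itc(p, D):
    return (1.0 + math.exp(p["lnk"]) * D) ** (-p["s"])


def _f_Lt(p, D):
    # D^(-k) is undefined at D = 0; the immediate option is undiscounted by
    # convention, f(0) = 1.
    return _with_zero_limit(lambda d: d ** (-p["k"]), D, 1.0)


def _f_Q(p, D):
    # quasi-hyperbolic present bias: f jumps from 1 at D = 0 to beta just after
    return _with_zero_limit(lambda d: p["beta"] * np.exp(-math.exp(p["lnk"]) * d), D, 1.0)


def _f_De(p, D):
    a, b, w = math.exp(p["lna"]), math.exp(p["lnb"]), p["w"]
    return w * np.exp(-a * D) + (1.0 - w) * np.exp(-b * D)


def _f_Eut(p, prob):
    return prob ** (1.0 / p["alpha"])


def _f_H_rc(p, prob):
    return _with_zero_limit(lambda q: 1.0 / (1.0 + p["h"] * (1.0 / q - 1.0)), prob, 0.0)


def _f_Ge(p, prob):
    d, g, a = p["delta"], p["gamma"], p["alpha"]
    num = d * prob ** g
    return (num / (num + (1.0 - prob) ** g)) ** (1.0 / a)


def _f_T(p, prob):
    g, a = p["gamma"], p["alpha"]
    w = _with_zero_limit(
        lambda q: q ** g / (q ** g + (1.0 - q) ** g) ** (1.0 / g), prob, 0.0)
    return w ** (1.0 / a)


def _f_P(p, prob):
    d, g, a = p["delta"], p["gamma"], p["alpha"]
    return _with_zero_limit(
        lambda q: np.exp(-(d / a) * (-np.log(q)) ** g), prob, 0.0)


def _f_Gh_rc(p, prob):
    return _with_zero_limit(
        lambda q: (1.0 + p["h"] * (1.0 / q - 1.0)) ** (-p["s"]), prob, 0.0)


def _u_risk_return(p, A, prob):
    var = A * A * prob * (1.0 - prob)  # variance of the two-outcome gamble
    return A * prob - p["b"] * var


def _u_attribute(p, A, prob):
    return p["b0"] + p["b1"] * A + p["b2"] * prob


def _u_cv(p, A, prob):
    # CV = sd/mean = sqrt((1-p)/p); undefined at p = 0 (excluded by design)
    with np.errstate(divide="ignore"):
        cv = np.sqrt((1.0 - prob) / prob)
    return A * prob - p["b"] * cv


_LNK = (-13.0, 3.0)

_FAMILY_LIST = [
    Family("E", "ITC", "exponential", ("lnk",), (_LNK,), (False,), _f=_f_E),
    Family("H", "ITC", "hyperbolic", ("lnk",), (_LNK,), (False,), _f=_f_H_itc),
    Family("Gh", "ITC", "generalized hyperbolic", ("lnk", "s"),
           (_LNK, (0.01, 20.0)), (False, True), _f=_f_Gh_itc),
    Family("Lt", "ITC", "log-time power", ("k",), ((1e-4, 5.0),), (True,), _f=_f_Lt),
    Family("Q", "ITC", "quasi-hyperbolic", ("beta", "lnk"),
           ((1e-6, 1.0), _LNK), (False, False), _f=_f_Q),
    Family("De", "ITC", "double exponential", ("w", "lna", "lnb"),
           ((0.0, 1.0), _LNK, _LNK), (False, False, False), _f=_f_De),
    Family("Eut", "RC", "expected utility (power)", ("alpha",),
           ((0.02, 50.0),), (True,), _f=_f_Eut),
    Family("H", "RC", "probability hyperbola", ("h",),
           ((1e-4, 1e3),), (True,), _f=_f_H_rc),
    Family("Ge", "RC", "Goldstein-Einhorn weighting", ("alpha", "delta", "gamma"),
           ((0.05, 20.0), (0.01, 100.0), (0.05, 10.0)), (True, True, True), _f=_f_Ge),
    Family("T", "RC", "Tversky-Kahneman weighting", ("alpha", "gamma"),
           ((0.05, 20.0), (0.05, 10.0)), (True, True), _f=_f_T),
    Family("P", "RC", "Prelec weighting", ("alpha", "delta", "gamma"),
           ((0.05, 20.0), (0.01, 100.0), (0.05, 10.0)), (True, True, True), _f=_f_P),
    Family("Gh", "RC", "generalized probability hyperbola", ("h", "s"),
           ((1e-4, 1e3), (0.01, 10.0)), (True, True), _f=_f_Gh_rc),
    Family("R", "RC", "risk-return (mean-variance)", ("b",),
           ((-5.0, 5.0),), (False,), discounting=False, _utility=_u_risk_return),
    Family("A", "RC", "linear attribute", ("b0", "b1", "b2"),
           ((-100.0, 100.0),) * 3, (False,) * 3, discounting=False,
           fit_sigma=False, _utility=_u_attribute),
    Family("C", "RC", "coefficient of variation", ("b",),
           ((-500.0, 500.0),), (False,), discounting=False, _utility=_u_cv),
]

FAMILIES: dict[tuple[str, str], Family] = {(f.task, f.code): f for f in _FAMILY_LIST}


def family(task: str, code: str) -> Family:
    try:
        return FAMILIES[(task, code)]
    except KeyError:
        avail = ", ".join(sorted(c for t, c in FAMILIES if t == task))
        raise KeyError(f"unknown {task} family {code!r}; available: {avail}") from None


def family_codes(task: str) -> list[str]:
    return [f.code for f in _FAMILY_LIST if f.task == task]


def discount_function(spec: ParametricSpec, X):
    """Closed-form discount weight f(X) of a discounting-form family."""
    return spec.f(X)


def option_utility(model, A, X):
    """Utility of one option under any model.

    ``model`` is a :class:`CBSModel`, a :class:`ParametricSpec` with
    parameters, or a (curve, CBSSpec) pair.  Discounting forms give
    U = A * f(X); the R/A/C risky-choice forms use their own expressions.
    """
    if isinstance(model, tuple):
        model = CBSModel(*model)
    if isinstance(model, CBSModel):
        return np.asarray(A, dtype=float) * model.f(X)
    if isinstance(model, ParametricSpec):
        if model.params is None:
            raise ConstraintError(f"{model.code}: parameters not set")
        return model.family.utility(model.params, A, X)
    raise TypeError(f"unsupported model type {type(model).__name__}")


# ---------------------------------------------------------------------------
# simulation parameter registry (the recovery-study generating functions)

def recovery_parameter_sets() -> dict[tuple[str, str], list[dict[str, float]]]:
    """The 4 generating parameter sets per simulating family (12 families).

    These are the study conditions of the function-recovery experiment: six
    ITC and six RC discounting-form families, four parameterizations each.
    """
    return {
        ("ITC", "E"): [{"lnk": v} for v in (-8.0, -6.0, -4.0, -2.0)],
        ("ITC", "H"): [{"lnk": v} for v in (-8.0, -6.0, -4.0, -2.0)],
        ("ITC", "Gh"): [{"lnk": k, "s": s}
                        for k, s in ((-7.0, 0.5), (-7.0, 2.0), (-4.0, 0.5), (-4.0, 2.0))],
        ("ITC", "Lt"): [{"k": v} for v in (0.4, 0.2, 0.1, 0.05)],
        ("ITC", "Q"): [{"beta": b, "lnk": k}
                       for b, k in ((0.4, -7.0), (0.4, -4.0), (0.8, -7.0), (0.8, -4.0))],
        ("ITC", "De"): [{"w": w, "lna": -8.0, "lnb": -3.0}
                        for w in (0.7, 0.5, 0.3, 0.1)],
        ("RC", "Eut"): [{"alpha": v} for v in (0.2, 0.6, 1.0, 2.0)],
        ("RC", "H"): [{"h": v} for v in (0.1, 0.5, 2.0, 7.0)],
        ("RC", "Ge"): [{"alpha": 0.8, "delta": d, "gamma": g}
                       for d, g in ((0.5, 0.5), (0.5, 2.0), (2.0, 0.5), (2.0, 2.0))],
        ("RC", "T"): [{"alpha": 0.8, "gamma": g} for g in (0.25, 0.5, 1.0, 3.0)],
        ("RC", "P"): [{"alpha": 0.8, "delta": d, "gamma": g}
                      for d, g in ((0.5, 0.5), (0.5, 2.0), (2.0, 0.5), (2.0, 2.0))],
        ("RC", "Gh"): [{"h": h, "s": s}
                       for h, s in ((2.0, 0.3), (7.0, 0.3), (2.0, 1.5), (7.0, 1.5))],
    }
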