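"""Logit choice likelihood and the constrained multi-start MLE engine.

The choice model is a binary logit on the utility difference:

    log[p(choice=1) / p(choice=2)] = sigma * (U1 - U2),   U = A * f(X)

``sigma`` (>= 0) is the inverse choice noise linking the utility scale to
choice probabilities; it absorbs the units of money, which is why the CBS
discount weights can live on [0, 1].

Fitting maximizes the log-likelihood over the feasible region with a smooth
constrained local optimizer from several starting points (one deterministic
"diagonal" start plus seeded random feasible draws, plus any caller-supplied
warm starts).  CBS shape constraints (handle boxes, the joint ordering and
the bilinear extension caps of the 2-piece chain) are passed as inequality
constraints; parametric families use plain box bounds.  Sigma is optimized
on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .bezier import CBSCurve, _invert_piece, _power_coeffs
from .models import (
    CBSModel,
    CBSSpec,
    ConstraintError,
    Family,
    ParametricSpec,
    build_cbs_curve,
    option_utility,
    two_piece_theta_from_curve,
)

__all__ = [
    "ChoiceTrial",
    "ChoiceDataset",
    "FitConfig",
    "FitResult",
    "choice_probability",
    "negative_log_likelihood",
    "feasible_start",
    "deterministic_start",
    "fit_model",
]

_P_CLIP = 1e-12  # keep log-probabilities finite at boundary fits


def _bernstein_y(pts: np.ndarray, t: np.ndarray) -> np.ndarray:
    u = 1.0 - t
    return (u * u * u) * pts[0, 1] + 3.0 * (u * u) * t * pts[1, 1] \
        + 3.0 * u * (t * t) * pts[2, 1] + (t * t * t) * pts[3, 1]


@dataclass(frozen=True)
class ChoiceTrial:
    """One binary trial: two (amount, attribute) options and the choice."""

    a1: float
    x1: float
    a2: float
    x2: float
    choice: int  # 1 or 2

    def __post_init__(self) -> None:
        if self.choice not in (1, 2):
            raise ValueError(f"choice must be 1 or 2, got {self.choice}")
        if self.a1 <= 0 or self.a2 <= 0:
            raise ValueError("amounts must be positive")


@dataclass(frozen=True)
class ChoiceDataset:
    """Trial-level choice data for one task (and typically one session)."""

    task: str  # "ITC" | "RC"
    trials: tuple[ChoiceTrial, ...]
    label: str | None = None

    def __post_init__(self) -> None:
        if self.task not in ("ITC", "RC"):
            raise ValueError(f"task must be 'ITC' or 'RC', got {self.task!r}")
        trials = tuple(self.trials)
        if not trials:
            raise ValueError("dataset must contain at least one trial")
        for i, tr in enumerate(trials):
            for x in (tr.x1, tr.x2):
                if self.task == "ITC" and x < 0:
                    raise ValueError(f"trial {i}: delays must be non-negative")
                if self.task == "RC" and not 0.0 <= x <= 1.0:
                    raise ValueError(f"trial {i}: probabilities must lie in [0, 1]")
        object.__setattr__(self, "trials", trials)

    @classmethod
    def from_arrays(cls, task: str, a1, x1, a2, x2, choice,
                    label: str | None = None) -> "ChoiceDataset":
        cols = [np.asarray(c) for c in (a1, x1, a2, x2, choice)]
        n = len(cols[0])
        trials = tuple(
            ChoiceTrial(float(cols[0][i]), float(cols[1][i]),
                        float(cols[2][i]), float(cols[3][i]), int(cols[4][i]))
            for i in range(n)
        )
        return cls(task, trials, label)

    def __len__(self) -> int:
        return len(self.trials)

    def arrays(self) -> dict[str, np.ndarray]:
        t = self.trials
        return {
            "a1": np.array([tr.a1 for tr in t]),
            "x1": np.array([tr.x1 for tr in t]),
            "a2": np.array([tr.a2 for tr in t]),
            "x2": np.array([tr.x2 for tr in t]),
            "choice": np.array([tr.choice for tr in t], dtype=int),
        }

    def n_choices(self) -> tuple[int, int]:
        """Counts of (option-1 choices, option-2 choices)."""
        c = np.array([tr.choice for tr in self.trials])
        return int(np.sum(c == 1)), int(np.sum(c == 2))

    def without_trial(self, index: int) -> "ChoiceDataset":
        trials = self.trials[:index] + self.trials[index + 1:]
        return ChoiceDataset(self.task, trials, self.label)

    def subset(self, indices: Sequence[int]) -> "ChoiceDataset":
        return ChoiceDataset(self.task, tuple(self.trials[i] for i in indices), self.label)


def choice_probability(u1, u2, sigma):
    """p(choice = 1) under the logit model: logistic(sigma * (u1 - u2))."""
    sigma = float(sigma)
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    p = expit(sigma * (u1 - u2))
    if p.ndim == 0:
        return float(p)
    return p


@dataclass
class FitConfig:
    """Optimizer settings for :func:`fit_model`.

    ``n_starts`` counts the random feasible starts added to the one
    deterministic start; per-start seeds are ``seed + i``.  ``extra_starts``
    are caller-supplied natural parameter vectors (shape params followed by
    sigma) used as additional warm starts.
    """

    n_starts: int = 10
    seed: int = 0
    maxiter: int = 500
    ftol: float = 1e-9
    constraint_tol: float = 1e-9
    sigma_bounds: tuple[float, float] = (1e-6, 1e6)
    extra_starts: tuple = ()


@dataclass
class FitResult:
    """A fitted model: parameters, noise scale, likelihood and diagnostics."""

    spec: CBSSpec | ParametricSpec
    theta: np.ndarray            # natural-scale shape/family parameters
    sigma: float
    log_likelihood: float
    n_starts: int
    best_start: int
    converged: bool
    flags: list[str] = field(default_factory=list)
    start_seeds: tuple[int, ...] = ()
    n_trials: int = 0

    @property
    def params(self) -> dict[str, float]:
        names = (self.spec.param_names if isinstance(self.spec, CBSSpec)
                 else self.spec.family.param_names)
        return dict(zip(names, (float(v) for v in self.theta)))

    def model(self):
        """The fitted model object usable with :func:`option_utility`."""
        if isinstance(self.spec, CBSSpec):
            return CBSModel(build_cbs_curve(self.theta, self.spec), self.spec)
        return self.spec.with_params(self.params)

    @property
    def curve(self) -> CBSCurve:
        if not isinstance(self.spec, CBSSpec):
            raise TypeError("only CBS fits carry a curve")
        return build_cbs_curve(self.theta, self.spec)

    def predict_choice1_probability(self, data: ChoiceDataset) -> np.ndarray:
        """Predicted p(choice = 1) per trial; ignores the recorded choices."""
        arr = data.arrays()
        model = self.model()
        u1 = option_utility(model, arr["a1"], arr["x1"])
        u2 = option_utility(model, arr["a2"], arr["x2"])
        return np.atleast_1d(choice_probability(u1, u2, self.sigma))

    @property
    def code(self) -> str:
        return self.spec.code


# ---------------------------------------------------------------------------
# likelihood

class _Problem:
    """Precomputed arrays and caches for repeated likelihood evaluation."""

    def __init__(self, data: ChoiceDataset, spec) -> None:
        self.data = data
        self.spec = spec
        arr = data.arrays()
        self.a1, self.a2 = arr["a1"], arr["a2"]
        self.choice1 = arr["choice"] == 1
        self.n = len(data)
        if isinstance(spec, CBSSpec):
            if spec.task != data.task:
                raise ValueError(f"spec task {spec.task} does not match data task {data.task}")
            scale = spec.x_scale if spec.task == "ITC" else 1.0
            x = np.concatenate([arr["x1"], arr["x2"]]) / scale
            if np.any(x < -1e-12) or np.any(x > 1 + 1e-12):
                raise ValueError(
                    "attribute outside the CBS domain after normalization; "
                    "increase x_scale (no extrapolation)"
                )
            self.ux, inv = np.unique(np.clip(x, 0.0, 1.0), return_inverse=True)
            self.inv1, self.inv2 = inv[: self.n], inv[self.n:]
            self.family = None
        else:
            self.family = spec.family
            if self.family.task != data.task:
                raise ValueError(f"family {spec.code} is a {self.family.task} model")
            self.x1, self.x2 = arr["x1"], arr["x2"]

    def _cbs_f_unique(self, theta: np.ndarray) -> np.ndarray:
        """f at the cached unique x values, bypassing curve-object plumbing.

        Assumes a feasible (or projected-feasible) shape vector; the public
        likelihood entry point validates instead via build_cbs_curve.
        """
        spec = self.spec
        itc = spec.task == "ITC"
        ux = self.ux
        if spec.n_pieces == 1:
            pts = np.empty((4, 2))
            pts[0] = (0.0, 1.0) if itc else (0.0, 0.0)
            pts[1] = theta[0:2]
            pts[2] = theta[2:4]
            pts[3] = (1.0, theta[4]) if itc else (1.0, 1.0)
            return _bernstein_y(pts, _invert_piece(_power_coeffs(pts[:, 0]), ux))
        h1, h2 = theta[0:2], theta[2:4]
        joint = theta[4:6]
        s = theta[6]
        h5 = theta[7:9]
        start = np.array([0.0, 1.0]) if itc else np.array([0.0, 0.0])
        end = np.array([1.0, theta[9]]) if itc else np.array([1.0, 1.0])
        p4 = joint + s * (joint - h2)
        first = np.array([start, h1, h2, joint])
        second = np.array([joint, p4, h5, end])
        k = int(np.searchsorted(ux, joint[0], side="right"))  # joint -> left piece
        f = np.empty_like(ux)
        if k:
            f[:k] = _bernstein_y(first, _invert_piece(_power_coeffs(first[:, 0]), ux[:k]))
        if k < ux.size:
            f[k:] = _bernstein_y(second, _invert_piece(_power_coeffs(second[:, 0]), ux[k:]))
        return f

    def utility_difference(self, theta: np.ndarray) -> np.ndarray:
        if self.family is None:
            f = self._cbs_f_unique(theta)
            return self.a1 * f[self.inv1] - self.a2 * f[self.inv2]
        params = dict(zip(self.family.param_names, theta))
        u1 = self.family.utility(params, self.a1, self.x1)
        u2 = self.family.utility(params, self.a2, self.x2)
        return u1 - u2

    def nll(self, theta: np.ndarray, sigma: float) -> float:
        du = self.utility_difference(theta)
        p1 = expit(sigma * du)
        p = np.where(self.choice1, p1, 1.0 - p1)
        return -float(np.sum(np.log(np.clip(p, _P_CLIP, 1.0))))


def negative_log_likelihood(theta: Sequence[float], data: ChoiceDataset, spec) -> float:
    """-sum of log choice probabilities for the full parameter vector.

    ``theta`` holds the natural shape/family parameters followed by sigma
    (sigma is omitted for families that fix it, i.e. the linear attribute
    model).  Infeasible parameters raise :class:`ConstraintError` — they are
    never silently projected.
    """
    theta = np.asarray(theta, dtype=float)
    fit_sigma = True if isinstance(spec, CBSSpec) else spec.family.fit_sigma
    if fit_sigma:
        shape, sigma = theta[:-1], float(theta[-1])
        if sigma < 0:
            raise ConstraintError("sigma must be non-negative")
    else:
        shape, sigma = theta, 1.0
    prob = _Problem(data, spec)
    if prob.family is None:
        build_cbs_curve(shape, spec)  # strict feasibility check
    else:
        if shape.shape != (len(prob.family.param_names),):
            raise ConstraintError(
                f"{spec.code} expects parameters {prob.family.param_names}")
        for v, name, (lo, hi) in zip(shape, prob.family.param_names, prob.family.bounds):
            if not lo - 1e-9 <= v <= hi + 1e-9:
                raise ConstraintError(f"{name}={v:.6g} outside [{lo:.6g}, {hi:.6g}]")
    return prob.nll(shape, sigma)


# ---------------------------------------------------------------------------
# starts

def deterministic_start(spec) -> np.ndarray:
    """A fixed feasible start (shape parameters + sigma = 1).

    For CBS this is the straight diagonal: collinear handles on the line from
    (0, 1) to (1, 0.5) for ITC, or from (0, 0) to (1, 1) for RC; the 2-piece
    version is the exact midpoint subdivision of that line.
    """
    if isinstance(spec, CBSSpec):
        if spec.task == "ITC":
            y_end = 0.5
            theta1 = np.array([1 / 3, 1.0 - (1 - y_end) / 3,
                               2 / 3, 1.0 - 2 * (1 - y_end) / 3, y_end])
            spec1 = CBSSpec("ITC", 1, spec.x_scale)
        else:
            theta1 = np.array([1 / 3, 1 / 3, 2 / 3, 2 / 3])
            spec1 = CBSSpec("RC", 1)
        if spec.n_pieces == 1:
            shape = theta1
        else:
            curve = build_cbs_curve(theta1, spec1)
            shape = two_piece_theta_from_curve(curve, spec)
        return np.append(shape, 1.0)
    fam = spec.family
    mid = []
    for (lo, hi), logs in zip(fam.bounds, fam.log_scale):
        if logs:
            mid.append(float(np.sqrt(lo * hi)))
        else:
            mid.append(0.5 * (lo + hi))
    # sensible neutral values where the box midpoint is extreme
    defaults = {"lnk": -4.0, "lna": -6.0, "lnb": -3.0, "beta": 0.8, "w": 0.5,
                "alpha": 1.0, "gamma": 1.0, "delta": 1.0, "h": 1.0, "s": 1.0,
                "k": 0.1, "b": 0.0, "b0": 0.0, "b1": 0.1, "b2": 0.1}
    shape = np.array([defaults.get(name, m)
                      for name, m in zip(fam.param_names, mid)])
    return np.append(shape, 1.0) if fam.fit_sigma else shape


def feasible_start(spec, rng: np.random.Generator) -> np.ndarray:
    """A strictly feasible random start (shape parameters + sigma = 1)."""
    if isinstance(spec, CBSSpec):
        decreasing = spec.task == "ITC"
        y_end = rng.uniform(0.02, 0.98) if decreasing else None
        if spec.n_pieces == 1:
            lo_y, hi_y = (y_end, 1.0) if decreasing else (0.0, 1.0)
            shape = [rng.uniform(0.0, 1.0), rng.uniform(lo_y, hi_y),
                     rng.uniform(0.0, 1.0), rng.uniform(lo_y, hi_y)]
            if decreasing:
                shape.append(y_end)
        else:
            jx = rng.uniform(0.15, 0.85)
            if decreasing:
                jy = rng.uniform(y_end, 1.0)
                h1 = [rng.uniform(0, jx), rng.uniform(jy, 1.0)]
                h2 = [rng.uniform(0, jx), rng.uniform(jy, 1.0)]
                caps = [3.0]
                if jx - h2[0] > 1e-9:
                    caps.append((1.0 - jx) / (jx - h2[0]))
                if h2[1] - jy > 1e-9:
                    caps.append((jy - y_end) / (h2[1] - jy))
                s = rng.uniform(0.0, min(caps))
                h5 = [rng.uniform(jx, 1.0), rng.uniform(y_end, jy)]
            else:
                jy = rng.uniform(0.02, 0.98)
                h1 = [rng.uniform(0, jx), rng.uniform(0, jy)]
                h2 = [rng.uniform(0, jx), rng.uniform(0, jy)]
                caps = [3.0]
                if jx - h2[0] > 1e-9:
                    caps.append((1.0 - jx) / (jx - h2[0]))
                if jy - h2[1] > 1e-9:
                    caps.append((1.0 - jy) / (jy - h2[1]))
                s = rng.uniform(0.0, min(caps))
                h5 = [rng.uniform(jx, 1.0), rng.uniform(jy, 1.0)]
            shape = h1 + h2 + [jx, jy, s] + h5
            if decreasing:
                shape.append(y_end)
        return np.append(np.array(shape), 1.0)
    fam = spec.family
    shape = []
    for (lo, hi), logs in zip(fam.bounds, fam.log_scale):
        if logs:
            shape.append(float(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        else:
            shape.append(float(rng.uniform(lo, hi)))
    shape = np.array(shape)
    return np.append(shape, 1.0) if fam.fit_sigma else shape


# ---------------------------------------------------------------------------
# optimizer plumbing

def _cbs_bounds_and_constraints(spec: CBSSpec, log_sigma_bounds):
    names = spec.param_names
    bounds = []
    for name in names:
        bounds.append((0.0, 50.0) if name == "s" else (0.0, 1.0))
    bounds.append(tuple(log_sigma_bounds))
    idx = {name: i for i, name in enumerate(names)}
    cons = []
    decreasing = spec.task == "ITC"

    def g(z):
        out = []
        if spec.n_pieces == 1:
            if decreasing:
                out += [z[idx["h1y"]] - z[idx["y_end"]],
                        z[idx["h2y"]] - z[idx["y_end"]]]
        else:
            jx, jy, s = z[idx["jx"]], z[idx["jy"]], z[idx["s"]]
            out += [jx - z[idx["h1x"]], jx - z[idx["h2x"]],
                    z[idx["h5x"]] - jx,
                    1.0 - (jx + s * (jx - z[idx["h2x"]]))]
            if decreasing:
                ye = z[idx["y_end"]]
                out += [z[idx["h1y"]] - jy, z[idx["h2y"]] - jy, jy - ye,
                        (jy - s * (z[idx["h2y"]] - jy)) - ye,
                        jy - z[idx["h5y"]], z[idx["h5y"]] - ye]
            else:
                out += [jy - z[idx["h1y"]], jy - z[idx["h2y"]],
                        1.0 - (jy + s * (jy - z[idx["h2y"]])),
                        z[idx["h5y"]] - jy]
        return np.array(out)

    if spec.n_pieces == 2 or decreasing:
        cons = [{"type": "ineq", "fun": g}]
    return bounds, cons


def _project_cbs(z: np.ndarray, spec: CBSSpec) -> np.ndarray:
    """Nearest-in-coordinates feasible shape vector (optimizer-internal).

    The constrained optimizer can probe mildly infeasible points during line
    search; the objective evaluates the projected point so the curve is
    always well-defined.  Final results are projected once and re-validated.
    """
    clip = lambda v, lo, hi: min(max(v, lo), hi)
    decreasing = spec.task == "ITC"
    z = [float(v) for v in z]
    if spec.n_pieces == 1:
        if decreasing:
            ye = clip(z[4], 0.0, 1.0)
            return np.array([clip(z[0], 0, 1), clip(z[1], ye, 1.0),
                             clip(z[2], 0, 1), clip(z[3], ye, 1.0), ye])
        return np.array([clip(v, 0.0, 1.0) for v in z[:4]])
    h1x, h1y, h2x, h2y, jx, jy, s, h5x, h5y = z[:9]
    jx = clip(jx, 0.0, 1.0)
    if decreasing:
        ye = clip(z[9], 0.0, 1.0)
        jy = clip(jy, ye, 1.0)
        h1 = [clip(h1x, 0, jx), clip(h1y, jy, 1.0)]
        h2 = [clip(h2x, 0, jx), clip(h2y, jy, 1.0)]
        s_cap = 50.0
        if jx - h2[0] > 1e-12:
            s_cap = min(s_cap, (1.0 - jx) / (jx - h2[0]))
        if h2[1] - jy > 1e-12:
            s_cap = min(s_cap, (jy - ye) / (h2[1] - jy))
        s = clip(s, 0.0, s_cap)
        h5 = [clip(h5x, jx, 1.0), clip(h5y, ye, jy)]
        return np.array(h1 + h2 + [jx, jy, s] + h5 + [ye])
    jy = clip(jy, 0.0, 1.0)
    h1 = [clip(h1x, 0, jx), clip(h1y, 0, jy)]
    h2 = [clip(h2x, 0, jx), clip(h2y, 0, jy)]
    s_cap = 50.0
    if jx - h2[0] > 1e-12:
        s_cap = min(s_cap, (1.0 - jx) / (jx - h2[0]))
    if jy - h2[1] > 1e-12:
        s_cap = min(s_cap, (1.0 - jy) / (jy - h2[1]))
    s = clip(s, 0.0, s_cap)
    h5 = [clip(h5x, jx, 1.0), clip(h5y, jy, 1.0)]
    return np.array(h1 + h2 + [jx, jy, s] + h5)


def _to_internal(shape: np.ndarray, fam: Family) -> np.ndarray:
    return np.array([np.log(v) if logs else v
                     for v, logs in zip(shape, fam.log_scale)])


def _from_internal(z: np.ndarray, fam: Family) -> np.ndarray:
    return np.array([np.exp(v) if logs else v
                     for v, logs in zip(z, fam.log_scale)])


def _screen_grid(fam: Family) -> list[np.ndarray]:
    """A coarse deterministic grid over a parametric family's box (sigma = 1).

    Misfit parameter regions make the logit likelihood cliff-like at sigma=1
    (every trial saturates), so a local optimizer started far from the truth
    can slide into a small-sigma basin and stay there.  Screening a fixed
    grid of parameter combinations by likelihood before polishing keeps the
    searched region well covered at negligible cost.
    """
    per_param = {1: 8, 2: 6, 3: 5}[len(fam.param_names)]
    axes = []
    for (lo, hi), logs in zip(fam.bounds, fam.log_scale):
        if logs:
            axes.append(np.exp(np.linspace(np.log(lo), np.log(hi), per_param + 2)[1:-1]))
        else:
            axes.append(np.linspace(lo, hi, per_param + 2)[1:-1])
    mesh = np.meshgrid(*axes, indexing="ij")
    shapes = np.stack([m.ravel() for m in mesh], axis=1)
    if fam.fit_sigma:
        shapes = np.hstack([shapes, np.ones((len(shapes), 1))])
    return [row for row in shapes]


def fit_model(data: ChoiceDataset, spec, config: FitConfig | None = None) -> FitResult:
    """Constrained maximum-likelihood fit of a CBS or parametric model.

    Candidate starts are the deterministic start, ``config.n_starts`` seeded
    random feasible starts, a coarse screening grid over the box (parametric
    families only) and any ``config.extra_starts``.  Every candidate's
    likelihood is evaluated; the most promising ones (and all extra starts)
    are polished with a smooth constrained optimizer (SLSQP for CBS shape
    constraints, L-BFGS-B for box-bounded parametric families) and the best
    final likelihood wins.  A start is never made worse: if polishing fails,
    the start itself remains a candidate.  Deterministic given
    ``config.seed``.
    """
    config = config or FitConfig()
    problem = _Problem(data, spec)
    is_cbs = isinstance(spec, CBSSpec)
    fam = None if is_cbs else spec.family
    fit_sigma = True if is_cbs else fam.fit_sigma
    log_sb = (np.log(config.sigma_bounds[0]), np.log(config.sigma_bounds[1]))

    # assemble candidate starts in natural scale: shape params (+ sigma)
    start_seeds = tuple(config.seed + i for i in range(config.n_starts))
    starts = [deterministic_start(spec)]
    for s in start_seeds:
        starts.append(feasible_start(spec, np.random.default_rng(s)))
    always_polish: set[int] = set()
    for extra in config.extra_starts:
        always_polish.add(len(starts))
        starts.append(np.asarray(extra, dtype=float))
    if not is_cbs:
        starts.extend(_screen_grid(fam))

    if is_cbs:
        bounds, cons = _cbs_bounds_and_constraints(spec, log_sb)
        n_shape = spec.n_shape_params

        def objective(z):
            shape = _project_cbs(z[:n_shape], spec)
            return problem.nll(shape, float(np.exp(z[-1])))

        def natural_to_z(theta):
            return np.append(np.clip(theta[:-1], [b[0] for b in bounds[:-1]],
                                     [b[1] for b in bounds[:-1]]),
                             np.clip(np.log(max(theta[-1], 1e-300)), *log_sb))

        def z_to_natural(z):
            return np.append(_project_cbs(z[:n_shape], spec), np.exp(z[-1]))

        method = "SLSQP"
        options = {"maxiter": config.maxiter, "ftol": config.ftol}
    else:
        lo = np.array([b[0] for b in fam.bounds])
        hi = np.array([b[1] for b in fam.bounds])
        ilo = _to_internal(lo, fam)
        ihi = _to_internal(hi, fam)
        bounds = list(zip(ilo, ihi))
        if fit_sigma:
            bounds.append(log_sb)
        cons = ()
        n_shape = len(fam.param_names)

        def objective(z):
            shape = _from_internal(z[:n_shape], fam)
            sigma = float(np.exp(z[-1])) if fit_sigma else 1.0
            return problem.nll(shape, sigma)

        def natural_to_z(theta):
            shape = np.clip(theta[:n_shape], lo, hi)
            z = _to_internal(shape, fam)
            if fit_sigma:
                z = np.append(z, np.clip(np.log(max(theta[-1], 1e-300)), *log_sb))
            return z

        def z_to_natural(z):
            shape = _from_internal(z[:n_shape], fam)
            if fit_sigma:
                return np.append(shape, np.exp(z[-1]))
            return shape

        method = "L-BFGS-B"
        options = {"maxiter": config.maxiter, "ftol": config.ftol}

    best_z = None
    best_nll = np.inf
    best_start = -1
    converged = False
    diagnostics = []
    z_cands = [natural_to_z(start) for start in starts]
    f_cands = np.array([objective(z) for z in z_cands])
    n_polish = max(2, config.n_starts + 1)
    polish = set(int(i) for i in np.argsort(f_cands, kind="stable")[:n_polish])
    polish |= always_polish
    for i, z0 in enumerate(z_cands):
        f0 = float(f_cands[i])
        if f0 < best_nll:
            best_nll, best_z, best_start = f0, z0, i
        if i not in polish:
            continue
        try:
            res = minimize(objective, z0, method=method, bounds=bounds,
                           constraints=cons, options=options)
        except Exception as exc:  # pragma: no cover - optimizer edge cases
            diagnostics.append(f"start {i}: {exc}")
            continue
        converged = converged or bool(res.success)
        diagnostics.append(f"start {i}: nll={res.fun:.6g} success={res.success}")
        if np.isfinite(res.fun) and res.fun < best_nll:
            best_nll, best_z, best_start = float(res.fun), res.x, i
    if best_z is None:
        raise RuntimeError("all optimization starts failed:\n" + "\n".join(diagnostics))

    final = z_to_natural(best_z)
    if fit_sigma:
        theta, sigma = final[:-1], float(final[-1])
    else:
        theta, sigma = final, 1.0
    nll = problem.nll(theta, sigma)

    flags: list[str] = []
    n1, n2 = data.n_choices()
    if n1 == 0 or n2 == 0:
        flags.append("separation: boundary solution likely")
    active = []
    zf = best_z
    for j, (blo, bhi) in enumerate(bounds[:len(zf)]):
        if zf[j] - blo < 1e-6 or bhi - zf[j] < 1e-6:
            active.append(j)
    if active:
        flags.append(f"active bounds at internal coordinates {active}")
    return FitResult(
        spec=spec, theta=np.asarray(theta, dtype=float), sigma=sigma,
        log_likelihood=-nll, n_starts=len(starts), best_start=best_start,
        converged=converged, flags=flags, start_seeds=start_seeds,
        n_trials=len(data),
    )
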