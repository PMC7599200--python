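"""Monotone cubic Bezier geometry.

A single cubic Bezier piece is defined by four planar control points
``P0..P3``.  Its x- and y-coordinates are independent cubic Bernstein
polynomials of an internal parameter ``t`` in [0, 1]:

    m(t) = (1-t)^3 P0x + 3(1-t)^2 t P1x + 3(1-t) t^2 P2x + t^3 P3x
    n(t) = (1-t)^3 P0y + 3(1-t)^2 t P1y + 3(1-t) t^2 P2y + t^3 P3y

When both coordinate polynomials are monotone in ``t`` the pair traces a
monotone function ``y = n(m^{-1}(x))``.  A sufficient condition is that the
two handles lie inside the bounding box of the endpoints:
``P1x, P2x in [P0x, P3x]`` and ``P1y, P2y`` between ``P0y`` and ``P3y``
(closed intervals, so flat segments are admissible).

Several pieces chain into a spline when adjacent pieces share an endpoint
exactly and the handle entering a joint, the joint, and the handle leaving it
are collinear with the outgoing handle on the opposite side — this matches
the one-sided derivatives and makes the chained curve C1-smooth.

Everything in this module is pure geometry: evaluation, inversion of the
x-polynomial by a safeguarded bracketed search, exact de Casteljau
subdivision, admissibility validation, and the exact polynomial area under
the curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BezierError",
    "BezierDomainError",
    "BezierPiece",
    "CBSCurve",
    "MonotoneReport",
    "eval_piece",
    "eval_piece_decasteljau",
    "invert_x",
    "eval_curve",
    "validate_monotone",
    "subdivide_piece",
    "curve_auc",
    "random_admissible_piece",
    "random_monotone_curve",
]

#: default tolerance on |m(t*) - x| for x-inversion
TOL_X = 1e-10
#: default absolute tolerance for the joint collinearity cross-product test
TOL_LIN = 1e-9
#: slack for closed-interval box membership (floating round-off only)
_TOL_BOX = 1e-12


class BezierError(ValueError):
    """Base class for curve-geometry errors."""


class BezierDomainError(BezierError):
    """An input (t or x) lies outside the valid domain of the curve."""


@dataclass(frozen=True, eq=False)
class BezierPiece:
    """One cubic segment, stored as a (4, 2) array of control points.

    The x-orientation is fixed left-to-right: ``P0x <= P3x``.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (4, 2):
            raise BezierError(f"expected 4 control points, got shape {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise BezierError("control points must be finite")
        if pts[0, 0] > pts[3, 0] + _TOL_BOX:
            raise BezierError(
                f"x-orientation must be left-to-right: P0x={pts[0, 0]} > P3x={pts[3, 0]}"
            )
        pts.flags.writeable = False
        object.__setattr__(self, "points", pts)

    @classmethod
    def from_points(cls, p0, p1, p2, p3) -> "BezierPiece":
        return cls(np.array([p0, p1, p2, p3], dtype=float))

    @property
    def p0(self) -> np.ndarray:
        return self.points[0]

    @property
    def p1(self) -> np.ndarray:
        return self.points[1]

    @property
    def p2(self) -> np.ndarray:
        return self.points[2]

    @property
    def p3(self) -> np.ndarray:
        return self.points[3]

    @property
    def x_range(self) -> tuple[float, float]:
        return float(self.points[0, 0]), float(self.points[3, 0])

    def x_power_coeffs(self) -> np.ndarray:
        """Power-basis coefficients (c0..c3) of m(t)."""
        return _power_coeffs(self.points[:, 0])

    def y_power_coeffs(self) -> np.ndarray:
        """Power-basis coefficients (c0..c3) of n(t)."""
        return _power_coeffs(self.points[:, 1])

    def is_admissible(self) -> bool:
        return not _piece_violations(self, 0)


@dataclass(frozen=True, eq=False)
class CBSCurve:
    """An ordered chain of 1+ monotone Bezier pieces with smooth joins.

    ``direction`` records the intended monotone direction of y in x:
    ``"decreasing"`` for delay discounting (ITC), ``"increasing"`` for
    probability weighting (RC).
    """

    pieces: tuple[BezierPiece, ...]
    direction: str  # "increasing" | "decreasing"

    def __post_init__(self) -> None:
        if self.direction not in ("increasing", "decreasing"):
            raise BezierError(f"unknown direction {self.direction!r}")
        pieces = tuple(self.pieces)
        if not pieces:
            raise BezierError("curve needs at least one piece")
        object.__setattr__(self, "pieces", pieces)

    @property
    def x_min(self) -> float:
        return float(self.pieces[0].points[0, 0])

    @property
    def x_max(self) -> float:
        return float(self.pieces[-1].points[3, 0])

    @property
    def y_start(self) -> float:
        return float(self.pieces[0].points[0, 1])

    @property
    def y_end(self) -> float:
        return float(self.pieces[-1].points[3, 1])

    def __call__(self, x):
        return eval_curve(self, x)


@dataclass
class MonotoneReport:
    """Outcome of :func:`validate_monotone`: truthy iff the curve is valid."""

    ok: bool
    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


def _power_coeffs(p: np.ndarray) -> np.ndarray:
    """Convert one Bernstein coordinate (4 control values) to power basis."""
    p0, p1, p2, p3 = (float(v) for v in p)
    return np.array(
        [
            p0,
            3.0 * (p1 - p0),
            3.0 * (p2 - 2.0 * p1 + p0),
            p3 - 3.0 * p2 + 3.0 * p1 - p0,
        ]
    )


def _bernstein_weights(t: np.ndarray) -> tuple[np.ndarray, ...]:
    u = 1.0 - t
    return u * u * u, 3.0 * u * u * t, 3.0 * u * t * t, t * t * t


def _check_t(t: np.ndarray) -> None:
    if np.any((t < 0.0) | (t > 1.0)) or not np.all(np.isfinite(t)):
        raise BezierDomainError("t must lie in [0, 1]")


def eval_piece(piece: BezierPiece, t):
    """Evaluate (m(t), n(t)) in Bernstein form; exact at the endpoints.

    ``t`` may be a scalar or an array; returns (x, y) with matching shape.
    """
    ta = np.asarray(t, dtype=float)
    _check_t(ta)
    b0, b1, b2, b3 = _bernstein_weights(ta)
    pts = piece.points
    x = b0 * pts[0, 0] + b1 * pts[1, 0] + b2 * pts[2, 0] + b3 * pts[3, 0]
    y = b0 * pts[0, 1] + b1 * pts[1, 1] + b2 * pts[2, 1] + b3 * pts[3, 1]
    if ta.ndim == 0:
        return float(x), float(y)
    return x, y


def eval_piece_decasteljau(piece: BezierPiece, t):
    """Evaluate a piece by repeated linear interpolation (test oracle)."""
    ta = np.asarray(t, dtype=float)
    _check_t(ta)
    w = ta[..., None]  # broadcast over the coordinate axis
    level = piece.points[(slice(None),) + (None,) * ta.ndim]  # (4, ..., 2)
    while level.shape[0] > 1:
        level = (1.0 - w) * level[:-1] + w * level[1:]
    x, y = level[0, ..., 0], level[0, ..., 1]
    if ta.ndim == 0:
        return float(x), float(y)
    return x, y


def _invert_piece(piece_or_coeffs, x: np.ndarray, tol: float = 1e-13,
                  max_iter: int = 100) -> np.ndarray:
    """Solve m(t) = x elementwise on one piece (m monotone non-decreasing).

    Safeguarded Newton iteration on the bracket [0, 1]: any step that leaves
    the current bracket, or a flat derivative, falls back to bisection, so
    convergence is guaranteed for monotone m.  Closed-form cubic roots are
    deliberately not used.
    """
    if isinstance(piece_or_coeffs, BezierPiece):
        c0, c1, c2, c3 = piece_or_coeffs.x_power_coeffs()
        x0, x3 = piece_or_coeffs.x_range
    else:
        c0, c1, c2, c3 = piece_or_coeffs
        x0 = c0
        x3 = c0 + c1 + c2 + c3
    xa = np.asarray(x, dtype=float)
    lo = np.zeros_like(xa)
    hi = np.ones_like(xa)
    span = max(x3 - x0, 1e-300)
    t = np.clip((xa - x0) / span, 0.0, 1.0)
    # pin exact endpoints so the round-trip is exact there
    at_lo = xa <= x0
    at_hi = xa >= x3
    t = np.where(at_lo, 0.0, np.where(at_hi, 1.0, t))
    pinned = at_lo | at_hi
    for _ in range(max_iter):
        m = ((c3 * t + c2) * t + c1) * t + c0
        err = m - xa
        err = np.where(pinned, 0.0, err)
        if np.max(np.abs(err)) <= tol:
            break
        below = err < 0.0
        lo = np.where(below, t, lo)
        hi = np.where(below, hi, t)
        deriv = (3.0 * c3 * t + 2.0 * c2) * t + c1
        with np.errstate(divide="ignore", invalid="ignore"):
            t_new = t - err / deriv
        bad = ~np.isfinite(t_new) | (t_new <= lo) | (t_new >= hi)
        t = np.where(pinned, t, np.where(bad, 0.5 * (lo + hi), t_new))
    return t


def _piece_index(curve: CBSCurve, x: np.ndarray) -> np.ndarray:
    """Assign each x to a piece; an x at a shared joint goes to the left piece."""
    if len(curve.pieces) == 1:
        return np.zeros(np.shape(x), dtype=int)
    joints = np.array([p.points[3, 0] for p in curve.pieces[:-1]])
    return np.searchsorted(joints, x, side="left")


def _check_curve_range(curve: CBSCurve, xa: np.ndarray) -> None:
    if xa.size and (np.min(xa) < curve.x_min - _TOL_BOX
                    or np.max(xa) > curve.x_max + _TOL_BOX):
        raise BezierDomainError(
            f"x outside curve range [{curve.x_min}, {curve.x_max}]; "
            "the curve does not extrapolate"
        )


def invert_x(curve: CBSCurve, x: float, tol: float = TOL_X) -> tuple[int, float]:
    """Find (piece index, t*) with m(t*) = x, by bracketed numerical search."""
    xa = np.asarray(float(x))
    _check_curve_range(curve, xa.reshape(1))
    idx = int(_piece_index(curve, xa))
    t = _invert_piece(curve.pieces[idx], xa.reshape(1), tol=tol)[0]
    return idx, float(t)


def eval_curve(curve: CBSCurve, x):
    """Evaluate y = n(m^{-1}(x)) elementwise; no extrapolation outside range."""
    xa = np.asarray(x, dtype=float)
    scalar = xa.ndim == 0
    flat = np.atleast_1d(xa).ravel()
    _check_curve_range(curve, flat)
    y = np.empty_like(flat)
    idx = _piece_index(curve, flat)
    for k, piece in enumerate(curve.pieces):
        mask = idx == k
        if not np.any(mask):
            continue
        t = _invert_piece(piece, flat[mask])
        _, yv = eval_piece(piece, t)
        y[mask] = yv
    if scalar:
        return float(y[0])
    return y.reshape(np.shape(xa))


def _piece_violations(piece: BezierPiece, k: int) -> list[str]:
    pts = piece.points
    out: list[str] = []
    x0, x3 = pts[0, 0], pts[3, 0]
    ylo = min(pts[0, 1], pts[3, 1])
    yhi = max(pts[0, 1], pts[3, 1])
    for i in (1, 2):
        if not (x0 - _TOL_BOX <= pts[i, 0] <= x3 + _TOL_BOX):
            out.append(f"piece {k}: P{i}x={pts[i, 0]:.6g} outside [{x0:.6g}, {x3:.6g}]")
        if not (ylo - _TOL_BOX <= pts[i, 1] <= yhi + _TOL_BOX):
            out.append(f"piece {k}: P{i}y={pts[i, 1]:.6g} outside [{ylo:.6g}, {yhi:.6g}]")
    return out


def validate_monotone(curve: CBSCurve, tol_lin: float = TOL_LIN) -> MonotoneReport:
    """Check monotone-admissibility and smooth joins; reports, never raises.

    Handle coordinates must lie in the closed box of the endpoints (boundary
    contact is admissible), endpoint y-ordering must follow the curve's
    direction, adjacent pieces must share the joint exactly, and at each
    interior joint the incoming handle, the joint, and the outgoing handle
    must be collinear (2-D cross product within ``tol_lin``) with the
    outgoing handle on the opposite side.
    """
    violations: list[str] = []
    for k, piece in enumerate(curve.pieces):
        violations.extend(_piece_violations(piece, k))
        y0, y3 = piece.points[0, 1], piece.points[3, 1]
        if curve.direction == "decreasing" and y3 > y0 + _TOL_BOX:
            violations.append(f"piece {k}: endpoint y increases on a decreasing curve")
        if curve.direction == "increasing" and y3 < y0 - _TOL_BOX:
            violations.append(f"piece {k}: endpoint y decreases on an increasing curve")
    for k in range(len(curve.pieces) - 1):
        a, b = curve.pieces[k], curve.pieces[k + 1]
        joint = a.points[3]
        if np.max(np.abs(b.points[0] - joint)) > _TOL_BOX:
            violations.append(f"joint {k}: pieces {k} and {k + 1} do not share the joint point")
            continue
        v_in = joint - a.points[2]   # P2 -> joint
        v_out = b.points[1] - joint  # joint -> P4
        cross = v_in[0] * v_out[1] - v_in[1] * v_out[0]
        if abs(cross) > tol_lin:
            violations.append(f"joint {k}: smoothness violated (cross product {cross:.3g})")
        if float(v_in @ v_out) < -tol_lin:
            violations.append(f"joint {k}: outgoing handle on the same side as the incoming one")
    return MonotoneReport(ok=not violations, violations=violations)


def subdivide_piece(piece: BezierPiece, t: float) -> tuple[BezierPiece, BezierPiece]:
    """Exact de Casteljau subdivision at internal parameter t in (0, 1).

    The two children trace exactly the same curve as the parent, share the
    split point, and are collinear at the new joint by construction.
    """
    t = float(t)
    if not 0.0 < t < 1.0:
        raise BezierDomainError("subdivision parameter must lie strictly inside (0, 1)")
    p = piece.points
    q = (1.0 - t) * p[:-1] + t * p[1:]
    r = (1.0 - t) * q[:-1] + t * q[1:]
    s = (1.0 - t) * r[0] + t * r[1]
    left = BezierPiece(np.array([p[0], q[0], r[0], s]))
    right = BezierPiece(np.array([s, r[1], q[2], p[3]]))
    return left, right


def curve_auc(curve: CBSCurve) -> float:
    """Exact area under the curve over the normalized domain [0, 1].

    Per piece, integral of y dx equals the closed-form integral of
    n(t) * m'(t) over t in [0, 1] — a degree-5 polynomial integrated
    analytically.  No quadrature is used.
    """
    if abs(curve.x_min) > 1e-9 or abs(curve.x_max - 1.0) > 1e-9:
        raise BezierDomainError(
            f"AUC is defined on the normalized domain [0, 1]; "
            f"curve spans [{curve.x_min}, {curve.x_max}]"
        )
    total = 0.0
    for piece in curve.pieces:
        cx = piece.x_power_coeffs()
        cy = piece.y_power_coeffs()
        dm = np.array([cx[1], 2.0 * cx[2], 3.0 * cx[3]])
        prod = np.convolve(cy, dm)  # degree 5
        total += float(np.sum(prod / (np.arange(prod.size) + 1.0)))
    return total


# ---------------------------------------------------------------------------
# random admissible geometry (used by property tests and simulations)

def random_admissible_piece(rng: np.random.Generator,
                            p0: Sequence[float], p3: Sequence[float]) -> BezierPiece:
    """A piece with the given endpoints and handles uniform in their box."""
    x0, y0 = p0
    x3, y3 = p3
    ylo, yhi = min(y0, y3), max(y0, y3)
    h = rng.uniform([x0, ylo, x0, ylo], [x3, yhi, x3, yhi])
    return BezierPiece.from_points(p0, (h[0], h[1]), (h[2], h[3]), p3)


def random_monotone_curve(rng: np.random.Generator, n_pieces: int = 1,
                          direction: str = "decreasing") -> CBSCurve:
    """A random monotone-admissible curve on [0, 1] x [0, 1].

    Decreasing curves run from (0, 1) to (1, y_end); increasing curves from
    (0, 0) to (1, 1).  Two-piece curves get a collinear outgoing handle
    ``P4 = joint + s * (joint - P2)`` with the extension s capped so the
    second piece stays admissible.
    """
    if direction == "decreasing":
        start, end = np.array([0.0, 1.0]), np.array([1.0, rng.uniform(0.0, 1.0)])
    elif direction == "increasing":
        start, end = np.array([0.0, 0.0]), np.array([1.0, 1.0])
    else:
        raise BezierError(f"unknown direction {direction!r}")
    if n_pieces == 1:
        return CBSCurve((random_admissible_piece(rng, start, end),), direction)
    if n_pieces != 2:
        raise BezierError("only 1- and 2-piece curves are supported")
    jx = rng.uniform(0.1, 0.9)
    if direction == "decreasing":
        jy = rng.uniform(end[1], start[1])
    else:
        jy = rng.uniform(start[1], end[1])
    joint = np.array([jx, jy])
    first = random_admissible_piece(rng, start, joint)
    p2 = first.points[2]
    v = joint - p2
    caps = [3.0]
    if v[0] > 1e-12:
        caps.append((end[0] - joint[0]) / v[0])
    span_y = end[1] - joint[1]  # same sign as v[1] for an admissible chain
    if abs(v[1]) > 1e-12:
        caps.append(span_y / v[1])
    s_max = min(caps)
    s = rng.uniform(0.0, s_max)
    p4 = joint + s * v
    ylo, yhi = min(joint[1], end[1]), max(joint[1], end[1])
    p5 = rng.uniform([joint[0], ylo], [end[0], yhi])
    second = BezierPiece(np.array([joint, p4, p5, end]))
    return CBSCurve((first, second), direction)
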