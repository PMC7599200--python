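"""Geometry of monotone cubic Bezier pieces and chained curves."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cbschoice.bezier import (
    BezierDomainError,
    BezierError,
    BezierPiece,
    CBSCurve,
    curve_auc,
    eval_curve,
    eval_piece,
    eval_piece_decasteljau,
    invert_x,
    random_monotone_curve,
    subdivide_piece,
    validate_monotone,
)

DIAGONAL = BezierPiece.from_points((0, 1), (1 / 3, 2 / 3), (2 / 3, 1 / 3), (1, 0))


def random_pieces(seed, n):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        x0, dx = rng.uniform(0, 0.5), rng.uniform(0.1, 0.5)
        y0, y3 = rng.uniform(0, 1, 2)
        box = rng.uniform([x0, min(y0, y3)] * 2, [x0 + dx, max(y0, y3)] * 2)
        out.append(BezierPiece.from_points(
            (x0, y0), box[:2], box[2:], (x0 + dx, y3)))
    return out


class TestEvalPiece:
    def test_endpoints_exact(self):
        for piece in random_pieces(1, 50):
            assert eval_piece(piece, 0.0) == tuple(piece.p0)
            assert eval_piece(piece, 1.0) == tuple(piece.p3)

    def test_bernstein_midpoint_weights(self):
        # weights at t = 1/2 are (1, 3, 3, 1)/8
        piece = BezierPiece.from_points((0, 1), (0.1, 2 / 3), (0.4, 1 / 3), (1, 0))
        x, y = eval_piece(piece, 0.5)
        assert x == pytest.approx(0.3125, abs=1e-15)

    def test_out_of_domain_t(self):
        with pytest.raises(BezierDomainError):
            eval_piece(DIAGONAL, 1.2)
        with pytest.raises(BezierDomainError):
            eval_piece(DIAGONAL, -0.01)

    def test_matches_decasteljau(self):
        rng = np.random.default_rng(3)
        for piece in random_pieces(2, 100):
            t = rng.uniform(0, 1, 20)
            xb, yb = eval_piece(piece, t)
            xd, yd = eval_piece_decasteljau(piece, t)
            np.testing.assert_allclose(xb, xd, atol=1e-12)
            np.testing.assert_allclose(yb, yd, atol=1e-12)

    @pytest.mark.parametrize("t", [0.0, 0.3, 0.5, 1.0])
    def test_decasteljau_degenerate_and_linear(self, t):
        point = BezierPiece(np.full((4, 2), 0.4))
        assert eval_piece_decasteljau(point, t) == pytest.approx((0.4, 0.4), abs=1e-12)
        seg = BezierPiece(np.linspace([0, 1], [1, 0], 4))
        x, y = eval_piece_decasteljau(seg, t)
        assert x == pytest.approx(t, abs=1e-12)
        assert y == pytest.approx(1 - t, abs=1e-12)


class TestInvertAndEvalCurve:
    def test_identity_map(self):
        curve = CBSCurve((BezierPiece(np.linspace([0, 1], [1, 0], 4)),), "decreasing")
        idx, t = invert_x(curve, 0.42)
        assert idx == 0
        assert t == pytest.approx(0.42, abs=1e-10)
        assert eval_curve(curve, 0.25) == pytest.approx(0.75, abs=1e-10)

    def test_inverse_of_eval_example(self):
        piece = BezierPiece.from_points((0, 1), (0.1, 2 / 3), (0.4, 1 / 3), (1, 0))
        curve = CBSCurve((piece,), "decreasing")
        _, t = invert_x(curve, 0.3125)
        assert t == pytest.approx(0.5, abs=1e-9)

    def test_no_extrapolation(self):
        curve = CBSCurve((DIAGONAL,), "decreasing")
        with pytest.raises(BezierDomainError):
            invert_x(curve, 1.5)
        with pytest.raises(BezierDomainError):
            eval_curve(curve, np.array([0.2, -0.3]))

    def test_endpoint_values_exact(self):
        for kind in ("decreasing", "increasing"):
            curve = random_monotone_curve(np.random.default_rng(5), 2, kind)
            assert eval_curve(curve, 0.0) == curve.y_start
            assert eval_curve(curve, 1.0) == curve.y_end

    def test_round_trip(self, rng):
        for n_pieces in (1, 2):
            curve = random_monotone_curve(rng, n_pieces, "decreasing")
            xs = rng.uniform(0, 1, 200)
            for x in xs:
                idx, t = invert_x(curve, x)
                m, _ = eval_piece(curve.pieces[idx], t)
                assert abs(m - x) <= 1e-10

    def test_joint_ties_resolve_left(self):
        left, right = subdivide_piece(DIAGONAL, 0.5)
        curve = CBSCurve((left, right), "decreasing")
        idx, _ = invert_x(curve, left.points[3, 0])
        assert idx == 0


class TestValidateMonotone:
    def test_admissible(self, rng):
        for n_pieces in (1, 2):
            for direction in ("decreasing", "increasing"):
                report = validate_monotone(random_monotone_curve(rng, n_pieces, direction))
                assert report, report.violations

    def test_box_violation(self):
        piece = BezierPiece.from_points((0, 1), (0.3, 1.2), (0.6, 0.4), (1, 0))
        report = validate_monotone(CBSCurve((piece,), "decreasing"))
        assert not report
        assert any("P1y" in v for v in report.violations)

    def test_smoothness_violation(self):
        left, right = subdivide_piece(DIAGONAL, 0.5)
        bent = np.array(right.points)
        bent[1] = [0.55, 0.48]  # off the P2-joint line
        report = validate_monotone(CBSCurve((left, BezierPiece(bent)), "decreasing"))
        assert not report
        assert any("smoothness" in v for v in report.violations)

    def test_boundary_handles_admissible(self):
        piece = BezierPiece.from_points((0, 1), (0, 1), (1, 0), (1, 0))
        assert validate_monotone(CBSCurve((piece,), "decreasing"))


class TestSubdivision:
    def test_linear_split(self):
        left, right = subdivide_piece(BezierPiece(np.linspace([0, 1], [1, 0], 4)), 0.5)
        np.testing.assert_allclose(left.points[3], [0.5, 0.5], atol=1e-15)
        np.testing.assert_allclose(right.points[0], [0.5, 0.5], atol=1e-15)

    def test_children_trace_parent(self, rng):
        for piece in random_pieces(7, 30):
            t = rng.uniform(0.2, 0.8)
            left, right = subdivide_piece(piece, t)
            chain = CBSCurve((left, right), "decreasing"
                             if piece.points[0, 1] >= piece.points[3, 1] else "increasing")
            xs = rng.uniform(piece.points[0, 0], piece.points[3, 0], 100)
            parent = CBSCurve((piece,), chain.direction)
            np.testing.assert_allclose(eval_curve(chain, xs), eval_curve(parent, xs),
                                       atol=1e-10)

    def test_children_stay_monotone(self, rng):
        # subdivision preserves the traced function, hence its monotonicity;
        # the handle-box certificate itself can be lost at extreme handle
        # configurations, so monotonicity is what is asserted here
        for piece in random_pieces(8, 300):
            direction = ("decreasing" if piece.points[0, 1] >= piece.points[3, 1]
                         else "increasing")
            left, right = subdivide_piece(piece, rng.uniform(0.1, 0.9))
            chain = CBSCurve((left, right), direction)
            xs = np.linspace(piece.points[0, 0], piece.points[3, 0], 200)
            dy = np.diff(eval_curve(chain, xs))
            if direction == "decreasing":
                assert np.all(dy <= 1e-12)
            else:
                assert np.all(dy >= -1e-12)

    def test_box_certificate_not_always_inherited(self):
        # monotone-admissible parent whose x-handles sit on opposite box edges:
        # the left child's first handle leaves the child's endpoint box even
        # though the child still traces a monotone function
        parent = BezierPiece.from_points((0, 1), (1, 0.7), (0, 0.3), (1, 0))
        assert parent.is_admissible()
        left, right = subdivide_piece(parent, 0.7)
        assert not validate_monotone(CBSCurve((left, right), "decreasing"))

    def test_invalid_split_point(self):
        with pytest.raises(BezierDomainError):
            subdivide_piece(DIAGONAL, 0.0)


class TestAUC:
    def test_triangle(self):
        curve = CBSCurve((BezierPiece(np.linspace([0, 1], [1, 0], 4)),), "decreasing")
        assert curve_auc(curve) == pytest.approx(0.5, abs=1e-15)

    def test_unit_square(self):
        piece = BezierPiece.from_points((0, 1), (0.2, 1), (0.7, 1), (1, 1))
        assert curve_auc(CBSCurve((piece,), "decreasing")) == pytest.approx(1.0, abs=1e-12)

    def test_matches_quadrature(self, rng):
        from conftest import quadrature_auc
        for _ in range(60):
            n_pieces = int(rng.integers(1, 3))
            direction = "decreasing" if rng.random() < 0.5 else "increasing"
            curve = random_monotone_curve(rng, n_pieces, direction)
            assert curve_auc(curve) == pytest.approx(quadrature_auc(curve), abs=1e-8)

    def test_requires_unit_domain(self):
        piece = BezierPiece.from_points((0, 1), (0.2, 0.8), (0.4, 0.3), (0.7, 0.1))
        with pytest.raises(BezierDomainError):
            curve_auc(CBSCurve((piece,), "decreasing"))


@given(st.integers(0, 10_000), st.sampled_from([1, 2]),
       st.sampled_from(["decreasing", "increasing"]))
@settings(max_examples=60, deadline=None)
def test_monotone_admissible_curves_are_monotone(seed, n_pieces, direction):
    """The handle-box constraint is sufficient for monotonicity of y(x)."""
    curve = random_monotone_curve(np.random.default_rng(seed), n_pieces, direction)
    y = eval_curve(curve, np.linspace(0, 1, 500))
    dy = np.diff(y)
    if direction == "decreasing":
        assert np.all(dy <= 1e-12)
    else:
        assert np.all(dy >= -1e-12)


@given(st.integers(0, 10_000), st.floats(0.05, 0.95))
@settings(max_examples=60, deadline=None)
def test_auc_of_admissible_curve_in_unit_interval(seed, _t):
    curve = random_monotone_curve(np.random.default_rng(seed), 2, "decreasing")
    assert -1e-12 <= curve_auc(curve) <= 1 + 1e-12


def test_orientation_enforced():
    with pytest.raises(BezierError):
        BezierPiece.from_points((1, 0), (0.6, 0.4), (0.3, 0.7), (0, 1))
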