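import numpy as np
import pytest
from scipy.integrate import quad

from cbschoice import ParametricSpec
from cbschoice.bezier import eval_curve
from cbschoice.simulate import generate_design, simulate_choices


def quadrature_auc(curve):
    """Adaptive-quadrature AUC oracle, independent of the closed form.

    y(x) is smooth except at interior joints (derivative kinks) and at
    vertical tangents where m'(t) = 0; both are passed to the integrator as
    breakpoints so its error estimate is reliable.
    """
    breaks = [p.points[3, 0] for p in curve.pieces[:-1]]
    for p in curve.pieces:
        c = p.x_power_coeffs()
        roots = np.roots([3 * c[3], 2 * c[2], c[1]])
        for r in roots:
            if np.isreal(r) and 0.0 < r.real < 1.0:
                breaks.append(float(np.polyval(c[::-1], r.real)))
    ref, _ = quad(lambda x: eval_curve(curve, x), 0.0, 1.0,
                  points=sorted(breaks), limit=400, epsabs=1e-11)
    return ref


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def exp_dataset():
    """A 400-trial ITC dataset simulated from exponential discounting."""
    true = ParametricSpec("ITC", "E", {"lnk": -4.0})
    design = generate_design("ITC", 20, seed=11)
    return simulate_choices(design, true, sigma=1.0, seed=12), true


@pytest.fixture(scope="session")
def rc_dataset():
    """A 100-trial RC dataset simulated from the probability hyperbola."""
    true = ParametricSpec("RC", "H", {"h": 2.0})
    design = generate_design("RC", 10, seed=21)
    return simulate_choices(design, true, sigma=1.0, seed=22), true
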