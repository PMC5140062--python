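import numpy as np
import pytest
from hypothesis import settings

from sloppysys.networks import Reaction, ReactionNetwork, Species
from sloppysys.simulate import Prediction

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


class LinearPredictor:
    """Toy predictor y_i = theta * x_i with a single log parameter.

    Mirrors the ODE predictor interface so fitting/FIM tests can use
    closed-form oracles on the exact code path the ODE models take.
    """

    param_names = ["theta"]

    def __init__(self, x, theta0: float = 1.0):
        self.x = np.asarray(x, dtype=float)
        self.theta0 = theta0
        self.index = [("lin", "y", float(t)) for t in self.x]

    def reference_log_params(self):
        return np.array([np.log(self.theta0)])

    def predict(self, log_params=None):
        theta = self.theta0 if log_params is None else float(np.exp(log_params[0]))
        return Prediction(index=list(self.index), values=theta * self.x,
                          param_names=self.param_names)

    def predict_with_sens(self, log_params=None):
        theta = self.theta0 if log_params is None else float(np.exp(log_params[0]))
        return Prediction(index=list(self.index), values=theta * self.x,
                          sens=(theta * self.x)[:, None],
                          param_names=self.param_names)


class ProductPredictor:
    """Unidentifiable toy y_i = theta1 * theta2 * x_i (only the product matters)."""

    param_names = ["theta1", "theta2"]

    def __init__(self, x):
        self.x = np.asarray(x, dtype=float)
        self.index = [("prod", "y", float(t)) for t in self.x]

    def reference_log_params(self):
        return np.zeros(2)

    def _vals(self, log_params):
        if log_params is None:
            log_params = np.zeros(2)
        return float(np.exp(log_params[0] + log_params[1]))

    def predict(self, log_params=None):
        p = self._vals(log_params)
        return Prediction(index=list(self.index), values=p * self.x,
                          param_names=self.param_names)

    def predict_with_sens(self, log_params=None):
        p = self._vals(log_params)
        vals = p * self.x
        return Prediction(index=list(self.index), values=vals,
                          sens=np.column_stack([vals, vals]),
                          param_names=self.param_names)


class TwoChannelPredictor:
    """y = (theta1 * x, theta2 * z): each channel informs one parameter."""

    param_names = ["theta1", "theta2"]

    def __init__(self, x, z):
        self.x = np.asarray(x, dtype=float)
        self.z = np.asarray(z, dtype=float)
        self.index = ([("two", "yx", float(t)) for t in self.x]
                      + [("two", "yz", float(t)) for t in self.z])

    def reference_log_params(self):
        return np.zeros(2)

    def predict_with_sens(self, log_params=None):
        if log_params is None:
            log_params = np.zeros(2)
        t1, t2 = np.exp(log_params)
        vals = np.concatenate([t1 * self.x, t2 * self.z])
        sens = np.zeros((vals.size, 2))
        sens[:self.x.size, 0] = t1 * self.x
        sens[self.x.size:, 1] = t2 * self.z
        return Prediction(index=list(self.index), values=vals, sens=sens,
                          param_names=self.param_names)

    def predict(self, log_params=None):
        p = self.predict_with_sens(log_params)
        p.sens = None
        return p


@pytest.fixture
def decay_network():
    """Single first-order conversion S -> P with rate k = 0.7."""
    return ReactionNetwork(
        species=[Species("S", 1.0), Species("P", 0.0)],
        reactions=[Reaction(name="decay", kind="mass_action_elementary",
                            substrates=(("S", 1),), products=(("P", 1),),
                            k="k")],
        parameters={"k": 0.7},
        observables={"S": {"S": 1.0}, "P": {"P": 1.0}},
    )


@pytest.fixture
def single_mm_network():
    """One Michaelis-Menten conversion E + S -> E + P."""
    return ReactionNetwork(
        species=[Species("E", 0.05), Species("S", 1.0), Species("P", 0.0)],
        reactions=[Reaction(name="conv", kind="michaelis_menten",
                            enzyme="E", substrates=(("S", 1),),
                            products=(("P", 1),), k_cat="k_cat", K_M="K_M")],
        parameters={"k_cat": 2.0, "K_M": 5.0},
        observables={"P": {"P": 1.0}},
    )


def rk4_integrate(rhs, y0, t_grid):
    """Fine-step fixed-grid RK4 oracle, independent of scipy's solvers."""
    y = np.array(y0, dtype=float)
    out = [y.copy()]
    for t0, t1 in zip(t_grid[:-1], t_grid[1:]):
        h = t1 - t0
        k1 = np.asarray(rhs(t0, y))
        k2 = np.asarray(rhs(t0 + h / 2, y + h / 2 * k1))
        k3 = np.asarray(rhs(t0 + h / 2, y + h / 2 * k2))
        k4 = np.asarray(rhs(t1, y + h * k3))
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        out.append(y.copy())
    return np.array(out)
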