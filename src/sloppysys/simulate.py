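"""Integrate network ODEs under experiment protocols; compute sensitivities.

All parameter derivatives are taken with respect to *log* parameters, the
dimensionless coordinates in which Fisher-information eigenvalues translate
into manifold widths.  Forward sensitivities are integrated as an augmented
ODE system using the networks' analytic Jacobians; a central finite-difference
fallback is provided for cross-checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .networks import DNARepairModel, ReactionNetwork

__all__ = [
    "ExperimentProtocol",
    "Prediction",
    "SimulationError",
    "simulate",
    "sensitivities",
    "fd_jacobian",
    "NetworkModel",
    "DNARepairSimulator",
    "dose_segments",
]

RTOL_DEFAULT = 1e-8
ATOL_DEFAULT = 1e-10


class SimulationError(RuntimeError):
    """ODE integration failed; message carries solver diagnostics."""


@dataclass(frozen=True)
class ExperimentProtocol:
    """One experimental condition.

    For signaling networks: initial-condition overrides, constant stimuli
    (species clamped at a level), knockouts (species zeroed and held), and
    over-expression (initial concentration multiplied by a factor).

    For radiation protocols: ``doses`` (fraction sizes, Gy), ``dose_rate``
    (Gy/min) and ``rest`` (hours between fractions); the dose rate is
    piecewise-constant, equal to ``dose_rate`` during irradiation and zero
    during rest.
    """

    id: str
    times: tuple[float, ...] = ()
    initial: dict[str, float] = field(default_factory=dict)
    stimuli: dict[str, float] = field(default_factory=dict)
    knockouts: tuple[str, ...] = ()
    overexpress: dict[str, float] = field(default_factory=dict)
    observables: tuple[str, ...] = ()
    doses: tuple[float, ...] = ()
    dose_rate: float = 1.84  # Gy/min
    rest: float = 4.0  # hours

    def __post_init__(self) -> None:
        ts = self.times
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("observation times must be strictly increasing")
        bad = set(self.knockouts) & set(self.overexpress)
        if bad:
            raise ValueError(f"species {sorted(bad)} both knocked out and over-expressed")
        if any(d <= 0 for d in self.doses):
            raise ValueError("fraction sizes must be positive")

    @property
    def total_dose(self) -> float:
        return float(sum(self.doses))


@dataclass
class Prediction:
    """Model output aligned to a flat data index.

    ``index`` rows are ``(experiment_id, observable, time)``; ``values`` is
    the matching vector and ``sens`` (optional) the M x N matrix of
    derivatives with respect to log parameters.
    """

    index: list[tuple[str, str, float]]
    values: np.ndarray
    sens: np.ndarray | None = None
    param_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.index) != self.values.shape[0]:
            raise ValueError("index/values length mismatch")
        if self.sens is not None:
            self.sens = np.asarray(self.sens, dtype=float)
            if self.sens.shape[0] != self.values.shape[0]:
                raise ValueError("sensitivity row count mismatch")
            if not np.all(np.isfinite(self.sens)):
                raise ValueError("non-finite sensitivities")

    def row_lookup(self) -> dict[tuple[str, str, float], int]:
        return {key: i for i, key in enumerate(self.index)}


def _build_initial_state(net: ReactionNetwork, protocol: ExperimentProtocol):
    names = net.species_names
    y0 = net.initial_state()
    pos = {n: i for i, n in enumerate(names)}
    for s, level in protocol.initial.items():
        y0[pos[s]] = level
    for s, factor in protocol.overexpress.items():
        y0[pos[s]] *= factor
    for s, level in protocol.stimuli.items():
        y0[pos[s]] = level
    clamped = np.zeros(len(names), dtype=bool)
    for s in protocol.stimuli:
        clamped[pos[s]] = True
    for s in protocol.knockouts:
        y0[pos[s]] = 0.0
        clamped[pos[s]] = True
    return y0, clamped


def _protocol_observables(net: ReactionNetwork, protocol: ExperimentProtocol):
    omap = net.observable_map()
    names = protocol.observables or tuple(omap)
    missing = [o for o in names if o not in omap]
    if missing:
        raise ValueError(f"unknown observables {missing}")
    return names, omap


def _observable_matrix(net, obs_names, omap):
    pos = {n: i for i, n in enumerate(net.species_names)}
    C = np.zeros((len(obs_names), len(pos)))
    for i, o in enumerate(obs_names):
        for s, c in omap[o].items():
            C[i, pos[s]] = c
    return C


def simulate(net: ReactionNetwork, protocol: ExperimentProtocol,
             params=None, rtol: float = RTOL_DEFAULT,
             atol: float = ATOL_DEFAULT) -> Prediction:
    """Integrate the network under one protocol; observable values only.

    ``params`` is a natural-scale parameter vector overriding the network's
    stored values.  Rows of the returned prediction run time-major, observable
    within time.
    """
    if params is not None:
        net = net.with_parameters(params)
    p = net.parameter_vector()
    rhs, jac_y, _ = net.compile()
    y0, clamped = _build_initial_state(net, protocol)
    obs_names, omap = _protocol_observables(net, protocol)
    C = _observable_matrix(net, obs_names, omap)
    times = np.asarray(protocol.times, dtype=float)
    if times.size == 0:
        raise ValueError("protocol has no observation times")

    free = ~clamped

    def f(t, y):
        dy = rhs(t, y, p)
        dy[clamped] = 0.0
        return dy

    def jac(t, y):
        J = jac_y(t, y, p)
        J[clamped, :] = 0.0
        return J

    t_end = float(times[-1])
    sol = solve_ivp(f, (0.0, t_end), y0, method="LSODA", jac=jac,
                    t_eval=times, rtol=rtol, atol=atol)
    if not sol.success:
        raise SimulationError(f"integration failed for {protocol.id!r}: {sol.message}")
    Y = sol.y  # (n_species, n_times)
    if np.any(Y < -1e3 * atol - 1e-9):
        raise SimulationError(
            f"negative concentrations beyond tolerance in {protocol.id!r}")
    obs = C @ Y  # (n_obs, n_times)
    index = [(protocol.id, o, float(t)) for t in times for o in obs_names]
    values = obs.T.reshape(-1)
    del free
    return Prediction(index=index, values=values,
                      param_names=net.parameter_names)


def sensitivities(net: ReactionNetwork, protocol: ExperimentProtocol,
                  params=None, rtol: float = RTOL_DEFAULT,
                  atol: float = ATOL_DEFAULT) -> Prediction:
    """Forward-sensitivity integration: values plus d(obs)/d(log params)."""
    if params is not None:
        net = net.with_parameters(params)
    p = net.parameter_vector()
    n_p = p.size
    rhs, jac_y, jac_p = net.compile()
    y0, clamped = _build_initial_state(net, protocol)
    n_s = y0.size
    obs_names, omap = _protocol_observables(net, protocol)
    C = _observable_matrix(net, obs_names, omap)
    times = np.asarray(protocol.times, dtype=float)
    if times.size == 0:
        raise ValueError("protocol has no observation times")

    def f_aug(t, z):
        y = z[:n_s]
        S = z[n_s:].reshape(n_s, n_p)
        dy = rhs(t, y, p)
        Jy = jac_y(t, y, p)
        Jp = jac_p(t, y, p) * p[None, :]  # chain rule to log parameters
        dy[clamped] = 0.0
        dS = Jy @ S + Jp
        dS[clamped, :] = 0.0
        return np.concatenate([dy, dS.reshape(-1)])

    z0 = np.concatenate([y0, np.zeros(n_s * n_p)])
    sol = solve_ivp(f_aug, (0.0, float(times[-1])), z0, method="LSODA",
                    t_eval=times, rtol=rtol, atol=atol)
    if not sol.success:
        raise SimulationError(f"sensitivity integration failed for {protocol.id!r}: {sol.message}")
    n_t = times.size
    Y = sol.y[:n_s, :]
    S = sol.y[n_s:, :].reshape(n_s, n_p, n_t)
    obs = C @ Y
    obs_sens = np.einsum("os,spt->opt", C, S)  # (n_obs, n_p, n_t)
    index = [(protocol.id, o, float(t)) for t in times for o in obs_names]
    values = obs.T.reshape(-1)
    sens = np.transpose(obs_sens, (2, 0, 1)).reshape(-1, n_p)
    return Prediction(index=index, values=values, sens=sens,
                      param_names=net.parameter_names)


def fd_jacobian(fun, x, step: float = 1e-4) -> np.ndarray:
    """Central-difference Jacobian of a vector function (rows = outputs)."""
    x = np.asarray(x, dtype=float)
    cols = []
    for j in range(x.size):
        hi, lo = x.copy(), x.copy()
        hi[j] += step
        lo[j] -= step
        cols.append((np.asarray(fun(hi)) - np.asarray(fun(lo))) / (2 * step))
    return np.column_stack(cols)


class NetworkModel:
    """Predictor over a fixed protocol set, in log-parameter coordinates.

    Bundles a network with its protocols so fitting and design see a single
    callable surface: ``predict(log_params)`` and ``predict_with_sens``.
    """

    def __init__(self, net: ReactionNetwork, protocols,
                 rtol: float = RTOL_DEFAULT, atol: float = ATOL_DEFAULT):
        self.net = net
        self.protocols = list(protocols)
        self.rtol = rtol
        self.atol = atol
        self.param_names = net.parameter_names

    @property
    def n_parameters(self) -> int:
        return len(self.param_names)

    def reference_log_params(self) -> np.ndarray:
        return self.net.log_parameter_vector()

    def _params(self, log_params):
        if log_params is None:
            return None
        return np.exp(np.asarray(log_params, dtype=float))

    def predict(self, log_params=None) -> Prediction:
        params = self._params(log_params)
        preds = [simulate(self.net, pr, params, self.rtol, self.atol)
                 for pr in self.protocols]
        return _concat(preds, self.param_names)

    def predict_with_sens(self, log_params=None) -> Prediction:
        params = self._params(log_params)
        preds = [sensitivities(self.net, pr, params, self.rtol, self.atol)
                 for pr in self.protocols]
        return _concat(preds, self.param_names)


def _concat(preds, param_names) -> Prediction:
    index = [row for p in preds for row in p.index]
    values = np.concatenate([p.values for p in preds])
    sens = None
    if all(p.sens is not None for p in preds):
        sens = np.vstack([p.sens for p in preds])
    return Prediction(index=index, values=values, sens=sens,
                      param_names=list(param_names))


# ---------------------------------------------------------------------------
# Radiation dose schedules and the DNA-repair simulator
# ---------------------------------------------------------------------------

def dose_segments(protocol: ExperimentProtocol) -> list[tuple[float, float, float]]:
    """Piecewise-constant dose-rate segments ``(t_start, t_end, r)`` in hours.

    Each fraction of size D at dose rate R (Gy/min) lasts D / (60 R) hours at
    rate 60 R Gy/h; fractions are separated by the protocol's rest interval.
    """
    if not protocol.doses:
        raise ValueError(f"protocol {protocol.id!r} has no dose fractions")
    rate_h = protocol.dose_rate * 60.0  # Gy/h
    segs = []
    t = 0.0
    for i, D in enumerate(protocol.doses):
        dur = D / rate_h
        segs.append((t, t + dur, rate_h))
        t += dur
        if i < len(protocol.doses) - 1:
            segs.append((t, t + protocol.rest, 0.0))
            t += protocol.rest
    return segs


class DNARepairSimulator:
    """Simulate lesion kinetics and survival for split-dose protocols.

    The survival endpoint is S = exp(-v(t_inf)): lethal lesions accumulated
    once repair has run to completion, a Poisson zero-class mapping.  "t_inf"
    is operationalized by integrating a post-irradiation repair window
    (``repair_window`` hours, doubled while the repairable pool u remains
    above ``u_tol``, capped at ``max_window`` hours).

    ``free`` names the parameters being estimated (positive, log-scale);
    the remaining four-of-six stay fixed, which is how the LPL and RS
    reductions are fitted.
    """

    SURVIVAL = "survival"

    def __init__(self, model: DNARepairModel, protocols,
                 free=("delta1", "delta2", "lambda1", "lambda2", "lambda3", "epsilon"),
                 rtol: float = RTOL_DEFAULT, atol: float = ATOL_DEFAULT,
                 u_tol: float = 1e-9, repair_window: float = 60.0,
                 max_window: float = 400.0):
        from .networks import DNA_PARAM_NAMES
        self.model = model
        self.protocols = list(protocols)
        self.free = tuple(free)
        unknown = set(self.free) - set(DNA_PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameters {sorted(unknown)}")
        for name in self.free:
            if getattr(model, name) <= 0:
                raise ValueError(f"free parameter {name} must be positive")
        self._all_names = DNA_PARAM_NAMES
        self.param_names = list(self.free)
        self.rtol = rtol
        self.atol = atol
        self.u_tol = u_tol
        self.repair_window = repair_window
        self.max_window = max_window

    @property
    def n_parameters(self) -> int:
        return len(self.free)

    def reference_log_params(self) -> np.ndarray:
        return np.log([getattr(self.model, n) for n in self.free])

    def _model_from_log(self, log_params) -> DNARepairModel:
        if log_params is None:
            return self.model
        vals = {n: getattr(self.model, n) for n in self._all_names}
        for n, lp in zip(self.free, np.asarray(log_params, dtype=float)):
            vals[n] = math.exp(lp)
        return DNARepairModel(**vals)

    def _integrate(self, protocol: ExperimentProtocol, m: DNARepairModel,
                   with_sens: bool):
        idx_free = [self._all_names.index(n) for n in self.free]
        n_f = len(idx_free)
        d1, d2 = m.delta1, m.delta2
        l1, l2, l3, eps = m.lambda1, m.lambda2, m.lambda3, m.epsilon

        # scalar-arithmetic RHS: called tens of thousands of times per fit
        def rhs(t, z, r):
            u = z[0] if z[0] > 0.0 else 0.0
            sat = 1.0 + eps * u
            u2 = u * u
            out = np.empty(z.shape[0])
            out[0] = d1 * r - l1 * u / sat - l2 * u - l3 * u2
            out[1] = d2 * r + l2 * u + l3 * u2
            if with_sens:
                ju = -l1 / (sat * sat) - l2 - 2.0 * l3 * u
                jvu = l2 + 2.0 * l3 * u
                # d(rhs)/d(log p) source terms, full parameter order
                bu = (d1 * r, 0.0, -l1 * u / sat, -l2 * u, -l3 * u2,
                      eps * l1 * u2 / (sat * sat))
                bv = (0.0, d2 * r, 0.0, l2 * u, l3 * u2, 0.0)
                for k, ip in enumerate(idx_free):
                    s_u = z[2 + k]
                    out[2 + k] = ju * s_u + bu[ip]
                    out[2 + n_f + k] = jvu * s_u + bv[ip]
            return out

        from scipy.integrate import odeint

        def sweep(z, t0, t1, r):
            with np.errstate(over="ignore", invalid="ignore"):
                out, info = odeint(lambda zz, t: rhs(t, zz, r), z,
                                   np.array([t0, t1]),
                                   rtol=self.rtol, atol=self.atol,
                                   full_output=True, mxstep=100_000)
            if info["message"] != "Integration successful.":
                raise SimulationError(
                    f"DNA model integration failed for {protocol.id!r}: "
                    f"{info['message']}")
            return out[-1]

        segs = dose_segments(protocol)
        z = np.zeros(2 + (2 * n_f if with_sens else 0))
        for t0, t1, r in segs:
            z = sweep(z, t0, t1, r)
        # repair phase: windows doubled until u has decayed
        t_irr = segs[-1][1]
        t_now = t_irr
        window = self.repair_window
        while True:
            z = sweep(z, t_now, t_now + window, 0.0)
            t_now += window
            if z[0] < self.u_tol or t_now >= self.max_window:
                break
            window *= 2.0
        return z, t_now

    def endpoint_time(self, protocol: ExperimentProtocol) -> float:
        """Nominal endpoint label used in prediction/dataset indices."""
        return round(dose_segments(protocol)[-1][1], 6)

    def _predict(self, log_params, with_sens: bool) -> Prediction:
        m = self._model_from_log(log_params)
        index, values, sens = [], [], []
        for pr in self.protocols:
            z, _ = self._integrate(pr, m, with_sens)
            v_end = z[1]
            surv = math.exp(-v_end)
            index.append((pr.id, self.SURVIVAL, self.endpoint_time(pr)))
            values.append(surv)
            if with_sens:
                dv_dlogp = z[2:].reshape(2, len(self.free))[1]
                sens.append(-surv * dv_dlogp)
        return Prediction(index=index, values=np.array(values),
                          sens=np.vstack(sens) if with_sens else None,
                          param_names=self.param_names)

    def predict(self, log_params=None) -> Prediction:
        return self._predict(log_params, with_sens=False)

    def predict_with_sens(self, log_params=None) -> Prediction:
        return self._predict(log_params, with_sens=True)

    def trajectory(self, protocol: ExperimentProtocol, times,
                   log_params=None) -> np.ndarray:
        """(u, v) at the requested times (hours); shape (2, len(times))."""
        from .networks import dna_repair_rhs
        m = self._model_from_log(log_params)

        def rhs(t, z, r):
            du, dv = dna_repair_rhs((max(z[0], 0.0), z[1]), t, r, m)
            return [du, dv]

        times = np.asarray(times, dtype=float)
        segs = dose_segments(protocol)
        t_final = max(times[-1], segs[-1][1])
        if segs[-1][1] < t_final:
            segs.append((segs[-1][1], t_final, 0.0))
        z = np.zeros(2)
        out = np.zeros((2, times.size))
        for t0, t1, r in segs:
            mask = (times >= t0) & (times <= t1)
            t_eval = np.unique(np.concatenate([times[mask], [t1]]))
            sol = solve_ivp(rhs, (t0, t1), z, method="LSODA", args=(r,),
                            t_eval=t_eval, rtol=self.rtol, atol=self.atol)
            if not sol.success:
                raise SimulationError(f"trajectory integration failed: {sol.message}")
            for i, t in enumerate(times):
                if mask[i]:
                    j = int(np.argmin(np.abs(sol.t - t)))
                    out[:, i] = sol.y[:, j]
            z = sol.y[:, -1]
        return out
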