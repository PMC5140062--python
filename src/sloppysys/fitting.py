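"""Weighted least-squares estimation in log-parameter space.

Fits minimize chi^2(theta) = sum_i (d_i - y_i(theta))^2 / sigma_i^2, optionally
plus log-parameter regularizers w_j (log x_j/x_j0)^2 that keep unidentifiable
combinations from drifting to infinity.  The reported chi^2 always excludes
the penalty.  Models enter through a predictor interface: any object with
``param_names``, ``reference_log_params()``, ``predict(log_params)`` and
``predict_with_sens(log_params)`` returning a :class:`~sloppysys.simulate.Prediction`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .simulate import Prediction

__all__ = [
    "Dataset",
    "Regularizer",
    "FitResult",
    "AlignmentError",
    "chi_squared",
    "fit",
    "multistart_fit",
    "generate_ensemble",
]

_CSV_COLUMNS = ["experiment_id", "observable", "time", "value", "sigma"]


class AlignmentError(KeyError):
    """Dataset rows could not be matched to prediction rows."""


@dataclass
class Dataset:
    """Observations d_i with standard errors sigma_i.

    ``records`` is a DataFrame with columns experiment_id, observable, time,
    value, sigma.  Row order is the residual ordering convention used
    throughout (bit-reproducible fits depend on it).
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _CSV_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")
        self.records = self.records[_CSV_COLUMNS].reset_index(drop=True)
        if not (self.records["sigma"] > 0).all():
            raise ValueError("all sigmas must be strictly positive")

    @property
    def M(self) -> int:
        return len(self.records)

    def keys(self) -> list[tuple[str, str, float]]:
        return [(r.experiment_id, r.observable, float(r.time))
                for r in self.records.itertuples()]

    @property
    def values(self) -> np.ndarray:
        return self.records["value"].to_numpy(dtype=float)

    @property
    def sigmas(self) -> np.ndarray:
        return self.records["sigma"].to_numpy(dtype=float)

    @classmethod
    def from_rows(cls, rows) -> "Dataset":
        return cls(pd.DataFrame(rows, columns=_CSV_COLUMNS))

    @classmethod
    def from_csv(cls, path) -> "Dataset":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    def concat(self, other: "Dataset") -> "Dataset":
        return Dataset(pd.concat([self.records, other.records], ignore_index=True))


def align(dataset: Dataset, prediction: Prediction) -> np.ndarray:
    """Prediction values reordered to dataset row order."""
    lookup = prediction.row_lookup()
    rows = []
    for key in dataset.keys():
        if key not in lookup:
            raise AlignmentError(f"no prediction for dataset record {key}")
        rows.append(lookup[key])
    return np.asarray(rows, dtype=int)


def chi_squared(dataset: Dataset, prediction: Prediction) -> float:
    """Weighted sum of squared errors sum_i (d_i - y_i)^2 / sigma_i^2."""
    rows = align(dataset, prediction)
    resid = (dataset.values - prediction.values[rows]) / dataset.sigmas
    return float(resid @ resid)


@dataclass(frozen=True)
class Regularizer:
    """Quadratic log-parameter penalty sum_j w_j (log x_j/x_j0)^2."""

    centers: np.ndarray  # log-scale centers, log(x_j0)
    weights: np.ndarray  # >= 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "centers", np.asarray(self.centers, dtype=float))
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if self.centers.shape != self.weights.shape:
            raise ValueError("centers/weights shape mismatch")
        if np.any(self.weights < 0):
            raise ValueError("regularizer weights must be nonnegative")

    @classmethod
    def at(cls, log_centers, weight: float) -> "Regularizer":
        log_centers = np.asarray(log_centers, dtype=float)
        return cls(log_centers, np.full_like(log_centers, float(weight)))

    def penalty(self, log_params) -> float:
        d = np.asarray(log_params, dtype=float) - self.centers
        return float(np.sum(self.weights * d * d))

    def residuals(self, log_params) -> np.ndarray:
        return np.sqrt(self.weights) * (np.asarray(log_params, dtype=float) - self.centers)


@dataclass
class FitResult:
    log_params: np.ndarray
    chi2: float
    residuals: np.ndarray  # data residuals in units of sigma, dataset order
    M: int
    N: int
    converged: bool
    param_names: list[str] = field(default_factory=list)
    regularizer: Regularizer | None = None
    n_evaluations: int = 0

    @property
    def params(self) -> np.ndarray:
        return np.exp(self.log_params)

    def to_dict(self) -> dict:
        return {
            "param_names": list(self.param_names),
            "log_params": self.log_params.tolist(),
            "params": self.params.tolist(),
            "chi2": self.chi2,
            "M": self.M,
            "N": self.N,
            "converged": self.converged,
        }


def _residual_functions(model, dataset: Dataset, reg: Regularizer | None,
                        n_params: int):
    from .simulate import SimulationError
    sig = dataset.sigmas
    d = dataset.values
    rows_cache: dict[str, np.ndarray] = {}
    BIG = 1e8  # finite sentinel when the ODE solver fails at a trial point

    def data_residuals(log_params):
        try:
            pred = model.predict(log_params)
        except SimulationError:
            return np.full(dataset.M, BIG)
        if "rows" not in rows_cache:
            rows_cache["rows"] = align(dataset, pred)
        return (pred.values[rows_cache["rows"]] - d) / sig

    def full_residuals(log_params):
        r = data_residuals(log_params)
        if reg is None:
            return r
        return np.concatenate([r, reg.residuals(log_params)])

    def full_jacobian(log_params):
        try:
            pred = model.predict_with_sens(log_params)
        except SimulationError:
            J = np.zeros((dataset.M, n_params))
        else:
            if "rows" not in rows_cache:
                rows_cache["rows"] = align(dataset, pred)
            J = pred.sens[rows_cache["rows"]] / sig[:, None]
        if reg is None:
            return J
        return np.vstack([J, np.diag(np.sqrt(reg.weights))])

    return data_residuals, full_residuals, full_jacobian


def fit(model, dataset: Dataset, init_log_params=None,
        reg: Regularizer | None = None, max_nfev: int = 100,
        xtol: float = 1e-8, ftol: float = 1e-8, gtol: float = 1e-8,
        log_bound: float = 20.0) -> FitResult:
    """Damped least-squares minimization of chi^2 (+ penalty) over log parameters.

    Uses scipy's trust-region-reflective Levenberg-Marquardt variant with
    box bounds |log theta| <= ``log_bound`` (rate constants spanning fewer
    than ~17 decades either side of 1), which keeps trial steps out of
    regions where the ODEs overflow.  The returned chi^2 excludes the
    penalty.  Non-convergence is flagged, not raised; the best iterate is
    returned.
    """
    if init_log_params is None:
        init_log_params = model.reference_log_params()
    init_log_params = np.asarray(init_log_params, dtype=float)
    init_log_params = np.clip(init_log_params, -log_bound + 1e-9, log_bound - 1e-9)
    data_res, full_res, full_jac = _residual_functions(
        model, dataset, reg, init_log_params.size)

    sol = least_squares(full_res, init_log_params, jac=full_jac, method="trf",
                        bounds=(-log_bound, log_bound), x_scale="jac",
                        xtol=xtol, ftol=ftol, gtol=gtol, max_nfev=max_nfev)
    r_data = data_res(sol.x)
    chi2 = float(r_data @ r_data)
    # LM can in principle wander; guard the descent property against the start
    r0 = data_res(init_log_params)
    chi2_init = float(r0 @ r0)
    pen = reg.penalty(sol.x) if reg is not None else 0.0
    pen_init = reg.penalty(init_log_params) if reg is not None else 0.0
    if chi2 + pen > chi2_init + pen_init:
        sol_x, chi2, r_data = init_log_params, chi2_init, r0
        converged = False
    else:
        sol_x, converged = sol.x, bool(sol.success)
    return FitResult(
        log_params=np.asarray(sol_x, dtype=float),
        chi2=chi2,
        residuals=r_data,
        M=dataset.M,
        N=init_log_params.size,
        converged=converged,
        param_names=list(getattr(model, "param_names", [])),
        regularizer=reg,
        n_evaluations=int(sol.nfev),
    )


def multistart_fit(model, dataset: Dataset, n_starts: int = 5,
                   weight_grid=(0.0,), seed: int = 0,
                   start_spread: float = 1.0, center_log_params=None,
                   **fit_kwargs) -> list[FitResult]:
    """Repeat fits over randomized starts and a regularization-weight grid.

    Starts are log-normal perturbations (sd ``start_spread`` in log space) of
    the model's reference parameters; the first start is unperturbed.
    Returns all results ranked by chi^2 (penalty excluded), so robustness can
    be read off as the dispersion of the top-ranked chi^2 across weights.
    """
    weight_grid = list(weight_grid)
    if not weight_grid:
        raise ValueError("weight grid must be nonempty")
    rng = np.random.default_rng(seed)
    ref = (np.asarray(center_log_params, dtype=float)
           if center_log_params is not None else model.reference_log_params())
    starts = [ref]
    for _ in range(n_starts - 1):
        starts.append(ref + start_spread * rng.standard_normal(ref.size))
    results = []
    for start in starts:
        for w in weight_grid:
            reg = Regularizer.at(start, w) if w > 0 else None
            results.append(fit(model, dataset, start, reg=reg, **fit_kwargs))
    results.sort(key=lambda r: r.chi2)
    return results


def generate_ensemble(model, dataset: Dataset, n_members: int = 20,
                      seed: int = 0, band: float | None = None,
                      start_spread: float = 1.0, reg_weight: float = 0.01,
                      max_attempts: int | None = None,
                      **fit_kwargs) -> list[FitResult]:
    """Parameter vectors consistent with the data, by repeated regularized refits.

    Each member refits from a random start with a weak regularizer centered at
    that start (so sloppy directions settle at start-dependent positions while
    stiff combinations converge), and is accepted if its chi^2 is within
    ``band`` of the best chi^2 seen (default band: N, the parameter count).
    Fewer than ``n_members`` admissible fits after ``max_attempts`` returns a
    partial ensemble with a warning.
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    rng = np.random.default_rng(seed)
    ref = model.reference_log_params()
    if band is None:
        band = float(ref.size)
    if max_attempts is None:
        max_attempts = 4 * n_members
    best = fit(model, dataset, ref, **fit_kwargs)
    accepted = [best]
    attempts = 0
    while len(accepted) < n_members and attempts < max_attempts:
        attempts += 1
        start = ref + start_spread * rng.standard_normal(ref.size)
        reg = Regularizer.at(start, reg_weight) if reg_weight > 0 else None
        res = fit(model, dataset, start, reg=reg, **fit_kwargs)
        best_chi2 = min(r.chi2 for r in accepted)
        if res.chi2 <= best_chi2 + band:
            accepted.append(res)
        # keep only members inside the band around the running best
        best_chi2 = min(r.chi2 for r in accepted)
        accepted = [r for r in accepted if r.chi2 <= best_chi2 + band]
    if len(accepted) < n_members:
        warnings.warn(
            f"ensemble incomplete: {len(accepted)}/{n_members} admissible fits "
            f"after {attempts} attempts", RuntimeWarning)
    return accepted[:n_members]
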