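"""Hyper-model of model error for least-squares fits.

The systematic error of an approximate model is represented by inflating the
noise: d_i = y_i(theta) + sigma_i xi_i + f sigma_i xi'_i, with f a
hyper-parameter estimated from the best-fit chi^2.  A model is adequate when
its discrepancy is both smaller than the experimental noise (f < 1) and
statistically indistinguishable from zero.  The module also contains the
geometric-spectrum argument bounding the chi^2 contribution of mechanisms a
sloppy model leaves out.

Key closed forms (all mutually consistent; see the regression test):

- f_hat            = sqrt(chi2/(M-N) - 1), clamped at 0
- sigma_f          = (1+f^2) / (f sqrt(2(M-N)))
- augmented FIM    = blockdiag(I/(1+f^2), 2 f^2 (M-N)/(1+f^2)^2)
- Cov(theta)       = (chi2/(M-N)) I^{-1}   (inflation factor sqrt(1+f_hat^2))
- acceptable f     = 1/sqrt(sqrt(2(M-N)) - 1), the fixed point sigma_f(f) = f
- missing-spectrum chi2 = (M-N) + lambda0 r/(1-r) for a geometric eigenvalue
  tail with ratio r below the smallest retained eigenvalue lambda0
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .fim import FIMSpectrum
from .fitting import Dataset
from .simulate import Prediction

__all__ = [
    "DiscrepancyReport",
    "SloppySpectrumModel",
    "neg_log_likelihood",
    "estimate_f",
    "sigma_f",
    "augmented_fim",
    "inflate_covariance",
    "acceptable_f",
    "spectrum_chi2",
    "discrepancy_report",
]


def neg_log_likelihood(dataset: Dataset, prediction: Prediction, f: float) -> float:
    """Negative log-likelihood of the noise-inflated Gaussian model.

    sum_i [ (d_i-y_i)^2 / (2 sigma_i^2 (1+f^2)) + log sigma_i
            + (1/2) log(1+f^2) + (1/2) log 2 pi ]
    """
    if f < 0:
        raise ValueError("f must be nonnegative")
    from .fitting import align
    rows = align(dataset, prediction)
    d, sig = dataset.values, dataset.sigmas
    y = prediction.values[rows]
    one_pf2 = 1.0 + f * f
    return float(np.sum((d - y) ** 2 / (2.0 * sig**2 * one_pf2)
                        + np.log(sig)
                        + 0.5 * math.log(one_pf2)
                        + 0.5 * math.log(2.0 * math.pi)))


def estimate_f(chi2: float, M: int, N: int) -> tuple[float, bool]:
    """Discrepancy factor f_hat = sqrt(chi2/(M-N) - 1) from a best-fit chi^2.

    chi^2 below its expectation M-N gives a negative radicand (the overfit
    side); f_hat is clamped at 0 and the second return value flags it.
    """
    if M <= N:
        raise ValueError("need more data points than parameters (M > N)")
    if chi2 < 0:
        raise ValueError("chi2 must be nonnegative")
    ratio = chi2 / (M - N) - 1.0
    if ratio <= 0:
        return 0.0, True
    return math.sqrt(ratio), False


def sigma_f(f: float, M: int, N: int) -> float:
    """Standard deviation of f_hat: (1+f^2)/(f sqrt(2(M-N))).

    Diverges as f -> 0 (the likelihood becomes flat in f there); f = 0
    returns +inf.
    """
    if M <= N:
        raise ValueError("need M > N")
    if f < 0:
        raise ValueError("f must be nonnegative")
    if f == 0:
        return math.inf
    return (1.0 + f * f) / (f * math.sqrt(2.0 * (M - N)))


def augmented_fim(base: FIMSpectrum, f: float, M: int, N: int) -> np.ndarray:
    """(N+1)x(N+1) FIM over (theta, f): blockdiag(I/(1+f^2), f-block).

    The f-block is 2 f^2 (M-N)/(1+f^2)^2; its inverse square root is
    :func:`sigma_f`.  Off-diagonal blocks vanish.
    """
    if f < 0:
        raise ValueError("f must be nonnegative")
    if M <= N:
        raise ValueError("need M > N")
    n = base.n
    one_pf2 = 1.0 + f * f
    out = np.zeros((n + 1, n + 1))
    out[:n, :n] = base.matrix / one_pf2
    out[n, n] = 2.0 * f * f * (M - N) / one_pf2**2
    return out


def inflate_covariance(base: FIMSpectrum, chi2: float, M: int, N: int) -> np.ndarray:
    """Discrepancy-inflated parameter covariance Cov(theta) = (chi2/(M-N)) I^{-1}.

    Relative to the naive I^{-1}, standard errors grow by sqrt(1 + f_hat^2).
    A singular FIM falls back to the pseudo-inverse; the unidentifiable
    directions then carry no (rather than infinite) variance and the result
    is flagged by a warning.
    """
    if M <= N:
        raise ValueError("need M > N")
    scale = chi2 / (M - N)
    I = base.matrix
    if base.eigenvalues[-1] <= 0 or np.linalg.cond(I) > 1e14:
        import warnings
        warnings.warn("FIM is singular; using pseudo-inverse (unidentifiable "
                      "directions excluded)", RuntimeWarning)
        return scale * np.linalg.pinv(I, hermitian=True)
    return scale * np.linalg.inv(I)


def acceptable_f(M: int, N: int) -> float:
    """Largest acceptable discrepancy: the f at which sigma_f(f) = f.

    f* = 1/sqrt(sqrt(2(M-N)) - 1).  Below f*, the estimated model error is
    within its own statistical uncertainty and does not limit predictions.
    """
    if M <= N:
        raise ValueError("need M > N")
    root = math.sqrt(2.0 * (M - N))
    if root <= 1.0:
        raise ValueError("M - N too small for an acceptable-f threshold")
    return 1.0 / math.sqrt(root - 1.0)


@dataclass(frozen=True)
class SloppySpectrumModel:
    """Geometric model of the eigenvalues an approximate model is missing.

    ``lambda0`` is the smallest eigenvalue retained by the approximate model
    and ``ratio`` the geometric spacing (0 < ratio < 1) of the tail the model
    omits; here ``ratio`` is a spectral ratio, unrelated to any dose rate.
    """

    lambda0: float
    ratio: float
    M: int
    N: int

    def __post_init__(self) -> None:
        if not 0.0 < self.ratio < 1.0:
            raise ValueError("ratio must lie strictly in (0, 1)")
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be positive")
        if self.M <= self.N:
            raise ValueError("need M > N")


def spectrum_chi2(model: SloppySpectrumModel) -> tuple[float, float, float]:
    """(chi2_predicted, f_predicted, lambda0_threshold) of the missing tail.

    Each omitted eigendirection with eigenvalue lambda contributes about
    lambda to the squared error, so a geometric tail below lambda0 adds
    lambda0 r/(1-r):

        chi2 = (M-N) + lambda0 r/(1-r)
        f    = sqrt(lambda0 r / ((1-r)(M-N)))

    and lambda0_threshold = (1-r)/r (M-N) is the largest retained eigenvalue
    for which the omitted tail still satisfies f <= 1.
    """
    r, lam0, dof = model.ratio, model.lambda0, model.M - model.N
    tail = lam0 * r / (1.0 - r)
    chi2 = dof + tail
    f = math.sqrt(tail / dof)
    lam0_threshold = (1.0 - r) / r * dof
    return chi2, f, lam0_threshold


@dataclass
class DiscrepancyReport:
    """f with uncertainty, acceptability threshold and covariance inflation."""

    f: float
    sigma_f: float
    f_acceptable: float
    inflation: float
    covariance: np.ndarray | None
    M: int
    N: int
    verdict: str
    clamped: bool = False

    def to_dict(self) -> dict:
        return {
            "f": self.f,
            "sigma_f": self.sigma_f,
            "f_acceptable": self.f_acceptable,
            "inflation": self.inflation,
            "M": self.M,
            "N": self.N,
            "verdict": self.verdict,
            "clamped": self.clamped,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        return (f"f = {self.f:.3g} +/- {self.sigma_f:.3g} "
                f"(acceptable {self.f_acceptable:.3g}, M={self.M}, N={self.N}) "
                f"-> {self.verdict}")


def discrepancy_report(chi2: float, M: int, N: int,
                       base_fim: FIMSpectrum | None = None,
                       rule: str = "threshold") -> DiscrepancyReport:
    """Assemble the full discrepancy analysis of one fit.

    ``rule`` selects the adequacy criterion: "threshold" compares f_hat with
    the acceptable-f fixed point; "two_sigma" asks whether f_hat is within
    two standard deviations of zero.
    """
    f, clamped = estimate_f(chi2, M, N)
    sf = sigma_f(f, M, N) if f > 0 else math.inf
    f_acc = acceptable_f(M, N)
    if rule == "threshold":
        adequate = f <= f_acc
    elif rule == "two_sigma":
        adequate = f == 0 or f <= 2.0 * sf
    else:
        raise ValueError(f"unknown adequacy rule {rule!r}")
    cov = None
    if base_fim is not None:
        cov = inflate_covariance(base_fim, max(chi2, float(M - N)), M, N)
    return DiscrepancyReport(
        f=f,
        sigma_f=sf,
        f_acceptable=f_acc,
        inflation=math.sqrt(1.0 + f * f),
        covariance=cov,
        M=M,
        N=N,
        verdict="adequate" if adequate else "inadequate",
        clamped=clamped,
    )
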