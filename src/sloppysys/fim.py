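"""Fisher Information Matrix spectra, manifold widths and classification.

For least squares with known noise, I_{mu nu} = sum_i sigma_i^{-2}
(dy_i/dtheta_mu)(dy_i/dtheta_nu), evaluated here in log-parameter
coordinates so that manifold widths are approximately sqrt(lambda_mu) in
units of the data standard deviation.  A direction with width >> 1 must be
tuned to reproduce the data (relevant); width << 1 is indistinguishable from
noise (irrelevant); widths near one are marginal.  "Sloppy" spectra are
near-geometric: eigenvalues roughly uniformly spaced on a log scale over many
orders of magnitude.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .simulate import Prediction

__all__ = ["FIMSpectrum", "compute_fim", "fim_from_spectrum", "transform_fim",
           "classify", "unidentifiable_parameters"]

EIGENVALUE_FLOOR_REL = 1e-15  # below this fraction of lambda_max, report 0


@dataclass
class FIMSpectrum:
    """A FIM with its eigen-decomposition and (optional) classification.

    eigenvalues are sorted descending and clipped at zero; widths are their
    square roots.  ``labels`` / ``sloppy`` / ``identifiable`` are populated by
    :func:`classify`.
    """

    matrix: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns match sorted eigenvalues
    param_names: list[str] = field(default_factory=list)
    labels: list[str] | None = None
    sloppy: bool | None = None
    identifiable: bool | None = None

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def widths(self) -> np.ndarray:
        return np.sqrt(np.maximum(self.eigenvalues, 0.0))

    def min_eigenvalue(self) -> float:
        return float(self.eigenvalues[-1])

    def to_dict(self) -> dict:
        return {
            "param_names": list(self.param_names),
            "eigenvalues": self.eigenvalues.tolist(),
            "widths": self.widths.tolist(),
            "labels": self.labels,
            "sloppy": self.sloppy,
            "identifiable": self.identifiable,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def log_spectrum_text(self) -> str:
        """Plain-text log10 spectrum, one eigenvalue per line."""
        lines = []
        for i, lam in enumerate(self.eigenvalues):
            log10 = np.log10(lam) if lam > 0 else float("-inf")
            label = self.labels[i] if self.labels else ""
            lines.append(f"{i:3d}  {lam: .6e}  log10={log10: .3f}  {label}")
        return "\n".join(lines)


def _decompose(I: np.ndarray, param_names) -> FIMSpectrum:
    I = np.asarray(I, dtype=float)
    sym_err = np.abs(I - I.T).max()
    scale = max(np.abs(I).max(), 1.0)
    if sym_err > 1e-12 * scale:
        raise ValueError("FIM is not symmetric")
    I = 0.5 * (I + I.T)
    lam, V = np.linalg.eigh(I)
    order = np.argsort(lam)[::-1]
    lam, V = lam[order], V[:, order]
    lam_max = lam[0] if lam.size and lam[0] > 0 else 0.0
    if lam.size and lam[-1] < -1e-10 * max(lam_max, 1.0):
        raise ValueError("FIM has a significantly negative eigenvalue")
    lam = np.where(lam < EIGENVALUE_FLOOR_REL * lam_max, 0.0, lam)
    lam = np.maximum(lam, 0.0)
    return FIMSpectrum(matrix=I, eigenvalues=lam, eigenvectors=V,
                       param_names=list(param_names or []))


def compute_fim(prediction: Prediction, sigmas) -> FIMSpectrum:
    """FIM of a Gaussian least-squares model from prediction sensitivities.

    I = J^T diag(1/sigma^2) J with J the sensitivity matrix in log-parameter
    coordinates.
    """
    if prediction.sens is None:
        raise ValueError("prediction carries no sensitivity matrix")
    sigmas = np.asarray(sigmas, dtype=float)
    if sigmas.shape[0] != prediction.sens.shape[0]:
        raise ValueError("sigma vector length mismatch")
    J = prediction.sens / sigmas[:, None]
    return _decompose(J.T @ J, prediction.param_names)


def fim_from_spectrum(I: np.ndarray, param_names=None) -> FIMSpectrum:
    """Wrap an explicit symmetric nonnegative-definite matrix."""
    return _decompose(I, param_names)


def transform_fim(spec: FIMSpectrum, jacobian: np.ndarray) -> FIMSpectrum:
    """Reparameterize: I_phi = (df/dphi)^T I_theta (df/dphi).

    ``jacobian`` is the Jacobian of the map theta = f(phi) and must be
    nonsingular; congruence preserves the number of zero eigenvalues.
    """
    J = np.asarray(jacobian, dtype=float)
    if J.shape != spec.matrix.shape:
        raise ValueError("jacobian shape mismatch")
    if abs(np.linalg.det(J)) < 1e-300 or np.linalg.matrix_rank(J) < J.shape[0]:
        raise np.linalg.LinAlgError("parameter-transformation jacobian is singular")
    return _decompose(J.T @ spec.matrix @ J, None)


def unidentifiable_parameters(spec: FIMSpectrum,
                              rel_tol: float = 1e-10) -> np.ndarray:
    """Boolean mask of parameters dominated by the FIM's null space.

    A parameter whose squared loading on (numerically) zero eigendirections
    exceeds one half carries essentially no information; its posterior
    standard deviation is unbounded, and pseudo-inverse covariances report a
    spuriously small variance there.  Callers inverting a singular FIM
    should flag these directions rather than trust their diagonal entries.
    """
    lam = spec.eigenvalues
    if lam.size == 0:
        return np.zeros(0, dtype=bool)
    null = lam <= rel_tol * max(lam[0], 1e-300)
    if not null.any():
        return np.zeros(lam.size, dtype=bool)
    load = (spec.eigenvectors[:, null] ** 2).sum(axis=1)
    return load > 0.5


def classify(spec: FIMSpectrum, noise_scale_cutoff: float = 1.0,
             marginal_band: tuple[float, float] = (0.1, 10.0),
             decades_span: float = 6.0,
             uniformity_tol: float = 2.5) -> FIMSpectrum:
    """Label eigendirections and flag sloppiness / identifiability.

    Directions are relevant above the marginal band, irrelevant below it and
    marginal within it (the band brackets lambda ~ 1, where manifold widths
    are comparable to the experimental noise).  The model is identifiable iff
    its smallest eigenvalue reaches ``noise_scale_cutoff``.  It is sloppy iff
    the positive eigenvalues span at least ``decades_span`` orders of
    magnitude with approximately uniform log-spacing (largest adjacent gap at
    most ``uniformity_tol`` times the mean gap).
    """
    if spec.eigenvalues.size == 0:
        raise ValueError("empty spectrum")
    lo, hi = marginal_band
    labels = []
    for lam in spec.eigenvalues:
        if lam > hi:
            labels.append("relevant")
        elif lam < lo:
            labels.append("irrelevant")
        else:
            labels.append("marginal")
    identifiable = bool(spec.eigenvalues[-1] >= noise_scale_cutoff)

    positive = spec.eigenvalues[spec.eigenvalues > 0]
    sloppy = False
    if positive.size >= 3:
        logs = np.log10(positive)
        span = logs[0] - logs[-1]
        if span >= decades_span:
            gaps = -np.diff(logs)
            mean_gap = span / (positive.size - 1)
            sloppy = bool(gaps.max() <= uniformity_tol * mean_gap)
    spec.labels = labels
    spec.sloppy = sloppy
    spec.identifiable = identifiable
    return spec
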