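"""Greedy E-optimal experimental design.

Candidate experiments are enumerated on a factorial grid; design proceeds by
repeatedly adding the candidate that maximizes the smallest eigenvalue of the
accumulated Fisher information (FIMs of independent experiments add).  The
greedy choice is local — evaluated at one parameter point — and carries no
optimality guarantee; on small pools an exhaustive subset search is provided
as a check and the greedy/exhaustive gap is reported, never hidden.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .fim import FIMSpectrum, compute_fim
from .simulate import ExperimentProtocol

__all__ = ["DesignResult", "enumerate_candidates", "greedy_select",
           "exhaustive_select", "candidate_fims"]


@dataclass
class DesignResult:
    selected: list[int]                   # candidate indices, selection order
    selected_protocols: list[ExperimentProtocol]
    min_eig_trajectory: list[float]       # after each greedy addition
    pool_size: int
    base_min_eig: float = 0.0             # smallest eigenvalue before any addition
    round_scores: list[list[float]] = field(default_factory=list)
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "selected_ids": [p.id for p in self.selected_protocols],
            "min_eig_trajectory": list(self.min_eig_trajectory),
            "base_min_eig": self.base_min_eig,
            "pool_size": self.pool_size,
            "degenerate": self.degenerate,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def enumerate_candidates(grid: dict[str, list], builder) -> list[ExperimentProtocol]:
    """Full factorial enumeration of experiment protocols.

    ``grid`` maps factor names to level lists; ``builder(index, **levels)``
    turns one combination into a protocol.  Enumeration order is
    deterministic: the last factor varies fastest, as with nested loops in
    declaration order.
    """
    if not grid:
        raise ValueError("empty factor grid")
    names = list(grid)
    for name in names:
        if not grid[name]:
            raise ValueError(f"factor {name!r} has no levels")
    protocols = []
    for i, combo in enumerate(itertools.product(*(grid[n] for n in names))):
        protocols.append(builder(i, **dict(zip(names, combo))))
    return protocols


def candidate_fims(model_factory, candidates, log_params, sigma_fn) -> list[np.ndarray]:
    """Per-candidate FIM matrices at a fixed parameter point.

    ``model_factory(protocol)`` returns a predictor for a single protocol;
    ``sigma_fn(prediction)`` the per-record noise scales used to weight it.
    """
    fims = []
    for cand in candidates:
        model = model_factory(cand)
        pred = model.predict_with_sens(log_params)
        fims.append(compute_fim(pred, sigma_fn(pred)).matrix)
    return fims


def _min_eig(I: np.ndarray) -> float:
    return float(np.linalg.eigvalsh(I)[0])


def greedy_select(candidates, fims, k: int,
                  base_fim: np.ndarray | None = None) -> DesignResult:
    """Select k experiments greedily maximizing the smallest combined eigenvalue.

    At each round, the candidate maximizing lambda_min(FIM_base +
    sum(FIM_selected) + FIM_candidate) is added; ties break toward the lowest
    candidate index.  Candidates may repeat (a repeated experiment doubles its
    information).  An all-zero candidate pool is flagged degenerate.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(fims) != len(candidates) or not candidates:
        raise ValueError("candidates/FIMs mismatch or empty pool")
    fims = [np.asarray(F, dtype=float) for F in fims]
    n = fims[0].shape[0]
    acc = np.zeros((n, n)) if base_fim is None else np.asarray(base_fim, dtype=float).copy()
    base_min = _min_eig(acc)
    degenerate = all(np.allclose(F, 0.0) for F in fims)

    selected: list[int] = []
    trajectory: list[float] = []
    round_scores: list[list[float]] = []
    for _ in range(k):
        scores = [_min_eig(acc + F) for F in fims]
        best = int(np.argmax(scores))  # argmax returns the first maximizer
        selected.append(best)
        acc = acc + fims[best]
        trajectory.append(scores[best])
        round_scores.append(scores)
    return DesignResult(
        selected=selected,
        selected_protocols=[candidates[i] for i in selected],
        min_eig_trajectory=trajectory,
        pool_size=len(candidates),
        base_min_eig=base_min,
        round_scores=round_scores,
        degenerate=degenerate,
    )


def exhaustive_select(fims, k: int, base_fim: np.ndarray | None = None):
    """Best size-k subset (without replacement) by brute force.

    Returns ``(indices, min_eigenvalue)``.  Intended for pools small enough
    to enumerate; used to measure the greedy gap.
    """
    fims = [np.asarray(F, dtype=float) for F in fims]
    n = fims[0].shape[0]
    base = np.zeros((n, n)) if base_fim is None else np.asarray(base_fim, dtype=float)
    best_subset, best_score = None, -np.inf
    for subset in itertools.combinations(range(len(fims)), k):
        acc = base.copy()
        for i in subset:
            acc = acc + fims[i]
        score = _min_eig(acc)
        if score > best_score:
            best_subset, best_score = subset, score
    return list(best_subset), best_score
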