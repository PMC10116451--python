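"""Distance-to-ideal (TOPSIS) selection of one plan from a Pareto archive.

Both objectives enter in minimisation convention ``(-F1, F2)``, so the ideal
point is the column-wise minimum and the anti-ideal the column-wise maximum
of the weighted, vector-normalised decision matrix.  Alternatives are ranked
by relative closeness ``R = d- / (d+ + d-)`` and the arg-max is selected,
ties broken by the lowest solution index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nsga import ParetoArchive

__all__ = [
    "EmptyArchiveError",
    "TopsisResult",
    "normalize",
    "ideal_points",
    "separations",
    "closeness",
    "rank_solutions",
    "decide",
]


class EmptyArchiveError(ValueError):
    """TOPSIS needs at least one candidate solution."""


@dataclass(frozen=True)
class TopsisResult:
    """All intermediate matrices of one TOPSIS ranking."""

    matrix: np.ndarray          # raw decision matrix (m x n, minimisation)
    weights: np.ndarray
    normalized: np.ndarray
    weighted: np.ndarray
    ideal: np.ndarray           # A+ (column minima)
    anti_ideal: np.ndarray      # A- (column maxima)
    d_plus: np.ndarray
    d_minus: np.ndarray
    closeness: np.ndarray       # R_i in [0, 1]
    selected: int


def _check_weights(weights, n: int) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"weights must have length {n}, got shape {w.shape}")
    if (w <= 0).any():
        raise ValueError("weights must be strictly positive")
    return w / w.sum()


def normalize(matrix: np.ndarray) -> np.ndarray:
    """Vector normalisation: divide each column by its Euclidean norm."""
    f = np.asarray(matrix, dtype=float)
    if f.ndim != 2 or f.shape[0] < 1 or f.shape[1] < 1:
        raise ValueError("decision matrix must be 2-D and non-empty")
    norms = np.sqrt((f**2).sum(axis=0))
    if (norms == 0).any():
        raise ValueError("decision matrix has an all-zero column; cannot normalise")
    return f / norms


def ideal_points(weighted: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ideal (column minima) and anti-ideal (column maxima) points.

    All columns must be cost-type (minimisation convention).
    """
    v = np.asarray(weighted, dtype=float)
    return v.min(axis=0), v.max(axis=0)


def separations(
    weighted: np.ndarray, ideal: np.ndarray, anti_ideal: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean distances of each row to the ideal and anti-ideal points."""
    v = np.asarray(weighted, dtype=float)
    d_plus = np.sqrt(((v - ideal) ** 2).sum(axis=1))
    d_minus = np.sqrt(((v - anti_ideal) ** 2).sum(axis=1))
    return d_plus, d_minus


def closeness(d_plus: np.ndarray, d_minus: np.ndarray) -> np.ndarray:
    """Relative closeness ``R = d- / (d+ + d-)``; 0.5 when both are zero
    (a degenerate archive of identical alternatives)."""
    d_plus = np.asarray(d_plus, dtype=float)
    d_minus = np.asarray(d_minus, dtype=float)
    total = d_plus + d_minus
    return np.where(total > 0, d_minus / np.where(total > 0, total, 1.0), 0.5)


def rank_solutions(matrix: np.ndarray, weights=(0.5, 0.5)) -> TopsisResult:
    """Run the full TOPSIS pipeline on a minimisation decision matrix."""
    f = np.asarray(matrix, dtype=float)
    if f.ndim != 2 or f.shape[0] < 1:
        raise ValueError("decision matrix must be 2-D with at least one row")
    w = _check_weights(weights, f.shape[1])
    n = normalize(f)
    v = w * n
    ideal, anti = ideal_points(v)
    d_plus, d_minus = separations(v, ideal, anti)
    r = closeness(d_plus, d_minus)
    selected = int(np.argmax(r))  # argmax takes the lowest index on ties
    return TopsisResult(
        matrix=f,
        weights=w,
        normalized=n,
        weighted=v,
        ideal=ideal,
        anti_ideal=anti,
        d_plus=d_plus,
        d_minus=d_minus,
        closeness=r,
        selected=selected,
    )


def decide(archive: ParetoArchive, weights=(0.5, 0.5)) -> tuple[np.ndarray, TopsisResult]:
    """Select one plan from a Pareto archive.

    Returns the selected plan (M x N integer matrix) and the full
    :class:`TopsisResult`.
    """
    if len(archive) == 0:
        raise EmptyArchiveError("cannot decide over an empty archive")
    result = rank_solutions(archive.objectives, weights)
    return archive.plans[result.selected], result
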