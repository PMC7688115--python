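"""Summary statistics of simulation output and the distance to the data.

Simulated acquisition logs are reduced to the same two pattern matrices as
the sherd data (a consumer "has" a ware in a period iff it acquired any
units), and compared by a normalised mean of squared differences:

    delta(s, d) = (1 / (P * |W|)) * sum_p sum_i (s_ip - d_ip)^2

on the [0, 1] proportion scale; the combined statistic is the plain mean of
the pattern-A and pattern-B deltas.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .abm import AcquisitionLog
from .patterns import PatternMatrix, TimeGrid

__all__ = ["DistanceReport", "simulated_patterns", "delta", "combined_distance"]


def simulated_patterns(
    log: AcquisitionLog, grid: TimeGrid | None = None
) -> tuple[PatternMatrix, PatternMatrix]:
    """Pattern matrices A and B from an acquisition log.

    Proportions are over consumers: A[p, w] is the share of consumers that
    acquired ware w during period p; B[p, k] the share holding exactly k
    distinct wares.
    """
    grid = grid if grid is not None else TimeGrid()
    present = log.units > 0  # (P, n_consumers, n_wares)
    n_wares = present.shape[2]
    a_vals = present.mean(axis=1)
    counts = present.sum(axis=2)  # (P, n_consumers)
    b_vals = np.stack(
        [(counts == k).mean(axis=1) for k in range(n_wares + 1)], axis=1
    )
    A = PatternMatrix("A", a_vals, log.wares, grid)
    B = PatternMatrix("B", b_vals, tuple(str(k) for k in range(n_wares + 1)), grid)
    return A, B


def _values(pattern: PatternMatrix | np.ndarray) -> np.ndarray:
    return pattern.values if isinstance(pattern, PatternMatrix) else np.asarray(pattern, float)


def delta(
    sim: PatternMatrix | np.ndarray,
    obs: PatternMatrix | np.ndarray,
    method: str = "mean_sq",
) -> float:
    """Distance between one simulated and one observed pattern matrix.

    ``method="mean_sq"`` (default) is the normalised sum of squared
    differences above; ``"rooted_per_period"`` replaces each period's summed
    squares with its Euclidean norm before the same normalisation.
    """
    s, d = _values(sim), _values(obs)
    if s.shape != d.shape:
        raise ValueError(f"shape mismatch: {s.shape} vs {d.shape}")
    P, W = s.shape
    sq = (s - d) ** 2
    if method == "mean_sq":
        return float(sq.sum() / (P * W))
    if method == "rooted_per_period":
        return float(np.sqrt(sq.sum(axis=1)).sum() / (P * W))
    raise ValueError(f"unknown method {method!r}")


@dataclass
class DistanceReport:
    """Combined distance between simulated and observed pattern pairs."""

    delta_A: float
    delta_B: float
    contributions_A: np.ndarray
    contributions_B: np.ndarray

    @property
    def combined(self) -> float:
        return (self.delta_A + self.delta_B) / 2.0

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "delta_A": self.delta_A,
                "delta_B": self.delta_B,
                "combined": self.combined,
                "contributions_A": self.contributions_A.tolist(),
                "contributions_B": self.contributions_B.tolist(),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def combined_distance(
    simA: PatternMatrix | np.ndarray,
    obsA: PatternMatrix | np.ndarray,
    simB: PatternMatrix | np.ndarray,
    obsB: PatternMatrix | np.ndarray,
    method: str = "mean_sq",
) -> DistanceReport:
    """Mean of the pattern-A and pattern-B deltas, with per-cell contributions."""
    ca = (_values(simA) - _values(obsA)) ** 2
    cb = (_values(simB) - _values(obsB)) ** 2
    return DistanceReport(
        delta_A=delta(simA, obsA, method=method),
        delta_B=delta(simB, obsB, method=method),
        contributions_A=ca,
        contributions_B=cb,
    )
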