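"""Ensemble objectives: target probability deficit and ensemble defect.

Both objectives map a (sequence, target structure) pair to [0, 1] and are
zero exactly when the ensemble is concentrated on the target:

* ``probability``: ``1 - p(y* | x)``, one minus the equilibrium
  probability of the target structure;
* ``ned``: the normalized ensemble defect, the mean probability that a
  position is incorrectly structured relative to the target, i.e. the
  expected per-position structure distance between the ensemble and y*.

The ensemble defect decomposes over positions; the per-position terms
("positional defects") also drive position sampling in the search, so the
unnormalized sum and its decomposition are exposed alongside the
normalized objective value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .folding import EnsembleSummary, FoldAnalysis, FoldingBackend
from .structures import SecondaryStructure

OBJECTIVE_KINDS = ("probability", "ned")


@dataclass
class ObjectiveSpec:
    """Which ensemble objective to optimize, bound to a folding backend."""

    kind: Literal["probability", "ned"]
    backend: FoldingBackend

    def __post_init__(self) -> None:
        if self.kind not in OBJECTIVE_KINDS:
            raise ValueError(
                f"unknown objective {self.kind!r}; expected one of {OBJECTIVE_KINDS}"
            )


def ensemble_defect(summary: EnsembleSummary, y_star: SecondaryStructure) -> float:
    """Unnormalized ensemble defect: expected structure distance to ``y_star``.

    ``n - 2 * sum_{(i,j) in pairs(y*)} p_ij - sum_{j in unpaired(y*)} q_j``,
    computed from the base-pair probability matrix alone.  Equals the
    Boltzmann-expected per-structure distance ``E_y[d(y*, y)]``.
    """
    n = summary.n
    if n != y_star.n:
        raise ValueError(f"dimension mismatch: {n} vs {y_star.n}")
    p = summary.bpp
    q = summary.unpaired_prob
    paired_mass = sum(p[i - 1, j - 1] for i, j in y_star.pair_set)
    unpaired_mass = sum(q[j - 1] for j in y_star.unpaired_set)
    return float(n - 2.0 * paired_mass - unpaired_mass)


def positional_defect(
    summary: EnsembleSummary, y_star: SecondaryStructure
) -> np.ndarray:
    """Per-position probability of being incorrectly structured.

    ``eps_i = 1 - q_i`` for positions unpaired in the target and
    ``1 - p_ij`` for positions paired to ``j`` in the target.  The vector
    sums to the (unnormalized) ensemble defect.
    """
    n = summary.n
    if n != y_star.n:
        raise ValueError(f"dimension mismatch: {n} vs {y_star.n}")
    partner = y_star.partner
    eps = np.empty(n)
    q = summary.unpaired_prob
    for i in range(n):
        j = partner[i]
        eps[i] = 1.0 - (q[i] if j < 0 else summary.bpp[i, j])
    np.clip(eps, 0.0, 1.0, out=eps)
    return eps


def objective_from_analysis(
    analysis: FoldAnalysis, y_star: SecondaryStructure, kind: str
) -> float:
    """Objective value from an existing fold analysis (no refolding)."""
    if kind == "probability":
        return float(min(max(1.0 - analysis.target_prob, 0.0), 1.0))
    if kind == "ned":
        val = ensemble_defect(analysis.summary, y_star) / y_star.n
        return float(min(max(val, 0.0), 1.0))
    raise ValueError(f"unknown objective {kind!r}")


def objective_value(
    x: str, y_star: SecondaryStructure, spec: ObjectiveSpec
) -> float:
    """Evaluate the selected objective for one sequence; always in [0, 1]."""
    analysis = spec.backend.analyze(x, y_star)
    return objective_from_analysis(analysis, y_star, spec.kind)
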