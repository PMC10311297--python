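"""ViennaRNA adapter behind the :class:`~rnadesign.folding.FoldingBackend` contract.

Importing this module requires the ViennaRNA Python bindings (``import
RNA``).  The adapter maps the contract onto the engine directly:

* ``fold_summary`` -> partition function + base-pair probability matrix,
* ``structure_prob`` -> equilibrium probability of a structure,
* ``mfe_structures`` / ``criterion`` -> the zero-slack suboptimal set
  (``subopt(0)``), which yields *all* minimum free energy structures and
  therefore an exact uniqueness test.

Engine options (temperature, dangle model, ...) are passed through to the
model details object rather than fixed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

try:
    import RNA
except ImportError as exc:  # pragma: no cover - exercised only without engine
    raise ImportError(
        "the 'vienna' backend requires the ViennaRNA Python bindings"
    ) from exc

from .folding import CriterionResult, EnsembleSummary, FoldAnalysis
from .structures import SecondaryStructure


def _kT_kcal(md) -> float:
    """kT in kcal/mol for the given model details (engine energies are kcal)."""
    return RNA.exp_param(md).kT / 1000.0


@dataclass
class ViennaBackend:
    """Thermodynamic folding engine (nearest-neighbor model) adapter."""

    temperature: float | None = None
    dangles: int | None = None

    name = "vienna"

    def _md(self):
        md = RNA.md()
        if self.temperature is not None:
            md.temperature = self.temperature
        if self.dangles is not None:
            md.dangles = self.dangles
        return md

    def _fc(self, x: str):
        return RNA.fold_compound(str(x), self._md())

    def fold_summary(self, x: str) -> EnsembleSummary:
        fc = self._fc(x)
        _, mfe = fc.mfe()
        fc.exp_params_rescale(mfe)
        _, dG = fc.pf()
        n = len(x)
        raw = np.array(fc.bpp())[1:, 1:]  # 1-based upper triangle from engine
        bpp = raw + raw.T
        np.clip(bpp, 0.0, 1.0, out=bpp)
        log_Q = -dG / _kT_kcal(self._md())
        return EnsembleSummary(log_Q=log_Q, bpp=bpp)

    def structure_prob(self, x: str, y: SecondaryStructure) -> float:
        fc = self._fc(x)
        _, mfe = fc.mfe()
        fc.exp_params_rescale(mfe)
        fc.pf()
        return fc.pr_structure(y.dotbracket)

    def analyze(self, x: str, y_star: SecondaryStructure) -> FoldAnalysis:
        fc = self._fc(x)
        _, mfe = fc.mfe()
        fc.exp_params_rescale(mfe)
        _, dG = fc.pf()
        n = len(x)
        raw = np.array(fc.bpp())[1:, 1:]
        bpp = raw + raw.T
        np.clip(bpp, 0.0, 1.0, out=bpp)
        summary = EnsembleSummary(log_Q=-dG / _kT_kcal(self._md()), bpp=bpp)
        e = fc.eval_structure(y_star.dotbracket)
        prob = math.exp((dG - e) / _kT_kcal(self._md()))
        return FoldAnalysis(summary=summary, target_prob=min(prob, 1.0))

    def mfe_structures(self, x: str) -> set[str]:
        fc = self._fc(x)
        return {s.structure for s in fc.subopt(0)}

    def criterion(self, x: str, y_star: SecondaryStructure) -> CriterionResult:
        mfe_set = self.mfe_structures(x)
        mfe = y_star.dotbracket in mfe_set
        return CriterionResult(mfe, mfe and len(mfe_set) == 1)
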