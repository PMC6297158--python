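"""Model/results objects: the public face of the correction engine.

``CorrectionModel`` pairs one molecule with an element registry and a
correction mode; its matrix is built lazily and cached.  ``fit`` solves
the non-negative deconvolution for one measured vector and returns a
``CorrectionResults`` carrying corrected values, fractional abundances,
mean enrichment, the relative residual and any data-quality warnings.
``simulate`` runs the model forward (v_m = P v_c), which is how known
ground truth is turned into synthetic uncorrected data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

from .chem import (
    ElementRegistry,
    MoleculeSpec,
    parse_element_file,
    parse_formula,
    default_elements_path,
)
from .matrix import CorrectionMatrix, build_matrix, format_state
from .solver import correct_vector, fractions, mean_enrichment, _enrichment_maxima

__all__ = ["CorrectionModel", "CorrectionResults"]


class CorrectionModel:
    """Correction model for one molecule.

    Parameters
    ----------
    molecule : MoleculeSpec
        Measured ion(s) with labelable-atom annotation and mode.
    registry : ElementRegistry
        Isotope abundances and tracer definitions.
    purity_correction : bool
        Include tracer-substrate impurity in the matrix (both
        correction directions) or correct natural abundance only.

    Examples
    --------
    >>> m = CorrectionModel.from_formula("Gly", "LabC2", mode="ms1",
    ...                                  purity_correction=False)
    >>> res = m.fit([97.871449, 51.582102, 20.546449])
    >>> np.round(res.corrected, 6)
    array([100.,  50.,  20.])
    """

    def __init__(
        self,
        molecule: MoleculeSpec,
        registry: ElementRegistry,
        *,
        purity_correction: bool = True,
    ):
        self.molecule = molecule
        self.registry = registry
        self.purity_correction = purity_correction

    @classmethod
    def from_formula(
        cls,
        name: str,
        product: str,
        neutral_loss: str | None = None,
        *,
        mode: str = "ms1",
        registry: ElementRegistry | None = None,
        purities: dict[str, float] | None = None,
        purity_correction: bool = True,
    ) -> "CorrectionModel":
        """Build a model from formula strings, defaulting to the packaged
        element table; ``purities`` overrides tracer purities."""
        if registry is None:
            registry = parse_element_file(default_elements_path())
        if purities:
            registry = registry.with_purities(purities)
        mol = MoleculeSpec(
            name,
            mode,  # type: ignore[arg-type]
            parse_formula(product),
            parse_formula(neutral_loss) if neutral_loss else None,
        )
        return cls(mol, registry, purity_correction=purity_correction)

    @cached_property
    def matrix(self) -> CorrectionMatrix:
        return build_matrix(self.molecule, self.registry, self.purity_correction)

    @property
    def k(self) -> int:
        return self.matrix.k

    @property
    def states(self) -> tuple:
        return self.matrix.cols

    def fit(self, v_m) -> "CorrectionResults":
        """Correct one measured vector (channel order = ``self.states``)."""
        v_c, residual_rel, warnings = correct_vector(self.matrix, np.asarray(v_m, float))
        return CorrectionResults(self, np.asarray(v_m, float), v_c, residual_rel, warnings)

    def simulate(self, v_c) -> np.ndarray:
        """Forward model: uncorrected vector P v_c from known truth."""
        v_c = np.asarray(v_c, dtype=float)
        if v_c.shape != (self.k,):
            raise ValueError(f"truth vector must have length {self.k}")
        return self.matrix.P @ v_c


@dataclass
class CorrectionResults:
    """Result of correcting one measured vector."""

    model: CorrectionModel
    measured: np.ndarray
    corrected: np.ndarray
    residual_rel: float
    warnings: list[str] = field(default_factory=list)

    @property
    def states(self) -> tuple:
        return self.model.states

    @cached_property
    def fractions(self) -> np.ndarray | None:
        """Fractional isotopologue abundances; None if all-zero."""
        return fractions(self.corrected)

    @cached_property
    def mean_enrichment(self) -> dict[str, float]:
        """Per-tracer mean enrichment sum_s t_i(s) f(s) / n_i; empty if
        fractions are undefined."""
        if self.fractions is None:
            return {}
        tracers, maxima = _enrichment_maxima(self.model.molecule, self.model.registry)
        return mean_enrichment(self.fractions, self.states, tracers, maxima)

    def to_frame(self) -> pd.DataFrame:
        labels = [format_state(s) for s in self.states]
        frac = self.fractions
        return pd.DataFrame(
            {
                "measured": self.measured,
                "corrected": self.corrected,
                "fraction": np.full(len(labels), np.nan) if frac is None else frac,
            },
            index=pd.Index(labels, name="state"),
        )

    def summary(self) -> str:
        mol = self.model.molecule
        lines = [
            "Isotopologue correction results",
            "===============================",
            f"Molecule:          {mol.name} ({mol.mode})",
            f"States (k):        {self.model.k}",
            f"Purity correction: {'on' if self.model.purity_correction else 'off'}",
            f"Relative residual: {self.residual_rel:.6g}",
        ]
        for tracer, e in self.mean_enrichment.items():
            lines.append(f"Mean enrichment {tracer}: {e:.6g}")
        lines.append("")
        lines.append(self.to_frame().to_string(float_format=lambda x: f"{x:.6g}"))
        for w in self.warnings:
            lines.append(f"WARNING: {w}")
        return "\n".join(lines)
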