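"""Correction of measured vectors: non-negative least squares on v_m = P v_c.

The linear system is solved with a non-negative constraint on the
corrected values, since unconstrained solutions can dip below zero when
low-abundance channels are measured inaccurately.  The Lawson-Hanson
NNLS solver (scipy) returns the global optimum of this convex problem;
whenever the unconstrained solution happens to be non-negative the two
coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .chem import ElementRegistry, MoleculeSpec
from .matrix import CorrectionMatrix, build_matrix, format_state

__all__ = [
    "CorrectionOptions",
    "correct_vector",
    "fractions",
    "mean_enrichment",
    "correct_dataset",
]

_COND_LIMIT = 1e12


@dataclass(frozen=True)
class CorrectionOptions:
    """Batch-correction policy knobs.

    purity_correction: include tracer-impurity terms in P.
    purity_overrides:  per-element tracer purity replacing the element
                       file's values for this run.
    strict_na:         a sample with any missing cell for a molecule
                       yields an all-missing result instead of treating
                       missing as zero.
    residual_warn:     relative-residual threshold above which a
                       data-quality warning is attached.
    """

    purity_correction: bool = True
    purity_overrides: dict[str, float] = field(default_factory=dict)
    strict_na: bool = False
    residual_warn: float = 0.05


def correct_vector(
    matrix: CorrectionMatrix | np.ndarray, v_m: np.ndarray
) -> tuple[np.ndarray, float, list[str]]:
    """Solve ``min ||P v_c - v_m||_2`` s.t. ``v_c >= 0``.

    Returns the corrected vector, the relative residual
    ``||P v_c - v_m|| / ||v_m||`` (0 for an all-zero input) and any
    warnings (all-zero input, ill-conditioned matrix).
    """
    P = matrix.P if isinstance(matrix, CorrectionMatrix) else np.asarray(matrix, float)
    v_m = np.asarray(v_m, dtype=float)
    if v_m.ndim != 1 or v_m.shape[0] != P.shape[0]:
        raise ValueError(
            f"measured vector length {v_m.shape} does not match matrix {P.shape}"
        )
    if not np.all(np.isfinite(v_m)):
        raise ValueError("measured vector contains non-finite values")
    if np.any(v_m < 0):
        raise ValueError("measured vector contains negative values (clamp first)")
    warnings: list[str] = []
    norm_m = float(np.linalg.norm(v_m))
    if norm_m == 0.0:
        warnings.append("all-zero measured vector; corrected values are zero")
        return np.zeros(P.shape[1]), 0.0, warnings
    cond = np.linalg.cond(P)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        warnings.append(f"correction matrix is ill-conditioned (cond ~ {cond:.3g})")
    v_c, rnorm = scipy.optimize.nnls(P, v_m)
    return v_c, float(rnorm) / norm_m, warnings


def fractions(v_c: np.ndarray) -> np.ndarray | None:
    """Corrected values normalized to fractional abundances; ``None``
    (undefined) when everything is zero."""
    v_c = np.asarray(v_c, dtype=float)
    if np.any(v_c < 0):
        raise ValueError("corrected values must be non-negative")
    total = v_c.sum()
    if total == 0.0:
        return None
    return v_c / total


def mean_enrichment(
    f: np.ndarray, states: tuple, tracers: tuple[str, ...], maxima: tuple[int, ...]
) -> dict[str, float]:
    """Average fraction of labelable positions carrying tracer, per
    tracer element: sum_s t_i(s) f(s) / n_i."""
    f = np.asarray(f, dtype=float)
    out: dict[str, float] = {}
    for idx, (tracer, n_i) in enumerate(zip(tracers, maxima)):
        if n_i < 1:
            continue
        acc = 0.0
        for state, fs in zip(states, f):
            if isinstance(state, tuple):
                t_i = state[idx] if len(maxima) > 1 else sum(state)
            else:
                t_i = state
            acc += t_i * fs
        out[tracer] = acc / n_i
    return out


def _enrichment_maxima(
    mol: MoleculeSpec, registry: ElementRegistry
) -> tuple[tuple[str, ...], tuple[int, ...]]:
    tracers = mol.tracer_elements(registry)
    if mol.mode == "msms":
        return tracers, (mol.n_labels(registry) + mol.m_labels(registry),)
    if mol.mode == "ms1":
        return tracers, (mol.n_labels(registry),)
    return tracers, mol.label_maxima(registry)


def correct_dataset(
    measurements,
    molecules: list[MoleculeSpec],
    registry: ElementRegistry,
    options: CorrectionOptions = CorrectionOptions(),
):
    """Correct every molecule x sample cell of a measurement table.

    Builds each molecule's matrix once and solves per sample.  Returns
    ``dict[(molecule, sample)] -> CorrectionResults`` in file order,
    plus a list of run-level warnings.
    """
    from .model import CorrectionModel  # deferred: model builds on this module

    registry = (
        registry.with_purities(options.purity_overrides)
        if options.purity_overrides
        else registry
    )
    results = {}
    run_warnings: list[str] = []
    for mol in molecules:
        model = CorrectionModel(
            mol, registry, purity_correction=options.purity_correction
        )
        run_warnings.extend(model.matrix.warnings())
        for sample in measurements.samples:
            v_m, n_missing = measurements.vector(mol, registry, sample)
            if n_missing:
                msg = (
                    f"{mol.name}/{sample}: {n_missing} missing value(s)"
                    + ("; result withheld" if options.strict_na else "; treated as 0")
                )
                run_warnings.append(msg)
                if options.strict_na:
                    results[(mol.name, sample)] = None
                    continue
            res = model.fit(v_m)
            if res.residual_rel > options.residual_warn:
                res.warnings.append(
                    f"{mol.name}/{sample}: relative residual "
                    f"{res.residual_rel:.3g} exceeds {options.residual_warn:g} "
                    "(poor data quality?)"
                )
            run_warnings.extend(
                w if w.startswith(mol.name) else f"{mol.name}/{sample}: {w}"
                for w in res.warnings
            )
            results[(mol.name, sample)] = res
    return results, run_warnings
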