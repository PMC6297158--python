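"""Assembly of the k x k correction matrix P.

Each column of P is the distribution of one true labeling state
evaluated at the measured channels; solving ``v_m = P @ v_c`` for
``v_c >= 0`` removes natural-abundance and tracer-impurity interference
from the measured vector ``v_m``.

Channel bookkeeping per mode:

* ``ms1``      — k = n + 1 channels at shifts ``i * tracer_shift``,
  i = 0..n; row key is the label index i.
* ``msms``     — k = (n + 1)(m + 1) precursor/product channel pairs
  (p, q) with q labels in the product ion and p - q in the neutral
  loss; entry = product-fragment distribution at q times neutral-loss
  distribution at p - q.
* ``highres``  — k = prod(n_i + 1) observed label vectors inside the
  box [0, n_1] x ... x [0, n_r].

Probability mass falling outside the measured channels (possible for
tracer shifts > 1 or heavy plain-atom isotopes) is dropped and recorded
per column in ``dropped_mass``; column sums are therefore <= 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .chem import ElementRegistry, MoleculeSpec
from .distributions import (
    fragment_distribution_nominal,
    species_distribution_highres,
)

__all__ = [
    "CorrectionMatrix",
    "build_matrix",
    "build_matrix_ms1",
    "build_matrix_msms",
    "build_matrix_highres",
    "expected_keys",
    "format_state",
    "parse_state",
    "marginalize_msms",
]

_DROP_REPORT_THRESHOLD = 1e-6


@dataclass(frozen=True)
class CorrectionMatrix:
    """Dense correction matrix with ordered measured-channel rows and
    true-label-state columns."""

    molecule: str
    mode: str
    P: np.ndarray
    rows: tuple  # measured keys
    cols: tuple  # true label states
    dropped_mass: tuple[float, ...] = field(default=())

    @property
    def k(self) -> int:
        return self.P.shape[0]

    def column(self, state) -> np.ndarray:
        return self.P[:, self.cols.index(state)]

    def warnings(self) -> list[str]:
        out = []
        for state, d in zip(self.cols, self.dropped_mass):
            if d > _DROP_REPORT_THRESHOLD:
                out.append(
                    f"{self.molecule}: state {format_state(state)} loses "
                    f"{d:.3g} probability mass outside measured channels"
                )
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.P,
            index=[format_state(r) for r in self.rows],
            columns=[format_state(c) for c in self.cols],
        )


def format_state(state) -> str:
    """Render a label state / measured key the way row keys spell it
    (ints as-is, tuples dot-joined)."""
    if isinstance(state, tuple):
        return ".".join(str(x) for x in state)
    return str(state)


def parse_state(text: str, mode: str):
    parts = text.split(".")
    try:
        values = [int(p) for p in parts]
    except ValueError:
        raise ValueError(f"malformed label-state suffix {text!r}") from None
    if any(v < 0 for v in values):
        raise ValueError(f"negative label count in {text!r}")
    if mode == "ms1":
        if len(values) != 1:
            raise ValueError(f"ms1 key suffix must be a single integer, got {text!r}")
        return values[0]
    return tuple(values)


def build_matrix_ms1(
    mol: MoleculeSpec, registry: ElementRegistry, purity_correction: bool = True
) -> CorrectionMatrix:
    tracer = registry[mol.single_tracer(registry)]
    n = mol.n_labels(registry)
    if n == 0:
        raise ValueError(f"{mol.name}: no labelable atoms, nothing to correct")
    k = n + 1
    shift = tracer.tracer_shift
    P = np.zeros((k, k))
    dropped = []
    for j in range(k):
        dist = fragment_distribution_nominal(mol.product, j, registry, purity_correction)
        for i in range(k):
            P[i, j] = dist.get(i * shift, 0.0)
        dropped.append(1.0 - P[:, j].sum())
    return CorrectionMatrix(
        mol.name, "ms1", P, tuple(range(k)), tuple(range(k)), tuple(dropped)
    )


def build_matrix_msms(
    mol: MoleculeSpec, registry: ElementRegistry, purity_correction: bool = True
) -> CorrectionMatrix:
    if mol.neutral_loss is None:
        raise ValueError(f"{mol.name}: msms mode requires a neutral loss")
    tracer = registry[mol.single_tracer(registry)]
    shift = tracer.tracer_shift
    n = mol.n_labels(registry)
    m = mol.m_labels(registry)
    # measured channels (p, q): q product-ion labels, p - q neutral-loss labels
    rows = sorted((q + l, q) for q in range(n + 1) for l in range(m + 1))
    cols = list(itertools.product(range(n + 1), range(m + 1)))
    k = len(cols)
    P = np.zeros((k, k))
    prod_dists = [
        fragment_distribution_nominal(mol.product, t, registry, purity_correction)
        for t in range(n + 1)
    ]
    nl_dists = [
        fragment_distribution_nominal(mol.neutral_loss, t, registry, purity_correction)
        for t in range(m + 1)
    ]
    dropped = []
    for j, (t_prod, t_nl) in enumerate(cols):
        for i, (p, q) in enumerate(rows):
            P[i, j] = prod_dists[t_prod].get(q * shift, 0.0) * nl_dists[t_nl].get(
                (p - q) * shift, 0.0
            )
        dropped.append(1.0 - P[:, j].sum())
    return CorrectionMatrix(
        mol.name, "msms", P, tuple(rows), tuple(cols), tuple(dropped)
    )


def build_matrix_highres(
    mol: MoleculeSpec, registry: ElementRegistry, purity_correction: bool = True
) -> CorrectionMatrix:
    tracers = mol.tracer_elements(registry)
    if not tracers:
        raise ValueError(f"{mol.name}: no tracer elements, nothing to correct")
    maxima = mol.label_maxima(registry)
    states = list(itertools.product(*(range(n_i + 1) for n_i in maxima)))
    k = len(states)
    P = np.zeros((k, k))
    index = {s: i for i, s in enumerate(states)}
    dropped = []
    for j, labels in enumerate(states):
        dist = species_distribution_highres(mol, labels, registry, purity_correction)
        for vec, p in dist.probs.items():
            i = index.get(vec)
            if i is not None:
                P[i, j] = p
        dropped.append(1.0 - P[:, j].sum())
    return CorrectionMatrix(
        mol.name, "highres", P, tuple(states), tuple(states), tuple(dropped)
    )


_BUILDERS = {
    "ms1": build_matrix_ms1,
    "msms": build_matrix_msms,
    "highres": build_matrix_highres,
}


def build_matrix(
    mol: MoleculeSpec, registry: ElementRegistry, purity_correction: bool = True
) -> CorrectionMatrix:
    """Build the correction matrix for ``mol`` in its declared mode."""
    return _BUILDERS[mol.mode](mol, registry, purity_correction)


def expected_keys(mol: MoleculeSpec, registry: ElementRegistry) -> list[str]:
    """Row keys a measurement file must provide for this molecule."""
    if mol.mode == "ms1":
        states: list = list(range(mol.n_labels(registry) + 1))
    elif mol.mode == "msms":
        n, m = mol.n_labels(registry), mol.m_labels(registry)
        states = sorted((q + l, q) for q in range(n + 1) for l in range(m + 1))
    else:
        states = list(
            itertools.product(*(range(n_i + 1) for n_i in mol.label_maxima(registry)))
        )
    return [f"{mol.name}_{format_state(s)}" for s in states]


def marginalize_msms(matrix: CorrectionMatrix, over: str) -> np.ndarray:
    """Collapse an MS/MS matrix to nominal-MS1 channels.

    ``over="precursor"`` sums rows over p at fixed product shift q,
    returning a (n+1) x k array comparable (column-wise, per product
    label) with the product fragment's MS1 matrix.  ``over="product"``
    sums over q at fixed precursor shift p, returning a (n+m+1) x k
    array comparable with the MS1 matrix of the pooled molecule.
    The identities are exact when no probability mass leaves the
    measured channel box.
    """
    if matrix.mode != "msms":
        raise ValueError("marginalize_msms needs an msms matrix")
    n = max(q for _, q in matrix.rows)
    nm = max(p for p, _ in matrix.rows)
    if over == "precursor":
        out = np.zeros((n + 1, matrix.k))
        for i, (_, q) in enumerate(matrix.rows):
            out[q] += matrix.P[i]
    elif over == "product":
        out = np.zeros((nm + 1, matrix.k))
        for i, (p, _) in enumerate(matrix.rows):
            out[p] += matrix.P[i]
    else:
        raise ValueError("over must be 'precursor' or 'product'")
    return out
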