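"""Brute-force enumeration oracle, independent of the convolution engine.

Every atom of a fragment gets an explicit list of (shift, probability)
options; the oracle iterates over the full Cartesian product of atom
assignments, multiplies probabilities and sums them by total shift (or
by observed label-count vector in the high-resolution case).  This is
exponential in the atom count and is only usable on tiny molecules,
which is exactly what makes it a trustworthy cross-check.
"""

from __future__ import annotations

import itertools

from midcorr.chem import ElementRegistry, FragmentFormula, MoleculeSpec


def _atom_options(frag: FragmentFormula, t: int, registry: ElementRegistry,
                  purity_correction: bool) -> list[list[tuple[int, float]]]:
    atoms: list[list[tuple[int, float]]] = []
    tracers = [el for el in registry.tracer_order if frag.labelable_count(el) > 0]
    assert len(tracers) <= 1, "nominal oracle handles a single tracer"
    if tracers:
        el = registry[tracers[0]]
        purity = registry.purity(el.symbol) if purity_correction else 1.0
        labeled = [(el.tracer_shift, purity)]
        if purity < 1.0:
            labeled.append((0, 1.0 - purity))
        for _ in range(t):
            atoms.append(labeled)
        natural = [(s, a) for s, a in el.isotopes if a > 0.0]
        for _ in range(frag.labelable_count(el.symbol) - t):
            atoms.append(natural)
    else:
        assert t == 0
    for sym in sorted(frag.plain):
        natural = [(s, a) for s, a in registry[sym].isotopes if a > 0.0]
        for _ in range(frag.plain[sym]):
            atoms.append(natural)
    return atoms


def enumeration_size(frag: FragmentFormula, registry: ElementRegistry) -> int:
    size = 1
    for sym, c in frag.plain.items():
        size *= len(registry[sym].isotopes) ** c
    for sym, c in frag.labelable.items():
        size *= 2 ** c
    return size


def nominal_distribution_bruteforce(
    frag: FragmentFormula, t: int, registry: ElementRegistry,
    purity_correction: bool = True,
) -> dict[int, float]:
    """Total-shift distribution by exhaustive per-atom enumeration."""
    out: dict[int, float] = {}
    for combo in itertools.product(*_atom_options(frag, t, registry, purity_correction)):
        shift = 0
        prob = 1.0
        for s, p in combo:
            shift += s
            prob *= p
        out[shift] = out.get(shift, 0.0) + prob
    return out


def highres_distribution_bruteforce(
    mol: MoleculeSpec, labels: tuple[int, ...], registry: ElementRegistry,
    purity_correction: bool = True,
) -> dict[tuple[int, ...], float]:
    """Observed-label-vector distribution by exhaustive enumeration.

    Per tracer element, each labeled position carries the tracer isotope
    with probability purity; every other atom of that element carries it
    with the tracer isotope's natural abundance.  Non-tracer elements
    cannot interfere (mass defects resolved) and are skipped.
    """
    tracers = mol.tracer_elements(registry)
    assert len(labels) == len(tracers)
    atoms: list[tuple[int, list[tuple[int, float]]]] = []  # (tracer idx, options)
    for idx, sym in enumerate(tracers):
        el = registry[sym]
        purity = registry.purity(sym) if purity_correction else 1.0
        a = el.tracer_abundance
        labeled = [(1, purity)] + ([(0, 1.0 - purity)] if purity < 1.0 else [])
        natural = [(1, a), (0, 1.0 - a)]
        for _ in range(labels[idx]):
            atoms.append((idx, labeled))
        for _ in range(mol.product.total_count(sym) - labels[idx]):
            atoms.append((idx, natural))
    out: dict[tuple[int, ...], float] = {}
    for combo in itertools.product(*(opts for _, opts in atoms)):
        counts = [0] * len(tracers)
        prob = 1.0
        for (idx, _), (hit, p) in zip(atoms, combo):
            counts[idx] += hit
            prob *= p
        key = tuple(counts)
        out[key] = out.get(key, 0.0) + prob
    return out


def matrix_bruteforce(mol: MoleculeSpec, registry: ElementRegistry,
                      purity_correction: bool = True):
    """Full correction matrix from the enumeration oracle (dense list of
    lists, same row/column ordering as the engine)."""
    import numpy as np

    if mol.mode == "ms1":
        tracer = registry[mol.single_tracer(registry)]
        n = mol.product.labelable_count(tracer.symbol)
        k = n + 1
        P = np.zeros((k, k))
        for j in range(k):
            d = nominal_distribution_bruteforce(mol.product, j, registry, purity_correction)
            for i in range(k):
                P[i, j] = d.get(i * tracer.tracer_shift, 0.0)
        return P
    if mol.mode == "msms":
        tracer = registry[mol.single_tracer(registry)]
        shift = tracer.tracer_shift
        n = mol.product.labelable_count(tracer.symbol)
        m = mol.neutral_loss.labelable_count(tracer.symbol)
        rows = sorted((q + l, q) for q in range(n + 1) for l in range(m + 1))
        cols = list(itertools.product(range(n + 1), range(m + 1)))
        P = np.zeros((len(rows), len(cols)))
        for j, (tp, tn) in enumerate(cols):
            dp = nominal_distribution_bruteforce(mol.product, tp, registry, purity_correction)
            dn = nominal_distribution_bruteforce(mol.neutral_loss, tn, registry, purity_correction)
            for i, (p, q) in enumerate(rows):
                P[i, j] = dp.get(q * shift, 0.0) * dn.get((p - q) * shift, 0.0)
        return P
    # highres
    maxima = mol.label_maxima(registry)
    states = list(itertools.product(*(range(n_i + 1) for n_i in maxima)))
    P = np.zeros((len(states), len(states)))
    index = {s: i for i, s in enumerate(states)}
    for j, labels in enumerate(states):
        d = highres_distribution_bruteforce(mol, labels, registry, purity_correction)
        for vec, p in d.items():
            if vec in index:
                P[index[vec], j] = p
    return P
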