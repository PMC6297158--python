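"""Nominal-mass-shift and label-count distributions of labeled species.

A species with a fixed number of tracer atoms incorporated from the
substrate still shows a *distribution* of nominal mass shifts, because
every other atom draws its isotope from the natural abundance table and
(optionally) every labeled position carries the tracer isotope only with
the substrate's isotopic purity.  These distributions are exact discrete
convolutions of per-atom isotope tables — binomial for two-isotope
elements, multinomial collapsed by total shift otherwise.

In high-resolution mode mass defects are resolved, so only the tracer
isotope of each tracer element can interfere with the measured labeling
patterns; the relevant distribution is then over *label-count vectors*
(one observed tracer-isotope count per tracer element), built from
independent binomials per element.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Iterator, Mapping

from .chem import ElementDef, ElementRegistry, FragmentFormula, MoleculeSpec

__all__ = [
    "ShiftDistribution",
    "LabelVectorDistribution",
    "natural_distribution",
    "purity_distribution",
    "convolve",
    "fragment_distribution_nominal",
    "species_distribution_highres",
]

_SUM_TOL = 1e-10


@dataclass(frozen=True)
class ShiftDistribution(Mapping[int, float]):
    """Sparse probability distribution over nominal mass shifts."""

    probs: dict[int, float]

    def __getitem__(self, shift: int) -> float:
        return self.probs[shift]

    def get(self, shift: int, default: float = 0.0) -> float:
        return self.probs.get(shift, default)

    def __iter__(self) -> Iterator[int]:
        return iter(self.probs)

    def __len__(self) -> int:
        return len(self.probs)

    @property
    def total(self) -> float:
        return sum(self.probs.values())

    def validate(self) -> "ShiftDistribution":
        if any(p < -1e-15 or p > 1 + 1e-12 for p in self.probs.values()):
            raise ValueError("probability outside [0, 1]")
        if abs(self.total - 1.0) > _SUM_TOL:
            raise ValueError(f"distribution sums to {self.total!r}, expected 1")
        return self


@dataclass(frozen=True)
class LabelVectorDistribution(Mapping[tuple[int, ...], float]):
    """Sparse distribution over observed label-count vectors (one entry
    per tracer element, in registry tracer order)."""

    probs: dict[tuple[int, ...], float]

    def __getitem__(self, key: tuple[int, ...]) -> float:
        return self.probs[key]

    def get(self, key: tuple[int, ...], default: float = 0.0) -> float:
        return self.probs.get(key, default)

    def __iter__(self) -> Iterator[tuple[int, ...]]:
        return iter(self.probs)

    def __len__(self) -> int:
        return len(self.probs)

    @property
    def total(self) -> float:
        return sum(self.probs.values())


POINT_MASS = ShiftDistribution({0: 1.0})


def convolve(a: ShiftDistribution, b: ShiftDistribution) -> ShiftDistribution:
    """Distribution of the sum of two independent shifts."""
    if len(a) == 1 and 0 in a.probs:
        return b
    if len(b) == 1 and 0 in b.probs:
        return a
    out: dict[int, float] = {}
    for u, pu in a.probs.items():
        for v, pv in b.probs.items():
            s = u + v
            out[s] = out.get(s, 0.0) + pu * pv
    return ShiftDistribution(out)


def natural_distribution(el: ElementDef, count: int) -> ShiftDistribution:
    """Total-shift distribution of ``count`` atoms drawing isotopes from
    ``el``'s natural abundance table (count-fold convolution)."""
    if count < 0:
        raise ValueError("count must be non-negative")
    single = ShiftDistribution({s: a for s, a in el.isotopes if a > 0.0})
    result = POINT_MASS
    # binary exponentiation keeps large counts cheap; convolution is associative
    base = single
    k = count
    while k:
        if k & 1:
            result = convolve(result, base)
        k >>= 1
        if k:
            base = convolve(base, base)
    return result


def purity_distribution(el: ElementDef, t: int, purity: float) -> ShiftDistribution:
    """Shift distribution of ``t`` labeled positions, each carrying the
    tracer isotope with probability ``purity`` and the light isotope
    otherwise (binomial mapped onto multiples of the tracer shift)."""
    if el.tracer_shift is None:
        raise ValueError(f"{el.symbol} has no tracer definition")
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"tracer purity must be in (0, 1], got {purity}")
    if t < 0:
        raise ValueError("label count must be non-negative")
    if purity == 1.0:
        return ShiftDistribution({t * el.tracer_shift: 1.0})
    probs: dict[int, float] = {}
    for j in range(t + 1):
        p = comb(t, j) * purity**j * (1.0 - purity) ** (t - j)
        if p > 0.0:
            probs[j * el.tracer_shift] = p
    return ShiftDistribution(probs)


def fragment_distribution_nominal(
    frag: FragmentFormula,
    t: int,
    registry: ElementRegistry,
    purity_correction: bool = True,
) -> ShiftDistribution:
    """Mass-shift distribution of a fragment carrying ``t`` tracer atoms.

    The tracer label is fixed at ``t * tracer_shift`` (or binomially
    degraded by substrate impurity when ``purity_correction`` is on);
    the remaining labelable positions and every plain atom draw isotopes
    from natural abundance.
    """
    tracers = [el for el in registry.tracer_order if frag.labelable_count(el) > 0]
    if len(tracers) > 1:
        raise ValueError("nominal-resolution distribution requires a single tracer")
    result = POINT_MASS
    if tracers:
        el = registry[tracers[0]]
        n_lab = frag.labelable_count(el.symbol)
        if not 0 <= t <= n_lab:
            raise ValueError(f"label count {t} outside [0, {n_lab}]")
        purity = registry.purity(el.symbol) if purity_correction else 1.0
        result = convolve(result, purity_distribution(el, t, purity))
        result = convolve(result, natural_distribution(el, n_lab - t))
    elif t != 0:
        raise ValueError("fragment has no labelable atoms but t > 0")
    for sym in sorted(frag.plain):
        count = frag.plain[sym]
        if count:
            result = convolve(result, natural_distribution(registry[sym], count))
    return result


def _observed_count_distribution(
    el: ElementDef, t: int, n_total: int, purity: float
) -> dict[int, float]:
    """Distribution of the number of tracer isotopes observed on one
    tracer element: Binom(t, purity) over the labeled positions plus
    Binom(n_total - t, a) over the rest, a = the tracer isotope's own
    natural abundance (other isotopes are spectrally resolved away)."""
    a = el.tracer_abundance
    labeled = {
        j: comb(t, j) * purity**j * (1.0 - purity) ** (t - j) for j in range(t + 1)
    }
    rest_n = n_total - t
    rest = {
        j: comb(rest_n, j) * a**j * (1.0 - a) ** (rest_n - j) for j in range(rest_n + 1)
    }
    out: dict[int, float] = {}
    for u, pu in labeled.items():
        if pu == 0.0:
            continue
        for v, pv in rest.items():
            if pv == 0.0:
                continue
            out[u + v] = out.get(u + v, 0.0) + pu * pv
    return out


def species_distribution_highres(
    mol: MoleculeSpec,
    labels: tuple[int, ...],
    registry: ElementRegistry,
    purity_correction: bool = True,
) -> LabelVectorDistribution:
    """Observed-label-vector distribution of a multi-tracer species.

    ``labels`` gives the true tracer atoms incorporated per tracer
    element (registry tracer order).  Each element contributes an
    independent count distribution; the joint distribution is their
    outer product.
    """
    tracers = mol.tracer_elements(registry)
    if len(labels) != len(tracers):
        raise ValueError(
            f"label vector length {len(labels)} != number of tracers {len(tracers)}"
        )
    per_element: list[dict[int, float]] = []
    for sym, t in zip(tracers, labels):
        el = registry[sym]
        n_lab = mol.product.labelable_count(sym)
        if not 0 <= t <= n_lab:
            raise ValueError(f"{sym}: label count {t} outside [0, {n_lab}]")
        n_total = mol.product.total_count(sym)
        purity = registry.purity(sym) if purity_correction else 1.0
        per_element.append(_observed_count_distribution(el, t, n_total, purity))
    joint: dict[tuple[int, ...], float] = {(): 1.0}
    for dist in per_element:
        new: dict[tuple[int, ...], float] = {}
        for vec, pv in joint.items():
            for c, pc in dist.items():
                new[vec + (c,)] = new.get(vec + (c,), 0.0) + pv * pc
        joint = new
    return LabelVectorDistribution(joint)
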