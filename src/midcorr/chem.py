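"""Element/isotope definitions, fragment formulas and input validation.

The correction engine needs three pieces of chemical bookkeeping:

* per-element natural isotope abundance tables, expressed as nominal mass
  shifts relative to the lightest isotope (``ElementDef``),
* which elements act as tracers, with the nominal shift of the tracer
  isotope and the isotopic purity of the tracer substrate
  (``ElementRegistry``),
* molecular formulas that distinguish metabolically labelable positions
  from atoms that can never carry tracer, e.g. atoms introduced by a
  derivatizing group (``FragmentFormula`` / ``MoleculeSpec``).

Formulas use an explicit grammar: ``LabC5C7H20NO2`` means five labelable
carbons plus seven plain carbons, twenty hydrogens, one nitrogen and two
oxygens.  Counts accumulate if a token repeats; a missing count means 1.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

__all__ = [
    "ElementDef",
    "ElementRegistry",
    "FragmentFormula",
    "MoleculeSpec",
    "Finding",
    "parse_element_file",
    "parse_formula",
    "render_formula",
    "parse_molecule_file",
    "validate_inputs",
    "default_elements_path",
]

Mode = Literal["ms1", "msms", "highres"]

_ABUNDANCE_TOL = 1e-6


class ParseError(ValueError):
    """Raised for malformed element tables, formulas or molecule files."""


@dataclass(frozen=True)
class ElementDef:
    """One element's isotope table plus optional tracer designation.

    ``isotopes`` maps nominal mass shift (relative to the lightest
    isotope) to natural abundance; abundances must sum to 1.
    ``tracer_shift`` is the shift of the tracer isotope (e.g. 1 for
    13C, 2 for 18O); ``tracer_purity`` is the probability that a
    nominally labeled position of the tracer substrate actually carries
    the tracer isotope.
    """

    symbol: str
    isotopes: tuple[tuple[int, float], ...]
    tracer_shift: int | None = None
    tracer_purity: float | None = None

    def __post_init__(self) -> None:
        shifts = [s for s, _ in self.isotopes]
        if len(shifts) != len(set(shifts)):
            raise ValueError(f"{self.symbol}: duplicate isotope shifts")
        if 0 not in shifts:
            raise ValueError(f"{self.symbol}: isotope table must include shift 0")
        if any(s < 0 for s in shifts):
            raise ValueError(f"{self.symbol}: negative isotope shift")
        total = sum(a for _, a in self.isotopes)
        if abs(total - 1.0) > _ABUNDANCE_TOL:
            raise ValueError(
                f"{self.symbol}: isotope abundances sum to {total!r}, expected 1"
            )
        if any(not 0.0 <= a <= 1.0 for _, a in self.isotopes):
            raise ValueError(f"{self.symbol}: abundance outside [0, 1]")
        if self.tracer_shift is not None:
            if self.tracer_shift <= 0:
                raise ValueError(f"{self.symbol}: tracer shift must be positive")
            if self.tracer_shift not in shifts:
                raise ValueError(
                    f"{self.symbol}: tracer shift {self.tracer_shift} not in isotope table"
                )
        elif self.tracer_purity is not None:
            raise ValueError(f"{self.symbol}: tracer purity given without tracer shift")
        if self.tracer_purity is not None and not 0.0 < self.tracer_purity <= 1.0:
            raise ValueError(f"{self.symbol}: tracer purity must be in (0, 1]")

    @property
    def is_tracer(self) -> bool:
        return self.tracer_shift is not None

    def abundance(self, shift: int) -> float:
        for s, a in self.isotopes:
            if s == shift:
                return a
        return 0.0

    @property
    def tracer_abundance(self) -> float:
        """Natural abundance of the tracer isotope itself."""
        if self.tracer_shift is None:
            raise ValueError(f"{self.symbol} is not a tracer element")
        return self.abundance(self.tracer_shift)


@dataclass(frozen=True)
class ElementRegistry:
    """All element definitions for a run, with tracer elements in file order."""

    defs: dict[str, ElementDef]
    tracer_order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.defs:
            raise ValueError("element registry is empty")
        missing = [t for t in self.tracer_order if t not in self.defs]
        if missing:
            raise ValueError(f"tracer elements not defined: {missing}")

    def __getitem__(self, symbol: str) -> ElementDef:
        try:
            return self.defs[symbol]
        except KeyError:
            raise KeyError(f"element {symbol!r} not in registry") from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.defs

    def purity(self, symbol: str) -> float:
        """Tracer purity for ``symbol``; defaults to 1.0 when unspecified."""
        p = self[symbol].tracer_purity
        return 1.0 if p is None else p

    def with_purities(self, purities: dict[str, float]) -> "ElementRegistry":
        """Return a copy with per-element tracer purities overridden."""
        new_defs = dict(self.defs)
        for sym, p in purities.items():
            d = self[sym]
            if d.tracer_shift is None:
                raise ValueError(f"{sym} is not a tracer element; cannot set purity")
            new_defs[sym] = ElementDef(d.symbol, d.isotopes, d.tracer_shift, p)
        return ElementRegistry(new_defs, self.tracer_order)


@dataclass(frozen=True)
class FragmentFormula:
    """Atom counts of a measured fragment, split into plain and labelable."""

    plain: dict[str, int] = field(default_factory=dict)
    labelable: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for d in (self.plain, self.labelable):
            if any(c < 0 for c in d.values()):
                raise ValueError("negative atom count")
        if self.total_atoms == 0:
            raise ValueError("formula has no atoms")

    @property
    def total_atoms(self) -> int:
        return sum(self.plain.values()) + sum(self.labelable.values())

    def labelable_count(self, element: str) -> int:
        return self.labelable.get(element, 0)

    def plain_count(self, element: str) -> int:
        return self.plain.get(element, 0)

    def total_count(self, element: str) -> int:
        return self.plain_count(element) + self.labelable_count(element)

    def elements(self) -> set[str]:
        return set(self.plain) | set(self.labelable)

    def merged(self, other: "FragmentFormula") -> "FragmentFormula":
        """Pool two fragments into one (product + neutral loss -> precursor)."""
        plain = dict(self.plain)
        for el, c in other.plain.items():
            plain[el] = plain.get(el, 0) + c
        lab = dict(self.labelable)
        for el, c in other.labelable.items():
            lab[el] = lab.get(el, 0) + c
        return FragmentFormula(plain, lab)


_TOKEN_RE = re.compile(r"(Lab)?([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> FragmentFormula:
    """Parse a formula string such as ``"LabC5C7H20NO2"``.

    Tokens are ``<El><count>`` (plain atoms) or ``Lab<El><count>``
    (labelable atoms); the count defaults to 1 and repeated tokens for
    the same element accumulate.
    """
    if not text:
        raise ParseError("empty formula")
    plain: dict[str, int] = {}
    labelable: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            raise ParseError(f"unrecognized formula token at position {pos} in {text!r}")
        lab, el, count_s = m.groups()
        count = int(count_s) if count_s else 1
        target = labelable if lab else plain
        target[el] = target.get(el, 0) + count
        pos = m.end()
    return FragmentFormula(plain, labelable)


def render_formula(frag: FragmentFormula) -> str:
    """Canonical string form; ``parse_formula(render_formula(f)) == f``."""
    parts = [f"Lab{el}{c}" for el, c in sorted(frag.labelable.items()) if c > 0]
    parts += [f"{el}{c}" for el, c in sorted(frag.plain.items()) if c > 0]
    if not parts:
        raise ValueError("cannot render empty formula")
    return "".join(parts)


@dataclass(frozen=True)
class MoleculeSpec:
    """A molecule to correct: name, acquisition mode and fragment formulas."""

    name: str
    mode: Mode
    product: FragmentFormula
    neutral_loss: FragmentFormula | None = None

    def __post_init__(self) -> None:
        if "_" in self.name:
            raise ValueError(
                f"molecule name {self.name!r} contains '_' (reserved as key separator)"
            )
        if self.mode not in ("ms1", "msms", "highres"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "msms" and self.neutral_loss is None:
            raise ValueError(f"{self.name}: msms mode requires a neutral-loss formula")
        if self.mode != "msms" and self.neutral_loss is not None:
            raise ValueError(f"{self.name}: neutral loss only allowed in msms mode")

    def tracer_elements(self, registry: ElementRegistry) -> tuple[str, ...]:
        """Tracer elements with labelable atoms, in registry tracer order."""
        lab = set(self.product.labelable)
        if self.neutral_loss is not None:
            lab |= set(self.neutral_loss.labelable)
        return tuple(t for t in registry.tracer_order if t in lab)

    def single_tracer(self, registry: ElementRegistry) -> str:
        tracers = self.tracer_elements(registry)
        if len(tracers) != 1:
            raise ValueError(
                f"{self.name}: nominal-resolution modes need exactly one tracer "
                f"element, found {tracers}"
            )
        return tracers[0]

    def n_labels(self, registry: ElementRegistry) -> int:
        """Maximum label count n in the product ion (single-tracer modes)."""
        return self.product.labelable_count(self.single_tracer(registry))

    def m_labels(self, registry: ElementRegistry) -> int:
        """Maximum label count m in the neutral loss (msms mode)."""
        if self.neutral_loss is None:
            return 0
        return self.neutral_loss.labelable_count(self.single_tracer(registry))

    def label_maxima(self, registry: ElementRegistry) -> tuple[int, ...]:
        """Per-tracer maximum label counts n_i (high-resolution mode)."""
        return tuple(
            self.product.labelable_count(t) for t in self.tracer_elements(registry)
        )

    def n_states(self, registry: ElementRegistry) -> int:
        """Dimension k of the correction problem for this molecule."""
        if self.mode == "ms1":
            return self.n_labels(registry) + 1
        if self.mode == "msms":
            return (self.n_labels(registry) + 1) * (self.m_labels(registry) + 1)
        k = 1
        for n_i in self.label_maxima(registry):
            k *= n_i + 1
        return k


# ---------------------------------------------------------------------------
# File parsing


def default_elements_path() -> Path:
    """Path of the element table shipped with the package (IUPAC abundances)."""
    return Path(str(resources.files("midcorr").joinpath("data/elements.csv")))


def _parse_isotopes(text: str, line_no: int) -> tuple[tuple[int, float], ...]:
    pairs = []
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        try:
            shift_s, ab_s = part.split(":")
            pairs.append((int(shift_s), float(ab_s)))
        except ValueError:
            raise ParseError(
                f"line {line_no}: malformed isotope entry {part!r} "
                "(expected shift:abundance)"
            ) from None
    if not pairs:
        raise ParseError(f"line {line_no}: empty isotope list")
    return tuple(pairs)


def parse_element_file(path: str | Path) -> ElementRegistry:
    """Read an element table CSV.

    Header: ``Element,Isotopes,TracerShift,TracerPurity``; Isotopes is a
    semicolon-joined list of ``shift:abundance`` pairs.  Empty
    TracerShift means the element is not a tracer.
    """
    path = Path(path)
    defs: dict[str, ElementDef] = {}
    tracer_order: list[str] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        expected = ["Element", "Isotopes", "TracerShift", "TracerPurity"]
        if [h.strip() for h in header] != expected:
            raise ParseError(f"{path}: bad header {header!r}, expected {expected}")
        for line_no, row in enumerate(reader, start=2):
            if not row or not any(cell.strip() for cell in row):
                continue
            if len(row) != 4:
                raise ParseError(f"{path} line {line_no}: expected 4 columns")
            symbol = row[0].strip()
            if symbol in defs:
                raise ParseError(f"{path} line {line_no}: duplicate element {symbol}")
            isotopes = _parse_isotopes(row[1], line_no)
            shift_s, purity_s = row[2].strip(), row[3].strip()
            tracer_shift = int(shift_s) if shift_s else None
            tracer_purity = float(purity_s) if purity_s else None
            try:
                d = ElementDef(symbol, isotopes, tracer_shift, tracer_purity)
            except ValueError as exc:
                raise ParseError(f"{path} line {line_no}: {exc}") from None
            defs[symbol] = d
            if d.is_tracer:
                tracer_order.append(symbol)
    return ElementRegistry(defs, tuple(tracer_order))


def parse_molecule_file(path: str | Path, mode: Mode) -> list[MoleculeSpec]:
    """Read a molecule table CSV.

    Header: ``Molecule,ProductFormula,NeutralLossFormula``; the neutral
    loss column is empty except in msms mode.
    """
    path = Path(path)
    molecules: list[MoleculeSpec] = []
    seen: set[str] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        expected = ["Molecule", "ProductFormula", "NeutralLossFormula"]
        if [h.strip() for h in header] != expected:
            raise ParseError(f"{path}: bad header {header!r}, expected {expected}")
        for line_no, row in enumerate(reader, start=2):
            if not row or not any(cell.strip() for cell in row):
                continue
            if len(row) != 3:
                raise ParseError(f"{path} line {line_no}: expected 3 columns")
            name = row[0].strip()
            if name in seen:
                raise ParseError(f"{path} line {line_no}: duplicate molecule {name}")
            seen.add(name)
            try:
                product = parse_formula(row[1].strip())
                nl_text = row[2].strip()
                neutral_loss = parse_formula(nl_text) if nl_text else None
                molecules.append(MoleculeSpec(name, mode, product, neutral_loss))
            except (ParseError, ValueError) as exc:
                raise ParseError(f"{path} line {line_no}: {exc}") from None
    return molecules


# ---------------------------------------------------------------------------
# Cross-input validation


@dataclass(frozen=True)
class Finding:
    """One validation finding; ``severity`` is ``"error"`` or ``"warning"``."""

    severity: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.severity.upper()}: {self.message}"


def validate_inputs(
    registry: ElementRegistry,
    molecules: Iterable[MoleculeSpec],
    measurements: "MeasurementTable | None" = None,
) -> list[Finding]:
    """Check that registry, molecules and measurements are mutually consistent.

    Errors: labelable atoms of an element with no tracer definition;
    missing measurement rows for expected label states.  Warnings:
    molecules with nothing to correct; negative measured values (which
    the reader clamps to zero).
    """
    from .matrix import expected_keys  # local import to avoid a cycle

    findings: list[Finding] = []
    for mol in molecules:
        lab_elements = set(mol.product.labelable)
        if mol.neutral_loss is not None:
            lab_elements |= set(mol.neutral_loss.labelable)
        for el in sorted(lab_elements):
            if el not in registry or not registry[el].is_tracer:
                findings.append(
                    Finding(
                        "error",
                        f"{mol.name}: labelable element {el} has no tracer "
                        "definition in the element file",
                    )
                )
        for el in sorted(mol.product.elements() | (
            mol.neutral_loss.elements() if mol.neutral_loss else set()
        )):
            if el not in registry:
                findings.append(
                    Finding("error", f"{mol.name}: element {el} not in element file")
                )
        if not lab_elements or all(
            (el not in registry or not registry[el].is_tracer) for el in lab_elements
        ):
            findings.append(
                Finding("warning", f"{mol.name}: no labelable tracer atoms; nothing to correct")
            )
            continue
        if measurements is not None:
            try:
                keys = expected_keys(mol, registry)
            except ValueError:
                continue  # already reported above
            for key in keys:
                if key not in measurements.keys:
                    findings.append(
                        Finding("error", f"missing key {key} in measurement file")
                    )
    if measurements is not None:
        for key, sample, value in measurements.negative_cells():
            findings.append(
                Finding(
                    "warning",
                    f"negative measured value {value} at {key}/{sample}; clamped to 0",
                )
            )
    return findings
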