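"""Measurement-table reading and result writing.

Measurement files are CSV with a ``Measurement`` key column and one
column per sample.  Row keys name the molecule and its measured label
state: ``Pro_3`` (MS1 shift 3), ``Asp_3.2`` (MS/MS precursor shift 3,
product-ion shift 2), ``Asn_3.1`` (high-resolution pattern: 3 tracer-1,
1 tracer-2).  Dots separate state components; the molecule name itself
may not contain an underscore.

Results are written as four CSV tables (corrected values, fractional
abundances, mean enrichment, relative residuals) plus a plain-text run
log; output is byte-identical across repeated runs on identical input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import ElementRegistry, MoleculeSpec, ParseError
from .matrix import expected_keys, format_state

__all__ = ["MeasurementTable", "read_measurement_file", "write_results"]


@dataclass
class MeasurementTable:
    """Measured intensities: rows = ``Molecule_state`` keys, columns =
    samples, with an explicit missing mask; negatives are clamped to 0
    when vectors are extracted (reported by ``negative_cells``)."""

    values: pd.DataFrame  # float, NaN for missing

    @property
    def keys(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def negative_cells(self) -> list[tuple[str, str, float]]:
        out = []
        for key, row in self.values.iterrows():
            for sample, v in row.items():
                if pd.notna(v) and v < 0:
                    out.append((key, sample, float(v)))
        return out

    def vector(
        self, mol: MoleculeSpec, registry: ElementRegistry, sample: str
    ) -> tuple[np.ndarray, int]:
        """Measured vector for one molecule/sample in matrix row order.

        Missing cells (absent rows or empty cells) count as missing and
        are filled with 0; negatives are clamped to 0.  Returns the
        vector and the number of missing cells.
        """
        keys = expected_keys(mol, registry)
        col = self.values[sample]
        v = np.zeros(len(keys))
        n_missing = 0
        for i, key in enumerate(keys):
            if key not in self.values.index or pd.isna(col.get(key)):
                n_missing += 1
            else:
                v[i] = max(float(col[key]), 0.0)
        return v, n_missing


def read_measurement_file(
    path: str | Path,
    molecules: list[MoleculeSpec] | None = None,
    mode: str | None = None,
) -> MeasurementTable:
    """Read a measurement CSV (header ``Measurement,<sample>,...``).

    When ``molecules``/``mode`` are given, every row key must name a
    known molecule and parse as a label state of that mode.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.columns[0] != "Measurement":
        raise ParseError(f"{path}: first column must be 'Measurement'")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: no sample columns")
    keys = df["Measurement"].tolist()
    dupes = pd.Index(keys)[pd.Index(keys).duplicated()]
    if len(dupes):
        raise ParseError(f"{path}: duplicate measurement key {dupes[0]!r}")
    names = {m.name for m in molecules} if molecules is not None else None
    from .matrix import parse_state

    for line_no, key in enumerate(keys, start=2):
        if "_" not in key:
            raise ParseError(
                f"{path} line {line_no}: key {key!r} lacks '_<state>' suffix"
            )
        name, suffix = key.split("_", 1)
        if names is not None and name not in names:
            raise ParseError(f"{path} line {line_no}: unknown molecule {name!r}")
        if mode is not None:
            try:
                parse_state(suffix, mode)
            except ValueError as exc:
                raise ParseError(f"{path} line {line_no}: {exc}") from None
    values = df.set_index("Measurement").apply(
        lambda col: pd.to_numeric(col.str.strip().replace("", None), errors="raise")
    )
    values = values.astype(float)
    return MeasurementTable(values)


def _fmt(x: float | None) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return ""
    return f"{x:.10g}"


def _write_table(path: Path, key_header: str, rows: list[tuple[str, list]]) -> None:
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        header, data = rows[0], rows[1:]
        fh.write(",".join([key_header] + list(header[1])) + "\n")
        for key, vals in data:
            fh.write(",".join([key] + [_fmt(v) for v in vals]) + "\n")


def write_results(results: dict, run_warnings: list[str], out_dir: str | Path) -> None:
    """Write corrected.csv, corrected_fractions.csv, mean_enrichment.csv,
    residuals.csv and run.log into ``out_dir``.

    ``results`` maps (molecule, sample) to a ``CorrectionResults`` (or
    None for withheld samples), as produced by ``correct_dataset``.
    """
    if not results:
        raise ValueError("no results to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    molecules: list[str] = []
    samples: list[str] = []
    for mol_name, sample in results:
        if mol_name not in molecules:
            molecules.append(mol_name)
        if sample not in samples:
            samples.append(sample)

    corrected_rows: list[tuple[str, list]] = [("", samples)]
    fraction_rows: list[tuple[str, list]] = [("", samples)]
    enrich_rows: list[tuple[str, list]] = [("", samples)]
    residual_rows: list[tuple[str, list]] = [("", samples)]

    for mol_name in molecules:
        any_res = next(
            (r for (m, _), r in results.items() if m == mol_name and r is not None),
            None,
        )
        if any_res is None:
            continue
        states = any_res.states
        per_sample = [results.get((mol_name, s)) for s in samples]
        for i, state in enumerate(states):
            key = f"{mol_name}_{format_state(state)}"
            corrected_rows.append(
                (key, [None if r is None else r.corrected[i] for r in per_sample])
            )
            fraction_rows.append(
                (
                    key,
                    [
                        None
                        if r is None or r.fractions is None
                        else r.fractions[i]
                        for r in per_sample
                    ],
                )
            )
        tracers = sorted({t for r in per_sample if r is not None for t in r.mean_enrichment})
        for tracer in tracers:
            enrich_rows.append(
                (
                    f"{mol_name}.{tracer}",
                    [
                        None if r is None else r.mean_enrichment.get(tracer)
                        for r in per_sample
                    ],
                )
            )
        residual_rows.append(
            (mol_name, [None if r is None else r.residual_rel for r in per_sample])
        )

    _write_table(out_dir / "corrected.csv", "Measurement", corrected_rows)
    _write_table(out_dir / "corrected_fractions.csv", "Measurement", fraction_rows)
    _write_table(out_dir / "mean_enrichment.csv", "Molecule.Tracer", enrich_rows)
    _write_table(out_dir / "residuals.csv", "Molecule", residual_rows)
    with (out_dir / "run.log").open("w", encoding="utf-8", newline="\n") as fh:
        for w in run_warnings:
            fh.write(w + "\n")
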