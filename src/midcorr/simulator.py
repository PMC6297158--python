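"""Reverse application of the correction: simulate uncorrected data.

Running the model forward, ``v_m = P v_c``, turns known ground truth
into the uncorrected vectors an instrument would report under natural
isotope abundance and tracer impurity.  This is how correction accuracy
is validated end-to-end, and how the packaged scenario fixtures
(isotopomer mixtures of known composition, composition series,
multi-tracer labeling) are produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import ElementDef, ElementRegistry, MoleculeSpec, parse_formula
from .matrix import CorrectionMatrix, format_state
from .model import CorrectionModel

__all__ = [
    "MixtureSpec",
    "SyntheticDataset",
    "simulate_measured",
    "make_mixture_fixture",
    "make_alanine_model",
    "make_composition_series",
    "make_multitracer_scenario",
    "random_dataset",
]

# Alanine isotopomer mixtures of known composition (concentrations in uM).
# The two singly-labeled isotopomers are indistinguishable at nominal mass
# resolution and are pooled into the m+1 component.
_MIXTURES: dict[int, dict[int, float]] = {
    1: {0: 50.000, 1: 12.500 + 12.500, 2: 3.125, 3: 0.781},
    2: {0: 20.000, 1: 20.000 + 20.000, 2: 20.000, 3: 20.000},
    3: {0: 10.000, 1: 20.000 + 40.000, 2: 10.000, 3: 30.000},
    4: {0: 100.000, 1: 1.000 + 1.000, 2: 1.000, 3: 1.000},
}


@dataclass(frozen=True)
class MixtureSpec:
    """Known isotopomer mixture: concentration (uM) per label count."""

    concentrations: dict[int, float]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.concentrations.values()):
            raise ValueError("concentrations must be non-negative")
        if not any(c > 0 for c in self.concentrations.values()):
            raise ValueError("at least one component must be present")

    @property
    def fractions(self) -> np.ndarray:
        n_max = max(self.concentrations)
        v = np.array([self.concentrations.get(i, 0.0) for i in range(n_max + 1)])
        return v / v.sum()

    @property
    def vector(self) -> np.ndarray:
        n_max = max(self.concentrations)
        return np.array([self.concentrations.get(i, 0.0) for i in range(n_max + 1)])


@dataclass
class SyntheticDataset:
    """Simulated uncorrected data with its generating ground truth."""

    model: CorrectionModel
    truth: np.ndarray  # (n_samples, k)
    measured: np.ndarray  # (n_samples, k)
    seed: int | None = None
    noise_sd: float = 0.0

    @property
    def sample_names(self) -> list[str]:
        return [f"sample{i + 1}" for i in range(self.truth.shape[0])]

    def _table(self, data: np.ndarray) -> pd.DataFrame:
        keys = [
            f"{self.model.molecule.name}_{format_state(s)}" for s in self.model.states
        ]
        return pd.DataFrame(data.T, index=pd.Index(keys, name="Measurement"),
                            columns=self.sample_names)

    def measured_frame(self) -> pd.DataFrame:
        return self._table(self.measured)

    def truth_frame(self) -> pd.DataFrame:
        return self._table(self.truth)


def simulate_measured(matrix: CorrectionMatrix | np.ndarray, v_c) -> np.ndarray:
    """Forward model v_m = P v_c (no noise)."""
    P = matrix.P if isinstance(matrix, CorrectionMatrix) else np.asarray(matrix, float)
    v_c = np.asarray(v_c, dtype=float)
    if v_c.shape != (P.shape[1],):
        raise ValueError(f"truth vector must have length {P.shape[1]}")
    return P @ v_c


def make_mixture_fixture(mixture_id: int) -> MixtureSpec:
    """One of the four packaged alanine isotopomer mixtures (m+0..m+3)."""
    try:
        return MixtureSpec(dict(_MIXTURES[mixture_id]))
    except KeyError:
        raise ValueError(f"mixture id must be 1..4, got {mixture_id}") from None


def make_alanine_model(
    n_tms: int = 2,
    *,
    purity: float = 0.99,
    purity_correction: bool = True,
    registry: ElementRegistry | None = None,
) -> CorrectionModel:
    """TMS-derivatized alanine, MS1 mode.

    Alanine (C3H7NO2) has 3 labelable carbons; each trimethylsilyl group
    replaces one hydrogen and adds SiC3H9.  ``n_tms`` parameterizes the
    derivatization degree (default 2, the common di-TMS derivative).
    """
    formula = f"LabC3C{3 * n_tms}H{7 + 8 * n_tms}NO2Si{n_tms}"
    return CorrectionModel.from_formula(
        "Ala",
        formula,
        mode="ms1",
        registry=registry,
        purities={"C": purity},
        purity_correction=purity_correction,
    )


def make_composition_series(
    c_atoms=range(0, 11), si_atoms=range(0, 4)
) -> pd.DataFrame:
    """Uncorrected m+0/m+1 ratio versus C/Si composition, at equal truth.

    For each hypothetical molecule with one labelable carbon plus the
    given plain C and Si atoms, the true m+0 and m+1 amounts are equal,
    so a perfect measurement would show a ratio of 1; the simulated
    uncorrected ratio shows the natural-abundance distortion instead.
    """
    rows = []
    for c in c_atoms:
        for si in si_atoms:
            formula = "LabC1" + (f"C{c}" if c else "") + (f"Si{si}" if si else "")
            model = CorrectionModel.from_formula(
                f"HypC{c}Si{si}", formula, mode="ms1", purity_correction=False
            )
            v_m = model.simulate(np.array([1.0, 1.0]))
            rows.append(
                {"c_atoms": c, "si_atoms": si, "uncorrected_ratio": v_m[0] / v_m[1]}
            )
    return pd.DataFrame(rows)


# Ground truth of the multi-tracer scenario: highly labeled species dominate,
# flanked by low-abundance species carrying one tracer atom less — the regime
# where tracer impurity distorts hardest.  Fixture constants, not measured data.
_MULTITRACER_TRUTH: dict[tuple[int, int], float] = {
    (4, 2): 1000.0,
    (4, 1): 600.0,
    (3, 2): 400.0,
    (3, 1): 10.0,
    (3, 0): 10.0,
}


def make_multitracer_scenario(
    purity: float = 0.98, purity_correction: bool = True
) -> SyntheticDataset:
    """Asparagine-like two-tracer (13C/15N) high-resolution scenario.

    Four labelable carbons and two labelable nitrogens (k = 15); truth
    is concentrated on highly labeled states; measured data simulated
    with the given tracer purity on both tracers.
    """
    model = CorrectionModel.from_formula(
        "Asn",
        "LabC4LabN2",
        mode="highres",
        purities={"C": purity, "N": purity},
        purity_correction=purity_correction,
    )
    truth = np.array(
        [_MULTITRACER_TRUTH.get(s, 0.0) for s in model.states]
    )
    measured = model.simulate(truth)
    return SyntheticDataset(model, truth[None, :], measured[None, :])


def random_dataset(
    seed: int,
    mode: str,
    molecule: MoleculeSpec | None = None,
    registry: ElementRegistry | None = None,
    n_samples: int = 3,
    noise_sd: float = 0.0,
    purity_correction: bool = True,
    purities: dict[str, float] | None = None,
) -> SyntheticDataset:
    """Seeded random truth vectors, simulated to uncorrected data.

    Truth entries are drawn i.i.d. uniform on [0, 100); optional
    relative Gaussian noise (sd = noise_sd * value) is added to the
    measured vectors and truncated at zero.
    """
    if seed is None:
        raise ValueError("an explicit seed is required")
    if molecule is None:
        defaults = {
            "ms1": ("Rnd", "LabC3C4H9NO2", None),
            "msms": ("Rnd", "LabC2C2H5O", "LabC1C3H7NO"),
            "highres": ("Rnd", "LabC3LabN2H6O2", None),
        }
        name, product, nl = defaults[mode]
        model = CorrectionModel.from_formula(
            name, product, nl, mode=mode, purities=purities,
            purity_correction=purity_correction,
        )
    else:
        if registry is None:
            raise ValueError("registry required when molecule is given")
        if purities:
            registry = registry.with_purities(purities)
        model = CorrectionModel(molecule, registry, purity_correction=purity_correction)
    rng = np.random.default_rng(seed)
    k = model.k
    truth = rng.uniform(0.0, 100.0, size=(n_samples, k))
    measured = truth @ model.matrix.P.T
    if noise_sd > 0.0:
        noise = rng.normal(0.0, 1.0, size=measured.shape) * noise_sd * measured
        measured = np.clip(measured + noise, 0.0, None)
    return SyntheticDataset(model, truth, measured, seed=seed, noise_sd=noise_sd)
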