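import random

import pytest

from midcorr.chem import (
    ElementRegistry,
    FragmentFormula,
    MoleculeSpec,
    default_elements_path,
    parse_element_file,
)


@pytest.fixture(scope="session")
def registry() -> ElementRegistry:
    """Packaged element table: C/H/N/O/Si/S, tracers C and N (shift 1)."""
    return parse_element_file(default_elements_path())


@pytest.fixture(scope="session")
def registry98(registry) -> ElementRegistry:
    return registry.with_purities({"C": 0.98, "N": 0.98})


def random_molecule(rng: random.Random, mode: str, max_atoms: int = 12,
                    max_enum: int = 5000) -> MoleculeSpec:
    """Random small molecule over {C,H,N,O,Si,S} whose brute-force
    enumeration stays tractable (used against the oracle)."""
    while True:
        if mode == "highres":
            lab = {"C": rng.randint(1, 3), "N": rng.randint(1, 2)}
        else:
            lab = {"C": rng.randint(1, 3)}
        budget = max_atoms - sum(lab.values())
        plain: dict[str, int] = {}
        for _ in range(rng.randint(0, budget)):
            el = rng.choice(["C", "H", "H", "N", "O", "Si", "S"])
            plain[el] = plain.get(el, 0) + 1
        if mode == "msms":
            nl_lab = {"C": rng.randint(0, 2)}
            nl_plain: dict[str, int] = {}
            for _ in range(rng.randint(0, 2)):
                el = rng.choice(["C", "H", "O"])
                nl_plain[el] = nl_plain.get(el, 0) + 1
            if sum(nl_lab.values()) + sum(nl_plain.values()) == 0:
                nl_plain["H"] = 1
            nl = FragmentFormula(nl_plain, {k: v for k, v in nl_lab.items() if v > 0})
        else:
            nl = None
        product = FragmentFormula(plain, lab)
        mol = MoleculeSpec("Rnd", mode, product, nl)  # type: ignore[arg-type]
        import oracle

        reg = parse_element_file(default_elements_path())
        size = oracle.enumeration_size(product, reg)
        if nl is not None:
            size = max(size, oracle.enumeration_size(nl, reg))
        total_atoms = product.total_atoms + (nl.total_atoms if nl else 0)
        if size <= max_enum and total_atoms <= max_atoms:
            return mol
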