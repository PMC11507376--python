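import numpy as np
import pytest

from edc_compare import (
    SyntheticSpec,
    make_toy_complex,
    simulate_density,
    smooth_map,
)


@pytest.fixture(scope="session")
def spec():
    return SyntheticSpec(seed=1)


@pytest.fixture(scope="session")
def toy_complex(spec):
    return make_toy_complex(spec)


@pytest.fixture(scope="session")
def toy_map(toy_complex, spec):
    return simulate_density(toy_complex, spec)


@pytest.fixture(scope="session")
def toy_smoothed(toy_map):
    return smooth_map(toy_map, window=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def _pdb_line(record, serial, name, resname, chain, resnum, x, y, z, element=""):
    """Strict fixed-column PDB ATOM/HETATM line; an empty element column
    exercises name-based inference."""
    # single-char/standard names start in column 14; 2-letter metal names in 13
    aligned = f"{name:<4}" if len(name) >= 4 or name in ("CU", "FE") else f" {name:<3}"
    return (
        f"{record:<6}{serial:>5} {aligned}{'':1}{resname:>3} {chain:1}"
        f"{resnum:>4}{'':4}{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"{'':10}{element:>2}"
    )


def _toy_pdb_text():
    """Two-model toy entry: 3-residue peptide + Cu in chain A, 2 residues +
    heme Fe in chain C, one water (to be dropped on read)."""
    blocks = []
    for m, dx in ((1, 0.0), (2, 0.1)):
        lines = [f"MODEL     {m:>4}"]
        rows = [
            ("ATOM", 1, "N", "ALA", "A", 1, 0.0 + dx, 0.0, 0.0, "N"),
            ("ATOM", 2, "CA", "ALA", "A", 1, 1.458 + dx, 0.0, 0.0, "C"),
            ("ATOM", 3, "C", "ALA", "A", 1, 2.0 + dx, 1.4, 0.0, "C"),
            ("ATOM", 4, "CA", "GLY", "A", 2, 4.5 + dx, 2.0, 1.0, ""),
            ("ATOM", 5, "CA", "SER", "A", 3, 7.8 + dx, 3.1, 2.5, "C"),
            ("HETATM", 6, "CU", "CU", "A", 99, 10.0 + dx, 5.0, 3.0, "CU"),
            ("ATOM", 7, "CA", "LEU", "C", 10, 20.0 + dx, 0.0, 0.0, "C"),
            ("ATOM", 8, "CA", "VAL", "C", 11, 23.5 + dx, 1.2, 0.5, "C"),
            ("HETATM", 9, "FE", "HEC", "C", 50, 25.0 + dx, 3.0, 1.0, "FE"),
        ]
        if m == 1:
            rows.append(("HETATM", 10, "O", "HOH", "A", 200, 50.0, 50.0, 50.0, "O"))
        lines += [_pdb_line(*r) for r in rows]
        lines.append("ENDMDL")
        blocks.append("\n".join(lines))
    return "\n".join(blocks) + "\nEND\n"


TOY_PDB = _toy_pdb_text()


@pytest.fixture()
def toy_pdb_path(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TOY_PDB)
    return p
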