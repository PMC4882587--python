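from pathlib import Path

import pytest

from rethread.design import build_design
from rethread.examples import (
    dhfr_design_inputs,
    dhfr_like_parent,
    sheet_toy,
    sheet_toy_design,
)

#: Directory for optional real coordinate files (not distributed; see README).
DATA_DIR = Path(__file__).parent / "data"

TINY_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00 10.00           C
ATOM      3  C   GLY A   1       2.000   1.400   0.000  1.00 10.00           C
ATOM      4  O   GLY A   1       1.500   2.300   0.700  1.00 10.00           O
ATOM      5  N   ALA A   2       3.300   1.500   0.000  1.00 11.00           N
ATOM      6  CA  ALA A   2       4.100   2.700   0.200  1.00 11.00           C
ATOM      7  C   ALA A   2       5.500   2.400   0.700  1.00 11.00           C
ATOM      8  N   SER A   3       6.400   3.400   0.700  1.00 12.00           N
ATOM      9  CA  SER A   3       7.800   3.300   1.200  1.00 12.00           C
ATOM     10  C   SER A   3       8.600   4.500   0.800  1.00 12.00           C
TER
END
"""


@pytest.fixture(scope="session")
def sheet():
    """Four-strand toy with a feasible middle-fragment swap."""
    return sheet_toy()


@pytest.fixture(scope="session")
def sheet_design(sheet):
    toy, annotation = sheet
    return sheet_toy_design(toy, annotation)


@pytest.fixture(scope="session")
def dhfr_like():
    """Synthetic 159-residue parent with the classic worked example's loops."""
    return dhfr_like_parent()


@pytest.fixture(scope="session")
def dhfr_design(dhfr_like):
    structure, annotation = dhfr_like
    excisions, order, extra = dhfr_design_inputs(structure)
    return build_design(
        structure.chains[0], excisions, order, annotation=annotation,
        extra_retained=extra, parent_id=structure.id,
    )
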