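import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from silamdyn.io import (
    Modification,
    ProteinRecord,
    PsmRecord,
    SampleDesign,
    parse_inline_peptide,
)


def psm(annotated: str, sample: str, count: int = 1, proteins=("P1",), score=None):
    """Build a PsmRecord from inline notation, e.g. 'ASK(+6.02)LR'."""
    peptide, mods = parse_inline_peptide(annotated)
    if score is not None:
        mods = tuple(
            Modification(m.name, m.delta_mass, m.position, m.residue, score)
            if m.name == "phospho"
            else m
            for m in mods
        )
    return PsmRecord(peptide, mods, tuple(proteins), count, sample)


@pytest.fixture
def two_group_design():
    """3 Control + 3 LPS animals, EC layer."""
    return [
        SampleDesign(f"{c}_EC_a{i}", c, "EC", f"{c}_animal{i}")
        for c in ("Control", "LPS")
        for i in (1, 2, 3)
    ]


@pytest.fixture
def tiny_proteome():
    return [
        ProteinRecord("P1", "protein one", "MAKRLSTKPEWIDNKAGER"),
        ProteinRecord("P2", "protein two", "MGGSKTTTRPLLVKYEEDR"),
    ]
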