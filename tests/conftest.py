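import pytest

from tmdmap.proteome_io import ProteinRecord, TMDInterval


@pytest.fixture
def toy_proteome() -> list[ProteinRecord]:
    """Two membrane proteins and one soluble protein with known helices."""
    return [
        # helix 1 at 10-30, helix 2 at 45-65
        ProteinRecord(
            "P1",
            "two-helix protein",
            "MKSTDDEQK"              # 1-9 loop
            + "LIVFAILVVLFAILVIVLFAI"  # 10-30 helix 1
            + "GGKDDSEQRESDEK"        # 31-44 loop
            + "ILVFAVLIVLFAILVIVLFAE"  # 45-65 helix 2
            + "KRDDSE",               # 66-71 tail
        ),
        ProteinRecord("P2", "soluble", "MKDDEESSGGKRDDEESSGGKRDDEESSGG"),
        # helix at 7-29
        ProteinRecord(
            "P3",
            "one-helix protein",
            "MKDSEG" + "AILVFLIVALLVIVFAILVIVLF" + "KRDDSEGGQQ",
        ),
    ]


@pytest.fixture
def toy_tmds(toy_proteome) -> list[TMDInterval]:
    return [
        TMDInterval("P1", 10, 30, 1),
        TMDInterval("P1", 45, 65, 2),
        TMDInterval("P3", 7, 29, 1),
    ]
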