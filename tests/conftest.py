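import pytest

from segscreen.model import (
    DEFAULT_SCHEMA,
    PhenotypicVector,
    ScreenTable,
    TreatmentRecord,
)


def build_vector(morph=(0, 0, 0, 0, 0, 0), seg=(0, 0, 0, 0, 0, 0)):
    """Vector from explicit morphology and segmentation halves."""
    return PhenotypicVector(tuple(morph) + tuple(seg), DEFAULT_SCHEMA)


def build_record(
    compound, conc=10.0, exp="wt_A",
    morph=(0, 0, 0, 0, 0, 0), seg=(0, 0, 0, 0, 0, 0),
    lethal=False, scored=True, n_embryos=5,
):
    vector = None
    if scored and not lethal:
        vector = build_vector(morph, seg)
    return TreatmentRecord(
        compound_id=compound,
        concentration=conc,
        experiment=exp,
        plate="P001",
        well="A01",
        lethal=lethal,
        n_embryos=n_embryos,
        n_scoreable=0 if lethal else n_embryos,
        vector=vector,
    )


def build_table(records):
    return ScreenTable(records=tuple(records), schema=DEFAULT_SCHEMA)


@pytest.fixture
def make_vector():
    return build_vector


@pytest.fixture
def make_record():
    return build_record


@pytest.fixture
def make_table():
    return build_table


@pytest.fixture
def small_table():
    """2 compounds x 2 concentrations x 2 experiments, fully scored."""
    records = []
    for compound, seg in (("C1", (3, 2, 3, 2, 3, 2)), ("C2", (0, 0, 0, 0, 0, 0))):
        for conc in (2.0, 10.0):
            for exp in ("wt_A", "wt_B"):
                records.append(
                    build_record(compound, conc, exp, seg=seg)
                )
    return build_table(records)
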