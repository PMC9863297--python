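import pytest

from eutsol import data


@pytest.fixture(scope="session")
def table1():
    """The packaged measured-solubility fixture (24 records)."""
    return data.load_table1()


@pytest.fixture(scope="session")
def water():
    return data.SolventComposition(
        components=(("water", 1.0, data.MOLAR_MASS["water"]),), des_label="water"
    )


def pick(records, label, T):
    """Record for a given DES label at a given temperature."""
    for r in records:
        if r.composition.des_label == label and abs(r.temperature - T) < 1e-9:
            return r
    raise LookupError(f"{label} @ {T} K")
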