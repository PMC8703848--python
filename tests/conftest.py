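import pytest

from bbbccs.compound_model import (
    BBBLabel,
    ChargeClass,
    CompoundDataset,
    CompoundRecord,
)


@pytest.fixture
def write_csv(tmp_path):
    """Write CSV text to a temp file and return its path."""

    def _write(text: str, name: str = "table.csv"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture
def tiny_dataset() -> CompoundDataset:
    """Three hand-built records covering both labels and a gap."""
    return CompoundDataset(
        records=[
            CompoundRecord(
                id="a",
                smiles="CCO",
                charge_class=ChargeClass.neutral,
                bbb_label=BBBLabel.BBB_plus,
                descriptors={"ccs": 150.0, "mw": 46.07, "xlogp3": -0.1},
            ),
            CompoundRecord(
                id="b",
                smiles="CCN",
                charge_class=ChargeClass.positive,
                bbb_label=BBBLabel.BBB_minus,
                descriptors={"ccs": 250.0, "mw": 45.08, "xlogp3": -2.0},
            ),
            CompoundRecord(
                id="c",
                smiles="CCC",
                charge_class=ChargeClass.negative,
                bbb_label=BBBLabel.unknown,
                descriptors={"mw": 44.1},
            ),
        ],
        name="tiny",
    )
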