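"""Domain types and table I/O for labelled compound libraries.

A compound library is a flat CSV table: one row per compound with an
identifier, a SMILES string, the predominant charge at physiological pH,
a blood-brain-barrier (BBB) permeation label and a sparse set of numeric
molecular descriptors (collision cross section in Å², molecular weight in
Da, polar surface area in Å², lipophilicity, H-bond counts, ...).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Descriptor columns recognised by default, in canonical order.
DESCRIPTOR_NAMES = (
    "ccs",
    "mw",
    "psa",
    "logd74",
    "xlogp3",
    "h_acceptors",
    "h_donors",
    "rotatable_bonds",
    "pka",
)

#: Descriptors that must be non-negative when present.
_NONNEGATIVE = frozenset({"ccs", "mw", "psa", "h_acceptors", "h_donors", "rotatable_bonds"})

#: Default mapping from CSV column name to record field / descriptor name.
DEFAULT_COLUMNS = {
    "id": "id",
    "smiles": "smiles",
    "charge": "charge_class",
    "bbb": "bbb_label",
    **{name: name for name in DESCRIPTOR_NAMES},
}


class ChargeClass(str, Enum):
    """Predominant charge of a compound at physiological pH."""

    positive = "positive"
    negative = "negative"
    neutral = "neutral"
    unknown = "unknown"


class BBBLabel(str, Enum):
    """Literature blood-brain-barrier permeation label."""

    BBB_plus = "BBB+"
    BBB_minus = "BBB-"
    unknown = "unknown"


# Accepted spellings, lower-cased.  BBB+/- and CNS+/- are used
# interchangeably in the source literature; 1/0 and p/n appear in
# machine-readable exports.
_LABEL_VOCAB = {
    "bbb+": BBBLabel.BBB_plus,
    "bbb-": BBBLabel.BBB_minus,
    "cns+": BBBLabel.BBB_plus,
    "cns-": BBBLabel.BBB_minus,
    "1": BBBLabel.BBB_plus,
    "0": BBBLabel.BBB_minus,
    "p": BBBLabel.BBB_plus,
    "n": BBBLabel.BBB_minus,
    "+": BBBLabel.BBB_plus,
    "-": BBBLabel.BBB_minus,
}

_CHARGE_VOCAB = {
    "positive": ChargeClass.positive,
    "pos": ChargeClass.positive,
    "+": ChargeClass.positive,
    "negative": ChargeClass.negative,
    "neg": ChargeClass.negative,
    "-": ChargeClass.negative,
    "neutral": ChargeClass.neutral,
    "0": ChargeClass.neutral,
}


class FormatError(ValueError):
    """Raised when an input table does not match the expected schema."""


class EmptyDatasetError(FormatError):
    """Raised when an input table contains no data rows."""


class AlignmentError(ValueError):
    """Raised when per-record annotations do not align with record ids."""


def parse_bbb_label(text: str | None) -> BBBLabel:
    """Map a raw label cell onto the BBB label vocabulary (case-insensitive)."""
    if text is None:
        return BBBLabel.unknown
    return _LABEL_VOCAB.get(text.strip().lower(), BBBLabel.unknown)


def parse_charge_class(text: str | None) -> ChargeClass:
    if text is None:
        return ChargeClass.unknown
    return _CHARGE_VOCAB.get(text.strip().lower(), ChargeClass.unknown)


@dataclass
class CompoundRecord:
    """One drug/compound with its labels and sparse descriptor map.

    Descriptors are stored in a plain mapping; a missing key means the
    value is unknown, never zero.
    """

    id: str
    smiles: str = ""
    charge_class: ChargeClass = ChargeClass.unknown
    bbb_label: BBBLabel = BBBLabel.unknown
    descriptors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in self.descriptors.items():
            if name in _NONNEGATIVE and value < 0:
                raise ValueError(f"descriptor {name!r} must be >= 0, got {value}")

    def descriptor(self, name: str) -> float | None:
        """Return a descriptor value, or None when absent."""
        value = self.descriptors.get(name)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        return value


@dataclass
class CompoundDataset:
    """An ordered, id-unique collection of compound records."""

    records: list[CompoundRecord]
    name: str = "dataset"

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids in dataset {self.name!r}: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]


@dataclass(frozen=True)
class DatasetSummary:
    """Counts and class ratio of a labelled dataset."""

    n_total: int
    n_plus: int
    n_minus: int
    n_unknown: int
    ratio: float | None  # n_plus / n_minus to one decimal; None when undefined


def dataset_summary(ds: CompoundDataset) -> DatasetSummary:
    """Count labelled records and report the positive:negative ratio.

    The ratio is rounded to one decimal, matching how compound-set class
    ratios are conventionally printed; it is None when there are no
    negatives.
    """
    n_plus = sum(1 for r in ds if r.bbb_label is BBBLabel.BBB_plus)
    n_minus = sum(1 for r in ds if r.bbb_label is BBBLabel.BBB_minus)
    n_total = len(ds)
    ratio = round(n_plus / n_minus, 1) if n_minus > 0 else None
    return DatasetSummary(
        n_total=n_total,
        n_plus=n_plus,
        n_minus=n_minus,
        n_unknown=n_total - n_plus - n_minus,
        ratio=ratio,
    )


def _parse_float(cell: str) -> float | None:
    try:
        value = float(cell)
    except (TypeError, ValueError):
        return None
    if math.isnan(value):
        return None
    return value


def _validate_smiles(smiles: str) -> bool:
    from rdkit import Chem  # optional dependency, imported lazily
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    return Chem.MolFromSmiles(smiles) is not None


def read_compound_table(
    path: str | Path,
    dialect: str = "standard",
    *,
    name: str | None = None,
    columns: Mapping[str, str] | None = None,
    validate_smiles: bool = False,
) -> CompoundDataset:
    """Read a compound CSV into a :class:`CompoundDataset`.

    Parameters
    ----------
    path:
        CSV file with a header row (UTF-8, RFC-4180 style).
    dialect:
        ``"standard"`` — full schema with id/smiles/charge/bbb/descriptor
        columns (all but ``smiles`` optional); ``"ccsbase_batch"`` — the
        single-SMILES-column upload format of batch CCS predictors.
    columns:
        Optional mapping from actual CSV column names to canonical field
        names, overriding :data:`DEFAULT_COLUMNS` entries.
    validate_smiles:
        When True, rows whose SMILES fails RDKit parsing are dropped and
        counted in the log.

    Unparseable numeric cells become absent descriptors and are logged;
    charge and label strings are mapped case-insensitively.
    """
    path = Path(path)
    if dialect not in ("standard", "ccsbase_batch"):
        raise ValueError(f"unknown dialect {dialect!r}")

    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        # user mapping is {csv_name: canonical_name}
        colmap.update({k.strip().lower(): v for k, v in columns.items()})

    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise EmptyDatasetError(f"{path}: empty file (no header row)")
        header = [h.strip().lower() for h in reader.fieldnames]
        rows = list(reader)

    if not rows:
        raise EmptyDatasetError(f"{path}: no data rows")

    canonical = {raw: colmap.get(low, low) for raw, low in zip(reader.fieldnames, header)}
    if "smiles" not in canonical.values():
        raise FormatError(f"{path}: missing SMILES column (header: {header})")

    records: list[CompoundRecord] = []
    n_bad_cells = 0
    n_bad_smiles = 0
    for i, row in enumerate(rows):
        fields: dict[str, str] = {}
        for raw_key, value in row.items():
            if raw_key is None:
                continue
            fields[canonical[raw_key]] = (value or "").strip()

        smiles = fields.get("smiles", "")
        if validate_smiles and not _validate_smiles(smiles):
            n_bad_smiles += 1
            continue

        descriptors: dict[str, float] = {}
        for dname in DESCRIPTOR_NAMES:
            cell = fields.get(dname)
            if cell in (None, ""):
                continue
            value = _parse_float(cell)
            if value is None:
                n_bad_cells += 1
                logger.warning(
                    "%s row %d: unparseable %s cell %r -> descriptor absent",
                    path.name, i + 1, dname, cell,
                )
                continue
            if dname in _NONNEGATIVE and value < 0:
                n_bad_cells += 1
                logger.warning(
                    "%s row %d: negative %s value %r -> descriptor absent",
                    path.name, i + 1, dname, cell,
                )
                continue
            descriptors[dname] = value

        records.append(
            CompoundRecord(
                id=fields.get("id") or f"row{i + 1}",
                smiles=smiles,
                charge_class=parse_charge_class(fields.get("charge_class")),
                bbb_label=parse_bbb_label(fields.get("bbb_label")),
                descriptors=descriptors,
            )
        )

    if validate_smiles and n_bad_smiles:
        logger.info("%s: dropped %d rows with invalid SMILES", path.name, n_bad_smiles)
    if not records:
        raise EmptyDatasetError(f"{path}: all rows dropped")
    return CompoundDataset(records=records, name=name or path.stem)


def write_compound_table(ds: CompoundDataset, path: str | Path) -> Path:
    """Write a dataset back to the standard CSV schema."""
    return write_predictions(ds, None, path)


def write_predictions(
    ds: CompoundDataset,
    predictions: Mapping[str, object] | Sequence[object] | None,
    path: str | Path,
    *,
    fired: Mapping[str, str] | None = None,
) -> Path:
    """Write a dataset CSV, optionally with predicted labels.

    ``predictions`` maps record id -> predicted :class:`BBBLabel` (or a
    sequence aligned with ``ds.records``); ``fired`` optionally maps id ->
    name of the rule clause that fired.  The output round-trips through
    :func:`read_compound_table`.
    """
    path = Path(path)
    pred_by_id: dict[str, object] | None
    if predictions is None:
        pred_by_id = None
    elif isinstance(predictions, Mapping):
        pred_by_id = dict(predictions)
    else:
        if len(predictions) != len(ds.records):
            raise AlignmentError(
                f"{len(predictions)} predictions for {len(ds.records)} records"
            )
        pred_by_id = {r.id: p for r, p in zip(ds.records, predictions)}
    if pred_by_id is not None:
        missing = [r.id for r in ds.records if r.id not in pred_by_id]
        if missing:
            raise AlignmentError(f"predictions missing for ids: {missing[:5]}")

    fieldnames = ["id", "smiles", "charge", "bbb", *DESCRIPTOR_NAMES]
    if pred_by_id is not None:
        fieldnames += ["predicted_bbb", "rule_fired"]

    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        for record in ds:
            row = {
                "id": record.id,
                "smiles": record.smiles,
                "charge": record.charge_class.value,
                "bbb": record.bbb_label.value,
            }
            for dname in DESCRIPTOR_NAMES:
                value = record.descriptor(dname)
                row[dname] = repr(value) if value is not None else ""
            if pred_by_id is not None:
                pred = pred_by_id[record.id]
                row["predicted_bbb"] = (
                    pred.value if isinstance(pred, BBBLabel)
                    else ("" if pred is None else str(pred))
                )
                row["rule_fired"] = (fired or {}).get(record.id, "")
            writer.writerow(row)
    return path
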