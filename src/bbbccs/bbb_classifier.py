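"""Threshold decision rules for BBB permeation.

Two rules are built in: the single-descriptor rule (BBB+ iff CCS < 200 Å²)
and the combined rule (BBB+ iff XlogP3 > -1 OR CCS < 200 Å²).  The
boundary is strict — a CCS of exactly 200 Å² is classified BBB- — with an
inclusive mode available.  Missing descriptors are never imputed: a single
rule reports the record as unclassifiable, a combined rule skips the
affected clause and logs it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .compound_model import BBBLabel, CompoundDataset

logger = logging.getLogger(__name__)


class Direction(str, Enum):
    below_is_positive = "below_is_positive"
    above_is_positive = "above_is_positive"


class Strictness(str, Enum):
    strict = "strict"
    inclusive = "inclusive"


class Combiner(str, Enum):
    any = "any"  # inclusive OR
    all = "all"  # AND


class UnclassifiableError(ValueError):
    """Raised when a rule cannot be evaluated for lack of descriptors."""


@dataclass(frozen=True)
class ThresholdRule:
    """Single-descriptor threshold rule."""

    descriptor: str
    threshold: float
    direction: Direction = Direction.below_is_positive
    strictness: Strictness = Strictness.strict

    def __post_init__(self) -> None:
        if not math.isfinite(self.threshold):
            raise ValueError(f"threshold must be finite, got {self.threshold}")

    def fires(self, value: float) -> bool:
        if self.direction is Direction.below_is_positive:
            return value < self.threshold if self.strictness is Strictness.strict \
                else value <= self.threshold
        return value > self.threshold if self.strictness is Strictness.strict \
            else value >= self.threshold

    @property
    def name(self) -> str:
        op = "<" if self.direction is Direction.below_is_positive else ">"
        if self.strictness is Strictness.inclusive:
            op += "="
        return f"{self.descriptor}{op}{self.threshold:g}"


@dataclass(frozen=True)
class CombinedRule:
    """Several threshold clauses joined by inclusive OR (default) or AND."""

    clauses: tuple[ThresholdRule, ...]
    combiner: Combiner = Combiner.any

    def __post_init__(self) -> None:
        if not self.clauses:
            raise ValueError("combined rule needs at least one clause")

    @property
    def name(self) -> str:
        joiner = " OR " if self.combiner is Combiner.any else " AND "
        return joiner.join(c.name for c in self.clauses)


#: BBB+ iff CCS < 200 Å² (strict boundary).
CCS_RULE = ThresholdRule("ccs", 200.0)
#: BBB+ iff XlogP3 > -1 and/or CCS < 200 Å² (inclusive OR).
CCS_XLOGP3_RULE = CombinedRule(
    clauses=(ThresholdRule("xlogp3", -1.0, Direction.above_is_positive), CCS_RULE),
)

BUILTIN_RULES: dict[str, ThresholdRule | CombinedRule] = {
    "ccs200": CCS_RULE,
    "ccs-xlogp3": CCS_XLOGP3_RULE,
}


def classify_by_ccs(ccs: float | None, rule: ThresholdRule = CCS_RULE) -> BBBLabel:
    """Classify one CCS value under a single-descriptor threshold rule."""
    if ccs is None or (isinstance(ccs, float) and math.isnan(ccs)):
        raise UnclassifiableError(f"descriptor {rule.descriptor!r} missing")
    return BBBLabel.BBB_plus if rule.fires(ccs) else BBBLabel.BBB_minus


def classify_combined(
    descriptors: Mapping[str, float],
    rule: CombinedRule = CCS_XLOGP3_RULE,
) -> tuple[BBBLabel, str | None]:
    """Classify a descriptor map under a combined rule.

    Returns (label, name-of-first-firing-clause-or-None).  Clauses whose
    descriptor is absent are skipped and logged; if every clause is
    skipped the record is unclassifiable.
    """
    evaluated: list[tuple[ThresholdRule, bool]] = []
    for clause in rule.clauses:
        value = descriptors.get(clause.descriptor)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            logger.debug("clause %s skipped: descriptor missing", clause.name)
            continue
        evaluated.append((clause, clause.fires(value)))
    if not evaluated:
        raise UnclassifiableError("all clause descriptors missing")
    if rule.combiner is Combiner.any:
        for clause, fired in evaluated:
            if fired:
                return BBBLabel.BBB_plus, clause.name
        return BBBLabel.BBB_minus, None
    if all(fired for _, fired in evaluated):
        return BBBLabel.BBB_plus, rule.name
    return BBBLabel.BBB_minus, None


@dataclass
class DatasetPredictions:
    """Per-record predictions of a rule over a dataset (order-preserving)."""

    ids: list[str]
    labels: list[BBBLabel | None]  # None = unclassifiable
    fired: dict[str, str] = field(default_factory=dict)  # id -> clause name

    @property
    def unclassifiable_ids(self) -> list[str]:
        return [i for i, lbl in zip(self.ids, self.labels) if lbl is None]

    @property
    def n_positive(self) -> int:
        return sum(1 for lbl in self.labels if lbl is BBBLabel.BBB_plus)

    def by_id(self) -> dict[str, BBBLabel | None]:
        return dict(zip(self.ids, self.labels))


def classify_dataset(
    ds: CompoundDataset,
    rule: ThresholdRule | CombinedRule = CCS_RULE,
) -> DatasetPredictions:
    """Apply a rule to every record; unclassifiable records are collected."""
    ids: list[str] = []
    labels: list[BBBLabel | None] = []
    fired: dict[str, str] = {}
    for record in ds:
        ids.append(record.id)
        try:
            if isinstance(rule, CombinedRule):
                label, clause = classify_combined(record.descriptors, rule)
                if clause is not None:
                    fired[record.id] = clause
            else:
                label = classify_by_ccs(record.descriptor(rule.descriptor), rule)
                if label is BBBLabel.BBB_plus:
                    fired[record.id] = rule.name
            labels.append(label)
        except UnclassifiableError:
            labels.append(None)
    n_uncls = sum(1 for lbl in labels if lbl is None)
    if n_uncls:
        logger.info("%d/%d records unclassifiable under rule", n_uncls, len(ids))
    return DatasetPredictions(ids=ids, labels=labels, fired=fired)


def load_rule(source: str | Path) -> ThresholdRule | CombinedRule:
    """Load a rule by builtin name or from a small YAML schema.

    YAML schema::

        combiner: any            # optional; presence of >1 clause implies combined
        clauses:
          - {descriptor: ccs, op: "<", threshold: 200}
          - {descriptor: xlogp3, op: ">", threshold: -1}
    """
    key = str(source)
    if key in BUILTIN_RULES:
        return BUILTIN_RULES[key]
    data = yaml.safe_load(Path(source).read_text())
    clauses = []
    for spec in data["clauses"]:
        op = spec.get("op", "<")
        direction = Direction.below_is_positive if op.startswith("<") \
            else Direction.above_is_positive
        strictness = Strictness.inclusive if op.endswith("=") else Strictness.strict
        clauses.append(
            ThresholdRule(spec["descriptor"], float(spec["threshold"]), direction, strictness)
        )
    if len(clauses) == 1 and "combiner" not in data:
        return clauses[0]
    return CombinedRule(tuple(clauses), Combiner(data.get("combiner", "any")))
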