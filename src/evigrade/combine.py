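"""Combine Venice levels with FPRP values into final cumulative evidence.

FPRP below the strong cutoff upgrades the level one step (strong stays
strong); FPRP above the noteworthiness cutoff downgrades one step (weak
stays weak); values in between leave the level unchanged.  Ungraded input
stays ungraded.  Evidence is tallied once per distinct (gene, variant) via
its primary analysis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

from . import fprp as fprp_engine
from . import venice
from .fprp import FprpConfig
from .records import AssociationRecord, Ethnicity
from .venice import EvidenceLevel

__all__ = [
    "Adjustment",
    "EvidenceAssessment",
    "adjust",
    "select_primary",
    "assess_record",
    "assess_records",
    "summarize",
]


class Adjustment(str, enum.Enum):
    UPGRADED = "upgraded"
    DOWNGRADED = "downgraded"
    UNCHANGED = "unchanged"
    NOT_APPLICABLE = "not_applicable"


_ORDER = [EvidenceLevel.WEAK, EvidenceLevel.MODERATE, EvidenceLevel.STRONG]

_PUBLISHED_LEVELS = {
    "strong": EvidenceLevel.STRONG,
    "moderate": EvidenceLevel.MODERATE,
    "weak": EvidenceLevel.WEAK,
}


@dataclass(frozen=True)
class EvidenceAssessment:
    gene: str
    variant: str
    cancer_type: str
    model: str
    ethnicity: str
    venice_level: EvidenceLevel
    fprp_value: float | None
    final_level: EvidenceLevel
    adjustment: Adjustment
    is_primary: bool = False
    n_total: int | None = None

    @property
    def variant_key(self) -> tuple[str, str]:
        return (self.gene, self.variant)


def adjust(
    venice_level: EvidenceLevel,
    fprp_value: float | None,
    config: FprpConfig | None = None,
) -> tuple[EvidenceLevel, Adjustment]:
    """One-step FPRP adjustment of a Venice level."""
    config = config or FprpConfig()
    if venice_level is EvidenceLevel.UNGRADED or fprp_value is None:
        return EvidenceLevel.UNGRADED if venice_level is EvidenceLevel.UNGRADED else venice_level, (
            Adjustment.NOT_APPLICABLE
        )
    index = _ORDER.index(venice_level)
    if fprp_value < config.strong_cutoff:
        new_index = min(index + 1, len(_ORDER) - 1)
        return _ORDER[new_index], (
            Adjustment.UPGRADED if new_index != index else Adjustment.UNCHANGED
        )
    if fprp_value > config.noteworthy_cutoff:
        new_index = max(index - 1, 0)
        return _ORDER[new_index], (
            Adjustment.DOWNGRADED if new_index != index else Adjustment.UNCHANGED
        )
    return venice_level, Adjustment.UNCHANGED


def select_primary(records: Sequence[AssociationRecord]) -> AssociationRecord:
    """Pick the primary analysis of a (gene, variant) group.

    An explicitly flagged record wins; otherwise the diverse-population
    record is preferred, with ties broken by the larger total sample size.
    """
    if not records:
        raise ValueError("cannot select a primary analysis from an empty group")
    flagged = [r for r in records if r.primary]
    if flagged:
        return flagged[0]
    diverse = [r for r in records if r.ethnicity is Ethnicity.DIVERSE]
    pool = diverse or list(records)
    return max(pool, key=lambda r: (r.n_total or 0, -records.index(r)))


def _published_level(record: AssociationRecord) -> EvidenceLevel:
    if record.pub_level is None:
        return EvidenceLevel.UNGRADED
    return _PUBLISHED_LEVELS.get(record.pub_level.lower(), EvidenceLevel.UNGRADED)


def assess_record(
    record: AssociationRecord,
    config: FprpConfig | None = None,
    use_published_grades: bool = False,
    use_published_fprp: bool = False,
) -> EvidenceAssessment:
    config = config or FprpConfig()
    if use_published_grades:
        level = _published_level(record)
    else:
        level = venice.grade(record).level
    if use_published_fprp:
        fprp_value = record.pub_fprp
    else:
        fprp_value = fprp_engine.assess(record, config).fprp
    final_level, adjustment = adjust(level, fprp_value, config)
    if level is EvidenceLevel.UNGRADED:
        final_level, adjustment = EvidenceLevel.UNGRADED, Adjustment.NOT_APPLICABLE
    return EvidenceAssessment(
        gene=record.gene,
        variant=record.variant,
        cancer_type=record.cancer_type.value,
        model=record.model.value,
        ethnicity=record.ethnicity.value,
        venice_level=level,
        fprp_value=fprp_value,
        final_level=final_level,
        adjustment=adjustment,
        is_primary=record.primary,
        n_total=record.n_total,
    )


def assess_records(
    records: Iterable[AssociationRecord],
    config: FprpConfig | None = None,
    use_published_grades: bool = False,
    use_published_fprp: bool = False,
) -> list[EvidenceAssessment]:
    return [
        assess_record(r, config, use_published_grades, use_published_fprp)
        for r in records
    ]


def _primary_assessment(group: list[EvidenceAssessment]) -> EvidenceAssessment:
    flagged = [a for a in group if a.is_primary]
    if flagged:
        return flagged[0]
    diverse = [a for a in group if a.ethnicity == Ethnicity.DIVERSE.value]
    pool = diverse or group
    return max(pool, key=lambda a: (a.n_total or 0, -group.index(a)))


def summarize(assessments: Iterable[EvidenceAssessment]) -> dict[str, int]:
    """Count distinct (gene, variant) pairs per final evidence level, using
    one primary analysis per variant."""
    groups: dict[tuple[str, str], list[EvidenceAssessment]] = {}
    for assessment in assessments:
        groups.setdefault(assessment.variant_key, []).append(assessment)
    counts = {level.value: 0 for level in EvidenceLevel}
    for group in groups.values():
        counts[_primary_assessment(group).final_level.value] += 1
    return counts
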