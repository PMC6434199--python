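"""Venice-criteria grading of association records.

Three elements are graded A/B/C (X when the needed information is missing):

* amount of evidence — observed count of test alleles/genotypes, falling
  back to a count range back-calculated from sample size and MAF;
* replication — between-study heterogeneity (I-squared);
* protection from bias — publication-bias diagnostics and the magnitude of
  the summary effect.

The combined level is strong when all elements are A, weak when any element
is C, moderate otherwise; any X blocks grading entirely.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from .records import AssociationRecord

__all__ = [
    "Grade",
    "EvidenceLevel",
    "VeniceGrade",
    "amount_grade",
    "calc_count_range",
    "replication_grade",
    "bias_grade",
    "combine_elements",
    "grade",
    "MIN_CALC_COUNT",
]

#: Back-calculated counts below this are considered too unreliable to grade.
MIN_CALC_COUNT = 3000

#: Summary effects weaker than this magnitude score C on the bias element
#: unless prospectively replicated (e.g. by GWAS).
MIN_EFFECT_MAGNITUDE = 1.15


class Grade(str, enum.Enum):
    A = "A"
    B = "B"
    C = "C"
    X = "X"  # not gradable from the available information


class EvidenceLevel(str, enum.Enum):
    STRONG = "strong"
    MODERATE = "moderate"
    WEAK = "weak"
    UNGRADED = "ungraded"


@dataclass(frozen=True)
class VeniceGrade:
    amount: Grade
    replication: Grade
    bias: Grade
    level: EvidenceLevel
    calc_count_low: int | None = None
    calc_count_high: int | None = None
    rationale: tuple[str, ...] = ()

    def as_string(self) -> str:
        """Three-letter element string, e.g. ``"ABA"``."""
        return self.amount.value + self.replication.value + self.bias.value


def _round_half_up_int(value: float) -> int:
    return int(math.floor(value + 0.5))


def amount_grade(test_count: int | None) -> Grade:
    """A above 1000 test alleles/genotypes, B for 100-1000, C below 100."""
    if test_count is None:
        return Grade.X
    if test_count > 1000:
        return Grade.A
    if test_count >= 100:
        return Grade.B
    return Grade.C


def calc_count_range(n_total: int, maf: float) -> tuple[int, int]:
    """MAF-derived (genotype count, allele count) bracket for the amount
    element: (round(N*maf), round(2*N*maf))."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0.0 < maf < 1.0:
        raise ValueError("maf must be in (0, 1)")
    return _round_half_up_int(n_total * maf), _round_half_up_int(2 * n_total * maf)


def replication_grade(i_squared: float | None) -> Grade:
    """A for I-squared below 25%, B for 25-50%, C above 50%; X if missing.

    Boundary values 25 and 50 are assigned to B (the published rule states
    open intervals and no observed row sits exactly on a boundary).
    """
    if i_squared is None:
        return Grade.X
    if i_squared < 25.0:
        return Grade.A
    if i_squared <= 50.0:
        return Grade.B
    return Grade.C


def bias_grade(record: AssociationRecord) -> Grade:
    """Protection-from-bias element.

    C when Egger's test indicates bias (p < 0.05) or the folded effect
    magnitude max(OR, 1/OR) is below 1.15 without prospective (GWAS)
    replication; X when no bias information exists at all; A otherwise.
    B encodes a qualitative "bias could be present" judgement and is only
    reachable through a per-record override.
    """
    if record.bias_override is not None:
        return Grade(record.bias_override)
    if record.egger_p is not None and record.egger_p < 0.05:
        return Grade.C
    note = record.egger_note
    if note is not None and note.startswith("<"):
        try:
            if float(note[1:]) <= 0.05:
                return Grade.C
        except ValueError:
            pass
    magnitude = max(record.or_point, 1.0 / record.or_point)
    if magnitude < MIN_EFFECT_MAGNITUDE and not record.gwas_replicated:
        return Grade.C
    if record.egger_p is None and note is None:
        return Grade.X
    return Grade.A


def combine_elements(amount: Grade, replication: Grade, bias: Grade) -> EvidenceLevel:
    elements = (amount, replication, bias)
    if Grade.X in elements:
        return EvidenceLevel.UNGRADED
    if all(g is Grade.A for g in elements):
        return EvidenceLevel.STRONG
    if Grade.C in elements:
        return EvidenceLevel.WEAK
    return EvidenceLevel.MODERATE


def grade(record: AssociationRecord, min_calc_count: int = MIN_CALC_COUNT) -> VeniceGrade:
    """Grade one record; deterministic and total on valid records."""
    rationale: list[str] = []

    calc_low = record.calc_low
    calc_high = record.calc_high
    if record.test_count is not None:
        amount = amount_grade(record.test_count)
        rationale.append(f"amount: observed test count {record.test_count} -> {amount.value}")
    else:
        if calc_high is None and record.n_total is not None and record.maf is not None:
            calc_low, calc_high = calc_count_range(record.n_total, record.maf)
            rationale.append(f"amount: calculated count range ({calc_low}, {calc_high}) from MAF")
        if calc_high is not None and calc_high >= min_calc_count:
            amount = amount_grade(calc_high)
            rationale.append(f"amount: calculated count {calc_high} -> {amount.value}")
        elif calc_high is not None:
            amount = Grade.X
            rationale.append(
                f"amount: calculated count {calc_high} below {min_calc_count}, not assessable"
            )
        else:
            amount = Grade.X
            rationale.append("amount: no observed or calculable count")

    replication = replication_grade(record.i_squared)
    rationale.append(
        "replication: I2 missing -> X"
        if record.i_squared is None
        else f"replication: I2 {record.i_squared}% -> {replication.value}"
    )

    bias = bias_grade(record)
    if record.bias_override is not None:
        rationale.append(f"bias: per-record override -> {bias.value}")
    else:
        rationale.append(f"bias: diagnostics and effect magnitude -> {bias.value}")

    level = combine_elements(amount, replication, bias)
    return VeniceGrade(
        amount=amount,
        replication=replication,
        bias=bias,
        level=level,
        calc_count_low=calc_low,
        calc_count_high=calc_high,
        rationale=tuple(rationale),
    )
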