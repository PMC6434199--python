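"""False-positive report probability engine.

Recovers the log-odds-ratio standard error from a reported confidence
interval, derives the two-sided observed p-value, the statistical power to
detect a target odds ratio, and combines them with a prior probability into
the false-positive report probability (FPRP).

Power convention: the critical value of the test is set at the observed
statistic itself (significance level equal to the observed p-value).  This
is the convention of the reference spreadsheet implementation and is the
only one that reproduces the published power columns; it was verified
against several published rows during calibration.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from scipy.stats import norm

from .records import AssociationRecord

__all__ = [
    "FprpConfig",
    "FprpCategory",
    "FprpResult",
    "se_from_ci",
    "observed_p",
    "power_to_detect",
    "fprp",
    "assess",
    "round_half_up",
]


def round_half_up(value: float, ndigits: int = 3) -> float:
    """Decimal round-half-up, matching the published tables' formatting."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FprpConfig:
    """Parameters of the FPRP assay."""

    prior: float = 0.001
    target_or: float = 1.5
    noteworthy_cutoff: float = 0.2
    strong_cutoff: float = 0.05
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 < self.prior < 1.0:
            raise ValueError(f"prior must be in (0, 1), got {self.prior}")
        if self.target_or <= 1.0:
            raise ValueError(f"target_or must exceed 1, got {self.target_or}")
        if not self.strong_cutoff < self.noteworthy_cutoff:
            raise ValueError("strong_cutoff must be below noteworthy_cutoff")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError(f"ci_level must be in (0, 1), got {self.ci_level}")


class FprpCategory(str, enum.Enum):
    STRONG = "strong"  # fprp < strong_cutoff
    MODERATE = "moderate"  # strong_cutoff <= fprp <= noteworthy_cutoff
    WEAK = "weak"  # fprp > noteworthy_cutoff


@dataclass(frozen=True)
class FprpResult:
    se: float
    z_obs: float
    p_obs: float
    power: float
    fprp: float
    category: FprpCategory
    noteworthy: bool


def se_from_ci(ci_low: float, ci_high: float, ci_level: float = 0.95) -> float:
    """Standard error of the log OR recovered by inverting a symmetric
    normal-theory confidence interval on the log scale."""
    if not (0.0 < ci_low and 0.0 < ci_high):
        raise ValueError("CI bounds must be positive")
    if ci_low >= ci_high:
        raise ValueError(
            f"degenerate interval ({ci_low}, {ci_high}): ci_low must be below ci_high"
        )
    if not 0.0 < ci_level < 1.0:
        raise ValueError(f"ci_level must be in (0, 1), got {ci_level}")
    z_crit = norm.ppf(0.5 * (1.0 + ci_level))
    return (math.log(ci_high) - math.log(ci_low)) / (2.0 * z_crit)


def observed_p(or_point: float, se: float) -> float:
    """Two-sided Wald p-value of the reported estimate against OR = 1.

    Uses the complementary normal tail (``norm.sf``) so extreme statistics
    (z beyond 40) do not underflow to a rounded 1 - CDF.
    """
    if or_point <= 0:
        raise ValueError("or_point must be positive")
    if se <= 0:
        raise ValueError("se must be positive")
    z_obs = abs(math.log(or_point)) / se
    return min(1.0, 2.0 * float(norm.sf(z_obs)))


def power_to_detect(or_point: float, se: float, target_or: float = 1.5) -> float:
    """Power to detect ``target_or`` when testing at significance level equal
    to the observed p-value (critical value = observed |z|).

    Protective estimates are folded to the risk scale via |log OR|, so the
    target is effectively 1/target_or for them.  Both rejection tails are
    included; the opposite tail matters for weakly powered designs.
    """
    if or_point <= 0 or se <= 0:
        raise ValueError("or_point and se must be positive")
    if target_or <= 1.0:
        raise ValueError("target_or must exceed 1")
    z_obs = abs(math.log(or_point)) / se
    z_target = math.log(target_or) / se
    return float(norm.sf(z_obs - z_target) + norm.cdf(-z_obs - z_target))


def fprp(p_obs: float, power: float, prior: float = 0.001) -> float:
    """FPRP = p(1-pi) / (p(1-pi) + power*pi)."""
    if not 0.0 <= p_obs <= 1.0:
        raise ValueError(f"p_obs={p_obs} outside [0, 1]")
    if not 0.0 <= power <= 1.0:
        raise ValueError(f"power={power} outside [0, 1]")
    if not 0.0 < prior <= 1.0:
        raise ValueError(f"prior={prior} outside (0, 1]")
    numerator = p_obs * (1.0 - prior)
    denominator = numerator + power * prior
    if denominator == 0.0:
        warnings.warn(
            "FPRP undefined: observed p and power are both zero; returning 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return numerator / denominator


def categorize(value: float, config: FprpConfig) -> FprpCategory:
    if value < config.strong_cutoff:
        return FprpCategory.STRONG
    if value <= config.noteworthy_cutoff:
        return FprpCategory.MODERATE
    return FprpCategory.WEAK


def assess(record: AssociationRecord, config: FprpConfig | None = None) -> FprpResult:
    """Full FPRP assessment of one association record from its OR and CI."""
    config = config or FprpConfig()
    se = se_from_ci(record.ci_low, record.ci_high, config.ci_level)
    p_obs = observed_p(record.or_point, se)
    z_obs = abs(math.log(record.or_point)) / se
    power = power_to_detect(record.or_point, se, config.target_or)
    value = fprp(p_obs, power, config.prior)
    return FprpResult(
        se=se,
        z_obs=z_obs,
        p_obs=p_obs,
        power=power,
        fprp=value,
        category=categorize(value, config),
        noteworthy=value < config.noteworthy_cutoff,
    )
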