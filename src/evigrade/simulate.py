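"""Synthetic case-control meta-analysis generator.

Emulates K independent case-control studies for one association: each study
draws exposed counts binomially in controls (from a stated control allele
frequency under the chosen genetic contrast) and in cases (from the control
odds shifted by a per-study true log OR, optionally perturbed by
between-study normal heterogeneity), then the studies are pooled into an
:class:`~evigrade.records.AssociationRecord` carrying the same summary
fields the grading pipeline consumes.  Identical spec + seed always yields
identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import meta
from .fprp import FprpConfig, assess
from .records import AssociationRecord, CancerType, Ethnicity, GeneticModel, Source

__all__ = [
    "SimulationSpec",
    "SimulatedStudy",
    "simulate_study",
    "simulate_studies",
    "simulate_association",
    "null_noteworthiness_rate",
]

_MODELS = ("allelic", "dominant", "recessive")


@dataclass(frozen=True)
class SimulationSpec:
    k_studies: int = 5
    n_cases_per_study: int | tuple[int, ...] = 1000
    n_controls_per_study: int | tuple[int, ...] = 1000
    control_maf: float = 0.3
    true_or: float = 1.0
    tau: float = 0.0  # between-study SD of the log OR
    model: str = "allelic"
    censor_small_nonsig: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_studies < 1:
            raise ValueError("k_studies must be at least 1")
        if not 0.0 < self.control_maf < 1.0:
            raise ValueError("control_maf must be in (0, 1)")
        if self.true_or <= 0:
            raise ValueError("true_or must be positive")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}")
        for name in ("n_cases_per_study", "n_controls_per_study"):
            value = getattr(self, name)
            sizes = (value,) if isinstance(value, int) else tuple(value)
            if any(n <= 0 for n in sizes):
                raise ValueError(f"{name} entries must be positive")
            if not isinstance(value, int) and len(sizes) != self.k_studies:
                raise ValueError(f"{name} list must have k_studies entries")

    def cases(self, index: int) -> int:
        value = self.n_cases_per_study
        return value if isinstance(value, int) else value[index]

    def controls(self, index: int) -> int:
        value = self.n_controls_per_study
        return value if isinstance(value, int) else value[index]


@dataclass(frozen=True)
class SimulatedStudy:
    a: int  # exposed cases
    b: int  # unexposed cases
    c: int  # exposed controls
    d: int  # unexposed controls
    log_or: float
    se: float

    @property
    def n_units(self) -> int:
        return self.a + self.b + self.c + self.d


def _exposure_probability(maf: float, model: str) -> float:
    """Control-group exposure probability implied by the allele frequency
    (Hardy-Weinberg for the genotype contrasts)."""
    if model == "allelic":
        return maf
    if model == "dominant":
        return 1.0 - (1.0 - maf) ** 2
    return maf * maf  # recessive


def _trials(n_subjects: int, model: str) -> int:
    # The allelic contrast counts alleles (2 per subject); genotype
    # contrasts count subjects.
    return 2 * n_subjects if model == "allelic" else n_subjects


def _table_stats(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    # 0.5 continuity correction on all cells only when any cell is zero.
    if min(a, b, c, d) == 0:
        fa, fb, fc, fd = (x + 0.5 for x in (a, b, c, d))
    else:
        fa, fb, fc, fd = float(a), float(b), float(c), float(d)
    log_or = math.log(fa * fd / (fb * fc))
    se = math.sqrt(1 / fa + 1 / fb + 1 / fc + 1 / fd)
    return log_or, se


def simulate_study(
    spec: SimulationSpec, study_index: int, rng: np.random.Generator
) -> SimulatedStudy:
    """Draw one study's 2x2 exposure table and its log OR / SE."""
    study_log_or = math.log(spec.true_or)
    if spec.tau > 0:
        study_log_or += spec.tau * rng.standard_normal()
    p_control = _exposure_probability(spec.control_maf, spec.model)
    if not 0.0 < p_control < 1.0:
        raise ValueError(f"degenerate control exposure probability {p_control}")
    odds_case = p_control / (1.0 - p_control) * math.exp(study_log_or)
    p_case = odds_case / (1.0 + odds_case)
    if not 0.0 < p_case < 1.0:
        raise ValueError(f"degenerate case exposure probability {p_case}")
    case_trials = _trials(spec.cases(study_index), spec.model)
    control_trials = _trials(spec.controls(study_index), spec.model)
    a = int(rng.binomial(case_trials, p_case))
    c = int(rng.binomial(control_trials, p_control))
    b = case_trials - a
    d = control_trials - c
    log_or, se = _table_stats(a, b, c, d)
    return SimulatedStudy(a=a, b=b, c=c, d=d, log_or=log_or, se=se)


def simulate_studies(spec: SimulationSpec) -> list[SimulatedStudy]:
    rng = np.random.default_rng(spec.seed)
    return [simulate_study(spec, i, rng) for i in range(spec.k_studies)]


def _censor(studies: list[SimulatedStudy]) -> list[SimulatedStudy]:
    """Minimal publication-bias mechanism: drop per-study non-significant
    results from studies smaller than the median size."""
    sizes = sorted(s.n_units for s in studies)
    median = sizes[len(sizes) // 2]
    kept = [
        s
        for s in studies
        if s.n_units >= median or abs(s.log_or) / s.se >= 1.959964
    ]
    if not kept:  # keep the largest study so the record stays well-defined
        kept = [max(studies, key=lambda s: s.n_units)]
    return kept


def _pooled_control_maf(studies: Sequence[SimulatedStudy], model: str) -> float | None:
    exposed = sum(s.c for s in studies)
    trials = sum(s.c + s.d for s in studies)
    if trials == 0:
        return None
    freq = exposed / trials
    if model == "dominant":
        freq = 1.0 - math.sqrt(max(0.0, 1.0 - freq))
    elif model == "recessive":
        freq = math.sqrt(freq)
    if not 0.0 < freq < 1.0:
        return None
    return freq


_RECORD_MODELS = {
    "allelic": GeneticModel.ALLELIC,
    "dominant": GeneticModel.DOMINANT,
    "recessive": GeneticModel.RECESSIVE,
}


def simulate_association(
    spec: SimulationSpec, gene: str = "SIMGENE", variant: str = "rs0"
) -> AssociationRecord:
    """Simulate K studies and assemble the pooled association record."""
    studies = simulate_studies(spec)
    if spec.censor_small_nonsig:
        studies = _censor(studies)
    summary = meta.summarize_studies(
        [s.log_or for s in studies], [s.se for s in studies]
    )
    n_cases = sum(spec.cases(i) for i in range(spec.k_studies))
    n_controls = sum(spec.controls(i) for i in range(spec.k_studies))
    return AssociationRecord(
        gene=gene,
        variant=variant,
        cancer_type=CancerType.EC,
        model=_RECORD_MODELS[spec.model],
        ethnicity=Ethnicity.UNSPECIFIED,
        or_point=math.exp(summary.pooled_log_or),
        ci_low=summary.ci_low,
        ci_high=summary.ci_high,
        egger_p=summary.egger_p,
        het_p=summary.q_p,
        i_squared=summary.i_squared,
        n_studies=summary.k,
        n_total=n_cases + n_controls,
        n_cases=n_cases,
        n_controls=n_controls,
        test_count=sum(s.a + s.c for s in studies),
        maf=_pooled_control_maf(studies, spec.model),
        source=Source.META_ANALYSIS,
    )


def null_noteworthiness_rate(
    spec: SimulationSpec,
    n_replicates: int,
    config: FprpConfig | None = None,
) -> float:
    """Fraction of null replicates (true OR = 1) judged noteworthy
    (FPRP below the cutoff); a calibration diagnostic."""
    if spec.true_or != 1.0:
        raise ValueError("null_noteworthiness_rate requires true_or = 1")
    if n_replicates < 1:
        raise ValueError("n_replicates must be positive")
    config = config or FprpConfig()
    noteworthy = 0
    for replicate in range(n_replicates):
        child = replace(spec, seed=(spec.seed * 1_000_003 + replicate) % 2**63)
        record = simulate_association(child)
        if assess(record, config).fprp < config.noteworthy_cutoff:
            noteworthy += 1
    return noteworthy / n_replicates
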