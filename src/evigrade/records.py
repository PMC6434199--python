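"""Domain types, validation, and tabular I/O for association summary records.

One :class:`AssociationRecord` corresponds to one published association
analysis (gene, variant, cancer type, genetic model, ethnicity stratum) with
its effect estimate, uncertainty, sample counts, heterogeneity and
publication-bias diagnostics.  Records are exchanged as TSV/CSV tables; two
curated fixture tables (``table1``: meta-analysis summaries, ``table2``:
GWAS summaries) ship inside the package.
"""

from __future__ import annotations

import csv
import enum
import re
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "MISSING",
    "CancerType",
    "GeneticModel",
    "Ethnicity",
    "Source",
    "AssociationRecord",
    "FixtureSet",
    "RecordError",
    "read_records",
    "write_records",
    "is_significant",
    "load_table1",
    "load_table2",
]

#: Token used for missing values in record tables (empty cells also parse
#: as missing on input).
MISSING = "Na"


class CancerType(str, enum.Enum):
    EC = "EC"
    ESCC = "ESCC"
    EADC = "EADC"


class GeneticModel(str, enum.Enum):
    ADDITIVE = "additive"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    HOMOZYGOUS = "homozygous"
    ALLELIC = "allelic"
    OTHER = "other"


class Ethnicity(str, enum.Enum):
    DIVERSE = "diverse"
    ASIAN = "Asian"
    CAUCASIAN = "Caucasian"
    UNSPECIFIED = "unspecified"


class Source(str, enum.Enum):
    META_ANALYSIS = "meta_analysis"
    GWAS = "gwas"


class RecordError(ValueError):
    """Raised for malformed cells or invariant violations, located by
    row and column where possible."""


@dataclass
class AssociationRecord:
    """One association analysis extracted from a meta-analysis or GWAS.

    Diagnostic p-values that were reported qualitatively rather than
    numerically (e.g. "No" observable bias, "<0.001", ">0.05") are kept
    verbatim in the ``*_note`` companion fields; the numeric field is then
    ``None``.
    """

    gene: str
    variant: str
    cancer_type: CancerType
    model: GeneticModel
    ethnicity: Ethnicity
    or_point: float
    ci_low: float
    ci_high: float
    year: int | None = None
    egger_p: float | None = None
    egger_note: str | None = None
    het_p: float | None = None
    het_note: str | None = None
    i_squared: float | None = None
    n_studies: int | None = None
    n_total: int | None = None
    n_cases: int | None = None
    n_controls: int | None = None
    test_count: int | None = None
    calc_low: int | None = None
    calc_high: int | None = None
    maf: float | None = None
    gwas_replicated: bool = False
    bias_override: str | None = None
    source: Source = Source.META_ANALYSIS
    #: Classification of the row as statistically significant.  Stored
    #: explicitly because two fixture rows have a printed CI bound touching
    #: 1.0 yet were classified significant (presumably the unrounded bound
    #: excluded 1.0); when ``None`` it is derived from the strict CI rule.
    significant: bool | None = None
    #: Headline analysis for its (gene, variant) group; used when tallying
    #: evidence levels once per distinct variant.
    primary: bool = False
    # Published assessment columns, kept to allow reproduction checks and
    # published-value evidence tallies decoupled from CI-rounding noise.
    pub_grade: str | None = None
    pub_level: str | None = None
    pub_power: float | None = None
    pub_fprp: float | None = None
    pub_evidence: str | None = None
    warnings: list[str] = field(default_factory=list, compare=False, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def key(self) -> tuple[str, str, str, str, str]:
        return (
            self.gene,
            self.variant,
            self.cancer_type.value,
            self.model.value,
            self.ethnicity.value,
        )

    @property
    def variant_key(self) -> tuple[str, str]:
        return (self.gene, self.variant)

    def validate(self) -> None:
        """Check invariants; hard violations raise :class:`RecordError`,
        tolerated discrepancies are appended to :attr:`warnings`."""
        if not (self.or_point > 0 and self.ci_low > 0 and self.ci_high > 0):
            raise RecordError(
                f"{self.gene} {self.variant}: OR and CI bounds must be positive"
            )
        if not (self.ci_low <= self.or_point <= self.ci_high):
            raise RecordError(
                f"{self.gene} {self.variant}: CI ({self.ci_low}, {self.ci_high}) "
                f"does not bracket OR {self.or_point}"
            )
        for name in ("egger_p", "het_p"):
            value = getattr(self, name)
            if value is not None and not 0.0 <= value <= 1.0:
                raise RecordError(f"{self.gene} {self.variant}: {name}={value} outside [0, 1]")
        if self.i_squared is not None and not 0.0 <= self.i_squared <= 100.0:
            raise RecordError(
                f"{self.gene} {self.variant}: i_squared={self.i_squared} outside [0, 100]"
            )
        if self.maf is not None and not 0.0 < self.maf < 1.0:
            raise RecordError(f"{self.gene} {self.variant}: maf={self.maf} outside (0, 1)")
        for name in ("n_studies",):
            value = getattr(self, name)
            if value is not None and value < 1:
                raise RecordError(f"{self.gene} {self.variant}: {name} must be positive")
        for name in ("n_total", "n_cases", "n_controls", "test_count"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise RecordError(f"{self.gene} {self.variant}: {name} must be non-negative")
        if self.bias_override is not None and self.bias_override not in ("A", "B", "C"):
            raise RecordError(
                f"{self.gene} {self.variant}: bias_override must be A, B or C"
            )
        if (
            self.n_total is not None
            and self.n_cases is not None
            and self.n_controls is not None
            and self.n_cases + self.n_controls != self.n_total
        ):
            # A handful of source rows print inconsistent totals; keep them
            # verbatim and record the discrepancy instead of failing.
            self.warnings.append(
                f"n_cases + n_controls = {self.n_cases + self.n_controls} "
                f"differs from n_total = {self.n_total}"
            )
        if self.significant is None:
            self.significant = is_significant(self)


def is_significant(record: AssociationRecord) -> bool:
    """Strict CI-exclusion rule: significant iff 1.0 lies outside
    [ci_low, ci_high].

    Advisory only: the stored :attr:`AssociationRecord.significant` flag
    takes precedence for rows whose printed bound touches 1.0.
    """
    return record.ci_low > 1.0 or record.ci_high < 1.0


@dataclass
class FixtureSet:
    """An ordered record collection with a label, e.g. a packaged table."""

    records: list[AssociationRecord]
    label: str

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def significant_variants(self) -> set[tuple[str, str]]:
        return {r.variant_key for r in self.records if r.significant}


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

COLUMNS = [
    "gene",
    "variant",
    "cancer_type",
    "year",
    "model",
    "ethnicity",
    "or_point",
    "ci_low",
    "ci_high",
    "egger_p",
    "het_p",
    "i_squared",
    "n_studies",
    "n_total",
    "n_cases",
    "n_controls",
    "test_count",
    "calc_low",
    "calc_high",
    "maf",
    "gwas_replicated",
    "bias_override",
    "source",
    "significant",
    "primary",
    "pub_grade",
    "pub_level",
    "pub_power",
    "pub_fprp",
    "pub_evidence",
]

REQUIRED_COLUMNS = ["gene", "variant", "cancer_type", "model", "ethnicity"]

_DASHES = "‐‑‒–—"
_OR_CI_RE = re.compile(
    r"^\s*([0-9. ]+)\s*\(\s*([0-9. ]+)\s*[-%s]\s*([0-9. ]+)\s*\)\s*$" % _DASHES
)


def _is_missing(token: str | None) -> bool:
    return token is None or token.strip() == "" or token.strip() == MISSING


def _clean_number(token: str) -> str:
    # The source tables typeset thousands with internal spaces ("22 935")
    # and percentages with a trailing "%".
    return token.replace(" ", "").replace(" ", "").rstrip("%")


def _parse_float(token: str) -> float:
    return float(_clean_number(token))


def _parse_int(token: str) -> int:
    cleaned = _clean_number(token)
    value = float(cleaned)
    if value != int(value):
        raise ValueError(f"expected integer, got {token!r}")
    return int(value)


def _parse_bool(token: str) -> bool:
    lowered = token.strip().lower()
    if lowered in ("true", "1", "yes"):
        return True
    if lowered in ("false", "0", "no"):
        return False
    raise ValueError(f"expected boolean, got {token!r}")


def _parse_p_cell(token: str) -> tuple[float | None, str | None]:
    """Parse a diagnostic p-value cell into (numeric value, verbatim note)."""
    stripped = token.strip()
    try:
        return _parse_float(stripped), None
    except ValueError:
        return None, stripped


def _split_or_ci(token: str) -> tuple[float, float, float]:
    match = _OR_CI_RE.match(token)
    if match is None:
        raise ValueError(f"cannot parse OR/CI string {token!r}")
    point, low, high = (float(_clean_number(g)) for g in match.groups())
    return point, low, high


def _row_to_record(row: dict[str, str], row_number: int) -> AssociationRecord:
    def cell(name: str) -> str | None:
        value = row.get(name)
        return None if _is_missing(value) else value.strip()

    def parse(name: str, parser):
        value = cell(name)
        if value is None:
            return None
        try:
            return parser(value)
        except ValueError as exc:
            raise RecordError(f"row {row_number}, column {name!r}: {exc}") from exc

    for name in REQUIRED_COLUMNS:
        if cell(name) is None:
            raise RecordError(f"row {row_number}: missing required column {name!r}")

    or_ci = cell("or_ci")
    if or_ci is not None:
        try:
            or_point, ci_low, ci_high = _split_or_ci(or_ci)
        except ValueError as exc:
            raise RecordError(f"row {row_number}, column 'or_ci': {exc}") from exc
    else:
        or_point = parse("or_point", _parse_float)
        ci_low = parse("ci_low", _parse_float)
        ci_high = parse("ci_high", _parse_float)
        if or_point is None or ci_low is None or ci_high is None:
            raise RecordError(
                f"row {row_number}: OR and CI bounds are required "
                "(or_point/ci_low/ci_high or a combined or_ci column)"
            )
    if ci_low > ci_high:
        raise RecordError(
            f"row {row_number}: ci_low {ci_low} exceeds ci_high {ci_high}"
        )

    egger_p, egger_note = (None, None)
    if cell("egger_p") is not None:
        egger_p, egger_note = _parse_p_cell(cell("egger_p"))
        if egger_p is not None and not 0 <= egger_p <= 1:
            raise RecordError(f"row {row_number}, column 'egger_p': {egger_p} outside [0, 1]")
    het_p, het_note = (None, None)
    if cell("het_p") is not None:
        het_p, het_note = _parse_p_cell(cell("het_p"))
        if het_p is not None and not 0 <= het_p <= 1:
            raise RecordError(f"row {row_number}, column 'het_p': {het_p} outside [0, 1]")

    try:
        record = AssociationRecord(
            gene=cell("gene"),
            variant=cell("variant"),
            cancer_type=CancerType(cell("cancer_type")),
            model=GeneticModel(cell("model")),
            ethnicity=Ethnicity(cell("ethnicity")),
            or_point=or_point,
            ci_low=ci_low,
            ci_high=ci_high,
            year=parse("year", _parse_int),
            egger_p=egger_p,
            egger_note=egger_note,
            het_p=het_p,
            het_note=het_note,
            i_squared=parse("i_squared", _parse_float),
            n_studies=parse("n_studies", _parse_int),
            n_total=parse("n_total", _parse_int),
            n_cases=parse("n_cases", _parse_int),
            n_controls=parse("n_controls", _parse_int),
            test_count=parse("test_count", _parse_int),
            calc_low=parse("calc_low", _parse_int),
            calc_high=parse("calc_high", _parse_int),
            maf=parse("maf", _parse_float),
            gwas_replicated=parse("gwas_replicated", _parse_bool) or False,
            bias_override=cell("bias_override"),
            source=Source(cell("source")) if cell("source") else Source.META_ANALYSIS,
            significant=parse("significant", _parse_bool),
            primary=parse("primary", _parse_bool) or False,
            pub_grade=cell("pub_grade"),
            pub_level=cell("pub_level"),
            pub_power=parse("pub_power", _parse_float),
            pub_fprp=parse("pub_fprp", _parse_float),
            pub_evidence=cell("pub_evidence"),
        )
    except RecordError:
        raise
    except ValueError as exc:
        raise RecordError(f"row {row_number}: {exc}") from exc
    return record


_DELIMITERS = {"tsv": "\t", "csv": ","}


def read_records(path: str | Path, dialect: str = "tsv") -> list[AssociationRecord]:
    """Read association records from a delimited table, preserving row order.

    Missing values may be encoded as ``"Na"`` or an empty cell.  A combined
    ``or_ci`` column of the form ``"1.49 (1.33-1.66)"`` is accepted in place
    of separate ``or_point``/``ci_low``/``ci_high`` columns.
    """
    if dialect not in _DELIMITERS:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'")
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter=_DELIMITERS[dialect])
        if reader.fieldnames is None:
            raise RecordError(f"{path}: empty file, expected a header row")
        header = set(reader.fieldnames)
        missing = [name for name in REQUIRED_COLUMNS if name not in header]
        if missing:
            raise RecordError(f"{path}: header lacks required columns {missing}")
        if "or_ci" not in header and not {"or_point", "ci_low", "ci_high"} <= header:
            raise RecordError(
                f"{path}: header needs 'or_ci' or 'or_point'/'ci_low'/'ci_high' columns"
            )
        records = []
        for i, row in enumerate(reader, start=2):  # header is line 1
            records.append(_row_to_record(row, i))
    return records


def _format_cell(value) -> str:
    if value is None:
        return MISSING
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, enum.Enum):
        return value.value
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_records(
    records: Iterable[AssociationRecord], path: str | Path, dialect: str = "tsv"
) -> None:
    """Write records to a delimited table; inverse of :func:`read_records`."""
    if dialect not in _DELIMITERS:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'")
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter=_DELIMITERS[dialect], lineterminator="\n")
        writer.writerow(COLUMNS)
        for record in records:
            # egger/het notes fold back into their p-value columns so that a
            # round trip reproduces the original cells.
            row = []
            for name in COLUMNS:
                if name == "egger_p":
                    value = record.egger_note if record.egger_note is not None else record.egger_p
                elif name == "het_p":
                    value = record.het_note if record.het_note is not None else record.het_p
                else:
                    value = getattr(record, name)
                row.append(_format_cell(value))
            writer.writerow(row)


def _load_fixture(name: str) -> FixtureSet:
    with resources.as_file(resources.files("evigrade.data").joinpath(name)) as path:
        return FixtureSet(records=read_records(path, dialect="tsv"), label=name.removesuffix(".tsv"))


def load_table1() -> FixtureSet:
    """Curated meta-analysis summary fixture (38 distinct significant variants)."""
    return _load_fixture("table1.tsv")


def load_table2() -> FixtureSet:
    """Curated GWAS summary fixture (17 records)."""
    return _load_fixture("table2.tsv")
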