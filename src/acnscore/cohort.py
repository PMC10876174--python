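"""Case and cohort data model for pediatric adrenocortical neoplasms (ACNs).

A :class:`CaseRecord` holds one tumor's histopathology (mitotic counts with
their HPF denominators, necrosis, invasion features, Ki67, reticulin
framework status), clinical fields (age, sex, COG stage) and outcome
(CR / AWD / DOD with follow-up months).  Cohorts round-trip losslessly
through plain CSV; the empty string encodes a missing value everywhere.

Mitotic counts are kept per reported denominator (50 HPF for the adult
Weiss convention, 20 HPF for the pediatric Wieneke convention).  Comparing
a count against a cutoff expressed over a different denominator raises
unless rescaling is explicitly requested: HPF area and counting protocol
differ between conventions, so a silent linear rescale would be wrong.
"""

from __future__ import annotations

import csv
import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Optional


class Sex(enum.Enum):
    M = "M"
    F = "F"


class Laterality(enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    UNKNOWN = "unknown"


class Stage(enum.Enum):
    """Children's Oncology Group stage."""

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    UNKNOWN = "unknown"


class Outcome(enum.Enum):
    CR = "CR"    # complete remission
    AWD = "AWD"  # alive with disease
    DOD = "DOD"  # died of disease
    UNKNOWN = "unknown"


class ReticulinCategory(enum.Enum):
    """State of the silver-stained reticulin fiber framework.

    ``QUANTITATIVE`` = loss of fibers over extensive areas;
    ``QUALITATIVE`` = frayed fibers of irregular thickness with the overall
    framework apparently preserved; ``BOTH`` = the two coexist.
    """

    INTACT = "intact"
    QUANTITATIVE = "quantitative"
    QUALITATIVE = "qualitative"
    BOTH = "both"


@dataclass(frozen=True)
class ReticulinStatus:
    category: ReticulinCategory

    @property
    def altered(self) -> bool:
        """True for any framework disruption (anything but INTACT)."""
        return self.category is not ReticulinCategory.INTACT


class DenominatorMismatchError(ValueError):
    """A mitotic count was compared against a cutoff over a different HPF
    denominator without explicit permission to rescale."""


@dataclass(frozen=True)
class MitoticCount:
    """Mitotic figures counted over a fixed number of high-power fields."""

    count: int
    denominator_hpf: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"negative mitotic count: {self.count}")
        if self.denominator_hpf <= 0:
            raise ValueError(f"non-positive HPF denominator: {self.denominator_hpf}")

    def exceeds(self, cutoff_count: float, cutoff_denominator_hpf: int,
                allow_rescale: bool = False) -> bool:
        """Strict comparison ``count > cutoff`` over a matching denominator.

        With ``allow_rescale`` the count is rescaled linearly to the cutoff's
        denominator (a warning is emitted); otherwise a mismatch raises.
        """
        if self.denominator_hpf == cutoff_denominator_hpf:
            return self.count > cutoff_count
        if not allow_rescale:
            raise DenominatorMismatchError(
                f"count per {self.denominator_hpf} HPF compared against a "
                f"cutoff per {cutoff_denominator_hpf} HPF"
            )
        warnings.warn(
            f"rescaling mitotic count from /{self.denominator_hpf} HPF to "
            f"/{cutoff_denominator_hpf} HPF assumes equal field area",
            stacklevel=2,
        )
        rescaled = self.count * cutoff_denominator_hpf / self.denominator_hpf
        return rescaled > cutoff_count


# Optional[bool] plays the role of a tristate: True / False / missing.
Tristate = Optional[bool]


@dataclass
class CaseRecord:
    """One tumor's pathological, clinical and outcome fields.

    Any field other than ``case_id`` may be missing (``None``); analyses
    exclude a case from a given score when a required field is missing.
    """

    case_id: str
    age_months: Optional[float] = None
    sex: Optional[Sex] = None
    laterality: Laterality = Laterality.UNKNOWN
    stage: Stage = Stage.UNKNOWN
    weight_g: Optional[float] = None
    size_cm: Optional[float] = None
    mitoses_per_50hpf: Optional[MitoticCount] = None
    mitoses_per_20hpf: Optional[MitoticCount] = None
    atypical_mitoses: Tristate = None
    necrosis: Tristate = None
    vascular_invasion: Tristate = None
    capsular_invasion: Tristate = None
    extra_adrenal_extension: Tristate = None
    vena_cava_invasion: Tristate = None
    ki67_percent: Optional[float] = None
    reticulin: Optional[ReticulinStatus] = None
    outcome: Outcome = Outcome.UNKNOWN
    followup_months: Optional[float] = None


@dataclass(frozen=True)
class Finding:
    """One validation finding: the offending field and the violated rule."""

    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}: {self.message}"


def validate_case(case: CaseRecord) -> list[Finding]:
    """Check a record against the model invariants.

    Returns an empty list iff the record is valid.  Validation is total:
    it never raises on a syntactically well-formed record.
    """
    findings: list[Finding] = []
    if not case.case_id:
        findings.append(Finding("case_id", "must be a non-empty string"))
    if case.age_months is not None and case.age_months < 0:
        findings.append(Finding("age_months", "must be non-negative"))
    for name in ("weight_g", "size_cm"):
        value = getattr(case, name)
        if value is not None and value <= 0:
            findings.append(Finding(name, "must be positive when present"))
    if case.ki67_percent is not None and not (0 <= case.ki67_percent <= 100):
        findings.append(Finding("ki67_percent", "must lie in [0, 100]"))
    if case.outcome is not Outcome.UNKNOWN and case.followup_months is None:
        findings.append(
            Finding("followup_months", "required when outcome is known")
        )
    if case.followup_months is not None and case.followup_months < 0:
        findings.append(Finding("followup_months", "must be non-negative"))
    for name, expected_denom in (("mitoses_per_50hpf", 50), ("mitoses_per_20hpf", 20)):
        mc = getattr(case, name)
        if mc is not None and mc.denominator_hpf != expected_denom:
            findings.append(
                Finding(name, f"denominator must be {expected_denom} HPF")
            )
    return findings


@dataclass
class Cohort:
    """An ordered collection of cases with unique ids."""

    cases: list[CaseRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for case in self.cases:
            if case.case_id in seen:
                raise ValueError(f"duplicate case_id: {case.case_id!r}")
            seen.add(case.case_id)

    def __len__(self) -> int:
        return len(self.cases)

    def __iter__(self) -> Iterator[CaseRecord]:
        return iter(self.cases)

    def validate(self) -> dict[str, list[Finding]]:
        """Per-case findings, keyed by case_id (valid cases omitted)."""
        out = {}
        for case in self.cases:
            findings = validate_case(case)
            if findings:
                out[case.case_id] = findings
        return out


# ---------------------------------------------------------------------------
# CSV serialization
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "case_id", "age_months", "sex", "laterality", "stage", "weight_g",
    "size_cm", "mitoses_50hpf", "mitoses_20hpf", "atypical_mitoses",
    "necrosis", "vascular_invasion", "capsular_invasion",
    "extra_adrenal_extension", "vena_cava_invasion", "ki67_percent",
    "reticulin", "outcome", "followup_months",
]


class SchemaError(ValueError):
    """A mandatory column could not be resolved in the input file."""


def read_schema_config(path: str | Path) -> dict[str, str]:
    """Read a ``canonical_name = user_column`` mapping (one pair per line,
    ``#`` comments and blank lines ignored)."""
    mapping: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise SchemaError(f"malformed schema line: {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in CSV_COLUMNS:
            raise SchemaError(f"unknown canonical field: {key!r}")
        mapping[key] = value
    return mapping


def _fmt_number(x: Optional[float]) -> str:
    if x is None:
        return ""
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def _fmt_bool(x: Tristate) -> str:
    return "" if x is None else ("true" if x else "false")


def _case_to_row(case: CaseRecord) -> dict[str, str]:
    return {
        "case_id": case.case_id,
        "age_months": _fmt_number(case.age_months),
        "sex": "" if case.sex is None else case.sex.value,
        "laterality": "" if case.laterality is Laterality.UNKNOWN else case.laterality.value,
        "stage": "" if case.stage is Stage.UNKNOWN else case.stage.value,
        "weight_g": _fmt_number(case.weight_g),
        "size_cm": _fmt_number(case.size_cm),
        "mitoses_50hpf": "" if case.mitoses_per_50hpf is None else str(case.mitoses_per_50hpf.count),
        "mitoses_20hpf": "" if case.mitoses_per_20hpf is None else str(case.mitoses_per_20hpf.count),
        "atypical_mitoses": _fmt_bool(case.atypical_mitoses),
        "necrosis": _fmt_bool(case.necrosis),
        "vascular_invasion": _fmt_bool(case.vascular_invasion),
        "capsular_invasion": _fmt_bool(case.capsular_invasion),
        "extra_adrenal_extension": _fmt_bool(case.extra_adrenal_extension),
        "vena_cava_invasion": _fmt_bool(case.vena_cava_invasion),
        "ki67_percent": _fmt_number(case.ki67_percent),
        "reticulin": "" if case.reticulin is None else case.reticulin.category.value,
        "outcome": "" if case.outcome is Outcome.UNKNOWN else case.outcome.value,
        "followup_months": _fmt_number(case.followup_months),
    }


def _parse_float(cell: str) -> Optional[float]:
    try:
        return float(cell)
    except ValueError:
        return None


def _parse_count(cell: str, denominator: int) -> Optional[MitoticCount]:
    try:
        n = int(float(cell))
        if n < 0:
            return None
        return MitoticCount(n, denominator)
    except ValueError:
        return None


def _parse_bool(cell: str) -> Tristate:
    low = cell.strip().lower()
    if low in ("true", "1", "yes", "y"):
        return True
    if low in ("false", "0", "no", "n"):
        return False
    return None


def _parse_enum(cell: str, enum_cls, default):
    low = cell.strip()
    for member in enum_cls:
        if low.lower() == member.value.lower() or low.upper() == member.name:
            return member
    return default


def _row_to_case(row: Mapping[str, str]) -> CaseRecord:
    def get(col: str) -> str:
        return (row.get(col) or "").strip()

    reticulin_cell = get("reticulin")
    reticulin_cat = _parse_enum(reticulin_cell, ReticulinCategory, None)
    return CaseRecord(
        case_id=get("case_id"),
        age_months=_parse_float(get("age_months")),
        sex=_parse_enum(get("sex"), Sex, None),
        laterality=_parse_enum(get("laterality"), Laterality, Laterality.UNKNOWN),
        stage=_parse_enum(get("stage"), Stage, Stage.UNKNOWN),
        weight_g=_parse_float(get("weight_g")),
        size_cm=_parse_float(get("size_cm")),
        mitoses_per_50hpf=_parse_count(get("mitoses_50hpf"), 50),
        mitoses_per_20hpf=_parse_count(get("mitoses_20hpf"), 20),
        atypical_mitoses=_parse_bool(get("atypical_mitoses")),
        necrosis=_parse_bool(get("necrosis")),
        vascular_invasion=_parse_bool(get("vascular_invasion")),
        capsular_invasion=_parse_bool(get("capsular_invasion")),
        extra_adrenal_extension=_parse_bool(get("extra_adrenal_extension")),
        vena_cava_invasion=_parse_bool(get("vena_cava_invasion")),
        ki67_percent=_parse_float(get("ki67_percent")),
        reticulin=None if reticulin_cat is None else ReticulinStatus(reticulin_cat),
        outcome=_parse_enum(get("outcome"), Outcome, Outcome.UNKNOWN),
        followup_months=_parse_float(get("followup_months")),
    )


def read_cohort(path: str | Path,
                schema_config: Optional[Mapping[str, str]] = None,
                provenance: Optional[str] = None) -> Cohort:
    """Read a cohort from CSV.

    ``schema_config`` maps canonical field names to the file's column names
    (identity by default).  Unparseable cells in optional fields become
    missing; a missing ``case_id`` column is a :class:`SchemaError`;
    duplicate ids raise ``ValueError`` naming the id.
    """
    path = Path(path)
    schema = dict(schema_config or {})
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header row required")
        header = set(reader.fieldnames)
        id_col = schema.get("case_id", "case_id")
        if id_col not in header:
            raise SchemaError(f"{path}: mandatory column {id_col!r} not found")
        cases = []
        for row in reader:
            canonical = {
                canon: row.get(schema.get(canon, canon), "")
                for canon in CSV_COLUMNS
            }
            cases.append(_row_to_case(canonical))
    return Cohort(cases=cases, provenance=provenance or str(path))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to CSV with the canonical column set.

    ``read_cohort(write_cohort(c))`` reproduces ``c`` field-for-field,
    including missingness.
    """
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.DictWriter(handle, fieldnames=CSV_COLUMNS)
        writer.writeheader()
        for case in cohort:
            writer.writerow(_case_to_row(case))


def cohort_to_frame(cohort: Cohort):
    """Cohort as a pandas DataFrame of the canonical CSV columns (strings,
    missing = empty string) plus parsed convenience columns used by the
    analysis drivers."""
    import pandas as pd

    rows = [_case_to_row(case) for case in cohort]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)
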