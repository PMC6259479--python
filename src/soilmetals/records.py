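"""Domain records for soil/plant concentration surveys, CSV I/O and validation.

The canonical layout is long ("tidy"): one row per measured value, keyed by
site, plot class (test vs control), medium (soil or plant tissue), tissue,
parameter and replicate.  A single schema therefore serves both the soil
samples and the four Carica papaya tissues of a biomonitoring campaign.

Units are fixed by parameter and never stored per row: pH is unitless,
electrical conductivity (EC) is in uS/cm, and metal concentrations are in
mg/kg dry weight.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

PLOT_CLASSES = ("test", "control")
MEDIA = ("soil", "tissue")
TISSUES = ("root", "leaf", "fruit", "stem", "none")
PLANT_TISSUES = ("root", "leaf", "fruit", "stem")
METALS = ("Pb", "Hg", "Cd", "Cu", "Zn")
PARAMETERS = ("pH", "EC") + METALS

#: Measurement unit per parameter (metals are mg/kg on a dry-weight basis).
UNITS: Mapping[str, str] = {"pH": "", "EC": "uS/cm", **{m: "mg/kg dw" for m in METALS}}

#: Default CSV header -> field-name map; override to read files with other headers.
DEFAULT_DIALECT: Mapping[str, str] = {
    "site_id": "site_id",
    "plot_class": "plot_class",
    "medium": "medium",
    "tissue": "tissue",
    "parameter": "parameter",
    "replicate": "replicate",
    "value": "value",
}

RECORD_FIELDS = tuple(DEFAULT_DIALECT)


class FormatError(ValueError):
    """A table could not be parsed (missing column, unreadable cell)."""


class ValidationError(ValueError):
    """Parsed data violates a domain rule (carries the offending report)."""

    def __init__(self, report: "ValidationReport"):
        self.report = report
        lines = [f"{f.rule}: {f.message}" for f in report.errors]
        super().__init__("validation failed:\n  " + "\n  ".join(lines))


@dataclass(frozen=True)
class ConcentrationRecord:
    """One measured value for a (site, plot class, medium, tissue, parameter, replicate).

    Construction checks only structural validity (known categories, positive
    replicate index); value-level rules such as non-negative concentrations or
    the soil/tissue consistency constraint are checked by
    :func:`validate_records`, so that questionable rows can be loaded, flagged
    and inspected instead of silently disappearing.
    """

    site_id: str
    plot_class: str
    medium: str
    tissue: str
    parameter: str
    replicate: int
    value: float

    def __post_init__(self) -> None:
        if not self.site_id:
            raise ValueError("site_id must be a non-empty string")
        if self.plot_class not in PLOT_CLASSES:
            raise ValueError(f"plot_class {self.plot_class!r} not in {PLOT_CLASSES}")
        if self.medium not in MEDIA:
            raise ValueError(f"medium {self.medium!r} not in {MEDIA}")
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue {self.tissue!r} not in {TISSUES}")
        if self.parameter not in PARAMETERS:
            raise ValueError(f"parameter {self.parameter!r} not in {PARAMETERS}")
        if int(self.replicate) < 1:
            raise ValueError("replicate must be a positive integer")

    @property
    def unit(self) -> str:
        return UNITS[self.parameter]

    def key(self) -> tuple:
        """Identity key; duplicates of it are flagged by validation."""
        return (self.site_id, self.medium, self.tissue, self.parameter, self.replicate)


@dataclass(frozen=True)
class RegulatoryLimit:
    """A permissible level set by an authority for one parameter in one medium.

    ``limit_low == limit_high`` for single-valued limits; ranges (e.g. the
    WHO mercury limit for plants, 0.05-0.5 mg/kg) keep both ends.
    """

    authority: str
    medium: str
    parameter: str
    limit_low: float
    limit_high: float

    def __post_init__(self) -> None:
        if self.medium not in MEDIA:
            raise ValueError(f"medium {self.medium!r} not in {MEDIA}")
        if self.parameter not in METALS:
            raise ValueError(f"parameter {self.parameter!r} is not a metal")
        if not (0 < self.limit_low <= self.limit_high):
            raise ValueError(
                f"{self.authority} {self.parameter}: limits must satisfy "
                f"0 < low <= high, got ({self.limit_low}, {self.limit_high})"
            )


@dataclass(frozen=True)
class Finding:
    ref: str  # human-readable reference to the offending record/summary
    rule: str
    severity: str  # "warning" | "error"
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    @property
    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]

    @property
    def warnings(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "warning"]

    def add(self, ref: str, rule: str, severity: str, message: str) -> None:
        self.findings.append(Finding(ref, rule, severity, message))

    def raise_on_error(self) -> None:
        if self.errors:
            raise ValidationError(self)


def _parse_row(row: Mapping[str, str], lineno: int) -> ConcentrationRecord:
    try:
        return ConcentrationRecord(
            site_id=row["site_id"].strip(),
            plot_class=row["plot_class"].strip(),
            medium=row["medium"].strip(),
            tissue=row["tissue"].strip(),
            parameter=row["parameter"].strip(),
            replicate=int(row["replicate"]),
            value=float(row["value"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"line {lineno}: cannot parse row ({exc})") from exc


def read_concentration_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    *,
    strict: bool = True,
) -> list[ConcentrationRecord]:
    """Read a long-format concentration CSV into records.

    Parameters
    ----------
    path
        CSV file with a header row.
    dialect
        Map from canonical field name to the column name used in the file;
        defaults to the canonical header itself.
    strict
        When true (default), run :func:`validate_records` on the result and
        raise :class:`ValidationError` if any error-severity finding is
        present (warnings pass).

    Row order is preserved.
    """
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, header expected")
        missing = [col for col in dialect.values() if col not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
        records = []
        for lineno, raw in enumerate(reader, start=2):
            row = {fieldname: raw[col] for fieldname, col in dialect.items()}
            records.append(_parse_row(row, lineno))
    if strict:
        validate_records(records).raise_on_error()
    return records


def write_concentration_table(records: Iterable[ConcentrationRecord], path: str | Path) -> None:
    """Write records to the canonical long-format CSV (round-trips exactly)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(RECORD_FIELDS)
        for r in records:
            writer.writerow(
                [r.site_id, r.plot_class, r.medium, r.tissue, r.parameter,
                 r.replicate, repr(r.value)]
            )


def read_limits(path: str | Path) -> list[RegulatoryLimit]:
    """Read a regulatory-limits CSV (authority, medium, parameter, low, high).

    A blank ``low`` or ``high`` duplicates the other end (single-valued
    limit); reversed ranges are normalized so ``limit_low <= limit_high``.
    Non-positive limits raise.
    """
    path = Path(path)
    limits = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"authority", "medium", "parameter", "low", "high"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise FormatError(f"{path}: limits CSV requires columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            low_s, high_s = row["low"].strip(), row["high"].strip()
            if not low_s and not high_s:
                raise FormatError(f"{path} line {lineno}: no limit value given")
            low = float(low_s) if low_s else float(high_s)
            high = float(high_s) if high_s else low
            low, high = min(low, high), max(low, high)
            try:
                limits.append(
                    RegulatoryLimit(
                        authority=row["authority"].strip(),
                        medium=row["medium"].strip(),
                        parameter=row["parameter"].strip(),
                        limit_low=low,
                        limit_high=high,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path} line {lineno}: {exc}") from exc
    return limits


def validate_records(
    records: Sequence[ConcentrationRecord],
    summaries: Sequence = (),
) -> ValidationReport:
    """Check domain rules and return a report of findings (never raises).

    Rules: negative concentrations (error), pH outside [0, 14] (error),
    tissue/medium inconsistency (error), duplicated record keys (error),
    and summary rows whose minimum exceeds their maximum (warning -- such
    rows are typically transcription typos that should be flagged, never
    silently repaired).

    The report is a pure function of the input multiset: idempotent and
    order-independent up to finding order.
    """
    report = ValidationReport()
    for r in records:
        ref = f"record {r.key()}"
        if r.parameter == "pH":
            if not (0.0 <= r.value <= 14.0):
                report.add(ref, "ph-range", "error", f"pH {r.value} outside [0, 14]")
        elif r.value < 0:
            report.add(ref, "negative-concentration", "error",
                       f"negative concentration {r.value} for {r.parameter}")
        if r.medium == "soil" and r.tissue != "none":
            report.add(ref, "tissue-medium-mismatch", "error",
                       "tissue set for soil record")
        if r.medium == "tissue" and r.tissue == "none":
            report.add(ref, "tissue-medium-mismatch", "error",
                       "tissue missing for plant record")
    counts = Counter(r.key() for r in records)
    for key, n in sorted(counts.items(), key=repr):
        if n > 1:
            report.add(f"record {key}", "duplicate-key", "error",
                       f"{n} records share key {key}")
    for s in summaries:
        smin = getattr(s, "min", None)
        smax = getattr(s, "max", None)
        if smin is not None and smax is not None and smin > smax:
            report.add(f"summary {s.group_key()}", "inverted-range", "warning",
                       f"min {smin} exceeds max {smax}")
    return report
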