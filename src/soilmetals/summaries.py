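"""Grouped descriptive summaries (n, mean, SD, min, max) of concentration records.

Two entry points feed the downstream indices: :func:`summarize` computes
summaries from raw records, and :func:`load_summary_table` loads tables that
are already aggregated -- the form in which published surveys usually report
their data (``mean +/- SD`` with ranges, replicate values unpublished).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import ConcentrationRecord, FormatError, RECORD_FIELDS

#: Default grouping: pool all sites, split by plot class, medium, tissue, parameter.
DEFAULT_GROUPING = ("plot_class", "medium", "tissue", "parameter")

SUMMARY_COLUMNS = ("site_scope", "plot_class", "medium", "tissue", "parameter",
                   "n", "mean", "sd", "min", "max")


@dataclass(frozen=True)
class GroupSummary:
    """Descriptive statistics for one group of measurements.

    ``site_scope`` is a site label when grouping by site, else ``"all"``.
    ``sd`` is the sample standard deviation (n-1 denominator) and is ``None``
    when undefined (n = 1) or not reported.  ``provenance`` records whether
    the numbers were computed here or loaded pre-aggregated.
    """

    site_scope: str
    plot_class: str
    medium: str
    tissue: str
    parameter: str
    n: int
    mean: float
    sd: float | None
    min: float
    max: float
    provenance: str = "computed"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be non-negative")

    def group_key(self) -> tuple:
        return (self.site_scope, self.plot_class, self.medium, self.tissue, self.parameter)

    def format_mean_sd(self) -> str:
        """Render ``mean+/-SD`` at report precision (1 dp for values >= 10,
        2 dp below); internal values keep full precision."""
        dp = 1 if abs(self.mean) >= 10 else 2
        if self.sd is None:
            return f"{self.mean:.{dp}f}"
        return f"{self.mean:.{dp}f}±{self.sd:.{dp}f}"


def records_to_frame(records: Iterable[ConcentrationRecord]) -> pd.DataFrame:
    """Long-format DataFrame view of a record list (one row per record)."""
    return pd.DataFrame([{f: getattr(r, f) for f in RECORD_FIELDS} for r in records])


def summarize(
    records: Sequence[ConcentrationRecord],
    by: Sequence[str] = DEFAULT_GROUPING,
) -> list[GroupSummary]:
    """Group records and compute n, mean, sample SD, min and max per group.

    ``by`` may contain any of ``site_id``, ``plot_class``, ``medium``,
    ``tissue``, ``parameter``.  Groups of a single value report ``sd=None``.
    """
    if not records:
        raise ValueError("no records")
    bad = [k for k in by if k not in RECORD_FIELDS or k in ("value", "replicate")]
    if bad:
        raise ValueError(f"cannot group by {bad}")
    frame = records_to_frame(records)
    out = []
    for key, grp in frame.groupby(list(by), sort=False):
        key = key if isinstance(key, tuple) else (key,)
        named = dict(zip(by, key))
        vals = grp["value"].to_numpy(dtype=float)
        n = vals.size
        out.append(
            GroupSummary(
                site_scope=str(named.get("site_id", "all")),
                plot_class=str(named.get("plot_class", "all")),
                medium=str(named.get("medium", "all")),
                tissue=str(named.get("tissue", "all")),
                parameter=str(named.get("parameter", "all")),
                n=int(n),
                mean=float(vals.mean()),
                sd=float(vals.std(ddof=1)) if n > 1 else None,
                min=float(vals.min()),
                max=float(vals.max()),
            )
        )
    return out


def load_summary_table(path: str | Path) -> list[GroupSummary]:
    """Load a pre-aggregated summary CSV.

    Expected columns: ``site_scope, plot_class, medium, tissue, parameter,
    n, mean, sd, min, max``; ``sd`` may be blank.  Rows are loaded verbatim
    (an inverted min/max range is a finding for ``validate_records``, not a
    load failure) and marked ``provenance="pre-aggregated"``.
    """
    frame = pd.read_csv(path)
    missing = [c for c in SUMMARY_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    out = []
    for row in frame.itertuples(index=False):
        sd = getattr(row, "sd")
        out.append(
            GroupSummary(
                site_scope=str(row.site_scope),
                plot_class=str(row.plot_class),
                medium=str(row.medium),
                tissue=str(row.tissue),
                parameter=str(row.parameter),
                n=int(row.n),
                mean=float(row.mean),
                sd=None if pd.isna(sd) else float(sd),
                min=float(row.min),
                max=float(row.max),
                provenance="pre-aggregated",
            )
        )
    return out


def summaries_to_frame(summaries: Iterable[GroupSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {c: getattr(s, c) for c in SUMMARY_COLUMNS}
        row["sd"] = np.nan if s.sd is None else s.sd
        rows.append(row)
    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))


def write_summary_table(summaries: Iterable[GroupSummary], path: str | Path) -> None:
    summaries_to_frame(summaries).to_csv(path, index=False)


def find(summaries: Iterable[GroupSummary], **eq) -> list[GroupSummary]:
    """All summaries whose fields equal the given keyword filters."""
    return [s for s in summaries
            if all(getattr(s, k) == v for k, v in eq.items())]


def one(summaries: Iterable[GroupSummary], **eq) -> GroupSummary:
    """The unique summary matching the filters; raises otherwise."""
    hits = find(summaries, **eq)
    if len(hits) != 1:
        raise LookupError(f"expected exactly one summary for {eq}, found {len(hits)}")
    return hits[0]
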