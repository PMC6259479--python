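"""Soil pollution indices: contamination factor, pollution load index,
interval classification, and regulatory-limit screening.

The contamination factor (CF) of a metal is the ratio of its concentration in
a sampled soil to a natural background value -- here, by default, the mean
concentration at an uncontaminated control plot.  The pollution load index
(PLI) of a site is the geometric mean of its CFs across all measured metals;
PLI > 1 signals a net pollution load.  CF and PLI values are mapped to
verbal contamination/pollution classes through an ordered interval scheme
(Lacatusu-style), and observed levels are screened against permissible
limits published by regulatory authorities (WHO for plant material, USEPA
and DPR for soils).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import gmean

from .records import RegulatoryLimit
from .summaries import GroupSummary


def contamination_factor(c_sample: float, c_background: float) -> float:
    """CF = c_sample / c_background (both in mg/kg; the ratio is dimensionless).

    The background concentration must be strictly positive.
    """
    if c_background <= 0:
        raise ValueError("background must be positive")
    if c_sample < 0:
        raise ValueError("sample concentration must be non-negative")
    return c_sample / c_background


def pollution_load_index(cfs: Sequence[float]) -> float:
    """Geometric mean of contamination factors: (CF1 * ... * CFn) ** (1/n).

    Zero is a valid CF and forces PLI = 0.
    """
    if len(cfs) == 0:
        raise ValueError("at least one contamination factor is required")
    if any(cf < 0 for cf in cfs):
        raise ValueError("contamination factors must be non-negative")
    if any(cf == 0 for cf in cfs):
        return 0.0
    return float(gmean(cfs))


@dataclass(frozen=True)
class ContaminationProfile:
    """Per-site contamination factors and the pollution load index."""

    site_id: str
    cfs: Mapping[str, float]  # metal -> CF

    @property
    def n_metals(self) -> int:
        return len(self.cfs)

    @property
    def pli(self) -> float:
        return pollution_load_index(list(self.cfs.values()))


def site_profiles(
    site_values: Mapping[str, Mapping[str, float]],
    background: Mapping[str, float],
) -> list[ContaminationProfile]:
    """Build one :class:`ContaminationProfile` per site.

    Parameters
    ----------
    site_values
        ``{site_id: {metal: soil concentration}}`` for the polluted sites.
    background
        ``{metal: background concentration}``; every metal listed here must
        be present at every site.

    Site order and metal order are preserved from the inputs.
    """
    profiles = []
    for site, values in site_values.items():
        cfs = {}
        for metal, c_bg in background.items():
            if metal not in values:
                raise ValueError(f"site {site!r} has no value for metal {metal!r}")
            cfs[metal] = contamination_factor(values[metal], c_bg)
        profiles.append(ContaminationProfile(site_id=site, cfs=cfs))
    return profiles


def background_from_summaries(
    summaries: Iterable[GroupSummary],
    metals: Sequence[str],
) -> dict[str, float]:
    """Control-plot mean soil concentration per metal (the default background)."""
    from .summaries import one

    return {
        m: one(summaries, plot_class="control", medium="soil", parameter=m).mean
        for m in metals
    }


@dataclass(frozen=True)
class ClassificationScheme:
    """Ordered value intervals mapped to contamination/pollution labels.

    ``intervals`` is a list of ``(lower, upper, label)`` in increasing order.
    Normalization makes the intervals contiguous and half-open under the
    scheme's boundary convention (default ``closed="right"``: a value v maps
    to the interval with lower < v <= upper, and the first interval also
    contains its lower bound).  Published interval tables often leave gaps
    between printed bin edges (an artifact of rounding the printed bounds);
    normalization closes each gap by extending an interval's upper bound to
    the next interval's lower bound, so that every non-negative value maps
    to exactly one label.
    """

    intervals: tuple[tuple[float, float, str], ...]
    closed: str = "right"

    def __post_init__(self) -> None:
        if self.closed not in ("left", "right"):
            raise ValueError("closed must be 'left' or 'right'")
        if not self.intervals:
            raise ValueError("scheme needs at least one interval")
        lowers = [iv[0] for iv in self.intervals]
        if lowers != sorted(lowers):
            raise ValueError("intervals must be sorted by lower bound")
        if lowers[0] != 0:
            raise ValueError("schemes must start at 0")

    @classmethod
    def from_rows(
        cls,
        rows: Sequence[tuple[float, float | None, str]],
        closed: str = "right",
    ) -> "ClassificationScheme":
        """Normalize printed ``(lower, upper, label)`` rows into a contiguous
        scheme.  ``upper=None`` on the last row means unbounded."""
        rows = sorted(rows, key=lambda r: r[0])
        norm = []
        for i, (lo, hi, label) in enumerate(rows):
            if i + 1 < len(rows):
                next_lo = rows[i + 1][0]
                hi = next_lo if (hi is None or hi < next_lo) else hi
            elif hi is None:
                hi = math.inf
            norm.append((float(lo), float(hi), str(label)))
        return cls(intervals=tuple(norm), closed=closed)

    @classmethod
    def from_csv(cls, path: str | Path, closed: str = "right") -> "ClassificationScheme":
        """Load a scheme CSV with columns ``rank, lower, upper, label``
        (blank upper = unbounded) and normalize it."""
        frame = pd.read_csv(path).sort_values("rank")
        rows = [
            (float(r.lower), None if pd.isna(r.upper) else float(r.upper), str(r.label))
            for r in frame.itertuples(index=False)
        ]
        return cls.from_rows(rows, closed=closed)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(iv[2] for iv in self.intervals)

    def rank(self, label: str) -> int:
        """Position of a label in scheme order (0 = least contaminated)."""
        return self.labels.index(label)

    def classify(self, value: float) -> str:
        """The unique label whose interval contains ``value``."""
        if value < 0:
            raise ValueError("classification is defined for non-negative values only")
        for i, (lo, hi, label) in enumerate(self.intervals):
            if self.closed == "right":
                if (lo < value <= hi) or (i == 0 and value == lo):
                    return label
            else:
                if (lo <= value < hi) or (i == len(self.intervals) - 1 and value == hi):
                    return label
        # only reachable when the last interval is bounded
        raise ValueError(f"value {value} above the scheme's support")


def classify_index(value: float, scheme: ClassificationScheme) -> str:
    """Classify a CF or PLI value under an interval scheme."""
    return scheme.classify(value)


@dataclass(frozen=True)
class Exceedance:
    site_scope: str
    plot_class: str
    medium: str
    tissue: str
    parameter: str
    authority: str
    observed: float
    limit_low: float
    limit_high: float
    verdict: str  # "below" | "within-range" | "exceeds"


@dataclass
class ExceedanceReport:
    entries: list[Exceedance] = field(default_factory=list)
    unmatched: list[str] = field(default_factory=list)  # parameters with no limit

    def to_frame(self) -> pd.DataFrame:
        cols = ["site_scope", "plot_class", "medium", "tissue", "parameter",
                "authority", "observed", "limit_low", "limit_high", "verdict"]
        return pd.DataFrame([{c: getattr(e, c) for c in cols} for e in self.entries],
                            columns=cols)

    def verdict(self, *, parameter: str, authority: str, **eq) -> str:
        hits = [e for e in self.entries
                if e.parameter == parameter and e.authority == authority
                and all(getattr(e, k) == v for k, v in eq.items())]
        if len(hits) != 1:
            raise LookupError(
                f"expected one entry for {parameter}/{authority} {eq}, found {len(hits)}")
        return hits[0].verdict


def _verdict(observed: float, limit: RegulatoryLimit) -> str:
    if observed > limit.limit_high:
        return "exceeds"
    if observed < limit.limit_low:
        return "below"
    return "within-range"


def screen_against_limits(
    summaries: Iterable[GroupSummary],
    limits: Sequence[RegulatoryLimit],
) -> ExceedanceReport:
    """Compare group mean concentrations against every applicable limit.

    A limit applies when its (medium, parameter) pair matches the summary's.
    Verdicts: ``exceeds`` when mean > limit_high, ``below`` when
    mean < limit_low, ``within-range`` otherwise.  Parameters for which no
    limit exists in the table are skipped and listed in ``unmatched``.
    """
    report = ExceedanceReport()
    seen_unmatched = set()
    for s in summaries:
        applicable = [l for l in limits
                      if l.medium == s.medium and l.parameter == s.parameter]
        if not applicable:
            key = f"{s.medium}:{s.parameter}"
            if key not in seen_unmatched:
                seen_unmatched.add(key)
                report.unmatched.append(key)
            continue
        for lim in applicable:
            report.entries.append(
                Exceedance(
                    site_scope=s.site_scope,
                    plot_class=s.plot_class,
                    medium=s.medium,
                    tissue=s.tissue,
                    parameter=s.parameter,
                    authority=lim.authority,
                    observed=s.mean,
                    limit_low=lim.limit_low,
                    limit_high=lim.limit_high,
                    verdict=_verdict(s.mean, lim),
                )
            )
    return report


def profiles_to_frame(
    profiles: Iterable[ContaminationProfile],
    scheme: ClassificationScheme | None = None,
) -> pd.DataFrame:
    """CF-matrix table: one row per site, CF_<metal> columns, PLI and,
    when a scheme is given, the PLI class."""
    rows = []
    for p in profiles:
        row: dict = {"site_id": p.site_id}
        row.update({f"CF_{m}": cf for m, cf in p.cfs.items()})
        row["PLI"] = p.pli
        if scheme is not None:
            row["PLI_class"] = scheme.classify(p.pli)
        rows.append(row)
    return pd.DataFrame(rows)
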