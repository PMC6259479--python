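"""Inferential statistics: paired t-tests and soil-tissue Pearson correlation.

The paired t-test compares matched test/control series (pairing by
position); the correlation screen computes the product-moment correlation
between every soil parameter and every plant-tissue parameter across sites,
with two-sided p-values and a significance flag at a configurable alpha
(0.05 by default, no multiple-testing correction -- an optional Holm
adjustment is available but off by default, matching common practice in
field biomonitoring reports).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .records import ConcentrationRecord, PARAMETERS, PLANT_TISSUES
from .summaries import records_to_frame


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    n: int
    mean_difference: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float
    significant: bool


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Two-sided paired t-test on positionally paired series.

    t = mean(d) / (sd(d) / sqrt(n)) on the differences d = x - y, with
    n - 1 degrees of freedom.  Degenerate difference series are resolved
    explicitly: all-zero differences give t = 0, p = 1; zero variance with a
    nonzero mean gives t = +/-inf, p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be one-dimensional and of equal length")
    n = x.size
    if n < 2:
        raise ValueError("at least two pairs are required")
    d = x - y
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    if sd_d == 0.0:
        if mean_d == 0.0:
            return TTestResult(t=0.0, df=n - 1, p=1.0, n=n, mean_difference=0.0)
        return TTestResult(t=math.copysign(math.inf, mean_d), df=n - 1, p=0.0,
                           n=n, mean_difference=mean_d)
    res = sps.ttest_rel(x, y)
    return TTestResult(t=float(res.statistic), df=n - 1, p=float(res.pvalue),
                       n=n, mean_difference=mean_d)


def pearson_r(x: Sequence[float], y: Sequence[float], alpha: float = 0.05) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided p-value.

    Requires at least three pairs and two non-constant series; the p-value
    comes from the t transform with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be one-dimensional and of equal length")
    if x.size < 3:
        raise ValueError("at least three pairs are required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    res = sps.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    return CorrelationResult(r=r, n=int(x.size), p=p, significant=bool(p < alpha))


def site_paired_test(
    records: Sequence[ConcentrationRecord],
    parameter: str,
    medium: str = "soil",
    tissue: str | None = None,
) -> TTestResult:
    """Test-vs-control paired test with per-site matching.

    Each test site contributes its mean value of ``parameter`` (over stands
    and, for plant records with ``tissue=None``, over the four tissues); the
    single control plot's mean is paired against every test site.  For
    ``medium="tissue"`` pass a tissue name to test one tissue only.
    """
    frame = records_to_frame(records)
    sel = (frame["medium"] == medium) & (frame["parameter"] == parameter)
    if medium == "tissue" and tissue is not None:
        sel &= frame["tissue"] == tissue
    frame = frame[sel]
    if frame.empty:
        raise ValueError(f"no records for {parameter} in {medium}")
    test = frame[frame["plot_class"] == "test"].groupby("site_id")["value"].mean()
    control = frame[frame["plot_class"] == "control"]["value"]
    if test.empty or control.empty:
        raise ValueError("both test and control records are required")
    x = test.sort_index().to_numpy()
    y = np.full(x.size, control.mean())
    return paired_t_test(x, y)


@dataclass
class CorrelationMatrix:
    """Soil-by-tissue correlation screen.

    ``r``, ``p`` and ``significant`` are DataFrames whose rows are
    (parameter, tissue) pairs and whose columns are soil parameters; ``n``
    is the number of sites behind every cell.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    n: int
    alpha: float
    adjust: str | None = None

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for (param, tissue) in self.r.index:
            for soil_param in self.r.columns:
                rows.append({
                    "tissue_parameter": param,
                    "tissue": tissue,
                    "soil_parameter": soil_param,
                    "r": self.r.loc[(param, tissue), soil_param],
                    "p": self.p.loc[(param, tissue), soil_param],
                    "n": self.n,
                    "significant": bool(self.significant.loc[(param, tissue), soil_param]),
                })
        return pd.DataFrame(rows)


def soil_tissue_correlation_matrix(
    records: Sequence[ConcentrationRecord],
    alpha: float = 0.05,
    adjust: str | None = None,
) -> CorrelationMatrix:
    """Correlate every tissue parameter with every soil parameter across sites.

    Per-site values are replicate means.  All sites with complete soil and
    tissue series enter; fewer than three complete sites is an error.
    ``adjust="holm"`` applies a Holm step-down correction over all cells
    before flagging significance.
    """
    frame = records_to_frame(records)
    soil = (frame[frame["medium"] == "soil"]
            .groupby(["site_id", "parameter"])["value"].mean().unstack())
    tiss = (frame[frame["medium"] == "tissue"]
            .groupby(["site_id", "parameter", "tissue"])["value"].mean().unstack([1, 2]))
    soil_params = [p for p in PARAMETERS if p in soil.columns]
    tissue_cols = [(p, t) for p in PARAMETERS for t in PLANT_TISSUES
                   if (p, t) in tiss.columns]
    if not soil_params or not tissue_cols:
        raise ValueError("records must include both soil and tissue measurements")
    sites = sorted(set(soil.dropna().index) & set(tiss.dropna().index))
    if len(sites) < 3:
        raise ValueError(f"need at least 3 complete sites, have {len(sites)}")
    soil = soil.loc[sites, soil_params]
    tiss = tiss.loc[sites, tissue_cols]

    index = pd.MultiIndex.from_tuples(tissue_cols, names=["parameter", "tissue"])
    r = pd.DataFrame(np.nan, index=index, columns=soil_params)
    p = pd.DataFrame(np.nan, index=index, columns=soil_params)
    for col in tissue_cols:
        for sp in soil_params:
            res = pearson_r(tiss[col], soil[sp], alpha=alpha)
            r.loc[col, sp] = res.r
            p.loc[col, sp] = res.p
    if adjust is None:
        significant = p < alpha
    elif adjust == "holm":
        flat = p.to_numpy().ravel()
        reject, _, _, _ = multipletests(flat, alpha=alpha, method="holm")
        significant = pd.DataFrame(reject.reshape(p.shape), index=p.index,
                                   columns=p.columns)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return CorrelationMatrix(r=r, p=p, significant=significant,
                             n=len(sites), alpha=alpha, adjust=adjust)
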