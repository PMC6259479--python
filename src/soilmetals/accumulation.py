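"""Plant uptake metrics: aerial portion, translocation factor, plant/soil ratio.

For each metal and plot class the aerial portion is the sum of the leaf,
fruit and stem mean concentrations; the translocation factor (TF) divides it
by the root mean, so TF > 1 indicates efficient root-to-shoot movement.  The
plant/soil concentration ratio divides the arithmetic mean of the four
tissue means by the supporting soil's mean concentration and is a
bioaccumulation indicator.  All concentrations are mg/kg dry weight; both
ratios are dimensionless and invariant under a common rescaling of units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .records import PLANT_TISSUES
from .summaries import GroupSummary, one


def aerial_concentration(leaf: float, fruit: float, stem: float) -> float:
    """Aerial-portion concentration: leaf + fruit + stem (mg/kg)."""
    if leaf < 0 or fruit < 0 or stem < 0:
        raise ValueError("tissue concentrations must be non-negative")
    return leaf + fruit + stem


def translocation_factor(aerial: float, root: float) -> float:
    """TF = aerial / root; the root concentration must be positive."""
    if root <= 0:
        raise ValueError("root concentration must be positive")
    if aerial < 0:
        raise ValueError("aerial concentration must be non-negative")
    return aerial / root


def plant_soil_ratio(root: float, leaf: float, fruit: float, stem: float,
                     soil: float) -> float:
    """mean(root, leaf, fruit, stem) / soil; soil must be positive."""
    if soil <= 0:
        raise ValueError("soil concentration must be positive")
    tissues = (root, leaf, fruit, stem)
    if any(t < 0 for t in tissues):
        raise ValueError("tissue concentrations must be non-negative")
    return (sum(tissues) / 4.0) / soil


@dataclass(frozen=True)
class AccumulationResult:
    """Uptake metrics for one metal in one plot class."""

    metal: str
    plot_class: str
    aerial: float
    root: float
    tf: float
    plant_mean: float
    soil_mean: float
    plant_soil_ratio: float


def accumulation_table(
    tissue_summaries: Iterable[GroupSummary],
    soil_summaries: Iterable[GroupSummary],
    metals: Sequence[str] | None = None,
    plot_classes: Sequence[str] = ("test", "control"),
) -> list[AccumulationResult]:
    """One :class:`AccumulationResult` per (metal, plot class).

    Each combination needs the four tissue means (root, leaf, fruit, stem)
    among ``tissue_summaries`` and a soil mean among ``soil_summaries``;
    a missing tissue raises an error naming the metal and tissue.  Metal
    order follows the input when ``metals`` is not given.
    """
    tissue_summaries = list(tissue_summaries)
    soil_summaries = list(soil_summaries)
    if metals is None:
        metals = list(dict.fromkeys(
            s.parameter for s in tissue_summaries if s.medium == "tissue"))
    results = []
    for metal in metals:
        for plot_class in plot_classes:
            means = {}
            for tissue in PLANT_TISSUES:
                try:
                    means[tissue] = one(tissue_summaries, medium="tissue",
                                        tissue=tissue, parameter=metal,
                                        plot_class=plot_class).mean
                except LookupError as exc:
                    raise ValueError(
                        f"missing {tissue} summary for metal {metal!r} "
                        f"({plot_class} plots)") from exc
            try:
                soil = one(soil_summaries, medium="soil", parameter=metal,
                           plot_class=plot_class).mean
            except LookupError as exc:
                raise ValueError(
                    f"missing soil summary for metal {metal!r} ({plot_class} plots)"
                ) from exc
            aerial = aerial_concentration(means["leaf"], means["fruit"], means["stem"])
            results.append(
                AccumulationResult(
                    metal=metal,
                    plot_class=plot_class,
                    aerial=aerial,
                    root=means["root"],
                    tf=translocation_factor(aerial, means["root"]),
                    plant_mean=sum(means.values()) / 4.0,
                    soil_mean=soil,
                    plant_soil_ratio=plant_soil_ratio(
                        means["root"], means["leaf"], means["fruit"],
                        means["stem"], soil),
                )
            )
    return results


def accumulation_to_frame(results: Iterable[AccumulationResult]) -> pd.DataFrame:
    cols = ["metal", "plot_class", "aerial", "root", "tf",
            "plant_mean", "soil_mean", "plant_soil_ratio"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results],
                        columns=cols)
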