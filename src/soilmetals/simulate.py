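"""Synthetic biomonitoring studies with known ground truth.

The generator emulates the sampling design of a workshop-contamination
survey: a handful of polluted (test) sites plus one uncontaminated control,
a few plant stands per site, soil and four plant tissues (root, leaf,
fruit, stem) measured for five metals plus pH and EC.

Concentrations follow a median-parameterized lognormal model: the soil
value at a (site, stand) is ``median * enrichment * exp(sigma * Z)`` with
standard-normal Z (enrichment = 1 at the control), so changing the
dispersion ``sigma`` never shifts the median.  Each tissue value multiplies
the local soil value by a metal-specific transfer slope, a tissue partition
weight, and lognormal residual noise ``exp(noise_sigma * Z)``.  The
closed-form expectations implied by a design (:func:`ground_truth`) carry
the ``exp(sigma**2 / 2)`` lognormal mean factor explicitly where it does
not cancel, so parameter-recovery checks have unambiguous targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .records import ConcentrationRecord, METALS, PLANT_TISSUES

#: Control-plot soil medians (mg/kg) sized like a tropical roadside survey.
DEFAULT_CONTROL_MEDIAN = {"Pb": 21.9, "Hg": 17.1, "Cd": 4.7, "Cu": 5.4, "Zn": 3.2}
#: Multiplicative soil enrichment at the polluted sites.
DEFAULT_ENRICHMENT = {"Pb": 3.4, "Hg": 2.2, "Cd": 4.3, "Cu": 10.4, "Zn": 14.9}
#: Expected tissue-mean / soil concentration ratio.
DEFAULT_TRANSFER_SLOPE = {"Pb": 0.611, "Hg": 0.776, "Cd": 0.605, "Cu": 0.693, "Zn": 0.476}
#: Relative tissue weights (root, leaf, fruit, stem); they average to 1.
DEFAULT_TISSUE_PARTITION = {"root": 0.90, "leaf": 1.07, "fruit": 1.01, "stem": 1.02}


@dataclass
class StudyDesign:
    """Parameters of a synthetic study; defaults emulate a seven-workshop
    survey with one forest control and three papaya stands per site."""

    n_test_sites: int = 7
    n_stands_per_site: int = 3
    metals: Sequence[str] = METALS
    control_soil_median: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_MEDIAN))
    enrichment: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ENRICHMENT))
    transfer_slope: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRANSFER_SLOPE))
    tissue_partition: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_PARTITION))
    lognormal_sigma: float = 0.2   # site/stand dispersion of soil values (log scale)
    noise_sigma: float = 0.1       # tissue-level residual dispersion (log scale)
    # (test, control) location parameters for the non-metal series
    ph_soil: tuple[float, float] = (4.7, 6.6)
    ph_tissue: tuple[float, float] = (5.7, 8.1)
    ph_sd: float = 0.3
    ec_soil: tuple[float, float] = (1660.0, 420.0)
    ec_tissue: tuple[float, float] = (1450.0, 400.0)
    ec_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_test_sites < 1:
            raise ValueError("n_test_sites must be >= 1")
        if self.n_stands_per_site < 1:
            raise ValueError("n_stands_per_site must be >= 1")
        if not self.metals:
            raise ValueError("metals must be non-empty")
        for name in ("control_soil_median", "enrichment", "transfer_slope"):
            table = getattr(self, name)
            for m in self.metals:
                if m not in table:
                    raise ValueError(f"{name} is missing metal {m!r}")
                if table[m] <= 0:
                    raise ValueError(f"{name}[{m!r}] must be positive")
        weights = self.tissue_partition
        if set(weights) != set(PLANT_TISSUES):
            raise ValueError(f"tissue_partition must weight exactly {PLANT_TISSUES}")
        if any(w <= 0 for w in weights.values()):
            raise ValueError("tissue_partition weights must be positive")
        if abs(sum(weights.values()) / len(weights) - 1.0) > 1e-9:
            raise ValueError("tissue_partition weights must average to 1")
        for name in ("lognormal_sigma", "noise_sigma", "ph_sd", "ec_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["metals"] = list(self.metals)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "StudyDesign":
        d = dict(data)
        for key in ("metals", "ph_soil", "ph_tissue", "ec_soil", "ec_tissue"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class MetricTruth:
    """Closed-form expectations for one metal under a design."""

    cf: float
    tf: float
    plant_soil_ratio: float


def ground_truth(design: StudyDesign) -> dict[str, MetricTruth]:
    """Expected CF, TF and plant/soil ratio per metal.

    CF: the lognormal mean factor is shared by test and control soils, so
    the expected contamination factor is the enrichment itself.  TF: soil,
    slope and noise distributions are common to all tissues of a plant, so
    the expected translocation factor is the partition-weight ratio
    (leaf + fruit + stem) / root.  Plant/soil ratio: the tissue-level noise
    does not cancel, leaving ``slope * exp(noise_sigma**2 / 2)``.
    """
    w = design.tissue_partition
    tf = (w["leaf"] + w["fruit"] + w["stem"]) / w["root"]
    noise_mean = float(np.exp(design.noise_sigma ** 2 / 2.0))
    return {
        m: MetricTruth(
            cf=float(design.enrichment[m]),
            tf=tf,
            plant_soil_ratio=float(design.transfer_slope[m]) * noise_mean,
        )
        for m in design.metals
    }


def generate_study(design: StudyDesign, seed: int | None = None) -> list[ConcentrationRecord]:
    """Draw one synthetic study as a flat record list.

    Deterministic given the seed (``design.seed`` unless overridden).  Sites
    are labelled ``S1..Sn`` plus ``"control"``; the stand index is stored as
    the replicate number.  Soil rows carry ``tissue="none"``.
    """
    design.validate()
    rng = np.random.default_rng(design.seed if seed is None else seed)
    sites = [(f"S{i + 1}", "test") for i in range(design.n_test_sites)]
    sites.append(("control", "control"))
    records: list[ConcentrationRecord] = []

    def add(site, plot, medium, tissue, param, rep, value):
        records.append(ConcentrationRecord(
            site_id=site, plot_class=plot, medium=medium, tissue=tissue,
            parameter=param, replicate=rep, value=float(value)))

    for site_id, plot in sites:
        test = plot == "test"
        for stand in range(1, design.n_stands_per_site + 1):
            for metal in design.metals:
                median = design.control_soil_median[metal]
                enr = design.enrichment[metal] if test else 1.0
                soil = median * enr * np.exp(design.lognormal_sigma * rng.standard_normal())
                add(site_id, plot, "soil", "none", metal, stand, soil)
                slope = design.transfer_slope[metal]
                for tissue in PLANT_TISSUES:
                    w = design.tissue_partition[tissue]
                    value = soil * slope * w * np.exp(
                        design.noise_sigma * rng.standard_normal())
                    add(site_id, plot, "tissue", tissue, metal, stand, value)
            idx = 0 if test else 1
            ph_soil = np.clip(rng.normal(design.ph_soil[idx], design.ph_sd), 0.0, 14.0)
            add(site_id, plot, "soil", "none", "pH", stand, ph_soil)
            ec_soil = design.ec_soil[idx] * np.exp(design.ec_sigma * rng.standard_normal())
            add(site_id, plot, "soil", "none", "EC", stand, ec_soil)
            for tissue in PLANT_TISSUES:
                ph_t = np.clip(rng.normal(design.ph_tissue[idx], design.ph_sd), 0.0, 14.0)
                add(site_id, plot, "tissue", tissue, "pH", stand, ph_t)
                ec_t = design.ec_tissue[idx] * np.exp(
                    design.ec_sigma * rng.standard_normal())
                add(site_id, plot, "tissue", tissue, "EC", stand, ec_t)
    return records
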