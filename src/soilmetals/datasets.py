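"""Bundled reference tables.

The package ships the published summary tables of a heavy-metal survey of
Carica papaya and supporting soils around seven automobile workshops (plus
one forest control) in Port Harcourt, Nigeria: per-tissue and soil
descriptive summaries, the per-site contamination-factor matrix, the
Lacatusu contamination/pollution interval scheme, and WHO/USEPA/DPR
regulatory limit tables.  These serve as worked-example inputs and as
fixtures for verifying the index computations against published values.
"""

from __future__ import annotations

from importlib.resources import as_file, files

import pandas as pd

from .indices import ClassificationScheme
from .records import RegulatoryLimit, read_limits
from .summaries import GroupSummary, load_summary_table


def _data_file(name: str):
    return as_file(files(__package__) / "data" / name)


def load_tissue_summaries() -> list[GroupSummary]:
    """Per-tissue summaries (pH, EC, five metals; test and control plots)."""
    with _data_file("tissue_summaries.csv") as path:
        return load_summary_table(path)


def load_soil_summaries() -> list[GroupSummary]:
    """Soil summaries (pH, EC, five metals; test and control plots)."""
    with _data_file("soil_summaries.csv") as path:
        return load_summary_table(path)


def load_contamination_factors() -> pd.DataFrame:
    """Per-site contamination factors, sites as rows and metals as columns."""
    with _data_file("contamination_factors.csv") as path:
        return pd.read_csv(path, index_col="site_id")


def load_lacatusu_scheme() -> ClassificationScheme:
    """The Lacatusu contamination/pollution interval scheme, normalized."""
    with _data_file("lacatusu_scheme.csv") as path:
        return ClassificationScheme.from_csv(path)


def load_regulatory_limits() -> list[RegulatoryLimit]:
    """WHO (plant tissue) and USEPA/DPR (soil) permissible levels."""
    with _data_file("regulatory_limits.csv") as path:
        return read_limits(path)
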