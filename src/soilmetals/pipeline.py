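"""End-to-end orchestration: records in, survey-style report tables out.

:func:`analyze_records` runs every analysis stage on a record list and
returns the intermediate objects; :func:`run_pipeline` drives it from a
flat YAML config file, writes the output CSVs and a machine-readable run
manifest, and guarantees that a failed run never leaves partial outputs
without a failure marker.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .accumulation import AccumulationResult, accumulation_table, accumulation_to_frame
from .datasets import load_lacatusu_scheme, load_regulatory_limits
from .indices import (ClassificationScheme, ContaminationProfile, ExceedanceReport,
                      background_from_summaries, profiles_to_frame,
                      screen_against_limits, site_profiles)
from .records import (ConcentrationRecord, METALS, ValidationReport,
                      read_concentration_table, read_limits,
                      validate_records, write_concentration_table)
from .simulate import StudyDesign, generate_study
from .stats import CorrelationMatrix, soil_tissue_correlation_matrix
from .summaries import (GroupSummary, find, load_summary_table, summaries_to_frame,
                        summarize, write_summary_table)


@dataclass
class AnalysisResult:
    """All stage outputs of one pipeline run."""

    summaries: list[GroupSummary]
    site_summaries: list[GroupSummary]
    profiles: list[ContaminationProfile]
    accumulation: list[AccumulationResult]
    correlations: CorrelationMatrix | None
    exceedance: ExceedanceReport
    validation: ValidationReport
    scheme: ClassificationScheme


def analyze_records(
    records: Sequence[ConcentrationRecord],
    limits=None,
    scheme: ClassificationScheme | None = None,
    background: Mapping[str, float] | None = None,
    metals: Sequence[str] = METALS,
    alpha: float = 0.05,
    adjust: str | None = None,
) -> AnalysisResult:
    """Run summaries, contamination profiles, accumulation metrics,
    correlation screening and limit screening on one record list.

    ``background`` defaults to the control-plot mean soil concentration of
    each metal.  The correlation matrix is ``None`` when fewer than three
    complete sites are available.
    """
    if limits is None:
        limits = load_regulatory_limits()
    if scheme is None:
        scheme = load_lacatusu_scheme()
    validation = validate_records(records)
    validation.raise_on_error()

    summaries = summarize(records)
    site_summaries = summarize(records, by=("site_id", "plot_class", "medium",
                                            "tissue", "parameter"))
    metals = [m for m in metals
              if any(s.parameter == m for s in site_summaries if s.medium == "soil")]
    if background is None:
        background = background_from_summaries(summaries, metals)
    site_values: dict[str, dict[str, float]] = {}
    for s in find(site_summaries, medium="soil", plot_class="test"):
        if s.parameter in metals:
            site_values.setdefault(s.site_scope, {})[s.parameter] = s.mean
    profiles = site_profiles(site_values, background)

    accumulation = accumulation_table(
        find(summaries, medium="tissue"), find(summaries, medium="soil"),
        metals=metals)
    try:
        correlations = soil_tissue_correlation_matrix(records, alpha=alpha,
                                                      adjust=adjust)
    except ValueError:
        correlations = None
    exceedance = screen_against_limits(summaries, limits)
    return AnalysisResult(
        summaries=summaries, site_summaries=site_summaries, profiles=profiles,
        accumulation=accumulation, correlations=correlations,
        exceedance=exceedance, validation=validation, scheme=scheme)


def _config_hash(config: Mapping) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


def run_pipeline(
    config: str | Path | Mapping,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Run the pipeline from a config file (or mapping) and write reports.

    Config keys: ``records`` (long-format CSV) or ``simulate: true`` with an
    optional ``design`` block; optional ``cf_table`` (per-site CF matrix CSV
    to profile directly); optional ``limits``/``scheme`` CSV paths (bundled
    tables by default); ``out_dir``, ``seed``, ``alpha``, ``adjust``.

    Outputs: ``summaries.csv``, ``profiles.csv``, ``accumulation.csv``,
    ``correlations.csv``, ``exceedance.csv``, plus ``records.csv`` for
    simulated data and a ``manifest.json`` recording inputs, config hash,
    package versions and the seed.  On failure a ``FAILED.txt`` marker is
    written next to whatever partial outputs exist.  Returns the written
    paths keyed by stage.
    """
    if isinstance(config, (str, Path)):
        config_path = Path(config)
        if not config_path.exists():
            raise FileNotFoundError(f"config file not found: {config_path}")
        with config_path.open() as fh:
            config = yaml.safe_load(fh) or {}
    config = dict(config)
    out_dir = Path(out_dir if out_dir is not None else config.get("out_dir", "."))
    seed = seed if seed is not None else config.get("seed")
    alpha = float(config.get("alpha", 0.05))
    adjust = config.get("adjust")

    # resolve and check every input before any computation or output
    inputs: dict[str, str] = {}
    paths: dict[str, Path] = {}
    for key in ("records", "cf_table", "limits", "scheme"):
        if config.get(key):
            p = Path(config[key])
            if not p.exists():
                raise FileNotFoundError(f"{key} file not found: {p}")
            paths[key] = p
            inputs[key] = str(p)
    simulate = bool(config.get("simulate", False))
    if not simulate and "records" not in paths and "cf_table" not in paths:
        raise ValueError("config must name a records CSV, a cf_table CSV, "
                         "or set simulate: true")

    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    try:
        limits = read_limits(paths["limits"]) if "limits" in paths \
            else load_regulatory_limits()
        scheme = ClassificationScheme.from_csv(paths["scheme"]) if "scheme" in paths \
            else load_lacatusu_scheme()

        records: list[ConcentrationRecord] = []
        if simulate:
            design = StudyDesign.from_dict(config.get("design", {}))
            records = generate_study(design, seed=seed)
            written["records"] = out_dir / "records.csv"
            write_concentration_table(records, written["records"])
        elif "records" in paths:
            records = read_concentration_table(paths["records"])

        if records:
            result = analyze_records(records, limits=limits, scheme=scheme,
                                     alpha=alpha, adjust=adjust)
            written["summaries"] = out_dir / "summaries.csv"
            write_summary_table(result.summaries, written["summaries"])
            written["site_summaries"] = out_dir / "site_summaries.csv"
            write_summary_table(result.site_summaries, written["site_summaries"])
            written["accumulation"] = out_dir / "accumulation.csv"
            accumulation_to_frame(result.accumulation).to_csv(
                written["accumulation"], index=False)
            if result.correlations is not None:
                written["correlations"] = out_dir / "correlations.csv"
                result.correlations.to_long_frame().to_csv(
                    written["correlations"], index=False)
            written["exceedance"] = out_dir / "exceedance.csv"
            result.exceedance.to_frame().to_csv(written["exceedance"], index=False)
            profiles = result.profiles
        else:
            profiles = []

        if "cf_table" in paths:
            cf = pd.read_csv(paths["cf_table"], index_col=0)
            # a CF matrix is already background-normalized: unit background
            profiles = site_profiles(
                {site: row.to_dict() for site, row in cf.iterrows()},
                {m: 1.0 for m in cf.columns})
        if profiles:
            written["profiles"] = out_dir / "profiles.csv"
            profiles_to_frame(profiles, scheme).to_csv(written["profiles"], index=False)

        manifest = {
            "inputs": inputs,
            "config_hash": _config_hash(config),
            "seed": seed,
            "alpha": alpha,
            "versions": {"soilmetals": __version__,
                         "pandas": pd.__version__},
            "outputs": {k: str(v) for k, v in written.items()},
            "timestamp": datetime.now(timezone.utc).isoformat(),
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        written["manifest"] = manifest_path
    except Exception as exc:
        (out_dir / "FAILED.txt").write_text(f"pipeline run failed: {exc}\n")
        raise
    return written
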