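"""Record parsing, CSV round-trips, limit tables and validation rules."""

import pytest
from hypothesis import given, strategies as st

from soilmetals.records import (
    ConcentrationRecord, FormatError, METALS, PLANT_TISSUES, ValidationError,
    read_concentration_table, read_limits, validate_records,
    write_concentration_table,
)
from soilmetals.summaries import GroupSummary

HEADER = "site_id,plot_class,medium,tissue,parameter,replicate,value\n"


def _write(tmp_path, body, header=HEADER, name="records.csv"):
    path = tmp_path / name
    path.write_text(header + body)
    return path


class TestReadConcentrationTable:
    def test_single_row_parses_to_one_record(self, tmp_path):
        path = _write(tmp_path, "S1,test,soil,none,Pb,1,73.6\n")
        (rec,) = read_concentration_table(path)
        assert rec == ConcentrationRecord("S1", "test", "soil", "none", "Pb", 1, 73.6)
        assert rec.unit == "mg/kg dw"

    def test_per_site_soil_fixture_has_one_record_per_cell(self, tmp_path, cf_table,
                                                           soil_summaries):
        # reconstruct per-site soil concentrations as CF x control mean:
        # 7 sites x 5 metals -> 35 records
        from soilmetals.summaries import one
        rows = []
        for site, cfs in cf_table.iterrows():
            for metal in METALS:
                bg = one(soil_summaries, plot_class="control", parameter=metal).mean
                rows.append(f"{site},test,soil,none,{metal},1,{cfs[metal] * bg}")
        path = _write(tmp_path, "\n".join(rows) + "\n")
        records = read_concentration_table(path)
        assert len(records) == 35
        assert [r.site_id for r in records[:5]] == ["S1"] * 5  # order preserved

    def test_missing_column_is_named_in_error(self, tmp_path):
        path = _write(tmp_path, "S1,test,soil,Pb,1,73.6\n",
                      header="site_id,plot_class,medium,parameter,replicate,value\n")
        with pytest.raises(FormatError, match="tissue"):
            read_concentration_table(path)

    def test_unparseable_value_reports_line_number(self, tmp_path):
        path = _write(tmp_path,
                      "S1,test,soil,none,Pb,1,73.6\nS1,test,soil,none,Hg,1,oops\n")
        with pytest.raises(FormatError, match="line 3"):
            read_concentration_table(path)

    def test_soil_row_with_tissue_fails_validation(self, tmp_path):
        path = _write(tmp_path, "S1,test,soil,leaf,Pb,1,73.6\n")
        with pytest.raises(ValidationError, match="tissue set for soil record"):
            read_concentration_table(path)

    def test_dialect_maps_foreign_headers(self, tmp_path):
        path = _write(tmp_path, "S1,test,soil,none,Pb,1,73.6\n",
                      header="station,class,medium,organ,analyte,rep,conc\n")
        dialect = {"site_id": "station", "plot_class": "class", "medium": "medium",
                   "tissue": "organ", "parameter": "analyte", "replicate": "rep",
                   "value": "conc"}
        (rec,) = read_concentration_table(path, dialect=dialect)
        assert rec.value == 73.6

    def test_constructor_rejects_unknown_categories(self):
        with pytest.raises(ValueError):
            ConcentrationRecord("S1", "polluted", "soil", "none", "Pb", 1, 1.0)
        with pytest.raises(ValueError):
            ConcentrationRecord("S1", "test", "soil", "none", "Fe", 1, 1.0)
        with pytest.raises(ValueError):
            ConcentrationRecord("S1", "test", "soil", "none", "Pb", 0, 1.0)


values = st.floats(min_value=0, max_value=1e6, allow_nan=False, allow_infinity=False)
tissue_records = st.builds(
    ConcentrationRecord,
    site_id=st.sampled_from(["S1", "S2", "control"]),
    plot_class=st.sampled_from(["test", "control"]),
    medium=st.just("tissue"),
    tissue=st.sampled_from(PLANT_TISSUES),
    parameter=st.sampled_from(METALS + ("EC",)),
    replicate=st.integers(min_value=1, max_value=9),
    value=values,
)
soil_records = st.builds(
    ConcentrationRecord,
    site_id=st.sampled_from(["S1", "S2", "control"]),
    plot_class=st.sampled_from(["test", "control"]),
    medium=st.just("soil"),
    tissue=st.just("none"),
    parameter=st.sampled_from(METALS + ("EC",)),
    replicate=st.integers(min_value=1, max_value=9),
    value=values,
)


@given(st.lists(tissue_records | soil_records, max_size=30))
def test_write_read_round_trip_is_exact(tmp_path_factory, records):
    """Writing then reading any record list reproduces it field-for-field."""
    path = tmp_path_factory.mktemp("rt") / "records.csv"
    write_concentration_table(records, path)
    assert read_concentration_table(path, strict=False) == records


class TestReadLimits:
    def test_single_valued_limit(self, tmp_path):
        path = _write(tmp_path, "WHO,tissue,Pb,0.3,0.3\n",
                      header="authority,medium,parameter,low,high\n", name="lim.csv")
        (lim,) = read_limits(path)
        assert lim.limit_low == lim.limit_high == 0.3

    def test_range_limit_normalized(self, tmp_path):
        path = _write(tmp_path, "WHO,tissue,Hg,0.5,0.05\n",
                      header="authority,medium,parameter,low,high\n", name="lim.csv")
        (lim,) = read_limits(path)
        assert (lim.limit_low, lim.limit_high) == (0.05, 0.5)

    def test_blank_low_duplicates_high(self, tmp_path):
        path = _write(tmp_path, "DPR,soil,Cd,,0.8\n",
                      header="authority,medium,parameter,low,high\n", name="lim.csv")
        (lim,) = read_limits(path)
        assert (lim.limit_low, lim.limit_high) == (0.8, 0.8)

    def test_non_positive_limit_rejected(self, tmp_path):
        path = _write(tmp_path, "DPR,soil,Cd,0,0.8\n",
                      header="authority,medium,parameter,low,high\n", name="lim.csv")
        with pytest.raises(FormatError):
            read_limits(path)

    def test_bundled_tables_load(self, limits):
        assert {l.authority for l in limits} == {"WHO", "USEPA", "DPR"}
        assert all(0 < l.limit_low <= l.limit_high for l in limits)


class TestValidateRecords:
    def test_negative_concentration_is_an_error(self):
        rec = ConcentrationRecord("S1", "test", "soil", "none", "Pb", 1, -1.0)
        report = validate_records([rec])
        assert [f.rule for f in report.errors] == ["negative-concentration"]

    def test_ph_out_of_range_is_an_error(self):
        rec = ConcentrationRecord("S1", "test", "soil", "none", "pH", 1, 15.0)
        assert validate_records([rec]).errors[0].rule == "ph-range"

    def test_duplicate_keys_flagged(self):
        rec = ConcentrationRecord("S1", "test", "soil", "none", "Pb", 1, 1.0)
        report = validate_records([rec, rec])
        assert [f.rule for f in report.errors] == ["duplicate-key"]

    def test_inverted_summary_range_is_a_warning_not_a_repair(self):
        # mirrors a published table row whose min/max were transposed
        summary = GroupSummary("all", "control", "tissue", "fruit", "Cd",
                               n=7, mean=2.8, sd=0.3, min=9.0, max=4.0)
        report = validate_records([], [summary])
        assert report.warnings[0].rule == "inverted-range"
        assert not report.errors
        assert summary.min == 9.0  # never silently swapped

    def test_clean_records_give_empty_report(self):
        recs = [ConcentrationRecord("S1", "test", "soil", "none", "Pb", 1, 1.0),
                ConcentrationRecord("S1", "test", "tissue", "leaf", "Pb", 1, 0.5)]
        assert validate_records(recs).ok

    @given(st.lists(tissue_records | soil_records, max_size=20),
           st.randoms(use_true_random=False))
    def test_validation_is_order_independent_and_idempotent(self, records, rnd):
        base = validate_records(records)
        again = validate_records(records)
        shuffled = list(records)
        rnd.shuffle(shuffled)
        permuted = validate_records(shuffled)
        as_multiset = lambda rep: sorted((f.rule, f.severity, f.ref) for f in rep.findings)
        assert as_multiset(base) == as_multiset(again) == as_multiset(permuted)
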