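"""CSV contract: parsing, cell validators, table validation, id minting."""

import datetime

import pytest
from hypothesis import given, settings, strategies as st

from cdefair.catalog import CatalogConfigError, DescendantOf
from cdefair.csv_template import (
    CsvParseError,
    mint_row_id,
    parse_csv,
    translate_labels,
    degrade_birth_dates,
    validate_date,
    validate_table,
    validate_term,
    write_csv,
)

HP_ROOT = "http://purl.obolibrary.org/obo/HP_0000118"


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text, encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# Parsing


def test_parse_well_formed(tmp_path, catalog):
    path = _write(
        tmp_path,
        "patient_status.csv",
        "pid,row_id,status_uri,death_date\n"
        "P1,R1,http://purl.obolibrary.org/obo/NCIT_C37987,\n"
        "P2,R2,http://purl.obolibrary.org/obo/NCIT_C28554,2019-01-02\n"
        "P3,R3,http://purl.obolibrary.org/obo/NCIT_C37987,\n",
    )
    table = parse_csv(path, catalog.get_model("patient_status"))
    assert len(table) == 3
    assert table.rows[1].get("death_date") == "2019-01-02"
    assert table.rows[0].pseudonym == "P1"
    assert not table.parse_notes


def test_parse_missing_pseudonym_column(tmp_path, catalog):
    path = _write(tmp_path, "patient_status.csv", "row_id,status_uri\nR1,x\n")
    with pytest.raises(CsvParseError, match="pid"):
        parse_csv(path, catalog.get_model("patient_status"))


def test_parse_extra_column_noted(tmp_path, catalog):
    path = _write(
        tmp_path,
        "patient_status.csv",
        "pid,row_id,status_uri,death_date,note\nP1,R1,http://x/a,,hello\n",
    )
    table = parse_csv(path, catalog.get_model("patient_status"))
    assert table.rows[0].get("note") == "hello"
    assert any("note" in n for n in table.parse_notes)


def test_parse_ragged_row_reports_line_number(tmp_path, catalog):
    path = _write(
        tmp_path,
        "patient_status.csv",
        "pid,row_id,status_uri,death_date\nP1,R1,http://x/a,\nP2,R2\n",
    )
    with pytest.raises(CsvParseError, match="line 3"):
        parse_csv(path, catalog.get_model("patient_status"))


def test_parse_missing_header(tmp_path, catalog):
    path = _write(tmp_path, "patient_status.csv", "")
    with pytest.raises(CsvParseError, match="header"):
        parse_csv(path, catalog.get_model("patient_status"))


def test_csv_round_trip(tmp_path, catalog, cohort):
    table = cohort["diagnosis"]
    path = write_csv(table, tmp_path / "diagnosis.csv")
    again = parse_csv(path, catalog.get_model("diagnosis"))
    assert again.header == table.header
    assert [r.cells for r in again.rows] == [dict(r.cells) for r in table.rows]


# ---------------------------------------------------------------------------
# Date validation


@pytest.mark.parametrize(
    "value,ok",
    [
        ("2001-03-14", True),
        ("1999-12-31", True),
        ("2000-02-29", True),  # leap day
        ("2001-02-30", False),  # calendar-invalid
        ("2001-02-29", False),  # not a leap year
        ("14/03/2001", False),  # registry dialect must be rejected
        ("2001-3-14", False),
        ("20010314", False),  # compact ISO dialect rejected
        ("2001-03-14T00:00:00", False),  # no time component
        ("2001-W11-3", False),
        ("", False),
    ],
)
def test_validate_date_cases(value, ok):
    assert validate_date(value) is ok


@settings(max_examples=300, derandomize=True)
@given(
    st.one_of(
        st.text(alphabet="0123456789-/:TW ", max_size=12),
        st.dates().map(lambda d: d.isoformat()),
        st.dates().map(lambda d: d.strftime("%d/%m/%Y")),
    )
)
def test_validate_date_matches_strptime_oracle(value):
    """Fuzzed agreement with an independent strict-parse oracle."""
    try:
        parsed = datetime.datetime.strptime(value, "%Y-%m-%d")
        # forbid lax single-digit %m/%d forms (strftime %Y is not zero-padded
        # for years < 1000 on glibc, so format explicitly)
        oracle = f"{parsed.year:04d}-{parsed.month:02d}-{parsed.day:02d}" == value
    except ValueError:
        oracle = False
    assert validate_date(value) is oracle


# ---------------------------------------------------------------------------
# Term validation


def test_validate_term_descendant_or_self(closures):
    constraint = DescendantOf(HP_ROOT)
    assert validate_term(HP_ROOT, constraint, closures)
    member = next(iter(closures.members(HP_ROOT) - {HP_ROOT}))
    assert validate_term(member, constraint, closures)


def test_validate_term_rejects_bare_label_and_outsiders(closures):
    constraint = DescendantOf(HP_ROOT)
    assert not validate_term("Male", constraint, closures)
    assert not validate_term("http://purl.obolibrary.org/obo/HP_9999999", constraint, closures)


def test_validate_term_missing_parent_is_config_error(closures):
    with pytest.raises(CatalogConfigError):
        validate_term("http://x/y", DescendantOf("http://example.org/unknown"), closures)


# ---------------------------------------------------------------------------
# Table validation


def test_valid_cohort_tables_have_no_issues(catalog, closures, cohort):
    for name, table in cohort.items():
        assert validate_table(table, catalog.get_model(name), closures) == []


def test_single_bad_date_yields_single_issue(tmp_path, catalog, closures):
    path = _write(
        tmp_path,
        "patient_status.csv",
        "pid,row_id,status_uri,death_date\n"
        "P1,R1,http://purl.obolibrary.org/obo/NCIT_C28554,02/01/2019\n",
    )
    table = parse_csv(path, catalog.get_model("patient_status"))
    issues = validate_table(table, catalog.get_model("patient_status"), closures)
    assert [i.code for i in issues] == ["bad_date"]
    assert issues[0].column == "death_date"


def test_duplicate_row_id_reported_per_row(tmp_path, catalog, closures):
    alive = "http://purl.obolibrary.org/obo/NCIT_C37987"
    path = _write(
        tmp_path,
        "patient_status.csv",
        f"pid,row_id,status_uri,death_date\nP1,X,{alive},\nP2,X,{alive},\nP3,R3,{alive},\n",
    )
    table = parse_csv(path, catalog.get_model("patient_status"))
    issues = validate_table(table, catalog.get_model("patient_status"), closures)
    dups = [i for i in issues if i.code == "duplicate_row_id"]
    assert len(dups) == 2 and all(i.row_id == "X" for i in dups)


def test_at_least_one_of_enforced(tmp_path, catalog, closures):
    path = _write(
        tmp_path,
        "undiagnosed.csv",
        "pid,row_id,phenotype_uri,variant_hgvs\nP1,R1,,\n",
    )
    table = parse_csv(path, catalog.get_model("undiagnosed"))
    issues = validate_table(table, catalog.get_model("undiagnosed"), closures)
    assert [i.code for i in issues] == ["missing_required"]


# ---------------------------------------------------------------------------
# Identifier minting


def test_mint_row_id_deterministic_and_distinct():
    clock = datetime.datetime(2021, 6, 1, 12, 0, 0)
    assert mint_row_id(clock, 7) == mint_row_id(clock, 7)
    assert mint_row_id(clock, 0) != mint_row_id(clock, 1)
    assert mint_row_id(clock, 0) != mint_row_id(clock + datetime.timedelta(seconds=1), 0)
    with pytest.raises(ValueError):
        mint_row_id(clock, -1)


def test_mint_row_id_collision_scan():
    """Brute-force uniqueness over 10,000 sequential mints."""
    clock = datetime.datetime(2021, 6, 1, 12, 0, 0)
    ids = {mint_row_id(clock, i) for i in range(10_000)}
    assert len(ids) == 10_000
    assert all(" " not in i and "/" not in i for i in ids)


# ---------------------------------------------------------------------------
# Helpers


def test_translate_labels_repairs_bare_labels(tmp_path, catalog):
    path = _write(
        tmp_path,
        "patient_status.csv",
        "pid,row_id,status_uri,death_date\nP1,R1,Dead,2019-01-02\n",
    )
    template = catalog.get_model("patient_status")
    table = translate_labels(parse_csv(path, template), template, catalog)
    assert table.rows[0].get("status_uri") == catalog.binding("3.1", "Dead")


def test_degrade_birth_dates(cohort):
    table = degrade_birth_dates(cohort["personal_information"])
    for row in table.rows:
        assert len(row.get("birth_date")) == 4 and row.get("birth_date").isdigit()
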