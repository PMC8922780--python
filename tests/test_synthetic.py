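"""Synthetic cohorts: determinism, clinical consistency, injection recall."""

import datetime

import pytest

from cdefair.csv_template import validate_table
from cdefair.synthetic import CohortConfig, generate_cohort, inject_errors, write_cohort


def _by_pid(table):
    return {row.pseudonym: row for row in table.rows}


def test_generation_is_byte_deterministic(tmp_path, catalog):
    config = CohortConfig(n_patients=10, seed=1)
    write_cohort(generate_cohort(config, catalog), tmp_path / "a")
    write_cohort(generate_cohort(config, catalog), tmp_path / "b")
    for path in sorted((tmp_path / "a").iterdir()):
        assert path.read_bytes() == (tmp_path / "b" / path.name).read_bytes()


@pytest.mark.parametrize("seed,n", [(0, 5), (7, 40), (123, 120)])
def test_generator_soundness_zero_issues(catalog, closures, seed, n):
    tables = generate_cohort(CohortConfig(n_patients=n, seed=seed), catalog)
    for name, table in tables.items():
        assert validate_table(table, catalog.get_model(name), closures) == []


def test_clinical_date_orderings_hold(catalog):
    tables = generate_cohort(CohortConfig(n_patients=60, seed=11), catalog)
    birth = {p: datetime.date.fromisoformat(r.get("birth_date"))
             for p, r in _by_pid(tables["personal_information"]).items()}
    history = _by_pid(tables["disease_history"])
    contact = _by_pid(tables["care_pathway"])
    for pid, row in history.items():
        onset = row.get("onset_date")
        diag = row.get("diagnosis_date")
        if onset:
            assert birth[pid] < datetime.date.fromisoformat(onset)
        if onset and diag:
            assert datetime.date.fromisoformat(onset) <= datetime.date.fromisoformat(diag)
        if diag:
            assert (
                datetime.date.fromisoformat(diag)
                <= datetime.date.fromisoformat(contact[pid].get("first_contact_date"))
            )
    dead = catalog.binding("3.1", "Dead")
    for pid, row in _by_pid(tables["patient_status"]).items():
        death = row.get("death_date")
        assert bool(death) == (row.get("status_uri") == dead)
        if death:
            assert datetime.date.fromisoformat(death) > birth[pid]


def test_pseudonyms_shared_across_models(catalog):
    tables = generate_cohort(CohortConfig(n_patients=25, seed=3), catalog)
    universe = {r.pseudonym for r in tables["patient_status"].rows}
    for table in tables.values():
        assert {r.pseudonym for r in table.rows} <= universe


def test_progression_ids_referentially_intact(catalog):
    tables = generate_cohort(
        CohortConfig(n_patients=80, seed=5, model_inclusion={"diagnosis": 0.5, "disease_history": 0.5}),
        catalog,
    )
    diag = {(r.pseudonym, r.get("progression_id")) for r in tables["diagnosis"].rows}
    hist = {(r.pseudonym, r.get("progression_id")) for r in tables["disease_history"].rows}
    assert diag <= hist


def test_inclusion_probability_thins_models(catalog):
    tables = generate_cohort(
        CohortConfig(n_patients=100, seed=2, model_inclusion={"phenotyping": 0.3}),
        catalog,
    )
    assert 10 <= len(tables["phenotyping"]) <= 55
    assert len(tables["patient_status"]) == 100


def test_bad_config_rejected():
    with pytest.raises(ValueError):
        CohortConfig(model_inclusion={"diagnosis": 1.5})
    with pytest.raises(ValueError):
        CohortConfig(date_window=(datetime.date(2020, 1, 1), datetime.date(2019, 1, 1)))


# ---------------------------------------------------------------------------
# Injection


def test_inject_rate_zero_is_identity(catalog, cohort):
    table = cohort["patient_status"]
    corrupted, ledger = inject_errors(table, 0.0, seed=1, catalog=catalog)
    assert ledger == [] and corrupted.rows == table.rows


def test_inject_rate_out_of_range(catalog, cohort):
    with pytest.raises(ValueError):
        inject_errors(cohort["diagnosis"], 1.5, catalog=catalog)
    with pytest.raises(ValueError):
        inject_errors(cohort["diagnosis"], 0.5, kinds=["no_such_code"], catalog=catalog)


def test_inject_saturation_bad_dates(catalog, closures):
    tables = generate_cohort(CohortConfig(n_patients=30, seed=4), catalog)
    table = tables["care_pathway"]
    corrupted, ledger = inject_errors(table, 1.0, kinds=["bad_date"], seed=2, catalog=catalog)
    assert len(ledger) == len(table)
    issues = validate_table(corrupted, catalog.get_model("care_pathway"), closures)
    assert {i.row_id for i in issues if i.code == "bad_date"} == {r[0] for r in ledger}


@pytest.mark.parametrize("seed", [0, 13])
def test_detection_recall_is_total(catalog, closures, seed):
    """Every ledger entry is matched by a reported issue (100% recall)."""
    tables = generate_cohort(CohortConfig(n_patients=50, seed=seed), catalog)
    total = 0
    for name, table in tables.items():
        corrupted, ledger = inject_errors(table, 0.2, seed=seed + 1, catalog=catalog)
        reported = {
            (i.row_id, i.column, i.code)
            for i in validate_table(corrupted, catalog.get_model(name), closures)
        }
        assert set(ledger) <= reported, f"missed injections in {name}"
        total += len(ledger)
    assert total > 30  # the experiment actually injected a fair number
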