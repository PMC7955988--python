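"""Update pipeline: staging, most-recent resolution, delete-and-append."""

import itertools
import random

import pytest

from medlinedb import fixtures as fx
from medlinedb.build import build_baseline
from medlinedb.db import Database, database_state, init_tables
from medlinedb.registry import TMP_PREFIX, VERSIONED_TABLES
from medlinedb.update import (
    UpdatePlan,
    apply_plan,
    resolve_plan,
    stage_updates,
    update_database,
)


def fresh_db():
    d = Database.connect(":memory:")
    init_tables(d)
    return d


def write_update(tmp_path, index, articles, deletions=(), seed=0):
    """One post-baseline file with sequence number ``index``."""
    path = tmp_path / f"pubmed26n{index:04d}.xml.gz"
    fx.write_file(path, articles, list(deletions), seed=seed)
    return str(path)


def test_stage_zero_files_is_noop(db):
    report = stage_updates([], db)
    assert report.files == [] and report.rows_per_table == {}
    assert TMP_PREFIX + "pub" not in db.table_names()


def test_staging_counts_equal_parse_counts(db, tmp_path):
    sizes = fx.PayloadSizes(authors=2, orcids=1)
    f = write_update(tmp_path, 10, [(i, 1, sizes) for i in (1, 2, 3)])
    report = stage_updates([f], db)
    assert report.rows_per_table["author"] == 6
    assert db.row_count(TMP_PREFIX + "author") == 6


def test_staging_is_append_only_across_files(db, tmp_path):
    sizes = fx.PayloadSizes()
    f1 = write_update(tmp_path, 10, [(5, 1, sizes)])
    f2 = write_update(tmp_path, 11, [(5, 1, sizes)])
    stage_updates([f1, f2], db)
    rows = db.fetchall(
        f"SELECT source_file FROM {TMP_PREFIX}pub WHERE pmid = 5 ORDER BY source_file"
    )
    assert [r[0] for r in rows] == ["pubmed26n0010.xml.gz", "pubmed26n0011.xml.gz"]


def test_resolver_same_version_later_file_wins(db, tmp_path):
    sizes = fx.PayloadSizes()
    stage_updates(
        [
            write_update(tmp_path, 10, [(5, 1, sizes)]),
            write_update(tmp_path, 11, [(5, 1, sizes)]),
        ],
        db,
    )
    plan = resolve_plan(db)
    assert plan.winners == {5: (1, "pubmed26n0011.xml.gz")}


def test_resolver_version_dominates_file_order(db, tmp_path):
    sizes = fx.PayloadSizes()
    stage_updates(
        [
            write_update(tmp_path, 10, [(9, 2, sizes)]),
            write_update(tmp_path, 11, [(9, 1, sizes)]),
        ],
        db,
    )
    plan = resolve_plan(db)
    assert plan.winners == {9: (2, "pubmed26n0010.xml.gz")}


def test_resolver_matches_brute_force_replay():
    """Random update/delete schedules agree with a last-event replay."""
    rng = random.Random(99)
    for _ in range(300):
        db = fresh_db()
        n_files = rng.randint(1, 5)
        files = [f"pubmed26n{i + 10:04d}.xml.gz" for i in range(n_files)]
        events = []  # (file_rank, kind, pmid, version)
        with db.transaction():
            init_tables(db, temporary=True)
            for rank, fname in enumerate(files):
                for _ in range(rng.randint(0, 6)):
                    pmid = rng.randint(1, 8)
                    if rng.random() < 0.25:
                        db.execute(
                            "INSERT INTO tmp_deletion (pmid, source_file) "
                            "VALUES (?, ?)",
                            (pmid, fname),
                        )
                        events.append((rank, "delete", pmid, None))
                    else:
                        version = rng.randint(1, 3)
                        db.execute(
                            f"INSERT INTO {TMP_PREFIX}pub "
                            "(pmid, version, title, language, source_file) "
                            "VALUES (?, ?, 't', 'eng', ?)",
                            (pmid, version, fname),
                        )
                        events.append((rank, "update", pmid, version))
        plan = resolve_plan(db)

        # oracle: per pmid, deletion iff no update in a strictly later file;
        # winner = max version, ties to the later file
        expected_winners, expected_deletions = {}, set()
        for pmid in {e[2] for e in events}:
            upd = [(r, v) for r, k, p, v in events if p == pmid and k == "update"]
            dels = [r for r, k, p, _ in events if p == pmid and k == "delete"]
            if dels and (not upd or max(dels) >= max(r for r, _ in upd)):
                expected_deletions.add(pmid)
            elif upd:
                version = max(v for _, v in upd)
                rank = max(r for r, v in upd if v == version)
                expected_winners[pmid] = (version, files[rank])
        assert plan.winners == expected_winners
        assert plan.deletions == expected_deletions
        db.close()


def test_apply_empty_plan_changes_nothing(db):
    init_tables(db, temporary=True)
    report = apply_plan(db, UpdatePlan())
    assert report.rows_deleted == 0
    assert all(v == 0 for v in report.rows_appended.values())


def test_new_pmid_appended_rows_equal_staged_rows(db, tmp_path):
    sizes = fx.PayloadSizes(authors=3, orcids=2)
    f = write_update(tmp_path, 10, [(42, 1, sizes)])
    stage_updates([f], db)
    staged_author = db.row_count(TMP_PREFIX + "author")
    report = apply_plan(db, resolve_plan(db))
    assert report.rows_deleted == 0
    assert report.rows_appended["author"] == staged_author == 3
    assert db.row_count("author") == 3


def test_conservation_appended_equals_staged_winning_rows(db, tmp_path):
    sizes_a, sizes_b = fx.PayloadSizes(authors=1), fx.PayloadSizes(authors=4)
    stage_updates(
        [
            write_update(tmp_path, 10, [(5, 1, sizes_a)]),
            write_update(tmp_path, 11, [(5, 1, sizes_b)]),
        ],
        db,
    )
    staged_winning = db.fetchone(
        f"SELECT COUNT(*) FROM {TMP_PREFIX}author "
        "WHERE pmid = 5 AND version = 1 AND source_file = 'pubmed26n0011.xml.gz'"
    )[0]
    report = apply_plan(db, resolve_plan(db))
    assert report.rows_appended["author"] == staged_winning == 4


ORDERINGS = list(itertools.permutations(["create", "update", "delete"]))


@pytest.mark.parametrize("ordering", ORDERINGS, ids=["-".join(o) for o in ORDERINGS])
def test_all_orderings_of_create_update_delete(tmp_path, ordering):
    """One op per update file, in every order; final state follows the
    most-recent rule: deletion wins iff no article data arrives in a later
    file; otherwise the maximal staged version's rows survive."""
    pmid, seed = 77, 4
    sizes = fx.PayloadSizes()
    files = []
    for i, op in enumerate(ordering):
        if op == "create":
            files.append(write_update(tmp_path, 10 + i, [(pmid, 1, sizes)], seed=seed))
        elif op == "update":
            files.append(write_update(tmp_path, 10 + i, [(pmid, 2, sizes)], seed=seed))
        else:
            files.append(write_update(tmp_path, 10 + i, [], [pmid], seed=seed))
    db = fresh_db()
    update_database(files, db)

    last_article = max(i for i, op in enumerate(ordering) if op != "delete")
    deleted = ordering.index("delete") >= last_article
    if deleted:
        for table in VERSIONED_TABLES:
            assert not db.fetchall(f"SELECT 1 FROM {table} WHERE pmid = ?", (pmid,))
    else:
        expected, _ = fx.article_payload(seed, pmid, 2, sizes)  # v2 = max version
        state = database_state(db)
        for table, rows in expected.items():
            want = {
                tuple(
                    int(v) if isinstance(v, bool) else v
                    for v in (r.get(c) for c in _cols(table))
                )
                for r in rows
            }
            assert set(state[table]) == want, table


def _cols(table):
    from medlinedb.registry import TABLES

    return TABLES[table].column_names


def test_update_after_delete_reinserts_delete_after_update_removes(tmp_path):
    sizes = fx.PayloadSizes()
    db = fresh_db()
    baseline = tmp_path / "pubmed26n0001.xml.gz"
    fx.write_file(baseline, [(3, 1, sizes)], seed=0)
    build_baseline([str(baseline)], db)

    update_database([write_update(tmp_path, 10, [], [3])], db)
    assert not db.fetchall("SELECT 1 FROM pub WHERE pmid = 3")

    update_database([write_update(tmp_path, 11, [(3, 2, sizes)])], db)
    assert db.fetchall("SELECT version FROM pub WHERE pmid = 3") == [(2,)]

    update_database([write_update(tmp_path, 12, [], [3])], db)
    for table in VERSIONED_TABLES:
        assert not db.fetchall(f"SELECT 1 FROM {table} WHERE pmid = 3")


def test_deletion_of_unknown_pmid_is_noop(tmp_path):
    db = fresh_db()
    report = update_database([write_update(tmp_path, 10, [], [12345])], db)
    assert report.plan.deletions == {12345}
    assert report.rows_deleted == 0


def test_idempotent_rerun_is_noop(make_corpus, run_pipelines):
    script, baseline, updates = make_corpus(41, n_pmids=30)
    db = run_pipelines(baseline, updates)
    before = database_state(db)
    report = update_database(baseline + updates, db)
    assert not report.plan.winners and not report.plan.deletions
    assert database_state(db) == before


def test_batch_split_equivalence(make_corpus, run_pipelines):
    for seed in (50, 51, 52, 53, 54):
        script, baseline, updates = make_corpus(seed, n_pmids=25)
        combined = run_pipelines(baseline, updates)
        split = run_pipelines(baseline, updates, per_file_batches=True)
        assert database_state(combined) == database_state(split), seed


def test_post_apply_uniqueness_and_tombstones(make_corpus, run_pipelines):
    script, baseline, updates = make_corpus(61, n_pmids=40)
    db = run_pipelines(baseline, updates)
    deleted = set()
    for _, ev in script.events:
        if ev.kind == "delete":
            deleted.add(ev.pmid)
        else:
            deleted.discard(ev.pmid)
    for table in VERSIONED_TABLES:
        assert not db.fetchall(
            f"SELECT pmid FROM {table} GROUP BY pmid "
            "HAVING COUNT(DISTINCT version) > 1"
        )
        for pmid in deleted:
            assert not db.fetchall(f"SELECT 1 FROM {table} WHERE pmid = ?", (pmid,))


def test_apply_failure_rolls_back_and_keeps_staging(db, tmp_path, monkeypatch):
    sizes = fx.PayloadSizes(authors=2, keywords=1)
    f = write_update(tmp_path, 10, [(6, 1, sizes)])
    stage_updates([f], db)
    plan = resolve_plan(db)
    real = db.execute

    def failing(sql, params=()):
        if sql.startswith("INSERT INTO keyword"):
            raise RuntimeError("boom")
        return real(sql, params)

    monkeypatch.setattr(db, "execute", failing)
    with pytest.raises(RuntimeError, match="boom"):
        apply_plan(db, plan)
    monkeypatch.undo()
    assert db.row_count("pub") == 0
    assert db.row_count(TMP_PREFIX + "pub") == 1  # staging retained for retry
    # the retry succeeds and drops staging
    apply_plan(db, resolve_plan(db))
    assert db.row_count("pub") == 1
    assert TMP_PREFIX + "pub" not in db.table_names()


def test_dry_run_reports_plan_but_changes_nothing(make_corpus):
    script, baseline, updates = make_corpus(71, n_pmids=20)
    db = fresh_db()
    build_baseline(baseline, db)
    before = database_state(db)
    ledger_before = db.row_count("xml_processed")
    report = update_database(updates, db, dry_run=True)
    assert report.dry_run
    assert report.plan.winners or report.plan.deletions
    assert database_state(db) == before
    assert db.row_count("xml_processed") == ledger_before
    assert TMP_PREFIX + "pub" not in db.table_names()
    # a real run afterwards still sees the files as unprocessed
    real = update_database(updates, db)
    assert real.plan.winners == report.plan.winners
    assert real.plan.deletions == report.plan.deletions


def test_end_to_end_matches_replay_oracle(make_corpus, run_pipelines):
    for seed in (81, 82, 83):
        script, baseline, updates = make_corpus(seed, n_pmids=50)
        db = run_pipelines(baseline, updates)
        assert database_state(db) == fx.replay_oracle(script), seed
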