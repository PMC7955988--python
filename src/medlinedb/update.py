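"""Incremental updates: stage post-baseline files, resolve winners, apply.

Post-baseline files carry new, updated and deleted PMIDs.  Their rows are
first parsed into staging twins of the main tables (``tmp_``-prefixed real
tables, each row tagged with its source file), deletion notices into
``tmp_deletion``.  Resolution then picks, per PMID, the most recent data —
maximal version, ties broken by file order — and whether the PMID's last
event is a deletion.  Application replaces each updated PMID's rows
wholesale and tombstones deleted PMIDs (all rows removed, none appended),
in one transaction; the staging tables are dropped only after success, so
a crashed run leaves them behind for inspection and retry.
"""

from __future__ import annotations

import datetime as _dt
import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

from . import ingest
from .build import CHUNK_ARTICLES
from .db import (
    Database,
    FileLogEntry,
    append_batch,
    file_sort_key,
    init_tables,
    log_file,
    unprocessed,
)
from .registry import TMP_DELETION, TMP_PREFIX, VERSIONED_TABLES, get_table

logger = logging.getLogger(__name__)


@dataclass
class UpdatePlan:
    """Resolved merge decision for one staged batch.

    ``winners`` maps each updated PMID to the (version, source file) whose
    rows will replace it; ``deletions`` holds PMIDs whose most recent event
    is a deletion notice.  The two sets are disjoint: a PMID updated and
    later deleted within the batch ends up in ``deletions`` only.
    """

    winners: dict[int, tuple[int, str]] = field(default_factory=dict)
    deletions: set[int] = field(default_factory=set)


@dataclass
class StageReport:
    files: list[str] = field(default_factory=list)
    rows_per_table: dict[str, int] = field(default_factory=dict)
    deletions_staged: int = 0


@dataclass
class ChangeReport:
    plan: UpdatePlan = field(default_factory=UpdatePlan)
    rows_deleted: int = 0
    rows_appended: dict[str, int] = field(default_factory=dict)
    dry_run: bool = False


def _staging_exists(db: Database) -> bool:
    return db.has_table(TMP_PREFIX + "pub")


def stage_updates(
    file_list: Sequence[str],
    db: Database,
    *,
    _in_transaction: bool = False,
) -> StageReport:
    """Parse unprocessed update files into the staging tables.

    Staging twins are created on demand and retained from a previous
    crashed run (their rows are part of the batch being resolved); each
    file's append and ledger entry share one transaction.  With zero
    unprocessed files and no leftover staging this is a no-op.
    """
    todo = unprocessed(file_list, db)
    report = StageReport()
    if not todo and not _staging_exists(db):
        return report
    if not _staging_exists(db):
        init_tables(db, temporary=True)
    for path in todo:
        file_name = os.path.basename(path)

        def _do(path=path, file_name=file_name) -> None:
            per_pmid: dict[int, dict[str, list[dict]]] = {}

            def flush() -> None:
                if not per_pmid:
                    return
                rows_by_table: dict[str, list[dict]] = {}
                keys = []
                for pmid, tables in per_pmid.items():
                    keys.append((pmid, file_name))
                    for table, rows in tables.items():
                        rows_by_table.setdefault(table, []).extend(rows)
                # a later occurrence of a pmid within this file replaces the
                # earlier one, even across chunk boundaries
                for table in VERSIONED_TABLES:
                    db.executemany(
                        f"DELETE FROM {TMP_PREFIX}{table} "
                        "WHERE pmid = ? AND source_file = ?",
                        keys,
                    )
                counts = append_batch(
                    db,
                    ingest.RecordBatch(file_name, rows_by_table),
                    into_temporary=True,
                    _in_transaction=True,
                )
                for table, n in counts.items():
                    report.rows_per_table[table] = (
                        report.rows_per_table.get(table, 0) + n
                    )
                per_pmid.clear()

            for kind, payload in ingest.parse_events(path, file_name):
                if kind == "delete":
                    if payload:
                        db.executemany(
                            f"INSERT INTO {TMP_DELETION} (pmid, source_file) "
                            "VALUES (?, ?)",
                            [(pmid, file_name) for pmid in payload],
                        )
                        report.deletions_staged += len(payload)
                    continue
                pmid = payload["pub"][0]["pmid"]
                if pmid in per_pmid:
                    del per_pmid[pmid]
                per_pmid[pmid] = payload
                if len(per_pmid) >= CHUNK_ARTICLES:
                    flush()
            flush()
            log_file(
                db,
                FileLogEntry(file_name, _dt.datetime.now(_dt.timezone.utc)),
                _in_transaction=True,
            )

        if _in_transaction:
            _do()
        else:
            with db.transaction():
                _do()
        report.files.append(file_name)
        logger.info("staged %s", file_name)
    return report


def resolve_plan(db: Database) -> UpdatePlan:
    """Per-PMID most-recent resolution over the staging tables.

    A PMID's winning rows are those of its maximal staged version; among
    equal versions the later file (in sequence order) wins.  A PMID whose
    last staged event in file order is a deletion notice — a notice in the
    same file outranks that file's article data, since it closes the
    document — is scheduled for tombstone deletion instead.
    """
    plan = UpdatePlan()
    if not _staging_exists(db):
        return plan
    updates: dict[int, tuple[tuple, int, str]] = {}  # pmid -> (best key, version, file)
    last_update_rank: dict[int, tuple] = {}
    for pmid, version, source in db.fetchall(
        f"SELECT DISTINCT pmid, version, source_file FROM {TMP_PREFIX}pub"
    ):
        rank = file_sort_key(source)
        key = (version, rank)
        if pmid not in updates or key > updates[pmid][0]:
            updates[pmid] = (key, version, source)
        if pmid not in last_update_rank or rank > last_update_rank[pmid]:
            last_update_rank[pmid] = rank
    last_delete_rank: dict[int, tuple] = {}
    for pmid, source in db.fetchall(
        f"SELECT pmid, source_file FROM {TMP_DELETION}"
    ):
        rank = file_sort_key(source)
        if pmid not in last_delete_rank or rank > last_delete_rank[pmid]:
            last_delete_rank[pmid] = rank
    for pmid, (_, version, source) in updates.items():
        del_rank = last_delete_rank.get(pmid)
        if del_rank is not None and del_rank >= last_update_rank[pmid]:
            plan.deletions.add(pmid)
        else:
            plan.winners[pmid] = (version, source)
    for pmid in last_delete_rank:
        if pmid not in updates:
            plan.deletions.add(pmid)
    return plan


def apply_plan(db: Database, plan: UpdatePlan) -> ChangeReport:
    """Delete-and-append the plan into the main tables, then drop staging.

    One transaction: every winner PMID's old rows are removed from every
    versioned table and exactly its winning (version, file) staged rows
    appended; deletion PMIDs are removed everywhere with nothing appended
    (a PMID never seen before is a logged no-op).  Mid-apply failure rolls
    the whole batch back and keeps the staging tables for retry.
    """
    report = ChangeReport(plan=plan)
    if not _staging_exists(db):
        return report
    touched = sorted(set(plan.winners) | plan.deletions)
    with db.transaction():
        for table in VERSIONED_TABLES:
            cur = 0
            for pmid in touched:
                c = db.execute(f"DELETE FROM {table} WHERE pmid = ?", (pmid,))
                cur += c.rowcount
            report.rows_deleted += cur
            spec = get_table(table)
            cols = ", ".join(spec.column_names)
            appended = 0
            for pmid, (version, source) in sorted(plan.winners.items()):
                c = db.execute(
                    f"INSERT INTO {table} ({cols}) "
                    f"SELECT {cols} FROM {TMP_PREFIX}{table} "
                    f"WHERE pmid = ? AND version = ? AND source_file = ?",
                    (pmid, version, source),
                )
                appended += c.rowcount
            report.rows_appended[table] = appended
    drop_staging(db)
    return report


def drop_staging(db: Database) -> None:
    with db.transaction():
        for table in VERSIONED_TABLES:
            db.drop_table(TMP_PREFIX + table)
        db.drop_table(TMP_DELETION)


def update_database(
    file_list: Sequence[str], db: Database, dry_run: bool = False
) -> ChangeReport:
    """Stage unprocessed update files, resolve, and apply (or, with
    ``dry_run``, report the plan and change nothing — not even the ledger).
    """
    if dry_run:
        staged_before = _staging_exists(db)
        try:
            with db.transaction():
                stage_updates(file_list, db, _in_transaction=True)
                plan = resolve_plan(db)
                report = ChangeReport(plan=plan, dry_run=True)
                raise _Rollback(report)
        except _Rollback as rb:
            if not staged_before:
                # the rollback removed the rows but staging DDL may remain
                if _staging_exists(db):
                    drop_staging(db)
            return rb.report
    report_stage = stage_updates(file_list, db)
    if not report_stage.files and not _staging_exists(db):
        return ChangeReport()
    plan = resolve_plan(db)
    return apply_plan(db, plan)


class _Rollback(Exception):
    def __init__(self, report: ChangeReport) -> None:
        self.report = report
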