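"""Baseline build: parse every baseline file, append, log, reduce to latest.

The annual baseline is a fixed set of XML files.  Each file is parsed,
appended to the main tables and logged to the ``xml_processed`` ledger
inside one transaction, in file order.  A PMID can legitimately recur
across baseline files — and even recur at the same version number — so
appends first drop any rows already present for the incoming
(pmid, version) pairs, making the later file the winner on a version tie.
After the last file, :func:`keep_latest` reduces every versioned table to
each PMID's maximal version.

With one worker, each file is consumed as a stream and appended in bounded
chunks, so memory stays flat however large the file; with several workers,
whole files are parsed concurrently in subprocesses and appended serially
in file order (memory is then bounded by a file, the price of parallel
parsing).  Interrupted builds resume: the ledger records completed files,
so a re-run skips them, and per-(pmid, version) replacement makes a
replayed file harmless.
"""

from __future__ import annotations

import datetime as _dt
import logging
import os
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Sequence

from . import ingest
from .db import Database, FileLogEntry, append_batch, log_file, unprocessed
from .registry import VERSIONED_TABLES

logger = logging.getLogger(__name__)

#: Articles buffered between appends on the streaming path.
CHUNK_ARTICLES = 2000


class BuildError(RuntimeError):
    pass


@dataclass
class BuildReport:
    """Outcome of one baseline build."""

    files_processed: int = 0
    rows_per_table: dict[str, int] = field(default_factory=dict)
    rows_removed: int = 0


def _flatten(per_pmid: dict[int, dict[str, list[dict]]], file_name: str) -> ingest.RecordBatch:
    rows_by_table: dict[str, list[dict]] = {}
    for tables in per_pmid.values():
        for table, rows in tables.items():
            rows_by_table.setdefault(table, []).extend(rows)
    return ingest.RecordBatch(source_file=file_name, rows_by_table=rows_by_table)


def upsert_rows(db: Database, batch: ingest.RecordBatch) -> dict[str, int]:
    """Insert a batch after dropping rows already held for its (pmid, version)s.

    The pre-delete makes re-appends and cross-file version ties land on the
    most recently processed data.  Caller manages the transaction.
    """
    keys = sorted({(r["pmid"], r["version"]) for r in batch.rows_by_table.get("pub", ())})
    for table in VERSIONED_TABLES:
        db.executemany(f"DELETE FROM {table} WHERE pmid = ? AND version = ?", keys)
    return append_batch(db, batch, _in_transaction=True)


def append_article_batch(db: Database, batch: ingest.RecordBatch) -> dict[str, int]:
    """Append one parsed file to the mains and log it, as one transaction."""
    with db.transaction():
        counts = upsert_rows(db, batch)
        log_file(
            db,
            FileLogEntry(batch.source_file, _dt.datetime.now(_dt.timezone.utc)),
            _in_transaction=True,
        )
    return counts


def _stream_append_file(db: Database, path: str) -> None:
    """Stream one baseline file into the mains in bounded chunks."""
    file_name = os.path.basename(path)
    with db.transaction():
        per_pmid: dict[int, dict[str, list[dict]]] = {}

        def flush() -> None:
            if per_pmid:
                upsert_rows(db, _flatten(per_pmid, file_name))
                per_pmid.clear()

        for kind, payload in ingest.parse_events(path, file_name):
            if kind == "delete":
                if payload:
                    raise BuildError(
                        f"baseline file {file_name!r} carries deletion notices"
                    )
                continue
            pmid = payload["pub"][0]["pmid"]
            if pmid in per_pmid:
                del per_pmid[pmid]  # last occurrence wins, freshest position
            per_pmid[pmid] = payload
            if len(per_pmid) >= CHUNK_ARTICLES:
                flush()
        flush()
        log_file(
            db,
            FileLogEntry(file_name, _dt.datetime.now(_dt.timezone.utc)),
            _in_transaction=True,
        )


def keep_latest(db: Database, table_name: str) -> int:
    """Drop every row of ``table_name`` below its PMID's maximal version.

    Set-based anti-join — one statement per table, no per-row cursoring —
    since the real corpus has tens of millions of rows per table.  Returns
    the number of rows removed.
    """
    with db.transaction():
        cur = db.execute(
            f"DELETE FROM {table_name} WHERE version < "
            f"(SELECT MAX(version) FROM {table_name} t2 "
            f"WHERE t2.pmid = {table_name}.pmid)"
        )
        return cur.rowcount


def build_baseline(
    file_list: Sequence[str], db: Database, worker_count: int = 1
) -> BuildReport:
    """Create the database from the baseline files.

    Every file is parsed, appended and logged; versioned tables are then
    reduced to the latest version of each PMID.  Baseline files carry no
    deletion notices — finding one aborts the build.  The final report's
    per-table totals are the post-reduction row counts.
    """
    if not file_list:
        raise BuildError("empty baseline file list")
    if worker_count < 1:
        raise ValueError("worker_count must be >= 1")
    todo = unprocessed(file_list, db)
    done_before = len(file_list) - len(todo)
    if done_before:
        logger.info("resuming build: %d file(s) already processed", done_before)
    report = BuildReport(files_processed=done_before)
    if worker_count == 1 or len(todo) <= 1:
        for path in todo:
            _stream_append_file(db, path)
            report.files_processed += 1
            logger.info("processed %s", os.path.basename(path))
    else:
        with ProcessPoolExecutor(max_workers=worker_count) as pool:
            for batch in pool.map(ingest.parse_file, todo):
                if batch.deleted_pmids:
                    raise BuildError(
                        f"baseline file {batch.source_file!r} carries deletion notices"
                    )
                append_article_batch(db, batch)
                report.files_processed += 1
                logger.info("processed %s", batch.source_file)
    for table in VERSIONED_TABLES:
        report.rows_removed += keep_latest(db, table)
        report.rows_per_table[table] = db.row_count(table)
    return report
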