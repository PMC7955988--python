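"""Example bibliometric analyses over the built database.

Two demonstration queries, each a join of a handful of the per-data-type
tables:

* authors per publication, grouped by year — ``pub_history`` ⋈ ``author``
  on ``pmid``;
* fraction of author names carrying an ORCID, grouped by month —
  ``pub_history`` ⋈ ``author`` ⋈ ``author_identifier`` on
  ``(pmid, author_pos)``.

A publication's year or month comes from its history: the earliest event
with the configured status (default ``entrez``, the database-entry stamp,
present on essentially every record).  Periods with no publications are
omitted, not zero-filled.

Caveat for historical data: the upstream indexing rules truncated long
author lists (at most 10 authors entered for records created 1984–1995,
at most 25 for 1996–1999).  Truncation does not move the median or the
interquartile range, but it biases the mean downward in those years.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .db import Database

DEFAULT_STATUS = "entrez"


def _per_pub_period(db: Database, status: str, width: int) -> str:
    # earliest event with the grouping status; substr(ISO date) gives the period
    return (
        f"SELECT pmid, substr(MIN(event_date), 1, {width}) AS period "
        "FROM pub_history WHERE pub_status = ? AND event_date IS NOT NULL "
        "GROUP BY pmid"
    )


def authors_per_pub_by_year(
    db: Database,
    year_range: tuple[int, int] = (1920, 2020),
    status: str = DEFAULT_STATUS,
) -> pd.DataFrame:
    """Distribution of the number of authors per publication, by year.

    Returns one row per year with at least one publication:
    ``(year, n_pubs, mean, median, q1, q3)`` of the per-publication author
    counts.  A publication's author count is its number of ``author`` rows
    (collective names included — each is one author-list entry);
    publications with no author rows are outside the join, as in a plain
    inner join of the two tables.
    """
    rows = db.fetchall(
        f"SELECT ph.period, a.pmid, COUNT(*) AS n_authors "
        f"FROM ({_per_pub_period(db, status, 4)}) ph "
        "JOIN author a ON a.pmid = ph.pmid "
        "GROUP BY ph.period, a.pmid",
        (status,),
    )
    cols = ["year", "n_pubs", "mean", "median", "q1", "q3"]
    if not rows:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows, columns=["year", "pmid", "n_authors"])
    df["year"] = df["year"].astype(int)
    lo, hi = year_range
    df = df[(df["year"] >= lo) & (df["year"] <= hi)]
    if df.empty:
        return pd.DataFrame(columns=cols)
    out = (
        df.groupby("year")["n_authors"]
        .agg(
            n_pubs="size",
            mean="mean",
            median="median",
            q1=lambda s: float(np.percentile(s, 25)),
            q3=lambda s: float(np.percentile(s, 75)),
        )
        .reset_index()
    )
    return out[cols]


def orcid_fraction_by_month(
    db: Database,
    month_range: tuple[str, str] = ("2013-01", "2020-08"),
    status: str = DEFAULT_STATUS,
) -> pd.DataFrame:
    """Percentage of author names with an ORCID identifier, by month.

    Returns ``(month, n_author_names, n_with_orcid, percent)`` for each
    ``YYYY-MM`` month in range with at least one author name; months with
    no publications are omitted.  Every author row counts in the
    denominator whether or not it has identifier rows; the numerator
    counts author rows with at least one ORCID-source identifier.
    """
    rows = db.fetchall(
        f"SELECT ph.period, COUNT(*) AS n_names, "
        "SUM(CASE WHEN ai.pmid IS NOT NULL THEN 1 ELSE 0 END) AS n_orcid "
        f"FROM ({_per_pub_period(db, status, 7)}) ph "
        "JOIN author a ON a.pmid = ph.pmid "
        "LEFT JOIN (SELECT DISTINCT pmid, author_pos FROM author_identifier "
        "           WHERE identifier_source = 'ORCID') ai "
        "ON ai.pmid = a.pmid AND ai.author_pos = a.author_pos "
        "GROUP BY ph.period",
        (status,),
    )
    cols = ["month", "n_author_names", "n_with_orcid", "percent"]
    if not rows:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows, columns=["month", "n_author_names", "n_with_orcid"])
    lo, hi = month_range
    df = df[(df["month"] >= lo) & (df["month"] <= hi)].reset_index(drop=True)
    if df.empty:
        return pd.DataFrame(columns=cols)
    df["percent"] = 100.0 * df["n_with_orcid"] / df["n_author_names"]
    return df.sort_values("month").reset_index(drop=True)[cols]
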