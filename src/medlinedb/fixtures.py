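"""Synthetic PubMed-style XML corpora and the ground-truth replay oracle.

Real baseline and post-baseline files are tens of thousands of deeply
nested article records; at desk scale we emulate the features the pipelines
actually have to survive: multi-article files, nested author / identifier /
history / MeSH structure, PMIDs carrying a ``Version`` attribute, the same
PMID reappearing across files with changed content, and ``DeleteCitation``
notices.

A corpus is described by an :class:`EventScript` — an ordered list of
create / update / delete events assigned to numbered files.  Two consumers
share nothing but the script:

* :func:`generate` renders the events into gzip XML files (byte-identical
  for a fixed seed), named with the zero-padded sequence pattern so the
  pipelines' file-ordering logic is exercised;
* :func:`replay_oracle` computes the expected final database state by
  straightforward per-event replay — the brute-force statement of the
  "most recent version, most recent file" rule, sharing no code with the
  build or update pipelines.

Article content is a pure function of ``(seed, pmid, version, sizes)``, so
the oracle can reconstruct exactly the rows the parser will extract from
the generated XML.
"""

from __future__ import annotations

import gzip
import random
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

from .registry import TABLES, VERSIONED_TABLES

# -- seeded vocabularies ---------------------------------------------------

LAST_NAMES = (
    "Smith Johnson Lee Chen Wang García-López Müller O'Brien Kim Patel Nguyen "
    "Ivanov Sato Kowalski Rossi Silva Andersen Novak Fischer Dubois Okafor "
    "Haddad Lindström Costa Moreau Petrov Tanaka Berg Romero Ali"
).split()

FORE_NAMES = (
    "James Mary Wei Yuki Priya Anna Omar Lars Sofia Pierre Elena Raj Hana "
    "Marco Ingrid Kofi Amira Jan Lucia Tom"
).split()

COLLECTIVE_NAMES = (
    "International Trial Consortium",
    "Genome Curation Working Group",
    "COVID Outcomes Network",
    "Rare Disease Registry Investigators",
)

JOURNALS = (
    ("Journal of Synthetic Biology", "1234-5678"),
    ("Annals of Test Medicine", "2345-6789"),
    ("Archives of Fixture Research", "3456-7890"),
    ("Computational Bibliometrics", "4567-8901"),
    ("The Placeholder Lancet", "5678-9012"),
)

MESH_TERMS = tuple(
    (term, f"D{idx:06d}")
    for idx, term in enumerate(
        (
            "Humans Animals Mice Neoplasms Inflammation Genomics Proteomics "
            "Epidemiology Algorithms Software Databases Phylogeny Mutation "
            "Biomarkers Metabolomics Microbiota Vaccines Aging Sleep Pain"
        ).split(),
        start=1,
    )
)

KEYWORDS = (
    "machine learning,bibliometrics,open science,reproducibility,"
    "meta-research,text mining,data sharing,peer review"
).split(",")

TITLE_WORDS = (
    "systematic analysis of longitudinal cohort reveals novel dynamics in "
    "clinical translational synthetic model networks expression profiles"
).split()

HISTORY_STATUSES = ("received", "accepted", "revised", "pubmed", "medline")

AGENCIES = (("NIGMS NIH HHS", "United States"), ("Wellcome Trust", "United Kingdom"))


# -- script model ----------------------------------------------------------


@dataclass(frozen=True)
class PayloadSizes:
    """Row counts per data type for one article revision."""

    authors: int = 2
    orcids: int = 1
    history: int = 3
    mesh: int = 2
    keywords: int = 1
    grants: int = 0
    collective: bool = False

    def __post_init__(self) -> None:
        if self.authors < 0 or self.history < 1:
            raise ValueError("authors >= 0 and history >= 1 required")
        if not 0 <= self.orcids <= self.authors:
            raise ValueError("orcids must be between 0 and authors")
        if self.authors == 0 and not self.collective:
            raise ValueError("an article needs at least one author row")


@dataclass(frozen=True)
class Event:
    """One scripted change: create or update an article, or delete its PMID."""

    kind: str  # 'create' | 'update' | 'delete'
    pmid: int
    version: int = 1
    sizes: PayloadSizes | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("create", "update", "delete"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.pmid < 1 or self.version < 1:
            raise ValueError("pmid and version must be >= 1")
        if self.kind != "delete" and self.sizes is None:
            object.__setattr__(self, "sizes", PayloadSizes())


@dataclass
class EventScript:
    """Ordered (file_index, event) pairs over baseline + update files.

    File indices ``0 .. n_baseline_files-1`` are baseline files; the rest
    are post-baseline update files.  Valid scripts create a PMID before
    updating or deleting it, keep versions non-decreasing per PMID, and put
    deletion notices only in update files.
    """

    seed: int
    n_baseline_files: int
    n_update_files: int
    events: list[tuple[int, Event]] = field(default_factory=list)

    @property
    def n_files(self) -> int:
        return self.n_baseline_files + self.n_update_files


class ScriptError(ValueError):
    """An :class:`EventScript` violates its invariants."""


def validate_script(script: EventScript) -> None:
    seen: dict[int, int] = {}  # pmid -> last version
    last_file = -1
    for file_index, ev in script.events:
        if not 0 <= file_index < script.n_files:
            raise ScriptError(f"event {ev} targets nonexistent file {file_index}")
        if file_index < last_file:
            raise ScriptError("events must be ordered by file index")
        last_file = file_index
        if ev.kind == "create":
            if ev.pmid in seen:
                raise ScriptError(f"pmid {ev.pmid} created twice")
            seen[ev.pmid] = ev.version
        elif ev.kind == "update":
            if ev.pmid not in seen:
                raise ScriptError(f"pmid {ev.pmid} updated before create: {ev}")
            if ev.version < seen[ev.pmid]:
                raise ScriptError(
                    f"pmid {ev.pmid} version decreases "
                    f"({seen[ev.pmid]} -> {ev.version})"
                )
            seen[ev.pmid] = ev.version
        else:  # delete
            if ev.pmid not in seen:
                raise ScriptError(f"pmid {ev.pmid} deleted before create: {ev}")
            if file_index < script.n_baseline_files:
                raise ScriptError(
                    f"deletion of pmid {ev.pmid} scripted in baseline file "
                    f"{file_index}; deletions are update-file only"
                )


# -- deterministic article content ----------------------------------------


def _article_rng(seed: int, pmid: int, version: int) -> random.Random:
    return random.Random(f"{seed}:{pmid}:{version}")


def _orcid(rng: random.Random) -> str:
    """Random ORCID with a valid ISO 7064 MOD 11-2 check character."""
    digits = [rng.randrange(10) for _ in range(15)]
    total = 0
    for d in digits:
        total = (total + d) * 2
    check = (12 - total % 11) % 11
    s = "".join(map(str, digits)) + ("X" if check == 10 else str(check))
    return f"{s[0:4]}-{s[4:8]}-{s[8:12]}-{s[12:16]}"


def _date(rng: random.Random) -> tuple[str, str]:
    """(ISO date, precision); day padded with 1 when the source omits it."""
    year = rng.randint(1950, 2024)
    roll = rng.random()
    if roll < 0.05:
        return f"{year:04d}-01-01", "year"
    month = rng.randint(1, 12)
    if roll < 0.15:
        return f"{year:04d}-{month:02d}-01", "month"
    day = rng.randint(1, 28)
    return f"{year:04d}-{month:02d}-{day:02d}", "day"


def article_payload(
    seed: int, pmid: int, version: int, sizes: PayloadSizes
) -> tuple[dict[str, list[dict]], dict]:
    """Rows (exactly as the parser will emit them) plus XML rendering hints.

    The hints carry presentation detail that the relational rows
    deliberately normalize away: raw ORCID spellings (URL prefix, missing
    dashes), the abstract's label, and whether a ``Version="1"`` attribute
    is written explicitly or left to the document default.
    """
    rng = _article_rng(seed, pmid, version)
    base = {"pmid": pmid, "version": version}
    rows: dict[str, list[dict]] = {}
    hints: dict = {}

    def add(table: str, **cols) -> None:
        rows.setdefault(table, []).append({**base, **cols})

    title = " ".join(rng.sample(TITLE_WORDS, 5)).capitalize()
    add("pub", title=f"{title} (study {pmid} v{version}).", language="eng")

    name, issn = rng.choice(JOURNALS)
    add(
        "journal",
        journal_name=name,
        issn=issn,
        volume=str(rng.randint(1, 120)),
        issue=str(rng.randint(1, 12)),
    )

    statuses = ["entrez"] + rng.sample(HISTORY_STATUSES, sizes.history - 1)
    for status in statuses:
        date, precision = _date(rng)
        add("pub_history", pub_status=status, event_date=date, date_precision=precision)

    for pos in range(1, sizes.authors + 1):
        last = rng.choice(LAST_NAMES)
        fore = rng.choice(FORE_NAMES)
        add(
            "author",
            author_pos=pos,
            last_name=last,
            fore_name=fore,
            initials=fore[0],
            suffix="Jr" if rng.random() < 0.05 else None,
            collective_name=None,
        )
    if sizes.collective:
        add(
            "author",
            author_pos=sizes.authors + 1,
            last_name=None,
            fore_name=None,
            initials=None,
            suffix=None,
            collective_name=rng.choice(COLLECTIVE_NAMES),
        )

    orcid_styles = []
    for pos in range(1, sizes.orcids + 1):
        add(
            "author_identifier",
            author_pos=pos,
            identifier_source="ORCID",
            identifier=_orcid(rng),
        )
        orcid_styles.append(rng.choice(("plain", "url", "nodash")))
    hints["orcid_styles"] = orcid_styles

    label = rng.choice((None, None, None, "BACKGROUND"))
    abstract_text = (
        f"We report {rng.choice(TITLE_WORDS)} findings for record {pmid}, "
        f"revision {version}."
    )
    hints["abstract"] = (label, abstract_text)
    add("abstract", text=f"{label}: {abstract_text}" if label else abstract_text)

    for term, ui in rng.sample(MESH_TERMS, sizes.mesh):
        add("mesh_term", term=term, ui=ui, major_topic=rng.random() < 0.3)

    for kw in rng.sample(KEYWORDS, sizes.keywords):
        add("keyword", keyword=kw)

    for i in range(sizes.grants):
        agency, country = rng.choice(AGENCIES)
        add(
            "grant_item",
            grant_id=f"R{rng.randint(1, 99):02d} GM{rng.randint(100000, 999999)}",
            agency=agency,
            country=country,
        )

    add("pub_type", type_name="Journal Article", ui="D016428")

    add("article_id", id_type="pubmed", id_value=str(pmid))
    add("article_id", id_type="doi", id_value=f"10.5555/synth.{pmid}.v{version}")

    hints["explicit_version"] = version != 1 or rng.random() < 0.5
    return rows, hints


# -- XML rendering ---------------------------------------------------------


def _sub(parent: etree._Element, tag: str, text: str | None = None, **attrs):
    el = etree.SubElement(parent, tag, **attrs)
    if text is not None:
        el.text = text
    return el


def _render_date(parent: etree._Element, iso: str, precision: str) -> None:
    y, m, d = iso.split("-")
    _sub(parent, "Year", y)
    if precision in ("month", "day"):
        _sub(parent, "Month", m)
    if precision == "day":
        _sub(parent, "Day", d)


def build_article_element(
    seed: int, pmid: int, version: int, sizes: PayloadSizes
) -> etree._Element:
    """One ``PubmedArticle`` element whose parse yields ``article_payload`` rows."""
    rows, hints = article_payload(seed, pmid, version, sizes)
    article = etree.Element("PubmedArticle")
    citation = _sub(article, "MedlineCitation", Status="MEDLINE")
    if hints["explicit_version"]:
        _sub(citation, "PMID", str(pmid), Version=str(version))
    else:
        _sub(citation, "PMID", str(pmid))

    art = _sub(citation, "Article")
    jrow = rows["journal"][0]
    journal = _sub(art, "Journal")
    _sub(journal, "ISSN", jrow["issn"], IssnType="Print")
    issue = _sub(journal, "JournalIssue")
    _sub(issue, "Volume", jrow["volume"])
    _sub(issue, "Issue", jrow["issue"])
    _sub(journal, "Title", jrow["journal_name"])
    _sub(art, "ArticleTitle", rows["pub"][0]["title"])

    label, abstract_text = hints["abstract"]
    abstract = _sub(art, "Abstract")
    if label:
        _sub(abstract, "AbstractText", abstract_text, Label=label)
    else:
        _sub(abstract, "AbstractText", abstract_text)

    author_list = _sub(art, "AuthorList", CompleteYN="Y")
    idents = {r["author_pos"]: r for r in rows.get("author_identifier", ())}
    for i, arow in enumerate(rows["author"]):
        author = _sub(author_list, "Author", ValidYN="Y")
        if arow["collective_name"] is not None:
            _sub(author, "CollectiveName", arow["collective_name"])
        else:
            _sub(author, "LastName", arow["last_name"])
            _sub(author, "ForeName", arow["fore_name"])
            _sub(author, "Initials", arow["initials"])
            if arow["suffix"]:
                _sub(author, "Suffix", arow["suffix"])
        ident = idents.get(arow["author_pos"])
        if ident is not None:
            style = hints["orcid_styles"][arow["author_pos"] - 1]
            value = ident["identifier"]
            if style == "url":
                value = f"https://orcid.org/{value}"
            elif style == "nodash":
                value = value.replace("-", "")
            _sub(author, "Identifier", value, Source="ORCID")

    _sub(art, "Language", rows["pub"][0]["language"])

    if rows.get("grant_item"):
        grant_list = _sub(art, "GrantList", CompleteYN="Y")
        for g in rows["grant_item"]:
            grant = _sub(grant_list, "Grant")
            _sub(grant, "GrantID", g["grant_id"])
            _sub(grant, "Agency", g["agency"])
            _sub(grant, "Country", g["country"])

    ptl = _sub(art, "PublicationTypeList")
    for p in rows["pub_type"]:
        _sub(ptl, "PublicationType", p["type_name"], UI=p["ui"])

    if rows.get("mesh_term"):
        mesh_list = _sub(citation, "MeshHeadingList")
        for m in rows["mesh_term"]:
            heading = _sub(mesh_list, "MeshHeading")
            _sub(
                heading,
                "DescriptorName",
                m["term"],
                UI=m["ui"],
                MajorTopicYN="Y" if m["major_topic"] else "N",
            )

    if rows.get("keyword"):
        kw_list = _sub(citation, "KeywordList", Owner="NOTNLM")
        for k in rows["keyword"]:
            _sub(kw_list, "Keyword", k["keyword"], MajorTopicYN="N")

    pubmed_data = _sub(article, "PubmedData")
    history = _sub(pubmed_data, "History")
    for h in rows["pub_history"]:
        event = _sub(history, "PubMedPubDate", PubStatus=h["pub_status"])
        _render_date(event, h["event_date"], h["date_precision"])
    id_list = _sub(pubmed_data, "ArticleIdList")
    for a in rows["article_id"]:
        _sub(id_list, "ArticleId", a["id_value"], IdType=a["id_type"])

    return article


def write_file(
    path,
    articles: list[tuple[int, int, PayloadSizes]],
    deletions: list[int] = (),
    *,
    seed: int = 0,
) -> None:
    """Write one gzip ``PubmedArticleSet`` file.

    ``articles`` is a list of (pmid, version, sizes) rendered in order;
    ``deletions`` become a trailing ``DeleteCitation`` element.  The gzip
    header's mtime is pinned so identical inputs give identical bytes.
    This low-level writer enforces no script invariants — tests use it to
    construct pathological event orderings directly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as raw:
        with gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0) as gz:
            with etree.xmlfile(gz, encoding="utf-8") as xf:
                xf.write_declaration()
                with xf.element("PubmedArticleSet"):
                    for pmid, version, sizes in articles:
                        xf.write(build_article_element(seed, pmid, version, sizes))
                        xf.flush()
                    if deletions:
                        dc = etree.Element("DeleteCitation")
                        for pmid in deletions:
                            _sub(dc, "PMID", str(pmid), Version="1")
                        xf.write(dc)


def file_names(script: EventScript) -> list[str]:
    """Sequence-patterned names, baseline first; updates continue the numbering."""
    return [
        f"pubmed26n{i + 1:04d}.xml.gz" for i in range(script.n_files)
    ]


def generate(script: EventScript, output_dir) -> list[str]:
    """Render the script into gzip XML files; returns paths, baseline first.

    Baseline files land in ``output_dir/baseline`` and update files in
    ``output_dir/updatefiles``, mirroring the NLM layout.  Deterministic:
    the same script yields byte-identical files.
    """
    validate_script(script)
    output_dir = Path(output_dir)
    names = file_names(script)
    per_file_articles: dict[int, list] = {i: [] for i in range(script.n_files)}
    per_file_deletions: dict[int, list[int]] = {i: [] for i in range(script.n_files)}
    for file_index, ev in script.events:
        if ev.kind == "delete":
            per_file_deletions[file_index].append(ev.pmid)
        else:
            per_file_articles[file_index].append((ev.pmid, ev.version, ev.sizes))
    paths = []
    for i, name in enumerate(names):
        sub = "baseline" if i < script.n_baseline_files else "updatefiles"
        path = output_dir / sub / name
        write_file(
            path,
            per_file_articles[i],
            per_file_deletions[i],
            seed=script.seed,
        )
        paths.append(str(path))
    return paths


def declared_counts(script: EventScript) -> dict[str, dict[str, int]]:
    """Per-file article and deletion counts the generator commits to."""
    counts: dict[str, dict[str, int]] = {
        name: {"articles": 0, "deletions": 0} for name in file_names(script)
    }
    names = file_names(script)
    for file_index, ev in script.events:
        key = "deletions" if ev.kind == "delete" else "articles"
        counts[names[file_index]][key] += 1
    return counts


# -- ground-truth oracle ---------------------------------------------------


def replay_oracle(script: EventScript) -> dict[str, dict[tuple, int]]:
    """Expected final state: row multiset per versioned table.

    Replays events one by one — each create/update overwrites the PMID's
    current (version, sizes), each delete removes it — then materializes the
    survivors' rows.  Row tuples follow the registry column order, with
    booleans stored as 0/1 as the database does.
    """
    validate_script(script)
    live: dict[int, tuple[int, PayloadSizes]] = {}
    for _, ev in script.events:
        if ev.kind == "delete":
            live.pop(ev.pmid, None)
        else:
            live[ev.pmid] = (ev.version, ev.sizes)

    state: dict[str, dict[tuple, int]] = {t: {} for t in VERSIONED_TABLES}
    for pmid, (version, sizes) in live.items():
        rows, _ = article_payload(script.seed, pmid, version, sizes)
        for table, table_rows in rows.items():
            cols = TABLES[table].column_names
            bucket = state[table]
            for row in table_rows:
                key = tuple(
                    int(v) if isinstance(v, bool) else v
                    for v in (row.get(c) for c in cols)
                )
                bucket[key] = bucket.get(key, 0) + 1
    return state


# -- randomized scripts ----------------------------------------------------


def random_sizes(rng: random.Random) -> PayloadSizes:
    authors = rng.randint(1, 4)
    return PayloadSizes(
        authors=authors,
        orcids=rng.randint(0, authors),
        history=rng.randint(1, 4),
        mesh=rng.randint(0, 3),
        keywords=rng.randint(0, 2),
        grants=rng.randint(0, 1),
        collective=rng.random() < 0.1,
    )


def random_script(
    seed: int,
    n_pmids: int = 50,
    n_baseline_files: int = 2,
    n_update_files: int = 3,
    multi_version_frac: float = 0.1,
    update_frac: float = 0.4,
    delete_frac: float = 0.1,
) -> EventScript:
    """A valid random script with updates, version bumps, and deletions.

    Defaults model a small corpus where most PMIDs have a single version
    (as in the real data, where multi-version records are the exception),
    roughly a tenth of PMIDs gain a second version, and a tenth are
    eventually deleted.  Some PMIDs first appear in update files, as new
    articles do after the annual baseline.
    """
    rng = random.Random(seed)
    pmids = sorted(rng.sample(range(100, 9_999_999), n_pmids))
    per_file: dict[int, list[Event]] = {
        i: [] for i in range(n_baseline_files + n_update_files)
    }
    for pmid in pmids:
        if n_update_files and rng.random() < 0.15:
            create_file = n_baseline_files + rng.randrange(n_update_files)
        else:
            create_file = rng.randrange(n_baseline_files)
        version = 1
        per_file[create_file].append(Event("create", pmid, version, random_sizes(rng)))
        last_file = create_file
        if n_update_files and rng.random() < update_frac:
            for _ in range(rng.randint(1, 2)):
                lo = max(last_file, n_baseline_files)
                upd_file = rng.randint(lo, n_baseline_files + n_update_files - 1)
                if rng.random() < multi_version_frac:
                    version += 1
                per_file[upd_file].append(
                    Event("update", pmid, version, random_sizes(rng))
                )
                last_file = upd_file
        if n_update_files and rng.random() < delete_frac:
            del_file = rng.randint(
                max(last_file, n_baseline_files), n_baseline_files + n_update_files - 1
            )
            per_file[del_file].append(Event("delete", pmid))
            last_file = del_file
            if rng.random() < 0.3 and last_file < n_baseline_files + n_update_files - 1:
                # resurrection: an update after the delete re-creates the record
                version += 1
                re_file = rng.randint(
                    last_file, n_baseline_files + n_update_files - 1
                )
                per_file[re_file].append(
                    Event("update", pmid, version, random_sizes(rng))
                )
    events: list[tuple[int, Event]] = []
    for i in sorted(per_file):
        rng.shuffle(per_file[i])
        events.extend((i, ev) for ev in per_file[i])
    # within-file shuffling may put an update/delete before its create or
    # invert versions; restore a valid order inside each file
    events = _restore_order(events)
    script = EventScript(seed, n_baseline_files, n_update_files, events)
    validate_script(script)
    return script


def _restore_order(events: list[tuple[int, Event]]) -> list[tuple[int, Event]]:
    """Stable-sort events within each file so per-PMID order is create-first,
    versions non-decreasing, deletes between the versions they separate."""
    ranked = [(fi, ev, idx) for idx, (fi, ev) in enumerate(events)]
    # deletes carry version 1 by default, which would sort them before the
    # updates they must follow; rank them at the pmid's maximal version and
    # after same-version articles (a DeleteCitation closes its document)
    max_version: dict[int, int] = {}
    for _, ev, _ in ranked:
        if ev.kind != "delete":
            max_version[ev.pmid] = max(max_version.get(ev.pmid, 1), ev.version)

    def key(item):
        fi, ev, idx = item
        v = max_version.get(ev.pmid, 1) if ev.kind == "delete" else ev.version
        kind_rank = {"create": 0, "update": 1, "delete": 2}[ev.kind]
        return (fi, ev.pmid, v, kind_rank, idx)

    ranked.sort(key=key)
    return [(fi, ev) for fi, ev, _ in ranked]
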