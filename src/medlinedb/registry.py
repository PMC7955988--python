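"""Table registry: the relational schema for the parsed MEDLINE data.

Each data type extracted from a ``PubmedArticleSet`` document lands in its
own table, linked to the others by PMID (and, for article-level data, by the
record's version number).  The registry is plain data — adding a column or a
table requires no change to the ingest or pipeline code, which iterate over
it.

Semantic column types are deliberately coarse (``integer``, ``text``,
``date``, ``boolean``, ``timestamp``); each backend dialect maps them to
concrete SQL types.

Element paths (relative to ``PubmedArticle`` unless noted):

===================  ==========================================================
table                source
===================  ==========================================================
pub                  MedlineCitation/PMID [@Version], Article/ArticleTitle,
                     Article/Language
journal              Article/Journal (Title, ISSN, JournalIssue/Volume, Issue)
pub_history          PubmedData/History/PubMedPubDate [@PubStatus] (Year,
                     Month, Day)
author               Article/AuthorList/Author (LastName, ForeName, Initials,
                     Suffix, CollectiveName), 1-based position
author_identifier    Article/AuthorList/Author/Identifier [@Source]
abstract             Article/Abstract/AbstractText (paragraphs concatenated,
                     labels kept as "LABEL: " prefixes)
mesh_term            MedlineCitation/MeshHeadingList/MeshHeading/
                     DescriptorName [@UI, @MajorTopicYN]
keyword              MedlineCitation/KeywordList/Keyword
grant_item           Article/GrantList/Grant (GrantID, Agency, Country)
pub_type             Article/PublicationTypeList/PublicationType [@UI]
article_id           PubmedData/ArticleIdList/ArticleId [@IdType]
chemical             MedlineCitation/ChemicalList/Chemical (RegistryNumber,
                     NameOfSubstance [@UI])
data_bank            Article/DataBankList/DataBank (one row per accession)
investigator         MedlineCitation/InvestigatorList/Investigator
comment_correction   MedlineCitation/CommentsCorrectionsList/
                     CommentsCorrections [@RefType] / PMID
xml_processed        ledger of processed source files (not article data)
citation             NIH Open Citation Collection edge list (not article data)
citation_version     source-version tag of the loaded citation collection
===================  ==========================================================
"""

from __future__ import annotations

from dataclasses import dataclass

#: Prefix used for the staging twins of versioned tables during updates.
TMP_PREFIX = "tmp_"

#: Name of the staging table recording deletion notices per source file.
TMP_DELETION = "tmp_deletion"


@dataclass(frozen=True)
class TableSpec:
    """One table: its name, ordered columns and whether it is PMID-versioned.

    ``keyed_by_version`` tables hold article-level data and always begin
    with ``(pmid, version)``; they participate in version reduction and in
    tombstone deletion.  The remaining tables (file ledger, citation graph)
    are maintained by their own pipelines.
    """

    name: str
    columns: tuple[tuple[str, str], ...]
    keyed_by_version: bool = True

    def __post_init__(self) -> None:
        if self.name != self.name.lower():
            raise ValueError(f"table name must be lowercase: {self.name!r}")
        names = [c for c, _ in self.columns]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate column in {self.name!r}")
        if self.keyed_by_version and names[:2] != ["pmid", "version"]:
            raise ValueError(
                f"versioned table {self.name!r} must start with (pmid, version)"
            )

    @property
    def column_names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.columns)


def _v(name: str, *cols: tuple[str, str]) -> TableSpec:
    return TableSpec(name, (("pmid", "integer"), ("version", "integer")) + cols)


REGISTRY: tuple[TableSpec, ...] = (
    _v("pub", ("title", "text"), ("language", "text")),
    _v(
        "journal",
        ("journal_name", "text"),
        ("issn", "text"),
        ("volume", "text"),
        ("issue", "text"),
    ),
    _v(
        "pub_history",
        ("pub_status", "text"),
        ("event_date", "date"),
        ("date_precision", "text"),
    ),
    _v(
        "author",
        ("author_pos", "integer"),
        ("last_name", "text"),
        ("fore_name", "text"),
        ("initials", "text"),
        ("suffix", "text"),
        ("collective_name", "text"),
    ),
    _v(
        "author_identifier",
        ("author_pos", "integer"),
        ("identifier_source", "text"),
        ("identifier", "text"),
    ),
    _v("abstract", ("text", "text")),
    _v("mesh_term", ("term", "text"), ("ui", "text"), ("major_topic", "boolean")),
    _v("keyword", ("keyword", "text")),
    _v("grant_item", ("grant_id", "text"), ("agency", "text"), ("country", "text")),
    _v("pub_type", ("type_name", "text"), ("ui", "text")),
    _v("article_id", ("id_type", "text"), ("id_value", "text")),
    _v("chemical", ("registry_number", "text"), ("substance", "text"), ("ui", "text")),
    _v("data_bank", ("data_bank_name", "text"), ("accession_number", "text")),
    _v(
        "investigator",
        ("investigator_pos", "integer"),
        ("last_name", "text"),
        ("fore_name", "text"),
        ("initials", "text"),
    ),
    _v("comment_correction", ("ref_type", "text"), ("ref_pmid", "integer")),
    TableSpec(
        "xml_processed",
        (
            ("file_name", "text"),
            ("processed_at", "timestamp"),
            ("checksum", "text"),
        ),
        keyed_by_version=False,
    ),
    TableSpec(
        "citation",
        (("citing_pmid", "integer"), ("cited_pmid", "integer")),
        keyed_by_version=False,
    ),
    TableSpec(
        "citation_version",
        (("version_label", "text"), ("retrieved_at", "timestamp")),
        keyed_by_version=False,
    ),
)

TABLES: dict[str, TableSpec] = {t.name: t for t in REGISTRY}

VERSIONED_TABLES: tuple[str, ...] = tuple(
    t.name for t in REGISTRY if t.keyed_by_version
)


def get_table(name: str) -> TableSpec:
    try:
        return TABLES[name]
    except KeyError:
        raise KeyError(f"unknown table {name!r}; not in registry") from None
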