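"""Domain types and readers/writers for FAERS-like adverse-event report data.

A spontaneous report is reduced to the two facts the case/non-case design
needs: the set of drugs on the report and the set of event terms (MedDRA
preferred-term-like, lowercase).  On disk a report set is a pair of
delimited tables mirroring the FAERS DRUG/REAC quarterly layout::

    drug table:     report_id <delim> drug_name
    reaction table: report_id <delim> event_term

The default delimiter is ``$`` (the FAERS ASCII convention); tab and comma
are also supported.  All names are normalized on read (lowercase, trimmed,
internal whitespace collapsed) so that matching downstream is exact string
equality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from pipn.errors import ValidationError

logger = logging.getLogger(__name__)

#: Minimal built-in synonym map (generic names only). Users may extend or
#: replace it via the ``synonyms`` argument of :func:`normalize_name` /
#: :func:`read_reports`.
DEFAULT_SYNONYMS: dict[str, str] = {
    "tamsulosin hcl": "tamsulosin",
    "tamsulosin hydrochloride": "tamsulosin",
    "doxazosin mesylate": "doxazosin",
    "paclitaxel protein-bound": "paclitaxel protein-bound",  # kept distinct
}

_DIALECTS = {"$": "$", "tab": "\t", "\t": "\t", ",": ",", "comma": ",", "dollar": "$"}


def _resolve_delimiter(dialect: str) -> str:
    try:
        return _DIALECTS[dialect]
    except KeyError:
        raise ValidationError(
            f"unsupported delimiter {dialect!r}; use one of '$', 'tab', ','"
        ) from None


def normalize_name(raw: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Normalize a drug or event name: casefold, trim, collapse internal
    whitespace, then apply an optional synonym map.

    Raises :class:`ValidationError` if the result is empty.
    """
    if raw is None:
        raise ValidationError("name is None")
    name = " ".join(str(raw).lower().split())
    if not name:
        raise ValidationError(f"name {raw!r} is empty after normalization")
    if synonyms is not None:
        name = synonyms.get(name, name)
        if not name:
            raise ValidationError(f"synonym map maps {raw!r} to an empty name")
    return name


@dataclass(frozen=True)
class AdverseEventReport:
    """One spontaneous report: an opaque id, its drugs and its event terms.

    ``drugs`` must be non-empty (a report without any drug is not a valid
    spontaneous report); ``events`` may be empty.  Names are expected to be
    already normalized.
    """

    report_id: str
    drugs: frozenset[str]
    events: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValidationError("report_id must be non-empty")
        if not self.drugs:
            raise ValidationError(f"report {self.report_id!r} has no drugs")
        object.__setattr__(self, "drugs", frozenset(self.drugs))
        object.__setattr__(self, "events", frozenset(self.events))


@dataclass
class ReportSet:
    """A collection of :class:`AdverseEventReport` with unique ids."""

    reports: list[AdverseEventReport] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.report_id for r in self.reports]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate report_ids: {dupes[:10]}")

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self):
        return iter(self.reports)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReportSet):
            return NotImplemented
        key = lambda r: r.report_id
        return sorted(self.reports, key=key) == sorted(other.reports, key=key)


@dataclass(frozen=True)
class CaseDefinition:
    """A named set of event terms; a report is a case iff it lists any of
    them (exact match on normalized terms)."""

    name: str
    terms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValidationError("case definition has no terms")
        object.__setattr__(self, "terms", frozenset(self.terms))


@dataclass(frozen=True)
class DrugGroup:
    """A named set of drug names treated as one exposure (a single drug is a
    group of size one)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"drug group {self.name!r} has no members")
        object.__setattr__(self, "members", frozenset(self.members))


def read_reports(
    drug_table: str | Path,
    reaction_table: str | Path,
    dialect: str = "$",
    synonyms: Mapping[str, str] | None = None,
) -> ReportSet:
    """Read a report set from a drug table and a reaction table.

    Both files need a header row; required columns are ``report_id`` and
    ``drug_name`` (drug table) / ``event_term`` (reaction table).  One
    report is built per distinct ``report_id``; duplicate (report_id, name)
    rows collapse silently into the set (with a logged count).  A report_id
    that appears only in the reaction table is an error: every report must
    carry at least one drug.
    """
    delim = _resolve_delimiter(dialect)
    drugs = pd.read_csv(drug_table, sep=delim, dtype=str, keep_default_na=False)
    reacs = pd.read_csv(reaction_table, sep=delim, dtype=str, keep_default_na=False)
    for df, col, path in ((drugs, "drug_name", drug_table), (reacs, "event_term", reaction_table)):
        missing = {"report_id", col} - set(df.columns)
        if missing:
            raise ValidationError(f"{path}: missing columns {sorted(missing)}")

    drug_ids = set(drugs["report_id"])
    orphan = sorted(set(reacs["report_id"]) - drug_ids)
    if orphan:
        raise ValidationError(
            f"reaction rows reference report_ids absent from the drug table "
            f"(a report must have >=1 drug): {orphan[:10]}"
        )

    drug_map: dict[str, set[str]] = {}
    n_dupes = 0
    for rid, name in zip(drugs["report_id"], drugs["drug_name"]):
        s = drug_map.setdefault(rid, set())
        norm = normalize_name(name, synonyms)
        n_dupes += norm in s
        s.add(norm)
    event_map: dict[str, set[str]] = {}
    for rid, term in zip(reacs["report_id"], reacs["event_term"]):
        s = event_map.setdefault(rid, set())
        norm = normalize_name(term, synonyms)
        n_dupes += norm in s
        s.add(norm)
    if n_dupes:
        logger.info("collapsed %d duplicate drug/event rows", n_dupes)

    reports = [
        AdverseEventReport(rid, frozenset(drug_map[rid]), frozenset(event_map.get(rid, ())))
        for rid in drug_map
    ]
    return ReportSet(reports, provenance=f"read from {drug_table} + {reaction_table}")


def write_reports(
    rs: ReportSet,
    drug_table: str | Path,
    reaction_table: str | Path,
    dialect: str = "$",
) -> None:
    """Write a report set as the two delimited tables (UTF-8, LF endings).

    Round-trip contract: ``read_reports(*write_reports(rs))`` equals ``rs``
    up to row order.
    """
    delim = _resolve_delimiter(dialect)
    drug_rows = [
        (r.report_id, d) for r in sorted(rs, key=lambda r: r.report_id) for d in sorted(r.drugs)
    ]
    reac_rows = [
        (r.report_id, e) for r in sorted(rs, key=lambda r: r.report_id) for e in sorted(r.events)
    ]
    pd.DataFrame(drug_rows, columns=["report_id", "drug_name"]).to_csv(
        drug_table, sep=delim, index=False, lineterminator="\n"
    )
    pd.DataFrame(reac_rows, columns=["report_id", "event_term"]).to_csv(
        reaction_table, sep=delim, index=False, lineterminator="\n"
    )


def make_report(report_id: str, drugs: Iterable[str], events: Iterable[str] = ()) -> AdverseEventReport:
    """Convenience constructor that normalizes names on the way in."""
    return AdverseEventReport(
        report_id,
        frozenset(normalize_name(d) for d in drugs),
        frozenset(normalize_name(e) for e in events),
    )
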