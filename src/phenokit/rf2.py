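"""Reading and writing the on-disk terminology formats.

SNOMED CT is distributed as Release Format 2 (RF2): tab-delimited tables
for concepts, descriptions and relationships. This module loads an RF2
*snapshot* (one row per component id, the current state of each component)
into a :class:`Release`, together with the auxiliary tables this toolkit
needs: a history/query table linking inactive concepts to active
supertypes with a 0-3 provenance level, Read-to-SNOMED mapping rows, and
codelist CSV files.

Loading is strict: missing columns, duplicate snapshot ids and broken
cross-table references raise rather than silently dropping rows. Inactive
rows are retained and flagged (historic EHR data may reference them).
SNOMED identifiers exceed the 32-bit range, so ids are parsed as 64-bit
integers and always serialized as plain digit strings.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .codelist import Codelist, CodelistEntry, _STATUSES
from .errors import FormatError, IntegrityError

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

# RF2 description type ids
FSN_TYPE_ID = 900000000000003001
SYNONYM_TYPE_ID = 900000000000013009

#: Columns required in each RF2 snapshot table (extras are ignored).
CONCEPT_COLUMNS = ("id", "effectiveTime", "active", "definitionStatusId")
DESCRIPTION_COLUMNS = (
    "id",
    "effectiveTime",
    "active",
    "conceptId",
    "languageCode",
    "typeId",
    "term",
)
RELATIONSHIP_COLUMNS = (
    "id",
    "effectiveTime",
    "active",
    "sourceId",
    "destinationId",
    "relationshipGroup",
    "typeId",
)

QUERY_COLUMNS = ("legacy_concept_id", "current_concept_id", "provenance")
MAPPING_COLUMNS = ("read_code", "concept_id")  # local_code optional
CODELIST_COLUMNS = ("concept_id", "term", "status", "provenance_tag")


@dataclass(frozen=True)
class HistoryRow:
    """Links an inactive/legacy concept to an active supertype.

    provenance follows the NHS query-table scale: 0 = subsumption always
    true, up to 3 = the original concept had at least two distinct
    meanings.
    """

    legacy_concept_id: int
    current_concept_id: int
    provenance: int

    def __post_init__(self) -> None:
        if self.provenance not in (0, 1, 2, 3):
            raise ValueError(f"provenance must be 0-3, got {self.provenance}")


@dataclass(frozen=True)
class MappingRow:
    """One Read V2 (and optionally local-dictionary) to SNOMED CT map."""

    read_code: str
    concept_id: int
    local_code: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.read_code and self.local_code is None:
            raise ValueError("mapping row needs a read_code or a local_code")


@dataclass
class Release:
    """An in-memory SNOMED CT snapshot release plus auxiliary tables.

    The three RF2 tables are pandas DataFrames with the column names of
    :data:`CONCEPT_COLUMNS` etc.; ``active`` is boolean and ids are int64.
    """

    concepts: pd.DataFrame
    descriptions: pd.DataFrame
    relationships: pd.DataFrame
    history: list[HistoryRow] = field(default_factory=list)
    mappings: list[MappingRow] = field(default_factory=list)

    @property
    def active_concept_ids(self) -> set[int]:
        return set(self.concepts.loc[self.concepts["active"], "id"])

    @property
    def concept_ids(self) -> set[int]:
        return set(self.concepts["id"])

    def fsn(self, concept_id: int) -> Optional[str]:
        """The active fully specified name of a concept, if any."""
        d = self.descriptions
        hit = d[
            (d["conceptId"] == concept_id)
            & d["active"]
            & (d["typeId"] == FSN_TYPE_ID)
        ]
        if hit.empty:
            return None
        return str(hit.iloc[0]["term"])


def _read_rf2_table(
    path: PathLike, required: Sequence[str], what: str
) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{what} file not found: {path}")
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8"
    )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{what} file {path} is missing required column(s): "
            + ", ".join(missing)
        )
    df = df[list(required)].copy()
    for col in required:
        if col.endswith(("Id", "id")) or col == "relationshipGroup":
            try:
                df[col] = df[col].astype("int64")
            except ValueError as exc:
                raise FormatError(
                    f"{what} file {path}: non-integer value in column {col}"
                ) from exc
    df["active"] = df["active"].astype("int64").astype(bool)
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise IntegrityError(
            f"{what} file {path}: duplicate snapshot id {dup}"
        )
    return df


def load_release(
    concept_path: PathLike,
    description_path: PathLike,
    relationship_path: PathLike,
) -> Release:
    """Load an RF2 snapshot (concept, description, relationship tables).

    Referential integrity is checked: active descriptions must reference a
    known concept, every active concept must have exactly one active FSN,
    and relationship endpoints must be known concepts. Inactive rows are
    kept with ``active == False``.
    """
    concepts = _read_rf2_table(concept_path, CONCEPT_COLUMNS, "concept")
    descriptions = _read_rf2_table(
        description_path, DESCRIPTION_COLUMNS, "description"
    )
    relationships = _read_rf2_table(
        relationship_path, RELATIONSHIP_COLUMNS, "relationship"
    )

    known = set(concepts["id"])
    active_desc = descriptions[descriptions["active"]]
    bad = set(active_desc["conceptId"]) - known
    if bad:
        raise IntegrityError(
            f"description(s) reference unknown concept id(s): {sorted(bad)[:5]}"
        )
    bad = (set(relationships["sourceId"]) | set(relationships["destinationId"])) - known
    if bad:
        raise IntegrityError(
            f"relationship(s) reference unknown concept id(s): {sorted(bad)[:5]}"
        )

    active_ids = set(concepts.loc[concepts["active"], "id"])
    fsn_rows = active_desc[active_desc["typeId"] == FSN_TYPE_ID]
    fsn_counts = fsn_rows.groupby(["conceptId", "languageCode"]).size()
    multi = fsn_counts[fsn_counts > 1]
    if not multi.empty:
        cid = multi.index[0][0]
        raise IntegrityError(
            f"concept {cid} has more than one active FSN in one language"
        )
    missing_fsn = active_ids - set(fsn_rows["conceptId"])
    if missing_fsn:
        raise IntegrityError(
            f"active concept(s) lack an active FSN: {sorted(missing_fsn)[:5]}"
        )

    n_inactive = int((~concepts["active"]).sum())
    logger.info(
        "loaded release: %d concepts (%d inactive), %d descriptions, "
        "%d relationships",
        len(concepts), n_inactive, len(descriptions), len(relationships),
    )
    return Release(concepts, descriptions, relationships)


def load_query_table(path: PathLike) -> list[HistoryRow]:
    """Load a merged history/query table (tab-delimited).

    Columns: ``legacy_concept_id``, ``current_concept_id``, ``provenance``.
    A provenance outside 0-3 is a format error naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"query table file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in QUERY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"query table {path} is missing column(s): " + ", ".join(missing)
        )
    rows: list[HistoryRow] = []
    for i, rec in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            prov = int(rec.provenance)
        except ValueError:
            prov = -1
        if prov not in (0, 1, 2, 3):
            raise FormatError(
                f"query table {path} row {i}: provenance "
                f"{rec.provenance!r} not in 0-3"
            )
        rows.append(
            HistoryRow(int(rec.legacy_concept_id), int(rec.current_concept_id), prov)
        )
    return rows


def load_mapping_table(path: PathLike) -> list[MappingRow]:
    """Load a Read-to-SNOMED mapping table (tab-delimited).

    Columns ``read_code`` and ``concept_id``; an optional ``local_code``
    column carries medcode-style local dictionary keys. A row may have an
    empty read_code only when it has a local_code (local-dictionary-only
    concepts).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mapping file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MAPPING_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"mapping table {path} is missing column(s): " + ", ".join(missing)
        )
    has_local = "local_code" in df.columns
    rows = []
    for i, rec in enumerate(df.itertuples(index=False), start=2):
        local = getattr(rec, "local_code", "") if has_local else ""
        try:
            rows.append(
                MappingRow(
                    read_code=str(rec.read_code),
                    concept_id=int(rec.concept_id),
                    local_code=str(local) or None,
                )
            )
        except ValueError as exc:
            raise FormatError(f"mapping table {path} row {i}: {exc}") from exc
    return rows


def read_codelist(path: PathLike, name: Optional[str] = None) -> Codelist:
    """Read a codelist CSV (concept_id, term, status, provenance_tag[, active]).

    The codelist name defaults to the file stem; the method is recorded as
    ``manual`` because an extensional CSV carries no definition.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"codelist file not found: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or any(
            c not in reader.fieldnames for c in CODELIST_COLUMNS
        ):
            raise FormatError(
                f"codelist {path} must have header columns "
                + ",".join(CODELIST_COLUMNS)
            )
        entries = []
        for i, rec in enumerate(reader, start=2):
            status = rec["status"]
            if status not in _STATUSES:
                raise FormatError(
                    f"codelist {path} row {i}: unknown status {status!r}"
                )
            entries.append(
                CodelistEntry(
                    concept_id=int(rec["concept_id"]),
                    term=rec["term"],
                    status=status,
                    provenance_tag=rec["provenance_tag"],
                    active=rec.get("active", "1") in ("1", "True", "true"),
                )
            )
    return Codelist(name=name or path.stem, method="manual", entries=entries)


def write_codelist(codelist: Codelist, path: PathLike) -> None:
    """Write a codelist CSV in canonical (deterministic) row order."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CODELIST_COLUMNS + ("active",))
        for e in codelist.sorted_entries():
            writer.writerow(
                [e.concept_id, e.term, e.status, e.provenance_tag,
                 1 if e.active else 0]
            )


def read_read_codelist(path: PathLike) -> list[tuple[str, str]]:
    """Read a legacy Read V2 codelist CSV with columns (code, description)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"Read codelist file not found: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "code" not in reader.fieldnames:
            raise FormatError(f"Read codelist {path} must have a 'code' column")
        out = []
        for rec in reader:
            if not rec["code"]:
                raise FormatError(f"Read codelist {path}: empty code")
            out.append((rec["code"], rec.get("description", "")))
    return out


# ---------------------------------------------------------------------------
# Writers for full releases (fixtures, `phenokit simulate`)

_RELEASE_FILES = {
    "concepts": ("sct2_Concept_Snapshot.txt", CONCEPT_COLUMNS),
    "descriptions": ("sct2_Description_Snapshot.txt", DESCRIPTION_COLUMNS),
    "relationships": ("sct2_Relationship_Snapshot.txt", RELATIONSHIP_COLUMNS),
}


def write_release(release: Release, out_dir: PathLike) -> None:
    """Write a Release back to RF2-style snapshot TSVs (plus query/mapping
    tables when present) under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for attr, (fname, cols) in _RELEASE_FILES.items():
        df = getattr(release, attr)[list(cols)].copy()
        df["active"] = df["active"].astype(int)
        df.to_csv(out_dir / fname, sep="\t", index=False)
    if release.history:
        write_query_table(release.history, out_dir / "query_table.tsv")
    if release.mappings:
        write_mapping_table(release.mappings, out_dir / "mapping.tsv")


def write_query_table(rows: Sequence[HistoryRow], path: PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(QUERY_COLUMNS)
        for r in rows:
            writer.writerow([r.legacy_concept_id, r.current_concept_id, r.provenance])


def write_mapping_table(rows: Sequence[MappingRow], path: PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(MAPPING_COLUMNS + ("local_code",))
        for r in rows:
            writer.writerow([r.read_code, r.concept_id, r.local_code or ""])


def load_release_dir(release_dir: PathLike) -> Release:
    """Load a release from a directory laid out as written by
    :func:`write_release` (the `phenokit simulate` output convention).

    RF2 tables are located by their ``sct2_Concept*/sct2_Description*/
    sct2_Relationship*`` filename prefixes, matching real snapshot
    releases. A ``query_table.tsv`` and ``mapping.tsv``, if present, are
    attached to the Release.
    """
    release_dir = Path(release_dir)

    def _find(prefix: str) -> Path:
        hits = sorted(release_dir.glob(f"{prefix}*"))
        if not hits:
            raise FileNotFoundError(
                f"no {prefix}* file found in {release_dir}"
            )
        return hits[0]

    release = load_release(
        _find("sct2_Concept"), _find("sct2_Description"), _find("sct2_Relationship")
    )
    qt = release_dir / "query_table.tsv"
    if qt.exists():
        release.history = load_query_table(qt)
    mp = release_dir / "mapping.tsv"
    if mp.exists():
        release.mappings = load_mapping_table(mp)
    return release
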