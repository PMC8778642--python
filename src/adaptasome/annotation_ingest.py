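"""Parse homology-search hit tables into an organism x family count matrix.

Proteomes annotated against peptidase (MEROPS), carbohydrate-active-enzyme
(CAZy/dbCAN) and transporter (TCDB) profile libraries yield raw hit tables:
NCBI BLAST tabular output (``-outfmt 6``) for the BLAST-based searches and
HMMER3 ``--domtblout`` tables for the HMM-based CAZyme search.  This module
parses those tables, applies an e-value cutoff, resolves protein-to-family
assignments under a selectable counting policy, and tabulates family copy
numbers per organism.
"""

from __future__ import annotations

import enum
import io
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Database",
    "AnnotationHit",
    "FamilyCountMatrix",
    "AssignmentPolicy",
    "family_from_subject",
    "parse_blast_tab",
    "parse_hmmscan_domtblout",
    "filter_hits",
    "assign_families",
    "build_count_matrix",
]

GAP_DEFAULT_EVALUE = 1e-10  # cutoff used for all three databases


class Database(str, enum.Enum):
    """Source profile library of an annotation hit."""

    MEROPS = "MEROPS"
    CAZY = "CAZY"
    TCDB = "TCDB"

    def __str__(self) -> str:  # keep TSV output plain
        return self.value


class AssignmentPolicy(str, enum.Enum):
    """How raw hits are converted to countable protein->family assignments.

    ``per_protein_per_family_once``
        each (protein, family) pair counts at most once — a protein with three
        HSPs against the same family contributes a single copy, but a protein
        matching two families contributes to both.
    ``best_family_per_protein``
        each protein counts exactly once, for its best-scoring family
        (lowest e-value, then highest bitscore, then lexicographically
        smallest family id).
    ``raw_hits``
        every hit line counts (HSP/domain-level counting).
    """

    PER_PROTEIN_PER_FAMILY_ONCE = "per_protein_per_family_once"
    BEST_FAMILY_PER_PROTEIN = "best_family_per_protein"
    RAW_HITS = "raw_hits"


@dataclass(frozen=True)
class AnnotationHit:
    """One query-protein-to-family-profile match."""

    organism_id: str
    query_id: str
    family_id: str
    database: Database
    evalue: float
    bitscore: float
    query_start: int | None = None
    query_end: int | None = None

    def __post_init__(self) -> None:
        if not self.family_id:
            raise ValueError("family_id must be nonempty")
        if self.evalue < 0:
            raise ValueError(f"evalue must be >= 0, got {self.evalue}")
        if (
            self.query_start is not None
            and self.query_end is not None
            and self.query_start > self.query_end
        ):
            raise ValueError(
                f"query_start {self.query_start} > query_end {self.query_end}"
            )


def family_from_subject(
    subject_id: str,
    database: Database,
    subject_map: Mapping[str, str] | None = None,
) -> str:
    """Extract the family identifier from a BLAST subject id.

    Subject ids are treated as ``<prefix>:<accession>`` or a plain accession.
    For MEROPS-style accessions the family is the part before the first dot
    (``A01.001`` -> ``A01``); TCDB accessions are dotted five-component
    identifiers whose family is the first three components
    (``2.A.1.8.1`` -> ``2.A.1``).  A ``subject_map`` overrides parsing
    entirely for ids it contains (header conventions vary across database
    releases).
    """
    if subject_map is not None and subject_id in subject_map:
        return subject_map[subject_id]
    accession = subject_id.split(":", 1)[-1]
    if database is Database.TCDB:
        parts = accession.split(".")
        return ".".join(parts[:3]) if len(parts) >= 3 else accession
    return accession.split(".", 1)[0]


class MalformedLineError(ValueError):
    """A hit-table line that cannot be parsed; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def _as_lines(stream: Iterable[str] | str) -> Iterable[str]:
    if isinstance(stream, str):
        return io.StringIO(stream)
    return stream


def parse_blast_tab(
    stream: Iterable[str] | str,
    organism_id: str,
    database: Database,
    subject_map: Mapping[str, str] | None = None,
) -> list[AnnotationHit]:
    """Parse 12-column NCBI BLAST tabular output (``-outfmt 6``).

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  Comment (``#``) and blank lines are
    skipped; line order is preserved.  Raises :class:`MalformedLineError`
    (naming the offending line) on a wrong column count or non-numeric field.
    """
    database = Database(database)
    hits: list[AnnotationHit] = []
    for lineno, raw in enumerate(_as_lines(stream), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 12:
            raise MalformedLineError(
                lineno, f"expected 12 tab-separated columns, found {len(fields)}"
            )
        qseqid, sseqid = fields[0], fields[1]
        try:
            qstart = int(fields[6])
            qend = int(fields[7])
            evalue = float(fields[10])
            bitscore = float(fields[11])
        except ValueError as exc:
            raise MalformedLineError(lineno, f"non-numeric field: {exc}") from None
        if not math.isfinite(evalue) or evalue < 0:
            raise MalformedLineError(lineno, f"invalid e-value {fields[10]!r}")
        hits.append(
            AnnotationHit(
                organism_id=organism_id,
                query_id=qseqid,
                family_id=family_from_subject(sseqid, database, subject_map),
                database=database,
                evalue=evalue,
                bitscore=bitscore,
                query_start=qstart,
                query_end=qend,
            )
        )
    return hits


# domtblout column layout (0-based): 0 target, 3 query, 12 i-Evalue,
# 13 domain score, 17/18 ali from/to; 23 columns minimum, description free-form.
_DOMTBL_MIN_FIELDS = 23


def parse_hmmscan_domtblout(
    stream: Iterable[str] | str,
    organism_id: str,
) -> list[AnnotationHit]:
    """Parse HMMER3 per-domain tabular output (``hmmscan --domtblout``).

    One hit per domain row; the target name is the CAZy profile
    (e.g. ``GH5.hmm`` -> family ``GH5``) and the e-value is the domain
    independent e-value (i-Evalue).  ``#`` comment lines are skipped.
    """
    hits: list[AnnotationHit] = []
    for lineno, raw in enumerate(_as_lines(stream), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < _DOMTBL_MIN_FIELDS:
            raise MalformedLineError(
                lineno,
                f"expected >= {_DOMTBL_MIN_FIELDS} whitespace-separated fields, "
                f"found {len(fields)}",
            )
        target = fields[0]
        family = target[:-4] if target.endswith(".hmm") else target
        try:
            evalue = float(fields[12])
            bitscore = float(fields[13])
            ali_from = int(fields[17])
            ali_to = int(fields[18])
        except ValueError as exc:
            raise MalformedLineError(lineno, f"non-numeric field: {exc}") from None
        hits.append(
            AnnotationHit(
                organism_id=organism_id,
                query_id=fields[3],
                family_id=family,
                database=Database.CAZY,
                evalue=evalue,
                bitscore=bitscore,
                query_start=ali_from,
                query_end=ali_to,
            )
        )
    return hits


def filter_hits(
    hits: Sequence[AnnotationHit], max_evalue: float = GAP_DEFAULT_EVALUE
) -> list[AnnotationHit]:
    """Keep hits with ``evalue <= max_evalue`` (inclusive), order preserved."""
    if not max_evalue > 0:
        raise ValueError(f"max_evalue must be > 0, got {max_evalue}")
    return [h for h in hits if h.evalue <= max_evalue]


Assignment = tuple[str, str, str, Database]  # (organism, query, family, database)


def assign_families(
    hits: Sequence[AnnotationHit],
    policy: AssignmentPolicy | str = AssignmentPolicy.PER_PROTEIN_PER_FAMILY_ONCE,
) -> list[Assignment]:
    """Resolve (already filtered) hits to countable protein->family assignments."""
    policy = AssignmentPolicy(policy)
    if policy is AssignmentPolicy.RAW_HITS:
        return [(h.organism_id, h.query_id, h.family_id, h.database) for h in hits]
    if policy is AssignmentPolicy.PER_PROTEIN_PER_FAMILY_ONCE:
        seen: dict[Assignment, None] = {}
        for h in hits:
            seen.setdefault((h.organism_id, h.query_id, h.family_id, h.database), None)
        return list(seen)
    # best_family_per_protein: lowest e-value, then highest bitscore,
    # then lexicographically smallest family id.
    best: dict[tuple[str, str], AnnotationHit] = {}
    for h in hits:
        key = (h.organism_id, h.query_id)
        cur = best.get(key)
        if cur is None or (h.evalue, -h.bitscore, h.family_id) < (
            cur.evalue,
            -cur.bitscore,
            cur.family_id,
        ):
            best[key] = h
    return [(h.organism_id, h.query_id, h.family_id, h.database) for h in best.values()]


FamilyKey = tuple[str, str]  # (database value, family_id)


class FamilyCountMatrix:
    """Organism x family table of nonnegative integer copy numbers.

    Backed by a :class:`pandas.DataFrame` with organisms as the index and a
    two-level column index ``(database, family_id)``, sorted lexicographically
    by database then family so serialization is deterministic.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            raise ValueError("duplicate organism ids")
        if data.columns.has_duplicates:
            raise ValueError("duplicate (database, family) columns")
        if data.size and (data.to_numpy() < 0).any():
            raise ValueError("counts must be >= 0")
        data = data.astype(np.int64, copy=False)
        data = data.sort_index(axis=1)
        data.columns = pd.MultiIndex.from_tuples(
            list(data.columns), names=["database", "family"]
        ) if len(data.columns) else pd.MultiIndex.from_arrays(
            [[], []], names=["database", "family"]
        )
        self.data = data

    @property
    def organisms(self) -> list[str]:
        return list(self.data.index)

    @property
    def families(self) -> list[FamilyKey]:
        return list(self.data.columns)

    @property
    def total(self) -> int:
        return int(self.data.to_numpy().sum()) if self.data.size else 0

    def counts(self, organism: str, family: FamilyKey) -> int:
        return int(self.data.at[organism, family])

    def row(self, organism: str) -> dict[FamilyKey, int]:
        """Nonzero counts for one organism."""
        s = self.data.loc[organism]
        return {k: int(v) for k, v in s.items() if v > 0}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FamilyCountMatrix):
            return NotImplemented
        return self.data.equals(other.data)

    def to_tsv(self, path_or_buf) -> None:
        """Write TSV: first column ``organism``, then ``<database>|<family>``."""
        out = self.data.copy()
        out.columns = [f"{db}|{fam}" for db, fam in out.columns]
        out.index.name = "organism"
        out.to_csv(path_or_buf, sep="\t")

    @classmethod
    def from_tsv(cls, path_or_buf) -> "FamilyCountMatrix":
        df = pd.read_csv(path_or_buf, sep="\t", index_col="organism")
        cols = []
        for c in df.columns:
            db, _, fam = c.partition("|")
            if not fam:
                raise ValueError(f"column {c!r} is not of the form '<database>|<family>'")
            Database(db)  # validate
            cols.append((db, fam))
        df.columns = pd.MultiIndex.from_tuples(cols, names=["database", "family"])
        df.index = df.index.astype(str)
        return cls(df)


def build_count_matrix(
    assignments: Iterable[Assignment],
    organisms: Sequence[str],
    families: Sequence[FamilyKey] | None = None,
) -> FamilyCountMatrix:
    """Tabulate assignments into a count matrix over the full organism roster.

    Organisms with no assignments appear as all-zero rows.  Families absent
    from every organism appear only if listed in an explicit ``families``
    roster.  An assignment naming an organism outside the roster is an error.
    """
    roster = list(organisms)
    if len(set(roster)) != len(roster):
        raise ValueError("duplicate organism ids in roster")
    roster_set = set(roster)
    tallies: dict[tuple[str, FamilyKey], int] = {}
    observed: dict[FamilyKey, None] = {}
    for org, _query, fam, db in assignments:
        if org not in roster_set:
            raise ValueError(f"assignment references organism {org!r} not in roster")
        key = (str(Database(db)), fam)
        observed.setdefault(key, None)
        tallies[(org, key)] = tallies.get((org, key), 0) + 1
    cols = sorted(observed) if families is None else sorted(set(families) | set(observed))
    mat = pd.DataFrame(0, index=pd.Index(roster, name="organism"), columns=range(len(cols)))
    mat.columns = pd.MultiIndex.from_tuples(cols, names=["database", "family"]) if cols else pd.MultiIndex.from_arrays([[], []], names=["database", "family"])
    for (org, key), n in tallies.items():
        mat.at[org, key] = n
    return FamilyCountMatrix(mat)
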