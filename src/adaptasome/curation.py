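"""Catalytic-residue curation of aligned protein families.

Homolog alignments for enzyme families (peptidases, CAZymes) routinely pick
up pseudogenes and non-catalytic homologs.  This module automates the
exclusion rule applied during manual alignment curation: a sequence is
removed if it carries a gap or a chemically invalid substitution at any
catalytic residue, or a large deletion inside a conserved enzymatic region.

Catalytic positions and conserved regions are given in coordinates of an
ungapped reference sequence present in the alignment; the module maps them
to alignment columns through the reference row's gap structure.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GAP_CHARS",
    "RELAXED_EQUIVALENCE",
    "CatalyticSiteSpec",
    "CurationReport",
    "SequenceVerdict",
    "map_reference_columns",
    "check_sequence",
    "curate_alignment",
    "read_alignment_fasta",
    "write_alignment_fasta",
    "load_site_spec",
]

GAP_CHARS = frozenset({"-", "."})

# Same-chemistry groups for the relaxed substitution policy:
# nucleophiles, acidic, basic, amide.
RELAXED_EQUIVALENCE: tuple[frozenset[str], ...] = (
    frozenset({"S", "T", "C"}),
    frozenset({"D", "E"}),
    frozenset({"K", "R", "H"}),
    frozenset({"N", "Q"}),
)


def _relaxed_allowed(residue: str) -> frozenset[str]:
    for group in RELAXED_EQUIVALENCE:
        if residue in group:
            return group
    return frozenset({residue})


@dataclass(frozen=True)
class CatalyticSiteSpec:
    """Catalytic positions and conserved regions of one family's reference.

    Positions and region bounds are 1-based in the UNGAPPED reference
    sequence.  ``allowed_residues`` maps each catalytic position to the set
    of acceptable amino acids; positions absent from the map default to the
    reference residue alone (strict) or its chemistry group (relaxed mode).
    """

    family_id: str
    reference_id: str
    catalytic_positions: tuple[int, ...] = ()
    allowed_residues: dict[int, frozenset[str]] = field(default_factory=dict)
    conserved_regions: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        for pos in self.catalytic_positions:
            if pos < 1:
                raise ValueError(f"catalytic position {pos} is not 1-based positive")
        for start, end in self.conserved_regions:
            if not (1 <= start <= end):
                raise ValueError(f"malformed conserved region ({start}, {end})")
        for pos, allowed in self.allowed_residues.items():
            if not allowed:
                raise ValueError(f"empty allowed-residue set at position {pos}")


@dataclass(frozen=True)
class SequenceVerdict:
    sequence_id: str
    status: str  # "pass" | "fail"
    reasons: frozenset[str]
    positions: dict[str, tuple[int, ...]]  # reason -> offending reference positions


@dataclass
class CurationReport:
    verdicts: list[SequenceVerdict]

    @property
    def passed(self) -> list[str]:
        return [v.sequence_id for v in self.verdicts if v.status == "pass"]

    @property
    def failed(self) -> list[str]:
        return [v.sequence_id for v in self.verdicts if v.status == "fail"]

    def to_tsv(self, path_or_buf) -> None:
        lines = ["sequence_id\tstatus\treasons\tpositions\n"]
        for v in self.verdicts:
            reasons = ";".join(sorted(v.reasons))
            positions = ";".join(
                f"{reason}:{','.join(map(str, pos))}"
                for reason, pos in sorted(v.positions.items())
            )
            lines.append(f"{v.sequence_id}\t{v.status}\t{reasons}\t{positions}\n")
        if isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__"):
            with open(path_or_buf, "w") as fh:
                fh.writelines(lines)
        else:
            path_or_buf.writelines(lines)


Alignment = Sequence[tuple[str, str]]  # (sequence id, aligned sequence)


def read_alignment_fasta(path_or_buf) -> list[tuple[str, str]]:
    if isinstance(path_or_buf, str) and "\n" in path_or_buf:
        path_or_buf = io.StringIO(path_or_buf)
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path_or_buf, "fasta")]


def write_alignment_fasta(alignment: Alignment, path_or_buf) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in alignment
    ]
    SeqIO.write(records, path_or_buf, "fasta")


def map_reference_columns(
    alignment: Alignment, spec: CatalyticSiteSpec
) -> dict[int, int]:
    """Map 1-based ungapped reference positions to 1-based alignment columns."""
    rows = dict(alignment)
    if spec.reference_id not in rows:
        raise ValueError(f"reference {spec.reference_id!r} not in alignment")
    ref = rows[spec.reference_id]
    mapping: dict[int, int] = {}
    residue = 0
    for col, char in enumerate(ref, start=1):
        if char not in GAP_CHARS:
            residue += 1
            mapping[residue] = col
    needed = max(
        [*spec.catalytic_positions, *(end for _s, end in spec.conserved_regions)],
        default=0,
    )
    if needed > residue:
        raise ValueError(
            f"reference {spec.reference_id!r} has {residue} residues but the "
            f"site spec needs position {needed}"
        )
    return mapping


def check_sequence(
    aligned_seq: str,
    spec: CatalyticSiteSpec,
    column_map: dict[int, int],
    reference_seq: str | None = None,
    relaxed: bool = False,
    deletion_threshold: float = 0.5,
) -> tuple[str, frozenset[str], dict[str, tuple[int, ...]]]:
    """Check one aligned sequence against the catalytic-site spec.

    Flags ``catalytic_gap`` for a gap at any catalytic column,
    ``invalid_substitution`` for a residue outside the allowed set there, and
    ``conserved_region_deletion`` when a conserved region's columns are more
    than ``deletion_threshold`` gaps.  ``reference_seq`` (the aligned
    reference row) supplies default allowed residues for positions the spec
    leaves implicit.
    """
    n_cols = max(column_map.values(), default=0)
    if n_cols and len(aligned_seq) < n_cols:
        raise ValueError(
            f"aligned sequence length {len(aligned_seq)} shorter than mapped "
            f"columns ({n_cols})"
        )
    seq = aligned_seq.upper()
    ref = reference_seq.upper() if reference_seq is not None else None
    reasons: set[str] = set()
    positions: dict[str, list[int]] = {}

    for pos in spec.catalytic_positions:
        col = column_map[pos]
        char = seq[col - 1]
        if char in GAP_CHARS:
            reasons.add("catalytic_gap")
            positions.setdefault("catalytic_gap", []).append(pos)
            continue
        allowed = spec.allowed_residues.get(pos)
        if allowed is None:
            if ref is None:
                raise ValueError(
                    f"no allowed residues for position {pos} and no reference row"
                )
            ref_res = ref[col - 1]
            allowed = _relaxed_allowed(ref_res) if relaxed else frozenset({ref_res})
        elif relaxed:
            allowed = frozenset().union(*(_relaxed_allowed(r) for r in allowed))
        if char not in allowed:
            reasons.add("invalid_substitution")
            positions.setdefault("invalid_substitution", []).append(pos)

    for start, end in spec.conserved_regions:
        cols = [column_map[p] for p in range(start, end + 1)]
        gaps = sum(1 for c in cols if seq[c - 1] in GAP_CHARS)
        if gaps / len(cols) > deletion_threshold:
            reasons.add("conserved_region_deletion")
            positions.setdefault("conserved_region_deletion", []).append(start)

    status = "fail" if reasons else "pass"
    return status, frozenset(reasons), {k: tuple(v) for k, v in positions.items()}


def curate_alignment(
    alignment: Alignment,
    spec: CatalyticSiteSpec,
    deletion_threshold: float = 0.5,
    relaxed: bool = False,
) -> tuple[list[tuple[str, str]], CurationReport]:
    """Filter an alignment to the sequences passing the catalytic-site check.

    The report covers every input sequence; the reference always passes;
    input order is preserved.  An empty result is a warning condition for
    the caller, not an exception.
    """
    if not (0 <= deletion_threshold <= 1):
        raise ValueError("deletion_threshold must be in [0, 1]")
    column_map = map_reference_columns(alignment, spec)
    ref_seq = dict(alignment)[spec.reference_id]
    lengths = {len(seq) for _name, seq in alignment}
    if len(lengths) > 1:
        raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
    verdicts: list[SequenceVerdict] = []
    kept: list[tuple[str, str]] = []
    for name, seq in alignment:
        status, reasons, positions = check_sequence(
            seq,
            spec,
            column_map,
            reference_seq=ref_seq,
            relaxed=relaxed,
            deletion_threshold=deletion_threshold,
        )
        verdicts.append(SequenceVerdict(name, status, reasons, positions))
        if status == "pass":
            kept.append((name, seq))
    return kept, CurationReport(verdicts)


def load_site_spec(stream: Iterable[str] | str) -> CatalyticSiteSpec:
    """Read a site spec TSV.

    Columns: family, reference_id, position, allowed_residues, region_start,
    region_end.  Each data row is either a catalytic-position row (position
    set, optionally allowed_residues as a string of one-letter codes) or a
    conserved-region row (region_start and region_end set).
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    rows = [line.rstrip("\n") for line in stream]
    rows = [r for r in rows if r.strip() and not r.startswith("#")]
    if not rows:
        raise ValueError("empty site spec")
    header = rows[0].split("\t")
    expected = ["family", "reference_id", "position", "allowed_residues", "region_start", "region_end"]
    if header != expected:
        raise ValueError(f"site spec header must be {expected}, got {header}")
    family_id = None
    reference_id = None
    catalytic: list[int] = []
    allowed: dict[int, frozenset[str]] = {}
    regions: list[tuple[int, int]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        fields = row.split("\t")
        if len(fields) != 6:
            raise ValueError(f"line {lineno}: expected 6 columns")
        fam, ref, pos, allow, rstart, rend = (f.strip() for f in fields)
        if family_id is None:
            family_id, reference_id = fam, ref
        elif (fam, ref) != (family_id, reference_id):
            raise ValueError(f"line {lineno}: mixed family/reference rows")
        if pos:
            p = int(pos)
            catalytic.append(p)
            if allow:
                allowed[p] = frozenset(allow.upper())
        elif rstart and rend:
            regions.append((int(rstart), int(rend)))
        else:
            raise ValueError(
                f"line {lineno}: row needs either a position or a region"
            )
    return CatalyticSiteSpec(
        family_id=family_id,
        reference_id=reference_id,
        catalytic_positions=tuple(catalytic),
        allowed_residues=allowed,
        conserved_regions=tuple(regions),
    )
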