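"""Multi-label lifestyle annotation of organisms.

Each organism carries zero or more of ten controlled lifestyle labels
(pathogen, opportunistic pathogen, saprotroph, commensal, mutualist,
living in water, living on land, endophyte, associated with plants,
associated with animals).  Labels are not exclusive: an amphibious plant
pathogen belongs to every matching group, so lifestyle groups overlap.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = ["VOCABULARY", "EcologyTable", "load_ecology", "normalize_label"]

VOCABULARY: frozenset[str] = frozenset(
    {
        "pathogen",
        "opportunistic_pathogen",
        "saprotroph",
        "commensal",
        "mutualist",
        "living_in_water",
        "living_on_land",
        "endophyte",
        "associated_with_plants",
        "associated_with_animals",
    }
)


def normalize_label(label: str) -> str:
    """Lower-case and replace runs of whitespace with underscores."""
    return "_".join(label.strip().lower().split())


@dataclass
class EcologyTable:
    """organism -> set of lifestyle labels, with a stable organism order."""

    entries: dict[str, frozenset[str]]
    vocabulary: frozenset[str] = field(default=VOCABULARY)

    def __post_init__(self) -> None:
        for org, labels in self.entries.items():
            unknown = set(labels) - self.vocabulary
            if unknown:
                raise ValueError(
                    f"organism {org!r} carries unknown label(s): {sorted(unknown)}"
                )
            self.entries[org] = frozenset(labels)

    @property
    def organisms(self) -> list[str]:
        return list(self.entries)

    def labels_of(self, organism: str) -> frozenset[str]:
        return self.entries[organism]

    def group_members(self, label: str) -> list[str]:
        """Organisms carrying ``label``, in stable roster order (may be empty)."""
        if label not in self.vocabulary:
            raise ValueError(f"unknown label {label!r}")
        return [org for org, labels in self.entries.items() if label in labels]

    def to_tsv(self, path_or_buf) -> None:
        lines = [
            f"{org}\t{';'.join(sorted(labels))}\n" for org, labels in self.entries.items()
        ]
        if isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__"):
            with open(path_or_buf, "w") as fh:
                fh.writelines(lines)
        else:
            path_or_buf.writelines(lines)


def load_ecology(
    stream: Iterable[str] | str,
    vocabulary: frozenset[str] = VOCABULARY,
) -> EcologyTable:
    """Read a two-column TSV: organism_id, semicolon-separated labels.

    Labels are normalized (lower-cased, spaces to underscores) and
    duplicates within a cell collapse.  An empty second column means the
    organism belongs to no group.  Unknown labels and duplicate organism
    rows are errors.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    entries: dict[str, frozenset[str]] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) not in (1, 2):
            raise ValueError(f"line {lineno}: expected 2 tab-separated columns")
        org = parts[0].strip()
        if not org:
            raise ValueError(f"line {lineno}: empty organism id")
        if org in entries:
            raise ValueError(f"line {lineno}: duplicate organism id {org!r}")
        cell = parts[1] if len(parts) == 2 else ""
        labels = {normalize_label(tok) for tok in cell.split(";") if tok.strip()}
        unknown = labels - vocabulary
        if unknown:
            raise ValueError(
                f"line {lineno}: organism {org!r} has unknown label(s) "
                f"{sorted(unknown)}"
            )
        entries[org] = frozenset(labels)
    return EcologyTable(entries=entries, vocabulary=vocabulary)
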