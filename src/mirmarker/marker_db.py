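"""Published bladder-cancer miRNA marker catalogue: model and TSV I/O.

The catalogue mirrors the literature-derived marker database the pipeline is
validated against: one row per miRNA with its published expression direction
(or methylation class), the supporting citations and an optional pathway note.
Names in the literature mix conventions freely (``hsa-miR-205``, ``miR205``,
``Let7c``); everything is joined on a canonical lower-case form.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence


class CatalogueError(ValueError):
    """Malformed catalogue file or conflicting records."""


class InvalidNameError(ValueError):
    """A miRNA name that cannot be canonicalized (empty/blank)."""


class PublishedStatus(str, Enum):
    UP = "UP"
    DOWN = "DOWN"
    CONTRADICTORY = "CONTRADICTORY"


class MarkerType(str, Enum):
    EXPRESSION = "EXPRESSION"
    METHYLATION_HYPO = "METHYLATION_HYPO"
    METHYLATION_HYPER = "METHYLATION_HYPER"


_SPECIES_PREFIX = re.compile(r"^[a-z]{3}-(?=(mir|let))")
_ARM_SUFFIX = re.compile(r"[-_. ]?(5p|3p)$")
_SEPARATORS = re.compile(r"[-_. ]")


def normalize_mirna_name(raw: str) -> str:
    """Canonicalize a free-text miRNA name.

    Lower-cases, strips a species prefix (``hsa-`` and friends), removes
    internal hyphens/spaces, and preserves a mature-arm suffix (``-5p``/
    ``-3p``) with a single leading hyphen.  Idempotent:
    ``normalize_mirna_name("hsa-miR-205") == "mir205"`` and
    ``normalize_mirna_name("mir205") == "mir205"``.
    """
    if raw is None or not str(raw).strip():
        raise InvalidNameError("miRNA name is empty")
    name = str(raw).strip().lower()
    name = _SPECIES_PREFIX.sub("", name)
    arm = None
    m = _ARM_SUFFIX.search(name)
    if m:
        arm = m.group(1)
        name = name[: m.start()]
    name = _SEPARATORS.sub("", name)
    if not name:
        raise InvalidNameError(f"miRNA name {raw!r} is empty after normalization")
    return f"{name}-{arm}" if arm else name


def resolve_published_status(
    directions: Sequence[PublishedStatus | str],
) -> PublishedStatus:
    """Combine per-study directions into one published status.

    All-UP gives UP, all-DOWN gives DOWN, anything mixed is CONTRADICTORY
    (the situation of miR141/miR205, reported both ways in the literature).
    Order-invariant.
    """
    if not directions:
        raise ValueError("no directions to resolve")
    dirs = {PublishedStatus(d) for d in directions}
    if dirs - {PublishedStatus.UP, PublishedStatus.DOWN}:
        raise ValueError("directions must be UP or DOWN")
    if dirs == {PublishedStatus.UP}:
        return PublishedStatus.UP
    if dirs == {PublishedStatus.DOWN}:
        return PublishedStatus.DOWN
    return PublishedStatus.CONTRADICTORY


@dataclass
class MarkerRecord:
    """One catalogue entry, keyed by canonical miRNA id."""

    mirna_id: str
    published_status: PublishedStatus
    marker_type: MarkerType = MarkerType.EXPRESSION
    references: list[str] = field(default_factory=list)
    pathway_note: str | None = None

    def __post_init__(self) -> None:
        self.mirna_id = normalize_mirna_name(self.mirna_id)
        self.published_status = PublishedStatus(self.published_status)
        self.marker_type = MarkerType(self.marker_type)


_COLUMNS = ["name", "status", "type", "references", "note"]


def load_marker_catalogue(path: str | Path) -> list[MarkerRecord]:
    """Read a marker catalogue TSV (columns name/status/type/references/note).

    Names are canonicalized on load; duplicate canonical ids are rejected so
    that ``hsa-miR-205`` and ``mir205`` cannot coexist.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise CatalogueError(f"{path}: empty catalogue file")
    header = lines[0].split("\t")
    if header != _COLUMNS:
        raise CatalogueError(
            f"{path}: expected header {_COLUMNS}, got {header}"
        )
    records: list[MarkerRecord] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(_COLUMNS):
            raise CatalogueError(f"{path}:{lineno}: expected 5 columns")
        name, status, mtype, refs, note = fields
        try:
            status_enum = PublishedStatus(status.strip().upper())
        except ValueError:
            raise CatalogueError(
                f"{path}:{lineno}: unknown status {status!r}"
            ) from None
        try:
            type_enum = MarkerType(mtype.strip().upper())
        except ValueError:
            raise CatalogueError(
                f"{path}:{lineno}: unknown marker type {mtype!r}"
            ) from None
        rec = MarkerRecord(
            mirna_id=name,
            published_status=status_enum,
            marker_type=type_enum,
            references=[r for r in refs.split("|") if r],
            pathway_note=note or None,
        )
        if rec.mirna_id in seen:
            raise CatalogueError(
                f"{path}:{lineno}: duplicate marker {rec.mirna_id!r} "
                "after name normalization"
            )
        seen.add(rec.mirna_id)
        records.append(rec)
    return records


def save_marker_catalogue(records: Iterable[MarkerRecord], path: str | Path) -> None:
    """Write records in the canonical TSV form (load/save round-trips bytewise)."""
    rows = ["\t".join(_COLUMNS)]
    for rec in records:
        rows.append(
            "\t".join(
                [
                    rec.mirna_id,
                    rec.published_status.value,
                    rec.marker_type.value,
                    "|".join(rec.references),
                    rec.pathway_note or "",
                ]
            )
        )
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


def bundled_catalogue() -> list[MarkerRecord]:
    """The packaged 102-marker bladder-cancer catalogue (95 expression + 7
    methylation markers; names not recoverable from the literature summary are
    synthetic fillers, labelled as such in their note field)."""
    with resources.as_file(
        resources.files("mirmarker.data") / "bladder_marker_catalogue.tsv"
    ) as p:
        return load_marker_catalogue(p)
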