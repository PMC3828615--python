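"""Concordance of observed status calls with the published catalogue, and
cross-method congruence sets.

Agreement is directional: an observed UP or DOWN matches the published
direction (a CONTRADICTORY published status matches either); NEUTRAL and
MIXED calls are non-directional and count against the per-method concordance
percentage without being "wrong" in direction.

Congruence places every marker assessed by at least two experimental methods
into exactly one cell keyed by the set of methods (plus the pseudo-method
``PUBLISHED``) that agree directionally on it — the largest such group wins;
markers on which no two methods agree land in the empty cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .diffexp import Status, StatusCall
from .marker_db import MarkerRecord, PublishedStatus

PUBLISHED = "PUBLISHED"


class Agreement(str, Enum):
    AGREE = "AGREE"
    DISAGREE = "DISAGREE"
    NOT_DIRECTIONAL = "NOT_DIRECTIONAL"


def marker_agreement(
    observed: StatusCall | Status, published_status: PublishedStatus
) -> Agreement:
    """Directional match of one observed call against the published status."""
    status = observed.status if isinstance(observed, StatusCall) else observed
    if status in (Status.NEUTRAL, Status.MIXED):
        return Agreement.NOT_DIRECTIONAL
    if published_status == PublishedStatus.CONTRADICTORY:
        return Agreement.AGREE
    return (
        Agreement.AGREE
        if status.value == published_status.value
        else Agreement.DISAGREE
    )


@dataclass
class MethodSummary:
    n_assessed: int
    n_agree: int

    @property
    def percent_agree(self) -> float | None:
        if self.n_assessed == 0:
            return None
        return 100.0 * self.n_agree / self.n_assessed


@dataclass
class ConcordanceReport:
    per_marker: pd.DataFrame
    summaries: dict[str, MethodSummary]
    congruence: dict[frozenset, tuple[str, ...]]


def _published_direction(status: PublishedStatus) -> str | None:
    """UP/DOWN for directional statuses, 'ANY' wildcard for CONTRADICTORY."""
    if status == PublishedStatus.CONTRADICTORY:
        return "ANY"
    return status.value


def _congruence_cell(
    directions: Mapping[str, str], published: str | None
) -> frozenset:
    """Cell for one marker: the largest set of mutually agreeing methods.

    ``directions`` maps experimental method -> UP/DOWN (non-directional calls
    omitted).  A directional published status joins its group; CONTRADICTORY
    published joins the winning group.  Ties prefer the group containing
    PUBLISHED, then the UP group.  Groups below two members give the empty
    cell (no mutual agreement).
    """
    groups: dict[str, set[str]] = {"UP": set(), "DOWN": set()}
    for method, d in directions.items():
        groups[d].add(method)
    if published in ("UP", "DOWN"):
        groups[published].add(PUBLISHED)
    up, down = groups["UP"], groups["DOWN"]
    if published == "ANY":
        # wildcard published agrees with either direction; join the larger
        target = up if len(up) >= len(down) else down
        if target:
            target.add(PUBLISHED)
    if len(up) > len(down):
        winner = up
    elif len(down) > len(up):
        winner = down
    elif PUBLISHED in up:
        winner = up
    else:
        winner = up if up else down
    return frozenset(winner) if len(winner) >= 2 else frozenset()


def concordance_summary(
    calls_by_method: Mapping[str, Mapping[str, StatusCall]],
    catalogue: Sequence[MarkerRecord],
) -> ConcordanceReport:
    """Per-method concordance percentages and the cross-method congruence
    partition over all catalogue markers.

    ``calls_by_method`` maps method name (DS/SSH/MA/QPCR...) to per-miRNA
    calls; markers with no call for a method are not assessed by it and do
    not enter that method's denominator.
    """
    if not calls_by_method:
        raise ValueError("need calls for at least one method")
    methods = sorted(calls_by_method)
    published = {r.mirna_id: r.published_status for r in catalogue}
    rows = []
    summaries = {m: MethodSummary(0, 0) for m in methods}
    congruence: dict[frozenset, list[str]] = {}
    for rec in catalogue:
        row: dict[str, object] = {"mirna": rec.mirna_id, "published": rec.published_status.value}
        directions: dict[str, str] = {}
        n_methods_assessed = 0
        for m in methods:
            call = calls_by_method[m].get(rec.mirna_id)
            if call is None:
                row[m] = ""
                row[f"{m}_agreement"] = "NOT_ASSESSED"
                continue
            n_methods_assessed += 1
            agreement = marker_agreement(call, rec.published_status)
            row[m] = call.status.value
            row[f"{m}_agreement"] = agreement.value
            summaries[m].n_assessed += 1
            if agreement == Agreement.AGREE:
                summaries[m].n_agree += 1
            if call.status in (Status.UP, Status.DOWN):
                directions[m] = call.status.value
        if n_methods_assessed >= 2:
            cell = _congruence_cell(directions, _published_direction(rec.published_status))
            congruence.setdefault(cell, []).append(rec.mirna_id)
        rows.append(row)
    return ConcordanceReport(
        per_marker=pd.DataFrame(rows),
        summaries=summaries,
        congruence={k: tuple(sorted(v)) for k, v in congruence.items()},
    )


def assessed_fraction(
    catalogue: Sequence[MarkerRecord], assessed_ids: set[str] | Sequence[str]
) -> tuple[int, float]:
    """How many catalogue markers were assessed, and the percentage of the
    catalogue they represent (38 of 102 -> 37.3)."""
    assessed_ids = set(assessed_ids)
    count = sum(1 for r in catalogue if r.mirna_id in assessed_ids)
    percent = 100.0 * count / len(catalogue) if catalogue else 0.0
    return count, percent


def direction_tally(calls: Sequence[StatusCall]) -> tuple[int, int, int, int]:
    """(n_up, n_down, n_mixed, n_neutral) over a method's calls."""
    n_up = sum(1 for c in calls if c.status == Status.UP)
    n_down = sum(1 for c in calls if c.status == Status.DOWN)
    n_mixed = sum(1 for c in calls if c.status == Status.MIXED)
    n_neutral = sum(1 for c in calls if c.status == Status.NEUTRAL)
    return n_up, n_down, n_mixed, n_neutral


def report_to_json(report: ConcordanceReport) -> dict:
    """JSON-ready summary: per-method percentages plus congruence cells."""
    return {
        "methods": {
            m: {
                "n_assessed": s.n_assessed,
                "n_agree": s.n_agree,
                "percent_agree": (
                    None if s.percent_agree is None else round(s.percent_agree, 1)
                ),
            }
            for m, s in sorted(report.summaries.items())
        },
        "congruence": {
            "+".join(sorted(cell)) if cell else "(none)": list(markers)
            for cell, markers in sorted(
                report.congruence.items(), key=lambda kv: sorted(kv[0])
            )
        },
    }


def write_report(report: ConcordanceReport, tsv_path: str | Path, json_path: str | Path) -> None:
    report.per_marker.to_csv(tsv_path, sep="\t", index=False)
    Path(json_path).write_text(
        json.dumps(report_to_json(report), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
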