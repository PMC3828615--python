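"""Per-marker diagnostic scoring: sensitivity, specificity and the summary
AUC = (Sp + Sn)/2 with the conventional 0.7 "valuable marker" threshold.

Sensitivity is the fraction of tumor samples whose ratio crosses the tier cut
in the marker's published direction.  Specificity needs per-normal-sample
ratios; with a single pooled normal (the deep-sequencing design) these do not
exist, so Sp and AUC are undefined and only Sn is reported — when several
individual normals are available, each normal is compared against the mean of
the remaining normals (leave-one-out) and Sp is the fraction not called in
the marker's direction.  Note this AUC is the (Sp+Sn)/2 summary statistic,
not a ROC-curve integral.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .diffexp import RatioProfile, Status, Tier
from .marker_db import MarkerRecord, PublishedStatus

AUC_VALUABLE_THRESHOLD = 0.7


@dataclass
class MarkerEvaluation:
    mirna_id: str
    direction_tested: Status
    tier: Tier
    sn: float | None
    sp: float | None
    auc: float | None
    valuable: bool
    assessed: bool


def _in_direction(ratio: float, direction: Status, tier: Tier) -> bool:
    if direction == Status.UP:
        return ratio > tier.up_cut
    if direction == Status.DOWN:
        return ratio < tier.down_cut
    raise ValueError("direction must be UP or DOWN")


def sensitivity_score(direction: Status, profile: RatioProfile, tier: Tier) -> float:
    """Sn = fraction of non-excluded tumor samples crossing the cut in the
    marker's direction."""
    if not profile.assessed:
        raise ValueError(f"{profile.mirna_id}: no non-excluded samples")
    hits = sum(1 for r in profile.ratios.values() if _in_direction(r, direction, tier))
    return hits / len(profile.ratios)


def leave_one_out_normal_ratios(normal_rpm: Mapping[str, float]) -> list[float]:
    """Each normal sample's abundance over the mean of the remaining normals.

    This reconstructs a specificity denominator for designs where tumors are
    compared to a pooled normal and no per-normal ratio exists natively.
    Zero-mean remainders give an infinite ratio when the sample itself is
    non-zero, and 1 (uninformative) when everything is zero.
    """
    samples = list(normal_rpm)
    if len(samples) < 2:
        raise ValueError("need >= 2 normal samples")
    ratios = []
    for s in samples:
        rest = [normal_rpm[t] for t in samples if t != s]
        mean_rest = sum(rest) / len(rest)
        if mean_rest == 0:
            ratios.append(float("inf") if normal_rpm[s] > 0 else 1.0)
        else:
            ratios.append(normal_rpm[s] / mean_rest)
    return ratios


def specificity_score(
    direction: Status, normal_ratios: Sequence[float], tier: Tier
) -> float:
    """Sp = fraction of normal samples NOT called in the marker's direction."""
    if len(normal_ratios) < 2:
        raise ValueError("need >= 2 normal samples for specificity")
    false_calls = sum(1 for r in normal_ratios if _in_direction(r, direction, tier))
    return 1.0 - false_calls / len(normal_ratios)


def auc_score(sp: float, sn: float) -> float:
    """AUC = (Sp + Sn)/2; valuable only when strictly above 0.7."""
    for name, v in (("sp", sp), ("sn", sn)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    return (sp + sn) / 2.0


def is_valuable(auc: float | None) -> bool:
    return auc is not None and auc > AUC_VALUABLE_THRESHOLD


def evaluate_markers(
    catalogue: Sequence[MarkerRecord],
    profiles: Mapping[str, RatioProfile],
    tier: Tier,
    normal_ratios: Mapping[str, Sequence[float]] | None = None,
) -> list[MarkerEvaluation]:
    """Score every catalogue marker at one tier.

    CONTRADICTORY markers are tested in both directions (two rows); markers
    absent from the profiles come back as not-assessed rows.  ``normal_ratios``
    optionally supplies per-marker leave-one-out normal ratios enabling Sp and
    AUC; without it only Sn is reported (the pooled-normal design).
    """
    evaluations: list[MarkerEvaluation] = []
    for rec in catalogue:
        if rec.published_status == PublishedStatus.CONTRADICTORY:
            directions = [Status.UP, Status.DOWN]
        else:
            directions = [Status(rec.published_status.value)]
        profile = profiles.get(rec.mirna_id)
        for direction in directions:
            if profile is None or not profile.assessed:
                evaluations.append(
                    MarkerEvaluation(
                        rec.mirna_id, direction, tier,
                        sn=None, sp=None, auc=None, valuable=False, assessed=False,
                    )
                )
                continue
            sn = sensitivity_score(direction, profile, tier)
            sp = auc = None
            nr = None if normal_ratios is None else normal_ratios.get(rec.mirna_id)
            if nr is not None and len(nr) >= 2:
                sp = specificity_score(direction, nr, tier)
                auc = auc_score(sp, sn)
            evaluations.append(
                MarkerEvaluation(
                    rec.mirna_id, direction, tier,
                    sn=sn, sp=sp, auc=auc, valuable=is_valuable(auc), assessed=True,
                )
            )
    return evaluations


def evaluations_to_frame(evaluations: Sequence[MarkerEvaluation]) -> pd.DataFrame:
    def fmt(v):
        return "" if v is None else f"{v:.6g}"

    return pd.DataFrame(
        {
            "mirna": [e.mirna_id for e in evaluations],
            "direction_tested": [e.direction_tested.value for e in evaluations],
            "tier": [e.tier.name for e in evaluations],
            "sn": [fmt(e.sn) for e in evaluations],
            "sp": [fmt(e.sp) for e in evaluations],
            "auc": [fmt(e.auc) for e in evaluations],
            "valuable": [str(e.valuable).lower() for e in evaluations],
            "assessed": [str(e.assessed).lower() for e in evaluations],
        }
    )


def evaluations_to_tsv(evaluations: Sequence[MarkerEvaluation], path: str | Path) -> None:
    evaluations_to_frame(evaluations).to_csv(path, sep="\t", index=False)
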