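"""Platform-specific differential-expression calls.

Three calling procedures, one per assay:

* deep sequencing (DS): per-tumor-sample abundance ratios against a pooled
  normal, classified by a vote rule — a miRNA is UP when more samples exceed
  the upper cut than fall below the lower cut, at one of three cut-off tiers
  (2x, 3x, 4x with reciprocal lower cuts);
* suppression subtractive hybridization (SSH): the ratio of normalized read
  counts between the tumor- and normal-enriched subtracted libraries, gated
  on a minimum total of 10 normalized reads and a 1.5-fold change;
* microarray (MA): a location test on log2 intensities (p < 0.01) combined
  with a 1.5-fold change of group means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

INF = math.inf


class Tier(Enum):
    """Fold-change cut-off tier: (upper cut, lower cut = 1/upper)."""

    SOFT = 2.0
    MEDIUM = 3.0
    STRICT = 4.0

    @property
    def up_cut(self) -> float:
        return self.value

    @property
    def down_cut(self) -> float:
        return 1.0 / self.value


class Status(str, Enum):
    UP = "UP"
    DOWN = "DOWN"
    NEUTRAL = "NEUTRAL"
    MIXED = "MIXED"


@dataclass
class RatioProfile:
    """Per-tumor-sample expression ratios r_s = R^BC_s / R^N for one miRNA.

    ``ratios`` maps sample id -> ratio; infinite when the pooled-normal
    abundance is zero but the tumor's is not (total suppression in normal).
    Samples where both terms are zero are excluded and carry no ratio.
    """

    mirna_id: str
    ratios: dict[str, float] = field(default_factory=dict)
    denominator_zero: set[str] = field(default_factory=set)
    excluded: set[str] = field(default_factory=set)

    @property
    def assessed(self) -> bool:
        return bool(self.ratios)


@dataclass
class StatusCall:
    mirna_id: str
    status: Status
    up_votes: int = 0
    down_votes: int = 0
    neutral_votes: int = 0
    tier: Tier | None = None
    method: str = "DS"
    ratios: tuple[float, ...] | None = None
    pvalue: float | None = None
    fold: float | None = None


def per_sample_ratios(
    counts, tumor_ids: Sequence[str], pooled_normal_id: str
) -> dict[str, RatioProfile]:
    """Compute R^BC_s / R^N ratio profiles from a CountTable (RPM scale).

    Ratios are denominator-invariant within a run: any common RPM scaling of
    tumor and normal columns cancels.
    """
    rpm = counts.rpm
    missing = [s for s in [*tumor_ids, pooled_normal_id] if s not in rpm.columns]
    if missing:
        raise KeyError(f"unknown sample id(s): {missing}")
    profiles: dict[str, RatioProfile] = {}
    normal = rpm[pooled_normal_id]
    for mirna in rpm.index:
        prof = RatioProfile(mirna_id=mirna)
        r_n = float(normal[mirna])
        for s in tumor_ids:
            r_bc = float(rpm.at[mirna, s])
            if r_bc == 0 and r_n == 0:
                prof.excluded.add(s)
            elif r_n == 0:
                prof.ratios[s] = INF
                prof.denominator_zero.add(s)
            else:
                prof.ratios[s] = r_bc / r_n
        profiles[mirna] = prof
    return profiles


def vote_classify(
    profile: RatioProfile, tier: Tier, method: str = "DS"
) -> StatusCall | None:
    """Classify a ratio profile by the per-sample vote rule.

    A sample votes up when its ratio exceeds the tier's upper cut (infinite
    ratios always vote up) and down when below the lower cut.  UP when up
    votes outnumber down votes, DOWN for the converse, MIXED on a non-zero
    tie, NEUTRAL when no sample votes.  Returns None when every sample was
    excluded (miRNA not assessed).
    """
    if not profile.assessed:
        return None
    up = sum(1 for r in profile.ratios.values() if r > tier.up_cut)
    down = sum(1 for r in profile.ratios.values() if r < tier.down_cut)
    neutral = len(profile.ratios) - up - down
    if up > down:
        status = Status.UP
    elif down > up:
        status = Status.DOWN
    elif up > 0:
        status = Status.MIXED
    else:
        status = Status.NEUTRAL
    return StatusCall(
        mirna_id=profile.mirna_id,
        status=status,
        up_votes=up,
        down_votes=down,
        neutral_votes=neutral,
        tier=tier,
        method=method,
        ratios=tuple(profile.ratios.values()),
    )


@dataclass
class SshPair:
    """Normalized read counts of one miRNA in the two subtracted libraries
    (SR^BC from the tumor-enriched, SR^N from the normal-enriched one)."""

    mirna_id: str
    sr_bc: float
    sr_n: float

    def __post_init__(self) -> None:
        if self.sr_bc < 0 or self.sr_n < 0:
            raise ValueError("SSH read counts must be non-negative")


def ssh_differential(
    pair: SshPair,
    min_total: float = 10.0,
    min_fold: float = 1.5,
    total_mode: str = "sum",
) -> StatusCall | None:
    """SSH call: requires >= ``min_total`` normalized reads (summed across the
    two libraries by default, or in each with ``total_mode='each'``), then a
    >= 1.5-fold ratio SR^BC/SR^N in either direction.  Returns None when the
    read-count gate fails (not assessed)."""
    if total_mode == "sum":
        enough = pair.sr_bc + pair.sr_n >= min_total
    elif total_mode == "each":
        enough = pair.sr_bc >= min_total and pair.sr_n >= min_total
    else:
        raise ValueError("total_mode must be 'sum' or 'each'")
    if not enough:
        return None
    ratio = INF if pair.sr_n == 0 else pair.sr_bc / pair.sr_n
    if ratio >= min_fold:
        status = Status.UP
    elif ratio <= 1.0 / min_fold:
        status = Status.DOWN
    else:
        status = Status.NEUTRAL
    return StatusCall(
        mirna_id=pair.mirna_id,
        status=status,
        up_votes=int(status == Status.UP),
        down_votes=int(status == Status.DOWN),
        neutral_votes=int(status == Status.NEUTRAL),
        method="SSH",
        fold=ratio,
    )


def location_test(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sided unequal-variance (Welch) location test on log2 intensities.

    Symmetric in group order; degenerate equal-constant groups give p = 1.
    Intensities must be positive (log-transformed internally).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("intensities must be positive")
    la, lb = np.log2(a), np.log2(b)
    if la.std(ddof=1) == 0 and lb.std(ddof=1) == 0:
        return 1.0 if la.mean() == lb.mean() else 0.0
    p = sps.ttest_ind(la, lb, equal_var=False).pvalue
    return float(p)


@dataclass
class ArraySignalTable:
    """Probe x sample intensity matrix with tumor/normal sample groups."""

    signals: pd.DataFrame
    tumor_ids: list[str]
    normal_ids: list[str]

    def __post_init__(self) -> None:
        missing = [
            s for s in [*self.tumor_ids, *self.normal_ids]
            if s not in self.signals.columns
        ]
        if missing:
            raise KeyError(f"samples missing from signal table: {missing}")


def ma_differential(
    table: ArraySignalTable,
    p_threshold: float = 0.01,
    min_fold: float = 1.5,
) -> dict[str, StatusCall]:
    """Microarray differential calls per probe.

    Differential iff the location test on log2 signals gives p < 0.01 AND the
    ratio of group means is >= 1.5 (or <= 1/1.5); the direction follows the
    mean ratio.  Per-sample ratios S^BC_s / Sa^N (each tumor sample over the
    average normal signal) are attached to every call regardless of status.
    """
    if len(table.tumor_ids) < 2 or len(table.normal_ids) < 2:
        raise ValueError("need >= 2 tumor and >= 2 normal samples")
    calls: dict[str, StatusCall] = {}
    for probe in table.signals.index:
        tumors = table.signals.loc[probe, table.tumor_ids].to_numpy(dtype=float)
        normals = table.signals.loc[probe, table.normal_ids].to_numpy(dtype=float)
        p = location_test(tumors, normals)
        mean_normal = normals.mean()
        fold = INF if mean_normal == 0 else tumors.mean() / mean_normal
        if p < p_threshold and (fold >= min_fold or fold <= 1.0 / min_fold):
            status = Status.UP if fold > 1 else Status.DOWN
        else:
            status = Status.NEUTRAL
        ratios = tuple(float(t) / mean_normal for t in tumors)
        calls[probe] = StatusCall(
            mirna_id=probe,
            status=status,
            up_votes=int(status == Status.UP),
            down_votes=int(status == Status.DOWN),
            neutral_votes=int(status == Status.NEUTRAL),
            method="MA",
            ratios=ratios,
            pvalue=p,
            fold=fold,
        )
    return calls


# --------------------------------------------------------------------------
# I/O helpers
# --------------------------------------------------------------------------

def load_ssh_pairs(path: str | Path) -> list[SshPair]:
    """Read an SSH pair TSV with columns mirna, sr_bc, sr_n."""
    frame = pd.read_csv(path, sep="\t")
    required = {"mirna", "sr_bc", "sr_n"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return [
        SshPair(mirna_id=row.mirna, sr_bc=float(row.sr_bc), sr_n=float(row.sr_n))
        for row in frame.itertuples(index=False)
    ]


def save_ssh_pairs(pairs: Sequence[SshPair], path: str | Path) -> None:
    pd.DataFrame(
        {
            "mirna": [p.mirna_id for p in pairs],
            "sr_bc": [p.sr_bc for p in pairs],
            "sr_n": [p.sr_n for p in pairs],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def load_array_signals(
    signals_path: str | Path, conditions_path: str | Path
) -> ArraySignalTable:
    """Read a probe x sample TSV plus a sample/condition sidecar TSV
    (columns sample, condition with TUMOR/NORMAL values)."""
    signals = pd.read_csv(signals_path, sep="\t", index_col=0).astype(float)
    cond = pd.read_csv(conditions_path, sep="\t")
    if not {"sample", "condition"}.issubset(cond.columns):
        raise ValueError(f"{conditions_path}: expected columns sample, condition")
    tumors = [r.sample for r in cond.itertuples(index=False) if r.condition.upper() == "TUMOR"]
    normals = [r.sample for r in cond.itertuples(index=False) if r.condition.upper() == "NORMAL"]
    return ArraySignalTable(signals=signals, tumor_ids=tumors, normal_ids=normals)


def save_array_signals(
    table: ArraySignalTable, signals_path: str | Path, conditions_path: str | Path
) -> None:
    table.signals.to_csv(signals_path, sep="\t", float_format="%.6g", index_label="probe")
    rows = [(s, "TUMOR") for s in table.tumor_ids] + [
        (s, "NORMAL") for s in table.normal_ids
    ]
    pd.DataFrame(rows, columns=["sample", "condition"]).to_csv(
        conditions_path, sep="\t", index=False
    )


def calls_to_frame(calls: Mapping[str, StatusCall] | Sequence[StatusCall]) -> pd.DataFrame:
    """Flatten StatusCalls into a tidy frame (ratios JSON-encoded)."""
    import json

    if isinstance(calls, Mapping):
        calls = list(calls.values())
    rows = []
    for c in calls:
        rows.append(
            {
                "mirna": c.mirna_id,
                "method": c.method,
                "tier": c.tier.name if c.tier else "",
                "status": c.status.value,
                "up_votes": c.up_votes,
                "down_votes": c.down_votes,
                "neutral_votes": c.neutral_votes,
                "pvalue": "" if c.pvalue is None else f"{c.pvalue:.6g}",
                "fold": "" if c.fold is None else f"{c.fold:.6g}",
                "ratios": "" if c.ratios is None else json.dumps(
                    [("Infinity" if math.isinf(r) else round(r, 6)) for r in c.ratios]
                ),
            }
        )
    return pd.DataFrame(rows)
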