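"""Synthetic study generator with known ground truth.

Emulates the study design the pipeline was built for: a handful of tumor
small-RNA libraries compared against one physically pooled normal library,
plus microarray intensities and a pair of subtracted (SSH) libraries for the
same miRNA population.  Counts follow a negative-binomial family
(gamma-Poisson; dispersion 0 degenerates to Poisson), array intensities are
log-normal, and SSH capture is an all-or-nothing Bernoulli per miRNA,
reflecting how poly(A)-primed library construction misses most mature
miRNAs.

The per-library normalization denominator is the nominal sequencing depth:
the simulated marker miRNAs are a minority of everything that maps to the
genome, so their fold changes do not move the denominator and expected RPM
ratios equal the true fold.

Default design (the "paperlike" preset): 100 miRNAs, 20% up at 4-fold and
20% down at 0.25-fold, base abundances log-uniform between 2,000 and 16,000
RPM (the catalogue markers that a deep-sequencing assay actually assesses
are the well-detected ones; markers below robust detection are modeled as
absent rather than as low-count noise), 9 tumor libraries vs a pool of 6
normals at 100,000 mapped reads per library, dispersion 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexp import ArraySignalTable, SshPair, Status, StatusCall
from .marker_db import MarkerRecord, MarkerType, PublishedStatus
from .smallrna import CountTable, Condition, ReadLibrary

NUCLEOTIDES = np.array(list("ACGT"))


@dataclass
class TruthTable:
    """Ground truth per miRNA: status, fold, expected RPM in normal tissue."""

    table: pd.DataFrame  # index mirna_id; columns true_status, true_fold, base_abundance, in_catalogue

    def __post_init__(self) -> None:
        t = self.table
        for mirna, row in t.iterrows():
            s, f = row["true_status"], row["true_fold"]
            ok = (
                (s == "UP" and f > 1)
                or (s == "DOWN" and 0 < f < 1)
                or (s == "NEUTRAL" and f == 1)
            )
            if not ok:
                raise ValueError(f"{mirna}: status {s} inconsistent with fold {f}")

    @property
    def mirnas(self) -> list[str]:
        return list(self.table.index)

    def status_of(self, mirna: str) -> str:
        return str(self.table.at[mirna, "true_status"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.6g", index_label="mirna")

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        return cls(pd.read_csv(path, sep="\t", index_col="mirna"))


def generate_truth(
    n_mirna: int = 100,
    frac_up: float = 0.2,
    frac_down: float = 0.2,
    fold_up: float = 4.0,
    fold_down: float = 0.25,
    base_range: tuple[float, float] = (2000.0, 16000.0),
    seed: int = 0,
    mirna_ids: Sequence[str] | None = None,
    catalogue_ids: Sequence[str] | None = None,
) -> TruthTable:
    """Draw a ground-truth table: exact UP/DOWN counts by construction,
    log-uniform base abundances, deterministic for a fixed seed."""
    if frac_up + frac_down > 1:
        raise ValueError("frac_up + frac_down must be <= 1")
    if not fold_up > 1:
        raise ValueError("fold_up must exceed 1 for UP miRNAs")
    if not 0 < fold_down < 1:
        raise ValueError("fold_down must be below 1 for DOWN miRNAs")
    rng = np.random.default_rng(seed)
    if mirna_ids is None:
        mirna_ids = [f"mir{i + 1:04d}" for i in range(n_mirna)]
    if len(mirna_ids) != n_mirna:
        raise ValueError("mirna_ids length must equal n_mirna")
    n_up = round(n_mirna * frac_up)
    n_down = round(n_mirna * frac_down)
    status = np.array(["NEUTRAL"] * n_mirna, dtype=object)
    order = rng.permutation(n_mirna)
    status[order[:n_up]] = "UP"
    status[order[n_up : n_up + n_down]] = "DOWN"
    fold = np.where(status == "UP", fold_up, np.where(status == "DOWN", fold_down, 1.0))
    lo, hi = base_range
    base = np.exp(rng.uniform(math.log(lo), math.log(hi), n_mirna))
    in_cat = (
        pd.Index(mirna_ids).isin(set(catalogue_ids))
        if catalogue_ids is not None
        else np.ones(n_mirna, dtype=bool)
    )
    table = pd.DataFrame(
        {
            "true_status": status,
            "true_fold": fold,
            "base_abundance": base,
            "in_catalogue": in_cat,
        },
        index=pd.Index(mirna_ids, name="mirna"),
    )
    return TruthTable(table)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with var = mu + dispersion * mu^2 (gamma-
    Poisson mixture); dispersion 0 is plain Poisson."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def simulate_count_libraries(
    truth: TruthTable,
    n_tumor: int = 9,
    n_normal_members: int = 6,
    depth: float = 1e5,
    dispersion: float = 0.05,
    seed: int = 0,
    pooled_normal_id: str = "normal_pool",
) -> CountTable:
    """Simulate raw miRNA counts for tumor libraries and one pooled normal.

    Each library's expected count is depth x base_abundance/1e6 (x fold in
    tumors).  The pooled normal is the sum of ``n_normal_members`` member
    draws at depth/n so the pool is sequenced at the same depth as a tumor
    library, with member-averaged biological dispersion.  total_mapped is set
    to the nominal depth per library (the simulated miRNAs are a subset of
    everything that maps).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    base = truth.table["base_abundance"].to_numpy()
    fold = truth.table["true_fold"].to_numpy()
    cols: dict[str, np.ndarray] = {}
    for t in range(n_tumor):
        cols[f"tumor_{t + 1:02d}"] = _nb_draw(rng, base * fold / 1e6 * depth, dispersion)
    pool = np.zeros(len(base))
    for _ in range(n_normal_members):
        pool += _nb_draw(rng, base / 1e6 * (depth / n_normal_members), dispersion)
    cols[pooled_normal_id] = pool
    raw = pd.DataFrame(cols, index=truth.table.index.copy())
    totals = pd.Series({s: float(depth) for s in raw.columns})
    return CountTable.from_raw(raw, total_mapped=totals)


def random_reference(
    mirna_ids: Sequence[str],
    length_range: tuple[int, int] = (20, 23),
    seed: int = 0,
) -> dict[str, str]:
    """Random mature-miRNA sequences (unique, 20-23 nt) for the given ids."""
    rng = np.random.default_rng(seed)
    reference: dict[str, str] = {}
    seen: set[str] = set()
    for mid in mirna_ids:
        while True:
            L = int(rng.integers(length_range[0], length_range[1] + 1))
            seq = "".join(rng.choice(NUCLEOTIDES, L))
            if seq not in seen:
                seen.add(seq)
                reference[mid] = seq
                break
    return reference


def render_reads(
    counts: CountTable,
    reference: Mapping[str, str],
    adapter: str = "TCGTATGCCGTCTTCTGCTTG",
    error_rate: float = 0.0,
    seed: int = 0,
    conditions: Mapping[str, Condition] | None = None,
) -> list[ReadLibrary]:
    """Render a CountTable into raw read libraries.

    Every counted read becomes the mature sequence with independent per-base
    substitutions at ``error_rate``, suffixed with the 3' adapter; with a low
    error rate quantification of the output recovers the input counts.
    """
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    missing = [m for m in counts.raw.index if m not in reference]
    if missing:
        raise KeyError(f"reference lacks sequences for: {missing[:5]}")
    rng = np.random.default_rng(seed)
    libraries = []
    for sample in counts.samples:
        cond = (conditions or {}).get(sample)
        if cond is None:
            cond = Condition.POOLED_NORMAL if "normal" in sample else Condition.TUMOR
        reads: list[str] = []
        for mirna, n in counts.raw[sample].items():
            n = int(round(n))
            if n <= 0:
                continue
            seq = np.array(list(reference[mirna]))
            for _ in range(n):
                read = seq
                if error_rate > 0:
                    mask = rng.random(len(seq)) < error_rate
                    if mask.any():
                        read = seq.copy()
                        # substitute with a uniformly different base
                        for pos in np.flatnonzero(mask):
                            choices = [b for b in "ACGT" if b != read[pos]]
                            read[pos] = choices[int(rng.integers(3))]
                reads.append("".join(read) + adapter)
        libraries.append(ReadLibrary(sample_id=sample, condition=cond, reads=reads))
    return libraries


def simulate_array_signals(
    truth: TruthTable,
    n_tumor: int = 8,
    n_normal: int = 4,
    log2_sd: float = 0.5,
    seed: int = 0,
) -> ArraySignalTable:
    """Log-normal array intensities; tumor means shifted by log2(true fold)."""
    if log2_sd < 0:
        raise ValueError("log2_sd must be >= 0")
    if n_tumor < 2 or n_normal < 2:
        raise ValueError("need >= 2 samples per group")
    rng = np.random.default_rng(seed)
    base_log2 = np.log2(truth.table["base_abundance"].to_numpy())
    shift = np.log2(truth.table["true_fold"].to_numpy())
    cols = {}
    for t in range(n_tumor):
        cols[f"ma_tumor_{t + 1:02d}"] = 2.0 ** (
            base_log2 + shift + rng.normal(0, log2_sd, len(base_log2))
        )
    for n in range(n_normal):
        cols[f"ma_normal_{n + 1:02d}"] = 2.0 ** (
            base_log2 + rng.normal(0, log2_sd, len(base_log2))
        )
    signals = pd.DataFrame(cols, index=truth.table.index.copy())
    return ArraySignalTable(
        signals=signals,
        tumor_ids=[c for c in cols if "tumor" in c],
        normal_ids=[c for c in cols if "normal" in c],
    )


def simulate_ssh_pairs(
    truth: TruthTable,
    depth: float = 1e4,
    capture_bias: float = 0.4,
    seed: int = 0,
) -> list[SshPair]:
    """Subtracted-library read counts with all-or-nothing capture.

    Each miRNA is captured with probability ``capture_bias`` (poly(A)-primed
    SSH misses most mature miRNAs); captured miRNAs get Poisson counts
    proportional to abundance (x fold on the tumor side), uncaptured ones a
    0/0 pair that the SSH caller reports as not assessed.
    """
    if not 0 <= capture_bias <= 1:
        raise ValueError("capture_bias must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rel = truth.table["base_abundance"].to_numpy()
    rel = rel / rel.sum()
    fold = truth.table["true_fold"].to_numpy()
    captured = rng.random(len(rel)) < capture_bias
    pairs = []
    for i, mirna in enumerate(truth.mirnas):
        if not captured[i]:
            pairs.append(SshPair(mirna_id=mirna, sr_bc=0.0, sr_n=0.0))
            continue
        sr_bc = float(rng.poisson(rel[i] * fold[i] * depth))
        sr_n = float(rng.poisson(rel[i] * depth))
        pairs.append(SshPair(mirna_id=mirna, sr_bc=sr_bc, sr_n=sr_n))
    return pairs


def truth_catalogue(truth: TruthTable, flip: Mapping[str, str] | None = None) -> list[MarkerRecord]:
    """Build a marker catalogue from the truth's in_catalogue miRNAs, using
    the true direction as the published one (optionally overridden per miRNA
    via ``flip`` to create planted disagreements).  NEUTRAL miRNAs have no
    published claim and are omitted — a published marker is by definition a
    claimed differential."""
    records = []
    for mirna, row in truth.table.iterrows():
        if not row["in_catalogue"] or row["true_status"] == "NEUTRAL":
            continue
        status = (flip or {}).get(mirna, row["true_status"])
        records.append(
            MarkerRecord(
                mirna_id=mirna,
                published_status=PublishedStatus(status),
                marker_type=MarkerType.EXPRESSION,
                references=["synthetic truth"],
                pathway_note="synthetic",
            )
        )
    return records


def evaluate_recovery(
    truth: TruthTable, calls: Mapping[str, StatusCall | None]
) -> dict[str, float]:
    """Score DS calls against the ground truth.

    Returns the fraction of assessed truly-directional miRNAs whose call
    matches the true direction, and the fraction of assessed truly-NEUTRAL
    miRNAs called directional (UP or DOWN).
    """
    n_dir = n_dir_recovered = n_neutral = n_neutral_directional = 0
    for mirna in truth.mirnas:
        call = calls.get(mirna)
        if call is None:
            continue
        true_status = truth.status_of(mirna)
        if true_status in ("UP", "DOWN"):
            n_dir += 1
            if call.status.value == true_status:
                n_dir_recovered += 1
        else:
            n_neutral += 1
            if call.status in (Status.UP, Status.DOWN):
                n_neutral_directional += 1
    return {
        "n_directional_assessed": n_dir,
        "directional_recovered": n_dir_recovered / n_dir if n_dir else float("nan"),
        "n_neutral_assessed": n_neutral,
        "neutral_called_directional": (
            n_neutral_directional / n_neutral if n_neutral else float("nan")
        ),
    }
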