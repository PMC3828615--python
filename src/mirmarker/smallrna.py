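"""Small-RNA read quantification.

Implements the desk-scale analogue of a small-RNA-seq pipeline: 3' adapter
trimming, length filtering, collapsing to a non-redundant sequence list,
mismatch-tolerant mapping against a mature-miRNA reference, and normalization
to reads-per-million-mapped (RPM).  Mapping slides each read over every
same-length window of each reference sequence and assigns it to the entries at
minimal Hamming distance (up to ``max_mismatch``, default 2); ties split the
read's multiplicity equally so read mass is conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .marker_db import normalize_mirna_name


class Condition(str, Enum):
    TUMOR = "TUMOR"
    NORMAL = "NORMAL"
    POOLED_NORMAL = "POOLED_NORMAL"


@dataclass
class ReadLibrary:
    """Raw reads for one sample. Empty libraries are allowed (degenerate)."""

    sample_id: str
    condition: Condition
    reads: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        self.condition = Condition(self.condition)

    def __len__(self) -> int:
        return len(self.reads)


def trim_adapter(read: str, adapter: str, min_overlap: int = 6) -> str:
    """Trim the 3' sequencing adapter from a read.

    Returns the prefix of ``read`` preceding the leftmost position where a
    prefix of ``adapter`` of length >= ``min_overlap`` matches exactly; the
    adapter may run off the read's 3' end.  Unchanged if no such occurrence.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if min_overlap > len(adapter):
        raise ValueError("min_overlap exceeds adapter length")
    n = len(read)
    for i in range(n):
        span = min(len(adapter), n - i)
        if span >= min_overlap and read[i : i + span] == adapter[:span]:
            return read[:i]
    return read


def filter_short(reads, min_len: int = 16):
    """Drop sequences shorter than ``min_len`` (default 16 nt).

    Accepts a sequence of reads (returns a list, order preserved) or a
    collapsed ``{sequence: multiplicity}`` mapping (returns a dict).
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if isinstance(reads, Mapping):
        return {s: m for s, m in reads.items() if len(s) >= min_len}
    return [r for r in reads if len(r) >= min_len]


def collapse_reads(reads: Iterable[str]) -> dict[str, int]:
    """Collapse reads into a non-redundant ``{sequence: multiplicity}`` map.

    First-seen order of sequences is preserved; multiplicities sum to the
    number of input reads.
    """
    collapsed: dict[str, int] = {}
    for r in reads:
        collapsed[r] = collapsed.get(r, 0) + 1
    return collapsed


def _window_distance(read: str, window: str, limit: int) -> int:
    """Hamming distance between equal-length strings, N never matches;
    returns limit+1 as soon as the limit is exceeded."""
    d = 0
    for a, b in zip(read, window):
        if a != b or a == "N":
            d += 1
            if d > limit:
                return d
    return d


def map_read(
    read: str, reference: Mapping[str, str], max_mismatch: int = 2
) -> tuple[int, tuple[str, ...]] | None:
    """Best placement of one read against a mature-miRNA reference.

    Scans every same-length window of every reference sequence and returns
    ``(distance, ids)`` for the minimal Hamming distance <= ``max_mismatch``
    (ids sorted; several ids when references tie), or None if unmapped.
    A read longer than a reference sequence cannot hit it.
    """
    best = max_mismatch
    hits: list[str] = []
    n = len(read)
    for rid, seq in reference.items():
        if n > len(seq):
            continue
        ref_best = max_mismatch + 1
        for i in range(len(seq) - n + 1):
            d = _window_distance(read, seq[i : i + n], best)
            if d < ref_best:
                ref_best = d
                if d == 0:
                    break
        if ref_best < best:
            best = ref_best
            hits = [rid]
        elif ref_best == best:
            hits.append(rid)
    if not hits:
        return None
    return best, tuple(sorted(hits))


def map_to_reference(
    collapsed: Mapping[str, int | float],
    reference: Mapping[str, str],
    max_mismatch: int = 2,
) -> tuple[dict[str, float], dict[str, float]]:
    """Map collapsed reads to a mature-miRNA reference.

    Returns ``(counts, unmapped)``: per-miRNA counts accumulating read
    multiplicities (split 1/k over k tied references), and the unmapped
    ``{sequence: multiplicity}`` remainder.
    """
    if not reference:
        raise ValueError("reference is empty")
    counts: dict[str, float] = {}
    unmapped: dict[str, float] = {}
    for seq, mult in collapsed.items():
        hit = map_read(seq, reference, max_mismatch)
        if hit is None:
            unmapped[seq] = unmapped.get(seq, 0) + mult
            continue
        _, ids = hit
        share = mult / len(ids)
        for rid in ids:
            counts[rid] = counts.get(rid, 0.0) + share
    return counts, unmapped


@dataclass
class CountTable:
    """Per-sample miRNA counts with RPM normalization.

    ``raw`` is a miRNA x sample matrix of mapped counts (fractional allowed
    for split multi-hits).  ``total_mapped`` is the per-sample normalization
    denominator; by default the column sums of ``raw``, but it may be larger
    when the table holds only a subset of everything that mapped (e.g. the
    marker miRNAs out of all genome-mapped reads).  Samples with zero total
    are flagged degenerate and get all-zero abundances.
    """

    raw: pd.DataFrame
    total_mapped: pd.Series
    scale: float = 1e6

    def __post_init__(self) -> None:
        if (self.raw.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.raw = self.raw.sort_index()
        self.total_mapped = self.total_mapped.reindex(self.raw.columns)
        if (self.total_mapped < 0).any():
            raise ValueError("negative total_mapped")

    @classmethod
    def from_raw(
        cls,
        raw: pd.DataFrame,
        total_mapped: pd.Series | Mapping[str, float] | None = None,
        scale: float = 1e6,
    ) -> "CountTable":
        if total_mapped is None:
            total_mapped = raw.sum(axis=0)
        return cls(raw=raw.astype(float), total_mapped=pd.Series(total_mapped, dtype=float), scale=scale)

    @property
    def samples(self) -> list[str]:
        return list(self.raw.columns)

    @property
    def degenerate_samples(self) -> list[str]:
        return [s for s in self.samples if self.total_mapped[s] == 0]

    @property
    def rpm(self) -> pd.DataFrame:
        denom = self.total_mapped.replace(0, np.nan)
        return (self.raw / denom * self.scale).fillna(0.0)

    def to_tsv(self, raw_path: str | Path, rpm_path: str | Path | None = None) -> None:
        frame = self.raw.copy()
        frame.loc["__total_mapped__"] = self.total_mapped
        frame.to_csv(raw_path, sep="\t", float_format="%.6g", index_label="mirna")
        if rpm_path is not None:
            self.rpm.to_csv(rpm_path, sep="\t", float_format="%.6g", index_label="mirna")

    @classmethod
    def from_tsv(cls, raw_path: str | Path, scale: float = 1e6) -> "CountTable":
        frame = pd.read_csv(raw_path, sep="\t", index_col="mirna")
        if "__total_mapped__" in frame.index:
            total = frame.loc["__total_mapped__"]
            frame = frame.drop(index="__total_mapped__")
        else:
            total = frame.sum(axis=0)
        return cls.from_raw(frame, total_mapped=total, scale=scale)


def normalize_counts(
    raw: pd.DataFrame | Mapping[str, Mapping[str, float]],
    scale: float = 1e6,
    total_mapped: Mapping[str, float] | None = None,
) -> CountTable:
    """Build a CountTable; abundance_i = scale * raw_i / total_mapped."""
    if not isinstance(raw, pd.DataFrame):
        raw = pd.DataFrame(raw).fillna(0.0)
    return CountTable.from_raw(raw, total_mapped=total_mapped, scale=scale)


def pool_libraries(
    libraries: Sequence[ReadLibrary], sample_id: str = "normal_pool"
) -> ReadLibrary:
    """Pool NORMAL libraries into one POOLED_NORMAL library (concatenated
    reads), mirroring physical pooling of normal RNA before sequencing."""
    if not libraries:
        raise ValueError("need at least one library to pool")
    if any(lib.condition != Condition.NORMAL for lib in libraries):
        raise ValueError("can only pool NORMAL libraries")
    reads: list[str] = []
    for lib in libraries:
        reads.extend(lib.reads)
    return ReadLibrary(sample_id=sample_id, condition=Condition.POOLED_NORMAL, reads=reads)


# --------------------------------------------------------------------------
# File I/O
# --------------------------------------------------------------------------

def read_reference_fasta(path: str | Path) -> dict[str, str]:
    """Load a mature-miRNA FASTA; headers are canonicalized (first token)."""
    reference: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = normalize_mirna_name(rec.id)
        if rid in reference:
            raise ValueError(f"duplicate reference entry {rid!r}")
        reference[rid] = str(rec.seq).upper().replace("U", "T")
    if not reference:
        raise ValueError(f"{path}: no sequences")
    return reference


def load_read_library(
    path: str | Path, sample_id: str, condition: Condition | str, fmt: str | None = None
) -> ReadLibrary:
    """Read a FASTQ/FASTA library (format guessed from the extension);
    Phred qualities are ignored."""
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    reads = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), fmt)]
    return ReadLibrary(sample_id=sample_id, condition=Condition(condition), reads=reads)


def write_fastq(library: ReadLibrary, path: str | Path) -> None:
    """Write a library as FASTQ with flat qualities (placeholders)."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, read in enumerate(library.reads):
            fh.write(f"@{library.sample_id}:{i}\n{read}\n+\n{'I' * len(read)}\n")


# --------------------------------------------------------------------------
# Quantification pipeline
# --------------------------------------------------------------------------

@dataclass
class QuantResult:
    sample_id: str
    counts: dict[str, float]
    unmapped: dict[str, float]
    spike_counts: dict[str, float]
    stats: dict[str, float]


def quantify_library(
    library: ReadLibrary,
    reference: Mapping[str, str],
    adapter: str | None = None,
    min_len: int = 16,
    max_mismatch: int = 2,
    min_overlap: int = 6,
    spike_reference: Mapping[str, str] | None = None,
) -> QuantResult:
    """Run trim -> length filter -> collapse -> map for one library.

    Reads failing the main reference are optionally rescued against a spike-in
    reference; spike hits are tallied separately and excluded from the mapped
    total used for normalization.
    """
    reads = library.reads
    if adapter:
        reads = [trim_adapter(r, adapter, min_overlap) for r in reads]
    kept = filter_short(reads, min_len)
    n_short = len(reads) - len(kept)
    collapsed = collapse_reads(kept)
    counts, unmapped = map_to_reference(collapsed, reference, max_mismatch)
    spike_counts: dict[str, float] = {}
    if spike_reference and unmapped:
        spike_counts, unmapped = map_to_reference(
            unmapped, spike_reference, max_mismatch
        )
    stats = {
        "input_reads": float(len(library.reads)),
        "short_discarded": float(n_short),
        "unique_sequences": float(len(collapsed)),
        "mapped": float(sum(counts.values())),
        "spike_mapped": float(sum(spike_counts.values())),
        "unmapped": float(sum(unmapped.values())),
    }
    return QuantResult(library.sample_id, counts, unmapped, spike_counts, stats)


def quantify_libraries(
    libraries: Sequence[ReadLibrary],
    reference: Mapping[str, str],
    adapter: str | None = None,
    min_len: int = 16,
    max_mismatch: int = 2,
    min_overlap: int = 6,
    spike_reference: Mapping[str, str] | None = None,
    scale: float = 1e6,
) -> tuple[CountTable, dict[str, QuantResult]]:
    """Quantify several libraries into one CountTable (RPM denominator =
    per-sample mapped total, spike-in hits excluded)."""
    results: dict[str, QuantResult] = {}
    for lib in libraries:
        if lib.sample_id in results:
            raise ValueError(f"duplicate sample_id {lib.sample_id!r}")
        results[lib.sample_id] = quantify_library(
            lib, reference, adapter, min_len, max_mismatch, min_overlap, spike_reference
        )
    all_mirnas = sorted(reference)
    raw = pd.DataFrame(
        {sid: {m: res.counts.get(m, 0.0) for m in all_mirnas} for sid, res in results.items()}
    )
    table = CountTable.from_raw(raw, scale=scale)
    return table, results
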