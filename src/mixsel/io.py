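"""Tables, region masks, and sequence context extraction.

All genomic intervals are half-open 0-based internally. Variant positions
are 1-based in TSV files (VCF convention) and converted at the boundary.
7-mer contexts are taken from the reference strand with no strand
collapsing; a pyrimidine-folding variant can be layered on top if needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_BASES = frozenset("ACGT")

#: canonical column order for variant tables
VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene_id",
    "exon_id",
    "context7",
    "depth",
    "observed",
    "consequence",
]

FEATURE_PREFIX = "feat_"


class VariantTableError(ValueError):
    """Schema- or row-level problem in a variant table."""


class ContextError(ValueError):
    """Out-of-range position or ambiguous base in a context window."""


@dataclass(frozen=True)
class VariantRecord:
    """One candidate single-nucleotide mutation.

    ``pos`` is 1-based. ``observed`` is the presence/absence indicator of
    the mutation as a rare variant in the population sample. ``features``
    is the ordered per-variant feature vector, or ``None`` for records used
    only by the neutral mutation model.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str
    exon_id: str
    context7: str
    depth: float
    observed: int
    consequence: str = "missense"
    features: np.ndarray | None = None

    def __post_init__(self):
        if len(self.context7) != 7 or self.context7[3] != self.ref:
            raise VariantTableError(
                f"context7 {self.context7!r} must have length 7 and be centered "
                f"on ref {self.ref!r}"
            )
        if self.alt == self.ref:
            raise VariantTableError(f"alt equals ref ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise VariantTableError(f"non-ACGT allele at {self.chrom}:{self.pos}")
        if self.depth < 0:
            raise VariantTableError(f"negative depth at {self.chrom}:{self.pos}")
        if self.observed not in (0, 1):
            raise VariantTableError(f"observed must be 0/1 at {self.chrom}:{self.pos}")


def read_variant_table(path: str | Path, feature_prefix: str = FEATURE_PREFIX) -> list[VariantRecord]:
    """Read a TSV variant table into validated records, preserving row order.

    Required columns are :data:`VARIANT_COLUMNS`; feature columns are those
    starting with ``feature_prefix``, taken in file order.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str, "exon_id": str})
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise VariantTableError(f"{path}: missing required column(s) {missing}")
    feat_cols = [c for c in df.columns if c.startswith(feature_prefix)]
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        feats = (
            np.array([float(row[c]) for c in feat_cols], dtype=float) if feat_cols else None
        )
        try:
            records.append(
                VariantRecord(
                    chrom=str(row["chrom"]),
                    pos=int(row["pos"]),
                    ref=str(row["ref"]),
                    alt=str(row["alt"]),
                    gene_id=str(row["gene_id"]),
                    exon_id=str(row["exon_id"]),
                    context7=str(row["context7"]),
                    depth=float(row["depth"]),
                    observed=int(row["observed"]),
                    consequence=str(row["consequence"]),
                    features=feats,
                )
            )
        except VariantTableError as e:
            # +2: header line plus 1-based numbering
            raise VariantTableError(f"{path}: line {i + 2}: {e}") from e
    return records


def write_variant_table(
    records: Sequence[VariantRecord],
    path: str | Path,
    feature_names: Sequence[str] | None = None,
    feature_prefix: str = FEATURE_PREFIX,
) -> None:
    """Write records to TSV, inverse of :func:`read_variant_table`."""
    rows = []
    n_feat = 0
    for r in records:
        d = {c: getattr(r, c) for c in VARIANT_COLUMNS}
        if r.features is not None:
            n_feat = len(r.features)
            names = feature_names or [f"{feature_prefix}{k}" for k in range(n_feat)]
            d.update(dict(zip(names, r.features)))
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def variants_to_frame(records: Sequence[VariantRecord]) -> pd.DataFrame:
    """Flatten records into a DataFrame with feat_<k> feature columns."""
    base = pd.DataFrame({c: [getattr(r, c) for r in records] for c in VARIANT_COLUMNS})
    if records and records[0].features is not None:
        feats = np.vstack([r.features for r in records])
        for k in range(feats.shape[1]):
            base[f"{FEATURE_PREFIX}{k}"] = feats[:, k]
    return base


# ---------------------------------------------------------------------------
# Region masks


@dataclass
class RegionMask:
    """A labelled set of genomic intervals, half-open 0-based, merged."""

    label: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.intervals = merge_intervals(self.intervals)

    @classmethod
    def from_bed(cls, path: str | Path, label: str) -> "RegionMask":
        ivs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                ivs.append((parts[0], int(parts[1]), int(parts[2])))
        return cls(label=label, intervals=ivs)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self.intervals:
                fh.write(f"{chrom}\t{start}\t{end}\t{self.label}\n")

    def to_bool(self, chrom: str, length: int) -> np.ndarray:
        """Per-base boolean membership array for one contig."""
        arr = np.zeros(length, dtype=bool)
        for c, s, e in self.intervals:
            if c == chrom:
                arr[max(0, s) : min(length, e)] = True
        return arr

    @classmethod
    def from_bool(cls, label: str, chrom: str, arr: np.ndarray) -> "RegionMask":
        ivs = [(chrom, int(s), int(e)) for s, e in bool_to_intervals(arr)]
        return cls(label=label, intervals=ivs)

    def contains(self, chrom: str, pos0: int) -> bool:
        return any(c == chrom and s <= pos0 < e for c, s, e in self.intervals)

    def total_length(self) -> int:
        return sum(e - s for _, s, e in self.intervals)


def merge_intervals(intervals: Iterable[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Sort and merge overlapping/adjacent half-open intervals per chrom."""
    out: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(intervals):
        if start >= end:
            raise ValueError(f"empty or inverted interval {chrom}:{start}-{end}")
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            out[-1] = (chrom, out[-1][1], max(out[-1][2], end))
        else:
            out.append((chrom, start, end))
    return out


def bool_to_intervals(arr: np.ndarray) -> list[tuple[int, int]]:
    """Runs of True in a boolean array, as half-open (start, end) pairs."""
    arr = np.asarray(arr, dtype=bool)
    if arr.size == 0:
        return []
    padded = np.concatenate([[False], arr, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


# ---------------------------------------------------------------------------
# Sequence context


def extract_context7(fasta: Mapping[str, str], chrom: str, pos: int) -> str:
    """7-mer reference context centered on 1-based position ``pos``.

    ``fasta`` is any mapping from contig name to sequence-like object
    (a ``pyfaidx.Fasta`` instance or a plain dict of strings).
    """
    seq = fasta[chrom]
    n = len(seq)
    if pos < 4 or pos > n - 3:
        raise ContextError(f"position {chrom}:{pos} too close to a contig edge (length {n})")
    window = str(seq[pos - 4 : pos + 3]).upper()
    if any(b not in VALID_BASES for b in window):
        raise ContextError(f"ambiguous base in context window at {chrom}:{pos}: {window!r}")
    return window


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Plain in-memory FASTA reader; use pyfaidx for large genomes."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs
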