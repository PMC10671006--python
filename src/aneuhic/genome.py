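"""Chromosome tables and BED-like genomic interval sets.

All coordinates are 0-based half-open (BED convention). A :class:`ChromSizes`
fixes the chromosome order used by every matrix and track derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ChromSizes",
    "GenomicIntervalSet",
    "merge_intervals",
]


@dataclass(frozen=True)
class ChromSizes:
    """Ordered chromosome name -> length (bp) table."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate chromosome names")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")

    @classmethod
    def from_dict(cls, d: Mapping[str, int]) -> "ChromSizes":
        return cls(tuple(d.keys()), tuple(int(v) for v in d.values()))

    @classmethod
    def from_file(cls, path: str | Path) -> "ChromSizes":
        """Read a two-column chrom.sizes TSV."""
        names, lengths = [], []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, length = line.split("\t")[:2]
            names.append(name)
            lengths.append(int(length))
        return cls(tuple(names), tuple(lengths))

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{n}\t{l}\n" for n, l in zip(self.names, self.lengths))
        )

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __getitem__(self, name: str) -> int:
        try:
            return self.lengths[self.names.index(name)]
        except ValueError:
            raise KeyError(name) from None

    def __iter__(self) -> Iterator[str]:
        return iter(self.names)

    def items(self) -> Iterator[tuple[str, int]]:
        return zip(self.names, self.lengths)

    @property
    def total_length(self) -> int:
        return sum(self.lengths)

    def as_series(self) -> pd.Series:
        return pd.Series(self.lengths, index=list(self.names), name="length")


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of half-open intervals; returns sorted, disjoint (starts, ends)."""
    if len(starts) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    order = np.argsort(starts, kind="stable")
    s = np.asarray(starts, dtype=np.int64)[order]
    e = np.asarray(ends, dtype=np.int64)[order]
    out_s, out_e = [s[0]], [e[0]]
    for a, b in zip(s[1:], e[1:]):
        if a <= out_e[-1]:  # abutting intervals merge too
            out_e[-1] = max(out_e[-1], b)
        else:
            out_s.append(a)
            out_e.append(b)
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


@dataclass
class GenomicIntervalSet:
    """BED-like intervals (chrom, start, end, label) tied to a ChromSizes.

    Interval semantics are half-open; labels are free-form strings
    (compartment "A"/"B", "cLAD", gene names, region directions ...).
    """

    df: pd.DataFrame
    chromsizes: ChromSizes | None = None
    _merged_cache: dict = field(default_factory=dict, repr=False, compare=False)

    COLUMNS = ("chrom", "start", "end", "label")

    def __post_init__(self) -> None:
        df = self.df
        if "label" not in df.columns:
            df = df.assign(label=".")
        df = df[list(self.COLUMNS)].reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            raise ValueError("intervals must satisfy start < end")
        if self.chromsizes is not None:
            unknown = set(df["chrom"]) - set(self.chromsizes.names)
            if unknown:
                raise ValueError(f"chromosomes not in ChromSizes: {sorted(unknown)}")
        self.df = df

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
        chromsizes: ChromSizes | None = None,
    ) -> "GenomicIntervalSet":
        rows = list(records)
        if rows and len(rows[0]) == 3:
            rows = [(*r, ".") for r in rows]
        df = pd.DataFrame(rows, columns=list(cls.COLUMNS))
        return cls(df, chromsizes)

    @classmethod
    def from_bed(cls, path: str | Path, chromsizes: ChromSizes | None = None) -> "GenomicIntervalSet":
        """Read BED3/BED4+ (extra columns ignored; column 4 becomes the label)."""
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            label = parts[3] if len(parts) > 3 else "."
            rows.append((parts[0], int(parts[1]), int(parts[2]), label))
        df = pd.DataFrame(rows, columns=list(cls.COLUMNS))
        return cls(df, chromsizes)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for row in self.df.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.label}\n")

    def __len__(self) -> int:
        return len(self.df)

    def filter_label(self, label: str) -> "GenomicIntervalSet":
        return GenomicIntervalSet(self.df[self.df["label"] == label], self.chromsizes)

    def chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.df[self.df["chrom"] == chrom]
        return sub["start"].to_numpy(), sub["end"].to_numpy()

    def merged(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Merged (union) intervals on one chromosome, cached."""
        if chrom not in self._merged_cache:
            self._merged_cache[chrom] = merge_intervals(*self.chrom_arrays(chrom))
        return self._merged_cache[chrom]

    def union_length(self, chrom: str) -> int:
        s, e = self.merged(chrom)
        return int((e - s).sum())

    def coverage_percent(self, chromsizes: ChromSizes | None = None) -> pd.Series:
        """Per-chromosome percent of length covered by the interval union."""
        cs = chromsizes or self.chromsizes
        if cs is None:
            raise ValueError("chromsizes required")
        return pd.Series(
            {name: 100.0 * self.union_length(name) / length for name, length in cs.items()},
            name="coverage_percent",
        )

    def overlap_bp(self, chrom: str, start: int, end: int) -> int:
        """Base pairs of [start, end) covered by the merged interval union."""
        ms, me = self.merged(chrom)
        if len(ms) == 0:
            return 0
        lo = np.searchsorted(me, start, side="right")
        hi = np.searchsorted(ms, end, side="left")
        if hi <= lo:
            return 0
        clip_s = np.clip(ms[lo:hi], start, end)
        clip_e = np.clip(me[lo:hi], start, end)
        return int((clip_e - clip_s).sum())
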