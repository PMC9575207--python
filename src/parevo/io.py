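"""Readers and writers for the standard file formats the pipeline consumes.

All genomic coordinates are 0-based, half-open (BED convention). Alignments
come in as MAF (with ancestor rows named after tree nodes) or as a directory
of equal-length per-node FASTA files; masks as BED; trees as newick with
labelled internal nodes; genotypes as VCF; depth as BedGraph or two-column
TSV; recombination maps and tallies as TSV.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class CoordinateSystemError(ValueError):
    """Raised when two objects live on different reference sequences."""


@dataclass(frozen=True)
class GenomicIntervals:
    """A sorted, disjoint set of 0-based half-open intervals on one sequence."""

    chrom: str
    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self):
        starts = np.asarray(self.starts, dtype=np.int64)
        ends = np.asarray(self.ends, dtype=np.int64)
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        if np.any(ends < starts):
            raise ValueError("interval end before start")
        if starts.size and np.any(starts[1:] < ends[:-1]):
            # merge overlapping/adjacent intervals so membership tests are simple
            merged_s, merged_e = [], []
            cs, ce = starts[0], ends[0]
            for s, e in zip(starts[1:], ends[1:]):
                if s <= ce:
                    ce = max(ce, e)
                else:
                    merged_s.append(cs)
                    merged_e.append(ce)
                    cs, ce = s, e
            merged_s.append(cs)
            merged_e.append(ce)
            starts = np.array(merged_s, dtype=np.int64)
            ends = np.array(merged_e, dtype=np.int64)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)

    @classmethod
    def empty(cls, chrom: str) -> "GenomicIntervals":
        return cls(chrom, np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))

    @classmethod
    def from_boolean(cls, chrom: str, flags: np.ndarray, offset: int = 0) -> "GenomicIntervals":
        """Build intervals from a per-position boolean track starting at `offset`."""
        flags = np.asarray(flags, dtype=bool)
        if flags.size == 0:
            return cls.empty(chrom)
        diff = np.diff(flags.astype(np.int8))
        starts = np.flatnonzero(diff == 1) + 1
        ends = np.flatnonzero(diff == -1) + 1
        if flags[0]:
            starts = np.concatenate([[0], starts])
        if flags[-1]:
            ends = np.concatenate([ends, [flags.size]])
        return cls(chrom, starts + offset, ends + offset)

    def __len__(self) -> int:
        return int(self.starts.size)

    @property
    def total_length(self) -> int:
        return int(np.sum(self.ends - self.starts))

    def contains(self, positions: np.ndarray) -> np.ndarray:
        """Vectorised membership test for 0-based positions."""
        positions = np.asarray(positions, dtype=np.int64)
        if self.starts.size == 0:
            return np.zeros(positions.shape, dtype=bool)
        idx = np.searchsorted(self.starts, positions, side="right") - 1
        inside = idx >= 0
        inside[inside] &= positions[inside] < self.ends[idx[inside]]
        return inside

    def window_counts(self, window: int, n_windows: int, offset: int = 0) -> np.ndarray:
        """Covered-position count per window of a fixed grid starting at `offset`."""
        counts = np.zeros(n_windows, dtype=np.int64)
        grid_end = offset + window * n_windows
        for s, e in zip(self.starts, self.ends):
            s, e = max(s, offset), min(e, grid_end)
            if s >= e:
                continue
            w0, w1 = (s - offset) // window, (e - 1 - offset) // window
            if w0 == w1:
                counts[w0] += e - s
                continue
            counts[w0] += (offset + (w0 + 1) * window) - s
            counts[w0 + 1 : w1] += window
            counts[w1] += e - (offset + w1 * window)
        return counts


def read_bed(path: str | Path, chrom: str | None = None) -> GenomicIntervals:
    """Read a BED file into intervals; all records must share one sequence name."""
    starts, ends, chroms = [], [], set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chroms.add(parts[0])
            starts.append(int(parts[1]))
            ends.append(int(parts[2]))
    if len(chroms) > 1:
        raise CoordinateSystemError(f"BED {path} spans multiple sequences: {sorted(chroms)}")
    name = chroms.pop() if chroms else (chrom or "ref")
    if chrom is not None and name != chrom:
        raise CoordinateSystemError(f"BED {path} is on {name!r}, expected {chrom!r}")
    return GenomicIntervals(name, np.array(starts, dtype=np.int64), np.array(ends, dtype=np.int64))


def write_bed(path: str | Path, intervals: GenomicIntervals,
              names: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, (s, e) in enumerate(zip(intervals.starts, intervals.ends)):
            if names is not None:
                fh.write(f"{intervals.chrom}\t{s}\t{e}\t{names[i]}\n")
            else:
                fh.write(f"{intervals.chrom}\t{s}\t{e}\n")


def read_depth(path: str | Path, length: int | None = None) -> np.ndarray:
    """Read a per-site depth track from BedGraph (chrom,start,end,depth) or
    two-column TSV (pos,depth); returns a dense array over [0, length)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] >= 4:  # BedGraph
        n = length if length is not None else int(df.iloc[:, 2].max())
        depth = np.zeros(n, dtype=np.float64)
        for _, row in df.iterrows():
            depth[int(row[1]) : int(row[2])] = float(row[3])
        return depth
    pos = df.iloc[:, 0].to_numpy(dtype=np.int64)
    n = length if length is not None else int(pos.max()) + 1
    depth = np.zeros(n, dtype=np.float64)
    depth[pos] = df.iloc[:, 1].to_numpy(dtype=np.float64)
    return depth


def write_bedgraph(path: str | Path, chrom: str, depth: np.ndarray) -> None:
    """Write a dense per-site track as run-length-encoded BedGraph."""
    depth = np.asarray(depth)
    with open(path, "w") as fh:
        if depth.size == 0:
            return
        change = np.flatnonzero(np.diff(depth)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [depth.size]])
        for s, e in zip(starts, ends):
            v = depth[s]
            fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_recomb_map(path: str | Path) -> pd.DataFrame:
    """Read a windowed recombination map TSV (chrom, start, end, rate[, usable])."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "rate"}
    if not required.issubset(df.columns):
        raise ValueError(f"recombination map {path} lacks columns {required - set(df.columns)}")
    if "usable" not in df.columns:
        df["usable"] = True
    return df


def write_tsv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_sample_sex(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV of sample id and sex label (F/M)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return {str(r[0]): str(r[1]).upper()[0] for r in df.itertuples(index=False)}
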