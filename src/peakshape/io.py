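"""Genomic file handling: peak intervals, read sources, midpoint extraction.

All coordinates are 0-based half-open internally (BED convention on
disk).  Reads are reduced to estimated fragment midpoints: on the +
strand ``start + fragment_length/2``, on the - strand
``end - fragment_length/2``, and the plain interval midpoint when the
strand is unknown.  A midpoint exactly at ``region.end`` is outside the
region; at ``region.start`` it is inside.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from peakshape.errors import InvalidInputError

__all__ = [
    "PeakRegion",
    "ReadRecord",
    "read_regions",
    "write_regions",
    "merge_overlapping",
    "BamReadSource",
    "BedReadSource",
    "InMemoryReadSource",
    "extract_midpoints",
    "count_reads",
    "write_reads_bed",
]

DEFAULT_FRAGMENT_LENGTH = 200.0


@dataclass(frozen=True)
class PeakRegion:
    """A genomic interval in which read distributions are compared."""

    chrom: str
    start: int
    end: int
    peak_id: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise InvalidInputError(
                f"region {self.peak_id}: start {self.start} must be < end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ReadRecord:
    """A mapped read (or fragment) interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise InvalidInputError(f"read start {self.start} must be < end {self.end}")
        if self.strand not in ("+", "-", "."):
            raise InvalidInputError(f"strand must be +, - or ., got {self.strand!r}")


_SKIP_PREFIXES = ("#", "track", "browser")


def read_regions(path, format: str = "auto") -> list[PeakRegion]:
    """Parse peak intervals from BED / ENCODE narrowPeak / broadPeak.

    Only the first four columns are used (chrom, start, end, name); extra
    columns of the ENCODE dialects are ignored.  Rows keep file order.
    Missing or "." names are replaced by ``peak_<line>``; duplicate names
    are rejected.
    """
    if format not in ("auto", "bed", "narrowPeak", "broadPeak"):
        raise InvalidInputError(f"unknown region format {format!r}")
    regions: list[PeakRegion] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InvalidInputError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise InvalidInputError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else ""
            if not name:
                name = f"peak_{lineno}"
            if name in seen:
                raise InvalidInputError(f"{path}:{lineno}: duplicate peak id {name!r}")
            seen.add(name)
            try:
                regions.append(PeakRegion(fields[0], start, end, name))
            except InvalidInputError as exc:
                raise InvalidInputError(f"{path}:{lineno}: {exc}") from exc
    return regions


def write_regions(path, regions: Iterable[PeakRegion]) -> None:
    """Write regions as BED4."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.peak_id}\n")


def merge_overlapping(regions: Iterable[PeakRegion]) -> list[PeakRegion]:
    """Union of overlapping or bookended intervals per chromosome.

    Merged ids are joined with "|".  Output is sorted by (chrom, start).
    """
    by_chrom: dict[str, list[PeakRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    out: list[PeakRegion] = []
    for chrom in sorted(by_chrom):
        rs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        cur_start, cur_end, ids = rs[0].start, rs[0].end, [rs[0].peak_id]
        for r in rs[1:]:
            if r.start <= cur_end:  # overlap or bookended
                cur_end = max(cur_end, r.end)
                ids.append(r.peak_id)
            else:
                out.append(PeakRegion(chrom, cur_start, cur_end, "|".join(ids)))
                cur_start, cur_end, ids = r.start, r.end, [r.peak_id]
        out.append(PeakRegion(chrom, cur_start, cur_end, "|".join(ids)))
    return out


def _midpoints(starts, ends, strands, fragment_length: float) -> np.ndarray:
    """Estimated fragment midpoints for read intervals (genomic coords)."""
    starts = np.asarray(starts, dtype=np.float64)
    ends = np.asarray(ends, dtype=np.float64)
    strands = np.asarray(strands)
    mid = 0.5 * (starts + ends)
    mid = np.where(strands == "+", starts + fragment_length / 2.0, mid)
    mid = np.where(strands == "-", ends - fragment_length / 2.0, mid)
    return mid


class BamReadSource:
    """Random-access reads from an indexed BAM file.

    Unmapped reads are always skipped; duplicate-marked and
    secondary/supplementary alignments are skipped by default.
    """

    def __init__(
        self,
        path,
        fragment_length: float = DEFAULT_FRAGMENT_LENGTH,
        skip_duplicates: bool = True,
        skip_secondary: bool = True,
    ):
        import pysam

        self.path = str(path)
        self.fragment_length = float(fragment_length)
        self.skip_duplicates = skip_duplicates
        self.skip_secondary = skip_secondary
        if not (
            os.path.exists(self.path + ".bai")
            or os.path.exists(self.path.removesuffix(".bam") + ".bai")
            or os.path.exists(self.path + ".csi")
        ):
            raise InvalidInputError(
                f"{self.path}: no BAM index found; run `samtools index` first"
            )
        self._bam = pysam.AlignmentFile(self.path, "rb")

    def extract_midpoints(self, region: PeakRegion) -> np.ndarray:
        """Midpoint offsets (bp from region.start) of reads overlapping region."""
        half = self.fragment_length / 2.0
        out = []
        for read in self._bam.fetch(region.chrom, region.start, region.end):
            if read.is_unmapped:
                continue
            if self.skip_duplicates and read.is_duplicate:
                continue
            if self.skip_secondary and (read.is_secondary or read.is_supplementary):
                continue
            if read.is_reverse:
                mid = read.reference_end - half
            else:
                mid = read.reference_start + half
            if region.start <= mid < region.end:
                out.append(mid - region.start)
        return np.asarray(out, dtype=np.float64)

    def count(self, region: PeakRegion) -> int:
        return self.extract_midpoints(region).size


class BedReadSource:
    """Reads from a BED file (columns chrom, start, end[, name, score, strand]).

    The file is loaded once into per-chromosome arrays sorted by start;
    region queries then use binary search.  Suitable both for full read
    intervals and for pre-computed 1-bp midpoint intervals.
    """

    def __init__(self, path, fragment_length: float = DEFAULT_FRAGMENT_LENGTH):
        self.path = str(path)
        self.fragment_length = float(fragment_length)
        try:
            df = pd.read_csv(
                self.path,
                sep="\t",
                header=None,
                comment="#",
                usecols=[0, 1, 2, 3, 4, 5],
                names=["chrom", "start", "end", "name", "score", "strand"],
                dtype={"chrom": str, "start": np.int64, "end": np.int64},
            )
        except ValueError:
            df = pd.read_csv(
                self.path,
                sep="\t",
                header=None,
                comment="#",
                usecols=[0, 1, 2],
                names=["chrom", "start", "end"],
                dtype={"chrom": str, "start": np.int64, "end": np.int64},
            )
            df["strand"] = "."
        df["strand"] = df["strand"].where(df["strand"].isin(["+", "-"]), ".")
        self._chroms: dict[str, tuple] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("start", kind="stable")
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            strands = sub["strand"].to_numpy()
            self._chroms[str(chrom)] = (starts, ends, strands, np.maximum.accumulate(ends))

    def extract_midpoints(self, region: PeakRegion) -> np.ndarray:
        entry = self._chroms.get(region.chrom)
        if entry is None:
            return np.empty(0, dtype=np.float64)
        starts, ends, strands, cummax_end = entry
        hi = int(np.searchsorted(starts, region.end, side="left"))
        lo = int(np.searchsorted(cummax_end[:hi], region.start, side="right"))
        if lo >= hi:
            return np.empty(0, dtype=np.float64)
        sl = slice(lo, hi)
        keep = ends[sl] > region.start  # overlap with [start, end)
        mid = _midpoints(starts[sl][keep], ends[sl][keep], strands[sl][keep],
                         self.fragment_length)
        mid = mid[(mid >= region.start) & (mid < region.end)]
        return mid - region.start

    def count(self, region: PeakRegion) -> int:
        return self.extract_midpoints(region).size


class InMemoryReadSource:
    """Read midpoints held in memory, keyed by peak id (simulation output)."""

    def __init__(self, offsets_by_peak: Mapping[str, np.ndarray]):
        self._data = {
            k: np.asarray(v, dtype=np.float64).ravel()
            for k, v in offsets_by_peak.items()
        }

    def extract_midpoints(self, region: PeakRegion) -> np.ndarray:
        arr = self._data.get(region.peak_id)
        if arr is None:
            return np.empty(0, dtype=np.float64)
        return arr[(arr >= 0) & (arr < region.length)]

    def count(self, region: PeakRegion) -> int:
        return self.extract_midpoints(region).size


def extract_midpoints(read_source, region: PeakRegion) -> np.ndarray:
    """Midpoint offsets of reads from ``read_source`` within ``region``."""
    return read_source.extract_midpoints(region)


def count_reads(read_source, regions: Iterable[PeakRegion]) -> np.ndarray:
    """Retained-midpoint count per region (same filtering as extraction)."""
    return np.array([read_source.count(r) for r in regions], dtype=np.int64)


def write_reads_bed(path, records: Iterable[ReadRecord]) -> None:
    """Write read intervals as BED6 (name ".", score 0)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t.\t0\t{r.strand}\n")
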