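"""Genomic interval sets (BED-style, 0-based half-open) and bin masks."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeModel

__all__ = ["IntervalSet", "read_bed", "write_bed", "intervals_to_bins"]

log = logging.getLogger(__name__)

_COLS = ["chrom", "start", "end", "name", "score"]


@dataclass
class IntervalSet:
    """A set of genomic intervals in 0-based half-open coordinates.

    Backed by a pandas DataFrame with columns chrom/start/end/name/score.
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=_COLS))

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col, default in (("name", "."), ("score", 0.0)):
            if col not in df.columns:
                df[col] = default
        df = df[_COLS]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            bad = df.index[df["start"] >= df["end"]][0]
            raise ValueError(f"interval with start >= end at record {bad}")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records) -> "IntervalSet":
        """Build from an iterable of (chrom, start, end[, name[, score]])."""
        rows = []
        for rec in records:
            chrom, start, end, *rest = rec
            name = rest[0] if len(rest) > 0 else "."
            score = rest[1] if len(rest) > 1 else 0.0
            rows.append((chrom, start, end, name, score))
        return cls(pd.DataFrame(rows, columns=_COLS))

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return (tuple(r) for r in self.df.itertuples(index=False))

    def sort(self) -> "IntervalSet":
        return IntervalSet(self.df.sort_values(["chrom", "start", "end"], kind="mergesort"))

    def merge(self) -> "IntervalSet":
        """Union of overlapping or adjacent intervals (names dropped)."""
        rows = []
        for chrom, sub in self.sort().df.groupby("chrom", sort=True):
            cur_s = cur_e = None
            for s, e in zip(sub["start"], sub["end"]):
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    rows.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            if cur_s is not None:
                rows.append((chrom, cur_s, cur_e))
        return IntervalSet.from_records(rows)

    def total_bp(self) -> int:
        m = self.merge().df
        return int((m["end"] - m["start"]).sum())

    def restrict(self, chrom: str) -> "IntervalSet":
        return IntervalSet(self.df[self.df["chrom"] == chrom])

    def intersect_bp(self, other: "IntervalSet") -> int:
        """Total bp shared with ``other`` (both merged first)."""
        total = 0
        a = self.merge().df
        b = other.merge().df
        for chrom in set(a["chrom"]) & set(b["chrom"]):
            sa = a[a["chrom"] == chrom]
            sb = b[b["chrom"] == chrom]
            i = j = 0
            ra = list(zip(sa["start"], sa["end"]))
            rb = list(zip(sb["start"], sb["end"]))
            while i < len(ra) and j < len(rb):
                s = max(ra[i][0], rb[j][0])
                e = min(ra[i][1], rb[j][1])
                if s < e:
                    total += e - s
                if ra[i][1] <= rb[j][1]:
                    i += 1
                else:
                    j += 1
        return total

    def jaccard(self, other: "IntervalSet") -> float:
        inter = self.intersect_bp(other)
        union = self.total_bp() + other.total_bp() - inter
        return inter / union if union else float("nan")

    def midpoints(self) -> pd.DataFrame:
        mid = (self.df["start"] + self.df["end"]) // 2
        return pd.DataFrame({"chrom": self.df["chrom"], "pos": mid})


def read_bed(path) -> IntervalSet:
    """Read BED3+ (0-based half-open); comment/track/browser lines skipped."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected >=3 BED columns")
            chrom, start_s, end_s = parts[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-integer coordinate") from None
            if start >= end:
                raise ValueError(f"{path}:{ln}: start >= end")
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            rows.append((chrom, start, end, name, score))
    return IntervalSet.from_records(rows)


def write_bed(intervals: IntervalSet, path) -> None:
    """Write BED5 (tab-separated), records in stored order."""
    path = Path(path)
    with open(path, "w") as fh:
        for chrom, start, end, name, score in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{_fmt_score(score)}\n")


def _fmt_score(score: float) -> str:
    return str(int(score)) if float(score) == int(score) else repr(float(score))


def intervals_to_bins(intervals: IntervalSet, genome: GenomeModel) -> dict[str, np.ndarray]:
    """Boolean mask per chromosome: True where a bin overlaps any interval by >=1 bp.

    Intervals extending past the chromosome end are clipped with a warning;
    unknown chromosomes raise.
    """
    masks = {c: np.zeros(genome.n_bins(c), dtype=bool) for c in genome.chrom_names}
    bs = genome.bin_size_bp
    for chrom, start, end, *_ in intervals:
        if chrom not in genome:
            raise KeyError(f"interval chromosome {chrom!r} not in genome")
        clen = genome.chrom_lengths_bp[genome.chrom_names.index(chrom)]
        if end > clen:
            log.warning("clipping interval %s:%d-%d to chromosome end %d", chrom, start, end, clen)
            end = clen
        if start >= end:
            continue
        first = start // bs
        last = (end - 1) // bs  # inclusive; half-open end excluded
        masks[chrom][first : last + 1] = True
    return masks
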