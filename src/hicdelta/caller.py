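"""Diagonal sliding-window calling of differential regions.

A square window of ``w`` bins (default 10) slides along the main diagonal of
the differential map in steps of one bin.  The window score is the plain sum
of log2-ratio values over the strict upper triangle of the window (main
diagonal excluded, each symmetric pixel counted once); masked pixels
contribute zero and the valid fraction is recorded.  A genome-wide threshold
is then chosen from the empirical score distribution — the lower-tail
quantile by default — and passing windows are merged into regions.

Summation order within a window is fixed (row-major over the upper
triangle, sequential accumulation) so scores are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffmap import DiffMap
from .genome import GenomeModel
from .intervals import IntervalSet

__all__ = [
    "WindowScoreTrack",
    "DifferentialRegionSet",
    "RecoveryReport",
    "window_scores",
    "choose_threshold",
    "call_regions",
    "evaluate_recovery",
]

log = logging.getLogger(__name__)


@dataclass
class WindowScoreTrack:
    genome: GenomeModel
    window_bins: int
    tracks: dict[str, pd.DataFrame]  # columns: start_bin, score, valid_fraction

    def all_scores(self) -> np.ndarray:
        if not self.tracks:
            return np.empty(0)
        return np.concatenate([t["score"].to_numpy() for t in self.tracks.values()])

    def n_windows(self) -> int:
        return sum(len(t) for t in self.tracks.values())

    def to_bedgraph(self, path) -> None:
        """Score per window start bin, bedGraph-compatible TSV."""
        bs = self.genome.bin_size_bp
        with open(path, "w") as fh:
            for chrom in self.genome.chrom_names:
                if chrom not in self.tracks:
                    continue
                for start, score, vf in self.tracks[chrom].itertuples(index=False):
                    fh.write(f"{chrom}\t{int(start) * bs}\t{(int(start) + 1) * bs}\t{score!r}\t{vf!r}\n")


@dataclass
class DifferentialRegionSet:
    regions: IntervalSet
    threshold: float
    window_bins: int
    direction: str
    method: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.regions)

    def to_bed(self, path) -> None:
        """BED6: name = region id, score = min window score scaled to [0,1000]."""
        strand = "."
        scores = self.regions.df["score"].to_numpy(dtype=float)
        if len(scores):
            lo, hi = float(np.min(scores)), float(np.max(scores))
            span = hi - lo
            scaled = np.full(len(scores), 1000) if span == 0 else np.round(
                1000 * (hi - scores) / span
            ).astype(int)
        else:
            scaled = scores
        with open(path, "w") as fh:
            for k, (chrom, start, end, name, _score) in enumerate(self.regions):
                fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{int(scaled[k])}\t{strand}\n")


def window_scores(diff: DiffMap, w: int = 10) -> WindowScoreTrack:
    """Score every diagonal window of ``w`` bins, step one bin.

    Chromosomes shorter than ``w`` bins are skipped with a warning.
    """
    if w < 2:
        raise ValueError("window must span at least 2 bins")
    tracks = {}
    n_pix = w * (w - 1) // 2
    for chrom in diff.genome.chrom_names:
        n = diff.genome.n_bins(chrom)
        if n < w:
            log.warning("chromosome %s has %d bins < window %d; skipped", chrom, n, w)
            continue
        v = diff.values[chrom]
        m = diff.mask[chrom]
        starts = np.arange(n - w + 1)
        scores = np.empty(len(starts))
        valid_frac = np.empty(len(starts))
        for idx, i in enumerate(starts):
            acc = 0.0
            n_valid = 0
            for p in range(i, i + w):
                for q in range(p + 1, i + w):
                    if m[p, q]:
                        acc += v[p, q]
                        n_valid += 1
            scores[idx] = acc
            valid_frac[idx] = n_valid / n_pix
        tracks[chrom] = pd.DataFrame(
            {"start_bin": starts, "score": scores, "valid_fraction": valid_frac}
        )
    return WindowScoreTrack(diff.genome, w, tracks)


def choose_threshold(
    track: WindowScoreTrack, method: str = "mean_sd", param: float | None = None
) -> float:
    """Threshold from the genome-wide window-score distribution.

    ``mean_sd`` (default): mean minus ``param`` (default 3) standard
    deviations — an outlier rule whose scale adapts to the bulk of the
    distribution, so genuinely affected windows can exceed any fixed share
    of the genome.  ``quantile``: the empirical ``param``-quantile (default
    0.01, lower tail for decrease calling); requires >= 100 scores and by
    construction passes about that fraction of windows.
    """
    scores = track.all_scores()
    if method == "quantile":
        if param is None:
            param = 0.01
        if len(scores) < 100:
            raise ValueError(
                f"only {len(scores)} windows; quantile threshold needs >= 100 — use method='mean_sd'"
            )
        return float(np.quantile(scores, param))
    if method == "mean_sd":
        if param is None:
            param = 3.0
        if len(scores) == 0:
            raise ValueError("no window scores")
        return float(np.mean(scores) - param * np.std(scores))
    raise ValueError(f"unknown threshold method {method!r}")


def call_regions(
    track: WindowScoreTrack,
    threshold: float,
    direction: str = "decrease",
    min_valid_fraction: float = 0.5,
) -> DifferentialRegionSet:
    """Merge passing windows into differential regions.

    A window passes when its score is <= threshold (direction='decrease') or
    >= threshold ('decrease' flipped for 'increase') and its valid fraction is
    at least ``min_valid_fraction``.  Overlapping or adjacent passing windows
    merge; a region spans from the first window's start bin to the last
    window's start bin plus ``w`` bins.
    """
    if direction not in ("decrease", "increase"):
        raise ValueError("direction must be 'decrease' or 'increase'")
    w = track.window_bins
    bs = track.genome.bin_size_bp
    rows = []
    for chrom in track.genome.chrom_names:
        if chrom not in track.tracks:
            continue
        t = track.tracks[chrom]
        passing = t["valid_fraction"].to_numpy() >= min_valid_fraction
        if direction == "decrease":
            passing &= t["score"].to_numpy() <= threshold
        else:
            passing &= t["score"].to_numpy() >= threshold
        starts = t["start_bin"].to_numpy()[passing]
        scores = t["score"].to_numpy()[passing]
        if len(starts) == 0:
            continue
        clen = track.genome.chrom_lengths_bp[track.genome.chrom_names.index(chrom)]
        run_start = starts[0]
        run_end = starts[0] + w
        run_score = scores[0]
        for s, sc in zip(starts[1:], scores[1:]):
            if s <= run_end:  # overlap or adjacency in bin space
                run_end = s + w
                run_score = min(run_score, sc) if direction == "decrease" else max(run_score, sc)
            else:
                rows.append((chrom, int(run_start) * bs, min(int(run_end) * bs, clen), run_score))
                run_start, run_end, run_score = s, s + w, sc
        rows.append((chrom, int(run_start) * bs, min(int(run_end) * bs, clen), run_score))
    records = [
        (chrom, start, end, f"DR{k}", score) for k, (chrom, start, end, score) in enumerate(rows)
    ]
    return DifferentialRegionSet(
        regions=IntervalSet.from_records(records),
        threshold=float(threshold),
        window_bins=w,
        direction=direction,
        method={"min_valid_fraction": min_valid_fraction},
    )


@dataclass
class RecoveryReport:
    recall: float | None
    precision: float | None
    truth_jaccard: pd.DataFrame  # per truth region: name, best jaccard
    called_jaccard: pd.DataFrame

    def min_truth_jaccard(self) -> float:
        return float(self.truth_jaccard["jaccard"].min()) if len(self.truth_jaccard) else float("nan")


def _one(chrom: str, start: int, end: int) -> IntervalSet:
    return IntervalSet.from_records([(chrom, start, end)])


def _per_region_jaccard(queries: IntervalSet, reference: IntervalSet) -> pd.DataFrame:
    """For each query interval: Jaccard against the union of reference
    intervals that intersect it."""
    ref = reference.merge()
    rows = []
    for chrom, start, end, name, _ in queries:
        q = _one(chrom, start, end)
        hits = [
            (c, s, e)
            for c, s, e, *_ in ref
            if c == chrom and s < end and e > start
        ]
        if not hits:
            rows.append((chrom, start, end, name, 0.0))
            continue
        u = IntervalSet.from_records(hits)
        inter = q.intersect_bp(u)
        union = q.total_bp() + u.total_bp() - inter
        rows.append((chrom, start, end, name, inter / union))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "jaccard"])


def evaluate_recovery(
    called: IntervalSet, truth: IntervalSet, j0: float = 0.25
) -> RecoveryReport:
    """Recall/precision of called regions against planted truth.

    Recall is the fraction of truth regions whose Jaccard with the union of
    overlapping calls reaches ``j0``; precision is the mirror statistic for
    called regions against truth.  Empty truth yields recall None (NA).
    """
    truth_j = _per_region_jaccard(truth, called)
    called_j = _per_region_jaccard(called, truth)
    recall = float((truth_j["jaccard"] >= j0).mean()) if len(truth_j) else None
    precision = float((called_j["jaccard"] >= j0).mean()) if len(called_j) else None
    return RecoveryReport(recall, precision, truth_j, called_j)
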