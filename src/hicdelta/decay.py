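"""Expected-by-distance models and distance-decay P(s) curves.

``expected_by_distance`` gives, per chromosome, the arithmetic mean contact
count at each integer bin separation (zeros included) — the denominator of
observed/expected pileups.  ``decay_curve`` pools pixels across autosomes
into log-spaced genomic-distance bins; ``compare_decay`` contrasts two
conditions as a per-bin log2 ratio with probe values read off at chosen
distances (defaults 1 Mb and 10 Mb).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .contacts import ContactMap

__all__ = [
    "ExpectedModel",
    "DecayCurve",
    "DecayComparison",
    "expected_by_distance",
    "decay_curve",
    "compare_decay",
    "fit_decay_slope",
]


@dataclass
class ExpectedModel:
    """Per-chromosome mean count at each integer separation (linear grid)."""

    profiles: dict[str, np.ndarray]  # length n_bins, index = separation in bins

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.profiles[chrom]


@dataclass
class DecayCurve:
    edges_bp: np.ndarray  # length n+1, strictly increasing
    freq: np.ndarray  # mean contacts per pixel in each distance bin
    pixel_counts: np.ndarray
    normalized: bool = False
    empty_bins: np.ndarray | None = None  # flags distance bins with no pixels

    def midpoints_bp(self) -> np.ndarray:
        return np.sqrt(self.edges_bp[:-1] * self.edges_bp[1:])

    def normalize(self) -> "DecayCurve":
        mass = float((self.freq * self.pixel_counts).sum())
        if mass <= 0:
            raise ValueError("curve has zero mass")
        return DecayCurve(self.edges_bp, self.freq / mass, self.pixel_counts, True, self.empty_bins)


@dataclass
class DecayComparison:
    edges_bp: np.ndarray
    log2_ratio: np.ndarray  # NaN where either curve is zero
    probes: dict[float, float]  # distance_bp -> interpolated log2 ratio


def expected_by_distance(cmap: ContactMap) -> ExpectedModel:
    """Mean count over all pixels at each separation, per chromosome (s=0 included)."""
    profiles = {}
    for chrom in cmap.genome.chrom_names:
        block = cmap.cis[chrom]
        n = block.shape[0]
        prof = np.empty(n)
        for s in range(n):
            prof[s] = float(np.diagonal(block, offset=s).mean())
        profiles[chrom] = prof
    return ExpectedModel(profiles)


def _per_separation_sums(cmap: ContactMap, chrom: str) -> tuple[np.ndarray, np.ndarray]:
    """(sum of counts, number of pixels) at each separation s >= 1."""
    block = cmap.cis[chrom]
    n = block.shape[0]
    sums = np.array([float(np.diagonal(block, offset=s).sum()) for s in range(1, n)])
    counts = np.arange(n - 1, 0, -1, dtype=np.int64)
    return sums, counts


def decay_curve(
    cmap: ContactMap,
    n_logbins: int = 50,
    s_min_bp: float | None = None,
    s_max_bp: float | None = None,
    normalize: bool = False,
) -> DecayCurve:
    """Genome-wide P(s): contacts per possible pixel in log-spaced distance bins.

    Pixels are pooled across autosomes before binning; zeros count.  Distance
    of separation s is ``s * bin_size`` bp.  Empty distance bins get frequency
    0 and are flagged.
    """
    bs = cmap.genome.bin_size_bp
    if s_min_bp is None:
        s_min_bp = bs
    if s_min_bp < bs:
        raise ValueError("s_min_bp must be at least one bin")
    if s_max_bp is None:
        s_max_bp = max(cmap.genome.chrom_lengths_bp[cmap.genome.chrom_names.index(c)]
                       for c in cmap.genome.autosomes)
    edges = np.geomspace(s_min_bp, s_max_bp, n_logbins + 1)
    total = np.zeros(n_logbins)
    pixels = np.zeros(n_logbins, dtype=np.int64)
    for chrom in cmap.genome.autosomes:
        sums, counts = _per_separation_sums(cmap, chrom)
        s_bp = np.arange(1, len(sums) + 1) * bs
        idx = np.searchsorted(edges, s_bp, side="right") - 1
        ok = (idx >= 0) & (idx < n_logbins) & (s_bp >= edges[0]) & (s_bp <= edges[-1])
        idx[ok & (s_bp == edges[-1])] = n_logbins - 1  # closed right edge
        np.add.at(total, idx[ok], sums[ok])
        np.add.at(pixels, idx[ok], counts[ok])
    freq = np.zeros(n_logbins)
    nonempty = pixels > 0
    freq[nonempty] = total[nonempty] / pixels[nonempty]
    curve = DecayCurve(edges, freq, pixels, False, ~nonempty)
    return curve.normalize() if normalize else curve


def compare_decay(
    a: DecayCurve,
    b: DecayCurve,
    probe_distances_bp: tuple[float, ...] = (1e6, 1e7),
) -> DecayComparison:
    """Per-bin log2(a/b) with zero-frequency bins masked as NaN.

    Probe values are linearly interpolated in log10-distance over the
    geometric bin midpoints of the masked ratio curve.
    """
    if a.edges_bp.shape != b.edges_bp.shape or not np.allclose(a.edges_bp, b.edges_bp):
        raise ValueError("decay curves have different distance-bin edges")
    ratio = np.full(len(a.freq), np.nan)
    ok = (a.freq > 0) & (b.freq > 0)
    ratio[ok] = np.log2(a.freq[ok] / b.freq[ok])
    mids = a.midpoints_bp()
    probes = {}
    valid = ~np.isnan(ratio)
    for d in probe_distances_bp:
        if valid.sum() < 2 or not (mids[valid][0] <= d <= mids[valid][-1]):
            probes[float(d)] = float("nan")
        else:
            probes[float(d)] = float(
                np.interp(np.log10(d), np.log10(mids[valid]), ratio[valid])
            )
    return DecayComparison(a.edges_bp, ratio, probes)


def fit_decay_slope(
    curve: DecayCurve,
    s_min_bp: float | None = None,
    s_max_bp: float | None = None,
) -> float:
    """Log-log slope of P(s) by least squares over a central distance range.

    Defaults fit between 10 bins' worth of the smallest edge and the square
    root of the span — the central, well-populated part of the curve.
    """
    mids = curve.midpoints_bp()
    if s_min_bp is None:
        s_min_bp = curve.edges_bp[0] * 10
    if s_max_bp is None:
        s_max_bp = float(np.sqrt(curve.edges_bp[0] * curve.edges_bp[-1]) * 3)
    sel = (mids >= s_min_bp) & (mids <= s_max_bp) & (curve.freq > 0)
    if sel.sum() < 3:
        raise ValueError("too few populated distance bins in the fit range")
    res = stats.linregress(np.log10(mids[sel]), np.log10(curve.freq[sel]))
    return float(res.slope)
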