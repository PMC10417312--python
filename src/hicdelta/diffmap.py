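"""Sum-scaling, the masked log2-ratio differential map, and coverage control.

Raw maps from the two conditions are first scaled by their overall sum of
contacts — cis pixels within autosomes (main diagonal excluded, each
unordered pair once) plus autosome-autosome trans pixels when present — so
that sequencing depth cancels.  The differential map is then the per-pixel
log2 ratio treated/control of the scaled maps.  Pixels where either raw map
is zero are masked by default; a pseudocount policy is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import ContactMap
from .genome import GenomeModel
from .intervals import IntervalSet, intervals_to_bins

__all__ = ["DiffMap", "CoverageReport", "overall_sum", "scale_map", "log2_ratio", "coverage_report"]

log = logging.getLogger(__name__)


@dataclass
class DiffMap:
    """Masked per-chromosome log2(treated/control) matrices at map resolution."""

    genome: GenomeModel
    values: dict[str, np.ndarray]
    mask: dict[str, np.ndarray]  # True = valid pixel
    scaling_totals: tuple[float, float]  # (control_total, treated_total)
    zero_policy: str = "mask"
    pseudocount: float | None = None

    def __post_init__(self) -> None:
        for chrom, v in self.values.items():
            m = self.mask[chrom]
            if v.shape != m.shape:
                raise ValueError(f"value/mask shape mismatch on {chrom}")
            if not np.isfinite(v[m]).all():
                raise ValueError(f"non-finite values under mask on {chrom}")


@dataclass
class CoverageReport:
    """Per-bin marginal coverage of both maps and per-region mean log2 ratios."""

    marginals_raw: dict[str, pd.DataFrame]  # columns: control, treated
    marginals_scaled: dict[str, pd.DataFrame]
    regions: pd.DataFrame = field(default_factory=pd.DataFrame)
    flag_bound: float = 0.3


def overall_sum(cmap: ContactMap) -> float:
    """Total contacts within and between autosomes, main diagonal excluded.

    Cis pixels count once per unordered pair (upper triangle, k=1); trans
    blocks between two autosomes are added in full.  Raises if the total is
    zero — such a map cannot be scaled.
    """
    autosomes = cmap.genome.autosomes
    if not autosomes:
        raise ValueError("genome has no autosomes")
    total = 0.0
    for chrom in autosomes:
        total += float(np.triu(cmap.cis[chrom], k=1).sum())
    if cmap.trans:
        for (c1, c2), block in cmap.trans.items():
            if cmap.genome.is_autosome(c1) and cmap.genome.is_autosome(c2):
                total += float(block.sum())
    if total <= 0:
        raise ValueError("overall sum is zero; map cannot be scaled")
    return total


def scale_map(cmap: ContactMap) -> ContactMap:
    """Divide every pixel by the map's overall autosomal sum."""
    total = overall_sum(cmap)
    out = cmap.scaled_by(1.0 / total)
    out.metadata["scaling_total"] = total
    return out


def log2_ratio(
    treated: ContactMap,
    control: ContactMap,
    zero_policy: str = "mask",
    pseudocount: float | None = None,
) -> DiffMap:
    """Differential map: per-pixel log2 of sum-scaled treated over control.

    ``zero_policy='mask'`` (default) marks pixels where either raw count is
    zero invalid; ``'pseudocount'`` adds psi to both scaled maps instead,
    with psi defaulting to the harmonic mean of the two depth reciprocals,
    ``2 / (control_total + treated_total)``.
    """
    if treated.genome != control.genome:
        raise ValueError("treated and control maps use different genomes")
    if zero_policy not in ("mask", "pseudocount"):
        raise ValueError(f"unknown zero policy {zero_policy!r}")
    t_total = overall_sum(treated)
    c_total = overall_sum(control)
    psi = None
    if zero_policy == "pseudocount":
        psi = pseudocount if pseudocount is not None else 2.0 / (c_total + t_total)
    values, mask = {}, {}
    for chrom in treated.genome.chrom_names:
        t = treated.cis[chrom] / t_total
        c = control.cis[chrom] / c_total
        if zero_policy == "mask":
            valid = (t > 0) & (c > 0)
            v = np.zeros_like(t)
            v[valid] = np.log2(t[valid] / c[valid])
        else:
            valid = np.ones(t.shape, dtype=bool)
            v = np.log2((t + psi) / (c + psi))
        values[chrom] = v
        mask[chrom] = valid
    return DiffMap(
        genome=treated.genome,
        values=values,
        mask=mask,
        scaling_totals=(c_total, t_total),
        zero_policy=zero_policy,
        pseudocount=psi,
    )


def coverage_report(
    control: ContactMap,
    treated: ContactMap,
    regions: IntervalSet | None = None,
    flag_bound: float = 0.3,
) -> CoverageReport:
    """Marginal (per-bin) coverage of both maps, raw and sum-scaled.

    For each query region the mean per-bin log2(treated/control) marginal
    ratio is reported for both raw and scaled maps; regions whose scaled
    |mean ratio| exceeds ``flag_bound`` are flagged.  A depleted-interaction
    call driven by a sequencing artefact would show up here; a genuine
    redistribution of contacts leaves marginals near even.
    """
    if treated.genome != control.genome:
        raise ValueError("maps use different genomes")
    g = control.genome
    c_total = overall_sum(control)
    t_total = overall_sum(treated)
    marg_raw, marg_scaled = {}, {}
    for chrom in g.chrom_names:
        c_m = control.cis[chrom].sum(axis=0)
        t_m = treated.cis[chrom].sum(axis=0)
        marg_raw[chrom] = pd.DataFrame({"control": c_m, "treated": t_m})
        marg_scaled[chrom] = pd.DataFrame({"control": c_m / c_total, "treated": t_m / t_total})
    rows = []
    if regions is None or len(regions) == 0:
        if regions is not None:
            log.warning("coverage_report called with an empty region set")
        region_df = pd.DataFrame(
            columns=["chrom", "start", "end", "name", "mean_log2_raw", "mean_log2_scaled", "flagged"]
        )
        return CoverageReport(marg_raw, marg_scaled, region_df, flag_bound)
    masks = intervals_to_bins(regions, g)
    for chrom, start, end, name, _ in regions:
        sel = np.zeros(g.n_bins(chrom), dtype=bool)
        bs = g.bin_size_bp
        sel[start // bs : -(-end // bs)] = True
        sel &= masks[chrom]
        c_r = marg_raw[chrom]["control"].to_numpy()[sel]
        t_r = marg_raw[chrom]["treated"].to_numpy()[sel]
        ok = (c_r > 0) & (t_r > 0)
        mean_raw = float(np.mean(np.log2(t_r[ok] / c_r[ok]))) if ok.any() else float("nan")
        mean_scaled = mean_raw + float(np.log2(c_total / t_total))
        rows.append((chrom, start, end, name, mean_raw, mean_scaled,
                     bool(abs(mean_scaled) > flag_bound)))
    region_df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "mean_log2_raw", "mean_log2_scaled", "flagged"]
    )
    return CoverageReport(marg_raw, marg_scaled, region_df, flag_bound)
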