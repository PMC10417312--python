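"""Binned contact matrices and their on-disk exchange formats.

The canonical exchange format is a sparse TSV triple format::

    #chrom1<TAB>bin1<TAB>chrom2<TAB>bin2<TAB>count

with integer bin indices local to each chromosome, one line per unordered
pixel (upper triangle for cis), unlisted pixels zero.  A minimal reader for
the .cool HDF5 binned-matrix container is provided as an optional adapter
behind the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome import GenomeModel

__all__ = [
    "ContactMap",
    "read_contact_tsv",
    "write_contact_tsv",
    "read_cool",
    "coarsen_map",
]

_HEADER = "#chrom1\tbin1\tchrom2\tbin2\tcount"


@dataclass
class ContactMap:
    """Symmetric non-negative binned contact matrices per chromosome.

    ``cis`` maps chromosome name -> dense symmetric (n_bins, n_bins) array.
    ``trans`` optionally maps ordered chromosome-name pairs (i-th before j-th
    in genome order) to rectangular blocks; trans contributes only to scaling
    totals, never to diagonal analyses.
    """

    genome: GenomeModel
    cis: dict[str, np.ndarray]
    trans: dict[tuple[str, str], np.ndarray] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom in self.genome.chrom_names:
            if chrom not in self.cis:
                self.cis[chrom] = np.zeros((self.genome.n_bins(chrom),) * 2)
        for chrom, block in self.cis.items():
            n = self.genome.n_bins(chrom)
            block = np.asarray(block, dtype=np.float64)
            if block.shape != (n, n):
                raise ValueError(f"cis block for {chrom} has shape {block.shape}, expected {(n, n)}")
            if not np.isfinite(block).all():
                raise ValueError(f"non-finite entries in cis block {chrom}")
            if (block < 0).any():
                raise ValueError(f"negative entries in cis block {chrom}")
            if not np.array_equal(block, block.T):
                raise ValueError(f"cis block for {chrom} is not symmetric")
            self.cis[chrom] = block
        if self.trans:
            order = {c: i for i, c in enumerate(self.genome.chrom_names)}
            for (c1, c2), block in self.trans.items():
                if order[c1] >= order[c2]:
                    raise ValueError("trans keys must be in genome order (c1 before c2)")
                shape = (self.genome.n_bins(c1), self.genome.n_bins(c2))
                block = np.asarray(block, dtype=np.float64)
                if block.shape != shape:
                    raise ValueError(f"trans block {c1}-{c2} has shape {block.shape}, expected {shape}")
                if not np.isfinite(block).all() or (block < 0).any():
                    raise ValueError(f"invalid entries in trans block {c1}-{c2}")
                self.trans[(c1, c2)] = block

    def copy(self) -> "ContactMap":
        return ContactMap(
            self.genome,
            {c: b.copy() for c, b in self.cis.items()},
            {k: b.copy() for k, b in self.trans.items()} if self.trans else None,
            dict(self.metadata),
        )

    def total(self) -> float:
        """Sum of all pixels, each unordered pair counted once."""
        t = 0.0
        for block in self.cis.values():
            t += float(np.triu(block).sum())
        if self.trans:
            for block in self.trans.values():
                t += float(block.sum())
        return t

    def scaled_by(self, factor: float) -> "ContactMap":
        out = self.copy()
        for c in out.cis:
            out.cis[c] = out.cis[c] * factor
        if out.trans:
            for k in out.trans:
                out.trans[k] = out.trans[k] * factor
        return out


def read_contact_tsv(path, genome: GenomeModel) -> ContactMap:
    """Read the TSV triple format into a dense symmetric :class:`ContactMap`.

    Hard errors name the offending line for unknown chromosomes, negative
    counts, out-of-range bins, and duplicate pixels (same unordered pair
    listed twice).
    """
    cis = {c: np.zeros((genome.n_bins(c),) * 2) for c in genome.chrom_names}
    trans: dict[tuple[str, str], np.ndarray] = {}
    seen_trans: dict[tuple[str, str], set] = {}
    order = {c: i for i, c in enumerate(genome.chrom_names)}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}:{ln}: expected 5 tab-separated fields")
            c1, b1s, c2, b2s, cnt_s = parts
            for c in (c1, c2):
                if c not in genome:
                    raise ValueError(f"{path}:{ln}: unknown chromosome {c!r}")
            b1, b2 = int(b1s), int(b2s)
            cnt = float(cnt_s)
            if cnt < 0:
                raise ValueError(f"{path}:{ln}: negative count")
            if c1 == c2:
                n = genome.n_bins(c1)
                if not (0 <= b1 < n and 0 <= b2 < n):
                    raise ValueError(f"{path}:{ln}: bin index out of range for {c1}")
                i, j = min(b1, b2), max(b1, b2)
                if cis[c1][i, j] != 0:
                    raise ValueError(f"{path}:{ln}: duplicate pixel {c1}:{i}-{j}")
                cis[c1][i, j] = cnt
                cis[c1][j, i] = cnt
            else:
                if order[c1] > order[c2]:
                    c1, c2, b1, b2 = c2, c1, b2, b1
                key = (c1, c2)
                if key not in trans:
                    trans[key] = np.zeros((genome.n_bins(c1), genome.n_bins(c2)))
                    seen_trans[key] = set()
                if not (0 <= b1 < trans[key].shape[0] and 0 <= b2 < trans[key].shape[1]):
                    raise ValueError(f"{path}:{ln}: bin index out of range for {c1}/{c2}")
                if (b1, b2) in seen_trans[key]:
                    raise ValueError(f"{path}:{ln}: duplicate pixel {c1}:{b1} x {c2}:{b2}")
                seen_trans[key].add((b1, b2))
                trans[key][b1, b2] = cnt
    return ContactMap(genome, cis, trans or None, {"source": str(path)})


def _fmt_count(v: float) -> str:
    return str(int(v)) if v == int(v) else repr(float(v))


def write_contact_tsv(cmap: ContactMap, path) -> None:
    """Write upper-triangle pixels, sorted; byte-identical for identical maps."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        for chrom in cmap.genome.chrom_names:
            block = cmap.cis[chrom]
            ii, jj = np.nonzero(np.triu(block))
            for i, j in zip(ii.tolist(), jj.tolist()):
                fh.write(f"{chrom}\t{i}\t{chrom}\t{j}\t{_fmt_count(block[i, j])}\n")
        if cmap.trans:
            order = {c: i for i, c in enumerate(cmap.genome.chrom_names)}
            for (c1, c2) in sorted(cmap.trans, key=lambda k: (order[k[0]], order[k[1]])):
                block = cmap.trans[(c1, c2)]
                ii, jj = np.nonzero(block)
                for i, j in zip(ii.tolist(), jj.tolist()):
                    fh.write(f"{c1}\t{i}\t{c2}\t{j}\t{_fmt_count(block[i, j])}\n")


def read_cool(path, genome: GenomeModel | None = None) -> ContactMap:
    """Minimal reader for the single-resolution .cool HDF5 container.

    Reads /chroms, /bins and /pixels and builds dense cis blocks (plus trans
    blocks if present).  If ``genome`` is omitted it is reconstructed from the
    file; chromosomes named like X/Y/M (optionally "chr"-prefixed) are flagged
    non-autosomal.
    """
    import h5py

    with h5py.File(path, "r") as f:
        chrom_names = [n.decode() if isinstance(n, bytes) else str(n) for n in f["chroms/name"][:]]
        chrom_lengths = [int(x) for x in f["chroms/length"][:]]
        starts = f["bins/start"][:]
        ends = f["bins/end"][:]
        bin_size = int((ends - starts).max())
        if genome is None:
            sex = {"X", "Y", "M", "MT"}
            flags = tuple(n.removeprefix("chr").upper() not in sex for n in chrom_names)
            genome = GenomeModel(tuple(chrom_names), tuple(chrom_lengths), bin_size, flags)
        bin_chrom_idx = f["bins/chrom"][:]
        bin1 = f["pixels/bin1_id"][:]
        bin2 = f["pixels/bin2_id"][:]
        count = f["pixels/count"][:]
    offsets = genome.chrom_offsets
    local_start = np.array([offsets[c] for c in chrom_names])[bin_chrom_idx]
    chrom_of_bin = np.array(chrom_names, dtype=object)[bin_chrom_idx]
    cis = {c: np.zeros((genome.n_bins(c),) * 2) for c in genome.chrom_names}
    trans: dict[tuple[str, str], np.ndarray] = {}
    order = {c: i for i, c in enumerate(genome.chrom_names)}
    for b1, b2, cnt in zip(bin1.tolist(), bin2.tolist(), count.tolist()):
        c1, c2 = chrom_of_bin[b1], chrom_of_bin[b2]
        l1, l2 = b1 - local_start[b1], b2 - local_start[b2]
        if c1 == c2:
            cis[c1][l1, l2] = cnt
            cis[c1][l2, l1] = cnt
        else:
            if order[c1] > order[c2]:
                c1, c2, l1, l2 = c2, c1, l2, l1
            trans.setdefault((c1, c2), np.zeros((genome.n_bins(c1), genome.n_bins(c2))))[l1, l2] = cnt
    return ContactMap(genome, cis, trans or None, {"source": str(path), "format": "cool"})


def coarsen_map(cmap: ContactMap, factor: int) -> ContactMap:
    """Sum counts over ``factor`` x ``factor`` blocks; conserves totals exactly.

    The coarse genome keeps chromosome lengths; its bin size is
    ``factor * bin_size``, so a trailing partial block becomes the last
    (shorter) coarse bin.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 2:
        raise ValueError("coarsening factor must be an integer >= 2")
    g = cmap.genome
    coarse = GenomeModel(g.chrom_names, g.chrom_lengths_bp, g.bin_size_bp * factor, g.autosome_flags)
    cis = {}
    for chrom in g.chrom_names:
        n, m = g.n_bins(chrom), coarse.n_bins(chrom)
        idx = np.arange(n) // factor
        tmp = np.zeros((m, n))
        np.add.at(tmp, idx, cmap.cis[chrom])
        out = np.zeros((m, m))
        np.add.at(out.T, idx, tmp.T)
        cis[chrom] = out
    trans = None
    if cmap.trans:
        trans = {}
        for (c1, c2), block in cmap.trans.items():
            i1 = np.arange(block.shape[0]) // factor
            i2 = np.arange(block.shape[1]) // factor
            tmp = np.zeros((coarse.n_bins(c1), block.shape[1]))
            np.add.at(tmp, i1, block)
            out = np.zeros((coarse.n_bins(c1), coarse.n_bins(c2)))
            np.add.at(out.T, i2, tmp.T)
            trans[(c1, c2)] = out
    return ContactMap(coarse, cis, trans, dict(cmap.metadata, coarsened_by=int(factor)))
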