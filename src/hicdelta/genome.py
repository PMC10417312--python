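"""Genome and bin bookkeeping.

A :class:`GenomeModel` fixes the chromosome order, chromosome lengths and a
single bin size, and thereby a global bin index used by every other module.
Bins are half-open ``[k*bin_size, (k+1)*bin_size)``; the last bin of each
chromosome may be shorter than ``bin_size`` and is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenomeModel", "read_chrom_sizes"]


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome names/lengths plus a fixed bin size.

    Parameters
    ----------
    chrom_names:
        Ordered chromosome identifiers.
    chrom_lengths_bp:
        Chromosome lengths in bp, same order; all positive.
    bin_size_bp:
        Bin width in bp, positive.
    autosome_flags:
        One boolean per chromosome; scaling totals and enrichment universes
        are restricted to autosomes.  Defaults to all-True.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths_bp: tuple[int, ...]
    bin_size_bp: int
    autosome_flags: tuple[bool, ...] = field(default=())

    def __post_init__(self) -> None:
        names = tuple(self.chrom_names)
        lengths = tuple(int(x) for x in self.chrom_lengths_bp)
        flags = tuple(self.autosome_flags) or (True,) * len(names)
        object.__setattr__(self, "chrom_names", names)
        object.__setattr__(self, "chrom_lengths_bp", lengths)
        object.__setattr__(self, "autosome_flags", tuple(bool(f) for f in flags))
        if len(names) != len(set(names)):
            raise ValueError("duplicate chromosome names")
        if len(lengths) != len(names) or len(self.autosome_flags) != len(names):
            raise ValueError("chrom_names, chrom_lengths_bp and autosome_flags must align")
        if any(l <= 0 for l in lengths):
            raise ValueError("chromosome lengths must be positive")
        if int(self.bin_size_bp) <= 0:
            raise ValueError("bin size must be positive")
        object.__setattr__(self, "bin_size_bp", int(self.bin_size_bp))

    # -- bin arithmetic ----------------------------------------------------

    def n_bins(self, chrom: str) -> int:
        length = self.chrom_lengths_bp[self._index(chrom)]
        return -(-length // self.bin_size_bp)  # ceil division

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chrom_names)

    @property
    def chrom_offsets(self) -> dict[str, int]:
        """Global bin offset of each chromosome's bin 0."""
        offs, acc = {}, 0
        for c in self.chrom_names:
            offs[c] = acc
            acc += self.n_bins(c)
        return offs

    def bin_id(self, chrom: str, start_bp: int) -> int:
        """Global bin id of the bin containing ``start_bp`` on ``chrom``."""
        if not 0 <= start_bp < self.chrom_lengths_bp[self._index(chrom)]:
            raise ValueError(f"position {start_bp} outside {chrom}")
        return self.chrom_offsets[chrom] + start_bp // self.bin_size_bp

    def bin_locus(self, bin_id: int) -> tuple[str, int]:
        """Inverse of :meth:`bin_id` on bin starts: (chrom, start_bp)."""
        if bin_id < 0:
            raise ValueError("negative bin id")
        for c in self.chrom_names:
            n = self.n_bins(c)
            if bin_id < n:
                return c, bin_id * self.bin_size_bp
            bin_id -= n
        raise ValueError("bin id beyond genome")

    def is_autosome(self, chrom: str) -> bool:
        return self.autosome_flags[self._index(chrom)]

    @property
    def autosomes(self) -> tuple[str, ...]:
        return tuple(c for c, f in zip(self.chrom_names, self.autosome_flags) if f)

    def bin_edges(self, chrom: str) -> np.ndarray:
        """Bin boundaries in bp, length ``n_bins+1`` (last edge clipped)."""
        n = self.n_bins(chrom)
        edges = np.arange(n + 1, dtype=np.int64) * self.bin_size_bp
        edges[-1] = min(edges[-1], self.chrom_lengths_bp[self._index(chrom)])
        return edges

    def _index(self, chrom: str) -> int:
        try:
            return self.chrom_names.index(chrom)
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names


def read_chrom_sizes(path, bin_size_bp: int) -> GenomeModel:
    """Build a GenomeModel from a chrom-sizes TSV: ``name<TAB>length[<TAB>flag]``.

    The optional third column marks autosomes (1/0, true/false); without it,
    chromosomes named like X/Y/M(T) — optionally "chr"-prefixed — are flagged
    non-autosomal.
    """
    names, lengths, flags = [], [], []
    sex = {"X", "Y", "M", "MT"}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            names.append(parts[0])
            lengths.append(int(parts[1]))
            if len(parts) > 2:
                flags.append(parts[2].lower() in ("1", "true", "yes"))
            else:
                flags.append(parts[0].removeprefix("chr").upper() not in sex)
    return GenomeModel(tuple(names), tuple(lengths), bin_size_bp, tuple(flags))
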