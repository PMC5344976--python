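"""Circular genome annotations: genes, GC and restriction-site tracks.

The annotation emulates a genome-reduced bacterium: a single circular
chromosome of ~816 kb carrying ~869 densely packed genes distributed over
both strands, with per-bin GC-fraction and restriction-site-count tracks
used downstream for domain-border feature tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import n_bins_for

#: printed average HpaII cutting frequency in bp, used as the default
#: restriction-site rate for the synthetic site track
DEFAULT_SITE_RATE_BP = 450.0


@dataclass
class GenomeAnnotation:
    """A circular genome with genes and per-bin feature tracks.

    Parameters
    ----------
    genome_length : int
        Chromosome length in bp.
    bin_size : int
        Track bin width in bp; bins are 0-based, half-open
        ``[k*bin_size, (k+1)*bin_size)``; a final partial bin is kept.
    genes : list of (start, end, strand)
        Gene coordinates in ``[0, genome_length)`` with ``start < end``
        after unwrapping; strand is ``"+"`` or ``"-"``.
    gc_track : ndarray
        GC fraction in [0, 1] per bin.
    site_track : ndarray
        Nonnegative restriction-site count per bin.
    """

    genome_length: int
    bin_size: int
    genes: list = field(default_factory=list)
    gc_track: np.ndarray | None = None
    site_track: np.ndarray | None = None
    circular: bool = True

    def __post_init__(self):
        if self.genome_length <= 0 or self.bin_size <= 0:
            raise ValueError("genome_length and bin_size must be positive")
        n = self.n_bins
        for g in self.genes:
            start, end, strand = g
            if not (0 <= start < self.genome_length):
                raise ValueError(f"gene start {start} outside [0, genome_length)")
            if not start < end:
                raise ValueError(f"gene ({start}, {end}) must satisfy start < end")
            if strand not in ("+", "-"):
                raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        if self.gc_track is not None:
            self.gc_track = np.asarray(self.gc_track, dtype=float)
            if self.gc_track.shape != (n,):
                raise ValueError("gc_track length must equal the number of bins")
            if np.any((self.gc_track < 0) | (self.gc_track > 1)):
                raise ValueError("gc_track values must lie in [0, 1]")
        if self.site_track is not None:
            self.site_track = np.asarray(self.site_track)
            if self.site_track.shape != (n,):
                raise ValueError("site_track length must equal the number of bins")
            if np.any(self.site_track < 0):
                raise ValueError("site_track values must be nonnegative")

    @property
    def n_bins(self) -> int:
        return n_bins_for(self.genome_length, self.bin_size)

    def bin_of(self, pos) -> np.ndarray:
        """Bin index of a genomic position (bp)."""
        pos = np.asarray(pos)
        if np.any((pos < 0) | (pos >= self.genome_length)):
            raise IndexError("position outside [0, genome_length)")
        return pos // self.bin_size

    def gene_midpoints(self) -> np.ndarray:
        return np.array([(s + e) // 2 for s, e, _ in self.genes], dtype=int)


def generate_genome_annotation(
    genome_length: int,
    n_genes: int,
    bin_size: int,
    seed: int,
    gene_fill: float = 0.85,
    strand_switch_prob: float = 0.25,
    site_rate_bp: float = DEFAULT_SITE_RATE_BP,
    gc_mean: float = 0.40,
    gc_sd: float = 0.03,
) -> GenomeAnnotation:
    """Generate a deterministic synthetic circular-genome annotation.

    Genes tile the genome on both strands in runs (geometric run length
    with switch probability ``strand_switch_prob``), producing occasional
    convergent and divergent junctions.  ``gene_fill`` is the target coding
    fraction.  The GC track is a smooth seeded profile around ``gc_mean``;
    the site track is Poisson with one site per ``site_rate_bp`` on average.
    """
    if genome_length <= 0 or bin_size <= 0:
        raise ValueError("genome_length and bin_size must be positive")
    if genome_length < 2 * bin_size:
        raise ValueError("genome_length must span at least 2 bins")
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")

    rng = np.random.default_rng(seed)
    n_bins = n_bins_for(genome_length, bin_size)

    # genes: draw lengths around the mean implied by gene_fill, walk the genome
    mean_len = gene_fill * genome_length / n_genes
    mean_gap = (1.0 - gene_fill) * genome_length / n_genes
    lengths = np.maximum(60, rng.gamma(4.0, mean_len / 4.0, size=n_genes)).astype(int)
    gaps = np.maximum(1, rng.exponential(mean_gap, size=n_genes)).astype(int)
    span = lengths.sum() + gaps.sum()
    if span >= genome_length:  # rescale to fit the circle
        scale = (genome_length - n_genes) / span
        lengths = np.maximum(30, (lengths * scale).astype(int))
        gaps = np.maximum(1, (gaps * scale).astype(int))

    strand = "+" if rng.random() < 0.5 else "-"
    genes = []
    pos = int(rng.integers(0, bin_size))
    for k in range(n_genes):
        start = pos
        end = min(start + int(lengths[k]), genome_length - 1)
        if start >= end:
            break
        genes.append((start, end, strand))
        pos = end + int(gaps[k])
        if pos >= genome_length - 60:
            break
        if rng.random() < strand_switch_prob:
            strand = "+" if strand == "-" else "-"

    # smooth GC profile: a few random harmonics on the circle plus noise
    theta = 2 * np.pi * np.arange(n_bins) / n_bins
    gc = np.full(n_bins, gc_mean)
    for harmonic in (1, 2, 3, 5):
        gc += (gc_sd / 2) * rng.normal() * np.sin(harmonic * theta + rng.uniform(0, 2 * np.pi))
    gc += gc_sd * 0.5 * rng.normal(size=n_bins)
    gc = np.clip(gc, 0.0, 1.0)

    sites = rng.poisson(bin_size / site_rate_bp, size=n_bins)

    return GenomeAnnotation(
        genome_length=genome_length,
        bin_size=bin_size,
        genes=genes,
        gc_track=gc,
        site_track=sites,
    )
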