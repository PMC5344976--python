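"""Genomic-feature enrichment tests at domain borders.

Each domain border is two bins: the last bin of the preceding domain and
the first bin of the following one.  Significance of a per-bin feature
track at the borders is assessed by a circular permutation test: every
permutation applies one uniform random rotation to the whole border set,
conserving the number and sizes of domains exactly, and the empirical
p-value is the fraction of null statistics at least as extreme as the
observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .annotation import GenomeAnnotation
from .domains import DomainSegmentation

SIDE_GREATER = "greater-or-equal"
SIDE_LESS = "less-or-equal"


@dataclass
class PermutationResult:
    observed: float
    null_values: np.ndarray
    p_value: float
    side: str
    n_permutations: int
    seed: int

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def border_bins(segmentation: DomainSegmentation) -> list:
    """(last bin of previous domain, first bin of next domain) per border.

    A circular genome with d domains has d borders and 2d border bins.
    """
    n = segmentation.n_bins
    return [((int(b) - 1) % n, int(b)) for b in segmentation.borders]


def _border_statistic(track: np.ndarray, borders: np.ndarray, n: int, statistic: str) -> float:
    bins = np.concatenate([((borders - 1) % n), borders % n])
    vals = track[bins]
    return float(vals.sum() if statistic == "sum" else vals.mean())


def permutation_feature_test(
    track,
    segmentation: DomainSegmentation,
    n_perm: int = 1000,
    side: str = SIDE_GREATER,
    seed: int = 0,
    statistic: str = "mean",
    plus_one: bool = False,
) -> PermutationResult:
    """Circular-shift permutation test of a per-bin track at domain borders.

    The observed statistic is the mean (or sum) of the track over the 2d
    border bins.  Each permutation rotates all borders jointly by one
    uniform random offset, preserving inter-border spacings; the p-value
    is ``#(null >= observed)/n_perm`` for the greater-or-equal side (resp.
    ``<=``), optionally with the (k+1)/(N+1) estimator (``plus_one``).
    """
    track = np.asarray(track, dtype=float)
    n = segmentation.n_bins
    if track.shape != (n,):
        raise ValueError("track length must equal the number of bins")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if side not in (SIDE_GREATER, SIDE_LESS):
        raise ValueError(f"unknown side {side!r}")
    borders = segmentation.borders
    observed = _border_statistic(track, borders, n, statistic)
    rng = np.random.default_rng(seed)
    offsets = rng.integers(0, n, size=n_perm)
    null = np.array([
        _border_statistic(track, (borders + off) % n, n, statistic) for off in offsets
    ])
    if side == SIDE_GREATER:
        hits = int(np.sum(null >= observed))
    else:
        hits = int(np.sum(null <= observed))
    p = (hits + 1) / (n_perm + 1) if plus_one else hits / n_perm
    if np.ptp(track) == 0:
        warnings.warn("constant track: permutation test is degenerate (p = 1)", stacklevel=2)
    return PermutationResult(observed=observed, null_values=null, p_value=float(p),
                             side=side, n_permutations=n_perm, seed=seed)


def convergent_divergent_track(annotation: GenomeAnnotation) -> dict:
    """Per-bin indicator tracks of convergent and divergent gene junctions.

    Adjacent gene pairs (by start coordinate, circularly) are classified
    by their strands: (+,-) is convergent (transcription pointing
    together), (-,+) divergent, equal strands co-directional.  The bin
    containing the junction midpoint is marked; overlapping genes get the
    overlap midpoint with a logged note.
    """
    genes = sorted(annotation.genes, key=lambda g: g[0])
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    n = annotation.n_bins
    conv = np.zeros(n)
    div = np.zeros(n)
    L = annotation.genome_length
    n_junctions = len(genes) if annotation.circular else len(genes) - 1
    for idx in range(n_junctions):
        s1, e1, st1 = genes[idx]
        s2, e2, st2 = genes[(idx + 1) % len(genes)]
        if idx == len(genes) - 1:  # wrap-around junction of the circular genome
            mid = ((e1 + s2 + L) // 2) % L
        else:
            if s2 < e1:
                warnings.warn(
                    f"overlapping genes at {s1}-{e1}/{s2}-{e2}; junction at overlap midpoint",
                    stacklevel=2,
                )
            mid = (e1 + s2) // 2 % L
        b = int(mid // annotation.bin_size)
        if (st1, st2) == ("+", "-"):
            conv[b] = 1.0
        elif (st1, st2) == ("-", "+"):
            div[b] = 1.0
    return {"convergent": conv, "divergent": div}


def gc_track_from_annotation(annotation: GenomeAnnotation) -> np.ndarray:
    """Validated per-bin GC fraction track (for depletion-side testing)."""
    if annotation.gc_track is None:
        raise ValueError("annotation carries no GC track")
    gc = np.asarray(annotation.gc_track, dtype=float)
    if np.any((gc < 0) | (gc > 1)):
        raise ValueError("GC fractions must lie in [0, 1]")
    return gc
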