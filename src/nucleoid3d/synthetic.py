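"""Synthetic data: planted-truth genomes, structures, contact maps, expression.

The generator mirrors the downstream detectors' models so that every
pipeline stage is testable without sequencing data: contact counts are
Poisson with a power-law decay in circular genomic distance, multiplied by
a planted within-domain boost and a weak secondary (anti-)diagonal
enhancement emulating inter-arm contacts of a circular chromosome whose
two replichores run alongside each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import child_seed, circular_distance_matrix
from .annotation import GenomeAnnotation, generate_genome_annotation  # noqa: F401  (re-export)
from .hic import ContactMatrix

#: default relative strength of the secondary diagonal
DEFAULT_ANTIDIAGONAL_EPS = 0.3


@dataclass
class PlantedTruth:
    """Ground truth for recovery tests.

    ``true_borders`` are domain boundary bins (same convention as the
    domain caller: the origin bin counts as a border, domain k spans
    ``[border_k, border_{k+1})`` circularly).  ``decay_exponent`` is the
    power-law slope b < 0 of expected counts vs circular distance;
    ``domain_boost`` multiplies expected counts for same-domain bin pairs.
    """

    n_bins: int
    true_borders: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    true_structure: np.ndarray | None = None
    decay_exponent: float = -1.0
    domain_boost: float = 1.0
    boosted_domains: frozenset | None = None  # None = every planted domain is boosted
    antidiagonal_eps: float = DEFAULT_ANTIDIAGONAL_EPS
    noise_seed: int = 0

    def __post_init__(self):
        self.true_borders = np.asarray(self.true_borders, dtype=int)
        if self.true_borders.size:
            if np.any(np.diff(self.true_borders) <= 0):
                raise ValueError("true_borders must be strictly increasing")
            if self.true_borders[0] < 0 or self.true_borders[-1] >= self.n_bins:
                raise ValueError("true_borders must lie in [0, n_bins)")
        if self.domain_boost < 1:
            raise ValueError("domain_boost must be >= 1")
        if self.decay_exponent >= 0:
            raise ValueError("decay_exponent must be negative (counts decay with distance)")

    def domain_of(self) -> np.ndarray:
        """Domain label per bin (0 if no borders planted)."""
        labels = np.zeros(self.n_bins, dtype=int)
        if self.true_borders.size == 0:
            return labels
        b = self.true_borders
        labels = np.searchsorted(b, np.arange(self.n_bins), side="right") - 1
        labels[labels < 0] = len(b) - 1  # bins before the first border wrap to the last domain
        return labels


def generate_true_structure(n_particles: int, particle_radius: float, seed: int,
                            wobble: float = 0.02) -> np.ndarray:
    """A closed circular particle chain with poles at particles 0 and n/2.

    Particles are laid on a circle whose chord between neighbours equals
    the sum of their radii (2r), then perturbed by a small seeded radial /
    axial wobble (fraction ``wobble`` of the spacing) so distinct seeds
    give distinct conformations.  By construction the two most mutually
    distant particles are (near) an antipodal pair.
    """
    if n_particles < 4:
        raise ValueError("need at least 4 particles")
    if particle_radius <= 0:
        raise ValueError("particle_radius must be positive")
    rng = np.random.default_rng(seed)
    spacing = 2.0 * particle_radius
    big_r = spacing / (2.0 * np.sin(np.pi / n_particles))
    theta = 2 * np.pi * np.arange(n_particles) / n_particles
    coords = np.column_stack([big_r * np.cos(theta), big_r * np.sin(theta),
                              np.zeros(n_particles)])
    coords += wobble * spacing * rng.standard_normal(coords.shape)
    return coords


def _expected_map(truth: PlantedTruth, n_bins: int, mean_depth: float) -> np.ndarray:
    d = circular_distance_matrix(n_bins).astype(float)
    d[d == 0] = 0.5  # self-contact cells use a half-bin effective distance
    lam = mean_depth * d ** truth.decay_exponent
    labels = truth.domain_of()
    if truth.true_borders.size:
        same = labels[:, None] == labels[None, :]
        if truth.boosted_domains is not None:
            boosted = np.isin(labels, list(truth.boosted_domains))
            same = same & boosted[:, None] & boosted[None, :]
        lam = np.where(same, lam * truth.domain_boost, lam)
    if truth.antidiagonal_eps:
        idx = np.arange(n_bins)
        refl = (n_bins - idx) % n_bins  # mirror bin across the origin
        dd = np.minimum(np.abs(idx[None, :] - refl[:, None]),
                        n_bins - np.abs(idx[None, :] - refl[:, None]))
        lam = lam * (1.0 + truth.antidiagonal_eps * np.exp(-0.5 * (dd / 2.0) ** 2))
    return lam


def simulate_contact_map(truth: PlantedTruth, n_bins: int, mean_depth: float,
                         seed: int, bin_size: int = 3000) -> ContactMatrix:
    """Poisson contact map with planted domains and a secondary diagonal.

    Expected count for bins (i, j): ``mean_depth * d(i,j)^b`` times the
    domain boost when i and j share a planted domain, times
    ``1 + eps * exp(-(antidiagonal offset)^2/8)``, with d the circular bin
    distance.  Counts are Poisson and exactly symmetric.
    """
    if n_bins < 8:
        raise ValueError("need at least 8 bins")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if truth.true_borders.size and n_bins != truth.n_bins:
        raise ValueError("n_bins must match truth.n_bins when domains are planted")
    lam = _expected_map(truth, n_bins, mean_depth)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n_bins)
    m = np.zeros((n_bins, n_bins))
    m[iu] = rng.poisson(lam[iu])
    m = np.triu(m) + np.triu(m, 1).T
    return ContactMatrix(values=m, bin_size=bin_size, state="raw")


def simulate_replicates(base_truth: PlantedTruth, n_replicates: int, depth_variation: float,
                        seed: int, n_bins: int | None = None, mean_depth: float = 50.0,
                        bin_size: int = 3000) -> list:
    """Independent Poisson replicate maps of one expectation with depth scaling.

    Replicate r has depth ``mean_depth * (1 + depth_variation * u_r)`` with
    u_r uniform on [-1, 1].  A single replicate is allowed (degenerate case).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    n_bins = n_bins if n_bins is not None else base_truth.n_bins
    rng = np.random.default_rng(seed)
    out = []
    for r in range(n_replicates):
        depth = mean_depth * (1.0 + depth_variation * rng.uniform(-1, 1))
        out.append(
            simulate_contact_map(base_truth, n_bins, depth,
                                 seed=child_seed(seed, 101, r), bin_size=bin_size)
        )
    return out


def contact_map_from_structure(coords: np.ndarray, mean_depth: float, seed: int,
                               exponent: float = -3.0, bin_size: int = 10000) -> ContactMatrix:
    """Poisson contact map whose expectation decays with spatial distance.

    Expected counts are ``mean_depth * (d_ij / d_min)^exponent`` with d_ij
    the Euclidean particle distance and d_min the smallest inter-particle
    distance, so the closest pair has expectation ``mean_depth``.  Used for
    structure-recovery benchmarks where the generating conformation is known.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    iu = np.triu_indices(n, 1)
    dmin = dist[iu].min()
    lam = np.zeros_like(dist)
    lam[iu] = mean_depth * (dist[iu] / dmin) ** exponent
    rng = np.random.default_rng(seed)
    m = np.zeros_like(lam)
    m[iu] = rng.poisson(lam[iu])
    m = m + m.T
    return ContactMatrix(values=m, bin_size=bin_size, state="raw")


def simulate_expression(annotation: GenomeAnnotation, borders, n_conditions: int,
                        rho_within: float, seed: int, n_replicates: int = 2,
                        replicate_sd: float = 0.05) -> dict:
    """Expression matrix with a shared latent factor per planted domain.

    Genes whose midpoints fall in the same planted domain load on a common
    per-condition factor with loading sqrt(rho_within), giving pairwise
    within-domain correlation ~ rho_within; genes in different domains are
    independent given condition effects.  Each condition contributes
    ``n_replicates`` sample columns (condition value plus a small replicate
    noise), emulating a replicate-paired compendium.

    Returns a dict with ``matrix`` (genes x samples), ``gene_midpoints``
    (bp), ``condition_of`` (condition index per sample column) and
    ``domain_of_gene``.
    """
    if not (0 <= rho_within < 1):
        raise ValueError("rho_within must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    borders = np.asarray(sorted(borders), dtype=int)
    mids = annotation.gene_midpoints()
    bins = mids // annotation.bin_size
    if borders.size:
        dom = np.searchsorted(borders, bins, side="right") - 1
        dom[dom < 0] = borders.size - 1
    else:
        dom = np.zeros(bins.size, dtype=int)
    n_genes = mids.size
    n_dom = int(dom.max()) + 1 if n_genes else 0
    factors = rng.standard_normal((n_dom, n_conditions))
    eps = rng.standard_normal((n_genes, n_conditions))
    cond_expr = np.sqrt(rho_within) * factors[dom] + np.sqrt(1 - rho_within) * eps
    cols, cond_of = [], []
    for rep in range(n_replicates):
        cols.append(cond_expr + replicate_sd * rng.standard_normal(cond_expr.shape))
        cond_of.append(np.arange(n_conditions))
    order = np.argsort(np.concatenate(cond_of), kind="stable")
    matrix = np.concatenate(cols, axis=1)[:, order]
    return {
        "matrix": matrix,
        "gene_midpoints": mids,
        "condition_of": np.concatenate(cond_of)[order],
        "domain_of_gene": dom,
    }
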