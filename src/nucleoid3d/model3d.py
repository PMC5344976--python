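"""Restraint-based 3D chromosome modelling from a normalized contact map.

Contact frequencies are converted to harmonic spatial restraints between
particles (one particle per bin): consecutive particles sit at the sum of
their radii; frequent pairs (z-score of log frequency above an upper
cutoff) are attracted to an equilibrium distance interpolated between the
proximal distance for non-interacting particles and the sum of radii;
infrequent pairs (below a lower cutoff) are kept beyond the proximal
distance.  Conformations are sampled by Monte-Carlo simulated annealing
from random initial coordinates, with a deterministic local quench at the
end of the schedule, and the lowest-penalty models are kept, clustered by
reflection-sensitive RMSD (mirror-image solutions form separate clusters)
and summarized geometrically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy import optimize, stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .hic import ContactMatrix

KIND_ADJACENT = 0
KIND_ATTRACT = 1
KIND_LOWER_BOUND = 2


def particle_radius(bin_size: int, scale: float) -> float:
    """Particle radius in nm: half the bin's contour length, bin_size*scale/2."""
    if bin_size <= 0 or scale <= 0:
        raise ValueError("bin_size and scale must be positive")
    return bin_size * scale / 2.0


@dataclass
class ModelingConfig:
    """Parameters of the restraint builder and annealing sampler.

    Defaults follow the empirically optimized values for a ~816 kb circular
    genome at 10 kb resolution: 0.0201 nm/bp scale (100.5 nm particle
    radius), 250 nm proximal distance for non-interacting particles, and
    z-score cutoffs of -0.6 (lower) / -0.2 (upper).
    """

    scale: float = 0.0201          # nm per bp
    maxdist: float = 250.0         # nm, proximal distance for non-interacting particles
    lower_cutoff: float = -0.6     # z-score below which pairs are kept apart
    upper_cutoff: float = -0.2     # z-score above which pairs attract
    n_models: int = 5000
    n_keep: int = 1000
    k_adjacent: float = 5.0        # force constants (consistent arbitrary units)
    k_attract: float = 1.0
    k_lower: float = 1.0
    t0: float = 1e4                # initial annealing temperature (energy units)
    tmin: float = 1.0
    n_temps: int = 60
    moves_per_particle: int = 3    # Metropolis moves per particle per temperature
    step0: float = 50.0            # nm, initial Gaussian move size
    quench_maxiter: int = 300      # L-BFGS iterations of the final quench
    seed: int = 0

    def __post_init__(self):
        if not self.lower_cutoff < self.upper_cutoff:
            raise ValueError("lower_cutoff must be < upper_cutoff")
        if self.n_keep > self.n_models:
            raise ValueError("n_keep must be <= n_models")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


@dataclass
class RestraintSet:
    """Harmonic restraints on a circular particle chain."""

    n_particles: int
    radii: np.ndarray          # nm per particle
    i: np.ndarray
    j: np.ndarray
    kind: np.ndarray           # KIND_* codes
    d0: np.ndarray             # equilibrium distance, nm
    k: np.ndarray              # force constant
    require_adjacency: bool = True  # relax for hand-built toy sets

    def __post_init__(self):
        for name in ("i", "j", "kind"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        for name in ("d0", "k", "radii"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        pairs = {}
        for a, b, kd in zip(self.i, self.j, self.kind):
            key = (min(a, b), max(a, b))
            if key in pairs and pairs[key] != kd:
                raise ValueError(f"pair {key} carries conflicting restraint kinds")
            pairs[key] = kd
        if self.require_adjacency:
            n = self.n_particles
            adjacent = {(min(a, b), max(a, b)) for a, b, kd in zip(self.i, self.j, self.kind)
                        if kd == KIND_ADJACENT}
            expected = {(min(p, (p + 1) % n), max(p, (p + 1) % n)) for p in range(n)}
            if not expected <= adjacent:
                raise ValueError("adjacency restraints missing for some consecutive circular pair")

    def __len__(self):
        return self.i.size


def build_restraints(matrix: ContactMatrix, config: ModelingConfig) -> RestraintSet:
    """Translate contact frequencies into spatial restraints.

    z-scores are computed on log10 of the positive normalized frequencies
    over non-adjacent, non-blacklisted pairs.  Pairs with z above the upper
    cutoff attract at a distance interpolated linearly in z between
    (upper_cutoff -> maxdist) and (max z -> sum of radii); pairs with z
    below the lower cutoff (including zero-frequency pairs) get a
    lower-bound restraint at maxdist; pairs in between are unrestrained.
    Consecutive circular pairs are always restrained at the sum of radii.
    """
    n = matrix.n_bins
    if not np.any(matrix.values > 0):
        raise ValueError("all-zero matrix carries no signal for restraint building")
    radius = particle_radius(matrix.bin_size, config.scale)
    radii = np.full(n, radius)
    sum_radii = 2.0 * radius

    ii, jj, kinds, d0s, ks = [], [], [], [], []
    for p in range(n - 1):
        ii.append(p); jj.append(p + 1); kinds.append(KIND_ADJACENT)
        d0s.append(radii[p] + radii[p + 1]); ks.append(config.k_adjacent)
    if n > 2:  # closing pair of the circle
        ii.append(0); jj.append(n - 1); kinds.append(KIND_ADJACENT)
        d0s.append(radii[0] + radii[n - 1]); ks.append(config.k_adjacent)

    active = matrix.active_mask()
    iu = np.triu_indices(n, 2)
    # exclude the circular closing pair (0, n-1), which is adjacent
    keep = ~((iu[0] == 0) & (iu[1] == n - 1))
    iu = (iu[0][keep], iu[1][keep])
    usable = active[iu[0]] & active[iu[1]]
    vals = matrix.values[iu]
    pos = usable & (vals > 0)
    if not np.any(pos):
        raise ValueError("no positive non-adjacent frequencies to transform")
    logv = np.log10(vals[pos])
    mu, sd = logv.mean(), logv.std()
    sd = sd if sd > 0 else 1.0
    z = np.full(vals.shape, -np.inf)
    z[pos] = (np.log10(vals[pos]) - mu) / sd
    zmax = z[pos].max()
    span = max(zmax - config.upper_cutoff, 1e-9)

    for a, b, zz, ok in zip(iu[0], iu[1], z, usable):
        if not ok:
            continue
        if zz >= config.upper_cutoff:
            frac = min((zz - config.upper_cutoff) / span, 1.0)
            d0 = config.maxdist + frac * (sum_radii - config.maxdist)
            ii.append(int(a)); jj.append(int(b)); kinds.append(KIND_ATTRACT)
            d0s.append(float(d0)); ks.append(config.k_attract)
        elif zz <= config.lower_cutoff:
            ii.append(int(a)); jj.append(int(b)); kinds.append(KIND_LOWER_BOUND)
            d0s.append(config.maxdist); ks.append(config.k_lower)

    return RestraintSet(n_particles=n, radii=radii, i=np.array(ii), j=np.array(jj),
                        kind=np.array(kinds), d0=np.array(d0s), k=np.array(ks))


@dataclass
class ModelEnsemble:
    """A set of 3D conformations with objective penalties and cluster labels."""

    coords: np.ndarray                 # (n_models, n_particles, 3), nm
    penalties: np.ndarray
    run_index: np.ndarray
    cluster_labels: np.ndarray | None = None
    centroid_indices: list | None = None
    energy_trace: np.ndarray | None = None  # (n_models, n_temps) annealing energies

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.penalties = np.asarray(self.penalties, dtype=float)
        self.run_index = np.asarray(self.run_index, dtype=int)

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_particles(self) -> int:
        return self.coords.shape[1]

    def distance_matrices(self) -> np.ndarray:
        diff = self.coords[:, :, None, :] - self.coords[:, None, :, :]
        return np.sqrt((diff ** 2).sum(-1))

    def median_distance_matrix(self) -> np.ndarray:
        return np.median(self.distance_matrices(), axis=0)


@njit(cache=False)
def _anneal_kernel(coords, ri, rj, kind, d0, kf, inc_off, inc_idx,
                   t0, tmin, n_temps, moves_per_temp, step0, seed):  # pragma: no cover
    np.random.seed(seed)
    n = coords.shape[0]
    cool = (tmin / t0) ** (1.0 / max(n_temps - 1, 1))
    trace = np.empty(n_temps)
    t = t0
    for it in range(n_temps):
        step = step0 * (t / t0) ** 0.5
        for _ in range(moves_per_temp):
            p = np.random.randint(0, n)
            dx = step * np.random.randn()
            dy = step * np.random.randn()
            dz = step * np.random.randn()
            delta = 0.0
            for s in range(inc_off[p], inc_off[p + 1]):
                r = inc_idx[s]
                a, b = ri[r], rj[r]
                vx = coords[a, 0] - coords[b, 0]
                vy = coords[a, 1] - coords[b, 1]
                vz = coords[a, 2] - coords[b, 2]
                dold = (vx * vx + vy * vy + vz * vz) ** 0.5
                if a == p:
                    vx += dx; vy += dy; vz += dz
                else:
                    vx -= dx; vy -= dy; vz -= dz
                dnew = (vx * vx + vy * vy + vz * vz) ** 0.5
                if kind[r] == 2:
                    eo = d0[r] - dold
                    en = d0[r] - dnew
                    eold = kf[r] * eo * eo if eo > 0 else 0.0
                    enew = kf[r] * en * en if en > 0 else 0.0
                else:
                    eold = kf[r] * (dold - d0[r]) ** 2
                    enew = kf[r] * (dnew - d0[r]) ** 2
                delta += enew - eold
            if delta <= 0.0 or np.random.random() < np.exp(-delta / t):
                coords[p, 0] += dx
                coords[p, 1] += dy
                coords[p, 2] += dz
        # energy bookkeeping for the schedule trace
        e = 0.0
        for r in range(ri.shape[0]):
            a, b = ri[r], rj[r]
            vx = coords[a, 0] - coords[b, 0]
            vy = coords[a, 1] - coords[b, 1]
            vz = coords[a, 2] - coords[b, 2]
            d = (vx * vx + vy * vy + vz * vz) ** 0.5
            if kind[r] == 2:
                viol = d0[r] - d
                if viol > 0:
                    e += kf[r] * viol * viol
            else:
                e += kf[r] * (d - d0[r]) ** 2
        trace[it] = e
        t *= cool
    return coords, trace


def restraint_energy(coords: np.ndarray, restraints: RestraintSet):
    """Objective value and gradient of the harmonic restraint potential."""
    c = coords.reshape(-1, 3)
    v = c[restraints.i] - c[restraints.j]
    d = np.sqrt((v ** 2).sum(-1))
    d = np.maximum(d, 1e-9)
    delta = d - restraints.d0
    viol = np.where(restraints.kind == KIND_LOWER_BOUND, np.minimum(delta, 0.0), delta)
    energy = float((restraints.k * viol ** 2).sum())
    coef = (2.0 * restraints.k * viol / d)[:, None] * v
    n = restraints.n_particles
    grad = np.zeros((n, 3))
    for axis in range(3):
        grad[:, axis] = (np.bincount(restraints.i, weights=coef[:, axis], minlength=n)
                         - np.bincount(restraints.j, weights=coef[:, axis], minlength=n))
    return energy, grad.reshape(-1)


def _incidence(restraints: RestraintSet):
    n = restraints.n_particles
    counts = np.bincount(restraints.i, minlength=n) + np.bincount(restraints.j, minlength=n)
    off = np.zeros(n + 1, dtype=np.int64)
    off[1:] = np.cumsum(counts)
    idx = np.empty(off[-1], dtype=np.int64)
    fill = off[:-1].copy()
    for r, (a, b) in enumerate(zip(restraints.i, restraints.j)):
        idx[fill[a]] = r
        fill[a] += 1
        idx[fill[b]] = r
        fill[b] += 1
    return off, idx


def optimize_ensemble(restraints: RestraintSet, config: ModelingConfig) -> ModelEnsemble:
    """Sample an ensemble of conformations by simulated annealing.

    Each model starts from random coordinates in a sphere of radius
    ``maxdist`` and runs an independent geometric-cooling Metropolis
    schedule (single-particle Gaussian displacements) followed by a
    deterministic L-BFGS quench of the same objective.  All randomness is
    derived from ``config.seed`` with one substream per model, so results
    are reproducible and independent of execution order.
    """
    inc_off, inc_idx = _incidence(restraints)
    n = restraints.n_particles
    coords_out = np.empty((config.n_models, n, 3))
    penalties = np.empty(config.n_models)
    traces = np.empty((config.n_models, config.n_temps))
    moves_per_temp = config.moves_per_particle * n
    for m in range(config.n_models):
        rng = np.random.default_rng([config.seed, m])
        c0 = rng.uniform(-config.maxdist, config.maxdist, size=(n, 3))
        kernel_seed = int(rng.integers(0, 2**31 - 1))
        c, trace = _anneal_kernel(
            np.ascontiguousarray(c0), restraints.i, restraints.j, restraints.kind,
            restraints.d0, restraints.k, inc_off, inc_idx,
            config.t0, config.tmin, config.n_temps, moves_per_temp,
            config.step0, kernel_seed,
        )
        res = optimize.minimize(
            restraint_energy, c.reshape(-1), args=(restraints,), jac=True,
            method="L-BFGS-B", options={"maxiter": config.quench_maxiter},
        )
        if not np.isfinite(res.fun):
            raise FloatingPointError(f"non-finite objective in model run {m}")
        coords_out[m] = res.x.reshape(n, 3)
        penalties[m] = res.fun
        traces[m] = trace
    return ModelEnsemble(coords=coords_out, penalties=penalties,
                         run_index=np.arange(config.n_models), energy_trace=traces)


def select_models(ensemble: ModelEnsemble, n_keep: int) -> ModelEnsemble:
    """Keep the n_keep lowest-penalty models; ties broken by run index."""
    if n_keep > ensemble.n_models:
        raise ValueError("n_keep exceeds ensemble size")
    order = np.lexsort((ensemble.run_index, ensemble.penalties))[:n_keep]
    order = order[np.argsort(ensemble.run_index[order])]
    return ModelEnsemble(
        coords=ensemble.coords[order],
        penalties=ensemble.penalties[order],
        run_index=ensemble.run_index[order],
        energy_trace=None if ensemble.energy_trace is None else ensemble.energy_trace[order],
    )


def superposed_rmsd(a: np.ndarray, b: np.ndarray, allow_reflection: bool = False) -> float:
    """Coordinate RMSD after optimal rigid superposition (Kabsch).

    By default only proper rotations are allowed, so a structure and its
    mirror image have a large RMSD and separate in clustering; with
    ``allow_reflection`` the improper solution is also considered.
    """
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    u, s, vt = np.linalg.svd(a0.T @ b0)
    d = np.sign(np.linalg.det(u @ vt))
    if allow_reflection:
        d = 1.0
    s = s.copy()
    s[-1] *= d
    msd = (np.sum(a0 ** 2) + np.sum(b0 ** 2) - 2.0 * s.sum()) / a.shape[0]
    return float(np.sqrt(max(msd, 0.0)))


def _align_to(ref: np.ndarray, coords: np.ndarray, allow_reflection: bool = False) -> np.ndarray:
    """Superpose coords onto ref (proper rotation unless reflections allowed)."""
    c0 = coords - coords.mean(axis=0)
    r0 = ref - ref.mean(axis=0)
    u, s, vt = np.linalg.svd(c0.T @ r0)
    d = np.sign(np.linalg.det(u @ vt))
    if allow_reflection:
        d = 1.0
    corr = np.diag([1.0, 1.0, d])
    rot = u @ corr @ vt
    return c0 @ rot + ref.mean(axis=0)


def cluster_models(
    ensemble: ModelEnsemble,
    linkage_method: str = "average",
    allow_reflection: bool = False,
    n_clusters: int | None = None,
    height_fraction: float = 0.5,
    tol_fraction: float = 0.01,
) -> ModelEnsemble:
    """Hierarchically cluster an ensemble by superposition RMSD.

    Without a fixed ``n_clusters`` the tree is cut at ``height_fraction``
    of the maximum merge height; ensembles whose spread is below
    ``tol_fraction`` of the mean radius of gyration collapse to a single
    cluster.  Labels are 0-based, ordered by decreasing cluster size; the
    centroid of each cluster is the member closest to the aligned mean
    coordinates.
    """
    if ensemble.n_models < 2:
        raise ValueError("need at least 2 models to cluster")
    nm = ensemble.n_models
    dist = np.zeros((nm, nm))
    for a in range(nm):
        for b in range(a + 1, nm):
            dist[a, b] = dist[b, a] = superposed_rmsd(
                ensemble.coords[a], ensemble.coords[b], allow_reflection=allow_reflection
            )
    link = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    rg = np.sqrt(((ensemble.coords - ensemble.coords.mean(axis=1, keepdims=True)) ** 2)
                 .sum(-1).mean(-1))
    scale = float(rg.mean())
    if n_clusters is not None:
        raw = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")
    elif link[:, 2].max() <= tol_fraction * scale:
        raw = np.ones(nm, dtype=int)
    else:
        raw = hierarchy.fcluster(link, t=height_fraction * link[:, 2].max(),
                                 criterion="distance")
    # relabel by cluster size (largest first), ties by first occurrence
    sizes = {c: np.sum(raw == c) for c in np.unique(raw)}
    order = sorted(sizes, key=lambda c: (-sizes[c], np.argmax(raw == c)))
    labels = np.empty(nm, dtype=int)
    for new, old in enumerate(order):
        labels[raw == old] = new

    centroids = []
    for c in range(len(order)):
        members = np.flatnonzero(labels == c)
        ref = ensemble.coords[members[0]]
        aligned = np.stack([_align_to(ref, ensemble.coords[m]) for m in members])
        mean_coords = aligned.mean(axis=0)
        rmsd_to_mean = [superposed_rmsd(mean_coords, ensemble.coords[m]) for m in members]
        centroids.append(int(members[int(np.argmin(rmsd_to_mean))]))

    return replace(ensemble, cluster_labels=labels, centroid_indices=centroids)


def ensemble_geometry(ensemble: ModelEnsemble) -> dict:
    """Per-model and median chromosome length, width and volume.

    length = distance between the two most distant particles; width =
    2 x radius of gyration; volume = prolate ellipsoid with the length as
    major axis and the width as minor-axis diameter, (4/3) pi (L/2) (W/2)^2,
    reported in um^3.  Medians are taken over per-model values.
    """
    if ensemble.n_particles < 2:
        raise ValueError("need at least 2 particles for geometry")
    dm = ensemble.distance_matrices()
    lengths = dm.reshape(ensemble.n_models, -1).max(axis=1)
    centered = ensemble.coords - ensemble.coords.mean(axis=1, keepdims=True)
    rg = np.sqrt((centered ** 2).sum(-1).mean(-1))
    widths = 2.0 * rg
    volumes_nm3 = (4.0 / 3.0) * np.pi * (lengths / 2.0) * (widths / 2.0) ** 2
    volumes = volumes_nm3 * 1e-9  # nm^3 -> um^3
    return {
        "length_nm": lengths,
        "width_nm": widths,
        "volume_um3": volumes,
        "median_length_nm": float(np.median(lengths)),
        "median_width_nm": float(np.median(widths)),
        "median_volume_um3": float(np.median(volumes)),
    }


def model_contact_map(
    ensemble: ModelEnsemble,
    contact_cutoff: float = 225.0,
    reference: ContactMatrix | None = None,
) -> tuple:
    """Ensemble contact map: fraction of models with particles closer than cutoff.

    The default cutoff is the midpoint of the attract-restraint
    equilibrium range under the default configuration (sum of radii 201 nm
    to proximal distance 250 nm), i.e. the distance scale the restraints
    define as "in contact".  Returns ``(matrix, correlation)``; the
    Pearson correlation with the reference map (over its non-blacklisted
    off-diagonal pairs) is None when no reference is given.
    """
    if contact_cutoff <= 0:
        raise ValueError("contact_cutoff must be positive")
    dm = ensemble.distance_matrices()
    frac = (dm < contact_cutoff).mean(axis=0)
    np.fill_diagonal(frac, 1.0)
    corr = None
    if reference is not None:
        mask = reference.pair_mask(include_diagonal=False)
        iu = np.triu(mask, 1)
        a, b = frac[iu], reference.values[iu]
        if np.std(a) == 0 or np.std(b) == 0:
            raise ValueError("undefined correlation: degenerate constant map")
        corr = float(stats.pearsonr(a, b)[0])
    return frac, corr


def locus_distances(ensemble: ModelEnsemble, loci) -> dict:
    """Median pairwise distances (nm) between selected loci across models."""
    loci = [int(x) for x in loci]
    for x in loci:
        if not 0 <= x < ensemble.n_particles:
            raise IndexError(f"locus {x} outside particle range")
    sub = ensemble.coords[:, loci, :]
    diff = sub[:, :, None, :] - sub[:, None, :, :]
    d = np.sqrt((diff ** 2).sum(-1))
    return {"loci": loci, "distances": d, "median": np.median(d, axis=0)}


def center_of_mass_profile(ensemble: ModelEnsemble) -> dict:
    """Distance of each particle to the conformation's centre of mass."""
    centered = ensemble.coords - ensemble.coords.mean(axis=1, keepdims=True)
    prof = np.sqrt((centered ** 2).sum(-1))
    return {"per_model": prof, "median": np.median(prof, axis=0)}
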